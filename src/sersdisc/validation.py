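"""Leave-one-out cross-validation, confusion accounting, and diagnostics.

Every fold refits the full model chain — dimensionality reduction plus
discriminant — on the n−1 retained samples before predicting the held-out
one, so no statistic ever sees the held-out row (the default; a config
switch reproduces the laxer fit-projection-once alternative for
sensitivity analysis). The positive class is the patient group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from . import chemometrics as chem
from .exceptions import FoldError, ReportError
from .types import CONTROL, PATIENT, SpectralDataset

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "MethodSpec",
    "EvaluationReport",
    "loocv",
    "compute_metrics",
    "train_test_gap",
]

METHOD_NAMES = ("pca_lda", "plsda", "pca_svm", "svm_raw", "lda_raw")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies with patient as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ReportError(f"confusion count {name}={v!r} must be a "
                                  "nonnegative integer")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Accuracy/precision/sensitivity/specificity as exact percentages.

    Values are kept as :class:`fractions.Fraction` on the 0–100 scale so
    presentation rounding (half-up, one decimal) is exact; a metric whose
    denominator is zero is ``None`` (explicitly not available, never 0).
    """

    accuracy: Fraction | None
    precision: Fraction | None
    sensitivity: Fraction | None
    specificity: Fraction | None

    def as_floats(self) -> dict:
        return {
            k: (None if v is None else float(v))
            for k, v in self.__dict__.items()
        }


def compute_metrics(confusion: ConfusionCounts) -> MetricSet:
    """Standard two-class metrics from confusion counts, exact rationals.

    accuracy = 100(TP+TN)/n, precision = 100·TP/(TP+FP),
    sensitivity = 100·TP/(TP+FN), specificity = 100·TN/(TN+FP).
    Zero-denominator ratios are returned as None.
    """
    n = confusion.total
    if n == 0:
        raise ReportError("empty evaluation: all confusion counts are zero")

    def ratio(num: int, den: int) -> Fraction | None:
        return None if den == 0 else Fraction(100 * num, den)

    return MetricSet(
        accuracy=ratio(confusion.tp + confusion.tn, n),
        precision=ratio(confusion.tp, confusion.tp + confusion.fp),
        sensitivity=ratio(confusion.tp, confusion.tp + confusion.fn),
        specificity=ratio(confusion.tn, confusion.tn + confusion.fp),
    )


@dataclass(frozen=True)
class MethodSpec:
    """A discrimination method plus its hyperparameters.

    ``name`` ∈ {pca_lda, plsda, pca_svm, svm_raw, lda_raw};
    ``n_components`` applies to the projection step (default 2, the
    robust small-sample choice), ``cost`` to the SVM, ``regularization``
    to LDA (None = automatic scaled ridge). ``band`` is a free-text tag
    naming the wavenumber window the dataset was restricted to.
    """

    name: str
    n_components: int = 2
    cost: float = 1.0
    regularization: float | None = None
    band: str = "full"

    def __post_init__(self) -> None:
        if self.name not in METHOD_NAMES:
            raise ValueError(
                f"unknown method {self.name!r}; choose from {METHOD_NAMES}"
            )

    def describe(self) -> str:
        bits = [self.name, f"band={self.band}"]
        if self.name in ("pca_lda", "plsda", "pca_svm"):
            bits.append(f"n_components={self.n_components}")
        if "svm" in self.name:
            bits.append(f"cost={self.cost}")
        return " ".join(bits)


@dataclass
class EvaluationReport:
    """LOOCV outcome: per-sample predictions, confusion counts, metrics."""

    sample_ids: np.ndarray
    true_labels: np.ndarray
    predicted_labels: np.ndarray
    confusion: ConfusionCounts
    metrics: MetricSet
    method: MethodSpec
    cv: str = "loocv"
    fold_models: list | None = None

    def __post_init__(self) -> None:
        if self.confusion.total != len(self.sample_ids):
            raise ReportError(
                f"confusion counts sum to {self.confusion.total} but there "
                f"are {len(self.sample_ids)} samples"
            )


@dataclass
class FittedChain:
    """One fold's fitted model chain (projection may be None for raw methods)."""

    projection: chem.ProjectionModel | None
    discriminant: chem.DiscriminantModel | None
    method: MethodSpec


def _lda_raw_fit(X: np.ndarray, labels: np.ndarray,
                 regularization: float | None) -> chem.DiscriminantModel:
    """Fisher LDA directly on wavenumber space (p ≫ n).

    The ridge-regularized scatter solve (S_w + λI)⁻¹ δ is carried out in
    sample space via the Woodbury identity, avoiding a p × p factorization.
    """
    labels = np.asarray(labels, dtype=object)
    mneg = labels == CONTROL
    mpos = labels == PATIENT
    mu_neg = X[mneg].mean(axis=0)
    mu_pos = X[mpos].mean(axis=0)
    Z = np.vstack([X[mneg] - mu_neg, X[mpos] - mu_pos])  # S_w = ZᵀZ
    d = X.shape[1]
    if regularization is None:
        regularization = 1e-8 * float((Z**2).sum()) / d
    lam = max(regularization, 1e-12)
    delta = mu_pos - mu_neg
    n = Z.shape[0]
    # (λI + ZᵀZ)⁻¹ δ = (δ − Zᵀ (λI_n + Z Zᵀ)⁻¹ Z δ)/λ
    small = lam * np.eye(n) + Z @ Z.T
    direction = (delta - Z.T @ np.linalg.solve(small, Z @ delta)) / lam
    s = X @ direction
    s_neg, s_pos = s[mneg], s[mpos]
    m_neg, m_pos = s_neg.mean(), s_pos.mean()
    n_neg, n_pos = s_neg.size, s_pos.size
    pooled_var = (((s_neg - m_neg) ** 2).sum() + ((s_pos - m_pos) ** 2).sum()) / (
        n_neg + n_pos - 2
    )
    prior_neg = n_neg / (n_neg + n_pos)
    threshold = 0.5 * (m_neg + m_pos)
    if pooled_var > 0 and m_pos != m_neg:
        threshold += pooled_var * np.log(prior_neg / (1 - prior_neg)) / (
            m_pos - m_neg
        )
    return chem.DiscriminantModel(
        direction=direction,
        threshold=float(threshold),
        class_order=(CONTROL, PATIENT),
        priors=(prior_neg, 1 - prior_neg),
        kind="lda",
    )


def fit_chain(X: np.ndarray, labels: np.ndarray, method: MethodSpec) -> FittedChain:
    """Fit the projection + discriminant chain for one method on (X, labels)."""
    if method.name == "pca_lda":
        proj = chem.pca_fit(X, method.n_components)
        scores = chem.pca_project(proj, X)
        disc = chem.lda_fit(scores, labels, method.regularization)
        return FittedChain(proj, disc, method)
    if method.name == "pca_svm":
        proj = chem.pca_fit(X, method.n_components)
        scores = chem.pca_project(proj, X)
        disc = chem.svm_fit_linear(scores, labels, cost=method.cost)
        return FittedChain(proj, disc, method)
    if method.name == "plsda":
        proj = chem.plsda_fit(X, labels, n_components=method.n_components)
        return FittedChain(proj, None, method)
    if method.name == "svm_raw":
        disc = chem.svm_fit_linear(X, labels, cost=method.cost)
        return FittedChain(None, disc, method)
    if method.name == "lda_raw":
        disc = _lda_raw_fit(X, labels, method.regularization)
        return FittedChain(None, disc, method)
    raise ValueError(f"unknown method {method.name!r}")


def predict_chain(chain: FittedChain, X: np.ndarray) -> np.ndarray:
    """Predict class labels for rows of X with a fitted chain."""
    if chain.method.name == "plsda":
        return chem.plsda_predict(chain.projection, X)
    scores = X
    if chain.projection is not None:
        scores = chem.pca_project(chain.projection, X)
    return chem.lda_predict(chain.discriminant, scores)


def confusion_from_predictions(
    true_labels: np.ndarray, predicted: np.ndarray
) -> ConfusionCounts:
    true_labels = np.asarray(true_labels, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    return ConfusionCounts(
        tp=int(np.sum((true_labels == PATIENT) & (predicted == PATIENT))),
        tn=int(np.sum((true_labels == CONTROL) & (predicted == CONTROL))),
        fp=int(np.sum((true_labels == CONTROL) & (predicted == PATIENT))),
        fn=int(np.sum((true_labels == PATIENT) & (predicted == CONTROL))),
    )


def loocv(
    dataset: SpectralDataset,
    method: MethodSpec,
    refit_projection: bool = True,
    return_models: bool = False,
) -> EvaluationReport:
    """Leave-one-out cross-validation of a discrimination method.

    For each sample i the full chain is refit on the n−1 remaining
    samples and applied to sample i. With ``refit_projection=False`` the
    projection (PCA/PLS) is fit once on the full dataset and only the
    discriminant is refit per fold — the laxer alternative, provided for
    sensitivity analysis and stamped into the report's ``cv`` field.

    Raises :class:`FoldError` if removing a sample leaves a fold without
    any sample of one class.
    """
    n = dataset.n_samples
    if n < 3:
        raise ValueError(f"LOOCV needs n ≥ 3, got {n}")
    if not dataset.has_both_classes():
        raise FoldError("dataset must contain both classes")
    X = dataset.matrix
    labels = dataset.labels

    global_proj = None
    if not refit_projection:
        if method.name == "plsda":
            global_proj = chem.plsda_fit(X, labels, method.n_components)
        elif method.name in ("pca_lda", "pca_svm"):
            global_proj = chem.pca_fit(X, method.n_components)

    predictions = np.empty(n, dtype=object)
    models: list = []
    for i in range(n):
        keep = np.arange(n) != i
        train_labels = labels[keep]
        for cls in (CONTROL, PATIENT):
            if np.sum(train_labels == cls) < 1:
                raise FoldError(
                    f"fold holding out sample {dataset.sample_ids[i]!r} "
                    f"loses the entire {cls!r} class"
                )
        Xtr = X[keep]
        if refit_projection or global_proj is None:
            chain = fit_chain(Xtr, train_labels, method)
        else:
            # projection frozen; only the discriminant refits per fold
            if method.name == "plsda":
                chain = FittedChain(global_proj, None, method)
            else:
                scores = chem.pca_project(global_proj, Xtr)
                if method.name == "pca_lda":
                    disc = chem.lda_fit(scores, train_labels,
                                        method.regularization)
                else:
                    disc = chem.svm_fit_linear(scores, train_labels,
                                               cost=method.cost)
                chain = FittedChain(global_proj, disc, method)
        predictions[i] = predict_chain(chain, X[i : i + 1])[0]
        if return_models:
            models.append(chain)

    confusion = confusion_from_predictions(labels, predictions)
    return EvaluationReport(
        sample_ids=dataset.sample_ids.copy(),
        true_labels=labels.copy(),
        predicted_labels=predictions,
        confusion=confusion,
        metrics=compute_metrics(confusion),
        method=method,
        cv="loocv" if refit_projection else "loocv(projection fit once)",
        fold_models=models if return_models else None,
    )


def train_test_gap(
    dataset: SpectralDataset,
    method: MethodSpec,
    component_grid: list[int],
) -> list[dict]:
    """Train-vs-LOOCV accuracy across component counts.

    For each setting, reports the mean training-fold accuracy, the LOOCV
    accuracy, and their gap — the overfitting diagnostic: with few
    components the two are nearly equal, with many the gap widens.
    """
    out = []
    n = dataset.n_samples
    for k in component_grid:
        mspec = MethodSpec(
            name=method.name,
            n_components=k,
            cost=method.cost,
            regularization=method.regularization,
            band=method.band,
        )
        report = loocv(dataset, mspec, return_models=True)
        train_accs = []
        for i, chain in enumerate(report.fold_models):
            keep = np.arange(n) != i
            pred = predict_chain(chain, dataset.matrix[keep])
            train_accs.append(
                float(np.mean(pred == dataset.labels[keep]))
            )
        loocv_acc = float(report.confusion.tp + report.confusion.tn) / n
        train_acc = float(np.mean(train_accs))
        out.append(
            {
                "n_components": k,
                "train_accuracy": train_acc,
                "loocv_accuracy": loocv_acc,
                "gap": train_acc - loocv_acc,
            }
        )
    return out
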