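"""Linear chemometrics implemented from first principles.

This module is the analytical core of the package: principal component
analysis via SVD, two-class Fisher linear discriminant analysis, NIPALS
PLS1 discriminant analysis with Wold VIP scores, and a soft-margin linear
support-vector machine. Everything is deterministic given the input
matrix; no randomized initialization anywhere.

Conventions
-----------
* The positive class is ``"patient"`` throughout (it maps to y = 1 in the
  PLS class indicator and to the ``+`` side of every decision rule).
* PCA component signs are fixed so the loading entry of largest magnitude
  is positive.
* Ties on a decision boundary go to the class with the larger prior;
  at equal priors, to the negative class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConvergenceError, RankError, SingularScatterError
from .types import CONTROL, PATIENT

__all__ = [
    "ProjectionModel",
    "DiscriminantModel",
    "VipProfile",
    "pca_fit",
    "pca_project",
    "lda_fit",
    "lda_predict",
    "plsda_fit",
    "plsda_predict",
    "plsda_decision",
    "vip_scores",
    "svm_fit_linear",
]

_RANK_TOL = 1e-10


@dataclass
class ProjectionModel:
    """Fitted dimensionality-reduction state for PCA or PLS.

    For PCA: `loadings` are orthonormal right-singular vectors (columns),
    `explained_variance_ratio` the per-component variance fractions.
    For PLS: the NIPALS weight/score/loading vectors and the regression
    vector `coef` (on centered X) plus `intercept` are stored; the
    `explained_variance_ratio` slot holds the fraction of y-variance
    explained per component.
    """

    kind: str  # "pca" | "pls"
    center: np.ndarray
    loadings: np.ndarray  # p × k (PCA loadings, or PLS x-loadings P)
    explained_variance_ratio: np.ndarray
    # PLS internals (None for PCA)
    x_weights: np.ndarray | None = None  # W, p × k
    x_scores: np.ndarray | None = None  # T, n × k
    y_loadings: np.ndarray | None = None  # q, length k
    coef: np.ndarray | None = None  # regression vector on centered X
    intercept: float | None = None
    y_mean: float | None = None
    class_order: tuple = (CONTROL, PATIENT)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class DiscriminantModel:
    """Linear two-class decision rule in a (projected) feature space.

    Predicts the positive class iff ``scores · direction > threshold``;
    exact ties go to the larger-prior class, negative at equal priors.
    """

    direction: np.ndarray
    threshold: float
    class_order: tuple = (CONTROL, PATIENT)  # (negative, positive)
    priors: tuple = (0.5, 0.5)
    kind: str = "lda"


@dataclass
class VipProfile:
    """Variable importance in projection, one score per wavenumber.

    Normalized so the squared scores average to one (Σ VIP² = p);
    VIP > `threshold` (conventionally 1.0) flags influential variables.
    """

    wavenumber: np.ndarray
    vip: np.ndarray
    threshold: float = 1.0

    def important_mask(self) -> np.ndarray:
        return self.vip > self.threshold


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_fit(matrix: np.ndarray, n_components: int) -> ProjectionModel:
    """PCA of a samples × wavenumbers matrix via SVD of the centered data.

    Singular-value decomposition of the column-centered matrix is used
    rather than an eigendecomposition of the covariance, for numerical
    stability. Component signs are fixed so each loading's
    largest-magnitude entry is positive.

    Raises
    ------
    RankError
        If the centered matrix has numerical rank below `n_components`.
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if n < 2:
        raise RankError("PCA needs at least 2 samples")
    if n_components < 1 or n_components > min(n - 1, p):
        raise RankError(
            f"n_components={n_components} not in [1, min(n−1, p)] = "
            f"[1, {min(n - 1, p)}]"
        )
    center = X.mean(axis=0)
    Xc = X - center
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > _RANK_TOL * s[0])) if s.size and s[0] > 0 else 0
    if rank < n_components:
        raise RankError(
            f"data rank {rank} < requested n_components {n_components}"
        )
    total = np.sum(s**2)
    ratio = (s**2 / total)[:n_components]
    V = Vt[:n_components].T  # p × k
    # deterministic sign: largest-|entry| of each loading made positive
    for k in range(V.shape[1]):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    return ProjectionModel(
        kind="pca",
        center=center,
        loadings=V,
        explained_variance_ratio=ratio,
    )


def pca_project(model: ProjectionModel, matrix: np.ndarray) -> np.ndarray:
    """Project samples onto the fitted components: (X − center) · loadings."""
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    if X.shape[1] != model.center.size:
        raise ValueError(
            f"matrix has {X.shape[1]} columns, model expects {model.center.size}"
        )
    return (X - model.center) @ model.loadings


# ---------------------------------------------------------------------------
# Fisher LDA
# ---------------------------------------------------------------------------

def _split_classes(labels: np.ndarray, class_order: tuple) -> tuple:
    labels = np.asarray(labels, dtype=object)
    neg, pos = class_order
    mneg = labels == neg
    mpos = labels == pos
    if mneg.sum() < 1 or mpos.sum() < 1:
        raise ValueError(
            f"both classes must be present, got {neg}:{int(mneg.sum())} "
            f"{pos}:{int(mpos.sum())}"
        )
    extra = ~(mneg | mpos)
    if extra.any():
        raise ValueError(f"unknown label {labels[extra][0]!r}")
    return mneg, mpos


def lda_fit(
    scores: np.ndarray,
    labels: np.ndarray,
    regularization: float | None = None,
    class_order: tuple = (CONTROL, PATIENT),
) -> DiscriminantModel:
    """Two-class Fisher discriminant in a low-dimensional score space.

    The discriminant direction maximizes the ratio of between-class to
    within-class variance: ``direction = (S_w + λI)⁻¹ (μ_pos − μ_neg)``
    with S_w the pooled within-class scatter. The decision threshold is
    placed where the two projected class-conditional Gaussians (shared
    variance, empirical priors) have equal posterior.

    `regularization` defaults to ``1e−8 · trace(S_w)/d``, enough to keep
    degenerate cross-validation folds solvable; pass 0 to disable (a
    singular scatter then raises :class:`SingularScatterError`).
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    mneg, mpos = _split_classes(labels, class_order)
    d = X.shape[1]
    mu_neg = X[mneg].mean(axis=0)
    mu_pos = X[mpos].mean(axis=0)
    Xn = X[mneg] - mu_neg
    Xp = X[mpos] - mu_pos
    Sw = Xn.T @ Xn + Xp.T @ Xp
    if regularization is None:
        regularization = 1e-8 * np.trace(Sw) / d
    A = Sw + regularization * np.eye(d)
    try:
        direction = np.linalg.solve(A, mu_pos - mu_neg)
    except np.linalg.LinAlgError as exc:
        raise SingularScatterError(
            "within-class scatter is singular; supply regularization > 0"
        ) from exc
    if not np.all(np.isfinite(direction)) or np.allclose(direction, 0):
        raise SingularScatterError(
            "within-class scatter is singular; supply regularization > 0"
        )
    # threshold from 1-D projected Gaussians with shared variance
    s = X @ direction
    s_neg, s_pos = s[mneg], s[mpos]
    m_neg, m_pos = s_neg.mean(), s_pos.mean()
    n_neg, n_pos = s_neg.size, s_pos.size
    pooled_var = (
        ((s_neg - m_neg) ** 2).sum() + ((s_pos - m_pos) ** 2).sum()
    ) / max(n_neg + n_pos - 2, 1)
    prior_neg = n_neg / (n_neg + n_pos)
    prior_pos = 1.0 - prior_neg
    midpoint = 0.5 * (m_neg + m_pos)
    if pooled_var > 0 and m_pos != m_neg:
        threshold = midpoint + pooled_var * np.log(prior_neg / prior_pos) / (
            m_pos - m_neg
        )
    else:
        threshold = midpoint
    return DiscriminantModel(
        direction=direction,
        threshold=float(threshold),
        class_order=class_order,
        priors=(prior_neg, prior_pos),
        kind="lda",
    )


def lda_predict(model: DiscriminantModel, scores: np.ndarray) -> np.ndarray:
    """Classify score rows with a fitted linear rule.

    Positive class iff ``scores · direction > threshold``; exact ties go
    to the larger-prior class (negative class at equal priors).
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    s = X @ model.direction
    neg, pos = model.class_order
    out = np.where(s > model.threshold, pos, neg).astype(object)
    ties = s == model.threshold
    if ties.any():
        tie_class = pos if model.priors[1] > model.priors[0] else neg
        out[ties] = tie_class
    return out


# ---------------------------------------------------------------------------
# PLS-DA (NIPALS PLS1) and VIP
# ---------------------------------------------------------------------------

def plsda_fit(
    matrix: np.ndarray,
    labels: np.ndarray,
    n_components: int = 2,
    max_iter: int = 500,
    tol: float = 1e-10,
    class_order: tuple = (CONTROL, PATIENT),
) -> ProjectionModel:
    """Partial least squares against a {0, 1} class indicator (PLS1, NIPALS).

    X is column-centered and y is the centered indicator (positive class
    → 1). Per component: weight w ∝ Xᵀy, score t = Xw, x-loading
    p = Xᵀt/(tᵀt), y-loading q = yᵀt/(tᵀt); X and y are deflated by the
    rank-one fits. The regression vector B = W (PᵀW)⁻¹ q predicts the
    indicator; `explained_variance_ratio` holds per-component fractions
    of y-variance explained.

    With a univariate y, the NIPALS inner loop converges in a single pass;
    the iteration cap exists for the general contract.
    """
    X = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels, dtype=object)
    neg, pos = class_order
    y = np.where(labels == pos, 1.0, 0.0)
    if np.all(y == y[0]):
        raise ValueError("class indicator has zero variance (single class)")
    n, p = X.shape
    if n_components < 1:
        raise RankError("n_components must be ≥ 1")
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xd = X - x_mean
    yd = y - y_mean
    ss_y_total = float(yd @ yd)
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    ssy = np.zeros(n_components)
    for a in range(n_components):
        w = Xd.T @ yd
        wnorm = np.linalg.norm(w)
        if wnorm <= _RANK_TOL:
            raise RankError(
                f"X rank exhausted after {a} PLS components "
                f"(requested {n_components})"
            )
        w /= wnorm
        # NIPALS inner loop (single-pass convergence for univariate y)
        for _ in range(max_iter):
            t = Xd @ w
            tt = float(t @ t)
            if tt <= _RANK_TOL:
                raise RankError(
                    f"degenerate score at PLS component {a + 1}"
                )
            w_new = Xd.T @ yd
            w_new /= np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
        else:
            raise ConvergenceError(
                f"NIPALS failed to converge in {max_iter} iterations"
            )
        t = Xd @ w
        tt = float(t @ t)
        p_a = Xd.T @ t / tt
        q_a = float(yd @ t / tt)
        Xd = Xd - np.outer(t, p_a)
        yd = yd - q_a * t
        W[:, a] = w
        P[:, a] = p_a
        T[:, a] = t
        q[a] = q_a
        ssy[a] = q_a**2 * tt
    coef = W @ np.linalg.solve(P.T @ W, q)
    return ProjectionModel(
        kind="pls",
        center=x_mean,
        loadings=P,
        explained_variance_ratio=ssy / ss_y_total,
        x_weights=W,
        x_scores=T,
        y_loadings=q,
        coef=coef,
        intercept=float(y_mean),
        y_mean=float(y_mean),
        class_order=class_order,
    )


def plsda_decision(model: ProjectionModel, matrix: np.ndarray) -> np.ndarray:
    """Continuous PLS prediction of the class indicator ŷ ∈ ℝ."""
    if model.kind != "pls":
        raise ValueError("model is not a PLS fit")
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    if X.shape[1] != model.center.size:
        raise ValueError(
            f"matrix has {X.shape[1]} columns, model expects {model.center.size}"
        )
    return (X - model.center) @ model.coef + model.intercept


def plsda_predict(model: ProjectionModel, matrix: np.ndarray) -> np.ndarray:
    """Classify by cutting the indicator prediction at 0.5 (ties → negative)."""
    yhat = plsda_decision(model, matrix)
    neg, pos = model.class_order
    return np.where(yhat > 0.5, pos, neg).astype(object)


def vip_scores(model: ProjectionModel, wavenumber: np.ndarray | None = None,
               threshold: float = 1.0) -> VipProfile:
    """Wold VIP scores from a fitted PLS model.

    ``VIP_j = sqrt( p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a )`` where
    SSY_a is the y-variance explained by component a. The squared scores
    sum to p, so they average to one; VIP > 1 is the conventional cut for
    important wavenumbers.
    """
    if model.kind != "pls" or model.x_weights is None:
        raise ValueError("VIP scores require a fitted PLS model")
    W = model.x_weights
    p = W.shape[0]
    ssy = model.explained_variance_ratio  # proportional to SSY_a
    wnorm2 = (W**2).sum(axis=0)
    contrib = (W**2 / wnorm2) @ ssy  # p-vector
    vip = np.sqrt(p * contrib / ssy.sum())
    if wavenumber is None:
        wavenumber = np.arange(p, dtype=float)
    return VipProfile(
        wavenumber=np.asarray(wavenumber, dtype=float),
        vip=vip,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Linear SVM
# ---------------------------------------------------------------------------

def svm_fit_linear(
    scores: np.ndarray,
    labels: np.ndarray,
    cost: float = 1.0,
    class_order: tuple = (CONTROL, PATIENT),
    max_iter: int = 100_000,
    tol: float = 1e-8,
) -> DiscriminantModel:
    """Soft-margin linear SVM via SMO on the exact dual program.

    Minimizes ``½ αᵀQα − Σα`` with ``Q_ij = y_i y_j ⟨x_i, x_j⟩`` subject
    to 0 ≤ α ≤ cost and Σ α_i y_i = 0, by sequential minimal
    optimization with maximal-violating-pair working-set selection
    (LIBSVM-style). Deterministic: ties in pair selection resolve to the
    lowest index. The decision rule is sign(w·x + b) with
    w = Σ α_i y_i x_i and b the KKT midpoint (averaged over free support
    vectors when any exist); stored as a :class:`DiscriminantModel` with
    ``threshold = −b``.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels, dtype=object)
    neg, pos = class_order
    y = np.where(labels == pos, 1.0, -1.0)
    if np.all(y == y[0]):
        raise ValueError("SVM needs two classes")
    if not cost > 0:
        raise ValueError(f"cost must be > 0, got {cost}")
    n = X.shape[0]
    K = X @ X.T
    Q = K * np.outer(y, y)
    alpha = np.zeros(n)
    grad = -np.ones(n)  # ∇(½αᵀQα − Σα) at α = 0

    for it in range(max_iter):
        # I_up: α can grow along +y direction; I_low: can shrink
        up = ((y > 0) & (alpha < cost)) | ((y < 0) & (alpha > 0))
        low = ((y > 0) & (alpha > 0)) | ((y < 0) & (alpha < cost))
        yg = -y * grad
        m_up = np.where(up, yg, -np.inf)
        m_low = np.where(low, yg, np.inf)
        i = int(np.argmax(m_up))
        j = int(np.argmin(m_low))
        if m_up[i] - m_low[j] <= tol:
            break
        # analytic minimization over the (i, j) pair
        quad = Q[i, i] + Q[j, j] - 2.0 * y[i] * y[j] * Q[i, j]
        quad = max(quad, 1e-12)
        delta = (m_up[i] - m_low[j]) / quad
        # bounds on the step along (+y_i, −y_j)
        step_i = (cost - alpha[i]) if y[i] > 0 else alpha[i]
        step_j = alpha[j] if y[j] > 0 else (cost - alpha[j])
        step = min(delta, step_i, step_j)
        alpha[i] += y[i] * step
        alpha[j] -= y[j] * step
        grad += step * (y[i] * Q[:, i] - y[j] * Q[:, j])
        alpha[i] = min(max(alpha[i], 0.0), cost)
        alpha[j] = min(max(alpha[j], 0.0), cost)
    else:
        raise ConvergenceError(
            f"SVM SMO did not converge within {max_iter} iterations"
        )

    w = (alpha * y) @ X
    free = (alpha > 1e-8 * cost) & (alpha < cost * (1 - 1e-8))
    if free.any():
        b = float(np.mean(y[free] - X[free] @ w))
    else:
        # KKT midpoint between the boundary sets
        up = ((y > 0) & (alpha < cost)) | ((y < 0) & (alpha > 0))
        low = ((y > 0) & (alpha > 0)) | ((y < 0) & (alpha < cost))
        yg = -y * grad
        hi = np.max(yg[up]) if up.any() else 0.0
        lo = np.min(yg[low]) if low.any() else 0.0
        b = float((hi + lo) / 2.0)
    n_pos = int((y > 0).sum())
    return DiscriminantModel(
        direction=w,
        threshold=-b,
        class_order=class_order,
        priors=((n - n_pos) / n, n_pos / n),
        kind="svm",
    )
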