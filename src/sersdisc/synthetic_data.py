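"""Synthetic two-class SERS-like spectral cohorts.

Blood-derived SERS spectra are dominated by a few dozen vibrational
bands riding on a fluorescence baseline, with per-spectrum multiplicative
gain (scatter), small wavenumber jitter, band-to-band amplitude
variability, and detector noise. The generator emulates exactly that
structure: each spectrum is a sum of Lorentzian (or Gaussian) lines whose
patient-class amplitudes are scaled by per-band multiplicative effects,
plus a random slowly-varying polynomial baseline, a lognormal gain, and
white noise.

The ``plasma`` and ``serum`` presets encode the band inventories and the
direction of every patient-vs-control intensity difference reported for
the two specimen types, at cohort sizes 14 controls / 27 patients
(plasma) and 14 / 29 (serum). A matched ``null`` variant removes every
class effect for FDR and permutation-null experiments.

All randomness flows from the single cohort seed through a fixed
stream-splitting scheme (one child stream per noise source, spawned from
``numpy.random.SeedSequence(seed)`` in a documented order), so the same
seed yields a bit-identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import GridSpec
from .types import CONTROL, PATIENT, SpectralDataset

__all__ = [
    "PeakSpec",
    "CohortSpec",
    "preset_plasma",
    "preset_serum",
    "simulate_cohort",
    "null_cohort",
    "scale_class_effects",
]

#: patient-class amplitude multipliers used by the presets: bands reported
#: as more intense in patients get EFFECT_UP, bands more intense in
#: controls get EFFECT_DOWN. Sized so the default PCA-LDA pipeline lands
#: in the ≥ 90% LOOCV accuracy regime at default noise.
EFFECT_UP = 1.3
EFFECT_DOWN = 0.77

#: fixed Chebyshev coefficients of the shared residual-background shape
#: (vendor-style baseline correction leaves a characteristic slowly-varying
#: remnant common to all spectra), and the sd of the per-spectrum random
#: perturbation of those coefficients.
BASELINE_MEAN_COEF = np.array([1.0, -0.8, 0.4, -0.15])
BASELINE_COEF_SD = 0.05


@dataclass(frozen=True)
class PeakSpec:
    """One vibrational band of the synthetic spectrum.

    `width` is the half-width at half-maximum in cm⁻¹. `class_effect`
    multiplies the amplitude for patient samples (> 1 patient-up, < 1
    patient-down, 1 null). `patient_only` bands contribute nothing to
    control spectra (a multiplicative effect cannot express an exactly
    absent band).
    """

    center: float
    width: float = 8.0
    base_amplitude: float = 0.5
    class_effect: float = 1.0
    shape: str = "lorentzian"
    patient_only: bool = False

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError(f"peak {self.center}: width must be > 0")
        if self.base_amplitude < 0:
            raise ValueError(f"peak {self.center}: base_amplitude must be ≥ 0")
        if not self.class_effect > 0:
            raise ValueError(f"peak {self.center}: class_effect must be > 0")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"peak {self.center}: unknown shape {self.shape!r}")

    def profile(self, grid: np.ndarray, shift: float = 0.0) -> np.ndarray:
        """Unit-amplitude line shape evaluated on `grid`, apex shifted by
        `shift` cm⁻¹."""
        z = (grid - (self.center + shift)) / self.width
        if self.shape == "lorentzian":
            return 1.0 / (1.0 + z**2)
        return np.exp(-np.log(2.0) * z**2)


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort."""

    n_control: int
    n_patient: int
    specimen: str
    peaks: tuple
    grid: GridSpec = field(default_factory=lambda: GridSpec(350.0, 2200.0, 1.0))
    baseline_amp: float = 0.2
    scatter_sd: float = 0.1
    noise_sd: float = 0.02
    jitter_sd: float = 1.0
    amplitude_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_patient < 0:
            raise ValueError("cohort sizes must be ≥ 0")
        for name in ("baseline_amp", "scatter_sd", "noise_sd", "jitter_sd",
                     "amplitude_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")

    def discriminative_centers(self) -> np.ndarray:
        """Centers of every band carrying a planted class difference."""
        return np.array(
            [pk.center for pk in self.peaks
             if pk.class_effect != 1.0 or pk.patient_only],
            dtype=float,
        )


# (center, base_amplitude) for the shared plasma band inventory; the three
# strongest bands of both groups sit at 642, 1136 and 1662 cm⁻¹.
_PLASMA_BANDS = (
    (390, 0.45), (498, 0.40), (596, 0.30), (642, 1.00), (728, 0.45),
    (815, 0.30), (893, 0.30), (1010, 0.50), (1075, 0.35), (1136, 1.00),
    (1209, 0.40), (1256, 0.35), (1336, 0.45), (1369, 0.35), (1406, 0.35),
    (1447, 0.40), (1508, 0.35), (1577, 0.40), (1617, 0.45), (1662, 1.00),
)
_PLASMA_DOWN = {1256, 1336, 1508, 1617, 1662}  # more intense in controls
_PLASMA_UP = {1010, 1209}  # more intense in patients

# serum inventory: the plasma list with the band positions reported for
# serum, plus the patient-only 1099 cm⁻¹ band.
_SERUM_BANDS = (
    (390, 0.45), (498, 0.40), (596, 0.30), (642, 1.00), (728, 0.45),
    (815, 0.30), (893, 0.30), (1010, 0.50), (1075, 0.35), (1099, 0.30),
    (1137, 1.00), (1210, 0.40), (1256, 0.35), (1331, 0.45), (1368, 0.35),
    (1412, 0.35), (1447, 0.40), (1511, 0.35), (1582, 0.40), (1660, 1.00),
)
_SERUM_UP = {498, 642, 815, 893, 1010, 1137, 1210, 1368, 1412}
_SERUM_DOWN = {728, 1331, 1447, 1511, 1582, 1660}
_SERUM_PATIENT_ONLY = {1099}


def _build_peaks(bands, up, down, patient_only=frozenset()):
    peaks = []
    for center, amp in bands:
        if center in patient_only:
            effect, only = EFFECT_UP, True
        elif center in up:
            effect, only = EFFECT_UP, False
        elif center in down:
            effect, only = EFFECT_DOWN, False
        else:
            effect, only = 1.0, False
        peaks.append(
            PeakSpec(center=float(center), base_amplitude=amp,
                     class_effect=effect, patient_only=only)
        )
    return tuple(peaks)


def preset_plasma(seed: int = 0) -> CohortSpec:
    """Plasma-like cohort: 20 bands, 14 controls vs 27 patients.

    Bands at 1256, 1336, 1508, 1617 and 1662 cm⁻¹ are more intense in
    controls; 1010 and 1209 cm⁻¹ are more intense in patients; the three
    strongest bands (642, 1136, 1662 cm⁻¹) are shared by both groups.
    """
    return CohortSpec(
        n_control=14,
        n_patient=27,
        specimen="plasma",
        peaks=_build_peaks(_PLASMA_BANDS, _PLASMA_UP, _PLASMA_DOWN),
        seed=seed,
    )


def preset_serum(seed: int = 0) -> CohortSpec:
    """Serum-like cohort: 14 controls vs 29 patients.

    Patient-up bands at 498, 642, 815, 893, 1010, 1137, 1210, 1368 and
    1412 cm⁻¹; control-up bands at 728, 1331, 1447, 1511, 1582 and
    1660 cm⁻¹; a 1099 cm⁻¹ band present only in patient spectra.
    """
    return CohortSpec(
        n_control=14,
        n_patient=29,
        specimen="serum",
        peaks=_build_peaks(_SERUM_BANDS, _SERUM_UP, _SERUM_DOWN,
                           _SERUM_PATIENT_ONLY),
        seed=seed,
    )


def scale_class_effects(spec: CohortSpec, factor: float) -> CohortSpec:
    """Scale every planted effect's log-magnitude by `factor`.

    ``factor=0`` removes all class structure; ``factor=1`` is the preset
    as-is. Patient-only band amplitudes scale linearly with `factor`.
    Useful for effect-size sweeps and "moderate effect" regimes.
    """
    peaks = tuple(
        replace(
            pk,
            class_effect=float(np.exp(factor * np.log(pk.class_effect))),
            base_amplitude=(pk.base_amplitude * factor
                            if pk.patient_only else pk.base_amplitude),
        )
        for pk in spec.peaks
    )
    return replace(spec, peaks=peaks)


def simulate_cohort(spec: CohortSpec) -> SpectralDataset:
    """Draw one labeled cohort from a :class:`CohortSpec`.

    Each spectrum is
    ``exp(N(0, scatter_sd)) · [Σ_k a_ik · shape_k(w; center_k + δ_i) +
    baseline_i(w)] + N(0, noise_sd)`` per grid node, with
    ``a_ik = base_amplitude_k · class_effect_k^[patient] ·
    exp(N(0, amplitude_cv))`` and a per-spectrum apex shift
    ``δ_i ~ N(0, jitter_sd)``. The baseline is a degree-3 Chebyshev
    polynomial scaled by `baseline_amp`, whose coefficients are a fixed
    shared shape (the characteristic residual left by vendor-style
    background subtraction) plus per-spectrum N(0, 0.05) perturbations.

    Controls come first (ids C01…), patients after (ids P01…); row order
    is deterministic and the whole dataset is a pure function of
    ``spec.seed``.
    """
    grid = spec.grid.nodes()
    n = spec.n_control + spec.n_patient
    k = len(spec.peaks)
    p = grid.size
    labels = np.array(
        [CONTROL] * spec.n_control + [PATIENT] * spec.n_patient, dtype=object
    )
    sample_ids = np.array(
        [f"C{i + 1:02d}" for i in range(spec.n_control)]
        + [f"P{i + 1:02d}" for i in range(spec.n_patient)],
        dtype=object,
    )

    # fixed stream-splitting: one child stream per randomness source
    streams = np.random.SeedSequence(spec.seed).spawn(5)
    rng_amp = np.random.default_rng(streams[0])
    rng_jitter = np.random.default_rng(streams[1])
    rng_baseline = np.random.default_rng(streams[2])
    rng_scatter = np.random.default_rng(streams[3])
    rng_noise = np.random.default_rng(streams[4])

    log_amp = rng_amp.normal(0.0, spec.amplitude_cv, size=(n, k)) \
        if spec.amplitude_cv > 0 else np.zeros((n, k))
    jitter = rng_jitter.normal(0.0, spec.jitter_sd, size=n) \
        if spec.jitter_sd > 0 else np.zeros(n)
    base_coef = BASELINE_MEAN_COEF + rng_baseline.normal(
        0.0, BASELINE_COEF_SD, size=(n, 4)
    )
    gain = np.exp(rng_scatter.normal(0.0, spec.scatter_sd, size=n)) \
        if spec.scatter_sd > 0 else np.ones(n)
    noise = rng_noise.normal(0.0, spec.noise_sd, size=(n, p)) \
        if spec.noise_sd > 0 else np.zeros((n, p))

    is_patient = labels == PATIENT
    u = 2.0 * (grid - grid[0]) / (grid[-1] - grid[0]) - 1.0  # grid → [−1, 1]
    matrix = np.empty((n, p))
    for i in range(n):
        signal = np.zeros(p)
        for j, pk in enumerate(spec.peaks):
            amp = pk.base_amplitude * np.exp(log_amp[i, j])
            if is_patient[i]:
                amp *= pk.class_effect
            elif pk.patient_only:
                amp = 0.0
            if amp != 0.0:
                signal += amp * pk.profile(grid, shift=jitter[i])
        if spec.baseline_amp > 0:
            signal += spec.baseline_amp * np.polynomial.chebyshev.chebval(
                u, base_coef[i]
            )
        matrix[i] = gain[i] * signal + noise[i]

    return SpectralDataset(
        grid=grid,
        matrix=matrix,
        labels=labels,
        specimen=spec.specimen,
        sample_ids=sample_ids,
        provenance=[{"stage": "simulate", "specimen": spec.specimen,
                     "seed": spec.seed, "n_control": spec.n_control,
                     "n_patient": spec.n_patient}],
    )


def null_cohort(spec: CohortSpec) -> SpectralDataset:
    """Simulate with every class effect removed (labels retained).

    All ``class_effect`` values are forced to 1 and patient-only bands
    are dropped, so patient and control spectra share one generating
    distribution — the ground truth for FDR-control and null-accuracy
    experiments.
    """
    peaks = tuple(
        replace(pk, class_effect=1.0)
        for pk in spec.peaks
        if not pk.patient_only
    )
    return simulate_cohort(replace(spec, peaks=peaks))
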