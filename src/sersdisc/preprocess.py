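"""Spectral preprocessing: grid alignment, SNV and area normalization,
asymmetric-least-squares baseline correction, and band restriction.

The pipeline order is resample → (optional baseline) → SNV → band
restriction; each step appends a provenance record to the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .exceptions import BandError, DegenerateSpectrumError, GridRangeError
from .types import SpectralDataset, Spectrum

__all__ = [
    "GridSpec",
    "BandSpec",
    "resample_to_grid",
    "snv_normalize",
    "area_normalize",
    "baseline_correct",
    "restrict_band",
]


@dataclass(frozen=True)
class GridSpec:
    """Uniform wavenumber grid: ``start, start+step, …, stop`` inclusive (cm⁻¹)."""

    start: float
    stop: float
    step: float = 1.0

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError(f"grid start {self.start} must be < stop {self.stop}")
        if not self.step > 0:
            raise ValueError(f"grid step must be > 0, got {self.step}")
        span = (self.stop - self.start) / self.step
        if abs(span - round(span)) > 1e-9:
            raise ValueError(
                f"(stop − start) = {self.stop - self.start} is not an integer "
                f"multiple of step {self.step}"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    def nodes(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_points)


@dataclass(frozen=True)
class BandSpec:
    """One or more closed wavenumber intervals [low, high] (cm⁻¹),
    sorted and non-overlapping."""

    intervals: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ivs = tuple((float(lo), float(hi)) for lo, hi in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        for lo, hi in ivs:
            if not lo < hi:
                raise BandError(f"band ({lo}, {hi}): low must be < high")
        for (lo1, hi1), (lo2, hi2) in zip(ivs, ivs[1:]):
            if lo2 <= hi1:
                raise BandError(
                    f"bands ({lo1}, {hi1}) and ({lo2}, {hi2}) overlap or are "
                    "unsorted"
                )

    def mask(self, grid: np.ndarray) -> np.ndarray:
        """Boolean mask of grid nodes inside any interval (endpoints inclusive)."""
        grid = np.asarray(grid, dtype=float)
        m = np.zeros(grid.shape, dtype=bool)
        for lo, hi in self.intervals:
            m |= (grid >= lo) & (grid <= hi)
        return m


def resample_to_grid(spectrum: Spectrum, grid: GridSpec) -> Spectrum:
    """Linearly interpolate a spectrum onto a uniform grid.

    The target grid must be fully contained in the spectrum's native range;
    no extrapolation is performed.
    """
    lo, hi = spectrum.wavenumbers[0], spectrum.wavenumbers[-1]
    if grid.start < lo - 1e-9 or grid.stop > hi + 1e-9:
        raise GridRangeError(
            f"sample {spectrum.sample_id!r}: target grid [{grid.start}, "
            f"{grid.stop}] extends beyond native range [{lo:g}, {hi:g}]"
        )
    nodes = grid.nodes()
    values = np.interp(nodes, spectrum.wavenumbers, spectrum.intensities)
    return Spectrum(
        sample_id=spectrum.sample_id,
        specimen=spectrum.specimen,
        label=spectrum.label,
        wavenumbers=nodes,
        intensities=values,
    )


def snv_normalize(dataset: SpectralDataset, ddof: int = 1) -> SpectralDataset:
    """Standard normal variate: each spectrum shifted to zero mean and
    scaled to unit standard deviation.

    Removes per-spectrum multiplicative scatter and additive offset; the
    standard preprocessing ahead of the multivariate analysis. `ddof=1`
    uses the sample standard deviation (denominator n−1); either convention
    converges for long spectra.
    """
    X = dataset.matrix
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=ddof, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        raise DegenerateSpectrumError(
            f"sample {dataset.sample_ids[zero[0]]!r}: constant spectrum "
            "(zero standard deviation), cannot SNV-normalize"
        )
    return dataset.with_matrix(
        (X - mean) / sd, step={"stage": "snv", "ddof": ddof}
    )


def area_normalize(dataset: SpectralDataset, band: BandSpec) -> SpectralDataset:
    """Divide each spectrum by its trapezoidal integral over `band`.

    Used for figure-style mean spectra (area under the curve over the
    350–2200 cm⁻¹ window equal to one); the multivariate chain uses SNV
    instead.
    """
    m = band.mask(dataset.grid)
    if m.sum() < 2:
        raise BandError("area band selects fewer than 2 grid nodes")
    areas = np.trapezoid(dataset.matrix[:, m], dataset.grid[m], axis=1)
    bad = np.flatnonzero(areas <= 0)
    if bad.size:
        raise DegenerateSpectrumError(
            f"sample {dataset.sample_ids[bad[0]]!r}: non-positive area "
            f"{areas[bad[0]]:g} over band, cannot area-normalize"
        )
    return dataset.with_matrix(
        dataset.matrix / areas[:, None],
        step={"stage": "area_normalize", "band": band.intervals},
    )


def _als_baseline(y: np.ndarray, lam: float, p_asym: float, iters: int) -> np.ndarray:
    """Asymmetric-least-squares baseline estimate (Eilers-style smoother).

    Minimizes Σ w_i (y_i − z_i)² + lam Σ (Δ²z)² with asymmetric weights
    w_i = p_asym where y > z (peaks) and 1 − p_asym where y ≤ z, iterated
    `iters` times.
    """
    n = y.size
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = lam * (D.T @ D)
    w = np.ones(n)
    z = y
    for _ in range(iters):
        W = sparse.diags(w, 0, format="csc")
        z = spsolve(W + penalty, w * y)
        w = np.where(y > z, p_asym, 1.0 - p_asym)
    return z


def baseline_correct(
    spectrum: Spectrum, lam: float = 1e5, p_asym: float = 0.01, iters: int = 10
) -> Spectrum:
    """Subtract a smooth fluorescence-background estimate from a spectrum.

    Asymmetric least squares: a second-difference-penalized smoother whose
    weights are iteratively biased below the signal, so that peaks sit on
    top of the estimated baseline. Constants and slow ramps lie in the
    smoother's null space and are removed; narrow Raman bands survive.

    Parameters
    ----------
    lam : float
        Smoothness penalty weight (> 0); larger = stiffer baseline.
    p_asym : float
        Asymmetry in (0, 1); weight on points above the baseline.
    iters : int
        Reweighting iterations (≥ 1).
    """
    if not lam > 0:
        raise ValueError(f"lam must be > 0, got {lam}")
    if not 0 < p_asym < 1:
        raise ValueError(f"p_asym must be in (0, 1), got {p_asym}")
    if iters < 1:
        raise ValueError(f"iters must be ≥ 1, got {iters}")
    baseline = _als_baseline(spectrum.intensities, lam, p_asym, iters)
    return Spectrum(
        sample_id=spectrum.sample_id,
        specimen=spectrum.specimen,
        label=spectrum.label,
        wavenumbers=spectrum.wavenumbers.copy(),
        intensities=spectrum.intensities - baseline,
    )


def baseline_correct_dataset(
    dataset: SpectralDataset, lam: float = 1e5, p_asym: float = 0.01, iters: int = 10
) -> SpectralDataset:
    """Apply :func:`baseline_correct` row-wise to a dataset."""
    corrected = np.vstack(
        [
            row - _als_baseline(row, lam, p_asym, iters)
            for row in dataset.matrix
        ]
    )
    return dataset.with_matrix(
        corrected,
        step={"stage": "baseline", "lam": lam, "p_asym": p_asym, "iters": iters},
    )


def restrict_band(dataset: SpectralDataset, band: BandSpec) -> SpectralDataset:
    """Keep exactly the grid columns falling inside `band` (endpoints inclusive)."""
    m = band.mask(dataset.grid)
    if not m.any():
        raise BandError(
            f"band {band.intervals} selects no grid nodes on "
            f"[{dataset.grid[0]:g}, {dataset.grid[-1]:g}]"
        )
    return dataset.with_matrix(
        dataset.matrix[:, m],
        step={"stage": "restrict_band", "band": band.intervals},
        grid=dataset.grid[m],
    )
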