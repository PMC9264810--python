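"""Core data containers shared by every pipeline stage.

A :class:`Spectrum` is one blood-sample SERS record (a wavenumber grid in
cm⁻¹ plus detector intensities, tagged with specimen type and class label).
A :class:`SpectralDataset` is the aligned samples × wavenumbers matrix that
all preprocessing, chemometric and univariate stages operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import SpectraParseError

SPECIMENS = ("plasma", "serum")
CONTROL = "control"
PATIENT = "patient"
LABELS = (CONTROL, PATIENT)


@dataclass(frozen=True)
class Spectrum:
    """One averaged SERS acquisition for a single sample.

    Parameters
    ----------
    sample_id : str
        Opaque sample identifier; preserved verbatim through IO.
    specimen : str
        ``"plasma"`` or ``"serum"``.
    label : str
        ``"control"`` or ``"patient"``.
    wavenumbers : ndarray
        Strictly increasing Raman shifts in cm⁻¹, length ≥ 2, all finite.
    intensities : ndarray
        Detector counts (arbitrary units), same length as `wavenumbers`.
    """

    sample_id: str
    specimen: str
    label: str
    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        x = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", x)
        if self.specimen not in SPECIMENS:
            raise SpectraParseError(
                f"sample {self.sample_id!r}: unknown specimen {self.specimen!r}"
            )
        if self.label not in LABELS:
            raise SpectraParseError(
                f"sample {self.sample_id!r}: unknown label {self.label!r}"
            )
        if w.ndim != 1 or w.size < 2:
            raise SpectraParseError(
                f"sample {self.sample_id!r}: needs ≥ 2 wavenumbers, got {w.size}"
            )
        if not np.all(np.isfinite(w)):
            raise SpectraParseError(
                f"sample {self.sample_id!r}: non-finite wavenumber"
            )
        diffs = np.diff(w)
        if np.any(diffs <= 0):
            bad = w[1:][diffs <= 0][0]
            raise SpectraParseError(
                f"sample {self.sample_id!r}: wavenumbers not strictly increasing "
                f"at {bad:g} cm⁻¹"
            )
        if x.shape != w.shape:
            raise SpectraParseError(
                f"sample {self.sample_id!r}: {x.size} intensities for "
                f"{w.size} wavenumbers"
            )
        if not np.all(np.isfinite(x)):
            raise SpectraParseError(
                f"sample {self.sample_id!r}: non-finite intensity"
            )

    def __len__(self) -> int:
        return int(self.wavenumbers.size)


@dataclass
class SpectralDataset:
    """Aligned spectra: one shared grid, one intensity row per sample.

    The ``provenance`` list records each preprocessing step applied
    (stage name plus parameters) so a run can be replayed.
    """

    grid: np.ndarray
    matrix: np.ndarray
    labels: np.ndarray
    specimen: str
    sample_ids: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.matrix.ndim != 2:
            raise SpectraParseError("matrix must be 2-D (samples × wavenumbers)")
        n, p = self.matrix.shape
        if self.grid.size != p:
            raise SpectraParseError(
                f"grid length {self.grid.size} != matrix columns {p}"
            )
        if self.labels.size != n or self.sample_ids.size != n:
            raise SpectraParseError(
                "labels/sample_ids length must equal matrix row count"
            )

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.matrix.shape[1]

    def class_mask(self, label: str) -> np.ndarray:
        return self.labels == label

    def has_both_classes(self) -> bool:
        return bool(np.any(self.labels == CONTROL) and np.any(self.labels == PATIENT))

    def subset(self, rows: Sequence[int] | np.ndarray) -> "SpectralDataset":
        rows = np.asarray(rows)
        return SpectralDataset(
            grid=self.grid.copy(),
            matrix=self.matrix[rows].copy(),
            labels=self.labels[rows].copy(),
            specimen=self.specimen,
            sample_ids=self.sample_ids[rows].copy(),
            provenance=list(self.provenance),
        )

    def with_matrix(self, matrix: np.ndarray, step: dict | None = None,
                    grid: np.ndarray | None = None) -> "SpectralDataset":
        """Copy with a new intensity matrix (and optionally grid), appending
        a provenance record."""
        prov = list(self.provenance)
        if step is not None:
            prov.append(step)
        out = replace(
            self,
            matrix=np.asarray(matrix, dtype=float),
            grid=self.grid.copy() if grid is None else np.asarray(grid, dtype=float),
        )
        out.provenance = prov
        return out

    def to_spectra(self) -> list[Spectrum]:
        return [
            Spectrum(
                sample_id=str(sid),
                specimen=self.specimen,
                label=str(lab),
                wavenumbers=self.grid.copy(),
                intensities=row.copy(),
            )
            for sid, lab, row in zip(self.sample_ids, self.labels, self.matrix)
        ]


def spectra_to_dataset(spectra: Sequence[Spectrum]) -> SpectralDataset:
    """Stack already-aligned spectra into a dataset.

    All spectra must share an identical wavenumber grid and specimen tag;
    use :func:`sersdisc.preprocess.resample_to_grid` first otherwise.
    File/sample order is preserved.
    """
    if not spectra:
        raise SpectraParseError("no spectra to stack")
    grid = spectra[0].wavenumbers
    specimen = spectra[0].specimen
    for s in spectra[1:]:
        if s.wavenumbers.shape != grid.shape or not np.allclose(
            s.wavenumbers, grid, rtol=0, atol=1e-9
        ):
            raise SpectraParseError(
                f"sample {s.sample_id!r}: grid differs from sample "
                f"{spectra[0].sample_id!r}; resample to a common grid first"
            )
        if s.specimen != specimen:
            raise SpectraParseError(
                f"sample {s.sample_id!r}: specimen {s.specimen!r} mixed with "
                f"{specimen!r}"
            )
    return SpectralDataset(
        grid=grid.copy(),
        matrix=np.vstack([s.intensities for s in spectra]),
        labels=np.array([s.label for s in spectra], dtype=object),
        specimen=specimen,
        sample_ids=np.array([s.sample_id for s in spectra], dtype=object),
    )
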