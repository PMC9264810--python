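"""Reading and writing labeled spectral tables and evaluation reports.

Two plain-text dialects are supported, both delimiter-autodetected
(comma or tab):

* **long** — one row per (sample, wavenumber) observation with columns
  ``sample_id, specimen, label, wavenumber, intensity``;
* **wide** — first column ``wavenumber``, one column per sample, with a
  small YAML/JSON sidecar (``<path>.meta.yaml`` / ``.meta.json``) that
  carries the specimen tag and per-sample labels.

Sample order is preserved exactly as encountered in the file, and
intensities round-trip at full stored precision. Evaluation reports are
written as TSV rows in the Sample / Accuracy / Precision / Sensitivity /
Specificity / True Pos. / True Neg. / False Pos. / False Neg. layout,
percentages rounded half-up to one decimal.
"""

from __future__ import annotations

import json
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ReportError, SpectraParseError
from .types import Spectrum
from .validation import EvaluationReport

__all__ = [
    "read_spectra_table",
    "write_spectra_table",
    "write_report",
    "format_percent",
]

_LONG_COLUMNS = ["sample_id", "specimen", "label", "wavenumber", "intensity"]

REPORT_COLUMNS = [
    "Sample", "Accuracy", "Precision", "Sensitivity", "Specificity",
    "True Pos.", "True Neg.", "False Pos.", "False Neg.",
]


def _detect_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8-sig") as fh:
        header = fh.readline()
    if not header:
        raise SpectraParseError(f"{path}: empty file")
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise SpectraParseError(
        f"{path}: could not detect delimiter (expected comma or tab)"
    )


def _sidecar_path(path: Path) -> Path:
    for ext in (".meta.yaml", ".meta.yml", ".meta.json"):
        cand = Path(str(path) + ext)
        if cand.exists():
            return cand
    raise SpectraParseError(
        f"{path}: wide format needs a metadata sidecar "
        f"({path}.meta.yaml or {path}.meta.json)"
    )


def _read_sidecar(path: Path) -> dict:
    text = path.read_text(encoding="utf-8")
    meta = (json.loads(text) if path.suffix == ".json" else yaml.safe_load(text))
    if not isinstance(meta, dict) or "samples" not in meta or "specimen" not in meta:
        raise SpectraParseError(
            f"{path}: sidecar must be a mapping with 'specimen' and 'samples'"
        )
    return meta


def read_spectra_table(
    path: str | Path,
    format: str,
    sidecar: str | Path | None = None,
) -> list[Spectrum]:
    """Read a long- or wide-format spectral table into validated records.

    Every :class:`~sersdisc.types.Spectrum` invariant (strictly
    increasing finite wavenumbers, finite intensities, known
    specimen/label) is enforced; violations raise
    :class:`~sersdisc.exceptions.SpectraParseError` naming the offending
    sample or wavenumber.
    """
    path = Path(path)
    if not path.exists():
        raise SpectraParseError(f"{path}: no such file")
    if format not in ("long", "wide"):
        raise SpectraParseError(f"unknown table format {format!r}")
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, encoding="utf-8-sig",
                     float_precision="round_trip")
    if format == "long":
        return _spectra_from_long(df, path)
    meta_path = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    return _spectra_from_wide(df, _read_sidecar(meta_path), path)


def _spectra_from_long(df: pd.DataFrame, path: Path) -> list[Spectrum]:
    missing = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing:
        raise SpectraParseError(f"{path}: long format missing columns {missing}")
    if df[["sample_id", "specimen", "label"]].isna().any().any():
        row = int(df[["sample_id", "specimen", "label"]].isna().any(axis=1).idxmax())
        raise SpectraParseError(
            f"{path}: missing metadata on data row {row + 1}"
        )
    spectra = []
    for sid in pd.unique(df["sample_id"]):  # file order preserved
        sub = df[df["sample_id"] == sid]
        specimen = sub["specimen"].iloc[0]
        label = sub["label"].iloc[0]
        if sub["specimen"].nunique() > 1 or sub["label"].nunique() > 1:
            raise SpectraParseError(
                f"{path}: sample {sid!r} has inconsistent specimen/label rows"
            )
        try:
            spectra.append(
                Spectrum(
                    sample_id=str(sid),
                    specimen=str(specimen),
                    label=str(label),
                    wavenumbers=sub["wavenumber"].to_numpy(dtype=float),
                    intensities=sub["intensity"].to_numpy(dtype=float),
                )
            )
        except SpectraParseError:
            raise
        except (TypeError, ValueError) as exc:
            raise SpectraParseError(
                f"{path}: sample {sid!r}: malformed numeric value ({exc})"
            ) from exc
    return spectra


def _spectra_from_wide(df: pd.DataFrame, meta: dict, path: Path) -> list[Spectrum]:
    if df.columns[0] != "wavenumber":
        raise SpectraParseError(
            f"{path}: wide format's first column must be 'wavenumber', "
            f"got {df.columns[0]!r}"
        )
    try:
        wavenumbers = df["wavenumber"].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise SpectraParseError(
            f"{path}: malformed wavenumber column ({exc})"
        ) from exc
    specimen = meta["specimen"]
    sample_meta = meta["samples"]
    spectra = []
    for col in df.columns[1:]:  # file column order preserved
        if col not in sample_meta:
            raise SpectraParseError(
                f"{path}: sample {col!r} has no entry in the metadata sidecar"
            )
        entry = sample_meta[col]
        label = entry["label"] if isinstance(entry, dict) else entry
        try:
            spectra.append(
                Spectrum(
                    sample_id=str(col),
                    specimen=str(specimen),
                    label=str(label),
                    wavenumbers=wavenumbers,
                    intensities=df[col].to_numpy(dtype=float),
                )
            )
        except SpectraParseError:
            raise
        except (TypeError, ValueError) as exc:
            raise SpectraParseError(
                f"{path}: sample {col!r}: malformed intensity ({exc})"
            ) from exc
    return spectra


def write_spectra_table(
    spectra: list[Spectrum],
    path: str | Path,
    format: str = "wide",
    delimiter: str | None = None,
) -> None:
    """Write spectra in the long or wide dialect (wide emits a YAML sidecar).

    Values are written with Python's shortest round-trip float
    representation, so read → write → read reproduces wavenumbers and
    intensities exactly.
    """
    path = Path(path)
    if not spectra:
        raise SpectraParseError("no spectra to write")
    sep = delimiter or ("\t" if path.suffix in (".tsv", ".tab") else ",")
    if format == "long":
        lines = [sep.join(_LONG_COLUMNS)]
        for s in spectra:
            for w, x in zip(s.wavenumbers, s.intensities):
                lines.append(sep.join(
                    [s.sample_id, s.specimen, s.label, repr(float(w)),
                     repr(float(x))]
                ))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return
    if format != "wide":
        raise SpectraParseError(f"unknown table format {format!r}")
    grid = spectra[0].wavenumbers
    for s in spectra[1:]:
        if s.wavenumbers.shape != grid.shape or not np.array_equal(
            s.wavenumbers, grid
        ):
            raise SpectraParseError(
                f"sample {s.sample_id!r}: wide format requires a shared grid"
            )
    header = sep.join(["wavenumber"] + [s.sample_id for s in spectra])
    lines = [header]
    for j, w in enumerate(grid):
        lines.append(sep.join(
            [repr(float(w))] + [repr(float(s.intensities[j])) for s in spectra]
        ))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    meta = {
        "specimen": spectra[0].specimen,
        "samples": {s.sample_id: {"label": s.label} for s in spectra},
    }
    Path(str(path) + ".meta.yaml").write_text(
        yaml.safe_dump(meta, sort_keys=False), encoding="utf-8"
    )


def format_percent(value: Fraction | float | None) -> str:
    """Render a 0–100 metric as e.g. ``87.8%``, half-up at one decimal;
    unavailable metrics render as ``NA``."""
    if value is None:
        return "NA"
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    return str(dec.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)) + "%"


def report_row(report: EvaluationReport, sample_name: str | None = None) -> list[str]:
    c = report.confusion
    m = report.metrics
    return [
        sample_name if sample_name is not None else report.method.describe(),
        format_percent(m.accuracy),
        format_percent(m.precision),
        format_percent(m.sensitivity),
        format_percent(m.specificity),
        str(c.tp), str(c.tn), str(c.fp), str(c.fn),
    ]


def write_report(
    report: EvaluationReport | list[EvaluationReport],
    path: str | Path,
    sample_names: list[str] | None = None,
) -> None:
    """Write one or more evaluation reports as a TSV table.

    Columns: Sample, Accuracy, Precision, Sensitivity, Specificity,
    True Pos., True Neg., False Pos., False Neg. — percentages half-up to
    one decimal.
    """
    reports = report if isinstance(report, list) else [report]
    if not reports:
        raise ReportError("no reports to write")
    for r in reports:
        if r.confusion.total == 0:
            raise ReportError("empty evaluation: all confusion counts are zero")
    names = sample_names or [None] * len(reports)
    lines = ["\t".join(REPORT_COLUMNS)]
    for r, name in zip(reports, names):
        lines.append("\t".join(report_row(r, name)))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
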