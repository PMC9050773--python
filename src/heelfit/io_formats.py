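"""CSV and JSON round-tripping for curves and fit reports.

Curve files are two-column CSV with header ``strain,stress_MPa`` — units are
fixed in the column name, there is no separate units field.  Lines starting
with ``#`` are comments.  Values are written with 10 significant digits, so a
write/read round trip reproduces a curve to that precision.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import FitResult
from .models import StressStrainCurve

__all__ = ["read_curve", "write_curve", "write_report", "write_ground_truth"]

HEADER = ("strain", "stress_MPa")


def read_curve(path, sort: bool = False) -> StressStrainCurve:
    """Read a stress–strain curve from CSV.

    Accepts the canonical ``strain,stress_MPa`` header or a headerless
    two-column file (with a warning).  Comment lines (``#``) are skipped.
    Duplicate strain values are collapsed by averaging their stresses, with a
    warning.  Decreasing strain is an error unless ``sort=True``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", header=None, dtype=str, skip_blank_lines=True)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse as CSV: {exc}") from exc
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns, found {df.shape[1]}")

    first = tuple(str(v).strip() for v in df.iloc[0])
    if first == HEADER:
        df = df.iloc[1:]
    else:
        try:
            [float(v) for v in first]
        except ValueError:
            raise ValueError(
                f"{path}: line 1: unrecognized header {first!r}; expected {HEADER}"
            )
        warnings.warn(f"{path}: no '{','.join(HEADER)}' header; assuming (strain, stress_MPa) columns")

    values = np.empty((len(df), 2))
    for row, (idx, pair) in enumerate(df.iterrows()):
        try:
            values[row] = [float(pair.iloc[0]), float(pair.iloc[1])]
        except (TypeError, ValueError):
            raise ValueError(f"{path}: line {idx + 1}: non-numeric row {tuple(pair)!r}")
    strain, stress = values[:, 0], values[:, 1]

    if sort:
        order = np.argsort(strain, kind="stable")
        strain, stress = strain[order], stress[order]
    elif np.any(np.diff(strain) < 0):
        raise ValueError(f"{path}: strain decreases; pass sort=True to sort on read")

    if np.any(np.diff(strain) == 0):
        warnings.warn(f"{path}: duplicate strain values collapsed by averaging stress")
        uniq, inverse = np.unique(strain, return_inverse=True)
        stress = np.bincount(inverse, weights=stress) / np.bincount(inverse)
        strain = uniq
    return StressStrainCurve(strain, stress)


def write_curve(curve: StressStrainCurve, path) -> None:
    """Write a curve as CSV with the canonical header, 10 significant digits."""
    if not isinstance(curve, StressStrainCurve):
        raise TypeError("write_curve expects a StressStrainCurve")
    path = Path(path)
    try:
        with path.open("w") as fh:
            fh.write(",".join(HEADER) + "\n")
            for e, s in zip(curve.strain, curve.stress):
                fh.write(f"{e:.10g},{s:.10g}\n")
    except OSError as exc:
        raise OSError(f"cannot write curve to {path}: {exc}") from exc


def write_report(result: FitResult, path) -> None:
    """Serialize a fit report to JSON with the fixed schema of FitResult.to_dict."""
    path = Path(path)
    try:
        with path.open("w") as fh:
            json.dump(result.to_dict(), fh, indent=2)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc


def write_ground_truth(curve: StressStrainCurve, path) -> None:
    """Write the generator's ground-truth sidecar (JSON) for a synthetic curve."""
    path = Path(path)
    try:
        payload = json.loads(curve.label) if curve.label else {}
    except json.JSONDecodeError:
        payload = {"label": curve.label}
    with path.open("w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
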