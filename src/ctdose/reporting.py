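"""Marker (TLD-site) dose extraction and percent-difference comparison
tables.

Conventions follow the usual presentation of TLD-versus-calculation CT
dose studies: each marker is a small voxel cluster standing in for the
chips at one organ site; its dose is the arithmetic mean over the cluster
(with the SD across cluster voxels).  Percent differences are
absolute-valued, normalized to the stated reference (measured doses for
measurement-vs-calculation columns, the Monte Carlo dose for the
calculation-vs-calculation column) and rounded half-away-from-zero to one
decimal, matching how such tables are printed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_engine import DoseGrid
from .errors import ConfigurationError, DomainError
from .phantom import MarkerSet

#: CSV column order for comparison reports
REPORT_COLUMNS = ["label",
                  "dose_measured", "sd_measured",
                  "dose_engine", "sd_engine",
                  "pct_measured_engine",
                  "dose_mc", "sd_mc",
                  "pct_mc_measured", "pct_mc_engine"]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed dose tables)."""
    f = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * f + 0.5) / f, x)


def marker_dose(dose: DoseGrid, markers: MarkerSet) -> dict[str, tuple[float, float]]:
    """Mean dose (and SD over cluster voxels) per marker label."""
    shape = np.asarray(dose.shape)
    out: dict[str, tuple[float, float]] = {}
    for label, idx in markers.markers.items():
        if idx.size == 0:
            raise ConfigurationError(f"marker {label!r} has an empty cluster")
        if np.any(idx < 0) or np.any(idx >= shape):
            raise ConfigurationError(f"marker {label!r} indices outside the grid")
        vals = dose.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out[label] = (float(vals.mean()), sd)
    return out


def percent_diff(reference: float, other: float) -> float:
    """100 * |reference - other| / reference, rounded to one decimal."""
    if reference <= 0:
        raise DomainError(f"reference dose must be positive, got {reference}")
    return round_half_away(100.0 * abs(reference - other) / reference, 1)


@dataclass
class ComparisonRow:
    label: str
    dose_measured: float | None = None
    sd_measured: float | None = None
    dose_engine: float | None = None
    sd_engine: float | None = None
    dose_mc: float | None = None
    sd_mc: float | None = None
    pct_measured_engine: float | None = None  # normalized to measured
    pct_mc_measured: float | None = None  # normalized to measured
    pct_mc_engine: float | None = None  # normalized to MC


def _as_marker_doses(source, markers: MarkerSet | None):
    if source is None:
        return None
    if isinstance(source, DoseGrid):
        if markers is None:
            raise ConfigurationError("markers required to extract doses from a grid")
        return marker_dose(source, markers)
    return {k: (v if isinstance(v, tuple) else (float(v), 0.0))
            for k, v in dict(source).items()}


def comparison_table(measured=None, engine=None, mc=None,
                     markers: MarkerSet | None = None) -> list[ComparisonRow]:
    """Build per-site comparison rows from two or three dose sources.

    Sources may be :class:`DoseGrid` objects (marker doses are extracted)
    or mappings ``label -> dose`` / ``label -> (dose, sd)``.
    """
    sources = {"measured": _as_marker_doses(measured, markers),
               "engine": _as_marker_doses(engine, markers),
               "mc": _as_marker_doses(mc, markers)}
    present = {k: v for k, v in sources.items() if v is not None}
    if len(present) < 2:
        raise ConfigurationError("need at least two dose sources to compare")
    labels = list(next(iter(present.values())))
    for name, doses in present.items():
        missing = [lab for lab in labels if lab not in doses]
        if missing or len(doses) != len(labels):
            raise ConfigurationError(
                f"source {name!r} does not cover the marker labels {missing or ''}")

    rows = []
    for lab in labels:
        row = ComparisonRow(label=lab)
        for name in present:
            d, sd = present[name][lab]
            setattr(row, f"dose_{name}", d)
            setattr(row, f"sd_{name}", sd)
        if row.dose_measured is not None and row.dose_engine is not None:
            row.pct_measured_engine = percent_diff(row.dose_measured, row.dose_engine)
        if row.dose_measured is not None and row.dose_mc is not None:
            row.pct_mc_measured = percent_diff(row.dose_measured, row.dose_mc)
        if row.dose_mc is not None and row.dose_engine is not None:
            row.pct_mc_engine = percent_diff(row.dose_mc, row.dose_engine)
        rows.append(row)
    return rows


def rows_to_dataframe(rows: list[ComparisonRow]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in rows])
    return df[[c for c in REPORT_COLUMNS if c in df.columns]]


def write_report(rows: list[ComparisonRow], path) -> None:
    rows_to_dataframe(rows).to_csv(path, index=False, float_format="%.6g")
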