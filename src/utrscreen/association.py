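"""Correlation of structural accessibility with measured repression.

For every tested MTI the structure stage yields accessibility metrics —
windowed paired-base fractions and coverage scores over a radius sweep —
and the screen stage yields a mean normalized RLU.  This module asks, per
miRNA and per metric (and per radius for the coverage score), whether the
two are linearly related, using the sample Pearson correlation with its
two-sided t-based p value.  Cells with too few observations or a constant
column are flagged as undefined rather than silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .layout import DEFAULT_RADII, StructureLayout, coverage_score, min_coverage_over_sites
from .seqsites import SeedSite
from .structure import SecondaryStructure, paired_fraction

__all__ = [
    "CorrelationResult",
    "pearson_correlation",
    "structure_metrics_table",
    "structure_rlu_scan",
    "site_count_rlu_correlation",
    "results_to_frame",
    "DEFAULT_WINDOWS",
]

#: windows (nt, both directions) for the paired-fraction metric
DEFAULT_WINDOWS = (0, 5, 50)

#: display threshold used when highlighting strongly reduced sites in plots
STRONG_REDUCTION_P = 1e-5


@dataclass
class CorrelationResult:
    """Pearson correlation of one accessibility metric with mean RLU."""

    mirna: str
    metric: str
    radius: Optional[float]
    pearson_r: float
    p_value: float
    n: int
    defined: bool = True
    reason: str = ""


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with its two-sided p value.

    p derives from ``t = r * sqrt((n - 2) / (1 - r^2))`` against a t
    distribution with n - 2 df.  Requires equal lengths >= 3 and nonzero
    variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def structure_metrics_table(
    entries: Iterable[dict],
    radii: Sequence[float] = DEFAULT_RADII,
    windows: Sequence[int] = DEFAULT_WINDOWS,
    site_selection: str = "min_coverage",
    selection_radius: float = 2.0,
) -> pd.DataFrame:
    """Per-MTI accessibility metrics in long form.

    Each entry is a dict with keys ``construct_id, mirna, structure``
    (:class:`SecondaryStructure`), ``layout`` (:class:`StructureLayout`),
    ``sites`` (non-empty list of :class:`SeedSite`), and optionally
    ``mean_rlu``.  For the paired-fraction windows a single representative
    site is chosen per ``site_selection``: ``"min_coverage"`` (the site
    with minimal coverage score at ``selection_radius``, i.e. the most
    accessible site) or ``"five_prime_most"``.  The coverage-score metric
    takes, at each radius, the minimum over the entry's sites.

    Returns columns ``construct_id, mirna, metric, radius, value[,
    mean_rlu]``.
    """
    if site_selection not in ("min_coverage", "five_prime_most"):
        raise ValueError(f"unknown site_selection {site_selection!r}")
    rows = []
    for entry in entries:
        sites: list[SeedSite] = list(entry["sites"])
        if not sites:
            raise ValueError(
                f"entry {entry.get('construct_id')!r} has no sites"
            )
        layout: StructureLayout = entry["layout"]
        structure: SecondaryStructure = entry["structure"]
        if site_selection == "min_coverage":
            chosen = min_coverage_over_sites(layout, sites, selection_radius).site
        else:
            chosen = min(sites, key=lambda s: s.start)
        base = {
            "construct_id": entry["construct_id"],
            "mirna": entry["mirna"],
        }
        if "mean_rlu" in entry:
            base["mean_rlu"] = entry["mean_rlu"]
        for w in windows:
            rows.append({
                **base,
                "metric": f"paired_fraction_w{w}",
                "radius": math.nan,
                "value": paired_fraction(structure, chosen, window=w),
            })
        for r in radii:
            best = min(coverage_score(layout, s, r).score for s in sites)
            rows.append({
                **base,
                "metric": "coverage_score",
                "radius": float(r),
                "value": best,
            })
    return pd.DataFrame(rows)


def _one_cell(mirna: str, metric: str, radius: Optional[float],
              x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    n = len(x)
    if n < 3:
        return CorrelationResult(mirna, metric, radius, math.nan, math.nan,
                                 n, defined=False, reason="n < 3")
    if np.var(x) == 0 or np.var(y) == 0:
        return CorrelationResult(mirna, metric, radius, math.nan, math.nan,
                                 n, defined=False, reason="zero variance")
    r, p = pearson_correlation(x, y)
    return CorrelationResult(mirna, metric, radius, r, p, n)


def structure_rlu_scan(mti_table: pd.DataFrame) -> list[CorrelationResult]:
    """Correlate each accessibility metric with mean RLU, per miRNA.

    ``mti_table`` is the long-form output of
    :func:`structure_metrics_table` joined with ``mean_rlu``.  One
    :class:`CorrelationResult` is produced per (miRNA, metric, radius)
    cell; under-populated or constant cells are returned flagged
    ``defined=False`` rather than dropped.
    """
    required = {"mirna", "metric", "radius", "value", "mean_rlu"}
    missing = required - set(mti_table.columns)
    if missing:
        raise ValueError(f"mti_table lacks columns: {sorted(missing)}")
    results = []
    keyed = mti_table.copy()
    keyed["_radius"] = keyed["radius"].fillna(-1.0)
    for (mirna, metric, rad), grp in keyed.groupby(["mirna", "metric", "_radius"],
                                                   sort=True):
        radius = None if rad < 0 else float(rad)
        results.append(_one_cell(
            str(mirna), str(metric), radius,
            grp["value"].to_numpy(float), grp["mean_rlu"].to_numpy(float),
        ))
    return results


def site_count_rlu_correlation(mti_table: pd.DataFrame) -> CorrelationResult:
    """Pearson correlation of per-construct site count with mean RLU.

    ``mti_table`` needs columns ``site_count`` and ``mean_rlu`` (one row
    per construct x miRNA).  A constant site-count column yields a flagged
    undefined result.
    """
    for col in ("site_count", "mean_rlu"):
        if col not in mti_table.columns:
            raise ValueError(f"mti_table lacks column {col!r}")
    return _one_cell(
        "(all)", "site_count", None,
        mti_table["site_count"].to_numpy(float),
        mti_table["mean_rlu"].to_numpy(float),
    )


def results_to_frame(results: Iterable[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
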