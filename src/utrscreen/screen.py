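"""Dual-luciferase reporter-screen statistics.

A screen co-transfects each 3'UTR reporter construct (firefly luciferase
with the UTR fragment, renilla luciferase as transfection control) with a
miRNA expression plasmid, and separately with the empty expression vector.
Four biological replicates are measured in technical duplicates.  Per
biological replicate, the firefly/renilla ratio is averaged over the two
duplicates (duplicates share a lysate and are not independent), and the
normalized RLU is the test ratio divided by the same replicate's
empty-vector ratio — a ratio of ratios, 1.0 meaning no effect.

An interaction (MTI) is *validated* when the mean normalized RLU falls
below 0.90 **and** a two-sided Welch t test between the test and control
ratios is significant at the nominal alpha of 0.05.  Genes represented by
several overlapping fragments are summarized by the maximal reduction and
the maximal significance over their fragments.

The module is organised statsmodels-style: build a :class:`ReporterScreen`
from a tidy measurement table, call :meth:`~ReporterScreen.fit`, and work
with the returned :class:`ScreenResults` (tables, rates, ``summary()``,
network export, volcano plot).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WelchResult",
    "MTIRecord",
    "GeneResult",
    "normalize_rlu",
    "replicate_ratios",
    "welch_t_test",
    "validate_mti",
    "aggregate_gene_level",
    "validation_rate",
    "ReporterScreen",
    "ScreenResults",
]

PLATE_COLUMNS = ["construct_id", "mirna", "replicate", "duplicate", "firefly", "renilla"]


@dataclass(frozen=True)
class WelchResult:
    """Welch two-sample t test: statistic, Welch-Satterthwaite df, p."""

    t: float
    df: float
    p: float


@dataclass
class MTIRecord:
    """One miRNA x reporter-construct result."""

    construct_id: str
    gene: str
    mirna: str
    normalized_rlu: tuple[float, ...]
    mean_rlu: float
    p_value: float
    validated: bool
    category: str
    t_statistic: float = float("nan")
    df: float = float("nan")


@dataclass
class GeneResult:
    """Gene-level aggregate: maximal reduction and maximal significance."""

    gene: str
    mirna: str
    best_rlu: float
    best_p: float
    validated: bool
    n_constructs: int = 1


def replicate_ratios(measurements: pd.DataFrame) -> pd.Series:
    """Per-replicate firefly/renilla ratio, duplicates averaged.

    ``measurements`` holds one condition (one construct x one expression
    vector) with columns replicate, duplicate, firefly, renilla.
    """
    df = measurements
    if (df["renilla"] <= 0).any():
        raise ValueError("non-positive renilla reading")
    if (df["firefly"] <= 0).any():
        raise ValueError("non-positive firefly reading")
    ratios = (df["firefly"] / df["renilla"]).groupby(df["replicate"]).mean()
    return ratios.sort_index()


def normalize_rlu(test: pd.DataFrame, control: pd.DataFrame) -> np.ndarray:
    """Per-replicate normalized RLU: test ratio / empty-vector ratio.

    Both frames must carry the same replicate structure (typically 4
    biological replicates in technical duplicates); returns one fraction
    per biological replicate, replicate-paired.
    """
    rt = replicate_ratios(test)
    rc = replicate_ratios(control)
    if list(rt.index) != list(rc.index):
        raise ValueError(
            f"replicate structure mismatch: test {list(rt.index)} "
            f"vs control {list(rc.index)}"
        )
    return (rt / rc).to_numpy()


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Two-sided Welch t test (unequal variances).

    Returns the t statistic, the Welch-Satterthwaite degrees of freedom
    and the two-sided p value.  Requires n >= 2 per sample and nonzero
    variance in at least one sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("undefined test: both samples have zero variance")
    with warnings.catch_warnings():
        # a single zero-variance sample (e.g. an exact-reference control) is
        # legitimate; scipy warns about the degenerate moment
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    return WelchResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


def validate_mti(
    mean_rlu: float,
    p: float,
    alpha: float = 0.05,
    rlu_cutoff: float = 0.90,
    upreg_cutoff: float = 1.10,
) -> tuple[bool, str]:
    """Apply the screen's validation rule and RLU category bins.

    validated  <=>  mean_rlu < rlu_cutoff and p < alpha.
    Categories: ``strong`` (< 0.70), ``moderate`` ([0.70, 0.90)), ``none``
    ([0.90, 1.10]), ``upregulated`` (> 1.10 with p < alpha; a
    non-significant increase stays ``none``).
    """
    validated = (mean_rlu < rlu_cutoff) and (p < alpha)
    if mean_rlu < 0.70:
        category = "strong"
    elif mean_rlu < rlu_cutoff:
        category = "moderate"
    elif mean_rlu <= upreg_cutoff:
        category = "none"
    else:
        category = "upregulated" if p < alpha else "none"
    return validated, category


def aggregate_gene_level(records: Iterable[MTIRecord]) -> GeneResult:
    """Summarize all fragments of one gene x miRNA pair.

    best_rlu is the minimum mean RLU over fragments, best_p the minimum p;
    the two minima may come from different fragments and are reported
    independently.  The gene is validated when any fragment is.
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one record")
    genes = {r.gene for r in records}
    mirnas = {r.mirna for r in records}
    if len(genes) != 1 or len(mirnas) != 1:
        raise ValueError("records must belong to a single gene x miRNA pair")
    return GeneResult(
        gene=records[0].gene,
        mirna=records[0].mirna,
        best_rlu=min(r.mean_rlu for r in records),
        best_p=min(r.p_value for r in records),
        validated=any(r.validated for r in records),
        n_constructs=len(records),
    )


def validation_rate(n_validated: int, n_tested: int) -> float:
    """Validated percentage of tested interactions, one decimal."""
    if n_tested <= 0:
        raise ValueError("no tested interactions")
    if not 0 <= n_validated <= n_tested:
        raise ValueError("validated count out of range")
    return round(100.0 * n_validated / n_tested, 1)


class ReporterScreen:
    """Model for one reporter-screen dataset.

    Parameters
    ----------
    plate_table : DataFrame
        Tidy measurements with columns ``construct_id, mirna, replicate,
        duplicate, firefly, renilla`` and optionally ``gene``.  Rows whose
        ``mirna`` equals ``control_label`` are the empty-expression-vector
        control condition of their construct.
    control_label : str
        Value of ``mirna`` marking control rows (default ``"empty"``).

    Use :meth:`from_normalized` when only pre-normalized per-replicate RLU
    fractions are available.
    """

    def __init__(self, plate_table: pd.DataFrame, control_label: str = "empty"):
        missing = [c for c in PLATE_COLUMNS if c not in plate_table.columns]
        if missing:
            raise ValueError(f"plate table lacks columns: {missing}")
        self.data = plate_table.copy()
        self.control_label = control_label
        self.mode = "plate"

    @classmethod
    def from_plate_table(cls, plate_table: pd.DataFrame,
                         control_label: str = "empty") -> "ReporterScreen":
        return cls(plate_table, control_label=control_label)

    @classmethod
    def from_normalized(cls, table: pd.DataFrame) -> "ReporterScreen":
        """Build from pre-normalized RLU fractions.

        ``table`` columns: ``construct_id, mirna, replicate,
        normalized_rlu`` (+ optional ``gene``).  The Welch test then
        compares the fractions against the control reference of exactly
        1.0 per replicate.
        """
        for col in ("construct_id", "mirna", "replicate", "normalized_rlu"):
            if col not in table.columns:
                raise ValueError(f"normalized table lacks column {col!r}")
        if (table["normalized_rlu"] <= 0).any():
            raise ValueError("normalized RLU values must be positive")
        obj = cls.__new__(cls)
        obj.data = table.copy()
        obj.control_label = None
        obj.mode = "normalized"
        return obj

    # -- fitting -----------------------------------------------------------

    def _conditions(self):
        """Yield (construct_id, gene, mirna, normalized, test, control)."""
        df = self.data
        has_gene = "gene" in df.columns
        if self.mode == "normalized":
            for (cid, mirna), grp in df.groupby(["construct_id", "mirna"], sort=True):
                gene = str(grp["gene"].iloc[0]) if has_gene else str(cid)
                norm = grp.sort_values("replicate")["normalized_rlu"].to_numpy(float)
                yield str(cid), gene, str(mirna), norm, norm, np.ones_like(norm)
            return
        for cid, grp in df.groupby("construct_id", sort=True):
            control = grp[grp["mirna"] == self.control_label]
            if control.empty:
                raise ValueError(f"construct {cid!r} has no control condition")
            rc = replicate_ratios(control)
            for mirna, test in grp[grp["mirna"] != self.control_label].groupby("mirna"):
                gene = str(test["gene"].iloc[0]) if has_gene else str(cid)
                rt = replicate_ratios(test)
                if list(rt.index) != list(rc.index):
                    raise ValueError(
                        f"replicate mismatch for construct {cid!r}, miRNA {mirna!r}"
                    )
                yield (str(cid), gene, str(mirna),
                       (rt / rc).to_numpy(), rt.to_numpy(), rc.to_numpy())

    def fit(self, alpha: float = 0.05, rlu_cutoff: float = 0.90,
            upreg_cutoff: float = 1.10) -> "ScreenResults":
        """Normalize, test and categorize every construct x miRNA condition."""
        records = []
        for cid, gene, mirna, norm, test, control in self._conditions():
            welch = welch_t_test(test, control)
            mean_rlu = float(norm.mean())
            validated, category = validate_mti(
                mean_rlu, welch.p, alpha=alpha,
                rlu_cutoff=rlu_cutoff, upreg_cutoff=upreg_cutoff,
            )
            records.append(MTIRecord(
                construct_id=cid, gene=gene, mirna=mirna,
                normalized_rlu=tuple(float(v) for v in norm),
                mean_rlu=mean_rlu, p_value=welch.p,
                validated=validated, category=category,
                t_statistic=welch.t, df=welch.df,
            ))
        return ScreenResults(self, records, alpha=alpha,
                             rlu_cutoff=rlu_cutoff, upreg_cutoff=upreg_cutoff)


class ScreenResults:
    """Fitted screen: per-construct and per-gene tables, rates, summaries."""

    def __init__(self, model: ReporterScreen, records: list[MTIRecord],
                 alpha: float, rlu_cutoff: float, upreg_cutoff: float):
        self.model = model
        self.records = records
        self.alpha = alpha
        self.rlu_cutoff = rlu_cutoff
        self.upreg_cutoff = upreg_cutoff

    @cached_property
    def mti_table(self) -> pd.DataFrame:
        """Per construct x miRNA: mean RLU, Welch test, validation flag.

        ``p_adj_bh`` is a Benjamini-Hochberg column emitted as
        supplementary output; validation itself uses nominal p values.
        """
        df = pd.DataFrame([
            {
                "construct_id": r.construct_id,
                "gene": r.gene,
                "mirna": r.mirna,
                "n_replicates": len(r.normalized_rlu),
                "mean_rlu": r.mean_rlu,
                "t_statistic": r.t_statistic,
                "df": r.df,
                "p_value": r.p_value,
                "validated": r.validated,
                "category": r.category,
            }
            for r in self.records
        ])
        if len(df):
            df["p_adj_bh"] = stats.false_discovery_control(df["p_value"])
        return df

    @cached_property
    def gene_table(self) -> pd.DataFrame:
        """Gene x miRNA aggregate: best (minimal) RLU and p, any-validated."""
        groups: dict[tuple[str, str], list[MTIRecord]] = {}
        for r in self.records:
            groups.setdefault((r.gene, r.mirna), []).append(r)
        rows = [aggregate_gene_level(v).__dict__ for v in groups.values()]
        df = pd.DataFrame(rows)
        return df.sort_values(["gene", "mirna"]).reset_index(drop=True)

    def validation_rates(self) -> pd.DataFrame:
        """Tested/validated counts and percentage per miRNA, plus overall."""
        df = self.mti_table
        rows = []
        for mirna, grp in df.groupby("mirna"):
            rows.append({
                "mirna": mirna,
                "tested": len(grp),
                "validated": int(grp["validated"].sum()),
                "rate_pct": validation_rate(int(grp["validated"].sum()), len(grp)),
            })
        rows.append({
            "mirna": "(all)",
            "tested": len(df),
            "validated": int(df["validated"].sum()),
            "rate_pct": validation_rate(int(df["validated"].sum()), len(df)),
        })
        return pd.DataFrame(rows)

    def category_counts(self) -> pd.Series:
        return self.mti_table["category"].value_counts()

    def network(self, predictions: Iterable[tuple[str, str]],
                genes: Optional[Iterable[str]] = None,
                mirnas: Optional[Iterable[str]] = None):
        """Bipartite gene-miRNA network annotated with evidence flags."""
        from .network import build_network

        gt = self.gene_table
        tested = {(g, m) for g, m in zip(gt["gene"], gt["mirna"])}
        validated = {
            (g, m)
            for g, m, v in zip(gt["gene"], gt["mirna"], gt["validated"])
            if v
        }
        genes = sorted(set(gt["gene"]) if genes is None else set(genes))
        mirnas = sorted(set(gt["mirna"]) if mirnas is None else set(mirnas))
        return build_network(genes, mirnas, predicted=set(predictions),
                            tested=tested, validated=validated)

    def summary(self) -> str:
        """Human-readable overview of the fitted screen."""
        rates = self.validation_rates()
        lines = [
            "Reporter screen results",
            "=" * 58,
            f"constructs x miRNA conditions tested: {len(self.mti_table)}",
            f"validation rule: mean RLU < {self.rlu_cutoff:.2f} and "
            f"Welch p < {self.alpha:g}",
            "",
            f"{'miRNA':<18}{'tested':>8}{'validated':>11}{'rate %':>9}",
            "-" * 46,
        ]
        for _, row in rates.iterrows():
            lines.append(
                f"{row['mirna']:<18}{row['tested']:>8}"
                f"{row['validated']:>11}{row['rate_pct']:>9.1f}"
            )
        counts = self.category_counts()
        lines += ["", "RLU categories: " + ", ".join(
            f"{k}={v}" for k, v in counts.items())]
        return "\n".join(lines)

    def volcano(self, ax=None):
        """Scatter of mean RLU vs -log10 p, one color per miRNA."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        df = self.mti_table
        for mirna, grp in df.groupby("mirna"):
            ax.scatter(grp["mean_rlu"], -np.log10(grp["p_value"]),
                       s=12, label=str(mirna), alpha=0.7)
        ax.axvline(self.rlu_cutoff, ls="--", lw=0.8, c="gray")
        ax.axhline(-np.log10(self.alpha), ls="--", lw=0.8, c="gray")
        ax.set_xlabel("mean normalized RLU")
        ax.set_ylabel("-log10 p")
        ax.legend(fontsize=7)
        return ax
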