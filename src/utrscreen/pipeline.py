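"""End-to-end pipeline: fragment -> scan -> structures -> coverage ->
screen statistics -> network -> structure/RLU correlation.

A :class:`PipelineConfig` collects input paths, the analysis parameters
(all thresholds surfaced, defaults matching the screen's conventions) and
the output directory; :func:`run_pipeline` executes the enabled stages in
order, writes every table with a provenance header (tool version, seed,
config hash) and returns the in-memory results.  Stage failures abort
with a stage-labeled :class:`StageError`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import io as uio
from .association import (
    DEFAULT_WINDOWS,
    results_to_frame,
    site_count_rlu_correlation,
    structure_metrics_table,
    structure_rlu_scan,
)
from .layout import DEFAULT_RADII, layout_2d
from .librarydesign import apply_plan, plan_fragments
from .screen import ReporterScreen
from .seqsites import UTRSequence, find_seed_sites
from .structure import fold_baseline

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "ALL_STAGES"]

logger = logging.getLogger("utrscreen")

ALL_STAGES = ("fragment", "scan", "fold", "coverage", "stats", "network",
              "correlate")


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the culprit."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")


@dataclass
class PipelineConfig:
    """Inputs, parameters and output location of one pipeline run."""

    # inputs: either full UTRs (to be tiled) or a ready fragment library
    utr_fasta: Optional[str] = None
    fragments_fasta: Optional[str] = None
    mirna_fasta: Optional[str] = None
    structures: Optional[str] = None  # Vienna dot-bracket, names = construct ids
    plates_tsv: Optional[str] = None
    predictions_tsv: Optional[str] = None  # columns gene, mirna

    # parameters (defaults follow the screen's conventions)
    target_len: int = 675
    overlap: int = 30
    windows: Sequence[int] = DEFAULT_WINDOWS
    radii: Sequence[float] = DEFAULT_RADII
    alpha: float = 0.05
    rlu_cutoff: float = 0.90
    upreg_cutoff: float = 1.10
    site_selection: str = "min_coverage"
    control_label: str = "empty"

    stages: Sequence[str] = ALL_STAGES
    rng_seed: int = 0
    outdir: str = "utrscreen_out"

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["windows"] = list(self.windows)
        d["radii"] = list(self.radii)
        d["stages"] = list(self.stages)
        return d

    def config_hash(self) -> str:
        # the hash identifies the analysis, not where it was written
        d = self.to_dict()
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        from . import __version__

        return [
            f"# utrscreen v{__version__}",
            f"# seed={self.rng_seed}",
            f"# config_hash={self.config_hash()}",
        ]


def _construct_id(frag: UTRSequence) -> str:
    return f"{frag.gene}|{frag.fragment_id}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns a result bundle (dict).

    Keys (as produced): ``fragments``, ``sites``, ``structures``,
    ``metrics``, ``screen_results``, ``network``, ``correlations``.
    Outputs are re-run byte-identical for identical (inputs, config,
    seed).
    """
    out = pathlib.Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    header = config.header_lines()
    stages = set(config.stages)
    results: dict = {}

    # -- fragment ---------------------------------------------------------
    fragments: list[UTRSequence] = []
    try:
        if config.fragments_fasta:
            fragments = uio.read_fragments_fasta(config.fragments_fasta)
        elif config.utr_fasta:
            for gene, seq in uio.read_utr_fasta(config.utr_fasta):
                plan = plan_fragments(len(seq), config.target_len,
                                      config.overlap, gene)
                fragments.extend(apply_plan(seq, plan))
            if "fragment" in stages:
                uio.write_fragments_fasta(out / "fragments.fasta", fragments)
        elif stages & {"fragment", "scan", "fold", "coverage"}:
            raise ValueError("no UTR or fragment FASTA provided")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("fragment", str(exc)) from exc
    results["fragments"] = fragments
    logger.info("fragment: %d fragments", len(fragments))

    # -- scan -------------------------------------------------------------
    sites_by_construct: dict[tuple[str, str], list] = {}
    if "scan" in stages:
        try:
            if not config.mirna_fasta:
                raise ValueError("scan stage needs a miRNA FASTA")
            mirnas = uio.read_mirna_fasta(config.mirna_fasta)
            pairs = []
            for frag in fragments:
                frag_sites = []
                for m in mirnas:
                    found = find_seed_sites(frag, m)
                    if found:
                        sites_by_construct[(_construct_id(frag), m.name)] = found
                        frag_sites.extend(found)
                pairs.append((frag, frag_sites))
            site_table = uio.sites_to_frame(pairs)
            uio.write_tsv(out / "sites.tsv", site_table, header)
            uio.write_sites_bed(out / "sites.bed", site_table)
            results["sites"] = site_table
            logger.info("scan: %d sites", len(site_table))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("scan", str(exc)) from exc

    # -- fold / ingest structures ----------------------------------------
    structures: dict[str, object] = {}
    if stages & {"fold", "coverage"}:
        try:
            if config.structures:
                structures = dict(uio.read_vienna(config.structures))
            elif "fold" in stages:
                for frag in fragments:
                    structures[_construct_id(frag)] = fold_baseline(frag.sequence)
                uio.write_vienna(out / "structures.dbn",
                                 sorted(structures.items()))
            else:
                raise ValueError(
                    "coverage stage needs a structures file or the fold stage"
                )
            results["structures"] = structures
            logger.info("structures: %d records", len(structures))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("fold", str(exc)) from exc

    # -- coverage / accessibility metrics ---------------------------------
    metrics = None
    if "coverage" in stages:
        try:
            entries = []
            for (cid, mirna_name), sites in sorted(sites_by_construct.items()):
                if cid not in structures:
                    raise ValueError(f"no structure for construct {cid!r}")
                struct = structures[cid]
                entries.append({
                    "construct_id": cid, "mirna": mirna_name,
                    "structure": struct, "layout": layout_2d(struct),
                    "sites": sites,
                })
            metrics = structure_metrics_table(
                entries, radii=config.radii, windows=config.windows,
                site_selection=config.site_selection,
            )
            uio.write_tsv(out / "structure_metrics.tsv", metrics, header)
            results["metrics"] = metrics
            logger.info("coverage: %d metric rows", len(metrics))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("coverage", str(exc)) from exc

    # -- stats ------------------------------------------------------------
    screen_results = None
    if "stats" in stages:
        try:
            if not config.plates_tsv:
                raise ValueError("stats stage needs a plate TSV")
            plates = uio.read_tsv(config.plates_tsv)
            model = ReporterScreen.from_plate_table(
                plates, control_label=config.control_label)
            screen_results = model.fit(
                alpha=config.alpha, rlu_cutoff=config.rlu_cutoff,
                upreg_cutoff=config.upreg_cutoff)
            uio.write_tsv(out / "mti_results.tsv",
                          screen_results.mti_table, header)
            uio.write_tsv(out / "gene_results.tsv",
                          screen_results.gene_table, header)
            (out / "summary.txt").write_text(
                "\n".join(header) + "\n" + screen_results.summary() + "\n")
            results["screen_results"] = screen_results
            logger.info("stats: %d MTI records", len(screen_results.records))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("stats", str(exc)) from exc

    # -- network ----------------------------------------------------------
    if "network" in stages:
        try:
            if screen_results is None:
                raise ValueError("network stage needs the stats stage")
            if config.predictions_tsv:
                pred_df = uio.read_tsv(config.predictions_tsv)
                predictions = {(str(g), str(m))
                               for g, m in zip(pred_df["gene"], pred_df["mirna"])}
            else:
                gt = screen_results.gene_table
                predictions = {(g, m) for g, m in zip(gt["gene"], gt["mirna"])}
            net = screen_results.network(predictions)
            uio.write_tsv(out / "network_edges.tsv", net.to_edge_table(), header)
            with open(out / "network_summary.yaml", "w") as fh:
                yaml.safe_dump(net.summary(), fh, sort_keys=True)
            results["network"] = net
            logger.info("network: %d edges", net.total_edges)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("network", str(exc)) from exc

    # -- correlate --------------------------------------------------------
    if "correlate" in stages:
        try:
            if metrics is None or screen_results is None:
                raise ValueError(
                    "correlate stage needs the coverage and stats stages")
            mti = screen_results.mti_table[["construct_id", "mirna",
                                            "mean_rlu"]]
            joined = metrics.merge(mti, on=["construct_id", "mirna"],
                                   how="inner")
            cells = structure_rlu_scan(joined)
            counts = (results["sites"]
                      .groupby(["gene", "fragment_id", "mirna"])
                      .size().rename("site_count").reset_index())
            counts["construct_id"] = (counts["gene"] + "|"
                                      + counts["fragment_id"])
            merged = counts.merge(mti, on=["construct_id", "mirna"],
                                  how="inner")
            cells.append(site_count_rlu_correlation(merged))
            corr = results_to_frame(cells)
            uio.write_tsv(out / "correlations.tsv", corr, header)
            results["correlations"] = corr
            logger.info("correlate: %d cells", len(corr))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("correlate", str(exc)) from exc

    return results
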