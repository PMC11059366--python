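"""Synthetic reporter-screen studies with known ground truth.

Every pipeline stage can be exercised end-to-end without wet-lab data:
random 3'UTRs with canonical sites planted at known positions (and a
guarantee of *no* unplanted sites for the configured miRNAs), fragment
libraries, per-construct true repression levels, and replicate
dual-luciferase plates with a stated noise model.

The measurement model mirrors the screen design: 4 biological replicates
in technical duplicates.  Per replicate the *normalized* RLU of a
construct is drawn as Normal(true mean, ``noise_sd``) truncated at 0; the
empty-vector control replicate ratio is exactly 1.0, so the Welch test
compares 4 noisy test ratios against the 4 control ratios.  Technical
duplicates are placed symmetrically around the replicate value, so their
average reproduces it exactly.  True effects default to: repressed
interactions uniform on [0.40, 0.88], null interactions 1.00, occasional
up-regulated interactions 1.30 — bracketing the effect sizes such screens
report.

Everything is deterministic given ``rng_seed``; the seed and a config
hash are recorded in every output header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .librarydesign import FragmentPlan, apply_plan, plan_fragments
from .seqsites import (
    MiRNA,
    SeedSite,
    UTRSequence,
    find_seed_sites,
    reverse_complement,
)
from .structure import SecondaryStructure, fold_baseline

__all__ = [
    "STUDY_MIRNAS",
    "StudyConfig",
    "StudyBundle",
    "UnplaceableSiteError",
    "generate_utr",
    "generate_plate",
    "generate_study",
]

_BASES = "ACGU"

#: The four Parkinson's-disease-associated miRNAs screened by default.
#: miR-133b is the canonical miRBase mature sequence; the others follow
#: their published mimic/probe sequences (miR-129-5p = MIMAT0000242).
STUDY_MIRNAS = (
    MiRNA("miR-129-5p", "CUUUUUGCGGUCUGGGCUUGC"),
    MiRNA("miR-129-1-3p", "AAGCCCUUACCCCAAAAAGUAU"),
    MiRNA("miR-133b", "UUUGGUCCCCUUCAACCAGCUA"),
    MiRNA("miR-873-5p", "GCAGGAACUUGUGAGUCUCCU"),
)

_SITE_SPAN = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}


class UnplaceableSiteError(ValueError):
    """Requested planted sites cannot be realised on the sequence."""


@dataclass
class StudyConfig:
    """Conditions of one synthetic study.

    Defaults reproduce the screen geometry (675/30 tiling, 4 replicates in
    technical duplicates, noise sd 0.05) at desk scale.
    """

    n_genes: int = 30
    utr_length_range: tuple[int, int] = (200, 4000)
    mirnas: Sequence[MiRNA] = STUDY_MIRNAS
    #: per-gene planted sites: gene -> list of (mirna_name, site_type,
    #: approx 1-based core start); None draws 1-3 random sites per gene
    planted_site_spec: Optional[Mapping[str, list[tuple[str, str, int]]]] = None
    sites_per_gene: tuple[int, int] = (1, 3)
    p_repressed: float = 0.60
    p_upregulated: float = 0.02
    repressed_range: tuple[float, float] = (0.40, 0.88)
    null_mean: float = 1.00
    upregulated_mean: float = 1.30
    noise_sd: float = 0.05
    replicates: int = 4
    duplicates: int = 2
    target_len: int = 675
    overlap: int = 30
    include_sensors: bool = True
    sensor_mean: float = 0.15
    fold_structures: bool = False
    rng_seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mirnas"] = [[m.name, m.sequence] for m in self.mirnas]
        if self.planted_site_spec is not None:
            d["planted_site_spec"] = {
                g: [list(t) for t in v] for g, v in self.planted_site_spec.items()
            }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _expected_site(mirna: MiRNA, site_type: str, core_start: int) -> SeedSite:
    """The SeedSite that scanning will report for a planted core (1-based)."""
    p = core_start
    coords = {
        "8mer": (p - 1, p + 6),
        "7mer-m8": (p - 1, p + 5),
        "7mer-A1": (p, p + 6),
        "6mer": (p, p + 5),
    }[site_type]
    return SeedSite(site_type, coords[0], coords[1], "", mirna.name)


def generate_utr(
    length: int,
    planted: Sequence[tuple[MiRNA, str, int]],
    rng: np.random.Generator,
    screen_mirnas: Optional[Sequence[MiRNA]] = None,
    max_attempts: int = 1000,
) -> tuple[str, list[SeedSite]]:
    """Random UTR sequence carrying exactly the requested canonical sites.

    ``planted`` lists ``(mirna, site_type, core_start)`` with ``core_start``
    the 1-based position of the 6mer core; positions are clamped so the
    site and its guard bases fit.  Background bases are uniform; guard
    bases adjacent to each core prevent unintended upgrades (e.g. a 6mer
    silently becoming an 8mer).  Any spuriously arising core for a
    screened miRNA is re-rolled locally, up to ``max_attempts`` times,
    which guarantees that scanning recovers exactly the planted sites.
    """
    if length < 20:
        raise ValueError("UTR length must be >= 20")
    screen_mirnas = list(screen_mirnas if screen_mirnas is not None else
                         [m for m, _, _ in planted])
    seq = list(rng.choice(list(_BASES), size=length))

    footprints: list[tuple[int, int]] = []  # 0-based inclusive stamped regions
    expected: set[tuple[str, str, int, int]] = set()
    for mirna, site_type, core_start in planted:
        if site_type not in _SITE_SPAN:
            raise ValueError(f"unknown site type {site_type!r}")
        p1 = int(np.clip(core_start, 2, length - 6))  # 1-based core start
        p = p1 - 1  # 0-based
        lo, hi = p - 1, p + 6
        for flo, fhi in footprints:
            if lo <= fhi and flo <= hi:
                raise UnplaceableSiteError(
                    f"planted sites overlap near position {p1}"
                )
        core = reverse_complement(mirna.seed)
        m8_base = reverse_complement(mirna.seed_extended)[0]
        seq[p : p + 6] = list(core)
        want_m8 = site_type in ("8mer", "7mer-m8")
        want_a1 = site_type in ("8mer", "7mer-A1")
        seq[lo] = m8_base if want_m8 else str(
            rng.choice([b for b in _BASES if b != m8_base]))
        seq[hi] = "A" if want_a1 else str(
            rng.choice([b for b in _BASES if b != "A"]))
        footprints.append((lo, hi))
        site = _expected_site(mirna, site_type, p1)
        expected.add((mirna.name, site.site_type, site.start, site.end))

    def in_footprint(k: int) -> bool:
        return any(flo <= k <= fhi for flo, fhi in footprints)

    for attempt in range(max_attempts + 1):
        fragment = UTRSequence("_", "_", "".join(seq))
        found = {
            (m.name, s.site_type, s.start, s.end)
            for m in screen_mirnas
            for s in find_seed_sites(fragment, m)
        }
        extra = found - expected
        if not extra:
            missing = expected - found
            assert not missing, f"planted sites lost: {missing}"
            break
        if attempt == max_attempts:
            raise UnplaceableSiteError(
                f"could not clear spurious sites after {max_attempts} attempts"
            )
        for _, stype, start, end in extra:
            # re-roll only the 6mer-core positions; hitting the core is what
            # destroys the match (extensions alone would merely retype it)
            core_start = start + 1 if stype in ("8mer", "7mer-m8") else start
            positions = [
                k for k in range(core_start - 1, core_start + 5)
                if not in_footprint(k)
            ]
            if not positions:
                raise UnplaceableSiteError(
                    "spurious site core lies entirely within planted sites"
                )
            for k in positions:
                seq[k] = str(rng.choice(list(_BASES)))

    sequence = "".join(seq)
    sites = [
        SeedSite(stype, start, end, sequence[start - 1 : end], name)
        for name, stype, start, end in sorted(expected, key=lambda t: (t[2], t[3]))
    ]
    return sequence, sites


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return mean
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)
    raise RuntimeError("truncated-normal sampling failed")  # pragma: no cover


def generate_plate(
    mti_truth: pd.DataFrame,
    noise_sd: float = 0.05,
    replicates: int = 4,
    duplicates: int = 2,
    rng: Optional[np.random.Generator] = None,
    control_label: str = "empty",
    renilla_base: float = 1.0e4,
) -> pd.DataFrame:
    """Raw plate readings realizing the given true effects.

    ``mti_truth`` has columns ``construct_id, mirna, true_mean`` (+
    optional ``gene``).  Returns tidy rows ``construct_id[, gene], mirna,
    replicate, duplicate, firefly, renilla`` including one control
    condition (``mirna == control_label``) per construct whose replicate
    ratio is exactly 1.0.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if (mti_truth["true_mean"] <= 0).any():
        raise ValueError("true means must be positive")
    has_gene = "gene" in mti_truth.columns
    genes = (dict(zip(mti_truth["construct_id"], mti_truth["gene"]))
             if has_gene else {})
    rows = []

    def emit(cid, mirna, rep, dup, firefly, renilla):
        row = {"construct_id": cid, "mirna": mirna, "replicate": rep,
               "duplicate": dup, "firefly": firefly, "renilla": renilla}
        if has_gene:
            row["gene"] = genes[cid]
        rows.append(row)

    for cid in sorted(mti_truth["construct_id"].unique()):
        for rep in range(1, replicates + 1):
            for dup in range(1, duplicates + 1):
                renilla = renilla_base * float(np.exp(rng.normal(0.0, 0.1)))
                emit(cid, control_label, rep, dup, renilla, renilla)
    for _, rec in mti_truth.sort_values(["construct_id", "mirna"]).iterrows():
        for rep in range(1, replicates + 1):
            v = _truncated_normal(rng, float(rec["true_mean"]), noise_sd)
            taus = np.abs(rng.normal(0.0, 0.01, size=duplicates // 2))
            offsets = []
            for tau in taus:
                offsets += [tau, -tau]
            offsets += [0.0] * (duplicates - len(offsets))
            for dup, off in enumerate(offsets[:duplicates], start=1):
                renilla = renilla_base * float(np.exp(rng.normal(0.0, 0.1)))
                emit(rec["construct_id"], rec["mirna"], rep, dup,
                     v * (1.0 + off) * renilla, renilla)
    return pd.DataFrame(rows)


@dataclass
class StudyBundle:
    """Everything one synthetic study produced, plus its ground truth."""

    config: StudyConfig
    mirnas: list[MiRNA]
    utrs: dict[str, str]
    plans: dict[str, FragmentPlan]
    fragments: list[UTRSequence]
    truth_sites: pd.DataFrame
    mti_truth: pd.DataFrame
    plates: pd.DataFrame
    predictions: set[tuple[str, str]]
    structures: Optional[dict[str, SecondaryStructure]] = None

    def header_lines(self) -> list[str]:
        from . import __version__

        return [
            f"# utrscreen v{__version__}",
            f"# seed={self.config.rng_seed}",
            f"# config_hash={self.config.config_hash()}",
        ]

    def write(self, outdir) -> None:
        """Serialize the bundle (FASTA / TSV / Vienna / YAML) into a directory."""
        import pathlib

        import yaml

        from . import io as uio

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        header = self.header_lines()
        uio.write_fasta(out / "mirnas.fasta",
                        [(m.name, m.sequence) for m in self.mirnas])
        uio.write_fasta(out / "utrs.fasta", sorted(self.utrs.items()))
        uio.write_fragments_fasta(out / "fragments.fasta", self.fragments)
        uio.write_tsv(out / "truth_sites.tsv", self.truth_sites, header)
        uio.write_tsv(out / "mti_truth.tsv", self.mti_truth, header)
        uio.write_tsv(out / "plates.tsv", self.plates, header)
        if self.structures is not None:
            uio.write_vienna(out / "structures.dbn",
                             sorted(self.structures.items()))
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh, sort_keys=True)


def _auto_planted(
    length: int,
    mirnas: Sequence[MiRNA],
    sites_per_gene: tuple[int, int],
    rng: np.random.Generator,
) -> list[tuple[MiRNA, str, int]]:
    lo, hi = sites_per_gene
    n_sites = int(rng.integers(lo, hi + 1))
    planted = []
    used: list[int] = []
    for _ in range(n_sites):
        for _ in range(50):
            pos = int(rng.integers(2, max(3, length - 6)))
            if all(abs(pos - u) >= 16 for u in used):
                used.append(pos)
                mirna = mirnas[int(rng.integers(len(mirnas)))]
                stype = ("8mer", "7mer-m8", "7mer-A1", "6mer")[
                    int(rng.integers(4))]
                planted.append((mirna, stype, pos))
                break
    return planted


def generate_study(config: StudyConfig) -> StudyBundle:
    """Generate a complete self-consistent synthetic study.

    Deterministic for a fixed ``config`` (including ``rng_seed``): the same
    configuration always yields byte-identical outputs.
    """
    rng = np.random.default_rng(config.rng_seed)
    mirnas = list(config.mirnas)
    by_name = {m.name: m for m in mirnas}

    utrs: dict[str, str] = {}
    plans: dict[str, FragmentPlan] = {}
    fragments: list[UTRSequence] = []
    site_rows = []
    lo, hi = config.utr_length_range
    for g in range(config.n_genes):
        gene = f"G{g + 1:04d}"
        length = int(rng.integers(lo, hi + 1))
        if config.planted_site_spec is not None:
            planted = [
                (by_name[name], stype, pos)
                for name, stype, pos in config.planted_site_spec.get(gene, [])
            ]
        else:
            planted = _auto_planted(length, mirnas, config.sites_per_gene, rng)
        sequence, sites = generate_utr(length, planted, rng,
                                       screen_mirnas=mirnas)
        utrs[gene] = sequence
        for s in sites:
            site_rows.append({
                "gene": gene, "mirna": s.mirna, "site_type": s.site_type,
                "start": s.start, "end": s.end, "target_seq": s.target_seq,
            })
        plan = plan_fragments(length, config.target_len, config.overlap, gene)
        plans[gene] = plan
        fragments.extend(apply_plan(sequence, plan))

    # tested MTIs: fragment x miRNA pairs with at least one site
    truth_rows = []
    for frag in fragments:
        cid = f"{frag.gene}|{frag.fragment_id}"
        for m in mirnas:
            n_sites = len(find_seed_sites(frag, m))
            if n_sites == 0:
                continue
            u = rng.random()
            if u < config.p_repressed:
                effect_class = "repressed"
                mean = float(rng.uniform(*config.repressed_range))
            elif u < config.p_repressed + config.p_upregulated:
                effect_class = "upregulated"
                mean = config.upregulated_mean
            else:
                effect_class = "null"
                mean = config.null_mean
            truth_rows.append({
                "construct_id": cid, "gene": frag.gene, "mirna": m.name,
                "true_mean": mean, "effect_class": effect_class,
                "n_sites": n_sites,
            })

    sensor_seqs: dict[str, str] = {}
    if config.include_sensors:
        for m in mirnas:
            insert = reverse_complement(m.sequence)
            flank = "".join(rng.choice(list(_BASES), size=20))
            cid = f"sensor_{m.name}"
            sensor_seqs[cid] = flank + insert + "UUUU" + insert + flank
            truth_rows.append({
                "construct_id": cid, "gene": cid, "mirna": m.name,
                "true_mean": config.sensor_mean, "effect_class": "sensor",
                "n_sites": 2,
            })

    mti_truth = pd.DataFrame(truth_rows)
    truth_sites = pd.DataFrame(site_rows)
    plates = generate_plate(
        mti_truth, noise_sd=config.noise_sd, replicates=config.replicates,
        duplicates=config.duplicates, rng=rng,
    ) if len(mti_truth) else pd.DataFrame(
        columns=["construct_id", "gene", "mirna", "replicate", "duplicate",
                 "firefly", "renilla"])

    structures = None
    if config.fold_structures:
        structures = {}
        for frag in fragments:
            cid = f"{frag.gene}|{frag.fragment_id}"
            structures[cid] = fold_baseline(frag.sequence)
        for cid, seq in sensor_seqs.items():
            structures[cid] = fold_baseline(seq)

    predictions = {
        (row["gene"], row["mirna"])
        for _, row in mti_truth.iterrows()
        if row["effect_class"] != "sensor"
    }
    return StudyBundle(
        config=config, mirnas=mirnas, utrs=utrs, plans=plans,
        fragments=fragments, truth_sites=truth_sites, mti_truth=mti_truth,
        plates=plates, predictions=predictions, structures=structures,
    )
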