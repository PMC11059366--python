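"""Canonical miRNA seed-site discovery on 3'UTR sequences.

A mature miRNA recognizes its targets chiefly through Watson-Crick pairing of
its seed region (nucleotides 2-7, extended seed 2-8) with the 3'UTR.  The four
canonical site classes are, on the target strand read 5'->3':

* ``6mer``      -- reverse complement of seed positions 2-7;
* ``7mer-m8``   -- reverse complement of positions 2-8;
* ``7mer-A1``   -- the 6mer core followed by an ``A`` opposite miRNA position 1
  (a literal target adenine, regardless of the miRNA's first nucleotide);
* ``8mer``      -- both extensions combined.

Matching here is exact Watson-Crick only; no G:U wobble, no 3'-compensatory
classes.  Each occurrence of the 6mer core is reported once, labeled with the
maximal class supported at that position, so a single physical site is never
counted as several types.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "AlphabetError",
    "MiRNA",
    "UTRSequence",
    "SeedSite",
    "SITE_TYPES",
    "normalize_sequence",
    "reverse_complement",
    "site_patterns",
    "find_seed_sites",
    "count_sites",
    "gc_content",
    "pairwise_site_overlap",
]

#: canonical site classes, strongest first
SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_RNA = set("ACGU")
_COMPLEMENT = str.maketrans("ACGU", "UGCA")


class AlphabetError(ValueError):
    """A sequence contains a character outside {A,C,G,T,U} (case-insensitive)."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position  # 1-based
        super().__init__(
            f"invalid nucleotide {char!r} at position {position} "
            "(expected A/C/G/T/U)"
        )


def normalize_sequence(raw: str) -> str:
    """Uppercase a DNA/RNA string and transcribe T -> U.

    Raises :class:`AlphabetError` naming the 1-based position of the first
    offending character; raises ``ValueError`` on empty input.
    """
    if not raw:
        raise ValueError("empty sequence")
    seq = raw.upper().replace("T", "U")
    for pos, char in enumerate(seq, start=1):
        if char not in _RNA:
            raise AlphabetError(raw[pos - 1], pos)
    return seq


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an RNA string (A<->U, G<->C)."""
    if not seq:
        raise ValueError("empty sequence")
    if not set(seq) <= _RNA:
        bad = next(i for i, c in enumerate(seq, 1) if c not in _RNA)
        raise AlphabetError(seq[bad - 1], bad)
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MiRNA:
    """A mature miRNA with its seed region.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"miR-129-5p"``.
    sequence : str
        Mature sequence 5'->3'; DNA input is normalized to RNA.  Mature
        miRNAs are typically 15-30 nt; at least 8 nt are required so that
        the extended seed (positions 2-8) exists.
    """

    name: str
    sequence: str

    def __post_init__(self):
        self.sequence = normalize_sequence(self.sequence)
        if len(self.sequence) < 8:
            raise ValueError(
                f"miRNA {self.name!r} is {len(self.sequence)} nt; "
                "at least 8 nt are required to define the extended seed"
            )

    @property
    def seed(self) -> str:
        """Seed region: positions 2-7 (6 nt)."""
        return self.sequence[1:7]

    @property
    def seed_extended(self) -> str:
        """Extended seed: positions 2-8 (7 nt)."""
        return self.sequence[1:8]


@dataclass
class UTRSequence:
    """A 3'UTR sequence or reporter-sized fragment thereof.

    ``parent_offset`` is the 1-based start of this fragment within the full
    UTR, so fragment coordinate ``x`` maps to UTR coordinate
    ``parent_offset + x - 1``.
    """

    gene: str
    fragment_id: str
    sequence: str
    parent_offset: int = 1

    def __post_init__(self):
        self.sequence = normalize_sequence(self.sequence)
        if self.parent_offset < 1:
            raise ValueError("parent_offset must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SeedSite:
    """One canonical binding site located on a fragment.

    Coordinates are 1-based inclusive on the fragment, 5'->3'; for 7mer-A1
    and 8mer sites the 3'-most base is the target A opposite miRNA
    position 1.  ``site_type`` is the maximal class supported at the core
    position.
    """

    site_type: str
    start: int
    end: int
    target_seq: str
    mirna: str

    def __post_init__(self):
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        expected = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}[self.site_type]
        if self.end - self.start + 1 != expected:
            raise ValueError(
                f"{self.site_type} site must span {expected} nt, "
                f"got [{self.start},{self.end}]"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


def site_patterns(mirna: MiRNA) -> dict[str, str]:
    """Target-strand patterns (5'->3') for the four canonical site classes.

    The 7mer-A1/8mer target adenine is a literal ``A`` irrespective of the
    miRNA's first nucleotide, following the standard canonical-site
    convention.
    """
    core = reverse_complement(mirna.seed)  # complement of positions 2-7
    m8 = reverse_complement(mirna.seed_extended)  # positions 2-8
    return {
        "6mer": core,
        "7mer-m8": m8,
        "7mer-A1": core + "A",
        "8mer": m8 + "A",
    }


def find_seed_sites(fragment: UTRSequence, mirna: MiRNA) -> list[SeedSite]:
    """Locate all canonical seed sites of ``mirna`` on ``fragment``.

    One :class:`SeedSite` is reported per distinct occurrence of the 6mer
    core, labeled with the maximal supported class (8mer > 7mer-m8 /
    7mer-A1 > 6mer).  Overlapping core occurrences are each reported.
    Returns sites sorted 5'->3' by start; an empty list if nothing matches.
    """
    seq = fragment.sequence
    core = reverse_complement(mirna.seed)
    # target base opposite miRNA position 8 (upstream of the core on the target)
    m8_base = mirna.seed_extended[6].translate(_COMPLEMENT)
    sites: list[SeedSite] = []
    p = seq.find(core)
    while p != -1:  # p is the 0-based core start
        has_m8 = p > 0 and seq[p - 1] == m8_base
        has_a1 = p + 6 < len(seq) and seq[p + 6] == "A"
        # 1-based inclusive coordinates; core occupies [p+1, p+6]
        if has_m8 and has_a1:
            start, end, stype = p, p + 7, "8mer"
        elif has_m8:
            start, end, stype = p, p + 6, "7mer-m8"
        elif has_a1:
            start, end, stype = p + 1, p + 7, "7mer-A1"
        else:
            start, end, stype = p + 1, p + 6, "6mer"
        sites.append(
            SeedSite(
                site_type=stype,
                start=start,
                end=end,
                target_seq=seq[start - 1 : end],
                mirna=mirna.name,
            )
        )
        p = seq.find(core, p + 1)
    sites.sort(key=lambda s: (s.start, s.end))
    return sites


def count_sites(fragment: UTRSequence, mirna: MiRNA) -> int:
    """Number of canonical sites of ``mirna`` on ``fragment``."""
    return len(find_seed_sites(fragment, mirna))


def gc_content(seq: str) -> float:
    """G+C percentage of a sequence, reported to one decimal.

    ``gc_content("UUUUUG")`` -> ``16.7`` (the miR-129-5p seed region).
    """
    if not seq:
        raise ValueError("empty sequence")
    gc = sum(1 for c in seq if c in "GCgc")
    return round(100.0 * gc / len(seq), 1)


def pairwise_site_overlap(
    site_sets: Mapping[str, Iterable[str]],
) -> dict[tuple[str, ...], int]:
    """Fragment-set intersection counts for every miRNA pair and triple.

    ``site_sets`` maps each miRNA name to the set of fragment identifiers
    carrying at least one of its sites.  Keys of the result are sorted
    miRNA-name tuples of length 2 or 3.
    """
    sets = {name: set(ids) for name, ids in site_sets.items()}
    names = sorted(sets)
    out: dict[tuple[str, ...], int] = {}
    for k in (2, 3):
        for combo in itertools.combinations(names, k):
            inter = set.intersection(*(sets[n] for n in combo))
            out[combo] = len(inter)
    return out
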