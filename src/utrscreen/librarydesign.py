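"""Tiling of full-length 3'UTRs into reporter-sized fragments.

Reporter plasmids limit the insert size, so long UTRs are synthesized as
tiles of roughly 675 bp with a fixed 30 bp overlap between consecutive
tiles.  The rule used here: the minimal number of fragments such that no
fragment exceeds ``target_len``, lengths as equal as possible (difference
at most 1 nt, the extra nucleotide going to earlier fragments), and every
consecutive pair overlapping by exactly ``overlap`` nt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .seqsites import UTRSequence, normalize_sequence

__all__ = ["FragmentPlan", "plan_fragments", "apply_plan", "library_summary"]


@dataclass
class FragmentPlan:
    """Tiling plan for one gene's full 3'UTR.

    ``fragments`` holds 1-based inclusive ``(start, end)`` intervals on the
    full UTR, sorted 5'->3', covering ``[1, L]`` without gaps and with each
    consecutive pair overlapping by exactly ``overlap`` nt (single-fragment
    plans excepted).
    """

    gene: str
    fragments: list[tuple[int, int]]
    target_len: int = 675
    overlap: int = 30

    @property
    def utr_length(self) -> int:
        return self.fragments[-1][1] if self.fragments else 0

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)


def plan_fragments(
    utr_length: int,
    target_len: int = 675,
    overlap: int = 30,
    gene: str = "",
) -> FragmentPlan:
    """Plan the tiling of a UTR of ``utr_length`` nt.

    A UTR no longer than ``target_len`` becomes a single fragment
    ``[1, utr_length]``; otherwise ``n = ceil((L - overlap) /
    (target_len - overlap))`` fragments are laid out with exact
    ``overlap``-nt junctions and near-equal lengths.
    """
    if utr_length < 1:
        raise ValueError("utr_length must be >= 1")
    if overlap < 0:
        raise ValueError("overlap must be >= 0")
    if target_len <= overlap:
        raise ValueError("target_len must exceed overlap")
    if utr_length <= target_len:
        return FragmentPlan(gene, [(1, utr_length)], target_len, overlap)

    step = target_len - overlap
    n = math.ceil((utr_length - overlap) / step)
    # total fragment nucleotides, counting each junction twice
    total = utr_length + (n - 1) * overlap
    base, extra = divmod(total, n)
    lengths = [base + 1 if k < extra else base for k in range(n)]
    fragments: list[tuple[int, int]] = []
    start = 1
    for length in lengths:
        fragments.append((start, start + length - 1))
        start = start + length - overlap
    assert fragments[-1][1] == utr_length
    return FragmentPlan(gene, fragments, target_len, overlap)


def apply_plan(utr_sequence: str, plan: FragmentPlan) -> list[UTRSequence]:
    """Cut a full UTR sequence according to ``plan``.

    Fragment identifiers are ``fragment_<k>`` (k starting at 1);
    ``parent_offset`` records each tile's 1-based start on the full UTR.
    """
    seq = normalize_sequence(utr_sequence)
    if plan.utr_length != len(seq):
        raise ValueError(
            f"plan covers {plan.utr_length} nt but sequence is {len(seq)} nt"
        )
    out = []
    for k, (start, end) in enumerate(plan.fragments, start=1):
        out.append(
            UTRSequence(
                gene=plan.gene,
                fragment_id=f"fragment_{k}",
                sequence=seq[start - 1 : end],
                parent_offset=start,
            )
        )
    return out


def library_summary(
    plans: Iterable[FragmentPlan],
    exclusions: Optional[set[tuple[str, int]]] = None,
) -> tuple[int, int]:
    """Totals ``(genes, fragments)`` over a collection of plans.

    ``exclusions`` lists ``(gene, fragment_index)`` pairs (1-based index)
    dropped from the library, e.g. tiles whose synthesis failed.  A gene is
    counted while at least one of its fragments remains.
    """
    exclusions = exclusions or set()
    n_genes = 0
    n_fragments = 0
    for plan in plans:
        kept = [
            k
            for k in range(1, plan.n_fragments + 1)
            if (plan.gene, k) not in exclusions
        ]
        if kept:
            n_genes += 1
            n_fragments += len(kept)
    return n_genes, n_fragments
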