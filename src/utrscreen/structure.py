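"""RNA secondary structure: dot-bracket ingestion, baseline folding,
and windowed accessibility of binding sites.

The primary path is ingestion of externally computed structures (Vienna
dot-bracket records, e.g. RNAfold output), so a production folding engine's
structures can be analyzed verbatim.  :func:`fold_baseline` provides a
self-contained deterministic alternative for fixtures and simulations: a
maximum-weight nested pairing (dynamic programming with pair weights
G-C = 3, A-U = 2, G-U = 1 and a minimum hairpin loop of 3 unpaired bases),
post-filtered to remove isolated base pairs and helix-terminal G-U pairs.
It is an approximation of a thermodynamic MFE structure, not a
reimplementation of any energy model.

Site accessibility is summarized as the percentage of paired bases
(characters ``(`` or ``)``) within the site, optionally extended by a
window of 0/5/50 nt on both sides, clipped to the molecule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .seqsites import SeedSite, normalize_sequence

__all__ = [
    "StructureError",
    "SecondaryStructure",
    "parse_dotbracket",
    "pairs_from_dotbracket",
    "dotbracket_from_pairs",
    "fold_baseline",
    "paired_fraction",
]

MIN_HAIRPIN = 3  # minimum unpaired bases closed by a hairpin pair

#: dynamic-programming pair weights (proxy for hydrogen-bond count)
PAIR_WEIGHTS = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}


class StructureError(ValueError):
    """Malformed secondary structure (unbalanced, pseudoknotted, ...)."""


def pairs_from_dotbracket(dotbracket: str) -> list[tuple[int, int]]:
    """Extract 1-based base pairs ``(i, j)``, ``i < j``, by bracket matching."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, char in enumerate(dotbracket, start=1):
        if char == "(":
            stack.append(pos)
        elif char == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            pairs.append((stack.pop(), pos))
        elif char != ".":
            raise StructureError(
                f"unsupported character {char!r} at position {pos} "
                "(pseudoknot brackets are not supported)"
            )
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(pairs)


def dotbracket_from_pairs(n: int, pairs: Sequence[tuple[int, int]]) -> str:
    chars = ["."] * n
    for i, j in pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


@dataclass
class SecondaryStructure:
    """A sequence with its nested (pseudoknot-free) pairing state.

    ``pairs`` holds 1-based ``(i, j)`` with ``i < j``; every pair spans at
    least :data:`MIN_HAIRPIN` + 1 backbone steps.
    """

    sequence: str
    dotbracket: str
    pairs: list[tuple[int, int]]

    def __post_init__(self):
        if len(self.sequence) != len(self.dotbracket):
            raise StructureError(
                f"sequence ({len(self.sequence)} nt) and structure "
                f"({len(self.dotbracket)} chars) differ in length"
            )
        for i, j in self.pairs:
            if j - i - 1 < MIN_HAIRPIN:
                raise StructureError(
                    f"pair ({i},{j}) closes a hairpin loop of "
                    f"{j - i - 1} < {MIN_HAIRPIN} bases"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def paired_mask(self) -> np.ndarray:
        """Boolean array, ``mask[k]`` true when base ``k+1`` is paired."""
        mask = np.zeros(len(self), dtype=bool)
        for i, j in self.pairs:
            mask[i - 1] = True
            mask[j - 1] = True
        return mask

    def helices(self) -> list[list[tuple[int, int]]]:
        """Maximal stacks of consecutively nested pairs, outermost first."""
        pair_set = set(self.pairs)
        helices = []
        for i, j in sorted(pair_set):
            if (i - 1, j + 1) in pair_set:
                continue  # not a helix start
            run = []
            a, b = i, j
            while (a, b) in pair_set:
                run.append((a, b))
                a, b = a + 1, b - 1
            helices.append(run)
        return helices


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Parse one Vienna-format record.

    Accepts an optional ``>name`` header line, a sequence line and a
    structure line; a trailing free-energy annotation on the structure line
    (e.g. ``(((...))) (-3.40)``) is ignored.
    """
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if len(lines) < 2:
        raise StructureError("expected a sequence line and a structure line")
    sequence = normalize_sequence(lines[0])
    dotbracket = lines[1].split()[0]
    pairs = pairs_from_dotbracket(dotbracket)
    return SecondaryStructure(sequence=sequence, dotbracket=dotbracket, pairs=pairs)


def _weight_matrix(seq: str) -> np.ndarray:
    n = len(seq)
    code = np.array([{"A": 0, "C": 1, "G": 2, "U": 3}[c] for c in seq])
    table = np.zeros((4, 4))
    table[2, 1] = table[1, 2] = 3.0
    table[0, 3] = table[3, 0] = 2.0
    table[2, 3] = table[3, 2] = 1.0
    return table[code[:, None], code[None, :]]


def _fill_dp(w: np.ndarray) -> np.ndarray:
    """Maximum-weight nested pairing table.

    Returns ``DP`` with one leading sentinel column: ``DP[i, j + 1]`` is the
    optimum for subsequence ``[i, j]`` (0-based inclusive) and
    ``DP[:, 0] == 0``, so ``DP[i, k]`` doubles as ``dp[i][k - 1]``.
    """
    n = w.shape[0]
    DP = np.zeros((n + 1, n + 1))
    span = MIN_HAIRPIN + 1
    for j in range(span, n):
        wv = w[: j - MIN_HAIRPIN, j]  # candidate partners k <= j - span
        ks = np.nonzero(wv)[0]
        if ks.size == 0:
            DP[: j + 1, j + 1] = DP[: j + 1, j]
            continue
        # c[k] = dp[k+1][j-1] + weight(k, j)
        c = DP[ks + 1, j] + wv[ks]
        # A[i, t] = dp[i][ks[t]-1] + c[t], invalid where ks[t] < i
        A = DP[: j + 1][:, ks] + c[None, :]
        invalid = ks[None, :] < np.arange(j + 1)[:, None]
        A[invalid] = -np.inf
        best = A.max(axis=1)
        DP[: j + 1, j + 1] = np.maximum(DP[: j + 1, j], best)
    return DP


def _traceback(DP: np.ndarray, w: np.ndarray) -> list[tuple[int, int]]:
    n = w.shape[0]
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        while j - i >= MIN_HAIRPIN + 1:
            if DP[i, j + 1] == DP[i, j]:
                j -= 1
                continue
            target = DP[i, j + 1]
            for k in range(i, j - MIN_HAIRPIN):
                wk = w[k, j]
                if wk and DP[i, k] + DP[k + 1, j] + wk == target:
                    pairs.append((k, j))
                    stack.append((k + 1, j - 1))
                    j = k - 1
                    break
            else:  # pragma: no cover - DP consistency guard
                raise AssertionError("traceback failed")
    return pairs


def _filter_pairs(seq: str, pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Drop helix-terminal G-U pairs, then isolated (length-1) helices."""

    def is_gu(p: tuple[int, int]) -> bool:
        a, b = seq[p[0] - 1], seq[p[1] - 1]
        return {a, b} == {"G", "U"}

    struct = SecondaryStructure(seq, dotbracket_from_pairs(len(seq), pairs), pairs)
    kept: list[tuple[int, int]] = []
    for helix in struct.helices():
        while helix and is_gu(helix[0]):
            helix = helix[1:]
        while helix and is_gu(helix[-1]):
            helix = helix[:-1]
        if len(helix) >= 2:
            kept.extend(helix)
    return sorted(kept)


def fold_baseline(seq: str) -> SecondaryStructure:
    """Deterministic maximum-weight nested structure of an RNA sequence.

    Pair weights G-C = 3 / A-U = 2 / G-U = 1, minimum hairpin loop of 3
    unpaired bases; the optimum is post-filtered so that no isolated base
    pair and no helix-terminal G-U pair remains.  Ties in the dynamic
    program are broken deterministically (3'-most base left unpaired first,
    then the 5'-most admissible partner).
    """
    sequence = normalize_sequence(seq)
    if len(sequence) < 10:
        raise ValueError("sequence too short to fold (need >= 10 nt)")
    w = _weight_matrix(sequence)
    # 1-based pairs out of the 0-based traceback
    raw = [(i + 1, j + 1) for i, j in _traceback(_fill_dp(w), w)]
    pairs = _filter_pairs(sequence, raw)
    return SecondaryStructure(
        sequence=sequence,
        dotbracket=dotbracket_from_pairs(len(sequence), pairs),
        pairs=pairs,
    )


def paired_fraction(
    structure: SecondaryStructure,
    site: SeedSite | tuple[int, int],
    window: int = 0,
) -> float:
    """Percentage of paired bases in a site extended by ``window`` nt.

    The interval ``[start - window, end + window]`` is clipped to the
    molecule; the value is ``100 * paired / total`` over the clipped
    interval.
    """
    start, end = (site.start, site.end) if isinstance(site, SeedSite) else site
    n = len(structure)
    if not (1 <= start <= end <= n):
        raise ValueError(f"site [{start},{end}] out of bounds for {n} nt structure")
    if window < 0:
        raise ValueError("window must be >= 0")
    lo = max(1, start - window)
    hi = min(n, end + window)
    segment = structure.dotbracket[lo - 1 : hi]
    paired = sum(1 for c in segment if c in "()")
    return 100.0 * paired / len(segment)
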