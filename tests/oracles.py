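"""Independent reference implementations used only to check the package.

Everything here is deliberately written from first principles (explicit
per-offset string comparison, exhaustive enumeration, textbook formulas,
double loops) and shares no code with the package.
"""

from __future__ import annotations

import math
from itertools import combinations

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def scan_oracle(seq: str, mirna_seq: str) -> list[tuple[str, int, int]]:
    """Exhaustive per-offset comparison of all four canonical patterns.

    Returns (site_type, start, end) with 1-based inclusive coordinates,
    maximal type per 6mer-core occurrence, sorted by start.
    """
    core = rc(mirna_seq[1:7])
    m8 = rc(mirna_seq[1:8])
    hits = []
    for p in range(len(seq) - 5):  # p = 0-based core start
        if seq[p : p + 6] != core:
            continue
        if p >= 1 and seq[p - 1 : p + 7] == m8 + "A":
            hits.append(("8mer", p, p + 7))
        elif p >= 1 and seq[p - 1 : p + 6] == m8:
            hits.append(("7mer-m8", p, p + 6))
        elif seq[p : p + 7] == core + "A":
            hits.append(("7mer-A1", p + 1, p + 7))
        else:
            hits.append(("6mer", p + 1, p + 6))
    return sorted(hits, key=lambda h: (h[1], h[2]))


_W = {("G", "C"): 3, ("C", "G"): 3, ("A", "U"): 2, ("U", "A"): 2,
      ("G", "U"): 1, ("U", "G"): 1}


def max_pairing_weight(seq: str, min_hairpin: int = 3) -> float:
    """Maximum total pair weight over *all* nested structures, by brute
    enumeration on the first position (feasible up to ~13 nt)."""

    def best(i: int, j: int) -> float:
        if j - i < min_hairpin + 1:
            return 0.0
        candidates = [best(i + 1, j)]  # i unpaired
        for k in range(i + min_hairpin + 1, j + 1):
            w = _W.get((seq[i], seq[k]))
            if w:
                candidates.append(w + best(i + 1, k - 1) + best(k + 1, j))
        return max(candidates)

    return best(0, len(seq) - 1)


def all_max_structures(seq: str, min_hairpin: int = 3) -> list[frozenset]:
    """Every nested pair set achieving the maximum weight (0-based pairs)."""

    def structs(i: int, j: int):
        if j - i < min_hairpin + 1:
            yield frozenset()
            return
        yield from structs(i + 1, j)
        for k in range(i + min_hairpin + 1, j + 1):
            if (seq[i], seq[k]) in _W:
                for inner in structs(i + 1, k - 1):
                    for outer in structs(k + 1, j):
                        yield inner | outer | {(i, k)}

    scored = [(sum(_W[(seq[i], seq[k])] for i, k in s), s)
              for s in set(structs(0, len(seq) - 1))]
    top = max(w for w, _ in scored)
    return [s for w, s in scored if w == top]


def brute_coverage(coords, start: int, end: int, r: float) -> float:
    """Coverage score by explicit double loop (1-based site coords)."""
    total = 0
    for s in range(start - 1, end):
        for v in range(len(coords)):
            dx = coords[s][0] - coords[v][0]
            dy = coords[s][1] - coords[v][1]
            if math.sqrt(dx * dx + dy * dy) <= r:
                total += 1
    return total / (end - start + 1)


def welch_closed_form(a, b) -> tuple[float, float, float]:
    """Textbook Welch t statistic, Welch-Satterthwaite df and two-sided p."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * tdist.sf(abs(t), df)
    return t, df, p


def pearson_closed_form(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return cov / (sx * sy)


def random_rna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))
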