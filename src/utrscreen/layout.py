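"""2D structure layouts and the coverage score of a binding site.

The coverage score measures how crowded the neighbourhood of a seed site is
in a planar drawing of the secondary structure.  The structure is a graph
``G = (V, E)``: vertices are bases, edges are backbone adjacencies plus
base-pair bonds.  Given per-vertex 2D coordinates, the score of a site
``S`` at radius ``r`` is

    score(S, r) = (1 / |S|) * sum_{s in S} #{ v in V : ||v - s||_2 <= r }

i.e. the mean number of vertices inside a closed Euclidean ball of radius
``r`` around each site base (the base itself counts).  A low score means an
open, accessible site; a high score a buried one.  When a fragment carries
several sites, the site with the smallest score — the most accessible one —
represents the fragment.

Coordinates are expressed in *length units*: after rescaling, the mean
distance between backbone-adjacent bases is exactly 1.  Layouts can be
computed here (:func:`layout_2d`, a deterministic radial loop drawing) or
imported from Graph Modeling Language files written by external drawing
tools (:func:`import_gml`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .seqsites import SeedSite
from .structure import SecondaryStructure, StructureError

__all__ = [
    "StructureLayout",
    "CoverageResult",
    "DEFAULT_RADII",
    "layout_2d",
    "export_gml",
    "import_gml",
    "coverage_score",
    "min_coverage_over_sites",
]

#: default radius sweep, in length units
DEFAULT_RADII = (0.8, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0)

_PAIR_SPAN = 1.0  # drawn distance between paired bases, before rescale


@dataclass
class StructureLayout:
    """Planar embedding of a secondary structure.

    ``coords`` is an ``(n, 2)`` array of vertex positions in length units
    (mean backbone-adjacent distance 1); ``pairs`` the 1-based base pairs;
    ``sequence`` the bases, when known.
    """

    coords: np.ndarray
    pairs: list[tuple[int, int]]
    sequence: Optional[str] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("layout coordinates must be finite")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.coords.shape[0]

    def backbone_spacings(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.coords, axis=0), axis=1)

    def rescaled(self) -> "StructureLayout":
        """Copy with coordinates scaled to unit mean backbone spacing."""
        spacings = self.backbone_spacings()
        if spacings.size == 0:
            return StructureLayout(self.coords.copy(), list(self.pairs), self.sequence)
        mean = spacings.mean()
        if mean <= 0:
            raise ValueError("degenerate layout: zero mean backbone spacing")
        return StructureLayout(self.coords / mean, list(self.pairs), self.sequence)

    def to_graph(self) -> nx.Graph:
        """G = (V, E): backbone path plus base-pair bonds, 1-based nodes."""
        g = nx.Graph()
        for k in range(self.n_vertices):
            label = self.sequence[k] if self.sequence else ""
            g.add_node(k + 1, label=label, x=float(self.coords[k, 0]),
                       y=float(self.coords[k, 1]))
        for k in range(self.n_vertices - 1):
            g.add_edge(k + 1, k + 2, kind="backbone")
        for i, j in self.pairs:
            if g.has_edge(i, j):
                continue
            g.add_edge(i, j, kind="pair")
        return g


@dataclass
class CoverageResult:
    """Coverage score of one site at one radius.

    ``site`` is the scored :class:`~utrscreen.seqsites.SeedSite` (or a bare
    ``(start, end)`` interval when scored positionally).
    """

    site: "SeedSite | tuple[int, int]"
    radius: float
    score: float
    is_min_over_sites: bool = False

    @property
    def start(self) -> int:
        return self.site.start if isinstance(self.site, SeedSite) else self.site[0]


def _loop_items(
    partner: np.ndarray, lo: int, hi: int
) -> list[tuple[str, int, int, int]]:
    """Top-level members of the region [lo, hi] (0-based inclusive).

    Yields ``("u", k, -1, -1)`` for unpaired bases and ``("h", k, q, h)``
    for a child helix: a maximal stack of ``h`` pairs starting at (k, q).
    """
    items = []
    k = lo
    while k <= hi:
        q = partner[k]
        if q == -1:
            items.append(("u", k, -1, -1))
            k += 1
        else:
            h = 1
            while partner[k + h] == q - h and q - h > k + h:
                h += 1
            items.append(("h", k, q, h))
            k = q + 1
    return items


def layout_2d(structure: SecondaryStructure) -> StructureLayout:
    """Deterministic radial loop layout of a nested structure.

    The exterior loop is drawn on a straight line; every interior loop is a
    circle whose circumference accommodates its members at unit spacing;
    helices are two parallel strands with unit rung spacing and constant
    pair span.  Coordinates are rescaled to unit mean backbone spacing.
    """
    n = len(structure)
    partner = np.full(n, -1, dtype=int)
    for i, j in structure.pairs:
        partner[i - 1] = j - 1
        partner[j - 1] = i - 1
    coords = np.zeros((n, 2))

    def place_helix(k: int, q: int, h: int, p5: np.ndarray, p3: np.ndarray,
                    d: np.ndarray) -> None:
        for t in range(h):
            coords[k + t] = p5 + d * t
            coords[q - t] = p3 + d * t
        inner5, inner3 = k + h - 1, q - h + 1
        if inner3 - inner5 - 1 >= 1:  # the closing pair encloses a loop
            place_loop(inner5, inner3, coords[inner5], coords[inner3], d)

    def place_loop(a: int, b: int, p5: np.ndarray, p3: np.ndarray,
                   d: np.ndarray) -> None:
        """Draw the loop closed by pair (a, b), whose bases sit at p5/p3."""
        items = _loop_items(partner, a + 1, b - 1)
        k_slots = 2 + sum(1 if it[0] == "u" else 2 for it in items)
        radius = 0.5 / math.sin(math.pi / k_slots)
        apothem = radius * math.cos(math.pi / k_slots)
        center = (p5 + p3) / 2.0 + d * apothem
        phi5 = math.atan2(p5[1] - center[1], p5[0] - center[0])
        phi3 = math.atan2(p3[1] - center[1], p3[0] - center[0])
        delta_short = math.atan2(math.sin(phi3 - phi5), math.cos(phi3 - phi5))
        sweep = delta_short - math.copysign(2 * math.pi, delta_short)
        step = sweep / (k_slots - 1)

        def slot_pos(s: float) -> np.ndarray:
            ang = phi5 + step * s
            return center + radius * np.array([math.cos(ang), math.sin(ang)])

        s = 1
        for it in items:
            if it[0] == "u":
                coords[it[1]] = slot_pos(s)
                s += 1
            else:
                _, k, q, h = it
                q5, q3 = slot_pos(s), slot_pos(s + 1)
                mid = (q5 + q3) / 2.0
                dd = mid - center
                dd = dd / np.linalg.norm(dd)
                place_helix(k, q, h, q5, q3, dd)
                s += 2

    # exterior loop: straight line along +x, helices branch upward
    x = 0.0
    for it in _loop_items(partner, 0, n - 1):
        if it[0] == "u":
            coords[it[1]] = (x, 0.0)
            x += 1.0
        else:
            _, k, q, h = it
            place_helix(k, q, h, np.array([x, 0.0]),
                        np.array([x + _PAIR_SPAN, 0.0]), np.array([0.0, 1.0]))
            x += _PAIR_SPAN + 1.0
    layout = StructureLayout(coords, list(structure.pairs), structure.sequence)
    return layout.rescaled()


def export_gml(layout: StructureLayout, path) -> None:
    """Write a layout as a GML graph with per-node ``x``/``y`` coordinates."""
    nx.write_gml(layout.to_graph(), str(path))


def import_gml(path) -> StructureLayout:
    """Read a GML structure graph back into a :class:`StructureLayout`.

    Node order (by integer id) is taken as backbone order; nodes must carry
    ``x``/``y`` coordinates (a nested ``graphics`` record is also accepted).
    Edges between non-consecutive nodes, or tagged ``kind "pair"``, become
    base pairs.  Coordinates are rescaled to unit mean backbone spacing.
    """
    g = nx.read_gml(str(path), label="id")
    if g.number_of_nodes() == 0:
        raise StructureError("empty GML graph")
    nodes = sorted(g.nodes)
    coords = []
    labels = []
    for node in nodes:
        attrs = g.nodes[node]
        x = attrs.get("x", attrs.get("graphics", {}).get("x"))
        y = attrs.get("y", attrs.get("graphics", {}).get("y"))
        if x is None or y is None:
            raise StructureError(f"node {node} lacks x/y coordinates")
        coords.append((float(x), float(y)))
        labels.append(str(attrs.get("label", "")))
    index = {node: k for k, node in enumerate(nodes)}
    pairs = []
    for u, v in g.edges:
        iu, iv = sorted((index[u], index[v]))
        kind = g.edges[u, v].get("kind")
        if kind == "backbone" or (kind is None and iv - iu == 1):
            continue
        pairs.append((iu + 1, iv + 1))
    for k in range(len(nodes) - 1):
        if not g.has_edge(nodes[k], nodes[k + 1]):
            raise StructureError(
                f"disconnected backbone between bases {k + 1} and {k + 2}"
            )
    sequence = "".join(labels) if all(len(l) == 1 for l in labels) else None
    layout = StructureLayout(np.array(coords), sorted(pairs), sequence)
    return layout.rescaled()


def coverage_score(
    layout: StructureLayout,
    site: SeedSite | tuple[int, int],
    r: float,
) -> CoverageResult:
    """Coverage score of ``site`` at radius ``r`` (length units).

    For every site base the vertices within a *closed* ball of radius ``r``
    are counted (each base counts itself); the score is the total divided
    by the site length, so it is at least 1 and at most ``|V|`` and is
    non-decreasing in ``r``.
    """
    if r <= 0:
        raise ValueError("radius must be > 0")
    start, end = (site.start, site.end) if isinstance(site, SeedSite) else site
    n = layout.n_vertices
    if not (1 <= start <= end <= n):
        raise ValueError(f"site [{start},{end}] out of bounds for {n}-vertex layout")
    seed = layout.coords[start - 1 : end]
    diff = seed[:, None, :] - layout.coords[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    counts = (dist <= r).sum(axis=1)
    score = float(counts.sum()) / (end - start + 1)
    return CoverageResult(site=site, radius=float(r), score=score)


def min_coverage_over_sites(
    layout: StructureLayout,
    sites: Sequence[SeedSite],
    r: float,
) -> CoverageResult:
    """The most accessible site: minimal coverage score at radius ``r``.

    Ties are broken toward the 5'-most site.  Raises on an empty site list.
    """
    if not sites:
        raise ValueError("need at least one site")
    results = [coverage_score(layout, s, r) for s in sites]
    best = min(results, key=lambda cr: (cr.score, cr.start))
    best.is_min_over_sites = True
    return best
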