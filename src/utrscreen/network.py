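"""Bipartite miRNA-target interaction (MTI) networks and screen arithmetic.

Genes and miRNAs form the two node sets of a complete bipartite graph;
every edge is a potential MTI annotated with three evidence flags:
``predicted`` (computational target prediction), ``tested`` (assayed in
the reporter screen) and ``validated`` (repressed per the screen's rule;
validation implies testing).
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Optional, Set, Tuple

import networkx as nx

__all__ = ["MTINetwork", "build_network", "fold_increase", "mti_space_size"]

Edge = Tuple[str, str]  # (gene, mirna)


class MTINetwork:
    """A complete bipartite gene x miRNA graph with per-edge evidence."""

    def __init__(self, graph: nx.Graph, genes: list[str], mirnas: list[str]):
        self.graph = graph
        self.genes = genes
        self.mirnas = mirnas

    def _edges_with(self, flag: str) -> set[Edge]:
        return {
            (g, m)
            for g in self.genes
            for m in self.mirnas
            if self.graph.edges[g, m][flag]
        }

    @property
    def total_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree_histogram(self, flag: str = "validated") -> Counter:
        """Genes binned by how many miRNAs hit them under ``flag``."""
        per_gene = Counter(g for g, _ in self._edges_with(flag))
        return Counter(per_gene.get(g, 0) for g in self.genes)

    def summary(self) -> dict:
        """Edge counts, coverage and confirmation rates (one decimal %)."""
        predicted = self._edges_with("predicted")
        tested = self._edges_with("tested")
        validated = self._edges_with("validated")
        confirmed = validated & predicted
        total = self.total_edges
        out = {
            "n_genes": len(self.genes),
            "n_mirnas": len(self.mirnas),
            "total_edges": total,
            "predicted_edges": len(predicted),
            "tested_edges": len(tested),
            "validated_edges": len(validated),
            "validated_and_predicted": len(confirmed),
            "pct_predicted": round(100.0 * len(predicted) / total, 1) if total else 0.0,
            "pct_validated_of_total": (
                round(100.0 * len(confirmed) / total, 1) if total else 0.0
            ),
            "confirmation_rate": (
                round(100.0 * len(confirmed) / len(predicted), 1)
                if predicted
                else float("nan")
            ),
            "genes_by_validated_mirnas": dict(sorted(self.degree_histogram().items())),
        }
        return out

    def to_edge_table(self):
        import pandas as pd

        rows = []
        for g in self.genes:
            for m in self.mirnas:
                attrs = self.graph.edges[g, m]
                rows.append({
                    "gene": g, "mirna": m,
                    "predicted": attrs["predicted"],
                    "tested": attrs["tested"],
                    "validated": attrs["validated"],
                })
        return pd.DataFrame(rows)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, str(path))


def build_network(
    genes: Iterable[str],
    mirnas: Iterable[str],
    predicted: Optional[Set[Edge]] = None,
    tested: Optional[Set[Edge]] = None,
    validated: Optional[Set[Edge]] = None,
) -> MTINetwork:
    """Complete bipartite network over ``genes`` x ``mirnas``.

    Evidence sets contain ``(gene, mirna)`` pairs; ``validated`` must be a
    subset of ``tested`` (a validation implies an assay), while
    ``predicted`` is independent evidence.
    """
    genes = sorted(set(genes))
    mirnas = sorted(set(mirnas))
    predicted = set(predicted or ())
    tested = set(tested or ())
    validated = set(validated or ())
    if not validated <= tested:
        raise ValueError("validated edges must be a subset of tested edges")
    graph = nx.Graph()
    graph.add_nodes_from(genes, bipartite="gene")
    graph.add_nodes_from(mirnas, bipartite="mirna")
    for g in genes:
        for m in mirnas:
            graph.add_edge(
                g, m,
                predicted=(g, m) in predicted,
                tested=(g, m) in tested,
                validated=(g, m) in validated,
            )
    return MTINetwork(graph, genes, mirnas)


def fold_increase(prior_count: int, new_total: int) -> float:
    """Ratio of a new validated-MTI total to a prior count, one decimal."""
    if prior_count < 1:
        raise ValueError("undefined ratio: prior count must be >= 1")
    return round(new_total / prior_count, 1)


def mti_space_size(n_genes: int, n_mirnas: int) -> int:
    """Size of the full interaction space: every gene x every miRNA."""
    if n_genes <= 0 or n_mirnas <= 0:
        raise ValueError("counts must be positive")
    return n_genes * n_mirnas
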