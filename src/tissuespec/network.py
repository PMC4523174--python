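"""Tissue co-enrichment network built from group-enriched classifications.

The network has two node kinds: tissue nodes, and combination nodes, one
per distinct enriched tissue group (each group contains the target
tissue).  A combination node carries the number of genes enriched in
exactly that group and is linked to each of its member tissues.  Groups
larger than ``max_combo`` are excluded from the network display but still
counted in per-tissue sharing tallies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .specificity import SpecificityResult

__all__ = ["EnrichmentNetwork", "build_network", "shared_tissue_counts"]


@dataclass
class EnrichmentNetwork:
    """Group-enrichment network around one target tissue."""

    target_tissue: str
    graph: nx.Graph
    combo_gene_count: dict[frozenset[str], int]
    target_enriched_count: int

    @property
    def tissue_nodes(self) -> set[str]:
        return {
            n for n, d in self.graph.nodes(data=True) if d.get("kind") == "tissue"
        }

    @property
    def combo_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("kind") == "combo"}

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))

    def edge_list_frame(self) -> pd.DataFrame:
        rows = [
            {
                "combo": a if self.graph.nodes[a]["kind"] == "combo" else b,
                "tissue": b if self.graph.nodes[a]["kind"] == "combo" else a,
                "n_genes": self.graph.nodes[
                    a if self.graph.nodes[a]["kind"] == "combo" else b
                ]["weight"],
            }
            for a, b in self.graph.edges()
        ]
        return pd.DataFrame(rows, columns=["combo", "tissue", "n_genes"])


def _combo_label(group: frozenset[str]) -> str:
    return "|".join(sorted(group))


def build_network(
    results: list[SpecificityResult],
    target_tissue: str,
    max_combo: int = 4,
) -> EnrichmentNetwork:
    """Build the co-enrichment network from classification results.

    ``max_combo`` caps the group size shown (display convention); the
    target's own enriched-gene count (highly + moderately) is stored as a
    node attribute on the target tissue.
    """
    combo_counts: Counter[frozenset[str]] = Counter()
    n_enriched = 0
    for r in results:
        if r.category in ("highly_enriched", "moderately_enriched"):
            n_enriched += 1
        elif r.category == "group_enriched" and 0 < len(r.group) <= max_combo:
            combo_counts[r.group] += 1

    g = nx.Graph()
    g.add_node(
        target_tissue, kind="tissue", weight=n_enriched, target=True
    )
    for group, count in combo_counts.items():
        label = _combo_label(group)
        g.add_node(label, kind="combo", weight=count)
        for tissue in sorted(group):
            if tissue not in g:
                g.add_node(tissue, kind="tissue", weight=0, target=False)
            g.add_edge(label, tissue)
    return EnrichmentNetwork(
        target_tissue=target_tissue,
        graph=g,
        combo_gene_count=dict(combo_counts),
        target_enriched_count=n_enriched,
    )


def shared_tissue_counts(
    results: list[SpecificityResult], target_tissue: str
) -> dict[str, int]:
    """Genes each non-target tissue shares with the target in enriched groups.

    Counts every group-enriched gene whose group contains both the tissue
    and the target, regardless of group size.
    """
    counts: Counter[str] = Counter()
    for r in results:
        if r.category != "group_enriched" or target_tissue not in r.group:
            continue
        for tissue in r.group:
            if tissue != target_tissue:
                counts[tissue] += 1
    return dict(counts)
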