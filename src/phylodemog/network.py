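"""Statistical-parsimony (TCS-style) haplotype networks.

The connection limit is the largest number of mutational steps for which
the cumulative probability that a connection is parsimonious (no
superimposed change along the path) still reaches the confidence level;
haplotype pairs within the limit are joined in increasing distance order,
multi-step connections receive synthetic "missing" intermediate nodes, and
alternative equal-length connections are kept and reported as loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .alignment import HaplotypeAlignment

__all__ = [
    "parsimony_probability",
    "connection_limit",
    "HaplotypeNetwork",
    "build_network",
    "modal_haplotype",
]


def parsimony_probability(j: int, L: int) -> float:
    """Probability that a j-step connection over L sites is parsimonious.

    Computed as the probability that none of the j changes is superimposed
    on another along the connecting lineage, accumulated multiplicatively:
    P_j = prod_{i=1..j} (1 - i/(2L)). Behaviour is pinned to the TCS
    program lineage, which yields a 15-step limit at 95% for 1248 sites.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if j < 0:
        raise ValueError("j must be >= 0")
    if j >= 2 * L:
        return 0.0
    i = np.arange(1, j + 1, dtype=float)
    return float(np.prod(1.0 - i / (2.0 * L)))


def connection_limit(L: int, confidence: float = 0.95) -> int:
    """Largest step count whose parsimony probability is >= confidence."""
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    j = 0
    while parsimony_probability(j + 1, L) >= confidence:
        j += 1
    return j


@dataclass
class HaplotypeNetwork:
    """Single-step haplotype graph with inferred intermediates.

    Real haplotype nodes carry ``kind='haplotype'`` and a frequency; synthetic
    intermediates ("missing haplotypes") carry ``kind='intermediate'`` and ids
    ``m1, m2, ...`` numbered per component in insertion order.
    """

    graph: nx.Graph
    connection_limit: int
    loops: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def components(self) -> list[set[str]]:
        comps = [set(c) for c in nx.connected_components(self.graph)]
        return sorted(comps, key=lambda c: (-len(c), min(c)))

    def component_haplotypes(self) -> list[list[str]]:
        out = []
        for comp in self.components:
            out.append(
                sorted(
                    n for n in comp if self.graph.nodes[n]["kind"] == "haplotype"
                )
            )
        return out

    def write_gml(self, path: str | Path) -> None:
        nx.write_gml(self.graph, str(path))

    def write_edge_tsv(self, path: str | Path) -> None:
        rows = [
            {"node_a": a, "node_b": b, "steps": 1}
            for a, b in sorted(self.graph.edges())
        ]
        pd.DataFrame(rows, columns=["node_a", "node_b", "steps"]).to_csv(
            path, sep="\t", index=False
        )

    def component_summary(self) -> pd.DataFrame:
        rows = []
        for i, comp in enumerate(self.components, start=1):
            haps = [n for n in comp if self.graph.nodes[n]["kind"] == "haplotype"]
            rows.append(
                {
                    "component": i,
                    "n_haplotypes": len(haps),
                    "n_intermediates": len(comp) - len(haps),
                    "haplotypes": ",".join(sorted(haps)),
                }
            )
        return pd.DataFrame(rows)


def build_network(aln: HaplotypeAlignment, limit: int) -> HaplotypeNetwork:
    """Agglomerative statistical-parsimony network up to ``limit`` steps.

    Pairs are connected in rounds of increasing distance d = 1..limit; within
    a round, pairs whose components were already distinct at the start of the
    round are joined (d > 1 via a chain of intermediates), ordered by the
    summed frequency of their endpoints (the higher-frequency, more probably
    ancestral haplotype connects first) then by id. An edge that closes a
    cycle formed within the same round is recorded as a loop and retained.
    """
    if limit < 1:
        raise ValueError("connection limit must be >= 1")
    g = nx.Graph()
    counts = dict(zip(aln.haplotype_ids, aln.haplotype_counts()))
    for h in aln.haplotype_ids:
        g.add_node(h, kind="haplotype", frequency=int(counts[h]))
    d = aln.pairwise_differences()
    loops: list[tuple[str, str, int]] = []
    n_mid = 0

    for step in range(1, limit + 1):
        pairs = [
            (aln.haplotype_ids[i], aln.haplotype_ids[j])
            for i in range(aln.k)
            for j in range(i + 1, aln.k)
            if d[i, j] == step
        ]
        pairs.sort(key=lambda ab: (-(counts[ab[0]] + counts[ab[1]]), ab[0], ab[1]))
        comp_at_start = {
            node: ci for ci, comp in enumerate(nx.connected_components(g))
            for node in comp
        }
        for a, b in pairs:
            same_before = comp_at_start[a] == comp_at_start[b]
            if same_before:
                # already linked at a shorter distance: not an alternative path
                continue
            if nx.has_path(g, a, b):
                loops.append((a, b, step))
            prev = a
            for _ in range(step - 1):
                n_mid += 1
                mid = f"_m{n_mid}"
                g.add_node(mid, kind="intermediate", frequency=0)
                g.add_edge(prev, mid)
                prev = mid
            g.add_edge(prev, b)

    _relabel_intermediates(g)
    return HaplotypeNetwork(graph=g, connection_limit=limit, loops=loops)


def _relabel_intermediates(g: nx.Graph) -> None:
    """Give intermediates ids m1, m2, ... consecutive within each component.

    Ids follow insertion order inside a component; the counter continues
    across components so node ids stay unique in the graph.
    """
    mapping = {}
    counter = 0
    for comp in sorted(nx.connected_components(g), key=min):
        mids = sorted(
            (n for n in comp if g.nodes[n]["kind"] == "intermediate"),
            key=lambda s: int(s[2:]),
        )
        for node in mids:
            counter += 1
            mapping[node] = f"m{counter}"
    nx.relabel_nodes(g, mapping, copy=False)


def modal_haplotype(net: HaplotypeNetwork, aln: HaplotypeAlignment) -> dict[int, str]:
    """Most frequent haplotype per component (candidate ancestral haplotype).

    Ties break first toward the haplotype with more network connections,
    then toward the lexically smaller id.
    """
    counts = dict(zip(aln.haplotype_ids, aln.haplotype_counts()))
    out: dict[int, str] = {}
    for i, comp in enumerate(net.components, start=1):
        haps = [n for n in comp if net.graph.nodes[n]["kind"] == "haplotype"]
        if not haps:
            raise ValueError("component without haplotypes")
        out[i] = min(
            haps,
            key=lambda h: (-counts[h], -net.graph.degree(h), h),
        )
    return out
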