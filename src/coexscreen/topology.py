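"""Degree / core-number topology per group network and the candidate screen.

A gene's importance in one group's network is its degree (number of
incident edges, both styles counted) and its core number (largest k such
that the gene survives iterative removal of all nodes with degree < k).
Differential hubness is the exact integer difference case minus control of
each statistic; candidates are the genes whose differential hubness
dominates an anchor gene's in magnitude, componentwise with ties allowed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from coexscreen.network import GroupNetwork, POSITIVE

DEFAULT_TOP_K = 20


@dataclass(frozen=True)
class TopologyRecord:
    """Per-gene degree and core number in each group, with differences."""

    gene_id: str
    degree_case: int
    degree_control: int
    kcore_case: int
    kcore_control: int

    @property
    def dif_degree(self) -> int:
        return self.degree_case - self.degree_control

    @property
    def dif_kcore(self) -> int:
        return self.kcore_case - self.kcore_control

    def __post_init__(self) -> None:
        for name in ("degree_case", "degree_control", "kcore_case", "kcore_control"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        if self.kcore_case > self.degree_case or self.kcore_control > self.degree_control:
            raise ValueError(f"core number exceeds degree for {self.gene_id!r}")


@dataclass
class CandidateSelection:
    """Result of the anchor-relative dominance screen."""

    anchor_gene: str
    anchor_dif_degree: int
    anchor_dif_kcore: int
    candidates: list[str]

    def __post_init__(self) -> None:
        if self.anchor_gene in self.candidates:
            raise ValueError("anchor cannot be its own candidate")


def _as_graph(network: GroupNetwork | nx.Graph, positive_only: bool = False) -> nx.Graph:
    if isinstance(network, nx.Graph):
        g = network
    else:
        g = network.to_graph()
    if positive_only:
        keep = [(u, v) for u, v, d in g.edges(data=True) if d.get("style", POSITIVE) == POSITIVE]
        h = nx.Graph()
        h.add_nodes_from(g.nodes)
        h.add_edges_from(keep)
        return h
    return g


def degrees(network: GroupNetwork | nx.Graph, positive_only: bool = False) -> dict[str, int]:
    """Edge count per node; nodes without edges get 0."""
    g = _as_graph(network, positive_only)
    return {node: int(d) for node, d in g.degree()}


def core_numbers(network: GroupNetwork | nx.Graph, positive_only: bool = False) -> dict[str, int]:
    """Core number per node: the largest k at which the node survives
    iterative pruning of all nodes with degree < k.  Isolated nodes get 0;
    edge signs are ignored unless ``positive_only``.
    """
    g = _as_graph(network, positive_only)
    return {node: int(k) for node, k in nx.core_number(g).items()}


def differential_topology(
    case_net: GroupNetwork | nx.Graph,
    control_net: GroupNetwork | nx.Graph,
    gene_universe: Sequence[str] | None = None,
    positive_only: bool = False,
) -> list[TopologyRecord]:
    """Per-gene (degree, core number) in each network plus exact differences.

    The universe defaults to the union of the two node sets; genes absent
    from one network get 0 there.  Output is ordered by the universe
    (sorted when defaulted).
    """
    deg_case = degrees(case_net, positive_only)
    deg_ctrl = degrees(control_net, positive_only)
    core_case = core_numbers(case_net, positive_only)
    core_ctrl = core_numbers(control_net, positive_only)
    if gene_universe is None:
        gene_universe = sorted(set(deg_case) | set(deg_ctrl))
    return [
        TopologyRecord(
            gene_id=g,
            degree_case=deg_case.get(g, 0),
            degree_control=deg_ctrl.get(g, 0),
            kcore_case=core_case.get(g, 0),
            kcore_control=core_ctrl.get(g, 0),
        )
        for g in gene_universe
    ]


def rank_top(records: Iterable[TopologyRecord], k: int = DEFAULT_TOP_K) -> list[TopologyRecord]:
    """Top-k records by |dif_degree| desc, then |dif_kcore| desc, then gene id.

    The sort is a deterministic, documented convention; alternative
    orderings of equal-|dif| records are possible upstream.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ordered = sorted(
        records, key=lambda r: (-abs(r.dif_degree), -abs(r.dif_kcore), r.gene_id)
    )
    return ordered[:k]


def select_candidates(records: Sequence[TopologyRecord], anchor: str) -> CandidateSelection:
    """Genes whose |dif_degree| and |dif_kcore| both reach the anchor's.

    Componentwise dominance in magnitude with ties allowed:
    candidate iff |dif_degree| >= |anchor dif_degree| AND
    |dif_kcore| >= |anchor dif_kcore| AND gene != anchor.
    """
    by_gene = {r.gene_id: r for r in records}
    if anchor not in by_gene:
        raise KeyError(f"anchor gene {anchor!r} not among the topology records")
    a = by_gene[anchor]
    ad, ak = abs(a.dif_degree), abs(a.dif_kcore)
    candidates = [
        r.gene_id
        for r in records
        if r.gene_id != anchor and abs(r.dif_degree) >= ad and abs(r.dif_kcore) >= ak
    ]
    return CandidateSelection(
        anchor_gene=anchor,
        anchor_dif_degree=a.dif_degree,
        anchor_dif_kcore=a.dif_kcore,
        candidates=candidates,
    )


def topology_frame(records: Sequence[TopologyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "degree_case": [r.degree_case for r in records],
            "degree_control": [r.degree_control for r in records],
            "kcore_case": [r.kcore_case for r in records],
            "kcore_control": [r.kcore_control for r in records],
            "dif_degree": [r.dif_degree for r in records],
            "dif_kcore": [r.dif_kcore for r in records],
        }
    )


def read_topology_table(path) -> list[TopologyRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return [
        TopologyRecord(
            gene_id=row.gene_id,
            degree_case=int(row.degree_case),
            degree_control=int(row.degree_control),
            kcore_case=int(row.kcore_case),
            kcore_control=int(row.kcore_control),
        )
        for row in df.itertuples()
    ]
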