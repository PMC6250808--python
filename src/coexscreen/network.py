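"""Per-group signed Pearson co-expression networks with FDR-thresholded edges.

For one group's samples, every gene pair gets a Pearson correlation and an
analytic two-sided p-value from the t-transform with n-2 degrees of
freedom.  BH-FDR is computed across the full pair universe of that group,
and edges are kept at fdr < threshold (strict).  Edge style is the sign of
the correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from coexscreen.diffexpr import bh_adjust
from coexscreen.io import ExpressionMatrix, SampleDesign

logger = logging.getLogger(__name__)

DEFAULT_EDGE_FDR = 0.01

POSITIVE = "Positive"
NEGATIVE = "Negative"


@dataclass(frozen=True)
class CorrelationEdge:
    """Significant correlation between an unordered gene pair.

    Stored with ``gene_a < gene_b`` lexicographically; ``style`` is
    ``Positive`` iff r > 0 and ``Negative`` iff r < 0 (r = 0 never passes
    significance).
    """

    gene_a: str
    gene_b: str
    r: float
    n: int
    p_value: float
    fdr: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-loop edge on {self.gene_a!r}")
        if self.gene_a > self.gene_b:
            a, b = self.gene_a, self.gene_b
            object.__setattr__(self, "gene_a", b)
            object.__setattr__(self, "gene_b", a)

    @property
    def style(self) -> str:
        return POSITIVE if self.r > 0 else NEGATIVE


@dataclass
class GroupNetwork:
    """Signed significant-correlation network for one sample group."""

    group: str
    nodes: list[str]
    edges: list[CorrelationEdge]
    n_samples: int
    fdr_max: float = DEFAULT_EDGE_FDR
    skipped_pairs: int = 0

    def __post_init__(self) -> None:
        pairs = set()
        node_set = set(self.nodes)
        for e in self.edges:
            key = (e.gene_a, e.gene_b)
            if key in pairs:
                raise ValueError(f"duplicate edge {key}")
            pairs.add(key)
            node_set.update(key)
        self.nodes = sorted(node_set)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_graph(self):
        """NetworkX view: simple undirected graph with edge attributes."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.gene_a, e.gene_b, r=e.r, p=e.p_value, fdr=e.fdr, style=e.style)
        return g


def pearson_r(x, y) -> float:
    """Product-moment correlation, clamped to [-1, 1] against rounding.

    Raises on length mismatch, n < 3 or zero variance in either vector
    (callers that sweep all pairs skip such pairs instead).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd @ xd) * (yd @ yd))
    if denom == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.clip((xd @ yd) / denom, -1.0, 1.0))


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson correlation via the t-transform.

    t = r * sqrt(n-2) / sqrt(1-r^2) referred to a t distribution with n-2
    degrees of freedom; |r| = 1 gives p = 0.
    """
    if n < 3:
        raise ValueError("correlation p-value needs n >= 3")
    if abs(r) > 1:
        raise ValueError(f"|r| = {abs(r)} > 1")
    if abs(r) == 1.0:
        return 0.0
    df = n - 2
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df))


def _pairwise_correlations(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs correlations for genes-in-rows ``values``.

    Returns (upper-triangle index pairs, r values); rows with zero variance
    are excluded from the pair universe.
    """
    n_genes = values.shape[0]
    sd = values.std(axis=1)
    ok = sd > 0
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(values)
    iu, ju = np.triu_indices(n_genes, k=1)
    keep = ok[iu] & ok[ju]
    return np.stack([iu[keep], ju[keep]], axis=1), np.clip(corr[iu[keep], ju[keep]], -1.0, 1.0)


def build_group_network(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    group: str,
    gene_ids: Sequence[str] | None = None,
    fdr_max: float = DEFAULT_EDGE_FDR,
) -> GroupNetwork:
    """Build the signed co-expression network of one group.

    Correlations use only that group's samples; the BH-FDR universe is all
    C(n_genes, 2) pairs of the supplied gene set (zero-variance pairs
    excluded and logged).  Nodes with no surviving edge stay in the node
    list with degree 0.
    """
    if not (0.0 <= fdr_max <= 1.0):
        raise ValueError(f"fdr_max must be in [0, 1], got {fdr_max}")
    if gene_ids is None:
        gene_ids = list(matrix.gene_ids)
    sub = matrix.subset_genes(gene_ids)
    samples = design.samples_in(group)
    if len(samples) < 3:
        raise ValueError(f"group {group!r} has {len(samples)} samples; need >= 3")
    sidx = matrix.sample_index()
    values = sub.values[:, [sidx[s] for s in samples]]
    n = len(samples)

    pairs, rs = _pairwise_correlations(values)
    n_possible = len(gene_ids) * (len(gene_ids) - 1) // 2
    skipped = n_possible - len(rs)
    if skipped:
        logger.warning("%s: %d zero-variance pairs excluded from the test universe", group, skipped)
    if len(rs) == 0:
        logger.warning("%s: no testable pairs; returning an empty network", group)
        return GroupNetwork(group, list(gene_ids), [], n, fdr_max, skipped_pairs=skipped)

    df = n - 2
    with np.errstate(divide="ignore"):
        t = rs * np.sqrt(df) / np.sqrt(1.0 - rs * rs)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.abs(rs) == 1.0] = 0.0
    # BH needs p in (0,1]; perfect correlations stay first in rank either way
    fdr = bh_adjust(np.clip(p, np.finfo(float).tiny, 1.0))
    fdr[p == 0.0] = 0.0

    edges = []
    for (i, j), r, pv, q in zip(pairs, rs, p, fdr):
        if q < fdr_max:
            a, b = sorted((gene_ids[i], gene_ids[j]))
            edges.append(CorrelationEdge(a, b, float(r), n, float(pv), float(q)))
    return GroupNetwork(group, list(gene_ids), edges, n, fdr_max, skipped_pairs=skipped)
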