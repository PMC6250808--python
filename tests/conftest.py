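import numpy as np
import pytest

from coexscreen.io import CASE, CONTROL, ExpressionMatrix, SampleDesign


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 6 samples with deterministic values."""
    rng = np.random.default_rng(0)
    return ExpressionMatrix(
        gene_ids=["g1", "g2", "g3"],
        sample_ids=[f"s{i}" for i in range(6)],
        values=rng.normal(5, 1, size=(3, 6)),
    )


@pytest.fixture
def tiny_design(tiny_matrix) -> SampleDesign:
    return SampleDesign(
        {s: (CONTROL if i < 3 else CASE) for i, s in enumerate(tiny_matrix.sample_ids)}
    )


def brute_force_bh(p_values):
    """O(m^2) step-up oracle: adjusted_i = min over p_j >= p_i of p_j * m / rank_j."""
    p = list(map(float, p_values))
    m = len(p)
    out = []
    for pi in p:
        candidates = []
        for pj in p:
            if pj >= pi:
                rank = sum(1 for x in p if x <= pj)
                candidates.append(pj * m / rank)
        out.append(min(1.0, min(candidates)))
    return out


def brute_force_core_numbers(graph):
    """Iterative-pruning oracle: core(v) = largest k at which v survives
    repeated removal of all nodes with degree < k."""
    import networkx as nx

    core = {v: 0 for v in graph.nodes}
    k = 1
    while True:
        g = graph.copy()
        while True:
            low = [v for v in g.nodes if g.degree(v) < k]
            if not low:
                break
            g.remove_nodes_from(low)
        if g.number_of_nodes() == 0:
            break
        for v in g.nodes:
            core[v] = k
        k += 1
    return core


def hypergeom_tail_oracle(a, b, c, d):
    """Exact over-representation tail by explicit enumeration of tables with
    the same margins: P(X >= a) for X = |DEG intersect set|."""
    from math import comb

    n_universe = a + b + c + d
    n_set = a + c
    n_deg = a + b
    denom = comb(n_universe, n_deg)
    total = 0
    for x in range(a, min(n_set, n_deg) + 1):
        total += comb(n_set, x) * comb(n_universe - n_set, n_deg - x)
    return total / denom
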