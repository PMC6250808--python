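import numpy as np
import pytest

from coexscreen.io import CASE, CONTROL, ExpressionMatrix, SampleDesign
from coexscreen.network import (
    build_group_network,
    correlation_pvalue,
    pearson_r,
)
from coexscreen.simulate import ModuleSpec, SyntheticSpec, generate_two_group_dataset


class TestPearsonR:
    def test_perfect_linear(self):
        x = np.arange(9.0)
        assert pearson_r(x, 2 * x + 1) == 1.0

    def test_perfect_anticorrelation(self):
        x = np.arange(9.0)
        assert pearson_r(x, -x) == -1.0

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 9))
        assert pearson_r(x, y) == pearson_r(y, x)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_r(np.ones(9), np.arange(9.0))

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            x, y = rng.normal(size=(2, 9))
            # direct covariance / sigma sigma oracle
            cov = np.mean((x - x.mean()) * (y - y.mean()))
            oracle = cov / (x.std() * y.std())
            assert pearson_r(x, y) == pytest.approx(oracle, abs=1e-12)


class TestCorrelationPvalue:
    # published anchor-partner rows: (r, group n, printed p)
    @pytest.mark.parametrize(
        "r,n,expected",
        [
            (0.9732955, 9, 9.98e-06),
            (0.9395096, 9, 0.0001689),
            (0.7989072, 9, 0.0098021),
            (0.901116, 18, 3.36e-07),
            (-0.675341, 18, 0.002101),
        ],
    )
    def test_reproduces_published_values(self, r, n, expected):
        assert correlation_pvalue(r, n) == pytest.approx(expected, rel=0.01)

    def test_zero_correlation(self):
        for n in (3, 9, 50):
            assert correlation_pvalue(0.0, n) == 1.0

    def test_perfect_correlation(self):
        assert correlation_pvalue(1.0, 9) == 0.0
        assert correlation_pvalue(-1.0, 9) == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            correlation_pvalue(0.5, 2)

    def test_out_of_range_r_rejected(self):
        with pytest.raises(ValueError):
            correlation_pvalue(1.2, 9)

    def test_two_sided_symmetry(self):
        assert correlation_pvalue(0.6, 12) == correlation_pvalue(-0.6, 12)

    def test_agrees_with_permutation_null(self):
        # analytic p vs a 1e5-draw permutation null at n=9
        rng = np.random.default_rng(2024)
        n, n_perm = 9, 100_000
        for target in (0.4, 0.6, 0.8):
            # draw until the sample r lands in the interesting band
            while True:
                x = rng.normal(size=n)
                y = target * x + np.sqrt(1 - target**2) * rng.normal(size=n)
                r_obs = pearson_r(x, y)
                if 0.3 < abs(r_obs) < 0.9:
                    break
            perms = np.array([rng.permutation(n) for _ in range(n_perm)])
            yp = y[perms]
            xc = x - x.mean()
            ypc = yp - yp.mean(axis=1, keepdims=True)
            rs = (ypc @ xc) / np.sqrt((xc @ xc) * np.sum(ypc**2, axis=1))
            p_perm = (1 + np.sum(np.abs(rs) >= abs(r_obs))) / (1 + n_perm)
            p_analytic = correlation_pvalue(r_obs, n)
            mc_err = 4 * np.sqrt(p_perm * (1 - p_perm) / n_perm)
            # the permutation null conditions on the observed sample values,
            # so at n=9 it sits O(1/n) away from the unconditional t null
            assert abs(p_analytic - p_perm) < mc_err + 0.15 * p_analytic


def _two_group(values, n_control=9, n_case=18):
    values = np.asarray(values, dtype=float)
    samples = [f"c{i}" for i in range(n_control)] + [f"p{i}" for i in range(n_case)]
    matrix = ExpressionMatrix([f"g{i}" for i in range(values.shape[0])], samples, values)
    design = SampleDesign(
        {s: (CONTROL if i < n_control else CASE) for i, s in enumerate(samples)}
    )
    return matrix, design


class TestBuildGroupNetwork:
    def test_deterministic_pair_single_edge(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=27)
        noise = rng.normal(size=27)
        matrix, design = _two_group(np.vstack([x, 2 * x, noise]))
        net = build_group_network(matrix, design, CONTROL)
        assert net.n_edges == 1
        edge = net.edges[0]
        assert {edge.gene_a, edge.gene_b} == {"g0", "g1"}
        assert edge.style == "Positive"
        assert edge.r == 1.0 and edge.fdr == 0.0

    def test_fdr_zero_keeps_nothing(self):
        rng = np.random.default_rng(1)
        matrix, design = _two_group(rng.normal(size=(5, 27)))
        net = build_group_network(matrix, design, CONTROL, fdr_max=0.0)
        assert net.n_edges == 0
        assert sorted(net.nodes) == [f"g{i}" for i in range(5)]

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(2)
        matrix, design = _two_group(rng.normal(size=(3, 27)))
        small = SampleDesign({"c0": CONTROL, "c1": CONTROL, "p0": CASE})
        values = matrix.values[:, :3]
        m2 = ExpressionMatrix(matrix.gene_ids, ["c0", "c1", "p0"], values)
        with pytest.raises(ValueError, match=">= 3"):
            build_group_network(m2, small, CONTROL)

    def test_zero_variance_pairs_skipped(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(3, 27))
        values[0, :] = 7.0  # flat gene
        matrix, design = _two_group(values)
        net = build_group_network(matrix, design, CONTROL)
        assert net.skipped_pairs == 2
        assert all("g0" not in (e.gene_a, e.gene_b) for e in net.edges)

    def test_style_matches_sign(self):
        spec = SyntheticSpec(
            n_genes=30,
            n_control=9,
            n_case=18,
            modules=[ModuleSpec(tuple(range(10)), 0.95, "both")],
            noise_sd=0.2,
            seed=4,
        )
        matrix, design, _ = generate_two_group_dataset(spec)
        net = build_group_network(matrix, design, CONTROL)
        assert net.n_edges > 0
        for e in net.edges:
            assert e.style == ("Positive" if e.r > 0 else "Negative")
            assert e.fdr < 0.01

    def test_gene_order_permutation_invariant(self):
        rng = np.random.default_rng(5)
        spec = SyntheticSpec(
            n_genes=15,
            modules=[ModuleSpec(tuple(range(6)), 0.9, "both")],
            noise_sd=0.3,
            seed=6,
        )
        matrix, design, _ = generate_two_group_dataset(spec)
        genes = list(matrix.gene_ids)
        shuffled = list(rng.permutation(genes))
        net_a = build_group_network(matrix, design, CONTROL, genes)
        net_b = build_group_network(matrix, design, CONTROL, shuffled)
        key = lambda n: sorted((e.gene_a, e.gene_b, round(e.r, 12)) for e in n.edges)
        assert key(net_a) == key(net_b)

    def test_removing_gene_preserves_r_of_remaining_pairs(self):
        spec = SyntheticSpec(
            n_genes=12,
            modules=[ModuleSpec(tuple(range(8)), 0.9, "both")],
            noise_sd=0.3,
            seed=7,
        )
        matrix, design, _ = generate_two_group_dataset(spec)
        full = build_group_network(matrix, design, CONTROL)
        reduced = build_group_network(matrix, design, CONTROL, matrix.gene_ids[1:])
        r_full = {(e.gene_a, e.gene_b): e.r for e in full.edges}
        r_reduced = {(e.gene_a, e.gene_b): e.r for e in reduced.edges}
        for pair in set(r_full) & set(r_reduced):
            assert r_full[pair] == pytest.approx(r_reduced[pair], abs=1e-12)

    def test_planted_module_density(self):
        # control-active module among 200 background genes: build the network
        # at the gene-selection scale the pipeline uses (module + 40 selected
        # background genes) and require in-module edge density >= 5x background
        spec = SyntheticSpec(
            n_genes=210,
            n_control=9,
            n_case=18,
            modules=[ModuleSpec(tuple(range(10)), 0.9, "control")],
            noise_sd=0.3,
            seed=8,
        )
        matrix, design, truth = generate_two_group_dataset(spec)
        selected = matrix.gene_ids[:50]  # 10 module + 40 background
        net = build_group_network(matrix, design, CONTROL, selected)
        module = set(truth.module_members[0])
        in_module = sum(1 for e in net.edges if e.gene_a in module and e.gene_b in module)
        out_module = net.n_edges - in_module
        density_in = in_module / (10 * 9 / 2)
        density_out = out_module / (50 * 49 / 2 - 45)
        assert in_module > 0
        assert density_in >= 5 * max(density_out, 1e-9)
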