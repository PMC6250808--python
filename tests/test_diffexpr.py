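import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_bh
from coexscreen.diffexpr import (
    DEGRecord,
    DEGTable,
    bh_adjust,
    compute_log2fc,
    filter_degs,
    make_deg_table,
    two_group_test,
)
from coexscreen.io import CASE, CONTROL, ExpressionMatrix, SampleDesign
from coexscreen.simulate import SyntheticSpec, generate_two_group_dataset


def _matrix_from(values, n_control, n_case):
    values = np.asarray(values, dtype=float)
    samples = [f"c{i}" for i in range(n_control)] + [f"p{i}" for i in range(n_case)]
    matrix = ExpressionMatrix(
        [f"g{i}" for i in range(values.shape[0])], samples, values
    )
    design = SampleDesign(
        {s: (CONTROL if i < n_control else CASE) for i, s in enumerate(samples)}
    )
    return matrix, design


class TestLog2FC:
    def test_ratio_mode_simple(self):
        matrix, design = _matrix_from([[2, 2, 2, 8, 8, 8]], 3, 3)
        lfc = compute_log2fc(matrix, design, mode="ratio_of_means")
        assert lfc[0] == pytest.approx(2.0)

    def test_identical_means_zero(self):
        matrix, design = _matrix_from([[5, 5, 5, 5, 5, 5]], 3, 3)
        for mode in ("ratio_of_means", "diff_of_logmeans"):
            assert compute_log2fc(matrix, design, mode=mode)[0] == 0.0

    def test_diff_of_logmeans(self):
        matrix, design = _matrix_from([[1, 1, 1, 4, 4, 4]], 3, 3)
        assert compute_log2fc(matrix, design)[0] == pytest.approx(3.0)

    def test_ratio_mode_rejects_nonpositive(self):
        matrix, design = _matrix_from([[-1, -1, -1, 2, 2, 2]], 3, 3)
        with pytest.raises(ValueError, match="non-positive"):
            compute_log2fc(matrix, design, mode="ratio_of_means")
        # a pseudocount rescues it
        lfc = compute_log2fc(matrix, design, mode="ratio_of_means", pseudocount=2.0)
        assert np.isfinite(lfc[0])

    def test_orientation_positive_means_higher_in_case(self):
        matrix, design = _matrix_from([[1, 1, 1, 9, 9, 9]], 3, 3)
        assert compute_log2fc(matrix, design)[0] > 0


class TestWelch:
    def test_identical_values_p_one(self):
        matrix, design = _matrix_from([[3, 3, 3, 3, 3, 3]], 3, 3)
        assert two_group_test(matrix, design)[0] == 1.0

    def test_single_sample_group_hard_error(self):
        values = np.arange(8, dtype=float).reshape(2, 4)
        samples = ["c0", "p0", "p1", "p2"]
        matrix = ExpressionMatrix(["g0", "g1"], samples, values)
        design = SampleDesign({"c0": CONTROL, "p0": CASE, "p1": CASE, "p2": CASE})
        with pytest.raises(ValueError, match="precomputed DEG table"):
            two_group_test(matrix, design)

    def test_type_i_error_near_nominal(self):
        # two groups from the same distribution: ~5% of p < 0.05
        rng = np.random.default_rng(42)
        values = rng.normal(0, 1, size=(1000, 40))
        matrix, design = _matrix_from(values, 20, 20)
        p = two_group_test(matrix, design)
        frac = np.mean(p < 0.05)
        assert abs(frac - 0.05) < 0.02

    def test_power_on_planted_shift(self):
        # 3-sd shift at n=9/18 detected for >=90% of genes
        rng = np.random.default_rng(1)
        n_genes = 200
        values = rng.normal(0, 1, size=(n_genes, 27))
        values[:, 9:] += 3.0
        matrix, design = _matrix_from(values, 9, 18)
        p = two_group_test(matrix, design)
        assert np.mean(p < 0.05) >= 0.9

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(3)
        matrix, design = _matrix_from(rng.normal(size=(50, 12)), 6, 6)
        p = two_group_test(matrix, design)
        assert np.all((p > 0) & (p <= 1))


class TestBH:
    def test_single_p(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_four(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_rejects_out_of_range(self):
        for bad in ([0.0], [1.5], [-0.1], [np.nan]):
            with pytest.raises(ValueError):
                bh_adjust(bad)

    def test_empty(self):
        assert bh_adjust([]).size == 0

    @given(
        st.lists(st.floats(min_value=1e-12, max_value=1.0, exclude_min=False), min_size=1, max_size=50)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, ps):
        np.testing.assert_allclose(bh_adjust(ps), brute_force_bh(ps), rtol=1e-12)

    def test_oracle_agreement_on_1000_random_lists(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m = rng.integers(1, 51)
            ps = rng.uniform(1e-8, 1.0, size=m)
            np.testing.assert_allclose(bh_adjust(ps), brute_force_bh(ps), rtol=1e-12)

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=2, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_permutation_equivariance(self, ps):
        perm = np.random.default_rng(0).permutation(len(ps))
        direct = np.asarray(bh_adjust(ps))[perm]
        permuted = bh_adjust(np.asarray(ps)[perm])
        np.testing.assert_allclose(direct, permuted, rtol=1e-12)

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(5)
        ps = rng.uniform(1e-6, 1, size=100)
        adj = bh_adjust(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestFilterDEGs:
    def _table(self, rows):
        return DEGTable([DEGRecord(f"g{i}", lfc, 0.001, fdr) for i, (lfc, fdr) in enumerate(rows)])

    def test_boundary_fdr_excluded(self):
        up, down = filter_degs(self._table([(3.0, 0.05)]))
        assert up == [] and down == []

    def test_boundary_log2fc_excluded(self):
        up, down = filter_degs(self._table([(1.0, 0.01)]))
        assert up == [] and down == []

    def test_direction_partition(self):
        up, down = filter_degs(self._table([(2.0, 0.01), (-2.0, 0.01)]))
        assert up == ["g0"] and down == ["g1"]

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(8)
        rows = [(float(rng.normal(0, 2)), float(rng.uniform(1e-4, 1))) for _ in range(200)]
        table = self._table(rows)
        base_up, base_down = filter_degs(table, fdr_max=0.05, min_abs_log2fc=1.0)
        loose_up, loose_down = filter_degs(table, fdr_max=0.10, min_abs_log2fc=0.5)
        assert set(base_up) <= set(loose_up)
        assert set(base_down) <= set(loose_down)

    def test_simulation_sensitivity_and_fdr(self):
        # 50 planted at log2fc=2 among 1000 genes, n=20/20
        spec = SyntheticSpec(
            n_genes=1000, n_control=20, n_case=20,
            deg_fraction=0.05, deg_log2fc=2.0, noise_sd=0.5, seed=31,
        )
        matrix, design, truth = generate_two_group_dataset(spec)
        table = make_deg_table(matrix, design)
        called = set(table.called_ids())
        planted = set(truth.planted_deg_ids)
        sensitivity = len(called & planted) / len(planted)
        fdr = len(called - planted) / max(1, len(called))
        assert sensitivity >= 0.9
        assert fdr <= 0.1

    def test_global_null_call_rate(self):
        # averaged over seeds, expected calls <= 0.05 * n_genes under the null
        n_genes = 200
        counts = []
        for seed in range(30):
            spec = SyntheticSpec(
                n_genes=n_genes, n_control=9, n_case=18, deg_fraction=0.0, noise_sd=0.5, seed=seed
            )
            matrix, design, _ = generate_two_group_dataset(spec)
            counts.append(len(make_deg_table(matrix, design).called_ids()))
        assert np.mean(counts) <= 0.05 * n_genes
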