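import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ailqtl.noia import (
    LocusFrequencies,
    conditional_scan,
    fit_noia,
    pairwise_interaction_network,
    reference_point,
    single_locus_design,
    two_locus_design,
)
from conftest import make_genotypes, make_samples


def _orthogonality_sums(freq, design):
    p = freq.as_array()
    xa = design.rows[:, 1]
    xd = design.rows[:, 2]
    return p @ xa, p @ xd, p @ (xa * xd)


class TestSingleLocusDesign:
    def test_hardy_weinberg_half(self):
        d = single_locus_design(LocusFrequencies(0.25, 0.5, 0.25))
        assert d.rows[:, 1] == pytest.approx([-1.0, 0.0, 1.0])
        assert d.rows[:, 2] == pytest.approx([-0.5, 0.5, -0.5])

    def test_unbalanced_frequencies(self):
        d = single_locus_design(LocusFrequencies(0.5, 0.25, 0.25))
        assert d.rows[:, 1] == pytest.approx([-0.75, 0.25, 1.25])
        assert d.rows[:, 2] == pytest.approx([-2 / 11, 8 / 11, -4 / 11], abs=1e-4)
        sums = _orthogonality_sums(LocusFrequencies(0.5, 0.25, 0.25), d)
        assert np.allclose(sums, 0.0, atol=1e-12)

    @given(
        a=st.floats(0.02, 0.96),
        frac=st.floats(0.02, 0.98),
    )
    @settings(deadline=None, max_examples=200)
    def test_orthogonality_identities(self, a, frac):
        p12 = (1 - a) * frac
        freq = LocusFrequencies(a, p12, 1 - a - p12)
        d = single_locus_design(freq)
        if d.flag:
            return
        assert np.allclose(_orthogonality_sums(freq, d), 0.0, atol=1e-12)

    def test_absent_class_gives_additive_only(self):
        d = single_locus_design(LocusFrequencies(0.6, 0.4, 0.0))
        assert d.flag == "additive_only"
        assert d.columns == ["mean", "a"]

    def test_additive_effect_equals_allele_substitution_at_hw(self):
        # at HW frequencies the NOIA additive effect equals the textbook
        # average allele-substitution effect alpha = a + d(p11 - p22 ... )
        rng = np.random.default_rng(0)
        q = 0.3  # ALT frequency
        n = 200_000
        g = rng.binomial(2, q, n).astype(np.int8)
        a_geno, d_geno = 7.0, 3.0  # genotype values -a, d, a
        y = np.select([g == 0, g == 1, g == 2], [-a_geno, d_geno, a_geno]).astype(float)
        alpha = a_geno + d_geno * (1 - 2 * q)  # textbook oracle
        gm = make_genotypes(g[:, None])
        fit = fit_noia(y, gm, ["m0"])
        assert fit.effects["a_m0"] == pytest.approx(alpha, rel=0.02)


class TestReferencePoint:
    def test_constant_values(self):
        assert reference_point(LocusFrequencies(0.2, 0.5, 0.3), [7, 7, 7]) == 7.0

    def test_weighted_mean(self):
        assert reference_point(LocusFrequencies(0.25, 0.5, 0.25), [0, 5, 10]) == 5.0

    def test_relabeling_symmetry(self):
        f = LocusFrequencies(0.1, 0.3, 0.6)
        g = LocusFrequencies(0.6, 0.3, 0.1)
        assert reference_point(f, [1, 2, 3]) == pytest.approx(reference_point(g, [3, 2, 1]))


class TestTwoLocusDesign:
    def test_nine_columns_and_kronecker_entry(self):
        f = LocusFrequencies(0.25, 0.5, 0.25)
        d = two_locus_design(f, f)
        assert d.rows.shape == (9, 9)
        assert d.columns == ["mean", "a_A", "d_A", "a_B", "d_B", "aa", "ad", "da", "dd"]
        # joint genotype (2,2) is the last row; aa = x_a(2) * x_a(2) = 1
        assert d.rows[8, d.columns.index("aa")] == pytest.approx(1.0)

    def test_joint_orthogonality_at_product_frequencies(self):
        fa = LocusFrequencies(0.3, 0.5, 0.2)
        fb = LocusFrequencies(0.15, 0.45, 0.4)
        d = two_locus_design(fa, fb)
        w = np.outer(fa.as_array(), fb.as_array()).ravel()
        gram = d.rows.T @ (w[:, None] * d.rows)
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-12


class TestFitNoia:
    def test_noise_free_additive_recovery(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, 600).astype(np.int8)
        gm = make_genotypes(g[:, None])
        d = single_locus_design(LocusFrequencies.from_genotypes(g))
        y = 10.0 * d.rows[g, 1]
        fit = fit_noia(y, gm, ["m0"])
        assert fit.effects["a_m0"] == pytest.approx(10.0, abs=1e-8)
        assert fit.effects["d_m0"] == pytest.approx(0.0, abs=1e-8)
        assert fit.effects["R"] == pytest.approx(0.0, abs=1e-8)

    def test_saturated_two_locus_reproduces_cell_means(self):
        rng = np.random.default_rng(2)
        n = 2000
        ga = rng.integers(0, 3, n).astype(np.int8)
        gb = rng.integers(0, 3, n).astype(np.int8)
        gm = make_genotypes(np.column_stack([ga, gb]))
        y = rng.normal(size=n) + 2.0 * ga * gb
        fit = fit_noia(y, gm, ["m0", "m1"])
        assert fit.fitted_values is not None
        for i in range(3):
            for j in range(3):
                cell = y[(ga == i) & (gb == j)]
                assert fit.fitted_values[i * 3 + j] == pytest.approx(cell.mean(), abs=1e-8)

    def test_reference_point_equals_sample_mean(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, 500).astype(np.int8)
        y = rng.normal(size=500) + g
        fit = fit_noia(y, make_genotypes(g[:, None]), ["m0"])
        assert fit.reference_point == pytest.approx(y.mean(), abs=1e-8)

    def test_model_reduction_leaves_additive_unchanged(self):
        # in-sample orthogonality: dropping dominance does not move a-hat
        rng = np.random.default_rng(4)
        g = rng.integers(0, 3, 800).astype(np.int8)
        y = rng.normal(size=800) + 0.7 * g + 0.4 * (g == 1)
        gm = make_genotypes(g[:, None])
        full = fit_noia(y, gm, ["m0"])

        d = single_locus_design(LocusFrequencies.from_genotypes(g))
        xa = d.rows[g, 1]
        beta = (xa @ y) / (xa @ xa)  # additive-only fit (columns orthogonal)
        assert full.effects["a_m0"] == pytest.approx(beta, abs=1e-8)

    def test_empty_joint_cells_flagged_inestimable(self):
        ga = np.array([0, 0, 1, 1, 2, 2] * 20, dtype=np.int8)
        gb = ga.copy()  # perfect correlation: many empty joint cells
        gm = make_genotypes(np.column_stack([ga, gb]))
        y = np.random.default_rng(5).normal(size=len(ga))
        fit = fit_noia(y, gm, ["m0", "m1"])
        assert fit.inestimable

    def test_parameter_recovery_coverage(self):
        rng = np.random.default_rng(6)
        hits = {"a": 0, "d": 0, "aa": 0}
        reps = 120
        for _ in range(reps):
            n = 1500
            ga = rng.binomial(2, 0.4, n).astype(np.int8)
            gb = rng.binomial(2, 0.6, n).astype(np.int8)
            da = single_locus_design(LocusFrequencies.from_genotypes(ga))
            db = single_locus_design(LocusFrequencies.from_genotypes(gb))
            y = (
                5.0 * da.rows[ga, 1]
                + 2.0 * da.rows[ga, 2]
                + 4.0 * da.rows[ga, 1] * db.rows[gb, 1]
                + rng.normal(size=n)
            )
            gm = make_genotypes(np.column_stack([ga, gb]))
            fit = fit_noia(y, gm, ["m0", "m1"])
            hits["a"] += abs(fit.effects["a_m0"] - 5.0) <= 2 * fit.se["a_m0"]
            hits["d"] += abs(fit.effects["d_m0"] - 2.0) <= 2 * fit.se["d_m0"]
            hits["aa"] += abs(fit.effects["aa_m0:m1"] - 4.0) <= 2 * fit.se["aa_m0:m1"]
        for k, h in hits.items():
            assert h / reps >= 0.90, k


class TestInteractionNetwork:
    def test_hub_architecture_detected(self):
        rng = np.random.default_rng(7)
        n = 2500
        hub = rng.binomial(2, 0.5, n).astype(np.int8)
        s1 = rng.binomial(2, 0.5, n).astype(np.int8)
        s2 = rng.binomial(2, 0.5, n).astype(np.int8)
        null = rng.binomial(2, 0.5, n).astype(np.int8)
        y = (
            0.4 * (hub - 1) * (s1 - 1)
            + 0.4 * (hub - 1) * (s2 - 1)
            + rng.normal(size=n)
        )
        gm = make_genotypes(np.column_stack([hub, s1, s2, null]))
        edges = pairwise_interaction_network(y, gm, gm.marker_ids)
        top = edges.nsmallest(2, "p")
        assert set(top["marker_i"]) == {"m0"}  # the hub is in both top edges
        assert set(top["marker_j"]) == {"m1", "m2"}

    def test_null_markers_edge_rate(self):
        rng = np.random.default_rng(8)
        n = 1200
        calls = rng.binomial(2, 0.5, size=(n, 6)).astype(np.int8)
        y = rng.normal(size=n)
        edges = pairwise_interaction_network(y, make_genotypes(calls), [f"m{i}" for i in range(6)])
        rate = (edges["p"] < 0.05).mean()
        assert rate < 0.15  # ~5% expected, 60 correlated tests

    def test_labeling_convention(self):
        # aa and dd symmetric in marker order; ad/da transpose
        rng = np.random.default_rng(9)
        n = 1000
        ga = rng.binomial(2, 0.5, n).astype(np.int8)
        gb = rng.binomial(2, 0.4, n).astype(np.int8)
        y = rng.normal(size=n) + 0.3 * ga * (gb == 1)
        g1 = make_genotypes(np.column_stack([ga, gb]))
        f12 = fit_noia(y, g1, ["m0", "m1"])
        f21 = fit_noia(y, g1, ["m1", "m0"])
        assert f12.effects["aa_m0:m1"] == pytest.approx(f21.effects["aa_m1:m0"], abs=1e-8)
        assert f12.effects["dd_m0:m1"] == pytest.approx(f21.effects["dd_m1:m0"], abs=1e-8)
        assert f12.effects["ad_m0:m1"] == pytest.approx(f21.effects["da_m1:m0"], abs=1e-8)


class TestConditionalScan:
    def _masking_data(self, seed=10, n=3000, effect=-0.5):
        rng = np.random.default_rng(seed)
        hub = rng.binomial(2, 0.5, n).astype(np.int8)
        focal = rng.binomial(2, 0.5, n).astype(np.int8)
        y = np.where(hub < 2, effect * focal, 0.0) + rng.normal(size=n)
        gm = make_genotypes(np.column_stack([hub, focal]))
        return gm, y, make_samples(n)

    def test_masking_epistasis_stratum_pattern(self):
        gm, y, samples = self._masking_data()
        res = conditional_scan(y, samples, gm, "m0", scan_markers=["m1"])
        assert res.strata[0][0].neglog10p > 6
        assert res.strata[1][0].neglog10p > 6
        assert res.strata[2][0].neglog10p < 2

    def test_no_epistasis_gives_homogeneous_effects(self):
        rng = np.random.default_rng(11)
        n = 4000
        hub = rng.binomial(2, 0.5, n).astype(np.int8)
        focal = rng.binomial(2, 0.5, n).astype(np.int8)
        y = 0.4 * focal + rng.normal(size=n)
        gm = make_genotypes(np.column_stack([hub, focal]))
        res = conditional_scan(y, make_samples(n), gm, "m0", scan_markers=["m1"])
        effects = [res.strata[g][0] for g in sorted(res.strata)]
        for a in effects:
            for b in effects:
                z = abs(a.effect - b.effect) / np.hypot(a.se, b.se)
                assert z < 4

    def test_grid_counts_sum_to_stratum_totals(self):
        gm, y, samples = self._masking_data(seed=12, n=800)
        res = conditional_scan(y, samples, gm, "m0", scan_markers=["m1"], focal_marker="m1")
        assert res.grid_count.sum() == sum(res.stratum_n.values())
        for j, g in enumerate((0, 1, 2)):
            assert res.grid_count[:, j].sum() == res.stratum_n[g]

    def test_small_stratum_omitted(self):
        rng = np.random.default_rng(13)
        n = 200
        hub = rng.binomial(2, 0.05, n).astype(np.int8)  # class 2 nearly absent
        gm = make_genotypes(np.column_stack([hub, rng.binomial(2, 0.5, n)]).astype(np.int8))
        y = rng.normal(size=n)
        res = conditional_scan(y, make_samples(n), gm, "m0", scan_markers=["m1"])
        assert 2 in res.omitted_strata
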