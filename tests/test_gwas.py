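import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ailqtl.datasets import GENOTYPE_GROUPS
from ailqtl.gwas import (
    anova_table,
    fit_marker_lm,
    genotype_group_summary,
    gwas_scan,
    lsd_letters,
    normalize_by_group,
    sequential_anova,
    stepwise_select,
)
from conftest import make_genotypes, make_samples


class TestNormalizeByGroup:
    def test_single_cell_zscores(self):
        samples = make_samples(3, bw8=[2.0, 4.0, 6.0])
        assert normalize_by_group(samples) == pytest.approx([-1.0, 0.0, 1.0])

    def test_cells_centered_independently(self):
        samples = make_samples(
            6,
            sexes=["F"] * 3 + ["M"] * 3,
            bw8=[1.0, 2.0, 3.0, 100.0, 200.0, 300.0],
        )
        y = normalize_by_group(samples)
        assert y[:3].mean() == pytest.approx(0.0)
        assert y[3:].mean() == pytest.approx(0.0)
        assert y.mean() == pytest.approx(0.0)

    def test_published_group_means_are_near_zero_weighted(self):
        # the published per-genotype normalized means are consistent with
        # a cohort normalized to mean zero
        rows = GENOTYPE_GROUPS["gga1_171v"]
        total = sum(n for _, _, _, n, _ in rows)
        weighted = sum(m * n for _, m, _, n, _ in rows) / total
        assert abs(weighted) < 0.01

    def test_zero_sd_cell_is_named_error(self):
        samples = make_samples(2, bw8=[5.0, 5.0])
        with pytest.raises(ValueError, match="generation=2"):
            normalize_by_group(samples)

    def test_missing_bw8_stays_nan(self):
        samples = make_samples(3, bw8=[1.0, None, 3.0])
        y = normalize_by_group(samples)
        assert np.isnan(y[1]) and np.isfinite(y[[0, 2]]).all()


class TestFitMarkerLm:
    def test_hand_computed_ols(self):
        # A = (0,0,1,1,2,2), y = (10,12,15,13,20,18): slope 4, intercept 10.667
        gm = make_genotypes(np.array([[0], [0], [1], [1], [2], [2]], dtype=np.int8))
        samples = make_samples(6)
        r = fit_marker_lm([10, 12, 15, 13, 20, 18], samples, gm, "m0")
        assert r.effect == pytest.approx(4.0)
        assert r.intercept == pytest.approx(32 / 3)
        assert r.n_used == 6

    def test_perfect_fit_flagged_degenerate(self):
        gm = make_genotypes(np.array([[0], [1], [2], [1]], dtype=np.int8))
        y = 2.0 * gm.calls[:, 0]
        r = fit_marker_lm(y, make_samples(4), gm, "m0")
        assert r.flag == "degenerate"
        assert r.effect == pytest.approx(2.0)
        assert r.residual_variance == 0.0
        assert r.pvalue == 0.0

    def test_conditioning_on_perfect_ld_is_rank_deficient(self):
        calls = np.array([[0, 0], [1, 1], [2, 2], [1, 1], [0, 0]], dtype=np.int8)
        gm = make_genotypes(calls)
        r = fit_marker_lm([1.0, 2.0, 3.0, 2.5, 0.5], make_samples(5), gm, "m0", conditioning=["m1"])
        assert r.flag == "rank_deficient"
        assert np.isnan(r.effect)

    def test_monomorphic_skipped(self):
        gm = make_genotypes(np.ones((4, 1), dtype=np.int8))
        r = fit_marker_lm([1, 2, 3, 4], make_samples(4), gm, "m0")
        assert r.flag == "monomorphic"

    def test_missing_cases_dropped_per_marker(self):
        from ailqtl.io import MISSING

        calls = np.array([[0], [1], [2], [MISSING]], dtype=np.int8)
        gm = make_genotypes(calls)
        r = fit_marker_lm([1.0, 2.0, 3.0, 99.0], make_samples(4), gm, "m0")
        assert r.n_used == 3

    def test_agrees_with_normal_equations_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            n = rng.integers(20, 60)
            calls = rng.integers(0, 3, size=(n, 1)).astype(np.int8)
            sexes = np.where(rng.random(n) < 0.5, "M", "F")
            gens = rng.integers(2, 5, n)
            y = rng.normal(size=n)
            samples = make_samples(n, sexes=list(sexes), generations=gens)
            r = fit_marker_lm(y, samples, make_genotypes(calls), "m0")
            if r.flag:
                continue
            # independent oracle: explicit normal equations
            cols = [np.ones(n)]
            if len(set(sexes)) > 1:
                cols.append((sexes == "M").astype(float))
            for g in sorted(set(gens))[1:]:
                cols.append((gens == g).astype(float))
            cols.append(calls[:, 0].astype(float))
            X = np.column_stack(cols)
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta
            sigma2 = resid @ resid / (n - X.shape[1])
            se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[-1, -1])
            assert r.effect == pytest.approx(beta[-1], abs=1e-8)
            assert r.se == pytest.approx(se, abs=1e-8)

    def test_marker_t_squared_equals_sequential_f_fitted_last(self, phenotyped):
        ph, y, g = phenotyped
        marker = g.marker_ids[7]
        r = fit_marker_lm(y, ph, g, marker)
        rows = sequential_anova(y, ph, g, [marker])
        f_row = [row for row in rows if row.term == marker][0]
        assert r.stat**2 == pytest.approx(f_row.f_value, rel=1e-8)
        assert r.pvalue == pytest.approx(f_row.pvalue, rel=1e-6)


class TestScan:
    def test_fast_path_matches_per_marker_fit(self, phenotyped):
        ph, y, g = phenotyped
        scan = gwas_scan(y, ph, g)
        for j in (0, 13, 42):
            slow = fit_marker_lm(y, ph, g, g.marker_ids[j])
            assert scan[j].effect == pytest.approx(slow.effect, abs=1e-10)
            assert scan[j].se == pytest.approx(slow.se, abs=1e-10)
            assert scan[j].pvalue == pytest.approx(slow.pvalue, rel=1e-8)

    def test_noise_free_additive_qtl_is_top_hit(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 3, size=(200, 20)).astype(np.int8)
        gm = make_genotypes(calls)
        y = 5.0 * calls[:, 12] + 0.01 * rng.normal(size=200)
        scan = gwas_scan(y, make_samples(200), gm)
        top = max(scan, key=lambda r: r.neglog10p)
        assert top.marker_id == "m12"

    def test_conditioning_on_causal_kills_linked_signal(self):
        rng = np.random.default_rng(3)
        causal = rng.integers(0, 3, size=300).astype(np.int8)
        calls = np.column_stack([causal, causal, rng.integers(0, 3, 300)]).astype(np.int8)
        gm = make_genotypes(calls)
        y = 3.0 * causal + rng.normal(size=300)
        samples = make_samples(300)
        naive = gwas_scan(y, samples, gm)
        cond = gwas_scan(y, samples, gm, markers=["m1", "m2"], conditioning=["m0"])
        assert naive[1].neglog10p > 10
        # m1 is a perfect copy of the conditioning marker -> rank deficient
        assert cond[0].flag == "rank_deficient"
        assert cond[1].pvalue > 0.001 or cond[1].flag is not None


class TestStepwise:
    def _qtl_panel(self, seed=4, effect=5.0):
        rng = np.random.default_rng(seed)
        calls = rng.integers(0, 3, size=(400, 6)).astype(np.int8)
        y = effect * calls[:, 2] + rng.normal(size=400)
        return make_genotypes(calls), y, make_samples(400)

    def test_single_true_qtl_selected(self):
        gm, y, samples = self._qtl_panel()
        fit = stepwise_select(y, samples, gm, gm.marker_ids)
        assert fit.selected == ["m2"]

    def test_perfect_ld_pair_keeps_exactly_one(self):
        rng = np.random.default_rng(5)
        causal = rng.integers(0, 3, size=400).astype(np.int8)
        calls = np.column_stack([causal, causal]).astype(np.int8)
        gm = make_genotypes(calls)
        y = 4.0 * causal + rng.normal(size=400)
        fit = stepwise_select(y, make_samples(400), gm, gm.marker_ids)
        assert len(fit.selected) == 1
        # tie rule: equal p -> lower panel position wins
        assert fit.selected == ["m0"]

    def test_all_null_candidates_select_nothing(self):
        gm, _, samples = self._qtl_panel(seed=6, effect=0.0)
        rng = np.random.default_rng(7)
        y = rng.normal(size=400)
        fit = stepwise_select(y, samples, gm, gm.marker_ids)
        assert fit.selected == []

    def test_aic_mode_finds_true_qtl(self):
        gm, y, samples = self._qtl_panel(seed=8)
        fit = stepwise_select(y, samples, gm, gm.marker_ids, criterion="aic")
        assert "m2" in fit.selected


class TestSequentialAnova:
    def test_orthogonal_term_f_invariant_to_order(self):
        rng = np.random.default_rng(9)
        n = 300
        # balanced, mutually orthogonal marker codings
        m0 = np.tile([0, 2], n // 2)
        m1 = np.repeat([0, 2], n // 2)
        gm = make_genotypes(np.column_stack([m0, m1]).astype(np.int8))
        y = rng.normal(size=n) + 0.5 * m0 + 0.3 * m1
        samples = make_samples(n)
        first = sequential_anova(y, samples, gm, ["m0", "m1"], covariates=())
        last = sequential_anova(y, samples, gm, ["m1", "m0"], covariates=())
        f_first = [r.f_value for r in first if r.term == "m0"][0]
        f_last = [r.f_value for r in last if r.term == "m0"][0]
        assert f_first == pytest.approx(f_last, rel=1e-8)

    def test_residual_row_and_f_definition(self, phenotyped):
        ph, y, g = phenotyped
        fit = stepwise_select(y, ph, g, g.marker_ids[:5], alpha_in=1.1, alpha_out=1.1)
        rows = anova_table(fit)
        resid = rows[-1]
        assert resid.term == "Residuals"
        for r in rows[:-1]:
            if r.df > 0 and np.isfinite(r.f_value):
                assert r.f_value == pytest.approx(r.mean_square / resid.mean_square, rel=1e-10)


class TestGroupSummaryAndLsd:
    def test_noise_free_additive_group_means(self):
        gm = make_genotypes(np.array([[0]] * 3 + [[1]] * 3 + [[2]] * 3, dtype=np.int8))
        y = -0.2 * gm.calls[:, 0].astype(float) + np.tile([-0.001, 0.0, 0.001], 3)
        groups = genotype_group_summary(y, make_samples(9), gm, "m0")
        assert [g.genotype for g in groups] == ["RR", "RA", "AA"]
        assert groups[0].mean - groups[1].mean == pytest.approx(0.2, abs=1e-6)
        assert groups[1].mean - groups[2].mean == pytest.approx(0.2, abs=1e-6)

    def test_single_class_marker_one_row(self):
        gm = make_genotypes(np.zeros((5, 1), dtype=np.int8))
        groups = genotype_group_summary(np.arange(5.0), make_samples(5), gm, "m0")
        assert len(groups) == 1 and groups[0].count == 5

    @pytest.mark.parametrize(
        "marker,expected",
        [(m, [row[4] for row in rows]) for m, rows in GENOTYPE_GROUPS.items()],
    )
    def test_published_letter_patterns(self, marker, expected):
        rows = GENOTYPE_GROUPS[marker]
        letters = lsd_letters([(m, sd, n) for _, m, sd, n, _ in rows], alpha=0.05)
        assert letters == expected

    def test_identical_groups_share_letter(self):
        letters = lsd_letters([(1.0, 1.0, 50), (1.0, 1.0, 50)], alpha=0.5)
        assert letters[0] == letters[1]

    def test_all_groups_distinct(self):
        letters = lsd_letters([(0.0, 0.1, 50), (10.0, 0.1, 50), (20.0, 0.1, 50)])
        assert letters == ["a", "b", "c"]

    @given(perm=st.permutations(range(3)))
    @settings(deadline=None, max_examples=6)
    def test_grouping_partition_invariant_to_input_order(self, perm):
        # the same-letter partition must not depend on input order
        rows = GENOTYPE_GROUPS["gga1_178v"]
        triples = [(m, sd, n) for _, m, sd, n, _ in rows]
        base = lsd_letters(triples)
        letters = lsd_letters([triples[i] for i in perm])

        def shares(ls, i, j):
            return bool(set(ls[i]) & set(ls[j]))

        inv = {p: i for i, p in enumerate(perm)}
        for i in range(3):
            for j in range(i + 1, 3):
                assert shares(base, i, j) == shares(letters, inv[i], inv[j])

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            lsd_letters([(0.0, 1.0, 1), (1.0, 1.0, 10)])


def test_effect_estimate_coverage_quick():
    # simulated additive effect within +/- 2 se in about 95% of replicates
    rng = np.random.default_rng(12)
    hits = 0
    reps = 150
    for _ in range(reps):
        n = 300
        calls = rng.binomial(2, 0.4, size=(n, 1)).astype(np.int8)
        y = 2.0 * calls[:, 0] + rng.normal(0, 3, n)
        r = fit_marker_lm(y, make_samples(n), make_genotypes(calls), "m0")
        hits += abs(r.effect - 2.0) <= 2 * r.se
    assert hits / reps >= 0.90
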