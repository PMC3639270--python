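import numpy as np
import pytest
from scipy import special, stats

from egaflow.de_model import (
    Formula,
    Model,
    adjust_bh,
    estimate_dispersion,
    expected_count_filter,
    fit_poisson,
    lrt,
    overdispersed_test,
    run_source_analysis,
    run_stage_analysis,
)
from egaflow.io_tables import CountMatrix, Stage
from egaflow.synthetic_data import GeneClass, SimConfig, simulate_counts


def two_group_deviance(y, n1):
    """Closed-form Poisson LRT for a two-group split with equal offsets:
    2 * sum_groups T_j * ln(mean_j / pooled mean)."""
    y = np.asarray(y, dtype=float)
    groups = [y[:n1], y[n1:]]
    pooled = y.mean()
    stat = 0.0
    for g in groups:
        stat += 2.0 * special.xlogy(g.sum(), g.mean() / pooled)
    return stat


def bruteforce_bh(p):
    """Textbook step-up: p_(k) * m / k, cumulative-min from the largest."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestFitPoisson:
    def test_intercept_only_fits_sample_mean(self, two_sample_design):
        fit = fit_poisson([10, 10], two_sample_design, [1000, 1000],
                          Formula.REDUCED_NO_STAGE)
        assert fit.fitted_means == pytest.approx([10, 10], rel=1e-8)
        # rate = mean count / library size
        assert np.exp(fit.coefficient("intercept")) == pytest.approx(0.01, rel=1e-8)

    def test_two_group_saturated_means(self, two_sample_design):
        fit = fit_poisson([10, 40], two_sample_design, [1000, 1000],
                          Formula.FULL_MAIN)
        assert fit.fitted_means == pytest.approx([10, 40], rel=1e-8)

    def test_unequal_offsets_give_per_group_rates(self, two_sample_design):
        fit = fit_poisson([10, 40], two_sample_design, [1000, 2000],
                          Formula.FULL_MAIN)
        rates = fit.fitted_means / np.array([1000.0, 2000.0])
        assert rates == pytest.approx([0.010, 0.020], rel=1e-8)
        # grid-scan oracle: the per-group Poisson likelihood peaks at y/N
        grid = np.linspace(0.001, 0.05, 4901)
        ll = special.xlogy(10, 1000 * grid) - 1000 * grid
        assert grid[np.argmax(ll)] == pytest.approx(0.010, abs=1e-5)

    def test_matches_statsmodels_glm(self, paper_design):
        """Independent cross-check of IRLS against a reference GLM fitter."""
        import statsmodels.api as sm
        from egaflow.de_model import _design_matrix

        rng = np.random.default_rng(4)
        N = np.array([1e6, 2e6, 5e5, 1e6, 3e6, 8e5])
        y = rng.poisson([30, 80, 15, 60, 200, 40])
        X, _ = _design_matrix(paper_design, Formula.FULL_MAIN)
        ref = sm.GLM(y, X, family=sm.families.Poisson(),
                     offset=np.log(N)).fit()
        fit = fit_poisson(y, paper_design, N, Formula.FULL_MAIN)
        assert fit.coefficients == pytest.approx(ref.params, rel=1e-6)
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-6)

    def test_all_zero_gene_flagged_boundary_not_error(self, paper_design):
        fit = fit_poisson([0] * 6, paper_design, [1e6] * 6, Formula.FULL_MAIN)
        assert fit.boundary
        assert np.all(fit.fitted_means > 0)  # clamped, never exactly zero

    def test_empty_stage_level_flagged_boundary(self, paper_design):
        fit = fit_poisson([20, 35, 150, 0, 0, 0], paper_design, [1e6] * 6,
                          Formula.FULL_MAIN)
        assert fit.boundary
        # the 4-cell fitted means collapse towards zero
        assert fit.fitted_means[3:].max() < 1e-4

    def test_negative_counts_rejected(self, two_sample_design):
        with pytest.raises(ValueError, match="non-negative"):
            fit_poisson([-1, 5], two_sample_design, [1e3, 1e3], Formula.FULL_MAIN)


class TestLrt:
    def test_identical_groups_give_null_statistic(self, two_sample_design):
        full = fit_poisson([25, 25], two_sample_design, [1000, 1000],
                           Formula.FULL_MAIN)
        red = fit_poisson([25, 25], two_sample_design, [1000, 1000],
                          Formula.REDUCED_NO_STAGE)
        stat, df, p = lrt(full, red)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_closed_form_deviance_example(self, two_sample_design):
        full = fit_poisson([10, 40], two_sample_design, [1000, 1000],
                           Formula.FULL_MAIN)
        red = fit_poisson([10, 40], two_sample_design, [1000, 1000],
                          Formula.REDUCED_NO_STAGE)
        stat, df, p = lrt(full, red)
        expected = 2 * (10 * np.log(10 / 25) + 40 * np.log(40 / 25))
        assert stat == pytest.approx(expected, abs=1e-8)
        assert df == 1

    def test_chi_square_critical_value(self):
        assert stats.chi2.sf(3.841, 1) == pytest.approx(0.05, abs=5e-4)

    def test_random_cases_match_closed_form(self, six_equal_design):
        """100 random 3v3 equal-offset splits agree with the deviance formula."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            y = rng.poisson(rng.uniform(5, 200), size=6)
            if y[:3].sum() == 0 or y[3:].sum() == 0:
                continue
            full = fit_poisson(y, six_equal_design, [1e6] * 6, Formula.FULL_MAIN)
            red = fit_poisson(y, six_equal_design, [1e6] * 6,
                              Formula.REDUCED_NO_STAGE)
            stat, _, _ = lrt(full, red)
            assert stat == pytest.approx(two_group_deviance(y, 3), abs=1e-8)

    def test_non_nested_rejected(self, paper_design):
        full = fit_poisson([1, 2, 3, 4, 5, 6], paper_design, [1e6] * 6,
                           Formula.FULL_MAIN)
        with pytest.raises(ValueError, match="not nested"):
            lrt(full, full)


class TestDispersion:
    def test_hand_computed_pearson_sum(self, six_equal_design):
        """Counts (4,16,4,16) around a fitted mean of 10: X2/df = 14.4/3."""
        from egaflow.io_tables import SampleDesign, Source

        design = SampleDesign(
            ["a", "b", "c", "d"],
            [Stage.TWO_CELL, Stage.TWO_CELL, Stage.FOUR_CELL, Stage.FOUR_CELL],
            [Source.IN_VIVO] * 4, ["1", "2", "1", "2"],
        )
        fit = fit_poisson([4, 16, 4, 16], design, [1000] * 4,
                          Formula.REDUCED_NO_STAGE)
        assert fit.fitted_means == pytest.approx([10] * 4, rel=1e-8)
        phi = estimate_dispersion(fit, [4, 16, 4, 16])
        assert phi == pytest.approx(14.4 / 3, rel=1e-8)

    def test_poisson_consistent_data_floored_at_one(self, six_equal_design):
        fit = fit_poisson([100, 101, 99, 100, 100, 100], six_equal_design,
                          [1e6] * 6, Formula.FULL_MAIN)
        assert estimate_dispersion(fit, [100, 101, 99, 100, 100, 100]) == 1.0

    def test_saturated_fit_returns_one(self, two_sample_design):
        fit = fit_poisson([10, 40], two_sample_design, [1e3] * 2,
                          Formula.FULL_MAIN)
        assert fit.df_residual == 0
        assert estimate_dispersion(fit, [10, 40]) == 1.0


class TestOverdispersedTest:
    @pytest.fixture()
    def fits(self, six_equal_design):
        full = fit_poisson([10, 10, 10, 40, 40, 40], six_equal_design,
                           [1e6] * 6, Formula.FULL_MAIN)
        red = fit_poisson([10, 10, 10, 40, 40, 40], six_equal_design,
                          [1e6] * 6, Formula.REDUCED_NO_STAGE)
        return full, red

    def test_phi_one_identical_to_standard(self, fits):
        full, red = fits
        stat, df, p_std = lrt(full, red)
        scaled, p = overdispersed_test(full, red, phi=1.0)
        assert scaled == pytest.approx(stat)
        assert p == pytest.approx(p_std)

    def test_scaled_statistic_example(self, two_sample_design):
        """LRT 19.27 scaled by phi=4 gives 4.82 and p ~ 0.028 on chi2(1)."""
        full = fit_poisson([10, 40], two_sample_design, [1e3] * 2,
                           Formula.FULL_MAIN)
        red = fit_poisson([10, 40], two_sample_design, [1e3] * 2,
                          Formula.REDUCED_NO_STAGE)
        scaled, p = overdispersed_test(full, red, phi=4.0, reference="chisq")
        assert scaled == pytest.approx(19.2745 / 4, abs=1e-3)
        assert p == pytest.approx(stats.chi2.sf(scaled, 1))
        assert p == pytest.approx(0.028, abs=0.001)

    def test_monotone_in_phi(self, fits):
        full, red = fits
        _, _, p_std = lrt(full, red)
        previous = p_std
        for phi in (1.0, 1.5, 2.0, 4.0, 10.0):
            _, p = overdispersed_test(full, red, phi=phi, reference="chisq")
            assert p >= previous - 1e-12
            previous = p

    def test_f_reference_more_conservative_in_tail(self, fits):
        full, red = fits
        _, p_chi = overdispersed_test(full, red, phi=2.0, reference="chisq")
        _, p_f = overdispersed_test(full, red, phi=2.0, reference="f")
        assert p_f > p_chi

    def test_phi_below_one_rejected(self, fits):
        with pytest.raises(ValueError, match="phi"):
            overdispersed_test(*fits, phi=0.5)


class TestExpectedCountFilter:
    @pytest.mark.parametrize(
        "means, retained",
        [
            ([5.0, 5.0, 0.1, 0.1, 0.1, 0.1], True),   # boundary: >= is inclusive
            ([4.99, 100, 0, 0, 0, 0], False),          # only one sample >= 5
            ([4.99] * 6, False),
            ([5.0] * 6, True),
        ],
    )
    def test_boundary_cases(self, means, retained):
        assert expected_count_filter(np.array([means]))[0] == retained

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(3)
        means = rng.gamma(2, 4, size=(500, 6))
        mask = expected_count_filter(means)
        brute = np.array([sum(v >= 5 for v in row) >= 2 for row in means])
        assert np.array_equal(mask, brute)


class TestAdjustBh:
    def test_textbook_stepup_example(self):
        adjusted = adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert adjusted == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        assert adjust_bh([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    def test_single_p_unchanged(self):
        assert adjust_bh([0.3]) == pytest.approx([0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            assert adjust_bh(p) == pytest.approx(bruteforce_bh(p), abs=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=200)
        assert np.all(adjust_bh(p) >= p - 1e-12)


class TestRunStageAnalysis:
    def test_null_matrix_uniform_raw_p(self, null_only_poisson_sim):
        """Poisson truth, standard model: raw p < 0.05 for ~5% of genes."""
        counts, design, _ = null_only_poisson_sim
        results = run_stage_analysis(counts, design, model=Model.STANDARD)
        p = np.array([r.p_raw for r in results if r.retained_by_filter])
        assert len(p) > 1500
        assert np.mean(p < 0.05) == pytest.approx(0.05, abs=0.02)

    def test_overdispersed_significant_subset_of_standard(self):
        counts, design, _ = simulate_counts(SimConfig(n_genes=600, seed=17))
        sig_std = {r.gene_id for r in run_stage_analysis(
            counts, design, model=Model.STANDARD) if r.significant}
        sig_od = {r.gene_id for r in run_stage_analysis(
            counts, design, model=Model.OVERDISPERSED) if r.significant}
        assert sig_od <= sig_std

    def test_standard_model_inflated_under_overdispersion(self):
        """phi=4 data: the standard Poisson test rejects far too often,
        motivating the overdispersed model."""
        config = SimConfig(n_genes=1500,
                           class_proportions={GeneClass.NULL: 1.0},
                           dispersion=4.0, seed=5)
        counts, design, _ = simulate_counts(config)
        res_std = run_stage_analysis(counts, design, model=Model.STANDARD)
        res_od = run_stage_analysis(counts, design, model=Model.OVERDISPERSED)
        p_std = np.array([r.p_raw for r in res_std if r.retained_by_filter])
        p_od = np.array([r.p_raw for r in res_od if r.retained_by_filter])
        assert np.mean(p_std < 0.05) > 0.15
        assert np.mean(p_od < 0.05) < 0.08

    def test_stage_effect_recovery_high_counts(self, high_count_sim):
        counts, design, truth = high_count_sim
        results = run_stage_analysis(counts, design, model=Model.OVERDISPERSED)
        idx = {g: i for i, g in enumerate(truth.gene_ids)}
        errors = [
            r.log2_fold_change - truth.stage_log2_effect[idx[r.gene_id]]
            for r in results
            if r.retained_by_filter
            and truth.classes[idx[r.gene_id]] in (GeneClass.TWO_CELL_ENRICHED,
                                                  GeneClass.FOUR_CELL_ENRICHED)
        ]
        assert len(errors) > 50
        assert abs(np.mean(errors)) < 0.3

    def test_bias_shrinks_with_counts(self):
        """Log2 stage effect bias decreases from low- to high-count scale."""
        biases = {}
        for label, mean in (("low", -12.5), ("high", -8.5)):
            config = SimConfig(n_genes=800, baseline_log_rate_mean=mean,
                               baseline_log_rate_sd=0.3, dispersion=1.0, seed=19)
            counts, design, truth = simulate_counts(config)
            results = run_stage_analysis(counts, design, model=Model.STANDARD)
            idx = {g: i for i, g in enumerate(truth.gene_ids)}
            errs = [abs(r.log2_fold_change - truth.stage_log2_effect[idx[r.gene_id]])
                    for r in results
                    if r.retained_by_filter and not r.boundary
                    and np.isfinite(truth.stage_log2_effect[idx[r.gene_id]])
                    and truth.stage_log2_effect[idx[r.gene_id]] != 0]
            biases[label] = np.mean(errs)
        assert biases["high"] < biases["low"]

    def test_result_invariants(self):
        counts, design, _ = simulate_counts(SimConfig(n_genes=400, seed=23))
        for r in run_stage_analysis(counts, design):
            if r.retained_by_filter:
                assert r.p_adjusted >= r.p_raw - 1e-12
            if r.significant:
                assert r.retained_by_filter and r.p_adjusted < 0.05
            assert r.dispersion_phi >= 1.0
            assert r.lrt_statistic >= 0.0


class TestRunSourceAnalysis:
    def test_no_source_effect_controls_false_positives(self):
        config = SimConfig(n_genes=1000, class_proportions={GeneClass.NULL: 1.0},
                           baseline_log_rate_mean=-9.0, seed=29)
        counts, design, _ = simulate_counts(config)
        per_stage = run_source_analysis(counts, design, model=Model.OVERDISPERSED)
        for stage, results in per_stage.items():
            retained = [r for r in results if r.retained_by_filter]
            frac = sum(r.significant for r in retained) / max(1, len(retained))
            assert frac <= 0.05 + 0.02

    def test_calls_concentrate_at_perturbed_stage(self):
        """In vitro effects injected only before genome activation are found
        at the 2-cell stage, mirroring the strong 2-cell/4-cell asymmetry."""
        config = SimConfig(n_genes=800, baseline_log_rate_mean=-8.0,
                           source_effect_fraction=0.1,
                           source_log2_effect_range=(1.5, 2.5), seed=11)
        counts, design, truth = simulate_counts(config)
        per_stage = run_source_analysis(counts, design, model=Model.OVERDISPERSED)
        n2 = sum(r.significant for r in per_stage[Stage.TWO_CELL])
        n4 = sum(r.significant for r in per_stage[Stage.FOUR_CELL])
        assert n2 >= 20
        assert n4 <= max(2, 0.1 * n2)
        # direction recorded from the contrast sign
        idx = {g: i for i, g in enumerate(truth.gene_ids)}
        for r in per_stage[Stage.TWO_CELL]:
            if r.significant and truth.source_log2_effect[idx[r.gene_id]] != 0:
                assert (np.sign(r.log2_fold_change)
                        == np.sign(truth.source_log2_effect[idx[r.gene_id]]))

    def test_identical_source_counts_give_null_statistic(self, paper_design):
        # same counts and offsets for both sources within each stage
        counts = CountMatrix(["g"], list(paper_design.sample_ids),
                             np.array([[30, 30, 30, 50, 50, 50]]),
                             np.array([1_000_000] * 6))
        per_stage = run_source_analysis(counts, paper_design, model=Model.STANDARD)
        for results in per_stage.values():
            assert results[0].lrt_statistic == pytest.approx(0.0, abs=1e-6)
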