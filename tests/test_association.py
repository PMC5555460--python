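"""Scans, stepwise conditional detection, joint fits, bias and power forms."""

import numpy as np
import pytest
from scipy import stats

import eqtlsim as es


class TestUnivariateScan:
    def test_null_pvalues_uniform(self):
        spec = es.LDBlockSpec([1000], [0.0])
        G = es.simulate_locus(500, 1000, block_spec=spec, seed=1)
        y = np.random.default_rng(2).standard_normal(500)
        scan = es.univariate_scan(G, y)
        ks = stats.kstest(scan.p_value, "uniform")
        assert ks.pvalue > 0.001

    def test_single_causal_estimate_within_ci(self):
        spec = es.LDBlockSpec([5], [0.0])
        G = es.simulate_locus(20_000, 5, block_spec=spec, seed=3)
        cfg = es.assign_effects(G, [2], scenario="1:0", seed=4, ve_fixed=[0.05])
        y = es.simulate_trait(G, cfg, seed=5).y
        scan = es.univariate_scan(G, y)
        assert abs(scan.beta_hat[2] - cfg.beta[0]) < 3 * scan.se[2]

    def test_exact_linear_trait(self):
        g = np.random.default_rng(6).binomial(2, 0.3, size=(200, 1)).astype(float)
        scan = es.univariate_scan(g, 1.7 * g[:, 0] + 3.0)
        assert scan.beta_hat[0] == pytest.approx(1.7)
        assert 0 < scan.p_value[0] <= 1e-300  # underflow-guarded minimum

    def test_constant_variant_excluded(self):
        d = np.column_stack([np.full(100, 2.0), np.arange(100) % 3])
        scan = es.univariate_scan(d, np.random.default_rng(7).standard_normal(100))
        assert scan.excluded[0] and not scan.excluded[1]
        assert np.isnan(scan.p_value[0])


class TestStepwiseConditional:
    def test_null_trait_rarely_detects(self):
        spec = es.LDBlockSpec([200], [0.0])
        G = es.simulate_locus(1000, 200, block_spec=spec, seed=8)
        hits = 0
        rng = np.random.default_rng(9)
        for _ in range(50):
            peaks = es.stepwise_conditional(G, rng.standard_normal(1000))
            hits += peaks.n_peaks > 0
        # family-wise rate bounded by 1 - (1 - 1e-5)^200 ~ 0.2%
        assert hits <= 2

    def test_two_independent_causals_both_found(self):
        spec = es.LDBlockSpec([40], [0.0])
        G = es.simulate_locus(2000, 40, block_spec=spec, seed=10)
        cfg = es.assign_effects(G, [5, 30], scenario="2:0", seed=11,
                                ve_fixed=[0.1, 0.1])
        found = 0
        rng = np.random.default_rng(12)
        for _ in range(20):
            y = es.simulate_trait(G, cfg, seed=rng).y
            peaks = es.stepwise_conditional(G, y)
            found += set(cfg.causal_idx) <= set(peaks.variant_idx)
        assert found >= 18  # per-site power ~ 1 at ve = 0.1, n = 2000

    def test_opposite_signs_in_high_ld_cancel(self):
        # equal effects, r^2 = 0.9, opposite directions: the marginal effect
        # shrinks to beta*(1 - r) and detection collapses
        detections = 0
        rng = np.random.default_rng(13)
        for _ in range(25):
            G = es.sample_pair(2000, 0.25, 0.25, np.sqrt(0.9), seed=rng)
            cfg = es.assign_effects(G, [0, 1], scenario="1:1", seed=rng,
                                    ve_fixed=[0.1, 0.1])
            y = es.simulate_trait(G, cfg, seed=rng).y
            detections += es.stepwise_conditional(G, y).n_peaks > 0
        single_power = es.univariate_power(0.1, 2000)
        assert single_power > 0.999
        assert detections / 25 < 0.5

    def test_first_step_is_argmin_of_scan(self, block_panel):
        cfg = es.assign_effects(block_panel, [10, 90], scenario="2:0", seed=14)
        y = es.simulate_trait(block_panel, cfg, seed=15).y
        peaks = es.stepwise_conditional(block_panel, y)
        scan = es.univariate_scan(block_panel, y)
        assert peaks.n_peaks >= 1
        assert peaks.variant_idx[0] == scan.argmin_p()

    def test_peaks_conditionally_significant_and_ordered(self, block_panel):
        cfg = es.assign_effects(block_panel, [5, 60, 120, 180],
                                scenario="4:0", seed=16)
        y = es.simulate_trait(block_panel, cfg, seed=17).y
        peaks = es.stepwise_conditional(block_panel, y, alpha=1e-5)
        assert np.all(peaks.p_value < 1e-5)
        assert np.all(np.diff(peaks.step) > 0)
        assert len(set(peaks.variant_idx)) == peaks.n_peaks


class TestJointFit:
    def test_single_variant_equals_univariate(self, block_panel):
        y = es.simulate_trait(
            block_panel,
            es.assign_effects(block_panel, [50], scenario="1:0", seed=18),
            seed=19,
        ).y
        jf = es.joint_fit(block_panel, y, [50])
        scan = es.univariate_scan(block_panel, y)
        assert jf.beta_hat[0] == pytest.approx(scan.beta_hat[50])
        assert jf.se[0] == pytest.approx(scan.se[50])

    def test_joint_unbiased_univariate_biased_at_high_ld(self):
        # pair at r^2 = 0.9: joint estimates centre on truth, univariate
        # estimates centre on truth + the omitted-variable bias
        r = np.sqrt(0.9)
        beta = 0.5
        rng = np.random.default_rng(20)
        joint_b, uni_b = [], []
        for _ in range(300):
            G = es.sample_pair(2000, 0.27639, 0.27639, r, seed=rng)
            y = beta * (G.dosages[:, 0] + G.dosages[:, 1]) + rng.standard_normal(2000)
            jf = es.joint_fit(G, y, [0, 1])
            joint_b.append(jf.beta_hat[0])
            uni_b.append(es.univariate_scan(G, y).beta_hat[0])
        expected_bias = es.expected_univariate_bias(r, beta, 0.27639, 0.27639)
        assert np.mean(joint_b) == pytest.approx(beta, abs=0.02)
        assert np.mean(uni_b) - beta == pytest.approx(expected_bias, abs=0.02)

    def test_perfect_collinearity_pruned(self):
        g = np.random.default_rng(21).binomial(2, 0.3, size=(300, 1)).astype(float)
        d = np.column_stack([g, g, np.random.default_rng(22).binomial(2, 0.4, 300)])
        y = d[:, 0] + np.random.default_rng(23).standard_normal(300)
        jf = es.joint_fit(d, y, [0, 1, 2])
        assert list(jf.variant_idx) == [0, 2]
        assert list(jf.pruned_idx) == [1]

    def test_degenerate_sample_size_errors(self):
        d = np.random.default_rng(24).normal(size=(4, 5))
        with pytest.raises(ValueError, match="parameters"):
            es.joint_fit(d, np.zeros(4), [0, 1, 2, 3, 4])


class TestExpectedUnivariateBias:
    def test_zero_ld_zero_bias(self):
        assert es.expected_univariate_bias(0.0, 0.8, 0.2, 0.4) == 0.0

    def test_equal_frequencies_ratio_cancels(self):
        assert es.expected_univariate_bias(0.6, 0.5, 0.3, 0.3) == pytest.approx(0.3)

    def test_frequency_ratio_orientation_matches_simulation(self):
        """The frequency ratio must be sqrt(p2 q2 / (p1 q1)) — omitted
        variant over focal — which only a large-n simulation can arbitrate
        against the transposed form."""
        r, b2, p1, p2 = 0.5, 0.4, 0.2, 0.5
        ours = es.expected_univariate_bias(r, b2, p1, p2)
        transposed = r * b2 * np.sqrt(p1 * (1 - p1) / (p2 * (1 - p2)))
        rng = np.random.default_rng(25)
        # haplotypes built directly from the four-cell table so the coupled
        # allele orientation is pinned (at maf 0.5 the minor allele is
        # ambiguous and re-orientation would scramble the sign of r)
        freqs = es.haplotype_frequencies(p1, p2, r)
        n = 4000
        biases = []
        for _ in range(300):
            cats = rng.choice(4, size=2 * n, p=freqs)
            a1, a2 = (cats >> 1) & 1, cats & 1
            g1 = (a1[0::2] + a1[1::2]).astype(float)
            g2 = (a2[0::2] + a2[1::2]).astype(float)
            y = 0.3 * g1 + b2 * g2 + rng.standard_normal(n)
            biases.append(es.univariate_scan(g1[:, None], y).beta_hat[0] - 0.3)
        mean = np.mean(biases)
        se = np.std(biases) / np.sqrt(len(biases))
        assert abs(mean - ours) < 3 * se
        assert abs(mean - transposed) > 10 * se  # rules out the other form

    def test_infeasible_r_rejected(self):
        with pytest.raises(ValueError, match="bound"):
            es.expected_univariate_bias(0.9, 0.5, 0.05, 0.5)


class TestUnivariatePower:
    def test_null_equals_alpha(self):
        assert es.univariate_power(0.0, 1000, 1e-5) == pytest.approx(1e-5)

    def test_monotone_in_n_and_ve(self):
        grid = [200, 500, 1000, 2000, 5000]
        powers = [es.univariate_power(0.03, n) for n in grid]
        assert np.all(np.diff(powers) > 0)
        powers_ve = [es.univariate_power(v, 800) for v in (0.01, 0.03, 0.06)]
        assert np.all(np.diff(powers_ve) > 0)


class TestRequiredSampleSize:
    def test_independent_pair_needs_small_n(self):
        res = es.required_sample_size(
            0.0, 0.1, tol=0.1, n_grid=range(100, 501, 100), reps=200, seed=30
        )
        # closed form: MAE ~ sqrt(2/pi)/sqrt(0.4 n) <= 0.1 -> n >= 159
        assert res.required_n == 200
        assert res.reached

    def test_error_curve_decreases_with_n(self):
        res = es.required_sample_size(
            0.5, 0.1, n_grid=[200, 800, 3200], reps=300, seed=31
        )
        mae = res.curve["mean_abs_error"].to_numpy()
        assert mae[0] > mae[1] > mae[2]

    def test_unreachable_tolerance_reported(self):
        res = es.required_sample_size(
            0.9, 0.1, tol=0.001, n_grid=[100, 200], reps=100, seed=32
        )
        assert res.required_n is None and not res.reached
        assert len(res.curve) == 2

    def test_variance_inflation_ordering(self):
        # 1/(1 - r^2) variance inflation: tighter LD needs more samples
        kw = dict(ve_each=0.1, n_grid=range(100, 2001, 100), reps=200)
        n_free = es.required_sample_size(0.0, seed=33, **kw).required_n
        n_tight = es.required_sample_size(0.8, seed=33, **kw).required_n
        assert n_free < n_tight
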