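"""fGn simulation: autocorrelation law, exactness, correlated trial-H draws."""

import numpy as np
import pytest
import sympy
from hypothesis import given
from hypothesis import strategies as st

from hurstlab import (
    CohortConfig,
    generate_cohort,
    hk_autocorrelation,
    sample_correlated_trial_h,
    simulate_fgn,
    simulate_fgn_batch,
)
from hurstlab.fgn import day_sd_for_target_icc, write_cohort
from hurstlab.reliability import icc_3k


class TestHKAutocorrelation:
    def test_lag_zero_is_one_from_formula(self):
        for h in (0.1, 0.5, 0.9, 1.0):
            assert hk_autocorrelation(h, 0).rho[0] == pytest.approx(1.0, abs=1e-15)

    def test_white_noise_has_zero_correlation(self):
        rho = hk_autocorrelation(0.5, 10).rho
        assert np.allclose(rho[1:], 0.0, atol=1e-12)

    def test_persistent_lag_one_closed_form(self):
        # 1/2 * 2^{2*0.75} - 1 = sqrt(2) - 1
        assert hk_autocorrelation(0.75, 1).rho[1] == pytest.approx(
            np.sqrt(2) - 1, abs=1e-12
        )

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.5])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            hk_autocorrelation(bad, 5)

    def test_matches_symbolic_evaluation(self, rng):
        """20 random (H, k) pairs against a 50-digit sympy evaluation.

        The formula subtracts terms of size k^{2H} to produce a much smaller
        result, so the achievable float64 accuracy is bounded by the
        cancellation: the tolerance scales with eps * k^{2H}. At small lags
        this is full 12-significant-digit agreement.
        """
        eps = np.finfo(float).eps
        for _ in range(20):
            h = float(rng.uniform(0.05, 1.0))
            k = int(rng.integers(1, 200))
            hs = sympy.Float(h, 50)
            expected = float(
                sympy.Rational(1, 2) * (k + 1) ** (2 * hs)
                + sympy.Rational(1, 2) * (k - 1) ** (2 * hs) - k ** (2 * hs)
            )
            got = hk_autocorrelation(h, k).rho[k]
            bound = max(1e-12 * abs(expected), 8 * eps * (k + 1) ** (2 * h))
            assert abs(got - expected) <= bound

    def test_matches_symbolic_evaluation_small_lags(self, rng):
        """Where cancellation is mild, demand 12 significant digits."""
        for _ in range(20):
            h = float(rng.uniform(0.05, 1.0))
            k = int(rng.integers(1, 6))
            hs = sympy.Float(h, 50)
            expected = float(
                sympy.Rational(1, 2) * (k + 1) ** (2 * hs)
                + sympy.Rational(1, 2) * (k - 1) ** (2 * hs) - k ** (2 * hs)
            )
            got = hk_autocorrelation(h, k).rho[k]
            assert got == pytest.approx(expected, rel=1e-12, abs=1e-14)

    @given(h=st.floats(0.01, 1.0), max_lag=st.integers(0, 100))
    def test_invariants(self, h, max_lag):
        rho = hk_autocorrelation(h, max_lag).rho
        assert rho[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.abs(rho) <= 1.0 + 1e-12)
        if h > 0.5 and max_lag >= 1:
            assert np.all(rho[1:] > 0.0)
            assert np.all(np.diff(rho) <= 1e-12)


class TestSimulateFgn:
    def test_white_noise_uncorrelated(self, rng):
        x = simulate_fgn_batch(np.full(1, 0.5), 1000, rng=rng)[0]
        xc = x - x.mean()
        r1 = (xc[:-1] * xc[1:]).sum() / (xc * xc).sum()
        assert abs(r1) < 3.0 / np.sqrt(1000)

    @pytest.mark.parametrize("h", [0.3, 0.5, 0.75, 0.9])
    def test_exact_autocovariance(self, h):
        """Product-moment ACF (true mean 0, variance 1) matches the HK law.

        Uses the unbiased cross-replicate moment E[x_t x_{t+k}] rather than
        the time-averaged sample ACF, whose mean-centering bias is large for
        long-memory series at this length.
        """
        rng = np.random.default_rng(99)
        x = simulate_fgn_batch(np.full(500, h), 512, rng=rng)
        rho = hk_autocorrelation(h, 5).rho
        for k in range(1, 6):
            per_rep = (x[:, :-k] * x[:, k:]).mean(axis=1)
            se = per_rep.std(ddof=1) / np.sqrt(per_rep.size)
            assert abs(per_rep.mean() - rho[k]) < 3.0 * se

    def test_unit_variance_and_sd_scaling(self):
        rng = np.random.default_rng(5)
        x = simulate_fgn_batch(np.full(400, 0.75), 256, rng=rng)
        var = (x * x).mean(axis=1)
        assert var.mean() == pytest.approx(1.0, abs=3 * var.std(ddof=1) / 20)
        y = simulate_fgn(0.75, 256, sd=2.5, seed=8)
        z = simulate_fgn(0.75, 256, sd=1.0, seed=8)
        assert np.allclose(y.values, 2.5 * z.values)

    def test_deterministic_under_seed(self):
        a = simulate_fgn(0.75, 50, seed=17)
        b = simulate_fgn(0.75, 50, seed=17)
        assert np.array_equal(a.values, b.values)

    @pytest.mark.parametrize("bad_h", [0.0, 1.0, -0.3, 2.0])
    def test_hurst_domain_error(self, bad_h):
        with pytest.raises(ValueError):
            simulate_fgn(bad_h, 64, seed=0)

    def test_length_error(self):
        with pytest.raises(ValueError):
            simulate_fgn(0.5, 4, seed=0)


class TestSampleCorrelatedTrialH:
    def test_icc_one_gives_identical_columns(self, rng):
        m = sample_correlated_trial_h(0.7, 0.1, 1.0, 5, 50, rng=rng)
        assert np.allclose(m.values, m.values[:, [0]])

    def test_icc_zero_gives_independent_columns(self, rng):
        m = sample_correlated_trial_h(0.75, 0.11, 0.0, 2, 5000, rng=rng)
        r = np.corrcoef(m.values.T)[0, 1]
        assert abs(r) < 3.0 / np.sqrt(5000)

    def test_design_moments_recovered(self, rng):
        """Mean 0.75, sd 0.11, compound-symmetry trial correlation 0.65."""
        m = sample_correlated_trial_h(0.75, 0.11, 0.65, 4, 5000, rng=rng)
        v = m.values
        assert v.mean() == pytest.approx(0.75, abs=0.01)
        assert v.std(ddof=1) == pytest.approx(0.11, abs=0.01)
        corr = np.corrcoef(v.T)
        pairs = corr[np.triu_indices(4, k=1)]
        assert pairs.mean() == pytest.approx(0.65, abs=0.03)
        # compound symmetry: all pairwise correlations statistically alike
        assert pairs.max() - pairs.min() < 6.0 / np.sqrt(5000)

    def test_support_handling(self, rng):
        clip = sample_correlated_trial_h(0.87, 0.11, 0.65, 2, 4000,
                                         rng=np.random.default_rng(3), truncate="clip")
        assert clip.values.max() <= 0.999 and clip.n_resampled > 0
        res = sample_correlated_trial_h(0.87, 0.11, 0.65, 2, 4000,
                                        rng=np.random.default_rng(3), truncate="resample")
        assert res.values.max() < 1.0 and res.n_resampled > 0
        # resampling pulls the realized mean down more than clipping
        assert res.values.mean() < clip.values.mean()
        with pytest.raises(ValueError):
            sample_correlated_trial_h(0.87, 0.11, 0.65, 2, 4000,
                                      rng=np.random.default_rng(3), truncate="none")

    @pytest.mark.parametrize("kwargs", [
        dict(mean=1.2, sd=0.1, icc=0.5), dict(mean=0.5, sd=-1.0, icc=0.5),
        dict(mean=0.5, sd=0.1, icc=1.5),
    ])
    def test_domain_errors(self, kwargs):
        with pytest.raises(ValueError):
            sample_correlated_trial_h(n_trials=3, n_subjects=10, seed=0, **kwargs)


class TestGenerateCohort:
    def test_shape_and_columns(self, small_cohort):
        config, cohort, truth = small_cohort
        assert list(cohort.columns) == ["subject", "group", "day", "trial",
                                        "variable", "stride", "value"]
        expected = config.n_subjects * 2 * 9 * config.n_strides
        assert len(cohort) == expected
        assert len(truth) == config.n_subjects * 18
        assert truth["true_h"].between(0, 1, inclusive="neither").all()

    def test_zero_day_and_trial_variance_duplicates_days(self):
        config = CohortConfig(groups={"g": 0.7}, n_subjects=6, n_strides=32,
                              sd_day=0.0, sd_trial=0.0, seed=3)
        _, truth = generate_cohort(config)
        wide = truth.pivot_table(index="subject", columns="day", values="true_h")
        assert np.allclose(wide[1], wide[2])

    def test_byte_identical_rerun(self, tmp_path):
        config = CohortConfig(groups={"g": 0.7}, n_subjects=3, n_strides=16, seed=11)
        paths = []
        for tag in ("a", "b"):
            cohort, _ = generate_cohort(config)
            p = tmp_path / f"{tag}.csv"
            write_cohort(cohort, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_designed_day_icc_recovered_from_truth(self):
        """Variance components chosen for day-average ICC(3,2) = 0.9."""
        sd_subject, sd_trial, k = 0.10, 0.03, 9
        sd_day = day_sd_for_target_icc(0.9, sd_subject, sd_trial, k)
        config = CohortConfig(groups={"g": 0.75}, n_subjects=60, n_strides=16,
                              sd_subject=sd_subject, sd_day=sd_day,
                              sd_trial=sd_trial, seed=29)
        _, truth = generate_cohort(config)
        cube = truth.sort_values(["subject", "day", "trial"])["true_h"].to_numpy()
        day_means = cube.reshape(60, 2, 9).mean(axis=2)
        res = icc_3k(day_means)
        assert res.ci_low < 0.9 < res.ci_high

    def test_config_validation(self):
        with pytest.raises(ValueError):
            generate_cohort(CohortConfig(groups={"g": 1.3}))
        with pytest.raises(ValueError):
            generate_cohort(CohortConfig(n_strides=4))
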