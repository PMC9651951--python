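"""Population statistics: regressions, group splits, Bayes factors."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from timecells.distributions import sample_bounded_powerlaw
from timecells.popstats import (
    alpha_posterior_summary,
    bayes_ttest,
    cdf_log_linearity,
    early_late_analysis,
    event_correlation_analysis,
    jzs_bf10,
    regress_quadratic,
    sign_split_chi2,
)
from timecells.synthgen import GeneratorConfig, generate_population


class TestSignSplit:
    def test_yates_corrected_value_for_93_of_131(self):
        chi2, p = sign_split_chi2(93, 131)
        assert chi2 == pytest.approx(22.3, abs=0.05)
        assert p < 0.001

    def test_even_split_is_zero(self):
        chi2, _ = sign_split_chi2(50, 100)
        assert chi2 == 0.0

    def test_hand_arithmetic(self):
        chi2, _ = sign_split_chi2(60, 100)
        assert chi2 == pytest.approx(2 * 9.5**2 / 50)

    @pytest.mark.parametrize("k,n", [(10, 30), (0, 7), (93, 131)])
    def test_symmetry(self, k, n):
        assert sign_split_chi2(k, n)[0] == pytest.approx(
            sign_split_chi2(n - k, n)[0])

    def test_errors(self):
        with pytest.raises(ValueError):
            sign_split_chi2(1, 0)
        with pytest.raises(ValueError):
            sign_split_chi2(5, 3)


class TestRegressQuadratic:
    def test_noiseless_linear_recovery(self):
        x = np.linspace(0.35, 7.2, 40)
        y = 0.11 + 0.14 * x
        rep = regress_quadratic(y, x)
        assert rep.coef("intercept") == pytest.approx(0.11, abs=1e-8)
        assert rep.coef("linear") == pytest.approx(0.14, abs=1e-8)
        assert rep.coef("quadratic") == pytest.approx(0.0, abs=1e-8)
        assert rep.r2_adj == pytest.approx(1.0)

    def test_quadratic_recovery(self, rng):
        x = np.linspace(0.35, 7.2, 131)
        y = 1.0 - 0.11 * x**2 + rng.normal(0, 0.05, 131)
        rep = regress_quadratic(y, x)
        assert rep.terms.loc["quadratic", "p"] < 0.001
        assert rep.coef("quadratic") < 0

    def test_null_calibration(self):
        """Independent noise: the BIC-approximate comparison should pick
        the null in the long run (> 80% of 200 seeds)."""
        wins = 0
        for s in range(200):
            r = np.random.default_rng(s)
            x = r.uniform(0.35, 7.2, 131)
            y = r.normal(0, 1, 131)
            wins += regress_quadratic(y, x).best_model == "null"
        assert wins / 200 > 0.8

    def test_errors(self):
        with pytest.raises(ValueError):
            regress_quadratic([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            regress_quadratic([1.0, 2.0, 3.0, 4.0], [2.0, 2.0, 2.0, 2.0])


class TestAlphaSummary:
    def test_point_mass(self):
        s = alpha_posterior_summary(np.ones(500))
        assert s["mean"] == 1.0
        assert s["ci95"] == (1.0, 1.0)
        assert s["frac_in_0.9_1.1"] == 1.0

    def test_normal_draws_fraction(self, rng):
        draws = rng.normal(1.0, 0.1, 100_000)
        s = alpha_posterior_summary(draws)
        assert s["frac_in_0.9_1.1"] == pytest.approx(0.6827, abs=0.01)

    def test_normal_posterior_summary_shape(self, rng):
        draws = rng.normal(0.92, 0.095, 100_000)
        s = alpha_posterior_summary(draws)
        assert s["mean"] == pytest.approx(0.92, abs=0.01)
        assert s["ci95"][0] == pytest.approx(0.92 - 1.96 * 0.095, abs=0.01)
        assert s["ci95"][1] == pytest.approx(0.92 + 1.96 * 0.095, abs=0.01)

    def test_minimum_draws(self):
        with pytest.raises(ValueError):
            alpha_posterior_summary(np.ones(10))


class TestCdfLogLinearity:
    def test_geometric_sequence_is_perfectly_linear(self):
        peaks = 0.35 * 2.0 ** np.arange(5)
        _, _, r2 = cdf_log_linearity(peaks)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_powerlaw_sample_is_linear_uniform_is_not(self):
        pl = sample_bounded_powerlaw(1.0, 0.35, 7.2, 10_000, seed=4)
        _, _, r2_pl = cdf_log_linearity(pl)
        rng = np.random.default_rng(4)
        _, _, r2_un = cdf_log_linearity(rng.uniform(0.35, 7.2, 10_000))
        assert r2_pl > 0.99
        assert r2_un < r2_pl - 0.05

    def test_positive_only(self):
        with pytest.raises(ValueError):
            cdf_log_linearity([0.0, 1.0])


class TestJzsBayesFactor:
    def test_two_sided_matches_pingouin(self):
        import pingouin as pg
        for t, n in ((2.5, 30), (1.0, 15), (4.2, 60)):
            assert jzs_bf10(t, n, n - 1) == pytest.approx(
                float(pg.bayesfactor_ttest(t, n)), rel=1e-3)

    def test_one_sided_doubles_under_agreement(self):
        # strongly positive t: nearly all H1 mass is already at delta>0,
        # so the one-sided BF is ~2x the two-sided BF
        two = jzs_bf10(4.0, 40, 39, alternative="two-sided")
        one = jzs_bf10(4.0, 40, 39, alternative="greater")
        assert one == pytest.approx(2 * two, rel=0.02)

    def test_bayes_ttest_two_sample(self, rng):
        x = rng.normal(0.8, 1.0, 50)
        y = rng.normal(0.0, 1.0, 50)
        res = bayes_ttest(x, y, alternative="greater")
        assert res["bf10"] > 10
        assert res["dof"] == 98


class TestEarlyLate:
    def test_split_counts_and_tests(self):
        peaks = sample_bounded_powerlaw(1.0, 0.35, 7.2, 131, seed=0)
        widths = 0.11 + 0.14 * peaks
        rep = early_late_analysis(peaks, widths)
        assert rep.n_early + rep.n_late == 131
        assert rep.early_uniform_ks is not None
        assert rep.normalized_two_sample_ks is not None

    def test_all_early_skips_late(self):
        peaks = np.linspace(0.4, 1.8, 20)
        rep = early_late_analysis(peaks, 0.11 + 0.14 * peaks)
        assert rep.n_late == 0
        assert rep.late_uniform_ks is None
        assert any("late" in w for w in rep.warnings)

    def test_threshold_at_max_puts_all_early(self):
        peaks = sample_bounded_powerlaw(1.0, 0.35, 7.2, 50, seed=1)
        rep = early_late_analysis(peaks, 0.11 + 0.14 * peaks,
                                  threshold=peaks.max() + 1)
        assert rep.n_early == 50 and rep.n_late == 0

    def test_two_sample_calibration_and_uniform_power(self):
        """Peaks drawn with alpha=1 share a normalized distribution across
        the 2 s split (rejection near nominal 5%), while within-group
        uniform-KS tests reject far above chance."""
        n_seeds = 60
        rej2 = reju = 0
        for s in range(n_seeds):
            peaks = sample_bounded_powerlaw(1.0, 0.35, 7.2, 131, seed=s)
            rep = early_late_analysis(peaks, 0.11 + 0.14 * peaks)
            rej2 += rep.normalized_two_sample_ks["p"] < 0.05
            reju += rep.early_uniform_ks["p"] < 0.05
        assert 0.0 <= rej2 / n_seeds <= 0.15
        assert reju / n_seeds > 0.6


class TestEventCorrelation:
    @staticmethod
    def frames(coupling, seed=13, n_cells=40):
        cfg = GeneratorConfig(n_time_cells=n_cells, n_distractor_cells=0,
                              n_interneurons=0, trials_per_cell=40,
                              event_coupling=coupling, seed=seed)
        _, truth = generate_population(cfg)
        trials = truth.trials.rename(columns={"cell_id": "unit_id",
                                              "mu_i": "mu",
                                              "event_offset": "event_offset_s"})
        cells = truth.cells.rename(columns={"cell_id": "unit_id"})[["unit_id", "M"]]
        return trials, cells

    def test_no_coupling_gives_null(self):
        trials, cells = self.frames(0.0)
        out = event_correlation_analysis(trials, cells)
        assert abs(out["mean_r"]) < 0.06
        assert out["one_sample"]["bf10"] < 3

    def test_positive_coupling_detected_and_early_stronger(self):
        trials, cells = self.frames(0.5, n_cells=60)
        out = event_correlation_analysis(trials, cells)
        assert out["one_sample"]["bf10"] > 10
        early = out["per_cell"]["M"] < 2.0
        assert out["per_cell"].loc[early, "r"].mean() > \
            out["per_cell"].loc[~early, "r"].mean()
        assert out["early_vs_late"]["bf10"] > 1

    def test_too_few_event_trials_excluded(self):
        trials = pd.DataFrame({"unit_id": "c0", "trial_id": [0, 1],
                               "mu": [1.0, 1.2], "event_offset_s": [0.1, -0.1]})
        cells = pd.DataFrame({"unit_id": ["c0"], "M": [1.1]})
        out = event_correlation_analysis(trials, cells)
        assert len(out["per_cell"]) == 0
        assert out["warnings"]

    def test_constant_offsets_excluded(self):
        trials = pd.DataFrame({"unit_id": "c0", "trial_id": range(8),
                               "mu": np.linspace(1, 2, 8),
                               "event_offset_s": 0.0})
        cells = pd.DataFrame({"unit_id": ["c0"], "M": [1.5]})
        out = event_correlation_analysis(trials, cells)
        assert len(out["per_cell"]) == 0
        assert any("constant" in w for w in out["warnings"])
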