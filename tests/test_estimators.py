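import numpy as np
import pytest
import statsmodels.api as sm

from netmr import estimators as est
from netmr.synthetic_data import SimConfig, simulate_arrays
from tests.conftest import random_instance


class TestWaldRatio:
    def test_arithmetic(self):
        e = est.wald_ratio(0.1, 0.02, 0.05, 0.01)
        assert e.beta == pytest.approx(0.5)
        assert e.se == pytest.approx(0.1)

    def test_null_numerator(self):
        e = est.wald_ratio(0.2, 0.02, 0.0, 0.01)
        assert e.beta == 0.0
        assert e.se == pytest.approx(0.05)

    def test_zero_exposure_effect_errors(self):
        with pytest.raises(ZeroDivisionError):
            est.wald_ratio(0.0, 0.02, 0.05, 0.01)


class TestIvw:
    def test_consistent_two_snp_instance(self):
        e = est.ivw(([0.1, 0.2], [0.01, 0.01], [0.02, 0.04], [0.01, 0.01]))
        assert e.beta == pytest.approx(0.2)
        assert e.extras["q"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_wls_through_origin_oracle(self, rng):
        # independent oracle: statsmodels weighted least squares, no const
        for _ in range(20):
            bx, bxse, by, byse = random_instance(rng, n=20)
            fit = sm.WLS(by, bx, weights=1.0 / byse ** 2).fit()
            e = est.ivw((bx, bxse, by, byse), effects_model="fixed")
            assert e.beta == pytest.approx(fit.params[0], abs=1e-10)
            # fixed-effects SE is (sum of weights on x)^(-1/2)
            se_oracle = float(np.sum(bx ** 2 / byse ** 2)) ** -0.5
            assert e.se == pytest.approx(se_oracle, abs=1e-10)

    def test_random_effects_inflates_se_when_overdispersed(self, rng):
        bx, bxse, by, byse = random_instance(rng, n=30)
        by = by + rng.normal(0, 0.05, 30)  # excess heterogeneity
        fixed = est.ivw((bx, bxse, by, byse), effects_model="fixed")
        auto = est.ivw((bx, bxse, by, byse), effects_model="auto")
        assert auto.se > fixed.se
        assert auto.beta == fixed.beta

    def test_insufficient_instruments(self):
        with pytest.raises(est.InsufficientInstrumentsError):
            est.ivw(([0.1], [0.01], [0.02], [0.01]))


class TestMaximumLikelihood:
    def test_reduces_to_ivw_when_exposure_noise_vanishes(self, rng):
        bx, _, by, byse = random_instance(rng, n=15)
        tiny = np.full(15, 1e-10)
        ml = est.maximum_likelihood((bx, tiny, by, byse))
        ref = est.ivw((bx, tiny, by, byse))
        assert ml.beta == pytest.approx(ref.beta, abs=1e-6)

    def test_exact_ratio_instance(self):
        e = est.maximum_likelihood(([0.1, 0.2], [0.01, 0.01],
                                    [0.02, 0.04], [0.01, 0.01]))
        assert e.beta == pytest.approx(0.2, abs=1e-8)


class TestWeightedMedian:
    def test_equal_weights_is_middle_ratio(self):
        bx = np.ones(3)
        by = np.array([0.1, 0.2, 0.3])
        byse = np.ones(3)
        e = est.weighted_median((bx, 0.01 * bx, by, byse), n_boot=50)
        assert e.beta == pytest.approx(0.2)

    def test_hand_interpolation_oracle(self):
        # ratios (0.1, 0.2, 0.3), weights (0.5, 0.25, 0.25):
        # 0.1 + 0.1*(0.5-0.25)/(0.625-0.25) = 0.16667
        bx = np.ones(3)
        by = np.array([0.1, 0.2, 0.3])
        byse = 1.0 / np.sqrt(np.array([0.5, 0.25, 0.25]))
        e = est.weighted_median((bx, 0.01 * bx, by, byse), n_boot=50)
        assert e.beta == pytest.approx(1 / 6, abs=1e-6)

    def test_invariant_to_snp_ordering(self, rng):
        bx, bxse, by, byse = random_instance(rng, n=15)
        perm = rng.permutation(15)
        a = est.weighted_median((bx, bxse, by, byse), n_boot=10, seed=1)
        b = est.weighted_median((bx[perm], bxse[perm], by[perm], byse[perm]),
                                n_boot=10, seed=1)
        assert a.beta == pytest.approx(b.beta, abs=1e-12)

    @pytest.mark.parametrize("n_invalid,breaks", [(98, False), (120, True)])
    def test_breakdown_point_at_half_the_weight(self, rng, n_invalid,
                                                breaks):
        # 49% invalid weight: estimate stays with the valid cluster;
        # 60% invalid weight: estimate defects to the contaminated value
        n = 200
        gamma = np.full(n, 0.3)  # equal strength -> weight share = count share
        truth, shift = 0.1, 1.0
        by_true = truth * gamma
        by_true[:n_invalid] += gamma[:n_invalid] * shift
        bx = gamma + rng.normal(0, 0.001, n)
        by = by_true + rng.normal(0, 0.005, n)
        e = est.weighted_median((bx, np.full(n, 0.001), by,
                                 np.full(n, 0.005)), n_boot=100, seed=2)
        near_valid = abs(e.beta - truth) < abs(e.beta - (truth + shift))
        assert near_valid != breaks


class TestEgger:
    def test_exact_linear_data_recovered(self, rng):
        bx = rng.uniform(0.05, 0.5, 10)
        by = 0.05 + 0.3 * bx
        byse = rng.uniform(0.005, 0.02, 10)
        e = est.egger((bx, 0.01 * np.ones(10), by, byse))
        assert e.beta == pytest.approx(0.3, abs=1e-10)
        assert e.extras["intercept"] == pytest.approx(0.05, abs=1e-10)
        assert e.extras["q"] == pytest.approx(0.0, abs=1e-10)

    def test_directional_pleiotropy_recovers_intercept(self, rng):
        n = 100
        gamma = rng.uniform(0.1, 0.5, n)
        alpha = rng.normal(0.05, 0.01, n)  # InSIDE holds
        byse = np.full(n, 0.01)
        by = 0.2 * gamma + alpha + rng.normal(0, 0.01, n)
        e = est.egger((gamma, np.full(n, 1e-6), by, byse))
        icpt, icpt_se = e.extras["intercept"], e.extras["intercept_se"]
        assert abs(icpt - 0.05) < 2 * max(icpt_se, 0.01 / np.sqrt(n))


class TestPresso:
    def test_clean_data_no_outliers(self, rng):
        bx, bxse, by, byse = random_instance(rng, n=20)
        e = est.mr_presso((bx, bxse, by, byse), n_sim=500, seed=3)
        assert e.extras["global_pval"] > 0.05
        assert e.extras["outlier_indices"] == []
        assert e.beta == pytest.approx(e.extras["raw"].beta)

    def test_spiked_outlier_flagged_and_corrected(self, rng):
        bx, bxse, by, byse = random_instance(rng, n=20)
        by = by.copy()
        by[7] += 10 * byse[7]
        e = est.mr_presso((bx, bxse, by, byse), n_sim=500, seed=3)
        assert 7 in e.extras["outlier_indices"]
        assert abs(e.beta - 0.2) < 2 * e.se
        assert e.extras["global_pval"] < 0.05

    def test_zero_simulations_is_config_error(self, rng):
        bx, bxse, by, byse = random_instance(rng, n=5)
        with pytest.raises(ValueError):
            est.mr_presso((bx, bxse, by, byse), n_sim=0)


class TestDivw:
    def test_reduces_to_ivw_without_exposure_noise(self, rng):
        bx, _, by, byse = random_instance(rng, n=15)
        zero = np.zeros(15)
        with np.errstate(all="ignore"):
            d = est.divw((bx, zero + 1e-300, by, byse))
        ref = est.ivw((bx, zero + 1e-300, by, byse), effects_model="fixed")
        assert d.beta == pytest.approx(ref.beta, rel=1e-12)

    def test_formula_oracle(self, rng):
        bx, bxse, by, byse = random_instance(rng, n=25)
        d = est.divw((bx, bxse, by, byse))
        # independent recomputation of the published point estimate
        oracle = (np.sum(bx * by / byse ** 2)
                  / np.sum((bx ** 2 - bxse ** 2) / byse ** 2))
        assert d.beta == pytest.approx(oracle, abs=1e-12)

    def test_less_biased_than_ivw_under_weak_instruments(self, rng):
        # mean F ~ 5, truth 0.1: dIVW should debias the IVW shrinkage
        reps, n = 100, 200
        bias_ivw, bias_divw = [], []
        for _ in range(reps):
            cfg = SimConfig(n_snps=n, target_mean_f=5.0, beta_em=0.0,
                            beta_mo=0.0, beta_eo_direct=0.1,
                            mediator_instrument_fraction=0.0,
                            seed=int(rng.integers(2**31)))
            arr = simulate_arrays(cfg)
            h = (arr["beta_exp"], arr["se_exp"], arr["beta_out"],
                 arr["se_out"])
            bias_ivw.append(est.ivw(h).beta - 0.1)
            try:
                bias_divw.append(est.divw(h).beta - 0.1)
            except est.WeakInstrumentSignal:
                pass
        assert abs(np.mean(bias_divw)) < abs(np.mean(bias_ivw))

    def test_pathological_weakness_signals(self):
        bx = np.array([0.01, -0.01, 0.02])
        bxse = np.array([0.5, 0.5, 0.5])
        with pytest.raises(est.WeakInstrumentSignal):
            est.divw((bx, bxse, np.zeros(3), np.ones(3)))


class TestConmix:
    def test_pure_component_recovered(self):
        n = 10
        bx = np.ones(n)
        by = np.full(n, 0.2)
        e = est.conmix((bx, np.full(n, 1e-4), by, np.full(n, 0.005)))
        assert e.beta == pytest.approx(0.2, abs=0.01)
        assert sorted(e.extras["valid_snps"]) == list(range(n))

    def test_two_cluster_contamination(self, rng):
        n = 30
        bx = np.ones(n)
        by = np.full(n, 0.2)
        invalid = np.arange(21, 30)
        by[invalid] = 1.0
        byse = np.full(n, 0.01)
        e = est.conmix((bx, np.full(n, 1e-4), by, byse))
        assert e.beta == pytest.approx(0.2, abs=0.02)
        assert set(e.extras["valid_snps"]) == set(range(21))

    def test_ci_widens_with_psi(self, rng):
        bx, bxse, by, byse = random_instance(rng, n=15)
        widths = []
        for psi in (1.0, 1.5, 3.0):
            e = est.conmix((bx, bxse, by, byse), psi_scale=psi)
            widths.append(e.ci_high - e.ci_low)
        assert widths[0] <= widths[1] <= widths[2]


class TestRaps:
    def test_concordant_with_ivw_on_clean_data(self, rng):
        bx, bxse, by, byse = random_instance(rng, n=50)
        r = est.raps((bx, bxse, by, byse))
        ref = est.ivw((bx, bxse, by, byse))
        assert abs(r.beta - ref.beta) < 2 * ref.se

    def test_l2_no_overdispersion_equals_ml(self, rng):
        bx, _, by, byse = random_instance(rng, n=15)
        tiny = np.full(15, 1e-12)
        r = est.raps((bx, tiny, by, byse), loss="l2", overdispersion=False)
        ml = est.maximum_likelihood((bx, tiny, by, byse))
        assert r.beta == pytest.approx(ml.beta, abs=1e-6)

    def test_huber_resists_gross_outliers(self, rng):
        reps = 60
        bias_raps, bias_ivw = [], []
        for _ in range(reps):
            bx, bxse, by, byse = random_instance(
                rng, n=40, beta=0.1, sy=0.005)
            by = by.copy()
            idx = rng.choice(40, 2, replace=False)  # 5% contamination
            by[idx] += 0.3
            bias_ivw.append(est.ivw((bx, bxse, by, byse)).beta - 0.1)
            bias_raps.append(est.raps((bx, bxse, by, byse)).beta - 0.1)
        assert abs(np.mean(bias_raps)) < abs(np.mean(bias_ivw))

    def test_unknown_loss_rejected(self, rng):
        bx, bxse, by, byse = random_instance(rng, n=5)
        with pytest.raises(ValueError):
            est.raps((bx, bxse, by, byse), loss="cauchy")


class TestCmlMa:
    def test_all_valid_concentrates_on_zero_invalid(self, rng):
        bx, bxse, by, byse = random_instance(rng, n=20)
        e = est.cml_ma((bx, bxse, by, byse), k_grid=range(0, 10))
        ml = est.maximum_likelihood((bx, bxse, by, byse))
        assert e.extras["k_best"] == 0
        assert e.beta == pytest.approx(ml.beta, abs=3 * ml.se / 10)

    def test_k_zero_equals_ml(self, rng):
        bx, bxse, by, byse = random_instance(rng, n=12)
        e = est.cml_ma((bx, bxse, by, byse), k_grid=[0])
        ml = est.maximum_likelihood((bx, bxse, by, byse))
        assert e.beta == pytest.approx(ml.beta, abs=1e-6)

    def test_planted_invalid_snps_selected(self, rng):
        hits = []
        for _ in range(10):
            bx, bxse, by, byse = random_instance(rng, n=30, sy=0.005)
            by = by.copy()
            idx = rng.choice(30, 3, replace=False)
            by[idx] += rng.choice([-1, 1], 3) * 0.2  # large offsets
            e = est.cml_ma((bx, bxse, by, byse), k_grid=range(0, 8))
            hits.append(e.extras["k_best"])
        # modal selected invalid-count is the planted 3
        assert np.bincount(hits).argmax() == 3


@pytest.mark.parametrize("method", ["ivw", "ml", "wm", "egger", "presso",
                                    "divw", "conmix", "raps", "cml"])
def test_exposure_rescaling_equivariance(method, rng):
    """Multiplying all exposure effects by c divides the estimate by c."""
    bx, bxse, by, byse = random_instance(rng, n=12)
    c = 2.5
    kwargs = {"wm": {"seed": 7, "n_boot": 50},
              "presso": {"seed": 7, "n_sim": 200},
              "cml": {"k_grid": range(0, 5)}}.get(method, {})
    fn = est.METHODS[method]
    a = fn((bx, bxse, by, byse), **kwargs)
    b = fn((c * bx, c * bxse, by, byse), **kwargs)
    assert b.beta == pytest.approx(a.beta / c, rel=1e-5, abs=1e-8)
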