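"""Reallocation validation, prediction, and the linear / MOVER-lognormal
difference estimators, cross-checked against Monte-Carlo oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import isotemporal as it
from isotemporal.coda import PART_NAMES, SequentialBinaryPartition
from isotemporal.model import ModelError
from isotemporal.substitution import ReallocationError, mover_lognormal_difference

SWAP = {"screen": -60.0, "physical_activity": 60.0}


class TestReallocationValidation:
    def test_swap_from_published_centre(self, centre):
        new = it.apply_reallocation(centre, it.Reallocation(SWAP))
        assert new["screen"] == pytest.approx(115.0)
        assert new["physical_activity"] == pytest.approx(176.9)
        for p in ("sleep", "quiet", "passive_transport", "school", "domestic_selfcare"):
            assert new[p] == pytest.approx(centre[p])
        assert new.values.sum() == pytest.approx(1440.0, abs=1e-9)

    def test_null_deltas_identity(self, centre):
        new = it.apply_reallocation(centre, it.Reallocation(np.zeros(7)))
        assert np.array_equal(new.values, centre.values)

    def test_overdraw_names_part_and_shortfall(self, centre):
        realloc = it.Reallocation({"quiet": -80.0, "sleep": 80.0}, cap=120)
        with pytest.raises(ReallocationError, match="negative value") as exc:
            it.apply_reallocation(centre, realloc)
        assert "quiet" in str(exc.value)
        assert "9.8" in str(exc.value)  # 80 - 70.2 min short

    def test_nonzero_net_sum_rejected(self):
        with pytest.raises(ReallocationError, match="net to zero"):
            it.Reallocation({"screen": -30.0, "sleep": 40.0})

    def test_cap_exceeded_rejected(self):
        with pytest.raises(ReallocationError, match="cap"):
            it.Reallocation({"screen": -90.0, "sleep": 90.0})
        # but a configured cap admits it
        it.Reallocation({"screen": -90.0, "sleep": 90.0}, cap=120.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=-59.0, max_value=59.0),
                    min_size=7, max_size=7),
           st.floats(min_value=0.5, max_value=30.0))
    def test_every_unbalanced_request_rejected(self, deltas, imbalance):
        deltas = np.asarray(deltas)
        deltas[0] = imbalance - deltas[1:].sum()  # force net sum = imbalance
        if abs(deltas[0]) > 60:
            deltas[0] = np.sign(deltas[0]) * 59.0
            deltas[1] += imbalance  # keep it unbalanced either way
            if abs(deltas[1]) > 60:
                return
        with pytest.raises(ReallocationError):
            it.Reallocation(deltas)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=6),
           st.floats(min_value=0.1, max_value=60.0))
    def test_every_overdraw_rejected(self, centre, part_idx, excess):
        take = min(centre.values[part_idx] + excess, 60.0)
        if take <= centre.values[part_idx]:
            return  # part too large to overdraw within the cap
        deltas = np.zeros(7)
        deltas[part_idx] = -take
        deltas[(part_idx + 1) % 7] = take
        with pytest.raises(ReallocationError, match="negative value"):
            it.apply_reallocation(centre, it.Reallocation(deltas))


class TestPrediction:
    def test_intercept_only_model(self, psych_model, centre, default_profile):
        m = psych_model
        m2 = it.FittedModel(
            outcome_name="flat", transform="identity",
            coefficients=np.r_[42.0, np.zeros(34)],
            covariance=np.zeros((35, 35)), residual_df=m.residual_df,
            sbp=m.sbp, favourable="higher", rss=m.rss, n_obs=m.n_obs)
        p = it.predict_outcome(m2, centre, default_profile)
        assert p.estimate == pytest.approx(42.0)
        assert p.se == 0.0

    def test_se_matches_monte_carlo_oracle(self, psych_model, centre,
                                           default_profile):
        """Contrast SE agrees within 2% with the sd of x'b over 100k draws of
        b ~ MVN(b_hat, V)."""
        p = it.predict_outcome(psych_model, centre, default_profile)
        rng = np.random.default_rng(77)
        draws = rng.multivariate_normal(
            psych_model.coefficients, psych_model.covariance, size=100_000,
            method="cholesky")
        x = it.build_design_row(it.ilr(centre, psych_model.sbp), default_profile)
        mc_sd = (draws @ x).std(ddof=1)
        assert p.se == pytest.approx(mc_sd, rel=0.02)

    def test_log_model_exponentiates(self, bodyfat_model, centre, default_profile):
        p = it.predict_outcome(bodyfat_model, centre, default_profile)
        assert p.raw_estimate == pytest.approx(np.exp(p.estimate))
        assert p.raw_ci[0] < p.raw_estimate < p.raw_ci[1]

    def test_zero_parts_imputed_before_prediction(self, psych_model,
                                                  default_profile):
        comp = it.close([700, 200, 140, 0, 40, 120, 240])
        p = it.predict_outcome(psych_model, comp, default_profile)
        imputed = it.replace_zeros_fixed(comp)
        p2 = it.predict_outcome(psych_model, imputed, default_profile)
        assert p.estimate == pytest.approx(p2.estimate)


class TestLinearDifference:
    def test_null_reallocation_zero_difference_zero_width(
            self, psych_model, centre, default_profile):
        est = it.estimate_difference_linear(
            psych_model, centre, centre, default_profile)
        assert est.difference == 0.0
        assert est.ci_low == est.ci_high == 0.0
        assert est.percent_difference == 0.0
        assert est.favourable is None

    def test_equals_prediction_difference_exactly(self, psych_model, centre,
                                                  default_profile):
        new = it.apply_reallocation(centre, it.Reallocation(SWAP))
        est = it.estimate_difference_linear(psych_model, centre, new,
                                            default_profile)
        p0 = it.predict_outcome(psych_model, centre, default_profile)
        p1 = it.predict_outcome(psych_model, new, default_profile)
        assert est.difference == pytest.approx(p1.estimate - p0.estimate,
                                               rel=1e-12, abs=1e-12)

    def test_reversal_antisymmetry(self, psych_model, centre, default_profile):
        new = it.apply_reallocation(centre, it.Reallocation(SWAP))
        fwd = it.estimate_difference_linear(psych_model, centre, new,
                                            default_profile)
        rev = it.estimate_difference_linear(psych_model, new, centre,
                                            default_profile)
        assert fwd.difference == pytest.approx(-rev.difference, rel=1e-12)
        assert fwd.ci_low == pytest.approx(-rev.ci_high, rel=1e-12)
        assert fwd.ci_high == pytest.approx(-rev.ci_low, rel=1e-12)

    def test_log_model_directed_to_lognormal_path(self, bodyfat_model, centre,
                                                  default_profile):
        with pytest.raises(ModelError, match="lognormal"):
            it.estimate_difference_linear(bodyfat_model, centre, centre,
                                          default_profile)

    def test_starting_composition_matters(self, psych_model, default_profile,
                                          centre):
        """With genuine second-order terms, the same reallocation from two
        starting compositions gives different differences."""
        assert np.any(psych_model.coefficients[7:28] != 0)
        other = it.close([650, 235, 56.9, 130.2, 35.8, 189.1, 143.0])
        realloc = it.Reallocation(SWAP)
        est_a = it.estimate_difference_linear(
            psych_model, centre, it.apply_reallocation(centre, realloc),
            default_profile)
        est_b = it.estimate_difference_linear(
            psych_model, other, it.apply_reallocation(other, realloc),
            default_profile)
        assert abs(est_a.difference - est_b.difference) > 1e-3


class TestMoverDifference:
    def test_null_reallocation_zero_difference_zero_width(
            self, bodyfat_model, centre, default_profile):
        est = it.estimate_difference_lognormal(
            bodyfat_model, centre, centre, default_profile)
        assert est.difference == 0.0
        assert est.ci_low == est.ci_high == 0.0
        assert est.favourable is None

    def test_identity_model_rejected(self, psych_model, centre, default_profile):
        with pytest.raises(ModelError, match="linear"):
            it.estimate_difference_lognormal(psych_model, centre, centre,
                                             default_profile)

    def test_interval_brackets_point_estimate(self, bodyfat_model, centre,
                                              default_profile):
        new = it.apply_reallocation(centre, it.Reallocation(SWAP))
        est = it.estimate_difference_lognormal(bodyfat_model, centre, new,
                                               default_profile)
        assert est.ci_low <= est.difference <= est.ci_high

    @pytest.mark.parametrize("r", [0.0, 0.6])
    def test_matches_simulation_percentiles(self, r):
        """MOVER limits for exp(y1)-exp(y0) agree with brute-force percentile
        limits from 200k correlated normal draws within 3% of the interval
        width."""
        y0, se0 = np.log(20.0), 0.05
        y1, se1 = np.log(19.0), 0.05
        df = 1637
        d, lo, hi = mover_lognormal_difference(y0, se0, y1, se1, r, df)
        rng = np.random.default_rng(123)
        cov = np.array([[se0**2, r * se0 * se1], [r * se0 * se1, se1**2]])
        draws = rng.multivariate_normal([y0, y1], cov, size=200_000,
                                        method="cholesky")
        diffs = np.exp(draws[:, 1]) - np.exp(draws[:, 0])
        p_lo, p_hi = np.percentile(diffs, [2.5, 97.5])
        width = p_hi - p_lo
        assert d == pytest.approx(np.exp(y1) - np.exp(y0))
        assert lo == pytest.approx(p_lo, abs=0.03 * width)
        assert hi == pytest.approx(p_hi, abs=0.03 * width)

    def test_taylor_limit_agrees_with_linear_scale(self):
        """For tiny effects and SEs, exp(y1)-exp(y0) ~ (y1-y0)*theta: the MOVER
        interval collapses onto the linear-contrast interval scaled by theta."""
        y0, y1, se = 1e-4, 3e-4, 1e-5
        d, lo, hi = mover_lognormal_difference(y0, se, y1, se, 0.0, 10_000)
        t = stats.t.ppf(0.975, 10_000)
        lin_half = t * np.sqrt(2) * se
        assert d == pytest.approx(y1 - y0, rel=1e-3)
        assert hi - lo == pytest.approx(2 * lin_half, rel=1e-3)


class TestPercentAndReport:
    def test_percent_difference_arithmetic(self, psych_model):
        est = it.SubstitutionEstimate(
            outcome_name="x", estimate_initial=20.0, ci_initial=(19, 21),
            estimate_new=19.2, ci_new=(18, 20), difference=-0.8,
            ci_low=-1.0, ci_high=-0.5, percent_difference=0.0, favourable=False)
        assert it.percent_difference(est) == pytest.approx(-4.0)

    def test_zero_baseline_undefined(self):
        est = it.SubstitutionEstimate(
            outcome_name="x", estimate_initial=0.0, ci_initial=(0, 0),
            estimate_new=1.0, ci_new=(0, 2), difference=1.0,
            ci_low=0.5, ci_high=1.5, percent_difference=0.0, favourable=True)
        with pytest.raises(ZeroDivisionError):
            it.percent_difference(est)

    def test_percent_sign_follows_difference(self, psych_model, centre,
                                             default_profile):
        new = it.apply_reallocation(centre, it.Reallocation(SWAP))
        est = it.estimate_difference_linear(psych_model, centre, new,
                                            default_profile)
        assert np.sign(est.percent_difference) == np.sign(est.difference)

    def test_favourable_direction_mapping(self, psych_model, bodyfat_model,
                                          centre, default_profile):
        new = it.apply_reallocation(centre, it.Reallocation(SWAP))
        report = it.substitution_report([psych_model, bodyfat_model], centre,
                                        it.Reallocation(SWAP), default_profile)
        psych = report["psychosocial"]
        bf = report["bodyfat"]
        assert psych.favourable == (psych.difference > 0)  # higher is better
        assert bf.favourable == (bf.difference < 0)        # lower is better


class TestBasisInvariance:
    def test_substitution_invariant_to_sbp(self, small_study, centre,
                                           default_profile):
        """Fitting the same data under two different ilr bases yields identical
        substitution estimates (the quadratic feature space is basis-free)."""
        _, data, _ = small_study
        new = it.apply_reallocation(centre, it.Reallocation(SWAP))
        rng = np.random.default_rng(2)
        estimates = []
        for sbp in (it.DEFAULT_SBP, SequentialBinaryPartition.random(rng),
                    SequentialBinaryPartition.random(rng)):
            m = it.fit_outcome_model(data[list(PART_NAMES)], data,
                                     data["psychosocial"], "psychosocial",
                                     sbp=sbp)
            estimates.append(it.estimate_difference_linear(
                m, centre, new, default_profile))
        ref = estimates[0]
        for est in estimates[1:]:
            assert est.difference == pytest.approx(ref.difference,
                                                   rel=1e-9, abs=1e-9)
            assert est.ci_low == pytest.approx(ref.ci_low, rel=1e-9, abs=1e-9)
            assert est.ci_high == pytest.approx(ref.ci_high, rel=1e-9, abs=1e-9)
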