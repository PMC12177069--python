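"""BH adjustment, subject/group biomarker models, diagnostics, feedback."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gaitdbs import stats
from gaitdbs.stats import (
    backward_select,
    bh_adjust,
    feedback_rank_model,
    fit_group_feature_model,
    fit_subject_phase_models,
    hemisphere_interaction_check,
    residual_diagnostics,
)
from gaitdbs.types import PHASES


def _bh_bruteforce(p):
    """Sort, scale by m/i, reverse cumulative min, cap at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    out_sorted = np.empty(m)
    cur = np.inf
    for i in range(m - 1, -1, -1):
        cur = min(cur, scaled[i])
        out_sorted[i] = min(cur, 1.0)
    out = np.empty(m)
    out[order] = out_sorted
    return out


class TestBhAdjust:
    def test_hand_example_all_equal_after_adjustment(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_hand_example_two_values(self):
        assert np.allclose(bh_adjust([0.005, 0.1]), [0.01, 0.1])

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 25))
            assert np.allclose(bh_adjust(p), _bh_bruteforce(p), atol=1e-14)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(size=10)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), ref, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


def _subject_table(n_trials=24, beta_ils=0.0, seed=0, wpi_noise=0.2):
    """Long feature table for one subject/site/band with known structure."""
    rng = np.random.default_rng(seed)
    rows = []
    feats = rng.standard_normal((n_trials, 4))
    wpi = 1.0 + beta_ils * feats[:, 3] + wpi_noise * rng.standard_normal(n_trials)
    for i in range(n_trials):
        for j, phase in enumerate(PHASES):
            rows.append(
                {
                    "subject_id": "S1",
                    "hemisphere": "left",
                    "site_or_pair": "GP",
                    "band": "beta",
                    "phase": phase,
                    "trial_id": f"t{i}",
                    "value": feats[i, j],
                    "wpi": wpi[i],
                }
            )
    return pd.DataFrame(rows)


class TestSubjectPhaseModels:
    def test_recovers_single_phase_effect(self):
        hits_true = hits_null = 0
        n_seeds = 40
        for seed in range(n_seeds):
            df = _subject_table(beta_ils=1.4, seed=seed)
            res = fit_subject_phase_models(df)
            ils = res[res["phase"] == "ILS"].iloc[0]
            ci = 1.96 * ils["se"]
            if abs(ils["estimate"] - 1.4) <= ci:
                hits_true += 1
            others = res[res["phase"] != "ILS"]
            if all(abs(r.estimate) <= 1.96 * r.se for r in others.itertuples()):
                hits_null += 1
        assert hits_true / n_seeds >= 0.90
        assert hits_null / n_seeds >= 0.75

    def test_null_fdr_controlled(self):
        """Across all-null models the adjusted-p<0.05 rate stays near alpha."""
        false_pos = total = 0
        for seed in range(200):
            df = _subject_table(beta_ils=0.0, seed=seed)
            res = fit_subject_phase_models(df)
            total += 1
            if (res["p_adj"] < 0.05).any():
                false_pos += 1
        assert false_pos / total <= 0.07

    def test_duplicated_phase_column_flagged(self):
        df = _subject_table(seed=1)
        dup = df[df["phase"] == "ILS"].copy()
        df.loc[df["phase"] == "CLS", "value"] = dup["value"].to_numpy()
        res = fit_subject_phase_models(df)
        assert (res["flag"] == "rank_deficient").all()

    def test_adjusted_at_least_raw(self):
        df = _subject_table(beta_ils=0.8, seed=2)
        res = fit_subject_phase_models(df)
        assert (res["p_adj"] >= res["p"] - 1e-12).all()


def _group_data(n_per=24, slope=0.0, seed=0, n_subjects=3, resid=0.15):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        intercept = 0.1 * rng.standard_normal()
        hemis = ("left", "right") if s < 2 else ("left",)
        for h in hemis:
            for i in range(n_per):
                wpi = rng.uniform(0.3, 1.6)
                val = intercept + slope * wpi + resid * rng.standard_normal()
                rows.append(
                    {
                        "subject_id": f"S{s}",
                        "hemisphere": h,
                        "wpi": wpi,
                        "value": val,
                    }
                )
    return pd.DataFrame(rows)


def _invert(df):
    # generator convention: value holds the feature, wpi the outcome
    return df


class TestGroupFeatureModel:
    def test_recovers_generative_slope(self):
        # outcome = wpi regressed on feature: construct wpi from feature
        rng = np.random.default_rng(0)
        hits = 0
        for seed in range(30):
            rows = []
            r2 = np.random.default_rng(seed)
            for s in range(3):
                b0 = 1.0 + 0.1 * r2.standard_normal()
                hemis = ("left", "right") if s < 2 else ("left",)
                for h in hemis:
                    for i in range(14):
                        f = r2.standard_normal()
                        w = b0 - 0.22 * f + 0.15 * r2.standard_normal()
                        rows.append({"subject_id": f"S{s}", "hemisphere": h,
                                     "value": f, "wpi": w})
            res = fit_group_feature_model(pd.DataFrame(rows))
            if abs(res.estimate + 0.22) <= 0.1:
                hits += 1
        assert hits / 30 >= 0.80

    def test_type_i_error_near_alpha(self):
        rejections = 0
        n_seeds = 150
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            rows = []
            for s in range(3):
                b0 = 1.0 + 0.1 * rng.standard_normal()
                hemis = ("left", "right") if s < 2 else ("left",)
                for h in hemis:
                    for i in range(14):
                        rows.append(
                            {
                                "subject_id": f"S{s}",
                                "hemisphere": h,
                                "value": rng.standard_normal(),
                                "wpi": b0 + 0.15 * rng.standard_normal(),
                            }
                        )
            res = fit_group_feature_model(pd.DataFrame(rows))
            if np.isfinite(res.lrt_p) and res.lrt_p < 0.05:
                rejections += 1
        assert rejections / n_seeds <= 0.08

    def test_too_few_observations_rejected(self):
        df = _group_data(n_per=2)
        with pytest.raises(ValueError):
            fit_group_feature_model(df.head(10))

    def test_balanced_hemispheres_no_spurious_main_effect(self):
        rng = np.random.default_rng(5)
        rows = []
        for s in range(3):
            for h in ("left", "right"):
                for i in range(12):
                    f = rng.standard_normal()
                    rows.append({"subject_id": f"S{s}", "hemisphere": h,
                                 "value": f, "wpi": 1.0 - 0.2 * f
                                 + 0.1 * rng.standard_normal()})
        res = fit_group_feature_model(pd.DataFrame(rows))
        assert res.estimate == pytest.approx(-0.2, abs=0.08)


class TestHemisphereInteraction:
    def _data(self, slope_l, slope_r, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(3):
            for h, slope in (("left", slope_l), ("right", slope_r)):
                for i in range(14):
                    f = rng.standard_normal()
                    rows.append({"subject_id": f"S{s}", "hemisphere": h,
                                 "value": f,
                                 "wpi": 1.0 + slope * f
                                 + 0.15 * rng.standard_normal()})
        return pd.DataFrame(rows)

    def test_same_slopes_interaction_not_preferred(self):
        wins = 0
        for seed in range(20):
            daic, p = hemisphere_interaction_check(self._data(-0.2, -0.2, seed))
            if daic > 0:
                wins += 1
        assert wins >= 12  # majority of seeds

    def test_opposite_slopes_detected(self):
        detected = 0
        for seed in range(20):
            _, p = hemisphere_interaction_check(self._data(-0.3, 0.3, seed))
            if p < 0.05:
                detected += 1
        assert detected >= 18

    def test_order_invariance(self):
        df = self._data(-0.2, -0.1, 3)
        a = hemisphere_interaction_check(df)
        b = hemisphere_interaction_check(df.sample(frac=1, random_state=0))
        assert a[0] == pytest.approx(b[0], abs=1e-6)

    def test_unilateral_data_rejected(self):
        df = self._data(-0.2, -0.2, 1)
        with pytest.raises(ValueError):
            hemisphere_interaction_check(df[df["hemisphere"] == "left"])


class TestBackwardSelect:
    def _data(self, true_cols, seed=0, n=70):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 5))
        w = 1.0 + 0.15 * rng.standard_normal(n)
        for j in true_cols:
            w = w + 0.5 * X[:, j]
        df = pd.DataFrame(X, columns=[f"f{j}" for j in range(5)])
        df["wpi"] = w
        df["subject_id"] = np.repeat([f"S{k}" for k in range(3)],
                                     [n - 2 * (n // 3), n // 3, n // 3])
        df["hemisphere"] = "left"
        return df

    def test_single_true_feature_retained(self):
        hits = 0
        for seed in range(15):
            kept = backward_select(self._data([2], seed), [f"f{j}" for j in range(5)])
            if "f2" in kept:
                hits += 1
        assert hits >= 13

    def test_all_null_mostly_empty(self):
        empties = 0
        for seed in range(15):
            kept = backward_select(self._data([], seed), [f"f{j}" for j in range(5)])
            if not kept:
                empties += 1
        assert empties >= 10

    def test_single_feature_reduces_to_lrt(self):
        kept = backward_select(self._data([0], 3), ["f0"])
        assert kept == ["f0"]


class TestDiagnostics:
    def test_gaussian_residuals_pass(self):
        ps = []
        for seed in range(100):
            r = np.random.default_rng(seed).standard_normal(70)
            ps.append(residual_diagnostics(r).shapiro_p)
        # p-values should be roughly uniform; KS against U(0,1)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_exponential_residuals_rejected(self):
        rejected = 0
        for seed in range(60):
            r = np.random.default_rng(seed).exponential(size=70)
            if residual_diagnostics(r).shapiro_p < 0.05:
                rejected += 1
        assert rejected / 60 >= 0.95

    def test_symmetric_residuals_low_skewness(self):
        sk = [
            residual_diagnostics(
                np.random.default_rng(s).uniform(-1, 1, 100)
            ).skewness
            for s in range(40)
        ]
        assert abs(np.mean(sk)) < 0.2

    def test_kurtosis_pearson_convention(self):
        r = np.random.default_rng(0).standard_normal(4000)
        assert residual_diagnostics(r).kurtosis == pytest.approx(3.0, abs=0.2)

    def test_small_sample_descriptive_only(self):
        rep = residual_diagnostics(np.array([0.1, -0.2, 0.3, 0.0, 0.1]))
        assert np.isnan(rep.shapiro_p) and rep.normality_ok is None


class TestFeedbackModel:
    def _table(self, concordance_exact=True, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(3):
            for v in range(4):
                n = 4
                wr = rng.permutation(n) + 1
                fr = wr if concordance_exact else rng.permutation(n) + 1
                for w, f in zip(wr, fr):
                    rows.append({"subject_id": f"S{s}", "visit_id": f"S{s}v{v}",
                                 "wpi_rank": int(w), "feedback_rank": int(f)})
        return pd.DataFrame(rows)

    def test_identity_ranks_slope_one(self):
        res = feedback_rank_model(self._table(True))
        assert res.slope == pytest.approx(1.0, abs=1e-6)
        assert res.p < 1e-6

    def test_independent_ranks_ci_covers_zero(self):
        covered = 0
        for seed in range(30):
            res = feedback_rank_model(self._table(False, seed))
            if abs(res.slope) <= 1.96 * res.se:
                covered += 1
        assert covered >= 27

    def test_constant_ranks_rejected(self):
        df = pd.DataFrame(
            {"subject_id": ["S1"] * 4, "wpi_rank": [1, 1, 1, 1],
             "feedback_rank": [1, 1, 1, 1]}
        )
        with pytest.raises(ValueError):
            feedback_rank_model(df)

    def test_generator_concordance_gives_positive_slope(self, small_cohort):
        from gaitdbs.synthetic import simulate_feedback

        positives = 0
        for seed in range(20):
            fb = simulate_feedback(small_cohort, 0.8, seed)
            res = feedback_rank_model(fb)
            if res.slope > 0:
                positives += 1
        assert positives >= 19
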