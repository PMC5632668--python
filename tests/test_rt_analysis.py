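import numpy as np
import pandas as pd
import pytest
from scipy import stats

from changescope.design_balancer import CONDITIONS
from changescope.errors import (
    FitError,
    InvalidParameterError,
    NoDataError,
    UnbalancedDesignError,
)
from changescope.image_metrics import ChangeRegion
from changescope.rt_analysis import (
    TrialTable,
    classify_trial,
    exclusion_filter,
    fit_ig_cdf,
    fit_rt_glm,
    ks_nonnormality,
    proportions_anova,
)
from changescope.synthetic_data import RtGenConfig, simulate_rts, stub_design

from conftest import PAPER_DEG_PER_PX


def make_table(n_subjects=60, per_cell=9, seed=0, n_nonhit=0, mu=3.0, lam=16.0):
    """Balanced trial table with iid inverse-Gaussian RTs (null data)."""
    rng = np.random.default_rng(seed)
    n = n_subjects * len(CONDITIONS) * per_cell
    subj = np.repeat([f"sub{i:03d}" for i in range(n_subjects)], len(CONDITIONS) * per_cell)
    cond = np.tile(np.repeat(CONDITIONS, per_cell), n_subjects)
    j = np.tile(np.arange(per_cell), n_subjects * len(CONDITIONS))
    rt = np.minimum(stats.invgauss.rvs(mu / lam, scale=lam, size=n, random_state=rng), 239.0)
    outcome = np.full(n, "hit", dtype=object)
    responded = np.ones(n, dtype=bool)
    k = np.arange(n)
    miss = (k < n_nonhit) & (k % 2 == 0)
    fa = (k < n_nonhit) & (k % 2 == 1)
    outcome[miss], outcome[fa] = "miss", "false_alarm"
    responded[miss] = False
    rt[miss] = 240.0
    hi_ce = np.char.startswith(cond.astype(str), "high")
    hi_si = np.char.endswith(cond.astype(str), "highSI")
    df = pd.DataFrame(
        {
            "subject_id": subj,
            "pair_id": [f"{s}_{c}_{jj}" for s, c, jj in zip(subj, cond, j)],
            "condition": cond,
            "rt_s": rt,
            "responded": responded,
            "outcome": outcome,
            "ce_change": np.where(hi_ce, 1.5, 0.5) + 0.001 * j,
            "si_change": np.where(hi_si, 1.5, 0.5) + 0.001 * j,
        }
    )
    return TrialTable(df)


class TestClassifyTrial:
    geom = None

    def setup_method(self):
        from changescope.image_metrics import ImageGeometry

        self.geom = ImageGeometry(481, 321, PAPER_DEG_PER_PX)
        mask = np.zeros((321, 481), dtype=bool)
        mask[100, 100] = True
        self.region = ChangeRegion(mask=mask)

    def test_click_on_region_pixel_is_hit(self):
        assert classify_trial(True, (100.0, 100.0), self.region, self.geom) == "hit"

    def test_radius_boundary(self):
        d_in = 0.74 / PAPER_DEG_PER_PX  # px distance at 0.74 deg
        d_out = 0.76 / PAPER_DEG_PER_PX
        assert classify_trial(True, (100.0 + d_in, 100.0), self.region, self.geom) == "hit"
        assert (
            classify_trial(True, (100.0 + d_out, 100.0), self.region, self.geom)
            == "false_alarm"
        )

    def test_no_response_is_miss(self):
        assert classify_trial(False, None, self.region, self.geom) == "miss"

    def test_out_of_bounds_click_false_alarm(self):
        assert classify_trial(True, (-5.0, 10.0), self.region, self.geom) == "false_alarm"


class TestExclusionFilter:
    def test_paper_scale_bookkeeping(self):
        table = make_table(n_nonhit=61)  # 2160 trials, 61 non-hits
        assert len(table) == 2160
        filtered, summary = exclusion_filter(table)
        assert summary["n_retained"] == 2099
        assert summary["n_excluded"] == 61
        assert len(filtered) == 2099

    def test_idempotent(self):
        table = make_table(n_subjects=6, n_nonhit=10)
        once, _ = exclusion_filter(table)
        twice, summary = exclusion_filter(once)
        assert len(twice) == len(once)
        assert summary["n_excluded"] == 0

    def test_counts_match_brute_force_tally(self):
        table = make_table(n_subjects=10, n_nonhit=17)
        filtered, summary = exclusion_filter(table)
        for cond in CONDITIONS:
            brute = sum(
                1
                for r in table.data.to_dict("records")
                if r["condition"] == cond and r["outcome"] == "hit"
            )
            assert summary["retained_by_condition"][cond] == brute

    def test_all_hit_identity(self):
        table = make_table(n_subjects=4)
        filtered, summary = exclusion_filter(table)
        assert len(filtered) == len(table)

    def test_empty_result_raises(self):
        table = make_table(n_subjects=2, per_cell=1, n_nonhit=8)
        with pytest.raises(NoDataError):
            exclusion_filter(table)


class TestProportionsAnova:
    def test_paper_degrees_of_freedom(self):
        table = make_table(n_subjects=60, n_nonhit=40)
        out = proportions_anova(table)  # default "cells" convention
        assert (out["false_alarm"]["df1"], out["false_alarm"]["df2"]) == (3, 236)

    def test_rm_convention_df(self):
        table = make_table(n_subjects=60, n_nonhit=40)
        out = proportions_anova(table, convention="rm")
        assert (out["miss"]["df1"], out["miss"]["df2"]) == (3, 177)

    def test_identical_proportions_zero_f(self):
        table = make_table(n_subjects=8)  # all hits everywhere
        out = proportions_anova(table)
        assert out["false_alarm"]["F"] == 0.0
        assert out["miss"]["F"] == 0.0

    def test_missing_cell_unbalanced(self):
        table = make_table(n_subjects=4)
        df = table.data
        df = df[~((df.subject_id == "sub000") & (df.condition == CONDITIONS[0]))]
        with pytest.raises(UnbalancedDesignError):
            proportions_anova(TrialTable(df))

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(1)
        reps, rejections = 1000, 0
        n, k, per_cell = 60, 4, 9
        for _ in range(reps):
            # null: identical binomial miss probability in every condition
            props = rng.binomial(per_cell, 0.1, size=(n, k)) / per_cell
            groups = [props[:, j] for j in range(k)]
            _, p = stats.f_oneway(*groups)
            rejections += p < 0.05
        assert 0.025 <= rejections / reps <= 0.08


class TestKsNonnormality:
    def test_d_bounded(self):
        rng = np.random.default_rng(0)
        d, p = ks_nonnormality(rng.normal(5, 1, 200))
        assert 0.0 <= d <= 1.0

    def test_calibrated_on_normal_data(self):
        rng = np.random.default_rng(2)
        hits = sum(
            ks_nonnormality(rng.normal(3, 1, 150))[1] < 0.05 for _ in range(200)
        )
        assert hits / 200 <= 0.10

    def test_power_on_skewed_ig_sample(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = stats.invgauss.rvs(3.0 / 4.0, scale=4.0, size=2000, random_state=rng)
            _, p = ks_nonnormality(x)
            assert p < 0.001

    def test_degenerate_input(self):
        with pytest.raises(InvalidParameterError):
            ks_nonnormality(np.full(50, 2.0))


class TestFitRtGlm:
    def test_residual_df_paper_scale(self):
        table = make_table(n_nonhit=61)
        filtered, _ = exclusion_filter(table)
        res = fit_rt_glm(filtered)
        assert res.df_resid == 2095  # 2099 hits minus 4 regressors

    def test_reordering_bit_identical(self):
        table = make_table(n_subjects=12, seed=5)
        res1 = fit_rt_glm(table)
        shuffled = TrialTable(
            table.data.sample(frac=1.0, random_state=99).reset_index(drop=True)
        )
        res2 = fit_rt_glm(shuffled)
        for k in res1.coefficients:
            assert res1.coefficients[k] == res2.coefficients[k]  # bitwise

    def test_type_one_error_per_regressor(self):
        reps = 500
        rej = {"ce": 0, "si": 0, "ce_x_si": 0}
        for seed in range(reps):
            table = make_table(n_subjects=20, per_cell=6, seed=seed)
            res = fit_rt_glm(table)
            for k in rej:
                rej[k] += res.p_values[k] < 0.05
        for k, cnt in rej.items():
            assert 0.02 <= cnt / reps <= 0.09, (k, cnt / reps)

    def test_recovery_on_coactivation_data(self):
        design, scores = stub_design(seed=1)
        all_sig = 0
        reps = 50
        for seed in range(reps):
            cfg = RtGenConfig(seed=seed, architecture="coactivation")
            table, _ = simulate_rts(design, cfg, scores=scores)
            filtered, _ = exclusion_filter(table)
            res = fit_rt_glm(filtered)
            ok = all(
                res.coefficients[k] < 0 and res.p_values[k] < 0.05
                for k in ("ce", "si", "ce_x_si")
            )
            all_sig += ok
        assert all_sig / reps >= 0.95

    def test_ranked_coding_recovers_graded_effects(self):
        # RT mean falls continuously with the ce/si scores (log-linear)
        rng = np.random.default_rng(17)
        n = 1200
        ce = rng.uniform(0, 1, n)
        si = rng.uniform(0, 1, n)
        mu = np.exp(1.6 - 0.8 * ce - 0.5 * si)
        lam = 25.0
        rt = stats.invgauss.rvs(mu / lam, scale=lam, random_state=rng)
        cond = np.where(
            ce > np.median(ce), "high", "low"
        ).astype(object) + np.where(si > np.median(si), "CE-highSI", "CE-lowSI")
        df = pd.DataFrame(
            {
                "subject_id": np.repeat([f"s{i}" for i in range(20)], n // 20),
                "pair_id": [f"p{i}" for i in range(n)],
                "condition": cond,
                "rt_s": rt,
                "responded": True,
                "outcome": "hit",
                "ce_change": ce,
                "si_change": si,
            }
        )
        res = fit_rt_glm(TrialTable(df), coding="ranked")
        assert res.coding == "ranked"
        assert res.coefficients["ce"] < 0 and res.p_values["ce"] < 0.05
        assert res.coefficients["si"] < 0 and res.p_values["si"] < 0.05

    def test_constant_factor_rejected(self):
        table = make_table(n_subjects=4)
        df = table.data[table.data.condition == "lowCE-lowSI"]
        with pytest.raises(InvalidParameterError):
            fit_rt_glm(TrialTable(df))

    def test_links_selectable(self):
        table = make_table(n_subjects=10)
        for link in ("log", "identity", "canonical"):
            res = fit_rt_glm(table, link=link)
            assert res.link == link
            assert res.df_resid == len(table) - 4


class TestFitIgCdf:
    def test_parameter_recovery(self):
        mu_true, lam_true = 3.0, 12.0
        errs_mu, errs_lam = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = stats.invgauss.rvs(
                mu_true / lam_true, scale=lam_true, size=500, random_state=rng
            )
            fit = fit_ig_cdf(x)
            errs_mu.append(abs(fit.mean / mu_true - 1))
            errs_lam.append(abs(fit.shape / lam_true - 1))
        assert np.median(errs_mu) < 0.10
        assert np.median(errs_lam) < 0.10

    def test_r_squared_quality_bar(self):
        good = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            x = stats.invgauss.rvs(0.25, scale=12.0, size=500, random_state=rng)
            good += fit_ig_cdf(x).r_squared >= 0.97
        assert good >= 95

    def test_shifted_variant_recovers_shift(self):
        rng = np.random.default_rng(7)
        x = 2.0 + stats.invgauss.rvs(0.2, scale=10.0, size=2000, random_state=rng)
        fit = fit_ig_cdf(x, shifted=True)
        assert fit.shift == pytest.approx(2.0, abs=0.4)
        assert fit.shift < x.min()

    def test_constant_input_raises(self):
        with pytest.raises(FitError):
            fit_ig_cdf(np.full(50, 3.0))

    def test_too_small_sample(self):
        with pytest.raises(InvalidParameterError):
            fit_ig_cdf(np.arange(1, 11))
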