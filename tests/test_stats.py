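import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats
from scipy.special import expit

from seltrack.stats import (
    binned_snr_slopes,
    dunn_posthoc,
    fit_rd_model,
    kruskal_dunn,
    pathway_summary,
    rd_snr_profile,
    si_bin_edges,
    validate_trial_table,
)


def generative_table(
    n_subjects=14,
    n_trials=160,
    seed=0,
    si_coef=0.1,
    gv_coef=-0.004,
    snr_coef=0.0,
    noise=0.03,
    gv_interaction=0.0,
):
    """Trial table with known generative coefficients for recovery tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        ths = rng.normal(-6, 1)
        offset = rng.normal(0, 0.02)
        snrs = rng.uniform(-12, 4, n_trials)
        for snr in snrs:
            si = float(expit(0.8 * (snr - ths)))
            effort = float(np.clip(expit(-(snr + 2) / 2) + rng.normal(0, 0.15), 0, 1))
            gv = 30 * (1 - 0.8 * effort) + rng.normal(0, 1)
            hr = rng.choice([0, 1 / 3, 2 / 3, 1.0])
            slope_gv = gv_coef + gv_interaction * (snr + 12) / 16
            rd = (
                si_coef * si + slope_gv * gv + snr_coef * snr + offset
                + rng.normal(0, noise)
            )
            rows.append(
                dict(subject=f"S{s:02d}", snr_db=snr, si=si,
                     ceiling_flag=si > 0.93, gv=gv, hr=hr,
                     rT=rd, rM=0.0, rD=rd, noise_type="babble")
            )
    return pd.DataFrame(rows)


class TestFitRdModel:
    def test_recovers_generative_signs(self):
        table = generative_table(seed=1)
        res = fit_rd_model(table, condition="all")
        assert res.effect("si").estimate > 0 and res.effect("si").p < 0.05
        assert res.effect("gv").estimate < 0 and res.effect("gv").p < 0.05

    def test_mediated_snr_not_significant(self):
        """SNR routed only through SI and effort leaves no unique SNR effect."""
        table = generative_table(seed=2)
        res = fit_rd_model(table, condition="below-ceiling")
        assert res.effect("snr_db").p > 0.05

    def test_pure_noise_lrt_not_significant(self):
        rng = np.random.default_rng(3)
        table = generative_table(seed=3, si_coef=0.0, gv_coef=0.0, noise=0.05)
        table["rD"] = rng.normal(0, 0.05, len(table))
        res = fit_rd_model(table, condition="all")
        assert res.lr_p_vs_null > 0.05

    def test_ceiling_condition_partitions_rows(self):
        table = generative_table(seed=4, n_subjects=4, n_trials=60)
        below = fit_rd_model(table, condition="below-ceiling")
        at = fit_rd_model(table, condition="at-ceiling")
        assert below.n_obs + at.n_obs == len(table)

    def test_constant_si_dropped_at_ceiling(self):
        table = generative_table(seed=5, n_subjects=4, n_trials=60)
        table.loc[table["ceiling_flag"], "si"] = 0.95
        res = fit_rd_model(table, condition="at-ceiling")
        assert "si" not in res.fixed_effects

    def test_collinear_predictors_rejected(self):
        table = generative_table(seed=6, n_subjects=3, n_trials=40)
        table["gv"] = 2.0 * table["snr_db"]  # exact collinearity after z-scoring
        with pytest.raises(ValueError, match="variance inflation"):
            fit_rd_model(table, predictors=["snr_db", "gv"], condition="all")

    def test_missing_rd_rejected(self):
        table = generative_table(seed=7, n_subjects=2, n_trials=10)
        table.loc[0, "rD"] = np.nan
        with pytest.raises(ValueError, match="missing rD"):
            validate_trial_table(table)


class TestBinnedSlopes:
    def test_sign_flip_across_si_bins(self):
        """Positive SNR coupling at low SI, negative at ceiling."""
        rng = np.random.default_rng(8)
        rows = []
        for s in range(6):
            for snr in rng.uniform(-12, 4, 120):
                si = float(expit(0.8 * (snr + 6)))
                ceiling = si > 0.9
                slope = -0.01 if ceiling else 0.01 * (1 - si)
                rd = slope * snr + rng.normal(0, 0.01)
                rows.append(dict(subject=f"S{s}", snr_db=snr, si=si,
                                 ceiling_flag=ceiling, gv=0.0, hr=0.0,
                                 rT=rd, rM=0.0, rD=rd, noise_type="babble"))
        table = pd.DataFrame(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            slopes = binned_snr_slopes(table, n_si_bins=4)
        first = slopes.iloc[0]
        ceil_row = slopes[slopes["bin"] == "ceiling"].iloc[0]
        assert first["slope"] > 0
        assert ceil_row["slope"] < 0

    def test_no_coupling_rarely_significant(self):
        rng = np.random.default_rng(9)
        table = generative_table(seed=9, si_coef=0.0, gv_coef=0.0, noise=0.05,
                                 n_subjects=6, n_trials=80)
        table["rD"] = rng.normal(0, 0.05, len(table))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            slopes = binned_snr_slopes(table, n_si_bins=4)
        assert slopes["significant"].sum() <= 1

    def test_single_bin_matches_global_slope(self):
        table = generative_table(seed=10, n_subjects=5, n_trials=80,
                                 si_coef=0.0, gv_coef=0.0, snr_coef=0.005)
        table["ceiling_flag"] = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            slopes = binned_snr_slopes(table, n_si_bins=1)
        assert len(slopes) == 1
        assert slopes.iloc[0]["slope"] == pytest.approx(0.005, rel=0.2)

    def test_bin_edges_partition_range(self):
        edges = si_bin_edges(0.96, 6)
        assert edges[0] == 0.0 and edges[-1] == pytest.approx(0.96)
        assert len(edges) == 7
        assert np.all(np.diff(edges) > 0)


class TestKruskalDunn:
    def test_null_calibration(self):
        """Omnibus p-values are ~uniform when all groups share a distribution."""
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(300):
            vals = rng.standard_normal(60)
            groups = np.repeat([0, 1 / 3, 2 / 3, 1.0], 15)
            p, _ = kruskal_dunn(vals, groups)
            pvals.append(p)
        ks = sp_stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(12)
        vals = np.concatenate([
            rng.normal(0, 1, 40), rng.normal(0, 1, 40), rng.normal(3, 1, 40)
        ])
        groups = np.repeat(["a", "b", "c"], 40)
        p, pairs = kruskal_dunn(vals, groups)
        assert p < 0.001
        sig = pairs[pairs["p_corrected"] < 0.05]
        assert set(sig["group_a"]) | set(sig["group_b"]) >= {"c"}
        ab = pairs[(pairs["group_a"] == "a") & (pairs["group_b"] == "b")]
        assert float(ab["p_corrected"].iloc[0]) > 0.05

    def test_identical_groups_capped_at_one(self):
        vals = np.concatenate([np.arange(10.0), np.arange(10.0)])
        groups = np.repeat(["a", "b"], 10)
        _, pairs = kruskal_dunn(vals, groups)
        assert float(pairs["p_corrected"].iloc[0]) == 1.0

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            kruskal_dunn(np.ones(20), np.repeat(["a", "b"], 10))

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="groups"):
            kruskal_dunn(np.arange(10.0), np.repeat("a", 10))


class TestPathwaySummary:
    def test_opposing_pathways_on_generative_table(self):
        table = generative_table(seed=13, gv_coef=-0.001, gv_interaction=-0.006)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = pathway_summary(table)
        assert rep.si_snr_positive
        assert rep.gv_snr_positive
        assert rep.rd_si_positive_weakening
        assert rep.rd_gv_negative_strengthening
        assert rep.opposing_pathways_hold

    def test_constant_effort_ablation(self):
        """Without an effort pathway, GV neither responds to SNR nor predicts rD."""
        rng = np.random.default_rng(14)
        table = generative_table(seed=14, gv_coef=0.0)
        table["gv"] = rng.normal(20, 2, len(table))  # effort decoupled
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = pathway_summary(table)
        assert not rep.gv_snr_positive
        assert abs(rep.rd_on_gv_by_snr_bin["slope"]).max() < 0.01

    def test_constant_si_excluded_with_notice(self):
        table = generative_table(seed=15, n_subjects=4, n_trials=60)
        table["si"] = 0.5
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = pathway_summary(table)
        assert any("SI constant" in n for n in rep.notes)
        assert len(rep.rd_on_si_by_snr_bin) == 0


class TestProfile:
    def test_rd_profile_locates_peak(self):
        rng = np.random.default_rng(16)
        snr = rng.uniform(-12, 4, 2000)
        rd = -((snr + 3.0) ** 2) / 100 + rng.normal(0, 0.02, len(snr))
        table = pd.DataFrame(
            dict(subject="S0", snr_db=snr, si=0.5, ceiling_flag=False,
                 gv=0.0, hr=0.0, rT=rd, rM=0.0, rD=rd, noise_type="babble")
        )
        prof = rd_snr_profile(table, n_bins=8)
        peak = prof.loc[prof["rd_mean"].idxmax(), "snr_center"]
        assert -5.5 < peak < -0.5


class TestDunnDirect:
    def test_two_group_dunn_matches_normal_approximation(self):
        """Dunn z for two groups equals the rank-sum z statistic."""
        rng = np.random.default_rng(17)
        a, b = rng.normal(0, 1, 25), rng.normal(1, 1, 25)
        vals = np.concatenate([a, b])
        groups = np.repeat(["a", "b"], 25)
        pairs = dunn_posthoc(vals, groups)
        z = float(pairs["z"].iloc[0])
        # independent oracle: standardized mean-rank difference
        ranks = sp_stats.rankdata(vals)
        se = np.sqrt(50 * 51 / 12 * (1 / 25 + 1 / 25))
        z_expected = (ranks[:25].mean() - ranks[25:].mean()) / se
        assert z == pytest.approx(z_expected, abs=1e-9)
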