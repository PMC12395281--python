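"""Mixed-effects statistical layer for the selective-tracking analysis.

The central question is how selective neural tracking rD relates to SNR,
intelligibility (SI), gaze velocity (GV, inversely indexing attentional
effort) and behavioral hit rate (HR).  The layer provides:

* linear mixed-effects (LME) models of rD with subject random effects,
  fitted separately for below-ceiling and at-ceiling trials;
* per-SI-bin LME slopes of rD on SNR (the sign-flip analysis);
* Kruskal-Wallis omnibus over HR groups with Bonferroni-corrected Dunn
  post hoc comparisons;
* a two-pathway mediation summary testing whether SNR acts on rD through
  SI (positive pathway) and effort/GV (negative pathway), leaving no
  independent SNR contribution.

Model fitting delegates to statsmodels' REML MixedLM; predictors are
z-scored within the analysis set so fixed effects are comparable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
import statsmodels.formula.api as smf

TRIAL_TABLE_COLUMNS = [
    "subject", "snr_db", "si", "ceiling_flag", "gv", "hr",
    "rT", "rM", "rD", "noise_type",
]


def validate_trial_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the per-trial table contract: no missing rD, SI in [0, 1]."""
    missing = [c for c in ("subject", "snr_db", "si", "rD") if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    if table["rD"].isna().any():
        raise ValueError("trial table contains missing rD values")
    if ((table["si"] < 0) | (table["si"] > 1)).any():
        raise ValueError("si must lie in [0, 1]")
    return table


@dataclass
class FixedEffect:
    name: str
    estimate: float
    se: float
    t: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass
class LMEResult:
    """Summary of one mixed-effects fit."""

    fixed_effects: dict[str, FixedEffect]
    random_intercept_var: float
    adjusted_r2: float
    lr_p_vs_null: float
    n_obs: int
    formula: str
    random_slopes: dict[str, float] = field(default_factory=dict)
    combined_slopes: dict[str, float] = field(default_factory=dict)

    def effect(self, name: str) -> FixedEffect:
        return self.fixed_effects[name]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 1e-12 else x - x.mean()


def _check_collinearity(df: pd.DataFrame, predictors: list[str]) -> None:
    if len(predictors) < 2:
        return
    X = df[predictors].to_numpy()
    corr = np.corrcoef(X, rowvar=False)
    if np.linalg.matrix_rank(corr, tol=1e-8) < len(predictors):
        vifs = {}
        for j, p in enumerate(predictors):
            others = np.delete(X, j, axis=1)
            beta, *_ = np.linalg.lstsq(
                np.column_stack([np.ones(len(X)), others]), X[:, j], rcond=None
            )
            resid = X[:, j] - np.column_stack([np.ones(len(X)), others]) @ beta
            r2 = 1 - resid.var() / X[:, j].var()
            vifs[p] = float("inf") if r2 >= 1 else 1.0 / (1.0 - r2)
        raise ValueError(f"rank-deficient predictors; variance inflation factors: {vifs}")


def _fit_mixedlm(
    df: pd.DataFrame,
    response: str,
    predictors: list[str],
    re_formula: str | None = None,
    do_lrt: bool = True,
) -> LMEResult:
    rhs = " + ".join(predictors) if predictors else "1"
    formula = f"{response} ~ {rhs}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["subject"], re_formula=re_formula)
        fit = model.fit(reml=True)

        def wald_p() -> float:
            # joint Wald chi2 on the predictor coefficients
            wald = float(np.sum((fit.fe_params[predictors] / fit.bse_fe[predictors]) ** 2))
            return float(sp_stats.chi2.sf(wald, df=len(predictors)))

        # likelihood-ratio test vs the intercept-only model needs ML fits;
        # boundary variance estimates can make those degenerate, in which
        # case the joint Wald test substitutes
        lr_p = float("nan")
        if predictors and do_lrt:
            try:
                ml_full = smf.mixedlm(formula, df, groups=df["subject"],
                                      re_formula=re_formula).fit(reml=False)
                ml_null = smf.mixedlm(f"{response} ~ 1", df, groups=df["subject"],
                                      re_formula=re_formula).fit(reml=False)
                lr = 2 * (ml_full.llf - ml_null.llf)
                lr_p = (
                    float(sp_stats.chi2.sf(max(lr, 0.0), df=len(predictors)))
                    if np.isfinite(lr)
                    else wald_p()
                )
            except (np.linalg.LinAlgError, ValueError):
                lr_p = wald_p()
        elif predictors:
            lr_p = wald_p()

    fe = {}
    for name in fit.fe_params.index:
        fe[name] = FixedEffect(
            name=name,
            estimate=float(fit.fe_params[name]),
            se=float(fit.bse_fe[name]),
            t=float(fit.tvalues[name]),
            p=float(fit.pvalues[name]),
        )
    y = df[response].to_numpy()
    try:
        fitted = fit.fittedvalues.to_numpy()
    except (ValueError, np.linalg.LinAlgError):
        # singular random-effect covariance (variance ~ 0): fixed part only
        fitted = np.asarray(fit.model.exog) @ np.asarray(fit.fe_params)
    resid = y - fitted
    r2 = 1 - resid.var() / y.var() if y.var() > 0 else float("nan")
    k = len(predictors)
    n = len(df)
    adj_r2 = 1 - (1 - r2) * (n - 1) / max(n - k - 1, 1)

    random_slopes: dict[str, float] = {}
    combined: dict[str, float] = {}
    try:
        random_effects = fit.random_effects
    except (ValueError, np.linalg.LinAlgError):
        random_effects = {}
    if re_formula and re_formula != "1":
        slope_name = re_formula.lstrip("~ ").strip()
        for grp, re_vals in random_effects.items():
            if slope_name in re_vals.index:
                random_slopes[str(grp)] = float(re_vals[slope_name])
                if slope_name in fit.fe_params.index:
                    combined[str(grp)] = float(fit.fe_params[slope_name] + re_vals[slope_name])
    try:
        ri_var = float(np.asarray(fit.cov_re)[0, 0])
    except Exception:
        ri_var = float("nan")
    return LMEResult(
        fixed_effects=fe,
        random_intercept_var=ri_var,
        adjusted_r2=float(adj_r2),
        lr_p_vs_null=lr_p,
        n_obs=n,
        formula=formula,
        random_slopes=random_slopes,
        combined_slopes=combined,
    )


def fit_rd_model(
    table: pd.DataFrame,
    predictors: list[str] | None = None,
    condition: str = "below-ceiling",
) -> LMEResult:
    """LME of rD on standardized predictors with a subject random intercept.

    ``condition`` selects below-ceiling or at-ceiling trials via
    ``ceiling_flag``.  SI is dropped automatically at ceiling when it is
    (near-)constant there.  Significance of fixed effects is the p < 0.05
    t-test reported in each :class:`FixedEffect`.
    """
    validate_trial_table(table)
    if condition not in ("below-ceiling", "at-ceiling", "all"):
        raise ValueError(f"unknown condition '{condition}'")
    df = table.copy()
    if condition != "all":
        want = condition == "at-ceiling"
        df = df[df["ceiling_flag"].astype(bool) == want].copy()
    if predictors is None:
        predictors = [p for p in ("snr_db", "si", "gv", "hr") if p in df.columns]
    predictors = [p for p in predictors if df[p].std() > 1e-9]
    df = df.dropna(subset=predictors + ["rD"]).copy()
    for p in predictors:
        df[p] = _zscore(df[p].to_numpy())
    _check_collinearity(df, predictors)
    return _fit_mixedlm(df, "rD", predictors)


def si_bin_edges(ceiling: float, n_bins: int) -> np.ndarray:
    """Equal-width SI bin edges from 0 to the ceiling."""
    return np.linspace(0.0, ceiling, n_bins + 1)


def binned_snr_slopes(
    table: pd.DataFrame,
    n_si_bins: int = 6,
    min_subjects: int = 2,
) -> pd.DataFrame:
    """LME slope of rD on SNR within each SI bin (+ a ceiling bin).

    SI is quantized into ``n_si_bins`` equal-width bins from 0 to the
    ceiling; trials flagged at ceiling form their own bin.  Within each bin
    an LME with subject random intercept and random SNR slope is fitted;
    the returned frame holds the fixed slope, its p-value, and the mean
    combined (fixed + random) slope.  Bins observed in fewer than
    ``min_subjects`` subjects are dropped with a warning.
    """
    validate_trial_table(table)
    if n_si_bins < 1:
        raise ValueError("n_si_bins must be >= 1")
    df = table.copy()
    below = df[~df["ceiling_flag"].astype(bool)].copy()
    edges = si_bin_edges(float(df["si"].max()), n_si_bins)
    below["si_bin"] = np.clip(np.digitize(below["si"], edges) - 1, 0, n_si_bins - 1)
    rows = []
    groups = [(f"si_bin_{b}", below[below["si_bin"] == b], edges[b], edges[b + 1])
              for b in range(n_si_bins)]
    ceil_df = df[df["ceiling_flag"].astype(bool)]
    if len(ceil_df):
        groups.append(("ceiling", ceil_df, float(ceil_df["si"].min()), float(df["si"].max())))
    for label, sub, lo, hi in groups:
        if sub["subject"].nunique() < min_subjects or len(sub) < 4:
            if len(sub):
                warnings.warn(f"SI bin {label} has < {min_subjects} subjects; dropped",
                              stacklevel=2)
            continue
        if sub["snr_db"].std() < 1e-9:
            warnings.warn(f"SI bin {label} has constant SNR; dropped", stacklevel=2)
            continue
        try:
            res = _fit_mixedlm(sub, "rD", ["snr_db"], re_formula="~snr_db", do_lrt=False)
        except (np.linalg.LinAlgError, ValueError):
            warnings.warn(f"SI bin {label}: degenerate mixed-model fit; dropped",
                          stacklevel=2)
            continue
        eff = res.effect("snr_db")
        combined = np.mean(list(res.combined_slopes.values())) if res.combined_slopes else eff.estimate
        rows.append(
            dict(
                bin=label, si_lo=lo, si_hi=hi, n_trials=len(sub),
                slope=eff.estimate, se=eff.se, p=eff.p,
                significant=eff.significant, combined_slope=float(combined),
            )
        )
    return pd.DataFrame(rows)


def dunn_posthoc(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons with Bonferroni correction.

    Standard z statistic on mean-rank differences with tie correction;
    p-values multiplied by the number of pairwise comparisons (capped at 1).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = [g for g in pd.unique(groups)]
    N = len(values)
    ranks = sp_stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1))
    rows = []
    n_pairs = len(labels) * (len(labels) - 1) // 2
    for a, b in itertools.combinations(labels, 2):
        ra, rb = ranks[groups == a], ranks[groups == b]
        se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1 / len(ra) + 1 / len(rb)))
        z = (ra.mean() - rb.mean()) / se if se > 0 else 0.0
        p = 2 * sp_stats.norm.sf(abs(z))
        rows.append(dict(group_a=a, group_b=b, z=float(z),
                         p_corrected=float(min(p * n_pairs, 1.0))))
    return pd.DataFrame(rows)


def kruskal_dunn(rd_values: np.ndarray, hr_groups: np.ndarray) -> tuple[float, pd.DataFrame]:
    """Kruskal-Wallis omnibus over HR groups plus Bonferroni-Dunn post hoc."""
    rd_values = np.asarray(rd_values, dtype=float)
    hr_groups = np.asarray(hr_groups)
    labels = pd.unique(hr_groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 non-empty groups")
    samples = [rd_values[hr_groups == g] for g in labels]
    if np.all(rd_values == rd_values[0]):
        raise ValueError("degenerate data: all values tied")
    omnibus_p = float(sp_stats.kruskal(*samples).pvalue)
    return omnibus_p, dunn_posthoc(rd_values, hr_groups)


@dataclass
class PathwaySummary:
    """Two-pathway mediation report: SNR -> SI -> rD and SNR -> effort -> rD."""

    si_on_snr: LMEResult
    gv_on_snr: LMEResult
    rd_on_si_by_snr_bin: pd.DataFrame
    rd_on_gv_by_snr_bin: pd.DataFrame
    si_snr_positive: bool
    gv_snr_positive: bool
    rd_si_positive_weakening: bool
    rd_gv_negative_strengthening: bool
    notes: list[str] = field(default_factory=list)

    @property
    def opposing_pathways_hold(self) -> bool:
        return (
            self.si_snr_positive
            and self.gv_snr_positive
            and self.rd_si_positive_weakening
            and self.rd_gv_negative_strengthening
        )


def _per_bin_slopes(df: pd.DataFrame, predictor: str, bin_col: str) -> pd.DataFrame:
    rows = []
    for b in sorted(df[bin_col].unique()):
        sub = df[df[bin_col] == b]
        if len(sub) < 4 or sub[predictor].std() < 1e-9 or sub["subject"].nunique() < 2:
            continue
        sub = sub.copy()
        sub[predictor] = _zscore(sub[predictor].to_numpy())
        try:
            res = _fit_mixedlm(sub, "rD", [predictor], do_lrt=False)
        except (np.linalg.LinAlgError, ValueError):
            continue
        eff = res.effect(predictor)
        rows.append(dict(snr_bin=b, snr_center=float(sub["snr_db"].mean()),
                         slope=eff.estimate, p=eff.p, n=len(sub)))
    return pd.DataFrame(rows)


def pathway_summary(table: pd.DataFrame, n_snr_bins: int = 4) -> PathwaySummary:
    """Test the opposing-pathway mediation pattern.

    Fits SI ~ SNR and GV ~ SNR (subject random intercept + random SNR
    slope), then per-SNR-bin LME slopes of rD on SI and on GV.  The report
    states whether: SI rises with SNR; GV rises with SNR (effort falls);
    the positive rD~SI slope weakens with SNR; and the negative rD~GV slope
    strengthens with SNR.
    """
    validate_trial_table(table)
    df = table.copy()
    notes: list[str] = []

    si_res = _fit_mixedlm(df, "si", ["snr_db"], re_formula="~snr_db")
    gv_ok = "gv" in df.columns and df["gv"].notna().any() and df["gv"].std() > 1e-9
    if gv_ok:
        gv_df = df.dropna(subset=["gv"])
        gv_res = _fit_mixedlm(gv_df, "gv", ["snr_db"], re_formula="~snr_db")
    else:
        notes.append("gaze velocity missing or constant; effort pathway not testable")
        gv_res = None

    edges = np.quantile(df["snr_db"], np.linspace(0, 1, n_snr_bins + 1))
    edges[-1] += 1e-9
    df["snr_bin"] = np.clip(np.digitize(df["snr_db"], edges) - 1, 0, n_snr_bins - 1)

    if df["si"].std() > 1e-9:
        si_slopes = _per_bin_slopes(df, "si", "snr_bin")
    else:
        notes.append("SI constant across trials; rD~SI pathway excluded")
        si_slopes = pd.DataFrame(columns=["snr_bin", "snr_center", "slope", "p", "n"])
    gv_slopes = (
        _per_bin_slopes(df.dropna(subset=["gv"]), "gv", "snr_bin")
        if gv_ok
        else pd.DataFrame(columns=["snr_bin", "snr_center", "slope", "p", "n"])
    )

    si_eff = si_res.effect("snr_db")
    si_snr_pos = si_eff.estimate > 0 and si_eff.significant
    if gv_res is not None:
        gv_eff = gv_res.effect("snr_db")
        gv_snr_pos = gv_eff.estimate > 0 and gv_eff.significant
    else:
        gv_snr_pos = False

    def weakening_positive(s: pd.DataFrame) -> bool:
        if len(s) < 2:
            return False
        first, last = s.iloc[0]["slope"], s.iloc[-1]["slope"]
        return s.iloc[0]["slope"] > 0 and last < first

    def strengthening_negative(s: pd.DataFrame) -> bool:
        if len(s) < 2:
            return False
        return s.iloc[-1]["slope"] < 0 and s.iloc[-1]["slope"] < s.iloc[0]["slope"]

    return PathwaySummary(
        si_on_snr=si_res,
        gv_on_snr=gv_res if gv_res is not None else si_res,
        rd_on_si_by_snr_bin=si_slopes,
        rd_on_gv_by_snr_bin=gv_slopes,
        si_snr_positive=bool(si_snr_pos),
        gv_snr_positive=bool(gv_snr_pos),
        rd_si_positive_weakening=bool(weakening_positive(si_slopes)),
        rd_gv_negative_strengthening=bool(strengthening_negative(gv_slopes)),
        notes=notes,
    )


def rd_snr_profile(table: pd.DataFrame, n_bins: int = 8) -> pd.DataFrame:
    """Mean rD per SNR bin; used to locate the tracking peak inside the grid."""
    validate_trial_table(table)
    edges = np.linspace(table["snr_db"].min(), table["snr_db"].max() + 1e-9, n_bins + 1)
    bins = np.clip(np.digitize(table["snr_db"], edges) - 1, 0, n_bins - 1)
    out = (
        table.assign(snr_bin=bins)
        .groupby("snr_bin")
        .agg(snr_center=("snr_db", "mean"), rd_mean=("rD", "mean"), n=("rD", "size"))
        .reset_index()
    )
    return out
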