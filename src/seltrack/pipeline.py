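"""End-to-end orchestration: simulate -> psychometrics -> tracking -> engagement -> TRF -> stats.

Every stage reads and writes plain containers (HDF5 + CSV/JSON); outputs
carry the configuration hash and seed so a rerun with the same
configuration is bit-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import engagement, psychometrics, stats, synth, tracking, trf
from .io import metadata_frame, write_dataset, write_report

log = logging.getLogger("seltrack")


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end analysis."""

    out_dir: str = "seltrack_out"
    seed: int = 0
    n_subjects: int = 2
    n_trials_per_subject: int = 32
    duration_s: float = 35.0
    eeg_window_ms: float = 400.0
    env_window_ms: float = 200.0
    ceiling_tol: float = 0.02
    n_perm: int = 200
    alpha: float = 0.05
    si_bins: int = 6
    response_window_s: tuple[float, float] = (0.2, 2.0)
    screen_width_m: float = 0.53
    screen_height_m: float = 0.30
    viewing_distance_m: float = 0.6
    cca_ridge: float = 1e-3
    trf_lambda_grid: tuple[float, ...] = trf.DEFAULT_LAMBDA_GRID
    snr_grid_points: int = 80

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "response_window_s" in raw:
            raw["response_window_s"] = tuple(raw["response_window_s"])
        if "trf_lambda_grid" in raw:
            raw["trf_lambda_grid"] = tuple(raw["trf_lambda_grid"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def experiment_config(self) -> synth.ExperimentConfig:
        return synth.ExperimentConfig(
            n_subjects=self.n_subjects,
            n_trials_per_subject=self.n_trials_per_subject,
            snr_grid=np.linspace(-12.0, 4.0, self.snr_grid_points),
            duration_s=self.duration_s,
        )


def _montage_channel_names(n_channels: int) -> list[str]:
    """Standard 64-channel montage names; positional labels otherwise."""
    if n_channels == tracking.N_EEG_CHANNELS:
        import mne

        return list(mne.channels.make_standard_montage("biosemi64").ch_names)
    return [f"ch{c:02d}" for c in range(n_channels)]


class StageError(RuntimeError):
    def __init__(self, stage: str, context: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed ({context}): {cause}")
        self.stage = stage


def fit_subject_curves(
    dataset: synth.SyntheticDataset,
) -> dict[str, psychometrics.PsychometricCurve]:
    """Per-subject psychometric curve: fit each noise type, average predictions."""
    curves: dict[str, psychometrics.PsychometricCurve] = {}
    for sid in dataset.subject_ids:
        per_noise = []
        for noise in synth.NOISE_TYPES:
            table = dataset.recall_tables.get((sid, noise))
            if table is not None:
                per_noise.append(psychometrics.fit_curve(table))
        if not per_noise:
            raise ValueError(f"no intelligibility data for subject {sid}")
        curves[sid] = (
            psychometrics.average_curves(*per_noise) if len(per_noise) == 2 else per_noise[0]
        )
    return curves


def assemble_trial_table(
    dataset: synth.SyntheticDataset,
    curves: dict[str, psychometrics.PsychometricCurve],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Run tracking + engagement and build the per-trial analysis table."""
    geometry = engagement.ScreenGeometry(
        config.screen_width_m, config.screen_height_m, config.viewing_distance_m
    )
    eeg_lags = tracking.LagSpec(config.eeg_window_ms)
    env_lags = tracking.LagSpec(config.env_window_ms)
    rows = []
    for sid in dataset.subject_ids:
        trials = dataset.subject_trials(sid)
        t0 = time.time()
        scores = tracking.crossval_scores(
            trials, eeg_lags=eeg_lags, env_lags=env_lags, ridge_reg=config.cca_ridge
        )
        log.info("tracking %s: %d trials in %.1f s", sid, len(trials), time.time() - t0)
        curve = curves[sid]
        for trial, sc in zip(trials, scores):
            d = trial.design
            si = float(psychometrics.si_at(curve, d.snr_db))
            gv = (
                engagement.gaze_velocity(trial.gaze, geometry)
                if trial.gaze is not None
                else float("nan")
            )
            hr = engagement.hit_rate(
                trial.word_onsets_s, trial.press_times_s, config.response_window_s
            )
            rows.append(
                dict(
                    trial_id=d.trial_id,
                    subject=sid,
                    snr_db=d.snr_db,
                    noise_type=d.noise_type,
                    si=si,
                    ceiling_flag=psychometrics.classify_ceiling(
                        curve, d.snr_db, config.ceiling_tol
                    ),
                    gv=gv,
                    hr=hr,
                    rT=sc.r_target,
                    rM=sc.r_masker,
                    rD=sc.r_diff,
                )
            )
    return pd.DataFrame(rows)


def trf_stage(
    dataset: synth.SyntheticDataset, table: pd.DataFrame, config: PipelineConfig
) -> dict:
    """Group TRFs by SI halves and GV tertiles; permutation significance."""
    trial_by_id = {t.design.trial_id: t for t in dataset.trials}
    trials = [trial_by_id[tid] for tid in table["trial_id"]]
    subjects = table["subject"].tolist()

    si_groups = trf.group_trfs(
        trials, table["si"].to_numpy(), bins=[(0.0, 0.5), (0.5, 1.0)],
        subjects=subjects, bin_labels=["si_low", "si_high"],
    )
    gv = table["gv"].to_numpy()
    out_groups = dict(si_groups)
    if np.isfinite(gv).sum() >= 3 and np.nanstd(gv) > 0:
        gv_bins = trf.quantile_bins(gv[np.isfinite(gv)], 3)
        gv_groups = trf.group_trfs(
            trials, gv, bins=gv_bins, subjects=subjects,
            bin_labels=["gv_low", "gv_mid", "gv_high"],
        )
        out_groups.update(gv_groups)

    # group-level permutation significance: per-subject observed TRFs are
    # compared to their permutation means by a paired t-test across subjects
    obs_rows, null_rows = [], []
    observed = None
    last_null = None
    for j, sid in enumerate(dataset.subject_ids):
        sub_trials = dataset.subject_trials(sid)[:8]
        envs = [t.env_target.samples[t.analysis_slice()] for t in sub_trials]
        eegs = [t.eeg[:, t.analysis_slice()] for t in sub_trials]
        est = trf.fit_trf(envs, eegs, lam=1.0)
        last_null = trf.permutation_null(
            envs, eegs, n_perm=max(config.n_perm // 4, 25),
            seed=config.seed + j, lam=1.0,
        )
        obs_rows.append(est.channel_average())
        null_rows.append(last_null.mean(axis=0))
        if observed is None:
            observed = est
    if len(obs_rows) >= 2:
        mask = trf.significant_components(
            np.array(obs_rows), np.array(null_rows), alpha=config.alpha
        )
    else:  # single subject: empirical permutation p per lag
        mask = trf.significant_components(observed, last_null, alpha=config.alpha)

    ch_names = _montage_channel_names(dataset.trials[0].eeg.shape[0])
    amp_rows = []
    for label, est in out_groups.items():
        for name, amps in trf.component_amplitudes(est).items():
            for ch, a in enumerate(amps):
                amp_rows.append(
                    dict(group=label, window=name, channel=ch_names[ch], amplitude=a)
                )
    return dict(
        groups=out_groups,
        significance=mask,
        amplitudes=pd.DataFrame(amp_rows),
        observed=observed,
    )


def stats_stage(table: pd.DataFrame, config: PipelineConfig) -> dict:
    below = stats.fit_rd_model(table, condition="below-ceiling")
    at = (
        stats.fit_rd_model(table, condition="at-ceiling")
        if table["ceiling_flag"].astype(bool).any()
        else None
    )
    slopes = stats.binned_snr_slopes(table, n_si_bins=config.si_bins)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pathway = stats.pathway_summary(table)
    profile = stats.rd_snr_profile(table)
    hr_vals = table["hr"].round(3)
    kd = None
    if hr_vals.nunique() >= 2:
        kd_p, kd_pairs = stats.kruskal_dunn(table["rD"].to_numpy(), hr_vals.to_numpy())
        kd = dict(omnibus_p=kd_p, pairwise=kd_pairs)
    return dict(below=below, at_ceiling=at, slopes=slopes, pathway=pathway,
                profile=profile, kruskal=kd)


def _lme_to_dict(res: stats.LMEResult | None) -> dict | None:
    if res is None:
        return None
    return dict(
        formula=res.formula,
        n_obs=res.n_obs,
        adjusted_r2=res.adjusted_r2,
        lr_p_vs_null=res.lr_p_vs_null,
        fixed_effects={
            k: dict(estimate=v.estimate, se=v.se, t=v.t, p=v.p, significant=v.significant)
            for k, v in res.fixed_effects.items()
        },
    )


def run_pipeline(config: PipelineConfig, dataset: synth.SyntheticDataset | None = None) -> dict:
    """Execute the full analysis; returns the report bundle (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = dict(config_hash=config.config_hash(), seed=config.seed)

    stage = "simulate"
    try:
        if dataset is None:
            dataset = synth.simulate_experiment(
                config.experiment_config(), seed=config.seed
            )
        metadata_frame(dataset).to_csv(out / "metadata.csv", index=False)

        stage = "psychometrics"
        curves = fit_subject_curves(dataset)

        stage = "tracking+engagement"
        table = assemble_trial_table(dataset, curves, config)
        table.assign(**stamp).to_csv(out / "scores.csv", index=False)

        stage = "trf"
        trf_out = trf_stage(dataset, table, config)
        trf_out["amplitudes"].assign(**stamp).to_csv(out / "trf_amplitudes.csv", index=False)

        stage = "stats"
        stat_out = stats_stage(table, config)
        stat_out["slopes"].assign(**stamp).to_csv(out / "snr_slopes_by_si_bin.csv", index=False)
    except Exception as err:  # noqa: BLE001 - re-raise with stage context
        raise StageError(stage, f"out_dir={config.out_dir}", err) from err

    pathway = stat_out["pathway"]
    profile = stat_out["profile"]
    peak_idx = int(profile["rd_mean"].idxmax())
    report = {
        **stamp,
        "n_subjects": len(dataset.subject_ids),
        "n_trials": len(dataset.trials),
        "psychometric_curves": {
            sid: dict(lw=c.lw, up=c.up, gr=c.gr, ths=c.ths) for sid, c in curves.items()
        },
        "rd_model_below_ceiling": _lme_to_dict(stat_out["below"]),
        "rd_model_at_ceiling": _lme_to_dict(stat_out["at_ceiling"]),
        "pathway": dict(
            si_snr_positive=pathway.si_snr_positive,
            gv_snr_positive=pathway.gv_snr_positive,
            rd_si_positive_weakening=pathway.rd_si_positive_weakening,
            rd_gv_negative_strengthening=pathway.rd_gv_negative_strengthening,
            opposing_pathways_hold=pathway.opposing_pathways_hold,
            notes=pathway.notes,
        ),
        "rd_snr_profile": profile.to_dict(orient="list"),
        "rd_peak_snr_db": float(profile["snr_center"][peak_idx]),
        "rd_peak_interior": bool(
            0 < peak_idx < len(profile) - 1
        ),
        "trf_significant_lags": int(trf_out["significance"].mask.sum()),
        "kruskal_omnibus_p": (
            stat_out["kruskal"]["omnibus_p"] if stat_out["kruskal"] else None
        ),
        "mean_rd": float(table["rD"].mean()),
    }
    write_report(report, out / "report.json")
    return report


def validate_dataset(data_dir: str | Path) -> list[str]:
    """Schema/alignment diagnostics for a dataset container; empty list = clean."""
    import h5py

    data_dir = Path(data_dir)
    problems: list[str] = []
    meta_path = data_dir / "metadata.csv"
    if not meta_path.exists():
        return [f"missing metadata table: {meta_path}"]
    meta = pd.read_csv(meta_path)
    required = {"trial_id", "subject_id", "snr_db", "noise_type", "lead_in_s", "duration_s"}
    missing = required - set(meta.columns)
    if missing:
        problems.append(f"metadata missing columns: {sorted(missing)}")
        return problems
    bad_snr = meta[(meta["snr_db"] < -12) | (meta["snr_db"] > 4)]
    for row in bad_snr.itertuples():
        problems.append(f"{row.trial_id}: snr_db={row.snr_db} outside [-12, +4] dB")
    for sid, sub in meta.groupby("subject_id"):
        path = data_dir / f"{sid}.h5"
        if not path.exists():
            problems.append(f"missing container for subject {sid}: {path}")
            continue
        with h5py.File(path, "r") as f:
            for row in sub.itertuples():
                if row.trial_id not in f:
                    problems.append(f"{row.trial_id}: missing from {path.name}")
                    continue
                g = f[row.trial_id]
                n_expected = int(round(row.duration_s * 100))
                if "eeg" not in g:
                    problems.append(f"{row.trial_id}: missing eeg dataset")
                    continue
                eeg = g["eeg"]
                if eeg.shape[0] != tracking.N_EEG_CHANNELS:
                    problems.append(
                        f"{row.trial_id}: {eeg.shape[0]} EEG channels, expected "
                        f"{tracking.N_EEG_CHANNELS}"
                    )
                for name in ("env_target", "env_masker"):
                    if name not in g:
                        problems.append(f"{row.trial_id}: missing {name}")
                    elif g[name].shape[0] != eeg.shape[1]:
                        problems.append(
                            f"{row.trial_id}: {name} length {g[name].shape[0]} "
                            f"!= eeg length {eeg.shape[1]} (misaligned)"
                        )
                if abs(eeg.shape[1] - n_expected) > 1:
                    problems.append(
                        f"{row.trial_id}: eeg length {eeg.shape[1]} inconsistent with "
                        f"duration {row.duration_s}s at 100 Hz"
                    )
                if "gaze_t" in g and len(g["gaze_t"]) > 1:
                    dt = float(np.median(np.diff(g["gaze_t"][()])))
                    if abs(dt - 1 / 60) > 1e-3:
                        problems.append(
                            f"{row.trial_id}: gaze sampling interval {dt:.4f}s != 1/60s"
                        )
    return problems
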