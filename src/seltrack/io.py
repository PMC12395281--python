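"""Dataset container I/O.

A simulated (or imported) experiment is stored as one HDF5 file per
subject, with one group per trial holding ``eeg`` (channels x time,
100 Hz), ``env_target`` / ``env_masker`` (100 Hz, z-scored),
``gaze_xy`` / ``gaze_t`` / ``blink_mask`` (60 Hz), alongside a single CSV
metadata table (one row per trial: identifiers, condition labels, SNR,
event times, lead-in).  Real EEG recordings can be brought in through the
EDF/BDF import helper.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .acoustics import Envelope
from .engagement import GazeRecord
from .synth import SyntheticDataset, TrialDesign, Voice
from .tracking import Trial

METADATA_COLUMNS = [
    "trial_id", "subject_id", "snr_db", "noise_type", "target_voice",
    "target_gender", "masker_voice", "masker_gender",
    "word_onsets_s", "press_times_s", "lead_in_s", "duration_s",
]


def _join(values) -> str:
    return ";".join(f"{v:.6f}" for v in np.atleast_1d(values))


def _split(text) -> np.ndarray:
    if isinstance(text, float) and np.isnan(text):
        return np.array([])
    text = str(text).strip()
    return np.array([float(v) for v in text.split(";") if v]) if text else np.array([])


def metadata_frame(dataset: SyntheticDataset) -> pd.DataFrame:
    rows = []
    for trial in dataset.trials:
        d = trial.design
        rows.append(
            dict(
                trial_id=d.trial_id,
                subject_id=d.subject_id,
                snr_db=d.snr_db,
                noise_type=d.noise_type,
                target_voice=d.target_voice.label,
                target_gender=d.target_voice.gender,
                masker_voice=d.masker_voice.label,
                masker_gender=d.masker_voice.gender,
                word_onsets_s=_join(trial.word_onsets_s),
                press_times_s=_join(trial.press_times_s),
                lead_in_s=d.lead_in_s,
                duration_s=d.duration_s,
            )
        )
    return pd.DataFrame(rows, columns=METADATA_COLUMNS)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write one HDF5 container per subject plus metadata/recall CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = metadata_frame(dataset)
    meta.to_csv(out / "metadata.csv", index=False)
    for sid in dataset.subject_ids:
        with h5py.File(out / f"{sid}.h5", "w") as f:
            for trial in dataset.subject_trials(sid):
                g = f.create_group(trial.design.trial_id)
                g.create_dataset("eeg", data=trial.eeg, compression="gzip")
                g.create_dataset("env_target", data=trial.env_target.samples)
                g.create_dataset("env_masker", data=trial.env_masker.samples)
                if trial.gaze is not None:
                    g.create_dataset("gaze_xy", data=trial.gaze.xy)
                    g.create_dataset("gaze_t", data=trial.gaze.t)
                    g.create_dataset("blink_mask", data=trial.gaze.blink_mask)
    if dataset.recall_tables:
        rows = []
        for (sid, noise), table in dataset.recall_tables.items():
            for snr, n, k in zip(table.snr_db, table.n_words, table.n_correct):
                rows.append(dict(subject=sid, noise_type=noise, snr_db=snr,
                                 n_words=int(n), n_correct=int(k)))
        pd.DataFrame(rows).to_csv(out / "recall.csv", index=False)
    return out


def read_dataset(data_dir: str | Path) -> SyntheticDataset:
    """Read a dataset container written by :func:`write_dataset`.

    Ground truth is not stored, so the returned dataset has ``truth=None``;
    all analysis stages work from the stored trials and metadata alone.
    """
    data_dir = Path(data_dir)
    meta = pd.read_csv(data_dir / "metadata.csv")
    designs, trials = [], []
    for sid, sub in meta.groupby("subject_id", sort=False):
        path = data_dir / f"{sid}.h5"
        with h5py.File(path, "r") as f:
            for row in sub.itertuples():
                design = TrialDesign(
                    trial_id=row.trial_id,
                    subject_id=row.subject_id,
                    target_voice=Voice(row.target_voice, row.target_gender),
                    masker_voice=Voice(row.masker_voice, row.masker_gender),
                    noise_type=row.noise_type,
                    snr_db=float(row.snr_db),
                    duration_s=float(row.duration_s),
                    lead_in_s=float(row.lead_in_s),
                )
                g = f[row.trial_id]
                gaze = None
                if "gaze_xy" in g:
                    gaze = GazeRecord(
                        xy=g["gaze_xy"][()], t=g["gaze_t"][()],
                        blink_mask=g["blink_mask"][()].astype(bool),
                    )
                trial = Trial(
                    eeg=g["eeg"][()],
                    env_target=Envelope(g["env_target"][()], 100.0, z_scored=True),
                    env_masker=Envelope(g["env_masker"][()], 100.0, z_scored=True),
                    gaze=gaze,
                    word_onsets_s=_split(row.word_onsets_s),
                    press_times_s=_split(row.press_times_s),
                    design=design,
                    analysis_start_s=float(row.lead_in_s),
                )
                designs.append(design)
                trials.append(trial)
    dataset = SyntheticDataset(designs=designs, trials=trials, truth=None)
    recall_path = data_dir / "recall.csv"
    if recall_path.exists():
        from .psychometrics import IntelligibilityTable

        rec = pd.read_csv(recall_path)
        for (sid, noise), sub in rec.groupby(["subject", "noise_type"]):
            dataset.recall_tables[(sid, noise)] = IntelligibilityTable(
                sub["snr_db"].to_numpy(), sub["n_words"].to_numpy(),
                sub["n_correct"].to_numpy(),
            )
    return dataset


def read_raw_edf_eeg(path: str | Path) -> tuple[np.ndarray, float]:
    """Import a real EEG recording from EDF/BDF (channels x time, fs)."""
    import mne

    path = Path(path)
    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    return raw.get_data(), float(raw.info["sfreq"])


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
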