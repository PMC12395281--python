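"""Synthetic multi-talker listening experiment with known ground truth.

The generator emulates the study conditions of a selective-listening
paradigm: four synthetic voices (two per gender), target always masked by
an opposite-gender talker plus one of two background noise types, SNR
drawn from a dense grid spanning -12 to +4 dB, ~35-s trials with a 3-s
lead-in excluded from analysis and three repeated words per trial.

The forward model ties every downstream quantity to explicit ground truth:

* EEG = g_T * conv(env_T, kernel_target) + g_M * conv(env_M, kernel_masker)
  + white Gaussian noise, with attention gains (g_T, g_M) driven by the
  trial's intelligibility SI(snr) and attentional effort effort(snr);
* gaze velocity rises as effort falls (effort declines logistically with
  SNR, centered at -2 dB);
* each repeated word is detected with probability SI x engagement, where
  engagement itself increases with effort.

This couples SNR to selective tracking only *through* SI and effort, the
structure the downstream mediation analysis is designed to detect.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import signal as sp_signal
from scipy.special import expit

from .acoustics import Envelope, zscore_envelope
from .engagement import GazeRecord
from .psychometrics import IntelligibilityTable, PsychometricCurve, si_at
from .tracking import EEG_LAGS, N_EEG_CHANNELS, Trial


@dataclass(frozen=True)
class Voice:
    label: str
    gender: str  # "male" | "female"


DEFAULT_VOICES: tuple[Voice, ...] = (
    Voice("M1", "male"),
    Voice("M2", "male"),
    Voice("F1", "female"),
    Voice("F2", "female"),
)

NOISE_TYPES: tuple[str, ...] = ("babble", "pedestrian")

SNR_GRID_DEFAULT: np.ndarray = np.linspace(-12.0, 4.0, 80)


@dataclass(frozen=True)
class TrialDesign:
    """Condition labels and timing for one trial."""

    trial_id: str
    subject_id: str
    target_voice: Voice
    masker_voice: Voice
    noise_type: str
    snr_db: float
    duration_s: float = 35.0
    n_repeated_words: int = 3
    lead_in_s: float = 3.0

    def __post_init__(self) -> None:
        if self.target_voice.gender == self.masker_voice.gender:
            raise ValueError("target and masker must have opposite genders")
        if not (-12.0 <= self.snr_db <= 4.0):
            raise ValueError(f"snr_db={self.snr_db} outside the [-12, +4] dB grid")
        if self.n_repeated_words != 3:
            raise ValueError("the paradigm inserts exactly 3 repeated words per trial")


def enumerate_conditions(
    voices: Sequence[Voice] = DEFAULT_VOICES,
    noise_types: Sequence[str] = NOISE_TYPES,
) -> list[tuple[Voice, Voice, str]]:
    """All (target, masker, noise) triples under the opposite-gender constraint.

    With 2 voices per gender and 2 noise types this is the full crossing of
    4 targets x 2 opposite-gender maskers x 2 noises = 16 combinations.
    """
    for v in voices:
        if not isinstance(v, Voice) or v.gender not in ("male", "female"):
            raise ValueError(f"voice {v!r} lacks a valid gender label")
    triples = [
        (t, m, nz)
        for t, m, nz in itertools.product(voices, voices, noise_types)
        if t.gender != m.gender
    ]
    return triples


# ---------------------------------------------------------------------------
# envelopes and kernels
# ---------------------------------------------------------------------------


def gen_envelope(duration_s: float, fs_hz: float = 100.0, seed: int = 0) -> np.ndarray:
    """Speech-like amplitude envelope: rectified low-passed Gaussian noise.

    White noise is low-passed at 8 Hz (the syllabic band), rectified, lightly
    smoothed again and clipped non-negative, so the modulation energy is
    dominated by 1-8 Hz as in natural speech envelopes.  Deterministic for a
    given seed.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    # pad to avoid filter edge transients inside the trial
    pad = int(fs_hz)
    x = rng.standard_normal(n + 2 * pad)
    sos = sp_signal.butter(4, 8.0, btype="low", fs=fs_hz, output="sos")
    slow = sp_signal.sosfiltfilt(sos, x)
    env = np.abs(slow)
    env = sp_signal.sosfiltfilt(sos, env)
    env = np.clip(env, 0.0, None)
    return env[pad : pad + n]


def _component_kernel(
    lags_ms: np.ndarray,
    components: Sequence[tuple[float, float, float]],
    topographies: np.ndarray,
) -> np.ndarray:
    """Sum of Gaussian bumps (latency_ms, width_ms, amplitude) x channel maps."""
    kernel = np.zeros((topographies.shape[0], len(lags_ms)))
    for (lat, width, amp), topo in zip(components, topographies.T):
        kernel += np.outer(topo, amp * np.exp(-0.5 * ((lags_ms - lat) / width) ** 2))
    return kernel


def default_kernels(n_channels: int = N_EEG_CHANNELS) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth target and masker response kernels (channels x lags).

    The target kernel has the canonical triphasic envelope-response shape:
    a positive component near 50 ms, a negative one near 110 ms and a
    positive one near 210 ms, each with a smooth (deterministic) scalp
    profile.  The masker kernel is weaker with later, flatter components.
    Support lies within the 400-ms analysis window.
    """
    lags_ms = EEG_LAGS.lags_ms
    ch = np.arange(n_channels)
    # smooth scalp profiles: frontal->occipital gradients of different phase
    topo = np.column_stack(
        [
            0.6 + 0.4 * np.cos(2 * np.pi * ch / n_channels),
            0.5 + 0.5 * np.sin(2 * np.pi * ch / n_channels + 0.7),
            0.7 + 0.3 * np.cos(4 * np.pi * ch / n_channels + 1.9),
        ]
    )
    k_target = _component_kernel(
        lags_ms, [(50.0, 15.0, 1.0), (110.0, 20.0, -0.8), (210.0, 30.0, 0.6)], topo
    )
    k_masker = _component_kernel(
        lags_ms, [(70.0, 25.0, 0.5), (160.0, 35.0, -0.3)], topo[:, :2]
    )
    return k_target, k_masker


def default_effort_fn(snr_db: float | np.ndarray) -> float | np.ndarray:
    """Attentional effort in [0, 1], declining logistically with SNR.

    Centered at -2 dB with a 2-dB slope: effort is high in hard (low-SNR)
    trials and collapses once speech is easy, the coupling hypothesized to
    produce the non-monotonic tracking-vs-SNR profile.
    """
    return expit(-(np.asarray(snr_db, dtype=float) + 2.0) / 2.0)


def default_attn_gain_fn(si: float, effort: float) -> tuple[float, float]:
    """Attention gains (g_T, g_M) from intelligibility and effort.

    g_T = 0.5 + 0.5*SI*(0.5 + 0.5*effort) rises with both SI and effort;
    g_M = 0.5*(1 - g_T) so the masker is always the weaker stream.
    """
    g_t = 0.5 + 0.5 * si * (0.5 + 0.5 * effort)
    g_m = 0.5 * (1.0 - g_t)
    return float(g_t), float(g_m)


def default_engagement_fn(effort: float) -> float:
    """Behavioral engagement factor: 0.9 at full effort, 0.6 at zero."""
    return 0.6 + 0.3 * effort


@dataclass
class GroundTruth:
    """Everything the generator knows and downstream stages try to recover."""

    kernel_target: np.ndarray
    kernel_masker: np.ndarray
    attn_gain_fn: Callable[[float, float], tuple[float, float]]
    effort_fn: Callable[[float], float]
    psycho_true: Mapping[str, PsychometricCurve]
    eeg_noise_sd: float = 100.0
    gaze_base_velocity: float = 30.0  # deg/s at zero effort
    engagement_fn: Callable[[float], float] = default_engagement_fn
    #: SD of the latent trial-to-trial effort fluctuation around
    #: effort_fn(snr); shared by attention gains, gaze and engagement, so
    #: gaze velocity carries trial-level information about the effort state.
    effort_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        self.kernel_target = np.asarray(self.kernel_target, dtype=float)
        self.kernel_masker = np.asarray(self.kernel_masker, dtype=float)
        if self.kernel_target.shape[0] != self.kernel_masker.shape[0]:
            raise ValueError("target and masker kernels must share the channel axis")


def make_ground_truth(
    subject_ids: Sequence[str],
    n_channels: int = N_EEG_CHANNELS,
    eeg_noise_sd: float = 100.0,
    gaze_base_velocity: float = 30.0,
    seed: int = 0,
) -> GroundTruth:
    """Default ground truth with per-subject psychometric curves.

    Subject thresholds are drawn around -6 dB (SD 1 dB) with growth rates
    0.6-1.0 per dB and ceilings 0.93-1.0, spanning the range a cohort of
    normal-hearing listeners shows on this task.
    """
    rng = np.random.default_rng(seed)
    k_t, k_m = default_kernels(n_channels)
    psycho = {
        sid: PsychometricCurve(
            lw=0.02,
            up=float(rng.uniform(0.93, 1.0)),
            gr=float(rng.uniform(0.6, 1.0)),
            ths=float(rng.normal(-6.0, 1.0)),
        )
        for sid in subject_ids
    }
    return GroundTruth(
        kernel_target=k_t,
        kernel_masker=k_m,
        attn_gain_fn=default_attn_gain_fn,
        effort_fn=default_effort_fn,
        psycho_true=psycho,
        eeg_noise_sd=eeg_noise_sd,
        gaze_base_velocity=gaze_base_velocity,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------


def _convolve_kernel(env: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal convolution of an envelope with a channels x lags kernel."""
    n = len(env)
    out = sp_signal.fftconvolve(kernel, env[None, :], axes=1)
    return out[:, :n]


def _simulate_gaze(
    duration_s: float,
    gv_target_deg_s: float,
    fs_gaze: float,
    rng: np.random.Generator,
) -> GazeRecord:
    """Random-walk gaze whose measured angular velocity tracks ``gv_target``.

    Angular step magnitudes are exponential with the requested mean; the
    walk stays near screen center (where angular and screen displacement are
    ~proportional) by reflecting at a central box.  Blinks arrive as short
    Poisson bursts.
    """
    n = int(round(duration_s * fs_gaze))
    dt = 1.0 / fs_gaze
    # viewing distance 0.6 m, screen 0.53 x 0.30 m (defaults of ScreenGeometry)
    step_angle = rng.exponential(gv_target_deg_s * dt, size=n - 1)
    theta = rng.uniform(0, 2 * np.pi, size=n - 1)
    step_m = np.tan(np.radians(step_angle)) * 0.6
    dx = step_m * np.cos(theta) / 0.53
    dy = step_m * np.sin(theta) / 0.30
    xy = np.empty((n, 2))
    xy[0] = (0.5, 0.5)
    for i in range(1, n):
        cand = xy[i - 1] + (dx[i - 1], dy[i - 1])
        # reflect at a central box so geometry stays near-linear
        cand = np.where(cand > 0.65, 1.3 - cand, cand)
        cand = np.where(cand < 0.35, 0.7 - cand, cand)
        xy[i] = np.clip(cand, 0.0, 1.0)
    t = np.arange(n) * dt
    blink = np.zeros(n, dtype=bool)
    n_blinks = rng.poisson(0.2 * duration_s)
    for start in rng.uniform(0, duration_s, size=n_blinks):
        length = rng.uniform(0.1, 0.3)
        blink[(t >= start) & (t < start + length)] = True
    return GazeRecord(xy=xy, t=t, blink_mask=blink)


def simulate_trial(design: TrialDesign, truth: GroundTruth, seed: int) -> Trial:
    """Forward-simulate one trial from the ground-truth model."""
    if truth.kernel_target.shape[0] != truth.kernel_masker.shape[0]:
        raise ValueError("kernel channel counts do not match")
    rng = np.random.default_rng(seed)
    fs = 100.0
    n = int(round(design.duration_s * fs))

    env_t_raw = gen_envelope(design.duration_s, fs, seed=int(rng.integers(2**31)))
    env_m_raw = gen_envelope(design.duration_s, fs, seed=int(rng.integers(2**31)))
    env_t = zscore_envelope(Envelope(env_t_raw, fs))
    env_m = zscore_envelope(Envelope(env_m_raw, fs))

    curve = truth.psycho_true[design.subject_id]
    si = float(si_at(curve, design.snr_db))
    effort = float(truth.effort_fn(design.snr_db))
    if truth.effort_sd > 0:
        # latent trial-level attentional state around the SNR-driven mean
        effort = float(np.clip(effort + rng.normal(0.0, truth.effort_sd), 0.0, 1.0))
    g_t, g_m = truth.attn_gain_fn(si, effort)

    eeg = g_t * _convolve_kernel(env_t.samples, truth.kernel_target)
    if g_m != 0.0:
        eeg = eeg + g_m * _convolve_kernel(env_m.samples, truth.kernel_masker)
    if truth.eeg_noise_sd > 0:
        eeg = eeg + truth.eeg_noise_sd * rng.standard_normal(eeg.shape)

    gv_target = truth.gaze_base_velocity * (1.0 - 0.8 * effort)
    gaze = _simulate_gaze(design.duration_s, gv_target, 60.0, rng)

    # three repeated words, one per third of the analysed span; short trials
    # (used in quick simulations) degrade gracefully to a compressed span
    span_lo = min(design.lead_in_s + 2.0, 0.8 * design.duration_s)
    span_hi = max(design.duration_s - 3.0, span_lo + 0.3)
    edges = np.linspace(span_lo, span_hi, design.n_repeated_words + 1)
    onsets = np.array(
        [
            rng.uniform(edges[j], max(edges[j] + 1e-6, edges[j + 1] - 0.5))
            for j in range(design.n_repeated_words)
        ]
    )
    engagement = float(truth.engagement_fn(effort))
    p_hit = si * engagement
    presses = []
    for onset in onsets:
        if rng.random() < p_hit:
            latency = float(np.clip(0.3 + rng.gamma(2.0, 0.2), 0.21, 2.0))
            presses.append(onset + latency)
    return Trial(
        eeg=eeg,
        env_target=env_t,
        env_masker=env_m,
        gaze=gaze,
        word_onsets_s=onsets,
        press_times_s=np.array(presses),
        design=design,
        analysis_start_s=design.lead_in_s,
    )


# ---------------------------------------------------------------------------
# experiment simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentConfig:
    """Cohort and condition-grid configuration; defaults are the study scale."""

    n_subjects: int = 14
    n_trials_per_subject: int = 160
    snr_grid: np.ndarray = field(default_factory=lambda: SNR_GRID_DEFAULT.copy())
    duration_s: float = 35.0
    lead_in_s: float = 3.0
    n_channels: int = N_EEG_CHANNELS
    recall_snr_levels: int = 16
    recall_words_per_level: int = 50

    @property
    def subject_ids(self) -> list[str]:
        return [f"S{j+1:02d}" for j in range(self.n_subjects)]


@dataclass
class SyntheticDataset:
    """One simulated experiment: designs, generated trials, ground truth."""

    designs: list[TrialDesign]
    trials: list[Trial]
    truth: GroundTruth
    recall_tables: dict[tuple[str, str], IntelligibilityTable] = field(default_factory=dict)

    def subject_trials(self, subject_id: str) -> list[Trial]:
        return [t for t in self.trials if t.design.subject_id == subject_id]

    @property
    def subject_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for d in self.designs:
            seen.setdefault(d.subject_id, None)
        return list(seen)


def _balanced_counts(n_trials: int, n_conditions: int) -> np.ndarray:
    counts = np.full(n_conditions, n_trials // n_conditions)
    remainder = n_trials - counts.sum()
    if remainder:
        warnings.warn(
            f"{n_trials} trials not divisible over {n_conditions} conditions; "
            "using the nearest balanced allocation",
            stacklevel=3,
        )
        counts[:remainder] += 1
    return counts


def simulate_recall_tables(
    config: ExperimentConfig, truth: GroundTruth, rng: np.random.Generator
) -> dict[tuple[str, str], IntelligibilityTable]:
    """Emulate the connected-speech intelligibility test per subject/noise."""
    levels = np.linspace(config.snr_grid.min(), config.snr_grid.max(), config.recall_snr_levels)
    tables = {}
    for sid in config.subject_ids:
        curve = truth.psycho_true[sid]
        for noise in NOISE_TYPES:
            p = si_at(curve, levels)
            n_words = np.full(len(levels), config.recall_words_per_level)
            k = rng.binomial(n_words, p)
            tables[(sid, noise)] = IntelligibilityTable(levels, n_words, k)
    return tables


def simulate_experiment(
    config: ExperimentConfig,
    truth: GroundTruth | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a full synthetic experiment, balanced over the 16 conditions.

    Fully reproducible from ``(config, seed)``.  SNR values cycle through
    the configured grid so the whole grid is spanned; each subject's trials
    are evenly distributed over the condition triples.
    """
    master = np.random.default_rng(seed)
    if truth is None:
        truth = make_ground_truth(
            config.subject_ids, n_channels=config.n_channels, seed=int(master.integers(2**31))
        )
    triples = enumerate_conditions()
    designs: list[TrialDesign] = []
    for sid in config.subject_ids:
        counts = _balanced_counts(config.n_trials_per_subject, len(triples))
        condition_seq = [
            triples[c] for c in np.repeat(np.arange(len(triples)), counts)
        ]
        master.shuffle(condition_seq)
        grid = np.sort(np.asarray(config.snr_grid, dtype=float))
        n = config.n_trials_per_subject
        if n >= len(grid):
            snrs = np.resize(grid, n)
        else:
            # fewer trials than grid values: sample evenly across the grid
            snrs = grid[np.round(np.linspace(0, len(grid) - 1, n)).astype(int)]
        snrs = master.permutation(snrs)
        for k, ((tv, mv, nz), snr) in enumerate(zip(condition_seq, snrs)):
            designs.append(
                TrialDesign(
                    trial_id=f"{sid}_T{k+1:03d}",
                    subject_id=sid,
                    target_voice=tv,
                    masker_voice=mv,
                    noise_type=nz,
                    snr_db=float(snr),
                    duration_s=config.duration_s,
                    lead_in_s=config.lead_in_s,
                )
            )
    trial_seeds = master.integers(2**31, size=len(designs))
    trials = [simulate_trial(d, truth, int(s)) for d, s in zip(designs, trial_seeds)]
    recall = simulate_recall_tables(config, truth, master)
    return SyntheticDataset(designs=designs, trials=trials, truth=truth, recall_tables=recall)
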