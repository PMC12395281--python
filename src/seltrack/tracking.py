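"""CCA-based selective neural speech tracking.

Per subject, linear models are trained to align lag-embedded speech
envelopes (200 ms receptive field) with lag-embedded 64-channel EEG
(400 ms receptive field) via canonical correlation analysis.  Separate
models are trained for the target and masker streams with
leave-one-trial-out cross-validation; on each held-out trial the Pearson
correlation of the first canonical pair yields rT (target) and rM
(masker), and their difference rD = rT - rM quantifies selective neural
tracking of the attended talker.

Whitening of the (rank-deficient or ill-conditioned) lag-embedded EEG
covariance is regularized; the default adds a small ridge proportional to
the mean eigenvalue and factorizes by Cholesky, which lets the expensive
EEG-side factorization be shared between the target and masker models in
every cross-validation fold.  A rank-truncating whitening (keep components
explaining a fixed variance fraction) is available via ``whiten="truncate"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg, signal

from .acoustics import Envelope
from .engagement import GazeRecord

N_EEG_CHANNELS = 64
EEG_FS_HZ = 100.0

#: Receptive-field lengths of the decoder (ms).
EEG_WINDOW_MS = 400.0
ENV_WINDOW_MS = 200.0


@dataclass(frozen=True)
class LagSpec:
    """Causal lag window for time embedding."""

    window_ms: float
    fs_hz: float = EEG_FS_HZ

    def __post_init__(self) -> None:
        step = 1000.0 / self.fs_hz
        if abs(self.window_ms / step - round(self.window_ms / step)) > 1e-9:
            raise ValueError(
                f"window_ms={self.window_ms} not divisible by the sample period {step} ms"
            )

    @property
    def n_lags(self) -> int:
        return int(round(self.window_ms * self.fs_hz / 1000.0))

    @property
    def lags_ms(self) -> np.ndarray:
        """Lag of each embedded column in ms (0, 10, ..., window_ms - 10 at 100 Hz)."""
        return np.arange(self.n_lags) * 1000.0 / self.fs_hz


EEG_LAGS = LagSpec(EEG_WINDOW_MS)
ENV_LAGS = LagSpec(ENV_WINDOW_MS)


@dataclass
class Trial:
    """One listening trial: aligned EEG, envelopes, gaze and events."""

    eeg: np.ndarray  # channels x time at 100 Hz
    env_target: Envelope
    env_masker: Envelope
    gaze: GazeRecord | None
    word_onsets_s: np.ndarray
    press_times_s: np.ndarray
    design: "object"  # TrialDesign; duck-typed to avoid a circular import
    analysis_start_s: float = 3.0

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        if self.eeg.ndim != 2:
            raise ValueError("eeg must be channels x time")
        n = self.eeg.shape[1]
        if len(self.env_target) != n or len(self.env_masker) != n:
            raise ValueError("EEG and envelopes must be time-aligned and equal length")

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    def analysis_slice(self, fs_hz: float = EEG_FS_HZ) -> slice:
        """Sample range after the lead-in window excluded from all analyses."""
        return slice(int(round(self.analysis_start_s * fs_hz)), self.n_samples)


@dataclass
class CCAModel:
    """Trained canonical projections for one stream (target or masker)."""

    stim_weights: np.ndarray  # env lags x components
    resp_weights: np.ndarray  # (channels*lags) x components
    canon_corrs: np.ndarray  # training canonical correlations, non-increasing
    stim_mean: np.ndarray
    resp_mean: np.ndarray
    env_lags: LagSpec = ENV_LAGS
    eeg_lags: LagSpec = EEG_LAGS
    training_trials: tuple = ()

    @property
    def n_components(self) -> int:
        return self.stim_weights.shape[1]


@dataclass
class TrackingScores:
    """Per-trial selective-tracking correlations."""

    r_target: float
    r_masker: float

    @property
    def r_diff(self) -> float:
        return self.r_target - self.r_masker


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

_MONTAGE_POSITIONS: np.ndarray | None = None


def _montage_positions() -> np.ndarray:
    """3-D sensor positions of a standard 64-channel montage (meters)."""
    global _MONTAGE_POSITIONS
    if _MONTAGE_POSITIONS is None:
        import mne

        montage = mne.channels.make_standard_montage("biosemi64")
        pos = montage.get_positions()["ch_pos"]
        _MONTAGE_POSITIONS = np.array([pos[name] for name in montage.ch_names])
    return _MONTAGE_POSITIONS


def detect_bad_channels(eeg: np.ndarray, k_mad: float = 5.0) -> np.ndarray:
    """Channels whose standard deviation is an outlier.

    A channel is flagged when its SD deviates from the median channel SD by
    more than ``k_mad`` (consistency-scaled) median absolute deviations.
    """
    sds = eeg.std(axis=1)
    med = np.median(sds)
    mad = 1.4826 * np.median(np.abs(sds - med))  # scaled to estimate sigma
    thresh = k_mad * mad + 1e-12 * max(med, 1.0)
    return np.abs(sds - med) > thresh


def interpolate_channels(eeg: np.ndarray, bad: np.ndarray, power: float = 2.0) -> np.ndarray:
    """Replace flagged channels by an inverse-distance-weighted average of the rest.

    Sensor geometry comes from a standard 64-channel montage; for other
    channel counts, positions are placed uniformly on a ring.
    """
    n_ch = eeg.shape[0]
    if n_ch == N_EEG_CHANNELS:
        pos = _montage_positions()
    else:
        theta = np.linspace(0, 2 * np.pi, n_ch, endpoint=False)
        pos = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(n_ch)])
    out = eeg.copy()
    good = np.flatnonzero(~bad)
    for ch in np.flatnonzero(bad):
        d = np.linalg.norm(pos[good] - pos[ch], axis=1)
        w = 1.0 / np.maximum(d, 1e-6) ** power
        out[ch] = (w[:, None] * eeg[good]).sum(axis=0) / w.sum()
    return out


def preprocess_eeg(raw_eeg: np.ndarray, fs_in: float, k_mad: float = 5.0) -> np.ndarray:
    """Anti-alias filter, resample to 100 Hz, and repair outlier channels.

    Aborts when more than half the channels are flagged, since interpolation
    from a minority of good channels is not trustworthy.
    """
    raw_eeg = np.asarray(raw_eeg, dtype=float)
    if raw_eeg.ndim != 2:
        raise ValueError("raw_eeg must be channels x time")
    if fs_in < 200:
        raise ValueError("input sampling rate must be >= 200 Hz")
    up, down = 100, int(round(fs_in))
    g = np.gcd(up, down)
    eeg = signal.resample_poly(raw_eeg, up // g, down // g, axis=1)
    bad = detect_bad_channels(eeg, k_mad=k_mad)
    if bad.sum() > eeg.shape[0] // 2:
        raise ValueError(
            f"{bad.sum()}/{eeg.shape[0]} channels flagged as bad; "
            "refusing to interpolate a majority of the montage"
        )
    if bad.any():
        eeg = interpolate_channels(eeg, bad)
    return eeg


# ---------------------------------------------------------------------------
# lag embedding
# ---------------------------------------------------------------------------


def lag_embed(sig: np.ndarray, lag_spec: LagSpec) -> np.ndarray:
    """Causal time-lag embedding.

    ``sig`` is (time,) or (features, time).  Row ``t`` of the output holds
    the signal at times ``t, t-1, ..., t-(n_lags-1)`` (zero-padded before
    the first sample).  Columns are ordered feature-major: for feature ``f``
    and lag index ``l`` the column is ``f * n_lags + l``.
    """
    sig = np.asarray(sig, dtype=float)
    if sig.ndim == 1:
        sig = sig[None, :]
    n_feat, n_time = sig.shape
    n_lags = lag_spec.n_lags
    if n_time <= n_lags:
        raise ValueError(f"signal length {n_time} must exceed n_lags={n_lags}")
    padded = np.concatenate([np.zeros((n_feat, n_lags - 1)), sig], axis=1)
    # sliding windows of length n_lags, reversed so column l is lag l
    windows = np.lib.stride_tricks.sliding_window_view(padded, n_lags, axis=1)
    out = windows[:, :, ::-1]  # (features, time, lags)
    return out.transpose(1, 0, 2).reshape(n_time, n_feat * n_lags)


# ---------------------------------------------------------------------------
# regularized CCA
# ---------------------------------------------------------------------------


def _whitener(S: np.ndarray, ridge: float, whiten: str, var_frac: float = 0.999):
    """Return a callable applying S^{-1/2}-like transforms.

    ridge: Cholesky of S + ridge*mean_eig*I -> (solve, apply_invT)
    truncate: eigendecomposition keeping components explaining var_frac of
    the variance, eigenvalue-floored.
    """
    p = S.shape[0]
    if whiten == "ridge":
        mean_eig = np.trace(S) / p
        if mean_eig <= 0:
            raise ValueError("degenerate covariance: non-positive trace")
        L = linalg.cholesky(S + ridge * mean_eig * np.eye(p), lower=True)

        def half_inv(B):  # L^{-1} B
            return linalg.solve_triangular(L, B, lower=True)

        def half_invT(B):  # L^{-T} B
            return linalg.solve_triangular(L, B, lower=True, trans="T")

        return half_inv, half_invT
    elif whiten == "truncate":
        w, V = linalg.eigh(S)
        w = w[::-1]
        V = V[:, ::-1]
        w = np.clip(w, 0.0, None)
        total = w.sum()
        if total <= 0:
            raise ValueError("degenerate covariance: zero variance")
        k = int(np.searchsorted(np.cumsum(w) / total, var_frac) + 1)
        k = min(k, np.sum(w > 1e-12 * w[0]))
        W = V[:, :k] / np.sqrt(w[:k])  # p x k, W^T S W = I

        def half_inv(B):  # W^T B  (k x ...)
            return W.T @ B

        def half_invT(B):  # W B  (p x ...)
            return W @ B

        return half_inv, half_invT
    raise ValueError(f"unknown whitening '{whiten}'")


def cca_from_covariances(
    Sxx: np.ndarray,
    Syy: np.ndarray,
    Sxy: np.ndarray,
    n_components: int,
    ridge: float = 1e-3,
    whiten: str = "ridge",
    env_whiten: str = "truncate",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical weights and correlations from (centered) covariance blocks.

    Returns ``(Wx, Wy, rho)`` with canonical correlations ``rho``
    non-increasing and projections unit-variance on the training data
    (in the regularized metric).  The stimulus (y) side defaults to
    rank-truncating whitening: the lag-embedded envelope of band-limited
    speech is severely rank-deficient, and ridge whitening would promote
    numerically meaningless near-null canonical directions.
    """
    if np.any(np.diag(Sxx) < 1e-12 * max(np.trace(Sxx), 1e-30) / Sxx.shape[0]):
        warnings.warn("near-constant columns in the design; regularized whitening applied",
                      stacklevel=2)
    x_half_inv, x_half_invT = _whitener(Sxx, ridge, whiten)
    y_half_inv, y_half_invT = _whitener(Syy, ridge, env_whiten)
    M = x_half_inv(y_half_inv(Sxy.T).T)  # = Lx^{-1} Sxy Ly^{-T}
    U, s, Vt = linalg.svd(M, full_matrices=False)
    k = min(n_components, len(s))
    Wx = x_half_invT(U[:, :k])
    Wy = y_half_invT(Vt[:k].T)
    return Wx, Wy, np.clip(s[:k], -1.0, 1.0)


def fit_cca(
    env_lagged: np.ndarray,
    eeg_lagged: np.ndarray,
    n_components: int = 1,
    ridge_reg: float = 1e-3,
    whiten: str = "ridge",
    env_whiten: str = "truncate",
) -> CCAModel:
    """Fit a regularized CCA between lag-embedded envelope and EEG."""
    if env_lagged.shape[0] != eeg_lagged.shape[0]:
        raise ValueError("row counts must match")
    mu_y, mu_x = env_lagged.mean(axis=0), eeg_lagged.mean(axis=0)
    Yc, Xc = env_lagged - mu_y, eeg_lagged - mu_x
    n = len(Yc)
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    Wx, Wy, rho = cca_from_covariances(
        Sxx, Syy, Sxy, n_components, ridge_reg, whiten, env_whiten
    )
    return CCAModel(
        stim_weights=Wy,
        resp_weights=Wx,
        canon_corrs=rho,
        stim_mean=mu_y,
        resp_mean=mu_x,
    )


def score_trial(
    model: CCAModel,
    env: np.ndarray,
    eeg: np.ndarray,
    component: int = 0,
) -> float:
    """Pearson correlation of the first canonical pair on a held-out trial."""
    env = np.asarray(env, dtype=float).ravel()
    if env.std() < 1e-12:
        raise ValueError("constant envelope: correlation undefined")
    if len(env) <= max(model.env_lags.n_lags, model.eeg_lags.n_lags):
        raise ValueError("trial shorter than the lag window")
    Y = lag_embed(env, model.env_lags) - model.stim_mean
    X = lag_embed(eeg, model.eeg_lags) - model.resp_mean
    u = Y @ model.stim_weights[:, component]
    v = X @ model.resp_weights[:, component]
    su, sv = u.std(), v.std()
    if su < 1e-12 or sv < 1e-12:
        raise ValueError("degenerate canonical projection on held-out trial")
    return float(np.corrcoef(u, v)[0, 1])


# ---------------------------------------------------------------------------
# leave-one-trial-out cross-validation
# ---------------------------------------------------------------------------


def _trial_arrays(trial: Trial) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sl = trial.analysis_slice()
    eeg = trial.eeg[:, sl]
    env_t = trial.env_target.samples[sl]
    env_m = trial.env_masker.samples[sl]
    return eeg, env_t, env_m


class _FoldAccumulator:
    """Per-trial sufficient statistics enabling exact leave-one-out covariances."""

    def __init__(self, trials: Sequence[Trial], eeg_lags: LagSpec, env_lags: LagSpec):
        self.eeg_lags, self.env_lags = eeg_lags, env_lags
        px, py = None, env_lags.n_lags
        self.Cxx: list[np.ndarray] = []
        self.Cxy_t: list[np.ndarray] = []
        self.Cxy_m: list[np.ndarray] = []
        self.Cyy_t: list[np.ndarray] = []
        self.Cyy_m: list[np.ndarray] = []
        self.sx: list[np.ndarray] = []
        self.sy_t: list[np.ndarray] = []
        self.sy_m: list[np.ndarray] = []
        self.ns: list[int] = []
        for trial in trials:
            eeg, env_t, env_m = _trial_arrays(trial)
            X = lag_embed(eeg, eeg_lags)
            Yt = lag_embed(env_t, env_lags)
            Ym = lag_embed(env_m, env_lags)
            # float32 storage for the large EEG Gram matrices (memory), the
            # running totals are accumulated in float64
            self.Cxx.append((X.T @ X).astype(np.float32))
            self.Cxy_t.append(X.T @ Yt)
            self.Cxy_m.append(X.T @ Ym)
            self.Cyy_t.append(Yt.T @ Yt)
            self.Cyy_m.append(Ym.T @ Ym)
            self.sx.append(X.sum(axis=0))
            self.sy_t.append(Yt.sum(axis=0))
            self.sy_m.append(Ym.sum(axis=0))
            self.ns.append(len(X))
        self.tot_Cxx = np.zeros_like(self.Cxx[0], dtype=np.float64)
        for C in self.Cxx:
            self.tot_Cxx += C
        self.tot = {
            "Cxy_t": sum(self.Cxy_t),
            "Cxy_m": sum(self.Cxy_m),
            "Cyy_t": sum(self.Cyy_t),
            "Cyy_m": sum(self.Cyy_m),
            "sx": sum(self.sx),
            "sy_t": sum(self.sy_t),
            "sy_m": sum(self.sy_m),
            "n": sum(self.ns),
        }

    def fold(self, i: int, stream: str, need_sxx: bool = True):
        """Centered covariance blocks with trial ``i`` left out."""
        n = self.tot["n"] - self.ns[i]
        sx = self.tot["sx"] - self.sx[i]
        sy = self.tot[f"sy_{stream}"] - (self.sy_t if stream == "t" else self.sy_m)[i]
        mx, my = sx / n, sy / n
        Sxx = None
        if need_sxx:
            Cxx = self.tot_Cxx - self.Cxx[i].astype(np.float64)
            Sxx = (Cxx - n * np.outer(mx, mx)) / (n - 1)
        Cxy = self.tot[f"Cxy_{stream}"] - (self.Cxy_t if stream == "t" else self.Cxy_m)[i]
        Cyy = self.tot[f"Cyy_{stream}"] - (self.Cyy_t if stream == "t" else self.Cyy_m)[i]
        Sxy = (Cxy - n * np.outer(mx, my)) / (n - 1)
        Syy = (Cyy - n * np.outer(my, my)) / (n - 1)
        return Sxx, Sxy, Syy, mx, my


def crossval_scores(
    trials: Sequence[Trial],
    eeg_lags: LagSpec = EEG_LAGS,
    env_lags: LagSpec = ENV_LAGS,
    ridge_reg: float = 1e-3,
    whiten: str = "ridge",
    min_trials: int = 10,
) -> list[TrackingScores]:
    """Leave-one-trial-out rT, rM, rD for one subject's trials.

    For every trial, target and masker CCA models are trained on all other
    trials (lead-in windows excluded) and evaluated on the held-out trial;
    the EEG-side whitening factorization is shared between the two streams
    within each fold.
    """
    if len(trials) < min_trials:
        raise ValueError(f"need >= {min_trials} trials per subject, got {len(trials)}")
    acc = _FoldAccumulator(trials, eeg_lags, env_lags)
    scores = []
    for i, trial in enumerate(trials):
        eeg, env_t, env_m = _trial_arrays(trial)
        r = {}
        # shared EEG whitener across streams
        Sxx_t, Sxy_t, Syy_t, mx, my_t = acc.fold(i, "t")
        mean_eig = np.trace(Sxx_t) / Sxx_t.shape[0]
        if whiten == "ridge":
            L = linalg.cholesky(Sxx_t + ridge_reg * mean_eig * np.eye(Sxx_t.shape[0]), lower=True)
            x_half_inv = lambda B: linalg.solve_triangular(L, B, lower=True)
            x_half_invT = lambda B: linalg.solve_triangular(L, B, lower=True, trans="T")
        else:
            x_half_inv, x_half_invT = _whitener(Sxx_t, ridge_reg, whiten)
        for stream, env in (("t", env_t), ("m", env_m)):
            _, Sxy, Syy, _, my = acc.fold(i, stream, need_sxx=False)
            y_half_inv, y_half_invT = _whitener(Syy, ridge_reg, "truncate")
            M = x_half_inv(y_half_inv(Sxy.T).T)
            U, s, Vt = linalg.svd(M, full_matrices=False)
            Wx = x_half_invT(U[:, :1])
            Wy = y_half_invT(Vt[:1].T)
            model = CCAModel(
                stim_weights=Wy,
                resp_weights=Wx,
                canon_corrs=np.clip(s[:1], -1, 1),
                stim_mean=my,
                resp_mean=mx,
                env_lags=env_lags,
                eeg_lags=eeg_lags,
            )
            r[stream] = score_trial(model, env, eeg)
        scores.append(TrackingScores(r_target=r["t"], r_masker=r["m"]))
    return scores
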