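"""Level arithmetic and speech-envelope extraction.

The listening paradigm mixes a target talker (fixed at 65 dB SPL) with one
masker talker and two-channel background noise, with masker and each noise
channel presented at equal sound pressure level.  Because the three competing
sources are incoherent and equally loud, the target SNR relative to the total
competing power is

    SNR = L_target - L_masker - 10*log10(3)

The constant is kept exact internally (10*log10(3) = 4.7712...); 4.77 is
display rounding only.

Envelope extraction for decoding uses the magnitude of the analytic signal
followed by an 10 Hz low-pass, resampling to 100 Hz, and z-scoring to zero
mean / unit variance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

#: Power penalty (dB) for summing three equal-level incoherent sources.
THREE_SOURCE_OFFSET_DB: float = 10.0 * math.log10(3.0)

#: Target presentation level used throughout the experiment (dB SPL).
TARGET_LEVEL_DB_SPL: float = 65.0

#: SNR grid bounds of the paradigm (dB).
SNR_MIN_DB: float = -12.0
SNR_MAX_DB: float = 4.0

ENVELOPE_FS_HZ: float = 100.0


@dataclass(frozen=True)
class MixingSpec:
    """Presentation levels realising a requested target SNR.

    The masker and each of the two noise channels share one level, so the
    total competing power is three times the masker power.
    """

    L_target: float
    snr_db: float
    L_masker: float
    L_noise_per_channel: float

    def __post_init__(self) -> None:
        if not math.isclose(self.L_masker, self.L_noise_per_channel, abs_tol=1e-9):
            raise ValueError("masker and per-channel noise levels must be equal")


@dataclass
class Envelope:
    """A slow amplitude-modulation envelope at 100 Hz."""

    samples: np.ndarray
    fs_hz: float = ENVELOPE_FS_HZ
    z_scored: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("envelope must be one-dimensional")

    def __len__(self) -> int:
        return len(self.samples)


def snr_from_levels(L_target: float, L_masker: float) -> float:
    """Target SNR (dB) given target and masker/noise presentation levels.

    Assumes the masker and both noise channels are presented at equal level,
    so the competing power is 3x the masker power.
    """
    if not (math.isfinite(L_target) and math.isfinite(L_masker)):
        raise ValueError("levels must be finite")
    return L_target - L_masker - THREE_SOURCE_OFFSET_DB


def levels_for_snr(L_target: float, snr_db: float) -> MixingSpec:
    """Masker/noise levels that realise ``snr_db`` at a given target level."""
    if not (SNR_MIN_DB <= snr_db <= SNR_MAX_DB):
        warnings.warn(
            f"snr_db={snr_db:g} outside the paradigm grid "
            f"[{SNR_MIN_DB:g}, {SNR_MAX_DB:g}] dB",
            stacklevel=2,
        )
    L_masker = L_target - snr_db - THREE_SOURCE_OFFSET_DB
    return MixingSpec(
        L_target=L_target,
        snr_db=snr_db,
        L_masker=L_masker,
        L_noise_per_channel=L_masker,
    )


def zscore_envelope(env: Envelope) -> Envelope:
    """Return the envelope z-scored to zero mean and unit variance."""
    x = env.samples
    sd = x.std()
    if sd < 1e-12:
        raise ValueError("degenerate envelope: zero variance, cannot z-score")
    return Envelope((x - x.mean()) / sd, fs_hz=env.fs_hz, z_scored=True)


def extract_envelope(waveform: np.ndarray, fs_in: float) -> Envelope:
    """Extract the slow amplitude envelope of an audio waveform.

    Magnitude of the analytic (Hilbert) signal, low-passed at 10 Hz, resampled
    to 100 Hz and z-scored.  ``fs_in`` must exceed 200 Hz.
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim != 1:
        raise ValueError("waveform must be one-dimensional")
    if fs_in <= 200:
        raise ValueError("input sampling rate must exceed 200 Hz")
    if np.max(np.abs(waveform)) < 1e-15:
        raise ValueError("degenerate input: silent waveform has no envelope")

    analytic = signal.hilbert(waveform)
    mag = np.abs(analytic)
    sos = signal.butter(4, 10.0, btype="low", fs=fs_in, output="sos")
    smooth = signal.sosfiltfilt(sos, mag)
    # resample_poly needs a rational rate ratio; round fs_in to the nearest Hz
    up, down = 100, int(round(fs_in))
    g = math.gcd(up, down)
    resampled = signal.resample_poly(smooth, up // g, down // g)
    resampled = np.clip(resampled, 0.0, None)
    return zscore_envelope(Envelope(resampled, fs_hz=ENVELOPE_FS_HZ))


def envelope_from_wav(path) -> Envelope:
    """Extract the decoding envelope from a WAV file (mono or first channel)."""
    from scipy.io import wavfile

    fs, data = wavfile.read(path)
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[:, 0]
    return extract_envelope(data, float(fs))
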