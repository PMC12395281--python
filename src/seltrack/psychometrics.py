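"""Psychometric modeling of speech intelligibility (SI) versus SNR.

Word-recall accuracy from the connected-speech task is modeled per subject
and noise type as a four-parameter logistic,

    SI(SNR) = lw + (up - lw) / (1 + exp(-gr * (SNR - ths)))

with lower bound ``lw`` (approaching 0), upper bound ``up`` (approaching 1),
growth rate ``gr`` (per dB) and speech-reception threshold ``ths`` (the SNR
where SI is halfway between the bounds).  Curves are fitted by maximum
binomial likelihood; the fitted upper bound is the subject's *ceiling SI*.
Per-subject curves for the two noise types are combined by averaging their
predictions over a dense SNR grid and refitting the logistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special


@dataclass(frozen=True)
class PsychometricCurve:
    """Four-parameter logistic SI curve.

    Attributes
    ----------
    lw, up : bounds of the SI range, 0 <= lw < up <= 1.
    gr : growth rate per dB, > 0.
    ths : speech-reception threshold in dB (SI = (lw+up)/2 there).
    """

    lw: float
    up: float
    gr: float
    ths: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lw < self.up <= 1.0):
            raise ValueError(f"require 0 <= lw < up <= 1, got lw={self.lw}, up={self.up}")
        if self.gr <= 0:
            raise ValueError(f"growth rate must be positive, got {self.gr}")


@dataclass
class IntelligibilityTable:
    """Per-SNR word-recall counts for one subject and noise type."""

    snr_db: np.ndarray
    n_words: np.ndarray
    n_correct: np.ndarray

    def __post_init__(self) -> None:
        self.snr_db = np.asarray(self.snr_db, dtype=float)
        self.n_words = np.asarray(self.n_words, dtype=int)
        self.n_correct = np.asarray(self.n_correct, dtype=int)
        if not (len(self.snr_db) == len(self.n_words) == len(self.n_correct)):
            raise ValueError("columns must have equal length")
        if np.any(self.n_words < 1):
            raise ValueError("trial counts must be >= 1")
        if np.any(self.n_correct < 0) or np.any(self.n_correct > self.n_words):
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def accuracy(self) -> np.ndarray:
        return self.n_correct / self.n_words

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IntelligibilityTable":
        return cls(df["snr_db"].to_numpy(), df["n_words"].to_numpy(), df["n_correct"].to_numpy())


def si_at(curve: PsychometricCurve, snr_db) -> np.ndarray | float:
    """Predicted SI at one or more SNR values; bounded by (lw, up)."""
    snr = np.asarray(snr_db, dtype=float)
    out = curve.lw + (curve.up - curve.lw) * special.expit(curve.gr * (snr - curve.ths))
    return float(out) if np.isscalar(snr_db) else out


def ceiling_si(curve: PsychometricCurve) -> float:
    """The regressed upper bound of the curve: the subject's ceiling SI."""
    return curve.up


def classify_ceiling(curve: PsychometricCurve, snr_db: float, tol: float = 0.02) -> bool:
    """True when SI at ``snr_db`` is within ``tol`` of ceiling.

    The criterion is relative to the curve's range: the trial counts as
    at-ceiling when ``up - SI(snr) <= tol * (up - lw)``.
    """
    if not (0.0 <= tol <= 0.1):
        raise ValueError("tol must lie in [0, 0.1]")
    gap = curve.up - si_at(curve, float(snr_db))
    return bool(gap <= tol * (curve.up - curve.lw))


def _neg_log_likelihood(params: np.ndarray, snr, n, k) -> float:
    lw, up, gr, ths = params
    p = lw + (up - lw) * special.expit(gr * (snr - ths))
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def fit_curve(table: IntelligibilityTable) -> PsychometricCurve:
    """Maximum-likelihood fit of the four-parameter logistic.

    Requires at least 4 distinct SNR levels with data on both sides of the
    inflection; all-correct or all-wrong data are rejected as
    non-identifiable.
    """
    snr, n, k = table.snr_db, table.n_words, table.n_correct
    levels = np.unique(snr)
    if len(levels) < 4:
        raise ValueError(
            f"under-determined fit: need >= 4 distinct SNR levels, got {len(levels)}"
        )
    acc = table.accuracy
    if np.all(k == n) or np.all(k == 0):
        raise ValueError(
            "non-identifiable data: all responses "
            f"{'correct' if np.all(k == n) else 'wrong'}; the threshold and "
            "growth rate cannot be estimated"
        )

    lo, hi = float(levels.min()), float(levels.max())
    span = max(hi - lo, 1.0)
    # threshold init: SNR where accuracy first crosses the midpoint of its range
    mid = (acc.min() + acc.max()) / 2.0
    order = np.argsort(snr)
    crossing = snr[order][int(np.argmax(acc[order] >= mid))]
    x0 = np.array([max(acc.min() - 0.01, 0.0), min(acc.max() + 0.01, 1.0), 4.0 / span, float(crossing)])

    bounds = [(0.0, 0.45), (0.55, 1.0), (1e-3, 20.0), (lo - span, hi + span)]
    x0 = np.array([np.clip(v, b[0] + 1e-6, b[1] - 1e-6) for v, b in zip(x0, bounds)])

    best = None
    for gr0 in (x0[2], 0.3, 1.0, 3.0):
        start = x0.copy()
        start[2] = gr0
        res = optimize.minimize(
            _neg_log_likelihood,
            start,
            args=(snr, n, k),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    lw, up, gr, ths = best.x
    # keep the ordering invariant under boundary round-off
    lw = min(lw, up - 1e-6)
    return PsychometricCurve(lw=float(lw), up=float(up), gr=float(gr), ths=float(ths))


def _refit_to_predictions(grid: np.ndarray, target: np.ndarray) -> tuple[PsychometricCurve, float]:
    """Least-squares logistic fit to a dense SI-vs-SNR prediction curve."""

    def resid(params):
        lw, up, gr, ths = params
        return lw + (up - lw) * special.expit(gr * (grid - ths)) - target

    lo, hi = float(grid.min()), float(grid.max())
    x0 = np.array([float(target.min()), float(target.max()), 0.8, float(grid[np.argmin(np.abs(target - (target.min() + target.max()) / 2))])])
    res = optimize.least_squares(
        resid,
        x0,
        bounds=([0.0, 0.5, 1e-3, lo - 20], [0.5, 1.0, 20.0, hi + 20]),
    )
    lw, up, gr, ths = res.x
    rmse = float(np.sqrt(np.mean(resid(res.x) ** 2)))
    return PsychometricCurve(float(min(lw, up - 1e-6)), float(up), float(gr), float(ths)), rmse


def average_curves(
    curve_a: PsychometricCurve,
    curve_b: PsychometricCurve,
    snr_grid: np.ndarray | None = None,
    rmse_warn: float = 0.02,
) -> PsychometricCurve:
    """Average two psychometric curves (e.g. the two noise types).

    Predictions are averaged pointwise over a dense SNR grid and the logistic
    is refitted to the mean — robust to parameter non-identifiability near
    ceiling.  Warns when the refit residual exceeds ``rmse_warn``.
    """
    if snr_grid is None:
        lo = min(curve_a.ths, curve_b.ths) - 15.0
        hi = max(curve_a.ths, curve_b.ths) + 15.0
        snr_grid = np.linspace(lo, hi, 601)
    mean_pred = 0.5 * (si_at(curve_a, snr_grid) + si_at(curve_b, snr_grid))
    fitted, rmse = _refit_to_predictions(np.asarray(snr_grid, dtype=float), mean_pred)
    if rmse > rmse_warn:
        warnings.warn(
            f"averaged curve is poorly captured by a logistic (RMSE={rmse:.4f})",
            stacklevel=2,
        )
    return fitted
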