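"""Dual source-detector fNIRS preprocessing.

Raw shallow/deep total-haemoglobin series are turned into one baseline
activity scalar per participant per hemisphere by the four-step chain:

1. linear detrend of both channels,
2. zero-phase low-pass filter (default 4th-order Butterworth, 0.1 Hz),
3. short-separation regression — the OLS residual of deep on
   {intercept, shallow} — to strip scalp/systemic haemodynamics,
4. baseline correction of each game block against its immediately
   preceding rest block, then averaging over game-block samples.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .types import ActivityEstimate, NeuralSeries, Recording

logger = logging.getLogger(__name__)

__all__ = [
    "detrend",
    "lowpass",
    "short_separation_regress",
    "baseline_correct",
    "block_average",
    "preprocess_recording",
    "preprocess_recordings",
]


def detrend(series: np.ndarray, fs: float | None = None) -> np.ndarray:
    """Remove the least-squares straight line (slope and intercept).

    After detrending, an OLS line fit to the output has zero slope and
    intercept to numerical tolerance. ``fs`` is accepted for interface
    symmetry; a linear trend is scale-free in time.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size < 2:
        raise ValueError("detrend requires a 1-D series of length >= 2")
    return _signal.detrend(series, type="linear")


def lowpass(series: np.ndarray, fs: float, cutoff: float = 0.1,
            order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    The two-pass application squares the single-pass magnitude response and
    cancels phase, so block boundaries are not shifted.  DC gain is exactly 1.
    """
    series = np.asarray(series, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if not cutoff < fs / 2:
        raise ValueError(f"cutoff ({cutoff} Hz) must be below Nyquist ({fs / 2} Hz)")
    sos = _signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return _signal.sosfiltfilt(sos, series)


def short_separation_regress(
    deep: np.ndarray,
    shallow: np.ndarray,
    fs: float | None = None,
    schedule=None,
) -> NeuralSeries:
    """Residual of OLS regression of the deep on the shallow channel.

    The residual is uncorrelated with the shallow signal and has zero mean.
    A constant (zero-variance) shallow channel cannot explain anything, so
    the fall-back is mean-centering the deep channel; this is flagged on the
    returned series and logged.
    """
    deep = np.asarray(deep, dtype=float)
    shallow = np.asarray(shallow, dtype=float)
    if deep.shape != shallow.shape or deep.ndim != 1 or deep.size < 3:
        raise ValueError("deep and shallow must be equal-length 1-D series (n >= 3)")
    s_centered = shallow - shallow.mean()
    ss = float(s_centered @ s_centered)
    if ss == 0.0:
        logger.warning("shallow channel is constant; falling back to mean-centering")
        return NeuralSeries(deep - deep.mean(), fs or 0.0, schedule,
                            coef=(float(deep.mean()), 0.0), fallback=True)
    slope = float(s_centered @ (deep - deep.mean())) / ss
    intercept = float(deep.mean() - slope * shallow.mean())
    resid = deep - (intercept + slope * shallow)
    return NeuralSeries(resid, fs or 0.0, schedule, coef=(intercept, slope))


def baseline_correct(neural: NeuralSeries) -> NeuralSeries:
    """Reference each game block to its immediately preceding rest block.

    Game-block samples have the preceding rest block's mean subtracted;
    rest-block samples have their own block mean subtracted.
    """
    if neural.schedule is None or neural.fs <= 0:
        raise ValueError("baseline_correct requires a schedule and sampling rate")
    values = neural.values.copy()
    schedule, fs = neural.schedule, neural.fs
    blocks = schedule.blocks
    rest_means = {}
    for i, block in enumerate(blocks):
        if block.label == "rest":
            rest_means[i] = values[schedule.sample_slice(block, fs)].mean()
    out = values.copy()
    for i, block in enumerate(blocks):
        sl = schedule.sample_slice(block, fs)
        if block.label == "game":
            if i == 0 or blocks[i - 1].label != "rest":
                raise ValueError(f"game block {i} has no immediately preceding rest block")
            out[sl] = values[sl] - rest_means[i - 1]
        else:
            out[sl] = values[sl] - rest_means[i]
    return NeuralSeries(out, fs, schedule, coef=neural.coef, fallback=neural.fallback)


def block_average(corrected: NeuralSeries, participant_id: str = "",
                  side: str = "left") -> ActivityEstimate:
    """Average the baseline-corrected signal over all game-block samples.

    The scalar equals the mean over the concatenated game samples, i.e. the
    per-block means weighted by their sample counts.
    """
    if corrected.schedule is None or corrected.fs <= 0:
        raise ValueError("block_average requires a schedule and sampling rate")
    game = corrected.schedule.game_blocks()
    if not game:
        raise ValueError("schedule contains no game blocks")
    means, sizes, total, count = [], [], 0.0, 0
    for block in game:
        seg = corrected.values[corrected.schedule.sample_slice(block, corrected.fs)]
        means.append(float(seg.mean()))
        sizes.append(int(seg.size))
        total += float(seg.sum())
        count += seg.size
    return ActivityEstimate(participant_id, side, total / count,
                            tuple(means), tuple(sizes))


def preprocess_recording(
    recording: Recording,
    cutoff: float = 0.1,
    order: int = 4,
    short_separation: bool = True,
) -> ActivityEstimate:
    """Full chain: detrend -> low-pass -> short-separation regression ->
    baseline correction -> game-block average.

    Detrending and filtering are applied to both channels before the
    regression consumes them.  ``short_separation=False`` skips the
    regression (mean-centering only) — useful for quantifying how much the
    shallow channel removes, not recommended for analysis.
    """
    fs, schedule = recording.fs, recording.schedule
    deep = lowpass(detrend(recording.deep), fs, cutoff=cutoff, order=order)
    shallow = lowpass(detrend(recording.shallow), fs, cutoff=cutoff, order=order)
    if short_separation:
        neural = short_separation_regress(deep, shallow, fs=fs, schedule=schedule)
    else:
        neural = NeuralSeries(deep - deep.mean(), fs, schedule)
    corrected = baseline_correct(neural)
    return block_average(corrected, participant_id=recording.participant_id,
                         side=recording.side)


def preprocess_recordings(recordings: Iterable[Recording], cutoff: float = 0.1,
                          order: int = 4) -> pd.DataFrame:
    """Preprocess many recordings into a tidy ``id, side, activity`` table."""
    rows = []
    for rec in recordings:
        est = preprocess_recording(rec, cutoff=cutoff, order=order)
        rows.append({"id": est.participant_id, "side": est.side,
                     "activity": est.activity})
    return pd.DataFrame(rows, columns=["id", "side", "activity"])
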