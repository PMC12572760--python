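"""Inhalation detection from airflow traces and sniff-rate statistics.

Inhalations are negative-going airflow deflections (polarity
configurable).  Detection: the trace is lightly smoothed, a robust
baseline SD is estimated from the median absolute deviation, and an onset
is scored at each crossing of k x SD in the inhalation direction,
enforcing a refractory period (default 100 ms).  The adaptive threshold
makes detection invariant to the overall amplitude scale of the trace.

Rates are event counts in half-open windows divided by window length;
the sniff CV is SD/mean of the per-trial counts in the 1 s after target
onset; sniff modulation compares per-animal rates in the baseline
([-1, 0) s before the first background), background ([-1, 0) s before
target) and target ([0, 1) s after target) windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .exact_stats import TestResult, paired_t
from .synthetic_data import SniffTrace

__all__ = [
    "detect_sniffs",
    "sniff_rate",
    "sniff_cv",
    "sniff_modulation",
]


def detect_sniffs(
    trace: SniffTrace | np.ndarray,
    sample_rate_hz: float | None = None,
    threshold_k: float = 2.0,
    refractory_s: float = 0.1,
    polarity: int = -1,
    smooth_s: float = 0.01,
) -> np.ndarray:
    """Detect inhalation onset times (s) in an airflow trace.

    Returns onset times of threshold crossings in the inhalation
    direction (``polarity=-1``: negative deflections), separated by at
    least ``refractory_s``.  A flat trace yields no onsets and a warning.
    """
    if isinstance(trace, SniffTrace):
        samples, fs = np.asarray(trace.samples, dtype=float), trace.sample_rate_hz
    else:
        if sample_rate_hz is None:
            raise ValueError("sample_rate_hz required for plain-array traces")
        samples, fs = np.asarray(trace, dtype=float), sample_rate_hz
    if not np.all(np.isfinite(samples)):
        raise ValueError("airflow trace contains non-finite samples")
    n_ref = int(round(refractory_s * fs))
    if samples.size <= n_ref:
        raise ValueError("trace shorter than the refractory period")

    x = polarity * samples  # inhalation now positive-going
    if smooth_s > 0:
        x = ndimage.gaussian_filter1d(x, smooth_s * fs, mode="nearest")
    if np.ptp(x) == 0:
        warnings.warn("flat airflow trace: no sniffs detected")
        return np.array([])
    mad = float(np.median(np.abs(x - np.median(x))))
    sd = 1.4826 * mad
    # amplitude-relative floor so a noise-free trace (MAD = 0) still uses a
    # meaningful threshold; both terms scale with the trace, so detection is
    # invariant to the overall amplitude scale
    thr = max(threshold_k * sd, 0.02 * float(x.max()))
    above = x > thr
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        crossings = np.concatenate([[0], crossings])
    onsets = []
    last = -np.inf
    for i in crossings:
        if i - last >= n_ref:
            onsets.append(i)
            last = i
    return np.asarray(onsets) / fs


def sniff_rate(onsets_s: np.ndarray, window: tuple[float, float]) -> float:
    """Onset count in the half-open window divided by its length (Hz)."""
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must have positive length")
    onsets_s = np.asarray(onsets_s, dtype=float)
    count = int(((onsets_s >= lo) & (onsets_s < hi)).sum())
    return count / (hi - lo)


def sniff_cv(per_trial_counts: np.ndarray, sd_ddof: int = 1) -> float:
    """SD/mean of per-trial sniff counts (target 1-s window)."""
    counts = np.asarray(per_trial_counts, dtype=float)
    if counts.size < 2:
        raise ValueError("sniff CV needs >= 2 trials")
    mean = counts.mean()
    if mean == 0:
        raise ValueError("sniff CV undefined: mean count is zero")
    return float(counts.std(ddof=sd_ddof) / mean)


@dataclass
class SniffModulation:
    per_animal: pd.DataFrame        # rates and deltas per animal
    background_test: TestResult     # background - baseline, paired t
    target_test: TestResult         # target - baseline, paired t


def sniff_modulation(
    trial_rates: pd.DataFrame,
) -> SniffModulation:
    """Per-animal sniff-rate modulation relative to baseline.

    ``trial_rates`` has one row per trial with columns animal_id,
    rate_baseline, rate_background, rate_target (Hz), e.g. from
    :func:`sniff_rate` on the windows [-1, 0) s before the first
    background, [-1, 0) s before target, and [0, 1) s after target.
    """
    required = {"animal_id", "rate_baseline", "rate_background", "rate_target"}
    if not required <= set(trial_rates.columns):
        raise ValueError(f"trial_rates must have columns {sorted(required)}")
    per_animal = trial_rates.groupby("animal_id")[
        ["rate_baseline", "rate_background", "rate_target"]
    ].mean()
    if len(per_animal) < 2:
        raise ValueError("sniff modulation needs >= 2 animals")
    per_animal["delta_background"] = per_animal["rate_background"] - per_animal["rate_baseline"]
    per_animal["delta_target"] = per_animal["rate_target"] - per_animal["rate_baseline"]
    bg = paired_t(per_animal["rate_background"].to_numpy(), per_animal["rate_baseline"].to_numpy())
    tg = paired_t(per_animal["rate_target"].to_numpy(), per_animal["rate_baseline"].to_numpy())
    return SniffModulation(per_animal=per_animal, background_test=bg, target_test=tg)
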