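"""Per-ROI trace extraction, air-window z-scoring, and windowed responses.

The ROI value per frame is the mean band-passed dF/F0 over the ROI's
pixels; the trace is then z-scored at the ROI level against that trial's
7-s air window (population-SD convention by default, configurable).  An
alternative ordering — z-score each pixel against its own air window and
average z values across the ROI — is available behind ``pixel_level=True``.

Windows are half-open intervals in seconds relative to a named anchor;
a frame belongs to a window iff its onset time lies inside it.  Standard
windows:

    air            [-7, 0)   relative to first-background onset
    background_pre [-1, 0)   relative to target onset
    target_500ms   [0, 0.5)  relative to target onset
    target_1s      [0, 1)    relative to target onset

plus 1-s sliding windows ``slide{center:+.2f}`` at caller-chosen centers
relative to target onset.  The resulting long-format ResponseTable — one
row per (trial, ROI, window) mean z — is the hub every downstream
statistic consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import FilteredMovie

__all__ = [
    "ROISet",
    "ROITrace",
    "STANDARD_WINDOWS",
    "sliding_window_name",
    "extract_roi_traces",
    "window_response",
    "build_response_table",
    "lick_aligned_average",
]

# window -> (anchor event, start_s, stop_s); half-open [start, stop)
STANDARD_WINDOWS: dict[str, tuple[str, float, float]] = {
    "air": ("bg1_on", -7.0, 0.0),
    "background_pre": ("target_on", -1.0, 0.0),
    "target_500ms": ("target_on", 0.0, 0.5),
    "target_1s": ("target_on", 0.0, 1.0),
}


def sliding_window_name(center_s: float) -> str:
    return f"slide{center_s:+.2f}"


@dataclass
class ROISet:
    """Integer label mask: 0 = outside, k >= 1 = ROI k."""

    label_mask: np.ndarray

    def __post_init__(self):
        mask = np.asarray(self.label_mask)
        if mask.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if mask.min() < 0:
            raise ValueError("label mask must be non-negative")
        self.label_mask = mask.astype(np.int64)

    @property
    def roi_ids(self) -> np.ndarray:
        ids = np.unique(self.label_mask)
        return ids[ids > 0]


@dataclass
class ROITrace:
    roi_id: int
    trial_id: str
    dff_trace: np.ndarray
    z_trace: np.ndarray
    air_mean: float
    air_sd: float
    frame_rate_hz: float
    event_times_s: dict


def extract_roi_traces(
    movie: FilteredMovie,
    rois: ROISet,
    sd_ddof: int = 0,
    pixel_level: bool = False,
) -> list[ROITrace]:
    """Extract per-ROI z-scored traces from a band-passed dF/F0 movie.

    ``sd_ddof=0`` is the population-SD z-scoring convention (default);
    ``sd_ddof=1`` uses the sample SD.  ``pixel_level=True`` switches to
    z-scoring each pixel first and averaging z across the ROI.
    Raises for empty ROIs and for ROIs whose air-window SD is zero.
    """
    frames = movie.frames
    mask = rois.label_mask
    if mask.shape != frames.shape[1:]:
        raise ValueError("ROI mask shape does not match movie frames")
    fs = movie.geometry.frame_rate_hz
    bg1_on = movie.event_times_s["bg1_on"]
    n_air = int(np.floor(bg1_on * fs + 1e-9))
    if n_air < 1:
        raise ValueError("air window contains no frames")

    flat = frames.reshape(frames.shape[0], -1)
    traces = []
    for roi_id in rois.roi_ids:
        idx = np.flatnonzero(mask.ravel() == roi_id)
        if idx.size == 0:
            raise ValueError(f"ROI {roi_id} has zero pixels")
        pix = flat[:, idx]  # T x n_pix
        if pixel_level:
            mu = pix[:n_air].mean(axis=0)
            sd = pix[:n_air].std(axis=0, ddof=sd_ddof)
            if np.any(sd == 0):
                raise ValueError(f"ROI {roi_id}: zero air-window SD at a pixel")
            z = ((pix - mu) / sd).mean(axis=1)
            dff = pix.mean(axis=1)
            air_mean, air_sd = float(dff[:n_air].mean()), float(dff[:n_air].std(ddof=sd_ddof))
        else:
            dff = pix.mean(axis=1)
            air_mean = float(dff[:n_air].mean())
            air_sd = float(dff[:n_air].std(ddof=sd_ddof))
            if air_sd == 0:
                raise ValueError(f"ROI {roi_id}: air-window SD is zero, z undefined")
            z = (dff - air_mean) / air_sd
        traces.append(ROITrace(
            roi_id=int(roi_id), trial_id=movie.trial_id,
            dff_trace=dff, z_trace=z, air_mean=air_mean, air_sd=air_sd,
            frame_rate_hz=fs, event_times_s=dict(movie.event_times_s),
        ))
    return traces


def _window_frames(trace: ROITrace, anchor: str, start_s: float, stop_s: float) -> np.ndarray:
    t = np.arange(trace.z_trace.size) / trace.frame_rate_hz - trace.event_times_s[anchor]
    # half-open membership by frame-onset time; tiny epsilon guards the
    # boundary against float rounding of the anchor time
    eps = 1e-9
    return np.flatnonzero((t >= start_s - eps) & (t < stop_s - eps))


def window_response(trace: ROITrace, window: str | tuple[str, float, float]) -> float:
    """Mean z over the frames whose onset time falls in the window."""
    if isinstance(window, str):
        if window not in STANDARD_WINDOWS:
            raise KeyError(f"unknown window {window!r}")
        anchor, start_s, stop_s = STANDARD_WINDOWS[window]
    else:
        anchor, start_s, stop_s = window
    idx = _window_frames(trace, anchor, start_s, stop_s)
    if idx.size == 0:
        raise ValueError(f"window [{start_s}, {stop_s}) rel {anchor} contains no frames")
    return float(trace.z_trace[idx].mean())


def build_response_table(
    filtered_movies: list[FilteredMovie],
    rois: ROISet,
    trial_table: pd.DataFrame,
    sliding_centers_s: tuple[float, ...] = (),
    sd_ddof: int = 0,
    pixel_level: bool = False,
) -> pd.DataFrame:
    """Quantify every (trial, ROI, window) into one long-format table.

    Returns trial metadata merged in, so each row carries
    (animal_id, genotype, condition, trial_id, roi_id, window, mean_z)
    plus odor / valence / outcome labels.
    """
    windows: dict[str, tuple[str, float, float]] = dict(STANDARD_WINDOWS)
    for c in sliding_centers_s:
        windows[sliding_window_name(c)] = ("target_on", c - 0.5, c + 0.5)
    rows = []
    for movie in filtered_movies:
        for trace in extract_roi_traces(movie, rois, sd_ddof=sd_ddof, pixel_level=pixel_level):
            for wname, wdef in windows.items():
                rows.append({
                    "trial_id": trace.trial_id,
                    "roi_id": trace.roi_id,
                    "window": wname,
                    "mean_z": window_response(trace, wdef),
                })
    resp = pd.DataFrame(rows)
    missing = {"trial_id", "outcome", "valence"} - set(trial_table.columns)
    if missing:
        raise ValueError(f"trial table is missing columns: {sorted(missing)}")
    merged = resp.merge(trial_table, on="trial_id", how="left", validate="many_to_one")
    if not np.isfinite(merged["mean_z"]).all():
        raise ValueError("non-finite responses in ResponseTable")
    return merged


def lick_aligned_average(
    traces: list[ROITrace] | list[np.ndarray],
    first_lick_times_s: list[float],
    frame_rate_hz: float | None = None,
    pre_s: float = 2.0,
    post_s: float = 1.0,
):
    """Average traces aligned to the first lick (lick = time 0).

    Returns ``(t_axis_s, mean, sem)``; SEM across trials.  Only lick
    trials may be passed; traces shorter than the requested span around
    the lick are rejected.
    """
    if len(traces) == 0:
        raise ValueError("no lick trials to align")
    if len(traces) != len(first_lick_times_s):
        raise ValueError("one lick time per trace required")
    arrs, fs = [], frame_rate_hz
    for tr in traces:
        if isinstance(tr, ROITrace):
            arrs.append(tr.z_trace)
            fs = tr.frame_rate_hz
        else:
            arrs.append(np.asarray(tr, dtype=float))
    if fs is None:
        raise ValueError("frame_rate_hz required for plain-array traces")
    n_pre, n_post = int(round(pre_s * fs)), int(round(post_s * fs))
    aligned = []
    for arr, lick in zip(arrs, first_lick_times_s):
        if lick is None or not np.isfinite(lick):
            raise ValueError("lick-aligned averaging requires a recorded lick per trial")
        k = int(round(lick * fs))
        if k - n_pre < 0 or k + n_post > arr.size:
            raise ValueError("trace too short for the requested alignment span")
        aligned.append(arr[k - n_pre : k + n_post])
    stack = np.vstack(aligned)
    t_axis = (np.arange(-n_pre, n_post)) / fs
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0]) if stack.shape[0] > 1 else np.zeros_like(mean)
    return t_axis, mean, sem
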