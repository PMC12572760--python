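"""Background-period activity as a predictor of target-period activity.

Three linked analyses:

* sliding-window correlation: per (ROI, mixture), the Pearson correlation
  across trials between the 1-s target-window response and the response
  in a 1-s sliding window at offsets spanning the air and background
  periods; averaged over ROIs, then animals.
* trial split by background response: per variable background odor,
  trials are classed low (<= 25th percentile) or high (>= 75th
  percentile) by their mean background-period activity across included
  glomeruli; population-vector similarity is then compared between the
  groups, and the difference (similarity on high minus low trials) is the
  per-mixture "coding improvement" of low background activation.
* background suppression with learning: per (animal, background odor),
  the mean background-period response of included glomeruli in the naive
  vs expert condition, with a one-sided exact binomial test on the count
  of suppressed mixtures and a parallel target-window computation as a
  specificity check.

Percentiles use linear interpolation between order statistics; "highest
75th percentile" is read as >= P75 (the top quartile).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discriminability import (
    CORRECT_OUTCOMES,
    build_population_vectors,
    filter_included,
    nearest_opposite_similarity,
)
from .exact_stats import TestResult, binomial_test_exact, pearson_r, sign_test_exact, two_sample_t
from .roi_quantification import sliding_window_name

__all__ = [
    "CouplingCurve",
    "TrialSplit",
    "SuppressionReport",
    "sliding_window_correlation",
    "split_trials_by_background",
    "coding_improvement",
    "vapor_pressure_correlation",
    "background_suppression",
]

DEFAULT_OFFSETS = (-3.5, -3.0, -2.5, -2.0, -1.5, -1.0, -0.5)
TARGET_WINDOW = "target_1s"
BACKGROUND_WINDOW = "background_pre"


@dataclass
class CouplingCurve:
    offsets_s: np.ndarray           # centers of the 1-s sliding windows
    r_per_offset: np.ndarray        # mean Pearson r across ROIs then animals
    per_animal: pd.DataFrame        # animal_id x offset
    n_animals: int


def sliding_window_correlation(
    resp: pd.DataFrame,
    offsets_s: tuple[float, ...] = DEFAULT_OFFSETS,
    target_window: str = TARGET_WINDOW,
    min_trials: int = 3,
) -> CouplingCurve:
    """Correlation between target-window and sliding-window responses.

    Pearson r across trials per (animal, ROI, mixture); rows with zero
    variance in either variable are dropped.  ROI/mixture r values are
    averaged per animal, then across animals.
    """
    names = [sliding_window_name(c) for c in offsets_s]
    missing = [n for n in names if n not in set(resp["window"])]
    if missing:
        raise ValueError(f"ResponseTable lacks sliding windows {missing}; "
                         "pass sliding_centers_s when quantifying")
    wide = resp[resp["window"].isin(names + [target_window])].pivot_table(
        index=["animal_id", "roi_id", "mixture_id", "trial_id"],
        columns="window", values="mean_z",
    )
    per_animal_rows = {}
    for animal, adf in wide.groupby(level="animal_id"):
        rs = {n: [] for n in names}
        for (_, _roi, _mix), g in adf.groupby(level=["animal_id", "roi_id", "mixture_id"]):
            y = g[target_window].to_numpy()
            if y.size < min_trials or np.ptp(y) == 0:
                continue
            for n in names:
                x = g[n].to_numpy()
                if np.ptp(x) == 0:
                    continue
                rs[n].append(np.corrcoef(x, y)[0, 1])
        per_animal_rows[animal] = {n: (float(np.mean(v)) if v else np.nan) for n, v in rs.items()}
    per_animal = pd.DataFrame(per_animal_rows).T
    per_animal.index.name = "animal_id"
    per_animal.columns = list(offsets_s)
    curve = per_animal.mean(axis=0).to_numpy()
    return CouplingCurve(offsets_s=np.asarray(offsets_s), r_per_offset=curve,
                         per_animal=per_animal, n_animals=len(per_animal))


@dataclass
class TrialSplit:
    table: pd.DataFrame             # trial_id, background odor, value, group
    thresholds: pd.DataFrame        # per background odor: p25, p75


def split_trials_by_background(
    resp: pd.DataFrame,
    included: np.ndarray,
    window: str = BACKGROUND_WINDOW,
    min_trials: int = 8,
) -> TrialSplit:
    """Classify trials low / middle / high by mean background-period
    activity across the included glomeruli, per variable background odor.

    Thresholds are the 25th / 75th percentiles (linear interpolation) of
    that odor's trial values, pooled over all trials.  When P25 == P75
    every trial of that odor is degenerate and excluded.
    """
    sub = filter_included(resp[resp["window"] == window], included)
    if sub.empty:
        raise ValueError("no background-window responses for the included ROIs")
    per_trial = sub.groupby(
        ["variable_background_odor", "trial_id"], as_index=False
    )["mean_z"].mean().rename(columns={"mean_z": "background_value"})
    rows, th_rows = [], []
    for odor, grp in per_trial.groupby("variable_background_odor"):
        vals = grp["background_value"].to_numpy()
        if vals.size < min_trials:
            raise ValueError(
                f"background odor {odor!r} has {vals.size} trials; >= {min_trials} required")
        p25, p75 = np.percentile(vals, [25, 75])
        th_rows.append({"variable_background_odor": odor, "p25": p25, "p75": p75})
        for _, r in grp.iterrows():
            v = r["background_value"]
            if p25 == p75:
                group = "degenerate"
            elif v <= p25:
                group = "low"
            elif v >= p75:
                group = "high"
            else:
                group = "middle"
            rows.append({"trial_id": r["trial_id"], "variable_background_odor": odor,
                         "background_value": v, "group": group})
    return TrialSplit(table=pd.DataFrame(rows), thresholds=pd.DataFrame(th_rows))


@dataclass
class CodingImprovement:
    per_mixture: pd.DataFrame       # mixture_id, sim_high, sim_low, improvement
    sign_test: TestResult
    t_test: TestResult


def coding_improvement(
    resp: pd.DataFrame,
    split: TrialSplit,
    included: np.ndarray,
    window: str = "target_500ms",
) -> CodingImprovement:
    """Per-mixture nearest-opposite similarity on high- minus low-background
    trials (positive = low background activation improves separability).

    Population vectors are built per group from correct trials with the
    500 ms window.  Tested with a two-sided sign test on the count of
    mixtures with sim_high > sim_low and a two-sample t test.
    """
    groups = {}
    for gname in ("high", "low"):
        ids = split.table.loc[split.table["group"] == gname, "trial_id"]
        sub = resp[resp["trial_id"].isin(ids)]
        if sub.empty:
            raise ValueError(f"no trials in the {gname!r} background group")
        # per-mixture precondition (>= 1 correct trial in the group) is
        # applied mixture-wise: unanalyzable mixtures drop out
        vectors = build_population_vectors(sub, included, window=window, strict=False)
        groups[gname] = nearest_opposite_similarity(vectors)
    per_mix = pd.DataFrame({"sim_high": groups["high"], "sim_low": groups["low"]}).dropna()
    if per_mix.empty:
        raise ValueError("no mixture analyzable in both background groups")
    per_mix["improvement"] = per_mix["sim_high"] - per_mix["sim_low"]
    per_mix = per_mix.rename_axis("mixture_id").reset_index()
    nonzero = per_mix[per_mix["improvement"] != 0]
    if nonzero.empty:
        raise ValueError("all mixtures tie exactly; tests undefined")
    k = int((nonzero["improvement"] > 0).sum())
    sign = sign_test_exact(k, len(nonzero))
    t = two_sample_t(per_mix["sim_high"].to_numpy(), per_mix["sim_low"].to_numpy())
    return CodingImprovement(per_mixture=per_mix, sign_test=sign, t_test=t)


def vapor_pressure_correlation(
    improvements: pd.DataFrame, vapor_pressure_mmHg: dict[str, float]
) -> TestResult | None:
    """Pearson correlation of per-(animal, odor) coding improvement with
    the odor vapor pressure.  ``improvements`` needs columns ``odor_id``
    and ``improvement``.  Returns None (with a warning) when metadata is
    missing or the improvement has zero variance.
    """
    import warnings

    df = improvements.copy()
    df["vp"] = df["odor_id"].map(vapor_pressure_mmHg)
    if df["vp"].isna().any():
        missing = sorted(df.loc[df["vp"].isna(), "odor_id"].unique())
        warnings.warn(f"no vapor pressure for odor(s) {missing}; skipping correlation")
        return None
    agg = df.groupby(["animal_id", "odor_id"], as_index=False)[["improvement", "vp"]].mean() \
        if "animal_id" in df.columns else df
    if np.ptp(agg["improvement"].to_numpy()) == 0 or np.ptp(agg["vp"].to_numpy()) == 0:
        warnings.warn("zero variance; vapor-pressure correlation undefined")
        return None
    return pearson_r(agg["vp"].to_numpy(), agg["improvement"].to_numpy())


@dataclass
class SuppressionReport:
    per_mixture: pd.DataFrame       # animal, background odor, naive/expert means, ratio
    n_suppressed: int
    n_total: int
    binomial: TestResult
    target_check: pd.DataFrame      # same on the target window (specificity)
    target_n_suppressed: int
    target_binomial: TestResult


def _condition_means(
    resp: pd.DataFrame, included: np.ndarray, window: str, outcomes: tuple[str, ...] | None
) -> pd.DataFrame:
    sub = filter_included(resp[resp["window"] == window], included)
    if outcomes is not None:
        sub = sub[sub["outcome"].isin(outcomes)]
    if sub.empty:
        raise ValueError(f"no responses in window {window!r} after filtering")
    means = sub.groupby(
        ["animal_id", "variable_background_odor", "condition"]
    )["mean_z"].mean().unstack("condition")
    return means.dropna()


def background_suppression(
    resp: pd.DataFrame,
    included: np.ndarray,
    window: str = BACKGROUND_WINDOW,
    target_window: str = TARGET_WINDOW,
    correct_only: bool = False,
) -> SuppressionReport:
    """Naive-vs-expert background-period response per (animal, background
    odor), the count suppressed (expert < naive) with a one-sided exact
    binomial test (smaller tail), and the parallel target-window check on
    correct no-go trials.

    The background window ends at target onset, before any lick can
    occur, so by default all trials enter the background means (the
    larger sample halves the session-mean noise); ``correct_only=True``
    restricts to hits and correct rejections.
    """
    outcomes = CORRECT_OUTCOMES if correct_only else None
    bg = _condition_means(resp, included, window, outcomes)
    if not {"naive", "expert"} <= set(bg.columns):
        raise ValueError("background_suppression needs both naive and expert conditions")
    bg = bg.reset_index()
    bg["ratio"] = bg["expert"] / bg["naive"]
    bg["suppressed"] = bg["expert"] < bg["naive"]
    k, n = int(bg["suppressed"].sum()), len(bg)
    tgt = _condition_means(resp, included, target_window, ("correct_rejection",)).reset_index()
    tgt["ratio"] = tgt["expert"] / tgt["naive"]
    tgt["suppressed"] = tgt["expert"] < tgt["naive"]
    kt, nt = int(tgt["suppressed"].sum()), len(tgt)
    return SuppressionReport(
        per_mixture=bg, n_suppressed=k, n_total=n,
        binomial=binomial_test_exact(k, n),
        target_check=tgt, target_n_suppressed=kt,
        target_binomial=binomial_test_exact(kt, nt),
    )
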