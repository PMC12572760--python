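"""Trial-to-trial variability: coefficient of variation with inclusion
gates and the trial-matched subsampling control.

CV = SD / mean of the per-trial responses of one (glomerulus, mixture),
computed on correct-rejection trials in the 1 s window after target onset
(no licking, so the measure is free of motor-evoked activity).  Gates:

  session gate  >= 20 correct rejections per (animal, condition)
  ROI gate      at least one no-go mixture with trial-averaged response > 1 z
  pair gates    >= 6 repeats and mean response >= 0.1 z per (ROI, mixture)

Sample SD (ddof=1) by default; configurable.  The subsampling control
recomputes the CV in both conditions at the matched (smaller) trial count,
drawing without replacement with a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exact_stats import TestResult, paired_t

__all__ = [
    "CV_WINDOW",
    "cv_per_roi_mixture",
    "matched_subsample_cv",
    "condition_contrast",
]

CV_WINDOW = "target_1s"
MIN_TRIALS = 6
MIN_MEAN_Z = 0.1
MIN_SESSION_CR = 20
ROI_GATE_Z = 1.0


def _cv(values: np.ndarray, ddof: int) -> tuple[float, float, float]:
    mean = float(values.mean())
    sd = float(values.std(ddof=ddof)) if values.size > ddof else np.nan
    return mean, sd, (sd / mean if mean != 0 and np.isfinite(sd) else np.nan)


def _cr_responses(resp: pd.DataFrame, window: str) -> pd.DataFrame:
    sub = resp[(resp["window"] == window) & (resp["outcome"] == "correct_rejection")]
    if sub.empty:
        raise ValueError(f"no correct-rejection rows for window {window!r}")
    return sub


def cv_per_roi_mixture(
    resp: pd.DataFrame,
    window: str = CV_WINDOW,
    sd_ddof: int = 1,
    min_trials: int = MIN_TRIALS,
    min_mean_z: float = MIN_MEAN_Z,
    min_session_cr: int = MIN_SESSION_CR,
    roi_gate_z: float = ROI_GATE_Z,
) -> pd.DataFrame:
    """CVTable: one row per (animal, condition, roi, mixture) with the CV
    and an inclusion flag carrying the first failed gate as a reason code.
    """
    sub = _cr_responses(resp, window)
    n_cr = sub.groupby(["animal_id", "condition"])["trial_id"].nunique()
    # trial-averaged response per no-go mixture, max over mixtures
    mix_avg = sub.groupby(["animal_id", "condition", "roi_id", "mixture_id"])["mean_z"].mean()
    roi_best = mix_avg.groupby(["animal_id", "condition", "roi_id"]).max()

    rows = []
    for (animal, cond, roi, mix), grp in sub.groupby(
        ["animal_id", "condition", "roi_id", "mixture_id"], sort=True
    ):
        vals = grp["mean_z"].to_numpy()
        mean, sd, cv = _cv(vals, sd_ddof)
        reason = ""
        if n_cr.loc[(animal, cond)] < min_session_cr:
            reason = "session_lt_min_cr"
        elif roi_best.loc[(animal, cond, roi)] <= roi_gate_z:
            reason = "roi_no_response_gt_1z"
        elif vals.size < min_trials:
            reason = "fewer_than_min_trials"
        elif mean < min_mean_z:
            reason = "mean_below_min"
        rows.append({
            "animal_id": animal, "condition": cond, "roi_id": roi, "mixture_id": mix,
            "n_trials": int(vals.size), "mean_resp": mean, "sd_resp": sd,
            "cv": cv if reason == "" else np.nan,
            "included": reason == "", "reason": reason,
        })
    return pd.DataFrame(rows)


def matched_subsample_cv(
    resp: pd.DataFrame,
    seed: int = 0,
    window: str = CV_WINDOW,
    sd_ddof: int = 1,
    min_trials: int = MIN_TRIALS,
    min_mean_z: float = MIN_MEAN_Z,
    n_draws: int = 1,
) -> pd.DataFrame:
    """Trial-matched CV control: per (animal, roi, mixture), subsample the
    condition with more correct rejections (without replacement) down to
    the other's count before computing both CVs.

    One draw by default (matching the single reported control);
    ``n_draws > 1`` averages the CV over independent draws.  Pairs whose
    matched n falls below the repeat gate, or whose subsampled mean falls
    below the mean gate, are excluded.
    """
    sub = _cr_responses(resp, window)
    conds = sorted(sub["condition"].unique())
    if len(conds) != 2:
        raise ValueError(f"need exactly two conditions, got {conds}")
    rng = np.random.default_rng(seed)
    rows = []
    for (animal, roi, mix), grp in sub.groupby(["animal_id", "roi_id", "mixture_id"], sort=True):
        by_cond = {c: g.sort_values("trial_id")["mean_z"].to_numpy()
                   for c, g in grp.groupby("condition")}
        if set(by_cond) != set(conds):
            continue
        n_match = min(v.size for v in by_cond.values())
        if n_match < min_trials:
            continue
        cvs, means = {}, {}
        for c, vals in by_cond.items():
            draws = []
            for _ in range(n_draws):
                take = (rng.choice(vals.size, size=n_match, replace=False)
                        if vals.size > n_match else np.arange(vals.size))
                draws.append(_cv(vals[take], sd_ddof))
            means[c] = float(np.mean([d[0] for d in draws]))
            cvs[c] = float(np.mean([d[2] for d in draws]))
        if any(means[c] < min_mean_z for c in conds):
            continue
        row = {"animal_id": animal, "roi_id": roi, "mixture_id": mix, "n_matched": n_match}
        for c in conds:
            row[f"cv_{c}"] = cvs[c]
            row[f"mean_{c}"] = means[c]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ConditionContrast:
    per_animal: pd.DataFrame        # animal_id x condition mean CV
    grand_mean: dict                # condition -> (mean, sem, n_pairs)
    t_test: TestResult


def condition_contrast(cvtable: pd.DataFrame) -> ConditionContrast:
    """Per-animal mean CV per condition and the paired two-sided t test
    across animals (animals lacking either condition are dropped)."""
    inc = cvtable[cvtable["included"]] if "included" in cvtable.columns else cvtable
    if inc.empty:
        raise ValueError("no included (roi, mixture) pairs")
    conds = sorted(inc["condition"].unique())
    if len(conds) != 2:
        raise ValueError(f"need exactly two conditions, got {conds}")
    per_animal = inc.pivot_table(index="animal_id", columns="condition",
                                 values="cv", aggfunc="mean").dropna()
    if len(per_animal) < 2:
        raise ValueError("paired t test needs >= 2 animals with both conditions")
    grand = {}
    for c in conds:
        vals = inc.loc[inc["condition"] == c, "cv"].to_numpy()
        grand[c] = (float(vals.mean()),
                    float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan,
                    int(vals.size))
    test = paired_t(per_animal[conds[0]].to_numpy(), per_animal[conds[1]].to_numpy())
    return ConditionContrast(per_animal=per_animal, grand_mean=grand, t_test=test)
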