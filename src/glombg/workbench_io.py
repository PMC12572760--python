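"""File formats, pipeline configuration, and the end-to-end driver.

Conventions: coordinates are 0-based (row, column); time is in seconds
from acquisition start; windows are half-open.  Movies are multi-page
TIFF, one file per trial, frame order = time.  ROI masks are 16-bit label
TIFFs.  Tables are CSV with fixed column names; configs and summaries are
JSON.  Every summary records the config hash and seed for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import background_coupling as bc
from . import discriminability as dsc
from . import sniff_analysis as sniff
from . import variability as var
from .preprocessing import preprocess_trial
from .roi_quantification import ROISet, build_response_table
from .synthetic_data import (
    AcquisitionGeometry,
    ConditionParams,
    GroundTruth,
    LickModel,
    SniffModel,
    SynthConfig,
    TrialMovie,
    TrialTiming,
    default_odor_panel,
    make_glomerular_map,
    make_tuning,
    simulate_session,
)

__all__ = [
    "PipelineConfig",
    "write_movie_tiff",
    "read_movie_tiff",
    "write_label_mask",
    "read_label_mask",
    "write_trial_table",
    "read_trial_table",
    "validate_trial_table",
    "config_to_json",
    "config_from_json",
    "simulate_animal",
    "quantify_animal",
    "simulate_cohort",
    "run_pipeline",
]

TRIAL_TABLE_COLUMNS = [
    "trial_id", "session_id", "animal_id", "genotype", "condition",
    "variable_background_odor", "target_odor", "mixture_id",
    "valence", "outcome", "first_lick_s",
]
GENOTYPES = ("WT", "Shank3B_het", "Cntnap2_ko")


# ---------------------------------------------------------------------------
# codecs

def write_movie_tiff(path, movie: TrialMovie) -> None:
    tifffile.imwrite(str(path), np.asarray(movie.frames, dtype=np.float32))


def read_movie_tiff(path, geometry: AcquisitionGeometry, event_times_s: dict,
                    trial_id: str) -> TrialMovie:
    frames = tifffile.imread(str(path))
    if frames.ndim != 3:
        raise ValueError(f"{path}: expected a T x H x W stack, got shape {frames.shape}")
    return TrialMovie(frames=frames, geometry=geometry,
                      event_times_s=dict(event_times_s), trial_id=trial_id)


def write_label_mask(path, label_mask: np.ndarray) -> None:
    mask = np.asarray(label_mask)
    if mask.min() < 0:
        raise ValueError("label mask must be non-negative")
    if mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("label mask exceeds 16-bit label range")
    tifffile.imwrite(str(path), mask.astype(np.uint16))


def read_label_mask(path) -> np.ndarray:
    mask = tifffile.imread(str(path))
    if mask.ndim != 2:
        raise ValueError(f"{path}: label mask must be 2-D")
    if mask.min() < 0:
        raise ValueError(f"{path}: negative labels rejected")
    return mask.astype(np.int64)


def validate_trial_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(TRIAL_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing column(s): {sorted(missing)}")
    bad_outcome = df[
        ((df["valence"] == "go") & ~df["outcome"].isin(["hit", "miss"]))
        | ((df["valence"] == "no_go") & ~df["outcome"].isin(["correct_rejection", "false_alarm"]))
    ]
    if not bad_outcome.empty:
        raise ValueError(
            f"outcome inconsistent with valence for trial(s) "
            f"{bad_outcome['trial_id'].tolist()[:5]}"
        )
    lick_required = df["outcome"].isin(["hit", "false_alarm"])
    if df.loc[lick_required, "first_lick_s"].isna().any():
        raise ValueError("first_lick_s must be present for hit / false_alarm trials")
    if df.loc[~lick_required, "first_lick_s"].notna().any():
        raise ValueError("first_lick_s must be absent for miss / correct_rejection trials")
    return df


def write_trial_table(path, df: pd.DataFrame) -> None:
    validate_trial_table(df)
    df.to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_trial_table(df)


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class PipelineConfig:
    """Everything a reproducible end-to-end run needs.

    The synthetic generator block carries the study conditions; the
    analysis block carries the documented thresholds (inclusion z = 1,
    CV gates, percentile split) and convention switches (SD ddof,
    z-scoring order).  Round-trips losslessly through JSON.
    """

    synth: SynthConfig = field(default_factory=SynthConfig)
    n_animals: int = 2
    genotype: str = "Shank3B_het"
    conditions: tuple[str, ...] = ("naive", "expert")
    n_trials_per_condition: int = 32
    go_fraction: float = 0.5
    sliding_centers_s: tuple[float, ...] = bc.DEFAULT_OFFSETS
    inclusion_threshold_z: float = 1.0
    cv_min_trials: int = 6
    cv_min_mean_z: float = 0.1
    cv_min_session_cr: int = 20
    sd_ddof_z: int = 0
    sd_ddof_cv: int = 1
    pixel_level_z: bool = False
    seed: int = 0


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_to_json(config: PipelineConfig) -> str:
    return json.dumps(_to_jsonable(config), indent=2, sort_keys=True)


def config_from_json(text: str) -> PipelineConfig:
    d = json.loads(text)
    s = d["synth"]
    synth = SynthConfig(
        geometry=AcquisitionGeometry(
            pixel_size_um=s["geometry"]["pixel_size_um"],
            frame_rate_hz=s["geometry"]["frame_rate_hz"],
            fov_pixels=tuple(s["geometry"]["fov_pixels"]),
        ),
        timing=TrialTiming(**s["timing"]),
        n_glomeruli=s["n_glomeruli"],
        footprint_sigma_um=s["footprint_sigma_um"],
        frac_target_responsive=s["frac_target_responsive"],
        frac_background_responsive=s["frac_background_responsive"],
        conditions={k: ConditionParams(**v) for k, v in s["conditions"].items()},
        background_amplitude=s["background_amplitude"],
        target_amplitude=s["target_amplitude"],
        amplitude_cv=s["amplitude_cv"],
        response_amplitude_dff=s["response_amplitude_dff"],
        tau_rise_s=s["tau_rise_s"],
        tau_decay_s=s["tau_decay_s"],
        diffuse_field_sigma_um=s["diffuse_field_sigma_um"],
        diffuse_amplitude_dff=s["diffuse_amplitude_dff"],
        respiration_hz=s["respiration_hz"],
        respiration_amplitude=s["respiration_amplitude"],
        baseline_counts=s["baseline_counts"],
        shot_noise_sd=s["shot_noise_sd"],
        lick_model=LickModel(**s["lick_model"]),
        sniff_model=SniffModel(**s["sniff_model"]),
        seed=s["seed"],
    )
    return PipelineConfig(
        synth=synth,
        n_animals=d["n_animals"],
        genotype=d["genotype"],
        conditions=tuple(d["conditions"]),
        n_trials_per_condition=d["n_trials_per_condition"],
        go_fraction=d["go_fraction"],
        sliding_centers_s=tuple(d["sliding_centers_s"]),
        inclusion_threshold_z=d["inclusion_threshold_z"],
        cv_min_trials=d["cv_min_trials"],
        cv_min_mean_z=d["cv_min_mean_z"],
        cv_min_session_cr=d["cv_min_session_cr"],
        sd_ddof_z=d["sd_ddof_z"],
        sd_ddof_cv=d["sd_ddof_cv"],
        pixel_level_z=d["pixel_level_z"],
        seed=d["seed"],
    )


def config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(config_to_json(config).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# simulation + quantification driver

def simulate_animal(
    synth: SynthConfig,
    animal_id: str,
    genotype: str,
    conditions: tuple[str, ...],
    n_trials: int,
    go_fraction: float,
    seed: int,
):
    """Simulate one animal: a shared glomerular map / tuning and one
    session per condition.  Returns (sessions, ground_truth) where
    ``sessions[condition] = (movies, trial_table, sniff_traces)``.
    """
    gt = make_glomerular_map(synth, seed=seed)
    gt.tuning = make_tuning(synth, seed=seed + 1)
    gt.odors = default_odor_panel()
    sessions = {}
    for i, cond in enumerate(conditions):
        movies, table, sniffs, _ = simulate_session(
            synth, n_trials, cond, ground_truth=gt, animal_id=animal_id,
            genotype=genotype, go_fraction=go_fraction, seed=seed + 100 + i,
        )
        sessions[cond] = (movies, table, sniffs)
    return sessions, gt


def quantify_animal(
    sessions: dict,
    gt: GroundTruth,
    sliding_centers_s: tuple[float, ...] = (),
    sd_ddof: int = 0,
    pixel_level: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Preprocess and quantify every trial of one animal.

    Returns (response table, trial table) over all conditions.  Movies
    are processed one at a time to bound memory.
    """
    rois = ROISet(gt.roi_labels.astype(np.int64))
    resp_parts, table_parts = [], []
    for cond, (movies, table, _sniffs) in sessions.items():
        # generator: one filtered movie in memory at a time
        filtered = (preprocess_trial(m, reference=None, register=False) for m in movies)
        resp = build_response_table(
            filtered, rois, table,
            sliding_centers_s=sliding_centers_s, sd_ddof=sd_ddof, pixel_level=pixel_level,
        )
        resp_parts.append(resp)
        table_parts.append(table)
    return (pd.concat(resp_parts, ignore_index=True),
            pd.concat(table_parts, ignore_index=True))


def simulate_cohort(
    synth: SynthConfig,
    n_animals: int,
    genotype: str = "Shank3B_het",
    conditions: tuple[str, ...] = ("naive", "expert"),
    n_trials: int = 32,
    go_fraction: float = 0.5,
    sliding_centers_s: tuple[float, ...] = (),
    seed: int = 0,
    sd_ddof: int = 0,
    keep_sniffs: bool = False,
):
    """Simulate + preprocess + quantify a cohort of synthetic animals.

    Returns ``(resp, trials, ground_truths, sniffs)``; ``resp`` is the
    concatenated ResponseTable across animals and conditions.
    """
    resp_parts, trial_parts, gts, all_sniffs = [], [], {}, {}
    for a in range(n_animals):
        animal_id = f"{genotype.lower()}_{a:02d}"
        animal_seed = seed * 1009 + a * 13 + 1
        sessions, gt = simulate_animal(
            synth, animal_id, genotype, conditions, n_trials, go_fraction, animal_seed)
        resp, trials = quantify_animal(sessions, gt, sliding_centers_s, sd_ddof=sd_ddof)
        resp_parts.append(resp)
        trial_parts.append(trials)
        gts[animal_id] = gt
        if keep_sniffs:
            all_sniffs[animal_id] = {c: s[2] for c, s in sessions.items()}
    return (pd.concat(resp_parts, ignore_index=True),
            pd.concat(trial_parts, ignore_index=True), gts, all_sniffs)


# ---------------------------------------------------------------------------
# plots

def plot_coupling_curve(curve, path) -> None:
    """Mean background-target correlation vs sliding-window offset."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    for _, row in curve.per_animal.iterrows():
        ax.plot(curve.offsets_s, row.to_numpy(), color="0.7", lw=0.8)
    ax.plot(curve.offsets_s, curve.r_per_offset, color="tab:blue", lw=2,
            label=f"mean of {curve.n_animals} animals")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("window center rel. target onset (s)")
    ax.set_ylabel("Pearson r with 1-s target response")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_suppression_scatter(report, path) -> None:
    """Naive vs expert mean background response per (animal, odor)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3.4, 3.4))
    ax.scatter(report.per_mixture["naive"], report.per_mixture["expert"],
               s=18, color="tab:red", alpha=0.8)
    lim = max(report.per_mixture[["naive", "expert"]].max()) * 1.1
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlabel("naive background response (z)")
    ax.set_ylabel("expert background response (z)")
    ax.set_title(f"{report.n_suppressed}/{report.n_total} suppressed, "
                 f"p = {report.binomial.p:.2g}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# end-to-end pipeline

def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig, outdir, simulate: bool = True,
                 plots: bool = False) -> dict:
    """Execute the full analysis chain on a simulated cohort and write the
    report bundle (tables as CSV, summary as JSON) into ``outdir``.

    Stages: simulate -> preprocess -> quantify -> {discriminability,
    variability, coupling, sniff} -> exact statistics.  A stage failure
    aborts with the stage name in the exception message.  Identical
    configs produce identical summary JSON.
    """
    if not simulate:
        raise NotImplementedError("only --simulate runs are supported; movie-folder "
                                  "ingestion goes through the codec functions")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "n_animals": config.n_animals,
    }

    stage = "simulate+quantify"
    try:
        resp, trials, gts, sniffs = simulate_cohort(
            config.synth, config.n_animals, config.genotype, config.conditions,
            config.n_trials_per_condition, config.go_fraction,
            config.sliding_centers_s, seed=config.seed,
            sd_ddof=config.sd_ddof_z, keep_sniffs=True,
        )
        resp.to_csv(outdir / "response_table.csv", index=False)
        write_trial_table(outdir / "trial_table.csv", trials)
        for animal_id, gt in gts.items():
            write_label_mask(outdir / f"roi_labels_{animal_id}.tif", gt.roi_labels)

        stage = "discriminability"
        included = dsc.select_included_glomeruli(resp, threshold=config.inclusion_threshold_z)
        sims = {}
        for cond in config.conditions:
            rows = []
            for animal_id in sorted(resp["animal_id"].unique()):
                sub = resp[(resp["animal_id"] == animal_id) & (resp["condition"] == cond)]
                vec = dsc.build_population_vectors(sub, included, strict=False)
                sim = dsc.nearest_opposite_similarity(vec)
                rows += [{"animal_id": animal_id, "mixture_id": m, "similarity": s}
                         for m, s in sim.items()]
            sims[cond] = pd.DataFrame(rows)
        report = dsc.compare_conditions(sims["naive"], sims["expert"])
        report.table.to_csv(outdir / "similarity_report.csv", index=False)
        summary["discriminability"] = {
            "n_included_roi_pairs": int(len(included)),
            "k_decreased": report.k_decreased, "n": report.n,
            "sign_test_p": report.sign_test.p,
        }

        stage = "variability"
        cvtable = var.cv_per_roi_mixture(
            resp, sd_ddof=config.sd_ddof_cv, min_trials=config.cv_min_trials,
            min_mean_z=config.cv_min_mean_z, min_session_cr=config.cv_min_session_cr)
        cvtable.to_csv(outdir / "cv_table.csv", index=False)
        summary["variability"] = {"n_included_pairs": int(cvtable["included"].sum())}
        try:
            contrast = var.condition_contrast(cvtable)
            summary["variability"].update({
                "mean_cv": {c: contrast.grand_mean[c][0] for c in contrast.grand_mean},
                "paired_t_p": contrast.t_test.p,
            })
        except ValueError as e:
            summary["variability"]["note"] = str(e)

        stage = "coupling"
        curve = bc.sliding_window_correlation(resp, config.sliding_centers_s)
        curve.per_animal.to_csv(outdir / "coupling_curve.csv")
        if plots:
            plot_coupling_curve(curve, outdir / "coupling_curve.png")
        summary["coupling"] = {
            "offsets_s": list(map(float, curve.offsets_s)),
            "r_per_offset": [float(r) for r in curve.r_per_offset],
        }
        naive = resp[resp["condition"] == "naive"]
        imp_rows, skipped = [], []
        for animal_id in sorted(naive["animal_id"].unique()):
            sub = naive[naive["animal_id"] == animal_id]
            try:
                split = bc.split_trials_by_background(sub, included)
                ci = bc.coding_improvement(sub, split, included)
            except ValueError:
                # per-animal precondition failed (too few trials per odor
                # or no analyzable mixture); skip the animal, not the run
                skipped.append(animal_id)
                continue
            for _, r in ci.per_mixture.iterrows():
                imp_rows.append({"animal_id": animal_id, **r.to_dict()})
        imp = pd.DataFrame(imp_rows)
        imp.to_csv(outdir / "coding_improvement.csv", index=False)
        if len(imp):
            summary["coding_improvement"] = {
                "mean": float(imp["improvement"].mean()),
                "k_positive": int((imp["improvement"] > 0).sum()),
                "n": int((imp["improvement"] != 0).sum()),
                "animals_skipped": skipped,
            }
            # does the improvement track odor vapor pressure? (it should not)
            vp = {o.odor_id: o.vapor_pressure_mmHg for o in default_odor_panel()
                  if o.vapor_pressure_mmHg is not None}
            mix_odors = trials.drop_duplicates("mixture_id").set_index("mixture_id")
            for role, col in (("background", "variable_background_odor"),
                              ("target", "target_odor")):
                df = imp[["animal_id", "mixture_id", "improvement"]].copy()
                df["odor_id"] = df["mixture_id"].map(mix_odors[col])
                res = bc.vapor_pressure_correlation(df, vp)
                if res is not None:
                    summary["coding_improvement"][f"vapor_pressure_r_{role}"] = res.statistic
                    summary["coding_improvement"][f"vapor_pressure_p_{role}"] = res.p
        else:
            summary["coding_improvement"] = {"animals_skipped": skipped}
        supp = bc.background_suppression(resp, included)
        supp.per_mixture.to_csv(outdir / "suppression_report.csv", index=False)
        if plots:
            plot_suppression_scatter(supp, outdir / "suppression_scatter.png")
        summary["suppression"] = {
            "n_suppressed": supp.n_suppressed, "n_total": supp.n_total,
            "binomial_p": supp.binomial.p,
            "mean_ratio": float(supp.per_mixture["ratio"].mean()),
            "target_n_suppressed": supp.target_n_suppressed,
        }

        stage = "sniff"
        tm = config.synth.timing
        rate_rows = []
        for animal_id, by_cond in sniffs.items():
            for cond, traces in by_cond.items():
                for tr in traces:
                    onsets = sniff.detect_sniffs(tr)
                    rate_rows.append({
                        "animal_id": animal_id, "condition": cond, "trial_id": tr.trial_id,
                        "rate_baseline": sniff.sniff_rate(onsets, (tm.bg1_on - 1.0, tm.bg1_on)),
                        "rate_background": sniff.sniff_rate(onsets, (tm.target_on - 1.0, tm.target_on)),
                        "rate_target": sniff.sniff_rate(onsets, (tm.target_on, tm.target_on + 1.0)),
                    })
        rates = pd.DataFrame(rate_rows)
        rates.to_csv(outdir / "sniff_rates.csv", index=False)
        summary["sniff"] = {}
        for cond, grp in rates.groupby("condition"):
            entry = {k: float(grp[f"rate_{k}"].mean())
                     for k in ("baseline", "background", "target")}
            try:
                mod = sniff.sniff_modulation(grp)
                entry["background_vs_baseline_p"] = mod.background_test.p
                entry["target_vs_baseline_p"] = mod.target_test.p
            except ValueError:
                pass
            try:
                # per-animal CV of target-window sniff counts (1-s window,
                # so counts equal the rate values)
                cvs = [sniff.sniff_cv(g["rate_target"].to_numpy())
                       for _, g in grp.groupby("animal_id")
                       if len(g) >= 2 and g["rate_target"].mean() > 0]
                if cvs:
                    entry["rate_cv"] = float(np.mean(cvs))
            except ValueError:
                pass
            summary["sniff"][cond] = entry
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    summary = _round_floats(summary)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (outdir / "config.json").write_text(config_to_json(config))
    return summary
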