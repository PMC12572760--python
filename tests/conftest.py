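"""Shared fixtures: a small synthetic cohort, quantified once per session,
plus an analytic (movie-free) response model for large-trial statistics.

Everything is generated programmatically at test time; the geometry is
deliberately small (112 x 112 px, 16 well-separated glomeruli) so the
full movie pipeline stays fast while keeping the 13.2 um/px, 20 Hz
acquisition and the 7 s / 750 ms / 750 ms / 3 s trial structure.
"""

from __future__ import annotations

import numpy as np
import pytest

from glombg.synthetic_data import AcquisitionGeometry, SynthConfig
from glombg.workbench_io import simulate_animal, quantify_animal


def small_config(**overrides) -> SynthConfig:
    defaults = dict(
        geometry=AcquisitionGeometry(fov_pixels=(112, 112)),
        n_glomeruli=16,
        seed=7,
    )
    defaults.update(overrides)
    return SynthConfig(**defaults)


@pytest.fixture(scope="session")
def mini_cohort():
    """Two animals (16 glomeruli each) x {naive, expert} x 24 trials,
    quantified end to end.

    Behavioral accuracy is raised above the study defaults so that every
    mixture keeps correct trials at this tiny trial count; the fixture
    exercises pipeline mechanics, not the recovery statistics.
    """
    from glombg.synthetic_data import ConditionParams

    synth = small_config(conditions={
        "naive": ConditionParams(gain_cv=1.5, gain_coupling_rho=0.5,
                                 background_amplitude_scale=1.0, accuracy=0.85),
        "expert": ConditionParams(gain_cv=1.05, gain_coupling_rho=0.2,
                                  background_amplitude_scale=0.7, accuracy=0.95),
    })
    resp_parts, trial_parts, gts = [], [], {}
    for a in range(2):
        sessions, gt = simulate_animal(
            synth, f"mouse{a}", "Cntnap2_ko", ("naive", "expert"),
            n_trials=24, go_fraction=0.5, seed=100 + a)
        resp, trials = quantify_animal(sessions, gt, sliding_centers_s=(-2.0, -0.5))
        resp_parts.append(resp)
        trial_parts.append(trials)
        gts[f"mouse{a}"] = gt
    import pandas as pd

    return pd.concat(resp_parts, ignore_index=True), pd.concat(trial_parts, ignore_index=True), gts


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


READOUT_NOISE_Z = 0.245   # windowed-readout noise floor of the movie path
READOUT_Z_SCALE = 0.6     # approximate dff -> z conversion of the movie path


def analytic_response_table(cfg, n_trials, condition, gt, seed, animal_id, rng,
                            go_fraction=0.5):
    """ResponseTable from the generator's linear readout model, no movies.

    The movie pipeline measures (band-passed footprint readout) x
    (amplitude x gain x window-mean kinetics) plus a noise floor; that
    linear model is validated against the rendered pipeline by the
    ground-truth recovery test, so large-trial statistical properties can
    be exercised here at negligible cost.
    """
    import pandas as pd

    from glombg.synthetic_data import simulate_session

    _, table, _, gt = simulate_session(cfg, n_trials, condition, ground_truth=gt,
                                       animal_id=animal_id, go_fraction=go_fraction,
                                       seed=seed, render_movies=False)
    tm = cfg.timing
    fs = cfg.geometry.frame_rate_hz
    t = np.arange(int(round(tm.total_s * fs))) / fs

    def kern(on):
        k = np.zeros_like(t)
        d = (t >= on) & (t < tm.odor_off)
        k[d] = 1 - np.exp(-(t[d] - on) / cfg.tau_rise_s)
        return k

    k1, k2, kt = kern(tm.bg1_on), kern(tm.bg2_on), kern(tm.target_on)
    windows = {
        "background_pre": (t >= tm.target_on - 1) & (t < tm.target_on),
        "target_500ms": (t >= tm.target_on) & (t < tm.target_on + 0.5),
        "target_1s": (t >= tm.target_on) & (t < tm.target_on + 1.0),
    }
    cond = cfg.condition(condition)
    roi_ids = gt.tuning.index.to_numpy()
    gains = gt.gains[gt.gains.trial_id.isin(table.trial_id)]
    piv = {c: gains.pivot(index="trial_id", columns="roi_id", values=c)
              .loc[table.trial_id].to_numpy()
           for c in ("g_bg", "g_bg_post", "g_target")}
    a_vb = gt.tuning[table.variable_background_odor].to_numpy().T * cond.background_amplitude_scale
    a_fb = np.tile(gt.tuning["s_limonene"].to_numpy() * cond.background_amplitude_scale,
                   (len(table), 1))
    a_tg = gt.tuning[table.target_odor].to_numpy().T * cond.target_amplitude_scale
    parts = []
    for wname, m in windows.items():
        cb1, cb2, ct = k1[m].mean(), k2[m].mean(), kt[m].mean()
        if wname == "background_pre":
            val = (cb1 * a_vb + cb2 * a_fb) * piv["g_bg"]
        else:
            val = (cb1 * a_vb + cb2 * a_fb) * piv["g_bg_post"] + ct * a_tg * piv["g_target"]
        z = READOUT_Z_SCALE * val + rng.normal(0, READOUT_NOISE_Z, val.shape)
        df = pd.DataFrame(z, columns=roi_ids)
        df["trial_id"] = table.trial_id.to_numpy()
        long = df.melt(id_vars="trial_id", var_name="roi_id", value_name="mean_z")
        long["window"] = wname
        parts.append(long)
    resp = pd.concat(parts, ignore_index=True).merge(table, on="trial_id")
    return resp, table, gt
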