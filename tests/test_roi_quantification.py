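"""ROI trace extraction, z-scoring conventions, window arithmetic, and
ground-truth recovery of windowed responses on near-noise-free movies."""

import numpy as np
import pytest

from glombg.preprocessing import FilteredMovie, bandpass_movie, compute_dff, preprocess_trial
from glombg.roi_quantification import (
    ROISet,
    ROITrace,
    build_response_table,
    extract_roi_traces,
    lick_aligned_average,
    window_response,
)
from glombg.synthetic_data import AcquisitionGeometry, ConditionParams, simulate_session

from conftest import small_config

# toy 8x8 frames; the geometry record only supplies frame rate here
GEOM = AcquisitionGeometry(fov_pixels=(32, 32))
EVENTS = {"bg1_on": 7.0, "bg2_on": 7.75, "target_on": 8.5, "odor_off": 11.5}


def filtered_from_array(frames, trial_id="t0", geometry=GEOM, events=EVENTS):
    return FilteredMovie(frames=np.asarray(frames, dtype=float), geometry=geometry,
                         event_times_s=dict(events), trial_id=trial_id)


def mask_with_one_roi():
    mask = np.zeros((8, 8), dtype=int)
    mask[2:4, 2:4] = 1
    return ROISet(mask)


class TestExtractTraces:
    def test_roi_mean_of_uniform_pixels(self, rng):
        frames = rng.normal(0, 0.05, size=(160, 8, 8))
        frames[:, 2:4, 2:4] = 0.2
        traces = extract_roi_traces(filtered_from_array(frames), mask_with_one_roi())
        assert np.allclose(traces[0].dff_trace, 0.2)

    def test_z_scoring_population_sd_convention(self):
        # air values {0.00, 0.02, 0.04} repeated, response 0.05:
        # air mean 0.02, population SD 0.02*sqrt(2/3)... use exact values:
        frames = np.zeros((4, 8, 8))
        for t, v in enumerate([0.00, 0.02, 0.04, 0.05]):
            frames[t, 2:4, 2:4] = v
        events = dict(EVENTS)
        events["bg1_on"] = 3 / GEOM.frame_rate_hz  # 3 air frames
        tr = extract_roi_traces(filtered_from_array(frames, events=events),
                                mask_with_one_roi())[0]
        air = np.array([0.0, 0.02, 0.04])
        sd_pop = air.std()  # ddof=0
        assert tr.air_mean == pytest.approx(0.02)
        assert tr.air_sd == pytest.approx(sd_pop)
        assert tr.z_trace[3] == pytest.approx((0.05 - 0.02) / sd_pop)
        # with SD forced to 0.02 the hand-computed z is 1.5
        assert (0.05 - 0.02) / 0.02 == 1.5

    def test_air_window_z_stats_by_construction(self, rng):
        frames = rng.normal(size=(260, 8, 8))
        tr = extract_roi_traces(filtered_from_array(frames), mask_with_one_roi())[0]
        n_air = 140
        assert abs(tr.z_trace[:n_air].mean()) < 1e-10
        assert abs(tr.z_trace[:n_air].std() - 1) < 1e-10

    def test_constant_trace_rejected(self):
        frames = np.full((160, 8, 8), 0.3)
        with pytest.raises(ValueError, match="SD is zero"):
            extract_roi_traces(filtered_from_array(frames), mask_with_one_roi())

    def test_mask_shape_mismatch(self, rng):
        frames = rng.normal(size=(160, 6, 6))
        with pytest.raises(ValueError, match="shape"):
            extract_roi_traces(filtered_from_array(frames), mask_with_one_roi())

    def test_pixel_level_alternative_differs(self, rng):
        frames = rng.normal(size=(260, 8, 8)) * np.linspace(0.5, 2.0, 64).reshape(8, 8)
        fm = filtered_from_array(frames)
        roi = mask_with_one_roi()
        a = extract_roi_traces(fm, roi)[0].z_trace
        b = extract_roi_traces(fm, roi, pixel_level=True)[0].z_trace
        assert not np.allclose(a, b)


class TestWindows:
    def _trace(self, z):
        return ROITrace(roi_id=1, trial_id="t", dff_trace=z, z_trace=np.asarray(z, float),
                        air_mean=0.0, air_sd=1.0, frame_rate_hz=20.0, event_times_s=EVENTS)

    def test_constant_window_mean(self):
        z = np.zeros(260)
        z[170:180] = 2.0  # [0, 0.5) after target at frame 170
        assert window_response(self._trace(z), "target_500ms") == 2.0

    def test_target_500ms_is_ten_frames(self):
        z = np.zeros(260)
        z[170:180] = 1.0
        z[180] = 100.0  # first frame outside the half-open window
        assert window_response(self._trace(z), "target_500ms") == 1.0

    def test_background_pre_frame_indices(self):
        # target at 8.5 s -> frame 170; [-1, 0) covers frames 150..169
        z = np.zeros(260)
        z[150:170] = 3.0
        assert window_response(self._trace(z), "background_pre") == 3.0
        z2 = np.zeros(260)
        z2[149] = 100.0
        z2[170] = 100.0
        assert window_response(self._trace(z2), "background_pre") == 0.0

    def test_partition_background_pre_and_target_1s_disjoint(self):
        z = np.arange(260.0)
        bg = window_response(self._trace(z), "background_pre")
        t1 = window_response(self._trace(z), "target_1s")
        assert bg == np.mean(np.arange(150, 170))
        assert t1 == np.mean(np.arange(170, 190))

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="no frames"):
            window_response(self._trace(np.zeros(10)), "target_1s")


class TestResponseTableAndGroundTruth:
    def test_ground_truth_recovery_linear_oracle(self):
        """Windowed responses on a near-noise-free movie must match the
        linear prediction  M @ amplitudes, with M the ROI-mean of each
        band-passed footprint (cross-talk included)."""
        cfg = small_config(
            shot_noise_sd=1e-3, diffuse_amplitude_dff=0.0, respiration_amplitude=0.0,
            conditions={"naive": ConditionParams(gain_cv=0.5, gain_coupling_rho=0.0,
                                                 accuracy=1.0)},
            seed=17,
        )
        movies, table, _, gt = simulate_session(cfg, 1, "naive", go_fraction=0.0)
        movie = movies[0]
        fm = preprocess_trial(movie)
        rois = ROISet(gt.roi_labels.astype(int))
        traces = {t.roi_id: t for t in extract_roi_traces(fm, rois)}

        # oracle: band-pass each footprint once, average over ROI masks
        bp = bandpass_movie(gt.footprints.astype(float), cfg.geometry)
        n = gt.footprints.shape[0]
        # M[k-1, g] = mean over ROI k's pixels of glomerulus g's
        # band-passed footprint (cross-talk from neighbours included)
        M = np.zeros((n, n))
        for k in range(1, n + 1):
            sel = gt.roi_labels == k
            M[k - 1] = bp[:, sel].mean(axis=1)

        trial = table.iloc[0]
        gains = gt.gains.set_index("roi_id")
        # window-mean of the calcium kernels over target_1s, from the movie
        # timeline itself (frames 170..189 at 20 Hz)
        t_axis = np.arange(fm.frames.shape[0]) / 20.0
        win = (t_axis >= 8.5) & (t_axis < 9.5)

        def kernel(on):
            k = np.zeros_like(t_axis)
            during = (t_axis >= on) & (t_axis < 11.5)
            k[during] = 1 - np.exp(-(t_axis[during] - on) / cfg.tau_rise_s)
            return k[win].mean()

        amp = (gt.tuning[trial.variable_background_odor].to_numpy() * kernel(7.0)
               + gt.tuning["s_limonene"].to_numpy() * kernel(7.75)
               + gt.tuning[trial.target_odor].to_numpy() * kernel(8.5))
        amp = amp * gains["g_tg"].to_numpy() * cfg.response_amplitude_dff
        predicted_dff = M @ amp

        measured = np.array([
            window_response(traces[k], "target_1s") * traces[k].air_sd + traces[k].air_mean
            for k in range(1, n + 1)
        ])
        big = np.abs(predicted_dff) > 1e-4
        assert big.sum() > 10
        assert np.allclose(measured[big], predicted_dff[big], rtol=0.005, atol=1e-6)

    def test_build_response_table_schema(self, mini_cohort):
        resp, trials, _ = mini_cohort
        assert {"animal_id", "condition", "trial_id", "roi_id", "window",
                "mean_z", "outcome", "valence", "mixture_id"} <= set(resp.columns)
        # every (trial, roi) appears exactly once per window
        counts = resp.groupby(["trial_id", "roi_id", "window"]).size()
        assert (counts == 1).all()
        assert np.isfinite(resp["mean_z"]).all()

    def test_missing_trial_columns_rejected(self, rng):
        import pandas as pd

        frames = rng.normal(size=(260, 8, 8))
        fm = filtered_from_array(frames)
        bad = pd.DataFrame({"trial_id": ["t0"]})
        with pytest.raises(ValueError, match="missing columns"):
            build_response_table([fm], mask_with_one_roi(), bad)


class TestLickAlignedAverage:
    def test_identical_traces_zero_sem(self):
        tr = np.sin(np.linspace(0, 6, 260))
        t_axis, mean, sem = lick_aligned_average([tr, tr], [9.5, 9.5], frame_rate_hz=20.0)
        assert np.allclose(sem, 0.0)
        k = int(9.5 * 20)
        assert np.allclose(mean, tr[k - 40 : k + 20])

    def test_offset_traces_align(self):
        base = np.zeros(260)
        base[100] = 1.0  # event at frame 100
        shifted = np.roll(base, 5)
        t_axis, mean, _ = lick_aligned_average(
            [base, shifted], [100 / 20.0, 105 / 20.0], frame_rate_hz=20.0)
        peak = t_axis[np.argmax(mean)]
        assert peak == 0.0 and mean.max() == 1.0

    def test_ramp_rises_before_lick(self):
        # generator lick ramp: average across hits rises ~0.2 s pre-lick
        cfg = small_config(seed=23,
                           conditions={"naive": ConditionParams(accuracy=1.0)})
        movies, table, _, gt = simulate_session(cfg, 6, "naive", go_fraction=1.0)
        rois = ROISet(gt.roi_labels.astype(int))
        zs, licks = [], []
        for m in movies:
            lick = table.set_index("trial_id").loc[m.trial_id, "first_lick_s"]
            tr = extract_roi_traces(preprocess_trial(m), rois)[0]
            zs.append(tr.z_trace)
            licks.append(float(lick))
        t_axis, mean, _ = lick_aligned_average(zs, licks, frame_rate_hz=20.0,
                                               pre_s=1.0, post_s=0.5)
        before = mean[(t_axis >= -0.6) & (t_axis < -0.3)].mean()
        ramp_window = mean[(t_axis >= -0.15) & (t_axis < 0.0)].mean()
        assert ramp_window > before

    def test_requires_lick_trials(self):
        with pytest.raises(ValueError):
            lick_aligned_average([], [])
        with pytest.raises(ValueError):
            lick_aligned_average([np.zeros(260)], [np.nan], frame_rate_hz=20.0)
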