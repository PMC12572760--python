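"""Sliding-window coupling, percentile trial split, coding improvement,
vapor-pressure correlation, and suppression counting."""

import numpy as np
import pandas as pd
import pytest

from glombg.background_coupling import (
    background_suppression,
    coding_improvement,
    sliding_window_correlation,
    split_trials_by_background,
    vapor_pressure_correlation,
)
from glombg.roi_quantification import sliding_window_name


def coupling_table(x, y, offsets=(-0.5,), animal="m0", roi=1, mixture="b1+ng"):
    """Rows pairing target_1s responses y with sliding-window responses x."""
    rows = []
    for i, (xi, yi) in enumerate(zip(x, y)):
        base = {"animal_id": animal, "roi_id": roi, "mixture_id": mixture,
                "trial_id": f"t{i}", "outcome": "correct_rejection",
                "valence": "no_go", "variable_background_odor": mixture.split("+")[0]}
        rows.append({**base, "window": "target_1s", "mean_z": yi})
        for c in offsets:
            rows.append({**base, "window": sliding_window_name(c), "mean_z": xi})
    return pd.DataFrame(rows)


class TestSlidingCorrelation:
    def test_duplicated_predictor_gives_one(self, rng):
        y = rng.normal(size=20)
        curve = sliding_window_correlation(coupling_table(y, y), offsets_s=(-0.5,))
        assert curve.r_per_offset[0] == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        x, y = rng.normal(size=(2, 1000))
        curve = sliding_window_correlation(coupling_table(x, y), offsets_s=(-0.5,))
        assert abs(curve.r_per_offset[0]) < 0.07

    def test_zero_variance_rows_dropped(self, rng):
        df = coupling_table(np.ones(10), rng.normal(size=10))
        curve = sliding_window_correlation(df, offsets_s=(-0.5,))
        assert np.isnan(curve.r_per_offset[0])  # nothing left to average

    def test_missing_window_is_reported(self, rng):
        df = coupling_table(rng.normal(size=5), rng.normal(size=5))
        with pytest.raises(ValueError, match="sliding windows"):
            sliding_window_correlation(df, offsets_s=(-2.5,))


def split_input(values_by_odor, roi_ids=(1,)):
    rows = []
    for odor, values in values_by_odor.items():
        for i, v in enumerate(values):
            for roi in roi_ids:
                rows.append({
                    "animal_id": "m0", "roi_id": roi, "window": "background_pre",
                    "mean_z": v, "trial_id": f"{odor}_t{i}",
                    "variable_background_odor": odor, "outcome": "correct_rejection",
                    "valence": "no_go", "mixture_id": f"{odor}+ng",
                })
    return pd.DataFrame(rows)


class TestTrialSplit:
    def test_linear_interpolation_percentiles(self):
        split = split_trials_by_background(split_input({"a": list(range(1, 9))}),
                                           included=np.array([1]))
        th = split.thresholds.iloc[0]
        assert th.p25 == pytest.approx(2.75) and th.p75 == pytest.approx(6.25)
        groups = split.table.set_index("trial_id").group
        assert set(split.table[split.table.group == "low"].background_value) == {1, 2}
        assert set(split.table[split.table.group == "high"].background_value) == {7, 8}
        assert (groups.loc[["a_t2", "a_t3", "a_t4", "a_t5"]] == "middle").all()

    def test_all_equal_degenerate(self):
        split = split_trials_by_background(split_input({"a": [2.0] * 10}),
                                           included=np.array([1]))
        assert (split.table.group == "degenerate").all()

    def test_split_independent_per_odor(self):
        split = split_trials_by_background(
            split_input({"a": list(range(1, 9)), "b": [v + 100 for v in range(1, 9)]}),
            included=np.array([1]))
        low_b = split.table[(split.table.variable_background_odor == "b")
                            & (split.table.group == "low")]
        assert set(low_b.background_value) == {101, 102}

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            split_trials_by_background(split_input({"a": [1, 2, 3]}),
                                       included=np.array([1]))

    def test_groups_partition_nondegenerate_trials(self, rng):
        split = split_trials_by_background(
            split_input({"a": list(rng.normal(size=40))}), included=np.array([1]))
        assert set(split.table.group) <= {"low", "middle", "high"}
        low = set(split.table[split.table.group == "low"].trial_id)
        high = set(split.table[split.table.group == "high"].trial_id)
        assert not (low & high)
        assert len(split.table) == 40


class TestVaporPressure:
    def test_exact_linear_gives_one(self):
        vp = {"a": 4.8, "b": 8.0, "c": 12.8}
        df = pd.DataFrame({"animal_id": "m0", "odor_id": list(vp),
                           "improvement": [2 * v + 1 for v in vp.values()]})
        res = vapor_pressure_correlation(df, vp)
        assert res.statistic == pytest.approx(1.0)

    def test_constant_improvement_flagged(self):
        vp = {"a": 4.8, "b": 8.0}
        df = pd.DataFrame({"animal_id": "m0", "odor_id": list(vp), "improvement": [1.0, 1.0]})
        with pytest.warns(UserWarning, match="zero variance"):
            assert vapor_pressure_correlation(df, vp) is None

    def test_missing_metadata_skips_with_warning(self):
        df = pd.DataFrame({"animal_id": "m0", "odor_id": ["a", "zz"], "improvement": [1.0, 2.0]})
        with pytest.warns(UserWarning, match="no vapor pressure"):
            assert vapor_pressure_correlation(df, {"a": 4.8}) is None

    def test_shuffled_pairing_is_null(self, rng):
        # permutation oracle: shuffled improvements give small |r| typically
        vp = {f"o{i}": float(v) for i, v in enumerate(rng.uniform(4, 13, 16))}
        imp = rng.normal(size=16)
        rs = []
        for _ in range(300):
            perm = rng.permutation(16)
            df = pd.DataFrame({"animal_id": "m0", "odor_id": list(vp),
                               "improvement": imp[perm]})
            rs.append(vapor_pressure_correlation(df, vp).statistic)
        assert abs(np.mean(rs)) < 0.05


def suppression_table(naive_by_odor, expert_by_odor, animal="m0", roi=1):
    rows = []
    for cond, by_odor in (("naive", naive_by_odor), ("expert", expert_by_odor)):
        for odor, values in by_odor.items():
            for i, v in enumerate(values):
                for window, z in (("background_pre", v), ("target_1s", v + 1.0)):
                    rows.append({
                        "animal_id": animal, "condition": cond, "roi_id": roi,
                        "window": window, "mean_z": z,
                        "trial_id": f"{animal}_{cond}_{odor}_{i}",
                        "variable_background_odor": odor, "mixture_id": f"{odor}+ng",
                        "outcome": "correct_rejection", "valence": "no_go",
                    })
    return pd.DataFrame(rows)


class TestSuppression:
    def test_equal_conditions_ratio_one(self):
        df = suppression_table({"a": [1.0] * 4}, {"a": [1.0] * 4})
        rep = background_suppression(df, included=np.array([1]))
        assert rep.per_mixture.ratio.iloc[0] == pytest.approx(1.0)
        assert rep.n_suppressed == 0

    def test_counts_and_binomial(self):
        naive = {f"o{i}": [1.0] * 4 for i in range(4)}
        expert = {f"o{i}": [0.7] * 4 for i in range(3)}
        expert["o3"] = [1.5] * 4
        rep = background_suppression(suppression_table(naive, expert),
                                     included=np.array([1]))
        assert rep.n_suppressed == 3 and rep.n_total == 4
        # one-sided smaller tail: P(X>=3), X~Bin(4,1/2) = 5/16
        assert rep.binomial.p == pytest.approx(5 / 16)

    def test_target_check_reported(self):
        df = suppression_table({"a": [1.0] * 4}, {"a": [0.5] * 4})
        rep = background_suppression(df, included=np.array([1]))
        assert rep.target_check is not None
        assert {"naive", "expert", "ratio"} <= set(rep.target_check.columns)


class TestCodingImprovement:
    def test_identical_groups_zero(self, rng):
        # identical high/low trial responses -> improvement exactly 0 -> error
        # (all ties); construct near-identical groups instead
        rows = []
        for odor in ("a", "b"):
            for i in range(16):
                val = "go" if i % 2 else "no_go"
                out = "hit" if val == "go" else "correct_rejection"
                bg_val = float(i)  # deterministic split
                for roi in (1, 2, 3):
                    z = {1: 2.0, 2: 1.0, 3: 0.5}[roi] + (0.3 if val == "go" else 0.0)
                    rows.append({
                        "animal_id": "m0", "roi_id": roi, "trial_id": f"{odor}{i}",
                        "variable_background_odor": odor, "mixture_id": f"{odor}+{val}",
                        "valence": val, "outcome": out,
                        "window": "background_pre", "mean_z": bg_val,
                    })
                    rows.append({
                        "animal_id": "m0", "roi_id": roi, "trial_id": f"{odor}{i}",
                        "variable_background_odor": odor, "mixture_id": f"{odor}+{val}",
                        "valence": val, "outcome": out,
                        "window": "target_500ms", "mean_z": z,
                    })
        df = pd.DataFrame(rows)
        split = split_trials_by_background(df, included=np.array([1, 2, 3]))
        with pytest.raises(ValueError, match="tie"):
            coding_improvement(df, split, included=np.array([1, 2, 3]))
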