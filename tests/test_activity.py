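"""Burst-Duration summarization, window extraction, traces and CSV round trips."""
import numpy as np
import pandas as pd
import pytest

import vmrstats as v
from vmrstats.errors import (
    MalformedInputError,
    SchemaError,
    ValidationError,
    WindowOutOfRangeError,
)


def _frames(moved_by_second, fps=30, animal="a1"):
    """Build a frame table from a list of per-second moved-frame counts."""
    moved = np.concatenate(
        [
            np.concatenate([np.ones(k, dtype=int), np.zeros(fps - k, dtype=int)])
            for k in moved_by_second
        ]
    )
    return v.FrameMovementTable(
        pd.DataFrame(
            {"animal_id": animal, "frame_index": np.arange(len(moved)), "moved": moved}
        ),
        fps=fps,
    )


class TestSummarizeBurstDuration:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([15], [0.5]),
            ([30], [1.0]),
            ([0], [0.0]),
            ([10, 0, 0], [1 / 3, 0.0, 0.0]),
        ],
    )
    def test_fraction_of_moved_frames(self, counts, expected):
        act = v.summarize_burst_duration(_frames(counts))
        assert act.data["second"].tolist() == list(range(1, len(counts) + 1))
        np.testing.assert_allclose(act.data["activity"].to_numpy(), expected)

    def test_partial_tail_second_dropped(self):
        fr = _frames([15, 15])
        fr = v.FrameMovementTable(fr.data.iloc[:-10], fps=30)  # second 2 incomplete
        act = v.summarize_burst_duration(fr)
        assert act.data["second"].tolist() == [1]

    def test_conservation_of_moved_frames(self, rng):
        """Sum of activity * fps over complete seconds equals the moved count."""
        counts = rng.integers(0, 31, size=20)
        act = v.summarize_burst_duration(_frames(list(counts)))
        assert act.data["activity"].sum() * 30 == pytest.approx(counts.sum())

    def test_duplicate_frame_rejected(self):
        df = pd.DataFrame({"animal_id": "a", "frame_index": [0, 0], "moved": [0, 1]})
        with pytest.raises(MalformedInputError, match="duplicate"):
            v.FrameMovementTable(df, fps=30)

    def test_nonbinary_moved_rejected(self):
        df = pd.DataFrame({"animal_id": "a", "frame_index": [0, 1], "moved": [0, 2]})
        with pytest.raises(MalformedInputError, match="moved"):
            v.FrameMovementTable(df, fps=30)

    def test_burst_threshold_removes_short_bouts(self):
        moved = np.zeros(60, dtype=int)
        moved[5:7] = 1   # 2-frame bout: removed at threshold 3
        moved[20:25] = 1  # 5-frame bout: kept
        fr = v.FrameMovementTable(
            pd.DataFrame({"animal_id": "a", "frame_index": np.arange(60), "moved": moved}),
            fps=30,
        )
        out = v.apply_burst_threshold(fr, 3)
        assert out.data["moved"].sum() == 5


class TestExtractWindows:
    def test_window_index_arithmetic(self, tiny_activity):
        sched = v.StimulusSchedule(
            pd.DataFrame(
                {"event_time_s": [3], "transition": ["on"], "trial_index": [1]}
            )
        )
        w = v.extract_windows(tiny_activity, sched, pre_len=2, post_len=2)
        a1 = w.data[w.data["animal_id"] == "a1"]
        assert a1["rel_second"].tolist() == [-1, 0, 1, 2]
        # windowed values are the original values at the mapped seconds
        assert (a1["activity"] == 0.2).all()

    def test_event_near_boundary_rejected(self, tiny_activity):
        sched = v.StimulusSchedule(
            pd.DataFrame(
                {"event_time_s": [4], "transition": ["on"], "trial_index": [1]}
            )
        )
        with pytest.raises(WindowOutOfRangeError, match="4"):
            v.extract_windows(tiny_activity, sched, pre_len=2, post_len=2)

    def test_incomplete_animal_excluded_per_event_only(self, tiny_activity):
        df = tiny_activity.data
        df = df[~((df["animal_id"] == "a2") & (df["second"] == 3))]
        act = v.ActivityMatrix(df)
        sched = v.StimulusSchedule(
            pd.DataFrame(
                {
                    "event_time_s": [2, 4],
                    "transition": ["on", "off"],
                    "trial_index": [1, 1],
                }
            )
        )
        w = v.extract_windows(act, sched, pre_len=1, post_len=1)
        a2 = w.data[w.data["animal_id"] == "a2"]
        assert sorted(a2["event_time_s"].unique()) == [4]  # dropped from event 2 only
        assert w.n_excluded == 1

    def test_six_windows_for_three_trials(self, small_windows, small_config):
        per_animal = small_windows.data.groupby("animal_id")["event_time_s"].nunique()
        assert (per_animal == 2 * small_config.n_trials).all()

    def test_values_never_fabricated(self, small_experiment, small_windows):
        activity, _, _ = small_experiment
        merged = small_windows.data.assign(
            second=lambda d: d["event_time_s"] + d["rel_second"]
        ).merge(
            activity.data[["animal_id", "second", "activity"]],
            on=["animal_id", "second"],
            suffixes=("_win", "_orig"),
        )
        assert (merged["activity_win"] == merged["activity_orig"]).all()


class TestSummarizeTraces:
    def test_two_constant_vectors(self, tiny_activity):
        sched = v.StimulusSchedule(
            pd.DataFrame(
                {"event_time_s": [2], "transition": ["on"], "trial_index": [1]}
            )
        )
        w = v.extract_windows(tiny_activity, sched, pre_len=2, post_len=2)
        tr = v.summarize_traces(w, ["strain"])
        np.testing.assert_allclose(tr.data["mean"], 0.3, atol=1e-15)
        np.testing.assert_allclose(tr.data["sd"], np.sqrt(0.02), rtol=1e-12)
        assert (tr.data["n"] == 2).all()

    def test_single_vector_sd_zero(self, tiny_activity):
        sub = v.ActivityMatrix(tiny_activity.data[tiny_activity.data.animal_id == "a1"])
        sched = v.StimulusSchedule(
            pd.DataFrame(
                {"event_time_s": [2], "transition": ["on"], "trial_index": [1]}
            )
        )
        w = v.extract_windows(sub, sched, pre_len=2, post_len=2)
        tr = v.summarize_traces(w, ["strain"])
        assert (tr.data["sd"] == 0).all() and (tr.data["n"] == 1).all()

    def test_mean_invariant_to_row_order_and_split(self, small_windows):
        tr = v.summarize_traces(small_windows, ["strain"])
        shuffled = v.WindowedActivitySet(
            small_windows.data.sample(frac=1, random_state=0),
            small_windows.pre_len,
            small_windows.post_len,
        )
        tr2 = v.summarize_traces(shuffled, ["strain"])
        merged = tr.data.merge(tr2.data, on=["strain", "rel_second"])
        np.testing.assert_allclose(merged["mean_x"], merged["mean_y"], atol=1e-12)
        # split into strains and recombine with weighted means == pooled mean
        split = v.summarize_traces(small_windows, ["strain", "stage_dpf"]).data
        w_mean = (
            split.assign(wm=lambda d: d["mean"] * d["n"])
            .groupby(["strain", "rel_second"])
            .apply(lambda g: g["wm"].sum() / g["n"].sum(), include_groups=False)
            .rename("mean_recombined")
            .reset_index()
        )
        merged = tr.data.merge(w_mean, on=["strain", "rel_second"])
        np.testing.assert_allclose(
            merged["mean"], merged["mean_recombined"], atol=1e-12
        )


class TestRoundTrips:
    def test_activity_round_trip(self, tiny_activity, tmp_path):
        path = tmp_path / "act.csv"
        v.write_activity_table(tiny_activity, path)
        back = v.read_activity_table(path)
        pd.testing.assert_frame_equal(back.data, tiny_activity.data)

    def test_windows_round_trip(self, small_windows, tmp_path):
        path = tmp_path / "win.csv"
        v.write_windows(small_windows, path)
        back = v.read_windows(path)
        assert back.pre_len == small_windows.pre_len
        assert back.post_len == small_windows.post_len
        np.testing.assert_array_equal(
            back.data["activity"].to_numpy(), small_windows.data["activity"].to_numpy()
        )

    def test_frame_table_round_trip_keeps_fps(self, tmp_path):
        fr = _frames([10, 20], fps=30)
        path = tmp_path / "frames.csv"
        v.write_frame_table(fr, path)
        back = v.read_frame_table(path)
        assert back.fps == 30
        pd.testing.assert_frame_equal(back.data, fr.data)

    def test_activity_out_of_bounds_rejected(self, tiny_activity, tmp_path):
        df = tiny_activity.data.copy()
        df.loc[3, "activity"] = 1.2
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="row 3"):
            v.read_activity_table(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"animal_id": ["a"], "second": [1]}).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="activity"):
            v.read_activity_table(path)

    def test_non_alternating_schedule_rejected(self, tmp_path):
        path = tmp_path / "sched.csv"
        pd.DataFrame(
            {
                "event_time_s": [10, 20],
                "transition": ["on", "on"],
                "trial_index": [1, 2],
            }
        ).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="alternate"):
            v.read_schedule(path)

    def test_non_integer_event_time_rejected(self):
        with pytest.raises(SchemaError, match="integer"):
            v.StimulusSchedule(
                pd.DataFrame(
                    {
                        "event_time_s": [10.5],
                        "transition": ["on"],
                        "trial_index": [1],
                    }
                )
            )
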