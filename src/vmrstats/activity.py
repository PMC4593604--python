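"""Activity data model: Burst Duration, stimulus windows, mean traces.

The per-second activity measure is the *Burst Duration*: the fraction of
video frames within one second in which an animal is detected moving.  With a
camera running at ``fps`` frames per second, second ``s`` (1-based) summarizes
the frames falling in the half-open interval ``[s-1, s)`` seconds, i.e.
0-based frame indices ``(s-1)*fps .. s*fps - 1``.  Relative to a stimulus
event, second 0 is the last pre-change second and second 1 the first
post-change second; the same convention is used everywhere in the package.

Containers are thin dataclasses around long-form :class:`pandas.DataFrame`
objects whose column layout matches the CSV interchange format exactly, so
reading and writing are trivial round trips.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    MalformedInputError,
    SchemaError,
    ValidationError,
    WindowOutOfRangeError,
)

logger = logging.getLogger(__name__)

#: metadata columns carried per animal through every container
METADATA_COLUMNS = ["strain", "stage_dpf", "well", "bio_rep", "plate_id"]

ACTIVITY_COLUMNS = ["animal_id"] + METADATA_COLUMNS + ["second", "activity"]
FRAME_COLUMNS = ["animal_id", "frame_index", "moved"]
SCHEDULE_COLUMNS = ["event_time_s", "transition", "trial_index"]
WINDOW_COLUMNS = (
    ["animal_id"]
    + METADATA_COLUMNS
    + ["event_time_s", "stimulus", "trial_index", "rel_second", "activity"]
)


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required columns: {missing}")


@dataclass
class FrameMovementTable:
    """Per-frame binary movement calls for each animal.

    ``data`` holds one row per (animal, frame) with columns ``animal_id``,
    ``frame_index`` (0-based, absolute) and ``moved`` (0/1).  Optional
    metadata columns (strain etc.) are carried through to the summarized
    activity table when present.
    """

    data: pd.DataFrame
    fps: int = 30

    def __post_init__(self):
        _require_columns(self.data, FRAME_COLUMNS, "frame movement table")
        if self.fps < 1:
            raise ValidationError(f"fps must be >= 1, got {self.fps}")
        moved = self.data["moved"].to_numpy()
        bad = ~np.isin(moved, (0, 1))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise MalformedInputError(
                f"moved flag outside {{0,1}} at row {row} "
                f"(value {moved[np.flatnonzero(bad)[0]]!r})"
            )
        if self.data.duplicated(subset=["animal_id", "frame_index"]).any():
            dup = self.data[self.data.duplicated(subset=["animal_id", "frame_index"])]
            raise MalformedInputError(
                "duplicate (animal_id, frame_index) pairs, first at "
                f"animal {dup.iloc[0]['animal_id']!r} frame {dup.iloc[0]['frame_index']}"
            )


@dataclass
class ActivityMatrix:
    """Per-animal, per-second Burst Duration values with factor metadata.

    The universal input of every statistic in the package.  ``data`` is long
    form with columns ``animal_id, strain, stage_dpf, well, bio_rep,
    plate_id, second, activity``; one row per (animal, second); activity in
    [0, 1]; ``second`` is 1-based absolute experiment time.
    """

    data: pd.DataFrame

    def __post_init__(self):
        _require_columns(self.data, ACTIVITY_COLUMNS, "activity table")
        act = self.data["activity"].to_numpy(dtype=float)
        bad = (act < 0) | (act > 1) | ~np.isfinite(act)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"activity outside [0, 1] at row {row} (value {act[row]})"
            )
        if self.data.duplicated(subset=["animal_id", "second"]).any():
            raise MalformedInputError("duplicate (animal_id, second) pairs")

    @property
    def animals(self) -> pd.DataFrame:
        """One metadata row per animal."""
        return (
            self.data[["animal_id"] + METADATA_COLUMNS]
            .drop_duplicates("animal_id")
            .set_index("animal_id")
        )


@dataclass
class StimulusSchedule:
    """Light On/Off transition times with technical-repeat (trial) indices."""

    events: pd.DataFrame

    def __post_init__(self):
        _require_columns(self.events, SCHEDULE_COLUMNS, "stimulus schedule")
        ev = self.events
        times = ev["event_time_s"].to_numpy()
        if not np.array_equal(times, times.astype(int)):
            raise SchemaError("event times must be integer second boundaries")
        if len(times) > 1 and not (np.diff(times) > 0).all():
            raise SchemaError("event times must be strictly increasing")
        trans = ev["transition"].str.lower()
        if not trans.isin(["on", "off"]).all():
            raise SchemaError("transition must be 'on' or 'off'")
        if (trans.to_numpy()[1:] == trans.to_numpy()[:-1]).any():
            raise SchemaError("transitions must alternate on/off")

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class WindowedActivitySet:
    """Fixed-length activity vectors aligned to light-change events.

    ``data`` is long form: one row per (animal, event, relative second) with
    the activity value, its stimulus label (``on``/``off``), trial index and
    all animal metadata.  Relative seconds run ``-pre_len+1 .. 0`` (before the
    change) and ``1 .. post_len`` (after); every retained (animal, event) pair
    has a complete set of seconds.
    """

    data: pd.DataFrame
    pre_len: int = 30
    post_len: int = 30
    n_excluded: int = 0

    def __post_init__(self):
        _require_columns(self.data, WINDOW_COLUMNS, "windowed activity set")

    def profile_matrix(
        self, rel_lo: int, rel_hi: int, mask: pd.Series | None = None
    ) -> tuple[np.ndarray, pd.DataFrame]:
        """Pivot to an (observations x seconds) matrix over ``rel_lo..rel_hi``.

        Each row is one (animal, event) observation; columns are the relative
        seconds in increasing order.  Returns the matrix together with one
        label row per observation (animal metadata, stimulus, trial).
        """
        df = self.data if mask is None else self.data[mask]
        df = df[(df["rel_second"] >= rel_lo) & (df["rel_second"] <= rel_hi)]
        wide = df.pivot_table(
            index=["animal_id", "event_time_s"],
            columns="rel_second",
            values="activity",
            aggfunc="first",
        ).sort_index(axis=1)
        wide = wide.dropna()
        labels = (
            df.drop_duplicates(["animal_id", "event_time_s"])
            .set_index(["animal_id", "event_time_s"])
            .loc[wide.index, METADATA_COLUMNS + ["stimulus", "trial_index"]]
            .reset_index()
        )
        return wide.to_numpy(dtype=float), labels


@dataclass
class TraceSummary:
    """Group mean +/- SD traces over relative seconds (plotting/export data)."""

    data: pd.DataFrame = field(default_factory=pd.DataFrame)


def apply_burst_threshold(frames: FrameMovementTable, threshold: int) -> FrameMovementTable:
    """Zero out movement bouts shorter than ``threshold`` consecutive frames.

    Off by default throughout the package; provided for setups that want to
    discard small movements before summarization.
    """
    if threshold <= 1:
        return frames
    df = frames.data.sort_values(["animal_id", "frame_index"]).copy()
    out = []
    for _, grp in df.groupby("animal_id", sort=False):
        moved = grp["moved"].to_numpy().astype(int)
        # run-length scan over consecutive moved frames
        edges = np.flatnonzero(np.diff(np.concatenate(([0], moved, [0]))))
        starts, ends = edges[::2], edges[1::2]
        for a, b in zip(starts, ends):
            if b - a < threshold:
                moved[a:b] = 0
        grp = grp.copy()
        grp["moved"] = moved
        out.append(grp)
    return FrameMovementTable(pd.concat(out, ignore_index=True), fps=frames.fps)


def summarize_burst_duration(frames: FrameMovementTable) -> ActivityMatrix:
    """Collapse per-frame movement calls to per-second Burst Duration.

    Second ``s`` gets the fraction of moved frames among the ``fps`` frames
    with indices ``(s-1)*fps .. s*fps - 1``.  A trailing second with fewer
    than ``fps`` recorded frames is dropped.
    """
    fps = frames.fps
    df = frames.data
    meta_cols = [c for c in METADATA_COLUMNS if c in df.columns]
    rows = []
    for animal, grp in df.groupby("animal_id", sort=True):
        idx = grp["frame_index"].to_numpy(dtype=np.int64)
        moved = grp["moved"].to_numpy(dtype=np.int64)
        second = idx // fps + 1  # 1-based: frames [0, fps) -> second 1
        counts = pd.Series(moved).groupby(second).sum()
        nframes = pd.Series(np.ones_like(moved)).groupby(second).sum()
        complete = nframes[nframes == fps].index
        dropped = len(nframes) - len(complete)
        if dropped:
            logger.info(
                "animal %r: dropped %d partial second(s) at the recording tail",
                animal,
                dropped,
            )
        sec_df = pd.DataFrame(
            {
                "animal_id": animal,
                "second": complete.to_numpy(),
                "activity": counts.loc[complete].to_numpy() / fps,
            }
        )
        for c in meta_cols:
            sec_df[c] = grp[c].iloc[0]
        rows.append(sec_df)
    out = pd.concat(rows, ignore_index=True)
    for c in METADATA_COLUMNS:
        if c not in out.columns:
            out[c] = "NA"
    return ActivityMatrix(out[ACTIVITY_COLUMNS])


def extract_windows(
    activity: ActivityMatrix,
    schedule: StimulusSchedule,
    pre_len: int = 30,
    post_len: int = 30,
) -> WindowedActivitySet:
    """Cut stimulus-aligned windows out of the absolute-time activity table.

    For an event at absolute second ``E`` the pre-change vector covers
    absolute seconds ``E-pre_len+1 .. E`` (relative ``-pre_len+1 .. 0``) and
    the post-change vector ``E+1 .. E+post_len`` (relative ``1 ..
    post_len``).  Animals missing any second of a window are excluded from
    that event only (complete case); the exclusion count is logged and kept
    on the returned object.
    """
    if pre_len < 1 or post_len < 1:
        raise ValidationError("pre_len and post_len must be >= 1")
    df = activity.data
    smin, smax = int(df["second"].min()), int(df["second"].max())
    pieces = []
    n_excluded = 0
    for ev in schedule.events.itertuples(index=False):
        e = int(ev.event_time_s)
        lo, hi = e - pre_len + 1, e + post_len
        if lo < smin or hi > smax:
            raise WindowOutOfRangeError(
                e,
                f"event at {e}s needs seconds {lo}..{hi} but the recording "
                f"covers {smin}..{smax}",
            )
        win = df[(df["second"] >= lo) & (df["second"] <= hi)].copy()
        counts = win.groupby("animal_id")["second"].size()
        complete = counts[counts == pre_len + post_len].index
        n_excluded += int((counts != pre_len + post_len).sum())
        win = win[win["animal_id"].isin(complete)]
        win["event_time_s"] = e
        win["stimulus"] = str(ev.transition).lower()
        win["trial_index"] = int(ev.trial_index)
        win["rel_second"] = win["second"] - e
        pieces.append(win[WINDOW_COLUMNS])
    if n_excluded:
        logger.warning(
            "extract_windows: excluded %d (animal, event) pairs with incomplete windows",
            n_excluded,
        )
    out = pd.concat(pieces, ignore_index=True) if pieces else pd.DataFrame(columns=WINDOW_COLUMNS)
    return WindowedActivitySet(out, pre_len=pre_len, post_len=post_len, n_excluded=n_excluded)


def summarize_traces(windows: WindowedActivitySet, grouping: list[str]) -> TraceSummary:
    """Mean, sample SD (ddof=1; 0 when n=1) and n per group and relative second."""
    df = windows.data
    for g in grouping:
        if g not in df.columns:
            raise SchemaError(f"grouping field {g!r} not present in window metadata")
    agg = (
        df.groupby(grouping + ["rel_second"], observed=True)["activity"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0, n="size")
        .reset_index()
    )
    return TraceSummary(agg)


# ---------------------------------------------------------------------------
# CSV readers/writers.  One dialect: comma-delimited, UTF-8, '.' decimal,
# header required.  Floats are written with 17 significant digits so a
# write -> read cycle reproduces float64 values bit-exactly.
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"


def write_activity_table(activity: ActivityMatrix, path) -> None:
    activity.data.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_activity_table(path) -> ActivityMatrix:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ACTIVITY_COLUMNS, f"activity table {path}")
    return ActivityMatrix(df[ACTIVITY_COLUMNS])


def write_frame_table(frames: FrameMovementTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fps={frames.fps}\n")
        frames.data.to_csv(fh, index=False)


def read_frame_table(path, fps: int | None = None) -> FrameMovementTable:
    """Read a frame table; fps comes from a ``# fps=N`` header comment unless given."""
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            if fps is None and "fps=" in first:
                fps = int(first.split("fps=")[1].strip())
            df = pd.read_csv(fh, float_precision="round_trip")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, float_precision="round_trip")
    if fps is None:
        fps = 30
    _require_columns(df, FRAME_COLUMNS, f"frame table {path}")
    return FrameMovementTable(df, fps=fps)


def write_schedule(schedule: StimulusSchedule, path) -> None:
    schedule.events.to_csv(path, index=False)


def read_schedule(path) -> StimulusSchedule:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, SCHEDULE_COLUMNS, f"stimulus schedule {path}")
    return StimulusSchedule(df)


def write_windows(windows: WindowedActivitySet, path) -> None:
    windows.data.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_windows(path) -> WindowedActivitySet:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, WINDOW_COLUMNS, f"windowed activity set {path}")
    rel = df["rel_second"]
    return WindowedActivitySet(
        df, pre_len=int(-rel.min()) + 1, post_len=int(rel.max())
    )
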