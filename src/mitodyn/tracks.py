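"""Trajectory tables: container, CSV round trip, and localization linking.

The trajectory CSV dialect is ``trajectory_id,frame,time_s,x_um,y_um`` with an
optional ``true_state`` column ('bound'/'free', simulation ground truth).
Linking is a deliberately simple greedy nearest-neighbour tracker used as
plumbing for simulated localizations; production trackers (multi-hypothesis
MTT-style software) are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("trajectory_id", "frame", "time_s", "x_um", "y_um")


@dataclass
class TrajectorySet:
    """A collection of per-particle localization tracks.

    ``df`` holds one row per localization, sorted by (trajectory_id, frame).
    ``frame_interval`` is the camera frame time in seconds and is the common
    currency every downstream stage relies on.
    """

    df: pd.DataFrame
    frame_interval: float
    source: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        self.df = self.df.sort_values(
            ["trajectory_id", "frame"], kind="stable"
        ).reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.df
        if len(df) == 0:
            return
        if not np.isfinite(df[["x_um", "y_um", "time_s"]].to_numpy()).all():
            raise ValueError("non-finite coordinates or times")
        dup = df.duplicated(subset=["trajectory_id", "frame"])
        if dup.any():
            row = df.index[dup][0]
            raise ValueError(
                f"duplicated (trajectory_id, frame) at row {row}: "
                f"{df.loc[row, ['trajectory_id', 'frame']].tolist()}"
            )
        same = df["trajectory_id"].to_numpy()[1:] == df["trajectory_id"].to_numpy()[:-1]
        dframe = np.diff(df["frame"].to_numpy())
        bad = same & (dframe <= 0)
        if bad.any():
            row = int(np.nonzero(bad)[0][0]) + 1
            raise ValueError(f"non-increasing frame index within trajectory at row {row}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_trajectories(self) -> int:
        return self.df["trajectory_id"].nunique()

    def groupby(self):
        return self.df.groupby("trajectory_id", sort=True)

    def track_lengths(self) -> pd.Series:
        """Number of localizations per trajectory."""
        return self.df.groupby("trajectory_id").size()

    def write_csv(self, path) -> None:
        cols = [c for c in (*REQUIRED_COLUMNS, "true_state") if c in self.df.columns]
        out = self.df[cols].copy()
        out.to_csv(path, index=False, float_format="%.6f")


def read_trajectories(path, frame_interval: float) -> TrajectorySet:
    """Read a trajectory CSV, validating the dialect and the invariants.

    Raises ``ValueError`` with a row-level message for missing columns,
    duplicated or non-monotone frames within a trajectory, and NaN
    coordinates.  A header-only file yields an empty TrajectorySet.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if len(df) and df[["x_um", "y_um"]].isna().any().any():
        row = int(df.index[df[["x_um", "y_um"]].isna().any(axis=1)][0])
        raise ValueError(f"{path}: NaN coordinate at row {row}")
    df["frame"] = df["frame"].astype(int)
    return TrajectorySet(df=df, frame_interval=frame_interval, source=str(path))


def write_trajectories(tracks: TrajectorySet, path) -> None:
    tracks.write_csv(path)


def read_localizations(path) -> pd.DataFrame:
    """Read a localization CSV (``frame,x_um,y_um[,intensity]``)."""
    df = pd.read_csv(path)
    for c in ("frame", "x_um", "y_um"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing required column {c!r}")
    if len(df) and (df["frame"] < 0).any():
        raise ValueError(f"{path}: negative frame index")
    return df


def link_localizations(
    locs: pd.DataFrame,
    max_jump: float,
    max_gap: int = 1,
    frame_interval: float = 1.0,
) -> TrajectorySet:
    """Greedy nearest-neighbour frame-to-frame linking with gap closing.

    Each detection links to the nearest unclaimed track end within
    ``max_jump`` µm per frame step over at most ``max_gap + 1`` frame steps;
    ties break by smaller distance, then by lower trajectory id.  Unlinked
    detections seed new trajectories.  This greedy scheme is adequate at
    simulation densities (≲0.1 particles/µm²) and is validated against
    ground-truth simulated tracks, not against real dense data.
    """
    if max_jump <= 0:
        raise ValueError("max_jump must be > 0")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")

    rows: list[tuple[int, int, float, float, float]] = []
    # open track ends: trajectory_id -> (frame, x, y)
    ends: dict[int, tuple[int, float, float]] = {}
    next_id = 0
    for frame in sorted(locs["frame"].unique()):
        sub = locs[locs["frame"] == frame]
        xs = sub["x_um"].to_numpy(float)
        ys = sub["y_um"].to_numpy(float)
        # drop expired track ends
        ends = {
            tid: e for tid, e in ends.items() if frame - e[0] <= max_gap + 1
        }
        candidates = []
        for tid, (f0, x0, y0) in ends.items():
            steps = frame - f0
            d = np.hypot(xs - x0, ys - y0)
            for j in range(len(sub)):
                if d[j] <= max_jump * steps:
                    candidates.append((d[j], tid, j))
        candidates.sort(key=lambda c: (c[0], c[1]))
        claimed_t: set[int] = set()
        claimed_d: set[int] = set()
        assign: dict[int, int] = {}
        for d, tid, j in candidates:
            if tid in claimed_t or j in claimed_d:
                continue
            claimed_t.add(tid)
            claimed_d.add(j)
            assign[j] = tid
        for j in range(len(sub)):
            tid = assign.get(j)
            if tid is None:
                tid = next_id
                next_id += 1
            ends[tid] = (int(frame), float(xs[j]), float(ys[j]))
            rows.append((tid, int(frame), frame * frame_interval,
                         float(xs[j]), float(ys[j])))

    df = pd.DataFrame(
        rows, columns=["trajectory_id", "frame", "time_s", "x_um", "y_um"]
    )
    return TrajectorySet(df=df, frame_interval=frame_interval, source="linked")


__all__ = [
    "TrajectorySet", "read_trajectories", "write_trajectories",
    "read_localizations", "link_localizations", "REQUIRED_COLUMNS",
]
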