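"""Rendition tables: reading, writing, validation and time covariates.

A *rendition* is one production of the target syllable/utterance. The
behavioral record of an experiment is an ordered table of renditions with a
day index, a time-of-day fraction ``h`` in [0, 1) (local midnight = 0), the
pitch in Hz, and -- during the feedback period only -- the white-noise (WN)
threshold, the hit flag and the contingency direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PitchTrajectory",
    "TrajectoryFormatError",
    "TrajectoryValidationError",
    "read_trajectory",
    "write_trajectory",
    "split_baseline_feedback",
    "history_counts",
]

#: canonical column order for rendition tables on disk
COLUMNS = ["subject", "day", "h", "pitch_hz", "hit", "threshold_hz", "contingency"]


class TrajectoryFormatError(ValueError):
    """Malformed rendition table (missing columns, bad dialect)."""


class TrajectoryValidationError(ValueError):
    """Structurally valid table whose contents violate an invariant."""


@dataclass
class PitchTrajectory:
    """Ordered sequence of renditions of one subject.

    The table is stored as a :class:`pandas.DataFrame` with columns
    ``day`` (int), ``h`` (float in [0, 1)), ``pitch_hz`` (float > 0) and
    nullable ``hit``, ``threshold_hz``, ``contingency``.
    """

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        _validate(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def pitch(self) -> np.ndarray:
        return self.df["pitch_hz"].to_numpy(dtype=float)

    @property
    def day(self) -> np.ndarray:
        return self.df["day"].to_numpy(dtype=int)

    @property
    def h(self) -> np.ndarray:
        return self.df["h"].to_numpy(dtype=float)

    @property
    def threshold(self) -> np.ndarray:
        """Threshold in Hz, NaN during baseline."""
        return self.df["threshold_hz"].to_numpy(dtype=float)

    @property
    def hit(self) -> np.ndarray:
        """Hit flags as float (1.0 hit, 0.0 escape, NaN baseline)."""
        return self.df["hit"].to_numpy(dtype=float)

    @property
    def is_feedback(self) -> np.ndarray:
        return np.isfinite(self.threshold)

    @property
    def contingency(self) -> str | None:
        vals = self.df["contingency"].dropna().unique()
        if len(vals) == 0:
            return None
        if len(vals) > 1:
            raise TrajectoryValidationError(
                f"multiple contingency directions in one trajectory: {vals}"
            )
        return str(vals[0])

    @property
    def seconds(self) -> np.ndarray:
        """Within-day time in seconds (h * 86400)."""
        return self.h * 86400.0

    def slice(self, mask_or_index) -> "PitchTrajectory":
        return PitchTrajectory(self.df.loc[mask_or_index].copy(), dict(self.meta))


def _validate(df: pd.DataFrame) -> None:
    for col in ("day", "h", "pitch_hz"):
        if col not in df.columns:
            raise TrajectoryFormatError(f"missing required column {col!r}")
    for col in ("hit", "threshold_hz", "contingency"):
        if col not in df.columns:
            df[col] = np.nan
    if "subject" not in df.columns:
        df["subject"] = "unknown"

    if len(df) < 2:
        raise TrajectoryValidationError("a trajectory needs at least 2 renditions")

    pitch = df["pitch_hz"].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(pitch) | (pitch <= 0))
    if bad.size:
        raise TrajectoryValidationError(
            f"non-positive or non-finite pitch on row {int(bad[0])}"
        )

    day = df["day"].to_numpy()
    if np.any(np.diff(day) < 0):
        raise TrajectoryValidationError("day indices must be non-decreasing")

    h = df["h"].to_numpy(dtype=float)
    if np.any((h < 0) | (h >= 1)):
        raise TrajectoryValidationError("time-of-day fraction h must lie in [0, 1)")
    key = day.astype(float) + h
    if np.any(np.diff(key) <= 0):
        raise TrajectoryValidationError(
            "renditions must be strictly ordered by (day, h)"
        )

    thr = df["threshold_hz"].to_numpy(dtype=float)
    hit = df["hit"].to_numpy(dtype=float)
    if np.any(np.isfinite(thr) != np.isfinite(hit)):
        raise TrajectoryValidationError(
            "hit and threshold must be present/absent together"
        )

    cont = df["contingency"]
    for c, check in (("low", np.less), ("high", np.greater)):
        m = (cont == c) & np.isfinite(thr)
        if m.any():
            expect = check(pitch[m.to_numpy()], thr[m.to_numpy()]).astype(float)
            if not np.array_equal(expect, hit[m.to_numpy()]):
                raise TrajectoryValidationError(
                    f"hit flags inconsistent with contingency={c!r} and thresholds"
                )


def read_trajectory(path, dialect: dict | None = None) -> PitchTrajectory:
    """Read a delimited rendition table (CSV/TSV autodetected).

    Parameters
    ----------
    path
        Delimited text file with a header row. Required columns: ``pitch_hz``
        and either (``day``, ``h``) or an ISO-8601 ``timestamp``.
    dialect
        Optional map from the canonical column names to the file's column
        names, e.g. ``{"pitch_hz": "frequency"}``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})

    if "pitch_hz" not in df.columns:
        raise TrajectoryFormatError("missing required column 'pitch_hz'")

    if "timestamp" in df.columns and not {"day", "h"} <= set(df.columns):
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
        midnight = ts.dt.normalize()
        df["day"] = (midnight - midnight.iloc[0]).dt.days
        df["h"] = (ts - midnight).dt.total_seconds() / 86400.0
        df = df.drop(columns=["timestamp"])
    if not {"day", "h"} <= set(df.columns):
        raise TrajectoryFormatError(
            "need either columns ('day', 'h') or an ISO-8601 'timestamp'"
        )

    meta = {"source": str(path)}
    if "subject" in df.columns:
        subj = df["subject"].dropna().unique()
        if len(subj) == 1:
            meta["subject"] = str(subj[0])
    return PitchTrajectory(df, meta)


def write_trajectory(traj: PitchTrajectory, path) -> None:
    """Write a rendition table re-readable by :func:`read_trajectory`."""
    out = traj.df.reindex(columns=COLUMNS)
    out.to_csv(path, index=False)


def split_baseline_feedback(
    traj: PitchTrajectory,
) -> tuple[PitchTrajectory | None, PitchTrajectory | None]:
    """Split into the baseline prefix and the feedback (WN) suffix.

    The feedback period must be a contiguous suffix: a threshold present
    before a threshold-free rendition is a structure error. Either part may
    be ``None`` if empty.
    """
    fb = traj.is_feedback
    if fb.any():
        onset = int(np.argmax(fb))
        if not fb[onset:].all():
            raise TrajectoryValidationError(
                "feedback renditions must form a contiguous suffix"
            )
    else:
        onset = len(traj)
    base = traj.slice(traj.df.index[:onset]) if onset >= 2 else None
    feed = traj.slice(traj.df.index[onset:]) if len(traj) - onset >= 2 else None
    return base, feed


def history_counts(traj: PitchTrajectory, x: float = 2.0, n_h: int = 5) -> np.ndarray:
    """Recent-singing counts n_h(t): renditions within the last ``x`` seconds.

    Counts renditions strictly inside the half-open window
    ``(time_t - x, time_t)`` on the same day, clipped to ``n_h - 1`` so that
    the history-offset index ``1 + n_h(t)`` lies in ``{1, ..., n_h}``. The
    window never crosses midnight. The first rendition of each day has
    count 0.
    """
    if x <= 0:
        raise ValueError("history horizon x must be > 0")
    if n_h < 1:
        raise ValueError("history ceiling n_h must be >= 1")
    day = traj.day
    sec = traj.seconds
    out = np.zeros(len(traj), dtype=int)
    for d in np.unique(day):
        idx = np.flatnonzero(day == d)
        t = sec[idx]
        lo = np.searchsorted(t, t - x, side="right")
        out[idx] = np.arange(len(idx)) - lo
    return np.minimum(out, n_h - 1)


def save_param_bundle(path, bundle: dict) -> None:
    """Write a fitted-parameter bundle as JSON."""
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(bundle, indent=2, default=_default))


def load_param_bundle(path) -> dict:
    return json.loads(Path(path).read_text())
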