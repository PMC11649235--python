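"""Centroid-tracking ingestion and speed/distance kinematics.

The pipeline's raw input is a per-frame centroid track (pixels, fixed
frame rate) with optional binary annotation channels for airborne (jump)
and tail-rattle states.  A calibration coefficient — centimetres per
pixel, determined from the known arena size — converts pixel
displacements to physical speed in cm/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InputError

__all__ = ["Trajectory", "SpeedSeries", "load_tracking", "save_tracking",
           "compute_speed", "distance_traveled"]

#: timestamps must be uniform to within this tolerance (s)
_T_UNIFORM_TOL = 1e-6


@dataclass
class Trajectory:
    """Per-frame centroid positions with calibration and annotations.

    Parameters
    ----------
    fps : float
        Frame rate in frames per second.
    t : ndarray
        Per-frame timestamps (s), strictly increasing and uniform.
    x, y : ndarray
        Centroid position in pixels.
    calibration : float
        Centimetres per pixel (> 0).
    channels : dict of str -> ndarray
        Optional per-frame binary annotations (``airborne``,
        ``tail_rattle``); missing channels default to all-zero.
    """

    fps: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    calibration: float
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.t)
        if len(self.x) != n or len(self.y) != n:
            raise InputError("t, x, y must have equal lengths")
        if self.calibration <= 0:
            raise InputError(f"calibration must be > 0, got {self.calibration}")
        if self.fps <= 0:
            raise InputError(f"fps must be > 0, got {self.fps}")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise FormatError("timestamps must be strictly increasing")
            if np.ptp(dt) > _T_UNIFORM_TOL:
                raise FormatError(
                    "timestamps must be uniform to within 1e-6 s "
                    f"(spread {np.ptp(dt):.2e} s)")
        for name in ("airborne", "tail_rattle"):
            ch = self.channels.get(name)
            if ch is None:
                self.channels[name] = np.zeros(n, dtype=np.int8)
            else:
                ch = np.asarray(ch)
                if len(ch) != n:
                    raise InputError(
                        f"channel {name!r} length {len(ch)} != {n} frames")
                self.channels[name] = ch.astype(np.int8)

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps


@dataclass
class SpeedSeries:
    """Per-frame speed (cm/s) sharing the source trajectory's timebase."""

    t: np.ndarray
    v: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if len(self.t) != len(self.v):
            raise InputError("t and v must have equal lengths")
        if np.any(self.v < 0):
            raise InputError("speed values must be non-negative")


_REQUIRED_COLUMNS = ("frame", "t_s", "x_px", "y_px")
_OPTIONAL_CHANNELS = ("airborne", "tail_rattle")


def load_tracking(path: str | Path, calibration: float,
                  fps: float | None = None) -> Trajectory:
    """Read a tracking table (``frame,t_s,x_px,y_px[,airborne,tail_rattle]``).

    ``fps`` defaults to the reciprocal of the median timestamp step.
    Missing annotation columns default to all-zero channels.  Gaps in the
    frame numbering or non-uniform timestamps raise :class:`FormatError`.
    """
    df = pd.read_csv(path)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"tracking table is missing column {col!r}")
    frames = df["frame"].to_numpy()
    if len(frames) >= 2 and not np.array_equal(
            np.diff(frames), np.ones(len(frames) - 1, dtype=frames.dtype)):
        raise FormatError("frame numbering has gaps or repeats")
    t = df["t_s"].to_numpy(dtype=float)
    if fps is None:
        if len(t) < 2:
            raise InputError("cannot infer fps from fewer than 2 frames")
        fps = 1.0 / float(np.median(np.diff(t)))
    channels = {name: df[name].to_numpy() for name in _OPTIONAL_CHANNELS
                if name in df.columns}
    return Trajectory(fps=fps, t=t, x=df["x_px"].to_numpy(dtype=float),
                      y=df["y_px"].to_numpy(dtype=float),
                      calibration=calibration, channels=channels)


def save_tracking(traj: Trajectory, path: str | Path) -> Path:
    """Write a trajectory as a delimited tracking table (round-trips)."""
    path = Path(path)
    df = pd.DataFrame({
        "frame": np.arange(traj.n_frames),
        "t_s": traj.t,
        "x_px": traj.x,
        "y_px": traj.y,
        "airborne": traj.channels["airborne"],
        "tail_rattle": traj.channels["tail_rattle"],
    })
    df.to_csv(path, index=False)
    return path


def compute_speed(traj: Trajectory) -> SpeedSeries:
    """Frame-to-frame centroid speed in cm/s.

    ``v[i]`` is the calibrated Euclidean displacement between frames
    ``i-1`` and ``i`` times the frame rate; ``v[0]`` copies ``v[1]`` so the
    series length matches the frame count.  No smoothing is applied.
    """
    if traj.n_frames < 2:
        raise InputError("speed requires at least 2 frames")
    disp = np.hypot(np.diff(traj.x), np.diff(traj.y))
    v = np.empty(traj.n_frames)
    v[1:] = traj.calibration * disp * traj.fps
    v[0] = v[1]
    return SpeedSeries(t=traj.t, v=v, fps=traj.fps)


def distance_traveled(speed: SpeedSeries, start: float, end: float,
                      bin_width: float = 0.5) -> float:
    """Distance (cm) over ``[start, end)`` by integrating binned mean speed.

    The window is partitioned into ``bin_width``-second bins (0.5 s by
    default); the distance is the sum of each bin's mean speed times its
    width, with a partial trailing bin weighted by its actual width.
    """
    if end <= start:
        raise InputError(f"empty window [{start}, {end})")
    total = 0.0
    b0 = start
    while b0 < end - 1e-12:
        b1 = min(b0 + bin_width, end)
        sel = (speed.t >= b0 - 1e-9) & (speed.t < b1 - 1e-9)
        if sel.any():
            total += float(speed.v[sel].mean()) * (b1 - b0)
        b0 = b1
    return total
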