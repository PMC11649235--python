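"""Bout segmentation: freezing, darting, jumping, tail rattling.

Freezing is a complete cessation of movement lasting at least 1 s,
operationalised here as centroid speed below a small ceiling ``eps``.
Darting is a rapid horizontal burst from rest back to rest, detected with
a speed hysteresis (a bout opens when speed rises above ``v_start`` from
below ``v_stop`` and closes at the last frame before speed returns below
``v_stop``) and a minimum duration of eight frames (266 ms at 30 frames/s).
Jumps and tail rattles are consumed from manual/simulated annotation
channels — a 2-D centroid cannot certify "all four paws off the floor".
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import csv

import numpy as np

from .errors import InputError
from .kinematics import SpeedSeries, Trajectory

__all__ = ["Behavior", "Bout", "detect_freezing", "detect_darts",
           "extract_jumps", "extract_tail_rattles", "export_bouts",
           "import_bouts", "FREEZE_EPS", "DART_V_START", "DART_V_STOP",
           "DART_MIN_FRAMES", "FREEZE_MIN_DURATION"]

FREEZE_EPS = 0.5  #: cm/s, default freezing speed ceiling
FREEZE_MIN_DURATION = 1.0  #: s
DART_V_START = 10.0  #: cm/s, hysteresis opening threshold
DART_V_STOP = 4.0  #: cm/s, hysteresis closing ("full stop") threshold
DART_MIN_FRAMES = 8  #: frames (266 ms at 30 frames/s)


class Behavior(str, Enum):
    FREEZE = "freeze"
    DART = "dart"
    JUMP = "jump"
    TAIL_RATTLE = "tail_rattle"
    LOCOMOTE = "locomote"  # used by the simulator's ground truth


@dataclass(frozen=True)
class Bout:
    """A labeled behavioral interval, half-open ``[start, end)`` seconds."""

    behavior: Behavior
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InputError(
                f"bout end {self.end} must exceed start {self.start}")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def overlap(self, start: float, end: float) -> float:
        """Length of intersection with ``[start, end)``."""
        return max(0.0, min(self.end, end) - max(self.start, start))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) frame index pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8),
                                                 [0]))))
    return [(int(a), int(b) - 1) for a, b in zip(idx[::2], idx[1::2])]


def detect_freezing(speed: SpeedSeries, eps: float = FREEZE_EPS,
                    min_dur: float = FREEZE_MIN_DURATION) -> list[Bout]:
    """Freezing bouts: maximal runs of frames with speed below ``eps``.

    Runs whose duration falls short of ``min_dur`` (default 1 s) are
    discarded.  Returned bouts are sorted and non-overlapping; a run of
    ``n`` frames spans ``n / fps`` seconds.
    """
    if eps <= 0:
        raise InputError(f"eps must be > 0, got {eps}")
    if min_dur <= 0:
        raise InputError(f"min_dur must be > 0, got {min_dur}")
    bouts = []
    for first, last in _runs(speed.v < eps):
        n = last - first + 1
        if n / speed.fps >= min_dur - 1e-9:
            start = speed.t[first]
            bouts.append(Bout(Behavior.FREEZE, float(start),
                              float(start + n / speed.fps)))
    return bouts


def detect_darts(speed: SpeedSeries, v_start: float = DART_V_START,
                 v_stop: float = DART_V_STOP,
                 min_frames: int = DART_MIN_FRAMES) -> list[Bout]:
    """Dart bouts by speed hysteresis.

    A bout opens at the first frame where speed exceeds ``v_start`` after
    having been below ``v_stop`` (rest), and closes at the last frame
    before speed returns below ``v_stop`` (the frame before the animal is
    back at a full stop).  Bouts with fewer than ``min_frames`` frames are
    discarded.
    """
    if v_start <= v_stop:
        raise InputError(
            f"v_start ({v_start}) must exceed v_stop ({v_stop})")
    if v_stop <= 0:
        raise InputError(f"v_stop must be > 0, got {v_stop}")
    if min_frames < 1:
        raise InputError(f"min_frames must be >= 1, got {min_frames}")
    v = speed.v
    bouts = []
    armed = True  # session starts counted as "at rest"
    i = 0
    n = len(v)
    while i < n:
        if v[i] < v_stop:
            armed = True
        elif armed and v[i] > v_start:
            j = i
            while j + 1 < n and v[j + 1] >= v_stop:
                j += 1
            if j - i + 1 >= min_frames:
                start = speed.t[i]
                bouts.append(Bout(Behavior.DART, float(start),
                                  float(start + (j - i + 1) / speed.fps)))
            armed = False
            i = j
        i += 1
    return bouts


def _channel_bouts(traj: Trajectory, channel: str,
                   behavior: Behavior) -> list[Bout]:
    ch = np.asarray(traj.channels[channel], dtype=bool)
    bouts = []
    for first, last in _runs(ch):
        start = traj.t[first]
        bouts.append(Bout(behavior, float(start),
                          float(start + (last - first + 1) / traj.fps)))
    return bouts


def extract_jumps(traj: Trajectory) -> list[Bout]:
    """Jump bouts: maximal runs of the ``airborne`` annotation channel.

    A jump's event time (for histograms and counting) is its start.
    """
    return _channel_bouts(traj, "airborne", Behavior.JUMP)


def extract_tail_rattles(traj: Trajectory) -> list[Bout]:
    """Tail-rattle bouts passed through from the annotation channel."""
    return _channel_bouts(traj, "tail_rattle", Behavior.TAIL_RATTLE)


def export_bouts(bouts: Sequence[Bout], path: str | Path) -> Path:
    """Write bouts as a delimited interval table (behavior,start_s,end_s)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["behavior", "start_s", "end_s"])
        for b in bouts:
            writer.writerow([b.behavior.value, repr(b.start), repr(b.end)])
    return path


def import_bouts(path: str | Path) -> list[Bout]:
    """Read an interval table written by :func:`export_bouts`."""
    bouts = []
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != ["behavior", "start_s", "end_s"]:
            raise InputError(f"unexpected bout-table header {header!r}")
        for row in reader:
            bouts.append(Bout(Behavior(row[0]), float(row[1]), float(row[2])))
    return bouts
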