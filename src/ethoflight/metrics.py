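"""Trial- and period-level behavioral metrics aligned to a schedule.

Each SCS trial contributes a set of 10 s analysis windows: ``pre_scs``
(the 10 s before SCS onset), ``tone`` and ``wn`` (the two stimulus
halves, named by stimulus content so that in reversed-SCS sessions the
``wn`` window precedes the ``tone`` window), plus a 1 s ``shock`` window
on conditioning days and the session's ``baseline`` window.

The central derived quantities are percent freezing (percent of window
time covered by freeze bouts), the activity index
``speed_CS / speed_avg-preSCS + jumps`` — the per-trial ratio of mean
CS-period speed to the session-wide pooled pre-SCS mean speed, plus the
number of escape jumps starting in that CS period (1 means locomotion
unchanged from baseline) — distance traveled, peri-stimulus event
histograms, difference scores, and cohort percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .detectors import Behavior, Bout
from .errors import InputError
from .kinematics import SpeedSeries, distance_traveled
from .protocol import SCS_DURATION, SessionSchedule

__all__ = ["Period", "PeriodWindow", "period_windows", "percent_freezing",
           "pre_scs_average_speed", "activity_index", "bin_events",
           "diff_score", "pre_vs_cs_diff", "cohort_percentage",
           "subsample_cohort", "session_metrics", "DENOM_FLOOR",
           "SHOCK_REACTION_EXTENSION"]

#: floor (cm/s) substituted for near-zero pre-SCS denominators
DENOM_FLOOR = 0.1
#: s appended after shock offset when counting reactions "to shock"
SHOCK_REACTION_EXTENSION = 1.0
CS_HALF = 10.0  #: s, duration of the tone and WN halves of the SCS


class Period(str, Enum):
    BASELINE = "baseline"
    PRE_SCS = "pre_scs"
    TONE = "tone"
    WN = "wn"
    SHOCK = "shock"
    ISI = "isi"


@dataclass(frozen=True)
class PeriodWindow:
    """One analysis window, half-open ``[start, end)`` seconds."""

    trial_index: int
    period: Period
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InputError("window end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


def period_windows(schedule: SessionSchedule) -> list[PeriodWindow]:
    """All analysis windows of one session.

    Per trial: ``pre_scs`` is the 10 s before SCS onset; the first and
    second 10 s halves of the SCS are named by stimulus content (``tone``
    then ``wn`` for the standard SCS, the reverse for reversed groups).
    Shock windows are emitted wherever the schedule contains shocks, and
    one ``baseline`` window spans ``[0, spec.baseline)``.
    """
    spec = schedule.spec
    windows: list[PeriodWindow] = []
    if spec.baseline > 0:
        windows.append(PeriodWindow(0, Period.BASELINE, 0.0, spec.baseline))
    first_half, second_half = ((Period.WN, Period.TONE) if spec.reversed_scs
                               else (Period.TONE, Period.WN))
    for trial, onset in enumerate(schedule.scs_onsets, start=1):
        if onset < CS_HALF:
            raise InputError(
                f"trial {trial} SCS onset {onset} s leaves no room for a "
                "10 s pre-SCS window")
        windows.append(PeriodWindow(trial, Period.PRE_SCS,
                                    onset - CS_HALF, onset))
        windows.append(PeriodWindow(trial, first_half, onset, onset + CS_HALF))
        windows.append(PeriodWindow(trial, second_half, onset + CS_HALF,
                                    onset + SCS_DURATION))
    for shock in schedule.shocks():
        windows.append(PeriodWindow(shock.trial_index, Period.SHOCK,
                                    shock.onset, shock.offset))
    windows.sort(key=lambda w: (w.start, w.end))
    return windows


def percent_freezing(bouts: Sequence[Bout], window: PeriodWindow) -> float:
    """Percent of the window's time covered by freeze bouts.

    Bouts straddling the window edges contribute only their overlap.
    """
    if window.duration <= 0:
        raise InputError("zero-length window")
    covered = sum(b.overlap(window.start, window.end) for b in bouts
                  if b.behavior is Behavior.FREEZE)
    return 100.0 * covered / window.duration


def pre_scs_average_speed(speed: SpeedSeries,
                          windows: Sequence[PeriodWindow],
                          floor: float = DENOM_FLOOR) -> tuple[float, bool]:
    """Session-wide mean speed pooled over all pre-SCS windows.

    Returns ``(value, floored)``; when the pooled mean falls below
    ``floor`` the floor is substituted and flagged, so activity-index
    denominators never approach zero.
    """
    pre = [w for w in windows if w.period is Period.PRE_SCS]
    if not pre:
        raise InputError("no pre_scs windows in the session")
    sel = np.zeros(len(speed.t), dtype=bool)
    for w in pre:
        sel |= (speed.t >= w.start - 1e-9) & (speed.t < w.end - 1e-9)
    mean = float(speed.v[sel].mean())
    if mean < floor:
        return floor, True
    return mean, False


def _mean_speed_in(speed: SpeedSeries, window: PeriodWindow) -> float:
    sel = (speed.t >= window.start - 1e-9) & (speed.t < window.end - 1e-9)
    if not sel.any():
        raise InputError(f"no frames inside window [{window.start}, "
                         f"{window.end})")
    return float(speed.v[sel].mean())


def activity_index(speed: SpeedSeries, jumps: Sequence[Bout],
                   cs_window: PeriodWindow, denom: float) -> float:
    """CS-period mean speed over the pre-SCS denominator, plus jump count.

    ``denom`` is the (possibly floored) session-wide pooled pre-SCS mean
    speed.  Jumps are counted by bout start time within the CS window, so
    a jump straddling the window edge counts once.
    """
    if denom <= 0:
        raise InputError(f"denominator must be > 0, got {denom}")
    if cs_window.period not in (Period.TONE, Period.WN):
        raise InputError("activity index is defined for tone/wn windows, "
                         f"got {cs_window.period.value}")
    n_jumps = sum(1 for b in jumps if b.behavior is Behavior.JUMP
                  and cs_window.start <= b.start < cs_window.end)
    return _mean_speed_in(speed, cs_window) / denom + n_jumps


def bin_events(bouts: Sequence[Bout], window: PeriodWindow,
               bin_width: float = 1.0) -> np.ndarray:
    """Histogram of bout start times within the window (half-open bins).

    ``bin_width`` must divide the window length; a 10 s stimulus window
    yields 10 bins, each coinciding with one pip.  Events exactly on a bin
    edge fall in the later bin.
    """
    n_bins = window.duration / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise InputError(
            f"bin width {bin_width} does not divide window length "
            f"{window.duration}")
    n_bins = int(round(n_bins))
    counts = np.zeros(n_bins, dtype=int)
    for b in bouts:
        if window.start <= b.start < window.end:
            i = int((b.start - window.start) / bin_width + 1e-9)
            counts[min(i, n_bins - 1)] += 1
    return counts


def diff_score(values: Sequence[float], k: int = 4) -> float:
    """Mean of the first ``k`` trials minus mean of the last ``k``.

    Positive values measure a decrease across the session (the sign
    convention used for extinction of freezing); pass the negated result
    where an increase is the quantity of interest.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2 * k:
        raise InputError(
            f"need at least {2 * k} trials for k={k}, got {len(values)}")
    return float(values[:k].mean() - values[-k:].mean())


def pre_vs_cs_diff(metrics: pd.DataFrame, period: Period | str) -> pd.Series:
    """Per-animal mean over trials of (CS-period minus pre-SCS freezing).

    ``metrics`` is a tidy table with columns ``animal_id, trial_index,
    period, percent_freezing`` (as produced by :func:`session_metrics`).
    """
    period = Period(period)
    cs = metrics[metrics["period"] == period.value]
    pre = metrics[metrics["period"] == Period.PRE_SCS.value]
    try:
        merged = cs.merge(pre, on=["animal_id", "trial_index"],
                          suffixes=("_cs", "_pre"), validate="one_to_one")
    except pd.errors.MergeError as exc:
        raise InputError(f"duplicate (animal, trial) rows: {exc}") from exc
    if len(merged) != len(cs) or len(merged) != len(pre):
        raise InputError("pre_scs and CS-period trials do not match")
    merged["d"] = (merged["percent_freezing_cs"]
                   - merged["percent_freezing_pre"])
    return merged.groupby("animal_id")["d"].mean()


def cohort_percentage(bouts_per_animal: Mapping[str, Sequence[Bout]],
                      windows: Sequence[PeriodWindow],
                      behavior: Behavior | str) -> float:
    """Percent of animals with >= 1 bout starting inside any listed window."""
    if not bouts_per_animal:
        raise InputError("empty cohort")
    behavior = Behavior(behavior)
    n_hit = 0
    for bouts in bouts_per_animal.values():
        if any(b.behavior is behavior
               and any(w.start <= b.start < w.end for w in windows)
               for b in bouts):
            n_hit += 1
    return 100.0 * n_hit / len(bouts_per_animal)


def subsample_cohort(animals: Sequence, n: int = 20, seed: int = 0) -> list:
    """Seeded uniform sample of ``n`` animals without replacement.

    Used to match cohort sizes in frequency-based comparisons (e.g. 20
    random subjects from a 32-animal group).  Stable across runs for the
    same seed.
    """
    if n > len(animals):
        raise InputError(
            f"cannot sample {n} from a cohort of {len(animals)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(animals), size=n, replace=False)
    return [animals[i] for i in sorted(idx)]


def session_metrics(speed: SpeedSeries, bouts: Sequence[Bout],
                    schedule: SessionSchedule, animal_id: str = "a0",
                    sex: str = "", shock_extension: float =
                    SHOCK_REACTION_EXTENSION) -> pd.DataFrame:
    """Tidy per-(trial, period) metrics table for one animal's session.

    One row per analysis window with percent freezing, activity index
    (tone/wn windows only), jump/dart/tail-rattle counts, distance
    traveled, and mean speed.  Shock-window event counts use a window
    extended ``shock_extension`` s beyond shock offset to capture
    reactions to the shock.
    """
    windows = period_windows(schedule)
    denom, floored = (pre_scs_average_speed(speed, windows)
                      if any(w.period is Period.PRE_SCS for w in windows)
                      else (DENOM_FLOOR, False))
    jumps = [b for b in bouts if b.behavior is Behavior.JUMP]
    rows = []
    for w in windows:
        count_end = (w.end + shock_extension if w.period is Period.SHOCK
                     else w.end)

        def _count(behavior: Behavior) -> int:
            return sum(1 for b in bouts if b.behavior is behavior
                       and w.start <= b.start < count_end)

        row = {
            "animal_id": animal_id,
            "sex": sex,
            "group": schedule.spec.group.value,
            "session": schedule.spec.session.value,
            "trial_index": w.trial_index,
            "period": w.period.value,
            "percent_freezing": percent_freezing(bouts, w),
            "jumps": _count(Behavior.JUMP),
            "darts": _count(Behavior.DART),
            "tail_rattles": _count(Behavior.TAIL_RATTLE),
            "distance": distance_traveled(speed, w.start, w.end),
            "mean_speed": _mean_speed_in(speed, w),
            "denom_floored": floored,
        }
        row["activity_index"] = (
            activity_index(speed, jumps, w, denom)
            if w.period in (Period.TONE, Period.WN) else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
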