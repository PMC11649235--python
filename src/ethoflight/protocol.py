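"""Stimulus schedules for the serial-compound-stimulus (SCS) paradigm.

The SCS is a 20 s compound cue: ten 0.5 s tone pips at 1 Hz followed by
ten 0.5 s white-noise (WN) pips at 1 Hz.  "Reversed" variants invert the
pip order (WN first, tone second) at identical timing.  A session is a
baseline period, a train of SCS presentations (with footshocks according
to the group contingency) separated by pseudorandom inter-stimulus
intervals (ISIs), and a tail period, with a fixed published total length.

Five group contingencies exist:

========  =============================================================
group     conditioning-day contingency
========  =============================================================
PA        paired: each SCS co-terminates with a 1 s footshock
PA_R      as PA with the reversed SCS
UN        unpaired: 5 SCS and 5 shocks interleaved, shock never
          predictable from the SCS
UN_R      as UN with the reversed SCS
SO        shock only: 5 shocks, no SCS
========  =============================================================

All times are real-valued seconds from session start; every stimulus
interval is half-open ``[onset, onset + duration)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

from .errors import ConstraintError, InputError

__all__ = [
    "StimulusKind",
    "Session",
    "Group",
    "StimulusEvent",
    "SessionSpec",
    "SessionSchedule",
    "scs_events",
    "session_spec",
    "build_schedule",
    "export_schedule",
    "import_schedule",
    "SCS_DURATION",
    "PIP_DURATION",
    "SHOCK_DURATION",
    "UNPAIRED_GUARD_GAP",
]

SCS_DURATION = 20.0  #: s, ten tone + ten WN pips at 1 Hz
PIP_DURATION = 0.5  #: s per pip
SHOCK_DURATION = 1.0  #: s
PIPS_PER_STIMULUS = 10
#: minimum gap (s) between an SCS offset and any shock onset in unpaired
#: schedules, so the SCS cannot predict shock
UNPAIRED_GUARD_GAP = 20.0


class StimulusKind(str, Enum):
    TONE_PIP = "tone_pip"
    WN_PIP = "wn_pip"
    SHOCK = "shock"


class Session(str, Enum):
    PREEXP = "PreExp"
    CD1 = "CD1"
    CD2 = "CD2"
    EXT1 = "Ext1"
    EXT2 = "Ext2"


class Group(str, Enum):
    PA = "PA"
    UN = "UN"
    SO = "SO"
    PA_R = "PA_R"
    UN_R = "UN_R"


#: groups that hear the reversed SCS (WN pips first, then tone pips)
REVERSED_GROUPS = frozenset({Group.PA_R, Group.UN_R})


@dataclass(frozen=True)
class StimulusEvent:
    """One timed stimulus: a single pip or a footshock.

    ``trial_index`` is 1-based for events tied to an SCS trial and 0 for
    shocks not tied to one (unpaired and shock-only schedules).
    """

    kind: StimulusKind
    onset: float
    duration: float
    trial_index: int

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise InputError(f"event onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise InputError(f"event duration must be > 0, got {self.duration}")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class SessionSpec:
    """Parameters defining one session of one group variant."""

    session: Session
    group: Group
    baseline: float
    n_trials: int
    isi_range: tuple[float, float]
    tail: float
    total: float
    seed: int = 0
    n_shocks: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.isi_range
        if lo > hi:
            raise InputError(f"isi_range min {lo} exceeds max {hi}")
        if self.baseline < 0 or self.tail < 0 or self.total <= 0:
            raise InputError("baseline/tail must be >= 0 and total > 0")

    @property
    def reversed_scs(self) -> bool:
        return self.group in REVERSED_GROUPS


@dataclass(frozen=True)
class SessionSchedule:
    """Timed stimulus events for one session, sorted by onset."""

    spec: SessionSpec
    events: tuple[StimulusEvent, ...]
    scs_onsets: tuple[float, ...]
    total_duration: float

    def shocks(self) -> list[StimulusEvent]:
        return [e for e in self.events if e.kind is StimulusKind.SHOCK]

    def pips(self) -> list[StimulusEvent]:
        return [e for e in self.events if e.kind is not StimulusKind.SHOCK]


# ---------------------------------------------------------------------------
# built-in published session layouts
# ---------------------------------------------------------------------------

#: (baseline, n_trials, isi_range, tail, total, n_shocks) per session/group.
#: Conditioning layouts differ by contingency; PreExp and extinction are
#: shared by all groups (SO hears no SCS before extinction day 1).
_PREEXP = dict(baseline=180.0, n_trials=4, isi_range=(90.0, 100.0), tail=40.0,
               total=590.0, n_shocks=0)
_EXT = dict(baseline=180.0, n_trials=16, isi_range=(60.0, 120.0), tail=50.0,
            total=1910.0, n_shocks=0)
_CD_PAIRED = dict(baseline=180.0, n_trials=5, isi_range=(90.0, 150.0),
                  tail=60.0, total=820.0, n_shocks=5)
_CD_UNPAIRED = dict(baseline=180.0, n_trials=5, isi_range=(40.0, 60.0),
                    tail=90.0, total=820.0, n_shocks=5)
_CD_SHOCK_ONLY = dict(baseline=180.0, n_trials=0, isi_range=(120.0, 160.0),
                      tail=80.0, total=820.0, n_shocks=5)


def session_spec(session: Session | str, group: Group | str,
                 seed: int = 0) -> SessionSpec:
    """Return the built-in published spec for ``(session, group)``.

    The same base ``seed`` yields different stimulus timing on CD1 vs CD2
    (per-day sub-seeds), matching the design in which stimulus timing and
    ISI differ between the two conditioning days.
    """
    session = Session(session)
    group = Group(group)
    if session is Session.PREEXP:
        layout = _PREEXP
    elif session in (Session.CD1, Session.CD2):
        if group in (Group.PA, Group.PA_R):
            layout = _CD_PAIRED
        elif group in (Group.UN, Group.UN_R):
            layout = _CD_UNPAIRED
        else:
            layout = _CD_SHOCK_ONLY
    else:
        layout = _EXT
    return SessionSpec(session=session, group=group, seed=seed, **layout)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def scs_events(onset: float, variant: str = "standard",
               trial_index: int = 1) -> list[StimulusEvent]:
    """Twenty pip events of one SCS presentation starting at ``onset``.

    ``variant`` is ``"standard"`` (10 tone pips then 10 WN pips) or
    ``"reversed"`` (10 WN pips then 10 tone pips).  Pips play at a 1 Hz
    cycle: pip *i* starts at ``onset + i`` seconds and lasts 0.5 s, so the
    SCS spans ``[onset, onset + 20)`` s.
    """
    if onset < 0:
        raise InputError(f"SCS onset must be >= 0, got {onset}")
    if variant == "standard":
        first, second = StimulusKind.TONE_PIP, StimulusKind.WN_PIP
    elif variant == "reversed":
        first, second = StimulusKind.WN_PIP, StimulusKind.TONE_PIP
    else:
        raise InputError(f"unknown SCS variant {variant!r}")
    events = []
    for i in range(2 * PIPS_PER_STIMULUS):
        kind = first if i < PIPS_PER_STIMULUS else second
        events.append(StimulusEvent(kind, onset + float(i), PIP_DURATION,
                                    trial_index))
    return events


def _sample_isis(rng: np.random.Generator, n: int,
                 isi_range: tuple[float, float], required_sum: float,
                 what: str) -> np.ndarray:
    """n ISIs, each within ``isi_range``, summing exactly to ``required_sum``.

    Draw uniformly, then repeatedly shift-and-clip toward the required sum.
    Feasible iff n*min <= required_sum <= n*max.
    """
    lo, hi = isi_range
    if n == 0:
        if abs(required_sum) > 1e-9:
            raise ConstraintError(
                f"{what}: no ISI gaps but {required_sum:.1f} s unaccounted")
        return np.zeros(0)
    if not (n * lo - 1e-9 <= required_sum <= n * hi + 1e-9):
        raise ConstraintError(
            f"{what}: {n} ISIs in [{lo}, {hi}] s cannot sum to "
            f"{required_sum:.1f} s (feasible range [{n * lo:.1f}, "
            f"{n * hi:.1f}] s)")
    isis = rng.uniform(lo, hi, size=n)
    for _ in range(200):
        deficit = required_sum - isis.sum()
        if abs(deficit) < 1e-9:
            break
        free = (isis < hi - 1e-12) if deficit > 0 else (isis > lo + 1e-12)
        isis[free] = np.clip(isis[free] + deficit / free.sum(), lo, hi)
    else:  # pragma: no cover - bounded feasible adjustment always converges
        raise ConstraintError(f"{what}: ISI adjustment failed to converge")
    return isis


def _paired_events(spec: SessionSpec, rng: np.random.Generator,
                   with_shock: bool) -> tuple[list[StimulusEvent], list[float]]:
    """SCS-only or paired SCS+shock trains (PreExp, extinction, PA/PA-R CD)."""
    n = spec.n_trials
    occupied = n * SCS_DURATION
    required = spec.total - spec.baseline - spec.tail - occupied
    isis = _sample_isis(rng, max(n - 1, 0), spec.isi_range, required,
                        f"{spec.session.value}/{spec.group.value}")
    variant = "reversed" if spec.reversed_scs else "standard"
    events: list[StimulusEvent] = []
    onsets: list[float] = []
    t = spec.baseline
    for trial in range(1, n + 1):
        onsets.append(t)
        events.extend(scs_events(t, variant, trial))
        if with_shock:
            # shock co-terminates with the SCS: final 1 s of the 20 s span
            events.append(StimulusEvent(StimulusKind.SHOCK,
                                        t + SCS_DURATION - SHOCK_DURATION,
                                        SHOCK_DURATION, trial))
        t += SCS_DURATION
        if trial < n:
            t += float(isis[trial - 1])
    return events, onsets


def _unpaired_events(spec: SessionSpec,
                     rng: np.random.Generator) -> tuple[list[StimulusEvent],
                                                        list[float]]:
    """Interleaved SCS and shocks such that the SCS never predicts shock.

    The ten stimuli (5 SCS, 5 shocks) are shuffled per seed, subject to a
    guard gap: no shock onset within ``UNPAIRED_GUARD_GAP`` s of an SCS
    offset, and never a strict SCS->shock alternation throughout.
    """
    n_stim = spec.n_trials + spec.n_shocks
    occupied = spec.n_trials * SCS_DURATION + spec.n_shocks * SHOCK_DURATION
    required = spec.total - spec.baseline - spec.tail - occupied
    isis = _sample_isis(rng, n_stim - 1, spec.isi_range, required,
                        f"{spec.session.value}/{spec.group.value}")
    order = ["scs"] * spec.n_trials + ["shock"] * spec.n_shocks
    for _ in range(1000):
        rng.shuffle(order)
        pairs = sum(1 for a, b in zip(order, order[1:])
                    if a == "scs" and b == "shock")
        # reject orderings in which shock always (or never-informatively
        # often) follows the SCS; <= 2 of 5 shocks directly after an SCS
        if pairs <= 2:
            break
    variant = "reversed" if spec.reversed_scs else "standard"
    events: list[StimulusEvent] = []
    onsets: list[float] = []
    t = spec.baseline
    trial = 0
    for i, stim in enumerate(order):
        if stim == "scs":
            trial += 1
            onsets.append(t)
            events.extend(scs_events(t, variant, trial))
            t += SCS_DURATION
        else:
            events.append(StimulusEvent(StimulusKind.SHOCK, t,
                                        SHOCK_DURATION, 0))
            t += SHOCK_DURATION
        if i < n_stim - 1:
            t += float(isis[i])
    return events, onsets


def _shock_only_events(spec: SessionSpec,
                       rng: np.random.Generator) -> tuple[list[StimulusEvent],
                                                          list[float]]:
    occupied = spec.n_shocks * SHOCK_DURATION
    required = spec.total - spec.baseline - spec.tail - occupied
    isis = _sample_isis(rng, max(spec.n_shocks - 1, 0), spec.isi_range,
                        required, f"{spec.session.value}/{spec.group.value}")
    events = []
    t = spec.baseline
    for i in range(spec.n_shocks):
        events.append(StimulusEvent(StimulusKind.SHOCK, t, SHOCK_DURATION, 0))
        t += SHOCK_DURATION
        if i < spec.n_shocks - 1:
            t += float(isis[i])
    return events, []


def build_schedule(spec: SessionSpec) -> SessionSchedule:
    """Lay out one session's stimulus events from its spec.

    The layout is baseline, a stimulus train with pseudorandom ISIs drawn
    from ``spec.isi_range`` and jointly adjusted so the session length
    equals ``spec.total`` exactly, then the tail.  The random stream is
    derived from ``(spec.seed, spec.session)``, so one base seed gives
    different stimulus timing on CD1 vs CD2 while reversed and standard
    variants of the same group class share identical timing.
    """
    # per-day sub-seed; reversed groups share their counterpart's timing
    timing_group = {Group.PA_R: Group.PA, Group.UN_R: Group.UN}.get(
        spec.group, spec.group)
    rng = np.random.default_rng(
        [spec.seed, list(Session).index(spec.session),
         [Group.PA, Group.UN, Group.SO].index(timing_group)])
    paired_shocks = (spec.n_shocks > 0
                     and spec.group in (Group.PA, Group.PA_R))
    if spec.group is Group.SO and spec.n_shocks > 0:
        events, onsets = _shock_only_events(spec, rng)
    elif spec.n_shocks > 0 and not paired_shocks:
        events, onsets = _unpaired_events(spec, rng)
    elif spec.n_trials == 0 and spec.n_shocks == 0:
        events, onsets = [], []
        if abs(spec.total - spec.baseline - spec.tail) > 1e-9:
            raise ConstraintError(
                "empty schedule requires total == baseline + tail")
    else:
        events, onsets = _paired_events(spec, rng, with_shock=paired_shocks)
    events.sort(key=lambda e: (e.onset, e.kind.value))
    last_off = max((e.offset for e in events), default=spec.baseline)
    if last_off + spec.tail - spec.total > 1e-6:
        raise ConstraintError(
            f"stimulus train overruns the session: last offset {last_off:.1f}"
            f" + tail {spec.tail:.1f} > total {spec.total:.1f} s")
    return SessionSchedule(spec=spec, events=tuple(events),
                           scs_onsets=tuple(onsets),
                           total_duration=spec.total)


# ---------------------------------------------------------------------------
# event table I/O
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = ("kind", "onset_s", "duration_s", "trial_index")


def export_schedule(schedule: SessionSchedule, path: str | Path) -> Path:
    """Write the schedule as a delimited event table (one row per event)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_EVENT_COLUMNS)
        for e in schedule.events:
            writer.writerow([e.kind.value, repr(e.onset), repr(e.duration),
                             e.trial_index])
    return path


def import_schedule(path: str | Path,
                    spec: SessionSpec | None = None) -> SessionSchedule:
    """Read an event table written by :func:`export_schedule`.

    If ``spec`` is omitted a minimal custom spec is reconstructed from the
    events (total = last offset, zero baseline/tail).
    """
    path = Path(path)
    events: list[StimulusEvent] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if tuple(header) != _EVENT_COLUMNS:
            raise InputError(f"unexpected event-table header {header!r}")
        for row in reader:
            events.append(StimulusEvent(StimulusKind(row[0]), float(row[1]),
                                        float(row[2]), int(row[3])))
    events.sort(key=lambda e: (e.onset, e.kind.value))
    # first pip of each trial marks the SCS onset
    first_pip: dict[int, float] = {}
    for e in events:
        if e.kind is not StimulusKind.SHOCK and e.trial_index > 0:
            prev = first_pip.get(e.trial_index, e.onset)
            first_pip[e.trial_index] = min(prev, e.onset)
    onsets = [first_pip[k] for k in sorted(first_pip)]
    if spec is None:
        total = max((e.offset for e in events), default=1.0)
        spec = SessionSpec(session=Session.CD1, group=Group.PA, baseline=0.0,
                           n_trials=len(onsets), isi_range=(0.0, total),
                           tail=0.0, total=total)
    return SessionSchedule(spec=spec, events=tuple(events),
                           scs_onsets=tuple(onsets),
                           total_duration=spec.total)
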