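"""Synthetic trajectory generator with group/period/trial structure.

Emulates centroid tracking of a mouse in a 30 cm circular arena at 30
frames/s during SCS conditioning and extinction.  Behavior is a
semi-Markov process over four states — freeze, locomote, dart, jump —
whose occupancy probabilities depend on the experimental group, session,
stimulus period and trial number (the "state table").  Dwell-weighted
state sampling makes the configured occupancies equal the long-run time
fractions, so pipeline measurements of percent freezing converge to
``100 * p`` for a configured occupancy ``p``.

Emissions per state:

* freeze — per-frame jitter with speed well below the freezing ceiling;
* locomote — AR(1)-autocorrelated speed (~0.2 s correlation time) around
  a per-cell mean, on a smooth bounded walk;
* dart — a trapezoidal speed burst from rest back to rest, at least 14
  frames long, peaking far above the dart-opening threshold;
* jump — moderate-speed frames with the ``airborne`` channel set.

The default state tables are calibration choices, not measured rates:
they are tuned so that the full pipeline reproduces the published
cohort-level CD2 white-noise activity indices (PA and UN groups) and the
qualitative ethogram structure (flight emerging during conditioning in
the paired group only, extinction of jumping, return of freezing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .detectors import Behavior, Bout
from .errors import InputError
from .kinematics import Trajectory
from .metrics import Period, period_windows
from .protocol import Group, Session, SessionSchedule, session_spec, \
    build_schedule

__all__ = ["EmissionParams", "SimParams", "AnnotatedTrajectory",
           "CohortAnimal", "default_params", "simulate_session",
           "simulate_cohort", "DEFAULT_FPS", "DEFAULT_CALIBRATION",
           "DEFAULT_ARENA_DIAMETER"]

DEFAULT_FPS = 30.0
DEFAULT_ARENA_DIAMETER = 30.0  #: cm
#: 30 cm arena spanning ~450 px -> 1/15 cm per pixel
DEFAULT_CALIBRATION = 1.0 / 15.0

_STATES = ("freeze", "locomote", "dart", "jump")


@dataclass(frozen=True)
class EmissionParams:
    """Per-state speed/duration emission parameters (seconds, cm/s)."""

    freeze_speed_mean: float = 0.15
    freeze_speed_sd: float = 0.05
    freeze_speed_max: float = 0.35
    freeze_dwell: tuple[float, float] = (1.0, 3.0)
    locomote_speed_mean: float = 4.0
    locomote_speed_sd: float = 1.0
    locomote_speed_clip: tuple[float, float] = (0.8, 9.0)
    locomote_ar: float = 0.85  # ~0.2 s speed autocorrelation at 30 fps
    locomote_dwell: tuple[float, float] = (0.5, 2.0)
    dart_peak: tuple[float, float] = (18.0, 32.0)
    dart_frames: tuple[int, int] = (14, 20)
    jump_frames: tuple[int, int] = (9, 15)
    jump_speed: tuple[float, float] = (4.0, 8.0)

    def mean_dwell(self, state: str, fps: float) -> float:
        if state == "freeze":
            return 0.5 * sum(self.freeze_dwell)
        if state == "locomote":
            return 0.5 * sum(self.locomote_dwell)
        if state == "dart":
            return 0.5 * sum(self.dart_frames) / fps
        return 0.5 * sum(self.jump_frames) / fps

    def min_frames(self, state: str, fps: float) -> int:
        if state == "freeze":
            return int(round(self.freeze_dwell[0] * fps))
        if state == "locomote":
            return int(round(self.locomote_dwell[0] * fps))
        if state == "dart":
            return self.dart_frames[0]
        return self.jump_frames[0]


#: a state-table cell: occupancy over the four states plus optional
#: per-cell overrides (``locomote_speed``)
Cell = Mapping[str, float]


@dataclass
class SimParams:
    """Group-specific simulation parameters.

    ``state_table`` maps ``(session, period)`` to either a single cell or
    a per-trial list of cells; a cell maps state names to occupancy
    probabilities (summing to 1) and may carry a ``locomote_speed``
    override (cm/s).
    """

    group: Group
    state_table: dict[tuple[str, str], Cell | list[Cell]]
    emission: EmissionParams = field(default_factory=EmissionParams)
    fps: float = DEFAULT_FPS
    arena_diameter: float = DEFAULT_ARENA_DIAMETER
    calibration: float = DEFAULT_CALIBRATION
    seed: int = 0

    def occupancy(self, session: Session, period: Period,
                  trial_index: int) -> dict[str, float]:
        """The occupancy cell for one (session, period, trial)."""
        key = (session.value, period.value)
        if key not in self.state_table:
            raise InputError(f"no state-table cell for {key}")
        cell = self.state_table[key]
        if isinstance(cell, list):
            i = min(max(trial_index - 1, 0), len(cell) - 1)
            cell = cell[i]
        probs = {s: float(cell.get(s, 0.0)) for s in _STATES}
        total = sum(probs.values())
        if total <= 0:
            raise InputError(f"cell {key} has no probability mass")
        if abs(total - 1.0) > 1e-6:
            raise InputError(f"cell {key} occupancies sum to {total}, not 1")
        out = dict(probs)
        if "locomote_speed" in cell:
            out["locomote_speed"] = float(cell["locomote_speed"])
        return out


@dataclass
class AnnotatedTrajectory:
    """A simulated session: trajectory, ground-truth bouts, schedule."""

    trajectory: Trajectory
    truth_bouts: list[Bout]
    schedule: SessionSchedule
    animal_id: str = "a0"
    sex: str = ""


@dataclass
class CohortAnimal:
    """One simulated animal's sessions, keyed by session name."""

    animal_id: str
    sex: str
    sessions: dict[str, AnnotatedTrajectory]


# ---------------------------------------------------------------------------
# default parameter tables
# ---------------------------------------------------------------------------

def _logistic(lo: float, hi: float, n: int, mid: float,
              rate: float = 1.0) -> list[float]:
    """Logistic ramp from ``lo`` to ``hi`` over trials 1..n."""
    t = np.arange(1, n + 1, dtype=float)
    w = 1.0 / (1.0 + np.exp(-rate * (t - mid)))
    return list(lo + (hi - lo) * w)


def _cells(n: int, freeze=None, dart=None, jump=None,
           locomote_speed: float | None = None) -> list[dict]:
    """Per-trial cells from per-trial freeze/dart/jump series.

    Locomote takes the remaining probability mass in every trial.
    """
    def _series(x):
        if x is None:
            return [0.0] * n
        if np.isscalar(x):
            return [float(x)] * n
        return [float(v) for v in x]

    fz, dt, jp = _series(freeze), _series(dart), _series(jump)
    cells = []
    for f, d, j in zip(fz, dt, jp):
        cell = {"freeze": f, "dart": d, "jump": j,
                "locomote": 1.0 - f - d - j}
        if cell["locomote"] < -1e-9:
            raise InputError("cell occupancies exceed 1")
        cell["locomote"] = max(cell["locomote"], 0.0)
        if locomote_speed is not None:
            cell["locomote_speed"] = locomote_speed
        cells.append(cell)
    return cells


def _c(freeze=0.0, dart=0.0, jump=0.0,
       locomote_speed: float | None = None) -> dict:
    return _cells(1, freeze, dart, jump, locomote_speed)[0]


def default_params(group: Group | str, seed: int = 0) -> SimParams:
    """Shipped default simulation parameters for one group.

    The tables encode the paradigm's behavioral structure: in the paired
    (PA) group freezing to the tone grows across conditioning while the
    white-noise half of the SCS evokes escape jumping and darting by CD2;
    unpaired (UN) and shock-only (SO) controls show elevated WN
    locomotion but almost no flight; reversed groups (PA-R/UN-R) freeze
    to the tone with near-zero WN jumping; during extinction the PA jump
    rate decays to zero by mid-Ext1 while WN freezing climbs.  Absolute
    rates are calibration choices (see module docstring), not measured
    quantities.
    """
    group = Group(group)
    quiet = _c(freeze=0.05)
    table: dict[tuple[str, str], Cell | list[Cell]] = {}

    def put(session: str, **periods: Cell | list[Cell]) -> None:
        for period, cell in periods.items():
            table[(session, period)] = cell

    # pre-exposure: novelty, little freezing, no flight (all groups)
    put("PreExp", baseline=quiet, pre_scs=quiet, tone=_c(freeze=0.08),
        wn=_c(freeze=0.05), isi=quiet, shock=quiet)

    if group in (Group.PA, Group.PA_R):
        shock_cell = _c(dart=0.35, jump=0.55)
        put("CD1",
            baseline=_c(freeze=0.10),
            pre_scs=_cells(5, freeze=_logistic(0.2, 0.6, 5, 3.0)),
            tone=_cells(5, freeze=_logistic(0.25, 0.7, 5, 3.0)),
            wn=_cells(5, freeze=0.10,
                      dart=_logistic(0.02, 0.20, 5, 3.5),
                      jump=_logistic(0.0, 0.15, 5, 3.5)),
            shock=shock_cell, isi=_c(freeze=0.30))
        put("CD2",
            baseline=_c(freeze=0.35),
            pre_scs=_c(freeze=0.70),
            tone=_cells(5, freeze=_logistic(0.70, 0.85, 5, 2.5)),
            wn=_cells(5, freeze=0.05, dart=0.30, jump=0.35),
            shock=shock_cell, isi=_c(freeze=0.50))
        put("Ext1",
            baseline=_c(freeze=0.40),
            pre_scs=_c(freeze=0.70),
            tone=_c(freeze=0.80),
            wn=_cells(16, freeze=_logistic(0.10, 0.50, 16, 8.0, 0.8),
                      dart=_logistic(0.20, 0.03, 16, 8.0, 0.8),
                      jump=_logistic(0.25, 0.0, 16, 5.0, 1.2)),
            isi=_c(freeze=0.50), shock=quiet)
        put("Ext2",
            baseline=_c(freeze=0.35),
            pre_scs=_c(freeze=0.60),
            tone=_c(freeze=0.75),
            wn=_cells(16, freeze=_logistic(0.55, 0.70, 16, 8.0, 0.5),
                      dart=0.02),
            isi=_c(freeze=0.50), shock=quiet)
        if group is Group.PA_R:
            # reversed SCS: WN (first half) evokes freezing, not flight;
            # tone freezing stays uniformly high through extinction
            put("CD1",
                baseline=_c(freeze=0.10),
                pre_scs=_cells(5, freeze=_logistic(0.2, 0.6, 5, 3.0)),
                tone=_cells(5, freeze=_logistic(0.3, 0.8, 5, 3.0)),
                wn=_cells(5, freeze=_logistic(0.2, 0.5, 5, 3.0),
                          jump=0.004),
                shock=shock_cell, isi=_c(freeze=0.30))
            put("CD2",
                baseline=_c(freeze=0.35),
                pre_scs=_c(freeze=0.80),
                tone=_c(freeze=0.88), wn=_c(freeze=0.55, jump=0.004),
                shock=shock_cell, isi=_c(freeze=0.50))
            for ext in ("Ext1", "Ext2"):
                put(ext, baseline=_c(freeze=0.35),
                    pre_scs=_c(freeze=0.65),
                    tone=_c(freeze=0.85), wn=_c(freeze=0.50),
                    isi=_c(freeze=0.50), shock=quiet)
    elif group in (Group.UN, Group.UN_R):
        shock_cell = _c(dart=0.35, jump=0.55)
        wn_speed = 8.0 if group is Group.UN_R else 6.5
        put("CD1",
            baseline=_c(freeze=0.15),
            pre_scs=_c(freeze=0.50, locomote_speed=3.0),
            tone=_c(freeze=0.25),
            wn=_cells(5, freeze=0.05, jump=[0.05, 0, 0, 0, 0],
                      locomote_speed=wn_speed - 1.0),
            shock=shock_cell, isi=_c(freeze=0.35))
        put("CD2",
            baseline=_c(freeze=0.45),
            pre_scs=_c(freeze=0.65, locomote_speed=3.0),
            tone=_c(freeze=0.30),
            wn=_cells(5, freeze=0.03, jump=[0.03, 0, 0, 0, 0],
                      locomote_speed=wn_speed),
            shock=shock_cell, isi=_c(freeze=0.40))
        for ext in ("Ext1", "Ext2"):
            put(ext, baseline=_c(freeze=0.30),
                pre_scs=_c(freeze=0.55, locomote_speed=3.0),
                tone=_c(freeze=0.30),
                wn=_c(freeze=0.05, locomote_speed=6.0),
                isi=_c(freeze=0.40), shock=quiet)
    else:  # SO: no SCS during conditioning; first hears the SCS in Ext1
        shock_cell = _c(dart=0.40, jump=0.50)
        for cd in ("CD1", "CD2"):
            put(cd, baseline=_c(freeze=0.15), shock=shock_cell,
                isi=_c(freeze=0.40), pre_scs=_c(freeze=0.40),
                tone=_c(freeze=0.20), wn=_c(freeze=0.10))
        for ext in ("Ext1", "Ext2"):
            put(ext, baseline=_c(freeze=0.30),
                pre_scs=_c(freeze=0.45, locomote_speed=3.0),
                tone=_c(freeze=0.20),
                wn=_c(freeze=0.05, dart=0.15, locomote_speed=5.0),
                isi=_c(freeze=0.40), shock=quiet)

    return SimParams(group=group, state_table=table, seed=seed)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _frame_labels(schedule: SessionSchedule,
                  fps: float) -> tuple[np.ndarray, np.ndarray]:
    """(period, trial) label per frame; shock windows take precedence."""
    n = int(round(schedule.total_duration * fps))
    periods = np.full(n, Period.ISI.value, dtype=object)
    trials = np.zeros(n, dtype=int)
    ordered = sorted(period_windows(schedule),
                     key=lambda w: w.period is Period.SHOCK)
    for w in ordered:
        a = int(round(w.start * fps))
        b = min(int(round(w.end * fps)), n)
        periods[a:b] = w.period.value
        trials[a:b] = w.trial_index
    return periods, trials


def simulate_session(schedule: SessionSchedule, params: SimParams,
                     animal_seed: int = 0) -> AnnotatedTrajectory:
    """Simulate one animal's session against a stimulus schedule.

    The behavioral state is re-sampled at every bout end and at every
    (period, trial) boundary; state probabilities are dwell-weighted so
    that configured occupancies equal expected time fractions.  Fully
    reproducible given ``(params.seed, animal_seed)``.
    """
    if params.fps <= 0 or params.calibration <= 0:
        raise InputError("fps and calibration must be > 0")
    fps = params.fps
    em = params.emission
    rng = np.random.default_rng([abs(params.seed), abs(animal_seed), 17])
    periods, trials = _frame_labels(schedule, fps)
    n = len(periods)
    session = schedule.spec.session

    mean_dwell = {s: em.mean_dwell(s, fps) for s in _STATES}

    v = np.zeros(n)
    airborne = np.zeros(n, dtype=np.int8)
    states: list[tuple[str, int, int]] = []  # (state, first, last) frames

    # segment boundaries where the (period, trial) cell changes
    seg_change = np.flatnonzero(
        (periods[1:] != periods[:-1]) | (trials[1:] != trials[:-1])) + 1
    seg_ends = np.append(seg_change, n)

    i = 0
    seg_ptr = 0
    last_loco = None
    while i < n:
        while seg_ends[seg_ptr] <= i:
            seg_ptr += 1
        seg_end = int(seg_ends[seg_ptr])
        cell = params.occupancy(session, Period(periods[i]), int(trials[i]))
        loco_mean = cell.pop("locomote_speed", em.locomote_speed_mean)
        # dwell-weighted decision probabilities (renewal correction)
        names = [s for s in _STATES if cell[s] > 0]
        weights = np.array([cell[s] / mean_dwell[s] for s in names])
        state = names[rng.choice(len(names), p=weights / weights.sum())]
        remaining = seg_end - i
        if remaining < em.min_frames(state, fps) and state in ("dart",
                                                               "jump"):
            state = "locomote" if cell["locomote"] > 0 else "freeze"

        if state == "freeze":
            d = min(int(round(rng.uniform(*em.freeze_dwell) * fps)),
                    remaining)
            v[i:i + d] = np.clip(
                rng.normal(em.freeze_speed_mean, em.freeze_speed_sd, d),
                0.0, em.freeze_speed_max)
        elif state == "locomote":
            d = min(int(round(rng.uniform(*em.locomote_dwell) * fps)),
                    remaining)
            lo, hi = em.locomote_speed_clip
            cur = last_loco if last_loco is not None else loco_mean
            ar, sd = em.locomote_ar, em.locomote_speed_sd
            noise = rng.normal(0.0, sd * np.sqrt(1 - ar * ar), d)
            seq = np.empty(d)
            for k in range(d):
                cur = loco_mean + ar * (cur - loco_mean) + noise[k]
                seq[k] = cur
            seq = np.clip(seq, lo, min(hi, loco_mean + 3 * sd))
            v[i:i + d] = seq
            last_loco = float(seq[-1])
        elif state == "dart":
            d = min(int(rng.integers(em.dart_frames[0],
                                     em.dart_frames[1] + 1)), remaining)
            peak = rng.uniform(*em.dart_peak)
            prof = np.full(d, peak)
            ramp = min(3, max(1, (d - 2) // 2))
            prof[0] = prof[-1] = 1.0
            for k in range(1, ramp + 1):
                frac = k / (ramp + 1)
                prof[k] = 1.0 + (peak - 1.0) * frac
                prof[-1 - k] = 1.0 + (peak - 1.0) * frac
            v[i:i + d] = prof
        else:  # jump
            d = min(int(rng.integers(em.jump_frames[0],
                                     em.jump_frames[1] + 1)), remaining)
            v[i:i + d] = rng.uniform(*em.jump_speed, d)
            airborne[i:i + d] = 1
        states.append((state, i, i + d - 1))
        i += d

    # integrate a bounded smooth walk from the speed series
    radius = params.arena_diameter / 2.0
    r_eff = radius - 1.0
    theta = rng.uniform(0, 2 * np.pi)
    pos = np.zeros((n, 2))
    cur = rng.uniform(-radius / 3, radius / 3, 2)
    turn = rng.normal(0.0, 0.35, n)
    for k in range(n):
        theta += turn[k]
        step = v[k] / fps
        nxt = cur + step * np.array([np.cos(theta), np.sin(theta)])
        if np.hypot(*nxt) > r_eff:
            # turn back toward the arena centre
            theta = np.arctan2(-cur[1], -cur[0]) + rng.normal(0.0, 0.2)
            nxt = cur + step * np.array([np.cos(theta), np.sin(theta)])
            if np.hypot(*nxt) > r_eff:
                nxt = cur * max(0.0, 1.0 - step / max(np.hypot(*cur), 1e-9))
        pos[k] = nxt
        cur = nxt

    # frame k's displacement from frame k-1 encodes v[k] exactly
    x_px = 320.0 + pos[:, 0] / params.calibration
    y_px = 240.0 + pos[:, 1] / params.calibration

    traj = Trajectory(fps=fps, t=np.arange(n) / fps, x=x_px, y=y_px,
                      calibration=params.calibration,
                      channels={"airborne": airborne})
    behavior_map = {"freeze": Behavior.FREEZE, "locomote": Behavior.LOCOMOTE,
                    "dart": Behavior.DART, "jump": Behavior.JUMP}
    bouts = []
    # adjacent same-state intervals merge, except darts: each dart burst
    # returns to rest, so back-to-back darts are distinct bouts (jumps
    # merge because a jump is a maximal airborne run by definition)
    mergeable = (Behavior.FREEZE, Behavior.LOCOMOTE, Behavior.JUMP)
    for state, first, last in states:
        if bouts and bouts[-1].behavior is behavior_map[state] \
                and bouts[-1].behavior in mergeable \
                and abs(bouts[-1].end - first / fps) < 1e-9:
            bouts[-1] = Bout(bouts[-1].behavior, bouts[-1].start,
                             (last + 1) / fps)
        else:
            bouts.append(Bout(behavior_map[state], first / fps,
                              (last + 1) / fps))
    return AnnotatedTrajectory(trajectory=traj, truth_bouts=bouts,
                               schedule=schedule)


def simulate_cohort(group: Group | str, n_animals: int,
                    sessions: Sequence[Session | str],
                    params: SimParams | None = None,
                    seed: int = 0) -> list[CohortAnimal]:
    """Simulate a cohort across sessions with per-animal sub-seeds.

    All animals of a group share each session's stimulus schedule (as in
    the real paradigm, where one program drives each group's session);
    sex labels are assigned in equal numbers (males first).
    """
    if n_animals < 1:
        raise InputError("n_animals must be >= 1")
    if not sessions:
        raise InputError("session list must not be empty")
    group = Group(group)
    if params is None:
        params = default_params(group, seed=seed)
    schedules = {Session(s): build_schedule(session_spec(Session(s), group,
                                                         seed=seed))
                 for s in sessions}
    animals = []
    for a in range(n_animals):
        sex = "M" if a < (n_animals + 1) // 2 else "F"
        sess_data = {}
        for s, schedule in schedules.items():
            sub_seed = 1000 * a + list(Session).index(s)
            annotated = simulate_session(schedule, params,
                                         animal_seed=sub_seed)
            annotated.animal_id = f"{group.value}_{a:03d}"
            annotated.sex = sex
            sess_data[s.value] = annotated
        animals.append(CohortAnimal(animal_id=f"{group.value}_{a:03d}",
                                    sex=sex, sessions=sess_data))
    return animals
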