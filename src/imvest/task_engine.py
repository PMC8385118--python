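"""Headless simulation of the adaptive VR stress task and its control scenario.

The stress scenario presents timed mental-arithmetic trials inside a virtual
3 x 5 m tiled room.  Display time is titrated in 60 ms steps to pin a rolling
five-trial accuracy inside a 40-60% band; wrong (or timed-out, or randomly
"flipped") answers blow up a random floor tile, and walking over the resulting
gap makes the simulated participant fall into a fresh room.  The control
scenario presents easy one-digit arithmetic at a fixed, generous display time
with none of the stressful elements.

Everything here is deterministic given a seed: simulated agents stand in for
human participants, and the session log (tick positions, trial records, tile
events, trigger stream) mirrors what the original desktop application writes.
"""

from __future__ import annotations

import json
import math
import os
import re
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EngineConfig",
    "TrialRecord",
    "SessionLog",
    "AgentSpec",
    "BehaviorSummary",
    "Trigger",
    "GAP",
    "OUT_OF_ROOM",
    "ROOM_COLS",
    "ROOM_ROWS",
    "N_TILES",
    "CENTER_TILES",
    "CORNER_TILES",
    "EDGE_TILES",
    "rolling_performance",
    "update_display_time",
    "sample_iti",
    "generate_formula",
    "evaluate_formula",
    "adjudicate_response",
    "explode_random_tile",
    "point_to_tile",
    "run_session",
    "behavior_metrics",
    "write_session_log",
    "read_session_log",
    "read_settings",
    "write_settings",
]

# ---------------------------------------------------------------------------
# Room geometry: 3 x 5 grid of 1 m^2 tiles, x in [0, 3), z in [0, 5),
# row-major index = row * 3 + col with col = floor(x), row = floor(z).
# ---------------------------------------------------------------------------

ROOM_COLS = 3
ROOM_ROWS = 5
N_TILES = ROOM_COLS * ROOM_ROWS

GAP = -1
OUT_OF_ROOM = -2

#: the 3 central tiles (x in [1,2), z in [1,4))
CENTER_TILES = frozenset(r * ROOM_COLS + 1 for r in (1, 2, 3))
#: the 4 corner tiles
CORNER_TILES = frozenset(
    r * ROOM_COLS + c for r in (0, ROOM_ROWS - 1) for c in (0, ROOM_COLS - 1)
)
#: the 12 peripheral tiles (everything but the center; corners included)
EDGE_TILES = frozenset(range(N_TILES)) - CENTER_TILES

#: backward shift (m) from the HMD to the body position used for tile tests
BODY_OFFSET = 0.10


class Trigger(IntEnum):
    """Numbered trigger events logged in place of hardware serial pulses."""

    SESSION_START = 1
    TRAINING_START = 2
    TRAINING_END = 3
    T1_START = 11
    T2_START = 12
    T3_START = 13
    T4_START = 14
    T1_END = 21
    T2_END = 22
    T3_END = 23
    T4_END = 24
    EXPLOSION = 30
    FALL = 31
    RESTART = 32
    VOICE_PAUSE = 33
    SESSION_END = 40


TEST_BLOCKS = ("T1", "T2", "T3", "T4")


@dataclass
class EngineConfig:
    """All task parameters; defaults replicate the published scenario."""

    initial_display_time: float = 2.5  # s
    display_step: float = 0.060  # s
    display_guard_min: float = 1.0  # s; decrement only while above this
    display_guard_max: float = 3.0  # s; increment only while below this
    perf_band: tuple[float, float] = (0.40, 0.60)
    rolling_window: int = 5
    iti_mean: float = 1.75  # s
    iti_jitter: float = 0.525  # s, uniform half-width
    flip_prob: float = 0.05
    flip_basis: str = "correct-only"  # or "all-trials"
    faux_average: float = 63.0  # percent
    block_duration: float = 150.0  # s
    n_test_blocks: int = 4
    training_trials: int = 4
    alarm_duration: float = 1.0  # s
    explosion_duration: float = 0.75  # s
    fall_duration: float = 2.0  # s trial scheduling suspended by a fall
    fall_accel_factor: float = 1.2  # per 16 ms frame
    fall_initial_speed: float = 0.05  # m per 16 ms frame
    fall_landing_depth: float = 10.0  # m
    control_display_time: float = 5.0  # s
    control_iti: float = 1.0  # s
    voice_pause: float = 10.0  # s; session clock pauses during it
    position_rate: float = 10.0  # Hz tick rate of the position log
    timeout_incorrect_frac: float = 0.3  # agent: P(timeout | wrong)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.display_guard_min < self.initial_display_time < self.display_guard_max):
            raise ValueError("initial display time must lie strictly inside the guards")
        if not self.perf_band[0] < self.perf_band[1]:
            raise ValueError("perf_band lower bound must be below upper bound")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")
        if self.rolling_window < 1:
            raise ValueError("rolling_window must be >= 1")
        if self.block_duration <= 0:
            raise ValueError("zero-duration blocks are not allowed")
        if self.flip_basis not in ("correct-only", "all-trials"):
            raise ValueError("flip_basis must be 'correct-only' or 'all-trials'")


@dataclass
class TrialRecord:
    trial_index: int
    block: str  # training, T1..T4
    formula: str
    formula_truth: bool
    display_time: float  # s
    response: str  # true-press | false-press | timeout
    response_latency: float | None  # s, None on timeout
    raw_correct: bool
    flipped: bool
    recorded_outcome: bool
    exploded_tile: int | None
    onset_time: float  # s from session start
    adjustment: int = 0  # +1 display-time increment, -1 decrement, 0 none


@dataclass
class SessionLog:
    participant_id: str
    scenario: str  # stress | control
    trials: list[TrialRecord] = field(default_factory=list)
    ticks: pd.DataFrame | None = None
    tile_events: list[dict] = field(default_factory=list)
    falls: list[dict] = field(default_factory=list)
    triggers: list[tuple[int, float]] = field(default_factory=list)
    blocks: list[tuple[str, float, float]] = field(default_factory=list)

    def block_window(self, label: str) -> tuple[float, float] | None:
        for name, t0, t1 in self.blocks:
            if name == label:
                return (t0, t1)
        return None


@dataclass
class AgentSpec:
    """Simulated participant: psychometric curve, latency and movement models.

    Accuracy is a logistic in display time, ``P(correct; dt) =
    1 / (1 + exp(-(dt - c) / acc_scale))`` with the offset ``c`` fixed so that
    ``P(correct; 2.5 s) = ability``.  It is monotone increasing in display
    time, as titration requires.
    """

    ability: float = 0.5  # P(correct) at the 2.5 s reference display time
    acc_scale: float = 0.35  # s, logistic scale of the psychometric curve
    movement: str = "random-walk"  # or "stationary"
    move_speed: float = 0.35  # m/s random-walk speed
    heading_sd: float = 0.8  # rad/s heading diffusion

    def p_correct(self, display_time: float) -> float:
        a = min(max(self.ability, 0.01), 0.99)
        c = 2.5 - self.acc_scale * math.log(a / (1.0 - a))
        return 1.0 / (1.0 + math.exp(-(display_time - c) / self.acc_scale))

    def sample_latency(self, display_time: float, rng: np.random.Generator) -> float:
        # strictly below display time, centred near 55% of it
        return display_time * (0.15 + 0.75 * rng.beta(2.0, 2.0))


@dataclass
class BehaviorSummary:
    """Per-block behavioral and difficulty-adjustment metrics (T1-T4)."""

    blocks: dict = field(default_factory=dict)  # label -> dict of metrics

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self.blocks, orient="index")


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def rolling_performance(outcomes: Sequence[bool], window: int) -> float:
    """Fraction of correct outcomes among the most recent ``window`` trials.

    With fewer than ``window`` trials available the fraction is computed over
    what exists.
    """
    if len(outcomes) == 0:
        raise ValueError("rolling performance is undefined for an empty outcome list")
    recent = list(outcomes)[-window:]
    return sum(bool(o) for o in recent) / len(recent)


def _to_ms(seconds: float) -> int:
    return int(round(seconds * 1000.0))


def update_display_time(rolling_perf: float, display_time: float, cfg: EngineConfig) -> float:
    """One titration step: +/-60 ms depending on performance and guards.

    Guards are evaluated on the *current* value, so 3.04 s is reachable from
    2.98 s and 1.00 s is a hard floor only because the decrement guard fails
    there.  Arithmetic is done in integer milliseconds so that every change is
    exactly one step.
    """
    if display_time <= 0:
        raise ValueError("display_time must be positive")
    dt = _to_ms(display_time)
    step = _to_ms(cfg.display_step)
    lo, hi = cfg.perf_band
    if rolling_perf > hi and dt > _to_ms(cfg.display_guard_min):
        dt -= step
    elif rolling_perf < lo and dt < _to_ms(cfg.display_guard_max):
        dt += step
    return dt / 1000.0


def sample_iti(cfg: EngineConfig, rng: np.random.Generator, training: bool = False) -> float:
    """Inter-trial interval: fixed during training, uniformly jittered in test."""
    if training:
        return cfg.iti_mean
    return cfg.iti_mean + rng.uniform(-cfg.iti_jitter, cfg.iti_jitter)


_FORMULA_RE = re.compile(r"^\s*(\d+)\s*([+\-−])\s*(\d+)\s*=\s*(\d+)\s*$")


def evaluate_formula(text: str) -> bool:
    """True iff the displayed equality holds arithmetically."""
    m = _FORMULA_RE.match(text)
    if m is None:
        raise ValueError(f"unparseable formula: {text!r}")
    a, op, b, shown = int(m.group(1)), m.group(2), int(m.group(3)), int(m.group(4))
    value = a + b if op == "+" else a - b
    return value == shown


def generate_formula(scenario: str, rng: np.random.Generator) -> tuple[str, bool]:
    """Draw an addition/subtraction equality; displayed truth is 50/50.

    Control: one-digit operands.  Stress: operands 1-99 with non-negative
    results (difficulty is carried by display time, not operand size).
    """
    hi = 9 if scenario == "control" else 99
    a = int(rng.integers(1, hi + 1))
    b = int(rng.integers(1, hi + 1))
    op = "+" if rng.random() < 0.5 else "-"
    if op == "-" and b > a:
        a, b = b, a
    value = a + b if op == "+" else a - b
    truth = bool(rng.random() < 0.5)
    if truth:
        shown = value
    else:
        delta = int(rng.integers(1, 11))
        if rng.random() < 0.5 and value - delta >= 0:
            shown = value - delta
        else:
            shown = value + delta
    formula = f"{a} {op} {b} = {shown}"
    return formula, truth


def adjudicate_response(
    raw_response: str,
    truth: bool,
    flip_draw: float,
    cfg: EngineConfig,
) -> tuple[bool, bool, bool]:
    """Score a trial: (raw_correct, flipped, recorded_outcome).

    A timeout is always recorded incorrect.  With the default
    ``correct-only`` flip basis, a correct press is recorded incorrect with
    probability ``flip_prob``; with ``all-trials`` any press is force-scored
    incorrect with that probability.
    """
    if raw_response == "timeout":
        return False, False, False
    if raw_response not in ("true-press", "false-press"):
        raise ValueError(f"unknown response {raw_response!r}")
    raw_correct = (raw_response == "true-press") == bool(truth)
    if cfg.flip_basis == "correct-only":
        if raw_correct and flip_draw < cfg.flip_prob:
            return True, True, False
        return raw_correct, False, raw_correct
    # all-trials basis
    if flip_draw < cfg.flip_prob:
        return raw_correct, True, False
    return raw_correct, False, raw_correct


def explode_random_tile(
    remaining: Iterable[int], rng: np.random.Generator
) -> tuple[frozenset[int], int | None, bool]:
    """Remove one uniformly chosen remaining tile.

    Returns (new remaining set, exploded tile or None, fall_inevitable flag).
    With no tiles left, falling is inevitable and the state is returned
    unchanged.
    """
    tiles = sorted(remaining)
    if not tiles:
        return frozenset(), None, True
    tile = tiles[int(rng.integers(0, len(tiles)))]
    return frozenset(t for t in tiles if t != tile), tile, False


def point_to_tile(x: float, z: float, removed: Iterable[int] = ()) -> int:
    """Row-major tile index under (x, z); GAP if removed, OUT_OF_ROOM outside.

    The caller is responsible for converting an HMD position to the body
    position (0.10 m behind the HMD) before calling.
    """
    if not (math.isfinite(x) and math.isfinite(z)):
        raise ValueError("coordinates must be finite")
    if not (0.0 <= x < ROOM_COLS and 0.0 <= z < ROOM_ROWS):
        return OUT_OF_ROOM
    idx = int(z) * ROOM_COLS + int(x)
    if idx in set(removed):
        return GAP
    return idx


# ---------------------------------------------------------------------------
# Session simulation
# ---------------------------------------------------------------------------


class _Walker:
    """Agent position process, ticked at the position-log rate."""

    def __init__(self, agent: AgentSpec, rng: np.random.Generator, dt: float):
        self.agent = agent
        self.rng = rng
        self.dt = dt
        self.x = 1.5
        self.z = 2.5
        self.heading = rng.uniform(0, 2 * math.pi) if agent.movement == "random-walk" else 0.0

    def step(self) -> tuple[float, float]:
        if self.agent.movement == "stationary":
            return self.x, self.z
        self.heading += self.rng.normal(0.0, self.agent.heading_sd * math.sqrt(self.dt))
        step = self.agent.move_speed * self.dt
        nx = self.x + step * math.sin(self.heading)
        nz = self.z + step * math.cos(self.heading)
        # reflect off the walls (small margin keeps the body inside the room)
        m = 0.05
        if nx < m or nx > ROOM_COLS - m:
            nx = min(max(nx, m), ROOM_COLS - m)
            self.heading = -self.heading
        if nz < BODY_OFFSET + m or nz > ROOM_ROWS - m:
            nz = min(max(nz, BODY_OFFSET + m), ROOM_ROWS - m)
            self.heading = math.pi - self.heading
        self.x, self.z = nx, nz
        return nx, nz


class _Session:
    def __init__(self, agent, cfg: EngineConfig, scenario: str, rng, participant_id: str):
        self.agent = agent
        self.cfg = cfg
        self.scenario = scenario
        self.rng = rng
        self.t = 0.0
        self.tiles: frozenset[int] = frozenset(range(N_TILES))
        self.walker = _Walker(agent, rng, 1.0 / cfg.position_rate)
        self.log = SessionLog(participant_id=participant_id, scenario=scenario)
        self.rows: list[tuple] = []
        self.outcomes: list[bool] = []
        self.cum_correct = 0
        self.cum_total = 0
        self.display_time = cfg.initial_display_time
        self.trial_counter = 0
        self.next_tick = 0.0
        self.current_trial = 0
        self.current_truth = False
        self.current_formula = ""
        self.pending_press: tuple[float, int] | None = None

    # -- time advancing ----------------------------------------------------

    def advance(self, duration: float, check_falls: bool = False) -> None:
        """Advance the session clock, emitting position ticks; handle falls."""
        end = self.t + duration
        while self.next_tick < end:
            self.t = self.next_tick
            x, z = self.walker.step()
            body_tile = point_to_tile(x, max(z - BODY_OFFSET, 0.0), set(range(N_TILES)) - self.tiles)
            button = 0
            if self.pending_press is not None and self.t >= self.pending_press[0]:
                button = self.pending_press[1]
                self.pending_press = None
            self.rows.append(
                (
                    self.t,
                    x,
                    1.70,
                    z,
                    x + 0.20,
                    1.10,
                    z + 0.25,
                    button,
                    self.current_trial,
                    int(self.current_truth),
                    self.current_formula,
                    body_tile,
                )
            )
            self.next_tick += self.walker.dt
            if check_falls and body_tile == GAP:
                self._fall(self.t)
                end = max(end, self.t)
        self.t = max(self.t, end)

    def _fall(self, when: float) -> None:
        self.log.falls.append({"time": when, "x": self.walker.x, "z": self.walker.z})
        self.log.triggers.append((int(Trigger.FALL), when))
        # falling + landing on a fresh room; trial scheduling suspended
        self.advance(self.cfg.fall_duration, check_falls=False)
        for ev in self.log.tile_events:
            if ev["restore_time"] is None:
                ev["restore_time"] = self.t
        self.tiles = frozenset(range(N_TILES))

    # -- trial -------------------------------------------------------------

    def run_trial(self, block: str) -> None:
        cfg = self.cfg
        training = block == "training"
        control = self.scenario == "control"
        dt = cfg.control_display_time if control else (cfg.initial_display_time if training else self.display_time)
        formula, truth = generate_formula(self.scenario, self.rng)
        self.trial_counter += 1
        self.current_trial = self.trial_counter
        self.current_truth = truth
        self.current_formula = formula
        onset = self.t

        p = self.agent.p_correct(dt)
        intends_correct = self.rng.random() < p
        if intends_correct:
            response = "true-press" if truth else "false-press"
            latency = self.agent.sample_latency(dt, self.rng)
        else:
            if self.rng.random() < cfg.timeout_incorrect_frac:
                response, latency = "timeout", None
            else:
                response = "false-press" if truth else "true-press"
                latency = self.agent.sample_latency(dt, self.rng)

        flip_draw = float(self.rng.random())
        raw_correct, flipped, recorded = adjudicate_response(response, truth, flip_draw, cfg)

        if latency is not None:
            self.pending_press = (onset + latency, 1 if response == "true-press" else 2)
        self.advance(latency if latency is not None else dt, check_falls=False)

        exploded: int | None = None
        adjustment = 0
        self.outcomes.append(recorded)
        self.cum_total += 1
        self.cum_correct += int(recorded)

        if not training and not control:
            perf = rolling_performance(self.outcomes, cfg.rolling_window)
            new_dt = update_display_time(perf, self.display_time, cfg)
            adjustment = int(round((new_dt - self.display_time) / cfg.display_step))
            self.display_time = new_dt
            if not recorded:
                self.tiles, exploded, inevitable = explode_random_tile(self.tiles, self.rng)
                if exploded is not None:
                    self.log.tile_events.append(
                        {"tile": exploded, "removal_time": self.t, "restore_time": None}
                    )
                    self.log.triggers.append((int(Trigger.EXPLOSION), self.t))
                    self.advance(cfg.alarm_duration, check_falls=True)
                if inevitable:
                    self._fall(self.t)

        self.log.trials.append(
            TrialRecord(
                trial_index=self.trial_counter,
                block=block,
                formula=formula,
                formula_truth=truth,
                display_time=dt,
                response=response,
                response_latency=latency,
                raw_correct=raw_correct,
                flipped=flipped,
                recorded_outcome=recorded,
                exploded_tile=exploded,
                onset_time=onset,
                adjustment=adjustment,
            )
        )

        self.current_formula = ""
        self.current_trial = 0
        iti = cfg.control_iti if control else sample_iti(cfg, self.rng, training=training)
        self.advance(iti, check_falls=(not training and not control))

    # -- restart -----------------------------------------------------------

    def restart(self) -> None:
        self.log.triggers.append((int(Trigger.RESTART), self.t))
        self.display_time = self.cfg.initial_display_time
        self.outcomes.clear()
        self.cum_correct = 0
        self.cum_total = 0
        for ev in self.log.tile_events:
            if ev["restore_time"] is None:
                ev["restore_time"] = self.t
        self.tiles = frozenset(range(N_TILES))


def run_session(
    agent: AgentSpec,
    cfg: EngineConfig,
    scenario: str = "stress",
    rng: np.random.Generator | int | None = None,
    participant_id: str = "",
) -> SessionLog:
    """Simulate one full session (training then T1-T4) and return its log.

    Deterministic given the seed.  The stress scenario titrates display time,
    explodes tiles on recorded errors, pauses for voice messages after T1, T2
    and T3 (the task clock stops, so no task time is consumed), and performs a
    full restart at the end of T2 (display time, performance counters and all
    15 tiles reset).  The control scenario uses a fixed 5 s display, 1 s ITI,
    no explosions, no titration, and block T4 has no arithmetic.
    """
    if scenario not in ("stress", "control"):
        raise ValueError("scenario must be 'stress' or 'control'")
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    s = _Session(agent, cfg, scenario, rng, participant_id)
    s.log.triggers.append((int(Trigger.SESSION_START), 0.0))

    # training: fixed number of trials, fixed display time and ITI
    s.log.triggers.append((int(Trigger.TRAINING_START), s.t))
    t0 = s.t
    for _ in range(cfg.training_trials):
        s.run_trial("training")
    s.log.blocks.append(("training", t0, s.t))
    s.log.triggers.append((int(Trigger.TRAINING_END), s.t))

    start_codes = (Trigger.T1_START, Trigger.T2_START, Trigger.T3_START, Trigger.T4_START)
    end_codes = (Trigger.T1_END, Trigger.T2_END, Trigger.T3_END, Trigger.T4_END)
    for b in range(cfg.n_test_blocks):
        label = TEST_BLOCKS[b]
        s.log.triggers.append((int(start_codes[b]), s.t))
        t0 = s.t
        t_end = t0 + cfg.block_duration
        if scenario == "control" and label == "T4":
            s.advance(cfg.block_duration)  # free play, no arithmetic
        else:
            while s.t < t_end:
                s.run_trial(label)
        s.log.blocks.append((label, t0, s.t))
        s.log.triggers.append((int(end_codes[b]), s.t))
        if label in ("T1", "T2", "T3"):
            s.log.triggers.append((int(Trigger.VOICE_PAUSE), s.t))
        if label == "T2" and scenario == "stress":
            s.restart()

    s.log.triggers.append((int(Trigger.SESSION_END), s.t))
    s.log.ticks = pd.DataFrame(
        s.rows,
        columns=[
            "time_s",
            "hmd_x",
            "hmd_y",
            "hmd_z",
            "ctrl_x",
            "ctrl_y",
            "ctrl_z",
            "button",
            "trial_number",
            "trial_truth",
            "formula",
            "current_tile",
        ],
    )
    return s.log


# ---------------------------------------------------------------------------
# Behavioral metrics
# ---------------------------------------------------------------------------


def behavior_metrics(log: SessionLog) -> BehaviorSummary:
    """Per-block (T1-T4) behavior and difficulty-adjustment summary.

    Distance is the summed horizontal (x, z) HMD path length; position-class
    times are derived from the body tile under each position tick, so
    ``time_center + time_edges`` equals the on-floor time of the block.
    """
    out = BehaviorSummary()
    ticks = log.ticks if log.ticks is not None else pd.DataFrame()
    tick_dt = None
    if len(ticks) > 1:
        tick_dt = float(np.median(np.diff(ticks["time_s"].to_numpy())))
    for label in TEST_BLOCKS:
        window = log.block_window(label)
        trials = [tr for tr in log.trials if tr.block == label]
        if window is None or (not trials and log.scenario == "stress"):
            out.blocks[label] = {"present": False}
            continue
        t0, t1 = window
        m: dict = {"present": True}
        if trials:
            m["performance"] = float(np.mean([tr.recorded_outcome for tr in trials]))
            lats = [tr.response_latency for tr in trials if tr.response_latency is not None]
            m["latency"] = float(np.mean(lats)) if lats else float("nan")
            m["competence"] = m["performance"] / m["latency"] if lats and m["latency"] > 0 else float("nan")
            m["increments_pct"] = 100.0 * np.mean([tr.adjustment > 0 for tr in trials])
            m["decrements_pct"] = 100.0 * np.mean([tr.adjustment < 0 for tr in trials])
            m["adjustment_balance"] = m["decrements_pct"] - m["increments_pct"]
            m["n_trials"] = len(trials)
        m["falls"] = sum(1 for f in log.falls if t0 <= f["time"] < t1)
        if len(ticks):
            sel = ticks[(ticks["time_s"] >= t0) & (ticks["time_s"] < t1)]
            xy = sel[["hmd_x", "hmd_z"]].to_numpy()
            m["distance"] = float(np.sum(np.hypot(*np.diff(xy, axis=0).T))) if len(xy) > 1 else 0.0
            tiles = sel["current_tile"].to_numpy()
            on_floor = tiles[tiles >= 0]
            m["tiles_visited"] = int(len(np.unique(on_floor)))
            dt = tick_dt or 0.0
            m["time_center"] = float(np.isin(on_floor, list(CENTER_TILES)).sum() * dt)
            m["time_edges"] = float(np.isin(on_floor, list(EDGE_TILES)).sum() * dt)
            m["time_corners"] = float(np.isin(on_floor, list(CORNER_TILES)).sum() * dt)
        out.blocks[label] = m
    return out


# ---------------------------------------------------------------------------
# Serialization: tick CSV + trial CSV + events JSON, round-trip exact
# ---------------------------------------------------------------------------

_TICK_COLUMNS = [
    "time_s",
    "hmd_x",
    "hmd_y",
    "hmd_z",
    "ctrl_x",
    "ctrl_y",
    "ctrl_z",
    "button",
    "trial_number",
    "trial_truth",
    "formula",
    "current_tile",
]

_TRIAL_COLUMNS = [
    "trial_index",
    "block",
    "formula",
    "formula_truth",
    "display_time",
    "response",
    "response_latency",
    "raw_correct",
    "flipped",
    "recorded_outcome",
    "exploded_tile",
    "onset_time",
    "adjustment",
]


def write_session_log(log: SessionLog, path: str) -> None:
    """Write a session log to a directory: session.csv, trials.csv, events.json.

    An empty participant id is replaced by a random identifier, mirroring the
    original application's behavior.
    """
    os.makedirs(path, exist_ok=True)
    pid = log.participant_id
    if not pid:
        pid = f"P{np.random.default_rng().integers(10**8):08d}"
        log.participant_id = pid
    ticks = log.ticks if log.ticks is not None else pd.DataFrame(columns=_TICK_COLUMNS)
    ticks.to_csv(os.path.join(path, "session.csv"), index=False)
    rows = []
    for tr in log.trials:
        rows.append(
            {
                "trial_index": tr.trial_index,
                "block": tr.block,
                "formula": tr.formula,
                "formula_truth": int(tr.formula_truth),
                "display_time": repr(tr.display_time),
                "response": tr.response,
                "response_latency": "" if tr.response_latency is None else repr(tr.response_latency),
                "raw_correct": int(tr.raw_correct),
                "flipped": int(tr.flipped),
                "recorded_outcome": int(tr.recorded_outcome),
                "exploded_tile": "" if tr.exploded_tile is None else tr.exploded_tile,
                "onset_time": repr(tr.onset_time),
                "adjustment": tr.adjustment,
            }
        )
    pd.DataFrame(rows, columns=_TRIAL_COLUMNS).to_csv(os.path.join(path, "trials.csv"), index=False)
    meta = {
        "participant_id": pid,
        "scenario": log.scenario,
        "blocks": log.blocks,
        "tile_events": log.tile_events,
        "falls": log.falls,
    }
    with open(os.path.join(path, "events.json"), "w") as fh:
        json.dump(meta, fh)
    with open(os.path.join(path, "triggers.jsonl"), "w") as fh:
        for code, t in log.triggers:
            fh.write(json.dumps({"code": int(code), "time_s": t}) + "\n")


def read_session_log(path: str) -> SessionLog:
    """Read a directory written by :func:`write_session_log` (exact round-trip)."""
    ticks = pd.read_csv(
        os.path.join(path, "session.csv"), float_precision="round_trip", keep_default_na=False
    )
    missing = [c for c in _TICK_COLUMNS if c not in ticks.columns]
    if missing:
        raise ValueError(f"session.csv is missing required column(s): {', '.join(missing)}")
    ticks = ticks[_TICK_COLUMNS]
    for col, dtype in [("time_s", float), ("hmd_x", float), ("hmd_y", float), ("hmd_z", float),
                       ("ctrl_x", float), ("ctrl_y", float), ("ctrl_z", float),
                       ("button", int), ("trial_number", int), ("trial_truth", int),
                       ("current_tile", int)]:
        ticks[col] = ticks[col].astype(dtype)
    ticks["formula"] = ticks["formula"].astype(str).replace("nan", "")

    trials_df = pd.read_csv(
        os.path.join(path, "trials.csv"),
        float_precision="round_trip",
        keep_default_na=False,
        dtype=str,
    )
    missing = [c for c in _TRIAL_COLUMNS if c not in trials_df.columns]
    if missing:
        raise ValueError(f"trials.csv is missing required column(s): {', '.join(missing)}")
    trials = []
    for i, row in enumerate(trials_df.itertuples(index=False), start=2):
        try:
            trials.append(
                TrialRecord(
                    trial_index=int(row.trial_index),
                    block=row.block,
                    formula=row.formula,
                    formula_truth=bool(int(row.formula_truth)),
                    display_time=float(row.display_time),
                    response=row.response,
                    response_latency=None if row.response_latency == "" else float(row.response_latency),
                    raw_correct=bool(int(row.raw_correct)),
                    flipped=bool(int(row.flipped)),
                    recorded_outcome=bool(int(row.recorded_outcome)),
                    exploded_tile=None if row.exploded_tile == "" else int(row.exploded_tile),
                    onset_time=float(row.onset_time),
                    adjustment=int(row.adjustment),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"trials.csv: malformed row at line {i}: {exc}") from exc
    with open(os.path.join(path, "events.json")) as fh:
        meta = json.load(fh)
    triggers = []
    with open(os.path.join(path, "triggers.jsonl")) as fh:
        for line in fh:
            d = json.loads(line)
            triggers.append((d["code"], d["time_s"]))
    return SessionLog(
        participant_id=meta["participant_id"],
        scenario=meta["scenario"],
        trials=trials,
        ticks=ticks,
        tile_events=meta["tile_events"],
        falls=meta["falls"],
        triggers=triggers,
        blocks=[tuple(b) for b in meta["blocks"]],
    )


# ---------------------------------------------------------------------------
# Settings file (key=value text)
# ---------------------------------------------------------------------------

_SETTINGS_KEYS = {
    "initial_display_time": float,
    "display_step": float,
    "display_guard_min": float,
    "display_guard_max": float,
    "iti_mean": float,
    "iti_jitter": float,
    "flip_prob": float,
    "flip_basis": str,
    "faux_average": float,
    "block_duration": float,
    "training_trials": int,
    "voice_pause": float,
    "control_display_time": float,
    "control_iti": float,
    "rng_seed": int,
}


def read_settings(path: str) -> EngineConfig:
    """Load an EngineConfig from a ``key=value`` text settings file."""
    overrides: dict = {}
    band = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"settings file line {lineno}: expected key=value, got {line!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in ("perf_lower", "perf_upper"):
                band[key] = float(value)
            elif key in _SETTINGS_KEYS:
                overrides[key] = _SETTINGS_KEYS[key](value)
            # unknown keys (audio paths, serial port ids) are ignored
    cfg = EngineConfig(**overrides)
    if band:
        cfg = replace(
            cfg,
            perf_band=(band.get("perf_lower", cfg.perf_band[0]), band.get("perf_upper", cfg.perf_band[1])),
        )
    return cfg


def write_settings(cfg: EngineConfig, path: str) -> None:
    with open(path, "w") as fh:
        for key in _SETTINGS_KEYS:
            fh.write(f"{key}={getattr(cfg, key)}\n")
        fh.write(f"perf_lower={cfg.perf_band[0]}\n")
        fh.write(f"perf_upper={cfg.perf_band[1]}\n")
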