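"""Glucose supply schedules and chamber-level glucose/washout dynamics.

Two chamber models are supported:

* **chemostat** — glucose in the chamber is depleted by cellular uptake and
  replenished by medium flow at dilution rate ``D``; cells wash out at
  per-capita rate ``D`` (removal rate D*N).
* **NCG** ("no competition for glucose") — the limiting case of a very
  large, fast-flowing chamber: cells no longer affect the glucose
  concentration, which simply relaxes toward the supply concentration at
  rate ``D``.  Population size is regulated instead by crowding: the removal
  rate is d*N^2, i.e. the per-capita loss rate grows with N.

The supply concentration [Glc]_0(t) follows a schedule: constant, a square
wave with equal ON/OFF phases, or a pulse train of short ON pulses separated
by long OFF phases whose durations may vary from cycle to cycle
(truncated-normal draws, cached per cycle so a realization is reproducible
from its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GlucoseSchedule",
    "ScheduleRealization",
    "EnvironmentConfig",
    "supply_concentration",
    "glucose_derivative",
    "removal_count",
]

#: Shortest OFF phase allowed when OFF durations are drawn at random (min).
MIN_OFF_DURATION = 1.0


@dataclass(frozen=True)
class GlucoseSchedule:
    """Supply-concentration schedule [Glc]_0(t).

    ``kind`` is one of ``constant`` (always ``glc0_on``), ``square_wave``
    (ON and OFF phases of equal duration ``T_on``) or ``pulse_train``
    (ON pulses of ``T_on`` minutes separated by OFF phases of mean
    ``T_off_mean`` with coefficient of variation ``T_off_cv``).
    ``t_origin`` shifts the phase origin.
    """

    kind: str = "constant"
    glc0_on: float = 2.0
    glc0_off: float = 0.01
    T_on: float = 20.0
    T_off_mean: float = 20.0
    T_off_cv: float = 0.0
    t_origin: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "square_wave", "pulse_train"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.glc0_on < 0 or self.glc0_off < 0:
            raise ValueError("supply concentrations must be non-negative")
        if self.kind != "constant":
            if self.T_on <= 0 or self.T_off_mean <= 0:
                raise ValueError("phase durations must be positive")
        if self.T_off_cv < 0:
            raise ValueError("T_off_cv must be non-negative")

    @property
    def off_duration_fixed(self) -> float:
        """OFF duration for deterministic schedules (square wave: = T_on)."""
        return self.T_on if self.kind == "square_wave" else self.T_off_mean

    @property
    def mean_period(self) -> float:
        if self.kind == "constant":
            return float("inf")
        return self.T_on + self.off_duration_fixed


class ScheduleRealization:
    """A concrete realization of a schedule: cycle boundaries and lookups.

    OFF durations with ``T_off_cv > 0`` are drawn lazily, one per cycle, from
    a normal distribution (mean ``T_off_mean``, sd = cv * mean) truncated
    below at :data:`MIN_OFF_DURATION`, and cached — queries at any time are
    reproducible given the same seed.
    """

    def __init__(self, schedule: GlucoseSchedule, rng: np.random.Generator | None = None):
        self.schedule = schedule
        self._rng = rng if rng is not None else np.random.default_rng(0)
        # boundaries[i] is the start time of segment i; values alternate
        # ON, OFF, ON, OFF, ... starting with ON at t_origin.
        self._boundaries: list[float] = [schedule.t_origin]
        self._is_on: list[bool] = [True]

    def _draw_off(self) -> float:
        s = self.schedule
        if s.T_off_cv == 0:
            return s.off_duration_fixed
        d = self._rng.normal(s.off_duration_fixed, s.T_off_cv * s.off_duration_fixed)
        return max(d, MIN_OFF_DURATION)

    def _extend_to(self, t: float) -> None:
        s = self.schedule
        if s.kind == "constant":
            return
        while self._boundaries[-1] <= t:
            last_on = self._is_on[-1]
            dur = s.T_on if last_on else self._draw_off()
            self._boundaries.append(self._boundaries[-1] + dur)
            self._is_on.append(not last_on)

    def _segment_index(self, t: float) -> int:
        self._extend_to(t)
        return int(np.searchsorted(self._boundaries, t, side="right") - 1)

    def supply(self, t: float) -> float:
        """[Glc]_0 at time t (mM)."""
        if t < self.schedule.t_origin:
            raise ValueError("time before schedule origin")
        s = self.schedule
        if s.kind == "constant":
            return s.glc0_on
        i = self._segment_index(t)
        return s.glc0_on if self._is_on[i] else s.glc0_off

    def phase_at(self, t: float) -> tuple[str, int]:
        """('on'|'off', cycle index) at time t; a cycle is ON then OFF."""
        s = self.schedule
        if s.kind == "constant":
            return ("on", 0)
        i = self._segment_index(t)
        return ("on" if self._is_on[i] else "off", i // 2)

    def breakpoints(self, t0: float, t1: float) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise-constant supply over [t0, t1].

        Returns ``(times, values)`` with ``times[0] <= t0`` and subsequent
        entries the switch times inside (t0, t1); ``values[j]`` applies from
        ``times[j]`` until the next entry.
        """
        s = self.schedule
        if s.kind == "constant":
            return np.array([t0]), np.array([s.glc0_on])
        self._extend_to(t1)
        b = np.asarray(self._boundaries)
        on = np.asarray(self._is_on)
        i0 = int(np.searchsorted(b, t0, side="right") - 1)
        i1 = int(np.searchsorted(b, t1, side="left"))
        times = np.concatenate(([t0], b[i0 + 1 : i1]))
        vals = np.where(on[i0:i1], s.glc0_on, s.glc0_off).astype(float)
        return times, vals

    def cycle_bounds(self, i: int) -> tuple[float, float]:
        """(start, end) of cycle i (ON start to next ON start)."""
        s = self.schedule
        if s.kind == "constant":
            raise ValueError("constant schedule has no cycles")
        self._extend_to(self.schedule.t_origin)
        while len(self._boundaries) < 2 * i + 3:
            self._extend_to(self._boundaries[-1])
        return self._boundaries[2 * i], self._boundaries[2 * i + 2]


def initial_chamber_glucose(schedule: GlucoseSchedule) -> float:
    """Sensible chamber glucose at simulation start.

    For pulse trains the chamber rests near the OFF supply level between
    pulses (a 300 mM, 1 min pulse only raises the chamber by a few mM);
    for constant and square-wave schedules the chamber starts equilibrated
    with the supply at t = 0.
    """
    if schedule.kind == "pulse_train":
        return schedule.glc0_off
    return schedule.glc0_on


def supply_concentration(
    t: float,
    sched: GlucoseSchedule | ScheduleRealization,
    rng: np.random.Generator | None = None,
) -> float:
    """Supply concentration [Glc]_0 at time ``t``.

    Accepts either a :class:`ScheduleRealization` (preferred for repeated
    queries) or a bare schedule, in which case a realization is created on
    the fly from ``rng``.
    """
    if isinstance(sched, GlucoseSchedule):
        sched = ScheduleRealization(sched, rng)
    return sched.supply(t)


@dataclass
class EnvironmentConfig:
    """Chamber parameters: mode, volumes/rates and the glucose schedule."""

    mode: str = "ncg"
    V_ch: float = 1e-8
    D: float = 5.0
    d: float = 1e-6
    schedule: GlucoseSchedule = field(default_factory=GlucoseSchedule)

    def __post_init__(self) -> None:
        if self.mode not in ("chemostat", "ncg"):
            raise ValueError("mode must be 'chemostat' or 'ncg'")
        if self.D <= 0:
            raise ValueError("D must be positive")
        if self.mode == "chemostat" and self.V_ch <= 0:
            raise ValueError("chemostat requires V_ch > 0")
        if self.mode == "ncg" and self.d <= 0:
            raise ValueError("NCG requires d > 0")


def glucose_derivative(
    glc: float,
    v_up: np.ndarray,
    volumes: np.ndarray,
    env: EnvironmentConfig,
    glc0_now: float,
) -> float:
    """d[Glc]/dt in the chamber (mM/min).

    Chemostat: -sum_i v_up,i V_i / V_ch + D ([Glc]_0 - [Glc]).
    NCG: D ([Glc]_0 - [Glc]) — uptake does not feed back on the chamber.
    """
    if glc < 0:
        raise ValueError("glucose concentration must be non-negative")
    d_glc = env.D * (glc0_now - glc)
    if env.mode == "chemostat":
        d_glc -= float(np.dot(np.asarray(v_up), np.asarray(volumes))) / env.V_ch
    return d_glc


def removal_count(
    N: int, env: EnvironmentConfig, dt: float, rng: np.random.Generator
) -> int:
    """Number of cells removed by outflow/crowding over an interval dt.

    The per-capita loss rate is D (chemostat) or d*N (NCG).  Each cell is
    removed independently with the exact survival probability
    1 - exp(-rate * dt), so the count is binomial.
    """
    if N < 0 or dt <= 0:
        raise ValueError("need N >= 0 and dt > 0")
    if N == 0:
        return 0
    rate = env.D if env.mode == "chemostat" else env.d * N
    p = -np.expm1(-rate * dt)
    return int(rng.binomial(N, p))
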