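"""Transient well-mixed (single-zone) indoor-air model.

The space is a single box of volume V (m³) with fresh-air ventilation at an
air-change rate λ (1/h).  A constituent released at rate S(t) (µg/h) obeys

    V dC/dt = S(t) - λ V C(t),

with C spatially uniform at every instant (the well-mixed contract).  The
integrator advances the exact solution of this linear ODE over each output
step — piecewise-constant source segments use the exponential closed form,
puff events are instantaneous mass injections ΔC = m/V — so trajectories are
accurate to round-off for both source modes, and an exact cumulative vented
mass is maintained for conservation audits.

Vapor/particle partitioning of a semivolatile constituent is applied
instantaneously at each output time (gas–particle equilibration for
submicron droplets is sub-millisecond, far faster than ventilation): the
vapor phase holds up to the saturation mass concentration C* and any excess
condenses to the particle phase.  Constituents without a C* are treated as
fully volatile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SourceProfile",
    "AirState",
    "simulate_box",
    "partition_equilibrium",
    "average_concentration",
    "mass_balance_error",
]


@dataclass(frozen=True)
class SourceProfile:
    """Constituent release schedule: continuous rate or discrete puffs."""

    mode: str  # "continuous" | "puff"
    total_rate: float = 0.0  # µg/h, continuous mode
    event_times: np.ndarray = field(default_factory=lambda: np.empty(0))  # h
    event_mass: np.ndarray = field(default_factory=lambda: np.empty(0))  # µg per event

    def __post_init__(self) -> None:
        if self.mode not in ("continuous", "puff"):
            raise ValueError(f"unknown source mode {self.mode!r}")
        object.__setattr__(self, "event_times", np.atleast_1d(np.asarray(self.event_times, float)))
        masses = np.atleast_1d(np.asarray(self.event_mass, float))
        if self.mode == "puff":
            if masses.size == 1 and self.event_times.size > 1:
                masses = np.full(self.event_times.size, float(masses[0]))
            if masses.size != self.event_times.size:
                raise ValueError("event_mass must match event_times")
            if (masses < 0).any() or not np.isfinite(masses).all():
                raise ValueError("event masses must be finite and nonnegative")
            if not np.isfinite(self.event_times).all():
                raise ValueError("event times must be finite")
        else:
            if not math.isfinite(self.total_rate) or self.total_rate < 0:
                raise ValueError("total_rate must be finite and nonnegative")
        object.__setattr__(self, "event_mass", masses)

    @classmethod
    def continuous(cls, rate: float) -> "SourceProfile":
        return cls(mode="continuous", total_rate=rate)

    @classmethod
    def puffs(cls, times, mass) -> "SourceProfile":
        return cls(mode="puff", event_times=np.asarray(times, float), event_mass=mass)

    def total_mass(self, duration: float) -> float:
        """Mass emitted (µg) over [0, duration]."""
        if self.mode == "continuous":
            return self.total_rate * duration
        in_window = (self.event_times >= 0) & (self.event_times <= duration)
        return float(self.event_mass[in_window].sum())


@dataclass
class AirState:
    """Trajectory of one constituent in the box.

    ``time`` may contain duplicated instants at puff events (left and right
    limits), which keeps trapezoidal time-averaging exact across the jumps.
    """

    time: np.ndarray  # h
    total: np.ndarray  # µg/m³
    vapor: np.ndarray  # µg/m³
    particle: np.ndarray  # µg/m³
    volume: float  # m³
    ach: float  # 1/h
    vented_mass: float  # µg removed by ventilation over the run (exact)

    @property
    def vapor_fraction(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(self.total > 0, self.vapor / self.total, 1.0)
        return f


def partition_equilibrium(total_concentration, saturation_mass_concentration=None):
    """Split a total concentration into vapor and particle phases.

    Single-component equilibrium: vapor = min(total, C*); the excess over
    the saturation mass concentration C* condenses to particles.  With C*
    absent the constituent is fully volatile and stays in the vapor phase.
    Accepts scalars or arrays; returns ``(vapor, particle)``.
    """
    total = np.asarray(total_concentration, float)
    if (total < 0).any():
        raise ValueError("total concentration must be nonnegative")
    if saturation_mass_concentration is None:
        vapor = total.copy()
    else:
        cstar = float(saturation_mass_concentration)
        if cstar < 0:
            raise ValueError("saturation mass concentration must be nonnegative")
        vapor = np.minimum(total, cstar)
    particle = total - vapor
    if total.ndim == 0:
        return float(vapor), float(particle)
    return vapor, particle


def _step_exact(c0: float, s_rate: float, lam: float, volume: float, dt: float):
    """Advance the linear box ODE one step with constant source.

    Returns (c1, vented) where ``vented`` is λV∫C dt over the step, from the
    exact per-step mass balance S·dt = V(c1-c0) + vented.
    """
    if lam > 0:
        decay = math.exp(-lam * dt)
        c_inf = s_rate / (lam * volume)
        c1 = c_inf + (c0 - c_inf) * decay
        vented = s_rate * dt - volume * (c1 - c0)
    else:
        c1 = c0 + s_rate * dt / volume
        vented = 0.0
    return c1, vented


def simulate_box(
    volume: float,
    ach: float,
    source: SourceProfile,
    duration: float,
    initial_concentration: float = 0.0,
    timestep: float | None = None,
    saturation_mass_concentration: float | None = None,
) -> AirState:
    """Integrate the well-mixed box model over [0, duration].

    ``timestep`` sets the output grid spacing (default duration/2000, and it
    must be at most duration/100).  In puff mode it must also resolve the
    inter-puff spacing, and event times are inserted into the grid as
    duplicated points carrying the pre- and post-injection concentrations.
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    if ach < 0:
        raise ValueError("air-change rate must be nonnegative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if initial_concentration < 0:
        raise ValueError("initial concentration must be nonnegative")
    if timestep is None:
        timestep = duration / 2000.0
    if timestep <= 0 or timestep > duration / 100.0:
        raise ValueError("timestep must be positive and at most duration/100")

    events = np.empty(0)
    masses = np.empty(0)
    if source.mode == "puff":
        order = np.argsort(source.event_times, kind="stable")
        t_ev, m_ev = source.event_times[order], source.event_mass[order]
        keep = (t_ev >= 0) & (t_ev <= duration)
        events, masses = t_ev[keep], m_ev[keep]
        if events.size >= 2:
            min_gap = float(np.diff(events).min())
            if min_gap > 0 and timestep > min_gap:
                raise ValueError(
                    "timestep too coarse to resolve puff events; "
                    f"need <= {min_gap:g} h"
                )

    n_steps = max(int(math.ceil(duration / timestep)), 100)
    base = np.linspace(0.0, duration, n_steps + 1)
    # duplicated event instants: index of the pair start in the final grid
    grid = np.unique(np.concatenate([base, events]))
    times: list[float] = []
    concs: list[float] = []
    rate = source.total_rate if source.mode == "continuous" else 0.0

    c = float(initial_concentration)
    vented = 0.0
    ev_i = 0
    t_prev = 0.0
    times.append(0.0)
    concs.append(c)
    # puff exactly at t=0 fires before anything decays; record the jump as a
    # duplicated instant so C(0) stays the pre-injection initial condition
    while ev_i < events.size and events[ev_i] == 0.0:
        c += masses[ev_i] / volume
        ev_i += 1
        times.append(0.0)
        concs.append(c)
    for t in grid[1:]:
        dt = t - t_prev
        c, dv = _step_exact(c, rate, ach, volume, dt)
        vented += dv
        times.append(t)
        concs.append(c)
        while ev_i < events.size and events[ev_i] == t:
            c += masses[ev_i] / volume
            ev_i += 1
            times.append(t)  # duplicated point: right limit after injection
            concs.append(c)
        t_prev = t

    time = np.asarray(times)
    total = np.asarray(concs)
    vapor, particle = partition_equilibrium(total, saturation_mass_concentration)
    return AirState(
        time=time,
        total=total,
        vapor=np.asarray(vapor),
        particle=np.asarray(particle),
        volume=volume,
        ach=ach,
        vented_mass=vented,
    )


def average_concentration(state: AirState, window: tuple[float, float] | None = None) -> float:
    """Time-weighted mean total concentration over a window (trapezoidal).

    The default window is the full simulated range.  Window endpoints not on
    the output grid are filled by interpolation.
    """
    t0 = float(state.time[0])
    t1 = float(state.time[-1])
    if window is None:
        lo, hi = t0, t1
    else:
        lo, hi = float(window[0]), float(window[1])
    if not (t0 <= lo < hi <= t1):
        raise ValueError("window must be non-empty and within the simulated range")
    inside = (state.time > lo) & (state.time < hi)
    t = np.concatenate([[lo], state.time[inside], [hi]])
    c = np.concatenate(
        [
            [np.interp(lo, state.time, state.total)],
            state.total[inside],
            [np.interp(hi, state.time, state.total)],
        ]
    )
    return float(np.trapezoid(c, t) / (hi - lo))


def mass_balance_error(state: AirState, source: SourceProfile) -> float:
    """Relative closure error of the conservation audit.

    Emitted mass must equal the stored mass change plus the ventilated mass:
    ``S_total = V·(C(T) − C(0)) + λV∫C dt``.  Returns |imbalance| relative
    to the larger of emitted mass and stored+vented mass (0 when both are 0).
    """
    duration = float(state.time[-1] - state.time[0])
    emitted = source.total_mass(duration)
    stored = state.volume * (float(state.total[-1]) - float(state.total[0]))
    accounted = stored + state.vented_mass
    scale = max(abs(emitted), abs(accounted))
    if scale == 0:
        return 0.0
    return abs(emitted - accounted) / scale
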