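"""The transport term F(c): advection, meals, and the upper-GIT black box.

Lumen material moves proximally-to-distally at a constant velocity set by the
colon length and the mean transit time (MTT); mucus material is stationary.
Dietary fiber enters at the proximal boundary as short meal pulses.  The
upper GIT (mouth to ileum) is treated as a black box of dilution units that,
by default, passes the ingested fiber mass through unchanged; optional
first-order dilution tanks smooth the meal square pulse into an Erlang-shaped
signal without changing its mass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc

from .errors import ConfigurationError, ValidationError

__all__ = [
    "DietSchedule",
    "FlowSpec",
    "parse_pattern",
    "velocity_from_transit",
    "inflow_concentration",
    "advective_flux",
    "forcing_breakpoints",
]


def parse_pattern(text: str) -> list[bool]:
    """Parse a run-length day pattern like ``"14on,7off,14on"`` to booleans."""
    out: list[bool] = []
    for token in text.split(","):
        m = re.fullmatch(r"\s*(\d+)\s*(on|off)\s*", token, re.IGNORECASE)
        if not m:
            raise ConfigurationError(f"bad pattern token {token!r}; expected e.g. '14on'")
        out.extend([m.group(2).lower() == "on"] * int(m.group(1)))
    if not out:
        raise ConfigurationError("empty diet pattern")
    return out


@dataclass
class DietSchedule:
    """Pulsed-meal fiber intake.

    ``on_off_pattern`` is a per-day sequence (day 0 first) that cycles for
    simulations longer than the pattern; ``True`` days deliver the meals,
    ``False`` days deliver no fiber.
    """

    fiber_per_day: float = 30.0          # g/day
    meal_times: tuple[float, ...] = (0.0, 4.0, 10.0)  # clock hours of a day
    meal_duration: float = 0.25          # h
    on_off_pattern: list[bool] = field(default_factory=lambda: [True])

    def __post_init__(self) -> None:
        if self.fiber_per_day < 0:
            raise ValidationError(f"fiber_per_day must be >= 0, got {self.fiber_per_day}")
        if self.meal_duration <= 0:
            raise ValidationError(f"meal_duration must be > 0, got {self.meal_duration}")
        if any(not 0 <= m < 24 for m in self.meal_times):
            raise ValidationError(f"meal_times must lie in [0, 24), got {self.meal_times}")
        if isinstance(self.on_off_pattern, str):
            self.on_off_pattern = parse_pattern(self.on_off_pattern)

    def day_is_on(self, day: int) -> bool:
        return bool(self.on_off_pattern[int(day) % len(self.on_off_pattern)])

    def meal_mass(self) -> float:
        """Fiber mass per meal, g."""
        return self.fiber_per_day / len(self.meal_times)

    def meal_windows(self, t0: float, t1: float) -> list[tuple[float, float]]:
        """(start, end) of every meal on an on-day intersecting [t0, t1]."""
        out = []
        for day in range(max(0, int(np.floor(t0 / 24.0)) - 1), int(np.floor(t1 / 24.0)) + 1):
            if not self.day_is_on(day):
                continue
            for m in self.meal_times:
                a = 24.0 * day + m
                if a + self.meal_duration >= t0 and a <= t1:
                    out.append((a, a + self.meal_duration))
        return out


def velocity_from_transit(length: float, mtt: float) -> float:
    """Advection velocity (m/h) = colon length / mean transit time."""
    if length <= 0 or mtt <= 0:
        raise ValidationError(f"length and mean transit time must be > 0, got {length}, {mtt}")
    return length / mtt


@dataclass
class FlowSpec:
    """Constant-velocity flow derived from the mean transit time."""

    mean_transit_time: float = 24.0   # h
    colon_length: float = 1.5         # m
    lumen_volume: float = 1.503       # L
    dilution: float = 1.0             # upper-GIT concentration multiplier
    dilution_stages: int = 0          # k first-order tanks smoothing the pulse
    dilution_tau: float = 0.5         # h, tank time constant

    def __post_init__(self) -> None:
        if min(self.mean_transit_time, self.colon_length, self.lumen_volume) <= 0:
            raise ValidationError("FlowSpec values must be positive")
        if self.dilution_stages < 0 or self.dilution_tau <= 0:
            raise ValidationError("dilution_stages must be >= 0 and dilution_tau > 0")

    @property
    def velocity(self) -> float:
        """m/h; exactly colon_length / mean_transit_time."""
        return velocity_from_transit(self.colon_length, self.mean_transit_time)

    @property
    def volumetric_flow(self) -> float:
        """L/h through the lumen."""
        return self.lumen_volume / self.mean_transit_time


def _erlang_cdf(k: int, t, tau: float):
    x = np.maximum(np.asarray(t, dtype=float), 0.0) / tau
    return gammainc(k, x)


def inflow_fiber_concentration(t, diet: DietSchedule, flow: FlowSpec):
    """Fiber concentration (g/L) of the boundary inflow at time(s) ``t``.

    During a meal on an on-day the square-pulse concentration is
    ``meal_mass / (volumetric_flow * meal_duration) * dilution``; with
    ``dilution_stages`` k >= 1 the pulse is smoothed through k first-order
    tanks (mass-preserving Erlang response).
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    tt = np.atleast_1d(t)
    amp = diet.meal_mass() / (flow.volumetric_flow * diet.meal_duration) * flow.dilution
    out = np.zeros_like(tt)
    # Meals older than the lookback contribute negligibly to a smoothed tail.
    lookback = 48.0 + 10.0 * flow.dilution_stages * flow.dilution_tau
    windows = diet.meal_windows(float(tt.min()) - lookback, float(tt.max()))
    k = flow.dilution_stages
    for a, b in windows:
        if k == 0:
            out += amp * ((tt >= a) & (tt < b))
        else:
            out += amp * (
                _erlang_cdf(k, tt - a, flow.dilution_tau)
                - _erlang_cdf(k, tt - b, flow.dilution_tau)
            )
    return float(out[0]) if scalar else out


def inflow_concentration(t, diet: DietSchedule, flow: FlowSpec, layout=None):
    """Boundary state vector (g/L) at time ``t``.

    With a layout, returns the full environment-local vector (fiber slot set,
    all other components at the zero background: only fermentation-generated
    water is tracked, so inflow water is not counted).  Without a layout,
    returns the fiber concentration alone.
    """
    fiber = inflow_fiber_concentration(t, diet, flow)
    if layout is None:
        return fiber
    c = np.zeros(layout.n_local)
    c[layout.local_index("fiber")] = fiber
    return c


def advective_flux(c_lumen_field: np.ndarray, velocity: float, inflow=None) -> np.ndarray:
    """First-order upwind interface fluxes for the lumen field.

    ``c_lumen_field`` has shape (n_cells, ...); the result has shape
    (n_cells + 1, ...): ``flux[0] = v * c_inflow`` (zero if no inflow is
    given) and ``flux[i] = v * c[i-1]`` — the outflow boundary is free.
    Mucus states are stationary and have no flux by construction.
    """
    if velocity < 0:
        raise ConfigurationError("negative velocity is unsupported (flow is proximal to distal)")
    c = np.asarray(c_lumen_field, dtype=float)
    flux = np.empty((c.shape[0] + 1,) + c.shape[1:])
    flux[0] = 0.0 if inflow is None else velocity * np.asarray(inflow, dtype=float)
    flux[1:] = velocity * c
    return flux


def forcing_breakpoints(diet: DietSchedule, t0: float, t1: float, extra=()) -> np.ndarray:
    """Times in [t0, t1] where the boundary forcing is discontinuous.

    Meal on/off edges (square pulses only) plus any caller-supplied times
    (perturbation windows); used to split stiff integration into segments.
    """
    pts = {float(t0), float(t1)}
    for a, b in diet.meal_windows(t0, t1):
        for p in (a, b):
            if t0 < p < t1:
                pts.add(p)
    for p in extra:
        if t0 < p < t1:
            pts.add(float(p))
    return np.array(sorted(pts))
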