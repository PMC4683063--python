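"""Comparison statistics and time-series diagnostics.

Coarse composition classifies material at a location as fiber, biomass,
sugar, SCFA or others.  The central statistic is the biomass share of total
material,

    %Biomass = Biomass / TotalMass,

with biomass summed over all strains of all four functional groups in both
the lumen and mucus environments, weighted by the lumen:mucus volume ratio.
Representations are compared through the pointwise percent deviation

    %Deviation = (%Biomass_D - %Biomass_C) / %Biomass_D,

where D is the discrete (stage) and C the continuous (grid) solution, the
stage solution extrapolated piecewise-constant over the colon length.
Positive values mean the discrete representation over-predicts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "COARSE_CATEGORIES",
    "CompositionSummary",
    "coarse_composition",
    "outflow_composition_series",
    "percent_biomass",
    "DeviationField",
    "percent_deviation",
    "detect_periodic_onset",
    "recovery_time",
    "community_composition",
]

COARSE_CATEGORIES = ("fiber", "biomass", "sugar", "scfa", "others")


def _coarse_masks(layout, lactate_as_scfa: bool = True):
    """Local-state boolean masks per coarse category."""
    masks = {
        "fiber": layout.local_category_mask("fiber"),
        "biomass": layout.local_category_mask("biomass"),
        "sugar": layout.local_category_mask("sugar"),
        "scfa": layout.local_category_mask("scfa"),
        "others": layout.local_category_mask("solute_gas", "water", "gas_phase"),
    }
    if not lactate_as_scfa:
        lac = np.array([comp.name == "lactate" for comp, _ in layout.local_states])
        masks["scfa"] = masks["scfa"] & ~lac
        masks["others"] = masks["others"] | lac
    return masks


def _env_weights(result, environment: str) -> np.ndarray:
    frac = result.scenario.params.physical.mucus_volume_fraction
    if environment == "weighted":
        return np.array([1.0 - frac, frac])
    if environment == "lumen":
        return np.array([1.0, 0.0])
    if environment == "mucus":
        return np.array([0.0, 1.0])
    raise ValidationError(f"environment must be weighted/lumen/mucus, got {environment!r}")


def _frames(result) -> np.ndarray:
    nt, n_loc = result.states.shape[:2]
    return result.states.reshape(nt, n_loc, 2, result.layout.n_local)


@dataclass
class CompositionSummary:
    """Coarse mass fractions over (time x location); nan where mass is zero."""

    times: np.ndarray
    x: np.ndarray
    fractions: dict[str, np.ndarray]   # category -> (nt, n_loc)
    environment: str

    def stack(self) -> np.ndarray:
        """(nt, n_loc, 5) array in COARSE_CATEGORIES order."""
        return np.stack([self.fractions[c] for c in COARSE_CATEGORIES], axis=-1)


def coarse_composition(result, environment: str = "weighted",
                       lactate_as_scfa: bool = True) -> CompositionSummary:
    """Coarse composition of material at every stored (time, location)."""
    w = _env_weights(result, environment)
    masks = _coarse_masks(result.layout, lactate_as_scfa)
    mass = (_frames(result) * w[None, None, :, None]).sum(axis=2)  # (nt, n_loc, n_local)
    total = mass.sum(axis=-1)
    fractions = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for cat, m in masks.items():
            fractions[cat] = np.where(total > 0, mass[:, :, m].sum(axis=-1) / total, np.nan)
    return CompositionSummary(
        times=result.times, x=result.x_centers, fractions=fractions, environment=environment
    )


def outflow_composition_series(result, environment: str = "weighted") -> tuple[np.ndarray, np.ndarray]:
    """(times, (nt, 5)) coarse composition at the distal outlet."""
    comp = coarse_composition(result, environment)
    return result.times, comp.stack()[:, -1, :]


def percent_biomass(result, x="outflow", t=None, environment: str = "weighted"):
    """Biomass share of total material at a location.

    ``x`` is ``"outflow"``, a location index, or a position in metres;
    ``t`` a time in hours (nearest stored frame) or ``None`` for the whole
    series.  Volume-weighted over both environments by default.  Returns
    nan where total mass vanishes (a sterile, empty state), never raises.
    """
    w = _env_weights(result, environment)
    masks = _coarse_masks(result.layout)
    if x == "outflow":
        xi = result.n_locations - 1
    elif isinstance(x, (int, np.integer)):
        xi = int(x)
    else:
        xi = int(np.argmin(np.abs(result.x_centers - float(x))))
    mass = (_frames(result)[:, xi] * w[None, :, None]).sum(axis=1)  # (nt, n_local)
    total = mass.sum(axis=-1)
    bio = mass[:, masks["biomass"]].sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        series = np.where(total > 0, bio / total, np.nan)
    if t is None:
        return series
    ti = int(np.argmin(np.abs(result.times - float(t))))
    return float(series[ti])


def _percent_biomass_field(result, environment: str = "weighted") -> np.ndarray:
    w = _env_weights(result, environment)
    masks = _coarse_masks(result.layout)
    mass = (_frames(result) * w[None, None, :, None]).sum(axis=2)
    total = mass.sum(axis=-1)
    bio = mass[:, :, masks["biomass"]].sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, bio / total, np.nan)


@dataclass
class DeviationField:
    """Percent deviation between representations over (time x position)."""

    times: np.ndarray
    x: np.ndarray
    values: np.ndarray  # (nt, n_x); nan where the discrete prediction is zero


def percent_deviation(discrete, continuous, environment: str = "weighted") -> DeviationField:
    """(%B_D - %B_C) / %B_D on the continuous grid.

    The stage solution is extrapolated over the colon length as
    piecewise-constant blocks of equal extent (thirds for the classical
    3-stage chain).  Positive values: the discrete representation
    over-predicts; nan flags points where %B_D is zero.
    """
    if len(discrete.times) != len(continuous.times) or not np.allclose(
        discrete.times, continuous.times, atol=1e-6
    ):
        raise ValidationError("representations must share the same output times")
    pb_d = _percent_biomass_field(discrete, environment)    # (nt, n_stages)
    pb_c = _percent_biomass_field(continuous, environment)  # (nt, n_grid)
    n_stages = pb_d.shape[1]
    n_grid = pb_c.shape[1]
    # map each grid cell to its covering stage block
    stage_of = np.minimum((np.arange(n_grid) * n_stages) // n_grid, n_stages - 1)
    pb_d_on_grid = pb_d[:, stage_of]
    with np.errstate(invalid="ignore", divide="ignore"):
        dev = np.where(pb_d_on_grid != 0, (pb_d_on_grid - pb_c) / pb_d_on_grid, np.nan)
    return DeviationField(times=continuous.times, x=continuous.x_centers, values=dev)


# ---------------------------------------------------------------------------
# Time-series diagnostics
# ---------------------------------------------------------------------------


def _window_view(times: np.ndarray, values: np.ndarray, period: float):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    dt = np.diff(times)
    if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValidationError("series must be uniformly sampled")
    n_per = period / dt[0]
    n = int(round(n_per))
    if abs(n_per - n) > 1e-6 or n < 2:
        raise ValidationError(
            f"period {period} h is not a multiple of the sampling step {dt[0]} h"
        )
    n_windows = len(times) // n
    return values, n, n_windows


def detect_periodic_onset(times, values, period: float = 24.0, tol: float = 0.01) -> float:
    """Earliest time from which the series repeats with the given period.

    Successive whole-period windows (anchored at the series start) are
    compared in the sup norm, relative to the earlier window's sup norm,
    component-wise; the onset is the start of the first window after which
    every consecutive-window discrepancy stays below ``tol``.  Returns nan
    if periodicity is never reached.  Requires at least three whole periods.
    """
    times = np.asarray(times, dtype=float)
    values, n, n_windows = _window_view(times, values, period)
    if n_windows < 3:
        raise ValidationError("series must span at least three whole periods")
    wins = values[: n_windows * n].reshape(n_windows, n, -1)
    diff = np.abs(np.diff(wins, axis=0)).max(axis=1)            # (n_windows-1, k)
    scale = np.maximum(np.abs(wins[:-1]).max(axis=1), 1e-12)
    rel = (diff / scale).max(axis=1)                            # (n_windows-1,)
    bad = np.flatnonzero(rel >= tol)
    j0 = 0 if bad.size == 0 else int(bad[-1]) + 1
    if j0 > n_windows - 2:
        return float("nan")
    return float(times[0] + j0 * period)


def _baseline_orbit(times, values, t_start, period, n_per):
    """Two-period average before t_start, returned phase-aligned so that
    entry j holds the orbit value at sample phase j (relative to times[0])."""
    pre = np.flatnonzero((times >= t_start - 2 * period - 1e-9) & (times < t_start - 1e-9))
    if pre.size < 2 * n_per:
        raise ValidationError(
            "baseline requires at least two whole periods before the perturbation"
        )
    idx = pre[-2 * n_per :]
    vals = values[idx]
    orbit = 0.5 * (vals[:n_per] + vals[n_per:])
    return np.roll(orbit, idx[0] % n_per)


def recovery_time(
    times,
    values,
    t_pert_end: float,
    t_pert_start: float | None = None,
    baseline: np.ndarray | None = None,
    period: float = 24.0,
    tol: float = 0.05,
) -> float:
    """Duration after the perturbation window until the series re-joins its
    pre-perturbation periodic orbit.

    The baseline orbit is the two-period average immediately before
    ``t_pert_start`` (or passed explicitly as one period of samples).  The
    recovery time is the first lag ``d`` such that the series stays within
    ``tol`` (relative) of the baseline orbit for one full period starting at
    ``t_pert_end + d``.  Returns nan when the horizon ends first; an
    unperturbed series recovers at d = 0.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValidationError("recovery_time expects a single scalar series")
    v2, n, _ = _window_view(times, values, period)
    if baseline is None:
        if t_pert_start is None:
            raise ValidationError("either a baseline orbit or t_pert_start is required")
        base = _baseline_orbit(times, values, t_pert_start, period, n)
    else:
        base = np.asarray(baseline, dtype=float)
        if len(base) != n:
            raise ValidationError(f"baseline must hold one period ({n} samples)")
    dt = times[1] - times[0]
    i_end = int(np.searchsorted(times, t_pert_end - 1e-9))
    # phase of each sample relative to the baseline window
    scale = np.maximum(np.abs(base), 1e-12)
    for i0 in range(i_end, len(times) - n + 1):
        phase = np.arange(i0, i0 + n) % n
        if np.all(np.abs(values[i0 : i0 + n] - base[phase]) / scale[phase] <= tol):
            return float(times[i0] - t_pert_end)
    return float("nan")


def community_composition(result, group: str, t: float) -> np.ndarray:
    """Per-strain biomass fractions of a functional group at time ``t``.

    Volume-weighted colon totals, normalized within the group; nan for all
    strains if the group is extinct at ``t``.
    """
    layout = result.layout
    times = result.times
    ti = int(np.argmin(np.abs(times - float(t))))
    frac = result.scenario.params.physical.mucus_volume_fraction
    w = np.array([1.0 - frac, frac])
    frame = _frames(result)[ti]  # (n_loc, 2, n_local)
    totals = np.array(
        [
            float((frame[:, :, layout.local_index(f"X_{group}", s)] * w).sum())
            for s in layout.strains_of(group)
        ]
    )
    total = totals.sum()
    if total <= 0:
        return np.full(len(totals), np.nan)
    return totals / total
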