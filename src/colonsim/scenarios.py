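"""Simulation scenarios: experiment designs and time-windowed perturbations.

A :class:`Scenario` is a complete, serializable specification of one run:
physical/kinetic parameters, diet schedule, community structure (strains per
functional group and their biochemical deviation), perturbation windows,
seed, horizon and solver settings.  Preset builders reproduce the standard
experiment designs: the 5 x 3 flow/fiber grid, the diet-dropout experiment,
and the community (decay-boost) perturbation experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigurationError, ValidationError
from .exchange import ExchangeSpec  # noqa: F401  (re-exported for config users)
from .state import (
    BFGS,
    ParameterSet,
    StrainParameters,
    default_parameters,
    load_parameters,
    sample_strain_parameters,
    single_strain_parameters,
)
from .transport import DietSchedule, FlowSpec

__all__ = [
    "Perturbation",
    "Scenario",
    "standard_scenario",
    "make_flow_fiber_grid",
    "diet_perturbation_scenario",
    "community_perturbation_scenario",
    "apply_perturbations",
    "resolve_dominant_strain",
]

#: Default decay-rate multiplier of the community perturbation (the boosted
#: cell-lysis rate of the targeted strain).
DEFAULT_DECAY_BOOST = 10.0


@dataclass
class Perturbation:
    """A time-windowed disturbance.

    ``decay_boost`` multiplies the decay (cell lysis) rate of one strain —
    the target may be an explicit strain id or ``"dominant"``, resolved at
    window start from the simulated community.  ``diet_off`` zeroes the fiber
    inflow inside the window.
    """

    kind: str                       # decay_boost | diet_off
    start_day: float
    length_days: float
    group: str = "SD"
    strain: int | str = "dominant"
    factor: float = DEFAULT_DECAY_BOOST

    def __post_init__(self) -> None:
        if self.kind not in ("decay_boost", "diet_off"):
            raise ConfigurationError(f"unknown perturbation kind {self.kind!r}")
        if self.length_days < 0:
            raise ValidationError("perturbation length must be >= 0 days")
        if self.factor < 1:
            raise ValidationError("decay boost factor must be >= 1")
        if self.group not in BFGS:
            raise ConfigurationError(f"unknown group {self.group!r}")

    @property
    def start(self) -> float:
        return 24.0 * self.start_day

    @property
    def end(self) -> float:
        return 24.0 * (self.start_day + self.length_days)

    def active(self, t: float) -> bool:
        return self.length_days > 0 and self.start <= t < self.end


@dataclass
class Scenario:
    """A complete simulation specification."""

    name: str = "custom"
    params: ParameterSet = field(default_factory=default_parameters)
    diet: DietSchedule = field(default_factory=DietSchedule)
    strain_counts: dict[str, int] = field(default_factory=lambda: {g: 1 for g in BFGS})
    deviation: float = 0.0
    seed: int = 0
    perturbations: list[Perturbation] = field(default_factory=list)
    t_end: float = 56 * 24.0            # h
    gas_mode: str = "dissolved_only"
    mode: str = "pfr"                   # preferred representation: pfr | cstr
    grid_n: int | None = None           # None -> params.numerics.grid_n
    n_stages: int = 3
    output_every: float | None = None   # None -> params.numerics.output_every
    dilution_stages: int = 0
    dilution_tau: float = 0.5

    def __post_init__(self) -> None:
        for p in self.perturbations:
            if p.end > self.t_end + 1e-9:
                raise ValidationError(
                    f"perturbation window [{p.start}, {p.end}] h exceeds t_end={self.t_end} h"
                )
            if (
                p.kind == "decay_boost"
                and isinstance(p.strain, int)
                and not 1 <= p.strain <= self.strain_counts.get(p.group, 1)
            ):
                raise ConfigurationError(
                    f"perturbation targets strain {p.strain} of {p.group}, but the "
                    f"scenario has {self.strain_counts.get(p.group, 1)} strain(s)"
                )

    # ------------------------------------------------------------------ build
    @property
    def flow(self) -> FlowSpec:
        ph = self.params.physical
        return FlowSpec(
            mean_transit_time=ph.mean_transit_time,
            colon_length=ph.colon_length,
            lumen_volume=ph.lumen_volume,
            dilution=1.0,
            dilution_stages=self.dilution_stages,
            dilution_tau=self.dilution_tau,
        )

    def build_strains(self) -> dict[str, list[StrainParameters]]:
        """Sample per-strain kinetic multipliers, reproducibly from the seed."""
        if self.deviation == 0 and all(self.strain_counts[g] == 1 for g in BFGS):
            return single_strain_parameters()
        rng = np.random.default_rng(self.seed)
        subseeds = {g: int(rng.integers(2**31)) for g in BFGS}
        return {
            g: sample_strain_parameters(
                self.params, g, self.strain_counts[g], self.deviation, subseeds[g]
            )
            for g in BFGS
        }

    def fiber_inflow_scale(self, t: float) -> float:
        """0 inside any diet_off window, else 1."""
        for p in self.perturbations:
            if p.kind == "diet_off" and p.active(t):
                return 0.0
        return 1.0

    # -------------------------------------------------------------- serialize
    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = self.params.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        d["params"] = load_parameters(d["params"])
        d["diet"] = DietSchedule(**d["diet"])
        d["perturbations"] = [Perturbation(**p) for p in d["perturbations"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def standard_scenario(
    fiber_per_day: float = 30.0,
    mean_transit_time: float = 24.0,
    t_end_days: float = 56.0,
    **kwargs,
) -> Scenario:
    """The reference run: 30 g fiber/day over 3 meals, MTT 24 h, single strains."""
    params = kwargs.pop("params", None) or default_parameters()
    params.physical.mean_transit_time = float(mean_transit_time)
    return Scenario(
        name=f"standard_mtt{mean_transit_time:g}_fpd{fiber_per_day:g}",
        params=params,
        diet=DietSchedule(fiber_per_day=fiber_per_day),
        t_end=t_end_days * 24.0,
        **kwargs,
    )


def make_flow_fiber_grid(t_end_days: float = 56.0) -> list[Scenario]:
    """The 15-scenario design: MTT {6,12,24,48,96} h x fiber {15,30,45} g/day.

    Single-strain groups, 56 simulated days each.
    """
    return [
        standard_scenario(fiber_per_day=f, mean_transit_time=m, t_end_days=t_end_days)
        for m in (6.0, 12.0, 24.0, 48.0, 96.0)
        for f in (15.0, 30.0, 45.0)
    ]


#: Approximation of the diet-dropout day pattern (exact published pattern is
#: figure-only): three 14-day regular-diet blocks separated by 7-day
#: zero-fiber blocks over a 10-week horizon.
DIET_DROPOUT_PATTERN = "14on,7off,14on,7off,14on,7off,7on"


def diet_perturbation_scenario(
    n_sd_strains: int = 5,
    seed: int = 0,
    deviation: float = 0.10,
    mode: str = "cstr",
    t_end_days: float = 70.0,
) -> Scenario:
    """Diet-dropout experiment: regular 30 g/day diet with zero-fiber periods.

    Community refinement applies to the sugar-degrading group (1, 2, 5 or 10
    strains at 10% biochemical deviation in the published design).
    """
    counts = {g: 1 for g in BFGS}
    counts["SD"] = int(n_sd_strains)
    return Scenario(
        name=f"diet_dropout_sd{n_sd_strains}",
        diet=DietSchedule(fiber_per_day=30.0, on_off_pattern=DIET_DROPOUT_PATTERN),
        strain_counts=counts,
        deviation=deviation,
        seed=seed,
        t_end=t_end_days * 24.0,
        mode=mode,
    )


def community_perturbation_scenario(
    window_days: float,
    seed: int = 0,
    deviation: float = 0.01,
    factor: float = DEFAULT_DECAY_BOOST,
    n_sd_strains: int = 5,
    start_day: float = 56.0,
    observe_days: float = 56.0,
    mode: str = "cstr",
) -> Scenario:
    """Community perturbation: boosted lysis of the dominant SD strain.

    After a 56-day burn-in on the regular diet, the decay rate of the
    dominant sugar-degrading strain is multiplied by ``factor`` for
    ``window_days`` days; the run continues ``observe_days`` beyond the
    window end so that recovery and community structure can be assessed.
    """
    counts = {g: 1 for g in BFGS}
    counts["SD"] = int(n_sd_strains)
    perturbations = []
    if window_days > 0:
        perturbations.append(
            Perturbation(
                kind="decay_boost",
                start_day=start_day,
                length_days=window_days,
                group="SD",
                strain="dominant",
                factor=factor,
            )
        )
    return Scenario(
        name=f"community_perturb_w{window_days:g}",
        diet=DietSchedule(fiber_per_day=30.0),
        strain_counts=counts,
        deviation=deviation,
        seed=seed,
        perturbations=perturbations,
        t_end=(start_day + window_days + observe_days) * 24.0,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Perturbation application and dominance
# ---------------------------------------------------------------------------


def apply_perturbations(
    strains: dict[str, list[StrainParameters]],
    scenario: Scenario,
    t: float,
    resolved: dict[int, int] | None = None,
):
    """Effective per-strain parameters at time ``t``.

    Inside a ``decay_boost`` window the target strain's decay multiplier is
    scaled by the window's factor; outside every window the originals are
    returned unchanged.  ``resolved`` maps perturbation index -> strain id
    for ``"dominant"`` targets (filled in by the solver at window start).
    Diet windows do not touch kinetic parameters (they act on the inflow).
    """
    boosts: dict[tuple[str, int], float] = {}
    for i, p in enumerate(scenario.perturbations):
        if p.kind != "decay_boost" or not p.active(t):
            continue
        strain = p.strain
        if strain == "dominant":
            if resolved is None or i not in resolved:
                raise ConfigurationError(
                    "dominant-strain perturbation not resolved; run through the solver "
                    "or pass an explicit strain id"
                )
            strain = resolved[i]
        key = (p.group, int(strain))
        boosts[key] = boosts.get(key, 1.0) * p.factor
    if not boosts:
        return strains
    out = {}
    for g, lst in strains.items():
        new = []
        for sp in lst:
            f = boosts.get((g, sp.strain_id))
            if f:
                mult = dict(sp.multipliers)
                mult["k_dec"] = mult.get("k_dec", 1.0) * f
                sp = StrainParameters(sp.group, sp.strain_id, mult, sp.initial_fraction)
            new.append(sp)
        out[g] = new
    return out


def _group_strain_totals(result, group: str, ti: int) -> np.ndarray:
    """Colon-total, volume-weighted biomass per strain of ``group`` at frame ti."""
    layout = result.layout
    ph = result.scenario.params.physical
    w = np.array([1.0 - ph.mucus_volume_fraction, ph.mucus_volume_fraction])
    frame = result.states[ti].reshape(result.n_locations, len(layout.environments), layout.n_local)
    totals = []
    for s in layout.strains_of(group):
        li = layout.local_index(f"X_{group}", s)
        totals.append(float((frame[:, :, li] * w).sum()))
    return np.array(totals)


def resolve_dominant_strain(result, group: str, t: float, allow_singleton: bool = False) -> int:
    """The strain with the highest colon-total biomass at time ``t``.

    Volume-weighted over both environments and summed over all locations;
    ties break toward the lowest strain id.  Perturbing a singleton group is
    a whole-group knockdown, so it must be requested explicitly.
    """
    layout = result.layout
    if layout.strain_counts[group] < 2 and not allow_singleton:
        raise ConfigurationError(
            f"group {group} has a single strain; pass allow_singleton=True to "
            "target a whole-group knockdown"
        )
    times = result.times
    if not times[0] - 1e-9 <= t <= times[-1] + 1e-9:
        raise ValidationError(f"t={t} outside simulated range [{times[0]}, {times[-1]}]")
    ti = int(np.argmin(np.abs(times - t)))
    totals = _group_strain_totals(result, group, ti)
    return int(np.argmax(totals)) + 1  # argmax returns the first (lowest id) maximum
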