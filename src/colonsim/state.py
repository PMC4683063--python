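"""Components, state-vector layout, and model parameters.

The model tracks dissolved materials (fiber, sugar, fermentation acids,
dissolved gases, fermentation water) and the four biomass functional groups
(BFGs) -- sugar degraders (SD), lactate degraders (LD), hydrogen-oxidizing
acetogens (HDA) and hydrogen-oxidizing methanogens (HDM) -- in two
environments, the flowing lumen and the wall-bound mucus layer.  Each BFG may
be expanded into several kinetic variants ("strains") whose rate parameters
are drawn around the group base values.

All concentrations are g/L, times are hours, lengths are metres.
"""

from __future__ import annotations

import copy
import io
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError, ValidationError
from .exchange import ExchangeSpec

__all__ = [
    "BFGS",
    "Component",
    "dissolved_components",
    "gas_components",
    "component_catalog",
    "StateLayout",
    "build_state_layout",
    "StrainParameters",
    "sample_strain_parameters",
    "single_strain_parameters",
    "GroupKinetics",
    "PhysicalParams",
    "HydrolysisParams",
    "StoichiometryParams",
    "NumericsParams",
    "InitialState",
    "ParameterSet",
    "default_parameters",
    "load_parameters",
    "save_parameters",
]

#: Biomass functional groups, in catalog order.
BFGS = ("SD", "LD", "HDA", "HDM")

#: Kinetic parameters that receive stochastic per-strain multipliers.
#: Stoichiometric product fractions are never perturbed (mass balance).
PERTURBED_PARAMETERS = ("k_m", "K_S", "Y", "k_dec")

ENVIRONMENTS = ("lumen", "mucus")


@dataclass(frozen=True)
class Component:
    """A tracked material.

    ``category`` is one of ``fiber, sugar, scfa, solute_gas, gas_phase,
    water, biomass``; ``group`` names the BFG for biomass components.
    """

    name: str
    category: str
    group: str | None = None


def dissolved_components() -> list[Component]:
    """The 14-entry dissolved catalog (before strain expansion)."""
    return [
        Component("fiber", "fiber"),
        Component("sugar", "sugar"),
        Component("lactate", "scfa"),
        Component("acetate", "scfa"),
        Component("propionate", "scfa"),
        Component("butyrate", "scfa"),
        Component("h2_dissolved", "solute_gas"),
        Component("ch4_dissolved", "solute_gas"),
        Component("co2_dissolved", "solute_gas"),
        Component("water", "water"),
        Component("X_SD", "biomass", "SD"),
        Component("X_LD", "biomass", "LD"),
        Component("X_HDA", "biomass", "HDA"),
        Component("X_HDM", "biomass", "HDM"),
    ]


def gas_components() -> list[Component]:
    """The 3 additional gas-phase components of the gas-inclusive catalog."""
    return [
        Component("h2_gas", "gas_phase"),
        Component("ch4_gas", "gas_phase"),
        Component("co2_gas", "gas_phase"),
    ]


def component_catalog(gas_mode: str = "dissolved_only") -> list[Component]:
    if gas_mode == "dissolved_only":
        return dissolved_components()
    if gas_mode == "with_gas":
        return dissolved_components() + gas_components()
    raise ConfigurationError(f"unknown gas_mode {gas_mode!r}")


@dataclass(frozen=True)
class StateLayout:
    """Canonical index map from (environment, component, strain) to position.

    The layout is environment-major: all lumen states first, then all mucus
    states, each in catalog order with biomass components expanded into
    ascending strain slots.  ``n_states = n_env * (n_base - 4 + sum(strains))``.
    """

    environments: tuple[str, ...]
    strain_counts: Mapping[str, int]
    gas_mode: str
    local_states: tuple[tuple[Component, int | None], ...]

    # ------------------------------------------------------------------ sizes
    @property
    def n_local(self) -> int:
        return len(self.local_states)

    @property
    def n_states(self) -> int:
        return len(self.environments) * self.n_local

    # ---------------------------------------------------------------- indexing
    def local_index(self, name: str, strain: int | None = None) -> int:
        for i, (comp, s) in enumerate(self.local_states):
            if comp.name == name and (s == strain or (strain is None and s in (None, 1))):
                return i
        raise KeyError(f"no state ({name!r}, strain={strain})")

    def index(self, environment: str, name: str, strain: int | None = None) -> int:
        try:
            e = self.environments.index(environment)
        except ValueError:
            raise KeyError(f"unknown environment {environment!r}") from None
        return e * self.n_local + self.local_index(name, strain)

    def triple(self, i: int) -> tuple[str, str, int | None]:
        if not 0 <= i < self.n_states:
            raise IndexError(i)
        e, loc = divmod(i, self.n_local)
        comp, strain = self.local_states[loc]
        return self.environments[e], comp.name, strain

    # ---------------------------------------------------------- category masks
    def local_category_mask(self, *categories: str) -> np.ndarray:
        return np.array(
            [comp.category in categories for comp, _ in self.local_states]
        )

    def biomass_local_indices(self, group: str | None = None) -> np.ndarray:
        idx = [
            i
            for i, (comp, _) in enumerate(self.local_states)
            if comp.category == "biomass" and (group is None or comp.group == group)
        ]
        return np.array(idx, dtype=int)

    def strains_of(self, group: str) -> list[int]:
        return list(range(1, self.strain_counts[group] + 1))


def build_state_layout(
    strain_counts: Mapping[str, int] | None = None,
    gas_mode: str = "dissolved_only",
    environments: Sequence[str] = ENVIRONMENTS,
) -> StateLayout:
    """Construct the deterministic state layout.

    ``strain_counts`` must provide a positive count for each of the four
    BFGs; ``None`` means one strain per group.
    """
    if strain_counts is None:
        strain_counts = {g: 1 for g in BFGS}
    for g in BFGS:
        if g not in strain_counts:
            raise ConfigurationError(f"strain_counts missing group {g!r}")
        n = strain_counts[g]
        if not (isinstance(n, (int, np.integer)) and n >= 1):
            raise ConfigurationError(f"strain count for {g!r} must be >= 1, got {n!r}")
    extra = set(strain_counts) - set(BFGS)
    if extra:
        raise ConfigurationError(f"unknown groups in strain_counts: {sorted(extra)}")
    if not environments:
        raise ConfigurationError("environments must be non-empty")

    local: list[tuple[Component, int | None]] = []
    for comp in component_catalog(gas_mode):
        if comp.category == "biomass":
            for s in range(1, strain_counts[comp.group] + 1):
                local.append((comp, s))
        else:
            local.append((comp, None))
    return StateLayout(
        environments=tuple(environments),
        strain_counts=dict(strain_counts),
        gas_mode=gas_mode,
        local_states=tuple(local),
    )


# ---------------------------------------------------------------------------
# Strain parameter sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrainParameters:
    """Kinetic multipliers and initial biomass share for one strain."""

    group: str
    strain_id: int
    multipliers: Mapping[str, float]
    initial_fraction: float


def single_strain_parameters() -> dict[str, list[StrainParameters]]:
    """One unperturbed strain per group (the base, unexpanded model)."""
    return {
        g: [StrainParameters(g, 1, {p: 1.0 for p in PERTURBED_PARAMETERS}, 1.0)]
        for g in BFGS
    }


def sample_strain_parameters(
    base: "ParameterSet",
    group: str,
    n: int,
    deviation: float,
    seed: int,
) -> list[StrainParameters]:
    """Draw ``n`` kinetic variants of ``group``.

    Each perturbed parameter gets an independent multiplier from
    ``Uniform(1 - deviation, 1 + deviation)``; initial biomass is split
    equally among the strains.  Reproducible for a fixed seed.
    """
    if group not in BFGS:
        raise ConfigurationError(f"unknown group {group!r}")
    if not 0 <= deviation < 1:
        raise ValidationError(
            f"deviation must be in [0, 1), got {deviation} (>= 1 allows negative rates)"
        )
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.uniform(1 - deviation, 1 + deviation, size=(n, len(PERTURBED_PARAMETERS)))
    if deviation == 0:
        draws = np.ones_like(draws)
    return [
        StrainParameters(
            group=group,
            strain_id=j + 1,
            multipliers=dict(zip(PERTURBED_PARAMETERS, draws[j])),
            initial_fraction=1.0 / n,
        )
        for j in range(n)
    ]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class PhysicalParams:
    colon_length: float = 1.5           # m
    total_volume: float = 1.67          # L
    mucus_volume_fraction: float = 0.10
    mean_transit_time: float = 24.0     # h

    @property
    def lumen_volume(self) -> float:
        return self.total_volume * (1.0 - self.mucus_volume_fraction)

    @property
    def mucus_volume(self) -> float:
        return self.total_volume * self.mucus_volume_fraction


@dataclass
class GroupKinetics:
    k_m: float      # maximum uptake rate, g substrate / g biomass / h
    K_S: float      # half-saturation, g/L
    Y: float        # biomass yield, g biomass / g substrate
    k_dec: float    # first-order decay, 1/h


@dataclass
class HydrolysisParams:
    k_hyd: float = 0.25   # 1/h
    K_Z: float = 0.5      # g/L, fiber half-saturation
    eps_X: float = 0.5    # biomass crowding weight in the Contois-type law
    law: str = "contois"  # or "first_order"


@dataclass
class StoichiometryParams:
    """Mass-basis product splits of the fermentation processes.

    ``sd_products`` / ``ld_products``: fractions of the catabolized substrate
    mass (i.e. of ``1 - Y``) routed to each product; must sum to 1, water
    closing the elemental balance.  ``hda_coeffs`` / ``hdm_coeffs``: signed
    mass coefficients per g of dissolved H2 consumed in catabolism (negative
    CO2 = co-consumed); their net sum must equal 1 so each column of the
    stoichiometry matrix sums to zero.
    """

    sd_products: dict[str, float] = field(default_factory=dict)
    ld_products: dict[str, float] = field(default_factory=dict)
    hda_coeffs: dict[str, float] = field(default_factory=dict)
    hdm_coeffs: dict[str, float] = field(default_factory=dict)


@dataclass
class NumericsParams:
    grid_n: int = 51
    rtol: float = 1e-6
    atol: float = 1e-9
    output_every: float = 1.0   # h
    cfl: float = 0.9
    clip_threshold: float = 1e-12
    max_clipped_fraction: float = 1e-6


@dataclass
class InitialState:
    biomass_seed: float = 1e-3  # g/L per strain, both environments


@dataclass
class ParameterSet:
    """Physical, kinetic, stoichiometric, exchange and numerical parameters."""

    physical: PhysicalParams = field(default_factory=PhysicalParams)
    hydrolysis: HydrolysisParams = field(default_factory=HydrolysisParams)
    groups: dict[str, GroupKinetics] = field(default_factory=dict)
    stoichiometry: StoichiometryParams = field(default_factory=StoichiometryParams)
    exchange: ExchangeSpec = field(default_factory=ExchangeSpec)
    numerics: NumericsParams = field(default_factory=NumericsParams)
    initial: InitialState = field(default_factory=InitialState)
    co2_limit_K: float = 1e-4  # g/L, secondary CO2 saturation for HDA/HDM
    inhibition_profile: list[float] | None = None  # optional static I(x) in (0,1]

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _default_yaml_text() -> str:
    ref = resources.files("colonsim.data").joinpath("default_parameters.yaml")
    return ref.read_text()


def default_parameters() -> ParameterSet:
    """The documented default parameter set, read from the shipped data file."""
    return load_parameters(None)


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if k in out and isinstance(out[k], dict) and isinstance(v, Mapping):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def _require_nonneg(value: float, key: str) -> float:
    v = float(value)
    if not np.isfinite(v) or v < 0:
        raise ValidationError(f"{key} must be a finite non-negative number, got {value!r}")
    return v


def load_parameters(config=None) -> ParameterSet:
    """Build a validated :class:`ParameterSet`.

    ``config`` may be ``None`` (pure defaults), a mapping of overrides, a YAML
    string, or a path to a YAML file.  Unknown keys raise; defaults fill
    everything not given.
    """
    base = yaml.safe_load(_default_yaml_text())
    if config is None:
        merged = base
    else:
        if isinstance(config, (str, Path)) and not isinstance(config, Mapping):
            text = Path(config).read_text() if Path(str(config)).is_file() else str(config)
            override = yaml.safe_load(io.StringIO(text)) or {}
        else:
            override = config
        if not isinstance(override, Mapping):
            raise ConfigurationError("config must parse to a mapping")
        unknown = set(override) - set(base)
        if unknown:
            raise ConfigurationError(f"unknown top-level config keys: {sorted(unknown)}")
        merged = _deep_merge(base, override)
    return _params_from_dict(merged)


def _params_from_dict(d: Mapping) -> ParameterSet:
    phys = PhysicalParams(**d["physical"])
    _require_nonneg(phys.colon_length, "physical.colon_length")
    _require_nonneg(phys.total_volume, "physical.total_volume")
    _require_nonneg(phys.mean_transit_time, "physical.mean_transit_time")
    if not 0 < phys.mucus_volume_fraction < 1:
        raise ValidationError(
            "physical.mucus_volume_fraction must be in (0, 1), got "
            f"{phys.mucus_volume_fraction}"
        )

    hyd = HydrolysisParams(**d["hydrolysis"])
    for key in ("k_hyd", "K_Z", "eps_X"):
        _require_nonneg(getattr(hyd, key), f"hydrolysis.{key}")
    if hyd.law not in ("contois", "first_order"):
        raise ValidationError(f"hydrolysis.law must be 'contois' or 'first_order', got {hyd.law!r}")

    groups = {}
    for g in BFGS:
        if g not in d["groups"]:
            raise ConfigurationError(f"groups.{g} missing from parameter config")
        gk = GroupKinetics(**d["groups"][g])
        for key in ("k_m", "K_S", "Y", "k_dec"):
            _require_nonneg(getattr(gk, key), f"groups.{g}.{key}")
        if gk.Y >= 1:
            raise ValidationError(f"groups.{g}.Y must be < 1, got {gk.Y}")
        groups[g] = gk

    st = StoichiometryParams(**{k: dict(v) for k, v in d["stoichiometry"].items()})
    for proc, fractions in (("sd_products", st.sd_products), ("ld_products", st.ld_products)):
        for name, f in fractions.items():
            _require_nonneg(f, f"stoichiometry.{proc}.{name}")
        total = sum(fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"stoichiometry.{proc} fractions must sum to 1, got {total!r}"
            )
    for proc, coeffs in (("hda_coeffs", st.hda_coeffs), ("hdm_coeffs", st.hdm_coeffs)):
        total = sum(coeffs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"stoichiometry.{proc} net coefficients must sum to 1, got {total!r}"
            )

    exch = ExchangeSpec(**d["exchange"])
    exch.validate()

    num = NumericsParams(**d["numerics"])
    if num.grid_n < 1:
        raise ValidationError("numerics.grid_n must be >= 1")

    init = InitialState(**d["initial"])
    _require_nonneg(init.biomass_seed, "initial.biomass_seed")

    profile = d.get("inhibition_profile")
    if profile is not None:
        profile = [float(v) for v in profile]
        if any(not 0 < v <= 1 for v in profile):
            raise ValidationError("inhibition_profile values must lie in (0, 1]")

    return ParameterSet(
        physical=phys,
        hydrolysis=hyd,
        groups=groups,
        stoichiometry=st,
        exchange=exch,
        numerics=num,
        initial=init,
        co2_limit_K=_require_nonneg(d["co2_limit_K"], "co2_limit_K"),
        inhibition_profile=profile,
    )


def save_parameters(params: ParameterSet, path: str | Path | None = None) -> str:
    """Serialize a parameter set to YAML; round-trips through load_parameters."""
    text = yaml.safe_dump(params.to_dict(), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
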