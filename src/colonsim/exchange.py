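"""Lumen-mucus-host component exchange.

The mucus layer is a fixed-volume medium attached to the colon wall.  Between
it and the flowing lumen, materials move by first-order (linear) fluxes:
biomass attaches and detaches; sugar and the solutes (SCFAs, dissolved
gases, fermentation water) diffuse down their concentration differences;
mucus fiber sloughs off into the lumen; and an endogenous mucin source
produces fiber in the mucus at a constant rate.  SCFAs and dissolved gases
are additionally absorbed from the lumen by the host.  All transfers
are expressed per unit volume of their source compartment, and converted with
the lumen:mucus volume ratio so that transferred mass is conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["ExchangeSpec", "exchange_term", "exchange_fluxes", "absorbed_mass"]


@dataclass
class ExchangeSpec:
    """First-order exchange rates (1/h) and the mucin source (g/L/h).

    ``absorb`` maps a component category (``scfa``, ``solute_gas``, ``sugar``,
    ``water``) to a lumen-to-host removal rate.  Water and gas-phase
    components never exchange with the mucus.
    """

    absorb: dict[str, float] = field(
        default_factory=lambda: {"scfa": 0.3, "solute_gas": 0.1, "sugar": 0.0, "water": 0.0}
    )
    attach: float = 0.1            # biomass lumen -> mucus, 1/h
    detach: float = 0.05           # biomass mucus -> lumen, 1/h
    sugar_diffusion: float = 0.5   # sugar lumen <-> mucus, 1/h
    solute_diffusion: float = 0.5  # SCFA/dissolved gas/water lumen <-> mucus, 1/h
    mucus_production: float = 0.05  # endogenous mucin fiber source in mucus, g/L/h
    slough: float = 0.02           # mucus fiber -> lumen, 1/h

    def validate(self) -> None:
        for cat, rate in self.absorb.items():
            if cat not in ("scfa", "solute_gas", "sugar", "water"):
                raise ValidationError(f"exchange.absorb: unknown category {cat!r}")
            if not np.isfinite(rate) or rate < 0:
                raise ValidationError(f"exchange.absorb.{cat} must be >= 0, got {rate!r}")
        for name in ("attach", "detach", "sugar_diffusion", "solute_diffusion",
                     "mucus_production", "slough"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"exchange.{name} must be >= 0, got {v!r}")


def _masks(layout):
    """Per-category local index masks, cached on the layout object."""
    cached = getattr(layout, "_exchange_masks", None)
    if cached is not None:
        return cached
    masks = {
        "biomass": layout.local_category_mask("biomass"),
        "fiber": layout.local_category_mask("fiber"),
        "sugar": layout.local_category_mask("sugar"),
        "solute": layout.local_category_mask("scfa", "solute_gas", "water"),
    }
    absorb_cats = ("scfa", "solute_gas", "sugar", "water")
    masks["absorb_cats"] = {c: layout.local_category_mask(c) for c in absorb_cats}
    object.__setattr__(layout, "_exchange_masks", masks)
    return masks


def exchange_fluxes(c_lumen, c_mucus, spec: ExchangeSpec, volumes, layout):
    """Exchange derivatives plus host-absorption and mucin-production fluxes.

    ``c_lumen`` and ``c_mucus`` may be 1-D local state vectors or 2-D arrays
    of shape (n_cells, n_local).  ``volumes`` is a ``(V_lum, V_muc)`` pair.
    Returns ``(dc_lumen, dc_mucus, absorbed, produced)`` where ``absorbed``
    is the per-local-state absorption rate in lumen-concentration units
    (g/L_lum/h) and ``produced`` is the mucin source in mucus-concentration
    units (g/L_muc/h).
    """
    V_lum, V_muc = volumes
    if V_lum <= 0 or V_muc <= 0:
        raise ValidationError(f"volumes must be positive, got {(V_lum, V_muc)}")
    c_lumen = np.asarray(c_lumen, dtype=float)
    c_mucus = np.asarray(c_mucus, dtype=float)
    if c_lumen.shape != c_mucus.shape or c_lumen.shape[-1] != layout.n_local:
        raise ValidationError(
            f"state vectors must both have {layout.n_local} local states, "
            f"got {c_lumen.shape} and {c_mucus.shape}"
        )
    nu = V_lum / V_muc  # converts lumen-volume fluxes to mucus concentration units
    m = _masks(layout)

    d_lum = np.zeros_like(c_lumen)
    d_muc = np.zeros_like(c_mucus)
    absorbed = np.zeros_like(c_lumen)

    # Host absorption (lumen only; mass leaves the system).
    for cat, rate in spec.absorb.items():
        if rate > 0:
            mask = m["absorb_cats"][cat]
            flux = rate * c_lumen[..., mask]
            d_lum[..., mask] -= flux
            absorbed[..., mask] += flux

    # Biomass attachment / detachment.
    bm = m["biomass"]
    if spec.attach > 0:
        flux = spec.attach * c_lumen[..., bm]          # per L lumen
        d_lum[..., bm] -= flux
        d_muc[..., bm] += flux * nu
    if spec.detach > 0:
        flux = spec.detach * c_mucus[..., bm]          # per L mucus
        d_muc[..., bm] -= flux
        d_lum[..., bm] += flux / nu

    # Diffusive transfers toward equal concentrations (rate on the lumen
    # side): sugar, and the solute class (SCFA, dissolved gases, water --
    # fermentation products formed in the mucus must reach the lumen/host).
    for rate, key in ((spec.sugar_diffusion, "sugar"), (spec.solute_diffusion, "solute")):
        if rate > 0:
            sel = m[key]
            flux = rate * (c_lumen[..., sel] - c_mucus[..., sel])
            d_lum[..., sel] -= flux
            d_muc[..., sel] += flux * nu

    # Mucus fiber: sloughing into the lumen and endogenous production.
    fb = m["fiber"]
    if spec.slough > 0:
        flux = spec.slough * c_mucus[..., fb]
        d_muc[..., fb] -= flux
        d_lum[..., fb] += flux / nu
    produced = np.zeros_like(c_mucus)
    if spec.mucus_production > 0:
        d_muc[..., fb] += spec.mucus_production
        produced[..., fb] += spec.mucus_production

    return d_lum, d_muc, absorbed, produced


def exchange_term(c_lumen, c_mucus, spec: ExchangeSpec, volumes, layout):
    """The E(c) contribution: ``(dc_lumen, dc_mucus)`` in g/L/h.

    For every transferred component ``V_lum * dc_lum + V_muc * dc_muc = 0``
    except host absorption (mass removed) and mucin production (mass added).
    """
    d_lum, d_muc, _, _ = exchange_fluxes(c_lumen, c_mucus, spec, volumes, layout)
    return d_lum, d_muc


def absorbed_mass(result) -> "np.ndarray":
    """Cumulative host-absorbed mass (g) per local state over time.

    Array of shape (n_times, n_local); non-decreasing in time, all zero when
    every absorption rate is zero.
    """
    return np.asarray(result.absorbed)
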