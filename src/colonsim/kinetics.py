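"""The reaction term R(c): the anaerobic digestion network.

Digestion follows a five-step carbohydrate pathway: fiber is hydrolyzed to
monomer sugar by enzymes of the sugar-degrading flora, sugar is fermented by
SD strains to mixed acids, H2 and CO2; lactate is fermented further by LD
strains; and dissolved hydrogen is respired by acetogens (HDA, producing
acetate) and methanogens (HDM, producing methane).  Each of the four groups
also decays at a first-order rate, returning its mass to the particulate
fiber pool so that the network is closed on a mass basis.

With one strain per group this is the classical 9-process network
(hydrolysis, four uptakes, four decays); with (nSD, nLD, nHDA, nHDM) strains
the process count is ``1 + 2 * sum(n)``: one shared hydrolysis driven by
total SD biomass, plus one uptake and one decay per strain.  Every column of
the stoichiometry matrix sums to zero (g/g mass basis).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, NumericalError
from .state import BFGS, ParameterSet, StateLayout, StrainParameters, single_strain_parameters

__all__ = ["Process", "ReactionNetwork", "build_reaction_network", "process_rates", "reaction_term"]

#: substrate wiring: group -> substrate component name
UPTAKE_SUBSTRATE = {
    "SD": "sugar",
    "LD": "lactate",
    "HDA": "h2_dissolved",
    "HDM": "h2_dissolved",
}

_UPTAKE_LABEL = {
    "SD": "glucose_utilization",
    "LD": "lactate_utilization",
    "HDA": "acetogenesis",
    "HDM": "methanogenesis",
}


@dataclass(frozen=True)
class Process:
    name: str
    kind: str                 # hydrolysis | uptake | decay
    actor: int | None         # environment-local biomass state index
    substrate: int | None     # environment-local substrate index
    parameters: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ReactionNetwork:
    """Rate laws plus a (n_local x n_processes) mass stoichiometry matrix."""

    layout: StateLayout
    processes: tuple[Process, ...]
    stoichiometry: np.ndarray
    # --- precomputed arrays for vectorized evaluation ---
    _hyd: Mapping[str, float]
    _sd_idx: np.ndarray              # local indices of all SD strains
    _up_X: np.ndarray                # actor index per uptake process
    _up_S: np.ndarray                # substrate index per uptake process
    _up_km: np.ndarray
    _up_KS: np.ndarray
    _up_co2: np.ndarray              # bool: CO2-co-consuming pathway
    _dec_X: np.ndarray
    _dec_k: np.ndarray
    _co2_idx: int
    _co2_K: float

    @property
    def n_processes(self) -> int:
        return len(self.processes)

    # ------------------------------------------------------------------ rates
    def rate_matrix(self, C: np.ndarray, inhibition: np.ndarray | None = None) -> np.ndarray:
        """Process rates (g/L/h) for states ``C`` of shape (..., n_local).

        Negative concentrations are clamped to zero for rate evaluation only.
        ``inhibition`` optionally multiplies hydrolysis and uptake rates
        (static acidity profile; broadcast over leading axes).
        """
        C = np.asarray(C, dtype=float)
        if not np.all(np.isfinite(C)):
            raise NumericalError("non-finite concentration passed to rate evaluation")
        Cc = np.maximum(C, 0.0)
        rho = np.zeros(C.shape[:-1] + (self.n_processes,))

        h = self._hyd
        Z = Cc[..., 0]  # fiber is local state 0 by catalog order
        Xsd = Cc[..., self._sd_idx].sum(axis=-1)
        if h["law"] == "first_order":
            rho_h = h["k_hyd"] * Z
        else:
            denom = h["K_Z"] + Z + h["eps_X"] * Xsd
            rho_h = np.divide(
                h["k_hyd"] * Z * Xsd, denom, out=np.zeros_like(Z), where=denom > 0
            )
        rho[..., 0] = rho_h

        S = Cc[..., self._up_S]
        X = Cc[..., self._up_X]
        up = self._up_km * S / (self._up_KS + S) * X
        if np.any(self._up_co2):
            co2 = Cc[..., self._co2_idx, None]
            lim = co2 / (self._co2_K + co2)
            up = np.where(self._up_co2, up * lim, up)
        n_up = len(self._up_X)
        rho[..., 1 : 1 + n_up] = up
        if inhibition is not None:
            inh = np.asarray(inhibition)[..., None]
            rho[..., : 1 + n_up] *= inh

        rho[..., 1 + n_up :] = self._dec_k * Cc[..., self._dec_X]
        return rho

    def reaction_matrix(self, C: np.ndarray, inhibition=None) -> np.ndarray:
        """dc/dt contribution, shape like ``C``."""
        return self.rate_matrix(C, inhibition) @ self.stoichiometry.T

    def rate_jacobian(self, C: np.ndarray, inhibition: np.ndarray | None = None) -> np.ndarray:
        """d(rho)/d(c): shape (..., n_processes, n_local).

        Derivatives are taken of the clamped rate laws; columns belonging to
        negative concentrations are zeroed (the rates there are constant 0).
        """
        C = np.asarray(C, dtype=float)
        Cc = np.maximum(C, 0.0)
        lead = C.shape[:-1]
        n_local = C.shape[-1]
        J = np.zeros(lead + (self.n_processes, n_local))

        h = self._hyd
        Z = Cc[..., 0]
        if h["law"] == "first_order":
            J[..., 0, 0] = h["k_hyd"]
        else:
            Xsd = Cc[..., self._sd_idx].sum(axis=-1)
            den = h["K_Z"] + Z + h["eps_X"] * Xsd
            with np.errstate(invalid="ignore", divide="ignore"):
                dZ = np.where(den > 0, h["k_hyd"] * Xsd * (den - Z) / den**2, 0.0)
                dX = np.where(den > 0, h["k_hyd"] * Z * (den - h["eps_X"] * Xsd) / den**2, 0.0)
            J[..., 0, 0] = dZ
            for i in self._sd_idx:
                J[..., 0, i] = dX

        n_up = len(self._up_X)
        S = Cc[..., self._up_S]
        X = Cc[..., self._up_X]
        monod = S / (self._up_KS + S)
        dmonod = self._up_KS / (self._up_KS + S) ** 2
        lim = np.ones_like(monod)
        if np.any(self._up_co2):
            co2 = Cc[..., self._co2_idx, None]
            lim = np.where(self._up_co2, co2 / (self._co2_K + co2), 1.0)
            dlim = self._co2_K / (self._co2_K + co2) ** 2
            base = self._up_km * monod * X
            rows = np.arange(1, 1 + n_up)
            contrib = np.where(self._up_co2, base * dlim, 0.0)
            J[..., rows, self._co2_idx] += contrib
        rows = np.arange(1, 1 + n_up)
        J[..., rows, self._up_S] += self._up_km * X * dmonod * lim
        J[..., rows, self._up_X] += self._up_km * monod * lim
        if inhibition is not None:
            J[..., : 1 + n_up, :] *= np.asarray(inhibition)[..., None, None]

        dec_rows = np.arange(1 + n_up, self.n_processes)
        J[..., dec_rows, self._dec_X] += self._dec_k

        J *= (C >= 0.0)[..., None, :]
        return J

    def reaction_jacobian(self, C: np.ndarray, inhibition=None) -> np.ndarray:
        """d(R)/d(c) dense blocks, shape (..., n_local, n_local)."""
        J = self.rate_jacobian(C, inhibition)
        return np.einsum("lp,...pk->...lk", self.stoichiometry, J)

    # ------------------------------------------------------------- variations
    def with_decay_boost(self, group: str, strain_id: int, factor: float) -> "ReactionNetwork":
        """A copy with one strain's decay rate multiplied by ``factor``."""
        target = self.layout.local_index(f"X_{group}", strain_id)
        dec_k = self._dec_k.copy()
        hit = np.flatnonzero(self._dec_X == target)
        if hit.size != 1:
            raise ConfigurationError(f"no unique decay process for {group} strain {strain_id}")
        dec_k[hit] *= factor
        return replace(self, _dec_k=dec_k)


def build_reaction_network(
    layout: StateLayout,
    params: ParameterSet,
    strains: Mapping[str, Sequence[StrainParameters]] | None = None,
) -> ReactionNetwork:
    """Assemble the strain-expanded digestion network for one environment.

    ``strains`` maps each BFG to its :class:`StrainParameters` list; the
    counts must match ``layout.strain_counts``.  The returned network is
    checked to be mass-closed (every stoichiometry column sums to zero).
    """
    if strains is None:
        strains = single_strain_parameters()
    for g in BFGS:
        have = len(strains.get(g, ()))
        want = layout.strain_counts[g]
        if have != want:
            raise ConfigurationError(
                f"group {g}: layout expects {want} strains, got {have} parameter sets"
            )

    li = layout.local_index
    n_local = layout.n_local
    st = params.stoichiometry
    product_map = {
        "SD": st.sd_products,
        "LD": st.ld_products,
        "HDA": st.hda_coeffs,
        "HDM": st.hdm_coeffs,
    }
    fiber = li("fiber")
    processes: list[Process] = []
    columns: list[np.ndarray] = []

    hyd_col = np.zeros(n_local)
    hyd_col[fiber] = -1.0
    hyd_col[li("sugar")] = 1.0
    processes.append(
        Process(
            "hydrolysis",
            "hydrolysis",
            actor=None,
            substrate=fiber,
            parameters={
                "k_hyd": params.hydrolysis.k_hyd,
                "K_Z": params.hydrolysis.K_Z,
                "eps_X": params.hydrolysis.eps_X,
                "law": params.hydrolysis.law,
            },
        )
    )
    columns.append(hyd_col)

    up_X, up_S, up_km, up_KS, up_co2 = [], [], [], [], []
    dec_X, dec_k = [], []
    dec_processes: list[Process] = []
    dec_columns: list[np.ndarray] = []
    for g in BFGS:
        base = params.groups[g]
        sub = li(UPTAKE_SUBSTRATE[g])
        for sp in strains[g]:
            x = li(f"X_{g}", sp.strain_id)
            m = sp.multipliers
            km = base.k_m * m.get("k_m", 1.0)
            KS = base.K_S * m.get("K_S", 1.0)
            Y = base.Y * m.get("Y", 1.0)
            kd = base.k_dec * m.get("k_dec", 1.0)

            col = np.zeros(n_local)
            col[sub] = -1.0
            col[x] = Y
            for comp, coeff in product_map[g].items():
                col[li(comp)] += (1.0 - Y) * coeff
            suffix = "" if layout.strain_counts[g] == 1 else f"_{sp.strain_id}"
            processes.append(
                Process(
                    f"{_UPTAKE_LABEL[g]}{suffix}",
                    "uptake",
                    actor=x,
                    substrate=sub,
                    parameters={"k_m": km, "K_S": KS, "Y": Y},
                )
            )
            columns.append(col)
            up_X.append(x)
            up_S.append(sub)
            up_km.append(km)
            up_KS.append(KS)
            up_co2.append(g in ("HDA", "HDM"))

            dcol = np.zeros(n_local)
            dcol[x] = -1.0
            dcol[fiber] = 1.0
            dec_processes.append(
                Process(
                    f"decay_{g}{suffix}", "decay", actor=x, substrate=None,
                    parameters={"k_dec": kd},
                )
            )
            dec_columns.append(dcol)
            dec_X.append(x)
            dec_k.append(kd)

    processes.extend(dec_processes)
    columns.extend(dec_columns)
    S = np.column_stack(columns)

    colsum = np.abs(S.sum(axis=0)).max()
    if colsum > 1e-10:
        raise ConfigurationError(
            f"stoichiometry columns must sum to zero (max |sum| = {colsum:.2e}); "
            "check the product-fraction tables"
        )

    return ReactionNetwork(
        layout=layout,
        processes=tuple(processes),
        stoichiometry=S,
        _hyd={
            "k_hyd": params.hydrolysis.k_hyd,
            "K_Z": params.hydrolysis.K_Z,
            "eps_X": params.hydrolysis.eps_X,
            "law": params.hydrolysis.law,
        },
        _sd_idx=layout.biomass_local_indices("SD"),
        _up_X=np.array(up_X, dtype=int),
        _up_S=np.array(up_S, dtype=int),
        _up_km=np.array(up_km),
        _up_KS=np.array(up_KS),
        _up_co2=np.array(up_co2, dtype=bool),
        _dec_X=np.array(dec_X, dtype=int),
        _dec_k=np.array(dec_k),
        _co2_idx=layout.local_index("co2_dissolved"),
        _co2_K=params.co2_limit_K,
    )


def stoichiometry_table(network: ReactionNetwork):
    """The mass stoichiometry as a tidy table (component rows, process columns)."""
    import pandas as pd

    index = [
        comp.name if strain is None else f"{comp.name}_{strain}"
        for comp, strain in network.layout.local_states
    ]
    return pd.DataFrame(
        network.stoichiometry,
        index=index,
        columns=[p.name for p in network.processes],
    )


def rate_table(network: ReactionNetwork):
    """Effective per-process rate parameters (strain multipliers applied)."""
    import pandas as pd

    rows = []
    for p in network.processes:
        row = {"process": p.name, "kind": p.kind}
        row.update({k: v for k, v in p.parameters.items() if not isinstance(v, str)})
        rows.append(row)
    return pd.DataFrame(rows).set_index("process")


def process_rates(c_local: np.ndarray, network: ReactionNetwork) -> np.ndarray:
    """Rate vector rho (g/L/h) for one environment-local state vector."""
    return network.rate_matrix(np.asarray(c_local, dtype=float))


def reaction_term(c_local: np.ndarray, network: ReactionNetwork) -> np.ndarray:
    """dc/dt = stoichiometry . rho; sums to zero over states (mass closure)."""
    return network.reaction_matrix(np.asarray(c_local, dtype=float))
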