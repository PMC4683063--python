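"""Time integration of the full advection-reaction-exchange model.

Two representations are exposed.  ``simulate_pfr`` solves the spatially
continuous model by the method of lines on a uniform grid (first-order
upwind advection, stiff implicit integration of the coupled system);
``simulate_cstr_chain`` solves N serially connected well-mixed stages.  With
upwind fluxes the two semi-discretizations are *identical* ODE systems --
an n-cell grid is an n-stage cascade with stage dilution rate n/MTT -- which
is exploited as a cross-verification oracle in the test-suite.

The default integration is monolithic: one stiff BDF solve over all cells
with an analytic sparse Jacobian (dense within-cell reaction blocks, a
constant exchange operator, constant upwind couplings), factorized with
sparse LU.  Integration is split into segments at boundary-forcing
discontinuities (meal edges, perturbation windows) inside which the forcing
is smooth.  A Strang operator-splitting mode (explicit upwind advection at
CFL-limited steps, implicit reaction/exchange in between) is available as
``method="split"`` for the plug-flow representation.

Meal pulses, absorption and mucin production are accumulated as quadrature
states integrated alongside the model, so the global mass audit
(inflow - outflow - absorbed + produced = change of stored mass) closes to
integration tolerance on every run.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, NumericalError, ValidationError
from .exchange import exchange_fluxes
from .kinetics import ReactionNetwork, build_reaction_network
from .scenarios import Scenario
from .state import StateLayout, build_state_layout
from .transport import inflow_fiber_concentration, forcing_breakpoints

__all__ = [
    "SimulationResult",
    "simulate_pfr",
    "simulate_cstr_chain",
    "run_replicates",
    "mass_audit",
]

#: The coarsest spatial discretization of the continuous representation.
MIN_GRID_N = 51


@dataclass
class SimulationResult:
    """Concentration field over (time x location x state) with accumulators."""

    times: np.ndarray                  # h, strictly increasing
    states: np.ndarray                 # (nt, n_locations, n_states), g/L
    layout: StateLayout
    scenario: Scenario
    mode: str                          # "pfr" | "cstr"
    x_centers: np.ndarray | None       # m (PFR) or stage mid-positions (CSTR)
    inflow: np.ndarray                 # (nt, n_local) cumulative g
    outflow: np.ndarray
    absorbed: np.ndarray
    produced: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    resolved_dominant: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def n_locations(self) -> int:
        return self.states.shape[1]

    @property
    def lumen(self) -> np.ndarray:
        """(nt, n_locations, n_local) lumen concentrations."""
        return self.states[:, :, : self.layout.n_local]

    @property
    def mucus(self) -> np.ndarray:
        return self.states[:, :, self.layout.n_local : 2 * self.layout.n_local]

    def outflow_lumen(self) -> np.ndarray:
        """(nt, n_local) lumen concentrations at the distal outlet."""
        return self.lumen[:, -1, :]


# ---------------------------------------------------------------------------
# Core right-hand side
# ---------------------------------------------------------------------------


class _Model:
    """Assembled, per-segment-constant pieces of the ODE system."""

    def __init__(self, scenario: Scenario, n_cells: int, mode: str):
        self.scenario = scenario
        self.n_cells = int(n_cells)
        self.mode = mode
        self.layout = build_state_layout(scenario.strain_counts, scenario.gas_mode)
        if tuple(self.layout.environments) != ("lumen", "mucus"):
            raise ConfigurationError("the solver requires the (lumen, mucus) environment pair")
        self.params = scenario.params
        self.strains = scenario.build_strains()
        self.network = build_reaction_network(self.layout, self.params, self.strains)
        self.flow = scenario.flow
        self.diet = scenario.diet

        ph = self.params.physical
        self.V_lum = ph.lumen_volume
        self.V_muc = ph.mucus_volume
        self.V_cell_lum = self.V_lum / self.n_cells
        self.V_cell_muc = self.V_muc / self.n_cells
        self.Q = self.flow.volumetric_flow
        self.adv = self.n_cells / self.flow.mean_transit_time  # v/dx, 1/h

        self.n_local = self.layout.n_local
        self.n_states = self.layout.n_states
        self.nfield = self.n_cells * self.n_states
        self.n_aux = 4 * self.n_local
        self.fiber_i = self.layout.local_index("fiber")

        inh = self.params.inhibition_profile
        if inh is not None:
            if len(inh) != self.n_cells:
                raise ValidationError(
                    f"inhibition_profile has {len(inh)} values but the run uses "
                    f"{self.n_cells} locations"
                )
            self.inhibition = np.asarray(inh, dtype=float)
        else:
            self.inhibition = None

    # ------------------------------------------------------------------ state
    def initial_vector(self, initial_field: np.ndarray | None = None) -> np.ndarray:
        y0 = np.zeros(self.nfield + self.n_aux)
        field = y0[: self.nfield].reshape(self.n_cells, 2, self.n_local)
        if initial_field is not None:
            given = np.asarray(initial_field, dtype=float)
            if given.shape != field.shape:
                raise ConfigurationError(
                    f"initial_field must have shape {field.shape}, got {given.shape}"
                )
            field[:] = given
            return y0
        # Each group starts at biomass_seed in total, split over its strains,
        # so strain refinement leaves the initial community unchanged.
        seed = self.params.initial.biomass_seed
        for g, lst in self.strains.items():
            for sp in lst:
                li = self.layout.local_index(f"X_{g}", sp.strain_id)
                field[:, :, li] = seed * sp.initial_fraction
        return y0

    def boundary_concentration(self, t, scale: float) -> np.ndarray:
        """(n_local,) or (n_local, nt) boundary inflow vector."""
        fib = scale * inflow_fiber_concentration(t, self.diet, self.flow)
        c = np.zeros(self.n_local) if np.ndim(t) == 0 else np.zeros((self.n_local,) + np.shape(t))
        c[self.fiber_i] = fib
        return c

    # ------------------------------------------------------------------- rhs
    def make_rhs(self, network: ReactionNetwork, diet_scale: float,
                 c_in_const: np.ndarray | None = None):
        """Batch-vectorized RHS: accepts y of shape (n,) or (n, k).

        The batched form lets the stiff solver evaluate whole groups of
        finite-difference Jacobian columns in a single call.
        """
        n_cells, n_local, nfield = self.n_cells, self.n_local, self.nfield
        adv, Q = self.adv, self.Q
        spec = self.params.exchange
        vols = (self.V_lum, self.V_muc)
        layout = self.layout
        inh = self.inhibition

        def rhs(t, y):
            single = y.ndim == 1
            Y = y[:, None] if single else y
            k = Y.shape[1]
            field = Y[:nfield].T.reshape(k, n_cells, 2, n_local)
            c_lum = field[:, :, 0, :]
            c_muc = field[:, :, 1, :]

            d_lum, d_muc, absorbed, produced = exchange_fluxes(
                c_lum, c_muc, spec, vols, layout
            )
            d_lum += network.reaction_matrix(c_lum, inh)
            d_muc += network.reaction_matrix(c_muc, inh)

            if c_in_const is not None:
                c_in = c_in_const
            else:
                c_in = self.boundary_concentration(np.float64(t), diet_scale)
            d_lum[:, 1:] += adv * (c_lum[:, :-1] - c_lum[:, 1:])
            d_lum[:, 0] += adv * (c_in[None, :] - c_lum[:, 0])

            dY = np.empty((k, nfield + self.n_aux))
            dY[:, :nfield] = np.stack([d_lum, d_muc], axis=2).reshape(k, nfield)
            aux = dY[:, nfield:]
            aux[:, :n_local] = Q * c_in[None, :]
            aux[:, n_local : 2 * n_local] = Q * c_lum[:, -1]
            aux[:, 2 * n_local : 3 * n_local] = absorbed.sum(axis=1) * self.V_cell_lum
            aux[:, 3 * n_local :] = produced.sum(axis=1) * self.V_cell_muc
            out = dY.T
            return out[:, 0] if single else out

        return rhs

    # ------------------------------------------------------------- jacobian
    def exchange_operator(self) -> tuple[np.ndarray, np.ndarray]:
        """(E, a): the constant linear exchange operator on one cell's
        (lumen, mucus) state block, and the per-state absorption rates.

        Exchange fluxes are linear in the concentrations, so the operator is
        recovered exactly by probing with unit vectors.
        """
        n_local = self.n_local
        spec = self.params.exchange
        vols = (self.V_lum, self.V_muc)
        E = np.zeros((self.n_states, self.n_states))
        absorb = np.zeros(n_local)
        zero = np.zeros(n_local)
        base_l, base_m, base_a, _ = exchange_fluxes(zero, zero, spec, vols, self.layout)
        for j in range(self.n_states):
            cl, cm = zero.copy(), zero.copy()
            (cl if j < n_local else cm)[j % n_local] = 1.0
            dl, dm, ab, _ = exchange_fluxes(cl, cm, spec, vols, self.layout)
            E[:n_local, j] = dl - base_l
            E[n_local:, j] = dm - base_m
            if j < n_local:
                absorb[j] = (ab - base_a)[j]
        return E, absorb

    def make_jac(self, network: ReactionNetwork):
        """Analytic sparse Jacobian of the full system (for the BDF solver)."""
        n_cells, n_local, n_states = self.n_cells, self.n_local, self.n_states
        nfield = self.nfield
        n = nfield + self.n_aux
        m2 = n_cells * 2

        # per-(cell, env) dense reaction blocks
        li = np.arange(n_local)
        off = (np.arange(m2) // 2) * n_states + (np.arange(m2) % 2) * n_local
        block_rows = (off[:, None, None] + np.broadcast_to(li[:, None], (n_local, n_local))).ravel()
        block_cols = (off[:, None, None] + np.broadcast_to(li[None, :], (n_local, n_local))).ravel()

        rows, cols, vals = [], [], []
        E, absorb = self.exchange_operator()
        er, ec = np.nonzero(E)
        for c in range(n_cells):
            rows.append(c * n_states + er)
            cols.append(c * n_states + ec)
            vals.append(E[er, ec])
        # advection: -adv on lumen diagonals, +adv from the upstream cell
        for c in range(n_cells):
            rows.append(c * n_states + li)
            cols.append(c * n_states + li)
            vals.append(np.full(n_local, -self.adv))
            if c > 0:
                rows.append(c * n_states + li)
                cols.append((c - 1) * n_states + li)
                vals.append(np.full(n_local, self.adv))
        # accumulators: outflow <- last cell lumen, absorbed <- every cell lumen
        rows.append(nfield + n_local + li)
        cols.append((n_cells - 1) * n_states + li)
        vals.append(np.full(n_local, self.Q))
        for c in range(n_cells):
            rows.append(nfield + 2 * n_local + li)
            cols.append(c * n_states + li)
            vals.append(absorb * self.V_cell_lum)
        const_rows = np.concatenate(rows)
        const_cols = np.concatenate(cols)
        const_vals = np.concatenate(vals)

        all_rows = np.concatenate([block_rows, const_rows])
        all_cols = np.concatenate([block_cols, const_cols])
        inh_all = None if self.inhibition is None else np.repeat(self.inhibition, 2)

        def jac(t, y):
            field = y[:nfield].reshape(m2, n_local)
            Jb = network.reaction_jacobian(field, inh_all)
            data = np.concatenate([Jb.ravel(), const_vals])
            return sparse.coo_matrix((data, (all_rows, all_cols)), shape=(n, n)).tocsc()

        return jac

    # ------------------------------------------------------- dominant strains
    def dominant_strain(self, y: np.ndarray, group: str) -> int:
        field = y[: self.nfield].reshape(self.n_cells, 2, self.n_local)
        w = np.array([1.0 - self.params.physical.mucus_volume_fraction,
                      self.params.physical.mucus_volume_fraction])
        totals = []
        for s in self.layout.strains_of(group):
            li = self.layout.local_index(f"X_{group}", s)
            totals.append(float((field[:, :, li] * w).sum()))
        return int(np.argmax(totals)) + 1


# ---------------------------------------------------------------------------
# Monolithic (method-of-lines) integration
# ---------------------------------------------------------------------------


def _active_boosts(model: _Model, t_mid: float, resolved: dict, y: np.ndarray):
    """(group, strain, factor) tuples active at ``t_mid``, resolving dominants."""
    out = []
    for i, p in enumerate(model.scenario.perturbations):
        if p.kind != "decay_boost" or not p.active(t_mid):
            continue
        strain = p.strain
        if strain == "dominant":
            if i not in resolved:
                if model.layout.strain_counts[p.group] < 2:
                    raise ConfigurationError(
                        f"perturbation {i} targets the dominant strain of {p.group}, "
                        "which has a single strain; give an explicit strain id"
                    )
                resolved[i] = model.dominant_strain(y, p.group)
            strain = resolved[i]
        out.append((p.group, int(strain), p.factor))
    return tuple(sorted(out))


def _clip_negative(y: np.ndarray, model: _Model, threshold: float) -> float:
    """Clip negative field states to zero; return the clipped mass (g)."""
    field = y[: model.nfield].reshape(model.n_cells, 2, model.n_local)
    neg = field < -threshold
    if not neg.any():
        np.clip(field, 0.0, None, out=field)
        return 0.0
    vols = np.array([model.V_cell_lum, model.V_cell_muc])[None, :, None]
    clipped = float((np.where(neg, -field, 0.0) * vols).sum())
    np.clip(field, 0.0, None, out=field)
    return clipped


def _integrate_mol(model: _Model, t_end: float, output_every: float,
                   initial_field=None) -> SimulationResult:
    scenario = model.scenario
    num = model.params.numerics
    outputs = np.arange(0.0, t_end + 1e-9, output_every)
    pert_edges = [e for p in scenario.perturbations for e in (p.start, p.end)]
    breaks = forcing_breakpoints(model.diet, 0.0, t_end, extra=pert_edges)

    y = model.initial_vector(initial_field)
    resolved: dict[int, int] = {}
    frames = [y.copy()]
    frame_times = [0.0]
    diag = {"nfev": 0, "njev": 0, "nlu": 0, "n_segments": 0, "clipped_mass": 0.0}
    clip_thresh = num.clip_threshold

    cached_key, cached_net = None, None
    for ta, tb in zip(breaks[:-1], breaks[1:]):
        t_mid = 0.5 * (ta + tb)
        boosts = _active_boosts(model, t_mid, resolved, y)
        if boosts != cached_key:
            net = model.network
            for g, s, f in boosts:
                net = net.with_decay_boost(g, s, f)
            cached_key, cached_net = boosts, (net, model.make_jac(net))
        net, jac = cached_net
        diet_scale = scenario.fiber_inflow_scale(t_mid)
        # Square-pulse forcing is constant between breakpoints; freeze it.
        c_in_const = (
            model.boundary_concentration(t_mid, diet_scale)
            if scenario.dilution_stages == 0
            else None
        )
        rhs = model.make_rhs(net, diet_scale, c_in_const)

        mask = (outputs > ta + 1e-12) & (outputs <= tb + 1e-12)
        t_eval = np.unique(np.append(outputs[mask], tb))
        sol = solve_ivp(
            rhs, (ta, tb), y, method="BDF", t_eval=t_eval,
            rtol=num.rtol, atol=num.atol, jac=jac, vectorized=True,
        )
        if not sol.success:
            raise NumericalError(
                f"stiff integration failed on segment [{ta:.3f}, {tb:.3f}] h: {sol.message}"
            )
        diag["nfev"] += sol.nfev
        diag["njev"] += sol.njev
        diag["nlu"] += sol.nlu
        diag["n_segments"] += 1
        for tk, yk in zip(sol.t, sol.y.T):
            if np.any(np.abs(outputs - tk) < 1e-9):
                yk = yk.copy()
                diag["clipped_mass"] += _clip_negative(yk, model, clip_thresh)
                frames.append(yk)
                frame_times.append(tk)
        y = sol.y[:, -1].copy()
        diag["clipped_mass"] += _clip_negative(y, model, clip_thresh)

    return _package(model, np.array(frame_times), frames, diag, resolved)


def _package(model, times, frames, diag, resolved) -> SimulationResult:
    Y = np.asarray(frames)
    keep = np.concatenate([[True], np.diff(times) > 1e-12])
    times, Y = times[keep], Y[keep]
    nl = model.n_local
    states = Y[:, : model.nfield].reshape(len(times), model.n_cells, model.n_states)
    aux = Y[:, model.nfield :]
    inflow_total = float(aux[-1, :nl].sum())
    if inflow_total > 0 and diag["clipped_mass"] > model.params.numerics.max_clipped_fraction * inflow_total:
        raise NumericalError(
            f"clipped negative mass {diag['clipped_mass']:.3e} g exceeds "
            f"{model.params.numerics.max_clipped_fraction:.0e} of throughput"
        )
    dx = model.params.physical.colon_length / model.n_cells
    x_centers = (np.arange(model.n_cells) + 0.5) * dx
    diag.update(
        n_ode=model.nfield,
        n_aux=model.n_aux,
        n_locations=model.n_cells,
        rtol=model.params.numerics.rtol,
        atol=model.params.numerics.atol,
    )
    return SimulationResult(
        times=times,
        states=states,
        layout=model.layout,
        scenario=model.scenario,
        mode=model.mode,
        x_centers=x_centers,
        inflow=aux[:, :nl],
        outflow=aux[:, nl : 2 * nl],
        absorbed=aux[:, 2 * nl : 3 * nl],
        produced=aux[:, 3 * nl :],
        diagnostics=diag,
        resolved_dominant=dict(resolved),
        seed=model.scenario.seed,
    )


# ---------------------------------------------------------------------------
# Strang operator splitting (plug-flow alternative)
# ---------------------------------------------------------------------------


def _integrate_split(model: _Model, t_end: float, output_every: float,
                     initial_field=None) -> SimulationResult:
    """Strang splitting: implicit reaction/exchange halves around explicit upwind.

    Restricted to square-pulse boundary forcing (no dilution smoothing), so
    the advected inflow mass per step can be computed exactly from meal
    window overlaps.
    """
    scenario = model.scenario
    if scenario.dilution_stages != 0:
        raise ConfigurationError("method='split' requires dilution_stages=0")
    num = model.params.numerics
    dt_adv = num.cfl / model.adv
    outputs = np.arange(0.0, t_end + 1e-9, output_every)
    pert_edges = [e for p in scenario.perturbations for e in (p.start, p.end)]
    breaks = forcing_breakpoints(model.diet, 0.0, t_end, extra=pert_edges)
    # output times must be hit exactly: merge them into the step boundaries
    grid = np.unique(np.concatenate([breaks, outputs]))

    spars = _reaction_sparsity(model)
    y = model.initial_vector(initial_field)
    resolved: dict[int, int] = {}
    frames, frame_times = [y.copy()], [0.0]
    diag = {"nfev": 0, "njev": 0, "nlu": 0, "n_segments": 0, "clipped_mass": 0.0}
    nl = model.n_local
    amp0 = model.diet.meal_mass() / (model.flow.volumetric_flow * model.diet.meal_duration)

    cached_key, cached_net = None, None
    for ta, tb in zip(grid[:-1], grid[1:]):
        t_mid = 0.5 * (ta + tb)
        boosts = _active_boosts(model, t_mid, resolved, y)
        if boosts != cached_key:
            net = model.network
            for g, s, f in boosts:
                net = net.with_decay_boost(g, s, f)
            cached_key, cached_net = boosts, net
        scale = scenario.fiber_inflow_scale(t_mid)
        windows = [w for w in model.diet.meal_windows(ta, tb)]

        n_sub = max(1, int(np.ceil((tb - ta) / dt_adv)))
        dt = (tb - ta) / n_sub
        t = ta
        for _ in range(n_sub):
            y = _reaction_half(model, cached_net, y, t, 0.5 * dt, spars, diag)
            _advect_step(model, y, t, dt, amp0 * scale, windows)
            y = _reaction_half(model, cached_net, y, t + 0.5 * dt, 0.5 * dt, spars, diag)
            t += dt
        diag["clipped_mass"] += _clip_negative(y, model, num.clip_threshold)
        diag["n_segments"] += 1
        if np.any(np.abs(outputs - tb) < 1e-9):
            frames.append(y.copy())
            frame_times.append(tb)

    return _package(model, np.array(frame_times), frames, diag, resolved)


def _reaction_sparsity(model: _Model) -> sparse.csr_matrix:
    """Block-diagonal within-cell pattern (reaction+exchange only)."""
    n = model.nfield + model.n_aux
    rows, cols = [], []
    idx = np.arange(model.n_states)
    loc = np.arange(model.n_local)
    for c in range(model.n_cells):
        base = c * model.n_states
        rows.append(np.repeat(base + idx, model.n_states))
        cols.append(np.tile(base + idx, model.n_states))
        rows.append(model.nfield + 2 * model.n_local + loc)
        cols.append(base + loc)
    r, c = np.concatenate(rows), np.concatenate(cols)
    return sparse.coo_matrix((np.ones_like(r, dtype=np.int8), (r, c)), shape=(n, n)).tocsr()


def _reaction_half(model, network, y, t0, dt, spars, diag):
    nfield, n_local = model.nfield, model.n_local
    spec = model.params.exchange
    vols = (model.V_lum, model.V_muc)
    inh = model.inhibition

    def rhs(t, yy):
        field = yy[:nfield].reshape(model.n_cells, 2, n_local)
        c_lum, c_muc = field[:, 0, :], field[:, 1, :]
        d_lum, d_muc, absorbed, produced = exchange_fluxes(c_lum, c_muc, spec, vols, model.layout)
        d_lum += network.reaction_matrix(c_lum, inh)
        d_muc += network.reaction_matrix(c_muc, inh)
        dy = np.zeros_like(yy)
        dfield = dy[:nfield].reshape(model.n_cells, 2, n_local)
        dfield[:, 0, :] = d_lum
        dfield[:, 1, :] = d_muc
        dy[nfield + 2 * n_local : nfield + 3 * n_local] = absorbed.sum(axis=0) * model.V_cell_lum
        dy[nfield + 3 * n_local :] = produced.sum(axis=0) * model.V_cell_muc
        return dy

    num = model.params.numerics
    sol = solve_ivp(rhs, (t0, t0 + dt), y, method="BDF",
                    rtol=num.rtol, atol=num.atol, jac_sparsity=spars)
    if not sol.success:
        raise NumericalError(f"reaction half-step failed at t={t0:.3f} h: {sol.message}")
    diag["nfev"] += sol.nfev
    diag["njev"] += sol.njev
    diag["nlu"] += sol.nlu
    return sol.y[:, -1].copy()


def _advect_step(model, y, t, dt, amp, windows):
    """Explicit upwind advection over [t, t+dt]; exact inflow-mass bookkeeping."""
    nfield, n_local = model.nfield, model.n_local
    field = y[:nfield].reshape(model.n_cells, 2, n_local)
    c_lum = field[:, 0, :]
    overlap = sum(max(0.0, min(t + dt, b) - max(t, a)) for a, b in windows)
    c_in = np.zeros(n_local)
    c_in[model.fiber_i] = amp * overlap / dt
    upstream = np.vstack([c_in[None, :], c_lum[:-1]])
    aux = y[nfield:]
    aux[:n_local] += model.Q * c_in * dt
    aux[n_local : 2 * n_local] += model.Q * c_lum[-1] * dt
    field[:, 0, :] = c_lum + model.adv * dt * (upstream - c_lum)


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------


def simulate_pfr(
    scenario: Scenario,
    grid_n: int | None = None,
    t_end: float | None = None,
    output_every: float | None = None,
    method: str = "mol",
    allow_coarse: bool = False,
    initial_field=None,
) -> SimulationResult:
    """Simulate the spatially continuous representation.

    ``grid_n`` defaults to the scenario/parameter setting and must be at
    least 51 (the coarsest supported discretization) unless ``allow_coarse``
    is set -- coarse grids are only meaningful for cross-checks against the
    stage representation.  ``method`` is ``"mol"`` (monolithic stiff
    method-of-lines, default) or ``"split"`` (Strang operator splitting).
    """
    grid_n = int(grid_n or scenario.grid_n or scenario.params.numerics.grid_n)
    if grid_n < MIN_GRID_N and not allow_coarse:
        raise ConfigurationError(
            f"grid_n={grid_n} is below the coarsest supported grid ({MIN_GRID_N}); "
            "pass allow_coarse=True for verification runs"
        )
    model = _Model(scenario, grid_n, mode="pfr")
    t_end = float(t_end if t_end is not None else scenario.t_end)
    output_every = float(output_every or scenario.output_every or scenario.params.numerics.output_every)
    if method == "mol":
        return _integrate_mol(model, t_end, output_every, initial_field)
    if method == "split":
        return _integrate_split(model, t_end, output_every, initial_field)
    raise ConfigurationError(f"unknown method {method!r}")


def simulate_cstr_chain(
    scenario: Scenario,
    n_stages: int | None = None,
    t_end: float | None = None,
    output_every: float | None = None,
    initial_field=None,
) -> SimulationResult:
    """Simulate the discrete representation: N serially connected stages.

    Stage volumes are equal; stage i receives the outflow of stage i-1 and
    stage 1 the boundary signal; mucus states do not flow between stages.
    """
    n_stages = int(n_stages or scenario.n_stages)
    if n_stages < 1:
        raise ConfigurationError("n_stages must be >= 1")
    model = _Model(scenario, n_stages, mode="cstr")
    t_end = float(t_end if t_end is not None else scenario.t_end)
    output_every = float(output_every or scenario.output_every or scenario.params.numerics.output_every)
    result = _integrate_mol(model, t_end, output_every, initial_field)
    return result


def run_replicates(
    scenario: Scenario,
    n_reps: int,
    base_seed: int = 0,
    mode: str | None = None,
    **kwargs,
) -> list[SimulationResult]:
    """Repeat a scenario with replicate strain-sampling seeds.

    Replicate r runs with seed ``base_seed + r`` (strain sampling only; the
    physics is deterministic).  Results carry their seeds.
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    mode = mode or scenario.mode
    out = []
    for r in range(n_reps):
        sc = copy.deepcopy(scenario)
        sc.seed = base_seed + r
        if mode == "pfr":
            out.append(simulate_pfr(sc, **kwargs))
        elif mode == "cstr":
            out.append(simulate_cstr_chain(sc, **kwargs))
        else:
            raise ConfigurationError(f"unknown mode {mode!r}")
    return out


def mass_audit(result: SimulationResult) -> dict:
    """Global mass balance: inflow - outflow - absorbed + produced vs storage.

    Returns the worst relative residual over output frames, normalized by
    total throughput (cumulative inflow plus initial stored mass).
    """
    ph = result.scenario.params.physical
    n = result.n_locations
    vols = np.array([ph.lumen_volume / n, ph.mucus_volume / n])
    nt = len(result.times)
    frames = result.states.reshape(nt, n, 2, result.layout.n_local)
    stored = (frames * vols[None, None, :, None]).sum(axis=(1, 2, 3))
    inflow = result.inflow.sum(axis=1)
    outflow = result.outflow.sum(axis=1)
    absorbed = result.absorbed.sum(axis=1)
    produced = result.produced.sum(axis=1)
    residual = inflow - outflow - absorbed + produced - (stored - stored[0])
    scale = max(inflow[-1] + stored[0], 1e-12)
    return {
        "max_abs_residual": float(np.abs(residual).max()),
        "relative": float(np.abs(residual).max() / scale),
        "throughput": float(scale),
    }
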