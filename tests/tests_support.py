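"""Shared helpers for transport verification tests."""

import numpy as np

import colonsim as cs
from conftest import transport_only_params


def pulse_l1_errors(grids, t_end=4.0, pulse=(0.3, 0.6)):
    """L1 error of an advected square pulse against its exact translation."""
    errors = []
    for n in grids:
        params = transport_only_params()
        sc = cs.Scenario(params=params, diet=cs.DietSchedule(fiber_per_day=0.0),
                         t_end=t_end)
        layout = cs.build_state_layout()
        field = np.zeros((n, 2, layout.n_local))
        x = (np.arange(n) + 0.5) * (1.5 / n)
        field[(x >= pulse[0]) & (x < pulse[1]), 0, layout.local_index("fiber")] = 1.0
        res = cs.simulate_pfr(sc, grid_n=n, t_end=t_end, output_every=t_end,
                              method="split", initial_field=field, allow_coarse=True)
        v = sc.flow.velocity
        exact = ((x >= pulse[0] + t_end * v) & (x < pulse[1] + t_end * v)).astype(float)
        errors.append(np.abs(res.lumen[-1, :, 0] - exact).mean() * 1.5)
    return errors
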