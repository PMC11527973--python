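"""Independent ODE oracle for sensorgram simulation.

Integrates the component rate equations dR_i/dt = ka_i*C(t)*(rmax_i - R_i)
- kd_i*R_i numerically with a generic stiff-capable adaptive integrator,
deliberately sharing no code with the package's piecewise closed form.
Used only by tests (anti-circularity).
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp


def ode_response(model, schedule, t_grid, rtol=1e-9, atol=1e-12):
    """Total response on t_grid by per-segment adaptive integration."""
    t_grid = np.asarray(t_grid, dtype=float)
    comps = model.components
    n = len(comps)
    out = np.zeros((n, t_grid.size))
    r0 = np.zeros(n)
    for seg in schedule.segments:
        C = seg.concentration_M

        def rhs(t, R):
            return np.array(
                [c.ka * C * (c.rmax - R[i]) - c.kd * R[i] for i, c in enumerate(comps)]
            )

        in_seg = (t_grid >= seg.start_s) & (t_grid < seg.end_s)
        # the final grid point may sit exactly at the schedule end
        if seg is schedule.segments[-1]:
            in_seg |= t_grid == seg.end_s
        t_eval = np.unique(np.concatenate([t_grid[in_seg], [seg.end_s]]))
        sol = solve_ivp(
            rhs,
            (seg.start_s, seg.end_s),
            r0,
            method="Radau",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        assert sol.success, sol.message
        if np.any(in_seg):
            pos = np.searchsorted(sol.t, t_grid[in_seg])
            out[:, in_seg] = sol.y[:, pos]
        r0 = sol.y[:, -1]
    total = out.sum(axis=0)
    if model.bulk_ri_RU:
        starts = np.array([s.start_s for s in schedule.segments])
        idx = np.clip(np.searchsorted(starts, t_grid, side="right") - 1, 0,
                      len(schedule.segments) - 1)
        assoc = np.array([s.kind == "association" for s in schedule.segments])
        total = total + model.bulk_ri_RU * assoc[idx]
    return total
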