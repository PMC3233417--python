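"""Independent numerical oracles used by the test-suite.

Deliberately simple and separate from the package's solver path: a
classical fixed-step RK4 integrator and a plain-Python re-implementation
of the daily cadmium difference equations.
"""

from __future__ import annotations

import numpy as np


def rk4(rhs, y0, t_end, dt, t0=0.0):
    """Classical fixed-step fourth-order Runge-Kutta; returns final state."""
    y = np.array(y0, dtype=float)
    n = int(round((t_end - t0) / dt))
    t = t0
    for _ in range(n):
        k1 = rhs(t, y)
        k2 = rhs(t + dt / 2, y + dt / 2 * k1)
        k3 = rhs(t + dt / 2, y + dt / 2 * k2)
        k4 = rhs(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
    return y


def cadmium_reference(params, sex, intake_ug_per_day, n_days):
    """Step-by-step re-implementation of the daily Cd transfer scheme.

    Returns (pools dict, cumulative urine, cumulative feces) after
    ``n_days`` of constant dietary intake.
    """
    pools = {"plasma": 0.0, "rbc": 0.0, "blood_mt": 0.0,
             "liver": 0.0, "kidney": 0.0, "other": 0.0}
    urine = feces = 0.0
    f_abs = params.absorption_fraction[sex]
    for _ in range(n_days):
        outgoing = {}
        for src, targets in params.transfers_per_day.items():
            for tgt, frac in targets.items():
                outgoing[(src, tgt)] = pools[src] * frac
        for (src, tgt), amt in outgoing.items():
            pools[src] -= amt
            if tgt == "urine":
                urine += amt
            elif tgt == "feces":
                feces += amt
            else:
                pools[tgt] += amt
        pools["plasma"] += f_abs * intake_ug_per_day
        feces += (1.0 - f_abs) * intake_ug_per_day
    return pools, urine, feces
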