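"""Independent numeric oracle for one-compartment PK profiles.

Integrates dC/dt = rate(t)/V - k_e * C piecewise with ``solve_ivp``
(bolus doses enter as instantaneous jumps of D/V), never reusing the
package's closed-form superposition.
"""

import numpy as np
from scipy.integrate import solve_ivp


def ode_concentration(doses, k_e, V, times):
    """Concentration at ``times`` for DoseEvent-like (drug,time,route,amount)."""
    times = np.asarray(times, dtype=float)
    boluses = sorted((ev.time, ev.amount) for ev in doses if ev.route == "bolus")
    rate_changes = []  # (time, delta_rate)
    open_rate = None
    for ev in sorted(doses, key=lambda e: e.time):
        if ev.route == "infusion_start":
            rate_changes.append((ev.time, ev.amount))
            open_rate = ev.amount
        elif ev.route == "infusion_stop":
            rate_changes.append((ev.time, -open_rate))
            open_rate = None
    breakpoints = sorted(
        {0.0, float(times[-1])}
        | {t for t, _ in boluses}
        | {t for t, _ in rate_changes}
    )
    c = 0.0
    rate = 0.0
    out = np.zeros_like(times)
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        c += sum(amt / V for t, amt in boluses if np.isclose(t, a))
        rate += sum(dr for t, dr in rate_changes if np.isclose(t, a))
        mask = (times >= a) & (times < b)
        t_eval = times[mask]
        sol = solve_ivp(
            lambda t, y: rate / V - k_e * y[0],
            (a, b),
            [c],
            t_eval=np.unique(np.concatenate([t_eval, [b]])),
            rtol=1e-10,
            atol=1e-12,
        )
        if t_eval.size:
            out[mask] = sol.y[0][: t_eval.size]
        c = sol.y[0][-1]
    last = np.isclose(times, breakpoints[-1])
    out[last] = c
    return out


def random_schedule(rng, drug="levetiracetam"):
    """A random bolus/infusion schedule on [0, 72) h."""
    from ea_trial_sim.pkpd import DoseEvent

    events = []
    for _ in range(rng.integers(1, 4)):
        events.append(
            DoseEvent(drug, float(rng.uniform(0, 24)), "bolus", float(rng.uniform(1, 15)))
        )
    cursor = float(rng.uniform(0, 10))
    for _ in range(rng.integers(0, 3)):  # infusion intervals never overlap
        start = cursor + float(rng.uniform(0, 8))
        stop = start + float(rng.uniform(2, 20))
        if stop >= 71.9:
            break
        events.append(DoseEvent(drug, start, "infusion_start", float(rng.uniform(0.2, 2.0))))
        events.append(DoseEvent(drug, stop, "infusion_stop"))
        cursor = stop + float(rng.uniform(0.5, 5))
    return sorted(events, key=lambda e: (e.time, e.route))
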