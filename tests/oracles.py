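"""Independent fixed-step integration oracles for the predation models.

Deliberately primitive (forward Euler on a fine fixed grid, plain Python
floats) so they share no code path with the adaptive solvers they check.
"""

from __future__ import annotations


def euler_adsorption(r, k, n, b0, p0, t_end, dt=1e-4):
    """Forward-Euler integration of the adsorption-limited model.

    Returns (t_col, b_col, p_col, p_end): the argmax of b on the step grid
    and the state there, plus the final phage concentration.
    """
    b, p = b0, p0
    t = 0.0
    best_b, best_t, best_p = b, 0.0, p
    steps = int(round(t_end / dt))
    for _ in range(steps):
        infection = k * p * b
        b += dt * (r * b - infection)
        p += dt * (n * infection)
        t += dt
        if b > best_b:
            best_b, best_t, best_p = b, t, p
    return best_t, best_b, best_p, p


def euler_latency(r, n, tau, b0, p0, t_end, dt=1e-6):
    """Heun (explicit trapezoid) integration of the latency-limited model.

    Second order, so the argmax quantization (one step) dominates the error.
    """
    b, p = b0, p0
    t = 0.0
    best_b, best_t, best_p = b, 0.0, p
    steps = int(round(t_end / dt))
    for _ in range(steps):
        db1 = r * b - p / tau
        dp1 = n * p / tau
        b1 = b + dt * db1
        p1 = p + dt * dp1
        db2 = r * b1 - p1 / tau
        dp2 = n * p1 / tau
        b += 0.5 * dt * (db1 + db2)
        p += 0.5 * dt * (dp1 + dp2)
        t += dt
        if b > best_b:
            best_b, best_t, best_p = b, t, p
    return best_t, best_b, best_p, p


def sampled_euler_latency(r, n, tau, b0, p0, times, dt=1e-6):
    """Euler trajectory of the latency model sampled at the given times."""
    out_b, out_p = [], []
    b, p = b0, p0
    t = 0.0
    for target in times:
        while t < target - dt / 2:
            db1 = r * b - p / tau
            dp1 = n * p / tau
            b1 = b + dt * db1
            p1 = p + dt * dp1
            b += 0.5 * dt * (db1 + (r * b1 - p1 / tau))
            p += 0.5 * dt * (dp1 + n * p1 / tau)
            t += dt
        out_b.append(b)
        out_p.append(p)
    return out_b, out_p
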