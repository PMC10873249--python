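"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's vectorized/analytic code paths:
fixed points come from sign-change bisection, branch following from
direct time integration, and the small-n Moran law from a scalar,
dictionary-based exhaustive expansion of the transition tree.
"""

from __future__ import annotations

import math

from scipy.integrate import solve_ivp


# --- bistable oracles -------------------------------------------------------

def bisect_roots(func, lo=-10.0, hi=10.0, grid=4000, tol=1e-12):
    """All roots of a scalar function found by sign-change bisection."""
    roots = []
    xs = [lo + (hi - lo) * i / grid for i in range(grid + 1)]
    for a, b in zip(xs, xs[1:]):
        fa, fb = func(a), func(b)
        if fa == 0.0:
            roots.append(a)
            continue
        if fa * fb < 0:
            while b - a > tol:
                m = 0.5 * (a + b)
                if func(a) * func(m) <= 0:
                    b = m
                else:
                    a = m
            roots.append(0.5 * (a + b))
    return roots


def integrate_to_steady_state(x0, lam_path, cubic, horizon=80.0):
    """Final state after integrating the ODE through each rate in turn."""
    x = x0
    for lam in lam_path:
        sol = solve_ivp(
            lambda _, y: lam + cubic(y[0]) - y[0],
            (0.0, horizon),
            [x],
            rtol=1e-10,
            atol=1e-12,
        )
        x = float(sol.y[0, -1])
    return x


# --- Moran small-n oracle ---------------------------------------------------

def moran_exhaustive(
    n, birth, death, m, survival_tol=1e-12, min_steps=400, max_steps=100000
):
    """Exhaustive transition-tree expansion of the transient Moran law.

    Scalar dictionary propagation over states ``(n_O, n_J, n_T)``.  One
    step removes a cell (death-weighted) and divides another cell drawn
    among the remaining ones; a daughter may mutate.  Absorbed mass is
    accumulated per outcome class with post-step counts and step index.

    Returns a dict with per-class mass and raw moments of count and time.
    """
    b_o, b_j, b_t = birth[0], birth[1], birth[2]
    d_o, d_j, d_t = death[0], death[1], death[2]
    m_oj, m_ot, m_jjt, m_ttj = m

    prob = {(n, 0, 0): 1.0}
    classes = {
        "J": dict(mass=0.0, c1=0.0, c2=0.0, t1=0.0, t2=0.0),
        "T": dict(mass=0.0, c1=0.0, c2=0.0, t1=0.0, t2=0.0),
        "amb": dict(mass=0.0, c1=0.0, c2=0.0, t1=0.0, t2=0.0),
    }
    step = 0
    survival = 1.0
    while survival >= survival_tol or step <= min_steps:
        if step >= max_steps:
            raise RuntimeError("oracle did not converge")
        step += 1
        new = {}
        for (o, j, t), p in prob.items():
            death_w = o * d_o + j * d_j + t * d_t
            for dead, w in (("O", o * d_o), ("J", j * d_j), ("T", t * d_t)):
                if w == 0.0:
                    continue
                p_death = p * w / death_w
                oo = o - (dead == "O")
                jj = j - (dead == "J")
                tt = t - (dead == "T")
                birth_w = oo * b_o + jj * b_j + tt * b_t
                outcomes = (
                    ("O", oo * b_o * (1 - m_oj - m_ot)),
                    ("J", oo * b_o * m_oj + jj * b_j * (1 - m_jjt)),
                    ("T", oo * b_o * m_ot + tt * b_t * (1 - m_ttj)),
                    ("JT", jj * b_j * m_jjt),
                    ("TJ", tt * b_t * m_ttj),
                )
                for born, bw in outcomes:
                    if bw == 0.0:
                        continue
                    q = p_death * bw / birth_w
                    if born == "O":
                        key = (oo + 1, jj, tt)
                    elif born == "J":
                        key = (oo, jj + 1, tt)
                    elif born == "T":
                        key = (oo, jj, tt + 1)
                    else:
                        # absorbing: a double mutant appeared
                        if born == "JT" and tt == 0:
                            cls, cnt = "J", jj
                        elif born == "TJ" and jj == 0:
                            cls, cnt = "T", tt
                        else:
                            cls, cnt = "amb", 0
                        acc = classes[cls]
                        acc["mass"] += q
                        acc["c1"] += q * cnt
                        acc["c2"] += q * cnt * cnt
                        acc["t1"] += q * step
                        acc["t2"] += q * step * step
                        continue
                    new[key] = new.get(key, 0.0) + q
        prob = new
        survival = sum(prob.values())

    result = {"survival": survival, "steps": step}
    for cls in ("J", "T"):
        acc = classes[cls]
        mass = acc["mass"]
        mean_c = acc["c1"] / mass
        mean_t = acc["t1"] / mass
        result[cls] = dict(
            mass=mass,
            mean_count=mean_c,
            sd_count=math.sqrt(max(acc["c2"] / mass - mean_c**2, 0.0)),
            mean_time=mean_t,
            sd_time=math.sqrt(max(acc["t2"] / mass - mean_t**2, 0.0)),
        )
    result["ambiguous"] = classes["amb"]["mass"]
    return result
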