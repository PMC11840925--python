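"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain loops / direct
integrations, sharing no code with the package implementation, so that
agreement is evidence rather than tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp


# ---------------------------------------------------------------------------
# exchange detector oracle: enumerate all pairs x all frame pairs


def oracle_detect(zs, ids, threshold, span, region):
    """Brute-force exchange detection on a (F, N) Z matrix.

    Returns a set of (ligand_a, ligand_b, i, j) tuples, a..b sorted.
    """
    F, N = zs.shape
    lo, hi = span
    nz = (zs - lo) / (hi - lo)
    out = set()
    for a in range(N):
        for b in range(a + 1, N):
            cands = []
            for i in range(F):
                for j in range(i + 1, F):
                    si = nz[i, a] - nz[i, b]
                    sj = nz[j, a] - nz[j, b]
                    if si * sj >= 0:
                        continue
                    if abs(sj - si) <= threshold:
                        continue
                    zm = (zs[i, a] + zs[i, b] + zs[j, a] + zs[j, b]) / 4.0
                    if not (region[0] <= zm <= region[1]):
                        continue
                    cands.append((j - i, i, j))
            cands.sort()
            accepted = []
            for _, i, j in cands:
                if any(not (j < ai or bj < i) for ai, bj in accepted):
                    continue
                accepted.append((i, j))
            for i, j in accepted:
                out.add((ids[a], ids[b], i, j))
    return out


# ---------------------------------------------------------------------------
# zone statistics oracles


def oracle_zone_index(z, zones):
    for k, (_, lo, hi) in enumerate(zones):
        if lo <= z < hi:
            return k
    raise AssertionError("zones do not cover the line")


def oracle_dwell_totals(zs, dt, zones):
    """Per-ligand, per-zone frame tally x frame interval."""
    F, N = zs.shape
    totals = np.zeros((N, len(zones)))
    for li in range(N):
        for f in range(F):
            totals[li, oracle_zone_index(zs[f, li], zones)] += dt
    return totals


def oracle_transits(zs, zones):
    """Count solution-to-solution traversals by scanning zone strings."""
    F, N = zs.shape
    ic, ec = 0, len(zones) - 1
    count = 0
    for li in range(N):
        seq = [oracle_zone_index(zs[f, li], zones) for f in range(F)]
        last_solution = None
        for zi in seq:
            if zi in (ic, ec):
                if last_solution is not None and zi != last_solution:
                    count += 1
                last_solution = zi
    return count


def oracle_pore_entries(zs, zones):
    F, N = zs.shape
    ic, ec = 0, len(zones) - 1
    count = 0
    for li in range(N):
        for f in range(F - 1):
            z0 = oracle_zone_index(zs[f, li], zones)
            z1 = oracle_zone_index(zs[f + 1, li], zones)
            if z0 in (ic, ec) and z1 not in (ic, ec):
                count += 1
    return count


# ---------------------------------------------------------------------------
# carrier oracles


def oracle_master_equation(rates, G_out, G_in, p0=None, t_end=None):
    """Stationary probabilities by long-time stiff ODE integration."""
    r = rates
    Q = np.zeros((4, 4))
    Q[0, 1] = r.a * G_out
    Q[1, 0] = r.b
    Q[1, 2] = r.c
    Q[2, 1] = r.d
    Q[2, 3] = r.e
    Q[3, 2] = r.f * G_in
    Q[0, 3] = r.g
    Q[3, 0] = r.h
    A = Q.T - np.diag(Q.sum(axis=1))
    if p0 is None:
        p0 = np.full(4, 0.25)
    if t_end is None:
        positive = Q[Q > 0]
        t_end = 200.0 / positive.min()
    sol = solve_ivp(lambda t, p: A @ p, (0, t_end), p0, method="Radau",
                    rtol=1e-12, atol=1e-14)
    p = sol.y[:, -1]
    return p / p.sum()


def oracle_tracer_fluxes_mc(rates, G_out, G_in, n_steps=300_000, seed=0):
    """Gillespie simulation of one carrier; counts labelled deliveries.

    A ligand bound from outside and released inside is one influx
    delivery (and vice versa for efflux).  Returns (influx, efflux,
    se_influx, se_efflux) in deliveries per unit time.
    """
    r = rates
    rng = np.random.default_rng(seed)
    # transitions: (from, to, rate); state order C_out, CG_out, CG_in, C_in
    trans = [
        (0, 1, r.a * G_out),
        (1, 0, r.b),
        (1, 2, r.c),
        (2, 1, r.d),
        (2, 3, r.e),
        (3, 2, r.f * G_in),
        (0, 3, r.g),
        (3, 0, r.h),
    ]
    by_state = {s: [(to, rate) for (fr, to, rate) in trans if fr == s and rate > 0]
                for s in range(4)}
    state, t = 0, 0.0
    origin = None  # side the currently bound ligand came from
    n_in = n_out = 0
    for _ in range(n_steps):
        moves = by_state[state]
        rates_here = np.array([m[1] for m in moves])
        total = rates_here.sum()
        t += rng.exponential(1.0 / total)
        nxt = moves[rng.choice(len(moves), p=rates_here / total)][0]
        if state == 0 and nxt == 1:
            origin = "out"
        elif state == 3 and nxt == 2:
            origin = "in"
        elif state == 2 and nxt == 3:
            if origin == "out":
                n_in += 1
            origin = None
        elif state == 1 and nxt == 0:
            if origin == "in":
                n_out += 1
            origin = None
        state = nxt
    return (
        n_in / t,
        n_out / t,
        np.sqrt(max(n_in, 1)) / t,
        np.sqrt(max(n_out, 1)) / t,
    )


def oracle_boltzmann_z(potential, edges):
    """Expected bin occupancy for a 1-D potential (kT = 1)."""
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = np.exp(-potential(centers))
    return w / w.sum()
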