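"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's sweep/closed-form code paths:
overlap counts are recomputed by direct pairwise enumeration over all edges,
and breakpoint-time integrals by adaptive numerical quadrature.
"""
from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import quad

from argsmc import ArgTables, simulate


# ---------------------------------------------------------------------------
# Hand-built fixtures
# ---------------------------------------------------------------------------

L_TWO = 100
T_COAL = 7.3


@pytest.fixture
def two_sample_arg() -> ArgTables:
    """Two samples coalescing at time T_COAL on a 100 bp genome."""
    return ArgTables.build([0.0, 0.0, T_COAL], [(2, 0, 0, L_TWO), (2, 1, 0, L_TWO)], L_TWO)


FOUR_EDGE = dict(L=100, x=40, tu=3.0, tv=8.0)


@pytest.fixture
def four_edge_arg() -> ArgTables:
    """Two samples, one recombination (recombination nodes already removed).

    Nodes a=0, b=1 at time 0; u=2 at tu; v=3 at tv.  Edges:
    (u,a,0,x), (u,b,0,L), (v,a,x,L), (v,u,x,L).  Node u is unary on [x, L).
    """
    p = FOUR_EDGE
    return ArgTables.build(
        [0.0, 0.0, p["tu"], p["tv"]],
        [(2, 0, 0, p["x"]), (2, 1, 0, p["L"]), (3, 0, p["x"], p["L"]), (3, 2, p["x"], p["L"])],
        p["L"],
    )


def four_edge_hand_loglik(r: float, lam: float) -> float:
    """Term-by-term hand assembly of the likelihood of the four-edge fixture."""
    L, x, tu, tv = FOUR_EDGE["L"], FOUR_EDGE["x"], FOUR_EDGE["tu"], FOUR_EDGE["tv"]
    return (
        np.log(r)
        + 2 * np.log(lam)
        - r * (x * tu + L * tu + (L - x - 1) * tv + (L - x) * (tv - tu))
        - lam * tu
        + np.log(np.exp(-lam * tu) * (np.exp((lam - r) * tu) - 1) / (lam - r))
        - lam * (tv - tu)
    )


def small_random_args(count: int, max_edges: int = 30, base_seed: int = 1000):
    """Small simulated ARGs (SMC and Hudson) with at most ``max_edges`` edges."""
    out = []
    seed = base_seed
    while len(out) < count:
        model = "smc" if seed % 2 else "hudson"
        arg, _ = simulate(
            n=3 + seed % 4,
            L=50 + 17 * (seed % 5),
            r=5e-4,
            demography=40.0,
            seed=seed,
            model=model,
        )
        if 0 < arg.num_edges <= max_edges:
            out.append(arg)
        seed += 1
    return out


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------


def brute_overlap_count(arg: ArgTables, e: int, t: float) -> int:
    """I_e(t) by direct enumeration over all earlier edges."""
    tc = arg.edge_child_time
    tp = arg.edge_parent_time
    key_e = (arg.edge_left[e], arg.edge_child[e])
    x = arg.edge_left[e]
    n = 0
    for f in range(arg.num_edges):
        if f == e:
            continue
        if (arg.edge_left[f], arg.edge_child[f]) >= key_e:
            continue
        if arg.edge_left[f] <= x < arg.edge_right[f] and tc[f] <= t < tp[f]:
            n += 1
    return n


def brute_hazard(arg: ArgTables, e: int, s: float, t: float) -> float:
    """F(e, s, t) by integrating the brute-force count over its breakpoints."""
    tc = arg.edge_child_time
    tp = arg.edge_parent_time
    pts = sorted(
        {s, t}
        | {float(v) for v in np.concatenate([tc, tp]) if s < v < t}
    )
    total = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        total += (b - a) * brute_overlap_count(arg, e, 0.5 * (a + b))
    return total


def quad_coal_term(arg: ArgTables, e: int, r: float, lam: float) -> float:
    """log B_e for a breakpoint-initiated edge by adaptive quadrature."""
    tc = float(arg.edge_child_time[e])
    tp = float(arg.edge_parent_time[e])
    neighbours = [
        float(arg.edge_parent_time[f])
        for f in range(arg.num_edges)
        if arg.edge_child[f] == arg.edge_child[e] and arg.edge_right[f] == arg.edge_left[e]
    ]
    upper = min([tp] + neighbours)

    def integrand(s):
        return np.exp(-r * s - lam * brute_hazard(arg, e, s, tp))

    breaks = sorted(
        {tc, upper}
        | {
            float(v)
            for v in np.concatenate([arg.edge_child_time, arg.edge_parent_time])
            if tc < v < upper
        }
    )
    val = 0.0
    for a, b in zip(breaks[:-1], breaks[1:]):
        val += quad(integrand, a, b, limit=200)[0]
    return np.log(val)
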