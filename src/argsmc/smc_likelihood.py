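"""Per-edge SMC log-likelihood of an ARG, plus the classical event-based comparator.

Under the backwards-time sequentially Markov coalescent (SMC) with
recombination rate ``r`` per bp per generation and pairwise coalescence rate
``lam = 1/(2 Ne)``, the likelihood of an ARG ``G = (N, E)`` factorises over
nodes and edges:

    L(G | r, lam) = r**(|E|-|N|+nr) * lam**(|E|-|N|+ns)
                    * prod_e A_e(r) * B_e(r, lam)

where ``nr`` and ``ns`` count root (in-degree 0) and leaf (out-degree 0)
nodes.  For an edge ``e = (p, c, x, y)`` with child time ``tc`` and parent
time ``tp``:

* ``A_e(r) = exp(-r * links * (tp - tc))`` is the probability that none of
  the edge's eligible links recombined over its lifetime, with ``links``
  equal to ``y - x`` when the edge is the leftmost edge above ``c`` and
  ``y - x - 1`` otherwise.
* ``B_e`` is the common-ancestry hazard term.  Writing ``I_e(t)`` for the
  number of *earlier* edges (in the total order by ``(left, child)``) whose
  genomic interval contains ``x`` and that are present at time ``t``, and
  ``F(e, s, t) = int_s^t I_e(z) dz``, the leftmost edge of a child
  contributes ``exp(-lam * F(e, tc, tp))``, and an edge initiated by a
  recombination breakpoint contributes the integral over the unknown
  breakpoint time, ``int_tc^{min(tp, tp')} exp(-r s) exp(-lam F(e, s, tp)) ds``,
  where ``tp'`` is the parent time of the genomically adjacent same-child
  edge ending at ``x``.

Everything is accumulated in log space; the breakpoint-time integral is
evaluated in closed form on each constant piece of ``I_e`` and combined with
log-sum-exp, so ARGs with many thousands of edges are handled without
underflow.  The computation never needs explicit recombination nodes: the
locally unary spans of coalescent nodes carry all required information.
"""
from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .arg_core import (
    NODE_CUT_NONLEFTMOST,
    ArgTables,
    ParameterError,
    StructuralError,
    node_degrees,
    validate_arg,
)

__all__ = [
    "OverlapProfile",
    "EdgeTerms",
    "LikelihoodResult",
    "PiecewiseLikelihoodResult",
    "LikelihoodEvaluator",
    "edge_order_key",
    "edge_total_order",
    "event_exponents",
    "recombination_initiated",
    "leftmost_flags",
    "eligible_links",
    "edge_area_logterm",
    "overlap_profiles",
    "hazard_integral",
    "edge_coal_logterm",
    "degree_log_factor",
    "arg_log_likelihood",
    "arg_log_likelihood_piecewise",
    "mutation_log_likelihood",
    "mutations_per_edge",
    "kyf_log_likelihood",
]


# ---------------------------------------------------------------------------
# Edge ordering, leftmost flags, eligible links
# ---------------------------------------------------------------------------


def edge_order_key(edge: Sequence[int]) -> tuple[int, int]:
    """Total-order key for an edge ``(parent, child, left, right)``: (left, child)."""
    parent, child, left, right = edge
    return (left, child)


def edge_total_order(arg: ArgTables) -> np.ndarray:
    """Permutation of edge rows sorted by the total order (left, then child)."""
    return np.lexsort((arg.edge_child, arg.edge_left))


def _raw_leftmost(arg: ArgTables) -> np.ndarray:
    """left == min left per child, ignoring virtual-node inheritance."""
    xc = np.full(arg.num_nodes, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(xc, arg.edge_child, arg.edge_left)
    return arg.edge_left == xc[arg.edge_child]


def recombination_initiated(arg: ArgTables) -> np.ndarray:
    """Per-edge flag: was this edge initiated by a recombination breakpoint?

    True for a non-leftmost edge with a genomically *adjacent* same-child
    edge ending exactly at its left coordinate.  A non-leftmost edge whose
    child has a gap just left of it (the child is a local root there — its
    material's local MRCA sits below) was not created by a recombination
    visible on this child and carries no ``r`` factor; its breakpoint-time
    integral degenerates to the plain survival term.  This keeps the number
    of recombinations implied by the ARG equal to the event count on
    event-complete inputs, including those with multi-segment ancestral
    material recorded as several same-child edges.
    """
    ends = set(zip(arg.edge_child.tolist(), arg.edge_right.tolist()))
    adjacent = np.fromiter(
        (
            (int(c), int(l)) in ends
            for c, l in zip(arg.edge_child, arg.edge_left)
        ),
        dtype=bool,
        count=arg.num_edges,
    )
    return ~_raw_leftmost(arg) & adjacent


def event_exponents(arg: ArgTables) -> tuple[int, int]:
    """Counts of (recombination, coalescence) events implied by the tables.

    Recombinations: edges initiated by an adjacent breakpoint.  Coalescences:
    for each node, its number of *distinct* children minus one (several
    edges to one child record one inheritance relationship over split
    genomic spans, not extra mergers).  On ARGs whose per-child edges tile a
    contiguous interval and with no duplicate (parent, child) pairs these
    equal the degree-based exponents ``|E| - |N| + nr`` and ``|E| - |N| + ns``.
    """
    n_re = int(np.sum(recombination_initiated(arg)))
    pairs = {(int(p), int(c)) for p, c in zip(arg.edge_parent, arg.edge_child)}
    n_parents = len({p for p, _ in pairs})
    n_ca = len(pairs) - n_parents
    return n_re, n_ca


def leftmost_flags(arg: ArgTables) -> np.ndarray:
    """Per-edge flag: is this the leftmost edge above its child?

    ``x_c`` is the minimum left coordinate over edges with child ``c``; the
    (unique) edge starting there is leftmost.  Edges whose child is a virtual
    slice node inherit the status of the edge they were cut from, recorded in
    the virtual node's flags.
    """
    left = arg.edge_left
    child = arg.edge_child
    xc = np.full(arg.num_nodes, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(xc, child, left)
    flags = left == xc[child]
    cut_nonleftmost = (arg.node_flags[child] & NODE_CUT_NONLEFTMOST) != 0
    return flags & ~cut_nonleftmost


def eligible_links(edge: Sequence[int], leftmost: bool) -> int:
    """Adjacent base-pair positions on which recombination could have occurred.

    ``y - x`` for the leftmost edge of a child, else ``y - x - 1`` (the link
    at the edge's own left breakpoint is excluded, since that is where the
    initiating recombination happened).
    """
    _, _, left, right = edge
    span = int(right) - int(left)
    return span if leftmost else span - 1


def edge_area_logterm(edge: Sequence[int], leftmost: bool, r: float, duration: float) -> float:
    """``log A_e(r) = -r * eligible_links * (tp - tc)``."""
    if r < 0:
        raise ParameterError(f"recombination rate must be non-negative, got {r}")
    if duration < 0:
        raise ParameterError("edge duration must be non-negative")
    return -r * eligible_links(edge, leftmost) * duration


# ---------------------------------------------------------------------------
# Overlap profiles and hazard integrals
# ---------------------------------------------------------------------------


@dataclass
class OverlapProfile:
    """Piecewise-constant count ``I_e(t)`` of earlier overlapping edges.

    ``breakpoints`` has ``m + 1`` increasing times from ``tc`` to ``tp``;
    ``counts[i]`` holds ``I_e`` on ``[breakpoints[i], breakpoints[i+1])``.
    """

    edge: int
    breakpoints: np.ndarray
    counts: np.ndarray

    @property
    def tc(self) -> float:
        return float(self.breakpoints[0])

    @property
    def tp(self) -> float:
        return float(self.breakpoints[-1])

    def integral(self, s: float | None = None, t: float | None = None) -> float:
        return hazard_integral(self, self.tc if s is None else s,
                               self.tp if t is None else t)


def hazard_integral(profile: OverlapProfile, s: float, t: float) -> float:
    """Exact ``F(e, s, t) = int_s^t I_e(z) dz`` for piecewise-constant ``I_e``."""
    if s > t:
        raise ParameterError(f"need s <= t, got s={s}, t={t}")
    if not (profile.tc <= s and t <= profile.tp):
        raise ParameterError("integration limits outside the edge's time support")
    lo = np.maximum(profile.breakpoints[:-1], s)
    hi = np.minimum(profile.breakpoints[1:], t)
    return float(np.sum(np.clip(hi - lo, 0.0, None) * profile.counts))


def _profile_from_intervals(edge, tc, tp, starts, ends) -> OverlapProfile:
    """Build the profile on [tc, tp) from the clipped time intervals of
    earlier overlapping edges."""
    if tp <= tc:
        return OverlapProfile(
            edge=edge,
            breakpoints=np.array([tc, tp]),
            counts=np.zeros(1, dtype=np.int64),
        )
    pts = np.unique(np.concatenate([[tc, tp], starts, ends]))
    delta = np.zeros(len(pts), dtype=np.int64)
    np.add.at(delta, np.searchsorted(pts, starts), 1)
    np.add.at(delta, np.searchsorted(pts, ends), -1)
    counts = np.cumsum(delta)[:-1]
    return OverlapProfile(edge=edge, breakpoints=pts, counts=counts)


def _sweep_overlaps(arg: ArgTables):
    """Yield ``(edge_index, starts, ends)``: the time intervals (clipped to the
    focal edge's support) of earlier edges whose genomic interval contains the
    focal edge's left endpoint.

    A single left-to-right sweep over edge left endpoints maintains the set
    of edges covering the current position; edges are retired via a heap on
    their right coordinates, giving O(|E| log |E|) plus output size.
    """
    tc_all = arg.edge_child_time
    tp_all = arg.edge_parent_time
    order = edge_total_order(arg)
    heap: list[tuple[int, int]] = []
    active: set[int] = set()
    for e in order:
        x = arg.edge_left[e]
        while heap and heap[0][0] <= x:
            _, gone = heapq.heappop(heap)
            active.discard(gone)
        if active:
            idx = np.fromiter(active, np.int64, len(active))
            starts = np.maximum(tc_all[idx], tc_all[e])
            ends = np.minimum(tp_all[idx], tp_all[e])
            keep = starts < ends
            starts, ends = starts[keep], ends[keep]
        else:
            starts = ends = np.empty(0, dtype=np.float64)
        yield int(e), starts, ends
        active.add(int(e))
        heapq.heappush(heap, (int(arg.edge_right[e]), int(e)))


def overlap_profiles(arg: ArgTables) -> list[OverlapProfile]:
    """Per-edge ``I_e(t)`` profiles, in edge-table row order."""
    tc_all = arg.edge_child_time
    tp_all = arg.edge_parent_time
    profiles: list[OverlapProfile | None] = [None] * arg.num_edges
    for e, starts, ends in _sweep_overlaps(arg):
        profiles[e] = _profile_from_intervals(e, tc_all[e], tp_all[e], starts, ends)
    return profiles  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Closed-form breakpoint-time integral
# ---------------------------------------------------------------------------


def _log_integral_exp(g, a, d):
    """``log int_a^{a+d} exp(g s) ds`` for d > 0, stable across all g.

    Equal to ``g a + log d + f(g d)`` with ``f(x) = log((exp(x) - 1) / x)``;
    near ``x = 0`` (the r = lam*k degenerate case) the series
    ``f(x) = x/2 + x^2/24 + O(x^4)`` is used.
    """
    g = np.asarray(g, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    x = g * d
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        f_pos = x + np.log1p(-np.exp(-np.abs(x))) - np.log(np.abs(x))
        f_neg = np.log1p(-np.exp(-np.abs(x))) - np.log(np.abs(x))
    f_small = x / 2.0 + x * x / 24.0
    small = np.abs(x) < 1e-6
    f = np.where(small, f_small, np.where(x > 0, f_pos, f_neg))
    return g * a + np.log(d) + f


def edge_coal_logterm(
    profile: OverlapProfile,
    leftmost: bool,
    r: float,
    lam: float,
    tp_prime: float | None = None,
) -> float:
    """``log B_e(r, lam)`` for a single edge from its overlap profile.

    Leftmost edges contribute ``-lam * F(e, tc, tp)``.  A recombination-
    initiated edge integrates the breakpoint time ``s`` over
    ``[tc, min(tp, tp')]``; the integrand ``exp(-r s - lam F(e, s, tp))`` is
    exponential on each constant piece of ``I_e`` and is integrated exactly,
    with the pieces combined by log-sum-exp.  ``tp_prime=None`` means the
    left-neighbour edge is absent (e.g. the child is a local root just left
    of ``x``), leaving the breakpoint time unconstrained from the left.
    Zero-length edges have probability density zero: ``-inf``.
    """
    tc, tp = profile.tc, profile.tp
    if tp <= tc:
        return -np.inf
    if leftmost:
        return -lam * profile.integral()
    upper = tp if tp_prime is None else min(tp, tp_prime)
    if upper <= tc:
        return -np.inf
    pts = profile.breakpoints
    counts = profile.counts
    # cumulative integral of I_e from tc to each breakpoint
    cum = np.concatenate([[0.0], np.cumsum(np.diff(pts) * counts)])
    total = cum[-1]
    a = np.minimum(pts[:-1], upper)
    b = np.minimum(pts[1:], upper)
    keep = a < b
    a, b, k = a[keep], b[keep], counts[keep]
    # F(e, b_i, tp) = total - cumulative at b_i
    f_b = total - (cum[:-1][keep] + (b - pts[:-1][keep]) * k)
    terms = -lam * f_b - lam * k * b + _log_integral_exp(lam * k - r, a, b - a)
    m = np.max(terms)
    return float(m + np.log(np.sum(np.exp(terms - m))))


# ---------------------------------------------------------------------------
# Degree factor and full likelihood
# ---------------------------------------------------------------------------


def _xlogy(x: float, y: float) -> float:
    if x == 0:
        return 0.0
    return x * np.log(y) if y > 0 else -np.inf


def degree_log_factor(arg: ArgTables, r: float, lam: float):
    """Node-degree factor of the likelihood.

    Every node with ``k`` children implies ``k - 1`` binary mergers (a factor
    ``lam**(k-1)``, polytomies being treated as unresolved zero-length-edge
    merger chains) and every node with ``k`` parents implies ``k - 1``
    ancestral recombinations (a factor ``r**(k-1)``).  Summing over nodes
    gives exponents ``|E| - |N| + nr`` for ``r`` and ``|E| - |N| + ns`` for
    ``lam``.  Returns ``(r_exponent, lambda_exponent, log value)``.
    """
    deg = node_degrees(arg)
    n, e = arg.num_nodes, arg.num_edges
    r_exp = e - n + deg.nr
    lam_exp = e - n + deg.ns
    if (r == 0 and r_exp > 0) or (lam == 0 and lam_exp > 0):
        warnings.warn("zero rate with a positive exponent: likelihood is zero")
    value = _xlogy(r_exp, r) + _xlogy(lam_exp, lam)
    return r_exp, lam_exp, value


@dataclass
class EdgeTerms:
    """Per-edge likelihood breakdown."""

    edge: int
    leftmost: bool
    eligible_links: int
    log_A: float
    log_B: float
    tp_prime: float | None = None


@dataclass
class LikelihoodResult:
    log_likelihood: float
    r_exponent: int
    lambda_exponent: int
    r: float
    lam: float
    edge_terms: list[EdgeTerms] | None = None


@dataclass
class PiecewiseLikelihoodResult:
    """Per-slice likelihoods under a piecewise-constant demography.

    ``total`` approximates the whole-ARG log-likelihood: the breakpoint-time
    integrals of edges cut at slice boundaries are confined to the slice
    containing the child, so the product over slices is exact only when no
    such integral's domain crosses a boundary.
    """

    per_slice: list[LikelihoodResult]
    total: float
    breakpoints: tuple[float, ...]
    lambdas: tuple[float, ...]


class LikelihoodEvaluator:
    """Precomputed per-edge structure allowing fast evaluation over (r, lam) grids.

    The genomic sweep (overlap profiles, leftmost flags, neighbour lookups)
    is done once at construction; each call to :meth:`log_likelihood` is then
    a vectorised pass over the stored piece decomposition.
    """

    def __init__(self, arg: ArgTables, validate: bool = True):
        if validate:
            violations = validate_arg(arg, allow_zero_length_edges=True)
            if violations:
                from .arg_core import ArgValidationError

                raise ArgValidationError("; ".join(violations))
        self.arg = arg
        self.r_exponent, self.lambda_exponent = event_exponents(arg)
        self.re_initiated = recombination_initiated(arg)
        self.leftmost = leftmost_flags(arg)
        span = arg.edge_right - arg.edge_left
        self.links = np.where(self.leftmost, span, span - 1)
        tc = arg.edge_child_time
        tp = arg.edge_parent_time
        self.duration = tp - tc
        self.zero_length = self.duration <= 0
        self.total_area = float(np.sum(self.links * np.where(self.zero_length, 0.0, self.duration)))

        # B-term classification.  Only breakpoint-initiated edges integrate
        # over the unknown recombination time; leftmost edges, edges behind a
        # genomic gap, and pass-through continuations above a virtual slice
        # node all contribute a plain survival exponential.
        child_virtual = arg.is_virtual[arg.edge_child]
        self.integral_type = self.re_initiated & (~child_virtual) & (~self.zero_length)
        # tp' lookup: same-child edge whose right coordinate equals our left.
        neighbour_tp = {}
        for i in range(arg.num_edges):
            neighbour_tp[(int(arg.edge_child[i]), int(arg.edge_right[i]))] = tp[i]
        self.tp_prime = np.full(arg.num_edges, np.inf)
        for i in np.flatnonzero(self.integral_type):
            self.tp_prime[i] = neighbour_tp.get(
                (int(arg.edge_child[i]), int(arg.edge_left[i])), np.inf
            )

        # One sweep builds: F_total per edge, and the piece decomposition
        # (a, b, k, F(e, b, tp)) for integral-type edges, truncated at
        # U = min(tp, tp').
        f_total = np.zeros(arg.num_edges)
        piece_edge: list[int] = []
        piece_a: list[np.ndarray] = []
        piece_b: list[np.ndarray] = []
        piece_k: list[np.ndarray] = []
        piece_fb: list[np.ndarray] = []
        self.empty_integral = np.zeros(arg.num_edges, dtype=bool)
        for e, starts, ends in _sweep_overlaps(arg):
            f_total[e] = float(np.sum(ends - starts))
            if not self.integral_type[e]:
                continue
            upper = min(tp[e], self.tp_prime[e])
            if upper <= tc[e]:
                self.empty_integral[e] = True
                continue
            prof = _profile_from_intervals(e, tc[e], tp[e], starts, ends)
            pts, counts = prof.breakpoints, prof.counts
            cum = np.concatenate([[0.0], np.cumsum(np.diff(pts) * counts)])
            a = np.minimum(pts[:-1], upper)
            b = np.minimum(pts[1:], upper)
            keep = a < b
            a, b, k = a[keep], b[keep], counts[keep].astype(np.float64)
            fb = f_total[e] - (cum[:-1][keep] + (b - pts[:-1][keep]) * k)
            piece_edge.append(e)
            piece_a.append(a)
            piece_b.append(b)
            piece_k.append(k)
            piece_fb.append(fb)
        self.f_total = f_total
        self.exp_type = (~self.integral_type) & (~self.zero_length)
        if piece_edge:
            lengths = np.array([len(a) for a in piece_a])
            self._group_edges = np.array(piece_edge, dtype=np.int64)
            self._group_starts = np.concatenate([[0], np.cumsum(lengths)])
            self._pa = np.concatenate(piece_a)
            self._pb = np.concatenate(piece_b)
            self._pk = np.concatenate(piece_k)
            self._pfb = np.concatenate(piece_fb)
        else:
            self._group_edges = np.empty(0, dtype=np.int64)
            self._group_starts = np.zeros(1, dtype=np.int64)
            self._pa = self._pb = self._pk = self._pfb = np.empty(0)

    # -- evaluation ---------------------------------------------------------

    def _log_b_integrals(self, r: float, lam: float) -> np.ndarray:
        """log B_e for the integral-type edges, aligned with self._group_edges."""
        if len(self._pa) == 0:
            return np.empty(0)
        terms = (
            -lam * self._pfb
            - lam * self._pk * self._pb
            + _log_integral_exp(lam * self._pk - r, self._pa, self._pb - self._pa)
        )
        starts = self._group_starts[:-1]
        m = np.maximum.reduceat(terms, starts)
        widths = np.diff(self._group_starts)
        shifted = np.exp(terms - np.repeat(m, widths))
        return m + np.log(np.add.reduceat(shifted, starts))

    def log_likelihood(
        self,
        r: float,
        Ne: float | None = None,
        *,
        lam: float | None = None,
        per_edge: bool = False,
    ) -> LikelihoodResult:
        if (lam is None) == (Ne is None):
            raise ParameterError("pass exactly one of Ne or lam")
        if lam is None:
            if Ne <= 0:
                raise ParameterError(f"Ne must be positive, got {Ne}")
            lam = 1.0 / (2.0 * Ne)
        if r < 0 or lam < 0:
            raise ParameterError("rates must be non-negative")
        value = _xlogy(self.r_exponent, r) + _xlogy(self.lambda_exponent, lam)
        log_a = -r * np.where(self.zero_length, 0.0, self.links * self.duration)
        log_b = np.full(self.arg.num_edges, -np.inf)
        log_b[self.exp_type] = -lam * self.f_total[self.exp_type]
        if len(self._group_edges):
            log_b[self._group_edges] = self._log_b_integrals(r, lam)
        degenerate = bool(np.any(self.zero_length) or np.any(self.empty_integral))
        total = -np.inf if degenerate else float(value + np.sum(log_a) + np.sum(log_b))
        terms = None
        if per_edge:
            terms = [
                EdgeTerms(
                    edge=i,
                    leftmost=bool(self.leftmost[i]),
                    eligible_links=int(self.links[i]),
                    log_A=float(log_a[i]),
                    log_B=float(log_b[i]),
                    tp_prime=(
                        float(self.tp_prime[i]) if self.integral_type[i] else None
                    ),
                )
                for i in range(self.arg.num_edges)
            ]
        return LikelihoodResult(
            log_likelihood=total,
            r_exponent=self.r_exponent,
            lambda_exponent=self.lambda_exponent,
            r=float(r),
            lam=float(lam),
            edge_terms=terms,
        )


def arg_log_likelihood(
    arg: ArgTables,
    r: float,
    Ne: float | None = None,
    *,
    lam: float | None = None,
    per_edge: bool = False,
    validate: bool = True,
) -> LikelihoodResult:
    """SMC log-likelihood of an ARG; ``-inf`` iff some edge has zero length."""
    return LikelihoodEvaluator(arg, validate=validate).log_likelihood(
        r, Ne, lam=lam, per_edge=per_edge
    )


def arg_log_likelihood_piecewise(
    arg: ArgTables,
    r: float,
    demography,
    spec=None,
    per_edge: bool = False,
) -> PiecewiseLikelihoodResult:
    """Approximate log-likelihood under piecewise-constant Ne via time slicing.

    The ARG is cut at the demography change times; each slice is evaluated
    with its own constant coalescence rate and the per-slice values are
    summed.  This factorisation is exact except for breakpoint-time
    integrals whose domain crosses a slice boundary.
    """
    from .arg_core import SliceSpec, time_slice, validate_demography

    validate_demography(demography)
    breaks = tuple(p.end_time for p in demography[:-1])
    if spec is not None and tuple(spec.breakpoints) != breaks:
        raise ParameterError(
            f"slice breakpoints {spec.breakpoints} do not match "
            f"demography change times {breaks}"
        )
    lambdas = tuple(p.lam for p in demography)
    if not breaks:
        res = arg_log_likelihood(arg, r, lam=lambdas[0], per_edge=per_edge)
        return PiecewiseLikelihoodResult([res], res.log_likelihood, (), lambdas)
    slices = time_slice(arg, SliceSpec(breaks))
    per_slice = [
        arg_log_likelihood(s, r, lam=lam, per_edge=per_edge)
        for s, lam in zip(slices, lambdas)
    ]
    total = float(sum(x.log_likelihood for x in per_slice))
    return PiecewiseLikelihoodResult(per_slice, total, breaks, lambdas)


# ---------------------------------------------------------------------------
# Infinite-sites mutation likelihood
# ---------------------------------------------------------------------------


def mutations_per_edge(arg: ArgTables) -> np.ndarray:
    """Count the table's mutations per edge row (keyed by child + position)."""
    counts = np.zeros(arg.num_edges, dtype=np.int64)
    by_child: dict[int, list[int]] = {}
    for i in range(arg.num_edges):
        by_child.setdefault(int(arg.edge_child[i]), []).append(i)
    for c, pos in zip(arg.mut_child, arg.mut_position):
        hit = [
            i
            for i in by_child.get(int(c), ())
            if arg.edge_left[i] <= pos < arg.edge_right[i]
        ]
        if not hit:
            raise StructuralError(
                f"mutation at position {pos} above node {c} matches no edge"
            )
        counts[hit[0]] += 1
    return counts


def mutation_log_likelihood(
    arg: ArgTables, mutations: np.ndarray | None = None, mu: float = 0.0
) -> float:
    """Infinite-sites Poisson log-likelihood, decomposed per edge.

    Each edge carries ``m_e ~ Poisson(mu * a_e)`` mutations with
    ``a_e = (y - x) (tp - tc)`` in bp * generations; the total is
    ``sum_e m_e log(mu a_e) - mu a_e - log(m_e!)``.
    """
    if mu < 0:
        raise ParameterError(f"mutation rate must be non-negative, got {mu}")
    m = mutations_per_edge(arg) if mutations is None else np.asarray(mutations)
    if len(m) != arg.num_edges:
        raise StructuralError(
            f"need one count per edge ({arg.num_edges}), got {len(m)}"
        )
    area = (arg.edge_right - arg.edge_left) * (
        arg.edge_parent_time - arg.edge_child_time
    )
    rate = mu * area
    with np.errstate(divide="ignore", invalid="ignore"):
        log_rate = np.where(m > 0, np.log(rate, where=rate > 0,
                                          out=np.full(len(m), -np.inf)), 0.0)
    return float(np.sum(m * log_rate - rate - gammaln(m + 1)))


# ---------------------------------------------------------------------------
# Classical event-based (KYF-style) comparator for full ARGs
# ---------------------------------------------------------------------------


def kyf_log_likelihood(arg: ArgTables, r: float, Ne: float) -> float:
    """Event-decomposed full-ARG likelihood under the coalescent with recombination.

    Requires an event-complete ARG: every node's lineage must end at a single
    dated event, i.e. all parent edges of a node share one parent time (the
    two-recombination-node convention satisfies this).  Each of the ``#CA``
    coalescences contributes ``log lam`` and each of the ``#RE``
    recombinations ``log r``; the waiting times contribute the total hazard
    ``-int r B(t) + lam k(t)(k(t)-1)/2 dt`` with ``k(t)`` the number of
    extant lineages and ``B(t)`` the total eligible links of the edges
    present at ``t`` (the same link convention as ``A_e``, so the
    r-dependence matches the per-edge likelihood exactly; the lineage-pair
    counting is all-pairs rather than overlapping-pairs).
    """
    if Ne <= 0:
        raise ParameterError(f"Ne must be positive, got {Ne}")
    lam = 1.0 / (2.0 * Ne)
    tp = arg.edge_parent_time
    tc = arg.edge_child_time
    # Lineage lifespans: [node time, time of the node's parent event).
    end_time = np.full(arg.num_nodes, np.nan)
    for i in range(arg.num_edges):
        c = arg.edge_child[i]
        if np.isnan(end_time[c]):
            end_time[c] = tp[i]
        elif end_time[c] != tp[i]:
            raise StructuralError(
                f"node {c} has parent edges at different times "
                f"({end_time[c]} vs {tp[i]}): not an event-complete ARG"
            )
    n_re, n_ca = event_exponents(arg)
    # Recombination hazard: same per-edge accounting as the A_e terms.
    lm = leftmost_flags(arg)
    span = arg.edge_right - arg.edge_left
    links = np.where(lm, span, span - 1)
    hazard_re = r * float(np.sum(links * (tp - tc)))
    # Coalescence hazard: integral of k(k-1)/2 over lineage counts.
    has_parent = ~np.isnan(end_time)
    starts = arg.node_time[has_parent]
    ends = end_time[has_parent]
    times = np.unique(np.concatenate([starts, ends]))
    k = np.zeros(len(times), dtype=np.int64)
    np.add.at(k, np.searchsorted(times, starts), 1)
    np.add.at(k, np.searchsorted(times, ends), -1)
    k = np.cumsum(k)[:-1]
    hazard_ca = lam * float(np.sum(np.diff(times) * k * (k - 1) / 2.0))
    return _xlogy(n_re, r) + _xlogy(n_ca, lam) - hazard_re - hazard_ca
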