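"""Backwards-in-time simulation of the SMC (and a minimal Hudson mode).

The state is a set of lineages, each carrying the genomic segments of its
ancestral material.  Two competing exponential clocks drive the process
backwards in time:

* recombination at total rate ``r * B(t)`` where ``B(t)`` sums each
  lineage's splittable links (integer positions strictly inside its
  segments); a recombination splits one lineage in two at a uniformly chosen
  link, leaving the total ancestral material unchanged;
* coalescence at rate ``lam(t)`` per *coalescible pair*.  In SMC mode
  lineages are strictly ordered by ``(left endpoint, label)`` and lineage
  ``k`` can coalesce into a later lineage ``j`` iff ``j``'s left endpoint
  falls inside ``k``'s interval; the number of coalescible pairs is then the
  number of overlapping pairs.  Hudson mode uses all ``k (k - 1) / 2``
  pairs.

Every event is recorded in the emitted ARG with full detail: two
recombination nodes per recombination (distinct left and right parents at
the same time, flagged ``NODE_IS_RE_EVENT``) and one node per coalescence,
whose locally unary spans are retained.  On coalescence, material for which
the merged lineage is the only remaining carrier has reached its local MRCA
and is dropped from further tracking (so a lineage can occasionally carry
more than one segment); the run ends when no coalescible pair remains.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .arg_core import (
    NODE_IS_RE_EVENT,
    NODE_IS_SAMPLE,
    ArgTables,
    DemographyPiece,
    ParameterError,
    piecewise_demography,
    validate_demography,
)

__all__ = [
    "Lineage",
    "SimEvent",
    "coalescible_pairs",
    "simulate",
    "event_counts",
]


@dataclass
class Lineage:
    """An extant ancestral lineage: a label, a head node, and its material."""

    label: int
    head: int
    segments: list[tuple[int, int]]  # ordered, disjoint half-open intervals

    @property
    def left(self) -> int:
        return self.segments[0][0]

    @property
    def right(self) -> int:
        return self.segments[-1][1]

    @property
    def material(self) -> int:
        return sum(r - l for l, r in self.segments)

    @property
    def links(self) -> int:
        return sum(r - l - 1 for l, r in self.segments)


@dataclass
class SimEvent:
    """One recombination (RE) or common-ancestor (CA) event."""

    time: float
    kind: str  # "RE" or "CA"
    child_heads: tuple[int, ...]
    new_nodes: tuple[int, ...]
    breakpoint: int | None
    total_material: int
    # lineage snapshot after the event, when requested: (label, left, right)
    lineages_after: list[tuple[int, int, int]] | None = None


def coalescible_pairs(lineages: Sequence[Lineage | tuple[int, int, int]]):
    """Coalescible-pair count and the per-lineage sets under the SMC order.

    Returns ``(total, c)`` where ``c[j]`` is the set of labels that can
    coalesce *into* lineage ``j``: the lineages earlier in the strict
    ``(left, label)`` order whose interval contains ``j``'s left endpoint.
    The sets are disjoint and ``total = sum(len(c[j]))``.
    """
    rows = [
        (lin.label, lin.left, lin.right) if isinstance(lin, Lineage) else tuple(lin)
        for lin in lineages
    ]
    rows.sort(key=lambda t: (t[1], t[0]))
    c: dict[int, set[int]] = {}
    for j, (lab_j, x_j, _) in enumerate(rows):
        c[lab_j] = {lab_k for lab_k, _, y_k in rows[:j] if y_k > x_j}
    total = sum(len(s) for s in c.values())
    return total, c


def event_counts(events: Sequence[SimEvent]) -> tuple[int, int]:
    """(number of recombination events, number of coalescence events)."""
    n_re = sum(1 for e in events if e.kind == "RE")
    n_ca = sum(1 for e in events if e.kind == "CA")
    return n_re, n_ca


def _as_demography(demography) -> list[DemographyPiece]:
    if isinstance(demography, (int, float)):
        return piecewise_demography([float(demography)])
    pieces = list(demography)
    validate_demography(pieces)
    return pieces


class _Recorder:
    def __init__(self, n: int):
        self.time = [0.0] * n
        self.flags = [NODE_IS_SAMPLE] * n
        self.edges: list[tuple[int, int, int, int]] = []

    def add_node(self, time: float, flags: int = 0) -> int:
        self.time.append(time)
        self.flags.append(flags)
        return len(self.time) - 1

    def add_edge(self, parent: int, child: int, left: int, right: int) -> None:
        self.edges.append((parent, child, left, right))

    def tables(self, sequence_length: int) -> ArgTables:
        return ArgTables.build(
            node_times=self.time,
            edges=self.edges,
            sequence_length=sequence_length,
            flags=self.flags,
        )


def _draw_waiting_time(rng, t, piece_index, pieces, rate_re, ca_pairs):
    """Next event time under a piecewise-constant coalescence rate."""
    while True:
        lam = pieces[piece_index].lam
        total = rate_re + lam * ca_pairs
        if total <= 0:
            raise RuntimeError("no events possible but the process has not finished")
        w = rng.exponential(1.0 / total)
        if t + w >= pieces[piece_index].end_time:
            t = pieces[piece_index].end_time
            piece_index += 1
            continue
        return t + w, piece_index, total


def _smc_pair_matrix(lineages: list[Lineage]):
    """Boolean matrix over the (left, label)-sorted order: entry [j, k] set iff
    the earlier lineage k can coalesce into j (k's interval contains j's left
    endpoint); plus the sorted order of list indices."""
    lefts = np.array([lin.left for lin in lineages], dtype=np.int64)
    rights = np.array([lin.right for lin in lineages], dtype=np.int64)
    labels = np.array([lin.label for lin in lineages], dtype=np.int64)
    order = np.lexsort((labels, lefts))
    l_o = lefts[order]
    r_o = rights[order]
    k = len(order)
    earlier = np.arange(k)[None, :] < np.arange(k)[:, None]
    m = earlier & (r_o[None, :] > l_o[:, None])
    return m, order


def _split_segments(segments, bp):
    left = [seg for seg in segments if seg[1] <= bp]
    right = [seg for seg in segments if seg[0] >= bp]
    for l, r in segments:
        if l < bp < r:
            left.append((l, bp))
            right.insert(0, (bp, r))
    left.sort()
    right.sort()
    return left, right


def _segments_from_mask(mask: np.ndarray, offset: int) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + offset
    ends = np.flatnonzero(diff == -1) + offset
    return list(zip(starts.tolist(), ends.tolist()))


def _simulate_core(n, L, r, pieces, rng, model, track_state):
    rec = _Recorder(n)
    lineages = [Lineage(label=i, head=i, segments=[(0, L)]) for i in range(n)]
    next_label = n
    events: list[SimEvent] = []
    # Extant carriers per position; when a merge leaves a sole carrier the
    # position has reached its local MRCA and is stripped from tracking.
    counts = np.full(L, n, dtype=np.int32)
    t = 0.0
    piece_index = 0

    def snapshot():
        if not track_state:
            return None
        return [(lin.label, lin.left, lin.right) for lin in lineages]

    while len(lineages) >= 2:
        if model == "smc":
            m, order = _smc_pair_matrix(lineages)
            ca_pairs = int(m.sum())
        else:
            k = len(lineages)
            ca_pairs = k * (k - 1) // 2
        if model == "smc" and ca_pairs == 0:
            break
        links = np.array([lin.links for lin in lineages], dtype=np.int64)
        rate_re = r * int(links.sum())
        while t >= pieces[piece_index].end_time:
            piece_index += 1
        t, piece_index, total_rate = _draw_waiting_time(
            rng, t, piece_index, pieces, rate_re, ca_pairs
        )
        if rng.random() < rate_re / total_rate:
            # recombination: lineage by its links, then a uniform splittable link
            i = rng.choice(len(lineages), p=links / links.sum())
            lin = lineages.pop(i)
            seg_links = np.array([sr - sl - 1 for sl, sr in lin.segments])
            s = rng.choice(len(lin.segments), p=seg_links / seg_links.sum())
            sl, sr = lin.segments[s]
            bp = int(rng.integers(sl + 1, sr))
            left_segs, right_segs = _split_segments(lin.segments, bp)
            left_parent = rec.add_node(t, NODE_IS_RE_EVENT)
            right_parent = rec.add_node(t, NODE_IS_RE_EVENT)
            for l, rr in left_segs:
                rec.add_edge(left_parent, lin.head, l, rr)
            for l, rr in right_segs:
                rec.add_edge(right_parent, lin.head, l, rr)
            lineages.append(Lineage(next_label, left_parent, left_segs))
            lineages.append(Lineage(next_label + 1, right_parent, right_segs))
            next_label += 2
            events.append(
                SimEvent(
                    time=t,
                    kind="RE",
                    child_heads=(lin.head,),
                    new_nodes=(left_parent, right_parent),
                    breakpoint=bp,
                    total_material=sum(x.material for x in lineages),
                    lineages_after=snapshot(),
                )
            )
        else:
            if model == "smc":
                flat = np.flatnonzero(m.ravel())
                pick = flat[rng.integers(len(flat))]
                jo, ko = divmod(int(pick), len(order))
                lin_i, lin_j = lineages[order[jo]], lineages[order[ko]]
            else:
                i, j = rng.choice(len(lineages), size=2, replace=False)
                lin_i, lin_j = lineages[int(i)], lineages[int(j)]
            lineages = [
                lin for lin in lineages if lin.label not in (lin_i.label, lin_j.label)
            ]
            u = rec.add_node(t)
            for l, rr in lin_i.segments:
                rec.add_edge(u, lin_i.head, l, rr)
            for l, rr in lin_j.segments:
                rec.add_edge(u, lin_j.head, l, rr)
            # merge material, drop spans whose local MRCA is now reached
            a = min(lin_i.left, lin_j.left)
            b = max(lin_i.right, lin_j.right)
            mask_i = np.zeros(b - a, dtype=bool)
            for l, rr in lin_i.segments:
                mask_i[l - a : rr - a] = True
            mask_j = np.zeros(b - a, dtype=bool)
            for l, rr in lin_j.segments:
                mask_j[l - a : rr - a] = True
            window = counts[a:b]
            window[mask_i & mask_j] -= 1
            union = mask_i | mask_j
            window[union & (window == 1)] = 0  # local MRCA reached: strip
            keep = union & (window >= 2)
            segs = _segments_from_mask(keep, a)
            if segs:
                lineages.append(Lineage(next_label, u, segs))
                next_label += 1
            events.append(
                SimEvent(
                    time=t,
                    kind="CA",
                    child_heads=(lin_i.head, lin_j.head),
                    new_nodes=(u,),
                    breakpoint=None,
                    total_material=sum(x.material for x in lineages),
                    lineages_after=snapshot(),
                )
            )
    return rec.tables(L), events


def simulate(
    n: int,
    L: int,
    r: float,
    demography,
    seed: int,
    model: str = "smc",
    mu: float | None = None,
    track_state: bool = False,
) -> tuple[ArgTables, list[SimEvent]]:
    """Simulate an ARG for ``n`` haploid samples on an ``L`` bp genome.

    ``demography`` is a diploid ``Ne`` or a list of
    :class:`~argsmc.arg_core.DemographyPiece` tiling ``[0, inf)``.  ``model``
    is ``"smc"`` (coalescence restricted to overlapping pairs under the
    strict lineage order) or ``"hudson"`` (all-pairs coalescence).  With
    ``mu`` set, infinite-sites mutations are dropped on each edge as
    Poisson(``mu`` * span * duration).  ``track_state=True`` stores a
    lineage snapshot in every event record.  Deterministic given ``seed``.
    """
    if n < 2:
        raise ParameterError("need at least two samples")
    if L < 1:
        raise ParameterError("sequence length must be >= 1 bp")
    if r < 0:
        raise ParameterError("recombination rate must be non-negative")
    if model not in ("smc", "hudson"):
        raise ParameterError(f"unknown model {model!r} (expected 'smc' or 'hudson')")
    pieces = _as_demography(demography)
    rng = np.random.default_rng(seed)
    arg, events = _simulate_core(n, L, r, pieces, rng, model, track_state)
    if mu is not None and mu > 0:
        span = arg.edge_right - arg.edge_left
        duration = arg.edge_parent_time - arg.edge_child_time
        m = rng.poisson(mu * span * duration)
        child, pos = [], []
        for i in np.flatnonzero(m):
            for p in rng.integers(arg.edge_left[i], arg.edge_right[i], size=m[i]):
                child.append(int(arg.edge_child[i]))
                pos.append(int(p))
        arg.mut_child = np.asarray(child, dtype=np.int64)
        arg.mut_position = np.asarray(pos, dtype=np.int64)
    return arg, events
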