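"""ARG data model: node/edge tables, validation, I/O and structural transforms.

An ancestral recombination graph (ARG) is stored as a pair of tables: a node
table (one row per haploid genome, with a time in generations before present)
and an edge table of inheritance statements ``(parent, child, left, right)``
meaning the child inherited the half-open genomic interval ``[left, right)``
from the parent.  Genomic coordinates are 0-based integers, time is
continuous and increases into the past, and samples sit at time 0.

The transforms in this module (recombination-node removal, full
simplification, random internal-node deletion, time slicing, edge squashing)
produce new :class:`ArgTables` instances and never mutate their input.
"""
from __future__ import annotations

import json
import pathlib
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tskit

__all__ = [
    "NODE_IS_SAMPLE",
    "NODE_IS_RE_EVENT",
    "NODE_IS_CA_EVENT",
    "NODE_IS_VIRTUAL",
    "NODE_CUT_NONLEFTMOST",
    "ArgTables",
    "SliceSpec",
    "DemographyPiece",
    "ArgValidationError",
    "StructuralError",
    "ParameterError",
    "piecewise_demography",
    "validate_arg",
    "assert_valid",
    "node_degrees",
    "DegreeSummary",
    "load_arg",
    "save_arg",
    "remove_recombination_nodes",
    "fully_simplify",
    "drop_internal_nodes",
    "time_slice",
    "squash_edges",
    "local_tree_count",
]

# Node flag bits.  The sample / recombination-event / common-ancestor-event
# bits follow the tskit / msprime conventions so that full ARGs written by
# msprime's record_full_arg round-trip with their flags intact.
NODE_IS_SAMPLE = 1
NODE_IS_RE_EVENT = 1 << 17
NODE_IS_CA_EVENT = 1 << 18
# A pass-through node introduced by time_slice at a slice boundary.
NODE_IS_VIRTUAL = 1 << 20
# Virtual node created by cutting an edge that was *not* the leftmost edge of
# its child; the sub-edges above it keep the y-x-1 eligible-link convention.
NODE_CUT_NONLEFTMOST = 1 << 21


class ArgValidationError(ValueError):
    """The node/edge tables violate a structural invariant."""


class StructuralError(ValueError):
    """The tables are valid but lack structure an operation requires."""


class ParameterError(ValueError):
    """A model parameter is out of its allowed range."""


@dataclass(frozen=True)
class DemographyPiece:
    """A piecewise-constant population-size epoch ``[start_time, end_time)``.

    ``Ne`` is the diploid effective size; the pairwise coalescence rate on
    the piece is ``lam = 1 / (2 Ne)`` per generation.
    """

    start_time: float
    end_time: float
    Ne: float

    def __post_init__(self):
        if not (self.start_time >= 0 and self.end_time > self.start_time):
            raise ParameterError(
                f"invalid epoch [{self.start_time}, {self.end_time})"
            )
        if not self.Ne > 0:
            raise ParameterError(f"Ne must be positive, got {self.Ne}")

    @property
    def lam(self) -> float:
        return 1.0 / (2.0 * self.Ne)


def piecewise_demography(
    ne_values: Sequence[float], breakpoints: Sequence[float] = ()
) -> list[DemographyPiece]:
    """Build a demography tiling ``[0, inf)`` from sizes and change times."""
    breakpoints = list(breakpoints)
    if len(ne_values) != len(breakpoints) + 1:
        raise ParameterError(
            "need exactly one more Ne value than breakpoints "
            f"(got {len(ne_values)} sizes, {len(breakpoints)} breakpoints)"
        )
    bounds = [0.0, *breakpoints, np.inf]
    if not all(a < b for a, b in zip(bounds, bounds[1:])):
        raise ParameterError("breakpoints must be strictly increasing and > 0")
    return [
        DemographyPiece(bounds[i], bounds[i + 1], ne)
        for i, ne in enumerate(ne_values)
    ]


def validate_demography(pieces: Sequence[DemographyPiece]) -> None:
    if not pieces:
        raise ParameterError("demography must contain at least one piece")
    if pieces[0].start_time != 0:
        raise ParameterError("demography must start at time 0")
    if not np.isinf(pieces[-1].end_time):
        raise ParameterError("final demography piece must extend to +inf")
    for a, b in zip(pieces, pieces[1:]):
        if a.end_time != b.start_time:
            raise ParameterError(
                f"demography pieces must tile [0, inf): gap/overlap at "
                f"{a.end_time} vs {b.start_time}"
            )


@dataclass(frozen=True)
class SliceSpec:
    """Strictly increasing time breakpoints, implicitly bounded by 0 and inf."""

    breakpoints: tuple[float, ...]

    def __init__(self, breakpoints: Iterable[float]):
        bps = tuple(float(b) for b in breakpoints)
        if any(not np.isfinite(b) or b <= 0 for b in bps):
            raise ParameterError("slice breakpoints must be finite and > 0")
        if any(a >= b for a, b in zip(bps, bps[1:])):
            raise ParameterError("slice breakpoints must be strictly increasing")
        object.__setattr__(self, "breakpoints", bps)

    @property
    def bounds(self) -> list[tuple[float, float]]:
        edges = [0.0, *self.breakpoints, np.inf]
        return list(zip(edges[:-1], edges[1:]))


def _as_array(x, dtype):
    a = np.asarray(x, dtype=dtype)
    return np.atleast_1d(a) if a.ndim else a.reshape(0)


@dataclass
class ArgTables:
    """Node and edge tables plus the genome length, the universal ARG container.

    Node ``i``'s attributes live at index ``i`` of the node arrays; ids are
    therefore contiguous by construction.  Mutations are optional and are
    keyed by ``(child node, position)`` following the infinite-sites model:
    the mutation sits on the edge above ``mut_child`` covering ``mut_position``.
    """

    node_time: np.ndarray
    node_flags: np.ndarray
    edge_parent: np.ndarray
    edge_child: np.ndarray
    edge_left: np.ndarray
    edge_right: np.ndarray
    sequence_length: int
    mut_child: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    mut_position: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    # For sliced tables: original node id per node (-1 for virtual nodes).
    node_orig: np.ndarray | None = None

    def __post_init__(self):
        self.node_time = np.asarray(self.node_time, dtype=np.float64).ravel()
        self.node_flags = np.asarray(self.node_flags, dtype=np.uint32).ravel()
        self.edge_parent = np.asarray(self.edge_parent, dtype=np.int64).ravel()
        self.edge_child = np.asarray(self.edge_child, dtype=np.int64).ravel()
        self.edge_left = np.asarray(self.edge_left, dtype=np.int64).ravel()
        self.edge_right = np.asarray(self.edge_right, dtype=np.int64).ravel()
        self.mut_child = np.asarray(self.mut_child, dtype=np.int64).ravel()
        self.mut_position = np.asarray(self.mut_position, dtype=np.int64).ravel()
        self.sequence_length = int(self.sequence_length)

    # -- constructors -----------------------------------------------------

    @classmethod
    def build(
        cls,
        node_times: Sequence[float],
        edges: Sequence[tuple[int, int, int, int]],
        sequence_length: int,
        samples: Sequence[int] | None = None,
        flags: Sequence[int] | None = None,
        mutations: Sequence[tuple[int, int]] = (),
    ) -> "ArgTables":
        """Convenience constructor from plain records.

        ``edges`` are ``(parent, child, left, right)`` tuples.  If neither
        ``samples`` nor ``flags`` is given, nodes at time 0 are samples.
        """
        times = np.asarray(node_times, dtype=np.float64)
        if flags is not None:
            fl = np.asarray(flags, dtype=np.uint32)
        else:
            fl = np.zeros(len(times), dtype=np.uint32)
            sample_ids = (
                np.flatnonzero(times == 0) if samples is None else np.asarray(samples)
            )
            fl[sample_ids] |= NODE_IS_SAMPLE
        e = np.asarray(list(edges), dtype=np.int64).reshape(-1, 4)
        m = np.asarray(list(mutations), dtype=np.int64).reshape(-1, 2)
        return cls(
            node_time=times,
            node_flags=fl,
            edge_parent=e[:, 0],
            edge_child=e[:, 1],
            edge_left=e[:, 2],
            edge_right=e[:, 3],
            sequence_length=sequence_length,
            mut_child=m[:, 0],
            mut_position=m[:, 1],
        )

    # -- basic accessors ---------------------------------------------------

    @property
    def num_nodes(self) -> int:
        return len(self.node_time)

    @property
    def num_edges(self) -> int:
        return len(self.edge_parent)

    @property
    def num_mutations(self) -> int:
        return len(self.mut_child)

    @property
    def is_sample(self) -> np.ndarray:
        return (self.node_flags & NODE_IS_SAMPLE) != 0

    @property
    def is_virtual(self) -> np.ndarray:
        return (self.node_flags & NODE_IS_VIRTUAL) != 0

    @property
    def samples(self) -> np.ndarray:
        return np.flatnonzero(self.is_sample)

    @property
    def edge_child_time(self) -> np.ndarray:
        return self.node_time[self.edge_child]

    @property
    def edge_parent_time(self) -> np.ndarray:
        return self.node_time[self.edge_parent]

    def copy(self) -> "ArgTables":
        return ArgTables(
            node_time=self.node_time.copy(),
            node_flags=self.node_flags.copy(),
            edge_parent=self.edge_parent.copy(),
            edge_child=self.edge_child.copy(),
            edge_left=self.edge_left.copy(),
            edge_right=self.edge_right.copy(),
            sequence_length=self.sequence_length,
            mut_child=self.mut_child.copy(),
            mut_position=self.mut_position.copy(),
            node_orig=None if self.node_orig is None else self.node_orig.copy(),
        )

    def equals(self, other: "ArgTables") -> bool:
        """Exact table equality (ignoring ``node_orig`` provenance)."""
        return (
            self.sequence_length == other.sequence_length
            and np.array_equal(self.node_time, other.node_time)
            and np.array_equal(self.node_flags, other.node_flags)
            and np.array_equal(self.edge_parent, other.edge_parent)
            and np.array_equal(self.edge_child, other.edge_child)
            and np.array_equal(self.edge_left, other.edge_left)
            and np.array_equal(self.edge_right, other.edge_right)
            and np.array_equal(self.mut_child, other.mut_child)
            and np.array_equal(self.mut_position, other.mut_position)
        )

    # -- tskit interop -----------------------------------------------------

    def to_tree_sequence(self) -> tskit.TreeSequence:
        """Convert to a tskit tree sequence (edges sorted, flags preserved)."""
        tables = tskit.TableCollection(sequence_length=float(self.sequence_length))
        tables.nodes.set_columns(
            flags=self.node_flags.astype(np.uint32),
            time=self.node_time,
        )
        tables.edges.set_columns(
            left=self.edge_left.astype(np.float64),
            right=self.edge_right.astype(np.float64),
            parent=self.edge_parent.astype(np.int32),
            child=self.edge_child.astype(np.int32),
        )
        if self.num_mutations:
            pos_order = np.argsort(self.mut_position, kind="stable")
            unique_pos, site_of_mut = np.unique(
                self.mut_position, return_inverse=True
            )
            for p in unique_pos:
                tables.sites.add_row(position=float(p), ancestral_state="0")
            for i in pos_order:
                tables.mutations.add_row(
                    site=int(site_of_mut[i]),
                    node=int(self.mut_child[i]),
                    derived_state="1",
                )
        tables.sort()
        tables.build_index()
        if self.num_mutations:
            tables.compute_mutation_parents()
        return tables.tree_sequence()

    @classmethod
    def from_tree_sequence(cls, ts: tskit.TreeSequence) -> "ArgTables":
        left = ts.edges_left
        right = ts.edges_right
        if not (np.all(left == np.floor(left)) and np.all(right == np.floor(right))):
            raise ArgValidationError(
                "tree sequence has non-integer edge coordinates"
            )
        mut_child = np.array(
            [m.node for m in ts.mutations()], dtype=np.int64
        )
        mut_pos = np.array(
            [ts.site(m.site).position for m in ts.mutations()], dtype=np.int64
        )
        return cls(
            node_time=ts.nodes_time.copy(),
            node_flags=ts.nodes_flags.copy(),
            edge_parent=ts.edges_parent.astype(np.int64),
            edge_child=ts.edges_child.astype(np.int64),
            edge_left=left.astype(np.int64),
            edge_right=right.astype(np.int64),
            sequence_length=int(ts.sequence_length),
            mut_child=mut_child,
            mut_position=mut_pos,
        )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_arg(arg: ArgTables, allow_zero_length_edges: bool = False) -> list[str]:
    """Check every table invariant; return a list of violations (empty = valid).

    Zero-length edges (parent and child at the same time) are normally
    reported, since most operations treat them as degenerate; the likelihood
    code tolerates them (the log-likelihood is ``-inf``).
    """
    v: list[str] = []
    n, ne = arg.num_nodes, arg.num_edges
    if not np.all(np.isfinite(arg.node_time)):
        v.append("node times must be finite")
    if np.any(arg.node_time < 0):
        v.append("node times must be non-negative")
    if ne:
        bad = (arg.edge_parent < 0) | (arg.edge_parent >= n)
        for i in np.flatnonzero(bad):
            v.append(f"edge {i}: parent id {arg.edge_parent[i]} not in node table")
        bad = (arg.edge_child < 0) | (arg.edge_child >= n)
        for i in np.flatnonzero(bad):
            v.append(f"edge {i}: child id {arg.edge_child[i]} not in node table")
        if v:
            return v  # id errors make the remaining checks meaningless
        tp, tc = arg.edge_parent_time, arg.edge_child_time
        bad = tp < tc if allow_zero_length_edges else tp <= tc
        for i in np.flatnonzero(bad):
            v.append(
                f"edge {i} ({arg.edge_parent[i]},{arg.edge_child[i]},"
                f"{arg.edge_left[i]},{arg.edge_right[i]}): "
                f"parent time {tp[i]} <= child time {tc[i]}"
            )
        bad = ~(
            (0 <= arg.edge_left)
            & (arg.edge_left < arg.edge_right)
            & (arg.edge_right <= arg.sequence_length)
        )
        for i in np.flatnonzero(bad):
            v.append(
                f"edge {i}: interval [{arg.edge_left[i]}, {arg.edge_right[i]}) "
                f"invalid for sequence length {arg.sequence_length}"
            )
        # Per-child genomic intervals must be pairwise disjoint.
        order = np.lexsort((arg.edge_left, arg.edge_child))
        c, l, r = arg.edge_child[order], arg.edge_left[order], arg.edge_right[order]
        same_child = c[1:] == c[:-1]
        overlap = same_child & (l[1:] < r[:-1])
        for j in np.flatnonzero(overlap):
            v.append(
                f"child {c[j]}: overlapping edge intervals "
                f"[{l[j]},{r[j]}) and [{l[j + 1]},{r[j + 1]})"
            )
    for i in range(arg.num_mutations):
        ch, pos = arg.mut_child[i], arg.mut_position[i]
        if not (0 <= ch < n):
            v.append(f"mutation {i}: node id {ch} not in node table")
        elif not (0 <= pos < arg.sequence_length):
            v.append(f"mutation {i}: position {pos} outside the genome")
    return v


def assert_valid(arg: ArgTables, allow_zero_length_edges: bool = False) -> None:
    violations = validate_arg(arg, allow_zero_length_edges)
    if violations:
        raise ArgValidationError("; ".join(violations))


@dataclass(frozen=True)
class DegreeSummary:
    in_degree: np.ndarray  # edges with the node as child
    out_degree: np.ndarray  # edges with the node as parent
    nr: int  # nodes with in-degree 0 (roots)
    ns: int  # nodes with out-degree 0 (leaves / samples)


def node_degrees(arg: ArgTables) -> DegreeSummary:
    """Per-node in/out degrees plus the root (nr) and leaf (ns) counts."""
    n = arg.num_nodes
    in_deg = np.bincount(arg.edge_child, minlength=n)
    out_deg = np.bincount(arg.edge_parent, minlength=n)
    return DegreeSummary(
        in_degree=in_deg,
        out_degree=out_deg,
        nr=int(np.sum(in_deg == 0)),
        ns=int(np.sum(out_deg == 0)),
    )


def local_tree_count(arg: ArgTables) -> int:
    """Number of distinct local trees along the genome (via tskit)."""
    return arg.to_tree_sequence().num_trees


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_NODE_COLUMNS = ["id", "time", "is_sample", "flags"]
_EDGE_COLUMNS = ["parent", "child", "left", "right"]
_MUT_COLUMNS = ["edge_child", "position"]


def load_arg(path, format: str | None = None) -> ArgTables:
    """Load an ARG from a tskit ``.trees`` file or a TSV table directory.

    The TSV dialect: ``nodes.tsv`` with columns ``id  time  is_sample  flags``,
    ``edges.tsv`` with ``parent  child  left  right``, optional
    ``mutations.tsv`` with ``edge_child  position`` and optional
    ``metadata.json`` holding ``sequence_length`` (defaults to the maximum
    edge right coordinate).
    """
    path = pathlib.Path(path)
    if format is None:
        format = "tsv" if path.is_dir() else "trees"
    if format == "trees":
        if not path.exists():
            raise FileNotFoundError(f"no such file: {path}")
        arg = ArgTables.from_tree_sequence(tskit.load(str(path)))
    elif format == "tsv":
        arg = _load_tsv(path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'trees' or 'tsv')")
    assert_valid(arg)
    return arg


def _read_tsv(path: pathlib.Path, columns: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as e:  # pragma: no cover - pandas error text varies
        raise ArgValidationError(f"{path.name}: parse failure: {e}") from e
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ArgValidationError(f"{path.name}: missing columns {missing}")
    return df


def _load_tsv(directory: pathlib.Path) -> ArgTables:
    nodes = _read_tsv(directory / "nodes.tsv", _NODE_COLUMNS)
    edges = _read_tsv(directory / "edges.tsv", _EDGE_COLUMNS)
    ids = nodes["id"].to_numpy()
    if not np.array_equal(np.sort(ids), np.arange(len(ids))):
        raise ArgValidationError(
            "nodes.tsv: ids must be unique and form a contiguous range from 0"
        )
    order = np.argsort(ids)
    flags = nodes["flags"].to_numpy(dtype=np.uint32)[order]
    flags = np.where(
        nodes["is_sample"].to_numpy(dtype=bool)[order],
        flags | NODE_IS_SAMPLE,
        flags & ~np.uint32(NODE_IS_SAMPLE),
    )
    mut_path = directory / "mutations.tsv"
    if mut_path.exists():
        muts = _read_tsv(mut_path, _MUT_COLUMNS)
        mut_child = muts["edge_child"].to_numpy(dtype=np.int64)
        mut_pos = muts["position"].to_numpy(dtype=np.int64)
    else:
        mut_child = np.empty(0, np.int64)
        mut_pos = np.empty(0, np.int64)
    meta_path = directory / "metadata.json"
    if meta_path.exists():
        sequence_length = int(json.loads(meta_path.read_text())["sequence_length"])
    else:
        sequence_length = int(edges["right"].max()) if len(edges) else 1
    return ArgTables(
        node_time=nodes["time"].to_numpy(dtype=np.float64)[order],
        node_flags=flags,
        edge_parent=edges["parent"].to_numpy(dtype=np.int64),
        edge_child=edges["child"].to_numpy(dtype=np.int64),
        edge_left=edges["left"].to_numpy(dtype=np.int64),
        edge_right=edges["right"].to_numpy(dtype=np.int64),
        sequence_length=sequence_length,
        mut_child=mut_child,
        mut_position=mut_pos,
    )


def save_arg(arg: ArgTables, path, format: str | None = None) -> None:
    """Write to a ``.trees`` file or a TSV directory (see :func:`load_arg`)."""
    path = pathlib.Path(path)
    if format is None:
        format = "trees" if path.suffix == ".trees" else "tsv"
    if format == "trees":
        arg.to_tree_sequence().dump(str(path))
        return
    path.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame(
        {
            "id": np.arange(arg.num_nodes),
            "time": arg.node_time,
            "is_sample": arg.is_sample.astype(int),
            "flags": arg.node_flags,
        }
    )
    edges = pd.DataFrame(
        {
            "parent": arg.edge_parent,
            "child": arg.edge_child,
            "left": arg.edge_left,
            "right": arg.edge_right,
        }
    )
    nodes.to_csv(path / "nodes.tsv", sep="\t", index=False, float_format="%.17g")
    edges.to_csv(path / "edges.tsv", sep="\t", index=False)
    if arg.num_mutations:
        pd.DataFrame(
            {"edge_child": arg.mut_child, "position": arg.mut_position}
        ).to_csv(path / "mutations.tsv", sep="\t", index=False)
    (path / "metadata.json").write_text(
        json.dumps({"sequence_length": arg.sequence_length}) + "\n"
    )


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------


class _MutableGraph:
    """Edge list with parent/child adjacency supporting sequential node deletion."""

    def __init__(self, arg: ArgTables):
        self.edges: list[list[int] | None] = [
            [int(p), int(c), int(l), int(r)]
            for p, c, l, r in zip(
                arg.edge_parent, arg.edge_child, arg.edge_left, arg.edge_right
            )
        ]
        self.by_parent: dict[int, set[int]] = {}
        self.by_child: dict[int, set[int]] = {}
        for i, (p, c, _, _) in enumerate(self.edges):
            self.by_parent.setdefault(p, set()).add(i)
            self.by_child.setdefault(c, set()).add(i)
        self.dead_nodes: set[int] = set()
        self.mutations: list[list[int]] = [
            [int(c), int(pos)] for c, pos in zip(arg.mut_child, arg.mut_position)
        ]

    def _add_edge(self, p: int, c: int, l: int, r: int) -> None:
        i = len(self.edges)
        self.edges.append([p, c, l, r])
        self.by_parent.setdefault(p, set()).add(i)
        self.by_child.setdefault(c, set()).add(i)

    def _drop_edge(self, i: int) -> None:
        p, c, _, _ = self.edges[i]
        self.by_parent[p].discard(i)
        self.by_child[c].discard(i)
        self.edges[i] = None

    def delete_node(self, u: int) -> None:
        """Remove ``u``, re-attaching its children to its parents over overlaps."""
        child_edges = [self.edges[i] for i in sorted(self.by_parent.get(u, ()))]
        parent_edges = [self.edges[i] for i in sorted(self.by_child.get(u, ()))]
        for i in list(self.by_parent.get(u, ())) + list(self.by_child.get(u, ())):
            self._drop_edge(i)
        for _, c, cl, cr in child_edges:
            for p, _, pl, pr in parent_edges:
                l, r = max(cl, pl), min(cr, pr)
                if l < r:
                    self._add_edge(p, c, l, r)
        # Mutations above u move down to the child edge covering their position.
        for m in self.mutations:
            if m[0] == u:
                covering = [c for _, c, cl, cr in child_edges if cl <= m[1] < cr]
                m[0] = covering[0] if covering else -1
        self.dead_nodes.add(u)

    def finalize(self, arg: ArgTables) -> ArgTables:
        keep = np.ones(arg.num_nodes, dtype=bool)
        keep[list(self.dead_nodes)] = False
        new_id = np.cumsum(keep) - 1
        rows = sorted(
            (e for e in self.edges if e is not None),
            key=lambda e: (e[2], e[1], e[0]),
        )
        edges = np.asarray(rows, dtype=np.int64).reshape(-1, 4)
        kept_muts = [m for m in self.mutations if m[0] >= 0]
        if len(kept_muts) < len(self.mutations):
            warnings.warn(
                f"{len(self.mutations) - len(kept_muts)} mutation(s) fell on "
                "genomic spans not inherited below a deleted node and were dropped"
            )
        muts = np.asarray(kept_muts, dtype=np.int64).reshape(-1, 2)
        return ArgTables(
            node_time=arg.node_time[keep],
            node_flags=arg.node_flags[keep],
            edge_parent=new_id[edges[:, 0]],
            edge_child=new_id[edges[:, 1]],
            edge_left=edges[:, 2],
            edge_right=edges[:, 3],
            sequence_length=arg.sequence_length,
            mut_child=new_id[muts[:, 0]] if len(muts) else muts[:, 0],
            mut_position=muts[:, 1],
        )


def _children_disjoint(lefts: np.ndarray, rights: np.ndarray) -> bool:
    order = np.argsort(lefts)
    return bool(np.all(rights[order][:-1] <= lefts[order][1:]))


def _recombination_nodes(arg: ArgTables) -> np.ndarray:
    """Nodes to treat as recombinant: explicit flags, or unary-everywhere nodes."""
    flagged = np.flatnonzero((arg.node_flags & NODE_IS_RE_EVENT) != 0)
    if len(flagged):
        return flagged
    deg = node_degrees(arg)
    candidates = np.flatnonzero(
        (deg.out_degree >= 1) & ~arg.is_sample & ~arg.is_virtual
    )
    result = []
    for u in candidates:
        idx = np.flatnonzero(arg.edge_parent == u)
        if _children_disjoint(arg.edge_left[idx], arg.edge_right[idx]):
            result.append(u)
    return np.asarray(result, dtype=np.int64)


def remove_recombination_nodes(arg: ArgTables) -> ArgTables:
    """Splice recombinant (everywhere-unary) nodes out of the ARG.

    Each removed node's child edges are fused with its parent edges over
    their genomic overlaps; the locally unary spans of coalescent nodes are
    untouched, so the local trees along the genome are unchanged.  Nodes
    carrying the recombination-event flag are removed; if no node is flagged,
    nodes that are unary in every local tree they appear in are used instead.
    """
    targets = _recombination_nodes(arg)
    if len(targets) == 0:
        return arg.copy()
    graph = _MutableGraph(arg)
    # Child-first (ascending time) so chained recombinant nodes fuse cleanly.
    for u in sorted(targets, key=lambda u: (arg.node_time[u], u)):
        graph.delete_node(int(u))
    out = graph.finalize(arg)
    bad = validate_arg(out)
    if bad:
        raise StructuralError(
            "recombination-node removal produced invalid tables: " + "; ".join(bad)
        )
    return out


def fully_simplify(arg: ArgTables) -> ArgTables:
    """Remove all locally unary nodes: splice single-child nodes out of every
    local tree, keeping only nodes that are coalescent or a sample in at
    least one tree.  Implemented via tskit's simplify (unary nodes dropped)."""
    ts = arg.to_tree_sequence()
    simplified = ts.simplify(filter_sites=False)
    return ArgTables.from_tree_sequence(simplified)


def drop_internal_nodes(arg: ArgTables, fraction: float, seed: int) -> ArgTables:
    """Delete a random ``floor(fraction * count)`` of the internal nodes.

    Eligible nodes are neither samples nor the root of any local tree (their
    child-edge coverage is fully covered by their parent edges).  Each
    deleted node's children are re-attached to its parents over the
    overlapping genomic intervals, creating polytomies where the parent was
    not unary.  Deterministic given ``seed``.
    """
    if not (0 <= fraction < 1):
        raise ParameterError("fraction must be in [0, 1)")
    eligible = []
    for u in range(arg.num_nodes):
        if arg.is_sample[u] or arg.is_virtual[u]:
            continue
        child_idx = np.flatnonzero(arg.edge_parent == u)
        if len(child_idx) == 0:
            continue
        parent_idx = np.flatnonzero(arg.edge_child == u)
        if len(parent_idx) == 0:
            continue
        if _covers(
            arg.edge_left[parent_idx],
            arg.edge_right[parent_idx],
            arg.edge_left[child_idx],
            arg.edge_right[child_idx],
        ):
            eligible.append(u)
    k = int(np.floor(fraction * len(eligible)))
    if k == 0:
        return arg.copy()
    rng = np.random.default_rng(seed)
    selected = rng.choice(np.asarray(eligible, dtype=np.int64), size=k, replace=False)
    graph = _MutableGraph(arg)
    for u in sorted(selected.tolist()):
        graph.delete_node(u)
    out = graph.finalize(arg)
    bad = validate_arg(out)
    if bad:
        raise StructuralError(
            "internal-node deletion produced invalid tables: " + "; ".join(bad)
        )
    return out


def _covers(pl, pr, cl, cr) -> bool:
    """True if the union of [pl, pr) intervals covers every [cl, cr) interval."""
    order = np.argsort(pl)
    merged: list[list[int]] = []
    for l, r in zip(pl[order], pr[order]):
        if merged and l <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], r)
        else:
            merged.append([int(l), int(r)])
    for l, r in zip(cl, cr):
        if not any(ml <= l and r <= mr for ml, mr in merged):
            return False
    return True


def time_slice(arg: ArgTables, spec: SliceSpec) -> list[ArgTables]:
    """Cut the ARG into horizontal time bands ``[0,T1), [T1,T2), ..., [Tk,inf)``.

    Edges spanning a boundary are cut there by introducing a virtual
    pass-through node (in-degree 1, out-degree 1 across adjacent slices), so
    the per-slice tables jointly carry every original edge's exact time
    support.  A node whose time equals a breakpoint belongs to the older
    slice; virtual nodes cutting a non-leftmost edge carry a flag so the
    eligible-link convention survives slicing.
    """
    bounds = spec.bounds
    if len(bounds) == 1:
        return [arg.copy()]
    tc_all = arg.edge_child_time
    tp_all = arg.edge_parent_time
    # Leftmost status on the *original* tables (min left per child).
    xc: dict[int, int] = {}
    for c, l in zip(arg.edge_child, arg.edge_left):
        xc[c] = min(xc.get(c, np.inf), l)
    nonleftmost = np.array(
        [l > xc[c] for c, l in zip(arg.edge_child, arg.edge_left)], dtype=bool
    )

    slices = []
    for lo, hi in bounds:
        in_band = (tc_all < hi) & (tp_all > lo)
        edge_idx = np.flatnonzero(in_band)
        orig_nodes: set[int] = set()
        virtual_nodes: dict[tuple[int, float], int] = {}  # (edge, time) -> local id
        node_rows: list[tuple[float, int, int]] = []  # (time, flags, orig id)
        # Original nodes whose time falls in [lo, hi), referenced or not.
        for u in np.flatnonzero((arg.node_time >= lo) & (arg.node_time < hi)):
            orig_nodes.add(int(u))
        edge_rows = []
        # One virtual node per cut (parent, child, boundary): same-pair edges
        # recording split genomic spans share their pass-through node, so a
        # single inheritance relationship stays a single relationship per slice.
        virt_leftmost_left: dict[tuple, tuple[int, bool]] = {}
        for i in edge_idx:
            c, p = int(arg.edge_child[i]), int(arg.edge_parent[i])
            if tc_all[i] >= lo:
                child = ("orig", c)
                orig_nodes.add(c)
            else:
                child = ("virt", p, c, lo)
            if tp_all[i] <= hi:
                parent = ("orig", p)
                orig_nodes.add(p)
            else:
                parent = ("virt", p, c, hi)
            for key in (parent, child):
                if key[0] == "virt":
                    cand = (int(arg.edge_left[i]), bool(nonleftmost[i]))
                    if key not in virt_leftmost_left or cand < virt_leftmost_left[key]:
                        virt_leftmost_left[key] = cand
            edge_rows.append(
                (parent, child, int(arg.edge_left[i]), int(arg.edge_right[i]), i)
            )
        orig_sorted = sorted(orig_nodes)
        local_id = {("orig", u): j for j, u in enumerate(orig_sorted)}
        for u in orig_sorted:
            node_rows.append((float(arg.node_time[u]), int(arg.node_flags[u]), u))
        # Virtual nodes appended after original ids, ordered by (time, pair).
        virt_keys = sorted(
            {
                key
                for parent, child, *_ in edge_rows
                for key in (parent, child)
                if key[0] == "virt"
            },
            key=lambda k: (k[3], k[1], k[2]),
        )
        for key in virt_keys:
            flags = NODE_IS_VIRTUAL
            if virt_leftmost_left[key][1]:
                flags |= NODE_CUT_NONLEFTMOST
            local_id[key] = len(node_rows)
            node_rows.append((float(key[3]), flags, -1))
        parents = np.array([local_id[e[0]] for e in edge_rows], dtype=np.int64)
        children = np.array([local_id[e[1]] for e in edge_rows], dtype=np.int64)
        lefts = np.array([e[2] for e in edge_rows], dtype=np.int64)
        rights = np.array([e[3] for e in edge_rows], dtype=np.int64)
        order = np.lexsort((parents, children, lefts))
        out = ArgTables(
            node_time=np.array([r[0] for r in node_rows], dtype=np.float64),
            node_flags=np.array([r[1] for r in node_rows], dtype=np.uint32),
            edge_parent=parents[order],
            edge_child=children[order],
            edge_left=lefts[order],
            edge_right=rights[order],
            sequence_length=arg.sequence_length,
            node_orig=np.array([r[2] for r in node_rows], dtype=np.int64),
        )
        slices.append(out)
    return slices


def squash_edges(arg: ArgTables) -> ArgTables:
    """Merge genomically adjacent edges with identical (parent, child)."""
    if arg.num_edges == 0:
        return arg.copy()
    order = np.lexsort((arg.edge_left, arg.edge_parent, arg.edge_child))
    p = arg.edge_parent[order]
    c = arg.edge_child[order]
    l = arg.edge_left[order]
    r = arg.edge_right[order]
    rows: list[list[int]] = []
    for i in range(len(p)):
        if rows and rows[-1][0] == p[i] and rows[-1][1] == c[i] and rows[-1][3] == l[i]:
            rows[-1][3] = int(r[i])
        else:
            rows.append([int(p[i]), int(c[i]), int(l[i]), int(r[i])])
    rows.sort(key=lambda e: (e[2], e[1], e[0]))
    edges = np.asarray(rows, dtype=np.int64)
    return replace(
        arg.copy(),
        edge_parent=edges[:, 0],
        edge_child=edges[:, 1],
        edge_left=edges[:, 2],
        edge_right=edges[:, 3],
    )
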