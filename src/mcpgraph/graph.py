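"""Directed weighted hypothesis graphs and the closure weighting algorithm.

A *weighting strategy* for a family of ``m`` null hypotheses assigns to every
non-empty subset ``J`` of the index set a weight vector ``w_j(J)``.  Here the
strategy is generated from a directed weighted graph: each node is an
elementary hypothesis carrying an initial weight (its share of the overall
significance level), and each directed edge ``i -> j`` carries the fraction
``g_ij`` of node ``i``'s weight that is propagated to ``j`` once ``H_i`` is
removed (rejected).  Repeatedly removing the hypotheses outside ``J`` and
updating the graph yields ``w_j(J)``; the result does not depend on the
removal order, so the graph compactly encodes all ``2^m - 1`` intersection
weight vectors of the closure.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GraphValidationError",
    "HypothesisGraph",
    "ClosureWeightTable",
    "MonotonicityReport",
    "ExhaustivenessReport",
    "new_graph",
    "remove_and_update",
    "subset_weights",
    "closure_weights",
    "check_monotonicity",
    "check_exhaustive",
    "make_standard_graph",
    "read_graph",
    "write_graph",
]

TOL = 1e-9
#: ceiling on m for closure enumeration (2^m - 1 subsets)
MAX_CLOSURE_SIZE = 20


class GraphValidationError(ValueError):
    """A hypothesis graph, weight table or related input violates its invariants."""


@dataclass(frozen=True)
class HypothesisGraph:
    """A graphical weighting strategy.

    Parameters
    ----------
    names
        Unique labels for the ``m`` hypotheses (user-facing, typically
        ``H1 .. Hm``).
    weights
        Initial weights ``w_i`` for the global intersection; non-negative,
        summing to at most 1.
    transition
        ``m x m`` matrix ``G = (g_ij)`` with ``0 <= g_ij <= 1``, zero
        diagonal, and every row sum at most 1.  ``g_ij`` is the fraction of
        ``H_i``'s weight passed to ``H_j`` on removal of ``H_i``.
    """

    names: tuple[str, ...]
    weights: np.ndarray = field(repr=False)
    transition: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.names)
        object.__setattr__(self, "names", names)
        try:
            w = np.asarray(self.weights, dtype=float).reshape(-1)
            g = np.asarray(self.transition, dtype=float)
        except (TypeError, ValueError) as exc:
            raise GraphValidationError(f"non-numeric graph entries: {exc}") from exc
        m = len(names)
        if m < 1:
            raise GraphValidationError("a graph needs at least one hypothesis")
        if len(set(names)) != m:
            raise GraphValidationError(f"duplicate hypothesis names in {names}")
        if w.shape != (m,):
            raise GraphValidationError(
                f"weight vector has length {w.shape[0]}, expected {m}"
            )
        if g.shape != (m, m):
            raise GraphValidationError(
                f"transition matrix has shape {g.shape}, expected {(m, m)}"
            )
        if np.any(w < -TOL):
            raise GraphValidationError(f"negative initial weight in {w.tolist()}")
        if w.sum() > 1 + TOL:
            raise GraphValidationError(
                f"initial weights sum to {w.sum():.6g} > 1"
            )
        if np.any(g < -TOL) or np.any(g > 1 + TOL):
            raise GraphValidationError("transition weights must lie in [0, 1]")
        if np.any(np.abs(np.diag(g)) > TOL):
            raise GraphValidationError("transition matrix must have zero diagonal")
        rows = g.sum(axis=1)
        if np.any(rows > 1 + TOL):
            bad = int(np.argmax(rows))
            raise GraphValidationError(
                f"row sum for {names[bad]} is {rows[bad]:.6g} > 1"
            )
        w = np.clip(w, 0.0, None)
        g = np.clip(g, 0.0, 1.0)
        np.fill_diagonal(g, 0.0)
        w.flags.writeable = False
        g.flags.writeable = False
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "transition", g)

    @property
    def m(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise GraphValidationError(f"unknown hypothesis {name!r}") from None

    def remove(self, j: int) -> "HypothesisGraph":
        return remove_and_update(self, j)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HypothesisGraph):
            return NotImplemented
        return (
            self.names == other.names
            and np.allclose(self.weights, other.weights, atol=TOL)
            and np.allclose(self.transition, other.transition, atol=TOL)
        )

    def __hash__(self) -> int:  # frozen dataclass with arrays
        return hash(self.names)


def new_graph(
    names: Iterable[str],
    weights: Iterable[float],
    transition: Iterable[Iterable[float]],
) -> HypothesisGraph:
    """Validate and build a :class:`HypothesisGraph`."""
    return HypothesisGraph(tuple(names), np.asarray(list(weights)), np.asarray(transition))


def _update_arrays(
    w: np.ndarray, g: np.ndarray, alive: np.ndarray, j: int
) -> None:
    """In-place removal of node ``j``: propagate its weight and rewire edges.

    For every surviving ``l``: ``w_l += w_j * g_jl``.  For every surviving
    ordered pair ``(k, l)``: ``g_kl = (g_kl + g_kj * g_jl) / (1 - g_kj * g_jk)``
    when ``g_kj * g_jk < 1``, else 0 (a two-node loop of total weight one has
    nowhere left to send its level).
    """
    alive[j] = False
    idx = np.flatnonzero(alive)
    w[idx] += w[j] * g[j, idx]
    w[j] = 0.0
    gkj = g[idx, j]
    gjk = g[j, idx]
    denom = 1.0 - gkj * gjk
    new = g[np.ix_(idx, idx)] + np.outer(gkj, g[j, idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        new = np.where(denom[:, None] > TOL, new / denom[:, None], 0.0)
    np.fill_diagonal(new, 0.0)
    g[np.ix_(idx, idx)] = np.clip(new, 0.0, 1.0)
    g[j, :] = 0.0
    g[:, j] = 0.0


def remove_and_update(graph: HypothesisGraph, j: int) -> HypothesisGraph:
    """Remove hypothesis ``j`` (0-based index) and return the updated graph."""
    if not 0 <= j < graph.m:
        raise GraphValidationError(
            f"index {j} not in graph on {graph.m} hypotheses"
        )
    if graph.m == 1:
        raise GraphValidationError("cannot remove the last hypothesis")
    w = graph.weights.copy()
    g = graph.transition.copy()
    alive = np.ones(graph.m, dtype=bool)
    _update_arrays(w, g, alive, j)
    keep = np.flatnonzero(alive)
    names = tuple(graph.names[i] for i in keep)
    return HypothesisGraph(names, w[keep], g[np.ix_(keep, keep)])


def _as_indices(graph_or_m, J: Iterable[int]) -> tuple[int, ...]:
    m = graph_or_m if isinstance(graph_or_m, int) else graph_or_m.m
    J = tuple(sorted(set(int(j) for j in J)))
    if not J:
        raise GraphValidationError("index subset J must be non-empty")
    if J[0] < 0 or J[-1] >= m:
        raise GraphValidationError(f"subset {J} out of range for m={m}")
    return J


def subset_weights(
    graph: HypothesisGraph, J: Iterable[int], order: Iterable[int] | None = None
) -> np.ndarray:
    """Weights ``w_j(J)`` for the intersection hypothesis ``H_J``.

    Removes the complement of ``J`` (in ``order`` if given, else ascending)
    and returns the surviving weights aligned with ``sorted(J)``.  The result
    is removal-order invariant.
    """
    J = _as_indices(graph, J)
    comp = [i for i in range(graph.m) if i not in J]
    if order is not None:
        order = list(order)
        if sorted(order) != comp:
            raise GraphValidationError("removal order must enumerate the complement of J")
        comp = order
    w = graph.weights.copy()
    g = graph.transition.copy()
    alive = np.ones(graph.m, dtype=bool)
    for j in comp:
        _update_arrays(w, g, alive, j)
    return w[list(J)]


def _mask(J: Iterable[int]) -> int:
    mask = 0
    for j in J:
        mask |= 1 << int(j)
    return mask


def _unmask(mask: int) -> tuple[int, ...]:
    out, i = [], 0
    while mask:
        if mask & 1:
            out.append(i)
        mask >>= 1
        i += 1
    return tuple(out)


@dataclass(frozen=True)
class ClosureWeightTable:
    """Weight vectors for every non-empty intersection hypothesis.

    Maps each non-empty ``J`` (subset of ``0..m-1``) to the weights
    ``w_j(J)`` of its members.  Hypotheses outside ``J`` carry no entry
    (rendered as ``-`` in tabular output, never as 0: a zero weight is a
    meaningful local level).
    """

    names: tuple[str, ...]
    _entries: dict[int, np.ndarray] = field(repr=False)

    @property
    def m(self) -> int:
        return len(self.names)

    def __len__(self) -> int:
        return len(self._entries)

    def subsets(self) -> Iterator[tuple[int, ...]]:
        for mask in sorted(self._entries):
            yield _unmask(mask)

    def __contains__(self, J: Iterable[int]) -> bool:
        return _mask(J) in self._entries

    def weights(self, J: Iterable[int]) -> np.ndarray:
        """Weight vector over ``sorted(J)``."""
        J = _as_indices(self.m, J)
        try:
            return self._entries[_mask(J)]
        except KeyError:
            raise GraphValidationError(f"subset {J} not in table") from None

    def weight(self, J: Iterable[int], j: int) -> float:
        J = _as_indices(self.m, J)
        if j not in J:
            raise GraphValidationError(f"hypothesis {j} not in subset {J}")
        return float(self.weights(J)[J.index(j)])

    def to_frame(self) -> pd.DataFrame:
        """Table-style view: one row per subset, NaN for absent hypotheses."""
        rows, labels = [], []
        order = sorted(
            self._entries,
            key=lambda mask: (-bin(mask).count("1"), tuple(_unmask(mask))),
        )
        for mask in order:
            J = _unmask(mask)
            w = self._entries[mask]
            row = {self.names[j]: w[k] for k, j in enumerate(J)}
            rows.append(row)
            labels.append(" ∩ ".join(self.names[j] for j in J))
        return pd.DataFrame(rows, index=labels, columns=list(self.names))


def closure_weights(graph: HypothesisGraph) -> ClosureWeightTable:
    """Generate the full closure weight table (all ``2^m - 1`` subsets).

    Enumerates subsets by a depth-first sequence of single removals so that
    intermediate graphs are shared along each branch.
    """
    m = graph.m
    if m > MAX_CLOSURE_SIZE:
        raise GraphValidationError(
            f"closure enumeration limited to m <= {MAX_CLOSURE_SIZE} (got {m})"
        )
    entries: dict[int, np.ndarray] = {}

    def rec(w: np.ndarray, g: np.ndarray, alive: np.ndarray, start: int) -> None:
        idx = np.flatnonzero(alive)
        entries[_mask(idx)] = w[idx].copy()
        for j in idx[idx >= start]:
            if alive.sum() == 1:
                break
            w2, g2, a2 = w.copy(), g.copy(), alive.copy()
            _update_arrays(w2, g2, a2, int(j))
            rec(w2, g2, a2, int(j) + 1)

    rec(graph.weights.copy(), graph.transition.copy(), np.ones(m, dtype=bool), 0)
    return ClosureWeightTable(graph.names, entries)


@dataclass(frozen=True)
class MonotonicityReport:
    """Result of the weight-monotonicity check that underwrites consonance."""

    passed: bool
    violations: tuple[tuple[tuple[int, ...], tuple[int, ...], int], ...]


def check_monotonicity(table: ClosureWeightTable) -> MonotonicityReport:
    """Check ``w_j(J') >= w_j(J)`` for all ``J' ⊆ J`` and ``j ∈ J'``.

    Only immediate pairs ``J' = J \\ {k}`` need inspection: the general
    condition follows along removal chains.  Violating triples ``(J, J', j)``
    are reported with 0-based member tuples.
    """
    violations = []
    for J in table.subsets():
        if len(J) < 2:
            continue
        wJ = table.weights(J)
        for k in J:
            Jp = tuple(i for i in J if i != k)
            wJp = table.weights(Jp)
            for pos, j in enumerate(Jp):
                if wJp[pos] < wJ[J.index(j)] - TOL:
                    violations.append((J, Jp, j))
    return MonotonicityReport(not violations, tuple(violations))


@dataclass(frozen=True)
class ExhaustivenessReport:
    passed: bool
    failing_subset: tuple[int, ...] | None


def check_exhaustive(table: ClosureWeightTable) -> ExhaustivenessReport:
    """Check that every subset's weights sum to exactly 1.

    Subsets are scanned from the full index set downwards; the first failing
    subset is reported.
    """
    for J in sorted(table.subsets(), key=lambda J: (-len(J), J)):
        if abs(table.weights(J).sum() - 1.0) > TOL:
            return ExhaustivenessReport(False, J)
    return ExhaustivenessReport(True, None)


def _default_names(m: int) -> tuple[str, ...]:
    return tuple(f"H{i + 1}" for i in range(m))


def make_standard_graph(kind: str, **params) -> HypothesisGraph:
    """Construct a named standard weighting strategy.

    Kinds
    -----
    ``holm``
        Weighted Holm on ``m`` hypotheses (``weights`` optional, default
        equal): ``g_ij = w_j / (1 - w_i)``.
    ``fixed_sequence``
        Hierarchical testing of ``m`` hypotheses in order at full level.
    ``fallback``
        Fallback procedure for a given initial ``weights`` vector; each
        hypothesis passes its level to the next in sequence.
    ``truncated_holm_two_families``
        Two primaries tested by a truncated Holm procedure with truncation
        ``gamma``; the fraction ``1 - gamma`` of a rejected primary's level
        is released to a secondary family of two hypotheses tested by Holm.
    ``hierarchical``
        Two dose levels, each with a primary and a secondary endpoint in
        strict hierarchy; a fully rejected dose passes its weight to the
        other dose's primary.
    ``hierarchical_delta``
        The same strategy with additional ``delta``-weight edges between the
        two primaries, used to enforce consonance of the correlation-aware
        parametric test (``delta=0`` recovers ``hierarchical``).
    """
    if kind == "holm":
        if "weights" in params:
            w = np.asarray(params["weights"], dtype=float)
            m = len(w)
        else:
            m = int(params["m"])
            w = np.full(m, 1.0 / m)
        if np.any(w <= 0) or abs(w.sum() - 1.0) > TOL:
            raise GraphValidationError("holm weights must be positive and sum to 1")
        g = np.zeros((m, m))
        for i in range(m):
            for j in range(m):
                if i != j:
                    g[i, j] = w[j] / (1.0 - w[i])
        return HypothesisGraph(_default_names(m), w, g)
    if kind == "fixed_sequence":
        m = int(params["m"])
        w = np.zeros(m)
        w[0] = 1.0
        g = np.zeros((m, m))
        for i in range(m - 1):
            g[i, i + 1] = 1.0
        return HypothesisGraph(_default_names(m), w, g)
    if kind == "fallback":
        w = np.asarray(params["weights"], dtype=float)
        m = len(w)
        g = np.zeros((m, m))
        for i in range(m - 1):
            g[i, i + 1] = 1.0
        return HypothesisGraph(_default_names(m), w, g)
    if kind == "truncated_holm_two_families":
        gamma = float(params["gamma"])
        if not 0.0 <= gamma <= 1.0:
            raise GraphValidationError(f"gamma must lie in [0, 1], got {gamma}")
        w = np.array([0.5, 0.5, 0.0, 0.0])
        g = np.zeros((4, 4))
        g[0, 1] = g[1, 0] = gamma
        g[0, 2] = g[0, 3] = g[1, 2] = g[1, 3] = (1.0 - gamma) / 2.0
        g[2, 3] = g[3, 2] = 1.0
        return HypothesisGraph(_default_names(4), w, g)
    if kind == "hierarchical":
        w = np.array([0.5, 0.5, 0.0, 0.0])
        g = np.zeros((4, 4))
        g[0, 2] = g[1, 3] = g[2, 1] = g[3, 0] = 1.0
        return HypothesisGraph(_default_names(4), w, g)
    if kind == "hierarchical_delta":
        delta = float(params["delta"])
        if not 0.0 <= delta <= 1.0:
            raise GraphValidationError(f"delta must lie in [0, 1], got {delta}")
        w = np.array([0.5, 0.5, 0.0, 0.0])
        g = np.zeros((4, 4))
        g[0, 1] = g[1, 0] = delta
        g[0, 2] = g[1, 3] = 1.0 - delta
        g[2, 1] = g[3, 0] = 1.0
        return HypothesisGraph(_default_names(4), w, g)
    raise GraphValidationError(f"unknown standard graph kind {kind!r}")


def write_graph(graph: HypothesisGraph, path) -> None:
    """Serialise a graph to JSON (``names``, ``weights``, ``transition``)."""
    payload = {
        "names": list(graph.names),
        "weights": graph.weights.tolist(),
        "transition": graph.transition.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_graph(path) -> HypothesisGraph:
    """Read a graph from the JSON layout written by :func:`write_graph`."""
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise GraphValidationError(f"malformed graph file {path}: {exc}") from exc
    try:
        return new_graph(payload["names"], payload["weights"], payload["transition"])
    except KeyError as exc:
        raise GraphValidationError(f"graph file {path} is missing field {exc}") from exc


def write_transition_csv(graph: HypothesisGraph, path) -> None:
    """Transition matrix as CSV with a header row of hypothesis names."""
    pd.DataFrame(graph.transition, index=graph.names, columns=graph.names).to_csv(path)


def read_transition_csv(path) -> tuple[tuple[str, ...], np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    return tuple(df.columns), df.to_numpy(dtype=float)
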