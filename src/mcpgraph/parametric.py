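"""Weighted parametric (min-p) closed tests exploiting known correlations.

When the joint null distribution of the one-sided normal test statistics is
known — fully, or within blocks of a partition with unknown cross-block
dependence — the weighted Bonferroni test of each intersection ``H_J`` can be
sharpened: reject ``H_J`` if some ``p_j <= c_J * w_j(J) * alpha`` where
``c_J >= 1`` is the largest constant keeping the (blockwise Bonferroni bound
on the) rejection probability at ``alpha``.  Consonance of the resulting
closure — needed for a sequentially rejective shortcut — amounts to the
local levels ``c_J * w_j(J) * alpha`` being monotone under shrinking ``J``,
and can be enforced for the two-dose two-endpoint hierarchical strategy by
adding delta-weight edges between the primaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._mvn import prob_none_below
from .bonferroni import _check_alpha, _check_p, adjusted_p_bonferroni
from .graph import (
    ClosureWeightTable,
    GraphValidationError,
    HypothesisGraph,
    closure_weights,
    make_standard_graph,
)
from .results import TestOutcome

__all__ = [
    "CorrelationModel",
    "ConsonanceError",
    "ConsonanceReport",
    "critical_constant",
    "local_pvalue_parametric",
    "closed_parametric",
    "local_levels_table",
    "check_consonance_parametric",
    "sequential_parametric",
    "min_consonance_delta",
    "dunnett_correlation",
]

TOL = 1e-9


class ConsonanceError(GraphValidationError):
    """The requested shortcut requires a consonant procedure."""


@dataclass(frozen=True)
class CorrelationModel:
    """Correlation matrix with known and unknown entries.

    ``matrix`` holds pairwise correlations of the one-sided normal test
    statistics, with ``nan`` marking unknown entries.  The known/unknown
    pattern must be block-diagonal under some ordering; the induced blocks
    ``I_1, ..., I_l`` partition the index set, every within-block entry is
    known and every cross-block entry unknown.  A fully known matrix is the
    single-block special case.
    """

    matrix: np.ndarray = field(repr=False)
    blocks: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise GraphValidationError("correlation matrix must be square")
        m = mat.shape[0]
        if not np.allclose(np.diag(mat), 1.0, atol=TOL):
            raise GraphValidationError("correlation matrix diagonal must be 1")
        known = ~np.isnan(mat)
        if not np.array_equal(known, known.T) or not np.allclose(
            np.nan_to_num(mat), np.nan_to_num(mat.T), atol=TOL
        ):
            raise GraphValidationError("correlation matrix must be symmetric")
        with np.errstate(invalid="ignore"):
            if np.any(np.abs(mat[known]) > 1 + TOL):
                raise GraphValidationError("correlations must lie in [-1, 1]")
        # connected components of the "known" relation
        blocks: list[tuple[int, ...]] = []
        seen = np.zeros(m, dtype=bool)
        for i in range(m):
            if seen[i]:
                continue
            comp = {i}
            stack = [i]
            while stack:
                k = stack.pop()
                for j in np.flatnonzero(known[k]):
                    if j not in comp:
                        comp.add(int(j))
                        stack.append(int(j))
            seen[list(comp)] = True
            blocks.append(tuple(sorted(comp)))
        for block in blocks:
            sub = mat[np.ix_(block, block)]
            if np.any(np.isnan(sub)):
                raise GraphValidationError(
                    f"unknown entries inside block {tuple(b + 1 for b in block)}: "
                    "the known/unknown pattern must be block-diagonal"
                )
            if np.min(np.linalg.eigvalsh(sub)) < -1e-8:
                raise GraphValidationError(
                    f"block {tuple(b + 1 for b in block)} is not positive semidefinite"
                )
        mat = mat.copy()
        mat.flags.writeable = False
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "blocks", tuple(sorted(blocks)))

    @property
    def m(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def fully_known(cls, matrix) -> "CorrelationModel":
        return cls(np.asarray(matrix, dtype=float))

    @classmethod
    def independent(cls, m: int) -> "CorrelationModel":
        return cls(np.eye(m))

    @classmethod
    def unknown(cls, m: int) -> "CorrelationModel":
        mat = np.full((m, m), np.nan)
        np.fill_diagonal(mat, 1.0)
        return cls(mat)

    def restrict(self, indices) -> "CorrelationModel":
        """Sub-model on ``sorted(indices)``."""
        idx = sorted(set(int(i) for i in indices))
        return CorrelationModel(self.matrix[np.ix_(idx, idx)])

    @classmethod
    def from_csv(cls, path) -> "CorrelationModel":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float))

    def to_csv(self, path, names=None) -> None:
        names = list(names) if names is not None else [f"H{i+1}" for i in range(self.m)]
        pd.DataFrame(self.matrix, index=names, columns=names).to_csv(path, na_rep="NA")


def _union_probability(
    weights: np.ndarray, corr: CorrelationModel, scale: float
) -> float:
    """Blockwise Bonferroni bound on P(some P_j <= w_j * scale).

    Zero-weight hypotheses contribute nothing (their threshold is 0 and the
    p-values are continuous), so the joint distribution never degenerates.
    """
    total = 0.0
    for block in corr.blocks:
        members = [j for j in block if weights[j] > 0]
        if not members:
            continue
        t = np.clip(weights[members] * scale, 0.0, 1.0)
        total += 1.0 - prob_none_below(t, corr.matrix[np.ix_(members, members)])
    return total


def critical_constant(weights, corr: CorrelationModel, alpha: float) -> float:
    """Largest ``c_J`` with blockwise rejection probability equal to ``alpha``.

    Solves ``sum_h P(union_{j in block h} {P_j <= c w_j alpha}) = alpha`` by
    bracketed root finding.  ``c_J = 1`` recovers the weighted Bonferroni
    test; under any shared known correlation structure ``c_J >= 1``.
    """
    alpha = _check_alpha(alpha)
    w = np.asarray(weights, dtype=float).reshape(-1)
    if w.shape[0] != corr.m:
        raise GraphValidationError(
            f"{w.shape[0]} weights supplied for a {corr.m}-variate correlation model"
        )
    if np.any(w < -TOL) or w.sum() > 1 + TOL:
        raise GraphValidationError("weights must be non-negative and sum to at most 1")
    w = np.clip(w, 0.0, None)
    if not np.any(w > 0):
        raise GraphValidationError(
            "critical constant undefined when every weight is zero"
        )

    def f(c: float) -> float:
        return _union_probability(w, corr, c * alpha) - alpha

    upper = (1.0 - 1e-12) / (alpha * w.max())
    f1 = f(1.0)
    if f1 >= -1e-12:
        return 1.0
    if f(upper) < 0:
        raise ArithmeticError(
            "no sign change when bracketing the critical constant"
        )
    return float(brentq(f, 1.0, upper, xtol=1e-10, rtol=1e-12))


def local_pvalue_parametric(
    J, p, table: ClosureWeightTable, corr: CorrelationModel
) -> float:
    """Local p-value of ``H_J``: the smallest level at which it is rejected.

    With ``t = min_{j in J, w_j>0} p_j / w_j(J)``, the local p-value is the
    blockwise union probability ``sum_h P(union {P_j <= w_j(J) t})`` capped
    at 1.  If every weight in ``J`` is zero the intersection can never be
    rejected and the local p-value is 1 by convention.
    """
    J = tuple(sorted(set(int(j) for j in J)))
    wJ = table.weights(J)
    p = np.asarray(p, dtype=float)
    pos = wJ > 0
    if not pos.any():
        return 1.0
    t = float(np.min(p[list(J)][pos] / wJ[pos]))
    full_w = np.zeros(corr.m)
    full_w[list(J)] = wJ
    sub = corr.restrict(J)
    w_sub = full_w[list(J)]
    return min(1.0, _union_probability(w_sub, sub, t))


def closed_parametric(
    graph: HypothesisGraph, p, corr: CorrelationModel, alpha: float
) -> TestOutcome:
    """Closed test with a weighted parametric test per intersection.

    ``H_i`` is rejected iff every intersection containing it has local
    p-value at most ``alpha``; the adjusted p-value is the maximum local
    p-value over those intersections.
    """
    p = _check_p(graph, p)
    alpha = _check_alpha(alpha)
    if corr.m != graph.m:
        raise GraphValidationError("correlation model size does not match graph")
    table = closure_weights(graph)
    adjusted = np.zeros(graph.m)
    for J in table.subsets():
        local = local_pvalue_parametric(J, p, table, corr)
        for j in J:
            adjusted[j] = max(adjusted[j], local)
    adjusted = np.minimum(adjusted, 1.0)
    return TestOutcome(
        graph.names, adjusted <= alpha, adjusted, "closed weighted parametric", alpha
    )


def local_levels_table(
    graph: HypothesisGraph, corr: CorrelationModel, alpha: float
) -> pd.DataFrame:
    """Per-intersection local significance levels ``c_J * w_j(J) * alpha``.

    Returns a frame with one row per intersection (largest first), the
    member levels in the hypothesis columns (NaN for absent members) and the
    critical constant in column ``c_J``.
    """
    alpha = _check_alpha(alpha)
    table = closure_weights(graph)
    rows, labels, consts = [], [], []
    subsets = sorted(table.subsets(), key=lambda J: (-len(J), J))
    for J in subsets:
        wJ = table.weights(J)
        if np.any(wJ > 0):
            c = critical_constant(wJ, corr.restrict(J), alpha)
        else:
            c = 1.0
        rows.append({graph.names[j]: c * wJ[k] * alpha for k, j in enumerate(J)})
        labels.append(" ∩ ".join(graph.names[j] for j in J))
        consts.append(c)
    frame = pd.DataFrame(rows, index=labels, columns=list(graph.names))
    frame["c_J"] = consts
    return frame


@dataclass(frozen=True)
class ConsonanceReport:
    """Violations of local-level monotonicity across nested intersections."""

    passed: bool
    violations: tuple[tuple[tuple[int, ...], tuple[int, ...], int], ...]


def check_consonance_parametric(
    graph: HypothesisGraph, corr: CorrelationModel, alpha: float, tol: float = TOL
) -> ConsonanceReport:
    """Check ``c_J' * w_j(J') >= c_J * w_j(J)`` for all ``J' ⊂ J``, ``j ∈ J'``.

    Monotone local levels make the closed parametric procedure consonant, so
    the sequentially rejective shortcut applies.  Immediate pairs
    ``J' = J \\ {k}`` suffice by transitivity.
    """
    alpha = _check_alpha(alpha)
    table = closure_weights(graph)
    level: dict[tuple[int, ...], np.ndarray] = {}
    for J in table.subsets():
        wJ = table.weights(J)
        c = critical_constant(wJ, corr.restrict(J), alpha) if np.any(wJ > 0) else 1.0
        level[J] = c * wJ * alpha
    violations = []
    for J in table.subsets():
        if len(J) < 2:
            continue
        for k in J:
            Jp = tuple(i for i in J if i != k)
            for pos, j in enumerate(Jp):
                if level[Jp][pos] < level[J][J.index(j)] - tol:
                    violations.append((J, Jp, j))
    return ConsonanceReport(not violations, tuple(violations))


def sequential_parametric(
    graph: HypothesisGraph, p, corr: CorrelationModel, alpha: float
) -> TestOutcome:
    """Sequentially rejective weighted parametric test (consonant case).

    At each step the critical constant ``c_I`` of the current index set is
    computed and any ``H_j`` with ``p_j <= c_I * w_j * alpha`` is rejected
    (smallest eligible index first), after which the graph is updated.
    Refuses to run when the procedure is not consonant — the shortcut is
    then invalid and the full closure (:func:`closed_parametric`) must be
    used.  Decisions agree with :func:`closed_parametric`; adjusted p-values
    are taken from the closure.
    """
    p = _check_p(graph, p)
    alpha = _check_alpha(alpha)
    report = check_consonance_parametric(graph, corr, alpha)
    if not report.passed:
        raise ConsonanceError(
            "the weighted parametric procedure is not consonant for this graph "
            "and correlation model; use closed_parametric instead"
        )
    current = graph
    alive = list(range(graph.m))
    trace: list[tuple[int, float]] = []
    rejected = np.zeros(graph.m, dtype=bool)
    while alive:
        w = current.weights
        if np.any(w > 0):
            c = critical_constant(w, corr.restrict(alive), alpha)
        else:
            break
        levels = c * w * alpha
        eligible = [k for k in range(len(alive)) if p[alive[k]] <= levels[k]]
        if not eligible:
            break
        k = eligible[0]
        j = alive[k]
        rejected[j] = True
        trace.append((j, float(levels[k])))
        if len(alive) == 1:
            break
        current = current.remove(k)
        alive.pop(k)
    closed = closed_parametric(graph, p, corr, alpha)
    return TestOutcome(
        graph.names, rejected, closed.adjusted_p,
        "sequential weighted parametric", alpha, tuple(trace),
    )


def min_consonance_delta(
    corr: CorrelationModel, alpha: float, tol: float = 1e-6
) -> float:
    """Smallest delta making the delta-augmented hierarchical graph consonant.

    Bisects ``delta`` in ``[0, 1]`` on the consonance check of
    ``make_standard_graph("hierarchical_delta", delta=...)`` under the given
    block correlation model.  The bound grows with the within-primary
    correlation and degenerates to 1 as it approaches 1.
    """
    alpha = _check_alpha(alpha)

    def ok(delta: float) -> bool:
        g = make_standard_graph("hierarchical_delta", delta=delta)
        return check_consonance_parametric(g, corr, alpha).passed

    if ok(0.0):
        return 0.0
    if not ok(1.0):
        raise ArithmeticError("no delta in [0, 1] yields a consonant procedure")
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if ok(mid):
            hi = mid
        else:
            lo = mid
    return hi


def dunnett_correlation(n0: float, n1: float, n2: float) -> float:
    """Correlation of two dose-vs-control z contrasts with group sizes n1, n2
    against a shared control of size n0; reduces to 1/2 for equal sizes."""
    if n0 <= 0 or n1 <= 0 or n2 <= 0:
        raise GraphValidationError("group sizes must be positive")
    return float(np.sqrt((n1 / (n0 + n1)) * (n2 / (n0 + n2))))


def parametric_vs_bonferroni(
    graph: HypothesisGraph, p, corr: CorrelationModel, alpha: float
) -> pd.DataFrame:
    """Side-by-side adjusted p-values of the parametric and Bonferroni closures."""
    par = closed_parametric(graph, p, corr, alpha)
    bon_adj = adjusted_p_bonferroni(graph, p)
    return pd.DataFrame(
        {
            "parametric_adj_p": par.adjusted_p,
            "bonferroni_adj_p": bon_adj,
            "parametric_rejected": par.rejected,
            "bonferroni_rejected": bon_adj <= alpha,
        },
        index=list(graph.names),
    )
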