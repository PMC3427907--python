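"""Weighted Simes tests on the closure and the partially sequential shortcut.

The weighted Simes test rejects an intersection ``H_J`` if some ``p_j`` is at
most ``alpha`` times the cumulative weight of all members of ``J`` with
p-values not exceeding ``p_j``.  It is valid under positive regression
dependence (PRD) of the one-sided test statistics — e.g. multivariate normal
with non-negative correlations — and dominates the weighted Bonferroni test
(whose condition uses only ``w_j`` instead of the cumulative weight).  When
PRD can only be asserted within blocks of a partition, the test is applied
per block at the block's cumulative-weight share of ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bonferroni import _check_alpha, _check_p, sequential_bonferroni
from .graph import (
    GraphValidationError,
    HypothesisGraph,
    _update_arrays,
    check_exhaustive,
    closure_weights,
)
from .results import TestOutcome

__all__ = [
    "PrdPartition",
    "weighted_simes_reject",
    "closed_simes",
    "algorithm4_simes",
    "partitioned_simes_reject",
    "closed_partitioned_simes",
]


@dataclass(frozen=True)
class PrdPartition:
    """Disjoint index blocks within which the user asserts PRD.

    The package documents but cannot verify positive regression dependence;
    the assertion is the analyst's responsibility.
    """

    blocks: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        blocks = tuple(tuple(sorted(set(int(i) for i in b))) for b in self.blocks)
        flat = [i for b in blocks for i in b]
        if len(flat) != len(set(flat)):
            raise GraphValidationError("partition blocks must be disjoint")
        if not flat:
            raise GraphValidationError("partition must be non-empty")
        object.__setattr__(self, "blocks", blocks)

    def validate_cover(self, m: int) -> None:
        flat = sorted(i for b in self.blocks for i in b)
        if flat != list(range(m)):
            raise GraphValidationError(
                f"partition {self.blocks} does not cover indices 0..{m - 1}"
            )

    @classmethod
    def single(cls, m: int) -> "PrdPartition":
        return cls((tuple(range(m)),))

    @classmethod
    def singletons(cls, m: int) -> "PrdPartition":
        return cls(tuple((i,) for i in range(m)))

    @classmethod
    def parse(cls, text: str) -> "PrdPartition":
        """Parse ``"1,2;3,4"`` (1-based labels) into a partition."""
        try:
            blocks = tuple(
                tuple(int(tok) - 1 for tok in part.split(","))
                for part in text.split(";")
                if part.strip()
            )
        except ValueError as exc:
            raise GraphValidationError(f"cannot parse partition {text!r}") from exc
        return cls(blocks)


def _simes_local_ratio(pJ: np.ndarray, wJ: np.ndarray) -> float:
    """min_j p_j / (cumulative weight of members with p <= p_j); inf if 0."""
    order = np.argsort(pJ, kind="stable")
    cumw = np.cumsum(wJ[order])
    # ties: every member with an equal p-value counts toward the cumulative weight
    p_sorted = pJ[order]
    for i in range(len(p_sorted) - 2, -1, -1):
        if p_sorted[i + 1] == p_sorted[i]:
            cumw[i] = cumw[i + 1]
    with np.errstate(divide="ignore"):
        ratios = np.where(cumw > 0, p_sorted / np.where(cumw > 0, cumw, 1.0), np.inf)
    return float(ratios.min())


def weighted_simes_reject(p_J, w_J, alpha: float) -> bool:
    """Weighted Simes test of a single intersection.

    Rejects iff some ``p_j <= (sum of w_k over p_k <= p_j) * alpha``.  With
    equal weights this is the classical unweighted Simes test.
    """
    alpha = _check_alpha(alpha)
    pJ = np.asarray(p_J, dtype=float).reshape(-1)
    wJ = np.asarray(w_J, dtype=float).reshape(-1)
    if pJ.shape != wJ.shape:
        raise GraphValidationError("p-values and weights differ in length")
    if np.any(wJ < 0) or wJ.sum() > 1 + 1e-9:
        raise GraphValidationError("weights must be non-negative and sum to at most 1")
    return _simes_local_ratio(pJ, wJ) <= alpha


def _closed_simes_adjusted(
    graph: HypothesisGraph, p: np.ndarray, partition: PrdPartition | None
) -> np.ndarray:
    table = closure_weights(graph)
    adjusted = np.zeros(graph.m)
    for J in table.subsets():
        wJ = table.weights(J)
        pJ = p[list(J)]
        if partition is None:
            local = _simes_local_ratio(pJ, wJ)
        else:
            local = np.inf
            for block in partition.blocks:
                sel = [k for k, j in enumerate(J) if j in block]
                if sel:
                    local = min(local, _simes_local_ratio(pJ[sel], wJ[sel]))
        for j in J:
            adjusted[j] = max(adjusted[j], local)
    return np.minimum(adjusted, 1.0)


def closed_simes(graph: HypothesisGraph, p, alpha: float) -> TestOutcome:
    """Closed test with a weighted Simes test per intersection.

    Adjusted p-values use the min over members of ``p_j`` divided by the
    cumulative weight of smaller-or-equal p-values — the smallest level at
    which the intersection's Simes condition fires — maximised over the
    containing intersections.
    """
    p = _check_p(graph, p)
    alpha = _check_alpha(alpha)
    adjusted = _closed_simes_adjusted(graph, p, None)
    return TestOutcome(
        graph.names, adjusted <= alpha, adjusted, "closed weighted Simes", alpha
    )


def algorithm4_simes(graph: HypothesisGraph, p, alpha: float) -> TestOutcome:
    """Partially sequential weighted Simes procedure.

    Steps: (i) all ``p > alpha`` — retain everything; (ii) all
    ``p <= alpha`` — reject everything (valid because the closure weights
    are exhaustive); (iii) run the sequentially rejective Bonferroni
    procedure; if at most two hypotheses survive they cannot be rejected by
    the Simes closure either — retain them; (iv) otherwise rebuild the graph
    on the survivors (weights and transitions as updated by the rejections)
    and (v) apply the closed weighted Simes criterion on that survivor
    closure.  Decisions are identical to :func:`closed_simes`; step (ii) is
    skipped when the weights are not exhaustive.
    """
    p = _check_p(graph, p)
    alpha = _check_alpha(alpha)
    m = graph.m
    exhaustive = check_exhaustive(closure_weights(graph)).passed
    if np.all(p > alpha):
        return TestOutcome(
            graph.names, np.zeros(m, bool), _closed_simes_adjusted(graph, p, None),
            "weighted Simes (partially sequential)", alpha,
        )
    if exhaustive and np.all(p <= alpha):
        return TestOutcome(
            graph.names, np.ones(m, bool), _closed_simes_adjusted(graph, p, None),
            "weighted Simes (partially sequential)", alpha,
        )
    seq = sequential_bonferroni(graph, p, alpha)
    rejected = seq.rejected.copy()
    survivors = [i for i in range(m) if not rejected[i]]
    adjusted = _closed_simes_adjusted(graph, p, None)
    if len(survivors) > 2:
        # graph state after the Bonferroni rejections
        w = graph.weights.copy()
        g = graph.transition.copy()
        alive = np.ones(m, dtype=bool)
        for j, _ in seq.trace:
            _update_arrays(w, g, alive, j)
        keep = np.flatnonzero(alive)
        sub = HypothesisGraph(
            tuple(graph.names[i] for i in keep), w[keep], g[np.ix_(keep, keep)]
        )
        sub_out = closed_simes(sub, p[keep], alpha)
        for pos, i in enumerate(keep):
            rejected[i] = sub_out.rejected[pos]
    return TestOutcome(
        graph.names, rejected, adjusted,
        "weighted Simes (partially sequential)", alpha, seq.trace,
    )


def partitioned_simes_reject(
    p_J, w_J, partition: PrdPartition, alpha: float, members=None
) -> bool:
    """Weighted Simes test applied per PRD block with a Bonferroni join.

    ``members`` gives the global indices of the entries of ``p_J``/``w_J``
    (default ``0..len-1``).  Rejects iff some block's weighted Simes
    condition fires with the block's own cumulative weights.  A single block
    recovers :func:`weighted_simes_reject`; all-singleton blocks recover the
    weighted Bonferroni test.
    """
    alpha = _check_alpha(alpha)
    pJ = np.asarray(p_J, dtype=float).reshape(-1)
    wJ = np.asarray(w_J, dtype=float).reshape(-1)
    if pJ.shape != wJ.shape:
        raise GraphValidationError("p-values and weights differ in length")
    idx = list(range(len(pJ))) if members is None else list(members)
    covered = set()
    for block in partition.blocks:
        sel = [k for k, j in enumerate(idx) if j in block]
        covered.update(idx[k] for k in sel)
        if sel and _simes_local_ratio(pJ[sel], wJ[sel]) <= alpha:
            return True
    if covered != set(idx):
        raise GraphValidationError("partition does not cover the tested subset")
    return False


def closed_partitioned_simes(
    graph: HypothesisGraph, p, partition: PrdPartition, alpha: float
) -> TestOutcome:
    """Closed test with the block-partitioned weighted Simes test per intersection."""
    p = _check_p(graph, p)
    alpha = _check_alpha(alpha)
    partition.validate_cover(graph.m)
    adjusted = _closed_simes_adjusted(graph, p, partition)
    return TestOutcome(
        graph.names, adjusted <= alpha, adjusted,
        "closed partitioned weighted Simes", alpha,
    )
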