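"""Weighted Bonferroni tests on the closure and the sequentially rejective shortcut.

The closed weighted Bonferroni procedure rejects an elementary hypothesis
``H_i`` iff every intersection ``H_J`` with ``i ∈ J`` has some ``j ∈ J`` with
``p_j <= w_j(J) * alpha``.  Because graph-generated weights are monotone
(removing hypotheses only adds weight), the closure never has to be
enumerated: the m-step sequentially rejective procedure — reject any ``H_j``
with ``p_j <= w_j * alpha`` on the current graph, propagate its weight,
repeat — reaches identical decisions.
"""

from __future__ import annotations

import numpy as np

from .graph import (
    GraphValidationError,
    HypothesisGraph,
    _update_arrays,
    closure_weights,
)
from .results import TestOutcome

__all__ = [
    "sequential_bonferroni",
    "closed_bonferroni",
    "adjusted_p_bonferroni",
]


def _check_p(graph: HypothesisGraph, p) -> np.ndarray:
    p = np.asarray(p, dtype=float).reshape(-1)
    if p.shape != (graph.m,):
        raise GraphValidationError(
            f"{p.shape[0]} p-values supplied for {graph.m} hypotheses"
        )
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise GraphValidationError("p-values must lie in [0, 1]")
    return p


def _check_alpha(alpha: float) -> float:
    alpha = float(alpha)
    if not 0.0 < alpha < 1.0:
        raise GraphValidationError(f"alpha must lie in (0, 1), got {alpha}")
    return alpha


def sequential_bonferroni(
    graph: HypothesisGraph, p, alpha: float
) -> TestOutcome:
    """Sequentially rejective weighted Bonferroni test.

    Repeatedly rejects the hypothesis with the smallest ratio
    ``p_j / w_j`` (ties and the choice among eligible hypotheses do not
    affect the decisions; the smallest eligible index is taken) and updates
    the graph.  Adjusted p-values are obtained by continuing the sequence
    past ``alpha``: the running maximum of the min-ratios is the smallest
    level at which each successive hypothesis falls.
    """
    p = _check_p(graph, p)
    alpha = _check_alpha(alpha)
    m = graph.m
    w = graph.weights.copy()
    g = graph.transition.copy()
    alive = np.ones(m, dtype=bool)
    adjusted = np.ones(m)
    trace: list[tuple[int, float]] = []
    running = 0.0
    while alive.any():
        idx = np.flatnonzero(alive)
        with np.errstate(divide="ignore"):
            ratios = np.where(w[idx] > 0, p[idx] / np.where(w[idx] > 0, w[idx], 1.0), np.inf)
        k = int(np.argmin(ratios))
        j = int(idx[k])
        running = max(running, float(ratios[k]))
        adjusted[j] = min(running, 1.0)
        if running <= alpha:
            trace.append((j, float(w[j] * alpha)))
        if alive.sum() == 1:
            break
        _update_arrays(w, g, alive, j)
    rejected = adjusted <= alpha
    return TestOutcome(
        graph.names, rejected, adjusted, "sequential weighted Bonferroni",
        alpha, tuple(trace),
    )


def adjusted_p_bonferroni(graph: HypothesisGraph, p) -> np.ndarray:
    """Adjusted p-values of the closed weighted Bonferroni test.

    The local p-value of ``H_J`` is ``min_{j∈J} p_j / w_j(J)`` (with
    ``x/0 := +inf``); the adjusted p-value of ``H_i`` is the maximum local
    p-value over all ``J`` containing ``i``, capped at 1.
    """
    p = _check_p(graph, p)
    table = closure_weights(graph)
    adjusted = np.zeros(graph.m)
    for J in table.subsets():
        w = table.weights(J)
        with np.errstate(divide="ignore"):
            local = np.min(np.where(w > 0, p[list(J)] / np.where(w > 0, w, 1.0), np.inf))
        for j in J:
            adjusted[j] = max(adjusted[j], local)
    return np.minimum(adjusted, 1.0)


def closed_bonferroni(graph: HypothesisGraph, p, alpha: float) -> TestOutcome:
    """Closed test with a weighted Bonferroni test per intersection."""
    alpha = _check_alpha(alpha)
    adjusted = adjusted_p_bonferroni(graph, p)
    return TestOutcome(
        graph.names, adjusted <= alpha, adjusted, "closed weighted Bonferroni", alpha
    )
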