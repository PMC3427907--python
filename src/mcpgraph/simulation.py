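"""Monte-Carlo validation: synthetic p-values, FWER and power estimation.

The generator draws one-sided z-statistics from a multivariate normal with a
specified correlation matrix and noncentrality (effect) vector — the
standard known-variance analysis-of-variance setting the closed procedures
assume — and converts them to p-values ``p = 1 - Phi(Z)``.  A noncentrality
of 0 marks a true null.  All compared procedures are evaluated on the same
replicate matrix (paired comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import norm

from .graph import GraphValidationError, HypothesisGraph, closure_weights
from .parametric import CorrelationModel

__all__ = [
    "SimulationSpec",
    "simulate_pvalues",
    "estimate_error_rates",
    "ErrorRateEstimate",
    "rowwise",
    "batch_closed_bonferroni",
    "batch_closed_simes",
    "batch_closed_parametric",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth for a Monte-Carlo run.

    ``correlation`` is the generator's full (fully known) correlation
    matrix; ``noncentrality`` the mean shift of each z-statistic (0 = true
    null); ``nsim`` the replicate count; ``seed`` feeds a single
    ``numpy.random.default_rng`` stream.
    """

    correlation: np.ndarray = field(repr=False)
    noncentrality: np.ndarray = field(repr=False)
    nsim: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        corr = np.asarray(self.correlation, dtype=float)
        delta = np.asarray(self.noncentrality, dtype=float).reshape(-1)
        if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
            raise GraphValidationError("correlation matrix must be square")
        if corr.shape[0] != delta.shape[0]:
            raise GraphValidationError("noncentrality length must match correlation")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-9):
            raise GraphValidationError("correlation diagonal must be 1")
        if not np.allclose(corr, corr.T, atol=1e-9):
            raise GraphValidationError("correlation matrix must be symmetric")
        if np.min(np.linalg.eigvalsh(corr)) < -1e-8:
            raise GraphValidationError("correlation matrix is not positive semidefinite")
        if int(self.nsim) < 1:
            raise GraphValidationError("nsim must be at least 1")
        corr = corr.copy()
        corr.flags.writeable = False
        delta = delta.copy()
        delta.flags.writeable = False
        object.__setattr__(self, "correlation", corr)
        object.__setattr__(self, "noncentrality", delta)
        object.__setattr__(self, "nsim", int(self.nsim))

    @property
    def m(self) -> int:
        return self.correlation.shape[0]


def simulate_pvalues(spec: SimulationSpec) -> np.ndarray:
    """``nsim x m`` matrix of one-sided p-values under the spec's model."""
    rng = np.random.default_rng(spec.seed)
    # eigen square root handles singular (e.g. perfectly correlated) models
    vals, vecs = np.linalg.eigh(spec.correlation)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = rng.standard_normal((spec.nsim, spec.m)) @ root.T + spec.noncentrality
    return norm.sf(z)


@dataclass(frozen=True)
class ErrorRateEstimate:
    """Monte-Carlo FWER/power estimates with binomial standard errors."""

    fwer: float
    fwer_se: float
    power: np.ndarray
    power_se: np.ndarray
    expected_rejections: float
    nsim: int
    true_nulls: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"power": self.power, "se": self.power_se},
            index=[f"H{i + 1}" for i in range(len(self.power))],
        )
        frame.attrs["fwer"] = self.fwer
        return frame


def rowwise(procedure: Callable[[np.ndarray], object]) -> Callable[[np.ndarray], np.ndarray]:
    """Adapt a per-vector procedure (returning a TestOutcome or boolean
    vector) to the batch interface of :func:`estimate_error_rates`."""

    def batch(P: np.ndarray) -> np.ndarray:
        out = []
        for row in P:
            res = procedure(row)
            out.append(res.rejected if hasattr(res, "rejected") else np.asarray(res, bool))
        return np.asarray(out, dtype=bool)

    return batch


def estimate_error_rates(
    procedure: Callable[[np.ndarray], np.ndarray],
    spec: SimulationSpec,
    true_nulls,
) -> ErrorRateEstimate:
    """Estimate FWER (over ``true_nulls``) and per-hypothesis rejection rates.

    ``procedure`` receives the full ``nsim x m`` p-value matrix and must
    return an ``nsim x m`` boolean rejection matrix (use :func:`rowwise` for
    per-vector callables).
    """
    true_nulls = tuple(sorted(set(int(i) for i in true_nulls)))
    if any(i < 0 or i >= spec.m for i in true_nulls):
        raise GraphValidationError("true_nulls out of range")
    P = simulate_pvalues(spec)
    R = np.asarray(procedure(P), dtype=bool)
    if R.shape != P.shape:
        raise GraphValidationError(
            f"procedure returned shape {R.shape}, expected {P.shape}"
        )
    any_false_rej = (
        R[:, true_nulls].any(axis=1) if true_nulls else np.zeros(spec.nsim, bool)
    )
    fwer = float(any_false_rej.mean())
    power = R.mean(axis=0)
    n = spec.nsim
    return ErrorRateEstimate(
        fwer=fwer,
        fwer_se=float(np.sqrt(fwer * (1 - fwer) / n)),
        power=power,
        power_se=np.sqrt(power * (1 - power) / n),
        expected_rejections=float(R.sum(axis=1).mean()),
        nsim=n,
        true_nulls=true_nulls,
    )


def batch_closed_bonferroni(
    graph: HypothesisGraph, alpha: float
) -> Callable[[np.ndarray], np.ndarray]:
    """Vectorised closed weighted Bonferroni test over a p-value matrix."""
    table = closure_weights(graph)
    subsets = list(table.subsets())

    def batch(P: np.ndarray) -> np.ndarray:
        n = P.shape[0]
        adjusted = np.zeros((n, graph.m))
        for J in subsets:
            w = table.weights(J)
            with np.errstate(divide="ignore"):
                ratios = np.where(w > 0, P[:, list(J)] / np.where(w > 0, w, 1.0), np.inf)
            local = ratios.min(axis=1)
            cols = list(J)
            adjusted[:, cols] = np.maximum(adjusted[:, cols], local[:, None])
        return adjusted <= alpha

    return batch


def batch_closed_simes(
    graph: HypothesisGraph, alpha: float
) -> Callable[[np.ndarray], np.ndarray]:
    """Vectorised closed weighted Simes test over a p-value matrix."""
    table = closure_weights(graph)
    subsets = list(table.subsets())

    def batch(P: np.ndarray) -> np.ndarray:
        n = P.shape[0]
        adjusted = np.zeros((n, graph.m))
        for J in subsets:
            w = table.weights(J)
            pJ = P[:, list(J)]
            order = np.argsort(pJ, axis=1, kind="stable")
            cumw = np.cumsum(w[order], axis=1)
            p_sorted = np.take_along_axis(pJ, order, axis=1)
            with np.errstate(divide="ignore"):
                ratios = np.where(
                    cumw > 0, p_sorted / np.where(cumw > 0, cumw, 1.0), np.inf
                )
            local = ratios.min(axis=1)
            cols = list(J)
            adjusted[:, cols] = np.maximum(adjusted[:, cols], local[:, None])
        return adjusted <= alpha

    return batch


def batch_closed_parametric(
    graph: HypothesisGraph, corr: CorrelationModel, alpha: float
) -> Callable[[np.ndarray], np.ndarray]:
    """Closed weighted parametric test over a p-value matrix.

    Blocks of size one and two are evaluated with closed-form normal and
    bivariate-normal probabilities (vectorised); larger blocks fall back to
    a per-replicate computation.
    """
    from ._mvn import bvn_cdf  # local import keeps scipy.special off the hot path

    table = closure_weights(graph)
    subsets = list(table.subsets())
    max_block = max((len(b) for b in corr.blocks), default=1)

    def batch(P: np.ndarray) -> np.ndarray:
        n = P.shape[0]
        adjusted = np.zeros((n, graph.m))
        for J in subsets:
            w = table.weights(J)
            pos = w > 0
            if not pos.any():
                continue
            pJ = P[:, list(J)]
            with np.errstate(divide="ignore"):
                t = np.min(
                    np.where(pos, pJ / np.where(pos, w, 1.0), np.inf), axis=1
                )
            local = np.zeros(n)
            for block in corr.blocks:
                sel = [k for k, j in enumerate(J) if j in block and w[k] > 0]
                if not sel:
                    continue
                thresh = np.clip(w[sel][None, :] * t[:, None], 0.0, 1.0)
                upper = norm.ppf(1.0 - thresh)
                if len(sel) == 1:
                    surv = norm.cdf(upper[:, 0])
                elif len(sel) == 2:
                    gj = [list(J)[k] for k in sel]
                    rho = float(corr.matrix[gj[0], gj[1]])
                    surv = bvn_cdf(upper[:, 0], upper[:, 1], rho)
                else:
                    gj = [list(J)[k] for k in sel]
                    sub = corr.matrix[np.ix_(gj, gj)]
                    from ._mvn import joint_cdf

                    surv = np.array([joint_cdf(u, sub) for u in upper])
                local += 1.0 - surv
            cols = list(J)
            adjusted[:, cols] = np.maximum(
                adjusted[:, cols], np.minimum(local, 1.0)[:, None]
            )
        return adjusted <= alpha

    if max_block > 2:
        batch.__doc__ = "closed parametric batch (slow path for blocks > 2)"
    return batch
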