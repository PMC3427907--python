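"""Shared result container for the closed and sequential test procedures."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TestOutcome:
    """Decisions of a multiple test procedure.

    Attributes
    ----------
    names
        Hypothesis labels.
    rejected
        Boolean rejection flags per hypothesis.
    adjusted_p
        Adjusted p-values (smallest overall level at which each hypothesis
        is rejected), in ``(0, 1]``; ``None`` when not computed.
    trace
        For sequential procedures: the rejection sequence as
        ``(index, local level at rejection)`` pairs; empty otherwise.
    method
        Label of the procedure that produced the outcome.
    alpha
        The overall significance level the decisions refer to.
    """

    names: tuple[str, ...]
    rejected: np.ndarray = field(repr=False)
    adjusted_p: np.ndarray | None = field(repr=False)
    method: str = ""
    alpha: float | None = None
    trace: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        rej = np.asarray(self.rejected, dtype=bool)
        rej.flags.writeable = False
        object.__setattr__(self, "rejected", rej)
        if self.adjusted_p is not None:
            adj = np.asarray(self.adjusted_p, dtype=float)
            adj.flags.writeable = False
            object.__setattr__(self, "adjusted_p", adj)

    @property
    def rejected_names(self) -> tuple[str, ...]:
        return tuple(n for n, r in zip(self.names, self.rejected) if r)

    def to_frame(self) -> pd.DataFrame:
        data = {"rejected": self.rejected}
        if self.adjusted_p is not None:
            data["adjusted_p"] = self.adjusted_p
        return pd.DataFrame(data, index=list(self.names))

    def __str__(self) -> str:
        lines = [f"{self.method} at alpha={self.alpha}"]
        for i, name in enumerate(self.names):
            adj = "" if self.adjusted_p is None else f"  adj p={self.adjusted_p[i]:.4f}"
            lines.append(
                f"  {name}: {'rejected' if self.rejected[i] else 'retained'}{adj}"
            )
        return "\n".join(lines)
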