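"""Pearson correlation analysis and multicollinearity-based filtering.

The filter codifies as a deterministic greedy rule what is often done by
hand: while any retained pair of descriptors correlates beyond the
threshold (default |r| = 0.75), drop the member of the worst-offending
pair that correlates less with the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationMatrix:
    names: tuple[str, ...]
    values: np.ndarray  # symmetric, unit diagonal

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.names), columns=list(self.names))

    def r(self, a: str, b: str) -> float:
        i, j = self.names.index(a), self.names.index(b)
        return float(self.values[i, j])


def correlation_matrix(table: pd.DataFrame) -> CorrelationMatrix:
    """Pearson correlation matrix of the descriptor columns."""
    if table.shape[0] < 3:
        raise SelectionError("need at least 3 rows for correlation analysis")
    X = table.to_numpy(dtype=float)
    stds = X.std(axis=0)
    constant = [c for c, s in zip(table.columns, stds) if s == 0.0]
    if constant:
        raise SelectionError(f"constant column(s) make correlations undefined: {constant}")
    r = np.corrcoef(X, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(names=tuple(table.columns), values=r)


def multicollinearity_filter(
    table: pd.DataFrame,
    target,
    threshold: float = 0.75,
) -> list[str]:
    """Greedily drop descriptors until no pair exceeds |r| = threshold.

    Offending pairs are resolved worst-first; within a pair the member with
    the lower |correlation with the target| goes, ties broken by dropping
    the later column in the table's (canonical) order. The result is
    deterministic and idempotent.
    """
    if not (0.0 < threshold <= 1.0):
        raise SelectionError(f"threshold must be in (0, 1], got {threshold}")
    corr = correlation_matrix(table)
    y = np.asarray(target, dtype=float)
    if y.shape[0] != table.shape[0]:
        raise SelectionError("target length does not match table rows")
    target_r = {
        name: abs(float(np.corrcoef(table[name].to_numpy(dtype=float), y)[0, 1]))
        for name in table.columns
    }
    names = list(table.columns)
    kept = list(names)
    while True:
        worst = None  # (|r|, i, j) with i, j canonical positions
        for ai in range(len(kept)):
            for bi in range(ai + 1, len(kept)):
                a, b = kept[ai], kept[bi]
                rab = abs(corr.r(a, b))
                if rab > threshold and (worst is None or rab > worst[0]):
                    worst = (rab, a, b)
        if worst is None:
            break
        _, a, b = worst
        if target_r[a] > target_r[b]:
            kept.remove(b)
        elif target_r[b] > target_r[a]:
            kept.remove(a)
        else:  # tie: drop the later column in canonical order
            kept.remove(b if names.index(b) > names.index(a) else a)
    if not kept:
        raise SelectionError("filter removed every descriptor")
    return kept
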