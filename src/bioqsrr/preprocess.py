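"""Descriptor-matrix pruning and auto-scaling.

Descriptor software emits thousands of columns, many constant or
mutually redundant on a small compound set.  Before subset selection
the matrix is pruned: constant columns, nearly constant columns, and
one member of every highly correlated pair (|Pearson r| >= threshold)
are removed.  Auto-scaling (zero mean, unit sample sd per column) is
applied before clustering and heat-map display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import DescriptorMatrix

__all__ = ["PruningReport", "prune_descriptors", "autoscale"]


@dataclass
class PruningReport:
    """Accounting of every column removed during pruning."""

    removed_constant: list[str] = field(default_factory=list)
    removed_near_constant: list[str] = field(default_factory=list)
    removed_correlated: list[tuple[str, str]] = field(default_factory=list)  # (kept, dropped)
    corr_threshold: float = 0.95
    near_constant_max_freq: float = 0.95

    @property
    def dropped(self) -> list[str]:
        return (
            self.removed_constant
            + self.removed_near_constant
            + [d for _, d in self.removed_correlated]
        )

    def to_dict(self) -> dict:
        return {
            "removed_constant": list(self.removed_constant),
            "removed_near_constant": list(self.removed_near_constant),
            "removed_correlated": [list(p) for p in self.removed_correlated],
            "corr_threshold": self.corr_threshold,
            "near_constant_max_freq": self.near_constant_max_freq,
        }


def _is_near_constant(col: np.ndarray, max_freq: float) -> bool:
    # most frequent value occupies > max_freq of entries, or the spread is
    # negligible relative to the magnitude of the values
    _, counts = np.unique(col, return_counts=True)
    if counts.max() / col.size > max_freq:
        return True
    scale = max(np.abs(col).max(), 1.0)
    return float(np.std(col, ddof=1)) < 1e-8 * scale


def prune_descriptors(
    X: DescriptorMatrix,
    corr_threshold: float = 0.95,
    near_constant_max_freq: float = 0.95,
    tie_break: str = "keep_first",
) -> tuple[DescriptorMatrix, PruningReport]:
    """Remove constant, nearly constant and highly correlated descriptors.

    Correlated pairs are resolved deterministically: with
    ``tie_break="keep_first"`` the earlier column in input order is kept;
    ``"keep_higher_variance"`` keeps the higher-variance member.

    Raises
    ------
    ValueError
        If fewer than 2 compounds are supplied or every descriptor is
        removed.
    """
    if X.shape[0] < 2:
        raise ValueError("pruning requires at least 2 compounds")
    if tie_break not in ("keep_first", "keep_higher_variance"):
        raise ValueError(f"unknown tie_break {tie_break!r}")

    report = PruningReport(
        corr_threshold=corr_threshold, near_constant_max_freq=near_constant_max_freq
    )
    df = X.frame
    survivors: list[str] = []
    for name in df.columns:
        col = df[name].to_numpy()
        if np.ptp(col) == 0:
            report.removed_constant.append(name)
        elif _is_near_constant(col, near_constant_max_freq):
            report.removed_near_constant.append(name)
        else:
            survivors.append(name)

    # greedy scan over pairs in column order; |r| >= threshold drops one member
    if survivors:
        corr = df[survivors].corr().abs().to_numpy()
        var = df[survivors].var(ddof=1).to_numpy()
        dropped = np.zeros(len(survivors), dtype=bool)
        for i in range(len(survivors)):
            if dropped[i]:
                continue
            for j in range(i + 1, len(survivors)):
                if dropped[j] or corr[i, j] < corr_threshold:
                    continue
                if tie_break == "keep_higher_variance" and var[j] > var[i]:
                    keep, drop = j, i
                else:
                    keep, drop = i, j
                dropped[drop] = True
                report.removed_correlated.append((survivors[keep], survivors[drop]))
                if drop == i:
                    break
        survivors = [s for s, d in zip(survivors, dropped) if not d]

    if not survivors:
        raise ValueError("pruning removed every descriptor; relax the thresholds")
    pruned = DescriptorMatrix(
        df[survivors],
        provenance={k: v for k, v in X.provenance.items() if k in survivors},
    )
    return pruned, report


def autoscale(X):
    """Standardise every column to mean 0 and unit sample sd (ddof=1).

    Accepts a DescriptorMatrix, DataFrame or 2-D array and returns the
    same kind.  Constant columns are rejected: prune first.
    """
    if isinstance(X, DescriptorMatrix):
        return DescriptorMatrix(autoscale(X.frame), provenance=X.provenance)
    if isinstance(X, pd.DataFrame):
        arr = autoscale(X.to_numpy(dtype=float))
        return pd.DataFrame(arr, index=X.index, columns=X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    sd = arr.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = list(np.where(sd == 0)[0])
        raise ValueError(f"constant column(s) at index {bad}; prune before auto-scaling")
    return (arr - arr.mean(axis=0)) / sd
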