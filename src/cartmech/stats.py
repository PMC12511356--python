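"""Nonparametric group comparisons for cohort summaries.

Kruskal-Wallis omnibus tests across the three groups followed by pairwise
Mann-Whitney U tests, reported with significance flags at 0.05 (strict) and
0.1 (trend).  No multiple-testing correction is applied; all three pairwise
contrasts are always reported alongside the omnibus test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["GroupComparison", "kruskal_wallis", "mann_whitney_u", "compare_groups"]


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p-value."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    if all(np.allclose(a, arrays[0][0]) for a in arrays):
        return 0.0, 1.0  # scipy rejects the all-identical case; H is 0 there
    H, p = sps.kruskal(*arrays)
    return float(H), float(p)


def mann_whitney_u(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact enumeration for small samples (both n <= 8, no ties), normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupComparison:
    """One variable compared across groups at one epoch."""

    variable: str
    epoch: str
    group_values: dict
    H: float = 0.0
    p_omnibus: float = 1.0
    pairwise: dict = field(default_factory=dict)

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_omnibus < alpha

    def flags(self) -> dict:
        """Per-contrast significance flags at 0.05 (strict) and 0.1 (trend)."""
        out = {}
        for pair, (_, p) in self.pairwise.items():
            out[pair] = "p<0.05" if p < 0.05 else ("p<0.1" if p < 0.1 else "ns")
        return out


def compare_groups(variable: str, epoch: str, group_values: dict) -> GroupComparison:
    """Omnibus + pairwise comparison of one variable across P/NP/C groups."""
    names = [g for g in ("P", "NP", "C") if g in group_values and len(group_values[g])]
    gc = GroupComparison(variable=variable, epoch=epoch, group_values=group_values)
    if len(names) < 2:
        return gc
    gc.H, gc.p_omnibus = kruskal_wallis([np.asarray(group_values[g]) for g in names])
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            gc.pairwise[f"{a}-{b}"] = mann_whitney_u(
                np.asarray(group_values[a]), np.asarray(group_values[b])
            )
    return gc
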