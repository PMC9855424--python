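"""Scalar quantification arithmetic and multiplicity-adjusted comparisons.

Covers the study's non-imaging numerics: relative qPCR expression by the
2^-ΔΔCT method, Western-blot band ratios (e.g. LC3-II/I,
p-CaMKIIδ/CaMKIIδ) with optional normalization to a control-group mean,
and two-sample t comparisons with Holm–Šidák or Tukey multiplicity
adjustment as used for the figure asterisks.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "DdctInput",
    "ComparisonResult",
    "fold_change_ddct",
    "band_ratio",
    "normalize_to_control",
    "holm_sidak_adjust",
    "pairwise_compare",
]


@dataclass(frozen=True)
class DdctInput:
    """CT quadruple for one gene: target/reference in sample and control."""

    ct_target_sample: float
    ct_ref_sample: float
    ct_target_control: float
    ct_ref_control: float

    def __post_init__(self) -> None:
        for name in (
            "ct_target_sample",
            "ct_ref_sample",
            "ct_target_control",
            "ct_ref_control",
        ):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")


def fold_change_ddct(inp: DdctInput) -> float:
    """Relative expression fold change by the 2^-ΔΔCT method.

    ΔCT = CT(target) - CT(reference) within each condition;
    ΔΔCT = ΔCT(sample) - ΔCT(control); returns 2^-ΔΔCT. Equal CTs give
    1.0, and swapping sample and control inverts the fold change.
    """
    dct_sample = inp.ct_target_sample - inp.ct_ref_sample
    dct_control = inp.ct_target_control - inp.ct_ref_control
    return float(2.0 ** -(dct_sample - dct_control))


def band_ratio(numerator_intensity: float, denominator_intensity: float) -> float:
    """Densitometry band ratio (e.g. LC3-II / LC3-I).

    A plain intensity ratio: invariant to a common exposure scaling of
    both bands. The denominator must be positive.
    """
    if denominator_intensity <= 0:
        raise ValueError(
            f"denominator intensity must be positive, got {denominator_intensity}"
        )
    return float(numerator_intensity) / float(denominator_intensity)


def normalize_to_control(
    values: Sequence[float], control_values: Sequence[float]
) -> np.ndarray:
    """Rescale measurements so the control-group mean maps to exactly 1.0."""
    ctrl = np.asarray(control_values, dtype=float)
    m = float(np.mean(ctrl))
    if m <= 0:
        raise ValueError("control mean must be positive for normalization")
    return np.asarray(values, dtype=float) / m


def holm_sidak_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm–Šidák step-down adjusted p-values.

    Sort the m raw p-values ascending; the i-th smallest (1-based) is
    adjusted to ``1 - (1 - p_(i))^(m - i + 1)``, then a running maximum
    enforces monotone nondecreasing adjusted values in raw-p order.
    A single test is returned unchanged.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m, dtype=float)
    running = 0.0
    for rank, idx in enumerate(order):
        a = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, a)
        adj[idx] = min(1.0, running)
    return adj


@dataclass
class ComparisonResult:
    """One pairwise group comparison with its multiplicity-adjusted p."""

    group_a: str
    group_b: str
    statistic: float
    raw_p: float
    adj_p: float
    method: str
    n_a: int
    n_b: int
    skipped_reason: str | None = None


def pairwise_compare(
    values_by_group: Mapping[str, Sequence[float]],
    comparisons: Sequence[tuple[str, str]] | None = None,
    method: str = "holm_sidak",
    equal_var: bool = True,
) -> list[ComparisonResult]:
    """Two-sided two-sample t comparisons with multiplicity adjustment.

    ``method``: ``"holm_sidak"`` adjusts the family of requested pairs by
    the Šidák step-down; ``"tukey"`` uses studentized-range (Tukey HSD)
    adjusted p-values computed across *all* groups with n >= 2 (pooled
    variance, the classical post-hoc setting); ``"none"`` reports raw p.
    The per-pair statistic and raw p come from the two-sample t-test
    (pooled variance by default, Welch with ``equal_var=False``). Groups
    with fewer than two observations are skipped with a reason. Adjusted
    p-values never fall below the raw p.
    """
    if method not in ("holm_sidak", "tukey", "none"):
        raise ValueError("method must be 'holm_sidak', 'tukey' or 'none'")
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if comparisons is None:
        comparisons = list(combinations(groups.keys(), 2))

    results: list[ComparisonResult] = []
    testable: list[int] = []
    for a, b in comparisons:
        for name in (a, b):
            if name not in groups:
                raise KeyError(f"unknown group {name!r}")
        na, nb = groups[a].size, groups[b].size
        if na < 2 or nb < 2:
            small = a if na < 2 else b
            results.append(
                ComparisonResult(
                    a, b, float("nan"), float("nan"), float("nan"), method, na, nb,
                    skipped_reason=f"group {small!r} has n < 2",
                )
            )
            continue
        t, p = sps.ttest_ind(groups[a], groups[b], equal_var=equal_var)
        testable.append(len(results))
        results.append(
            ComparisonResult(a, b, float(t), float(p), float(p), method, na, nb)
        )

    if not testable:
        return results

    if method == "holm_sidak":
        adj = holm_sidak_adjust([results[i].raw_p for i in testable])
        for i, a_p in zip(testable, adj):
            results[i].adj_p = float(a_p)
    elif method == "tukey":
        big = {k: v for k, v in groups.items() if v.size >= 2}
        names = list(big.keys())
        if len(names) < 2:
            raise ValueError("Tukey adjustment needs at least two groups with n >= 2")
        hsd = sps.tukey_hsd(*[big[k] for k in names])
        pos = {k: i for i, k in enumerate(names)}
        for i in testable:
            r = results[i]
            tukey_p = float(hsd.pvalue[pos[r.group_a], pos[r.group_b]])
            # Tukey pools MSE over all groups; clip so adj_p >= raw_p holds
            r.adj_p = float(min(1.0, max(tukey_p, r.raw_p)))
    return results
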