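"""Proportion-in-window cohort contrasts.

Patients are split into halves (median split) or tertiles by the
proportion of their trigger-day follicles inside a size window, and the
outcome counts are compared across groups with the Kruskal–Wallis test
followed by Dunn's post hoc pairwise comparisons.  A confounder check
compares the *total* follicle counts between the top and bottom groups:
if the groups also differ in how many follicles they have, a crude
outcome contrast would overstate the effect of the size profile.

Group 0 always holds the lowest proportions and group k−1 the highest;
``delta_top_bottom`` is mean(top) − mean(bottom).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort, DegenerateError, OUTCOMES, ValidationError, Window

__all__ = [
    "GroupAssignment",
    "ContrastResult",
    "split_by_proportion",
    "kruskal_wallis",
    "dunn_posthoc",
    "contrast_report",
]

CORRECTIONS = ("none", "bonferroni", "holm")


@dataclass
class GroupAssignment:
    """Per-patient group labels 0..k−1 from a proportion split."""

    labels: np.ndarray
    k: int
    boundaries: tuple[float, ...]

    def group_sizes(self) -> list[int]:
        return [int((self.labels == g).sum()) for g in range(self.k)]


def split_by_proportion(cohort: Cohort, window: Window, k: int) -> GroupAssignment:
    """Rank patients by proportion-in-window and cut into k near-equal groups.

    Ties at a boundary are resolved by stable (file) order, so the split
    is deterministic and seed-independent.  If every patient has the
    same proportion the split is degenerate and an error is raised.
    """
    if k not in (2, 3):
        raise ValidationError("k must be 2 (median split) or 3 (tertiles)")
    n = len(cohort)
    if k > n:
        raise ValidationError(f"cannot split {n} patients into {k} groups")
    props = cohort.proportions(window)
    if np.ptp(props) == 0.0:
        raise DegenerateError(
            f"all patients have proportion {props[0]:.3f} in window {window}; "
            "split impossible"
        )
    order = np.argsort(props, kind="stable")
    labels = np.empty(n, dtype=int)
    # rank r -> group floor(r*k/n): sizes differ by at most 1
    labels[order] = (np.arange(n) * k) // n
    boundaries = tuple(float(np.quantile(props, i / k)) for i in range(1, k))
    return GroupAssignment(labels=labels, k=k, boundaries=boundaries)


def _tie_term(pooled: np.ndarray) -> tuple[float, float]:
    """(sum(t^3 - t), N) over tie groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    t = counts.astype(float)
    return float(np.sum(t**3 - t)), float(pooled.size)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, int, float]:
    """Kruskal–Wallis H with tie correction; p from chi-square, k−1 df.

    If every pooled observation is identical the statistic is defined as
    H = 0, p = 1 (no evidence of any difference).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValidationError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if pooled.size < 5:
        raise ValidationError("need >= 5 total observations for the chi-square approximation")
    df = len(groups) - 1
    if np.ptp(pooled) == 0.0:
        return 0.0, df, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), df, float(p)


def dunn_posthoc(groups: list[np.ndarray], correction: str = "holm") -> pd.DataFrame:
    """Dunn's pairwise rank comparisons after Kruskal–Wallis.

    z_ij = (mean rank_i − mean rank_j) / sqrt(A · (1/n_i + 1/n_j)) with
    A = N(N+1)/12 − Σ(t³−t)/(12(N−1)); two-sided normal p values,
    adjusted by the chosen multiple-comparison correction.
    """
    if correction not in CORRECTIONS:
        raise ValidationError(f"unknown correction {correction!r}; choose from {CORRECTIONS}")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValidationError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    splits = np.cumsum(sizes)[:-1]
    mean_ranks = [r.mean() for r in np.split(ranks, splits)]
    tie_sum, _ = _tie_term(pooled)
    a = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            if a <= 0:  # all observations identical
                z, p = 0.0, 1.0
            else:
                se = np.sqrt(a * (1.0 / sizes[i] + 1.0 / sizes[j]))
                z = (mean_ranks[i] - mean_ranks[j]) / se
                p = float(2.0 * stats.norm.sf(abs(z)))
            rows.append({"group_i": i, "group_j": j, "z": float(z), "p_raw": p})
    out = pd.DataFrame(rows)
    if correction == "none":
        out["p_adjusted"] = out["p_raw"]
    else:
        out["p_adjusted"] = multipletests(out["p_raw"].to_numpy(), method=correction)[1]
    return out


@dataclass
class ContrastResult:
    """Group summaries, top-vs-bottom deltas and rank tests for one window."""

    window: Window
    k: int
    assignment: GroupAssignment
    #: per outcome -> DataFrame with group, n, mean, median, q1, q3
    summaries: dict[str, pd.DataFrame]
    #: outcome -> mean(top) − mean(bottom)
    delta_top_bottom: dict[str, float]
    #: outcome -> median(top) − median(bottom)
    delta_top_bottom_median: dict[str, float]
    #: outcome -> (H, df, p)
    kw: dict[str, tuple[float, int, float]]
    #: outcome -> Dunn pairwise table
    dunn: dict[str, pd.DataFrame]
    #: (mean total bottom, mean total top, p from KW k=2)
    follicle_total_check: tuple[float, float, float]


def contrast_report(
    cohort: Cohort,
    window: Window,
    k: int = 3,
    correction: str = "holm",
    outcomes: tuple[str, ...] = ("oocytes", "mature", "zygotes"),
) -> ContrastResult:
    """Full proportion-in-window contrast for one cohort and window."""
    for o in outcomes:
        if o not in OUTCOMES:
            raise ValidationError(f"unknown outcome {o!r}")
    assignment = split_by_proportion(cohort, window, k)
    labels = assignment.labels

    summaries: dict[str, pd.DataFrame] = {}
    delta: dict[str, float] = {}
    delta_med: dict[str, float] = {}
    kw: dict[str, tuple[float, int, float]] = {}
    dunn: dict[str, pd.DataFrame] = {}
    for o in outcomes:
        y = cohort.outcome_vector(o)
        groups = [y[labels == g] for g in range(k)]
        summaries[o] = pd.DataFrame(
            {
                "group": range(k),
                "n": [g.size for g in groups],
                "mean": [float(g.mean()) for g in groups],
                "median": [float(np.median(g)) for g in groups],
                "q1": [float(np.quantile(g, 0.25)) for g in groups],
                "q3": [float(np.quantile(g, 0.75)) for g in groups],
            }
        )
        delta[o] = float(groups[-1].mean() - groups[0].mean())
        delta_med[o] = float(np.median(groups[-1]) - np.median(groups[0]))
        kw[o] = kruskal_wallis(groups)
        dunn[o] = dunn_posthoc(groups, correction=correction)

    totals = cohort.totals().astype(float)
    bottom, top = totals[labels == 0], totals[labels == k - 1]
    _, _, p_tot = kruskal_wallis([bottom, top])
    check = (float(bottom.mean()), float(top.mean()), p_tot)

    return ContrastResult(
        window=window,
        k=k,
        assignment=assignment,
        summaries=summaries,
        delta_top_bottom=delta,
        delta_top_bottom_median=delta_med,
        kw=kw,
        dunn=dunn,
        follicle_total_check=check,
    )
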