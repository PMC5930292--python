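"""Counterfactual patient simulation with a fitted forest.

To isolate the effect of the size profile from the effect of follicle
number, simulate patients who all carry the same number of follicles
(20 by default) placed either entirely inside the optimal window or
entirely outside it, and compare the forest's predicted oocyte counts
between the two scenarios.

Each simulated follicle's bin is drawn uniformly over the eligible bins
(the window bins for ``all_in_window``; the 8–25 bins excluding the
window for ``all_out_window``).  Uniform allocation is a modelling
choice, exposed as a pluggable allocator for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import stats

from .cohort import (
    DegenerateError,
    MIN_DIAMETER,
    MAX_DIAMETER,
    N_BINS,
    SizeHistogram,
    ValidationError,
    Window,
)
from .forest import ForestModel, predict_matrix

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "ComparisonResult",
    "simulate_profiles",
    "compare_scenarios",
]

SCENARIOS = ("all_in_window", "all_out_window")


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulated-patient scenario."""

    scenario: str
    window: Window
    n_patients: int = 1000
    n_follicles: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValidationError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.n_patients < 1 or self.n_follicles < 1:
            raise ValidationError("n_patients and n_follicles must be >= 1")
        if not self.eligible_bins():
            raise DegenerateError(
                f"scenario {self.scenario} has no eligible bins for window {self.window}"
            )

    def eligible_bins(self) -> list[int]:
        full = range(MIN_DIAMETER, MAX_DIAMETER + 1)
        if self.scenario == "all_in_window":
            return [d for d in full if d in self.window]
        return [d for d in full if d not in self.window]


@dataclass
class ScenarioResult:
    """Predicted outcome distribution for one scenario."""

    mean_pred: float
    #: across-patient 95% quantiles of the per-patient predictions
    pred_limits: tuple[float, float]
    #: per-tree 95% quantiles of tree-level mean predictions
    tree_limits: tuple[float, float]
    predictions: np.ndarray
    #: fraction of profiles with any bin count outside the training range
    coverage_outside: float


@dataclass
class ComparisonResult:
    a: ScenarioResult
    b: ScenarioResult
    diff: float
    p: float


def simulate_profiles(
    spec: ScenarioSpec,
    allocator: Optional[Callable[[np.random.Generator, list[int], int], np.ndarray]] = None,
) -> list[SizeHistogram]:
    """Simulate ``n_patients`` histograms of ``n_follicles`` follicles each.

    ``allocator(rng, bins, n_follicles)`` returns the per-follicle bin
    draws; the default draws uniformly over the eligible bins.
    """
    rng = np.random.default_rng(spec.seed)
    bins = spec.eligible_bins()
    if allocator is None:
        allocator = lambda r, b, m: np.asarray(b)[r.integers(0, len(b), size=m)]
    out = []
    for _ in range(spec.n_patients):
        drawn = np.asarray(allocator(rng, bins, spec.n_follicles), dtype=np.int64)
        arr = np.bincount(drawn - MIN_DIAMETER, minlength=N_BINS)
        out.append(SizeHistogram(arr.astype(np.int64)))
    return out


def _scenario_result(forest: ForestModel, profiles: list[SizeHistogram], level: float = 0.95) -> ScenarioResult:
    X = np.stack([h.as_array() for h in profiles]).astype(float)
    per_tree = predict_matrix(forest, X, per_tree=True)  # (n_trees, n_patients)
    preds = per_tree.mean(axis=0)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(preds, [alpha, 1.0 - alpha])
    tree_means = per_tree.mean(axis=1)
    tlo, thi = np.quantile(tree_means, [alpha, 1.0 - alpha])
    if forest.feature_min is not None:
        outside = (X < forest.feature_min) | (X > forest.feature_max)
        coverage = float(outside.any(axis=1).mean())
    else:
        coverage = float("nan")
    return ScenarioResult(
        mean_pred=float(preds.mean()),
        pred_limits=(float(min(lo, preds.mean())), float(max(hi, preds.mean()))),
        tree_limits=(float(tlo), float(thi)),
        predictions=preds,
        coverage_outside=coverage,
    )


def compare_scenarios(
    forest: ForestModel,
    spec_a: ScenarioSpec,
    spec_b: ScenarioSpec,
    test: str = "mannwhitney",
) -> ComparisonResult:
    """Predict both scenarios and test the difference in predictions.

    ``diff`` is mean(a) − mean(b); the p value comes from a two-sided
    Mann–Whitney U test on the two prediction samples (Welch's t test
    available as ``test="welch"``).
    """
    res_a = _scenario_result(forest, simulate_profiles(spec_a))
    res_b = _scenario_result(forest, simulate_profiles(spec_b))
    pa, pb = res_a.predictions, res_b.predictions
    if np.ptp(np.concatenate([pa, pb])) == 0.0:
        p = 1.0  # constant forest: scenarios indistinguishable
    elif test == "mannwhitney":
        p = float(stats.mannwhitneyu(pa, pb, alternative="two-sided").pvalue)
    elif test == "welch":
        p = float(stats.ttest_ind(pa, pb, equal_var=False).pvalue)
    else:
        raise ValidationError(f"unknown test {test!r}")
    return ComparisonResult(a=res_a, b=res_b, diff=float(pa.mean() - pb.mean()), p=p)
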