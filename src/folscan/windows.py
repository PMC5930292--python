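"""Exhaustive size-window regression scan.

Stage one of the analysis: for every contiguous diameter window
[lo, hi] within 8–25 mm, regress the outcome count on the number of
follicles inside the window with simple least squares, and report the
window with the highest coefficient of determination r².  With 18 bins
there are 18·19/2 = 171 windows.

Conventions for degenerate fits (constant predictor or constant
outcome) are explicit: a window whose count does not vary across the
cohort is kept in the result with r² = 0 and flagged degenerate, so
every scan reports all 171 windows; a constant outcome gives r² = 0 and
p = 1.  No multiple-testing adjustment is applied across windows — the
scan reports raw r² and p, and is a screening step, not an inferential
one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    Cohort,
    DegenerateError,
    MIN_DIAMETER,
    MAX_DIAMETER,
    ValidationError,
    Window,
)

__all__ = ["OLSFit", "WindowScanResult", "enumerate_windows", "fit_simple_ols", "scan_windows"]


@dataclass(frozen=True)
class OLSFit:
    """Simple least-squares fit of outcome on one predictor."""

    slope: float
    intercept: float
    r2: float
    p_slope: float
    n: int
    degenerate: bool = False


def enumerate_windows(min_d: int = MIN_DIAMETER, max_d: int = MAX_DIAMETER) -> list[Window]:
    """All contiguous windows [lo, hi] with min_d <= lo <= hi <= max_d,
    in lexicographic order."""
    if not (MIN_DIAMETER <= min_d <= max_d <= MAX_DIAMETER):
        raise ValidationError(
            f"require {MIN_DIAMETER} <= min_d <= max_d <= {MAX_DIAMETER}, "
            f"got ({min_d}, {max_d})"
        )
    return [Window(lo, hi) for lo in range(min_d, max_d + 1) for hi in range(lo, max_d + 1)]


def fit_simple_ols(x, y) -> OLSFit:
    """Least-squares line y = slope·x + intercept with r² and a two-sided
    t test on the slope (n − 2 degrees of freedom).

    A constant predictor is an error (the caller decides how to handle
    degenerate windows); a constant outcome yields r² = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 3:
        raise ValidationError("need at least 3 observations for inference")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    sxy = float(xc @ yc)
    if sxx == 0.0:
        raise DegenerateError("predictor is constant; slope undefined")
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    if syy == 0.0:
        return OLSFit(slope=slope, intercept=intercept, r2=0.0, p_slope=1.0, n=n)
    ss_res = syy - slope * sxy
    r2 = 1.0 - ss_res / syy
    # guard tiny negative residual SS from cancellation on perfect fits
    se2 = max(ss_res, 0.0) / ((n - 2) * sxx)
    if se2 == 0.0:
        p = 0.0
    else:
        t = slope / np.sqrt(se2)
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return OLSFit(slope=float(slope), intercept=intercept, r2=float(min(max(r2, 0.0), 1.0)),
                  p_slope=p, n=n)


@dataclass
class WindowScanResult:
    """All 171 per-window fits plus the argmax-r² window."""

    fits: dict[Window, OLSFit]
    best_window: Window
    outcome: str

    @property
    def best_fit(self) -> OLSFit:
        return self.fits[self.best_window]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "lo": w.lo,
                "hi": w.hi,
                "n": f.n,
                "slope": f.slope,
                "intercept": f.intercept,
                "r2": f.r2,
                "p": f.p_slope,
                "degenerate": f.degenerate,
            }
            for w, f in sorted(self.fits.items())
        ]
        return pd.DataFrame(rows)


def scan_windows(
    cohort: Cohort,
    outcome: str,
    min_d: int = MIN_DIAMETER,
    max_d: int = MAX_DIAMETER,
) -> WindowScanResult:
    """Fit every window's simple OLS and select the argmax-r² window.

    Ties on r² are broken toward the narrower window, then the lower
    ``lo``.  If every window is degenerate (all patients share one
    histogram) a :class:`DegenerateError` is raised.
    """
    if len(cohort) < 3:
        raise ValidationError("need a cohort of at least 3 patients")
    windows = enumerate_windows(min_d, max_d)
    X = cohort.design_matrix()
    y = cohort.outcome_vector(outcome)
    n = len(cohort)

    # prefix sums make each window count an O(1) column difference
    P = np.concatenate([np.zeros((n, 1), dtype=np.int64), np.cumsum(X, axis=1)], axis=1)
    counts = np.stack(
        [P[:, w.hi - MIN_DIAMETER + 1] - P[:, w.lo - MIN_DIAMETER] for w in windows],
        axis=1,
    ).astype(float)

    xm = counts.mean(axis=0)
    xc = counts - xm
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = xc.T @ yc
    syy = float(yc @ yc)

    fits: dict[Window, OLSFit] = {}
    ok = sxx > 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(ok, sxy / np.where(ok, sxx, 1.0), 0.0)
        ss_res = syy - slope * sxy
        r2 = np.where(ok & (syy > 0), 1.0 - ss_res / syy if syy > 0 else 0.0, 0.0)
        r2 = np.clip(r2, 0.0, 1.0)
        se2 = np.maximum(ss_res, 0.0) / ((n - 2) * np.where(ok, sxx, 1.0))
        tstat = np.where(se2 > 0, slope / np.sqrt(np.where(se2 > 0, se2, 1.0)), np.inf)
        pvals = np.where(
            ok & (syy > 0),
            np.where(np.isinf(tstat), 0.0, 2.0 * stats.t.sf(np.abs(tstat), n - 2)),
            1.0,
        )
    intercepts = y.mean() - slope * xm

    for j, w in enumerate(windows):
        fits[w] = OLSFit(
            slope=float(slope[j]),
            intercept=float(intercepts[j]),
            r2=float(r2[j]),
            p_slope=float(pvals[j]),
            n=n,
            degenerate=not bool(ok[j]),
        )
    if not ok.any():
        raise DegenerateError(
            "every window has a constant follicle count across the cohort "
            "(all patients share one histogram); scan is undefined"
        )
    best = max(fits, key=lambda w: (fits[w].r2, -w.width, -w.lo))
    return WindowScanResult(fits=fits, best_window=best, outcome=outcome)
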