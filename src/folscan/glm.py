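"""Multi-predictor per-diameter regression (generalized linear model stage).

The single-window scan compares size categories one at a time, and
overlapping windows share follicles, so its fits are autocorrelated.
This stage instead regresses the outcome on all 18 per-diameter counts
simultaneously and reads off which diameters carry independent signal.

The default family is Gaussian with identity link, which reports a
conventional r² for the whole model; a Poisson log-link fit (IRLS, Wald
z tests) is offered as an alternative for the count outcomes.  Columns
with zero variance in the cohort (e.g. nobody has a 25 mm follicle)
cannot be tested: they are dropped from the design, flagged, and
reported with p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort, DegenerateError, DIAMETERS, ValidationError

__all__ = ["GLMFit", "fit_diameter_glm", "significance_table", "star_code"]

FAMILIES = ("gaussian_identity", "poisson_log")

#: Printed significance tiers: * p<0.05, ** p<0.01, *** p<0.0001.
STAR_TIERS = ((1e-4, "***"), (1e-2, "**"), (5e-2, "*"))


def star_code(p: float) -> str:
    """Star code for a p value (three tiers, '' if not significant)."""
    for cut, stars in STAR_TIERS:
        if p < cut:
            return stars
    return ""


@dataclass
class GLMFit:
    """Per-diameter coefficients, standard errors and p values."""

    coef: dict[int, float]
    se: dict[int, float]
    p: dict[int, float]
    intercept: float
    r2_model: float
    n: int
    outcome: str
    family: str
    dropped: tuple[int, ...] = ()

    def significant(self, alpha: float = 0.05) -> list[int]:
        return [d for d in DIAMETERS if self.p[d] < alpha]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "diameter": d,
                "coef": self.coef[d],
                "se": self.se[d],
                "p": self.p[d],
                "stars": star_code(self.p[d]),
                "degenerate": d in self.dropped,
            }
            for d in DIAMETERS
        ]
        return pd.DataFrame(rows)


def _collinear_columns(X: np.ndarray, diams: list[int]) -> list[int]:
    """Columns whose removal does not reduce the design rank."""
    Xc = np.column_stack([np.ones(len(X)), X])
    full_rank = np.linalg.matrix_rank(Xc)
    out = []
    for j, d in enumerate(diams):
        sub = np.delete(Xc, j + 1, axis=1)
        if np.linalg.matrix_rank(sub) == full_rank:
            out.append(d)
    return out


def fit_diameter_glm(
    cohort: Cohort, outcome: str, family: str = "gaussian_identity"
) -> GLMFit:
    """Regress ``outcome`` on all per-diameter counts at once.

    Gaussian-identity: ordinary least squares with two-sided t tests
    per coefficient and r² = 1 − SSres/SStot.  Poisson-log: IRLS with
    Wald z tests; ``r2_model`` is then the deviance-based pseudo-r²
    (1 − deviance/null deviance).
    """
    if family not in FAMILIES:
        raise ValidationError(f"unknown family {family!r}; choose from {FAMILIES}")
    X = cohort.design_matrix().astype(float)
    y = cohort.outcome_vector(outcome)
    n = len(cohort)

    variable = X.std(axis=0) > 0
    dropped = tuple(d for d, v in zip(DIAMETERS, variable) if not v)
    keep = [i for i, v in enumerate(variable) if v]
    if not keep:
        raise DegenerateError(
            "every diameter count is constant across the cohort; nothing to fit"
        )
    if n <= len(keep) + 1:
        raise ValidationError(
            f"cohort of {n} too small for {len(keep)} non-degenerate predictors"
        )
    Xk = X[:, keep]
    diams = [DIAMETERS[i] for i in keep]
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), Xk])) < len(keep) + 1:
        bad = _collinear_columns(Xk, diams)
        raise DegenerateError(f"singular design matrix; collinear diameter columns: {bad}")

    Xc = sm.add_constant(Xk, prepend=True)
    if family == "gaussian_identity":
        res = sm.OLS(y, Xc).fit()
        r2_model = float(res.rsquared)
    else:
        model = sm.GLM(y, Xc, family=sm.families.Poisson())
        res = model.fit(maxiter=100, tol=1e-8)
        if not res.converged:
            raise ValidationError(
                f"Poisson IRLS did not converge in 100 iterations "
                f"(deviance trace tail: {res.fit_history['deviance'][-3:]})"
            )
        r2_model = float(1.0 - res.deviance / res.null_deviance)

    coef = {d: 0.0 for d in DIAMETERS}
    se = {d: float("nan") for d in DIAMETERS}
    p = {d: 1.0 for d in DIAMETERS}
    for j, d in enumerate(diams):
        coef[d] = float(res.params[j + 1])
        se[d] = float(res.bse[j + 1])
        p[d] = float(res.pvalues[j + 1])
    return GLMFit(
        coef=coef,
        se=se,
        p=p,
        intercept=float(res.params[0]),
        r2_model=r2_model,
        n=n,
        outcome=outcome,
        family=family,
        dropped=dropped,
    )


def significance_table(fits: list[GLMFit]) -> pd.DataFrame:
    """Diameter-by-fit matrix of p values with star codes.

    Mirrors the published table layout: one row per diameter 8–25, one
    column pair (p, stars) per fitted outcome/cohort.
    """
    if not fits:
        raise ValidationError("need at least one fit")
    data: dict[str, list] = {"diameter": list(DIAMETERS)}
    for f in fits:
        label = f"{f.outcome}"
        if sum(g.outcome == f.outcome for g in fits) > 1:
            label = f"{f.outcome}[{fits.index(f)}]"
        data[f"p_{label}"] = [f.p[d] for d in DIAMETERS]
        data[f"stars_{label}"] = [star_code(f.p[d]) for d in DIAMETERS]
    return pd.DataFrame(data)
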