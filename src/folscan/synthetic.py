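"""Synthetic trigger-day cohorts with a known diameter→oocyte yield curve.

Real trigger-day data are shaped by the clinical trigger rule — the
trigger is given once two to three lead follicles reach 17–18 mm — so a
patient's size histogram is a snapshot conditioned on that rule firing.
The generator emulates this by drawing a per-patient diameter sample
from a skew-normal distribution and rigidly shifting it so that the
n-th largest follicle sits exactly at the lead threshold, i.e. the scan
was taken on the morning the rule fired.  Outcomes follow the premise
that follicles that are too small or too large are less likely to yield
a mature oocyte: each follicle yields an oocyte with a probability
given by a diameter-dependent yield curve, and downstream counts
(mature, zygote, embryo, grade-1 embryo) are nested Bernoulli
thinnings.

The latent per-follicle draws are retained in :class:`GroundTruth`, so
recovery tests can compare what an analysis found with what was planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
from scipy import stats

from .cohort import (
    Cohort,
    PatientRecord,
    SizeHistogram,
    ValidationError,
    Window,
    histogram_from_diameters,
    MIN_DIAMETER,
    MAX_DIAMETER,
)

__all__ = [
    "YieldCurve",
    "CountDistribution",
    "DiameterDistribution",
    "TriggerRule",
    "GeneratorConfig",
    "GroundTruth",
    "yield_probability",
    "simulate_trigger_day_profile",
    "generate_cohort",
    "preset",
    "PRESETS",
]


@dataclass(frozen=True)
class YieldCurve:
    """Per-follicle probability of yielding an oocyte as a function of diameter.

    ``step`` is an indicator plateau: probability ``p_in`` for
    diameters in [lo_true, hi_true], ``p_out`` elsewhere.
    ``double_logistic`` smooths both edges with logistic shoulders of
    scale ``edge_scale`` mm:

        p(d) = p_out + (p_in - p_out) * sigma((d - lo)/s) * sigma((hi - d)/s)
    """

    shape: Literal["step", "double_logistic"] = "step"
    lo_true: float = 12.0
    hi_true: float = 19.0
    p_in: float = 0.8
    p_out: float = 0.1
    edge_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ValidationError("require 0 <= p_out <= p_in <= 1")
        if not self.lo_true < self.hi_true:
            raise ValidationError("require lo_true < hi_true")
        if self.shape == "double_logistic" and self.edge_scale <= 0:
            raise ValidationError("edge_scale must be > 0")
        if self.shape not in ("step", "double_logistic"):
            raise ValidationError(f"unknown curve shape {self.shape!r}")


def yield_probability(d, curve: YieldCurve):
    """Evaluate the yield curve at diameter(s) ``d`` (mm). Vectorized."""
    d = np.asarray(d, dtype=float)
    if curve.shape == "step":
        p = np.where((d >= curve.lo_true) & (d <= curve.hi_true), curve.p_in, curve.p_out)
    else:
        s = curve.edge_scale
        lo_edge = 1.0 / (1.0 + np.exp(-(d - curve.lo_true) / s))
        hi_edge = 1.0 / (1.0 + np.exp(-(curve.hi_true - d) / s))
        p = curve.p_out + (curve.p_in - curve.p_out) * lo_edge * hi_edge
    return float(p) if p.ndim == 0 else p


@dataclass(frozen=True)
class CountDistribution:
    """Distribution of the number of follicles visible on day of trigger.

    ``dispersion`` is the negative-binomial size parameter k, with
    variance mean + mean^2/k (ignored for the Poisson family).
    """

    family: Literal["negative_binomial", "poisson"] = "negative_binomial"
    mean: float = 14.0
    dispersion: float = 50.0

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValidationError("count mean must be > 0")
        if self.family == "negative_binomial" and self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        if self.family not in ("negative_binomial", "poisson"):
            raise ValidationError(f"unknown count family {self.family!r}")

    def sample(self, rng: np.random.Generator, minimum: int) -> int:
        """Draw one count, truncated below at ``minimum`` by resampling."""
        while True:
            if self.family == "poisson":
                n = int(rng.poisson(self.mean))
            else:
                k = self.dispersion
                n = int(rng.negative_binomial(k, k / (k + self.mean)))
            if n >= minimum:
                return n


@dataclass(frozen=True)
class DiameterDistribution:
    """Skew-normal model of raw (pre-shift) follicle diameters.

    ``mean`` and ``sd`` are the location and scale parameters of the
    skew-normal, ``skew`` its shape parameter (negative = left tail of
    smaller follicles trailing behind the leads).  ``spread_sigma`` is
    the log-normal sigma of a per-patient multiplier on ``sd``: patients
    differ in how synchronized their follicular cohort is, which is what
    makes the proportion of follicles inside a size window vary across
    patients (from well under 70% to 100%).
    """

    mean: float = 14.0
    sd: float = 3.0
    skew: float = -2.0
    spread_sigma: float = 0.35

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValidationError("diameter sd must be > 0")
        if self.spread_sigma < 0:
            raise ValidationError("spread_sigma must be >= 0")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw one patient's raw diameters (one spread multiplier per call)."""
        scale = self.sd * rng.lognormal(0.0, self.spread_sigma) if self.spread_sigma else self.sd
        return stats.skewnorm.rvs(
            self.skew, loc=self.mean, scale=scale, size=size, random_state=rng
        )


@dataclass(frozen=True)
class TriggerRule:
    """Clinical trigger rule: n_lead follicles at or beyond lead_mm."""

    n_lead: int = 2
    lead_mm: float = 17.0

    def __post_init__(self) -> None:
        if self.n_lead < 1:
            raise ValidationError("n_lead must be >= 1")
        if self.lead_mm <= 0:
            raise ValidationError("lead_mm must be > 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cohort.

    Outcome-cascade probabilities are per-item Bernoulli thinning rates
    (oocyte→mature→zygote→embryo→grade-1); defaults reflect typical
    laboratory rates (≈80% maturity, ≈70% fertilisation, ≈50% cleavage
    to transferable embryo, ≈40% of embryos top grade).
    """

    n_patients: int = 500
    follicle_count_dist: CountDistribution = field(default_factory=CountDistribution)
    diameter_dist: DiameterDistribution = field(default_factory=DiameterDistribution)
    trigger_rule: TriggerRule = field(default_factory=TriggerRule)
    yield_curve: YieldCurve = field(default_factory=YieldCurve)
    p_mature_given_oocyte: float = 0.8
    p_zygote_given_mature: float = 0.7
    p_embryo_given_zygote: float = 0.5
    p_grade1_given_embryo: float = 0.4
    seed: int = 0
    trigger_label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        for name in (
            "p_mature_given_oocyte",
            "p_zygote_given_mature",
            "p_embryo_given_zygote",
            "p_grade1_given_embryo",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "follicle_count_dist" in d and isinstance(d["follicle_count_dist"], dict):
            d["follicle_count_dist"] = CountDistribution(**d["follicle_count_dist"])
        if "diameter_dist" in d and isinstance(d["diameter_dist"], dict):
            d["diameter_dist"] = DiameterDistribution(**d["diameter_dist"])
        if "trigger_rule" in d and isinstance(d["trigger_rule"], dict):
            d["trigger_rule"] = TriggerRule(**d["trigger_rule"])
        if "yield_curve" in d and isinstance(d["yield_curve"], dict):
            d["yield_curve"] = YieldCurve(**d["yield_curve"])
        return cls(**d)


#: Presets matching the three study arms at cohort scale.  They differ
#: in the follicle-count distribution (medians 14 / 17 / 27 follicles on
#: day of trigger) and the lead rule (kisspeptin waits for three
#: follicles >= 18 mm); everything else is shared.
PRESETS: dict[str, dict] = {
    "hcg_like": dict(
        follicle_count_dist=CountDistribution("negative_binomial", 14.0, 50.0),
        trigger_rule=TriggerRule(2, 17.0),
        trigger_label="hcg",
    ),
    "gnrha_like": dict(
        follicle_count_dist=CountDistribution("negative_binomial", 17.0, 6.0),
        trigger_rule=TriggerRule(2, 17.0),
        trigger_label="gnrha",
    ),
    "kisspeptin_like": dict(
        follicle_count_dist=CountDistribution("negative_binomial", 27.0, 5.0),
        trigger_rule=TriggerRule(3, 18.0),
        trigger_label="kisspeptin",
    ),
}


def preset(name: str, **overrides) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from a named preset.

    ``overrides`` are passed through to the config (e.g. ``n_patients``,
    ``seed``, ``yield_curve``).
    """
    if name not in PRESETS:
        raise ValidationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    kw.update(overrides)
    return GeneratorConfig(**kw)


def _profile_diameters(rng: np.random.Generator, config: GeneratorConfig) -> np.ndarray:
    """Binned integer diameters for one patient (floor/pooling applied)."""
    rule = config.trigger_rule
    n = config.follicle_count_dist.sample(rng, rule.n_lead)
    raw = config.diameter_dist.sample(rng, n)
    # rigid shift so the n_lead-th largest follicle sits at the lead
    # threshold: the scan is taken on the morning the trigger rule fires
    lead = np.partition(raw, n - rule.n_lead)[n - rule.n_lead]
    raw = raw + (rule.lead_mm - lead)
    # a wide spread can push the smallest draws to or below zero after
    # the shift; they are far under the 8 mm aspiration floor either way
    raw = raw[raw > 0.0]
    h = histogram_from_diameters(raw)
    # recover the binned per-follicle diameters (order irrelevant downstream)
    return np.repeat(
        np.arange(MIN_DIAMETER, MAX_DIAMETER + 1), h.as_array()
    )


def simulate_trigger_day_profile(
    rng: np.random.Generator, config: GeneratorConfig
) -> SizeHistogram:
    """Draw one patient's trigger-day size histogram."""
    return histogram_from_diameters(_profile_diameters(rng, config).astype(float))


@dataclass
class GroundTruth:
    """Latent per-follicle draws underlying a synthetic cohort."""

    yield_curve: YieldCurve
    #: per patient: binned follicle diameters (mm)
    diameters: list[np.ndarray]
    #: per patient: boolean, follicle yielded an oocyte
    oocyte: list[np.ndarray]
    #: per patient: boolean, follicle yielded a *mature* oocyte
    mature: list[np.ndarray]

    def expected_oocytes(self, h: SizeHistogram) -> float:
        """Analytic E[n_oocytes | histogram] = sum_d counts[d] * p(d)."""
        d = np.arange(MIN_DIAMETER, MAX_DIAMETER + 1, dtype=float)
        return float(np.dot(h.as_array(), yield_probability(d, self.yield_curve)))

    def expected_mature(self, h: SizeHistogram, p_mature: float) -> float:
        return self.expected_oocytes(h) * p_mature

    def to_json(self) -> str:
        payload = {
            "yield_curve": asdict(self.yield_curve),
            "patients": [
                {
                    "diameters": d.tolist(),
                    "oocyte": o.astype(int).tolist(),
                    "mature": m.astype(int).tolist(),
                }
                for d, o, m in zip(self.diameters, self.oocyte, self.mature)
            ],
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a synthetic cohort and its latent ground truth.

    A single seeded generator is threaded through all draws in fixed
    patient order, so the same config reproduces the cohort exactly.
    """
    rng = np.random.default_rng(config.seed)
    records: list[PatientRecord] = []
    truth = GroundTruth(config.yield_curve, [], [], [])
    width = max(5, len(str(config.n_patients)))
    for i in range(config.n_patients):
        d = _profile_diameters(rng, config)
        p = yield_probability(d.astype(float), config.yield_curve)
        oo = rng.random(d.size) < p
        mat = oo & (rng.random(d.size) < config.p_mature_given_oocyte)
        n_oo = int(oo.sum())
        n_mat = int(mat.sum())
        n_zyg = int(rng.binomial(n_mat, config.p_zygote_given_mature))
        n_emb = int(rng.binomial(n_zyg, config.p_embryo_given_zygote))
        n_g1 = int(rng.binomial(n_emb, config.p_grade1_given_embryo))
        h = SizeHistogram(np.bincount(d - MIN_DIAMETER, minlength=18).astype(np.int64))
        records.append(
            PatientRecord(
                patient_id=f"S{i:0{width}d}",
                trigger=config.trigger_label,
                histogram=h,
                n_oocytes=n_oo,
                n_mature=n_mat,
                n_zygotes=n_zyg,
                n_embryos=n_emb,
                n_grade1=n_g1,
            )
        )
        truth.diameters.append(d)
        truth.oocyte.append(oo)
        truth.mature.append(mat)
    return Cohort(records), truth
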