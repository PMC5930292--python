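import numpy as np
import pytest

import folscan as fs
from folscan.cohort import DIAMETERS, MIN_DIAMETER, Cohort, PatientRecord, SizeHistogram


def cohort_from_matrix(X, y, outcome="oocytes", trigger="synthetic"):
    """Build a cohort from an n x 18 count matrix and one outcome vector.

    The chosen outcome gets y; the rest are set to keep invariants
    (mature <= oocytes etc.) satisfied.
    """
    X = np.asarray(X, dtype=np.int64)
    y = np.asarray(y)
    records = []
    for i in range(X.shape[0]):
        v = int(round(float(y[i])))
        v = max(v, 0)
        counts = dict(n_oocytes=0, n_mature=0, n_zygotes=0, n_embryos=0, n_grade1=0)
        if outcome == "oocytes":
            counts["n_oocytes"] = v
        elif outcome == "mature":
            counts["n_oocytes"] = v
            counts["n_mature"] = v
        else:
            counts[f"n_{outcome}"] = v
        records.append(
            PatientRecord(f"P{i:04d}", trigger, SizeHistogram(X[i]), **counts)
        )
    return Cohort(records)


@pytest.fixture(scope="session")
def step_curve():
    return fs.YieldCurve("step", 12, 19, 0.8, 0.05)


@pytest.fixture(scope="session")
def step_cohort(step_curve):
    """n=300 synthetic cohort driven by the step yield curve [12, 19]."""
    cfg = fs.preset("hcg_like", n_patients=300, seed=42, yield_curve=step_curve)
    cohort, truth = fs.generate_cohort(cfg)
    return cohort, truth, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
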