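"""Core data types for trigger-day follicle cohorts.

An IVF cycle is summarised on the morning of trigger by the ultrasound
follicle diameters, recorded here as counts per integer millimetre bin
over the aspirated range 8–25 mm, together with downstream laboratory
outcome counts (oocytes, mature oocytes, zygotes, embryos, grade-1
embryos).  Everything downstream — the window scan, the per-diameter
GLM, the regression forest, the proportion contrasts — consumes these
types.

Binning convention: a measured diameter is rounded half-away-from-zero
to the nearest integer millimetre; diameters below 8 mm are excluded
(not aspirated at retrieval), diameters above 25 mm are pooled into the
25 mm bin.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

MIN_DIAMETER = 8
MAX_DIAMETER = 25
#: Integer mm bins used everywhere, in order.
DIAMETERS: tuple[int, ...] = tuple(range(MIN_DIAMETER, MAX_DIAMETER + 1))
N_BINS = len(DIAMETERS)

#: Outcome name -> PatientRecord attribute.
OUTCOMES: dict[str, str] = {
    "oocytes": "n_oocytes",
    "mature": "n_mature",
    "zygotes": "n_zygotes",
    "embryos": "n_embryos",
    "grade1": "n_grade1",
}

TRIGGERS = ("hcg", "gnrha", "kisspeptin", "synthetic")


class ValidationError(ValueError):
    """Raised when input data violate a domain invariant."""


class ParseError(ValidationError):
    """Raised when a cohort file cannot be parsed; names the offending row."""


class DegenerateError(ValueError):
    """Raised when an operation is undefined on degenerate input
    (zero denominator, zero-variance predictor, impossible split)."""


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (np.rint rounds half to even)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True, order=True)
class Window:
    """Contiguous diameter window [lo, hi] mm, inclusive at both ends."""

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not (MIN_DIAMETER <= self.lo <= self.hi <= MAX_DIAMETER):
            raise ValidationError(
                f"window [{self.lo}, {self.hi}] must satisfy "
                f"{MIN_DIAMETER} <= lo <= hi <= {MAX_DIAMETER}"
            )

    @property
    def width(self) -> int:
        return self.hi - self.lo + 1

    def bins(self) -> range:
        return range(self.lo, self.hi + 1)

    def __contains__(self, d: int) -> bool:
        return self.lo <= d <= self.hi

    def __str__(self) -> str:
        return f"{self.lo}-{self.hi}"

    @classmethod
    def parse(cls, text: str) -> "Window":
        """Parse 'LO:HI' or 'LO-HI'."""
        for sep in (":", "-"):
            if sep in text:
                lo, hi = text.split(sep, 1)
                return cls(int(lo), int(hi))
        raise ValidationError(f"cannot parse window {text!r}; expected LO:HI")


class SizeHistogram:
    """Counts of trigger-day follicles per integer mm bin, 8–25.

    Stored densely as an int array over :data:`DIAMETERS`; the
    ``counts`` property exposes the sparse non-zero mapping.
    """

    __slots__ = ("_arr",)

    def __init__(self, counts: Mapping[int, int] | Sequence[int] | np.ndarray = ()):
        arr = np.zeros(N_BINS, dtype=np.int64)
        if isinstance(counts, Mapping):
            for d, c in counts.items():
                d = int(d)
                if not MIN_DIAMETER <= d <= MAX_DIAMETER:
                    raise ValidationError(f"bin {d} outside {MIN_DIAMETER}..{MAX_DIAMETER}")
                if c < 0:
                    raise ValidationError(f"negative count {c} in bin {d}")
                arr[d - MIN_DIAMETER] = int(c)
        else:
            vals = np.asarray(counts, dtype=np.int64)
            if vals.size:
                if vals.shape != (N_BINS,):
                    raise ValidationError(
                        f"dense histogram must have {N_BINS} bins, got {vals.shape}"
                    )
                if (vals < 0).any():
                    raise ValidationError("negative count in histogram")
                arr = vals.copy()
        self._arr = arr

    @property
    def counts(self) -> dict[int, int]:
        return {d: int(c) for d, c in zip(DIAMETERS, self._arr) if c}

    def as_array(self) -> np.ndarray:
        """Dense counts over bins 8..25 (length 18, copy)."""
        return self._arr.copy()

    def __getitem__(self, d: int) -> int:
        if not MIN_DIAMETER <= d <= MAX_DIAMETER:
            return 0
        return int(self._arr[d - MIN_DIAMETER])

    def total(self) -> int:
        return int(self._arr.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SizeHistogram):
            return NotImplemented
        return bool(np.array_equal(self._arr, other._arr))

    def __hash__(self) -> int:
        return hash(self._arr.tobytes())

    def __repr__(self) -> str:
        return f"SizeHistogram({self.counts})"


def histogram_from_diameters(diameters: Iterable[float]) -> SizeHistogram:
    """Bin raw measured diameters (mm) into a :class:`SizeHistogram`.

    Diameters are rounded half-away-from-zero to the nearest mm; values
    below 8 mm are dropped (below the aspiration floor), values above
    25 mm are pooled into the 25 mm bin.

    Raises
    ------
    ValidationError
        If any diameter is zero or negative.
    """
    d = np.asarray(list(diameters), dtype=float)
    if d.size == 0:
        return SizeHistogram()
    if (d <= 0).any() or not np.isfinite(d).all():
        raise ValidationError("diameters must be finite and > 0 mm")
    binned = _round_half_away(d).astype(np.int64)
    binned = binned[binned >= MIN_DIAMETER]
    binned = np.minimum(binned, MAX_DIAMETER)
    arr = np.bincount(binned - MIN_DIAMETER, minlength=N_BINS)
    return SizeHistogram(arr.astype(np.int64))


def count_in_window(h: SizeHistogram, w: Window) -> int:
    """Number of follicles with binned diameter in ``w`` (inclusive)."""
    a = h.as_array()
    return int(a[w.lo - MIN_DIAMETER : w.hi - MIN_DIAMETER + 1].sum())


def proportion_in_window(h: SizeHistogram, w: Window) -> float:
    """Fraction of a patient's follicles inside ``w``; undefined on empty scans."""
    total = h.total()
    if total == 0:
        raise DegenerateError("proportion undefined: histogram has no follicles")
    return count_in_window(h, w) / total


def oocyte_yield(n: int, h: SizeHistogram, w: Window) -> float:
    """Oocyte yield: ``n`` divided by the follicle count inside ``w``.

    The denominator restricts to a size window (e.g. 12–19 mm); the
    ratio may exceed 1 because oocytes can come from follicles outside
    the window — such values are meaningful and are not clamped.
    """
    denom = count_in_window(h, w)
    if denom == 0:
        raise DegenerateError(f"oocyte yield undefined: no follicles in window {w}")
    return n / denom


@dataclass
class PatientRecord:
    """One IVF cycle: trigger-day histogram plus outcome counts."""

    patient_id: str
    trigger: str
    histogram: SizeHistogram
    n_oocytes: int
    n_mature: int
    n_zygotes: int
    n_embryos: int
    n_grade1: int

    def __post_init__(self) -> None:
        if self.trigger not in TRIGGERS:
            raise ValidationError(
                f"patient {self.patient_id}: unknown trigger {self.trigger!r}"
            )
        for name in OUTCOMES.values():
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(
                    f"patient {self.patient_id}: {name}={v!r} must be a non-negative integer"
                )
            setattr(self, name, int(v))
        if self.n_mature > self.n_oocytes:
            raise ValidationError(
                f"patient {self.patient_id}: n_mature ({self.n_mature}) > "
                f"n_oocytes ({self.n_oocytes})"
            )
        if self.n_grade1 > self.n_embryos:
            raise ValidationError(
                f"patient {self.patient_id}: n_grade1 ({self.n_grade1}) > "
                f"n_embryos ({self.n_embryos})"
            )

    def outcome(self, name: str) -> int:
        return int(getattr(self, OUTCOMES[name]))


class Cohort:
    """Ordered collection of :class:`PatientRecord` with unique ids."""

    def __init__(self, records: Sequence[PatientRecord]):
        ids = [r.patient_id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient_id(s): {dupes}")
        self.records: list[PatientRecord] = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.records[i]

    def design_matrix(self) -> np.ndarray:
        """n_patients x 18 matrix of per-bin follicle counts."""
        return np.stack([r.histogram.as_array() for r in self.records])

    def outcome_vector(self, outcome: str) -> np.ndarray:
        if outcome not in OUTCOMES:
            raise ValidationError(f"unknown outcome {outcome!r}; choose from {list(OUTCOMES)}")
        return np.array([r.outcome(outcome) for r in self.records], dtype=float)

    def totals(self) -> np.ndarray:
        return np.array([r.histogram.total() for r in self.records], dtype=np.int64)

    def proportions(self, w: Window) -> np.ndarray:
        """Per-patient proportion of follicles inside ``w`` (errors if any scan empty)."""
        out = np.empty(len(self.records))
        for i, r in enumerate(self.records):
            try:
                out[i] = proportion_in_window(r.histogram, w)
            except DegenerateError as e:
                raise DegenerateError(
                    f"patient {r.patient_id}: {e}"
                ) from None
        return out


# ---------------------------------------------------------------------------
# CSV I/O
#
# Wide layout (one row per cycle):
#   patient_id,trigger,d8,...,d25,n_oocytes,n_mature,n_zygotes,n_embryos,n_grade1
# Long layout (raw diameters, outcomes unknown):
#   patient_id,diameter_mm

_DCOLS = [f"d{d}" for d in DIAMETERS]
_WIDE_COLS = ["patient_id", "trigger"] + _DCOLS + list(OUTCOMES.values())


def read_cohort(source: str | io.TextIOBase) -> Cohort:
    """Read a cohort CSV (wide layout, or long raw-diameter layout).

    The long layout carries no outcome counts; records read from it get
    trigger ``synthetic`` and all-zero outcomes, suitable only for
    histogram-level operations.
    """
    df = pd.read_csv(source, dtype={"patient_id": str})
    cols = set(df.columns)
    if cols == {"patient_id", "diameter_mm"}:
        return _cohort_from_long(df)
    missing = [c for c in _WIDE_COLS if c not in cols]
    if missing:
        raise ParseError(f"cohort CSV missing column(s): {missing}")
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rd = row._asdict()
        try:
            counts = np.array([rd[c] for c in _DCOLS], dtype=np.int64)
            if (counts < 0).any():
                raise ValidationError("negative follicle count")
            rec = PatientRecord(
                patient_id=str(rd["patient_id"]),
                trigger=str(rd["trigger"]),
                histogram=SizeHistogram(counts),
                **{k: int(rd[k]) for k in OUTCOMES.values()},
            )
        except (ValidationError, ValueError, TypeError) as e:
            raise ParseError(f"row {row_no} (patient_id={rd.get('patient_id')!r}): {e}") from None
        records.append(rec)
    try:
        return Cohort(records)
    except ValidationError as e:
        raise ParseError(str(e)) from None


def _cohort_from_long(df: pd.DataFrame) -> Cohort:
    records = []
    for pid, grp in df.groupby("patient_id", sort=False):
        try:
            h = histogram_from_diameters(grp["diameter_mm"].to_numpy(dtype=float))
        except ValidationError as e:
            raise ParseError(f"patient_id={pid!r}: {e}") from None
        records.append(
            PatientRecord(str(pid), "synthetic", h, 0, 0, 0, 0, 0)
        )
    return Cohort(records)


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for r in cohort:
        row: dict[str, object] = {"patient_id": r.patient_id, "trigger": r.trigger}
        arr = r.histogram.as_array()
        row.update({c: int(v) for c, v in zip(_DCOLS, arr)})
        row.update({k: getattr(r, k) for k in OUTCOMES.values()})
        rows.append(row)
    return pd.DataFrame(rows, columns=_WIDE_COLS)


def write_cohort(cohort: Cohort, sink: str | io.TextIOBase) -> None:
    """Write the wide-layout CSV; write→read round-trips to an equal cohort."""
    cohort_to_frame(cohort).to_csv(sink, index=False, lineterminator="\n")
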