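"""Cap-index vulnerability scoring and OCT/IVUS agreement analysis.

The cap index is an ordinal 0-4 score driven by minimum cap thickness:
index 0 marks a slice or plaque with no lipid component (no cap points);
index 1 a cap thicker than 200 um; index 2 a cap in (150, 200] um; index 3 a
cap in (65, 150] um; index 4 a thin-cap fibroatheroma with cap <= 65 um.
Agreement between modalities is summarised by a 4x4 confusion table with OCT
as the reference, per-class prediction metrics, over/under-estimation rates
and a baseline-to-follow-up trend comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

INDEX_DESCRIPTIONS = {
    0: "no component (very stable)",
    1: "min cap thickness > 200 um (stable)",
    2: "150 um < min cap thickness <= 200 um (slightly unstable)",
    3: "65 um < min cap thickness <= 150 um (moderately unstable)",
    4: "min cap thickness <= 65 um (highly unstable)",
}

#: Comparison slack when converting mm to um, so a 0.200 mm cap sits exactly
#: on the 200 um boundary despite binary floating point.
_UM_EPS = 1e-6


class VulnerabilityError(ValueError):
    """Base class for cap-index bookkeeping failures."""


@dataclass(frozen=True)
class CapIndexScheme:
    """Thresholds (um) of the step function mapping min cap thickness to 1-4."""

    t_high_um: float = 200.0
    t_mid_um: float = 150.0
    t_low_um: float = 65.0

    def __post_init__(self) -> None:
        if not (0 < self.t_low_um < self.t_mid_um < self.t_high_um):
            raise VulnerabilityError("thresholds must satisfy 0 < low < mid < high")


DEFAULT_SCHEME = CapIndexScheme()


def assign_cap_index(
    min_capt_mm: Optional[float], scheme: CapIndexScheme = DEFAULT_SCHEME
) -> int:
    """Cap index of a slice or plaque from its minimum cap thickness.

    ``None`` (no lipid component, hence no cap points) maps to 0.  Threshold
    boundaries are inclusive on the upper edge of the lower class: exactly
    200 um is index 2, exactly 65 um is index 4.
    """
    if min_capt_mm is None:
        return 0
    if not np.isfinite(min_capt_mm) or min_capt_mm <= 0:
        raise VulnerabilityError(
            f"minimum cap thickness must be positive, got {min_capt_mm!r}"
        )
    t_um = 1000.0 * float(min_capt_mm)
    if t_um > scheme.t_high_um + _UM_EPS:
        return 1
    if t_um > scheme.t_mid_um + _UM_EPS:
        return 2
    if t_um > scheme.t_low_um + _UM_EPS:
        return 3
    return 4


@dataclass
class CapIndexConfusion:
    """4x4 count table: reference (OCT) rows x test (IVUS) columns, classes 1-4."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (4, 4) or np.any(c < 0):
            raise VulnerabilityError("confusion counts must be a nonnegative 4x4 table")
        self.counts = c

    @classmethod
    def from_indices(
        cls, ref_indices: Sequence[int], test_indices: Sequence[int]
    ) -> "CapIndexConfusion":
        ref = np.asarray(ref_indices, dtype=int)
        test = np.asarray(test_indices, dtype=int)
        if ref.shape != test.shape:
            raise VulnerabilityError("reference and test index sequences differ in length")
        for arr, name in ((ref, "reference"), (test, "test")):
            if arr.size and (arr.min() < 1 or arr.max() > 4):
                raise VulnerabilityError(f"{name} indices must lie in 1..4")
        counts = np.zeros((4, 4), dtype=int)
        np.add.at(counts, (ref - 1, test - 1), 1)
        return cls(counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        """Group sizes: slices per reference class."""
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def group_disagreement(self) -> np.ndarray:
        """Per reference class: fraction of slices whose test index differs."""
        diag = np.diag(self.counts)
        rows = self.row_totals
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(rows > 0, (rows - diag) / rows, np.nan)

    def overall_disagreement(self) -> float:
        if self.total == 0:
            raise VulnerabilityError("empty confusion table")
        return float((self.total - np.trace(self.counts)) / self.total)


def build_confusion(
    ref_indices: Sequence[int], test_indices: Sequence[int]
) -> CapIndexConfusion:
    """Tally a 4x4 cap-index confusion table (index-0 slices excluded upstream)."""
    return CapIndexConfusion.from_indices(ref_indices, test_indices)


def classification_metrics(confusion: CapIndexConfusion) -> pd.DataFrame:
    """Per-class precision, recall, specificity and NPV (percent).

    A class absent from the reference rows has all metrics undefined (NaN);
    precision is additionally undefined for an empty test column.
    """
    if confusion.total == 0:
        raise VulnerabilityError("empty confusion table")
    c = confusion.counts
    total = confusion.total
    rows, cols = confusion.row_totals, confusion.col_totals
    out = []
    for k in range(4):
        tp = int(c[k, k])
        fn = int(rows[k] - tp)
        fp = int(cols[k] - tp)
        tn = total - rows[k] - fp
        if rows[k] == 0:
            prec = rec = spec = npv = np.nan
        else:
            prec = 100 * tp / cols[k] if cols[k] > 0 else np.nan
            rec = 100 * tp / rows[k]
            spec = 100 * tn / (total - rows[k]) if total - rows[k] > 0 else np.nan
            npv = 100 * tn / (tn + fn) if tn + fn > 0 else np.nan
        out.append(
            {
                "cap_index": k + 1,
                "precision_pct": prec,
                "recall_pct": rec,
                "specificity_pct": spec,
                "npv_pct": npv,
            }
        )
    return pd.DataFrame(out).set_index("cap_index")


def over_under_rates(
    confusion: CapIndexConfusion, restrict_to: Optional[Iterable[int]] = None
) -> dict:
    """Over/under-estimation fractions of the test modality against reference.

    ``restrict_to`` limits the scope to a subset of reference classes (e.g.
    {2, 3}, the slightly/moderately unstable groups).  The three fractions sum
    to 1 over the scope.
    """
    c = confusion.counts
    rows = range(4) if restrict_to is None else sorted(int(r) - 1 for r in restrict_to)
    over = under = agree = 0
    for r in rows:
        if not 0 <= r <= 3:
            raise VulnerabilityError("restrict_to classes must lie in 1..4")
        for t in range(4):
            if t > r:
                over += c[r, t]
            elif t < r:
                under += c[r, t]
            else:
                agree += c[r, t]
    in_scope = over + under + agree
    if in_scope == 0:
        raise VulnerabilityError("no slices in the requested scope")
    return {
        "over": over / in_scope,
        "under": under / in_scope,
        "agree": agree / in_scope,
        "n": int(in_scope),
    }


@dataclass
class TrendRecord:
    """One patient's baseline-to-follow-up cap-index change in both modalities."""

    patient_id: str
    oct_t1: int
    oct_t2: int
    ivus_t1: int
    ivus_t2: int

    @property
    def delta_oct(self) -> int:
        return self.oct_t2 - self.oct_t1

    @property
    def delta_ivus(self) -> int:
        return self.ivus_t2 - self.ivus_t1

    @staticmethod
    def _classify(delta: int) -> str:
        if delta > 0:
            return "more vulnerable"
        if delta < 0:
            return "more stable"
        return "unchanged"

    @property
    def trend_oct(self) -> str:
        return self._classify(self.delta_oct)

    @property
    def trend_ivus(self) -> str:
        return self._classify(self.delta_ivus)

    @property
    def modalities_agree(self) -> bool:
        """True when the IVUS index change equals the OCT index change."""
        return self.delta_oct == self.delta_ivus


def trend_analysis(records: Sequence[TrendRecord]) -> tuple[pd.DataFrame, float]:
    """Tabulate per-patient index changes and the OCT/IVUS agreement rate."""
    if not records:
        raise VulnerabilityError("trend analysis needs at least one patient")
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "oct_t1": [r.oct_t1 for r in records],
            "oct_t2": [r.oct_t2 for r in records],
            "delta_oct": [r.delta_oct for r in records],
            "ivus_t1": [r.ivus_t1 for r in records],
            "ivus_t2": [r.ivus_t2 for r in records],
            "delta_ivus": [r.delta_ivus for r in records],
            "trend_oct": [r.trend_oct for r in records],
            "agree": [r.modalities_agree for r in records],
        }
    )
    return df, float(df["agree"].mean())


def trend_from_min_caps(
    min_caps: pd.DataFrame, scheme: CapIndexScheme = DEFAULT_SCHEME
) -> tuple[pd.DataFrame, float]:
    """Trend analysis from plaque minimum cap thickness values.

    ``min_caps`` needs one row per patient with columns ``patient_id``,
    ``oct_t1_mm``, ``oct_t2_mm``, ``ivus_t1_mm``, ``ivus_t2_mm`` (NaN for a
    plaque with no cap points).  A missing timepoint raises.
    """
    required = ["patient_id", "oct_t1_mm", "oct_t2_mm", "ivus_t1_mm", "ivus_t2_mm"]
    for col in required:
        if col not in min_caps.columns:
            raise VulnerabilityError(f"missing column {col!r}")
    records = []
    for _, row in min_caps.iterrows():
        vals = {}
        for col in required[1:]:
            v = row[col]
            vals[col] = assign_cap_index(None if pd.isna(v) else float(v), scheme)
        records.append(
            TrendRecord(
                patient_id=str(row["patient_id"]),
                oct_t1=vals["oct_t1_mm"],
                oct_t2=vals["oct_t2_mm"],
                ivus_t1=vals["ivus_t1_mm"],
                ivus_t2=vals["ivus_t2_mm"],
            )
        )
    return trend_analysis(records)
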