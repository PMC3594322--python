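"""Qualitative localization calls and per-construct cohort summaries.

Each imaged mitotic cell is scored positive (chromosome-associated signal),
absent, or cannot-call.  Cannot-call covers cells whose reporter is
strongly over- or under-expressed (outside the expression QC window) and
cells without a well-defined metaphase plate on the morphology channel —
the latter is a human judgment supplied as a flag.  A quantitative CER
above the configurable threshold (default 1.6, the lower edge of the
1.6–1.7 band that tracks qualitative positivity) maps to "positive".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .quantify import CERMeasurement

__all__ = [
    "BoxStats",
    "Call",
    "CohortSummary",
    "DEFAULT_CER_THRESHOLD",
    "QualitativeCall",
    "classify_cell",
    "summarize_cohort",
]

#: Default CER threshold for a positive call; the band 1.6–1.7 correlates
#: with qualitative positivity and the lower edge is adopted.
DEFAULT_CER_THRESHOLD = 1.6

#: Minimum number of QC-passing cells expected per construct.
MIN_COHORT = 8


class Call(str, Enum):
    POSITIVE = "positive"
    ABSENT = "absent"
    CANNOT_CALL = "cannot_call"


@dataclass(frozen=True)
class QualitativeCall:
    call: Call
    reason: str = ""


@dataclass(frozen=True)
class BoxStats:
    """Box-and-whisker summary: Tukey hinges, median, full range, mean."""

    mean: float
    median: float
    q1: float
    q3: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min <= self.q1 <= self.median <= self.q3 <= self.max):
            raise ValueError("box statistics must be ordered min<=q1<=median<=q3<=max")

    @classmethod
    def from_values(cls, values) -> "BoxStats":
        """Tukey median-of-halves hinges (n odd: median included in both halves)."""
        x = np.sort(np.asarray(values, dtype=float))
        n = x.size
        if n == 0:
            raise ValueError("no values to summarize")

        def hinge(sorted_half):
            m = sorted_half.size
            mid = m // 2
            if m % 2:
                return float(sorted_half[mid])
            return float((sorted_half[mid - 1] + sorted_half[mid]) / 2.0)

        half = (n + 1) // 2  # lower half length, median included when n odd
        return cls(
            mean=float(x.mean()),
            median=hinge(x),
            q1=hinge(x[:half]),
            q3=hinge(x[n - half:]),
            min=float(x[0]),
            max=float(x[-1]),
        )


@dataclass
class CohortSummary:
    construct: str
    n_total: int
    n_positive: int
    n_absent: int
    n_cannot_call: int
    cer_values: list[float]
    box: BoxStats | None

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("cohort must contain at least one cell")
        if self.n_positive + self.n_absent + self.n_cannot_call != self.n_total:
            raise ValueError("call counts must sum to n_total")


def classify_cell(
    m: CERMeasurement,
    plate_defined: bool = True,
    cer_threshold: float = DEFAULT_CER_THRESHOLD,
) -> QualitativeCall:
    """Three-way localization call for one measured cell.

    Cells without a well-defined metaphase plate or outside the expression
    QC window are cannot-call; otherwise the call is positive iff the CER
    strictly exceeds the threshold ("above 1.6" is read strictly, so a CER
    of exactly 1.6 scores absent).
    """
    if not plate_defined:
        return QualitativeCall(Call.CANNOT_CALL, "no well-defined metaphase plate")
    if not m.qc_pass:
        lo, hi = m.meta.get("qc_window", (50.0, 500.0))
        reason = "overexpression" if m.cell_mean > hi else "underexpression"
        return QualitativeCall(Call.CANNOT_CALL, reason)
    if m.cer > cer_threshold:
        return QualitativeCall(Call.POSITIVE)
    return QualitativeCall(Call.ABSENT)


def summarize_cohort(
    cells: list[tuple[CERMeasurement, bool]],
    construct: str = "",
    cer_threshold: float = DEFAULT_CER_THRESHOLD,
) -> CohortSummary:
    """Aggregate calls and CER distribution statistics for one construct.

    ``cells`` is a list of (measurement, plate_defined) pairs.  CER
    distribution statistics cover callable cells only (well-defined plate
    and QC pass), matching the inclusion rule of the quantitative assay.
    Warns when fewer than 8 callable cells remain.
    """
    if not cells:
        raise ValueError("empty cohort")
    calls = [classify_cell(m, plate_defined, cer_threshold) for m, plate_defined in cells]
    n_pos = sum(c.call is Call.POSITIVE for c in calls)
    n_abs = sum(c.call is Call.ABSENT for c in calls)
    n_cc = sum(c.call is Call.CANNOT_CALL for c in calls)
    cer_values = [
        m.cer
        for (m, plate_defined), c in zip(cells, calls)
        if c.call is not Call.CANNOT_CALL
    ]
    if len(cer_values) < MIN_COHORT:
        warnings.warn(
            f"{construct or 'cohort'}: only {len(cer_values)} QC-passing cells "
            f"(<{MIN_COHORT})",
            stacklevel=2,
        )
    box = BoxStats.from_values(cer_values) if cer_values else None
    return CohortSummary(
        construct=construct,
        n_total=len(cells),
        n_positive=n_pos,
        n_absent=n_abs,
        n_cannot_call=n_cc,
        cer_values=cer_values,
        box=box,
    )
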