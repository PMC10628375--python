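"""Field- and case-level quantification of tumor-stroma ratio (TSR) and
stromal tumor-infiltrating lymphocytes (sTIL) from grid square counts.

A field is one circular microphotograph with an inscribed 10x10 grid.  Each
small square is labeled T (tumor-predominant), S (stroma-predominant),
L (lymphocyte-predominant stroma, a subset of S) or NA (inconclusive/empty).
The two field-level statistics are

    TSR (%)  = 100 * n_S / (n_T + n_S)       NA squares excluded
    sTIL (%) = 100 * n_L / n_S               T and NA squares excluded

A case is scored by averaging the defined per-field percentages over its
(typically ten) fields, rounding half-up to a whole percent, clamping the
reportable value into [1, 99] (0% and 100% are never reported), and binning
into a four-tier score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .errors import InvalidParameterError, UndefinedRatioError

logger = logging.getLogger(__name__)

MODE_TSR = "tsr"
MODE_STIL = "stil"
MODES = (MODE_TSR, MODE_STIL)

#: Four-tier score bins on the rounded integer percent: (low, high, score).
SCORE_BINS = ((0, 25, 1), (26, 50, 2), (51, 75, 3), (76, 100, 4))


@dataclass(frozen=True)
class FieldCounts:
    """Square tallies for one field.

    ``n_S`` counts ALL stroma-predominant squares, including the ``n_L``
    lymphocyte-predominant ones; this is what makes sTIL = n_L / n_S a
    fraction of the stromal compartment.
    """

    n_T: int
    n_S: int
    n_L: int = 0
    n_NA: int = 0
    n_total: int = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("n_T", "n_S", "n_L", "n_NA"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise InvalidParameterError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_total is None:
            object.__setattr__(self, "n_total", self.n_T + self.n_S + self.n_NA)
        if self.n_T + self.n_S + self.n_NA != self.n_total:
            raise InvalidParameterError(
                f"n_T + n_S + n_NA = {self.n_T + self.n_S + self.n_NA} != n_total = {self.n_total}"
            )
        if self.n_L > self.n_S:
            raise InvalidParameterError(f"n_L = {self.n_L} exceeds n_S = {self.n_S}")


@dataclass(frozen=True)
class FieldResult:
    """Per-field percentages; ``None`` where the denominator was zero."""

    tsr_percent: float | None = None
    stil_percent: float | None = None

    def value(self, parameter: str) -> float | None:
        _check_mode(parameter)
        return self.tsr_percent if parameter == MODE_TSR else self.stil_percent


@dataclass(frozen=True)
class CaseReport:
    """Case-level aggregate for one parameter (TSR or sTIL)."""

    parameter: str
    field_percents: tuple  # raw per-field percentages, None where undefined
    mean_percent: float
    rounded_percent: int
    reportable_percent: int
    score: int
    n_fields_used: int = 0

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "field_percents": list(self.field_percents),
            "mean_percent": self.mean_percent,
            "rounded_percent": self.rounded_percent,
            "reportable_percent": self.reportable_percent,
            "score": self.score,
            "n_fields_used": self.n_fields_used,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CaseReport":
        return cls(
            parameter=d["parameter"],
            field_percents=tuple(d["field_percents"]),
            mean_percent=d["mean_percent"],
            rounded_percent=d["rounded_percent"],
            reportable_percent=d["reportable_percent"],
            score=d["score"],
            n_fields_used=d["n_fields_used"],
        )


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise InvalidParameterError(f"mode must be one of {MODES}, got {mode!r}")


def compute_tsr(counts: FieldCounts) -> float:
    """Tumor-stroma ratio of one field: 100 * n_S / (n_T + n_S).

    NA squares never enter the denominator.  Raises
    :class:`UndefinedRatioError` when the field has no T or S squares.
    """
    denom = counts.n_T + counts.n_S
    if denom == 0:
        raise UndefinedRatioError("TSR undefined: no tumor- or stroma-predominant squares")
    return 100.0 * counts.n_S / denom


def compute_stil(counts: FieldCounts) -> float:
    """Stromal TIL percentage of one field: 100 * n_L / n_S.

    Tumor and NA squares are excluded entirely.  Raises
    :class:`UndefinedRatioError` when the field has no stromal squares.
    """
    if counts.n_S == 0:
        raise UndefinedRatioError("sTIL undefined: no stroma-predominant squares")
    return 100.0 * counts.n_L / counts.n_S


def field_result(counts: FieldCounts) -> FieldResult:
    """Both per-field percentages, ``None`` where undefined."""
    tsr = compute_tsr(counts) if counts.n_T + counts.n_S > 0 else None
    stil = compute_stil(counts) if counts.n_S > 0 else None
    return FieldResult(tsr_percent=tsr, stil_percent=stil)


def round_percent(x: float) -> int:
    """Round a percentage half-up to the nearest whole number (67.76 -> 68,
    49.5 -> 50).  Half-up, not banker's rounding."""
    if not 0.0 <= x <= 100.0:
        raise InvalidParameterError(f"percent must be in [0, 100], got {x}")
    return int(math.floor(x + 0.5))


def clamp_reportable(p: int) -> int:
    """Clamp a rounded percent into the reportable range [1, 99].

    0% and 100% are never reported for either parameter (there is always
    some of the other compartment, and empty space between lymphocytes).
    """
    if p == 0:
        logger.warning("rounded percent 0 clamped to reportable 1")
        return 1
    if p == 100:
        logger.warning("rounded percent 100 clamped to reportable 99")
        return 99
    return p


def score_percent(p: int) -> int:
    """Four-tier score of a rounded integer percent.

    Bins: [0, 25] -> 1, [26, 50] -> 2, [51, 75] -> 3, [76, 100] -> 4.
    """
    if not 0 <= p <= 100:
        raise InvalidParameterError(f"percent must be in [0, 100], got {p}")
    for lo, hi, score in SCORE_BINS:
        if lo <= p <= hi:
            return score
    raise AssertionError("unreachable: bins partition [0, 100]")


def aggregate_case(field_counts: list, parameter: str) -> CaseReport:
    """Aggregate a case from its fields' counts.

    The per-field percentages for ``parameter`` ("tsr" or "stil") are
    averaged over fields where they are defined (zero-denominator fields are
    skipped with a warning), then rounded half-up, clamped into [1, 99] and
    binned into the four-tier score.
    """
    _check_mode(parameter)
    if not field_counts:
        raise InvalidParameterError("aggregate_case needs at least one field")
    percents = []
    for i, counts in enumerate(field_counts):
        try:
            p = compute_tsr(counts) if parameter == MODE_TSR else compute_stil(counts)
        except UndefinedRatioError:
            logger.warning("field %d has an undefined %s percentage; skipped", i, parameter)
            p = None
        percents.append(p)
    defined = [p for p in percents if p is not None]
    if not defined:
        raise UndefinedRatioError(f"{parameter} undefined in every field of the case")
    mean = sum(defined) / len(defined)
    rounded = round_percent(mean)
    reportable = clamp_reportable(rounded)
    return CaseReport(
        parameter=parameter,
        field_percents=tuple(percents),
        mean_percent=mean,
        rounded_percent=rounded,
        reportable_percent=reportable,
        score=score_percent(reportable),
        n_fields_used=len(defined),
    )
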