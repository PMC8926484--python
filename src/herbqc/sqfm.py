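"""Systematic quantified fingerprint method (SQFM).

A batch fingerprint (sample fingerprint, SFP, vector x of common-peak areas)
is judged against a reference fingerprint (RFP, vector y — here the
batch-wise average profile) through three parameters:

* macro-qualitative similarity
  ``S_m = ½·[ Σxᵢyᵢ/√(Σxᵢ²·Σyᵢ²) + Σ(xᵢ/yᵢ)/√(n·Σ(xᵢ/yᵢ)²) ]`` — the mean of
  the congruence (cosine) coefficient and a mean-ratio similarity; both
  terms are ≤ 1 by Cauchy–Schwarz and equal 1 exactly when x ∝ y.
* macro-quantitative similarity ``P_m = (C + P)/2`` where
  ``C = 100·Σxᵢyᵢ/Σyᵢ²`` (projection content, %) and
  ``P = 100·(Σxᵢ/Σyᵢ)·cos(x, y)`` (cosine-weighted total-area ratio, %).
* fingerprint variation coefficient ``α = |1 − P/C|``.

An 8-grade quality class (1 = Best … 8 = Inferior) is assigned per
parameter from threshold criteria; the overall grade is the worst (largest)
of the three parameter grades.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError, InsufficientDataError
from .peakio import FingerprintMatrix

QUALITY_LABELS = (
    "Best", "Better", "Good", "Fine", "Moderate", "Common", "Defective", "Inferior",
)


@dataclass(frozen=True)
class GradingTable:
    """Threshold criteria mapping (S_m, P_m, α) to grades 1–8.

    Grade g (1-based) requires S_m ≥ ``s_m_floors[g-1]``, P_m inside
    ``p_m_intervals[g-1]`` (inclusive endpoints) and α ≤
    ``alpha_ceilings[g-1]``.  The last entries are unbounded so grade 8
    catches everything.
    """

    s_m_floors: tuple[float, ...] = (0.95, 0.90, 0.85, 0.80, 0.70, 0.60, 0.50, 0.0)
    p_m_intervals: tuple[tuple[float, float], ...] = (
        (95, 105), (90, 110), (85, 115), (80, 120),
        (70, 130), (60, 140), (50, 150), (0, np.inf),
    )
    alpha_ceilings: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.30, 0.40, 0.50, np.inf)
    labels: tuple[str, ...] = QUALITY_LABELS

    def __post_init__(self) -> None:
        if not (len(self.s_m_floors) == len(self.p_m_intervals)
                == len(self.alpha_ceilings) == len(self.labels) == 8):
            raise DomainError("grading table must define exactly 8 grades")
        if list(self.s_m_floors[:-1]) != sorted(self.s_m_floors[:-1], reverse=True):
            raise DomainError("S_m floors must be strictly descending")
        if list(self.alpha_ceilings) != sorted(self.alpha_ceilings):
            raise DomainError("alpha ceilings must be ascending")
        for (lo1, hi1), (lo2, hi2) in zip(self.p_m_intervals, self.p_m_intervals[1:]):
            if not (lo2 <= lo1 and hi1 <= hi2):
                raise DomainError("P_m intervals must be nested")


DEFAULT_GRADING = GradingTable()


@dataclass(frozen=True)
class SQFMResult:
    """Full SQFM evaluation of one batch against the RFP."""

    batch: str
    s_m: float
    c_pct: float
    p_pct: float
    p_m_pct: float
    alpha: float
    grade: int
    quality: str
    param_grades: tuple[int, int, int] = (0, 0, 0)   # (S_m, P_m, α) grades


# ---------------------------------------------------------------------------
# Metric primitives
# ---------------------------------------------------------------------------

def _check_pair(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise DomainError("x and y must be 1-D vectors of equal positive length")
    if np.any(x <= 0) or np.any(y <= 0):
        raise DomainError("all fingerprint entries must be > 0")
    return x, y


def s_m(x: Sequence[float], y: Sequence[float]) -> float:
    """Macro-qualitative similarity of an SFP x to the RFP y; in (0, 1]."""
    x, y = _check_pair(x, y)
    cos = float(x @ y / np.sqrt((x @ x) * (y @ y)))
    r = x / y
    ratio = float(r.sum() / np.sqrt(r.size * (r @ r)))
    return 0.5 * (cos + ratio)


def c_pct(x: Sequence[float], y: Sequence[float]) -> float:
    """Projection content C = 100·Σxy/Σy² — content of x along the RFP, %."""
    x, y = _check_pair(x, y)
    return float(100.0 * (x @ y) / (y @ y))


def p_pct(x: Sequence[float], y: Sequence[float]) -> float:
    """Cosine-weighted total-area ratio P = 100·(Σx/Σy)·cos(x, y), %."""
    x, y = _check_pair(x, y)
    cos = float(x @ y / np.sqrt((x @ x) * (y @ y)))
    return float(100.0 * (x.sum() / y.sum()) * cos)


def p_m_alpha(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Macro-quantitative similarity P_m = (C+P)/2 and variation α = |1 − P/C|."""
    c = c_pct(x, y)
    p = p_pct(x, y)
    return 0.5 * (c + p), abs(1.0 - p / c)


# ---------------------------------------------------------------------------
# Grading
# ---------------------------------------------------------------------------

def grade(
    s_m_value: float,
    p_m_pct_value: float,
    alpha_value: float,
    table: GradingTable = DEFAULT_GRADING,
) -> tuple[int, str, tuple[int, int, int]]:
    """Map (S_m, P_m, α) to the 8-grade quality class.

    Each parameter gets the best (lowest) grade whose criterion it meets;
    the overall grade is the worst of the three, with its quality label.
    Returns (overall grade, label, (S_m grade, P_m grade, α grade)).
    """
    if not 0 < s_m_value <= 1 + 1e-12:
        raise DomainError(f"S_m must lie in (0, 1], got {s_m_value}")
    if alpha_value < 0:
        raise DomainError(f"alpha must be >= 0, got {alpha_value}")

    g_s = next(i + 1 for i, floor in enumerate(table.s_m_floors) if s_m_value >= floor)
    g_p = next(
        i + 1
        for i, (lo, hi) in enumerate(table.p_m_intervals)
        if lo <= p_m_pct_value <= hi
    )
    g_a = next(i + 1 for i, ceil in enumerate(table.alpha_ceilings) if alpha_value <= ceil)
    overall = max(g_s, g_p, g_a)
    return overall, table.labels[overall - 1], (g_s, g_p, g_a)


# ---------------------------------------------------------------------------
# Batch evaluation
# ---------------------------------------------------------------------------

def build_rfp(fm: FingerprintMatrix) -> np.ndarray:
    """Reference fingerprint by the average-value method: column means."""
    if len(fm.batch_ids) < 2:
        raise InsufficientDataError("need >= 2 batches to build the RFP")
    return fm.areas.mean(axis=0)


def evaluate_one(
    batch: str,
    x: Sequence[float],
    rfp: Sequence[float],
    table: GradingTable = DEFAULT_GRADING,
) -> SQFMResult:
    sm = s_m(x, rfp)
    c = c_pct(x, rfp)
    p = p_pct(x, rfp)
    pm, a = 0.5 * (c + p), abs(1.0 - p / c)
    g, label, params = grade(min(sm, 1.0), pm, a, table)
    return SQFMResult(
        batch=batch, s_m=sm, c_pct=c, p_pct=p, p_m_pct=pm, alpha=a,
        grade=g, quality=label, param_grades=params,
    )


def evaluate_batches(
    fm: FingerprintMatrix,
    rfp: Sequence[float] | None = None,
    table: GradingTable = DEFAULT_GRADING,
) -> list[SQFMResult]:
    """Evaluate every batch against the RFP; the RFP self-row comes last.

    The self-row is the RFP evaluated against itself and is always
    (S_m = 1, P_m = 100, α = 0, grade 1) — a built-in sanity anchor.
    """
    y = build_rfp(fm) if rfp is None else np.asarray(rfp, dtype=float)
    results = [
        evaluate_one(b, fm.areas[i], y, table) for i, b in enumerate(fm.batch_ids)
    ]
    results.append(evaluate_one("RFP", y, y, table))
    return results
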