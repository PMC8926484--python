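"""QAMS quantification, relative correction factors, and validation statistics.

QAMS (quantitative analysis of multicomponents by single marker) calibrates
one internal reference standard (IRS, component k) and derives every other
component s through a relative correction factor

    f_ks = (W_k · A_s) / (W_s · A_k)

where W is injected mass and A peak area.  Given f_ks, the amount of s in a
sample injection follows from the IRS peak alone:
W_s = W_k · A_s / (f_ks · A_k).

The module also provides the conventional external-standard content (ESM,
single-point against a same-volume reference injection), the replicate
summary statistics used in method validation (precision / repeatability /
stability RSDs, spike recovery), and the paired t-test comparing ESM with
QAMS contents across batches.

All RSDs use the sample (n−1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConsistencyError, DomainError, InsufficientDataError


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StatSummary:
    """Replicate summary: count, mean, sample sd, and RSD% (100·sd/mean)."""

    n: int
    mean: float
    sd: float
    rsd_pct: float


def summarize(values: Sequence[float]) -> StatSummary:
    """Mean, sample standard deviation (n−1) and relative SD of replicates."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(f"need >= 2 values for a summary, got {arr.size}")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return StatSummary(n=int(arr.size), mean=mean, sd=sd, rsd_pct=100.0 * sd / mean)


# ---------------------------------------------------------------------------
# Relative correction factors
# ---------------------------------------------------------------------------

def compute_rcf(w_k: float, a_k: float, w_s: float, a_s: float) -> float:
    """Relative correction factor f_ks = (W_k·A_s)/(W_s·A_k).

    W are injected masses (µg), A peak areas, k the IRS and s the target
    component.  f_ks·f_sk = 1 by construction.
    """
    for name, v in (("w_k", w_k), ("a_k", a_k), ("w_s", w_s), ("a_s", a_s)):
        if not v > 0:
            raise DomainError(f"{name} must be > 0, got {v}")
    return (w_k * a_s) / (w_s * a_k)


@dataclass
class RCFSet:
    """Per-replicate relative correction factors against one IRS, summarised."""

    irs: str
    values: dict[str, list[float]]          # component -> per-replicate f_ks
    labels: list[str] = field(default_factory=list)   # replicate labels
    mean: dict[str, float] = field(init=False)
    rsd_pct: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.mean, self.rsd_pct = {}, {}
        for comp, vals in self.values.items():
            if any(v <= 0 for v in vals):
                raise DomainError(f"f_{self.irs}/{comp}: all factors must be > 0")
            s = summarize(vals)
            self.mean[comp] = s.mean
            self.rsd_pct[comp] = s.rsd_pct


def rcf_summary(
    replicates: Sequence[tuple[str, Mapping[str, float]]],
    irs: str = "IRS",
) -> RCFSet:
    """Summarise per-replicate RCFs: mean and sample RSD per component.

    ``replicates`` is a list of (label, {component: f}) pairs — one entry per
    injection volume, instrument or column.  Every replicate must report the
    same component set.
    """
    if len(replicates) < 2:
        raise InsufficientDataError("need >= 2 replicates to summarise RCFs")
    comps = list(replicates[0][1].keys())
    for label, fmap in replicates:
        if set(fmap.keys()) != set(comps):
            raise ConsistencyError(
                f"replicate {label!r} components {sorted(fmap)} != {sorted(comps)}"
            )
    values = {c: [float(fmap[c]) for _, fmap in replicates] for c in comps}
    return RCFSet(irs=irs, values=values, labels=[label for label, _ in replicates])


# ---------------------------------------------------------------------------
# Content determination
# ---------------------------------------------------------------------------

def esm_content(a_sample: float, a_ref: float, m_ref_ug: float, m_sample_ug: float) -> float:
    """External-standard content, % w/w, by single-point calibration.

    The sample and the reference solution are injected at the same volume;
    the analyte mass in the sample injection is A_sample/A_ref times the
    reference mass, expressed against the sample load (µg of extract
    injected).
    """
    for name, v in (("a_sample", a_sample), ("a_ref", a_ref),
                    ("m_ref_ug", m_ref_ug), ("m_sample_ug", m_sample_ug)):
        if not v > 0:
            raise DomainError(f"{name} must be > 0, got {v}")
    return 100.0 * (a_sample / a_ref) * (m_ref_ug / m_sample_ug)


def qams_content(
    a_s: float,
    a_k: float,
    w_k_ug: float,
    f_ks: float,
    m_sample_ug: float,
) -> float:
    """QAMS content of component s, % w/w of the sample load.

    The IRS mass in the sample injection is ``w_k_ug`` (determined against
    the reference); the component mass follows from the area ratio divided
    by the relative correction factor: W_s = W_k·A_s/(f_ks·A_k).
    """
    for name, v in (("a_s", a_s), ("a_k", a_k), ("w_k_ug", w_k_ug),
                    ("f_ks", f_ks), ("m_sample_ug", m_sample_ug)):
        if not v > 0:
            raise DomainError(f"{name} must be > 0, got {v}")
    w_s = (w_k_ug * a_s) / (f_ks * a_k)
    return 100.0 * w_s / m_sample_ug


@dataclass(frozen=True)
class ContentResult:
    """Per-batch contents (% w/w) from one quantification method."""

    batch: str
    method: str                         # "ESM" or "QAMS"
    contents_pct: Mapping[str, float]   # marker -> content %

    def __post_init__(self) -> None:
        if self.method not in ("ESM", "QAMS"):
            raise DomainError(f"method must be ESM or QAMS, got {self.method!r}")
        for marker, c in self.contents_pct.items():
            if not c > 0:
                raise DomainError(f"batch {self.batch}, {marker}: content must be > 0")


# ---------------------------------------------------------------------------
# Recovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryRecord:
    """One spike-recovery determination."""

    content_mg: float     # analyte already in the sample
    added_mg: float       # spiked amount
    measured_mg: float    # total found after spiking
    rate_pct: float       # 100·(measured − content)/added


def recovery(content_mg: float, added_mg: float, measured_mg: float) -> RecoveryRecord:
    """Spike recovery rate; may exceed 100% when the spike over-recovers."""
    if not added_mg > 0:
        raise DomainError(f"added_mg must be > 0, got {added_mg}")
    rate = 100.0 * (measured_mg - content_mg) / added_mg
    return RecoveryRecord(
        content_mg=content_mg, added_mg=added_mg, measured_mg=measured_mg, rate_pct=rate
    )


# ---------------------------------------------------------------------------
# ESM vs QAMS comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MethodComparison:
    """Paired t-test of ESM vs QAMS contents for one marker across batches.

    ``degenerate`` marks a zero-variance difference vector, for which the t
    statistic is undefined: an exactly zero shift is reported as p = 1 (no
    difference), a non-zero constant shift as p = 0 with the shift recorded.
    """

    marker: str
    n: int
    t: float
    df: int
    p: float
    no_significant_difference: bool     # at alpha = 0.05
    degenerate: bool = False
    shift: float | None = None          # constant ESM−QAMS shift if degenerate


def compare_methods(
    esm: Sequence[ContentResult],
    qams: Sequence[ContentResult],
    alpha: float = 0.05,
) -> list[MethodComparison]:
    """Per-marker paired two-sided t-test of batch-wise ESM vs QAMS contents."""
    esm_by_batch = {r.batch: r for r in esm}
    qams_by_batch = {r.batch: r for r in qams}
    if set(esm_by_batch) != set(qams_by_batch):
        raise ConsistencyError("ESM and QAMS results cover different batches")
    batches = sorted(esm_by_batch)
    if len(batches) < 2:
        raise InsufficientDataError("need >= 2 paired batches for a t-test")
    markers = list(esm_by_batch[batches[0]].contents_pct.keys())
    for b in batches:
        if set(esm_by_batch[b].contents_pct) != set(markers) or set(
            qams_by_batch[b].contents_pct
        ) != set(markers):
            raise ConsistencyError(f"batch {b}: marker sets differ between methods")

    out = []
    for m in markers:
        x = np.array([esm_by_batch[b].contents_pct[m] for b in batches])
        y = np.array([qams_by_batch[b].contents_pct[m] for b in batches])
        d = x - y
        n = len(d)
        if np.allclose(d, d[0], rtol=0, atol=1e-12):
            shift = float(d[0])
            zero = abs(shift) < 1e-12
            out.append(
                MethodComparison(
                    marker=m, n=n, t=0.0 if zero else np.inf, df=n - 1,
                    p=1.0 if zero else 0.0,
                    no_significant_difference=zero,
                    degenerate=True, shift=shift,
                )
            )
            continue
        res = stats.ttest_rel(x, y)
        out.append(
            MethodComparison(
                marker=m, n=n, t=float(res.statistic), df=n - 1,
                p=float(res.pvalue),
                no_significant_difference=bool(res.pvalue > alpha),
            )
        )
    return out
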