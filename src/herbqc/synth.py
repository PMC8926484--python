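"""Synthetic chromatographic data with known ground truth.

Generates mixed-reference injection series, sample injections and batch
fingerprint matrices from a power-law detector response per marker
(log-log linear: area = exp(intercept)·mass^slope), multiplicative
Gaussian area noise at a stated CV, and batch-level scale (total content)
plus per-peak shape perturbations.  Every pipeline stage can thus be tested
against the truth that generated its input.

The default configuration mirrors a four-saponin HPLC assay: markers D, A,
F and B9 with their published response parameters and reference
concentrations, a 3–30 µl seven-point reference series, injection noise at
0.5% CV, and five 11-peak batch fingerprints with the markers at common
peaks 5, 8, 9 and 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .peakio import FingerprintMatrix, MarkerDef, Peak, PeakTable

#: retention-time span (min) over which common peaks are spread
_RT_SPAN = (8.0, 68.0)


@dataclass(frozen=True)
class MarkerResponse:
    """A marker plus its true detector-response parameters."""

    marker: MarkerDef
    slope: float        # power-law exponent (ln area vs ln mass)
    intercept: float    # ln area at 1 µg

    def area_at(self, mass_ug: float) -> float:
        return float(np.exp(self.intercept) * mass_ug**self.slope)


def default_markers() -> list[MarkerResponse]:
    """The four-saponin marker panel with published response parameters."""
    rts = common_peak_rts(11)
    spec = [
        # name, ref conc mg/ml, common peak (1-based), linear range µg, slope, intercept
        ("D", 0.614, 5, (1.84, 18.42), 0.9781, 5.7314),
        ("A", 0.242, 8, (0.73, 7.26), 0.9925, 6.1778),
        ("F", 0.496, 9, (1.49, 14.88), 1.0209, 5.7846),
        ("B9", 0.385, 10, (1.16, 11.55), 1.0403, 5.4396),
    ]
    return [
        MarkerResponse(
            marker=MarkerDef(
                name=name, ref_conc=conc, common_peak_index=idx,
                linear_range=rng, rt=float(rts[idx - 1]),
            ),
            slope=slope, intercept=intercept,
        )
        for name, conc, idx, rng, slope, intercept in spec
    ]


def common_peak_rts(n_common: int) -> np.ndarray:
    """Evenly spaced retention times for the common peaks."""
    return np.linspace(*_RT_SPAN, n_common)


def _default_base_profile() -> tuple[float, ...]:
    # 11-peak profile; markers at peaks 5 (D, strongest), 8 (A), 9 (F), 10 (B9)
    # with areas on the scale of a 20 µl reference injection
    return (420.0, 880.0, 1350.0, 760.0, 3571.0, 980.0, 640.0,
            2324.0, 3333.0, 1893.0, 510.0)


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth parameters for all generators; ``seed`` fixes everything."""

    markers: tuple[MarkerResponse, ...] = field(
        default_factory=lambda: tuple(default_markers())
    )
    volumes_ul: tuple[float, ...] = (3, 5, 10, 15, 20, 25, 30)
    noise_cv: float = 0.005             # multiplicative area noise (precision ~0.5%)
    n_batches: int = 5
    n_common: int = 11
    batch_scales: tuple[float, ...] = (0.95, 0.55, 1.05, 1.20, 1.05)
    shape_noise_cv: float = 0.05        # per-peak profile perturbation
    base_profile: tuple[float, ...] = field(default_factory=_default_base_profile)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0 or self.shape_noise_cv < 0:
            raise ValidationError("noise CVs must be >= 0")
        if any(v <= 0 for v in self.volumes_ul):
            raise ValidationError("injection volumes must be > 0")
        if self.n_batches < 2:
            raise ValidationError("need n_batches >= 2")
        if len(self.batch_scales) != self.n_batches:
            raise ValidationError("batch_scales length must equal n_batches")
        if any(s <= 0 for s in self.batch_scales):
            raise ValidationError("batch scales must be > 0")
        if len(self.base_profile) != self.n_common:
            raise ValidationError("base_profile length must equal n_common")
        if self.markers and max(m.marker.common_peak_index for m in self.markers) > self.n_common:
            raise ValidationError("marker common_peak_index exceeds n_common")

    def with_(self, **kw) -> "SynthConfig":
        return replace(self, **kw)

    def marker_defs(self) -> list[MarkerDef]:
        return [m.marker for m in self.markers]


def _rng(cfg: SynthConfig, salt: int) -> np.random.Generator:
    # one seeded stream per generator call; salt separates the generators
    return np.random.default_rng([salt, cfg.seed])


def _noisy(rng: np.random.Generator, values: np.ndarray, cv: float) -> np.ndarray:
    if cv == 0:
        return values.copy()
    factors = 1.0 + rng.normal(0.0, cv, size=values.shape)
    return values * np.clip(factors, 0.05, None)   # keep areas positive


# ---------------------------------------------------------------------------
# Reference injections
# ---------------------------------------------------------------------------

def gen_reference_series(cfg: SynthConfig) -> list[PeakTable]:
    """Mixed-reference injections across the configured volume series.

    Each table holds one peak per marker at its retention time, with
    area = exp(intercept)·mass^slope·(1 + ε), ε ~ N(0, noise_cv²) and
    mass = ref_conc × volume.
    """
    rng = _rng(cfg, salt=1)
    tables = []
    for vol in cfg.volumes_ul:
        true = np.array([m.area_at(m.marker.ref_conc * vol) for m in cfg.markers])
        areas = _noisy(rng, true, cfg.noise_cv)
        peaks = [
            Peak(peak_id=i + 1, rt=m.marker.rt, area=float(a))
            for i, (m, a) in enumerate(zip(cfg.markers, areas))
        ]
        tables.append(PeakTable(injection_id=f"ref_{vol:g}ul", volume=float(vol), peaks=peaks))
    return tables


def gen_reference_replicates(
    cfg: SynthConfig, n: int = 6, volume_ul: float = 20.0
) -> list[PeakTable]:
    """Repeated same-volume reference injections (precision-style replicates)."""
    rng = _rng(cfg, salt=2)
    true = np.array([m.area_at(m.marker.ref_conc * volume_ul) for m in cfg.markers])
    tables = []
    for r in range(n):
        areas = _noisy(rng, true, cfg.noise_cv)
        peaks = [
            Peak(peak_id=i + 1, rt=m.marker.rt, area=float(a))
            for i, (m, a) in enumerate(zip(cfg.markers, areas))
        ]
        tables.append(
            PeakTable(injection_id=f"ref_rep{r + 1}", volume=volume_ul, peaks=peaks)
        )
    return tables


# ---------------------------------------------------------------------------
# Sample injections
# ---------------------------------------------------------------------------

def gen_sample_tables(
    cfg: SynthConfig,
    true_contents_pct: dict[str, float],
    m_sample_ug: float = 40.0,
    n: int = 1,
    volume_ul: float = 20.0,
) -> list[PeakTable]:
    """Sample injections with known marker contents (% w/w of the load).

    Marker areas follow the response model at mass = content·load; the
    remaining common peaks carry the scaled base profile.  Ground truth is
    the ``true_contents_pct`` argument itself.
    """
    missing = [m.marker.name for m in cfg.markers if m.marker.name not in true_contents_pct]
    if missing:
        raise ValidationError(f"true_contents_pct missing markers {missing}")
    rng = _rng(cfg, salt=3)
    rts = common_peak_rts(cfg.n_common)
    marker_idx = {m.marker.common_peak_index - 1: m for m in cfg.markers}
    tables = []
    for r in range(n):
        areas = np.empty(cfg.n_common)
        for i in range(cfg.n_common):
            if i in marker_idx:
                m = marker_idx[i]
                mass = true_contents_pct[m.marker.name] / 100.0 * m_sample_ug
                areas[i] = m.area_at(mass)
            else:
                areas[i] = cfg.base_profile[i]
        areas = _noisy(rng, areas, cfg.noise_cv)
        peaks = [
            Peak(peak_id=i + 1, rt=float(rts[i]), area=float(a))
            for i, a in enumerate(areas)
        ]
        tables.append(
            PeakTable(injection_id=f"sample_rep{r + 1}", volume=volume_ul, peaks=peaks)
        )
    return tables


# ---------------------------------------------------------------------------
# Batch fingerprints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FingerprintTruth:
    """Ground truth behind a generated fingerprint matrix.

    ``expected_c_pct[b] = 100·scale_b / mean(scales)`` is the projection
    content each batch shows against the average-method RFP when the shape
    noise is zero (all profiles proportional, so C = P = P_m there).
    """

    base_profile: tuple[float, ...]
    batch_scales: tuple[float, ...]
    expected_c_pct: tuple[float, ...]


def gen_fingerprints(cfg: SynthConfig) -> tuple[FingerprintMatrix, FingerprintTruth]:
    """Batch fingerprint matrix: row b = base · scale_b · (1 + shape noise)."""
    rng = _rng(cfg, salt=4)
    base = np.asarray(cfg.base_profile, dtype=float)
    scales = np.asarray(cfg.batch_scales, dtype=float)
    rows = np.empty((cfg.n_batches, cfg.n_common))
    for b in range(cfg.n_batches):
        rows[b] = _noisy(rng, base * scales[b], cfg.shape_noise_cv)
    fm = FingerprintMatrix(
        batch_ids=[str(b + 1) for b in range(cfg.n_batches)],
        areas=rows,
        peak_rts=common_peak_rts(cfg.n_common),
    )
    truth = FingerprintTruth(
        base_profile=tuple(base),
        batch_scales=tuple(scales),
        expected_c_pct=tuple(100.0 * scales / scales.mean()),
    )
    return fm, truth
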