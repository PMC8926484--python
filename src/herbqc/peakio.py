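"""Peak-table and fingerprint I/O, plus retention-time based peak matching.

The universal input record is a *peak table*: one HPLC injection reduced to
integrated peaks (id, retention time in minutes, detector area).  Fingerprint
matrices hold the areas of the *common peaks* — peaks present in every batch
at matched retention time — one row per batch.

Matching is by absolute retention-time tolerance (single-linkage clustering
of the pooled retention times, cut at the tolerance).  Ambiguity — two peaks
of one injection inside one cluster — is an error, never a silent drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    AmbiguityError,
    FormatError,
    ValidationError,
)

#: default retention-time tolerance (minutes) for peak matching
DEFAULT_RT_TOLERANCE = 0.2

PEAK_COLUMNS = ("peak_id", "rt", "area")


@dataclass(frozen=True)
class Peak:
    """One integrated chromatographic peak."""

    peak_id: int
    rt: float       # retention time, minutes
    area: float     # detector response, arbitrary units

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValidationError(f"peak {self.peak_id}: area must be > 0, got {self.area}")
        if self.rt < 0:
            raise ValidationError(f"peak {self.peak_id}: rt must be >= 0, got {self.rt}")


@dataclass
class PeakTable:
    """All peaks of one injection, sorted by retention time."""

    injection_id: str
    volume: float               # injected volume, µl
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.volume > 0:
            raise ValidationError(f"injection {self.injection_id}: volume must be > 0")
        ids = [p.peak_id for p in self.peaks]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"injection {self.injection_id}: duplicate peak_id")
        self.peaks = sorted(self.peaks, key=lambda p: p.rt)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def rts(self) -> np.ndarray:
        return np.array([p.rt for p in self.peaks])

    @property
    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.peaks])


@dataclass(frozen=True)
class MarkerDef:
    """A quantified marker component.

    ``ref_conc`` is the concentration of the marker in the mixed reference
    solution (mg/ml); the injected mass at volume v µl is ``ref_conc * v`` µg.
    ``common_peak_index`` is the 1-based position of the marker's peak among
    the common fingerprint peaks.  ``rt`` (optional) locates the marker's
    peak in a raw peak table by retention-time proximity.
    """

    name: str
    ref_conc: float                     # mg/ml
    common_peak_index: int
    linear_range: tuple[float, float]   # injected mass, µg
    rt: float | None = None             # expected retention time, min

    def __post_init__(self) -> None:
        if not self.ref_conc > 0:
            raise ValidationError(f"marker {self.name}: ref_conc must be > 0")
        low, high = self.linear_range
        if not low < high:
            raise ValidationError(f"marker {self.name}: linear range low must be < high")


@dataclass
class FingerprintMatrix:
    """Common-peak areas, one row per batch, columns ordered by retention time."""

    batch_ids: list[str]
    areas: np.ndarray               # shape (n_batches, n_common), all > 0
    peak_rts: np.ndarray | None = None   # mean rt per common peak, if known

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.ndim != 2:
            raise ValidationError("fingerprint areas must be a 2-D matrix")
        if len(self.batch_ids) != self.areas.shape[0]:
            raise ValidationError("batch_ids length must match number of rows")
        if not np.all(self.areas > 0):
            raise ValidationError("all fingerprint areas must be > 0")

    @property
    def n_common(self) -> int:
        return self.areas.shape[1]

    def row(self, batch_id: str) -> np.ndarray:
        return self.areas[self.batch_ids.index(batch_id)]


# ---------------------------------------------------------------------------
# Peak-table I/O (TSV/CSV with header peak_id, rt, area)
# ---------------------------------------------------------------------------

def _dialect_sep(path: Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if dialect not in ("tsv", "csv"):
        raise FormatError(f"unknown dialect {dialect!r} (use 'tsv' or 'csv')")
    return "\t" if dialect == "tsv" else ","


def read_peak_table(
    path: str | Path,
    dialect: str | None = None,
    injection_id: str | None = None,
    volume: float = 20.0,
) -> PeakTable:
    """Read one injection's peak table from a delimited text file.

    The file must carry a header with columns ``peak_id``, ``rt``, ``area``.
    Rows with non-positive area raise :class:`ValidationError` naming the row.
    """
    path = Path(path)
    sep = _dialect_sep(path, dialect)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}")
    peaks = []
    for idx, rec in df.iterrows():
        area = float(rec["area"])
        if not area > 0:
            raise ValidationError(f"{path.name} row {idx + 1}: area must be > 0, got {area}")
        peaks.append(Peak(peak_id=int(rec["peak_id"]), rt=float(rec["rt"]), area=area))
    return PeakTable(
        injection_id=injection_id if injection_id is not None else path.stem,
        volume=volume,
        peaks=peaks,
    )


def write_peak_table(table: PeakTable, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    sep = _dialect_sep(path, dialect)
    df = pd.DataFrame(
        {
            "peak_id": [p.peak_id for p in table.peaks],
            "rt": [p.rt for p in table.peaks],
            "area": [p.area for p in table.peaks],
        }
    )
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Fingerprint-matrix I/O (CSV: batch_id, p1..pN)
# ---------------------------------------------------------------------------

def read_fingerprint_matrix(path: str | Path) -> FingerprintMatrix:
    df = pd.read_csv(path)
    if "batch_id" not in df.columns:
        raise FormatError(f"{Path(path).name}: missing 'batch_id' column")
    peak_cols = [c for c in df.columns if c != "batch_id"]
    if not peak_cols:
        raise FormatError(f"{Path(path).name}: no peak columns found")
    return FingerprintMatrix(
        batch_ids=[str(b) for b in df["batch_id"]],
        areas=df[peak_cols].to_numpy(dtype=float),
    )


def write_fingerprint_matrix(fm: FingerprintMatrix, path: str | Path) -> None:
    cols = {f"p{i + 1}": fm.areas[:, i] for i in range(fm.n_common)}
    pd.DataFrame({"batch_id": fm.batch_ids, **cols}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Marker-definition I/O (YAML list or CSV)
# ---------------------------------------------------------------------------

def read_markers(path: str | Path) -> list[MarkerDef]:
    """Read marker definitions from YAML (list of mappings) or CSV."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        records = yaml.safe_load(path.read_text())
        if not isinstance(records, list):
            raise FormatError(f"{path.name}: expected a YAML list of markers")
    else:
        records = pd.read_csv(path).to_dict("records")
    markers = []
    for rec in records:
        try:
            markers.append(
                MarkerDef(
                    name=str(rec["name"]),
                    ref_conc=float(rec["ref_conc_mg_ml"]),
                    common_peak_index=int(rec["common_peak_index"]),
                    linear_range=(float(rec["linear_low_ug"]), float(rec["linear_high_ug"])),
                    rt=float(rec["rt"]) if rec.get("rt") is not None and not pd.isna(rec.get("rt")) else None,
                )
            )
        except KeyError as exc:
            raise FormatError(f"{path.name}: marker record missing field {exc}") from exc
    return markers


def write_markers(markers: Sequence[MarkerDef], path: str | Path) -> None:
    records = [
        {
            "name": m.name,
            "ref_conc_mg_ml": m.ref_conc,
            "common_peak_index": m.common_peak_index,
            "linear_low_ug": m.linear_range[0],
            "linear_high_ug": m.linear_range[1],
            "rt": m.rt,
        }
        for m in markers
    ]
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(records, sort_keys=False))
    else:
        pd.DataFrame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def _rt_clusters(pooled: list[tuple[float, int, Peak]], tol: float) -> list[list[tuple[float, int, Peak]]]:
    """Single-linkage clusters of pooled (rt, table-index, peak), cut at tol.

    In one dimension single linkage with cut height ``tol`` is exactly:
    sort by rt and split wherever consecutive rts differ by more than tol.
    """
    pooled = sorted(pooled, key=lambda t: t[0])
    clusters: list[list[tuple[float, int, Peak]]] = []
    current: list[tuple[float, int, Peak]] = []
    for item in pooled:
        if current and item[0] - current[-1][0] > tol:
            clusters.append(current)
            current = []
        current.append(item)
    if current:
        clusters.append(current)
    return clusters


def match_common_peaks(
    tables: Sequence[PeakTable],
    rt_tolerance: float = DEFAULT_RT_TOLERANCE,
) -> FingerprintMatrix:
    """Identify common peaks across injections and stack their areas.

    A cluster of retention times is a common peak iff every injection
    contributes exactly one peak lying within ``rt_tolerance`` of the
    cluster's mean rt.  A cluster that spans every injection but contains
    two peaks of one injection is ambiguous and raises
    :class:`AmbiguityError` listing the offending retention times.
    Columns are ordered by mean retention time.
    """
    if len(tables) < 2:
        raise ValidationError("need at least two peak tables to match common peaks")
    if not rt_tolerance > 0:
        raise ValidationError("rt_tolerance must be > 0")

    pooled = [(p.rt, ti, p) for ti, t in enumerate(tables) for p in t.peaks]
    n_tables = len(tables)
    common: list[tuple[float, np.ndarray]] = []   # (mean rt, areas per table)
    for cluster in _rt_clusters(pooled, rt_tolerance):
        members = [ti for _, ti, _ in cluster]
        covers_all = set(members) == set(range(n_tables))
        if not covers_all:
            continue
        dup = [ti for ti in set(members) if members.count(ti) > 1]
        if dup:
            rts = sorted(rt for rt, ti, _ in cluster if ti in dup)
            raise AmbiguityError(
                f"injection(s) {[tables[ti].injection_id for ti in dup]} contribute "
                f"multiple peaks to one rt cluster (rts {rts})"
            )
        mean_rt = float(np.mean([rt for rt, _, _ in cluster]))
        if any(abs(rt - mean_rt) > rt_tolerance for rt, _, _ in cluster):
            continue    # too spread out to call one peak
        areas = np.empty(n_tables)
        for rt, ti, peak in cluster:
            areas[ti] = peak.area
        common.append((mean_rt, areas))

    common.sort(key=lambda c: c[0])
    if not common:
        raise ValidationError("no common peaks found at the given rt tolerance")
    return FingerprintMatrix(
        batch_ids=[t.injection_id for t in tables],
        areas=np.column_stack([a for _, a in common]),
        peak_rts=np.array([rt for rt, _ in common]),
    )


def assign_marker_peaks(
    table: PeakTable,
    markers: Sequence[MarkerDef],
    rt_tolerance: float = DEFAULT_RT_TOLERANCE,
) -> dict[str, Peak]:
    """Assign each marker to the unique peak within ``rt_tolerance`` of its rt.

    Markers without a stated rt are assigned positionally: the table must
    then contain exactly one peak per marker, matched in retention-time
    order of the markers' common-peak indices.
    """
    out: dict[str, Peak] = {}
    with_rt = [m for m in markers if m.rt is not None]
    if len(with_rt) == len(markers):
        for m in markers:
            hits = [p for p in table.peaks if abs(p.rt - m.rt) <= rt_tolerance]
            if not hits:
                raise ValidationError(
                    f"injection {table.injection_id}: no peak within "
                    f"{rt_tolerance} min of marker {m.name} (rt {m.rt})"
                )
            if len(hits) > 1:
                raise AmbiguityError(
                    f"injection {table.injection_id}: marker {m.name} matches "
                    f"{len(hits)} peaks (rts {[p.rt for p in hits]})"
                )
            out[m.name] = hits[0]
        return out
    if len(table) != len(markers):
        raise ValidationError(
            f"injection {table.injection_id}: positional marker assignment needs "
            f"exactly {len(markers)} peaks, found {len(table)}"
        )
    order = sorted(markers, key=lambda m: m.common_peak_index)
    for m, p in zip(order, table.peaks):
        out[m.name] = p
    return out
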