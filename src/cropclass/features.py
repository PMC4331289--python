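"""Per-parcel spectral-band / vegetation-index extraction and the feature matrix.

For every parcel and every acquisition the module computes the arithmetic
mean of each spectral band over the parcel's member pixels plus three
vegetation indices:

    NDVI = (NIR - Red) / (NIR + Red)   (greenness)
    Stu  = Red / Green                 (stubble / senescence)
    BG   = Blue / Green                (bare-soil brightness)

Records are assembled into a parcels x (7 variables x n times) matrix —
column names ``T{k}{Var}`` such as ``T3NDVI`` — with one label column, the
input of the decision-tree stage.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cropclass.geo_io import UNKNOWN, ParcelSet, RasterScene, parcel_pixel_indices

log = logging.getLogger(__name__)

#: Canonical per-time variables, in column order (time-major matrices).
VARIABLES = ("Blue", "Gree", "Red", "NIR", "NDVI", "Stu", "BG")

#: Parse-time aliases for variable tokens in matrix headers.
VARIABLE_ALIASES = {"Green": "Gree", "B/G": "BG", "STU": "Stu", "B_G": "BG"}

LABEL_COLUMN = "label"
ID_COLUMN = "parcel_id"

_COLUMN_RE = re.compile(r"^(T\d+)(.+)$")


class MatrixFormatError(ValueError):
    """Raised for malformed matrix / SBVI files."""


def compute_vi(blue, gree, red, nir):
    """Vegetation indices from band values (scalars or arrays).

    Returns ``(ndvi, stu, bg)``; a ratio whose denominator is zero yields
    NaN (the missing sentinel). Negative inputs are a domain error: digital
    numbers are non-negative by construction.
    """
    blue, gree, red, nir = (np.asarray(a, dtype=float) for a in (blue, gree, red, nir))
    for name, a in (("blue", blue), ("gree", gree), ("red", red), ("nir", nir)):
        if np.any(~np.isfinite(a)) or np.any(a < 0):
            raise ValueError(f"band {name} holds negative or non-finite values")
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(nir + red > 0, (nir - red) / (nir + red), np.nan)
        stu = np.where(gree > 0, red / gree, np.nan)
        bg = np.where(gree > 0, blue / gree, np.nan)
    if ndvi.ndim == 0:
        return float(ndvi), float(stu), float(bg)
    return ndvi, stu, bg


@dataclass
class SBVIRecord:
    """Band means and vegetation indices of one parcel, one row per time."""

    parcel_id: str
    values: dict[str, dict[str, float]] = field(default_factory=dict)
    pixel_counts: dict[str, int] = field(default_factory=dict)

    @property
    def times(self) -> list[str]:
        return list(self.values)

    def features(self, times: list[str] | None = None) -> dict[str, float]:
        """Flat ``{T{k}{Var}: value}`` view, time-major."""
        out: dict[str, float] = {}
        for t in times or self.times:
            if t not in self.values:
                raise KeyError(f"record {self.parcel_id} has no time {t}")
            for var in VARIABLES:
                out[f"{t}{var}"] = self.values[t][var]
        return out


@dataclass
class MatrixData:
    """Parcels x features table with a label column (the DT input).

    ``frame`` is indexed by parcel ID; feature columns are time-major
    (``T1Blue`` ... ``T1BG``, ``T2Blue`` ...) and the final column is the
    label (:data:`~cropclass.geo_io.UNKNOWN` for unlabeled parcels).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if LABEL_COLUMN not in self.frame.columns:
            raise MatrixFormatError("matrix lacks a label column")
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].tolist()
            raise MatrixFormatError(f"duplicate parcel IDs: {dupes}")
        for col in self.feature_columns:
            if not _COLUMN_RE.match(col) or _parse_column(col)[1] not in VARIABLES:
                raise MatrixFormatError(f"unrecognized feature column {col!r}")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c != LABEL_COLUMN]

    @property
    def times(self) -> list[str]:
        seen: list[str] = []
        for c in self.feature_columns:
            t = _parse_column(c)[0]
            if t not in seen:
                seen.append(t)
        return seen

    @property
    def labels(self) -> pd.Series:
        return self.frame[LABEL_COLUMN]

    def features(self) -> pd.DataFrame:
        return self.frame[self.feature_columns]

    def restrict(self, times: list[str]) -> "MatrixData":
        """Restrict columns to a subset of times (time-major order kept)."""
        missing = [t for t in times if t not in self.times]
        if missing:
            raise MatrixFormatError(f"times not in matrix: {missing}")
        cols = [f"{t}{v}" for t in times for v in VARIABLES]
        return MatrixData(self.frame[cols + [LABEL_COLUMN]].copy())

    def with_labels(self, mapper) -> "MatrixData":
        """Return a copy whose labels are transformed by ``mapper``."""
        frame = self.frame.copy()
        frame[LABEL_COLUMN] = [mapper(v) for v in frame[LABEL_COLUMN]]
        return MatrixData(frame)

    def labeled(self) -> "MatrixData":
        """Rows with ground truth only."""
        return MatrixData(self.frame[self.frame[LABEL_COLUMN] != UNKNOWN].copy())

    def __len__(self) -> int:
        return len(self.frame)


def _parse_column(col: str) -> tuple[str, str]:
    m = _COLUMN_RE.match(col)
    if not m:
        raise MatrixFormatError(f"unrecognized feature column {col!r}")
    time, var = m.group(1), m.group(2)
    var = VARIABLE_ALIASES.get(var, var)
    return time, var


def _check_aligned(series: list[RasterScene]) -> None:
    if not series:
        raise ValueError("empty scene series")
    ref = series[0]
    tags = [s.time_tag for s in series]
    if len(set(tags)) != len(tags):
        raise ValueError(f"duplicate time tags in series: {tags}")
    for s in series[1:]:
        if s.shape != ref.shape or s.geotransform != ref.geotransform:
            raise ValueError(
                f"scene {s.time_tag} grid does not match {ref.time_tag}"
            )
        if s.crs_tag != ref.crs_tag:
            raise ValueError(f"scene {s.time_tag} CRS differs")


def extract_sbvi(
    series: list[RasterScene],
    parcels: ParcelSet,
    vi_mode: str = "per_pixel",
    buffer: float = 0.0,
) -> list[SBVIRecord]:
    """Extract per-parcel band means and vegetation indices for every time.

    ``vi_mode='per_pixel'`` (default) computes each index per pixel and
    averages over the parcel, respecting the nonlinearity of NDVI;
    ``vi_mode='from_means'`` evaluates the index formulas on the band
    means. Parcels covering no pixel are excluded and logged.
    """
    if vi_mode not in ("per_pixel", "from_means"):
        raise ValueError(f"unknown vi_mode {vi_mode!r}")
    _check_aligned(series)
    if parcels.crs_tag != series[0].crs_tag:
        raise ValueError(
            f"CRS mismatch: parcels {parcels.crs_tag!r} vs scenes {series[0].crs_tag!r}"
        )
    records: list[SBVIRecord] = []
    dropped: list[str] = []
    for parcel in parcels:
        idx = parcel_pixel_indices(series[0], parcel.polygon, buffer=buffer)
        if not idx:
            dropped.append(parcel.parcel_id)
            continue
        rows = np.fromiter((r for r, _ in idx), dtype=int, count=len(idx))
        cols = np.fromiter((c for _, c in idx), dtype=int, count=len(idx))
        rec = SBVIRecord(parcel.parcel_id)
        for scene in series:
            px = {b: scene.bands[b][rows, cols] for b in ("Blue", "Gree", "Red", "NIR")}
            means = {b: float(np.mean(v)) for b, v in px.items()}
            if vi_mode == "per_pixel":
                ndvi, stu, bg = compute_vi(px["Blue"], px["Gree"], px["Red"], px["NIR"])
                vi = {"NDVI": float(np.mean(ndvi)), "Stu": float(np.mean(stu)),
                      "BG": float(np.mean(bg))}
            else:
                ndvi, stu, bg = compute_vi(
                    means["Blue"], means["Gree"], means["Red"], means["NIR"]
                )
                vi = {"NDVI": ndvi, "Stu": stu, "BG": bg}
            rec.values[scene.time_tag] = {**means, **vi}
            rec.pixel_counts[scene.time_tag] = len(idx)
        records.append(rec)
    if dropped:
        log.warning("excluded %d parcel(s) with no covered pixels: %s",
                    len(dropped), dropped)
    return records


def build_matrix(
    records: list[SBVIRecord],
    labels: dict[str, str] | None = None,
    times_subset: list[str] | None = None,
) -> MatrixData:
    """Assemble SBVI records into the DT feature matrix.

    Rows with any missing feature value are dropped with a warning; an
    empty result is an error.
    """
    if not records:
        raise MatrixFormatError("no complete parcels: no records supplied")
    available = records[0].times
    times = list(times_subset) if times_subset is not None else available
    if not times:
        raise MatrixFormatError("empty times subset")
    bad = [t for t in times if t not in available]
    if bad:
        raise MatrixFormatError(f"times not in series: {bad}")
    labels = labels or {}
    rows, index, incomplete = [], [], []
    for rec in records:
        feats = rec.features(times)
        if any(not np.isfinite(v) for v in feats.values()):
            incomplete.append(rec.parcel_id)
            continue
        feats[LABEL_COLUMN] = labels.get(rec.parcel_id, UNKNOWN)
        rows.append(feats)
        index.append(rec.parcel_id)
    if incomplete:
        log.warning("dropped %d parcel(s) with missing features: %s",
                    len(incomplete), incomplete)
    if not rows:
        raise MatrixFormatError("no complete parcels")
    frame = pd.DataFrame(rows, index=pd.Index(index, name=ID_COLUMN))
    return MatrixData(frame)


# ---------------------------------------------------------------------------
# Text formats: matrix file and per-parcel SBVI files


def write_matrix(matrix: MatrixData, path: str | Path) -> None:
    """Tab-delimited matrix file: header row, '.' decimals, UTF-8."""
    frame = matrix.frame.reset_index()
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_matrix(path: str | Path) -> MatrixData:
    """Read a matrix file, canonicalizing header aliases (B/G -> BG ...)."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or not lines[0].strip():
        raise MatrixFormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[0] != ID_COLUMN or LABEL_COLUMN not in header:
        raise MatrixFormatError(
            f"{path}: line 1: header must start with {ID_COLUMN!r} and "
            f"contain {LABEL_COLUMN!r}"
        )
    canon = [header[0]]
    for col in header[1:]:
        if col == LABEL_COLUMN:
            canon.append(col)
            continue
        t, var = _parse_column(col)
        if var not in VARIABLES:
            raise MatrixFormatError(f"{path}: line 1: unknown variable in {col!r}")
        canon.append(f"{t}{var}")
    ncol = len(canon)
    label_pos = canon.index(LABEL_COLUMN)
    index, rows = [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != ncol:
            raise MatrixFormatError(
                f"{path}: line {lineno}: expected {ncol} fields, got {len(parts)}"
            )
        row = {}
        for col, val in zip(canon, parts):
            if col == ID_COLUMN:
                index.append(val)
            elif col == LABEL_COLUMN:
                row[col] = val
            else:
                try:
                    row[col] = float(val)
                except ValueError as exc:
                    raise MatrixFormatError(
                        f"{path}: line {lineno}: non-numeric value {val!r} in {col}"
                    ) from exc
        rows.append(row)
    if not rows:
        raise MatrixFormatError(f"{path}: no data rows")
    frame = pd.DataFrame(rows, index=pd.Index(index, name=ID_COLUMN))
    # keep label last for readability
    cols = [c for c in frame.columns if c != LABEL_COLUMN] + [LABEL_COLUMN]
    return MatrixData(frame[cols])


def write_sbvi(record: SBVIRecord, path: str | Path) -> None:
    """Per-parcel SBVI file: one row per time, tab-delimited."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time\t" + "\t".join(VARIABLES) + "\tpixel_count\n")
        for t in record.times:
            vals = record.values[t]
            fh.write(t + "\t" + "\t".join(repr(vals[v]) for v in VARIABLES)
                     + f"\t{record.pixel_counts[t]}\n")


def read_sbvi(path: str | Path, parcel_id: str | None = None) -> SBVIRecord:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise MatrixFormatError(f"{path}: empty SBVI file")
    header = lines[0].split("\t")
    if header[0] != "time":
        raise MatrixFormatError(f"{path}: line 1: SBVI header must start with 'time'")
    vars_in = [VARIABLE_ALIASES.get(v, v) for v in header[1:-1]]
    rec = SBVIRecord(parcel_id or path.stem)
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise MatrixFormatError(f"{path}: line {lineno}: ragged row")
        t = parts[0]
        try:
            rec.values[t] = {v: float(x) for v, x in zip(vars_in, parts[1:-1])}
            rec.pixel_counts[t] = int(parts[-1])
        except ValueError as exc:
            raise MatrixFormatError(f"{path}: line {lineno}: non-numeric value") from exc
    return rec
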