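"""Data model and tabular I/O for single-cell IFISH cohorts.

A cohort is two tables: one row per quantified tumor cell and one row per
patient of clinical covariates.  Cell intensities are assumed to be already
adjusted for background and perinuclear signal upstream (by the image-analysis
pipeline that produced them); the ``intensities_adjusted`` provenance flag
records that assumption.  Both tables travel as pandas DataFrames inside a
:class:`CohortTable`; :class:`CellRecord` / :class:`ClinicalRecord` give a
typed row view for single-record work.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Mapping

import numpy as np
import pandas as pd

INTENSITY_MAX = 4095  # 12-bit scale
TIMEPOINTS = ("pre", "post", "metastasis")
SPATIAL_LABELS = ("cluster", "scatter", "mix")

#: canonical cell-table columns, in storage order
CELL_COLUMNS = (
    "patient_id",
    "timepoint",
    "image_id",
    "er_intensity",
    "her2_intensity",
    "her2_area_px",
    "cent17_count",
    "spatial_label",
)

CLINICAL_COLUMNS = (
    "patient_id",
    "pcr",
    "relapse",
    "death_bc",
    "time_dfs",
    "time_os",
    "er_status_ihc",
    "grade",
    "her2_ihc",
)


class SchemaError(ValueError):
    """A required column is missing or unmappable."""


class ValidationError(ValueError):
    """One or more rows violate the cell/clinical record contract."""

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


@dataclass(frozen=True)
class CellRecord:
    """One tumor cell's quantified markers.

    Intensities are dimensionless on a 12-bit scale [0, 4095];
    ``her2_area_px`` is the total *HER2* probe signal area within the nucleus
    in pixels.  ``cent17_count`` and ``spatial_label`` may be missing.
    """

    patient_id: str
    timepoint: str
    image_id: str
    er_intensity: float
    her2_intensity: float
    her2_area_px: float
    cent17_count: int | None = None
    spatial_label: str | None = None

    def __post_init__(self):
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(f"timepoint {self.timepoint!r} not one of {TIMEPOINTS}")
        for name in ("er_intensity", "her2_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= INTENSITY_MAX:
                raise ValidationError(f"{name}={v} outside [0, {INTENSITY_MAX}]")
        if self.her2_area_px < 0:
            raise ValidationError(f"her2_area_px={self.her2_area_px} is negative")
        if self.cent17_count is not None and self.cent17_count < 0:
            raise ValidationError(f"cent17_count={self.cent17_count} is negative")
        if self.spatial_label is not None and self.spatial_label not in SPATIAL_LABELS:
            raise ValidationError(f"spatial_label {self.spatial_label!r} not one of {SPATIAL_LABELS}")


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient clinical covariates and outcome indicators.

    ``pcr`` is pathological complete response: no residual invasive tumor
    cells after neoadjuvant treatment.  Times are follow-up months
    (disease-free and overall breast-cancer-specific survival).
    """

    patient_id: str
    pcr: bool
    relapse: bool
    death_bc: bool
    time_dfs: float
    time_os: float
    er_status_ihc: str | None = None
    grade: int | None = None
    her2_ihc: str | None = None

    def __post_init__(self):
        if self.time_dfs <= 0 or self.time_os <= 0:
            raise ValidationError(
                f"follow-up times must be positive (got dfs={self.time_dfs}, os={self.time_os})"
            )
        if self.her2_ihc is not None and self.her2_ihc not in ("2+", "3+"):
            raise ValidationError(f"her2_ihc {self.her2_ihc!r} not one of ('2+', '3+')")


@dataclass
class CohortTable:
    """All cells and clinical covariates of a cohort, plus provenance.

    ``cells`` and ``clinical`` are DataFrames with the canonical columns;
    ``truth`` carries planted simulation parameters (synthetic cohorts only).
    """

    cells: pd.DataFrame
    clinical: pd.DataFrame | None = None
    provenance: dict[str, Any] = field(default_factory=dict)
    truth: dict[str, Any] | None = None

    def __post_init__(self):
        self.cells = self.cells.reset_index(drop=True)
        if self.clinical is not None:
            self.clinical = self.clinical.reset_index(drop=True)
            missing = set(self.cells["patient_id"]) - set(self.clinical["patient_id"])
            if missing:
                raise ValidationError(
                    f"cells reference patients absent from clinical table: {sorted(missing)}"
                )

    def iter_cells(self) -> Iterator[CellRecord]:
        for row in self.cells.itertuples(index=False):
            d = row._asdict()
            yield CellRecord(**{k: d[k] for k in CELL_COLUMNS if k in d})

    def samples(self) -> pd.core.groupby.DataFrameGroupBy:
        """Group cells by (patient, timepoint) — the unit of analysis.

        Multiple images per biopsy are pooled; ``image_id`` is retained for
        audit only.
        """
        return self.cells.groupby(["patient_id", "timepoint"], sort=True)

    def sample_sizes(self) -> pd.Series:
        return self.samples().size()

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.provenance, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# I/O

_REQUIRED_CELL_COLS = ("patient_id", "timepoint", "er_intensity", "her2_intensity", "her2_area_px")
_NUMERIC_CELL_COLS = ("er_intensity", "her2_intensity", "her2_area_px")


def _sniff_sep(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_cells(
    path: str | Path | io.TextIOBase,
    schema: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> CohortTable:
    """Read a delimited per-cell table into a validated :class:`CohortTable`.

    Parameters
    ----------
    path
        CSV/TSV file with a header row, or an open text buffer.
    schema
        Optional mapping ``{canonical_name: column_name_in_file}`` for files
        whose headers differ from the canonical ones.
    sep
        Field delimiter; inferred from the filename extension when omitted.

    Raises
    ------
    SchemaError
        if a required column cannot be found.
    ValidationError
        if any row fails validation; the offending 1-based data row numbers
        are listed in the message and on ``exc.rows``.
    """
    if sep is None:
        sep = _sniff_sep(path) if isinstance(path, (str, Path)) else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if schema:
        missing_src = [v for v in schema.values() if v not in raw.columns]
        if missing_src:
            raise SchemaError(f"schema maps to columns absent from file: {missing_src}")
        raw = raw.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in _REQUIRED_CELL_COLS if c not in raw.columns]
    if missing:
        raise SchemaError(f"required columns missing: {missing}; present: {list(raw.columns)}")
    if "image_id" not in raw.columns:
        raw["image_id"] = "img0"
    for opt in ("cent17_count", "spatial_label"):
        if opt not in raw.columns:
            raw[opt] = ""

    bad_rows: dict[int, str] = {}
    df = raw.loc[:, list(CELL_COLUMNS)].copy()
    # validate with the tolerant parser, convert with numpy's correctly
    # rounded one so that read -> write round-trips to the same bytes
    for col in _NUMERIC_CELL_COLS:
        vals = pd.to_numeric(df[col], errors="coerce")
        for i in df.index[vals.isna()]:
            bad_rows.setdefault(i + 1, f"non-numeric {col}={df.at[i, col]!r}")
        if not vals.isna().any():
            vals = df[col].to_numpy(dtype="U32").astype(np.float64)
        df[col] = vals
    cent = df["cent17_count"].replace("", np.nan)
    cent_num = pd.to_numeric(cent, errors="coerce")
    for i in df.index[cent.notna() & cent_num.isna()]:
        bad_rows.setdefault(i + 1, f"non-numeric cent17_count={cent[i]!r}")
    if not (cent.notna() & cent_num.isna()).any():
        cent_num = cent.fillna("nan").to_numpy(dtype="U32").astype(np.float64)
    df["cent17_count"] = cent_num
    df["spatial_label"] = df["spatial_label"].replace("", np.nan).astype(object)

    ok = ~df.index.isin([r - 1 for r in bad_rows])
    bounds_bad = ok & (
        ~df["timepoint"].isin(TIMEPOINTS)
        | (df["er_intensity"] < 0) | (df["er_intensity"] > INTENSITY_MAX)
        | (df["her2_intensity"] < 0) | (df["her2_intensity"] > INTENSITY_MAX)
        | (df["her2_area_px"] < 0)
        | (df["cent17_count"] < 0)
        | (df["spatial_label"].notna() & ~df["spatial_label"].isin(SPATIAL_LABELS))
    )
    for i in df.index[bounds_bad]:
        bad_rows.setdefault(i + 1, "value outside allowed range/enum")
    if bad_rows:
        listing = "; ".join(f"row {r}: {m}" for r, m in sorted(bad_rows.items()))
        raise ValidationError(f"{len(bad_rows)} invalid row(s): {listing}", rows=sorted(bad_rows))

    return CohortTable(cells=df, provenance={"source": str(path), "intensities_adjusted": True})


def write_cells(cohort: CohortTable, path: str | Path, sep: str | None = None) -> None:
    """Write the cell table as delimited text (inverse of :func:`read_cells`)."""
    if sep is None:
        sep = _sniff_sep(path)
    cohort.cells.to_csv(path, sep=sep, index=False)


_BOOL_MAP = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}


def read_clinical(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read the per-patient clinical table, coercing event indicators to bool."""
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ("patient_id", "pcr", "relapse", "death_bc", "time_dfs", "time_os") if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical table missing columns: {missing}")
    df["patient_id"] = df["patient_id"].astype(str)
    for col in ("pcr", "relapse", "death_bc"):
        if df[col].dtype == object:
            df[col] = df[col].astype(str).str.lower().map(_BOOL_MAP)
        df[col] = df[col].astype(bool)
    bad = df.index[(df["time_dfs"] <= 0) | (df["time_os"] <= 0)]
    if len(bad):
        raise ValidationError(
            f"non-positive follow-up times on row(s) {[i + 1 for i in bad]}",
            rows=[i + 1 for i in bad],
        )
    return df


# ---------------------------------------------------------------------------
# Filtering


@dataclass(frozen=True)
class ExclusionReport:
    """Which (patient, timepoint) samples were dropped and why."""

    excluded: tuple[tuple[str, str, int], ...]  # (patient_id, timepoint, n_cells)
    min_cells: int

    def __str__(self) -> str:
        if not self.excluded:
            return f"no samples excluded (min_cells={self.min_cells})"
        lines = [f"excluded {len(self.excluded)} sample(s) with < {self.min_cells} cells:"]
        lines += [f"  {p} / {t}: {n} cells" for p, t, n in self.excluded]
        return "\n".join(lines)


def filter_samples(cohort: CohortTable, min_cells: int = 50) -> tuple[CohortTable, ExclusionReport]:
    """Drop (patient, timepoint) samples with too few tumor cells.

    Samples with very low residual tumor cellularity (typically after
    neoadjuvant therapy) yield unstable composition estimates and are
    excluded.  Surviving records are returned unchanged.
    """
    if min_cells < 1:
        raise ValueError(f"min_cells must be >= 1, got {min_cells}")
    sizes = cohort.sample_sizes()
    drop = sizes[sizes < min_cells]
    excluded = tuple((str(p), str(t), int(n)) for (p, t), n in drop.items())
    if len(excluded) == 0:
        kept = cohort.cells
    else:
        group_size = cohort.cells.groupby(["patient_id", "timepoint"])["patient_id"].transform("size")
        kept = cohort.cells[group_size >= min_cells]
    clinical = cohort.clinical
    if clinical is not None:
        clinical = clinical[clinical["patient_id"].isin(set(kept["patient_id"]))]
    out = CohortTable(
        cells=kept.reset_index(drop=True),
        clinical=None if clinical is None else clinical.reset_index(drop=True),
        provenance={**cohort.provenance, "min_cells": min_cells},
        truth=cohort.truth,
    )
    return out, ExclusionReport(excluded=excluded, min_cells=min_cells)


def cells_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    """Build a canonical cell DataFrame from :class:`CellRecord` objects."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=list(CELL_COLUMNS))
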