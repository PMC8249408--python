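"""Marked cell point patterns: data model, validation, and tabular I/O.

A pattern is one patient's multiplex-IHC cell table: 2-D coordinates in
micrometres plus two categorical marks, the cell *phenotype* (B cell,
T-cell lineages, cancer, other) and the *tissue category* (cancer-cell
island vs stroma, assigned upstream by tissue segmentation).  Patterns are
exchanged as plain CSV/TSV with a small ``# key=value`` metadata header and
an optional WKT sidecar carrying the region-of-interest polygon.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely import wkt as shapely_wkt
from shapely.geometry import Point, Polygon

__all__ = [
    "PHENOTYPES",
    "TISSUE_CATEGORIES",
    "LYMPHOCYTE_PHENOTYPES",
    "T_LINEAGE_PHENOTYPES",
    "CellRecord",
    "RegionOfInterest",
    "PointPattern",
    "ValidationReport",
    "PatternFormatError",
    "PatternValidationError",
    "normalize_phenotype",
    "normalize_tissue_category",
    "read_pattern_table",
    "write_pattern_table",
    "validate_pattern",
]

PHENOTYPES = ("B", "T", "T_CD8", "T_helper", "Treg", "cancer", "other")
TISSUE_CATEGORIES = ("cancer_island", "stroma")

#: Phenotypes that count as lymphocytes (B plus every T-cell lineage).
LYMPHOCYTE_PHENOTYPES = frozenset({"B", "T", "T_CD8", "T_helper", "Treg"})
#: CD3+ T-cell lineages, pooled when subtype resolution is unavailable.
T_LINEAGE_PHENOTYPES = frozenset({"T", "T_CD8", "T_helper", "Treg"})

OUTCOMES = ("good", "poor", "normal", "unlabeled")

# Default mapping from staining-panel labels to canonical phenotypes.  The two
# panels used in practice label cells by marker (CD20, CD3, ...) or by class
# (Tumor, Stroma); anything phenotyped but unmatched maps to "other".
DEFAULT_PHENOTYPE_ALIASES: dict[str, str] = {
    "b": "B", "cd20": "B", "b cell": "B", "bcell": "B",
    "t": "T", "cd3": "T", "t cell": "T", "tcell": "T",
    "t_cd8": "T_CD8", "cd8": "T_CD8", "cytotoxic": "T_CD8",
    "t_helper": "T_helper", "th": "T_helper", "cd4": "T_helper",
    "helper": "T_helper",
    "treg": "Treg", "foxp3": "Treg", "regulatory": "Treg",
    "cancer": "cancer", "ck": "cancer", "panck": "cancer",
    "pan-ck": "cancer", "tumor": "cancer", "cytokeratin": "cancer",
    "other": "other", "stromal": "other", "dapi": "other",
}

DEFAULT_TISSUE_ALIASES: dict[str, str] = {
    "cancer_island": "cancer_island", "cancerisland": "cancer_island",
    "cancer island": "cancer_island", "island": "cancer_island",
    "tumor": "cancer_island", "tumour": "cancer_island",
    "stroma": "stroma", "stromal": "stroma",
}

REQUIRED_COLUMNS = ("cell_id", "x_um", "y_um", "phenotype", "tissue_category")


class PatternFormatError(ValueError):
    """Raised for structurally unreadable pattern tables."""


class PatternValidationError(ValueError):
    """Raised when a table parses but violates the data-model invariants."""


def normalize_phenotype(label: str,
                        aliases: Mapping[str, str] | None = None) -> str | None:
    """Map a raw phenotype label onto the canonical enum, or None."""
    if label in PHENOTYPES:
        return label
    table = DEFAULT_PHENOTYPE_ALIASES if aliases is None else aliases
    return table.get(str(label).strip().lower())


def normalize_tissue_category(label: str,
                              aliases: Mapping[str, str] | None = None) -> str | None:
    if label in TISSUE_CATEGORIES:
        return label
    table = DEFAULT_TISSUE_ALIASES if aliases is None else aliases
    return table.get(str(label).strip().lower())


@dataclass(frozen=True)
class CellRecord:
    """One phenotyped cell with coordinates in micrometres."""

    cell_id: str
    x: float
    y: float
    phenotype: str
    tissue_category: str

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise PatternValidationError(
                f"cell {self.cell_id}: non-finite coordinates ({self.x}, {self.y})")
        if self.phenotype not in PHENOTYPES:
            raise PatternValidationError(
                f"cell {self.cell_id}: unknown phenotype {self.phenotype!r}")
        if self.tissue_category not in TISSUE_CATEGORIES:
            raise PatternValidationError(
                f"cell {self.cell_id}: unknown tissue category "
                f"{self.tissue_category!r}")

    @property
    def is_lymphocyte(self) -> bool:
        return self.phenotype in LYMPHOCYTE_PHENOTYPES


@dataclass
class RegionOfInterest:
    """Pathologist-outlined tumor region: denominator for every density.

    ``area_mm2`` is authoritative; the polygon, when present, must agree with
    it to 0.1% relative tolerance (coordinates in μm, 1 mm² = 1e6 μm²).
    """

    area_mm2: float
    boundary: Polygon | None = None
    from_bounding_box: bool = False

    def __post_init__(self) -> None:
        if not (self.area_mm2 > 0):
            raise PatternValidationError(f"ROI area must be > 0, got {self.area_mm2}")
        if self.boundary is not None:
            poly_mm2 = self.boundary.area / 1e6
            if abs(poly_mm2 - self.area_mm2) > 1e-3 * self.area_mm2:
                raise PatternValidationError(
                    f"ROI polygon area {poly_mm2:.6g} mm² disagrees with "
                    f"declared area {self.area_mm2:.6g} mm² beyond 0.1%")

    @classmethod
    def from_polygon(cls, boundary: Polygon) -> "RegionOfInterest":
        return cls(area_mm2=boundary.area / 1e6, boundary=boundary)

    def contains(self, x: float, y: float) -> bool:
        if self.boundary is None:
            return True
        return self.boundary.covers(Point(x, y))


class PointPattern:
    """A patient's marked point pattern.

    Cells are stored in a pandas DataFrame with columns
    ``cell_id, x, y, phenotype, tissue_category``; row order is preserved and
    defines deterministic tie-breaking downstream (e.g. border-cell
    assignment during clustering).
    """

    def __init__(self,
                 cells: pd.DataFrame | Iterable[CellRecord],
                 roi: RegionOfInterest,
                 patient_id: str = "anon",
                 outcome: str = "unlabeled") -> None:
        if outcome not in OUTCOMES:
            raise PatternValidationError(f"unknown outcome {outcome!r}")
        if isinstance(cells, pd.DataFrame):
            df = cells.reset_index(drop=True).copy()
        else:
            df = pd.DataFrame(
                [(c.cell_id, c.x, c.y, c.phenotype, c.tissue_category)
                 for c in cells],
                columns=["cell_id", "x", "y", "phenotype", "tissue_category"])
        missing = {"cell_id", "x", "y", "phenotype", "tissue_category"} - set(df.columns)
        if missing:
            raise PatternFormatError(f"cell table missing columns: {sorted(missing)}")
        df["cell_id"] = df["cell_id"].astype(str)
        df["x"] = df["x"].astype(float)
        df["y"] = df["y"].astype(float)
        self.cells = df
        self.roi = roi
        self.patient_id = str(patient_id)
        self.outcome = outcome

    # -- basic accessors -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) float array of coordinates in μm."""
        return self.cells[["x", "y"]].to_numpy(dtype=float)

    @property
    def lymphocyte_mask(self) -> np.ndarray:
        return self.cells["phenotype"].isin(LYMPHOCYTE_PHENOTYPES).to_numpy()

    def phenotype_mask(self, phenotypes: Iterable[str]) -> np.ndarray:
        return self.cells["phenotype"].isin(set(phenotypes)).to_numpy()

    def tissue_mask(self, tissue_scope: str) -> np.ndarray:
        if tissue_scope == "any":
            return np.ones(self.n_cells, dtype=bool)
        if tissue_scope not in TISSUE_CATEGORIES:
            raise ValueError(f"unknown tissue scope {tissue_scope!r}")
        return (self.cells["tissue_category"] == tissue_scope).to_numpy()

    def records(self) -> list[CellRecord]:
        return [CellRecord(*row) for row in
                self.cells[["cell_id", "x", "y", "phenotype",
                            "tissue_category"]].itertuples(index=False)]

    def __repr__(self) -> str:  # pragma: no cover
        return (f"PointPattern(patient_id={self.patient_id!r}, "
                f"outcome={self.outcome!r}, n_cells={self.n_cells}, "
                f"roi_area={self.roi.area_mm2:.4g} mm²)")

    def equals(self, other: "PointPattern", tol_um: float = 1e-6) -> bool:
        """Field-by-field equality up to coordinate serialization tolerance."""
        if (self.patient_id != other.patient_id or self.outcome != other.outcome
                or self.n_cells != other.n_cells):
            return False
        a, b = self.cells, other.cells
        if (not (a["cell_id"].to_numpy() == b["cell_id"].to_numpy()).all()
                or not (a["phenotype"].to_numpy() == b["phenotype"].to_numpy()).all()
                or not (a["tissue_category"].to_numpy()
                        == b["tissue_category"].to_numpy()).all()):
            return False
        if not np.allclose(self.coords, other.coords, atol=tol_um, rtol=0):
            return False
        return math.isclose(self.roi.area_mm2, other.roi.area_mm2,
                            rel_tol=1e-9, abs_tol=1e-12)


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def is_empty(self) -> bool:
        return not self.violations and not self.warnings


def validate_pattern(pattern: PointPattern) -> ValidationReport:
    """Check the data-model invariants; returns a report, never raises.

    Duplicate coordinates are a warning only — two cells may legitimately
    share a centroid at digitization resolution.
    """
    report = ValidationReport()
    df = pattern.cells
    # Known alias labels are normalized in place with a warning; only truly
    # unmappable labels count as violations.
    for col, normalizer, valid in (
            ("phenotype", normalize_phenotype, PHENOTYPES),
            ("tissue_category", normalize_tissue_category, TISSUE_CATEGORIES)):
        raw = df[col]
        noncanon = ~raw.isin(valid)
        if noncanon.any():
            mapped = raw[noncanon].map(lambda s: normalizer(s))
            fixable = mapped.notna()
            if fixable.any():
                df.loc[mapped.index[fixable], col] = mapped[fixable]
                report.warnings.append(
                    f"normalized {int(fixable.sum())} alias {col} labels")
    xy = pattern.coords
    if not np.isfinite(xy).all():
        bad = np.where(~np.isfinite(xy).all(axis=1))[0]
        report.violations.append(f"non-finite coordinates at rows {bad.tolist()}")
    if df["cell_id"].duplicated().any():
        dupes = df.loc[df["cell_id"].duplicated(), "cell_id"].unique()
        report.violations.append(f"duplicate cell ids: {dupes[:5].tolist()}")
    bad_ph = ~df["phenotype"].isin(PHENOTYPES)
    if bad_ph.any():
        report.violations.append(
            f"unknown phenotypes at rows {df.index[bad_ph].tolist()[:10]}")
    bad_tc = ~df["tissue_category"].isin(TISSUE_CATEGORIES)
    if bad_tc.any():
        report.violations.append(
            f"unknown tissue categories at rows {df.index[bad_tc].tolist()[:10]}")
    dup_xy = df.duplicated(subset=["x", "y"])
    if dup_xy.any():
        report.warnings.append(
            f"{int(dup_xy.sum())} cells share coordinates with another cell")
    if pattern.roi.from_bounding_box:
        report.warnings.append(
            "ROI area defaulted to the bounding box of the cells")
    if pattern.roi.boundary is not None and len(df):
        inside = np.fromiter(
            (pattern.roi.contains(x, y) for x, y in xy), dtype=bool, count=len(xy))
        if not inside.all():
            report.violations.append(
                f"{int((~inside).sum())} cells fall outside the ROI boundary")
    return report


# -- tabular I/O ---------------------------------------------------------

def _metadata_lines(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def read_pattern_table(path: str | Path,
                       roi_area_mm2: float | None = None,
                       column_map: Mapping[str, str] | None = None,
                       phenotype_aliases: Mapping[str, str] | None = None,
                       tissue_aliases: Mapping[str, str] | None = None,
                       ) -> PointPattern:
    """Read a pattern from a delimited text table (CSV or TSV).

    Leading ``# key=value`` lines may carry ``patient_id``, ``outcome`` and
    ``roi_area_mm2``.  A WKT sidecar ``<stem>.roi.wkt`` next to the table, if
    present, supplies the ROI polygon.  ROI area precedence: explicit
    argument > polygon area > metadata line > cell bounding box (the last is
    flagged in the validation report).

    ``column_map`` renames caller columns onto the canonical header
    ``(cell_id, x_um, y_um, phenotype, tissue_category)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _metadata_lines(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError as exc:
        raise PatternFormatError(f"{path}: empty table") from exc
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns
               and not (c == "cell_id")]
    if missing:
        raise PatternFormatError(f"{path}: missing required columns {missing}")
    if "cell_id" not in df.columns:
        df.insert(0, "cell_id", [f"c{i}" for i in range(len(df))])
    if len(df) == 0:
        raise PatternFormatError(f"{path}: table has no data rows")

    bad_rows: list[tuple[int, str]] = []
    phenos = []
    for i, raw in enumerate(df["phenotype"]):
        canon = normalize_phenotype(raw, phenotype_aliases)
        if canon is None:
            bad_rows.append((i, f"phenotype {raw!r}"))
            canon = "other"
        phenos.append(canon)
    tissues = []
    for i, raw in enumerate(df["tissue_category"]):
        canon = normalize_tissue_category(raw, tissue_aliases)
        if canon is None:
            bad_rows.append((i, f"tissue_category {raw!r}"))
            canon = "stroma"
        tissues.append(canon)
    if bad_rows:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in bad_rows[:10])
        raise PatternValidationError(
            f"{path}: {len(bad_rows)} rows with unmappable labels ({detail})")

    cells = pd.DataFrame({
        "cell_id": df["cell_id"].astype(str),
        "x": df["x_um"].astype(float),
        "y": df["y_um"].astype(float),
        "phenotype": phenos,
        "tissue_category": tissues,
    })

    boundary = None
    wkt_path = path.parent / (path.stem + ".roi.wkt")
    if wkt_path.exists():
        boundary = shapely_wkt.loads(wkt_path.read_text().strip())

    from_bbox = False
    if roi_area_mm2 is not None:
        area = float(roi_area_mm2)
    elif boundary is not None:
        area = boundary.area / 1e6
    elif "roi_area_mm2" in meta:
        area = float(meta["roi_area_mm2"])
    else:
        xy = cells[["x", "y"]].to_numpy(dtype=float)
        span = xy.max(axis=0) - xy.min(axis=0)
        area = max(float(span[0] * span[1]) / 1e6, 1e-12)
        from_bbox = True
        warnings.warn(
            f"{path}: no ROI area given; defaulting to cell bounding box "
            f"({area:.4g} mm²)", stacklevel=2)

    roi = RegionOfInterest(area_mm2=area, boundary=boundary,
                           from_bounding_box=from_bbox)
    pattern = PointPattern(
        cells, roi,
        patient_id=meta.get("patient_id", path.stem),
        outcome=meta.get("outcome", "unlabeled"))
    report = validate_pattern(pattern)
    if not report.ok:
        raise PatternValidationError(f"{path}: {report.violations}")
    return pattern


def write_pattern_table(pattern: PointPattern, path: str | Path) -> Path:
    """Write a pattern to CSV/TSV readable by :func:`read_pattern_table`.

    Numeric fields use repr-precision serialization (well beyond 6
    significant digits).  A polygon ROI, when present, is written to a
    ``<stem>.roi.wkt`` sidecar.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pattern.cells.rename(columns={"x": "x_um", "y": "y_um"})
    header = (f"# patient_id={pattern.patient_id}\n"
              f"# outcome={pattern.outcome}\n"
              f"# roi_area_mm2={pattern.roi.area_mm2!r}\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep=sep, index=False, float_format="%.10g")
    if pattern.roi.boundary is not None:
        wkt_path = path.parent / (path.stem + ".roi.wkt")
        wkt_path.write_text(pattern.roi.boundary.wkt + "\n")
    return path
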