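"""Image and cohort-table I/O plus physically calibrated annular regions.

En face OCT-angiography exports are square single-channel rasters whose pixel
values are SSADA decorrelation amplitudes.  This module turns those rasters
into :class:`EnFaceAngiogram` objects normalised to [0, 1], builds the annular
regions of interest every vascular metric is computed over (the parafovea,
1.0–3.0 mm around the fovea, and the peripapillary "donut", 2.0–4.0 mm around
the optic nerve head, optionally split into four 90° quadrants), and reads and
writes the per-participant cohort table used by the case-control statistics.

Conventions
-----------
* 0-based (row, col) pixel indices; distances are measured between pixel
  centres in millimetres (``mm_per_px = field_width_mm / width``).
* Annulus membership is half-open, ``inner_radius <= d < outer_radius``, so
  concentric rings partition exactly.
* Quadrant boundaries are the two 45° diagonals through the centre; the
  superior quadrant contains the "up" image direction.  Temporal/nasal labels
  depend on eye laterality: for a right eye (OD) disc scan, image-left is
  temporal.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

SCAN_TYPES = ("macula", "disc")
LAYERS = ("SCP", "DCP", "whole_retina", "RPC", "SVC")
QUADRANTS = ("all", "superior", "inferior", "temporal", "nasal")
GROUPS = ("aMCI", "eAD", "control")
EYES = ("OD", "OS")

#: groups pooled into the cognitively impaired arm of every comparison
IMPAIRED_GROUPS = ("aMCI", "eAD")


@dataclass(frozen=True)
class ScaleInfo:
    """Physical pixel calibration derived from the scan geometry."""

    um_per_px: float
    px_area_um2: float

    @classmethod
    def from_geometry(cls, field_width_mm: float, width_px: int) -> "ScaleInfo":
        um = 1000.0 * field_width_mm / width_px
        return cls(um_per_px=um, px_area_um2=um * um)


@dataclass
class EnFaceAngiogram:
    """A 2-D en face decorrelation image with physical scan geometry.

    Parameters
    ----------
    pixels
        Square 2-D float array with values in [0, 1].
    field_width_mm
        Physical side length of the scan (3.0 for macular, 4.5 for disc scans).
    center_px
        (row, col) of the fovea or disc centre; defaults to the geometric
        image centre.
    scan_type
        ``"macula"`` or ``"disc"``.
    layer
        Device-segmented vascular layer the projection comes from.
    quality
        (SQ, SSI) device image-quality scores, if known.
    """

    pixels: np.ndarray
    field_width_mm: float
    scan_type: str
    layer: str | None = None
    center_px: tuple[int, int] | None = None
    quality: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"angiogram must be 2-D, got shape {self.pixels.shape}")
        h, w = self.pixels.shape
        if h != w:
            raise ValueError(f"angiogram must be square, got {h}x{w}")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 1):
            raise ValueError("pixel values must lie in [0, 1]")
        if self.field_width_mm <= 0:
            raise ValueError("field_width_mm must be positive")
        if self.scan_type not in SCAN_TYPES:
            raise ValueError(f"scan_type must be one of {SCAN_TYPES}")
        if self.layer is not None and self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}")
        if self.center_px is None:
            self.center_px = (h // 2, w // 2)
        r, c = self.center_px
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"center_px {self.center_px} outside {h}x{w} image")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def mm_per_px(self) -> float:
        return self.field_width_mm / self.pixels.shape[1]

    @property
    def scale(self) -> ScaleInfo:
        return ScaleInfo.from_geometry(self.field_width_mm, self.pixels.shape[1])

    def replace(self, **changes) -> "EnFaceAngiogram":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)


@dataclass
class AnnularROI:
    """Donut-shaped region of interest, optionally a single 90° quadrant."""

    center_px: tuple[int, int]
    inner_diameter_mm: float
    outer_diameter_mm: float
    quadrant: str
    pixel_mask: np.ndarray

    @property
    def area_px(self) -> int:
        return int(self.pixel_mask.sum())

    def area_mm2(self, scale: ScaleInfo) -> float:
        return self.area_px * scale.px_area_um2 / 1e6


def read_angiogram(
    path: str | Path,
    field_width_mm: float,
    scan_type: str,
    center_px: tuple[int, int] | None = None,
    layer: str | None = None,
    quality: tuple[int, int] | None = None,
) -> EnFaceAngiogram:
    """Read a single-channel 8/16-bit grayscale TIFF or PNG as an angiogram.

    Integer intensities are mapped linearly to [0, 1] by dividing by the dtype
    maximum (255 or 65535); float rasters must already be in [0, 1].
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # pragma: no cover - message formatting only
        raise IOError(f"could not read image file {path}: {exc}") from exc
    if raw.ndim != 2:
        raise ValueError(f"{path}: expected single-channel image, got shape {raw.shape}")
    if raw.shape[0] != raw.shape[1]:
        raise ValueError(f"{path}: expected square image, got {raw.shape}")
    if np.issubdtype(raw.dtype, np.integer):
        pixels = raw.astype(float) / np.iinfo(raw.dtype).max
    elif np.issubdtype(raw.dtype, np.floating):
        pixels = raw.astype(float)
        if pixels.min() < 0 or pixels.max() > 1:
            raise ValueError(f"{path}: float image must be normalised to [0, 1]")
    else:
        raise ValueError(f"{path}: unsupported dtype {raw.dtype}")
    return EnFaceAngiogram(
        pixels=pixels,
        field_width_mm=field_width_mm,
        scan_type=scan_type,
        layer=layer,
        center_px=center_px,
        quality=quality,
    )


def write_angiogram(image: EnFaceAngiogram, path: str | Path, bit_depth: int = 16) -> None:
    """Write an angiogram as an 8- or 16-bit grayscale raster (TIFF/PNG)."""
    if bit_depth == 16:
        arr = np.round(image.pixels * 65535).astype(np.uint16)
    elif bit_depth == 8:
        arr = np.round(image.pixels * 255).astype(np.uint8)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    iio.imwrite(Path(path), arr)


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Export a boolean mask as a 0/255 8-bit PNG."""
    iio.imwrite(Path(path), (np.asarray(mask, bool).astype(np.uint8) * 255))


def _quadrant_labels(eye: str) -> dict[str, int]:
    """Map quadrant names to sector indices (0=right, 1=up, 2=left, 3=down).

    Image "up" is the superior retina.  For OD the temporal retina is
    image-left; for OS it is image-right.
    """
    if eye not in EYES:
        raise ValueError(f"eye must be one of {EYES}")
    left, right = ("temporal", "nasal") if eye == "OD" else ("nasal", "temporal")
    return {right: 0, "superior": 1, left: 2, "inferior": 3}


def make_annulus(
    image: EnFaceAngiogram,
    inner_diameter_mm: float,
    outer_diameter_mm: float,
    quadrant: str = "all",
    eye: str = "OD",
) -> AnnularROI:
    """Build the boolean mask of an annulus (optionally one quadrant) on *image*.

    Membership is half-open in radius, ``inner <= d < outer`` (distances
    between pixel centres), and quadrants are half-open 90° sectors bounded by
    the 45° diagonals, so the four quadrant masks partition the full annulus
    exactly.  An outer ring larger than the field is clipped at the image edge.
    """
    if quadrant not in QUADRANTS:
        raise ValueError(f"quadrant must be one of {QUADRANTS}")
    if not (0 <= inner_diameter_mm <= outer_diameter_mm):
        raise ValueError(
            f"need 0 <= inner < outer, got {inner_diameter_mm} / {outer_diameter_mm}"
        )
    if inner_diameter_mm == outer_diameter_mm and inner_diameter_mm > 0:
        # zero-width annulus: empty by the half-open rule
        pass
    h, w = image.shape
    cr, cc = image.center_px
    rows = np.arange(h)[:, None] - cr
    cols = np.arange(w)[None, :] - cc
    d_mm = np.hypot(rows, cols) * image.mm_per_px
    mask = (d_mm >= inner_diameter_mm / 2.0) & (d_mm < outer_diameter_mm / 2.0)
    if quadrant != "all":
        sector = _quadrant_labels(eye)[quadrant]
        # angle measured from image-right axis, "up" (decreasing row) positive
        theta = np.degrees(np.arctan2(-rows, cols + 0.0))
        idx = np.floor((theta + 45.0) / 90.0).astype(int) % 4
        mask &= idx == sector
    return AnnularROI(
        center_px=(cr, cc),
        inner_diameter_mm=inner_diameter_mm,
        outer_diameter_mm=outer_diameter_mm,
        quadrant=quadrant,
        pixel_mask=mask,
    )


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

#: canonical column names of the long-format cohort table (one row per
#: participant-eye); metric columns are optional and any subset may be present.
REQUIRED_COLUMNS = [
    "id",
    "group",
    "age",
    "gender",
    "race",
    "eye",
    "sq_macula",
    "ssi_macula",
    "sq_disc",
    "ssi_disc",
    "moca",
    "cdr",
    "craft_imm",
    "craft_del",
    "ravlt_del",
    "iop_mmhg",
    "education_years",
    "interval_years",
]

METRIC_COLUMNS = [
    "scp_vd",
    "scp_vld",
    "scp_afi",
    "rpc_vd_global",
    "rpc_vd_superior",
    "rpc_vd_capillary",
    "rpc_vld",
    "svc_vd",
    "svc_vld",
    "wr_vd",
    "dcp_vd",
    "faz_area_mm2",
    "rnfl_um",
]

_FLOAT_FIELDS = [
    "age",
    "moca",
    "cdr",
    "craft_imm",
    "craft_del",
    "ravlt_del",
    "iop_mmhg",
    "education_years",
    "interval_years",
]


@dataclass
class ParticipantRecord:
    """One participant-eye row of the cohort table.

    Cognitive scores and vascular metrics may be missing (NaN); missing cells
    are preserved as NaN, never zero-filled.  ``impaired`` pools the aMCI and
    eAD diagnoses into the case arm.
    """

    id: str
    group: str
    age: float
    gender: str
    race: str
    eye: str
    sq_macula: float = np.nan
    ssi_macula: float = np.nan
    sq_disc: float = np.nan
    ssi_disc: float = np.nan
    moca: float = np.nan
    cdr: float = np.nan
    craft_imm: float = np.nan
    craft_del: float = np.nan
    ravlt_del: float = np.nan
    iop_mmhg: float = np.nan
    education_years: float = np.nan
    interval_years: float = np.nan
    pathology: bool = False
    metrics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.eye not in EYES:
            raise ValueError(f"eye must be one of {EYES}, got {self.eye!r}")

    @property
    def impaired(self) -> bool:
        return self.group in IMPAIRED_GROUPS


def _read_table(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path, sheet_name=0)
    return pd.read_csv(path, float_precision="round_trip")


def read_cohort_table(
    path: str | Path,
    column_map: Mapping[str, str] | str | Path | None = None,
) -> list[ParticipantRecord]:
    """Read a cohort table (CSV or first sheet of an XLSX) into typed records.

    Parameters
    ----------
    column_map
        Optional mapping from the file's column names to the canonical names in
        :data:`REQUIRED_COLUMNS` / :data:`METRIC_COLUMNS`, or a path to a JSON
        file holding one.  Useful for externally deposited tables whose
        headers differ from the canonical schema.
    """
    path = Path(path)
    df = _read_table(path)
    if column_map is not None:
        if isinstance(column_map, (str, Path)):
            column_map = json.loads(Path(column_map).read_text())
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    dup = df.duplicated(subset=["id", "eye"])
    if dup.any():
        bad = df.loc[dup, ["id", "eye"]].itertuples(index=False)
        raise ValueError(
            f"{path}: duplicate (id, eye) rows: "
            + ", ".join(f"({r.id}, {r.eye})" for r in bad)
        )
    records: list[ParticipantRecord] = []
    metric_cols = [c for c in METRIC_COLUMNS if c in df.columns]
    for _, row in df.iterrows():
        kwargs = {
            "id": str(row["id"]),
            "group": str(row["group"]),
            "gender": str(row["gender"]),
            "race": str(row["race"]),
            "eye": str(row["eye"]),
            "pathology": bool(row.get("pathology", False))
            and not pd.isna(row.get("pathology", False)),
        }
        for col in _FLOAT_FIELDS + ["sq_macula", "ssi_macula", "sq_disc", "ssi_disc"]:
            val = row.get(col, np.nan)
            kwargs[col] = float(val) if not pd.isna(val) else np.nan
        metrics = {}
        for col in metric_cols:
            val = row[col]
            metrics[col] = float(val) if not pd.isna(val) else np.nan
        records.append(ParticipantRecord(metrics=metrics, **kwargs))
    return records


def cohort_to_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Flatten records back into the canonical long-format table."""
    rows = []
    for rec in records:
        row = {c: getattr(rec, c) for c in REQUIRED_COLUMNS}
        row["pathology"] = rec.pathology
        row.update(rec.metrics)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_table(records: Sequence[ParticipantRecord], path: str | Path) -> None:
    """Write records as CSV (UTF-8) or XLSX depending on the file suffix."""
    path = Path(path)
    df = cohort_to_frame(records)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df.to_excel(path, index=False)
    else:
        # repr is shortest-round-trip: reading the CSV back restores the exact
        # doubles, so write -> read is the identity on records
        df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
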