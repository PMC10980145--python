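"""Readers and writers for every artifact the pipeline touches.

Calibrated single-channel TIFF micrographs, plain-text polygon ROI files,
per-object morphometry tables and regional summary tables (CSV).  All
coordinates are 0-based (row, col) with pixel centers at integer
coordinates; a pixel belongs to a polygon iff its center lies inside or on
the boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon

__all__ = [
    "Micrograph",
    "RegionOfInterest",
    "read_micrograph",
    "write_micrograph",
    "read_roi",
    "write_roi",
    "write_morphometry_table",
    "read_morphometry_table",
    "write_summary_table",
    "read_summary_table",
    "MORPHOMETRY_COLUMNS",
    "SUMMARY_COLUMNS",
]

_UM_PER_INCH = 25400.0
_UM_PER_CM = 10000.0


@dataclass(eq=False)
class Micrograph:
    """A calibrated 2-D fluorescence intensity image.

    Parameters
    ----------
    intensities : ndarray, shape (rows, cols)
        Non-negative, finite pixel intensities.  Stored as float64; integer
        input is converted without rescaling.
    pixel_size_um : float
        Physical side length of one pixel in micrometres (> 0).
    source_id : str
        Free-form slide/animal/region label used in reports.
    """

    intensities: np.ndarray
    pixel_size_um: float
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("intensities must be a non-empty 2-D array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if arr.min() < 0:
            raise ValueError("intensities must be non-negative")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be > 0")
        self.intensities = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass(eq=False)
class RegionOfInterest:
    """A simple polygon in pixel coordinates restricting analysis.

    Vertices are ordered (row, col) pairs; the polygon must be simple
    (non-self-intersecting) and enclose positive area.  The polygon's
    geometric (shoelace) area is the density denominator, so the vertex
    coordinates — not any rasterization — define it.
    """

    vertices: np.ndarray
    name: str = "roi"
    _polygon: Polygon = field(init=False, repr=False)

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=np.float64)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise ValueError(
                f"ROI {self.name!r}: need >= 3 (row, col) vertices, got shape {verts.shape}"
            )
        if not np.all(np.isfinite(verts)):
            raise ValueError(f"ROI {self.name!r}: vertices must be finite")
        poly = Polygon(verts)
        # A bow-tie given as an explicit ring is invalid in shapely terms.
        if not poly.is_valid or not poly.is_simple:
            raise ValueError(f"ROI {self.name!r} is self-intersecting or degenerate")
        if poly.area <= 0:
            raise ValueError(f"ROI {self.name!r} encloses no area")
        self.vertices = verts
        self._polygon = poly

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    @property
    def area_px2(self) -> float:
        """Enclosed area in squared pixels (shoelace on the vertices)."""
        return self._polygon.area

    def area_mm2(self, pixel_size_um: float) -> float:
        return self.area_px2 * pixel_size_um**2 * 1e-6

    def contains_points(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Boundary-inclusive membership test for pixel centers."""
        pts = shapely.points(np.column_stack([np.asarray(rows, float), np.asarray(cols, float)]))
        return shapely.covers(self._polygon, pts)


# ---------------------------------------------------------------------------
# TIFF micrographs
# ---------------------------------------------------------------------------

def write_micrograph(micrograph: Micrograph, path: str | Path) -> None:
    """Write a single-channel grayscale TIFF with pixel-size calibration.

    The pixel size is stored twice: exactly, as JSON in the ImageDescription
    tag, and as standard resolution tags (pixels per centimetre) for other
    readers.  Pixel data round-trips bit-identically through
    :func:`read_micrograph`.
    """
    px = micrograph.pixel_size_um
    desc = json.dumps({"pixel_size_um": px, "source_id": micrograph.source_id})
    tifffile.imwrite(
        str(path),
        micrograph.intensities,
        photometric="minisblack",
        resolution=(_UM_PER_CM / px, _UM_PER_CM / px),
        resolutionunit="CENTIMETER",
        description=desc,
    )


def _pixel_size_from_tags(page: "tifffile.TiffPage") -> float | None:
    tags = page.tags
    if "XResolution" not in tags or "ResolutionUnit" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0 or den == 0:
        return None
    unit = int(tags["ResolutionUnit"].value)
    per_unit = {2: _UM_PER_INCH, 3: _UM_PER_CM}.get(unit)
    if per_unit is None:  # RESUNIT.NONE
        return None
    return per_unit * den / num


def read_micrograph(
    path: str | Path,
    pixel_size_um_override: float | None = None,
    source_id: str | None = None,
) -> Micrograph:
    """Read a single-channel grayscale TIFF as a :class:`Micrograph`.

    Pixel size is taken from the file (exact JSON description written by
    :func:`write_micrograph`, else standard resolution tags); the override
    is used only when the file carries none.  Integer intensities are
    converted to float without rescaling.

    Raises
    ------
    ValueError
        If the image is multi-channel/RGB (extract one channel first), or
        if no pixel size is available from either the file or the override.
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        if arr.ndim != 2:
            raise ValueError(
                f"{path.name}: expected a single-channel grayscale image, got shape "
                f"{arr.shape}; extract one channel before analysis"
            )
        pixel_size = None
        desc = page.tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
                pixel_size = float(meta["pixel_size_um"])
                if source_id is None:
                    source_id = meta.get("source_id") or None
            except (ValueError, TypeError, KeyError):
                pixel_size = None
        if pixel_size is None:
            pixel_size = _pixel_size_from_tags(page)
    if pixel_size is None:
        pixel_size = pixel_size_um_override
    if pixel_size is None:
        raise ValueError(
            f"{path.name}: no pixel size in TIFF metadata and no override supplied"
        )
    return Micrograph(arr, float(pixel_size), source_id if source_id is not None else path.stem)


# ---------------------------------------------------------------------------
# ROI polygon text files
# ---------------------------------------------------------------------------
#
# Format: one polygon per record; records separated by blank lines.  The
# first non-comment line of a record is the polygon name, each following
# line one "row,col" vertex.  Lines starting with '#' are comments.

def write_roi(rois: RegionOfInterest | list[RegionOfInterest], path: str | Path) -> None:
    if isinstance(rois, RegionOfInterest):
        rois = [rois]
    blocks = []
    for roi in rois:
        lines = [roi.name] + [f"{float(r)!r},{float(c)!r}" for r, c in roi.vertices]
        blocks.append("\n".join(lines))
    Path(path).write_text("\n\n".join(blocks) + "\n")


def read_roi(path: str | Path) -> list[RegionOfInterest]:
    """Read the plain-text polygon format; validates every polygon."""
    text = Path(path).read_text()
    rois: list[RegionOfInterest] = []
    for block in text.split("\n\n"):
        lines = [ln.strip() for ln in block.splitlines()]
        lines = [ln for ln in lines if ln and not ln.startswith("#")]
        if not lines:
            continue
        name, vertex_lines = lines[0], lines[1:]
        verts = []
        for ln in vertex_lines:
            r, c = ln.split(",")
            verts.append((float(r), float(c)))
        if len(verts) < 3:
            raise ValueError(f"ROI {name!r} in {path}: fewer than 3 vertices")
        rois.append(RegionOfInterest(np.array(verts), name=name))
    return rois


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

MORPHOMETRY_COLUMNS = [
    "object_id",
    "source_id",
    "area_um2",
    "equivalent_diameter_um",
    "eccentricity",
    "centroid_row",
    "centroid_col",
    "object_class",
]

SUMMARY_COLUMNS = [
    "region",
    "n_animals",
    "n_slides",
    "count_mean",
    "count_sd",
    "density_mean",
    "density_sd",
    "area_mean",
    "area_sd",
    "diam_oligomer_um",
    "diam_plaque_um",
    "ecc_mean",
    "ecc_sd",
    "area_slide_mean",
    "ecc_slide_mean",
]


def write_morphometry_table(objects: list, path: str | Path, source_id: str = "") -> None:
    """Write per-object morphometry rows as CSV in a fixed column order.

    ``objects`` may be ObjectMorphometry instances or (source_id, object)
    pairs; an empty list yields a header-only CSV.
    """
    rows = []
    for item in objects:
        sid, m = item if isinstance(item, tuple) else (source_id, item)
        rows.append(
            {
                "object_id": m.object_id,
                "source_id": sid,
                "area_um2": m.area_um2,
                "equivalent_diameter_um": m.equivalent_diameter_um,
                "eccentricity": m.eccentricity,
                "centroid_row": m.centroid[0],
                "centroid_col": m.centroid[1],
                "object_class": m.object_class,
            }
        )
    df = pd.DataFrame(rows, columns=MORPHOMETRY_COLUMNS)
    df.to_csv(path, index=False)


def read_morphometry_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_summary_table(rows: list, path: str | Path) -> None:
    """Write RegionSummary rows as CSV; missing SDs (n=1) stay empty."""
    records = []
    for s in rows:
        records.append(
            {
                "region": s.region,
                "n_animals": s.n_animals,
                "n_slides": s.n_slides,
                "count_mean": s.count_mean,
                "count_sd": s.count_sd,
                "density_mean": s.density_mean,
                "density_sd": s.density_sd,
                "area_mean": s.area_mean,
                "area_sd": s.area_sd,
                "diam_oligomer_um": s.diameter_mean_by_class.get("oligomer"),
                "diam_plaque_um": s.diameter_mean_by_class.get("plaque"),
                "ecc_mean": s.eccentricity_mean,
                "ecc_sd": s.eccentricity_sd,
                "area_slide_mean": s.area_slide_mean,
                "ecc_slide_mean": s.eccentricity_slide_mean,
            }
        )
    df = pd.DataFrame(records, columns=SUMMARY_COLUMNS)
    df.to_csv(path, index=False)


def read_summary_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
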