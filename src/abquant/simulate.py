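"""Synthetic calibrated micrographs with planted elliptical amyloid-like objects.

The generator emulates the statistical structure the analysis assumes in a
FAM-channel brain-section image: a noisy tissue background bounded by a
rectangular tissue region on dark glass, and two bright elliptical object
populations — small oligomer-like objects (~2 um equivalent diameter) and
large plaque-like objects (~14 um) — with eccentricities centered near
0.5.  Every planted object is exported as ground truth, so each analysis
stage can be verified against known answers.

Diameters here are equivalent-area diameters: an object with diameter d
and eccentricity e gets semi-axes a = (d/2)/(1-e^2)^(1/4) and
b = (d/2)*(1-e^2)^(1/4), so pi*a*b = pi*(d/2)^2 exactly and the configured
diameter is what a perfect measurement recovers.

Population draws are truncated normals, cut at mean +/- 3 SD and floored
at 0.5 um, which bounds each class's diameter support: any classification
cutoff strictly between the two supports separates the classes exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import Micrograph, RegionOfInterest
from .segment import LabeledObjects

__all__ = [
    "SimulationConfig",
    "GroundTruthObject",
    "generate_micrograph",
    "analysis_roi",
    "rasterize_truth",
    "truth_to_frame",
]

_DIAMETER_FLOOR_UM = 0.5


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic micrograph.

    image_shape : (rows, cols) in pixels.
    pixel_size_um : physical pixel size, um/pixel.
    n_oligomers, n_plaques : planted object counts per class.
    oligomer_diameter_um, plaque_diameter_um : (mean, SD) of the
        equivalent-diameter populations, um.
    eccentricity_mean, eccentricity_sd : ellipse eccentricity population.
    background_level : tissue autofluorescence level (arbitrary intensity
        units); the glass outside the tissue is level 0.
    background_noise_sd : SD of additive Gaussian noise, clipped at 0.
    object_peak_intensity : flat-top object intensity; must exceed the
        background level.
    tissue_fraction : fraction of the frame covered by the (rectangular)
        tissue region, in (0, 1].
    roi_margin_px : inset of the returned analysis ROI from the tissue
        boundary.  The tissue-edge intensity step depresses a local-mean
        threshold up to half a window inside the tissue, so keep this
        margin larger than half the analysis window.
    min_gap_px : minimum clearance between planted objects (conservative
        bounding-circle test), so segmentation cannot merge neighbors.
    seed : RNG seed; identical seeds give bit-identical output.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.25
    n_oligomers: int = 50
    n_plaques: int = 10
    oligomer_diameter_um: tuple[float, float] = (2.0, 0.3)
    plaque_diameter_um: tuple[float, float] = (14.0, 2.0)
    eccentricity_mean: float = 0.5
    eccentricity_sd: float = 0.1
    background_level: float = 20.0
    background_noise_sd: float = 3.0
    object_peak_intensity: float = 120.0
    tissue_fraction: float = 0.9
    roi_margin_px: float = 80.0
    min_gap_px: float = 5.0
    max_placement_attempts: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if rows < 8 or cols < 8:
            raise ValueError("image_shape too small")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be > 0")
        if self.n_oligomers < 0 or self.n_plaques < 0:
            raise ValueError("object counts must be non-negative")
        for name in ("oligomer_diameter_um", "plaque_diameter_um"):
            mean, sd = getattr(self, name)
            if not (mean > 0) or sd < 0:
                raise ValueError(f"{name}: mean must be > 0 and SD >= 0")
        if not (0.0 <= self.eccentricity_mean < 1.0):
            raise ValueError("eccentricity_mean must lie in [0, 1)")
        if self.eccentricity_sd < 0:
            raise ValueError("eccentricity_sd must be >= 0")
        if not (self.object_peak_intensity > self.background_level):
            raise ValueError("objects must be brighter than the background")
        if self.background_level < 0 or self.background_noise_sd < 0:
            raise ValueError("background level and noise SD must be >= 0")
        if not (0.0 < self.tissue_fraction <= 1.0):
            raise ValueError("tissue_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class GroundTruthObject:
    """One planted ellipse, in both pixel and physical coordinates."""

    object_id: int
    center: tuple[float, float]  # (row, col), pixels
    semi_major_um: float
    semi_minor_um: float
    orientation_rad: float
    true_class: str

    def __post_init__(self) -> None:
        if not (self.semi_major_um >= self.semi_minor_um > 0):
            raise ValueError("need semi_major_um >= semi_minor_um > 0")

    @property
    def true_area_um2(self) -> float:
        return math.pi * self.semi_major_um * self.semi_minor_um

    @property
    def true_eccentricity(self) -> float:
        return math.sqrt(1.0 - (self.semi_minor_um / self.semi_major_um) ** 2)

    @property
    def true_equivalent_diameter_um(self) -> float:
        return 2.0 * math.sqrt(self.semi_major_um * self.semi_minor_um)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int, floor: float
) -> np.ndarray:
    """Normal(mean, sd) truncated to [max(floor, mean-3sd), mean+3sd]."""
    lo, hi = max(floor, mean - 3.0 * sd), mean + 3.0 * sd
    if sd == 0:
        return np.full(n, mean)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled) + 8)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _tissue_rectangle(config: SimulationConfig) -> tuple[float, float, float, float]:
    """(min_row, min_col, max_row, max_col) of the tissue region."""
    rows, cols = config.image_shape
    shrink = math.sqrt(config.tissue_fraction)
    mr = 0.5 * rows * (1.0 - shrink)
    mc = 0.5 * cols * (1.0 - shrink)
    return mr, mc, rows - 1 - mr, cols - 1 - mc


def analysis_roi(config: SimulationConfig) -> RegionOfInterest:
    """The rectangular analysis ROI a simulated micrograph will carry.

    Inset ``roi_margin_px`` from the tissue boundary; depends only on the
    configuration, so planted densities can be chosen from its area before
    any image is rendered.
    """
    mr, mc, Mr, Mc = _tissue_rectangle(config)
    g = config.roi_margin_px
    lo_r, lo_c, hi_r, hi_c = mr + g, mc + g, Mr - g, Mc - g
    if lo_r >= hi_r or lo_c >= hi_c:
        raise ValueError("roi_margin_px leaves no analysis region")
    return RegionOfInterest(
        np.array([(lo_r, lo_c), (lo_r, hi_c), (hi_r, hi_c), (hi_r, lo_c)]),
        name="tissue",
    )


def _ellipse_pixels(
    obj: GroundTruthObject, image_shape: tuple[int, int], pixel_size_um: float
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of pixels whose centers lie inside the ellipse."""
    a = obj.semi_major_um / pixel_size_um
    b = obj.semi_minor_um / pixel_size_um
    r0, c0 = obj.center
    theta = obj.orientation_rad
    rmin = max(0, int(math.floor(r0 - a)))
    rmax = min(image_shape[0] - 1, int(math.ceil(r0 + a)))
    cmin = max(0, int(math.floor(c0 - a)))
    cmax = min(image_shape[1] - 1, int(math.ceil(c0 + a)))
    if rmin > rmax or cmin > cmax:
        return np.empty(0, int), np.empty(0, int)
    rr, cc = np.meshgrid(
        np.arange(rmin, rmax + 1), np.arange(cmin, cmax + 1), indexing="ij"
    )
    dr, dc = rr - r0, cc - c0
    u = dr * math.cos(theta) + dc * math.sin(theta)
    v = -dr * math.sin(theta) + dc * math.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return rr[inside], cc[inside]


def generate_micrograph(
    config: SimulationConfig,
) -> tuple[Micrograph, list[GroundTruthObject], RegionOfInterest]:
    """Render one synthetic micrograph with its ground truth and analysis ROI.

    Objects are rejection-sampled so that each ellipse lies entirely inside
    the ROI and bounding circles keep ``min_gap_px`` clearance; placement
    failure after ``max_placement_attempts`` per object raises, naming the
    crowding problem.  Each object is a flat top at
    ``object_peak_intensity`` over background + Gaussian noise (clipped at
    0); a pixel belongs to an object iff its center lies inside the
    ellipse, the same rule :func:`rasterize_truth` uses.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.image_shape
    px = config.pixel_size_um

    # plaques must span at least 2 px at this resolution
    plaque_lo = max(
        _DIAMETER_FLOOR_UM,
        config.plaque_diameter_um[0] - 3.0 * config.plaque_diameter_um[1],
    )
    if config.n_plaques > 0 and plaque_lo < 2.0 * px:
        raise ValueError(
            f"plaque diameter can fall below 2 pixels ({plaque_lo:.2f} um at "
            f"{px} um/pixel): objects would be unresolvable"
        )

    mr, mc, Mr, Mc = _tissue_rectangle(config)
    roi = analysis_roi(config)
    v = roi.vertices
    roi_bounds = (v[:, 0].min(), v[:, 1].min(), v[:, 0].max(), v[:, 1].max())

    # sample both populations (plaques first: large objects place harder)
    classes = ["plaque"] * config.n_plaques + ["oligomer"] * config.n_oligomers
    diam_p = _truncated_normal(
        rng, *config.plaque_diameter_um, config.n_plaques, _DIAMETER_FLOOR_UM
    )
    diam_o = _truncated_normal(
        rng, *config.oligomer_diameter_um, config.n_oligomers, _DIAMETER_FLOOR_UM
    )
    diameters = np.concatenate([diam_p, diam_o])
    n_total = diameters.size
    eccs = np.clip(
        _truncated_normal(rng, config.eccentricity_mean, config.eccentricity_sd, n_total, 0.0),
        0.0,
        0.95,
    )
    thetas = rng.uniform(0.0, math.pi, size=n_total)

    objects: list[GroundTruthObject] = []
    placed: list[tuple[float, float, float]] = []  # (row, col, bounding radius px)
    for i in range(n_total):
        d, e, th = diameters[i], eccs[i], thetas[i]
        a_um = 0.5 * d / (1.0 - e**2) ** 0.25
        b_um = 0.5 * d * (1.0 - e**2) ** 0.25
        a_px = a_um / px
        lo_r, lo_c = roi_bounds[0] + a_px, roi_bounds[1] + a_px
        hi_r, hi_c = roi_bounds[2] - a_px, roi_bounds[3] - a_px
        if lo_r >= hi_r or lo_c >= hi_c:
            raise RuntimeError(
                f"object of semi-major {a_px:.1f} px cannot fit inside the ROI; "
                "enlarge the frame or shrink the objects"
            )
        for _ in range(config.max_placement_attempts):
            r = rng.uniform(lo_r, hi_r)
            c = rng.uniform(lo_c, hi_c)
            ok = all(
                math.hypot(r - pr, c - pc) >= a_px + prad + config.min_gap_px
                for pr, pc, prad in placed
            )
            if ok:
                break
        else:
            raise RuntimeError(
                f"could not place object {i + 1}/{n_total} after "
                f"{config.max_placement_attempts} attempts: the frame is too "
                "crowded for non-overlapping placement at these counts and sizes"
            )
        placed.append((r, c, a_px))
        objects.append(
            GroundTruthObject(
                object_id=len(objects) + 1,
                center=(r, c),
                semi_major_um=a_um,
                semi_minor_um=b_um,
                orientation_rad=float(th),
                true_class=classes[i],
            )
        )

    # render: glass at 0, tissue at background_level, additive noise, objects on top
    level = np.zeros((rows, cols), dtype=np.float64)
    rr = np.arange(rows)[:, None]
    cc = np.arange(cols)[None, :]
    tissue = (rr >= mr) & (rr <= Mr) & (cc >= mc) & (cc <= Mc)
    level[tissue] = config.background_level
    img = level + rng.normal(0.0, config.background_noise_sd, size=(rows, cols))
    np.clip(img, 0.0, None, out=img)
    for obj in objects:
        pr, pc = _ellipse_pixels(obj, (rows, cols), px)
        img[pr, pc] = config.object_peak_intensity

    micrograph = Micrograph(img, px, source_id=f"sim-seed{config.seed}")
    return micrograph, objects, roi


def rasterize_truth(
    objects: list[GroundTruthObject],
    image_shape: tuple[int, int],
    pixel_size_um: float,
) -> LabeledObjects:
    """Label image carrying each object's id at pixels whose centers it covers.

    Raises if two objects claim the same pixel (overlap) or an object
    covers no pixel center at this resolution.
    """
    lab = np.zeros(image_shape, dtype=np.int32)
    for obj in objects:
        pr, pc = _ellipse_pixels(obj, image_shape, pixel_size_um)
        if pr.size == 0:
            raise ValueError(
                f"object {obj.object_id} covers no pixel center at "
                f"{pixel_size_um} um/pixel"
            )
        taken = lab[pr, pc]
        if np.any(taken):
            other = int(taken[taken > 0][0])
            raise ValueError(
                f"objects {other} and {obj.object_id} overlap in the raster"
            )
        lab[pr, pc] = obj.object_id
    n = len(objects)
    ids = sorted(o.object_id for o in objects)
    if ids != list(range(1, n + 1)):
        raise ValueError("object_ids must be 1..n for a label image")
    return LabeledObjects(lab, n)


def truth_to_frame(objects: list[GroundTruthObject]):
    """Ground-truth table as a DataFrame (one row per planted object)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "object_id": o.object_id,
                "center_row": o.center[0],
                "center_col": o.center[1],
                "semi_major_um": o.semi_major_um,
                "semi_minor_um": o.semi_minor_um,
                "orientation_rad": o.orientation_rad,
                "true_class": o.true_class,
                "true_area_um2": o.true_area_um2,
                "true_eccentricity": o.true_eccentricity,
                "true_equivalent_diameter_um": o.true_equivalent_diameter_um,
            }
            for o in objects
        ],
        columns=[
            "object_id",
            "center_row",
            "center_col",
            "semi_major_um",
            "semi_minor_um",
            "orientation_rad",
            "true_class",
            "true_area_um2",
            "true_eccentricity",
            "true_equivalent_diameter_um",
        ],
    )
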