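"""Per-object morphometry, oligomer/plaque classification, and regional density.

Measurements follow the classical region-properties conventions: area is
the pixel count scaled by the pixel area; equivalent diameter is the
diameter of the circle of equal area, ``2*sqrt(A/pi)``; eccentricity comes
from the ellipse sharing the object's second central moments, with each
pixel treated as a unit square (a +1/12 correction on both diagonal
moments) so single pixels are circles (eccentricity 0) and thin lines stay
finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator

from .io import RegionOfInterest
from .segment import LabeledObjects

__all__ = [
    "ObjectMorphometry",
    "DensityResult",
    "ObjectMeasurer",
    "measure_objects",
    "classify_object",
    "classify_objects",
    "compute_density",
    "OLIGOMER",
    "PLAQUE",
]

OLIGOMER = "oligomer"
PLAQUE = "plaque"


@dataclass(frozen=True)
class ObjectMorphometry:
    """Shape parameters of one segmented object.

    ``object_class`` is None until classification is applied.
    """

    object_id: int
    area_um2: float
    equivalent_diameter_um: float
    eccentricity: float
    centroid: tuple[float, float]
    object_class: str | None = None


@dataclass(frozen=True)
class DensityResult:
    """Object count over geometric ROI area, in objects per mm^2."""

    n_objects: int
    roi_area_mm2: float
    density_per_mm2: float


class ObjectMeasurer(BaseEstimator):
    """Measure labeled objects; a fit-shaped wrapper over :func:`measure_objects`.

    Parameters
    ----------
    pixel_size_um : float
        Physical pixel size; all areas and diameters are expressed in
        micrometres through it.
    class_cutoff_diameter_um : float or None
        If set, objects are classified during :meth:`fit`.

    Attributes
    ----------
    objects_ : list of ObjectMorphometry
    n_objects_ : int
    """

    def __init__(self, pixel_size_um: float = 1.0, class_cutoff_diameter_um: float | None = None):
        self.pixel_size_um = pixel_size_um
        self.class_cutoff_diameter_um = class_cutoff_diameter_um

    def fit(self, X: LabeledObjects, y=None):
        objs = measure_objects(X, self.pixel_size_um)
        if self.class_cutoff_diameter_um is not None:
            objs = classify_objects(objs, self.class_cutoff_diameter_um)
        self.objects_ = objs
        self.n_objects_ = len(objs)
        return self


def measure_objects(labels: LabeledObjects, pixel_size_um: float) -> list[ObjectMorphometry]:
    """Compute area, equivalent diameter, eccentricity and centroid per object.

    Eccentricity: with mu the 2x2 second-central-moment matrix of the
    object's pixel coordinates, plus 1/12 on each diagonal entry (pixel as
    unit square), and eigenvalues l1 >= l2, eccentricity = sqrt(1 - l2/l1).
    """
    if not (pixel_size_um > 0):
        raise ValueError("pixel_size_um must be > 0")
    lab = labels.labels
    n = labels.n_objects
    out: list[ObjectMorphometry] = []
    if n == 0:
        return out
    slices = [s for s in _find_objects(lab, n)]
    px_area = pixel_size_um**2
    for obj_id, sl in enumerate(slices, start=1):
        if sl is None:
            raise RuntimeError(f"label {obj_id} has no pixels")
        rr, cc = np.nonzero(lab[sl] == obj_id)
        rr = rr + sl[0].start
        cc = cc + sl[1].start
        npx = rr.size
        r0, c0 = rr.mean(), cc.mean()
        dr, dc = rr - r0, cc - c0
        mrr = dr @ dr / npx + 1.0 / 12.0
        mcc = dc @ dc / npx + 1.0 / 12.0
        mrc = dr @ dc / npx
        # eigenvalues of [[mrr, mrc], [mrc, mcc]] in closed form
        half_tr = 0.5 * (mrr + mcc)
        delta = math.hypot(0.5 * (mrr - mcc), mrc)
        l1, l2 = half_tr + delta, half_tr - delta
        ecc = math.sqrt(max(0.0, 1.0 - l2 / l1))
        area = npx * px_area
        out.append(
            ObjectMorphometry(
                object_id=obj_id,
                area_um2=area,
                equivalent_diameter_um=2.0 * math.sqrt(area / math.pi),
                eccentricity=ecc,
                centroid=(float(r0), float(c0)),
            )
        )
    return out


def _find_objects(lab: np.ndarray, n: int):
    from scipy import ndimage

    return ndimage.find_objects(lab, max_label=n)


def classify_object(m: ObjectMorphometry, class_cutoff_diameter_um: float) -> str:
    """Oligomer iff equivalent diameter < cutoff, else plaque."""
    if not (class_cutoff_diameter_um > 0):
        raise ValueError("class_cutoff_diameter_um must be > 0")
    return OLIGOMER if m.equivalent_diameter_um < class_cutoff_diameter_um else PLAQUE


def classify_objects(
    objects: list[ObjectMorphometry], class_cutoff_diameter_um: float
) -> list[ObjectMorphometry]:
    """Return copies with ``object_class`` filled in."""
    return [
        replace(m, object_class=classify_object(m, class_cutoff_diameter_um))
        for m in objects
    ]


def compute_density(
    n_objects: int, roi: RegionOfInterest, pixel_size_um: float
) -> DensityResult:
    """Objects per mm^2 over the ROI's geometric (shoelace) area.

    The denominator is the polygon's vertex-defined area, not a pixel
    count, so it is independent of the rasterization.
    """
    if not (pixel_size_um > 0):
        raise ValueError("pixel_size_um must be > 0")
    if n_objects < 0:
        raise ValueError("n_objects must be >= 0")
    area_mm2 = roi.area_mm2(pixel_size_um)
    if area_mm2 <= 0:
        raise ValueError(f"ROI {roi.name!r} has zero area")
    return DensityResult(
        n_objects=int(n_objects),
        roi_area_mm2=area_mm2,
        density_per_mm2=n_objects / area_mm2,
    )
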