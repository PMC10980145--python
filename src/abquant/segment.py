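"""Segmentation of bright amyloid-like objects from a noisy tissue background.

Four stages, in the order they run in the pipeline: local-mean adaptive
thresholding, binary morphological opening, ROI restriction, and
connected-component labeling (followed by a minimum-area filter).  Each
stage exists both as a stateless scikit-learn-style transformer and as a
plain function.

The adaptive threshold marks a pixel foreground iff its intensity strictly
exceeds the mean of its ``window_px`` x ``window_px`` neighborhood
(mirror-padded at the borders) plus ``offset``.  The comparison is done on
exact separable box *sums* rather than pre-divided means, so on a constant
image no pixel ever exceeds its own neighborhood mean.

A practical constraint of any local-mean threshold: the window must be
larger than the widest object of interest, otherwise the local mean inside
a large object approaches the object intensity and its interior falls
below threshold (the object hollows out).  Choose ``window_px`` greater
than the largest expected object diameter in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin
from skimage.morphology import disk, opening as _sk_opening

from .io import Micrograph, RegionOfInterest

__all__ = [
    "SegmentationConfig",
    "PixelMask",
    "LabeledObjects",
    "AdaptiveThresholder",
    "MorphologicalOpener",
    "RoiRestrictor",
    "ObjectLabeler",
    "adaptive_threshold",
    "morphological_open",
    "apply_roi",
    "label_objects",
    "filter_small_objects",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Free parameters of the segmentation and classification stages.

    window_px : odd neighborhood side for the local-mean threshold (px).
    offset : intensity added to the local mean; foreground requires
        ``value > mean + offset``.  Set it a few noise standard deviations
        above zero to suppress background speckle.
    opening_radius_px : radius of the discrete disk structuring element.
    connectivity : 4 or 8; pixel adjacency used for labeling.
    min_object_area_um2 : objects smaller than this are discarded after
        labeling, before morphometry.
    class_cutoff_diameter_um : equivalent-diameter cutoff separating
        oligomer-like from plaque-like objects (consumed by morphometry).
    """

    window_px: int = 51
    offset: float = 6.0
    opening_radius_px: int = 1
    connectivity: int = 8
    min_object_area_um2: float = 0.5
    class_cutoff_diameter_um: float = 6.0

    def __post_init__(self) -> None:
        if self.window_px < 3 or self.window_px % 2 == 0:
            raise ValueError("window_px must be an odd integer >= 3")
        if self.opening_radius_px < 0:
            raise ValueError("opening_radius_px must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_object_area_um2 < 0:
            raise ValueError("min_object_area_um2 must be >= 0")
        if not (self.class_cutoff_diameter_um > 0):
            raise ValueError("class_cutoff_diameter_um must be > 0")


@dataclass(eq=False)
class PixelMask:
    """Binary foreground mask with the shape of its source image."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise ValueError("mask must be 2-D")
        self.values = arr.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())


@dataclass(eq=False)
class LabeledObjects:
    """Integer-labeled connected components; 0 is background.

    Positive labels are exactly 1..n_objects, assigned in raster order of
    each component's first-encountered pixel.
    """

    labels: np.ndarray
    n_objects: int

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be 2-D")
        if lab.size and lab.min() < 0:
            raise ValueError("labels must be non-negative")
        present = np.unique(lab)
        present = present[present > 0]
        if len(present) != self.n_objects or (
            len(present) and present[-1] != self.n_objects
        ):
            raise ValueError("labels must be exactly {0, 1, ..., n_objects}")
        self.labels = lab.astype(np.int32)


def _as_array(image) -> np.ndarray:
    if isinstance(image, Micrograph):
        return image.intensities
    return np.asarray(image, dtype=np.float64)


def _as_mask_array(mask) -> np.ndarray:
    if isinstance(mask, PixelMask):
        return mask.values
    return np.asarray(mask, dtype=bool)


# ---------------------------------------------------------------------------
# Transformers
# ---------------------------------------------------------------------------

class AdaptiveThresholder(TransformerMixin, BaseEstimator):
    """Local-mean adaptive threshold, ``value > window mean + offset``.

    Stateless: :meth:`fit` only validates parameters.  :meth:`transform`
    accepts a :class:`~abquant.io.Micrograph` or a 2-D array and returns a
    boolean array of the same shape.
    """

    def __init__(self, window_px: int = 51, offset: float = 6.0):
        self.window_px = window_px
        self.offset = offset

    def fit(self, X=None, y=None):
        if self.window_px < 3 or self.window_px % 2 == 0:
            raise ValueError("window_px must be an odd integer >= 3")
        self.n_features_in_ = 0
        return self

    def transform(self, X) -> np.ndarray:
        self.fit()
        img = _as_array(X)
        w = self.window_px
        if w > min(img.shape):
            raise ValueError(
                f"window_px={w} exceeds image extent {img.shape}"
            )
        kernel = np.ones(w, dtype=np.float64)
        sums = ndimage.correlate1d(img, kernel, axis=0, mode="mirror")
        sums = ndimage.correlate1d(sums, kernel, axis=1, mode="mirror")
        n = float(w * w)
        # value > mean + offset, compared via exact window sums
        return img * n > sums + self.offset * n


class MorphologicalOpener(TransformerMixin, BaseEstimator):
    """Binary opening (erosion then dilation) with a discrete disk.

    Radius 0 is the identity.  Pixels outside the frame count as foreground
    during erosion and background during dilation, so a foreground region
    flush with the frame edge is not eaten from outside.
    """

    def __init__(self, radius_px: int = 1):
        self.radius_px = radius_px

    def fit(self, X=None, y=None):
        if self.radius_px < 0:
            raise ValueError("radius_px must be >= 0")
        return self

    def transform(self, X) -> np.ndarray:
        self.fit()
        mask = _as_mask_array(X)
        if self.radius_px == 0:
            return mask.copy()
        return _sk_opening(mask, footprint=disk(self.radius_px)).astype(bool)


class RoiRestrictor(TransformerMixin, BaseEstimator):
    """Restrict a foreground mask to pixel centers covered by an ROI polygon."""

    def __init__(self, roi: RegionOfInterest | None = None):
        self.roi = roi

    def fit(self, X=None, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        mask = _as_mask_array(X)
        if self.roi is None:
            return mask.copy()
        rows, cols = mask.shape
        minr, minc, maxr, maxc = self.roi.polygon.bounds
        if maxr < 0 or maxc < 0 or minr > rows - 1 or minc > cols - 1:
            raise ValueError(
                f"ROI {self.roi.name!r} lies entirely outside the image frame"
            )
        out = np.zeros_like(mask)
        fg_r, fg_c = np.nonzero(mask)
        if fg_r.size:
            keep = self.roi.contains_points(fg_r, fg_c)
            out[fg_r[keep], fg_c[keep]] = True
        return out


class ObjectLabeler(TransformerMixin, BaseEstimator):
    """Connected-component labeling; behaves like a clusterer on pixels.

    After :meth:`fit`, ``labels_`` holds the label image and ``n_objects_``
    the component count.  Labels 1..n are assigned in raster order of each
    component's first pixel.
    """

    def __init__(self, connectivity: int = 8):
        self.connectivity = connectivity

    def _structure(self) -> np.ndarray:
        if self.connectivity == 4:
            return ndimage.generate_binary_structure(2, 1)
        if self.connectivity == 8:
            return ndimage.generate_binary_structure(2, 2)
        raise ValueError("connectivity must be 4 or 8")

    def fit(self, X, y=None):
        mask = _as_mask_array(X)
        lab, n = ndimage.label(mask, structure=self._structure())
        self.labels_ = _relabel_raster_order(lab, n)
        self.n_objects_ = n
        return self

    def transform(self, X) -> np.ndarray:
        return self.fit(X).labels_


def _relabel_raster_order(labels: np.ndarray, n: int) -> np.ndarray:
    """Renumber labels 1..n by raster order of first occurrence."""
    if n == 0:
        return labels.astype(np.int32)
    flat = labels.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.nonzero(flat)[0]
    # reversed so the earliest index wins
    first[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first[1:], kind="stable")
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[1 + order] = np.arange(1, n + 1, dtype=np.int32)
    return remap[labels]


# ---------------------------------------------------------------------------
# Function wrappers (the stable module API)
# ---------------------------------------------------------------------------

def adaptive_threshold(image, window_px: int = 51, offset: float = 6.0) -> PixelMask:
    """Foreground where intensity > local window mean + offset (strict)."""
    values = AdaptiveThresholder(window_px=window_px, offset=offset).transform(image)
    return PixelMask(values)


def morphological_open(mask, radius_px: int = 1) -> PixelMask:
    """Binary opening with a discrete disk; radius 0 returns the input."""
    return PixelMask(MorphologicalOpener(radius_px=radius_px).transform(mask))


def apply_roi(mask, roi: RegionOfInterest) -> PixelMask:
    """Keep foreground pixels whose centers fall inside the ROI (boundary inclusive)."""
    return PixelMask(RoiRestrictor(roi=roi).transform(mask))


def label_objects(mask, connectivity: int = 8) -> LabeledObjects:
    """Label maximal connected foreground components 1..n in raster order."""
    est = ObjectLabeler(connectivity=connectivity).fit(mask)
    return LabeledObjects(est.labels_, est.n_objects_)


def filter_small_objects(
    labeled: LabeledObjects, min_area_um2: float, pixel_size_um: float
) -> LabeledObjects:
    """Drop components smaller than ``min_area_um2``; renumber the rest.

    Applied after labeling and before morphometry so single-pixel noise
    survivors never enter the object statistics or the density numerator.
    """
    if min_area_um2 <= 0 or labeled.n_objects == 0:
        return labeled
    lab = labeled.labels
    areas_px = np.bincount(lab.ravel(), minlength=labeled.n_objects + 1)[1:]
    min_px = min_area_um2 / pixel_size_um**2
    keep = areas_px >= min_px
    remap = np.zeros(labeled.n_objects + 1, dtype=np.int32)
    remap[1:][keep] = np.arange(1, int(keep.sum()) + 1, dtype=np.int32)
    return LabeledObjects(remap[lab], int(keep.sum()))
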