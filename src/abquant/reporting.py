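"""Cross-slide aggregation and the two simple cohort statistics.

A region summary collects, across the slides of one brain region: object
count and density (mean and sample SD across slides), object-level area
and eccentricity statistics pooled over all objects of all slides, and the
per-class mean equivalent diameters.  Because pooling over objects and
averaging slide means answer slightly different questions, both are
reported: the pooled values are the headline columns and the
mean-of-slide-means variants sit alongside them.

The cohort comparison is the classical unpaired (pooled-variance Student)
two-sample t-test; Welch's unequal-variance variant is available behind a
flag.  Staining intensity across images is ranked by the number of pixels
above a fixed intensity threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .io import Micrograph
from .morphometry import OLIGOMER, PLAQUE, DensityResult, ObjectMorphometry

__all__ = [
    "SlideResult",
    "RegionSummary",
    "TTestResult",
    "aggregate_region",
    "threshold_pixel_count",
    "unpaired_t_test",
]


@dataclass(frozen=True)
class SlideResult:
    """Everything measured on one slide (one image + one ROI)."""

    source_id: str
    region: str
    objects: tuple[ObjectMorphometry, ...]
    density: DensityResult
    animal_id: str = ""

    def __post_init__(self) -> None:
        if self.density.n_objects != len(self.objects):
            raise ValueError(
                f"slide {self.source_id!r}: density.n_objects="
                f"{self.density.n_objects} but {len(self.objects)} objects"
            )


@dataclass(frozen=True)
class RegionSummary:
    """One summary row for a brain region; SDs are sample SDs (n-1).

    SDs are None where fewer than two values exist (e.g. a single slide).
    """

    region: str
    n_animals: int
    n_slides: int
    count_mean: float
    count_sd: float | None
    density_mean: float
    density_sd: float | None
    area_mean: float | None
    area_sd: float | None
    diameter_mean_by_class: dict
    eccentricity_mean: float | None
    eccentricity_sd: float | None
    area_slide_mean: float | None
    eccentricity_slide_mean: float | None


def _mean_sd(values: Sequence[float]) -> tuple[float | None, float | None]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return None, None
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else None
    return mean, sd


def aggregate_region(slides: Sequence[SlideResult]) -> RegionSummary:
    """Aggregate the slides of one region into a summary row.

    Count and density statistics are across slides; area and eccentricity
    statistics pool every object of every slide; per-class diameters pool
    likewise.  The result is invariant to slide order.
    """
    if len(slides) == 0:
        raise ValueError("need at least one slide")
    regions = {s.region for s in slides}
    if len(regions) != 1:
        raise ValueError(f"slides mix regions: {sorted(regions)}")
    (region,) = regions

    count_mean, count_sd = _mean_sd([len(s.objects) for s in slides])
    density_mean, density_sd = _mean_sd([s.density.density_per_mm2 for s in slides])

    pooled = [m for s in slides for m in s.objects]
    area_mean, area_sd = _mean_sd([m.area_um2 for m in pooled])
    ecc_mean, ecc_sd = _mean_sd([m.eccentricity for m in pooled])

    diam_by_class: dict = {}
    for cls in (OLIGOMER, PLAQUE):
        ds = [m.equivalent_diameter_um for m in pooled if m.object_class == cls]
        diam_by_class[cls] = float(np.mean(ds)) if ds else None

    # mean-of-slide-means variants (slides without objects contribute nothing)
    slide_area = [np.mean([m.area_um2 for m in s.objects]) for s in slides if s.objects]
    slide_ecc = [np.mean([m.eccentricity for m in s.objects]) for s in slides if s.objects]
    area_slide_mean = float(np.mean(slide_area)) if slide_area else None
    ecc_slide_mean = float(np.mean(slide_ecc)) if slide_ecc else None

    animals = {s.animal_id or s.source_id for s in slides}
    return RegionSummary(
        region=region,
        n_animals=len(animals),
        n_slides=len(slides),
        count_mean=count_mean,
        count_sd=count_sd,
        density_mean=density_mean,
        density_sd=density_sd,
        area_mean=area_mean,
        area_sd=area_sd,
        diameter_mean_by_class=diam_by_class,
        eccentricity_mean=ecc_mean,
        eccentricity_sd=ecc_sd,
        area_slide_mean=area_slide_mean,
        eccentricity_slide_mean=ecc_slide_mean,
    )


def threshold_pixel_count(image: Micrograph | np.ndarray, threshold: float) -> int:
    """Number of pixels strictly above a fixed intensity threshold.

    Used to rank staining intensity across images once a common threshold
    is chosen for the comparison batch.
    """
    arr = image.intensities if isinstance(image, Micrograph) else np.asarray(image)
    return int(np.count_nonzero(arr > threshold))


class TTestResult(NamedTuple):
    t_statistic: float
    p_value: float
    mean_difference: float
    se_difference: float
    df: float


def unpaired_t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
) -> TTestResult:
    """Two-sided unpaired two-sample t-test (pooled variance by default).

    Returns the t statistic, the two-sided p-value from the t distribution
    with n_a + n_b - 2 degrees of freedom (Welch-Satterthwaite df when
    ``equal_var=False``), the difference of means (a - b) and its standard
    error.  Two identical constant groups give t = 0, p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = float(a.mean() - b.mean())
    if equal_var:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        sa2, sb2 = va / na, vb / nb
        se = math.sqrt(sa2 + sb2)
        df = (
            (sa2 + sb2) ** 2 / (sa2**2 / (na - 1) + sb2**2 / (nb - 1))
            if se > 0
            else na + nb - 2
        )
    if se == 0:
        if diff == 0:
            return TTestResult(0.0, 1.0, 0.0, 0.0, float(df))
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t = diff / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(float(t), p, diff, float(se), float(df))
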