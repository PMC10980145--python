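"""End-to-end orchestration: load or simulate slides, segment, measure,
classify, compute densities, aggregate per region and write reports.

Stages run in a fixed order on every slide: load -> adaptive threshold ->
morphological opening -> ROI restriction -> connected-component labeling
-> minimum-area filter -> morphometry -> classification -> density.  A run
is driven by one configuration (YAML on disk or a dict) and a seed; rerun
with the same configuration and seed, it reproduces its output files
bit-identically.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from sklearn.base import BaseEstimator

from . import io as abio
from .io import Micrograph, RegionOfInterest
from .morphometry import ObjectMeasurer, compute_density
from .reporting import SlideResult, aggregate_region
from .segment import (
    LabeledObjects,
    SegmentationConfig,
    adaptive_threshold,
    apply_roi,
    filter_small_objects,
    label_objects,
    morphological_open,
)
from .simulate import SimulationConfig, generate_micrograph, truth_to_frame

__all__ = ["SlideAnalyzer", "RunConfig", "run_pipeline", "full_frame_roi"]

logger = logging.getLogger("abquant")


def full_frame_roi(shape: tuple[int, int], name: str = "frame") -> RegionOfInterest:
    """ROI covering every pixel center of an image frame."""
    rows, cols = shape
    return RegionOfInterest(
        np.array([(-0.5, -0.5), (-0.5, cols - 0.5), (rows - 0.5, cols - 0.5), (rows - 0.5, -0.5)]),
        name=name,
    )


class SlideAnalyzer(BaseEstimator):
    """Segment and measure one micrograph; scikit-learn estimator shape.

    Parameters mirror :class:`~abquant.segment.SegmentationConfig`.
    :meth:`fit` runs the full per-slide chain and exposes the results as
    fitted attributes:

    ``mask_`` : boolean foreground after threshold, opening and ROI;
    ``labels_`` : :class:`LabeledObjects` after the minimum-area filter;
    ``n_objects_`` : surviving object count;
    ``objects_`` : classified :class:`ObjectMorphometry` list;
    ``density_`` : :class:`DensityResult` over the ROI used.
    """

    def __init__(
        self,
        window_px: int = 51,
        offset: float = 6.0,
        opening_radius_px: int = 1,
        connectivity: int = 8,
        min_object_area_um2: float = 0.5,
        class_cutoff_diameter_um: float = 6.0,
    ):
        self.window_px = window_px
        self.offset = offset
        self.opening_radius_px = opening_radius_px
        self.connectivity = connectivity
        self.min_object_area_um2 = min_object_area_um2
        self.class_cutoff_diameter_um = class_cutoff_diameter_um

    def segmentation_config(self) -> SegmentationConfig:
        return SegmentationConfig(**self.get_params())

    def fit(self, X: Micrograph, y=None, roi: RegionOfInterest | None = None):
        self.segmentation_config()  # validate parameters
        if roi is None:
            roi = full_frame_roi(X.shape)
        mask = adaptive_threshold(X, self.window_px, self.offset)
        mask = morphological_open(mask, self.opening_radius_px)
        mask = apply_roi(mask, roi)
        labeled = label_objects(mask, self.connectivity)
        labeled = filter_small_objects(labeled, self.min_object_area_um2, X.pixel_size_um)
        measurer = ObjectMeasurer(
            pixel_size_um=X.pixel_size_um,
            class_cutoff_diameter_um=self.class_cutoff_diameter_um,
        ).fit(labeled)
        self.roi_ = roi
        self.mask_ = mask.values
        self.labels_ = labeled
        self.n_objects_ = labeled.n_objects
        self.objects_ = measurer.objects_
        self.density_ = compute_density(labeled.n_objects, roi, X.pixel_size_um)
        return self

    def to_slide_result(self, region: str, source_id: str, animal_id: str = "") -> SlideResult:
        return SlideResult(
            source_id=source_id,
            region=region,
            objects=tuple(self.objects_),
            density=self.density_,
            animal_id=animal_id,
        )


@dataclass
class RunConfig:
    """One pipeline run: a slide manifest XOR a simulation block.

    ``slides``: list of dicts with keys image, region and optionally roi,
    pixel_size_um, source_id, animal_id.  ``simulation``: list of dicts,
    each a :class:`SimulationConfig` field set plus region / n_slides /
    source_id.  Exactly one of the two must be present.
    """

    outdir: Path
    slides: list | None = None
    simulation: list | None = None
    segmentation: SegmentationConfig = dataclasses.field(default_factory=SegmentationConfig)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.slides is None) == (self.simulation is None):
            raise ValueError("config needs exactly one of 'slides' or 'simulation'")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_dict(cls, data: dict, outdir: str | Path | None = None) -> "RunConfig":
        data = dict(data)
        seg = SegmentationConfig(**data.pop("segmentation", {}))
        out = outdir if outdir is not None else data.pop("outdir", ".")
        data.pop("outdir", None)
        return cls(
            outdir=Path(out),
            slides=data.pop("slides", None),
            simulation=data.pop("simulation", None),
            segmentation=seg,
            seed=int(data.pop("seed", 0)),
            log_level=str(data.pop("log_level", "INFO")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path, outdir: str | Path | None = None) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data, outdir=outdir)


def _simulation_configs(run: RunConfig):
    """Expand the simulation block into (region, source_id, SimulationConfig)."""
    out = []
    counter = 0
    for block in run.simulation:
        block = dict(block)
        region = block.pop("region", "simulated")
        n_slides = int(block.pop("n_slides", 1))
        base_source = block.pop("source_id", None)
        block.pop("seed", None)  # per-slide seeds derive from the run seed
        for k in range(n_slides):
            seed = int(
                np.random.SeedSequence([run.seed, counter]).generate_state(1)[0] % (2**31)
            )
            cfg = SimulationConfig(**block, seed=seed)
            sid = base_source or f"{region}-slide{k + 1}"
            if base_source and n_slides > 1:
                sid = f"{base_source}-{k + 1}"
            out.append((region, sid, cfg))
            counter += 1
    return out


def _load_slide(entry: dict, base: Path):
    entry = dict(entry)
    img_path = base / entry["image"]
    micrograph = abio.read_micrograph(
        img_path,
        pixel_size_um_override=entry.get("pixel_size_um"),
        source_id=entry.get("source_id"),
    )
    roi = None
    if entry.get("roi"):
        rois = abio.read_roi(base / entry["roi"])
        if not rois:
            raise ValueError(f"ROI file {entry['roi']} contains no polygons")
        roi = rois[0]
    return micrograph, roi, entry.get("region", "unknown"), entry.get("animal_id", "")


def run_pipeline(config: RunConfig) -> tuple[Path, Path, Path]:
    """Execute a full run; returns (morphometry CSV, summary CSV, log) paths.

    Every slide failure is re-raised with the slide identity attached; a
    failing slide aborts the whole run rather than being skipped silently.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.log(getattr(logging, config.log_level.upper(), logging.INFO), msg)
        log_lines.append(msg)

    log(f"seed: {config.seed}")
    for key, value in dataclasses.asdict(config.segmentation).items():
        log(f"segmentation.{key}: {value}")

    analyzer = SlideAnalyzer(**dataclasses.asdict(config.segmentation))

    slide_inputs = []
    if config.simulation is not None:
        for region, sid, sim_cfg in _simulation_configs(config):
            for key, value in dataclasses.asdict(sim_cfg).items():
                log(f"simulate[{sid}].{key}: {value}")
            micrograph, truth, roi = generate_micrograph(sim_cfg)
            micrograph = Micrograph(micrograph.intensities, micrograph.pixel_size_um, sid)
            abio.write_micrograph(micrograph, outdir / f"{sid}.tif")
            truth_to_frame(truth).to_csv(outdir / f"{sid}.truth.csv", index=False)
            abio.write_roi(roi, outdir / f"{sid}.roi.txt")
            slide_inputs.append((micrograph, roi, region, "", sid))
    else:
        for entry in config.slides:
            try:
                micrograph, roi, region, animal = _load_slide(entry, Path("."))
            except Exception as exc:
                raise RuntimeError(
                    f"slide {entry.get('source_id') or entry.get('image')!r} failed: {exc}"
                ) from exc
            sid = micrograph.source_id
            log(f"slide[{sid}]: image={entry['image']} region={region}")
            slide_inputs.append((micrograph, roi, region, animal, sid))

    results: list[SlideResult] = []
    all_objects = []
    for micrograph, roi, region, animal, sid in slide_inputs:
        try:
            analyzer.fit(micrograph, roi=roi)
        except Exception as exc:
            raise RuntimeError(f"slide {sid!r} failed: {exc}") from exc
        res = analyzer.to_slide_result(region=region, source_id=sid, animal_id=animal)
        log(
            f"slide[{sid}]: n_objects={res.density.n_objects} "
            f"roi_area_mm2={res.density.roi_area_mm2:.6g} "
            f"density_per_mm2={res.density.density_per_mm2:.6g}"
        )
        results.append(res)
        all_objects.extend((sid, m) for m in res.objects)

    morph_path = outdir / "morphometry.csv"
    abio.write_morphometry_table(all_objects, morph_path)

    by_region: dict[str, list[SlideResult]] = {}
    for res in results:
        by_region.setdefault(res.region, []).append(res)
    summaries = [aggregate_region(slides) for _, slides in sorted(by_region.items())]
    summary_path = outdir / "summary.csv"
    abio.write_summary_table(summaries, summary_path)

    # per-slide table, useful for downstream cohort comparisons
    import pandas as pd

    pd.DataFrame(
        [
            {
                "source_id": r.source_id,
                "region": r.region,
                "animal_id": r.animal_id,
                "n_objects": r.density.n_objects,
                "roi_area_mm2": r.density.roi_area_mm2,
                "density_per_mm2": r.density.density_per_mm2,
            }
            for r in results
        ]
    ).to_csv(outdir / "slides.csv", index=False)

    log_path.write_text("\n".join(log_lines) + "\n")
    return morph_path, summary_path, log_path
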