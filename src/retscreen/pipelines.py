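"""End-to-end screening pipelines tying the detectors together."""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import fundus_segmentation as fundus
from . import io as rio
from . import oct_denoise, oct_rnfl
from .config import PipelineConfig
from .dr_grading import fundus_coordinates, grade_severity
from .exceptions import PipelineStageError, RetscreenError
from .types import (
    BoundaryTrace,
    DrReport,
    MorphScales,
    OctImage,
    RgbImage,
    RnflReport,
)

log = logging.getLogger("retscreen")


def _stage(name: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except RetscreenError as exc:
        raise PipelineStageError(name, exc) from exc
    log.info("stage %-14s %.3f s", name, time.perf_counter() - t0)
    return result


@dataclass(frozen=True)
class DrResult:
    """DR pipeline output bundle."""

    report: DrReport
    disc_center_rc: tuple[float, float]
    odd_px: float
    fovea_center_rc: tuple[float, float]


def run_dr_pipeline(
    image: str | Path | RgbImage,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> DrResult:
    """Preprocess, detect all fundus features, and grade DR severity.

    Order: preprocess -> optic disc -> vessels -> exudates -> fovea -> MAHM
    -> region partition -> grade.  With ``out_dir`` set, writes the report
    JSON, lesion masks (PNG), and component tables (CSV).
    """
    config = config or PipelineConfig()
    fc = config.fundus
    img = image if isinstance(image, RgbImage) else rio.load_rgb(image)
    if fc.preprocess:
        img = _stage("preprocess", fundus.preprocess, img, clip_limit=fc.clahe_clip_limit)
    scales = (
        MorphScales.for_width(img.width_px) if fc.scale_with_width else fc.scales
    )
    disc = _stage("optic_disc", fundus.detect_optic_disc, img)
    vessels = _stage(
        "vessels", fundus.extract_vessels, img, scales, min_area_px=fc.vessel_min_area_px
    )
    exudates = _stage(
        "exudates",
        fundus.detect_exudates,
        img,
        scales,
        disc,
        confirm_green_intensity=fc.confirm_exudates_green,
    )
    fovea = _stage("fovea", fundus.detect_fovea, img, vessels, disc)
    mahm = _stage(
        "mahm", fundus.detect_mahm, img, vessels, vessel_margin_px=fc.mahm_vessel_margin_px
    )
    partition = _stage("partition", fundus_coordinates, disc, fovea, img.shape)
    report = _stage("grade", grade_severity, exudates, mahm, partition, config.grading)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = report.to_dict()
        payload["disc_center_rc"] = list(disc.center_rc)
        payload["odd_px"] = disc.odd_px
        payload["fovea_center_rc"] = list(fovea.center_rc)
        (out / "dr_report.json").write_text(json.dumps(payload, indent=2))
        rio.save_mask_png(out / "vessels.png", vessels)
        rio.save_mask_png(out / "exudates.png", exudates)
        rio.save_mask_png(out / "mahm.png", mahm)
        rio.save_mask_png(out / "optic_disc.png", disc.mask)
        rio.save_components_csv(out / "exudates.csv", exudates)
        rio.save_components_csv(out / "mahm.csv", mahm)
    return DrResult(
        report=report,
        disc_center_rc=disc.center_rc,
        odd_px=disc.odd_px,
        fovea_center_rc=fovea.center_rc,
    )


@dataclass(frozen=True)
class RnflResult:
    """Single-scan RNFL output."""

    report: RnflReport
    anterior: BoundaryTrace
    posterior: BoundaryTrace


def run_rnfl_single(
    image: str | Path | OctImage, config: PipelineConfig | None = None
) -> RnflResult:
    """Boundary extraction and thickness for one OCT B-scan."""
    config = config or PipelineConfig()
    oc = config.oct
    img = image if isinstance(image, OctImage) else rio.load_oct(image, oc.axial_um_per_px)
    smoothed = _stage("gaussian", oct_denoise.gaussian_smooth, img)
    smoothed = _stage("median", oct_denoise.median_filter, smoothed)
    init = _stage("anterior_init", oct_rnfl.initial_anterior, smoothed)
    coarse = _stage("snake", oct_rnfl.greedy_snake, smoothed, init, oc.snake)
    # final refinement on the edge-preserved (diffused) field: the Gaussian
    # pre-blur biases the edge location by a pixel or two, the diffused image
    # does not
    sharp = _stage("diffuse", oct_denoise.anisotropic_diffuse, img, oc.diffusion)
    anterior = _stage("snake_refine", oct_rnfl.greedy_snake, sharp, coarse, oc.snake)
    # the posterior stage diffuses anisotropically itself, so it gets the raw
    # image: pre-blurring would only smear the posterior edge
    posterior = _stage(
        "posterior",
        oct_rnfl.estimate_posterior,
        img,
        anterior,
        oc.diffusion,
        n_sd=oc.posterior_n_sd,
        anterior_margin_px=oc.anterior_margin_px,
        rpe_depth_px=oc.rpe_depth_px,
        snake=oc.snake if oc.snake_posterior else None,
    )
    report = _stage(
        "thickness", oct_rnfl.rnfl_thickness, anterior, posterior, img.axial_um_per_px
    )
    return RnflResult(report=report, anterior=anterior, posterior=posterior)


@dataclass(frozen=True)
class PatientRnflResult:
    """Per-scan reports plus the per-patient aggregate (mean of scan means)."""

    scans: tuple[RnflResult, ...]
    failures: tuple[tuple[str, str], ...]
    mean_thickness_um: float
    label: str


def run_rnfl_pipeline(
    images: list[str | Path | OctImage],
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PatientRnflResult:
    """Run the RNFL chain over one or more scans and aggregate per patient."""
    if not images:
        raise RetscreenError("run_rnfl_pipeline requires at least one image")
    config = config or PipelineConfig()
    scans: list[RnflResult] = []
    failures: list[tuple[str, str]] = []
    for i, image in enumerate(images):
        name = str(image) if not isinstance(image, OctImage) else f"scan[{i}]"
        try:
            scans.append(run_rnfl_single(image, config))
        except RetscreenError as exc:
            failures.append((name, str(exc)))
            log.warning("scan %s failed: %s", name, exc)
    if not scans:
        raise RetscreenError("all scans failed; no aggregate available")
    if failures:
        warnings.warn(
            f"{len(failures)} of {len(images)} scans failed; aggregate uses successes only",
            stacklevel=2,
        )
    mean = float(np.mean([s.report.mean_thickness_um for s in scans]))
    label = oct_rnfl.classify_glaucoma(mean)

    result = PatientRnflResult(
        scans=tuple(scans), failures=tuple(failures), mean_thickness_um=mean, label=label
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = {
            "mean_thickness_um": mean,
            "label": label,
            "scans": [
                {"mean_thickness_um": s.report.mean_thickness_um, "label": s.report.label}
                for s in scans
            ],
            "failures": [{"image": n, "error": e} for n, e in failures],
        }
        (out / "rnfl_report.json").write_text(json.dumps(payload, indent=2))
        for i, s in enumerate(scans):
            rio.save_traces_csv(
                out / f"traces_{i:02d}.csv", s.anterior, s.posterior, s.report.thickness_um
            )
    return result
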