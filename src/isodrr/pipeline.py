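"""End-to-end geometric validation on the synthetic head phantom.

The pipeline replays the validation design entirely in silico: generate the
phantom, render the study projections with the divergent-beam renderer,
measure the six landmark distances on the images, compute the same
distances with the analytic projection oracle, put both sets in front of a
seeded panel of simulated observers, and summarise agreement with ICC(A,k)
and Bland–Altman limits.  Because the oracle plays the role the real
radiographs played, any disagreement beyond observer noise is a geometry
defect in the renderer.
"""
from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .geometry import (DetectorSpec, IsocentricSetup, default_projections,
                       pose_from_isocentric, projection_config_load, with_detector)
from .images import DRRImage, write_image
from .landmarks import (MeasurementDefinition, MeasurementRecord, detect_marker,
                        load_measurement_definitions, project_point,
                        projected_distance, records_to_csv, roi_around,
                        round_half_away)
from .phantom import HeadPhantomParams, LandmarkCatalogue, generate_head_phantom
from .render import RenderParams, render_drr
from .stats import (AgreementReport, ObserverMatrix, bland_altman, icc_a_k,
                    plot_bland_altman, simulate_observers, summarize_measurements)

logger = logging.getLogger(__name__)


@dataclass
class ValidationRunConfig:
    """Everything a reproducible validation run needs."""

    seed: int = 0
    phantom: HeadPhantomParams = field(default_factory=HeadPhantomParams)
    detector: DetectorSpec = field(default_factory=DetectorSpec)
    render: RenderParams = field(default_factory=RenderParams)
    projections: list[IsocentricSetup] | None = None  # None -> packaged study set
    measurements: list[MeasurementDefinition] | None = None  # None -> packaged six
    n_observers: int = 4
    observer_sigma_mm: float = 1.5
    observer_round_to_mm: bool = True
    roi_half_width_mm: float = 5.0
    out_dir: Path | None = None
    write_images: bool = True


@dataclass
class ValidationResult:
    """Outputs of one validation run."""

    report: AgreementReport
    records: list[MeasurementRecord]
    observer_matrix: ObserverMatrix
    summary: "object"  # pandas DataFrame
    mean_pairs: list[tuple[float, float]]
    images: dict[str, DRRImage]
    analytic_mm: dict[str, float]
    image_mm: dict[str, float]
    artifacts: dict[str, Path]


def measure_projection(
    img: DRRImage,
    pose,
    det: DetectorSpec,
    cat: LandmarkCatalogue,
    defs: list[MeasurementDefinition],
    roi_half_width_mm: float = 5.0,
) -> dict[str, float]:
    """Image-based distances (mm) for the definitions on one projection.

    ROIs are centred on the analytically predicted marker positions — the
    in-silico analogue of an observer knowing roughly where each landmark
    sits before reading off the ruler.
    """
    out = {}
    for d in defs:
        rois = []
        for lm in (d.landmark_a, d.landmark_b):
            pred = project_point(cat.get(lm), pose, det)
            rois.append(roi_around(pred, img, half_width_mm=roi_half_width_mm))
        a = detect_marker(img, rois[0])
        b = detect_marker(img, rois[1])
        out[d.name] = float(np.hypot(a.u_mm - b.u_mm, a.v_mm - b.v_mm))
    return out


def run_validation(cfg: ValidationRunConfig) -> ValidationResult:
    """Run the full phantom → render → measure → agreement pipeline."""
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    logger.info("stage phantom: generating synthetic head (seed=%d)", cfg.seed)
    vol, cat = generate_head_phantom(cfg.phantom, seed=cfg.seed)

    projections = cfg.projections or default_projections()
    projections = [with_detector(p, cfg.detector) for p in projections]
    defs = cfg.measurements or load_measurement_definitions()
    by_projection: dict[str, list[MeasurementDefinition]] = {}
    for d in defs:
        by_projection.setdefault(d.projection, []).append(d)
    missing = set(by_projection) - {p.name for p in projections}
    if missing:
        raise ValueError(f"measurements reference unknown projections: {sorted(missing)}")

    images: dict[str, DRRImage] = {}
    poses = {}
    for setup in projections:
        logger.info("stage render: %s (alpha=%g, beta=%g)", setup.name,
                    setup.alpha_deg, setup.beta_deg)
        pose = pose_from_isocentric(setup)
        poses[setup.name] = pose
        img = render_drr(vol, pose, setup.detector, cfg.render)
        images[setup.name] = img
        if out_dir and cfg.write_images:
            artifacts[f"image_{setup.name}"] = write_image(img, out_dir / f"{setup.name}.png")

    analytic_mm: dict[str, float] = {}
    image_mm: dict[str, float] = {}
    records: list[MeasurementRecord] = []
    for proj_name, proj_defs in by_projection.items():
        pose = poses[proj_name]
        det = next(p.detector for p in projections if p.name == proj_name)
        logger.info("stage measure: %s (%d distances)", proj_name, len(proj_defs))
        measured = measure_projection(images[proj_name], pose, det, cat, proj_defs,
                                      cfg.roi_half_width_mm)
        for d in proj_defs:
            analytic = projected_distance(d.landmark_a, d.landmark_b, cat, pose, det)
            analytic_mm[d.name] = analytic
            image_mm[d.name] = measured[d.name]
            records.append(MeasurementRecord(proj_name, d.landmark_a, d.landmark_b,
                                             analytic, "analytic", d.plane))
            records.append(MeasurementRecord(proj_name, d.landmark_a, d.landmark_b,
                                             measured[d.name], "image", d.plane))

    # observer panel over both modalities; one matrix of 2 x n_measurements items
    names = [d.name for d in defs]
    truths = [analytic_mm[n] for n in names] + [image_mm[n] for n in names]
    item_meas = names + names
    item_mod = ["analytic"] * len(names) + ["image"] * len(names)
    logger.info("stage observers: k=%d sigma=%g mm", cfg.n_observers, cfg.observer_sigma_mm)
    matrix = simulate_observers(
        truths, k=cfg.n_observers, sigma_mm=cfg.observer_sigma_mm,
        round_to_mm=cfg.observer_round_to_mm, seed=cfg.seed,
        measurements=item_meas, modalities=item_mod,
    )
    # interleave (analytic, image) per measurement, mirroring the paired table
    order = [i for pair in zip(range(len(names)), range(len(names), 2 * len(names)))
             for i in pair]
    matrix = ObserverMatrix(
        values=matrix.values[order],
        measurements=[matrix.measurements[i] for i in order],
        modalities=[matrix.modalities[i] for i in order],
        raters=matrix.raters,
    )

    logger.info("stage stats: ICC + Bland-Altman")
    icc, lo, hi = icc_a_k(matrix)
    summary, pairs = summarize_measurements(matrix)
    ba = bland_altman(pairs)
    report = AgreementReport(
        bias_mm=ba.bias_mm, sd_mm=ba.sd_mm, loa_low_mm=ba.loa_low_mm,
        loa_high_mm=ba.loa_high_mm, n_pairs=ba.n_pairs,
        icc=icc, icc_ci_low=lo, icc_ci_high=hi,
    )

    if out_dir:
        artifacts["measurements"] = records_to_csv(records, out_dir / "measurements.csv")
        artifacts["observers"] = matrix.to_table_csv(out_dir / "observers.csv")
        summary_path = out_dir / "summary.csv"
        summary.to_csv(summary_path, float_format="%.6f")
        artifacts["summary"] = summary_path
        artifacts["report"] = _write_report(report, out_dir / "report.txt")
        artifacts["bland_altman"] = plot_bland_altman(pairs, report,
                                                      out_dir / "bland_altman.png")
        artifacts["manifest"] = _write_manifest(cfg, out_dir / "manifest.json")

    return ValidationResult(
        report=report, records=records, observer_matrix=matrix, summary=summary,
        mean_pairs=pairs, images=images, analytic_mm=analytic_mm,
        image_mm=image_mm, artifacts=artifacts,
    )


def _write_report(report: AgreementReport, path: Path) -> Path:
    lines = [
        "agreement report",
        f"ICC(A,k) = {report.icc:.3f} (95% CI {report.icc_ci_low:.3f}-{report.icc_ci_high:.3f})",
        f"Bland-Altman bias = {round_half_away(report.bias_mm, 2):.2f} mm "
        f"(SD {round_half_away(report.sd_mm, 2):.2f})",
        f"95% limits of agreement: {round_half_away(report.loa_high_mm, 2):.2f} "
        f"to {round_half_away(report.loa_low_mm, 2):.2f} mm",
        f"n pairs = {report.n_pairs}",
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def _config_dict(cfg: ValidationRunConfig) -> dict:
    d = asdict(cfg)
    d["out_dir"] = str(cfg.out_dir) if cfg.out_dir else None
    if cfg.projections is not None:
        d["projections"] = [asdict(p) for p in cfg.projections]
    if cfg.measurements is not None:
        d["measurements"] = [asdict(m) for m in cfg.measurements]
    return d


def _write_manifest(cfg: ValidationRunConfig, path: Path) -> Path:
    manifest = {
        "isodrr_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": _config_dict(cfg),
    }
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def stats_report(observer_csv: str | Path, out_dir: str | Path | None = None
                 ) -> AgreementReport:
    """ICC + Bland–Altman from an observer table CSV (measurement,modality,obs…)."""
    matrix = ObserverMatrix.from_table_csv(observer_csv)
    icc, lo, hi = icc_a_k(matrix)
    summary, pairs = summarize_measurements(matrix)
    ba = bland_altman(pairs)
    report = AgreementReport(
        bias_mm=ba.bias_mm, sd_mm=ba.sd_mm, loa_low_mm=ba.loa_low_mm,
        loa_high_mm=ba.loa_high_mm, n_pairs=ba.n_pairs,
        icc=icc, icc_ci_low=lo, icc_ci_high=hi,
    )
    if out_dir:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out_dir / "summary.csv", float_format="%.6f")
        _write_report(report, out_dir / "report.txt")
        plot_bland_altman(pairs, report, out_dir / "bland_altman.png")
    return report
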