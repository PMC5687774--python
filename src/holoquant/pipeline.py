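"""End-to-end orchestration: simulate -> secure transfer -> locate ->
characterise -> segment -> recognise -> calibrate -> predict.

Two entry levels are provided.  :func:`run_experiment` executes the whole
chain in memory on a simulated acquisition campaign (six sensors, eleven pH
levels) and returns every intermediate quantity — this is what the tests and
the reproduction script drive.  :func:`demo_dataset` and :func:`run_pipeline`
are the file-based equivalents behind the command-line interface, emitting
PNG scenes with JSON ground-truth sidecars, a predictions CSV and a run
manifest with per-stage input/output hashes.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import polygon as _polygon
from skimage.transform import warp

from . import calibrate as cal
from . import camera as cam
from . import locate as loc
from . import recognize as rec
from . import segment as seg
from . import simulate as sim

__all__ = ["PipelineConfig", "demo_dataset", "run_experiment", "run_pipeline", "quad_iou"]


@dataclass
class PipelineConfig:
    """Flat configuration for every pipeline stage."""

    seed: int = 0
    # simulator / demo dataset
    n_sensors: int = 6
    clutter: float = 0.3
    noise_sd: float = 0.003
    gamma_rgb: tuple[float, float, float] = (2.1, 2.0, 1.9)
    vignette: float = 0.25
    image_size: tuple[int, int] = (512, 512)
    sensor_hue_spread_deg: float = 4.0
    # secure transfer
    passcode: str = "ph0sensor"
    wavelet: str = "haar"
    keep_fraction: float = 0.12
    # locator
    min_inliers: int = 12
    layout_fraction: float = 0.3
    # camera characterisation
    term_sets: tuple = ("linear3", "poly5", "poly8", "poly11", "poly20")
    # segmentation
    method: str = "kmeans"
    colour_space: str = "lab"
    vm_params: seg.VMParams = field(default_factory=seg.VMParams)
    smooth_sigma: float = 1.0
    # recognition / calibration
    som_epochs: int = 60
    n_test_sensors: int = 2

    def to_text(self) -> str:
        lines = []
        for k in self.__dataclass_fields__:
            v = getattr(self, k)
            if isinstance(v, seg.VMParams):
                for sub in ("m_const", "mu", "sigma", "k_min", "k_max", "sign_variant"):
                    lines.append(f"vm.{sub}={getattr(v, sub)}")
            elif isinstance(v, (tuple, list)):
                lines.append(f"{k}={','.join(str(x) for x in v)}")
            else:
                lines.append(f"{k}={v}")
        return "\n".join(lines) + "\n"


def _mix_default() -> np.ndarray:
    # mild channel cross-talk typical of a phone sensor
    return np.array([[0.90, 0.07, 0.03], [0.05, 0.90, 0.05], [0.03, 0.08, 0.89]])


def _demo_camera(cfg: PipelineConfig, seed: int) -> sim.CameraSimConfig:
    return sim.CameraSimConfig(
        gamma_rgb=cfg.gamma_rgb,
        vignette_strength=cfg.vignette,
        mix_matrix=_mix_default(),
        noise_sd=cfg.noise_sd,
        seed=seed,
        size=cfg.image_size,
    )


def _sensor_offsets(cfg: PipelineConfig) -> np.ndarray:
    if cfg.n_sensors == 1:
        return np.zeros(1)
    s = cfg.sensor_hue_spread_deg / 2.0
    return np.linspace(-s, s, cfg.n_sensors)


def quad_iou(quad_a: np.ndarray, quad_b: np.ndarray, shape: tuple[int, int]) -> float:
    """Intersection-over-union of two [row, col] quadrilaterals."""
    masks = []
    for quad in (quad_a, quad_b):
        q = np.asarray(quad, dtype=float)
        rr, cc = _polygon(q[:, 0], q[:, 1], shape=shape)
        m = np.zeros(shape, dtype=bool)
        m[rr, cc] = True
        masks.append(m)
    union = np.logical_or(*masks).sum()
    return float(np.logical_and(*masks).sum() / union) if union else 0.0


# ---------------------------------------------------------------------------
# Demo dataset on disk
# ---------------------------------------------------------------------------

def demo_dataset(out_dir, seed: int = 0, config: PipelineConfig | None = None,
                 ph_levels: tuple[float, ...] = sim.PH_LEVELS) -> dict:
    """Write the simulated acquisition campaign: one chart, one grey card, the
    fiducial template and n_sensors x 11 pH scenes with truth sidecars."""
    cfg = config or PipelineConfig(seed=seed)
    out = Path(out_dir)
    (out / "scenes").mkdir(parents=True, exist_ok=True)
    camera = _demo_camera(cfg, seed)

    chart_img, chart_truth = sim.render_chart(camera)
    sim.write_image(out / "chart.png", chart_img)
    sim.write_truth(out / "chart.json", chart_truth)
    sim.write_image(out / "grey_card.png", sim.render_grey_card(camera))
    sim.write_image(out / "template.png", sim.render_template())

    offsets = _sensor_offsets(cfg)
    files = []
    for s in range(cfg.n_sensors):
        for ph in ph_levels:
            scene_cam = sim.CameraSimConfig(
                gamma_rgb=camera.gamma_rgb, vignette_strength=camera.vignette_strength,
                mix_matrix=camera.mix, noise_sd=camera.noise_sd,
                seed=seed * 1000 + s * 16 + int(round(ph * 4)), size=camera.size,
            )
            img, truth = sim.render_scene(scene_cam, ph, cfg.clutter, hue_offset_deg=offsets[s])
            stem = f"sensor{s}_ph{ph:.2f}"
            sim.write_image(out / "scenes" / f"{stem}.png", img)
            sim.write_truth(out / "scenes" / f"{stem}.json", truth)
            files.append({"file": f"scenes/{stem}.png", "sensor": s, "ph": ph})
    manifest = {"seed": seed, "n_scenes": len(files), "scenes": files}
    with open(out / "dataset.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


# ---------------------------------------------------------------------------
# Per-scene processing
# ---------------------------------------------------------------------------

@dataclass
class SceneOutcome:
    detection: loc.Detection | None
    segmentation: seg.SegmentationResult | None
    descriptors: list[rec.ROIDescriptor]
    segment_masks_scene: dict[int, np.ndarray]
    window_slices: tuple | None
    error: str | None = None


def process_scene(scene_rgb: np.ndarray, template: np.ndarray, characterizer: cam.CameraCharacterizer,
                  cfg: PipelineConfig) -> SceneOutcome:
    """Locate the fiducial, extract and segment the sensor window, and build
    one hybrid colour descriptor per segment (plus each segment's mask warped
    back to scene coordinates for scoring)."""
    try:
        det = loc.match_template(scene_rgb, template, min_inliers=cfg.min_inliers, seed=cfg.seed)
    except loc.NoDetectionError as exc:
        return SceneOutcome(None, None, [], {}, None, error=str(exc))

    xyz_scene = characterizer.transform(scene_rgb)
    rgb_patch, _ = loc.extract_roi_patch(scene_rgb, det, layout=cfg.layout_fraction)
    xyz_patch, _ = loc.extract_roi_patch(xyz_scene, det, layout=cfg.layout_fraction)

    segmentation, _vm = seg.auto_segment(
        rgb_patch, method=cfg.method, colour_space=cfg.colour_space, params=cfg.vm_params,
        seed=cfg.seed, xyz_image=xyz_patch, smooth_sigma=cfg.smooth_sigma,
    )
    descriptors = []
    masks = {}
    h, w = det.template_shape
    lo_r = int(round(h * (1 - cfg.layout_fraction) / 2))
    lo_c = int(round(w * (1 - cfg.layout_fraction) / 2))
    for sid in range(segmentation.k):
        if not np.any(segmentation.labels == sid):
            continue
        descriptors.append(rec.extract_descriptor(xyz_patch, rgb_patch, segmentation.labels, sid))
        canvas = np.zeros((h, w))
        ph, pw = segmentation.labels.shape
        canvas[lo_r : lo_r + ph, lo_c : lo_c + pw] = (segmentation.labels == sid).astype(float)
        warped = warp(canvas, det.transform.inverse, output_shape=scene_rgb.shape[:2], order=0)
        masks[sid] = warped > 0.5
    window = (slice(lo_r, lo_r + segmentation.labels.shape[0]), slice(lo_c, lo_c + segmentation.labels.shape[1]))
    return SceneOutcome(det, segmentation, descriptors, masks, window)


def _mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union) if union else 0.0


# ---------------------------------------------------------------------------
# Full in-memory experiment
# ---------------------------------------------------------------------------

def run_experiment(seed: int = 0, config: PipelineConfig | None = None,
                   scenes_per_sensor: tuple[float, ...] = sim.PH_LEVELS) -> dict:
    """Simulate the full acquisition campaign and run the complete chain.

    Returns a dictionary with camera-recovery diagnostics, locator scores,
    recognition scores, and the held-out calibration metrics.
    """
    cfg = config or PipelineConfig(seed=seed)
    cfg.seed = seed
    camera = _demo_camera(cfg, seed)
    offsets = _sensor_offsets(cfg)
    template = sim.render_template()

    # characterisation imagery
    chart_img, chart_truth = sim.render_chart(camera)
    grey_card = sim.render_grey_card(camera)
    characterizer = cam.CameraCharacterizer(term_sets=cfg.term_sets).fit(
        chart_img, chart_truth.patch_boxes, chart_truth.chart_xyz,
        chart_truth.grey_indices, chart_truth.grey_luminance, grey_card,
    )

    records = []
    for s in range(cfg.n_sensors):
        for ph in scenes_per_sensor:
            scene_cam = sim.CameraSimConfig(
                gamma_rgb=camera.gamma_rgb, vignette_strength=camera.vignette_strength,
                mix_matrix=camera.mix, noise_sd=camera.noise_sd,
                seed=seed * 1000 + s * 16 + int(round(ph * 4)), size=camera.size,
            )
            img, truth = sim.render_scene(scene_cam, ph, cfg.clutter, hue_offset_deg=offsets[s])
            outcome = process_scene(img, template, characterizer, cfg)
            records.append({"sensor": s, "ph": ph, "truth": truth, "outcome": outcome})

    # locator score: quad IoU against truth
    shape = cfg.image_size
    loc_ious = [
        quad_iou(r["outcome"].detection.quad, r["truth"].quad, shape)
        for r in records if r["outcome"].detection is not None
    ]
    detected = sum(r["outcome"].detection is not None for r in records)

    # label training segments against ground truth (overlap of segment with
    # the true hologram mask), train the SOM, and recognise the ROI everywhere
    sensors = np.array([r["sensor"] for r in records])
    uniq = np.unique(sensors)
    rng = np.random.default_rng(seed)
    test_sensors = set(rng.choice(uniq, size=cfg.n_test_sensors, replace=False).tolist())

    train_X, train_y = [], []
    for r in records:
        if r["sensor"] in test_sensors or r["outcome"].detection is None:
            continue
        for d in r["outcome"].descriptors:
            m = r["outcome"].segment_masks_scene[d.segment_id]
            inter = np.logical_and(m, r["truth"].roi_mask).sum()
            frac = inter / max(m.sum(), 1)
            train_X.append(d.vector)
            train_y.append("hologram" if frac > 0.5 else "background")
    som = rec.SOMClassifier(n_epochs=cfg.som_epochs, seed=seed).fit(np.stack(train_X), np.array(train_y))

    roi_iou, roi_hits = [], 0
    descs, phs, sens = [], [], []
    for r in records:
        out = r["outcome"]
        if out.detection is None:
            continue
        try:
            _, roi_sid = rec.classify_segments(som, out.descriptors)
        except rec.NoROIError:
            continue
        iou = _mask_iou(out.segment_masks_scene[roi_sid], r["truth"].roi_mask)
        roi_iou.append(iou)
        roi_hits += iou > 0.5
        d = next(d for d in out.descriptors if d.segment_id == roi_sid)
        descs.append(d.vector)
        phs.append(r["ph"])
        sens.append(r["sensor"])

    descs = np.stack(descs)
    phs = np.array(phs)
    sens = np.array(sens)
    is_test = np.isin(sens, list(test_sensors))
    mlp = cal.MLPCalibrator(cal.MLPConfig(seed=seed)).fit(descs[~is_test], phs[~is_test])
    metrics = cal.evaluate(mlp, descs[is_test], phs[is_test])
    train_metrics = cal.evaluate(mlp, descs[~is_test], phs[~is_test])

    result = {
        "config": cfg,
        "camera": {
            "true_gamma": np.asarray(camera.gamma_rgb),
            "fitted_gamma": characterizer.gamma_.gamma_rgb,
            "model_median_dE": characterizer.model_.median_dE,
            "selected_terms": characterizer.model_.n_terms,
        },
        "locator": {
            "n_scenes": len(records),
            "n_detected": detected,
            "iou": np.array(loc_ious),
            "frac_iou_gt_05": float(np.mean([i > 0.5 for i in loc_ious])) if loc_ious else 0.0,
        },
        "recognition": {
            "roi_iou": np.array(roi_iou),
            "frac_roi_iou_gt_05": float(np.mean([i > 0.5 for i in roi_iou])) if roi_iou else 0.0,
        },
        "calibration": {
            "test": metrics,
            "train": train_metrics,
            "test_sensors": sorted(test_sensors),
            "n_train": int((~is_test).sum()),
            "n_test": int(is_test.sum()),
        },
        "records": records,
        "som": som,
        "mlp": mlp,
        "characterizer": characterizer,
        "template": template,
    }
    return result


def compare_segmentation_methods(
    scenes: list[tuple[np.ndarray, sim.SceneTruth]],
    characterizer: cam.CameraCharacterizer,
    template: np.ndarray,
    cfg: PipelineConfig | None = None,
    colour_space: str = "lab",
) -> dict:
    """Agreement between k-means and fuzzy c-means sensor quantification.

    For every scene the fiducial is located once, the sensor window is
    segmented with both methods, the segment overlapping the true sensor mask
    is taken as the ROI under each method, and its three mean colour
    coordinates in ``colour_space`` form one 3-targets x 2-methods table.
    Returns the scene-averaged one-way ICC, per-scene ICC results and
    per-coordinate Bland-Altman limits; scenes where either method fails are
    skipped with a warning entry.
    """
    from . import agreement as agr
    from .color import xyz_to_lab

    cfg = cfg or PipelineConfig()
    tables, skipped = [], []
    for idx, (scene_rgb, truth) in enumerate(scenes):
        try:
            det = loc.match_template(scene_rgb, template, min_inliers=cfg.min_inliers, seed=cfg.seed)
        except loc.NoDetectionError as exc:
            skipped.append(f"scene {idx}: {exc}")
            continue
        xyz_scene = characterizer.transform(scene_rgb)
        rgb_patch, _ = loc.extract_roi_patch(scene_rgb, det, layout=cfg.layout_fraction)
        xyz_patch, _ = loc.extract_roi_patch(xyz_scene, det, layout=cfg.layout_fraction)
        # true sensor mask in rectified patch coordinates
        h, w = det.template_shape
        lo_r = int(round(h * (1 - cfg.layout_fraction) / 2))
        lo_c = int(round(w * (1 - cfg.layout_fraction) / 2))
        truth_patch = warp(truth.roi_mask.astype(float), det.transform, output_shape=(h, w), order=0)
        truth_win = truth_patch[lo_r : lo_r + rgb_patch.shape[0], lo_c : lo_c + rgb_patch.shape[1]] > 0.5

        coords = {}
        for method in ("kmeans", "fcm"):
            segmentation, _ = seg.auto_segment(
                rgb_patch, method=method, colour_space=cfg.colour_space, params=cfg.vm_params,
                seed=cfg.seed, xyz_image=xyz_patch, smooth_sigma=cfg.smooth_sigma,
            )
            overlaps = [
                (np.logical_and(segmentation.labels == sid, truth_win).sum() / max((segmentation.labels == sid).sum(), 1), sid)
                for sid in range(segmentation.k)
            ]
            frac, roi_sid = max(overlaps)
            if frac < 0.2:
                coords = {}
                skipped.append(f"scene {idx}: {method} found no segment over the sensor")
                break
            mask = segmentation.labels == roi_sid
            if colour_space == "lab":
                coords[method] = xyz_to_lab(xyz_patch[mask]).mean(axis=0)
            elif colour_space == "rgb":
                coords[method] = rgb_patch[mask].mean(axis=0)
            else:
                from .color import rgb_to_hsi

                hsi = rgb_to_hsi(rgb_patch[mask])
                from .color import circular_mean_deg

                coords[method] = np.array([
                    circular_mean_deg(hsi[:, 0], hsi[:, 1] + 1e-12), hsi[:, 1].mean(), hsi[:, 2].mean()
                ])
        if coords:
            tables.append(np.column_stack([coords["kmeans"], coords["fcm"]]))
    if not tables:
        raise RuntimeError("both methods failed on every scene")
    mean_icc, per_scene, ba = agr.compare_methods(tables)
    return {"mean_icc": mean_icc, "per_scene_icc": per_scene, "bland_altman": ba,
            "tables": tables, "skipped": skipped}


# ---------------------------------------------------------------------------
# File-based pipeline (CLI backend)
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(dataset_dir, out_dir, config: PipelineConfig | None = None) -> dict:
    """Run the chain on a demo-dataset directory tree and write predictions.

    Expects the layout written by :func:`demo_dataset` (chart.png/.json,
    grey_card.png, template.png, scenes/*.png with .json sidecars).  Emits
    ``predictions.csv`` and ``manifest.json`` in ``out_dir``.
    """
    dataset_dir, out_path = Path(dataset_dir), Path(out_dir)
    cfg = config or PipelineConfig()
    out_path.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "warnings": []}

    def stage(name: str, inputs: list[Path]):
        manifest["stages"].append(
            {"stage": name, "time": time.time(), "inputs": {str(p): _sha256(p) for p in inputs if p.exists()}}
        )

    for required in ("chart.png", "chart.json", "grey_card.png", "template.png"):
        if not (dataset_dir / required).exists():
            raise FileNotFoundError(
                f"missing {required} in {dataset_dir}: run the simulate/demo stage first "
                "(a camera cannot be characterised without its chart and grey card)"
            )

    stage("characterise", [dataset_dir / "chart.png", dataset_dir / "grey_card.png"])
    chart_img = sim.read_image(dataset_dir / "chart.png")
    chart_truth = sim.read_truth(dataset_dir / "chart.json")
    grey_card = sim.read_image(dataset_dir / "grey_card.png")
    template = sim.read_image(dataset_dir / "template.png")
    characterizer = cam.CameraCharacterizer(term_sets=cfg.term_sets).fit(
        chart_img, chart_truth.patch_boxes, chart_truth.chart_xyz,
        chart_truth.grey_indices, chart_truth.grey_luminance, grey_card,
    )

    with open(dataset_dir / "dataset.json") as fh:
        dataset = json.load(fh)
    scene_files = [dataset_dir / rec_["file"] for rec_ in dataset["scenes"]]
    stage("process-scenes", scene_files)

    records = []
    for entry in dataset["scenes"]:
        img = sim.read_image(dataset_dir / entry["file"])
        truth = sim.read_truth((dataset_dir / entry["file"]).with_suffix(".json"))
        outcome = process_scene(img, template, characterizer, cfg)
        if outcome.error:
            manifest["warnings"].append(f"{entry['file']}: {outcome.error}")
        records.append({"sensor": entry["sensor"], "ph": entry["ph"], "truth": truth,
                        "outcome": outcome, "file": entry["file"]})

    sensors = np.unique([r["sensor"] for r in records])
    rng = np.random.default_rng(cfg.seed)
    test_sensors = set(rng.choice(sensors, size=cfg.n_test_sensors, replace=False).tolist())

    train_X, train_y = [], []
    for r in records:
        if r["sensor"] in test_sensors or r["outcome"].detection is None:
            continue
        for d in r["outcome"].descriptors:
            m = r["outcome"].segment_masks_scene[d.segment_id]
            frac = np.logical_and(m, r["truth"].roi_mask).sum() / max(m.sum(), 1)
            train_X.append(d.vector)
            train_y.append("hologram" if frac > 0.5 else "background")
    som = rec.SOMClassifier(n_epochs=cfg.som_epochs, seed=cfg.seed).fit(np.stack(train_X), np.array(train_y))

    rows = []
    descs, phs, sens = [], [], []
    for r in records:
        out = r["outcome"]
        if out.detection is None:
            rows.append((r["file"], r["ph"], "", "no-detection"))
            continue
        try:
            _, roi_sid = rec.classify_segments(som, out.descriptors)
        except rec.NoROIError:
            rows.append((r["file"], r["ph"], "", "no-roi"))
            continue
        d = next(d for d in out.descriptors if d.segment_id == roi_sid)
        descs.append(d.vector)
        phs.append(r["ph"])
        sens.append(r["sensor"])
        rows.append((r["file"], r["ph"], d, ""))

    descs_arr, phs_arr, sens_arr = np.stack(descs), np.array(phs), np.array(sens)
    is_test = np.isin(sens_arr, list(test_sensors))
    stage("calibrate", [])
    mlp = cal.MLPCalibrator(cal.MLPConfig(seed=cfg.seed)).fit(descs_arr[~is_test], phs_arr[~is_test])

    import csv

    pred_path = out_path / "predictions.csv"
    with open(pred_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["scene_id", "true_ph", "predicted_ph", "flags"])
        for file, ph, d, flag in rows:
            if flag:
                writer.writerow([file, f"{ph:.2f}", "", flag])
            else:
                pred, oob = mlp.predict(d.vector[None, :], return_flags=True)
                writer.writerow([file, f"{ph:.2f}", f"{pred[0]:.4f}",
                                 "out-of-range" if oob[0] else ""])

    metrics = cal.evaluate(mlp, descs_arr[is_test], phs_arr[is_test]) if is_test.any() else None
    manifest["outputs"] = {str(pred_path): _sha256(pred_path)}
    manifest["test_sensors"] = sorted(int(s) for s in test_sensors)
    if metrics:
        manifest["test_rmse"] = metrics["rmse"]
        manifest["test_r2"] = metrics["r2"]
    with open(out_path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
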