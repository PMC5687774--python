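"""Synthetic scene and camera simulator for colorimetric sensor readout.

Provides programmatically generated stand-ins for a physical acquisition
setup: a 24-patch colour chart, an 18%-grey uniformity card, and cluttered
scenes containing a QR-like fiducial with a central circular "hologram"
patch whose hue encodes pH over the 3.00-6.50 operating range.  Every render
passes through a parameterised forward camera model (channel mixing, power-law
encoding, vignetting, additive Gaussian noise) and returns complete ground
truth, so each downstream stage can be scored without re-deriving anything.

The forward model for a linear-light scene S is::

    image = clip( V * (mix @ S)^(1/gamma) + noise, 0, 1 )

with V the radial vignetting field ``1 - strength * (r / r_corner)^2``.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass

import numpy as np
from skimage.draw import disk as _disk
from skimage.transform import SimilarityTransform, warp

from .color import linear_rgb_to_xyz

__all__ = [
    "CameraSimConfig",
    "SceneTruth",
    "PH_LEVELS",
    "hue_from_ph",
    "render_chart",
    "render_scene",
    "render_grey_card",
    "render_template",
    "invert_camera",
    "write_image",
    "read_image",
    "write_truth",
    "read_truth",
]

#: Buffer pH levels of the reference acquisition protocol.
PH_LEVELS = (3.00, 4.00, 4.50, 4.75, 5.00, 5.25, 5.50, 5.75, 6.00, 6.25, 6.50)

#: Hue (degrees) at the acid end (pH 3.00) and alkaline end (pH 6.50) of the
#: operating range.  Blue at low pH descending monotonically toward red; the
#: red end sits a few degrees above zero so that hue never wraps through
#: 0/360 inside the operating range.
HUE_RANGE_DEG = (240.0, 5.0)

_PH_RANGE = (3.00, 6.50)


def hue_from_ph(ph: float | np.ndarray) -> float | np.ndarray:
    """Monotone (piecewise-linear, here single-piece) pH -> hue map in degrees."""
    ph = np.asarray(ph, dtype=float)
    lo, hi = _PH_RANGE
    h0, h1 = HUE_RANGE_DEG
    out = h0 + (h1 - h0) * (ph - lo) / (hi - lo)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CameraSimConfig:
    """Parameters of the simulated camera and render geometry."""

    gamma_rgb: tuple[float, float, float] = (2.2, 2.2, 2.2)
    vignette_strength: float = 0.0
    mix_matrix: np.ndarray | None = None  # None -> identity
    noise_sd: float = 0.0
    seed: int = 0
    size: tuple[int, int] = (512, 512)

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.gamma_rgb):
            raise ValueError("gamma exponents must be positive")
        if not 0.0 <= self.vignette_strength < 1.0:
            raise ValueError("vignette_strength must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.mix_matrix is not None:
            m = np.asarray(self.mix_matrix, dtype=float)
            if m.shape != (3, 3) or abs(np.linalg.det(m)) < 1e-12:
                raise ValueError("mix_matrix must be a nonsingular 3x3 matrix")
            object.__setattr__(self, "mix_matrix", m)

    @property
    def mix(self) -> np.ndarray:
        return np.eye(3) if self.mix_matrix is None else self.mix_matrix


@dataclass
class SceneTruth:
    """Complete ground truth accompanying a render."""

    roi_mask: np.ndarray | None = None
    quad: np.ndarray | None = None  # 4 x [row, col], top-left then clockwise
    true_hue_deg: float | None = None
    true_ph: float | None = None
    chart_xyz: np.ndarray | None = None
    patch_boxes: list[tuple[int, int, int, int]] | None = None  # r0, r1, c0, c1
    grey_indices: np.ndarray | None = None
    grey_luminance: np.ndarray | None = None
    patch_reflectance: np.ndarray | None = None
    scene_linear: np.ndarray | None = None  # pre-camera linear-light scene


# ---------------------------------------------------------------------------
# Forward camera model
# ---------------------------------------------------------------------------

def vignette_field(shape: tuple[int, int], strength: float) -> np.ndarray:
    """Radial falloff field, 1 at the centre and 1-strength at the corners."""
    h, w = shape
    rows = np.arange(h) - (h - 1) / 2.0
    cols = np.arange(w) - (w - 1) / 2.0
    r2 = rows[:, None] ** 2 + cols[None, :] ** 2
    return 1.0 - strength * r2 / r2.max() if r2.max() > 0 else np.ones(shape)


def apply_camera(scene_linear: np.ndarray, config: CameraSimConfig, rng: np.random.Generator | None) -> np.ndarray:
    """Render a linear-light scene through the forward camera model."""
    mixed = np.clip(scene_linear @ config.mix.T, 0.0, None)
    gam = np.asarray(config.gamma_rgb, dtype=float)
    encoded = mixed ** (1.0 / gam)
    encoded *= vignette_field(scene_linear.shape[:2], config.vignette_strength)[:, :, None]
    if config.noise_sd > 0 and rng is not None:
        encoded = encoded + rng.normal(0.0, config.noise_sd, encoded.shape)
    return np.clip(encoded, 0.0, 1.0)


def invert_camera(image: np.ndarray, config: CameraSimConfig) -> np.ndarray:
    """Undo the forward model with the true parameters (noise excepted)."""
    v = vignette_field(image.shape[:2], config.vignette_strength)[:, :, None]
    gam = np.asarray(config.gamma_rgb, dtype=float)
    linear = np.clip(image / v, 0.0, None) ** gam
    return linear @ np.linalg.inv(config.mix).T


def _rng(config: CameraSimConfig, *salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed,) + salt))


# ---------------------------------------------------------------------------
# Colour chart and grey card
# ---------------------------------------------------------------------------

# Relative luminances of the six-step neutral ramp (brightest first), matching
# a typical 24-patch chart's neutral wedge.
GREY_LUMINANCE = np.array([0.90, 0.591, 0.362, 0.198, 0.090, 0.031])

# Linear-light reflectances of the 18 chromatic patches (rows of linear RGB).
_CHROMA_REFLECTANCE = np.array(
    [
        [0.43, 0.26, 0.21], [0.70, 0.53, 0.41], [0.26, 0.35, 0.57],
        [0.22, 0.38, 0.14], [0.44, 0.40, 0.64], [0.31, 0.75, 0.62],
        [0.81, 0.38, 0.07], [0.17, 0.22, 0.64], [0.72, 0.22, 0.25],
        [0.26, 0.11, 0.36], [0.62, 0.73, 0.11], [0.88, 0.58, 0.09],
        [0.09, 0.13, 0.52], [0.15, 0.53, 0.14], [0.67, 0.11, 0.10],
        [0.93, 0.80, 0.05], [0.70, 0.19, 0.55], [0.07, 0.50, 0.64],
    ]
)


def chart_reflectance(n_patches: int = 24) -> tuple[np.ndarray, np.ndarray]:
    """Patch reflectances and the indices of the neutral (grey) patches.

    The last six patches are always the neutral ramp; chromatic patches fill
    the rest (cycling through a fixed palette beyond 24).
    """
    if n_patches < 6:
        raise ValueError("a chart needs at least the six-step neutral ramp")
    n_chroma = n_patches - 6
    reps = int(np.ceil(n_chroma / len(_CHROMA_REFLECTANCE))) if n_chroma else 0
    chroma = np.tile(_CHROMA_REFLECTANCE, (max(reps, 1), 1))[:n_chroma]
    grey = np.repeat(GREY_LUMINANCE[:, None], 3, axis=1)
    refl = np.vstack([chroma, grey]) if n_chroma else grey
    grey_idx = np.arange(n_chroma, n_patches)
    return refl, grey_idx


def _chart_layout(n_patches: int, shape: tuple[int, int]) -> list[tuple[int, int, int, int]]:
    n_cols = 6 if n_patches % 6 == 0 else int(np.ceil(np.sqrt(n_patches)))
    n_rows = int(np.ceil(n_patches / n_cols))
    h, w = shape
    margin = 0.06
    cell_h = (1 - 2 * margin) / n_rows
    cell_w = (1 - 2 * margin) / n_cols
    gap = 0.15  # fraction of a cell left between patches
    boxes = []
    for i in range(n_patches):
        r, c = divmod(i, n_cols)
        top = margin + r * cell_h + gap / 2 * cell_h
        left = margin + c * cell_w + gap / 2 * cell_w
        boxes.append(
            (
                int(round(top * h)),
                int(round((top + (1 - gap) * cell_h) * h)),
                int(round(left * w)),
                int(round((left + (1 - gap) * cell_w) * w)),
            )
        )
    return boxes


def render_chart(config: CameraSimConfig, n_patches: int = 24) -> tuple[np.ndarray, SceneTruth]:
    """Render the reference colour chart through the simulated camera.

    Returns the encoded image and ground truth holding the noiseless
    reference XYZ of every patch, exact patch pixel boxes, and the neutral
    ramp's indices and luminances (needed for gamma estimation).
    """
    refl, grey_idx = chart_reflectance(n_patches)
    boxes = _chart_layout(n_patches, config.size)
    scene = np.full(config.size + (3,), 0.22)
    for (r0, r1, c0, c1), rho in zip(boxes, refl):
        scene[r0:r1, c0:c1] = rho
    image = apply_camera(scene, config, _rng(config, 1))
    truth = SceneTruth(
        chart_xyz=linear_rgb_to_xyz(refl),
        patch_boxes=boxes,
        grey_indices=grey_idx,
        grey_luminance=GREY_LUMINANCE.copy(),
        patch_reflectance=refl,
        scene_linear=scene,
    )
    return image, truth


def render_grey_card(config: CameraSimConfig, reflectance: float = 0.18) -> np.ndarray:
    """Uniform 18%-grey card: the only spatial structure is vignetting + noise."""
    scene = np.full(config.size + (3,), reflectance)
    return apply_camera(scene, config, _rng(config, 2))


# ---------------------------------------------------------------------------
# QR-like fiducial and sensor scene
# ---------------------------------------------------------------------------

_N_MODULES = 25  # module grid of the fiducial
_QUIET = 2  # quiet-zone border, in modules
_CENTRE_MODULES = 9  # reserved black central space
_HOLO_RADIUS_MODULES = 3.4  # hologram circle radius

_BLACK, _WHITE = 0.04, 0.92


def fiducial_matrix() -> np.ndarray:
    """Deterministic binary module matrix with three finder squares and a
    reserved black central space (payload encoding is out of scope)."""
    n = _N_MODULES
    m = np.ones((n, n), dtype=int)
    bits = np.random.default_rng(20170903).integers(0, 2, size=(n, n))
    m[:, :] = bits
    for r0, c0 in [(0, 0), (0, n - 7), (n - 7, 0)]:  # finder patterns
        m[r0 : r0 + 7, c0 : c0 + 7] = 0
        m[r0 + 1 : r0 + 6, c0 + 1 : c0 + 6] = 1
        m[r0 + 2 : r0 + 5, c0 + 2 : c0 + 5] = 0
        if r0 == 0:
            m[7, c0 : c0 + 7] = 1
        else:
            m[r0 - 1, 0:7] = 1
        m[r0 : r0 + 7, 7 if c0 == 0 else c0 - 1] = 1
    c = (n - _CENTRE_MODULES) // 2
    m[c : c + _CENTRE_MODULES, c : c + _CENTRE_MODULES] = 0
    return m


def _fiducial_patch(module_px: int, hologram_rgb: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Canonical linear-light fiducial patch plus hologram mask."""
    m = fiducial_matrix()
    grid = np.pad(m, _QUIET, constant_values=1)
    patch = np.where(np.kron(grid, np.ones((module_px, module_px)))[:, :, None] > 0, _WHITE, _BLACK)
    patch = np.repeat(patch, 3, axis=2) if patch.shape[2] == 1 else patch
    side = patch.shape[0]
    mask = np.zeros(patch.shape[:2], dtype=bool)
    if hologram_rgb is not None:
        centre = (side - 1) / 2.0
        rr, cc = _disk((centre, centre), _HOLO_RADIUS_MODULES * module_px, shape=patch.shape[:2])
        patch[rr, cc] = hologram_rgb
        mask[rr, cc] = True
    return patch, mask


def render_template(module_px: int = 12) -> np.ndarray:
    """Ideal (pre-camera) image of the fiducial used for template matching."""
    patch, _ = _fiducial_patch(module_px, None)
    return np.clip(patch, 0.0, 1.0)


def _hsv_rgb(h_deg: float, s: float, v: float) -> np.ndarray:
    return np.array(colorsys.hsv_to_rgb((h_deg % 360.0) / 360.0, s, v))


def render_scene(
    config: CameraSimConfig,
    ph: float,
    clutter_level: float,
    hue_offset_deg: float = 0.0,
) -> tuple[np.ndarray, SceneTruth]:
    """Render a cluttered scene with the fiducial-embedded sensor.

    The hologram hue encodes ``ph`` through :func:`hue_from_ph` (plus an
    optional per-sensor offset emulating batch-to-batch variation).
    ``clutter_level`` in [0, 1] scales the number and strength of background
    distractors, specular highlights and shadow gradients; at levels >= 0.6
    one distractor is deliberately given a hue within 20 degrees of the ROI
    hue as a hard negative.
    """
    if not _PH_RANGE[0] <= ph <= _PH_RANGE[1]:
        raise ValueError(f"ph must lie in [{_PH_RANGE[0]}, {_PH_RANGE[1]}]")
    if not 0.0 <= clutter_level <= 1.0:
        raise ValueError("clutter_level must lie in [0, 1]")

    h, w = config.size
    rng = _rng(config, 3, int(round(ph * 100)), int(round(clutter_level * 100)))

    # --- background: gentle two-point gradient of a desaturated colour
    base_a = _hsv_rgb(rng.uniform(0, 360), 0.12, 0.50)
    base_b = base_a * rng.uniform(0.65, 0.9)
    t = np.linspace(0.0, 1.0, h)[:, None, None]
    scene = base_a[None, None, :] * (1 - t) + base_b[None, None, :] * t
    scene = np.broadcast_to(scene, (h, w, 3)).copy()

    # --- distractor objects
    hue = (hue_from_ph(ph) + hue_offset_deg) % 360.0
    n_obj = int(round(clutter_level * 8))
    for i in range(max(n_obj - 1, 0) if clutter_level >= 0.6 else n_obj):
        colour = _hsv_rgb(rng.uniform(0, 360), rng.uniform(0.5, 0.9), rng.uniform(0.3, 0.7))
        cy, cx = rng.uniform(0.08, 0.92, 2) * (h, w)
        radius = rng.uniform(0.03, 0.08) * min(h, w)
        if rng.random() < 0.5:
            rr, cc = _disk((cy, cx), radius, shape=(h, w))
            scene[rr, cc] = colour
        else:
            r0, c0 = int(max(cy - radius, 0)), int(max(cx - radius, 0))
            scene[r0 : int(cy + radius), c0 : int(cx + radius)] = colour
    if clutter_level >= 0.6:
        # hard negative: a distractor sharing the ROI's hue window, drawn last
        # and placed in a corner the fiducial cannot reach
        colour = _hsv_rgb((hue + rng.uniform(-12, 12)) % 360.0, rng.uniform(0.7, 0.9), rng.uniform(0.5, 0.7))
        corner = rng.integers(0, 4)
        cy = (0.1 if corner < 2 else 0.9) * h + rng.uniform(-0.03, 0.03) * h
        cx = (0.1 if corner % 2 == 0 else 0.9) * w + rng.uniform(-0.03, 0.03) * w
        rr, cc = _disk((cy, cx), rng.uniform(0.06, 0.09) * min(h, w), shape=(h, w))
        scene[rr, cc] = colour

    # --- shadow gradient and specular highlights
    if clutter_level > 0:
        direction = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        ramp = (np.cos(direction) * yy / h + np.sin(direction) * xx / w + 1) / 2
        scene *= (1.0 - 0.35 * clutter_level * ramp)[:, :, None]

    # --- fiducial with the hologram, pasted on top
    module_px = 12
    holo_rgb = _hsv_rgb(hue, 0.88, 0.78)
    patch, holo_mask = _fiducial_patch(module_px, holo_rgb)
    side = patch.shape[0]
    scale = rng.uniform(0.75, 0.95) * 0.52 * min(h, w) / side
    angle = np.radians(rng.uniform(-30, 30))
    shift = rng.uniform(-0.06, 0.06, 2) * min(h, w)
    tf = SimilarityTransform(translation=(-side / 2, -side / 2))
    tf = tf + SimilarityTransform(scale=scale, rotation=angle)
    tf = tf + SimilarityTransform(translation=(w / 2 + shift[1], h / 2 + shift[0]))

    warped = warp(patch, tf.inverse, output_shape=(h, w), order=1, cval=0.0)
    alpha = warp(np.ones((side, side)), tf.inverse, output_shape=(h, w), order=1, cval=0.0)
    scene = alpha[:, :, None] * warped + (1 - alpha[:, :, None]) * scene
    roi_mask = warp(holo_mask.astype(float), tf.inverse, output_shape=(h, w), order=0) > 0.5

    # highlights go on last but never on the hologram itself
    n_spot = int(round(clutter_level * 3))
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_spot):
        for _attempt in range(20):
            cy, cx = rng.uniform(0.1, 0.9, 2) * (h, w)
            sigma = rng.uniform(0.02, 0.05) * min(h, w)
            if not roi_mask[int(cy), int(cx)]:
                break
        blob = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
        blob[roi_mask] = 0.0
        scene += 0.5 * clutter_level * blob[:, :, None]

    scene = np.clip(scene, 0.0, 1.0)
    corners_xy = np.array([[0, 0], [side - 1, 0], [side - 1, side - 1], [0, side - 1]], dtype=float)
    quad = tf(corners_xy)[:, ::-1]  # (x, y) -> (row, col)

    image = apply_camera(scene, config, rng)
    truth = SceneTruth(
        roi_mask=roi_mask,
        quad=quad,
        true_hue_deg=hue,
        true_ph=float(ph),
        scene_linear=scene,
    )
    return image, truth


# ---------------------------------------------------------------------------
# File I/O: 8-bit PNG plus JSON truth sidecar
# ---------------------------------------------------------------------------

def write_image(path, image: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(str(path), (np.clip(image, 0, 1) * 255).round().astype(np.uint8))


def read_image(path) -> np.ndarray:
    import imageio.v3 as iio

    arr = iio.imread(str(path))
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    return arr[:, :, :3].astype(float) / 255.0


def _mask_to_rle(mask: np.ndarray) -> list[int]:
    flat = np.asarray(mask, dtype=bool).ravel()
    runs: list[int] = []
    val, count = False, 0
    for px in flat:
        if px == val:
            count += 1
        else:
            runs.append(count)
            val, count = px, 1
    runs.append(count)
    return runs


def _rle_to_mask(runs: list[int], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, val = 0, False
    for run in runs:
        if val:
            flat[pos : pos + run] = True
        pos += run
        val = not val
    return flat.reshape(shape)


def write_truth(path, truth: SceneTruth, mask_shape: tuple[int, int] | None = None) -> None:
    """Serialise ground truth as JSON (mask run-length encoded, row-major,
    starting with the length of the leading False run; quad as 0-based
    [row, col] pairs, top-left then clockwise)."""
    doc: dict = {}
    if truth.roi_mask is not None:
        doc["roi_mask_rle"] = _mask_to_rle(truth.roi_mask)
        doc["mask_shape"] = list(truth.roi_mask.shape)
    if truth.quad is not None:
        doc["quad"] = np.asarray(truth.quad).tolist()
    if truth.true_hue_deg is not None:
        doc["true_hue_deg"] = truth.true_hue_deg
    if truth.true_ph is not None:
        doc["true_ph"] = truth.true_ph
    if truth.chart_xyz is not None:
        doc["chart_xyz"] = np.asarray(truth.chart_xyz).tolist()
    if truth.patch_boxes is not None:
        doc["patch_boxes"] = [list(b) for b in truth.patch_boxes]
    if truth.grey_indices is not None:
        doc["grey_indices"] = np.asarray(truth.grey_indices).tolist()
    if truth.grey_luminance is not None:
        doc["grey_luminance"] = np.asarray(truth.grey_luminance).tolist()
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_truth(path) -> SceneTruth:
    with open(path) as fh:
        doc = json.load(fh)
    truth = SceneTruth()
    if "roi_mask_rle" in doc:
        truth.roi_mask = _rle_to_mask(doc["roi_mask_rle"], tuple(doc["mask_shape"]))
    if "quad" in doc:
        truth.quad = np.asarray(doc["quad"], dtype=float)
    truth.true_hue_deg = doc.get("true_hue_deg")
    truth.true_ph = doc.get("true_ph")
    if "chart_xyz" in doc:
        truth.chart_xyz = np.asarray(doc["chart_xyz"], dtype=float)
    if "patch_boxes" in doc:
        truth.patch_boxes = [tuple(b) for b in doc["patch_boxes"]]
    if "grey_indices" in doc:
        truth.grey_indices = np.asarray(doc["grey_indices"], dtype=int)
    if "grey_luminance" in doc:
        truth.grey_luminance = np.asarray(doc["grey_luminance"], dtype=float)
    return truth
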