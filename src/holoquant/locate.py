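"""Fiducial localisation by local-feature template matching.

Finds the QR-like target (and hence the embedded sensor) in a cluttered
scene: scale/rotation-covariant keypoints are detected on greyscale versions
of template and scene, descriptors are matched with a nearest-neighbour
ratio test, and a RANSAC homography maps the template corners into the
scene.  The detector is pluggable behind a small interface; the default is
ORB (an unencumbered detector with the same contract as SURF-style
detectors: repeatable under in-plane rotation and scaling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import ORB, match_descriptors
from skimage.measure import ransac
from skimage.transform import ProjectiveTransform, warp

__all__ = [
    "Detection",
    "NoDetectionError",
    "detect_features",
    "match_template",
    "extract_roi_patch",
    "to_grey",
]

# ITU-R 601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])

DEFAULT_MIN_INLIERS = 12
DEFAULT_RESIDUAL_PX = 3.0


class NoDetectionError(RuntimeError):
    """Raised when the fiducial cannot be located (signal: re-capture)."""


@dataclass
class Detection:
    quad: np.ndarray  # 4 x [row, col], template corners projected into scene
    n_matched: int  # geometrically consistent feature pairs (inliers)
    inlier_ratio: float
    transform: ProjectiveTransform  # template (x, y) -> scene (x, y)
    template_shape: tuple[int, int]


def to_grey(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    return image[:, :, :3] @ _LUMA


@dataclass
class FeatureSet:
    keypoints: np.ndarray  # n x [row, col]
    descriptors: np.ndarray  # n x d (binary for ORB)


def detect_features(image: np.ndarray, n_strongest: int = 100, seed: int = 0) -> FeatureSet:
    """Detect up to ``n_strongest`` keypoints with descriptors on a greyscale
    image (colour input is converted with 601 luma weights)."""
    grey = to_grey(image)
    if grey.shape[0] < 64 or grey.shape[1] < 64:
        raise ValueError("image must be at least 64 x 64 for feature detection")
    if np.ptp(grey) == 0:
        return FeatureSet(np.empty((0, 2)), np.empty((0, 256), dtype=bool))
    orb = ORB(n_keypoints=n_strongest, fast_threshold=0.05)
    try:
        orb.detect_and_extract(grey)
    except RuntimeError:  # no interest points found
        return FeatureSet(np.empty((0, 2)), np.empty((0, 256), dtype=bool))
    return FeatureSet(orb.keypoints, orb.descriptors)


def match_template(
    scene: np.ndarray,
    template: np.ndarray,
    n_strongest: int = 800,
    min_inliers: int = DEFAULT_MIN_INLIERS,
    lowe_ratio: float | None = None,
    residual_px: float = DEFAULT_RESIDUAL_PX,
    seed: int = 0,
) -> Detection:
    """Locate the template in the scene and return its projected corners.

    Putative correspondences use mutual-nearest-neighbour (cross-checked)
    Hamming matching; a Lowe ratio test is available through ``lowe_ratio``
    but disabled by default — with binary descriptors on a self-similar
    target the first and second neighbours are often near-equidistant, so the
    ratio test starves RANSAC of the correct matches it can easily sort out.
    If the first attempt falls short of ``min_inliers`` the matcher retries
    once with twice as many keypoints before raising
    :class:`NoDetectionError`.
    """
    for factor in (1, 2):
        try:
            return _match_once(scene, template, n_strongest * factor, min_inliers,
                               lowe_ratio, residual_px, seed)
        except NoDetectionError as exc:
            last_err = exc
    raise last_err


def _match_once(scene, template, n_strongest, min_inliers, lowe_ratio, residual_px, seed) -> Detection:
    feats_t = detect_features(template, n_strongest, seed)
    feats_s = detect_features(scene, n_strongest, seed)
    if len(feats_t.keypoints) < 4 or len(feats_s.keypoints) < 4:
        raise NoDetectionError("not enough features to attempt a match")
    kwargs = {"max_ratio": lowe_ratio} if lowe_ratio is not None else {}
    matches = match_descriptors(
        feats_t.descriptors, feats_s.descriptors, metric="hamming",
        cross_check=True, **kwargs,
    )
    if len(matches) < max(4, min_inliers):
        raise NoDetectionError(f"only {len(matches)} putative matches; sensor not found, re-capture")
    # transform estimation works in (x, y) = (col, row) coordinates
    src = feats_t.keypoints[matches[:, 0]][:, ::-1]
    dst = feats_s.keypoints[matches[:, 1]][:, ::-1]
    model, inliers = ransac(
        (src, dst), ProjectiveTransform, min_samples=4,
        residual_threshold=residual_px, max_trials=2000, rng=seed,
    )
    n_in = int(inliers.sum()) if inliers is not None else 0
    if model is None or n_in < min_inliers:
        raise NoDetectionError(f"{n_in} consistent matches < {min_inliers}; sensor not found, re-capture")
    h, w = to_grey(template).shape
    corners_xy = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], dtype=float)
    quad_xy = model(corners_xy)
    quad = quad_xy[:, ::-1]
    # refit on the inliers only for a cleaner corner estimate
    refit = ProjectiveTransform.from_estimate(src[inliers], dst[inliers])
    if refit:
        model = refit
        quad_xy = model(corners_xy)
        quad = quad_xy[:, ::-1]
    if not _is_convex(quad_xy):
        raise NoDetectionError("estimated quad is degenerate; sensor not found, re-capture")
    return Detection(
        quad=quad,
        n_matched=n_in,
        inlier_ratio=n_in / len(matches),
        transform=model,
        template_shape=(h, w),
    )


def _is_convex(quad_xy: np.ndarray) -> bool:
    crosses = []
    for i in range(4):
        a, b, c = quad_xy[i], quad_xy[(i + 1) % 4], quad_xy[(i + 2) % 4]
        u, v = b - a, c - b
        crosses.append(u[0] * v[1] - u[1] * v[0])
    crosses = np.asarray(crosses)
    return bool(np.all(crosses > 0) or np.all(crosses < 0))


def extract_roi_patch(
    scene: np.ndarray,
    det: Detection,
    layout: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Rectify the detected quad and return its central ``layout`` fraction.

    Returns the extracted patch (square, side = layout x template side) and a
    boolean mask of that central window in scene coordinates.  When the
    detection is an axis-aligned integer translation the patch is a direct
    pixel crop (bit-exact); otherwise the quad is resampled through the
    inverse homography.
    """
    if not 0.0 < layout <= 1.0:
        raise ValueError("layout fraction must lie in (0, 1]")
    h, w = det.template_shape
    params = det.transform.params
    if not np.all(np.isfinite(params)) or abs(np.linalg.det(params)) < 1e-12:
        raise FloatingPointError("degenerate homography")

    lo_r, hi_r = int(round(h * (1 - layout) / 2)), int(round(h * (1 + layout) / 2))
    lo_c, hi_c = int(round(w * (1 - layout) / 2)), int(round(w * (1 + layout) / 2))

    scene = np.asarray(scene, dtype=float)
    if _is_integer_translation(params):
        dc, dr = int(round(params[0, 2])), int(round(params[1, 2]))
        patch = scene[dr + lo_r : dr + hi_r, dc + lo_c : dc + hi_c].copy()
        mask = np.zeros(scene.shape[:2], dtype=bool)
        mask[dr + lo_r : dr + hi_r, dc + lo_c : dc + hi_c] = True
        return patch, mask

    rectified = warp(scene, det.transform, output_shape=(h, w), order=1, cval=0.0)
    patch = rectified[lo_r:hi_r, lo_c:hi_c].copy()
    # forward-map the central window outline into scene coordinates
    from skimage.draw import polygon

    win_xy = np.array(
        [[lo_c, lo_r], [hi_c - 1, lo_r], [hi_c - 1, hi_r - 1], [lo_c, hi_r - 1]], dtype=float
    )
    scene_xy = det.transform(win_xy)
    rr, cc = polygon(scene_xy[:, 1], scene_xy[:, 0], shape=scene.shape[:2])
    mask = np.zeros(scene.shape[:2], dtype=bool)
    mask[rr, cc] = True
    return patch, mask


def _is_integer_translation(params: np.ndarray, tol: float = 1e-9) -> bool:
    ident = np.eye(3)
    delta = params / params[2, 2] - ident
    if abs(delta[0, 0]) > tol or abs(delta[1, 1]) > tol:
        return False
    off_diag = np.array([delta[0, 1], delta[1, 0], delta[2, 0], delta[2, 1]])
    if np.any(np.abs(off_diag) > tol):
        return False
    tr = params[:2, 2] / params[2, 2]
    return bool(np.all(np.abs(tr - np.round(tr)) < tol))
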