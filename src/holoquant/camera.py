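"""Camera characterisation: gamma linearisation, flat-field correction and
polynomial regression from linearised RGB to CIEXYZ.

The characterisation chain estimated from a colour chart and a uniform grey
card is applied to later images in the order

    flat-field normalise -> gamma linearise -> polynomial RGB->XYZ

The flat-field gain is estimated on, and applied to, the encoded (pre-
linearisation) values: the radial falloff multiplies the encoded signal, so
dividing it out there removes the non-uniformity exactly, after which the
per-channel power law can be estimated from the neutral ramp without spatial
bias.  The per-channel exponents are fitted in the log-log domain with a free
scale (exposure) term, ``value = A * luminance^(1/gamma)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .color import delta_e_ab, xyz_to_lab

__all__ = [
    "GammaFit",
    "FlatField",
    "PolyCameraModel",
    "TERM_PRESETS",
    "estimate_gamma",
    "fit_flat_field",
    "build_term_vector",
    "fit_poly_model",
    "select_model",
    "apply_camera_model",
    "patch_means",
    "CameraCharacterizer",
]


# ---------------------------------------------------------------------------
# Polynomial term presets (exponent triples (p, q, r) for R^p G^q B^r)
# ---------------------------------------------------------------------------

def _monomials_upto(degree: int) -> tuple[tuple[int, int, int], ...]:
    terms = []
    for d in range(degree + 1):
        for p in range(d, -1, -1):
            for q in range(d - p, -1, -1):
                terms.append((p, q, d - p - q))
    return tuple(terms)


#: Named augmented-RGB term sets.  Term sets are data: any iterable of
#: exponent triples may be passed wherever a preset name is accepted, so the
#: larger sets from the camera-characterisation literature can be supplied
#: directly as configuration.
TERM_PRESETS: dict[str, tuple[tuple[int, int, int], ...]] = {
    "linear3": ((1, 0, 0), (0, 1, 0), (0, 0, 1)),
    "poly5": ((1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1), (0, 0, 0)),
    "poly8": (
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, 0, 1), (0, 1, 1),
        (1, 1, 1), (0, 0, 0),
    ),
    "poly11": (
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, 0, 1), (0, 1, 1),
        (2, 0, 0), (0, 2, 0), (0, 0, 2),
        (1, 1, 1), (0, 0, 0),
    ),
    # the complete degree<=3 monomial basis (20 terms, constant included)
    "poly20": _monomials_upto(3),
}


def resolve_term_set(term_set) -> tuple[tuple[int, int, int], ...]:
    if isinstance(term_set, str):
        try:
            return TERM_PRESETS[term_set]
        except KeyError:
            raise ValueError(f"unknown term preset {term_set!r}; have {sorted(TERM_PRESETS)}") from None
    terms = tuple(tuple(int(e) for e in t) for t in term_set)
    if not terms:
        raise ValueError("term_set must be nonempty")
    return terms


# ---------------------------------------------------------------------------
# Gamma estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaFit:
    gamma_rgb: np.ndarray  # three positive exponents
    scale_rgb: np.ndarray  # fitted per-channel exposure scale A
    fit_residual: float  # RMS residual of the log-domain fit

    def linearise(self, values: np.ndarray) -> np.ndarray:
        """Apply value^gamma per channel (scale removed first)."""
        v = np.clip(np.asarray(values, dtype=float) / self.scale_rgb, 0.0, None)
        return v**self.gamma_rgb


def estimate_gamma(grey_rgb: np.ndarray, grey_luminance: np.ndarray) -> GammaFit:
    """Fit per-channel power laws from the neutral-ramp patches.

    Least squares in the log-log domain of ``value = A * luminance^(1/gamma)``
    per channel; linearisation later applies ``(value/A)^gamma``.

    Parameters
    ----------
    grey_rgb : (n, 3) array
        Mean encoded RGB of the neutral patches, values in (0, 1].
    grey_luminance : (n,) array
        Reference relative luminance of each patch, in (0, 1].
    """
    grey_rgb = np.asarray(grey_rgb, dtype=float)
    lum = np.asarray(grey_luminance, dtype=float)
    if grey_rgb.ndim != 2 or grey_rgb.shape[1] != 3 or grey_rgb.shape[0] != lum.shape[0]:
        raise ValueError("grey_rgb must be (n, 3) with matching luminances")
    ok = (lum > 0) & np.all(grey_rgb > 0, axis=1)
    if np.unique(lum[ok]).size < 3:
        raise ValueError("need at least 3 neutral patches with distinct nonzero luminances")
    x = np.log(lum[ok])
    design = np.column_stack([x, np.ones_like(x)])
    gammas, scales, sq = [], [], 0.0
    for ch in range(3):
        y = np.log(grey_rgb[ok, ch])
        (slope, intercept), res, *_ = np.linalg.lstsq(design, y, rcond=None)
        if slope <= 0:
            raise ValueError("non-monotone neutral ramp: cannot estimate a positive exponent")
        gammas.append(1.0 / slope)
        scales.append(np.exp(intercept))
        sq += float(res[0]) if res.size else float(np.sum((design @ [slope, intercept] - y) ** 2))
    residual = float(np.sqrt(sq / (3 * ok.sum())))
    return GammaFit(np.array(gammas), np.array(scales), residual)


# ---------------------------------------------------------------------------
# Flat field
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlatField:
    gain_map: np.ndarray  # (H, W, 3) multiplicative correction
    calibration_constants: np.ndarray  # the three channel means of the card

    def apply(self, image: np.ndarray) -> np.ndarray:
        if image.shape != self.gain_map.shape:
            raise ValueError("image shape does not match the flat-field gain map")
        return image * self.gain_map


def fit_flat_field(grey_card: np.ndarray, surface_degree: int = 4) -> FlatField:
    """Estimate a multiplicative gain map from a uniform grey-card image.

    A low-order 2-D polynomial surface is least-squares fitted to each channel
    of the card — a global fit smooths out shot noise without the boundary
    bias a convolution filter would leave on a curved falloff field — and
    ``gain(x, y, ch) = mean_ch / surface(x, y, ch)``.  The three channel means
    are kept as the calibration constants.
    """
    card = np.asarray(grey_card, dtype=float)
    if card.ndim != 3 or card.shape[2] != 3:
        raise ValueError("grey card must be an H x W x 3 image")
    h, w = card.shape[:2]
    yy = np.linspace(-1.0, 1.0, h)
    xx = np.linspace(-1.0, 1.0, w)
    terms = [(i, j) for i in range(surface_degree + 1) for j in range(surface_degree + 1 - i)]
    design = np.stack([np.outer(yy**i, xx**j).ravel() for i, j in terms], axis=1)
    coeffs, *_ = np.linalg.lstsq(design, card.reshape(-1, 3), rcond=None)
    smoothed = (design @ coeffs).reshape(card.shape)
    if np.any(smoothed <= 0):
        raise FloatingPointError("grey card contains zero signal after surface fitting")
    means = card.mean(axis=(0, 1))
    return FlatField(gain_map=means / smoothed, calibration_constants=means)


# ---------------------------------------------------------------------------
# Polynomial model
# ---------------------------------------------------------------------------

def build_term_vector(rgb: np.ndarray, term_set) -> np.ndarray:
    """Augmented vector(s) with element i = R^p G^q B^r for term_set[i]."""
    terms = resolve_term_set(term_set)
    rgb = np.asarray(rgb, dtype=float)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    cols = [r**p * g**q * b**s for (p, q, s) in terms]
    return np.stack(cols, axis=-1)


@dataclass(frozen=True)
class PolyCameraModel:
    term_set: tuple[tuple[int, int, int], ...]
    coeffs: np.ndarray  # 3 x n_terms, rows map augmented vector to X, Y, Z
    median_dE: float

    @property
    def n_terms(self) -> int:
        return len(self.term_set)

    def predict(self, rgb_linear: np.ndarray) -> np.ndarray:
        return build_term_vector(rgb_linear, self.term_set) @ self.coeffs.T


def fit_poly_model(patch_rgb: np.ndarray, patch_xyz: np.ndarray, term_set) -> PolyCameraModel:
    """Least-squares polynomial mapping from linearised patch RGB to XYZ.

    The model's figure of merit is the median CIE76 colour difference between
    predicted and reference patch colours after conversion to L*a*b*.
    """
    terms = resolve_term_set(term_set)
    rgb = np.asarray(patch_rgb, dtype=float)
    xyz = np.asarray(patch_xyz, dtype=float)
    if rgb.ndim != 2 or rgb.shape[1] != 3 or rgb.shape != xyz.shape:
        raise ValueError("patch_rgb and patch_xyz must both be (n, 3)")
    if rgb.shape[0] < len(terms):
        raise ValueError(f"need at least {len(terms)} patches to fit {len(terms)} terms")
    design = build_term_vector(rgb, terms)
    rank = np.linalg.matrix_rank(design)
    if rank < len(terms):
        raise np.linalg.LinAlgError(
            f"rank-deficient design ({rank} < {len(terms)} terms): add patches with more "
            "distinct colours or choose a smaller term set"
        )
    coeffs, *_ = np.linalg.lstsq(design, xyz, rcond=None)
    pred = design @ coeffs
    dE = delta_e_ab(xyz_to_lab(pred), xyz_to_lab(xyz))
    return PolyCameraModel(term_set=terms, coeffs=coeffs.T, median_dE=float(np.median(dE)))


def select_model(candidates) -> PolyCameraModel:
    """Pick the candidate with the smallest median colour error; ties go to
    the model with fewer terms."""
    cands = list(candidates)
    if not cands:
        raise ValueError("no candidate models")
    return min(cands, key=lambda m: (m.median_dE, m.n_terms))


def apply_camera_model(
    image: np.ndarray,
    gamma: GammaFit,
    ff: FlatField | None,
    model: PolyCameraModel,
) -> np.ndarray:
    """Full correction chain for an encoded image: flat-field -> gamma
    linearise -> polynomial; returns the XYZ image (Y scale of the model's
    training references)."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    if ff is not None:
        img = ff.apply(img)
    linear = gamma.linearise(img)
    return model.predict(linear)


def patch_means(image: np.ndarray, boxes, centre_fraction: float = 0.5) -> np.ndarray:
    """Mean RGB per chart patch over the central ``centre_fraction`` of each
    patch cell (edge pixels are excluded to avoid bleed)."""
    out = []
    for r0, r1, c0, c1 in boxes:
        mr = (r1 - r0) * (1 - centre_fraction) / 2
        mc = (c1 - c0) * (1 - centre_fraction) / 2
        out.append(
            image[int(r0 + mr) : int(np.ceil(r1 - mr)), int(c0 + mc) : int(np.ceil(c1 - mc))].mean(axis=(0, 1))
        )
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------

class CameraCharacterizer:
    """Characterise a camera from a chart image (sklearn-style).

    Parameters
    ----------
    term_sets : sequence of preset names or exponent-triple lists
        Candidate polynomial term sets; the one with the smallest median
        colour error on the training patches is selected.
    surface_degree : int
        Degree of the 2-D polynomial surface for the flat-field estimate.
    centre_fraction : float
        Central fraction of each patch cell used for the mean RGB.

    Attributes (after :meth:`fit`)
    ------------------------------
    gamma_ : GammaFit
    flat_field_ : FlatField or None
    model_ : PolyCameraModel (the selected candidate)
    candidates_ : list of all fitted PolyCameraModel
    """

    def __init__(self, term_sets=("linear3", "poly5", "poly8", "poly11", "poly20"),
                 surface_degree: int = 4, centre_fraction: float = 0.5):
        self.term_sets = term_sets
        self.surface_degree = surface_degree
        self.centre_fraction = centre_fraction

    def get_params(self, deep: bool = True) -> dict:
        return {
            "term_sets": self.term_sets,
            "surface_degree": self.surface_degree,
            "centre_fraction": self.centre_fraction,
        }

    def set_params(self, **params) -> "CameraCharacterizer":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(
        self,
        chart_image: np.ndarray,
        patch_boxes,
        patch_xyz: np.ndarray,
        grey_indices: np.ndarray,
        grey_luminance: np.ndarray,
        grey_card: np.ndarray | None = None,
    ) -> "CameraCharacterizer":
        self.flat_field_ = fit_flat_field(grey_card, self.surface_degree) if grey_card is not None else None
        img = self.flat_field_.apply(chart_image) if self.flat_field_ is not None else np.asarray(chart_image, float)
        means = patch_means(img, patch_boxes, self.centre_fraction)
        self.gamma_ = estimate_gamma(means[np.asarray(grey_indices)], grey_luminance)
        linear = self.gamma_.linearise(means)
        self.candidates_ = [fit_poly_model(linear, patch_xyz, ts) for ts in self.term_sets]
        self.model_ = select_model(self.candidates_)
        return self

    def transform(self, image: np.ndarray) -> np.ndarray:
        """Encoded RGB image -> XYZ image through the fitted chain."""
        if not hasattr(self, "model_"):
            raise RuntimeError("CameraCharacterizer is not fitted")
        return apply_camera_model(image, self.gamma_, self.flat_field_, self.model_)

    def fit_transform(self, chart_image, patch_boxes, patch_xyz, grey_indices, grey_luminance, grey_card=None):
        return self.fit(chart_image, patch_boxes, patch_xyz, grey_indices, grey_luminance, grey_card).transform(chart_image)
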