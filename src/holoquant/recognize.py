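"""Colour-space separability scoring, segment descriptors and SOM-based
recognition of the sensor segment.

The separability of a labelled feature set is a Fisher-style scatter ratio:
with within-class scatter Sw (sum over classes of the member deviations
around the class mean) and between-class scatter Sb (size-weighted deviations
of class means around the grand mean), the default score is
``J = trace(Sw^-1 Sb)`` — large when classes are tight and far apart.  A
``literal_product`` variant computing ``trace(Sb Sw)`` is kept for
comparison, but it is not scale-invariant and is not the default.

The hologram segment is recognised by a self-organising map: a 10 x 10 grid
of codebook vectors is trained unsupervised on 9-dimensional hybrid colour
descriptors (mean R, G, B, H, S, I, L*, a*, b* per segment), then calibrated
by majority vote of the training labels mapped to each node; empty nodes
inherit the label of the nearest labelled node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .color import circular_mean_deg, rgb_to_hsi, xyz_to_lab

__all__ = [
    "SeparabilityReport",
    "ROIDescriptor",
    "separability",
    "extract_descriptor",
    "SOMClassifier",
    "NoROIError",
    "classify_segments",
]

DESCRIPTOR_NAMES = ("R", "G", "B", "H", "S", "I", "L", "a", "b")


class NoROIError(RuntimeError):
    """No segment recognised as the sensor (signal: re-capture)."""


@dataclass
class SeparabilityReport:
    J: float
    Sw: np.ndarray
    Sb: np.ndarray
    class_means: np.ndarray
    grand_mean: np.ndarray
    class_sizes: np.ndarray
    total: int
    n_classes: int


class SingularScatterError(np.linalg.LinAlgError):
    pass


def separability(features: np.ndarray, labels: np.ndarray, variant: str = "ratio") -> SeparabilityReport:
    """Fisher separability of labelled feature rows.

    variant='ratio' (default): J = trace(Sw^-1 Sb); variant='literal_product':
    J = trace(Sb Sw).  Raises :class:`SingularScatterError` (naming the
    collapsed class) when Sw is singular and the ratio form is requested.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be (n, d) with one label per row")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("separability needs at least two classes")
    d = X.shape[1]
    Sw = np.zeros((d, d))
    means, sizes = [], []
    for cls in classes:
        members = X[y == cls]
        mi = members.mean(axis=0)
        dev = members - mi
        Sw += dev.T @ dev
        means.append(mi)
        sizes.append(len(members))
    means = np.asarray(means)
    sizes = np.asarray(sizes)
    n = int(sizes.sum())
    grand = (sizes[:, None] * means).sum(axis=0) / n
    dev = means - grand
    Sb = (sizes[:, None, None] * (dev[:, :, None] * dev[:, None, :])).sum(axis=0)

    if variant == "literal_product":
        J = float(np.trace(Sb @ Sw))
    elif variant == "ratio":
        try:
            J = float(np.trace(np.linalg.solve(Sw, Sb)))
        except np.linalg.LinAlgError:
            collapsed = [str(c) for c, s in zip(classes, sizes) if s < 2]
            raise SingularScatterError(
                "within-class scatter is singular"
                + (f" (classes with <2 members: {', '.join(collapsed)})" if collapsed else "")
            ) from None
    else:
        raise ValueError("variant must be 'ratio' or 'literal_product'")
    return SeparabilityReport(J=J, Sw=Sw, Sb=Sb, class_means=means, grand_mean=grand,
                              class_sizes=sizes, total=n, n_classes=classes.size)


@dataclass
class ROIDescriptor:
    vector: np.ndarray  # (9,) mean R, G, B, H, S, I, L*, a*, b*
    segment_id: int
    pixel_count: int


def extract_descriptor(
    xyz_image: np.ndarray,
    rgb_image: np.ndarray,
    labels: np.ndarray,
    segment_id: int,
) -> ROIDescriptor:
    """9-dimensional hybrid colour descriptor of one segment.

    Means are per coordinate over the segment's pixels; hue is averaged on
    its circle; L*a*b* comes from the XYZ image, RGB and HSI from the RGB
    image.
    """
    mask = np.asarray(labels) == segment_id
    count = int(mask.sum())
    if count == 0:
        raise ValueError(f"segment {segment_id} is empty")
    rgb = np.asarray(rgb_image, dtype=float)[mask]
    xyz = np.asarray(xyz_image, dtype=float)[mask]
    hsi = rgb_to_hsi(rgb)
    lab = xyz_to_lab(xyz)
    hue = circular_mean_deg(hsi[:, 0], weights=hsi[:, 1] + 1e-12)
    vec = np.concatenate([
        rgb.mean(axis=0),
        [hue, hsi[:, 1].mean(), hsi[:, 2].mean()],
        lab.mean(axis=0),
    ])
    return ROIDescriptor(vector=vec, segment_id=int(segment_id), pixel_count=count)


# ---------------------------------------------------------------------------
# Self-organising map
# ---------------------------------------------------------------------------

class SOMClassifier:
    """Self-organising map with majority-vote node calibration.

    A ``grid_shape`` lattice of codebook vectors is trained by competitive
    learning with a Gaussian neighbourhood (radius and learning rate decay
    linearly over the epochs) on z-scored inputs; each node is then labelled
    by the majority class of the training samples it wins, and nodes that win
    nothing inherit the nearest labelled node's class.

    Attributes after ``fit``: ``codebook_`` (grid + vectors), ``node_labels_``,
    ``quantisation_errors_`` (one value per epoch), ``mean_``/``scale_``.
    """

    def __init__(self, grid_shape: tuple[int, int] = (10, 10), n_epochs: int = 500,
                 learning_rate: float = 0.5, radius: float = 5.0, seed: int = 0,
                 standardise: bool = True):
        self.grid_shape = grid_shape
        self.n_epochs = n_epochs
        self.learning_rate = learning_rate
        self.radius = radius
        self.seed = seed
        self.standardise = standardise

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("grid_shape", "n_epochs", "learning_rate", "radius", "seed", "standardise")}

    def set_params(self, **kw) -> "SOMClassifier":
        for k, v in kw.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- internals ---------------------------------------------------------
    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.standardise:
            return (X - self.mean_) / self.scale_
        return X

    def _winners(self, Z: np.ndarray) -> np.ndarray:
        d2 = ((Z[:, None, :] - self.codebook_[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SOMClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be (n, d) with one label per row")
        if not np.all(np.isfinite(X)):
            raise ValueError("descriptors contain non-finite values")
        import warnings

        if np.unique(y).size < 2:
            warnings.warn("single-class training data: every node gets that class", stacklevel=2)
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        self.scale_ = np.where(scale > 0, scale, 1.0)
        Z = self._transform(X)

        rows, cols = self.grid_shape
        n_nodes = rows * cols
        grid = np.stack(np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij"), axis=-1).reshape(-1, 2)
        rng = np.random.default_rng(self.seed)
        self.codebook_ = Z[rng.integers(0, len(Z), n_nodes)] + rng.normal(0, 1e-3, (n_nodes, Z.shape[1]))

        self.quantisation_errors_ = []
        for epoch in range(self.n_epochs):
            frac = epoch / max(self.n_epochs - 1, 1)
            lr = self.learning_rate * (1.0 - frac) + 0.01 * frac
            rad = max(self.radius * (1.0 - frac), 1.0)
            order = rng.permutation(len(Z))
            for i in order:
                z = Z[i]
                win = int(np.argmin(((self.codebook_ - z) ** 2).sum(axis=1)))
                g2 = ((grid - grid[win]) ** 2).sum(axis=1)
                h = np.exp(-g2 / (2 * rad**2))
                self.codebook_ += (lr * h)[:, None] * (z - self.codebook_)
            d2 = ((Z[:, None, :] - self.codebook_[None, :, :]) ** 2).sum(axis=2)
            self.quantisation_errors_.append(float(np.sqrt(d2.min(axis=1)).mean()))

        # calibration: majority label per node, nearest labelled node fills gaps
        winners = self._winners(Z)
        labels = np.empty(n_nodes, dtype=object)
        for node in range(n_nodes):
            hits = y[winners == node]
            if len(hits):
                vals, counts = np.unique(hits, return_counts=True)
                labels[node] = vals[np.argmax(counts)]
        filled = np.array([lab is not None for lab in labels])
        if not filled.any():
            raise RuntimeError("no node won any training sample")
        for node in np.flatnonzero(~filled):
            src = np.flatnonzero(filled)
            nearest = src[np.argmin(((grid[src] - grid[node]) ** 2).sum(axis=1))]
            labels[node] = labels[nearest]
        self.node_labels_ = labels
        self.grid_ = grid
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "codebook_"):
            raise RuntimeError("SOMClassifier is not fitted")
        Z = self._transform(X)
        return self.node_labels_[self._winners(Z)]


def classify_segments(model: SOMClassifier, descriptors: list[ROIDescriptor],
                      roi_label="hologram") -> tuple[np.ndarray, int]:
    """Label each segment descriptor and return (labels, ROI segment id).

    The ROI is the segment classified as ``roi_label``; if several qualify
    the one with the largest pixel count wins.  Raises :class:`NoROIError`
    when no segment carries the label.
    """
    X = np.stack([d.vector for d in descriptors])
    labels = model.predict(X)
    hits = [i for i, lab in enumerate(labels) if lab == roi_label]
    if not hits:
        raise NoROIError("no segment recognised as the sensor; re-capture")
    best = max(hits, key=lambda i: descriptors[i].pixel_count)
    return labels, descriptors[best].segment_id
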