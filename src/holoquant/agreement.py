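"""Method-agreement statistics: intraclass correlation and Bland-Altman.

The ICC here is the one-way random-effects form computed from the
between-target and within-target mean squares of an n-targets x k-methods
table::

    MS_B = 1/(n-1) * sum_x k (m_x - mu)^2
    MS_W = 1/(n(k-1)) * sum_x sum_j (x_j - m_x)^2
    ICC  = (MS_B - MS_W) / (MS_B + (k-1) MS_W)

where m_x is the mean of the methods on target x and mu the grand mean.  For
two segmentation methods quantifying the three colour coordinates of the
recognised sensor region, targets are the coordinates and methods the
algorithms.  Bland-Altman agreement reports the mean difference (bias) and
the bias +/- 1.96 sd limits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ICCResult", "BlandAltmanResult", "icc", "bland_altman", "compare_methods"]


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ms_between: float
    ms_within: float


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float


def icc(table: np.ndarray) -> ICCResult:
    """One-way random-effects intraclass correlation of an n x k table."""
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("agreement table must be n>=2 targets by k>=2 methods")
    if not np.all(np.isfinite(x)):
        raise ValueError("agreement table has missing cells")
    n, k = x.shape
    mx = x.mean(axis=1)
    mu = x.mean()
    ms_b = k * np.sum((mx - mu) ** 2) / (n - 1)
    ms_w = np.sum((x - mx[:, None]) ** 2) / (n * (k - 1))
    denom = ms_b + (k - 1) * ms_w
    if denom == 0:
        raise ZeroDivisionError("degenerate table: all cells equal")
    return ICCResult(icc=float((ms_b - ms_w) / denom), ms_between=float(ms_b), ms_within=float(ms_w))


def bland_altman(pairs: np.ndarray, multiplier: float = 1.96) -> BlandAltmanResult:
    """Bias and limits of agreement of paired measurements (n x 2).

    Differences are column 1 minus column 2; the limits are
    bias +/- multiplier * sd with the sample (n-1) standard deviation.
    """
    x = np.asarray(pairs, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2 or x.shape[0] < 2:
        raise ValueError("need an n x 2 array with n >= 2")
    d = x[:, 0] - x[:, 1]
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias=bias, loa_low=bias - multiplier * sd, loa_high=bias + multiplier * sd, sd_diff=sd)


def compare_methods(
    scene_tables: list[np.ndarray],
) -> tuple[float, list[ICCResult], list[BlandAltmanResult]]:
    """Agreement of two methods across a set of scenes.

    Each element of ``scene_tables`` is one scene's n-targets x 2-methods
    table (e.g. the three colour coordinates of the recognised region under
    each segmentation method).  Returns the scene-averaged ICC, the per-scene
    ICC results, and per-coordinate Bland-Altman results pooled over scenes.
    """
    if not scene_tables:
        raise ValueError("no scenes to compare")
    icc_results = [icc(t) for t in scene_tables]
    mean_icc = float(np.mean([r.icc for r in icc_results]))
    stacked = np.stack([np.asarray(t, dtype=float) for t in scene_tables])  # scenes x targets x 2
    if len(scene_tables) >= 2:
        ba = [bland_altman(stacked[:, coord, :]) for coord in range(stacked.shape[1])]
    else:  # a single scene: pool its targets into one limits-of-agreement estimate
        ba = [bland_altman(stacked[0])]
    return mean_icc, icc_results, ba
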