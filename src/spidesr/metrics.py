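"""Quantitative evaluation: image quality, segmentation agreement, clustering.

Image quality is measured by PSNR (``10*log10(peak^2 / MSE)``, peak =
``2^n - 1`` with n = 8 after rescaling) and by a whole-image-statistics SSIM

    SSIM = (2 mu_x mu_y + e1)(2 cov_xy + e2)
           / ((mu_x^2 + mu_y^2 + e1)(var_x + var_y + e2))

with the stabilizers e1 = 6.5025 = (0.01*255)^2 and e2 = 58.5225 =
(0.03*255)^2; both are computed per channel and averaged.  A sliding-window
SSIM mode is available for cross-checking against common implementations.

Segmentation agreement works on integer label masks (0 = background): cells
are matched one-to-one greedily by descending IoU above a threshold, then
object counts give the extraction accuracy and matched pairs give per-cell
pixel IoU / F1.  Two accuracy conventions exist in the field's reports,
``TP/(2TP+FP+FN)`` and the F1-style ``2TP/(2TP+FP+FN)``; both are computed
(the former is the default) and neither is silently preferred.

Clustering validity uses the Calinski-Harabasz and Davies-Bouldin indices,
implemented from their scatter/centroid definitions (sklearn serves as an
independent cross-check in the test suite, not as the implementation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats
from skimage import measure as _measure

from .io import ImageGrid

__all__ = [
    "LabelMask",
    "MatchResult",
    "ClusterAssignment",
    "psnr",
    "ssim",
    "iou",
    "f1_pixel",
    "match_cells",
    "extraction_accuracy",
    "quantify_cells",
    "expression_distance",
    "ch_score",
    "db_score",
    "pearson",
]

SSIM_C1 = 6.5025
SSIM_C2 = 58.5225


@dataclass
class LabelMask:
    """Integer-labeled segmentation raster; 0 is background."""

    labels: np.ndarray

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be 2-D")
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.allclose(lab, np.rint(lab)):
                raise ValueError("labels must be integers")
            lab = np.rint(lab).astype(np.int32)
        if lab.min() < 0:
            raise ValueError("labels must be nonnegative")
        self.labels = lab.astype(np.int32)

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_cells(self) -> int:
        return int(self.cell_ids.size)


@dataclass
class MatchResult:
    """One-to-one cell matching between predicted and reference masks."""

    tp_pairs: list[tuple[int, int, float]]  # (pred label, ref label, IoU)
    fp_labels: list[int]
    fn_labels: list[int]

    @property
    def tp(self) -> int:
        return len(self.tp_pairs)

    @property
    def fp(self) -> int:
        return len(self.fp_labels)

    @property
    def fn(self) -> int:
        return len(self.fn_labels)


def _channels(x) -> np.ndarray:
    """(C, H, W) float array in the [0,255] convention from grid or array."""
    if isinstance(x, ImageGrid):
        return x.rescaled().pixels
    a = np.asarray(x, dtype=np.float64)
    return a[None] if a.ndim == 2 else a


def psnr(x, y, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB, per channel then averaged.

    Identical images return ``inf`` (the documented MSE = 0 sentinel).
    """
    cx, cy = _channels(x), _channels(y)
    if cx.shape != cy.shape:
        raise ValueError(f"shape mismatch {cx.shape} vs {cy.shape}")
    vals = []
    for a, b in zip(cx, cy):
        mse = float(np.mean((a - b) ** 2))
        vals.append(np.inf if mse == 0 else 10.0 * np.log10(peak ** 2 / mse))
    return float(np.mean(vals))


def _ssim_global(a: np.ndarray, b: np.ndarray) -> float:
    mu_x, mu_y = a.mean(), b.mean()
    var_x, var_y = a.var(), b.var()
    cov = ((a - mu_x) * (b - mu_y)).mean()
    return float((2 * mu_x * mu_y + SSIM_C1) * (2 * cov + SSIM_C2)
                 / ((mu_x ** 2 + mu_y ** 2 + SSIM_C1)
                    * (var_x + var_y + SSIM_C2)))


def ssim(x, y, windowed: bool = False) -> float:
    """Structural similarity from whole-image moments, per channel, averaged.

    ``windowed=True`` switches to the common sliding-window variant
    (scikit-image) for cross-checking; the default follows the global form.
    """
    cx, cy = _channels(x), _channels(y)
    if cx.shape != cy.shape:
        raise ValueError(f"shape mismatch {cx.shape} vs {cy.shape}")
    if windowed:
        from skimage.metrics import structural_similarity
        return float(np.mean([
            structural_similarity(a, b, data_range=255.0)
            for a, b in zip(cx, cy)]))
    return float(np.mean([_ssim_global(a, b) for a, b in zip(cx, cy)]))


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two boolean pixel sets; both-empty -> 1."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def f1_pixel(a: np.ndarray, b: np.ndarray) -> float:
    """Pixel-level F1 = 2TP/(2TP+FP+FN) of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    tp = np.logical_and(a, b).sum()
    fp = np.logical_and(a, ~b).sum()
    fn = np.logical_and(~a, b).sum()
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else float(2 * tp / denom)


def match_cells(pred: LabelMask, ref: LabelMask,
                iou_threshold: float = 0.1) -> MatchResult:
    """Greedy one-to-one matching by descending pairwise IoU >= threshold."""
    if pred.labels.shape != ref.labels.shape:
        raise ValueError("mask shape mismatch")
    p, r = pred.labels.ravel(), ref.labels.ravel()
    both = (p > 0) & (r > 0)
    # overlap counts for co-occurring (pred, ref) label pairs
    pairs, counts = np.unique(np.stack([p[both], r[both]]), axis=1,
                              return_counts=True)
    area_p = dict(zip(*np.unique(p[p > 0], return_counts=True)))
    area_r = dict(zip(*np.unique(r[r > 0], return_counts=True)))
    cand = []
    for (pl, rl), inter in zip(pairs.T, counts):
        union = area_p[pl] + area_r[rl] - inter
        v = inter / union
        if v >= iou_threshold:
            cand.append((float(v), int(pl), int(rl)))
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p: set[int] = set()
    used_r: set[int] = set()
    tp_pairs = []
    for v, pl, rl in cand:
        if pl in used_p or rl in used_r:
            continue
        used_p.add(pl)
        used_r.add(rl)
        tp_pairs.append((pl, rl, v))
    fp = [int(l) for l in sorted(area_p) if l not in used_p]
    fn = [int(l) for l in sorted(area_r) if l not in used_r]
    return MatchResult(tp_pairs, fp, fn)


def extraction_accuracy(match: MatchResult, variant: str = "printed") -> float:
    """Cell-extraction accuracy from object counts.

    ``variant="printed"`` evaluates TP/(2TP+FP+FN) (note its maximum is 0.5);
    ``variant="f1"`` evaluates the conventional 2TP/(2TP+FP+FN).  Returns
    ``nan`` when TP = FP = FN = 0.
    """
    tp, fp, fn = match.tp, match.fp, match.fn
    denom = 2 * tp + fp + fn
    if denom == 0:
        return float("nan")
    if variant == "printed":
        return tp / denom
    if variant == "f1":
        return 2 * tp / denom
    raise ValueError(f"unknown variant {variant!r}")


def _perimeter_edges(mask: np.ndarray) -> int:
    """Count of exposed 4-neighbor pixel edges of a boolean mask."""
    m = np.asarray(mask, dtype=bool)
    pad = np.pad(m, 1)
    exposed = 0
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        exposed += int((m & ~pad[1 + dr:1 + dr + m.shape[0],
                                 1 + dc:1 + dc + m.shape[1]]).sum())
    return exposed


def quantify_cells(channels: dict[str, ImageGrid], mask: LabelMask,
                   percentile: float = 99.0) -> pd.DataFrame:
    """Per-cell spatial features and mean marker expressions.

    Expressions are the per-cell mean pixel values of each channel; per
    channel across cells they are censored at the 99th percentile (values
    above are set to it) and then normalized to it, giving values in [0, 1].
    Spatial features: area (pixels), perimeter (exposed 4-neighbor edges),
    long/short axis lengths of the second-moment ellipse.
    """
    ids = mask.cell_ids
    if ids.size == 0:
        return pd.DataFrame(columns=["label", "area", "perimeter",
                                     "long_axis", "short_axis"])
    rows = []
    props = {pr.label: pr for pr in _measure.regionprops(mask.labels)}
    for lab in ids:
        pr = props[int(lab)]
        rows.append({
            "label": int(lab),
            "area": int(pr.area),
            "perimeter": _perimeter_edges(mask.labels == lab),
            "long_axis": float(pr.axis_major_length),
            "short_axis": float(pr.axis_minor_length),
        })
    table = pd.DataFrame(rows)
    for name, grid in channels.items():
        if grid.shape != mask.labels.shape:
            raise ValueError(f"channel {name!r} dims do not match mask")
        px = grid.channel(0)
        means = np.array([px[mask.labels == lab].mean() for lab in ids])
        table[f"{name}_mean"] = means
        p = float(np.percentile(means, percentile))
        if p > 0:
            censored = np.minimum(means, p)
            table[f"{name}_norm"] = censored / p
        else:
            table[f"{name}_norm"] = 0.0
    return table


def expression_distance(cell_pred: np.ndarray, cell_ref: np.ndarray) -> float:
    """Euclidean distance between two normalized expression vectors."""
    a = np.asarray(cell_pred, dtype=np.float64)
    b = np.asarray(cell_ref, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("channel sets differ")
    return float(np.linalg.norm(a - b))


@dataclass
class ClusterAssignment:
    """n x d feature rows with a cluster index per row."""

    points: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        self.labels = np.asarray(self.labels)
        if self.points.shape[0] != self.labels.shape[0]:
            raise ValueError("points/labels length mismatch")

    @property
    def k(self) -> int:
        return int(np.unique(self.labels).size)

    @property
    def n(self) -> int:
        return int(self.points.shape[0])


def ch_score(assign: ClusterAssignment) -> float:
    """Calinski-Harabasz index: tr(B)(n-k) / (tr(W)(k-1)); higher = better.

    tr(B) sums cluster sizes times squared centroid-to-grand-mean distances;
    tr(W) sums squared point-to-centroid distances.  All-identical points
    within clusters give tr(W) = 0 and the documented ``inf`` sentinel.
    """
    n, k = assign.n, assign.k
    if not 2 <= k <= n - 1:
        raise ValueError(f"need 2 <= k <= n-1, got k={k}, n={n}")
    grand = assign.points.mean(axis=0)
    tr_b = tr_w = 0.0
    for lab in np.unique(assign.labels):
        pts = assign.points[assign.labels == lab]
        c = pts.mean(axis=0)
        tr_b += pts.shape[0] * float(((c - grand) ** 2).sum())
        tr_w += float(((pts - c) ** 2).sum())
    if tr_w == 0:
        return float("inf")
    return tr_b * (n - k) / (tr_w * (k - 1))


def db_score(assign: ClusterAssignment) -> float:
    """Davies-Bouldin index: mean over clusters of max (S_i+S_j)/M_ij; lower = better."""
    n, k = assign.n, assign.k
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    labs = np.unique(assign.labels)
    cents = np.stack([assign.points[assign.labels == l].mean(axis=0)
                      for l in labs])
    scatter = np.array([
        float(np.linalg.norm(assign.points[assign.labels == l] - c,
                             axis=1).mean())
        for l, c in zip(labs, cents)])
    m = np.linalg.norm(cents[:, None] - cents[None, :], axis=2)
    off = ~np.eye(k, dtype=bool)
    if np.any(m[off] == 0):
        raise ZeroDivisionError(
            "coincident cluster centroids make the Davies-Bouldin "
            "ratio undefined")
    with np.errstate(divide="ignore"):
        ratio = (scatter[:, None] + scatter[None, :]) / np.where(off, m, np.inf)
    return float(ratio.max(axis=1).mean())


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; zero-variance input returns ``nan``."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(_stats.pearsonr(x, y).statistic)
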