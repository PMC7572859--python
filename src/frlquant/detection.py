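"""Gold-particle detection in replica micrographs.

Colloidal gold appears as a compact near-black disk, far darker than
either the replica texture or the shadowed IMP bumps.  The detector is
a multi-scale scale-normalized Laplacian-of-Gaussian filter with the
polarity chosen for dark blobs, followed by per-scale peak picking and
cross-scale greedy non-maximum suppression with an exclusion radius of
half the smaller requested diameter.  Each surviving detection carries
an estimated diameter from its best-responding scale (log-parabolic
interpolation across neighbor scales) and a bounded response score.

The quantification pipeline does not require images at all — coordinate
tables can be consumed directly — so detection is exercised against the
renderer's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .render import Rendering

DEFAULT_DIAMETERS_NM = (5.0, 10.0)
SIZE_CLASS_THRESHOLD_NM = 7.5  # midpoint; boundary assigned to the larger class
DEFAULT_MATCH_TOL_NM = 10.0
#: minimum scale-normalized LoG response (gray levels) to accept a blob;
#: a full-contrast gold disk responds at ~>40, IMP shadows at ~<15.
DEFAULT_MIN_RESPONSE = 25.0
#: response at which the score saturates to 1.
SCORE_SATURATION = 60.0


@dataclass
class DetectionResult:
    """Detections in nm: columns x_nm, y_nm, est_diameter_nm, class, score."""

    detections: pd.DataFrame
    px_size: float

    def __len__(self) -> int:
        return len(self.detections)

    def xy(self) -> np.ndarray:
        if self.detections.empty:
            return np.zeros((0, 2))
        return self.detections[["x_nm", "y_nm"]].to_numpy()


@dataclass(frozen=True)
class MatchReport:
    """Detection-vs-truth matching summary."""

    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    f1: float
    class_confusion: pd.DataFrame  # truth class x detected class counts
    pairs: pd.DataFrame  # matched (det_index, truth_index, distance_nm)


def _scale_grid(diameters_nm, px_size: float) -> np.ndarray:
    """LoG sigmas (px) bracketing each requested disk diameter.

    A disk of radius r maximizes the scale-normalized LoG at
    sigma = r / sqrt(2); three sigmas per diameter give the parabolic
    diameter estimate some support.
    """
    sigmas = []
    for d in diameters_nm:
        s = d / (2.0 * np.sqrt(2.0) * px_size)
        sigmas.extend([0.8 * s, s, 1.25 * s])
    return np.unique(np.round(np.asarray(sigmas), 4))


def detect_particles(
    image: np.ndarray,
    px_size: float,
    diameters: tuple[float, ...] = DEFAULT_DIAMETERS_NM,
    min_response: float = DEFAULT_MIN_RESPONSE,
    origin: tuple[float, float] = (0.0, 0.0),
) -> DetectionResult:
    """Detect dark gold disks at scales matched to ``diameters`` (nm).

    Returns positions in nm (``origin`` maps pixel (0, 0) corner to nm),
    estimated diameters, and scores in [0, 1].  An empty or flat image
    yields an empty result.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        return DetectionResult(_empty_detections(), px_size)
    sigmas = _scale_grid(diameters, px_size)
    # dark blobs: LoG of a dark disk is positive at the center
    stack = np.stack(
        [(s**2) * ndi.gaussian_laplace(img, s) for s in sigmas]
    )
    candidates = []
    for k, s in enumerate(sigmas):
        resp = stack[k]
        footprint = int(max(3, 2 * round(s) + 1))
        local_max = resp == ndi.maximum_filter(resp, size=footprint)
        ys, xs = np.nonzero(local_max & (resp >= min_response))
        for y, x in zip(ys, xs):
            candidates.append((float(resp[y, x]), k, int(y), int(x)))
    if not candidates:
        return DetectionResult(_empty_detections(), px_size)

    # estimate each candidate's diameter before suppression so the NMS
    # can account for blob extent
    log_s = np.log(sigmas)
    enriched = []
    for resp, k, y, x in candidates:
        # log-parabolic interpolation of the best scale
        if 0 < k < len(sigmas) - 1:
            r0, r1, r2 = stack[k - 1, y, x], resp, stack[k + 1, y, x]
            denom = r0 - 2 * r1 + r2
            delta = 0.0 if denom == 0 else np.clip(0.5 * (r0 - r2) / denom, -1, 1)
            ls = log_s[k] + delta * (log_s[k + 1] - log_s[k - 1]) / 2.0
        else:
            ls = log_s[k]
        sigma_best = float(np.exp(ls))
        d_est = 2.0 * np.sqrt(2.0) * sigma_best * px_size
        enriched.append((resp, d_est, y, x))

    # greedy NMS, strongest first; a candidate is suppressed inside the
    # footprint of an accepted blob plus the half-smallest-diameter
    # exclusion margin (secondary scale responses sit on a particle's rim,
    # so the margin alone is not enough)
    enriched.sort(reverse=True)
    excl_px = min(diameters) / 2.0 / px_size
    kept: list[tuple[float, float, int, int]] = []
    for resp, d_est, y, x in enriched:
        radius = excl_px + max(0.0, d_est / 2.0 / px_size)
        if any(
            (x - kx) ** 2 + (y - ky) ** 2 < max(radius, excl_px + kd / 2.0 / px_size) ** 2
            for _, kd, ky, kx in kept
        ):
            continue
        kept.append((resp, d_est, y, x))

    rows = []
    for resp, d_est, y, x in kept:
        rows.append(
            dict(
                x_nm=origin[0] + (x + 0.5) * px_size,
                y_nm=origin[1] + (y + 0.5) * px_size,
                est_diameter_nm=d_est,
                size_class=classify_size(d_est),
                score=float(min(1.0, resp / SCORE_SATURATION)),
            )
        )
    det = pd.DataFrame(rows).sort_values("score", ascending=False, ignore_index=True)
    return DetectionResult(det, px_size)


def _empty_detections() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["x_nm", "y_nm", "est_diameter_nm", "size_class", "score"]
    )


def detect_in_rendering(rendering: Rendering, **kwargs) -> DetectionResult:
    """Run :func:`detect_particles` on a rendering, in its nm frame."""
    return detect_particles(
        rendering.image, rendering.px_size, origin=rendering.origin, **kwargs
    )


def classify_size(estimated_diameter_nm: float) -> int:
    """5 if the estimated diameter is below 7.5 nm, else 10 (the boundary
    itself is assigned to the larger class)."""
    if estimated_diameter_nm <= 0:
        raise ValueError(f"diameter must be > 0, got {estimated_diameter_nm}")
    return 5 if estimated_diameter_nm < SIZE_CLASS_THRESHOLD_NM else 10


def match_truth(
    result: DetectionResult,
    truth: pd.DataFrame,
    tol: float = DEFAULT_MATCH_TOL_NM,
) -> MatchReport:
    """Greedy nearest-neighbor matching of detections to ground truth.

    Pairs are formed in order of increasing distance; each detection and
    each truth point is used at most once; a pair matches iff its
    distance is <= ``tol`` nm.
    """
    if tol <= 0:
        raise ValueError("match tolerance must be > 0")
    det_xy = result.xy()
    truth_xy = (
        truth[["x_nm", "y_nm"]].to_numpy() if len(truth) else np.zeros((0, 2))
    )
    n_det, n_truth = len(det_xy), len(truth_xy)
    pairs = []
    if n_det and n_truth:
        d = np.hypot(
            det_xy[:, None, 0] - truth_xy[None, :, 0],
            det_xy[:, None, 1] - truth_xy[None, :, 1],
        )
        cand = [
            (d[i, j], i, j)
            for i in range(n_det)
            for j in range(n_truth)
            if d[i, j] <= tol
        ]
        cand.sort()
        used_det: set[int] = set()
        used_truth: set[int] = set()
        for dist, i, j in cand:
            if i in used_det or j in used_truth:
                continue
            used_det.add(i)
            used_truth.add(j)
            pairs.append((i, j, float(dist)))
    tp = len(pairs)
    fp = n_det - tp
    fn = n_truth - tp
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    f1 = (
        2 * precision * recall / (precision + recall)
        if tp and (precision + recall) > 0
        else 0.0
    )
    classes = [5, 10]
    conf = pd.DataFrame(0, index=classes, columns=classes)
    for i, j, _ in pairs:
        t_cls = int(truth.iloc[j]["size_class_nm"])
        d_cls = int(result.detections.iloc[i]["size_class"])
        if t_cls in classes and d_cls in classes:
            conf.loc[t_cls, d_cls] += 1
    return MatchReport(
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        precision=precision,
        recall=recall,
        f1=f1,
        class_confusion=conf,
        pairs=pd.DataFrame(pairs, columns=["det_index", "truth_index", "distance_nm"]),
    )


def match_truth_optimal(
    result: DetectionResult, truth: pd.DataFrame, tol: float = DEFAULT_MATCH_TOL_NM
) -> int:
    """Maximum-cardinality matching within ``tol`` (brute-force oracle for
    the greedy matcher), via the assignment problem on a padded cost."""
    from scipy.optimize import linear_sum_assignment

    det_xy = result.xy()
    truth_xy = truth[["x_nm", "y_nm"]].to_numpy() if len(truth) else np.zeros((0, 2))
    if not len(det_xy) or not len(truth_xy):
        return 0
    d = np.hypot(
        det_xy[:, None, 0] - truth_xy[None, :, 0],
        det_xy[:, None, 1] - truth_xy[None, :, 1],
    )
    cost = np.where(d <= tol, 0.0, 1.0)
    ri, ci = linear_sum_assignment(cost)
    return int(np.sum(cost[ri, ci] == 0.0))


def segment_imp_cluster(
    image: np.ndarray,
    seed_point_px: tuple[float, float],
    px_size: float,
    origin: tuple[float, float] = (0.0, 0.0),
    energy_sigma_nm: float = 1.5,
    energy_window_nm: float = 16.0,
    energy_factor: float = 1.5,
    close_radius_nm: float = 12.0,
    seed_search_nm: float = 30.0,
) -> np.ndarray:
    """Semi-automated IMP-cluster segmentation from a seed click.

    Local texture energy (windowed standard deviation of the lightly
    smoothed image) is thresholded at ``energy_factor`` times the image
    median energy; the connected component containing the seed (or the
    dominant component within ``seed_search_nm`` of it, emulating an
    imprecise click) is closed morphologically, and IMP centers are
    returned as the bright local maxima inside it, in nm.  A seed on
    flat background returns an empty array.

    ``seed_point_px`` is (col, row) in pixels.
    """
    from scipy.ndimage import (
        binary_closing,
        binary_fill_holes,
        gaussian_filter,
        label,
        maximum_filter,
        uniform_filter,
    )

    img = np.asarray(image, dtype=float)
    smooth = gaussian_filter(img, energy_sigma_nm / px_size)
    w = max(3, int(round(energy_window_nm / px_size)))
    mean = uniform_filter(smooth, w)
    sq = uniform_filter(smooth**2, w)
    energy = np.sqrt(np.maximum(sq - mean**2, 0.0))
    thresh = energy_factor * np.median(energy)
    mask = energy > thresh
    lab, _ = label(mask)
    sx, sy = int(round(seed_point_px[0])), int(round(seed_point_px[1]))
    if not (0 <= sy < lab.shape[0] and 0 <= sx < lab.shape[1]):
        raise ValueError("seed point outside the image")
    seed_label = lab[sy, sx]
    if seed_label == 0 and seed_search_nm > 0:
        rad = max(1, int(round(seed_search_nm / px_size)))
        sub = lab[max(sy - rad, 0) : sy + rad + 1, max(sx - rad, 0) : sx + rad + 1]
        vals = sub[sub > 0]
        if len(vals):
            seed_label = int(np.bincount(vals).argmax())
    if seed_label == 0:
        return np.zeros((0, 2))
    region = lab == seed_label
    r = max(1, int(round(close_radius_nm / px_size)))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    selem = xx**2 + yy**2 <= r**2
    region = binary_fill_holes(binary_closing(region, structure=selem))

    # IMP centers: bright local maxima of the smoothed image inside the region
    fp = max(3, int(round(IMP_MIN_SEPARATION_NM / px_size)) | 1)
    is_max = smooth == maximum_filter(smooth, size=fp)
    bright = smooth > np.median(smooth) + 0.15 * IMP_PROMINENCE
    ys, xs = np.nonzero(is_max & bright & region)
    if len(ys) == 0:
        return np.zeros((0, 2))
    return np.column_stack(
        [origin[0] + (xs + 0.5) * px_size, origin[1] + (ys + 0.5) * px_size]
    )


IMP_MIN_SEPARATION_NM = 6.0
IMP_PROMINENCE = 26.0
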