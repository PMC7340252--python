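"""Ab initio shape-based particle detection (local-threshold picking).

The picker needs only three parameters: the estimated particle size in
unbinned pixels, an integer bin size, and a detection threshold.  The
micrograph is binned, min-max normalized to [0, 1], and a binary mask is
formed where a pixel exceeds its local mean by more than the threshold.
Connected mask components become candidate particles (intensity-weighted
centroids), and candidates closer than one particle size are cleaned up
greedily, larger features winning.

Because detection is purely intensity based, bright contaminants such as
crystalline ice are picked at this stage too; rejecting them is the job
of the downstream 2D-classification / CNN loop.

The local thresholding is deliberately simple -- deviation from the local
mean on the normalized image -- so the quoted working thresholds
(1e-3 ... 1.5e-3) live on a well-defined [0, 1] scale.  The strategy
function is pluggable if a different local statistic is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_core import CoordinateSet, Micrograph, bin_image, minmax_normalize

__all__ = [
    "LocalpickerParams",
    "local_threshold_mask",
    "detect_features",
    "enforce_min_distance",
    "localpick",
]

_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class LocalpickerParams:
    """The three parameters of the ab initio picker.

    ``particle_size`` is the particle diameter in unbinned pixels; it is
    used only for the minimum-distance cleanup and the local window, not
    for pattern matching.  Working defaults: ``bin_size`` 9 and
    ``threshold`` 1e-3 ... 1.5e-3 on the normalized intensity scale.
    """

    particle_size: int
    bin_size: int = 9
    threshold: float = 0.0015
    invert: bool = False  # pick dark-on-bright particles by negating first
    auto_threshold_sigmas: float | None = None

    def __post_init__(self) -> None:
        if self.particle_size < 8:
            raise ValueError("particle_size must be >= 8 unbinned px")
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")
        if self.auto_threshold_sigmas is not None and not self.auto_threshold_sigmas > 0:
            raise ValueError("auto_threshold_sigmas must be > 0")


def local_mean(image: np.ndarray, window_px: int) -> np.ndarray:
    """Windowed mean with reflective boundary handling.

    Reflection does not duplicate the edge pixel (scipy's ``mirror``),
    matching ``np.pad(mode="reflect")``.
    """
    return ndimage.uniform_filter(np.asarray(image, dtype=np.float64), size=window_px, mode="mirror")


def local_threshold_mask(image: np.ndarray, window_px: int, threshold: float) -> np.ndarray:
    """Binary mask of pixels exceeding their local mean by > threshold.

    ``image`` is expected binned and min-max normalized to [0, 1];
    ``window_px`` must be odd and >= 3.
    """
    image = np.asarray(image)
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window_px}")
    if window_px > min(image.shape):
        raise ValueError(f"window {window_px} larger than image {image.shape}")
    deviation = image - local_mean(image, window_px)
    return deviation > threshold


def detect_features(
    mask: np.ndarray,
    image: np.ndarray,
    threshold: float,
    window_px: int,
    min_area: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Label mask components and return their weighted centroids.

    Components are 8-connected.  Each component yields a centroid
    weighted by the positive deviation from the local mean; components
    whose maximum deviation is below ``threshold`` are discarded (the
    local-maxima cutoff), as are components spanning fewer than
    ``min_area`` pixels (single-pixel noise excursions).  Returns
    ``(centroids, areas)`` where centroids are ``(x, y)`` rows in the
    same (binned) pixel frame as the mask and areas are component pixel
    counts, usable as detection scores.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_EIGHT_CONN)
    if n == 0:
        return np.empty((0, 2)), np.empty(0)
    deviation = np.asarray(image, dtype=np.float64) - local_mean(image, window_px)
    idx = np.arange(1, n + 1)
    max_dev = ndimage.labeled_comprehension(deviation, labels, idx, np.max, float, -np.inf)
    comp_area = ndimage.sum_labels(mask, labels, idx)
    keep = (max_dev >= threshold) & (comp_area >= min_area)
    weights = np.where(mask, np.clip(deviation, 0.0, None), 0.0)
    # fall back to plain (unweighted) centroid for degenerate zero-weight blobs
    wsum = ndimage.sum_labels(weights, labels, idx)
    centroids = []
    for k, lab in enumerate(idx):
        if not keep[k]:
            continue
        if wsum[k] > 0:
            cy, cx = ndimage.center_of_mass(weights, labels, lab)
        else:
            cy, cx = ndimage.center_of_mass(mask, labels, lab)
        centroids.append((cx, cy))
    if not centroids:
        return np.empty((0, 2)), np.empty(0)
    return np.array(centroids, dtype=np.float64), comp_area[keep].astype(np.float64)


def enforce_min_distance(
    coords: np.ndarray,
    min_dist: float,
    scores: np.ndarray | None = None,
    tie_break_xy: bool = False,
) -> np.ndarray:
    """Greedy minimum-distance cleanup.

    Candidates are visited in descending score order (input order when no
    scores are given) and accepted iff they lie at least ``min_dist``
    from every already-accepted candidate.  Returns indices into
    ``coords`` in acceptance order.  With ``tie_break_xy`` equal scores
    are ordered by (x, y) lexicographically, making the result
    independent of input order.
    """
    if min_dist < 0:
        raise ValueError("min_dist must be >= 0")
    coords = np.asarray(coords, dtype=np.float64).reshape(-1, 2)
    n = len(coords)
    if n == 0:
        return np.empty(0, dtype=int)
    if scores is None:
        order = np.arange(n)
    elif tie_break_xy:
        order = np.lexsort((coords[:, 1], coords[:, 0], -np.asarray(scores, dtype=np.float64)))
    else:
        order = np.argsort(-np.asarray(scores, dtype=np.float64), kind="stable")
    accepted: list[int] = []
    acc_xy = np.empty((0, 2))
    for i in order:
        if len(accepted):
            d2 = ((acc_xy - coords[i]) ** 2).sum(axis=1)
            if d2.min() < min_dist**2:
                continue
        accepted.append(int(i))
        acc_xy = np.vstack([acc_xy, coords[i]])
    return np.array(accepted, dtype=int)


def localpick(micrograph: Micrograph, params: LocalpickerParams) -> CoordinateSet:
    """Run the full ab initio picking pipeline on one micrograph.

    bin -> min-max normalize -> local-threshold mask (window = binned
    particle size, rounded up to odd) -> feature centroids -> rescale to
    the unbinned frame -> minimum-distance cleanup at one particle size.
    """
    image = micrograph.image
    if params.invert:
        image = -image
    binned = bin_image(image, params.bin_size)
    norm = minmax_normalize(binned)
    window = int(np.ceil(params.particle_size / params.bin_size))
    if window % 2 == 0:
        window += 1
    window = max(window, 3)
    threshold = params.threshold
    if params.auto_threshold_sigmas is not None:
        # threshold scales with the image's dynamic range (bright contaminants
        # compress the normalized signal), so anchor it to the robust noise
        # scale of the deviation image instead of a fixed number
        deviation = norm - local_mean(norm, window)
        mad_sd = 1.4826 * float(np.median(np.abs(deviation - np.median(deviation))))
        threshold = params.auto_threshold_sigmas * mad_sd
    mask = local_threshold_mask(norm, window, threshold)
    # a real particle spans a sizable fraction of its binned footprint;
    # single-pixel excursions are noise
    binned_area = np.pi * (params.particle_size / (2.0 * params.bin_size)) ** 2
    min_area = max(2, int(round(0.1 * binned_area)))
    centroids, areas = detect_features(mask, norm, threshold, window, min_area=min_area)
    if len(centroids) == 0:
        return CoordinateSet.empty(micrograph.id)
    # binned pixel i covers unbinned [i*b, (i+1)*b); its center is i*b + b/2
    unbinned = centroids * params.bin_size + params.bin_size / 2.0
    h, w = micrograph.shape
    unbinned[:, 0] = np.clip(unbinned[:, 0], 0, w - 1)
    unbinned[:, 1] = np.clip(unbinned[:, 1], 0, h - 1)
    keep = enforce_min_distance(unbinned, float(params.particle_size), scores=areas)
    sel = unbinned[keep]
    return CoordinateSet(sel[:, 0], sel[:, 1], None, micrograph.id)
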