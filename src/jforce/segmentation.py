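"""Cluster segmentation from the junction-marker channel.

The cluster footprint is segmented by Gaussian smoothing, a
first-minimum-after-first-maximum histogram threshold, largest connected
component, and a small morphological closing.  Interfaces themselves are
inputs (hand-drawn in the original workflow, generator-provided here);
this module rasterizes them to partition the cluster into per-cell
footprints and measures interface lengths.

Pixel convention: 0-based indices, origin top-left, x = column,
y = row; physical quantities via ``pixel_size`` (um/px).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.morphology import binary_closing, binary_dilation, disk

__all__ = [
    "ClusterFrame",
    "histogram_threshold",
    "segment_cluster_mask",
    "dilate_cluster_mask",
    "partition_cells",
    "interface_length",
]


@dataclass
class ClusterFrame:
    """Per-frame segmentation products.

    ``cell_footprints`` is a labelled image (0 = background, 1..n cells);
    footprints are disjoint and cover the tight mask.  ``interfaces`` is
    the list of interface records used for the partition (objects with
    ``junction_id``, ``cell_a``, ``cell_b`` and ``points`` in px).
    """

    marker_image: np.ndarray = field(repr=False)
    tight_mask: np.ndarray = field(repr=False)
    dilated_mask: np.ndarray = field(repr=False)
    cell_footprints: np.ndarray = field(repr=False)
    interfaces: list = field(default_factory=list)
    cell_centers: np.ndarray | None = None  # (n, 2) xy px
    pixel_size: float = 1.0


def histogram_threshold(image: np.ndarray, bins: int = 256) -> float:
    """First histogram minimum after the lowest-intensity maximum.

    The histogram uses 256 bins over the observed range and is smoothed
    with a 3-bin moving average before extremum detection (raw float
    histograms are too spiky for reliable extrema).  Falls back to a
    bimodal (Otsu) split with a warning when no interior minimum exists.
    """
    img = np.asarray(image, dtype=float)
    counts, edges = np.histogram(img.ravel(), bins=bins)
    smooth = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    # first local maximum from the low-intensity end
    imax = None
    for i in range(1, bins - 1):
        if smooth[i] >= smooth[i - 1] and smooth[i] > smooth[i + 1]:
            imax = i
            break
    if imax is None:
        imax = int(np.argmax(smooth[: bins // 2]))
    for i in range(imax + 1, bins - 1):
        if smooth[i] <= smooth[i - 1] and smooth[i] < smooth[i + 1]:
            return float(centers[i])
    from skimage.filters import threshold_otsu

    warnings.warn("histogram has no interior minimum; falling back to Otsu split")
    return float(threshold_otsu(img))


def segment_cluster_mask(
    marker_image: np.ndarray, smooth_sigma: float = 5.0, closing_radius: int = 3
) -> np.ndarray:
    """Segment the tight cluster mask from the junction-marker image.

    Pipeline: Gaussian smoothing (sd 5 px) -> first-minimum-after-first-
    maximum histogram threshold -> largest connected component ->
    morphological closing with a disk of radius 3 px.  Holes larger than
    the closing scale stay open (they are genuine cluster-external space,
    e.g. transient gaps during divisions).
    """
    img = np.asarray(marker_image, dtype=float)
    if img.max() == img.min():
        raise ValueError("marker image is constant; cannot segment")
    sm = ndimage.gaussian_filter(img, smooth_sigma)
    thr = histogram_threshold(sm)
    binary = sm > thr
    labels, n = ndimage.label(binary)
    if n == 0:
        raise ValueError("no foreground found at histogram threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = 1 + int(np.argmax(sizes))
    mask = labels == largest
    return binary_closing(mask, disk(closing_radius))


def dilate_cluster_mask(tight_mask: np.ndarray, radius_px: int = 15) -> np.ndarray:
    """Dilate the tight mask with a disk structuring element.

    The dilated mask is the thin-plate model domain; it captures
    significant tractions falling outside the marker-based segmentation
    (limited bead-tracking resolution, faint protrusions and retraction
    fibres).  The stated working range is 15-45 px.
    """
    if radius_px < 0:
        raise ValueError("radius must be >= 0")
    if radius_px == 0:
        return np.asarray(tight_mask, dtype=bool).copy()
    if not 15 <= radius_px <= 45:
        warnings.warn(f"dilation radius {radius_px} px outside the usual 15-45 px range")
    return binary_dilation(np.asarray(tight_mask, dtype=bool), disk(radius_px))


def _rasterize_polyline(points_px: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean image of an 8-connected polyline."""
    out = np.zeros(shape, dtype=bool)
    p = np.asarray(points_px)
    for (x0, y0), (x1, y1) in zip(p[:-1], p[1:]):
        rr, cc = draw_line(int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1)))
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        out[rr[keep], cc[keep]] = True
    return out


def partition_cells(
    tight_mask: np.ndarray, interfaces: list, extend_px: float = 20.0
) -> tuple[np.ndarray, np.ndarray]:
    """Partition the tight mask into labelled per-cell footprints.

    Interfaces are rasterized as cuts; 4-connected components of the
    mask minus the cuts become cell labels (matched to the interface
    ``cell_a``/``cell_b`` ids); cut pixels are then assigned to the
    adjacent label with the nearest centroid.  Cuts are prolonged by
    ``extend_px`` along their end tangents so a segmented mask that
    bulges slightly past the drawn interface ends is still separated.
    Returns the labelled image (labels are ``cell_id + 1``) and the
    (n, 2) xy centroid array.
    """
    mask = np.asarray(tight_mask, dtype=bool)
    if not interfaces:
        labels = mask.astype(int)
        cy, cx = ndimage.center_of_mass(mask)
        return labels, np.array([[cx, cy]])
    cuts = np.zeros_like(mask)
    for itf in interfaces:
        pts = np.asarray(itf.points, dtype=float)
        if extend_px > 0 and len(pts) >= 2:
            k = min(len(pts) - 1, 8)
            t0 = pts[0] - pts[k]
            t1 = pts[-1] - pts[-1 - k]
            segs = [pts]
            if np.linalg.norm(t0) > 0:
                segs.insert(0, (pts[0] + extend_px * t0 / np.linalg.norm(t0))[None])
            if np.linalg.norm(t1) > 0:
                segs.append((pts[-1] + extend_px * t1 / np.linalg.norm(t1))[None])
            pts = np.vstack(segs)
        cuts |= _rasterize_polyline(pts, mask.shape)
    # dilate cuts by 1 px so 4-connectivity cannot leak through diagonals
    cuts = binary_dilation(cuts, np.ones((2, 2), dtype=bool))
    pieces, npieces = ndimage.label(mask & ~cuts, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]
    ))
    cell_ids = sorted({itf.cell_a for itf in interfaces} | {itf.cell_b for itf in interfaces})
    n_cells = len(cell_ids)
    # keep the n_cells largest pieces; tiny slivers get merged in the
    # nearest-centroid cut assignment below
    sizes = ndimage.sum_labels(np.ones(mask.shape), pieces, np.arange(1, npieces + 1))
    order = np.argsort(sizes)[::-1]
    if npieces < n_cells:
        bad = _failing_interface(pieces, interfaces)
        raise ValueError(
            f"interface {bad} fails to separate its cells (gap in the cut)"
        )
    keep = set((order[:n_cells] + 1).tolist())
    relabel = np.zeros(npieces + 1, dtype=int)
    for new, piece in enumerate(sorted(keep), start=1):
        relabel[piece] = new
    labels = relabel[pieces]
    # assign remaining pixels (cuts, slivers) to nearest labelled centroid
    centroids = np.array(ndimage.center_of_mass(mask, labels, range(1, n_cells + 1)))
    missing = mask & (labels == 0)
    if np.any(missing):
        yy, xx = np.nonzero(missing)
        d2 = (
            (yy[:, None] - centroids[None, :, 0]) ** 2
            + (xx[:, None] - centroids[None, :, 1]) ** 2
        )
        labels[yy, xx] = 1 + np.argmin(d2, axis=1)
    # verify every interface separates two different labels
    for itf in interfaces:
        pts = np.asarray(itf.points)
        mid = pts[len(pts) // 2]
        tang = pts[min(len(pts) - 1, len(pts) // 2 + 3)] - pts[max(0, len(pts) // 2 - 3)]
        nrm = np.array([-tang[1], tang[0]])
        nn = np.linalg.norm(nrm)
        if nn == 0:
            continue
        nrm = nrm / nn
        la = _label_at(labels, mid + 4 * nrm)
        lb = _label_at(labels, mid - 4 * nrm)
        if la != 0 and la == lb:
            raise ValueError(
                f"interface {getattr(itf, 'junction_id', '?')} fails to separate "
                f"(gap > 2 px): both sides map to label {la}"
            )
    centroids_final = np.array(
        ndimage.center_of_mass(mask, labels, range(1, n_cells + 1))
    )
    centers_xy = centroids_final[:, ::-1]
    return labels, centers_xy


def labels_for_cell_ids(labels: np.ndarray, interfaces: list) -> dict[int, int]:
    """Map interface cell ids to partition labels.

    Relies on the interface orientation convention: ``cell_a`` lies on
    the left of the polyline traversal (left normal = (ty, -tx) in
    y-down pixel coordinates).  Votes are collected along each interface
    and resolved by majority, so a single noisy probe cannot flip the
    mapping.
    """
    votes: dict[int, dict[int, int]] = {}
    for itf in interfaces:
        pts = np.asarray(itf.points)
        for frac in (0.3, 0.5, 0.7):
            i = int(frac * (len(pts) - 1))
            lo, hi = max(0, i - 3), min(len(pts) - 1, i + 3)
            tang = pts[hi] - pts[lo]
            nl = np.linalg.norm(tang)
            if nl == 0:
                continue
            left = np.array([tang[1], -tang[0]]) / nl
            la = _label_at(labels, pts[i] + 4 * left)
            lb = _label_at(labels, pts[i] - 4 * left)
            if la > 0:
                votes.setdefault(itf.cell_a, {}).setdefault(la, 0)
                votes[itf.cell_a][la] += 1
            if lb > 0:
                votes.setdefault(itf.cell_b, {}).setdefault(lb, 0)
                votes[itf.cell_b][lb] += 1
    mapping = {}
    for cid, v in votes.items():
        mapping[cid] = max(v.items(), key=lambda kv: kv[1])[0]
    if len(set(mapping.values())) != len(mapping):
        raise ValueError("ambiguous label-to-cell mapping from interface sides")
    return mapping


def match_labels_to_cells(
    labels: np.ndarray, reference_masks: list[np.ndarray]
) -> np.ndarray:
    """Relabel a partition so label ``i+1`` is cell ``i`` of the reference.

    Labels are matched to reference footprints by maximal overlap
    (labels themselves are arbitrary; comparisons are relabel-invariant).
    Returns a relabelled image.
    """
    n = len(reference_masks)
    mapping = np.zeros(labels.max() + 1, dtype=int)
    used = set()
    for i, ref in enumerate(reference_masks):
        vals, counts = np.unique(labels[ref & (labels > 0)], return_counts=True)
        if len(vals) == 0:
            raise ValueError(f"reference cell {i} overlaps no label")
        for v in vals[np.argsort(counts)[::-1]]:
            if v not in used:
                mapping[v] = i + 1
                used.add(int(v))
                break
        else:
            raise ValueError("ambiguous label-to-cell matching")
    return mapping[labels]


def _label_at(labels: np.ndarray, xy: np.ndarray) -> int:
    y, x = int(round(xy[1])), int(round(xy[0]))
    if 0 <= y < labels.shape[0] and 0 <= x < labels.shape[1]:
        return int(labels[y, x])
    return 0


def _failing_interface(pieces: np.ndarray, interfaces: list):
    for itf in interfaces:
        pts = np.asarray(itf.points)
        mid = pts[len(pts) // 2]
        tang = pts[-1] - pts[0]
        nrm = np.array([-tang[1], tang[0]])
        nn = np.linalg.norm(nrm)
        if nn == 0:
            continue
        nrm /= nn
        la = _label_at(pieces, mid + 4 * nrm)
        lb = _label_at(pieces, mid - 4 * nrm)
        if la != 0 and la == lb:
            return getattr(itf, "junction_id", "?")
    return "?"


def interface_length(
    points_px: np.ndarray,
    tight_mask: np.ndarray | None = None,
    pixel_size: float = 1.0,
    step: int = 10,
) -> float:
    """Chord length of an interface polyline in um.

    Cumulative Euclidean length of segments connecting every ``step``-th
    pixel of the curve (the curve is assumed sampled at ~1 px arc steps).
    Chords whose endpoints fall into segmentation holes are not counted,
    avoiding overestimation where the curve crosses cluster-external
    space.
    """
    pts = np.asarray(points_px, dtype=float)
    if len(pts) < 2:
        raise ValueError("polyline needs at least 2 points")
    samples = pts[::step]
    if not np.array_equal(samples[-1], pts[-1]):
        samples = np.vstack([samples, pts[-1]])
    if tight_mask is not None:
        mask = np.asarray(tight_mask, dtype=bool)
        ok = np.array([_label_at(mask.astype(int), p) == 1 for p in samples])
    else:
        ok = np.ones(len(samples), dtype=bool)
    total = 0.0
    for a, b, ka, kb in zip(samples[:-1], samples[1:], ok[:-1], ok[1:]):
        if ka and kb:
            total += float(np.hypot(*(b - a)))
    if total == 0.0 and tight_mask is not None:
        warnings.warn("interface lies entirely inside a segmentation hole")
    return total * pixel_size
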