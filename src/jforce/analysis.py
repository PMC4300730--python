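"""Junction-level analytics: stress-intensity correlation, coupling
length, connectivity strata, and force-transmission cross-correlations.

The central questions these tools answer: does the junctional adhesion
marker (E-cadherin) accumulate where mechanical stress is transmitted,
down to what sub-junctional length scale is that coupling resolvable,
and are force fluctuations at one junction of a cell transmitted to its
other junctions or locally absorbed by the cell's own tractions?
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import convolve

__all__ = [
    "CorrelationResult",
    "sample_intensity_along_interface",
    "intensity_stress_correlation",
    "coupling_length_scale",
    "junction_autocorrelation_length",
    "classify_edges_min_k",
    "resample_and_normalize",
    "vector_cross_correlation",
    "transmission_analysis",
]


@dataclass
class CorrelationResult:
    coefficient: float
    n_samples: int
    n_junctions: int = 1
    segment_length_um: float | None = None
    randomized: bool = False

    def __post_init__(self) -> None:
        if np.isfinite(self.coefficient) and not -1.0 <= self.coefficient <= 1.001:
            raise ValueError("correlation coefficient outside [-1, 1]")


def _disk_kernel(radius: int) -> np.ndarray:
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (x**2 + y**2 <= radius**2).astype(float)


def sample_intensity_along_interface(
    marker_image: np.ndarray,
    points_px: np.ndarray,
    smooth_radius: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Marker intensity at profile sample points.

    The image is smoothed with a plain average filter with circular
    support (radius 10 px) and read at the nearest pixel of each sample
    point.  Returns (values, keep-mask); samples outside the image are
    dropped and flagged so the paired stress sample can be dropped too.
    """
    img = np.asarray(marker_image, dtype=float)
    k = _disk_kernel(smooth_radius)
    sm = convolve(img, k / k.sum(), mode="nearest")
    pts = np.asarray(points_px)
    ix = np.round(pts[:, 0]).astype(int)
    iy = np.round(pts[:, 1]).astype(int)
    keep = (ix >= 0) & (ix < img.shape[1]) & (iy >= 0) & (iy < img.shape[0])
    if not keep.all():
        warnings.warn(f"{np.sum(~keep)} intensity samples outside image dropped")
    vals = np.full(len(pts), np.nan)
    vals[keep] = sm[iy[keep], ix[keep]]
    return vals, keep


def intensity_stress_correlation(
    intensity: np.ndarray, stress_mag: np.ndarray
) -> CorrelationResult:
    """Pearson correlation of marker intensity and stress magnitude.

    Callers pool pairs as they wish: per interface per frame, or all
    pairs of all interfaces of all clusters over all frames grouped
    together.
    """
    I = np.asarray(intensity, dtype=float)
    s = np.asarray(stress_mag, dtype=float)
    ok = np.isfinite(I) & np.isfinite(s)
    I, s = I[ok], s[ok]
    if len(I) < 3:
        raise ValueError("need at least 3 intensity/stress pairs")
    if np.std(I) == 0 or np.std(s) == 0:
        warnings.warn("zero variance in intensity or stress; correlation undefined")
        return CorrelationResult(np.nan, len(I))
    r = float(np.corrcoef(I, s)[0, 1])
    return CorrelationResult(r, len(I))


def _segment_bounds(arc: np.ndarray, dl: float) -> list[np.ndarray] | None:
    """Index groups partitioning samples into segments of arc length dl.

    Junctions shorter than dl yield None (skipped).  The remainder
    fragment is complemented with neighbouring points so the last
    segment also spans exactly dl (it overlaps its neighbour).
    """
    total = arc[-1]
    if total < dl:
        return None
    bounds = np.arange(0.0, total, dl)
    groups = []
    for b in bounds:
        if b + dl <= total:
            sel = np.flatnonzero((arc >= b) & (arc < b + dl))
        else:
            sel = np.flatnonzero(arc >= total - dl)  # complemented remainder
        if len(sel) > 0:
            groups.append(sel)
    return groups


def coupling_length_scale(
    junction_samples: list[dict],
    dl_grid: np.ndarray,
    rng: np.random.Generator,
    min_junctions: int = 5,
) -> pd.DataFrame:
    """Length scale of intensity-stress coupling by segment randomization.

    For each junction (dict with ``arc_um``, ``intensity``,
    ``stress_mag``) the correct-pairing Pearson coefficient is computed
    once.  For each segment length dl, each junction longer than dl is
    subdivided into dl-long segments (the remainder complemented with
    neighbouring points), intensities are permuted within each segment,
    and one randomized coefficient per junction results.  The coupling
    length is the smallest dl at which the median randomized coefficient
    falls below half the median correct coefficient: coarser shuffles
    destroy the correlation, finer ones do not, so the crossover marks
    the scale on which stress and marker recruitment co-vary.

    Returns a DataFrame with columns dl_um, median_correct,
    median_randomized, ratio, n_junctions, low_n; the estimate is the
    smallest dl with ratio < 0.5.
    """
    correct = {}
    for j, js in enumerate(junction_samples):
        I, s = np.asarray(js["intensity"]), np.asarray(js["stress_mag"])
        if len(I) >= 3 and np.std(I) > 0 and np.std(s) > 0:
            correct[j] = float(np.corrcoef(I, s)[0, 1])
    rows = []
    for dl in np.asarray(dl_grid, dtype=float):
        cor, rand = [], []
        for j, js in enumerate(junction_samples):
            if j not in correct:
                continue
            arc = np.asarray(js["arc_um"])
            groups = _segment_bounds(arc, dl)
            if groups is None:
                continue
            I = np.asarray(js["intensity"]).copy()
            s = np.asarray(js["stress_mag"])
            for sel in groups:
                I[sel] = I[rng.permutation(sel)]
            if np.std(I) > 0:
                rand.append(float(np.corrcoef(I, s)[0, 1]))
                cor.append(correct[j])
        if not cor:
            rows.append(
                dict(dl_um=dl, median_correct=np.nan, median_randomized=np.nan,
                     ratio=np.nan, n_junctions=0, low_n=True)
            )
            continue
        mc, mr = float(np.median(cor)), float(np.median(rand))
        rows.append(
            dict(
                dl_um=dl,
                median_correct=mc,
                median_randomized=mr,
                ratio=mr / mc if mc != 0 else np.nan,
                n_junctions=len(cor),
                low_n=len(cor) < min_junctions,
            )
        )
    return pd.DataFrame(rows)


def estimate_coupling_length(curves: pd.DataFrame) -> float:
    """Smallest segment length whose randomized/correct ratio is < 0.5."""
    ok = curves.dropna(subset=["ratio"])
    below = ok[ok["ratio"] < 0.5]
    if below.empty:
        return float("nan")
    return float(below["dl_um"].iloc[0])


def junction_autocorrelation_length(
    junction_samples: list[dict], max_lag: int | None = None
) -> tuple[float, pd.DataFrame]:
    """Arc-length scale of sub-junctional intensity autocorrelation.

    Per junction the normalized (Pearson) autocorrelation is computed at
    integer sample lags; the median across junctions is taken per lag,
    and the reported length is the arc-length lag at which the median
    first drops below 0.5 (linear interpolation between lags).
    """
    spacings, coeffs = [], []
    for js in junction_samples:
        I = np.asarray(js["intensity"], dtype=float)
        arc = np.asarray(js["arc_um"])
        if len(I) < 10:
            continue
        spacing = arc[-1] / (len(arc) - 1)
        spacings.append(spacing)
        nmax = len(I) - 3 if max_lag is None else min(max_lag, len(I) - 3)
        ac = np.full(nmax + 1, np.nan)
        ac[0] = 1.0
        for m in range(1, nmax + 1):
            a, b = I[:-m], I[m:]
            if np.std(a) > 0 and np.std(b) > 0:
                ac[m] = np.corrcoef(a, b)[0, 1]
        coeffs.append(ac)
    if not coeffs:
        raise ValueError("no junction with >= 10 samples")
    spacing = float(np.median(spacings))
    nlag = max(len(c) for c in coeffs)
    med = np.full(nlag, np.nan)
    for m in range(nlag):
        vals = [c[m] for c in coeffs if len(c) > m and np.isfinite(c[m])]
        if vals:
            med[m] = np.median(vals)
    curve = pd.DataFrame({"lag_um": np.arange(nlag) * spacing, "median_autocorr": med})
    length = float("nan")
    for m in range(1, nlag):
        if np.isfinite(med[m]) and med[m] < 0.5:
            # linear interpolation between lag m-1 and m
            y0, y1 = med[m - 1], med[m]
            frac = (0.5 - y0) / (y1 - y0) if y1 != y0 else 0.0
            length = (m - 1 + frac) * spacing
            break
    return length, curve


def classify_edges_min_k(cgraph, min_k_filter: int | None = None) -> pd.DataFrame:
    """Stratify junctions by minimal connectivity degree.

    ``min_k`` of an edge is the smaller connectivity degree k of its two
    cells -- a proxy for peripheral (min_k = 1) versus embedded
    junctions.  Returns a long-format table (junction_id, min_k,
    f_mag_pN, length_um, stress_pN_per_um), optionally filtered to one
    stratum.
    """
    g = cgraph.graph
    rows = []
    for a, b, d in g.edges(data=True):
        f = d.get("f_fem") if d.get("f_fem") is not None else d.get("f_balance")
        mag = np.nan if f is None else float(np.linalg.norm(f))
        length = d.get("length_um")
        rows.append(
            dict(
                junction_id=d["junction_id"],
                min_k=d["min_k"],
                f_mag_pN=mag,
                length_um=length,
                stress_pN_per_um=(mag / length if length else np.nan),
            )
        )
    df = pd.DataFrame(rows)
    if min_k_filter is not None:
        df = df[df["min_k"] == min_k_filter].reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------


def resample_and_normalize(
    times_s: np.ndarray,
    values: np.ndarray,
    target_interval_s: float = 240.0,
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Bin-average a series to a fixed frame interval and normalize.

    Series acquired faster than the target rate are averaged over
    ``target_interval_s`` bins; slower series pass through with a
    warning.  Each component is then normalized to unit variance so
    series from different cells or junctions can be pooled.
    """
    t = np.asarray(times_s, dtype=float)
    v = np.asarray(values, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    dt = np.median(np.diff(t))
    if dt > target_interval_s:
        warnings.warn(
            f"native interval {dt:.0f}s exceeds target {target_interval_s:.0f}s; "
            "passing series through unchanged"
        )
        out_t, out_v = t, v.copy()
    else:
        nbins = int(np.floor((t[-1] - t[0]) / target_interval_s)) + 1
        idx = np.clip(((t - t[0]) // target_interval_s).astype(int), 0, nbins - 1)
        out_v = np.zeros((nbins, v.shape[1]))
        counts = np.zeros(nbins)
        np.add.at(counts, idx, 1)
        for c in range(v.shape[1]):
            acc = np.zeros(nbins)
            np.add.at(acc, idx, v[:, c])
            out_v[:, c] = acc / np.maximum(counts, 1)
        keep = counts > 0
        out_v = out_v[keep]
        out_t = t[0] + target_interval_s * (np.flatnonzero(keep) + 0.5)
    if normalize:
        sd = out_v.std(axis=0)
        if np.any(sd == 0):
            warnings.warn("constant series: variance normalization undefined")
        out_v = out_v / np.where(sd == 0, 1.0, sd)
    return out_t, out_v


def vector_cross_correlation(
    f1: np.ndarray, f2: np.ndarray, lags: np.ndarray | list[int] = (0,),
    min_overlap: int = 5,
) -> pd.DataFrame:
    """Temporal vector cross-correlation c(dt) of two 2-vector series.

    c_f1,f2(dt) = 1/2 [ corr(f1x(t+dt), f2x(t)) + corr(f1y(t+dt), f2y(t)) ],
    the mean of the diagonal componentwise correlations; for isotropic
    statistics the off-diagonal terms average to zero and the two
    diagonal terms estimate the same quantity, so their mean is the
    rotation-invariant scalar correlation in [-1, 1].  Positive dt means
    f1 lags behind f2.  Lags with fewer than ``min_overlap`` overlapping
    frames are reported as NaN.
    """
    a = np.atleast_2d(np.asarray(f1, dtype=float))
    b = np.atleast_2d(np.asarray(f2, dtype=float))
    if a.shape != b.shape:
        raise ValueError("tracks must be equal-length and aligned")
    n = a.shape[0]
    rows = []
    for dt in lags:
        dt = int(dt)
        if dt >= 0:
            a_w, b_w = a[dt:], b[: n - dt]
        else:
            a_w, b_w = a[:n + dt], b[-dt:]
        if len(a_w) < min_overlap:
            rows.append(dict(dt=dt, c=np.nan, n=len(a_w)))
            continue
        cs = []
        for comp in range(a.shape[1]):
            x, y = a_w[:, comp], b_w[:, comp]
            if np.std(x) == 0 or np.std(y) == 0:
                cs.append(np.nan)
            else:
                cs.append(np.corrcoef(x, y)[0, 1])
        rows.append(dict(dt=dt, c=float(np.nanmean(cs)), n=len(a_w)))
    return pd.DataFrame(rows)


def cross_correlation_matrix(f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
    """Full 2x2 componentwise correlation matrix at zero lag."""
    a = np.asarray(f1, dtype=float)
    b = np.asarray(f2, dtype=float)
    out = np.full((2, 2), np.nan)
    for i in range(2):
        for j in range(2):
            if np.std(a[:, i]) > 0 and np.std(b[:, j]) > 0:
                out[i, j] = np.corrcoef(a[:, i], b[:, j])[0, 1]
    return out


def transmission_analysis(
    junction_tracks: dict[int, np.ndarray],
    residual_track: np.ndarray,
    cell_id: int | None = None,
) -> pd.DataFrame:
    """Force-transmission signature of one (middle) cell.

    ``junction_tracks`` maps junction id -> (n_frames, 2) force series
    f_i,m exerted on the cell; ``residual_track`` is the cell's
    (n_frames, 2) residual traction force series.  For each junction i
    the zero-lag correlations c(f_i,m, sum_{j != i} f_j,m) and
    c(f_i,m, f_res,m) are reported.  A passive force transducer gives
    junction-junction correlation -> -1 with no junction-traction
    correlation; an anchored cell that absorbs junctional fluctuations
    into its own tractions gives the reverse.
    """
    if len(junction_tracks) < 2:
        raise ValueError("transmission analysis needs a cell with >= 2 junctions")
    jids = sorted(junction_tracks)
    rows = []
    for i in jids:
        fi = np.asarray(junction_tracks[i], dtype=float)
        others = np.sum([junction_tracks[j] for j in jids if j != i], axis=0)
        c_jj = vector_cross_correlation(fi, others, [0])["c"].iloc[0]
        c_jt = vector_cross_correlation(fi, residual_track, [0])["c"].iloc[0]
        rows.append(
            dict(cell_id=cell_id, junction_id=i, c_junction_junction=c_jj,
                 c_junction_traction=c_jt, n_frames=len(fi))
        )
    return pd.DataFrame(rows)
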