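"""Traction force microscopy: forward elastic model, bead tracking, FTTC.

The substrate is modelled as an isotropic, linear elastic, infinite
half-space.  Surface displacements follow from the traction field by
convolution with the Boussinesq Green function

    G_ij(r) = (1+nu) / (pi E r^3) * [ (1-nu) r^2 delta_ij + nu r_i r_j ]

Traction reconstruction inverts this convolution per Fourier mode with
zero-order Tikhonov regularization (regularized Fourier-transform
traction cytometry, FTTC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from skimage.feature import peak_local_max

from .fields import SubstrateModel, VectorField2D

__all__ = [
    "FttcConfig",
    "boussinesq_point_displacement",
    "boussinesq_displacement",
    "track_bead_displacements",
    "interpolate_to_grid",
    "fttc_reconstruct",
    "greens_tensor_fourier",
    "lambda2_from_legacy",
]


@dataclass
class FttcConfig:
    """Parameters of bead tracking and traction reconstruction.

    ``template_size`` is the square block (px) matched between the
    unstrained reference and the deformed bead image; 15-25 px is the
    usual range, with smaller templates on stiffer substrates.
    ``significance_ratio`` is the minimum ratio of the primary to the
    secondary correlation peak for a displacement to be accepted.
    ``regularization`` is the dimensionless Tikhonov lambda^2 applied to
    the operator normalized by its largest singular value (see
    :func:`fttc_reconstruct`).
    """

    template_size: int = 21
    max_shift: int = 16
    significance_ratio: float = 1.5
    regularization: float = 1e-3
    output_spacing: float = 1.5

    def __post_init__(self) -> None:
        if self.template_size < 5:
            raise ValueError("template_size must be >= 5 px")
        if self.regularization < 0:
            raise ValueError("regularization (lambda^2) must be >= 0")


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def boussinesq_point_displacement(
    points_xy: np.ndarray, force_pn: np.ndarray, substrate: SubstrateModel
) -> np.ndarray:
    """Surface displacement (um) of a point force (pN) at the origin.

    Closed-form Green function evaluation, mainly used as an oracle for
    the gridded convolution.
    """
    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
    E, nu = substrate.youngs_modulus, substrate.poisson
    r = np.linalg.norm(pts, axis=1)
    if np.any(r == 0):
        raise ValueError("point displacement is singular at r=0")
    pref = (1 + nu) / (np.pi * E * r**3)
    out = np.empty_like(pts)
    f = np.asarray(force_pn, dtype=float)
    rr_f = pts[:, 0] * f[0] + pts[:, 1] * f[1]
    out[:, 0] = pref * ((1 - nu) * r**2 * f[0] + nu * pts[:, 0] * rr_f)
    out[:, 1] = pref * ((1 - nu) * r**2 * f[1] + nu * pts[:, 1] * rr_f)
    return out


def _boussinesq_kernel(
    ny: int, nx: int, spacing: float, substrate: SubstrateModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cell-integrated Green-function kernel on a (2ny, 2nx) padded grid.

    Every kernel entry is the exact integral of G over one square grid
    cell, obtained from the closed-form antiderivatives

        int int x^2/r^3 dx dy = y ln(x + r)
        int int y^2/r^3 dx dy = x ln(y + r)
        int int x y/r^3 dx dy = -r

    evaluated at the four cell corners.  This renders the singular
    self-cell (an improper but convergent integral) and the strongly
    curved near-field cells exactly, so the discrete operator is a
    well-defined quadrature of the continuous convolution.
    """
    E, nu = substrate.youngs_modulus, substrate.poisson
    Ny, Nx = 2 * ny, 2 * nx
    iy = np.arange(Ny)
    ix = np.arange(Nx)
    # signed shifts with wrap-around ordering for circular convolution
    sy = np.where(iy <= Ny // 2, iy, iy - Ny) * spacing
    sx = np.where(ix <= Nx // 2, ix, ix - Nx) * spacing
    h = spacing / 2.0
    pref = (1 + nu) / (np.pi * E)

    def corner_eval(fn):
        out = np.zeros((Ny, Nx))
        for sgn_x, x_off in ((1, h), (-1, -h)):
            for sgn_y, y_off in ((1, h), (-1, -h)):
                X, Y = np.meshgrid(sx + x_off, sy + y_off)
                out += sgn_x * sgn_y * fn(X, Y)
        return out

    def I_x2(x, y):  # antiderivative of x^2 / r^3
        r = np.hypot(x, y)
        return y * np.log(x + r)

    def I_y2(x, y):
        r = np.hypot(x, y)
        return x * np.log(y + r)

    def I_xy(x, y):
        return -np.hypot(x, y)

    # G_xx = pref [ (1-nu)/r + nu x^2/r^3 ] = pref [ (1-nu) y^2/r^3 + x^2/r^3 ]
    gxx = pref * corner_eval(lambda x, y: (1 - nu) * I_y2(x, y) + I_x2(x, y))
    gyy = pref * corner_eval(lambda x, y: (1 - nu) * I_x2(x, y) + I_y2(x, y))
    gxy = pref * nu * corner_eval(I_xy)
    return gxx, gxy, gyy


def boussinesq_displacement(
    traction: VectorField2D, substrate: SubstrateModel
) -> VectorField2D:
    """Forward map traction (Pa) -> surface displacement (um).

    FFT convolution on a grid zero-padded by a factor 2 per axis to
    suppress periodic wrap-around of the long-ranged kernel; the r=0
    self-term is handled analytically (see ``_boussinesq_kernel``).
    Linear in the traction and in 1/E.
    """
    ny, nx = traction.shape
    gxx, gxy, gyy = _boussinesq_kernel(ny, nx, traction.spacing, substrate)
    tx = np.zeros((2 * ny, 2 * nx))
    ty = np.zeros_like(tx)
    tx[:ny, :nx] = traction.values[:, :, 0]
    ty[:ny, :nx] = traction.values[:, :, 1]
    Tx = sfft.rfft2(tx)
    Ty = sfft.rfft2(ty)
    Gxx = sfft.rfft2(gxx)
    Gxy = sfft.rfft2(gxy)
    Gyy = sfft.rfft2(gyy)
    ux = sfft.irfft2(Gxx * Tx + Gxy * Ty, s=tx.shape)[:ny, :nx]
    uy = sfft.irfft2(Gxy * Tx + Gyy * Ty, s=tx.shape)[:ny, :nx]
    out = np.stack([ux, uy], axis=-1)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite displacement from forward model")
    return VectorField2D(traction.origin, traction.spacing, out)


# ---------------------------------------------------------------------------
# bead tracking
# ---------------------------------------------------------------------------


def _fit_1d(c0: float, c1: float, c2: float) -> float:
    """Sub-pixel vertex from three samples around a correlation peak.

    Gaussian (log-parabola) fit when all samples are positive -- exact
    for the Gaussian-shaped peaks of bead correlations -- falling back
    to a plain 3-point quadratic fit otherwise.
    """
    if c0 > 0 and c1 > 0 and c2 > 0:
        l0, l1, l2 = np.log(c0), np.log(c1), np.log(c2)
        denom = l0 - 2 * l1 + l2
        if denom < 0:
            return float(np.clip(0.5 * (l0 - l2) / denom, -0.5, 0.5))
    denom = c0 - 2 * c1 + c2
    if denom < 0:
        return float(np.clip(0.5 * (c0 - c2) / denom, -0.5, 0.5))
    return 0.0


def _subpixel_offset(score: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    py, px = peak
    dy = dx = 0.0
    if 0 < py < score.shape[0] - 1:
        dy = _fit_1d(score[py - 1, px], score[py, px], score[py + 1, px])
    if 0 < px < score.shape[1] - 1:
        dx = _fit_1d(score[py, px - 1], score[py, px], score[py, px + 1])
    return dy, dx


def _ncc_map(template: np.ndarray, window: np.ndarray) -> np.ndarray:
    """Normalized cross-correlation of a template over a search window."""
    th, tw = template.shape
    wh, ww = window.shape
    oh, ow = wh - th + 1, ww - tw + 1
    t = template - template.mean()
    tnorm = np.sqrt((t**2).sum())
    # sliding sums via cumulative-sum integral images
    ii = np.zeros((wh + 1, ww + 1))
    ii[1:, 1:] = np.cumsum(np.cumsum(window, axis=0), axis=1)
    ii2 = np.zeros((wh + 1, ww + 1))
    ii2[1:, 1:] = np.cumsum(np.cumsum(window**2, axis=0), axis=1)

    def box(i):
        return i[th:, tw:] - i[:-th, tw:] - i[th:, :-tw] + i[:-th, :-tw]

    s1 = box(ii)
    s2 = box(ii2)
    npix = th * tw
    var = s2 - s1**2 / npix
    var = np.maximum(var, 0.0)
    # cross term by FFT-free direct correlation (small arrays)
    from scipy.signal import fftconvolve

    cross = fftconvolve(window, t[::-1, ::-1], mode="valid")
    denom = tnorm * np.sqrt(var)
    out = np.zeros((oh, ow))
    good = denom > 1e-12 * max(tnorm, 1.0)
    out[good] = cross[good] / denom[good]
    return np.clip(out, -1.0, 1.0)


def _refine_fractional(
    template: np.ndarray, window: np.ndarray, iy: int, ix: int,
    init: tuple[float, float],
) -> tuple[float, float]:
    """Maximize the interpolated NCC at fractional shifts.

    The integer-shift score map is contaminated by neighbouring beads,
    which biases 3-point vertex fits; maximizing the correlation of the
    template against the cubic-interpolated window instead finds the
    true continuous peak (exactly zero offset for identical images).
    """
    from scipy.ndimage import map_coordinates
    from scipy.optimize import minimize

    th, tw = template.shape
    t = template - template.mean()
    tnorm = np.sqrt((t**2).sum())
    gy, gx = np.mgrid[0:th, 0:tw]

    def neg_ncc(s):
        sy, sx = s
        w = map_coordinates(
            window, [gy + iy + sy, gx + ix + sx], order=3, mode="nearest"
        )
        wc = w - w.mean()
        denom = tnorm * np.sqrt((wc**2).sum())
        if denom <= 0:
            return 0.0
        return -(t * wc).sum() / denom

    res = minimize(
        neg_ncc, np.asarray(init), method="Nelder-Mead",
        options={"xatol": 0.02, "fatol": 1e-6, "maxiter": 40},
    )
    sy, sx = np.clip(res.x, -1.0, 1.0)
    return float(sy), float(sx)


def track_bead_displacements(
    reference: np.ndarray,
    deformed: np.ndarray,
    config: FttcConfig,
    pixel_size: float = 1.0,
):
    """Block-matching bead tracking between reference and deformed images.

    Beads are detected as local intensity maxima in the unstrained
    reference frame.  A square template centred on each bead is matched
    in the deformed image by maximizing the normalized cross-correlation
    score within ``+-max_shift`` px, refined to sub-pixel resolution by a
    quadratic fit around the peak.  Candidates whose primary peak is not
    at least ``significance_ratio`` times the secondary peak (outside a
    2-px exclusion zone) are rejected as insignificant matches.

    Returns
    -------
    positions : (N, 2) float array, bead xy positions in um
    displacements : (N, 2) float array, displacements in um
    """
    ref = np.asarray(reference, dtype=float)
    defo = np.asarray(deformed, dtype=float)
    if ref.shape != defo.shape:
        raise ValueError("reference and deformed images must have equal shape")
    half = config.template_size // 2
    m = config.max_shift
    thresh = ref.mean() + 0.5 * ref.std()
    peaks = peak_local_max(ref, min_distance=3, threshold_abs=thresh)
    if len(peaks) == 0:
        warnings.warn("no beads detected in reference image")
        return np.empty((0, 2)), np.empty((0, 2))
    positions = []
    disps = []
    H, W = ref.shape
    for py, px in peaks:
        y0, y1 = py - half, py + half + 1
        x0, x1 = px - half, px + half + 1
        if y0 - m < 0 or x0 - m < 0 or y1 + m > H or x1 + m > W:
            continue
        template = ref[y0:y1, x0:x1]
        window = defo[y0 - m : y1 + m, x0 - m : x1 + m]
        score = _ncc_map(template, window)
        iy, ix = np.unravel_index(np.argmax(score), score.shape)
        best = score[iy, ix]
        # secondary peak outside a 4-px exclusion zone around the primary
        masked = score.copy()
        masked[max(0, iy - 4) : iy + 5, max(0, ix - 4) : ix + 5] = -np.inf
        second = masked.max()
        if second > 0 and best < config.significance_ratio * second:
            continue
        if best <= 0:
            continue
        dy0, dx0 = _subpixel_offset(score, (iy, ix))
        dy, dx = _refine_fractional(template, window, iy, ix, (dy0, dx0))
        shift = np.array([ix - m + dx, iy - m + dy])
        positions.append([px, py])
        disps.append(shift)
    if not positions:
        warnings.warn("all bead matches rejected by significance test")
        return np.empty((0, 2)), np.empty((0, 2))
    return (
        np.asarray(positions, dtype=float) * pixel_size,
        np.asarray(disps, dtype=float) * pixel_size,
    )


def interpolate_to_grid(
    positions_um: np.ndarray,
    displacements_um: np.ndarray,
    output_spacing: float,
    origin: tuple[float, float] | None = None,
    shape: tuple[int, int] | None = None,
) -> VectorField2D:
    """Scattered bead displacements -> regular grid displacement field.

    Piecewise-linear interpolation inside the convex hull of the samples
    with nearest-neighbour extrapolation at the margins.  When origin and
    (ny, nx) shape are not given, a square grid covering the sample
    bounding box is used.
    """
    pos = np.asarray(positions_um, dtype=float)
    disp = np.asarray(displacements_um, dtype=float)
    if len(pos) < 4:
        raise ValueError("need at least 4 displacement samples")
    if np.linalg.matrix_rank(pos - pos.mean(axis=0)) < 2:
        raise ValueError("degenerate (collinear) sample geometry")
    if origin is None or shape is None:
        from .fields import grid_covering

        bbox = (pos[:, 0].min(), pos[:, 1].min(), pos[:, 0].max(), pos[:, 1].max())
        origin, shape = grid_covering(bbox, output_spacing)
    lin = LinearNDInterpolator(pos, disp)
    near = NearestNDInterpolator(pos, disp)
    xs = origin[0] + output_spacing * np.arange(shape[1])
    ys = origin[1] + output_spacing * np.arange(shape[0])
    XX, YY = np.meshgrid(xs, ys)
    pts = np.column_stack([XX.ravel(), YY.ravel()])
    vals = lin(pts)
    bad = ~np.isfinite(vals[:, 0])
    if np.any(bad):
        vals[bad] = near(pts[bad])
    return VectorField2D(origin, output_spacing, vals.reshape(shape[0], shape[1], 2))


# ---------------------------------------------------------------------------
# inverse model (FTTC)
# ---------------------------------------------------------------------------


def greens_tensor_fourier(
    kx: np.ndarray, ky: np.ndarray, substrate: SubstrateModel
) -> np.ndarray:
    """Fourier Boussinesq tensor G_hat(k), shape (..., 2, 2), units um/Pa.

    G_hat(k) = 2 (1+nu) / (E k^3) * (k^2 I - nu k k^T); Hermitian positive
    semi-definite for k != 0 with eigenvalues 2(1+nu)(1-nu)/(E k) along
    k_hat and 2(1+nu)/(E k) across it.
    """
    E, nu = substrate.youngs_modulus, substrate.poisson
    k2 = kx**2 + ky**2
    zero = k2 == 0
    k2s = np.where(zero, 1.0, k2)
    pref = 2.0 * (1 + nu) / (E * np.sqrt(k2s) ** 3)
    G = np.empty(k2.shape + (2, 2))
    G[..., 0, 0] = pref * ((1 - nu) * k2 + nu * ky**2)
    G[..., 1, 1] = pref * ((1 - nu) * k2 + nu * kx**2)
    G[..., 0, 1] = -pref * nu * kx * ky
    G[..., 1, 0] = G[..., 0, 1]
    G[zero] = 0.0
    return G


def lambda2_from_legacy(
    lambda2_legacy: float, substrate: SubstrateModel, n_padded: int, spacing: float
) -> float:
    """Map a raw-operator lambda^2 to the normalized-operator scale.

    Historic FTTC implementations quote lambda^2 relative to the
    unnormalized Boussinesq operator in (Pa, um) units (values of order
    5e-8 to 1e-6).  This package defines lambda^2 relative to the
    operator scaled by its largest singular value s_max = 2(1+nu)/(E k_min),
    so the equivalent value is lambda2_legacy / s_max^2.
    """
    kmin = 2 * np.pi / (n_padded * spacing)
    smax = 2 * (1 + substrate.poisson) / (substrate.youngs_modulus * kmin)
    return lambda2_legacy / smax**2


def fttc_reconstruct(
    displacement: VectorField2D,
    substrate: SubstrateModel,
    lambda2: float = 0.0,
) -> VectorField2D:
    """Regularized FTTC: displacement field (um) -> traction field (Pa).

    Per Fourier mode k != 0 solves the zero-order Tikhonov system

        T_hat = (Gn^H Gn + lambda^2 I)^-1 Gn^H u_hat / s_max,

    where Gn = G_hat / s_max is the Boussinesq tensor normalized by its
    largest singular value, making ``lambda2`` a dimensionless
    regularization strength comparable across grids and substrates.  The
    k = 0 mode is set to zero (no net force).  The grid is zero-padded by
    a factor 2 per axis before the transform.
    """
    ny, nx = displacement.shape
    if ny != nx:
        raise ValueError("FTTC requires a square grid")
    if lambda2 < 0:
        raise ValueError("lambda2 must be >= 0")
    h = displacement.spacing
    N = 2 * nx
    u = np.zeros((N, N, 2))
    u[:ny, :nx] = displacement.values
    U = np.stack([np.fft.fft2(u[:, :, 0]), np.fft.fft2(u[:, :, 1])], axis=-1)
    freqs = 2 * np.pi * np.fft.fftfreq(N, d=h)
    KX, KY = np.meshgrid(freqs, freqs)
    G = greens_tensor_fourier(KX, KY, substrate)
    kmin = 2 * np.pi / (N * h)
    smax = 2 * (1 + substrate.poisson) / (substrate.youngs_modulus * kmin)
    Gn = G / smax
    # (Gn^T Gn + lambda^2 I)^-1 Gn^T, all 2x2 real symmetric per mode
    A = np.einsum("...ji,...jk->...ik", Gn, Gn)
    A[..., 0, 0] += lambda2
    A[..., 1, 1] += lambda2
    det = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
    k2 = KX**2 + KY**2
    nonzero = k2 > 0
    inv = np.zeros_like(A)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv[..., 0, 0] = A[..., 1, 1] / det
        inv[..., 1, 1] = A[..., 0, 0] / det
        inv[..., 0, 1] = -A[..., 0, 1] / det
        inv[..., 1, 0] = -A[..., 1, 0] / det
    inv[~nonzero] = 0.0
    rhs = np.einsum("...ji,...j->...i", Gn, U)
    That = np.einsum("...ij,...j->...i", inv, rhs) / smax
    That[~nonzero] = 0.0
    tx = np.real(np.fft.ifft2(That[..., 0]))[:ny, :nx]
    ty = np.real(np.fft.ifft2(That[..., 1]))[:ny, :nx]
    return VectorField2D(displacement.origin, h, np.stack([tx, ty], axis=-1))
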