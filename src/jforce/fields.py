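"""Regular 2-D vector fields and substrate description.

Unit system used throughout the package: lengths in micrometres (um),
stresses/tractions in pascal (Pa = pN/um^2), forces in piconewton (pN),
energies in attojoule (aJ = pN*um).  With these units the Boussinesq
surface displacement of a point force, u = F (1+nu) / (pi E r), needs no
conversion constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator


@dataclass(frozen=True)
class SubstrateModel:
    """Isotropic, linear elastic, infinite half-space substrate.

    Parameters
    ----------
    youngs_modulus : float
        Young's modulus E of the gel in Pa (typical polyacrylamide TFM
        substrates: 8000-35000 Pa).
    poisson : float
        Poisson ratio nu, dimensionless, in [0, 0.5].
    """

    youngs_modulus: float
    poisson: float = 0.5

    def __post_init__(self) -> None:
        if not self.youngs_modulus > 0:
            raise ValueError("youngs_modulus must be positive")
        if not 0.0 <= self.poisson <= 0.5:
            raise ValueError("poisson must lie in [0, 0.5]")


@dataclass
class VectorField2D:
    """A 2-vector field sampled on a regular square-spaced grid.

    ``values`` has shape (ny, nx, 2) with the last axis being (x, y)
    components.  The sample at index (iy, ix) sits at physical position
    ``origin + spacing * (ix, iy)`` in um.  Used both for displacement
    fields (values in um) and traction fields (values in Pa).
    """

    origin: tuple[float, float]
    spacing: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != 2:
            raise ValueError("values must have shape (ny, nx, 2)")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    @property
    def x(self) -> np.ndarray:
        """x coordinates of the grid columns (um)."""
        return self.origin[0] + self.spacing * np.arange(self.values.shape[1])

    @property
    def y(self) -> np.ndarray:
        """y coordinates of the grid rows (um)."""
        return self.origin[1] + self.spacing * np.arange(self.values.shape[0])

    @property
    def pixel_area(self) -> float:
        """Area of one grid cell in um^2."""
        return self.spacing**2

    def copy(self) -> "VectorField2D":
        return VectorField2D(self.origin, self.spacing, self.values.copy())

    def interpolator(self, fill_value: float = 0.0):
        """Bilinear interpolator mapping (N, 2) xy points (um) -> (N, 2) vectors."""
        itp = RegularGridInterpolator(
            (self.y, self.x),
            self.values,
            method="linear",
            bounds_error=False,
            fill_value=fill_value,
        )

        def _eval(points_xy: np.ndarray) -> np.ndarray:
            pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
            return itp(pts[:, ::-1])

        return _eval

    def sample(self, points_xy: np.ndarray) -> np.ndarray:
        return self.interpolator()(points_xy)

    def integral(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Integrate the field over the grid (optionally over a boolean mask).

        For a traction field in Pa this returns a net force in pN.
        Accumulates in extended precision: balance checks compare sums of
        ~1e5 pN magnitude down to the 1e-9 pN level.
        """
        if mask is None:
            vals = self.values.reshape(-1, 2)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.shape:
                raise ValueError("mask shape does not match field grid")
            vals = self.values[mask]
        acc = vals.astype(np.longdouble).sum(axis=0) * np.longdouble(self.pixel_area)
        return acc.astype(float)

    def to_dataframe(self):
        """Long-format export with columns x_um, y_um, tx, ty."""
        import pandas as pd

        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame(
            {
                "x_um": xx.ravel(),
                "y_um": yy.ravel(),
                "vx": self.values[:, :, 0].ravel(),
                "vy": self.values[:, :, 1].ravel(),
            }
        )

    @classmethod
    def from_grid(
        cls, origin: tuple[float, float], spacing: float, shape: tuple[int, int]
    ) -> "VectorField2D":
        """All-zero field of grid shape (ny, nx)."""
        return cls(origin, spacing, np.zeros((shape[0], shape[1], 2)))


def grid_covering(
    bbox_um: tuple[float, float, float, float], spacing: float, square: bool = True
) -> tuple[tuple[float, float], tuple[int, int]]:
    """Origin and (ny, nx) of a regular grid covering a bounding box.

    ``bbox_um`` is (xmin, ymin, xmax, ymax).  When ``square`` the grid is
    made square (nx == ny) by symmetric enlargement, as required by the
    Fourier traction reconstruction.
    """
    xmin, ymin, xmax, ymax = bbox_um
    nx = int(np.ceil((xmax - xmin) / spacing)) + 1
    ny = int(np.ceil((ymax - ymin) / spacing)) + 1
    if square:
        n = max(nx, ny)
        xmin -= (n - nx) * spacing / 2
        ymin -= (n - ny) * spacing / 2
        nx = ny = n
    return (xmin, ymin), (ny, nx)
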