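"""Regular 3-D grids, rigid transforms and smooth random fields.

All volumes in the package live on an isotropic RAS grid whose world origin is
the volume centre (affine = diag(voxel) with a centring translation).  Rigid
transforms are expressed in world coordinates (mm / degrees) and applied about
the volume centre, which is also the rotation centre used when simulating head
repositioning between scan sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class Grid:
    """Isotropic 3-D sampling grid."""

    shape: tuple[int, int, int]
    voxel_size: float  # mm

    @property
    def affine(self) -> np.ndarray:
        """Voxel-to-world RAS affine with the world origin at the grid centre."""
        a = np.eye(4)
        a[:3, :3] = np.eye(3) * self.voxel_size
        a[:3, 3] = -0.5 * (np.asarray(self.shape) - 1) * self.voxel_size
        return a

    @property
    def fov(self) -> np.ndarray:
        return np.asarray(self.shape) * self.voxel_size

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates (mm) of all voxel centres, as a sparse meshgrid."""
        axes = [
            (np.arange(n) - 0.5 * (n - 1)) * self.voxel_size for n in self.shape
        ]
        return np.meshgrid(*axes, indexing="ij", sparse=True)


@dataclass(frozen=True)
class RigidTransform:
    """Rigid world-space transform: rotate (deg, xyz extrinsic) about the
    volume centre, then translate (mm)."""

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = Rotation.from_euler(
            "xyz", self.rotation_deg, degrees=True
        ).as_matrix()
        m[:3, 3] = self.translation_mm
        return m

    def inverse(self) -> "RigidTransform":
        r = Rotation.from_euler("xyz", self.rotation_deg, degrees=True)
        rinv = r.inv()
        tinv = -rinv.apply(np.asarray(self.translation_mm))
        return RigidTransform(
            tuple(rinv.as_euler("xyz", degrees=True)), tuple(tinv)
        )

    @property
    def is_identity(self) -> bool:
        return not (
            np.any(np.asarray(self.rotation_deg))
            or np.any(np.asarray(self.translation_mm))
        )


def apply_rigid(
    volume: np.ndarray,
    grid: Grid,
    transform: RigidTransform,
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Move the object in ``volume`` by ``transform``: out(x) = in(T⁻¹ x).

    ``order`` is the spline interpolation order (1 = trilinear, 4 = the
    4th-order B-spline used on the analysis side).
    """
    if transform.is_identity:
        return volume.copy()
    if abs(np.linalg.det(transform.matrix()[:3, :3]) - 1.0) > 1e-6:
        raise ValueError("transform is not rigid (non-unit determinant)")
    aff = grid.affine
    # voxel_in = inv(A) @ T^-1 @ A @ voxel_out
    m = np.linalg.inv(aff) @ transform.inverse().matrix() @ aff
    return ndimage.affine_transform(
        volume, m[:3, :3], offset=m[:3, 3], order=order, cval=cval,
        mode="constant", prefilter=order > 1,
    )


def bandlimited_field(
    grid: Grid, cutoff_mm: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean, unit-SD Gaussian random field with no spatial-frequency
    content above ``1 / cutoff_mm`` (hard spectral cutoff)."""
    white = rng.standard_normal(grid.shape)
    freqs = [np.fft.fftfreq(n, d=grid.voxel_size) for n in grid.shape]
    kx, ky, kz = np.meshgrid(*freqs, indexing="ij", sparse=True)
    k = np.sqrt(kx**2 + ky**2 + kz**2)
    spec = np.fft.fftn(white)
    spec[k > 1.0 / cutoff_mm] = 0.0
    f = np.fft.ifftn(spec).real
    sd = f.std()
    if sd == 0:
        return np.zeros(grid.shape)
    return (f - f.mean()) / sd


def scaled_exp_field(
    g: np.ndarray, mask: np.ndarray, lo: float, hi: float
) -> np.ndarray:
    """Map a smooth field affinely so that exp(field) spans exactly
    [lo, hi] within ``mask``, and return exp(field) everywhere.

    Positivity is guaranteed by the exponential; smoothness is preserved by
    the affine rescaling.
    """
    if lo <= 0 or hi < lo:
        raise ValueError("require 0 < lo <= hi")
    gm = g[mask]
    span = gm.max() - gm.min()
    if span == 0:
        return np.full(g.shape, 0.5 * (lo + hi))
    s = (g - gm.min()) / span  # 0..1 within mask
    return np.exp(np.log(lo) + s * (np.log(hi) - np.log(lo)))


def dct_axis_factors(grid: Grid, cutoff_mm: float) -> list[np.ndarray]:
    """Per-axis cosine factors of a separable low-frequency basis whose
    shortest half-wavelength is ``cutoff_mm``.  Factor i has shape
    ``(n_i, k_i + 1)``."""
    factors = []
    for n in grid.shape:
        length = n * grid.voxel_size
        kmax = int(np.floor(2.0 * length / cutoff_mm))
        x = (np.arange(n) + 0.5) / n
        factors.append(
            np.stack([np.cos(np.pi * k * x) for k in range(kmax + 1)], axis=1)
        )
    return factors


class SmoothFieldFitter:
    """Penalized least-squares projection of masked voxel data onto a
    low-frequency separable cosine basis; the workhorse behind bias-field
    estimation.

    ``ridge`` adds a smoothness prior that damps coefficients near the spatial
    cutoff (weight grows with |k|^4, as for a squared-Laplacian energy), which
    keeps the co-estimated bias fields from chasing noise; 0 gives plain least
    squares.  The fit remains linear in the data, so intensity-scale
    invariance of downstream posteriors is preserved.
    """

    def __init__(
        self, grid: Grid, mask: np.ndarray, cutoff_mm: float, ridge: float = 0.0
    ):
        self.grid = grid
        self.mask = mask
        self._factors = dct_axis_factors(grid, cutoff_mm)
        ix, iy, iz = np.nonzero(mask)
        fx, fy, fz = (f[i] for f, i in zip(self._factors, (ix, iy, iz)))
        nk = [f.shape[1] for f in self._factors]
        nb = nk[0] * nk[1] * nk[2]
        self._b = np.einsum("vi,vj,vk->vijk", fx, fy, fz).reshape(len(ix), nb)
        gram = self._b.T @ self._b
        avg_diag = np.trace(gram) / nb
        if ridge > 0:
            kx, ky, kz = np.meshgrid(
                *(np.arange(n) / max(n - 1, 1) for n in nk), indexing="ij"
            )
            weight = (kx**2 + ky**2 + kz**2) ** 2
            gram[np.diag_indices_from(gram)] += ridge * avg_diag * weight.ravel()
        gram[np.diag_indices_from(gram)] += 1e-8 * avg_diag
        self._gram_inv = np.linalg.inv(gram)

    @property
    def n_basis(self) -> int:
        return self._b.shape[1]

    def fit_masked(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fit masked ``values`` (1-D, one per mask voxel); returns the
        coefficients and the smooth fit at the mask voxels."""
        coef = self._gram_inv @ (self._b.T @ values)
        return coef, self._b @ coef

    def evaluate(self, coef: np.ndarray) -> np.ndarray:
        """Evaluate a coefficient vector on the full grid (separable sum)."""
        fx, fy, fz = self._factors
        c = coef.reshape(fx.shape[1], fy.shape[1], fz.shape[1])
        return np.einsum("ijk,xi,yj,zk->xyz", c, fx, fy, fz, optimize=True)

    def fit(self, values: np.ndarray) -> np.ndarray:
        """Fit masked ``values`` and return the field on the full grid."""
        coef, _ = self.fit_masked(values)
        return self.evaluate(coef)
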