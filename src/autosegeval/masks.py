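"""Binary voxel masks on anisotropic grids, parametric organ shapes, and smooth warps.

The mask is the unit of all geometry in the package: a boolean voxel array
together with its physical voxel spacing (mm) and the physical position of
the first voxel centre (origin, mm). Masks may live on sub-grids of a larger
study grid; the origin records where the sub-grid sits, and two masks are
comparable whenever they share shape and spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class BinaryMask:
    """A 3D boolean voxel grid with physical spacing and origin.

    Parameters
    ----------
    voxels : ndarray of bool, shape (nx, ny, nz)
        Foreground indicator per voxel.
    spacing_mm : tuple of 3 floats
        Voxel size along each axis, strictly positive, in mm.
    origin_mm : tuple of 3 floats
        Physical coordinate of the centre of voxel (0, 0, 0), in mm.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3 or min(vox.shape) < 1:
            raise ValueError("voxels must be a 3D array with every axis length >= 1")
        if vox.dtype != bool:
            vox = vox.astype(bool)
        object.__setattr__(self, "voxels", vox)
        sp = tuple(float(s) for s in self.spacing_mm)
        if len(sp) != 3 or not all(np.isfinite(s) and s > 0 for s in sp):
            raise ValueError("spacing_mm must be three finite, strictly positive values")
        object.__setattr__(self, "spacing_mm", sp)
        og = tuple(float(o) for o in self.origin_mm)
        if len(og) != 3 or not all(np.isfinite(o) for o in og):
            raise ValueError("origin_mm must be three finite values")
        object.__setattr__(self, "origin_mm", og)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_ml(self) -> float:
        return self.n_foreground * float(np.prod(self.spacing_mm)) / 1000.0

    def same_grid(self, other: "BinaryMask") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing_mm, other.spacing_mm)

    def embed(self, grid_shape: tuple[int, int, int],
              grid_origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> "BinaryMask":
        """Place this (sub-grid) mask onto a larger grid with the same spacing.

        The offset between the two origins must be a whole number of voxels;
        foreground falling outside the target grid raises.
        """
        off = (np.asarray(self.origin_mm) - np.asarray(grid_origin_mm)) / np.asarray(self.spacing_mm)
        idx = np.rint(off).astype(int)
        if not np.allclose(off, idx, atol=1e-6):
            raise ValueError("origin offset is not voxel-aligned with the target grid")
        out = np.zeros(grid_shape, dtype=bool)
        sl_out, sl_in = [], []
        for ax in range(3):
            lo, hi = idx[ax], idx[ax] + self.shape[ax]
            if (lo < 0 or hi > grid_shape[ax]) and self.voxels.any():
                clipped = self.voxels[tuple(
                    slice(max(0, -idx[a]), min(self.shape[a], grid_shape[a] - idx[a]))
                    for a in range(3))]
                if clipped.sum() != self.n_foreground:
                    raise ValueError("mask foreground does not fit inside the target grid")
            sl_out.append(slice(max(lo, 0), min(hi, grid_shape[ax])))
            sl_in.append(slice(max(0, -lo), max(0, -lo) + (min(hi, grid_shape[ax]) - max(lo, 0))))
        out[tuple(sl_out)] = self.voxels[tuple(sl_in)]
        return BinaryMask(out, self.spacing_mm, grid_origin_mm)


def superellipsoid(shape: tuple[int, int, int],
                   spacing_mm,
                   center_mm,
                   semiaxes_mm,
                   exponent: float = 2.0,
                   origin_mm=(0.0, 0.0, 0.0)) -> BinaryMask:
    """Rasterise a superellipsoid |x/a|^n + |y/b|^n + |z/c|^n <= 1 onto a grid.

    Coordinates are voxel centres in mm. exponent 2 gives an ellipsoid;
    larger exponents give boxier shapes, smaller ones pinched shapes.
    """
    spacing = np.asarray(spacing_mm, dtype=float)
    center = np.asarray(center_mm, dtype=float)
    semi = np.asarray(semiaxes_mm, dtype=float)
    if np.any(semi <= 0):
        raise ValueError("semiaxes must be strictly positive")
    axes = [origin_mm[a] + spacing[a] * np.arange(shape[a]) - center[a] for a in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij", sparse=True)
    q = (np.abs(X / semi[0]) ** exponent
         + np.abs(Y / semi[1]) ** exponent
         + np.abs(Z / semi[2]) ** exponent)
    return BinaryMask(q <= 1.0, tuple(spacing), tuple(origin_mm))


def signed_distance(mask: BinaryMask) -> np.ndarray:
    """Signed Euclidean distance (mm) to the foreground surface; negative inside."""
    vox = mask.voxels
    sp = mask.spacing_mm
    if not vox.any():
        return np.full(vox.shape, np.inf)
    outside = ndimage.distance_transform_edt(~vox, sampling=sp)
    inside = ndimage.distance_transform_edt(vox, sampling=sp)
    return outside - inside


def smooth_displacement_field(shape: tuple[int, int, int],
                              spacing_mm,
                              rms_mm: float,
                              correlation_mm: float,
                              rng: np.random.Generator,
                              coarse_factor: int = 4) -> np.ndarray:
    """Draw a smooth random 3-vector displacement field, shape (3, nx, ny, nz), in mm.

    White Gaussian noise is drawn on a coarse grid, Gaussian-filtered at the
    requested correlation length, linearly upsampled, and rescaled so the
    root-mean-square displacement magnitude equals ``rms_mm``.
    """
    if rms_mm < 0:
        raise ValueError("rms_mm must be >= 0")
    if rms_mm == 0:
        return np.zeros((3,) + tuple(shape))
    spacing = np.asarray(spacing_mm, dtype=float)
    coarse = tuple(max(4, int(np.ceil(s / coarse_factor))) for s in shape)
    sigma_vox = correlation_mm / (spacing * coarse_factor)
    comps = []
    for _ in range(3):
        noise = rng.standard_normal(coarse)
        noise = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="nearest")
        zoom = [shape[a] / coarse[a] for a in range(3)]
        comps.append(ndimage.zoom(noise, zoom, order=1, mode="nearest", grid_mode=True))
    field = np.stack(comps)
    rms = np.sqrt(np.mean(np.sum(field ** 2, axis=0)))
    if rms == 0:
        return field
    return field * (rms_mm / rms)


def warp_mask(mask: BinaryMask, field_mm: np.ndarray) -> BinaryMask:
    """Deform a mask by a displacement field (mm), resampling its signed distance.

    The warped indicator is {x : sdf(x + u(x)) <= 0}, i.e. boundary points move
    by approximately -u. Linear interpolation of the signed distance keeps the
    warped surface smooth at sub-voxel displacements.
    """
    return warp_sdf(signed_distance(mask), mask, field_mm)


def warp_sdf(sdf: np.ndarray, mask: BinaryMask, field_mm: np.ndarray) -> BinaryMask:
    """Same as :func:`warp_mask` but reusing a precomputed signed distance."""
    if field_mm.shape != (3,) + mask.shape:
        raise ValueError("displacement field shape does not match mask grid")
    sp = np.asarray(mask.spacing_mm)
    idx = np.indices(mask.shape, dtype=float)
    coords = idx + field_mm / sp[:, None, None, None]
    warped = ndimage.map_coordinates(sdf, coords, order=1, mode="nearest")
    return BinaryMask(warped <= 0.0, mask.spacing_mm, mask.origin_mm)


def save_nifti(mask: BinaryMask, path) -> None:
    """Write a mask as NIfTI (uint8), encoding spacing and origin in the affine."""
    import nibabel as nib

    affine = np.diag(list(mask.spacing_mm) + [1.0])
    affine[:3, 3] = mask.origin_mm
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    nib.save(img, str(path))


def load_nifti(path) -> BinaryMask:
    """Read a mask written by :func:`save_nifti` (diagonal affine expected)."""
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine
    spacing = tuple(float(abs(affine[a, a])) for a in range(3))
    origin = tuple(float(affine[a, 3]) for a in range(3))
    data = np.asarray(img.dataobj)
    return BinaryMask(data > 0.5, spacing, origin)
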