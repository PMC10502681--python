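"""Oblique-acquisition correction and background-field removal.

``rotate_to_scanner`` resamples an obliquely acquired field map onto a
scanner-axis-aligned grid (trilinear interpolation), so that the dipole
kernel can be built with B0 along the grid z axis.  ``pdf_remove`` implements
projection onto dipole fields (PDF): the background field inside the brain is
modelled as the field of susceptibility sources *outside* the mask, fitted by
weighted least squares; subtracting the fitted field leaves the local field
generated by in-mask tissue.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .fieldmap import FieldMap
from .inversion import DipoleKernel, _crop, _embed, _pad_shape, dipole_kernel
from .masking import BinaryMask

logger = logging.getLogger(__name__)

__all__ = ["RotationSpec", "rotate_to_scanner", "pdf_remove"]


@dataclass
class RotationSpec:
    """Rigid rotation taking the image grid into scanner-axis alignment.

    ``rotation`` is a proper orthonormal 3x3 matrix (determinant +1); build
    one from Euler angles with :meth:`from_euler`.  Only trilinear
    interpolation is supported.
    """

    rotation: np.ndarray
    interpolation: str = "trilinear"

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        if r.shape != (3, 3) or not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be a 3x3 orthonormal matrix")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (determinant +1)")
        if self.interpolation != "trilinear":
            raise ValueError("only trilinear interpolation is supported")
        self.rotation = r

    @classmethod
    def from_euler(cls, angles_deg, order="xyz") -> "RotationSpec":
        r = Rotation.from_euler(order, angles_deg, degrees=True).as_matrix()
        return cls(rotation=r)


def _rotate_volume(vol, rot, voxel_size, order):
    """Resample ``vol`` with the inverse rotation about the grid centre.

    Works in millimetre (world) coordinates so anisotropic voxels rotate
    correctly; out-of-domain samples are filled with NaN.
    """
    vs = np.asarray(voxel_size, dtype=float)
    centre = (np.asarray(vol.shape) - 1) / 2.0
    scale = np.diag(vs)
    # output voxel -> world -> inverse-rotate -> input voxel
    m = np.diag(1.0 / vs) @ rot.T @ scale
    offset = centre - m @ centre
    return ndimage.affine_transform(vol.astype(float), m, offset=offset,
                                    order=order, mode="constant", cval=np.nan)


def rotate_to_scanner(fmap: FieldMap, rot: RotationSpec):
    """Rotate a field map into scanner-axis alignment.

    Returns ``(FieldMap, BinaryMask)``: the resampled field (out-of-domain
    voxels zeroed) and the validity mask of voxels whose trilinear support lay
    entirely inside the original volume; downstream masks should be
    intersected with it.  The rotated map carries ``b0_direction`` rotated
    accordingly (the scanner z axis, for an exact oblique correction).
    """
    out = _rotate_volume(fmap.values, rot.rotation, fmap.voxel_size, order=1)
    valid = np.isfinite(out)
    out[~valid] = 0.0
    new_dir = rot.rotation @ np.asarray(fmap.b0_direction, dtype=float)
    rotated = FieldMap(out, fmap.units, fmap.voxel_size, fmap.b0_strength,
                       new_dir, fmap.affine)
    return rotated, BinaryMask(valid, fmap.voxel_size)


def rotate_labels(values: np.ndarray, rot: RotationSpec) -> np.ndarray:
    """Nearest-neighbour resampling of an integer label volume."""
    out = _rotate_volume(values.astype(float), rot.rotation, (1, 1, 1), order=0)
    out = np.nan_to_num(out, nan=0.0)
    return np.rint(out).astype(values.dtype)


def pdf_remove(total_field: FieldMap, mask: BinaryMask, weight=None, *,
               tol: float = 1e-4, max_iter: int = 200, pad_factor: int = 2,
               guard_voxels: int = 2):
    """Projection onto dipole fields.

    Solves ``min_y || W M (f - d * y) ||_2^2`` over external sources ``y``
    supported on the complement of the mask dilated by ``guard_voxels`` (a
    separation band stabilising the projection) within the padded field of view, by conjugate gradient on the normal equations.
    Returns ``(local_field, background_field)`` as FieldMaps in the input
    units: ``background = d * y_hat`` and ``local = M (f - background)``.
    """
    if total_field.units != "ppm":
        raise ValueError("pdf_remove expects a ppm field map")
    f = np.nan_to_num(np.asarray(total_field.values, dtype=float))
    m = mask.values
    if m.shape != f.shape:
        raise ValueError("mask grid does not match field")
    w = m.astype(float) if weight is None else np.asarray(weight, float) * m

    shape = f.shape
    big = _pad_shape(shape, pad_factor)
    kern = dipole_kernel(big, total_field.voxel_size, total_field.b0_direction)
    d = kern.values
    # external support: complement of the dilated mask, within the padded FOV
    dil = ndimage.binary_dilation(m, iterations=guard_voxels) if guard_voxels else m
    ext = ~_embed(dil, big)
    w_big = _embed(w, big)
    w2 = w_big * w_big
    f_big = _embed(f * m, big)

    def conv(x):
        return np.fft.ifftn(d * np.fft.fftn(x)).real

    def normal_op(y):
        return ext * conv(w2 * conv(ext * y))

    b = ext * conv(w2 * f_big)
    y = np.zeros(big)
    r = b.copy()
    p = r.copy()
    rs = np.vdot(r, r).real
    b_norm = np.sqrt(rs) or 1.0
    converged = rs == 0.0
    it = 0
    while not converged and it < max_iter:
        it += 1
        ap = normal_op(p)
        denom = np.vdot(p, ap).real
        if denom <= 0:
            break
        a_cg = rs / denom
        y += a_cg * p
        r -= a_cg * ap
        rs_new = np.vdot(r, r).real
        if np.sqrt(rs_new) / b_norm < tol:
            converged = True
        p = r + (rs_new / rs) * p
        rs = rs_new
    if not converged and it:
        warnings.warn(
            f"PDF CG stopped at iteration {it} with relative residual "
            f"{np.sqrt(rs) / b_norm:.2e} (tol {tol:g}); returning best iterate",
            RuntimeWarning)
    logger.info("pdf_remove: %d CG iterations, relative residual %.2e", it,
                np.sqrt(rs) / b_norm)

    background = _crop(conv(ext * y), shape)
    local = m * (f - background)
    return (total_field.with_values(local),
            total_field.with_values(background))
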