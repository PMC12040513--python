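"""Per-lesion reference axes: surface-in gradient, tract, vein and
orthogonal-to-vein directions.

The surface-in gradient field is the normalized gradient of the Euclidean
distance transform from the ventricular surface: on the surface it equals the
outward surface normal, and it stays defined throughout the white matter,
which the tangent-plane picture alone does not give for lesions away from the
ventricles.  Because the distance gradient has a consistent outward sign,
per-lesion averaging of this field is signed (component-wise).  Tract
eigenvector maps carry an arbitrary per-voxel sign, so tract (and
displacement-derived) axes are averaged sign-free through the dyadic
orientation tensor sum_i u_i u_i^T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_core import (
    LabelVolume,
    VectorVolume,
    canonical_axis,
    resolve_to_world,
    voxel_spacing,
)


@dataclass
class FeatureAxes:
    """The four reference axes of one lesion; any may be undefined (None)."""

    lesion_id: int
    g: np.ndarray | None = None       # surface-in gradient
    w: np.ndarray | None = None       # dominant tract direction
    v: np.ndarray | None = None       # vein axis
    v90: np.ndarray | None = None     # orthogonal-to-vein construct
    vein_voxel_count: int = 0
    qc_flags: list = field(default_factory=list)
    dispersion: dict = field(default_factory=dict)

    def defined(self) -> dict[str, np.ndarray]:
        return {
            name: ax
            for name, ax in (("G", self.g), ("W", self.w), ("V", self.v), ("V90", self.v90))
            if ax is not None
        }


def _world_gradient(scalar: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Gradient of a scalar grid with respect to world coordinates."""
    spacing = voxel_spacing(affine)
    g = np.stack(np.gradient(scalar, *spacing), axis=-1)
    # rotate voxel-frame gradient into world frame (columns of A normalized)
    r = np.asarray(affine)[:3, :3] / spacing[None, :]
    return g @ r.T


def surface_in_field(ventricles: LabelVolume, smooth_sigma_mm: float = 1.0) -> VectorVolume:
    """Unit outward-normal field of the ventricular surface, extended through
    the brain as the normalized gradient of the Euclidean distance transform.

    Zero (undefined) inside the ventricle mask and on ridges of the distance
    map where the gradient is numerically degenerate.  A mild Gaussian
    smoothing of the distance map (``smooth_sigma_mm``, default 1 mm)
    regularizes the facet structure that surface digitization imprints on
    the exact distance field; it leaves planar and far-field normals
    unchanged.
    """
    mask = ventricles.data > 0
    if not mask.any():
        raise ValueError("ventricle mask is empty")
    spacing = voxel_spacing(ventricles.affine)
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    if smooth_sigma_mm > 0:
        dist = ndimage.gaussian_filter(dist, smooth_sigma_mm / spacing)
    grad = _world_gradient(dist, ventricles.affine)
    norms = np.linalg.norm(grad, axis=-1)
    ok = (~mask) & (norms > 0.5)   # ridge voxels have shortened gradients
    out = np.zeros_like(grad)
    out[ok] = grad[ok] / norms[ok][..., None]
    return VectorVolume(
        data=out, affine=ventricles.affine, frame="world-mm", semantics="axis"
    )


def lesion_gradient_axis(
    voxels: np.ndarray,
    fld: VectorVolume,
    mean_norm_min: float = 0.2,
):
    """Signed component-wise mean of the surface-in field over a lesion.

    Returns ``(axis | None, flags)``; undefined when fewer than one lesion
    voxel has a defined field value or when the mean resultant norm falls
    below ``mean_norm_min`` (high dispersion).
    """
    voxels = np.atleast_2d(np.asarray(voxels))
    vecs = fld.data[voxels[:, 0], voxels[:, 1], voxels[:, 2]]
    defined = np.linalg.norm(vecs, axis=-1) > 0
    if not defined.any():
        raise ValueError("no defined surface-in gradient voxels inside lesion")
    mean = vecs[defined].mean(axis=0)
    n = np.linalg.norm(mean)
    if n < mean_norm_min:
        return None, ["gradient_high_dispersion"]
    return canonical_axis(mean / n), []


def orientation_tensor(vectors: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Dyadic (sign-free) orientation tensor sum_i w_i u_i u_i^T of unit axes."""
    u = np.asarray(vectors, dtype=float)
    if weights is None:
        weights = np.ones(u.shape[0])
    return np.einsum("i,ij,ik->jk", np.asarray(weights, dtype=float), u, u)


def principal_axis(tensor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal eigenvector (canonical sign) and descending eigenvalues."""
    evals, evecs = np.linalg.eigh(tensor)
    order = np.argsort(evals)[::-1]
    return canonical_axis(evecs[:, order[0]]), evals[order]


def lesion_tract_axis(voxels: np.ndarray, tract_field: VectorVolume):
    """Dominant tract axis over a lesion via the dyadic orientation tensor.

    Sets a ``crossing_fibre`` QC flag when the top two tensor eigenvalues
    differ by less than 20% relative (no single dominant population).
    """
    voxels = np.atleast_2d(np.asarray(voxels))
    vecs = tract_field.data[voxels[:, 0], voxels[:, 1], voxels[:, 2]]
    norms = np.linalg.norm(vecs, axis=-1)
    defined = norms > 0
    if not defined.any():
        raise ValueError("all tract vectors are zero within lesion")
    t = orientation_tensor(vecs[defined])
    axis, evals = principal_axis(t)
    flags = []
    if evals[0] > 0 and (evals[0] - evals[1]) / evals[0] < 0.2:
        flags.append("crossing_fibre")
    return axis, flags


def lesion_vein_axis(
    voxels: np.ndarray,
    veins: LabelVolume,
    min_vein_voxels: int = 3,
):
    """Principal axis of the vein voxels intersecting a lesion.

    The intersecting vein voxels are pooled (all vein labels binarized) and
    their world-space second-moment matrix is eigen-decomposed, exactly as in
    the lesion ellipsoid fit.  Undefined (``None``) when fewer than
    ``min_vein_voxels`` vein voxels fall inside the lesion — such lesions are
    excluded from vein-dependent classification.

    Returns ``(axis | None, n_vein_voxels)``.
    """
    voxels = np.atleast_2d(np.asarray(voxels))
    inside = veins.data[voxels[:, 0], voxels[:, 1], voxels[:, 2]] > 0
    n = int(inside.sum())
    if n < min_vein_voxels:
        return None, n
    pts = resolve_to_world(voxels[inside], veins.affine)
    c = pts.mean(axis=0)
    d = pts - c
    axis, _ = principal_axis(d.T @ d / n)
    return axis, n


def orthogonal_vein_axis(v: np.ndarray, eps1: np.ndarray, parallel_tol_deg: float = 1.0):
    """Orthogonal-to-vein axis: the in-plane direction nearest the lesion
    major axis (projection of eps1 onto the plane perpendicular to v).

    When eps1 is parallel to v within ``parallel_tol_deg`` the projection is
    degenerate and a deterministic fallback v x e is used, with e the
    canonical basis vector least aligned with v; the result carries a flag.

    Returns ``(axis, flags)``.
    """
    if v is None:
        raise ValueError("vein axis undefined; v90 cannot be constructed")
    v = np.asarray(v, dtype=float)
    v = v / np.linalg.norm(v)
    e1 = np.asarray(eps1, dtype=float)
    e1 = e1 / np.linalg.norm(e1)
    proj = e1 - (e1 @ v) * v
    sin_angle = np.linalg.norm(proj)
    if sin_angle < np.sin(np.deg2rad(parallel_tol_deg)):
        e = np.eye(3)[int(np.argmin(np.abs(v)))]
        axis = np.cross(v, e)
        axis /= np.linalg.norm(axis)
        return canonical_axis(axis), ["v90_degenerate_fallback"]
    return canonical_axis(proj / sin_angle), []


def compute_feature_axes(
    lesion_id: int,
    voxels: np.ndarray,
    eps1: np.ndarray,
    surface_field: VectorVolume,
    tract_field: VectorVolume,
    veins: LabelVolume,
    min_vein_voxels: int = 3,
    mean_norm_min: float = 0.2,
) -> FeatureAxes:
    """Assemble all four reference axes for one lesion."""
    axes = FeatureAxes(lesion_id=lesion_id)
    try:
        axes.g, gflags = lesion_gradient_axis(voxels, surface_field, mean_norm_min)
        axes.qc_flags += gflags
    except ValueError:
        axes.qc_flags.append("gradient_undefined")
    try:
        axes.w, wflags = lesion_tract_axis(voxels, tract_field)
        axes.qc_flags += wflags
    except ValueError:
        axes.qc_flags.append("tract_undefined")
    axes.v, axes.vein_voxel_count = lesion_vein_axis(voxels, veins, min_vein_voxels)
    if axes.v is not None:
        axes.v90, vflags = orthogonal_vein_axis(axes.v, eps1)
        axes.qc_flags += vflags
    return axes
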