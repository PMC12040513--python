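"""Synthetic phantoms with known ground truth for every pipeline stage.

A phantom is a small world-space scene on a regular grid: a ventricle slab
(or sphere) at the bottom of the volume, ellipsoidal lesions placed on a
lattice of disjoint cells, a one-voxel-calibre vein tube through each lesion,
a piecewise-uniform tract axis field, MT-on/off image pairs at two timepoints
satisfying the MTR identity exactly before noise, and an analytic
displacement field whose Jacobian determinant is closed-form on the lesion
voxels.

Lesions are digitized by a centre-of-voxel inclusion test against the
analytic ellipsoid, matching the moment-fitting convention of the shape
module.  Each lesion's intended orientation category is realized by choosing
the major axis and the vein/tract axes with at least ~20 deg of margin from
the 45 deg decision boundary; a small random rigid jitter (default 3 deg)
and a random in-plane rotation decorate the scene without crossing any
boundary.

Under the projection construction of the orthogonal-to-vein axis, alignment
with V90 at the 45 deg threshold is the complement of alignment with V, so
the exclusive categories G, W, GW and NONE exist only on the decision
boundary; requesting them (or V and V90 together) raises at build time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .direction_fields import FeatureAxes, orthogonal_vein_axis
from .io_core import ImageVolume, LabelVolume, VectorVolume, resolve_to_world
from .orientation import classify_axis

REALIZABLE_CATEGORIES = ("V", "GV", "WV", "GWV", "V90", "GV90", "WV90", "GWV90")

#: per-patient mixture of intended categories, loosely mimicking the
#: reported cohort distribution restricted to the realizable set
DEFAULT_CATEGORY_MIXTURE = {
    "V": 0.33,
    "WV": 0.31,
    "GV": 0.13,
    "GWV": 0.11,
    "V90": 0.04,
    "GV90": 0.03,
    "WV90": 0.03,
    "GWV90": 0.02,
}

#: cohort rates of expansion/contraction and the volume ratios injected
DEFAULT_DYNAMICS_MIXTURE = {
    "expanding": (0.13, 1.12),
    "contracting": (0.07, 0.88),
    "stable": (0.80, 1.00),
}

NAWM_MTR_PU = 40.0
LESION_MTR_PU = 30.0
MT_OFF_SIGNAL = 100.0
VEIN_RADIUS_MM = 0.6
SHARED_TILT_DEG = 25.0   # tilt from the surface normal for G-shared categories


@dataclass
class LesionSpec:
    lesion_id: int
    centre_mm: np.ndarray
    semi_axes_mm: np.ndarray          # descending, mm
    eps1: np.ndarray                  # intended major axis (unit)
    category: str
    vein_axis: np.ndarray
    tract_axis: np.ndarray
    volume_ratio: float = 1.0         # injected Jacobian inside the lesion
    stretch_axis: np.ndarray | None = None   # default: eps1
    delta_mtr_pu: float = 0.0
    mtr_baseline_pu: float = LESION_MTR_PU


@dataclass
class PhantomSpec:
    patient_id: str
    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    ventricle: tuple = ("slab", 6.0)  # ("slab", z_max_mm) | ("sphere", centre, r)
    lesions: list[LesionSpec] = field(default_factory=list)
    default_tract_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    noise_sigma: float = 0.0          # additive Gaussian on MT images only
    arm: str = "placebo"
    seed: int = 0

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0], a[1, 1], a[2, 2] = self.voxel_size_mm
        return a


@dataclass
class PhantomBundle:
    spec: PhantomSpec
    labels: LabelVolume
    ventricles: LabelVolume
    veins: LabelVolume
    tract_field: VectorVolume
    mt_off_t0: ImageVolume
    mt_on_t0: ImageVolume
    mt_off_t1: ImageVolume
    mt_on_t1: ImageVolume
    displacement: VectorVolume
    truth: pd.DataFrame


def _rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)


def category_geometry(
    category: str,
    phi_rad: float = 0.0,
    jitter: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Axis triple (eps1, vein, tract) realizing an intended category.

    The surface-in gradient is +z (slab ventricle below the lesions).
    ``phi_rad`` rotates the construction about z (leaving every angle to the
    gradient unchanged); ``jitter``, if given, is a small rotation matrix
    applied to the whole triple.  Raises for categories that are not
    realizable with margin under the projection v90 construction.
    """
    if category not in REALIZABLE_CATEGORIES:
        raise ValueError(
            f"category {category!r} is not realizable with margin; "
            f"choose one of {REALIZABLE_CATEGORIES}"
        )
    z = np.array([0.0, 0.0, 1.0])
    x = _rotation_about(z, phi_rad) @ np.array([1.0, 0.0, 0.0])
    y = np.cross(z, x)
    t = np.deg2rad(SHARED_TILT_DEG)
    tilted = np.sin(t) * x + np.cos(t) * z

    table = {
        "V":      (x, x, y),
        "GV":     (z, z, x),
        "WV":     (x, x, x),
        "GWV":    (tilted, tilted, tilted),
        "V90":    (x, y, z),
        "GV90":   (z, x, y),
        "WV90":   (x, y, x),
        "GWV90":  (tilted, y, tilted),
    }
    e1, v, w = (np.array(u, dtype=float) for u in table[category])
    if jitter is not None:
        e1, v, w = jitter @ e1, jitter @ v, jitter @ w
    return e1, v, w


def true_orientation(
    lesion: LesionSpec, g_axis: np.ndarray, threshold_deg: float = 45.0
):
    """Analytic category and boundary margin of a lesion spec's true axes."""
    v90, _ = orthogonal_vein_axis(lesion.vein_axis, lesion.eps1)
    axes = FeatureAxes(
        lesion_id=lesion.lesion_id,
        g=np.asarray(g_axis, float),
        w=lesion.tract_axis,
        v=lesion.vein_axis,
        v90=v90,
    )
    label = classify_axis(lesion.eps1, axes, threshold_deg)
    margin = min(abs(a - threshold_deg) for a in label.angles.values())
    return label, margin


def _complete_basis(e1: np.ndarray) -> np.ndarray:
    """Rotation matrix with first column e1 (deterministic completion)."""
    e1 = np.asarray(e1, float) / np.linalg.norm(e1)
    helper = np.eye(3)[int(np.argmin(np.abs(e1)))]
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


def _voxel_centre_grid(shape, affine, lo=None, hi=None):
    """World coordinates of voxel centres in an index sub-box [lo, hi)."""
    if lo is None:
        lo = (0, 0, 0)
    if hi is None:
        hi = shape
    idx = np.stack(
        np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij"),
        axis=-1,
    )
    flat = idx.reshape(-1, 3)
    world = resolve_to_world(flat, affine).reshape(idx.shape)
    return idx, world


def _bounding_box(centre_vox, radius_vox, shape):
    lo = np.maximum(np.floor(centre_vox - radius_vox).astype(int), 0)
    hi = np.minimum(np.ceil(centre_vox + radius_vox).astype(int) + 1, shape)
    return lo, hi


def _taper(r: np.ndarray, r1: float, r2: float) -> np.ndarray:
    """Smooth compact support: 1 for r<=r1, cos^2 ramp to 0 at r2."""
    psi = np.zeros_like(r)
    psi[r <= r1] = 1.0
    ramp = (r > r1) & (r < r2)
    psi[ramp] = np.cos((r[ramp] - r1) / (r2 - r1) * np.pi / 2.0) ** 2
    return psi


def build_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Rasterize a phantom spec into the full input bundle plus ground truth.

    The MT image pairs satisfy the MTR identity exactly before noise; the
    displacement field is linear (hence closed-form Jacobian) on every lesion
    voxel and compactly supported within the lesion's lattice cell.
    """
    affine = spec.affine
    shape = tuple(spec.shape)
    vox = np.asarray(spec.voxel_size_mm, float)
    inv_vox = 1.0 / vox
    rng = np.random.default_rng(spec.seed)

    labels = np.zeros(shape, dtype=np.int32)
    veins = np.zeros(shape, dtype=np.int32)
    tract = np.zeros(shape + (3,), dtype=float)
    tract[:] = np.asarray(spec.default_tract_axis, float)
    mtr_t0 = np.full(shape, NAWM_MTR_PU)
    mtr_t1 = np.full(shape, NAWM_MTR_PU)
    disp = np.zeros(shape + (3,), dtype=float)

    # ventricle geometry; g axis for the truth table is the outward normal
    _, world_all = _voxel_centre_grid(shape, affine)
    if spec.ventricle[0] == "slab":
        vent = (world_all[..., 2] <= float(spec.ventricle[1])).astype(np.int32)
        g_axis_of = lambda c: np.array([0.0, 0.0, 1.0])
    elif spec.ventricle[0] == "sphere":
        centre = np.asarray(spec.ventricle[1], float)
        radius = float(spec.ventricle[2])
        vent = (
            np.linalg.norm(world_all - centre, axis=-1) <= radius
        ).astype(np.int32)
        g_axis_of = lambda c: (np.asarray(c) - centre) / np.linalg.norm(np.asarray(c) - centre)
    else:
        raise ValueError(f"unknown ventricle geometry {spec.ventricle[0]!r}")

    truth_rows = []
    for les in spec.lesions:
        c = np.asarray(les.centre_mm, float)
        a = np.asarray(les.semi_axes_mm, float)
        if np.any(a <= 0):
            raise ValueError("lesion semi-axes must be positive")
        r = _complete_basis(les.eps1)
        c_vox = (c - affine[:3, 3]) * inv_vox
        lo, hi = _bounding_box(c_vox, a.max() * inv_vox + 2, shape)
        idx, world = _voxel_centre_grid(shape, affine, lo, hi)
        local = (world - c) @ r
        inside = np.sum((local / a) ** 2, axis=-1) <= 1.0
        if not inside.any():
            raise ValueError(f"lesion {les.lesion_id} rasterizes to zero voxels")
        sel = tuple(idx[inside].T)
        labels[sel] = les.lesion_id

        # vein tube through the lesion centre
        v = np.asarray(les.vein_axis, float)
        v = v / np.linalg.norm(v)
        half_len = a.max() + 4.0
        lo_v, hi_v = _bounding_box(c_vox, (half_len + 2 * VEIN_RADIUS_MM) * inv_vox, shape)
        idx_v, world_v = _voxel_centre_grid(shape, affine, lo_v, hi_v)
        d = world_v - c
        t_par = d @ v
        radial = np.linalg.norm(d - t_par[..., None] * v, axis=-1)
        tube = (np.abs(t_par) <= half_len) & (radial <= VEIN_RADIUS_MM)
        veins[tuple(idx_v[tube].T)] = les.lesion_id

        # piecewise-uniform tract axis in the lesion's neighbourhood
        w = np.asarray(les.tract_axis, float)
        w = w / np.linalg.norm(w)
        tract[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = w

        # MTR fields
        mtr_t0[sel] = les.mtr_baseline_pu
        mtr_t1[sel] = les.mtr_baseline_pu + les.delta_mtr_pu

        # analytic stretch: linear on a core ball covering the lesion and
        # the differencing stencil, tapered to zero inside the cell
        s = float(les.volume_ratio)
        if s != 1.0:
            axis = les.stretch_axis if les.stretch_axis is not None else les.eps1
            axis = np.asarray(axis, float)
            axis = axis / np.linalg.norm(axis)
            r1 = a.max() + 3.0
            r2 = r1 + 5.0
            lo_d, hi_d = _bounding_box(c_vox, r2 * inv_vox + 1, shape)
            idx_d, world_d = _voxel_centre_grid(shape, affine, lo_d, hi_d)
            d = world_d - c
            rad = np.linalg.norm(d, axis=-1)
            u = (s - 1.0) * (d @ axis)[..., None] * axis
            disp[lo_d[0]:hi_d[0], lo_d[1]:hi_d[1], lo_d[2]:hi_d[2]] += (
                u * _taper(rad, r1, r2)[..., None]
            )

        label, margin = true_orientation(les, g_axis_of(c))
        dyn = "expanding" if s > 1 else ("contracting" if s < 1 else "stable")
        truth_rows.append(
            {
                "patient_id": spec.patient_id,
                "lesion_id": les.lesion_id,
                "arm": spec.arm,
                "intended_category": les.category,
                "true_category": label.category,
                "margin_deg": margin,
                "true_eps1_x": les.eps1[0],
                "true_eps1_y": les.eps1[1],
                "true_eps1_z": les.eps1[2],
                "true_volume_ratio": s,
                "intended_dyn_class": dyn,
                "true_delta_mtr_pu": les.delta_mtr_pu,
            }
        )
        if label.category != les.category:
            raise ValueError(
                f"lesion {les.lesion_id}: intended category {les.category} "
                f"not realized (got {label.category})"
            )

    mt_off_t0 = np.full(shape, MT_OFF_SIGNAL)
    mt_off_t1 = np.full(shape, MT_OFF_SIGNAL)
    mt_on_t0 = mt_off_t0 * (1.0 - mtr_t0 / 100.0)
    mt_on_t1 = mt_off_t1 * (1.0 - mtr_t1 / 100.0)
    if spec.noise_sigma > 0:
        mt_off_t0 = mt_off_t0 + rng.normal(0, spec.noise_sigma, shape)
        mt_on_t0 = mt_on_t0 + rng.normal(0, spec.noise_sigma, shape)
        mt_off_t1 = mt_off_t1 + rng.normal(0, spec.noise_sigma, shape)
        mt_on_t1 = mt_on_t1 + rng.normal(0, spec.noise_sigma, shape)

    return PhantomBundle(
        spec=spec,
        labels=LabelVolume(labels, affine),
        ventricles=LabelVolume(vent, affine),
        veins=LabelVolume(veins, affine),
        tract_field=VectorVolume(tract, affine, semantics="axis"),
        mt_off_t0=ImageVolume(mt_off_t0, affine, units="au"),
        mt_on_t0=ImageVolume(mt_on_t0, affine, units="au"),
        mt_off_t1=ImageVolume(mt_off_t1, affine, units="au"),
        mt_on_t1=ImageVolume(mt_on_t1, affine, units="au"),
        displacement=VectorVolume(disp, affine, semantics="displacement"),
        truth=pd.DataFrame(truth_rows),
    )


def sample_cohort(
    n_patients: int = 20,
    lesions_per_patient: int = 15,
    category_mixture: dict[str, float] | None = None,
    dynamics_mixture: dict[str, tuple[float, float]] | None = None,
    arm_effect_pu: float = 0.6,
    arm_effect_category: str = "GV",
    jitter_deg: float = 3.0,
    voxel_size_mm: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> list[PhantomSpec]:
    """Draw a reproducible cohort of phantom specs.

    Patients alternate between the ``placebo`` and ``active`` arms; lesions
    draw an intended category from ``category_mixture`` and a dynamics class
    (with its injected volume ratio) from ``dynamics_mixture``.  Active-arm
    lesions of ``arm_effect_category`` receive an extra ``arm_effect_pu`` of
    MTR change, emulating a treatment effect confined to one orientation.
    """
    mixture = dict(category_mixture or DEFAULT_CATEGORY_MIXTURE)
    total = sum(mixture.values())
    if total <= 0:
        raise ValueError("degenerate category mixture")
    cats = sorted(mixture)
    probs = np.array([mixture[c] / total for c in cats])
    unknown = set(cats) - set(REALIZABLE_CATEGORIES)
    if unknown:
        raise ValueError(f"unrealizable categories in mixture: {sorted(unknown)}")
    dyn = dict(dynamics_mixture or DEFAULT_DYNAMICS_MIXTURE)
    dyn_names = sorted(dyn)
    dyn_probs = np.array([dyn[d][0] for d in dyn_names])
    dyn_probs = dyn_probs / dyn_probs.sum()

    if n_patients == 0:
        return []
    rng = np.random.default_rng(seed)

    # disjoint 30 mm cells on a lattice; slab ventricle below
    cell = 30.0
    nx = int(np.ceil(lesions_per_patient ** (1 / 2)))
    ny = int(np.ceil(lesions_per_patient / nx))
    z0 = 10.0
    shape = (
        int(np.ceil(nx * cell / voxel_size_mm)),
        int(np.ceil(ny * cell / voxel_size_mm)),
        int(np.ceil((z0 + cell) / voxel_size_mm)),
    )

    specs = []
    for p in range(n_patients):
        pid = f"p{p:02d}"
        arm = "placebo" if p % 2 == 0 else "active"
        lesions = []
        for k in range(lesions_per_patient):
            cat = cats[int(rng.choice(len(cats), p=probs))]
            dcls = dyn_names[int(rng.choice(len(dyn_names), p=dyn_probs))]
            ratio = dyn[dcls][1]
            phi = rng.uniform(0, 2 * np.pi)
            jitter = None
            if jitter_deg > 0:
                ax = rng.normal(size=3)
                ax /= np.linalg.norm(ax)
                jitter = _rotation_about(ax, np.deg2rad(rng.uniform(0, jitter_deg)))
            e1, v, w = category_geometry(cat, phi_rad=phi, jitter=jitter)
            ix, iy = k % nx, k // nx
            centre = np.array(
                [(ix + 0.5) * cell, (iy + 0.5) * cell, z0 + cell / 2.0]
            )
            # sizes keep the major axis well determined at 1 mm digitization
            a1 = rng.uniform(5.0, 6.5)
            if rng.uniform() < 0.1:
                semis = np.array([6.0, 4.2, 3.9])    # low-anisotropy tail
            else:
                a2 = rng.uniform(1.8, 2.5)
                semis = np.array([a1, a2, a2 * rng.uniform(0.9, 1.0)])
            delta = arm_effect_pu if (arm == "active" and cat == arm_effect_category) else 0.0
            lesions.append(
                LesionSpec(
                    lesion_id=k + 1,
                    centre_mm=centre,
                    semi_axes_mm=semis,
                    eps1=e1,
                    category=cat,
                    vein_axis=v,
                    tract_axis=w,
                    volume_ratio=ratio,
                    delta_mtr_pu=delta,
                )
            )
        specs.append(
            PhantomSpec(
                patient_id=pid,
                shape=shape,
                voxel_size_mm=(voxel_size_mm,) * 3,
                ventricle=("slab", 6.0),
                lesions=lesions,
                noise_sigma=noise_sigma,
                arm=arm,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def write_bundle(bundle: PhantomBundle, out_dir) -> None:
    """Emit the bundle as the NIfTI/CSV files the pipeline consumes."""
    from pathlib import Path

    from .io_core import write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(bundle.labels, out / "lesions.nii.gz")
    write_volume(bundle.ventricles, out / "ventricles.nii.gz")
    write_volume(bundle.veins, out / "veins.nii.gz")
    write_volume(bundle.tract_field, out / "tract_field.nii.gz")
    write_volume(bundle.mt_off_t0, out / "mt_off_baseline.nii.gz")
    write_volume(bundle.mt_on_t0, out / "mt_on_baseline.nii.gz")
    write_volume(bundle.mt_off_t1, out / "mt_off_followup.nii.gz")
    write_volume(bundle.mt_on_t1, out / "mt_on_followup.nii.gz")
    write_volume(bundle.displacement, out / "displacement.nii.gz")
    bundle.truth.to_csv(out / "ground_truth.csv", index=False)
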