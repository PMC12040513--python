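"""Volume containers, NIfTI I/O, coordinate handling and configuration.

All geometry downstream of this module is computed in world (mm, RAS)
coordinates: voxel indices are 0-based and mapped through the 4x4
voxel-to-world affine, so anisotropic voxel grids do not distort directions
or distances.

Axis-semantics vector fields (tract eigenvector maps, surface-in gradients)
are equivalence classes {u, -u}; :func:`canonical_axis` normalizes storage to
the representative whose largest-magnitude component is non-negative.
Displacement fields are signed world-mm vectors on the baseline grid.
"""

from __future__ import annotations

import logging
import sys
import time
from contextlib import contextmanager
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

logger = logging.getLogger("lesiondir")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class VolumeError(ValueError):
    """Base class for volume contract violations."""


class MissingFileError(VolumeError):
    pass


class DimensionMismatchError(VolumeError):
    pass


class NonInvertibleAffineError(VolumeError):
    pass


class OutOfGridError(VolumeError):
    pass


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise NonInvertibleAffineError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise NonInvertibleAffineError("affine spatial block is singular")
    return affine


@dataclass
class ImageVolume:
    """3D scalar grid with a voxel-to-world affine (mm, RAS)."""

    data: np.ndarray
    affine: np.ndarray
    units: str = "unitless"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise DimensionMismatchError(
                f"ImageVolume needs a 3D grid, got shape {self.data.shape}"
            )
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass
class LabelVolume:
    """3D non-negative integer grid; 0 = background, k > 0 = object id."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionMismatchError(
                f"LabelVolume needs a 3D grid, got shape {self.data.shape}"
            )
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded, atol=1e-6):
                raise VolumeError("label data is not integer-valued")
            self.data = rounded.astype(np.int32)
        if self.data.min() < 0:
            raise VolumeError("labels must be non-negative")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def labels(self) -> np.ndarray:
        vals = np.unique(self.data)
        return vals[vals > 0]


@dataclass
class VectorVolume:
    """3D grid of 3-vectors (stored as shape (X, Y, Z, 3)).

    ``semantics`` is ``"axis"`` for sign-free unit directions (zero vector =
    undefined) or ``"displacement"`` for signed world-mm displacements.
    ``frame`` records whether components are world-mm ("world-mm") or raw
    voxel steps ("voxel"); every operation in this package expects world-mm.
    """

    data: np.ndarray
    affine: np.ndarray
    frame: str = "world-mm"
    semantics: str = "axis"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[3] != 3:
            raise DimensionMismatchError(
                f"VectorVolume needs shape (X,Y,Z,3), got {self.data.shape}"
            )
        if self.semantics not in ("axis", "displacement"):
            raise VolumeError(f"unknown semantics {self.semantics!r}")
        if not np.all(np.isfinite(self.data)):
            raise VolumeError("vector field contains non-finite components")
        self.affine = _check_affine(self.affine)
        if self.semantics == "axis":
            norms = np.linalg.norm(self.data, axis=-1)
            defined = norms > 0
            bad = defined & (np.abs(norms - 1.0) > 1e-3)
            if np.any(bad):
                # tolerate storage rounding: renormalize near-unit vectors
                self.data[defined] /= norms[defined][:, None]
            self.data = canonical_axis_field(self.data)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape[:3]

    def defined_mask(self) -> np.ndarray:
        return np.linalg.norm(self.data, axis=-1) > 0


def canonical_axis(u: np.ndarray) -> np.ndarray:
    """Return the representative of the axis {u, -u} whose largest-magnitude
    component is non-negative (ties broken by the last such component)."""
    u = np.asarray(u, dtype=float)
    if np.allclose(u, 0):
        return u
    i = int(np.argmax(np.abs(u)))
    return -u if u[i] < 0 else u


def canonical_axis_field(data: np.ndarray) -> np.ndarray:
    comp = np.abs(data).argmax(axis=-1)
    lead = np.take_along_axis(data, comp[..., None], axis=-1)[..., 0]
    sign = np.where(lead < 0, -1.0, 1.0)
    return data * sign[..., None]


def read_volume(path: str | Path, expected_semantics: str = "scalar"):
    """Read a NIfTI file into the container matching ``expected_semantics``.

    ``expected_semantics`` is one of ``"scalar"``, ``"label"``, ``"axis"``,
    ``"displacement"``.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such file: {path}")
    img = nib.load(str(path))
    affine = np.asarray(img.affine, dtype=float)
    data = np.asarray(img.dataobj)
    if expected_semantics == "scalar":
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        if data.ndim != 3:
            raise DimensionMismatchError(f"expected 3D scalar image, got {data.shape}")
        return ImageVolume(data=data.astype(float), affine=affine)
    if expected_semantics == "label":
        if data.ndim != 3:
            raise DimensionMismatchError(f"expected 3D label image, got {data.shape}")
        return LabelVolume(data=data, affine=affine)
    if expected_semantics in ("axis", "displacement"):
        if data.ndim != 4 or data.shape[3] != 3:
            raise DimensionMismatchError(
                f"expected 4D (X,Y,Z,3) vector image, got {data.shape}"
            )
        return VectorVolume(
            data=data.astype(float), affine=affine, semantics=expected_semantics
        )
    raise ValueError(f"unknown expected_semantics {expected_semantics!r}")


def write_volume(vol, path: str | Path) -> None:
    """Write any volume container to NIfTI, preserving the affine bit-exact."""
    data = vol.data
    if isinstance(vol, LabelVolume):
        data = data.astype(np.int32)
    img = nib.Nifti1Image(np.asarray(data), np.asarray(vol.affine))
    nib.save(img, str(path))


def resolve_to_world(voxel_coords, affine: np.ndarray, shape=None) -> np.ndarray:
    """Map 0-based voxel index triples to world-mm coordinates, y = A x.

    If ``shape`` is given, coordinates outside the grid raise
    :class:`OutOfGridError`.
    """
    affine = _check_affine(affine)
    coords = np.atleast_2d(np.asarray(voxel_coords, dtype=float))
    if coords.shape[-1] != 3:
        raise DimensionMismatchError("voxel coordinates must be triples")
    if shape is not None:
        shape = np.asarray(shape)
        if np.any(coords < 0) or np.any(coords > shape - 1):
            raise OutOfGridError("voxel coordinate outside grid")
    return coords @ affine[:3, :3].T + affine[:3, 3]


def resolve_to_voxel(world_coords, affine: np.ndarray) -> np.ndarray:
    """Inverse of :func:`resolve_to_world` (continuous voxel coordinates)."""
    affine = _check_affine(affine)
    coords = np.atleast_2d(np.asarray(world_coords, dtype=float))
    inv = np.linalg.inv(affine)
    return coords @ inv[:3, :3].T + inv[:3, 3]


def voxel_spacing(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel edge lengths in mm (norms of the affine columns)."""
    return np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)


@dataclass
class AnalysisConfig:
    """Thresholds and switches shared by the pipeline stages.

    angle_threshold_deg  alignment cut between the lesion axis and a feature
                         axis; the headline analysis uses 45 deg, with 30 deg
                         as the sensitivity setting.
    min_volume_mm3       smallest lesion retained (world volume).
    sd_multiplier        k in the cohort mean +/- k*SD Jacobian cut.
    v90_mode             "projection" (axis = lesion major axis projected
                         into the vein-orthogonal plane) or "plane"
                         (aligned-with-V90 iff angle to the vein exceeds the
                         threshold).
    anisotropy_on        "axis_lengths" (default) or "moments": which scale
                         enters the fractional-anisotropy formula.
    expansion_axis_mode  "displacement" (magnitude-weighted orientation
                         tensor of displacement vectors) or "strain"
                         (principal stretch of the lesion-mean strain
                         tensor).
    """

    angle_threshold_deg: float = 45.0
    min_volume_mm3: float = 3.0
    sd_multiplier: float = 1.0
    min_vein_voxels: int = 3
    mean_norm_min: float = 0.2
    v90_mode: str = "projection"
    anisotropy_on: str = "axis_lengths"
    expansion_axis_mode: str = "displacement"
    chance_samples: int = 100_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def replace(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


@contextmanager
def stage_timer(name: str):
    """Log wall-clock timing of a pipeline stage to stderr."""
    t0 = time.perf_counter()
    logger.info("stage %s: start", name)
    try:
        yield
    finally:
        logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
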