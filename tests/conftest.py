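import logging

import numpy as np
import pandas as pd
import pytest

from lesiondir.io_core import AnalysisConfig
from lesiondir.pipeline import analyze_cohort
from lesiondir.synthetic import build_phantom, sample_cohort

logging.getLogger("lesiondir").setLevel(logging.WARNING)


def digitize_ellipsoid(semi_axes, rotation=None, centre=None, spacing=1.0, pad=3):
    """Voxel indices of an analytic ellipsoid digitized on an isotropic grid
    by centre-of-voxel inclusion (independent of the package's generator)."""
    a = np.asarray(semi_axes, dtype=float)
    r = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    extent = int(np.ceil(a.max() / spacing)) + pad
    if centre is None:
        centre = np.full(3, extent + 0.37)  # off-lattice to avoid symmetry ties
    g = np.arange(0, 2 * extent + 1)
    idx = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)
    local = (idx * spacing - np.asarray(centre) * spacing) @ r
    inside = np.sum((local / a) ** 2, axis=-1) <= 1.0
    return idx[inside]


def rotation_about(axis, angle_deg):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.deg2rad(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


def axis_angle_deg(a, b):
    a = np.asarray(a, float); b = np.asarray(b, float)
    c = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.degrees(np.arccos(min(c, 1.0))))


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """Six-patient, eight-lesion phantom cohort with ground truth."""
    specs = sample_cohort(n_patients=6, lesions_per_patient=8, seed=123)
    return [build_phantom(s) for s in specs]


@pytest.fixture(scope="session")
def small_cohort_result(small_cohort, config):
    res = analyze_cohort(small_cohort, config)
    truth = pd.concat([b.truth for b in small_cohort], ignore_index=True)
    merged = res.lesions.merge(truth, on=["patient_id", "lesion_id"])
    return res, merged
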