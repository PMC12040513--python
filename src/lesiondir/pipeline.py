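"""End-to-end drivers: per-patient analysis and cohort-level aggregation.

``analyze_patient`` runs the baseline stages (lesion extraction, ellipsoid
fits, feature axes, orientation categories) and the longitudinal stages
(Jacobian determinants, expansion axes, MTR change) on one input bundle.
Expansion/contraction calls need the pooled cohort, so ``analyze_cohort``
collects per-lesion mean Jacobians across patients, applies the cohort
mean +/- k*SD rule, attributes directions of change, and builds the
per-patient, vs-chance and group-MTR summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    cohort_mean_proportions,
    group_mtr_table,
    per_patient_proportions,
    vs_chance_table,
)
from .direction_fields import compute_feature_axes, surface_in_field
from .io_core import AnalysisConfig, stage_timer
from .longitudinal import (
    classify_change_direction,
    classify_dynamics,
    compute_mtr,
    expansion_axis,
    jacobian_determinant,
    lesion_mean_jacobian,
    lesion_mtr_change,
)
from .orientation import chance_single, classify_lesion
from .shape import extract_lesions, summarize_lesion
from .synthetic import PhantomBundle


@dataclass
class PatientResult:
    patient_id: str
    lesions: pd.DataFrame            # one row per included lesion
    excluded: pd.DataFrame           # excluded lesions with reasons
    labels: list                     # OrientationLabel per classified lesion
    feature_axes: dict               # uid -> FeatureAxes
    expansion_axes: dict             # uid -> axis | None


def _axis_cols(prefix: str, axis) -> dict:
    if axis is None:
        return {f"{prefix}_{c}": np.nan for c in "xyz"}
    return {f"{prefix}_{c}": float(a) for c, a in zip("xyz", axis)}


def analyze_patient(bundle: PhantomBundle, cfg: AnalysisConfig) -> PatientResult:
    """Run every per-patient stage of the pipeline on one bundle."""
    pid = bundle.spec.patient_id
    affine = bundle.labels.affine

    with stage_timer(f"{pid}:extract"):
        kept, excluded_small = extract_lesions(bundle.labels, cfg.min_volume_mm3)
    with stage_timer(f"{pid}:fields"):
        g_field = surface_in_field(bundle.ventricles)
        jac = jacobian_determinant(bundle.displacement)
        mtr0 = compute_mtr(bundle.mt_off_t0, bundle.mt_on_t0)
        mtr1 = compute_mtr(bundle.mt_off_t1, bundle.mt_on_t1)

    rows, excluded_rows, labels = [], [], []
    axes_of, exp_axis_of = {}, {}
    for lid, reason in excluded_small.items():
        excluded_rows.append({"patient_id": pid, "lesion_id": lid, "reason": reason})

    with stage_timer(f"{pid}:lesions"):
        for lid, voxels in kept.items():
            uid = f"{pid}_L{lid}"
            shp = summarize_lesion(
                voxels, affine, lesion_id=lid, patient_id=pid,
                anisotropy_on=cfg.anisotropy_on,
            )
            axes = compute_feature_axes(
                lid, voxels, shp.major_axis, g_field, bundle.tract_field,
                bundle.veins, cfg.min_vein_voxels, cfg.mean_norm_min,
            )
            axes_of[uid] = axes

            if axes.v is None:
                # vein direction not assessable: excluded from classification
                excluded_rows.append(
                    {"patient_id": pid, "lesion_id": lid, "reason": "vein axis undefined"}
                )
                continue

            label = classify_lesion(
                shp.major_axis, axes, cfg.angle_threshold_deg, cfg.v90_mode
            )
            labels.append(label)

            try:
                exp_ax, exp_flags = expansion_axis(
                    voxels, bundle.displacement, mode=cfg.expansion_axis_mode
                )
            except ValueError:
                # volumetrically static lesion: no deformation to orient
                exp_ax, exp_flags = None, ["zero_displacement"]
            exp_axis_of[uid] = exp_ax
            dir_label = classify_change_direction(
                exp_ax, axes, cfg.angle_threshold_deg, cfg.v90_mode
            )

            rows.append(
                {
                    "uid": uid,
                    "patient_id": pid,
                    "lesion_id": lid,
                    "arm": bundle.spec.arm,
                    "volume_mm3": shp.volume_mm3,
                    "anisotropy": shp.anisotropy,
                    **_axis_cols("centroid", shp.centroid),
                    "lambda1_mm": shp.axis_lengths[0],
                    "lambda2_mm": shp.axis_lengths[1],
                    "lambda3_mm": shp.axis_lengths[2],
                    **_axis_cols("eps1", shp.major_axis),
                    **_axis_cols("g", axes.g),
                    **_axis_cols("w", axes.w),
                    **_axis_cols("v", axes.v),
                    **_axis_cols("v90", axes.v90),
                    "vein_voxel_count": axes.vein_voxel_count,
                    "category": label.category,
                    "exclusive": label.exclusive,
                    **{
                        f"angle_{f}_deg": label.angles.get(f, np.nan)
                        for f in ("G", "W", "V", "V90")
                    },
                    "mean_jacobian": lesion_mean_jacobian(voxels, jac),
                    **_axis_cols("expansion_axis", exp_ax),
                    "direction_category": dir_label.category if dir_label else "UNDEFINED",
                    "delta_mtr_pu": lesion_mtr_change(mtr0, mtr1, voxels),
                    "qc_flags": ";".join(shp.qc_flags + axes.qc_flags + exp_flags),
                }
            )

    return PatientResult(
        patient_id=pid,
        lesions=pd.DataFrame(rows),
        excluded=pd.DataFrame(excluded_rows),
        labels=labels,
        feature_axes=axes_of,
        expansion_axes=exp_axis_of,
    )


@dataclass
class CohortResult:
    lesions: pd.DataFrame
    excluded: pd.DataFrame
    patient_summary: pd.DataFrame
    cohort_proportions: pd.Series
    vs_chance: pd.DataFrame
    mtr_by_group: pd.DataFrame


def analyze_cohort(bundles: list[PhantomBundle], cfg: AnalysisConfig) -> CohortResult:
    """Full pipeline over a cohort of input bundles."""
    per_patient = [analyze_patient(b, cfg) for b in bundles]
    lesions = pd.concat(
        [r.lesions for r in per_patient if len(r.lesions)], ignore_index=True
    )
    excluded = pd.concat(
        [r.excluded for r in per_patient if len(r.excluded)], ignore_index=True
    ) if any(len(r.excluded) for r in per_patient) else pd.DataFrame(
        columns=["patient_id", "lesion_id", "reason"]
    )

    with stage_timer("cohort:dynamics"):
        mean_jac = dict(zip(lesions["uid"], lesions["mean_jacobian"]))
        dyn = classify_dynamics(mean_jac, cfg.sd_multiplier)
        lesions["dyn_class"] = lesions["uid"].map(dyn)

    with stage_timer("cohort:summaries"):
        # OrientationLabel keeps per-patient lesion ids; remap to unique ids
        relabeled = []
        patient_map = {}
        for r in per_patient:
            for l in r.labels:
                uid = f"{r.patient_id}_L{l.lesion_id}"
                ll = type(l)(
                    lesion_id=uid, aligned=l.aligned, category=l.category,
                    exclusive=l.exclusive, angles=l.angles,
                )
                relabeled.append(ll)
                patient_map[uid] = r.patient_id

        patient_summary = per_patient_proportions(relabeled, patient_map)
        cohort_props = cohort_mean_proportions(patient_summary)
        vs_chance = vs_chance_table(
            relabeled, patient_map, chance_single(cfg.angle_threshold_deg)
        )
        mtr_by_group = group_mtr_table(
            lesions.rename(columns={"delta_mtr_pu": "delta_mtr"})[
                ["category", "arm", "delta_mtr"]
            ]
        )

    return CohortResult(
        lesions=lesions,
        excluded=excluded,
        patient_summary=patient_summary,
        cohort_proportions=cohort_props,
        vs_chance=vs_chance,
        mtr_by_group=mtr_by_group,
    )
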