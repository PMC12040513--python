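"""Per-patient aggregation, observed-vs-chance tests and group MTR tables.

Proportions are computed within patient first and then averaged unweighted
across patients, so patients with many lesions do not dominate cohort
percentages.  Observed-vs-chance comparisons use the exact binomial test on
pooled lesion counts against the theoretical alignment probability, with a
per-patient sign summary alongside; p-values are not adjusted for multiple
comparisons by default (a Benjamini-Hochberg switch is provided).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import logger
from .orientation import CATEGORIES, OrientationLabel


def per_patient_proportions(
    labels: list[OrientationLabel],
    patient_of: dict[int, str],
    categories: tuple[str, ...] = CATEGORIES,
) -> pd.DataFrame:
    """Within-patient category proportions, one row per patient.

    Every lesion must be mapped to a patient; patients with zero included
    lesions are dropped with a warning.  The cohort summary row is the
    unweighted mean across patients and is exposed via
    :func:`cohort_mean_proportions`.
    """
    recs = []
    for lab in labels:
        if lab.lesion_id not in patient_of:
            raise KeyError(f"lesion {lab.lesion_id} has no patient mapping")
        recs.append({"patient_id": patient_of[lab.lesion_id], "category": lab.category})
    df = pd.DataFrame(recs)
    rows = []
    for pid, grp in df.groupby("patient_id", sort=True):
        n = len(grp)
        if n == 0:
            logger.warning("patient %s has no included lesions; dropped", pid)
            continue
        counts = grp["category"].value_counts()
        row = {"patient_id": pid, "n_lesions": n}
        for c in categories:
            row[f"prop_{c}"] = counts.get(c, 0) / n
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_mean_proportions(per_patient: pd.DataFrame) -> pd.Series:
    """Unweighted across-patient mean of each category proportion."""
    cols = [c for c in per_patient.columns if c.startswith("prop_")]
    out = per_patient[cols].mean(axis=0)
    out.index = [c.removeprefix("prop_") for c in cols]
    return out


def observed_vs_chance(
    n_aligned: int,
    n_total: int,
    expected: float,
    per_patient_props: np.ndarray | None = None,
) -> dict:
    """Exact binomial test of pooled alignment counts against a theoretical
    chance probability, plus a per-patient sign summary.

    ``direction`` is "more"/"less" relative to ``expected`` or "none" when
    the two-sided p-value is not below 0.05.
    """
    if not (0.0 < expected < 1.0):
        raise ValueError("expected probability must lie in (0, 1)")
    if n_total <= 0:
        raise ValueError("no observations")
    res = stats.binomtest(n_aligned, n_total, expected, alternative="two-sided")
    observed = n_aligned / n_total
    if res.pvalue < 0.05:
        direction = "more" if observed > expected else "less"
    else:
        direction = "none"
    out = {
        "n_aligned": n_aligned,
        "n_total": n_total,
        "observed": observed,
        "expected": expected,
        "p_value": float(res.pvalue),
        "direction": direction,
    }
    if per_patient_props is not None:
        props = np.asarray(per_patient_props, dtype=float)
        out["n_patients_above"] = int((props > expected).sum())
        out["n_patients_below"] = int((props < expected).sum())
    return out


def vs_chance_table(
    labels: list[OrientationLabel],
    patient_of: dict[int, str],
    expected_single: float,
    features: tuple[str, ...] = ("G", "W", "V", "V90"),
) -> pd.DataFrame:
    """Observed-vs-chance comparison for each feature, both exclusive
    (aligned with that feature alone) and overall (aligned with it at all)."""
    df = pd.DataFrame(
        {
            "patient_id": [patient_of[l.lesion_id] for l in labels],
            **{
                f: [f in l.aligned for l in labels] for f in features
            },
            "exclusive": [l.exclusive for l in labels],
            "category": [l.category for l in labels],
        }
    )
    rows = []
    for f in features:
        for scope in ("exclusive", "overall"):
            if scope == "exclusive":
                hit = df[f] & df["exclusive"]
            else:
                hit = df[f]
            per_pat = df.assign(hit=hit).groupby("patient_id")["hit"].mean().to_numpy()
            res = observed_vs_chance(
                int(hit.sum()), len(df), expected_single, per_pat
            )
            res.update({"feature": f, "scope": scope, "mean_patient_prop": per_pat.mean()})
            rows.append(res)
    return pd.DataFrame(rows)


def group_mtr_table(
    lesion_table: pd.DataFrame,
    min_cell_n: int = 5,
    adjust: bool = False,
) -> pd.DataFrame:
    """Unadjusted per-category mean (SD) lesion MTR change by treatment arm.

    ``lesion_table`` needs columns ``category``, ``arm`` and ``delta_mtr``.
    Cells with fewer than ``min_cell_n`` lesions are kept but flagged.  The
    between-arm column is the raw difference of cell means (first arm listed
    minus second); covariate-adjusted modelling is out of scope here.  With
    ``adjust=True`` a Benjamini-Hochberg column is added to the Welch t-test
    p-values.
    """
    required = {"category", "arm", "delta_mtr"}
    if not required <= set(lesion_table.columns):
        raise KeyError(f"lesion table must have columns {sorted(required)}")
    arms = sorted(lesion_table["arm"].dropna().unique())
    rows = []
    for cat, grp in lesion_table.groupby("category", sort=True):
        row: dict = {"category": cat}
        cells = {}
        for arm in arms:
            vals = grp.loc[grp["arm"] == arm, "delta_mtr"].dropna().to_numpy()
            cells[arm] = vals
            row[f"n_{arm}"] = len(vals)
            row[f"mean_{arm}"] = vals.mean() if len(vals) else np.nan
            row[f"sd_{arm}"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
        row["low_count_flag"] = any(len(v) < min_cell_n for v in cells.values())
        if len(arms) == 2:
            a, b = arms
            row["arm_difference"] = row[f"mean_{a}"] - row[f"mean_{b}"]
            if len(cells[a]) > 1 and len(cells[b]) > 1:
                row["p_value"] = float(
                    stats.ttest_ind(cells[a], cells[b], equal_var=False).pvalue
                )
            else:
                row["p_value"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    if adjust and "p_value" in out:
        from statsmodels.stats.multitest import multipletests

        ok = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
        out["p_value_bh"] = adj
    return out
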