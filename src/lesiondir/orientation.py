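"""Angular classification of lesion axes against feature axes, the
11-category orientation taxonomy, and chance-alignment probabilities.

A lesion axis is attributed to a feature when the (axial) angle between the
two is strictly below the threshold (45 deg in the headline analysis; 30 deg
as the sensitivity setting).  Because the lesion and feature directions are
axes rather than signed vectors, angles are folded to [0, 90] via the
absolute dot product.  The resulting aligned set over {G, W, V, V90} maps to
one of 11 canonical categories or NONE; V and V90 are mutually exclusive at
thresholds <= 45 deg by the geometry of orthogonal axes
(cos^2 a + cos^2 b <= 1).

The chance model for a single feature axis is the spherical-cap fraction of
a uniformly random axis: P(angle < t) = 1 - cos t, giving 29% at 45 deg.
Joint category probabilities for a lesion's actual axis geometry are
estimated by Monte-Carlo sphere sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .direction_fields import FeatureAxes

FEATURES = ("G", "W", "V", "V90")

#: canonical category name for each admissible aligned subset
CATEGORY_NAMES = {
    frozenset(): "NONE",
    frozenset({"G"}): "G",
    frozenset({"V"}): "V",
    frozenset({"W"}): "W",
    frozenset({"V90"}): "V90",
    frozenset({"G", "V"}): "GV",
    frozenset({"G", "W"}): "GW",
    frozenset({"W", "V"}): "WV",
    frozenset({"G", "V90"}): "GV90",
    frozenset({"W", "V90"}): "WV90",
    frozenset({"G", "W", "V"}): "GWV",
    frozenset({"G", "W", "V90"}): "GWV90",
}

CATEGORIES = tuple(
    n for n in ("G", "GV", "W", "WV", "V", "GW", "GWV", "V90", "GV90", "WV90", "GWV90", "NONE")
)


@dataclass
class OrientationLabel:
    lesion_id: int
    aligned: frozenset
    category: str
    exclusive: bool
    angles: dict = field(default_factory=dict)   # degrees to each defined axis

    @property
    def is_none(self) -> bool:
        return self.category == "NONE"


def label_from_category(lesion_id, category: str) -> OrientationLabel:
    """Rebuild a minimal OrientationLabel from its canonical category name
    (inverse of the classification naming; used when re-reading CSV output)."""
    lookup = {name: key for key, name in CATEGORY_NAMES.items()}
    if category not in lookup:
        raise ValueError(f"unknown category {category!r}")
    aligned = lookup[category]
    return OrientationLabel(
        lesion_id=lesion_id,
        aligned=aligned,
        category=category,
        exclusive=len(aligned) == 1,
        angles={},
    )


def angle_between_axes(a: np.ndarray, b: np.ndarray) -> float:
    """Axial angle between two directions, in degrees within [0, 90]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cannot measure an angle to a zero vector")
    c = abs(float(a @ b)) / (na * nb)
    return float(np.degrees(np.arccos(min(c, 1.0))))


def _canonical_category(aligned: set[str]) -> str:
    key = frozenset(aligned)
    if key not in CATEGORY_NAMES:
        raise ValueError(f"inadmissible aligned set {sorted(aligned)}")
    return CATEGORY_NAMES[key]


def classify_axis(
    axis: np.ndarray,
    axes: FeatureAxes,
    threshold_deg: float = 45.0,
    v90_mode: str = "projection",
) -> OrientationLabel:
    """Attribute a lesion axis to every defined feature axis within the
    threshold (strict inequality) and name the resulting category.

    ``v90_mode`` selects the orthogonal-to-vein rule: ``"projection"`` tests
    the axis against the stored v90 axis; ``"plane"`` declares V90 alignment
    whenever the angle to the vein itself exceeds the threshold.

    Lesions with an undefined vein axis must be filtered out upstream; this
    function still classifies on whatever axes are defined.
    """
    if axis is None:
        raise ValueError("lesion axis undefined")
    if not (0.0 < threshold_deg < 90.0):
        raise ValueError("threshold must lie in (0, 90) degrees")
    defined = axes.defined()
    angles = {name: angle_between_axes(axis, ax) for name, ax in defined.items()}
    aligned = {name for name, ang in angles.items() if ang < threshold_deg and name != "V90"}
    if "V90" in defined:
        if v90_mode == "projection":
            v90_hit = angles["V90"] < threshold_deg
        elif v90_mode == "plane":
            v90_hit = "V" in angles and angles["V"] > threshold_deg
        else:
            raise ValueError(f"unknown v90_mode {v90_mode!r}")
        if v90_hit:
            aligned.add("V90")
    if "V" in aligned and "V90" in aligned:
        # geometrically impossible for threshold <= 45; for larger
        # thresholds keep the closer of the two axes
        drop = "V90" if angles["V"] <= angles.get("V90", 90.0) else "V"
        aligned.discard(drop)
    return OrientationLabel(
        lesion_id=axes.lesion_id,
        aligned=frozenset(aligned),
        category=_canonical_category(aligned),
        exclusive=len(aligned) == 1,
        angles=angles,
    )


def classify_lesion(
    eps1: np.ndarray,
    axes: FeatureAxes,
    threshold_deg: float = 45.0,
    v90_mode: str = "projection",
) -> OrientationLabel:
    """Baseline orientation category of a lesion's major axis."""
    return classify_axis(eps1, axes, threshold_deg, v90_mode)


def chance_single(threshold_deg: float) -> float:
    """Probability that a uniformly random axis falls within ``threshold_deg``
    of one fixed axis: the spherical-cap (sector) fraction 1 - cos(t)."""
    if not (0.0 < threshold_deg <= 90.0):
        raise ValueError("threshold must lie in (0, 90] degrees")
    return float(1.0 - np.cos(np.deg2rad(threshold_deg)))


def sample_uniform_axes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random unit axes on the sphere (n, 3)."""
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def chance_joint(
    axes: FeatureAxes,
    threshold_deg: float = 45.0,
    n_samples: int = 100_000,
    seed: int = 0,
    v90_mode: str = "projection",
) -> dict[str, float]:
    """Monte-Carlo category probabilities for a random lesion axis given this
    lesion's actual feature-axis geometry.

    Returns a map category -> probability over the mutually exclusive
    categories (11 + NONE); entries for categories inadmissible under this
    lesion's defined axes are 0 and the values sum to 1.
    """
    defined = axes.defined()
    if not defined:
        raise ValueError("no defined feature axes")
    rng = np.random.default_rng(seed)
    samples = sample_uniform_axes(n_samples, rng)
    cos_t = np.cos(np.deg2rad(threshold_deg))

    hits: dict[str, np.ndarray] = {}
    for name, ax in defined.items():
        hits[name] = np.abs(samples @ np.asarray(ax)) > cos_t
    if "V90" in defined and v90_mode == "plane":
        hits["V90"] = ~hits.get("V", np.zeros(n_samples, bool))
    if "V" in hits and "V90" in hits:
        both = hits["V"] & hits["V90"]
        if both.any():
            av = np.degrees(np.arccos(np.clip(np.abs(samples @ defined["V"]), 0, 1)))
            a9 = np.degrees(np.arccos(np.clip(np.abs(samples @ defined["V90"]), 0, 1)))
            keep_v = av <= a9
            hits["V"] = hits["V"] & (~both | keep_v)
            hits["V90"] = hits["V90"] & (~both | ~keep_v)

    # encode each sample's aligned subset and count categories
    probs = {c: 0.0 for c in CATEGORIES}
    code = np.zeros(n_samples, dtype=np.int8)
    for bit, name in enumerate(FEATURES):
        if name in hits:
            code |= hits[name].astype(np.int8) << bit
    counts = np.bincount(code, minlength=16)
    for subset_code, n in enumerate(counts):
        if n == 0:
            continue
        aligned = {name for bit, name in enumerate(FEATURES) if subset_code >> bit & 1}
        probs[_canonical_category(aligned)] += n / n_samples
    return probs
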