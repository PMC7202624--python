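"""Trainable pixel classification of elastin vs background.

Training protocol: multi-scale filter-bank features per pixel, random
undersampling of the majority class, correlation-based feature-subset
selection (CFS), information-gain-ratio ranking, and a bagged random forest
(200 trees by default).  Prediction thresholds the forest's elastin
probability and forces pixels outside the FOV to background.

The feature bank is a fixed, documented set of 8 filter responses per scale
(Gaussian smoothing, gradient magnitude, Laplacian of Gaussian, the two
Hessian eigenvalues, difference of Gaussians, local variance, local median)
at scales sigma in {1, 2, 4, 8, 16} pixels, boundary-handled by reflective
padding.  It is configurable via :class:`FeatureBankConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .errors import ValidationError
from .image_io import PCLEImage
from .postprocess import SegmentationMask

#: Class codes used in label images and training sets.
CLASS_ELASTIN = 1
CLASS_BACKGROUND = 2

#: Feature bank archive format version; models refuse to load across versions.
BANK_VERSION = "1"

_DISCRETIZE_BINS = 10  # equal-frequency bins for CFS / gain ratio


@dataclass(frozen=True)
class FeatureBankConfig:
    scales: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0)
    version: str = BANK_VERSION

    def feature_names(self) -> list[str]:
        names = []
        for s in self.scales:
            tag = f"{s:g}"
            names += [
                f"gauss_s{tag}",
                f"gradmag_s{tag}",
                f"log_s{tag}",
                f"hess_max_s{tag}",
                f"hess_min_s{tag}",
                f"dog_s{tag}",
                f"var_s{tag}",
                f"median_s{tag}",
            ]
        return names


@dataclass
class FeatureStack:
    """Per-pixel feature vectors over the named bank."""

    features: np.ndarray  # (H, W, F) float32
    feature_names: list[str]
    fov_mask: np.ndarray
    spacing_um: float

    def __post_init__(self) -> None:
        if self.features.shape[-1] != len(self.feature_names):
            raise ValidationError("feature_names length must equal stack depth")


def compute_features(
    image: PCLEImage, bank: FeatureBankConfig = FeatureBankConfig()
) -> FeatureStack:
    """Deterministic multi-scale feature stack (reflective boundary handling).

    Pixels outside the FOV carry features too; they are flagged through the
    stack's ``fov_mask`` and handled at prediction time.
    """
    img = image.pixels.astype(np.float64)
    planes = []
    for s in bank.scales:
        gauss = ndimage.gaussian_filter(img, s, mode="reflect")
        gradmag = ndimage.gaussian_gradient_magnitude(img, s, mode="reflect")
        # Hessian by central differences of the smoothed image: exactly zero
        # on constant input (truncated 2nd-order Gaussian kernels are not).
        gr, gc = np.gradient(gauss)
        hrr, hrc = np.gradient(gr)
        hcc = np.gradient(gc, axis=1)
        log = hrr + hcc
        half_trace = (hrr + hcc) / 2.0
        disc = np.sqrt(((hrr - hcc) / 2.0) ** 2 + hrc**2)
        dog = gauss - ndimage.gaussian_filter(img, 1.6 * s, mode="reflect")
        local_var = np.clip(
            ndimage.gaussian_filter(img**2, s, mode="reflect") - gauss**2, 0.0, None
        )
        size = 2 * int(round(s)) + 1
        local_median = ndimage.median_filter(img, size=size, mode="reflect")
        planes += [
            gauss,
            gradmag,
            log,
            half_trace + disc,
            half_trace - disc,
            dog,
            local_var,
            local_median,
        ]
    stack = np.stack(planes, axis=-1).astype(np.float32)
    return FeatureStack(
        features=stack,
        feature_names=bank.feature_names(),
        fov_mask=image.fov_mask,
        spacing_um=image.spacing_um,
    )


@dataclass
class TrainingSet:
    """Labelled pixel instances with provenance."""

    X: np.ndarray  # (n, F)
    y: np.ndarray  # (n,), values in {CLASS_ELASTIN, CLASS_BACKGROUND}
    feature_names: list[str]
    provenance: list[tuple[str, tuple[int, int]]]

    @property
    def n_instances(self) -> int:
        return int(self.y.size)

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.y, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def subset(self, idx: np.ndarray) -> "TrainingSet":
        return TrainingSet(
            X=self.X[idx],
            y=self.y[idx],
            feature_names=self.feature_names,
            provenance=[self.provenance[i] for i in idx],
        )


def collect_instances(
    stack: FeatureStack, labels: np.ndarray, source_id: str = ""
) -> TrainingSet:
    """One instance per labelled pixel; unlabelled (0) pixels are ignored."""
    labels = np.asarray(labels)
    if labels.shape != stack.features.shape[:2]:
        raise ValidationError(
            f"label shape {labels.shape} does not match image shape "
            f"{stack.features.shape[:2]}"
        )
    coords = np.argwhere(labels > 0)
    if coords.size == 0:
        raise ValidationError("label image contains no labelled pixels")
    y = labels[coords[:, 0], coords[:, 1]].astype(np.int64)
    present = set(np.unique(y).tolist())
    if not {CLASS_ELASTIN, CLASS_BACKGROUND} <= present:
        raise ValidationError(
            f"both classes must be labelled; found only classes {sorted(present)}"
        )
    X = stack.features[coords[:, 0], coords[:, 1], :]
    provenance = [(source_id, (int(r), int(c))) for r, c in coords]
    return TrainingSet(
        X=X, y=y, feature_names=stack.feature_names, provenance=provenance
    )


def concat_training_sets(sets: Sequence[TrainingSet]) -> TrainingSet:
    names = sets[0].feature_names
    for ts in sets[1:]:
        if ts.feature_names != names:
            raise ValidationError("cannot concatenate sets with different banks")
    return TrainingSet(
        X=np.concatenate([ts.X for ts in sets]),
        y=np.concatenate([ts.y for ts in sets]),
        feature_names=names,
        provenance=[p for ts in sets for p in ts.provenance],
    )


def undersample(ts: TrainingSet, seed: int) -> TrainingSet:
    """Random undersampling of the majority class to exact class balance.

    Minority instances are untouched; majority instances are subsampled
    without replacement.  Already-balanced sets are returned unchanged.
    """
    counts = ts.class_counts()
    if len(counts) < 2:
        raise ValidationError("both classes must be present")
    (c_min, n_min), (c_maj, n_maj) = sorted(counts.items(), key=lambda kv: kv[1])
    if n_min == n_maj:
        return ts
    rng = np.random.default_rng(seed)
    maj_idx = np.flatnonzero(ts.y == c_maj)
    keep_maj = rng.choice(maj_idx, size=n_min, replace=False)
    idx = np.sort(np.concatenate([np.flatnonzero(ts.y == c_min), keep_maj]))
    return ts.subset(idx)


# ---------------------------------------------------------------------------
# Discretization and information measures (shared by CFS and gain ratio)

def _discretize(x: np.ndarray, bins: int = _DISCRETIZE_BINS) -> np.ndarray:
    """Equal-frequency discretization into at most ``bins`` integer codes."""
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="left")


def _entropy_codes(codes: np.ndarray) -> float:
    counts = np.bincount(codes)
    p = counts[counts > 0] / codes.size
    return float(-np.sum(p * np.log2(p)))


def _mutual_info(a: np.ndarray, b: np.ndarray) -> float:
    """I(a;b) in bits for integer-coded variables."""
    n_a, n_b = a.max() + 1, b.max() + 1
    joint = np.bincount(a * n_b + b, minlength=n_a * n_b).reshape(n_a, n_b)
    joint = joint / joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (pa @ pb)[nz])))


def _symmetrical_uncertainty(a: np.ndarray, b: np.ndarray) -> float:
    ha, hb = _entropy_codes(a), _entropy_codes(b)
    if ha == 0 or hb == 0:
        return 0.0
    return 2.0 * _mutual_info(a, b) / (ha + hb)


def cfs_merit(r_cf: np.ndarray, r_ff: np.ndarray, subset: Sequence[int]) -> float:
    """CFS merit of a feature subset.

    merit = k * mean(r_cf) / sqrt(k + k(k-1) * mean(r_ff)) where r_cf is the
    feature-class correlation and r_ff the pairwise feature-feature
    correlation (both symmetrical uncertainty).
    """
    k = len(subset)
    if k == 0:
        return 0.0
    mean_cf = float(np.mean(r_cf[list(subset)]))
    if k == 1:
        return mean_cf
    idx = np.asarray(subset)
    sub = r_ff[np.ix_(idx, idx)]
    mean_ff = float(sub[np.triu_indices(k, 1)].mean())
    return k * mean_cf / np.sqrt(k + k * (k - 1) * mean_ff)


def _su_tables(ts: TrainingSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Discretized features, feature-class SU vector and feature-feature SU matrix."""
    n_feat = ts.X.shape[1]
    codes = np.stack([_discretize(ts.X[:, j]) for j in range(n_feat)])
    y_codes = (ts.y == CLASS_ELASTIN).astype(np.int64)
    r_cf = np.array(
        [_symmetrical_uncertainty(codes[j], y_codes) for j in range(n_feat)]
    )
    r_ff = np.eye(n_feat)
    for i in range(n_feat):
        for j in range(i + 1, n_feat):
            r_ff[i, j] = r_ff[j, i] = _symmetrical_uncertainty(codes[i], codes[j])
    return codes, r_cf, r_ff


def select_features_cfs(ts: TrainingSet) -> list[str]:
    """Greedy forward correlation-based feature selection.

    Starting from the empty set, repeatedly add the feature that most
    increases the CFS merit; stop when no addition improves it.  Constant
    features are excluded up front with a warning.  Always returns a
    non-empty subset.
    """
    if ts.X.shape[1] < 2:
        raise ValidationError("CFS needs at least 2 features")
    if len(ts.class_counts()) < 2:
        raise ValidationError("both classes must be present")
    codes, r_cf, r_ff = _su_tables(ts)
    candidates = []
    for j in range(ts.X.shape[1]):
        if np.unique(codes[j]).size < 2:
            warnings.warn(
                f"excluding constant feature {ts.feature_names[j]!r} from CFS"
            )
        else:
            candidates.append(j)
    if not candidates:
        raise ValidationError("all features are constant")
    selected: list[int] = []
    best_merit = 0.0
    while True:
        gains = [
            (cfs_merit(r_cf, r_ff, selected + [j]), j)
            for j in candidates
            if j not in selected
        ]
        if not gains:
            break
        merit, j = max(gains)
        if merit <= best_merit and selected:
            break
        selected.append(j)
        best_merit = merit
    return [ts.feature_names[j] for j in sorted(selected)]


def rank_information_gain_ratio(ts: TrainingSet) -> list[tuple[str, float]]:
    """Features ranked by information gain ratio, descending.

    gain ratio = (H(class) - H(class | feature)) / H(feature) on
    equal-frequency discretized features; features with zero entropy get
    ratio 0 by convention.
    """
    if len(ts.class_counts()) < 2:
        raise ValidationError("both classes must be present")
    y_codes = (ts.y == CLASS_ELASTIN).astype(np.int64)
    out = []
    for j, name in enumerate(ts.feature_names):
        codes = _discretize(ts.X[:, j])
        h_f = _entropy_codes(codes)
        ratio = 0.0 if h_f == 0 else _mutual_info(codes, y_codes) / h_f
        out.append((name, float(ratio)))
    out.sort(key=lambda kv: -kv[1])
    return out


@dataclass
class ClassifierModel:
    """Trained forest plus everything needed to reproduce its inputs."""

    forest: RandomForestClassifier
    selected_features: list[str]
    bank: FeatureBankConfig
    training_seed: int
    n_trees: int
    decision_threshold: float = 0.5
    feature_ranking: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if not self.selected_features:
            raise ValidationError("selected_features must be non-empty")

    def save(self, path) -> None:
        joblib.dump(
            {
                "bank_version": self.bank.version,
                "bank_scales": self.bank.scales,
                "forest": self.forest,
                "selected_features": self.selected_features,
                "training_seed": self.training_seed,
                "n_trees": self.n_trees,
                "decision_threshold": self.decision_threshold,
                "feature_ranking": self.feature_ranking,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        blob = joblib.load(path)
        if blob.get("bank_version") != BANK_VERSION:
            raise ValidationError(
                f"model bank version {blob.get('bank_version')!r} is incompatible "
                f"with this package (expected {BANK_VERSION!r})"
            )
        return cls(
            forest=blob["forest"],
            selected_features=blob["selected_features"],
            bank=FeatureBankConfig(scales=tuple(blob["bank_scales"])),
            training_seed=blob["training_seed"],
            n_trees=blob["n_trees"],
            decision_threshold=blob["decision_threshold"],
            feature_ranking=blob["feature_ranking"],
        )


def train_forest(
    ts: TrainingSet,
    n_trees: int = 200,
    seed: int = 0,
    selected_features: Optional[list[str]] = None,
    bank: FeatureBankConfig = FeatureBankConfig(),
    decision_threshold: float = 0.5,
) -> ClassifierModel:
    """Bagged random forest with per-node sqrt(d) feature subsetting.

    ``selected_features`` restricts training to a feature subset (as produced
    by CFS); the default uses the full bank.
    """
    if n_trees < 1:
        raise ValidationError("n_trees must be >= 1")
    if len(ts.class_counts()) < 2:
        raise ValidationError("both classes must be present")
    names = selected_features if selected_features else list(ts.feature_names)
    missing = [n for n in names if n not in ts.feature_names]
    if missing:
        raise ValidationError(f"unknown feature names: {missing}")
    cols = [ts.feature_names.index(n) for n in names]
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(ts.X[:, cols], ts.y)
    return ClassifierModel(
        forest=forest,
        selected_features=names,
        bank=bank,
        training_seed=seed,
        n_trees=n_trees,
        decision_threshold=decision_threshold,
    )


def _elastin_probability(model: ClassifierModel, X: np.ndarray) -> np.ndarray:
    proba = model.forest.predict_proba(X)
    class_idx = list(model.forest.classes_).index(CLASS_ELASTIN)
    return proba[:, class_idx]


def _model_columns(model: ClassifierModel, feature_names: list[str]) -> list[int]:
    missing = [n for n in model.selected_features if n not in feature_names]
    if missing:
        raise ValidationError(f"feature stack is missing features: {missing}")
    return [feature_names.index(n) for n in model.selected_features]


def predict_mask(model: ClassifierModel, stack: FeatureStack) -> SegmentationMask:
    """Per-pixel elastin probability thresholded at the decision threshold.

    Pixels outside the FOV are forced to background.
    """
    cols = _model_columns(model, stack.feature_names)
    h, w = stack.features.shape[:2]
    X = stack.features[..., cols].reshape(-1, len(cols))
    p = _elastin_probability(model, X).reshape(h, w)
    mask = (p >= model.decision_threshold) & stack.fov_mask
    return SegmentationMask(
        mask=mask, spacing_um=stack.spacing_um, fov_mask=stack.fov_mask
    )


def predict_probability(model: ClassifierModel, stack: FeatureStack) -> np.ndarray:
    """Elastin probability image (no thresholding, FOV not applied)."""
    cols = _model_columns(model, stack.feature_names)
    h, w = stack.features.shape[:2]
    X = stack.features[..., cols].reshape(-1, len(cols))
    return _elastin_probability(model, X).reshape(h, w)


def evaluate_roc(model: ClassifierModel, test: TrainingSet) -> float:
    """Area under the ROC curve on a held-out set (rank statistic, midranks)."""
    if len(test.class_counts()) < 2:
        raise ValidationError("test set must contain both classes")
    cols = [test.feature_names.index(n) for n in model.selected_features]
    p = _elastin_probability(model, test.X[:, cols])
    return float(roc_auc_score(test.y == CLASS_ELASTIN, p))
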