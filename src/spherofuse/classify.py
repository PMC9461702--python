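"""Semi-automated doublet-candidate triage.

Each detected microwell of the first frame is summarized by a fixed vector of
morphological and intensity descriptors of its segmented content, and a
cost-sensitive random forest separates positive wells (a usable spheroid
pair, manual labels 1 or 2) from negative ones (label 0: empty, debris,
single spheroids, triplets, or hopelessly overlapping pairs).  Because only
~8% of wells hold a usable doublet and a missed doublet is lost to the assay
while a false positive merely costs a click during review, false negatives
are charged five times the cost of false positives — both through
class-weighted training and through a cost-minimizing decision threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .microwell import WellCircle
from .segment import EmptyWellError, _segment_crop

__all__ = ["ClassifierSpec", "DoubletClassifier", "FEATURE_NAMES",
           "well_features", "train_classifier", "evaluate_classifier",
           "binary_metrics"]


@dataclass(frozen=True)
class ClassifierSpec:
    """Random-forest settings; defaults follow the published configuration."""

    n_trees: int = 60
    predictors_per_split: int = 30
    min_leaf_size: int = 3
    fn_cost: float = 5.0   # cost of missing a true doublet
    fp_cost: float = 1.0   # cost of passing a non-doublet to review


_OBJ_PROPS = ("area", "perimeter", "solidity", "eccentricity",
              "equivalent_diameter_area", "axis_major_length",
              "axis_minor_length", "extent")

FEATURE_NAMES: tuple[str, ...] = (
    "object_count", "small_object_count", "small_object_area",
    "covered_fraction", "centroid_distance_norm",
    "area_1", "perimeter_1", "roundness_1", "solidity_1", "eccentricity_1",
    "eq_radius_1", "major_axis_1", "minor_axis_1", "extent_1",
    "area_2", "perimeter_2", "roundness_2", "solidity_2", "eccentricity_2",
    "eq_radius_2", "major_axis_2", "minor_axis_2", "extent_2",
    "area_ratio", "total_object_area", "interior_mean", "interior_sd",
    "interior_contrast", "object_mean_intensity", "focus_proxy",
    "center_offset_norm", "pair_axis_eccentricity",
)


def well_features(crop: np.ndarray, well: WellCircle,
                  min_area: int = 150) -> np.ndarray:
    """Descriptor vector of one well crop (fixed length/order, finite).

    The well interior is segmented with the same operator chain as the
    doublet initialization, but keeping every component; descriptors cover
    the two largest objects (area, shape, roundness), their size ratio and
    centre distance, small-object (debris) statistics, interior intensity
    statistics and a gradient-energy focus proxy.  Empty wells yield
    all-zero object descriptors rather than errors.
    """
    crop = np.asarray(crop, dtype=float)
    yy, xx = np.mgrid[: crop.shape[0], : crop.shape[1]]
    interior_radius = well.radius - 1.0
    interior = np.hypot(xx - well.x, yy - well.y) < interior_radius
    try:
        mask = _segment_crop(crop, (well.x, well.y), interior_radius,
                             min_area=3, max_components=64,
                             second_component_frac=0.0)
    except EmptyWellError:
        mask = np.zeros_like(interior)
    labels, n = ndimage.label(mask)
    props = measure.regionprops(labels)
    big = sorted((p for p in props if p.area >= min_area),
                 key=lambda p: p.area, reverse=True)
    small = [p for p in props if p.area < min_area]
    feats: dict[str, float] = {name: 0.0 for name in FEATURE_NAMES}
    feats["object_count"] = float(len(big))
    feats["small_object_count"] = float(len(small))
    feats["small_object_area"] = float(sum(p.area for p in small))
    feats["total_object_area"] = float(mask.sum())
    feats["covered_fraction"] = float(mask.sum() / interior.sum())
    for i, p in enumerate(big[:2], start=1):
        feats[f"area_{i}"] = float(p.area)
        feats[f"perimeter_{i}"] = float(p.perimeter)
        feats[f"roundness_{i}"] = float(
            4 * np.pi * p.area / max(p.perimeter, 1.0) ** 2)
        feats[f"solidity_{i}"] = float(p.solidity)
        feats[f"eccentricity_{i}"] = float(p.eccentricity)
        feats[f"eq_radius_{i}"] = float(p.equivalent_diameter_area / 2.0)
        feats[f"major_axis_{i}"] = float(p.axis_major_length)
        feats[f"minor_axis_{i}"] = float(p.axis_minor_length)
        feats[f"extent_{i}"] = float(p.extent)
    if len(big) >= 2:
        p1, p2 = big[0], big[1]
        feats["area_ratio"] = float(p2.area / p1.area)
        c1 = np.array(p1.centroid)
        c2 = np.array(p2.centroid)
        req = (p1.equivalent_diameter_area + p2.equivalent_diameter_area) / 2.0
        feats["centroid_distance_norm"] = float(
            np.linalg.norm(c1 - c2) / max(req, 1.0))
    vals = crop[interior]
    feats["interior_mean"] = float(vals.mean())
    feats["interior_sd"] = float(vals.std())
    p5, p95 = np.percentile(vals, [5, 95])
    feats["interior_contrast"] = float(p95 - p5)
    if mask.any():
        feats["object_mean_intensity"] = float(crop[mask].mean())
        ys, xs = np.nonzero(mask)
        feats["center_offset_norm"] = float(
            np.hypot(xs.mean() - well.x, ys.mean() - well.y) / well.radius)
        mu20 = np.mean((xs - xs.mean()) ** 2)
        mu02 = np.mean((ys - ys.mean()) ** 2)
        mu11 = np.mean((xs - xs.mean()) * (ys - ys.mean()))
        tr, det = mu20 + mu02, mu20 * mu02 - mu11 ** 2
        disc = max(tr * tr / 4 - det, 0.0)
        lam1 = tr / 2 + np.sqrt(disc)
        lam2 = max(tr / 2 - np.sqrt(disc), 1e-9)
        feats["pair_axis_eccentricity"] = float(np.sqrt(1 - lam2 / lam1))
    gy, gx = np.gradient(crop)
    feats["focus_proxy"] = float(np.mean((gx ** 2 + gy ** 2)[interior]))
    vec = np.array([feats[name] for name in FEATURE_NAMES], dtype=float)
    return np.nan_to_num(vec, nan=0.0, posinf=0.0, neginf=0.0)


# ---------------------------------------------------------------------------
# Training / prediction
# ---------------------------------------------------------------------------

@dataclass
class DoubletClassifier:
    """Fitted cost-sensitive forest plus its decision threshold."""

    forest: RandomForestClassifier
    threshold: float
    spec: ClassifierSpec

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forest.predict_proba(np.asarray(X, dtype=float))[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(int)


def _binarize(labels: np.ndarray) -> np.ndarray:
    """Manual labels {0,1,2} -> positive = {1,2}."""
    return (np.asarray(labels) >= 1).astype(int)


def train_classifier(X: np.ndarray, labels: np.ndarray,
                     spec: ClassifierSpec = ClassifierSpec(),
                     seed: int = 0) -> DoubletClassifier:
    """Train the cost-sensitive random forest on well feature vectors.

    Labels are binarized (1 and 2 are positive).  The false-negative /
    false-positive cost asymmetry enters twice: classes are weighted
    ``fn_cost : fp_cost`` during training, and the decision threshold on the
    predicted probability is chosen to minimize the empirical
    ``fn_cost * FN + fp_cost * FP`` on the training set (ties resolved
    toward the more sensitive, lower threshold).
    """
    X = np.asarray(X, dtype=float)
    y = _binarize(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    forest = RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features=min(spec.predictors_per_split, X.shape[1]),
        min_samples_leaf=spec.min_leaf_size,
        class_weight={0: spec.fp_cost, 1: spec.fn_cost},
        random_state=seed,
    )
    forest.fit(X, y)
    proba = forest.predict_proba(X)[:, 1]
    cands = np.unique(np.concatenate([[0.0, 0.5], proba]))
    best_thr, best_cost = 0.5, np.inf
    for thr in cands:  # ascending: later candidates win only on strict gain
        pred = proba >= thr
        cost = (spec.fn_cost * np.sum((pred == 0) & (y == 1))
                + spec.fp_cost * np.sum((pred == 1) & (y == 0)))
        if cost < best_cost:
            best_cost, best_thr = cost, thr
    return DoubletClassifier(forest=forest, threshold=float(best_thr),
                             spec=spec)


def binary_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Accuracy, sensitivity, precision and F1 from a confusion table.

    Undefined ratios (no positives in truth, or no positive predictions)
    are reported as NaN, never as zero.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    acc = (tp + tn) / max(len(y_true), 1)
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    prec = tp / (tp + fp) if (tp + fp) else float("nan")
    f1 = (2 * prec * sens / (prec + sens)
          if (tp + fn) and (tp + fp) and (prec + sens) > 0 else float("nan"))
    return {"accuracy": acc, "sensitivity": sens, "precision": prec,
            "f1": f1, "tp": tp, "tn": tn, "fp": fp, "fn": fn}


@dataclass
class EvaluationReport:
    """Per-fold cross-validation metrics and their mean +/- SD summary."""

    per_fold: pd.DataFrame          # fold x group x metric (long format)
    summary: pd.DataFrame           # group x metric -> mean, sd

    def metric(self, name: str, group: str = "overall") -> tuple[float, float]:
        row = self.summary.loc[(self.summary["group"] == group)
                               & (self.summary["metric"] == name)]
        return float(row["mean"].iloc[0]), float(row["sd"].iloc[0])


def evaluate_classifier(X: np.ndarray, labels: np.ndarray,
                        groups: np.ndarray | None = None,
                        spec: ClassifierSpec = ClassifierSpec(),
                        k: int = 5, seed: int = 0) -> EvaluationReport:
    """K-fold cross-validated evaluation, stratified by group x class.

    Folds are stratified jointly on the acquisition group (e.g. maturation
    day) and the binarized class, so each ~1/k validation fold mirrors the
    per-group class balance — the k-fold analogue of a grouped 80/20 split.
    Metrics (accuracy, sensitivity, precision, F1) are reported per fold for
    the merged validation set and for each group, then summarized as mean
    +/- SD over folds; folds where a ratio is undefined are excluded from
    that ratio's summary rather than counted as zero.
    """
    X = np.asarray(X, dtype=float)
    y = _binarize(labels)
    if groups is None:
        groups = np.zeros(len(y), dtype=int)
    groups = np.asarray(groups)
    strat = np.array([f"{g}|{c}" for g, c in zip(groups, y)])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, va) in enumerate(skf.split(X, strat)):
        clf = train_classifier(X[tr], y[tr], spec=spec, seed=seed + fold)
        pred = clf.predict(X[va])
        m = binary_metrics(y[va], pred)
        rows.append({"fold": fold, "group": "overall", **m})
        for g in np.unique(groups):
            sel = groups[va] == g
            if sel.any():
                rows.append({"fold": fold, "group": str(g),
                             **binary_metrics(y[va][sel], pred[sel])})
    per_fold = pd.DataFrame(rows)
    metrics = ["accuracy", "sensitivity", "precision", "f1"]
    srows = []
    for g, gdf in per_fold.groupby("group"):
        for mname in metrics:
            vals = gdf[mname].dropna()
            srows.append({"group": g, "metric": mname,
                          "mean": vals.mean() if len(vals) else float("nan"),
                          "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                          "n_folds": len(vals)})
    return EvaluationReport(per_fold=per_fold, summary=pd.DataFrame(srows))
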