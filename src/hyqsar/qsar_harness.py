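"""QSAR model training, evaluation and hybridization experiments.

Implements the experimental machinery around the descriptor subsets: target
discretization into classes, seeded (stratified) train/test splits at the
standard 50/50, 66/34 and 75/25 rates, five learner families (linear
regression with Akaike backward elimination, decision stump, one-hidden-layer
back-propagation network, random forest, random committee), the evaluation
metrics of the WEKA tradition (CC, RAE, RRSE for regression; %CC, weighted
ROC area, confusion matrix, probability-residual RAE/RRSE for
classification), subset hybridization by ordered union, the 100-replicate
random-replacement significance test, and paired confidence-interval
comparison of two method's metric series.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .chemio import DescriptorTable
from .feature_select import DescriptorSubset

__all__ = [
    "Interval",
    "DiscretizationRule",
    "HIA_RULE",
    "BBB_RULE",
    "EE_RULE",
    "REFERENCE_SUBSETS",
    "SplitSpec",
    "LearnerSpec",
    "EvaluationReport",
    "ReplacementTestResult",
    "discretize",
    "split_dataset",
    "train_predict",
    "evaluate_regression",
    "evaluate_classification",
    "combine_subsets",
    "assemble_reaction_table",
    "run_replacement_test",
    "compare_with_ci",
]


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interval:
    lo: float
    hi: float
    lo_closed: bool
    hi_closed: bool

    def contains(self, v: float) -> bool:
        above = v > self.lo or (self.lo_closed and v == self.lo)
        below = v < self.hi or (self.hi_closed and v == self.hi)
        return above and below


@dataclass(frozen=True)
class DiscretizationRule:
    """Maps a numeric property to class labels via explicit intervals.

    Intervals must not overlap; several intervals may share a label (e.g. the
    two extreme enantiopurity bands). ``class_order`` fixes the nominal label
    order used for ARFF declarations, probability columns and tie-breaking.
    """

    property_name: str
    intervals: tuple[tuple[Interval, str], ...]
    class_order: tuple[str, ...]
    declared_range: tuple[float, float] = (-math.inf, math.inf)

    def __post_init__(self) -> None:
        if len(self.class_order) < 2:
            raise ValueError("a discretization rule needs at least 2 classes")
        labels = {lab for _, lab in self.intervals}
        if labels != set(self.class_order):
            raise ValueError("class_order must list exactly the interval labels")

    def class_labels(self) -> list[str]:
        return list(self.class_order)

    def apply(self, values: np.ndarray) -> np.ndarray:
        return discretize(values, self)


def discretize(values, rule: DiscretizationRule) -> np.ndarray:
    """Map each numeric value to its class label; values outside the declared
    range or uncovered by any interval raise with the offenders listed."""
    v = np.asarray(values, dtype=float)
    lo, hi = rule.declared_range
    out_of_range = [float(x) for x in v if not (lo <= x <= hi)]
    if out_of_range:
        raise ValueError(
            f"values outside declared range {rule.declared_range} for "
            f"{rule.property_name}: {out_of_range}")
    labels = np.empty(v.shape, dtype=object)
    for i, x in enumerate(v.ravel()):
        for interval, lab in rule.intervals:
            if interval.contains(float(x)):
                labels.ravel()[i] = lab
                break
        else:
            raise ValueError(f"value {x} matches no interval of {rule.property_name}")
    return labels


#: Intestinal absorption: fraction < 0.7 does not absorb, >= 0.7 absorbs.
HIA_RULE = DiscretizationRule(
    property_name="HIA",
    intervals=(
        (Interval(-math.inf, 0.7, False, False), "Not Absorb"),
        (Interval(0.7, math.inf, True, False), "Absorb"),
    ),
    class_order=("Not Absorb", "Absorb"),
    declared_range=(0.0, 1.0),
)

#: logBB <= -0.7 -> BBB+, (-0.7, -0.3] -> gray area, > -0.3 -> BBB-.
#: This orientation follows the published thresholds verbatim even though it
#: inverts the conventional reading (compounds crossing the barrier usually
#: have *high* logBB); relabel via a custom rule if needed.
BBB_RULE = DiscretizationRule(
    property_name="logBB",
    intervals=(
        (Interval(-math.inf, -0.7, False, True), "BBB+"),
        (Interval(-0.7, -0.3, False, True), "Gray area"),
        (Interval(-0.3, math.inf, False, False), "BBB-"),
    ),
    class_order=("BBB+", "Gray area", "BBB-"),
)

#: Enantiomeric excess: both extremes ([0,10] and [90,100], boundaries
#: included) are high-enantiopurity; the central band is low-enantiopurity.
EE_RULE = DiscretizationRule(
    property_name="ee",
    intervals=(
        (Interval(0.0, 10.0, True, True), "High-enantiopurity"),
        (Interval(10.0, 90.0, False, False), "Low-enantiopurity"),
        (Interval(90.0, 100.0, True, True), "High-enantiopurity"),
    ),
    class_order=("Low-enantiopurity", "High-enantiopurity"),
    declared_range=(0.0, 100.0),
)


#: Published descriptor subsets for the three endpoints (BBB, HIA, EE):
#: one learned subset per endpoint plus the two lowest-RAE selected subsets.
REFERENCE_SUBSETS: dict[str, dict[str, DescriptorSubset]] = {
    "BBB": {
        "CT_BBB": DescriptorSubset("CT_BBB", ["CODES-T1", "CODES-T2", "CODES-T3"],
                                   "learned"),
        "M2_BBB": DescriptorSubset("M2_BBB", ["nR06", "SIC1", "CIC5"], "selected"),
        "M13_BBB": DescriptorSubset(
            "M13_BBB",
            ["AMW", "RBN", "MATS5e", "MATS4p", "EEig12d", "JGI7", "Hy"],
            "selected"),
    },
    "HIA": {
        "CT_HIA": DescriptorSubset("CT_HIA", ["CODES-T1", "CODES-T2", "CODES-T3"],
                                   "learned"),
        "M5_HIA": DescriptorSubset(
            "M5_HIA", ["AMW", "MATS7m", "ESpm01d", "TPSA(NO)"], "selected"),
        "M9_HIA": DescriptorSubset(
            "M9_HIA", ["AMW", "GATS6v", "JGI4", "VRp2", "TPSA(NO)"], "selected"),
    },
    "EE": {
        "CT_EE": DescriptorSubset(
            "CT_EE",
            ["Sa", "Sb", "Sc", "Sd", "La", "Lb", "Lc", "Ld", "Le", "Lf"],
            "learned"),
        "M9_EE": DescriptorSubset(
            "M9_EE",
            ["AMW Sust", "EEig11d Sust", "JGI6 Sust", "TPSA.NO. Lig"],
            "selected"),
        "M14_EE": DescriptorSubset(
            "M14_EE",
            ["AMW Sust", "PJI2 Sust", "EEig12x Sust", "EEig09d Sust",
             "EEig11d Sust", "GGI8 Sust", "nDB Lig", "nH Lig", "nR09 Lig",
             "TI2 Lig", "PW5 Lig", "D.Dr08 Lig", "AAC Lig", "MATS5v Lig",
             "MATS8v Lig", "MATS3p Lig", "GATS1e Lig"],
            "selected"),
    },
}


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition: seeded shuffle, then floor(n * fraction) rows to
    the training side; stratified mode preserves class proportions."""

    train_fraction: float = 0.66
    stratified: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train fraction must be in (0, 1)")


def split_dataset(
    table: DescriptorTable,
    spec: SplitSpec,
    labels: Optional[Sequence] = None,
) -> tuple[DescriptorTable, DescriptorTable]:
    """Split into (train, test). For stratified splits ``labels`` defaults to
    the table's (label) target; every class needs at least 2 members."""
    n = table.n_compounds
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    ids = np.asarray(table.ids, dtype=object)
    n_train = int(math.floor(n * spec.train_fraction))
    n_train = min(max(n_train, 1), n - 1)

    if not spec.stratified:
        train_ids = ids[perm[:n_train]]
        test_ids = ids[perm[n_train:]]
    else:
        if labels is None:
            if table.target is None or table.is_numeric_target():
                raise ValueError("stratified split needs class labels")
            labels = table.target
        lab = np.asarray(pd.Series(labels).astype(str))
        classes = list(dict.fromkeys(lab))
        counts = {c: int(np.sum(lab == c)) for c in classes}
        single = [c for c, k in counts.items() if k < 2]
        if single:
            raise ValueError(f"classes with a single member cannot be stratified: {single}")
        base = {c: int(math.floor(counts[c] * spec.train_fraction)) for c in classes}
        base = {c: min(max(base[c], 1), counts[c] - 1) for c in classes}
        # distribute the remainder toward the global floor(n * f) target
        remainder = n_train - sum(base.values())
        frac = sorted(classes,
                      key=lambda c: -(counts[c] * spec.train_fraction - math.floor(counts[c] * spec.train_fraction)))
        for c in frac:
            if remainder <= 0:
                break
            if base[c] < counts[c] - 1:
                base[c] += 1
                remainder -= 1
        train_idx, test_idx = [], []
        for c in classes:
            members = [i for i in perm if lab[i] == c]
            train_idx.extend(members[: base[c]])
            test_idx.extend(members[base[c]:])
        train_ids = ids[np.asarray(train_idx, dtype=int)]
        test_ids = ids[np.asarray(test_idx, dtype=int)]
    return table.take(list(train_ids)), table.take(list(test_ids))


# ---------------------------------------------------------------------------
# Learners
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LearnerSpec:
    """One of the five learner families with its (era-default) parameters."""

    family: str                       # linear_regression | decision_stump | mlp
                                      # | random_forest | random_committee
    trees: int = 10                   # random forest size
    k_attributes: Optional[int] = None  # attributes per node; default ceil(log2(m)+1)
    committee_size: int = 10
    hidden_width: Optional[int] = None  # default ceil((descriptors+classes)/2)
    learning_rate: float = 0.3
    momentum: float = 0.2
    epochs: int = 500
    seed: int = 0

    _FAMILIES = ("linear_regression", "decision_stump", "mlp",
                 "random_forest", "random_committee")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}")
        if self.trees < 1 or self.committee_size < 1 or self.epochs < 1:
            raise ValueError("learner size parameters must be positive")


def _check_columns(train: DescriptorTable, test: DescriptorTable) -> None:
    if train.descriptor_names != test.descriptor_names:
        raise ValueError(
            f"descriptor columns differ between train {train.descriptor_names} "
            f"and test {test.descriptor_names}")


def _resolve_k(spec: LearnerSpec, m: int) -> int:
    k = spec.k_attributes if spec.k_attributes is not None else int(math.ceil(math.log2(m) + 1)) if m > 1 else 1
    if k > m:
        raise ValueError(f"K={k} exceeds the {m} available descriptors")
    return max(1, k)


def train_predict(
    train: DescriptorTable,
    test: DescriptorTable,
    spec: LearnerSpec,
    task: str = "regression",
    class_order: Optional[Sequence[str]] = None,
):
    """Fit one learner on the training table and predict the test table.

    Regression returns a numeric prediction vector; classification returns a
    (probabilities DataFrame with one column per class in ``class_order``,
    class_order) pair. All stochastic learners take their seed from ``spec``.
    """
    _check_columns(train, test)
    if train.target is None:
        raise ValueError("training table has no target")
    x_tr = train.values.to_numpy(dtype=float)
    x_te = test.values.to_numpy(dtype=float)

    if task == "regression":
        y_tr = train.target.to_numpy(dtype=float)
        return _predict_regression(x_tr, y_tr, x_te, spec)
    if task != "classification":
        raise ValueError(f"unknown task {task!r}")

    y_lab = np.asarray(pd.Series(train.target).astype(str))
    if class_order is None:
        class_order = list(dict.fromkeys(y_lab))
    class_order = list(class_order)
    unknown = sorted(set(y_lab) - set(class_order))
    if unknown:
        raise ValueError(f"training labels not in class order: {unknown}")
    if len(set(y_lab)) < 2:
        raise ValueError("degenerate single-class training set")
    probs = _predict_classification(x_tr, y_lab, x_te, spec, class_order)
    return pd.DataFrame(probs, columns=class_order, index=test.ids), class_order


# -- regression learners ----------------------------------------------------

def _lstsq_fit(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    a = np.column_stack([x, np.ones(len(x))])
    coef, *_ = np.linalg.lstsq(a, y, rcond=None)
    return coef


def _lstsq_predict(x: np.ndarray, coef: np.ndarray) -> np.ndarray:
    return np.column_stack([x, np.ones(len(x))]) @ coef


def _akaike_backward(x: np.ndarray, y: np.ndarray) -> list[int]:
    """Greedy backward elimination by the Akaike criterion on the training fit."""
    n = len(y)

    def aic(cols: list[int]) -> float:
        coef = _lstsq_fit(x[:, cols] if cols else np.empty((n, 0)), y)
        resid = y - _lstsq_predict(x[:, cols] if cols else np.empty((n, 0)), coef)
        sse = float(np.sum(resid**2))
        sse = max(sse, 1e-300)
        return n * math.log(sse / n) + 2 * (len(cols) + 1)

    cols = list(range(x.shape[1]))
    current = aic(cols)
    while len(cols) > 1:
        candidates = [(aic([c for c in cols if c != drop]), drop) for drop in cols]
        best_aic, best_drop = min(candidates)
        if best_aic < current:
            cols = [c for c in cols if c != best_drop]
            current = best_aic
        else:
            break
    return cols


def _predict_regression(x_tr, y_tr, x_te, spec: LearnerSpec) -> np.ndarray:
    if spec.family == "linear_regression":
        cols = _akaike_backward(x_tr, y_tr)
        coef = _lstsq_fit(x_tr[:, cols], y_tr)
        return _lstsq_predict(x_te[:, cols], coef)
    if spec.family == "decision_stump":
        feat, thr, left, right = _fit_regression_stump(x_tr, y_tr)
        return np.where(x_te[:, feat] <= thr, left, right)
    if spec.family == "mlp":
        from sklearn.exceptions import ConvergenceWarning
        from sklearn.neural_network import MLPRegressor

        h = spec.hidden_width or int(math.ceil((x_tr.shape[1] + 1) / 2))
        model = MLPRegressor(
            hidden_layer_sizes=(h,), activation="logistic", solver="sgd",
            learning_rate_init=spec.learning_rate, momentum=spec.momentum,
            max_iter=spec.epochs, random_state=spec.seed, tol=0.0,
            nesterovs_momentum=False, alpha=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(x_tr, y_tr)
        return model.predict(x_te)
    if spec.family == "random_forest":
        from sklearn.ensemble import RandomForestRegressor

        k = _resolve_k(spec, x_tr.shape[1])
        model = RandomForestRegressor(n_estimators=spec.trees, max_features=k,
                                      random_state=spec.seed)
        model.fit(x_tr, y_tr)
        return model.predict(x_te)
    # random committee: mean of randomized trees differing only in seed
    from sklearn.tree import ExtraTreeRegressor

    members = []
    for i in range(spec.committee_size):
        t = ExtraTreeRegressor(random_state=spec.seed + i, max_features=1.0)
        t.fit(x_tr, y_tr)
        members.append(t.predict(x_te))
    return np.mean(np.stack(members, axis=0), axis=0)


def _fit_regression_stump(x: np.ndarray, y: np.ndarray):
    """Exhaustive single-split stump minimizing squared error.

    Returns (feature, threshold, left mean, right mean); a constant-feature
    table degenerates to a single leaf (threshold +inf).
    """
    best = (math.inf, 0, math.inf, float(np.mean(y)), float(np.mean(y)))
    for feat in range(x.shape[1]):
        vals = np.unique(x[:, feat])
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = (lo + hi) / 2.0
            mask = x[:, feat] <= thr
            left, right = y[mask], y[~mask]
            sse = float(np.sum((left - left.mean())**2) + np.sum((right - right.mean())**2))
            if sse < best[0]:
                best = (sse, feat, thr, float(left.mean()), float(right.mean()))
    return best[1], best[2], best[3], best[4]


# -- classification learners -------------------------------------------------

def _indicator(y_lab: np.ndarray, class_order: list[str]) -> np.ndarray:
    return np.stack([(y_lab == c).astype(float) for c in class_order], axis=1)


def _normalize_probs(scores: np.ndarray) -> np.ndarray:
    p = np.clip(scores, 0.0, None)
    sums = p.sum(axis=1, keepdims=True)
    flat = sums[:, 0] <= 0
    p[flat] = 1.0
    sums = p.sum(axis=1, keepdims=True)
    return p / sums


def _reorder_proba(proba: np.ndarray, model_classes, class_order: list[str]) -> np.ndarray:
    out = np.zeros((proba.shape[0], len(class_order)))
    lookup = {str(c): i for i, c in enumerate(model_classes)}
    for j, c in enumerate(class_order):
        if c in lookup:
            out[:, j] = proba[:, lookup[c]]
    return out


def _predict_classification(x_tr, y_lab, x_te, spec: LearnerSpec,
                            class_order: list[str]) -> np.ndarray:
    if spec.family == "linear_regression":
        ind = _indicator(y_lab, class_order)
        coef = _lstsq_fit(x_tr, ind)
        return _normalize_probs(_lstsq_predict(x_te, coef))
    if spec.family == "decision_stump":
        return _classification_stump(x_tr, y_lab, x_te, class_order)
    if spec.family == "mlp":
        from sklearn.exceptions import ConvergenceWarning
        from sklearn.neural_network import MLPClassifier

        h = spec.hidden_width or int(math.ceil((x_tr.shape[1] + len(class_order)) / 2))
        model = MLPClassifier(
            hidden_layer_sizes=(h,), activation="logistic", solver="sgd",
            learning_rate_init=spec.learning_rate, momentum=spec.momentum,
            max_iter=spec.epochs, random_state=spec.seed, tol=0.0,
            nesterovs_momentum=False, alpha=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(x_tr, y_lab)
        return _reorder_proba(model.predict_proba(x_te), model.classes_, class_order)
    if spec.family == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        k = _resolve_k(spec, x_tr.shape[1])
        model = RandomForestClassifier(n_estimators=spec.trees, max_features=k,
                                       random_state=spec.seed)
        model.fit(x_tr, y_lab)
        return _reorder_proba(model.predict_proba(x_te), model.classes_, class_order)
    from sklearn.tree import ExtraTreeClassifier

    members = []
    for i in range(spec.committee_size):
        t = ExtraTreeClassifier(random_state=spec.seed + i, max_features=1.0)
        t.fit(x_tr, y_lab)
        members.append(_reorder_proba(t.predict_proba(x_te), t.classes_, class_order))
    return np.mean(np.stack(members, axis=0), axis=0)


def _classification_stump(x_tr, y_lab, x_te, class_order: list[str]) -> np.ndarray:
    """Single best split by class entropy; leaves predict their class frequencies."""

    def entropy(labels: np.ndarray) -> float:
        _, counts = np.unique(labels, return_counts=True)
        p = counts / counts.sum()
        return float(-np.sum(p * np.log2(p)))

    n = len(y_lab)
    overall = np.array([np.mean(y_lab == c) for c in class_order])
    best = (entropy(y_lab), None, None, overall, overall)
    for feat in range(x_tr.shape[1]):
        vals = np.unique(x_tr[:, feat])
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = (lo + hi) / 2.0
            mask = x_tr[:, feat] <= thr
            h = (mask.sum() * entropy(y_lab[mask]) + (~mask).sum() * entropy(y_lab[~mask])) / n
            if h < best[0] - 1e-12:
                left = np.array([np.mean(y_lab[mask] == c) for c in class_order])
                right = np.array([np.mean(y_lab[~mask] == c) for c in class_order])
                best = (h, feat, thr, left, right)
    _, feat, thr, left, right = best
    if feat is None:
        return np.tile(overall, (len(x_te), 1))
    mask = x_te[:, feat] <= thr
    out = np.where(mask[:, None], left[None, :], right[None, :])
    return out


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def evaluate_regression(predicted, actual, train_mean: float) -> dict:
    """CC (Pearson), RAE (%) and RRSE (%) against the training-mean baseline.

    RAE = 100 * sum|pred - y| / sum|y - ybar_train|;
    RRSE = 100 * sqrt(sum(pred - y)^2 / sum(y - ybar_train)^2).
    A constant prediction vector has undefined Pearson correlation and scores
    CC = 0 (with a warning), matching common tool behaviour.
    """
    pred = np.asarray(predicted, dtype=float)
    y = np.asarray(actual, dtype=float)
    if pred.shape != y.shape or y.size < 2:
        raise ValueError("predicted and actual must be equal-length vectors (n >= 2)")
    abs_dev = float(np.sum(np.abs(y - train_mean)))
    sq_dev = float(np.sum((y - train_mean) ** 2))
    if abs_dev == 0 or sq_dev == 0:
        raise ValueError("uninformative test set: no deviation from the training mean")
    if np.std(pred) == 0 or np.std(y) == 0:
        warnings.warn("constant vector: correlation undefined, reporting CC=0")
        cc = 0.0
    else:
        cc = float(np.corrcoef(pred, y)[0, 1])
    rae = 100.0 * float(np.sum(np.abs(pred - y))) / abs_dev
    rrse = 100.0 * math.sqrt(float(np.sum((pred - y) ** 2)) / sq_dev)
    return {"CC": cc, "RAE": rae, "RRSE": rrse}


def _auc_midrank(scores: np.ndarray, positive: np.ndarray) -> float:
    """One-vs-rest ROC area by the midrank statistic."""
    n_pos = int(positive.sum())
    n_neg = len(positive) - n_pos
    if n_pos == 0 or n_neg == 0:
        return math.nan
    ranks = stats.rankdata(scores)
    return float((ranks[positive].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate_classification(
    probabilities,
    actual,
    train_class_freq: Sequence[float],
    class_order: Sequence[str],
) -> dict:
    """%CC, prevalence-weighted ROC area, confusion matrix and
    probability-residual RAE/RRSE against the training class-frequency baseline.

    Predicted class is the argmax probability (ties resolved toward the
    earlier class in ``class_order``); the confusion matrix has actual classes
    as rows and predicted classes as columns.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(pd.Series(actual).astype(str))
    class_order = list(class_order)
    k = len(class_order)
    if p.ndim != 2 or p.shape[1] != k:
        raise ValueError("probability matrix shape does not match class order")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("probability rows must sum to 1")
    unknown = sorted(set(y) - set(class_order))
    if unknown:
        raise ValueError(f"unknown labels in test set: {unknown}")
    q = np.asarray(train_class_freq, dtype=float)
    if q.shape != (k,):
        raise ValueError("train class frequencies must align with class order")

    pred_idx = np.argmax(p, axis=1)  # argmax takes the first maximum: earlier class wins
    actual_idx = np.array([class_order.index(c) for c in y])
    n = len(y)
    pcc = 100.0 * float(np.mean(pred_idx == actual_idx))

    cm = np.zeros((k, k), dtype=int)
    for a, b in zip(actual_idx, pred_idx):
        cm[a, b] += 1
    confusion = pd.DataFrame(cm, index=class_order, columns=class_order)

    # prevalence-weighted one-vs-rest ROC
    weighted = 0.0
    total_w = 0.0
    for j in range(k):
        positive = actual_idx == j
        prevalence = float(positive.mean())
        if prevalence == 0:
            continue
        auc = _auc_midrank(p[:, j], positive)
        if math.isnan(auc):  # class covers every sample: undefined, neutral 0.5
            auc = 0.5
        weighted += prevalence * auc
        total_w += prevalence
    roc = weighted / total_w if total_w > 0 else math.nan

    ind = np.zeros((n, k))
    ind[np.arange(n), actual_idx] = 1.0
    baseline = np.tile(q, (n, 1))
    abs_base = float(np.sum(np.abs(baseline - ind)))
    sq_base = float(np.sum((baseline - ind) ** 2))
    rae = 100.0 * float(np.sum(np.abs(p - ind))) / abs_base if abs_base > 0 else math.nan
    rrse = 100.0 * math.sqrt(float(np.sum((p - ind) ** 2)) / sq_base) if sq_base > 0 else math.nan
    return {"%CC": pcc, "ROC": roc, "confusion_matrix": confusion,
            "RAE": rae, "RRSE": rrse}


@dataclass
class EvaluationReport:
    """Metrics of one experimental scenario (subset x learner x split x task)."""

    task: str                     # "regression" | "classification"
    subset: str
    learner: str
    split: float
    metrics: dict
    dataset: str = ""
    seed: Optional[int] = None

    def flat(self) -> dict:
        row = {"dataset": self.dataset, "task": self.task, "subset": self.subset,
               "learner": self.learner, "split": self.split, "seed": self.seed}
        for k, v in self.metrics.items():
            if k == "confusion_matrix":
                row[k] = v.to_numpy().tolist() if hasattr(v, "to_numpy") else v
            else:
                row[k] = v
        return row


# ---------------------------------------------------------------------------
# Hybridization and reaction tables
# ---------------------------------------------------------------------------

def combine_subsets(a: DescriptorSubset, b: DescriptorSubset) -> DescriptorSubset:
    """Ordered union of two subsets (a's names, then b's unseen names)."""
    seen = set(a.descriptors)
    union = list(a.descriptors) + [d for d in b.descriptors if d not in seen]
    if not union:
        raise ValueError("empty union")
    return DescriptorSubset(
        name=f"{a.name} ∪ {b.name}",
        descriptors=union,
        provenance="combined",
        parents=(a.name, b.name),
    )


def assemble_reaction_table(
    substrate_codes: DescriptorTable,
    ligand_codes: DescriptorTable,
    pairs: Sequence[tuple[str, str, float]],
    substrate_suffix: str = "",
    ligand_suffix: str = "",
    target_name: str = "ee",
) -> DescriptorTable:
    """One row per (substrate, ligand, target) reaction pair.

    Columns are the substrate-pool columns followed by the ligand-pool columns
    (optionally suffixed per pool to keep names unique); duplicate pairs are
    allowed and preserved as separate rows.
    """
    if not pairs:
        raise ValueError("no reaction pairs")
    sub_cols = [c + substrate_suffix for c in substrate_codes.descriptor_names]
    lig_cols = [c + ligand_suffix for c in ligand_codes.descriptor_names]
    if set(sub_cols) & set(lig_cols):
        raise ValueError("substrate and ligand column names collide; use suffixes")
    rows, targets, ids = [], [], []
    counter: dict[str, int] = {}
    for sid, lid, target in pairs:
        if sid not in substrate_codes.values.index:
            raise KeyError(f"unknown substrate id {sid!r}")
        if lid not in ligand_codes.values.index:
            raise KeyError(f"unknown ligand id {lid!r}")
        rows.append(np.concatenate([
            substrate_codes.values.loc[sid].to_numpy(dtype=float),
            ligand_codes.values.loc[lid].to_numpy(dtype=float)]))
        targets.append(float(target))
        base = f"{sid}|{lid}"
        counter[base] = counter.get(base, 0) + 1
        ids.append(base if counter[base] == 1 else f"{base}#{counter[base]}")
    frame = pd.DataFrame(rows, columns=sub_cols + lig_cols, index=ids)
    return DescriptorTable(frame, pd.Series(targets, index=ids, name=target_name),
                           target_name)


# ---------------------------------------------------------------------------
# Random-replacement significance test
# ---------------------------------------------------------------------------

@dataclass
class ReplacementTestResult:
    replicate_cc: np.ndarray
    mean_cc: float
    reference_cc: float
    p_value: float  # fraction of replicates with CC >= reference


def run_replacement_test(
    table: DescriptorTable,
    fixed_subset: Union[DescriptorSubset, Sequence[str]],
    replaced_size: int,
    excluded: Sequence[str],
    learner: LearnerSpec,
    split: SplitSpec,
    replicates: int = 100,
    reference_cc: float = 0.0,
    seed: int = 0,
) -> ReplacementTestResult:
    """Monte Carlo null for the contribution of a descriptor group.

    Each replicate replaces the group with ``replaced_size`` descriptors drawn
    uniformly (without replacement) from the table minus the fixed subset and
    the excluded pool, then retrains and evaluates the regression model under
    identical split/learner settings and records its CC. The empirical p-value
    is the fraction of replicates reaching the reference CC.
    """
    fixed = list(fixed_subset.descriptors) if isinstance(fixed_subset, DescriptorSubset) \
        else list(fixed_subset)
    pool = [c for c in table.descriptor_names
            if c not in set(fixed) and c not in set(excluded)]
    if len(pool) < replaced_size:
        raise ValueError(
            f"pool of {len(pool)} descriptors cannot supply {replaced_size} replacements")
    ccs = np.empty(replicates)
    for i in range(replicates):
        rng = np.random.default_rng((seed + i) % (2**31))
        picked = list(rng.choice(np.asarray(pool, dtype=object), size=replaced_size,
                                 replace=False))
        sub = table.subset(fixed + picked)
        train, test = split_dataset(sub, split)
        pred = train_predict(train, test, learner, task="regression")
        metrics = evaluate_regression(pred, test.target.to_numpy(dtype=float),
                                      float(train.target.mean()))
        ccs[i] = metrics["CC"]
    return ReplacementTestResult(
        replicate_cc=ccs,
        mean_cc=float(ccs.mean()),
        reference_cc=float(reference_cc),
        p_value=float(np.mean(ccs >= reference_cc)),
    )


# ---------------------------------------------------------------------------
# Confidence-interval comparison
# ---------------------------------------------------------------------------

def compare_with_ci(
    a: Sequence[float],
    b: Sequence[float],
    level: float = 0.95,
    method: str = "t",
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict:
    """Paired comparison of two metric series via a CI on the mean difference.

    ``method='t'`` uses the Student-t interval on the paired differences;
    ``method='bootstrap'`` uses seeded percentile resampling. The difference
    is flagged significant when the CI excludes 0. Zero-variance differences
    yield a degenerate (point) interval, flagged rather than raised.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length series of at least 3 paired values")
    d = x - y
    mean = float(d.mean())
    # constant shift up to floating-point rounding of the inputs
    degenerate = bool(float(d.std(ddof=0)) <= 1e-12 * (abs(mean) + 1.0))
    if degenerate:
        lo = hi = mean
    elif method == "t":
        s = float(d.std(ddof=1))
        t_crit = float(stats.t.ppf((1 + level) / 2, len(d) - 1))
        half = t_crit * s / math.sqrt(len(d))
        lo, hi = mean - half, mean + half
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        means = rng.choice(d, size=(n_boot, len(d)), replace=True).mean(axis=1)
        alpha = (1 - level) / 2
        lo, hi = (float(np.quantile(means, alpha)),
                  float(np.quantile(means, 1 - alpha)))
    else:
        raise ValueError(f"unknown method {method!r}")
    significant = not (lo <= 0.0 <= hi)
    return {"mean_difference": mean, "ci": (lo, hi), "level": level,
            "significant": significant, "degenerate": degenerate}
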