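"""Membership classification: tuning, training, prediction and metrics.

The target stock is discriminated from all other populations with a binary
classifier chosen by leave-one-out cross-validation (LOOCV) over a parameter
grid, using the F-score as the principal selection statistic. Three
algorithm families are configured natively: a randomized-tree ensemble
(mtry x splitrule {gini, extratrees} x minimum node size — the full default
grid enumerates 9 x 2 x 9 = 162 combinations), Gaussian naive Bayes, and
k-nearest neighbours. Missing dosages are mean-imputed; test-time imputation
reuses the training means so no information leaks from held-out samples.

A sample is assigned to the target stock only when its membership
probability strictly exceeds the threshold (default 0.5): a probability of
exactly 0.5 goes to the other class.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier

from .datatypes import GenotypeMatrix

log = logging.getLogger("gsikit")


# ---------------------------------------------------------------- imputation

def impute_means(
    dosage: np.ndarray, means: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Replace missing dosages by the per-marker observed mean.

    When ``means`` is given (prediction time) those stored training means
    are used instead of recomputing. Imputed values stay within the 0-2
    dosage scale because observed dosages do. Raises if a marker has no
    observed call and no stored mean.
    """
    X = np.asarray(dosage, dtype=float).copy()
    nan = np.isnan(X)
    if means is None:
        n_obs = (~nan).sum(axis=0)
        if (n_obs == 0).any():
            j = int(np.flatnonzero(n_obs == 0)[0])
            raise ValueError(
                f"marker column {j} has no observed calls; "
                "run QC before imputation"
            )
        with np.errstate(invalid="ignore"):
            means = np.nanmean(X, axis=0)
    means = np.asarray(means, dtype=float)
    X[nan] = np.broadcast_to(means, X.shape)[nan]
    return X, means


# ------------------------------------------------------------ data splitting

def stratified_split(
    labels: Sequence[str], test_fraction: float = 0.20, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class hold-out: ``floor(test_fraction * n_class)`` samples per
    class drawn without replacement; returns (train indices, test indices)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        n_test = int(np.floor(test_fraction * len(members)))
        if n_test >= len(members) and len(members) > 0 and test_fraction < 1.0:
            n_test = len(members) - 1
        chosen = rng.choice(members, size=n_test, replace=False)
        test_idx.extend(int(i) for i in chosen)
        if len(members) - n_test == 0:
            raise ValueError(f"class {cls!r} has no training samples left")
    test = np.array(sorted(test_idx), dtype=int)
    train = np.setdiff1d(np.arange(len(labels)), test)
    return train, test


# ------------------------------------------------------------- tuning grids

@dataclass
class TuningGrid:
    """Named algorithm plus lists of candidate parameter values."""

    algorithm: str  # "random_forest" | "naive_bayes" | "knn"
    params: dict[str, list] = field(default_factory=dict)

    def __len__(self) -> int:
        n = 1
        for v in self.params.values():
            n *= len(v)
        return n


def default_forest_grid() -> TuningGrid:
    """The published randomized-tree grid: mtry 2-10, gini/extratrees split
    rules, minimum node size 2-10 — 162 combinations."""
    return TuningGrid(
        "random_forest",
        {
            "mtry": list(range(2, 11)),
            "splitrule": ["gini", "extratrees"],
            "min_node_size": list(range(2, 11)),
        },
    )


def default_grids(small: bool = False) -> list[TuningGrid]:
    if small:
        forest = TuningGrid(
            "random_forest",
            {"mtry": [2, 4], "splitrule": ["gini", "extratrees"],
             "min_node_size": [2, 5]},
        )
    else:
        forest = default_forest_grid()
    return [
        forest,
        TuningGrid("naive_bayes", {"var_smoothing": [1e-9, 1e-6, 1e-3]}),
        TuningGrid("knn", {"k": [3, 5, 7]}),
    ]


def enumerate_grid(grid: TuningGrid) -> list[dict]:
    """Cartesian product of the parameter lists in deterministic
    lexicographic (declaration) order."""
    if not grid.params:
        return [{}]
    keys = list(grid.params)
    for k in keys:
        if not grid.params[k]:
            raise ValueError(f"empty parameter list {k!r}")
    return [dict(zip(keys, combo))
            for combo in itertools.product(*(grid.params[k] for k in keys))]


def build_estimator(
    algorithm: str, params: dict, seed: int = 0, n_trees: int = 500
) -> Any:
    """Instantiate a scikit-learn estimator honouring the grid contract."""
    if algorithm == "random_forest":
        cls = (ExtraTreesClassifier if params.get("splitrule") == "extratrees"
               else RandomForestClassifier)
        return cls(
            n_estimators=n_trees,
            max_features=params.get("mtry", "sqrt"),
            min_samples_leaf=params.get("min_node_size", 1),
            criterion="gini",
            random_state=seed,
            bootstrap=True,
        )
    if algorithm == "naive_bayes":
        return GaussianNB(var_smoothing=params.get("var_smoothing", 1e-9))
    if algorithm == "knn":
        return KNeighborsClassifier(n_neighbors=params.get("k", 5))
    raise ValueError(f"unknown algorithm {algorithm!r}")


# -------------------------------------------------------------------- LOOCV

def loocv_evaluate(
    dosage: np.ndarray,
    labels: Sequence[str],
    algorithm: str,
    params: dict,
    positive_class: str,
    seed: int = 0,
    n_trees: int = 500,
) -> Optional[dict]:
    """Leave-one-out evaluation of one (algorithm, parameter) combination.

    Each sample is predicted by a model fit on the other n-1 (imputation
    means recomputed on those n-1); metrics are computed once on the pooled
    out-of-fold predictions. Returns None when the combination cannot be
    fit (e.g. single-class folds the algorithm rejects).
    """
    y = np.asarray(labels)
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 training samples")
    if len(np.unique(y)) < 2:
        raise ValueError("LOOCV needs both classes present")
    preds = np.empty(n, dtype=object)
    try:
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            X_tr, means = impute_means(dosage[mask])
            X_te, _ = impute_means(dosage[i:i + 1], means)
            est = build_estimator(algorithm, params, seed=seed, n_trees=n_trees)
            est.fit(X_tr, y[mask])
            preds[i] = est.predict(X_te)[0]
    except Exception as exc:  # combination failed, not fatal
        log.warning("LOOCV failed for %s %s: %s", algorithm, params, exc)
        return None
    rep = classification_metrics(y, preds.astype(y.dtype), positive_class)
    return {"f_score": rep.f_score, "accuracy": rep.accuracy, "kappa": rep.kappa}


@dataclass
class FittedModel:
    """A trained membership classifier with everything prediction needs."""

    algorithm: str
    params: dict
    marker_ids: list[str]
    impute_means_: np.ndarray
    estimator: Any
    positive_class: str
    seed: int
    n_train: int


def tune_and_train(
    gm: GenotypeMatrix,
    grids: Sequence[TuningGrid],
    positive_class: str,
    seed: int = 0,
    n_trees: int = 500,
) -> tuple[FittedModel, list[dict]]:
    """Score every (algorithm, combination) by LOOCV F-score and refit the
    winner on the full training set.

    Ties break by accuracy, then kappa, then grid order. The returned
    leaderboard has one row per combination (failed ones carry None metrics).
    """
    if gm.labels is None:
        raise ValueError("training matrix must carry population labels")
    leaderboard: list[dict] = []
    best: Optional[tuple] = None
    rank = 0
    for grid in grids:
        for params in enumerate_grid(grid):
            metrics = loocv_evaluate(
                gm.dosage, gm.labels, grid.algorithm, params,
                positive_class, seed=seed, n_trees=n_trees,
            )
            row = {"algorithm": grid.algorithm, "params": params,
                   "metrics": metrics}
            leaderboard.append(row)
            if metrics is not None:
                key = (metrics["f_score"], metrics["accuracy"],
                       metrics["kappa"], -rank)
                if best is None or key > best[0]:
                    best = (key, grid.algorithm, params)
            rank += 1
    if best is None:
        raise RuntimeError(
            f"all {len(leaderboard)} tuning combinations failed; "
            f"leaderboard: {leaderboard}"
        )
    _, algorithm, params = best
    X, means = impute_means(gm.dosage)
    est = build_estimator(algorithm, params, seed=seed, n_trees=n_trees)
    est.fit(X, np.asarray(gm.labels))
    model = FittedModel(
        algorithm=algorithm,
        params=params,
        marker_ids=list(gm.marker_ids),
        impute_means_=means,
        estimator=est,
        positive_class=positive_class,
        seed=seed,
        n_train=gm.n_samples,
    )
    log.info("tune_and_train winner: %s %s", algorithm, params)
    return model, leaderboard


def train_fixed(
    gm: GenotypeMatrix,
    algorithm: str,
    params: dict,
    positive_class: str,
    seed: int = 0,
    n_trees: int = 500,
) -> FittedModel:
    """Fit one configuration directly (no tuning)."""
    if gm.labels is None:
        raise ValueError("training matrix must carry population labels")
    X, means = impute_means(gm.dosage)
    est = build_estimator(algorithm, params, seed=seed, n_trees=n_trees)
    est.fit(X, np.asarray(gm.labels))
    return FittedModel(algorithm, params, list(gm.marker_ids), means, est,
                       positive_class, seed, gm.n_samples)


def predict_membership(
    model: FittedModel, gm: GenotypeMatrix, threshold: float = 0.5
) -> tuple[np.ndarray, list[str]]:
    """Per-sample probability of target-stock membership and hard labels.

    The marker set must equal the training set (columns are aligned by name;
    absent or extra markers are an error). Assignment to the target class
    requires probability strictly above the threshold.
    """
    missing = [m for m in model.marker_ids if m not in gm.marker_ids]
    extra = [m for m in gm.marker_ids if m not in model.marker_ids]
    if missing or extra:
        raise ValueError(
            f"marker mismatch with training set; absent: {missing}, "
            f"unexpected: {extra}"
        )
    aligned = gm.subset_markers(model.marker_ids)
    X, _ = impute_means(aligned.dosage, model.impute_means_)
    classes = list(model.estimator.classes_)
    pos = classes.index(model.positive_class)
    proba = model.estimator.predict_proba(X)[:, pos]
    other = next(c for c in classes if c != model.positive_class) \
        if len(classes) > 1 else "other"
    labels = [model.positive_class if p > threshold else other for p in proba]
    return proba, labels


# ------------------------------------------------------------------ metrics

@dataclass
class ClassificationReport:
    """2x2 confusion matrix (rows = known, cols = predicted; positive class
    first) with the derived agreement statistics."""

    confusion: np.ndarray
    accuracy: float
    f_score: float
    kappa: float
    sensitivity: float
    specificity: float
    precision: float
    chi_square: float
    chi_df: int
    chi_p: float
    undefined_precision: bool = False
    membership_probabilities: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        d = {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "f_score": self.f_score,
            "kappa": self.kappa,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "chi_square": self.chi_square,
            "chi_df": self.chi_df,
            "chi_p": self.chi_p,
        }
        if self.membership_probabilities is not None:
            d["membership_probabilities"] = [
                float(p) for p in self.membership_probabilities
            ]
        return d


def confusion_table(
    known: Sequence[str], predicted: Sequence[str], positive_class: str
) -> np.ndarray:
    """2x2 table, rows known / cols predicted, positive class first."""
    known = np.asarray(known)
    predicted = np.asarray(predicted)
    if known.shape != predicted.shape:
        raise ValueError("known and predicted labels differ in length")
    kp = known == positive_class
    pp = predicted == positive_class
    return np.array(
        [[int((kp & pp).sum()), int((kp & ~pp).sum())],
         [int((~kp & pp).sum()), int((~kp & ~pp).sum())]]
    )


def chi_square_independence(
    table: np.ndarray, correction: bool = True
) -> tuple[float, int, float]:
    """Pearson chi-square of independence for a 2x2 table.

    With Yates continuity correction (default):
    X^2 = n (max(|ad - bc| - n/2, 0))^2 / [(a+b)(c+d)(a+c)(b+d)], df = 1.
    A zero marginal makes the statistic undefined (NaN returned, flagged in
    the log).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("chi-square of independence expects a 2x2 table")
    a, b, c, d = t.ravel()
    n = t.sum()
    marg = np.array([a + b, c + d, a + c, b + d])
    if (marg == 0).any() or n < 1:
        log.warning("chi-square undefined: zero marginal in %s", t.tolist())
        return float("nan"), 1, float("nan")
    det = abs(a * d - b * c)
    if correction:
        det = max(det - n / 2.0, 0.0)
    stat = n * det**2 / marg.prod()
    p = float(chi2_dist.sf(stat, 1))
    return float(stat), 1, p


def classification_metrics(
    known: Sequence[str],
    predicted: Sequence[str],
    positive_class: str,
    membership_probabilities: Optional[np.ndarray] = None,
) -> ClassificationReport:
    """Confusion-matrix statistics for a two-class assignment.

    accuracy = trace/n; sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    F = harmonic mean of precision and recall (0, flagged, when no positive
    predictions exist); kappa = (p_o - p_e)/(1 - p_e) with expected agreement
    p_e from the marginals.
    """
    cm = confusion_table(known, predicted, positive_class)
    tp, fn, fp, tn = cm[0, 0], cm[0, 1], cm[1, 0], cm[1, 1]
    n = cm.sum()
    accuracy = (tp + tn) / n
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    undefined = (tp + fp) == 0
    precision = tp / (tp + fp) if not undefined else float("nan")
    if undefined or np.isnan(sensitivity) or (precision + sensitivity) == 0:
        f_score = 0.0
    else:
        f_score = 2 * precision * sensitivity / (precision + sensitivity)
    p_o = accuracy
    p_e = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / (n * n)
    kappa = (p_o - p_e) / (1 - p_e) if p_e != 1 else 0.0
    chi, df, p = chi_square_independence(cm)
    return ClassificationReport(
        confusion=cm,
        accuracy=float(accuracy),
        f_score=float(f_score),
        kappa=float(kappa),
        sensitivity=float(sensitivity),
        specificity=float(specificity),
        precision=float(precision),
        chi_square=chi,
        chi_df=df,
        chi_p=p,
        undefined_precision=bool(undefined),
        membership_probabilities=membership_probabilities,
    )


def probability_distribution_summary(
    groups: dict[str, Sequence[float]]
) -> dict[str, dict[str, float]]:
    """Five-number summary plus mean per group of membership probabilities
    (quantiles by the linear-interpolation convention)."""
    out: dict[str, dict[str, float]] = {}
    for name, probs in groups.items():
        v = np.asarray(list(probs), dtype=float)
        if v.size == 0:
            raise ValueError(f"group {name!r} is empty")
        out[name] = {
            "min": float(v.min()),
            "q1": float(np.quantile(v, 0.25)),
            "median": float(np.quantile(v, 0.5)),
            "mean": float(v.mean()),
            "q3": float(np.quantile(v, 0.75)),
            "max": float(v.max()),
        }
    return out
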