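"""Model training and validation: wrapper feature selection, protocol suite,
cost-sensitive tuning and cross-therapy-state transfer.

The classification stack combines two models: a decision tree ranks the
features (features used close to the root separate the training set best),
and a support vector machine classifies. The wrapper tuning grid crosses the
number of top-ranked features (1..16) with the SVM regularization cost
(1..20), scored by 10-fold stratified cross-validated misclassification
error. Three validation protocols are provided:

* ``kfold_validate`` — 10-fold stratified CV, ranking and tuning redone
  inside every fold;
* ``run_algorithm1`` — 20 repetitions of a stratified 70/30 train/test
  split, with ranking and tuning on the training split only;
* ``loso_validate`` — leave-one-subject-out: each fold holds out every step
  of one subject, and the held-out subject contributes no rows to ranking,
  tuning or fitting. Per-fold selected-feature lists feed the >=80%
  selection-frequency analysis.

Additional operations: joint pre-FOG window / model-family selection by
10-fold accuracy with seeded random-search hyperparameter tuning, false
negative cost tuning (a class-weight multiplier on the positive class,
trading specificity for sensitivity), an OR-rule model combination, and the
cross-condition experiment (train on one therapy state, test on the other).

Every routine is a pure function of (data, config, seed), and every protocol
carries a leakage audit: it asserts at run time that held-out rows (and
held-out subjects or conditions) touched no training stage, and records the
outcome in its report.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .evaluation import (
    METRIC_NAMES,
    PerformanceReport,
    compute_metrics,
    confusion_counts,
    roc_curve,
)
from .features import FEATURE_COLUMNS

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "ValidationReport",
    "rank_features_dt",
    "tune_inner",
    "fit_model",
    "kfold_validate",
    "run_algorithm1",
    "loso_validate",
    "selection_frequency",
    "select_window_and_model",
    "sample_hyperparams",
    "tune_fn_cost",
    "combine_or",
    "cross_condition",
]

FAMILIES = ("svm", "knn", "lda", "logistic")
DEFAULT_C_RANGE = tuple(range(1, 21))

#: decision-tree ranking parameters: Gini split criterion, minimum leaf
#: size 1; max_leaf_nodes=16 caps a binary tree at 15 splits
_TREE_KW = dict(criterion="gini", min_samples_leaf=1, max_leaf_nodes=16)


class ModelingError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family with hyperparameters, feature subset and FN cost.

    ``params`` keys per family (ranges enforced by ``validate``):

    * svm — kernel in {linear, quadratic, gaussian}; kernel_scale in
      [0.001, 100]; box_constraint in [0.01, 100]
    * knn — n_neighbors in [1, 50]; metric in {euclidean, manhattan};
      weight in {equal, inverse, squared_inverse}
    * lda — gamma in [0.01, 1] (shrinkage); delta in [0.01, 100]
      (coefficient elimination threshold)
    * logistic — lam in [0.01, 100] (L2 penalty strength)
    """

    family: str = "svm"
    params: tuple[tuple[str, object], ...] = ()
    features: tuple[str, ...] = tuple(FEATURE_COLUMNS)
    fn_cost: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES and self.family != "decision_tree":
            raise ModelingError(f"unknown family {self.family!r}")
        if self.fn_cost < 1:
            raise ModelingError("fn_cost must be >= 1 (a zero cost never fires)")
        self.validate()

    @property
    def p(self) -> dict:
        return dict(self.params)

    def with_params(self, **kw) -> "ModelSpec":
        p = self.p
        p.update(kw)
        return replace(self, params=tuple(sorted(p.items())))

    def validate(self) -> None:
        p = self.p
        checks = {
            "svm": [
                ("kernel", lambda v: v in ("linear", "quadratic", "gaussian")),
                ("kernel_scale", lambda v: 1e-3 <= v <= 100),
                ("box_constraint", lambda v: 0.01 <= v <= 100),
            ],
            "knn": [
                ("n_neighbors", lambda v: 1 <= v <= 50),
                ("metric", lambda v: v in ("euclidean", "manhattan")),
                ("weight", lambda v: v in ("equal", "inverse", "squared_inverse")),
            ],
            "lda": [
                ("gamma", lambda v: 0.01 <= v <= 1),
                ("delta", lambda v: 0.01 <= v <= 100),
            ],
            "logistic": [("lam", lambda v: 0.01 <= v <= 100)],
        }
        for key, ok in checks.get(self.family, []):
            if key in p and not ok(p[key]):
                raise ModelingError(f"{self.family} parameter {key}={p[key]!r} out of range")


class _ShrunkenLDA:
    """LDA with shrinkage ``gamma`` and a coefficient-elimination ``delta``.

    After fitting a least-squares shrunken LDA, coefficients with magnitude
    below ``delta`` are zeroed — the predictor-elimination semantics of the
    delta threshold in classification-toolbox discriminant models.
    """

    def __init__(self, gamma: float = 0.01, delta: float = 0.0, priors=None):
        self.gamma, self.delta, self.priors = gamma, delta, priors

    def fit(self, X, y):
        self._lda = LinearDiscriminantAnalysis(
            solver="lsqr", shrinkage=self.gamma, priors=self.priors
        )
        self._lda.fit(X, y)
        if self.delta > 0:
            coef = self._lda.coef_.copy()
            coef[np.abs(coef) < self.delta] = 0.0
            self._lda.coef_ = coef
        return self

    def decision_function(self, X):
        return self._lda.decision_function(X)

    def predict(self, X):
        return self._lda.predict(X)


class _ThresholdedKNN(KNeighborsClassifier):
    """kNN with cost-sensitive posterior thresholding.

    Predicts positive when ``cost * p(1) >= p(0)`` — the Bayes decision under
    an asymmetric false-negative cost, which kNN cannot express through
    sample weights.
    """

    def __init__(self, cost=1.0, **kw):
        self.cost = cost
        super().__init__(**kw)

    def predict(self, X):
        proba = self.predict_proba(X)
        return (self.cost * proba[:, 1] >= proba[:, 0]).astype(int)


def _sq_inverse(dist: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        w = 1.0 / (dist**2)
    w[np.isinf(w)] = 1e12
    return w


def _build_classifier(spec: ModelSpec, seed: int):
    p = spec.p
    cost = float(max(spec.fn_cost, 1.0))
    cw = None if cost == 1.0 else {0: 1.0, 1: cost}
    if spec.family == "svm":
        kernel = p.get("kernel", "linear")
        C = float(p.get("box_constraint", 1.0))
        scale = float(p.get("kernel_scale", 1.0))
        if kernel == "linear":
            return LinearSVC(
                C=C, dual=False, class_weight=cw, max_iter=5000, tol=1e-3,
                random_state=seed,
            )
        # max_iter bounds the libsvm solver: extreme (scale, C) corners of
        # the admissible range otherwise iterate near-indefinitely
        gamma = 1.0 / scale**2
        if kernel == "quadratic":
            return SVC(kernel="poly", degree=2, coef0=1.0, gamma=gamma, C=C,
                       class_weight=cw, max_iter=20000)
        return SVC(kernel="rbf", gamma=gamma, C=C, class_weight=cw,
                   max_iter=20000)
    if spec.family == "knn":
        weight = {"equal": "uniform", "inverse": "distance",
                  "squared_inverse": _sq_inverse}[p.get("weight", "equal")]
        return _ThresholdedKNN(
            cost=cost,
            n_neighbors=int(p.get("n_neighbors", 5)),
            metric=p.get("metric", "euclidean"),
            weights=weight,
        )
    if spec.family == "lda":
        priors = None
        if cost != 1.0:
            # scaling the positive prior by the cost is the Bayes-equivalent
            # realization of a false-negative cost in a discriminant model
            priors = np.array([1.0, cost])
            priors = priors / priors.sum()
        return _ShrunkenLDA(gamma=float(p.get("gamma", 0.01)),
                            delta=float(p.get("delta", 0.0)), priors=priors)
    if spec.family == "logistic":
        return LogisticRegression(
            C=1.0 / float(p.get("lam", 1.0)), class_weight=cw, max_iter=2000,
            random_state=seed,
        )
    if spec.family == "decision_tree":
        return DecisionTreeClassifier(**_TREE_KW, class_weight=cw, random_state=seed)
    raise ModelingError(spec.family)


@dataclass
class TrainedModel:
    """A fitted classifier with its scaler, feature subset and class prior."""

    spec: ModelSpec
    scaler: StandardScaler
    clf: object
    class_prior: dict[int, float]

    def _X(self, data: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(data, pd.DataFrame):
            data = data[list(self.spec.features)].to_numpy(dtype=float)
        return self.scaler.transform(data)

    def predict(self, data) -> np.ndarray:
        return np.asarray(self.clf.predict(self._X(data)), dtype=int)

    def decision_scores(self, data) -> np.ndarray:
        X = self._X(data)
        if hasattr(self.clf, "decision_function"):
            return np.asarray(self.clf.decision_function(X), dtype=float)
        proba = self.clf.predict_proba(X)
        return np.asarray(proba[:, 1], dtype=float)


def fit_model(train: pd.DataFrame, spec: ModelSpec, seed: int = 0) -> TrainedModel:
    """Standardize the selected features on the training rows and fit."""
    X = train[list(spec.features)].to_numpy(dtype=float)
    y = train["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ModelingError("training data must contain both classes")
    scaler = StandardScaler().fit(X)
    clf = _build_classifier(spec, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(scaler.transform(X), y)
    prior = {int(c): float(np.mean(y == c)) for c in (0, 1)}
    return TrainedModel(spec=spec, scaler=scaler, clf=clf, class_prior=prior)


# ---------------------------------------------------------------------------
# Decision-tree feature ranking
# ---------------------------------------------------------------------------


def rank_features_dt(
    train: pd.DataFrame,
    feature_cols: Sequence[str] = FEATURE_COLUMNS,
    seed: int = 0,
) -> list[str]:
    """Rank features by the shallowest tree depth at which each first splits.

    Features used near the root of a Gini decision tree (min leaf 1, at most
    15 splits) separate the training classes best. Ties are broken by total
    impurity decrease, then by original column order; features the tree never
    uses are appended in original order. Deterministic given the seed.
    """
    y = train["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ModelingError("feature ranking needs both classes")
    X = train[list(feature_cols)].to_numpy(dtype=float)
    tree = DecisionTreeClassifier(**_TREE_KW, random_state=seed).fit(X, y)
    t = tree.tree_
    first_depth = np.full(len(feature_cols), np.inf)
    stack = [(0, 0)]
    while stack:
        node, depth = stack.pop()
        if t.children_left[node] == -1:
            continue
        f = t.feature[node]
        first_depth[f] = min(first_depth[f], depth)
        stack.append((t.children_left[node], depth + 1))
        stack.append((t.children_right[node], depth + 1))
    importance = tree.feature_importances_
    order = sorted(
        range(len(feature_cols)),
        key=lambda i: (first_depth[i], -importance[i], i),
    )
    return [feature_cols[i] for i in order]


# ---------------------------------------------------------------------------
# Inner wrapper tuning (features x regularization cost)
# ---------------------------------------------------------------------------


def _cv_folds(y: np.ndarray, n_splits: int, seed: int) -> list:
    smallest = int(np.min(np.bincount(y)))
    eff = min(n_splits, smallest)
    if eff < n_splits:
        warnings.warn(
            f"class too small for {n_splits} folds; using {eff}", stacklevel=3
        )
    if eff < 2:
        raise ModelingError("a class has fewer than 2 members; cannot cross-validate")
    skf = StratifiedKFold(n_splits=eff, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), y))


def tune_inner(
    train: pd.DataFrame,
    ranking: Sequence[str],
    c_range: Sequence[float] = DEFAULT_C_RANGE,
    n_splits: int = 10,
    seed: int = 0,
) -> tuple[int, float, np.ndarray]:
    """Exhaustive grid over (#top-ranked features, SVM cost) by 10-fold CV.

    Returns ``(best_f, best_c, error_surface)`` where the surface has shape
    ``(len(ranking), len(c_range))`` of mean misclassification error. The
    arg-min tie-break prefers fewer features, then a smaller cost (row-major
    first occurrence).
    """
    y = train["label"].to_numpy(dtype=int)
    folds = _cv_folds(y, n_splits, seed)
    n_feat = len(ranking)
    surface = np.zeros((n_feat, len(c_range)))
    X_all = train[list(ranking)].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for fi in range(n_feat):
            Xf = X_all[:, : fi + 1]
            errs = np.zeros(len(c_range))
            for tr, te in folds:
                scaler = StandardScaler().fit(Xf[tr])
                Xtr, Xte = scaler.transform(Xf[tr]), scaler.transform(Xf[te])
                for ci, c in enumerate(c_range):
                    clf = LinearSVC(C=float(c), dual=False, max_iter=5000,
                                    tol=1e-3, random_state=seed)
                    clf.fit(Xtr, y[tr])
                    errs[ci] += np.mean(clf.predict(Xte) != y[te])
            surface[fi] = errs / len(folds)
    best = np.unravel_index(int(np.argmin(surface)), surface.shape)
    return best[0] + 1, float(c_range[best[1]]), surface


def _tuned_svm_spec(
    train: pd.DataFrame,
    c_range: Sequence[float],
    n_splits: int,
    seed: int,
    fn_cost: float = 1.0,
) -> tuple[ModelSpec, list[str]]:
    """Rank on the training rows, tune (f, c), and return the resulting spec."""
    ranking = rank_features_dt(train, seed=seed)
    f, c, _ = tune_inner(train, ranking, c_range, n_splits, seed)
    spec = ModelSpec(
        family="svm",
        params=(("box_constraint", c), ("kernel", "linear")),
        features=tuple(ranking[:f]),
        fn_cost=fn_cost,
    )
    return spec, ranking


# ---------------------------------------------------------------------------
# Validation protocols
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Per-fold and aggregate performance for one validation protocol."""

    protocol: str
    fold_reports: list[PerformanceReport]
    aggregate: pd.DataFrame  # metric -> mean, sd over folds (NaN-skipping)
    pooled: PerformanceReport | None = None
    extras: dict = field(default_factory=dict)
    leakage_audit: bool = False

    def mean(self, metric: str) -> float:
        return float(self.aggregate.loc[metric, "mean"])


def _aggregate(reports: list[PerformanceReport]) -> pd.DataFrame:
    rows = {}
    for m in METRIC_NAMES:
        vals = np.array([r.metrics[m] for r in reports], dtype=float)
        vals = vals[~np.isnan(vals)]
        rows[m] = {
            "mean": float(vals.mean()) if vals.size else math.nan,
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else math.nan,
            "n_folds_defined": int(vals.size),
        }
    return pd.DataFrame(rows).T


def _evaluate(
    model: TrainedModel, test: pd.DataFrame
) -> tuple[PerformanceReport, np.ndarray, np.ndarray]:
    y = test["label"].to_numpy(dtype=int)
    pred = model.predict(test)
    scores = model.decision_scores(test)
    return compute_metrics(confusion_counts(y, pred)), pred, scores


def _audit(
    train: pd.DataFrame, test: pd.DataFrame, by: str | None = None
) -> bool:
    """Assert train/test isolation; returns True (raises on violation)."""
    if len(set(train.index) & set(test.index)):
        raise ModelingError("leakage: train and test share rows")
    if by is not None and set(train[by]) & set(test[by]):
        raise ModelingError(f"leakage: train and test share {by} values")
    return True


def kfold_validate(
    dataset: pd.DataFrame,
    n_splits: int = 10,
    c_range: Sequence[float] = DEFAULT_C_RANGE,
    inner_splits: int = 10,
    seed: int = 0,
) -> ValidationReport:
    """Stratified k-fold protocol; ranking and tuning redone per fold."""
    y = dataset["label"].to_numpy(dtype=int)
    folds = _cv_folds(y, n_splits, seed)
    reports, preds, ys, scores = [], [], [], []
    audit_ok = True
    for tr, te in folds:
        train, test = dataset.iloc[tr], dataset.iloc[te]
        audit_ok &= _audit(train, test)
        spec, _ = _tuned_svm_spec(train, c_range, inner_splits, seed)
        model = fit_model(train, spec, seed)
        rep, pred, score = _evaluate(model, test)
        reports.append(rep)
        ys.append(test["label"].to_numpy(int))
        preds.append(pred)
        scores.append(score)
    pooled = compute_metrics(
        confusion_counts(np.concatenate(ys), np.concatenate(preds))
    )
    return ValidationReport(
        protocol=f"kfold{n_splits}",
        fold_reports=reports,
        aggregate=_aggregate(reports),
        pooled=pooled,
        leakage_audit=audit_ok,
    )


def run_algorithm1(
    dataset: pd.DataFrame,
    k: int = 20,
    test_frac: float = 0.3,
    c_range: Sequence[float] = DEFAULT_C_RANGE,
    inner_splits: int = 10,
    seed: int = 0,
) -> ValidationReport:
    """Repeated stratified 70/30 train/test wrapper protocol.

    Each of the ``k`` repetitions draws an independent stratified split,
    ranks the features and tunes (f, c) on the training split only, fits,
    and scores the held-out 30%.
    """
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(k)]
    reports = []
    specs = []
    audit_ok = True
    for rs in rep_seeds:
        train, test = train_test_split(
            dataset, test_size=test_frac, stratify=dataset["label"],
            random_state=rs,
        )
        audit_ok &= _audit(train, test)
        spec, _ = _tuned_svm_spec(train, c_range, inner_splits, rs)
        model = fit_model(train, spec, rs)
        rep, _, _ = _evaluate(model, test)
        reports.append(rep)
        specs.append(spec)
    return ValidationReport(
        protocol=f"split7030x{k}",
        fold_reports=reports,
        aggregate=_aggregate(reports),
        extras={"specs": specs},
        leakage_audit=audit_ok,
    )


def loso_validate(
    dataset: pd.DataFrame,
    c_range: Sequence[float] = DEFAULT_C_RANGE,
    inner_splits: int = 10,
    seed: int = 0,
    fn_cost: float = 1.0,
    spec: ModelSpec | None = None,
) -> ValidationReport:
    """Leave-one-subject-out validation with per-fold wrapper selection.

    When ``spec`` is given, its family/hyperparameters/cost are reused but
    feature ranking and (for SVM) the wrapper grid are still re-run inside
    each fold on training subjects only. Folds where the held-out subject
    has a single class keep their defined metrics and flag the rest.
    """
    subjects = sorted(dataset["subject_id"].unique())
    if len(subjects) < 2:
        raise ModelingError("LOSO requires at least 2 subjects")
    reports, selected, ys, preds, scores = [], {}, [], [], []
    audit_ok = True
    for s in subjects:
        train = dataset[dataset["subject_id"] != s]
        test = dataset[dataset["subject_id"] == s]
        audit_ok &= _audit(train, test, by="subject_id")
        if spec is None or spec.family == "svm":
            fold_spec, _ = _tuned_svm_spec(
                train, c_range, inner_splits, seed, fn_cost=fn_cost
            )
            if spec is not None:  # keep caller's cost/kernel params
                fold_spec = replace(
                    spec, features=fold_spec.features, params=fold_spec.params
                )
        else:
            fold_spec = spec
        model = fit_model(train, fold_spec, seed)
        rep, pred, score = _evaluate(model, test)
        reports.append(rep)
        selected[s] = list(fold_spec.features)
        ys.append(test["label"].to_numpy(int))
        preds.append(pred)
        scores.append(score)
    y_all = np.concatenate(ys)
    pred_all = np.concatenate(preds)
    score_all = np.concatenate(scores)
    pooled = compute_metrics(confusion_counts(y_all, pred_all))
    if len(np.unique(y_all)) == 2:
        pooled.roc_points, pooled.auc = roc_curve(score_all, y_all)
    return ValidationReport(
        protocol="loso",
        fold_reports=reports,
        aggregate=_aggregate(reports),
        pooled=pooled,
        extras={
            "subjects": subjects,
            "selected_features": selected,
            "selection_frequency": selection_frequency(selected),
            "predictions": pd.DataFrame(
                {
                    "subject_id": np.concatenate(
                        [
                            [s] * int((dataset["subject_id"] == s).sum())
                            for s in subjects
                        ]
                    ),
                    "row_index": np.concatenate(
                        [dataset.index[dataset["subject_id"] == s] for s in subjects]
                    ),
                    "label": y_all,
                    "prediction": pred_all,
                    "score": score_all,
                }
            ),
        },
        leakage_audit=audit_ok,
    )


def selection_frequency(selected: dict[str, list[str]]) -> pd.Series:
    """Fraction of LOSO folds in which each feature was selected."""
    n = len(selected)
    counts: dict[str, int] = {f: 0 for f in FEATURE_COLUMNS}
    for feats in selected.values():
        for f in feats:
            counts[f] += 1
    return pd.Series({f: c / n for f, c in counts.items()}).sort_values(
        ascending=False
    )


# ---------------------------------------------------------------------------
# Window x model-family selection
# ---------------------------------------------------------------------------


def sample_hyperparams(family: str, rng: np.random.Generator) -> dict:
    """Draw one hyperparameter set uniformly (log-uniform for scale-like
    parameters) from the family's admissible range."""
    if family == "svm":
        return {
            "kernel": rng.choice(["linear", "quadratic", "gaussian"]).item(),
            "kernel_scale": float(10 ** rng.uniform(-3, 2)),
            "box_constraint": float(10 ** rng.uniform(-2, 2)),
        }
    if family == "knn":
        return {
            "n_neighbors": int(rng.integers(1, 51)),
            "metric": rng.choice(["euclidean", "manhattan"]).item(),
            "weight": rng.choice(["equal", "inverse", "squared_inverse"]).item(),
        }
    if family == "lda":
        return {
            "gamma": float(rng.uniform(0.01, 1.0)),
            "delta": float(10 ** rng.uniform(-2, 2)),
        }
    if family == "logistic":
        return {"lam": float(10 ** rng.uniform(-2, 2))}
    raise ModelingError(family)


def _cv_accuracy(
    dataset: pd.DataFrame, spec: ModelSpec, folds: list, seed: int
) -> float:
    y = dataset["label"].to_numpy(dtype=int)
    correct = 0
    for tr, te in folds:
        model = fit_model(dataset.iloc[tr], spec, seed)
        correct += int(np.sum(model.predict(dataset.iloc[te]) == y[te]))
    return 100.0 * correct / len(y)


def select_window_and_model(
    dataset_builder: Callable[[float], pd.DataFrame],
    windows: Sequence[float] = (2.0, 3.0, 4.0, 5.0),
    families: Sequence[str] = FAMILIES,
    n_splits: int = 10,
    budget: int = 30,
    seed: int = 0,
) -> tuple[float, str, pd.DataFrame, dict]:
    """Joint pre-FOG window / classifier-family selection by CV accuracy.

    ``dataset_builder(window_s)`` must return the labeled prediction dataset
    for that window. Each (window, family) cell tunes its hyperparameters
    with a seeded random search of ``budget`` evaluations, scored by
    ``n_splits``-fold stratified CV accuracy; the best cell (ties towards the
    shorter window and the earlier family) is returned together with the full
    accuracy table and the per-cell winning hyperparameters.
    """
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(index=list(windows), columns=list(families), dtype=float)
    best_params: dict[tuple[float, str], dict] = {}
    for w in windows:
        ds = dataset_builder(w)
        y = ds["label"].to_numpy(dtype=int)
        if len(np.unique(y)) < 2:
            raise ModelingError(f"window {w}s produced a single-class dataset")
        folds = _cv_folds(y, n_splits, seed)
        for fam in families:
            best_acc, best_p = -np.inf, {}
            for _ in range(budget):
                params = sample_hyperparams(fam, rng)
                spec = ModelSpec(
                    family=fam, params=tuple(sorted(params.items()))
                )
                try:
                    acc = _cv_accuracy(ds, spec, folds, seed)
                except ModelingError:
                    continue
                if acc > best_acc:
                    best_acc, best_p = acc, params
            table.loc[w, fam] = best_acc
            best_params[(w, fam)] = best_p
    best_w, best_fam, best_val = None, None, -np.inf
    for w in windows:
        for fam in families:
            if table.loc[w, fam] > best_val:
                best_w, best_fam, best_val = w, fam, table.loc[w, fam]
    return float(best_w), str(best_fam), table, best_params


# ---------------------------------------------------------------------------
# False-negative cost tuning and OR combination
# ---------------------------------------------------------------------------


def tune_fn_cost(
    dataset: pd.DataFrame,
    spec: ModelSpec,
    costs: Sequence[float] = tuple(range(1, 11)),
    n_splits: int = 10,
    f_score_tolerance: float = 5.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Sweep the false-negative cost and pick the most sensitive usable one.

    For each cost the model is re-fit in stratified CV with the positive
    class up-weighted by the cost; the curve reports CV sensitivity, accuracy
    and F-score. The chosen cost maximizes sensitivity subject to keeping the
    F-score within ``f_score_tolerance`` points of the unweighted (cost 1)
    model; ties go to the smaller cost. A cost whose predictions are all
    positive is flagged degenerate in the curve.
    """
    y = dataset["label"].to_numpy(dtype=int)
    folds = _cv_folds(y, n_splits, seed)
    rows = []
    for cost in costs:
        cspec = replace(spec, fn_cost=float(cost))
        preds = np.empty_like(y)
        for tr, te in folds:
            model = fit_model(dataset.iloc[tr], cspec, seed)
            preds[te] = model.predict(dataset.iloc[te])
        rep = compute_metrics(confusion_counts(y, preds))
        rows.append(
            {
                "fn_cost": float(cost),
                "sensitivity": rep.metrics["sensitivity"],
                "accuracy": rep.metrics["accuracy"],
                "f_score": rep.metrics["f_score"],
                "degenerate_all_positive": bool(np.all(preds == 1)),
            }
        )
    curve = pd.DataFrame(rows)
    base_f = curve.loc[curve["fn_cost"] == min(costs), "f_score"].iloc[0]
    ok = curve[curve["f_score"] >= base_f - f_score_tolerance]
    ok = ok.sort_values(["sensitivity", "fn_cost"], ascending=[False, True])
    chosen = float(ok["fn_cost"].iloc[0])
    return curve, chosen


def combine_or(models: Sequence[TrainedModel], data: pd.DataFrame) -> np.ndarray:
    """OR-rule ensemble: positive when *any* model votes positive.

    Can only add positives, so its sensitivity is at least the best
    individual model's on the same data (at the price of specificity).
    """
    if len(models) < 2:
        raise ModelingError("OR combination needs at least 2 models")
    votes = np.column_stack([m.predict(data) for m in models])
    return (votes.max(axis=1) > 0).astype(int)


# ---------------------------------------------------------------------------
# Cross-therapy-state transfer
# ---------------------------------------------------------------------------


def cross_condition(
    dataset: pd.DataFrame,
    train_condition: str,
    test_condition: str,
    c_range: Sequence[float] = DEFAULT_C_RANGE,
    inner_splits: int = 10,
    fn_cost: float = 1.0,
    seed: int = 0,
) -> tuple[PerformanceReport, TrainedModel]:
    """Train the full pipeline on one therapy state, test on the other.

    Ranking, wrapper tuning and fitting see only ``train_condition`` rows;
    the isolation is asserted and reflected in the returned report's
    ``extras`` — a violation raises instead of silently degrading.
    """
    for cond in (train_condition, test_condition):
        if cond not in set(dataset["condition"]):
            raise ModelingError(f"condition {cond!r} absent from dataset")
    train = dataset[dataset["condition"] == train_condition]
    test = dataset[dataset["condition"] == test_condition]
    _audit(train, test, by="condition")
    spec, _ = _tuned_svm_spec(train, c_range, inner_splits, seed, fn_cost=fn_cost)
    model = fit_model(train, spec, seed)
    rep, pred, score = _evaluate(model, test)
    y = test["label"].to_numpy(int)
    if len(np.unique(y)) == 2:
        rep.roc_points, rep.auc = roc_curve(score, y)
    return rep, model
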