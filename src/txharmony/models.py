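"""Balanced splitting, the three classifiers, ROC/AUC and the DeLong test.

The classifier configurations are fixed low-parameter settings suited to
small-n / large-p cohorts: a 100-tree depth-5 random forest with balanced
class weights and out-of-bag scoring, a linear SVM (squared hinge, L2,
C = 1) and LDA with the eigen solver and Ledoit-Wolf shrinkage so the
within-class covariance stays invertible when genes outnumber samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.svm import LinearSVC

from txharmony.errors import ConfigurationError, DataError

__all__ = [
    "SplitPlan",
    "ClassifierSpec",
    "DEFAULT_SPECS",
    "FittedModel",
    "ModelEval",
    "split_balanced",
    "train_classifier",
    "roc_auc",
    "random_feature_baseline",
    "BaselineResult",
    "delong_test",
]


@dataclass
class SplitPlan:
    assignment: pd.Series  # sample_id -> "train" | "test"
    frac: float
    strata: tuple[str, ...]

    @property
    def train_samples(self) -> list[str]:
        return list(self.assignment.index[self.assignment == "train"])

    @property
    def test_samples(self) -> list[str]:
        return list(self.assignment.index[self.assignment == "test"])


@dataclass(frozen=True)
class ClassifierSpec:
    """Fixed-configuration classifier factory ("rf", "svm" or "lda")."""

    kind: str
    seed: int = 0
    params: dict = field(default_factory=dict)

    def build(self):
        if self.kind == "rf":
            opts = dict(
                n_estimators=100,
                max_depth=5,
                min_samples_split=2,
                bootstrap=True,
                class_weight="balanced",
                oob_score=True,
                random_state=self.seed,
            )
            opts.update(self.params)
            return RandomForestClassifier(**opts)
        if self.kind == "svm":
            # random_state pins liblinear's internal shuffling for exact reruns
            opts = dict(loss="squared_hinge", penalty="l2", C=1.0, random_state=self.seed)
            opts.update(self.params)
            return LinearSVC(**opts)
        if self.kind == "lda":
            opts = dict(solver="eigen", shrinkage="auto")  # Ledoit-Wolf shrinkage
            opts.update(self.params)
            return LinearDiscriminantAnalysis(**opts)
        raise ConfigurationError(f"unknown classifier kind: {self.kind!r}")

    def with_seed(self, seed: int) -> "ClassifierSpec":
        return replace(self, seed=seed)


DEFAULT_SPECS: dict[str, ClassifierSpec] = {
    "rf": ClassifierSpec("rf"),
    "svm": ClassifierSpec("svm"),
    "lda": ClassifierSpec("lda"),
}


@dataclass
class FittedModel:
    spec: ClassifierSpec
    estimator: object
    genes: list[str]

    def scores(self, X: pd.DataFrame) -> np.ndarray:
        """Continuous score: decision value (linear kinds) or class-1 probability (RF)."""
        arr = X[self.genes].to_numpy(dtype=float)
        est = self.estimator
        if hasattr(est, "decision_function"):
            return np.asarray(est.decision_function(arr), dtype=float)
        return np.asarray(est.predict_proba(arr)[:, 1], dtype=float)

    @property
    def score_threshold(self) -> float:
        return 0.0 if hasattr(self.estimator, "decision_function") else 0.5

    @property
    def coefficients(self) -> pd.Series:
        est = self.estimator
        if not hasattr(est, "coef_"):
            raise DataError(f"{self.spec.kind} has no per-gene coefficients")
        return pd.Series(np.ravel(est.coef_), index=self.genes)

    @property
    def oob_accuracy(self) -> float | None:
        return getattr(self.estimator, "oob_score_", None)


@dataclass
class ModelEval:
    kind: str
    scores: np.ndarray
    y: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    accuracy: float

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "auc": self.auc,
            "accuracy": self.accuracy,
            "scores": self.scores.tolist(),
            "fpr": self.fpr.tolist(),
            "tpr": self.tpr.tolist(),
        }


def _age_bin(age: float) -> str:
    return "young" if age <= 16 else "old"


def split_balanced(meta: pd.DataFrame, frac: float = 0.8, seed: int = 0) -> SplitPlan:
    """Deterministic 80/20 split stratified over study x class x sex x strain x age bin.

    Each stratum cell contributes ``round(n * (1 - frac))`` test samples
    (half-up rounding), so class proportions are preserved within +-1 sample
    per study and every study is represented in training.  Ages are binned
    at 16 weeks.  Errors if a class ends up absent from the test side.
    """
    if not 0.0 < frac < 1.0:
        raise ConfigurationError("frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    cells = meta.groupby(
        ["study_id", "class", "sex", "strain", meta["age_weeks"].map(_age_bin)],
        sort=True,
        observed=True,
    )
    assignment = pd.Series("train", index=meta.index, name="split")
    for _, cell in cells:
        n = len(cell)
        n_test = int(np.floor(n * (1.0 - frac) + 0.5))
        if n_test >= n:  # never empty a cell's training side
            n_test = n - 1
        if n_test <= 0:
            continue
        order = rng.permutation(cell.index.to_numpy())
        assignment.loc[order[:n_test]] = "test"
    test_meta = meta.loc[assignment == "test"]
    if test_meta["class"].nunique() < meta["class"].nunique():
        raise DataError("a class is absent from the test set; adjust frac or strata")
    return SplitPlan(
        assignment=assignment,
        frac=frac,
        strata=("study_id", "class", "sex", "strain", "age_bin"),
    )


def train_classifier(
    X_train: pd.DataFrame, y_train: np.ndarray, spec: ClassifierSpec
) -> FittedModel:
    y_train = np.asarray(y_train)
    arr = X_train.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise DataError("NaN in training matrix")
    if len(np.unique(y_train)) < 2:
        raise DataError("training labels contain a single class")
    est = spec.build()
    est.fit(arr, y_train)
    return FittedModel(spec=spec, estimator=est, genes=list(X_train.columns))


def roc_auc(model: FittedModel, X_test: pd.DataFrame, y_test: np.ndarray) -> ModelEval:
    """Holdout ROC and AUC; AUC is the rank (Mann-Whitney) statistic with ties at 1/2."""
    y_test = np.asarray(y_test)
    if len(np.unique(y_test)) < 2:
        raise DataError("test labels contain a single class")
    scores = model.scores(X_test)
    fpr, tpr, _ = roc_curve(y_test, scores)
    auc = float(roc_auc_score(y_test, scores))
    acc = float(np.mean((scores > model.score_threshold).astype(int) == y_test))
    return ModelEval(
        kind=model.spec.kind, scores=scores, y=y_test, fpr=fpr, tpr=tpr, auc=auc, accuracy=acc
    )


@dataclass
class BaselineResult:
    """AUC distributions from random k-gene subsets, one array per classifier."""

    aucs: dict[str, np.ndarray]
    subsets: list[list[str]]

    @property
    def means(self) -> dict[str, float]:
        return {name: float(a.mean()) for name, a in self.aucs.items()}

    def median_iteration(self, kind: str) -> int:
        """Index of the iteration whose AUC sits at the distribution median."""
        a = self.aucs[kind]
        return int(np.argsort(a, kind="stable")[(len(a) - 1) // 2])


def random_feature_baseline(
    X: pd.DataFrame,
    y: np.ndarray,
    split: SplitPlan,
    k: int,
    specs: dict[str, ClassifierSpec] | None = None,
    n_iter: int = 1000,
    seed: int = 0,
) -> BaselineResult:
    """Null AUC distribution from ``n_iter`` random k-gene subsets.

    Each iteration draws k genes uniformly without replacement, refits every
    classifier on the fixed training side and scores AUC on the fixed test
    side.  Returns the full AUC sample per classifier plus the subsets
    drawn, so a particular realization can be refit for paired testing.
    """
    if n_iter < 1:
        raise ConfigurationError("n_iter must be >= 1")
    if k > X.shape[1]:
        raise ConfigurationError("k exceeds the number of genes")
    specs = specs or DEFAULT_SPECS
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    ser = pd.Series(y, index=X.index)
    tr, te = split.train_samples, split.test_samples
    out = {name: np.empty(n_iter) for name in specs}
    subsets: list[list[str]] = []
    genes = np.array(X.columns)
    for i in range(n_iter):
        subset = list(genes[rng.choice(len(genes), size=k, replace=False)])
        subsets.append(subset)
        Xtr, Xte = X.loc[tr, subset], X.loc[te, subset]
        for name, spec in specs.items():
            model = train_classifier(Xtr, ser.loc[tr].to_numpy(), spec)
            out[name][i] = roc_auc(model, Xte, ser.loc[te].to_numpy()).auc
    return BaselineResult(aucs=out, subsets=subsets)


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values: per-positive V10 and per-negative V01."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    # psi(x, y) = 1 if x > y, 1/2 if tie, 0 otherwise
    psi = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    return psi.mean(axis=1), psi.mean(axis=0)


def delong_test(eval_a: ModelEval, eval_b: ModelEval, y_test: np.ndarray | None = None) -> dict:
    """Paired two-sided DeLong comparison of two correlated AUCs.

    Both evaluations must score the identical test samples in identical
    order.  The variance of the AUC difference comes from the empirical
    covariance of the structural components (placement values) of the two
    score vectors; the p-value is from the standard normal.
    """
    y = np.asarray(y_test) if y_test is not None else eval_a.y
    if not np.array_equal(eval_a.y, eval_b.y) or not np.array_equal(eval_a.y, y):
        raise DataError("DeLong test requires identical test labels in identical order")
    if len(eval_a.scores) != len(eval_b.scores):
        raise DataError("score vectors differ in length")

    v10_a, v01_a = _placements(eval_a.scores, y)
    v10_b, v01_b = _placements(eval_b.scores, y)
    auc_a, auc_b = v10_a.mean(), v10_b.mean()
    m, n = len(v10_a), len(v01_a)

    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = float(auc_a - auc_b)
    if var <= 0:
        return {"auc_diff": diff, "variance": 0.0, "z": 0.0 if diff == 0 else np.inf, "p": 1.0 if diff == 0 else 0.0}
    z = diff / np.sqrt(var)
    p = float(2.0 * norm.sf(abs(z)))
    return {"auc_diff": diff, "variance": float(var), "z": float(z), "p": p}
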