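"""Sequential mRMR feature selection with cross-validated accuracy traces.

Relevance is the one-way ANOVA F-statistic of a gene against the binary
class; redundancy is the mean absolute Pearson correlation with the genes
already selected.  Each step adds the gene maximizing the quotient
F / max(mean|r|, eps) (the "FCQ" form; a difference form is available).
Selection stops at ``k_max``, canonically the number of training samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif
from sklearn.model_selection import StratifiedKFold

from txharmony.errors import ConfigurationError, DataError

__all__ = ["FeatureScore", "SelectionTrace", "mrmr_select", "cv_accuracy_curve", "select_elbow"]

EPS_REDUNDANCY = 1e-12


@dataclass(frozen=True)
class FeatureScore:
    gene: str
    relevance: float
    redundancy: float
    score: float


@dataclass
class SelectionTrace:
    selected: list[FeatureScore]
    k_max: int
    mode: str = "quotient"
    cv_curve: pd.DataFrame | None = None  # filled by cv_accuracy_curve

    @property
    def genes(self) -> list[str]:
        return [s.gene for s in self.selected]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.selected) + 1),
                "gene": [s.gene for s in self.selected],
                "relevance": [s.relevance for s in self.selected],
                "redundancy": [s.redundancy for s in self.selected],
                "score": [s.score for s in self.selected],
            }
        )


def mrmr_select(X: pd.DataFrame, y: np.ndarray, k_max: int, mode: str = "quotient") -> SelectionTrace:
    """Greedy mRMR over a training samples x genes matrix.

    The first gene maximizes the F-statistic; each later gene maximizes
    relevance/redundancy ("quotient") or relevance - redundancy
    ("difference").  Ties break lexicographically on gene ID; the procedure
    is fully deterministic.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DataError("mRMR requires both classes in y")
    if k_max < 1:
        raise ConfigurationError("k_max must be >= 1")
    if k_max > X.shape[1]:
        raise ConfigurationError("k_max exceeds the number of genes")
    if k_max > X.shape[0]:
        raise ConfigurationError(
            "k_max exceeds the number of training samples (stopping rule: k_max <= n)"
        )
    if mode not in ("quotient", "difference"):
        raise ConfigurationError(f"unknown mRMR mode: {mode!r}")

    # lexicographic column order makes argmax tie-breaking lexicographic
    X = X[sorted(X.columns)]
    genes = np.array(X.columns)
    arr = X.to_numpy(dtype=float)
    n, p = arr.shape

    with np.errstate(invalid="ignore", divide="ignore"):
        F, _ = f_classif(arr, y)
    F = np.nan_to_num(F, nan=0.0, posinf=np.finfo(float).max)

    # unit-normalized columns make each redundancy update a single matvec
    centered = arr - arr.mean(axis=0)
    norms = np.linalg.norm(centered, axis=0)
    unit = np.divide(centered, norms, out=np.zeros_like(centered), where=norms > 0)

    selected_idx: list[int] = []
    scores: list[FeatureScore] = []
    redundancy_sum = np.zeros(p)
    available = np.ones(p, dtype=bool)

    for step in range(k_max):
        if step == 0:
            crit = F.copy()
            red = np.zeros(p)
        else:
            red = redundancy_sum / step
            if mode == "quotient":
                crit = F / np.maximum(red, EPS_REDUNDANCY)
            else:
                crit = F - red
        crit = np.where(available, crit, -np.inf)
        best = int(np.argmax(crit))  # first max = lexicographically smallest gene
        selected_idx.append(best)
        scores.append(
            FeatureScore(
                gene=str(genes[best]),
                relevance=float(F[best]),
                redundancy=float(red[best]),
                score=float(crit[best]),
            )
        )
        available[best] = False
        r_new = np.abs(unit.T @ unit[:, best])
        # zero-variance columns have r undefined; treat as fully redundant
        r_new = np.where(norms > 0, r_new, 1.0)
        if norms[best] == 0:
            r_new = np.ones(p)
        redundancy_sum += np.clip(r_new, 0.0, 1.0)

    return SelectionTrace(selected=scores, k_max=k_max, mode=mode)


def cv_accuracy_curve(
    X: pd.DataFrame,
    y: np.ndarray,
    trace: SelectionTrace,
    classifier_specs: dict,
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified k-fold accuracy at each mRMR iteration.

    Iteration k trains every classifier on the first k selected genes; the
    fold assignment is fixed once (stratified by class) and reused across
    iterations and classifiers so curves are paired.  Returns a tidy frame
    with columns (k, classifier, mean_accuracy, sd_accuracy).
    """
    y = np.asarray(y)
    counts = np.bincount(y)
    if n_folds > counts.min():
        raise DataError(f"n_folds={n_folds} exceeds minority class count {counts.min()}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(y)), y))

    rows = []
    arr = X[trace.genes].to_numpy(dtype=float)
    for k in range(1, len(trace.genes) + 1):
        Xk = arr[:, :k]
        for name, spec in classifier_specs.items():
            accs = []
            for tr, te in folds:
                est = spec.build()
                est.fit(Xk[tr], y[tr])
                accs.append(float(np.mean(est.predict(Xk[te]) == y[te])))
            rows.append(
                {
                    "k": k,
                    "classifier": name,
                    "mean_accuracy": float(np.mean(accs)),
                    "sd_accuracy": float(np.std(accs, ddof=1)),
                }
            )
    curve = pd.DataFrame(rows)
    trace.cv_curve = curve
    return curve


def select_elbow(curve, mode: str = "kneedle", manual_k: int | None = None) -> int:
    """Pick the feature count at the accuracy curve's elbow.

    ``manual`` returns ``manual_k`` unchanged.  ``kneedle`` takes the mean
    accuracy over classifiers at each k and returns the k with maximum
    perpendicular-style distance above the chord joining the curve's
    endpoints; a flat or linear curve has no elbow and raises, in which case
    a manual k must be supplied.
    """
    if mode == "manual":
        if manual_k is None or manual_k < 1:
            raise ConfigurationError("manual elbow mode requires a positive manual_k")
        return int(manual_k)
    if mode != "kneedle":
        raise ConfigurationError(f"unknown elbow mode: {mode!r}")

    if isinstance(curve, pd.DataFrame):
        mean_curve = curve.groupby("k")["mean_accuracy"].mean()
        ks = mean_curve.index.to_numpy(dtype=float)
        vals = mean_curve.to_numpy(dtype=float)
    else:
        vals = np.asarray(curve, dtype=float)
        ks = np.arange(1, len(vals) + 1, dtype=float)
    if len(vals) < 3:
        raise DataError("kneedle needs a curve of length >= 3")

    # vertical distance above the endpoint chord, evaluated at each k
    x0, x1 = ks[0], ks[-1]
    y0, y1 = vals[0], vals[-1]
    chord = y0 + (ks - x0) * (y1 - y0) / (x1 - x0)
    dist = vals - chord
    if float(dist.max()) <= 1e-8:
        raise DataError("no elbow: accuracy curve is flat or linear; supply manual_k")
    return int(ks[int(np.argmax(dist))])
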