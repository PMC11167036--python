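"""Permutation feature importance, cross-model rank concordance, and
correlation-distance gene-set expansion.

Permutation importance of a gene is the drop in holdout AUC when that
gene's test column is shuffled (mean over repeats); it is model-agnostic,
which makes per-gene rankings comparable across classifier families.
Because an mRMR panel is deliberately non-redundant, each selected gene
stands for a cluster of correlated genes; ``expand_correlated_set``
recovers that cluster as the k nearest genes under the signed correlation
distance d = 1 - r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance as _sk_permutation_importance

from txharmony.errors import ConfigurationError, DataError
from txharmony.models import FittedModel

__all__ = [
    "ImportanceTable",
    "ConcordanceTable",
    "permutation_importance",
    "rank_concordance",
    "calibrate_expansion_k",
    "expand_correlated_set",
]


@dataclass
class ImportanceTable:
    kind: str
    table: pd.DataFrame  # index gene; columns mean_drop, sd_drop, rank
    n_repeats: int

    @property
    def ranks(self) -> pd.Series:
        return self.table["rank"]


@dataclass
class ConcordanceTable:
    table: pd.DataFrame  # index gene; per-source rank columns + rank_median, rank_iqr, rank_sd

    @property
    def top_concordant(self) -> list[str]:
        return list(self.table.index)


def permutation_importance(
    model: FittedModel,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    n_repeats: int = 100,
    seed: int = 0,
) -> ImportanceTable:
    """AUC-scored permutation importance on the holdout set.

    Importance of gene g = baseline AUC minus the mean AUC over
    ``n_repeats`` independent shuffles of column g; may be negative.  Ranks
    are 1 = largest drop, ties broken by gene ID (via a stable sort on a
    gene-sorted table).
    """
    y_test = np.asarray(y_test)
    if len(np.unique(y_test)) < 2:
        raise DataError("permutation importance needs both classes in y_test")
    arr = X_test[model.genes]
    res = _sk_permutation_importance(
        model.estimator,
        arr.to_numpy(dtype=float),
        y_test,
        scoring="roc_auc",
        n_repeats=n_repeats,
        random_state=seed,
    )
    table = pd.DataFrame(
        {"mean_drop": res.importances_mean, "sd_drop": res.importances_std},
        index=pd.Index(model.genes, name="gene"),
    ).sort_index()
    order = np.argsort(-table["mean_drop"].to_numpy(), kind="stable")
    ranks = np.empty(len(table), dtype=int)
    ranks[order] = np.arange(1, len(table) + 1)
    table["rank"] = ranks
    return ImportanceTable(kind=model.spec.kind, table=table, n_repeats=n_repeats)


def rank_concordance(
    tables: list[ImportanceTable], mrmr_order: list[str] | None = None
) -> ConcordanceTable:
    """Assemble per-gene rank vectors across models and order by concordance.

    Most-concordant-important first: smallest rank median, then smallest
    rank IQR (linear-interpolation quantiles), then gene ID.  The rank SD is
    emitted alongside the IQR.
    """
    if len(tables) + (mrmr_order is not None) < 2:
        raise DataError("concordance needs at least two rankings")
    gene_sets = [set(t.table.index) for t in tables]
    if any(gs != gene_sets[0] for gs in gene_sets[1:]):
        raise DataError("importance tables cover different gene sets")
    ranks = pd.DataFrame({f"rank_{t.kind}": t.ranks for t in tables})
    if mrmr_order is not None:
        if set(mrmr_order) != gene_sets[0]:
            raise DataError("mRMR order covers a different gene set")
        ranks["rank_mrmr"] = pd.Series(
            np.arange(1, len(mrmr_order) + 1), index=pd.Index(mrmr_order, name="gene")
        )
    arr = ranks.to_numpy(dtype=float)
    out = ranks.copy()
    out["rank_median"] = np.median(arr, axis=1)
    q1 = np.percentile(arr, 25, axis=1)  # linear interpolation
    q3 = np.percentile(arr, 75, axis=1)
    out["rank_iqr"] = q3 - q1
    out["rank_sd"] = arr.std(axis=1, ddof=1)
    # stable sort after an index sort => ties resolve by gene ID
    out = out.sort_index(kind="stable").sort_values(["rank_median", "rank_iqr"], kind="stable")
    return ConcordanceTable(table=out)


def _correlation_distance(Z: pd.DataFrame, gene: str) -> pd.Series:
    """Signed correlation distance d = 1 - Pearson r of every gene to ``gene``."""
    if gene not in Z.columns:
        raise DataError(f"gene {gene!r} absent from matrix")
    arr = Z.to_numpy(dtype=float)
    g = Z.columns.get_loc(gene)
    centered = arr - arr.mean(axis=0)
    norms = np.linalg.norm(centered, axis=0)
    if norms[g] == 0:
        raise DataError(f"gene {gene!r} has zero variance")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = centered.T @ centered[:, g] / (norms * norms[g])
    r = np.where(norms > 0, r, np.nan)
    return pd.Series(1.0 - r, index=Z.columns, name="distance")


def calibrate_expansion_k(Z: pd.DataFrame, anchor_gene: str, target_gene: str) -> int:
    """Rank of ``target_gene`` among all genes by correlation distance to the anchor.

    Used to pick the expansion size k from a known co-regulated (anchor,
    regulator) pair: k is the 1-based position of the target when every
    other gene is sorted by ascending d = 1 - r (ties by gene ID).
    """
    d = _correlation_distance(Z, anchor_gene).drop(anchor_gene)
    if target_gene not in d.index:
        raise DataError(f"target gene {target_gene!r} absent from matrix")
    ordered = d.sort_index(kind="stable").sort_values(kind="stable")
    return int(np.nonzero(ordered.index.to_numpy() == target_gene)[0][0]) + 1


def expand_correlated_set(Z: pd.DataFrame, gene: str, k: int) -> list[str]:
    """The k nearest genes to ``gene`` by signed correlation distance.

    The seed gene is excluded; anticorrelated genes (d near 2) rank last.
    Deterministic: distance ties break on gene ID.
    """
    if k <= 0:
        raise ConfigurationError("expansion size k must be positive")
    if k >= Z.shape[1]:
        raise ConfigurationError("k must be smaller than the gene count")
    d = _correlation_distance(Z, gene).drop(gene)
    ordered = d.sort_index(kind="stable").sort_values(kind="stable")
    return list(ordered.index[:k])
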