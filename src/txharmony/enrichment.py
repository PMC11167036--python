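"""Gene rankings, preranked GSEA, BH adjustment, and overlap analysis.

Two ranking routes feed enrichment: per-study log2 fold-changes of
median-of-ratios-normalized counts (the classical single-study route) and
the signed coefficients of a linear SVM trained on the merged harmonized
matrix over all retained genes (the merged-study route).  Gene sets are
scored with the weighted Kolmogorov-Smirnov running-sum statistic against
a gene-label permutation null, and single-vs-merged significance overlap
is tabulated per study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from txharmony.errors import ConfigurationError, DataError
from txharmony.harmonize import SizeFactors, apply_size_factors
from txharmony.models import FittedModel
from txharmony.simulate import StudyBundle

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "OverlapTable",
    "fold_change_rank",
    "svm_coefficient_rank",
    "enrichment_score",
    "gsea_preranked",
    "bh_adjust",
    "overlap_analysis",
    "overlap_percentage",
]


@dataclass
class RankedList:
    """Signed ranking metric per gene; descending metric, ties by gene ID."""

    metric: pd.Series
    source: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.metric.to_numpy(dtype=float)).all():
            raise DataError("ranking metric contains non-finite values")
        self.metric = self.metric.sort_index(kind="stable").sort_values(
            ascending=False, kind="stable"
        )

    @property
    def genes(self) -> list[str]:
        return list(self.metric.index)


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # index set name; ES, NES, pval, padj, size, leading_edge
    skipped: list[str]  # sets outside the size bounds

    def significant(self, cutoff: float = 0.1) -> set[str]:
        return set(self.table.index[self.table["padj"] <= cutoff])


@dataclass
class OverlapTable:
    table: pd.DataFrame


def fold_change_rank(bundle: StudyBundle, size_factors: SizeFactors) -> RankedList:
    """Per-study log2 fold-change ranking on normalized counts.

    metric = log2((mean normalized spaceflown + 0.5) / (mean normalized
    ground + 0.5)); the 0.5 pseudocount keeps zero-mean genes finite.
    """
    classes = bundle.metadata["class"]
    if set(classes.unique()) != {"spaceflown", "ground"}:
        raise DataError(f"study {bundle.study_id}: both classes required for fold change")
    norm = apply_size_factors(bundle.counts, size_factors)
    sf_mean = norm.loc[:, classes == "spaceflown"].mean(axis=1)
    gc_mean = norm.loc[:, classes == "ground"].mean(axis=1)
    metric = np.log2((sf_mean + 0.5) / (gc_mean + 0.5))
    return RankedList(metric=metric, source=f"log2fc:{bundle.study_id}")


def svm_coefficient_rank(model: FittedModel) -> RankedList:
    """Ranking by the signed coefficients of a linear model fit on all retained genes."""
    coefs = model.coefficients  # raises for non-linear kinds
    return RankedList(metric=coefs.astype(float), source="svm_coefficients")


def enrichment_score(
    ranked_genes: list[str],
    metrics: np.ndarray,
    member_mask: np.ndarray,
    p: float = 1.0,
) -> tuple[float, int]:
    """Weighted KS enrichment score for one set over a descending ranking.

    P_hit accumulates |metric|^p over set members (normalized), P_miss
    accumulates uniformly over non-members; ES is the running deviation
    P_hit - P_miss at its largest absolute excursion (signed).  Returns
    (ES, extremum position).
    """
    n = len(ranked_genes)
    n_hit = int(member_mask.sum())
    if n_hit == 0 or n_hit == n:
        raise DataError("gene set is empty or spans the whole universe")
    w = np.abs(metrics) ** p
    hit_w = np.where(member_mask, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all member metrics are zero: fall back to unweighted steps
        hit_w = member_mask.astype(float)
        total = hit_w.sum()
    p_hit = np.cumsum(hit_w) / total
    p_miss = np.cumsum(~member_mask) / (n - n_hit)
    dev = p_hit - p_miss
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i]), i


def gsea_preranked(
    ranked: RankedList,
    sets: dict[str, list[str]],
    p: float = 1.0,
    n_perm: int = 1000,
    min_size: int = 10,
    max_size: int = 500,
    seed: int = 0,
) -> EnrichmentResult:
    """Preranked GSEA with a gene-label permutation null.

    For each set (restricted to the ranked universe, sizes within
    [min_size, max_size]) the null is built by re-drawing the member labels
    uniformly over the ranking ``n_perm`` times.  NES divides ES by the mean
    |null ES| of matching sign; the p-value counts sign-matched null scores
    at least as extreme, with add-one smoothing.  BH adjustment is applied
    across all scored sets.  The leading edge is the set members at or
    before the ES extremum (after it for negative ES).
    """
    genes = ranked.genes
    if not genes:
        raise DataError("empty ranked universe")
    metrics = ranked.metric.to_numpy(dtype=float)
    index = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)
    n = len(genes)

    rows, skipped = [], []
    leading: dict[str, list[str]] = {}
    for name, members in sets.items():
        in_univ = [g for g in members if g in index]
        if not min_size <= len(in_univ) <= max_size:
            skipped.append(name)
            continue
        mask = np.zeros(n, dtype=bool)
        mask[[index[g] for g in in_univ]] = True
        es, pos = enrichment_score(genes, metrics, mask, p=p)

        null = np.empty(n_perm)
        k = len(in_univ)
        for b in range(n_perm):
            pm = np.zeros(n, dtype=bool)
            pm[rng.choice(n, size=k, replace=False)] = True
            null[b], _ = enrichment_score(genes, metrics, pm, p=p)
        same_sign = null >= 0 if es >= 0 else null < 0
        n_sign = int(same_sign.sum())
        mean_mag = np.abs(null[same_sign]).mean() if n_sign else np.nan
        nes = es / mean_mag if n_sign and mean_mag > 0 else np.nan
        extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
        pval = (1.0 + extreme) / (1.0 + n_sign) if n_sign else 1.0

        if es >= 0:
            core = [g for g in genes[: pos + 1] if mask[index[g]]]
        else:
            core = [g for g in genes[pos:] if mask[index[g]]]
        leading[name] = core
        rows.append(
            {"set": name, "size": k, "ES": es, "NES": nes, "pval": min(pval, 1.0)}
        )

    if not rows:
        raise DataError("no gene set fell within the size bounds of the ranked universe")
    table = pd.DataFrame(rows).set_index("set")
    table["padj"] = bh_adjust(table["pval"].to_numpy())
    table["leading_edge"] = [",".join(leading[s]) for s in table.index]
    return EnrichmentResult(table=table, skipped=skipped)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    pvals = np.asarray(pvals, dtype=float)
    if ((pvals < 0) | (pvals > 1)).any() or np.isnan(pvals).any():
        raise DataError("p-values must lie in [0, 1]")
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def overlap_percentage(count: int, total: int) -> float:
    """Percentage of a total, rounded to one decimal as printed in overlap tables."""
    if total <= 0:
        raise DataError("total must be positive")
    return round(100.0 * count / total, 1)


def overlap_analysis(
    single_results: dict[str, EnrichmentResult],
    merged_result: EnrichmentResult,
    sig_cutoff: float = 0.1,
    loose_cutoff: float = 0.9,
) -> OverlapTable:
    """Single-vs-merged significance overlap per study.

    Per study: sets significant only there, sets shared with the merged
    analysis (both at ``sig_cutoff``), the merged sets also present in the
    study's result at the loose cutoff, and the merged-only complement.
    Percentages are of the single-study significant total, one decimal.
    """
    if merged_result is None:
        raise DataError("merged result is required")
    merged_sig = merged_result.significant(sig_cutoff)
    rows = []
    for study, res in sorted(single_results.items()):
        single_sig = res.significant(sig_cutoff)
        shared = single_sig & merged_sig
        single_only = single_sig - merged_sig
        loose = res.significant(loose_cutoff)
        n_single = len(single_sig)
        rows.append(
            {
                "study": study,
                "single_total": n_single,
                "single_only": len(single_only),
                "single_only_pct": overlap_percentage(len(single_only), n_single) if n_single else float("nan"),
                "shared": len(shared),
                "shared_pct": overlap_percentage(len(shared), n_single) if n_single else float("nan"),
                "merged_overlap_total": len(merged_sig & loose),
                "merged_only": len(merged_sig - shared),
            }
        )
    return OverlapTable(table=pd.DataFrame(rows).set_index("study"))
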