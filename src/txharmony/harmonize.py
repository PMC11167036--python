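"""Per-study QC, filtering, normalization and merging.

The harmonization contract: every transform with estimable parameters
(median-of-ratios reference, ``log2(x+1)`` z-score moments, the coverage
threshold) is fit on training samples only, per study, and then applied to
all samples of that study, before studies are concatenated into one
samples x genes matrix with a one-hot spaceflown target vector.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from txharmony.errors import ConfigurationError, DataError
from txharmony.simulate import StudyBundle

__all__ = [
    "OutlierReport",
    "GeneFilterMask",
    "SizeFactors",
    "StandardizationParams",
    "HarmonizedMatrix",
    "PCAReport",
    "pooled_raw_pc_scores",
    "flag_outliers",
    "filter_genes",
    "size_factors_mor",
    "apply_size_factors",
    "standardize_study",
    "merge_studies",
    "pca_diagnostics",
]


@dataclass
class OutlierReport:
    """Per-sample exclusion flags for one study."""

    flags: pd.DataFrame  # columns: pca_outlier, rin_flag, excluded, reason
    global_rin_mean: float

    @property
    def excluded_samples(self) -> list[str]:
        return list(self.flags.index[self.flags["excluded"]])


@dataclass
class GeneFilterMask:
    kept: list[str]
    removed: dict[str, str]  # gene -> reason in {pseudogene, low_coverage}
    coverage: pd.Series  # per non-pseudogene gene, fraction of samples with count >= min_count
    threshold: float


@dataclass
class SizeFactors:
    factors: pd.Series  # per-sample positive size factors
    reference_genes: list[str]  # genes nonzero in all reference samples


@dataclass
class StandardizationParams:
    """Per-gene log2-scale moments estimated from one study's training samples."""

    mu: pd.Series
    sigma: pd.Series
    train_samples: list[str]

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.mu.to_json().encode())
        h.update(self.sigma.to_json().encode())
        h.update(json.dumps(self.train_samples).encode())
        return h.hexdigest()


@dataclass
class HarmonizedMatrix:
    """Merged samples x genes standardized matrix with one-hot target.

    ``y`` encodes spaceflown = 1, ground = 0; ``provenance`` records each
    transform applied (name + parameter hash) so a transform cannot be
    applied twice.
    """

    X: pd.DataFrame
    y: np.ndarray
    sample_meta: pd.DataFrame
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.y) != self.X.shape[0]:
            raise DataError("target vector length differs from sample count")
        if self.X.isna().any().any():
            raise DataError("harmonized matrix contains missing values")


@dataclass
class PCAReport:
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame  # samples x PCs
    silhouettes: dict[str, float]  # label name -> silhouette on PC1-2


def _pooled_counts(bundles: list[StudyBundle]) -> pd.DataFrame:
    genes = bundles[0].gene_ids
    for b in bundles[1:]:
        if b.gene_ids != genes:
            raise DataError("bundles do not share an identical gene universe/order")
    return pd.concat([b.counts for b in bundles], axis=1)


def pooled_raw_pc_scores(bundles: list[StudyBundle], n_components: int = 2) -> pd.DataFrame:
    """PC1/PC2 scores of all samples on pooled unnormalized counts."""
    pooled = _pooled_counts(bundles)
    X = pooled.T.to_numpy(dtype=float)
    pca = PCA(n_components=min(n_components, min(X.shape) - 1))
    scores = pca.fit_transform(X - X.mean(axis=0))
    cols = [f"PC{i+1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=pooled.columns, columns=cols)


def flag_outliers(
    bundle: StudyBundle,
    raw_pc_scores: pd.DataFrame,
    pca_sd_mult: float = 3.0,
    rin_sd_mult: float = 2.0,
    global_rin_mean: float | None = None,
) -> OutlierReport:
    """Flag samples far from their study's PC1-2 centroid or with low RIN.

    A sample is a PCA outlier when its distance from the study centroid in
    (PC1, PC2) exceeds ``pca_sd_mult`` times the SD of those distances; its
    RIN is flagged when below the global cohort mean AND more than
    ``rin_sd_mult`` SDs below the study mean.  Either flag excludes.
    """
    meta = bundle.metadata
    pcs = raw_pc_scores.loc[meta.index, ["PC1", "PC2"]].to_numpy()
    n = len(meta)

    pca_flags = np.zeros(n, dtype=bool)
    if n >= 3:
        centroid = pcs.mean(axis=0)
        dist = np.linalg.norm(pcs - centroid, axis=1)
        sd = dist.std(ddof=1)
        if sd > 0:
            pca_flags = dist > pca_sd_mult * sd
    else:
        warnings.warn(
            f"study {bundle.study_id}: fewer than 3 samples, PCA outlier rule skipped",
            stacklevel=2,
        )

    rin_flags = np.zeros(n, dtype=bool)
    if "rin" in meta.columns and meta["rin"].notna().all():
        rin = meta["rin"].to_numpy(dtype=float)
        mu = float(global_rin_mean) if global_rin_mean is not None else float(rin.mean())
        study_mu, study_sd = rin.mean(), rin.std(ddof=1)
        if study_sd > 0:
            rin_flags = (rin < mu) & (rin < study_mu - rin_sd_mult * study_sd)
    else:
        mu = float(global_rin_mean) if global_rin_mean is not None else float("nan")

    excluded = pca_flags | rin_flags
    reason = np.where(
        pca_flags & rin_flags,
        "pca_outlier+rin_flag",
        np.where(pca_flags, "pca_outlier", np.where(rin_flags, "rin_flag", "")),
    )
    flags = pd.DataFrame(
        {"pca_outlier": pca_flags, "rin_flag": rin_flags, "excluded": excluded, "reason": reason},
        index=meta.index,
    )
    return OutlierReport(flags=flags, global_rin_mean=mu)


def filter_genes(
    bundles: list[StudyBundle],
    pseudogenes: set[str],
    min_count: int = 5,
    coverage_rule: str = "mean",
    theta: float | None = None,
    samples: list[str] | None = None,
) -> GeneFilterMask:
    """Remove pseudogenes, then low-sample-coverage genes.

    Coverage of a gene is the fraction of pooled samples (optionally
    restricted to ``samples``, e.g. the training side) with count >=
    ``min_count``.  Under the ``"mean"`` rule the keep threshold is the mean
    coverage over genes strictly between 0 and 1 coverage — the fully absent
    and fully covered tails are excluded from the mean, mirroring how a
    tail-removed coverage distribution is summarized.  ``"fixed"`` uses
    ``theta`` directly.
    """
    pooled = _pooled_counts(bundles)
    if samples is not None:
        pooled = pooled[list(samples)]

    removed: dict[str, str] = {g: "pseudogene" for g in pooled.index if g in pseudogenes}
    kept_pool = pooled.drop(index=list(removed))
    if kept_pool.empty:
        raise DataError("no genes left after pseudogene removal")

    coverage = (kept_pool >= min_count).mean(axis=1)
    if coverage_rule == "mean":
        interior = coverage[(coverage > 0) & (coverage < 1)]
        threshold = float(interior.mean()) if len(interior) else 0.0
    elif coverage_rule == "fixed":
        if theta is None or not 0.0 <= theta <= 1.0:
            raise ConfigurationError("fixed coverage rule needs theta in [0, 1]")
        threshold = float(theta)
    else:
        raise ConfigurationError(f"unknown coverage rule: {coverage_rule!r}")

    # zero-coverage genes are always uninformative, even if the threshold
    # degenerates to 0 (no interior coverage values)
    keep_mask = (coverage >= threshold) & (coverage > 0)
    for g in coverage.index[~keep_mask]:
        removed[g] = "low_coverage"
    kept = list(coverage.index[keep_mask])
    if not kept:
        raise DataError("gene universe empty after coverage filtering")
    return GeneFilterMask(kept=kept, removed=removed, coverage=coverage, threshold=threshold)


def size_factors_mor(
    counts: pd.DataFrame, reference_samples: list[str] | None = None
) -> SizeFactors:
    """Median-of-ratios size factors (genes x samples input).

    The pseudo-reference is the per-gene geometric mean over the reference
    samples (all samples by default), restricted to genes nonzero in every
    reference sample; a sample's factor is the median over those genes of
    count / reference.  Passing the training samples as
    ``reference_samples`` keeps test values out of the reference.
    """
    ref = counts[list(reference_samples)] if reference_samples is not None else counts
    nonzero = (ref > 0).all(axis=1)
    if not nonzero.any():
        raise DataError("median-of-ratios undefined: no gene is nonzero in every reference sample")
    ref_genes = list(counts.index[nonzero])
    log_ref = np.log(ref.loc[ref_genes].to_numpy(dtype=float))
    geomean = np.exp(log_ref.mean(axis=1))
    with np.errstate(divide="ignore"):
        ratios = counts.loc[ref_genes].to_numpy(dtype=float) / geomean[:, None]
    factors = np.median(ratios, axis=0)
    if (factors <= 0).any():
        raise DataError("nonpositive size factor encountered")
    return SizeFactors(
        factors=pd.Series(factors, index=counts.columns), reference_genes=ref_genes
    )


def apply_size_factors(counts: pd.DataFrame, sf: SizeFactors) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    if list(sf.factors.index) != list(counts.columns):
        raise DataError("size factors do not match sample columns")
    if (sf.factors <= 0).any():
        raise DataError("nonpositive size factor")
    return counts / sf.factors


def standardize_study(
    normalized: pd.DataFrame,
    train_samples: list[str] | None = None,
    params: StandardizationParams | None = None,
    min_sigma: float = 0.0,
) -> tuple[pd.DataFrame, StandardizationParams]:
    """``log2(x+1)`` then per-gene z-score with training-only moments.

    Either ``train_samples`` (moments estimated there, population SD) or a
    previously fitted ``params`` must be given.  Genes whose training SD is
    ``<= min_sigma`` get sigma set to NaN; callers drop those genes globally
    before merging (see :func:`zero_variance_genes`).
    """
    logx = np.log2(normalized + 1.0)
    if params is None:
        if train_samples is None:
            train_samples = list(normalized.columns)
        if len(train_samples) < 2:
            raise DataError("need at least 2 training samples to standardize")
        train = logx[list(train_samples)]
        mu = train.mean(axis=1)
        sigma = train.std(axis=1, ddof=0)
        sigma = sigma.where(sigma > min_sigma, np.nan)
        params = StandardizationParams(mu=mu, sigma=sigma, train_samples=list(train_samples))
    if params.sigma.notna().sum() == 0:
        raise DataError("all genes have zero training variance")
    Z = logx.sub(params.mu, axis=0).div(params.sigma, axis=0)
    return Z, params


def zero_variance_genes(params_by_study: dict[str, StandardizationParams]) -> set[str]:
    """Genes with zero training variance in any study (dropped globally)."""
    bad: set[str] = set()
    for p in params_by_study.values():
        bad |= set(p.sigma.index[p.sigma.isna()])
    return bad


def merge_studies(
    z_by_study: dict[str, pd.DataFrame],
    meta: pd.DataFrame,
    provenance: list[dict] | None = None,
) -> HarmonizedMatrix:
    """Concatenate per-study Z matrices (genes x samples) into samples x genes.

    Gene lists must be identical and identically ordered; a mismatch is an
    error, never a silent reorder.  The target is one-hot spaceflown = 1.
    """
    study_ids = sorted(z_by_study)
    genes = list(z_by_study[study_ids[0]].index)
    for sid in study_ids[1:]:
        if list(z_by_study[sid].index) != genes:
            raise DataError(f"gene order mismatch between studies (at {sid})")
    X = pd.concat([z_by_study[sid].T for sid in study_ids], axis=0)
    meta = meta.loc[X.index]
    y = (meta["class"] == "spaceflown").to_numpy(dtype=int)
    prov = list(provenance) if provenance else []
    prov.append({"step": "merge_studies", "params": _hash_params({"studies": study_ids})})
    return HarmonizedMatrix(X=X, y=y, sample_meta=meta, provenance=prov)


def _hash_params(params: dict) -> str:
    return hashlib.sha256(json.dumps(params, sort_keys=True, default=str).encode()).hexdigest()[:16]


def record_transform(provenance: list[dict], step: str, params: dict) -> None:
    """Append a transform record; re-applying the same step is rejected."""
    if any(p["step"] == step for p in provenance):
        raise DataError(f"transform {step!r} already applied")
    provenance.append({"step": step, "params": _hash_params(params)})


def pca_diagnostics(
    X: pd.DataFrame, labels: dict[str, pd.Series], n_components: int | None = None
) -> PCAReport:
    """PCA of a samples x genes matrix plus per-label silhouettes on PC1-2.

    Explained-variance fractions cover all principal components (they sum to
    one); silhouettes are computed on the first two PC scores for each label
    vector supplied (e.g. study and class).
    """
    arr = X.to_numpy(dtype=float)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DataError("PCA needs at least 2 samples and 2 genes")
    centered = arr - arr.mean(axis=0)
    if np.allclose(centered, 0):
        raise DataError("constant matrix: PCA undefined")
    max_rank = min(arr.shape[0] - 1, arr.shape[1])
    k = max_rank if n_components is None else min(n_components, max_rank)
    pca = PCA(n_components=max_rank)
    scores = pca.fit_transform(centered)[:, :k]
    evr = pca.explained_variance_ratio_
    cols = [f"PC{i+1}" for i in range(k)]
    score_df = pd.DataFrame(scores, index=X.index, columns=cols)

    sils: dict[str, float] = {}
    pc12 = scores[:, : min(2, k)]
    for name, lab in labels.items():
        lab = lab.loc[X.index]
        if lab.nunique() >= 2 and len(lab) > lab.nunique():
            sils[name] = float(silhouette_score(pc12, lab.to_numpy()))
        else:
            sils[name] = float("nan")
    return PCAReport(explained_variance_ratio=evr, scores=score_df, silhouettes=sils)
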