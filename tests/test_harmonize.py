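"""Filtering, normalization, standardization and merging against hand oracles."""

import numpy as np
import pandas as pd
import pytest

from txharmony.errors import ConfigurationError, DataError
from txharmony.harmonize import (
    apply_size_factors,
    filter_genes,
    flag_outliers,
    merge_studies,
    pca_diagnostics,
    pooled_raw_pc_scores,
    record_transform,
    size_factors_mor,
    standardize_study,
    zero_variance_genes,
)
from txharmony.simulate import StudyBundle


def _bundle(counts: dict, classes: list[str], study: str = "ST", rin=None) -> StudyBundle:
    df = pd.DataFrame(counts).T  # rows genes, columns samples
    df.columns = [f"{study}_s{i}" for i in range(df.shape[1])]
    n = df.shape[1]
    meta = pd.DataFrame(
        {
            "study_id": study,
            "mission": study,
            "class": classes,
            "strain": "C57BL/6J",
            "age_weeks": 16,
            "sex": "F",
            "library_prep": "ribo_depletion",
            "rin": rin if rin is not None else [9.0] * n,
        },
        index=pd.Index(df.columns, name="sample_id"),
    )
    return StudyBundle(study, df.astype("int64"), meta)


# ---------------------------------------------------------------- size factors


def test_mor_size_factors_match_geometric_mean_oracle():
    # genes g1..g3 with S1=(2,4,8), S2=(4,8,16): geomeans (2.83, 5.66, 11.31),
    # per-gene ratios are constant per sample so medians are 1/sqrt(2), sqrt(2)
    counts = pd.DataFrame({"S1": [2, 4, 8], "S2": [4, 8, 16]}, index=["g1", "g2", "g3"])
    sf = size_factors_mor(counts)
    np.testing.assert_allclose(sf.factors.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)], atol=1e-4)
    assert sf.reference_genes == ["g1", "g2", "g3"]


def test_mor_identical_samples_and_scaling_property():
    counts = pd.DataFrame({"S1": [3, 7, 11], "S2": [3, 7, 11]}, index=["g1", "g2", "g3"])
    sf = size_factors_mor(counts)
    assert sf.factors.nunique() == 1
    doubled = counts.copy()
    doubled["S2"] = counts["S2"] * 2
    sf2 = size_factors_mor(doubled)
    # doubling one sample's library scales only that sample's factor
    ratio = sf2.factors / sf.factors
    assert ratio["S2"] / ratio["S1"] == pytest.approx(2.0)


def test_mor_requires_an_all_nonzero_gene():
    counts = pd.DataFrame({"S1": [0, 5], "S2": [5, 0]}, index=["g1", "g2"])
    with pytest.raises(DataError, match="nonzero in every reference sample"):
        size_factors_mor(counts)


def test_apply_size_factors_division_and_depth_invariance():
    counts = pd.DataFrame({"S1": [2, 4, 8], "S2": [4, 8, 16]}, index=["g1", "g2", "g3"])
    sf = size_factors_mor(counts)
    norm = apply_size_factors(counts, sf)
    np.testing.assert_allclose(norm["S1"].to_numpy(), [2.83, 5.66, 11.31], atol=0.01)
    # per-sample depth factors with geometric mean 1 (here 2 and 1/2) change the
    # size factors but leave the normalized matrix bit-identical: MoR factors are
    # relative to the study's own geometric-mean reference
    rng = np.random.default_rng(4)
    base = pd.DataFrame(2 * rng.integers(1, 50, (6, 2)), index=[f"g{i}" for i in range(6)],
                        columns=["S1", "S2"])
    scaled = base.copy()
    scaled["S1"] = base["S1"] * 2
    scaled["S2"] = base["S2"] // 2
    n1 = apply_size_factors(base, size_factors_mor(base))
    n2 = apply_size_factors(scaled, size_factors_mor(scaled))
    np.testing.assert_allclose(n1.to_numpy(), n2.to_numpy(), rtol=1e-12)


# -------------------------------------------------------------- gene filtering


def test_coverage_mean_rule_hand_computation():
    # coverages {0, 1, 0.1, 0.3} over 10 samples; interior mean = 0.2 keeps {1.0, 0.3}
    n = 10
    rows = {
        "g_zero": [0] * n,
        "g_full": [9] * n,
        "g_low": [9] + [0] * 9,
        "g_mid": [9, 9, 9] + [0] * 7,
    }
    b = _bundle(rows, ["spaceflown"] * 5 + ["ground"] * 5)
    mask = filter_genes([b], pseudogenes=set(), min_count=5)
    assert mask.threshold == pytest.approx(0.2)
    assert sorted(mask.kept) == ["g_full", "g_mid"]
    assert mask.removed == {"g_zero": "low_coverage", "g_low": "low_coverage"}


def test_pseudogenes_removed_before_coverage():
    n = 6
    rows = {"g1": [9] * n, "pg1": [9] * n, "g2": [0] * n}
    b = _bundle(rows, ["spaceflown"] * 3 + ["ground"] * 3)
    mask = filter_genes([b], pseudogenes={"pg1"}, min_count=5)
    assert mask.removed["pg1"] == "pseudogene"
    assert "pg1" not in mask.coverage.index
    assert mask.kept == ["g1"]


def test_fixed_coverage_rule_and_validation():
    n = 4
    rows = {"g1": [9] * n, "g2": [9, 0, 0, 0]}
    b = _bundle(rows, ["spaceflown"] * 2 + ["ground"] * 2)
    mask = filter_genes([b], pseudogenes=set(), coverage_rule="fixed", theta=0.5)
    assert mask.kept == ["g1"]
    with pytest.raises(ConfigurationError):
        filter_genes([b], pseudogenes=set(), coverage_rule="fixed", theta=1.7)


# ------------------------------------------------------------- standardization


def test_log2_and_zscore_definitions():
    norm = pd.DataFrame(
        {"s1": [0.0, 1.0, 3.0], "s2": [1.0, 3.0, 0.0], "s3": [3.0, 0.0, 1.0]},
        index=["g1", "g2", "g3"],
    )
    Z, params = standardize_study(norm)
    # log2(x+1): 0 -> 0, 1 -> 1, 3 -> 2
    logx = np.log2(norm + 1)
    assert set(np.round(logx.to_numpy().ravel(), 12)) == {0.0, 1.0, 2.0}
    np.testing.assert_allclose(Z.mean(axis=1), 0.0, atol=1e-10)
    np.testing.assert_allclose(Z.std(axis=1, ddof=0), 1.0, atol=1e-10)


def test_train_only_params_reused_on_test_samples():
    rng = np.random.default_rng(1)
    norm = pd.DataFrame(rng.gamma(2, 10, (5, 8)), index=[f"g{i}" for i in range(5)],
                        columns=[f"s{i}" for i in range(8)])
    train = [f"s{i}" for i in range(6)]
    Z, params = standardize_study(norm, train_samples=train)
    np.testing.assert_allclose(Z[train].mean(axis=1), 0.0, atol=1e-10)
    # refitting with stored params reproduces the transform bit-for-bit
    Z2, _ = standardize_study(norm, params=params)
    pd.testing.assert_frame_equal(Z, Z2)


def test_zero_variance_gene_dropped_globally():
    normA = pd.DataFrame({"s1": [5.0, 1.0], "s2": [5.0, 2.0]}, index=["g1", "g2"])
    normB = pd.DataFrame({"t1": [4.0, 1.0], "t2": [6.0, 3.0]}, index=["g1", "g2"])
    _, pA = standardize_study(normA)
    _, pB = standardize_study(normB)
    # g1 constant in study A only -> dropped from every study
    assert zero_variance_genes({"A": pA, "B": pB}) == {"g1"}


# ---------------------------------------------------------------------- merge


def test_merge_concatenates_and_encodes_target():
    z1 = pd.DataFrame(np.ones((2, 3)), index=["g1", "g2"], columns=["a1", "a2", "a3"])
    z2 = pd.DataFrame(np.zeros((2, 4)), index=["g1", "g2"], columns=["b1", "b2", "b3", "b4"])
    meta = pd.DataFrame(
        {"class": ["spaceflown", "ground", "spaceflown", "ground", "ground", "spaceflown", "ground"]},
        index=["a1", "a2", "a3", "b1", "b2", "b3", "b4"],
    )
    hm = merge_studies({"A": z1, "B": z2}, meta)
    assert hm.X.shape == (7, 2)
    assert len(hm.y) == 7
    assert hm.y.sum() == (meta["class"] == "spaceflown").sum()
    # input order invariance up to row permutation
    hm2 = merge_studies({"B": z2, "A": z1}, meta)
    pd.testing.assert_frame_equal(hm.X.sort_index(), hm2.X.sort_index())


def test_merge_rejects_gene_order_mismatch():
    z1 = pd.DataFrame(np.ones((2, 2)), index=["g1", "g2"], columns=["a1", "a2"])
    z2 = pd.DataFrame(np.ones((2, 2)), index=["g2", "g1"], columns=["b1", "b2"])
    meta = pd.DataFrame({"class": ["ground"] * 4}, index=["a1", "a2", "b1", "b2"])
    with pytest.raises(DataError, match="gene order mismatch"):
        merge_studies({"A": z1, "B": z2}, meta)


def test_provenance_rejects_reapplied_transform():
    prov: list[dict] = []
    record_transform(prov, "mor_log2_zscore", {})
    with pytest.raises(DataError, match="already applied"):
        record_transform(prov, "mor_log2_zscore", {})


# ------------------------------------------------------------------- outliers


def test_no_outliers_for_tight_cluster():
    n = 8
    b = _bundle({f"g{i}": list(range(10, 10 + n)) for i in range(4)},
                ["spaceflown"] * 4 + ["ground"] * 4, rin=[9.0] * n)
    pcs = pd.DataFrame({"PC1": np.zeros(n), "PC2": np.zeros(n)}, index=b.metadata.index)
    rep = flag_outliers(b, pcs, global_rin_mean=8.02)
    assert rep.excluded_samples == []


def test_displaced_sample_flagged_as_pca_outlier():
    n = 8
    b = _bundle({f"g{i}": list(range(10, 10 + n)) for i in range(4)},
                ["spaceflown"] * 4 + ["ground"] * 4)
    rng = np.random.default_rng(0)
    pcs = pd.DataFrame(
        {"PC1": rng.normal(0, 1, n), "PC2": rng.normal(0, 1, n)}, index=b.metadata.index
    )
    pcs.iloc[0] = [40.0, 40.0]  # ~10+ SD from the centroid
    rep = flag_outliers(b, pcs)
    assert rep.flags.iloc[0]["pca_outlier"]
    assert rep.flags.iloc[0]["reason"] == "pca_outlier"
    assert rep.excluded_samples == [b.metadata.index[0]]


def test_global_rin_mean_is_arithmetic_mean():
    n = 3
    b = _bundle({f"g{i}": [10] * n for i in range(4)},
                ["spaceflown", "ground", "ground"], rin=[8.0, 8.0, 8.06])
    pcs = pd.DataFrame({"PC1": np.zeros(n), "PC2": np.zeros(n)}, index=b.metadata.index)
    rep = flag_outliers(b, pcs)
    assert rep.global_rin_mean == pytest.approx(8.02)


def test_rin_rule_needs_both_conditions():
    # below the study tail but above the global mean -> not flagged
    n = 6
    rin = [9.5, 9.5, 9.5, 9.5, 9.5, 9.3]
    b = _bundle({f"g{i}": [10] * n for i in range(4)},
                ["spaceflown"] * 3 + ["ground"] * 3, rin=rin)
    pcs = pd.DataFrame({"PC1": np.zeros(n), "PC2": np.zeros(n)}, index=b.metadata.index)
    rep = flag_outliers(b, pcs, global_rin_mean=8.02)
    assert not rep.flags["rin_flag"].any()
    # same shape but shifted below the global mean -> the deviant sample is flagged
    rin2 = [8.0, 8.0, 8.0, 8.0, 8.0, 7.0]
    b2 = _bundle({f"g{i}": [10] * n for i in range(4)},
                 ["spaceflown"] * 3 + ["ground"] * 3, rin=rin2)
    rep2 = flag_outliers(b2, pcs, global_rin_mean=8.02)
    assert list(rep2.flags["rin_flag"]) == [False] * 5 + [True]


def test_tiny_study_skips_pca_rule_with_warning():
    b = _bundle({"g1": [10, 12], "g2": [3, 4]}, ["spaceflown", "ground"])
    pcs = pd.DataFrame({"PC1": [0.0, 99.0], "PC2": [0.0, 99.0]}, index=b.metadata.index)
    with pytest.warns(UserWarning, match="fewer than 3 samples"):
        rep = flag_outliers(b, pcs)
    assert not rep.flags["pca_outlier"].any()


# ------------------------------------------------------------------------ PCA


def test_pca_collinear_data_has_pc1_fraction_one():
    X = pd.DataFrame({"g1": [0.0, 1, 2, 3], "g2": [0.0, 2, 4, 6]},
                     index=["s1", "s2", "s3", "s4"])
    rep = pca_diagnostics(X, {})
    assert rep.explained_variance_ratio[0] == pytest.approx(1.0)


def test_pca_fractions_match_covariance_eigenvalues():
    rng = np.random.default_rng(2)
    X = pd.DataFrame(rng.normal(0, 1, (12, 5)), columns=[f"g{i}" for i in range(5)])
    rep = pca_diagnostics(X, {})
    cov = np.cov(X.to_numpy().T, ddof=1)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    np.testing.assert_allclose(rep.explained_variance_ratio[: len(eig)], eig / eig.sum(), atol=1e-10)
    assert np.all(np.diff(rep.explained_variance_ratio) <= 1e-12)
    assert rep.explained_variance_ratio.sum() == pytest.approx(1.0)


def test_pca_rejects_constant_matrix():
    X = pd.DataFrame(np.ones((4, 3)), columns=["g1", "g2", "g3"])
    with pytest.raises(DataError, match="constant matrix"):
        pca_diagnostics(X, {})


def test_per_sample_depth_shift_is_removed_by_mor_log_z(tiny_cohort):
    """Two studies differing only by per-sample depth factors (geometric mean 1)
    give identical Z matrices after MoR + log2 + z-score."""
    bundles, _ = tiny_cohort
    counts = (bundles[0].counts * 2).astype("int64")  # even counts so halving stays integral
    n = counts.shape[1]
    scale = np.array([2.0 if j < n // 2 else 0.5 for j in range(n)])
    if n % 2:  # keep the geometric mean of the factors exactly 1
        scale[-1] = 1.0
    scaled = counts.copy()
    for j, c in enumerate(scale):
        col = counts.iloc[:, j]
        scaled.iloc[:, j] = (col * 2 if c == 2.0 else col // 2 if c == 0.5 else col)
    Z1, _ = standardize_study(apply_size_factors(counts, size_factors_mor(counts)))
    Z2, _ = standardize_study(apply_size_factors(scaled, size_factors_mor(scaled)))
    np.testing.assert_allclose(Z1.to_numpy(), Z2.to_numpy(), atol=1e-8, equal_nan=True)
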