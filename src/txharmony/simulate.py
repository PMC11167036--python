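"""Synthetic multi-study RNA-seq cohorts with planted structure.

The generator emulates the statistical situation the harmonization pipeline
is built for: several small rodent missions (6-59 animals each, spaceflown
vs. ground control arms) profiled on heterogeneous platforms, where
study-of-origin effects dominate the raw-count variance and a weak shared
spaceflight signal is spread over a modest set of genes.  Counts are drawn
from a negative binomial whose log2-mean is

    baseline_g + study_offset_{s,g} + class_j * log2fc_g + w_rho * f_{b(g),j}

scaled by a per-sample library-size multiplier times a per-study depth
multiplier (protocols differ between missions, so depth is itself a batch
variable).  ``study_offset`` gives each study its own per-gene batch
signature; ``f`` is a per-sample latent factor
shared by all genes of a correlated block, giving tunable within-block
Pearson correlation; ``log2fc`` is the planted signed spaceflight effect on
signal genes.  A fraction of genes is labelled pseudogene, and low baseline
means produce the low-count sparsity real bulk data show.

One (anchor, regulator) gene pair is planted inside the first correlated
block so correlation-distance expansion can be calibrated against a known
positively co-regulated pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from txharmony import io
from txharmony.errors import ConfigurationError

__all__ = [
    "StudyTemplate",
    "DEFAULT_COHORT",
    "SimConfig",
    "StudyBundle",
    "GroundTruth",
    "generate_multistudy_counts",
    "generate_gene_annotation",
    "expected_signal",
]


@dataclass(frozen=True)
class StudyTemplate:
    """Post-QC shape and covariates of one study's cohort."""

    study_id: str
    mission: str
    n_spaceflown: int
    n_ground: int
    strain: str
    ages_weeks: tuple[int, ...]  # cycled over samples, so mixed-age cohorts are possible
    sex: str
    library_prep: str

    @property
    def n_samples(self) -> int:
        return self.n_spaceflown + self.n_ground


# Default six-study rodent-mission cohort template: sample sizes 6/10/8/18/36/59
# (137 animals total), mixed strains, ages 10-32 weeks, one male cohort, and
# one mRNA-enrichment library against five ribo-depletion libraries.
DEFAULT_COHORT: tuple[StudyTemplate, ...] = (
    StudyTemplate("OSD-47", "RR1-CASIS", 3, 3, "C57BL/6NTac", (32,), "F", "mRNA_enrichment"),
    StudyTemplate("OSD-168", "RR1-NASA", 5, 5, "C57BL/6J", (16,), "F", "ribo_depletion"),
    StudyTemplate("OSD-168b", "RR3", 4, 4, "BALB/c", (12,), "F", "ribo_depletion"),
    StudyTemplate("OSD-242", "RR9", 5, 13, "C57BL/6J", (10,), "M", "ribo_depletion"),
    StudyTemplate("OSD-245", "RR6", 17, 19, "C57BL/6NTac", (32,), "F", "ribo_depletion"),
    StudyTemplate("OSD-379", "RR8", 27, 32, "BALB/cAnNTac", (10, 32), "F", "ribo_depletion"),
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the qualitative regime of the real missions: study
    batch effects (``study_effect_sd`` per-gene offsets plus ~20x between-study
    depth tiers) dominate the raw variance, the planted spaceflight effect is
    one log2 fold-change on 60 genes, the negative-binomial dispersion is the
    0.1 typical of bulk liver RNA-seq, and the gene universe is a desk-scale
    2000 genes.
    """

    studies: tuple[StudyTemplate, ...] = DEFAULT_COHORT
    n_genes: int = 2000
    n_signal_genes: int = 60
    signal_log2fc: float = 1.0
    frac_signal_up: float = 0.5
    study_effect_sd: float = 1.2
    baseline_log2_mean_range: tuple[float, float] = (0.0, 9.0)
    signal_baseline_min: float = 3.0
    nb_dispersion: float = 0.1
    n_correlated_blocks: int = 10
    block_size: int = 20
    block_rho: float = 0.7
    pseudogene_fraction: float = 0.15
    libsize_sd: float = 0.3
    study_libsize_sd: float = 1.0  # between-study sequencing-depth spread (log scale)
    rin_mean: float = 8.0
    rin_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be positive")
        if not self.studies:
            raise ConfigurationError("at least one study is required")
        for st in self.studies:
            if st.n_spaceflown < 1 or st.n_ground < 1:
                raise ConfigurationError(f"study {st.study_id}: sample sizes must be >= 1")
        if self.block_size * self.n_correlated_blocks > self.n_genes:
            raise ConfigurationError("correlated blocks exceed the gene universe")
        if not 0.0 <= self.block_rho < 1.0:
            raise ConfigurationError("block_rho must be in [0, 1)")
        if not 0.0 <= self.pseudogene_fraction <= 1.0:
            raise ConfigurationError("pseudogene_fraction must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        n_special = self.block_size * self.n_correlated_blocks + self.n_signal_genes
        if n_special + math.ceil(self.pseudogene_fraction * self.n_genes) > self.n_genes:
            raise ConfigurationError(
                "pseudogenes, blocks and signal genes together exceed the gene universe"
            )


@dataclass
class StudyBundle:
    """One study's raw counts (genes x samples) plus per-sample metadata."""

    study_id: str
    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.shape[1] != len(self.metadata):
            raise ConfigurationError(
                f"study {self.study_id}: {self.counts.shape[1]} count columns "
                f"vs {len(self.metadata)} metadata rows"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class GroundTruth:
    """What was planted: signal genes and effects, blocks, pseudogenes."""

    genes: tuple[str, ...]
    signal_log2fc: dict[str, float]  # gene -> signed planted effect
    block_assignments: dict[str, int]  # block member gene -> block index
    pseudogene_ids: set[str]
    anchor_gene: str
    regulator_gene: str

    @property
    def signal_gene_ids(self) -> set[str]:
        return set(self.signal_log2fc)

    def to_json(self, path: str | Path) -> None:
        io.write_json(
            {
                "genes": list(self.genes),
                "signal_log2fc": self.signal_log2fc,
                "block_assignments": self.block_assignments,
                "pseudogene_ids": sorted(self.pseudogene_ids),
                "anchor_gene": self.anchor_gene,
                "regulator_gene": self.regulator_gene,
            },
            path,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = io.read_json(path)
        return cls(
            genes=tuple(d["genes"]),
            signal_log2fc=d["signal_log2fc"],
            block_assignments={g: int(b) for g, b in d["block_assignments"].items()},
            pseudogene_ids=set(d["pseudogene_ids"]),
            anchor_gene=d["anchor_gene"],
            regulator_gene=d["regulator_gene"],
        )


def _gene_ids(n: int) -> list[str]:
    # ENSEMBL-style fixed-width IDs so lexicographic and numeric order agree
    return [f"ENSMUSG{i:011d}" for i in range(1, n + 1)]


def generate_multistudy_counts(config: SimConfig) -> tuple[list[StudyBundle], GroundTruth]:
    """Draw the synthetic cohort; same config + seed gives identical output.

    Returns one :class:`StudyBundle` per study template (shared gene IDs,
    identical order) and the :class:`GroundTruth` of planted structure.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    n_genes = config.n_genes

    # Partition the universe: blocks first, then signal genes, then
    # pseudogenes from the remainder (signal genes are never pseudogenes and
    # never block members, keeping planted roles disjoint).
    perm = rng.permutation(n_genes)
    n_block = config.block_size * config.n_correlated_blocks
    block_idx = perm[:n_block]
    signal_idx = perm[n_block : n_block + config.n_signal_genes]
    n_pseudo = int(round(config.pseudogene_fraction * n_genes))
    pseudo_pool = perm[n_block + config.n_signal_genes :]
    pseudo_idx = pseudo_pool[:n_pseudo]

    block_starts = range(0, n_block, config.block_size) if config.block_size > 0 else range(0)
    block_assignments = {
        genes[g]: b
        for b, start in enumerate(block_starts)
        for g in block_idx[start : start + config.block_size]
    }
    pseudogene_ids = {genes[g] for g in pseudo_idx}

    # Planted signed effects: a deterministic up/down split of the magnitude.
    n_up = int(round(config.frac_signal_up * config.n_signal_genes))
    signs = np.array([1.0] * n_up + [-1.0] * (config.n_signal_genes - n_up))
    log2fc = np.zeros(n_genes)
    log2fc[signal_idx] = signs * config.signal_log2fc
    signal_log2fc = {genes[g]: float(log2fc[g]) for g in signal_idx}

    # Anchor/regulator pair: first two members of block 0.
    first_block = sorted(g for g, b in block_assignments.items() if b == 0)
    anchor_gene, regulator_gene = (first_block[0], first_block[1]) if len(first_block) >= 2 else (genes[0], genes[0])

    lo, hi = config.baseline_log2_mean_range
    baseline = rng.uniform(lo, hi, size=n_genes)
    # keep signal genes expressed enough to survive coverage filtering
    low_signal = signal_idx[baseline[signal_idx] < config.signal_baseline_min]
    baseline[low_signal] = rng.uniform(config.signal_baseline_min, hi, size=low_signal.size)

    rho = config.block_rho
    w_block = math.sqrt(rho / (1.0 - rho)) if rho > 0 else 0.0
    block_of_gene = np.full(n_genes, -1)
    for b, start in enumerate(block_starts):
        block_of_gene[block_idx[start : start + config.block_size]] = b

    # Distinct per-study sequencing depths: archives pool labs and protocols
    # whose depths differ systematically, so depth tiers are spread evenly
    # (with jitter) rather than drawn iid, which could collide.
    n_studies = len(config.studies)
    if n_studies > 1:
        tiers = np.linspace(-1.5, 1.5, n_studies)
    else:
        tiers = np.zeros(1)
    depth_tiers = np.exp(config.study_libsize_sd * tiers[rng.permutation(n_studies)])

    bundles: list[StudyBundle] = []
    for s_idx, st in enumerate(config.studies):
        n = st.n_samples
        study_offset = rng.normal(0.0, config.study_effect_sd, size=n_genes)
        # per-study depth tier (library prep / protocol) on top of
        # per-sample library-size noise
        libsize = depth_tiers[s_idx] * rng.lognormal(0.0, config.libsize_sd, size=n)
        y = np.array([1] * st.n_spaceflown + [0] * st.n_ground)
        factors = rng.standard_normal((config.n_correlated_blocks, n)) if n_block else np.zeros((0, n))

        log2mu = (
            baseline[:, None]
            + study_offset[:, None]
            + np.outer(log2fc, y)
        )
        in_block = block_of_gene >= 0
        if n_block:
            log2mu[in_block] += w_block * factors[block_of_gene[in_block]]
        mu = np.exp2(log2mu) * libsize[None, :]

        if config.nb_dispersion <= 1e-8:
            counts = rng.poisson(mu)
        else:
            size = 1.0 / config.nb_dispersion
            p = size / (size + mu)
            counts = rng.negative_binomial(size, p)

        sample_ids = [f"{st.study_id}_S{j+1:02d}" for j in range(n)]
        ages = [st.ages_weeks[j % len(st.ages_weeks)] for j in range(n)]
        rin = np.clip(rng.normal(config.rin_mean, config.rin_sd, size=n), 1.0, 10.0)
        meta = pd.DataFrame(
            {
                "study_id": st.study_id,
                "mission": st.mission,
                "class": np.where(y == 1, "spaceflown", "ground"),
                "strain": st.strain,
                "age_weeks": ages,
                "sex": st.sex,
                "library_prep": st.library_prep,
                "rin": np.round(rin, 2),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        counts_df = pd.DataFrame(
            counts.astype("int64"), index=pd.Index(genes, name="gene_id"), columns=sample_ids
        )
        bundles.append(StudyBundle(st.study_id, counts_df, meta))

    truth = GroundTruth(
        genes=tuple(genes),
        signal_log2fc=signal_log2fc,
        block_assignments=block_assignments,
        pseudogene_ids=pseudogene_ids,
        anchor_gene=anchor_gene,
        regulator_gene=regulator_gene,
    )
    return bundles, truth


def generate_gene_annotation(
    truth: GroundTruth,
    sets_per_signal: int = 5,
    set_size: int = 20,
    seed: int = 0,
) -> tuple[set[str], dict[str, list[str]]]:
    """Build annotation inputs from the ground truth.

    Returns the pseudogene ID set (exactly ``truth.pseudogene_ids``) and a
    GMT-style collection: "signal_up"/"signal_down" sets chunked from the
    planted genes, plus ``sets_per_signal`` size-matched null sets of random
    non-signal genes per signal set.
    """
    if sets_per_signal < 1:
        raise ConfigurationError("sets_per_signal must be >= 1")
    rng = np.random.default_rng(seed)
    up = sorted(g for g, fc in truth.signal_log2fc.items() if fc > 0)
    down = sorted(g for g, fc in truth.signal_log2fc.items() if fc < 0)
    background = sorted(set(truth.genes) - truth.signal_gene_ids)

    sets: dict[str, list[str]] = {}
    n_null = 0
    for label, members in (("signal_up", up), ("signal_down", down)):
        for i, start in enumerate(range(0, len(members), set_size)):
            chunk = members[start : start + set_size]
            if len(chunk) < 2:
                continue
            sets[f"{label}_{i + 1:02d}"] = chunk
            for _ in range(sets_per_signal):
                n_null += 1
                null = rng.choice(background, size=len(chunk), replace=False)
                sets[f"null_{n_null:03d}"] = sorted(null.tolist())
    return set(truth.pseudogene_ids), sets


def expected_signal(truth: GroundTruth) -> list[str]:
    """Planted genes ranked by |log2fc| descending, ties by gene ID."""
    return sorted(truth.signal_log2fc, key=lambda g: (-abs(truth.signal_log2fc[g]), g))


def write_cohort(
    bundles: list[StudyBundle],
    truth: GroundTruth,
    outdir: str | Path,
    sets_per_signal: int = 5,
    seed: int = 0,
) -> None:
    """Serialize a generated cohort as the pipeline's file interface.

    Per-study counts and metadata TSVs, a pooled metadata TSV, the pseudogene
    list, a GMT collection and the ground-truth JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metas = []
    for b in bundles:
        io.write_counts_tsv(b.counts, outdir / f"counts_{b.study_id}.tsv")
        metas.append(b.metadata)
    io.write_metadata_tsv(pd.concat(metas), outdir / "metadata.tsv")
    pseudo, sets = generate_gene_annotation(truth, sets_per_signal=sets_per_signal, seed=seed)
    io.write_pseudogene_list(pseudo, outdir / "pseudogenes.txt")
    io.write_gmt(sets, outdir / "gene_sets.gmt")
    truth.to_json(outdir / "ground_truth.json")


def read_cohort(indir: str | Path) -> tuple[list[StudyBundle], pd.DataFrame]:
    """Load per-study counts and pooled metadata written by :func:`write_cohort`."""
    indir = Path(indir)
    meta = io.read_metadata_tsv(indir / "metadata.tsv")
    bundles = []
    for study_id, study_meta in meta.groupby("study_id", sort=True):
        counts = io.read_counts_tsv(indir / f"counts_{study_id}.tsv")
        bundles.append(StudyBundle(str(study_id), counts[study_meta.index], study_meta))
    return bundles, meta
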