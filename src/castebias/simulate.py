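"""Synthetic data generators for every arm of the pipeline.

The original raw expression and spectral-count tables were never
deposited, so the pipeline is exercised end to end on simulated studies
whose statistical structure matches what the analysis assumes:

* **Expression**: two rearing groups (10 foundress-reared vs 7
  worker-reared by default), 38 genes plus an endogenous control, a
  designated subset of truly up-regulated genes (16 by default, shifted
  on the log2 scale), correlated gene blocks realized through a shared
  latent factor (pairwise r 0.93 by default, mirroring the printed
  insulin-pathway correlations), a multiplicative per-sample technical
  scale factor that control normalization must cancel, log-normal
  biological noise, technical triplicates, and sparse missingness that
  never hits the control gene.
* **Spectral counts**: Poisson counts per database hit with per-lane
  loading factors, a beta-lactoglobulin-style spike-in standard, five
  gel bands in the in-gel dialect, low-abundance decoy hits, and a
  designated fold-change subset (5 vs 5 samples by default).
* **Genotypes**: haplodiploid microsatellite calls — diploid females
  with two draws per locus, haploid males with one, occasional
  triploids with three — with per-locus amplification failure and truth
  labels for recovery tests.

All generators are deterministic given their seed (byte-identical
repeat calls). Effect sizes are free parameters of the simulation; the
defaults are stated in units of the within-group biological SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "ExpressionSimConfig",
    "SpectralSimConfig",
    "GenotypeSimConfig",
    "ExpressionStudy",
    "SpectralCountTable",
    "GenotypeTable",
    "simulate_expression_study",
    "simulate_spectral_study",
    "simulate_genotype_table",
    "default_gene_ids",
]

GROUP1 = "FR"  # foundress-reared (putative worker-destined)
GROUP2 = "WR"  # worker-reared (putative gyne-destined)


def default_gene_ids(n_genes: int = 38) -> list[str]:
    return [f"g{i + 1:02d}" for i in range(n_genes)]


# ---------------------------------------------------------------------------
# expression studies
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSimConfig:
    """Study conditions for a simulated qPCR candidate-gene experiment.

    ``log2_effect`` applies to every gene in ``de_gene_ids`` (positive =
    up in group 2, the worker-reared larvae); pass a mapping for
    per-gene effects. ``correlation_blocks`` are ``(gene ids, pairwise
    r)`` pairs realized via one shared latent factor per block. The
    default configuration is the 38-gene, 16-up-regulated, 10-vs-7
    design with three correlated blocks at r = 0.93.
    """

    n_group1: int = 10
    n_group2: int = 7
    n_genes: int = 38
    de_gene_ids: Sequence[str] = field(
        default_factory=lambda: default_gene_ids()[:16]
    )
    log2_effect: float | Mapping[str, float] = 2.5
    correlation_blocks: Sequence[tuple[Sequence[str], float]] = field(
        default_factory=lambda: [
            (("g01", "g02", "g03"), 0.93),
            (("g04", "g05", "g06"), 0.93),
            (("g07", "g08"), 0.93),
        ]
    )
    gene_base_mean: float = 10.0  # log2 absolute copies
    biological_sd: float = 1.0  # log2 scale, within-group
    sample_scale_sd: float = 0.25  # log2 scale, removable technical factor
    triplicate_cv: float = 0.1
    control_gene_id: str = "RSP8"
    missing_rate: float = 0.003
    n_replicates: int = 3
    seed: int = 0

    def gene_ids(self) -> list[str]:
        return default_gene_ids(self.n_genes)

    def effect_of(self, gene: str) -> float:
        if isinstance(self.log2_effect, Mapping):
            return float(self.log2_effect.get(gene, 0.0))
        return float(self.log2_effect) if gene in set(self.de_gene_ids) else 0.0

    def validate(self) -> None:
        genes = set(self.gene_ids())
        if self.n_group1 < 2 or self.n_group2 < 2:
            raise ConfigurationError("group sizes must be >= 2")
        if self.control_gene_id in genes:
            raise ConfigurationError(
                "control gene id collides with a simulated gene id"
            )
        unknown = set(self.de_gene_ids) - genes
        if unknown:
            raise ConfigurationError(f"de_gene_ids not in gene set: {sorted(unknown)}")
        if self.control_gene_id in set(self.de_gene_ids):
            raise ConfigurationError("control gene must have effect 0")
        for members, r in self.correlation_blocks:
            if not 0 <= r < 1:
                raise ConfigurationError(f"block correlation {r} must be in [0, 1)")
            if self.control_gene_id in set(members):
                raise ConfigurationError("control gene belongs to no correlation block")
            bad = set(members) - genes
            if bad:
                raise ConfigurationError(f"block members not in gene set: {sorted(bad)}")
        blocks = [set(m) for m, _ in self.correlation_blocks]
        for i in range(len(blocks)):
            for j in range(i + 1, len(blocks)):
                if blocks[i] & blocks[j]:
                    raise ConfigurationError("correlation blocks must be disjoint")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.triplicate_cv < 0 or self.biological_sd < 0 or self.sample_scale_sd < 0:
            raise ConfigurationError("noise scales must be non-negative")
        if self.n_replicates < 1:
            raise ConfigurationError("need at least one technical replicate")


@dataclass
class ExpressionStudy:
    """A complete simulated (or loaded) expression study.

    ``quantities`` holds positive absolute quantities, genes (plus the
    control gene) in rows, ``(sample, replicate)`` MultiIndex columns;
    missing cells are NaN, never zero.
    """

    quantities: pd.DataFrame
    groups: pd.Series
    control_gene_id: str
    replicate_runs: dict[str, list[str]] = field(default_factory=dict)
    contig_pairs: list[tuple[str, str]] = field(default_factory=list)
    truth: dict = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.groups.index)

    @property
    def gene_ids(self) -> list[str]:
        return [g for g in self.quantities.index if g != self.control_gene_id]


def simulate_expression_study(cfg: ExpressionSimConfig) -> ExpressionStudy:
    """Draw one expression study under ``cfg``.

    Signal and noise are composed on the log2 scale: gene base mean, the
    group-2 shift for truly differential genes, a block latent factor
    (loading ``sqrt(r)``) plus residual noise for block members, the
    per-sample technical scale factor (applied to every gene including
    the control), and finally multiplicative triplicate noise with the
    configured CV. The control gene carries no biological noise — it is
    the uniformly expressed reference the normalization divides by.

    All random draws are made regardless of whether their scale
    parameter is zero, so studies that differ only in, say,
    ``sample_scale_sd`` share every other draw at equal seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.gene_ids()
    n = cfg.n_group1 + cfg.n_group2
    samples = [f"{GROUP1}{i + 1:02d}" for i in range(cfg.n_group1)] + [
        f"{GROUP2}{i + 1:02d}" for i in range(cfg.n_group2)
    ]
    groups = pd.Series(
        [GROUP1] * cfg.n_group1 + [GROUP2] * cfg.n_group2, index=samples, name="group"
    )
    is_g2 = (groups == GROUP2).to_numpy()

    scale = cfg.sample_scale_sd * rng.standard_normal(n)  # log2 per-sample factor

    block_of = {}
    block_r = {}
    for bi, (members, r) in enumerate(cfg.correlation_blocks):
        for m in members:
            block_of[m] = bi
            block_r[m] = r
    latents = rng.standard_normal((len(cfg.correlation_blocks), n))
    eps = rng.standard_normal((len(genes), n))

    log2q = np.empty((len(genes), n))
    for gi, g in enumerate(genes):
        mu = cfg.gene_base_mean + cfg.effect_of(g) * is_g2
        if g in block_of:
            r = block_r[g]
            noise = np.sqrt(r) * latents[block_of[g]] + np.sqrt(1 - r) * eps[gi]
        else:
            noise = eps[gi]
        log2q[gi] = mu + cfg.biological_sd * noise + scale

    control = cfg.gene_base_mean + scale  # no biological noise by design

    all_log2 = np.vstack([log2q, control])
    index = genes + [cfg.control_gene_id]

    # multiplicative triplicate noise with the configured CV (log-normal)
    sigma = float(np.sqrt(np.log1p(cfg.triplicate_cv**2)))
    rep_noise = rng.standard_normal((len(index), n, cfg.n_replicates))
    reps = 2.0 ** all_log2[:, :, None] * np.exp(
        sigma * rep_noise - sigma**2 / 2.0
    )

    # completely-at-random missingness, whole-cell, never the control
    miss_draw = rng.random((len(genes), n))
    missing = miss_draw < cfg.missing_rate
    reps[:-1][missing] = np.nan

    columns = pd.MultiIndex.from_product(
        [samples, range(1, cfg.n_replicates + 1)], names=["sample", "rep"]
    )
    quantities = pd.DataFrame(
        reps.reshape(len(index), n * cfg.n_replicates), index=index, columns=columns
    )
    truth = {
        "de_gene_ids": list(cfg.de_gene_ids),
        "log2_effect": {g: cfg.effect_of(g) for g in genes},
        "scale_factors": pd.Series(scale, index=samples),
        "missing_cells": [
            (genes[i], samples[j]) for i, j in np.argwhere(missing)
        ],
    }
    return ExpressionStudy(
        quantities=quantities,
        groups=groups,
        control_gene_id=cfg.control_gene_id,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# spectral-count tables
# ---------------------------------------------------------------------------

@dataclass
class SpectralSimConfig:
    """Conditions for a simulated label-free spectral-count experiment.

    Counts are Poisson with mean ``base_intensity * lane_loading *
    fold_change`` (fold applied to differential hits in group 2 only),
    optionally gamma-overdispersed. In-gel mode splits each hit's mean
    across ``n_bands`` gel bands via a fixed per-hit band profile and
    adds a Poisson spike-in standard per (sample, band). Decoy hits are
    generated at low intensity and are never differential.

    The default fixture is a 24-hit table (21 targets, 3 decoys) with 9
    differential hits whose spectral mass is balanced across groups:
    four low-abundance hits 8-fold up in group 2 and five high-abundance
    hits 8-fold down, with base intensities chosen so the total
    differential mass gained equals the mass lost. Total-count
    normalization divides by the lane total, so an *unbalanced*
    differential mass shifts every null hit's normalized value between
    groups (a compositional artifact of this normalization family);
    balancing the differential mass keeps the null hits exchangeable.
    When ``base_intensity`` is None this layout is resolved from the
    fold map: up-hits get base 6, down-hits 38.4, remaining targets a
    geometric ladder from 5 to 20.
    """

    n_per_group: int = 5
    n_hits: int = 24
    de_hit_ids: Sequence[str] = field(
        default_factory=lambda: [f"hit{i + 1:02d}" for i in range(9)]
    )
    fold_change: float | Mapping[str, float] = field(
        default_factory=lambda: {
            **{f"hit{i + 1:02d}": 8.0 for i in range(4)},
            **{f"hit{i + 1:02d}": 0.125 for i in range(4, 9)},
        }
    )
    base_intensity: float | Sequence[float] | None = None
    lane_loading_sd: float = 0.2  # sd of log lane loading
    lane_loading: Sequence[float] | None = None  # explicit override
    spike_in_mean: float = 30.0
    n_bands: int = 5
    mode: Literal["in_gel", "in_liquid"] = "in_gel"
    decoy_fraction: float = 0.125
    decoy_intensity: float = 1.0
    overdispersion: float = 0.0
    seed: int = 0

    def target_ids(self) -> list[str]:
        n_decoy = int(round(self.decoy_fraction * self.n_hits))
        return [f"hit{i + 1:02d}" for i in range(self.n_hits - n_decoy)]

    def decoy_ids(self) -> list[str]:
        n_decoy = int(round(self.decoy_fraction * self.n_hits))
        return [f"decoy{i + 1:02d}" for i in range(n_decoy)]

    def fold_of(self, hit: str) -> float:
        if isinstance(self.fold_change, Mapping):
            return float(self.fold_change.get(hit, 1.0))
        return float(self.fold_change) if hit in set(self.de_hit_ids) else 1.0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("need at least 2 samples per group")
        if self.spike_in_mean <= 0:
            raise ConfigurationError("spike_in_mean must be > 0")
        if not 0 <= self.decoy_fraction < 1:
            raise ConfigurationError("decoy_fraction must be in [0, 1)")
        if self.mode not in ("in_gel", "in_liquid"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.n_bands < 1:
            raise ConfigurationError("n_bands must be >= 1")
        targets = set(self.target_ids())
        bad = set(self.de_hit_ids) - targets
        if bad:
            raise ConfigurationError(
                f"de_hit_ids must be target (non-decoy) hits: {sorted(bad)}"
            )
        if self.lane_loading is not None and len(self.lane_loading) != 2 * self.n_per_group:
            raise ConfigurationError("lane_loading needs one factor per sample")
        if self.overdispersion < 0:
            raise ConfigurationError("overdispersion must be >= 0")


@dataclass
class SpectralCountTable:
    """Raw spectral counts: hits x (sample, band), plus spike-in counts,
    group labels, decoy flags and an optional protein grouping."""

    counts: pd.DataFrame  # MultiIndex columns (sample, band)
    spike_in: pd.Series | None  # indexed by (sample, band); None for in-liquid
    groups: pd.Series
    decoy: pd.Series
    mode: Literal["in_gel", "in_liquid"]
    protein_group: pd.Series | None = None
    truth: dict = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.groups.index)

    def sample_totals(self) -> pd.DataFrame:
        """Raw counts summed over bands: hits x samples."""
        return self.counts.T.groupby(level="sample").sum().T[self.samples]


def simulate_spectral_study(cfg: SpectralSimConfig) -> SpectralCountTable:
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    targets, decoys = cfg.target_ids(), cfg.decoy_ids()
    hits = targets + decoys
    n = 2 * cfg.n_per_group
    samples = [f"{GROUP1}{i + 1:02d}" for i in range(cfg.n_per_group)] + [
        f"{GROUP2}{i + 1:02d}" for i in range(cfg.n_per_group)
    ]
    groups = pd.Series(
        [GROUP1] * cfg.n_per_group + [GROUP2] * cfg.n_per_group,
        index=samples,
        name="group",
    )
    is_g2 = (groups == GROUP2).to_numpy()

    if cfg.base_intensity is None:
        folds_t = np.array([cfg.fold_of(h) for h in targets])
        base_t = np.empty(len(targets))
        n_null = int(np.sum(folds_t == 1.0))
        base_t[folds_t > 1.0] = 6.0
        base_t[folds_t < 1.0] = 38.4
        base_t[folds_t == 1.0] = np.geomspace(5.0, 20.0, num=max(n_null, 1))[:n_null]
    elif np.isscalar(cfg.base_intensity):
        base_t = np.full(len(targets), float(cfg.base_intensity))
    else:
        base_t = np.asarray(cfg.base_intensity, dtype=float)
        if len(base_t) != len(targets):
            raise ConfigurationError(
                "base_intensity must be scalar or one value per target hit"
            )
    base = np.concatenate([base_t, np.full(len(decoys), cfg.decoy_intensity)])

    if cfg.lane_loading is not None:
        lane = np.asarray(cfg.lane_loading, dtype=float)
    else:
        lane = np.exp(cfg.lane_loading_sd * rng.standard_normal(n))

    fold = np.array([cfg.fold_of(h) for h in hits])
    mean = base[:, None] * np.where(is_g2[None, :], fold[:, None], 1.0) * lane[None, :]
    if cfg.overdispersion > 0:
        shape = 1.0 / cfg.overdispersion
        mean = mean * rng.gamma(shape, 1.0 / shape, size=mean.shape)

    n_bands = cfg.n_bands if cfg.mode == "in_gel" else 1
    bands = list(range(1, n_bands + 1))
    if n_bands > 1:
        profile = rng.dirichlet(np.full(n_bands, 2.0), size=len(hits))
    else:
        profile = np.ones((len(hits), 1))
    lam = mean[:, :, None] * profile[:, None, :]
    counts = rng.poisson(lam)

    columns = pd.MultiIndex.from_product([samples, bands], names=["sample", "band"])
    counts_df = pd.DataFrame(
        counts.reshape(len(hits), n * n_bands), index=hits, columns=columns
    )
    spike = None
    if cfg.mode == "in_gel":
        spike_counts = rng.poisson(cfg.spike_in_mean * lane[:, None], size=(n, n_bands))
        spike = pd.Series(spike_counts.ravel(), index=columns, name="spikein_count")
    decoy_flags = pd.Series(
        [h in set(decoys) for h in hits], index=hits, name="is_decoy"
    )
    protein_group = pd.Series(hits, index=hits, name="protein_group")
    truth = {
        "de_hit_ids": list(cfg.de_hit_ids),
        "fold_change": {h: cfg.fold_of(h) for h in hits},
        "lane_loading": pd.Series(lane, index=samples),
    }
    return SpectralCountTable(
        counts=counts_df,
        spike_in=spike,
        groups=groups,
        decoy=decoy_flags,
        mode=cfg.mode,
        protein_group=protein_group,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# microsatellite genotypes
# ---------------------------------------------------------------------------

def _default_allele_freqs(n_loci: int) -> list[np.ndarray]:
    # five alleles per locus, moderately uneven — typical microsatellite
    # diversity; all-homozygous diploids are then rare (~1e-4 per specimen)
    base = np.array([0.35, 0.25, 0.20, 0.12, 0.08])
    return [base.copy() for _ in range(n_loci)]


@dataclass
class GenotypeSimConfig:
    """Conditions for a simulated haplodiploid genotyping cohort.

    Truth classes are allocated deterministically (rounded fractions,
    shuffled order) so a cohort of 29 with ``male_fraction=18/29``
    contains exactly 18 haploid males — the worker-reared sex ratio the
    sexing stage must recover.
    """

    n_specimens: int = 29
    n_loci: int = 6
    allele_freqs: Sequence[Sequence[float]] | None = None
    male_fraction: float = 18.0 / 29.0
    triploid_fraction: float = 1.0 / 29.0
    amplification_failure_rate: float = 0.03
    seed: int = 0

    def freqs(self) -> list[np.ndarray]:
        if self.allele_freqs is None:
            return _default_allele_freqs(self.n_loci)
        return [np.asarray(f, dtype=float) for f in self.allele_freqs]

    def validate(self) -> None:
        if self.n_specimens < 1 or self.n_loci < 1:
            raise ConfigurationError("need >=1 specimen and >=1 locus")
        freqs = self.freqs()
        if len(freqs) != self.n_loci:
            raise ConfigurationError("one allele-frequency vector per locus required")
        for i, f in enumerate(freqs):
            if (f < 0).any() or abs(f.sum() - 1.0) > 1e-8:
                raise ConfigurationError(
                    f"allele frequencies at locus {i + 1} must sum to 1"
                )
        if not (0 <= self.male_fraction <= 1 and 0 <= self.triploid_fraction <= 1):
            raise ConfigurationError("fractions must be in [0, 1]")
        if self.male_fraction + self.triploid_fraction > 1:
            raise ConfigurationError("male_fraction + triploid_fraction must be <= 1")
        if not 0 <= self.amplification_failure_rate < 1:
            raise ConfigurationError("amplification_failure_rate must be in [0, 1)")


@dataclass
class GenotypeTable:
    """Specimen x locus allele calls; each cell is a tuple of distinct
    allele labels, empty for failed amplification."""

    genotypes: pd.DataFrame
    truth: pd.Series | None = None  # 'female' | 'male' | 'triploid'

    @property
    def specimens(self) -> list[str]:
        return list(self.genotypes.index)

    @property
    def loci(self) -> list[str]:
        return list(self.genotypes.columns)


def simulate_genotype_table(cfg: GenotypeSimConfig) -> GenotypeTable:
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    freqs = cfg.freqs()
    n = cfg.n_specimens
    n_males = int(round(cfg.male_fraction * n))
    n_triploid = int(round(cfg.triploid_fraction * n))
    if n_males + n_triploid > n:
        n_triploid = n - n_males
    statuses = (
        ["male"] * n_males
        + ["triploid"] * n_triploid
        + ["female"] * (n - n_males - n_triploid)
    )
    rng.shuffle(statuses)
    ploidy = {"male": 1, "female": 2, "triploid": 3}

    loci = [f"L{i + 1}" for i in range(cfg.n_loci)]
    rows = []
    specimens = [f"sp{i + 1:03d}" for i in range(n)]
    for status in statuses:
        row = []
        for f in freqs:
            if rng.random() < cfg.amplification_failure_rate:
                row.append(())
                continue
            # allele labels: microsatellite-style fragment sizes
            draws = rng.choice(len(f), size=ploidy[status], p=f)
            alleles = tuple(sorted({120 + 2 * int(a) for a in draws}))
            row.append(alleles)
        rows.append(row)
    genotypes = pd.DataFrame(rows, index=specimens, columns=loci)
    truth = pd.Series(statuses, index=specimens, name="truth")
    return GenotypeTable(genotypes=genotypes, truth=truth)
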