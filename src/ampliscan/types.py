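"""Core domain containers shared across the pipeline.

Coordinate convention: 1-based closed intervals internally (VCF-native).
BED input is converted at the boundary (see :mod:`ampliscan.io_utils`).
Copy number is expressed relative to normal diploid dosage: 1.0 means two
chromosomal copies of a single-copy locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigurationError(ValueError):
    """Raised when a scenario or run configuration is internally inconsistent."""


@dataclass
class AmpOriginSpec:
    """One independent amplification event: a piecewise-constant copy-number
    haplotype over the amplified span.

    ``breakpoints`` are strictly increasing 1-based positions delimiting
    ``len(breakpoints) - 1`` segments; ``segment_copies[i]`` is the number of
    copies per haplotype of segment ``i`` (integer >= 1).  Outside
    ``[breakpoints[0], breakpoints[-1])`` the haplotype is single copy.
    ``carrier_fraction`` is the fraction of the assigned population carrying
    this haplotype.
    """

    origin_id: str
    breakpoints: tuple
    segment_copies: tuple
    carrier_fraction: float
    population: str

    def __post_init__(self):
        bp = np.asarray(self.breakpoints, dtype=np.int64)
        if len(bp) < 2:
            raise ConfigurationError("need at least two breakpoints (one segment)")
        if not np.all(np.diff(bp) > 0):
            raise ConfigurationError("breakpoints must be strictly increasing")
        if len(self.segment_copies) != len(bp) - 1:
            raise ConfigurationError(
                "segment_copies length must equal number of segments"
            )
        if any(c < 1 for c in self.segment_copies):
            raise ConfigurationError("copies must be >= 1 everywhere")
        if not 0.0 < self.carrier_fraction <= 1.0:
            raise ConfigurationError("carrier_fraction must be in (0, 1]")

    @property
    def span(self):
        """(start, end) of the amplified region, 1-based half-open."""
        return int(self.breakpoints[0]), int(self.breakpoints[-1])

    def copies_at(self, positions: np.ndarray) -> np.ndarray:
        """Per-haplotype copy count at each position (1 outside the span)."""
        positions = np.asarray(positions, dtype=np.int64)
        copies = np.ones(positions.shape, dtype=np.float64)
        bp = np.asarray(self.breakpoints, dtype=np.int64)
        seg = np.searchsorted(bp, positions, side="right") - 1
        inside = (seg >= 0) & (seg < len(self.segment_copies))
        copies[inside] = np.asarray(self.segment_copies, dtype=np.float64)[seg[inside]]
        return copies


@dataclass
class SweepModel:
    """Haplotype structure of carriers around the focal locus.

    kind: 'hard' (one founder), 'soft' (k founders) or 'neutral' (no founder
    copying).  ``decay_length`` is the exponential scale (bp) over which a
    carrier haplotype retains the founder allele; ``theta`` is background
    diversity per site (probability a background site is polymorphic feeds
    off the neutral frequency spectrum).
    """

    kind: str = "neutral"
    k: int = 1
    decay_length: float = 200_000.0
    theta: float = 0.01

    def __post_init__(self):
        if self.kind not in ("hard", "soft", "neutral"):
            raise ConfigurationError(f"unknown sweep kind {self.kind!r}")
        if self.theta <= 0:
            raise ConfigurationError("theta must be > 0")
        if self.kind == "hard":
            self.k = 1
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")


@dataclass
class SimScenario:
    """Full parameterization of a synthetic cohort.

    populations: list of (name, region, n_individuals).
    mask_intervals: [(start, end, inflation_factor)] repeat-inflated regions.
    dropout_intervals: [(start, end)] forced below 3x depth.
    phenotype_coefs: (beta0, beta_cn, beta_tsr, noise_sd) for the rating model.
    site_spacing: distance between simulated depth sites (bp).
    focal_gene: (start, end) of the focal amplified gene, 1-based half-open.
    tsr_freq: allele frequency of the target-site resistance mutation.
    """

    chrom_length: int = 1_000_000
    chrom: str = "chr5"
    populations: list = field(default_factory=lambda: [("popA", "regionA", 10)])
    origins: list = field(default_factory=list)
    mean_depth: float = 20.0
    nb_dispersion: float = 50.0
    bias_sd: float = 0.0
    mask_intervals: list = field(default_factory=list)
    dropout_intervals: list = field(default_factory=list)
    sweep_model: SweepModel = field(default_factory=SweepModel)
    phenotype_coefs: tuple = (0.0, 0.5, 1.0, 0.5)
    seed: int = 0
    site_spacing: int = 1
    n_snps: int = 2000
    focal_gene: tuple = (495_000, 505_000)
    tsr_freq: float = 0.0

    def __post_init__(self):
        if self.mean_depth <= 0:
            raise ConfigurationError("mean_depth must be > 0")
        if any(n < 2 for _, _, n in self.populations):
            raise ConfigurationError("each population needs >= 2 individuals")
        # intervals are 1-based closed
        for iv in self.mask_intervals:
            if not (1 <= iv[0] <= iv[1] <= self.chrom_length):
                raise ConfigurationError(f"mask interval {iv} outside chromosome")
        for iv in self.dropout_intervals:
            if not (1 <= iv[0] <= iv[1] <= self.chrom_length):
                raise ConfigurationError(f"dropout interval {iv} outside chromosome")
        for o in self.origins:
            s, e = o.span
            if not (1 <= s < e <= self.chrom_length + 1):
                raise ConfigurationError(
                    f"origin {o.origin_id} span outside chromosome"
                )
        for ms, me, _ in self.mask_intervals:
            for ds, de in self.dropout_intervals:
                if ms <= de and ds <= me:
                    raise ConfigurationError(
                        "mask and dropout intervals overlap: "
                        f"[{ms},{me}] vs [{ds},{de}]"
                    )

    @property
    def sample_ids(self):
        out = []
        for name, _, n in self.populations:
            out.extend(f"{name}_{i:03d}" for i in range(n))
        return out

    @property
    def sample_population(self):
        out = {}
        for name, region, n in self.populations:
            for i in range(n):
                out[f"{name}_{i:03d}"] = (name, region)
        return out


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    sample_ids: list
    origin_of: dict            # sample_id -> origin_id or None
    founder_of: dict           # sample_id -> (founder haplotype id per hap)
    true_cn_focal: dict        # sample_id -> diploid-relative CN at focal gene
    tsr_dosage: dict           # sample_id -> 0/1/2
    liabilities: dict          # sample_id -> latent phenotype (filled on demand)
    alpha: float | None = None
    origins: list = field(default_factory=list)

    def true_cn(self, sample_id: str, positions: np.ndarray) -> np.ndarray:
        """Diploid-relative CN over ``positions`` for one individual."""
        oid = self.origin_of.get(sample_id)
        if oid is None:
            return np.ones(len(positions), dtype=np.float64)
        origin = next(o for o in self.origins if o.origin_id == oid)
        return origin.copies_at(positions)


@dataclass
class DepthTrack:
    """One individual's per-site read depth."""

    sample_id: str
    chrom: str
    positions: np.ndarray      # 1-based, strictly increasing
    depth: np.ndarray          # non-negative integers

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if len(self.positions) != len(self.depth):
            raise ValueError("positions and depth length mismatch")
        if len(self.positions) and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if len(self.depth) and self.depth.min() < 0:
            raise ValueError("depth must be non-negative")


@dataclass
class CoverageNormalizer:
    """Modal genome-wide depth of one sample, with exclusion bookkeeping."""

    sample_id: str
    mode_depth: float
    excluded_mask: list
    n_sites_used: int

    def __post_init__(self):
        if self.mode_depth <= 0:
            raise ValueError("mode_depth must be > 0")
        if self.n_sites_used <= 0:
            raise ValueError("n_sites_used must be > 0")


@dataclass
class CopyNumberProfile:
    """Mode-normalized CN averaged in fixed-width windows tiling a region.

    Windows are half-open ``[start, start + width)`` with 1-based starts;
    windows without any covered site carry NaN (missing), never zero.
    """

    sample_id: str
    chrom: str
    region: tuple              # (start, end), 1-based half-open
    window_starts: np.ndarray
    cn: np.ndarray             # NaN = missing
    window_width: int


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes as alt-allele dosage.

    ``genotypes`` is (n_samples, n_sites) int8 with values {0, 1, 2} and -1
    for missing.  ``populations`` maps sample_id -> (population, region).
    """

    sample_ids: list
    chrom: str
    positions: np.ndarray
    genotypes: np.ndarray
    populations: dict = field(default_factory=dict)
    ref: list = field(default_factory=list)
    alt: list = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sample_ids), len(self.positions)):
            raise ValueError("genotype matrix shape mismatch")
        bad = ~np.isin(self.genotypes, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2} or -1 (missing)")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) >= 0):
            raise ValueError("positions must be sorted")

    def subset_samples(self, ids) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        return GenotypeMatrix(
            sample_ids=list(ids),
            chrom=self.chrom,
            positions=self.positions.copy(),
            genotypes=self.genotypes[idx],
            populations={s: self.populations[s] for s in ids if s in self.populations},
            ref=list(self.ref),
            alt=list(self.alt),
        )


@dataclass
class ProfileCorrelation:
    """Pairwise Spearman rho among amplified individuals' coverage profiles."""

    sample_ids: list
    rho: np.ndarray            # symmetric, unit diagonal, NaN = missing pair
    labels: dict               # sample_id -> (population, region)
    region_of_interest: tuple

    def __post_init__(self):
        n = len(self.sample_ids)
        if self.rho.shape != (n, n):
            raise ValueError("rho matrix shape mismatch")
        if not np.allclose(np.diag(self.rho), 1.0, equal_nan=False):
            raise ValueError("rho diagonal must be 1")
        off = self.rho[~np.eye(n, dtype=bool)]
        finite = off[np.isfinite(off)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("rho entries must lie in [-1, 1]")


@dataclass
class OriginCall:
    """Inferred number of independent amplification origins."""

    sample_ids: list
    cluster: np.ndarray
    n_origins: int
    linkage_threshold: float
    mean_within_rho: float
    mean_between_rho: float


@dataclass
class PseudohaploidMatrix:
    """One random allele per sample per site: values {0, 1}, -1 missing."""

    sample_ids: list
    chrom: str
    positions: np.ndarray
    alleles: np.ndarray
    seed: int

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.sample_ids), len(self.positions)):
            raise ValueError("allele matrix shape mismatch")


@dataclass
class EHHDecay:
    """Extended haplotype homozygosity decay around a core site."""

    core_pos: int
    group: str
    distances: np.ndarray      # signed bp offsets from core (0 included)
    ehh: np.ndarray            # values in [0, 1]; 1 at distance 0
    ihh_left: float
    ihh_right: float

    @property
    def ihh(self) -> float:
        return self.ihh_left + self.ihh_right


@dataclass
class FEstimate:
    """ABBA-BABA f admixture proportion with block-jackknife uncertainty."""

    f_hat: float
    se: float
    ci_low: float
    ci_high: float
    n_blocks: int
    block_size: int

    def __post_init__(self):
        if not (self.ci_low <= self.f_hat <= self.ci_high):
            raise ValueError("CI must contain the point estimate")
        if self.n_blocks < 10:
            raise ValueError("need >= 10 jackknife blocks")
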