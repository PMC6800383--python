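"""Synthetic cohorts with the statistical structure the pipeline assumes.

Depth is drawn per site from a negative binomial whose mean is
``mean_depth * trueCN * bias * mask_inflation``; sequencing depth is
overdispersed relative to Poisson and the mode-based normalization downstream
presumes a unimodal depth distribution, which the NB satisfies.  SNP
haplotypes use a founder-copying model: carriers copy one of k founder
haplotypes near the focal locus and revert to background alleles with
probability rising exponentially with distance — enough to produce the
qualitative hard/soft-sweep signatures without a full coalescent.

All randomness flows from the scenario seed; per-individual substreams are
spawned deterministically with :class:`numpy.random.SeedSequence` so adding
an individual never perturbs the others.
"""

from __future__ import annotations

import numpy as np

from .types import (
    AmpOriginSpec,
    ConfigurationError,
    DepthTrack,
    GenotypeMatrix,
    SimScenario,
    SimTruth,
)

__all__ = [
    "build_truth",
    "simulate_depth",
    "simulate_genotypes",
    "simulate_admixture",
    "simulate_phenotypes",
    "simulate_cohort",
    "origin_cohort_scenario",
    "random_amp_profile",
]


def _spawn(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child generator for a (seed, key...) path."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def build_truth(scenario: SimScenario) -> SimTruth:
    """Assign origins, founders and target-site genotypes to the cohort.

    Carrier assignment is deterministic given the scenario seed.  Carriers
    bear the amplification haplotype on both chromosomes, so an individual's
    diploid-relative CN equals the origin's per-haplotype segment copies.
    """
    rng = _spawn(scenario.seed, 0)
    pops = scenario.sample_population
    origin_of = {s: None for s in pops}
    founder_of = {}
    by_pop: dict = {}
    for s, (pop, _) in pops.items():
        by_pop.setdefault(pop, []).append(s)

    for origin in scenario.origins:
        members = by_pop.get(origin.population, [])
        free = [s for s in members if origin_of[s] is None]
        n_carriers = int(round(origin.carrier_fraction * len(members)))
        n_carriers = min(n_carriers, len(free))
        carriers = sorted(rng.choice(free, size=n_carriers, replace=False).tolist())
        for s in carriers:
            origin_of[s] = origin.origin_id

    # Founder haplotype ids for the sweep model: carriers draw among k
    # founders (hard => k = 1); each diploid gets two draws.
    sm = scenario.sweep_model
    carriers_all = sorted(s for s, o in origin_of.items() if o is not None)
    if sm.kind != "neutral" and carriers_all and sm.k > len(carriers_all):
        raise ConfigurationError(
            f"soft sweep with k={sm.k} founders exceeds {len(carriers_all)} carriers"
        )
    for s in pops:
        if origin_of[s] is not None and sm.kind != "neutral":
            fid = int(rng.integers(sm.k))
            founder_of[s] = (fid, fid)
        else:
            founder_of[s] = None

    tsr = {}
    for s in pops:
        if scenario.tsr_freq > 0:
            tsr[s] = int(rng.binomial(2, scenario.tsr_freq))
        else:
            tsr[s] = 0

    truth = SimTruth(
        sample_ids=list(pops),
        origin_of=origin_of,
        founder_of=founder_of,
        true_cn_focal={},
        tsr_dosage=tsr,
        liabilities={},
        origins=list(scenario.origins),
    )
    gs, ge = scenario.focal_gene
    mid = np.array([(gs + ge) // 2])
    for s in pops:
        truth.true_cn_focal[s] = float(truth.true_cn(s, mid)[0])
    return truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float):
    """Negative binomial with mean ``mean`` and dispersion ``size_param``
    (var = mean + mean^2/size)."""
    mean = np.maximum(mean, 1e-9)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_depth(scenario: SimScenario, truth: SimTruth | None = None):
    """Per-individual depth tracks plus ground truth.

    Depth at each site follows NB(mean_depth * trueCN * bias * inflation);
    sites inside dropout intervals get depth drawn uniformly from {0, 1, 2}.
    The per-site lognormal bias is a site property (e.g. mappability) shared
    across individuals.
    """
    if truth is None:
        truth = build_truth(scenario)
    positions = np.arange(
        1, scenario.chrom_length + 1, scenario.site_spacing, dtype=np.int64
    )

    bias_rng = _spawn(scenario.seed, 1)
    if scenario.bias_sd > 0:
        bias = bias_rng.lognormal(
            mean=-0.5 * scenario.bias_sd**2, sigma=scenario.bias_sd, size=len(positions)
        )
    else:
        bias = np.ones(len(positions))

    # intervals are 1-based closed throughout the package
    inflation = np.ones(len(positions))
    for ms, me, factor in scenario.mask_intervals:
        inflation[(positions >= ms) & (positions <= me)] = factor
    dropout = np.zeros(len(positions), dtype=bool)
    for ds, de in scenario.dropout_intervals:
        dropout |= (positions >= ds) & (positions <= de)

    tracks = {}
    for i, s in enumerate(truth.sample_ids):
        rng = _spawn(scenario.seed, 2, i)
        cn = truth.true_cn(s, positions)
        mean = scenario.mean_depth * cn * bias * inflation
        depth = _nb_draw(rng, mean, scenario.nb_dispersion)
        if dropout.any():
            depth[dropout] = rng.integers(0, 3, size=int(dropout.sum()))
        tracks[s] = DepthTrack(
            sample_id=s, chrom=scenario.chrom, positions=positions, depth=depth
        )
    return tracks, truth


def _background_freqs(rng: np.random.Generator, n_sites: int, n_hap: int):
    """Allele frequencies from the folded neutral spectrum, P(i) ∝ 1/i."""
    i = np.arange(1, n_hap)
    w = 1.0 / i
    counts = rng.choice(i, size=n_sites, p=w / w.sum())
    return counts / n_hap


def simulate_genotypes(scenario: SimScenario, truth: SimTruth | None = None):
    """Diploid SNP genotypes with hard/soft-sweep structure among carriers.

    Background sites segregate at frequencies drawn from the folded neutral
    spectrum.  Carrier haplotypes copy their founder's allele near the focal
    locus; the probability of retaining the founder allele decays as
    exp(-distance / decay_length).
    """
    if truth is None:
        truth = build_truth(scenario)
    sm = scenario.sweep_model
    samples = truth.sample_ids
    n = len(samples)
    n_hap = 2 * n

    rng = _spawn(scenario.seed, 3)
    positions = np.sort(
        rng.choice(
            np.arange(1, scenario.chrom_length + 1),
            size=min(scenario.n_snps, scenario.chrom_length),
            replace=False,
        )
    )
    freqs = _background_freqs(rng, len(positions), n_hap)

    # Founder haplotypes for the sweep.
    founders = None
    if sm.kind != "neutral":
        frng = _spawn(scenario.seed, 4)
        founders = (frng.random((sm.k, len(positions))) < freqs).astype(np.int8)

    gs, ge = scenario.focal_gene
    center = (gs + ge) // 2
    if np.isfinite(sm.decay_length):
        p_keep = np.exp(-np.abs(positions - center) / sm.decay_length)
    else:
        p_keep = np.ones(len(positions))

    genotypes = np.empty((n, len(positions)), dtype=np.int8)
    for i, s in enumerate(samples):
        g = _spawn(scenario.seed, 5, i)
        haps = (g.random((2, len(positions))) < freqs).astype(np.int8)
        if founders is not None and truth.founder_of[s] is not None:
            for h in range(2):
                fid = truth.founder_of[s][h]
                keep = g.random(len(positions)) < p_keep
                haps[h, keep] = founders[fid, keep]
        genotypes[i] = haps.sum(axis=0)

    pops = scenario.sample_population
    return (
        GenotypeMatrix(
            sample_ids=list(samples),
            chrom=scenario.chrom,
            positions=positions,
            genotypes=genotypes,
            populations={s: pops[s] for s in samples},
            ref=["A"] * len(positions),
            alt=["T"] * len(positions),
        ),
        truth,
    )


def simulate_admixture(
    n_sites: int,
    alpha: float,
    sample_sizes,
    seed: int,
    fst_drift: float = 0.1,
    site_spacing: int = 100,
):
    """Allele-frequency table for (P1, P2, P3, O) under a two-source mixture.

    Each site's P2 allele derives from the P3 lineage with probability
    ``alpha`` and from the P1 lineage otherwise, so the ABBA-BABA f
    statistic has expectation ``alpha``.  Lineage frequencies diverge from
    a shared ancestral frequency by Balding–Nichols drift of strength
    ``fst_drift``; the outgroup O is fixed ancestral.  Finite-sample
    frequencies are returned (binomial sampling of 2N alleles per group).

    Returns a dict with keys 'pos', 'p1', 'p2', 'p3', 'pO'.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if any(s < 2 for s in sample_sizes):
        raise ValueError("each panel needs >= 2 individuals")
    n1, n2, n3, nO = sample_sizes
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(9,)))

    anc = rng.uniform(0.05, 0.95, size=n_sites)
    a = anc * (1 - fst_drift) / fst_drift
    b = (1 - anc) * (1 - fst_drift) / fst_drift
    p1 = rng.beta(a, b)
    p3 = rng.beta(a, b)
    from_p3 = rng.random(n_sites) < alpha
    p2 = np.where(from_p3, p3, p1)

    def finite(p, n_ind):
        return rng.binomial(2 * n_ind, p) / (2 * n_ind)

    return {
        "pos": np.arange(1, n_sites + 1, dtype=np.int64) * site_spacing,
        "p1": finite(p1, n1),
        "p2": finite(p2, n2),
        "p3": finite(p3, n3),
        "pO": np.zeros(n_sites),
        "n3": 2 * n3,
    }


def simulate_phenotypes(truth: SimTruth, coefs, seed: int = 0) -> dict:
    """Visual-injury ratings on the 0 (highly sensitive) to 5 (no injury)
    scale from a latent linear liability.

    latent = b0 + b_cn * CN_focal + b_tsr * TSR + Normal(0, noise_sd),
    rounded to the nearest integer and clamped into {0..5}.
    """
    b0, b_cn, b_tsr, noise_sd = coefs
    for c in (b0, b_cn, b_tsr, noise_sd):
        if not np.isfinite(c):
            raise ValueError("phenotype coefficients must be finite")
    rng = _spawn(seed, 6)
    ratings = {}
    for s in truth.sample_ids:
        latent = (
            b0
            + b_cn * truth.true_cn_focal[s]
            + b_tsr * truth.tsr_dosage[s]
            + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        )
        truth.liabilities[s] = float(latent)
        ratings[s] = int(np.clip(np.rint(latent), 0, 5))
    return ratings


def simulate_cohort(scenario: SimScenario):
    """Run every generator for one scenario: depth, genotypes, ratings, truth."""
    truth = build_truth(scenario)
    tracks, _ = simulate_depth(scenario, truth)
    genos, _ = simulate_genotypes(scenario, truth)
    ratings = simulate_phenotypes(truth, scenario.phenotype_coefs, seed=scenario.seed)
    return tracks, genos, ratings, truth


def origin_cohort_scenario(
    n_origins: int,
    carriers_per_origin: int = 8,
    seed: int = 0,
    mean_depth: float = 20.0,
    span: tuple = (200_000, 800_000),
    n_segments: int = 30,
    max_copies: int = 10,
    site_spacing: int = 50,
    chrom_length: int = 1_000_000,
    focal_gene: tuple = (495_000, 505_000),
) -> SimScenario:
    """Cohort where ``n_origins`` independent amplification events each have
    ``carriers_per_origin`` carriers.

    Each origin is a fine-grained (30-segment by default) piecewise haplotype
    over a span that covers the whole profiled region, mimicking a large
    tandem amplification around the focal gene whose internal structure is
    distinctive per event; carriers of one event share it exactly.
    """
    rng = _spawn(seed, 8)
    origins = []
    for i in range(n_origins):
        bp, cp = random_amp_profile(
            rng, span, n_segments=n_segments, max_copies=max_copies
        )
        origins.append(
            AmpOriginSpec(
                origin_id=f"origin{i}",
                breakpoints=bp,
                segment_copies=cp,
                carrier_fraction=1.0 / n_origins,
                population="pop0",
            )
        )
    return SimScenario(
        chrom_length=chrom_length,
        populations=[("pop0", "regionA", n_origins * carriers_per_origin)],
        origins=origins,
        mean_depth=mean_depth,
        site_spacing=site_spacing,
        focal_gene=focal_gene,
        seed=seed,
    )


def random_amp_profile(
    rng: np.random.Generator,
    span: tuple,
    n_segments: int = 4,
    max_copies: int = 6,
):
    """Draw random (breakpoints, segment_copies) for one amplification origin.

    Segment boundaries are uniform within ``span``; copies per segment are
    uniform in {2..max_copies}, so independently drawn origins have
    distinctive step profiles while a shared origin is identical across its
    carriers.
    """
    s, e = span
    inner = np.sort(rng.choice(np.arange(s + 1, e), size=n_segments - 1, replace=False))
    bp = tuple(int(x) for x in np.concatenate([[s], inner, [e]]))
    copies = tuple(int(c) for c in rng.integers(2, max_copies + 1, size=n_segments))
    return bp, copies
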