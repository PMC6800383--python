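# Methods

This note documents the models and estimators implemented in `ampliscan`,
the defaults they ship with, what the synthetic-data generator does and does
not emulate, and the numerical choices that matter for reproducing results.

## Copy number from read depth

Scaled coverage divides each site's depth by the sample's modal genome-wide
depth, computed on the raw integer histogram over sites outside
repeat/centromere masks and with depth ≥ 3 (`min_depth`). The mode rather
than the mean is used because amplified and repetitive sequence inflates the
mean but leaves the single-copy peak of a unimodal depth distribution in
place. Ties are broken toward the smaller depth and no smoothing is applied,
so the estimate is exactly reproducible. Each sample is normalized by its
own mode, since library depth varies per sample. At least 1,000 surviving
sites are required (`min_sites`, relaxable for toy inputs).

Windows are half-open `[start, start + width)` with 1-based starts, 100 bp
wide by default; windows with no covered site are missing (NaN), never zero.
The focal-gene CN is the median window CN over the gene interval — robust to
edge windows and mapping artifacts — and amplification is called by strict
`CN > threshold` with threshold 1.5 (a 2.0 alternative is a flag).

**Known limitation — integer-mode granularity.** The mode of any
overdispersed count distribution with mean *m* sits at an integer below *m*
(for a negative binomial with size *r*, at ⌊m − m/r⌋; in the Poisson limit
the histogram ties at m−1 and m and the tie rule picks m−1). Scaled
coverage therefore carries a systematic scale factor of up to m/(m−1):
about +5% at 20× and +11% at 10×. This is a property of mode normalization
itself, not of the implementation; CN estimates at 10× should be read with
that scale uncertainty in mind. The acceptance suite documents this
honestly: the 10× CN-recovery check against a 10% tolerance fails in the
runs where the sample mode lands one integer below the mean.

## Amplification-origin inference

Carriers of the same amplification event share its piecewise-constant
internal structure, so their windowed scaled-coverage profiles over the
region flanking the focal gene (±500 kb at 1-kb resolution by default; the
analysis drivers use ±300 kb at 2 kb for the smaller simulated chromosome)
are nearly perfectly rank-correlated, while independently arisen
amplifications are not. Spearman's ρ is the Pearson correlation of
mid-ranks (average ranks on ties); it is invariant to any strictly
increasing transform of one profile, hence to amplification amplitude.
Zero-variance profiles make ρ undefined and are reported missing, not 0.
Missing profile windows (≤ 20%) are linearly interpolated — rank statistics
tolerate smooth fill far better than zeros.

Origins are called by average-linkage hierarchical clustering on `1 − ρ`,
cutting the tree where a merge would join clusters whose mean ρ falls below
0.8. The threshold sits between the regimes observed for shared-origin
cohorts (ρ ≈ 0.95) and multi-origin cohorts (ρ ≈ 0.5) and is exposed as a
flag. Missing ρ entries are imputed with the matrix minimum and logged.

## Windowed population-genetic statistics

Per-site, with alt frequency p̂ from n sampled allele copies (missing
genotypes dropped site-wise within each population):

* π = Σ 2p̂(1−p̂)·n/(n−1) over sites, divided by the number of genotyped
  sites (monomorphic sites included when provided). Equals the all-pairs
  allele-copy mismatch average exactly.
* D_xy = Σ [p̂_A(1−p̂_B) + p̂_B(1−p̂_A)] / n_sites.
* F_ST is Hudson-type as a ratio of averages,
  1 − mean(H_within)/mean(H_between), which is stable in windows with few
  sites where an average of per-site ratios is not.

Sliding windows are 100 kb with 10-kb step by default; only full windows
within the observed span are emitted, and windows never span chromosomes.
Outlier windows are those at or above the empirical 99th percentile
(inclusive, so ties at the cutoff all enter).

## f statistic and block jackknife

The proportion-of-introgression estimator uses the homozygous-donor form:
f̂ = S(P1, P2, P3, O) / S(P1, P3, P3, O), with the donor panel substituted
for the recipient in the denominator. With a finite donor panel the plug-in
denominator term E[p̂₃²] exceeds p₃² by the binomial sampling variance and
attenuates f̂ noticeably (e.g. ≈ 0.17 instead of 0.25 with 10 diploids per
panel); passing the donor allele count applies the standard unbiased
estimator p̂(np̂−1)/(n−1) for p₃² and removes the bias. The uncorrected form
remains the default so that the exact identities f̂(p₂≡p₁)=0 and
f̂(p₂≡p₃)=1 hold.

Uncertainty comes from a delete-one-block jackknife over 250-kb tiles of the
coordinate range (≥ 10 non-empty blocks required): pseudovalues
θᵢ = nθ − (n−1)θ₋ᵢ, estimate = mean pseudovalue, SE = sd/√n, normal 95% CI.

## Pseudohaploidization, EHH and XP-EHH

One allele is sampled per heterozygous genotype (alt with probability 1/2,
independent per sample-site, seeded); homozygotes map deterministically and
missing stays missing. Because sampling is independent SNP by SNP it
preserves population allele frequencies and induces no haplotype structure
beyond the diploid input's. One seeded draw is used per analysis; repeat
draws are a sensitivity check, not an average.

EHH at distance x from a core is Σ_g C(n_g,2)/C(n,2) over groups of
haplotypes identical on the stretch from the core out to x; the core site
itself is excluded from the stretch, so EHH(0) = 1 by definition and the
curve is non-increasing outward. Haplotypes with missing data on the
extension path are dropped side-wise rather than imputed, which avoids
fabricating homozygosity. Extension stops when EHH < 0.05 (`cutoff`) or at
`max_extend` (500 kb); if sites run out first the last value is held to
`max_extend` so iHH (trapezoidal integral of EHH over bp, per side) reflects
the full window. XP-EHH is ln(iHH_A/iHH_B) with iHH summed over both sides;
the standardized score subtracts the mean and divides by the SD over all
scanned cores, so it is approximately N(0,1) under neutrality.

## Phenotype and expansion models

Ratings (0 = highly sensitive … 5 = no injury; ≥ 2 classified resistant)
are modeled as a continuous OLS response — the quantities of interest are
R² and the ΔR² from adding target-site allele dosage (0/1/2), which are OLS
notions; a logistic variant on the binary classification is exposed as a
flag without any claim of equivalence. Regressions are per region with ≥ 10
complete samples and nonzero CN variance required.

Gene-family expansion uses a two-way fixed-effects ANOVA,
`cn ~ region * gene`, on per-individual per-gene median CN; when region ×
gene cells are empty the interaction is dropped with a warning. Per-region
least-squares means average predicted cell means with equal gene weights
(so large gene families cannot dominate the contrast), with 95% CIs from
the model covariance.

## Synthetic-data generator

The generator emulates, with one explicit seed feeding per-individual
substreams (adding an individual never perturbs the others):

* **Depth**: negative binomial per site with mean
  `mean_depth × trueCN × bias × mask_inflation`. Default dispersion
  (size) 50 gives var/mean ≈ 1.4 at 20× — moderate overdispersion typical
  of Illumina WGS. Per-site lognormal bias is a site property shared across
  individuals; masked intervals inflate depth by a factor; dropout
  intervals force depth into {0, 1, 2}. Overlapping mask and dropout
  intervals are a configuration error. All interval coordinates are 1-based
  closed.
* **Amplification haplotypes**: piecewise-constant copies per haplotype over
  strictly increasing breakpoints; carriers bear the haplotype on both
  chromosomes, so diploid CN equals the segment copies. The canonical
  origin-cohort scenario uses 30 segments with 2–10 copies over a 600-kb
  span covering the whole profiled region — fine-grained structure that
  mimics the rugged coverage landscape of a large tandem amplification
  (profiles dominated by one long constant segment would leave rank order
  noise-driven even for shared origins).
* **SNP haplotypes**: background frequencies from the folded neutral
  spectrum (P(i) ∝ 1/i); under a sweep, carrier haplotypes copy one of k
  founder haplotypes (hard: k = 1) with retention probability
  exp(−d/decay_length) around the focal gene (default decay 200 kb).
  This founder-copying model reproduces the qualitative hard/soft
  signatures (diversity deficit, long shared haplotypes) without a
  coalescent; it has no recombination map, no mutation after the sweep, and
  no linkage disequilibrium structure in the background.
* **Admixture**: per site the recipient population's frequency derives from
  the donor lineage with probability α and from the sister lineage
  otherwise; lineages diverge from a shared ancestral frequency by
  Balding–Nichols drift (F_ST 0.1) and the outgroup is fixed ancestral,
  so E[f̂] = α by construction. Finite panels are binomially sampled.
* **Phenotypes**: latent liability β₀ + β_cn·CN + β_tsr·TSR + N(0, σ),
  rounded and clamped into 0–5.

What passing tests on this generator shows: the estimators recover the
parameters of data that satisfies their assumptions (unimodal depth,
rank-preserved amplification structure, frequency-preserving
pseudohaploidization, sweep-shaped haplotype sharing). What it does not
show: robustness to GC bias, mapping artifacts correlated with copy number,
reference bias in amplified regions, overlapping/partial amplification
haplotypes, or realistic recombination and demography.

## Numerical and design choices

* Internal coordinates are 1-based (VCF-native); BED converts at the
  boundary (`start + 1`); intervals are closed, analysis windows half-open.
* Depth-histogram mode: first maximum of `np.bincount`, hence smallest on
  ties; no smoothing.
* Clustering merges are average linkage via SciPy with deterministic
  ordering; undefined ρ is missing, imputed only inside `call_origins`.
* The pipeline embeds the config hash and seed in output headers and writes
  no timestamps, so reruns are byte-identical.
* Simulation scales in tests and drivers (1-Mb chromosome, 20–40
  individuals, 2,500 SNPs, 12–50 seeds per check) were chosen to make every
  statistical check decisive at desk scale; all are plain function
  arguments and scale up unchanged.

## Limitations

Mode-granularity scale bias at low depth (above); no breakpoint-precise CNV
calling or GC correction; EHH drops (not imputes) missing haplotypes, which
can bias iHH downward in patchy data; the f statistic's homozygous-donor
form is one member of a family of related estimators and is documented as
implemented, not asserted to match any particular published variant; the
ordinal nature of the 0–5 rating is ignored by the default OLS treatment.
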