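# ampliscan

Population-genomic analysis of gene-amplification-mediated herbicide
resistance, built for the common situation in weed genomics where resistance
arises by tandem amplification of the herbicide's target gene (the canonical
case being *EPSPS* amplification under glyphosate): short-read resequencing
depth carries the copy-number signal, and the questions are *who is
amplified*, *how many independent amplification events occurred*, *what kind
of selective sweep spread them*, *how much ancestry flowed between
populations*, and *how well copy number predicts the resistance phenotype*.

The package is aimed at population geneticists working from per-sample depth
tables and a biallelic SNP VCF. Every analysis stage is a tested library
function; a seeded synthetic-cohort generator provides ground truth for all
of them.

## What it computes

**Copy number from depth.** Scaled coverage of sample *i* at site *s* is
`d_i(s) / m_i`, where `m_i` is the mode of the integer genome-wide depth
histogram after excluding repeat/centromere masks and sites below 3×; the
mode represents single-copy diploid coverage, so 1.0 = normal dosage.
Windowed means (100 bp by default) give per-window CN; the focal-gene CN is
the median window CN over the gene, and `CN > 1.5` (strict) classifies an
individual as amplified.

**Amplification origins.** Carriers of one amplification event share its
internal breakpoint structure, so their coverage profiles over the region
flanking the focal gene are rank-correlated even when amplification
intensity differs. For all pairs of amplified individuals the package
computes Spearman's ρ of windowed scaled coverage, then clusters `1 − ρ`
(average linkage, cut at ρ = 0.8) — the cluster count is the inferred number
of independent amplification events.

**Sweep contrasts.** Genotypes are pseudohaploidized (one random allele per
heterozygous site, seeded) so multi-copy loci cannot inflate within-
individual diversity. Per window the package reports carrier π,
non-carrier π, Δπ and Hudson-type F_ST between groups, plus EHH decay and
XP-EHH = ln(iHH_A / iHH_B) at a core site (positive → longer shared
haplotypes, i.e. a harder/more recent sweep, in group A).

**Introgression.** The ABBA–BABA proportion-of-introgression statistic
f̂ = S(P1, P2, P3, O) / S(P1, P3, P3, O) with
S = Σ_s [(1−p₁)p₂p₃(1−p_O) − p₁(1−p₂)p₃(1−p_O)], an optional finite-panel
correction for the donor term, and a 250-kb block jackknife for the 95% CI.

**Resistance models.** OLS of the 0–5 injury rating on focal CN per region
(R², slope p-value) and the ΔR² from adding the target-site mutation
dosage; two-way region × gene ANOVA with interaction for gene-family
copy-number expansion, with equal-gene-weight least-squares means.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on the bundled
synthetic cohort (20 individuals, two independent amplification origins,
hard sweep among carriers, seed 1) and write tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_copy_number.py
python analysis/03_amplification_origins.py
python analysis/04_sweep_scan.py
python analysis/05_introgression.py
python analysis/06_resistance_models.py
```

which prints:

```
cohort: 20 individuals, 8 amplification carriers across 2 independent origins
8 of 20 individuals classified amplified (truth: 8); calls -> results/cn_calls.csv
inferred 2 independent origins (truth: 2); mean within-cluster rho 0.96, between 0.15
carrier-pi minimum at window [440001, 540001) (focal gene at (495000, 505000)); raw XP-EHH at core = 1.829 (longer haplotypes in carriers)
alpha=0.25: f_hat=0.2434 [0.2064, 0.2803] (20 blocks)
regionA: slope=0.514 (p=4.1e-07), R^2=0.97, delta-R^2(TSR)=0.001
expansion ANOVA: LS means agricultural 1.977 [1.956, 1.998] vs natural 1.798 [1.777, 1.819] (true shift 0.2)
```

Reading the output: all 8 true carriers are recovered by the CN > 1.5 rule;
the pairwise-ρ clustering separates the two amplification haplotypes cleanly
(within-cluster ρ ≈ 0.96 vs ≈ 0.15 between); the carrier-diversity minimum
and positive XP-EHH localize the hard sweep at the focal gene; the f̂ CI
covers the true mixture proportion 0.25; and the rating regression and
expansion ANOVA recover the simulated effect sizes.

The same pipeline is exposed as a CLI (`ampliscan all --seed 1 --outdir out/`)
whose outputs embed the config hash and seed and are byte-identical across
reruns.

## Layout

```
src/ampliscan/     library: sim, coverage, origins, popgen, sweep,
                   resistance, io_utils, cli
analysis/          numbered narrative drivers over the library
tests/             pytest suite (unit, property, end-to-end)
scripts/           acceptance.py
docs/methods.md    models, estimators, parameter defaults, limitations
```
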