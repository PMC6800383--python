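"""Windowed diversity and differentiation statistics, the ABBA-BABA f
admixture-proportion estimator, and block-jackknife uncertainty.

Per-site definitions (all on alt-allele frequency p with n sampled allele
copies):

* pi: unbiased mean pairwise difference, 2 p (1 - p) n / (n - 1), summed over
  sites and divided by the number of genotyped sites in the window
  (monomorphic sites included when provided).
* Dxy: p_A (1 - p_B) + p_B (1 - p_A), averaged the same way.
* Fst: Hudson-type ratio of averages, 1 - mean(H_within) / mean(H_between),
  with H_within the average of the two populations' unbiased
  heterozygosities and H_between the Dxy site term; a ratio of averages is
  robust in windows with few sites, unlike an average of per-site ratios.
* f: the "homozygous-donor" ABBA-BABA proportion-of-introgression form,
  S(P1, P2, P3, O) / S(P1, P3, P3, O), which substitutes the donor panel
  for the recipient in the denominator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import FEstimate, GenotypeMatrix

__all__ = [
    "allele_stats",
    "pi",
    "pi_haplotypes",
    "dxy",
    "fst",
    "windowed_scan",
    "outlier_windows",
    "f_admixture",
    "block_jackknife",
    "f_with_jackknife",
]


def allele_stats(genos: np.ndarray):
    """Per-site (n allele copies, alt count, alt frequency) from dosage rows.

    ``genos`` is (n_samples, n_sites) with -1 for missing; missing genotypes
    are dropped site-wise (complete-case within the population).
    """
    genos = np.asarray(genos)
    present = genos >= 0
    n = 2 * present.sum(axis=0)
    alt = np.where(present, genos, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return n, alt, p


def _het_unbiased(n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Unbiased expected heterozygosity 2p(1-p)n/(n-1); NaN where n < 2."""
    with np.errstate(invalid="ignore", divide="ignore"):
        h = 2.0 * p * (1.0 - p) * n / np.maximum(n - 1.0, 1e-12)
    return np.where(n >= 2, h, np.nan)


def pi(genos: np.ndarray) -> float:
    """Nucleotide diversity per site for one population's dosage rows.

    Equals the brute-force mean pairwise haplotype difference per genotyped
    site; monomorphic sites contribute 0 to the numerator but count in the
    denominator.  Returns NaN for an empty window.
    """
    n, _, p = allele_stats(genos)
    h = _het_unbiased(n, p)
    usable = np.isfinite(h)
    if not usable.any():
        return float("nan")
    return float(np.nansum(h[usable]) / usable.sum())


def pi_haplotypes(haps: np.ndarray) -> float:
    """Nucleotide diversity for haploid allele rows ({0,1}, -1 missing).

    Each row contributes one allele copy per site; otherwise identical to
    :func:`pi` (unbiased per-site heterozygosity, averaged over genotyped
    sites).  For two haploid sequences this is exactly the fraction of
    differing sites.
    """
    haps = np.asarray(haps)
    present = haps >= 0
    n = present.sum(axis=0)
    alt = np.where(present, haps, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    h = _het_unbiased(n.astype(float), p)
    usable = np.isfinite(h)
    if not usable.any():
        return float("nan")
    return float(np.nansum(h[usable]) / usable.sum())


def dxy(genos_a: np.ndarray, genos_b: np.ndarray) -> float:
    """Mean between-population pairwise difference per site."""
    na, _, pa = allele_stats(genos_a)
    nb, _, pb = allele_stats(genos_b)
    term = pa * (1.0 - pb) + pb * (1.0 - pa)
    usable = (na >= 1) & (nb >= 1) & np.isfinite(term)
    if not usable.any():
        return float("nan")
    return float(term[usable].sum() / usable.sum())


def fst(genos_a: np.ndarray, genos_b: np.ndarray) -> float:
    """Hudson-type Fst, ratio of averages over usable sites.

    Sites where either population has fewer than 2 allele copies are
    skipped.  Returns NaN when no usable site exists or mean H_between is 0.
    """
    na, _, pa = allele_stats(genos_a)
    nb, _, pb = allele_stats(genos_b)
    hw = (_het_unbiased(na, pa) + _het_unbiased(nb, pb)) / 2.0
    hb = pa * (1.0 - pb) + pb * (1.0 - pa)
    usable = np.isfinite(hw) & np.isfinite(hb)
    if not usable.any():
        return float("nan")
    mean_hb = hb[usable].mean()
    if mean_hb == 0:
        return float("nan")
    return float(1.0 - hw[usable].mean() / mean_hb)


def _window_starts(pos_min: int, pos_max: int, window: int, step: int):
    """Starts of full windows: only windows lying entirely within the span
    of observed sites are emitted (no partial trailing windows)."""
    first = ((pos_min - 1) // step) * step + 1
    last = pos_max - window + 1
    return np.arange(first, max(last, first) + 1, step, dtype=np.int64)


def windowed_scan(
    genos: GenotypeMatrix,
    populations: dict,
    window: int = 100_000,
    step: int = 10_000,
) -> pd.DataFrame:
    """Sliding-window pi / Dxy / Fst for every population (pair).

    ``populations`` maps population name -> list of sample ids.  Windows are
    [start, start + window) advancing by ``step``; set step = window for the
    nonoverlapping mode used by the f statistic.  Windows never span
    chromosomes (the matrix holds one chromosome).
    """
    if step > window:
        raise ValueError("step must not exceed window in sliding mode")
    pos = genos.positions
    rows = []
    pop_idx = {
        p: [genos.sample_ids.index(s) for s in ids] for p, ids in populations.items()
    }
    if len(pos) == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_sites", "stat", "value"]
        )
    for start in _window_starts(int(pos.min()), int(pos.max()), window, step):
        end = start + window
        lo, hi = np.searchsorted(pos, [start, end])
        if hi <= lo:
            continue
        stats = {}
        for p, idx in pop_idx.items():
            stats[f"pi_{p}"] = pi(genos.genotypes[idx, lo:hi])
        names = sorted(pop_idx)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                ga = genos.genotypes[pop_idx[a], lo:hi]
                gb = genos.genotypes[pop_idx[b], lo:hi]
                stats[f"dxy_{a}_{b}"] = dxy(ga, gb)
                stats[f"fst_{a}_{b}"] = fst(ga, gb)
        for stat, value in stats.items():
            rows.append(
                {
                    "chrom": genos.chrom,
                    "start": int(start),
                    "end": int(end),
                    "n_sites": int(hi - lo),
                    "stat": stat,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)


def outlier_windows(
    values: np.ndarray, quantile: float = 0.99
) -> np.ndarray:
    """Indices of windows at or above the empirical upper quantile.

    The cutoff is computed on non-missing values; ties at the cutoff are all
    included (inclusive >=).  Requires >= 100 windows for the tail to mean
    anything.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if not finite.any():
        raise ValueError("all window statistics missing")
    if len(values) < 100:
        raise ValueError("need >= 100 windows for outlier classification")
    cutoff = np.quantile(values[finite], quantile)
    return np.flatnonzero(finite & (values >= cutoff))


def _f_sums(p1, p2, p3, pO):
    """Numerator-style ABBA-BABA sum S for one (P1, P2, P3, O) slot filling."""
    return float(np.sum((1 - p1) * p2 * p3 * (1 - pO) - p1 * (1 - p2) * p3 * (1 - pO)))


def f_admixture(p1, p2, p3, pO, n3: int | None = None) -> float:
    """Proportion of introgression: f = S(P1,P2,P3,O) / S(P1,P3,P3,O).

    The denominator replaces the recipient P2 with a second copy of the
    donor panel P3, i.e. the expected signal under complete replacement.
    Sites contributing 0 to the denominator stay in the sums.

    The denominator's S(P1,P3,P3,O) reduces to sum of (p3^2 - p1 p3); with a
    finite donor panel E[p-hat^2] exceeds p^2 by the binomial sampling
    variance, which attenuates f.  Passing ``n3`` (the number of sampled
    allele copies in the P3 panel) replaces p3^2 with its unbiased
    estimator p-hat (n p-hat - 1) / (n - 1).  Without ``n3`` the raw
    plug-in form is used, for which p2 == p3 gives exactly 1.
    """
    arrs = [np.asarray(a, dtype=float) for a in (p1, p2, p3, pO)]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("frequency arrays must share one site set")
    for a in arrs:
        if ((a < 0) | (a > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")
    p1, p2, p3, pO = arrs
    if n3 is None:
        denom = _f_sums(p1, p3, p3, pO)
    else:
        if n3 < 2:
            raise ValueError("n3 must be >= 2 allele copies")
        p3_sq = p3 * (n3 * p3 - 1.0) / (n3 - 1.0)
        denom = float(np.sum((p3_sq - p1 * p3) * (1 - pO)))
    if denom == 0:
        raise ZeroDivisionError("f undefined: denominator sum is 0")
    return _f_sums(p1, p2, p3, pO) / denom


def block_jackknife(
    stat_fn,
    positions: np.ndarray,
    block: int = 250_000,
    min_blocks: int = 10,
) -> FEstimate:
    """Delete-one-block jackknife over contiguous genomic blocks.

    ``stat_fn(keep_mask)`` must return the statistic computed on the sites
    where ``keep_mask`` is True.  Blocks partition the coordinate range into
    ``block``-bp tiles; empty tiles are dropped.  Pseudovalues
    theta_i = n theta_all - (n - 1) theta_(-i); the estimate is their mean,
    SE their sd / sqrt(n), CI the normal +/- 1.96 SE interval.
    """
    positions = np.asarray(positions, dtype=np.int64)
    block_of = (positions - 1) // block
    blocks = np.unique(block_of)
    n = len(blocks)
    if n < min_blocks:
        raise ValueError(f"only {n} non-empty blocks (< {min_blocks})")
    full = np.ones(len(positions), dtype=bool)
    theta_all = stat_fn(full)
    pseudo = np.empty(n)
    for i, b in enumerate(blocks):
        keep = block_of != b
        pseudo[i] = n * theta_all - (n - 1) * stat_fn(keep)
    est = float(pseudo.mean())
    se = float(pseudo.std(ddof=1) / np.sqrt(n))
    return FEstimate(
        f_hat=est,
        se=se,
        ci_low=est - 1.96 * se,
        ci_high=est + 1.96 * se,
        n_blocks=int(n),
        block_size=int(block),
    )


def f_with_jackknife(
    freqs: dict, block: int = 250_000, n3: int | None = None
) -> FEstimate:
    """f-hat with a 250-kb block jackknife CI from a (P1,P2,P3,O) table.

    ``freqs`` has arrays 'pos', 'p1', 'p2', 'p3', 'pO' (as produced by
    :func:`ampliscan.sim.simulate_admixture`, whose 'n3' entry carries the
    donor-panel allele count for the finite-panel correction).
    """
    if n3 is None:
        n3 = freqs.get("n3")

    def stat(mask):
        return f_admixture(
            freqs["p1"][mask],
            freqs["p2"][mask],
            freqs["p3"][mask],
            freqs["pO"][mask],
            n3=n3,
        )

    return block_jackknife(stat, freqs["pos"], block=block)
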