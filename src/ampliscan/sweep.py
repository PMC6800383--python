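"""Pseudohaploid construction and haplotype-homozygosity sweep contrasts.

High-copy loci can carry more alleles per individual than a diploid caller
reports, inflating apparent diversity within individuals.  Sampling one
allele per heterozygous genotype (pseudohaploidization) makes amplified and
non-amplified individuals comparable: any excess differentiation then
reflects differences among individuals, not among haplotypes within them.
Because sampling is independent SNP by SNP it preserves population allele
frequencies and induces no haplotype structure beyond the diploid input's.

EHH from a core site is the probability that two randomly chosen haplotypes
are identical over the stretch from the core out to a given distance,
estimated as sum over identity groups g of C(n_g, 2) / C(n, 2).  XP-EHH
compares the area under the EHH curve (iHH) between two groups:
ln(iHH_A / iHH_B), positive when group A carries longer shared haplotypes
(a more recent or harder sweep).
"""

from __future__ import annotations

import logging

import numpy as np

from .types import EHHDecay, GenotypeMatrix, PseudohaploidMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "pseudohaploidize",
    "ehh",
    "xpehh",
    "xpehh_scan",
    "amplified_contrast",
]


def pseudohaploidize(genos: GenotypeMatrix, seed: int) -> PseudohaploidMatrix:
    """Sample one allele per sample per site.

    Homozygous dosage maps deterministically (0 -> 0, 2 -> 1); heterozygous
    sites draw alt with probability 1/2, independently per sample-site;
    missing stays missing.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(11,)))
    g = genos.genotypes
    draws = (rng.random(g.shape) < 0.5).astype(np.int8)
    alleles = np.where(g == 1, draws, g // 2).astype(np.int8)
    alleles[g == -1] = -1
    return PseudohaploidMatrix(
        sample_ids=list(genos.sample_ids),
        chrom=genos.chrom,
        positions=genos.positions.copy(),
        alleles=alleles,
        seed=seed,
    )


def _ehh_one_side(haps: np.ndarray, positions: np.ndarray, core_idx: int,
                  direction: int, cutoff: float, max_extend: float):
    """EHH decay walking site by site away from the core on one side.

    Haplotypes with missing data anywhere on the path so far are dropped
    for that side (no homozygosity is fabricated by imputation).  Returns
    (distances >= 0, ehh values, ihh).
    """
    core_pos = positions[core_idx]
    order = (
        range(core_idx + 1, haps.shape[1])
        if direction > 0
        else range(core_idx - 1, -1, -1)
    )
    alive = haps[:, core_idx] >= 0
    n0 = int(alive.sum())
    if n0 < 4:
        raise ValueError("need >= 4 haplotypes without missing data at the core")

    distances = [0.0]
    ehh_vals = [1.0]
    # identity groups keyed by the haplotype prefix seen so far
    keys = np.zeros(haps.shape[0], dtype=np.int64)
    for j in order:
        d = abs(int(positions[j]) - int(core_pos))
        if d > max_extend:
            break
        alive &= haps[:, j] >= 0
        n = int(alive.sum())
        if n < 2:
            break
        # refine identity groups with this site's allele; re-key through
        # np.unique so keys stay bounded by the haplotype count
        combo = keys * 2 + np.where(haps[:, j] > 0, 1, 0)
        _, keys = np.unique(combo, return_inverse=True)
        _, counts = np.unique(keys[alive], return_counts=True)
        num = (counts * (counts - 1) // 2).sum()
        den = n * (n - 1) // 2
        e = num / den
        distances.append(float(d))
        ehh_vals.append(float(e))
        if e < cutoff:
            break
    # extension exhausted sites while still homozygous enough: hold the last
    # value out to max_extend so iHH reflects the full window
    if distances[-1] < max_extend and ehh_vals[-1] >= cutoff:
        distances.append(float(max_extend))
        ehh_vals.append(ehh_vals[-1])
    ihh = float(np.trapezoid(ehh_vals, distances))
    return np.asarray(distances), np.asarray(ehh_vals), ihh


def ehh(
    haps: PseudohaploidMatrix,
    core_pos: int,
    cutoff: float = 0.05,
    max_extend: float = 500_000.0,
    group: str = "",
) -> EHHDecay:
    """EHH decay in both directions from the core, with per-side iHH.

    Extension stops when EHH drops below ``cutoff`` or ``max_extend`` bp is
    reached; iHH is the trapezoidal integral of EHH over physical distance
    on each side.  EHH at distance 0 is 1 by definition and the curve is
    non-increasing with distance on each side.
    """
    core_idx = int(np.searchsorted(haps.positions, core_pos))
    if core_idx >= len(haps.positions) or haps.positions[core_idx] != core_pos:
        core_idx = int(np.argmin(np.abs(haps.positions - core_pos)))
    a = haps.alleles
    dl, el, ihh_l = _ehh_one_side(a, haps.positions, core_idx, -1, cutoff, max_extend)
    dr, er, ihh_r = _ehh_one_side(a, haps.positions, core_idx, +1, cutoff, max_extend)
    distances = np.concatenate([-dl[::-1], dr[1:]])
    values = np.concatenate([el[::-1], er[1:]])
    return EHHDecay(
        core_pos=int(haps.positions[core_idx]),
        group=group,
        distances=distances,
        ehh=values,
        ihh_left=ihh_l,
        ihh_right=ihh_r,
    )


def _subset(haps: PseudohaploidMatrix, ids) -> PseudohaploidMatrix:
    idx = [haps.sample_ids.index(s) for s in ids]
    return PseudohaploidMatrix(
        sample_ids=list(ids),
        chrom=haps.chrom,
        positions=haps.positions,
        alleles=haps.alleles[idx],
        seed=haps.seed,
    )


def xpehh(
    haps_a: PseudohaploidMatrix,
    haps_b: PseudohaploidMatrix,
    core_pos: int,
    cutoff: float = 0.05,
    max_extend: float = 500_000.0,
) -> float:
    """Unstandardized XP-EHH at one core: ln(iHH_A / iHH_B), iHH summed over
    both sides.  Positive values mean longer shared haplotypes in group A.
    Returns NaN with a warning when iHH_B is 0."""
    ea = ehh(haps_a, core_pos, cutoff=cutoff, max_extend=max_extend, group="A")
    eb = ehh(haps_b, core_pos, cutoff=cutoff, max_extend=max_extend, group="B")
    if eb.ihh == 0:
        logger.warning("iHH of group B is 0 at core %d; XP-EHH undefined", core_pos)
        return float("nan")
    if ea.ihh == 0:
        return float("nan")
    return float(np.log(ea.ihh / eb.ihh))


def xpehh_scan(
    haps_a: PseudohaploidMatrix,
    haps_b: PseudohaploidMatrix,
    core_positions,
    cutoff: float = 0.05,
    max_extend: float = 500_000.0,
):
    """Raw and genome-standardized XP-EHH over a set of cores.

    The standardized score subtracts the mean and divides by the SD of the
    raw scores across all scanned cores, so under neutrality it is
    approximately standard normal.
    """
    raw = np.array(
        [
            xpehh(haps_a, haps_b, int(c), cutoff=cutoff, max_extend=max_extend)
            for c in core_positions
        ]
    )
    finite = np.isfinite(raw)
    if finite.sum() >= 2 and np.nanstd(raw) > 0:
        z = (raw - np.nanmean(raw)) / np.nanstd(raw)
    else:
        z = np.full_like(raw, np.nan)
    return raw, z


def amplified_contrast(
    genos: GenotypeMatrix,
    amplified: dict,
    region: tuple,
    window: int = 100_000,
    step: int = 10_000,
):
    """Per-window pi_amplified, pi_nonamplified, delta-pi and between-group
    Fst across ``region``.

    ``amplified`` maps sample_id -> bool (from the CN classifier).  Groups
    of size < 2 yield missing statistics with a logged warning.
    """
    import pandas as pd

    from .popgen import fst as _fst
    from .popgen import pi as _pi

    amp_ids = [s for s in genos.sample_ids if amplified.get(s)]
    non_ids = [s for s in genos.sample_ids if s in amplified and not amplified[s]]
    if len(amp_ids) < 2 or len(non_ids) < 2:
        logger.warning(
            "group sizes %d amplified / %d non-amplified; statistics missing",
            len(amp_ids),
            len(non_ids),
        )
    amp_idx = [genos.sample_ids.index(s) for s in amp_ids]
    non_idx = [genos.sample_ids.index(s) for s in non_ids]
    pos = genos.positions
    start, end = region
    rows = []
    for ws in range(int(start), int(end), step):
        we = ws + window
        if we > end:
            break
        lo, hi = np.searchsorted(pos, [ws, we])
        if hi <= lo:
            continue
        pa = _pi(genos.genotypes[amp_idx, lo:hi]) if len(amp_idx) >= 2 else np.nan
        pn = _pi(genos.genotypes[non_idx, lo:hi]) if len(non_idx) >= 2 else np.nan
        f = (
            _fst(genos.genotypes[amp_idx, lo:hi], genos.genotypes[non_idx, lo:hi])
            if len(amp_idx) >= 2 and len(non_idx) >= 2
            else np.nan
        )
        rows.append(
            {
                "chrom": genos.chrom,
                "start": ws,
                "end": we,
                "n_sites": int(hi - lo),
                "pi_amplified": pa,
                "pi_nonamplified": pn,
                "delta_pi": pn - pa if np.isfinite(pa) and np.isfinite(pn) else np.nan,
                "fst": f,
            }
        )
    return pd.DataFrame(rows)
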