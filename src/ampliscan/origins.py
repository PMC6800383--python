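"""Amplification-profile similarity and origin counting.

Independent tandem-amplification events create distinct piecewise coverage
profiles over the amplified region, while carriers of a shared origin show
near-identical profiles.  Spearman's rank correlation of windowed scaled
coverage over the region surrounding the focal gene quantifies similarity in
the rank — not the amplitude — of the copy-number landscape, so carriers of
the same origin at different amplification intensities still correlate
highly.  Average-linkage clustering of 1 - rho with a cut at a configurable
rho threshold turns the pairwise matrix into an origin count.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .types import CopyNumberProfile, OriginCall, ProfileCorrelation

logger = logging.getLogger(__name__)

__all__ = [
    "extract_profile",
    "spearman_rho",
    "pairwise_matrix",
    "group_mean_rho",
    "call_origins",
]


def extract_profile(
    track,
    scaled: np.ndarray,
    focal_gene: tuple,
    flank: int = 500_000,
    resolution: int = 1000,
    max_missing_frac: float = 0.2,
) -> np.ndarray:
    """Windowed mean scaled coverage over the region flanking the focal gene.

    The profile covers ``[center - flank, center + flank)`` at ``resolution``
    bp per window (2 * flank / resolution windows).  Windows without covered
    sites are linearly interpolated from their neighbors; a profile with
    more than ``max_missing_frac`` missing windows raises, since rank
    correlation on a mostly-interpolated vector is unreliable.
    """
    gs, ge = focal_gene
    center = (gs + ge) // 2
    start = center - flank
    end = center + flank
    from .coverage import windowed_cn

    prof = windowed_cn(track, scaled, (start, end), window_width=resolution)
    cn = prof.cn.copy()
    missing = ~np.isfinite(cn)
    if missing.mean() > max_missing_frac:
        raise ValueError(
            f"{missing.mean():.0%} of profile windows missing "
            f"(> {max_missing_frac:.0%}); profile unreliable"
        )
    if missing.any():
        x = np.arange(len(cn))
        cn[missing] = np.interp(x[missing], x[~missing], cn[~missing])
    return cn


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks
    (ties get the average rank).

    Returns NaN (missing, not 0) when either vector has zero variance,
    where the statistic is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("profiles must have equal length")
    if len(x) < 10:
        raise ValueError("need >= 10 windows for a meaningful rank correlation")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("profiles must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho = spearmanr(x, y).statistic
    return float(rho)


def pairwise_matrix(
    profiles: dict, labels: dict, region_of_interest: tuple = (0, 0)
) -> ProfileCorrelation:
    """All-pairs Spearman rho among amplified individuals' profiles.

    Rank correlation is invariant to positive rescaling of any single
    profile, so amplitude differences between carriers do not matter.
    Samples whose profile is constant (undefined rho) yield NaN rows,
    logged as a warning.
    """
    ids = sorted(profiles)
    if len(ids) < 2:
        raise ValueError("need >= 2 amplified samples")
    n = len(ids)
    rho = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                r = spearman_rho(profiles[ids[i]], profiles[ids[j]])
            except ValueError:
                r = float("nan")
            if not np.isfinite(r):
                logger.warning(
                    "undefined rho for pair (%s, %s); recorded as missing",
                    ids[i],
                    ids[j],
                )
            rho[i, j] = rho[j, i] = r
    return ProfileCorrelation(
        sample_ids=ids,
        rho=rho,
        labels={s: labels[s] for s in ids},
        region_of_interest=region_of_interest,
    )


def _off_diagonal(rho: np.ndarray, idx_a, idx_b=None) -> np.ndarray:
    """Off-diagonal entries within idx_a, or spanning idx_a x idx_b."""
    if idx_b is None:
        vals = [rho[i, j] for k, i in enumerate(idx_a) for j in idx_a[k + 1 :]]
    else:
        vals = [rho[i, j] for i in idx_a for j in idx_b]
    return np.asarray(vals, dtype=float)


def group_mean_rho(corr: ProfileCorrelation, grouping: str = "population") -> dict:
    """Mean off-diagonal rho within each group, between groups, and overall.

    ``grouping`` selects 'population' or 'region' from the sample labels.
    Singleton groups have no within-group pairs and report NaN.
    """
    field = {"population": 0, "region": 1}[grouping]
    groups: dict = {}
    for i, s in enumerate(corr.sample_ids):
        groups.setdefault(corr.labels[s][field], []).append(i)

    out = {"within": {}, "between": {}, "overall": float("nan")}
    all_off = _off_diagonal(corr.rho, list(range(len(corr.sample_ids))))
    out["overall"] = float(np.nanmean(all_off)) if len(all_off) else float("nan")
    names = sorted(groups)
    for g in names:
        vals = _off_diagonal(corr.rho, groups[g])
        out["within"][g] = float(np.nanmean(vals)) if len(vals) else float("nan")
    for a_i, ga in enumerate(names):
        for gb in names[a_i + 1 :]:
            vals = _off_diagonal(corr.rho, groups[ga], groups[gb])
            out["between"][(ga, gb)] = (
                float(np.nanmean(vals)) if len(vals) else float("nan")
            )
    return out


def call_origins(corr: ProfileCorrelation, rho_threshold: float = 0.8) -> OriginCall:
    """Cluster carriers into independent amplification origins.

    Average-linkage hierarchical clustering on distance 1 - rho, cut where a
    merge would join clusters whose average rho falls below
    ``rho_threshold``; the number of resulting clusters is the inferred
    number of independent amplification events.  Missing rho entries are
    imputed with the matrix minimum (most conservative: treats the pair as
    maximally dissimilar among observed values) and logged.
    """
    n = len(corr.sample_ids)
    if n < 2:
        raise ValueError("need >= 2 samples")
    rho = corr.rho.copy()
    off = ~np.eye(n, dtype=bool)
    missing = off & ~np.isfinite(rho)
    if missing.any():
        fill = np.nanmin(rho[off]) if np.isfinite(rho[off]).any() else -1.0
        logger.warning(
            "imputing %d missing rho entries with matrix minimum %.3f",
            int(missing.sum()) // 2,
            fill,
        )
        rho[missing] = fill
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    condensed = squareform((dist + dist.T) / 2.0, checks=False)
    link = average(condensed)
    cluster = fcluster(link, t=1.0 - rho_threshold, criterion="distance")

    within, between = [], []
    for i in range(n):
        for j in range(i + 1, n):
            (within if cluster[i] == cluster[j] else between).append(rho[i, j])
    return OriginCall(
        sample_ids=list(corr.sample_ids),
        cluster=cluster,
        n_origins=int(cluster.max()),
        linkage_threshold=rho_threshold,
        mean_within_rho=float(np.mean(within)) if within else float("nan"),
        mean_between_rho=float(np.mean(between)) if between else float("nan"),
    )
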