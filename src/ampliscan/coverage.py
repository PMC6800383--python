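"""Mode-normalized copy number from per-site read depth.

The normalizer is the modal genome-wide depth of each sample, computed on
the integer depth histogram after excluding repeat/centromeric intervals and
low-coverage sites (< 3x by default): the mode represents the depth of
single-copy sequence, so scaled coverage of 1.0 means normal diploid dosage.
Each sample is normalized by its own mode because per-sample sequencing
depth varies.
"""

from __future__ import annotations

import numpy as np

from .types import CopyNumberProfile, CoverageNormalizer, DepthTrack

__all__ = [
    "estimate_mode_depth",
    "normalize",
    "windowed_cn",
    "gene_median_cn",
    "classify_amplified",
    "focal_cn",
]


def _mask_sites(positions: np.ndarray, intervals) -> np.ndarray:
    """Boolean array: True where a position falls inside any interval
    (1-based closed; intervals may carry extra trailing fields)."""
    masked = np.zeros(len(positions), dtype=bool)
    for iv in intervals:
        s, e = iv[0], iv[1]
        masked |= (positions >= s) & (positions <= e)
    return masked


def estimate_mode_depth(
    track: DepthTrack,
    mask_intervals=(),
    min_depth: int = 3,
    min_sites: int = 1000,
) -> CoverageNormalizer:
    """Modal depth over unmasked sites with depth >= ``min_depth``.

    The mode is taken on the raw integer histogram (no smoothing); ties are
    broken toward the smaller depth so the estimate is reproducible.
    Fewer than ``min_sites`` surviving sites raises, because a mode from a
    thin histogram makes normalization unreliable.
    """
    masked = _mask_sites(track.positions, mask_intervals)
    keep = ~masked & (track.depth >= min_depth)
    surviving = track.depth[keep]
    if len(surviving) < min_sites:
        raise ValueError(
            f"only {len(surviving)} sites survive exclusions "
            f"(< {min_sites}); mode estimate unreliable"
        )
    counts = np.bincount(surviving)
    mode = int(np.argmax(counts))  # argmax returns the first (smallest) maximum
    return CoverageNormalizer(
        sample_id=track.sample_id,
        mode_depth=float(mode),
        excluded_mask=list(mask_intervals),
        n_sites_used=int(len(surviving)),
    )


def normalize(track: DepthTrack, normalizer: CoverageNormalizer) -> np.ndarray:
    """Per-site scaled coverage: depth / modal depth (1.0 = diploid single copy)."""
    if track.sample_id != normalizer.sample_id:
        raise ValueError(
            f"normalizer for {normalizer.sample_id!r} applied to track "
            f"{track.sample_id!r}"
        )
    return track.depth / normalizer.mode_depth


def windowed_cn(
    track: DepthTrack,
    scaled: np.ndarray,
    region: tuple,
    window_width: int = 100,
) -> CopyNumberProfile:
    """Mean scaled coverage in fixed windows tiling ``region``.

    ``region`` is (start, end), 1-based half-open.  Each window's CN is the
    mean scaled coverage over sites in [start, start + width); windows with
    no covered site are NaN (missing), never zero.
    """
    start, end = region
    if end <= start:
        raise ValueError(f"empty region ({start}, {end})")
    window_starts = np.arange(start, end, window_width, dtype=np.int64)
    idx = np.searchsorted(track.positions, [start, end])
    pos = track.positions[idx[0] : idx[1]]
    vals = scaled[idx[0] : idx[1]]
    which = (pos - start) // window_width
    sums = np.bincount(which, weights=vals, minlength=len(window_starts))
    counts = np.bincount(which, minlength=len(window_starts))
    with np.errstate(invalid="ignore"):
        cn = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return CopyNumberProfile(
        sample_id=track.sample_id,
        chrom=track.chrom,
        region=(start, end),
        window_starts=window_starts,
        cn=cn,
        window_width=window_width,
    )


def gene_median_cn(profile: CopyNumberProfile, gene_intervals: dict) -> dict:
    """Median window CN within each gene for one individual.

    ``gene_intervals`` maps gene_id -> (start, end), 1-based half-open.
    Genes with no non-missing window report NaN.  The median across a gene's
    100-bp windows is robust to paralog-specific mapping artifacts that
    inflate individual windows.
    """
    out = {}
    w = profile.window_width
    for gene, (gs, ge) in gene_intervals.items():
        # windows [ws, ws+w) overlapping [gs, ge)
        sel = (profile.window_starts + w > gs) & (profile.window_starts < ge)
        vals = profile.cn[sel]
        vals = vals[np.isfinite(vals)]
        out[gene] = float(np.median(vals)) if len(vals) else float("nan")
    return out


def classify_amplified(cn_focal: float, threshold: float = 1.5) -> bool:
    """True iff focal CN strictly exceeds ``threshold`` (default 1.5)."""
    if cn_focal < 0:
        raise ValueError("copy number cannot be negative")
    return bool(cn_focal > threshold)


def focal_cn(profile: CopyNumberProfile, focal_gene: tuple) -> float:
    """Focal-gene CN for classification: median window CN across the gene
    interval (robust to edge windows)."""
    return gene_median_cn(profile, {"focal": focal_gene})["focal"]
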