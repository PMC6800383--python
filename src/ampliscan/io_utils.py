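"""Readers and writers for the formats the pipeline touches.

Internal coordinates are 1-based closed (VCF-native).  BED input is 0-based
half-open and converted at the boundary (start + 1); bedGraph output keeps
BED convention.  Every table the pipeline writes embeds the run seed and a
hash of the configuration in comment headers so reruns are verifiable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CopyNumberProfile, DepthTrack, GenotypeMatrix

__all__ = [
    "read_depth_tsv",
    "write_depth_tsv",
    "read_bed",
    "write_bedgraph",
    "read_bedgraph",
    "read_vcf",
    "write_vcf",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_config",
    "config_hash",
    "header_lines",
]


def read_depth_tsv(path, sample_id: str | None = None) -> DepthTrack:
    """Per-sample depth table: 3 columns (chrom, 1-based pos, depth), no header.

    Positions must be strictly increasing within the chromosome; the first
    offending line is named on error.  An empty file yields an empty track.
    """
    path = Path(path)
    sample_id = sample_id or path.stem.split(".")[0]
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            rows.append((parts[0], int(parts[1]), int(parts[2])))
    if not rows:
        return DepthTrack(
            sample_id=sample_id,
            chrom="",
            positions=np.empty(0, dtype=np.int64),
            depth=np.empty(0, dtype=np.int64),
        )
    chroms = {r[0] for r in rows}
    if len(chroms) > 1:
        raise ValueError(f"{path}: multiple chromosomes in one track not supported")
    pos = np.array([r[1] for r in rows], dtype=np.int64)
    bad = np.flatnonzero(np.diff(pos) <= 0)
    if len(bad):
        raise ValueError(f"{path}: positions not strictly increasing at line {bad[0] + 2}")
    return DepthTrack(
        sample_id=sample_id,
        chrom=rows[0][0],
        positions=pos,
        depth=np.array([r[2] for r in rows], dtype=np.int64),
    )


def write_depth_tsv(track: DepthTrack, path) -> None:
    with open(path, "w") as fh:
        for p, d in zip(track.positions, track.depth):
            fh.write(f"{track.chrom}\t{p}\t{d}\n")


def read_bed(path) -> list:
    """BED intervals (0-based half-open) -> internal 1-based closed
    [(chrom, start+1, end, name?)]: BED "99 200" covers bases 100..200."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else None
            out.append((chrom, start + 1, end, name))
    return out


def write_bedgraph(profile: CopyNumberProfile, path, header: list | None = None):
    """CN profile as bedGraph (0-based half-open); missing windows skipped."""
    with open(path, "w") as fh:
        for line in header or []:
            fh.write(f"#{line}\n")
        for ws, cn in zip(profile.window_starts, profile.cn):
            if np.isfinite(cn):
                fh.write(
                    f"{profile.chrom}\t{ws - 1}\t{ws - 1 + profile.window_width}\t{cn:.6f}\n"
                )


def read_bedgraph(path, sample_id: str = "") -> CopyNumberProfile:
    rows = []
    chrom = ""
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track")):
                continue
            c, s, e, v = line.rstrip("\n").split("\t")
            chrom = c
            rows.append((int(s) + 1, int(e) - int(s), float(v)))
    if not rows:
        raise ValueError(f"{path}: empty bedGraph")
    width = rows[0][1]
    return CopyNumberProfile(
        sample_id=sample_id,
        chrom=chrom,
        region=(rows[0][0], rows[-1][0] + width),
        window_starts=np.array([r[0] for r in rows], dtype=np.int64),
        cn=np.array([r[2] for r in rows]),
        window_width=width,
    )


def read_vcf(path, populations: dict | None = None) -> GenotypeMatrix:
    """Biallelic SNP dosage matrix from a VCF with GT.

    Multiallelic records are skipped with a logged count; ./. becomes the
    missing sentinel.  One chromosome per file is assumed (the pipeline's
    focal analyses are single-chromosome).
    """
    import logging

    from cyvcf2 import VCF

    logger = logging.getLogger(__name__)
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    positions, rows, ref, alt = [], [], [], []
    chrom = ""
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        chrom = rec.CHROM
        positions.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (gts012), 3=missing;
        # copy because cyvcf2 reuses the buffer across records
        rows.append(np.array(rec.gt_types, copy=True))
    vcf.close()
    if n_multi:
        logger.info("skipped %d multiallelic records", n_multi)
    geno = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    geno = np.where(geno == 3, -1, geno).astype(np.int8)
    return GenotypeMatrix(
        sample_ids=samples,
        chrom=chrom,
        positions=np.array(positions, dtype=np.int64),
        genotypes=geno,
        populations=populations or {},
        ref=ref,
        alt=alt,
    )


def write_vcf(genos: GenotypeMatrix, path, header_extra: list | None = None) -> None:
    """Minimal VCFv4.2 with GT only."""
    gt_str = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in header_extra or []:
            fh.write(f"##{line}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={genos.chrom or 'chr5'}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genos.sample_ids)
            + "\n"
        )
        for j, pos in enumerate(genos.positions):
            ref = genos.ref[j] if genos.ref else "A"
            alt = genos.alt[j] if genos.alt else "T"
            gts = "\t".join(gt_str[int(g)] for g in genos.genotypes[:, j])
            fh.write(f"{genos.chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet CSV: sample_id, population, region, rating, optional tsr."""
    df = pd.read_csv(path, comment="#")
    required = {"sample_id", "population", "region", "rating"}
    if required - set(df.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    if not df["rating"].between(0, 5).all():
        raise ValueError("ratings must lie in [0, 5]")
    return df


def write_sample_sheet(df: pd.DataFrame, path, header: list | None = None) -> None:
    with open(path, "w") as fh:
        for line in header or []:
            fh.write(f"#{line}\n")
        df.to_csv(fh, index=False)


def read_config(path) -> dict:
    """Flat key = value configuration; numbers parsed, '#' comments ignored."""
    cfg = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            try:
                cfg[key] = int(value)
            except ValueError:
                try:
                    cfg[key] = float(value)
                except ValueError:
                    cfg[key] = value
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping."""
    payload = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def header_lines(cfg: dict, seed: int) -> list:
    """Comment header embedded in every output file: config hash + seed."""
    return [f"config_hash={config_hash(cfg)}", f"seed={seed}"]
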