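import numpy as np
import pytest

from ampliscan.types import AmpOriginSpec, SimScenario, SweepModel


@pytest.fixture
def flat_scenario():
    """No origins, no masks: every individual is a plain diploid at 20x."""
    return SimScenario(
        chrom_length=120_000,
        populations=[("popA", "regionA", 4)],
        mean_depth=20.0,
        seed=11,
        focal_gene=(55_000, 65_000),
    )


@pytest.fixture
def carrier_scenario():
    """Half the cohort carries a uniform 3-copies-per-haplotype amplification."""
    origin = AmpOriginSpec(
        origin_id="o0",
        breakpoints=(40_000, 80_000),
        segment_copies=(3,),
        carrier_fraction=0.5,
        population="popA",
    )
    return SimScenario(
        chrom_length=120_000,
        populations=[("popA", "regionA", 6)],
        origins=[origin],
        mean_depth=20.0,
        seed=5,
        focal_gene=(55_000, 65_000),
    )


@pytest.fixture
def sweep_scenario_factory():
    """Sweep cohorts: a single amplification with hard/soft/neutral haplotype
    structure among carriers."""

    def make(kind, seed, decay=2e6, k=1, n=24, n_snps=2500):
        origin = AmpOriginSpec(
            origin_id="o0",
            breakpoints=(200_000, 800_000),
            segment_copies=(5,),
            carrier_fraction=0.5,
            population="popA",
        )
        return SimScenario(
            chrom_length=1_000_000,
            populations=[("popA", "regionA", n)],
            origins=[origin],
            sweep_model=SweepModel(kind=kind, k=k, decay_length=decay, theta=0.01),
            n_snps=n_snps,
            seed=seed,
            focal_gene=(495_000, 505_000),
        )

    return make


def brute_force_pi(genos):
    """All-pairs allele-copy comparison oracle for nucleotide diversity.

    Expands each diploid dosage into two allele copies and averages the
    mismatch indicator over every pair of copies, per genotyped site,
    normalized by the number of genotyped sites.
    """
    genos = np.asarray(genos)
    total = 0.0
    n_sites = 0
    for j in range(genos.shape[1]):
        col = genos[:, j]
        copies = []
        for g in col:
            if g >= 0:
                copies.extend([1] * g + [0] * (2 - g))
        n = len(copies)
        if n < 2:
            continue
        n_sites += 1
        diff = sum(
            copies[a] != copies[b] for a in range(n) for b in range(a + 1, n)
        )
        total += diff / (n * (n - 1) / 2)
    return total / n_sites if n_sites else float("nan")


def brute_force_dxy(genos_a, genos_b):
    """Between-population all-pairs allele-copy comparison oracle."""
    genos_a, genos_b = np.asarray(genos_a), np.asarray(genos_b)
    total = 0.0
    n_sites = 0
    for j in range(genos_a.shape[1]):
        ca = [al for g in genos_a[:, j] if g >= 0 for al in [1] * g + [0] * (2 - g)]
        cb = [al for g in genos_b[:, j] if g >= 0 for al in [1] * g + [0] * (2 - g)]
        if not ca or not cb:
            continue
        n_sites += 1
        diff = sum(a != b for a in ca for b in cb)
        total += diff / (len(ca) * len(cb))
    return total / n_sites if n_sites else float("nan")


def brute_force_spearman(x, y):
    """Rank correlation by explicit mid-rank assignment and the Pearson
    product-moment formula."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def brute_force_ehh(haps, core_idx, target_idx):
    """Enumerate identity groups of haplotype stretches from the core out to
    the target (core site itself excluded, so EHH at the core is 1) and
    return sum C(n_g, 2) / C(n, 2)."""
    if target_idx > core_idx:
        lo, hi = core_idx + 1, target_idx
    else:
        lo, hi = target_idx, core_idx - 1
    stretches = ["".join(map(str, row[lo : hi + 1])) for row in haps]
    n = len(stretches)
    groups = {}
    for s in stretches:
        groups[s] = groups.get(s, 0) + 1
    num = sum(c * (c - 1) // 2 for c in groups.values())
    return num / (n * (n - 1) // 2)
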