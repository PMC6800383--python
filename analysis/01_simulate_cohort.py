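#!/usr/bin/env python
"""Generate the synthetic study cohort.

Two populations of 10 individuals; two independent amplification origins
(one per population, 40% carrier frequency) over a 600-kb span around the
focal gene; hard-sweep haplotype structure among carriers; ratings driven by
focal copy number plus a target-site allele.  Writes per-sample depth TSVs,
a GT-only VCF, the sample sheet and the ground-truth sidecar under
scratch/cohort/ (bulky regenerable data; summary tables live in results/).
"""

from pathlib import Path

from ampliscan import cli

OUT = Path(__file__).resolve().parent.parent / "scratch" / "cohort"


def main(seed: int = 1):
    cfg = {"seed": seed}
    scen, tracks, genos, sheet, truth = cli.run_simulate(cfg, OUT)
    n_carriers = sum(1 for o in truth.origin_of.values() if o)
    print(f"cohort: {len(truth.sample_ids)} individuals, "
          f"{n_carriers} amplification carriers across "
          f"{len(scen.origins)} independent origins")
    print(f"wrote depth tracks, cohort.vcf, samples.csv, truth.json -> {OUT}")


if __name__ == "__main__":
    main()
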