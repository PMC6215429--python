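#!/usr/bin/env python
"""Simulate amplicon sequencing of injected embryo pools.

One sample per template design, five replicate samples for the workhorse
NT 120 S design (mirroring five independent injection experiments), each
a mixture of WT, NHEJ, perfect-HDR and erroneous-integration molecules
at embryo-pool magnitudes.  FASTQ and ground-truth tables are written
under scratch/sim/ (bulky per-read data).
"""

from pathlib import Path

import numpy as np

from hdramp import OutcomeSpec, enumerate_designs, plan_substitutions, simulate_sample, write_fastq

import importlib.util as _ilu

_design = _ilu.spec_from_file_location("design01", Path(__file__).parent / "01_design_templates.py")
design01 = _ilu.module_from_spec(_design)
_design.loader.exec_module(design01)

OUT = Path(__file__).resolve().parent.parent / "scratch" / "sim"
N_READS = 4000
REPLICATES = 5


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    site = design01.build_locus()
    subs = plan_substitutions(site)
    panel = enumerate_designs(site, subs)

    # per-design single sample; total HDR varies by design, perfect stays
    # in a narrow band (the study's central observation)
    rng = np.random.default_rng(11)
    for k, template in enumerate(panel):
        perfect = float(rng.uniform(0.01, 0.04))
        erroneous = float(rng.uniform(0.01, 0.06))
        spec = OutcomeSpec(
            n_reads=N_READS,
            proportions={
                "WT": 1 - 0.4 - perfect - erroneous,
                "NHEJ": 0.4,
                "HDR_perfect": perfect,
                "HDR_erroneous": erroneous,
            },
            seed=1000 + k,
        )
        sample = simulate_sample(spec, site, template)
        d = OUT / template.design_code.replace(" ", "_")
        d.mkdir(exist_ok=True)
        write_fastq(sample, d / "reads.fastq")
        sample.truth_frame().to_csv(d / "truth.tsv", sep="\t", index=False)
        print(f"{template.design_code:16s} perfect {perfect:.3f} erroneous {erroneous:.3f} -> {d.name}")

    # replicate series for NT 120 S
    template = next(t for t in panel if t.design_code == "NT 120 S")
    for rep in range(REPLICATES):
        spec = OutcomeSpec(n_reads=N_READS, seed=2000 + rep)
        sample = simulate_sample(spec, site, template)
        d = OUT / f"NT_120_S_rep{rep + 1}"
        d.mkdir(exist_ok=True)
        write_fastq(sample, d / "reads.fastq")
        sample.truth_frame().to_csv(d / "truth.tsv", sep="\t", index=False)
    print(f"{REPLICATES} replicate samples for NT 120 S written")


if __name__ == "__main__":
    main()
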