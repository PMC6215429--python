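#!/usr/bin/env python
"""Screen simulated founder fish for germline scarless HDR.

Simulates germ-cell samples for eight founders with heterogeneous HDR
burdens (most low, a couple high — the mosaic pattern seen in F0
screens), classifies them, and flags founders whose scarless repair rate
exceeds 10%.  Writes results/founder_screen.tsv.
"""

from pathlib import Path

import numpy as np

from hdramp import (
    OutcomeSpec,
    aggregate,
    classify_sample,
    enumerate_designs,
    plan_substitutions,
    screen_founders,
    simulate_sample,
)

import importlib.util as _ilu

_design = _ilu.spec_from_file_location("design01", Path(__file__).parent / "01_design_templates.py")
design01 = _ilu.module_from_spec(_design)
_design.loader.exec_module(design01)

OUT = Path(__file__).resolve().parent.parent / "results"
N_FOUNDERS = 8


def main():
    site = design01.build_locus()
    subs = plan_substitutions(site)
    template = next(
        t for t in enumerate_designs(site, subs) if t.design_code == "NT 120 S"
    )
    rng = np.random.default_rng(8)
    # mosaic germline burdens: mostly negative or low, a few strong carriers
    burdens = [0.0, 0.0, 0.004, 0.01, 0.02, 0.06, 0.13, 0.22]
    rng.shuffle(burdens)
    founders = []
    for i, perfect in enumerate(burdens):
        erroneous = perfect * float(rng.uniform(0.3, 1.2))
        nhej = 0.3
        spec = OutcomeSpec(
            n_reads=3000,
            proportions={
                "WT": 1 - nhej - perfect - erroneous,
                "NHEJ": nhej,
                "HDR_perfect": perfect,
                "HDR_erroneous": erroneous,
            },
            seed=4000 + i,
        )
        sample = simulate_sample(spec, site, template)
        labels = classify_sample(((r[0], r[1]) for r in sample.reads), site, template)
        founders.append((f"founder_{i + 1}", aggregate(labels)))

    report = screen_founders(founders, threshold=10.0)
    report.to_csv(OUT / "founder_screen.tsv", sep="\t", index=False)
    print(report.to_string(index=False))
    flagged = report[report["flagged"]]["founder_id"].tolist()
    print(f"\n{len(flagged)} of {N_FOUNDERS} founders above 10% scarless HDR: {flagged}")


if __name__ == "__main__":
    main()
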