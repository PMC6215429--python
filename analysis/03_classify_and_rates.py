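#!/usr/bin/env python
"""Classify every simulated sample and tabulate HDR rates.

Reads the FASTQ samples from scratch/sim/, classifies each read, and
writes per-sample label tables plus one summary row per sample
(total/perfect/erroneous percentages and the per-position curve) to
results/rates.tsv.  Prints classification accuracy against the truth
sidecars.
"""

from pathlib import Path

import pandas as pd

from hdramp import aggregate, classify_sample, enumerate_designs, plan_substitutions
from hdramp.io import labels_frame, read_fastq

import importlib.util as _ilu

_design = _ilu.spec_from_file_location("design01", Path(__file__).parent / "01_design_templates.py")
design01 = _ilu.module_from_spec(_design)
_design.loader.exec_module(design01)

SIM = Path(__file__).resolve().parent.parent / "scratch" / "sim"
OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    site = design01.build_locus()
    subs = plan_substitutions(site)
    panel = {t.design_code.replace(" ", "_"): t for t in enumerate_designs(site, subs)}

    rows = []
    for d in sorted(SIM.iterdir()):
        if not (d / "reads.fastq").exists():
            continue
        code = d.name.split("_rep")[0]
        template = panel[code]
        reads = ((rid, seq) for rid, seq, _ in read_fastq(d / "reads.fastq"))
        labels = classify_sample(reads, site, template)
        labels_frame(labels).to_csv(d / "labels.tsv", sep="\t", index=False)
        rates = aggregate(labels, template)
        truth = pd.read_csv(d / "truth.tsv", sep="\t")
        lab_cat = {l.read_id: l.category for l in labels}
        agree = (truth["category"] == truth["read_id"].map(lab_cat)).mean()
        row = {"sample": d.name, "design": code.replace("_", " "), "truth_agreement": agree}
        row.update(rates.to_row())
        rows.append(row)
        print(
            f"{d.name:20s} total {rates.total_hdr_pct:5.2f}%  perfect {rates.perfect_pct:5.2f}%  "
            f"erroneous {rates.erroneous_pct:5.2f}%  agreement {agree:.3f}"
        )

    table = pd.DataFrame(rows)
    table.to_csv(OUT / "rates.tsv", sep="\t", index=False)
    print(f"\n{len(rows)} samples -> {OUT / 'rates.tsv'}")


if __name__ == "__main__":
    main()
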