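#!/usr/bin/env python
"""Design the ssODN repair-template panel for the synthetic target locus.

Builds a 240 bp amplicon carrying the smad6a protospacer, locates the
Cas9 cut (3 bp upstream of the NGG PAM), plans the point substitutions
(five in the window −15..+11 around the cut plus a PAM-guanine mask) and
enumerates the ten-template panel.  Writes the panel FASTA/TSV, the
sgRNA gBlock and the site description under results/design/.
"""

import json
from pathlib import Path

import numpy as np

from hdramp import build_gblock, enumerate_designs, locate_cut_site, plan_substitutions
from hdramp.io import write_fasta, write_templates

PROTOSPACER = "GGGTACAGGCGGCCCACAC"
SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "design"


def build_locus(seed=SEED):
    rng = np.random.default_rng(seed)
    dna = lambda n: "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
    ref = dna(110) + PROTOSPACER + "AGG" + dna(108)
    return locate_cut_site(ref, PROTOSPACER)


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    site = build_locus()
    subs = plan_substitutions(site)
    panel = enumerate_designs(site, subs)

    write_fasta({"amplicon": site.reference_seq}, OUT / "reference.fa")
    write_templates(panel, OUT)
    (OUT / "gblock.txt").write_text(build_gblock(site.protospacer) + "\n")
    meta = {
        "protospacer": site.protospacer,
        "strand": site.protospacer_strand,
        "pam_start": site.pam_start,
        "cut_index": site.cut_index,
        "substitutions": [
            {"rel_pos": s.rel_pos, "ref": s.ref_base, "alt": s.alt_base, "pam_mask": s.pam_mask}
            for s in subs
        ],
    }
    (OUT / "site.json").write_text(json.dumps(meta, indent=2) + "\n")

    print(f"cut site at reference index {site.cut_index} (PAM at {site.pam_start})")
    print(f"planned substitutions at rel positions {[s.rel_pos for s in subs]}")
    print(f"{len(panel)} templates designed:")
    for t in panel:
        print(f"  {t.design_code:16s} arms {t.left_arm_len}/{t.right_arm_len}")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
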