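"""Shared fixtures: a deterministic synthetic target locus, an in-frame
coding locus, and the designed template panel."""

from __future__ import annotations

import numpy as np
import pytest

from hdramp import (
    enumerate_designs,
    locate_cut_site,
    plan_substitutions,
)

SMAD6A_PROTOSPACER = "GGGTACAGGCGGCCCACAC"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def site():
    """240 bp amplicon with the protospacer planted mid-amplicon (cut at 126)."""
    rng = np.random.default_rng(1)
    left = random_dna(rng, 110)
    right = random_dna(rng, 108)
    ref = left + SMAD6A_PROTOSPACER + "AGG" + right
    return locate_cut_site(ref, SMAD6A_PROTOSPACER)


@pytest.fixture(scope="session")
def subs(site):
    return plan_substitutions(site)


@pytest.fixture(scope="session")
def panel(site, subs):
    return enumerate_designs(site, subs)


@pytest.fixture(scope="session")
def template(panel):
    """The workhorse design: non-target, 120 nt, symmetric."""
    return next(t for t in panel if t.design_code == "NT 120 S")


def _stop_free_codons(rng: np.random.Generator, n_codons: int) -> str:
    stops = {"TAA", "TAG", "TGA"}
    out = []
    while len(out) < n_codons:
        c = random_dna(rng, 3)
        if c not in stops:
            out.append(c)
    return "".join(out)


@pytest.fixture(scope="session")
def coding_locus():
    """A stop-free 240 bp CDS (frame 0) with a uniquely matching internal
    protospacer+NGG, for synonymous-design tests."""
    from hdramp.design import _iupac_regex

    rng = np.random.default_rng(7)
    pam_re = _iupac_regex("NGG")
    while True:
        ref = _stop_free_codons(rng, 80)
        for start in range(95, 125):
            proto = ref[start : start + 19]
            if not pam_re.match(ref, start + 19):
                continue
            try:
                site = locate_cut_site(ref, proto)
            except Exception:
                continue
            if site.protospacer_strand == "forward" and 95 <= site.cut_index <= 145:
                return site
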