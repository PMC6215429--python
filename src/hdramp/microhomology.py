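"""Junction microhomology and the template-switching hypothesis.

Erroneous ssODN-mediated repair is thought to arise from synthesis-
dependent strand annealing (SDSA) in which the nascent strand dissociates
and re-primes on a different template position, guided by short stretches
of sequence identity (microhomology).  If so, the observed junctions of a
fragment chain should sit at positions with more flanking homology than
uniformly re-drawn switch points.

Two notions of junction homology are used:

* :func:`junction_mh` — the maximal exact overlap between the end of the
  upstream context and the start of a downstream sequence (used literally
  for unassigned filler, and as the general-purpose primitive);
* for fragments with a known source, homology is measured against the
  source bases immediately 5' of the fragment's start in its *oriented*
  source — the bases a re-priming 3' end would anneal to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import reverse_complement

from .fragments import (
    REFERENCE,
    TEMPLATE_FWD,
    TEMPLATE_REV,
    UNASSIGNED,
    FragmentChain,
)

__all__ = [
    "junction_mh",
    "mh_before",
    "SwitchJunction",
    "SwitchPath",
    "reconstruct_switch_path",
    "mh_enrichment",
]

#: upstream context retained on junction records (caps reported homology)
MAX_CONTEXT = 30


def junction_mh(upstream_context: str, downstream_source: str) -> int:
    """Length of the maximal exact suffix of ``upstream_context`` equal to
    a prefix of ``downstream_source``."""
    if not upstream_context or not downstream_source:
        return 0
    k_max = min(len(upstream_context), len(downstream_source))
    for k in range(k_max, 0, -1):
        if upstream_context[-k:] == downstream_source[:k]:
            return k
    return 0


def mh_before(upstream_context: str, oriented_source: str, start: int) -> int:
    """Homology between the upstream context's 3' end and the source bases
    immediately preceding ``start`` in ``oriented_source`` — the annealing
    footprint of a template switch landing at ``start``."""
    k_max = min(len(upstream_context), start, MAX_CONTEXT)
    for k in range(k_max, 0, -1):
        if upstream_context[-k:] == oriented_source[start - k : start]:
            return k
    return 0


@dataclass(frozen=True)
class SwitchJunction:
    """One switch event: synthesis leaves ``from_source`` and resumes in
    ``to_source`` at ``to_start`` (offset in the oriented source)."""

    from_source: str
    to_source: str
    upstream_context: str
    microhomology_len: int
    to_start: int | None = None  # oriented source offset (None for filler)
    to_len: int = 0  # fragment length, for redrawing admissible starts
    internal: bool = False  # switch between integrated fragments


@dataclass
class SwitchPath:
    """Junction-by-junction account of one erroneously repaired read."""

    junctions: list[SwitchJunction]

    @property
    def total_switches(self) -> int:
        return len(self.junctions)


def _oriented(source: str, template_seq: str, reference: str) -> str | None:
    if source == TEMPLATE_FWD:
        return template_seq
    if source == TEMPLATE_REV:
        return reverse_complement(template_seq)
    if source == REFERENCE:
        return reference
    return None


def reconstruct_switch_path(
    chain: FragmentChain,
    template,
    reference_window: str,
) -> SwitchPath:
    """Recompute every junction's microhomology for a fragment chain.

    Emits one junction per fragment boundary, including the genome->first
    fragment entry and the last fragment->genome resumption (a chain of k
    fragments yields k+1 junctions).  Requires ``chain.left_flank_end`` /
    ``right_flank_start`` and ``novel_seq`` to be populated.
    """
    tpl = template if isinstance(template, str) else template.ps_sequence
    ref = reference_window
    if chain.left_flank_end is None or chain.right_flank_start is None:
        raise ValueError("chain lacks flank coordinates")
    novel = chain.novel_seq
    junctions: list[SwitchJunction] = []
    prev_source = "genome"
    for idx, frag in enumerate(chain.fragments):
        upstream = (ref[: chain.left_flank_end] + novel[: frag.read_interval[0]])[-MAX_CONTEXT:]
        if frag.source == UNASSIGNED:
            seq = novel[frag.read_interval[0] : frag.read_interval[1]]
            mh = junction_mh(upstream, seq)
            junctions.append(
                SwitchJunction(prev_source, UNASSIGNED, upstream, mh, None, frag.length, idx > 0)
            )
        else:
            oriented = _oriented(frag.source, tpl, ref)
            start = frag.oriented_start
            if start is None:
                s, e = frag.source_interval
                start = len(tpl) - e if frag.source == TEMPLATE_REV else s
            mh = mh_before(upstream, oriented, start)
            junctions.append(
                SwitchJunction(prev_source, frag.source, upstream, mh, start, frag.length, idx > 0)
            )
        prev_source = frag.source
    # resumption of genomic sequence after the insertion
    upstream = (ref[: chain.left_flank_end] + novel)[-MAX_CONTEXT:]
    mh = mh_before(upstream, ref, chain.right_flank_start)
    junctions.append(
        SwitchJunction(prev_source, "genome", upstream, mh, chain.right_flank_start, 0, False)
    )
    return SwitchPath(junctions=junctions)


def mh_enrichment(
    paths: list[SwitchPath],
    template,
    reference_window: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation test for microhomology enrichment at template switches.

    The statistic is the mean microhomology over *internal* switch
    junctions into an assigned source (junctions whose positions are set
    by the cut site — chain entry and genomic resumption — carry no
    information about switching and are excluded).  The null re-draws
    each junction's landing position uniformly over the admissible starts
    of its oriented source, keeping source, orientation, fragment length
    and upstream context fixed.  One-sided p-value, small-sample safe:
    ``(1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    tpl = template if isinstance(template, str) else template.ps_sequence
    usable: list[tuple[str, str, int, int]] = []  # (upstream, oriented source, mh, max start)
    for path in paths:
        for j in path.junctions:
            if not j.internal or j.to_start is None:
                continue
            oriented = _oriented(j.to_source, tpl, reference_window)
            if oriented is None or len(oriented) < j.to_len:
                continue
            usable.append((j.upstream_context, oriented, j.microhomology_len, len(oriented) - j.to_len))
    if not usable:
        raise ValueError("nothing to test: no internal switch junctions")

    observed = float(np.mean([u[2] for u in usable]))
    rng = np.random.default_rng(seed)
    null_means = np.empty(n_perm)
    for b in range(n_perm):
        tot = 0
        for upstream, oriented, _, smax in usable:
            s = int(rng.integers(0, smax + 1))
            tot += mh_before(upstream, oriented, s)
        null_means[b] = tot / len(usable)
    p = (1 + int(np.sum(null_means >= observed))) / (n_perm + 1)
    return {
        "n_junctions": len(usable),
        "observed_mean_mh": observed,
        "null_mean_mh": float(null_means.mean()),
        "p_value": float(p),
    }
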