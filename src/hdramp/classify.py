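"""Per-read classification of amplicon reads into repair outcomes.

Each read is aligned semi-globally to the reference amplicon (affine gaps,
free end clips), planned substitutions are called, and any novel sequence
(internal insertions, terminal clips) is decomposed into repair-template /
reference fragments.  The read is then labelled:

``WT``
    no planned substitutions, no indels, no novel fragments;
``NHEJ``
    indel(s) at the locus without planned substitutions or
    template-derived fragments;
``HDR_perfect``
    carries the planned substitution closest to the cut and no
    template-derived fragment (under the read-level definition this holds
    regardless of co-occurring indels; ``strict`` mode instead routes
    substitution+indel reads to ``mixed_hdr_indel``);
``HDR_erroneous``
    carries the closest substitution together with at least one
    integrated repair-template fragment;
``integration_without_hdr``
    template fragment present but the closest substitution absent;
``ambiguous``
    mismatch rate above the configured noise ceiling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Seq import reverse_complement

from .design import RepairTemplate, TargetSite
from .fragments import (
    FragmentChain,
    decompose_fragments,
)

__all__ = [
    "ScoringParams",
    "ClassifyConfig",
    "Alignment",
    "NovelSegment",
    "ReadLabel",
    "merge_pairs",
    "align_read",
    "call_substitutions",
    "extract_novel_sequence",
    "classify_read",
    "classify_sample",
    "CATEGORIES",
]

log = logging.getLogger(__name__)

CATEGORIES = (
    "WT",
    "NHEJ",
    "HDR_perfect",
    "HDR_erroneous",
    "integration_without_hdr",
    "mixed_hdr_indel",
    "ambiguous",
)


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scores: free end clips; a gap of length L costs
    ``gap_open + L * gap_extend``.  Defaults make a >=10 nt foreign
    insertion clip or gap out rather than force-align."""

    match: int = 2
    mismatch: int = -4
    gap_open: int = 12
    gap_extend: int = 1

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"  # local = free end clips on both sequences
        aligner.match_score = self.match
        aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@dataclass(frozen=True)
class ClassifyConfig:
    scoring: ScoringParams = ScoringParams()
    min_novel_len: int = 10  # insertions/clips shorter than this are indel noise
    min_frag_match: int = 10
    frag_mismatch_tol: float = 0.05
    substitution_mode: str = "anywhere"  # or "genomic_only"
    perfect_definition: str = "paper"  # or "strict"
    seq_error_estimate: float = 0.01  # per-base; noise ceiling is 5x this
    min_overlap: int = 20  # paired-end merge


@dataclass
class Alignment:
    """Semi-global alignment of a read against the reference amplicon.

    ``ops`` is a CIGAR-like list of ``(op, length)`` with op in
    ``M`` (match), ``X`` (mismatch), ``I`` (insertion to reference),
    ``D`` (deletion from reference), ``S`` (end clip).  Ops cover the
    whole read.
    """

    read_id: str
    ops: list[tuple[str, int]]
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    score: float
    edits: list[tuple[int, str, str]] = field(default_factory=list)  # (ref_pos, ref, alt)

    @property
    def n_aligned_columns(self) -> int:
        return sum(l for op, l in self.ops if op in "MX")

    def indels(self, min_len: int = 1) -> list[tuple[str, int]]:
        return [(op, l) for op, l in self.ops if op in "ID" and l >= min_len]


@dataclass(frozen=True)
class NovelSegment:
    """A read interval not explained by the reference (insertion or clip)."""

    read_interval: tuple[int, int]
    kind: str  # "insertion" | "clip5" | "clip3"
    ref_pos: int  # reference coordinate where the segment interrupts the alignment
    seq: str


@dataclass
class ReadLabel:
    read_id: str
    category: str
    presence: dict[int, bool]  # rel_pos -> substitution present
    chain: FragmentChain | None = None
    orientation: str = "forward"
    n_indels: int = 0

    @property
    def is_hdr(self) -> bool:
        return self.category in ("HDR_perfect", "HDR_erroneous")


def merge_pairs(
    mate1: tuple[str, str],
    mate2: tuple[str, str],
    min_overlap: int = 20,
    max_mismatch_rate: float = 0.1,
) -> tuple[str, str] | None:
    """Overlap-merge a read pair into a single consensus read.

    ``mate1``/``mate2`` are ``(sequence, quality)`` with mate2 given in
    sequencing orientation (it is reverse-complemented here).  Returns the
    merged ``(sequence, quality)``, or ``None`` when no acceptable overlap
    of at least ``min_overlap`` exists (caller should fall back to
    single-end handling).  Disagreements resolve toward the higher-quality
    base (ties toward mate1).
    """
    s1, q1 = mate1
    s2 = reverse_complement(mate2[0])
    q2 = mate2[1][::-1]
    best = None  # (agreement score, overlap length)
    max_ov = min(len(s1), len(s2))
    for ov in range(max_ov, min_overlap - 1, -1):
        a = s1[len(s1) - ov :]
        b = s2[:ov]
        mism = sum(x != y for x, y in zip(a, b))
        if mism <= max_mismatch_rate * ov:
            score = ov - 2 * mism
            if best is None or score > best[0]:
                best = (score, ov)
    if best is None:
        return None
    ov = best[1]
    head = s1[: len(s1) - ov]
    tail = s2[ov:]
    mid = []
    midq = []
    for k in range(ov):
        i1 = len(s1) - ov + k
        b1, b2 = s1[i1], s2[k]
        if b1 == b2 or q1[i1] >= q2[k]:
            mid.append(b1)
            midq.append(max(q1[i1], q2[k]))
        else:
            mid.append(b2)
            midq.append(q2[k])
    return head + "".join(mid) + tail, q1[: len(s1) - ov] + "".join(midq) + q2[ov:]


def _ops_from_biopython(aln, read: str, ref: str) -> tuple[list, list]:
    """CIGAR-like op list + mismatch records from a Biopython alignment."""
    tgt_blocks, qry_blocks = aln.aligned
    ops: list[tuple[str, int]] = []
    edits: list[tuple[int, str, str]] = []
    if len(qry_blocks) == 0:
        return [("S", len(read))] if read else [], edits
    read_pos = 0
    first_q = qry_blocks[0][0]
    if first_q > 0:
        ops.append(("S", int(first_q)))
        read_pos = int(first_q)
    prev_t = None
    for (t0, t1), (q0, q1) in zip(tgt_blocks, qry_blocks):
        t0, t1, q0, q1 = int(t0), int(t1), int(q0), int(q1)
        if prev_t is not None:
            if q0 > read_pos:
                ops.append(("I", q0 - read_pos))
            if t0 > prev_t:
                ops.append(("D", t0 - prev_t))
        read_pos = q0
        run_op = None
        run_len = 0
        for k in range(t1 - t0):
            op = "M" if read[q0 + k] == ref[t0 + k] else "X"
            if op == "X":
                edits.append((t0 + k, ref[t0 + k], read[q0 + k]))
            if op == run_op:
                run_len += 1
            else:
                if run_op:
                    ops.append((run_op, run_len))
                run_op, run_len = op, 1
        if run_op:
            ops.append((run_op, run_len))
        read_pos = q1
        prev_t = t1
    if read_pos < len(read):
        ops.append(("S", len(read) - read_pos))
    return ops, edits


def align_read(
    read: str,
    reference_window: str,
    params: ScoringParams = ScoringParams(),
    read_id: str = "read",
) -> Alignment:
    """Best-scoring alignment of the read to the reference window with
    affine gaps and cost-free end clipping on both sequences."""
    if not read or not reference_window:
        raise ValueError("align_read requires non-empty sequences")
    aligner = params.make_aligner()
    aln = next(iter(aligner.align(reference_window, read)))
    ops, edits = _ops_from_biopython(aln, read, reference_window)
    tgt_blocks, qry_blocks = aln.aligned
    if len(qry_blocks):
        ref_start, ref_end = int(tgt_blocks[0][0]), int(tgt_blocks[-1][1])
        read_start, read_end = int(qry_blocks[0][0]), int(qry_blocks[-1][1])
    else:
        ref_start = ref_end = read_start = read_end = 0
    return Alignment(
        read_id=read_id,
        ops=ops,
        ref_start=ref_start,
        ref_end=ref_end,
        read_start=read_start,
        read_end=read_end,
        score=float(aln.score),
        edits=edits,
    )


def _aligned_ref_base(aln: Alignment, read: str, ref_pos: int) -> str | None:
    """Read base aligned to a reference position (None if deleted/clipped)."""
    rp = aln.ref_start
    qp = aln.read_start
    for op, l in aln.ops:
        if op == "S":
            continue
        if op in "MX":
            if rp <= ref_pos < rp + l:
                return read[qp + (ref_pos - rp)]
            rp += l
            qp += l
        elif op == "D":
            if rp <= ref_pos < rp + l:
                return None
            rp += l
        elif op == "I":
            qp += l
    return None


def extract_novel_sequence(
    aln: Alignment, read: str, min_len: int = 10
) -> list[NovelSegment]:
    """Insertions and terminal clips of length >= ``min_len``, i.e. read
    sequence the reference does not explain."""
    out: list[NovelSegment] = []
    rp = aln.ref_start
    qp = 0
    for k, (op, l) in enumerate(aln.ops):
        if op == "S":
            if l >= min_len:
                kind = "clip5" if k == 0 else "clip3"
                ref_pos = aln.ref_start if k == 0 else aln.ref_end
                out.append(NovelSegment((qp, qp + l), kind, ref_pos, read[qp : qp + l]))
            qp += l
        elif op == "I":
            if l >= min_len:
                out.append(NovelSegment((qp, qp + l), "insertion", rp, read[qp : qp + l]))
            qp += l
        elif op in "MX":
            qp += l
            rp += l
        elif op == "D":
            rp += l
    return out


def call_substitutions(
    aln: Alignment,
    read: str,
    template: RepairTemplate,
    mode: str = "anywhere",
    chain: FragmentChain | None = None,
) -> dict[int, bool]:
    """Presence of each planned substitution in the read.

    ``genomic_only`` requires the alternate base at the aligned genomic
    position.  ``anywhere`` (read-level counting) additionally accepts the
    substitution inside an integrated template fragment, judged by whether
    a template-derived fragment of ``chain`` covers the substitution's
    template offset.
    """
    presence: dict[int, bool] = {}
    for sub in template.subs:
        seen = _aligned_ref_base(aln, read, sub.ref_index) == sub.alt_base
        if not seen and mode == "anywhere" and chain is not None:
            seen = chain.template_coverage(template.ps_offset(sub.rel_pos))
        presence[sub.rel_pos] = bool(seen)
    return presence


def _noise_mismatch_rate(aln: Alignment, template: RepairTemplate) -> float:
    """Mismatch rate over aligned columns, planned positions excluded."""
    planned = {s.ref_index for s in template.subs}
    unplanned = sum(1 for pos, _, _ in aln.edits if pos not in planned)
    cols = aln.n_aligned_columns
    return unplanned / cols if cols else 0.0


def classify_read(
    read: str,
    site: TargetSite,
    template: RepairTemplate,
    config: ClassifyConfig = ClassifyConfig(),
    read_id: str = "read",
) -> ReadLabel:
    """Label one (merged or single-end) read.

    The read is aligned in both orientations and the better one is kept,
    so a read and its reverse complement always receive the same label.
    """
    ref = site.reference_seq
    aln = align_read(read, ref, config.scoring, read_id)
    orientation = "forward"
    # near-perfect forward alignments need no reverse attempt
    if aln.score < 0.9 * config.scoring.match * len(read):
        rc = reverse_complement(read)
        aln_rc = align_read(rc, ref, config.scoring, read_id)
        if aln_rc.score > aln.score:
            aln, read, orientation = aln_rc, rc, "reverse"

    novel = extract_novel_sequence(aln, read, config.min_novel_len)
    chain: FragmentChain | None = None
    if novel:
        joined = "".join(seg.seq for seg in novel)
        chain = decompose_fragments(
            joined, template, ref, config.min_frag_match, config.frag_mismatch_tol
        )
        first = novel[0]
        chain.left_flank_end = first.ref_pos
        chain.right_flank_start = first.ref_pos
        # a deletion op adjacent to the insertion shifts the resumption point
        for op, l in aln.ops:
            if op == "D":
                chain.right_flank_start += l

    presence = call_substitutions(aln, read, template, config.substitution_mode, chain)
    closest = presence.get(template.closest_rel_pos, False)
    n_indels = len(aln.indels())
    has_template_frag = chain.has_template_fragment if chain else False

    if _noise_mismatch_rate(aln, template) > 5 * config.seq_error_estimate:
        category = "ambiguous"
    elif has_template_frag:
        category = "HDR_erroneous" if closest else "integration_without_hdr"
    elif closest:
        if config.perfect_definition == "strict" and (n_indels > 0 or novel):
            category = "mixed_hdr_indel"
        else:
            category = "HDR_perfect"
    elif n_indels > 0 or novel:
        category = "NHEJ"
    else:
        category = "WT"

    return ReadLabel(
        read_id=read_id,
        category=category,
        presence=presence,
        chain=chain,
        orientation=orientation,
        n_indels=n_indels,
    )


def classify_sample(
    reads,
    site: TargetSite,
    template: RepairTemplate,
    config: ClassifyConfig = ClassifyConfig(),
) -> list[ReadLabel]:
    """Classify an iterable of ``(read_id, sequence)`` records.

    Unreadable records (empty or non-DNA sequence) are logged and skipped.
    """
    labels: list[ReadLabel] = []
    skipped = 0
    for read_id, seq in reads:
        seq = seq.upper()
        if not seq or any(b not in "ACGTN" for b in seq):
            skipped += 1
            log.warning("skipping unreadable read %s", read_id)
            continue
        labels.append(classify_read(seq, site, template, config, read_id))
    if skipped:
        log.warning("%d reads skipped as unreadable", skipped)
    return labels
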