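"""Decomposition of novel read sequence into repair-template / reference
fragments.

Erroneously repaired reads carry, at the cut site, concatenations of
repair-template substrings in either orientation, sometimes interleaved
with short stretches not traceable to any source.  ``decompose_fragments``
tiles such a novel sequence with fragments drawn from the template
(forward), the reverse-complemented template, or the local reference,
requiring each assigned fragment to span at least ``min_match`` bases at a
mismatch rate of at most ``tol``; everything else becomes ``unassigned``
filler.

Objective (lexicographic): maximise the number of assigned bases, then
minimise the fragment count, then canonical per-fragment tie-breaking
(template before reference, forward before reverse complement, smallest
offset in the oriented source).  The optimum is found by exact dynamic
programming over all segmentations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import reverse_complement

__all__ = ["Fragment", "Junction", "FragmentChain", "decompose_fragments",
           "SOURCE_CODES", "chain_to_string", "chain_from_string"]

TEMPLATE_FWD = "template_fwd"
TEMPLATE_REV = "template_rev"
REFERENCE = "reference"
UNASSIGNED = "unassigned"

#: rank used for tie-breaking and the compact string form
SOURCE_CODES = {TEMPLATE_FWD: "T+", TEMPLATE_REV: "T-", REFERENCE: "R+", UNASSIGNED: "U"}
_RANK_TO_SOURCE = {0: TEMPLATE_FWD, 1: TEMPLATE_REV, 2: REFERENCE, 3: UNASSIGNED}
_SOURCE_TO_RANK = {v: k for k, v in _RANK_TO_SOURCE.items()}

_FORBIDDEN = 10**6  # mismatch sentinel barring out-of-range diagonal cells


@dataclass(frozen=True)
class Fragment:
    """One tile of the novel sequence.

    ``source_interval`` is half-open in *template coordinates* for both
    template orientations (a ``template_rev`` fragment with interval
    [s, e) reads as revcomp(template[s:e])), in reference coordinates for
    ``reference`` fragments, and ``None`` for unassigned filler.
    ``oriented_start`` is the fragment's offset in its oriented source
    sequence (used for tie-breaking and switch-point permutation).
    """

    source: str
    read_interval: tuple[int, int]
    source_interval: tuple[int, int] | None = None
    oriented_start: int | None = None

    @property
    def length(self) -> int:
        return self.read_interval[1] - self.read_interval[0]

    @property
    def assigned(self) -> bool:
        return self.source != UNASSIGNED


@dataclass(frozen=True)
class Junction:
    """Boundary between consecutive chain elements (or chain and genome)."""

    position: int  # read offset within the novel sequence (or 0 / len)
    microhomology_len: int = 0


@dataclass
class FragmentChain:
    """Ordered decomposition of one read's novel sequence.

    ``left_flank_end`` / ``right_flank_start`` are the reference
    coordinates flanking the insertion (they differ by the size of any
    co-occurring locus deletion).
    """

    fragments: list[Fragment]
    novel_seq: str
    left_flank_end: int | None = None
    right_flank_start: int | None = None
    junctions: list[Junction] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def has_template_fragment(self) -> bool:
        return any(f.source in (TEMPLATE_FWD, TEMPLATE_REV) for f in self.fragments)

    def template_coverage(self, template_pos: int) -> bool:
        """Does any template-derived fragment cover this template offset?"""
        for f in self.fragments:
            if f.source in (TEMPLATE_FWD, TEMPLATE_REV):
                s, e = f.source_interval
                if s <= template_pos < e:
                    return True
        return False


def chain_to_string(chain: FragmentChain) -> str:
    """Compact form, e.g. ``T+[20,60)|U[0,5)|T-[90,120)``."""
    parts = []
    for f in chain.fragments:
        code = SOURCE_CODES[f.source]
        iv = f.source_interval if f.source_interval is not None else f.read_interval
        parts.append(f"{code}[{iv[0]},{iv[1]})")
    return "|".join(parts)


def chain_from_string(s: str, novel_seq: str = "") -> FragmentChain:
    """Inverse of :func:`chain_to_string` (read intervals of assigned
    fragments are reconstructed from consecutive lengths)."""
    frags: list[Fragment] = []
    pos = 0
    for part in s.split("|"):
        if not part:
            continue
        code = part[: 2 if part[1] in "+-" else 1]
        lo, hi = part[len(code) + 1 : -1].split(",")
        iv = (int(lo), int(hi))
        source = {v: k for k, v in SOURCE_CODES.items()}[code]
        length = iv[1] - iv[0]
        if source == UNASSIGNED:
            frags.append(Fragment(source, read_interval=iv))
            pos = iv[1]
        else:
            frags.append(Fragment(source, read_interval=(pos, pos + length), source_interval=iv))
            pos += length
    return FragmentChain(fragments=frags, novel_seq=novel_seq)


def _to_u8(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


class _SourceIndex:
    """Per-source cumulative mismatch counts along every alignment diagonal.

    For source ``S`` and novel ``N``, diagonal ``k`` pairs ``N[i]`` with
    ``S[i + k]``.  ``cum[k - k_min, j]`` holds the mismatch count of
    ``N[0:j]`` on that diagonal, with out-of-range cells poisoned so that
    intervals leaving the source are never feasible.
    """

    def __init__(self, source: str, novel: np.ndarray):
        n = len(novel)
        m = len(source)
        self.m = m
        self.k_min = -(n - 1)
        ks = np.arange(self.k_min, m)  # all diagonals
        idx = ks[:, None] + np.arange(n)[None, :]
        inside = (idx >= 0) & (idx < m)
        sarr = _to_u8(source)
        svals = sarr[np.clip(idx, 0, m - 1)]
        mm = np.where(inside, (svals != novel[None, :]).astype(np.int64), _FORBIDDEN)
        self.cum = np.concatenate(
            [np.zeros((len(ks), 1), dtype=np.int64), np.cumsum(mm, axis=1)], axis=1
        )

    def best_starts(self, i: int, n: int, allowed: np.ndarray) -> np.ndarray:
        """For fixed read start ``i``: smallest feasible oriented source
        start per read end ``j`` (-1 where none).

        ``allowed[L]`` is the mismatch budget for an interval of length L.
        """
        mm = self.cum[:, i + 1 : n + 1] - self.cum[:, i : i + 1]  # (K, n - i)
        ok = mm <= allowed[None, 1 : n - i + 1]
        any_ok = ok.any(axis=0)
        first_k = np.argmax(ok, axis=0)  # first diagonal index = smallest k
        starts = first_k + self.k_min + i  # oriented source start s = i + k
        return np.where(any_ok, starts, -1)


def decompose_fragments(
    novel: str,
    template,
    reference_window: str,
    min_match: int = 10,
    tol: float = 0.05,
) -> FragmentChain:
    """Optimal tiling of ``novel`` into template/reference/unassigned
    fragments (see module docstring for the objective).

    ``template`` may be a :class:`~hdramp.design.RepairTemplate` (its
    protospacer-strand sequence is searched) or a plain string.
    """
    tpl = template if isinstance(template, str) else template.ps_sequence
    n = len(novel)
    if n == 0:
        return FragmentChain(fragments=[], novel_seq="")
    sources = [tpl, reverse_complement(tpl), reference_window]
    if n < min_match:
        return FragmentChain(
            fragments=[Fragment(UNASSIGNED, (0, n))], novel_seq=novel
        )

    narr = _to_u8(novel)
    indexes = [_SourceIndex(s, narr) for s in sources]
    lengths = np.arange(n + 1)
    budget = np.floor(tol * lengths).astype(np.int64)

    # starts[rank][i][j] = smallest oriented source start of a feasible
    # assigned fragment novel[i:j) in source `rank`, or -1.
    starts_by_rank: list[list[np.ndarray]] = []
    for idx in indexes:
        starts_by_rank.append([idx.best_starts(i, n, budget) for i in range(n)])

    # Backward DP over suffixes.  State: (-assigned_bases, fragment_count,
    # fragment key tuple); fragment key = (read_start, rank, oriented_start).
    INF = (1, 0, ())
    best: list[tuple] = [INF] * (n + 1)
    best[n] = (0, 0, ())
    choice: list[tuple | None] = [None] * (n + 1)
    for i in range(n - 1, -1, -1):
        cand_best = None
        cand_choice = None
        for j in range(i + 1, n + 1):
            tail = best[j]
            length = j - i
            frag = None  # (rank, oriented_start)
            if length >= min_match:
                for rank in range(3):
                    s = starts_by_rank[rank][i][j - i - 1]
                    if s >= 0:
                        frag = (rank, int(s))
                        break
            if frag is None:
                # unassigned filler; merging with an unassigned tail head is
                # never optimal, so no special casing is needed
                key = (tail[0], tail[1] + 1, ((i, 3, -1),) + tail[2])
                pick = (j, 3, -1)
            else:
                key = (tail[0] - length, tail[1] + 1, ((i, frag[0], frag[1]),) + tail[2])
                pick = (j, frag[0], frag[1])
            if cand_best is None or key < cand_best:
                cand_best = key
                cand_choice = pick
        best[i] = cand_best
        choice[i] = cand_choice

    frags: list[Fragment] = []
    i = 0
    tpl_len = len(tpl)
    while i < n:
        j, rank, s = choice[i]
        source = _RANK_TO_SOURCE[rank]
        if source == UNASSIGNED:
            frags.append(Fragment(UNASSIGNED, (i, j)))
        else:
            length = j - i
            if source == TEMPLATE_REV:
                src_iv = (tpl_len - s - length, tpl_len - s)
            else:
                src_iv = (s, s + length)
            frags.append(
                Fragment(source, (i, j), source_interval=src_iv, oriented_start=s)
            )
        i = j
    return FragmentChain(fragments=frags, novel_seq=novel)
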