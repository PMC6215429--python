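"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations, sharing no code with the package.
"""

from __future__ import annotations

from functools import lru_cache

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def gotoh_local_score(a: str, b: str, match=2, mismatch=-4, open_=12, extend=1) -> float:
    """Full-matrix Smith-Waterman with affine gaps: a gap of length L costs
    open_ + L * extend; free end clipping on both sequences."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Fi, Fi1 = E[i], F[i], F[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            Ei[j] = max(Hi[j - 1] - open_ - extend, Ei[j - 1] - extend)
            Fi[j] = max(Hi1[j] - open_ - extend, Fi1[j] - extend)
            diag = Hi1[j - 1] + (match if ai == b[j - 1] else mismatch)
            h = max(0.0, diag, Ei[j], Fi[j])
            Hi[j] = h
            if h > best:
                best = h
    return best


def brute_force_cut(ref: str, proto: str) -> tuple[str, int, int]:
    """Scan both strands for protospacer followed by NGG; return
    (strand, pam_start, cut_index) of the unique hit."""
    hits = []
    for i in range(len(ref) - len(proto) - 2):
        if ref[i : i + len(proto)] == proto and ref[i + len(proto) + 1 : i + len(proto) + 3] == "GG":
            hits.append(("forward", i + len(proto), i + len(proto) - 3))
    rc = revcomp(ref)
    n = len(ref)
    for i in range(n - len(proto) - 2):
        if rc[i : i + len(proto)] == proto and rc[i + len(proto) + 1 : i + len(proto) + 3] == "GG":
            pam_start = n - i - len(proto) - 3
            hits.append(("reverse", pam_start, pam_start + 6))
    assert len(hits) == 1
    return hits[0]


def oracle_decompose(novel: str, template: str, reference: str, min_match: int, tol: float):
    """Reference solution for the fragment-tiling objective: maximise
    assigned bases, then minimise fragment count, then per-fragment
    (read_start, source rank, oriented start).  Memoised recursion over
    all segmentations with direct string comparison.

    Returns a list of (source_rank, oriented_start or -1, read_start,
    read_end).
    """
    sources = [template, revcomp(template), reference]
    n = len(novel)

    def frag_label(i: int, j: int):
        length = j - i
        if length < min_match:
            return None
        budget = int(tol * length)
        for rank, src in enumerate(sources):
            for s in range(len(src) - length + 1):
                mm = 0
                for k in range(length):
                    if src[s + k] != novel[i + k]:
                        mm += 1
                        if mm > budget:
                            break
                else:
                    return (rank, s)
        return None

    @lru_cache(maxsize=None)
    def solve(i: int):
        """Best (neg assigned, count, frag key tuple) for novel[i:]."""
        if i == n:
            return (0, 0, ())
        best = None
        for j in range(i + 1, n + 1):
            lab = frag_label(i, j)
            tail = solve(j)
            if lab is None:
                key = (tail[0], tail[1] + 1, ((i, 3, -1),) + tail[2])
            else:
                key = (tail[0] - (j - i), tail[1] + 1, ((i, lab[0], lab[1]),) + tail[2])
            if best is None or key < best:
                best = key
        return best

    _, _, frags = solve(0)
    out = []
    for k, (start, rank, s) in enumerate(frags):
        end = frags[k + 1][0] if k + 1 < len(frags) else n
        out.append((rank, s, start, end))
    return out


def max_overlap(a: str, b: str) -> int:
    """Largest k with a's k-suffix equal to b's k-prefix, by set scan."""
    ks = [k for k in range(1, min(len(a), len(b)) + 1) if a[len(a) - k :] == b[:k]]
    return max(ks, default=0)
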