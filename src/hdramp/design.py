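"""ssODN repair-template design around a Cas9 cut site.

Geometry conventions
--------------------
All reference coordinates are 0-based.  ``cut_index`` is an inter-base
coordinate on the reference: SpCas9 cleaves bluntly 3 bp upstream of the
PAM, i.e. between ``cut_index - 1`` and ``cut_index`` when the protospacer
lies on the forward strand.

Substitution positions are expressed relative to the cut on the
*protospacer strand* (the strand carrying the protospacer, read 5'->3'
with the PAM to the right).  There is no position 0: ``+1`` is the first
base 3' of the cut, ``-1`` the first base 5' of it.  The PAM occupies
relative positions +4..+6, so its two guanines sit at +5 and +6.

Repair templates either share sequence identity with the protospacer
strand -- the strand the sgRNA does *not* bind, labelled ``non_target``
(NT) -- or with its complement (``target``, T).  Reverse-complementing an
NT design yields the T design of the same geometry.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

__all__ = [
    "DesignError",
    "TargetSite",
    "PlannedSub",
    "RepairTemplate",
    "DesignProfile",
    "locate_cut_site",
    "plan_substitutions",
    "build_template",
    "enumerate_designs",
    "build_gblock",
    "T7_LEADER",
    "SGRNA_SCAFFOLD",
]

# T7 in vitro transcription leader (the trailing GG fulfils the polymerase
# initiation requirement) and the invariant sgRNA scaffold.
T7_LEADER = "CCGCTAGCTAATACGACTCACTATA"
SGRNA_SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCC"
    "GTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGCTTTT"
)

_PURINES = frozenset("AG")

# Standard-table codon -> amino acid, stops included.
_CODON_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_AA[_stop] = "*"


class DesignError(ValueError):
    """Raised when a repair-template design request cannot be satisfied."""


def _iupac_regex(pattern: str) -> re.Pattern:
    return re.compile(
        "".join(f"[{ambiguous_dna_values[b]}]" for b in pattern.upper())
    )


@dataclass(frozen=True)
class TargetSite:
    """A CRISPR target: reference, protospacer placement and cut position."""

    reference_id: str
    reference_seq: str
    protospacer: str
    pam_pattern: str
    protospacer_strand: str  # "forward" | "reverse"
    pam_start: int  # 0-based reference index of the PAM's leftmost base
    cut_index: int  # inter-base reference coordinate of the blunt cut

    def ref_index(self, rel_pos: int) -> int:
        """Forward-reference index of a protospacer-strand relative position."""
        if rel_pos == 0:
            raise ValueError("rel_pos 0 does not exist (+1 is the first base 3' of the cut)")
        c = self.cut_index
        if self.protospacer_strand == "forward":
            return c + rel_pos - 1 if rel_pos > 0 else c + rel_pos
        return c - rel_pos if rel_pos > 0 else c - rel_pos - 1

    @property
    def pam_guanine_rel_positions(self) -> tuple[int, int]:
        """Relative positions of the two PAM guanines (NGG -> +5, +6)."""
        return (5, 6)


@dataclass(frozen=True)
class PlannedSub:
    """One planned single-base substitution.

    ``ref_base``/``alt_base`` are given on the *forward reference strand*;
    ``ref_index`` is the forward-reference coordinate of the substituted
    base, and ``rel_pos`` its protospacer-strand position relative to the
    cut.
    """

    rel_pos: int
    ref_base: str
    alt_base: str
    ref_index: int
    synonymous: bool = False
    pam_mask: bool = False

    def __post_init__(self):
        if self.rel_pos == 0:
            raise ValueError("rel_pos must be non-zero")
        if self.alt_base == self.ref_base:
            raise ValueError("alt_base must differ from ref_base")


@dataclass(frozen=True)
class DesignProfile:
    """Knobs of the substitution plan.

    Defaults request five substitutions inside the window spanning 15 nt
    upstream to 11 nt downstream of the cut (protospacer-strand
    coordinates), plus one PAM-guanine mask where a synonymous option
    exists.
    """

    n_subs: int = 5
    window: tuple[int, int] = (-15, 11)
    pam_mask: bool = True


@dataclass(frozen=True)
class RepairTemplate:
    """A designed ssODN.

    ``sequence`` is the oligo 5'->3'.  ``ps_sequence`` is the same design
    written on the protospacer strand (equal to ``sequence`` for NT
    designs, its reverse complement for T designs); ``window_start`` /
    ``window_end`` delimit the homologous window on the forward reference.
    Arm lengths are measured on the protospacer strand: ``left_arm_len``
    bases 5' of the cut, ``right_arm_len`` bases 3' of it.
    """

    design_code: str
    strand: str  # "target" | "non_target"
    sequence: str
    ps_sequence: str
    left_arm_len: int
    right_arm_len: int
    window_start: int
    window_end: int
    subs: tuple[PlannedSub, ...] = field(default=())

    @property
    def total_len(self) -> int:
        return len(self.sequence)

    def ps_offset(self, rel_pos: int) -> int:
        """Index within ``ps_sequence`` of a cut-relative position."""
        if rel_pos == 0:
            raise ValueError("rel_pos 0 does not exist")
        return self.left_arm_len + (rel_pos - 1 if rel_pos > 0 else rel_pos)

    @property
    def rel_positions(self) -> tuple[int, ...]:
        """Planned substitution positions, cut-proximal first."""
        return tuple(sorted((s.rel_pos for s in self.subs), key=lambda r: (abs(r), -r)))

    @property
    def closest_rel_pos(self) -> int:
        if not self.subs:
            raise ValueError("template has no planned substitutions")
        return self.rel_positions[0]


def locate_cut_site(
    reference_seq: str,
    protospacer: str,
    pam_pattern: str = "NGG",
    reference_id: str = "ref",
) -> TargetSite:
    """Locate a protospacer+PAM on either strand and derive the cut.

    The protospacer must occur exactly once, immediately 5' of a PAM
    match.  The blunt cut lies 3 bp upstream of the PAM on the
    protospacer strand.
    """
    ref = reference_seq.upper()
    proto = protospacer.upper()
    if not 18 <= len(proto) <= 20:
        raise DesignError(f"protospacer length {len(proto)} outside 18-20 nt")
    pam_re = _iupac_regex(pam_pattern)
    plen = len(pam_pattern)
    n, L = len(ref), len(proto)

    hits: list[tuple[str, int]] = []  # (strand, fwd protospacer start)
    for i in range(n - L - plen + 1):
        if ref[i : i + L] == proto and pam_re.match(ref, i + L):
            hits.append(("forward", i))
    rc = reverse_complement(ref)
    for i in range(n - L - plen + 1):
        if rc[i : i + L] == proto and pam_re.match(rc, i + L):
            hits.append(("reverse", i))

    if not hits:
        raise DesignError("protospacer not found")
    if len(hits) > 1:
        raise DesignError("ambiguous target: protospacer+PAM matches more than once")

    strand, i = hits[0]
    if strand == "forward":
        pam_start = i + L
        cut_index = pam_start - 3
    else:
        # i is the start in reverse-complement coordinates
        pam_start = n - i - L - plen
        cut_index = pam_start + plen + 3
    return TargetSite(
        reference_id=reference_id,
        reference_seq=ref,
        protospacer=proto,
        pam_pattern=pam_pattern.upper(),
        protospacer_strand=strand,
        pam_start=pam_start,
        cut_index=cut_index,
    )


def _codon_context(ref: str, frame: int, g: int) -> tuple[str, int, int] | None:
    """Codon containing forward index ``g`` for CDS starting at ``frame``."""
    if g < frame:
        return None
    k = (g - frame) // 3
    start = frame + 3 * k
    if start + 3 > len(ref):
        return None
    return ref[start : start + 3], start, g - start


def synonymous_alternatives(ref: str, frame: int, g: int) -> list[str]:
    """All alt bases at forward index ``g`` that leave the protein unchanged."""
    ctx = _codon_context(ref, frame, g)
    if ctx is None:
        return []
    codon, _, pos = ctx
    if any(b not in "ACGT" for b in codon):
        return []
    aa = _CODON_AA[codon]
    out = []
    for b in "ACGT":
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if _CODON_AA[alt] == aa:
            out.append(b)
    return out


def _pick_alt(ref_base: str, candidates: list[str]) -> str | None:
    """Prefer transversions (they are maximally distinct from the reference
    base), break ties alphabetically."""
    if not candidates:
        return None
    ref_is_purine = ref_base in _PURINES

    def key(b: str) -> tuple[int, str]:
        transversion = (b in _PURINES) != ref_is_purine
        return (0 if transversion else 1, b)

    return min(candidates, key=key)


def plan_substitutions(
    site: TargetSite,
    cds_frame: int | None = None,
    profile: DesignProfile = DesignProfile(),
) -> list[PlannedSub]:
    """Plan the point substitutions carried by every template of the panel.

    Positions are drawn from ``profile.window`` (cut-relative,
    protospacer strand).  When ``cds_frame`` is given (forward-reference
    index of a codon start, reading frame assumed to run to the end of
    the reference), every substitution must be synonymous.  The position
    closest to the cut is always included; the remaining picks spread
    across the window by farthest-point selection.  A PAM-guanine mask is
    appended when requested and admissible.
    """
    ref = site.reference_seq
    lo, hi = profile.window
    pam_rel = set(range(4, 4 + len(site.pam_pattern)))  # PAM masked separately
    admissible: dict[int, str] = {}  # rel_pos -> alt base (forward strand)
    for r in list(range(lo, 0)) + list(range(1, hi + 1)):
        if r in pam_rel:
            continue
        g = site.ref_index(r)
        if not 0 <= g < len(ref):
            raise DesignError("substitution window outside the reference")
        if cds_frame is None:
            alt = _pick_alt(ref[g], [b for b in "ACGT" if b != ref[g]])
        else:
            alt = _pick_alt(ref[g], synonymous_alternatives(ref, cds_frame, g))
        if alt is not None:
            admissible[r] = alt

    subs: list[PlannedSub] = []
    if profile.n_subs > 0:
        if not admissible:
            raise DesignError("design infeasible: no admissible substitution in window")
        chosen: list[int] = []
        # the cut-proximal substitution defines HDR read-out; it goes first
        closest = min(admissible, key=lambda r: (abs(r), -r))
        chosen.append(closest)
        remaining = [r for r in admissible if r != closest]
        while len(chosen) < profile.n_subs and remaining:
            pick = max(remaining, key=lambda r: (min(abs(r - c) for c in chosen), -abs(r), r))
            chosen.append(pick)
            remaining.remove(pick)
        for r in sorted(chosen):
            g = site.ref_index(r)
            subs.append(
                PlannedSub(
                    rel_pos=r,
                    ref_base=ref[g],
                    alt_base=admissible[r],
                    ref_index=g,
                    synonymous=cds_frame is not None,
                )
            )

    if profile.pam_mask:
        for r in site.pam_guanine_rel_positions:
            g = site.ref_index(r)
            if not 0 <= g < len(ref):
                continue
            if cds_frame is None:
                alt = _pick_alt(ref[g], [b for b in "ACGT" if b != ref[g]])
            else:
                alt = _pick_alt(ref[g], synonymous_alternatives(ref, cds_frame, g))
            if alt is not None:
                subs.append(
                    PlannedSub(
                        rel_pos=r,
                        ref_base=ref[g],
                        alt_base=alt,
                        ref_index=g,
                        synonymous=cds_frame is not None,
                        pam_mask=True,
                    )
                )
                break  # mask a single guanine, as on the printed designs
    return subs


def _arm_lengths(total_len: int, symmetry: str, long_arm_side: str | None) -> tuple[int, int]:
    if symmetry == "S":
        if total_len % 2:
            raise DesignError("symmetric template length must be even")
        return total_len // 2, total_len // 2
    if symmetry == "A":
        short, long_ = 30, total_len - 30
        if long_ <= short:
            raise DesignError("asymmetric template too short for a 30 nt short arm")
        if long_arm_side == "left":
            return long_, short
        if long_arm_side == "right":
            return short, long_
        raise DesignError("asymmetric design needs long_arm_side 'left' or 'right'")
    raise DesignError(f"unknown symmetry {symmetry!r}")


def build_template(
    site: TargetSite,
    subs: list[PlannedSub],
    total_len: int,
    symmetry: str = "S",
    strand: str = "non_target",
    long_arm_side: str | None = None,
) -> RepairTemplate:
    """Assemble one ssODN design.

    Arms flank the cut on the protospacer strand ('left' = 5' of the cut
    = PAM-distal).  The edited protospacer-strand window *is* the NT
    oligo; the T oligo is its reverse complement.
    """
    if strand not in ("target", "non_target"):
        raise DesignError(f"unknown strand {strand!r}")
    left, right = _arm_lengths(total_len, symmetry, long_arm_side)
    ref = site.reference_seq
    c = site.cut_index
    if site.protospacer_strand == "forward":
        start, end = c - left, c + right
    else:
        start, end = c - right, c + left
    if start < 0 or end > len(ref):
        raise DesignError("arms out of bounds")

    window = list(ref[start:end])
    for s in subs:
        if start <= s.ref_index < end:
            if window[s.ref_index - start] != s.ref_base:
                raise DesignError(
                    f"planned substitution at ref index {s.ref_index} does not match the reference"
                )
            window[s.ref_index - start] = s.alt_base
    edited = "".join(window)
    ps_seq = edited if site.protospacer_strand == "forward" else reverse_complement(edited)
    seq = ps_seq if strand == "non_target" else reverse_complement(ps_seq)

    label = "NT" if strand == "non_target" else "T"
    if symmetry == "S":
        code = f"{label} {total_len} S"
    else:
        code = f"{label} {total_len} A {long_arm_side}"
    kept = tuple(s for s in subs if start <= s.ref_index < end)
    return RepairTemplate(
        design_code=code,
        strand=strand,
        sequence=seq,
        ps_sequence=ps_seq,
        left_arm_len=left,
        right_arm_len=right,
        window_start=start,
        window_end=end,
        subs=kept,
    )


#: the template geometries evaluated in the panel: three symmetric total
#: lengths and the two informative 120 nt asymmetries (30/90 arms).
PANEL_GEOMETRIES: tuple[tuple[int, str, str | None], ...] = (
    (60, "S", None),
    (120, "S", None),
    (180, "S", None),
    (120, "A", "left"),
    (120, "A", "right"),
)


def enumerate_designs(site: TargetSite, subs: list[PlannedSub]) -> list[RepairTemplate]:
    """The full ten-member ssODN panel: {NT, T} x {60 S, 120 S, 180 S,
    120 A left, 120 A right}."""
    return [
        build_template(site, subs, total_len, symmetry, strand, side)
        for strand in ("non_target", "target")
        for (total_len, symmetry, side) in PANEL_GEOMETRIES
    ]


def build_gblock(protospacer: str) -> str:
    """sgRNA in vitro transcription construct for a protospacer.

    T7 leader + GG + the last 18 nt of the protospacer + the invariant
    sgRNA scaffold; 125 nt in total.
    """
    proto = protospacer.upper()
    if len(proto) < 18:
        raise DesignError("protospacer too short (< 18 nt)")
    if any(b not in "ACGT" for b in proto):
        raise DesignError("protospacer must be unambiguous DNA")
    return T7_LEADER + "GG" + proto[-18:] + SGRNA_SCAFFOLD
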