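"""Synthetic amplicon reads with known repair outcomes.

The generator emulates pooled-embryo amplicon deep sequencing of a
CRISPR/Cas9 + ssODN experiment: each molecule is wild type, carries an
NHEJ indel at the cut, is a scarless HDR product carrying a subset of the
planned substitutions, or carries an erroneous integration of repair-
template fragments (possibly inverted, partial, multiple, interleaved
with untraceable filler, with an optional deletion of flanking locus
sequence).  Per-base sequencing errors are injected as substitutions.
Every read comes with a ground-truth record; erroneous reads reconstruct
exactly from their fragment chains, so the generator is its own decoder.

Default mixture proportions sit at the magnitudes reported for zebrafish
embryo pools (perfect and erroneous HDR a few percent each, NHEJ tens of
percent), and the default per-position incorporation declines about
fourfold from the cut-proximal to the cut-distal substitution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .design import RepairTemplate, TargetSite
from .fragments import (
    REFERENCE,
    TEMPLATE_FWD,
    TEMPLATE_REV,
    UNASSIGNED,
    Fragment,
    FragmentChain,
    chain_to_string,
)
from .microhomology import MAX_CONTEXT, junction_mh, mh_before

__all__ = [
    "IndelModel",
    "FragmentModel",
    "OutcomeSpec",
    "TruthRecord",
    "SimulatedSample",
    "default_incorporation",
    "make_perfect_read",
    "make_nhej_read",
    "make_erroneous_read",
    "simulate_sample",
    "write_fastq",
]

QUAL_CHAR = "?"  # constant Q30

CATEGORY_ORDER = ("WT", "NHEJ", "HDR_perfect", "HDR_erroneous")


@dataclass(frozen=True)
class IndelModel:
    """NHEJ indel sizes: geometric, capped; insertions vs deletions."""

    p_insertion: float = 1 / 3
    size_geom_p: float = 0.25
    max_size: int = 30


@dataclass(frozen=True)
class FragmentModel:
    """Erroneous-integration structure.

    ``mh_weight`` biases switch landing sites toward positions with >= 2 nt
    of homology to the preceding junction context (0 = uniform switching).
    Filler lengths stay below typical fragment-assignment thresholds, so
    filler reads back as unassigned.
    """

    n_frags_probs: tuple[float, ...] = (0.5, 0.3, 0.2)  # P(1), P(2), P(3) fragments
    p_reverse: float = 0.3
    min_frag_len: int = 20
    p_locus_deletion: float = 0.3
    max_deletion: int = 20
    p_filler: float = 0.2
    filler_len: tuple[int, int] = (3, 8)
    mh_weight: float = 4.0


def default_incorporation(template: RepairTemplate) -> dict[int, float]:
    """Linear decline from certain incorporation next to the cut to ~25%
    at 15 nt away (the observed several-fold distance decay)."""
    out = {}
    for r in template.rel_positions:
        d = abs(r)
        out[r] = max(0.25, 1.0 - 0.75 * (d - 1) / 14)
    out[template.closest_rel_pos] = 1.0
    return out


@dataclass(frozen=True)
class OutcomeSpec:
    """Mixture and noise parameters of one simulated sample."""

    n_reads: int = 10_000
    proportions: dict = field(
        default_factory=lambda: {
            "WT": 0.52,
            "NHEJ": 0.40,
            "HDR_perfect": 0.04,
            "HDR_erroneous": 0.04,
        }
    )
    per_position_incorporation: dict | None = None  # rel_pos -> probability
    indel_model: IndelModel = IndelModel()
    fragment_model: FragmentModel = FragmentModel()
    seq_error_rate: float = 0.001
    read_len: int = 250
    paired: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        probs = [self.proportions.get(c, 0.0) for c in CATEGORY_ORDER]
        if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("proportions must be probabilities summing to 1")
        if not 0 <= self.seq_error_rate < 1:
            raise ValueError("seq_error_rate must be in [0, 1)")


@dataclass
class TruthRecord:
    read_id: str
    category: str
    presence: dict[int, bool] = field(default_factory=dict)
    chain: FragmentChain | None = None
    indel: tuple[str, int] | None = None  # ("ins"|"del", size)
    junction_mh: list[int] = field(default_factory=list)


@dataclass
class SimulatedSample:
    """In-memory FASTQ + truth table."""

    reads: list  # single-end: (id, seq, qual); paired: (id, (s1, q1), (s2, q2))
    truth: list[TruthRecord]
    spec: OutcomeSpec

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            rows.append(
                {
                    "read_id": t.read_id,
                    "category": t.category,
                    "presence": ",".join(
                        f"{r}:{int(v)}" for r, v in sorted(t.presence.items())
                    ),
                    "chain": chain_to_string(t.chain) if t.chain else "",
                    "indel": f"{t.indel[0]}{t.indel[1]}" if t.indel else "",
                    "junction_mh": ",".join(map(str, t.junction_mh)),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["read_id", "category", "presence", "chain", "indel", "junction_mh"],
        )


def _rand_bases(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def make_perfect_read(
    template: RepairTemplate,
    incorporation: dict[int, float],
    rng: np.random.Generator,
    site: TargetSite,
) -> tuple[str, TruthRecord]:
    """A scarless HDR molecule: the reference with a sampled subset of the
    planned substitutions.  The cut-proximal substitution is always
    incorporated — it is what defines the molecule as an HDR product."""
    seq = list(site.reference_seq)
    presence: dict[int, bool] = {}
    closest = template.closest_rel_pos
    for sub in template.subs:
        p = 1.0 if sub.rel_pos == closest else incorporation.get(sub.rel_pos, 0.0)
        take = bool(rng.random() < p)
        if take:
            seq[sub.ref_index] = sub.alt_base
        presence[sub.rel_pos] = take
    return "".join(seq), TruthRecord("", "HDR_perfect", presence=presence)


def make_nhej_read(
    reference_window: str,
    cut: int,
    indel_model: IndelModel,
    rng: np.random.Generator,
) -> tuple[str, TruthRecord]:
    """One indel centred on the cut; no planned substitutions."""
    m = indel_model
    while True:
        size = min(int(rng.geometric(m.size_geom_p)), m.max_size)
        if rng.random() < m.p_insertion:
            ins = _rand_bases(rng, size)
            seq = reference_window[:cut] + ins + reference_window[cut:]
            return seq, TruthRecord("", "NHEJ", indel=("ins", size))
        left = size // 2
        right = size - left
        if cut - left < 0 or cut + right > len(reference_window):
            continue  # deletion exceeds the window; resample
        seq = reference_window[: cut - left] + reference_window[cut + right :]
        return seq, TruthRecord("", "NHEJ", indel=("del", size))


def _oriented_template(template_seq: str, orientation: str) -> str:
    return template_seq if orientation == TEMPLATE_FWD else reverse_complement(template_seq)


def _weighted_start(
    rng: np.random.Generator,
    upstream: str,
    oriented: str,
    frag_len: int,
    lo: int,
    hi: int,
    mh_weight: float,
) -> int:
    """Sample a fragment start in [lo, hi]; with mh_weight > 0, starts with
    >= 2 nt of homology to the upstream context are favoured."""
    starts = np.arange(lo, hi + 1)
    if mh_weight <= 0 or not len(upstream):
        return int(rng.choice(starts))
    w = np.ones(len(starts))
    for k, s in enumerate(starts):
        if mh_before(upstream, oriented, int(s)) >= 2:
            w[k] += mh_weight
    return int(rng.choice(starts, p=w / w.sum()))


def make_erroneous_read(
    template: RepairTemplate,
    reference_window: str,
    fragment_model: FragmentModel,
    rng: np.random.Generator,
    site: TargetSite,
) -> tuple[str, TruthRecord]:
    """A molecule with template-fragment integration at the cut.

    1..k template substrings (each forward or reverse-complement relative
    to the protospacer strand), optional untraceable filler between them,
    and an optional one-sided deletion of flanking locus sequence.  The
    first fragment always covers the cut-proximal planned substitution
    (SDSA initiates at the cut), making the molecule an HDR-erroneous
    product by construction.  Junction microhomology against each
    fragment's oriented source is recorded as sampled.
    """
    fm = fragment_model
    ref = reference_window
    cut = site.cut_index
    tpl = template.ps_sequence
    L = len(tpl)

    a = b = cut
    if rng.random() < fm.p_locus_deletion:
        d = int(rng.integers(1, fm.max_deletion + 1))
        if rng.random() < 0.5:
            a = max(0, cut - d)
        else:
            b = min(len(ref), cut + d)

    n_frags = 1 + int(rng.choice(len(fm.n_frags_probs), p=np.array(fm.n_frags_probs)))
    closest_off = template.ps_offset(template.closest_rel_pos)

    insert_parts: list[str] = []
    frags: list[Fragment] = []
    mh_list: list[int] = []
    pos = 0  # within the novel sequence
    for k in range(n_frags):
        upstream = (ref[:a] + "".join(insert_parts))[-MAX_CONTEXT:]
        if k > 0 and rng.random() < fm.p_filler:
            flen = int(rng.integers(fm.filler_len[0], fm.filler_len[1] + 1))
            filler = _rand_bases(rng, flen)
            mh_list.append(junction_mh(upstream, filler))
            frags.append(Fragment(UNASSIGNED, (pos, pos + flen)))
            insert_parts.append(filler)
            pos += flen
            upstream = (ref[:a] + "".join(insert_parts))[-MAX_CONTEXT:]
        orientation = TEMPLATE_REV if rng.random() < fm.p_reverse else TEMPLATE_FWD
        oriented = _oriented_template(tpl, orientation)
        frag_len = int(rng.integers(fm.min_frag_len, L + 1))
        if k == 0:
            # oriented-coordinate position of the cut-proximal substitution
            tgt = closest_off if orientation == TEMPLATE_FWD else L - 1 - closest_off
            lo = max(0, tgt - frag_len + 1)
            hi = min(L - frag_len, tgt)
            if hi < lo:  # fragment longer than needed; anchor at the boundary
                lo = hi = max(0, min(L - frag_len, tgt))
            start = _weighted_start(rng, upstream, oriented, frag_len, lo, hi, fm.mh_weight)
        else:
            start = _weighted_start(
                rng, upstream, oriented, frag_len, 0, L - frag_len, fm.mh_weight
            )
        mh_list.append(mh_before(upstream, oriented, start))
        piece = oriented[start : start + frag_len]
        if orientation == TEMPLATE_REV:
            src_iv = (L - start - frag_len, L - start)
        else:
            src_iv = (start, start + frag_len)
        frags.append(
            Fragment(orientation, (pos, pos + frag_len), source_interval=src_iv, oriented_start=start)
        )
        insert_parts.append(piece)
        pos += frag_len

    novel = "".join(insert_parts)
    upstream = (ref[:a] + novel)[-MAX_CONTEXT:]
    mh_list.append(mh_before(upstream, ref, b))
    seq = ref[:a] + novel + ref[b:]

    chain = FragmentChain(
        fragments=frags, novel_seq=novel, left_flank_end=a, right_flank_start=b
    )
    presence = {
        sub.rel_pos: chain.template_coverage(template.ps_offset(sub.rel_pos))
        for sub in template.subs
    }
    return seq, TruthRecord(
        "", "HDR_erroneous", presence=presence, chain=chain, junction_mh=mh_list
    )


def _inject_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    out = list(seq)
    for p in positions:
        out[p] = "ACGT"[(("ACGT".index(out[p]) + 1 + int(rng.integers(0, 3))) % 4)]
    return "".join(out)


def simulate_sample(
    spec: OutcomeSpec,
    site: TargetSite,
    template: RepairTemplate,
) -> SimulatedSample:
    """Draw ``n_reads`` molecules from the outcome mixture and emit reads.

    Single-end mode emits each full molecule (representing merged
    amplicon reads); paired mode emits ``2 x read_len`` mates from the
    molecule ends, which must overlap by at least 20 bases.  Identical
    seeds give byte-identical output.
    """
    spec.validate()
    if spec.paired and len(site.reference_seq) > 2 * spec.read_len - 20:
        raise ValueError("amplicon too long for read configuration")
    rng = np.random.default_rng(spec.seed)
    probs = np.array([spec.proportions.get(c, 0.0) for c in CATEGORY_ORDER])
    counts = rng.multinomial(spec.n_reads, probs)
    categories = np.repeat(np.arange(len(CATEGORY_ORDER)), counts)
    rng.shuffle(categories)
    incorporation = (
        spec.per_position_incorporation
        if spec.per_position_incorporation is not None
        else default_incorporation(template)
    )

    reads = []
    truth: list[TruthRecord] = []
    for i, ci in enumerate(categories):
        cat = CATEGORY_ORDER[ci]
        if cat == "WT":
            seq, rec = site.reference_seq, TruthRecord("", "WT")
        elif cat == "NHEJ":
            seq, rec = make_nhej_read(site.reference_seq, site.cut_index, spec.indel_model, rng)
        elif cat == "HDR_perfect":
            seq, rec = make_perfect_read(template, incorporation, rng, site)
        else:
            seq, rec = make_erroneous_read(
                template, site.reference_seq, spec.fragment_model, rng, site
            )
        rec.read_id = f"read_{i:06d}"
        seq = _inject_errors(seq, spec.seq_error_rate, rng)
        truth.append(rec)
        if spec.paired:
            m1 = seq[: spec.read_len]
            m2 = reverse_complement(seq[-spec.read_len :])
            reads.append(
                (rec.read_id, (m1, QUAL_CHAR * len(m1)), (m2, QUAL_CHAR * len(m2)))
            )
        else:
            reads.append((rec.read_id, seq, QUAL_CHAR * len(seq)))
    return SimulatedSample(reads=reads, truth=truth, spec=spec)


def write_fastq(sample: SimulatedSample, path, path2=None) -> None:
    """Write the sample as FASTQ (two files in paired mode)."""
    if sample.spec.paired:
        if path2 is None:
            raise ValueError("paired output needs two paths")
        with open(path, "w") as f1, open(path2, "w") as f2:
            for read_id, (s1, q1), (s2, q2) in sample.reads:
                f1.write(f"@{read_id}/1\n{s1}\n+\n{q1}\n")
                f2.write(f"@{read_id}/2\n{s2}\n+\n{q2}\n")
    else:
        with open(path, "w") as f:
            for read_id, seq, qual in sample.reads:
                f.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
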