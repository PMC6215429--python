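"""Target-site geometry, substitution planning and the ssODN panel."""

import numpy as np
import pytest
from Bio.Seq import Seq, reverse_complement

from hdramp import (
    DesignError,
    DesignProfile,
    build_gblock,
    build_template,
    enumerate_designs,
    locate_cut_site,
    plan_substitutions,
)
from hdramp.design import SGRNA_SCAFFOLD, T7_LEADER, synonymous_alternatives

from .conftest import SMAD6A_PROTOSPACER, random_dna
from .oracles import brute_force_cut, revcomp


class TestLocateCutSite:
    def test_blunt_cut_three_bp_upstream_of_pam(self):
        ref = "T" * 10 + SMAD6A_PROTOSPACER + "AGG" + "A" * 30
        site = locate_cut_site(ref, SMAD6A_PROTOSPACER)
        assert site.pam_start == 29
        assert site.cut_index == 26

    def test_reverse_strand_gives_same_physical_cut(self):
        fwd = "TCA" * 10 + SMAD6A_PROTOSPACER + "AGG" + "GAT" * 10
        site_f = locate_cut_site(fwd, SMAD6A_PROTOSPACER)
        site_r = locate_cut_site(reverse_complement(fwd), SMAD6A_PROTOSPACER)
        assert site_r.protospacer_strand == "reverse"
        assert site_r.cut_index == len(fwd) - site_f.cut_index

    def test_missing_and_ambiguous_targets_raise(self):
        ref = "A" * 60
        with pytest.raises(DesignError, match="not found"):
            locate_cut_site(ref, SMAD6A_PROTOSPACER)
        twice = ("T" * 5 + SMAD6A_PROTOSPACER + "AGG") * 2 + "A" * 10
        with pytest.raises(DesignError, match="ambiguous"):
            locate_cut_site(twice, SMAD6A_PROTOSPACER)

    def test_matches_exhaustive_scan_on_random_references(self):
        rng = np.random.default_rng(42)
        n_checked = 0
        for _ in range(200):
            proto = random_dna(rng, 19)
            left = random_dna(rng, int(rng.integers(30, 80)))
            right = random_dna(rng, int(rng.integers(30, 80)))
            strand = rng.random() < 0.5
            insert = proto + "TGG"
            if strand:
                insert = revcomp(insert)
            ref = left + insert + right
            try:
                expected = brute_force_cut(ref, proto)
            except AssertionError:
                continue  # accidental extra hit; not a valid instance
            try:
                site = locate_cut_site(ref, proto)
            except DesignError:
                continue  # ambiguous under IUPAC NGG but not the strict scan
            n_checked += 1
            assert (site.protospacer_strand, site.pam_start, site.cut_index) == expected
        assert n_checked > 150


class TestPlanSubstitutions:
    def test_window_confined_with_pam_mask(self, coding_locus):
        subs = plan_substitutions(coding_locus, cds_frame=0)
        regular = [s for s in subs if not s.pam_mask]
        masks = [s for s in subs if s.pam_mask]
        assert len(regular) == 5
        assert all(-15 <= s.rel_pos <= 11 for s in regular)
        assert all(s.synonymous for s in subs)
        if masks:  # a synonymous PAM mask is added whenever possible
            assert masks[0].rel_pos in (5, 6)
            assert masks[0].ref_base == "G" or coding_locus.protospacer_strand == "reverse"

    def test_synonymous_substitutions_preserve_protein(self, coding_locus):
        subs = plan_substitutions(coding_locus, cds_frame=0)
        ref = coding_locus.reference_seq
        edited = list(ref)
        for s in subs:
            edited[s.ref_index] = s.alt_base
        assert Seq("".join(edited)).translate() == Seq(ref).translate()

    def test_zero_request_returns_empty(self, site):
        assert plan_substitutions(site, profile=DesignProfile(n_subs=0, pam_mask=False)) == []

    def test_closest_to_cut_position_always_included(self, site):
        subs = plan_substitutions(site)
        positions = [s.rel_pos for s in subs if not s.pam_mask]
        assert min(abs(p) for p in positions) == 1

    @pytest.mark.parametrize(
        "codon, pos",
        [("CTG", 2), ("ATG", 2), ("TGG", 1), ("GGA", 2), ("AAA", 0)],
    )
    def test_synonymous_alternatives_match_codon_table(self, codon, pos):
        from Bio.Data.CodonTable import standard_dna_table

        table = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            table[stop] = "*"
        expected = sorted(
            b
            for b in "ACGT"
            if b != codon[pos] and table[codon[:pos] + b + codon[pos + 1 :]] == table[codon]
        )
        assert sorted(synonymous_alternatives(codon, 0, pos)) == expected


class TestBuildTemplate:
    def test_symmetric_120_has_60_nt_arms(self, site, subs):
        t = build_template(site, subs, 120, "S", "non_target")
        assert (t.left_arm_len, t.right_arm_len) == (60, 60)
        assert t.total_len == 120 == len(t.sequence)

    def test_no_substitutions_yields_reference_substring(self, site):
        t = build_template(site, [], 60, "S", "non_target")
        assert t.sequence in site.reference_seq

    def test_strand_duality(self, site, subs):
        nt = build_template(site, subs, 120, "S", "non_target")
        tt = build_template(site, subs, 120, "S", "target")
        assert tt.sequence == reverse_complement(nt.sequence)
        assert tt.ps_sequence == nt.ps_sequence

    def test_arms_out_of_bounds(self, site):
        with pytest.raises(DesignError, match="out of bounds"):
            build_template(site, [], 600, "S", "non_target")

    def test_template_differs_from_reference_exactly_at_planned_positions(self, site, subs):
        """Character-diff oracle over random panel geometries."""
        rng = np.random.default_rng(3)
        ref = site.reference_seq
        for _ in range(200):
            total = int(rng.choice([60, 120, 180]))
            symmetry = "S" if total != 120 or rng.random() < 0.5 else "A"
            side = str(rng.choice(["left", "right"])) if symmetry == "A" else None
            strand = str(rng.choice(["target", "non_target"]))
            t = build_template(site, subs, total, symmetry, strand, side)
            window = ref[t.window_start : t.window_end]
            ps = t.ps_sequence if site.protospacer_strand == "forward" else revcomp(t.ps_sequence)
            diffs = {
                t.window_start + k for k, (a, b) in enumerate(zip(window, ps)) if a != b
            }
            assert diffs == {s.ref_index for s in t.subs}
            assert len(t.subs) == len(subs)  # all planned subs inside every window


class TestEnumerateDesigns:
    def test_panel_is_ten_distinct_designs(self, panel):
        codes = [t.design_code for t in panel]
        assert len(codes) == 10 and len(set(codes)) == 10
        assert {t.total_len for t in panel} == {60, 120, 180}

    def test_asymmetric_members_have_30_90_arms(self, panel):
        asym = [t for t in panel if " A " in t.design_code]
        assert len(asym) == 4
        for t in asym:
            assert sorted((t.left_arm_len, t.right_arm_len)) == [30, 90]

    def test_invariants_hold_for_every_member(self, panel, site):
        for t in panel:
            assert t.left_arm_len + t.right_arm_len == t.total_len == len(t.sequence)
            # planned edits recoverable from the sequence itself
            ref_ps = (
                site.reference_seq
                if site.protospacer_strand == "forward"
                else revcomp(site.reference_seq)
            )
            # ps window within protospacer-strand reference
            cut_ps = (
                site.cut_index
                if site.protospacer_strand == "forward"
                else len(site.reference_seq) - site.cut_index
            )
            window = ref_ps[cut_ps - t.left_arm_len : cut_ps + t.right_arm_len]
            n_diff = sum(a != b for a, b in zip(window, t.ps_sequence))
            assert n_diff == len(t.subs)


class TestGBlock:
    def test_n_segment_is_last_18_nt(self):
        gb = build_gblock(SMAD6A_PROTOSPACER)
        assert gb.startswith(T7_LEADER + "GG")
        assert gb[27:45] == SMAD6A_PROTOSPACER[-18:]
        assert gb.endswith(SGRNA_SCAFFOLD)

    def test_18mer_protospacer_used_verbatim(self):
        proto = SMAD6A_PROTOSPACER[-18:]
        gb = build_gblock(proto)
        assert gb[27:45] == proto

    def test_total_length_125(self):
        assert len(build_gblock(SMAD6A_PROTOSPACER)) == 125
        assert len(build_gblock("ACGTACGTACGTACGTACGT")) == 125

    def test_short_protospacer_rejected(self):
        with pytest.raises(DesignError, match="too short"):
            build_gblock("ACGTACGT")
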