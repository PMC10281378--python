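"""Array detection, ORF scanning, anti-repeat search, sgRNA assembly,
target enumeration, and recombineering templates."""

import numpy as np
import pytest

from cas9kit.errors import UsageError
from cas9kit.locus_miner import (apply_recombination, build_recomb_template,
                                 design_sgrna, eh_sgrna, find_anti_repeat,
                                 find_crispr_arrays, find_orfs, find_targets)
from cas9kit.seq_io import IupacPattern, SeqRecord, iupac_match, revcomp
from cas9kit.synthetic_data import eh_locus_contig, gen_locus_contig
from tests.conftest import random_record


class TestArrayDetection:
    def test_eh_preset_geometry_recovered(self):
        contig, truth = eh_locus_contig(seed=0, orf_len_aa=120)
        (arr,) = find_crispr_arrays(contig)
        assert arr.repeat_length == 36
        assert arr.spacer_lengths == [29]
        assert len(arr.units) == 2
        assert [list(u) for u in arr.units] == truth["units"]

    def test_recovery_over_random_seeds(self):
        """Planted geometry is recovered for 50 random seeds."""
        for seed in range(50):
            contig, truth = eh_locus_contig(seed=seed, orf_len_aa=100)
            (arr,) = find_crispr_arrays(contig)
            assert (arr.repeat_length, arr.spacer_lengths,
                    len(arr.units)) == (36, [29], 2), f"seed {seed}"

    def test_random_contig_agrees_with_brute_force_oracle(self):
        """An i.i.d. contig: the detector and an exhaustive repeated-substring
        oracle agree that there is no array."""
        contig = random_record(np.random.default_rng(11), 800, "rand")
        seq = contig.bases

        def oracle_has_array(min_rep=18, max_rep=45, min_sp=15, max_sp=45):
            for i in range(len(seq)):
                for d in range(min_rep + min_sp, max_rep + max_sp + 1):
                    j = i + d
                    for L in range(min_rep, min(max_rep, d - min_sp) + 1):
                        if j + L > len(seq):
                            break
                        if d - L < min_sp:
                            continue
                        if seq[i:i + L] == seq[j:j + L]:
                            return True
            return False

        assert find_crispr_arrays(contig) == []
        assert not oracle_has_array()

    def test_short_contig_empty(self):
        assert find_crispr_arrays(SeqRecord("s", "ACGTACGT")) == []

    def test_multi_unit_array(self):
        rng = np.random.default_rng(21)
        repeat = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 30)])
        spacers = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 20)])
                   for _ in range(3)]
        contig, truth = gen_locus_contig(repeat, spacers, 100, 3, seed=22)
        (arr,) = find_crispr_arrays(contig)
        assert len(arr.units) == 4
        assert arr.repeat_consensus == repeat
        assert [s for s, _, _ in arr.spacers] == truth["spacers"]


class TestOrfScan:
    def test_planted_forward_orf(self):
        contig, truth = eh_locus_contig(seed=2, orf_len_aa=150)
        orfs = find_orfs(contig, 100)
        match = [(s, e, st, p) for s, e, st, p in orfs
                 if [s, e] == truth["orf"]]
        assert len(match) == 1
        s, e, strand, protein = match[0]
        assert strand == "+" and len(protein) == 150
        assert protein == truth["protein"]

    def test_reverse_strand_orf_maps_back(self):
        contig, truth = eh_locus_contig(seed=3, orf_len_aa=140)
        flipped = SeqRecord("rc", revcomp(contig.bases))
        n = len(contig.bases)
        s, e = truth["orf"]
        expect = (n - e, n - s)
        hits = [(a, b, st, p) for a, b, st, p in find_orfs(flipped, 100)
                if (a, b) == expect]
        assert len(hits) == 1
        assert hits[0][2] == "-" and hits[0][3] == truth["protein"]

    def test_all_a_contig_has_no_orfs(self):
        assert find_orfs(SeqRecord("a", "A" * 600), 100) == []

    def test_open_ended_orf_flag(self):
        seq = "TAA" + "ATG" + "GCT" * 120  # no stop before the contig edge
        contig = SeqRecord("open", seq)
        assert find_orfs(contig, 100) == []
        (orf,) = find_orfs(contig, 100, include_open=True)
        assert orf[2] == "+" and len(orf[3]) == 121


class TestAntiRepeat:
    def test_planted_anti_repeat_found(self):
        contig, truth = eh_locus_contig(seed=4, orf_len_aa=110)
        (arr,) = find_crispr_arrays(contig)
        hits = find_anti_repeat(contig, arr)
        assert hits
        best = hits[0]
        assert [best.start, best.end] == truth["anti_repeat"]
        assert best.mismatches == 4 and best.strand == "-"

    def test_tighter_budget_excludes_it(self):
        contig, _ = eh_locus_contig(seed=4, orf_len_aa=110)
        (arr,) = find_crispr_arrays(contig)
        assert find_anti_repeat(contig, arr, max_mismatch=2) == []

    def test_array_units_never_reported(self):
        contig, _ = eh_locus_contig(seed=5, orf_len_aa=110)
        (arr,) = find_crispr_arrays(contig)
        for cand in find_anti_repeat(contig, arr, max_mismatch=6):
            for us, ue in arr.units:
                assert cand.end <= us or ue <= cand.start


class TestSgRNADesign:
    def test_default_architecture_lengths(self, eh):
        sg = eh_sgrna()
        assert len(sg) == 118
        assert len(sg) - len(sg.spacer) == 95
        assert sg.linker == "GAAA"
        assert sg.full_sequence == (sg.spacer + sg.repeat_part + sg.linker
                                    + sg.tracr_part)

    def test_component_coordinates_partition(self):
        sg = eh_sgrna()
        comps = sg.components
        assert comps["spacer"] == (0, 23)
        assert comps["tracr_part"][1] == len(sg)
        spans = sorted(comps.values())
        assert all(a[1] == b[0] for a, b in zip(spans, spans[1:]))

    def test_empty_spacer_gives_backbone_only(self, eh):
        sg = design_sgrna(eh["repeat"], eh["tracrrna"], "")
        assert len(sg) == 95

    def test_additivity(self, eh):
        sg = design_sgrna(eh["repeat"], eh["tracrrna"], "A" * 20,
                          keep_repeat=20, keep_tracr=70)
        assert len(sg) == 20 + 20 + 4 + 70 == 114

    def test_duplex_mismatches_within_budget(self):
        assert eh_sgrna().duplex_mismatches <= 6

    def test_truncation_longer_than_source(self, eh):
        with pytest.raises(UsageError):
            design_sgrna("ACGT" * 4, eh["tracrrna"], "", keep_repeat=18)
        with pytest.raises(UsageError):
            design_sgrna(eh["repeat"], "ACGT", "", keep_tracr=73)


class TestFindTargets:
    @staticmethod
    def oracle(seq: str, pam: str, glen: int):
        """Independent sliding-window enumeration on both strands."""
        hits = set()
        plen = len(pam)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for i in range(len(s) - glen - plen + 1):
                if iupac_match(s[i + glen:i + glen + plen], pam):
                    if strand == "+":
                        hits.add((i, i + glen, "+"))
                    else:
                        hits.add((len(s) - i - glen, len(s) - i, "-"))
        return hits

    @pytest.mark.parametrize("pam", ["TGGN", "NGGN"])
    def test_matches_oracle_on_random_sequences(self, pam):
        rng = np.random.default_rng(3)
        for _ in range(100):
            rec = random_record(rng, 500)
            got = {(t.start, t.end, t.strand)
                   for t in find_targets(rec, IupacPattern(pam), 23)}
            assert got == self.oracle(rec.bases, pam, 23)

    def test_no_gg_no_hits(self):
        rec = SeqRecord("x", "ATATATATAT" * 10)
        assert find_targets(rec, IupacPattern("TGGN"), 23) == []

    def test_minus_strand_round_trip(self):
        rng = np.random.default_rng(9)
        rec = random_record(rng, 300)
        for t in find_targets(rec, IupacPattern("TGGN"), 23):
            if t.strand == "-":
                assert revcomp(t.protospacer + t.pam_region) in rec.bases

    def test_pam_region_matches_pattern(self):
        rec = random_record(np.random.default_rng(4), 400)
        for t in find_targets(rec, IupacPattern("TGGN"), 23):
            assert iupac_match(t.pam_region, "TGGN")


class TestRecombTemplate:
    def test_reported_arm_lengths_give_308(self):
        tpl = build_recomb_template("A" * 145, "G" * 163)
        assert len(tpl) == 308
        assert tpl.arm_boundary == 145

    def test_tiny_concat(self):
        tpl = build_recomb_template("AAA", "TTT")
        assert tpl.sequence == "AAATTT" and len(tpl) == 6

    def test_empty_arm_rejected(self):
        with pytest.raises(UsageError):
            build_recomb_template("", "ACGT")

    def test_in_silico_recombination_deletes_between_arm_segment(self):
        rng = np.random.default_rng(6)
        up = random_record(rng, 40).bases
        mid = random_record(rng, 60).bases
        down = random_record(rng, 45).bases
        locus = "CC" + up + mid + down + "GG"
        tpl = build_recomb_template(up, down)
        assert apply_recombination(locus, tpl) == "CC" + up + down + "GG"
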