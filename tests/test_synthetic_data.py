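"""Generators: conservation, determinism, and planted ground truth."""

import numpy as np
import pytest
from scipy import stats

from cas9kit.errors import ConfigError, UsageError
from cas9kit.pam_depletion import count_pams
from cas9kit.seq_io import IupacPattern, SeqRecord, revcomp
from cas9kit.synthetic_data import (ActivityModel, PamLibrarySpec,
                                    apply_allele, eh_locus_contig,
                                    gen_cleavage_fragments,
                                    gen_editing_amplicons, gen_locus_contig,
                                    gen_pam_library, gen_screen_reads,
                                    load_preset, normalize_label,
                                    parse_allele_label)
from tests.conftest import ADAPTER, FLANKS, random_record


class TestPamLibrary:
    def test_variant_enumeration_and_conservation(self, invivo_spec):
        table, truth = gen_pam_library(invivo_spec, 6400, skew=0.0, seed=1)
        assert len(table.counts) == 64
        assert table.total == 6400
        assert all(v.startswith("T") for v in table.variants)

    def test_seed_determinism(self, invivo_spec):
        t1, _ = gen_pam_library(invivo_spec, 6400, seed=1)
        t2, _ = gen_pam_library(invivo_spec, 6400, seed=1)
        assert t1.counts == t2.counts

    def test_uniform_composition_chi_square(self, invivo_spec):
        """skew 0 at high depth passes a chi-square uniformity test."""
        table, _ = gen_pam_library(invivo_spec, 10**6, skew=0.0, seed=2)
        counts = np.array(list(table.counts.values()))
        assert stats.chisquare(counts).pvalue > 0.001

    def test_skew_unbalances(self, invivo_spec):
        table, _ = gen_pam_library(invivo_spec, 10**5, skew=2.0, seed=3)
        counts = np.array(list(table.counts.values()))
        assert counts.max() > 5 * max(counts.min(), 1)

    def test_nonpositive_depth(self, invivo_spec):
        with pytest.raises(UsageError):
            gen_pam_library(invivo_spec, 0)


class TestScreenReads:
    def test_null_model_frequencies_match(self, invivo_spec):
        """survival == 1 everywhere: arm compositions differ only by noise."""
        lib, _ = gen_pam_library(invivo_spec, 50_000, seed=4)
        act = ActivityModel({v: 1.0 for v in lib.variants})
        treat, ctrl, _ = gen_screen_reads(lib, act, 50_000, 0.0, FLANKS,
                                          invivo_spec, seed=5)
        t = count_pams(treat, invivo_spec)
        c = count_pams(ctrl, invivo_spec)
        obs = np.array([[t.counts[v], c.counts[v]] for v in t.variants])
        assert stats.chi2_contingency(obs.T).pvalue > 0.001

    def test_error_free_reads_equal_ground_truth_tally(self, invivo_spec):
        lib, _ = gen_pam_library(invivo_spec, 1000, seed=6)
        act = ActivityModel({v: 1.0 for v in lib.variants})
        treat, ctrl, truth = gen_screen_reads(lib, act, 1000, 0.0, FLANKS,
                                              invivo_spec, seed=7)
        t = count_pams(treat, invivo_spec, max_anchor_mismatch=0)
        assert t.counts == truth["treatment_counts"]
        assert t.unassigned == 0

    def test_missing_variant_rejected(self, invivo_spec):
        lib, _ = gen_pam_library(invivo_spec, 100, seed=0)
        partial = ActivityModel({v: 1.0 for v in list(lib.variants)[:10]})
        with pytest.raises(ConfigError):
            gen_screen_reads(lib, partial, 10, 0.0, FLANKS, invivo_spec)

    def test_error_rate_bounds(self, invivo_spec):
        lib, _ = gen_pam_library(invivo_spec, 100, seed=0)
        act = ActivityModel({v: 1.0 for v in lib.variants})
        with pytest.raises(UsageError):
            gen_screen_reads(lib, act, 10, 0.5, FLANKS, invivo_spec)


class TestCleavageFragments:
    def test_only_cleaved_variants_yield_junctions(self, invivo_spec):
        lib, _ = gen_pam_library(invivo_spec, 10_000, seed=8)
        target = "TGGA"
        act = ActivityModel({v: (0.0 if v == target else 1.0)
                             for v in lib.variants})
        reads, ctx, truth = gen_cleavage_fragments(lib, act, 3, 0, ADAPTER,
                                                   5000, invivo_spec, seed=9)
        assert set(truth["cleaved_counts"]) == {target}
        top = [r for r in reads if r.id.endswith("top")]
        assert top and all(target in r.bases for r in top)

    def test_blunt_and_staggered_termini(self, invivo_spec):
        lib, _ = gen_pam_library(invivo_spec, 1000, seed=10)
        act = ActivityModel({v: 0.0 for v in lib.variants})
        _, ctx, truth = gen_cleavage_fragments(lib, act, 3, 0, ADAPTER, 100,
                                               invivo_spec, seed=11)
        assert truth["top_terminus"] == truth["bottom_terminus"] == \
            ctx.pam_start - 3
        _, _, truth4 = gen_cleavage_fragments(lib, act, 3, 4, ADAPTER, 100,
                                              invivo_spec, seed=11)
        assert truth4["top_terminus"] - truth4["bottom_terminus"] == 4

    def test_short_adapter_rejected(self, invivo_spec):
        lib, _ = gen_pam_library(invivo_spec, 100, seed=0)
        act = ActivityModel({v: 0.0 for v in lib.variants})
        with pytest.raises(ConfigError):
            gen_cleavage_fragments(lib, act, 3, 0, "ACGT", 10, invivo_spec)


class TestEditingAmplicons:
    def _ref(self, seed=12, n=120):
        return random_record(np.random.default_rng(seed), n, "ref")

    def test_no_editing_no_noise(self):
        ref = self._ref()
        reads, truth = gen_editing_amplicons(ref, 60, 0.0, {}, 0.0, 50,
                                             seed=13)
        assert all(r.bases == ref.bases for r in reads)
        assert all(x["class"] == "wt" for x in truth["reads"])

    def test_pure_single_deletion_spectrum(self):
        """spectrum {-2:1D: 1} at rate 1: every read lacks the base at cut-2."""
        ref = self._ref()
        cut = 60
        reads, _ = gen_editing_amplicons(ref, cut, 1.0, {"-2:1D": 1.0}, 0.0,
                                         20, seed=14)
        expected = ref.bases[:cut - 2] + ref.bases[cut - 1:]
        assert all(r.bases == expected for r in reads)

    def test_indel_count_binomial(self):
        reads, truth = gen_editing_amplicons(self._ref(), 60, 0.1,
                                             {"-2:1D": 1.0}, 0.0, 10_000,
                                             seed=15)
        n_indel = sum(1 for x in truth["reads"] if x["class"] == "indel")
        sd = np.sqrt(10_000 * 0.1 * 0.9)
        assert abs(n_indel - 1000) <= 3 * sd

    def test_label_outside_amplicon_rejected(self):
        with pytest.raises(ConfigError):
            gen_editing_amplicons(self._ref(), 5, 1.0, {"-10:3D": 1.0}, 0.0,
                                  1, seed=0)

    def test_label_parsing(self):
        assert parse_allele_label("-2:1D") == (-2, 1, "D")
        assert parse_allele_label("+1:2I") == (1, 2, "I")
        for bad in ("0:1D", "2D", "-2:0D", "-2:1X"):
            with pytest.raises(UsageError):
                parse_allele_label(bad)

    def test_apply_and_normalize(self):
        ref = "AAACGTACGTTT"
        # deletion of the G at cut-2 (index 4) in a non-repetitive context
        assert apply_allele(ref, 6, "-2:1D") == "AAACTACGTTT"
        # left-shift through the homopolymer: deleting either T of TT is the
        # same allele, reported at its leftmost placement
        assert normalize_label("AATTC", 4, "-1:1D") == "-2:1D"
        assert apply_allele("AATTC", 4, "-1:1D") == apply_allele(
            "AATTC", 4, "-2:1D")


class TestLocusContig:
    def test_eh_preset_planted_truth_by_substring(self, eh):
        contig, truth = eh_locus_contig(seed=0, orf_len_aa=120)
        seq = contig.bases
        for s, e in truth["units"]:
            assert seq[s:e] == eh["repeat"]
        (sp,) = truth["spacer_coords"]
        assert seq[sp[0]:sp[1]] == eh["array_spacer"]
        a = truth["anti_repeat"]
        anti = seq[a[0]:a[1]]
        mm = sum(x != y for x, y in zip(anti, revcomp(eh["repeat"])))
        assert mm == truth["anti_repeat_mismatches"] == 4

    def test_orf_translates_to_requested_length(self):
        contig, truth = gen_locus_contig("A" * 10 + "CGTTGCAATGCATCGATTGG",
                                         ["ACGT" * 5], 150, 2, seed=1)
        from Bio.Seq import Seq

        s, e = truth["orf"]
        protein = str(Seq(contig.bases[s:e]).translate())
        assert protein.endswith("*") and len(protein) - 1 == 150
        assert truth["protein"] == protein[:-1]

    def test_seed_determinism(self):
        c1, _ = eh_locus_contig(seed=3, orf_len_aa=110)
        c2, _ = eh_locus_contig(seed=3, orf_len_aa=110)
        assert c1.bases == c2.bases

    def test_parameter_validation(self):
        with pytest.raises(UsageError):
            gen_locus_contig("ACGT", [], 150)  # repeat too short
        with pytest.raises(UsageError):
            gen_locus_contig("A" * 20, [], 50)  # ORF too short


class TestActivityModel:
    def test_probability_bounds(self):
        with pytest.raises(UsageError):
            ActivityModel({"TGGA": 1.5})

    def test_from_rule(self):
        act = ActivityModel.from_rule("TNNN", "NGGN", 1e-4, 1.0)
        assert act.survival["TGGA"] == 1e-4
        assert act.survival["TACA"] == 1.0
        assert len(act.survival) == 64
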