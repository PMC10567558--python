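"""Simulator tests: control construction, chemistry agreement with the
decoding tables, determinism, and parameter recovery at small scale."""

import numpy as np
import pytest

from hairpincode import (ConversionModel, DecodingModel, Methylome,
                         make_controls, make_sample_genome, simulate_library)
from hairpincode.codec import BasePairColumn, resolve_pair
from hairpincode.simulate import (STATE_5HMC, STATE_5MC, STATE_UNMOD,
                                  _convert_fragment, cytosine_context)


class TestControls:
    def test_lambda_like_every_cpg_is_5mc_both_strands(self, controls):
        refs, meth = controls
        lam = meth.df[meth.df.chrom == "lambda_like"]
        cpg = lam[lam.context == "CpG"]
        assert len(cpg) > 0
        assert (cpg.state == STATE_5MC).all()
        assert (cpg.level == 1.0).all()
        assert set(cpg.strand) == {"+", "-"}
        # sanity: CpG rows come in strand pairs across every CpG dinucleotide
        seq = refs["lambda_like"]
        n_cpg_dinucl = seq.count("CG")
        assert len(cpg) == 2 * n_cpg_dinucl

    def test_puc19_like_has_zero_modified_positions(self, controls):
        _, meth = controls
        puc = meth.df[meth.df.chrom == "puc19_like"]
        assert (puc.state == STATE_UNMOD).all()
        assert (puc.level == 0.0).all()

    def test_hmc_oligo_has_three_hmc_strand_positions(self, controls):
        refs, meth = controls
        oligo = meth.df[(meth.df.chrom == "hmc_oligo")
                        & (meth.df.state == STATE_5HMC)]
        assert len(oligo) == 3
        # symmetric CpG: a +/- pair at adjacent positions; asymmetric: a
        # lone + site
        plus = sorted(oligo[oligo.strand == "+"].pos)
        minus = sorted(oligo[oligo.strand == "-"].pos)
        assert len(plus) == 2 and len(minus) == 1
        assert minus[0] == plus[0] + 1
        seq = refs["hmc_oligo"]
        assert len(seq) == 80
        for p in plus:
            assert seq[p:p + 2] == "CG"

    def test_context_annotation(self):
        #        0123456
        seq = "ACGACTACA"
        assert cytosine_context(seq, 1, "+") == "CpG"
        assert cytosine_context(seq, 4, "+") == "CHH"   # C T A
        assert cytosine_context(seq, 7, "+") == "CHH"   # C A (end)
        assert cytosine_context(seq, 2, "-") == "CpG"   # G preceded by C
        seq2 = "CAG"
        assert cytosine_context(seq2, 0, "+") == "CHG"


class TestChemistryAgreement:
    """The simulator and the permissible-pair tables are independent
    renderings of the conversion chemistry; with zero failure rates every
    simulated column must land exactly on the table."""

    def test_five_letter_single_base_states(self, five_letter):
        rng = np.random.default_rng(0)
        conv = ConversionModel()
        cases = {  # fragment, state string -> expected original/copy arms
            ("A", "."): ("A", "T"),
            ("T", "."): ("T", "A"),
            ("G", "."): ("G", "T"),
            ("C", "."): ("T", "G"),
            ("C", "m"): ("C", "G"),
            ("C", "h"): ("C", "G"),
        }
        for (frag, states), expected in cases.items():
            got = _convert_fragment(frag, states, False, conv, rng)
            assert got == expected
            col = BasePairColumn(got[0][0], got[1][0], 30, 30)
            st = resolve_pair(col, five_letter)
            assert st.genetic_base == frag
            assert (st.mod_status != "none") == (states != ".")

    def test_six_letter_cpg_unit_patterns(self, six_letter):
        rng = np.random.default_rng(0)
        conv = ConversionModel()
        cases = {
            ("CG", ".."): ("TG", "GT"),   # unmod CpG
            ("CG", "m."): ("CG", "GC"),   # 5mC: methyl copied -> protected C
            ("CG", "h."): ("CG", "GT"),   # 5hmC: no copy
        }
        for (frag, states), expected in cases.items():
            got = _convert_fragment(frag, states, True, conv, rng)
            assert got == expected

    def test_six_letter_non_cpg_5mc_is_not_copied(self):
        rng = np.random.default_rng(0)
        got = _convert_fragment("CA", "m.", True, ConversionModel(), rng)
        assert got == ("CA", "GT")

    def test_protect_failure_reads_as_unmod(self):
        rng = np.random.default_rng(0)
        conv = ConversionModel(p_protect_fail=1.0)
        assert _convert_fragment("C", "m", False, conv, rng) == ("T", "G")

    def test_deamination_failure_reads_as_modc(self):
        rng = np.random.default_rng(0)
        conv = ConversionModel(p_deam_fail=1.0)
        assert _convert_fragment("C", ".", False, conv, rng) == ("C", "G")

    def test_copy_failure_reads_as_5hmc_pattern(self):
        rng = np.random.default_rng(0)
        conv = ConversionModel(p_copy_fail=1.0)
        assert _convert_fragment("CG", "m.", True, conv, rng) == ("CG", "GT")

    def test_glyc_failure_reads_as_5mc_pattern(self):
        rng = np.random.default_rng(0)
        conv = ConversionModel(p_glyc_fail=1.0)
        assert _convert_fragment("CG", "h.", True, conv, rng) == ("CG", "GC")


class TestSimulateLibrary:
    def test_determinism_identical_seeds(self, controls, control_weights):
        refs, meth = controls
        model = DecodingModel.six_letter()
        conv = ConversionModel(p_protect_fail=0.1, seq_error_rate=0.01,
                               pcr_duplicate_rate=0.1)
        a = simulate_library(refs, meth, conv, model, 50, seed=99,
                             reference_weights=control_weights)
        b = simulate_library(refs, meth, conv, model, 50, seed=99,
                             reference_weights=control_weights)
        assert a[0] == b[0]
        assert a[1].fragments.equals(b[1].fragments)
        assert a[1].reads.equals(b[1].reads)
        c = simulate_library(refs, meth, conv, model, 50, seed=100,
                             reference_weights=control_weights)
        assert c[0] != a[0]

    def test_truth_coordinates_match_reference(self, controls,
                                               control_weights):
        refs, meth = controls
        model = DecodingModel.five_letter()
        pairs, truth = simulate_library(refs, meth, ConversionModel(), model,
                                        40, seed=3,
                                        reference_weights=control_weights)
        from hairpincode.align import reverse_complement
        for row in truth.fragments.itertuples(index=False):
            window = refs[row.chrom][row.start:row.end]
            expected = window if row.strand == "+" else \
                reverse_complement(window)
            assert row.sequence == expected

    def test_duplicates_flagged_and_counted(self, controls, control_weights):
        refs, meth = controls
        model = DecodingModel.five_letter()
        conv = ConversionModel(pcr_duplicate_rate=0.5)
        pairs, truth = simulate_library(refs, meth, conv, model, 200, seed=5,
                                        reference_weights=control_weights)
        n_dup = int(truth.reads.duplicate.sum())
        assert len(pairs) == len(truth.reads) == 200 + n_dup
        # Binomial(200, 0.5): 3 SD band
        assert abs(n_dup - 100) <= 3 * np.sqrt(200 * 0.25)

    def test_hairpin_readthrough_on_short_fragments(self, controls):
        refs, meth = controls
        model = DecodingModel.five_letter()
        pairs, truth = simulate_library({"hmc_oligo": refs["hmc_oligo"]},
                                        meth, ConversionModel(), model, 5,
                                        read_length=60, fragment_length=40,
                                        seed=8)
        from hairpincode import DEFAULT_HAIRPIN, ResolverParams
        from hairpincode.resolver import resolve_read_pair
        params = ResolverParams(hairpin=DEFAULT_HAIRPIN)
        for r1, r2 in pairs:
            assert len(r1.seq) == 60
            rr = resolve_read_pair(r1, r2, model, params)
            assert rr.passed
            assert len(rr.sequence) == 40

    def test_invalid_inputs_raise(self, controls):
        refs, meth = controls
        with pytest.raises(ValueError):
            ConversionModel(p_deam_fail=1.5)
        with pytest.raises(ValueError):
            simulate_library({}, meth, ConversionModel(),
                             DecodingModel.five_letter(), 10, seed=1)


class TestSampleGenome:
    def test_empty_vcf_when_no_snps(self):
        sample = make_sample_genome(length=5000, n_het_snps=0, seed=2)
        assert sample.variants.empty

    def test_haplotypes_differ_exactly_at_snps(self):
        sample = make_sample_genome(length=20000, n_het_snps=8, seed=2)
        h1, h2 = sample.hap_seqs
        diffs = [i for i, (a, b) in enumerate(zip(h1, h2)) if a != b]
        assert diffs == sorted(sample.variants.pos)
        for row in sample.variants.itertuples(index=False):
            assert h1[row.pos] == row.ref
            assert h2[row.pos] == row.alt

    def test_asm_loci_fully_methylated_in_cis_with_ref_allele(self):
        sample = make_sample_genome(length=20000, n_het_snps=8,
                                    asm_fraction=1.0, seed=2, asm_window=60)
        m1, m2 = sample.methylomes
        for row in sample.asm_truth.itertuples(index=False):
            assert row.is_asm == 1
            near1 = m1.df[(m1.df.context == "CpG")
                          & (abs(m1.df.pos - row.pos) <= 60)]
            assert len(near1) > 0
            assert (near1.level == 1.0).all()
            near2 = m2.df[(m2.df.context == "CpG")
                          & (abs(m2.df.pos - row.pos) <= 60)]
            assert (near2.level == 0.0).all()

    def test_beta_mixture_levels_span_unit_interval(self):
        sample = make_sample_genome(length=30000, n_het_snps=0, seed=6)
        levels = sample.methylomes[0].df.query("context == 'CpG'").level
        assert levels.min() >= 0.0 and levels.max() <= 1.0
        assert (levels > 0.8).mean() > 0.3
        assert (levels < 0.2).mean() > 0.05


class TestMethylomeIO:
    def test_tsv_round_trip(self, controls, tmp_path):
        _, meth = controls
        path = tmp_path / "meth.tsv"
        meth.to_tsv(path)
        again = Methylome.from_tsv(path)
        assert again.df.equals(meth.df)
        assert again.state_at("hmc_oligo", 20, "+") == (STATE_5HMC, 1.0)
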