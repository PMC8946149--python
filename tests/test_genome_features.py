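import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ocstrat import genome_features as gf
from ocstrat.reference import ReferenceGenome, revcomp
from ocstrat.variant_io import CopyNumberSegment, SomaticVariant, StructuralVariant


@pytest.fixture(scope="module")
def flat_ref():
    # hand-built contig: positions are 1-based
    #            123456789012345678901234567890
    seq_chrA = "GACGTTTTTACGATCGATCGAAACCCGGGT"
    seq_chrB = "TTACGTACGTACGTACGTAAGCTAGCTAAG"
    return ReferenceGenome({"chrA": seq_chrA, "chrB": seq_chrB})


class TestSbsContext:
    def test_pyrimidine_reference_kept(self, flat_ref):
        # chrA pos 3 = C with flanks A and G
        v = SomaticVariant("chrA", 3, "C", "A")
        assert gf.classify_sbs_context(v, flat_ref) == "A[C>A]G"

    def test_purine_reference_reverse_complemented(self, flat_ref):
        # chrA pos 4 = G (context CGT); G>T == revcomp A[C>A]CG? -> "A[C>A]G"
        v = SomaticVariant("chrA", 4, "G", "T")
        key = gf.classify_sbs_context(v, flat_ref)
        assert key is not None and key[2] in "CT"

    def test_key_space_is_96(self):
        assert len(set(gf.SBS96_KEYS)) == 96

    def test_contig_edge_returns_none(self, flat_ref):
        v = SomaticVariant("chrA", 1, "G", "T")
        assert gf.classify_sbs_context(v, flat_ref) is None

    @given(st.integers(2, 29), st.sampled_from("ACGT"))
    def test_strand_involution(self, pos, alt):
        """A variant and its reverse-complement description share a key."""
        seq = "ACGTTGCAATCGGCTAAGCTTCGATCGGTA"
        ref = ReferenceGenome({"fw": seq, "rc": revcomp(seq)})
        base = seq[pos - 1]
        if alt == base:
            return
        v_fw = SomaticVariant("fw", pos, base, alt)
        v_rc = SomaticVariant("rc", len(seq) - pos + 1, revcomp(base), revcomp(alt))
        assert gf.classify_sbs_context(v_fw, ref) == gf.classify_sbs_context(v_rc, ref)


class TestDbs:
    def test_canonical_kept(self):
        assert gf.classify_dbs(SomaticVariant("chr1", 5, "CT", "AA")) == "CT>AA"

    def test_noncanonical_reverse_complemented(self):
        assert gf.classify_dbs(SomaticVariant("chr1", 5, "AG", "TC")) == "CT>GA"

    def test_key_space_enumeration_is_78(self):
        # brute-force: canonicalize all 16x9 doublet substitutions and count
        # distinct classes
        keys = set()
        for r1 in "ACGT":
            for r2 in "ACGT":
                for a1 in "ACGT":
                    for a2 in "ACGT":
                        if a1 == r1 or a2 == r2:
                            continue
                        keys.add(
                            gf.classify_dbs(
                                SomaticVariant("c", 1, r1 + r2, a1 + a2)
                            )
                        )
        assert keys == set(gf.DBS78_KEYS)
        assert len(keys) == 78


class TestIndelClassification:
    def test_1bp_del_in_homopolymer(self):
        #         1234567890
        ref = ReferenceGenome({"c": "ACTTTTTGCA"})
        # delete one T from the 5-run (anchored VCF at pos 3)
        v = SomaticVariant("c", 3, "TT", "T")
        assert gf.classify_indel(v, ref) == "1:Del:T:5"

    def test_microhomology_deletion(self):
        # deletion of CGA whose 2bp prefix CG recurs right after
        #                 123456789012
        ref = ReferenceGenome({"c": "ATCGACGTTAGC"})
        # delete pos 3-5 "CGA"; following seq "CGT" shares prefix "CG" (len 2)
        v = SomaticVariant("c", 2, "TCGA", "T")
        assert gf.classify_indel(v, ref) == "3:Del:M:2"

    def test_repeat_insertion_of_adjacent_4mer(self):
        ref = ReferenceGenome({"c": "ATCGATTTTTTACG"})
        # insert "CGAT" before pos 3 where ref[3..6] == CGAT
        v = SomaticVariant("c", 2, "T", "TCGAT")
        key = gf.classify_indel(v, ref)
        assert key == "4:Ins:R:1"

    def test_tandem_repeat_deletion(self):
        ref = ReferenceGenome({"c": "AACGCGCGTT"})
        # delete one CG of the (CG)x3 run starting pos 3
        v = SomaticVariant("c", 2, "ACG", "A")
        assert gf.classify_indel(v, ref) == "2:Del:R:3"

    def test_unique_deletion_is_r1(self):
        ref = ReferenceGenome({"c": "ATACGGTCAA"})
        v = SomaticVariant("c", 3, "ACG", "A")  # delete CG, no repeat, no MH?
        key = gf.classify_indel(v, ref)
        assert key.split(":")[1] == "Del"

    def test_key_space_is_83(self):
        assert len(set(gf.ID83_KEYS)) == 83


class TestSvCategories:
    @pytest.mark.parametrize(
        "span,expected",
        [(9_999, "DUP.short"), (10_000, "DUP.long")],
    )
    def test_10kb_boundary(self, span, expected):
        sv = StructuralVariant("chr1", 1000, "chr1", 1000 + span, "DUP")
        assert gf.categorize_sv(sv) == expected

    def test_tra_single_bucket(self):
        sv = StructuralVariant("chr1", 1, "chr2", 99, "TRA")
        assert gf.categorize_sv(sv) == "TRA"


class TestCountConservation:
    def test_sums_match_event_counts(self, toy_reference):
        from ocstrat.synthetic_data import default_archetypes, simulate_sample

        s = simulate_sample(default_archetypes()[4], toy_reference, 99)
        cc = gf.count_contexts(s.variants, s.svs, toy_reference)
        n_snv = sum(1 for v in s.variants if v.vclass == "SNV")
        assert cc.sbs96.sum() == n_snv
        assert cc.sv10.sum() == len(s.svs) == cc.total_sv
        assert cc.total_snv_mnv_indel == len(s.variants)

    def test_spectrum_convergence_total_variation(self, full_reference):
        """Empirical SBS-96 frequencies approach the generating spectrum."""
        from ocstrat.signatures import packaged_catalog
        from ocstrat.synthetic_data import (
            _KmerSampler,
            _mix_to_spectrum,
            _simulate_snvs,
        )

        catalog = packaged_catalog("sbs")
        mix = {"SBS3": 0.5, "SBS1": 0.2, "SBS5": 0.3}
        rng = np.random.default_rng(7)
        sampler = _KmerSampler(full_reference)
        variants = _simulate_snvs(rng, 20_000, mix, catalog, sampler)
        cc = gf.count_contexts(variants, [], full_reference)
        emp = cc.sbs96 / cc.sbs96.sum()
        target = _mix_to_spectrum(mix, catalog)
        tv = 0.5 * np.abs(emp - target).sum()
        assert tv < 0.05


class TestPloidy:
    def _seg(self, chrom, start, end, cn, major=None):
        major = cn / 2 if major is None else major
        return CopyNumberSegment(chrom, start, end, cn, major)

    def test_fraction_thresholding(self):
        segs = [
            self._seg("chr1", 1, 300, 1.0),
            self._seg("chr1", 301, 800, 2.0),
            self._seg("chr1", 801, 1000, 3.0),
        ]
        pp = gf.ploidy_fractions(segs)
        assert (pp.frac_haploid, pp.frac_diploid, pp.frac_polyploid) == pytest.approx(
            (0.3, 0.5, 0.2)
        )

    def test_all_diploid(self):
        pp = gf.ploidy_fractions([self._seg("chr1", 1, 100, 2.0)])
        assert pp.frac_diploid == 1.0

    @pytest.mark.parametrize("cn,bucket", [(1.5, "diploid"), (2.5, "diploid"),
                                           (1.4999, "haploid"), (2.5001, "polyploid")])
    def test_closed_interval_endpoints(self, cn, bucket):
        pp = gf.ploidy_fractions([self._seg("chr1", 1, 100, cn)])
        assert getattr(pp, f"frac_{bucket}") == 1.0

    def test_empty_segments_error(self):
        with pytest.raises(ValueError):
            gf.ploidy_fractions([])

    @given(st.permutations(range(5)))
    def test_permutation_invariance_and_sum(self, order):
        segs = [
            self._seg("chr1", 1 + 100 * i, 100 + 100 * i, cn)
            for i, cn in enumerate([0.8, 1.7, 2.2, 3.5, 2.5])
        ]
        base = gf.ploidy_fractions(segs)
        perm = gf.ploidy_fractions([segs[i] for i in order])
        assert perm == base
        total = base.frac_haploid + base.frac_diploid + base.frac_polyploid
        assert abs(total - 1.0) < 1e-12


class TestWgd:
    def _autosome(self, chrom, major):
        return CopyNumberSegment(chrom, 1, 1000, max(2.0, 2 * major), major)

    def test_11_autosomes_above_is_wgd(self):
        segs = [self._autosome(f"chr{i}", 1.6) for i in range(1, 12)]
        segs += [self._autosome(f"chr{i}", 1.0) for i in range(12, 23)]
        assert gf.call_wgd(segs) is True

    def test_exactly_10_autosomes_is_not_wgd(self):
        segs = [self._autosome(f"chr{i}", 1.6) for i in range(1, 11)]
        segs += [self._autosome(f"chr{i}", 1.0) for i in range(11, 23)]
        assert gf.call_wgd(segs) is False

    def test_all_diploid_not_wgd(self):
        segs = [self._autosome(f"chr{i}", 1.0) for i in range(1, 23)]
        assert gf.call_wgd(segs) is False

    def test_length_weighted_mean_within_autosome(self):
        # one long segment below 1.5 outweighs a short one above
        segs = [
            CopyNumberSegment("chr1", 1, 9000, 2.0, 1.0),
            CopyNumberSegment("chr1", 9001, 10000, 4.0, 3.0),
        ]
        segs += [self._autosome(f"chr{i}", 1.6) for i in range(2, 13)]
        # chr1 mean major = (9000*1.0 + 1000*3.0)/10000 = 1.2 -> 11 above
        assert gf.call_wgd(segs) is True


class TestTmb:
    def test_zero(self):
        assert gf.compute_tmb(0).tmb == 0.0

    def test_denominator_cancels_at_genome_size(self):
        assert gf.compute_tmb(2_858_674_662).tmb == pytest.approx(1e6)

    def test_direct_division(self):
        assert gf.compute_tmb(10_000).tmb == pytest.approx(10_000 / 2858.674662)
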