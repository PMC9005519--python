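import numpy as np
import pytest

from hitikit.quant import (
    IndelSpecies,
    JunctionReport,
    QuantError,
    ThresholdPolicy,
    WindowSpec,
    classify_junctions,
    dual_amplicon_hiti,
    window_indel_frequency,
)
from hitikit.seqcore import NucSeq
from hitikit.simulate import (
    OutcomeMixture,
    make_junction_insertion_allele,
    simulate_alleles,
    simulate_amplicon_reads,
    simulate_junction_reads,
)


def _wt_reads(locus, n, rng, span=(None, None)):
    """Error-free reads tiling the locus and covering the cut window."""
    cut = locus.cut_pos
    lo = span[0] if span[0] is not None else cut - 100
    hi = span[1] if span[1] is not None else cut + 100
    return [NucSeq(f"r{i}", locus.ref.bases[lo:hi]) for i in range(n)]


class TestWindowIndelFrequency:
    def test_unmodified_reads_have_zero_indel_pct(self, locus, rng):
        summ = window_indel_frequency(_wt_reads(locus, 100, rng), locus)
        assert summ.pct_indel == 0.0
        assert summ.pct_unmodified == 100.0

    def test_ten_percent_one_nt_deletions_counted(self, locus, rng):
        cut = locus.cut_pos
        wt = locus.ref.bases[cut - 100:cut + 100]
        mut = (locus.ref.bases[cut - 100:cut]
               + locus.ref.bases[cut + 1:cut + 101])
        reads = [NucSeq(f"u{i}", wt) for i in range(90)]
        reads += [NucSeq(f"d{i}", mut) for i in range(10)]
        summ = window_indel_frequency(reads, locus)
        assert summ.pct_indel == pytest.approx(10.0)
        assert summ.spectrum_counts == {-1: 10}

    def test_deletion_outside_window_counts_unmodified(self, locus):
        cut = locus.cut_pos
        # 3-nt deletion 30 nt 3' of the cut: outside the 17-nt flank
        mut = (locus.ref.bases[cut - 100:cut + 30]
               + locus.ref.bases[cut + 33:cut + 103])
        summ = window_indel_frequency([NucSeq("d", mut)], locus)
        assert summ.pct_indel == 0.0
        assert summ.n_unmodified == 1

    def test_reads_not_covering_window_are_excluded(self, locus):
        cut = locus.cut_pos
        far = NucSeq("far", locus.ref.bases[cut + 30:cut + 130])
        near = NucSeq("near", locus.ref.bases[cut - 60:cut + 60])
        summ = window_indel_frequency([far, near], locus)
        assert summ.n_assigned == 1
        assert summ.n_excluded == 1

    def test_no_informative_reads_raises(self, locus):
        cut = locus.cut_pos
        far = NucSeq("far", locus.ref.bases[cut + 50:cut + 150])
        with pytest.raises(QuantError):
            window_indel_frequency([far], locus)

    def test_enlarging_flank_never_decreases_pct_indel(self, locus):
        cut = locus.cut_pos
        reads = []
        for off in (0, 5, 12, 20, 25):  # deletions at varying distance
            reads.append(NucSeq(
                f"d{off}",
                locus.ref.bases[cut - 120:cut + off]
                + locus.ref.bases[cut + off + 2:cut + 122],
            ))
        reads.append(NucSeq("u", locus.ref.bases[cut - 120:cut + 120]))
        prev = -1.0
        for flank in (5, 10, 17, 26):
            summ = window_indel_frequency(reads, locus, WindowSpec(flank))
            assert summ.pct_indel >= prev
            prev = summ.pct_indel

    def test_class_exhaustiveness(self, locus, rng):
        summ = window_indel_frequency(_wt_reads(locus, 20, rng), locus)
        assert summ.n_assigned == summ.n_unmodified + summ.n_indel + summ.n_hiti


class TestDualAmplicon:
    def test_identical_references_rejected(self, locus, dual_design,
                                           amplicon_locus):
        with pytest.raises(QuantError):
            dual_amplicon_hiti([], dual_design.wt_ref, dual_design.wt_ref,
                               amplicon_locus)

    def test_zero_integration_gives_zero_hiti(self, locus, donor, dual_design,
                                              amplicon_locus):
        alleles = simulate_alleles(
            locus, donor, OutcomeMixture({"unmodified": 1.0}), 50, seed=0)
        reads = simulate_amplicon_reads(
            alleles, dual_design.fwd_primer,
            [dual_design.wt_rev_primer, dual_design.hybrid_rev_primer],
            n_reads=400, seed=1)
        summ = dual_amplicon_hiti(reads, dual_design.wt_ref,
                                  dual_design.hybrid_ref, amplicon_locus)
        assert summ.pct_hiti == 0.0
        assert summ.pct_unmodified == 100.0

    def test_five_percent_mixture_recovered(self, locus, donor, dual_design,
                                            amplicon_locus):
        mix = OutcomeMixture({"unmodified": 0.95, "precise_hiti": 0.05})
        alleles = simulate_alleles(locus, donor, mix, 2000, seed=2)
        reads = simulate_amplicon_reads(
            alleles, dual_design.fwd_primer,
            [dual_design.wt_rev_primer, dual_design.hybrid_rev_primer],
            n_reads=4000, seed=3)
        truth = sum(r.outcome == "precise_hiti" for r in reads) / len(reads)
        summ = dual_amplicon_hiti(reads, dual_design.wt_ref,
                                  dual_design.hybrid_ref, amplicon_locus)
        assert summ.pct_hiti == pytest.approx(100 * truth, abs=1e-6)

    def test_ambiguous_read_excluded(self, dual_design, amplicon_locus):
        # a read wholly inside the shared forward-primer-side region scores
        # equally on both references
        shared = dual_design.wt_ref.bases[:60]
        assert dual_design.hybrid_ref.bases[:60] == shared
        summ = dual_amplicon_hiti(
            [NucSeq("amb", shared), NucSeq("wt", dual_design.wt_ref.bases)],
            dual_design.wt_ref, dual_design.hybrid_ref, amplicon_locus)
        assert summ.n_ambiguous == 1
        assert summ.n_assigned == 1

    def test_class_exhaustiveness_with_mixture(self, locus, donor,
                                               dual_design, amplicon_locus):
        mix = OutcomeMixture({"unmodified": 0.8, "nhej_indel": 0.1,
                              "precise_hiti": 0.1})
        alleles = simulate_alleles(locus, donor, mix, 500, seed=4)
        reads = simulate_amplicon_reads(
            alleles, dual_design.fwd_primer,
            [dual_design.wt_rev_primer, dual_design.hybrid_rev_primer],
            n_reads=1000, seed=5)
        summ = dual_amplicon_hiti(reads, dual_design.wt_ref,
                                  dual_design.hybrid_ref, amplicon_locus)
        assert summ.n_assigned == (summ.n_unmodified + summ.n_indel
                                   + summ.n_hiti)
        total_pct = summ.pct_unmodified + summ.pct_indel + summ.pct_hiti
        assert total_pct == pytest.approx(100.0, abs=0.01)


@pytest.fixture(scope="module")
def junction_system(system):
    from hitikit.donor import predict_integration
    from hitikit.seqcore import NucSeq, revcomp

    locus, donor = system
    hy = predict_integration(locus, donor, "forward").edited_allele
    cut = locus.cut_pos
    fwd = locus.ref.slice(cut - 150, cut - 130, id="jx_fwd")
    rev = NucSeq("jx_rev", revcomp(hy.bases[cut + 180:cut + 200]))
    jref = hy.slice(cut - 150, cut + 200, id="jx_ref")
    return locus, donor, fwd, rev, jref


class TestClassifyJunctions:
    def test_all_precise_reports_no_species(self, junction_system):
        locus, donor, fwd, rev, jref = junction_system
        alleles = simulate_alleles(
            locus, donor, OutcomeMixture({"precise_hiti": 1.0}), 10, seed=0)
        reads = simulate_junction_reads(alleles, fwd, rev, 200, seed=1)
        rep = classify_junctions(reads, jref, 150)
        assert rep.pct_precise == 100.0
        assert rep.species == []

    def test_forty_nt_insertion_species_recovered_at_5pct(self,
                                                          junction_system):
        locus, donor, fwd, rev, jref = junction_system
        ins = make_junction_insertion_allele(locus, donor, 40, "five", seed=3)
        precise = simulate_alleles(
            locus, donor, OutcomeMixture({"precise_hiti": 1.0}), 1, seed=4)[0]
        pool = [precise] * 19 + [ins]
        reads = simulate_junction_reads(pool, fwd, rev, 1000, seed=7)
        rep = classify_junctions(reads, jref, 150,
                                 policy=ThresholdPolicy.for_tissue("retina"))
        sp = rep.species_by_length(40, "I")
        assert sp is not None
        n = rep.n_spanning
        sd = 100 * (0.05 * 0.95 / n) ** 0.5
        assert abs(sp.pct - 5.0) <= 3 * sd

    def test_threshold_boundary_is_inclusive(self):
        policy = ThresholdPolicy.for_tissue("retina")
        below = IndelSpecies("I", 7, 9, 0.09)
        at = IndelSpecies("I", 40, 10, 0.10)
        rep = JunctionReport(10_000, 9981, 0, [below, at], policy)
        filtered = rep.apply_policy(policy)
        assert filtered.species == [at]

    def test_threshold_filter_is_idempotent(self):
        policy = ThresholdPolicy(0.5)
        species = [IndelSpecies("I", 40, 5, 0.5),
                   IndelSpecies("D", 3, 4, 0.4),
                   IndelSpecies("I", 48, 60, 6.0)]
        rep = JunctionReport(1000, 931, 0, species, policy)
        once = rep.apply_policy(policy)
        twice = once.apply_policy(policy)
        assert once.species == twice.species

    def test_tissue_presets(self):
        assert ThresholdPolicy.for_tissue("retina").min_species_frequency == 0.1
        assert ThresholdPolicy.for_tissue("liver").min_species_frequency == 0.5
        with pytest.raises(ValueError):
            ThresholdPolicy.for_tissue("kidney")
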