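import numpy as np
import pytest

from hitikit.donor import predict_integration
from hitikit.simulate import (
    Integration,
    OutcomeMixture,
    SimulationError,
    apply_integrations,
    make_example_system,
    make_mock_aav,
    make_mock_genome,
    replay_allele,
    simulate_alleles,
    simulate_amplicon_reads,
    simulate_capture_reads,
    simulate_junction_reads,
    design_dual_amplicon,
)


class TestOutcomeMixture:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(SimulationError):
            OutcomeMixture({"unmodified": 0.5, "precise_hiti": 0.4})

    def test_unknown_label_rejected(self):
        with pytest.raises(SimulationError):
            OutcomeMixture({"weird": 1.0})


class TestSimulateAlleles:
    def test_pure_unmodified_returns_reference(self, locus, donor):
        alleles = simulate_alleles(
            locus, donor, OutcomeMixture({"unmodified": 1.0}), 100, seed=0)
        assert all(a.seq.bases == locus.ref.bases for a in alleles)

    def test_pure_precise_matches_integration_prediction(self, locus, donor):
        pred = predict_integration(locus, donor, "forward")
        alleles = simulate_alleles(
            locus, donor, OutcomeMixture({"precise_hiti": 1.0}), 20, seed=0)
        for a in alleles:
            assert a.seq.bases == pred.edited_allele.bases
            assert a.seq.bases.count(donor.payload.bases) == 1

    def test_same_seed_reproduces_byte_identical_alleles(self, locus, donor):
        mix = OutcomeMixture({
            "unmodified": 0.4, "nhej_indel": 0.3, "precise_hiti": 0.1,
            "imprecise_hiti": 0.1, "inverted_hiti": 0.05,
            "vector_fragment": 0.05,
        })
        aav = make_mock_aav(donor, np.random.default_rng(1))
        a1 = simulate_alleles(locus, donor, mix, 200, seed=42, aav=aav)
        a2 = simulate_alleles(locus, donor, mix, 200, seed=42, aav=aav)
        assert [(a.seq.bases, a.outcome) for a in a1] == \
               [(a.seq.bases, a.outcome) for a in a2]

    def test_truth_events_replay_to_identical_sequence(self, locus, donor):
        mix = OutcomeMixture({
            "unmodified": 0.2, "nhej_indel": 0.3, "precise_hiti": 0.1,
            "imprecise_hiti": 0.2, "inverted_hiti": 0.1,
            "vector_fragment": 0.1,
        })
        aav = make_mock_aav(donor, np.random.default_rng(1))
        for a in simulate_alleles(locus, donor, mix, 300, seed=7, aav=aav):
            assert replay_allele(locus, donor, a, aav).bases == a.seq.bases

    def test_outcome_fractions_within_three_binomial_sd(self, locus, donor):
        mix = OutcomeMixture({
            "unmodified": 0.6, "nhej_indel": 0.25, "precise_hiti": 0.15,
        })
        n = 10_000
        alleles = simulate_alleles(locus, donor, mix, n, seed=3)
        for label, f in mix.fractions.items():
            count = sum(a.outcome == label for a in alleles)
            sd = (n * f * (1 - f)) ** 0.5
            assert abs(count - n * f) <= 3 * sd

    def test_vector_fragment_requires_mock_aav(self, locus, donor):
        with pytest.raises(SimulationError):
            simulate_alleles(locus, donor,
                             OutcomeMixture({"vector_fragment": 1.0}),
                             5, seed=0)


class TestAmpliconReads:
    def test_error_free_reads_are_exact_substrings(self, locus, donor,
                                                   dual_design):
        alleles = simulate_alleles(
            locus, donor, OutcomeMixture({"unmodified": 1.0}), 50, seed=0)
        reads = simulate_amplicon_reads(
            alleles, dual_design.fwd_primer,
            [dual_design.wt_rev_primer, dual_design.hybrid_rev_primer],
            n_reads=200, seed=1)
        assert len(reads) == 200
        from hitikit.seqcore import revcomp

        for r in reads:
            s = r.seq if r.mate == 1 else revcomp(r.seq)
            assert s in dual_design.wt_ref.bases

    def test_hybrid_read_share_tracks_allele_fraction(self, locus, donor,
                                                      dual_design):
        mix = OutcomeMixture({"unmodified": 0.95, "precise_hiti": 0.05})
        alleles = simulate_alleles(locus, donor, mix, 4000, seed=5)
        true_f = sum(a.outcome == "precise_hiti" for a in alleles) / 4000
        reads = simulate_amplicon_reads(
            alleles, dual_design.fwd_primer,
            [dual_design.wt_rev_primer, dual_design.hybrid_rev_primer],
            n_reads=10_000, seed=6)
        hybrid = sum(r.outcome == "precise_hiti" for r in reads) / len(reads)
        sd = (true_f * (1 - true_f) / 5000) ** 0.5
        assert abs(hybrid - true_f) <= 3 * sd

    def test_fastq_output_is_byte_deterministic(self, tmp_path, locus, donor,
                                                dual_design):
        alleles = simulate_alleles(
            locus, donor, OutcomeMixture({"unmodified": 1.0}), 20, seed=0)
        outs = []
        for name in ("a.fastq", "b.fastq"):
            reads = simulate_amplicon_reads(
                alleles, dual_design.fwd_primer,
                [dual_design.wt_rev_primer], n_reads=100, seed=9,
                sub_error_rate=0.01)
            p = tmp_path / name
            reads.to_fastq(p)
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]

    def test_absent_primers_raise(self, locus, donor, rng):
        alleles = simulate_alleles(
            locus, donor, OutcomeMixture({"unmodified": 1.0}), 5, seed=0)
        with pytest.raises(SimulationError):
            simulate_amplicon_reads(alleles, "ACGT" * 5, ["TTTT" * 5],
                                    n_reads=10, seed=0)


class TestJunctionReads:
    @pytest.fixture()
    def junction_setup(self, locus, donor):
        from hitikit.seqcore import NucSeq, revcomp

        hy = predict_integration(locus, donor, "forward").edited_allele
        cut = locus.cut_pos
        fwd = locus.ref.slice(cut - 150, cut - 130, id="jx_fwd")
        rev = NucSeq("jx_rev", revcomp(hy.bases[cut + 180:cut + 200]))
        return fwd, rev

    def test_reads_trimmed_to_350(self, locus, donor, junction_setup):
        fwd, rev = junction_setup
        alleles = simulate_alleles(
            locus, donor, OutcomeMixture({"precise_hiti": 1.0}), 10, seed=0)
        reads = simulate_junction_reads(alleles, fwd, rev, 100, seed=2)
        assert all(len(r.seq) <= 350 for r in reads)

    def test_precise_alleles_give_exact_reference_reads(self, locus, donor,
                                                        junction_setup):
        fwd, rev = junction_setup
        hy = predict_integration(locus, donor, "forward").edited_allele
        alleles = simulate_alleles(
            locus, donor, OutcomeMixture({"precise_hiti": 1.0}), 10, seed=0)
        reads = simulate_junction_reads(alleles, fwd, rev, 50, seed=2)
        assert all(r.seq in hy.bases for r in reads)

    def test_junction_insertion_allele_reads_carry_insertion(
            self, locus, donor, junction_setup):
        from hitikit.simulate import make_junction_insertion_allele

        fwd, rev = junction_setup
        allele = make_junction_insertion_allele(locus, donor, 40, "five",
                                                seed=3)
        reads = simulate_junction_reads([allele], fwd, rev, 10, seed=2)
        ins = allele.events[0]["seq"]
        assert all(ins in r.seq for r in reads)


class TestCaptureReads:
    def test_all_reads_from_rois_at_extreme_enrichment(self, locus, rng):
        genome = make_mock_genome(locus, rng)
        rois = {"chr1": [(genome.locus_start, genome.locus_end)]}
        reads = simulate_capture_reads(genome.chroms, rois, n_reads=300,
                                       enrichment_factor=1e9, seed=4)
        lo, hi = genome.locus_start, genome.locus_end
        for r in reads:
            chrom, start = r.source_allele.split(":")
            assert chrom == "chr1"
            assert int(start) + 150 > lo and int(start) < hi

    def test_no_integration_means_no_chimeric_truth(self, locus, rng):
        genome = make_mock_genome(locus, rng)
        edited, spans = apply_integrations(genome, [])
        reads = simulate_capture_reads(
            edited, {"chr1": [(genome.locus_start, genome.locus_end)]},
            n_reads=300, seed=4, insert_spans=spans)
        assert sum(r.outcome == "chimeric" for r in reads) == 0

    def test_ontarget_integration_yields_chimeric_reads_at_cut(
            self, locus, donor, rng):
        genome = make_mock_genome(locus, rng)
        cut_abs = genome.locus_start + locus.cut_pos
        edited, spans = apply_integrations(
            genome, [Integration("chr1", cut_abs, donor.core.bases)])
        reads = simulate_capture_reads(
            edited,
            {"chr1": [(cut_abs - 200, cut_abs + len(donor.core) + 200)]},
            n_reads=500, seed=4, insert_spans=spans)
        chimeric = [r for r in reads if r.outcome == "chimeric"]
        assert chimeric
        a, b = spans["chr1"][0]
        for r in chimeric:
            start = int(r.source_allele.split(":")[1])
            assert start < a < start + 150 or start < b < start + 150

    def test_empty_genome_rejected(self):
        with pytest.raises(SimulationError):
            simulate_capture_reads({}, {}, n_reads=10, seed=0)
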