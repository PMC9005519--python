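#!/usr/bin/env python
"""Dual-amplicon HITI quantification on a simulated retina-like read set.

Simulates a 5% precise-HITI / 10% NHEJ-indel allele population (the
retina-like regime), sequences it to 20,000 error-free paired reads with a
shared forward primer over both amplicons, and recovers the class
percentages and the cut-window indel length spectrum.
"""

from pathlib import Path

from hitikit.quant import dual_amplicon_hiti
from hitikit.reports import rows_to_tsv
from hitikit.seqcore import place_guide
from hitikit.simulate import (
    OutcomeMixture,
    design_dual_amplicon,
    make_example_system,
    simulate_alleles,
    simulate_amplicon_reads,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "amplicon_hiti"
SEED = 42
MIXTURE = {"unmodified": 0.85, "nhej_indel": 0.10, "precise_hiti": 0.05}
N_ALLELES, N_READS = 5000, 20_000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    locus, donor = make_example_system(seed=11)
    design = design_dual_amplicon(locus, donor)
    mixture = OutcomeMixture(MIXTURE)
    alleles = simulate_alleles(locus, donor, mixture, N_ALLELES, seed=SEED)
    reads = simulate_amplicon_reads(
        alleles, design.fwd_primer,
        [design.wt_rev_primer, design.hybrid_rev_primer],
        n_reads=N_READS, seed=SEED + 1)
    amp_locus = place_guide(design.wt_ref, locus.guide)
    summary = dual_amplicon_hiti(reads, design.wt_ref, design.hybrid_ref,
                                 amp_locus)
    truth_hiti = 100 * sum(r.outcome == "precise_hiti" for r in reads) / len(reads)
    print(f"{len(reads)} reads, {summary.n_assigned} assigned, "
          f"{summary.n_ambiguous} ambiguous, {summary.n_excluded} excluded")
    print(f"pct_hiti      = {summary.pct_hiti:6.3f}  (read-truth {truth_hiti:.3f})")
    print(f"pct_indel     = {summary.pct_indel:6.3f}")
    print(f"pct_unmodified= {summary.pct_unmodified:6.3f}")
    print("indel spectrum (signed length: %):")
    for length, pct in summary.spectrum.items():
        print(f"  {length:+4d}: {pct:.3f}")
    print("-> the estimator tracks the simulated allele mixture; "
          "NHEJ indels concentrate at small negative (deletion) lengths")

    summary.to_json(OUT / "edit_summary.json")
    rows = ([{"class": "unmodified", "count": summary.n_unmodified,
              "pct": round(summary.pct_unmodified, 4)},
             {"class": "indel", "count": summary.n_indel,
              "pct": round(summary.pct_indel, 4)},
             {"class": "hiti", "count": summary.n_hiti,
              "pct": round(summary.pct_hiti, 4)}]
            + [{"class": f"indel_len_{k:+d}", "count": v,
                "pct": round(summary.spectrum[k], 4)}
               for k, v in sorted(summary.spectrum_counts.items())])
    rows_to_tsv(rows, OUT / "edit_summary.tsv")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
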