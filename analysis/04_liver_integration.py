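#!/usr/bin/env python
"""Split-read integration-site detection on capture-style liver-like reads.

Builds a mock host genome with an on-target integration (chr1 cut site) and
a decoy integration (chr2), adds episomal vector molecules, simulates
enriched capture reads, and runs the split-read procedure: strict alignment
to the donor insert, 22/30-nt partition thresholds, flank realignment to
vector + host references, per-chromosome tallies and the insert-anchored
on-target count.  Also prints the persistence arithmetic comparing HITI to
conventional episomal gene replacement.
"""

from pathlib import Path

import numpy as np

from hitikit.integration import (
    find_insert_reads,
    ontarget_insert_frequency,
    realign_flanks,
    write_partition_fastas,
)
from hitikit.reports import percent_reduction, rows_to_tsv, write_json
from hitikit.simulate import (
    Integration,
    apply_integrations,
    make_example_system,
    make_mock_aav,
    make_mock_genome,
    simulate_capture_reads,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "liver_integration"
SEED = 5
N_READS = 1200


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    locus, donor = make_example_system(seed=11)
    rng = np.random.default_rng(SEED)
    genome = make_mock_genome(locus, rng, n_chroms=4)
    aav = make_mock_aav(donor, rng)
    core = donor.core
    cut_abs = genome.locus_start + locus.cut_pos
    edited, spans = apply_integrations(genome, [
        Integration("chr1", cut_abs, core.bases),
        Integration("chr2", 2500, core.bases),
    ])
    rois = {"chr1": [(cut_abs - 300, cut_abs + len(core) + 300)],
            "chr2": [(2200, 2500 + len(core) + 300)]}
    reads = simulate_capture_reads(edited, rois, n_reads=N_READS,
                                   episomal_vector=aav, episomal_copies=2,
                                   enrichment_factor=50, seed=SEED + 1,
                                   insert_spans=spans)

    result = find_insert_reads(reads, core)
    print(f"{result.n_reads} reads: {len(result.partitions)} chimeric "
          f"partitions, {len(result.insert_only)} insert-only, "
          f"{len(result.discarded_partial)} discarded (22/30-nt thresholds), "
          f"{len(result.non_insert)} non-insert")
    refs = dict(edited)
    refs["mock_aav"] = aav
    tally = realign_flanks(result.partitions, refs)
    print("flank realignment tally (chimeric evidence per reference):")
    for row in tally.to_rows():
        print(f"  {row['reference']:>10}: {row['count']:5d} ({row['pct']:.2f}%)")
    print("-> integration chromosomes (chr1 on-target, chr2 decoy) collect "
          "flanks; vector-assigned flanks reflect episomes/concatemers, "
          "not host integration")

    res = ontarget_insert_frequency(
        reads, core, locus.ref, (locus.cut_pos - 10, locus.cut_pos + 10))
    print(f"on-target: {res.anchored_count} insert-anchored reads / "
          f"{res.total_covering} reads over the cleavage region "
          f"({100 * res.frequency:.1f}%)")

    reduction = percent_reduction(18.2, 2.5)
    print(f"episomal gene-replacement comparator: 18.2% -> 2.5% DsRed+ "
          f"hepatocytes = {reduction:.0f}% reduction during liver growth "
          f"(integrated HITI alleles persist)")

    write_partition_fastas(result, OUT / "insert_portions.fasta",
                           OUT / "flank_portions.fasta")
    rows_to_tsv(tally.to_rows(), OUT / "integration_tally.tsv")
    write_json({"anchored_count": res.anchored_count,
                "total_covering": res.total_covering,
                "frequency": round(res.frequency, 6),
                "hepatocyte_pct_reduction": round(reduction, 1)},
               OUT / "ontarget.json")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
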