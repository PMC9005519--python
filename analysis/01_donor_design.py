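#!/usr/bin/env python
"""Design and validate the demo HITI donor; predict integration outcomes.

Builds the reproducible demo locus (random reference, single SpCas9 site)
and its kozak donor, checks the cassette anatomy, and verifies the core
asymmetry of the design: forward integration destroys both half-sites while
inverted integration regenerates two cleavable sites.
"""

from pathlib import Path

from hitikit.donor import export_donor_fasta, predict_integration, validate_donor
from hitikit.reports import rows_to_tsv, write_json
from hitikit.seqcore import write_bed, write_fasta
from hitikit.simulate import make_example_system

OUT = Path(__file__).resolve().parents[1] / "results" / "donor_design"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    locus, donor = make_example_system(seed=11)
    print(f"locus: {len(locus.ref)} nt, guide on {locus.strand} strand, "
          f"cut at {locus.cut_pos}")
    print(f"donor cassette: {len(donor)} nt "
          f"({', '.join(n for n, _ in donor.parts)})")

    report = validate_donor(donor, locus)
    print("donor validation:", "PASS" if report.passed else "FAIL")
    for name, (ok, detail) in report.checks.items():
        print(f"  {name}: {'ok' if ok else 'FAIL ' + detail}")

    rows = []
    for orientation in ("forward", "inverted"):
        pred = predict_integration(locus, donor, orientation)
        rows.append({
            "orientation": orientation,
            "edited_allele_len": len(pred.edited_allele),
            "recleavable_sites": pred.recleavable_sites,
        })
        print(f"{orientation} integration: allele {len(pred.edited_allele)} "
              f"nt, {pred.recleavable_sites} re-cleavable site(s)")
    print("-> forward integration is locked in; inverted integration is "
          "re-cut, biasing steady-state outcomes toward the forward product")

    export_donor_fasta(donor, OUT / "donor.fasta", OUT / "donor_parts.tsv")
    write_fasta([locus.ref], OUT / "locus.fasta")
    write_bed([locus], OUT / "guide_placement.bed")
    rows_to_tsv(rows, OUT / "integration_predictions.tsv")
    write_json({k: {"passed": ok, "detail": d}
                for k, (ok, d) in report.checks.items()},
               OUT / "validation.json")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
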