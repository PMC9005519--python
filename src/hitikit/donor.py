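"""HITI donor cassette construction, validation and integration prediction.

A HITI donor is a promoterless cassette flanked by *inverted* copies of the
genomic SpCas9 target site:

    inverted site | STOPx3 frames | START | payload CDS | polyA | inverted site

Cas9 cuts the genomic site and both donor flanks; NHEJ ligates the released
donor core into the genomic gap.  Because the flanks are inverted, forward
integration reconstitutes no cleavable site (integration is locked in),
while inverted integration regenerates a full site at both junctions and is
re-cleaved.  The STOP cassette knocks out the endogenous reading frame in
all three frames regardless of junction precision; the START element
(kozak or a short synthetic IRES) initiates translation of the payload.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqcore import (
    GuideSpec,
    NucSeq,
    TargetLocus,
    count_stop_codons,
    cut_in_inverted_site,
    cut_in_site,
    revcomp,
    scan_sites,
    stops_in_three_frames,
)

#: Six STOP codons (TAA at offsets 0,4,8,12,16,20) covering all three frames.
DEFAULT_STOP_CASSETTE = NucSeq("stop_cassette", "TAAATAAATAAATAAATAAATAAA")

#: Consensus kozak element placed immediately before the payload ATG.
KOZAK = NucSeq("kozak", "GCCACC")

#: 50-nt synthetic stand-in for the short IRES translation-start element
#: (a fixed arbitrary sequence; the biological IRES identity is irrelevant
#: to the integration arithmetic modelled here).
SYNTHETIC_IRES_50 = NucSeq(
    "ires50",
    "GTTATTTTCCACCATATTGCCGTCTTTTGGCAATGTGAGGGCCCGGAAAC",
)

#: Minimal synthetic polyadenylation element carrying the AATAAA signal.
DEFAULT_POLYA = NucSeq(
    "polyA",
    "AATAAAAGATCTTTATTTTCATTAGATCTGTGTGTTGGTTTTTTGTGTG",
)

#: Default AAV single-vector donor size cap (nt).
DEFAULT_DONOR_CAP = 2700

START_ELEMENTS = {"kozak": KOZAK, "ires": SYNTHETIC_IRES_50}


class DonorDesignError(ValueError):
    """Donor cannot be assembled as requested."""


@dataclass(frozen=True)
class HitiDonor:
    """An assembled HITI donor cassette with orientation metadata."""

    five_site: NucSeq       # inverted target site, 5' flank
    stop_cassette: NucSeq
    start_type: str         # "kozak" | "ires"
    start_element: NucSeq
    payload: NucSeq         # CDS, begins ATG
    polya: NucSeq
    three_site: NucSeq      # inverted target site, 3' flank
    guide: GuideSpec

    @property
    def parts(self) -> list[tuple[str, NucSeq]]:
        return [
            ("five_site", self.five_site),
            ("stop_cassette", self.stop_cassette),
            (f"start_{self.start_type}", self.start_element),
            ("payload", self.payload),
            ("polya", self.polya),
            ("three_site", self.three_site),
        ]

    @property
    def cassette(self) -> NucSeq:
        return NucSeq("donor", "".join(s.bases for _, s in self.parts))

    def __len__(self) -> int:
        return sum(len(s) for _, s in self.parts)

    def _flank_cut(self, flank: NucSeq) -> int:
        """Blunt-cut coordinate within a flank, respecting its orientation
        (a direct-orientation flank is cut at the site's own cut position,
        an inverted flank at the mirrored one)."""
        hits = scan_sites(flank, self.guide)
        if hits and hits[0][1] == "+":
            return hits[0][0] + cut_in_site(self.guide)
        return cut_in_inverted_site(self.guide)

    @property
    def core(self) -> NucSeq:
        """The donor segment released by Cas9 cutting both flanks.

        Each flank is cut at its internal blunt-cut position; the 5' flank
        keeps its 3' remainder and the 3' flank keeps its 5' stub.
        """
        k5 = self._flank_cut(self.five_site)
        k3 = self._flank_cut(self.three_site)
        mid = "".join(
            s.bases for name, s in self.parts[1:-1]
        )
        return NucSeq(
            "donor_core",
            self.five_site.bases[k5:] + mid + self.three_site.bases[:k3],
        )

    def part_table(self) -> list[tuple[str, int, int]]:
        """(part, start, end) rows over the cassette, 0-based half-open."""
        rows, pos = [], 0
        for name, s in self.parts:
            rows.append((name, pos, pos + len(s)))
            pos += len(s)
        return rows


def build_donor(
    locus: TargetLocus,
    payload: NucSeq,
    start_type: str = "kozak",
    polya: NucSeq = DEFAULT_POLYA,
    stop_cassette: NucSeq = DEFAULT_STOP_CASSETTE,
    start_seq: NucSeq | None = None,
    max_len: int = DEFAULT_DONOR_CAP,
) -> HitiDonor:
    """Assemble a donor for the locus' guide in the canonical part order."""
    if start_type not in START_ELEMENTS:
        raise DonorDesignError(f"unknown start_type {start_type!r}")
    if not payload.bases.startswith("ATG"):
        raise DonorDesignError("payload CDS must begin with ATG")
    if stops_in_three_frames(stop_cassette) != (True, True, True):
        raise DonorDesignError("stop cassette must cover all three frames")
    site = locus.target_site
    inverted = NucSeq("inverted_site", revcomp(site).bases)
    donor = HitiDonor(
        five_site=NucSeq("five_site", inverted.bases),
        stop_cassette=stop_cassette,
        start_type=start_type,
        start_element=start_seq or START_ELEMENTS[start_type],
        payload=payload,
        polya=polya,
        three_site=NucSeq("three_site", inverted.bases),
        guide=locus.guide,
    )
    if len(donor) > max_len:
        raise DonorDesignError(
            f"cassette {len(donor)} nt exceeds the {max_len} nt donor cap"
        )
    return donor


@dataclass
class DonorValidation:
    """Per-check pass/fail report; failures carry an explanation."""

    checks: dict[str, tuple[bool, str]] = field(default_factory=dict)

    def add(self, name: str, ok: bool, detail: str = "") -> None:
        self.checks[name] = (ok, detail)

    @property
    def passed(self) -> bool:
        return all(ok for ok, _ in self.checks.values())

    def failures(self) -> list[str]:
        return [f"{k}: {d}" for k, (ok, d) in self.checks.items() if not ok]


def validate_donor(
    donor: HitiDonor,
    locus: TargetLocus,
    max_len: int = DEFAULT_DONOR_CAP,
    min_stops: int = 6,
) -> DonorValidation:
    """Check flank presence/orientation, STOP coverage, ATG and size."""
    rep = DonorValidation()
    site = locus.target_site
    inv = revcomp(site).bases
    for name, flank in (("five_site", donor.five_site),
                        ("three_site", donor.three_site)):
        present = len(flank) == len(site)
        rep.add(f"{name}_present", present,
                "" if present else f"{name} missing or wrong length")
        if flank.bases == inv:
            rep.add(f"{name}_inverted", True)
        elif flank.bases == site.bases:
            rep.add(
                f"{name}_inverted", False,
                "direct-orientation flank: forward integration would "
                "regenerate an intact target site (re-cleavage risk)",
            )
        else:
            rep.add(f"{name}_inverted", False,
                    f"{name} is not the inverted target site")
    frames = stops_in_three_frames(donor.stop_cassette)
    rep.add("stops_three_frames", frames == (True, True, True),
            f"frames covered: {frames}")
    n_stops = count_stop_codons(donor.stop_cassette)
    rep.add("stops_count", n_stops >= min_stops,
            f"{n_stops} STOP codons (need >= {min_stops})")
    rep.add("payload_atg", donor.payload.bases.startswith("ATG"),
            "payload must begin ATG")
    rep.add("size_cap", len(donor) <= max_len,
            f"{len(donor)} nt vs cap {max_len} nt")
    return rep


@dataclass(frozen=True)
class IntegrationPrediction:
    """Predicted edited allele for one integration orientation."""

    orientation: str          # "forward" | "inverted"
    edited_allele: NucSeq
    five_junction: NucSeq     # sequence centred on the 5' ligation point
    three_junction: NucSeq
    recleavable_sites: int
    insert_start: int         # insert span in edited_allele coordinates
    insert_end: int


def predict_integration(
    locus: TargetLocus,
    donor: HitiDonor,
    orientation: str = "forward",
    junction_flank: int = 30,
) -> IntegrationPrediction:
    """Model blunt Cas9 cuts at the locus and both donor flanks, then
    precise NHEJ ligation of the released donor core into the genomic gap.

    Forward integration yields junctions that each carry only half of a
    target site, so no intact protospacer+PAM remains; inverted integration
    reconstitutes a full site at both junctions (re-cleavable).
    """
    if orientation not in ("forward", "inverted"):
        raise ValueError(f"orientation must be forward/inverted, got {orientation!r}")
    core = donor.core.bases
    insert = core if orientation == "forward" else revcomp(core)
    cut = locus.cut_pos
    edited = NucSeq(
        f"{locus.ref.id}:{orientation}_hiti",
        locus.ref.bases[:cut] + insert + locus.ref.bases[cut:],
    )
    j5, j3 = cut, cut + len(insert)
    five = edited.slice(max(0, j5 - junction_flank), j5 + junction_flank,
                        id="five_junction")
    three = edited.slice(max(0, j3 - junction_flank), j3 + junction_flank,
                         id="three_junction")
    n_sites = len(scan_sites(edited, locus.guide))
    return IntegrationPrediction(
        orientation=orientation,
        edited_allele=edited,
        five_junction=five,
        three_junction=three,
        recleavable_sites=n_sites,
        insert_start=j5,
        insert_end=j3,
    )


def is_recleavable(seq: NucSeq | str, guide: GuideSpec) -> bool:
    """True iff an exact protospacer immediately followed by a PAM-pattern
    match occurs on either strand (exact-site semantics, no mismatches)."""
    return bool(scan_sites(seq, guide))


def export_donor_fasta(donor: HitiDonor, fasta_path, tsv_path=None) -> None:
    """Annotated FASTA (part boundaries in the description) + part TSV."""
    table = donor.part_table()
    desc = " ".join(f"{n}:{a}-{b}" for n, a, b in table)
    with open(fasta_path, "w") as fh:
        fh.write(f">donor {desc}\n")
        b = donor.cassette.bases
        for i in range(0, len(b), 80):
            fh.write(b[i:i + 80] + "\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("part\tstart\tend\n")
            for n, a, b2 in table:
                fh.write(f"{n}\t{a}\t{b2}\n")
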