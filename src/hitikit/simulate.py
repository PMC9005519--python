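"""Synthetic-data generator for HITI editing experiments.

Produces edited-allele populations and seeded FASTQ read sets with
ground-truth labels, emulating three sequencing designs:

* dual-amplicon reads -- paired-end 150-nt reads co-amplified from the
  wild-type and donor-integrated alleles with a shared forward primer;
* junction-amplicon reads -- single-end reads generated long (600 nt) and
  trimmed to 350 nt, spanning one HITI junction;
* capture-style reads -- 150-nt reads drawn from a mock host genome with
  integrated alleles plus episomal vector copies, enriched over regions of
  interest, yielding host/donor/vector chimeric junction reads.

The error model is substitution-only by default so that every called
insertion or deletion is attributable to a simulated editing event.
All randomness flows from a caller-supplied seed; identical configuration
yields byte-identical FASTQ output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .donor import HitiDonor, predict_integration
from .seqcore import NucSeq, TargetLocus, revcomp

OUTCOMES = (
    "unmodified",
    "nhej_indel",
    "precise_hiti",
    "imprecise_hiti",
    "inverted_hiti",
    "vector_fragment",
)

ITR_LEN = 145
_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


def random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


@dataclass(frozen=True)
class OutcomeMixture:
    """Editing-outcome fractions plus the NHEJ indel length model.

    Indel lengths follow a truncated geometric distribution over 1..50 with
    success probability ``indel_geom_p``; deletions outnumber insertions
    ``deletion_fraction : (1 - deletion_fraction)`` (default 3:1).
    """

    fractions: dict[str, float]
    indel_geom_p: float = 0.25
    deletion_fraction: float = 0.75
    max_indel: int = 50

    def __post_init__(self) -> None:
        bad = set(self.fractions) - set(OUTCOMES)
        if bad:
            raise SimulationError(f"unknown outcome labels {sorted(bad)}")
        vals = list(self.fractions.values())
        if any(v < 0 for v in vals):
            raise SimulationError("fractions must be >= 0")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise SimulationError(f"fractions sum to {sum(vals)}, not 1")

    def full(self) -> np.ndarray:
        return np.array([self.fractions.get(o, 0.0) for o in OUTCOMES])

    def draw_indel(self, rng: np.random.Generator) -> int:
        """Signed indel length: negative = deletion, positive = insertion."""
        length = int(min(rng.geometric(self.indel_geom_p), self.max_indel))
        sign = -1 if rng.random() < self.deletion_fraction else 1
        return sign * length


@dataclass(frozen=True)
class AlleleRecord:
    """A simulated edited allele plus the events that produced it."""

    id: str
    seq: NucSeq
    outcome: str
    events: tuple[dict, ...] = ()


@dataclass(frozen=True)
class Read:
    id: str
    seq: str
    qual: str
    mate: int               # 0 = single-end, 1/2 = pair mates
    source_allele: str
    outcome: str


@dataclass
class ReadSet:
    reads: list[Read]
    paired: bool

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def to_fastq(self, path, mate: int | None = None) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                if mate is not None and r.mate != mate:
                    continue
                fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")

    def write_truth_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tsource_allele\toutcome\n")
            for r in self.reads:
                fh.write(f"{r.id}\t{r.source_allele}\t{r.outcome}\n")


def make_mock_aav(donor: HitiDonor, rng: np.random.Generator) -> NucSeq:
    """Mock AAV vector genome: 145-nt ITR stand-ins flanking the cassette."""
    itr5 = random_bases(rng, ITR_LEN)
    itr3 = random_bases(rng, ITR_LEN)
    return NucSeq("mock_aav", itr5 + donor.cassette.bases + itr3)


# ---------------------------------------------------------------------------
# allele simulation

def _apply_junction_indel(
    seq: str, pos: int, signed_len: int, rng: np.random.Generator
) -> tuple[str, dict]:
    """Centred deletion or insertion at a ligation point ``pos``."""
    if signed_len < 0:
        length = -signed_len
        left = length // 2
        start = max(0, pos - left)
        event = {"type": "del", "pos": start, "len": length}
        return seq[:start] + seq[start + length:], event
    ins = random_bases(rng, signed_len)
    event = {"type": "ins", "pos": pos, "seq": ins}
    return seq[:pos] + ins + seq[pos:], event


def simulate_alleles(
    locus: TargetLocus,
    donor: HitiDonor,
    mixture: OutcomeMixture,
    n: int,
    seed: int | np.random.Generator,
    aav: NucSeq | None = None,
    vector_fragment_len: tuple[int, int] = (50, 500),
) -> list[AlleleRecord]:
    """Draw ``n`` alleles from the outcome mixture (seeded multinomial).

    ``aav`` (a mock vector genome) is required when the mixture includes
    ``vector_fragment`` outcomes.
    """
    if n < 1:
        raise SimulationError("n must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if mixture.fractions.get("vector_fragment", 0) > 0 and aav is None:
        raise SimulationError("vector_fragment outcomes need a mock AAV genome")
    fwd = predict_integration(locus, donor, "forward")
    inv = predict_integration(locus, donor, "inverted")
    cut = locus.cut_pos
    probs = mixture.full()
    draws = rng.choice(len(OUTCOMES), size=n, p=probs)
    alleles: list[AlleleRecord] = []
    for i, k in enumerate(draws):
        outcome = OUTCOMES[k]
        aid = f"allele{i:06d}"
        events: tuple[dict, ...] = ()
        if outcome == "unmodified":
            seq = locus.ref.bases
        elif outcome == "nhej_indel":
            signed = mixture.draw_indel(rng)
            seq, ev = _apply_junction_indel(locus.ref.bases, cut, signed, rng)
            events = (ev,)
        elif outcome == "precise_hiti":
            seq = fwd.edited_allele.bases
        elif outcome == "imprecise_hiti":
            seq = fwd.edited_allele.bases
            which = rng.choice(3, p=[0.4, 0.4, 0.2])  # 5', 3', both
            evs = []
            if which in (1, 2):  # 3' first so 5' coordinates stay valid
                signed = mixture.draw_indel(rng)
                seq, ev = _apply_junction_indel(seq, fwd.insert_end, signed, rng)
                ev["junction"] = "three"
                evs.append(ev)
            if which in (0, 2):
                signed = mixture.draw_indel(rng)
                seq, ev = _apply_junction_indel(seq, fwd.insert_start, signed, rng)
                ev["junction"] = "five"
                evs.append(ev)
            events = tuple(evs)
        elif outcome == "inverted_hiti":
            seq = inv.edited_allele.bases
        else:  # vector_fragment
            lo, hi = vector_fragment_len
            hi = min(hi, len(aav))
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, len(aav) - length + 1))
            frag = aav.bases[start:start + length]
            orient = "+" if rng.random() < 0.5 else "-"
            if orient == "-":
                frag = revcomp(frag)
            seq = locus.ref.bases[:cut] + frag + locus.ref.bases[cut:]
            events = ({"type": "vector_fragment", "start": start,
                       "len": length, "orient": orient},)
        alleles.append(AlleleRecord(aid, NucSeq(aid, seq), outcome, events))
    return alleles


def replay_allele(
    locus: TargetLocus, donor: HitiDonor, record: AlleleRecord,
    aav: NucSeq | None = None,
) -> NucSeq:
    """Re-derive an allele sequence from its recorded truth events."""
    cut = locus.cut_pos
    if record.outcome == "unmodified":
        return NucSeq(record.id, locus.ref.bases)
    if record.outcome in ("precise_hiti", "imprecise_hiti"):
        seq = predict_integration(locus, donor, "forward").edited_allele.bases
    elif record.outcome == "inverted_hiti":
        return NucSeq(
            record.id,
            predict_integration(locus, donor, "inverted").edited_allele.bases,
        )
    elif record.outcome == "nhej_indel":
        seq = locus.ref.bases
    else:  # vector_fragment
        ev = record.events[0]
        frag = aav.bases[ev["start"]:ev["start"] + ev["len"]]
        if ev["orient"] == "-":
            frag = revcomp(frag)
        return NucSeq(record.id,
                      locus.ref.bases[:cut] + frag + locus.ref.bases[cut:])
    for ev in record.events:
        if ev["type"] == "del":
            seq = seq[:ev["pos"]] + seq[ev["pos"] + ev["len"]:]
        elif ev["type"] == "ins":
            seq = seq[:ev["pos"]] + ev["seq"] + seq[ev["pos"]:]
    return NucSeq(record.id, seq)


def make_junction_insertion_allele(
    locus: TargetLocus,
    donor: HitiDonor,
    insertion_len: int,
    junction: str = "five",
    seed: int | np.random.Generator = 0,
) -> AlleleRecord:
    """An imprecise-HITI allele with a defined insertion at one junction."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    fwd = predict_integration(locus, donor, "forward")
    pos = fwd.insert_start if junction == "five" else fwd.insert_end
    ins = random_bases(rng, insertion_len)
    seq = fwd.edited_allele.bases
    seq = seq[:pos] + ins + seq[pos:]
    ev = {"type": "ins", "pos": pos, "seq": ins, "junction": junction}
    return AlleleRecord("junction_ins", NucSeq("junction_ins", seq),
                        "imprecise_hiti", (ev,))


# ---------------------------------------------------------------------------
# read simulation

def _add_substitutions(
    seq: str, rate: float, rng: np.random.Generator
) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        cur = arr[i].decode()
        alt = [b for b in "ACGT" if b != cur]
        arr[i] = alt[int(rng.integers(0, len(alt)))].encode()
    return arr.tobytes().decode()


def _find_amplicon(
    seq: str, fwd_primer: str, rev_primers: Sequence[str]
) -> tuple[int, int] | None:
    f = seq.find(fwd_primer)
    if f < 0:
        return None
    best_end = None
    for rp in rev_primers:
        rc = revcomp(rp)
        r = seq.find(rc, f + len(fwd_primer))
        if r >= 0:
            end = r + len(rc)
            if best_end is None or end < best_end:
                best_end = end
    if best_end is None:
        return None
    return f, best_end


def simulate_amplicon_reads(
    alleles: Sequence[AlleleRecord],
    fwd_primer: NucSeq | str,
    rev_primers: Sequence[NucSeq | str],
    n_reads: int,
    read_len: int = 150,
    paired: bool = True,
    sub_error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    max_amplicon_len: int = 2000,
    qual_char: str = "?",  # Q30, Phred+33
) -> ReadSet:
    """Paired-end reads from PCR amplicons delimited by the primers.

    Each allele's amplicon runs from the forward primer to the nearest
    reverse-primer binding site (one reverse primer per reference form, as
    in the dual-amplicon design).  Alleles without both primer sites, or
    with an amplicon over ``max_amplicon_len``, drop out of the pool
    (unamplifiable).  At ``sub_error_rate`` 0 every read is an exact
    substring of its source amplicon.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    fwd = fwd_primer.bases if isinstance(fwd_primer, NucSeq) else fwd_primer
    revs = [p.bases if isinstance(p, NucSeq) else p for p in rev_primers]
    pool: list[tuple[AlleleRecord, str]] = []
    for a in alleles:
        span = _find_amplicon(a.seq.bases, fwd, revs)
        if span is None:
            continue
        amp = a.seq.bases[span[0]:span[1]]
        if len(amp) <= max_amplicon_len:
            pool.append((a, amp))
    if not pool:
        raise SimulationError("primers absent from every allele")
    if paired and n_reads % 2:
        raise SimulationError("paired output needs an even n_reads")
    n_frag = n_reads // 2 if paired else n_reads
    picks = rng.integers(0, len(pool), size=n_frag)
    reads: list[Read] = []
    for i, j in enumerate(picks):
        a, amp = pool[int(j)]
        if paired:
            r1 = _add_substitutions(amp[:read_len], sub_error_rate, rng)
            r2 = _add_substitutions(
                revcomp(amp[-read_len:] if len(amp) >= read_len else amp),
                sub_error_rate, rng)
            reads.append(Read(f"amp{i:07d}/1", r1, qual_char * len(r1), 1,
                              a.id, a.outcome))
            reads.append(Read(f"amp{i:07d}/2", r2, qual_char * len(r2), 2,
                              a.id, a.outcome))
        else:
            r = _add_substitutions(amp[:read_len], sub_error_rate, rng)
            reads.append(Read(f"amp{i:07d}", r, qual_char * len(r), 0,
                              a.id, a.outcome))
    return ReadSet(reads, paired)


def simulate_junction_reads(
    alleles: Sequence[AlleleRecord],
    fwd_primer: NucSeq | str,
    rev_primer: NucSeq | str,
    n_reads: int,
    raw_len: int = 600,
    trimmed_len: int = 350,
    sub_error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    qual_char: str = "?",
) -> ReadSet:
    """Single-end junction-amplicon reads, generated at ``raw_len`` from the
    forward-primer end and then truncated to ``trimmed_len`` (emulating the
    adapter/quality trimming step that shortens 600-nt reads to 350 nt)."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    fwd = fwd_primer.bases if isinstance(fwd_primer, NucSeq) else fwd_primer
    rev = rev_primer.bases if isinstance(rev_primer, NucSeq) else rev_primer
    pool: list[tuple[AlleleRecord, str]] = []
    for a in alleles:
        span = _find_amplicon(a.seq.bases, fwd, [rev])
        if span is not None:
            pool.append((a, a.seq.bases[span[0]:span[1]]))
    if not pool:
        raise SimulationError("junction primers absent from every allele")
    picks = rng.integers(0, len(pool), size=n_reads)
    reads = []
    for i, j in enumerate(picks):
        a, amp = pool[int(j)]
        raw = amp[:raw_len]
        r = _add_substitutions(raw[:trimmed_len], sub_error_rate, rng)
        reads.append(Read(f"jx{i:07d}", r, qual_char * len(r), 0,
                          a.id, a.outcome))
    return ReadSet(reads, paired=False)


# ---------------------------------------------------------------------------
# capture-style simulation

@dataclass
class MockGenome:
    """Named chromosomes with the target locus embedded in one of them."""

    chroms: dict[str, NucSeq]
    target_chrom: str
    locus_start: int          # locus.ref span within the target chromosome
    locus_end: int


def make_mock_genome(
    locus: TargetLocus,
    seed: int | np.random.Generator,
    n_chroms: int = 3,
    chrom_len: int = 6000,
) -> MockGenome:
    """Random chromosomes; the target locus sequence replaces a segment in
    the middle of chr1."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    chroms: dict[str, NucSeq] = {}
    start = (chrom_len - len(locus.ref)) // 2
    for i in range(n_chroms):
        name = f"chr{i + 1}"
        bases = random_bases(rng, chrom_len)
        if i == 0:
            bases = (bases[:start] + locus.ref.bases
                     + bases[start + len(locus.ref):])
        chroms[name] = NucSeq(name, bases)
    return MockGenome(chroms, "chr1", start, start + len(locus.ref))


@dataclass(frozen=True)
class Integration:
    chrom: str
    pos: int                  # chromosome coordinate of the insertion point
    insert: str               # inserted sequence (donor core, etc.)


def apply_integrations(
    genome: MockGenome, integrations: Sequence[Integration]
) -> tuple[dict[str, NucSeq], dict[str, list[tuple[int, int]]]]:
    """Insert donor cores into chromosomes; returns edited chromosomes and
    per-chromosome insert spans (in edited coordinates)."""
    per_chrom: dict[str, list[Integration]] = {}
    for ig in integrations:
        per_chrom.setdefault(ig.chrom, []).append(ig)
    edited: dict[str, NucSeq] = {}
    spans: dict[str, list[tuple[int, int]]] = {}
    for name, seq in genome.chroms.items():
        evs = sorted(per_chrom.get(name, []), key=lambda e: e.pos)
        bases, shift, sp = seq.bases, 0, []
        for ig in evs:
            p = ig.pos + shift
            bases = bases[:p] + ig.insert + bases[p:]
            sp.append((p, p + len(ig.insert)))
            shift += len(ig.insert)
        edited[name] = NucSeq(name, bases)
        spans[name] = sp
    return edited, spans


def simulate_capture_reads(
    chroms: dict[str, NucSeq],
    rois: dict[str, list[tuple[int, int]]],
    n_reads: int,
    episomal_vector: NucSeq | None = None,
    episomal_copies: int = 0,
    enrichment_factor: float = 50.0,
    read_len: int = 150,
    sub_error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    insert_spans: dict[str, list[tuple[int, int]]] | None = None,
    qual_char: str = "?",
) -> ReadSet:
    """Capture-style reads enriched over regions of interest.

    Read start positions overlapping an ROI are weighted ``enrichment_factor``
    against a uniform background.  Episomal vector copies are whole-molecule
    ROIs with copy-number weight and produce donor/vector reads with no host
    flank.  Reads overlapping a recorded integration-insert boundary are
    labelled ``chimeric`` in their truth outcome.
    """
    if not chroms and not (episomal_vector and episomal_copies):
        raise SimulationError("empty genome")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    molecules: list[tuple[str, str, float, list[tuple[int, int]]]] = []
    for name, seq in chroms.items():
        molecules.append((name, seq.bases, 1.0, rois.get(name, [])))
    if episomal_vector is not None and episomal_copies > 0:
        molecules.append((
            episomal_vector.id, episomal_vector.bases,
            float(episomal_copies),
            [(0, len(episomal_vector))],
        ))
    weights, index = [], []
    for mi, (name, bases, copies, roi) in enumerate(molecules):
        n_start = len(bases) - read_len + 1
        if n_start <= 0:
            continue
        w = np.full(n_start, copies)
        for a, b in roi:
            lo, hi = max(0, a - read_len + 1), min(n_start, b)
            if hi > lo:
                w[lo:hi] *= enrichment_factor
        weights.append(w)
        index.append(mi)
    w_all = np.concatenate(weights)
    p = w_all / w_all.sum()
    starts = rng.choice(len(w_all), size=n_reads, p=p)
    offsets = np.cumsum([0] + [len(w) for w in weights])
    reads = []
    for i, flat in enumerate(starts):
        mi = int(np.searchsorted(offsets, flat, side="right") - 1)
        s = int(flat - offsets[mi])
        name, bases, _, _ = molecules[index[mi]]
        frag = bases[s:s + read_len]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        outcome = "background"
        if name == (episomal_vector.id if episomal_vector else None):
            outcome = "episomal_vector"
        elif insert_spans and name in insert_spans:
            for a, b in insert_spans[name]:
                if (s < a < s + read_len) or (s < b < s + read_len):
                    outcome = "chimeric"
                    break
                if a <= s and s + read_len <= b:
                    outcome = "insert_only"
                    break
        seq = _add_substitutions(frag, sub_error_rate, rng)
        reads.append(Read(f"cap{i:07d}", seq, qual_char * len(seq), 0,
                          f"{name}:{s}", outcome))
    return ReadSet(reads, paired=False)


# ---------------------------------------------------------------------------
# worked example system shared by analyses, tests and the acceptance script

def make_example_system(
    seed: int = 11,
    payload_len: int = 300,
    flank: int = 180,
) -> tuple[TargetLocus, HitiDonor]:
    """A reproducible rhodopsin-like demo locus and kozak donor.

    The reference is a random sequence with a single embedded 20-nt guide
    site (AGG PAM) ``flank`` nt from each end; the payload is a random CDS
    beginning ATG, standing in for a fluorescent-reporter CDS.
    """
    from .donor import build_donor
    from .seqcore import GuideSpec, place_guide, scan_sites

    rng = np.random.default_rng(seed)
    while True:
        proto = random_bases(rng, 20)
        left = random_bases(rng, flank)
        right = random_bases(rng, flank)
        ref = NucSeq("target_locus", left + proto + "AGG" + right)
        guide = GuideSpec(NucSeq("guide", proto))
        if len(scan_sites(ref, guide)) != 1:
            continue
        locus = place_guide(ref, guide)
        payload = NucSeq("payload", "ATG" + random_bases(rng, payload_len - 3))
        donor = build_donor(locus, payload, start_type="kozak")
        fwd = predict_integration(locus, donor, "forward")
        inv = predict_integration(locus, donor, "inverted")
        if fwd.recleavable_sites == 0 and inv.recleavable_sites == 2:
            return locus, donor


@dataclass(frozen=True)
class DualAmpliconDesign:
    """Primer/reference design for dual-amplicon HITI quantification."""

    fwd_primer: NucSeq
    wt_rev_primer: NucSeq
    hybrid_rev_primer: NucSeq
    wt_ref: NucSeq
    hybrid_ref: NucSeq
    cut_in_amplicon: int      # cut position in wt_ref coordinates


def design_dual_amplicon(
    locus: TargetLocus,
    donor: HitiDonor,
    up: int = 105,
    down: int = 115,
    primer_len: int = 20,
) -> DualAmpliconDesign:
    """Shared-forward-primer amplicons of similar size over the wild-type
    and precise-HITI alleles, with the cut ``up`` nt from the amplicon start
    so that both 150-nt mates of either amplicon span the +/-17-nt window."""
    cut = locus.cut_pos
    fwd = locus.ref.slice(cut - up, cut - up + primer_len, id="fwd_primer")
    wt_amp = locus.ref.slice(cut - up, cut + down, id="wt_amplicon")
    wt_rev = NucSeq("wt_rev_primer",
                    revcomp(locus.ref.bases[cut + down - primer_len:cut + down]))
    hy = predict_integration(locus, donor, "forward").edited_allele
    hy_amp = hy.slice(cut - up, cut + down, id="hybrid_amplicon")
    hy_rev = NucSeq("hybrid_rev_primer",
                    revcomp(hy.bases[cut + down - primer_len:cut + down]))
    return DualAmpliconDesign(fwd, wt_rev, hy_rev, wt_amp, hy_amp, up)
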