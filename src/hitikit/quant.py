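"""Amplicon-side editing quantification.

Implements the three read-level quantifications used to measure HITI:

* windowed INDEL frequency -- a read is "modified" iff an I/D event in its
  alignment overlaps the +/-17-nt window around the blunt cut;
* dual-amplicon HITI estimation -- pooled reads from co-amplified wild-type
  and donor-integrated alleles are assigned to the reference with the
  higher local-alignment score; hybrid-assigned reads count as HITI alleles;
* junction precision classification -- junction-amplicon reads are grouped
  into a "precise" class and (type, length) indel species, with a
  tissue-specific minimum species frequency (retina 0.1%, liver 0.5%,
  inclusive >=).

Substitution mismatches never count as modification: editing outcomes are
INDEL-defined here.  Reads whose alignment does not span the whole window
are uninformative and are excluded from denominators.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .align import (
    AlignParams,
    AlignmentRecord,
    DEFAULT_PARAMS,
    align_local,
    best_score,
    cigar_indels,
)
from .seqcore import NucSeq, TargetLocus
from .simulate import Read, ReadSet


class QuantError(ValueError):
    pass


@dataclass(frozen=True)
class WindowSpec:
    """Flank (nt) on each side of the cut; default 17 gives a 34-nt window."""

    flank: int = 17

    def __post_init__(self) -> None:
        if self.flank < 1:
            raise ValueError("flank must be >= 1")

    def interval(self, cut_pos: int) -> tuple[int, int]:
        return cut_pos - self.flank, cut_pos + self.flank


@dataclass(frozen=True)
class ThresholdPolicy:
    """Minimum reported indel-species frequency (%), inclusive >=."""

    min_species_frequency: float = 0.1

    def __post_init__(self) -> None:
        if self.min_species_frequency < 0:
            raise ValueError("min_species_frequency must be >= 0")

    @classmethod
    def for_tissue(cls, tissue: str) -> "ThresholdPolicy":
        presets = {"retina": 0.1, "liver": 0.5}
        if tissue not in presets:
            raise ValueError(f"unknown tissue preset {tissue!r}")
        return cls(presets[tissue])


@dataclass
class EditSummary:
    """Per-class counts/frequencies over assigned (informative) reads."""

    n_assigned: int
    n_unmodified: int
    n_indel: int
    n_hiti: int
    n_ambiguous: int
    n_excluded: int
    spectrum_counts: dict[int, int] = field(default_factory=dict)

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.n_assigned if self.n_assigned else 0.0

    @property
    def pct_unmodified(self) -> float:
        return self._pct(self.n_unmodified)

    @property
    def pct_indel(self) -> float:
        return self._pct(self.n_indel)

    @property
    def pct_hiti(self) -> float:
        return self._pct(self.n_hiti)

    @property
    def spectrum(self) -> dict[int, float]:
        """Signed indel length (insertions +, deletions -) -> frequency %."""
        return {k: self._pct(v) for k, v in sorted(self.spectrum_counts.items())}

    def to_dict(self) -> dict:
        return {
            "n_assigned": self.n_assigned,
            "n_ambiguous": self.n_ambiguous,
            "n_excluded": self.n_excluded,
            "pct_unmodified": round(self.pct_unmodified, 4),
            "pct_indel": round(self.pct_indel, 4),
            "pct_hiti": round(self.pct_hiti, 4),
            "spectrum": {str(k): round(v, 4) for k, v in self.spectrum.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def _iter_reads(reads) -> Iterable[tuple[str, str]]:
    if isinstance(reads, ReadSet):
        for r in reads:
            yield r.id, r.seq
    else:
        for r in reads:
            if isinstance(r, Read):
                yield r.id, r.seq
            elif isinstance(r, NucSeq):
                yield r.id, r.bases
            else:
                yield r


def events_in_window(
    rec: AlignmentRecord, window: tuple[int, int]
) -> list[tuple[str, int, int]]:
    """I/D events whose ref span overlaps [wstart, wend).

    Deletions occupy [pos, pos+len); insertions are points, counted when
    wstart <= pos <= wend so a junction insertion exactly at the window edge
    (e.g. at the cut between the two flanks) is attributed to the cut.
    """
    ws, we = window
    out = []
    for typ, length, roff in cigar_indels(rec):
        pos = rec.ref_start + roff
        if typ == "D":
            if pos < we and pos + length > ws:
                out.append((typ, length, pos))
        else:
            if ws <= pos <= we:
                out.append((typ, length, pos))
    return out


def _covers(rec: AlignmentRecord, window: tuple[int, int]) -> bool:
    return rec.ref_start <= window[0] and rec.ref_end >= window[1]


def window_indel_frequency(
    reads,
    locus: TargetLocus,
    window: WindowSpec = WindowSpec(),
    params: AlignParams = DEFAULT_PARAMS,
) -> EditSummary:
    """Windowed INDEL quantification against a single reference.

    Reads that fail to align, or whose alignment does not span the whole
    window, are excluded from the denominator.
    """
    win = window.interval(locus.cut_pos)
    n_unmod = n_indel = n_excl = 0
    spectrum: Counter[int] = Counter()
    for rid, seq in _iter_reads(reads):
        rec = align_local(NucSeq(rid, seq), locus.ref, params)
        if rec is None or not _covers(rec, win):
            n_excl += 1
            continue
        evs = events_in_window(rec, win)
        if evs:
            n_indel += 1
            for typ, length, _ in evs:
                spectrum[length if typ == "I" else -length] += 1
        else:
            n_unmod += 1
    n_assigned = n_unmod + n_indel
    if n_assigned == 0:
        raise QuantError("no read spans the cleavage window")
    return EditSummary(
        n_assigned=n_assigned, n_unmodified=n_unmod, n_indel=n_indel,
        n_hiti=0, n_ambiguous=0, n_excluded=n_excl,
        spectrum_counts=dict(spectrum),
    )


def dual_amplicon_hiti(
    reads,
    wt_ref: NucSeq,
    hybrid_ref: NucSeq,
    locus: TargetLocus,
    window: WindowSpec = WindowSpec(),
    params: AlignParams = DEFAULT_PARAMS,
) -> EditSummary:
    """Dual-amplicon HITI-allele estimation over pooled reads.

    Each read goes to the reference with the higher local score (equal
    scores -> ambiguous, excluded).  Hybrid-assigned reads count as HITI;
    wild-type-assigned reads spanning the cleavage window are subclassified
    into indel vs unmodified.  ``locus`` must carry the cut position in
    ``wt_ref`` coordinates (e.g. ``place_guide(wt_ref, guide)``).
    """
    if wt_ref.bases == hybrid_ref.bases:
        raise QuantError("wild-type and hybrid references are identical")
    win = window.interval(locus.cut_pos)
    n_unmod = n_indel = n_hiti = n_ambig = n_excl = 0
    spectrum: Counter[int] = Counter()
    fast_scores = params.clip_penalty == 0
    for rid, seq in _iter_reads(reads):
        q = NucSeq(rid, seq)
        if fast_scores:
            # score-only comparison; the full alignment (traceback) is only
            # needed for wild-type-assigned reads
            s_wt = best_score(q, wt_ref, params)
            s_hy = best_score(q, hybrid_ref, params)
            s_wt = s_wt if s_wt >= params.min_score else float("-inf")
            s_hy = s_hy if s_hy >= params.min_score else float("-inf")
            rec_wt = None
        else:
            rec_wt = align_local(q, wt_ref, params)
            rec_hy = align_local(q, hybrid_ref, params)
            s_wt = rec_wt.score if rec_wt else float("-inf")
            s_hy = rec_hy.score if rec_hy else float("-inf")
        if s_wt == float("-inf") and s_hy == float("-inf"):
            n_excl += 1
        elif s_hy > s_wt:
            n_hiti += 1
        elif s_wt > s_hy:
            if rec_wt is None:
                rec_wt = align_local(q, wt_ref, params)
            if rec_wt is None or not _covers(rec_wt, win):
                n_excl += 1
                continue
            evs = events_in_window(rec_wt, win)
            if evs:
                n_indel += 1
                for typ, length, _ in evs:
                    spectrum[length if typ == "I" else -length] += 1
            else:
                n_unmod += 1
        else:
            n_ambig += 1
    n_assigned = n_unmod + n_indel + n_hiti
    if n_assigned == 0:
        raise QuantError("no read could be assigned to either amplicon")
    return EditSummary(
        n_assigned=n_assigned, n_unmodified=n_unmod, n_indel=n_indel,
        n_hiti=n_hiti, n_ambiguous=n_ambig, n_excluded=n_excl,
        spectrum_counts=dict(spectrum),
    )


@dataclass(frozen=True)
class IndelSpecies:
    type: str          # "I" | "D"
    length: int
    count: int
    pct: float

    @property
    def signed_length(self) -> int:
        return self.length if self.type == "I" else -self.length


@dataclass
class JunctionReport:
    """Precision classification of junction-amplicon reads."""

    n_spanning: int
    n_precise: int
    n_excluded: int
    species: list[IndelSpecies]
    policy: ThresholdPolicy

    @property
    def pct_precise(self) -> float:
        return 100.0 * self.n_precise / self.n_spanning if self.n_spanning else 0.0

    def species_by_length(self, length: int, type: str = "I") -> IndelSpecies | None:
        for sp in self.species:
            if sp.type == type and sp.length == length:
                return sp
        return None

    def apply_policy(self, policy: ThresholdPolicy) -> "JunctionReport":
        """Drop species below the threshold (inclusive >= keeps); idempotent."""
        kept = [sp for sp in self.species
                if sp.pct >= policy.min_species_frequency]
        return JunctionReport(self.n_spanning, self.n_precise,
                              self.n_excluded, kept, policy)

    def to_rows(self) -> list[dict]:
        rows = [{"class": "precise", "type": "", "length": 0,
                 "count": self.n_precise, "pct": round(self.pct_precise, 4)}]
        for sp in self.species:
            rows.append({"class": "indel_species", "type": sp.type,
                         "length": sp.length, "count": sp.count,
                         "pct": round(sp.pct, 4)})
        return rows


def classify_junctions(
    reads,
    junction_ref: NucSeq,
    junction_pos: int,
    window: WindowSpec = WindowSpec(),
    policy: ThresholdPolicy = ThresholdPolicy(0.1),
    params: AlignParams = DEFAULT_PARAMS,
) -> JunctionReport:
    """Classify junction reads as precise vs indel species at the junction.

    ``junction_pos`` is the ligation point in ``junction_ref`` coordinates.
    Species frequencies are computed over window-spanning reads, then
    filtered by the tissue threshold (inclusive >=).
    """
    win = window.interval(junction_pos)
    n_precise = n_excl = n_span = 0
    counter: Counter[tuple[str, int]] = Counter()
    for rid, seq in _iter_reads(reads):
        rec = align_local(NucSeq(rid, seq), junction_ref, params)
        if rec is None or not _covers(rec, win):
            n_excl += 1
            continue
        n_span += 1
        evs = events_in_window(rec, win)
        if not evs:
            n_precise += 1
        else:
            for typ, length, _ in evs:
                counter[(typ, length)] += 1
    species = [
        IndelSpecies(typ, length, c, 100.0 * c / n_span if n_span else 0.0)
        for (typ, length), c in sorted(counter.items())
    ]
    report = JunctionReport(n_span, n_precise, n_excl, species, policy)
    return report.apply_policy(policy)
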