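"""Split-read detection of donor/vector integration from capture-style reads.

Procedure: align every read to the donor insert under a near-exact-match
("strict") preset so that any non-donor segment is soft-clipped; reads with
a *partial* alignment carry a donor/other junction and are partitioned into
an insert portion and a flank portion (kept only when strictly longer than
22 and 30 nt respectively); flanks are then realigned against the vector
genome and the host chromosomes, and the best-scoring reference accumulates
chimeric-read evidence.  On-target integration is counted by anchoring on
reads whose insert alignment covers the first 10 nt of the insert and
overlaps the cleavage region after realignment to the target gene.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .align import AlignParams, STRICT_PARAMS, align_local, best_score
from .seqcore import NucSeq
from .simulate import ReadSet
from .quant import _iter_reads


@dataclass(frozen=True)
class SplitReadPartition:
    """A chimeric read split into donor-insert and flank portions."""

    read_id: str
    insert_portion: str
    flank_portion: str
    insert_ref_start: int    # insert-coordinate interval of the alignment
    insert_ref_end: int
    strand: str
    flank_side: str          # "left" | "right" of the oriented read


@dataclass
class PartitionResult:
    partitions: list[SplitReadPartition] = field(default_factory=list)
    insert_only: list[str] = field(default_factory=list)
    discarded_partial: list[str] = field(default_factory=list)
    non_insert: list[str] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return (len(self.partitions) + len(self.insert_only)
                + len(self.discarded_partial) + len(self.non_insert))


def find_insert_reads(
    reads,
    insert: NucSeq,
    params: AlignParams = STRICT_PARAMS,
    min_insert_len: int = 22,
    min_flank_len: int = 30,
    full_clip_tolerance: int = 5,
) -> PartitionResult:
    """Partition reads by their strict alignment to the donor insert.

    Full-length alignments (total clipping <= ``full_clip_tolerance``) are
    insert-only evidence (episomal/vector molecules, not chimeric).  Partial
    alignments become :class:`SplitReadPartition` when the aligned insert
    portion is strictly longer than ``min_insert_len`` nt and the clipped
    flank strictly longer than ``min_flank_len`` nt; otherwise the read is
    discarded.  When both ends are clipped the larger clip is the flank.
    """
    if len(insert) < 50:
        raise ValueError("insert must be >= 50 nt")
    result = PartitionResult()
    for rid, seq in _iter_reads(reads):
        q = NucSeq(rid, seq)
        rec = align_local(q, insert, params)
        if rec is None:
            result.non_insert.append(rid)
            continue
        oriented = q.bases if rec.strand == "+" else _rc(q.bases)
        left = rec.query_start
        right = len(oriented) - rec.query_end
        if left + right <= full_clip_tolerance:
            result.insert_only.append(rid)
            continue
        if left >= right:
            flank, side = oriented[:left], "left"
        else:
            flank, side = oriented[rec.query_end:], "right"
        insert_portion = oriented[rec.query_start:rec.query_end]
        if len(insert_portion) > min_insert_len and len(flank) > min_flank_len:
            result.partitions.append(SplitReadPartition(
                read_id=rid, insert_portion=insert_portion,
                flank_portion=flank,
                insert_ref_start=rec.ref_start, insert_ref_end=rec.ref_end,
                strand=rec.strand, flank_side=side,
            ))
        else:
            result.discarded_partial.append(rid)
    return result


def _rc(s: str) -> str:
    from .seqcore import revcomp
    return revcomp(s)


@dataclass
class IntegrationTally:
    """Per-reference chimeric-flank counts from realignment."""

    counts: dict[str, int] = field(default_factory=dict)
    ambiguous: int = 0
    unmapped: int = 0
    total_partitions: int = 0

    def to_rows(self) -> list[dict]:
        total = max(self.total_partitions, 1)
        rows = [
            {"reference": ref, "count": c, "pct": round(100.0 * c / total, 4)}
            for ref, c in sorted(self.counts.items(),
                                 key=lambda kv: (-kv[1], kv[0]))
        ]
        rows.append({"reference": "ambiguous", "count": self.ambiguous,
                     "pct": round(100.0 * self.ambiguous / total, 4)})
        rows.append({"reference": "unmapped", "count": self.unmapped,
                     "pct": round(100.0 * self.unmapped / total, 4)})
        return rows

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_rows(), fh, indent=2)
            fh.write("\n")


def realign_flanks(
    partitions: list[SplitReadPartition],
    references: dict[str, NucSeq],
    params: AlignParams = STRICT_PARAMS,
) -> IntegrationTally:
    """Assign each flank to its best-scoring reference (vector or host
    chromosome).  Ties between references are ambiguous and excluded;
    flanks below the score cutoff everywhere are unmapped."""
    if not references:
        raise ValueError("empty reference set")
    tally = IntegrationTally(counts={name: 0 for name in references},
                             total_partitions=len(partitions))
    for part in partitions:
        flank = NucSeq(part.read_id + ":flank", part.flank_portion)
        scores = {
            name: best_score(flank, ref, params)
            for name, ref in references.items()
        }
        top = max(scores.values())
        if top < params.min_score:
            tally.unmapped += 1
            continue
        winners = [name for name, s in scores.items() if s == top]
        if len(winners) > 1:
            tally.ambiguous += 1
        else:
            tally.counts[winners[0]] += 1
    return tally


@dataclass(frozen=True)
class OnTargetResult:
    anchored_count: int       # insert-anchored chimeric reads in the region
    total_covering: int       # all reads overlapping the cleavage region
    frequency: float


def ontarget_insert_frequency(
    reads,
    insert: NucSeq,
    target_gene_ref: NucSeq,
    cleavage_region: tuple[int, int],
    params: AlignParams = STRICT_PARAMS,
    anchor_len: int = 10,
) -> OnTargetResult:
    """Count insert-anchored reads at the cleavage region.

    Step 1: keep reads whose strict insert alignment is partial (soft clip
    present) and covers insert positions [0, ``anchor_len``).  Step 2:
    realign those reads to the target gene.  Step 3: count those whose
    alignment overlaps ``cleavage_region``; the frequency denominator is all
    reads whose target-gene alignment overlaps the region.
    """
    start, end = cleavage_region
    if not (0 <= start < end <= len(target_gene_ref)):
        raise ValueError("cleavage_region outside the target gene reference")
    anchored_ids = set()
    read_list = [(rid, seq) for rid, seq in _iter_reads(reads)]
    for rid, seq in read_list:
        rec = align_local(NucSeq(rid, seq), insert, params)
        if rec is None:
            continue
        qlen = len(seq)
        clipped = (rec.query_start > 0) or (rec.query_end < qlen)
        if clipped and rec.ref_start == 0 and rec.ref_end >= anchor_len:
            anchored_ids.add(rid)
    anchored = total = 0
    for rid, seq in read_list:
        rec = align_local(NucSeq(rid, seq), target_gene_ref, params)
        if rec is None:
            continue
        if rec.ref_start < end and rec.ref_end > start:
            total += 1
            if rid in anchored_ids:
                anchored += 1
    freq = anchored / total if total else 0.0
    return OnTargetResult(anchored, total, freq)


def write_partition_fastas(
    result: PartitionResult, insert_fasta_path, flank_fasta_path
) -> None:
    """The two intermediate FASTA files: insert portions and flanks."""
    with open(insert_fasta_path, "w") as fh:
        for p in result.partitions:
            fh.write(f">{p.read_id}/insert\n{p.insert_portion}\n")
    with open(flank_fasta_path, "w") as fh:
        for p in result.partitions:
            fh.write(f">{p.read_id}/flank\n{p.flank_portion}\n")
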