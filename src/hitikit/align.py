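"""Local pairwise alignment with CIGAR output and soft clips.

The alignment engine is Smith-Waterman with affine gaps (Bio.Align's C
implementation in local mode); this module owns the scoring presets, strand
handling, CIGAR extraction from alignment coordinates, left-normalisation
of indels, clip accounting and the minimum-score cutoff.

Two presets are provided:

* ``DEFAULT_PARAMS`` -- permissive BWA-MEM-like scoring (match 1, mismatch 4,
  gap open 6, gap extend 1) used for amplicon/junction quantification where
  real editing indels must be represented as I/D operations.
* ``STRICT_PARAMS`` -- a near-exact-match regime (match 1, mismatch 50, gap
  open 60, gap extend 10) used for split-read donor detection, where any
  divergent read segment should be soft-clipped rather than extended
  through.  Gap of length k costs open + k*extend.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass

from .seqcore import NucSeq, revcomp

_CIG_RE = re.compile(r"(\d+)([MIDS])")


class CigarError(ValueError):
    """Malformed CIGAR string."""


@dataclass(frozen=True)
class AlignParams:
    match: float = 1.0
    mismatch_penalty: float = 4.0
    gap_open: float = 6.0
    gap_extend: float = 1.0
    clip_penalty: float = 0.0
    min_score: float = 20.0

    def __post_init__(self) -> None:
        for name in ("mismatch_penalty", "gap_open", "gap_extend",
                     "clip_penalty"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_score < 0:
            raise ValueError("min_score must be >= 0")


DEFAULT_PARAMS = AlignParams()
#: Transcription of the near-exact-identity external-aligner regime
#: (-O 60 -B 50 -E 10, clipping free) into Smith-Waterman terms.
STRICT_PARAMS = AlignParams(
    match=1.0, mismatch_penalty=50.0, gap_open=60.0, gap_extend=10.0,
    clip_penalty=0.0, min_score=20.0,
)


@dataclass(frozen=True)
class AlignmentRecord:
    """A single best local hit.

    ``cigar`` is over {M,I,D,S}; for strand ``-`` it describes the
    reverse-complemented query (SAM convention).  ``query_start/query_end``
    delimit the aligned interval on that same oriented query.
    """

    query_id: str
    ref_id: str
    ref_start: int
    strand: str
    cigar: str
    score: float
    query_start: int
    query_end: int

    @property
    def ops(self) -> list[tuple[int, str]]:
        return parse_cigar(self.cigar)

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(
            n for n, op in self.ops if op in "MD"
        )


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIG_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise CigarError(f"malformed CIGAR {cigar!r}")
    if any(n <= 0 for n, _ in ops):
        raise CigarError(f"non-positive run length in {cigar!r}")
    return ops


@functools.lru_cache(maxsize=16)
def _make_aligner(params: AlignParams):
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    alpha = "ACGTN"
    mat = substitution_matrices.Array(alpha, dims=2)
    for a in alpha:
        for b in alpha:
            if a == b and a != "N":
                mat[a, b] = params.match
            else:
                mat[a, b] = -params.mismatch_penalty
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def raw_score(query: str, ref: str, params: AlignParams = DEFAULT_PARAMS) -> float:
    """Best local score of query (as given) against ref; 0 if none."""
    return float(_make_aligner(params).score(ref, query))


def best_score(
    query: NucSeq | str,
    ref: NucSeq | str,
    params: AlignParams = DEFAULT_PARAMS,
    strands: str = "both",
) -> float:
    """Best local score over the requested strands (no CIGAR extraction)."""
    q = query.bases if isinstance(query, NucSeq) else query
    r = ref.bases if isinstance(ref, NucSeq) else ref
    scores = []
    if strands in ("both", "+"):
        if params.match > 0 and "N" not in q and q in r:
            return len(q) * params.match
        scores.append(raw_score(q, r, params))
    if strands in ("both", "-"):
        rc = revcomp(q)
        if params.match > 0 and "N" not in rc and rc in r:
            return len(q) * params.match
        scores.append(raw_score(rc, r, params))
    return max(scores)


def _coords_to_cigar(coords, qlen: int) -> tuple[str, int, int, int]:
    """Convert Bio.Align coordinates (target row, query row) to CIGAR.

    Returns (cigar, ref_start, query_start, query_end)."""
    t, q = coords[0], coords[1]
    ops: list[tuple[int, str]] = []
    if q[0] > 0:
        ops.append((int(q[0]), "S"))
    for i in range(len(t) - 1):
        dt, dq = int(t[i + 1] - t[i]), int(q[i + 1] - q[i])
        if dt and dq:
            ops.append((dt, "M"))
        elif dt:
            ops.append((dt, "D"))
        elif dq:
            ops.append((dq, "I"))
    if qlen - int(q[-1]) > 0:
        ops.append((qlen - int(q[-1]), "S"))
    merged: list[tuple[int, str]] = []
    for n, op in ops:
        if merged and merged[-1][1] == op:
            merged[-1] = (merged[-1][0] + n, op)
        else:
            merged.append((n, op))
    cigar = "".join(f"{n}{op}" for n, op in merged)
    return cigar, int(t[0]), int(q[0]), int(q[-1])


def _left_align_indels(cigar: str, ref_start: int, ref: str,
                       query: str) -> str:
    """Shift I/D runs leftward while score-preserving (the variant-calling
    left-alignment convention).  ``query`` is the oriented query string."""
    ops = parse_cigar(cigar)
    changed = True
    while changed:
        changed = False
        rpos, qpos = ref_start, 0
        positions = []
        for n, op in ops:
            positions.append((rpos, qpos))
            if op == "M":
                rpos += n
                qpos += n
            elif op == "D":
                rpos += n
            elif op in "IS":
                qpos += n
        for i in range(1, len(ops) - 1):
            n, op = ops[i]
            pn, pop = ops[i - 1]
            if op not in "ID" or pop != "M":
                continue
            r0, q0 = positions[i]
            shift = 0
            while shift < pn - 1:
                if op == "D":
                    a = ref[r0 - shift - 1]
                    b = ref[r0 + n - shift - 1]
                else:
                    a = query[q0 - shift - 1]
                    b = query[q0 + n - shift - 1]
                if a != b:
                    break
                shift += 1
            if shift:
                ops[i - 1] = (pn - shift, "M")
                nxt = ops[i + 1]
                if nxt[1] == "M":
                    ops[i + 1] = (nxt[0] + shift, "M")
                else:
                    ops.insert(i + 1, (shift, "M"))
                changed = True
                break
    ops = [x for x in ops if x[0] > 0]
    merged: list[tuple[int, str]] = []
    for n, op in ops:
        if merged and merged[-1][1] == op:
            merged[-1] = (merged[-1][0] + n, op)
        else:
            merged.append((n, op))
    return "".join(f"{n}{op}" for n, op in merged)


def align_local(
    query: NucSeq,
    ref: NucSeq,
    params: AlignParams = DEFAULT_PARAMS,
    strands: str = "both",
) -> AlignmentRecord | None:
    """Best local alignment of query against ref; ``None`` below min_score.

    Both strands are tried when ``strands='both'``; ties prefer '+'.
    Unaligned query ends are reported as soft clips; each clipped end incurs
    ``clip_penalty`` against the reported score.
    """
    candidates = []
    if strands in ("both", "+"):
        candidates.append(("+", query.bases))
    if strands in ("both", "-"):
        candidates.append(("-", revcomp(query.bases)))
    if not candidates:
        raise ValueError(f"strands must be '+', '-' or 'both', got {strands!r}")
    # an exact occurrence attains the maximal possible local score
    # (len * match), so the DP can be skipped; leftmost occurrence matches
    # the smallest-ref_start tie-break
    if params.match > 0:
        for strand, q in candidates:
            if "N" in q:
                continue
            pos = ref.bases.find(q)
            if pos < 0:
                continue
            score = len(q) * params.match
            if score < params.min_score:
                return None
            return AlignmentRecord(
                query_id=query.id, ref_id=ref.id, ref_start=pos,
                strand=strand, cigar=f"{len(q)}M", score=score,
                query_start=0, query_end=len(q),
            )
    aligner = _make_aligner(params)
    best_strand, best_q, best = None, None, 0.0
    for strand, q in candidates:
        s = float(aligner.score(ref.bases, q))
        if s > best:
            best_strand, best_q, best = strand, q, s
    if best_strand is None or best <= 0:
        return None
    alns = aligner.align(ref.bases, best_q)
    aln = alns[0]
    cigar, ref_start, q0, q1 = _coords_to_cigar(aln.coordinates, len(best_q))
    cigar = _left_align_indels(cigar, ref_start, ref.bases, best_q)
    n_clips = sum(1 for n, op in parse_cigar(cigar) if op == "S")
    score = best - params.clip_penalty * n_clips
    if score < params.min_score:
        return None
    return AlignmentRecord(
        query_id=query.id, ref_id=ref.id, ref_start=ref_start,
        strand=best_strand, cigar=cigar, score=score,
        query_start=q0, query_end=q1,
    )


def cigar_indels(rec: AlignmentRecord) -> list[tuple[str, int, int]]:
    """One (type, length, ref_offset) event per I/D run.

    ``ref_offset`` is measured from ``rec.ref_start`` (add ``ref_start`` for
    absolute coordinates).  Soft clips are not events.
    """
    events, roff = [], 0
    for n, op in rec.ops:
        if op == "M":
            roff += n
        elif op == "D":
            events.append(("D", n, roff))
            roff += n
        elif op == "I":
            events.append(("I", n, roff))
    return events


def clipped_segments(
    rec: AlignmentRecord, query: NucSeq
) -> tuple[str, str, str]:
    """Partition the oriented query into (left clip, aligned, right clip).

    For strand '-' the partition is over the reverse-complemented query,
    matching the CIGAR's orientation.
    """
    q = query.bases if rec.strand == "+" else revcomp(query.bases)
    ops = rec.ops
    left = ops[0][0] if ops and ops[0][1] == "S" else 0
    right = ops[-1][0] if len(ops) > 1 and ops[-1][1] == "S" else 0
    return q[:left], q[left:len(q) - right], q[len(q) - right:] if right else ""


def write_sam(records, refs: list[NucSeq], queries: dict[str, NucSeq], path) -> None:
    """Minimal SAM emission (header + 11 mandatory columns, clips kept)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for r in refs:
            fh.write(f"@SQ\tSN:{r.id}\tLN:{len(r)}\n")
        for rec in records:
            q = queries[rec.query_id]
            seq = q.bases if rec.strand == "+" else revcomp(q.bases)
            flag = 0 if rec.strand == "+" else 16
            fh.write(
                f"{rec.query_id}\t{flag}\t{rec.ref_id}\t{rec.ref_start + 1}"
                f"\t60\t{rec.cigar}\t*\t0\t0\t{seq}\t*\n"
            )
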