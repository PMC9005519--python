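"""Nucleotide sequence model, guide placement and cut-site arithmetic.

Coordinates are 0-based, half-open throughout.  ``cut_pos`` always names the
first base 3' of the blunt SpCas9 cut on the reference top strand, regardless
of the strand the guide binds.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC nucleotide codes -> set of concrete bases matched
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}
_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class SequenceError(ValueError):
    """Invalid nucleotide sequence."""


class GuideNotFoundError(LookupError):
    """Protospacer+PAM not found on either strand."""


class AmbiguousGuideError(LookupError):
    """Protospacer+PAM occurs at more than one position."""

    def __init__(self, positions: list[tuple[int, str]]):
        self.positions = positions
        super().__init__(
            "guide matches at multiple positions: "
            + ", ".join(f"{p}({s})" for p, s in positions)
        )


@dataclass(frozen=True)
class NucSeq:
    """An uppercase DNA sequence over {A,C,G,T,N} with a text label."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", self.bases.upper())
        if not self.bases:
            raise SequenceError(f"{self.id!r}: empty sequence")
        bad = set(self.bases) - _ALPHABET
        if bad:
            raise SequenceError(
                f"{self.id!r}: non-ACGTN characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases

    def slice(self, start: int, end: int, id: str | None = None) -> "NucSeq":
        return NucSeq(id or f"{self.id}[{start}:{end}]", self.bases[start:end])


def revcomp(seq: NucSeq | str) -> NucSeq | str:
    """Reverse complement; N maps to N.  Involution and length-preserving."""
    if isinstance(seq, NucSeq):
        return NucSeq(f"rc({seq.id})", seq.bases.translate(_COMPLEMENT)[::-1])
    s = seq.upper()
    bad = set(s) - _ALPHABET
    if bad:
        raise SequenceError(f"non-ACGTN characters {sorted(bad)!r}")
    return s.translate(_COMPLEMENT)[::-1]


def _rc_str(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GuideSpec:
    """A 20-nt SpCas9 protospacer with its PAM pattern and cut offset.

    ``cut_offset`` is counted in nucleotides from the PAM-proximal end of the
    protospacer; the SpCas9 default of 3 yields the canonical blunt cut
    between protospacer positions 16|17.
    """

    protospacer: NucSeq
    pam_pattern: str = "NGG"
    cut_offset: int = 3

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise SequenceError(
                f"protospacer must be 20 nt, got {len(self.protospacer)}"
            )
        if "N" in self.protospacer.bases:
            raise SequenceError("protospacer may not contain N")
        pam = self.pam_pattern.upper()
        if not pam or any(c not in IUPAC for c in pam):
            raise SequenceError(f"invalid PAM pattern {self.pam_pattern!r}")
        object.__setattr__(self, "pam_pattern", pam)
        if not 1 <= self.cut_offset <= 19:
            raise ValueError("cut_offset must be in [1, 19]")

    @property
    def pam_len(self) -> int:
        return len(self.pam_pattern)

    @property
    def site_len(self) -> int:
        return len(self.protospacer) + self.pam_len


def _pattern_to_regex(pattern: str) -> str:
    # IUPAC character classes; an N in the *reference* never matches because
    # the classes only contain concrete bases.
    return "".join(
        c if len(IUPAC[c]) == 1 else "[" + IUPAC[c] + "]" for c in pattern
    )


def scan_sites(seq: NucSeq | str, guide: GuideSpec) -> list[tuple[int, str]]:
    """All exact protospacer+PAM occurrences on either strand.

    Returns ``(top_strand_start_of_site, strand)`` pairs, where the site span
    is ``[start, start + site_len)`` on the top strand.  Overlapping hits are
    all reported.
    """
    bases = seq.bases if isinstance(seq, NucSeq) else seq.upper()
    plus = _pattern_to_regex(guide.protospacer.bases + guide.pam_pattern)
    minus = _pattern_to_regex(
        guide.pam_pattern.translate(_IUPAC_COMPLEMENT)[::-1]
        + _rc_str(guide.protospacer.bases)
    )
    hits: list[tuple[int, str]] = []
    for m in re.finditer(f"(?=({plus}))", bases):
        hits.append((m.start(), "+"))
    for m in re.finditer(f"(?=({minus}))", bases):
        hits.append((m.start(), "-"))
    hits.sort()
    return hits


@dataclass(frozen=True)
class TargetLocus:
    """A reference with a uniquely placed guide and its derived cut site."""

    ref: NucSeq
    guide: GuideSpec
    strand: str
    protospacer_start: int  # top-strand leftmost base of the protospacer
    cut_pos: int            # first base 3' of the blunt cut, top strand
    site_start: int         # top-strand leftmost base of protospacer+PAM span

    @property
    def site_seq(self) -> NucSeq:
        """The protospacer+PAM span as it appears on the top strand."""
        return self.ref.slice(
            self.site_start, self.site_start + self.guide.site_len,
            id=f"{self.ref.id}:site",
        )

    @property
    def target_site(self) -> NucSeq:
        """Protospacer+PAM read 5'->3' on the guide's strand."""
        s = self.site_seq
        return s if self.strand == "+" else revcomp(s)


def place_guide(ref: NucSeq, guide: GuideSpec) -> TargetLocus:
    """Locate the protospacer+PAM on either strand and derive the cut.

    Plus strand: cut ``cut_offset`` nt 5' of the PAM, so with the default
    offset of 3 the blunt cut falls between protospacer positions 16|17 and
    ``cut_pos = protospacer_start + 17``.
    """
    hits = scan_sites(ref, guide)
    if not hits:
        raise GuideNotFoundError(
            f"guide {guide.protospacer.bases} not found in {ref.id!r}"
        )
    if len(hits) > 1:
        raise AmbiguousGuideError(hits)
    start, strand = hits[0]
    plen = len(guide.protospacer)
    if strand == "+":
        ps = start
        cut = ps + plen - guide.cut_offset
    else:
        # site on top strand reads rc(PAM) + rc(protospacer)
        ps = start + guide.pam_len
        cut = start + guide.pam_len + guide.cut_offset
    return TargetLocus(
        ref=ref, guide=guide, strand=strand,
        protospacer_start=ps, cut_pos=cut, site_start=start,
    )


def cut_in_site(guide: GuideSpec) -> int:
    """Cut coordinate inside a 5'->3' protospacer+PAM site string."""
    return len(guide.protospacer) - guide.cut_offset


def cut_in_inverted_site(guide: GuideSpec) -> int:
    """Cut coordinate inside an inverted (revcomp) protospacer+PAM string."""
    return guide.pam_len + guide.cut_offset


def stops_in_three_frames(seq: NucSeq | str) -> tuple[bool, bool, bool]:
    """Whether a STOP codon (TAA/TAG/TGA) starts in each frame 0/1/2."""
    bases = seq.bases if isinstance(seq, NucSeq) else seq.upper()
    if len(bases) < 3:
        raise SequenceError("need at least 3 nt to scan codons")
    found = [False, False, False]
    for i in range(len(bases) - 2):
        if bases[i:i + 3] in STOP_CODONS:
            found[i % 3] = True
    return tuple(found)  # type: ignore[return-value]


def count_stop_codons(seq: NucSeq | str) -> int:
    """Number of positions (any frame, overlaps allowed) starting a STOP."""
    bases = seq.bases if isinstance(seq, NucSeq) else seq.upper()
    return sum(bases[i:i + 3] in STOP_CODONS for i in range(len(bases) - 2))


# ---------------------------------------------------------------------------
# FASTA / BED plumbing

def read_fasta(path) -> list[NucSeq]:
    from Bio import SeqIO

    return [NucSeq(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: Iterable[NucSeq], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.bases), width):
                fh.write(s.bases[i:i + width] + "\n")


def write_bed(loci: Iterable[TargetLocus], path) -> None:
    """BED6 export of guide placements (site span, 0-based half-open)."""
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(
                f"{loc.ref.id}\t{loc.site_start}\t"
                f"{loc.site_start + loc.guide.site_len}\t"
                f"{loc.guide.protospacer.bases}\t0\t{loc.strand}\n"
            )
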