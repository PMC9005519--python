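"""Independent brute-force oracles used to cross-check the implementation."""

from hitikit.align import AlignParams

NEG_INF = float("-inf")


def sw_affine_score(query: str, ref: str, params: AlignParams) -> float:
    """Exhaustive affine-gap Smith-Waterman best local score.

    Three-state dynamic program (match/ins/del) written independently of the
    package's alignment engine; a gap of length k costs
    ``gap_open + k * gap_extend``.
    """
    n, m = len(ref), len(query)
    best = 0.0
    # H: alignment ends in match/mismatch; E: gap in query (deletion from
    # ref consumed); F: gap in ref (insertion of query bases)
    H = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    E = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    F = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            a, b = ref[i - 1], query[j - 1]
            sub = params.match if (a == b and a != "N") else -params.mismatch_penalty
            prev = max(H[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1], 0.0)
            H[i][j] = prev + sub
            E[i][j] = max(
                max(H[i - 1][j], F[i - 1][j]) - params.gap_open - params.gap_extend,
                E[i - 1][j] - params.gap_extend,
            )
            F[i][j] = max(
                max(H[i][j - 1], E[i][j - 1]) - params.gap_open - params.gap_extend,
                F[i][j - 1] - params.gap_extend,
            )
            best = max(best, H[i][j], E[i][j], F[i][j])
    return best


def stops_by_enumeration(seq: str) -> tuple[bool, bool, bool]:
    """Frame coverage of STOP codons by direct enumeration of every index."""
    stops = {"TAA", "TAG", "TGA"}
    frames = [False, False, False]
    for i in range(len(seq)):
        if seq[i:i + 3] in stops:
            frames[i % 3] = True
    return tuple(frames)
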