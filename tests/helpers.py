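"""Independent oracles used by unit and acceptance tests.

Everything here is deliberately written against different primitives than the
production code: alignments are scored by enumerating or memo-recursing over
move sequences, and genomic truth comes from the per-base walk in
``genestruct.fixtures.per_base_truth`` rather than interval arithmetic.
"""

from __future__ import annotations

from functools import lru_cache

from genestruct.genome_model import Contig, GenomicInterval, Transcript

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2.0, -1.0, -10.0, -0.5

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def score_moves(a: str, b: str, moves: str) -> float:
    """Score an explicit alignment given as a move string over {M,X,Y}.

    M consumes one char of each; X consumes only ``a``; Y consumes only ``b``.
    Each maximal run of X (or of Y) is one gap: open + extend·length.
    """
    score = 0.0
    i = j = 0
    prev = ""
    for move in moves:
        if move == "M":
            score += MATCH if a[i] == b[j] else MISMATCH
            i += 1
            j += 1
        else:
            if move != prev:
                score += GAP_OPEN
            score += GAP_EXTEND
            if move == "X":
                i += 1
            else:
                j += 1
        prev = move
    assert i == len(a) and j == len(b), "moves do not consume both sequences"
    return score


def enumerate_alignment_scores(a: str, b: str) -> float:
    """Best score over literally every monotone global alignment (tiny inputs)."""
    best = float("-inf")
    stack = [(0, 0, "")]
    while stack:
        i, j, moves = stack.pop()
        if i == len(a) and j == len(b):
            best = max(best, score_moves(a, b, moves))
            continue
        if i < len(a) and j < len(b):
            stack.append((i + 1, j + 1, moves + "M"))
        if i < len(a):
            stack.append((i + 1, j, moves + "X"))
        if j < len(b):
            stack.append((i, j + 1, moves + "Y"))
    return best


def memo_best_score(a: str, b: str) -> float:
    """Exact optimum over all global alignments, by top-down recursion.

    Independent of the production bottom-up DP (suffix-oriented, recursive,
    state = which gap type is currently open).
    """

    @lru_cache(maxsize=None)
    def go(i: int, j: int, open_gap: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            sub = MATCH if a[i] == b[j] else MISMATCH
            options.append(sub + go(i + 1, j + 1, ""))
        if i < len(a):
            cost = GAP_EXTEND if open_gap == "X" else GAP_OPEN + GAP_EXTEND
            options.append(cost + go(i + 1, j, "X"))
        if j < len(b):
            cost = GAP_EXTEND if open_gap == "Y" else GAP_OPEN + GAP_EXTEND
            options.append(cost + go(i, j + 1, "Y"))
        return max(options)

    result = go(0, 0, "")
    go.cache_clear()
    return result


def blocks_score(a: str, b: str, blocks) -> float:
    """Re-score a block alignment from scratch (checks internal consistency)."""
    score = 0.0
    prev_i = prev_j = 0  # last consumed positions
    for iso_start, canon_start, length in blocks:
        gap_a = iso_start - 1 - prev_i
        gap_b = canon_start - 1 - prev_j
        if gap_a:
            score += GAP_OPEN + GAP_EXTEND * gap_a
        if gap_b:
            score += GAP_OPEN + GAP_EXTEND * gap_b
        for k in range(length):
            score += (
                MATCH
                if a[iso_start - 1 + k] == b[canon_start - 1 + k]
                else MISMATCH
            )
        prev_i = iso_start - 1 + length
        prev_j = canon_start - 1 + length
    gap_a = len(a) - prev_i
    gap_b = len(b) - prev_j
    if gap_a:
        score += GAP_OPEN + GAP_EXTEND * gap_a
    if gap_b:
        score += GAP_OPEN + GAP_EXTEND * gap_b
    return score


def mirror_contig(contig: Contig) -> Contig:
    return Contig(name=contig.name, sequence=revcomp(contig.sequence))


def mirror_transcript(t: Transcript, contig_length: int) -> Transcript:
    """Reverse-complement coordinate relabeling: start' = L − end, strand flips."""
    flip = "-" if t.strand == "+" else "+"

    def mirror(iv: GenomicInterval) -> GenomicInterval:
        return GenomicInterval(
            iv.contig, contig_length - iv.end, contig_length - iv.start, flip
        )

    return Transcript(
        id=t.id,
        gene_id=t.gene_id,
        gene_name=t.gene_name,
        strand=flip,
        exons=tuple(sorted(mirror(iv) for iv in t.exons)),
        cds=tuple(sorted(mirror(iv) for iv in t.cds)),
        phase0=t.phase0,
    )
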