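"""Isoform selection and isoform↔canonical position projection.

A transcript's genomic translation does not always equal the canonical
sequence of its accession; queries therefore route through the matching
splice isoform and an explicit isoform→canonical alignment, expressed as
ungapped blocks.

The aligner is a global affine-gap dynamic program (Gotoh) with fixed,
documented tie-breaking so outputs are bit-reproducible:
match +2, mismatch −1, gap open −10, gap extend −0.5 (a gap of length *k*
costs open + k·extend); traceback preference diagonal > gap-in-canonical >
gap-in-isoform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

from .errors import CoordinateRangeError, FormatError

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

MATCH = 2.0
MISMATCH = -1.0
GAP_OPEN = -10.0
GAP_EXTEND = -0.5

#: minimum global-alignment identity for accepting a non-exact isoform match
DEFAULT_IDENTITY_THRESHOLD = 0.95

NEG_INF = float("-inf")


@dataclass(frozen=True)
class Isoform:
    isoform_id: str
    sequence: str
    is_canonical: bool

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"isoform {self.isoform_id}: empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise FormatError(
                f"isoform {self.isoform_id}: illegal residues {sorted(bad)!r}"
            )


@dataclass(frozen=True)
class IsoformSet:
    """All protein isoforms of one accession; exactly one is canonical."""

    accession: str
    isoforms: tuple[Isoform, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "isoforms", tuple(self.isoforms))
        ids = [iso.isoform_id for iso in self.isoforms]
        if len(set(ids)) != len(ids):
            raise FormatError(f"accession {self.accession}: duplicate isoform ids")
        n_canon = sum(iso.is_canonical for iso in self.isoforms)
        if n_canon != 1:
            raise FormatError(
                f"accession {self.accession}: {n_canon} canonical isoforms, need 1"
            )

    @property
    def canonical(self) -> Isoform:
        return next(iso for iso in self.isoforms if iso.is_canonical)

    def get(self, isoform_id: str) -> Isoform:
        for iso in self.isoforms:
            if iso.isoform_id == isoform_id:
                return iso
        raise KeyError(isoform_id)


@dataclass(frozen=True)
class IsoformAlignment:
    """Ungapped aligned blocks between an isoform and the canonical sequence.

    Blocks are ``(iso_start, canon_start, length)`` with 1-based starts,
    non-overlapping and strictly increasing in both sequences. Mismatches may
    occur inside blocks; gaps only between them.
    """

    isoform_id: str
    accession: str
    blocks: tuple[tuple[int, int, int], ...]
    score: float
    iso_len: int
    canon_len: int


def read_isoform_fasta(path: str | Path) -> list[IsoformSet]:
    """Read the isoform FASTA dialect.

    Header ``>ACCESSION-N |canonical`` marks the canonical isoform of
    ``ACCESSION``; plain ``>ACCESSION-N`` otherwise.
    """
    by_accession: dict[str, list[Isoform]] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        isoform_id = record.id
        if "-" not in isoform_id:
            raise FormatError(
                f"isoform header {isoform_id!r} lacks an '-N' suffix"
            )
        accession = isoform_id.rsplit("-", 1)[0]
        is_canonical = "|canonical" in record.description
        by_accession.setdefault(accession, []).append(
            Isoform(isoform_id, str(record.seq).upper(), is_canonical)
        )
    if not by_accession:
        raise FormatError(f"no FASTA records in {path}")
    return [
        IsoformSet(accession=acc, isoforms=tuple(isos))
        for acc, isos in sorted(by_accession.items())
    ]


def write_isoform_fasta(sets: Sequence[IsoformSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iso_set in sorted(sets, key=lambda s: s.accession):
            for iso in iso_set.isoforms:
                tag = " |canonical" if iso.is_canonical else ""
                fh.write(f">{iso.isoform_id}{tag}\n")
                for i in range(0, len(iso.sequence), 60):
                    fh.write(iso.sequence[i : i + 60] + "\n")


# traceback states
_M, _X, _Y = 0, 1, 2  # aligned / gap-in-canonical (consumes iso) / gap-in-isoform


def _align_path(a: str, b: str) -> tuple[float, list[tuple[int, int]]]:
    """Gotoh global alignment of ``a`` (isoform) vs ``b`` (canonical).

    Returns the optimal score and the list of aligned (i, j) pairs (1-based)
    in order. Tie-breaking is fixed: at equal score prefer state M, then X
    (gap in canonical), then Y (gap in isoform), both when choosing a cell's
    predecessor and when choosing the final state.
    """
    n, m = len(a), len(b)
    # score[s][i][j]: best score ending at (i, j) in state s
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    ptr: dict[tuple[int, int, int], int] = {}
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = GAP_OPEN + GAP_EXTEND * i
        ptr[(_X, i, 0)] = _M if i == 1 else _X
    for j in range(1, m + 1):
        Y[0][j] = GAP_OPEN + GAP_EXTEND * j
        ptr[(_Y, 0, j)] = _M if j == 1 else _Y
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            sub = MATCH if ai == b[j - 1] else MISMATCH
            # state M: consume a[i] and b[j]
            best_state = _M
            best = M[i - 1][j - 1]
            if X[i - 1][j - 1] > best:
                best, best_state = X[i - 1][j - 1], _X
            if Y[i - 1][j - 1] > best:
                best, best_state = Y[i - 1][j - 1], _Y
            M[i][j] = best + sub
            ptr[(_M, i, j)] = best_state
            # state X: consume a[i] only (gap character in canonical)
            open_x = M[i - 1][j] + GAP_OPEN + GAP_EXTEND
            ext_x = X[i - 1][j] + GAP_EXTEND
            if open_x >= ext_x:
                X[i][j] = open_x
                ptr[(_X, i, j)] = _M
            else:
                X[i][j] = ext_x
                ptr[(_X, i, j)] = _X
            # state Y: consume b[j] only (gap character in isoform)
            open_y = M[i][j - 1] + GAP_OPEN + GAP_EXTEND
            ext_y = Y[i][j - 1] + GAP_EXTEND
            if open_y >= ext_y:
                Y[i][j] = open_y
                ptr[(_Y, i, j)] = _M
            else:
                Y[i][j] = ext_y
                ptr[(_Y, i, j)] = _Y
    finals = (M[n][m], X[n][m], Y[n][m])
    state = max((_M, _X, _Y), key=lambda s: (finals[s], -s))
    score = finals[state]
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 or j > 0:
        prev = ptr[(state, i, j)]
        if state == _M:
            pairs.append((i, j))
            i, j = i - 1, j - 1
        elif state == _X:
            i -= 1
        else:
            j -= 1
        state = prev
    pairs.reverse()
    return score, pairs


def _pairs_to_blocks(
    pairs: Sequence[tuple[int, int]]
) -> tuple[tuple[int, int, int], ...]:
    blocks: list[tuple[int, int, int]] = []
    for i, j in pairs:
        if blocks:
            bi, bj, ln = blocks[-1]
            if i == bi + ln and j == bj + ln:
                blocks[-1] = (bi, bj, ln + 1)
                continue
        blocks.append((i, j, 1))
    return tuple(blocks)


def align_isoform_to_canonical(
    iso_seq: str,
    canon_seq: str,
    isoform_id: str = "",
    accession: str = "",
) -> IsoformAlignment:
    """Globally align an isoform to the canonical sequence as ungapped blocks."""
    if not iso_seq or not canon_seq:
        raise FormatError("cannot align empty sequences")
    score, pairs = _align_path(iso_seq, canon_seq)
    return IsoformAlignment(
        isoform_id=isoform_id,
        accession=accession,
        blocks=_pairs_to_blocks(pairs),
        score=score,
        iso_len=len(iso_seq),
        canon_len=len(canon_seq),
    )


def alignment_identity(a: str, b: str) -> float:
    """Fraction of identically aligned residues over max(len(a), len(b))."""
    _, pairs = _align_path(a, b)
    same = sum(1 for i, j in pairs if a[i - 1] == b[j - 1])
    return same / max(len(a), len(b))


def select_isoform(
    translated: str,
    iso: IsoformSet,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> tuple[str, str]:
    """Pick the isoform matching a genomic translation.

    Returns ``(isoform_id, "exact")`` on sequence equality (canonical wins
    ties, then lexicographically smallest id); otherwise the best
    global-alignment identity ≥ ``identity_threshold`` gives
    ``(id, "best_alignment")``; otherwise ``("", "none")``.
    """
    if not translated:
        raise FormatError("empty translation")
    exact = [i for i in iso.isoforms if i.sequence == translated]
    if exact:
        exact.sort(key=lambda i: (not i.is_canonical, i.isoform_id))
        return exact[0].isoform_id, "exact"
    best_id, best_identity = "", -1.0
    for candidate in sorted(
        iso.isoforms, key=lambda i: (not i.is_canonical, i.isoform_id)
    ):
        ident = alignment_identity(translated, candidate.sequence)
        if ident > best_identity:
            best_id, best_identity = candidate.isoform_id, ident
    if best_identity >= identity_threshold:
        return best_id, "best_alignment"
    return "", "none"


def identity_alignment(
    seq: str, isoform_id: str = "", accession: str = ""
) -> IsoformAlignment:
    """The trivial self-alignment of ``seq`` (single full-length block)."""
    return IsoformAlignment(
        isoform_id=isoform_id,
        accession=accession,
        blocks=((1, 1, len(seq)),),
        score=MATCH * len(seq),
        iso_len=len(seq),
        canon_len=len(seq),
    )


def isoform_to_canonical(aln: IsoformAlignment, pos: int) -> int | None:
    """Project a 1-based isoform position to the canonical sequence.

    ``None`` when the position is isoform-specific (falls in a gap).
    """
    if not 1 <= pos <= aln.iso_len:
        raise CoordinateRangeError(
            f"isoform position {pos} outside [1, {aln.iso_len}]"
        )
    for iso_start, canon_start, length in aln.blocks:
        if iso_start <= pos < iso_start + length:
            return canon_start + (pos - iso_start)
    return None


def canonical_to_isoform(aln: IsoformAlignment, pos: int) -> int | None:
    """Inverse of :func:`isoform_to_canonical`."""
    if not 1 <= pos <= aln.canon_len:
        raise CoordinateRangeError(
            f"canonical position {pos} outside [1, {aln.canon_len}]"
        )
    for iso_start, canon_start, length in aln.blocks:
        if canon_start <= pos < canon_start + length:
            return iso_start + (pos - canon_start)
    return None
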