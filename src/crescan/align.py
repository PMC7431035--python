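"""Pairwise local and global alignment with identity statistics.

Exact affine-gap dynamic programming (no heuristic seeding, no banding):
:func:`smith_waterman` for the best local alignment,
:func:`waterman_eggert` for successive declumped suboptimal local
alignments, and :func:`needleman_wunsch` for a global alignment of the
matched intervals.  These stand in for the BLAST/BLAT/Matcher/MLAGAN
steps of a cross-species regulatory-element screen, at desk scale where
exactness is affordable.

Conventions
-----------
* A gap of length L costs ``gap_open + L * gap_extend``.
* ``N`` scores as a mismatch everywhere and never counts as identical.
* Identity = identical columns / total alignment columns (gap columns
  count in the denominator only) — the BLAST "Identities" convention.
* Traceback ties break diagonal > gap-in-b (up) > gap-in-a (left), so
  outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _dp

GAP = "-"

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Window-pair size above which exact DP is refused (memory guard).
MAX_WINDOW = 100_000


def encode(seq: str) -> np.ndarray:
    """Integer-encode a DNA string (A=0, C=1, G=2, T=3, other=N=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScoringScheme:
    """Integer match/mismatch scores with affine gap penalties.

    Defaults mirror EDNAFULL match/mismatch values with Matcher-like gap
    costs.  ``mismatch`` must be <= 0 and the expected per-pair score
    under a uniform background must be negative for E-value theory to
    apply (checked by the significance module, not here).
    """

    match: int = 5
    mismatch: int = -4
    gap_open: int = 16
    gap_extend: int = 4

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0:
            raise ValueError("mismatch score must be <= 0")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")


@dataclass
class LocalAlignment:
    """A scored gapped alignment between two sequence intervals.

    Intervals are 0-based half-open offsets into the *input* sequences.
    ``a_gapped`` and ``b_gapped`` are equal-length strings over
    ``{A,C,G,T,N,-}``; no column is a gap in both rows.
    """

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    a_gapped: str
    b_gapped: str
    score: int
    n_identical: int = 0
    n_columns: int = 0
    identity: float = 0.0
    evalue: Optional[float] = None

    @property
    def a_interval(self) -> tuple[int, int]:
        return (self.a_start, self.a_end)

    @property
    def b_interval(self) -> tuple[int, int]:
        return (self.b_start, self.b_end)

    def rescore(self, scheme: ScoringScheme) -> int:
        """Recompute the score from the gapped strings (audit check)."""
        score = 0
        gap_a = gap_b = False  # separate runs: a-gap next to b-gap is two gaps
        for ca, cb in zip(self.a_gapped, self.b_gapped):
            if ca == GAP:
                score -= scheme.gap_extend if gap_a else scheme.gap_open + scheme.gap_extend
                gap_a, gap_b = True, False
            elif cb == GAP:
                score -= scheme.gap_extend if gap_b else scheme.gap_open + scheme.gap_extend
                gap_a, gap_b = False, True
            else:
                gap_a = gap_b = False
                if ca == cb and ca != "N":
                    score += scheme.match
                else:
                    score += scheme.mismatch
        return score

    def pretty(self, width: int = 60) -> str:
        """Three-line text block (a / match line / b) for logs."""
        out = []
        mid = "".join(
            "|" if ca == cb and ca != "N" and ca != GAP else " "
            for ca, cb in zip(self.a_gapped, self.b_gapped)
        )
        for i in range(0, len(self.a_gapped), width):
            out.append(self.a_gapped[i : i + width])
            out.append(mid[i : i + width])
            out.append(self.b_gapped[i : i + width])
            out.append("")
        return "\n".join(out).rstrip()


def alignment_identity(aln: LocalAlignment) -> tuple[int, int, float]:
    """Count identical columns over total columns of a gapped alignment.

    N never counts as identical; gap columns enter the denominator only.
    Raises ``ValueError`` on unequal gapped lengths.
    """
    a, b = aln.a_gapped, aln.b_gapped
    if len(a) != len(b):
        raise ValueError(
            f"gapped rows differ in length: {len(a)} vs {len(b)}"
        )
    n_columns = len(a)
    n_identical = sum(
        1 for ca, cb in zip(a, b) if ca == cb and ca != GAP and ca != "N"
    )
    identity = n_identical / n_columns if n_columns else 0.0
    return n_identical, n_columns, identity


def _finish(aln: LocalAlignment) -> LocalAlignment:
    ni, nc, ident = alignment_identity(aln)
    aln.n_identical = ni
    aln.n_columns = nc
    aln.identity = ident
    return aln


def _traceback(a, b, bi, bj, ptr, local):
    """Walk the bit-packed pointer matrix from (bi, bj)."""
    ra, rb = [], []
    i, j = bi, bj
    state = "H"
    while True:
        p = ptr[i, j]
        if state == "H":
            src = p & 3
            if src == 0:
                break
            if not local and i == 0 and j == 0:
                break
            if src == 1:
                ra.append(a[i - 1])
                rb.append(b[j - 1])
                i -= 1
                j -= 1
            elif src == 2:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            ra.append(a[i - 1])
            rb.append(GAP)
            i -= 1
            state = "F" if p & 8 else "H"
        else:  # E
            ra.append(GAP)
            rb.append(b[j - 1])
            j -= 1
            state = "E" if p & 4 else "H"
    return i, j, "".join(reversed(ra)), "".join(reversed(rb))


def _check_sizes(a: str, b: str) -> None:
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if len(a) > MAX_WINDOW or len(b) > MAX_WINDOW:
        raise ValueError(
            f"sequence longer than {MAX_WINDOW} bp; split into windows"
        )


def smith_waterman(
    a: str,
    b: str,
    scheme: ScoringScheme = ScoringScheme(),
    _forbidden: Optional[np.ndarray] = None,
) -> LocalAlignment:
    """Best affine-gap local alignment of ``a`` vs ``b``.

    Returns an empty alignment with score 0 when no cell scores
    positively (e.g. all-mismatch inputs).
    """
    _check_sizes(a, b)
    ea, eb = encode(a), encode(b)
    if _forbidden is None:
        _forbidden = np.zeros((len(a), len(b)), dtype=np.uint8)
    best, bi, bj, ptr = _dp.sw_fill(
        ea, eb, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend,
        _forbidden,
    )
    if best <= 0:
        return LocalAlignment(0, 0, 0, 0, "", "", 0)
    ai, aj, ga, gb = _traceback(a, b, bi, bj, ptr, local=True)
    return _finish(LocalAlignment(ai, bi, aj, bj, ga, gb, int(best)))


def waterman_eggert(
    a: str,
    b: str,
    scheme: ScoringScheme = ScoringScheme(),
    k_max: int = 5,
    min_score: int = 1,
) -> list[LocalAlignment]:
    """Up to ``k_max`` declumped local alignments in non-increasing score order.

    After each alignment the residue pairs it used are barred from the
    diagonal transition and the matrix is recomputed, so successive
    alignments share no aligned residue pair (Waterman-Eggert
    declumping, as in EMBOSS Matcher).  Alignments scoring below
    ``min_score`` are dropped.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    _check_sizes(a, b)
    forbidden = np.zeros((len(a), len(b)), dtype=np.uint8)
    out: list[LocalAlignment] = []
    floor = max(int(min_score), 1)
    for _ in range(k_max):
        aln = smith_waterman(a, b, scheme, _forbidden=forbidden)
        if aln.score < floor:
            break
        out.append(aln)
        i, j = aln.a_start, aln.b_start
        for ca, cb in zip(aln.a_gapped, aln.b_gapped):
            if ca != GAP and cb != GAP:
                forbidden[i, j] = 1
                i += 1
                j += 1
            elif ca != GAP:
                i += 1
            else:
                j += 1
    return out


def needleman_wunsch(
    a: str,
    b: str,
    scheme: ScoringScheme = ScoringScheme(),
) -> LocalAlignment:
    """Affine-gap global alignment with penalized end gaps.

    Same statistics fields and tie-breaking as :func:`smith_waterman`;
    intervals always span both full inputs.
    """
    _check_sizes(a, b)
    ea, eb = encode(a), encode(b)
    score, ptr = _dp.nw_fill(
        ea, eb, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend
    )
    _, _, ga, gb = _traceback(a, b, len(a), len(b), ptr, local=False)
    return _finish(LocalAlignment(0, len(a), 0, len(b), ga, gb, int(score)))


def _column_scores(aln: LocalAlignment, scheme: ScoringScheme) -> list[int]:
    """Per-column score contributions (affine gap columns carry open/extend)."""
    out = []
    gap_a = gap_b = False
    for ca, cb in zip(aln.a_gapped, aln.b_gapped):
        if ca == GAP:
            out.append(-(scheme.gap_extend if gap_a else scheme.gap_open + scheme.gap_extend))
            gap_a, gap_b = True, False
        elif cb == GAP:
            out.append(-(scheme.gap_extend if gap_b else scheme.gap_open + scheme.gap_extend))
            gap_a, gap_b = False, True
        else:
            gap_a = gap_b = False
            out.append(scheme.match if (ca == cb and ca != "N") else scheme.mismatch)
    return out


def split_alignment(
    aln: LocalAlignment,
    scheme: ScoringScheme = ScoringScheme(),
    x_drop: int = 100,
) -> list[LocalAlignment]:
    """Split an alignment at internal score drops deeper than ``x_drop``.

    An optimal local alignment will bridge two strong blocks across a
    long weak stretch whenever the total stays positive; seeded
    heuristics (BLAST/BLAT) instead terminate extension once the score
    falls ``x_drop`` below its running maximum, reporting the blocks as
    separate HSPs.  This reproduces that behavior as a post-pass: walk
    the columns, cut wherever the running score drops more than
    ``x_drop`` below the segment peak, then trim each piece to its
    maximal-scoring core.  Pieces are returned in input order with
    intervals and statistics recomputed; a clean alignment comes back
    unchanged (single piece).
    """
    cols = _column_scores(aln, scheme)
    if not cols:
        return [aln]
    pieces: list[tuple[int, int]] = []  # column ranges, half-open
    start = 0
    run = 0
    peak = 0
    peak_pos = -1  # last column included in the peak
    for i, s in enumerate(cols):
        run += s
        if run > peak:
            peak = run
            peak_pos = i
        if peak - run > x_drop:
            if peak_pos >= start:
                pieces.append((start, peak_pos + 1))
            start = i + 1
            run = 0
            peak = 0
            peak_pos = i  # empty until a positive column arrives
    if peak_pos >= start:
        pieces.append((start, peak_pos + 1))
    if len(pieces) == 1 and pieces[0] == (0, len(cols)):
        return [aln]
    out = []
    for cs, ce in pieces:
        piece = _slice_alignment(aln, cols, cs, ce, scheme)
        if piece is not None:
            out.append(piece)
    return out or [aln]


def _slice_alignment(
    aln: LocalAlignment, cols: list[int], cs: int, ce: int, scheme: ScoringScheme
) -> Optional[LocalAlignment]:
    """Extract the maximal-scoring core of columns [cs, ce), re-scored."""
    # Kadane over the piece: trims weak ends left by the x-drop cut
    cur, cur_start = 0, cs
    best, bs, be = None, cs, ce
    for i in range(cs, ce):
        if cur <= 0:
            cur, cur_start = 0, i
        cur += cols[i]
        if best is None or cur > best:
            best, bs, be = cur, cur_start, i + 1
    if best is None or best <= 0:
        return None
    a_off = sum(1 for c in aln.a_gapped[:bs] if c != GAP)
    b_off = sum(1 for c in aln.b_gapped[:bs] if c != GAP)
    ga = aln.a_gapped[bs:be]
    gb = aln.b_gapped[bs:be]
    a_len = sum(1 for c in ga if c != GAP)
    b_len = sum(1 for c in gb if c != GAP)
    piece = LocalAlignment(
        aln.a_start + a_off, aln.a_start + a_off + a_len,
        aln.b_start + b_off, aln.b_start + b_off + b_len,
        ga, gb, 0,
    )
    piece.score = piece.rescore(scheme)
    return _finish(piece)


def best_local_score(a: str, b: str, scheme: ScoringScheme = ScoringScheme()) -> int:
    """Score-only Smith-Waterman (used by the E-value calibration)."""
    _check_sizes(a, b)
    return int(
        _dp.sw_score_only(
            encode(a), encode(b),
            scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend,
        )
    )
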