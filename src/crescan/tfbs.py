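"""PWM construction, exact-p-value scanning, and conserved-stretch mapping.

A position frequency matrix (raw JASPAR counts) becomes a log-odds PWM
against an i.i.d. background; the full null distribution of the PWM
score is computed exactly by column-wise convolution on a fixed score
grid, so every hit carries an exact p-value P(score >= s) rather than a
relative-score heuristic.  Hits on refined cross-species alignments are
flagged as inside or outside the conserved stretches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .align import GAP, LocalAlignment
from .significance import BackgroundModel

#: score grid granularity (nats); scores are rounded half-even onto it
GRID = 1e-3
MAX_WIDTH = 25


@dataclass
class PWM:
    """Log-odds motif matrix (nats) with background and score distribution.

    Column probabilities are ``(count + pseudocount * p_bg) /
    (total + pseudocount)``; log-odds are ``log(p / p_bg)``.  Use
    :meth:`to_bits` only for display.
    """

    log_odds: np.ndarray  # 4 x width, nats
    background: BackgroundModel
    pseudocount: float
    id: str = "pwm"

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        if self.log_odds.ndim != 2 or self.log_odds.shape[0] != 4 or self.log_odds.shape[1] < 1:
            raise ValueError("log_odds must be a 4 x width matrix with width >= 1")

    @property
    def width(self) -> int:
        return self.log_odds.shape[1]

    def to_bits(self) -> np.ndarray:
        return self.log_odds / math.log(2.0)

    def reverse_complement(self) -> "PWM":
        return replace(self, log_odds=self.log_odds[::-1, ::-1].copy(), id=self.id + "_rc")

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.log_odds.argmax(axis=0))


@dataclass
class TFBSHit:
    """One PWM match: position/strand in the scanned sequence, score, p-value.

    ``position`` is the forward-strand offset of the match window;
    ``width`` is the PWM width, so the window is
    ``[position, position + width)`` regardless of strand.
    """

    pwm_id: str
    position: int
    strand: str
    score: float
    pvalue: float
    width: int = 0
    inside_conserved: Optional[bool] = None


def pfm_to_pwm(
    counts: np.ndarray,
    background: BackgroundModel = BackgroundModel(),
    pseudocount: float = 0.01,
    pwm_id: str = "pwm",
) -> PWM:
    """Raw count matrix -> log-odds PWM (nats).

    With ``pseudocount`` 0 an all-zero column is an error; larger
    pseudocounts shrink log-odds monotonically toward 0.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
        raise ValueError("counts must be a 4 x width matrix with width >= 1")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    totals = counts.sum(axis=0)
    if pseudocount == 0 and (totals == 0).any():
        raise ValueError("all-zero PFM column with pseudocount 0")
    bg = background.as_array()[:, None]
    probs = (counts + pseudocount * bg) / (totals + pseudocount)
    with np.errstate(divide="ignore"):
        log_odds = np.log(probs) - np.log(bg)
    return PWM(log_odds=log_odds, background=background, pseudocount=pseudocount, id=pwm_id)


@dataclass
class ScoreDistribution:
    """Exact discrete null distribution of a PWM score on the GRID lattice."""

    offsets: np.ndarray  # integer grid indices
    probs: np.ndarray

    def pvalue(self, score: float) -> float:
        """P(score' >= score) under the background, on the grid."""
        target = _to_grid(score)
        return float(self.probs[self.offsets >= target].sum())

    def pvalue_grid(self, grid_score: int) -> float:
        """P(score' >= grid_score) for an integer grid score.

        Exact when ``grid_score`` is the sum of the same per-column
        rounded scores the distribution was built from.
        """
        return float(self.probs[self.offsets >= grid_score].sum())

    def survival(self) -> tuple[np.ndarray, np.ndarray]:
        sf = np.cumsum(self.probs[::-1])[::-1]
        return self.offsets * GRID, sf


def _to_grid(score: float) -> int:
    """Round a score in nats onto the integer grid, half-even."""
    return int(np.rint(score / GRID))


def exact_score_distribution(
    pwm: PWM, background: Optional[BackgroundModel] = None
) -> ScoreDistribution:
    """Null score distribution by column-wise convolution on the score grid.

    Probabilities sum to 1 within 1e-9.  Widths above 25 are refused
    (the grid support grows linearly in width but this guards against
    pathological matrices).
    """
    if pwm.width > MAX_WIDTH:
        raise ValueError(f"PWM width {pwm.width} > {MAX_WIDTH}: grid would blow up")
    bg = (background or pwm.background).as_array()
    grid_scores = np.rint(pwm.log_odds / GRID).astype(np.int64)  # 4 x width
    lo = int(grid_scores.min(axis=0).sum())
    hi = int(grid_scores.max(axis=0).sum())
    dist = np.zeros(hi - lo + 1)
    # start with column 0
    cur_lo = 0
    cur = np.array([1.0])
    for col in range(pwm.width):
        col_scores = grid_scores[:, col]
        new_lo = cur_lo + int(col_scores.min())
        new_hi = cur_lo + len(cur) - 1 + int(col_scores.max())
        new = np.zeros(new_hi - new_lo + 1)
        for base in range(4):
            s = int(col_scores[base])
            start = cur_lo + s - new_lo
            new[start : start + len(cur)] += bg[base] * cur
        cur, cur_lo = new, new_lo
    total = cur.sum()
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(f"distribution mass {total} != 1")
    nz = cur > 0
    offsets = np.arange(cur_lo, cur_lo + len(cur))[nz]
    return ScoreDistribution(offsets=offsets, probs=cur[nz])


_CODE = {b: i for i, b in enumerate("ACGT")}


def scan(
    seq: str,
    pwm: PWM,
    pvalue_threshold: float = 1e-4,
    distribution: Optional[ScoreDistribution] = None,
    relative_threshold: Optional[float] = None,
) -> list[TFBSHit]:
    """Scan both strands of ``seq``; emit hits with p-value <= threshold.

    Any N inside a window disqualifies that window.  ``position`` is the
    forward-strand offset of the window for both strands.  When
    ``relative_threshold`` is given (e.g. 0.8), hits are instead called
    at score >= relative_threshold * max_score (common JASPAR usage) and
    p-values are still reported.
    """
    w = pwm.width
    if len(seq) < w:
        raise ValueError(f"sequence length {len(seq)} < PWM width {w}")
    dist = distribution or exact_score_distribution(pwm)
    if relative_threshold is not None:
        score_cut = relative_threshold * pwm.max_score()
    else:
        score_cut = None
    codes = np.array([_CODE.get(c, -1) for c in seq], dtype=np.int64)
    n = len(seq)
    hits: list[TFBSHit] = []
    lo_fwd = pwm.log_odds
    lo_rev = pwm.reverse_complement().log_odds
    for strand, lo_mat in (("+", lo_fwd), ("-", lo_rev)):
        # score on the same rounded grid the null distribution uses, so
        # p-values are exact by construction (p of the max score is the
        # probability of the consensus word, never 0)
        grid_mat = np.rint(lo_mat / GRID).astype(np.int64)
        cols = np.arange(w)
        for i in range(n - w + 1):
            window = codes[i : i + w]
            if (window < 0).any():
                continue
            score = float(lo_mat[window, cols].sum())
            p = dist.pvalue_grid(int(grid_mat[window, cols].sum()))
            if score_cut is not None:
                keep = score >= score_cut
            else:
                keep = p <= pvalue_threshold
            if keep:
                hits.append(TFBSHit(pwm.id, i, strand, score, p, width=w))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def smoothed_column_identity(aln: LocalAlignment, window: int = 21) -> np.ndarray:
    """Per-column identity of a gapped alignment, moving-average smoothed."""
    ident = np.array(
        [1.0 if (a == b and a != GAP and a != "N") else 0.0
         for a, b in zip(aln.a_gapped, aln.b_gapped)]
    )
    if len(ident) == 0:
        return ident
    half = window // 2
    padded = np.pad(ident, half, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def map_to_conserved(
    hits: list[TFBSHit],
    refined_alignment: LocalAlignment,
    min_identity: float = 0.62,
    smooth_window: int = 21,
) -> list[TFBSHit]:
    """Set ``inside_conserved`` on hits scanned from the refined query sequence.

    A hit is inside a conserved stretch iff its whole window maps to
    alignment columns whose smoothed local identity is >= ``min_identity``.
    Hit positions are offsets into the *query* (ungapped species-A side)
    of the refined alignment; hits outside the aligned interval are false.
    """
    smooth = smoothed_column_identity(refined_alignment, smooth_window)
    col_of_query = [
        col for col, ca in enumerate(refined_alignment.a_gapped) if ca != GAP
    ]
    n_query = len(col_of_query)
    for hit in hits:
        if hit.width <= 0:
            raise ValueError(f"hit at {hit.position}: width not set")
        if hit.position < 0 or hit.position + hit.width > n_query:
            hit.inside_conserved = False
            continue
        cols = col_of_query[hit.position : hit.position + hit.width]
        lo, hi = cols[0], cols[-1]
        hit.inside_conserved = bool((smooth[lo : hi + 1] >= min_identity).all())
    return hits
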