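"""The cross-species conserved CRE screen.

Candidate conserved cis-regulatory elements are found by declumped
local alignment inside homolog-anchored genomic windows, then pushed
through a four-criterion classifier:

1. homolog linkage — the match lies in windows around the same
   homologous gene pair (guaranteed by the window construction);
2. a minimum of 62% sequence identity over at least 55 alignment
   columns with E-value at most 0.1;
3. not an unannotated protein sequence — no exon overlap, and
   optionally no open reading frame of >= 300 bp inside the candidate;
4. not a repetitive element — less than half the candidate span flagged
   as low-complexity or tandem repeat.

Candidates passing all four are checked for reciprocal uniqueness (the
query searched back against the whole partner sequence set must hit
only the homologous gene's window) and refined by global alignment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .align import (
    LocalAlignment,
    ScoringScheme,
    needleman_wunsch,
    revcomp,
    split_alignment,
    waterman_eggert,
)
from .io_formats import AnnotationSet, GenomeLocus, HomologyTable
from .significance import KarlinParams, evalue, score_for_evalue

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CriteriaThresholds:
    """Classifier cutoffs.

    ``min_identity`` and ``min_length`` are inclusive bounds on the
    gapped alignment (identity = identities / columns); ``max_evalue``
    is the highest acceptable E-value; ``flank`` sizes the homolog
    search windows.
    """

    min_identity: float = 0.62
    min_length: int = 55
    max_evalue: float = 0.1
    flank: int = 20_000
    max_exon_overlap: int = 0
    orf_veto: bool = False
    min_orf_length: int = 300
    repeat_span_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.min_identity < 1.0):
            raise ValueError("min_identity must be in (0, 1)")
        if self.min_length <= 0 or self.max_evalue <= 0 or self.flank < 0:
            raise ValueError("thresholds must be positive")


@dataclass
class Criteria:
    """Per-criterion pass/fail evidence for one candidate."""

    homolog_linked: bool
    identity_length_evalue: bool
    noncoding: bool
    nonrepetitive: bool

    def all_pass(self) -> bool:
        return (
            self.homolog_linked
            and self.identity_length_evalue
            and self.noncoding
            and self.nonrepetitive
        )

    def failing(self) -> list[str]:
        return [k for k, v in vars(self).items() if not v]


@dataclass
class Window:
    """A search window inside one locus, anchored on a gene."""

    locus: GenomeLocus
    start: int
    end: int
    gene: str

    @property
    def seq(self) -> str:
        return self.locus.subseq(self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class CandidateCRE:
    """A cross-species sequence match with its classification evidence.

    Coordinates are locus-local, 0-based half-open, on the + strand;
    ``hit_strand`` records which strand of species B the match lies on.
    ``verdict`` is the conjunction of the four criteria and (when
    tested) reciprocal uniqueness.
    """

    id: str
    query_chrom: str
    query_start: int
    query_end: int
    hit_chrom: str
    hit_start: int
    hit_end: int
    hit_strand: str
    alignment: LocalAlignment
    linked_gene_pair: tuple[str, str] = ("none", "none")
    criteria: Optional[Criteria] = None
    reciprocal_unique: Optional[bool] = None  # None = untested
    refined_identity: Optional[float] = None
    refined_alignment: Optional[LocalAlignment] = None
    tfbs_hits: Optional[int] = None

    @property
    def verdict(self) -> bool:
        if self.criteria is None or not self.criteria.all_pass():
            return False
        if self.reciprocal_unique is False:
            return False
        return True

    @property
    def query_seq_cached(self) -> Optional[str]:
        return getattr(self, "_query_seq", None)


def homolog_windows(
    locus_a: GenomeLocus,
    locus_b: GenomeLocus,
    annotations_a: AnnotationSet,
    annotations_b: AnnotationSet,
    homology: HomologyTable,
    flank: int = 20_000,
    include_intergenic: bool = False,
) -> list[tuple[Window, Window]]:
    """One window pair per (gene_A, gene_B) homolog combination.

    Windows are the gene span +/- ``flank``, clipped to locus bounds.
    With ``include_intergenic`` the species-A window of every pair is
    widened to also cover the span between consecutive species-A genes
    named in the homology table (for tandem paralog pairs).
    Unresolvable gene ids raise ``ValueError``.
    """
    homology.validate(annotations_a, annotations_b)
    genes_a = {iv.name: iv for iv in annotations_a.of_kind("gene")}
    genes_b = {iv.name: iv for iv in annotations_b.of_kind("gene")}
    a_named = [genes_a[g] for g, _p in homology.rows]
    pairs = []
    for gene_a, partners in homology.rows:
        iv_a = genes_a[gene_a]
        a_start = max(0, iv_a.start - flank)
        a_end = min(len(locus_a), iv_a.end + flank)
        if include_intergenic and len(a_named) > 1:
            lo = min(iv.start for iv in a_named)
            hi = max(iv.end for iv in a_named)
            a_start = min(a_start, max(0, lo - flank))
            a_end = max(a_end, min(len(locus_a), hi + flank))
        for gene_b in partners:
            iv_b = genes_b[gene_b]
            b_start = max(0, iv_b.start - flank)
            b_end = min(len(locus_b), iv_b.end + flank)
            pairs.append(
                (
                    Window(locus_a, a_start, a_end, gene_a),
                    Window(locus_b, b_start, b_end, gene_b),
                )
            )
    return pairs


def candidate_search(
    window_a: Window,
    window_b: Window,
    scheme: ScoringScheme = ScoringScheme(),
    params: Optional[KarlinParams] = None,
    k_max: int = 5,
    min_score: Optional[int] = None,
    max_evalue_for_min_score: float = 10.0,
    x_drop: int = 100,
) -> list[CandidateCRE]:
    """Declumped local alignments of a homolog window pair, both strands.

    Each alignment becomes a :class:`CandidateCRE` (criteria unfilled)
    with its E-value attached from ``params``.  The species-B window is
    searched forward and reverse-complemented; hits from both strands
    are pooled in non-increasing score order, capped at ``k_max``.
    ``min_score`` defaults to the score whose E-value equals
    ``max_evalue_for_min_score`` (a permissive pre-filter).

    Every alignment is passed through an ``x_drop`` split first, so two
    strong conserved blocks bridged across a long weak stretch are
    reported as separate candidates, matching the HSP semantics of
    seeded search tools.
    """
    seq_a, seq_b = window_a.seq, window_b.seq
    if not seq_a or not seq_b:
        raise ValueError("search windows must be non-empty")
    m, n = len(seq_a), len(seq_b)
    n_space = 2 * n  # both strands of B are searched
    if min_score is None:
        if params is not None:
            min_score = max(
                1, math.ceil(score_for_evalue(max_evalue_for_min_score, m, n_space, params))
            )
        else:
            min_score = 1
    hits: list[tuple[LocalAlignment, str]] = []
    rc_b = revcomp(seq_b)
    for strand, sb in (("+", seq_b), ("-", rc_b)):
        for aln in waterman_eggert(seq_a, sb, scheme, k_max=k_max, min_score=min_score):
            for piece in split_alignment(aln, scheme, x_drop=x_drop):
                if piece.score >= min_score:
                    hits.append((piece, strand))
    hits.sort(key=lambda h: (-h[0].score, h[0].a_start, h[1]))
    out = []
    for rank, (aln, strand) in enumerate(hits[:k_max]):
        if params is not None:
            aln.evalue = evalue(aln.score, m, n_space, params)
        if strand == "+":
            b_start, b_end = aln.b_start, aln.b_end
        else:  # map reverse-strand coordinates back to the forward strand
            b_start, b_end = n - aln.b_end, n - aln.b_start
        cand = CandidateCRE(
            id=f"{window_a.gene}~{window_b.gene}~{rank}",
            query_chrom=window_a.locus.chrom,
            query_start=window_a.start + aln.a_start,
            query_end=window_a.start + aln.a_end,
            hit_chrom=window_b.locus.chrom,
            hit_start=window_b.start + b_start,
            hit_end=window_b.start + b_end,
            hit_strand=strand,
            alignment=aln,
            linked_gene_pair=(window_a.gene, window_b.gene),
        )
        cand._query_seq = seq_a[aln.a_start : aln.a_end]
        cand._hit_seq = rc_b[aln.b_start : aln.b_end] if strand == "-" else seq_b[aln.b_start : aln.b_end]
        out.append(cand)
    return out


def find_orfs(seq: str, min_length: int = 300) -> list[tuple[int, int, str]]:
    """Open reading frames (ATG..stop) of >= ``min_length`` nt, both strands.

    Returns (start, end, strand) in forward-strand coordinates.
    """
    stops = {"TAA", "TAG", "TGA"}
    out = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        n = len(s)
        for frame in range(3):
            start = None
            for i in range(frame, n - 2, 3):
                codon = s[i : i + 3]
                if start is None and codon == "ATG":
                    start = i
                elif start is not None and codon in stops:
                    if i + 3 - start >= min_length:
                        if strand == "+":
                            out.append((start, i + 3, "+"))
                        else:
                            out.append((n - (i + 3), n - start, "-"))
                    start = None
    return out


def mask_coding(
    candidate: CandidateCRE,
    annotations_a: AnnotationSet,
    thresholds: CriteriaThresholds = CriteriaThresholds(),
    query_seq: Optional[str] = None,
) -> bool:
    """True iff the candidate's query interval is non-coding.

    Fails when exon overlap exceeds ``max_exon_overlap`` (default 0 bp:
    a single overlapping base vetoes).  When ``orf_veto`` is enabled, or
    when no exon annotation exists at all, an ORF of
    >= ``min_orf_length`` bp inside the candidate also vetoes.
    """
    exons = [iv for iv in annotations_a.of_kind("exon") if iv.chrom == candidate.query_chrom]
    overlap = sum(iv.overlap(candidate.query_start, candidate.query_end) for iv in exons)
    if overlap > thresholds.max_exon_overlap:
        return False
    if thresholds.orf_veto or not exons:
        seq = query_seq if query_seq is not None else candidate.query_seq_cached
        if seq and find_orfs(seq, thresholds.min_orf_length):
            return False
    return True


def shannon_entropy(window_counts: np.ndarray) -> float:
    """Base-composition Shannon entropy (bits) of one window."""
    total = window_counts.sum()
    if total == 0:
        return 0.0
    p = window_counts[window_counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def detect_repeats(
    seq: str,
    window: int = 16,
    entropy_threshold: float = 1.0,
    max_period: int = 6,
    min_copies: int = 4,
    min_span: int = 12,
) -> list[tuple[int, int]]:
    """Low-complexity and tandem-repeat intervals of ``seq``, merged.

    Low complexity: sliding windows whose base-composition entropy falls
    below ``entropy_threshold`` bits.  Tandem: maximal runs where a unit
    of period <= ``max_period`` repeats >= ``min_copies`` times over at
    least ``min_span`` bp.  Adjacent or overlapping intervals are merged.
    """
    if window < 16:
        raise ValueError("entropy window must be >= 16 bp")
    n = len(seq)
    flagged: list[tuple[int, int]] = []
    if n >= window:
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        counts = np.zeros((n - window + 1, 4), dtype=np.int32)
        for k, base in enumerate(b"ACGT"):
            isb = (codes == base).astype(np.int32)
            cs = np.concatenate([[0], np.cumsum(isb)])
            counts[:, k] = cs[window:] - cs[:-window]
        with np.errstate(divide="ignore", invalid="ignore"):
            p = counts / window
            ent = -np.nansum(np.where(p > 0, p * np.log2(p), 0.0), axis=1)
        for i in np.nonzero(ent < entropy_threshold)[0]:
            flagged.append((int(i), int(i) + window))
    # tandem repeats: seq[i] == seq[i + p] runs
    for p in range(1, max_period + 1):
        i = 0
        while i < n - p:
            if seq[i] == seq[i + p]:
                j = i
                while j < n - p and seq[j] == seq[j + p]:
                    j += 1
                span = (j - i) + p  # total repeated region
                if span >= max(min_copies * p, min_span):
                    flagged.append((i, i + span))
                i = j + 1
            else:
                i += 1
    if not flagged:
        return []
    flagged.sort()
    merged = [list(flagged[0])]
    for s, e in flagged[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def apply_criteria(
    candidate: CandidateCRE,
    thresholds: CriteriaThresholds,
    annotations_a: AnnotationSet,
    window_seq_a: Optional[str] = None,
    window_start_a: int = 0,
) -> CandidateCRE:
    """Fill the four criteria on a candidate (reciprocal stays untested).

    Criterion 2 is identity >= min_identity AND columns >= min_length
    AND E-value <= max_evalue, all on the gapped local alignment.
    Criterion 4 fails when more than ``repeat_span_fraction`` of the
    candidate span is repeat-flagged.  Every failure is logged with the
    failing criterion named.
    """
    aln = candidate.alignment
    if aln.evalue is None:
        raise ValueError(f"candidate {candidate.id}: E-value not set; attach params first")
    homolog_linked = candidate.linked_gene_pair[0] != "none"
    crit2 = (
        aln.identity >= thresholds.min_identity
        and aln.n_columns >= thresholds.min_length
        and aln.evalue <= thresholds.max_evalue
    )
    noncoding = mask_coding(candidate, annotations_a, thresholds)
    if window_seq_a is not None:
        repeats = detect_repeats(window_seq_a)
        repeats = [(s + window_start_a, e + window_start_a) for s, e in repeats]
    else:
        qseq = candidate.query_seq_cached or ""
        repeats = [
            (s + candidate.query_start, e + candidate.query_start)
            for s, e in (detect_repeats(qseq) if len(qseq) >= 16 else [])
        ]
    frac = _repeat_fraction(candidate.query_start, candidate.query_end, repeats)
    nonrepetitive = frac <= thresholds.repeat_span_fraction
    candidate.criteria = Criteria(
        homolog_linked=homolog_linked,
        identity_length_evalue=crit2,
        noncoding=noncoding,
        nonrepetitive=nonrepetitive,
    )
    if not candidate.criteria.all_pass():
        logger.info(
            "candidate %s fails criteria: %s",
            candidate.id,
            ",".join(candidate.criteria.failing()),
        )
    return candidate


def _repeat_fraction(start: int, end: int, repeats: list[tuple[int, int]]) -> float:
    span = end - start
    if span <= 0:
        return 0.0
    covered = sum(max(0, min(e, end) - max(s, start)) for s, e in repeats)
    return covered / span


def reciprocal_uniqueness(
    candidate: CandidateCRE,
    loci_b: list[GenomeLocus],
    homolog_window_b: Window,
    scheme: ScoringScheme = ScoringScheme(),
    params: Optional[KarlinParams] = None,
    thresholds: CriteriaThresholds = CriteriaThresholds(),
    tile: int = 2000,
    k_max: int = 10,
) -> bool:
    """True iff every criterion-2-passing hit of the query against all of
    species B lies inside the homologous gene's window.

    The query sequence is searched with the same declumped aligner over
    overlapping tiles of every species-B locus, both strands.  A
    candidate with no criterion-passing hit anywhere (not even its own)
    is vacuously unique and logged as a warning.
    """
    query = candidate.query_seq_cached
    if query is None:
        raise ValueError(f"candidate {candidate.id}: query sequence not cached")
    qlen = len(query)
    overlap = qlen + 10
    any_hit = False
    for locus in loci_b:
        n = len(locus)
        step = max(tile - overlap, 1)
        for tstart in range(0, max(n - overlap, 1), step):
            tend = min(n, tstart + tile)
            tseq = locus.subseq(tstart, tend)
            if len(tseq) < thresholds.min_length:
                continue
            for strand, s in (("+", tseq), ("-", revcomp(tseq))):
                alns = waterman_eggert(query, s, scheme, k_max=k_max, min_score=1)
                for aln in alns:
                    if params is not None:
                        aln.evalue = evalue(aln.score, qlen, 2 * n, params)
                    else:
                        aln.evalue = 0.0
                    passes = (
                        aln.identity >= thresholds.min_identity
                        and aln.n_columns >= thresholds.min_length
                        and aln.evalue <= thresholds.max_evalue
                    )
                    if not passes:
                        continue
                    any_hit = True
                    if strand == "+":
                        h_start, h_end = tstart + aln.b_start, tstart + aln.b_end
                    else:
                        h_start = tstart + (len(tseq) - aln.b_end)
                        h_end = tstart + (len(tseq) - aln.b_start)
                    inside = (
                        locus.chrom == homolog_window_b.locus.chrom
                        and h_start >= homolog_window_b.start
                        and h_end <= homolog_window_b.end
                    )
                    if not inside:
                        logger.info(
                            "candidate %s: off-target hit %s:%d-%d (%s)",
                            candidate.id, locus.chrom, h_start, h_end, strand,
                        )
                        return False
            if tend == n:
                break
    if not any_hit:
        logger.warning(
            "candidate %s: no criterion-passing hit anywhere in species B; "
            "reciprocal uniqueness true by vacuity", candidate.id,
        )
    return True


def refine(candidate: CandidateCRE, scheme: ScoringScheme = ScoringScheme()) -> float:
    """Global alignment of the matched intervals; records refined identity.

    The refined alignment (block structure) is retained on the candidate
    for TFBS mapping.  Refinement never changes the verdict.
    """
    query = candidate.query_seq_cached
    hit = getattr(candidate, "_hit_seq", None)
    if query is None or hit is None:
        raise ValueError(f"candidate {candidate.id}: interval sequences not cached")
    aln = needleman_wunsch(query, hit, scheme)
    candidate.refined_alignment = aln
    candidate.refined_identity = aln.identity
    return aln.identity
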