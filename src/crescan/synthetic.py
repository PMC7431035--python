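"""Synthetic ortholog locus pairs with planted ground truth.

Generates a pair of single-"chromosome" loci for two nominal species
that share a central homologous gene (with coding exons written as real
ORFs), one or more conserved noncoding elements at a controlled percent
identity, low-complexity or tandem repeats, and PWM motif instances
planted inside the conserved elements.  Every planted feature is
returned with exact coordinates in a :class:`TruthSet`, so recovery and
false-positive rates of the conservation screen can be measured without
any genome download.

Divergence model: uniform (Jukes-Cantor-like) substitution to one of
the three other bases, substitution count drawn as
Binomial(length, 1 - target_identity); indels of length 1-3 (truncated
geometric) at ``indel_rate`` events per substituted site.  The realized
identity of each planted element is measured afterwards by global
alignment of the two copies — the classifier consumes realized, not
nominal, identity.  Background sequence is i.i.d. uniform {A,C,G,T},
a known null for false-positive measurement.  There is no rate
heterogeneity, CpG effect, or rearrangement: this emulates the
identity/length/E-value axes of a real comparison, not its genomic
texture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .align import ScoringScheme, needleman_wunsch
from .io_formats import AnnotationSet, GenomeLocus, HomologyTable, Interval

_BASES = np.array(list("ACGT"))
_STOP = {"TAA", "TAG", "TGA"}
_SENSE = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP and a + b + c != "ATG"
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic ortholog locus pair.

    ``target_identity`` applies to the planted conserved elements,
    ``background_identity`` to everything else (0 means the two
    backgrounds are independent); both are global-alignment identities.
    """

    locus_length: int = 3000
    n_conserved_elements: int = 1
    element_length: int = 150
    target_identity: float = 0.85
    background_identity: float = 0.0
    indel_rate: float = 0.05
    n_repeats: int = 1
    repeat_kind: str = "tandem"  # homopolymer | tandem
    repeat_length: int = 60
    n_exons: int = 2
    exon_length: int = 120
    intron_length: int = 100
    #: minimum background spacer between planted features; chosen above
    #: the spacer length a local alignment can profitably bridge at the
    #: default scoring (x-drop split threshold / expected bridge cost)
    min_feature_spacing: int = 200
    planted_motifs: tuple[tuple[str, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.target_identity <= 1.0):
            raise ValueError("target_identity must be in (0, 1]")
        if not (0.0 <= self.background_identity < 1.0):
            raise ValueError("background_identity must be in [0, 1)")
        if self.target_identity <= self.background_identity:
            raise ValueError("target_identity must exceed background_identity")
        if self.repeat_kind not in ("homopolymer", "tandem"):
            raise ValueError("repeat_kind must be homopolymer or tandem")
        if self.n_exons > 0 and self.exon_length % 3 != 0:
            raise ValueError("exon_length must be a multiple of 3 (exons carry ORFs)")

    @classmethod
    def from_config(cls, path) -> "SyntheticSpec":
        """Read a flat key=value config file (unknown keys are errors)."""
        kwargs = {}
        valid = set(cls.__dataclass_fields__)
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#")[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, val = (x.strip() for x in line.split("=", 1))
                if key not in valid:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                f = cls.__dataclass_fields__[key]
                if f.type in ("int",):
                    kwargs[key] = int(val)
                elif f.type in ("float",):
                    kwargs[key] = float(val)
                else:
                    kwargs[key] = val
        return cls(**kwargs)


@dataclass
class TruthElement:
    """One planted conserved element, with coordinates in both loci."""

    pair_id: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    realized_identity: float


@dataclass
class TruthMotif:
    """One planted PWM instance (coordinates in species A)."""

    pwm_id: str
    a_start: int
    a_end: int
    strand: str


@dataclass
class TruthSet:
    """Exact coordinates of everything the generator planted."""

    annotations_a: AnnotationSet = field(default_factory=AnnotationSet)
    annotations_b: AnnotationSet = field(default_factory=AnnotationSet)
    elements: list[TruthElement] = field(default_factory=list)
    motifs: list[TruthMotif] = field(default_factory=list)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=length))


def evolve_sequence(
    seq: str, target_identity: float, indel_rate: float, seed: int
) -> str:
    """Diverge ``seq`` so expected global-alignment identity is ``target_identity``.

    Substitution positions are uniform without replacement, each base
    replaced by one of the three others; the substitution count is
    Binomial(L, 1 - target_identity).  Indel events (insertion or
    deletion, length 1-3 truncated geometric) occur at ``indel_rate``
    events per substituted site.  Deterministic given ``seed``.
    """
    if not (0.0 < target_identity <= 1.0):
        raise ValueError("target_identity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if target_identity == 1.0 and indel_rate == 0.0:
        return seq
    chars = np.array(list(seq))
    n = len(chars)
    n_sub = rng.binomial(n, 1.0 - target_identity)
    if n_sub > 0:
        pos = rng.choice(n, size=n_sub, replace=False)
        for p in pos:
            others = [b for b in "ACGTN" if b != chars[p] and b != "N"][:3]
            chars[p] = others[rng.integers(len(others))]
    out = chars.tolist()
    n_indel = rng.binomial(n_sub, min(indel_rate, 1.0)) if n_sub else 0
    # geometric lengths truncated to 1..3
    for _ in range(n_indel):
        length = min(int(rng.geometric(0.5)), 3)
        at = int(rng.integers(0, len(out) + 1))
        if rng.random() < 0.5 and len(out) > length:
            del out[at : at + length]
        else:
            ins = rng.choice(_BASES, size=length).tolist()
            out[at:at] = ins
    return "".join(out)


def plant_motif(
    seq: str, pfm_counts: np.ndarray, position: int, strand: str, seed: int
) -> str:
    """Write one PFM-sampled motif instance into ``seq`` at ``position``.

    Each motif column is drawn from that column's frequency
    distribution; the instance is reverse-complemented when strand is
    '-'.  Deterministic given ``seed``.
    """
    counts = np.asarray(pfm_counts, dtype=float)
    width = counts.shape[1]
    if position < 0 or position + width > len(seq):
        raise ValueError(
            f"motif of width {width} at position {position} exceeds sequence length {len(seq)}"
        )
    rng = np.random.default_rng(seed)
    letters = []
    for col in counts.T:
        p = col / col.sum()
        letters.append(str(rng.choice(_BASES, p=p)))
    instance = "".join(letters)
    if strand == "-":
        instance = instance.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    return seq[:position] + instance + seq[position + width :]


def _make_repeat(kind: str, length: int, rng: np.random.Generator) -> str:
    if kind == "homopolymer":
        base = str(rng.choice(_BASES))
        return base * length
    unit_len = int(rng.integers(2, 6))
    unit = random_sequence(unit_len, rng)
    reps = -(-length // unit_len)
    return (unit * reps)[:length]


def _make_orf(length: int, rng: np.random.Generator) -> str:
    """ATG + sense codons + stop, total ``length`` nt (multiple of 3)."""
    n_codons = length // 3 - 2
    body = "".join(rng.choice(_SENSE) for _ in range(max(n_codons, 0)))
    return ("ATG" + body + "TAA")[:length]


def generate_locus_pair(
    spec: SyntheticSpec,
    pfms: Optional[dict[str, np.ndarray]] = None,
    scheme: ScoringScheme = ScoringScheme(),
) -> tuple[GenomeLocus, GenomeLocus, HomologyTable, TruthSet]:
    """Generate one ortholog locus pair plus homology table and truth set.

    Layout: a central gene (exons + introns) flanked by background, with
    conserved elements and repeats placed non-overlapping in the flanks.
    Species B is built segment-by-segment from species A: elements and
    exons diverged at ``target_identity``, repeats copied verbatim,
    background diverged at ``background_identity`` (or independent when
    that is 0).  Raises ``ValueError`` before any output if the features
    do not fit.
    """
    pfms = pfms or {}
    for pwm_id, _count in spec.planted_motifs:
        if pwm_id not in pfms:
            raise ValueError(f"planted motif {pwm_id!r} has no PFM supplied")
    rng = np.random.default_rng(spec.seed)

    gene_len = (
        spec.n_exons * spec.exon_length + max(spec.n_exons - 1, 0) * spec.intron_length
        if spec.n_exons > 0
        else 0
    )
    n_flank_feats = spec.n_conserved_elements + spec.n_repeats
    pad = spec.min_feature_spacing
    need = (
        gene_len
        + spec.n_conserved_elements * spec.element_length
        + spec.n_repeats * spec.repeat_length
        + (n_flank_feats + 2) * pad
    )
    if need > spec.locus_length:
        raise ValueError(
            f"features need {need} bp but locus_length is {spec.locus_length}"
        )

    # --- species A as an ordered list of (tag, payload, seq) segments ---
    # tags: bg, exon, element, repeat
    feats: list[tuple[str, str]] = []  # (tag, seq) for flank features
    for e in range(spec.n_conserved_elements):
        seq = random_sequence(spec.element_length, rng)
        feats.append((f"element:{e}", seq))
    for r in range(spec.n_repeats):
        feats.append((f"repeat:{r}", _make_repeat(spec.repeat_kind, spec.repeat_length, rng)))
    order = rng.permutation(len(feats))
    feats = [feats[i] for i in order]
    n_left = len(feats) // 2
    left_feats, right_feats = feats[:n_left], feats[n_left:]

    gene_segments: list[tuple[str, str]] = []
    for x in range(spec.n_exons):
        if x > 0:
            gene_segments.append(("bg", random_sequence(spec.intron_length, rng)))
        gene_segments.append((f"exon:{x}", _make_orf(spec.exon_length, rng)))

    flank_total = spec.locus_length - gene_len
    left_budget = flank_total // 2
    right_budget = flank_total - left_budget

    def layout(features: list[tuple[str, str]], budget: int) -> list[tuple[str, str]]:
        """Interleave features with random background, filling ``budget`` bp."""
        feat_bp = sum(len(s) for _t, s in features)
        free = budget - feat_bp
        n_gaps = len(features) + 1
        # split free bp into n_gaps parts, each >= pad (checked above globally)
        if free < n_gaps * pad:
            raise ValueError("flank features do not fit")
        cuts = np.sort(rng.choice(free - n_gaps * pad + 1, size=max(n_gaps - 1, 0)))
        gap_sizes = np.diff(np.concatenate([[0], cuts, [free - n_gaps * pad]])) + pad
        segs: list[tuple[str, str]] = []
        for g, feat in zip(gap_sizes, features + [None]):
            segs.append(("bg", random_sequence(int(g), rng)))
            if feat is not None:
                segs.append(feat)
        return segs

    segments = layout(left_feats, left_budget) + gene_segments + layout(right_feats, right_budget)

    # --- plant motifs inside conserved elements (species A) ---
    motif_plan: list[tuple[str, int, int, str]] = []  # (pwm_id, elem_idx, offset, strand)
    if spec.planted_motifs and spec.n_conserved_elements > 0:
        for pwm_id, count in spec.planted_motifs:
            width = pfms[pwm_id].shape[1]
            for c in range(count):
                elem_idx = int(rng.integers(spec.n_conserved_elements))
                offset = int(rng.integers(0, spec.element_length - width + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                motif_plan.append((pwm_id, elem_idx, offset, strand))
        new_segments = []
        for tag, seq in segments:
            if tag.startswith("element:"):
                idx = int(tag.split(":")[1])
                for pwm_id, elem_idx, offset, strand in motif_plan:
                    if elem_idx == idx:
                        seq = plant_motif(
                            seq, pfms[pwm_id], offset, strand,
                            seed=int(rng.integers(2**31)),
                        )
                new_segments.append((tag, seq))
            else:
                new_segments.append((tag, seq))
        segments = new_segments

    # --- build species B segment-by-segment ---
    truth = TruthSet()
    seq_a_parts: list[str] = []
    seq_b_parts: list[str] = []
    pos_a = pos_b = 0
    a_coords: dict[str, tuple[int, int]] = {}
    b_coords: dict[str, tuple[int, int]] = {}
    elem_pairs: dict[str, tuple[str, str]] = {}
    for tag, seq in segments:
        sub_seed = int(rng.integers(2**31))
        if tag == "bg":
            if spec.background_identity > 0.0:
                seq_b = evolve_sequence(seq, spec.background_identity, spec.indel_rate, sub_seed)
            else:
                seq_b = random_sequence(len(seq), rng)
        elif tag.startswith("repeat:"):
            seq_b = seq  # repeats shared verbatim: exercises the repeat veto
        else:  # element or exon: conserved at target_identity
            seq_b = evolve_sequence(seq, spec.target_identity, spec.indel_rate, sub_seed)
        seq_a_parts.append(seq)
        seq_b_parts.append(seq_b)
        if tag != "bg":
            a_coords[tag] = (pos_a, pos_a + len(seq))
            b_coords[tag] = (pos_b, pos_b + len(seq_b))
            if tag.startswith("element:"):
                elem_pairs[tag] = (seq, seq_b)
        pos_a += len(seq)
        pos_b += len(seq_b)

    seq_a = "".join(seq_a_parts)
    seq_b = "".join(seq_b_parts)
    locus_a = GenomeLocus("speciesA", "locusA", 0, len(seq_a), "+", seq_a, "locusA")
    locus_b = GenomeLocus("speciesB", "locusB", 0, len(seq_b), "+", seq_b, "locusB")

    # --- annotations + truth bookkeeping ---
    def gene_span(coords: dict[str, tuple[int, int]]) -> Optional[tuple[int, int]]:
        exons = [v for k, v in coords.items() if k.startswith("exon:")]
        if not exons:
            return None
        return min(s for s, _ in exons), max(e for _, e in exons)

    for species, coords, ann, chrom in (
        ("A", a_coords, truth.annotations_a, "locusA"),
        ("B", b_coords, truth.annotations_b, "locusB"),
    ):
        span = gene_span(coords)
        if span:
            ann.add(Interval(chrom, span[0], span[1], "+", "gene", f"gene{species}"))
        for tag, (s, e) in sorted(coords.items(), key=lambda kv: kv[1]):
            kind, idx = tag.split(":")
            if kind == "exon":
                ann.add(Interval(chrom, s, e, "+", "exon", f"exon{species}_{idx}"))
            elif kind == "repeat":
                ann.add(Interval(chrom, s, e, "+", "repeat", f"repeat{species}_{idx}"))
            elif kind == "element":
                ann.add(Interval(chrom, s, e, "+", "cre_truth", f"cre_{idx}"))

    for tag, (ea, eb) in sorted(elem_pairs.items()):
        idx = tag.split(":")[1]
        aln = needleman_wunsch(ea, eb, scheme)
        truth.elements.append(
            TruthElement(
                pair_id=f"cre_{idx}",
                a_start=a_coords[tag][0], a_end=a_coords[tag][1],
                b_start=b_coords[tag][0], b_end=b_coords[tag][1],
                realized_identity=aln.identity,
            )
        )
    for pwm_id, elem_idx, offset, strand in motif_plan:
        tag = f"element:{elem_idx}"
        width = pfms[pwm_id].shape[1]
        truth.motifs.append(
            TruthMotif(
                pwm_id=pwm_id,
                a_start=a_coords[tag][0] + offset,
                a_end=a_coords[tag][0] + offset + width,
                strand=strand,
            )
        )

    homology = HomologyTable()
    if spec.n_exons > 0:
        homology.rows.append(("geneA", ["geneB"]))
    _assert_no_overlap(truth)
    return locus_a, locus_b, homology, truth


def _assert_no_overlap(truth: TruthSet) -> None:
    """Construction invariant: no truth element overlaps an exon or repeat."""
    for ann in (truth.annotations_a, truth.annotations_b):
        elements = ann.of_kind("cre_truth")
        blockers = ann.of_kind("exon") + ann.of_kind("repeat")
        for el in elements:
            for blk in blockers:
                if el.overlap(blk.start, blk.end) > 0:
                    raise AssertionError(
                        f"planted element {el.name} overlaps {blk.kind} {blk.name}"
                    )


def write_pair(locus_a, locus_b, homology, truth, outdir, seed: int) -> dict[str, str]:
    """Write the generated pair as FASTA + BED + homology TSV.

    The seed is surfaced in every filename.  Returns the path map.
    """
    from pathlib import Path

    from .io_formats import write_bed, write_fasta, write_homology

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta_a": outdir / f"speciesA_seed{seed}.fasta",
        "fasta_b": outdir / f"speciesB_seed{seed}.fasta",
        "bed_a": outdir / f"speciesA_seed{seed}.bed",
        "bed_b": outdir / f"speciesB_seed{seed}.bed",
        "homology": outdir / f"homology_seed{seed}.tsv",
    }
    write_fasta([locus_a], paths["fasta_a"])
    write_fasta([locus_b], paths["fasta_b"])
    write_bed(truth.annotations_a, paths["bed_a"])
    write_bed(truth.annotations_b, paths["bed_b"])
    write_homology(homology, paths["homology"])
    return {k: str(v) for k, v in paths.items()}
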