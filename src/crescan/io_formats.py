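"""Readers and writers for the external formats the screen touches.

Every coordinate in this package is 0-based, half-open, on the + strand
of the stored sequence (BED convention).  GFF3 input (1-based inclusive)
is converted on read.  FASTA ids are the first whitespace-delimited
header token.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

VALID_BASES = set("ACGTN")
#: annotation vocabulary; "candidate" appears only in screen output BED
ANNOTATION_KINDS = frozenset({"gene", "exon", "repeat", "cre_truth", "candidate"})


@dataclass
class GenomeLocus:
    """A named sequence interval with species, strand and coordinates.

    ``seq`` is uppercase DNA over {A,C,G,T,N}; ``start``/``end`` are
    0-based half-open offsets with ``end - start == len(seq)``.
    """

    species: str
    chrom: str
    start: int
    end: int
    strand: str
    seq: str
    id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"locus {self.id}: end ({self.end}) must exceed start ({self.start})")
        if self.end - self.start != len(self.seq):
            raise ValueError(
                f"locus {self.id}: span {self.end - self.start} != sequence length {len(self.seq)}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"locus {self.id}: strand must be + or -")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"locus {self.id}: non-IUPAC character {sorted(bad)[0]!r} in sequence"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def subseq(self, start: int, end: int) -> str:
        """Slice in locus-local coordinates."""
        return self.seq[start:end]


@dataclass(frozen=True)
class Interval:
    """Half-open annotated interval; ``kind`` is a restricted vocabulary."""

    chrom: str
    start: int
    end: int
    strand: str
    kind: str
    name: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"interval {self.name}: start must be < end")
        if self.kind not in ANNOTATION_KINDS:
            raise ValueError(f"interval {self.name}: unknown kind {self.kind!r}")

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class AnnotationSet:
    """Ordered collection of annotation intervals for one sequence set."""

    intervals: list[Interval] = field(default_factory=list)

    def of_kind(self, kind: str) -> list[Interval]:
        return [iv for iv in self.intervals if iv.kind == kind]

    def by_name(self, name: str) -> Optional[Interval]:
        for iv in self.intervals:
            if iv.name == name:
                return iv
        return None

    def add(self, iv: Interval) -> None:
        self.intervals.append(iv)


@dataclass
class HomologyTable:
    """Rows mapping one species-A gene id to one or more species-B gene ids."""

    rows: list[tuple[str, list[str]]] = field(default_factory=list)

    def validate(self, ann_a: AnnotationSet, ann_b: AnnotationSet) -> None:
        """Every gene id must resolve to a gene interval in its annotation set."""
        genes_a = {iv.name for iv in ann_a.of_kind("gene")}
        genes_b = {iv.name for iv in ann_b.of_kind("gene")}
        for gene_a, partners in self.rows:
            if gene_a not in genes_a:
                raise ValueError(f"homology table: unknown species-A gene {gene_a!r}")
            for g in partners:
                if g not in genes_b:
                    raise ValueError(f"homology table: unknown species-B gene {g!r}")


def read_fasta(path: str | Path, species: str = "") -> list[GenomeLocus]:
    """Read FASTA records as loci (start=0, end=length, + strand).

    Lowercase input is uppercased; an empty file or a non-IUPAC character
    is an error naming the offending record and character.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty FASTA file")
    loci = []
    for rec in records:
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} contains non-IUPAC character {sorted(bad)[0]!r}"
            )
        loci.append(
            GenomeLocus(
                species=species, chrom=rec.id, start=0, end=len(seq),
                strand="+", seq=seq, id=rec.id,
            )
        )
    return loci


def write_fasta(loci: Iterable[GenomeLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for locus in loci:
            fh.write(f">{locus.id}\n")
            for i in range(0, len(locus.seq), 70):
                fh.write(locus.seq[i : i + 70] + "\n")


def read_bed(path: str | Path) -> AnnotationSet:
    """Read a 6-column BED file; column 4 is parsed as ``kind:name``."""
    out = AnnotationSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            start, end = int(start), int(end)
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start ({start}) must be < end ({end})")
            if ":" in name:
                kind, label = name.split(":", 1)
            else:
                kind, label = name, name
            out.add(Interval(chrom, start, end, strand, kind, label))
    return out


def write_bed(annotations: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in annotations.intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.kind}:{iv.name}\t0\t{iv.strand}\n"
            )


_GFF_KIND = {
    "gene": "gene",
    "exon": "exon",
    "CDS": "exon",
    "repeat_region": "repeat",
    "dispersed_repeat": "repeat",
    "tandem_repeat": "repeat",
}


def read_gff3(path: str | Path) -> AnnotationSet:
    """Read GFF3 annotations, converting 1-based inclusive to 0-based half-open.

    Feature types outside the internal vocabulary (gene/exon/repeat) are
    skipped.  The ``ID`` or ``Name`` attribute becomes the interval name.
    """
    out = AnnotationSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = fields
            kind = _GFF_KIND.get(ftype)
            if kind is None:
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            name = attr.get("ID") or attr.get("Name") or f"{ftype}_{lineno}"
            out.add(Interval(chrom, int(start) - 1, int(end), strand, kind, name))
    return out


def read_homology(path: str | Path) -> HomologyTable:
    """Read a two-column TSV; the second column is comma-separated gene ids."""
    table = HomologyTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 TSV columns")
            partners = [g.strip() for g in fields[1].split(",") if g.strip()]
            if not partners:
                raise ValueError(f"{path}:{lineno}: no partner gene ids")
            table.rows.append((fields[0].strip(), partners))
    return table


def write_homology(table: HomologyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene_a, partners in table.rows:
            fh.write(f"{gene_a}\t{','.join(partners)}\n")


_JASPAR_ORDER = "ACGT"


def read_jaspar_pfm(path: str | Path):
    """Read the first matrix of a JASPAR 2016+ PFM text file.

    Returns ``(matrix_id, counts)`` with counts a 4 x width list of
    floats in fixed A,C,G,T row order regardless of the file's row
    order.  A missing base row or a negative count is an error.
    """
    matrices = read_jaspar_pfms(path)
    if not matrices:
        raise ValueError(f"{path}: no PFM records found")
    return matrices[0]


def read_jaspar_pfms(path: str | Path):
    """Read all matrices of a JASPAR PFM text file (see read_jaspar_pfm)."""
    import numpy as np

    out = []
    with open(path) as fh:
        header = None
        rows: dict[str, list[float]] = {}

        def flush():
            if header is None:
                return
            missing = [b for b in _JASPAR_ORDER if b not in rows]
            if missing:
                raise ValueError(f"{path}: matrix {header!r} missing base row {missing[0]!r}")
            widths = {len(v) for v in rows.values()}
            if len(widths) != 1:
                raise ValueError(f"{path}: matrix {header!r} has ragged rows")
            if widths == {0}:
                raise ValueError(f"{path}: matrix {header!r} has zero columns")
            counts = np.array([rows[b] for b in _JASPAR_ORDER], dtype=float)
            if (counts < 0).any():
                raise ValueError(f"{path}: matrix {header!r} has a negative count")
            out.append((header, counts))

        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0]
                rows = {}
            else:
                token = line[0].upper()
                if token not in _JASPAR_ORDER:
                    raise ValueError(f"{path}: unexpected PFM row starting with {line[0]!r}")
                body = line[1:].replace("[", " ").replace("]", " ")
                rows[token] = [float(x) for x in body.split()]
        flush()
    return out


_TSV_COLUMNS = [
    "candidate_id", "query_chrom", "query_start", "query_end",
    "hit_chrom", "hit_start", "hit_end", "hit_strand",
    "identity_pct", "aligned_length", "evalue",
    "homolog_linked", "identity_length_evalue", "noncoding", "nonrepetitive",
    "reciprocal_unique", "refined_identity", "tfbs_hits", "verdict",
]


def write_candidates(candidates, path_bed: str | Path, path_tsv: str | Path) -> None:
    """Write classified candidates as BED6 (species-A intervals) + full TSV.

    Raises ``ValueError`` if any candidate has unfilled criteria.
    """
    for cand in candidates:
        if cand.criteria is None:
            raise ValueError(f"candidate {cand.id}: criteria not filled; classify first")
    with open(path_bed, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for cand in candidates:
            fh.write(
                f"{cand.query_chrom}\t{cand.query_start}\t{cand.query_end}\t"
                f"candidate:{cand.id}\t{cand.alignment.score}\t+\n"
            )
    with open(path_tsv, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for cand in candidates:
            c = cand.criteria
            writer.writerow([
                cand.id, cand.query_chrom, cand.query_start, cand.query_end,
                cand.hit_chrom, cand.hit_start, cand.hit_end, cand.hit_strand,
                f"{cand.alignment.identity * 100:.2f}", cand.alignment.n_columns,
                f"{cand.alignment.evalue:.3g}" if cand.alignment.evalue is not None else "NA",
                c.homolog_linked, c.identity_length_evalue, c.noncoding, c.nonrepetitive,
                cand.reciprocal_unique if cand.reciprocal_unique is not None else "untested",
                f"{cand.refined_identity:.4f}" if cand.refined_identity is not None else "absent",
                cand.tfbs_hits if cand.tfbs_hits is not None else 0,
                "pass" if cand.verdict else "fail",
            ])
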