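"""Readers and writers for the on-disk formats the pipeline touches.

FASTA and FASTQ (Phred+33) carry genomes and reads; GFF3 plus its companion
FASTA carries CDS annotation; the ``.pep``/``.nuc``/``.function`` trio is the
three-file convention consumed by gene-family comparison tools (protein FASTA,
CDS FASTA, and a tab-delimited function table).

All coordinates on disk are 1-based inclusive (GFF3 convention).  Sequences
are uppercased on read; ``N`` is accepted on input.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

__all__ = [
    "SeqRecord",
    "ReadRecord",
    "Feature",
    "AnnotationSet",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_gff3",
    "write_gff3",
    "write_pgap_inputs",
]

_IUPAC = set("ACGTN")


class FormatError(ValueError):
    """Raised for malformed input files; message names the offending line."""


@dataclass
class SeqRecord:
    """A named nucleotide sequence over {A,C,G,T,N}."""

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadRecord:
    """A sequencing read with per-base Phred+33 quality."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.quality) != len(self.sequence):
            raise FormatError(
                f"read {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Feature:
    """A CDS feature in 1-based inclusive coordinates on a named contig."""

    feature_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    type: str = "CDS"
    product: str = "hypothetical protein"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id!r}: bad strand {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"feature {self.feature_id!r}: bad interval {self.start}..{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotationSet:
    """A genome: its contigs plus the CDS features called on them."""

    genome_id: str
    contigs: list[SeqRecord] = field(default_factory=list)
    features: list[Feature] = field(default_factory=list)

    def contig(self, contig_id: str) -> SeqRecord:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(f"unknown contig {contig_id!r} in genome {self.genome_id!r}")

    def feature_nuc(self, feat: Feature) -> str:
        """Extract a feature's nucleotide sequence (strand-resolved)."""
        seq = self.contig(feat.contig_id).sequence[feat.start - 1 : feat.end]
        if feat.strand == "-":
            seq = revcomp(seq)
        return seq

    def validate(self) -> None:
        seen: set[str] = set()
        lengths = {c.id: len(c) for c in self.contigs}
        for f in self.features:
            if f.feature_id in seen:
                raise ValueError(f"duplicate feature id {f.feature_id!r}")
            seen.add(f.feature_id)
            if f.contig_id not in lengths:
                raise ValueError(
                    f"feature {f.feature_id!r} names unknown contig {f.contig_id!r}"
                )
            if f.end > lengths[f.contig_id]:
                raise ValueError(
                    f"feature {f.feature_id!r} end {f.end} beyond contig "
                    f"{f.contig_id!r} length {lengths[f.contig_id]}"
                )


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an {A,C,G,T,N} string."""
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike, alphabet: str = "nucleotide") -> list[SeqRecord]:
    """Parse a FASTA file into records, uppercasing and validating bases.

    Raises :class:`FormatError` (naming the line) on an empty file, a file not
    starting with ``>``, a duplicate id, or a non-IUPAC character.  With
    ``alphabet="protein"`` character validation is skipped (for protein sets
    such as known-product references).
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_desc = ""
    chunks: list[str] = []

    def flush(lineno: int) -> None:
        nonlocal cur_id, chunks
        if cur_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}: record {cur_id!r} has empty sequence (line {lineno})")
        records.append(SeqRecord(cur_id, seq, cur_desc))
        cur_id, chunks = None, []

    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if lineno == 1 and not line.startswith(">"):
                raise FormatError(f"{path}: line 1 does not start with '>'")
            if line.startswith(">"):
                flush(lineno)
                head = line[1:].split(None, 1)
                if not head:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                cur_id = head[0]
                cur_desc = head[1] if len(head) > 1 else ""
                if cur_id in seen:
                    raise FormatError(f"{path}: duplicate id {cur_id!r} at line {lineno}")
                seen.add(cur_id)
            elif line:
                up = line.upper()
                bad = (set(up) - _IUPAC) if alphabet == "nucleotide" else set()
                if bad:
                    raise FormatError(
                        f"{path}: non-IUPAC character {sorted(bad)[0]!r} at line {lineno}"
                    )
                chunks.append(up)
        if lineno == 0:
            raise FormatError(f"{path}: empty file")
        flush(lineno)
    return records


def write_fasta(
    records: list[SeqRecord], path: str | os.PathLike, width: int = 70
) -> None:
    """Write records in the given order, wrapping sequence lines at *width*."""
    if not records:
        raise ValueError("write_fasta: no records to write")
    if width < 1:
        raise ValueError(f"write_fasta: width must be positive, got {width}")
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            fh.write(head + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | os.PathLike) -> list[ReadRecord]:
    """Parse 4-line FASTQ records; qualities are kept byte-exact."""
    reads: list[ReadRecord] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise FormatError(
            f"{path}: truncated FASTQ record near line {len(lines) - len(lines) % 4 + 1}"
        )
    for i in range(0, len(lines), 4):
        head, seq, sep, qual = lines[i : i + 4]
        if not head.startswith("@"):
            raise FormatError(f"{path}: line {i + 1} does not start with '@'")
        if not sep.startswith("+"):
            raise FormatError(f"{path}: line {i + 3} is not a '+' separator")
        if len(seq) != len(qual):
            raise FormatError(
                f"{path}: line {i + 4}: quality length {len(qual)} != "
                f"sequence length {len(seq)}"
            )
        reads.append(ReadRecord(head[1:].split()[0], seq.upper(), qual))
    return reads


def write_fastq(reads: list[ReadRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


# ---------------------------------------------------------------------------
# GFF3 (CDS only) + companion FASTA
# ---------------------------------------------------------------------------

def read_gff3(path: str | os.PathLike, fasta_path: str | os.PathLike) -> AnnotationSet:
    """Read CDS features from a GFF3 file, with contigs from *fasta_path*.

    Only ``CDS`` lines are retained; the product is taken from the
    ``product=`` attribute and defaults to ``hypothetical protein``.
    """
    contigs = read_fasta(fasta_path)
    genome_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    ann = AnnotationSet(genome_id, contigs)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 columns, got {len(cols)}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != "CDS":
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            feat = Feature(
                feature_id=attr_map.get("ID", f"cds_{lineno}"),
                contig_id=seqid,
                start=int(start),
                end=int(end),
                strand=strand,
                product=attr_map.get("product", "hypothetical protein"),
            )
            ann.features.append(feat)
    ann.validate()
    return ann


def write_gff3(ann: AnnotationSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in ann.contigs:
            fh.write(f"##sequence-region {c.id} 1 {len(c)}\n")
        for f in ann.features:
            attrs = f"ID={f.feature_id};product={f.product}"
            fh.write(
                f"{f.contig_id}\tpankit\tCDS\t{f.start}\t{f.end}\t.\t{f.strand}\t0\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# pep / nuc / function trio
# ---------------------------------------------------------------------------

def write_pgap_inputs(ann: AnnotationSet, out_prefix: str | os.PathLike) -> tuple[str, str, str]:
    """Write the three comparison inputs derived from one genome's annotation.

    ``<prefix>.pep`` holds translated proteins (no stop symbol), ``<prefix>.nuc``
    the CDS nucleotide sequences, and ``<prefix>.function`` tab-delimited lines
    ``feature_id<TAB>-<TAB>product`` (the COG column is fixed to ``-`` since no
    COG assignment is made).  The three files share one feature ordering.
    A CDS with an internal stop is skipped from all three files with a warning.
    """
    import warnings

    from .annotation import translate

    cds = [f for f in ann.features if f.type == "CDS"]
    if not cds:
        raise ValueError(f"genome {ann.genome_id!r} has no CDS features")
    prefix = os.fspath(out_prefix)
    pep_path, nuc_path, fun_path = prefix + ".pep", prefix + ".nuc", prefix + ".function"
    pep_recs, nuc_recs, fun_lines = [], [], []
    for f in cds:
        nuc = ann.feature_nuc(f)
        prot = translate(nuc)
        if "*" in prot:
            warnings.warn(
                f"CDS {f.feature_id} contains an internal stop; skipped", stacklevel=2
            )
            continue
        pep_recs.append(SeqRecord(f.feature_id, prot, f.product))
        nuc_recs.append(SeqRecord(f.feature_id, nuc, f.product))
        fun_lines.append(f"{f.feature_id}\t-\t{f.product}")
    if not pep_recs:
        raise ValueError(f"genome {ann.genome_id!r}: all CDS were skipped")
    _write_plain_fasta(pep_recs, pep_path)
    _write_plain_fasta(nuc_recs, nuc_path)
    with open(fun_path, "w") as fh:
        fh.write("\n".join(fun_lines) + "\n")
    return pep_path, nuc_path, fun_path


def _write_plain_fasta(records: list[SeqRecord], path: str, width: int = 70) -> None:
    # protein records may contain residues outside the nucleotide alphabet,
    # so bypass write_fasta's record type without validation
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            fh.write(head + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
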