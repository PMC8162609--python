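"""CDS annotation of genomes and assembled contigs.

Annotation here is plain prokaryotic ORF calling: in each of the six reading
frames, for every stop codon the longest open reading frame ending at that
stop (i.e. starting at the earliest in-frame start codon after the previous
stop) is called, provided it reaches the minimum length.  Translation uses the
bacterial genetic code (NCBI table 11), under which ATG, GTG and TTG all serve
as start codons.  No ribosome-binding-site or coding-potential model is used.

Products start out as ``hypothetical protein``; :func:`assign_products` can
rename them from the best qualifying similarity hit against a reference
protein set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from Bio.Seq import Seq

from .seqio import AnnotationSet, Feature, SeqRecord, revcomp

__all__ = ["OrfCall", "AnnotParams", "translate", "find_orfs", "annotate_genome", "assign_products"]

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class AnnotParams:
    """ORF-calling parameters.

    min_orf_nt counts nucleotides including the stop codon; 150 nt (50 aa)
    mirrors common prokaryotic annotation minima.
    """

    min_orf_nt: int = 150
    start_codons: frozenset[str] = frozenset({"ATG", "GTG", "TTG"})

    def __post_init__(self) -> None:
        if self.min_orf_nt % 3 != 0 or self.min_orf_nt < 30:
            raise ValueError(f"min_orf_nt must be a multiple of 3 >= 30, got {self.min_orf_nt}")


@dataclass
class OrfCall:
    """One called ORF, in 1-based inclusive plus-strand coordinates."""

    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    nuc: str
    protein: str


def translate(nuc: str) -> str:
    """Translate a CDS with NCBI table 11; the trailing stop is dropped.

    Internal stops render as ``*`` (callers reject such CDS); codons
    containing ``N`` render as ``X``.
    """
    if len(nuc) % 3 != 0:
        raise ValueError(f"CDS length {len(nuc)} is not a multiple of 3")
    prot = str(Seq(nuc).translate(table=11))
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


def _scan_frame(seq: str, frame: int, params: AnnotParams) -> list[tuple[int, int]]:
    """ORF spans (0-based start, 0-based end-exclusive incl. stop) in one frame."""
    out = []
    start_pos: int | None = None
    for p in range(frame, len(seq) - 2, 3):
        codon = seq[p : p + 3]
        if codon in STOP_CODONS:
            if start_pos is not None and p + 3 - start_pos >= params.min_orf_nt:
                out.append((start_pos, p + 3))
            start_pos = None
        elif start_pos is None and codon in params.start_codons:
            start_pos = p
    return out


def find_orfs(contig: SeqRecord, params: AnnotParams | None = None) -> list[OrfCall]:
    """Call ORFs on both strands of a contig, sorted by (start, end)."""
    params = params or AnnotParams()
    seq = contig.sequence
    L = len(seq)
    calls: list[OrfCall] = []
    for frame in range(3):
        for s, e in _scan_frame(seq, frame, params):
            nuc = seq[s:e]
            calls.append(
                OrfCall(contig.id, s + 1, e, "+", frame, nuc, translate(nuc))
            )
    rc = revcomp(seq)
    for frame in range(3):
        for s, e in _scan_frame(rc, frame, params):
            nuc = rc[s:e]
            calls.append(
                OrfCall(contig.id, L - e + 1, L - s, "-", frame, nuc, translate(nuc))
            )
    calls.sort(key=lambda c: (c.start, c.end, c.strand))
    return calls


def annotate_genome(
    genome_id: str,
    contigs: list[SeqRecord],
    params: AnnotParams | None = None,
) -> AnnotationSet:
    """Annotate a genome's contigs; feature ids are sequential in coordinate order."""
    params = params or AnnotParams()
    ann = AnnotationSet(genome_id, list(contigs))
    n = 0
    for contig in contigs:
        for call in find_orfs(contig, params):
            n += 1
            ann.features.append(
                Feature(
                    feature_id=f"{genome_id}_{n:05d}",
                    contig_id=call.contig_id,
                    start=call.start,
                    end=call.end,
                    strand=call.strand,
                )
            )
    ann.validate()
    return ann


def assign_products(
    ann: AnnotationSet,
    reference_proteins: list[SeqRecord],
    thresholds=None,
) -> AnnotationSet:
    """Name each CDS from its best qualifying hit against reference proteins.

    CDS with no qualifying hit keep ``hypothetical protein``.  The operation is
    idempotent.  Reference protein descriptions carry the product names.
    """
    from .similarity import ScoringScheme, Thresholds, search

    thresholds = thresholds or Thresholds()
    if not reference_proteins:
        return ann
    queries = [
        SeqRecord(f.feature_id, translate(ann.feature_nuc(f)))
        for f in ann.features
    ]
    hits = search(queries, reference_proteins, ScoringScheme.protein(), thresholds)
    best: dict[str, tuple[float, str]] = {}
    names = {r.id: (r.description or r.id) for r in reference_proteins}
    for h in hits:
        cand = (h.evalue, names[h.subject_id])
        if h.query_id not in best or cand < best[h.query_id]:
            best[h.query_id] = cand
    out = AnnotationSet(ann.genome_id, ann.contigs, [])
    for f in ann.features:
        product = best[f.feature_id][1] if f.feature_id in best else f.product
        out.features.append(replace(f, product=product))
    return out
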