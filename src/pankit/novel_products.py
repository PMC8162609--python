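"""Stage-1 orchestration: recover gene products missing from a reference.

The flow mirrors the two observations the stage rests on: reads that do not
map to the reference carry sequence the reference lacks, and assembled CDS
from those reads that share no similarity with the reference's own CDS are
genuinely new products.  New products are appended to the end of the genome
file as bare CDS records, after which a second annotation round runs on the
updated genome; repeating the stage on the updated genome identifies nothing
(the products are now part of the reference).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

from . import assembly, mapping
from .annotation import AnnotParams, annotate_genome, assign_products, translate
from .seqio import (
    AnnotationSet,
    Feature,
    ReadRecord,
    SeqRecord,
    read_fasta,
    read_fastq,
    write_fasta,
)
from .similarity import ScoringScheme, Thresholds, search

__all__ = ["DiscoveryReport", "DiscoveryResult", "identify_new_products", "update_genome", "run_discovery", "discover"]


@dataclass
class DiscoveryReport:
    """Summary counts over the identified new products."""

    new_products: int = 0       # products with a transferred (non-hypothetical) name
    hypothetical: int = 0       # products left as "hypothetical protein"
    total: int = 0
    mean_len_nt: int = 0

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("new_products\thypothetical\ttotal\tmean_len_nt\n")
            fh.write(f"{self.new_products}\t{self.hypothetical}\t{self.total}\t{self.mean_len_nt}\n")


@dataclass
class DiscoveryResult:
    counts: dict[str, int]
    contigs: list[assembly.Contig]
    ref_ann: AnnotationSet
    asm_ann: AnnotationSet
    new_features: list[Feature] = field(default_factory=list)
    updated: list[SeqRecord] = field(default_factory=list)
    second_ann: AnnotationSet | None = None
    report: DiscoveryReport = field(default_factory=DiscoveryReport)


def identify_new_products(
    ref_ann: AnnotationSet,
    asm_ann: AnnotationSet,
    scheme: ScoringScheme | None = None,
    thresholds: Thresholds | None = None,
) -> list[Feature]:
    """Assembled CDS with no qualifying similarity to any reference CDS.

    Comparison is at the protein level.  Redundant assembled CDS (those that
    hit each other at the same thresholds) are collapsed to the longest
    representative, so one missing gene yields one product.  Result ordered
    by assembly coordinates.
    """
    scheme = scheme or ScoringScheme.protein()
    thresholds = thresholds or Thresholds()
    if not asm_ann.features:
        return []
    asm_prots = [
        SeqRecord(f.feature_id, translate(asm_ann.feature_nuc(f)))
        for f in asm_ann.features
    ]
    ref_prots = [
        SeqRecord(f.feature_id, translate(ref_ann.feature_nuc(f)))
        for f in ref_ann.features
    ]
    hit_ids = (
        {h.query_id for h in search(asm_prots, ref_prots, scheme, thresholds)}
        if ref_prots
        else set()
    )
    novel = [f for f in asm_ann.features if f.feature_id not in hit_ids]
    # collapse mutually-similar assembled CDS to the longest representative
    novel_prots = [p for p in asm_prots if p.id in {f.feature_id for f in novel}]
    redundant: set[str] = set()
    by_id = {f.feature_id: f for f in novel}
    self_hits = search(novel_prots, novel_prots, scheme, thresholds)
    for h in self_hits:
        if h.query_id == h.subject_id:
            continue
        fa, fb = by_id.get(h.query_id), by_id.get(h.subject_id)
        if fa is None or fb is None:
            continue
        shorter = min(
            (fa, fb), key=lambda f: (len(f), f.feature_id)
        )
        longer = fa if shorter is fb else fb
        if longer.feature_id not in redundant:
            redundant.add(shorter.feature_id)
    novel = [f for f in novel if f.feature_id not in redundant]
    novel.sort(key=lambda f: (f.contig_id, f.start, f.end))
    return novel


def update_genome(
    reference: list[SeqRecord],
    new_features: list[Feature],
    asm_ann: AnnotationSet,
) -> list[SeqRecord]:
    """Append one CDS record per new feature at the end of the genome file.

    Original records are preserved byte-identical and in order; appended
    record ids are ``new_<feature_id>``.
    """
    updated = [SeqRecord(r.id, r.sequence, r.description) for r in reference]
    for f in new_features:
        updated.append(SeqRecord(f"new_{f.feature_id}", asm_ann.feature_nuc(f), f.product))
    return updated


def discover(
    reference: list[SeqRecord],
    reads1: list[ReadRecord],
    reads2: list[ReadRecord],
    *,
    map_params: mapping.MapParams | None = None,
    asm_k: int = 31,
    asm_min_count: int = 2,
    asm_min_len: int = 200,
    annot_params: AnnotParams | None = None,
    thresholds: Thresholds | None = None,
    known_proteins: list[SeqRecord] | None = None,
) -> DiscoveryResult:
    """Run stage 1 in memory: partition, repair, assemble, annotate, identify,
    update, re-annotate, report."""
    map_params = map_params or mapping.MapParams()
    annot_params = annot_params or AnnotParams()
    thresholds = thresholds or Thresholds()

    index = mapping.build_index(reference, map_params.k)
    up1, up2, singles, counts = mapping.partition_reads(reads1, reads2, index, map_params)
    paired1, paired2, orphans = mapping.repair_pairs(up1, up2)
    unmapped = paired1 + paired2 + orphans + singles

    graph = assembly.prune(assembly.build_graph(unmapped, asm_k), asm_min_count)
    contigs = assembly.extract_contigs(graph, asm_min_len)

    ref_ann = annotate_genome("ref", reference, annot_params)
    asm_ann = annotate_genome("asm", assembly.contigs_to_records(contigs), annot_params)
    result = DiscoveryResult(counts, contigs, ref_ann, asm_ann)

    result.new_features = identify_new_products(ref_ann, asm_ann, thresholds=thresholds)
    result.updated = update_genome(reference, result.new_features, asm_ann)
    result.second_ann = annotate_genome("updated", result.updated, annot_params)

    named_ann = AnnotationSet("new", asm_ann.contigs, list(result.new_features))
    if known_proteins:
        named_ann = assign_products(named_ann, known_proteins, thresholds)
    n_named = sum(1 for f in named_ann.features if f.product != "hypothetical protein")
    total = len(named_ann.features)
    lengths = [len(f) for f in named_ann.features]
    result.new_features = named_ann.features
    result.report = DiscoveryReport(
        new_products=n_named,
        hypothetical=total - n_named,
        total=total,
        mean_len_nt=round(statistics.fmean(lengths)) if lengths else 0,
    )
    return result


def run_discovery(
    reference_path: str,
    reads1_path: str,
    reads2_path: str | None,
    out_prefix: str,
    **kwargs,
) -> tuple[str, AnnotationSet, DiscoveryReport]:
    """File-level stage 1: read inputs, run :func:`discover`, write the
    updated genome; returns (updated path, second-round annotation, report)."""
    reference = read_fasta(reference_path)
    reads1 = read_fastq(reads1_path)
    reads2 = read_fastq(reads2_path) if reads2_path else []
    known = kwargs.pop("known_proteins_path", None)
    if known:
        kwargs["known_proteins"] = read_fasta(known, alphabet="protein")
    result = discover(reference, reads1, reads2, **kwargs)
    updated_path = f"{out_prefix}.updated.fasta"
    write_fasta(result.updated, updated_path)
    return updated_path, result.second_ann, result.report
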