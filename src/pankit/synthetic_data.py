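"""Synthetic multi-strain pangenomes, simulated reads, and planted-gene scenarios.

The generator emulates a bacterial strain panel with a known gene-family
structure: a fixed core shared by every strain, plus accessory families whose
discovery curve follows Heap's law.  Strain g (in the canonical order)
introduces ``round(kappa * g**-alpha_true)`` new accessory families, and each
family persists over a consecutive run of strains (a gain-then-loss reading
of accessory dynamics).  Run lengths are allocated from a multiplicity
spectrum solved by non-negative least squares against the exact
hypergeometric first-occurrence curve, so that the expected new-family count
when strains are accumulated in a *random* order is again
``kappa * N**-alpha_true`` -- the property a Heap's-law fit on permutation
curves actually measures.  Family membership is therefore deterministic given
the spec; randomness enters only through sequences and layout.

Genes are random codon sequences (start codon, no in-frame stop, stop codon);
all members of a family share one sequence.  Spacers between genes are
stop-rich in all six frames and free of start codons at the gene boundaries,
so ORF calling recovers the planted genes exactly.

Reads are fixed-length substitution-error reads with constant quality
(the pipeline never consumes qualities); paired mates use ``/1``/``/2`` id
suffixes.  ``plant_missing_genes`` builds the scenario where gene products
are present in the read set but absent from the reference sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .seqio import AnnotationSet, Feature, ReadRecord, SeqRecord, revcomp

__all__ = [
    "PangenomeSpec",
    "ReadSimSpec",
    "TruthTable",
    "random_gene",
    "generate_pangenome",
    "simulate_reads",
    "plant_missing_genes",
]

STOPS = ("TAA", "TAG", "TGA")
STARTS = ("ATG", "GTG", "TTG")

# 12 nt of stop codons in all six frames and no start codon anywhere;
# self-reverse-complementary, so both strands are protected.
STOP_BLOCK = "TTAATTAATTAA"


def _round_half_up(x: float) -> int:
    return max(0, int(math.floor(x + 0.5)))


@dataclass
class PangenomeSpec:
    """Study conditions for a synthetic strain panel."""

    n_genomes: int = 12
    core_families: int = 30
    kappa: float = 60.0
    alpha_true: float = 0.45
    gene_len_range: tuple[int, int] = (300, 900)
    spacer_len_range: tuple[int, int] = (50, 150)
    gc: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("need at least 2 genomes")
        lo, hi = self.gene_len_range
        if lo % 3 or hi % 3 or lo < 150:
            raise ValueError("gene lengths must be multiples of 3, minimum 150")
        if not (0 < self.gc < 1):
            raise ValueError("gc must lie in (0, 1)")


@dataclass
class ReadSimSpec:
    """Read-simulation conditions; insert parameters apply to paired mode."""

    read_len: int = 100
    coverage: float = 30.0
    paired: bool = True
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_len < 50:
            raise ValueError("read_len must be >= 50")
        if not (0 <= self.error_rate < 0.1):
            raise ValueError("error_rate must lie in [0, 0.1)")
        if self.paired and self.insert_mean < self.read_len:
            raise ValueError("insert_mean must be >= read_len for paired reads")


@dataclass
class TruthTable:
    """Oracle mapping of genes to families and families to genomes."""

    family_of_gene: dict[str, str] = field(default_factory=dict)
    genomes_of_family: dict[str, set[str]] = field(default_factory=dict)
    planted_genes: list[str] = field(default_factory=list)

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tfamily\tgenomes\n")
            for gene, fam in sorted(self.family_of_gene.items()):
                genomes = ",".join(sorted(self.genomes_of_family[fam]))
                fh.write(f"{gene}\t{fam}\t{genomes}\n")


def random_gene(length: int, gc: float, rng: np.random.Generator) -> str:
    """A CDS: start codon, non-stop codons at the given GC bias, stop codon."""
    if length % 3 != 0 or length < 9:
        raise ValueError(f"gene length must be a multiple of 3 and >= 9, got {length}")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    need = length // 3 - 2
    codons: list[str] = []
    while len(codons) < need:
        # draw in batches and reject stop codons
        batch = rng.choice(bases, size=(need - len(codons) + 8, 3), p=p)
        for row in batch:
            codon = "".join(row)
            if codon not in STOPS:
                codons.append(codon)
    stop = STOPS[int(rng.integers(len(STOPS)))]
    return "ATG" + "".join(codons[:need]) + stop


def _spacer(length: int, gc: float, rng: np.random.Generator) -> str:
    """Stop-rich spacer: STOP_BLOCK bookends with a random middle."""
    if length < 2 * len(STOP_BLOCK):
        reps = -(-length // len(STOP_BLOCK))
        return (STOP_BLOCK * reps)[:length]
    mid_len = length - 2 * len(STOP_BLOCK)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    mid = "".join(rng.choice(np.array(list("ACGT")), size=mid_len, p=p))
    return STOP_BLOCK + mid + STOP_BLOCK


def _first_occurrence_matrix(G: int) -> np.ndarray:
    """A[N-2, m-1] = P(family of multiplicity m first seen at position N)."""
    A = np.zeros((G - 1, G - 1))
    for j, m in enumerate(range(1, G)):
        def p_gt(n: int) -> float:
            return math.comb(G - m, n) / math.comb(G, n) if G - m >= n else 0.0
        for i, N in enumerate(range(2, G + 1)):
            A[i, j] = p_gt(N - 1) - p_gt(N)
    return A


def _largest_remainder(q: np.ndarray, total: int) -> np.ndarray:
    fl = np.floor(q).astype(int)
    short = total - int(fl.sum())
    order = np.argsort(-(q - fl), kind="stable")
    fl[order[:short]] += 1
    return fl


def accessory_layout(G: int, kappa: float, alpha: float) -> list[tuple[int, int]]:
    """Deterministic accessory-family plan: (first_genome, run_length) pairs.

    Genome g introduces exactly ``round(kappa * g**-alpha)`` families; each
    family occupies the consecutive genomes ``first .. first+run-1``.  Run
    lengths follow the NNLS-matched multiplicity spectrum, truncated per
    genome to the runs that fit before the panel ends.
    """
    sched = [_round_half_up(kappa * g ** (-alpha)) for g in range(1, G + 1)]
    if sum(sched) == 0:
        return []
    A = _first_occurrence_matrix(G)
    Ns = np.arange(2, G + 1, dtype=float)
    target = kappa * Ns ** (-alpha)
    spectrum, _ = nnls(A, target)
    if spectrum.sum() == 0:
        spectrum = np.ones(G - 1)
    plan: list[tuple[int, int]] = []
    for g, n_g in enumerate(sched, start=1):
        if n_g == 0:
            continue
        cap = G - g + 1
        pg = spectrum.copy()
        pg[cap:] = 0.0
        pg = pg / pg.sum()
        counts = _largest_remainder(pg * n_g, n_g)
        for j, cnt in enumerate(counts):
            plan.extend([(g, j + 1)] * int(cnt))
    return plan


def generate_pangenome(
    spec: PangenomeSpec,
) -> tuple[list[tuple[list[SeqRecord], AnnotationSet]], TruthTable]:
    """Generate the strain panel: one (records, truth annotation) per genome.

    Deterministic under ``spec.seed``.  Genome ids are ``G01``, ``G02``, ...;
    each genome is a single contig of genes separated by stop-rich spacers.
    Truth features carry the family id in their product field.
    """
    rng = np.random.default_rng(spec.seed)
    G = spec.n_genomes
    plan = accessory_layout(G, spec.kappa, spec.alpha_true)
    families: list[tuple[str, set[int]]] = []
    for i in range(spec.core_families):
        families.append((f"core_{i + 1:04d}", set(range(1, G + 1))))
    for i, (first, run) in enumerate(plan):
        families.append((f"acc_{i + 1:04d}", set(range(first, min(first + run, G + 1)))))
    if not families:
        raise ValueError("spec yields zero genes")

    lo, hi = spec.gene_len_range
    lengths = rng.integers(lo // 3, hi // 3 + 1, size=len(families)) * 3
    seqs = {
        fam: random_gene(int(n), spec.gc, rng)
        for (fam, _), n in zip(families, lengths)
    }

    truth = TruthTable()
    genomes: list[tuple[list[SeqRecord], AnnotationSet]] = []
    slo, shi = spec.spacer_len_range
    for g in range(1, G + 1):
        gid = f"G{g:02d}"
        present = [fam for fam, members in families if g in members]
        order = rng.permutation(len(present))
        parts: list[str] = []
        layout: list[tuple[str, int, int, str]] = []  # fam, start, end, strand
        pos = 0
        for idx in order:
            fam = present[idx]
            sp = _spacer(int(rng.integers(slo, shi + 1)), spec.gc, rng)
            parts.append(sp)
            pos += len(sp)
            gene = seqs[fam]
            strand = "+" if rng.random() < 0.5 else "-"
            parts.append(gene if strand == "+" else revcomp(gene))
            layout.append((fam, pos + 1, pos + len(gene), strand))
            pos += len(gene)
        parts.append(_spacer(int(rng.integers(slo, shi + 1)), spec.gc, rng))
        contig = SeqRecord(f"{gid}_chr", "".join(parts))
        ann = AnnotationSet(gid, [contig])
        for n, (fam, start, end, strand) in enumerate(layout, start=1):
            fid = f"{gid}_{n:05d}"
            ann.features.append(
                Feature(fid, contig.id, start, end, strand, product=fam)
            )
            truth.family_of_gene[fid] = fam
            truth.genomes_of_family.setdefault(fam, set()).add(gid)
        ann.validate()
        genomes.append(([contig], ann))
    return genomes, truth


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate == 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def simulate_reads(
    genome: list[SeqRecord], spec: ReadSimSpec
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Uniform-position fixed-length reads at the requested coverage.

    Per contig, ``ceil(coverage * length / read_len)`` reads are drawn
    (split across mates when paired); strands are uniform and substitution
    errors i.i.d. at ``error_rate``.  Contigs shorter than the read length
    are skipped with a warning.  Deterministic under ``spec.seed``.
    """
    import warnings

    rng = np.random.default_rng(spec.seed)
    rl = spec.read_len
    qual = "I" * rl
    reads1: list[ReadRecord] = []
    reads2: list[ReadRecord] = []
    for contig in genome:
        L = len(contig.sequence)
        if L < rl:
            warnings.warn(f"contig {contig.id} shorter than read_len; skipped", stacklevel=2)
            continue
        n_total = math.ceil(spec.coverage * L / rl)
        if not spec.paired:
            for i in range(n_total):
                start = int(rng.integers(0, L - rl + 1))
                frag = contig.sequence[start : start + rl]
                if rng.random() < 0.5:
                    frag = revcomp(frag)
                reads1.append(
                    ReadRecord(f"{contig.id}_r{i + 1}", _mutate(frag, spec.error_rate, rng), qual)
                )
            continue
        n_pairs = math.ceil(n_total / 2)
        for i in range(n_pairs):
            insert = int(round(rng.normal(spec.insert_mean, spec.insert_sd)))
            insert = max(rl, min(insert, L))
            start = int(rng.integers(0, L - insert + 1))
            frag = contig.sequence[start : start + insert]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            r1 = _mutate(frag[:rl], spec.error_rate, rng)
            r2 = _mutate(revcomp(frag[-rl:]), spec.error_rate, rng)
            base = f"{contig.id}_p{i + 1}"
            reads1.append(ReadRecord(f"{base}/1", r1, qual))
            reads2.append(ReadRecord(f"{base}/2", r2, qual))
    return reads1, reads2


def plant_missing_genes(
    genome: list[SeqRecord],
    truth: AnnotationSet,
    n_plant: int,
    rng: np.random.Generator,
) -> tuple[list[SeqRecord], list[SeqRecord], list[str]]:
    """Excise genes from the reference while keeping them in the read source.

    Returns ``(excised_reference, original_genome, planted_feature_ids)``;
    reads should be simulated from the original genome so the planted genes
    are represented only in reads.
    """
    if n_plant >= len(truth.features):
        raise ValueError(f"cannot plant {n_plant} of {len(truth.features)} genes")
    if n_plant == 0:
        return [SeqRecord(r.id, r.sequence, r.description) for r in genome], genome, []
    chosen_idx = sorted(rng.choice(len(truth.features), size=n_plant, replace=False))
    chosen = [truth.features[i] for i in chosen_idx]
    excised: list[SeqRecord] = []
    for rec in genome:
        spans = sorted(
            ((f.start, f.end) for f in chosen if f.contig_id == rec.id), reverse=True
        )
        seq = rec.sequence
        for start, end in spans:
            seq = seq[: start - 1] + seq[end:]
        excised.append(SeqRecord(rec.id, seq, rec.description))
    return excised, genome, [f.feature_id for f in chosen]
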