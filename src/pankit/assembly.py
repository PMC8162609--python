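"""De novo assembly of unmapped reads into unitig contigs.

A plain de Bruijn assembler: k-mers (k = 31 by default) are counted under
their canonical form, low-multiplicity k-mers and short dead-end tips are
pruned as error removal, and contigs are the maximal non-branching paths
(unitigs) of the bidirected graph.  There is no bubble popping, scaffolding
or paired-end distance use: downstream stages only need ORF-bearing contigs,
so unitigs suffice.

Output is deterministic and independent of read input order: k-mers are
iterated in lexicographic order and each unitig is emitted as the
lexicographically smaller of itself and its reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import ReadRecord, SeqRecord, revcomp

__all__ = ["DeBruijnGraph", "Contig", "build_graph", "prune", "extract_contigs"]

_BASES = "ACGT"


def _canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class DeBruijnGraph:
    """Canonical k-mer multiplicities; nodes are (k-1)-mers, edges k-mers."""

    k: int
    counts: dict[str, int] = field(default_factory=dict)

    def has(self, kmer: str) -> bool:
        return _canonical(kmer) in self.counts

    def fwd_exts(self, node: str) -> list[str]:
        """Bases b such that the edge node+b exists."""
        return [b for b in _BASES if self.has(node + b)]

    def bwd_exts(self, node: str) -> list[str]:
        return [b for b in _BASES if self.has(b + node)]


@dataclass
class Contig:
    contig_id: str
    sequence: str
    mean_kmer_coverage: float

    def __len__(self) -> int:
        return len(self.sequence)


def build_graph(reads: list[ReadRecord], k: int = 31) -> DeBruijnGraph:
    """Count every ACGT-only k-mer of every read under canonical form."""
    if k % 2 == 0:
        raise ValueError(f"k must be odd, got {k}")
    graph = DeBruijnGraph(k)
    counts = graph.counts
    for read in reads:
        seq = read.sequence
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:  # non-ACGT bases contribute no k-mer
                continue
            canon = _canonical(kmer)
            counts[canon] = counts.get(canon, 0) + 1
    return graph


def _unitigs(graph: DeBruijnGraph) -> list[str]:
    """Maximal non-branching paths, each k-mer consumed exactly once."""
    k = graph.k
    visited: set[str] = set()
    out: list[str] = []
    for start in sorted(graph.counts):
        if start in visited:
            continue
        visited.add(start)
        seq = start
        while True:  # rightward
            node = seq[-(k - 1):]
            f = graph.fwd_exts(node)
            if len(f) != 1:
                break
            nxt = node + f[0]
            if len(graph.bwd_exts(nxt[1:])) != 1:
                break
            canon = _canonical(nxt)
            if canon in visited:
                break
            visited.add(canon)
            seq += f[0]
        while True:  # leftward
            node = seq[: k - 1]
            b = graph.bwd_exts(node)
            if len(b) != 1:
                break
            prv = b[0] + node
            if len(graph.fwd_exts(prv[:-1])) != 1:
                break
            canon = _canonical(prv)
            if canon in visited:
                break
            visited.add(canon)
            seq = b[0] + seq
        out.append(min(seq, revcomp(seq)))
    return out


def prune(graph: DeBruijnGraph, min_count: int = 2, tip_len: int | None = None) -> DeBruijnGraph:
    """Remove low-count k-mers, then short dead-end tips, to a fixed point.

    A tip is a unitig shorter than *tip_len* (default 2k) attached to the rest
    of the graph at exactly one end; isolated short paths are kept (they are
    legitimate small contigs, subject to the later length filter).  The
    operation is idempotent on its own output.
    """
    k = graph.k
    if tip_len is None:
        tip_len = 2 * k
    kept = DeBruijnGraph(k, {km: c for km, c in graph.counts.items() if c >= min_count})
    while True:
        removed = False
        for seq in _unitigs(kept):
            if len(seq) >= tip_len:
                continue
            attached_left = bool(kept.bwd_exts(seq[: k - 1]))
            attached_right = bool(kept.fwd_exts(seq[-(k - 1):]))
            if attached_left != attached_right:  # dead at exactly one end
                for i in range(len(seq) - k + 1):
                    kept.counts.pop(_canonical(seq[i : i + k]), None)
                removed = True
        if not removed:
            break
    return kept


def extract_contigs(graph: DeBruijnGraph, min_len: int = 200) -> list[Contig]:
    """Emit unitigs at least *min_len* long, sorted by decreasing length."""
    k = graph.k
    contigs = []
    for seq in _unitigs(graph):
        if len(seq) < min_len:
            continue
        cov = sum(
            graph.counts[_canonical(seq[i : i + k])] for i in range(len(seq) - k + 1)
        ) / (len(seq) - k + 1)
        contigs.append((seq, cov))
    contigs.sort(key=lambda t: (-len(t[0]), t[0]))
    return [
        Contig(f"contig_{i + 1}", seq, cov) for i, (seq, cov) in enumerate(contigs)
    ]


def contigs_to_records(contigs: list[Contig]) -> list[SeqRecord]:
    return [
        SeqRecord(c.contig_id, c.sequence, f"mean_kmer_coverage={c.mean_kmer_coverage:.2f}")
        for c in contigs
    ]
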