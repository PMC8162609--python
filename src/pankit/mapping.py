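"""Partition reads into mapped/unmapped against a reference, and repair pairs.

Mapping is seed-and-ungapped-extend: canonical k-mer seeds are binned by
(contig, strand, diagonal); a read maps when some bin collects enough seeds
and the ungapped extension along that diagonal (clipped to contig bounds)
reaches the identity threshold over the read's aligned span.  The pipeline
only consumes the mapped/unmapped partition, so no alignments, mapping
qualities or SAM records are produced.  Gaps are not modelled: a read with an
indel relative to the reference may be called unmapped.

Pair repair separates mate-synchronized pairs from orphaned reads
(singletons) so that downstream assembly never sees half a pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .seqio import ReadRecord, SeqRecord, revcomp

__all__ = ["KmerIndex", "MapParams", "build_index", "classify_read", "partition_reads", "repair_pairs", "strip_mate_suffix"]


@dataclass
class MapParams:
    """Defaults chosen so error-free reads always map and foreign genes never do."""

    k: int = 21
    min_seed_hits: int = 2
    min_identity: float = 0.9

    def __post_init__(self) -> None:
        if self.k % 2 == 0 or not (15 <= self.k <= 31):
            raise ValueError(f"k must be odd and in [15, 31], got {self.k}")
        if self.min_seed_hits < 1:
            raise ValueError("min_seed_hits must be >= 1")
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must lie in (0, 1]")


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerIndex:
    """Postings of every reference k-mer position under its canonical form.

    Each posting is ``(contig_id, offset, is_forward)`` where ``is_forward``
    records whether the canonical form equals the contig's forward k-mer.
    """

    k: int
    postings: dict[str, list[tuple[str, int, bool]]] = field(default_factory=dict)
    contig_lengths: dict[str, int] = field(default_factory=dict)
    contig_seqs: dict[str, str] = field(default_factory=dict)


def build_index(reference: list[SeqRecord], k: int = 21) -> KmerIndex:
    """Index every position of every contig at least k long."""
    if k % 2 == 0:
        raise ValueError(f"k must be odd, got {k}")
    idx = KmerIndex(k)
    usable = 0
    for contig in reference:
        seq = contig.sequence
        if len(seq) < k:
            continue
        usable += 1
        idx.contig_lengths[contig.id] = len(seq)
        idx.contig_seqs[contig.id] = seq
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            canon = canonical(kmer)
            idx.postings.setdefault(canon, []).append((contig.id, i, canon == kmer))
    if usable == 0:
        raise ValueError(f"no contig reaches k={k}")
    return idx


def _diagonal_identity(read: str, contig: str, diag: int) -> float:
    """Ungapped identity of the read against the contig along one diagonal.

    ``diag`` is the contig offset of read position 0; the comparison is
    clipped to contig bounds and identity is taken over the aligned span.
    """
    lo = max(0, -diag)
    hi = min(len(read), len(contig) - diag)
    if hi <= lo:
        return 0.0
    matches = sum(1 for i in range(lo, hi) if read[i] == contig[diag + i])
    return matches / (hi - lo)


def classify_read(read: ReadRecord, index: KmerIndex, params: MapParams | None = None) -> str:
    """Return ``"mapped"`` or ``"unmapped"``."""
    params = params or MapParams()
    k = index.k
    seq = read.sequence
    if len(seq) < k:
        warnings.warn(f"read {read.id} shorter than k={k}; treated as unmapped", stacklevel=2)
        return "unmapped"
    bins: dict[tuple[str, str, int], int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        canon = canonical(kmer)
        postings = index.postings.get(canon)
        if not postings:
            continue
        read_forward = canon == kmer
        for contig_id, offset, ref_forward in postings:
            if read_forward == ref_forward:
                key = (contig_id, "+", offset - i)
            else:
                # reverse-strand hit: anti-diagonal is constant for colinear seeds
                key = (contig_id, "-", offset + i + k - 1)
            bins[key] = bins.get(key, 0) + 1
    for (contig_id, strand, diag), nseeds in sorted(
        bins.items(), key=lambda kv: (-kv[1], kv[0])
    ):
        if nseeds < params.min_seed_hits:
            break
        contig = index.contig_seqs[contig_id]
        if strand == "+":
            ident = _diagonal_identity(seq, contig, diag)
        else:
            rc = revcomp(seq)
            # read position j (in rc orientation) sits at contig offset
            # diag - (k - 1) - ... : recompute as forward diagonal of rc read
            ident = _diagonal_identity(rc, contig, diag - len(seq) + 1)
        if ident >= params.min_identity:
            return "mapped"
    return "unmapped"


def strip_mate_suffix(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def partition_reads(
    reads1: list[ReadRecord],
    reads2: list[ReadRecord],
    index: KmerIndex,
    params: MapParams | None = None,
) -> tuple[list[ReadRecord], list[ReadRecord], list[ReadRecord], dict[str, int]]:
    """Split reads into unmapped pairs, unmapped singletons, and counts.

    Single-end input (``reads2`` empty): every unmapped read becomes a
    singleton.  Paired input: a pair with both mates unmapped is kept as a
    pair; a pair with exactly one unmapped mate routes that mate to
    singletons (never feeding a mapped read to assembly).
    """
    params = params or MapParams()
    counts = {"total": len(reads1) + len(reads2), "mapped": 0, "unmapped_pair_reads": 0, "singletons": 0}
    up1: list[ReadRecord] = []
    up2: list[ReadRecord] = []
    singles: list[ReadRecord] = []
    if not reads2:
        for r in reads1:
            if classify_read(r, index, params) == "mapped":
                counts["mapped"] += 1
            else:
                singles.append(r)
        counts["singletons"] = len(singles)
        return up1, up2, singles, counts
    if len(reads1) != len(reads2):
        raise ValueError(f"paired files differ in length: {len(reads1)} vs {len(reads2)}")
    for r1, r2 in zip(reads1, reads2):
        if strip_mate_suffix(r1.id) != strip_mate_suffix(r2.id):
            raise ValueError(f"pair files out of sync at read {r1.id!r} / {r2.id!r}")
        m1 = classify_read(r1, index, params) == "mapped"
        m2 = classify_read(r2, index, params) == "mapped"
        if m1 and m2:
            counts["mapped"] += 2
        elif not m1 and not m2:
            up1.append(r1)
            up2.append(r2)
        else:
            counts["mapped"] += 1
            singles.append(r2 if m1 else r1)
    counts["unmapped_pair_reads"] = len(up1) + len(up2)
    counts["singletons"] = len(singles)
    return up1, up2, singles, counts


def repair_pairs(
    r1: list[ReadRecord], r2: list[ReadRecord]
) -> tuple[list[ReadRecord], list[ReadRecord], list[ReadRecord]]:
    """Split two read lists into id-synchronized pairs plus singletons.

    Ids are matched after stripping ``/1``/``/2`` mate suffixes; paired output
    follows r1 order.  Duplicate ids within one file are an error.
    """
    def by_id(reads: list[ReadRecord], which: str) -> dict[str, ReadRecord]:
        out: dict[str, ReadRecord] = {}
        for r in reads:
            key = strip_mate_suffix(r.id)
            if key in out:
                raise ValueError(f"duplicate read id {key!r} in {which}")
            out[key] = r
        return out

    map1, map2 = by_id(r1, "r1"), by_id(r2, "r2")
    paired1, paired2, singles = [], [], []
    for r in r1:
        key = strip_mate_suffix(r.id)
        if key in map2:
            paired1.append(r)
            paired2.append(map2[key])
        else:
            singles.append(r)
    for r in r2:
        if strip_mate_suffix(r.id) not in map1:
            singles.append(r)
    return paired1, paired2, singles


def write_mapping_summary(counts: dict[str, int], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tcount\n")
        for key in ("total", "mapped", "unmapped_pair_reads", "singletons"):
            fh.write(f"{key}\t{counts[key]}\n")
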