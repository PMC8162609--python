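"""Independent reference implementations used to cross-check the package.

These deliberately avoid the code paths they verify: the alignment oracle is
a plain three-state Gotoh DP (the package delegates to Biopython's C
aligner), the ORF oracle is a direct six-frame scan, the clustering oracle is
union-find over an all-pairs hit list, and the curve oracle computes
pan/core/new by explicit set operations per order.
"""

from __future__ import annotations

import itertools

from Bio.Align import substitution_matrices

from pankit.similarity import ScoringScheme, Thresholds, evalue, local_align

BLOSUM62 = substitution_matrices.load("BLOSUM62")
STOPS = ("TAA", "TAG", "TGA")
START_CODONS = ("ATG", "GTG", "TTG")
_COMP = str.maketrans("ACGTN", "TGCAN")


def gotoh_local_score(a: str, b: str, scheme: ScoringScheme) -> int:
    """Optimal affine-gap local alignment score by a hand-written DP."""
    def s(x, y):
        if scheme.mode == "protein":
            return int(BLOSUM62[x][y])
        return scheme.match if x == y else scheme.mismatch

    go, ge = scheme.gap_open + scheme.gap_extend, scheme.gap_extend
    n, m = len(a), len(b)
    NEG = -(10 ** 9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - go, E[i][j - 1] - ge)
            F[i][j] = max(H[i - 1][j] - go, F[i - 1][j] - ge)
            H[i][j] = max(0, H[i - 1][j - 1] + s(a[i - 1], b[j - 1]), E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def brute_force_orfs(seq: str, min_orf_nt: int) -> set[tuple[int, int, str]]:
    """Six-frame ORF scan: (start, end, strand), 1-based inclusive."""
    out = set()
    rc = seq.translate(_COMP)[::-1]
    for strand, s in (("+", seq), ("-", rc)):
        L = len(s)
        for frame in range(3):
            start = None
            for p in range(frame, L - 2, 3):
                codon = s[p : p + 3]
                if codon in STOPS:
                    if start is not None and p + 3 - start >= min_orf_nt:
                        if strand == "+":
                            out.add((start + 1, p + 3, "+"))
                        else:
                            out.add((L - (p + 3) + 1, L - start, "-"))
                    start = None
                elif start is None and codon in START_CODONS:
                    start = p
    return out


def union_find_clusters(
    tagged: list[tuple[str, str, str]],
    scheme: ScoringScheme,
    thr: Thresholds,
) -> set[frozenset[tuple[str, str]]]:
    """All-pairs hits + union-find over (genome_id, feature_id, sequence)."""
    parent = list(range(len(tagged)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    db_len = sum(len(t[2]) for t in tagged)
    for i, j in itertools.combinations(range(len(tagged)), 2):
        h = local_align(tagged[i][2], tagged[j][2], scheme)
        if h is None:
            continue
        ev = evalue(h.score, len(tagged[i][2]), db_len, scheme)
        if (
            ev <= thr.max_evalue
            and h.identity >= thr.min_identity
            and max(h.q_coverage, h.s_coverage) >= thr.min_coverage
        ):
            parent[find(i)] = find(j)
    groups: dict[int, set[tuple[str, str]]] = {}
    for i, (gid, fid, _) in enumerate(tagged):
        groups.setdefault(find(i), set()).add((gid, fid))
    return {frozenset(g) for g in groups.values()}


def curves_by_set_ops(patterns: list[set[str]], order: list[str]):
    """pan/core/new per N for one genome order, by explicit set operations."""
    out = []
    seen_families: set[int] = set()
    for n in range(1, len(order) + 1):
        prefix = set(order[:n])
        pan_fams = {i for i, p in enumerate(patterns) if p & prefix}
        core = sum(1 for p in patterns if prefix <= p)
        new = len(pan_fams - seen_families)
        seen_families = pan_fams
        out.append((n, len(pan_fams), core, new))
    return out
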