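import itertools
import math

import numpy as np
import pandas as pd
import pytest

from oracles import union_find_clusters

from pankit import pangenome as pg
from pankit.annotation import translate
from pankit.seqio import SeqRecord
from pankit.similarity import ScoringScheme, Thresholds, evalue, local_align

AA = "ACDEFGHIKLMNPQRSTVWY"


def _matrix_from_patterns(patterns, genome_ids):
    """PanMatrix from binary presence rows (one gene per present genome)."""
    clusters = [
        {(g, f"g{i}_{g}") for g in genomes} for i, genomes in enumerate(patterns)
    ]
    return pg.pan_matrix(pg.GeneFamilyClusters(clusters), genome_ids)


# toy with clusters {core:2, g1-only:1, g1&g2:1}
TOY = _matrix_from_patterns(
    [{"g1", "g2", "g3"}, {"g1", "g2", "g3"}, {"g1"}, {"g1", "g2"}],
    ["g1", "g2", "g3"],
)


class TestClusterGeneFamilies:
    def test_identical_proteins_one_cluster(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list(AA), size=120))
        sets = {g: [SeqRecord(f"{g}_1", seq)] for g in ("a", "b", "c")}
        clusters = pg.cluster_gene_families(sets)
        assert len(clusters.clusters) == 1 and len(clusters.clusters[0]) == 3

    def test_single_linkage_transitivity(self):
        rng = np.random.default_rng(1)
        a = "".join(rng.choice(list(AA), size=100))
        b = list(a)
        for p in rng.choice(100, size=12, replace=False):
            b[p] = AA[int(rng.integers(20))]
        b = "".join(b)
        c = list(b)
        for p in rng.choice(100, size=12, replace=False):
            c[p] = AA[int(rng.integers(20))]
        c = "".join(c)
        sets = {"ga": [SeqRecord("A", a)], "gb": [SeqRecord("B", b)], "gc": [SeqRecord("C", c)]}
        thr = Thresholds(1e-5, 0.7, 0.7)
        clusters = pg.cluster_gene_families(sets, thresholds=thr)
        # a-b and b-c are within threshold; a-c may not be, but single
        # linkage must still merge all three if both edges exist
        scheme = ScoringScheme.protein()
        def hit(x, y):
            h = local_align(x, y, scheme)
            if h is None:
                return False
            ev = evalue(h.score, len(x), 300, scheme)
            return ev <= thr.max_evalue and h.identity >= thr.min_identity and max(h.q_coverage, h.s_coverage) >= thr.min_coverage
        if hit(a, b) and hit(b, c):
            assert len(clusters.clusters) == 1

    def test_matches_union_find_oracle_on_random_instances(self):
        """Components equal a brute-force union-find over all-pairs hits."""
        rng = np.random.default_rng(2)
        scheme = ScoringScheme.protein()
        thr = Thresholds()
        for inst in range(20):
            n_genomes = int(rng.integers(2, 4))
            base = ["".join(rng.choice(list(AA), size=60)) for _ in range(3)]
            sets = {}
            tags = []
            for g in range(n_genomes):
                gid = f"g{g}"
                prots = []
                for j in range(int(rng.integers(1, 4))):
                    if rng.random() < 0.6:  # mutated copy of a base protein
                        seq = list(base[int(rng.integers(3))])
                        for p in rng.choice(60, size=6, replace=False):
                            seq[p] = AA[int(rng.integers(20))]
                        seq = "".join(seq)
                    else:
                        seq = "".join(rng.choice(list(AA), size=60))
                    prots.append(SeqRecord(f"p{j}", seq))
                    tags.append((gid, f"p{j}", seq))
                sets[gid] = prots
            got = {frozenset(c) for c in pg.cluster_gene_families(sets, scheme, thr).clusters}
            expected = union_find_clusters(tags, scheme, thr)
            assert got == expected, f"instance {inst}"

    def test_panel_clusters_equal_truth_families(self, small_panel):
        genomes, truth = small_panel
        sets = {
            ann.genome_id: [
                SeqRecord(f.feature_id, translate(ann.feature_nuc(f)))
                for f in ann.features
            ]
            for _, ann in genomes
        }
        clusters = pg.cluster_gene_families(sets)
        matrix = pg.pan_matrix(clusters, [ann.genome_id for _, ann in genomes])
        truth_patterns = sorted(
            tuple(sorted(v)) for v in truth.genomes_of_family.values()
        )
        got_patterns = sorted(
            tuple(sorted(np.array(matrix.genome_ids)[row])) for row in matrix.presence
        )
        assert got_patterns == truth_patterns


class TestPanMatrix:
    def test_gene_count_conserved(self, small_panel):
        genomes, truth = small_panel
        sets = {
            ann.genome_id: [
                SeqRecord(f.feature_id, translate(ann.feature_nuc(f)))
                for f in ann.features
            ]
            for _, ann in genomes
        }
        matrix = pg.pan_matrix(
            pg.cluster_gene_families(sets), [ann.genome_id for _, ann in genomes]
        )
        assert matrix.counts.to_numpy().sum() == sum(
            len(ann.features) for _, ann in genomes
        )

    def test_identical_genomes_core_rows_only(self):
        m = _matrix_from_patterns([{"a", "b"}, {"a", "b"}], ["a", "b"])
        assert (m.presence.sum(axis=1) == 2).all()


class TestSampleCurves:
    def test_exhaustive_enumeration_below_threshold(self):
        samples = pg.sample_curves(TOY, n_perms=5, seed=0)
        assert max(s.perm_id for s in samples) + 1 == math.factorial(3)

    def test_identical_genomes_flat_curves(self):
        m = _matrix_from_patterns([{"a", "b", "c"}] * 4, ["a", "b", "c"])
        for s in pg.sample_curves(m, 10, 0):
            assert s.pan == s.core == 4
            assert s.new == (4 if s.N == 1 else 0)

    def test_pan_at_g_order_free(self):
        samples = pg.sample_curves(TOY, 10, 0)
        finals = {s.pan for s in samples if s.N == 3}
        assert finals == {4}

    def test_curve_identities_per_permutation(self):
        samples = pg.sample_curves(TOY, 10, 0)
        by_perm = {}
        for s in samples:
            by_perm.setdefault(s.perm_id, []).append(s)
        for perm in by_perm.values():
            perm.sort(key=lambda s: s.N)
            assert perm[0].pan == perm[0].core == perm[0].new
            for prev, cur in zip(perm, perm[1:]):
                assert cur.pan - prev.pan == cur.new
                assert cur.pan >= prev.pan and cur.core <= prev.core

    def test_toy_median_pan_matches_hand_enumeration(self):
        # orders of (g1,g2,g3); pan after 2 genomes: g1g2/g2g1 -> 4,
        # g1g3/g3g1 -> 4, g2g3/g3g2 -> 3; median of [4,4,4,4,3,3] = 4
        samples = pg.sample_curves(TOY, 10, 0)
        pans_at_2 = [s.pan for s in samples if s.N == 2]
        assert sorted(pans_at_2) == [3, 3, 4, 4, 4, 4]
        assert float(np.median(pans_at_2)) == 4.0


class TestFitHeapsLaw:
    def _samples_from_series(self, series):
        # one permutation whose new(N) is the given exact series
        out = []
        pan = 0
        for n, v in enumerate(series, start=1):
            pan += v
            out.append(pg.CurveSample(0, n, pan, 0, v))
        return out

    def test_exact_power_law_recovered(self):
        series = [500] + [100 * n ** -0.5 for n in range(2, 9)]
        samples = self._samples_from_series(series)
        fit = pg.fit_heaps_law(samples, "median")
        assert fit.alpha == pytest.approx(0.5, abs=1e-9)
        assert fit.kappa == pytest.approx(100, rel=1e-9)
        assert fit.rss == pytest.approx(0, abs=1e-12)
        assert fit.verdict == "open"

    def test_all_zero_news_degenerate(self):
        samples = self._samples_from_series([10, 0, 0, 0])
        fit = pg.fit_heaps_law(samples)
        assert fit.verdict == "degenerate" and fit.alpha == math.inf

    def test_closed_verdict_for_steep_decay(self):
        series = [500] + [1000 * n ** -2.0 for n in range(2, 9)]
        fit = pg.fit_heaps_law(self._samples_from_series(series))
        assert fit.verdict == "closed" and fit.alpha > 1

    def test_alpha_recovery_on_generated_panel(self):
        from pankit.synthetic_data import PangenomeSpec, generate_pangenome

        genomes, truth = generate_pangenome(
            PangenomeSpec(n_genomes=12, core_families=30, kappa=60, alpha_true=0.45, seed=3)
        )
        gids = [ann.genome_id for _, ann in genomes]
        clusters = pg.GeneFamilyClusters(
            [
                {(g, fam) for g in members}
                for fam, members in sorted(truth.genomes_of_family.items())
            ]
        )
        matrix = pg.pan_matrix(clusters, gids)
        samples = pg.sample_curves(matrix, 500, seed=4)
        fit = pg.fit_heaps_law(samples, "median")
        assert fit.alpha == pytest.approx(0.45, abs=0.05)
        assert fit.verdict == "open"


class TestUniqueAndShared:
    def test_identical_genomes_no_uniques(self):
        m = _matrix_from_patterns([{"a", "b"}] * 3, ["a", "b"])
        assert pg.unique_genes(m) == {"a": 0, "b": 0}

    def test_private_singletons_counted(self):
        m = _matrix_from_patterns([{"a"}, {"a"}, {"a"}, {"a", "b"}], ["a", "b"])
        assert pg.unique_genes(m) == {"a": 3, "b": 0}

    def test_panel_uniques_match_truth(self, small_panel):
        genomes, truth = small_panel
        gids = [ann.genome_id for _, ann in genomes]
        clusters = pg.GeneFamilyClusters(
            [
                {(g, fam) for g in members}
                for fam, members in sorted(truth.genomes_of_family.items())
            ]
        )
        matrix = pg.pan_matrix(clusters, gids)
        expected = {g: 0 for g in gids}
        for fam, members in truth.genomes_of_family.items():
            if len(members) == 1:
                expected[next(iter(members))] += 1
        assert pg.unique_genes(matrix) == expected

    def test_shared_distribution_toy(self):
        assert pg.shared_distribution(TOY) == {3: 2, 2: 1, 1: 1}

    def test_shared_distribution_conserves_clusters(self, small_panel):
        genomes, truth = small_panel
        gids = [ann.genome_id for _, ann in genomes]
        clusters = pg.GeneFamilyClusters(
            [
                {(g, fam) for g in members}
                for fam, members in sorted(truth.genomes_of_family.items())
            ]
        )
        matrix = pg.pan_matrix(clusters, gids)
        assert sum(pg.shared_distribution(matrix).values()) == len(clusters.clusters)


class TestDistancesAndTrees:
    def test_identical_genomes_zero_distance(self):
        m = _matrix_from_patterns([{"a", "b", "c"}] * 3, ["a", "b", "c"])
        d = pg.pan_distance_matrix(m)
        assert np.allclose(d.to_numpy(), 0)

    def test_disjoint_genomes_distance_one(self):
        m = _matrix_from_patterns([{"a"}, {"b"}, {"c"}], ["a", "b", "c"])
        d = pg.pan_distance_matrix(m).to_numpy()
        assert np.allclose(d[~np.eye(3, dtype=bool)], 1.0)

    def test_triangle_inequality_random_sweep(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            P = rng.random((15, 4)) < 0.5
            P[:, 0] |= ~P.any(axis=1)  # no empty genomes
            m = _matrix_from_patterns(
                [
                    {f"g{j}" for j in range(4) if P[i, j]}
                    for i in range(15)
                ],
                [f"g{j}" for j in range(4)],
            )
            D = pg.pan_distance_matrix(m).to_numpy()
            for a, b, c in itertools.permutations(range(4), 3):
                assert D[a, c] <= D[a, b] + D[b, c] + 1e-12

    def test_upgma_textbook_example(self):
        d = pd.DataFrame(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        nwk = pg.build_tree(d, "upgma")
        assert nwk.replace(" ", "") in ("((a:1,b:1):1,c:2);", "(c:2,(a:1,b:1):1);")

    def test_tree_leaves_equal_genome_set(self, small_panel):
        genomes, truth = small_panel
        gids = [ann.genome_id for _, ann in genomes]
        clusters = pg.GeneFamilyClusters(
            [
                {(g, fam) for g in members}
                for fam, members in sorted(truth.genomes_of_family.items())
            ]
        )
        d = pg.pan_distance_matrix(pg.pan_matrix(clusters, gids))
        for method in ("nj", "upgma"):
            nwk = pg.build_tree(d, method)
            import re

            leaves = set(re.findall(r"G\d+", nwk))
            assert leaves == set(gids)

    def test_nj_recovers_additive_topology(self):
        # tree ((a,b),(c,d)) with internal edge 3: additive distances
        d = pd.DataFrame(
            [
                [0, 2, 7, 7],
                [2, 0, 7, 7],
                [7, 7, 0, 2],
                [7, 7, 2, 0],
            ],
            index=list("abcd"), columns=list("abcd"), dtype=float,
        )
        nwk = pg.build_tree(d, "nj")
        import dendropy

        tree = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert pdm.distance(taxa["a"], taxa["b"]) == pytest.approx(2)
        assert pdm.distance(taxa["c"], taxa["d"]) == pytest.approx(2)
        assert pdm.distance(taxa["a"], taxa["c"]) == pytest.approx(7)

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame([[0, 1, 2], [9, 0, 1], [2, 1, 0]], index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError, match="symmetric"):
            pg.build_tree(d)
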