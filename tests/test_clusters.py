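"""Expression programs, set statistics and PWM scanning."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from sklearn.metrics import adjusted_rand_score

from pausekit.annotation import GeneModel
from pausekit.clusters import (PWM, ClusterAssignment, biotype_composition,
                               divergent_pairs, kmeans_cluster,
                               length_comparison, overlap_test, pwm_scan,
                               read_pwm, representation_score,
                               score_distribution, write_pwm)
from pausekit.quantify import relative_matrix
from pausekit.simulate import ARCHETYPES


def _assignment(labels: dict) -> ClusterAssignment:
    s = pd.Series(labels, name="cluster")
    k = s.max()
    cent = pd.DataFrame(np.zeros((k, 3)), index=pd.RangeIndex(1, k + 1))
    return ClusterAssignment(labels=s, centroids=cent,
                             relmat=pd.DataFrame(index=s.index))


class TestKmeans:
    def test_k1_centroid_is_column_mean(self, rng):
        mat = pd.DataFrame(rng.random((40, 3)), columns=list("abc"))
        asg = kmeans_cluster(mat, k=1, seed=0)
        np.testing.assert_allclose(asg.centroids.iloc[0], mat.mean(axis=0))
        assert (asg.labels == 1).all()

    def test_six_planted_archetypes_recovered(self, rng):
        prog = rng.integers(0, 6, 1200)
        noisy = ARCHETYPES[prog] * np.exp(rng.normal(0, 0.05, (1200, 3)))
        relmat = relative_matrix(pd.DataFrame(noisy, columns=["SG", "SC", "RS"]))
        asg = kmeans_cluster(relmat, k=6, seed=0)
        assert adjusted_rand_score(prog, asg.labels.values) >= 0.9

    def test_same_seed_gives_identical_labels(self, rng):
        mat = pd.DataFrame(rng.random((100, 3)))
        a = kmeans_cluster(mat, k=4, seed=3)
        b = kmeans_cluster(mat, k=4, seed=3)
        pd.testing.assert_series_equal(a.labels, b.labels)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans_cluster(pd.DataFrame(np.ones((3, 2))), k=6, seed=0)

    def test_centroid_equals_mean_of_members(self, rng):
        mat = pd.DataFrame(rng.random((60, 3)), columns=list("abc"))
        asg = kmeans_cluster(mat, k=3, seed=1)
        for c in (1, 2, 3):
            np.testing.assert_allclose(
                asg.centroids.loc[c], mat.loc[asg.members(c)].mean(axis=0),
                atol=1e-9)


class TestBiotypeComposition:
    def _genes(self, biotypes):
        return [GeneModel(f"g{i}", "c", "+", 0, 100, b)
                for i, b in enumerate(biotypes)]

    def test_single_biotype_is_100_percent(self):
        genes = self._genes(["protein_coding"] * 4)
        asg = _assignment({f"g{i}": 1 for i in range(4)})
        comp = biotype_composition(asg, genes)
        assert comp.loc[1, "protein_coding"] == 100.0

    def test_percentages_sum_to_100_per_cluster(self, rng):
        bts = rng.choice(["protein_coding", "lncRNA", "other"], 60)
        genes = self._genes(bts)
        asg = _assignment({f"g{i}": int(rng.integers(1, 4)) for i in range(60)})
        comp = biotype_composition(asg, genes)
        np.testing.assert_allclose(comp.sum(axis=1), 100.0)

    def test_invariant_to_gene_order(self, rng):
        bts = rng.choice(["protein_coding", "lncRNA"], 30)
        genes = self._genes(bts)
        asg = _assignment({f"g{i}": 1 + i % 2 for i in range(30)})
        a = biotype_composition(asg, genes)
        b = biotype_composition(asg, genes[::-1])
        pd.testing.assert_frame_equal(a, b)

    def test_printed_lncrna_share_arithmetic(self):
        """762 lncRNA of 1986 genes -> 38.4% to one decimal."""
        genes = self._genes(["lncRNA"] * 762 + ["protein_coding"] * (1986 - 762))
        asg = _assignment({f"g{i}": 1 for i in range(1986)})
        comp = biotype_composition(asg, genes)
        assert round(comp.loc[1, "lncRNA"], 1) == 38.4


class TestLengthComparison:
    def _setup(self, lengths_by_cluster):
        genes, labels = [], {}
        i = 0
        for c, lengths in lengths_by_cluster.items():
            for L in lengths:
                genes.append(GeneModel(f"g{i}", "c", "+", 0, int(L) - 1))
                labels[f"g{i}"] = c
                i += 1
        return genes, _assignment(labels)

    def test_disjoint_supports_exact_p(self):
        # n=5 vs 5 with completely separated lengths: two-sided exact
        # p = 2 * 1/C(10,5) = 2/252
        genes, asg = self._setup({1: [100, 110, 120, 130, 140],
                                  2: [1000, 1100, 1200, 1300, 1400]})
        out = length_comparison(asg, genes, focal_cluster=1)
        assert out.loc[2, "p"] == pytest.approx(2 / comb(10, 5, exact=True))

    def test_swapping_groups_leaves_p_unchanged(self, rng):
        genes, asg = self._setup({1: rng.integers(500, 5000, 12),
                                  2: rng.integers(500, 5000, 15)})
        p12 = length_comparison(asg, genes, focal_cluster=1).loc[2, "p"]
        p21 = length_comparison(asg, genes, focal_cluster=2).loc[1, "p"]
        assert p12 == pytest.approx(p21)

    def test_identical_distributions_not_significant_on_permuted_halves(self, rng):
        pool = rng.lognormal(8, 0.5, 400).astype(int) + 300
        ps = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            perm = r.permutation(pool)
            genes, asg = self._setup({1: perm[:200], 2: perm[200:]})
            ps.append(length_comparison(asg, genes, focal_cluster=1).loc[2, "p"])
        assert 0.2 < np.mean(ps) < 0.8  # p roughly uniform under the null


class TestDivergentPairs:
    def _genes(self):
        return [
            GeneModel("m1", "c", "+", 10_000, 20_000, "protein_coding"),
            GeneModel("l1", "c", "-", 9_200, 8_000, "lncRNA"),    # 800 nt away
            GeneModel("m2", "c", "+", 50_000, 60_000, "protein_coding"),
            GeneModel("l2", "c", "-", 48_800, 47_000, "lncRNA"),  # 1200 nt away
            GeneModel("l3", "c", "+", 70_000, 72_000, "lncRNA"),  # sense: no pair
            GeneModel("m3", "c", "+", 68_500, 69_500, "protein_coding"),
        ]

    def test_antisense_within_1kb_detected_beyond_not(self):
        genes = self._genes()
        asg = _assignment({g.gene_id: 6 for g in genes})
        pairs = divergent_pairs(genes, asg, focal_cluster=6)
        assert ("m1", "l1") in pairs
        assert all(l != "l2" for _, l in pairs)
        assert all(l != "l3" for _, l in pairs)

    def test_no_lncrnas_gives_empty(self):
        genes = [g for g in self._genes() if g.biotype != "lncRNA"]
        asg = _assignment({g.gene_id: 6 for g in genes})
        assert divergent_pairs(genes, asg, focal_cluster=6) == []

    def test_members_must_share_the_focal_cluster(self):
        genes = self._genes()
        labels = {g.gene_id: 6 for g in genes}
        labels["m1"] = 1
        pairs = divergent_pairs(genes, _assignment(labels), focal_cluster=6)
        assert all(m != "m1" for m, _ in pairs)

    def test_planted_pairs_recovered_from_truth(self, small_truth):
        _, truth = small_truth
        g = truth.genes
        planted = {(row["paired_with"], gid)
                   for gid, row in g[g["paired_with"] != ""].iterrows()}
        labels = {gid: (6 if row["program"] == 6 else 1)
                  for gid, row in g.iterrows()}
        pairs = divergent_pairs(truth.gene_models(annotated=False),
                                _assignment(labels), focal_cluster=6)
        assert planted <= set(pairs)


class TestRepresentationScore:
    def test_uniform_de_draw_scores_near_one(self, rng):
        labels = {f"g{i}": int(rng.integers(1, 5)) for i in range(2000)}
        asg = _assignment(labels)
        de = set(rng.choice(list(labels), 400, replace=False))
        scores = representation_score(de, asg)
        assert (scores - 1).abs().max() < 0.25

    def test_concentrated_de_scores_inverse_cluster_share(self):
        labels = {f"g{i}": 1 + i // 25 for i in range(100)}  # 4 x 25 genes
        asg = _assignment(labels)
        de = {f"g{i}" for i in range(10)}  # all inside cluster 1 (25% share)
        scores = representation_score(de, asg)
        assert scores[1] == pytest.approx(4.0)
        assert scores[2] == 0.0

    def test_size_weighted_mean_is_one(self, rng):
        labels = {f"g{i}": int(rng.integers(1, 6)) for i in range(500)}
        asg = _assignment(labels)
        de = set(rng.choice(list(labels), 60, replace=False))
        scores = representation_score(de, asg)
        sizes = asg.sizes()
        weighted = (scores * sizes / sizes.sum()).sum()
        assert weighted == pytest.approx(1.0)

    def test_empty_de_set_is_an_error(self):
        asg = _assignment({"g0": 1})
        with pytest.raises(ValueError):
            representation_score(set(), asg)


class TestOverlapTest:
    def test_matches_exhaustive_enumeration_small_universe(self, rng):
        """P(overlap >= k) equals exact enumeration over all draws of B for
        every universe <= 12."""
        for universe in (6, 9, 12):
            items = [f"x{i}" for i in range(universe)]
            for trial in range(8):
                na, nb = rng.integers(1, universe + 1, 2)
                A = set(rng.choice(items, na, replace=False))
                B = set(rng.choice(items, nb, replace=False))
                obs, p = overlap_test(A, B, universe)
                hits = sum(1 for combo in itertools.combinations(items, nb)
                           if len(A & set(combo)) >= obs)
                exact = hits / comb(universe, nb, exact=True)
                assert p == pytest.approx(exact, abs=1e-12)

    def test_complete_overlap_has_p_one(self):
        U = {"a", "b", "c"}
        obs, p = overlap_test(U, U, 3)
        assert obs == 3 and p == pytest.approx(1.0)

    def test_p_decreases_as_overlap_grows_at_fixed_margins(self):
        from scipy.stats import hypergeom
        ps = [float(hypergeom.sf(k - 1, 100, 20, 30)) for k in range(0, 15)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestPwmScan:
    def _pwm(self, consensus="TATAAA", strength=0.85):
        rows = []
        for b in consensus:
            row = np.full(4, (1 - strength) / 3)
            row["ACGT".index(b)] = strength
            rows.append(row)
        return PWM(probs=np.array(rows), name="toy")

    def test_score_distribution_matches_word_enumeration(self):
        """Exact upper-tail p-values equal brute force over all 4^L words."""
        pwm = self._pwm("TACG", 0.7)
        lo = pwm.log_odds()
        words = itertools.product(range(4), repeat=pwm.length)
        brute = {}
        for w in words:
            s = 0.0
            for i, j in enumerate(w):
                s += lo[i, j]
            brute[s] = brute.get(s, 0.0) + 0.25 ** pwm.length
        scores, upper = score_distribution(pwm)
        for s in brute:
            i = int(np.searchsorted(scores, s))
            expected = sum(p for t, p in brute.items() if t >= s)
            assert upper[i] == pytest.approx(expected, abs=1e-12)

    def test_consensus_word_has_minimal_p(self):
        pwm = self._pwm()
        scores, upper = score_distribution(pwm)
        # P(score >= max) = product of consensus base probabilities under
        # uniform background
        assert upper[-1] == pytest.approx(0.25 ** pwm.length, abs=1e-15)

    def test_designed_motif_free_sequence_has_no_matches(self):
        pwm = self._pwm("TATAAA")
        table, pct = pwm_scan({"g1": "CGCGCGCGCGCGCGCGCGCG"}, pwm, p_thr=0.005)
        assert table.loc["g1", "n_matches"] == 0
        assert pct == 0.0

    def test_consensus_containing_sequence_matches(self):
        pwm = self._pwm("TATAAA")
        table, pct = pwm_scan({"g1": "CCCCTATAAACCCC", "g2": "GGGGGGGGGGGGGG"},
                              pwm, p_thr=0.005)
        assert table.loc["g1", "n_matches"] >= 1
        assert pct == 50.0

    def test_no_sequences_is_an_error(self):
        with pytest.raises(ValueError):
            pwm_scan({}, self._pwm())

    def test_sequence_shorter_than_motif_warned_and_skipped(self):
        with pytest.warns(UserWarning, match="shorter"):
            table, _ = pwm_scan({"short": "AC", "ok": "CCCCTATAAACCCC"},
                                self._pwm(), p_thr=0.005)
        assert list(table.index) == ["ok"]

    def test_pwm_file_roundtrip(self, tmp_path):
        pwm = self._pwm("TATAAA")
        write_pwm(pwm, tmp_path / "m.txt")
        back = read_pwm(tmp_path / "m.txt")
        assert back.name == "toy"
        np.testing.assert_allclose(back.probs, pwm.probs, atol=1e-3)

    def test_zero_probability_cells_rejected(self):
        with pytest.raises(ValueError, match="pseudocount|zero"):
            PWM(probs=np.array([[1.0, 0.0, 0.0, 0.0]]))
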