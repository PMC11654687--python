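"""Genetics operations against hand-executed and closed-form oracles."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from impactmodes.genetics import (
    clump,
    compute_pgs,
    hwe_test,
    ld_r2,
    optimize_pgs,
    pgs_grid,
    prune_relatedness,
    qc_filter,
)
from impactmodes.types import DataError, SummaryStats

from conftest import toy_genotypes


def hwe_oracle(n_AA, n_Aa, n_aa):
    """Independent chi-square goodness-of-fit computation."""
    n = n_AA + n_Aa + n_aa
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    chi2 = ((np.array([n_AA, n_Aa, n_aa]) - exp) ** 2 / exp).sum()
    return float(stats.chi2.sf(chi2, 1))


class TestHwe:
    def test_exact_proportions_give_p_one(self):
        assert hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_extreme_departure(self):
        # (50, 0, 50): expected 25/50/25, chi2 = 100
        p = hwe_test(50, 0, 50)
        assert p == pytest.approx(float(stats.chi2.sf(100.0, 1)), rel=1e-10)
        assert p == pytest.approx(1.52e-23, rel=0.01)

    def test_monomorphic_degenerate(self):
        assert hwe_test(100, 0, 0) == 1.0
        assert hwe_test(0, 0, 37) == 1.0

    def test_negative_counts_error(self):
        with pytest.raises(DataError):
            hwe_test(-1, 5, 5)

    @given(
        st.tuples(
            st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
        ).filter(lambda c: sum(c) > 0)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_oracle(self, counts):
        assert hwe_test(*counts) == pytest.approx(hwe_oracle(*counts), abs=1e-10)


class TestQcFilter:
    def test_identity_when_all_pass(self, rng):
        d = rng.binomial(2, 0.3, size=(500, 5)).astype(float)
        g = toy_genotypes(d)
        out = qc_filter(g)
        assert out.n_variants == 5

    def test_three_violations_attributed(self, rng):
        # one low-MAF, one low-info, one HWE-violating variant among passers
        d = rng.binomial(2, 0.3, size=(600, 5)).astype(float)
        d[:, 1] = rng.binomial(2, 0.004, size=600)  # rare
        d[:, 3] = rng.choice([0.0, 2.0], size=600)  # no hets: HWE violation
        maf = d.mean(axis=0) / 2
        info = np.array([0.95, 0.99, 0.5, 0.99, 0.9])  # variant 2 fails info
        g = toy_genotypes(d, maf=np.minimum(maf, 1 - maf), info=info)
        out, report = qc_filter(g, with_report=True)
        assert list(out.variants["id"]) == ["v0", "v4"]
        assert report["removed_maf"] == 1
        assert report["removed_info"] == 1
        assert report["removed_hwe"] == 1

    def test_idempotent(self, rng):
        d = rng.binomial(2, rng.uniform(0.05, 0.5, 8), size=(400, 8)).astype(float)
        g = toy_genotypes(d)
        once = qc_filter(g)
        twice = qc_filter(once)
        pd.testing.assert_frame_equal(once.variants, twice.variants)


class TestLdR2:
    def test_identical_vectors(self):
        v = np.array([0.0, 1, 2, 0, 1])
        assert ld_r2(v, v) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert ld_r2(np.array([0, 1, 2, 0.0]), np.array([2, 1, 0, 2.0])) == pytest.approx(1.0)

    def test_zero_variance_errors(self):
        with pytest.raises(DataError):
            ld_r2(np.array([1.0, 1, 1]), np.array([0.0, 1, 2]))

    def test_matches_corrcoef_oracle(self, rng):
        for _ in range(20):
            a = rng.uniform(0, 2, 50)
            b = rng.uniform(0, 2, 50)
            assert ld_r2(a, b) == pytest.approx(
                np.corrcoef(a, b)[0, 1] ** 2, abs=1e-12
            )


def clump_oracle(ss_table, g, p_thresh, r2_thresh, window_kb):
    """Plain re-execution of the greedy clumping rule from its definition."""
    meta = g.variants.set_index("id")
    cand = [
        (row.p, meta.loc[row.id, "pos"], row.id)
        for row in ss_table.itertuples(index=False)
        if row.p < p_thresh and row.id in meta.index
    ]
    cand.sort()
    alive = {c[2] for c in cand}
    chosen = []
    for _, _, vid in cand:
        if vid not in alive:
            continue
        chosen.append(vid)
        alive.discard(vid)
        j = g.variant_index([vid])[0]
        for _, _, other in cand:
            if other not in alive:
                continue
            o = g.variant_index([other])[0]
            if meta.loc[other, "chrom"] != meta.loc[vid, "chrom"]:
                continue
            if abs(meta.loc[other, "pos"] - meta.loc[vid, "pos"]) > window_kb * 1000:
                continue
            a, b = g.dosages[:, j], g.dosages[:, o]
            if a.std() == 0 or b.std() == 0:
                continue
            if np.corrcoef(a, b)[0, 1] ** 2 >= r2_thresh:
                alive.discard(other)
    return chosen


def make_ss(ids, ps, betas=None):
    n = len(ids)
    return SummaryStats(
        pd.DataFrame(
            {
                "id": ids,
                "effect_allele": ["G"] * n,
                "other_allele": ["A"] * n,
                "beta": betas if betas is not None else np.ones(n),
                "se": np.ones(n),
                "p": ps,
            }
        )
    )


class TestClump:
    def test_two_unlinked_variants_both_indices(self, rng):
        d = rng.binomial(2, 0.3, size=(200, 2)).astype(float)
        g = toy_genotypes(d, pos=[1000, 900_000])
        ss = make_ss(["v0", "v1"], [1e-4, 1e-3])
        assert clump(ss, g) == ["v0", "v1"]

    def test_correlated_neighbour_clumped_away(self, rng):
        # hand-executed greedy: v0 indexes, v1 (r2 ~ 0.5 with v0) removed,
        # v2 fails the p threshold
        base = rng.binomial(2, 0.5, size=400).astype(float)
        flip = rng.random(400) < 0.15
        partner = np.where(flip, 2 - base, base)
        other = rng.binomial(2, 0.5, size=400).astype(float)
        g = toy_genotypes(np.column_stack([base, partner, other]),
                          pos=[1000, 2000, 3000])
        assert ld_r2(base, partner) >= 0.1
        ss = make_ss(["v0", "v1", "v2"], [1e-5, 1e-4, 0.5])
        assert clump(ss, g, p_thresh=0.01, r2_thresh=0.1) == ["v0"]

    def test_window_rule_keeps_distant_pair(self, rng):
        # r2 = 1 but 600 kb apart: both retained
        v = rng.binomial(2, 0.4, size=300).astype(float)
        g = toy_genotypes(np.column_stack([v, v]), pos=[1000, 601_000])
        ss = make_ss(["v0", "v1"], [1e-5, 1e-4])
        assert clump(ss, g, window_kb=500) == ["v0", "v1"]

    def test_no_candidate_empty(self, rng):
        g = toy_genotypes(rng.binomial(2, 0.3, size=(100, 2)).astype(float))
        ss = make_ss(["v0", "v1"], [0.5, 0.9])
        assert clump(ss, g, p_thresh=0.01) == []

    def test_matches_exhaustive_oracle_random_fixtures(self, rng):
        for rep in range(8):
            n_var = int(rng.integers(5, 21))
            blocks = rng.integers(0, max(2, n_var // 3), size=n_var)
            base = rng.binomial(2, 0.5, size=(300, n_var)).astype(float)
            for v in range(n_var):
                same = np.flatnonzero(blocks == blocks[v])
                if same[0] != v:
                    flip = rng.random(300) < 0.1
                    base[:, v] = np.where(flip, 2 - base[:, same[0]], base[:, same[0]])
            pos = 1 + np.arange(n_var) * int(rng.integers(1000, 400_000))
            g = toy_genotypes(base, pos=pos)
            ps = rng.uniform(1e-6, 1.0, n_var)
            ss = make_ss([f"v{i}" for i in range(n_var)], ps)
            assert clump(ss, g, 0.5, 0.2, 500) == clump_oracle(
                ss.table, g, 0.5, 0.2, 500
            )

    def test_row_order_independence(self, rng):
        d = rng.binomial(2, 0.4, size=(300, 10)).astype(float)
        g = toy_genotypes(d)
        ps = rng.uniform(0, 0.02, 10)
        ss = make_ss([f"v{i}" for i in range(10)], ps)
        shuffled = SummaryStats(ss.table.sample(frac=1, random_state=1))
        assert clump(ss, g) == clump(shuffled, g)

    def test_idempotence_on_indices(self, rng):
        d = rng.binomial(2, 0.4, size=(300, 12)).astype(float)
        g = toy_genotypes(d)
        ss = make_ss([f"v{i}" for i in range(12)], rng.uniform(0, 0.02, 12))
        first = clump(ss, g)
        sub = SummaryStats(ss.table[ss.table["id"].isin(first)])
        assert clump(sub, g.subset_variants(first)) == first


def pairs_df(rows):
    return pd.DataFrame(rows, columns=["id1", "id2", "kinship"])


class TestPruneRelatedness:
    def test_empty_pairs_keeps_everyone(self):
        kept = prune_relatedness(pairs_df([]), subjects=["a", "b", "c"])
        assert kept == {"a", "b", "c"}

    def test_star_graph_removes_hub(self):
        rows = [("hub", leaf, 0.25) for leaf in ["l1", "l2", "l3", "l4"]]
        kept = prune_relatedness(pairs_df(rows))
        assert kept == {"l1", "l2", "l3", "l4"}

    def test_chain_graph(self):
        # a-b-c-d: degree-2 ties broken by largest id => c removed, then edge
        # a-b remains: b removed; kept = {a, d}... hand execution:
        rows = [("a", "b", 0.25), ("b", "c", 0.25), ("c", "d", 0.25)]
        kept = prune_relatedness(pairs_df(rows))
        # degrees: b=2, c=2 -> remove c; remaining edge a-b, remove b
        assert kept == {"a", "d"}

    def test_clique_left_with_one(self):
        ids = ["a", "b", "c", "d"]
        rows = [(ids[i], ids[j], 0.25) for i in range(4) for j in range(i + 1, 4)]
        kept = prune_relatedness(pairs_df(rows))
        assert kept == {"a"}

    def test_subthreshold_pairs_ignored(self):
        rows = [("a", "b", 0.02), ("b", "c", 0.0439)]
        kept = prune_relatedness(pairs_df(rows), threshold=0.044)
        assert kept == {"a", "b", "c"}

    def test_output_edge_free(self, rng):
        ids = [f"s{i}" for i in range(30)]
        rows = [
            (ids[int(rng.integers(30))], ids[int(rng.integers(30))], float(rng.uniform(0, 0.3)))
            for _ in range(60)
        ]
        rows = [r for r in rows if r[0] != r[1]]
        kept = prune_relatedness(pairs_df(rows), threshold=0.044)
        for a, b, kin in rows:
            if kin >= 0.044:
                assert not (a in kept and b in kept)


class TestComputePgs:
    def test_zero_weights_zero_scores(self, rng):
        g = toy_genotypes(rng.binomial(2, 0.3, size=(50, 3)).astype(float))
        w = pd.DataFrame({"id": ["v0", "v1"], "effect_allele": ["G", "G"],
                          "weight": [0.0, 0.0]})
        assert np.all(compute_pgs(g, w).scores == 0)

    def test_single_variant_alt_weight_one(self, rng):
        g = toy_genotypes(rng.binomial(2, 0.3, size=(50, 2)).astype(float))
        w = pd.DataFrame({"id": ["v1"], "effect_allele": ["G"], "weight": [1.0]})
        np.testing.assert_array_equal(compute_pgs(g, w).scores, g.dosages[:, 1])

    def test_hand_computed_with_allele_flip(self):
        d = np.array([[0.0, 1, 2], [1, 2, 0], [2, 0, 1]])
        g = toy_genotypes(d)
        w = pd.DataFrame(
            {"id": ["v0", "v1", "v2"], "effect_allele": ["G", "A", "G"],
             "weight": [1.0, 2.0, -1.0]}
        )
        # v1 effect allele is ref => dosage flips to 2 - d
        expected = d[:, 0] * 1.0 + (2 - d[:, 1]) * 2.0 + d[:, 2] * -1.0
        np.testing.assert_allclose(compute_pgs(g, w).scores, expected)

    def test_unknown_allele_skipped(self, rng):
        g = toy_genotypes(rng.binomial(2, 0.3, size=(20, 2)).astype(float))
        w = pd.DataFrame({"id": ["v0", "v1"], "effect_allele": ["T", "G"],
                          "weight": [5.0, 1.0]})
        pgs = compute_pgs(g, w)
        assert pgs.n_skipped == 1
        np.testing.assert_array_equal(pgs.scores, g.dosages[:, 1])

    def test_strand_consistent_relabel_invariance(self, rng):
        d = rng.binomial(2, 0.4, size=(40, 1)).astype(float)
        g1 = toy_genotypes(d)
        g2 = toy_genotypes(2 - d)  # relabel: swap ref/alt, flip dosage
        w1 = pd.DataFrame({"id": ["v0"], "effect_allele": ["G"], "weight": [0.7]})
        w2 = pd.DataFrame({"id": ["v0"], "effect_allele": ["A"], "weight": [0.7]})
        np.testing.assert_allclose(
            compute_pgs(g1, w1).scores, compute_pgs(g2, w2).scores
        )

    def test_missing_dosage_mean_imputed(self):
        d = np.array([[0.0], [2.0], [np.nan], [2.0]])
        g = toy_genotypes(np.nan_to_num(d, nan=0.0))
        g.dosages = d  # inject a missing call
        w = pd.DataFrame({"id": ["v0"], "effect_allele": ["G"], "weight": [1.0]})
        scores = compute_pgs(g, w).scores
        assert scores[2] == pytest.approx(4.0 / 3.0)


class TestPgsGridAndOptimize:
    def test_threshold_one_equals_full_weights(self, rng):
        d = rng.binomial(2, 0.4, size=(100, 6)).astype(float)
        g = toy_genotypes(d, pos=1 + np.arange(6) * 900_000)
        betas = rng.normal(size=6)
        ss = make_ss([f"v{i}" for i in range(6)], rng.uniform(0.2, 1.0, 6), betas)
        family = pgs_grid(ss, g, [1.0], clump_first=False)
        full = compute_pgs(
            g,
            pd.DataFrame({"id": ss.table["id"], "effect_allele": "G",
                          "weight": betas}),
        )
        np.testing.assert_allclose(family[1.0].scores, full.scores)

    def test_variant_counts_monotone_in_threshold(self, rng):
        d = rng.binomial(2, 0.4, size=(150, 20)).astype(float)
        g = toy_genotypes(d, pos=1 + np.arange(20) * 900_000)
        ss = make_ss([f"v{i}" for i in range(20)], rng.uniform(0, 1, 20),
                     rng.normal(size=20))
        family = pgs_grid(ss, g, [0.01, 0.1, 0.5, 1.0])
        counts = [family[t].n_variants_used for t in (0.01, 0.1, 0.5, 1.0)]
        assert counts == sorted(counts)

    def test_single_candidate_selected(self, rng):
        scores = rng.normal(size=60)
        idps = rng.normal(size=(60, 3))
        design = np.ones((60, 1))
        best, rep = optimize_pgs({"only": scores}, idps, design)
        assert best == "only"

    def test_perfect_predictor_selected(self, rng):
        idps = rng.normal(size=(80, 2))
        design = np.ones((80, 1))
        family = {"noise": rng.normal(size=80), "exact": idps[:, 1].copy()}
        best, rep = optimize_pgs(family, idps, design)
        assert best == "exact"
        assert np.isinf(rep.best_t)
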