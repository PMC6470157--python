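"""Panel-statistics tests with independent brute-force oracles for the
Ward merge tree, the BH step-up adjustment, and the PCA coordinates."""

import numpy as np
import pandas as pd
import pytest

import esomech as em
from esomech.edp import hierarchical_cluster, pca_top3


def make_panel(values, calls=None, n_donors=None):
    """Wrap a genes x samples array (vehicle/treated interleaved) in a PanelMatrix."""
    values = np.asarray(values, float)
    n_genes, n_samples = values.shape
    donors = n_donors or n_samples // 2
    genes = [f"G{i}" for i in range(n_genes)]
    rows, cols = [], []
    for d in range(donors):
        for arm in ("vehicle", "treated"):
            sid = f"D{d + 1}_{arm}"
            rows.append({"sample_id": sid, "donor_id": f"D{d + 1}", "arm": arm})
            cols.append(sid)
    calls = np.ones_like(values, bool) if calls is None else np.asarray(calls, bool)
    return em.PanelMatrix(
        values=pd.DataFrame(values, index=genes, columns=cols),
        call_flags=pd.DataFrame(calls, index=genes, columns=cols),
        samples=pd.DataFrame(rows),
    )


class TestCallRateFilter:
    def test_all_detected_all_retained(self):
        pm = make_panel(np.ones((5, 6)))
        assert len(em.call_rate_filter(pm, 0.5).retained_genes) == 5

    def test_gene_below_half_call_rate_dropped(self):
        calls = np.ones((2, 10), bool)
        calls[1, :6] = False  # 4/10 detected
        pm = make_panel(np.ones((2, 10)), calls)
        fp = em.call_rate_filter(pm, 0.5)
        assert fp.retained_genes == ["G0"]

    def test_constructed_sixty_of_ninety_six(self):
        # 60 genes fully detected, 36 detected in only 4 of 10 samples
        calls = np.zeros((96, 10), bool)
        calls[:60] = True
        calls[60:, :4] = True
        pm = make_panel(np.ones((96, 10)), calls)
        assert len(em.call_rate_filter(pm, 0.5).retained_genes) == 60

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        calls = rng.random((40, 10)) < rng.uniform(0.2, 0.9, size=(40, 1))
        pm = make_panel(np.zeros((40, 10)), calls)
        counts = [len(em.call_rate_filter(pm, th).retained_genes) for th in (0.2, 0.4, 0.6, 0.8)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_threshold_validated(self):
        pm = make_panel(np.ones((2, 4)))
        with pytest.raises(ValueError):
            em.call_rate_filter(pm, 0.0)

    def test_empty_result_warns(self):
        pm = make_panel(np.ones((2, 4)), np.zeros((2, 4), bool))
        with pytest.warns(UserWarning):
            fp = em.call_rate_filter(pm, 0.5)
        assert fp.retained_genes == []


def brute_force_ward(X):
    """Naive Ward agglomeration: merge the pair minimizing the SSE increase;
    report heights as sqrt(2 * delta SSE) (the scaling scipy uses)."""
    clusters = {i: [i] for i in range(X.shape[0])}
    heights = []
    next_id = X.shape[0]
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                pa, pb = X[clusters[a]], X[clusters[b]]
                na, nb = len(pa), len(pb)
                d2 = na * nb / (na + nb) * np.sum((pa.mean(0) - pb.mean(0)) ** 2)
                if best is None or d2 < best[0]:
                    best = (d2, a, b)
        d2, a, b = best
        heights.append(np.sqrt(2 * d2))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return np.array(heights)


class TestHierarchicalCluster:
    def test_identical_samples_merge_at_zero_height(self):
        X = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        res = hierarchical_cluster(X, axis=0)
        assert res.linkage[0, 2] == pytest.approx(0.0)

    def test_close_pair_merges_first(self):
        X = pd.DataFrame([[0.0], [1.0], [10.0]], index=["a", "b", "c"])
        res = hierarchical_cluster(X, axis=0)
        first = {int(res.linkage[0, 0]), int(res.linkage[0, 1])}
        assert first == {0, 1}

    def test_merge_heights_match_brute_force_ward(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(6, 4))
        res = hierarchical_cluster(pd.DataFrame(X), axis=0)
        expected = brute_force_ward(X)
        assert np.allclose(np.sort(res.linkage[:, 2]), np.sort(expected), rtol=1e-6)

    def test_deterministic_for_fixed_input(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(10, 5)))
        a, b = hierarchical_cluster(X), hierarchical_cluster(X)
        assert np.array_equal(a.linkage, b.linkage)
        assert a.order == b.order


class TestPCA:
    def test_collinear_data_loads_one_component(self):
        t = np.linspace(0, 1, 6)
        X = pd.DataFrame(np.outer([1.0, 2.0, -0.5], t), columns=[f"s{i}" for i in range(6)])
        res = pca_top3(X)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)
        assert res.rank_deficient

    def test_variance_fractions_valid(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(8, 6)))
        res = pca_top3(X)
        assert np.all(np.diff(res.variance_fractions) <= 1e-12)
        assert res.variance_fractions.sum() <= 1.0 + 1e-12

    def test_coordinates_match_eigendecomposition(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(5, 4))  # genes x samples -> 4 samples, 5 genes
        df = pd.DataFrame(X, columns=[f"s{i}" for i in range(4)])
        res = pca_top3(df)
        # independent oracle: eigendecomposition of the sample covariance
        S = X.T - X.T.mean(axis=0, keepdims=True)  # samples x genes
        cov = S.T @ S
        w, V = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        for j in range(res.n_components):
            v = V[:, order[j]]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            coords = S @ v
            assert np.allclose(res.coordinates.iloc[:, j].to_numpy(), coords, atol=1e-8)

    def test_needs_four_samples(self):
        with pytest.raises(ValueError):
            pca_top3(pd.DataFrame(np.ones((5, 3))))


def bh_step_up(p):
    """Hand-worked BH: p_(i) * m / i, then enforce monotonicity from the top."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        adj[i] = min(adj[i], adj[i + 1])
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestPairedDE:
    def test_zero_differences_give_maximal_p(self):
        base = np.tile(np.arange(4, dtype=float), (3, 1))
        pm = make_panel(np.repeat(base, 2, axis=1))  # treated == vehicle per donor
        de = em.paired_de(pm)
        assert np.all(de.table["p_raw"] == 1.0)
        assert np.all(de.table["mean_log2_diff"] == 0.0)

    def test_bh_matches_hand_step_up(self):
        rng = np.random.default_rng(21)
        values = rng.normal(5, 1, size=(10, 12))
        values[:3, 1::2] += 2.0  # treated columns of first three genes
        pm = make_panel(values)
        de = em.paired_de(pm)
        assert np.allclose(de.table["p_adj"], bh_step_up(de.table["p_raw"]), rtol=1e-9)

    def test_adjusted_p_dominates_raw(self):
        rng = np.random.default_rng(22)
        pm = make_panel(rng.normal(size=(30, 8)))
        de = em.paired_de(pm)
        assert np.all(de.table["p_adj"] >= de.table["p_raw"] - 1e-12)
        assert np.all(de.table["p_adj"] <= 1.0)

    def test_undetected_entries_drop_the_pair_for_that_gene(self):
        rng = np.random.default_rng(23)
        values = rng.normal(size=(3, 10))
        calls = np.ones_like(values, bool)
        calls[0, 0] = False  # vehicle arm of donor 1, gene 0
        de = em.paired_de(make_panel(values, calls))
        assert de.table["n_pairs"].tolist() == [4, 5, 5]

    def test_requires_two_donor_pairs(self):
        pm = make_panel(np.ones((3, 2)), n_donors=1)
        with pytest.raises(ValueError):
            em.paired_de(pm)

    def test_deterministic(self):
        rng = np.random.default_rng(24)
        values = rng.normal(size=(20, 10))
        a = em.paired_de(make_panel(values)).table
        b = em.paired_de(make_panel(values)).table
        assert a.equals(b)


class TestFoldChangeSets:
    def test_identical_inputs_fully_overlap(self):
        fc = {"g1": 8.0, "g2": 0.1, "g3": 2.0}
        res = em.fold_change_sets(fc, fc, threshold=5.0)
        assert res.both == ["g1", "g2"]  # |FC| magnitude 8 and 10
        assert res.only_a == res.only_b == []

    def test_exactly_fivefold_is_excluded(self):
        res = em.fold_change_sets({"g1": 5.0}, {"g1": 5.00001}, threshold=5.0)
        assert res.only_b == ["g1"]
        assert res.both == []

    def test_counts_match_enumeration(self):
        fc_a = {f"g{i}": v for i, v in enumerate([10, 6, 4, 0.05, 1.0, 7])}
        fc_b = {f"g{i}": v for i, v in enumerate([10, 1, 9, 0.05, 8, 1.2])}
        res = em.fold_change_sets(fc_a, fc_b, threshold=5.0)
        set_a = {g for g, v in fc_a.items() if max(v, 1 / v) > 5}
        set_b = {g for g, v in fc_b.items() if max(v, 1 / v) > 5}
        assert set(res.both) == set_a & set_b
        assert set(res.only_a) == set_a - set_b
        assert set(res.only_b) == set_b - set_a

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValueError):
            em.fold_change_sets({"g": 2.0}, {"g": 2.0}, threshold=1.0)


class TestVolcano:
    def test_flag_requires_both_criteria(self):
        rng = np.random.default_rng(31)
        values = rng.normal(5, 0.3, size=(20, 10))
        values[0, 1::2] += 3.0   # strong effect: significant and > 2-fold
        values[1, 1::2] += 0.2   # weak effect
        de = em.paired_de(make_panel(values))
        vt = em.volcano_table(de, fc_threshold=2.0, alpha=0.05)
        assert bool(vt.iloc[0]["significant"])
        assert not bool(vt.iloc[1]["significant"])

    def test_flag_count_matches_brute_force_filter(self):
        rng = np.random.default_rng(32)
        values = rng.normal(5, 0.5, size=(25, 10))
        values[:6, 1::2] += rng.uniform(1.5, 3.0, size=(6, 5))
        de = em.paired_de(make_panel(values))
        vt = em.volcano_table(de, fc_threshold=2.0, alpha=0.05)
        t = de.table
        mag = np.maximum(t["fold_change"], 1 / t["fold_change"])
        expected = int(np.sum((t["p_adj"] < 0.05) & (mag > 2.0)))
        assert int(vt["significant"].sum()) == expected


class TestEffectRecovery:
    def test_block_of_strong_effects_is_recovered(self):
        """Genes with a paired log2 effect >= 2.5 (within a realistic block of
        dysregulated genes) are volcano-flagged in >= 80% of replicates."""
        genes = [f"EDP{i + 1:03d}" for i in range(60)]
        spec = em.eoe_like_effects(genes, seed=0)
        strong = [g for g, v in spec.items() if abs(v) >= 2.5]
        hits = total = 0
        for seed in range(25):
            pm = em.generate_panel(
                n_genes=60, donors=5, effect_spec=spec, missing_spec=1.0, seed=500 + seed
            )
            vt = em.volcano_table(em.paired_de(pm))
            for g in strong:
                total += 1
                hits += bool(vt.loc[g, "significant"])
        assert hits / total >= 0.8
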