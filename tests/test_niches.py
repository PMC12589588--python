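import numpy as np
import pandas as pd
import pytest

from conftest import two_block_cellmap
from lungscape.io import CellMap
from lungscape.niches import (compare_conditions, composition_matrix,
                              enrichment_graph, niche_cluster,
                              niche_condition_composition, pairwise_enrichment,
                              UNASSIGNED_NICHE)


def random_cellmap(n=200, types=("A", "B"), seed=0, sample_id="s1"):
    rng = np.random.default_rng(seed)
    return CellMap(pd.DataFrame({
        "cell_id": np.arange(n), "x": rng.uniform(0, 600, n),
        "y": rng.uniform(0, 600, n),
        "type_label": rng.choice(list(types), n), "sample_id": sample_id}))


class TestCompositionMatrix:
    def test_homogeneous_sample_rows_all_one_type(self):
        cm = random_cellmap(100, types=("A",), seed=1)
        comp = composition_matrix(cm, k=20)
        assert (comp.counts["A"] == 20).all()

    def test_matches_brute_force_all_pairs_sort(self):
        cm = random_cellmap(50, seed=2)
        k = 5
        comp = composition_matrix(cm, k=k)
        df = cm.data
        xy = df[["x", "y"]].to_numpy()
        for i in range(50):
            d = np.hypot(*(xy - xy[i]).T)
            d[i] = np.inf
            nn = np.argsort(d, kind="stable")[:k]
            expected = df["type_label"].to_numpy()[nn]
            for t in comp.counts.columns:
                assert comp.counts.loc[i, t] == (expected == t).sum()

    def test_no_cross_sample_neighbors(self):
        # two samples occupying the same coordinates: with cross-sample
        # leakage, neighbors would mix types; isolation keeps rows pure
        a = random_cellmap(60, types=("A",), seed=3, sample_id="s1").data
        b = random_cellmap(60, types=("B",), seed=3, sample_id="s2").data
        b["cell_id"] += 1000
        cm = CellMap(pd.concat([a, b], ignore_index=True))
        comp = composition_matrix(cm, k=10)
        assert (comp.counts.to_numpy().sum(axis=1) == 10).all()
        first = comp.meta["sample_id"] == "s1"
        assert (comp.counts.loc[first.to_numpy(), "B"] == 0).all()
        assert (comp.counts.loc[(~first).to_numpy(), "A"] == 0).all()

    def test_small_sample_error_names_sample(self):
        cm = random_cellmap(5, seed=4)
        with pytest.raises(ValueError, match="s1"):
            composition_matrix(cm, k=10)


class TestPairwiseEnrichment:
    def test_planted_blocks_enriched_within_depleted_between(self):
        cm, _ = two_block_cellmap(300, p1=1.0, p2=0.0, seed=5)
        res = pairwise_enrichment(cm, k=20, n_permutations=300, seed=0)
        assert res.zscores.loc["A", "A"] > 2
        assert res.zscores.loc["B", "B"] > 2
        assert res.zscores.loc["A", "B"] < 0

    def test_row_order_invariance(self):
        cm, _ = two_block_cellmap(100, seed=6)
        res1 = pairwise_enrichment(cm, k=10, n_permutations=100, seed=3)
        shuffled = CellMap(cm.data.sample(frac=1, random_state=9).reset_index(drop=True))
        res2 = pairwise_enrichment(shuffled, k=10, n_permutations=100, seed=3)
        # rows are canonicalized internally, so z is exactly order-invariant
        pd.testing.assert_frame_equal(res1.observed, res2.observed)
        pd.testing.assert_frame_equal(res1.zscores, res2.zscores)

    def test_null_calibration_loose(self):
        """Random labels: fraction of |z| > 2 stays below the loose 10%
        two-sided-normal bound across replicates."""
        exceed = total = 0
        for rep in range(10):
            cm = random_cellmap(300, seed=100 + rep)
            res = pairwise_enrichment(cm, k=15, n_permutations=300, seed=rep)
            z = res.zscores.to_numpy()[np.triu_indices(2)]
            exceed += (np.abs(z) > 2).sum()
            total += z.size
        assert exceed / total <= 0.10

    def test_too_few_permutations_rejected(self):
        cm = random_cellmap(50, seed=7)
        with pytest.raises(ValueError):
            pairwise_enrichment(cm, k=5, n_permutations=5, seed=0)

    def test_single_type_rejected(self):
        cm = random_cellmap(50, types=("A",), seed=8)
        with pytest.raises(ValueError):
            pairwise_enrichment(cm, k=5, n_permutations=100, seed=0)


class TestEnrichmentGraph:
    def _result(self, zmat, types=("A", "B")):
        from lungscape.niches import EnrichmentResult

        z = pd.DataFrame(zmat, index=list(types), columns=list(types))
        return EnrichmentResult(np.array(types), z, z, z, z, 100, 0)

    def test_all_below_threshold_edgeless_with_nodes(self):
        g = enrichment_graph(self._result([[1.0, 0.5], [0.5, 1.0]]))
        assert set(g.nodes) == {"A", "B"}
        assert g.number_of_edges() == 0

    def test_exact_threshold_excluded(self):
        g = enrichment_graph(self._result([[2.0, 2.0], [2.0, 2.0]]), threshold=2.0)
        assert g.number_of_edges() == 0

    def test_planted_blocks_give_within_type_edges(self):
        cm, _ = two_block_cellmap(300, p1=1.0, p2=0.0, seed=9)
        res = pairwise_enrichment(cm, k=20, n_permutations=300, seed=1)
        g = enrichment_graph(res, threshold=2.0)
        assert g.has_edge("A", "A") and g.has_edge("B", "B")
        assert not g.has_edge("A", "B")


class TestNicheCluster:
    def test_min_size_boundary_49_removed_50_kept(self):
        from lungscape.niches import apply_size_floor

        labels = np.r_[np.zeros(200, int), np.ones(50, int), np.full(49, 2)]
        out = apply_size_floor(labels, min_cluster_size=50)
        sizes = pd.Series(out).value_counts()
        assert sizes[UNASSIGNED_NICHE] == 49          # the 49-cell cluster removed
        assert sizes[0] == 200 and sizes[1] == 50     # relabeled by size, 50 kept

    def test_all_clusters_below_floor_is_error(self):
        from lungscape.niches import apply_size_floor

        with pytest.raises(ValueError):
            apply_size_floor(np.array([0, 0, 1, 1]), min_cluster_size=50)

    def test_two_planted_niches_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        cm, truth = two_block_cellmap(500, p1=0.8, p2=0.2, seed=10)
        comp = composition_matrix(cm, k=20)
        labels = niche_cluster(comp, resolution=1.0, min_cluster_size=50, seed=0)
        assert labels.max() + 1 == 2
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_homogeneous_sample_single_niche(self):
        cm = random_cellmap(200, types=("A",), seed=11)
        labels = niche_cluster(composition_matrix(cm, 20), 1.0, 50, seed=0)
        assert set(labels) == {0}

    def test_fixed_seed_deterministic(self):
        cm, _ = two_block_cellmap(200, seed=12)
        comp = composition_matrix(cm, k=15)
        a = niche_cluster(comp, 1.0, 50, seed=4)
        b = niche_cluster(comp, 1.0, 50, seed=4)
        np.testing.assert_array_equal(a, b)


class TestNicheConditionComposition:
    def test_single_niche_proportion_one(self):
        cm = random_cellmap(60, types=("A",), seed=13)
        tab = niche_condition_composition(np.zeros(60, dtype=int), cm)
        assert tab.loc["s1", "niche_0"] == pytest.approx(1.0)

    def test_matches_manual_counting(self):
        df = pd.concat([
            random_cellmap(40, seed=14, sample_id="s1").data,
            random_cellmap(60, seed=15, sample_id="s2").data.assign(
                cell_id=lambda d: d["cell_id"] + 500)], ignore_index=True)
        df["condition"] = np.where(df["sample_id"] == "s1", "healthy", "COPD")
        cm = CellMap(df)
        labels = np.r_[np.zeros(20, int), np.ones(20, int),
                       np.zeros(30, int), np.full(30, UNASSIGNED_NICHE)]
        tab = niche_condition_composition(labels, cm)
        assert tab.loc["s1", "niche_0"] == pytest.approx(0.5)
        assert tab.loc["s1", "niche_1"] == pytest.approx(0.5)
        assert tab.loc["s2", "niche_0"] == pytest.approx(0.5)
        assert tab.loc["s2", "unassigned"] == pytest.approx(0.5)
        assert tab.loc["s1", "condition"] == "healthy"

    def test_invariant_to_cell_order(self):
        cm = random_cellmap(50, seed=16)
        labels = np.random.default_rng(0).integers(0, 2, 50)
        a = niche_condition_composition(labels, cm)
        perm = np.random.default_rng(1).permutation(50)
        cm2 = CellMap(cm.data.iloc[perm].reset_index(drop=True))
        b = niche_condition_composition(labels[perm], cm2)
        pd.testing.assert_frame_equal(a, b)


class TestCompareConditions:
    def _props(self, rows, cats=None):
        cats = cats or [f"c{i}" for i in range(len(rows[0]))]
        idx = [f"s{i}" for i in range(len(rows))]
        return pd.DataFrame(rows, index=idx, columns=cats)

    def test_identical_vectors_all_adjusted_one(self):
        props = self._props([[0.2, 0.8]] * 4)
        cond = pd.Series(["H", "H", "D", "D"], index=props.index)
        res = compare_conditions(props, cond)
        assert (res["p_adj"] == 1.0).all()

    def test_holm_sidak_matches_closed_form(self):
        """The step-down adjustment on 3 raw p-values equals the hand
        formula max_j<=i (1-(1-p_(j))^(m-j+1))."""
        from statsmodels.stats.multitest import multipletests

        raw = np.array([0.01, 0.04, 0.03])
        adj = multipletests(raw, method="holm-sidak")[1]
        order = np.argsort(raw)
        expected = np.empty(3)
        running = 0.0
        for rank, idx in enumerate(order):
            val = 1 - (1 - raw[idx]) ** (3 - rank)
            running = max(running, val)
            expected[idx] = running
        np.testing.assert_allclose(adj, expected, atol=1e-12)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(17)
        rows = rng.normal(0.10, 0.02, size=(6, 8)).clip(1e-4)
        rows[3:, 0] = rng.normal(0.40, 0.02, size=3).clip(1e-4)
        props = self._props(rows.tolist())
        cond = pd.Series(["H"] * 3 + ["D"] * 3, index=props.index)
        res = compare_conditions(props, cond)
        assert res.loc["c0", "p_adj"] < 0.05

    def test_zero_replacement_half_minimum(self):
        # category with zeros: replacement must leave the test finite
        props = self._props([[0.0, 0.5], [0.02, 0.5], [0.04, 0.5], [0.06, 0.5]])
        cond = pd.Series(["H", "H", "D", "D"], index=props.index)
        res = compare_conditions(props, cond)
        assert np.isfinite(res.loc["c0", "t"])

    def test_single_condition_rejected(self):
        props = self._props([[0.5, 0.5]] * 4)
        cond = pd.Series(["H"] * 4, index=props.index)
        with pytest.raises(ValueError):
            compare_conditions(props, cond)


class TestConditionNicheFixture:
    def test_copd_niche_has_higher_copd_proportion(self):
        """Planted AT0+immune niche present only in disease samples plus an
        AT0 abundance shift yields >=1 niche with higher mean proportion in
        disease than in health."""
        from shapely.geometry import Polygon
        from lungscape.synthetic import SynthConfig, generate_tissue

        niche_poly = Polygon([(330, -150), (630, -150), (630, 150), (330, 150)])
        base = dict(n_epithelial=0, n_alveolar=350,
                    epithelial_mixture={"basal": 1.0})
        cfg_h = SynthConfig(**base)
        cfg_d = SynthConfig(**base, condition_effect={"AT0": 4.0},
                            niche_plan=[("at0imm", niche_poly,
                                         {"AT0": 0.5, "immune": 0.5})])
        frames = []
        for i in range(2):
            cm, _, _, _ = generate_tissue(cfg_h, seed=20 + i,
                                          sample_id=f"h{i}", condition="healthy")
            frames.append(cm.data)
        for i in range(2):
            cm, _, _, _ = generate_tissue(cfg_d, seed=30 + i,
                                          sample_id=f"d{i}", condition="COPD")
            frames.append(cm.data)
        combined = CellMap(pd.concat(frames, ignore_index=True))
        comp = composition_matrix(combined, k=20)
        labels = niche_cluster(comp, resolution=1.0, min_cluster_size=50, seed=0)
        tab = niche_condition_composition(labels, combined)
        niche_cols = [c for c in tab.columns if c.startswith("niche_")]
        means = tab.groupby("condition")[niche_cols].mean()
        assert (means.loc["COPD"] > means.loc["healthy"]).any()
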