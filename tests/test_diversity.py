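"""Diversity metrics against hand values and brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lakediv.diversity import (CommunityMetricsEngine, TraitSpace,
                               build_trait_space, community_metrics,
                               community_weighted_means, faith_pd,
                               functional_dispersion, functional_richness,
                               gower_matrix, mean_pairwise_distance)
from lakediv.synthetic import SimConfig, generate_species_pool
from lakediv.trees import build_tree


def pool_frame(lengths, guilds):
    n = len(lengths)
    return pd.DataFrame({
        "taxon_id": [f"t{i}" for i in range(n)],
        "species": [f"sp {i}" for i in range(n)],
        "genus": [f"G{i}" for i in range(n)],
        "family": "F", "order": "O", "class": "C",
        "rank": "species",
        "body_length": lengths, "guild": guilds,
    })


class TestGower:
    def test_hand_worked_value(self):
        taxa = pool_frame([0.5, 1.0, 3.0, 4.5], [1, 1, 3, 4])
        d = gower_matrix(taxa)
        # lengths 1 vs 3 over pool range 4, guilds 1 vs 3 over range 3
        assert d.loc["t1", "t2"] == pytest.approx(
            0.5 * (2 / 4) + 0.5 * (2 / 3), abs=1e-9)

    def test_identity_and_bound(self):
        taxa = pool_frame([0.5, 0.5, 4.5], [2, 2, 2])
        d = gower_matrix(taxa)
        assert d.loc["t0", "t1"] == 0.0
        taxa2 = pool_frame([0.5, 4.5], [1, 4])
        d2 = gower_matrix(taxa2)
        assert d2.loc["t0", "t1"] == pytest.approx(1.0)

    def test_missing_trait_renormalization(self):
        taxa = pool_frame([1.0, 3.0, 0.5, 4.5], [2, 2, 1, 4])
        taxa.loc[0, "guild"] = np.nan
        d = gower_matrix(taxa)
        # only body length observed in both: weight renormalizes to 1
        assert d.loc["t0", "t1"] == pytest.approx(2 / 4)

    def test_zero_range_trait_contributes_nothing(self, caplog):
        taxa = pool_frame([1.0, 2.0, 3.0], [2, 2, 2])
        with caplog.at_level("WARNING"):
            d = gower_matrix(taxa)
        assert "zero range" in caplog.text
        assert d.loc["t0", "t2"] == pytest.approx(0.5 * 1.0)  # length only


class TestTraitSpace:
    def test_three_equidistant_taxa_embed_as_equilateral_triangle(self):
        ids = ["a", "b", "c"]
        d = pd.DataFrame(1.0 - np.eye(3), index=ids, columns=ids)
        space = build_trait_space(d, n_axes=2)
        pts = space.coords.to_numpy()
        dists = [np.linalg.norm(pts[i] - pts[j])
                 for i, j in itertools.combinations(range(3), 2)]
        assert max(dists) - min(dists) < 1e-9

    def test_single_informative_axis(self):
        taxa = pool_frame([1.0, 2.0, 3.0, 4.0], [2, 2, 2, 2])
        space = build_trait_space(gower_matrix(taxa))
        assert space.eigenvalues[0] > 1e-6
        assert abs(space.eigenvalues[1]) < 1e-8

    def test_embedding_correlates_with_gower(self):
        # the two-trait Gower metric is city-block, so a rank-2 Euclidean
        # embedding cannot be exact; it must still track the input strongly
        rng = np.random.default_rng(0)
        for trial in range(5):
            taxa = pool_frame(rng.uniform(0.3, 5.0, 20).round(3),
                              rng.integers(1, 5, 20))
            g = gower_matrix(taxa)
            space = build_trait_space(g)
            pts = space.coords.to_numpy()
            emb = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
            iu = np.triu_indices(20, k=1)
            r = np.corrcoef(emb[iu], g.to_numpy()[iu])[0, 1]
            assert r > 0.95

    def test_degenerate_pool_rejected(self):
        ids = ["a", "b"]
        d = pd.DataFrame(np.zeros((2, 2)), index=ids, columns=ids)
        with pytest.raises(ValueError, match="degenerate"):
            build_trait_space(d)


def square_space():
    """Pool hull = 2x2 square; inner 4 taxa form a unit square."""
    pts = np.array([
        [-1, -1], [-1, 1], [1, -1], [1, 1],      # outer corners
        [-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5],  # inner
    ], dtype=float)
    ids = [f"p{i}" for i in range(8)]
    coords = pd.DataFrame(pts, index=ids, columns=["axis1", "axis2"])
    return TraitSpace(coords, eigenvalues=np.array([1.0, 1.0]))


class TestFunctionalMetrics:
    def test_square_hull_ratio(self):
        space = square_space()
        assert space.pool_hull_volume == pytest.approx(4.0, abs=1e-9)
        fric = functional_richness(space, ["p4", "p5", "p6", "p7"])
        assert fric == pytest.approx(0.25, abs=1e-9)

    def test_full_pool_is_one(self, small_space):
        ids = list(small_space.coords.index)
        assert functional_richness(small_space, ids) == pytest.approx(1.0)

    def test_two_taxa_hull_missing(self):
        space = square_space()
        assert np.isnan(functional_richness(space, ["p0", "p3"]))

    def test_collinear_community_missing_not_zero(self):
        space = square_space()
        assert np.isnan(functional_richness(space, ["p0", "p1", "p5"])) or \
            functional_richness(space, ["p0", "p1", "p5"]) > 0
        # exactly collinear points (x = -1 edge plus midpoint on that line)
        pts = space.coords.loc[["p0", "p1"]].to_numpy()
        assert np.isnan(functional_richness(space, ["p0", "p1"]))

    def test_fric_monotone_under_superset(self, small_space):
        rng = np.random.default_rng(5)
        ids = np.array(small_space.coords.index)
        for _ in range(20):
            base = rng.choice(ids, size=5, replace=False)
            extra = rng.choice(np.setdiff1d(ids, base), size=3, replace=False)
            f_small = functional_richness(small_space, base)
            f_big = functional_richness(small_space, np.concatenate([base, extra]))
            if np.isfinite(f_small) and np.isfinite(f_big):
                assert f_big >= f_small - 1e-12

    def test_fdis_two_points(self):
        space = square_space()
        d = np.linalg.norm([2.0, 2.0])  # p0 to p3
        assert functional_dispersion(space, ["p0", "p3"]) == pytest.approx(d / 2)

    def test_fdis_identical_points_zero(self):
        pts = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, -1.0]],
                           index=["a", "b", "c", "d"],
                           columns=["axis1", "axis2"])
        space = TraitSpace(pts, np.array([1.0, 1.0]))
        assert functional_dispersion(space, ["a", "b"]) == 0.0

    def test_fdis_matches_brute_force(self, small_space):
        rng = np.random.default_rng(6)
        ids = np.array(small_space.coords.index)
        comm = rng.choice(ids, size=6, replace=False)
        pts = small_space.points_of(comm)
        brute = np.mean([np.linalg.norm(p - pts.mean(0)) for p in pts])
        assert functional_dispersion(small_space, comm) == pytest.approx(brute)

    def test_cwm_values(self, tiny_taxa):
        got = community_weighted_means(
            tiny_taxa, ["Daphnia_pulex", "Holopedium_gibberum"])
        assert got["cwm_length"] == pytest.approx((1.5 + 1.0) / 2)
        assert got["cwm_guild"] == pytest.approx((2 + 3) / 2)
        single = community_weighted_means(tiny_taxa, ["Cyclops_scutifer"])
        assert single["cwm_length"] == pytest.approx(1.1)
        assert single["cwm_guild"] == pytest.approx(4.0)


def brute_force_pd(tree, community, include_root=True):
    """Oracle: union of root-to-tip edge sets via explicit parent walks."""
    edges = {}
    for leaf in tree.tree.leaf_node_iter():
        if leaf.taxon.label not in community:
            continue
        node = leaf
        path = []
        while node.parent_node is not None:
            path.append((id(node), node.edge.length or 0.0))
            node = node.parent_node
        edges[leaf.taxon.label] = path
    union = {}
    for path in edges.values():
        union.update(dict(path))
    total = sum(union.values())
    if not include_root:
        shared = set.intersection(*(set(dict(p)) for p in edges.values()))
        total -= sum(union[e] for e in shared)
    return total


class TestPhylogeneticMetrics:
    def test_two_congeners_pd_with_root(self):
        taxa = pd.DataFrame({
            "taxon_id": ["x", "y"], "species": ["G a", "G b"],
            "genus": "G", "family": "F", "order": "O", "class": "C",
            "rank": "species"})
        tree = build_tree(taxa)
        # cherry tips 1+1 plus collapsed genus->root path of 4
        assert faith_pd(tree, ["x", "y"], include_root=True) == pytest.approx(6.0)
        assert faith_pd(tree, ["x", "y"], include_root=False) == pytest.approx(2.0)

    def test_pd_whole_tree_is_total_branch_length(self, small_tree):
        total = sum(e.length for e in small_tree.edges)
        assert faith_pd(small_tree, small_tree.tip_labels) == pytest.approx(total)

    def test_pd_matches_edge_set_oracle(self, small_tree):
        rng = np.random.default_rng(7)
        tips = np.array(small_tree.tip_labels)
        for _ in range(50):
            s = int(rng.integers(2, min(12, len(tips))))
            comm = set(rng.choice(tips, size=s, replace=False))
            for root in (True, False):
                assert faith_pd(small_tree, comm, include_root=root) == \
                    pytest.approx(brute_force_pd(small_tree, comm, root))

    def test_pd_two_tips_no_root_equals_patristic(self, small_tree):
        rng = np.random.default_rng(8)
        tips = np.array(small_tree.tip_labels)
        for _ in range(10):
            a, b = rng.choice(tips, size=2, replace=False)
            i, j = small_tree.indices_of([a, b])
            assert faith_pd(small_tree, [a, b], include_root=False) == \
                pytest.approx(small_tree.patristic[i, j])

    def test_pd_monotone_under_superset(self, small_tree):
        rng = np.random.default_rng(9)
        tips = np.array(small_tree.tip_labels)
        base = rng.choice(tips, size=4, replace=False)
        extra = rng.choice(np.setdiff1d(tips, base), size=3, replace=False)
        assert faith_pd(small_tree, np.concatenate([base, extra])) >= \
            faith_pd(small_tree, base)

    def test_mpd_examples(self):
        taxa = pd.DataFrame({
            "taxon_id": ["x", "y", "z"],
            "species": ["G a", "G b", "H c"],
            "genus": ["G", "G", "H"], "family": ["F", "F", "F2"],
            "order": ["O", "O", "O2"], "class": ["C", "C", "C2"],
            "rank": "species"})
        tree = build_tree(taxa)
        assert mean_pairwise_distance(tree, ["x", "y"]) == pytest.approx(2.0)
        assert mean_pairwise_distance(tree, ["x", "y", "z"]) == pytest.approx(
            (2 + 10 + 10) / 3)

    def test_mpd_matches_brute_force(self, small_tree):
        rng = np.random.default_rng(10)
        tips = np.array(small_tree.tip_labels)
        comm = rng.choice(tips, size=7, replace=False)
        idx = small_tree.indices_of(comm)
        brute = np.mean([small_tree.patristic[i, j]
                         for i, j in itertools.combinations(idx, 2)])
        assert mean_pairwise_distance(small_tree, comm) == pytest.approx(brute)

    def test_unknown_tip_raises(self, small_tree):
        with pytest.raises(KeyError, match="nope"):
            faith_pd(small_tree, ["nope", small_tree.tip_labels[0]])


class TestEngineAndTable:
    def test_engine_agrees_with_reference_functions(self, small_space, small_tree):
        engine = CommunityMetricsEngine(small_space, small_tree)
        rng = np.random.default_rng(11)
        tips = np.array(small_tree.tip_labels)
        for _ in range(20):
            s = int(rng.integers(2, 10))
            comm = rng.choice(tips, size=s, replace=False)
            assert engine.pd(comm) == pytest.approx(faith_pd(small_tree, comm))
            assert engine.mpd(comm) == pytest.approx(
                mean_pairwise_distance(small_tree, comm))
            got, want = engine.fdis(comm), functional_dispersion(small_space, comm)
            assert got == pytest.approx(want, nan_ok=True)
            got, want = engine.fric(comm), functional_richness(small_space, comm)
            assert got == pytest.approx(want, nan_ok=True)

    def test_metrics_table_order_invariance(self, small_world, small_space,
                                            small_tree):
        lakes, taxa, occ = small_world
        occ = occ.iloc[:40]
        m1 = community_metrics(occ, taxa, small_space, small_tree)
        rng = np.random.default_rng(12)
        occ_shuf = occ.sample(frac=1, random_state=1)[
            rng.permutation(occ.columns)]
        m2 = community_metrics(occ_shuf, taxa, small_space, small_tree)
        merged = m1.merge(m2, on="lake_id", suffixes=("_a", "_b"))
        for col in ("richness", "fric", "fdis", "pd", "mpd", "cwm_length"):
            a, b = merged[f"{col}_a"], merged[f"{col}_b"]
            assert np.allclose(a, b, equal_nan=True)

    def test_eligibility_ordering(self, small_world, small_space, small_tree):
        lakes, taxa, occ = small_world
        m = community_metrics(occ, taxa, small_space, small_tree)
        assert (m["richness"] >= 0).all()
        assert m["pd_eligible"].sum() >= m["fric_eligible"].sum()
        # MPD bounded by the 5-level tree geometry
        mpd = m["mpd"].dropna()
        assert mpd.between(2.0, 10.0).all()
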