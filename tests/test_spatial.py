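"""Inflammatory-spot calling, hex rings, and the inside-out axis."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nichetrack import scoring, spatial, synthetic
from nichetrack.config import PipelineConfig
from nichetrack.datatypes import GeneSet, ParameterError, SpotGrid
from conftest import block_genes


def full_lattice(rows=9, cols=9):
    r, c = [], []
    for i in range(rows):
        for k in range(cols):
            r.append(i)
            c.append(i % 2 + 2 * k)
    r, c = np.array(r), np.array(c)
    n = r.size
    return SpotGrid(
        spot_ids=[f"s{i}" for i in range(n)],
        array_row=r,
        array_col=c,
        pixel_xy=np.column_stack([c * 50.0, r * 86.6]),
        gene_ids=["gA"],
        counts=np.ones((1, n), dtype=int),
    )


class TestHexAdjacency:
    def test_isolated_spot_has_no_neighbors(self):
        g = SpotGrid(
            spot_ids=["a"], array_row=[0], array_col=[0],
            pixel_xy=[[0.0, 0.0]], gene_ids=["g"], counts=[[1]],
        )
        assert spatial.hex_adjacency(g) == {"a": []}

    def test_interior_spot_has_six_neighbors(self):
        g = full_lattice()
        adj = spatial.hex_adjacency(g)
        interior = [
            s for s, r, c in zip(g.spot_ids, g.array_row, g.array_col)
            if 2 <= r <= 6 and 4 <= c <= 12
        ]
        assert interior and all(len(adj[s]) == 6 for s in interior)

    def test_adjacency_symmetric(self):
        g = full_lattice(5, 5)
        adj = spatial.hex_adjacency(g)
        for s, nbrs in adj.items():
            for nb in nbrs:
                assert s in adj[nb]

    @given(st.integers(2, 6), st.integers(2, 6))
    @settings(max_examples=20, deadline=None)
    def test_neighbor_distance_equals_pitch(self, rows, cols):
        g = full_lattice(rows, cols)
        adj = spatial.hex_adjacency(g)
        idx = {s: i for i, s in enumerate(g.spot_ids)}
        for s, nbrs in adj.items():
            for nb in nbrs:
                d = np.linalg.norm(g.pixel_xy[idx[s]] - g.pixel_xy[idx[nb]])
                assert d == pytest.approx(100.0, rel=1e-3)


class TestCallInflammatorySpots:
    def make_scores(self, values):
        s = pd.Series(values, index=[f"s{i}" for i in range(len(values))])
        return scoring.ModuleScoreResult(
            scores=s, gene_set="ifng", controls={}, n_bins=24, seed=0
        )

    def test_nonpositive_scores_give_empty_mask(self):
        mask = spatial.call_inflammatory_spots(self.make_scores([-0.2, 0.0, -1e-12]))
        assert not mask.any()

    def test_zero_score_is_not_inflammatory(self):
        mask = spatial.call_inflammatory_spots(self.make_scores([0.0, 1e-9]))
        assert mask.tolist() == [False, True]

    def test_planted_hotspots_called_precisely(self):
        # dense band of foci with fast (one-pitch) decay: called spots must
        # concentrate within two pitches of the planted centers
        centers = [
            (3, 5), (4, 11), (6, 16), (7, 22), (9, 27), (10, 32),
            (12, 6), (13, 12), (15, 17), (16, 23), (18, 28), (19, 35),
        ]
        p = synthetic.SpotSimParams(hotspot_centers=centers, decay_um=100.0)
        grid, truth = synthetic.simulate_spot_grid(p, seed=2)
        expr = grid.as_expression()
        scoring.log_normalize(expr)
        gs = GeneSet("ifng", tuple(block_genes(truth, "inflammatory")))
        res = scoring.module_score(expr, gs, seed=0)
        mask = spatial.call_inflammatory_spots(res)
        d = truth["spots"].set_index("spot_id")["dist_to_hotspot_um"]
        called = d[mask[mask].index]
        assert len(called) > 0
        assert (called <= 200.0).mean() >= 0.8


class TestSpotHierarchy:
    def single_is(self, grid, row, col):
        mask = pd.Series(False, index=grid.spot_ids)
        hit = [
            s for s, r, c in zip(grid.spot_ids, grid.array_row, grid.array_col)
            if r == row and c == col
        ]
        mask[hit[0]] = True
        return mask

    def test_single_interior_is_gives_hex_ring_sizes(self):
        g = full_lattice(11, 11)
        adj = spatial.hex_adjacency(g)
        h = spatial.build_spot_hierarchy(self.single_is(g, 5, 11), adj)
        sizes = h.classes.value_counts()
        assert sizes["IS"] == 1 and sizes["NNS"] == 6
        assert sizes["ENS1"] == 12 and sizes["ENS2"] == 18

    def test_ring_sizes_match_bfs_oracle(self):
        g = full_lattice(11, 11)
        adj = spatial.hex_adjacency(g)
        h = spatial.build_spot_hierarchy(self.single_is(g, 5, 11), adj)
        # brute-force BFS depths from the IS spot
        import collections

        start = h.spots_of("IS")[0]
        depth = {start: 0}
        q = collections.deque([start])
        while q:
            s = q.popleft()
            for nb in adj[s]:
                if nb not in depth:
                    depth[nb] = depth[s] + 1
                    q.append(nb)
        names = {0: "IS", 1: "NNS", 2: "ENS1", 3: "ENS2"}
        for s, cls in h.classes.items():
            assert cls == names.get(depth.get(s, 99), "other")

    def test_no_is_yields_all_other(self):
        g = full_lattice(5, 5)
        adj = spatial.hex_adjacency(g)
        mask = pd.Series(False, index=g.spot_ids)
        h = spatial.build_spot_hierarchy(mask, adj)
        assert set(h.classes) == {"other"}

    def test_adjacent_is_share_nns_without_double_count(self):
        g = full_lattice(9, 9)
        adj = spatial.hex_adjacency(g)
        mask = pd.Series(False, index=g.spot_ids)
        pair = [
            s for s, r, c in zip(g.spot_ids, g.array_row, g.array_col)
            if (r, c) in [(4, 8), (4, 10)]
        ]
        mask[pair] = True
        h = spatial.build_spot_hierarchy(mask, adj)
        sizes = h.classes.value_counts()
        assert sizes["IS"] == 2 and sizes["NNS"] == 8  # two fused hexagons

    def test_classes_partition_masked_spots(self, spot_sim):
        grid, truth = spot_sim
        gs = GeneSet("ifng", tuple(block_genes(truth, "inflammatory")))
        res = scoring.module_score(grid.as_expression(), gs, seed=0)
        h = spatial.build_spot_hierarchy(
            spatial.call_inflammatory_spots(res), spatial.hex_adjacency(grid)
        )
        assert sorted(h.classes.index) == sorted(grid.spot_ids)
        assert set(h.classes) <= set(spatial.HIERARCHY_CLASSES)

    def test_idempotent_and_order_independent(self):
        g = full_lattice(7, 7)
        adj = spatial.hex_adjacency(g)
        mask = self.single_is(g, 3, 7)
        h1 = spatial.build_spot_hierarchy(mask, adj)
        h2 = spatial.build_spot_hierarchy(mask.iloc[::-1], adj)
        pd.testing.assert_series_equal(h1.classes.sort_index(), h2.classes.sort_index())


class TestPseudoSpace:
    def test_gradient_and_inside_out_ordering(self, spot_sim):
        grid, truth = spot_sim
        gs = GeneSet("ifng", tuple(block_genes(truth, "inflammatory")))
        res = scoring.module_score(grid.as_expression(), gs, seed=0)
        h = spatial.build_spot_hierarchy(
            spatial.call_inflammatory_spots(res), spatial.hex_adjacency(grid)
        )
        means = [res.scores[h.spots_of(c)].mean() for c in ("IS", "NNS", "ENS1", "ENS2")]
        assert all(np.diff(means) < 0)  # IFN signal decreases outward
        ps = spatial.pseudospatial_modules(grid, h, 4, PipelineConfig(seed=0))
        s = [ps.class_summary.loc[c, "mean"] for c in ("IS", "NNS", "ENS1", "ENS2")]
        assert all(np.diff(s) > 0)  # ordering runs inside-out

    def test_inflammatory_block_in_innermost_module(self, spot_sim):
        grid, truth = spot_sim
        gs = GeneSet("ifng", tuple(block_genes(truth, "inflammatory")))
        res = scoring.module_score(grid.as_expression(), gs, seed=0)
        h = spatial.build_spot_hierarchy(
            spatial.call_inflammatory_spots(res), spatial.hex_adjacency(grid)
        )
        ps = spatial.pseudospatial_modules(grid, h, 4, PipelineConfig(seed=0))
        inflam = block_genes(truth, "inflammatory")
        mods = ps.modules.module.reindex(inflam).dropna()
        assert (mods == 1).mean() > 0.9

    def test_uniform_expression_rejected(self):
        g = full_lattice(7, 7)
        n = g.n_spots
        g = SpotGrid(
            spot_ids=g.spot_ids, array_row=g.array_row, array_col=g.array_col,
            pixel_xy=g.pixel_xy, gene_ids=[f"g{i}" for i in range(30)],
            counts=np.ones((30, n), dtype=int),
        )
        expr = g.as_expression()
        scoring.log_normalize(expr)
        g.set_lognorm(expr.lognorm)
        mask = pd.Series(False, index=g.spot_ids)
        mask.iloc[20] = True
        h = spatial.build_spot_hierarchy(mask, spatial.hex_adjacency(g))
        with pytest.raises(ParameterError, match="degenerate"):
            spatial.pseudospatial_modules(g, h, 4, PipelineConfig(seed=0))
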