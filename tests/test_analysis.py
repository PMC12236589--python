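"""Ratemap aggregation, decoding, place-cell metrics, recall, PCA."""

import numpy as np
import pytest

from gridmind.analysis import (
    CellCriteria,
    aggregate_ratemaps,
    decode_position,
    detect_field_centers,
    grid_metrics,
    identify_place_cells,
    measure_grid_geometry,
    occupancy_distribution,
    project_recall_pca,
    recall_query,
    spatial_information,
)
from gridmind.env import Arena, Trajectory
from gridmind.maps import (
    PhaseHierarchy,
    Ratemap,
    SMCSpec,
    make_grid_modules,
    make_smc_map,
    sample_responses,
)
from gridmind.models import HCMECModel, TrainConfig, World
from gridmind.network import RNNParams


@pytest.fixture(scope="module")
def arena():
    return Arena(100.0, 100.0, 4.0)


class TestAggregation:
    def test_constant_unit_yields_flat_map_on_visited_bins(self, arena):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 100, size=(500, 2))
        act = np.full((500, 1), 0.7)
        rmap = aggregate_ratemaps(pos, act, arena)
        assert np.allclose(rmap.rates[rmap.valid], 0.7)

    def test_roundtrip_recovers_ground_truth_on_visited_bins(self, arena):
        smc = make_smc_map(SMCSpec(n_cells=5, correlation_length=25.0), arena, 1)
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 100, size=(3000, 2))
        traj = Trajectory(pos, np.zeros(3000), np.ones(3000), 0.05)
        resp = sample_responses(smc, traj)
        rmap = aggregate_ratemaps(pos, resp, arena)
        v = rmap.valid
        assert np.allclose(rmap.rates[v], smc.rates[v], atol=1e-12)

    def test_unvisited_bins_flagged_invalid_not_zero(self, arena):
        pos = np.tile([10.0, 10.0], (20, 1))
        rmap = aggregate_ratemaps(pos, np.ones((20, 2)), arena)
        assert rmap.valid.sum() == 1
        assert not rmap.valid[5, 5]

    def test_zero_occupancy_rejected(self, arena):
        with pytest.raises(ValueError):
            aggregate_ratemaps(np.empty((0, 2)), np.empty((0, 1)), arena)


class TestDecoding:
    @pytest.fixture(scope="class")
    def smc(self, arena):
        return make_smc_map(SMCSpec(n_cells=12, correlation_length=20.0),
                            arena, 2)

    def test_exact_dictionary_vector_decodes_to_its_bin(self, arena, smc):
        q = smc.rates[7, 13]
        pos = decode_position(q, smc)
        assert pos[0] == pytest.approx((7 + 0.5) * 4.0)
        assert pos[1] == pytest.approx((13 + 0.5) * 4.0)

    def test_subgap_noise_preserves_decoded_bin(self, arena, smc):
        flat = smc.flattened()
        q = flat[321]
        d = np.linalg.norm(flat - q, axis=1)
        gap = np.partition(d, 1)[1]
        rng = np.random.default_rng(3)
        noise = rng.normal(size=q.shape)
        noise *= 0.49 * gap / np.linalg.norm(noise)
        assert np.array_equal(decode_position(q, smc), decode_position(q + noise, smc))

    def test_tie_breaks_to_lowest_flattened_index(self, arena):
        rates = np.zeros((5, 5, 2))
        rates[1, 1] = rates[3, 2] = [1.0, 1.0]  # identical dictionary entries
        rmap = Ratemap(rates, Arena(20, 20, 4.0))
        pos = decode_position(np.array([1.0, 1.0]), rmap)
        # bin (1,1) precedes bin (3,2) in flattened order
        assert np.allclose(pos, [6.0, 6.0])

    def test_matches_bruteforce_linear_scan(self, arena, smc):
        rng = np.random.default_rng(4)
        queries = rng.uniform(0, 1, size=(200, smc.n_cells))
        got = decode_position(queries, smc)
        flat = smc.flattened()
        for q, g in zip(queries, got):
            idx = int(np.argmin(np.sum((flat - q) ** 2, axis=1)))
            ix, iy = idx // arena.ny, idx % arena.ny
            assert np.allclose(g, [(ix + 0.5) * 4.0, (iy + 0.5) * 4.0])

    def test_query_length_mismatch_rejected(self, smc):
        with pytest.raises(ValueError):
            decode_position(np.ones(3), smc)


class TestSpatialInformation:
    def test_uniform_cell_carries_no_information(self):
        occ = np.full((10, 10), 0.01)
        assert spatial_information(np.full((10, 10), 3.0), occ) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_single_active_bin_gives_log2_B(self):
        B = 64
        occ = np.full(B, 1 / B)
        rates = np.zeros(B)
        rates[17] = 5.0
        assert spatial_information(rates, occ) == pytest.approx(np.log2(B))

    def test_invariant_to_rate_scaling(self):
        rng = np.random.default_rng(5)
        rates = rng.uniform(0, 2, (8, 8))
        occ = rng.dirichlet(np.ones(64)).reshape(8, 8)
        a = spatial_information(rates, occ)
        b = spatial_information(7.3 * rates, occ)
        assert a == pytest.approx(b, rel=1e-9)

    def test_sharpening_increases_information(self):
        occ = np.full(100, 0.01)
        broad = np.zeros(100); broad[:10] = 1.0
        sharp = np.zeros(100); sharp[:2] = 5.0
        assert spatial_information(sharp, occ) > spatial_information(broad, occ)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            spatial_information(np.array([-1.0, 1.0]), np.array([0.5, 0.5]))


class TestPlaceCellIdentification:
    def test_silent_population_yields_empty_list(self, arena):
        rmap = Ratemap(np.zeros((arena.nx, arena.ny, 4)), arena, "HPC")
        occ = np.full((arena.nx, arena.ny), 1 / (arena.nx * arena.ny))
        assert identify_place_cells(rmap, occ) == []

    def test_single_field_unit_passes_uniform_unit_fails(self, arena):
        nx, ny = arena.nx, arena.ny
        rates = np.zeros((nx, ny, 2))
        rates[10:13, 10:13, 0] = 1.0          # compact place field
        rates[:, :, 1] = 0.2                   # spatially uniform
        occ = np.full((nx, ny), 1 / (nx * ny))
        picked = identify_place_cells(Ratemap(rates, arena, "HPC"), occ,
                                      CellCriteria(min_rate=0.001, min_sic=0.5))
        assert picked == [0]


class TestGridMetrics:
    @pytest.fixture(scope="class")
    def grid_cell_map(self):
        arena = Arena(120.0, 120.0, 2.0)
        h = PhaseHierarchy.from_smallest_period(30.0, n_modules=1)
        (mod, rmap), = make_grid_modules(h, 1, arena, seed=0)
        return rmap.rates[:, :, 0]

    def test_ideal_grid_cell_scores_positive(self, grid_cell_map):
        out = grid_metrics(grid_cell_map)
        assert out["grid_score"] > 0

    def test_single_gaussian_field_scores_nonpositive(self):
        x, y = np.meshgrid(np.arange(60), np.arange(60), indexing="ij")
        blob = np.exp(-((x - 30) ** 2 + (y - 30) ** 2) / (2 * 6.0**2))
        assert grid_metrics(blob)["grid_score"] <= 0

    def test_autocorrelogram_is_one_at_zero_lag(self, grid_cell_map):
        ac = grid_metrics(grid_cell_map)["autocorrelogram"]
        cx, cy = (np.array(ac.shape) - 1) // 2
        assert ac[cx, cy] == pytest.approx(1.0)

    def test_constant_map_has_undefined_score(self):
        out = grid_metrics(np.full((40, 40), 2.0))
        assert np.isnan(out["grid_score"])


class TestFieldGeometry:
    def test_module1_spacing_and_ratio(self):
        arena = Arena(150.0, 150.0, 1.0)
        h = PhaseHierarchy.from_smallest_period(30.0, n_modules=1)
        (mod, rmap), = make_grid_modules(h, 2, arena, seed=0)
        geom = measure_grid_geometry(rmap.rates[:, :, 1], arena, mod.field_sigma)
        assert geom["spacing"] == pytest.approx(30.0, abs=1.0)
        assert geom["ratio"] == pytest.approx(3.26, abs=0.05)

    def test_field_centers_on_lattice(self):
        arena = Arena(150.0, 150.0, 1.0)
        h = PhaseHierarchy.from_smallest_period(30.0, n_modules=1)
        (mod, rmap), = make_grid_modules(h, 1, arena, seed=3)
        centers = detect_field_centers(rmap.rates[:, :, 0], arena,
                                       mod.field_sigma)
        # every detected center sits within a bin of some lattice point
        frac = np.linalg.solve(mod.lattice_basis, centers.T).T
        err = np.abs(frac - np.round(frac)) @ np.abs(mod.lattice_basis.T)
        assert np.all(np.linalg.norm(err, axis=1) < 1.5)


class TestRecallProtocol:
    @pytest.fixture(scope="class")
    def world(self):
        return World.build(
            1, arena=Arena(80, 80, 4.0), n_modules=2, cells_per_module=8,
            smc_spec=SMCSpec(n_cells=12, correlation_length=15.0),
        )

    def test_untrained_network_fails_to_recall(self, world):
        """Negative control: a random network does not converge to the cued
        location."""
        model = HCMECModel(world, n_hidden=16)
        params = RNNParams.init(model.layout, 0)
        target = np.array([40.0, 40.0])
        trace = recall_query(
            params, world, world.smc_pattern(target), Tq=100,
            target_position=target,
        )
        assert len(trace.distances["GC"]) == 100
        assert trace.distances["GC"][-1] > 2 * world.sigma1

    def test_query_horizon_matches_Tq(self, world):
        model = HCMECModel(world, n_hidden=16)
        params = RNNParams.init(model.layout, 0)
        trace = recall_query(params, world, world.smc_pattern([20.0, 20.0]),
                             Tq=37)
        assert trace.states.shape[0] == 38
        for pos in trace.decoded.values():
            assert pos.shape == (37, 2)


class TestRecallPCA:
    def test_projection_properties(self, arena):
        smc = make_smc_map(SMCSpec(n_cells=10, correlation_length=20.0),
                           arena, 6)
        rng = np.random.default_rng(7)
        states = rng.uniform(0, 1, size=(50, 10))
        out = project_recall_pca(smc, states)
        assert out["map_coords"].shape == (arena.nx * arena.ny, 3)
        assert out["trace_coords"].shape == (50, 3)
        evr = out["explained_variance_ratio"]
        assert evr.sum() <= 1.0 + 1e-9

    def test_target_response_lands_on_projected_manifold_point(self, arena):
        smc = make_smc_map(SMCSpec(n_cells=10, correlation_length=20.0),
                           arena, 6)
        out = project_recall_pca(smc, smc.rates[4, 9][None, :])
        idx = 4 * arena.ny + 9
        assert np.allclose(out["trace_coords"][0], out["map_coords"][idx],
                           atol=1e-9)

    def test_too_few_cells_rejected(self, arena):
        rmap = Ratemap(np.ones((arena.nx, arena.ny, 2)), arena)
        with pytest.raises(ValueError):
            project_recall_pca(rmap, np.ones((3, 2)))
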