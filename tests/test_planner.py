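"""Toroidal phase algebra, Markov sequential planning, vector navigation."""

import math

import numpy as np
import pytest

from gridmind.maps import GridModuleSpec, PhaseHierarchy
from gridmind.planner import (
    ModulePhase,
    build_transition_matrix,
    combine_multiscale,
    contraction_margin,
    decode_module_displacement,
    modules_from_hierarchy,
    phase_of_position,
    plan_phase_path,
    vector_navigate,
    wrap_phase,
)


def brute_force_wrap(raw):
    """Oracle: enumerate all 2pi-shifted candidates, keep the one in (-pi, pi]."""
    out = np.empty_like(raw)
    for i, r in enumerate(np.atleast_1d(raw)):
        cands = [r + 2 * np.pi * k for k in range(-3, 4)]
        sel = [c for c in cands if -np.pi < c <= np.pi]
        assert len(sel) == 1
        out[i] = sel[0]
    return out


class TestPhaseAlgebra:
    def test_phase_at_lattice_points_is_zero(self):
        mod = GridModuleSpec(30.0, orientation=0.3)
        for ab in ([0, 0], [3, -2], [-1, 5]):
            pos = mod.lattice_basis @ np.array(ab, dtype=float)
            phi = phase_of_position(pos, mod).phi
            assert np.allclose(np.minimum(phi, 2 * np.pi - phi), 0.0, atol=1e-9)

    def test_phase_is_linear_in_lattice_coordinates(self):
        mod = GridModuleSpec(30.0)
        pos = mod.lattice_basis @ np.array([0.25, 0.5])
        assert np.allclose(phase_of_position(pos, mod).phi, [np.pi / 2, np.pi])

    def test_phase_periodicity_under_lattice_shifts(self):
        mod = GridModuleSpec(42.0, orientation=0.7)
        rng = np.random.default_rng(0)
        for _ in range(50):
            pos = rng.uniform(-100, 100, 2)
            ab = rng.integers(-4, 5, 2).astype(float)
            p1 = phase_of_position(pos, mod).phi
            p2 = phase_of_position(pos + mod.lattice_basis @ ab, mod).phi
            assert np.allclose(p1, p2, atol=1e-8)

    def test_singular_basis_rejected(self):
        with pytest.raises(ValueError):
            phase_of_position([1.0], np.array([[0.0]]))


class TestDisplacementDecoding:
    def test_identical_phases_decode_to_zero(self):
        mod = GridModuleSpec(30.0)
        phi = ModulePhase(np.array([1.0, 2.0]))
        assert np.allclose(decode_module_displacement(phi, phi, mod), 0.0)

    def test_1d_quarter_turn_is_quarter_period(self):
        d = decode_module_displacement(
            np.array([np.pi / 2]), np.array([np.pi]), np.array([[30.0]])
        )
        assert d == pytest.approx(7.5)

    def test_2d_wrap_selects_principal_candidate(self):
        # target phase (3pi/2, pi/2) from (0,0) wraps to (-pi/2, +pi/2)
        mod = GridModuleSpec(30.0)
        d = decode_module_displacement(
            np.array([0.0, 0.0]), np.array([3 * np.pi / 2, np.pi / 2]), mod
        )
        expect = mod.lattice_basis @ np.array([-0.25, 0.25])
        assert np.allclose(d, expect)

    @pytest.mark.parametrize("dims", [1, 2])
    def test_wrap_matches_bruteforce_oracle(self, dims):
        rng = np.random.default_rng(dims)
        basis = np.array([[30.0]]) if dims == 1 else GridModuleSpec(30.0).lattice_basis
        for _ in range(500):
            pc = rng.uniform(0, 2 * np.pi, dims)
            pt = rng.uniform(0, 2 * np.pi, dims)
            got = decode_module_displacement(pc, pt, basis)
            expect = basis @ (brute_force_wrap(pt - pc) / (2 * np.pi))
            assert np.allclose(got, expect, atol=1e-12)

    def test_per_axis_magnitude_bounded_by_half_period(self):
        rng = np.random.default_rng(1)
        period = 30.0
        for _ in range(1000):
            pc, pt = rng.uniform(0, 2 * np.pi, (2, 1))
            d = decode_module_displacement(pc, pt, np.array([[period]]))
            assert abs(d[0]) <= period / 2 + 1e-12

    def test_antipodal_tie_resolves_to_positive_direction(self):
        assert wrap_phase(np.array([np.pi]))[0] == pytest.approx(np.pi)
        assert wrap_phase(np.array([-np.pi]))[0] == pytest.approx(np.pi)


class TestMultiscaleCombination:
    def test_single_module_reduces_to_module_decoder(self):
        mod = GridModuleSpec(30.0)
        rng = np.random.default_rng(2)
        pc = ModulePhase(rng.uniform(0, 2 * np.pi, 2))
        pt = ModulePhase(rng.uniform(0, 2 * np.pi, 2))
        assert np.allclose(
            combine_multiscale([pc], [pt], [mod]),
            decode_module_displacement(pc, pt, mod),
        )

    def test_two_scale_1d_worked_example(self):
        # l1=30, l2=30e, true displacement 20: module 1 is undercovered
        h = PhaseHierarchy(30.0 / math.e, math.e, 2)
        mods = modules_from_hierarchy(h, dims=1)
        pc = [phase_of_position([0.0], m) for m in mods]
        pt = [phase_of_position([20.0], m) for m in mods]
        d_hat = combine_multiscale(pc, pt, mods)
        assert d_hat[0] == pytest.approx(5.0)
        assert 20.0 - d_hat[0] == pytest.approx(15.0)

    def test_exact_when_all_scales_decodable(self):
        h = PhaseHierarchy.from_smallest_period(30.0, n_modules=4)
        mods = modules_from_hierarchy(h, dims=2)
        rng = np.random.default_rng(3)
        for _ in range(30):
            # decodable means within half a period along each lattice axis
            u = rng.uniform(-0.49, 0.49, 2)
            d = mods[0].lattice_basis @ u
            pc = [phase_of_position(np.zeros(2), m) for m in mods]
            pt = [phase_of_position(d, m) for m in mods]
            assert np.allclose(combine_multiscale(pc, pt, mods), d, atol=1e-8)

    def test_mismatched_lists_rejected(self):
        h = PhaseHierarchy.from_smallest_period(30.0, n_modules=2)
        mods = modules_from_hierarchy(h, dims=1)
        p = phase_of_position([1.0], mods[0])
        with pytest.raises(ValueError):
            combine_multiscale([p], [p, p], mods)


class TestContractionMargin:
    def test_zero_undercovered_scales_cost_nothing(self):
        assert contraction_margin(math.e, 0) == 0.0

    def test_known_value_for_s_e_k_1(self):
        assert contraction_margin(math.e, 1) == pytest.approx(1 / math.e)

    def test_below_one_for_s_e_all_k(self):
        for k in range(1, 30):
            assert contraction_margin(math.e, k) < 1.0

    def test_worst_case_margin_is_stricter(self):
        for s in (math.e, math.sqrt(math.e)):
            for k in (1, 3, 10):
                assert contraction_margin(s, k, worst_case=True) > contraction_margin(
                    s, k
                )

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            contraction_margin(0.9, 1)


class TestTransitionMatrix:
    def test_ideal_ring_rows_are_uniform_on_neighbourhood(self):
        tm = build_transition_matrix(8, dims=1)
        for i in range(8):
            support = {(i - 1) % 8, i, (i + 1) % 8}
            assert set(np.flatnonzero(tm.T[i])) == support
            assert np.allclose(tm.T[i, list(support)], 1 / 3)

    def test_rows_always_stochastic(self):
        rng = np.random.default_rng(4)
        seqs = [np.cumsum(rng.uniform(0, 0.3, 200)) % (2 * np.pi) for _ in range(5)]
        tm = build_transition_matrix(12, dims=1, phase_sequences=seqs)
        assert np.allclose(tm.T.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(tm.T >= 0)

    def test_small_step_walk_recovers_local_support(self):
        # phase increments below one bin width cannot skip bins
        n_bins = 10
        rng = np.random.default_rng(5)
        step = 2 * np.pi / n_bins * 0.4
        seqs = [np.cumsum(rng.uniform(-step, step, 500)) % (2 * np.pi)
                for _ in range(10)]
        tm = build_transition_matrix(n_bins, dims=1, phase_sequences=seqs)
        for i in range(n_bins):
            support = set(np.flatnonzero(tm.T[i]))
            assert support <= {(i - 1) % n_bins, i, (i + 1) % n_bins}

    def test_empty_trajectory_set_rejected(self):
        with pytest.raises(ValueError):
            build_transition_matrix(8, dims=1, phase_sequences=[])


class TestSequentialPlanning:
    def test_trivial_plan_start_equals_target(self):
        tm = build_transition_matrix(8, dims=1)
        res = plan_phase_path(tm, 3, 3)
        assert res.path == [3] and res.converged

    def test_ring_geodesic_both_directions(self):
        tm = build_transition_matrix(8, dims=1)
        assert plan_phase_path(tm, 0, 3).path == [0, 1, 2, 3]
        assert plan_phase_path(tm, 0, 5).path == [0, 7, 6, 5]

    def test_antipodal_tie_breaks_positive(self):
        tm = build_transition_matrix(8, dims=1)
        res = plan_phase_path(tm, 0, 4)
        assert res.path == [0, 1, 2, 3, 4]

    def test_plan_vector_remains_probability_vector(self):
        tm = build_transition_matrix(12, dims=1)
        res = plan_phase_path(tm, 0, 6)
        assert np.all(res.v_plan >= 0)
        assert res.v_plan.sum() == pytest.approx(1.0)

    def test_torus_plan_follows_chebyshev_geodesic(self):
        tm = build_transition_matrix(6, dims=2)
        start, target = tm.ravel((0, 0)), tm.ravel((2, 5))
        res = plan_phase_path(tm, start, target)
        assert res.converged
        assert len(res.path) - 1 == 2  # dx=2, dy=-1 wrapped

    def test_invalid_bin_rejected(self):
        tm = build_transition_matrix(8, dims=1)
        with pytest.raises(ValueError):
            plan_phase_path(tm, 0, 99)


class TestVectorNavigation:
    def setup_method(self):
        self.h1 = PhaseHierarchy(30.0 / math.e, math.e, 6)
        self.mods1 = modules_from_hierarchy(self.h1, dims=1)

    def test_start_at_target_takes_no_steps(self):
        tph = [phase_of_position([50.0], m) for m in self.mods1]
        nav = vector_navigate([50.0], tph, self.mods1, step_fraction=1.0)
        assert len(nav.positions) == 1 and nav.converged

    def test_one_step_convergence_when_fully_decodable(self):
        # d below half the smallest period: the average is exact
        tph = [phase_of_position([57.0], m) for m in self.mods1]
        nav = vector_navigate(
            [50.0], tph, self.mods1, step_fraction=1.0, tol=0.01
        )
        assert nav.converged
        assert len(nav.positions) == 2
        assert nav.positions[-1][0] == pytest.approx(57.0, abs=1e-6)

    def test_monotone_contraction_with_two_decodable_scales(self):
        rng = np.random.default_rng(6)
        halves = self.h1.periods / 2
        for _ in range(200):
            k = rng.integers(0, 5)  # at least two decodable scales
            lo = halves[k - 1] if k > 0 else 0.1
            d = rng.uniform(lo, halves[k] * 0.999)
            tph = [phase_of_position([d], m) for m in self.mods1]
            nav = vector_navigate(
                [0.0], tph, self.mods1, step_fraction=1.0,
                tol=self.h1.periods[0] / 20, max_steps=50,
            )
            rem = np.abs(d - nav.positions[:, 0])
            assert np.all(np.diff(rem) < 0)
            assert nav.converged

    def test_single_decodable_scale_admits_spurious_fixed_points(self):
        """With only the largest scale decodable, the averaged decoder can
        stall at a nonzero remaining distance: the undercovered wraps cancel
        the decodable contribution.  This bounds what the hierarchy
        guarantees (contraction needs two decodable scales)."""
        d = 1416.62
        tph = [phase_of_position([d], m) for m in self.mods1]
        nav = vector_navigate(
            [0.0], tph, self.mods1, step_fraction=1.0,
            tol=self.h1.periods[0] / 20, max_steps=200,
        )
        # the decoded-step estimate vanishes (phase-consistent stop) while
        # the true remaining distance is still hundreds of centimetres
        assert abs(d - nav.positions[-1][0]) > 10 * self.h1.periods[0]

    def test_invalid_step_fraction_rejected(self):
        with pytest.raises(ValueError):
            vector_navigate([0.0], [], [], step_fraction=0.0)
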