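"""Candidate grid, grid distribution reconstruction, and the sampling loop."""

import numpy as np
import pytest

from placemol.conditioning import ConditionSet
from placemol.experiments import brute_force_grid_distribution
from placemol.generator import (CandidateGrid, GenerationConfig,
                                build_candidate_grid, generate,
                                generation_step, grid_log_masses,
                                position_distribution_on_grid,
                                GenerationState)
from placemol.model_heads import DistanceBinning, bin_index
from placemol._autodiff import Tensor
from placemol import _autodiff as ad


class TestCandidateGrid:
    def test_spacing_equals_radius_gives_seven_points(self):
        g = build_candidate_grid(spacing=1.0, radius=1.0)
        assert g.n_points == 7  # center + 6 axial neighbors
        norms = np.linalg.norm(g.offsets, axis=1)
        assert sorted(np.round(norms, 9)) == [0.0] + [1.0] * 6

    def test_all_offsets_inside_sphere(self):
        g = build_candidate_grid(spacing=0.21, radius=1.3)
        assert np.all(np.linalg.norm(g.offsets, axis=1) <= 1.3 + 1e-9)

    def test_symmetric_under_negation(self):
        g = build_candidate_grid(spacing=0.37, radius=1.5)
        pts = {tuple(np.round(p, 9)) for p in g.offsets}
        assert pts == {tuple(np.round(-np.array(p), 9)) for p in pts}

    def test_degenerate_spec_rejected(self):
        with pytest.raises(ValueError):
            build_candidate_grid(spacing=0.0, radius=1.0)
        with pytest.raises(ValueError):
            build_candidate_grid(spacing=0.1, radius=-1.0)


class TestGridDistribution:
    def test_matches_brute_force_reference(self, tiny_model, rng):
        cfg = tiny_model.config
        binning = DistanceBinning.of(cfg)
        grid = build_candidate_grid(spacing=0.5, radius=1.7)
        origin, focus = cfg.token_type_codes
        with ad.no_grad():
            y = tiny_model.condition_vector(ConditionSet({"target": 1.0}))
            for _ in range(8):
                n = int(rng.integers(1, 5))
                atoms = np.cumsum(rng.normal(scale=0.8, size=(n, 3)), axis=0)
                f = atoms[int(rng.integers(n))]
                pos = np.vstack([np.zeros(3), f, atoms])
                types = np.concatenate([[origin, focus],
                                        rng.choice(cfg.chemical_types, n)])
                z = int(rng.choice(cfg.chemical_types))
                probs, _ = position_distribution_on_grid(
                    pos, types, y, z, grid, tiny_model, focus_position=f)
                assert probs.sum() == pytest.approx(1.0, abs=1e-9)
                X = tiny_model.featurize(pos, types)
                rows = tiny_model.distance_distributions(X, y, z).data
                ref = brute_force_grid_distribution(rows, pos, f, grid,
                                                    binning)
                rel = np.abs(probs - ref) / np.maximum(ref, 1e-300)
                assert rel.max() < 1e-10

    def test_single_one_hot_row_selects_spherical_shell(self):
        """One predecessor with a one-hot distance distribution puts all mass
        on grid points whose distance falls in that bin."""
        binning = DistanceBinning(30, 0.1)
        grid = build_candidate_grid(spacing=0.1, radius=1.7)
        focus = np.zeros(3)
        rows = np.zeros((1, 30))
        rows[0, 14] = 1.0  # bin 15 (1-based): distances near 1.4 A
        log_mass, pts = grid_log_masses(rows, focus.reshape(1, 3), focus,
                                        grid, binning)
        w = np.exp(log_mass - log_mass.max())
        w /= w.sum()
        d = np.linalg.norm(pts, axis=1)
        on_shell = bin_index(d, binning) == 15
        assert w[~on_shell].sum() == pytest.approx(0.0, abs=1e-200)
        assert w[on_shell].sum() == pytest.approx(1.0)


class TestGenerationLoop:
    def test_same_seed_reproducible(self, tiny_model):
        conds = ConditionSet({"target": 2.0})
        gcfg = GenerationConfig(max_atoms=6, n_samples=4, seed=11,
                                grid_spacing=0.3, grid_radius=1.7)
        a = generate(tiny_model, conds, gcfg)
        b = generate(tiny_model, conds, gcfg)
        for ra, rb in zip(a, b):
            assert ra.finished == rb.finished
            if ra.molecule is not None:
                np.testing.assert_array_equal(ra.molecule.positions,
                                              rb.molecule.positions)
                np.testing.assert_array_equal(ra.molecule.types,
                                              rb.molecule.types)

    def test_finished_molecules_took_2n_steps(self, tiny_model):
        res = generate(tiny_model, ConditionSet({"target": 2.0}),
                       GenerationConfig(max_atoms=8, n_samples=12, seed=5,
                                        grid_spacing=0.3, grid_radius=1.7))
        finished = [r for r in res if r.finished and r.molecule is not None]
        assert finished, "untrained model should still finish some samples"
        for r in finished:
            assert r.n_steps == 2 * r.molecule.n_atoms

    def test_never_stopping_model_aborts_at_cap(self, tiny_model):
        stop_bias = tiny_model.net.params["type_head/b1"]
        saved = stop_bias.data.copy()
        try:
            stop_bias.data[tiny_model.config.stop_index] = -1e6
            res = generate(tiny_model, ConditionSet({"target": 2.0}),
                           GenerationConfig(max_atoms=3, n_samples=2, seed=1,
                                            grid_spacing=0.3,
                                            grid_radius=1.7))
            for r in res:
                assert r.abort_reason == "max_atoms_exceeded"
                assert not r.finished
                assert r.molecule.n_atoms == 3
        finally:
            stop_bias.data[...] = saved

    def test_forced_stop_marks_focus_without_placing(self, tiny_model):
        stop_bias = tiny_model.net.params["type_head/b1"]
        saved = stop_bias.data.copy()
        try:
            stop_bias.data[tiny_model.config.stop_index] = 1e6
            grid = build_candidate_grid(0.3, 1.7)
            with ad.no_grad():
                y = tiny_model.condition_vector(ConditionSet({"target": 2.0}))
                y = Tensor(y.data)
            state = GenerationState.fresh()
            state.positions = [np.array([0.0, 0.0, 1.0])]
            state.types = [6]
            n_before = len(state.types)
            generation_step(state, tiny_model, y, grid,
                            np.random.default_rng(0))
            assert len(state.types) == n_before
            assert state.finished_atoms == {0}
            assert state.done
        finally:
            stop_bias.data[...] = saved

    def test_rigid_motion_of_structure_and_grid_preserves_distribution(
            self, tiny_model, rng):
        cfg = tiny_model.config
        origin, focus_code = cfg.token_type_codes
        atoms = np.cumsum(rng.normal(scale=0.8, size=(3, 3)), axis=0)
        f = atoms[1]
        pos = np.vstack([np.zeros(3), f, atoms])
        types = np.concatenate([[origin, focus_code], [6, 6, 8]])
        grid = build_candidate_grid(0.4, 1.7)
        with ad.no_grad():
            y = tiny_model.condition_vector(ConditionSet({"target": 2.0}))
            Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            t = rng.normal(size=3) * 3
            moved_grid = CandidateGrid(grid.offsets @ Q.T, grid.spacing,
                                       grid.radius)
            p0, _ = position_distribution_on_grid(pos, types, y, 6, grid,
                                                  tiny_model,
                                                  focus_position=f)
            p1, _ = position_distribution_on_grid(pos @ Q.T + t, types, y, 6,
                                                  moved_grid, tiny_model,
                                                  focus_position=f @ Q.T + t)
        assert np.abs(p0 - p1).max() < 1e-5
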