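"""Losses, their analytic limits, gradients, and the optimization schedule."""

import numpy as np
import pytest

from placemol._autodiff import Tensor
from placemol.chem_data import Molecule, MoleculeDataset
from placemol.conditioning import ConditionSet, ConditionSpec
from placemol.experiments import _gradcheck
from placemol.fixtures import ToySpec, make_toy_dataset
from placemol.model import AtomPlacementModel
from placemol.model_heads import DistanceBinning, bin_centers
from placemol.representation import ModelConfig
from placemol.trajectory import STOP_CODE, build_neighbor_graph, \
    sample_placement_sequence
from placemol.training import (LossConfig, TrainingConfig, batch_loss,
                               conditions_from_molecule, distance_loss,
                               expand_ground_truth_distance, sequence_loss,
                               train, type_loss)


@pytest.fixture()
def binning():
    return DistanceBinning(40, 0.1)


class TestGroundTruthExpansion:
    def test_normalized_and_peaked_at_nearest_bin(self, binning, rng):
        for _ in range(20):
            r1, r2 = rng.normal(size=3), rng.normal(size=3)
            q = expand_ground_truth_distance(r1, r2, binning, 100.0)
            assert q.sum() == pytest.approx(1.0, abs=1e-12)
            d = np.linalg.norm(r1 - r2)
            centers = bin_centers(binning)
            if d <= centers[-1]:
                assert abs(centers[np.argmax(q)] - d) <= \
                    binning.width / 2 + 1e-12
            else:  # beyond the covered range: mass piles into the last bin
                assert np.argmax(q) == binning.n_bins - 1

    def test_large_gamma_approaches_one_hot(self, binning):
        q = expand_ground_truth_distance([0, 0, 0], [0, 0, 1.02], binning,
                                         1e6)
        assert q.max() > 0.999


class TestLossLimits:
    def test_perfect_prediction_zero_loss(self, tiny_model):
        cfg = tiny_model.config
        one_hot = np.zeros(cfg.n_type_classes)
        one_hot[cfg.stop_index] = 1.0
        assert float(type_loss(Tensor(one_hot), STOP_CODE,
                               tiny_model).data) == pytest.approx(0, abs=1e-9)

    def test_uniform_prediction_log_nclasses(self, tiny_model):
        cfg = tiny_model.config  # HCNOF + stop -> 6 classes, ln 6
        assert cfg.n_type_classes == 6
        u = Tensor(np.full(6, 1 / 6))
        assert float(type_loss(u, 6, tiny_model).data) == pytest.approx(
            np.log(6.0), abs=1e-9)

    def test_hand_two_type_value(self, tiny_model):
        p = np.array([0.25, 0.55, 0.05, 0.05, 0.05, 0.05])
        assert float(type_loss(Tensor(p), 6, tiny_model).data) == \
            pytest.approx(-np.log(0.55), abs=1e-9)

    def test_distance_loss_uniform_is_log_nbins(self, binning, rng):
        q = np.stack([expand_ground_truth_distance(rng.normal(size=3),
                                                   rng.normal(size=3),
                                                   binning, 100.0)
                      for _ in range(3)])
        p = Tensor(np.full((3, 40), 1 / 40))
        assert float(distance_loss(p, q).data) == pytest.approx(np.log(40),
                                                                abs=1e-6)

    def test_distance_loss_lower_bound_is_entropy(self, binning, rng):
        q = np.stack([expand_ground_truth_distance(rng.normal(size=3),
                                                   rng.normal(size=3),
                                                   binning, 100.0)
                      for _ in range(2)])
        ent = -(q * np.log(q + 1e-12)).sum() / 2
        assert float(distance_loss(Tensor(q), q).data) == pytest.approx(
            ent, abs=1e-6)

    def test_two_bin_hand_example(self):
        p = Tensor(np.array([[0.7, 0.3]]))
        q = np.array([[0.4, 0.6]])
        expect = -(0.4 * np.log(0.7) + 0.6 * np.log(0.3))
        assert float(distance_loss(p, q).data) == pytest.approx(expect,
                                                                rel=1e-9)


class TestBatchLoss:
    def test_single_atom_sequence_expansion(self, tiny_model):
        """One atom: two steps (place, stop); the stop step has no distance
        term and weights are 1/|A| and 1/(0.5|A|) with |A| = 2."""
        from placemol import _autodiff as ad
        from placemol.training import step_losses

        mol = Molecule(np.zeros((1, 3)), np.array([6]))
        g = build_neighbor_graph(mol, "radial", 2.0)
        seq = sample_placement_sequence(mol, g, np.random.default_rng(0))
        conds = ConditionSet({"target": 1.0})
        lcfg = LossConfig(DistanceBinning.of(tiny_model.config))
        with ad.no_grad():
            total = float(batch_loss([(seq, conds)], tiny_model, lcfg).data)
            y = tiny_model.condition_vector(conds)
            parts = [step_losses(s, tiny_model, y, lcfg) for s in seq.steps]
        (lt1, ld1), (lt2, ld2) = parts
        assert ld2 is None  # delta kills the stop step's distance term
        expect = float(lt1.data) / 2 + float(ld1.data) / 1 + float(lt2.data) / 2
        assert total == pytest.approx(expect, rel=1e-12)

    def test_empty_batch_rejected(self, tiny_model):
        lcfg = LossConfig(DistanceBinning.of(tiny_model.config))
        with pytest.raises(ValueError):
            batch_loss([], tiny_model, lcfg)

    def test_rigid_motion_invariance(self, tiny_model, rng):
        from placemol import _autodiff as ad

        mol = Molecule(np.array([[0, 0, 0], [1.4, 0, 0], [2.0, 1.1, 0.2]]),
                       np.array([6, 6, 8]))
        g = build_neighbor_graph(mol, "radial", 2.0)
        seq = sample_placement_sequence(mol, g, np.random.default_rng(5))
        conds = ConditionSet({"target": 3.0})
        lcfg = LossConfig(DistanceBinning.of(tiny_model.config))
        with ad.no_grad():
            base = float(sequence_loss(seq, tiny_model, conds, lcfg).data)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.normal(size=3) * 3
        moved = Molecule(mol.positions @ Q.T + t, mol.types)
        g2 = build_neighbor_graph(moved, "radial", 2.0)
        seq2 = sample_placement_sequence(moved, g2, np.random.default_rng(5))
        with ad.no_grad():
            rot = float(sequence_loss(seq2, tiny_model, conds, lcfg).data)
        assert rot == pytest.approx(base, abs=1e-8)


class TestGradients:
    def test_finite_difference_agreement(self, tiny_model):
        lcfg = LossConfig(DistanceBinning.of(tiny_model.config))
        assert _gradcheck(tiny_model, lcfg, seed=17) < 1e-4


def _chain_setup(n_mols=5):
    spec = ConditionSpec(name="length", kind="scalar", lam_min=2.0,
                         lam_max=9.0, d_omega=1.0, widths=(8, 8))
    cfg = ModelConfig.tiny(conditions=(spec,), chemical_types=(6,))
    model = AtomPlacementModel.create(cfg, seed=2)
    ds = make_toy_dataset(ToySpec(palette=(6,), size_min=3, size_max=5,
                                  seed=8), n_mols)
    lcfg = LossConfig(DistanceBinning.of(cfg))
    return model, ds, lcfg


class TestTrainingLoop:
    def test_loss_decreases_on_toy_set(self):
        model, ds, lcfg = _chain_setup()
        tcfg = TrainingConfig(batch_size=5, lr=1e-3, patience=50,
                              max_epochs=25, seed=3, neighbor_mode="radial",
                              neighbor_cutoff=1.6)
        state = train(ds, ds, model, tcfg, lcfg)
        first = state.history[0][2]
        assert state.history[-1][2] < first
        assert state.best_val_loss <= state.history[0][3]

    def test_identical_seeds_identical_trajectories(self):
        histories = []
        for _ in range(2):
            model, ds, lcfg = _chain_setup()
            tcfg = TrainingConfig(batch_size=5, lr=1e-3, patience=50,
                                  max_epochs=5, seed=3,
                                  neighbor_mode="radial", neighbor_cutoff=1.6)
            histories.append(train(ds, ds, model, tcfg, lcfg).history)
        assert histories[0] == histories[1]

    def test_patience_halves_lr_on_plateau(self):
        """With a vanishing learning rate the parameters never move, so the
        validation loss is constant and the schedule must halve the (already
        tiny) learning rate exactly every `patience` epochs."""
        model, ds, lcfg = _chain_setup(n_mols=2)
        lr0 = 1e-30
        tcfg = TrainingConfig(batch_size=2, lr=lr0, patience=10,
                              stop_lr=1e-40, max_epochs=35, seed=3,
                              neighbor_mode="radial", neighbor_cutoff=1.6)
        state = train(ds, ds, model, tcfg, lcfg)
        lrs = [h[1] for h in state.history]
        # epoch 0 always improves on the initial +inf, so the plateau counter
        # starts at epoch 1: halvings land after epochs 10, 20, 30
        assert lrs[:11] == [lr0] * 11
        assert lrs[11:21] == [lr0 / 2] * 10
        assert lrs[21:31] == [lr0 / 4] * 10
        assert lrs[31:35] == [lr0 / 8] * 4
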