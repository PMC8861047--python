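"""Losses and the optimization schedule.

Each supervised placement step contributes a cross-entropy between the
predicted next-type distribution and the one-hot ground truth, and — on
placement (non-stop) steps only — the mean over preceding atoms/tokens of the
cross-entropy between predicted distance distributions and the Gaussian-
expanded ground-truth distances.  A mini-batch of M sequences is scored as

    (1/M) sum_m sum_a [ l_type(a)/|A_m| + delta(a) l_dist(a)/(0.5 |A_m|) ]

where |A_m| = 2 n_m and delta kills distance terms on stop steps.  Training
uses Adam starting at lr 1e-4, halving after 10 epochs without validation
improvement and stopping at lr <= 1e-6; the lowest-validation-loss snapshot
is kept.  Validation sequences are drawn once with a fixed seed so model
selection is comparable across epochs.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import _autodiff as ad
from ._autodiff import Adam, Tensor
from .chem_data import Molecule, MoleculeDataset, composition
from .conditioning import ConditionSet
from .model import AtomPlacementModel
from .model_heads import DistanceBinning, bin_centers
from .trajectory import (NeighborGraph, PlacementSequence, PlacementStep,
                         STOP_CODE, build_neighbor_graph,
                         sample_placement_sequence)

__all__ = ["LossConfig", "TrainingConfig", "TrainingState",
           "expand_ground_truth_distance", "type_loss", "distance_loss",
           "sequence_loss", "batch_loss", "train", "conditions_from_molecule"]

_LOG_EPS = 1e-12  # clamp inside cross-entropies; early training can hit zero bins


@dataclass(frozen=True)
class LossConfig:
    binning: DistanceBinning
    gamma: float | None = None  # Gaussian expansion width; default 10 / d_mu

    @property
    def gamma_value(self) -> float:
        g = 10.0 / self.binning.width if self.gamma is None else self.gamma
        if g <= 0:
            raise ValueError("gamma must be positive")
        return g


@dataclass
class TrainingConfig:
    batch_size: int = 5
    lr: float = 1e-4
    decay: float = 0.5
    patience: int = 10
    stop_lr: float = 1e-6
    max_epochs: int = 10_000
    seed: int = 0
    neighbor_mode: str = "bond"
    neighbor_cutoff: float = 3.0

    def __post_init__(self):
        if not (0 < self.decay < 1):
            raise ValueError("decay must be in (0, 1)")
        if min(self.batch_size, self.lr, self.patience, self.stop_lr) <= 0:
            raise ValueError("batch size, lr, patience, stop_lr must be positive")


@dataclass
class TrainingState:
    epoch: int = 0
    lr: float = 0.0
    best_val_loss: float = math.inf
    best_params: dict = field(default_factory=dict)
    history: list = field(default_factory=list)  # (epoch, lr, train, val)


def expand_ground_truth_distance(r_next: np.ndarray, r_j: np.ndarray,
                                 binning: DistanceBinning,
                                 gamma: float) -> np.ndarray:
    """q_l ~ exp(-gamma (||r_next - r_j|| - l*d_mu)^2), normalized over the
    L bin centers l*d_mu, l = 0..L-1."""
    d = float(np.linalg.norm(np.asarray(r_next, float) - np.asarray(r_j, float)))
    e = -gamma * (d - bin_centers(binning)) ** 2
    e -= e.max()
    q = np.exp(e)
    return q / q.sum()


def _ground_truth_rows(step: PlacementStep, binning: DistanceBinning,
                       gamma: float) -> np.ndarray:
    return np.stack([expand_ground_truth_distance(step.next_position, r_j,
                                                  binning, gamma)
                     for r_j in step.partial_positions])


def type_loss(probs: Tensor, next_type: int, model: AtomPlacementModel) -> Tensor:
    """-log p(Z_i = Z_next); Z_next may be the stop marker."""
    cfg = model.config
    idx = cfg.stop_index if next_type == STOP_CODE \
        else cfg.chemical_types.index(int(next_type))
    return -((probs[np.array([idx])] + _LOG_EPS).log().sum())


def distance_loss(p_rows: Tensor, q_rows: np.ndarray) -> Tensor:
    """-(1/(i-1)) sum_j sum_l q_jl log p_jl over all preceding atoms+tokens."""
    m = q_rows.shape[0]
    return -((Tensor(q_rows) * (p_rows + _LOG_EPS).log()).sum()) / float(m)


def step_losses(step: PlacementStep, model: AtomPlacementModel, y: Tensor,
                loss_cfg: LossConfig) -> tuple[Tensor, Tensor | None]:
    X = model.featurize(step.partial_positions, step.partial_types)
    probs = model.type_distribution(X, y)
    lt = type_loss(probs, step.next_type, model)
    if step.is_stop:
        return lt, None
    p_rows = model.distance_distributions(X, y, step.next_type)
    q_rows = _ground_truth_rows(step, loss_cfg.binning, loss_cfg.gamma_value)
    return lt, distance_loss(p_rows, q_rows)


def sequence_loss(seq: PlacementSequence, model: AtomPlacementModel,
                  conditions: ConditionSet, loss_cfg: LossConfig) -> Tensor:
    """sum_a [ l_type/|A| + delta l_dist/(0.5 |A|) ] for one sequence."""
    y = model.condition_vector(conditions)
    n_steps = float(len(seq))
    total = Tensor(0.0)
    for step in seq.steps:
        lt, ld = step_losses(step, model, y, loss_cfg)
        total = total + lt / n_steps
        if ld is not None:
            total = total + ld / (0.5 * n_steps)
    return total


def batch_loss(batch: Sequence[tuple[PlacementSequence, ConditionSet]],
               model: AtomPlacementModel, loss_cfg: LossConfig) -> Tensor:
    if not batch:
        raise ValueError("empty batch")
    total = Tensor(0.0)
    for seq, conds in batch:
        total = total + sequence_loss(seq, model, conds, loss_cfg)
    return total / float(len(batch))


def conditions_from_molecule(mol: Molecule,
                             model: AtomPlacementModel) -> ConditionSet:
    """Condition values read off a training molecule, per the model's specs:
    composition kinds from the atom types, `n_atoms` from the size, other
    scalars/vectors from the property map."""
    values: dict[str, object] = {}
    for spec in model.config.conditions:
        if spec.kind == "composition":
            values[spec.name] = composition(mol)
        elif spec.name == "n_atoms":
            values[spec.name] = float(mol.properties.get("n_atoms", mol.n_atoms))
        else:
            values[spec.name] = mol.properties[spec.name]
    return ConditionSet(values)


def _resample(molecules, graphs, rng, conditions_fn, model):
    out = []
    for mol, g in zip(molecules, graphs):
        seq = sample_placement_sequence(mol, g, rng)
        out.append((seq, conditions_fn(mol, model)))
    return out


def train(train_split: MoleculeDataset, val_split: MoleculeDataset,
          model: AtomPlacementModel, tcfg: TrainingConfig, loss_cfg: LossConfig,
          conditions_fn: Callable = None, log_path=None) -> TrainingState:
    """Full optimization loop; returns the state holding the best snapshot
    (also written back into the model parameters on exit)."""
    conditions_fn = conditions_fn or conditions_from_molecule
    graphs_train = [build_neighbor_graph(m, tcfg.neighbor_mode,
                                         tcfg.neighbor_cutoff)
                    for m in train_split]
    graphs_val = [build_neighbor_graph(m, tcfg.neighbor_mode,
                                       tcfg.neighbor_cutoff)
                  for m in val_split]
    # fixed validation sequences: comparable selection across epochs
    val_rng = np.random.default_rng((tcfg.seed + 1) % 2 ** 31)
    val_batchable = _resample(val_split.molecules, graphs_val, val_rng,
                              conditions_fn, model)

    opt = Adam(model.net.params, lr=tcfg.lr)
    state = TrainingState(lr=tcfg.lr, best_params=model.net.copy_data())
    since_improve = 0
    log_fh = open(log_path, "w") if log_path else None
    if log_fh:
        log_fh.write("epoch\tlr\ttrain_loss\tval_loss\n")
    try:
        for epoch in range(tcfg.max_epochs):
            state.epoch = epoch
            ep_rng = np.random.default_rng((tcfg.seed + 9973 * (epoch + 1))
                                           % 2 ** 31)
            pairs = _resample(train_split.molecules, graphs_train, ep_rng,
                              conditions_fn, model)
            order = ep_rng.permutation(len(pairs))
            losses = []
            for start in range(0, len(pairs), tcfg.batch_size):
                chunk = [pairs[i] for i in order[start:start + tcfg.batch_size]]
                opt.zero_grad()
                loss = batch_loss(chunk, model, loss_cfg)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}; "
                        f"history={state.history[-5:]}")
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            train_loss = float(np.mean(losses))
            with ad.no_grad():
                val_loss = float(batch_loss(val_batchable, model,
                                            loss_cfg).data)
            state.history.append((epoch, opt.lr, train_loss, val_loss))
            if log_fh:
                log_fh.write(f"{epoch}\t{opt.lr:.3e}\t{train_loss:.6f}\t"
                             f"{val_loss:.6f}\n")
            if val_loss < state.best_val_loss:
                state.best_val_loss = val_loss
                state.best_params = model.net.copy_data()
                since_improve = 0
            else:
                since_improve += 1
                if since_improve >= tcfg.patience:
                    opt.lr *= tcfg.decay
                    since_improve = 0
            state.lr = opt.lr
            if opt.lr <= tcfg.stop_lr:
                break
    finally:
        if log_fh:
            log_fh.close()
    model.net.load_data(state.best_params)
    return state
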