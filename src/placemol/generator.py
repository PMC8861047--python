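"""Conditional sampling of 3d molecules, one atom per pair of steps.

Generation mirrors training: both tokens start at the coordinate origin; at
every step an unfinished atom is drawn uniformly as focus (the origin token
stands in on the very first step), the next type is sampled from the
averaged type distribution, and — unless the stop marker was drawn — the
next position is sampled from a distribution reconstructed on a cubic
candidate grid clipped to a sphere and centered on the focus.  The grid mass
of a candidate point is the product over all preceding atoms/tokens of their
predicted probability for the corresponding distance bin; products are
accumulated in log space and normalized over the grid.  A molecule is
finished when every placed atom has received a stop mark; attempting to
place more than `max_atoms` atoms aborts the sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .chem_data import Molecule
from .conditioning import ConditionSet
from .model import AtomPlacementModel
from .model_heads import DistanceBinning, bin_index
from .trajectory import STOP_CODE

__all__ = ["CandidateGrid", "GenerationConfig", "GenerationResult",
           "SamplingError", "build_candidate_grid", "grid_log_masses",
           "position_distribution_on_grid", "GenerationState",
           "generation_step", "generate"]


class SamplingError(RuntimeError):
    pass


@dataclass(frozen=True)
class CandidateGrid:
    offsets: np.ndarray  # (P, 3) relative coordinates, A
    spacing: float
    radius: float

    @property
    def n_points(self) -> int:
        return self.offsets.shape[0]


def build_candidate_grid(spacing: float = 0.05,
                         radius: float = 1.7) -> CandidateGrid:
    """Cubic lattice of the given spacing clipped to a sphere of the given
    radius.  The radius must cover first-neighbor bond lengths, since atoms
    are always placed adjacent to the focus."""
    if spacing <= 0 or radius <= 0:
        raise ValueError("spacing and radius must be positive")
    k = int(np.floor(radius / spacing + 1e-9))
    ax = spacing * np.arange(-k, k + 1)
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1).reshape(-1, 3)
    keep = np.linalg.norm(pts, axis=1) <= radius + 1e-9
    return CandidateGrid(pts[keep], spacing, radius)


@dataclass
class GenerationConfig:
    max_atoms: int = 35
    n_samples: int = 1
    seed: int = 0
    grid_spacing: float = 0.05
    grid_radius: float = 1.7

    def __post_init__(self):
        if self.max_atoms < 1:
            raise ValueError("max_atoms must be >= 1")


@dataclass
class GenerationResult:
    molecule: Molecule | None
    finished: bool
    abort_reason: str | None = None   # None | "max_atoms_exceeded"
    log_probs: list = field(default_factory=list)  # per-step diagnostics
    n_steps: int = 0


def grid_log_masses(row_probs: np.ndarray, row_positions: np.ndarray,
                    focus_position: np.ndarray, grid: CandidateGrid,
                    binning: DistanceBinning) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized log grid masses and the absolute candidate positions.

    For candidate r' = offset + r_focus the mass is the product over rows j of
    p_j[b(||r_j - r'||)]; computed in log space (up to ~36 factors of small
    bin probabilities underflow otherwise).
    """
    pts = grid.offsets + np.asarray(focus_position, float)
    d = np.linalg.norm(row_positions[:, None, :] - pts[None, :, :], axis=-1)
    bins = bin_index(d, binning) - 1                      # 0-based, (m, P)
    logp = np.log(row_probs + 1e-300)
    log_mass = np.take_along_axis(logp, bins, axis=1).sum(axis=0)
    return log_mass, pts


def position_distribution_on_grid(partial_positions, partial_types,
                                  y: Tensor, next_type: int,
                                  grid: CandidateGrid,
                                  model: AtomPlacementModel,
                                  focus_position=None
                                  ) -> tuple[np.ndarray, np.ndarray]:
    """Normalized probabilities over grid candidate positions (and the
    positions themselves).  The grid is centered on the focus token, whose
    coordinates are row 1 of the partial structure unless given explicitly."""
    pos = np.asarray(partial_positions, float).reshape(-1, 3)
    if focus_position is None:
        focus_position = pos[1]
    X = model.featurize(pos, partial_types)
    rows = model.distance_distributions(X, y, next_type).data
    log_mass, pts = grid_log_masses(rows, pos, focus_position, grid,
                                    DistanceBinning.of(model.config))
    m = log_mass.max()
    if not np.isfinite(m):
        raise SamplingError("all-zero position mass over the candidate grid")
    w = np.exp(log_mass - m)
    return w / w.sum(), pts


@dataclass
class GenerationState:
    origin: np.ndarray
    positions: list            # placed atom coordinates
    types: list                # placed atomic numbers
    finished_atoms: set
    n_steps: int = 0
    done: bool = False
    abort_reason: str | None = None
    log_probs: list = field(default_factory=list)

    @staticmethod
    def fresh() -> "GenerationState":
        return GenerationState(origin=np.zeros(3), positions=[], types=[],
                               finished_atoms=set())

    @property
    def open_atoms(self) -> list[int]:
        return [i for i in range(len(self.types))
                if i not in self.finished_atoms]


def generation_step(state: GenerationState, model: AtomPlacementModel,
                    y: Tensor, grid: CandidateGrid,
                    rng: np.random.Generator, max_atoms: int = 35) -> GenerationState:
    """One sampling step; mutates and returns the state."""
    cfg = model.config
    if state.done:
        return state
    open_atoms = state.open_atoms
    if state.types and not open_atoms:
        state.done = True
        return state

    if not state.types:
        focus_pos = state.origin          # first step: grid on the origin
        focus_atom = None
    else:
        focus_atom = open_atoms[int(rng.integers(len(open_atoms)))]
        focus_pos = state.positions[focus_atom]

    origin_code, focus_code = cfg.token_type_codes
    types = np.array([origin_code, focus_code] + state.types, dtype=np.int64)
    pos = np.vstack([state.origin, focus_pos] + [np.asarray(p)
                                                 for p in state.positions])
    state.n_steps += 1
    with ad.no_grad():
        X = model.featurize(pos, types)
        tprobs = model.type_distribution(X, y).data
        t_idx = int(rng.choice(cfg.n_type_classes, p=tprobs / tprobs.sum()))
        if t_idx == cfg.stop_index:
            state.log_probs.append(float(np.log(tprobs[t_idx] + 1e-300)))
            if focus_atom is None:
                state.done = True         # stop before any atom: empty sample
            else:
                state.finished_atoms.add(focus_atom)
                if not state.open_atoms:
                    state.done = True
            return state
        next_type = cfg.chemical_types[t_idx]
        if len(state.types) >= max_atoms:
            state.done = True
            state.abort_reason = "max_atoms_exceeded"
            return state
        rows = model.distance_distributions(X, y, next_type).data
    log_mass, pts = grid_log_masses(rows, pos, focus_pos, grid,
                                    DistanceBinning.of(cfg))
    m = log_mass.max()
    if not np.isfinite(m):
        raise SamplingError("all-zero position mass over the candidate grid")
    w = np.exp(log_mass - m)
    w /= w.sum()
    p_idx = int(rng.choice(len(w), p=w))
    state.log_probs.append(float(np.log(tprobs[t_idx] + 1e-300)
                                 + np.log(w[p_idx] + 1e-300)))
    state.positions.append(pts[p_idx].copy())
    state.types.append(int(next_type))
    return state


def _result_from_state(state: GenerationState, index: int) -> GenerationResult:
    finished = state.abort_reason is None and \
        len(state.finished_atoms) == len(state.types)
    mol = None
    if state.types:
        mol = Molecule(np.array(state.positions), np.array(state.types),
                       id=f"generated-{index}")
    return GenerationResult(molecule=mol, finished=finished,
                            abort_reason=state.abort_reason,
                            log_probs=state.log_probs, n_steps=state.n_steps)


def generate(model: AtomPlacementModel, conditions: ConditionSet,
             gcfg: GenerationConfig) -> list[GenerationResult]:
    """Sample `n_samples` molecules; sample k is reproducible from
    (seed, k) alone."""
    grid = build_candidate_grid(gcfg.grid_spacing, gcfg.grid_radius)
    with ad.no_grad():
        y = model.condition_vector(conditions)
        y = Tensor(y.data)  # detach
    results = []
    for k in range(gcfg.n_samples):
        rng = np.random.default_rng((gcfg.seed * 1_000_003 + k) % 2 ** 31)
        state = GenerationState.fresh()
        while not state.done:
            generation_step(state, model, y, grid, rng,
                            max_atoms=gcfg.max_atoms)
        results.append(_result_from_state(state, k))
    return results
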