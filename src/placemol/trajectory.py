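"""Atom-placement trajectories: one molecule -> a supervised 2n-step sequence.

Each training molecule is rebuilt atom by atom.  Two auxiliary tokens steer
the process: the origin token sits at the center of mass (growth proceeds
inside-out) and the focus token is co-located with the atom around which the
next placement is localized.  A sequence interleaves n placement steps (the
next atom is the unplaced neighbor of the focus closest to the center of
mass) with n stop steps (a focus with no unplaced neighbors is marked
finished), for exactly 2n supervised steps.  Focus selection among unfinished
placed atoms is uniform; finished atoms are never refocused.

Token type codes are reserved integers above the chemical range; the stop
marker uses code 0 (atomic numbers start at 1).  Tokens carry no probability:
the learned factorization starts with the first real atom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_data import Molecule

__all__ = [
    "STOP_CODE", "TokenState", "NeighborGraph", "PlacementStep",
    "PlacementSequence", "token_codes", "build_neighbor_graph",
    "initialize_tokens", "sample_placement_sequence", "sequence_to_xyz",
]

STOP_CODE = 0  # disjoint from atomic numbers (>= 1) and token codes


def token_codes(chemical_types) -> tuple[int, int]:
    """(origin_code, focus_code): reserved integers above the chemical range."""
    top = max(int(z) for z in chemical_types)
    return top + 1, top + 2


@dataclass
class TokenState:
    origin_position: np.ndarray
    focus_position: np.ndarray
    origin_type_id: int
    focus_type_id: int


@dataclass
class NeighborGraph:
    n: int
    edges: frozenset  # of frozenset({i, j})
    mode: str         # "bond" | "radial"

    def neighbors(self, i: int) -> list[int]:
        out = []
        for e in self.edges:
            a, b = tuple(e)
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.n, self.n), dtype=bool)
        for e in self.edges:
            a, b = tuple(e)
            A[a, b] = A[b, a] = True
        return A

    def is_connected(self) -> bool:
        if self.n <= 1:
            return True
        A = self.adjacency()
        seen = {0}
        stack = [0]
        while stack:
            i = stack.pop()
            for j in np.flatnonzero(A[i]):
                if j not in seen:
                    seen.add(int(j))
                    stack.append(int(j))
        return len(seen) == self.n


def build_neighbor_graph(mol: Molecule, mode: str = "bond",
                         cutoff: float = 3.0) -> NeighborGraph:
    """Neighborhood used to constrain growth: perceived bonds, or (fallback /
    explicit choice) all pairs within a radial cutoff."""
    if mode not in ("bond", "radial"):
        raise ValueError(f"unknown neighbor mode {mode!r}")
    if mode == "bond":
        try:
            from .validity import perceive_bonds
            graph = perceive_bonds(mol)
            edges = frozenset(frozenset((i, j)) for i, j, _ in graph.bonds)
            return NeighborGraph(mol.n_atoms, edges, "bond")
        except Exception:
            import warnings
            warnings.warn(f"bond perception failed for {mol.id!r}; "
                          f"falling back to radial cutoff {cutoff} A")
            mode = "radial"
    d = np.linalg.norm(mol.positions[:, None] - mol.positions[None, :], axis=-1)
    edges = frozenset(frozenset((int(i), int(j)))
                      for i in range(mol.n_atoms) for j in range(i + 1, mol.n_atoms)
                      if d[i, j] <= cutoff)
    return NeighborGraph(mol.n_atoms, edges, "radial")


def initialize_tokens(mol: Molecule | None, stage: str = "training",
                      chemical_types=(1, 6, 7, 8, 9),
                      mass_weighted: bool = True) -> TokenState:
    """Token start state: both tokens at the molecule's center of mass during
    training, at the coordinate origin during generation."""
    origin_code, focus_code = token_codes(chemical_types)
    if stage == "training":
        if mol is None:
            raise ValueError("training stage requires a molecule")
        com = mol.center_of_mass(mass_weighted=mass_weighted)
    elif stage == "generation":
        com = np.zeros(3)
    else:
        raise ValueError(f"unknown stage {stage!r}")
    return TokenState(origin_position=com.copy(), focus_position=com.copy(),
                      origin_type_id=origin_code, focus_type_id=focus_code)


@dataclass
class PlacementStep:
    partial_types: np.ndarray      # [origin_code, focus_code, placed atoms...]
    partial_positions: np.ndarray  # matching coordinates; rows 0/1 are tokens
    focus_index: int               # index into placed atoms; -1 on the first step
    next_type: int                 # atomic number, or STOP_CODE
    next_position: np.ndarray | None

    @property
    def is_stop(self) -> bool:
        return self.next_type == STOP_CODE


@dataclass
class PlacementSequence:
    steps: list[PlacementStep]
    molecule_id: str = ""
    conditions: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.steps)


def sample_placement_sequence(mol: Molecule, nbrs: NeighborGraph,
                              rng: np.random.Generator,
                              mass_weighted: bool = True) -> PlacementSequence:
    """Sample one supervised placement sequence (2n steps) for a molecule.

    Step 1 places the atom closest to the center of mass (ties broken
    uniformly); afterwards each step focuses a uniformly chosen unfinished
    placed atom and either places its unplaced neighbor closest to the center
    of mass or, if none remains, supervises the stop marker and retires the
    focus.
    """
    if not nbrs.is_connected():
        raise ValueError(f"neighbor graph of {mol.id!r} is disconnected; "
                         "growth cannot reach every atom")
    n = mol.n_atoms
    com = mol.center_of_mass(mass_weighted=mass_weighted)
    origin_code, focus_code = token_codes(mol.types)
    d_com = np.linalg.norm(mol.positions - com, axis=1)
    A = nbrs.adjacency()

    placed: list[int] = []     # molecule atom indices in placement order
    finished: set[int] = set()
    steps: list[PlacementStep] = []

    def snapshot(focus_pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        types = np.concatenate([[origin_code, focus_code],
                                mol.types[placed]]).astype(np.int64)
        pos = np.vstack([com, focus_pos, mol.positions[placed]]) if placed \
            else np.vstack([com, focus_pos])
        return types, pos

    # first placement: atom closest to the center of mass, focus = origin
    close = np.flatnonzero(np.isclose(d_com, d_com.min()))
    first = int(rng.choice(close))
    types, pos = snapshot(com)
    steps.append(PlacementStep(types, pos, focus_index=-1,
                               next_type=int(mol.types[first]),
                               next_position=mol.positions[first].copy()))
    placed.append(first)

    while len(finished) < n:
        open_atoms = [a for a in placed if a not in finished]
        fi = int(rng.integers(len(open_atoms)))
        focus = open_atoms[fi]
        focus_pos = mol.positions[focus]
        types, pos = snapshot(focus_pos)
        unplaced_nbrs = [j for j in np.flatnonzero(A[focus])
                         if j not in placed]
        if unplaced_nbrs:
            dists = d_com[unplaced_nbrs]
            cands = [unplaced_nbrs[k]
                     for k in np.flatnonzero(np.isclose(dists, dists.min()))]
            nxt = int(rng.choice(cands))
            steps.append(PlacementStep(types, pos,
                                       focus_index=placed.index(focus),
                                       next_type=int(mol.types[nxt]),
                                       next_position=mol.positions[nxt].copy()))
            placed.append(nxt)
        else:
            steps.append(PlacementStep(types, pos,
                                       focus_index=placed.index(focus),
                                       next_type=STOP_CODE,
                                       next_position=None))
            finished.add(focus)
    assert len(steps) == 2 * n
    return PlacementSequence(steps, molecule_id=mol.id)


def sequence_to_xyz(seq: PlacementSequence, path) -> None:
    """Debug dump: each step as one XYZ frame, tokens encoded as dummy elements
    (origin -> 'X'/Ne slot is not standard, so He/Ne placeholders are used)."""
    from .chem_data import Z_TO_SYMBOL

    with open(path, "w") as fh:
        for k, step in enumerate(seq.steps):
            fh.write(f"{len(step.partial_types)}\n"
                     f"step {k} next={step.next_type}\n")
            for t, r in zip(step.partial_types, step.partial_positions):
                sym = Z_TO_SYMBOL.get(int(t))
                if sym is None:  # token codes
                    sym = "He" if t == step.partial_types[0] else "Ne"
                fh.write(f"{sym} {r[0]:.6f} {r[1]:.6f} {r[2]:.6f}\n")
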