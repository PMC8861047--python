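"""Synthetic toy molecules and curated reference geometries.

The toy generator builds idealized families (collinear chains, regular rings,
tetrahedra) with optional coordinate noise and per-element synthetic
energies, so the whole pipeline — trajectory sampling, training, generation,
validity filtering — can be exercised without any external corpus.  Curated
fixtures are standard textbook geometries (methane, ethane, ethanol, H2) plus
deliberately pathological structures (clashing atoms, disconnected fragments,
a hypervalent carbon) and stereochemistry probes (a chiral center with its
mirror image, cis/trans difluoroethene).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_data import Molecule, MoleculeDataset, composition

__all__ = ["ToySpec", "make_toy_dataset", "curated_fixture", "FIXTURE_NAMES"]


@dataclass
class ToySpec:
    family: str = "chains"            # chains | rings | tetrahedra
    size_min: int = 3
    size_max: int = 8
    bond_length: float = 1.5          # Angstrom
    palette: tuple[int, ...] = (6,)   # atomic numbers, cycled along the structure
    noise: float = 0.0                # coordinate noise sigma, Angstrom
    energy_coeffs: dict[int, float] | None = None   # eV per atom of element Z
    energy_noise: float = 0.0         # eV
    seed: int = 0

    def __post_init__(self):
        if self.size_min < 1 or self.size_max < self.size_min:
            raise ValueError("invalid size range")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.family not in ("chains", "rings", "tetrahedra"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "rings" and self.size_min < 3:
            raise ValueError("rings need at least 3 atoms")
        if not self.palette:
            raise ValueError("empty palette")


def _chain(n: int, d: float) -> np.ndarray:
    xs = (np.arange(n) - (n - 1) / 2.0) * d
    pos = np.zeros((n, 3))
    pos[:, 0] = xs
    return pos


def _ring(n: int, d: float) -> np.ndarray:
    radius = d / (2.0 * np.sin(np.pi / n))
    ang = 2 * np.pi * np.arange(n) / n
    return np.stack([radius * np.cos(ang), radius * np.sin(ang),
                     np.zeros(n)], axis=1)


_TET_DIRS = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3)


def _tetrahedron(d: float) -> np.ndarray:
    return np.vstack([np.zeros(3), d * _TET_DIRS])


def make_toy_dataset(spec: ToySpec, n: int) -> MoleculeDataset:
    """Generate `n` toy molecules; deterministic under spec.seed.

    Attached properties: `n_atoms` and `length` (the structure size) always;
    `energy` (eV) when `spec.energy_coeffs` is given, generated as
    sum_Z n_Z * c_Z + Normal(0, energy_noise).
    """
    rng = np.random.default_rng(spec.seed)
    mols = []
    names = set()
    for k in range(n):
        size = int(rng.integers(spec.size_min, spec.size_max + 1))
        if spec.family == "chains":
            pos = _chain(size, spec.bond_length)
            types = [spec.palette[i % len(spec.palette)] for i in range(size)]
        elif spec.family == "rings":
            size = max(size, 3)
            pos = _ring(size, spec.bond_length)
            types = [spec.palette[i % len(spec.palette)] for i in range(size)]
        else:  # tetrahedra
            pos = _tetrahedron(spec.bond_length)
            types = [spec.palette[0]] + [spec.palette[-1]] * 4
        if spec.noise > 0:
            pos = pos + rng.normal(0.0, spec.noise, pos.shape)
        mol = Molecule(pos, np.array(types), id=f"{spec.family}-{k}")
        props = {"n_atoms": float(mol.n_atoms), "length": float(size)}
        names.update(props)
        if spec.energy_coeffs is not None:
            e = sum(spec.energy_coeffs[int(z)] for z in mol.types)
            if spec.energy_noise > 0:
                e += rng.normal(0.0, spec.energy_noise)
            props["energy"] = float(e)
            names.add("energy")
        mol.properties = props
        mols.append(mol)
    return MoleculeDataset(mols, property_names=frozenset(names),
                           provenance=f"toy:{spec.family}:seed={spec.seed}")


# ---------------------------------------------------------------------------
# Curated fixtures
# ---------------------------------------------------------------------------

def _methane() -> Molecule:
    a = 1.089 / np.sqrt(3.0)
    pos = [[0, 0, 0], [a, a, a], [-a, -a, a], [-a, a, -a], [a, -a, -a]]
    return Molecule(np.array(pos), np.array([6, 1, 1, 1, 1]), id="methane")


def _ethane() -> Molecule:
    # staggered C2H6; C-C 1.536, C-H 1.091
    cc = 1.536 / 2
    pos = [[-cc, 0.0, 0.0], [cc, 0.0, 0.0]]
    types = [6, 6]
    r_ch, theta = 1.091, np.deg2rad(111.2 - 90.0)
    for s, phase in ((-1, 0.0), (1, np.pi / 3)):
        for k in range(3):
            ang = phase + 2 * np.pi * k / 3
            pos.append([s * (cc + r_ch * np.sin(theta)),
                        r_ch * np.cos(theta) * np.cos(ang),
                        r_ch * np.cos(theta) * np.sin(ang)])
            types.append(1)
    return Molecule(np.array(pos), np.array(types), id="ethane")


def _ethanol() -> Molecule:
    pos = [
        [-1.1879, 0.3829, 0.0000],   # C
        [0.0000, -0.5526, 0.0000],   # C
        [1.1877, 0.2146, 0.0000],    # O
        [-1.0935, 1.0216, 0.8819],   # H
        [-1.0935, 1.0216, -0.8819],  # H
        [-2.1171, -0.1891, 0.0000],  # H
        [0.0429, -1.1931, 0.8853],   # H
        [0.0429, -1.1931, -0.8853],  # H
        [1.9471, -0.3800, 0.0000],   # H (hydroxyl)
    ]
    return Molecule(np.array(pos), np.array([6, 6, 8, 1, 1, 1, 1, 1, 1]),
                    id="ethanol")


def _h2() -> Molecule:
    return Molecule(np.array([[0, 0, 0], [0, 0, 0.74]]), np.array([1, 1]),
                    id="h2")


def _clashing_pair() -> Molecule:
    # two carbons far too close to admit any sensible neutral bonding
    m = _methane()
    pos = np.vstack([m.positions, m.positions + np.array([0.5, 0.0, 0.0])])
    types = np.concatenate([m.types, m.types])
    return Molecule(pos, types, id="clashing_pair")


def _disconnected_pair() -> Molecule:
    m = _methane()
    pos = np.vstack([m.positions, m.positions + np.array([10.0, 0.0, 0.0])])
    types = np.concatenate([m.types, m.types])
    return Molecule(pos, types, id="disconnected_pair")


def _hypervalent_c() -> Molecule:
    pos = [[0, 0, 0], [1.1, 0, 0], [-1.1, 0, 0], [0, 1.1, 0], [0, -1.1, 0],
           [0, 0, 1.1]]
    return Molecule(np.array(pos), np.array([6, 1, 1, 1, 1, 1]),
                    id="hypervalent_c")


def _chiral(mirror: bool = False) -> Molecule:
    """A chiral carbon: C bonded to H, F, OH and NH2 (four distinct groups)."""
    d = _TET_DIRS
    pos = [np.zeros(3)]
    types = [6]
    pos.append(1.09 * d[0]); types.append(1)          # H
    pos.append(1.35 * d[1]); types.append(9)          # F
    o = 1.41 * d[2]
    pos.append(o); types.append(8)                    # O
    oh_dir = d[2] + 0.9 * d[0]
    pos.append(o + 0.96 * oh_dir / np.linalg.norm(oh_dir)); types.append(1)
    nn = 1.47 * d[3]
    pos.append(nn); types.append(7)                   # N
    for mix in (d[1], d[2]):
        h_dir = d[3] + 0.9 * mix
        pos.append(nn + 1.01 * h_dir / np.linalg.norm(h_dir)); types.append(1)
    arr = np.array(pos)
    if mirror:
        arr[:, 0] *= -1.0
    return Molecule(arr, np.array(types),
                    id="chiral_mirror" if mirror else "chiral")


def _difluoroethene(cis: bool) -> Molecule:
    s = 1.0 if cis else -1.0
    pos = [
        [-0.66, 0.0, 0.0], [0.66, 0.0, 0.0],          # C=C
        [-1.32, 1.16, 0.0], [1.32, s * 1.16, 0.0],    # F, F
        [-1.22, -0.94, 0.0], [1.22, -s * 0.94, 0.0],  # H, H
    ]
    return Molecule(np.array(pos), np.array([6, 6, 9, 9, 1, 1]),
                    id="cis_difluoroethene" if cis else "trans_difluoroethene")


_BUILDERS = {
    "methane": _methane,
    "ethane": _ethane,
    "ethanol": _ethanol,
    "h2": _h2,
    "clashing_pair": _clashing_pair,
    "disconnected_pair": _disconnected_pair,
    "hypervalent_c": _hypervalent_c,
    "chiral": lambda: _chiral(False),
    "chiral_mirror": lambda: _chiral(True),
    "cis_difluoroethene": lambda: _difluoroethene(True),
    "trans_difluoroethene": lambda: _difluoroethene(False),
}

FIXTURE_NAMES = tuple(sorted(_BUILDERS))


def curated_fixture(name: str) -> Molecule:
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
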