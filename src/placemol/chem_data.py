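"""Molecule containers, XYZ / QM9 ingestion and conditioning properties.

The QM9 benchmark is distributed as one extended-XYZ file per molecule: an
atom-count line, a property line with 15 scalar fields (rotational constants,
dipole moment, isotropic polarizability, HOMO/LUMO/gap, <R^2>, zero-point
vibrational energy, U0/U/H/G, heat capacity), then per-atom lines with element
symbol, Cartesian coordinates in Angstrom and a Mulliken charge.  Energetic
fields are stored in Hartree and converted to eV on ingestion.

Conditioning properties computed here: atomic composition, relative atomic
energy (residual of a per-element least-squares energy baseline, per atom) and
1024-bit path-based fingerprints compared by Tanimoto similarity.
"""

from __future__ import annotations

import math
import os
import re
import tarfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Molecule", "MoleculeDataset", "Composition", "Fingerprint",
    "EnergyBaseline", "ParseError", "HARTREE_TO_EV",
    "load_qm9", "read_xyz", "write_xyz", "composition", "split_dataset",
    "fit_energy_baseline", "relative_atomic_energy", "path_fingerprint",
    "tanimoto", "write_property_table",
]

HARTREE_TO_EV = 27.211386

SYMBOL_TO_Z = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17,
}
Z_TO_SYMBOL = {z: s for s, z in SYMBOL_TO_Z.items()}

# standard atomic weights (u); used for centers of mass
ATOMIC_MASS = {
    1: 1.008, 2: 4.0026, 3: 6.94, 4: 9.0122, 5: 10.81, 6: 12.011,
    7: 14.007, 8: 15.999, 9: 18.998, 10: 20.180, 11: 22.990, 12: 24.305,
    13: 26.982, 14: 28.085, 15: 30.974, 16: 32.06, 17: 35.45,
}

# QM9 property-line field names, in file order (after the "gdb <index>" tag)
QM9_FIELDS = ("A", "B", "C", "mu", "alpha", "homo", "lumo", "gap", "r2",
              "zpve", "U0", "U", "H", "G", "Cv")
_HARTREE_FIELDS = frozenset({"homo", "lumo", "gap", "zpve", "U0", "U", "H", "G"})


class ParseError(ValueError):
    """Malformed XYZ / QM9 record; the message names the offending record."""


@dataclass
class Molecule:
    """A 3d structure: positions in Angstrom, atomic numbers, optional properties."""

    positions: np.ndarray
    types: np.ndarray
    properties: dict = field(default_factory=dict)
    id: str = ""

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 3)
        self.types = np.asarray(self.types, dtype=np.int64)
        if self.positions.shape[0] != self.types.shape[0]:
            raise ValueError("positions and types disagree in length")
        if self.n_atoms < 1:
            raise ValueError("a molecule has at least one atom")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError(f"non-finite coordinates in molecule {self.id!r}")
        if np.any(self.types < 1):
            raise ValueError("atomic numbers must be >= 1")

    @property
    def n_atoms(self) -> int:
        return self.types.shape[0]

    def center_of_mass(self, mass_weighted: bool = True) -> np.ndarray:
        if mass_weighted:
            w = np.array([ATOMIC_MASS[int(z)] for z in self.types])
        else:
            w = np.ones(self.n_atoms)
        return (self.positions * w[:, None]).sum(axis=0) / w.sum()

    def mirrored(self) -> "Molecule":
        """Mirror image (x coordinate negated)."""
        pos = self.positions.copy()
        pos[:, 0] *= -1.0
        return Molecule(pos, self.types.copy(), dict(self.properties),
                        id=self.id + "~mirror" if self.id else "")


@dataclass
class MoleculeDataset:
    molecules: list[Molecule]
    property_names: frozenset = frozenset()
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.molecules)

    def __iter__(self) -> Iterator[Molecule]:
        return iter(self.molecules)

    def __getitem__(self, i) -> Molecule:
        return self.molecules[i]


@dataclass(frozen=True)
class Composition:
    counts: tuple  # ((Z, count), ...) sorted by Z

    @staticmethod
    def from_counts(counts: dict[int, int]) -> "Composition":
        return Composition(tuple(sorted((int(z), int(c)) for z, c in counts.items()
                                        if c > 0)))

    @property
    def n_atoms(self) -> int:
        return sum(c for _, c in self.counts)

    @property
    def count_map(self) -> dict[int, int]:
        return dict(self.counts)

    @property
    def fractions(self) -> dict[int, float]:
        n = self.n_atoms
        return {z: c / n for z, c in self.counts}

    def formula(self) -> str:
        # Hill order: C, H, then alphabetical
        cm = self.count_map
        parts = []
        for z in (6, 1):
            if z in cm:
                parts.append(f"{Z_TO_SYMBOL[z]}{cm[z]}")
        rest = sorted((Z_TO_SYMBOL[z], c) for z, c in cm.items() if z not in (6, 1))
        parts.extend(f"{s}{c}" for s, c in rest)
        return "".join(parts)


def composition(mol: Molecule) -> Composition:
    zs, counts = np.unique(mol.types, return_counts=True)
    return Composition.from_counts({int(z): int(c) for z, c in zip(zs, counts)})


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length 1024-bit path fingerprint."""

    bits: bytes  # packed; use `array` for the boolean view

    N_BITS = 1024

    @staticmethod
    def from_array(arr: np.ndarray) -> "Fingerprint":
        arr = np.asarray(arr, dtype=bool)
        if arr.shape != (Fingerprint.N_BITS,):
            raise ValueError(f"fingerprints are {Fingerprint.N_BITS} bits long")
        return Fingerprint(np.packbits(arr).tobytes())

    @property
    def array(self) -> np.ndarray:
        return np.unpackbits(np.frombuffer(self.bits, dtype=np.uint8)).astype(bool)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a AND b| / |a OR b|; two all-zero fingerprints count as identical (1.0)."""
    va, vb = a.array, b.array
    if va.shape != vb.shape:
        raise ValueError("fingerprint length mismatch")
    union = int(np.sum(va | vb))
    if union == 0:
        return 1.0
    return int(np.sum(va & vb)) / union


def path_fingerprint(mol: Molecule, bond_graph) -> Fingerprint:
    """1024-bit linear-path fingerprint (paths up to 7 atoms) of the bond graph.

    Depends only on connectivity, so conformers of one graph map to identical
    bit vectors.
    """
    from rdkit import Chem

    rdmol = bond_graph.to_rdkit()
    if rdmol.GetNumAtoms() == 0:
        raise ValueError("empty bond graph")
    fp = Chem.RDKFingerprint(rdmol, minPath=1, maxPath=7,
                             fpSize=Fingerprint.N_BITS)
    arr = np.zeros(Fingerprint.N_BITS, dtype=bool)
    arr[list(fp.GetOnBits())] = True
    return Fingerprint.from_array(arr)


# ---------------------------------------------------------------------------
# XYZ input / output
# ---------------------------------------------------------------------------

_STAR_EXP = re.compile(r"\*\^")


def _parse_float(token: str) -> float:
    # some QM9 records write exponents as "1.234*^-5"
    return float(_STAR_EXP.sub("e", token))


def _parse_record(lines: list[str], source: str) -> tuple[Molecule, str]:
    """Parse one XYZ record (already split into lines); returns (molecule, comment)."""
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{source}: bad atom-count line {lines[0]!r}")
    if len(lines) < n + 2:
        raise ParseError(f"{source}: expected {n} atom lines, found {len(lines) - 2}")
    comment = lines[1].rstrip("\n")
    types, pos = [], []
    for k in range(n):
        fields = lines[2 + k].split()
        if len(fields) < 4:
            raise ParseError(f"{source}: malformed atom line {lines[2 + k]!r}")
        sym = fields[0]
        if sym not in SYMBOL_TO_Z:
            raise ParseError(f"{source}: unknown element {sym!r}")
        types.append(SYMBOL_TO_Z[sym])
        try:
            pos.append([_parse_float(f) for f in fields[1:4]])
        except ValueError:
            raise ParseError(f"{source}: bad coordinates {lines[2 + k]!r}")
    # a trailing line that itself parses as coordinates signals a count mismatch
    if len(lines) > n + 2:
        extra = lines[n + 2].split()
        if len(extra) >= 4 and extra[0] in SYMBOL_TO_Z:
            try:
                [_parse_float(f) for f in extra[1:4]]
            except ValueError:
                pass
            else:
                raise ParseError(f"{source}: atom-count line disagrees with "
                                 "coordinate lines")
    return Molecule(np.array(pos), np.array(types), id=source), comment


def _parse_qm9_properties(comment: str, source: str) -> dict:
    tokens = comment.replace("\t", " ").split()
    # dialect: "gdb <index> <15 values>"
    if len(tokens) >= 17 and tokens[0] == "gdb":
        values = tokens[2:17]
    elif len(tokens) >= 15:
        values = tokens[-15:]
    else:
        raise ParseError(f"{source}: property line has {len(tokens)} fields, "
                         "expected the 15-field QM9 layout")
    props: dict = {}
    for name, tok in zip(QM9_FIELDS, values):
        try:
            v = _parse_float(tok)
        except ValueError:
            raise ParseError(f"{source}: bad property value {tok!r} for {name}")
        if name in _HARTREE_FIELDS:
            v *= HARTREE_TO_EV
        props[name] = v
    return props


def _iter_xyz_records(text: str, source: str):
    lines = text.splitlines()
    i = 0
    idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError:
            raise ParseError(f"{source}[{idx}]: bad atom-count line {lines[i]!r}")
        chunk = lines[i:i + n + 2]
        # QM9 per-molecule files carry trailing frequency/SMILES/InChI lines;
        # in multi-record archives the next count line delimits records.
        j = i + n + 2
        while j < len(lines) and not _looks_like_count(lines[j]):
            chunk.append(lines[j])
            j += 1
        yield chunk, f"{source}[{idx}]"
        idx += 1
        i = j


def _looks_like_count(line: str) -> bool:
    parts = line.split()
    return len(parts) == 1 and parts[0].isdigit()


def read_xyz(path: str | Path) -> list[Molecule]:
    """Read a (multi-record) plain XYZ file; record ids come from the comment line."""
    path = Path(path)
    mols = []
    for chunk, src in _iter_xyz_records(path.read_text(), str(path)):
        mol, comment = _parse_record(chunk, src)
        if comment.strip():
            mol.id = comment.strip()
        mols.append(mol)
    return mols


def write_xyz(path: str | Path, molecules: Iterable[Molecule],
              precision: int = 8) -> None:
    """Write molecules as a multi-record XYZ archive (comment line = id)."""
    with open(path, "w") as fh:
        for mol in molecules:
            fh.write(f"{mol.n_atoms}\n{mol.id}\n")
            for z, r in zip(mol.types, mol.positions):
                fh.write(f"{Z_TO_SYMBOL[int(z)]} "
                         + " ".join(f"{c:.{precision}f}" for c in r) + "\n")


def load_qm9(path: str | Path) -> MoleculeDataset:
    """Load a QM9-style corpus: a directory of .xyz files, one .xyz file
    (single- or multi-record) or a tar archive of per-molecule files.

    Energetic properties (HOMO, LUMO, gap, zpve, U0, U, H, G) are converted
    from Hartree to eV.  Malformed records raise ParseError naming the record.
    """
    path = Path(path)
    texts: list[tuple[str, str]] = []
    if path.is_dir():
        for p in sorted(path.glob("*.xyz")):
            texts.append((p.read_text(), p.name))
    elif tarfile.is_tarfile(path):
        with tarfile.open(path) as tf:
            for member in sorted(tf.getmembers(), key=lambda m: m.name):
                if member.isfile() and member.name.endswith(".xyz"):
                    texts.append((tf.extractfile(member).read().decode(),
                                  member.name))
    elif path.is_file():
        texts.append((path.read_text(), path.name))
    else:
        raise IOError(f"unreadable QM9 path: {path}")
    if not texts:
        raise IOError(f"no .xyz records under {path}")

    mols: list[Molecule] = []
    for text, name in texts:
        for chunk, src in _iter_xyz_records(text, name):
            mol, comment = _parse_record(chunk, src)
            mol.properties = _parse_qm9_properties(comment, src)
            tokens = comment.split()
            if len(tokens) >= 2 and tokens[0] == "gdb":
                mol.id = f"gdb_{tokens[1]}"
            else:
                mol.id = src
            mols.append(mol)
    return MoleculeDataset(mols, property_names=frozenset(QM9_FIELDS),
                           provenance=str(path))


# ---------------------------------------------------------------------------
# Splitting and energy baseline
# ---------------------------------------------------------------------------

def split_dataset(ds: MoleculeDataset, n_pool: int, n_train: int, n_val: int,
                  exclusion_filter: Callable[[Molecule], bool] | None = None,
                  seed: int = 0,
                  validity_filter: Callable[[Molecule], bool] | None = None,
                  ) -> tuple[MoleculeDataset, MoleculeDataset, MoleculeDataset]:
    """Draw a training pool and split it.

    Order of operations: (1) molecules failing the validity check are removed
    entirely; (2) the exclusion filter (a predicate returning True for
    molecules to KEEP) restricts the pool candidates only — excluded molecules
    stay in the test remainder; (3) `n_pool` molecules are drawn uniformly
    without replacement and split into `n_train` / `n_val`; everything else
    valid becomes the test remainder.
    """
    if validity_filter is None:
        from .validity import validate_structure
        validity_filter = lambda m: validate_structure(m).valid  # noqa: E731
    valid = [m for m in ds if validity_filter(m)]
    if exclusion_filter is None:
        eligible = list(valid)
    else:
        eligible = [m for m in valid if exclusion_filter(m)]
    if n_train + n_val > n_pool:
        raise ValueError("n_train + n_val exceeds n_pool")
    if n_pool > len(eligible):
        raise ValueError(f"pool of {n_pool} requested but only {len(eligible)} "
                         "molecules remain after filtering")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(eligible))
    pool = [eligible[i] for i in order[:n_pool]]
    train = pool[:n_train]
    val = pool[n_train:n_train + n_val]
    pool_ids = {id(m) for m in pool}
    test = [m for m in valid if id(m) not in pool_ids]
    mk = lambda ms, tag: MoleculeDataset(ms, ds.property_names,  # noqa: E731
                                         provenance=f"{ds.provenance}:{tag}")
    return mk(train, "train"), mk(val, "val"), mk(test, "test")


@dataclass
class EnergyBaseline:
    per_type_energy: dict[int, float]  # eV per atom of each element
    fitted_on: str = ""

    def reference_energy(self, comp: Composition) -> float:
        try:
            return sum(c * self.per_type_energy[z] for z, c in comp.counts)
        except KeyError as exc:
            raise KeyError(f"baseline has no coefficient for element {exc}")


def fit_energy_baseline(train: MoleculeDataset, energy_key: str) -> EnergyBaseline:
    """Least-squares fit (no intercept) of molecular energy onto per-element
    atom counts over the training split."""
    types = sorted({int(z) for m in train for z in m.types})
    A = np.zeros((len(train), len(types)))
    y = np.zeros(len(train))
    col = {z: i for i, z in enumerate(types)}
    for i, m in enumerate(train):
        if energy_key not in m.properties:
            raise KeyError(f"molecule {m.id!r} lacks property {energy_key!r}")
        for z, c in composition(m).counts:
            A[i, col[z]] = c
        y[i] = m.properties[energy_key]
    rank = np.linalg.matrix_rank(A)
    if rank < len(types):
        # name an element whose count column never varies independently
        suspects = [Z_TO_SYMBOL.get(z, str(z)) for z in types
                    if np.ptp(A[:, col[z]]) == 0]
        raise ValueError("energy baseline fit is rank-deficient; suspect "
                         f"non-varying element counts: {suspects or types}")
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return EnergyBaseline({z: float(c) for z, c in zip(types, coef)},
                          fitted_on=train.provenance)


def relative_atomic_energy(mol: Molecule, baseline: EnergyBaseline,
                           energy_key: str) -> float:
    """(E - sum_Z n_Z * e_Z) / n_atoms in eV; negative = more stable than the
    per-element baseline predicts."""
    comp = composition(mol)
    e = mol.properties[energy_key]
    return (e - baseline.reference_energy(comp)) / comp.n_atoms


def write_property_table(path: str | Path, ds: MoleculeDataset,
                         names: Sequence[str], units: dict[str, str] | None = None
                         ) -> None:
    units = units or {}
    with open(path, "w") as fh:
        fh.write("id\tproperty\tvalue\tunit\n")
        for m in ds:
            for name in names:
                fh.write(f"{m.id}\t{name}\t{m.properties[name]!r}\t"
                         f"{units.get(name, '')}\n")
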