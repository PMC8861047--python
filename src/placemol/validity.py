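"""Validity and uniqueness assessment of 3d structures.

A generated structure is accepted when bond perception from the raw
coordinates succeeds, every atom's summed bond order matches its fixed
valence (H:1, C:4, N:3, O:2, F:1 for the QM9 element set) and the bond graph
is a single connected component.  Uniqueness uses canonical SMILES with an
enantiomer convention: the key of a structure is the lexicographic minimum of
its own canonical SMILES and that of its mirror image, so mirror-image
stereoisomers collide.  A non-isomeric key variant (stereo-descriptors
dropped) separates novel stereoisomers from novel constitutional isomers.

Bond perception can mis-assign orders in aromatic rings built from carbon and
nitrogen; a rescue heuristic retries those rings as aromatic and accepts the
structure if a valence-consistent kekulization exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .chem_data import Molecule, Z_TO_SYMBOL, composition

__all__ = [
    "BondGraph", "ValidityReport", "CanonicalKey", "BondPerceptionError",
    "DEFAULT_VALENCES", "perceive_bonds", "check_valid", "validate_structure",
    "canonical_key", "deduplicate", "match_against_reference",
]

DEFAULT_VALENCES = {1: 1, 6: 4, 7: 3, 8: 2, 9: 1}


class BondPerceptionError(RuntimeError):
    pass


@dataclass
class BondGraph:
    types: np.ndarray                    # atomic numbers
    bonds: list[tuple[int, int, int]]    # (i, j, integer order), i < j
    heuristic_rescued: bool = False
    _rdmol: object = field(default=None, repr=False)

    def __post_init__(self):
        for i, j, order in self.bonds:
            if i == j:
                raise ValueError("self-bonds are not allowed")
            if order < 1:
                raise ValueError("bond orders are >= 1")

    def degree_orders(self) -> np.ndarray:
        """Summed bond order per atom (aromatic bonds counted via kekulized orders)."""
        tot = np.zeros(len(self.types), dtype=int)
        for i, j, order in self.bonds:
            tot[i] += order
            tot[j] += order
        return tot

    def n_components(self) -> int:
        n = len(self.types)
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i, j, _ in self.bonds:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
        return len({find(i) for i in range(n)})

    def to_rdkit(self):
        if self._rdmol is None:
            raise BondPerceptionError("no perceived RDKit molecule attached")
        return self._rdmol


@dataclass(frozen=True)
class ValidityReport:
    valid: bool
    reasons: frozenset = frozenset()

    def __post_init__(self):
        assert self.valid == (not self.reasons)


@dataclass(frozen=True)
class CanonicalKey:
    key: str
    variant: str  # "isomeric" | "non_isomeric"


def _to_xyz_block(mol: Molecule) -> str:
    lines = [str(mol.n_atoms), mol.id or "mol"]
    for z, r in zip(mol.types, mol.positions):
        lines.append(f"{Z_TO_SYMBOL[int(z)]} {r[0]:.8f} {r[1]:.8f} {r[2]:.8f}")
    return "\n".join(lines) + "\n"


def _aromatic_cn_rescue(mol: Molecule):
    """Retry bond-order assignment treating C/N rings as aromatic.

    Starts from connectivity only, marks every 5- or 6-ring whose members are
    all carbon or nitrogen as aromatic and asks the toolkit for a kekulized,
    sanitized molecule.  Returns the RDKit mol on success, None otherwise.
    """
    from rdkit import Chem
    from rdkit.Chem import rdDetermineBonds

    rd = Chem.MolFromXYZBlock(_to_xyz_block(mol))
    if rd is None:
        return None
    try:
        rdDetermineBonds.DetermineConnectivity(rd)
    except Exception:
        return None
    rw = Chem.RWMol(rd)
    rings = Chem.GetSymmSSSR(rw)
    touched = False
    for ring in rings:
        atoms = list(ring)
        if len(atoms) not in (5, 6):
            continue
        if not all(rw.GetAtomWithIdx(a).GetAtomicNum() in (6, 7) for a in atoms):
            continue
        for a in atoms:
            rw.GetAtomWithIdx(a).SetIsAromatic(True)
        for k in range(len(atoms)):
            b = rw.GetBondBetweenAtoms(atoms[k], atoms[(k + 1) % len(atoms)])
            if b is not None:
                b.SetBondType(Chem.BondType.AROMATIC)
                b.SetIsAromatic(True)
        touched = True
    if not touched:
        return None
    try:
        m = rw.GetMol()
        Chem.SanitizeMol(m)
        Chem.Kekulize(m, clearAromaticFlags=False)
    except Exception:
        return None
    return m


def perceive_bonds(mol: Molecule) -> BondGraph:
    """Perceive bonds and integer bond orders from 3d coordinates.

    Raises BondPerceptionError when no chemically sensible neutral assignment
    exists (callers translate that into a valency_violation report).
    """
    from rdkit import Chem
    from rdkit.Chem import rdDetermineBonds

    rd = Chem.MolFromXYZBlock(_to_xyz_block(mol))
    rescued = False
    if rd is None:
        raise BondPerceptionError(f"toolkit rejected coordinates of {mol.id!r}")
    try:
        rdDetermineBonds.DetermineBonds(rd, charge=0)
    except Exception:
        rd = _aromatic_cn_rescue(mol)
        if rd is None and set(int(z) for z in mol.types) == {1}:
            # pure-hydrogen structures (H2) break the bond-order solver;
            # connectivity with single bonds is the only sensible assignment
            rd = Chem.MolFromXYZBlock(_to_xyz_block(mol))
            try:
                # connect-the-dots skips H-H pairs; the van-der-Waals method
                # perceives them
                rdDetermineBonds.DetermineConnectivity(rd, useVdw=True)
            except Exception:
                rd = None
        elif rd is not None:
            rescued = True
        if rd is None:
            raise BondPerceptionError(
                f"no neutral bond-order assignment found for {mol.id!r}")
    bonds = []
    kek = Chem.Mol(rd)
    try:
        Chem.Kekulize(kek, clearAromaticFlags=True)
    except Exception:
        kek = rd
    for b in kek.GetBonds():
        order = int(round(b.GetBondTypeAsDouble()))
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        bonds.append((min(i, j), max(i, j), max(order, 1)))
    return BondGraph(mol.types.copy(), bonds, heuristic_rescued=rescued,
                     _rdmol=rd)


def check_valid(mol: Molecule, graph: BondGraph,
                valences: dict[int, int] | None = None,
                aborted: bool = False) -> ValidityReport:
    """Valence-and-connectivity check of a perceived bond graph."""
    valences = valences or DEFAULT_VALENCES
    reasons = set()
    if aborted:
        reasons.add("generation_aborted")
    orders = graph.degree_orders()
    for z, total in zip(graph.types, orders):
        if valences.get(int(z)) != int(total):
            reasons.add("valency_violation")
            break
    if graph.n_components() > 1:
        reasons.add("disconnected")
    return ValidityReport(valid=not reasons, reasons=frozenset(reasons))


def validate_structure(mol: Molecule, valences: dict[int, int] | None = None,
                       aborted: bool = False) -> ValidityReport:
    """perceive_bonds + check_valid, folding perception failures into the report."""
    try:
        graph = perceive_bonds(mol)
    except BondPerceptionError:
        reasons = {"valency_violation"}
        if aborted:
            reasons.add("generation_aborted")
        return ValidityReport(valid=False, reasons=frozenset(reasons))
    return check_valid(mol, graph, valences=valences, aborted=aborted)


def _canonical_smiles(mol: Molecule, isomeric: bool) -> str:
    from rdkit import Chem

    graph = perceive_bonds(mol)
    rd = Chem.Mol(graph.to_rdkit())
    Chem.AssignStereochemistryFrom3D(rd)
    return Chem.MolToSmiles(rd, isomericSmiles=isomeric)


def canonical_key(mol: Molecule, graph: BondGraph | None = None,
                  variant: str = "isomeric") -> CanonicalKey:
    """Canonical-SMILES key; enantiomers collide by construction.

    The key is the lexicographic minimum of the canonical string of the
    structure and of its mirror image.  `variant="non_isomeric"` drops stereo
    descriptors entirely (used to classify novel stereoisomers).
    """
    if variant not in ("isomeric", "non_isomeric"):
        raise ValueError(f"unknown variant {variant!r}")
    iso = variant == "isomeric"
    try:
        s1 = _canonical_smiles(mol, iso)
        s2 = _canonical_smiles(mol.mirrored(), iso) if iso else s1
    except BondPerceptionError as exc:
        raise RuntimeError(f"canonicalization failed for {mol.id!r}: {exc}")
    return CanonicalKey(key=min(s1, s2), variant=variant)


def deduplicate(results: Sequence, retention: str = "first",
                property_of: Callable | None = None,
                key_of: Callable | None = None
                ) -> tuple[list, dict[str, int]]:
    """Group by canonical key; keep one representative per group.

    retention="first" keeps the earliest-sampled structure; "lowest_value"
    keeps the one minimizing `property_of(item)` (e.g., predicted relative
    atomic energy).  Returns (unique items in first-seen order, key ->
    multiplicity).
    """
    if retention not in ("first", "lowest_value"):
        raise ValueError(f"unknown retention {retention!r}")
    if retention == "lowest_value" and property_of is None:
        raise ValueError("lowest_value retention needs property_of")
    key_of = key_of or (lambda m: canonical_key(m).key)
    order: list[str] = []
    best: dict[str, object] = {}
    mult: dict[str, int] = {}
    for item in results:
        k = key_of(item)
        if k not in best:
            order.append(k)
            best[k] = item
            mult[k] = 1
        else:
            mult[k] += 1
            if retention == "lowest_value" and (
                    property_of(item) < property_of(best[k])):
                best[k] = item
    return [best[k] for k in order], mult


def match_against_reference(unique: Sequence[Molecule],
                            reference: Iterable[Molecule]
                            ) -> dict[str, list[Molecule]]:
    """Partition unique generated molecules against a reference corpus.

    seen: isomeric key present in the reference (mirror images included by the
    key convention); novel_stereoisomer: only the non-isomeric key is present;
    unseen_in_reference: neither.
    """
    ref_iso = set()
    ref_flat = set()
    for m in reference:
        ref_iso.add(canonical_key(m, variant="isomeric").key)
        ref_flat.add(canonical_key(m, variant="non_isomeric").key)
    out = {"seen": [], "novel_stereoisomer": [], "unseen_in_reference": []}
    for m in unique:
        k_iso = canonical_key(m, variant="isomeric").key
        if k_iso in ref_iso:
            out["seen"].append(m)
            continue
        k_flat = canonical_key(m, variant="non_isomeric").key
        if k_flat in ref_flat:
            out["novel_stereoisomer"].append(m)
        else:
            out["unseen_in_reference"].append(m)
    return out


def ring_statistics(graph: BondGraph) -> list[int]:
    """Sizes of the smallest set of smallest rings of the bond graph."""
    from rdkit import Chem

    return sorted(len(r) for r in Chem.GetSymmSSSR(graph.to_rdkit()))


def bond_order_counts(graph: BondGraph) -> dict[int, int]:
    out: dict[int, int] = {}
    for _, _, order in graph.bonds:
        out[order] = out.get(order, 0) + 1
    return out
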