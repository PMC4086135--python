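"""Ring-centered molecular fragmentation and fragment-set similarity.

The linker rule decomposes a molecule into cyclic fragments: ring systems
(rings sharing an atom are one system) are the fragment cores, acyclic
atoms lying between two distinct ring systems (linkers, including branches
hanging off the linker path) are deleted, and acyclic substituents attached
to exactly one ring system stay with it.  Attachment points left by linker
removal are hydrogen-capped so each fragment is a valid standalone molecule.

Two molecules are compared through their fragment sets: an n×m Tanimoto
matrix over fragment fingerprints is searched for the one-to-one assignment
of min(n, m) fragment pairs with the maximal coefficient sum, and the sum is
normalized by the smaller fragment count, giving a score in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from scipy.optimize import linear_sum_assignment

from .compound_model import StandardizedCompound
from .fingerprints import Fingerprint, fingerprint, tanimoto

logger = logging.getLogger(__name__)

__all__ = [
    "Fragment",
    "FragmentSet",
    "FragmentSimilarityMatrix",
    "fragment",
    "fragment_similarity",
    "assignment_score",
]


@dataclass(frozen=True)
class Fragment:
    smiles: str
    fingerprint: Fingerprint


@dataclass(frozen=True)
class FragmentSet:
    """Non-redundant fragments of one parent, sorted by canonical SMILES."""

    parent_id: str
    fragments: tuple[Fragment, ...]

    def __len__(self) -> int:
        return len(self.fragments)


@dataclass(frozen=True)
class FragmentSimilarityMatrix:
    n: int
    m: int
    coefficients: np.ndarray  # shape (n, m), entries in [0, 1]


def _ring_systems(mol: Chem.Mol) -> list[set[int]]:
    """Maximal ring systems: unions of SSSR rings sharing at least one atom."""
    rings = [set(r) for r in mol.GetRingInfo().AtomRings()]
    systems: list[set[int]] = []
    for ring in rings:
        merged = ring
        rest = []
        for system in systems:
            if merged & system:
                merged = merged | system
            else:
                rest.append(system)
        rest.append(merged)
        systems = rest
    return systems


def _acyclic_components(mol: Chem.Mol, ring_atoms: set[int]) -> list[set[int]]:
    """Connected components of the non-ring atoms."""
    seen: set[int] = set()
    components = []
    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        if idx in ring_atoms or idx in seen:
            continue
        stack = [idx]
        comp = set()
        while stack:
            i = stack.pop()
            if i in comp:
                continue
            comp.add(i)
            for nbr in mol.GetAtomWithIdx(i).GetNeighbors():
                j = nbr.GetIdx()
                if j not in ring_atoms and j not in comp:
                    stack.append(j)
        seen |= comp
        components.append(comp)
    return components


def _submol(mol: Chem.Mol, keep: set[int]) -> Chem.Mol:
    """Extract the induced submolecule on ``keep``; open valences become Hs."""
    rw = Chem.RWMol(mol)
    for idx in sorted(set(range(mol.GetNumAtoms())) - keep, reverse=True):
        rw.RemoveAtom(idx)
    sub = rw.GetMol()
    for atom in sub.GetAtoms():
        atom.SetNoImplicit(False)
    Chem.SanitizeMol(sub)
    return sub


def fragment(compound: StandardizedCompound, kind: str = "circular_d4") -> FragmentSet:
    """Decompose a standardized compound by the linker rule.

    An acyclic molecule has no ring cores to anchor the rule and degrades to
    a single fragment: the whole molecule.
    """
    mol = compound.rdkit_mol()
    systems = _ring_systems(mol)
    if not systems:
        frags = {compound.canonical_smiles}
    else:
        ring_atoms = set().union(*systems)
        system_of = {}
        for si, system in enumerate(systems):
            for idx in system:
                system_of[idx] = si
        # Assign each acyclic component to the ring systems it touches.
        attached: dict[int, list[set[int]]] = {si: [] for si in range(len(systems))}
        for comp in _acyclic_components(mol, ring_atoms):
            touching = set()
            for idx in comp:
                for nbr in mol.GetAtomWithIdx(idx).GetNeighbors():
                    j = nbr.GetIdx()
                    if j in ring_atoms:
                        touching.add(system_of[j])
            if len(touching) == 1:
                attached[touching.pop()].append(comp)
            # len >= 2: linker component, deleted. len == 0 cannot occur in a
            # connected molecule that contains at least one ring.
        frags = set()
        for si, system in enumerate(systems):
            keep = set(system)
            for comp in attached[si]:
                keep |= comp
            sub = _submol(mol, keep)
            frags.add(Chem.MolToSmiles(sub))
    records = []
    for smi in sorted(frags):
        frag_mol = Chem.MolFromSmiles(smi)
        stub = StandardizedCompound(
            canonical_id=smi, canonical_smiles=smi,
            heavy_atom_count=frag_mol.GetNumHeavyAtoms(), mol=frag_mol,
        )
        records.append(Fragment(smiles=smi, fingerprint=fingerprint(stub, kind)))
    return FragmentSet(parent_id=compound.canonical_id, fragments=tuple(records))


def similarity_matrix(a: FragmentSet, b: FragmentSet) -> FragmentSimilarityMatrix:
    coeff = np.array(
        [[tanimoto(fa.fingerprint, fb.fingerprint) for fb in b.fragments]
         for fa in a.fragments],
        dtype=float,
    ).reshape(len(a), len(b))
    return FragmentSimilarityMatrix(n=len(a), m=len(b), coefficients=coeff)


def assignment_score(coefficients: np.ndarray) -> float:
    """Best one-to-one assignment sum over an n×m similarity matrix,
    normalized by min(n, m)."""
    coefficients = np.asarray(coefficients, dtype=float)
    n, m = coefficients.shape
    if n == 0 or m == 0:
        return 0.0
    rows, cols = linear_sum_assignment(coefficients, maximize=True)
    return float(coefficients[rows, cols].sum()) / min(n, m)


def fragment_similarity(a: FragmentSet, b: FragmentSet) -> float:
    """Optimal-assignment fragment similarity in [0, 1]."""
    if len(a) == 0 or len(b) == 0:
        logger.warning("fragment similarity with an empty fragment set is 0.0")
        return 0.0
    return assignment_score(similarity_matrix(a, b).coefficients)


# ---------------------------------------------------------------------------
# Cache I/O


def write_fragment_cache(sets: list[FragmentSet], path) -> None:
    """TSV cache: parent canonical_id, fragment canonical SMILES."""
    with open(path, "w") as fh:
        fh.write("parent_id\tfragment_smiles\n")
        for fset in sets:
            for frag in fset.fragments:
                fh.write(f"{fset.parent_id}\t{frag.smiles}\n")
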