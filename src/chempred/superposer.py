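"""3D superposition of small molecules via principal axes of inertia.

The alignment protocol: for each molecule a small ensemble of low-energy
conformers is generated (distance geometry + force-field minimization).
Each conformer is translated so its heavy-atom center of mass sits at the
origin and rotated so its principal axes of inertia coincide with the
coordinate axes (largest moment on x, smallest on z).  Because the axes are
only defined up to sign, superposing two conformers requires searching just
four proper orientations (identity and 180° rotations about x, y, z).  In
each orientation atom pairs are mapped nearest-first under a maximum
distance threshold; the orientation with the most mapped pairs wins (ties
broken by lower rmsd), and the pair similarity is

    score = N_S / max(N_A, N_B) * exp(-rmsd)

with N_S mapped pairs and rmsd over those pairs.  The molecule-level 3D
similarity is the maximum score over all conformer pairs.

Symmetric tops, whose principal axes are not unique, get two safeguards:
the degenerate axis plane is re-anchored deterministically to the atom
farthest from the origin (making the frame equivariant under rigid motions
of the input), and the orientation search widens to all 24 proper
axis permutations/flips.

Hydrogens are excluded throughout (inertia tensor and atom mapping).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .compound_model import StandardizedCompound

__all__ = [
    "Conformer",
    "SuperpositionResult",
    "ConformerError",
    "generate_conformers",
    "inertial_frame",
    "superpose",
    "score_conformer_sets",
    "similarity_3d",
    "DEFAULT_CONFORMER_SEED",
]

DEFAULT_CONFORMER_SEED = 2014
_DEGENERACY_RTOL = 1e-6

_PT = Chem.GetPeriodicTable()


class ConformerError(RuntimeError):
    """Conformer embedding failed for a molecule."""


@dataclass
class Conformer:
    """Heavy-atom geometry of one conformation."""

    parent_id: str
    atom_elements: list[str]
    coords: np.ndarray  # (n_atoms, 3), Å
    energy_rank: int = 0
    energy: float = math.nan
    moments: np.ndarray | None = field(default=None, repr=False)
    degenerate: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.coords) != len(self.atom_elements):
            raise ValueError("coords and atom_elements length mismatch")


@dataclass(frozen=True)
class SuperpositionResult:
    n_superposed: int
    rmsd: float
    orientation_index: int
    score: float
    mapped: bool = True  # False when no atom pair fell under the threshold


# --- orientation sets -------------------------------------------------------

def _proper_sign_flips() -> list[np.ndarray]:
    mats = []
    for sx, sy, sz in itertools.product((1, -1), repeat=3):
        if sx * sy * sz == 1:
            mats.append(np.diag((float(sx), float(sy), float(sz))))
    return mats


def _proper_signed_permutations() -> list[np.ndarray]:
    mats = []
    for perm in itertools.permutations(range(3)):
        p = np.zeros((3, 3))
        for i, j in enumerate(perm):
            p[i, j] = 1.0
        for flip in itertools.product((1, -1), repeat=3):
            m = p * np.array(flip, dtype=float)[:, None]
            if round(np.linalg.det(m)) == 1:
                mats.append(m)
    return mats


_ORIENT4 = _proper_sign_flips()          # 4 matrices
_ORIENT24 = _proper_signed_permutations()  # 24 matrices


# --- conformer generation ---------------------------------------------------

def generate_conformers(
    compound: StandardizedCompound,
    max_conformers: int = 100,
    seed: int = DEFAULT_CONFORMER_SEED,
) -> list[Conformer]:
    """Embed and minimize up to ``max_conformers`` distinct conformers,
    sorted by increasing force-field energy.  Deterministic under ``seed``."""
    if max_conformers < 1:
        raise ValueError("max_conformers must be >= 1")
    mol = Chem.AddHs(Chem.MolFromSmiles(compound.canonical_smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.pruneRmsThresh = 0.3
    params.useRandomCoords = False
    conf_ids = AllChem.EmbedMultipleConfs(mol, numConfs=max_conformers, params=params)
    if len(conf_ids) == 0:
        raise ConformerError(
            f"conformer embedding failed for {compound.canonical_smiles!r}"
        )
    try:
        results = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=500)
        if all(code == -1 for code, _ in results):  # no MMFF parameters
            results = AllChem.UFFOptimizeMoleculeConfs(mol, maxIters=500)
    except Exception:
        results = AllChem.UFFOptimizeMoleculeConfs(mol, maxIters=500)
    energies = [e for _, e in results]
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    elements = [mol.GetAtomWithIdx(i).GetSymbol() for i in heavy]
    order = sorted(range(len(conf_ids)), key=lambda i: (energies[i], i))
    conformers = []
    for rank, i in enumerate(order[:max_conformers]):
        pos = mol.GetConformer(conf_ids[i]).GetPositions()[heavy]
        conformers.append(
            Conformer(
                parent_id=compound.canonical_id,
                atom_elements=list(elements),
                coords=pos,
                energy_rank=rank,
                energy=float(energies[i]),
            )
        )
    return conformers


# --- inertial frame ---------------------------------------------------------

def _inertia_tensor(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    r2 = (coords ** 2).sum(axis=1)
    tensor = np.zeros((3, 3))
    for k in range(3):
        tensor[k, k] = (masses * (r2 - coords[:, k] ** 2)).sum()
    for k, l in ((0, 1), (0, 2), (1, 2)):
        val = -(masses * coords[:, k] * coords[:, l]).sum()
        tensor[k, l] = tensor[l, k] = val
    return tensor


def _anchor_direction(coords: np.ndarray, plane: np.ndarray) -> np.ndarray | None:
    """Deterministic in-plane reference: projection of the atom with the
    largest in-plane displacement.  ``plane`` holds two orthonormal rows."""
    proj = coords @ plane.T  # (n, 2)
    norms = np.linalg.norm(proj, axis=1)
    k = int(np.argmax(norms))
    if norms[k] < 1e-8:
        return None
    p = proj[k] / norms[k]
    return p[0] * plane[0] + p[1] * plane[1]


def inertial_frame(conformer: Conformer) -> Conformer:
    """Return a copy translated to the heavy-atom center of mass and rotated
    into the principal-axes frame (largest moment on x, smallest on z);
    proper rotation only."""
    masses = np.array([_PT.GetAtomicWeight(el) for el in conformer.atom_elements])
    coords = conformer.coords - (masses[:, None] * conformer.coords).sum(0) / masses.sum()
    n = len(coords)
    if n == 1:
        return Conformer(
            parent_id=conformer.parent_id,
            atom_elements=list(conformer.atom_elements),
            coords=np.zeros((1, 3)),
            energy_rank=conformer.energy_rank,
            energy=conformer.energy,
            moments=np.zeros(3),
            degenerate=True,
        )
    tensor = _inertia_tensor(coords, masses)
    w, v = np.linalg.eigh(tensor)  # ascending eigenvalues
    # rows: x (largest moment), y, z (smallest moment)
    axes = v[:, [2, 1, 0]].T.copy()
    if np.linalg.det(axes) < 0:
        axes[2] *= -1
    moments = w[[2, 1, 0]]
    scale = max(moments[0], 1e-12)
    deg_xy = (moments[0] - moments[1]) / scale < _DEGENERACY_RTOL
    deg_yz = (moments[1] - moments[2]) / scale < _DEGENERACY_RTOL
    if deg_xy and deg_yz:
        # Spherical top: build the whole frame from the geometry.
        norms = np.linalg.norm(coords, axis=1)
        k = int(np.argmax(norms))
        if norms[k] > 1e-8:
            x = coords[k] / norms[k]
            rest = coords - (coords @ x)[:, None] * x[None, :]
            rnorms = np.linalg.norm(rest, axis=1)
            k2 = int(np.argmax(rnorms))
            if rnorms[k2] > 1e-8:
                y = rest[k2] / rnorms[k2]
            else:  # all atoms collinear with x
                basis = np.eye(3)
                y = basis[int(np.argmin(np.abs(x)))]
                y = y - (y @ x) * x
                y /= np.linalg.norm(y)
            axes = np.vstack([x, y, np.cross(x, y)])
    elif deg_xy:
        anchor = _anchor_direction(coords, axes[:2])
        if anchor is not None:
            x = anchor
            y = np.cross(axes[2], x)
            axes = np.vstack([x, y / np.linalg.norm(y), axes[2]])
    elif deg_yz:
        anchor = _anchor_direction(coords, axes[1:])
        if anchor is not None:
            y = anchor
            z = np.cross(axes[0], y)
            axes = np.vstack([axes[0], y, z / np.linalg.norm(z)])
    return Conformer(
        parent_id=conformer.parent_id,
        atom_elements=list(conformer.atom_elements),
        coords=coords @ axes.T,
        energy_rank=conformer.energy_rank,
        energy=conformer.energy,
        moments=moments,
        degenerate=bool(deg_xy or deg_yz),
    )


# --- superposition ----------------------------------------------------------

def _greedy_pairs(dist: np.ndarray, max_dist: float) -> np.ndarray:
    """Nearest-first mapping: repeatedly take the globally closest unmatched
    pair with distance <= max_dist.  Returns the mapped pair distances."""
    d = dist.copy()
    out = []
    while d.size:
        flat = int(np.argmin(d))
        i, j = np.unravel_index(flat, d.shape)
        if not np.isfinite(d[i, j]) or d[i, j] > max_dist:
            break
        out.append(d[i, j])
        d[i, :] = np.inf
        d[:, j] = np.inf
    return np.array(out)


def _optimal_pairs(dist: np.ndarray, max_dist: float) -> np.ndarray:
    """Maximum-cardinality mapping under the threshold, then minimal squared
    distance: solved as a linear assignment with a large penalty for
    over-threshold pairs."""
    from scipy.optimize import linear_sum_assignment

    big = (dist.size + 1) * (max_dist ** 2 + 1.0)
    cost = np.where(dist <= max_dist, dist ** 2, big)
    rows, cols = linear_sum_assignment(cost)
    good = cost[rows, cols] < big
    return dist[rows[good], cols[good]]


def superpose(
    a: Conformer,
    b: Conformer,
    max_pair_distance: float = 1.0,
    mapping: str = "greedy",
    match_elements: bool = False,
) -> SuperpositionResult:
    """Superpose conformer ``b`` onto ``a`` (both already in the inertial
    frame) over the proper-orientation set, map atom pairs under the distance
    threshold, and score the best orientation."""
    orientations = _ORIENT24 if (a.degenerate or b.degenerate) else _ORIENT4
    pair_fn = _greedy_pairs if mapping == "greedy" else _optimal_pairs
    if match_elements:
        el_a = np.array(a.atom_elements)
        el_b = np.array(b.atom_elements)
        mismatch = el_a[:, None] != el_b[None, :]
    best = None  # (-n_pairs, rmsd, orientation_index, dists)
    for oi, orient in enumerate(orientations):
        bc = b.coords @ orient.T
        diff = a.coords[:, None, :] - bc[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=2))
        if match_elements:
            dist = np.where(mismatch, np.inf, dist)
        dists = pair_fn(dist, max_pair_distance)
        n_pairs = len(dists)
        rmsd = float(np.sqrt((dists ** 2).mean())) if n_pairs else 0.0
        key = (-n_pairs, rmsd, oi)
        if best is None or key < best[:3]:
            best = (-n_pairs, rmsd, oi, dists)
    n_pairs, rmsd, oi = -best[0], best[1], best[2]
    if n_pairs == 0:
        return SuperpositionResult(
            n_superposed=0, rmsd=0.0, orientation_index=oi, score=0.0, mapped=False
        )
    score = n_pairs / max(len(a.coords), len(b.coords)) * math.exp(-rmsd)
    return SuperpositionResult(
        n_superposed=n_pairs, rmsd=rmsd, orientation_index=oi, score=score
    )


def score_conformer_sets(
    confs_a: list[Conformer],
    confs_b: list[Conformer],
    max_pair_distance: float = 1.0,
    mapping: str = "greedy",
    match_elements: bool = False,
) -> float:
    """Maximum superposition score over all conformer pairs (the conformers
    are brought into the inertial frame here if needed)."""
    fa = [c if c.moments is not None else inertial_frame(c) for c in confs_a]
    fb = [c if c.moments is not None else inertial_frame(c) for c in confs_b]
    best = 0.0
    for ca in fa:
        for cb in fb:
            res = superpose(
                ca, cb, max_pair_distance=max_pair_distance,
                mapping=mapping, match_elements=match_elements,
            )
            if res.score > best:
                best = res.score
    return best


def similarity_3d(
    a: StandardizedCompound,
    b: StandardizedCompound,
    max_conformers: int = 100,
    seed: int = DEFAULT_CONFORMER_SEED,
    max_pair_distance: float = 1.0,
    mapping: str = "greedy",
    match_elements: bool = False,
    conformer_cache: dict | None = None,
) -> float:
    """3D similarity of two compounds: best score over the conformer-pair
    grid (at most ``max_conformers**2`` comparisons)."""

    def ensemble(comp: StandardizedCompound) -> list[Conformer]:
        if conformer_cache is not None and comp.canonical_id in conformer_cache:
            return conformer_cache[comp.canonical_id]
        confs = [
            inertial_frame(c)
            for c in generate_conformers(comp, max_conformers=max_conformers, seed=seed)
        ]
        if conformer_cache is not None:
            conformer_cache[comp.canonical_id] = confs
        return confs

    return score_conformer_sets(
        ensemble(a), ensemble(b),
        max_pair_distance=max_pair_distance,
        mapping=mapping, match_elements=match_elements,
    )


# --- conformer SDF I/O ------------------------------------------------------

def write_conformers_sdf(conformers: list[Conformer], path) -> None:
    """Multi-record SDF; atoms only (no bonds), energy_rank as a property."""
    writer = Chem.SDWriter(str(path))
    try:
        for conf in conformers:
            rw = Chem.RWMol()
            for el in conf.atom_elements:
                atom = Chem.Atom(el)
                atom.SetNoImplicit(True)
                rw.AddAtom(atom)
            rdconf = Chem.Conformer(len(conf.atom_elements))
            for i, (x, y, z) in enumerate(conf.coords):
                rdconf.SetAtomPosition(i, (float(x), float(y), float(z)))
            mol = rw.GetMol()
            mol.AddConformer(rdconf)
            mol.UpdatePropertyCache(strict=False)
            mol.SetProp("_Name", conf.parent_id)
            mol.SetProp("energy_rank", str(conf.energy_rank))
            writer.write(mol)
    finally:
        writer.close()


def read_conformers_sdf(path) -> list[Conformer]:
    out = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    for mol in supplier:
        if mol is None:
            continue
        coords = mol.GetConformer().GetPositions()
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        heavy = [i for i, el in enumerate(elements) if el != "H"]
        rank = int(mol.GetProp("energy_rank")) if mol.HasProp("energy_rank") else 0
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        out.append(
            Conformer(
                parent_id=name,
                atom_elements=[elements[i] for i in heavy],
                coords=coords[heavy],
                energy_rank=rank,
            )
        )
    return out
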