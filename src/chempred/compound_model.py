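"""Parsing, standardization and deduplication of small molecules.

Every compound entering the toolkit — query structures, reference-library
drugs, interaction-table ligands — passes through :func:`standardize`, which
normalizes it to a single covalent fragment with a canonical InChI identity.
Compounds with identical standard InChI are treated as the same chemical
entity and merged by :func:`deduplicate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "RawCompound",
    "StandardizedCompound",
    "StandardizationConfig",
    "ParseError",
    "StandardizationError",
    "standardize",
    "deduplicate",
    "read_smiles_file",
    "read_sdf",
    "write_sdf",
    "write_tsv",
]


class ParseError(ValueError):
    """The input structure could not be parsed."""

    def __init__(self, source_id: str, message: str = "unparseable structure"):
        self.source_id = source_id
        super().__init__(f"{message} (source_id={source_id!r})")


class StandardizationError(ValueError):
    """The structure became empty or invalid during standardization."""


@dataclass(frozen=True)
class StandardizationConfig:
    """Knobs for structure normalization.

    keep_stereo:
        When false (default) stereo descriptors are stripped before the
        canonical InChI is computed, so stereoisomers merge into one record.
    neutralize_charges:
        Protonate/deprotonate simple acid/base groups to formal charge zero.
        Charges that cannot be removed without changing bonds (e.g. quaternary
        nitrogen) are kept.
    """

    keep_stereo: bool = False
    neutralize_charges: bool = True


@dataclass(frozen=True)
class RawCompound:
    """An un-normalized input structure plus whatever metadata came with it."""

    source_id: str
    structure: str  # SMILES string or MOL block
    metadata: dict = field(default_factory=dict, compare=False)


@dataclass
class StandardizedCompound:
    """A normalized single-fragment molecule keyed by standard InChI."""

    canonical_id: str
    canonical_smiles: str
    heavy_atom_count: int
    provenance_ids: list[str] = field(default_factory=list)
    mol: Chem.Mol = field(default=None, repr=False, compare=False)

    def rdkit_mol(self) -> Chem.Mol:
        if self.mol is None:
            self.mol = Chem.MolFromSmiles(self.canonical_smiles)
        return self.mol


# Neutralize +1 atoms carrying an H (not quaternary N) and -1 atoms that are
# not charge-balanced by an adjacent cation (keeps zwitterion-internal salts
# like N-oxides intact).
_NEUTRALIZE_PATTERN = Chem.MolFromSmarts(
    "[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]"
)


def _neutralize(mol: Chem.Mol) -> Chem.Mol:
    matches = mol.GetSubstructMatches(_NEUTRALIZE_PATTERN)
    if not matches:
        return mol
    mol = Chem.RWMol(mol)
    for (idx,) in matches:
        atom = mol.GetAtomWithIdx(idx)
        charge = atom.GetFormalCharge()
        n_h = atom.GetTotalNumHs()
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(n_h - charge)
        atom.UpdatePropertyCache()
    Chem.SanitizeMol(mol)
    return mol.GetMol()


def _parse_structure(raw: RawCompound) -> Chem.Mol:
    text = raw.structure
    if "\n" in text or "M  END" in text:
        mol = Chem.MolFromMolBlock(text, sanitize=True, removeHs=True)
    else:
        mol = Chem.MolFromSmiles(text)
    if mol is None or mol.GetNumAtoms() == 0:
        raise ParseError(raw.source_id)
    return mol


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if not frags:
        raise StandardizationError("no fragments after parsing")
    # Deterministic choice: most heavy atoms, then molecular weight,
    # then lexicographically smallest canonical SMILES.
    def key(frag: Chem.Mol):
        return (
            -frag.GetNumHeavyAtoms(),
            -Descriptors.MolWt(frag),
            Chem.MolToSmiles(frag),
        )

    return sorted(frags, key=key)[0]


def standardize(
    raw: RawCompound, config: StandardizationConfig | None = None
) -> StandardizedCompound:
    """Normalize a raw structure to a canonical single-fragment record.

    Keeps the largest covalent fragment (dropping salts and counter-ions),
    strips explicit hydrogens, perceives aromaticity, neutralizes simple
    formal charges, optionally removes stereochemistry, and discards any
    input coordinates.  The canonical identifier is the standard InChI of
    the final structure.

    Raises :class:`ParseError` for unparseable input and
    :class:`StandardizationError` if nothing remains after fragment isolation.
    """
    config = config or StandardizationConfig()
    mol = _parse_structure(raw)
    mol = _largest_fragment(mol)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - rdkit-specific failures
        raise StandardizationError(f"sanitization failed: {exc}") from exc
    mol = Chem.RemoveHs(mol)
    if mol.GetNumHeavyAtoms() == 0:
        raise StandardizationError(
            f"empty molecule after fragment isolation (source_id={raw.source_id!r})"
        )
    if config.neutralize_charges:
        mol = _neutralize(mol)
    if not config.keep_stereo:
        Chem.RemoveStereochemistry(mol)
    # Round-trip through canonical SMILES: discards coordinates and gives a
    # single normalized aromaticity model regardless of input convention.
    canonical_smiles = Chem.MolToSmiles(mol)
    mol = Chem.MolFromSmiles(canonical_smiles)
    if mol is None:
        raise StandardizationError(
            f"canonical SMILES round-trip failed (source_id={raw.source_id!r})"
        )
    inchi = Chem.MolToInchi(mol)
    if not inchi or not inchi.startswith("InChI=1S/"):
        raise StandardizationError(
            f"standard InChI generation failed (source_id={raw.source_id!r})"
        )
    return StandardizedCompound(
        canonical_id=inchi,
        canonical_smiles=canonical_smiles,
        heavy_atom_count=mol.GetNumHeavyAtoms(),
        provenance_ids=[raw.source_id],
        mol=mol,
    )


def deduplicate(
    compounds: list[StandardizedCompound],
) -> list[StandardizedCompound]:
    """Merge records with identical canonical_id, preserving first-appearance
    order and unioning provenance_ids."""
    merged: dict[str, StandardizedCompound] = {}
    for comp in compounds:
        existing = merged.get(comp.canonical_id)
        if existing is None:
            merged[comp.canonical_id] = replace(
                comp, provenance_ids=list(comp.provenance_ids)
            )
        else:
            existing.provenance_ids.extend(comp.provenance_ids)
    return list(merged.values())


# ---------------------------------------------------------------------------
# File I/O


def read_smiles_file(path) -> list[RawCompound]:
    """Read a SMILES file: one molecule per line, optional tab-separated id."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            source_id = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
            out.append(RawCompound(source_id=source_id, structure=smiles))
    return out


def read_sdf(path) -> list[RawCompound]:
    """Read an SDF/MOL V2000 file into raw compounds (MOL-block structures)."""
    out = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            out.append(RawCompound(source_id=f"record{i}", structure=""))
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        props = {k: mol.GetProp(k) for k in mol.GetPropNames()}
        out.append(
            RawCompound(
                source_id=name or f"record{i}",
                structure=Chem.MolToMolBlock(mol, kekulize=False),
                metadata=props,
            )
        )
    return out


def write_sdf(compounds: list[StandardizedCompound], path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for comp in compounds:
            mol = Chem.Mol(comp.rdkit_mol())
            mol.SetProp("_Name", comp.provenance_ids[0] if comp.provenance_ids else "")
            mol.SetProp("canonical_id", comp.canonical_id)
            mol.SetProp("provenance_ids", ";".join(comp.provenance_ids))
            writer.write(mol)
    finally:
        writer.close()


def write_tsv(compounds: list[StandardizedCompound], path) -> None:
    with open(path, "w") as fh:
        fh.write("canonical_id\tcanonical_smiles\tprovenance_ids\n")
        for comp in compounds:
            fh.write(
                f"{comp.canonical_id}\t{comp.canonical_smiles}\t"
                f"{';'.join(comp.provenance_ids)}\n"
            )
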