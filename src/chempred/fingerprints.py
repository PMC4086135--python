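"""Binary molecular fingerprints and Tanimoto similarity.

Three pluggable backends:

``circular_d4``
    Extended-connectivity (Morgan) fingerprint of diameter 4 (radius 2),
    used *unfolded*: the bit set holds the sparse environment identifiers,
    so no information is lost to folding collisions.  A folded variant is
    available via ``nbits``.
``structural_keys_166``
    The 166-key MDL structural key set (RDKit's MACCS implementation;
    key indices 1..166, position 0 unused).
``path_based``
    Daylight-style hashed linear paths up to 7 bonds, folded to 1024 bits.
    Stands in for proprietary path fingerprints so the backend-comparison
    harness has a third, non-circular representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .compound_model import StandardizedCompound

logger = logging.getLogger(__name__)

__all__ = ["Fingerprint", "FingerprintKindError", "KINDS", "fingerprint", "tanimoto",
           "write_fingerprint_cache", "read_fingerprint_cache"]

KINDS = ("circular_d4", "structural_keys_166", "path_based")

_MORGAN_RADIUS = 2  # diameter 4
_PATH_MAX_LENGTH = 7
_PATH_NBITS = 1024


class FingerprintKindError(ValueError):
    """Unknown fingerprint kind or kind mismatch in a comparison."""


@dataclass(frozen=True)
class Fingerprint:
    """A binary fingerprint as a set of set-bit positions.

    ``nbits == 0`` marks a sparse/unfolded fingerprint whose positions are
    raw environment identifiers rather than indices into a fixed-length
    bit string.
    """

    kind: str
    bits: frozenset
    nbits: int = 0

    def __post_init__(self):
        if self.nbits > 0 and self.bits and max(self.bits) >= self.nbits:
            raise ValueError("bit position outside folded fingerprint length")


def fingerprint(
    compound: StandardizedCompound, kind: str = "circular_d4", nbits: int = 0
) -> Fingerprint:
    """Compute a fingerprint of the requested kind.

    ``nbits`` applies only to ``circular_d4``: 0 (default) keeps the sparse
    unfolded identifier set; a positive value folds to that length.
    """
    mol = compound.rdkit_mol()
    if kind == "circular_d4":
        if nbits > 0:
            gen = rdFingerprintGenerator.GetMorganGenerator(
                radius=_MORGAN_RADIUS, fpSize=nbits
            )
            bits = frozenset(gen.GetFingerprint(mol).GetOnBits())
            return Fingerprint(kind=kind, bits=bits, nbits=nbits)
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=_MORGAN_RADIUS)
        sparse = gen.GetSparseCountFingerprint(mol)
        bits = frozenset(sparse.GetNonzeroElements().keys())
        return Fingerprint(kind=kind, bits=bits, nbits=0)
    if kind == "structural_keys_166":
        keys = MACCSkeys.GenMACCSKeys(mol)
        return Fingerprint(kind=kind, bits=frozenset(keys.GetOnBits()), nbits=167)
    if kind == "path_based":
        fp = Chem.RDKFingerprint(mol, maxPath=_PATH_MAX_LENGTH, fpSize=_PATH_NBITS)
        return Fingerprint(kind=kind, bits=frozenset(fp.GetOnBits()), nbits=_PATH_NBITS)
    raise FingerprintKindError(f"unknown fingerprint kind {kind!r}")


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| on bit sets.

    Two empty fingerprints compare as 0.0 (a degenerate, atom-poor input
    should not look like a perfect match).
    """
    if a.kind != b.kind:
        raise FingerprintKindError(
            f"cannot compare fingerprints of kind {a.kind!r} and {b.kind!r}"
        )
    if not a.bits and not b.bits:
        logger.warning("tanimoto of two empty fingerprints defined as 0.0")
        return 0.0
    inter = len(a.bits & b.bits)
    if inter == 0:
        return 0.0
    return inter / (len(a.bits) + len(b.bits) - inter)


# ---------------------------------------------------------------------------
# Cache I/O


def write_fingerprint_cache(entries: list[tuple[str, Fingerprint]], path) -> None:
    """TSV cache: canonical_id, kind, sorted comma-joined bits, nbits."""
    with open(path, "w") as fh:
        fh.write("canonical_id\tkind\tbits\tnbits\n")
        for canonical_id, fp in entries:
            bits = ",".join(str(b) for b in sorted(fp.bits))
            fh.write(f"{canonical_id}\t{fp.kind}\t{bits}\t{fp.nbits}\n")


def read_fingerprint_cache(path) -> list[tuple[str, Fingerprint]]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("canonical_id\t"):
            raise ValueError("not a fingerprint cache file")
        for line in fh:
            canonical_id, kind, bits_s, nbits_s = line.rstrip("\n").split("\t")
            if kind not in KINDS:
                raise FingerprintKindError(f"unknown fingerprint kind {kind!r}")
            bits = frozenset(int(b) for b in bits_s.split(",") if b)
            out.append((canonical_id, Fingerprint(kind=kind, bits=bits, nbits=int(nbits_s))))
    return out
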