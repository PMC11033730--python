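"""Chemistry primitives shared by all pipeline stages.

Canonical SMILES, Morgan (circular) fingerprints, Tanimoto similarity,
Bemis-Murcko scaffolds and nearest-neighbour lookup.  Everything is a thin,
deterministic layer over RDKit; fingerprint parameters default to the
community-standard radius 2 / 2048 bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

DEFAULT_FP_RADIUS = 2
DEFAULT_FP_BITS = 2048


class InvalidMoleculeError(ValueError):
    """Raised when a SMILES string does not parse to a molecular graph."""


def canonicalize(smiles: str) -> str:
    """Return RDKit's canonical SMILES for *smiles*.

    Deterministic and idempotent: equivalent notations map to the same
    string, and canonicalizing a canonical string is a fixed point.

    Raises
    ------
    InvalidMoleculeError
        If the string cannot be parsed.
    """
    if not smiles:
        raise InvalidMoleculeError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(f"cannot parse SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class Molecule:
    """A drug-like molecule keyed by an opaque identifier.

    ``canonical_smiles`` is derived on construction; two Molecule records
    with the same canonical form are chemically identical for every
    operation in this package.
    """

    id: str
    smiles: str
    name: Optional[str] = None
    canonical_smiles: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "canonical_smiles", canonicalize(self.smiles))

    def to_rdkit(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.canonical_smiles)
        if mol is None:  # pragma: no cover - canonical form always parses
            raise InvalidMoleculeError(self.canonical_smiles)
        return mol


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary substructure fingerprint of one molecule."""

    bits: np.ndarray  # uint8 0/1 vector
    radius: int
    molecule_id: str

    @property
    def n_bits(self) -> int:
        return self.bits.shape[0]

    def to_hex(self) -> str:
        return np.packbits(self.bits).tobytes().hex()


@dataclass(frozen=True)
class SimilarityHit:
    neighbor_id: str
    similarity: float


def morgan_fingerprint(
    mol: Molecule,
    radius: int = DEFAULT_FP_RADIUS,
    n_bits: int = DEFAULT_FP_BITS,
) -> Fingerprint:
    """Morgan fingerprint of *mol* as a dense 0/1 vector.

    Parameters mirror the usual ECFP convention: ``radius=2`` with 2048 bits
    corresponds to ECFP4.  Deterministic: identical canonical SMILES give
    identical bit vectors.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if n_bits < 64 or (n_bits & (n_bits - 1)) != 0:
        raise ValueError("n_bits must be a power of two >= 64")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol.to_rdkit())
    arr = np.zeros(n_bits, dtype=np.uint8)
    for idx in bv.GetOnBits():
        arr[idx] = 1
    return Fingerprint(bits=arr, radius=radius, molecule_id=mol.id)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) similarity |a AND b| / |a OR b|.

    Convention: two all-zero fingerprints are identical, so their similarity
    is defined as 1.0 (lets duplicate featureless molecules self-match).
    """
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    inter = int(np.sum(a.bits & b.bits))
    union = int(np.sum(a.bits | b.bits))
    if union == 0:
        return 1.0
    return inter / union


def bemis_murcko_scaffold(mol: Molecule) -> str:
    """Bemis-Murcko scaffold SMILES: ring systems plus linkers, side chains
    stripped.  Acyclic molecules yield the empty string."""
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol.to_rdkit())


def most_similar(
    query: Molecule,
    library: Sequence[Molecule],
    threshold: float,
    *,
    precomputed: Optional[dict[str, Fingerprint]] = None,
) -> Optional[SimilarityHit]:
    """Most Tanimoto-similar library member to *query*, if above threshold.

    Returns the member with maximal similarity when that maximum is
    ``>= threshold``, else ``None``.  Ties are broken by the
    lexicographically smallest ``neighbor_id`` so that downstream imputation
    is reproducible.  An empty library returns ``None``.

    ``precomputed`` may carry fingerprints keyed by molecule id to avoid
    recomputation in batch lookups.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    qfp = morgan_fingerprint(query)
    best: Optional[SimilarityHit] = None
    for member in library:
        if member.id == query.id:
            continue
        fp = precomputed.get(member.id) if precomputed else None
        if fp is None:
            fp = morgan_fingerprint(member)
        sim = tanimoto(qfp, fp)
        if best is None or sim > best.similarity or (
            sim == best.similarity and member.id < best.neighbor_id
        ):
            best = SimilarityHit(neighbor_id=member.id, similarity=sim)
    if best is None or best.similarity < threshold:
        return None
    return best


def fingerprint_library(molecules: Iterable[Molecule]) -> dict[str, Fingerprint]:
    """Precompute fingerprints for repeated nearest-neighbour queries."""
    return {m.id: morgan_fingerprint(m) for m in molecules}
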