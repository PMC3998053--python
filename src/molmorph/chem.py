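"""Molecule identity, fingerprints, similarity coefficients and the distance model.

A molecule is held as a :class:`MoleculeRecord` whose identity is its canonical
SMILES string: two records denote the same molecule iff their ``canonical_form``
strings are equal.  This identity is what the exploration engine uses for
deduplication and for detecting that the target has been reached — it is exact
and immune to fingerprint collisions.

Distances are derived from bit-vector fingerprints.  The default representation
is the Morgan (circular, ECFP4-like) fingerprint with radius 2 hashed to
2048 bits, compared with the Tanimoto coefficient; both are configurable.
When decoy molecules are present the distance to the target is averaged with
the distance to the *closest* decoy, which steers the search through remoter
regions of chemical space.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator

RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

__all__ = [
    "MoleculeError",
    "ParseError",
    "DisconnectedMoleculeError",
    "MoleculeRecord",
    "canonicalize",
    "record_from_mol",
    "FingerprintKind",
    "Fingerprint",
    "fingerprint",
    "SimilarityCoefficient",
    "similarity",
    "DistanceModel",
    "distance",
]


class MoleculeError(ValueError):
    """Base class for rejected molecular input."""


class ParseError(MoleculeError):
    """The structure string could not be parsed into a valid molecule."""


class DisconnectedMoleculeError(MoleculeError):
    """The structure contains more than one connected component."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A canonical molecular structure.

    Equality and hashing are by ``canonical_form`` only, so records can be used
    directly as set members and dict keys for deduplication.
    """

    canonical_form: str
    mol_weight: float
    element_multiset: tuple[tuple[str, int], ...]
    graph_handle: Chem.Mol = field(compare=False, repr=False, hash=False)
    label: str | None = field(default=None, compare=False)

    def __hash__(self) -> int:  # frozen dataclass w/ unhashable Mol field
        return hash(self.canonical_form)

    @property
    def elements(self) -> dict[str, int]:
        """Element symbol -> heavy-atom count, as a plain dict."""
        return dict(self.element_multiset)

    @property
    def num_heavy_atoms(self) -> int:
        return self.graph_handle.GetNumAtoms()

    def with_label(self, label: str | None) -> "MoleculeRecord":
        return MoleculeRecord(
            self.canonical_form, self.mol_weight, self.element_multiset,
            self.graph_handle, label,
        )


def record_from_mol(mol: Chem.Mol, label: str | None = None) -> MoleculeRecord:
    """Build a :class:`MoleculeRecord` from an already-parsed RDKit molecule."""
    if mol is None:
        raise ParseError("cannot build a record from a null molecule")
    frags = Chem.GetMolFrags(mol)
    if len(frags) != 1:
        raise DisconnectedMoleculeError(
            f"disconnected structure ({len(frags)} fragments): "
            f"{Chem.MolToSmiles(mol)!r}"
        )
    canonical = Chem.MolToSmiles(mol)
    # Re-parse from the canonical form so the stored graph is in canonical
    # atom order; canonicalization is then idempotent by construction.
    clean = Chem.MolFromSmiles(canonical)
    if clean is None:  # pragma: no cover - canonical SMILES always re-parse
        raise ParseError(f"canonical form failed to re-parse: {canonical!r}")
    counts: dict[str, int] = {}
    for atom in clean.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
    return MoleculeRecord(
        canonical_form=canonical,
        mol_weight=Descriptors.MolWt(clean),
        element_multiset=tuple(sorted(counts.items())),
        graph_handle=clean,
        label=label,
    )


def canonicalize(structure: "str | MoleculeRecord", label: str | None = None) -> MoleculeRecord:
    """Parse a SMILES string into a canonical :class:`MoleculeRecord`.

    Raises :class:`ParseError` for unparseable input and
    :class:`DisconnectedMoleculeError` for multi-fragment input.  Passing an
    existing record returns it unchanged (identity backbone is idempotent).
    """
    if isinstance(structure, MoleculeRecord):
        return structure if label is None else structure.with_label(label)
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ParseError(f"could not parse structure: {structure!r}")
    return record_from_mol(mol, label=label)


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------

class FingerprintKind(enum.Enum):
    """Registered fingerprint representations.

    MORGAN is the circular (ECFP4-like) fingerprint, radius 2, 2048 bits, and
    the engine default.  PATH hashes linear atom paths up to length 7 into
    2048 bits.  MACCS_LIKE is the 167-bit structural-key set.  The registry is
    an enum so new kinds can be added in one place.
    """

    MORGAN = "morgan"
    PATH = "path"
    MACCS_LIKE = "maccs"

    @property
    def length(self) -> int:
        return _FP_LENGTHS[self]

    @classmethod
    def from_name(cls, name: str) -> "FingerprintKind":
        name = name.strip().lower()
        for kind in cls:
            if kind.value == name or kind.name.lower() == name:
                return kind
        raise ValueError(f"unknown fingerprint kind: {name!r}")


_FP_LENGTHS = {
    FingerprintKind.MORGAN: 2048,
    FingerprintKind.PATH: 2048,
    FingerprintKind.MACCS_LIKE: 167,
}

_morgan_gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
_path_gen = rdFingerprintGenerator.GetRDKitFPGenerator(maxPath=7, fpSize=2048)


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-length bit vector tagged with its kind."""

    bits: np.ndarray  # bool array
    kind: FingerprintKind

    def __post_init__(self) -> None:
        if self.bits.dtype != np.bool_:
            object.__setattr__(self, "bits", self.bits.astype(bool))
        self.bits.setflags(write=False)
        if self.bits.shape != (self.kind.length,):
            raise ValueError(
                f"{self.kind.name} fingerprint must have {self.kind.length} bits,"
                f" got shape {self.bits.shape}"
            )

    @property
    def length(self) -> int:
        return self.kind.length

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Fingerprint):
            return NotImplemented
        return self.kind is other.kind and bool(np.array_equal(self.bits, other.bits))

    def __hash__(self) -> int:
        return hash((self.kind, self.bits.tobytes()))


def fingerprint(mol: MoleculeRecord, kind: FingerprintKind = FingerprintKind.MORGAN) -> Fingerprint:
    """Compute the bit-vector fingerprint of a molecule; deterministic per kind."""
    m = mol.graph_handle
    if kind is FingerprintKind.MORGAN:
        arr = _morgan_gen.GetFingerprintAsNumPy(m)
    elif kind is FingerprintKind.PATH:
        arr = _path_gen.GetFingerprintAsNumPy(m)
    elif kind is FingerprintKind.MACCS_LIKE:
        bv = MACCSkeys.GenMACCSKeys(m)
        arr = np.zeros(167, dtype=bool)
        arr[list(bv.GetOnBits())] = True
    else:  # pragma: no cover
        raise ValueError(f"unhandled fingerprint kind {kind}")
    return Fingerprint(bits=np.asarray(arr, dtype=bool), kind=kind)


# ---------------------------------------------------------------------------
# similarity coefficients
# ---------------------------------------------------------------------------

class SimilarityCoefficient(enum.Enum):
    """Bit-vector similarity coefficients mapping to [0, 1]."""

    TANIMOTO = "tanimoto"
    DICE = "dice"
    COSINE = "cosine"

    @classmethod
    def from_name(cls, name: str) -> "SimilarityCoefficient":
        name = name.strip().lower()
        for coeff in cls:
            if coeff.value == name:
                return coeff
        raise ValueError(f"unknown similarity coefficient: {name!r}")


def similarity(
    a: Fingerprint,
    b: Fingerprint,
    coeff: SimilarityCoefficient = SimilarityCoefficient.TANIMOTO,
) -> float:
    """Similarity of two equal-kind fingerprints in [0, 1].

    Tanimoto = |a∧b| / |a∨b|, Dice = 2|a∧b| / (|a|+|b|),
    Cosine = |a∧b| / sqrt(|a||b|).  For two all-zero vectors every coefficient
    is defined as 1 (identical, if empty, environments).
    """
    if a.kind is not b.kind or a.length != b.length:
        raise ValueError(
            f"fingerprint mismatch: {a.kind.name}/{a.length} vs {b.kind.name}/{b.length}"
        )
    na = int(a.bits.sum())
    nb = int(b.bits.sum())
    if na == 0 and nb == 0:
        return 1.0
    common = int(np.count_nonzero(a.bits & b.bits))
    if coeff is SimilarityCoefficient.TANIMOTO:
        union = na + nb - common
        return common / union
    if coeff is SimilarityCoefficient.DICE:
        return 2.0 * common / (na + nb)
    if coeff is SimilarityCoefficient.COSINE:
        if na == 0 or nb == 0:
            return 0.0
        return common / math.sqrt(na * nb)
    raise ValueError(f"unhandled coefficient {coeff}")  # pragma: no cover


# ---------------------------------------------------------------------------
# distance model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceModel:
    """Target (and optional decoy) fingerprints plus the coefficient in use.

    Without decoys the distance of a molecule is ``1 - similarity`` to the
    target.  With decoys, only the closest decoy counts and its distance is
    averaged with the target distance:  ``(d_T + min_k d_decoy_k) / 2``.
    """

    target_fp: Fingerprint
    decoy_fps: tuple[Fingerprint, ...] = ()
    coeff: SimilarityCoefficient = SimilarityCoefficient.TANIMOTO

    def __post_init__(self) -> None:
        for fp in self.decoy_fps:
            if fp.kind is not self.target_fp.kind:
                raise ValueError("all fingerprints in a DistanceModel must share a kind")

    @property
    def kind(self) -> FingerprintKind:
        return self.target_fp.kind

    @classmethod
    def from_molecules(
        cls,
        target: MoleculeRecord,
        decoys: Sequence[MoleculeRecord] = (),
        kind: FingerprintKind = FingerprintKind.MORGAN,
        coeff: SimilarityCoefficient = SimilarityCoefficient.TANIMOTO,
    ) -> "DistanceModel":
        return cls(
            target_fp=fingerprint(target, kind),
            decoy_fps=tuple(fingerprint(d, kind) for d in decoys),
            coeff=coeff,
        )

    def distance_of_fp(self, fp: Fingerprint) -> float:
        d_target = 1.0 - similarity(fp, self.target_fp, self.coeff)
        if not self.decoy_fps:
            return d_target
        d_decoy = min(1.0 - similarity(fp, d, self.coeff) for d in self.decoy_fps)
        return 0.5 * (d_target + d_decoy)

    def __call__(self, mol: "MoleculeRecord | Fingerprint") -> float:
        if isinstance(mol, Fingerprint):
            return self.distance_of_fp(mol)
        return self.distance_of_fp(fingerprint(mol, self.kind))


def distance(mol: "MoleculeRecord | Fingerprint", model: DistanceModel) -> float:
    """Distance of a molecule (or pre-computed fingerprint) under the model."""
    return model(mol)
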