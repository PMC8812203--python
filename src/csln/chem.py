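"""Molecule fingerprints and chemical similarity.

A molecule is represented by its MACCS structural keys: a binary vector
of length 167 where position 0 is an unused placeholder and positions
1-166 flag the presence of a fixed dictionary of substructural features.
Similarity between two molecules is the Tanimoto coefficient over the
set bits, the standard ligand-based similarity measure.

RDKit is required only for :func:`fingerprint_from_smiles` /
:func:`fingerprints_from_sdf`; everything else operates on plain bit
vectors, so precomputed fingerprints can be used without a chemistry
toolkit installed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ParseError

FP_LENGTH = 167  # MACCS keys: placeholder bit 0 plus 166 feature bits

__all__ = [
    "FP_LENGTH",
    "Fingerprint",
    "fingerprint_from_smiles",
    "fingerprints_from_sdf",
    "tanimoto",
    "bulk_tanimoto",
]


@dataclass(frozen=True)
class Fingerprint:
    """A 167-position binary MACCS-keys vector with its molecule id.

    Invariants (enforced at construction): length exactly 167, every
    entry 0/1, and position 0 equal to 0.
    """

    bits: np.ndarray
    molecule_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits, dtype=np.uint8)
        if arr.ndim != 1 or arr.shape[0] != FP_LENGTH:
            raise DataError(
                f"fingerprint for {self.molecule_id!r} has length "
                f"{arr.size}, expected {FP_LENGTH}"
            )
        orig = np.asarray(self.bits)
        if not ((orig == 0) | (orig == 1)).all():
            raise DataError(
                f"fingerprint for {self.molecule_id!r} contains entries "
                "other than 0/1"
            )
        if arr[0] != 0:
            raise DataError(
                f"fingerprint for {self.molecule_id!r} has position 0 set; "
                "bit 0 is a placeholder and must be 0"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "bits", arr)

    @property
    def n_set(self) -> int:
        return int(self.bits.sum())

    def on_bits(self) -> list[int]:
        """Indices of set bits, ascending."""
        return np.flatnonzero(self.bits).tolist()


def _require_rdkit():
    try:
        from rdkit import Chem
        from rdkit.Chem import MACCSkeys
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "RDKit is required to compute fingerprints from structures; "
            "install the 'chem' extra or supply precomputed fingerprints"
        ) from exc
    return Chem, MACCSkeys


def fingerprint_from_smiles(
    smiles: str, molecule_id: str = "", *, line: int | None = None
) -> Fingerprint:
    """Compute the MACCS-keys fingerprint of a molecule given as SMILES.

    The result depends only on the molecule, not on the particular
    SMILES spelling ("CCO" and "OCC" give identical vectors).

    Parameters
    ----------
    smiles:
        A SMILES string.
    molecule_id:
        Identifier stored on the returned fingerprint.
    line:
        Optional 1-based source line number, included in parse errors
        when the SMILES came from a file.
    """
    Chem, MACCSkeys = _require_rdkit()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        where = f" (line {line})" if line is not None else ""
        raise ParseError(f"unparseable SMILES {smiles!r}{where}")
    fp = MACCSkeys.GenMACCSKeys(mol)
    bits = np.zeros(FP_LENGTH, dtype=np.uint8)
    bits[list(fp.GetOnBits())] = 1
    return Fingerprint(bits=bits, molecule_id=molecule_id or smiles)


def fingerprints_from_sdf(path) -> dict[str, Fingerprint]:
    """Read an SDF (V2000) file and fingerprint every record.

    Molecule ids are taken from the record title line; records with an
    empty title get a positional id ``mol<i>``.
    """
    Chem, MACCSkeys = _require_rdkit()
    out: dict[str, Fingerprint] = {}
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ParseError(f"unparseable SDF record #{i + 1} in {path}")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        name = name.strip() or f"mol{i}"
        if name in out:
            raise DataError(f"duplicate molecule id {name!r} in {path}")
        fp = MACCSkeys.GenMACCSKeys(mol)
        bits = np.zeros(FP_LENGTH, dtype=np.uint8)
        bits[list(fp.GetOnBits())] = 1
        out[name] = Fingerprint(bits=bits, molecule_id=name)
    return out


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| over the set bits.

    Symmetric, in [0, 1]; equals 1 iff both bit sets are equal and
    nonempty. Two all-zero vectors score 0.0 by convention — a
    featureless vector should not match anything.
    """
    inter = int(np.bitwise_and(a.bits, b.bits).sum())
    union = int(np.bitwise_or(a.bits, b.bits).sum())
    if union == 0:
        return 0.0
    return inter / union


def bulk_tanimoto(matrix: np.ndarray, other: np.ndarray | None = None) -> np.ndarray:
    """Pairwise Tanimoto between rows of binary matrices.

    ``matrix`` is (n, 167); ``other`` defaults to ``matrix``. Returns the
    (n, m) similarity matrix. Rows whose union is empty score 0.
    """
    a = np.asarray(matrix, dtype=np.int64)
    b = a if other is None else np.asarray(other, dtype=np.int64)
    inter = a @ b.T
    union = a.sum(axis=1)[:, None] + b.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return sim
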