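"""Per-structure descriptor vectors and the pruned descriptor matrix.

Each standardized structure is featurized as the concatenation of

* the full RDKit catalog of 1D/2D molecular descriptors (constitutional
  counts, topological indices, charge/electronegativity surrogates,
  fragment counts; ~210 real-valued features), and
* an 881-bit substructure-key fingerprint: the first block encodes
  hierarchic element/ring count keys in the spirit of the PubChem CACTVS
  key set, the remainder is an RDKit pattern fingerprint folded to fill
  the 881 positions.  Bit-exact parity with any external fingerprint
  engine is a non-goal; what matters downstream is a rich, deterministic
  feature space computed on the canonical structure.

Features that cannot be evaluated for a molecule are masked invalid
(never silently zeroed); matrix assembly drops columns whose invalid
fraction exceeds a threshold and median-imputes the scattered rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .structure_io import StandardizedStructure

__all__ = [
    "ElementCounts",
    "DescriptorVector",
    "DescriptorMatrix",
    "FINGERPRINT_BITS",
    "compute_simple_counts",
    "compute_descriptor_vector",
    "assemble_and_prune",
    "feature_names",
]

FINGERPRINT_BITS = 881

# Hierarchic count keys: (element or ring marker, threshold); a bit is set
# when the molecule contains at least `threshold` occurrences.
_COUNT_KEYS: list[tuple[str, int]] = [
    (el, t)
    for el, thresholds in [
        ("H", (1, 2, 4, 8, 16, 32)),
        ("C", (1, 2, 4, 8, 16, 32)),
        ("N", (1, 2, 4, 8)),
        ("O", (1, 2, 4, 8, 16)),
        ("F", (1, 2, 4, 8, 16, 32)),
        ("P", (1, 2, 4)),
        ("S", (1, 2, 4)),
        ("Cl", (1, 2, 4)),
        ("Br", (1, 2)),
        ("I", (1, 2)),
        ("ring", (1, 2, 3, 4)),
        ("aromatic_ring", (1, 2, 3)),
    ]
    for t in thresholds
]
_PATTERN_BITS = FINGERPRINT_BITS - len(_COUNT_KEYS)


@dataclass(frozen=True)
class ElementCounts:
    """Simple atom counts (H includes implicit hydrogens)."""

    C: int
    H: int
    O: int
    N: int
    P: int
    S: int
    F: int
    aromatic_atom_count: int


@dataclass
class DescriptorVector:
    """One structure's features plus a per-feature validity mask."""

    canonical_smiles: str
    values: np.ndarray        # float, len == len(feature_names())
    valid: np.ndarray         # bool, same length


@dataclass
class DescriptorMatrix:
    """Structures x retained features, pruned and imputed.

    ``frame`` is indexed by canonical SMILES; ``raw_feature_count`` and
    ``retained_feature_count`` record the dimensionality before/after
    pruning.
    """

    frame: pd.DataFrame
    raw_feature_count: int
    retained_feature_count: int
    invalid_fraction_threshold: float

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index_label="canonical_smiles")

    def write_manifest(self, path: str | Path) -> None:
        lines = [
            f"# raw features: {self.raw_feature_count}",
            f"# retained features: {self.retained_feature_count}",
            f"# invalid_fraction_threshold: {self.invalid_fraction_threshold}",
            *self.frame.columns,
        ]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _as_mol(structure: StandardizedStructure | Chem.Mol | str) -> Chem.Mol:
    if isinstance(structure, StandardizedStructure):
        return structure.mol()
    if isinstance(structure, str):
        mol = Chem.MolFromSmiles(structure)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {structure}")
        return mol
    return structure


def compute_simple_counts(structure: StandardizedStructure | Chem.Mol | str) -> ElementCounts:
    """Element and aromatic-atom counts used by the classification rules."""
    mol = _as_mol(structure)
    counts = {s: 0 for s in ("C", "O", "N", "P", "S", "F")}
    hydrogens = 0
    aromatic = 0
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym in counts:
            counts[sym] += 1
        if sym == "H":
            hydrogens += 1
        hydrogens += atom.GetTotalNumHs()
        if atom.GetIsAromatic():
            aromatic += 1
    return ElementCounts(
        C=counts["C"], H=hydrogens, O=counts["O"], N=counts["N"],
        P=counts["P"], S=counts["S"], F=counts["F"],
        aromatic_atom_count=aromatic,
    )


_DESCRIPTOR_NAMES: list[str] = [name for name, _ in Descriptors.descList]


def feature_names() -> list[str]:
    """Fixed feature ordering: RDKit descriptors, then fingerprint bits."""
    return _DESCRIPTOR_NAMES + [f"FP{i:03d}" for i in range(FINGERPRINT_BITS)]


def _fingerprint(mol: Chem.Mol) -> np.ndarray:
    bits = np.zeros(FINGERPRINT_BITS, dtype=float)
    ri = mol.GetRingInfo()
    tallies = {
        "H": sum(a.GetTotalNumHs() for a in mol.GetAtoms()),
        "ring": ri.NumRings(),
        "aromatic_ring": sum(
            1
            for ring in ri.BondRings()
            if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring)
        ),
    }
    for atom in mol.GetAtoms():
        tallies[atom.GetSymbol()] = tallies.get(atom.GetSymbol(), 0) + 1
    for i, (key, threshold) in enumerate(_COUNT_KEYS):
        if tallies.get(key, 0) >= threshold:
            bits[i] = 1.0
    patt = Chem.PatternFingerprint(mol, fpSize=_PATTERN_BITS)
    for b in patt.GetOnBits():
        bits[len(_COUNT_KEYS) + b] = 1.0
    return bits


def compute_descriptor_vector(
    structure: StandardizedStructure | Chem.Mol | str,
) -> DescriptorVector:
    """Deterministic descriptor + fingerprint vector for one structure.

    Individual descriptor failures (exceptions, NaN, inf) are masked
    invalid rather than aborting the molecule.
    """
    mol = _as_mol(structure)
    smiles = Chem.MolToSmiles(mol)
    values = np.empty(len(_DESCRIPTOR_NAMES) + FINGERPRINT_BITS, dtype=float)
    valid = np.ones_like(values, dtype=bool)
    for i, (name, fn) in enumerate(Descriptors.descList):
        try:
            v = float(fn(mol))
        except Exception:
            v = math.nan
        if math.isnan(v) or math.isinf(v):
            values[i] = math.nan
            valid[i] = False
        else:
            values[i] = v
    values[len(_DESCRIPTOR_NAMES):] = _fingerprint(mol)
    return DescriptorVector(canonical_smiles=smiles, values=values, valid=valid)


def tanimoto(a: DescriptorVector, b: DescriptorVector) -> float:
    """Tanimoto similarity over the fingerprint block of two vectors."""
    fa = a.values[len(_DESCRIPTOR_NAMES):].astype(bool)
    fb = b.values[len(_DESCRIPTOR_NAMES):].astype(bool)
    union = np.logical_or(fa, fb).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(fa, fb).sum() / union)


def assemble_and_prune(
    vectors: Sequence[DescriptorVector],
    invalid_fraction_threshold: float = 0.1,
) -> DescriptorMatrix:
    """Stack vectors, drop unreliable columns, impute the stragglers.

    A column is dropped when its fraction of invalid entries exceeds the
    threshold; surviving invalid entries are replaced by the column
    median.  Raises ``ValueError('empty_matrix')`` if nothing survives.
    """
    if not vectors:
        raise ValueError("empty_matrix")
    names = feature_names()
    data = np.vstack([v.values for v in vectors])
    valid = np.vstack([v.valid for v in vectors])
    invalid_fraction = 1.0 - valid.mean(axis=0)
    keep = invalid_fraction <= invalid_fraction_threshold
    if not keep.any():
        raise ValueError("empty_matrix")
    data = data[:, keep]
    valid = valid[:, keep]
    kept_names = [n for n, k in zip(names, keep) if k]
    # median imputation over the valid entries of each retained column
    for j in range(data.shape[1]):
        col_invalid = ~valid[:, j]
        if col_invalid.any():
            data[col_invalid, j] = float(np.median(data[valid[:, j], j]))
    frame = pd.DataFrame(
        data, index=[v.canonical_smiles for v in vectors], columns=kept_names
    )
    frame.index.name = "canonical_smiles"
    return DescriptorMatrix(
        frame=frame,
        raw_feature_count=len(names),
        retained_feature_count=len(kept_names),
        invalid_fraction_threshold=invalid_fraction_threshold,
    )
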