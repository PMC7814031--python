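"""SMILES ingestion and standardization.

One chemical structure can carry many valid SMILES depending on the
software that wrote them (PubChem, EPA CompTox and RDKit all emit
different canonical strings for perfluorooctanesulfonic acid, for
example).  Everything downstream of this module — classification,
descriptors, deduplication — therefore runs on a single declared
dialect: the RDKit canonical SMILES of the standardized molecule.

Standardization applies, in order:

1. salt stripping — keep the largest fragment (most heavy atoms; ties
   broken by molecular weight, then by lexicographically smallest
   canonical SMILES);
2. isotope removal — all isotope labels cleared;
3. charge neutralization — anionic O/N/S protonated and protonated
   amines deprotonated; permanent charges (quaternary N, etc.) are
   kept and flagged rather than mangled;
4. RDKit canonicalization.

Unparseable SMILES are collected as :class:`Rejection` records, never
raised, so a bad row cannot abort a batch.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem.Descriptors import MolWt

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "RawRecord",
    "Rejection",
    "StandardizedStructure",
    "parse_record",
    "standardize",
    "standardize_batch",
    "deduplicate",
    "read_smiles_file",
    "write_structures_csv",
    "write_rejects_csv",
]


@dataclass(frozen=True)
class RawRecord:
    """A SMILES string exactly as supplied, with an opaque identifier."""

    id: str
    smiles: str


@dataclass(frozen=True)
class Rejection:
    """An input that could not be processed; ``reason`` is machine-readable."""

    id: str
    smiles: str
    reason: str


@dataclass
class StandardizedStructure:
    """A salt-stripped, isotope-free, neutralized, canonicalized molecule.

    ``canonical_smiles`` is idempotent under :func:`standardize`:
    re-standardizing it returns the identical string.
    """

    canonical_smiles: str
    source_ids: list[str] = field(default_factory=list)
    salt_stripped: bool = False
    isotopes_removed: bool = False
    neutralized: bool = False
    uncorrectable_charge: bool = False

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.canonical_smiles)
        if m is None:  # pragma: no cover - guarded by construction
            raise ValueError(f"stored SMILES no longer parses: {self.canonical_smiles}")
        return m


def parse_record(raw: RawRecord) -> Chem.Mol | Rejection:
    """Parse a raw SMILES, returning the molecule or an ``invalid_smiles`` rejection."""
    if not raw.smiles or not raw.smiles.strip():
        return Rejection(raw.id, raw.smiles, "invalid_smiles")
    mol = Chem.MolFromSmiles(raw.smiles)
    if mol is None:
        return Rejection(raw.id, raw.smiles, "invalid_smiles")
    return mol


def _largest_fragment(mol: Chem.Mol) -> tuple[Chem.Mol, bool]:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return mol, False
    # most heavy atoms, then higher MW, then smallest canonical SMILES
    best = max(
        frags,
        key=lambda f: (f.GetNumHeavyAtoms(), MolWt(f), _neg_lex(Chem.MolToSmiles(f))),
    )
    return best, True


class _neg_lex(str):
    """Inverts lexicographic comparison so max() picks the smallest string."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)


def _remove_isotopes(mol: Chem.Mol) -> tuple[Chem.Mol, bool]:
    changed = False
    for atom in mol.GetAtoms():
        if atom.GetIsotope():
            atom.SetIsotope(0)
            changed = True
    return mol, changed


# Neutralizable sites: anionic O/N/S gain a proton; protonated amines
# (positively charged N that still carries H) lose one.  Carbanions and
# permanent cations such as quaternary ammonium are left alone.
_NEG_PATTERN = Chem.MolFromSmarts("[O-,S-,N-;!$([N-]=*);!$([O-]N=O)]")
_POS_PATTERN = Chem.MolFromSmarts("[N+;H1,H2,H3,H4;!$([N+]=*)]")


def _neutralize(mol: Chem.Mol) -> tuple[Chem.Mol, bool, bool]:
    """Return (mol, changed, uncorrectable_charge_remains)."""
    mol = Chem.RWMol(mol)
    changed = False
    for atom in mol.GetAtoms():
        chg = atom.GetFormalCharge()
        if chg < 0 and atom.GetSymbol() in ("O", "N", "S"):
            atom.SetFormalCharge(chg + 1)
            atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
            atom.SetNoImplicit(False)
            changed = True
        elif chg > 0 and atom.GetSymbol() == "N" and atom.GetTotalNumHs() > 0:
            atom.SetFormalCharge(chg - 1)
            atom.SetNumExplicitHs(max(atom.GetTotalNumHs() - 1, 0))
            changed = True
    out = mol.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        # revert: leave the charge as supplied rather than emit a broken graph
        return Chem.MolFromSmiles(Chem.MolToSmiles(mol, canonical=False)) or out, False, True
    residual = Chem.GetFormalCharge(out) != 0
    return out, changed, residual


def standardize(raw: RawRecord) -> StandardizedStructure | Rejection:
    """Standardize one record into the project's canonical dialect."""
    mol = parse_record(raw)
    if isinstance(mol, Rejection):
        return mol
    mol, salt_stripped = _largest_fragment(mol)
    mol, isotopes_removed = _remove_isotopes(mol)
    mol, neutralized, residual = _neutralize(mol)
    smiles = Chem.MolToSmiles(mol)
    return StandardizedStructure(
        canonical_smiles=smiles,
        source_ids=[raw.id],
        salt_stripped=salt_stripped,
        isotopes_removed=isotopes_removed,
        neutralized=neutralized,
        uncorrectable_charge=residual,
    )


def standardize_batch(
    records: Iterable[RawRecord],
) -> tuple[list[StandardizedStructure], list[Rejection]]:
    """Standardize many records; rejects are returned, never raised."""
    structures: list[StandardizedStructure] = []
    rejects: list[Rejection] = []
    for raw in records:
        out = standardize(raw)
        if isinstance(out, Rejection):
            rejects.append(out)
        else:
            structures.append(out)
    return structures, rejects


def deduplicate(structures: Sequence[StandardizedStructure]) -> list[StandardizedStructure]:
    """Collapse structures sharing one canonical SMILES, merging source ids.

    First-occurrence input order is preserved; provenance flags are OR-ed
    so a merged entry records every transformation any variant required.
    """
    by_smiles: dict[str, StandardizedStructure] = {}
    for s in structures:
        hit = by_smiles.get(s.canonical_smiles)
        if hit is None:
            by_smiles[s.canonical_smiles] = StandardizedStructure(
                canonical_smiles=s.canonical_smiles,
                source_ids=list(s.source_ids),
                salt_stripped=s.salt_stripped,
                isotopes_removed=s.isotopes_removed,
                neutralized=s.neutralized,
                uncorrectable_charge=s.uncorrectable_charge,
            )
        else:
            hit.source_ids.extend(s.source_ids)
            hit.salt_stripped |= s.salt_stripped
            hit.isotopes_removed |= s.isotopes_removed
            hit.neutralized |= s.neutralized
            hit.uncorrectable_charge |= s.uncorrectable_charge
    return list(by_smiles.values())


def read_smiles_file(path: str | Path) -> list[RawRecord]:
    """Read a .smi file (SMILES [id] per line) or CSV with id,smiles columns."""
    path = Path(path)
    records: list[RawRecord] = []
    if path.suffix.lower() == ".csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"id", "smiles"} <= set(reader.fieldnames):
                raise ValueError(f"{path}: CSV must have 'id' and 'smiles' columns")
            for row in reader:
                records.append(RawRecord(id=row["id"], smiles=row["smiles"]))
    else:
        with path.open(encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                smiles = parts[0]
                ident = parts[1].strip() if len(parts) > 1 else f"{path.stem}-{i + 1}"
                records.append(RawRecord(id=ident, smiles=smiles))
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"{path}: duplicate record id {r.id!r}")
        seen.add(r.id)
    return records


def write_structures_csv(structures: Sequence[StandardizedStructure], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "canonical_smiles", "salt_stripped", "isotopes_removed", "neutralized"])
        for s in structures:
            writer.writerow(
                [";".join(s.source_ids), s.canonical_smiles,
                 s.salt_stripped, s.isotopes_removed, s.neutralized]
            )


def write_rejects_csv(rejects: Sequence[Rejection], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "reason"])
        for r in rejects:
            writer.writerow([r.id, r.smiles, r.reason])
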