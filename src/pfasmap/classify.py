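"""Rule-cascade classification of PFAS structures.

A per-/polyfluoroalkyl substance (PFAS) is a molecule carrying at least one
fully fluorinated carbon (a terminal -CF3 or a chain -CF2-).  Classification
proceeds through a fixed cascade:

1. definition filter — molecules without a -CF3/-CF2- group are either
   *PFAS derivatives* (fluorine replaced by Cl/Br on an otherwise
   perfluorinated carbon, fluorinated C=C / C=O carbons, fluorinated
   aromatic carbons) or *not PFAS*;
2. silicon filter — Si-containing PFASs form their own category because
   no published rule subdivides them further;
3. side-chain aromatic filter — aromatic molecules whose fluorinated
   content sits on an aliphatic side chain (OECD category);
4. ring opening — cyclic aliphatic PFASs are transformed to acyclic
   ones by breaking each carbocyclic ring and capping the two carbons of
   the broken bond with fluorine;
5. core module — ordered class/subclass pattern table (Buck/OECD rules)
   applied to the acyclic aliphatic structure.

The core rule order lives in ``data/rules.yaml`` so catalog updates from
the literature can be applied without code changes.  The cascade is a
total function: every parseable molecule receives exactly one result.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import yaml
from rdkit import Chem

from .structure_io import StandardizedStructure

__all__ = [
    "ClassificationResult",
    "Rule",
    "RuleSet",
    "load_ruleset",
    "contains_perfluorinated_carbon",
    "classify_derivative",
    "contains_silicon",
    "is_side_chain_fluorinated_aromatic",
    "open_rings",
    "perfluoro_chain_length",
    "classify_core",
    "classify",
    "classify_batch",
    "write_classification_csv",
]

CATEGORY_NOT_PFAS = "not_pfas"
CATEGORY_DERIVATIVE = "pfas_derivative"
CATEGORY_SILICON = "silicon_pfas"
CATEGORY_SIDE_CHAIN_AROMATIC = "side_chain_fluorinated_aromatic"
CATEGORY_ALIPHATIC = "aliphatic_pfas"

CLASS_DERIVATIVES = "PFAS_derivatives"
CLASS_UNCLASSIFIED = "unclassified_aliphatic"


@dataclass(frozen=True)
class ClassificationResult:
    """Category/class/subclass assignment with chain-length metadata.

    ``perfluoro_chain_length_n`` is the number of carbons in the longest
    contiguous run of fully fluorinated sp3 carbons (CF2/CF3); for a linear
    CnF2n+1 chain this is exactly n.  ``alkyl_spacer_m`` is the size of the
    largest plain N-alkyl group on a sulfonamide nitrogen (0 elsewhere).
    """

    category: str
    class_label: str = ""
    subclass_label: str = ""
    perfluoro_chain_length_n: int = 0
    alkyl_spacer_m: int = 0
    ring_opened: bool = False
    rings_opened: int = 0
    ring_opening_failed: bool = False


# ---------------------------------------------------------------------------
# module 1: PFAS definition + derivatives
# ---------------------------------------------------------------------------

def _is_cf3(atom: Chem.Atom) -> bool:
    if atom.GetSymbol() != "C" or atom.GetTotalNumHs() != 0:
        return False
    if any(b.GetBondType() != Chem.BondType.SINGLE for b in atom.GetBonds()):
        return False
    # >= 3 so tetrafluoromethane's carbon still counts as carrying a CF3
    return sum(1 for nb in atom.GetNeighbors() if nb.GetSymbol() == "F") >= 3


def _is_chain_cf2(atom: Chem.Atom) -> bool:
    # fully fluorinated chain carbon: sp3, H-free, exactly two F, the
    # remaining two bonds to carbon (the definitional -CF2- unit)
    if atom.GetSymbol() != "C" or atom.GetTotalNumHs() != 0:
        return False
    if any(b.GetBondType() != Chem.BondType.SINGLE for b in atom.GetBonds()):
        return False
    symbols = [nb.GetSymbol() for nb in atom.GetNeighbors()]
    return symbols.count("F") == 2 and symbols.count("C") == 2


def contains_perfluorinated_carbon(mol: Chem.Mol) -> bool:
    """True iff the molecule carries a terminal -CF3 or a chain -CF2- group."""
    return any(_is_cf3(a) or _is_chain_cf2(a) for a in mol.GetAtoms())


_DERIV_UNSATURATED = (
    Chem.MolFromSmarts("[F][CX3]=[CX3]"),
    Chem.MolFromSmarts("[F][CX3]=[OX1]"),
)
_DERIV_AROMATIC = Chem.MolFromSmarts("[F][c]")


def _has_halogen_substituted_perfluoro_carbon(mol: Chem.Mol) -> bool:
    # a would-be CF3/CF2 carbon in which some F is replaced by Cl or Br
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "C" or atom.GetTotalNumHs() != 0:
            continue
        if any(b.GetBondType() != Chem.BondType.SINGLE for b in atom.GetBonds()):
            continue
        symbols = [nb.GetSymbol() for nb in atom.GetNeighbors()]
        n_f = symbols.count("F")
        n_x = symbols.count("Cl") + symbols.count("Br")
        n_c = symbols.count("C")
        if n_f >= 1 and n_x >= 1 and n_f + n_x + n_c == len(symbols):
            return True
    return False


def classify_derivative(mol: Chem.Mol) -> ClassificationResult:
    """Subclassify a molecule that failed the -CF3/-CF2- definition test."""
    if _has_halogen_substituted_perfluoro_carbon(mol):
        sub = "halogen_substituted"
    elif any(mol.HasSubstructMatch(p) for p in _DERIV_UNSATURATED):
        sub = "fluorinated_unsaturated_carbon"
    elif mol.HasSubstructMatch(_DERIV_AROMATIC):
        sub = "fluorinated_aromatic_carbon"
    else:
        return ClassificationResult(category=CATEGORY_NOT_PFAS)
    return ClassificationResult(
        category=CATEGORY_DERIVATIVE,
        class_label=CLASS_DERIVATIVES,
        subclass_label=sub,
        perfluoro_chain_length_n=0,
    )


# ---------------------------------------------------------------------------
# modules 2-3: silicon + side-chain aromatics
# ---------------------------------------------------------------------------

def contains_silicon(mol: Chem.Mol) -> bool:
    return any(a.GetSymbol() == "Si" for a in mol.GetAtoms())


def is_side_chain_fluorinated_aromatic(mol: Chem.Mol) -> bool:
    """Aromatic ring plus an aliphatic CF3/CF2 side chain (OECD category).

    Callers reach this test only after the definition filter, so the
    presence of any aromatic atom is the discriminating condition.
    """
    return any(a.GetIsAromatic() for a in mol.GetAtoms()) and contains_perfluorinated_carbon(mol)


# ---------------------------------------------------------------------------
# module 4: ring opening
# ---------------------------------------------------------------------------

_ACID_ANCHORS = (
    Chem.MolFromSmarts("[SX4](=O)(=O)[OX2H1]"),
    Chem.MolFromSmarts("[CX3](=O)[OX2H1]"),
    Chem.MolFromSmarts("[PX4](=O)[OX2H1]"),
)


def _ring_atom_priority(mol: Chem.Mol, idx: int, ring: set[int], acid_atoms: set[int]) -> int:
    atom = mol.GetAtomWithIdx(idx)
    exo = [nb for nb in atom.GetNeighbors() if nb.GetIdx() not in ring]
    if any(nb.GetIdx() in acid_atoms for nb in exo):
        return 3
    if any(nb.GetSymbol() not in ("F", "C") for nb in exo):
        return 2
    if exo and all(nb.GetSymbol() == "F" for nb in exo):
        return 1
    return 0


def open_rings(mol: Chem.Mol) -> tuple[Chem.Mol, int, bool]:
    """Open every carbocycle; returns (molecule, rings_opened, failed).

    Each opening deletes one ring C-C bond and adds one fluorine to each
    of the two carbons of the broken bond, so the carbon count is
    preserved and the fluorine count grows by exactly two per ring.  The
    bond broken is the one incident to the ring carbon bearing the
    highest-priority exocyclic substituent (acid group > heteroatom >
    F-only > H-only), which places that substituent at a chain terminus.
    Rings containing non-carbon atoms are left intact and flagged.
    """
    mol = Chem.Mol(mol)
    opened = 0
    failed = False
    while True:
        ri = mol.GetRingInfo()
        if ri.NumRings() == 0:
            break
        carbo = [
            ring
            for ring in ri.AtomRings()
            if all(
                mol.GetAtomWithIdx(i).GetSymbol() == "C"
                and not mol.GetAtomWithIdx(i).GetIsAromatic()
                for i in ring
            )
        ]
        if not carbo:
            failed = True
            break
        acid_atoms: set[int] = set()
        for patt in _ACID_ANCHORS:
            for match in mol.GetSubstructMatches(patt):
                acid_atoms.add(match[0])
        ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
        ring = set(min(carbo, key=lambda r: tuple(sorted(ranks[i] for i in r))))
        anchor = max(ring, key=lambda i: (_ring_atom_priority(mol, i, ring, acid_atoms), ranks[i]))
        ring_neighbors = [
            nb.GetIdx()
            for nb in mol.GetAtomWithIdx(anchor).GetNeighbors()
            if nb.GetIdx() in ring
            and mol.GetBondBetweenAtoms(anchor, nb.GetIdx()).IsInRing()
        ]
        partner = min(
            ring_neighbors,
            key=lambda i: (_ring_atom_priority(mol, i, ring, acid_atoms), ranks[i]),
        )
        rw = Chem.RWMol(mol)
        rw.RemoveBond(anchor, partner)
        for idx in (anchor, partner):
            f = rw.AddAtom(Chem.Atom("F"))
            rw.AddBond(idx, f, Chem.BondType.SINGLE)
        candidate = rw.GetMol()
        try:
            Chem.SanitizeMol(candidate)
        except Exception:
            failed = True
            break
        mol = candidate
        opened += 1
    return mol, opened, failed


# ---------------------------------------------------------------------------
# perfluoroalkyl chain length
# ---------------------------------------------------------------------------

def _qualifying_chain_carbon(atom: Chem.Atom) -> bool:
    if atom.GetSymbol() != "C" or atom.GetTotalNumHs() != 0:
        return False
    if any(b.GetBondType() != Chem.BondType.SINGLE for b in atom.GetBonds()):
        return False
    n_f = sum(1 for nb in atom.GetNeighbors() if nb.GetSymbol() == "F")
    return n_f in (2, 3, 4)


def perfluoro_chain_length(mol: Chem.Mol) -> int:
    """Length of the longest contiguous run of fully fluorinated carbons.

    Computed as the longest simple path through the subgraph of CF2/CF3
    carbons connected by C-C bonds; for a linear CnF2n+1 perfluoroalkyl
    chain this is exactly n.  Returns 0 when no such carbon exists.
    """
    qual = [a.GetIdx() for a in mol.GetAtoms() if _qualifying_chain_carbon(a)]
    if not qual:
        return 0
    qual_set = set(qual)
    adj: dict[int, list[int]] = {i: [] for i in qual}
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if a in qual_set and b in qual_set:
            adj[a].append(b)
            adj[b].append(a)

    best = 1

    def dfs(node: int, seen: set[int], depth: int) -> None:
        nonlocal best
        best = max(best, depth)
        for nxt in adj[node]:
            if nxt not in seen:
                seen.add(nxt)
                dfs(nxt, seen, depth + 1)
                seen.remove(nxt)

    for start in qual:
        dfs(start, {start}, 1)
    return best


# ---------------------------------------------------------------------------
# core module: ordered class/subclass rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rule:
    subclass: str
    class_label: str
    kind: str                      # smarts | sulfonamide | composition
    patterns: tuple[Chem.Mol, ...] = ()
    head: str = ""
    check: str = ""

    def matches(self, mol: Chem.Mol) -> bool:
        if self.kind == "smarts":
            return all(mol.HasSubstructMatch(p) for p in self.patterns)
        if self.kind == "sulfonamide":
            return _sulfonamide_head(mol)[0] == self.head
        if self.kind == "composition":
            return _COMPOSITION_CHECKS[self.check](mol)
        raise ValueError(f"unknown rule kind {self.kind!r}")  # pragma: no cover


@dataclass(frozen=True)
class RuleSet:
    rules: tuple[Rule, ...]

    def subclasses(self) -> list[str]:
        return [r.subclass for r in self.rules]


def load_ruleset(path: str | Path | None = None) -> RuleSet:
    """Load the ordered subclass table (default: the packaged rules.yaml)."""
    if path is None:
        text = resources.files("pfasmap.data").joinpath("rules.yaml").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    raw = yaml.safe_load(text)
    rules: list[Rule] = []
    seen: set[str] = set()
    for entry in raw["rules"]:
        sub = entry["subclass"]
        if sub in seen:
            raise ValueError(f"subclass {sub!r} appears twice in the rule table")
        seen.add(sub)
        patterns = tuple(
            _compile_smarts(p) for p in entry.get("patterns", [])
        )
        rules.append(
            Rule(
                subclass=sub,
                class_label=entry["class"],
                kind=entry["kind"],
                patterns=patterns,
                head=entry.get("head", ""),
                check=entry.get("check", ""),
            )
        )
    return RuleSet(rules=tuple(rules))


def _compile_smarts(pattern: str) -> Chem.Mol:
    mol = Chem.MolFromSmarts(pattern)
    if mol is None:
        raise ValueError(f"invalid SMARTS in rule table: {pattern}")
    return mol


# --- sulfonamide (FASA) branch walk ----------------------------------------

_SULFONAMIDE_CORE = Chem.MolFromSmarts("[CX4](F)(F)[SX4](=O)(=O)[NX3]")


def _walk_branch(mol: Chem.Mol, nitrogen: int, root: int) -> tuple[str, int]:
    """Follow a linear chain from a sulfonamide N; return (head kind, carbons)."""
    chain = 0
    prev = nitrogen
    cur = mol.GetAtomWithIdx(root)
    while True:
        if cur.GetSymbol() == "C" and cur.GetTotalNumHs() == 3:
            return "alkyl", chain + 1
        if (
            cur.GetSymbol() == "C"
            and cur.GetTotalNumHs() == 2
            and cur.GetDegree() == 2
            and all(b.GetBondType() == Chem.BondType.SINGLE for b in cur.GetBonds())
        ):
            chain += 1
            nxt = [nb for nb in cur.GetNeighbors() if nb.GetIdx() != prev]
            prev = cur.GetIdx()
            cur = nxt[0]
            continue
        break
    if cur.GetSymbol() == "O" and cur.GetTotalNumHs() == 1:
        return "hydroxyl", chain
    if cur.GetSymbol() == "C" and _is_carboxyl(cur):
        return "carboxyl", chain
    if cur.GetSymbol() == "O" and cur.GetTotalNumHs() == 0:
        ester = _ester_head(mol, cur, prev)
        if ester:
            return ester, chain
    return "unknown", chain


def _is_carboxyl(atom: Chem.Atom) -> bool:
    has_oxo = any(
        b.GetBondType() == Chem.BondType.DOUBLE and b.GetOtherAtom(atom).GetSymbol() == "O"
        for b in atom.GetBonds()
    )
    has_oh = any(
        nb.GetSymbol() == "O" and nb.GetTotalNumHs() == 1 for nb in atom.GetNeighbors()
    )
    return has_oxo and has_oh


def _ester_head(mol: Chem.Mol, oxygen: Chem.Atom, prev: int) -> str:
    carbonyls = [
        nb
        for nb in oxygen.GetNeighbors()
        if nb.GetIdx() != prev
        and nb.GetSymbol() == "C"
        and any(
            b.GetBondType() == Chem.BondType.DOUBLE and b.GetOtherAtom(nb).GetSymbol() == "O"
            for b in nb.GetBonds()
        )
    ]
    if not carbonyls:
        return ""
    alpha = [
        nb for nb in carbonyls[0].GetNeighbors() if nb.GetSymbol() == "C"
    ]
    if not alpha:
        return ""
    a = alpha[0]
    vinylic = any(
        b.GetBondType() == Chem.BondType.DOUBLE and b.GetOtherAtom(a).GetSymbol() == "C"
        for b in a.GetBonds()
    )
    if not vinylic:
        return ""
    methyl = any(
        nb.GetSymbol() == "C" and nb.GetTotalNumHs() == 3 for nb in a.GetNeighbors()
    )
    return "methacrylate" if methyl else "acrylate"


_HEAD_PRIORITY = ("methacrylate", "acrylate", "carboxyl", "hydroxyl")


def _sulfonamide_head(mol: Chem.Mol) -> tuple[str, int]:
    """Classify the R1 head of a Rf-SO2N sulfonamide; return (head, m).

    ``head`` is one of methacrylate/acrylate/carboxyl/hydroxyl/none, or ""
    when the molecule has no perfluoroalkane sulfonamide core (or a branch
    the catalog does not recognize).  ``m`` is the largest plain N-alkyl
    size across the nitrogen's branches.
    """
    match = mol.GetSubstructMatch(_SULFONAMIDE_CORE)
    if not match:
        return "", 0
    nitrogen = match[-1]
    sulfur = match[3]
    heads: list[str] = []
    m = 0
    for nb in mol.GetAtomWithIdx(nitrogen).GetNeighbors():
        if nb.GetIdx() == sulfur:
            continue
        head, length = _walk_branch(mol, nitrogen, nb.GetIdx())
        if head == "alkyl":
            m = max(m, length)
        elif head == "unknown":
            return "", 0
        else:
            heads.append(head)
    for head in _HEAD_PRIORITY:
        if head in heads:
            return head, m
    return "none", m


# --- composition checks -----------------------------------------------------

def _element_set(mol: Chem.Mol) -> set[str]:
    return {a.GetSymbol() for a in mol.GetAtoms()}


def _total_hydrogens(mol: Chem.Mol) -> int:
    return sum(a.GetTotalNumHs() for a in mol.GetAtoms())


def _has_cc_double(mol: Chem.Mol) -> bool:
    return any(
        b.GetBondType() == Chem.BondType.DOUBLE
        and b.GetBeginAtom().GetSymbol() == "C"
        and b.GetEndAtom().GetSymbol() == "C"
        for b in mol.GetBonds()
    )


def _check_perfluoroalkane(mol: Chem.Mol) -> bool:
    return (
        _element_set(mol) <= {"C", "F"}
        and _total_hydrogens(mol) == 0
        and all(b.GetBondType() == Chem.BondType.SINGLE for b in mol.GetBonds())
    )


def _check_perfluoroalkene(mol: Chem.Mol) -> bool:
    return (
        _element_set(mol) <= {"C", "F"}
        and _total_hydrogens(mol) == 0
        and _has_cc_double(mol)
    )


def _check_perfluoroalcohol(mol: Chem.Mol) -> bool:
    if not _element_set(mol) <= {"C", "F", "O"}:
        return False
    oxygens = [a for a in mol.GetAtoms() if a.GetSymbol() == "O"]
    if not oxygens:
        return False
    if not all(a.GetTotalNumHs() == 1 and a.GetDegree() == 1 for a in oxygens):
        return False
    carbons_h = sum(a.GetTotalNumHs() for a in mol.GetAtoms() if a.GetSymbol() == "C")
    return carbons_h == 0


def _check_perfluoroketone(mol: Chem.Mol) -> bool:
    if not _element_set(mol) <= {"C", "F", "O"} or _total_hydrogens(mol) != 0:
        return False
    oxygens = [a for a in mol.GetAtoms() if a.GetSymbol() == "O"]
    if not oxygens:
        return False
    for o in oxygens:
        if o.GetDegree() != 1:
            return False
        bond = o.GetBonds()[0]
        if bond.GetBondType() != Chem.BondType.DOUBLE:
            return False
        carbonyl = bond.GetOtherAtom(o)
        c_neighbors = [nb for nb in carbonyl.GetNeighbors() if nb.GetSymbol() == "C"]
        if len(c_neighbors) != 2:
            return False
    return True


_COMPOSITION_CHECKS: dict[str, Callable[[Chem.Mol], bool]] = {
    "perfluoroalkane": _check_perfluoroalkane,
    "perfluoroalkene": _check_perfluoroalkene,
    "perfluoroalcohol": _check_perfluoroalcohol,
    "perfluoroketone": _check_perfluoroketone,
}


_DEFAULT_RULESET: RuleSet | None = None


def _default_ruleset() -> RuleSet:
    global _DEFAULT_RULESET
    if _DEFAULT_RULESET is None:
        _DEFAULT_RULESET = load_ruleset()
    return _DEFAULT_RULESET


def classify_core(mol: Chem.Mol, ruleset: RuleSet | None = None) -> tuple[str, str, int, int]:
    """Assign (class, subclass, n, m) to an acyclic aliphatic PFAS.

    The first matching rule in the ordered table wins; molecules matching
    no rule are ``unclassified_aliphatic``.  Total: never raises on a
    sanitized molecule.
    """
    ruleset = ruleset or _default_ruleset()
    n = perfluoro_chain_length(mol)
    for rule in ruleset.rules:
        if rule.matches(mol):
            m = _sulfonamide_head(mol)[1] if rule.kind == "sulfonamide" else 0
            return rule.class_label, rule.subclass, n, m
    return CLASS_UNCLASSIFIED, "", n, 0


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

def classify(
    structure: StandardizedStructure | Chem.Mol | str,
    ruleset: RuleSet | None = None,
) -> ClassificationResult:
    """Run the full classification cascade on a standardized structure."""
    if isinstance(structure, StandardizedStructure):
        mol = structure.mol()
    elif isinstance(structure, str):
        mol = Chem.MolFromSmiles(structure)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {structure}")
    else:
        mol = structure

    if not contains_perfluorinated_carbon(mol):
        return classify_derivative(mol)
    if contains_silicon(mol):
        return ClassificationResult(
            category=CATEGORY_SILICON,
            perfluoro_chain_length_n=perfluoro_chain_length(mol),
        )
    if any(a.GetIsAromatic() for a in mol.GetAtoms()):
        return ClassificationResult(
            category=CATEGORY_SIDE_CHAIN_AROMATIC,
            perfluoro_chain_length_n=perfluoro_chain_length(mol),
        )
    opened_mol, rings_opened, failed = open_rings(mol)
    class_label, subclass, n, m = classify_core(opened_mol, ruleset)
    return ClassificationResult(
        category=CATEGORY_ALIPHATIC,
        class_label=class_label,
        subclass_label=subclass,
        perfluoro_chain_length_n=n,
        alkyl_spacer_m=m,
        ring_opened=rings_opened > 0,
        rings_opened=rings_opened,
        ring_opening_failed=failed,
    )


def classify_batch(
    structures: Sequence[StandardizedStructure],
    ruleset: RuleSet | None = None,
) -> list[ClassificationResult]:
    return [classify(s, ruleset) for s in structures]


def write_classification_csv(
    structures: Sequence[StandardizedStructure],
    results: Sequence[ClassificationResult],
    path: str | Path,
) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["id", "canonical_smiles", "category", "class", "subclass", "n", "m", "ring_opened"]
        )
        for s, r in zip(structures, results):
            writer.writerow(
                [
                    ";".join(s.source_ids),
                    s.canonical_smiles,
                    r.category,
                    r.class_label,
                    r.subclass_label,
                    r.perfluoro_chain_length_n,
                    r.alkyl_spacer_m,
                    r.ring_opened,
                ]
            )
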