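"""Synthetic homologous-series corpora with known ground truth.

Real PFAS inventories (the EPA master list) cannot ship with the
package, so testing and the worked examples run on generated corpora:
homologous CnF2n+1 series for every subclass in the rule catalog,
branched-isomer variants (technical PFAS mixtures contain branched
isomers alongside the linear compound), plus derivative cases, silicon
and side-chain aromatic compounds, carbocyclic PFASs and non-PFAS
decoys.  Each generated structure carries the classification the
generator built it to have, making the generator the independent oracle
for the classifier.

Chain-length bookkeeping: a series is indexed by the homolog number its
subclass is named by (PFOA is the n=8 perfluoroalkyl carboxylic acid),
while the recorded ground-truth ``perfluoro_chain_length_n`` is the
structural quantity the classifier measures — the longest contiguous
CF2/CF3 run.  For subclasses whose naming counts a head-group carbon
(carboxylic/acyl compounds) the two differ by one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from rdkit import Chem

from .classify import (
    CATEGORY_ALIPHATIC,
    CATEGORY_DERIVATIVE,
    CATEGORY_NOT_PFAS,
    CATEGORY_SIDE_CHAIN_AROMATIC,
    CATEGORY_SILICON,
    CLASS_DERIVATIVES,
    ClassificationResult,
)

__all__ = [
    "SeriesSpec",
    "CorpusRecord",
    "SUBCLASS_CATALOG",
    "generate_series",
    "generate_corpus",
    "generate_embedding_benchmark",
    "NAMED_COMPOUNDS",
]


@dataclass(frozen=True)
class CorpusRecord:
    id: str
    smiles: str
    expected: ClassificationResult


@dataclass(frozen=True)
class SeriesSpec:
    """A homologous series: one subclass, a range of homolog numbers.

    ``n_range`` uses the subclass's naming convention; ``m_range`` (where
    applicable) sizes the N-alkyl group of sulfonamide subclasses.
    """

    subclass_label: str
    n_range: Sequence[int]
    m_range: Sequence[int] = (0,)


def _rf(k: int) -> str:
    """Linear perfluoroalkyl tail CkF2k+1 written head-first."""
    return "C(F)(F)" * k + "F"


def _rf_branched(p: int, q: int) -> str:
    """Perfluoroalkyl tail with a CF3 branch: p CF2, CF(CF3), q CF2, CF3."""
    return "C(F)(F)" * p + "C(F)(C(F)(F)F)" + "C(F)(F)" * q + "F"


def _alkyl_amine(m: int) -> str:
    """N-alkyl sulfonamide nitrogen prefix for m = 0, 1, 2, ..."""
    return "N" if m == 0 else "C" * m + "N"


@dataclass(frozen=True)
class _SubclassBuilder:
    class_label: str
    # SMILES from the homolog number n and N-alkyl size m
    build: Callable[[int, int], str]
    # structural chain length of the linear homolog n
    chain_n: Callable[[int], int]
    # rf carbons available for branched variants (None: no branched form)
    rf_of: Callable[[int], int] | None = None
    uses_m: bool = False


def _fasa_n(head: str) -> Callable[[int, int], str]:
    def build(n: int, m: int) -> str:
        amine = _alkyl_amine(m)
        if head:
            return head + amine.replace("N", "N(", 1) + ")S(=O)(=O)" + _rf(n) \
                if m > 0 else head + "NS(=O)(=O)" + _rf(n)
        return amine + "S(=O)(=O)" + _rf(n)
    return build


def _fasa_headed(head: str) -> Callable[[int, int], str]:
    # head examples: "OCC" (sulfonamidoethanol), "OC(=O)C" (acetic acid)
    def build(n: int, m: int) -> str:
        if m > 0:
            return head + "N(" + "C" * m + ")S(=O)(=O)" + _rf(n)
        return head + "NS(=O)(=O)" + _rf(n)
    return build


SUBCLASS_CATALOG: dict[str, _SubclassBuilder] = {
    # perfluoroalkyl acids
    "PFCAs": _SubclassBuilder(
        "PFAAs", lambda n, m: "OC(=O)" + _rf(n - 1), lambda n: n - 1, lambda n: n - 1
    ),
    "PFSAs": _SubclassBuilder(
        "PFAAs", lambda n, m: "OS(=O)(=O)" + _rf(n), lambda n: n, lambda n: n
    ),
    "PFPAs": _SubclassBuilder(
        "PFAAs", lambda n, m: "OP(=O)(O)" + _rf(n), lambda n: n, lambda n: n
    ),
    "PFPiAs": _SubclassBuilder(
        "PFAAs", lambda n, m: "OP(=O)(" + _rf(n) + ")" + _rf(n), lambda n: n
    ),
    "PFECAs": _SubclassBuilder(
        "PFAAs", lambda n, m: "OC(=O)C(F)(F)O" + _rf(n), lambda n: max(n, 1)
    ),
    "PFESAs": _SubclassBuilder(
        "PFAAs", lambda n, m: "OS(=O)(=O)C(F)(F)C(F)(F)O" + _rf(n), lambda n: max(n, 2)
    ),
    # FASA-based PFAA precursors
    "FASAs": _SubclassBuilder(
        "FASA_based_PFAA_precursors", _fasa_n(""), lambda n: n, lambda n: n, uses_m=True
    ),
    "FASEs": _SubclassBuilder(
        "FASA_based_PFAA_precursors", _fasa_headed("OCC"), lambda n: n, uses_m=True
    ),
    "FASAAs": _SubclassBuilder(
        "FASA_based_PFAA_precursors", _fasa_headed("OC(=O)C"), lambda n: n, uses_m=True
    ),
    "FASACs": _SubclassBuilder(
        "FASA_based_PFAA_precursors", _fasa_headed("C=CC(=O)OCC"), lambda n: n, uses_m=True
    ),
    "FASMACs": _SubclassBuilder(
        "FASA_based_PFAA_precursors", _fasa_headed("C=C(C)C(=O)OCC"), lambda n: n, uses_m=True
    ),
    # n:2 fluorotelomer-based PFAA precursors
    "FTOHs": _SubclassBuilder(
        "fluorotelomer_based_PFAA_precursors", lambda n, m: "OCC" + _rf(n),
        lambda n: n, lambda n: n
    ),
    "FTACs": _SubclassBuilder(
        "fluorotelomer_based_PFAA_precursors", lambda n, m: "C=CC(=O)OCC" + _rf(n), lambda n: n
    ),
    "FTMACs": _SubclassBuilder(
        "fluorotelomer_based_PFAA_precursors", lambda n, m: "C=C(C)C(=O)OCC" + _rf(n), lambda n: n
    ),
    "FTIs": _SubclassBuilder(
        "fluorotelomer_based_PFAA_precursors", lambda n, m: "ICC" + _rf(n), lambda n: n
    ),
    "FTOs": _SubclassBuilder(
        "fluorotelomer_based_PFAA_precursors", lambda n, m: "C=C" + _rf(n), lambda n: n
    ),
    "FTSAs": _SubclassBuilder(
        "fluorotelomer_based_PFAA_precursors", lambda n, m: "OS(=O)(=O)CC" + _rf(n), lambda n: n
    ),
    "monoPAPs": _SubclassBuilder(
        "fluorotelomer_based_PFAA_precursors", lambda n, m: "OP(=O)(O)OCC" + _rf(n), lambda n: n
    ),
    "diPAPs": _SubclassBuilder(
        "fluorotelomer_based_PFAA_precursors",
        lambda n, m: "OP(=O)(OCC" + _rf(n) + ")OCC" + _rf(n), lambda n: n
    ),
    "FTALs": _SubclassBuilder(
        "fluorotelomer_based_PFAA_precursors", lambda n, m: "O=CC" + _rf(n), lambda n: n
    ),
    "FTCAs": _SubclassBuilder(
        "fluorotelomer_based_PFAA_precursors", lambda n, m: "OC(=O)C" + _rf(n), lambda n: n
    ),
    "FTUALs": _SubclassBuilder(
        "fluorotelomer_based_PFAA_precursors", lambda n, m: "O=CC=C(F)" + _rf(n - 1),
        lambda n: n - 1
    ),
    "FTUCAs": _SubclassBuilder(
        "fluorotelomer_based_PFAA_precursors", lambda n, m: "OC(=O)C=C(F)" + _rf(n - 1),
        lambda n: n - 1
    ),
    # perfluoroalkyl PFAA precursors
    "PASFs": _SubclassBuilder(
        "perfluoroalkyl_PFAA_precursors", lambda n, m: "FS(=O)(=O)" + _rf(n), lambda n: n
    ),
    "PACFs": _SubclassBuilder(
        "perfluoroalkyl_PFAA_precursors", lambda n, m: "FC(=O)" + _rf(n - 1), lambda n: n - 1
    ),
    "PFAIs": _SubclassBuilder(
        "perfluoroalkyl_PFAA_precursors", lambda n, m: "I" + _rf(n), lambda n: n
    ),
    # non-PFAA perfluoroalkyls
    "perfluoroalkanes": _SubclassBuilder(
        "non_PFAA_perfluoroalkyls", lambda n, m: "F" + _rf(n), lambda n: n, lambda n: n
    ),
    "perfluoroalkenes": _SubclassBuilder(
        "non_PFAA_perfluoroalkyls", lambda n, m: "FC(F)=C(F)" + _rf(n - 2), lambda n: n - 2
    ),
    "perfluoroalcohols": _SubclassBuilder(
        "non_PFAA_perfluoroalkyls",
        lambda n, m: "OC(C(F)(F)F)(C(F)(F)F)" + _rf(n - 2), lambda n: max(n - 2, 1)
    ),
    "perfluoroketones": _SubclassBuilder(
        "non_PFAA_perfluoroalkyls", lambda n, m: "O=C(C(F)(F)F)" + _rf(n - 2),
        lambda n: max(n - 2, 1)
    ),
}


def _canonical(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - generator bug guard
        raise ValueError(f"generator produced invalid SMILES: {smiles}")
    return Chem.MolToSmiles(mol)


def _aliphatic(class_label: str, subclass: str, n: int, m: int = 0,
               ring_opened: bool = False) -> ClassificationResult:
    return ClassificationResult(
        category=CATEGORY_ALIPHATIC,
        class_label=class_label,
        subclass_label=subclass,
        perfluoro_chain_length_n=n,
        alkyl_spacer_m=m,
        ring_opened=ring_opened,
        rings_opened=1 if ring_opened else 0,
    )


def generate_series(spec: SeriesSpec) -> list[CorpusRecord]:
    """Generate one homologous series with ground-truth classifications."""
    if not spec.n_range:
        raise ValueError("invalid_spec: empty n_range")
    builder = SUBCLASS_CATALOG.get(spec.subclass_label)
    if builder is None:
        raise ValueError(f"invalid_spec: unknown subclass {spec.subclass_label!r}")
    m_values = list(spec.m_range) if builder.uses_m else [0]
    if not m_values:
        raise ValueError("invalid_spec: empty m_range")
    records = []
    for n in spec.n_range:
        if builder.chain_n(n) < 1:
            raise ValueError(f"invalid_spec: homolog number {n} too small for {spec.subclass_label}")
        for m in m_values:
            smiles = _canonical(builder.build(n, m))
            ident = f"{spec.subclass_label}-n{n}" + (f"-m{m}" if builder.uses_m else "")
            records.append(
                CorpusRecord(
                    id=ident,
                    smiles=smiles,
                    expected=_aliphatic(
                        builder.class_label, spec.subclass_label, builder.chain_n(n), m
                    ),
                )
            )
    return records


def _special_records() -> list[CorpusRecord]:
    """Cyclic, derivative, silicon, aromatic and decoy fixtures."""
    def rec(ident: str, smiles: str, expected: ClassificationResult) -> CorpusRecord:
        return CorpusRecord(id=ident, smiles=_canonical(smiles), expected=expected)

    derivative = lambda sub: ClassificationResult(
        category=CATEGORY_DERIVATIVE, class_label=CLASS_DERIVATIVES, subclass_label=sub
    )
    records = [
        # carbocyclic PFASs (ring-opened before core classification)
        rec("cyclic-PFSA-C6", "O=S(=O)(O)C1(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C1(F)F",
            _aliphatic("PFAAs", "PFSAs", 6, ring_opened=True)),
        rec("cyclic-perfluoroalkane-C5", "FC1(F)C(F)(F)C(F)(F)C(F)(F)C1(F)F",
            _aliphatic("non_PFAA_perfluoroalkyls", "perfluoroalkanes", 5, ring_opened=True)),
        rec("cyclic-perfluoroalkane-C6", "FC1(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C1(F)F",
            _aliphatic("non_PFAA_perfluoroalkyls", "perfluoroalkanes", 6, ring_opened=True)),
        # derivatives (fail the -CF3/-CF2- definition)
        rec("deriv-halogen-1", "ClC(F)(F)C(F)(F)Cl", derivative("halogen_substituted")),
        rec("deriv-halogen-2", "BrC(F)(F)Br", derivative("halogen_substituted")),
        rec("deriv-unsat-1", "O=C(F)F", derivative("fluorinated_unsaturated_carbon")),
        rec("deriv-unsat-2", "FC(F)=C(F)F", derivative("fluorinated_unsaturated_carbon")),
        rec("deriv-aromatic-1", "Fc1ccccc1", derivative("fluorinated_aromatic_carbon")),
        rec("deriv-aromatic-2", "Fc1c(F)c(F)c(F)c(F)c1F", derivative("fluorinated_aromatic_carbon")),
        # silicon PFASs
        rec("silicon-1", "C[Si](C)(C)CC(F)(F)F",
            ClassificationResult(category=CATEGORY_SILICON, perfluoro_chain_length_n=1)),
        rec("silicon-2", "C[Si](C)(CC(F)(F)C(F)(F)F)O[Si](C)(C)C",
            ClassificationResult(category=CATEGORY_SILICON, perfluoro_chain_length_n=2)),
        # side-chain fluorinated aromatics
        rec("aromatic-side-1", "c1ccccc1CC(F)(F)F",
            ClassificationResult(category=CATEGORY_SIDE_CHAIN_AROMATIC, perfluoro_chain_length_n=1)),
        rec("aromatic-side-2", "FC(F)(F)c1ccccc1",
            ClassificationResult(category=CATEGORY_SIDE_CHAIN_AROMATIC, perfluoro_chain_length_n=1)),
        rec("aromatic-side-3", "OC(=O)c1ccc(CC(F)(F)C(F)(F)F)cc1",
            ClassificationResult(category=CATEGORY_SIDE_CHAIN_AROMATIC, perfluoro_chain_length_n=2)),
    ]
    not_pfas = ClassificationResult(category=CATEGORY_NOT_PFAS)
    decoys = [
        ("decoy-ethanol", "CCO"),
        ("decoy-benzene", "c1ccccc1"),
        ("decoy-hexane", "CCCCCC"),
        ("decoy-acetone", "CC(C)=O"),
        ("decoy-glycine", "NCC(=O)O"),
        ("decoy-glucose", "OCC1OC(O)C(O)C(O)C1O"),
        ("decoy-caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
        ("decoy-aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
        ("decoy-monofluoroethane", "CCF"),
        ("decoy-dichloromethane", "ClCCl"),
    ]
    records.extend(rec(ident, smi, not_pfas) for ident, smi in decoys)
    return records


def generate_corpus(seed: int = 0) -> list[CorpusRecord]:
    """Deterministic mixed corpus covering the full catalog (>=200 records).

    Every subclass appears as an n = 4..9 homologous series (sulfonamide
    subclasses additionally with N-methyl variants), plus the special
    fixtures.  The seed only shuffles record order — content is fixed.
    """
    import random

    records: list[CorpusRecord] = []
    for subclass, builder in SUBCLASS_CATALOG.items():
        m_range = (0, 1) if builder.uses_m else (0,)
        records.extend(generate_series(SeriesSpec(subclass, range(4, 10), m_range)))
    records.extend(_special_records())
    rng = random.Random(seed)
    rng.shuffle(records)
    return records


def generate_embedding_benchmark() -> list[CorpusRecord]:
    """A 200-compound, 5-subclass corpus for embedding-quality checks.

    Five structurally distinct subclasses (carboxylic and sulfonic acids,
    telomer alcohols, sulfonamides, perfluoroalkanes), homolog numbers
    8..17, each as the linear compound and three monomethyl-branched
    isomers — mimicking the linear/branched composition of technical
    PFAS mixtures.
    """
    subclasses = ("PFCAs", "PFSAs", "FTOHs", "FASAs", "perfluoroalkanes")
    heads = {
        "PFCAs": "OC(=O)",
        "PFSAs": "OS(=O)(=O)",
        "FTOHs": "OCC",
        "FASAs": "NS(=O)(=O)",
        "perfluoroalkanes": "F",
    }
    records = []
    for subclass in subclasses:
        builder = SUBCLASS_CATALOG[subclass]
        assert builder.rf_of is not None
        # branch positions chosen so no two variants are mirror images of
        # one another (relevant for the symmetric perfluoroalkanes)
        positions = (1, 2, 3) if subclass == "perfluoroalkanes" else (2, 3, 4)
        for n in range(8, 18):
            k = builder.rf_of(n)
            variants: list[tuple[str, str, int]] = [("lin", _rf(k), k)]
            for p in positions:
                q = k - p - 2
                variants.append((f"br{p}", _rf_branched(p, q), max(p, q, 1)))
            for tag, rf, chain in variants:
                smiles = _canonical(heads[subclass] + rf)
                records.append(
                    CorpusRecord(
                        id=f"bench-{subclass}-n{n}-{tag}",
                        smiles=smiles,
                        expected=_aliphatic(builder.class_label, subclass, chain),
                    )
                )
    return records


def _named(name: str, smiles: str, class_label: str, subclass: str,
           n: int, m: int = 0) -> CorpusRecord:
    return CorpusRecord(
        id=name, smiles=_canonical(smiles), expected=_aliphatic(class_label, subclass, n, m)
    )


#: Curated truth table of well-known PFAS reference compounds, SMILES
#: hand-encoded from their systematic names.
NAMED_COMPOUNDS: tuple[CorpusRecord, ...] = (
    _named("PFBA", "OC(=O)C(F)(F)C(F)(F)C(F)(F)F", "PFAAs", "PFCAs", 3),
    _named("PFBS", "OS(=O)(=O)" + _rf(4), "PFAAs", "PFSAs", 4),
    _named("PFHxA", "OC(=O)" + _rf(5), "PFAAs", "PFCAs", 5),
    _named("PFHpA", "OC(=O)" + _rf(6), "PFAAs", "PFCAs", 6),
    _named("PFHxS", "OS(=O)(=O)" + _rf(6), "PFAAs", "PFSAs", 6),
    _named("PFOA", "OC(=O)" + _rf(7), "PFAAs", "PFCAs", 7),
    _named("PFNA", "OC(=O)" + _rf(8), "PFAAs", "PFCAs", 8),
    _named("FOSA", "NS(=O)(=O)" + _rf(8), "FASA_based_PFAA_precursors", "FASAs", 8),
    _named("PFOS", "OS(=O)(=O)" + _rf(8), "PFAAs", "PFSAs", 8),
    _named("PFDcA", "OC(=O)" + _rf(9), "PFAAs", "PFCAs", 9),
    _named("PFUnA", "OC(=O)" + _rf(10), "PFAAs", "PFCAs", 10),
    _named("PFDS", "OS(=O)(=O)" + _rf(10), "PFAAs", "PFSAs", 10),
    _named("PFDoA", "OC(=O)" + _rf(11), "PFAAs", "PFCAs", 11),
    _named("PFTdA", "OC(=O)" + _rf(13), "PFAAs", "PFCAs", 13),
    _named("FTOH (6:2)", "OCC" + _rf(6),
           "fluorotelomer_based_PFAA_precursors", "FTOHs", 6),
    _named("FTOH (8:2)", "OCC" + _rf(8),
           "fluorotelomer_based_PFAA_precursors", "FTOHs", 8),
    _named("FTUA (6:2)", "OC(=O)C=C(F)" + _rf(5),
           "fluorotelomer_based_PFAA_precursors", "FTUCAs", 5),
    _named("N-MeFOSA", "CNS(=O)(=O)" + _rf(8),
           "FASA_based_PFAA_precursors", "FASAs", 8, m=1),
    _named("N-EtFOSA", "CCNS(=O)(=O)" + _rf(8),
           "FASA_based_PFAA_precursors", "FASAs", 8, m=2),
    _named("N-MeFOSE", "OCCN(C)S(=O)(=O)" + _rf(8),
           "FASA_based_PFAA_precursors", "FASEs", 8, m=1),
    _named("N-EtFOSE", "OCCN(CC)S(=O)(=O)" + _rf(8),
           "FASA_based_PFAA_precursors", "FASEs", 8, m=2),
    _named("6:2 FTMAC", "C=C(C)C(=O)OCC" + _rf(6),
           "fluorotelomer_based_PFAA_precursors", "FTMACs", 6),
    _named("6:2 FTI", "ICC" + _rf(6),
           "fluorotelomer_based_PFAA_precursors", "FTIs", 6),
)
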