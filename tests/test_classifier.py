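"""Classification cascade: definition filter, derivatives, ring opening, core rules."""

from __future__ import annotations

import pytest
from rdkit import Chem

from pfasmap.classify import (
    classify,
    classify_derivative,
    contains_perfluorinated_carbon,
    contains_silicon,
    is_side_chain_fluorinated_aromatic,
    load_ruleset,
    open_rings,
    perfluoro_chain_length,
)
from pfasmap.structure_io import RawRecord, standardize
from pfasmap.synthetic import NAMED_COMPOUNDS

PFOS = "O=S(=O)(O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F"
PFOA = "OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F"
CYCLIC_PFHXS = "O=S(=O)(O)C1(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C1(F)F"
PFHXS = "O=S(=O)(O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F"


def _mol(smiles: str) -> Chem.Mol:
    return Chem.MolFromSmiles(smiles)


class TestDefinitionFilter:
    @pytest.mark.parametrize(
        "smiles, expected",
        [
            ("CCO", False),
            (PFOS, True),
            ("ClC(F)(F)C(F)(F)Cl", False),   # Cl blocks both CF3 and chain-CF2
            ("FC(F)F", False),               # CHF2: hydrogen disqualifies
            ("FC(F)(F)F", True),             # CF4 counts via CF3-like carbon
            ("Fc1ccccc1", False),            # aromatic F only
        ],
    )
    def test_cf3_or_chain_cf2(self, smiles, expected):
        assert contains_perfluorinated_carbon(_mol(smiles)) is expected


class TestDerivatives:
    @pytest.mark.parametrize(
        "smiles, subclass",
        [
            ("ClC(F)(F)C(F)(F)Cl", "halogen_substituted"),
            ("O=C(F)F", "fluorinated_unsaturated_carbon"),
            ("FC(F)=C(F)F", "fluorinated_unsaturated_carbon"),
            ("Fc1ccccc1", "fluorinated_aromatic_carbon"),
        ],
    )
    def test_derivative_subclasses(self, smiles, subclass):
        res = classify_derivative(_mol(smiles))
        assert res.category == "pfas_derivative"
        assert res.subclass_label == subclass

    def test_no_fluorinated_feature_is_not_pfas(self):
        assert classify_derivative(_mol("CCO")).category == "not_pfas"

    def test_halogen_rule_checked_before_unsaturated(self):
        # carries both a Cl-substituted perfluoro carbon and a C=C fluorine
        res = classify_derivative(_mol("FC(=C(F)F)C(F)(Cl)F"))
        assert res.subclass_label == "halogen_substituted"


class TestFilters:
    def test_silicon_detection(self):
        assert contains_silicon(_mol("C[Si](C)(C)CC(F)(F)F"))
        assert not contains_silicon(_mol(PFOS))

    def test_silicon_precedes_core(self):
        assert classify("C[Si](C)(C)CC(F)(F)F").category == "silicon_pfas"

    def test_side_chain_aromatic(self):
        assert is_side_chain_fluorinated_aromatic(_mol("c1ccccc1CC(F)(F)F"))
        assert not is_side_chain_fluorinated_aromatic(_mol(PFOA))

    def test_aromatic_fluoride_without_cf_chain_fails_module_one(self):
        res = classify("Fc1ccccc1")
        assert res.category == "pfas_derivative"


class TestRingOpening:
    def test_published_cyclohexane_example_string_exact(self):
        opened, n_rings, failed = open_rings(_mol(CYCLIC_PFHXS))
        assert (n_rings, failed) == (1, False)
        assert Chem.MolToSmiles(opened) == Chem.CanonSmiles(PFHXS)

    def test_acyclic_input_unchanged(self):
        opened, n_rings, _ = open_rings(_mol(PFOA))
        assert n_rings == 0
        assert Chem.MolToSmiles(opened) == Chem.CanonSmiles(PFOA)

    def test_perfluorocyclopentane_gains_two_fluorines(self):
        opened, n_rings, _ = open_rings(_mol("FC1(F)C(F)(F)C(F)(F)C(F)(F)C1(F)F"))
        assert n_rings == 1
        symbols = [a.GetSymbol() for a in opened.GetAtoms()]
        assert symbols.count("C") == 5
        assert symbols.count("F") == 12
        assert Chem.MolToSmiles(opened) == Chem.CanonSmiles(
            "FC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F"
        )

    def test_conservation_on_cyclic_corpus_members(self, corpus):
        cyclic = [r for r in corpus if r.expected.ring_opened]
        assert len(cyclic) >= 2
        for rec in cyclic:
            mol = _mol(rec.smiles)
            f_in = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "F")
            c_in = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "C")
            opened, n_rings, failed = open_rings(mol)
            assert not failed
            assert opened.GetRingInfo().NumRings() == 0
            f_out = sum(1 for a in opened.GetAtoms() if a.GetSymbol() == "F")
            c_out = sum(1 for a in opened.GetAtoms() if a.GetSymbol() == "C")
            assert c_out == c_in
            assert f_out == f_in + 2 * n_rings

    def test_heteroatom_ring_left_intact_and_flagged(self):
        # perfluorinated tetrahydrofuran ring: no carbocycle to open
        mol = _mol("FC1(F)OC(F)(F)C(F)(F)C1(F)F")
        opened, n_rings, failed = open_rings(mol)
        assert n_rings == 0 and failed
        assert Chem.MolToSmiles(opened) == Chem.MolToSmiles(mol)


class TestChainLength:
    @pytest.mark.parametrize(
        "smiles, n",
        [
            (PFOS, 8),
            (PFOA, 7),
            ("FC(F)(F)F", 1),
            ("CCO", 0),
            # monomethyl branch: longest run is the longer arm
            ("OS(=O)(=O)C(F)(F)C(F)(F)C(F)(C(F)(F)F)C(F)(F)C(F)(F)C(F)(F)F", 3),
        ],
    )
    def test_longest_run(self, smiles, n):
        assert perfluoro_chain_length(_mol(smiles)) == n


class TestCoreRules:
    def test_rule_table_loads_with_unique_subclasses(self):
        ruleset = load_ruleset()
        subs = ruleset.subclasses()
        assert len(subs) == len(set(subs))
        assert subs.index("PFESAs") < subs.index("PFSAs")
        assert subs.index("diPAPs") < subs.index("monoPAPs")
        assert subs.index("FTMACs") < subs.index("FTACs")

    @pytest.mark.parametrize(
        "smiles, class_label, subclass, n",
        [
            (PFOS, "PFAAs", "PFSAs", 8),
            ("OCCC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F",
             "fluorotelomer_based_PFAA_precursors", "FTOHs", 8),
            ("FC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F",
             "non_PFAA_perfluoroalkyls", "perfluoroalkanes", 6),
        ],
    )
    def test_reference_assignments(self, smiles, class_label, subclass, n):
        res = classify(smiles)
        assert (res.class_label, res.subclass_label, res.perfluoro_chain_length_n) == (
            class_label, subclass, n,
        )

    def test_unmatched_aliphatic_pfas_is_unclassified(self):
        # CF3 group on an otherwise unpatterned amide scaffold
        res = classify("CC(=O)NCC(F)(F)F")
        assert res.category == "aliphatic_pfas"
        assert res.class_label == "unclassified_aliphatic"
        assert res.subclass_label == ""


class TestFullCascade:
    def test_fosa_classification(self):
        res = classify(
            "NS(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F"
        )
        assert res.category == "aliphatic_pfas"
        assert res.class_label == "FASA_based_PFAA_precursors"
        assert res.subclass_label == "FASAs"
        assert (res.perfluoro_chain_length_n, res.alkyl_spacer_m) == (8, 0)

    def test_cyclic_sulfonic_acid_full_path(self):
        res = classify(CYCLIC_PFHXS)
        assert res.category == "aliphatic_pfas"
        assert (res.class_label, res.subclass_label) == ("PFAAs", "PFSAs")
        assert res.perfluoro_chain_length_n == 6
        assert res.ring_opened

    def test_every_corpus_member_gets_exactly_one_result(self, corpus):
        categories = {
            "not_pfas", "pfas_derivative", "silicon_pfas",
            "side_chain_fluorinated_aromatic", "aliphatic_pfas",
        }
        for rec in corpus:
            res = classify(rec.smiles)
            assert res.category in categories
            if res.subclass_label:
                assert res.class_label

    def test_generator_round_trip_exact(self, corpus):
        for rec in corpus:
            got = classify(rec.smiles)
            e = rec.expected
            assert (
                got.category, got.class_label, got.subclass_label,
                got.perfluoro_chain_length_n, got.alkyl_spacer_m, got.ring_opened,
            ) == (
                e.category, e.class_label, e.subclass_label,
                e.perfluoro_chain_length_n, e.alkyl_spacer_m, e.ring_opened,
            ), rec.id

    def test_named_reference_compounds(self):
        for rec in NAMED_COMPOUNDS:
            got = classify(rec.smiles)
            assert (got.class_label, got.subclass_label) == (
                rec.expected.class_label, rec.expected.subclass_label,
            ), rec.id
            assert got.perfluoro_chain_length_n == rec.expected.perfluoro_chain_length_n

    def test_input_representation_invariance(self):
        for base in [PFOS, NAMED_COMPOUNDS[17].smiles, CYCLIC_PFHXS]:
            ref = classify(standardize(RawRecord("r", base)))
            for variant in Chem.MolToRandomSmilesVect(_mol(base), 4, randomSeed=11):
                got = classify(standardize(RawRecord("v", variant)))
                assert got == ref

    def test_homologous_series_stability(self):
        from pfasmap.synthetic import SeriesSpec, generate_series

        for subclass in ("PFSAs", "FTOHs", "FASAs"):
            for rec in generate_series(SeriesSpec(subclass, range(4, 13))):
                got = classify(rec.smiles)
                assert got.subclass_label == subclass
                assert got.perfluoro_chain_length_n == rec.expected.perfluoro_chain_length_n
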