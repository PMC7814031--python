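# Ordered subclass rule table for acyclic aliphatic PFASs.
#
# The classifier evaluates these rules top to bottom; the FIRST match wins,
# so more specific patterns (esters, ethers, di-esters) must precede the
# generic patterns they contain.  Editing this file (or pointing the
# classifier at a copy) is the supported way to track future revisions of
# the PFAS class catalog without touching code.
#
# Rule kinds:
#   smarts      - every SMARTS in `patterns` must match the molecule
#   sulfonamide - perfluoroalkane sulfonamide family CnF2n+1-SO2N(R)(CmH2m-R1);
#                 the N-branch walk that determines R1 and the N-alkyl size m
#                 is programmatic, `head` names the R1 it claims
#   composition - whole-molecule elemental composition test (named check)
#
# Class label notes:
#   - Ether-containing perfluoro acids (PFECAs/PFESAs) are housed under
#     PFAAs; they are chemically perfluoroalkyl(ether) acids and keeping
#     them beside PFCAs/PFSAs preserves the two-level class-subclass shape.
#   - The n:2 fluorotelomer rules fix the alkyl spacer at C2H4; telomers
#     with other spacer lengths fall through to unclassified_aliphatic.

rules:
  # --- FASA-based PFAA precursors: CnF2n+1-SO2N(CmH2m)-R1 -------------------
  - subclass: FASMACs
    class: FASA_based_PFAA_precursors
    kind: sulfonamide
    head: methacrylate
  - subclass: FASACs
    class: FASA_based_PFAA_precursors
    kind: sulfonamide
    head: acrylate
  - subclass: FASAAs
    class: FASA_based_PFAA_precursors
    kind: sulfonamide
    head: carboxyl
  - subclass: FASEs
    class: FASA_based_PFAA_precursors
    kind: sulfonamide
    head: hydroxyl
  - subclass: FASAs
    class: FASA_based_PFAA_precursors
    kind: sulfonamide
    head: none

  # --- Perfluoroalkyl acids (PFAAs); ether variants first -------------------
  - subclass: PFESAs
    class: PFAAs
    kind: smarts
    patterns:
      - "[CX4](F)(F)S(=O)(=O)[OX2H1]"
      - "[CX4;!$(C=O)](F)O[CX4](F)"
  - subclass: PFECAs
    class: PFAAs
    kind: smarts
    patterns:
      - "[CX4](F)C(=O)[OX2H1]"
      - "[CX4;!$(C=O)](F)O[CX4](F)"
  - subclass: PFSAs
    class: PFAAs
    kind: smarts
    patterns:
      - "[CX4](F)(F)S(=O)(=O)[OX2H1]"
  - subclass: PFCAs
    class: PFAAs
    kind: smarts
    patterns:
      - "[CX4](F)(F)C(=O)[OX2H1]"
  - subclass: PFPiAs
    class: PFAAs
    kind: smarts
    patterns:
      - "[CX4](F)(F)P(=O)([OX2H1])[CX4](F)F"
  - subclass: PFPAs
    class: PFAAs
    kind: smarts
    patterns:
      - "[CX4](F)(F)P(=O)([OX2H1])[OX2H1]"

  # --- n:2 fluorotelomer-based PFAA precursors: CnF2n+1-C2H4-R1 -------------
  - subclass: diPAPs
    class: fluorotelomer_based_PFAA_precursors
    kind: smarts
    patterns:
      - "[CX4](F)(F)[CH2][CH2]OP(=O)([OX2H1])O[CH2][CH2][CX4](F)F"
  - subclass: monoPAPs
    class: fluorotelomer_based_PFAA_precursors
    kind: smarts
    patterns:
      - "[CX4](F)(F)[CH2][CH2]OP(=O)([OX2H1])[OX2H1]"
  - subclass: FTSAs
    class: fluorotelomer_based_PFAA_precursors
    kind: smarts
    patterns:
      - "[CX4](F)(F)[CH2][CH2]S(=O)(=O)[OX2H1]"
  - subclass: FTMACs
    class: fluorotelomer_based_PFAA_precursors
    kind: smarts
    patterns:
      - "[CX4](F)(F)[CH2][CH2]OC(=O)C(=[CH2])[CH3]"
  - subclass: FTACs
    class: fluorotelomer_based_PFAA_precursors
    kind: smarts
    patterns:
      - "[CX4](F)(F)[CH2][CH2]OC(=O)[CH]=[CH2]"
  - subclass: FTUCAs
    class: fluorotelomer_based_PFAA_precursors
    kind: smarts
    patterns:
      - "[CX4](F)(F)C(F)=[CH]C(=O)[OX2H1]"
  - subclass: FTUALs
    class: fluorotelomer_based_PFAA_precursors
    kind: smarts
    patterns:
      - "[CX4](F)(F)C(F)=[CH][CH]=O"
  - subclass: FTCAs
    class: fluorotelomer_based_PFAA_precursors
    kind: smarts
    patterns:
      - "[CX4](F)(F)[CH2]C(=O)[OX2H1]"
  - subclass: FTALs
    class: fluorotelomer_based_PFAA_precursors
    kind: smarts
    patterns:
      - "[CX4](F)(F)[CH2][CH]=O"
  - subclass: FTOHs
    class: fluorotelomer_based_PFAA_precursors
    kind: smarts
    patterns:
      - "[CX4](F)(F)[CH2][CH2][OX2H1]"
  - subclass: FTIs
    class: fluorotelomer_based_PFAA_precursors
    kind: smarts
    patterns:
      - "[CX4](F)(F)[CH2][CH2]I"
  - subclass: FTOs
    class: fluorotelomer_based_PFAA_precursors
    kind: smarts
    patterns:
      - "[CX4](F)(F)[CH]=[CH2]"

  # --- Perfluoroalkyl PFAA precursors ---------------------------------------
  - subclass: PASFs
    class: perfluoroalkyl_PFAA_precursors
    kind: smarts
    patterns:
      - "[CX4](F)(F)S(=O)(=O)F"
  - subclass: PACFs
    class: perfluoroalkyl_PFAA_precursors
    kind: smarts
    patterns:
      - "[CX4](F)(F)C(=O)F"
  - subclass: PFAIs
    class: perfluoroalkyl_PFAA_precursors
    kind: smarts
    patterns:
      - "[CX4](F)(F)I"

  # --- Non-PFAA perfluoroalkyls (whole-molecule composition) ----------------
  - subclass: perfluoroalkanes
    class: non_PFAA_perfluoroalkyls
    kind: composition
    check: perfluoroalkane
  - subclass: perfluoroalkenes
    class: non_PFAA_perfluoroalkyls
    kind: composition
    check: perfluoroalkene
  - subclass: perfluoroalcohols
    class: non_PFAA_perfluoroalkyls
    kind: composition
    check: perfluoroalcohol
  - subclass: perfluoroketones
    class: non_PFAA_perfluoroalkyls
    kind: composition
    check: perfluoroketone
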