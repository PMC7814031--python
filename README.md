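# pfasmap

Rule-based classification and unsupervised structure–function mapping of
per- and polyfluoroalkyl substances (PFASs).

PFASs — molecules with at least one fully fluorinated carbon (a terminal
–CF₃ or a chain –CF₂– group) — number in the thousands, but property and
hazard data exist for only a small fraction of them. `pfasmap` is for
environmental chemists and cheminformaticians who need to (i) assign any
SMILES to the Buck/OECD PFAS class–subclass hierarchy automatically and
(ii) see where new compounds fall in a descriptor-based chemical-space map
next to compounds with known properties.

## What it does

1. **SMILES standardization** (`pfasmap.structure_io`) — one structure can
   carry many valid canonical SMILES depending on the source database. All
   input is salt-stripped, isotope-cleared, charge-neutralized and
   rewritten in a single canonical dialect (RDKit canonical SMILES), then
   deduplicated.
2. **Rule-cascade classification** (`pfasmap.classify`) — a fixed cascade:
   PFAS definition filter → derivative subclassing (F→Cl/Br substitution,
   fluorinated C=C/C=O, fluorinated aromatics) → silicon filter →
   side-chain fluorinated aromatics → carbocycle ring opening (each broken
   ring C–C bond capped with two fluorines) → an ordered class/subclass
   pattern table covering PFAAs (PFCAs, PFSAs, PFPAs, PFPiAs,
   PFECAs, PFESAs), FASA-based precursors CₙF₂ₙ₊₁–SO₂N(CₘH₂ₘ)–R¹,
   n:2 fluorotelomer precursors CₙF₂ₙ₊₁–C₂H₄–R¹, perfluoroalkyl
   precursors, and non-PFAA perfluoroalkyls. The table ships as editable
   YAML (`pfasmap/data/rules.yaml`).
3. **Descriptors** (`pfasmap.descriptors`) — ~210 RDKit 1D/2D descriptors
   plus an 881-bit substructure-key fingerprint per structure; columns
   with too many invalid values are pruned, the rest median-imputed.
4. **Embedding** (`pfasmap.embed`) — features are standardized and reduced
   by PCA to the smallest k whose cumulative explained variance reaches a
   target (default 70%), then embedded with seeded 3D t-SNE
   (perplexity 50, 1000 steps by default). The three axes, TSNE-PCA-1/2/3,
   are the map's coordinate system. User compounds are transformed by the
   stored PCA model (never refit) and placed by inverse-distance-weighted
   k-NN interpolation.
5. **Maps** (`pfasmap.mapping`) — 3D interactive maps and 2D projections
   colored by category/class/subclass or by an overlaid per-compound
   property table (e.g. assay hit ratios), exported as HTML, JSON and CSV.

A synthetic homologous-series generator (`pfasmap.synthetic`) produces
corpora with known ground truth for every subclass, so the whole pipeline
runs and is tested without any external download.

## Worked example

```python
from pfasmap import standardize, deduplicate, classify, fraction_to_percent
from pfasmap.structure_io import RawRecord

variants = {  # three database spellings of perfluorooctanesulfonic acid
    "PubChem": "C(C(C(C(C(F)(F)S(=O)(=O)O)(F)F)(F)F)(F)F)(C(C(C(F)(F)F)(F)F)(F)F)(F)F",
    "EPA CompTox": "OS(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F",
    "RDKit": "O=S(=O)(O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F",
}
structures = [standardize(RawRecord(src, smi)) for src, smi in variants.items()]
unique = deduplicate(structures)
print(len(unique))                      # 1
res = classify(unique[0])
print(res.class_label, res.subclass_label, res.perfluoro_chain_length_n)
# PFAAs PFSAs 8

res = classify("O=S(=O)(O)C1(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C1(F)F")
print(res.subclass_label, res.perfluoro_chain_length_n, res.ring_opened)
# PFSAs 6 True        (cyclic acid opened to perfluorohexanesulfonic acid)

print(fraction_to_percent("210/851"))   # 24.7  (assay hit ratio as percent)
```

The three spellings collapse to one structure, classified as a
perfluoroalkane sulfonic acid (PFSA) with an eight-carbon perfluoroalkyl
chain; the cyclic undecafluorocyclohexanesulfonic acid is ring-opened and
classified as the six-carbon PFSA.

From the shell, the same pipeline runs as:

```bash
pfasmap build-reference --input reference.smi --out ref/        # train map
pfasmap place --input new.smi --reference ref/ --out placed/    # add compounds
pfasmap map --reference ref/ --user placed/ --property hits.csv \
            --level subclass --out maps/                        # render
```

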