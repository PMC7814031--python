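# Methods

## Standardization model

Chemical identity in this package is a string equality: two inputs are the
same compound iff they standardize to the same RDKit canonical SMILES.
Standardization composes four steps, in order:

1. *Salt stripping.* Multi-fragment inputs keep the fragment with the most
   heavy atoms; ties break by higher molecular weight, then by
   lexicographically smallest canonical SMILES. This is deterministic and
   keeps the organic parent of common salt forms.
2. *Isotope removal.* All isotope labels are cleared.
3. *Neutralization.* Anionic O/N/S centers are protonated and protonated
   amines deprotonated. Permanent charges (quaternary ammonium and other
   sites not fixable by a protonation change) are retained and flagged
   `uncorrectable_charge` rather than altered — how such species should be
   treated is genuinely open, and flag-and-keep preserves information.
4. *Canonicalization* to RDKit's canonical SMILES, the single dialect used
   for every string comparison in the code and tests.

The pipeline is idempotent (re-standardizing a canonical string is a
no-op) and never raises on bad input: unparseable SMILES become rejection
records in a rejects file so one bad row cannot abort a batch.
Tautomer and stereochemistry normalization are out of scope.

## Classification cascade

Classification is a total, deterministic function of the standardized
molecular graph, organized as filters before a core pattern table.

*Definition filter.* A molecule is PFAS iff it has a fully fluorinated
carbon: an sp3 carbon with ≥3 fluorines (–CF₃; the ≥ admits CF₄), or an
sp3, hydrogen-free carbon with exactly two fluorines and two carbon
neighbors (chain –CF₂–). The operationalization deliberately excludes
CHF₂ and CClF₂ carbons. Molecules that fail are either *derivatives* —
tested in fixed order for (a) a would-be CF₃/CF₂ carbon with F replaced
by Cl/Br, (b) fluorine on a C=C or C=O carbon, (c) fluorine on an
aromatic carbon — or *not PFAS*.

*Silicon and aromatic filters.* Si-containing PFASs form their own
terminal category (no published rule subdivides them). Remaining
aromatic-containing PFASs are *side-chain fluorinated aromatics*: their
CF₃/CF₂ content is necessarily aliphatic because aromatic-fluorine-only
molecules already failed the definition filter. Because this filter
precedes ring opening, aromatic rings are never opened.

*Ring opening.* Cyclic aliphatic PFASs are rewritten acyclic: for each
carbocycle, one ring C–C bond is deleted and each of its two carbons
capped with a new fluorine (+2 F per ring; carbon count invariant). The
bond broken is chosen at the ring carbon carrying the highest-priority
exocyclic substituent (acid group > other heteroatom > fluorine-only >
hydrogen), with canonical-rank tie-breaks, so acid groups end up at a
chain terminus — undecafluorocyclohexanesulfonic acid opens exactly to
perfluorohexanesulfonic acid. Fused systems are opened iteratively.
Rings containing non-carbon atoms (cyclic ethers) are left intact and
flagged `ring_opening_failed`; the stated transformation adds fluorine to
carbons and is undefined for heteroatoms.

*Core table.* An ordered rule list (shipped as `data/rules.yaml`;
first match wins) assigns (class, subclass). Order encodes specificity:
sulfonamide (FASA) heads are resolved before acids, ether acids
(PFECAs/PFESAs, housed under PFAAs) before their plain counterparts,
methacrylates before acrylates, diesters before monoesters, and
composition-defined non-PFAA perfluoroalkyls last. FASA subclasses are
matched by a programmatic walk from the sulfonamide nitrogen that
identifies each branch as plain alkyl (contributing the N-alkyl size m)
or a functional head (hydroxyl, carboxyl, acrylate, methacrylate);
fluorotelomer rules fix the n:2 spacer at C₂H₄, and telomers with other
spacers fall through to `unclassified_aliphatic` rather than guess.

*Chain length.* `perfluoro_chain_length_n` is the longest simple path
through the subgraph of fully fluorinated sp3 carbons (2–4 F, no H).
For linear CₙF₂ₙ₊₁ chains this is exactly n; for branched isomers it is
the longest arm, which need not end in CF₃ (the terminal CF₃ can sit on
the far side of the branch point). Homolog *naming* numbers differ from
this structural n by one for subclasses whose name counts a head-group
carbon (PFOA, the n=8 carboxylic acid, has a C₇F₁₅ chain).

## Descriptor space

Each structure's feature vector concatenates the full RDKit 1D/2D
descriptor catalog (~210 real features) with an 881-bit substructure-key
fingerprint: 47 hierarchic count keys (element and ring counts at
thresholds, in the spirit of the PubChem CACTVS key set) followed by an
RDKit pattern fingerprint folded into the remaining positions. The intent
is a rich, deterministic feature space computed on the canonical
structure — parity with any external descriptor engine is a non-goal.
Descriptor failures are masked invalid; matrix assembly drops columns
whose invalid fraction exceeds a threshold (default 0.1, configurable —
"significant number" is not a number) and median-imputes surviving gaps.
Median imputation is robust and order-independent, so row permutation
commutes with assembly.

## Embedding

Features are z-scored (constant columns dropped) before PCA: descriptor
magnitudes span orders of magnitude and unscaled PCA would be dominated
by a few count features. The retained component count k is the smallest
whose cumulative explained-variance ratio reaches `variance_target`
(default 0.70). A ratio target is used instead of a fixed k because k is
snapshot-specific — on a given reference set the same mechanism may
retain tens of components. Correctness of the selection is checked in the
test suite against a brute-force covariance eigendecomposition (matrices
up to 50×20, tolerance 1e-8), not against the library that computes it.

t-SNE runs on the PCA scores with three output dimensions; perplexity
(default 50) and step/iteration count (default 1000) are the two exposed
hyperparameters, seeded and logged on every run. Early exaggeration and
learning rate stay at scikit-learn defaults and are recorded in the run
log. Identical input + seed reproduces coordinates bit-exactly.

User compounds never refit anything: their descriptors are transformed by
the persisted PCA model and their map coordinates interpolated as the
inverse-distance-weighted mean of the k nearest reference points
(default k=10) in PCA space. A user compound identical to a reference
compound inherits its coordinates exactly. This out-of-sample rule is a
modelling choice (t-SNE has no native transform); every placed point is
marked `user_placed` so readers can tell interpolated positions from
embedded ones.

## Map documents

A map document is pure data: points (coordinates, classification path,
color, hover text, optional property value), a legend, a view mode.
Categorical colors are fixed by sorted label order over a colorblind-safe
palette, so runs are byte-reproducible. Property overlays switch to a
continuous min–max scale and leave compounds without data neutral gray;
overlays and 2D projections (any two of the three stored components,
never recomputed) return new documents and cannot mutate coordinates or
labels. Rendering is an adapter: CSV and JSON are written directly, and
the HTML export embeds the document model plus plotly.js from CDN, so
tests assert on the model rather than markup. Assay hit ratios supplied
as "active/total" strings convert to percentages via exact rational
arithmetic rounded to one decimal.

## Synthetic corpora — what they do and do not show

The generator builds homologous series for every subclass in the catalog
from head-group templates plus linear or monomethyl-branched CₙF₂ₙ₊₁
tails, with ground-truth labels attached by construction; the mixed
corpus (~234 structures, homologs n=4–9, N-alkyl variants for sulfonamide
subclasses) adds carbocyclic PFASs, all three derivative subclasses,
silicon and side-chain aromatic cases, and non-PFAS decoys. The
embedding benchmark is 200 structures: five head-group-distinct
subclasses × homolog numbers 8–17 × {linear, three branch positions},
mimicking the linear/branched composition of technical PFAS mixtures.
Corpus parameters are fixed study conditions, not tuning knobs.

Passing the round-trip suite shows the cascade implements its stated
rules exactly on structures drawn from those rules' own patterns; it does
not certify behavior on exotic real-world chemistries (mixed-function
heads, unusual spacers, polymeric PFASs), which may legitimately land in
`unclassified_aliphatic`. Likewise the benchmark's clean subclass
separation in t-SNE shows the embedding machinery preserves genuine
structure, not that real inventories separate as cleanly: synthetic
series are noise-free and more regular than any real list. Quantities
that depend on a specific external snapshot (master-list sizes,
2,090-column descriptor schemas, k=74 at 70% variance) are inherently
not reproducible from this repository and are not asserted anywhere.

## Numerical choices and limitations

- Component selection uses a 1e-12 slack inside the cumulative-variance
  search purely to absorb floating-point summation error; tests compare
  at 1e-8.
- PCA fit scores (SVD path) and transform scores (matmul path) agree to
  ~1 ulp, not exactly; pipeline-level tests therefore compare placements
  at 1e-9 while the library-level zero-distance contract is exact.
- Longest-path chain search is exact DFS over the perfluoro-carbon
  subgraph; realistic PFAS chains are near-linear so this is linear-time
  in practice.
- The rule catalog is reconstructed from published structural patterns;
  per-subclass divergence from other implementations on exotic structures
  is possible, and the YAML table is the supported place to amend rules.
- t-SNE geometry is seed-dependent by nature; only topology-level claims
  (neighbor purity, reproducibility at fixed seed) are ever asserted.
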