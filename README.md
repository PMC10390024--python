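# retrotag

Disconnection-prompt machinery for prompt-driven, single-step
retrosynthesis: identify the disconnection site of an atom-mapped reaction,
write it into the product SMILES as atom tags, build the prompt-dataset
variants used to train tag-aware sequence-to-sequence models, and evaluate
retrosynthesis predictions with round-trip accuracy, disconnection
accuracy, reagent-insensitive ground-truth matching, per-tag-count
stratification, and top-10 class diversity.

## Who this is for

Anyone preparing training corpora for, or evaluating, retrosynthesis
translation models that accept *disconnection prompts* — product SMILES in
which the atoms of the retrosynthetic cut are marked with atom-map tags
(`[*:1]` notation) so that the model can be steered toward a user-chosen
bond change. The package handles the full data side of that workflow;
the neural models themselves (translator, atom mapper, reaction
classifier) plug in behind small contracts, and deterministic
template-oracle implementations of all of them are included so every
pipeline stage runs and is testable on a laptop with no external corpora.

## The core ideas

**Disconnection site.** For an atom-mapped reaction with a single product,
a product atom belongs to the site iff its heavy-atom bond multiset
{(neighbor map number, bond order)} differs between the reactant and
product sides; a reactant-side neighbor that does not survive into the
product counts as a bond to a leaving group. The site size (number of
tags, 1-10 after filtering) stratifies every reported accuracy.

**Prompt grammar.** Exactly the site atoms carry map number 1 in the
canonical product SMILES; `strip_tags` inverts `insert_tags`, returning the
site on the product's canonical atom order (invariant to mapping and to
graph symmetry), which is the representation used for all site comparison.

**Dataset variants.** `disconnection_aware` (tagged product → precursors),
`permuted` (partially tagged product → precursors; proper subsets of the
site up to four tags, sampled), `autocomplete` (partially tagged →
fully tagged product), and `autotag` (bare product → tagged product).
Reactions are filtered to one product, 2-10 reactants, and 1-10 tags, then
split 90:5:5 (largest-remainder exact, grouped by product so no product
straddles splits), and tokenized with the standard reaction-SMILES regex.

**Metrics.** Round-trip accuracy: the forward model regenerates the product
from the top-1 precursors. Disconnection accuracy: the reconstructed
reaction (predicted precursors » forward-predicted product) is remapped and
its changed atoms recomputed; the prediction is correct iff the recomputed
site equals the prompt exactly. Ground-truth matching is component-set
equality after standardization, reported with and without unmapped
(non-product-contributing) species. Class diversity is the number of
unique reaction classes among the top-10 predictions for one input.

## Worked example

```python
import retrotag as rt

line = ("[CH3:1][C:2](=[O:3])[OH:4].[CH3:5][CH2:6][OH:7]"
        ">>[CH3:1][C:2](=[O:3])[O:7][CH2:6][CH3:5]")
rxn = rt.parse_reaction_line(line)
site = rt.find_changed_atoms(rxn)
print("edited atoms (map numbers):", sorted(site.atom_map_ids))

tagged = rt.insert_tags(rxn.product, site)
print("disconnection prompt:", tagged.smiles)

oracle = rt.TemplateOracleTranslator()
prediction = oracle.translate(tagged)
print("top-1 precursors:", " . ".join(prediction.top1))

forward = rt.TemplateForwardModel()
mapper = rt.OracleAtomMapper()
ok, product = rt.round_trip_match(rxn.product.bare_smiles, prediction.top1, forward)
print("round-trip product:", product, "->", ok)

recomputed = rt.recompute_site(product, list(prediction.top1), mapper)
print("disconnection match:", recomputed == rt.site_on_product(rxn.product, site))
```

prints

```
edited atoms (map numbers): [2, 7]
disconnection prompt: CC[O:1][C:1](C)=O
top-1 precursors: CC(=O)O . CCO
round-trip product: CCOC(C)=O -> True
disconnection match: True
```

The esterification changes two atoms — the carbonyl carbon (loses the
acid OH, gains the ester O) and the alcohol oxygen (gains the carbonyl
carbon) — so the prompt tags exactly those two. The steered oracle cuts
the ester bond there, the forward model regenerates ethyl acetate from
acetic acid + ethanol (round-trip true), and remapping the reconstructed
reaction recovers the prompted site (disconnection match true).

## Command line

```bash
retrotag fixtures --n 1000 --seed 42 --out data/        # reactions + sidecar annotations
retrotag build-dataset --input data/reactions.txt \
    --variant disconnection_aware --out corpus/         # six aligned src/tgt files
retrotag evaluate --reactions data/reactions.txt \
    --predictions preds.tsv --out report/               # per-record + stratified report
```

Prediction files are tab-separated `input  rank  precursors  [score]`, one
line per ranked prediction, so any external translation model can be
evaluated without running in-process.

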