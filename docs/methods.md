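# Methods

## The procedure

retrotag implements the data machinery of prompt-driven retrosynthesis.
The object of interest is a single-product, atom-mapped reaction written in
SMILES. From it the package derives a *disconnection site* — the set of
product atoms whose bonding changed — writes that site into the product as
atom tags (the disconnection *prompt*), constructs the four prompt-dataset
variants used to train tag-aware seq2seq models, and scores the
predictions of any retrosynthesis translator against site-level and
precursor-level ground truth.

### Site detection

For each mapped product atom, the multiset of heavy-atom bonds
`{(neighbor map number, bond order)}` is compared between the product side
and the corresponding reactant atom. A reactant-side neighbor whose map
number does not appear in the product (a leaving-group atom, mapped or
not) is collapsed onto the pseudo-neighbor `0`, so losing *any* departing
neighbor registers as a change. Comparison happens on the sanitized,
aromaticity-perceived graph (aromatic order 1.5), which makes the result
independent of kekulization and prevents spurious tags in ring-forming
reactions.

Two deliberate exclusions, each behind a switch that defaults to off:

* `include_h_changes` — an atom whose only change is its hydrogen count is
  not tagged. Tags mark disconnections; H-count changes are a byproduct of
  heavy-atom edits in ordinary single-step chemistry.
* `include_stereo_changes` — identical connectivity with a different CIP
  code does not tag an atom, for the same reason. The stereo comparison is
  CIP-code based and deliberately simple; reactions whose only edit is a
  stereocenter inversion are outside the intended scope.

An empty site is returned, not raised: it means no bond changed and the
record is removed by filtering ("no reaction").

### The tag grammar and site identity

`insert_tags` canonicalizes the product and puts map number 1 on exactly
the site atoms; any positive map number is accepted as a tag on read.
Because all tags share one number, a tagged SMILES cannot recover the
original reaction's map numbers. Sites are therefore compared in a
mapping-independent representation (`CanonicalSite`): the canonical,
map-free product SMILES plus the site expressed as canonical atom ranks.
Symmetry-equivalent atoms receive arbitrary tie-broken ranks, so the index
set is additionally normalized to the lexicographically smallest image
under the molecule's automorphism group (computed by self-substructure
matching, cached per product). Two prompts that tag chemically
indistinguishable atoms of a symmetric molecule thus compare equal — the
only defensible semantics, since no experiment could tell them apart.

### Prompt permutation and the model-variant corpora

"Permuting" tags means selecting proper, non-empty subsets of the site
(tags are a set; the grammar has no order), up to a preset limit of four
tagged atoms. One-tag sites are skipped — no proper subset exists. When
the enumeration exceeds a cap (default 20 subsets per product) it is
sampled uniformly without replacement, seeded per product (seed XOR
CRC32 of the product SMILES) so the sample is reproducible and independent
of input order.

Corpus construction filters reactions to one product, 2-10 mapped
reactants, and 1-10 site atoms (an optional token ceiling is exposed but
has no default: the appropriate value depends on the downstream model's
positional budget). Drop reasons (`product_count`, `reactant_count`,
`token_limit`, `no_tags`, `too_many_tags`) are counted and reproducible.
The four variants share one filtered reaction stream:

| variant | src | tgt |
|---|---|---|
| disconnection_aware | fully tagged product | precursors |
| permuted | partially tagged product | precursors |
| autocomplete | partially tagged product | fully tagged product |
| autotag | bare product | fully tagged product |

Precursor targets are canonical, map-free components joined by `.` in
lexicographic order (reproducible targets); unmapped reagents are included
unless configured off. Splits are 90:5:5 with largest-remainder rounding
— exact on any corpus size — and are assigned per *product*, not per
record, so the same product (and hence the same tagged src across
variants) never appears in two splits. Grouped exactness is achieved by a
seeded greedy fill of the small splits with a single-swap repair; it
fails loudly if group sizes cannot pack, and can be disabled
(`group_by_product=False`) for plain record-level splitting.

Enzymatic reactions carry a four-level EC number. The reaction-line
dialect appends ` |EC:x.x.x.x`; tagging and atom-mapping always operate on
the EC-stripped SMILES, and the number is re-attached to the source side
as four hierarchical tokens after a `|` separator (`[EC1_1] [EC2_3] ...`),
an encoding chosen here for exact round-tripping.

### Evaluation

* **Round-trip**: the top-1 precursors are pushed through a forward
  reaction model; the prediction passes iff the predicted product equals
  the input product after standardization (canonical, map-free, deduped,
  sorted — the normal form used for *every* equality in the package).
* **Disconnection**: the reaction `top-1 precursors >> forward-predicted
  product` is remapped by the pluggable atom mapper and the changed atoms
  recomputed; the prediction passes iff the recomputed `CanonicalSite`
  equals the prompt exactly. A `lenient` superset mode exists but is off:
  the prompt is the contract. A switch allows remapping against the input
  product instead of the forward model's.
* **Ground-truth match**: component-set equality, in two modes — all
  species, and restricted to mapped (product-contributing) species. The
  prediction side is restricted by remapping it against the product and
  dropping species that receive no atom maps. The two modes bracket the
  reagent variability of real corpora.
* **Class diversity**: unique reaction classes among the top-10
  predictions for one input, unclassifiable predictions excluded. Both the
  per-sample mean and the full distribution are reported, since either
  summary may be wanted.
* **Stratification**: accuracies are binned by number of tagged atoms
  rather than summarized as one TopN number — disconnection accuracy by
  the input prompt's tag count, round-trip by the *predicted* tag count
  (recalibrated to the bond changes the model actually made); both
  stratifications are emitted for both metrics since the captions of the
  reference figures fix only one pairing. Empty bins are absent, never 0%.
  Records with no prediction or a mapper failure are counted but excluded
  from bins; forward-model failure is an ordinary False outcome.

Round-trip and disconnection accuracy are deliberately independent: a
tag-blind model can regenerate the product from precursors that cut a
different bond, scoring high round-trip and low disconnection accuracy.
The test suite exercises exactly this divergence.

### Backends

Real models plug in behind four contracts: `Translator` (ranked precursor
sets for a tagged or bare product), `ForwardModelProtocol`, `AtomMapper`,
and `ReactionClassifier`. External seq2seq models interoperate through
tab-separated prediction files (`input, rank, precursors, score?`) read
into a `FilePredictionsTranslator`, so no training or inference code runs
in-process.

The shipped implementations are template oracles built on five reversible
reaction templates (esterification, amide coupling, Williamson ether
synthesis, Ullmann-type biaryl coupling, Diels-Alder cycloaddition; edited
sites of 2, 2, 2, 2 and 6 atoms). Each template pairs a retro rule with
its exact forward inverse, so `forward(retro(p)) == p` holds by
construction; the biaryl retro caps both aryl carbons with Br precisely so
the cut is invariant under the symmetry of the aromatic C-C match, and the
Diels-Alder fixture uses an unsubstituted ethylene dienophile so the two
forward match orientations give the same cycloadduct. The
`NaiveTranslator` is the tag-blind control: it ignores prompts and always
applies the most corpus-frequent applicable template (registry order) at
its first match.

## The synthetic data generator

The fixture generator emits atom-mapped single-product reactions whose
edited-atom sets, classes, and mapped/unmapped species are known *by
construction* — map numbers are assigned positionally while the SMILES is
assembled, never by running the site detector. That independence is what
makes the generator a usable oracle for the detector.

Scaffolds come from seeded decoration of the five template cores with
small alkyl/aryl fragments (product SMILES roughly 6-100 characters, the
range where tag-grammar handling is uncomplicated). Fragment combinations
are drawn without replacement per template, so products are unique until a
template's combinatorial space (a few hundred per template) is exhausted;
the default mix is uniform over the five templates. Options add 1-2
unmapped spectator species (pyridine, triethylamine, DCM, DMSO, THF,
water) per reaction with a configurable probability, and well-formed
random EC numbers for the enzymatic mode. A separate constructor builds
*multi-site* products — benzene cores carrying 2-3 different reactive
groups at disjoint sites — used for the steering, control-discrimination,
and class-diversity properties.

What the generator does **not** emulate: realistic reaction-type
frequencies, failed or ambiguous atom mappings, stereochemistry, multiple
products, ring-remapping noise, or the long tail of patent-corpus
heterogeneity. Passing tests therefore demonstrate that the machinery is
correct (detection matches construction, grammars invert, metrics
discriminate), not that any particular accuracy would be achieved on
USPTO-scale data with trained models.

## Problem sizes and numerical choices

The acceptance script and test suite use 500 fixture reactions for
site-detection and grammar properties, 1000 records for split exactness,
150 single-site and 200 multi-site records for metric discrimination and
class diversity, 150 spectator-bearing and 100 enzymatic reactions for the
reagent and EC properties — sizes at which every property is exercised
across all five templates while the whole suite runs in well under a
minute per stage. All randomness is driven by a single seed; sub-streams
(permutation sampling) derive order-independent per-product seeds from it.

Determinism notes: template matching, retro application, and forward
assignment all iterate in fixed registry/match order, so oracle outputs
are bit-stable; automorphism enumeration is capped at 10,000 matches
(far above anything the fixture scaffolds produce) and cached per product.

## Known limitations

* Disconnection comparison assumes the predicted product is the same
  molecule as the input product; when it is not, the record simply fails
  the match rather than attempting a cross-molecule site alignment.
* The stereo switch compares CIP codes only; bond-stereo (E/Z) edits are
  not tagged even when enabled.
* The oracle atom mapper only maps reactions its template registry can
  explain (plus the degenerate identity reaction); it is a test oracle,
  not a general-purpose mapper, and a neural mapper should be plugged in
  for real corpora.
* No tautomer or charge standardization is applied beyond RDKit
  canonicalization; corpora needing it should be normalized upstream.
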