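"""Backend contracts and the deterministic template-oracle implementations.

Four pluggable contracts connect the package to real models:

* :class:`Translator` — tagged (or bare) product in, ranked precursor sets out;
* :class:`ForwardModelProtocol` — precursor set in, single product out;
* :class:`AtomMapper` (defined in :mod:`retrotag.tagging`) — reaction SMILES
  in, fully mapped reaction SMILES out;
* :class:`ReactionClassifier` — reaction SMILES in, class label out.

The template-oracle implementations here are exact inverses of each other by
construction, which makes every metric assertable at desk scale.  The
:class:`NaiveTranslator` is a tag-blind control: it always applies the
corpus-most-frequent applicable template wherever it first matches,
standing in for a baseline model that cannot use disconnection prompts.

External seq2seq backends are wrapped through prediction files
(``input<TAB>rank<TAB>precursors<TAB>score?``) rather than in-process calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

from rdkit import Chem

from .chem_io import canonicalize, mol_from_smiles, standardize_component_set
from .errors import RetroTagError
from .tagging import TaggedProduct, tag_atoms
from .templates import DEFAULT_REGISTRY, ReactionTemplate


@dataclass(frozen=True)
class TranslationResult:
    """Ranked precursor sets (rank 1 first), each standardized."""

    ranked: tuple[tuple[str, ...], ...]
    scores: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if any(not s for s in self.ranked):
            raise ValueError("ranked precursor sets must be non-empty")
        if self.scores is not None and len(self.scores) != len(self.ranked):
            raise ValueError("scores length must match ranked length")

    @property
    def ok(self) -> bool:
        return bool(self.ranked)

    @property
    def top1(self) -> tuple[str, ...] | None:
        return self.ranked[0] if self.ranked else None

    @classmethod
    def empty(cls) -> "TranslationResult":
        return cls(ranked=())


class Translator(Protocol):
    def translate(self, src: TaggedProduct | str, top_n: int = 10) -> TranslationResult: ...


class ForwardModelProtocol(Protocol):
    def predict_product(self, precursors: Sequence[str]) -> str | None: ...


class ReactionClassifier(Protocol):
    def classify(self, reaction_smiles: str) -> str | None: ...


def _as_smiles(src: TaggedProduct | str) -> str:
    return src.smiles if isinstance(src, TaggedProduct) else src


def _bare_copy(mol: Chem.Mol) -> Chem.Mol:
    bare = Chem.Mol(mol)
    for a in bare.GetAtoms():
        a.SetAtomMapNum(0)
    return bare


class TemplateOracleTranslator:
    """Deterministic retro translator steered exactly by the tagged atoms.

    A registered template contributes a prediction iff one of its product
    matches has a site equal to the set of tagged atoms; the retro rule is
    then applied at that match.  Identical inputs give identical ranked
    outputs.
    """

    def __init__(self, registry: Sequence[ReactionTemplate] = DEFAULT_REGISTRY):
        self.registry = tuple(registry)

    def translate(self, src: TaggedProduct | str, top_n: int = 10) -> TranslationResult:
        try:
            mol = mol_from_smiles(_as_smiles(src))
        except RetroTagError:
            return TranslationResult.empty()
        tagged = frozenset(a.GetIdx() for a in mol.GetAtoms() if a.GetAtomMapNum() > 0)
        if not tagged:
            return TranslationResult.empty()
        bare = _bare_copy(mol)
        ranked: list[tuple[str, ...]] = []
        for template in self.registry:
            for match in template.product_matches(bare):
                site = frozenset(match[qm] for qm in template.site_maps)
                if site != tagged:
                    continue
                precursors = standardize_component_set(template.apply_retro(bare, match))
                if precursors not in ranked:
                    ranked.append(precursors)
        return TranslationResult(tuple(ranked[:top_n]))


class NaiveTranslator:
    """Tag-blind control: applies the most frequent applicable template.

    Ignores any tags on the input and cuts the molecule wherever the
    highest-priority (most corpus-frequent) template first matches; further
    matches and templates fill the lower ranks.
    """

    def __init__(self, registry: Sequence[ReactionTemplate] = DEFAULT_REGISTRY):
        self.registry = tuple(registry)

    def translate(self, src: TaggedProduct | str, top_n: int = 10) -> TranslationResult:
        try:
            mol = mol_from_smiles(_as_smiles(src))
        except RetroTagError:
            return TranslationResult.empty()
        bare = _bare_copy(mol)
        ranked: list[tuple[str, ...]] = []
        for template in self.registry:
            for match in template.product_matches(bare):
                precursors = standardize_component_set(template.apply_retro(bare, match))
                if precursors not in ranked:
                    ranked.append(precursors)
                if len(ranked) >= top_n:
                    return TranslationResult(tuple(ranked))
        return TranslationResult(tuple(ranked))


class TemplateForwardModel:
    """Forward reaction prediction by exact template inversion.

    Precursors are matched against the reactant-side patterns of each
    registered template (frequency order); the first successful combination
    yields the product.  Spectator species that match no pattern are
    ignored, so adding a reagent never changes the predicted product.
    """

    def __init__(self, registry: Sequence[ReactionTemplate] = DEFAULT_REGISTRY):
        self.registry = tuple(registry)

    def predict_product(self, precursors: Sequence[str]) -> str | None:
        try:
            mols = [mol_from_smiles(c) for c in standardize_component_set(precursors)]
        except RetroTagError:
            return None
        for template in self.registry:
            for product, _prov in template.iter_forward(mols):
                return Chem.MolToSmiles(_bare_copy(product))
        return None


class OracleAtomMapper:
    """Atom mapper whose maps are known by template construction.

    Replays every registered template forward over the precursors until one
    combination regenerates the stated product, then numbers the product
    atoms 1..N and transfers those numbers to the contributing precursor
    atoms via the tracked provenance.  Precursors that contribute no atoms
    stay unmapped.  Returns ``None`` when no template explains the reaction
    — except for the degenerate identity "reaction" (product among the
    precursors), which maps atom-by-atom to itself.
    """

    def __init__(self, registry: Sequence[ReactionTemplate] = DEFAULT_REGISTRY):
        self.registry = tuple(registry)

    def map_reaction(self, reaction_smiles: str) -> str | None:
        try:
            left, _, right = reaction_smiles.split(">")
            components = [canonicalize(c) for c in left.split(".") if c]
            product = canonicalize(right.split(" ")[0])
        except (ValueError, RetroTagError):
            return None
        if not components:
            return None
        product_mol = mol_from_smiles(product)

        if product in components:
            return self._identity(components, product, product_mol)

        try:
            mols = [mol_from_smiles(c) for c in components]
        except RetroTagError:
            return None
        for template in self.registry:
            for fwd_product, provenance in template.iter_forward(mols):
                fwd_bare = _bare_copy(fwd_product)
                if Chem.MolToSmiles(fwd_bare) != product:
                    continue
                match = product_mol.GetSubstructMatch(fwd_bare)
                if not match:
                    continue
                mapped_prod = Chem.Mol(product_mol)
                mapped_pre = [Chem.Mol(m) for m in mols]
                for fwd_idx, (mol_i, atom_i) in provenance.items():
                    map_no = fwd_idx + 1
                    mapped_prod.GetAtomWithIdx(match[fwd_idx]).SetAtomMapNum(map_no)
                    mapped_pre[mol_i].GetAtomWithIdx(atom_i).SetAtomMapNum(map_no)
                left_out = ".".join(Chem.MolToSmiles(m) for m in mapped_pre)
                return f"{left_out}>>{Chem.MolToSmiles(mapped_prod)}"
        return None

    def _identity(self, components, product, product_mol) -> str:
        mapped_prod = Chem.Mol(product_mol)
        for atom in mapped_prod.GetAtoms():
            atom.SetAtomMapNum(atom.GetIdx() + 1)
        mapped = Chem.MolToSmiles(mapped_prod)
        left = [mapped if c == product else c for c in components]
        return f"{'.'.join(left)}>>{mapped}"


class TemplateClassifier:
    """Labels a reaction with the class of the template that explains it."""

    def __init__(self, registry: Sequence[ReactionTemplate] = DEFAULT_REGISTRY):
        self.registry = tuple(registry)

    def classify(self, reaction_smiles: str) -> str | None:
        try:
            left, _, right = reaction_smiles.split(">")
            product = canonicalize(right.split(" ")[0])
            mols = [mol_from_smiles(canonicalize(c)) for c in left.split(".") if c]
        except (ValueError, RetroTagError):
            return None
        for template in self.registry:
            for fwd_product, _prov in template.iter_forward(mols):
                if Chem.MolToSmiles(_bare_copy(fwd_product)) == product:
                    return template.class_label
        return None


# ------------------------------------------------------------- AutoTag flow


def propose_sites(
    product_smiles: str, registry: Sequence[ReactionTemplate] = DEFAULT_REGISTRY
) -> list[TaggedProduct]:
    """Enumerate candidate disconnection prompts for a bare product.

    Desk-scale stand-in for an AutoTag model: every registered template
    match contributes one tagged product, in registry order.
    """
    mol = mol_from_smiles(product_smiles)
    bare = Chem.MolToSmiles(_bare_copy(mol))
    seen: set[frozenset] = set()
    out: list[TaggedProduct] = []
    for template in registry:
        for site in template.sites(mol_from_smiles(bare)):
            if site in seen:
                continue
            seen.add(site)
            out.append(tag_atoms(bare, site))
    return out


def pooled_translate(
    prompts: Sequence[TaggedProduct | str],
    translator: Translator,
    top_n: int = 10,
) -> TranslationResult:
    """Translate several prompts and pool their rankings round-robin.

    This is the AutoTag workflow: one bare product, several proposed sites,
    and a single merged top-N list across sites.
    """
    per_prompt = [translator.translate(p, top_n=top_n).ranked for p in prompts]
    pooled: list[tuple[str, ...]] = []
    rank = 0
    while len(pooled) < top_n:
        added = False
        for ranked in per_prompt:
            if rank < len(ranked) and ranked[rank] not in pooled:
                pooled.append(ranked[rank])
                added = True
                if len(pooled) == top_n:
                    break
        if not added:
            break
        rank += 1
    return TranslationResult(tuple(pooled))


# --------------------------------------------------------- prediction files


def write_predictions(
    path: str | Path,
    inputs: Sequence[str],
    results: Sequence[TranslationResult],
) -> None:
    """Write a tab-separated prediction file (``input rank precursors score?``)."""
    if len(inputs) != len(results):
        raise ValueError("inputs and results must align")
    with open(path, "w") as fh:
        for src, result in zip(inputs, results):
            for rank, precursors in enumerate(result.ranked, start=1):
                score = (
                    f"\t{result.scores[rank - 1]}" if result.scores is not None else ""
                )
                fh.write(f"{src}\t{rank}\t{'.'.join(precursors)}{score}\n")


def read_predictions(path: str | Path) -> dict[str, TranslationResult]:
    """Read a prediction file back into per-input results.

    Line order is irrelevant; ranks must be dense from 1 per input.
    """
    rows: dict[str, dict[int, tuple[tuple[str, ...], float | None]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise RetroTagError(f"malformed prediction line: {line!r}")
            src, rank_s, precursors = parts[0], parts[1], parts[2]
            score = float(parts[3]) if len(parts) > 3 and parts[3] else None
            rows.setdefault(src, {})[int(rank_s)] = (
                standardize_component_set(precursors.split(".")),
                score,
            )
    out: dict[str, TranslationResult] = {}
    for src, by_rank in rows.items():
        ranks = sorted(by_rank)
        if ranks != list(range(1, len(ranks) + 1)):
            raise RetroTagError(f"ranks not dense from 1 for input {src!r}")
        ranked = tuple(by_rank[r][0] for r in ranks)
        scores = tuple(by_rank[r][1] for r in ranks)
        out[src] = TranslationResult(
            ranked, scores if all(s is not None for s in scores) else None
        )
    return out


class FilePredictionsTranslator:
    """Translator backed by a prediction file from any external model."""

    def __init__(self, predictions: dict[str, TranslationResult]):
        self._predictions = predictions

    @classmethod
    def from_file(cls, path: str | Path) -> "FilePredictionsTranslator":
        return cls(read_predictions(path))

    def translate(self, src: TaggedProduct | str, top_n: int = 10) -> TranslationResult:
        result = self._predictions.get(_as_smiles(src))
        if result is None:
            return TranslationResult.empty()
        return TranslationResult(
            result.ranked[:top_n],
            result.scores[:top_n] if result.scores else None,
        )
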