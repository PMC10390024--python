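"""Reaction-SMILES parsing, canonicalization, and tokenization.

This module is the single canonicalization authority for the package: every
equality comparison elsewhere (target construction, metric evaluation) is
string equality of the RDKit canonical SMILES produced here.

Reaction-line dialect
---------------------
One reaction per line, ``reactants>>product`` with precursors dot-joined on
the left.  Two extensions are accepted and normalized away:

* a middle reagent field, ``reactants>reagents>product`` — middle species are
  treated as reagents and stripped of any atom maps;
* an optional `` |EC:x.x.x.x`` suffix carrying a four-level Enzyme Commission
  number for enzymatic reactions.

Anything after a tab character is ignored (corpora sometimes carry a
class-label column); the full original line is preserved on the parsed
record.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger

from .errors import (
    MappingError,
    MultiplicityError,
    ReactionParseError,
    TokenizationError,
)

RDLogger.DisableLog("rdApp.*")

#: The standard reaction-SMILES token pattern.  Bracket atoms, two-letter
#: halogens, and %nn ring closures are single tokens; everything else is
#: one character.
SMILES_TOKEN_PATTERN = (
    r"(\[[^\]]+\]|Br?|Cl?|N|O|S|P|F|I|b|c|n|o|s|p|\(|\)|\.|=|#|-|\+|\\|\/|:"
    r"|~|@|\?|>|\*|\$|%[0-9]{2}|[0-9])"
)
_TOKEN_RE = re.compile(SMILES_TOKEN_PATTERN)

_EC_SUFFIX_RE = re.compile(r"\s*\|EC:([0-9]+(?:\.[0-9]+){3})\s*$")

EC_PATTERN = re.compile(r"^[0-9]+(?:\.[0-9]+){3}$")


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string, raising :class:`ReactionParseError` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ReactionParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def canonicalize(smiles: str, keep_maps: bool = False) -> str:
    """Return the canonical form of *smiles*.

    Atom-map numbers are removed unless ``keep_maps`` is true.  The operation
    is idempotent and invariant to the input atom ordering.
    """
    mol = mol_from_smiles(smiles)
    if not keep_maps:
        for atom in mol.GetAtoms():
            atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol)


def tokenize_smiles(smiles: str) -> list[str]:
    """Split a SMILES (or tokenizable suffix) into grammar tokens.

    The concatenation of the returned tokens reproduces the input exactly;
    any residue outside the token grammar raises :class:`TokenizationError`.
    """
    if not smiles:
        raise TokenizationError("cannot tokenize an empty string")
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        # locate the first character not covered by a token
        pos = 0
        for match in _TOKEN_RE.finditer(smiles):
            if match.start() != pos:
                break
            pos = match.end()
        raise TokenizationError(
            f"untokenizable residue at position {pos}: {smiles[pos:pos + 10]!r}"
        )
    return tokens


def detokenize(tokens: Iterable[str]) -> str:
    """Inverse of :func:`tokenize_smiles` (plain concatenation)."""
    return "".join(tokens)


def standardize_component_set(components: Sequence[str]) -> tuple[str, ...]:
    """Canonicalize components with maps removed, dedupe, sort.

    This is the normal form used for *every* set-equality comparison in the
    evaluation stack.
    """
    return tuple(sorted({canonicalize(c, keep_maps=False) for c in components}))


@dataclass(frozen=True)
class Species:
    """One molecular species of a reaction.

    ``smiles`` is canonical (maps retained); ``mapped`` is true iff any atom
    carries a positive atom-map number.
    """

    smiles: str
    mapped: bool

    @classmethod
    def from_smiles(cls, smiles: str) -> "Species":
        mol = mol_from_smiles(smiles)
        mapped = any(a.GetAtomMapNum() > 0 for a in mol.GetAtoms())
        return cls(smiles=Chem.MolToSmiles(mol), mapped=mapped)

    @property
    def bare_smiles(self) -> str:
        """Canonical SMILES with atom maps removed."""
        return canonicalize(self.smiles, keep_maps=False)


@dataclass(frozen=True)
class MappedReaction:
    """A parsed single-product reaction.

    ``reactants`` are the mapped (product-contributing) species, ``reagents``
    the unmapped ones.  Map numbers are unique per side and every mapped
    product atom's number occurs in some reactant.
    """

    reactants: tuple[Species, ...]
    reagents: tuple[Species, ...]
    product: Species
    ec_number: str | None = None
    source_line: str = field(default="", compare=False)

    @property
    def precursors(self) -> tuple[Species, ...]:
        return self.reactants + self.reagents

    @property
    def taggable(self) -> bool:
        """True when the product is fully mapped and has mapped reactants."""
        if not self.reactants:
            return False
        mol = mol_from_smiles(self.product.smiles)
        return all(a.GetAtomMapNum() > 0 for a in mol.GetAtoms())

    def reaction_smiles(self, include_ec: bool = True) -> str:
        left = ".".join(s.smiles for s in self.precursors)
        line = f"{left}>>{self.product.smiles}"
        if include_ec and self.ec_number:
            line += f" |EC:{self.ec_number}"
        return line


def _collect_maps(species: Iterable[Species], side: str) -> set[int]:
    seen: set[int] = set()
    for sp in species:
        mol = mol_from_smiles(sp.smiles)
        for atom in mol.GetAtoms():
            n = atom.GetAtomMapNum()
            if n > 0:
                if n in seen:
                    raise MappingError(
                        f"map number {n} occurs more than once among {side} atoms"
                    )
                seen.add(n)
    return seen


def parse_reaction_line(line: str) -> MappedReaction:
    """Parse one reaction line into a :class:`MappedReaction`.

    Accepts the two-sided (``a.b>>p``) and three-field (``a>b>p``) dialects
    and an optional `` |EC:x.x.x.x`` suffix; see the module docstring.
    """
    raw = line.rstrip("\n")
    work = raw.split("\t")[0].strip()
    ec = None
    ec_match = _EC_SUFFIX_RE.search(work)
    if ec_match:
        ec = ec_match.group(1)
        work = work[: ec_match.start()].strip()

    parts = work.split(">")
    if len(parts) != 3:
        raise ReactionParseError(
            f"expected 'reactants>>product' (one arrow), got {raw!r}"
        )
    left, middle, right = (p.strip() for p in parts)
    if not right:
        raise MultiplicityError(f"no product in line {raw!r}")

    product_parts = [p for p in right.split(".") if p]
    if len(product_parts) != 1:
        raise MultiplicityError(
            f"expected exactly one product, got {len(product_parts)} in {raw!r}"
        )
    product = Species.from_smiles(product_parts[0])

    reactants: list[Species] = []
    reagents: list[Species] = []
    for frag in (f for f in left.split(".") if f):
        sp = Species.from_smiles(frag)
        (reactants if sp.mapped else reagents).append(sp)
    for frag in (f for f in middle.split(".") if f):
        # middle-field species are reagents by position; normalize by
        # stripping any stray maps so the two-sided invariant holds
        reagents.append(Species.from_smiles(canonicalize(frag, keep_maps=False)))

    reactant_maps = _collect_maps(reactants, "reactant")
    product_maps = _collect_maps([product], "product")
    missing = product_maps - reactant_maps
    if missing:
        raise MappingError(
            f"product map numbers {sorted(missing)} missing from reactants in {raw!r}"
        )

    return MappedReaction(
        reactants=tuple(reactants),
        reagents=tuple(reagents),
        product=product,
        ec_number=ec,
        source_line=raw,
    )


def partition_species(rxn: MappedReaction) -> tuple[tuple[Species, ...], tuple[Species, ...]]:
    """Split precursors into (mapped, unmapped) species.

    The union is all precursor species and the intersection is empty; used by
    the reagent-sensitivity analyses.
    """
    return rxn.reactants, rxn.reagents
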