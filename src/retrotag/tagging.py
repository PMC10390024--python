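"""Disconnection-site detection and the product tag grammar.

The disconnection site of an atom-mapped reaction is the set of product
atoms whose heavy-atom bonding changed between the two sides.  For each
mapped product atom the bond multiset ``{(neighbor map number, bond order)}``
is compared with the corresponding reactant atom's multiset, where a
reactant-side neighbor that does not survive into the product (leaving-group
atom, mapped or not) is recorded as a bond to the pseudo-neighbor ``0``.
Aromatic bonds compare on the sanitized, aromaticity-perceived graph (order
1.5), so kekulization differences never produce spurious tags.

Tags are written into the product SMILES as atom-map number 1 on exactly the
site atoms (``[*:1]`` notation); any positive map number is accepted as a
tag on read.

Because all tags share the number 1, a tagged SMILES cannot recover the
original reaction map numbers.  Sites are therefore made comparable across
different mappings through :class:`CanonicalSite`: the site expressed as
canonical atom ranks of the bare product.  Two prompts on the same molecule
are equal iff their canonical sites are equal, regardless of which mapper
produced them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Protocol, Sequence

from rdkit import Chem

from .chem_io import MappedReaction, Species, canonicalize, mol_from_smiles, parse_reaction_line
from .errors import MappingError, RetroTagError, TaggingError


class AtomMapper(Protocol):
    """Backend contract: reaction SMILES in, fully mapped reaction SMILES out.

    Implementations return ``None`` when the reaction cannot be mapped.
    """

    def map_reaction(self, reaction_smiles: str) -> str | None: ...


@dataclass(frozen=True)
class DisconnectionSite:
    """Site atoms identified by their reaction atom-map numbers."""

    atom_map_ids: frozenset[int]

    def __post_init__(self) -> None:
        if any(i <= 0 for i in self.atom_map_ids):
            raise TaggingError("site map ids must be positive")

    @property
    def n_tags(self) -> int:
        return len(self.atom_map_ids)

    def __bool__(self) -> bool:
        return bool(self.atom_map_ids)


@dataclass(frozen=True)
class CanonicalSite:
    """A site expressed on the canonical atom order of the bare product.

    ``product`` is the canonical, map-free product SMILES; ``atom_indices``
    are canonical atom ranks.  This representation is independent of atom
    mapping and of the SMILES the product was parsed from, so it is the
    common currency for prompt/prediction site comparison.
    """

    product: str
    atom_indices: frozenset[int]

    @property
    def n_tags(self) -> int:
        return len(self.atom_indices)


@dataclass(frozen=True)
class TaggedProduct:
    """Canonical product SMILES in which exactly the site atoms carry ``:1``."""

    smiles: str

    @property
    def n_tags(self) -> int:
        mol = mol_from_smiles(self.smiles)
        return sum(1 for a in mol.GetAtoms() if a.GetAtomMapNum() > 0)


def _strip_copy(mol: Chem.Mol) -> Chem.Mol:
    bare = Chem.Mol(mol)
    for atom in bare.GetAtoms():
        atom.SetAtomMapNum(0)
    return bare


@lru_cache(maxsize=4096)
def _rank_automorphisms(canonical_smiles: str) -> tuple[tuple[int, ...], ...]:
    """The molecule's automorphism group, expressed on canonical atom ranks."""
    mol = mol_from_smiles(canonical_smiles)
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    perms = []
    for auto in mol.GetSubstructMatches(mol, uniquify=False, maxMatches=10000):
        perm = [0] * len(ranks)
        for atom_i, image_i in enumerate(auto):
            perm[ranks[atom_i]] = ranks[image_i]
        perms.append(tuple(perm))
    return tuple(perms)


def _canonical_site_from_indices(mol: Chem.Mol, indices: Iterable[int]) -> CanonicalSite:
    bare = _strip_copy(mol)
    ranks = list(Chem.CanonicalRankAtoms(bare, breakTies=True))
    product = Chem.MolToSmiles(bare)
    site = frozenset(ranks[i] for i in indices)
    # symmetry-equivalent atoms receive arbitrary tie-broken ranks, so two
    # chemically identical prompts can land on different automorphic images;
    # normalize to the lexicographically smallest image
    if site:
        site = min(
            (frozenset(perm[i] for i in site) for perm in _rank_automorphisms(product)),
            key=sorted,
        )
    return CanonicalSite(product=product, atom_indices=site)


def site_on_product(product: Species | str, site: DisconnectionSite) -> CanonicalSite:
    """Express a map-number site on the product's canonical atom order."""
    smiles = product.smiles if isinstance(product, Species) else product
    mol = mol_from_smiles(smiles)
    idx_by_map = {a.GetAtomMapNum(): a.GetIdx() for a in mol.GetAtoms() if a.GetAtomMapNum() > 0}
    missing = site.atom_map_ids - idx_by_map.keys()
    if missing:
        raise TaggingError(f"site map ids {sorted(missing)} absent from product")
    return _canonical_site_from_indices(mol, (idx_by_map[m] for m in site.atom_map_ids))


def find_changed_atoms(
    rxn: MappedReaction,
    *,
    include_h_changes: bool = False,
    include_stereo_changes: bool = False,
) -> DisconnectionSite:
    """Identify product atoms whose bonding differs between the two sides.

    Parameters
    ----------
    rxn
        Fully product-mapped reaction (every product atom carries a map
        number present in some reactant).
    include_h_changes
        Also tag atoms whose total hydrogen count changed even though no
        heavy-atom bond did.  Off by default: tags mark disconnections, and
        H-only changes are a byproduct of heavy-atom edits.
    include_stereo_changes
        Also tag atoms whose CIP code changed with identical connectivity.
        Off by default for the same reason.

    Returns
    -------
    DisconnectionSite
        Possibly empty (identical sides); an empty site is returned for the
        caller to filter, never raised.
    """
    prod = mol_from_smiles(rxn.product.smiles)
    product_maps: dict[int, int] = {}
    for atom in prod.GetAtoms():
        n = atom.GetAtomMapNum()
        if n <= 0:
            raise MappingError(
                f"product atom {atom.GetIdx()} ({atom.GetSymbol()}) is unmapped"
            )
        product_maps[n] = atom.GetIdx()

    reactant_atoms: dict[int, tuple[Chem.Mol, int]] = {}
    reactant_mols = []
    for sp in rxn.reactants:
        mol = mol_from_smiles(sp.smiles)
        reactant_mols.append(mol)
        if include_stereo_changes:
            Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
        for atom in mol.GetAtoms():
            n = atom.GetAtomMapNum()
            if n > 0:
                reactant_atoms[n] = (mol, atom.GetIdx())
    if include_stereo_changes:
        Chem.AssignStereochemistry(prod, cleanIt=True, force=True)

    changed: set[int] = set()
    for map_no, pidx in product_maps.items():
        if map_no not in reactant_atoms:
            raise MappingError(f"product map {map_no} not found in reactants")
        patom = prod.GetAtomWithIdx(pidx)
        pbonds = Counter(
            (b.GetOtherAtom(patom).GetAtomMapNum(), b.GetBondTypeAsDouble())
            for b in patom.GetBonds()
        )
        rmol, ridx = reactant_atoms[map_no]
        ratom = rmol.GetAtomWithIdx(ridx)
        rbonds: Counter = Counter()
        for b in ratom.GetBonds():
            other = b.GetOtherAtom(ratom).GetAtomMapNum()
            # neighbors that do not survive into the product collapse onto
            # the leaving-group pseudo-neighbor 0
            key = other if other in product_maps else 0
            rbonds[(key, b.GetBondTypeAsDouble())] += 1
        if pbonds != rbonds:
            changed.add(map_no)
            continue
        if include_h_changes and patom.GetTotalNumHs() != ratom.GetTotalNumHs():
            changed.add(map_no)
            continue
        if include_stereo_changes:
            pcip = patom.GetPropsAsDict().get("_CIPCode")
            rcip = ratom.GetPropsAsDict().get("_CIPCode")
            if pcip != rcip:
                changed.add(map_no)
    return DisconnectionSite(frozenset(changed))


def insert_tags(product: Species | str, site: DisconnectionSite) -> TaggedProduct:
    """Write the tag grammar: exactly the site atoms carry map number 1."""
    smiles = product.smiles if isinstance(product, Species) else product
    mol = mol_from_smiles(smiles)
    idx_by_map = {a.GetAtomMapNum(): a.GetIdx() for a in mol.GetAtoms() if a.GetAtomMapNum() > 0}
    missing = site.atom_map_ids - idx_by_map.keys()
    if missing:
        raise TaggingError(f"site map ids {sorted(missing)} absent from product")
    site_idxs = {idx_by_map[m] for m in site.atom_map_ids}
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(1 if atom.GetIdx() in site_idxs else 0)
    return TaggedProduct(Chem.MolToSmiles(mol))


def tag_atoms(product_smiles: str, atom_indices: Iterable[int]) -> TaggedProduct:
    """Tag a product at explicit atom indices (for map-free products)."""
    mol = mol_from_smiles(product_smiles)
    idxs = set(atom_indices)
    bad = [i for i in idxs if i < 0 or i >= mol.GetNumAtoms()]
    if bad:
        raise TaggingError(f"atom indices out of range: {sorted(bad)}")
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(1 if atom.GetIdx() in idxs else 0)
    return TaggedProduct(Chem.MolToSmiles(mol))


def strip_tags(tagged: TaggedProduct | str) -> tuple[str, CanonicalSite]:
    """Read the tag grammar: return (bare canonical product, canonical site).

    Any positive map number is accepted as a tag, so sequentially numbered
    tags round-trip as well.
    """
    smiles = tagged.smiles if isinstance(tagged, TaggedProduct) else tagged
    mol = mol_from_smiles(smiles)
    idxs = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomMapNum() > 0]
    site = _canonical_site_from_indices(mol, idxs)
    return site.product, site


def recompute_site(
    product: str,
    predicted_precursors: Sequence[str],
    mapper: AtomMapper,
) -> CanonicalSite | None:
    """Re-derive the disconnection site of a predicted retrosynthetic step.

    The reaction ``predicted_precursors >> product`` is remapped with
    *mapper* and the changed atoms recomputed, returning the site on the
    product's canonical atom order (comparable to the input prompt).
    Returns ``None`` when the mapper fails or the remapped reaction is
    inconsistent — callers mark the evaluation record invalid rather than
    raising.
    """
    try:
        bare_product = canonicalize(product, keep_maps=False)
        reaction = ".".join(canonicalize(p) for p in predicted_precursors)
        reaction = f"{reaction}>>{bare_product}"
    except RetroTagError:
        return None
    mapped = mapper.map_reaction(reaction)
    if mapped is None:
        return None
    try:
        rxn = parse_reaction_line(mapped)
        site = find_changed_atoms(rxn)
        return site_on_product(rxn.product, site)
    except RetroTagError:
        return None
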