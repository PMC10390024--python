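"""Synthetic atom-mapped reaction fixtures with known disconnection sites.

Every other module is testable without external corpora because this
generator emits single-product, atom-mapped reaction lines whose edited-atom
sets, reaction classes, and mapped/unmapped species are known *by
construction* (positional bookkeeping while assembling the SMILES), never by
running the site-detection code they are used to test.

Scaffold diversity comes from seeded decoration of the five registered
reaction cores with small alkyl/aryl fragments; fragment combinations are
sampled without replacement per template, so products are unique until a
template's combinatorial space is exhausted.  Optional unmapped spectator
species (bases, solvents) and EC numbers exercise the reagent-sensitivity
and enzymatic code paths.

These fixtures make contracts assertable; they do not attempt realistic
patent-reaction statistics.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Callable, Sequence

from rdkit import Chem

from .chem_io import canonicalize, mol_from_smiles
from .errors import TemplateError
from .tagging import CanonicalSite, DisconnectionSite, TaggedProduct, strip_tags, tag_atoms
from .templates import DEFAULT_REGISTRY, ReactionTemplate, match_sites, registry_by_name

# decoration fragments; every string is valid SMILES when appended after an
# atom (single-bond attachment) and is free of reactive groups that would
# collide with a template core
ALKYL = (
    "C", "CC", "CCC", "CCCC", "CCCCC", "CCCCCC",
    "CC(C)C", "CCC(C)C", "CC(C)CC", "C(C)C", "C(C)(C)C", "CC(C)(C)C",
)
ARYL = (
    "c1ccccc1", "c1ccc(C)cc1", "c1ccc(F)cc1", "c1ccc(Cl)cc1",
    "c1cccc(C)c1", "c1ccc(CC)cc1", "Cc1ccccc1", "CCc1ccccc1",
    "c1ccc(C(C)C)cc1", "c1cccc(F)c1",
)
#: alkyls branched at the attachment atom — used on the O-alkyl side of
#: ethers so the CH2-O-CX4 core matches only at the constructed site
O_BRANCHED = ("C(C)C", "C(C)(C)C", "C(C)CC", "C(C)(C)CC", "C(C)CCC", "C(CC)CC")
RING_SUBST = ALKYL + ("F", "Cl")

#: unmapped spectator species (base, solvent, additive)
SPECTATORS = ("c1ccncc1", "CCN(CC)CC", "ClCCl", "CS(C)=O", "C1CCOC1", "O")


@lru_cache(maxsize=None)
def _natoms(frag: str) -> int:
    return mol_from_smiles(frag).GetNumAtoms()


@dataclass(frozen=True)
class FixtureReaction:
    """One generated reaction line plus its ground-truth annotations."""

    line: str
    template: str
    class_label: str
    site: DisconnectionSite
    product: str                    # canonical, map-free
    reactants: tuple[str, ...]      # mapped SMILES
    spectators: tuple[str, ...] = ()
    ec_number: str | None = None


def _instance(
    product_raw: str,
    reactant_specs: Sequence[tuple[str, dict[int, int]]],
    edited: Sequence[int],
) -> tuple[str, tuple[str, ...], frozenset]:
    """Assemble mapped SMILES from raw strings + positional correspondences.

    ``reactant_specs`` holds (raw SMILES, {reactant atom idx -> product atom
    idx}); atoms absent from the map are leaving-group atoms and stay
    unmapped.  Map number = product atom index + 1.
    """
    pmol = mol_from_smiles(product_raw)
    for atom in pmol.GetAtoms():
        atom.SetAtomMapNum(atom.GetIdx() + 1)
    product = Chem.MolToSmiles(pmol)
    reactants = []
    for raw, corr in reactant_specs:
        rmol = mol_from_smiles(raw)
        for ridx, pidx in corr.items():
            rmol.GetAtomWithIdx(ridx).SetAtomMapNum(pidx + 1)
        reactants.append(Chem.MolToSmiles(rmol))
    site = frozenset(i + 1 for i in edited)
    return product, tuple(reactants), site


# ---------------------------------------------------------------- builders
# one builder per template; each returns (product, mapped reactants, site)


def _ester(a: str, b: str):
    na, nb = _natoms(a), _natoms(b)
    acid = {0: 0, 1: 1, **{3 + j: 3 + nb + j for j in range(na)}}  # OH (idx 2) leaves
    alcohol = {0: 2, **{1 + j: 3 + j for j in range(nb)}}
    return _instance(
        f"C(=O)(O{b}){a}",
        [(f"C(=O)(O){a}", acid), (f"O{b}", alcohol)],
        [0, 2],
    )


def _amide(a: str, b: str):
    na, nb = _natoms(a), _natoms(b)
    acid = {0: 0, 1: 1, **{3 + j: 3 + nb + j for j in range(na)}}
    amine = {0: 2, **{1 + j: 3 + j for j in range(nb)}}
    return _instance(
        f"C(=O)(N{b}){a}",
        [(f"C(=O)(O){a}", acid), (f"N{b}", amine)],
        [0, 2],
    )


def _ether(a: str, b: str):
    na, nb = _natoms(a), _natoms(b)
    halide = {0: 0, **{2 + j: 2 + nb + j for j in range(na)}}  # Br (idx 1) leaves
    alcohol = {0: 1, **{1 + j: 2 + j for j in range(nb)}}
    return _instance(
        f"C(O{b}){a}",
        [(f"C(Br){a}", halide), (f"O{b}", alcohol)],
        [0, 1],
    )


def _biaryl(a: str, b: str):
    na, nb = _natoms(a), _natoms(b)
    halide1 = {i: i for i in range(6 + na)}  # Br at 6+na leaves
    halide2 = {1 + j: 6 + na + j for j in range(6 + nb)}  # Br (idx 0) leaves
    return _instance(
        f"c8cc({a})ccc8-c9cc({b})ccc9",
        [(f"c8cc({a})ccc8Br", halide1), (f"Brc9cc({b})ccc9", halide2)],
        [5 + na, 6 + na],
    )


def _diels_alder(x: str, a: str):
    nx, na = _natoms(x), _natoms(a)
    diene = {i: i for i in range(4 + nx + na)}
    ene = {0: 4 + nx + na, 1: 5 + nx + na}
    return _instance(
        f"C8({x})C=CC({a})CC8",
        [(f"C({x})=CC=C{a}", diene), ("C=C", ene)],
        [0, 1 + nx, 2 + nx, 3 + nx, 4 + nx + na, 5 + nx + na],
    )


_BUILDERS: dict[str, tuple[Callable, tuple, tuple]] = {
    # name -> (builder, pool for slot a, pool for slot b)
    "ester": (_ester, ALKYL + ARYL, ALKYL + ARYL),
    "amide": (_amide, ALKYL + ARYL, ALKYL + ARYL),
    "ether": (_ether, ALKYL + ARYL, O_BRANCHED),
    "biaryl": (_biaryl, RING_SUBST, RING_SUBST),
    "diels_alder": (_diels_alder, ALKYL, ALKYL + ARYL),
}


def generate_dataset(
    n: int,
    seed: int = 42,
    template_mix: dict[str, float] | None = None,
    spectator_prob: float = 0.0,
    ec_mode: bool = False,
    registry: Sequence[ReactionTemplate] = DEFAULT_REGISTRY,
) -> list[FixtureReaction]:
    """Generate *n* atom-mapped single-product reaction lines.

    Deterministic under *seed*.  ``template_mix`` weights the registered
    templates (uniform by default); ``spectator_prob`` adds 1-2 unmapped
    spectator species to the precursor side with that probability per
    reaction; ``ec_mode`` attaches a well-formed EC number to every line.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    by_name = registry_by_name(registry)
    names = [t.name for t in registry if t.name in _BUILDERS]
    if not names:
        raise TemplateError("empty template registry")
    if template_mix:
        unknown = set(template_mix) - set(names)
        if unknown:
            raise TemplateError(f"unknown templates in mix: {sorted(unknown)}")
        names = [t for t in names if template_mix.get(t, 0) > 0]
        weights = [template_mix[t] for t in names]
    else:
        weights = [1.0] * len(names)

    rng = random.Random(seed)
    seen_products: set[str] = set()
    out: list[FixtureReaction] = []
    for _ in range(n):
        name = rng.choices(names, weights=weights, k=1)[0]
        builder, pool_a, pool_b = _BUILDERS[name]
        for _attempt in range(80):
            a, b = rng.choice(pool_a), rng.choice(pool_b)
            product, reactants, site = builder(a, b)
            bare = canonicalize(product, keep_maps=False)
            if bare not in seen_products:
                break
        seen_products.add(bare)

        spectators: tuple[str, ...] = ()
        if spectator_prob > 0 and rng.random() < spectator_prob:
            spectators = tuple(rng.sample(SPECTATORS, rng.randint(1, 2)))
        ec = None
        if ec_mode:
            ec = (
                f"{rng.randint(1, 6)}.{rng.randint(1, 20)}"
                f".{rng.randint(1, 30)}.{rng.randint(1, 99)}"
            )
        left = ".".join(reactants + spectators)
        line = f"{left}>>{product}"
        if ec:
            line += f" |EC:{ec}"
        out.append(
            FixtureReaction(
                line=line,
                template=name,
                class_label=by_name[name].class_label,
                site=DisconnectionSite(site),
                product=bare,
                reactants=reactants,
                spectators=spectators,
                ec_number=ec,
            )
        )
    return out


# ---------------------------------------------------------- multi-site set


@dataclass(frozen=True)
class SiteAnnotation:
    template: str
    class_label: str
    atom_indices: frozenset          # indices into the canonical product SMILES
    tagged: TaggedProduct
    canonical_site: CanonicalSite


@dataclass(frozen=True)
class MultiSiteProduct:
    """A product compatible with >=2 templates at disjoint sites."""

    product: str
    sites: tuple[SiteAnnotation, ...]


_MS_GROUPS: tuple[tuple[str, Callable[[str], str], tuple], ...] = (
    ("ester", lambda f: f"C(=O)O{f}", ALKYL),
    ("amide", lambda f: f"C(=O)N{f}", ALKYL),
    ("ether", lambda f: f"CO{f}", O_BRANCHED),
    ("biaryl", lambda f: f"c9ccc({f})cc9", ALKYL),
)


def multi_site_products(
    k: int,
    seed: int = 42,
    registry: Sequence[ReactionTemplate] = DEFAULT_REGISTRY,
    n_sites: tuple[int, ...] = (2, 3),
) -> list[MultiSiteProduct]:
    """Products carrying 2-3 distinct reactive cores at disjoint sites.

    Each product is annotated with every (template, site) pair the registry
    finds in it; used for the steering and class-diversity properties.
    """
    rng = random.Random(seed)
    out: list[MultiSiteProduct] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < k and attempts < 80 * k:
        attempts += 1
        m = rng.choice([x for x in n_sites if 2 <= x <= len(_MS_GROUPS)])
        kinds = rng.sample(range(len(_MS_GROUPS)), m)
        groups = []
        for gi in kinds:
            name, fmt, pool = _MS_GROUPS[gi]
            groups.append(fmt(rng.choice(pool)))
        if m == 2:
            smiles = f"c8c({groups[0]})cc({groups[1]})cc8"
        else:
            smiles = f"c8c({groups[0]})cc({groups[1]})cc8{groups[2]}"
        product = canonicalize(smiles, keep_maps=False)
        if product in seen:
            continue
        matches = match_sites(product, registry)
        classes = {t.class_label for t, _ in matches}
        if len(matches) < 2 or len(classes) < 2:
            continue
        all_atoms = [s for _, s in matches]
        if len(frozenset().union(*all_atoms)) != sum(len(s) for s in all_atoms):
            continue  # overlapping sites: not usable for steering checks
        seen.add(product)
        annotations = []
        for template, idxs in matches:
            tagged = tag_atoms(product, idxs)
            _, canon = strip_tags(tagged)
            annotations.append(
                SiteAnnotation(
                    template=template.name,
                    class_label=template.class_label,
                    atom_indices=idxs,
                    tagged=tagged,
                    canonical_site=canon,
                )
            )
        out.append(MultiSiteProduct(product=product, sites=tuple(annotations)))
    if len(out) < k:
        raise TemplateError(f"could only build {len(out)} of {k} multi-site products")
    return out


# ------------------------------------------------------------------- files


def write_fixtures(fixtures: Sequence[FixtureReaction], directory: str | Path) -> None:
    """Write ``reactions.txt`` plus a tab-separated sidecar ``annotations.tsv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "reactions.txt", "w") as fh:
        for fx in fixtures:
            fh.write(fx.line + "\n")
    with open(directory / "annotations.tsv", "w") as fh:
        fh.write("template\tclass_label\tsite_map_ids\tproduct\tspectators\tec_number\n")
        for fx in fixtures:
            fh.write(
                "\t".join(
                    [
                        fx.template,
                        fx.class_label,
                        ",".join(str(i) for i in sorted(fx.site.atom_map_ids)),
                        fx.product,
                        ".".join(fx.spectators),
                        fx.ec_number or "",
                    ]
                )
                + "\n"
            )


def read_fixture_annotations(directory: str | Path) -> list[dict]:
    """Read the sidecar back as a list of dicts (site ids as frozenset)."""
    directory = Path(directory)
    rows = []
    with open(directory / "annotations.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            rec = dict(zip(header, line.rstrip("\n").split("\t")))
            rec["site_map_ids"] = frozenset(
                int(x) for x in rec["site_map_ids"].split(",") if x
            )
            rec["spectators"] = tuple(x for x in rec["spectators"].split(".") if x)
            rec["ec_number"] = rec["ec_number"] or None
            rows.append(rec)
    return rows
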