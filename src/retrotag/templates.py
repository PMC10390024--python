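"""Reaction templates: paired retro/forward rules with known edited atoms.

A :class:`ReactionTemplate` carries

* a mapped product-side SMARTS locating the reactive core in a product,
  with the subset of query maps that constitutes the disconnection site;
* the retro surgery (bonds broken, order changes, capping fragments) that
  turns a matched product into precursors;
* mapped reactant-side SMARTS plus the inverse forward surgery (cap atoms
  removed, bonds formed, order changes), so ``forward(retro(p)) == p`` holds
  exactly for any product the template matches.

The default registry covers esterification, amide coupling, Williamson
ether synthesis, Suzuki biaryl coupling, and the Diels-Alder cycloaddition
(edited-atom counts 2, 2, 2, 2 and 6).  Registry order doubles as the
corpus-frequency order used by the tag-blind control translator.

The same template objects drive the synthetic fixture generator, so the
generator's recorded edited-atom sets and the translator oracle agree by
construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

from rdkit import Chem

from .chem_io import mol_from_smiles
from .errors import TemplateError

_BOND_TYPE = {
    1.0: Chem.BondType.SINGLE,
    2.0: Chem.BondType.DOUBLE,
    3.0: Chem.BondType.TRIPLE,
}

_SRC_MOL = "_rt_src_mol"
_SRC_IDX = "_rt_src_idx"


def _release_implicit_h(mol: Chem.Mol) -> None:
    """Let sanitization recompute hydrogen counts after bond surgery.

    Atoms parsed from bracket SMILES (e.g. tagged ``[OH:1]``) carry fixed
    explicit-H counts; after bonds are broken or formed those counts are
    stale.  Neutral, radical-free atoms are reset to implicit-H accounting;
    aromatic N-H and charged/radical atoms keep their explicit counts.
    """
    for atom in mol.GetAtoms():
        if (
            atom.GetFormalCharge() == 0
            and atom.GetNumRadicalElectrons() == 0
            and not (atom.GetIsAromatic() and atom.GetNumExplicitHs() > 0)
        ):
            atom.SetNumExplicitHs(0)
            atom.SetNoImplicit(False)


@dataclass(frozen=True)
class ReactionTemplate:
    """One reversible single-step transformation with a known edited-atom set."""

    name: str
    class_label: str
    n_tags_nominal: int
    # --- retro direction (product -> precursors) ---
    product_smarts: str
    site_maps: frozenset
    broken_bonds: tuple = ()            # ((qmap, qmap), ...)
    retro_order_changes: tuple = ()     # ((qmap, qmap, order), ...)
    caps: tuple = ()                    # ((qmap, fragment_smiles), ...)
    # --- forward direction (precursors -> product) ---
    reactant_smarts: tuple = ()
    cap_maps: frozenset = frozenset()   # query maps of atoms deleted going forward
    new_bonds: tuple = ()               # ((qmap, qmap, order), ...)
    forward_order_changes: tuple = ()
    _product_query: Chem.Mol = field(init=False, repr=False, compare=False, default=None)
    _reactant_queries: tuple = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        pq = Chem.MolFromSmarts(self.product_smarts)
        if pq is None:
            raise TemplateError(f"bad product SMARTS for {self.name}")
        rqs = []
        for s in self.reactant_smarts:
            q = Chem.MolFromSmarts(s)
            if q is None:
                raise TemplateError(f"bad reactant SMARTS for {self.name}: {s}")
            rqs.append(q)
        object.__setattr__(self, "_product_query", pq)
        object.__setattr__(self, "_reactant_queries", tuple(rqs))

    # ------------------------------------------------------------------ retro

    def _qmap_index(self, query: Chem.Mol) -> dict[int, int]:
        return {
            a.GetAtomMapNum(): a.GetIdx()
            for a in query.GetAtoms()
            if a.GetAtomMapNum() > 0
        }

    def product_matches(self, mol: Chem.Mol) -> list[dict[int, int]]:
        """All core matches as {query map -> product atom idx} dicts."""
        qidx = self._qmap_index(self._product_query)
        out = []
        for match in mol.GetSubstructMatches(self._product_query, uniquify=True):
            out.append({qm: match[qi] for qm, qi in qidx.items()})
        return out

    def sites(self, mol: Chem.Mol) -> list[frozenset]:
        """Distinct disconnection sites (product atom-index sets) in *mol*."""
        seen: list[frozenset] = []
        for m in self.product_matches(mol):
            s = frozenset(m[qm] for qm in self.site_maps)
            if s not in seen:
                seen.append(s)
        return seen

    def apply_retro(self, mol: Chem.Mol, match: dict[int, int]) -> tuple[str, ...]:
        """Cut the matched core; return canonical precursor components."""
        rw = Chem.RWMol(mol)
        _release_implicit_h(rw)
        for a, b in self.broken_bonds:
            rw.RemoveBond(match[a], match[b])
        for a, b, order in self.retro_order_changes:
            rw.GetBondBetweenAtoms(match[a], match[b]).SetBondType(_BOND_TYPE[order])
        for qm, frag_smiles in self.caps:
            frag = mol_from_smiles(frag_smiles)
            amap = {}
            for atom in frag.GetAtoms():
                new = Chem.Atom(atom.GetAtomicNum())
                amap[atom.GetIdx()] = rw.AddAtom(new)
            for bond in frag.GetBonds():
                rw.AddBond(
                    amap[bond.GetBeginAtomIdx()],
                    amap[bond.GetEndAtomIdx()],
                    bond.GetBondType(),
                )
            rw.AddBond(match[qm], amap[0], Chem.BondType.SINGLE)
        out = rw.GetMol()
        try:
            Chem.SanitizeMol(out)
        except Exception as exc:  # pragma: no cover - defensive
            raise TemplateError(f"retro surgery failed for {self.name}: {exc}")
        frags = Chem.GetMolFrags(out, asMols=True)
        return tuple(sorted(Chem.MolToSmiles(f) for f in frags))

    # ---------------------------------------------------------------- forward

    def iter_forward(
        self, mols: Sequence[Chem.Mol], max_matches: int = 8
    ) -> Iterator[tuple[Chem.Mol, dict]]:
        """Yield (product mol, provenance) for every way this template can
        combine a subset of *mols*.

        Provenance maps product atom idx -> (precursor index, precursor atom
        idx); precursors not consumed by the template contribute nothing.
        """
        nq = len(self._reactant_queries)
        if nq == 0 or len(mols) < nq:
            return
        for assignment in itertools.permutations(range(len(mols)), nq):
            per_query = []
            ok = True
            for qi, mi in enumerate(assignment):
                matches = mols[mi].GetSubstructMatches(
                    self._reactant_queries[qi], uniquify=True
                )[:max_matches]
                if not matches:
                    ok = False
                    break
                per_query.append(matches)
            if not ok:
                continue
            for combo in itertools.product(*per_query):
                result = self._forward_once(mols, assignment, combo)
                if result is not None:
                    yield result

    def _forward_once(self, mols, assignment, combo):
        # tag provenance, combine the assigned precursors, do the surgery
        tagged = []
        qmap_to_idx: dict[int, int] = {}
        offset = 0
        combined = None
        for qi, mi in enumerate(assignment):
            mol = Chem.Mol(mols[mi])
            _release_implicit_h(mol)
            for atom in mol.GetAtoms():
                atom.SetIntProp(_SRC_MOL, mi)
                atom.SetIntProp(_SRC_IDX, atom.GetIdx())
            qidx = self._qmap_index(self._reactant_queries[qi])
            for qm, q_atom in qidx.items():
                qmap_to_idx[qm] = offset + combo[qi][q_atom]
            offset += mol.GetNumAtoms()
            combined = mol if combined is None else Chem.CombineMols(combined, mol)
            tagged.append(mol)
        rw = Chem.RWMol(combined)
        for a, b, order in self.new_bonds:
            rw.AddBond(qmap_to_idx[a], qmap_to_idx[b], _BOND_TYPE[order])
        for a, b, order in self.forward_order_changes:
            rw.GetBondBetweenAtoms(qmap_to_idx[a], qmap_to_idx[b]).SetBondType(
                _BOND_TYPE[order]
            )
        for idx in sorted((qmap_to_idx[qm] for qm in self.cap_maps), reverse=True):
            rw.RemoveAtom(idx)
        out = rw.GetMol()
        try:
            Chem.SanitizeMol(out)
        except Exception:
            return None
        if len(Chem.GetMolFrags(out)) != 1:
            return None
        provenance = {
            atom.GetIdx(): (atom.GetIntProp(_SRC_MOL), atom.GetIntProp(_SRC_IDX))
            for atom in out.GetAtoms()
        }
        return out, provenance


# --------------------------------------------------------------------------
# default registry
# --------------------------------------------------------------------------

ESTER = ReactionTemplate(
    name="ester",
    class_label="Esterification",
    n_tags_nominal=2,
    product_smarts="[CX3:1](=[OX1:2])[OX2:3][#6:4]",
    site_maps=frozenset({1, 3}),
    broken_bonds=((1, 3),),
    caps=((1, "O"),),
    reactant_smarts=(
        "[CX3:1](=[OX1:2])[OX2H1:10]",
        "[OX2H1:3][#6;!$([CX3]=[OX1]):4]",
    ),
    cap_maps=frozenset({10}),
    new_bonds=((1, 3, 1.0),),
)

AMIDE = ReactionTemplate(
    name="amide",
    class_label="Amide coupling",
    n_tags_nominal=2,
    product_smarts="[CX3:1](=[OX1:2])[NX3:3]",
    site_maps=frozenset({1, 3}),
    broken_bonds=((1, 3),),
    caps=((1, "O"),),
    reactant_smarts=(
        "[CX3:1](=[OX1:2])[OX2H1:10]",
        "[NX3;H2;!$(N[CX3]=[OX1]):3][#6]",
    ),
    cap_maps=frozenset({10}),
    new_bonds=((1, 3, 1.0),),
)

ETHER = ReactionTemplate(
    name="ether",
    class_label="Williamson ether synthesis",
    n_tags_nominal=2,
    product_smarts="[CX4H2:1][OX2:2][CX4:3]",
    site_maps=frozenset({1, 2}),
    broken_bonds=((1, 2),),
    caps=((1, "Br"),),
    reactant_smarts=(
        "[CX4H2:1][Br:10]",
        "[OX2H1:2][CX4:3]",
    ),
    cap_maps=frozenset({10}),
    new_bonds=((1, 2, 1.0),),
)

BIARYL = ReactionTemplate(
    # Ullmann-type halide/halide coupling: symmetric caps keep the retro
    # direction-independent under the [c]-[c] match symmetry
    name="biaryl",
    class_label="Biaryl coupling",
    n_tags_nominal=2,
    product_smarts="[c:1]-[c:2]",
    site_maps=frozenset({1, 2}),
    broken_bonds=((1, 2),),
    caps=((1, "Br"), (2, "Br")),
    reactant_smarts=(
        "[c:1][Br:10]",
        "[c:2][Br:11]",
    ),
    cap_maps=frozenset({10, 11}),
    new_bonds=((1, 2, 1.0),),
)

DIELS_ALDER = ReactionTemplate(
    name="diels_alder",
    class_label="Diels-Alder cycloaddition",
    n_tags_nominal=6,
    product_smarts="[CX4:1]1[CX3:2]=[CX3:3][CX4:4][CX4:5][CX4:6]1",
    site_maps=frozenset({1, 2, 3, 4, 5, 6}),
    broken_bonds=((4, 5), (6, 1)),
    retro_order_changes=((1, 2, 2.0), (2, 3, 1.0), (3, 4, 2.0), (5, 6, 2.0)),
    reactant_smarts=(
        "[CX3;!R:1]=[CX3;!R:2][CX3;!R:3]=[CX3;!R:4]",
        "[CX3H2:5]=[CX3H2:6]",
    ),
    new_bonds=((4, 5, 1.0), (6, 1, 1.0)),
    forward_order_changes=((1, 2, 1.0), (2, 3, 2.0), (3, 4, 1.0), (5, 6, 1.0)),
)

#: Registry in corpus-frequency order (most frequent first); the tag-blind
#: control translator applies the first applicable template.
DEFAULT_REGISTRY: tuple[ReactionTemplate, ...] = (
    ESTER,
    AMIDE,
    ETHER,
    BIARYL,
    DIELS_ALDER,
)


def registry_by_name(registry: Sequence[ReactionTemplate] = DEFAULT_REGISTRY) -> dict[str, ReactionTemplate]:
    return {t.name: t for t in registry}


def match_sites(
    product_smiles: str, registry: Sequence[ReactionTemplate] = DEFAULT_REGISTRY
) -> list[tuple[ReactionTemplate, frozenset]]:
    """All (template, site atom-index set) pairs found in a product.

    Indices refer to the atom order of the parsed *product_smiles*; callers
    needing mapping-independent sites convert via
    :func:`retrotag.tagging.tag_atoms` / :class:`CanonicalSite`.
    """
    mol = mol_from_smiles(product_smiles)
    out: list[tuple[ReactionTemplate, frozenset]] = []
    for template in registry:
        for site in template.sites(mol):
            out.append((template, site))
    return out
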