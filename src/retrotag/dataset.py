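"""Corpus construction: filtering, splits, EC annotation, seq2seq files.

Variants
--------
``disconnection_aware``
    src = fully tagged product, tgt = ground-truth precursors.
``permuted``
    src = partially tagged product (sampled proper subsets of the site),
    tgt = ground-truth precursors.
``autocomplete``
    src = partially tagged product, tgt = fully tagged product.
``autotag``
    src = bare product, tgt = fully tagged product.

Filtering keeps single-product reactions with 2-10 (mapped) reactants and a
disconnection site of 1-10 atoms; reactions with no tagged atoms imply no
bond change and are removed, as are sites larger than ten atoms.  Splits are
90:5:5 by largest-remainder rounding, with all records of one product
assigned to the same split to prevent leakage across variants.

Enzymatic reactions carry their EC number as four hierarchical tokens after
a ``|`` separator on the source side; tagging always operates on the
EC-stripped SMILES.
"""

from __future__ import annotations

import random
import zlib
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .chem_io import (
    EC_PATTERN,
    MappedReaction,
    detokenize,
    parse_reaction_line,
    tokenize_smiles,
)
from .errors import DatasetError, MappingError
from .prompts import sample_partial_sites
from .tagging import DisconnectionSite, find_changed_atoms, insert_tags

VARIANTS = ("disconnection_aware", "permuted", "autocomplete", "autotag")
SPLITS = ("train", "valid", "test")

EC_SEPARATOR = "|"

DROP_REASONS = (
    "product_count",
    "reactant_count",
    "token_limit",
    "no_tags",
    "too_many_tags",
)


@dataclass(frozen=True)
class FilterConfig:
    """Reaction-level filtering and corpus-construction knobs."""

    min_reactants: int = 2
    max_reactants: int = 10
    min_tags: int = 1
    max_tags: int = 10
    max_tokens: int | None = None
    require_single_product: bool = True
    # permutation expansion (permuted / autocomplete variants)
    max_permuted_tags: int = 4
    permutation_cap: int = 20
    # precursor side composition and EC handling
    include_reagents: bool = True
    include_ec: bool = True

    def __post_init__(self) -> None:
        if self.min_reactants > self.max_reactants:
            raise DatasetError("min_reactants > max_reactants")
        if self.min_tags > self.max_tags:
            raise DatasetError("min_tags > max_tags")


@dataclass(frozen=True)
class PromptRecord:
    """One src/tgt training example."""

    src_tokens: tuple[str, ...]
    tgt_tokens: tuple[str, ...]
    variant: str
    n_tags: int
    product: str                       # canonical bare product (split grouping key)
    split: str | None = None
    ec_number: str | None = None

    @property
    def src(self) -> str:
        return detokenize(self.src_tokens)

    @property
    def tgt(self) -> str:
        return detokenize(self.tgt_tokens)


def filter_reaction(
    rxn: MappedReaction, site: DisconnectionSite, cfg: FilterConfig | None = None
) -> tuple[bool, str | None]:
    """Total filtering decision: (keep, drop reason).

    Reasons are drawn from :data:`DROP_REASONS`; the first failing check in
    that order is reported.
    """
    cfg = cfg or FilterConfig()
    # product multiplicity is enforced at parse time; kept for completeness
    if cfg.require_single_product and "." in rxn.product.bare_smiles:
        return False, "product_count"
    if not (cfg.min_reactants <= len(rxn.reactants) <= cfg.max_reactants):
        return False, "reactant_count"
    if cfg.max_tokens is not None:
        precursors = ".".join(s.bare_smiles for s in rxn.precursors)
        if (
            len(tokenize_smiles(rxn.product.bare_smiles)) > cfg.max_tokens
            or len(tokenize_smiles(precursors)) > cfg.max_tokens
        ):
            return False, "token_limit"
    if site.n_tags < cfg.min_tags:
        return False, "no_tags"
    if site.n_tags > cfg.max_tags:
        return False, "too_many_tags"
    return True, None


def _record_seed(seed: int, product: str) -> int:
    # order-independent per-product seed for permutation sampling
    return (seed ^ zlib.crc32(product.encode())) & 0x7FFFFFFF


def build_variant_corpus(
    reactions: Iterable[MappedReaction | str],
    variant: str,
    cfg: FilterConfig | None = None,
    seed: int = 0,
) -> tuple[list[PromptRecord], Counter]:
    """Filter reactions and emit the records of one dataset variant.

    Returns (records, drop-reason counts).  Reactions that cannot be tagged
    at all (unmapped product) count as ``no_tags``.
    """
    if variant not in VARIANTS:
        raise DatasetError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    cfg = cfg or FilterConfig()
    records: list[PromptRecord] = []
    drops: Counter = Counter()
    for item in reactions:
        rxn = parse_reaction_line(item) if isinstance(item, str) else item
        try:
            site = find_changed_atoms(rxn)
        except MappingError:
            drops["no_tags"] += 1
            continue
        keep, reason = filter_reaction(rxn, site, cfg)
        if not keep:
            drops[reason] += 1
            continue
        records.extend(_records_for(rxn, site, variant, cfg, seed))
    return records, drops


def _records_for(
    rxn: MappedReaction,
    site: DisconnectionSite,
    variant: str,
    cfg: FilterConfig,
    seed: int,
) -> list[PromptRecord]:
    product = rxn.product
    bare = product.bare_smiles
    species = list(rxn.reactants) + (list(rxn.reagents) if cfg.include_reagents else [])
    tgt_precursors = ".".join(sorted(s.bare_smiles for s in species))
    full_tagged = insert_tags(product, site).smiles

    pairs: list[tuple[str, str, int]] = []  # (src, tgt, n_tags)
    if variant == "disconnection_aware":
        pairs.append((full_tagged, tgt_precursors, site.n_tags))
    elif variant in ("permuted", "autocomplete"):
        partials = sample_partial_sites(
            site, cfg.max_permuted_tags, cfg.permutation_cap, _record_seed(seed, bare)
        )
        for partial in partials:
            src = insert_tags(product, DisconnectionSite(partial.subset)).smiles
            tgt = tgt_precursors if variant == "permuted" else full_tagged
            pairs.append((src, tgt, partial.n_tags))
    elif variant == "autotag":
        if site:
            pairs.append((bare, full_tagged, site.n_tags))

    out = []
    for src, tgt, n_tags in pairs:
        record = PromptRecord(
            src_tokens=tuple(tokenize_smiles(src)),
            tgt_tokens=tuple(tokenize_smiles(tgt)),
            variant=variant,
            n_tags=n_tags,
            product=bare,
        )
        if rxn.ec_number and cfg.include_ec:
            record = attach_ec(record, rxn.ec_number)
        out.append(record)
    return out


# ------------------------------------------------------------------ EC


def ec_tokens(ec: str) -> tuple[str, ...]:
    """Four hierarchical tokens for a 4-level EC number (``[EC1_1] ...``)."""
    if not EC_PATTERN.match(ec):
        raise DatasetError(f"malformed EC number: {ec!r}")
    return tuple(f"[EC{i + 1}_{part}]" for i, part in enumerate(ec.split(".")))


def attach_ec(record: PromptRecord, ec: str) -> PromptRecord:
    """Append the EC encoding to the source side after a ``|`` separator."""
    tokens = ec_tokens(ec)
    if EC_SEPARATOR in record.src_tokens:
        record = strip_ec(record)
    return replace(
        record,
        src_tokens=record.src_tokens + (EC_SEPARATOR,) + tokens,
        ec_number=ec,
    )


def strip_ec(record: PromptRecord) -> PromptRecord:
    """Inverse of :func:`attach_ec`; identity on records without EC suffix."""
    if EC_SEPARATOR not in record.src_tokens:
        return replace(record, ec_number=None) if record.ec_number else record
    cut = record.src_tokens.index(EC_SEPARATOR)
    return replace(record, src_tokens=record.src_tokens[:cut], ec_number=None)


# ------------------------------------------------------------------ splits


def _largest_remainder(n: int, ratios: Sequence[float]) -> list[int]:
    quotas = [n * r / sum(ratios) for r in ratios]
    counts = [int(q) for q in quotas]
    for i in sorted(
        range(len(quotas)), key=lambda i: quotas[i] - counts[i], reverse=True
    )[: n - sum(counts)]:
        counts[i] += 1
    return counts


def assign_splits(
    records: Sequence[PromptRecord],
    ratios: Sequence[float] = (90, 5, 5),
    seed: int = 0,
    group_by_product: bool = True,
) -> list[PromptRecord]:
    """Assign train/valid/test splits at exact largest-remainder proportions.

    With ``group_by_product`` (default) all records sharing one product land
    in the same split — the leakage guard across variants.  Exactness then
    requires group sizes to pack into the split targets; a seeded greedy
    fill (smallest splits first) plus a single-swap repair achieves this
    whenever sizes permit and raises :class:`DatasetError` otherwise.
    """
    if len(ratios) != len(SPLITS):
        raise DatasetError(f"expected {len(SPLITS)} ratios")
    if abs(sum(ratios) - 100) > 1e-9:
        raise DatasetError("split ratios must sum to 100")
    n = len(records)
    if n < len(SPLITS):
        raise DatasetError(f"need at least {len(SPLITS)} records, got {n}")
    targets = _largest_remainder(n, ratios)
    rng = random.Random(seed)

    if not group_by_product:
        order = list(range(n))
        rng.shuffle(order)
        assignment = {}
        pos = 0
        for split, count in zip(SPLITS, targets):
            for i in order[pos : pos + count]:
                assignment[i] = split
            pos += count
        return [replace(r, split=assignment[i]) for i, r in enumerate(records)]

    groups: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        groups.setdefault(r.product, []).append(i)
    keys = sorted(groups)
    rng.shuffle(keys)

    assigned: dict[str, str] = {}
    # fill the small splits exactly first; everything left is train
    for split, target in (("test", targets[2]), ("valid", targets[1])):
        need = target
        for key in keys:
            if key in assigned or need == 0:
                continue
            size = len(groups[key])
            if size <= need:
                assigned[key] = split
                need -= size
        if need:
            need = _swap_repair(groups, assigned, keys, split, need)
        if need:
            raise DatasetError(
                f"cannot reach exact {split} split size (short by {need}); "
                "group sizes do not pack — consider group_by_product=False"
            )
    for key in keys:
        assigned.setdefault(key, "train")
    return [replace(r, split=assigned[r.product]) for r in records]


def _swap_repair(groups, assigned, keys, split, need) -> int:
    # swap one assigned group for one unassigned, larger group
    members = [k for k in keys if assigned.get(k) == split]
    free = [k for k in keys if k not in assigned]
    for k_in in members:
        for k_out in free:
            if len(groups[k_out]) - len(groups[k_in]) == need:
                del assigned[k_in]
                assigned[k_out] = split
                return 0
    return need


# ------------------------------------------------------------------ files


def write_corpus(records: Sequence[PromptRecord], directory: str | Path) -> None:
    """Write the six aligned corpus files plus per-split metadata.

    Files are ``src-{split}.txt`` / ``tgt-{split}.txt`` with one
    space-separated token line per record, aligned by line number, and a
    ``meta-{split}.tsv`` sidecar carrying variant/n_tags/EC/product so that
    :func:`read_corpus` is an exact inverse.
    """
    unassigned = [r for r in records if r.split not in SPLITS]
    if unassigned:
        raise DatasetError(f"{len(unassigned)} records have no split assigned")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_split: dict[str, list[PromptRecord]] = {s: [] for s in SPLITS}
    for r in records:
        by_split[r.split].append(r)
    for split in SPLITS:
        with open(directory / f"src-{split}.txt", "w") as fh:
            fh.writelines(" ".join(r.src_tokens) + "\n" for r in by_split[split])
        with open(directory / f"tgt-{split}.txt", "w") as fh:
            fh.writelines(" ".join(r.tgt_tokens) + "\n" for r in by_split[split])
        with open(directory / f"meta-{split}.tsv", "w") as fh:
            fh.write("variant\tn_tags\tec_number\tproduct\n")
            fh.writelines(
                f"{r.variant}\t{r.n_tags}\t{r.ec_number or ''}\t{r.product}\n"
                for r in by_split[split]
            )


def read_corpus(directory: str | Path) -> list[PromptRecord]:
    """Read a corpus directory back into records (inverse of write_corpus)."""
    directory = Path(directory)
    out: list[PromptRecord] = []
    for split in SPLITS:
        src_lines = (directory / f"src-{split}.txt").read_text().splitlines()
        tgt_lines = (directory / f"tgt-{split}.txt").read_text().splitlines()
        if len(src_lines) != len(tgt_lines):
            raise DatasetError(
                f"corpus integrity error: src/tgt length mismatch in split {split} "
                f"({len(src_lines)} vs {len(tgt_lines)})"
            )
        meta_path = directory / f"meta-{split}.tsv"
        metas: list[dict] | None = None
        if meta_path.exists():
            lines = meta_path.read_text().splitlines()
            header = lines[0].split("\t")
            metas = [dict(zip(header, l.split("\t"))) for l in lines[1:]]
            if len(metas) != len(src_lines):
                raise DatasetError(
                    f"corpus integrity error: meta length mismatch in split {split}"
                )
        for i, (src, tgt) in enumerate(zip(src_lines, tgt_lines)):
            meta = metas[i] if metas else {}
            out.append(
                PromptRecord(
                    src_tokens=tuple(src.split()),
                    tgt_tokens=tuple(tgt.split()),
                    variant=meta.get("variant", "unknown"),
                    n_tags=int(meta.get("n_tags", 0)),
                    product=meta.get("product", ""),
                    split=split,
                    ec_number=meta.get("ec_number") or None,
                )
            )
    return out
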