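"""Incomplete-prompt permutations and the autocomplete/AutoTag pairings.

"Permutation" here is subset selection: tags form a set in the grammar, so
emulating incomplete user input means tagging a proper, non-empty subset of
the full disconnection site, up to a preset limit of four tagged atoms.
Products with a single tag are omitted (no proper subsets exist).  When the
enumeration is large it is sampled uniformly without replacement under a
seed.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass

from .chem_io import Species
from .errors import TaggingError
from .tagging import DisconnectionSite, TaggedProduct, insert_tags, strip_tags


@dataclass(frozen=True)
class PartialSite:
    """A proper, non-empty subset of a parent disconnection site."""

    subset: frozenset
    parent_n: int

    def __post_init__(self) -> None:
        if not (1 <= len(self.subset) < self.parent_n):
            raise TaggingError(
                f"partial site size {len(self.subset)} invalid for parent of {self.parent_n}"
            )

    @property
    def n_tags(self) -> int:
        return len(self.subset)


def enumerate_partial_sites(
    site: DisconnectionSite, max_permuted_tags: int = 4
) -> list[PartialSite]:
    """All non-empty proper subsets of the site, up to the permutation limit.

    Returned in deterministic order (subset size, then sorted member tuple).
    Sites with one tag (or none) yield an empty list — the record is skipped
    by corpus construction, not an error.
    """
    n = site.n_tags
    if n <= 1:
        return []
    members = sorted(site.atom_map_ids)
    out: list[PartialSite] = []
    for k in range(1, min(n - 1, max_permuted_tags) + 1):
        for combo in itertools.combinations(members, k):
            out.append(PartialSite(frozenset(combo), parent_n=n))
    return out


def sample_partial_sites(
    site: DisconnectionSite,
    max_permuted_tags: int = 4,
    cap: int = 20,
    seed: int = 0,
) -> list[PartialSite]:
    """Uniform sample (without replacement) of the subset enumeration.

    Returns the full enumeration when it is no larger than *cap*;
    reproducible under *seed*.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    full = enumerate_partial_sites(site, max_permuted_tags)
    if len(full) <= cap:
        return full
    return random.Random(seed).sample(full, cap)


def make_autocomplete_pair(
    product: Species | str, site: DisconnectionSite, partial: PartialSite
) -> tuple[TaggedProduct, TaggedProduct]:
    """(partially tagged product, fully tagged product) training pair."""
    if not partial.subset < site.atom_map_ids:
        raise TaggingError("partial site is not a proper subset of the full site")
    src = insert_tags(product, DisconnectionSite(partial.subset))
    tgt = insert_tags(product, site)
    return src, tgt


def make_autotag_pair(
    product: Species | str, site: DisconnectionSite
) -> tuple[str, TaggedProduct]:
    """(bare canonical product, fully tagged product) training pair."""
    if not site:
        raise TaggingError("cannot build an AutoTag pair from an empty site")
    tgt = insert_tags(product, site)
    bare, _ = strip_tags(tgt)
    return bare, tgt
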