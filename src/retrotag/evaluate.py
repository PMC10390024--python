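"""Evaluation stack: round-trip, disconnection, ground-truth and class metrics.

Round-trip accuracy asks whether the top-1 predicted precursors, pushed
through a forward reaction model, regenerate the input product.
Disconnection accuracy goes further: the reconstructed reaction (predicted
precursors >> forward-predicted product) is remapped and its changed atoms
recomputed; the prediction counts as correct iff the recomputed site equals
the prompted site exactly, compared on the product's canonical atom order.
The two are deliberately independent — a model can regenerate the product
from precursors that cut a different bond.

Ground-truth matching is set equality after standardization, reported both
over all species and restricted to mapped (product-contributing) species,
because unmapped reagents are highly variable in real corpora.  Class
diversity counts the unique reaction classes among the top-10 predictions
for one input.

All aggregate accuracies are reported stratified by the number of tagged
atoms (input tags for disconnection accuracy, predicted tags for
round-trip) rather than as a single overall number; empty bins are absent,
not 0%.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .chem_io import MappedReaction, canonicalize, standardize_component_set
from .errors import RetroTagError
from .tagging import (
    AtomMapper,
    CanonicalSite,
    DisconnectionSite,
    find_changed_atoms,
    recompute_site,
    site_on_product,
)
from .translate import (
    ForwardModelProtocol,
    ReactionClassifier,
    TranslationResult,
)


@dataclass(frozen=True)
class EvalInput:
    """Ground truth for one test record."""

    product: str                        # canonical, map-free
    prompt: CanonicalSite
    gt_precursors: tuple[str, ...]      # all species, standardized
    gt_mapped: tuple[str, ...]          # mapped (product-contributing) species only
    n_tags: int
    ec_number: str | None = None

    @classmethod
    def from_reaction(
        cls, rxn: MappedReaction, site: DisconnectionSite | None = None
    ) -> "EvalInput":
        site = site if site is not None else find_changed_atoms(rxn)
        return cls(
            product=rxn.product.bare_smiles,
            prompt=site_on_product(rxn.product, site),
            gt_precursors=standardize_component_set([s.smiles for s in rxn.precursors]),
            gt_mapped=standardize_component_set([s.smiles for s in rxn.reactants]),
            n_tags=site.n_tags,
            ec_number=rxn.ec_number,
        )


@dataclass(frozen=True)
class EvalRecord:
    """Per-record evaluation flags."""

    n_tags_input: int
    n_tags_predicted: int
    round_trip: bool
    disconnection_match: bool
    gt_match_all: bool
    gt_match_mapped_only: bool
    top10_classes: frozenset = frozenset()
    valid: bool = True
    forward_failed: bool = False
    mapper_failed: bool = False


# ------------------------------------------------------------- primitives


def round_trip_match(
    product: str,
    prediction: Sequence[str],
    forward: ForwardModelProtocol,
) -> tuple[bool, str | None]:
    """Does the forward model regenerate *product* from the prediction?

    Returns (flag, forward-predicted product).  Forward failure is a False
    outcome, not an error.
    """
    predicted = forward.predict_product(prediction)
    if predicted is None:
        return False, None
    try:
        return canonicalize(predicted) == canonicalize(product), predicted
    except RetroTagError:
        return False, predicted


def disconnection_site_match(
    prompt: CanonicalSite,
    prediction: Sequence[str],
    reconstructed_product: str | None,
    mapper: AtomMapper,
    lenient: bool = False,
) -> tuple[bool, CanonicalSite | None]:
    """Compare the prompt with the site recomputed from the prediction.

    The reconstructed reaction is ``prediction >> reconstructed_product``
    (normally the forward model's product).  Exact set equality by default;
    ``lenient`` accepts a recomputed site that is a superset of the prompt.
    Returns (flag, recomputed site or None on mapper failure).
    """
    if reconstructed_product is None:
        return False, None
    recomputed = recompute_site(reconstructed_product, list(prediction), mapper)
    if recomputed is None:
        return False, None
    if recomputed.product != prompt.product:
        return False, recomputed
    if lenient:
        return prompt.atom_indices <= recomputed.atom_indices, recomputed
    return recomputed.atom_indices == prompt.atom_indices, recomputed


def gt_match(
    prediction: Sequence[str],
    ground_truth: Sequence[str],
    exclude_unmapped: bool = False,
    mapper: AtomMapper | None = None,
    product: str | None = None,
) -> bool:
    """Set equality with the ground-truth precursors after standardization.

    With ``exclude_unmapped`` both sides are restricted to mapped
    (product-contributing) species: the caller passes the mapped-only ground
    truth, and the prediction is restricted by remapping it against
    *product* with *mapper* (species receiving no atom map are dropped).
    """
    pred = standardize_component_set(prediction)
    truth = standardize_component_set(ground_truth)
    if exclude_unmapped and mapper is not None and product is not None:
        pred = _restrict_to_mapped(pred, product, mapper)
    return pred == truth


def _restrict_to_mapped(
    prediction: tuple[str, ...], product: str, mapper: AtomMapper
) -> tuple[str, ...]:
    from .chem_io import parse_reaction_line  # local import to avoid cycle noise

    mapped_line = mapper.map_reaction(f"{'.'.join(prediction)}>>{product}")
    if mapped_line is None:
        return prediction
    try:
        rxn = parse_reaction_line(mapped_line)
    except RetroTagError:
        return prediction
    return standardize_component_set([s.smiles for s in rxn.reactants])


def class_diversity(
    predictions: Sequence[Sequence[str]],
    product: str,
    classifier: ReactionClassifier,
) -> int:
    """Number of unique reaction classes among the top-10 predictions.

    Unclassifiable predictions are excluded from the count.
    """
    labels = set()
    for precursors in list(predictions)[:10]:
        label = classifier.classify(f"{'.'.join(precursors)}>>{product}")
        if label is not None:
            labels.add(label)
    return len(labels)


def topn_gt_match(
    result: TranslationResult, ground_truth: Sequence[str], n: int = 10
) -> bool:
    """Whether any of the top-N standardized precursor sets equals ground truth."""
    truth = standardize_component_set(ground_truth)
    return any(
        standardize_component_set(p) == truth for p in result.ranked[:n]
    )


# --------------------------------------------------------------- pipeline


def evaluate_record(
    inp: EvalInput,
    result: TranslationResult,
    forward: ForwardModelProtocol,
    mapper: AtomMapper,
    classifier: ReactionClassifier | None = None,
    use_input_product: bool = False,
    lenient: bool = False,
) -> EvalRecord:
    """Evaluate one prediction against its ground truth.

    ``use_input_product`` remaps against the input product instead of the
    forward-predicted one when reconstructing the reaction.
    """
    if not result.ok:
        return EvalRecord(
            n_tags_input=inp.n_tags,
            n_tags_predicted=0,
            round_trip=False,
            disconnection_match=False,
            gt_match_all=False,
            gt_match_mapped_only=False,
            valid=False,
        )
    top1 = result.top1
    rt, forward_product = round_trip_match(inp.product, top1, forward)
    reconstructed = inp.product if use_input_product else forward_product
    disc, recomputed = disconnection_site_match(
        inp.prompt, top1, reconstructed, mapper, lenient=lenient
    )
    mapper_failed = reconstructed is not None and recomputed is None
    classes: frozenset = frozenset()
    if classifier is not None:
        labels = set()
        for precursors in result.ranked[:10]:
            label = classifier.classify(f"{'.'.join(precursors)}>>{inp.product}")
            if label is not None:
                labels.add(label)
        classes = frozenset(labels)
    return EvalRecord(
        n_tags_input=inp.n_tags,
        n_tags_predicted=recomputed.n_tags if recomputed is not None else 0,
        round_trip=rt,
        disconnection_match=disc,
        gt_match_all=gt_match(top1, inp.gt_precursors),
        gt_match_mapped_only=gt_match(
            top1, inp.gt_mapped, exclude_unmapped=True, mapper=mapper, product=inp.product
        ),
        top10_classes=classes,
        valid=not mapper_failed,
        forward_failed=forward_product is None,
        mapper_failed=mapper_failed,
    )


@dataclass(frozen=True)
class BinStat:
    count: int
    accuracy: float


@dataclass(frozen=True)
class EvalReport:
    """Aggregate metrics, stratified by number of tagged atoms.

    Disconnection accuracy is stratified by the input prompt's tag count and,
    recalibrated, by the predicted tag count; round-trip accuracy likewise.
    Bins with no records are simply absent.  Overall values are
    count-weighted means over valid records.
    """

    disconnection_by_input_tags: dict[int, BinStat]
    disconnection_by_predicted_tags: dict[int, BinStat]
    round_trip_by_input_tags: dict[int, BinStat]
    round_trip_by_predicted_tags: dict[int, BinStat]
    overall_disconnection: float
    overall_round_trip: float
    gt_match_all_rate: float
    gt_match_mapped_only_rate: float
    mean_class_diversity: float | None
    class_diversity_distribution: dict[int, int] = field(default_factory=dict)
    n_records: int = 0
    n_valid: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Per-bin table (one row per metric/stratification/bin)."""
        rows = []
        for name, bins in (
            ("disconnection_by_input_tags", self.disconnection_by_input_tags),
            ("disconnection_by_predicted_tags", self.disconnection_by_predicted_tags),
            ("round_trip_by_input_tags", self.round_trip_by_input_tags),
            ("round_trip_by_predicted_tags", self.round_trip_by_predicted_tags),
        ):
            for n_tags in sorted(bins):
                stat = bins[n_tags]
                rows.append(
                    {
                        "metric": name,
                        "n_tags": n_tags,
                        "count": stat.count,
                        "accuracy": stat.accuracy,
                    }
                )
        return pd.DataFrame(rows, columns=["metric", "n_tags", "count", "accuracy"])


def _bins(pairs: list[tuple[int, bool]]) -> dict[int, BinStat]:
    grouped: dict[int, list[bool]] = {}
    for n, flag in pairs:
        grouped.setdefault(n, []).append(flag)
    return {
        n: BinStat(count=len(flags), accuracy=sum(flags) / len(flags))
        for n, flags in grouped.items()
    }


def _rate(flags: list[bool]) -> float:
    return sum(flags) / len(flags) if flags else 0.0


def stratify(records: Sequence[EvalRecord]) -> EvalReport:
    """Aggregate per-record flags into the stratified report.

    Invalid records (no prediction / mapper failure) are counted in
    ``n_records`` but excluded from bins and rates.
    """
    valid = [r for r in records if r.valid]
    diversities = [len(r.top10_classes) for r in valid if r.top10_classes]
    return EvalReport(
        disconnection_by_input_tags=_bins(
            [(r.n_tags_input, r.disconnection_match) for r in valid]
        ),
        disconnection_by_predicted_tags=_bins(
            [(r.n_tags_predicted, r.disconnection_match) for r in valid]
        ),
        round_trip_by_input_tags=_bins(
            [(r.n_tags_input, r.round_trip) for r in valid]
        ),
        round_trip_by_predicted_tags=_bins(
            [(r.n_tags_predicted, r.round_trip) for r in valid]
        ),
        overall_disconnection=_rate([r.disconnection_match for r in valid]),
        overall_round_trip=_rate([r.round_trip for r in valid]),
        gt_match_all_rate=_rate([r.gt_match_all for r in valid]),
        gt_match_mapped_only_rate=_rate([r.gt_match_mapped_only for r in valid]),
        mean_class_diversity=(
            sum(diversities) / len(diversities) if diversities else None
        ),
        class_diversity_distribution=dict(Counter(diversities)),
        n_records=len(records),
        n_valid=len(valid),
    )


def evaluate_all(
    inputs: Sequence[EvalInput],
    results: Sequence[TranslationResult],
    forward: ForwardModelProtocol,
    mapper: AtomMapper,
    classifier: ReactionClassifier | None = None,
    use_input_product: bool = False,
    lenient: bool = False,
) -> tuple[list[EvalRecord], EvalReport]:
    """Evaluate aligned (input, prediction) pairs and aggregate."""
    if len(inputs) != len(results):
        raise ValueError("inputs and results must align")
    records = [
        evaluate_record(
            inp,
            res,
            forward,
            mapper,
            classifier=classifier,
            use_input_product=use_input_product,
            lenient=lenient,
        )
        for inp, res in zip(inputs, results)
    ]
    return records, stratify(records)
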