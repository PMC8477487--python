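"""Receptor-matched training-set construction.

Molecular breast-cancer subtype tracks ER/HER2 receptor status, so a naive
IBC vs non-IBC training set risks learning subtype rather than disease. The
remedy used here: pair each positive (IBC) training sample with a negative
(non-IBC) sample carrying the *identical* ordinal (er_score, her2_score)
pair. Within each receptor-score stratum any positive can pair with any
negative, so the maximum-cardinality exact matching is min(#pos, #neg) pairs
per stratum, taken in lexicographic sample-id order for determinism.

Optionally, up to ``allow_unmatched`` extra samples per class are appended
unmatched, chosen as the leftover positive/negative pairs whose score
vectors are closest in L1 distance on the (ER, HER2) grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_core import POSITIVE_CLASS, CohortError, ExpressionCohort


@dataclass
class MatchedDesign:
    """A matched case-control training design plus the untouched holdout."""

    training_pairs: list[tuple[str, str]]  # (positive id, negative id), exact score match
    unmatched_ids: list[str] = field(default_factory=list)
    holdout_ids: list[str] = field(default_factory=list)

    @property
    def training_ids(self) -> list[str]:
        ids = [s for pair in self.training_pairs for s in pair]
        ids.extend(self.unmatched_ids)
        return ids

    @property
    def n_matched(self) -> int:
        return 2 * len(self.training_pairs)


def match_training_set(
    cohort: ExpressionCohort,
    allow_unmatched: int = 0,
    positive_label: str = POSITIVE_CLASS,
    negative_label: str = "nonIBC",
) -> MatchedDesign:
    """Build the receptor-matched training design.

    Exact maximum matching on the (er_score, her2_score) pair, stratum by
    stratum; ties broken by lexicographic sample-id order so the result is
    invariant to input sample order. Up to ``allow_unmatched`` additional
    samples *per class* are appended unmatched, picked as the leftover
    positive/negative combination with the smallest L1 score distance.
    Holdout is every cohort sample not in training (normals included).
    """
    positives = sorted(cohort.samples_with_label(positive_label))
    negatives = sorted(cohort.samples_with_label(negative_label))
    if not positives or not negatives:
        raise CohortError(
            f"matching needs >=1 {positive_label} and >=1 {negative_label} sample"
        )
    for sid in positives + negatives:
        ann = cohort.annotation(sid)
        if ann.er_score is None or ann.her2_score is None:
            raise CohortError(f"sample {sid!r} lacks a receptor score")

    def score(sid: str) -> tuple[int, int]:
        ann = cohort.annotation(sid)
        return (ann.er_score, ann.her2_score)

    strata: dict[tuple[int, int], tuple[list[str], list[str]]] = {}
    for sid in positives:
        strata.setdefault(score(sid), ([], []))[0].append(sid)
    for sid in negatives:
        strata.setdefault(score(sid), ([], []))[1].append(sid)

    pairs: list[tuple[str, str]] = []
    for key in sorted(strata):
        pos, neg = strata[key]
        for p, n in zip(pos, neg):  # both lex-sorted; min(|pos|,|neg|) pairs
            pairs.append((p, n))

    used = {s for pair in pairs for s in pair}
    unmatched: list[str] = []
    if allow_unmatched > 0:
        left_pos = [s for s in positives if s not in used]
        left_neg = [s for s in negatives if s not in used]
        candidates = sorted(
            (
                (
                    abs(score(p)[0] - score(n)[0]) + abs(score(p)[1] - score(n)[1]),
                    p,
                    n,
                )
                for p in left_pos
                for n in left_neg
            ),
        )
        taken_p: list[str] = []
        taken_n: list[str] = []
        for _, p, n in candidates:
            if len(taken_p) >= allow_unmatched:
                break
            if p in taken_p or n in taken_n:
                continue
            taken_p.append(p)
            taken_n.append(n)
        unmatched = sorted(taken_p + taken_n)

    if not pairs and not unmatched:
        raise CohortError(
            "no receptor-score stratum admits an exact positive/negative pair "
            "and allow_unmatched=0: empty design"
        )

    training = {s for pair in pairs for s in pair} | set(unmatched)
    holdout = [s for s in cohort.sample_ids if s not in training]
    return MatchedDesign(training_pairs=pairs, unmatched_ids=unmatched, holdout_ids=holdout)


def split_half(
    cohort: ExpressionCohort,
    seed: int,
    labels: tuple[str, str] = (POSITIVE_CLASS, "nonIBC"),
) -> tuple[list[str], list[str]]:
    """Stratified half split: per class, ceil(n/2) samples go to training
    (the extra sample on odd counts), the rest to holdout. Pure function of
    the seed."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 10]))
    training: list[str] = []
    holdout: list[str] = []
    for label in labels:
        members = sorted(cohort.samples_with_label(label))
        if len(members) < 2:
            raise CohortError(f"class {label!r} has fewer than 2 samples")
        perm = rng.permutation(len(members))
        n_train = math.ceil(len(members) / 2)
        chosen = {members[i] for i in perm[:n_train]}
        training.extend(s for s in members if s in chosen)
        holdout.extend(s for s in members if s not in chosen)
    return training, holdout
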