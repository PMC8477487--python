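"""End-to-end signature discovery, validation and specificity testing.

The discovery protocol: build a receptor-matched training set, fit the
bagged ensemble on *all* genes, rank genes by predictor importance, and keep
the top-k (default 59) as the signature. Validation retrains an ensemble
restricted to the signature genes and scores every sample of a cohort
(normals count as negatives). Specificity is assessed against a random-set
null: the distribution of holdout accuracy achieved by ensembles trained on
uniformly random gene sets of the signature's size, summarized by an
add-one empirical p-value.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from .forest import ForestConfig, ForestModel, importance, predict_proba, train_forest
from .io_core import (
    POSITIVE_CLASS,
    ClassificationResult,
    CohortError,
    ExpressionCohort,
    GeneSignature,
)
from .matching import MatchedDesign

logger = logging.getLogger("ibcsig")


# ---------------------------------------------------------------------------
# accuracy helper


def labelled_accuracy(
    cohort: ExpressionCohort,
    result: ClassificationResult,
    positive_label: str = POSITIVE_CLASS,
) -> float:
    """Fraction of class-annotated samples called correctly.

    Every non-positive label (non-IBC *and* normal) counts as negative, so a
    normal sample scored above threshold is an error.
    """
    correct = total = 0
    for sid, called_pos in zip(result.sample_ids, result.predicted_label, strict=True):
        label = cohort.class_of(sid)
        if label is None:
            continue
        total += 1
        correct += called_pos == (label == positive_label)
    if total == 0:
        raise CohortError("no class-annotated samples to score")
    return correct / total


# ---------------------------------------------------------------------------
# discovery


def discover_signature(
    cohort: ExpressionCohort,
    design: MatchedDesign,
    k: int = 59,
    cfg: ForestConfig | None = None,
    mode: str = "recursive",
    elim_fraction: float = 0.5,
    name: str = "signature",
) -> GeneSignature:
    """Derive a top-k gene signature from the matched training set.

    ``mode="recursive"`` (default) iteratively re-ranks: fit the ensemble on
    the surviving genes over ``design.training_ids``, keep the top
    ``elim_fraction`` by importance, and repeat until k genes remain — with a
    few dozen training samples this repeated re-ranking recovers planted
    genes markedly better than one pass, because each round re-estimates
    importance on a smaller, less diluted gene universe. ``mode="single"``
    is the one-shot variant: a single fit on all genes, take the top k.
    Deterministic for a fixed ``cfg.seed`` (each round derives its own seed).
    """
    cfg = cfg or ForestConfig()
    if k > cohort.n_genes:
        raise CohortError(f"k={k} exceeds the {cohort.n_genes}-gene universe")
    if mode not in ("recursive", "single"):
        raise CohortError(f"unknown discovery mode {mode!r}")
    if not 0.0 < elim_fraction < 1.0:
        raise CohortError("elim_fraction must lie strictly between 0 and 1")

    genes = list(cohort.gene_ids)
    round_no = 0
    while True:
        round_cfg = dataclasses.replace(cfg, seed=int(cfg.seed) * 1009 + round_no)
        model = train_forest(cohort, design.training_ids, genes, round_cfg)
        ranking = importance(model)
        if mode == "single" or len(genes) <= k:
            break
        genes = ranking.genes[: max(k, int(len(genes) * elim_fraction))]
        round_no += 1
    genes, scores = ranking.top(k)
    return GeneSignature(
        genes=genes,
        importance=scores,
        name=name,
        provenance=(
            f"discovered from {len(design.training_ids)} training samples "
            f"({design.n_matched} receptor-matched), mode={mode}, "
            f"n_trees={cfg.n_trees}, seed={cfg.seed}, k={k}"
        ),
    )


# ---------------------------------------------------------------------------
# validation


def validate_signature(
    cohort: ExpressionCohort,
    sig: GeneSignature,
    training_ids,
    cfg: ForestConfig | None = None,
    eval_cohort: ExpressionCohort | None = None,
) -> tuple[ForestModel, ClassificationResult, float]:
    """Retrain an ensemble restricted to the signature genes and score a
    whole cohort.

    Training samples come from ``cohort``; scoring covers every sample of
    ``eval_cohort`` (default: ``cohort`` itself, the within-cohort protocol).
    Accuracy is computed over all class-annotated evaluation samples with
    normals counted negative.
    """
    cfg = cfg or ForestConfig()
    eval_cohort = eval_cohort if eval_cohort is not None else cohort
    missing = [g for g in sig.genes if g not in set(eval_cohort.gene_ids)]
    if missing:
        raise CohortError(f"signature genes missing from evaluation cohort: {missing}")
    model = train_forest(cohort, training_ids, sig.genes, cfg)
    result = predict_proba(model, eval_cohort)
    acc = labelled_accuracy(eval_cohort, result)
    return model, result, acc


# ---------------------------------------------------------------------------
# random-set null


@dataclass
class NullAccuracyDistribution:
    """Holdout accuracies of ensembles trained on random gene sets, plus the
    add-one empirical p-value of the observed accuracy."""

    accuracies: list[float]
    n_iterations: int
    set_size: int
    observed_accuracy: float
    empirical_p: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.accuracies) != self.n_iterations:
            raise CohortError("accuracy list length differs from n_iterations")
        exceed = sum(a >= self.observed_accuracy for a in self.accuracies)
        self.empirical_p = (1 + exceed) / (self.n_iterations + 1)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))


def random_set_null(
    cohort: ExpressionCohort,
    design: MatchedDesign,
    set_size: int,
    n_iterations: int,
    observed_accuracy: float,
    cfg: ForestConfig | None = None,
    seed: int = 0,
    eval_cohort: ExpressionCohort | None = None,
) -> NullAccuracyDistribution:
    """Null distribution of accuracy from size-matched random gene sets.

    Per iteration: draw ``set_size`` genes uniformly without replacement,
    train on the design's training samples, and score a fixed evaluation
    set — the design's holdout samples by default, or every sample of
    ``eval_cohort`` when the observed accuracy was measured on an
    independent cohort. The same evaluation samples are used for every
    iteration, so the null and observed accuracies are directly comparable.
    The reference protocol uses ``set_size=59`` with 10,000 iterations.
    """
    cfg = cfg or ForestConfig()
    if set_size > cohort.n_genes:
        raise CohortError(f"set_size={set_size} exceeds gene universe")
    if n_iterations < 1:
        raise CohortError("n_iterations must be >= 1")
    if eval_cohort is None and not design.holdout_ids:
        raise CohortError("design has no holdout samples to evaluate on")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 30]))
    accuracies: list[float] = []
    for it in range(n_iterations):
        genes = [cohort.gene_ids[i] for i in rng.choice(cohort.n_genes, set_size, False)]
        it_cfg = dataclasses.replace(cfg, seed=int(rng.integers(2**31)))
        model = train_forest(cohort, design.training_ids, genes, it_cfg)
        if eval_cohort is None:
            result = predict_proba(model, cohort, design.holdout_ids)
            accuracies.append(labelled_accuracy(cohort, result))
        else:
            result = predict_proba(model, eval_cohort)
            accuracies.append(labelled_accuracy(eval_cohort, result))
    return NullAccuracyDistribution(
        accuracies=accuracies,
        n_iterations=n_iterations,
        set_size=set_size,
        observed_accuracy=observed_accuracy,
    )


# ---------------------------------------------------------------------------
# signature comparison


@dataclass
class OverlapReport:
    """Pairwise intersections and Jaccard indices between signatures."""

    names: list[str]
    intersections: dict[tuple[str, str], list[str]]
    jaccard: dict[tuple[str, str], float]

    def count(self, a: str, b: str) -> int:
        return len(self.intersections[(a, b) if (a, b) in self.intersections else (b, a)])


def compare_signatures(
    signatures: list[GeneSignature], case_fold: bool = False
) -> OverlapReport:
    """Pairwise gene overlap between signatures (exact id matching, with
    optional case folding)."""
    if len(signatures) < 2:
        raise CohortError("need at least 2 signatures to compare")
    names = []
    for i, sig in enumerate(signatures):
        names.append(sig.name or f"signature_{i + 1}")
    if len(set(names)) != len(names):
        names = [f"{n}#{i + 1}" for i, n in enumerate(names)]

    def norm(genes):
        return {g.casefold() if case_fold else g for g in genes}

    intersections: dict[tuple[str, str], list[str]] = {}
    jaccard: dict[tuple[str, str], float] = {}
    for i in range(len(signatures)):
        for j in range(i + 1, len(signatures)):
            a, b = norm(signatures[i].genes), norm(signatures[j].genes)
            inter = sorted(a & b)
            union = a | b
            key = (names[i], names[j])
            intersections[key] = inter
            jaccard[key] = len(inter) / len(union) if union else 0.0
    return OverlapReport(names=names, intersections=intersections, jaccard=jaccard)


# ---------------------------------------------------------------------------
# uniform benchmarking


@dataclass
class BenchmarkEntry:
    signature: str
    cohort: str
    accuracy: float | None  # None when flagged non-comparable
    n_genes_used: int
    n_genes_missing: int
    comparable: bool


def benchmark_signatures(
    cohorts: dict[str, tuple[ExpressionCohort, list[str]]],
    signatures: list[GeneSignature],
    cfg: ForestConfig | None = None,
) -> list[BenchmarkEntry]:
    """Uniform accuracy comparison of several signatures across cohorts.

    ``cohorts`` maps cohort name to (cohort, training sample ids); the same
    training split and seed are reused for every signature so the comparison
    is fair. Signature genes missing from a cohort are dropped with a logged
    warning; a signature losing more than half its genes is flagged
    non-comparable instead of scored.
    """
    cfg = cfg or ForestConfig()
    entries: list[BenchmarkEntry] = []
    for cname, (cohort, training_ids) in cohorts.items():
        universe = set(cohort.gene_ids)
        for i, sig in enumerate(signatures):
            sname = sig.name or f"signature_{i + 1}"
            present = [g for g in sig.genes if g in universe]
            n_missing = len(sig.genes) - len(present)
            if n_missing > 0:
                logger.warning(
                    "benchmark: %s loses %d/%d genes in cohort %s",
                    sname, n_missing, len(sig.genes), cname,
                )
            if len(present) * 2 < len(sig.genes) or not present:
                entries.append(
                    BenchmarkEntry(sname, cname, None, len(present), n_missing, False)
                )
                continue
            sub = GeneSignature(genes=present, name=sname)
            _, _, acc = validate_signature(cohort, sub, training_ids, cfg)
            entries.append(
                BenchmarkEntry(sname, cname, acc, len(present), n_missing, True)
            )
    return entries
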