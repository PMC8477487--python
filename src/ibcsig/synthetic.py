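"""Synthetic expression-cohort simulator.

Generates cohorts with the statistical structure the discovery/validation
pipeline assumes, so every downstream stage (matched training, importance
ranking, cross-cohort validation, random-set null, clustering, survival) is
testable without any external download.

The generative model, per gene g and sample s on the log2 scale::

    x[g, s] = baseline[g] + delta[g] * 1{class(s) = IBC} + eps[g, s]

* ``baseline[g] ~ Normal(8, 1.5)`` — a microarray-like per-gene average;
* ``eps ~ Normal(0, noise_sd)`` i.i.d.;
* ``delta[g] = sign[g] * effect_size * noise_sd`` for the ``n_signal``
  planted genes (sign drawn uniformly per gene so the signature is
  bidirectional, giving the familiar two-block heatmap) and 0 otherwise;
* normal-tissue samples carry no shift.

Validation cohorts reuse the same planted genes and effect directions but add
a batch effect (global offset plus per-gene jitter) and, in ``post`` mode,
attenuate the planted effect — emulating the loss of signal in biopsies taken
after chemotherapy.

Survival times are exponential with a class-dependent hazard; censoring is
independent of the event process.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_core import (
    POSITIVE_CLASS,
    CohortError,
    ExpressionCohort,
    SampleAnnotation,
)
from .survival import SurvivalTable

_BASELINE_MEAN = 8.0
_BASELINE_SD = 1.5

#: default joint distribution of (er_score, her2_score) pairs, shared by the
#: IBC and non-IBC classes so that most samples are exactly matchable (with
#: 20 vs 20 draws from this grid, ~90% of samples find an exact partner).
DEFAULT_RECEPTOR_GRID: tuple[tuple[tuple[int, int], float], ...] = (
    ((0, 0), 0.20),
    ((0, 3), 0.15),
    ((1, 0), 0.10),
    ((2, 0), 0.10),
    ((3, 0), 0.20),
    ((3, 1), 0.10),
    ((3, 3), 0.15),
)


@dataclass
class SurvivalConfig:
    """Exponential survival model: hazard ``h0`` for the negative class,
    ``h0 * hazard_ratio`` for the positive class; ``censoring_rate`` is the
    probability that a subject is censored (at a uniform time before its
    event) rather than observed."""

    baseline_hazard: float = 0.05
    hazard_ratio: float = 3.15
    censoring_rate: float = 0.3

    def validate(self) -> None:
        if self.baseline_hazard <= 0:
            raise CohortError("baseline_hazard must be > 0")
        if self.hazard_ratio <= 0:
            raise CohortError("hazard_ratio must be > 0")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise CohortError("censoring_rate must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Study conditions for the simulator; defaults mirror the discovery
    cohort design (2000 genes, a 59-gene bidirectional planted signature at
    1.5 noise-SD effect, 20 IBC / 20 non-IBC / 5 normal samples)."""

    n_genes: int = 2000
    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"IBC": 20, "nonIBC": 20, "normal": 5}
    )
    n_signal: int = 59
    effect_size: float = 1.5
    noise_sd: float = 1.0
    batch_shift: float = 0.5
    batch_jitter_sd: float = 0.3
    attenuation: float = 0.2
    receptor_grid: tuple = DEFAULT_RECEPTOR_GRID
    matchable_fraction: float = 0.9
    laplace_noise: bool = False
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_signal < 0:
            raise CohortError("n_genes must be positive and n_signal non-negative")
        if self.n_signal > self.n_genes:
            raise CohortError("n_signal exceeds n_genes")
        if not 0.0 <= self.attenuation <= 1.0:
            raise CohortError("attenuation must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise CohortError("noise_sd must be > 0")
        for label, n in self.n_per_class.items():
            if n <= 0:
                raise CohortError(f"class {label!r} has non-positive count {n}")
        probs = [p for _, p in self.receptor_grid]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise CohortError("receptor grid probabilities must be a distribution")
        if not 0.0 <= self.matchable_fraction <= 1.0:
            raise CohortError("matchable_fraction must lie in [0, 1]")
        self.survival.validate()


@dataclass
class SimulationTruth:
    """Ground truth of a simulated cohort, for parameter-recovery tests."""

    planted_genes: list[str]
    effect_signs: dict[str, int]  # gene -> +1 / -1
    baseline: np.ndarray  # per-gene baseline means, aligned to gene order
    true_class: dict[str, str]
    hazard_ratio: float


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def _noise(rng: np.random.Generator, cfg: SimulationConfig, shape) -> np.ndarray:
    if cfg.laplace_noise:
        # Laplace with the same SD as the Gaussian default
        return rng.laplace(0.0, cfg.noise_sd / np.sqrt(2.0), size=shape)
    return rng.normal(0.0, cfg.noise_sd, size=shape)


def _receptor_draw(rng: np.random.Generator, cfg: SimulationConfig, n: int):
    pairs = [p for p, _ in cfg.receptor_grid]
    probs = np.asarray([q for _, q in cfg.receptor_grid])
    idx = rng.choice(len(pairs), size=n, p=probs / probs.sum())
    return [pairs[i] for i in idx]


def _assign_receptors(rng: np.random.Generator, cfg: SimulationConfig, labels):
    """Receptor score pairs per sample.

    Scores are drawn iid from the configured grid, after which a
    ``matchable_fraction`` of the smaller IBC/non-IBC class is guaranteed an
    exact partner by copying score pairs across classes — emulating a cohort
    assembled so most training samples are receptor-matchable.
    """
    pairs = _receptor_draw(rng, cfg, len(labels))
    pos = [i for i, lab in enumerate(labels) if lab == POSITIVE_CLASS]
    neg = [i for i, lab in enumerate(labels) if lab == "nonIBC"]
    n_match = int(round(cfg.matchable_fraction * min(len(pos), len(neg))))
    if n_match > 0 and pos and neg:
        donors = rng.choice(pos, size=n_match, replace=False)
        receivers = rng.choice(neg, size=n_match, replace=False)
        for d, r in zip(donors, receivers, strict=True):
            pairs[r] = pairs[d]
    return pairs


def _build_samples(cfg: SimulationConfig, prefix: str):
    sample_ids, labels = [], []
    for label in sorted(cfg.n_per_class):
        for i in range(cfg.n_per_class[label]):
            sample_ids.append(f"{prefix}_{label}_{i + 1:03d}")
            labels.append(label)
    return sample_ids, labels


def simulate_cohort(cfg: SimulationConfig) -> tuple[ExpressionCohort, SimulationTruth]:
    """Generate a discovery cohort plus its ground truth.

    Pure function of ``cfg`` (including ``cfg.seed``): identical inputs give
    bit-identical outputs.
    """
    cfg.validate()
    rng = _rng(cfg.seed, 0)

    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    baseline = rng.normal(_BASELINE_MEAN, _BASELINE_SD, size=cfg.n_genes)
    planted_idx = rng.choice(cfg.n_genes, size=cfg.n_signal, replace=False)
    signs = rng.choice([-1, 1], size=cfg.n_signal)

    sample_ids, labels = _build_samples(cfg, "D")
    n_samples = len(sample_ids)
    values = baseline[:, None] + _noise(rng, cfg, (cfg.n_genes, n_samples))
    delta = cfg.effect_size * cfg.noise_sd
    pos_cols = [j for j, lab in enumerate(labels) if lab == POSITIVE_CLASS]
    for gi, sgn in zip(planted_idx, signs, strict=True):
        values[gi, pos_cols] += sgn * delta

    annotations: dict[str, SampleAnnotation] = {}
    receptor_pairs = _assign_receptors(rng, cfg, labels)
    for sid, lab, (er, her2) in zip(sample_ids, labels, receptor_pairs, strict=True):
        annotations[sid] = SampleAnnotation(
            sample_id=sid,
            class_label=lab,
            er_score=er,
            her2_score=her2,
            treatment="pre",
        )

    cohort = ExpressionCohort(gene_ids, sample_ids, values, annotations)
    truth = SimulationTruth(
        planted_genes=[gene_ids[i] for i in planted_idx],
        effect_signs={gene_ids[i]: int(s) for i, s in zip(planted_idx, signs, strict=True)},
        baseline=baseline,
        true_class=dict(zip(sample_ids, labels, strict=True)),
        hazard_ratio=cfg.survival.hazard_ratio,
    )
    return cohort, truth


def simulate_validation_cohort(
    cfg: SimulationConfig,
    truth: SimulationTruth,
    mode: str = "pre",
    n_per_class: dict[str, int] | None = None,
    seed: int | None = None,
) -> ExpressionCohort:
    """Generate an independent cohort sharing the discovery cohort's planted
    genes and effect directions.

    A batch effect (``cfg.batch_shift`` global offset plus per-gene
    ``Normal(0, cfg.batch_jitter_sd)`` jitter) is applied to all values. In
    ``mode="post"`` the planted effect is multiplied by ``cfg.attenuation``,
    emulating post-chemotherapy expression changes; ``mode="pre"`` keeps the
    full effect. Class counts default to the pre-treatment external cohort
    design (33 IBC vs 28 non-IBC).
    """
    cfg.validate()
    if mode not in ("pre", "post"):
        raise CohortError(f"mode must be 'pre' or 'post', got {mode!r}")
    if n_per_class is None:
        n_per_class = {"IBC": 33, "nonIBC": 28}
    vcfg = replace(cfg, n_per_class=dict(n_per_class))
    rng = _rng(cfg.seed if seed is None else seed, 1 if mode == "pre" else 2)

    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    if set(truth.planted_genes) - set(gene_ids):
        raise CohortError("truth planted genes inconsistent with configured n_genes")

    prefix = "VPRE" if mode == "pre" else "VPOST"
    sample_ids, labels = _build_samples(vcfg, prefix)
    n_samples = len(sample_ids)

    values = truth.baseline[:, None] + _noise(rng, cfg, (cfg.n_genes, n_samples))
    effect_scale = 1.0 if mode == "pre" else cfg.attenuation
    delta = cfg.effect_size * cfg.noise_sd * effect_scale
    pos_cols = [j for j, lab in enumerate(labels) if lab == POSITIVE_CLASS]
    gidx = {g: i for i, g in enumerate(gene_ids)}
    for g in truth.planted_genes:
        values[gidx[g], pos_cols] += truth.effect_signs[g] * delta

    # batch effect: global offset + frozen per-gene jitter
    values += cfg.batch_shift
    values += rng.normal(0.0, cfg.batch_jitter_sd, size=cfg.n_genes)[:, None]

    annotations: dict[str, SampleAnnotation] = {}
    receptor_pairs = _receptor_draw(rng, vcfg, n_samples)
    for sid, lab, (er, her2) in zip(sample_ids, labels, receptor_pairs, strict=True):
        annotations[sid] = SampleAnnotation(
            sample_id=sid,
            class_label=lab,
            er_score=er,
            her2_score=her2,
            treatment=mode,
        )
    return ExpressionCohort(gene_ids, sample_ids, values, annotations)


def simulate_survival(
    labels: dict[str, bool], cfg: SimulationConfig, seed: int | None = None
) -> SurvivalTable:
    """Draw exponential survival outcomes for binary-labelled samples.

    Positive samples (``True``) have hazard ``h0 * hazard_ratio``; negatives
    ``h0``. With probability ``censoring_rate`` a subject is censored at a
    uniform time before its event. Pure function of the seed.
    """
    cfg.validate()
    scfg = cfg.survival
    rng = _rng(cfg.seed if seed is None else seed, 3)

    sample_ids = list(labels)
    groups = ["positive" if labels[s] else "negative" for s in sample_ids]
    hazards = np.where(
        [labels[s] for s in sample_ids],
        scfg.baseline_hazard * scfg.hazard_ratio,
        scfg.baseline_hazard,
    )
    event_times = rng.exponential(1.0 / hazards)
    censored = rng.random(len(sample_ids)) < scfg.censoring_rate
    times = np.where(censored, rng.random(len(sample_ids)) * event_times, event_times)
    events = (~censored).astype(int)
    return SurvivalTable(
        sample_ids=sample_ids,
        time=times.tolist(),
        event=events.tolist(),
        group=groups,
    )
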