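"""Molecular subtyping and survival analysis.

Two independent facilities live here:

* **Nearest-centroid subtyping** — each sample's expression over a panel gene
  list is rank-correlated (Spearman) against five intrinsic-subtype centroids
  (Luminal A, Luminal B, HER2-enriched, Basal-like, Normal-like); the call is
  the argmax correlation, and a risk-of-recurrence (ROR) score is the affinely
  rescaled weighted sum of the subtype correlations. The centroid panel is a
  pluggable text file, so any published centroid/coefficient set can be
  supplied; :func:`synthetic_demo_panel` builds a small synthetic panel for
  testing and examples.

* **Survival comparison of two groups** — Kaplan–Meier product-limit curves,
  the Mantel–Haenszel log-rank test over event times, and an O/E hazard ratio
  ``(O1/E1)/(O2/E2)`` with a log-scale 95% CI using variance ``1/E1 + 1/E2``.
  Tied event times are handled by the simultaneous-event convention in both
  the KM estimator and the log-rank tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .io_core import CohortError, ExpressionCohort, _delimiter_for

SUBTYPES = ("LumA", "LumB", "Her2", "Basal", "Normal")

#: published ROR-S subtype weights (risk-of-recurrence, subtype-only variant)
ROR_S_COEFFICIENTS = {
    "Basal": 0.05,
    "Her2": 0.12,
    "LumA": -0.34,
    "LumB": 0.23,
    "Normal": 0.0,
}


# ---------------------------------------------------------------------------
# centroid panel


@dataclass
class CentroidPanel:
    """Per-subtype centroid vectors over a panel gene list, plus the ROR
    weights and affine rescaling constants (``ror = offset + scale * sum_s
    coef[s] * corr[s]``)."""

    genes: list[str]
    centroids: dict[str, np.ndarray]  # subtype -> vector aligned to genes
    ror_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(ROR_S_COEFFICIENTS)
    )
    ror_scale: float = 100.0
    ror_offset: float = 0.0

    def __post_init__(self) -> None:
        if set(self.centroids) != set(SUBTYPES):
            raise CohortError(
                f"panel must define exactly the subtypes {SUBTYPES}, "
                f"got {sorted(self.centroids)}"
            )
        for name, vec in self.centroids.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (len(self.genes),):
                raise CohortError(f"centroid {name!r} not aligned to panel genes")
            if not np.all(np.isfinite(vec)):
                raise CohortError(f"centroid {name!r} contains non-finite values")
            self.centroids[name] = vec
        missing = set(SUBTYPES) - set(self.ror_coefficients)
        if missing:
            raise CohortError(f"missing ROR coefficients for {sorted(missing)}")
        if not all(np.isfinite(v) for v in self.ror_coefficients.values()):
            raise CohortError("non-finite ROR coefficient")


@dataclass
class SubtypeCall:
    """One sample's subtype call: per-subtype Spearman correlations in
    [-1, 1], the argmax label, and the ROR score."""

    sample_id: str
    subtype: str
    correlations: dict[str, float]
    ror_score: float


def synthetic_demo_panel(n_genes: int = 10, seed: int = 7) -> CentroidPanel:
    """A small synthetic centroid panel for tests and examples.

    Centroids are random but fixed by the seed; this demonstrates the calling
    machinery and carries no biological meaning.
    """
    rng = np.random.default_rng(seed)
    genes = [f"PNL{i + 1:03d}" for i in range(n_genes)]
    centroids = {s: rng.normal(0.0, 1.0, size=n_genes) for s in SUBTYPES}
    return CentroidPanel(genes=genes, centroids=centroids)


def write_panel(panel: CentroidPanel, path: str) -> None:
    delim = _delimiter_for(path)
    with open(path, "w") as fh:
        for s in SUBTYPES:
            fh.write(f"# ror_coef {s} {panel.ror_coefficients[s]:.17g}\n")
        fh.write(f"# ror_scale {panel.ror_scale:.17g}\n")
        fh.write(f"# ror_offset {panel.ror_offset:.17g}\n")
        fh.write(delim.join(["gene", *SUBTYPES]) + "\n")
        for i, g in enumerate(panel.genes):
            row = [g] + [f"{panel.centroids[s][i]:.17g}" for s in SUBTYPES]
            fh.write(delim.join(row) + "\n")


def read_panel(path: str) -> CentroidPanel:
    delim = _delimiter_for(path)
    coefs: dict[str, float] = {}
    scale, offset = 100.0, 0.0
    genes: list[str] = []
    cols: dict[str, list[float]] = {s: [] for s in SUBTYPES}
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line.lstrip("#").split()
                if parts and parts[0] == "ror_coef":
                    coefs[parts[1]] = float(parts[2])
                elif parts and parts[0] == "ror_scale":
                    scale = float(parts[1])
                elif parts and parts[0] == "ror_offset":
                    offset = float(parts[1])
                continue
            parts = line.split(delim)
            if header is None:
                header = [p.strip() for p in parts]
                if header[0] != "gene" or set(header[1:]) != set(SUBTYPES):
                    raise CohortError(f"{path}:{lineno}: bad panel header {header}")
                continue
            genes.append(parts[0].strip())
            for name, cell in zip(header[1:], parts[1:], strict=True):
                cols[name].append(float(cell))
    if header is None:
        raise CohortError(f"{path}: empty panel file")
    centroids = {s: np.asarray(cols[s]) for s in SUBTYPES}
    return CentroidPanel(
        genes=genes,
        centroids=centroids,
        ror_coefficients=coefs or dict(ROR_S_COEFFICIENTS),
        ror_scale=scale,
        ror_offset=offset,
    )


# ---------------------------------------------------------------------------
# subtype calling


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    # rank correlation; ranks computed with average ties
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return 0.0
    return float(np.clip((rx * ry).sum() / denom, -1.0, 1.0))


def pam50_call(
    cohort: ExpressionCohort, panel: CentroidPanel, min_coverage: float = 0.5
) -> list[SubtypeCall]:
    """Call the intrinsic subtype of every cohort sample by Spearman
    correlation to the panel centroids.

    Panel genes absent from the cohort are dropped; if fewer than
    ``min_coverage`` of the panel genes remain the call is refused with a
    coverage report. Ties between subtypes break by the fixed subtype order.
    Because the correlation is rank-based, calls are invariant to any
    monotone per-sample transformation of expression.
    """
    present = [g for g in panel.genes if g in set(cohort.gene_ids)]
    coverage = len(present) / len(panel.genes)
    if coverage < min_coverage:
        missing = sorted(set(panel.genes) - set(present))
        raise CohortError(
            f"panel coverage {coverage:.0%} below required {min_coverage:.0%}; "
            f"missing genes: {missing}"
        )
    keep = [i for i, g in enumerate(panel.genes) if g in set(present)]
    expr = cohort.submatrix(present, cohort.sample_ids)  # samples x panel genes

    calls = []
    for j, sid in enumerate(cohort.sample_ids):
        corr = {
            s: _spearman(expr[j], panel.centroids[s][keep]) for s in SUBTYPES
        }
        best = max(SUBTYPES, key=lambda s: corr[s])  # ties -> earliest subtype
        call = SubtypeCall(
            sample_id=sid, subtype=best, correlations=corr, ror_score=float("nan")
        )
        call.ror_score = ror_score(call, panel)
        calls.append(call)
    return calls


def ror_score(call: SubtypeCall, panel: CentroidPanel) -> float:
    """Risk-of-recurrence score: affinely rescaled weighted sum of the
    sample's subtype correlations."""
    missing = [s for s in SUBTYPES if s not in call.correlations]
    if missing:
        raise CohortError(f"missing subtype correlations for {missing}")
    raw = sum(panel.ror_coefficients[s] * call.correlations[s] for s in SUBTYPES)
    return panel.ror_offset + panel.ror_scale * raw


# ---------------------------------------------------------------------------
# survival


@dataclass
class SurvivalTable:
    """Per-sample survival record: follow-up time, event flag (1 = event
    observed, 0 = censored), and a group label."""

    sample_ids: list[str]
    time: list[float]
    event: list[int]
    group: list[str]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if not (len(self.time) == len(self.event) == len(self.group) == n):
            raise CohortError("survival table columns have unequal lengths")
        if any(t < 0 for t in self.time):
            raise CohortError("survival times must be non-negative")
        if any(e not in (0, 1) for e in self.event):
            raise CohortError("event flags must be 0 or 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "time": self.time,
                "event": self.event,
                "group": self.group,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalTable":
        return cls(
            sample_ids=[str(s) for s in df["sample_id"]],
            time=[float(t) for t in df["time"]],
            event=[int(e) for e in df["event"]],
            group=[str(g) for g in df["group"]],
        )

    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.group:
            if g not in seen:
                seen.append(g)
        return seen


def km_curve(table: SurvivalTable, group: str) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan–Meier product-limit curve for one group.

    Returns ``(times, survival)`` where ``survival[i]`` is S(t) at
    ``times[i]``; the curve starts at S(0) = 1 and is non-increasing.
    """
    mask = [g == group for g in table.group]
    if not any(mask):
        raise CohortError(f"empty group {group!r}")
    t = np.asarray([x for x, m in zip(table.time, mask, strict=True) if m])
    e = np.asarray([x for x, m in zip(table.event, mask, strict=True) if m])
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    observed: tuple[float, float]
    expected: tuple[float, float]


def logrank_hr(table: SurvivalTable) -> LogrankResult:
    """Mantel–Haenszel log-rank test and O/E hazard ratio for two groups.

    At each distinct event time a 2x2 table of (deaths, at-risk) by group is
    tabulated; the statistic is ``(O1 - E1)^2 / V`` with the hypergeometric
    variance, p from chi-square with 1 df. The hazard ratio is
    ``(O1/E1)/(O2/E2)`` — group 1 is the first group label encountered — with
    a log-scale 95% CI using variance ``1/E1 + 1/E2``.
    """
    labels = table.groups()
    if len(labels) != 2:
        raise CohortError(f"log-rank requires exactly 2 groups, got {labels}")
    g1 = np.asarray([g == labels[0] for g in table.group])
    t = np.asarray(table.time, dtype=float)
    e = np.asarray(table.event, dtype=int)
    if e.sum() == 0:
        raise CohortError("log-rank undefined: no events observed")
    if g1.all() or (~g1).all():
        raise CohortError("log-rank requires both groups non-empty")

    # per distinct event time tau: deaths d_g and at-risk n_g per group
    taus = np.unique(t[e == 1])
    t1_all = np.sort(t[g1])
    t2_all = np.sort(t[~g1])
    te1 = np.sort(t[g1 & (e == 1)])
    te2 = np.sort(t[~g1 & (e == 1)])
    n1 = len(t1_all) - np.searchsorted(t1_all, taus, side="left")
    n2 = len(t2_all) - np.searchsorted(t2_all, taus, side="left")
    d1 = np.searchsorted(te1, taus, side="right") - np.searchsorted(te1, taus, side="left")
    d2 = np.searchsorted(te2, taus, side="right") - np.searchsorted(te2, taus, side="left")
    n = (n1 + n2).astype(float)
    d = (d1 + d2).astype(float)
    o1 = float(d1.sum())
    o2 = float(d2.sum())
    e1 = float((d * n1 / n).sum())
    e2 = float((d * n2 / n).sum())
    multi = n > 1
    var = float(
        (d[multi] * (n1[multi] / n[multi]) * (n2[multi] / n[multi])
         * (n[multi] - d[multi]) / (n[multi] - 1)).sum()
    )

    statistic = (o1 - e1) ** 2 / var if var > 0 else 0.0
    p_value = float(stats.chi2.sf(statistic, df=1)) if var > 0 else 1.0

    if e1 > 0 and e2 > 0 and o1 > 0 and o2 > 0:
        hr = (o1 / e1) / (o2 / e2)
        se = np.sqrt(1.0 / e1 + 1.0 / e2)
        ci_low = float(hr * np.exp(-1.959963984540054 * se))
        ci_high = float(hr * np.exp(+1.959963984540054 * se))
    else:
        # one group without observed or expected events: HR degenerate
        hr = np.inf if o2 == 0 or e2 == 0 else 0.0
        ci_low, ci_high = float("nan"), float("nan")

    return LogrankResult(
        statistic=float(statistic),
        p_value=p_value,
        hazard_ratio=float(hr),
        ci_low=ci_low,
        ci_high=ci_high,
        observed=(o1, o2),
        expected=(e1, e2),
    )
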