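"""Core data model and text I/O.

The package operates on three kinds of objects: an :class:`ExpressionCohort`
(a log2 gene-by-sample expression matrix with aligned per-sample clinical
annotations), a :class:`GeneSignature` (an ordered gene list, optionally with
importance scores), and a :class:`ClassificationResult` (per-sample positive
class probability scores with thresholded labels).

All file formats are plain delimited text:

* expression matrix — genes in rows, samples in columns, first column gene id,
  header row of sample ids; ``.tsv`` tab-delimited, ``.csv`` comma-delimited;
* annotations — one row per sample, required column ``class_label``, optional
  ``er_score``, ``her2_score``, ``treatment``, ``surv_time``, ``surv_event``;
* signature — two columns (gene, importance) with ``#``-prefixed provenance
  header lines.

Expression values are assumed already log2-transformed and normalized; no
normalization is performed here and missing expression values are rejected
(the tree ensembles downstream are defined on complete matrices).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CLASS_LABELS = ("IBC", "nonIBC", "normal")
POSITIVE_CLASS = "IBC"

#: annotation columns understood by the package, besides ``class_label``
ANNOTATION_COLUMNS = (
    "class_label",
    "er_score",
    "her2_score",
    "treatment",
    "surv_time",
    "surv_event",
)

_NA_TOKENS = {"", "na", "nan", "none", "null", "missing"}


class CohortError(ValueError):
    """Raised when a cohort, signature or annotation file is invalid."""


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip().lower() in _NA_TOKENS


@dataclass
class SampleAnnotation:
    """Per-sample clinical record; any field other than the id may be missing."""

    sample_id: str
    class_label: str | None = None  # one of CLASS_LABELS
    er_score: int | None = None
    her2_score: int | None = None
    treatment: str | None = None  # "pre" | "post"
    surv_time: float | None = None
    surv_event: int | None = None

    def validate(self) -> None:
        if self.class_label is not None and self.class_label not in CLASS_LABELS:
            raise CohortError(
                f"sample {self.sample_id!r}: unknown class_label {self.class_label!r} "
                f"(expected one of {CLASS_LABELS})"
            )
        if self.treatment is not None and self.treatment not in ("pre", "post"):
            raise CohortError(
                f"sample {self.sample_id!r}: treatment must be 'pre' or 'post', "
                f"got {self.treatment!r}"
            )
        if self.surv_time is not None and self.surv_time < 0:
            raise CohortError(f"sample {self.sample_id!r}: negative surv_time")
        if self.surv_event is not None and self.surv_event not in (0, 1):
            raise CohortError(f"sample {self.sample_id!r}: surv_event must be 0 or 1")


@dataclass
class ExpressionCohort:
    """A validated log2 expression matrix plus aligned sample annotations.

    ``values`` is genes x samples; row *i* is ``gene_ids[i]``, column *j* is
    ``sample_ids[j]``. Samples present in the matrix but never annotated carry
    an all-missing :class:`SampleAnnotation`.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    annotations: dict[str, SampleAnnotation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        dup_g = _duplicates(self.gene_ids)
        if dup_g:
            raise CohortError(f"duplicate gene ids: {sorted(dup_g)}")
        dup_s = _duplicates(self.sample_ids)
        if dup_s:
            raise CohortError(f"duplicate sample ids: {sorted(dup_s)}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise CohortError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise CohortError(
                f"non-finite expression value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        sample_set = set(self.sample_ids)
        for sid, ann in self.annotations.items():
            if sid not in sample_set:
                raise CohortError(f"annotated sample {sid!r} not in expression matrix")
            ann.validate()
        for sid in self.sample_ids:  # fill all-missing records
            self.annotations.setdefault(sid, SampleAnnotation(sample_id=sid))

    # -- accessors ----------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def annotation(self, sample_id: str) -> SampleAnnotation:
        return self.annotations[sample_id]

    def class_of(self, sample_id: str) -> str | None:
        return self.annotations[sample_id].class_label

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for sid in self.sample_ids:
            label = self.annotations[sid].class_label
            if label is not None:
                counts[label] = counts.get(label, 0) + 1
        return counts

    def samples_with_label(self, label: str) -> list[str]:
        return [s for s in self.sample_ids if self.annotations[s].class_label == label]

    def submatrix(self, gene_ids, sample_ids) -> np.ndarray:
        """Samples x genes slice (the orientation classifiers consume)."""
        gidx = self.gene_indices(gene_ids)
        sidx = [self._sample_index()[s] for s in sample_ids]
        return self.values[np.ix_(gidx, sidx)].T.copy()

    def gene_indices(self, gene_ids) -> list[int]:
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise CohortError(f"genes absent from cohort: {missing[:10]}")
        return [index[g] for g in gene_ids]

    def _sample_index(self) -> dict[str, int]:
        return {s: j for j, s in enumerate(self.sample_ids)}

    def subset_samples(self, sample_ids) -> "ExpressionCohort":
        sidx = self._sample_index()
        cols = [sidx[s] for s in sample_ids]
        return ExpressionCohort(
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            values=self.values[:, cols].copy(),
            annotations={s: replace(self.annotations[s]) for s in sample_ids},
        )


@dataclass
class GeneSignature:
    """Ordered gene list with optional aligned, non-increasing importances."""

    genes: list[str]
    importance: list[float] | None = None
    name: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        dup = _duplicates(self.genes)
        if dup:
            raise CohortError(f"duplicate genes in signature: {sorted(dup)}")
        if self.importance is not None:
            if len(self.importance) != len(self.genes):
                raise CohortError("importance list not aligned with genes")
            if any(v < 0 for v in self.importance):
                raise CohortError("importance scores must be non-negative")
            if not _non_increasing(self.importance):
                raise CohortError("importance scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSignature):
            return NotImplemented
        if self.genes != other.genes or self.name != other.name:
            return False
        if (self.importance is None) != (other.importance is None):
            return False
        if self.importance is not None:
            if not all(
                abs(a - b) <= 1e-12
                for a, b in zip(self.importance, other.importance, strict=True)
            ):
                return False
        return self.provenance == other.provenance


@dataclass
class ClassificationResult:
    """Per-sample positive-class probability scores and thresholded calls.

    A sample is called positive iff its score is *strictly* greater than the
    threshold (score exactly at the threshold goes negative).
    """

    sample_ids: list[str]
    prob_score: list[float]
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.prob_score):
            raise CohortError("sample_ids and prob_score lengths differ")
        for s, p in zip(self.sample_ids, self.prob_score, strict=True):
            if not 0.0 <= p <= 1.0:
                raise CohortError(f"probability score out of [0,1] for {s!r}: {p}")

    @property
    def predicted_label(self) -> list[bool]:
        return [p > self.threshold for p in self.prob_score]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "prob_score": self.prob_score,
                "predicted_label": [
                    POSITIVE_CLASS if y else f"non{POSITIVE_CLASS}"
                    for y in self.predicted_label
                ],
            }
        )


# ---------------------------------------------------------------------------
# helpers


def _duplicates(items) -> set:
    seen: set = set()
    dups: set = set()
    for x in items:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups


def _non_increasing(xs) -> bool:
    return all(a >= b - 1e-15 for a, b in zip(xs, xs[1:]))


def _delimiter_for(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# cohort I/O


def read_cohort(matrix_path: str, annotation_path: str | None = None) -> ExpressionCohort:
    """Load an expression matrix (+ optional annotation table) from text files.

    The matrix's column order defines the cohort's sample order. Samples in
    the matrix without an annotation row get all-missing annotations; an
    annotation row whose sample id is absent from the matrix is an error.
    """
    delim = _delimiter_for(matrix_path)
    df = pd.read_csv(matrix_path, sep=delim, index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    dup_g = _duplicates(gene_ids)
    if dup_g:
        raise CohortError(f"duplicate gene ids in {matrix_path}: {sorted(dup_g)}")
    dup_s = _duplicates(sample_ids)
    if dup_s:
        raise CohortError(f"duplicate sample ids in {matrix_path}: {sorted(dup_s)}")
    values = np.empty(df.shape, dtype=float)
    for i, row in enumerate(df.itertuples(index=False, name=None)):
        for j, cell in enumerate(row):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise CohortError(
                    f"non-numeric expression value {cell!r} at gene "
                    f"{gene_ids[i]!r} (row {i + 2}), sample {sample_ids[j]!r} "
                    f"(column {j + 2}) in {matrix_path}"
                ) from None

    annotations: dict[str, SampleAnnotation] = {}
    if annotation_path is not None:
        annotations = read_annotations(annotation_path, set(sample_ids))
    return ExpressionCohort(gene_ids, sample_ids, values, annotations)


def read_annotations(path: str, known_samples: set[str] | None = None):
    delim = _delimiter_for(path)
    df = pd.read_csv(path, sep=delim, dtype=str, keep_default_na=False)
    id_col = df.columns[0]
    if "class_label" not in df.columns:
        raise CohortError(f"annotation file {path} lacks required column 'class_label'")
    annotations: dict[str, SampleAnnotation] = {}
    for _, row in df.iterrows():
        sid = str(row[id_col])
        if known_samples is not None and sid not in known_samples:
            raise CohortError(
                f"annotation sample id {sid!r} not present in expression matrix"
            )
        ann = SampleAnnotation(sample_id=sid)
        ann.class_label = None if _is_missing(row["class_label"]) else str(row["class_label"])
        for col, conv in (
            ("er_score", int),
            ("her2_score", int),
            ("surv_time", float),
            ("surv_event", int),
        ):
            if col in df.columns and not _is_missing(row[col]):
                setattr(ann, col, conv(float(row[col])))
        if "treatment" in df.columns and not _is_missing(row["treatment"]):
            ann.treatment = str(row["treatment"])
        ann.validate()
        annotations[sid] = ann
    return annotations


def write_cohort(cohort: ExpressionCohort, matrix_path: str, annotation_path: str) -> None:
    delim = _delimiter_for(matrix_path)
    df = pd.DataFrame(cohort.values, index=cohort.gene_ids, columns=cohort.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(matrix_path, sep=delim, float_format="%.10g")

    rows = []
    for sid in cohort.sample_ids:
        ann = cohort.annotations[sid]
        rows.append(
            {
                "sample_id": sid,
                "class_label": ann.class_label if ann.class_label is not None else "",
                "er_score": "" if ann.er_score is None else ann.er_score,
                "her2_score": "" if ann.her2_score is None else ann.her2_score,
                "treatment": ann.treatment or "",
                "surv_time": "" if ann.surv_time is None else f"{ann.surv_time:.10g}",
                "surv_event": "" if ann.surv_event is None else ann.surv_event,
            }
        )
    pd.DataFrame(rows).to_csv(
        annotation_path, sep=_delimiter_for(annotation_path), index=False
    )


# ---------------------------------------------------------------------------
# signature I/O


def write_signature(sig: GeneSignature, path: str) -> None:
    delim = _delimiter_for(path)
    with open(path, "w") as fh:
        if sig.name:
            fh.write(f"# name: {sig.name}\n")
        for line in sig.provenance.splitlines():
            fh.write(f"# provenance: {line}\n")
        fh.write(delim.join(["gene", "importance"]) + "\n")
        for i, g in enumerate(sig.genes):
            imp = "" if sig.importance is None else f"{sig.importance[i]:.17g}"
            fh.write(f"{g}{delim}{imp}\n")


def read_signature(path: str) -> GeneSignature:
    delim = _delimiter_for(path)
    name = ""
    prov_lines: list[str] = []
    genes: list[str] = []
    importance: list[float] = []
    has_importance = False
    with open(path) as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("name:"):
                    name = body[len("name:"):].strip()
                elif body.startswith("provenance:"):
                    prov_lines.append(body[len("provenance:"):].strip())
                continue
            parts = line.split(delim)
            if not header_seen:
                if parts[0].strip().lower() != "gene":
                    raise CohortError(
                        f"{path}:{lineno}: expected header line starting with 'gene'"
                    )
                header_seen = True
                continue
            gene = parts[0].strip()
            if not gene:
                raise CohortError(f"{path}:{lineno}: empty gene id")
            if gene in genes:
                raise CohortError(f"{path}:{lineno}: duplicate gene {gene!r}")
            genes.append(gene)
            if len(parts) > 1 and parts[1].strip():
                try:
                    importance.append(float(parts[1]))
                except ValueError:
                    raise CohortError(
                        f"{path}:{lineno}: non-numeric importance {parts[1]!r}"
                    ) from None
                has_importance = True
            elif has_importance:
                raise CohortError(f"{path}:{lineno}: missing importance value")
    if has_importance and len(importance) != len(genes):
        raise CohortError(f"{path}: importance column incomplete")
    return GeneSignature(
        genes=genes,
        importance=importance if has_importance else None,
        name=name,
        provenance="\n".join(prov_lines),
    )


# ---------------------------------------------------------------------------
# model serialization (consumed by forest.ForestModel.save/load)


def write_json_doc(doc: dict, path: str) -> None:
    """Write a human-readable structured-text (JSON) document."""
    tmp = f"{path}.tmp"
    with open(tmp, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")
    os.replace(tmp, path)


def read_json_doc(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)
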