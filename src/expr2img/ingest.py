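"""Reading, normalizing and merging expression datasets.

Multi-cohort harmonization follows the standard recipe for merging
independently measured expression arrays: each dataset is standardized
per gene (z-score with the population standard deviation), datasets are
concatenated over the shared probe set, and each gene is min–max scaled
over the combined cohort so every value lands in [0, 1].
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import VALID_CLASSES, ExpressionMatrix, _find_duplicates
from .errors import FormatError, LabelingError

# Default regex for pulling a diagnosis token out of a GEO
# !Sample_characteristics_ch1 entry such as "status: AD".
DEFAULT_CHARACTERISTIC_REGEX = r"status:\s*([A-Za-z]+)"
DEFAULT_LABEL_MAP = {"AD": "AD", "MCI": "MCI", "NC": "NC", "CTL": "NC", "CONTROL": "NC"}


# ---------------------------------------------------------------------------
# pairwise tasks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairTask:
    """A binary classification task over diagnosis classes.

    ``positive_classes`` map to label 1 and ``negative_classes`` to 0.
    The positive side is the first-named group (AD in "AD vs NC").
    """

    name: str
    positive_classes: frozenset[str]
    negative_classes: frozenset[str]

    def __post_init__(self) -> None:
        if self.positive_classes & self.negative_classes:
            raise ValueError("positive and negative class sets overlap")
        union = self.positive_classes | self.negative_classes
        if not union <= set(VALID_CLASSES):
            raise ValueError(f"task classes {union} not a subset of {VALID_CLASSES}")


def _task(name: str, pos: set[str], neg: set[str]) -> PairTask:
    return PairTask(name, frozenset(pos), frozenset(neg))


TASKS: dict[str, PairTask] = {
    "AD_vs_NC": _task("AD_vs_NC", {"AD"}, {"NC"}),
    "AD_vs_MCI": _task("AD_vs_MCI", {"AD"}, {"MCI"}),
    "MCI_vs_NC": _task("MCI_vs_NC", {"MCI"}, {"NC"}),
    "AD_vs_MCI+NC": _task("AD_vs_MCI+NC", {"AD"}, {"MCI", "NC"}),
    "AD+MCI_vs_NC": _task("AD+MCI_vs_NC", {"AD", "MCI"}, {"NC"}),
}


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _attach_labels(frame: pd.DataFrame, labels_path: str | Path) -> tuple[list[str], list[str] | None]:
    lab = pd.read_csv(labels_path, dtype=str)
    if "sample_id" not in lab.columns or "label" not in lab.columns:
        raise LabelingError("labels CSV needs columns sample_id,label")
    mapping = dict(zip(lab["sample_id"], lab["label"]))
    missing = [s for s in frame.columns if s not in mapping]
    if missing:
        raise LabelingError(f"no label for samples: {missing}")
    labels = [mapping[s] for s in frame.columns]
    dataset_ids = None
    if "dataset_id" in lab.columns:
        dmap = dict(zip(lab["sample_id"], lab["dataset_id"]))
        dataset_ids = [dmap[s] for s in frame.columns]
    return labels, dataset_ids


def _parse_series_matrix(text: str, characteristic_regex: str, label_map: dict[str, str]):
    """Extract the value table and diagnosis labels from a GEO series-matrix file."""
    lines = text.splitlines()
    try:
        start = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin"))
        end = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end"))
    except StopIteration:
        raise FormatError("series-matrix table markers not found") from None
    table = "\n".join(lines[start + 1 : end])
    frame = pd.read_csv(io.StringIO(table), sep="\t", index_col=0)
    frame.columns = [str(c).strip('"') for c in frame.columns]
    frame.index = [str(i).strip('"') for i in frame.index]

    pattern = re.compile(characteristic_regex)
    labels: list[str] | None = None
    for l in lines[:start]:
        if not l.startswith("!Sample_characteristics_ch1"):
            continue
        fields = [f.strip('"') for f in l.split("\t")[1:]]
        hits = [pattern.search(f) for f in fields]
        if all(h is not None for h in hits) and len(fields) == frame.shape[1]:
            tokens = [h.group(1).upper() for h in hits]
            try:
                labels = [label_map[t] for t in tokens]
            except KeyError as e:
                raise LabelingError(
                    f"characteristic token {e.args[0]!r} has no mapping to {VALID_CLASSES}"
                ) from None
            break
    return frame, labels


def read_expression(
    path: str | Path,
    format: str = "tsv",
    labels_path: str | Path | None = None,
    dataset_id: str | None = None,
    characteristic_regex: str = DEFAULT_CHARACTERISTIC_REGEX,
    label_map: dict[str, str] | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV or a GEO series-matrix text file.

    TSV layout: genes in rows, first column = probe ID, header = sample IDs
    (what :func:`expr2img.simdata.write_cohort` writes).  Labels come from a
    companion two-column CSV.  For series-matrix files, values are parsed
    from the block between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` and labels from the sample-characteristics
    header lines via `characteristic_regex` and `label_map`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    labels: list[str] | None = None
    dataset_ids: list[str] | None = None
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        frame.index = [str(i) for i in frame.index]
        dup = _find_duplicates(frame.index)
        if dup:
            raise FormatError(f"duplicated probe IDs: {dup}")
        if labels_path is not None:
            labels, dataset_ids = _attach_labels(frame, labels_path)
    elif format == "geo_series_matrix":
        frame, labels = _parse_series_matrix(
            path.read_text(), characteristic_regex, label_map or DEFAULT_LABEL_MAP
        )
        dup = _find_duplicates(frame.index)
        if dup:
            raise FormatError(f"duplicated probe IDs: {dup}")
        if labels_path is not None:  # explicit file overrides header parsing
            labels, dataset_ids = _attach_labels(frame, labels_path)
    else:
        raise FormatError(f"unknown format {format!r}")

    did = dataset_id or path.stem
    return ExpressionMatrix(
        values=frame.to_numpy(dtype=float),
        probe_ids=list(frame.index),
        sample_ids=[str(c) for c in frame.columns],
        labels=labels,
        dataset_ids=dataset_ids or [did] * frame.shape[1],
    )


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def intersect_probes(matrices: list[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict all matrices to their shared probes, in lexicographic order.

    The canonical (sorted) row order makes the result independent of both the
    input file order and the order matrices are passed in.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to intersect")
    shared = set(matrices[0].probe_ids)
    for m in matrices[1:]:
        shared &= set(m.probe_ids)
    if not shared:
        raise FormatError("empty probe intersection across datasets")
    order = sorted(shared)
    out = []
    for m in matrices:
        pos = {p: i for i, p in enumerate(m.probe_ids)}
        out.append(m.subset_genes(np.array([pos[p] for p in order])))
    return out


def zscore_rows(values: np.ndarray) -> np.ndarray:
    """Per-row z-score with the population standard deviation.

    Constant rows (zero spread) map to all zeros rather than NaN.
    """
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population (ddof=0) by convention
    centered = values - mean
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, centered / np.where(sd == 0, 1.0, sd), 0.0)
    return z


def minmax_rows(values: np.ndarray) -> np.ndarray:
    """Per-row min–max scaling to [0, 1]; zero-range rows map to 0."""
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    rng = hi - lo
    return np.where(rng > 0, (values - lo) / np.where(rng == 0, 1.0, rng), 0.0)


def merge_and_normalize(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Standardize each dataset per gene, concatenate, min–max scale per gene.

    Requires all matrices to share an identical probe order (run
    :func:`intersect_probes` first).  The per-dataset z-score removes affine
    batch differences; the final per-gene min–max over the combined samples
    puts every gene on the [0, 1] scale.
    """
    ref = matrices[0].probe_ids
    for m in matrices[1:]:
        if m.probe_ids != ref:
            raise FormatError("probe order mismatch; run intersect_probes first")
    z_blocks = [zscore_rows(m.values) for m in matrices]
    values = minmax_rows(np.concatenate(z_blocks, axis=1))
    sample_ids: list[str] = []
    labels: list[str] = []
    dataset_ids: list[str] = []
    any_labels = all(m.labels is not None for m in matrices)
    for m in matrices:
        sample_ids.extend(m.sample_ids)
        dataset_ids.extend(m.dataset_ids or [m.dataset_id or "?"] * m.n_samples)
        if any_labels:
            labels.extend(m.labels)  # type: ignore[arg-type]
    return ExpressionMatrix(
        values=values,
        probe_ids=list(ref),
        sample_ids=sample_ids,
        labels=labels if any_labels else None,
        dataset_ids=dataset_ids,
    )


def make_pair_subset(matrix: ExpressionMatrix, task: PairTask | str) -> ExpressionMatrix:
    """Restrict to the task's classes and attach 0/1 labels (order preserved)."""
    if isinstance(task, str):
        try:
            task = TASKS[task]
        except KeyError:
            raise ValueError(f"unknown task {task!r}; known: {sorted(TASKS)}") from None
    if matrix.labels is None:
        raise LabelingError("matrix has no labels")
    present = set(matrix.labels)
    missing = (task.positive_classes | task.negative_classes) - present
    if missing:
        raise LabelingError(f"task classes absent from data: {sorted(missing)}")
    keep = [
        i
        for i, l in enumerate(matrix.labels)
        if l in task.positive_classes or l in task.negative_classes
    ]
    sub = matrix.subset_samples(np.array(keep))
    sub.binary_labels = np.array(
        [1 if l in task.positive_classes else 0 for l in sub.labels], dtype=int
    )
    return sub
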