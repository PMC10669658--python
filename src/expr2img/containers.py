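"""In-memory containers shared across the pipeline.

The base modality is an :class:`ExpressionMatrix`: a genes x samples numeric
table with probe identifiers, sample identifiers, per-sample diagnosis labels
(AD / MCI / NC) and per-sample dataset provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, LabelingError

VALID_CLASSES = ("AD", "MCI", "NC")


def _find_duplicates(items) -> list[str]:
    seen: set[str] = set()
    dup: list[str] = []
    for x in items:
        if x in seen and x not in dup:
            dup.append(x)
        seen.add(x)
    return dup


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with identifiers and labels.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_samples)
    probe_ids : list of unique probe identifiers, one per row
    sample_ids : list of unique sample identifiers, one per column
    labels : per-sample diagnosis strings, or None if unlabeled
    dataset_ids : per-sample originating-dataset identifier
    binary_labels : 0/1 array attached by pairwise-task subsetting, or None
    """

    values: np.ndarray
    probe_ids: list[str]
    sample_ids: list[str]
    labels: list[str] | None = None
    dataset_ids: list[str] | None = None
    binary_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2D genes x samples array")
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise FormatError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        dup = _find_duplicates(self.probe_ids)
        if dup:
            raise FormatError(f"duplicated probe IDs: {dup}")
        dup = _find_duplicates(self.sample_ids)
        if dup:
            raise FormatError(f"duplicated sample IDs: {dup}")
        if self.labels is not None:
            self.labels = [str(l) for l in self.labels]
            if len(self.labels) != self.n_samples:
                raise LabelingError(
                    f"{len(self.labels)} labels for {self.n_samples} samples"
                )
        if self.dataset_ids is not None:
            self.dataset_ids = [str(d) for d in self.dataset_ids]
            if len(self.dataset_ids) != self.n_samples:
                raise FormatError("dataset_ids length != sample count")

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def dataset_id(self) -> str | None:
        """The single dataset id, if all samples share one."""
        if not self.dataset_ids:
            return None
        uniq = set(self.dataset_ids)
        return self.dataset_ids[0] if len(uniq) == 1 else None

    # -- views ----------------------------------------------------------
    @property
    def X(self) -> np.ndarray:
        """Samples x genes view (the ML design-matrix orientation)."""
        return self.values.T

    def subset_samples(self, index: np.ndarray) -> "ExpressionMatrix":
        """Return a copy restricted to the given sample positions (order kept)."""
        index = np.asarray(index)
        return replace(
            self,
            values=self.values[:, index],
            sample_ids=[self.sample_ids[i] for i in index],
            labels=None if self.labels is None else [self.labels[i] for i in index],
            dataset_ids=None
            if self.dataset_ids is None
            else [self.dataset_ids[i] for i in index],
            binary_labels=None
            if self.binary_labels is None
            else self.binary_labels[index],
        )

    def subset_genes(self, index: np.ndarray) -> "ExpressionMatrix":
        """Return a copy restricted to the given gene positions (order kept)."""
        index = np.asarray(index)
        return replace(
            self,
            values=self.values[index, :],
            probe_ids=[self.probe_ids[i] for i in index],
        )

    # -- IO -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    def write_tsv(self, path: str | Path, labels_path: str | Path | None = None) -> None:
        """Write values as TSV (first column = probe ID, header = sample IDs).

        If `labels_path` is given, a companion CSV with columns
        sample_id,label[,dataset_id] is written alongside.
        """
        frame = self.to_frame()
        frame.index.name = "probe_id"
        frame.to_csv(path, sep="\t")
        if labels_path is not None:
            if self.labels is None:
                raise LabelingError("matrix has no labels to write")
            cols = {"sample_id": self.sample_ids, "label": self.labels}
            if self.dataset_ids is not None:
                cols["dataset_id"] = self.dataset_ids
            pd.DataFrame(cols).to_csv(labels_path, index=False)
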