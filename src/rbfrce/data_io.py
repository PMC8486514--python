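"""Reading and writing labeled expression matrices and ranked feature lists.

The central container is :class:`LabeledMatrix`, a samples x features numeric
matrix with per-sample class labels — the usual shape of a two-class
microarray or bulk expression study with tens of samples and thousands of
genes. Rankings produced by the selector are round-tripped through a small
TSV format (``rank\tfeature_id\tscore``).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


@dataclasses.dataclass
class LabeledMatrix:
    """A labeled expression matrix, oriented samples x features.

    Parameters
    ----------
    values
        Numeric matrix of shape (n_samples, n_features). Expression units are
        arbitrary; no normalisation is applied.
    labels
        Class label per sample (arbitrary hashable identifiers, >=2 distinct
        classes for supervised use).
    feature_ids
        Unique string identifier per feature (gene/probe names).
    sample_ids
        Unique string identifier per sample.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.values.ndim != 2:
            raise FormatError("values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.labels) != n or len(self.sample_ids) != n:
            raise FormatError("labels/sample_ids length must equal n_samples")
        if len(self.feature_ids) != p:
            raise FormatError("feature_ids length must equal n_features")
        if len(set(self.feature_ids)) != p:
            raise FormatError("feature ids must be unique")
        if np.isnan(self.values).any():
            raise FormatError("matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def encoded_labels(self) -> tuple[np.ndarray, list]:
        """Labels mapped to 0..C-1 in first-appearance order.

        Deterministic: the encoding depends only on the label sequence,
        not on sort order or hashing.
        """
        classes: list = []
        index: dict = {}
        for lab in self.labels:
            if lab not in index:
                index[lab] = len(classes)
                classes.append(lab)
        y = np.fromiter((index[lab] for lab in self.labels), dtype=np.int64,
                        count=len(self.labels))
        return y, classes

    def n_classes(self) -> int:
        return len(set(self.labels.tolist()))

    def subset_features(self, feature_ids: Sequence[str]) -> "LabeledMatrix":
        """Restrict to the given features, in the given order."""
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        try:
            cols = [pos[f] for f in feature_ids]
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown feature id {exc.args[0]!r}") from exc
        return LabeledMatrix(
            values=self.values[:, cols],
            labels=self.labels,
            feature_ids=np.asarray(list(feature_ids), dtype=object),
            sample_ids=self.sample_ids,
        )

    def subset_samples(self, rows: Sequence[int]) -> "LabeledMatrix":
        rows = list(rows)
        return LabeledMatrix(
            values=self.values[rows],
            labels=self.labels[rows],
            feature_ids=self.feature_ids,
            sample_ids=self.sample_ids[rows],
        )


@dataclasses.dataclass(frozen=True)
class RankingRecord:
    """One row of a feature ranking: rank 1 is the most important feature."""

    feature_id: str
    rank: int
    score: float


def _detect_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def read_expression_matrix(
    path: str | Path,
    orientation: str = "samples_as_rows",
    label_column: str = "label",
    sep: str | None = None,
    impute: str | None = None,
) -> LabeledMatrix:
    """Load a delimited expression matrix into a :class:`LabeledMatrix`.

    Parameters
    ----------
    path
        CSV/TSV file with a header row and an id column first. For
        ``samples_as_rows`` each row is a sample and ``label_column`` is a
        regular column; for ``features_as_rows`` each row is a feature and
        ``label_column`` is the row carrying the class labels.
    orientation
        ``samples_as_rows`` (default) or ``features_as_rows``. The result is
        always normalised to samples x features.
    label_column
        Name of the column (or row, for feature-major files) holding class
        labels.
    sep
        Field separator; by default inferred from the extension
        (``.tsv``/``.txt`` -> tab, else comma).
    impute
        ``None`` (default) rejects files with missing values; ``"mean"``
        fills each feature's missing entries with the feature mean.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if orientation not in {"samples_as_rows", "features_as_rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    delim = _detect_sep(path, sep)
    with open(path) as fh:  # pandas mangles duplicate header names; check raw
        header = fh.readline().rstrip("\n").split(delim)
    dupes = [h for h in set(header) if header.count(h) > 1]
    if dupes and orientation == "samples_as_rows":
        raise FormatError(f"{path}: duplicate feature id(s) {sorted(dupes)}")
    frame = pd.read_csv(path, sep=delim, index_col=0, dtype=str)
    if frame.empty:
        raise FormatError(f"{path}: no data rows")

    if orientation == "features_as_rows":
        if label_column not in frame.index:
            raise FormatError(f"{path}: label row {label_column!r} not found")
        frame = frame.T

    if label_column not in frame.columns:
        raise FormatError(f"{path}: label column {label_column!r} not found")
    labels = frame[label_column].to_numpy(dtype=object)
    body = frame.drop(columns=[label_column])
    feature_ids = body.columns.to_numpy(dtype=object)
    if len(set(feature_ids)) != len(feature_ids):
        dupes = body.columns[body.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate feature id(s) {dupes}")

    values = np.empty(body.shape, dtype=float)
    raw = body.to_numpy(dtype=object)
    for j, feat in enumerate(feature_ids):
        col = pd.to_numeric(raw[:, j], errors="coerce")
        bad = np.isnan(col) & ~pd.isna(raw[:, j])
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"{path}: non-numeric value {raw[row, j]!r} at sample "
                f"{body.index[row]!r}, feature {feat!r}"
            )
        values[:, j] = col

    if np.isnan(values).any():
        if impute == "mean":
            col_means = np.nanmean(values, axis=0)
            idx = np.where(np.isnan(values))
            values[idx] = col_means[idx[1]]
        else:
            i, j = (int(a[0]) for a in np.where(np.isnan(values)))
            raise FormatError(
                f"{path}: missing value at sample {body.index[i]!r}, feature "
                f"{feature_ids[j]!r} (pass impute='mean' to fill)"
            )

    return LabeledMatrix(
        values=values,
        labels=labels,
        feature_ids=feature_ids,
        sample_ids=body.index.to_numpy(dtype=object),
    )


def write_ranking(records: Sequence[RankingRecord], path: str | Path) -> None:
    """Write a ranking as TSV with columns ``rank, feature_id, score``."""
    if not records:
        raise ValueError("ranking must be nonempty")
    ranks = sorted(r.rank for r in records)
    if ranks != list(range(1, len(records) + 1)):
        raise ValueError(
            f"ranks must be a permutation of 1..{len(records)}, got {ranks}"
        )
    ordered = sorted(records, key=lambda r: r.rank)
    frame = pd.DataFrame(
        {
            "rank": [r.rank for r in ordered],
            "feature_id": [r.feature_id for r in ordered],
            "score": [repr(float(r.score)) for r in ordered],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_ranking(path: str | Path) -> list[RankingRecord]:
    """Read one ranking TSV back into records, ordered by rank."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty ranking file") from exc
    required = {"rank", "feature_id", "score"}
    if not required.issubset(frame.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    if frame.empty:
        raise FormatError(f"{path}: ranking has no rows")
    records = [
        RankingRecord(feature_id=str(row.feature_id), rank=int(row.rank),
                      score=float(row.score))
        for row in frame.itertuples()
    ]
    ranks = sorted(r.rank for r in records)
    if ranks != list(range(1, len(records) + 1)):
        raise FormatError(f"{path}: ranks are not a permutation of 1..K")
    return sorted(records, key=lambda r: r.rank)


def read_rankings_collection(paths: Sequence[str | Path]) -> list[list[str]]:
    """Read several ranking files into ordered feature-id lists.

    Lists of unequal length are returned as-is; truncation to a common k is
    the caller's decision (see ``stability_metrics.stability_report``).
    """
    rankings = []
    for path in paths:
        records = read_ranking(path)
        rankings.append([r.feature_id for r in records])
    lengths = {len(r) for r in rankings}
    if len(lengths) > 1:
        import warnings

        warnings.warn(
            f"ranking lists have differing lengths {sorted(lengths)}; "
            "truncate to a common k before comparing",
            stacklevel=2,
        )
    return rankings


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
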