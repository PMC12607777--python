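"""Readers/writers for the delimited formats the pipeline touches.

Expression matrices are genes-in-rows × samples-in-columns (the common
series-matrix convention); enrichment matrices are samples-in-rows because
they are the learning design matrix.  All loaders validate fully before
constructing an object: a malformed file never yields a partially-filled
container.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a sample whose class is unknown.  Both the empty string and
#: "NA" are accepted on read; the empty string is written.
UNLABELED = ""


class FormatError(ValueError):
    """A file violated the format contract (duplicate ids, bad cells...)."""


class IncompatibilityError(ValueError):
    """A saved model bundle does not match the incoming data or version."""


def _detect_delimiter(path: str | os.PathLike, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def _check_unique(ids, what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Real-valued genes × samples matrix with identifier vectors.

    Values may be on any monotone expression scale (log2 intensity,
    normalized counts): the enrichment stage uses only within-sample
    ordering.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_values(self, sample_id: str) -> np.ndarray:
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-backed): set_name -> (description, members)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def description(self, name: str) -> str:
        return self.sets[name][0]


@dataclass
class LabelMap:
    """sample_id -> class label (or the UNLABELED sentinel)."""

    labels: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.labels)

    def is_labeled(self, sample_id: str) -> bool:
        return self.labels[sample_id] != UNLABELED

    @property
    def n_labeled(self) -> int:
        return sum(1 for v in self.labels.values() if v != UNLABELED)


@dataclass
class EnrichmentMatrix:
    """Samples × gene-sets matrix of enrichment scores in [-1, 1]."""

    sample_ids: list[str]
    set_names: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.set_names, "set name")
        if self.scores.shape != (len(self.sample_ids), len(self.set_names)):
            raise FormatError(
                f"score shape {self.scores.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.set_names)} sets"
            )
        if self.scores.size and (
            np.nanmin(self.scores) < -1 - 1e-9 or np.nanmax(self.scores) > 1 + 1e-9
        ):
            raise FormatError("enrichment scores must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=self.set_names)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EnrichmentMatrix":
        return cls(
            sample_ids=[str(s) for s in frame.index],
            set_names=[str(c) for c in frame.columns],
            scores=frame.to_numpy(dtype=float),
        )


# ---------------------------------------------------------------------------
# delimited matrices


def _read_table(path, delimiter):
    delim = _detect_delimiter(path, delimiter)
    try:
        frame = pd.read_csv(path, sep=delim, index_col=0, dtype=str)
    except Exception as exc:  # noqa: BLE001 - rewrap for a uniform error type
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    row_ids = [str(i) for i in frame.index]
    col_ids = [str(c) for c in frame.columns]
    _check_unique(row_ids, "row id")
    _check_unique(col_ids, "column id")
    values = np.empty(frame.shape, dtype=float)
    raw = frame.to_numpy()
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            try:
                values[i, j] = float(raw[i, j])
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-numeric cell at row {row_ids[i]!r}, "
                    f"column {col_ids[j]!r}: {raw[i, j]!r}"
                ) from None
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise FormatError(
            f"missing/non-finite value at row {row_ids[i]!r}, column {col_ids[j]!r}"
        )
    return row_ids, col_ids, values


def _write_table(row_ids, col_ids, values, path, delimiter, corner=""):
    delim = _detect_delimiter(path, delimiter)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(delim.join([corner, *col_ids]) + "\n")
        for rid, row in zip(row_ids, values):
            fh.write(delim.join([rid, *(repr(float(v)) for v in row)]) + "\n")


def read_expression(path, delimiter: str | None = None) -> ExpressionMatrix:
    """Load a genes × samples table (header = sample ids, first column = gene ids)."""
    gene_ids, sample_ids, values = _read_table(path, delimiter)
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression(expr: ExpressionMatrix, path, delimiter: str | None = None) -> None:
    """Write with full decimal repr so read∘write is the identity."""
    _write_table(expr.gene_ids, expr.sample_ids, expr.values, path, delimiter, corner="gene_id")


def read_enrichment(path, delimiter: str | None = None) -> EnrichmentMatrix:
    sample_ids, set_names, scores = _read_table(path, delimiter)
    return EnrichmentMatrix(sample_ids, set_names, scores)


def write_enrichment(em: EnrichmentMatrix, path, delimiter: str | None = None) -> None:
    _write_table(em.sample_ids, em.set_names, em.scores, path, delimiter, corner="sample_id")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (MSigDB dialect): set_name TAB description TAB gene...

    Duplicate genes within one line are collapsed with a logged warning;
    duplicate set names and short lines are format errors.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected at least 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(genes)
            if len(members) < len(genes):
                logger.warning(
                    "gene set %s: %d duplicate gene(s) collapsed",
                    name,
                    len(genes) - len(members),
                )
            sets[name] = (description, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.names:
            desc = collection.description(name)
            members = sorted(collection.members(name))
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# labels


def read_labels(path, delimiter: str | None = None) -> LabelMap:
    """Two-column text (sample id, label); empty or "NA" label = unlabeled."""
    delim = _detect_delimiter(path, delimiter)
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(delim)
            if len(parts) == 1:
                parts = [parts[0], ""]
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            sid, label = parts[0], parts[1]
            if sid in labels:
                raise FormatError(f"{path}:{lineno}: repeated sample id {sid!r}")
            labels[sid] = UNLABELED if label in ("", "NA") else label
    return LabelMap(labels)


def write_labels(label_map: LabelMap, path, delimiter: str | None = None) -> None:
    delim = _detect_delimiter(path, delimiter)
    with open(path, "w", encoding="utf-8") as fh:
        for sid, label in label_map.labels.items():
            fh.write(f"{sid}{delim}{label}\n")


# ---------------------------------------------------------------------------
# model bundles

BUNDLE_VERSION = 1


def save_model(model, dirpath) -> None:
    """Persist a trained subtype classifier as a bundle directory.

    The bundle holds a JSON metadata file (class order, selected feature
    names, full config, format version) and an .npz parameter store.
    """
    os.makedirs(dirpath, exist_ok=True)
    arrays, meta = model.to_arrays()
    meta["bundle_version"] = BUNDLE_VERSION
    np.savez(os.path.join(dirpath, "weights.npz"), **arrays)
    with open(os.path.join(dirpath, "meta.json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)


def load_model(dirpath):
    """Load a bundle written by :func:`save_model`."""
    from .classifier import TrainedModel

    meta_path = os.path.join(dirpath, "meta.json")
    if not os.path.exists(meta_path):
        raise IncompatibilityError(f"{dirpath} is not a model bundle (no meta.json)")
    with open(meta_path, encoding="utf-8") as fh:
        meta = json.load(fh)
    if meta.get("bundle_version") != BUNDLE_VERSION:
        raise IncompatibilityError(
            f"bundle version {meta.get('bundle_version')} != supported {BUNDLE_VERSION}"
        )
    with np.load(os.path.join(dirpath, "weights.npz")) as npz:
        arrays = {k: npz[k] for k in npz.files}
    return TrainedModel.from_arrays(arrays, meta)
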