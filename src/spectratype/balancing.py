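"""Class balancing by SMOTE on the training spectra.

Minority classes are brought up to the majority count by interpolation: each
synthetic sample is x_i + λ·(x_nn − x_i) with x_nn one of x_i's k nearest
same-class neighbours (Euclidean on the enrichment features, which already
share the [−1, 1] range) and λ uniform on [0, 1].  Originals are preserved
verbatim; synthetic rows get generated ids.

Balancing belongs strictly to the training path — the pipeline driver never
routes validation data through this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .data_io import UNLABELED, EnrichmentMatrix, LabelMap

logger = logging.getLogger(__name__)


@dataclass
class LabeledDataset:
    """Feature matrix paired with class labels and an ordered class vocabulary."""

    sample_ids: list[str]
    features: np.ndarray
    labels: list[str]
    class_order: list[str]

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        n = len(self.sample_ids)
        if self.features.shape[0] != n or len(self.labels) != n:
            raise ValueError("sample ids, features and labels must have equal length")
        unknown = set(self.labels) - set(self.class_order)
        if unknown:
            raise ValueError(f"labels outside class_order: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def class_counts(self) -> dict[str, int]:
        return {c: self.labels.count(c) for c in self.class_order}


def drop_unlabeled(
    features: EnrichmentMatrix | np.ndarray,
    labels: LabelMap,
    sample_ids: list[str] | None = None,
    feature_names: list[str] | None = None,
) -> LabeledDataset:
    """Retain exactly the labeled samples, original order preserved.

    ``features`` is either an EnrichmentMatrix or a raw samples × features
    array with ``sample_ids`` supplied alongside.
    """
    if isinstance(features, EnrichmentMatrix):
        sample_ids = features.sample_ids
        matrix = features.scores
    else:
        if sample_ids is None:
            raise ValueError("sample_ids required with a raw feature array")
        matrix = np.atleast_2d(np.asarray(features, dtype=float))
    missing = [s for s in sample_ids if s not in labels.labels]
    if missing:
        raise ValueError(f"samples absent from label map: {missing[:5]}")
    keep = [i for i, s in enumerate(sample_ids) if labels.labels[s] != UNLABELED]
    if not keep:
        logger.warning("all %d samples are unlabeled; returning empty dataset", len(sample_ids))
    kept_ids = [sample_ids[i] for i in keep]
    kept_labels = [labels.labels[s] for s in kept_ids]
    class_order = sorted(set(kept_labels))
    return LabeledDataset(kept_ids, matrix[keep], kept_labels, class_order)


class SmoteBalancer(BaseEstimator):
    """SMOTE oversampler with the imbalanced-learn ``fit_resample`` calling
    convention.

    Parameters
    ----------
    k_neighbors : int, default 5
        Neighbours considered per minority point; clipped (with a logged
        warning) to class_size − 1 when a class is smaller than k + 1.
    random_state : int, default 0
    """

    def __init__(self, k_neighbors: int = 5, random_state: int = 0):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=object)
        rng = np.random.default_rng(self.random_state)
        classes = sorted(set(y))
        counts = {c: int(np.sum(y == c)) for c in classes}
        majority = max(counts.values())
        new_rows, new_labels = [X], [y]
        self.sampling_log_ = {}
        for c in classes:
            need = majority - counts[c]
            self.sampling_log_[c] = need
            if need == 0:
                continue
            if counts[c] < 2:
                raise ValueError(
                    f"class {c!r} has a single sample; SMOTE cannot interpolate "
                    "— duplicate it or drop the class first"
                )
            idx = np.flatnonzero(y == c)
            pts = X[idx]
            k = self.k_neighbors
            if k > counts[c] - 1:
                k = counts[c] - 1
                logger.warning(
                    "class %s: k_neighbors clipped from %d to %d", c, self.k_neighbors, k
                )
            nn = NearestNeighbors(n_neighbors=k + 1).fit(pts)
            # drop self-neighbour in column 0
            neigh = nn.kneighbors(pts, return_distance=False)[:, 1:]
            base = rng.integers(0, counts[c], size=need)
            pick = rng.integers(0, k, size=need)
            lam = rng.uniform(0.0, 1.0, size=need)
            partners = neigh[base, pick]
            synth = pts[base] + lam[:, None] * (pts[partners] - pts[base])
            new_rows.append(synth)
            new_labels.append(np.full(need, c, dtype=object))
        return np.vstack(new_rows), np.concatenate(new_labels)


def smote_balance(
    data: LabeledDataset, k_neighbors: int = 5, seed: int = 0
) -> LabeledDataset:
    """Balance every class up to the majority count; deterministic given seed."""
    counts = data.class_counts()
    if len(set(counts.values())) == 1:
        return data  # already balanced: no-op
    balancer = SmoteBalancer(k_neighbors=k_neighbors, random_state=seed)
    X_res, y_res = balancer.fit_resample(data.features, data.labels)
    n_orig = data.n_samples
    synth_ids = []
    tally: dict[str, int] = {}
    for label in y_res[n_orig:]:
        tally[label] = tally.get(label, 0) + 1
        synth_ids.append(f"synth_{label}_{tally[label]}")
    return LabeledDataset(
        sample_ids=list(data.sample_ids) + synth_ids,
        features=X_res,
        labels=list(y_res),
        class_order=list(data.class_order),
    )
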