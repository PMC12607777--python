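"""Univariate F-score feature selection over the enrichment spectra.

The default scorer is the regression F statistic

    F = (r² / (1 − r²)) · (n − 2)

with r the Pearson correlation between a feature and the numerically
encoded class label.  Class labels are encoded as consecutive integers
0..C−1 in sorted class-name order; the encoding travels with the model
bundle, because the regression score (unlike one-way ANOVA, also provided)
depends on it.  The top k features by score, ties broken by set name, are
kept; validation cohorts are *aligned* to that frozen selection, never
re-scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .data_io import EnrichmentMatrix

_METHODS = ("regression_f", "anova_f")


@dataclass
class FeatureScores:
    set_names: list[str]
    f_values: np.ndarray
    method: str


@dataclass
class SelectedFeatures:
    """Top-k set names in descending-score order."""

    names: list[str]
    k: int

    def __post_init__(self) -> None:
        if len(self.names) != self.k or len(set(self.names)) != self.k:
            raise ValueError("names must be k unique entries")


def encode_labels(labels, class_order: list[str] | None = None) -> np.ndarray:
    """Map class strings to consecutive integers in sorted class-name order."""
    order = class_order if class_order is not None else sorted(set(labels))
    code = {c: i for i, c in enumerate(order)}
    return np.fromiter((code[c] for c in labels), dtype=float, count=len(labels))


def regression_f_score(x, y_encoded) -> float:
    """F = (r²/(1−r²))·(n−2); constant x → 0; perfect correlation → +inf."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y_encoded, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc * xc))
    sy = np.sqrt(np.sum(yc * yc))
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = float(np.dot(xc, yc) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    r2 = r * r
    if r2 >= 1.0 - 1e-12:  # numerically perfect correlation -> sentinel
        return math.inf
    return (r2 / (1.0 - r2)) * (n - 2)


def anova_f_score(x, labels) -> float:
    """One-way ANOVA F: between-group over within-group mean square."""
    x = np.asarray(x, dtype=float)
    labels = list(labels)
    if len(labels) != x.size:
        raise ValueError("length mismatch between x and labels")
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 classes")
    arrays = [x[[i for i, l in enumerate(labels) if l == g]] for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every class needs at least 2 samples")
    grand = x.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    df_between = len(groups) - 1
    df_within = x.size - len(groups)
    ms_between = ss_between / df_between
    if ss_within == 0.0:
        return 0.0 if ms_between == 0.0 else math.inf
    return float(ms_between / (ss_within / df_within))


def score_features(
    spectra: EnrichmentMatrix, labels, method: str = "regression_f"
) -> FeatureScores:
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {_METHODS}")
    labels = list(labels)
    if method == "regression_f":
        y = encode_labels(labels)
        scores = np.fromiter(
            (regression_f_score(col, y) for col in spectra.scores.T),
            dtype=float,
            count=len(spectra.set_names),
        )
    else:
        scores = np.fromiter(
            (anova_f_score(col, labels) for col in spectra.scores.T),
            dtype=float,
            count=len(spectra.set_names),
        )
    return FeatureScores(list(spectra.set_names), scores, method)


def _ranked_names(scores: FeatureScores) -> list[str]:
    # descending score, ties (and +inf among themselves) by name ascending
    return [
        name
        for name, _ in sorted(
            zip(scores.set_names, scores.f_values), key=lambda t: (-t[1], t[0])
        )
    ]


def select_top_k(
    spectra: EnrichmentMatrix, labels, k: int, method: str = "regression_f"
) -> tuple[SelectedFeatures, EnrichmentMatrix]:
    """Keep the k best-scoring features; returns the selection and the
    column-reduced matrix in selected order."""
    n_features = len(spectra.set_names)
    if k < 1 or k > n_features:
        raise ValueError(f"k={k} out of range for {n_features} features")
    scores = score_features(spectra, labels, method)
    selected = SelectedFeatures(_ranked_names(scores)[:k], k)
    return selected, align_features(spectra, selected)


def align_features(
    spectra: EnrichmentMatrix, selected: SelectedFeatures
) -> EnrichmentMatrix:
    """Subset/reorder columns to a frozen training selection; never re-scores."""
    missing = [n for n in selected.names if n not in spectra.set_names]
    if missing:
        raise ValueError(f"features absent from matrix: {missing}")
    return EnrichmentMatrix.from_frame(spectra.to_frame()[selected.names])


class FScoreSelector(BaseEstimator, TransformerMixin):
    """Top-k univariate F-score selector (scikit-learn transformer).

    Accepts an EnrichmentMatrix or a plain samples × features array.

    Parameters
    ----------
    k : int, default 2000
    method : {"regression_f", "anova_f"}, default "regression_f"

    Attributes
    ----------
    scores_ : ndarray of per-feature F values (input feature order)
    selected_names_ : list of the k kept feature names, descending score
    """

    def __init__(self, k: int = 2000, method: str = "regression_f"):
        self.k = k
        self.method = method

    @staticmethod
    def _names_and_values(X) -> tuple[list[str], np.ndarray]:
        if isinstance(X, EnrichmentMatrix):
            return list(X.set_names), X.scores
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return [f"f{i}" for i in range(X.shape[1])], X

    def fit(self, X, y):
        names, values = self._names_and_values(X)
        if self.k < 1 or self.k > len(names):
            raise ValueError(f"k={self.k} out of range for {len(names)} features")
        labels = list(y)
        if self.method == "regression_f":
            encoded = encode_labels(labels)
            fvals = np.fromiter(
                (regression_f_score(col, encoded) for col in values.T),
                dtype=float, count=len(names),
            )
        elif self.method == "anova_f":
            fvals = np.fromiter(
                (anova_f_score(col, labels) for col in values.T),
                dtype=float, count=len(names),
            )
        else:
            raise ValueError(f"unknown method {self.method!r}; expected one of {_METHODS}")
        scores = FeatureScores(names, fvals, self.method)
        self.scores_ = fvals
        self.feature_names_in_ = names
        self.selected_ = SelectedFeatures(_ranked_names(scores)[: self.k], self.k)
        self.selected_names_ = list(self.selected_.names)
        return self

    def transform(self, X):
        if isinstance(X, EnrichmentMatrix):
            return align_features(X, self.selected_)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        index = {n: i for i, n in enumerate(self.feature_names_in_)}
        cols = [index[n] for n in self.selected_.names]
        return X[:, cols]
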