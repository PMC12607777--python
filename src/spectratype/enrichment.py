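"""Per-sample gene-set enrichment scoring ("functional spectra").

Each sample's genes are ranked by that sample's own expression, descending.
For a gene set S of size N_H inside a universe of N genes, two running sums
walk down the ranked list:

    P_hit(S, i)  = sum_{g_j in S, j <= i} |r_j|^p / N_R,
                   N_R = sum_{g_j in S} |r_j|^p
    P_miss(S, i) = sum_{g_j not in S, j <= i} 1 / (N - N_H)

The enrichment score (ES) is the signed value of P_hit - P_miss at the
position of maximal absolute deviation; it lies in [-1, 1] and reaches +1
exactly when every member outranks every non-member.  Because the ranking is
within-sample, a single sample can be scored in isolation — which is what
the prediction path requires.

The weight exponent p defaults to 1 (the canonical weighted statistic);
p = 0 degrades to a pure rank statistic that is invariant under any strictly
increasing transform of the expression values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .data_io import EnrichmentMatrix, ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


class DegenerateSetError(ValueError):
    """A gene set is disjoint from, or equal to, the measured universe."""


@dataclass
class EnrichmentParams:
    """Scoring parameters.

    weight_exponent
        Exponent p on |r_j| in the hit weights; 0 means rank-only.
    min_set_size, max_set_size
        Size filter applied *after* intersecting each set with the measured
        gene universe; sets outside the window are dropped.
    positive_only
        If True, report the maximum of the running sum instead of the signed
        two-sided extremum.
    """

    weight_exponent: float = 1.0
    min_set_size: int = 5
    max_set_size: int | None = None
    positive_only: bool = False

    def __post_init__(self) -> None:
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be >= 0")
        if self.min_set_size < 1:
            raise ValueError("min_set_size must be >= 1")


@dataclass
class RankedSample:
    """A sample's genes in descending-expression order with aligned metric values."""

    ordered_gene_ids: list[str]
    metric_values: np.ndarray

    def __post_init__(self) -> None:
        self.metric_values = np.asarray(self.metric_values, dtype=float)
        if len(self.ordered_gene_ids) != self.metric_values.shape[0]:
            raise ValueError("gene ids and metric values must have equal length")
        if np.any(np.diff(self.metric_values) > 0):
            raise ValueError("metric values must be non-increasing along the ranking")


def _rank_order(gene_ids: np.ndarray, values: np.ndarray) -> np.ndarray:
    # primary key: value descending; secondary: gene id ascending (determinism)
    return np.lexsort((gene_ids, -values))


def rank_sample(expr: ExpressionMatrix, sample_id: str) -> RankedSample:
    """Rank one sample's genes by expression, descending; ties by gene id."""
    values = expr.sample_values(sample_id)
    ids = np.asarray(expr.gene_ids, dtype=object)
    order = _rank_order(ids, values)
    return RankedSample(list(ids[order]), values[order])


def _hit_mask(ranked: RankedSample, members) -> np.ndarray:
    members = set(members)
    mask = np.fromiter(
        (g in members for g in ranked.ordered_gene_ids), dtype=bool,
        count=len(ranked.ordered_gene_ids),
    )
    n_hit = int(mask.sum())
    if n_hit == 0:
        raise DegenerateSetError("gene set is disjoint from the expression universe")
    if n_hit == mask.size:
        raise DegenerateSetError("gene set covers the whole expression universe")
    return mask


def _running_sum_from_mask(mask: np.ndarray, values: np.ndarray, p: float) -> np.ndarray:
    n = mask.size
    n_hit = int(mask.sum())
    weights = np.abs(values) ** p
    n_r = weights[mask].sum()
    if n_r == 0.0:
        # all member weights vanish (e.g. member expression exactly 0 with
        # p > 0): fall back to uniform hit steps so the statistic stays defined
        p_hit = np.cumsum(mask) / n_hit
    else:
        p_hit = np.cumsum(np.where(mask, weights, 0.0)) / n_r
    p_miss = np.cumsum(~mask) / (n - n_hit)
    return p_hit - p_miss


def running_sum(ranked: RankedSample, members, params: EnrichmentParams) -> np.ndarray:
    """P_hit − P_miss trajectory along the ranked list (length N, ends at 0)."""
    mask = _hit_mask(ranked, members)
    return _running_sum_from_mask(mask, ranked.metric_values, params.weight_exponent)


def _score_from_trajectory(traj: np.ndarray, positive_only: bool) -> float:
    if positive_only:
        return float(max(traj.max(), 0.0))
    # earliest index wins on ties in |deviation| (argmax convention)
    return float(traj[np.argmax(np.abs(traj))])


def enrichment_score(ranked: RankedSample, members, params: EnrichmentParams) -> float:
    """Signed value of the running sum at its maximal absolute deviation."""
    return _score_from_trajectory(running_sum(ranked, members, params), params.positive_only)


def _filter_sets(sets: GeneSetCollection, universe: set[str], params: EnrichmentParams):
    """Intersect each set with the universe, then size-filter. Order preserved."""
    survivors: list[tuple[str, np.ndarray]] = []
    dropped = 0
    n = len(universe)
    index = {g: i for i, g in enumerate(sorted(universe))}
    for name in sets.names:
        members = [g for g in sets.members(name) if g in universe]
        size = len(members)
        too_big = params.max_set_size is not None and size > params.max_set_size
        if size < params.min_set_size or too_big or size == n:
            dropped += 1
            continue
        survivors.append((name, np.fromiter((index[g] for g in members), dtype=int)))
    if dropped:
        logger.info("dropped %d gene set(s) after universe intersection / size filter", dropped)
    return survivors


def functional_spectra(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    params: EnrichmentParams | None = None,
) -> EnrichmentMatrix:
    """Score every (sample, gene set) pair: the samples × sets spectra matrix.

    Sets are intersected with the measured universe and size-filtered first;
    surviving sets keep collection order.  Vectorized across sets per sample.
    """
    params = params or EnrichmentParams()
    universe = set(expr.gene_ids)
    survivors = _filter_sets(sets, universe, params)
    if not survivors:
        raise DegenerateSetError(
            "no gene set survives universe intersection and size filtering"
        )
    sorted_genes = sorted(universe)
    sorted_pos = {g: i for i, g in enumerate(sorted_genes)}
    n = len(sorted_genes)
    # membership over genes in sorted-universe coordinates
    member_matrix = np.zeros((len(survivors), n), dtype=bool)
    for k, (_, idx) in enumerate(survivors):
        member_matrix[k, idx] = True
    n_hit = member_matrix.sum(axis=1)

    gene_pos = np.fromiter((sorted_pos[g] for g in expr.gene_ids), dtype=int)
    ids = np.asarray(expr.gene_ids, dtype=object)
    p = params.weight_exponent
    scores = np.empty((expr.n_samples, len(survivors)))
    for j in range(expr.n_samples):
        values = expr.values[:, j]
        order = _rank_order(ids, values)
        ranked_values = values[order]
        perm = gene_pos[order]  # sorted-universe index of gene at each rank
        m = member_matrix[:, perm]  # sets × ranks
        weights = np.abs(ranked_values) ** p
        hit_w = np.where(m, weights, 0.0)
        n_r = hit_w.sum(axis=1)
        uniform = n_r == 0.0
        if np.any(uniform):
            hit_w[uniform] = m[uniform].astype(float)
            n_r[uniform] = n_hit[uniform]
        p_hit = np.cumsum(hit_w, axis=1) / n_r[:, None]
        p_miss = np.cumsum(~m, axis=1) / (n - n_hit)[:, None]
        traj = p_hit - p_miss
        if params.positive_only:
            scores[j] = np.maximum(traj.max(axis=1), 0.0)
        else:
            best = np.argmax(np.abs(traj), axis=1)
            scores[j] = traj[np.arange(traj.shape[0]), best]
    return EnrichmentMatrix(
        sample_ids=list(expr.sample_ids),
        set_names=[name for name, _ in survivors],
        scores=scores,
    )


class SpectraTransformer(BaseEstimator, TransformerMixin):
    """Expression → enrichment-spectra transformer (scikit-learn style).

    Stateless apart from recording, at fit time, which gene sets survive the
    universe intersection and size filter — the feature vocabulary that
    ``transform`` then produces for any cohort.

    Parameters
    ----------
    gene_sets : GeneSetCollection
    weight_exponent : float, default 1.0
    min_set_size : int, default 5
    max_set_size : int or None, default None
    positive_only : bool, default False
    """

    def __init__(
        self,
        gene_sets: GeneSetCollection | None = None,
        weight_exponent: float = 1.0,
        min_set_size: int = 5,
        max_set_size: int | None = None,
        positive_only: bool = False,
    ):
        self.gene_sets = gene_sets
        self.weight_exponent = weight_exponent
        self.min_set_size = min_set_size
        self.max_set_size = max_set_size
        self.positive_only = positive_only

    def _params(self) -> EnrichmentParams:
        return EnrichmentParams(
            weight_exponent=self.weight_exponent,
            min_set_size=self.min_set_size,
            max_set_size=self.max_set_size,
            positive_only=self.positive_only,
        )

    def fit(self, X: ExpressionMatrix, y=None):
        if self.gene_sets is None:
            raise ValueError("gene_sets must be provided")
        survivors = _filter_sets(self.gene_sets, set(X.gene_ids), self._params())
        if not survivors:
            raise DegenerateSetError(
                "no gene set survives universe intersection and size filtering"
            )
        self.set_names_ = [name for name, _ in survivors]
        return self

    def transform(self, X: ExpressionMatrix) -> EnrichmentMatrix:
        em = functional_spectra(X, self.gene_sets, self._params())
        if not hasattr(self, "set_names_"):
            return em
        missing = [s for s in self.set_names_ if s not in em.set_names]
        if missing:
            raise DegenerateSetError(f"fitted gene sets absent from cohort: {missing}")
        frame = em.to_frame()[self.set_names_]
        return EnrichmentMatrix.from_frame(frame)
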