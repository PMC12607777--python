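"""Synthetic expression cohorts with subtype-specific pathway activation.

The generator emulates the statistical structure the pipeline assumes:
a large background of uninformative genes, a handful of "informative"
gene sets per class whose member genes are mean-shifted in samples of that
class, and optionally a fraction of unlabeled samples.  Expression is
Gaussian additive — sufficient because the enrichment stage uses only
within-sample ordering, which responds monotonically to a mean shift.

Every draw is deterministic given ``seed``; a ground-truth sidecar records
which sets are informative for which class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import (
    UNLABELED,
    ExpressionMatrix,
    GeneSetCollection,
    LabelMap,
)


@dataclass
class SimulationConfig:
    """Study-design knobs for one synthetic cohort.

    effect_size is the mean shift, in units of noise_sd, applied to member
    genes of a class's informative sets in that class's samples.
    overlap_fraction > 0 makes consecutive classes share that fraction of
    their informative genes (confusable subtypes).
    """

    n_genes: int = 2000
    n_sets: int = 50
    set_size_range: tuple[int, int] = (10, 20)
    n_classes: int = 4
    samples_per_class: tuple[int, ...] = (40, 40, 40, 40)
    informative_sets_per_class: int = 3
    effect_size: float = 3.0
    noise_sd: float = 1.0
    unlabeled_fraction: float = 0.0
    overlap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.samples_per_class = tuple(int(n) for n in self.samples_per_class)
        if len(self.samples_per_class) != self.n_classes:
            raise ValueError("samples_per_class must list one count per class")
        lo, hi = self.set_size_range
        if not (2 <= lo <= hi <= self.n_genes):
            raise ValueError("set sizes must lie within [2, n_genes]")
        if self.informative_sets_per_class * self.n_classes > self.n_sets:
            raise ValueError("more informative sets requested than n_sets")
        if not 0.0 <= self.unlabeled_fraction < 1.0:
            raise ValueError("unlabeled_fraction must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def class_names(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_classes)]


@dataclass
class GroundTruth:
    """Which sets are informative for which class (the recovery target)."""

    informative_sets: dict[str, list[str]] = field(default_factory=dict)

    @property
    def all_informative(self) -> list[str]:
        return [s for sets in self.informative_sets.values() for s in sets]


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{str(i).zfill(width)}" for i in range(n)]


def simulate_gene_sets(config: SimulationConfig) -> tuple[GeneSetCollection, GroundTruth]:
    """Draw the gene-set collection; informative sets disjoint across classes.

    Informative sets come first (per class, in class order) so their member
    pools can be kept disjoint; background sets are free draws from the
    whole universe.  With overlap_fraction > 0, each class's informative
    pool re-uses that fraction of the previous class's pool.
    """
    rng = np.random.default_rng(config.seed)
    genes = np.asarray(_gene_ids(config.n_genes), dtype=object)
    lo, hi = config.set_size_range
    n_inf = config.informative_sets_per_class
    max_size = hi * n_inf
    if max_size * config.n_classes > config.n_genes and config.overlap_fraction == 0.0:
        raise ValueError(
            "cannot keep informative sets disjoint across classes: "
            f"need up to {max_size * config.n_classes} genes, have {config.n_genes}"
        )
    pool = rng.permutation(config.n_genes)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    truth = GroundTruth({c: [] for c in config.class_names})
    cursor = 0
    prev_pool: np.ndarray | None = None
    width = len(str(config.n_sets - 1))
    set_idx = 0
    for c in config.class_names:
        take = max_size
        class_pool = pool[cursor : cursor + take]
        cursor += take
        if prev_pool is not None and config.overlap_fraction > 0.0:
            n_shared = int(round(config.overlap_fraction * take))
            class_pool = np.concatenate([prev_pool[:n_shared], class_pool[: take - n_shared]])
        prev_pool = class_pool
        offset = 0
        for _ in range(n_inf):
            size = int(rng.integers(lo, hi + 1))
            members = genes[class_pool[offset : offset + size]]
            offset += size
            name = f"SET_{str(set_idx).zfill(width)}"
            sets[name] = (f"informative:{c}", frozenset(members))
            truth.informative_sets[c].append(name)
            set_idx += 1
    while set_idx < config.n_sets:
        size = int(rng.integers(lo, hi + 1))
        members = genes[rng.choice(config.n_genes, size=size, replace=False)]
        name = f"SET_{str(set_idx).zfill(width)}"
        sets[name] = ("background", frozenset(members))
        set_idx += 1
    return GeneSetCollection(sets), truth


def simulate_cohort(
    config: SimulationConfig,
    sets: GeneSetCollection,
    truth: GroundTruth,
) -> tuple[ExpressionMatrix, LabelMap, GroundTruth]:
    """Draw expression and labels for the configured class sizes.

    Baseline expression is i.i.d. Normal(0, noise_sd); samples of class c
    have the member genes of c's informative sets shifted by
    +effect_size·noise_sd.  ``unlabeled_fraction`` of samples (rounded to
    the nearest count) are stripped of their label.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = _gene_ids(config.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    n_total = sum(config.samples_per_class)
    values = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_total))
    sample_ids: list[str] = []
    labels: dict[str, str] = {}
    col = 0
    swidth = len(str(n_total - 1))
    for c, count in zip(config.class_names, config.samples_per_class):
        shifted_genes = sorted(
            {g for s in truth.informative_sets[c] for g in sets.members(s)}
        )
        rows = [gene_index[g] for g in shifted_genes]
        for _ in range(count):
            sid = f"S{str(col).zfill(swidth)}"
            sample_ids.append(sid)
            labels[sid] = c
            if rows:
                values[rows, col] += config.effect_size * config.noise_sd
            col += 1
    n_unlabel = int(round(config.unlabeled_fraction * n_total))
    if n_unlabel:
        drop = rng.choice(n_total, size=n_unlabel, replace=False)
        for i in drop:
            labels[sample_ids[i]] = UNLABELED
    expr = ExpressionMatrix(genes, sample_ids, values)
    return expr, LabelMap(labels), truth


@dataclass
class SimulatedStudy:
    expression: ExpressionMatrix
    gene_sets: GeneSetCollection
    labels: LabelMap
    truth: GroundTruth
    config: SimulationConfig


def simulate(config: SimulationConfig | None = None) -> SimulatedStudy:
    """One-call generator: gene sets + cohort + ground truth."""
    config = config or SimulationConfig()
    sets, truth = simulate_gene_sets(config)
    expr, labels, truth = simulate_cohort(config, sets, truth)
    return SimulatedStudy(expr, sets, labels, truth, config)
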