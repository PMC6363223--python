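"""Synthetic multi-study benchmark generator.

Emulates the statistical structure the inference method assumes: several
datasets whose true regulatory networks share a controlled fraction of
edges while keeping dataset-unique edges; expression generated linearly
from latent TF activities plus Gaussian noise; priors with controlled
recall and a controlled false-edge rate (default one false interaction per
five true ones); and random prior/evaluation splits of a gold standard.

All randomness flows from a single integer seed through named substreams
(truth / activities / noise / prior / splits), so each component is
independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datasets import (DataError, ExpressionDataset, GoldStandard,
                       PriorMatrix, SampleMetadata)

_STREAM_TRUTH = 11
_STREAM_ACT = 13
_STREAM_NOISE = 17
_STREAM_PRIOR = 19
_STREAM_SPLIT = 23

#: nonzero regulatory weights are drawn uniform in +/-[LOW, HIGH] so planted
#: effects are bounded away from zero
WEIGHT_LOW, WEIGHT_HIGH = 0.5, 2.0


@dataclass
class SyntheticTruth:
    """Planted multi-study ground truth."""

    genes: list[str]
    tfs: list[str]
    weights: np.ndarray            # (n_datasets, n_genes, n_tfs)
    shared_mask: np.ndarray        # (n_genes, n_tfs) bool, edges common to all
    seed: int
    dataset_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.dataset_ids:
            self.dataset_ids = [f"synth{d}" for d in range(self.weights.shape[0])]

    @property
    def n_datasets(self) -> int:
        return self.weights.shape[0]

    def edges(self, dataset: int) -> set[tuple[str, str]]:
        rows, cols = np.nonzero(self.weights[dataset])
        return {(self.tfs[c], self.genes[r]) for r, c in zip(rows, cols)}

    def union_edges(self) -> set[tuple[str, str]]:
        any_nz = (self.weights != 0).any(axis=0)
        rows, cols = np.nonzero(any_nz)
        return {(self.tfs[c], self.genes[r]) for r, c in zip(rows, cols)}

    def gold_standard(self, dataset: int | None = None) -> GoldStandard:
        """Planted edges as a GoldStandard (one dataset, or the union)."""
        if dataset is not None:
            w = self.weights[dataset]
        else:
            first = np.argmax(self.weights != 0, axis=0)
            w = np.take_along_axis(self.weights, first[None], axis=0)[0]
            w = np.where((self.weights != 0).any(axis=0), w, 0.0)
        rows, cols = np.nonzero(w)
        return GoldStandard({(self.tfs[c], self.genes[r], int(np.sign(w[r, c])))
                             for r, c in zip(rows, cols)})


def _draw_weight(rng) -> float:
    return float(rng.choice([-1.0, 1.0]) * rng.uniform(WEIGHT_LOW, WEIGHT_HIGH))


def generate_truth(genes: int, tfs: int, datasets: int,
                   edges_per_gene: int = 2, shared_fraction: float = 0.8,
                   seed: int = 0) -> SyntheticTruth:
    """Sample sparse signed truth networks with a shared edge core.

    For each gene, ``round(shared_fraction * edges_per_gene)`` regulators
    (with identical signed weights) are shared by every dataset; the
    remaining regulators are drawn independently per dataset from the
    leftover TFs.
    """
    if not 0 <= shared_fraction <= 1:
        raise DataError("shared_fraction must lie in [0, 1]")
    if edges_per_gene > tfs:
        raise DataError("edges_per_gene cannot exceed the number of TFs")
    rng = np.random.default_rng([seed, _STREAM_TRUTH])
    gene_ids = [f"G{i:04d}" for i in range(genes)]
    tf_ids = [f"TF{k:02d}" for k in range(tfs)]
    W = np.zeros((datasets, genes, tfs))
    shared_mask = np.zeros((genes, tfs), bool)
    n_shared = int(round(shared_fraction * edges_per_gene))
    for g in range(genes):
        order = rng.permutation(tfs)
        shared = order[:n_shared]
        pool = order[n_shared:]
        for k in shared:
            w = _draw_weight(rng)
            W[:, g, k] = w
            shared_mask[g, k] = True
        n_unique = edges_per_gene - n_shared
        for d in range(datasets):
            picks = rng.choice(pool, size=n_unique, replace=False) if n_unique else []
            for k in picks:
                W[d, g, k] = _draw_weight(rng)
    return SyntheticTruth(gene_ids, tf_ids, W, shared_mask, seed)


def generate_expression(truth: SyntheticTruth, samples_per_dataset: int = 50,
                        noise_sigma: float = 0.5, time_series: bool = False,
                        ar_coef: float = 0.8, delta_t: float = 10.0,
                        ) -> tuple[list[ExpressionDataset], list[np.ndarray]]:
    """Generate expression ``X = W_true A + eps`` per dataset.

    Activities are i.i.d. standard normal per sample by default; with
    ``time_series=True`` each dataset is one AR(1) chain (stationary unit
    variance, lag-1 coefficient ``ar_coef``) with constant sampling
    interval ``delta_t``.  TF mRNA rows (activity + noise) are appended to
    the gene panel so the expression-fallback TFA path is exercisable.

    Returns the datasets and the true activity matrices (TFs x samples).
    """
    if noise_sigma < 0:
        raise DataError("noise_sigma must be >= 0")
    out, acts = [], []
    p = len(truth.tfs)
    n = samples_per_dataset
    for d in range(truth.n_datasets):
        rng_a = np.random.default_rng([truth.seed, _STREAM_ACT, d])
        rng_e = np.random.default_rng([truth.seed, _STREAM_NOISE, d])
        if time_series:
            A = np.empty((p, n))
            A[:, 0] = rng_a.standard_normal(p)
            innov = math.sqrt(1.0 - ar_coef ** 2)
            for t in range(1, n):
                A[:, t] = ar_coef * A[:, t - 1] + innov * rng_a.standard_normal(p)
        else:
            A = rng_a.standard_normal((p, n))
        X = truth.weights[d] @ A + noise_sigma * rng_e.standard_normal(
            (len(truth.genes), n))
        X_tf = A + noise_sigma * rng_e.standard_normal((p, n))
        samples = [f"{truth.dataset_ids[d]}_s{j:03d}" for j in range(n)]
        if time_series:
            md = SampleMetadata(
                list(samples), np.ones(n, bool),
                np.array([j == 0 for j in range(n)]),
                [None] + samples[:-1],
                np.array([np.nan] + [delta_t] * (n - 1)))
        else:
            md = SampleMetadata.steady_state(samples)
        ds = ExpressionDataset(truth.dataset_ids[d],
                               truth.genes + truth.tfs, samples,
                               np.vstack([X, X_tf]), md)
        out.append(ds)
        acts.append(A)
    return out, acts


def perfect_prior(truth: SyntheticTruth) -> PriorMatrix:
    """The union of planted edges with their true signed weights.

    Unlike :func:`corrupt_prior` (which emits +/-1 entries, like a curated
    edge list), this carries the generative magnitudes, so activity
    estimation inverts the truth exactly on fully shared networks.
    """
    first = np.argmax(truth.weights != 0, axis=0)
    w = np.take_along_axis(truth.weights, first[None], axis=0)[0]
    w = np.where((truth.weights != 0).any(axis=0), w, 0.0)
    return PriorMatrix(list(truth.genes), list(truth.tfs), w)


@dataclass
class CorruptedPrior:
    """A prior with known provenance of every entry.

    ``true_edges`` are planted interactions kept in the prior;
    ``false_edges`` are injected non-interactions, flagged so downstream
    analyses can compare confidence scores of true versus false prior
    entries.
    """

    prior: PriorMatrix
    true_edges: set[tuple[str, str]]
    false_edges: set[tuple[str, str]]


def corrupt_prior(truth: SyntheticTruth, recall: float = 1.0,
                  false_per_true: float = 5, seed: int | None = None,
                  ) -> CorruptedPrior:
    """Build a prior keeping a ``recall`` fraction of true edges plus noise.

    One false edge is added for every ``false_per_true`` kept true edges
    (``floor(kept / false_per_true)``; pass ``math.inf`` to disable).  False
    edges are sampled uniformly from pairs that are non-edges in every
    dataset, so the false set is disjoint from the truth by construction.
    """
    if not 0 < recall <= 1:
        raise DataError("recall must lie in (0, 1]")
    rng = np.random.default_rng([truth.seed if seed is None else seed,
                                 _STREAM_PRIOR])
    any_nz = (truth.weights != 0).any(axis=0)
    true_pairs = np.argwhere(any_nz)
    n_keep = int(round(recall * len(true_pairs)))
    keep_idx = rng.choice(len(true_pairs), size=n_keep, replace=False)
    keep_idx.sort()
    kept = true_pairs[keep_idx]

    n_false = 0 if math.isinf(false_per_true) else int(n_keep // false_per_true)
    non_pairs = np.argwhere(~any_nz)
    if n_false > len(non_pairs):
        raise DataError("not enough non-edges to sample false prior entries")
    false_sel = non_pairs[rng.choice(len(non_pairs), size=n_false,
                                     replace=False)] if n_false else np.empty((0, 2), int)

    values = np.zeros((len(truth.genes), len(truth.tfs)))
    first = np.argmax(truth.weights != 0, axis=0)
    for g, k in kept:
        values[g, k] = np.sign(truth.weights[first[g, k], g, k])
    for g, k in false_sel:
        values[g, k] = rng.choice([-1.0, 1.0])
    prior = PriorMatrix(list(truth.genes), list(truth.tfs), values)
    to_named = lambda pairs: {(truth.tfs[k], truth.genes[g]) for g, k in pairs}
    return CorruptedPrior(prior, to_named(kept), to_named(false_sel))


def split_gold_standard(gold: GoldStandard, prior_fraction: float = 0.5,
                        n_splits: int = 10, seed: int = 0,
                        ) -> list[tuple[GoldStandard, GoldStandard]]:
    """Random disjoint, exhaustive prior/evaluation partitions of a gold set.

    Ten independent splits reproduce the replication design used for the
    leave-out evaluations.
    """
    if not 0 < prior_fraction < 1:
        raise DataError("prior_fraction must lie in (0, 1)")
    rng = np.random.default_rng([seed, _STREAM_SPLIT])
    edges = sorted(gold.edges)
    n_prior = int(round(prior_fraction * len(edges)))
    splits = []
    for _ in range(n_splits):
        perm = rng.permutation(len(edges))
        prior_part = {edges[i] for i in perm[:n_prior]}
        eval_part = {edges[i] for i in perm[n_prior:]}
        splits.append((GoldStandard(prior_part), GoldStandard(eval_part)))
    return splits


def prior_from_edges(edges: set[tuple[str, str, int]] | GoldStandard,
                     genes: list[str], tfs: list[str]) -> PriorMatrix:
    """Materialise a signed edge set as a genes x TFs prior matrix."""
    if isinstance(edges, GoldStandard):
        edges = edges.edges
    values = np.zeros((len(genes), len(tfs)))
    g_idx = {g: i for i, g in enumerate(genes)}
    t_idx = {t: i for i, t in enumerate(tfs)}
    for tf, g, s in edges:
        if g in g_idx and tf in t_idx:
            values[g_idx[g], t_idx[tf]] = s
    return PriorMatrix(list(genes), list(tfs), values)
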