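"""Edge confidence scores, rank aggregation and gold-standard evaluation.

A selected predictor k for gene i in dataset d is scored by how much it
improves an ordinary-least-squares refit on the selected support:

    c_{k,i} = 1 - sigma^2_full / sigma^2_without_k

where sigma^2 is the residual variance with and without predictor k.  The
reduced model is nested in the full one, so c is always in [0, 1].
Unselected predictors score 0.

Scores from repeated bootstraps (and, for ensembles, from multiple
networks) are combined by averaging per-edge ranks and rescaling the
averaged ranks to confidences in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datasets import DataError, GoldStandard
from .multitask import TaskData


# ---------------------------------------------------------------------------
# confidence scores
# ---------------------------------------------------------------------------

def _ols_rss(design_rows: np.ndarray, response: np.ndarray) -> float:
    """Residual sum of squares of a minimum-norm OLS fit.

    The minimum-norm solution keeps the RSS well defined (and nested) even
    when the support contains exactly collinear predictors; removing one of
    an exact duplicate pair then leaves the RSS unchanged and the duplicate
    scores 0.
    """
    if design_rows.shape[0] == 0:
        return float(response @ response)
    coef, _, _, _ = np.linalg.lstsq(design_rows.T, response, rcond=None)
    resid = response - design_rows.T @ coef
    return float(resid @ resid)


def scores_one_task(design: np.ndarray, response: np.ndarray,
                    support: np.ndarray) -> np.ndarray:
    """Leave-one-predictor-out variance-explained scores for one dataset."""
    p = design.shape[0]
    c = np.zeros(p)
    idx = np.flatnonzero(support)
    if idx.size == 0:
        return c
    rss_full = _ols_rss(design[idx], response)
    for k in idx:
        rest = idx[idx != k]
        rss_red = _ols_rss(design[rest], response)
        if rss_red <= 0:
            c[k] = 0.0
        else:
            c[k] = 1.0 - rss_full / rss_red
    return np.clip(c, 0.0, 1.0)


def confidence_scores(support, tasks: list[TaskData]) -> np.ndarray:
    """Score the selected predictors of a fitted decomposition.

    ``support`` is a WeightDecomposition (its nonzero pattern is used) or a
    boolean (TFs x datasets) matrix.  Returns a (TFs x datasets) matrix of
    c in [0, 1]; unselected entries are 0.
    """
    mask = support if isinstance(support, np.ndarray) else support.support
    mask = np.asarray(mask, bool)
    p, d = mask.shape
    if len(tasks) != d:
        raise DataError("support/task count mismatch")
    out = np.zeros((p, d))
    for j, t in enumerate(tasks):
        out[:, j] = scores_one_task(t.design, t.response, mask[:, j])
    return out


# ---------------------------------------------------------------------------
# ranked networks and rank aggregation
# ---------------------------------------------------------------------------

@dataclass
class RankedNetwork:
    """A scored, ranked list of TF->gene regulatory hypotheses."""

    dataset_id: str
    tfs: list[str]
    genes: list[str]
    confidences: np.ndarray            # (n_genes, n_tfs) in [0, 1]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.confidences = np.asarray(self.confidences, float)
        if self.confidences.shape != (len(self.genes), len(self.tfs)):
            raise DataError("confidence matrix shape mismatch")
        if ((self.confidences < 0) | (self.confidences > 1)).any():
            raise DataError("confidences must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        """Edge list sorted by descending confidence (ties lexicographic)."""
        g_idx, t_idx = np.meshgrid(range(len(self.genes)), range(len(self.tfs)),
                                   indexing="ij")
        df = pd.DataFrame({
            "tf": [self.tfs[t] for t in t_idx.ravel()],
            "gene": [self.genes[g] for g in g_idx.ravel()],
            "combined_confidence": self.confidences.ravel(),
        })
        df = df.sort_values(["combined_confidence", "tf", "gene"],
                            ascending=[False, True, True],
                            kind="mergesort").reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        return df

    def edge_confidence(self, tf: str, gene: str) -> float:
        return float(self.confidences[self.genes.index(gene), self.tfs.index(tf)])


def _rank_matrix(scores: np.ndarray) -> np.ndarray:
    """Descending average ranks of a flat score array (1 = best, ties averaged)."""
    return rankdata(-scores, method="average")


def _ranks_to_confidences(mean_ranks: np.ndarray) -> np.ndarray:
    """Affine rescale: best achieved rank -> 1, worst -> 0 (all-tied -> 0.5)."""
    lo, hi = mean_ranks.min(), mean_ranks.max()
    if hi == lo:
        return np.full_like(mean_ranks, 0.5)
    return (hi - mean_ranks) / (hi - lo)


def rank_combine(score_matrices: list[np.ndarray], tfs: list[str],
                 genes: list[str], dataset_id: str = "combined",
                 provenance: dict | None = None) -> RankedNetwork:
    """Rank-average (genes x TFs) score matrices into one ranked network.

    Within each matrix edges are ranked by descending score with ties given
    their average rank; ranks are averaged across matrices, then mapped
    affinely to confidences in [0, 1].
    """
    if not score_matrices:
        raise DataError("no score matrices to combine")
    shape = (len(genes), len(tfs))
    flats = []
    for m in score_matrices:
        m = np.asarray(m, float)
        if m.shape != shape:
            raise DataError(f"score matrix shape {m.shape} != {shape}")
        flats.append(_rank_matrix(m.ravel()))
    mean_ranks = np.mean(flats, axis=0)
    conf = _ranks_to_confidences(mean_ranks).reshape(shape)
    return RankedNetwork(dataset_id, list(tfs), list(genes), conf,
                         provenance or {})


def combine_networks(networks: list[RankedNetwork],
                     dataset_id: str = "combined") -> RankedNetwork:
    """Ensemble by average rank across already-ranked networks (STL-C/MTL-C)."""
    if not networks:
        raise DataError("no networks to combine")
    first = networks[0]
    for net in networks[1:]:
        if net.tfs != first.tfs or net.genes != first.genes:
            raise DataError("networks cover different edge universes")
    return rank_combine([n.confidences for n in networks], first.tfs,
                        first.genes, dataset_id,
                        {"combined_from": [n.dataset_id for n in networks]})


# ---------------------------------------------------------------------------
# gold-standard evaluation
# ---------------------------------------------------------------------------

@dataclass
class PrCurve:
    """A prefix-based precision-recall step curve."""

    recall: np.ndarray
    precision: np.ndarray
    aupr: float


def _gold_restricted_edges(network: RankedNetwork, gold: GoldStandard):
    """Ranked candidate edges within the gold TF/gene universe."""
    tf_u, gene_u = gold.tfs, gold.genes
    df = network.to_frame()
    df = df[df["tf"].isin(tf_u) & df["gene"].isin(gene_u)]
    return list(zip(df["tf"], df["gene"]))


def precision_recall(network: RankedNetwork, gold: GoldStandard) -> PrCurve:
    """Precision-recall over the ranked list, restricted to the gold universe.

    Sweeps ranked prefixes, computing precision and recall at each, and
    integrates area by the step rule AUPR = sum precision * delta(recall).
    Gold-standard signs are ignored (presence/absence only).
    """
    if len(gold) == 0:
        raise DataError("empty gold standard")
    edges = _gold_restricted_edges(network, gold)
    positives = gold.pairs
    n_pos = len(positives)
    tp = 0
    prec, rec = [], []
    for i, e in enumerate(edges, start=1):
        if e in positives:
            tp += 1
        prec.append(tp / i)
        rec.append(tp / n_pos)
    prec_a = np.asarray(prec)
    rec_a = np.asarray(rec)
    if len(rec_a) == 0:
        return PrCurve(np.zeros(0), np.zeros(0), 0.0)
    drec = np.diff(np.concatenate([[0.0], rec_a]))
    return PrCurve(rec_a, prec_a, float(np.sum(prec_a * drec)))


def sign_agreement(network: RankedNetwork, gold: GoldStandard,
                   signs: dict[tuple[str, str], float]) -> float:
    """Diagnostic: fraction of recovered gold edges with matching sign."""
    agree = tot = 0
    for tf, g, s in gold.edges:
        pred = signs.get((tf, g))
        if pred:
            tot += 1
            if np.sign(pred) == s:
                agree += 1
    return agree / tot if tot else float("nan")


def filter_at_precision(network: RankedNetwork, gold: GoldStandard,
                        cutoff: float) -> list[tuple[str, str]]:
    """The maximal ranked prefix whose precision stays >= ``cutoff``."""
    if not 0 < cutoff <= 1:
        raise DataError("cutoff must be in (0, 1]")
    edges = _gold_restricted_edges(network, gold)
    positives = gold.pairs
    tp = 0
    best = 0
    for i, e in enumerate(edges, start=1):
        if e in positives:
            tp += 1
        if tp / i >= cutoff:
            best = i
    return edges[:best]


def overlap_counts(edge_sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Venn counts: edges belonging to exactly each subset of networks."""
    names = sorted(edge_sets)
    universe = set().union(*edge_sets.values()) if edge_sets else set()
    counts: dict[tuple[str, ...], int] = {}
    for edge in universe:
        key = tuple(n for n in names if edge in edge_sets[n])
        counts[key] = counts.get(key, 0) + 1
    return counts


def run_bootstraps(*args, **kwargs):
    """Bootstrap the full fit + scoring pipeline (see :mod:`.workflow`)."""
    from .workflow import run_bootstraps as _rb
    return _rb(*args, **kwargs)
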