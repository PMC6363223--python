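"""End-to-end inference runs: read -> align -> TFA -> fit -> score -> rank.

The engine here drives the per-gene solver over bootstraps of the
conditions and aggregates edge scores into ranked networks.  Per-gene fits
are embarrassingly parallel; workers share the numba kernels through
threads, so serial and parallel executions are bit-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml
from joblib import Parallel, delayed

from . import _solver, __version__
from .datasets import (DataError, ExpressionDataset, GoldStandard,
                       PriorMatrix, align_genes, read_expression,
                       read_gold_standard, read_prior, write_network)
from .design import build_halftau_response, build_regression_pairs
from .multitask import (DEFAULT_C_GRID_SIZE, DEFAULT_C_RANGE, DEFAULT_MAX_SWEEPS,
                        DEFAULT_RATIOS, DEFAULT_TOL)
from .scoring import (RankedNetwork, combine_networks, precision_recall,
                      rank_combine, scores_one_task)
from .tfa import estimate_activities, expression_as_activities
import math

MODE_STL = "stl"
MODE_MTL = "mtl"
TFA_PRIOR = "prior_pinv"
TFA_EXPRESSION = "expression"


# ---------------------------------------------------------------------------
# preparation
# ---------------------------------------------------------------------------

@dataclass
class PreparedRun:
    """Aligned designs/responses and penalty bookkeeping for one run."""

    dataset_ids: list[str]
    tfs: list[str]
    genes: list[str]                    # target genes being modelled
    designs: list[np.ndarray]           # per dataset (p, n_d) raw activities
    responses: list[np.ndarray]         # per dataset (G, n_d) raw expression
    phi: np.ndarray                     # (G, p, d) adaptive penalty weights
    active: np.ndarray                  # (G, p) bool candidate-regulator mask
    grid_lambda_s: np.ndarray
    grid_lambda_b: np.ndarray
    gamma: float
    tol: float = DEFAULT_TOL
    max_sweeps: int = DEFAULT_MAX_SWEEPS


def prepare_run(datasets: list[ExpressionDataset],
                priors: PriorMatrix | list[PriorMatrix],
                *, taus: dict[str, float] | float | None = None,
                tfa_mode: str = TFA_PRIOR,
                prior_weight: float = 1.0,
                gamma: float = 1.0,
                clip_prior: bool = False,
                target_genes: list[str] | None = None,
                c_range: tuple[float, float] = DEFAULT_C_RANGE,
                c_grid_size: int = DEFAULT_C_GRID_SIZE,
                ratios: tuple[float, ...] = DEFAULT_RATIOS,
                tol: float = DEFAULT_TOL,
                max_sweeps: int = DEFAULT_MAX_SWEEPS) -> PreparedRun:
    """Align data, estimate activities and build per-gene penalty state."""
    if prior_weight < 1:
        raise DataError("prior weight rho must be >= 1")
    datasets = align_genes(datasets)
    genes_all = datasets[0].genes
    if isinstance(priors, PriorMatrix):
        priors = [priors] * len(datasets)
    if len(priors) != len(datasets):
        raise DataError("need one prior per dataset (or a single shared prior)")
    tfs = sorted(set().union(*(p.tfs for p in priors)))

    if taus is None:
        taus = {}
    if isinstance(taus, (int, float)):
        taus = {ds.dataset_id: float(taus) for ds in datasets}

    designs, responses, priors_aligned = [], [], []
    target = sorted(target_genes) if target_genes is not None else genes_all
    missing = [g for g in target if g not in set(genes_all)]
    if missing:
        raise DataError(f"target genes absent after alignment: {missing[:5]}")
    for ds, prior in zip(datasets, priors):
        tau = float(taus.get(ds.dataset_id, 0.0))
        prior_d = prior.reindexed(genes_all, tfs)
        if clip_prior:
            prior_d = prior_d.clipped()
        priors_aligned.append(prior_d)
        if tfa_mode == TFA_PRIOR:
            halftau = build_halftau_response(ds, tau)
            activities = estimate_activities(prior_d, halftau, ds)
        elif tfa_mode == TFA_EXPRESSION:
            activities = expression_as_activities(ds, tfs)
        else:
            raise DataError(f"unknown tfa_mode {tfa_mode!r}")
        pairs = build_regression_pairs(ds, activities, tau)
        g_idx = [genes_all.index(g) for g in target]
        designs.append(pairs.design)
        responses.append(pairs.response[g_idx])

    G, p, d = len(target), len(tfs), len(datasets)
    phi = np.ones((G, p, d))
    if prior_weight > 1:
        for j, prior_d in enumerate(priors_aligned):
            in_prior = prior_d.to_frame().reindex(index=target).to_numpy() != 0
            col = np.where(in_prior, 1.0 / prior_weight, 1.0)   # (G, p)
            col *= (p / col.sum(axis=1))[:, None]
            phi[:, :, j] = col
    active = np.ones((G, p), dtype=np.bool_)
    tf_pos = {t: k for k, t in enumerate(tfs)}
    for gi, g in enumerate(target):
        k = tf_pos.get(g)
        if k is not None:
            active[gi, k] = False       # no self-regulation in the regression

    n_mean = float(np.mean([dm.shape[1] for dm in designs]))
    scale = math.sqrt(d * math.log(max(p, 2)) / n_mean)
    cs = np.logspace(math.log10(c_range[0]), math.log10(c_range[1]), c_grid_size)
    lam_s, lam_b = [], []
    for c in sorted(cs, reverse=True):
        for r in sorted(ratios, reverse=True):
            lam_s.append(r * c * scale)
            lam_b.append(c * scale)
    return PreparedRun([ds.dataset_id for ds in datasets], tfs, list(target),
                       designs, responses, phi, active,
                       np.array(lam_s), np.array(lam_b), float(gamma),
                       tol, max_sweeps)


# ---------------------------------------------------------------------------
# bootstrapped fitting
# ---------------------------------------------------------------------------

def _standardize_rows(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    out = np.zeros_like(M)
    ok = sd[:, 0] > 0
    out[ok] = (M[ok] - mu[ok]) / sd[ok]
    return out


def _score_genes_mtl(prep: PreparedRun, gram, atx_all, xtx_all, nvec, dfvec,
                     A_std, X_std, gene_indices) -> np.ndarray:
    """Fit + score a block of genes against all tasks jointly."""
    p, d = len(prep.tfs), len(prep.dataset_ids)
    out = np.zeros((len(gene_indices), p, d))
    for row, g in enumerate(gene_indices):
        atx = np.ascontiguousarray(atx_all[:, :, g])
        xtx = np.ascontiguousarray(xtx_all[:, g])
        S, B, idx, _, _ = _solver._select(
            gram, atx, xtx, nvec, dfvec, np.ascontiguousarray(prep.phi[g]),
            prep.grid_lambda_s, prep.grid_lambda_b, prep.gamma, True,
            prep.active[g], prep.tol, prep.max_sweeps)
        support = (S + B) != 0
        for j in range(d):
            out[row, :, j] = scores_one_task(A_std[j], X_std[j][g], support[:, j])
    return out


def _score_genes_stl(prep: PreparedRun, gram, atx_all, xtx_all, nvec, dfvec,
                     A_std, X_std, gene_indices) -> np.ndarray:
    """Fit + score a block of genes per dataset independently (lasso path)."""
    p, d = len(prep.tfs), len(prep.dataset_ids)
    out = np.zeros((len(gene_indices), p, d))
    for row, g in enumerate(gene_indices):
        for j in range(d):
            atx = np.ascontiguousarray(atx_all[j:j + 1, :, g])
            xtx = np.ascontiguousarray(xtx_all[j:j + 1, g])
            S, B, idx, _, _ = _solver._select(
                gram[j:j + 1], atx, xtx, nvec[j:j + 1], dfvec[j:j + 1],
                np.ascontiguousarray(prep.phi[g, :, j:j + 1]),
                prep.grid_lambda_s, prep.grid_lambda_b, prep.gamma, False,
                prep.active[g], prep.tol, prep.max_sweeps)
            support = (S + B)[:, 0] != 0
            out[row, :, j] = scores_one_task(A_std[j], X_std[j][g], support)
    return out


def bootstrap_scores(prep: PreparedRun, mode: str, n_boot: int, seed: int,
                     num_workers: int = 1, resample: bool = True,
                     ) -> list[np.ndarray]:
    """Score matrices (genes x TFs x datasets), one per bootstrap.

    Bootstrap ``b`` resamples condition columns with replacement (design and
    response jointly, so time-linked pairs stay aligned) with a generator
    seeded ``seed + b``; passing ``resample=False`` runs identity bootstraps.
    Deterministic given the seed, independent of ``num_workers``.
    """
    if n_boot < 1:
        raise DataError("n_boot must be >= 1")
    if mode not in (MODE_STL, MODE_MTL):
        raise DataError(f"unknown mode {mode!r}")
    G = len(prep.genes)
    d = len(prep.dataset_ids)
    score_fn = _score_genes_mtl if mode == MODE_MTL else _score_genes_stl
    chunks = np.array_split(np.arange(G), max(1, min(4 * max(num_workers, 1), G)))
    results = []
    for b in range(n_boot):
        rng = np.random.default_rng(seed + b)
        A_std, X_std = [], []
        nvec = np.zeros(d)
        dfvec = np.zeros(d)
        for j in range(d):
            n_j = prep.designs[j].shape[1]
            idx = rng.integers(0, n_j, n_j) if resample else np.arange(n_j)
            A_std.append(_standardize_rows(prep.designs[j][:, idx]))
            X_std.append(_standardize_rows(prep.responses[j][:, idx]))
            nvec[j] = n_j
            dfvec[j] = len(np.unique(idx))
        p = len(prep.tfs)
        gram = np.zeros((d, p, p))
        atx_all = np.zeros((d, p, G))
        xtx_all = np.zeros((d, G))
        for j in range(d):
            gram[j] = A_std[j] @ A_std[j].T
            atx_all[j] = A_std[j] @ X_std[j].T
            xtx_all[j] = (X_std[j] ** 2).sum(axis=1)
        blocks = Parallel(n_jobs=num_workers, prefer="threads")(
            delayed(score_fn)(prep, gram, atx_all, xtx_all, nvec, dfvec,
                              A_std, X_std, chunk)
            for chunk in chunks if len(chunk))
        results.append(np.vstack(blocks))
    return results


def run_bootstraps(datasets, priors, config: dict | None = None,
                   n_boot: int = 20, seed: int = 42, **kwargs) -> list[np.ndarray]:
    """Prepare a run from raw datasets/priors and bootstrap the scores."""
    config = dict(config or {})
    config.update(kwargs)
    mode = config.pop("mode", MODE_MTL)
    num_workers = config.pop("num_workers", 1)
    resample = config.pop("resample", True)
    prep = prepare_run(datasets, priors, **config)
    return bootstrap_scores(prep, mode, n_boot, seed, num_workers, resample)


# ---------------------------------------------------------------------------
# full inference
# ---------------------------------------------------------------------------

@dataclass
class InferenceOutput:
    """Ranked networks of one run (per dataset plus rank-combined ensemble)."""

    networks: dict[str, RankedNetwork]
    combined: RankedNetwork
    mode: str
    n_boot: int
    seed: int
    prep: PreparedRun = field(repr=False, default=None)


def run_inference(datasets, priors, *, mode: str = MODE_MTL,
                  n_boot: int = 20, seed: int = 42, num_workers: int = 1,
                  resample: bool = True, **prepare_kwargs) -> InferenceOutput:
    """Full pipeline: prepare, bootstrap, rank-average, combine."""
    prep = prepare_run(datasets, priors, **prepare_kwargs)
    scores = bootstrap_scores(prep, mode, n_boot, seed, num_workers, resample)
    provenance = {"n_boot": n_boot, "seed": seed, "mode": mode}
    networks = {}
    for j, did in enumerate(prep.dataset_ids):
        networks[did] = rank_combine([s[:, :, j] for s in scores],
                                     prep.tfs, prep.genes, did, dict(provenance))
    combined = combine_networks(list(networks.values()))
    combined.provenance.update(provenance)
    return InferenceOutput(networks, combined, mode, n_boot, seed, prep)


# ---------------------------------------------------------------------------
# config-file driven workflow
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """A YAML-backed run description (paths, mode and hyper-parameters)."""

    datasets: list[dict]
    output_dir: str
    gold_standard: str | None = None
    mode: str = MODE_MTL
    tfa_mode: str = TFA_PRIOR
    prior_weight: float = 1.0
    n_boot: int = 20
    gamma: float = 1.0
    seed: int = 42
    num_workers: int = 1
    clip_prior: bool = False
    target_genes: list[str] | None = None

    def __post_init__(self) -> None:
        if self.prior_weight < 1:
            raise DataError("prior_weight must be >= 1")
        if self.n_boot < 1:
            raise DataError("n_boot must be >= 1")
        if self.mode not in (MODE_STL, MODE_MTL):
            raise DataError(f"unknown mode {self.mode!r}")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(**raw)


def run_workflow(config: RunConfig) -> dict:
    """Execute a config-driven run and write the output bundle.

    Writes per-dataset network TSVs, the combined network, PR-curve TSVs
    and a summary JSON when a gold standard is given, and a manifest
    echoing the configuration for reproducibility.
    """
    datasets, priors, taus = [], [], {}
    for entry in config.datasets:
        ds = read_expression(entry["expression"], entry.get("metadata"),
                             dataset_id=entry.get("id"))
        datasets.append(ds)
        priors.append(read_prior(entry["prior"]))
        taus[ds.dataset_id] = float(entry.get("tau", 0.0))
    result = run_inference(
        datasets, priors, mode=config.mode, n_boot=config.n_boot,
        seed=config.seed, num_workers=config.num_workers,
        taus=taus, tfa_mode=config.tfa_mode,
        prior_weight=config.prior_weight, gamma=config.gamma,
        clip_prior=config.clip_prior, target_genes=config.target_genes)

    os.makedirs(config.output_dir, exist_ok=True)
    paths = {}
    for did, net in result.networks.items():
        paths[did] = os.path.join(config.output_dir, f"network_{did}.tsv")
        write_network(net, paths[did])
    paths["combined"] = os.path.join(config.output_dir, "network_combined.tsv")
    write_network(result.combined, paths["combined"])

    summary = {"mode": config.mode, "n_boot": config.n_boot, "aupr": {}}
    if config.gold_standard:
        gold = read_gold_standard(config.gold_standard)
        for name, net in {**result.networks,
                          "combined": result.combined}.items():
            curve = precision_recall(net, gold)
            summary["aupr"][name] = curve.aupr
            pr_path = os.path.join(config.output_dir, f"pr_{name}.tsv")
            np.savetxt(pr_path, np.column_stack([curve.recall, curve.precision]),
                       delimiter="\t", header="recall\tprecision", comments="")
    with open(os.path.join(config.output_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    manifest = {"version": __version__, "seed": config.seed,
                "config": {k: v for k, v in vars(config).items()}}
    with open(os.path.join(config.output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return {"result": result, "paths": paths, "summary": summary}
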