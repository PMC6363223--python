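"""Multitask sparse + block-sparse regression with adaptive prior weights.

Per gene, regression coefficients across ``d`` datasets form a TFs x datasets
matrix ``W`` decomposed as ``W = S + B``: ``S`` holds dataset-specific edges
(elementwise l1 penalty, rescaled by the adaptive prior matrix ``Phi``) and
``B`` holds edges shared across datasets (l1/l-inf row penalty).  Penalty
pairs (lambda_s, lambda_b) are searched on a grid constrained to
``1/2 < lambda_s/lambda_b < 1`` and the fit minimising the extended BIC
(gamma = 1 by default) is selected, with warm starts from most to least
penalised.

This module is the public face of the numba kernels in ``_solver``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _solver
from .datasets import DataError, PriorMatrix

DEFAULT_TOL = 1e-6
DEFAULT_MAX_SWEEPS = 1000
DEFAULT_C_RANGE = (0.01, 10.0)
DEFAULT_C_GRID_SIZE = 20
#: lambda_s / lambda_b ratios, strictly inside the open interval (1/2, 1)
DEFAULT_RATIOS = (0.55, 0.65, 0.75, 0.85, 0.95)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TaskData:
    """One dataset's standardized (design, response) pair for a single gene."""

    dataset_id: str
    design: np.ndarray          # (n_tfs, n) standardized activities
    response: np.ndarray        # (n,) standardized expression
    n: int = 0
    standardized: bool = True

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, float)
        self.response = np.asarray(self.response, float)
        if self.n == 0:
            self.n = self.response.shape[0]
        if self.design.shape[1] != self.n:
            raise DataError("design/response sample count mismatch")
        if self.n < 2:
            raise DataError("a task needs at least 2 samples")
        if not (np.isfinite(self.design).all() and np.isfinite(self.response).all()):
            raise DataError("non-finite values in task data")


def standardize_task(design: np.ndarray, response: np.ndarray,
                     dataset_id: str = "task") -> TaskData:
    """Z-score each predictor row and the response (population sd).

    Zero-variance predictor rows are set to all-zero, which pins their
    coefficient to zero inside the solver; a zero-variance response is
    likewise left at zero (the gene then gets an empty model).
    """
    d = np.asarray(design, float)
    r = np.asarray(response, float)
    mu = d.mean(axis=1, keepdims=True)
    sd = d.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    out = np.zeros_like(d)
    out[ok] = (d[ok] - mu[ok]) / sd[ok]
    rsd = r.std()
    rout = (r - r.mean()) / rsd if rsd > 0 else np.zeros_like(r)
    return TaskData(dataset_id, out, rout)


@dataclass
class PenaltyMatrix:
    """Adaptive-lasso weights Phi (TFs x datasets), with prior weight rho.

    Entries are 1/rho where the TF->gene edge is in that dataset's prior and
    1 otherwise, then each column is rescaled to sum to the number of
    predictors.  Phi multiplies the l1 penalty on S only, never B.
    """

    values: np.ndarray          # (n_tfs, n_datasets), all > 0 after rescale
    rho: float = 1.0


def build_penalty_matrix(priors: list[PriorMatrix], gene: str, rho: float,
                         tfs: list[str] | None = None) -> PenaltyMatrix:
    """Build Phi for one gene from per-dataset priors.

    Each dataset contributes one column; rho >= 1 sets how strongly prior
    edges are favoured (rho = 1 leaves Phi at all ones).
    """
    if rho < 1:
        raise DataError("prior weight rho must be >= 1")
    if tfs is None:
        tfs = priors[0].tfs
    p = len(tfs)
    cols = []
    for prior in priors:
        col = np.ones(p)
        if gene in prior.genes:
            row = prior.values[prior.genes.index(gene)]
            tf_idx = {t: i for i, t in enumerate(prior.tfs)}
            for k, tf in enumerate(tfs):
                i = tf_idx.get(tf)
                if i is not None and row[i] != 0:
                    col[k] = 1.0 / rho
        col *= p / col.sum()
        cols.append(col)
    return PenaltyMatrix(np.column_stack(cols), rho)


@dataclass
class SolverState:
    """Cached covariance (Gram) products shared across sweeps and penalties."""

    gram: np.ndarray            # (d, p, p): per task A A^T
    atx: np.ndarray             # (d, p): per task A X^T
    xtx: np.ndarray             # (d,): per task <X, X>
    nvec: np.ndarray            # (d,) float sample counts
    dataset_ids: list[str] = field(default_factory=list)
    dfvec: np.ndarray | None = None   # distinct-condition counts (defaults to nvec)

    def __post_init__(self) -> None:
        if self.dfvec is None:
            self.dfvec = self.nvec.copy()

    @property
    def n_tasks(self) -> int:
        return self.gram.shape[0]

    @property
    def n_tfs(self) -> int:
        return self.gram.shape[1]


def precompute_covariances(tasks: list[TaskData]) -> SolverState:
    """Cache A A^T, A X^T and <X, X> per task (the covariance-update trick).

    These cross-products dominate runtime and are reused across every
    penalty pair and coordinate-descent sweep.
    """
    if not tasks:
        raise DataError("at least one task required")
    p = tasks[0].design.shape[0]
    d = len(tasks)
    gram = np.zeros((d, p, p))
    atx = np.zeros((d, p))
    xtx = np.zeros(d)
    nvec = np.zeros(d)
    for i, t in enumerate(tasks):
        if t.design.shape[0] != p:
            raise DataError("tasks disagree on the number of TFs")
        gram[i] = t.design @ t.design.T
        atx[i] = t.design @ t.response
        xtx[i] = t.response @ t.response
        nvec[i] = t.n
    return SolverState(gram, atx, xtx, nvec, [t.dataset_id for t in tasks])


@dataclass
class WeightDecomposition:
    """A fitted W = S + B with its penalty state."""

    S: np.ndarray               # (p, d) dataset-specific part
    B: np.ndarray               # (p, d) shared row-sparse part
    lambda_s: float
    lambda_b: float
    converged: bool = True
    sweeps: int = 0
    ebic: float = math.nan

    @property
    def W(self) -> np.ndarray:
        return self.S + self.B

    @property
    def support(self) -> np.ndarray:
        return self.W != 0


# ---------------------------------------------------------------------------
# solver operations
# ---------------------------------------------------------------------------

def _active_mask(p: int, exclude: np.ndarray | None) -> np.ndarray:
    active = np.ones(p, dtype=np.bool_)
    if exclude is not None:
        active[np.asarray(exclude)] = False
    return active


def update_S(state: SolverState, S: np.ndarray, B: np.ndarray,
             phi: PenaltyMatrix, lambda_s: float) -> np.ndarray:
    """One cyclical pass of prior-weighted soft-threshold updates over S."""
    S = np.array(S, float)
    B = np.asarray(B, float)
    active = np.ones(state.n_tfs, dtype=np.bool_)
    _solver._sweep(state.gram, state.atx, state.nvec, phi.values,
                   float(lambda_s), np.inf, False, active, S, B.copy())
    return S


def update_B(state: SolverState, S: np.ndarray, B: np.ndarray,
             lambda_b: float) -> np.ndarray:
    """One cyclical pass of l-inf proximal row updates over B."""
    Sfrozen = np.asarray(S, float)
    B = np.array(B, float)
    d = state.n_tasks
    p = state.n_tfs
    v = np.empty(d)
    c = np.empty(d)
    row = np.empty(d)
    for k in range(p):
        for dd in range(d):
            g = state.gram[dd, k, k]
            if g <= 0:
                v[dd] = 0.0
                c[dd] = 0.0
                continue
            w = Sfrozen[:, dd] + B[:, dd]
            acc = w @ state.gram[dd, :, k]
            alpha = state.atx[dd, k] - acc + B[k, dd] * g
            v[dd] = alpha / state.nvec[dd]
            c[dd] = g / state.nvec[dd]
        _solver._linf_prox_row(v, c, float(lambda_b), row)
        B[k] = row
    return B


def fit_gene(tasks: list[TaskData] | SolverState, phi: PenaltyMatrix,
             lambda_s: float, lambda_b: float,
             warm: WeightDecomposition | None = None,
             exclude: np.ndarray | None = None,
             tol: float = DEFAULT_TOL,
             max_sweeps: int = DEFAULT_MAX_SWEEPS) -> WeightDecomposition:
    """Fit W = S + B for one gene at a fixed penalty pair.

    Alternates S and B coordinate sweeps until the largest coefficient
    change falls below ``tol``; the convex objective is non-increasing per
    sweep.  ``warm`` seeds S and B from a previous fit.
    """
    if lambda_s <= 0 or lambda_b <= 0:
        raise DataError("penalties must be positive")
    state = tasks if isinstance(tasks, SolverState) else precompute_covariances(tasks)
    p, d = state.n_tfs, state.n_tasks
    S = np.array(warm.S, float) if warm is not None else np.zeros((p, d))
    B = np.array(warm.B, float) if warm is not None else np.zeros((p, d))
    active = _active_mask(p, exclude)
    sweeps = _solver._fit(state.gram, state.atx, state.nvec, phi.values,
                          float(lambda_s), float(lambda_b), True, active,
                          S, B, tol, max_sweeps)
    if not (np.isfinite(S).all() and np.isfinite(B).all()):
        raise DataError("solver diverged: non-finite coefficients")
    return WeightDecomposition(S, B, float(lambda_s), float(lambda_b),
                               converged=sweeps < max_sweeps, sweeps=sweeps)


def objective(tasks: list[TaskData] | SolverState, phi: PenaltyMatrix,
              lambda_s: float, lambda_b: float,
              S: np.ndarray, B: np.ndarray) -> float:
    """Evaluate the penalised objective at (S, B)."""
    state = tasks if isinstance(tasks, SolverState) else precompute_covariances(tasks)
    return _solver._objective(state.gram, state.atx, state.xtx, state.nvec,
                              phi.values, float(lambda_s), float(lambda_b),
                              np.asarray(S, float), np.asarray(B, float))


def lambda_grid(tasks: list[TaskData] | SolverState,
                c_range: tuple[float, float] = DEFAULT_C_RANGE,
                n_c: int = DEFAULT_C_GRID_SIZE,
                ratios: tuple[float, ...] = DEFAULT_RATIOS,
                ) -> list[tuple[float, float]]:
    """Penalty pairs (lambda_s, lambda_b) over the c grid.

    lambda_b = c * sqrt(d * ln p / n_mean) for n_c log-spaced c values in
    ``c_range``; each lambda_b is paired with lambda_s at fixed ratios
    strictly inside (1/2, 1).  Pairs are ordered from most to least
    penalised for warm-start traversal.
    """
    if isinstance(tasks, SolverState):
        p, d = tasks.n_tfs, tasks.n_tasks
        n_mean = float(tasks.nvec.mean())
    else:
        if not tasks:
            raise DataError("tasks must be nonempty")
        p, d = tasks[0].design.shape[0], len(tasks)
        n_mean = float(np.mean([t.n for t in tasks]))
    scale = math.sqrt(d * math.log(max(p, 2)) / n_mean)
    cs = np.logspace(math.log10(c_range[0]), math.log10(c_range[1]), n_c)
    pairs = []
    for c in sorted(cs, reverse=True):
        lam_b = float(c * scale)
        for r in sorted(ratios, reverse=True):
            pairs.append((r * lam_b, lam_b))
    return pairs


def ebic(fit: WeightDecomposition, tasks: list[TaskData] | SolverState,
         gamma: float = 1.0) -> float:
    """Extended BIC of a fitted decomposition, averaged over tasks.

    gamma = 0 recovers the ordinary BIC; gamma = 1 (the default used for
    model selection) adds the full 2 ln C(p*d, k_d) predictor-space term.
    """
    if not 0 <= gamma <= 1:
        raise DataError("gamma must lie in [0, 1]")
    state = tasks if isinstance(tasks, SolverState) else precompute_covariances(tasks)
    return _solver._ebic(state.gram, state.atx, state.xtx, state.nvec,
                         state.dfvec, np.asarray(fit.S, float),
                         np.asarray(fit.B, float), float(gamma), state.n_tfs)


def select_model(tasks: list[TaskData] | SolverState, phi: PenaltyMatrix,
                 grid: list[tuple[float, float]] | None = None,
                 gamma: float = 1.0,
                 use_b: bool = True,
                 exclude: np.ndarray | None = None,
                 tol: float = DEFAULT_TOL,
                 max_sweeps: int = DEFAULT_MAX_SWEEPS) -> WeightDecomposition:
    """Fit the penalty grid with warm starts and return the EBIC minimiser.

    Ties keep the more-penalised (sparser) fit.  ``use_b=False`` restricts
    the model to the S component (the single-task lasso special case).
    """
    if not 0 <= gamma <= 1:
        raise DataError("gamma must lie in [0, 1]")
    state = tasks if isinstance(tasks, SolverState) else precompute_covariances(tasks)
    if grid is None:
        grid = lambda_grid(state)
    if not grid:
        raise DataError("empty penalty grid")
    lam_s = np.array([g[0] for g in grid])
    lam_b = np.array([g[1] for g in grid])
    active = _active_mask(state.n_tfs, exclude)
    S, B, idx, val, sweeps = _solver._select(
        state.gram, state.atx, state.xtx, state.nvec, state.dfvec,
        phi.values, lam_s, lam_b, float(gamma), use_b, active, tol, max_sweeps)
    if idx < 0:
        raise DataError("model selection failed: no finite EBIC on the grid")
    return WeightDecomposition(S, B, float(lam_s[idx]), float(lam_b[idx]),
                               converged=True, sweeps=int(sweeps), ebic=float(val))
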