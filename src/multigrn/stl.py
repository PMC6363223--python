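"""Single-task baseline: per-gene lasso with EBIC selection.

The lasso objective

    argmin_w  1/(2n) || X_i - A^T w ||^2 + lambda ||w||_1

is structurally the S-only, single-dataset special case of the multitask
decomposition, so it is solved by the same coordinate-descent kernels with
the B component disabled.  Optional adaptive prior weights enter exactly as
in the multitask case.  The penalty path reuses the multitask c-grid at
d = 1 and the fit minimising the single-dataset EBIC is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import DataError
from .multitask import (DEFAULT_MAX_SWEEPS, DEFAULT_TOL, PenaltyMatrix,
                        TaskData, ebic, lambda_grid, precompute_covariances,
                        select_model)


@dataclass
class StlFit:
    """One gene's selected lasso fit."""

    gene: str
    coef: np.ndarray            # (n_tfs,) exactly zero off-support
    lambda_: float
    ebic: float


def stl_lambda_path(task: TaskData,
                    **grid_kwargs) -> list[float]:
    """Lasso penalty path: the lambda_s values of the d=1 multitask grid."""
    return [ls for ls, _ in lambda_grid([task], **grid_kwargs)]


def fit_lasso_gene(design: np.ndarray, response: np.ndarray,
                   lambda_path: list[float] | None = None,
                   phi: np.ndarray | None = None,
                   gene: str = "gene",
                   gamma: float = 1.0,
                   exclude: np.ndarray | None = None,
                   tol: float = DEFAULT_TOL,
                   max_sweeps: int = DEFAULT_MAX_SWEEPS) -> StlFit:
    """Fit the lasso path for one gene and select by EBIC.

    ``design`` (TFs x n) and ``response`` (n,) are expected standardized.
    ``phi`` optionally supplies adaptive per-TF penalty weights.
    """
    design = np.asarray(design, float)
    response = np.asarray(response, float)
    if response.shape[0] < 2:
        raise DataError("n < 2 samples")
    if not (np.isfinite(design).all() and np.isfinite(response).all()):
        raise DataError("non-finite inputs")
    task = TaskData(gene, design, response)
    if lambda_path is None:
        lambda_path = stl_lambda_path(task)
    lams = sorted({float(l) for l in lambda_path}, reverse=True)
    if any(l <= 0 for l in lams):
        raise DataError("lambda values must be positive")
    p = design.shape[0]
    pm = PenaltyMatrix(np.ones((p, 1)) if phi is None
                       else np.asarray(phi, float).reshape(p, 1))
    state = precompute_covariances([task])
    # B disabled: pure l1 path; lambda_b entries are placeholders
    fit = select_model(state, pm, [(l, max(lams)) for l in lams],
                       gamma=gamma, use_b=False, exclude=exclude,
                       tol=tol, max_sweeps=max_sweeps)
    return StlFit(gene, fit.S[:, 0].copy(), fit.lambda_s, fit.ebic)
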