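"""Transcription factor activity (TFA) estimation.

Expression of known targets is used to estimate the latent activity of each
TF: with a signed prior connectivity matrix ``P`` (genes x TFs) and the
half-tau-shifted expression ``X`` of the prior genes, the activities solve
``X = P A`` in the least-squares sense, ``A_hat = pinv(P) @ X``.  TFs with no
targets in the prior (all-zero columns) fall back to their own measured
expression as an activity proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import DataError, ExpressionDataset, PriorMatrix
from .design import DesignResponseSet

#: relative singular-value cutoff for the pseudo-inverse; tolerates
#: rank deficiency from TFs with duplicate target sets
PINV_RCOND = 1e-10

SOURCE_PRIOR = "prior"
SOURCE_EXPRESSION = "expression"


@dataclass
class ActivityMatrix:
    """Estimated TF activities (TFs x samples, relative units).

    ``source`` flags each TF as estimated from the prior topology or as the
    expression fallback.
    """

    tfs: list[str]
    samples: list[str]
    values: np.ndarray                 # (n_tfs, n_samples)
    source: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.tfs), len(self.samples)):
            raise DataError("activity matrix dimensions inconsistent")
        if len(self.source) != len(self.tfs):
            raise DataError("one source flag per TF required")


def estimate_activities(prior: PriorMatrix, halftau_expression,
                        expression: ExpressionDataset) -> ActivityMatrix:
    """Estimate activities as ``pinv(P) @ X`` with expression fallback.

    Parameters
    ----------
    prior
        Signed connectivity; genes must be a subset of the expression genes.
    halftau_expression
        Expression shifted by tau/2 (a :class:`DesignResponseSet` or a raw
        matrix aligned to ``expression.genes`` x ``expression.samples``).
    expression
        The unshifted dataset, used for the expression fallback rows.
    """
    if isinstance(halftau_expression, DesignResponseSet):
        X_full = halftau_expression.values
    else:
        X_full = np.asarray(halftau_expression, float)
    if X_full.shape != (len(expression.genes), len(expression.samples)):
        raise DataError("half-tau expression not aligned to the dataset")

    gene_idx = {g: i for i, g in enumerate(expression.genes)}
    missing = [g for g in prior.genes if g not in gene_idx]
    if missing:
        raise DataError(f"prior genes absent from expression: {missing[:5]}")
    rows = [gene_idx[g] for g in prior.genes]
    X = X_full[rows]

    zero_col = np.all(prior.values == 0, axis=0)
    A = np.zeros((len(prior.tfs), len(expression.samples)))
    if not zero_col.all():
        P = prior.values[:, ~zero_col]
        A[~zero_col] = np.linalg.pinv(P, rcond=PINV_RCOND) @ X
    source = []
    for k, tf in enumerate(prior.tfs):
        if zero_col[k]:
            if tf not in gene_idx:
                raise DataError(
                    f"TF {tf!r} has no prior targets and no expression row "
                    f"for the fallback")
            A[k] = expression.values[gene_idx[tf]]
            source.append(SOURCE_EXPRESSION)
        else:
            source.append(SOURCE_PRIOR)
    return ActivityMatrix(list(prior.tfs), list(expression.samples), A, source)


def expression_as_activities(expression: ExpressionDataset,
                             tfs: list[str]) -> ActivityMatrix:
    """Use measured TF expression directly as the activity estimate."""
    if not tfs:
        raise DataError("empty TF list")
    gene_idx = {g: i for i, g in enumerate(expression.genes)}
    missing = [t for t in tfs if t not in gene_idx]
    if missing:
        raise DataError(f"TFs absent from expression: {missing[:5]}")
    A = expression.values[[gene_idx[t] for t in tfs]].copy()
    return ActivityMatrix(list(tfs), list(expression.samples), A,
                          [SOURCE_EXPRESSION] * len(tfs))
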