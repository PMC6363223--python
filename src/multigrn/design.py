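"""Time-delay-aware design and response construction.

Expression is modelled as responding to TF activities with a delay ``tau``:
for a time-series sample at time ``t_n`` the regression pairs expression
``X[:, t_n]`` with activities at ``t_n - tau``, and TFA estimation uses
expression shifted forward by ``tau/2``.  Times not observed directly are
obtained by linear interpolation along each time-series chain; times falling
outside a series are clamped to the series boundary (interpolation only,
never extrapolation).  Steady-state samples always map to themselves.

The time axis of a series is reconstructed by summing ``delta_t`` along
``previous_sample`` links.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import DataError, ExpressionDataset, SampleMetadata


@dataclass
class DesignResponseSet:
    """A matrix whose columns were moved along the time axis.

    ``mapping`` records, for each output condition, the source condition(s)
    and convex interpolation weights that produced it.  Steady-state
    conditions map to themselves with weight 1.
    """

    values: np.ndarray                      # (rows, n_conditions)
    conditions: list[str]
    mapping: dict[str, list[tuple[str, float]]]
    tau: float


def _series_of(md: SampleMetadata) -> list[list[int]]:
    """Group sample indices into time-series chains ordered by time."""
    idx = {s: i for i, s in enumerate(md.samples)}
    succ: dict[int, list[int]] = {}
    roots = []
    for i, s in enumerate(md.samples):
        if not md.is_timeseries[i]:
            continue
        prev = md.previous_sample[i]
        if prev is None:
            roots.append(i)
        else:
            succ.setdefault(idx[prev], []).append(i)
    chains = []
    for r in roots:
        chain = [r]
        cur = r
        while cur in succ:
            nxt = succ[cur]
            if len(nxt) > 1:
                raise DataError(
                    f"sample {md.samples[cur]!r} has multiple successors; "
                    f"branching time series are not supported")
            cur = nxt[0]
            chain.append(cur)
        chains.append(chain)
    n_ts = int(md.is_timeseries.sum())
    if sum(len(c) for c in chains) != n_ts:
        raise DataError("broken previous_sample chain: some time-series "
                        "samples are unreachable from a series start")
    return chains


def _chain_times(md: SampleMetadata, chain: list[int]) -> np.ndarray:
    t = np.zeros(len(chain))
    for j in range(1, len(chain)):
        t[j] = t[j - 1] + md.delta_t[chain[j]]
    return t


def _interp_weights(times: np.ndarray, target: float) -> list[tuple[int, float]]:
    """Indices/weights for linear interpolation at ``target``, clamped."""
    if target <= times[0]:
        return [(0, 1.0)]
    if target >= times[-1]:
        return [(len(times) - 1, 1.0)]
    hi = int(np.searchsorted(times, target))
    lo = hi - 1
    if times[hi] == target:
        return [(hi, 1.0)]
    w_hi = (target - times[lo]) / (times[hi] - times[lo])
    return [(lo, 1.0 - w_hi), (hi, w_hi)]


def _shifted(values: np.ndarray, md: SampleMetadata, shift: float,
             tau: float) -> DesignResponseSet:
    """Columns of ``values`` moved by ``shift`` time units along each series."""
    n = values.shape[1]
    out = values.copy()
    mapping = {s: [(s, 1.0)] for s in md.samples}
    for chain in _series_of(md):
        times = _chain_times(md, chain)
        cols = values[:, chain]
        for j, i in enumerate(chain):
            pieces = _interp_weights(times, times[j] + shift)
            col = np.zeros(values.shape[0])
            for k, w in pieces:
                col += w * cols[:, k]
            out[:, i] = col
            mapping[md.samples[i]] = [(md.samples[chain[k]], w) for k, w in pieces]
    assert out.shape[1] == n
    return DesignResponseSet(out, list(md.samples), mapping, tau)


def build_halftau_response(expression: ExpressionDataset, tau: float) -> DesignResponseSet:
    """Expression shifted forward by tau/2, used to inform TFA at t_n.

    For time-series samples the response at ``t_n + tau/2`` is linearly
    interpolated between the observed samples (clamped at the series end);
    steady-state columns are returned unchanged.
    """
    if tau < 0:
        raise DataError("tau must be non-negative")
    return _shifted(expression.values, expression.metadata, tau / 2.0, tau)


@dataclass
class RegressionPairs:
    """Aligned (design = activities at t - tau, response = expression) pair."""

    dataset_id: str
    tfs: list[str]
    genes: list[str]
    conditions: list[str]
    design: np.ndarray                      # (n_tfs, n_conditions)
    response: np.ndarray                    # (n_genes, n_conditions)
    mapping: dict[str, list[tuple[str, float]]]
    tau: float


def build_regression_pairs(expression: ExpressionDataset, activities,
                           tau: float) -> RegressionPairs:
    """Pair expression with activities delayed by ``tau``.

    Steady-state samples pair with their own activity column; a time-series
    sample at ``t_n`` pairs with activities linearly interpolated at
    ``t_n - tau`` (clamped to the series start when ``t_n - tau`` precedes
    it).  With ``tau=0`` this is an exact identity pairing.
    """
    if tau < 0:
        raise DataError("tau must be non-negative")
    if activities.samples != expression.samples:
        raise DataError("activities and expression sample ids do not match")
    shifted = _shifted(activities.values, expression.metadata, -tau, tau)
    return RegressionPairs(expression.dataset_id, list(activities.tfs),
                           list(expression.genes), list(expression.samples),
                           shifted.values, expression.values.copy(),
                           shifted.mapping, tau)
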