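"""Directed random walk with restart.

At each step the walker follows a random out-edge with probability 1 - r or
restarts from the initial distribution W0 with probability r:

    W_{t+1} = (1 - r) * M^T @ W_t + r * W0

where M is the row-stochastic transition matrix.  Because W0 is a unit L1
vector and M is row-stochastic, every iterate is a probability vector; the
ground node guarantees convergence.  Iteration stops when the L1 change
between consecutive iterates falls below ``tol`` (default 1e-10).  The
stationary vector W_inf scores each node's topological importance.

A direct solver is also provided: W_inf solves the linear system
(I - (1 - r) M^T) x = r W0, and serves as an independent cross-check of the
power iteration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph_core import GROUND_ID, TransitionMatrix
from .pathway_io import GROUND


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class WalkConfig:
    restart_prob: float = 0.7
    tol: float = 1e-10
    max_iter: int = 10000
    solver: Literal["power", "direct"] = "power"

    def __post_init__(self) -> None:
        if not 0 < self.restart_prob < 1:
            raise ValueError(f"restart_prob must be in (0,1), got {self.restart_prob}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


def _check_inputs(m: TransitionMatrix, w0: pd.Series) -> np.ndarray:
    row_sums = np.asarray(m.matrix.sum(axis=1)).ravel()
    if not np.allclose(row_sums, 1.0, atol=1e-10):
        raise ValueError("transition matrix is not row-stochastic")
    if list(w0.index) != m.node_order:
        w0 = w0.reindex(m.node_order)
        if w0.isna().any():
            raise ValueError("W0 index does not cover the node order")
    v = w0.to_numpy(dtype=float)
    if (v < 0).any():
        raise ValueError("W0 has negative entries")
    if abs(v.sum() - 1.0) > 1e-8:
        raise ValueError(f"W0 not L1-normalized (sum {v.sum():.3g})")
    return v


def walk(m: TransitionMatrix, w0: pd.Series, cfg: WalkConfig = WalkConfig()) -> pd.Series:
    """Iterate the restart walk to its stationary distribution W_inf."""
    v0 = _check_inputs(m, w0)
    mt = m.matrix.T.tocsr()
    r = cfg.restart_prob
    if cfg.solver == "direct":
        n = m.n
        a = sp.eye(n, format="csc") - (1.0 - r) * mt.tocsc()
        x = spla.spsolve(a, r * v0)
        return pd.Series(x, index=m.node_order)
    w = v0.copy()
    for _ in range(cfg.max_iter):
        w_next = (1.0 - r) * (mt @ w) + r * v0
        delta = np.abs(w_next - w).sum()
        w = w_next
        if delta < cfg.tol:
            return pd.Series(w, index=m.node_order)
    raise ConvergenceError(
        f"no convergence in {cfg.max_iter} iterations (last L1 change {delta:.3g})"
    )


def fixed_point_residual(
    m: TransitionMatrix, w0: pd.Series, w_inf: pd.Series, restart_prob: float
) -> float:
    """L1 residual of W_inf in the fixed-point equation; small at convergence."""
    v0 = w0.reindex(m.node_order).to_numpy(dtype=float)
    v = w_inf.reindex(m.node_order).to_numpy(dtype=float)
    mt = m.matrix.T
    return float(np.abs((1 - restart_prob) * (mt @ v) + restart_prob * v0 - v).sum())


def rank_nodes(
    w_inf: pd.Series,
    graph,
    kind: str | None = None,
) -> pd.DataFrame:
    """Nodes sorted by stationary weight, descending; ties broken by id.

    The ground node is always excluded; ``kind`` restricts to gene or
    metabolite nodes.  Returns a frame with node_id, kind, weight, rank.
    """
    rows = []
    for n in w_inf.index:
        if n == GROUND_ID:
            continue
        k = graph.node_kind(n)
        if k == GROUND or (kind is not None and k != kind):
            continue
        rows.append((n, k, float(w_inf[n])))
    rows.sort(key=lambda t: (-t[2], t[0]))
    return pd.DataFrame(
        [(n, k, w, i + 1) for i, (n, k, w) in enumerate(rows)],
        columns=["node_id", "kind", "weight", "rank"],
    )
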