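"""Diffusion profiles: random walk with restart by power iteration.

A diffusion profile is the stationary visitation distribution of a walker
that, at each step, continues along the biased transition matrix ``M`` with
probability ``alpha`` and restarts to the seed distribution ``s`` with
probability ``1 - alpha``. Mass sitting on dangling nodes (rows of ``M``
summing to zero) is re-injected through the restart vector. The update is

    r_{k+1} = (1 - alpha) * s + alpha * r_k M + alpha * (sum_{j in J} r_k[j]) * s

starting from r_0 = s and stopping once the L1 change drops to ``epsilon``
or below. The alpha factor on the dangling term is what keeps the total
mass at exactly 1 each iteration. A dense closed-form solver is provided as
an independent oracle for small networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .network import MultiscaleNetwork, TransitionMatrix

logger = logging.getLogger(__name__)

_EXACT_NODE_GUARD = 2000


@dataclass(frozen=True)
class DiffusionParams:
    """Walk parameters: continuation probability, tolerance, iteration cap.

    ``epsilon`` defaults to 1e-6; ``alpha`` defaults to 0.85, a conventional
    restart setting exposed in configuration rather than fixed.
    """

    alpha: float = 0.85
    epsilon: float = 1e-6
    max_iter: int = 10000

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")


@dataclass
class RestartVector:
    """Restart distribution ``s`` over the node index (sums to 1)."""

    s: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=np.float64)
        if self.s.ndim != 1 or len(self.s) != len(self.ids):
            raise ValueError("restart vector length must match the node index")
        if np.any(self.s < 0) or not np.any(self.s > 0):
            raise ValueError("restart vector must be nonnegative with nonempty support")
        if abs(self.s.sum() - 1.0) > 1e-12:
            raise ValueError("restart vector must sum to 1")


@dataclass
class DiffusionProfile:
    """L1-normalized visitation-probability vector over the node index."""

    r: np.ndarray
    ids: list[str]
    iterations_used: int
    converged: bool
    residuals: list[float] = field(default_factory=list)

    def as_series(self):
        import pandas as pd

        return pd.Series(self.r, index=self.ids, name="probability")


def make_restart_vector(net: MultiscaleNetwork, seed_ids: set[str]) -> RestartVector:
    """Uniform restart distribution over ``seed_ids``."""
    if not seed_ids:
        raise ValueError("seed set is empty")
    unknown = sorted(set(seed_ids) - set(net.index))
    if unknown:
        raise KeyError(f"seed id(s) not in network: {unknown}")
    s = np.zeros(net.n_nodes)
    for sid in seed_ids:
        s[net.index[sid]] = 1.0
    s /= s.sum()
    return RestartVector(s=s, ids=list(net.ids))


def diffuse_power(
    T: TransitionMatrix,
    s: RestartVector,
    p: DiffusionParams | None = None,
    debug: bool = False,
) -> DiffusionProfile:
    """Power-iterate the restart walk to its fixed point.

    With ``debug=True`` the per-iteration mass-conservation invariant
    (sum r_k == 1) is asserted and the L1 residual sequence is recorded.
    """
    p = p or DiffusionParams()
    if len(s.s) != T.n_nodes:
        raise ValueError("restart vector and transition matrix dimensions differ")
    sv = s.s
    m = T.matrix
    dangling = T.dangling
    r = sv.copy()
    residuals: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, p.max_iter + 1):
        dangling_mass = r[dangling].sum() if len(dangling) else 0.0
        r_next = (1.0 - p.alpha) * sv + p.alpha * (r @ m) + p.alpha * dangling_mass * sv
        resid = float(np.abs(r_next - r).sum())
        if debug:
            assert abs(r_next.sum() - 1.0) < 1e-9, "per-iteration mass conservation"
            residuals.append(resid)
        r = r_next
        if resid <= p.epsilon:
            converged = True
            break
    if not converged:
        logger.warning(
            "power iteration did not converge in %d iterations (alpha=%g, eps=%g)",
            p.max_iter, p.alpha, p.epsilon,
        )
    r = np.maximum(r, 0.0)
    r /= r.sum()
    return DiffusionProfile(
        r=r, ids=list(T.ids), iterations_used=iterations,
        converged=converged, residuals=residuals,
    )


def diffuse_exact(
    T: TransitionMatrix, s: RestartVector, alpha: float = 0.85
) -> DiffusionProfile:
    """Closed-form fixed point via a dense linear solve (small networks only).

    Solves ``r = (1 - alpha) s + alpha r M~`` where ``M~`` replaces each
    dangling row of ``M`` with the restart vector; this is exactly the limit
    of :func:`diffuse_power`. Guarded to networks of at most 2000 nodes.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    n = T.n_nodes
    if n > _EXACT_NODE_GUARD:
        raise ValueError(f"dense solve is limited to {_EXACT_NODE_GUARD} nodes, got {n}")
    if len(s.s) != n:
        raise ValueError("restart vector and transition matrix dimensions differ")
    m_tilde = T.matrix.toarray()
    if len(T.dangling):
        m_tilde[T.dangling, :] = s.s
    # row-vector fixed point r (I - alpha M~) = (1 - alpha) s, solved transposed
    a = np.eye(n) - alpha * m_tilde.T
    r = np.linalg.solve(a, (1.0 - alpha) * s.s)
    total = r.sum()
    assert abs(total - 1.0) < 1e-9, "exact solution must carry unit mass"
    r = np.maximum(r, 0.0)
    r /= r.sum()
    return DiffusionProfile(r=r, ids=list(T.ids), iterations_used=0, converged=True)
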