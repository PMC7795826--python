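"""Hypergeometric mixture model and burden-distribution inversion.

The peritoneum is discretised into N sub-surfaces, of which a latent number
K harbour microscopic metastases.  A set of n biopsies is a draw without
replacement, so the number of positive biopsies x given K follows the
hypergeometric law; marginally

    q(x) = sum_K  P(x | K)  p(K),

where p(K) is the cohort-level burden distribution over K = 0..N.  Given
the fitted biopsy-count distribution q, the inversion recovers p by
simplex-constrained least squares.  Because only n+1 values of q constrain
N+1 unknowns, the fit alone does not identify p; the default tie-break is
the minimum-Euclidean-norm solution on the optimal face (the vanishing-
regularisation limit of a Tikhonov penalty), with the penalised program
available through ``lam_reg``.

Summaries: the residual-disease probability P(K >= 1) = 1 - p(0), the
survival function S(n) = P(K > n), the spread indicators n(alpha) with
S(n(alpha)) <= alpha, and the corresponding surface fractions n / N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .geometry import SubSurfaceGrid
from .solvers import SolverDiagnostics, minimum_norm_lsq, penalized_lsq

__all__ = [
    "MixtureMatrix",
    "BurdenDistribution",
    "hypergeom_pmf",
    "build_forward_matrix",
    "invert_burden",
    "residual_probability",
    "survival_function",
    "spread_quantile",
    "spread_quantiles",
    "spread_fraction",
    "DEFAULT_ALPHAS",
]

DEFAULT_ALPHAS = (0.05, 0.25, 0.50, 0.75, 0.95)


@dataclass(frozen=True)
class MixtureMatrix:
    """Forward matrix H with H[x, K] = P(x positives | K affected), column-stochastic."""

    values: np.ndarray = field(repr=False)
    n_draws: int
    n_subsurfaces: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        expected = (self.n_draws + 1, self.n_subsurfaces + 1)
        if values.shape != expected:
            raise ValueError(f"matrix shape {values.shape} != {expected}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class BurdenDistribution:
    """Probability vector over the latent number K of mPM-bearing sub-surfaces."""

    p: np.ndarray = field(repr=False)
    residual_fit: float
    diagnostics: SolverDiagnostics | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("p must be a probability vector over K = 0..N")

    @property
    def n_subsurfaces(self) -> int:
        return self.p.size - 1

    def mean(self) -> float:
        return float(self.p @ np.arange(self.p.size))


def hypergeom_pmf(x: int, N: int, K: int, n: int) -> float:
    """P(x positives among n draws without replacement | K of N affected).

    Thin validated wrapper over the log-space-stable scipy implementation;
    zero outside the support max(0, n-(N-K)) <= x <= min(n, K).
    """
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= x <= n):
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    return float(stats.hypergeom.pmf(x, N, K, n))


def build_forward_matrix(grid: SubSurfaceGrid, n_draws: int) -> MixtureMatrix:
    """Assemble the (n_draws+1) x (N+1) hypergeometric mixture matrix."""
    N = grid.n_subsurfaces
    if n_draws > N:
        raise ValueError(f"n_draws={n_draws} exceeds N={N}")
    if n_draws < 0:
        raise ValueError("n_draws must be non-negative")
    K = np.arange(N + 1)
    values = np.vstack([stats.hypergeom.pmf(x, N, K, n_draws) for x in range(n_draws + 1)])
    return MixtureMatrix(values=values, n_draws=n_draws, n_subsurfaces=N)


def invert_burden(
    q: np.ndarray,
    H: MixtureMatrix,
    lam_reg: float = 0.0,
    refine: str = "auto",
) -> BurdenDistribution:
    """Recover the burden distribution p from the biopsy-count distribution q.

    Solves  min ||H p - q||^2 + lam_reg ||p||^2  over the probability
    simplex.  With ``lam_reg = 0`` (default) the exact least-squares fit is
    combined with the minimum-norm tie-break; with ``lam_reg > 0`` the
    penalised program is solved (recommended only for lam_reg >= 1e-6,
    below which it coincides numerically with the default).  ``refine``
    is forwarded to the minimum-norm solver ("auto" | "never" | "always").
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (H.n_draws + 1,):
        raise ValueError(f"q must have shape ({H.n_draws + 1},), got {q.shape}")
    if np.any(q < 0) or abs(q.sum() - 1.0) > 1e-8:
        raise ValueError("q must be a probability vector")
    if H.n_draws >= 1 and q[0] == 1.0 and lam_reg == 0.0:
        # q = delta_0 forces p = delta_0: any mass at K >= 1 implies a
        # positive probability of at least one positive biopsy.
        p = np.zeros(H.n_subsurfaces + 1)
        p[0] = 1.0
        return BurdenDistribution(p=p, residual_fit=0.0, diagnostics=None)
    if lam_reg == 0.0:
        p, diag = minimum_norm_lsq(H.values, q, refine=refine)
    else:
        p, diag = penalized_lsq(H.values, q, lam_reg)
    return BurdenDistribution(p=p, residual_fit=diag.fit_residual_sq, diagnostics=diag)


def residual_probability(burden: BurdenDistribution) -> float:
    """Probability that at least one sub-surface harbours mPM: 1 - p(0)."""
    return float(1.0 - burden.p[0])


def survival_function(burden: BurdenDistribution) -> np.ndarray:
    """S(n) = P(K > n) for n = 0..N; non-increasing with S(N) = 0."""
    S = 1.0 - np.cumsum(burden.p)
    S = np.maximum(S, 0.0)  # guard rounding at the tail
    S[-1] = 0.0
    return S


def spread_quantile(S: np.ndarray, alpha: float) -> int:
    """Smallest n >= 0 with S(n) <= alpha (S a step function, ties downward)."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    idx = np.nonzero(S <= alpha)[0]
    return int(idx[0])


def spread_quantiles(
    burden: BurdenDistribution, alphas: Sequence[float] = DEFAULT_ALPHAS
) -> Mapping[float, int]:
    """Spread indicators n(alpha) for each tail level alpha."""
    S = survival_function(burden)
    return {float(a): spread_quantile(S, a) for a in alphas}


def spread_fraction(n: int, grid: SubSurfaceGrid) -> float:
    """Fraction of the peritoneal surface represented by n sub-surfaces."""
    if not (0 <= n <= grid.n_subsurfaces):
        raise ValueError(f"n must lie in 0..{grid.n_subsurfaces}, got {n}")
    return n / grid.n_subsurfaces
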