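"""Simplex-constrained least-squares solvers for mixture deconvolution.

The inversion problem is: given a column-stochastic matrix H (m x (N+1),
m << N) and a probability vector q, find a probability vector p minimising
||H p - q||^2.  The problem is massively underdetermined: the minimiser set
is a face of the probability simplex.  Two selections are provided.

* ``minimum_norm_lsq`` (default in the public API): the exact least-squares
  fit combined with the minimum-Euclidean-norm tie-break, i.e. the limit of
  Tikhonov regularisation as the penalty weight goes to zero.  Stage one
  finds the optimal fit y* = H w by non-negative least squares with the
  normalisation enforced through a heavily weighted penalty row; stage two
  projects onto {p >= 0 : H p = y*, sum p = 1} by solving the associated
  15-dimensional smooth concave dual.

* ``penalized_lsq``: the Tikhonov-regularised program
  min ||H p - q||^2 + lam_reg ||p||^2 on the simplex, solved exactly via a
  semismooth-Newton method on its dual.  Reliable for lam_reg >= ~1e-6;
  below that the problem is numerically indistinguishable from the
  minimum-norm limit, which should be used instead.

Both solvers are deterministic: repeated calls return identical vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["SolverDiagnostics", "SolverError", "minimum_norm_lsq", "penalized_lsq"]


class SolverError(RuntimeError):
    """Solver failed to reach its convergence tolerance; carries diagnostics."""

    def __init__(self, message: str, diagnostics: "SolverDiagnostics"):
        super().__init__(f"{message} ({diagnostics})")
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class SolverDiagnostics:
    """Convergence record of one inversion."""

    fit_residual_sq: float      # ||H p - q||^2 at the returned solution
    stage1_residual_sq: float   # best attainable ||H w - q||^2 (NNLS stage)
    kkt_residual: float         # norm of the dual gradient at termination
    iterations: int
    refined: bool = False

    def __str__(self) -> str:  # compact, used in SolverError messages
        return (
            f"fit={self.fit_residual_sq:.3e} stage1={self.stage1_residual_sq:.3e} "
            f"kkt={self.kkt_residual:.3e} iters={self.iterations} refined={self.refined}"
        )


def _nnls_fit(H: np.ndarray, q: np.ndarray, gamma: float) -> np.ndarray:
    """Stage one: sparse w >= 0 with sum w = 1 minimising ||H w - q||^2.

    The sum constraint is enforced by a penalty row of weight gamma; the
    result is renormalised, shifting the fit by O(residual / gamma^2).
    """
    n_cols = H.shape[1]
    A = np.vstack([H, np.full((1, n_cols), gamma)])
    b = np.concatenate([q, [gamma]])
    w, _ = optimize.nnls(A, b)
    total = w.sum()
    if total <= 0:
        raise SolverError(
            "NNLS stage returned the zero vector",
            SolverDiagnostics(np.inf, np.inf, np.inf, 0),
        )
    return w / total


def _projection_dual(Aug: np.ndarray, y: np.ndarray, t0: np.ndarray, max_polish: int = 50):
    """Minimise ||p||^2 over {p >= 0 : Aug p = y} through its dual.

    The dual is  max_t  t.y - (1/4) ||max(0, Aug^T t)||^2,  a smooth concave
    piecewise-quadratic in dim(y) variables, with primal recovery
    p = max(0, Aug^T t) / 2.  L-BFGS-B does the bulk of the work; a
    semismooth-Newton polish sharpens the active set.
    """

    def negdual(t: np.ndarray):
        s = Aug.T @ t
        sp = np.maximum(0.0, s)
        value = -(t @ y) + 0.25 * np.sum(sp * sp)
        grad = -y + Aug @ (sp / 2.0)
        return value, grad

    res = optimize.minimize(
        negdual,
        t0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 20_000, "ftol": 1e-18, "gtol": 1e-12, "maxcor": 30, "maxls": 100},
    )
    t = res.x
    m = Aug.shape[0]

    def dual_value(t: np.ndarray) -> float:
        s = Aug.T @ t
        return float(t @ y - 0.25 * np.sum(np.maximum(0.0, s) ** 2))

    for _ in range(max_polish):
        s = Aug.T @ t
        p = np.maximum(0.0, s) / 2.0
        grad = y - Aug @ p
        if np.linalg.norm(grad) < 1e-13:
            break
        active = s > 0
        A_act = Aug[:, active]
        M = A_act @ A_act.T / 2.0
        try:
            direction = np.linalg.solve(M + 1e-13 * np.eye(m), grad)
        except np.linalg.LinAlgError:
            break
        base = dual_value(t)
        step, improved = 1.0, False
        while step > 1e-16:
            if dual_value(t + step * direction) >= base:
                improved = True
                break
            step /= 2.0
        if not improved:
            break
        t = t + step * direction
    s = Aug.T @ t
    p = np.maximum(0.0, s) / 2.0
    kkt = float(np.linalg.norm(y - Aug @ p))
    return p, kkt, int(res.nit)


def _nnls_refine(Aug: np.ndarray, y: np.ndarray, rho: float) -> np.ndarray:
    """High-accuracy stage two: min ||p||^2 s.t. Aug p = y, p >= 0 via the
    penalty form  min ||[rho*Aug; I] p - [rho*y; 0]||^2  with p >= 0.

    Exact active-set NNLS; equality violation scales as ||dual|| / rho^2.
    Slower than the dual route but tight, used for one-shot analyses.
    """
    m, n_cols = Aug.shape
    A = np.vstack([rho * Aug, np.eye(n_cols)])
    b = np.concatenate([rho * y, np.zeros(n_cols)])
    p, _ = optimize.nnls(A, b)
    return p


def minimum_norm_lsq(
    H: np.ndarray,
    q: np.ndarray,
    gamma: float = 1e4,
    refine: str = "auto",
    refine_kkt_threshold: float = 1e-6,
    refine_rho: float = 1e6,
) -> tuple[np.ndarray, SolverDiagnostics]:
    """Exact simplex-constrained least squares with minimum-norm tie-break.

    Parameters
    ----------
    H : (m, n) column-stochastic forward matrix.
    q : (m,) probability vector to deconvolve.
    gamma : weight of the sum-to-one penalty row in the NNLS fit stage.
    refine : "auto" runs the accurate NNLS projection whenever the fast dual
        leaves a KKT residual above ``refine_kkt_threshold``; "never" keeps
        the dual solution (used in simulation loops where the tie-break
        precision is immaterial); "always" forces the NNLS projection.
    """
    H = np.asarray(H, dtype=float)
    q = np.asarray(q, dtype=float)
    w = _nnls_fit(H, q, gamma)
    y_star = H @ w
    stage1 = float(np.sum((y_star - q) ** 2))
    Aug = np.vstack([H, np.ones(H.shape[1])])
    y = np.concatenate([y_star, [1.0]])
    t0 = np.linalg.lstsq(Aug.T, 2.0 * w, rcond=None)[0]
    p, kkt, iters = _projection_dual(Aug, y, t0)
    refined = False
    if refine == "always" or (refine == "auto" and kkt > refine_kkt_threshold):
        p = _nnls_refine(Aug, y, refine_rho)
        kkt = float(np.linalg.norm(y - Aug @ p))
        refined = True
    elif refine not in ("auto", "never", "always"):
        raise ValueError(f"unknown refine mode {refine!r}")
    total = p.sum()
    if not np.isfinite(total) or total <= 0:
        raise SolverError(
            "projection stage failed",
            SolverDiagnostics(np.inf, stage1, kkt, iters, refined),
        )
    p = p / total
    diag = SolverDiagnostics(
        fit_residual_sq=float(np.sum((H @ p - q) ** 2)),
        stage1_residual_sq=stage1,
        kkt_residual=kkt,
        iterations=iters,
        refined=refined,
    )
    return p, diag


def penalized_lsq(
    H: np.ndarray,
    q: np.ndarray,
    lam_reg: float,
    max_iter: int = 500,
    tol: float = 1e-11,
) -> tuple[np.ndarray, SolverDiagnostics]:
    """Tikhonov-regularised simplex least squares, solved exactly.

    Minimises ||H p - q||^2 + lam_reg ||p||^2 over the simplex via a damped
    semismooth-Newton method on the dual
        max_{u, nu}  -||u||^2/4 - u.q + nu - ||max(0, nu - H^T u)||^2/(4 lam_reg)
    with primal recovery p = max(0, nu - H^T u) / (2 lam_reg).
    """
    if lam_reg <= 0:
        raise ValueError("lam_reg must be positive; use minimum_norm_lsq for the limit")
    H = np.asarray(H, dtype=float)
    q = np.asarray(q, dtype=float)
    m, n_cols = H.shape
    u = np.zeros(m)
    nu = 2.0 * lam_reg / n_cols

    def eval_all(u, nu):
        s = nu - H.T @ u
        p = np.maximum(0.0, s) / (2.0 * lam_reg)
        value = -u @ u / 4.0 - u @ q + nu - lam_reg * np.sum(p * p)
        grad = np.concatenate([-u / 2.0 - q + H @ p, [1.0 - p.sum()]])
        return s, p, value, grad

    damping = 0.0
    it = 0
    for it in range(max_iter):
        s, p, value, grad = eval_all(u, nu)
        if np.linalg.norm(grad) < tol:
            break
        active = s > 0
        H_act = H[:, active]
        n_act = max(int(active.sum()), 1)
        M = np.zeros((m + 1, m + 1))
        M[:m, :m] = H_act @ H_act.T / (2.0 * lam_reg) + np.eye(m) / 2.0
        M[:m, m] = -H_act.sum(axis=1) / (2.0 * lam_reg)
        M[m, :m] = M[:m, m]
        M[m, m] = n_act / (2.0 * lam_reg)
        accepted = False
        level = damping
        for _ in range(60):
            try:
                d = np.linalg.solve(M + level * np.eye(m + 1), grad)
            except np.linalg.LinAlgError:
                level = max(level * 10.0, 1e-10)
                continue
            step = 1.0
            for _ in range(60):
                _, _, trial, _ = eval_all(u + step * d[:m], nu + step * d[m])
                if trial >= value + 1e-4 * step * (grad @ d):
                    accepted = True
                    break
                step /= 2.0
            if accepted:
                break
            level = max(level * 10.0, 1e-10)
        if not accepted:
            break
        u, nu = u + step * d[:m], nu + step * d[m]
        damping = level / 4.0
    s, p, value, grad = eval_all(u, nu)
    kkt = float(np.linalg.norm(grad))
    total = p.sum()
    diag = SolverDiagnostics(
        fit_residual_sq=float(np.sum((H @ (p / total) - q) ** 2)) if total > 0 else np.inf,
        stage1_residual_sq=np.nan,
        kkt_residual=kkt,
        iterations=it + 1,
        refined=False,
    )
    if total <= 0 or kkt > max(tol * 1e3, 1e-6):
        raise SolverError("penalized dual Newton did not converge", diag)
    return p / total, diag
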