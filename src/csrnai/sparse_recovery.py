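"""Sparse knockdown-profile recovery by l1 minimization.

Given readouts y = Phi x + e with ||e|| <= eps, the knockdown profile x is
recovered by basis pursuit denoising

    (P1)  min ||x||_1  s.t.  ||Phi x - y||_2 <= eps,

solved by proximal soft-thresholding (FISTA) with continuation on the
penalty parameter; the discrepancy principle maps eps to the penalty so the
residual lands within 1% of eps. An exhaustive minimum-support program (P0)
serves as an oracle on small instances, and the Candes-Romberg-Tao
restricted-isometry condition delta_3S + 3*delta_4S < 2, under which the
(P1) error is bounded by a constant times eps, can be checked exhaustively.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .motif_network import RIPEstimate, SensingMatrix, rip_delta

INNER_TOL = 1e-8       # optimality-violation tolerance, relative to the penalty
RESIDUAL_RTOL = 0.01   # discrepancy target: residual within 1% of eps
MAX_ITER = 10_000
SUPPORT_RTOL = 1e-6    # debias support threshold relative to max |x|
ZERO_EPS_RTOL = 1e-9   # eps=0: target residual relative to ||y||


class InfeasibleError(ValueError):
    """No x satisfies the residual constraint (eps too small for this y)."""


@dataclass(frozen=True)
class SparseSignal:
    """A K-sparse profile: values, support and sparsity."""

    values: np.ndarray

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.values)

    @property
    def sparsity(self) -> int:
        return int(np.count_nonzero(self.values))


@dataclass
class RecoveryResult:
    estimate: np.ndarray
    residual_norm: float
    objective: float       # l1 norm of the estimate
    iterations: int
    converged: bool
    debiased: bool
    support: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.support is None:
            self.support = np.flatnonzero(self.estimate)


def _phi_array(matrix) -> np.ndarray:
    if isinstance(matrix, SensingMatrix):
        return matrix.entries
    return np.asarray(matrix, dtype=float)


def _shrink(v, threshold, nonneg=False):
    """Soft-threshold prox of the l1 norm; one-sided under a nonnegativity cone."""
    if nonneg:
        return np.maximum(v - threshold, 0.0)
    return np.sign(v) * np.maximum(np.abs(v) - threshold, 0.0)


def _opt_violation(x, grad, lam):
    """Worst violation of the l1-penalized optimality (subgradient) condition."""
    on = x != 0
    viol = 0.0
    if on.any():
        viol = float(np.abs(grad[on] + lam * np.sign(x[on])).max())
    if (~on).any():
        viol = max(viol, float(np.maximum(np.abs(grad[~on]) - lam, 0.0).max()))
    return viol


def _fista(phi, y, lam, x0, lipschitz, max_iter, tol, gram=None, phity=None,
           nonneg=False):
    """FISTA with monotone restart for 0.5||Phi x - y||^2 + lam ||x||_1.

    Iterates until the subgradient optimality condition is met to
    ``tol * max(lam, scale)`` — a stall-proof criterion, unlike relative
    iterate change, which can halt far from the minimizer when the penalty
    is tiny. Returns (x, iterations).
    """
    if gram is None:
        gram = phi.T @ phi
    if phity is None:
        phity = phi.T @ y
    x = x0.copy()
    z = x.copy()
    t = 1.0
    step = 1.0 / lipschitz
    scale = float(np.abs(phity).max())
    target = tol * max(lam, 1e-6 * scale)

    def objective(v):
        r = gram @ v - 2.0 * phity
        return 0.5 * float(v @ r) + lam * float(np.abs(v).sum())

    f_prev = objective(x)
    for it in range(1, max_iter + 1):
        grad_z = gram @ z - phity
        x_new = _shrink(z - step * grad_z, lam * step, nonneg)
        f_new = objective(x_new)
        if f_new > f_prev:  # momentum overshoot: restart from the last iterate
            z = x.copy()
            t = 1.0
            grad_x = gram @ x - phity
            x_new = _shrink(x - step * grad_x, lam * step, nonneg)
            f_new = objective(x_new)
        t_new = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t * t))
        z = x_new + ((t - 1.0) / t_new) * (x_new - x)
        x, t, f_prev = x_new, t_new, f_new
        if it % 10 == 0 or it == max_iter:
            grad = gram @ x - phity
            if _opt_violation(x, grad, lam) <= target:
                return x, it
    return x, max_iter


def _debias(phi, y, x, eps):
    """Least-squares refit on the recovered support (removes l1 shrinkage).

    Support detection gates at three per-component noise standard deviations
    (3*eps/sqrt(m)): l1 solutions at the discrepancy penalty carry spurious
    coefficients of exactly that scale, and refitting on them would refit
    the noise. Components below the gate are statistically undetectable
    anyway. For eps = 0 only the relative floor applies.
    """
    gate = max(SUPPORT_RTOL * max(np.abs(x).max(), 1e-300),
               3.0 * eps / math.sqrt(phi.shape[0]))
    support = np.flatnonzero(np.abs(x) > gate)
    if support.size == 0:
        return x, float(np.linalg.norm(y))
    coef, *_ = np.linalg.lstsq(phi[:, support], y, rcond=None)
    out = np.zeros_like(x)
    out[support] = coef
    return out, float(np.linalg.norm(phi @ out - y))


def solve_p1(matrix, y, epsilon: float, debias: bool = True,
             max_iter: int = MAX_ITER, inner_tol: float = INNER_TOL,
             nonnegative: bool = False) -> RecoveryResult:
    """Solve the noise-aware l1 program (P1) by continuation + discrepancy.

    The penalized surrogate 0.5||Phi x - y||^2 + lam ||x||_1 is solved by
    FISTA along a decreasing penalty path; the path stops when the residual
    reaches eps, and a bisection on lam lands the residual within 1% of eps
    (for eps = 0, the penalty is driven toward 0 instead). ``debias=True``
    refits least squares on the recovered support, the configuration used
    for simulation reporting. ``nonnegative=True`` constrains the profile to
    the nonnegative cone (knockdown strengths cannot be negative) via the
    one-sided prox. Deterministic for fixed inputs.
    """
    phi = _phi_array(matrix)
    y = np.asarray(y, dtype=float).ravel()
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    m, n = phi.shape
    if y.shape[0] != m:
        raise ValueError(f"y has length {len(y)}, matrix has {m} rows")

    if np.linalg.norm(y) <= epsilon:
        return RecoveryResult(np.zeros(n), float(np.linalg.norm(y)), 0.0, 0, True, False)

    # feasibility floor: the unconstrained least-squares residual
    x_ls, *_ = np.linalg.lstsq(phi, y, rcond=None)
    res_floor = float(np.linalg.norm(phi @ x_ls - y))
    if res_floor > epsilon + 1e-9 + RESIDUAL_RTOL * epsilon:
        raise InfeasibleError(
            f"no solution reaches residual {epsilon:.3g}; best achievable is {res_floor:.3g}"
        )

    gram = phi.T @ phi
    phity = phi.T @ y
    lipschitz = float(np.linalg.norm(phi, 2) ** 2)
    lam_max = float(np.abs(phity).max())
    y_norm = float(np.linalg.norm(y))
    if epsilon == 0.0:
        # basis pursuit: drive the residual to numerical zero along the path
        target_lo, target_hi = 0.0, max(ZERO_EPS_RTOL * y_norm, 1e-14)
    else:
        target_hi = epsilon * (1.0 + RESIDUAL_RTOL)
        target_lo = epsilon * (1.0 - RESIDUAL_RTOL)

    x = np.zeros(n)
    total_iter = 0
    lam = 0.9 * lam_max
    lam_hi = lam_max  # residual(lam_hi) stays above the target band
    converged = False
    # continuation: halve lam until the residual dips into/below the band
    for _ in range(200):
        x, it = _fista(phi, y, lam, x, lipschitz, max_iter, inner_tol,
                       gram=gram, phity=phity, nonneg=nonnegative)
        total_iter += it
        residual = float(np.linalg.norm(phi @ x - y))
        if residual > target_hi:
            lam_hi = lam
            lam *= 0.5
            if lam < 1e-15 * lam_max:
                converged = epsilon == 0.0 and residual <= 1e-6 * y_norm
                break
            continue
        if residual >= target_lo:
            converged = True
            break
        # overshot below the band: bisect between lam and lam_hi
        lam_lo = lam
        for _ in range(50):
            lam = math.sqrt(max(lam_lo, 1e-300) * lam_hi)
            x, it = _fista(phi, y, lam, x, lipschitz, max_iter, inner_tol,
                           gram=gram, phity=phity, nonneg=nonnegative)
            total_iter += it
            residual = float(np.linalg.norm(phi @ x - y))
            if residual > target_hi:
                lam_hi = lam
            elif residual < target_lo:
                lam_lo = lam
            else:
                converged = True
                break
        break

    residual = float(np.linalg.norm(phi @ x - y))
    debiased = False
    if debias:
        # The refit residual may legitimately exceed eps: least squares on the
        # detected support leaves exactly the off-support noise component,
        # whose norm fluctuates around (and beyond) the eps = sigma*sqrt(m) bound.
        x_db, res_db = _debias(phi, y, x, epsilon)
        if nonnegative:
            x_db = np.maximum(x_db, 0.0)
            res_db = float(np.linalg.norm(phi @ x_db - y))
        if np.any(x_db):
            x, residual, debiased = x_db, res_db, True
    return RecoveryResult(
        estimate=x,
        residual_norm=residual,
        objective=float(np.abs(x).sum()),
        iterations=total_iter,
        converged=converged,
        debiased=debiased,
    )


def solve_p0_oracle(matrix, y, epsilon: float, max_support: int,
                    budget: int = 10 ** 6) -> RecoveryResult:
    """Exhaustive minimum-support program (P0) for small instances.

    Searches supports of size 0..max_support; each candidate support is fit
    by least squares; the smallest feasible support wins, ties resolved by
    smaller residual. Raises InfeasibleError when nothing within
    ``max_support`` meets the residual bound.
    """
    phi = _phi_array(matrix)
    y = np.asarray(y, dtype=float).ravel()
    n = phi.shape[1]
    total = sum(math.comb(n, s) for s in range(max_support + 1))
    if total > budget:
        raise ValueError(f"{total} supports exceed enumeration budget {budget}")
    tol = epsilon + 1e-9
    best = None
    for size in range(max_support + 1):
        for support in itertools.combinations(range(n), size):
            if size == 0:
                residual = float(np.linalg.norm(y))
                x = np.zeros(n)
            else:
                cols = phi[:, list(support)]
                coef, *_ = np.linalg.lstsq(cols, y, rcond=None)
                x = np.zeros(n)
                x[list(support)] = coef
                residual = float(np.linalg.norm(cols @ coef - y))
            if residual <= tol and (best is None or residual < best.residual_norm):
                best = RecoveryResult(x, residual, float(np.abs(x).sum()),
                                      0, True, False)
        if best is not None:
            return best
    raise InfeasibleError(
        f"no support of size <= {max_support} reaches residual {epsilon:.3g}"
    )


@dataclass
class TheoremRegime:
    holds: bool
    S: int
    delta_3S: float
    delta_4S: float


def check_theorem1_regime(matrix: SensingMatrix, S: int,
                          budget: int = 10 ** 6) -> TheoremRegime:
    """Check the restricted-isometry recovery condition delta_3S + 3*delta_4S < 2.

    Inside this regime, any signal supported on at most S columns is
    recovered by (P1) with error at most a constant multiple of the noise
    bound. Constants are computed exhaustively via :func:`rip_delta`.
    """
    d3: RIPEstimate = rip_delta(matrix, 3 * S, budget=budget)
    d4: RIPEstimate = rip_delta(matrix, 4 * S, budget=budget)
    return TheoremRegime(
        holds=bool(d3.delta_S + 3.0 * d4.delta_S < 2.0),
        S=S,
        delta_3S=d3.delta_S,
        delta_4S=d4.delta_S,
    )
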