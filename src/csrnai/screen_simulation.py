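"""Monte-Carlo evaluation of the pooled-screen recovery pipeline.

Reproduces the numerical experiments of the screening model: K-sparse
knockdown profiles with U(0,1) magnitudes, Gaussian readout noise at
controlled scale, l1 recovery with debiasing, and MSE/SNR sweeps over
sparsity and noise levels. Also provides the concatenated-orthonormal-basis
("Donoho") construction of a low-coherence 48 x 146 sensing matrix used as
the ideal example.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motif_network import SensingMatrix
from .sparse_recovery import SparseSignal, solve_p1


@dataclass(frozen=True)
class Measurement:
    """Noisy readout y = Phi x0 + e with its noise bookkeeping."""

    values: np.ndarray
    noise: np.ndarray
    epsilon: float
    sigma: float
    snr_db: float


@dataclass
class SimulationConfig:
    m: int = 48
    n: int = 146
    sparsity_levels: tuple = (3, 4, 5, 6)
    sigmas: tuple = (0.001, 0.005, 0.02)
    reps: int = 5
    seed: int = 0
    debias: bool = True

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if any(k > self.n or k < 1 for k in self.sparsity_levels):
            raise ValueError("every K must lie in 1..n")
        if any(s < 0 for s in self.sigmas):
            raise ValueError("sigmas must be >= 0")


def make_sparse_signal(n: int, k: int, rng: np.random.Generator) -> SparseSignal:
    """Draw n components from U(0,1) and zero all but the K largest."""
    if not 1 <= k <= n:
        raise ValueError(f"K={k} outside 1..{n}")
    raw = rng.uniform(0.0, 1.0, size=n)
    values = np.zeros(n)
    keep = np.argsort(raw)[-k:]
    values[keep] = raw[keep]
    return SparseSignal(values=values)


def add_noise(matrix, x0: np.ndarray, sigma: float,
              rng: np.random.Generator) -> Measurement:
    """Gaussian perturbation e ~ N(0, sigma^2) per component; y = Phi x0 + e.

    sigma is the standard deviation. The residual bound handed to the
    recovery program is the expected noise norm eps = sigma * sqrt(m), and
    SNR is defined as 10*log10(||Phi x0||^2 / (m sigma^2)).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    phi = matrix.entries if isinstance(matrix, SensingMatrix) else np.asarray(matrix)
    m = phi.shape[0]
    clean = phi @ x0
    noise = rng.normal(0.0, sigma, size=m) if sigma > 0 else np.zeros(m)
    signal_power = float(clean @ clean)
    snr = (
        10.0 * np.log10(signal_power / (m * sigma ** 2)) if sigma > 0 else np.inf
    )
    return Measurement(
        values=clean + noise,
        noise=noise,
        epsilon=sigma * np.sqrt(m),
        sigma=sigma,
        snr_db=float(snr),
    )


_K_RULE_VARIANTS = ("literal", "log10", "sqrt")


def sparsity_from_rule(c: float, m: int, n: int, variant: str = "literal") -> int:
    """Sparsity from a coefficient c and the matrix shape.

    Variants (rounding half away from zero, result clamped to 1..n):

    * ``literal`` — K = c*m/ln(n), the printed form of the rule;
    * ``log10``   — K = c*m/log10(n);
    * ``sqrt``    — K = c*sqrt(m)/log10(n), which at (m, n) = (48, 146)
      rounds to 3, 4, 5, 6 for c = 1, 1.2, 1.5, 2.
    """
    if c <= 0:
        raise ValueError("c must be > 0")
    if variant not in _K_RULE_VARIANTS:
        raise ValueError(f"variant must be one of {_K_RULE_VARIANTS}")
    if variant == "literal":
        value = c * m / np.log(n)
    elif variant == "log10":
        value = c * m / np.log10(n)
    else:
        value = c * np.sqrt(m) / np.log10(n)
    k = int(np.floor(value + 0.5))  # half away from zero (value is positive)
    return max(1, min(k, n))


@dataclass
class SweepRecord:
    K: int
    sigma: float
    snr_db: float
    mse: float
    normalized_error_pct: float
    rep: int
    converged: bool


def run_cell(matrix, k: int, sigma: float, rng: np.random.Generator,
             debias: bool = True) -> SweepRecord:
    """One simulation draw: generate, measure, recover, score."""
    phi = matrix.entries if isinstance(matrix, SensingMatrix) else np.asarray(matrix)
    n = phi.shape[1]
    x0 = make_sparse_signal(n, k, rng).values
    meas = add_noise(phi, x0, sigma, rng)
    result = solve_p1(phi, meas.values, meas.epsilon, debias=debias)
    err = result.estimate - x0
    return SweepRecord(
        K=k,
        sigma=sigma,
        snr_db=meas.snr_db,
        mse=float(err @ err) / n,
        normalized_error_pct=100.0 * float(np.linalg.norm(err) / np.linalg.norm(x0)),
        rep=0,
        converged=result.converged,
    )


def run_sweep(matrix, config: SimulationConfig) -> pd.DataFrame:
    """Full (K, sigma, rep) sweep; rows sorted by (K, sigma, rep).

    Each cell regenerates x0 and e from a substream seeded by
    (seed, K, sigma index, rep), so tables are bit-reproducible and
    individual cells can be recomputed in isolation.
    """
    rows = []
    for k in config.sparsity_levels:
        for si, sigma in enumerate(config.sigmas):
            for rep in range(config.reps):
                rng = np.random.default_rng(
                    np.random.SeedSequence([config.seed, k, si, rep])
                )
                rec = run_cell(matrix, k, sigma, rng, debias=config.debias)
                rec.rep = rep
                rows.append(rec)
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df.sort_values(["K", "sigma", "rep"]).reset_index(drop=True)


def donoho_matrix(m: int, n: int, n_bases: int = 3,
                  rng: np.random.Generator | None = None,
                  seed: int | None = None) -> SensingMatrix:
    """Low-coherence matrix from concatenated random orthonormal bases.

    ``n_bases`` random orthonormal bases of R^m (orthonormalized Gaussian
    draws) are concatenated column-wise; if fewer than n columns result, the
    remainder are unit-normalized Gaussian columns; extras are truncated.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if m >= n:
        import logging
        logging.getLogger("csrnai").warning(
            "m=%d >= n=%d: the matrix is not compressive", m, n
        )
    blocks = []
    for _ in range(n_bases):
        q, _ = np.linalg.qr(rng.normal(size=(m, m)))
        blocks.append(q)
    entries = np.concatenate(blocks, axis=1)
    if entries.shape[1] < n:
        extra = rng.normal(size=(m, n - entries.shape[1]))
        extra /= np.linalg.norm(extra, axis=0)
        entries = np.concatenate([entries, extra], axis=1)
    entries = entries[:, :n]
    return SensingMatrix(
        entries=entries,
        row_ids=[f"w{i + 1}" for i in range(m)],
        col_ids=[f"g{j + 1}" for j in range(n)],
        normalized=True,
    )


def simplex_frame(m: int, rng: np.random.Generator | None = None,
                  seed: int | None = None, jitter: float = 0.0) -> SensingMatrix:
    """The simplex equiangular frame: m+1 unit vectors in R^m, inner product -1/m.

    The most spread-out overcomplete frame a single extra column allows; for
    m = 6 its restricted-isometry constants (delta_3 = 1/3, delta_4 = 1/2)
    satisfy the recovery condition delta_3 + 3*delta_4 < 2 — the smallest
    matrices on which the l1 = l0 guarantee provably applies. ``jitter``
    adds entrywise Gaussian perturbation (renormalized) and a random
    rotation, giving distinct instances with nearby isometry constants.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    gram = np.full((m + 1, m + 1), -1.0 / m) + np.eye(m + 1) * (1.0 + 1.0 / m)
    w, u = np.linalg.eigh(gram)
    entries = (u[:, 1:] * np.sqrt(w[1:])).T  # drop the null direction
    entries /= np.linalg.norm(entries, axis=0)
    if jitter > 0:
        q, _ = np.linalg.qr(rng.normal(size=(m, m)))
        entries = q @ entries + jitter * rng.normal(size=(m, m + 1))
        entries /= np.linalg.norm(entries, axis=0)
    return SensingMatrix(
        entries=entries,
        row_ids=[f"w{i + 1}" for i in range(m)],
        col_ids=[f"g{j + 1}" for j in range(m + 1)],
        normalized=True,
    )


def ideal_example_errors(seed: int = 0, reps: int = 50, m: int = 48, n: int = 146,
                         k: int = 3, sigma: float = 0.001) -> np.ndarray:
    """Normalized recovery errors (%) for the ideal low-coherence example.

    One concatenated-orthonormal-basis matrix, ``reps`` independent K-sparse
    signals with Gaussian noise of scale sigma, debiased l1 recovery; returns
    the per-repetition normalized errors 100*||x_r - x_0|| / ||x_0||.
    """
    matrix = donoho_matrix(m, n, n_bases=3, seed=seed)
    errors = []
    for rep in range(reps):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1000 + rep]))
        rec = run_cell(matrix, k, sigma, rng, debias=True)
        errors.append(rec.normalized_error_pct)
    return np.array(errors)
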