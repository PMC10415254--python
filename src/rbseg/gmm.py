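"""Expectation-maximization fitting of Gaussian mixture models.

The pixel-labeling stage models the grayscale intensity histogram of a
fundus-image composite as a mixture of ``K`` Gaussians, each described by a
mean ``mu_k``, covariance ``Sigma_k`` and mixing probability ``pi_k``.  EM
alternates between computing posterior component memberships
(responsibilities) and re-estimating the component parameters from the
responsibility-weighted moments.  The implementation is dimension-generic
(``D >= 1``) although the segmentation pipeline uses scalar intensities.

All density arithmetic happens in log-space with per-point max subtraction so
that the ~6e5-pixel composites used by the pipeline do not underflow.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

#: Smallest eigenvalue permitted for any component covariance (intensities
#: live in [0, 1]; this stops components collapsing onto flat image regions).
VARIANCE_FLOOR = 1e-6

#: A component whose effective count drops below this is re-seeded from a
#: random data point instead of producing a degenerate M-step.
_MIN_EFFECTIVE_COUNT = 1e-8


class DegenerateComponentError(ValueError):
    """Raised when a covariance is singular below the variance floor."""


class NumericalDegeneracyError(FloatingPointError):
    """Raised when every component density underflows for some data point."""


@dataclass
class GmmModel:
    """Gaussian mixture parameters ``{mu, Sigma, pi}`` for ``K`` components."""

    mu: np.ndarray  # (K, D)
    Sigma: np.ndarray  # (K, D, D)
    pi: np.ndarray  # (K,)

    def __post_init__(self) -> None:
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.Sigma.ndim == 1:  # K scalar variances
            self.Sigma = self.Sigma.reshape(-1, 1, 1)
        self.pi = np.asarray(self.pi, dtype=float)

    @property
    def K(self) -> int:
        return self.mu.shape[0]

    @property
    def D(self) -> int:
        return self.mu.shape[1]

    def validate(self) -> None:
        if self.mu.shape != (self.K, self.D):
            raise ValueError("mu must have shape (K, D)")
        if self.Sigma.shape != (self.K, self.D, self.D):
            raise ValueError("Sigma must have shape (K, D, D)")
        if self.pi.shape != (self.K,):
            raise ValueError("pi must have shape (K,)")
        if np.any(self.pi < 0):
            raise ValueError("mixing probabilities must be non-negative")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("mixing probabilities must sum to 1")
        for k in range(self.K):
            S = self.Sigma[k]
            if not np.allclose(S, S.T, atol=1e-12):
                raise ValueError(f"Sigma[{k}] is not symmetric")
            if np.linalg.eigvalsh(S).min() < VARIANCE_FLOOR * (1 - 1e-9):
                raise DegenerateComponentError(
                    f"Sigma[{k}] has an eigenvalue below the variance floor"
                )

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "D": self.D,
            "mu": self.mu.tolist(),
            "Sigma": self.Sigma.tolist(),
            "pi": self.pi.tolist(),
        }


@dataclass
class FitResult:
    """Winning EM run: fitted model plus its log-likelihood trajectory."""

    model: GmmModel
    log_likelihood_trace: np.ndarray
    n_iter: int
    seed: int

    @property
    def log_likelihood(self) -> float:
        return float(self.log_likelihood_trace[-1])

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.model.to_dict(),
                "log_likelihood_trace": np.asarray(self.log_likelihood_trace).tolist(),
                "n_iter": int(self.n_iter),
                "seed": int(self.seed),
            }
        )


def log_component_density(x: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> float:
    """Log-density of a multivariate normal at a single point.

    ``-(D/2) ln 2pi - (1/2) ln |Sigma| - (1/2) (x-mu)^T Sigma^-1 (x-mu)``
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    if not np.allclose(Sigma, Sigma.T, atol=1e-12):
        raise DegenerateComponentError("Sigma must be symmetric")
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as exc:
        raise DegenerateComponentError("Sigma is not positive-definite") from exc
    D = x.size
    sol = np.linalg.solve(L, x - mu)
    log_det = 2.0 * np.sum(np.log(np.diag(L)))
    return float(-0.5 * D * np.log(2 * np.pi) - 0.5 * log_det - 0.5 * sol @ sol)


def _log_densities(data: np.ndarray, model: GmmModel) -> np.ndarray:
    """(N, K) matrix of per-component log-densities ``ln N(x_n | mu_k, Sigma_k)``."""
    N, D = data.shape
    out = np.empty((N, model.K))
    const = -0.5 * D * np.log(2 * np.pi)
    for k in range(model.K):
        try:
            L = np.linalg.cholesky(model.Sigma[k])
        except np.linalg.LinAlgError as exc:
            raise DegenerateComponentError(
                f"component {k} covariance is not positive-definite"
            ) from exc
        diff = data - model.mu[k]
        sol = np.linalg.solve(L, diff.T)
        log_det = 2.0 * np.sum(np.log(np.diag(L)))
        out[:, k] = const - 0.5 * log_det - 0.5 * np.sum(sol * sol, axis=0)
    return out


def _posteriors(data: np.ndarray, model: GmmModel) -> tuple[np.ndarray, np.ndarray]:
    """Responsibilities and per-point log-evidence, both log-space stabilized."""
    log_dens = _log_densities(data, model)
    with np.errstate(divide="ignore"):
        weighted = log_dens + np.log(model.pi)
    # max-subtraction: logsumexp is finite unless every component underflows
    log_norm = logsumexp(weighted, axis=1)
    if not np.all(np.isfinite(log_norm)):
        raise NumericalDegeneracyError(
            "all component densities underflowed for at least one data point"
        )
    gamma = np.exp(weighted - log_norm[:, None])
    return gamma, log_norm


def e_step(data: np.ndarray, model: GmmModel) -> np.ndarray:
    """Posterior responsibility ``gamma[n, k] = p(z_k = 1 | x_n)`` for every point.

    ``gamma[n,k] = pi_k N(x_n|mu_k,Sigma_k) / sum_j pi_j N(x_n|mu_j,Sigma_j)``
    """
    data = _as_matrix(data)
    gamma, _ = _posteriors(data, model)
    return gamma


def m_step(
    data: np.ndarray,
    gamma: np.ndarray,
    sample_weight: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> GmmModel:
    """Re-estimate ``{pi, mu, Sigma}`` from responsibility-weighted moments.

    ``pi_k = (1/N) sum_n gamma_nk``;  ``mu_k`` is the gamma-weighted mean;
    ``Sigma_k`` the gamma-weighted scatter about ``mu_k``, floored at
    :data:`VARIANCE_FLOOR`.  ``sample_weight`` lets one data row stand for many
    identical points (histogram-weighted EM); weights default to 1.

    A component whose effective count falls below ``1e-8`` is re-seeded from a
    random data point rather than aborting the fit.
    """
    data = _as_matrix(data)
    gamma = np.asarray(gamma, dtype=float)
    N, D = data.shape
    if gamma.shape[0] != N:
        raise ValueError("gamma and data row counts differ")
    if sample_weight is None:
        w = np.ones(N)
    else:
        w = np.asarray(sample_weight, dtype=float)
    wg = gamma * w[:, None]  # (N, K)
    K = gamma.shape[1]
    Nk = wg.sum(axis=0)  # effective counts
    N_total = w.sum()

    if rng is None:
        rng = np.random.default_rng(0)
    mu = np.empty((K, D))
    Sigma = np.empty((K, D, D))
    for k in range(K):
        if Nk[k] < _MIN_EFFECTIVE_COUNT:
            logger.warning("component %d collapsed; re-seeding from a data point", k)
            idx = int(rng.integers(N))
            mu[k] = data[idx]
            Sigma[k] = np.eye(D) * max(float(np.var(data)), VARIANCE_FLOOR)
            Nk[k] = _MIN_EFFECTIVE_COUNT
            continue
        mu[k] = wg[:, k] @ data / Nk[k]
        diff = data - mu[k]
        Sigma[k] = (diff * wg[:, k, None]).T @ diff / Nk[k]
        Sigma[k] = _floor_covariance(Sigma[k])
    pi = Nk / N_total
    pi = pi / pi.sum()
    return GmmModel(mu=mu, Sigma=Sigma, pi=pi)


def _floor_covariance(S: np.ndarray) -> np.ndarray:
    S = 0.5 * (S + S.T)
    if S.shape[0] == 1:
        return np.maximum(S, VARIANCE_FLOOR)
    vals, vecs = np.linalg.eigh(S)
    if vals.min() >= VARIANCE_FLOOR:
        return S
    vals = np.maximum(vals, VARIANCE_FLOOR)
    return (vecs * vals) @ vecs.T


def fit_gmm(
    data: np.ndarray,
    K: int,
    n_init: int = 25,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
    sample_weight: np.ndarray | None = None,
) -> FitResult:
    """Fit a K-component mixture by EM with ``n_init`` seeded restarts.

    Restart ``i`` is seeded ``seed + i``; each run starts from K means drawn
    uniformly from the data without replacement, the global data variance and
    uniform mixing weights, then alternates E and M steps until the mean
    per-point log-likelihood improves by less than ``tol`` (or ``max_iter``).
    The restart with the highest final total log-likelihood wins, making the
    whole fit a pure function of its arguments.
    """
    data = _as_matrix(data)
    N = data.shape[0]
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    if K >= N:
        raise ValueError(f"need more data points than components (N={N}, K={K})")
    if sample_weight is not None:
        sample_weight = np.asarray(sample_weight, dtype=float)
        if sample_weight.shape != (N,):
            raise ValueError("sample_weight must have one entry per data row")
    w_total = float(N) if sample_weight is None else float(sample_weight.sum())

    best: FitResult | None = None
    for i in range(n_init):
        run_seed = seed + i
        result = _em_single(data, K, run_seed, tol, max_iter, sample_weight, w_total)
        if best is None or result.log_likelihood > best.log_likelihood:
            best = result
    assert best is not None
    return best


def _em_single(
    data: np.ndarray,
    K: int,
    run_seed: int,
    tol: float,
    max_iter: int,
    sample_weight: np.ndarray | None,
    w_total: float,
) -> FitResult:
    rng = np.random.default_rng(run_seed)
    N, D = data.shape
    # means drawn uniformly from the distinct data rows: for the weighted
    # (histogram) fit this spreads the initial means across intensity modes
    # regardless of their mass, which is what lets restarts find minority
    # structures (lesions, disc) next to a dominant background mode
    idx = rng.choice(N, size=K, replace=False)
    var0 = max(float(np.var(data)), VARIANCE_FLOOR)
    model = GmmModel(
        mu=data[idx].copy(),
        Sigma=np.repeat((np.eye(D) * var0)[None], K, axis=0),
        pi=np.full(K, 1.0 / K),
    )
    w = sample_weight if sample_weight is not None else None
    trace: list[float] = []
    prev_mean_ll = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        gamma, log_norm = _posteriors(data, model)
        total_ll = float(log_norm @ w) if w is not None else float(log_norm.sum())
        trace.append(total_ll)
        model = m_step(data, gamma, sample_weight=w, rng=rng)
        mean_ll = total_ll / w_total
        if mean_ll - prev_mean_ll < tol and n_iter > 1:
            break
        prev_mean_ll = mean_ll
    # log-likelihood of the final parameter set (trace entry i is evaluated
    # *before* M-step i, so append one last evaluation for the returned model)
    _, log_norm = _posteriors(data, model)
    total_ll = float(log_norm @ w) if w is not None else float(log_norm.sum())
    trace.append(total_ll)
    return FitResult(
        model=model,
        log_likelihood_trace=np.asarray(trace),
        n_iter=n_iter,
        seed=run_seed,
    )


def assign_clusters(data: np.ndarray, model: GmmModel) -> np.ndarray:
    """Hard cluster labels: argmax responsibility, ties to the lowest index."""
    gamma = e_step(data, model)
    return np.argmax(gamma, axis=1)


def _as_matrix(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    if data.ndim != 2:
        raise ValueError("data must be an (N, D) matrix")
    return data
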