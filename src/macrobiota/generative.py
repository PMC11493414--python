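"""Stochastic-logistic / Gamma machinery and the three generative models.

A species following stochastic logistic growth with environmental noise,

    dx/dt = x/tau * (1 - x/K) + sqrt(sigma/tau) * x * xi(t),

has (under the Ito convention) a stationary Gamma abundance-fluctuation
distribution with shape ``alpha = (2 - sigma)/sigma`` and rate
``beta = 2/(sigma*K)``.  Normalising S independent Gamma species onto the
simplex gives the Scaled Dirichlet distribution; constraining its 2S
parameters with Taylor's law (variance = A * mean^zeta) and a mean-abundance
distribution (MAD) reduces the free parameters to at most three (mu, lambda,
A).  Convolving with read sampling yields the three count-table models:

MD
    Dirichlet (zeta = 1) composition + multinomial sampling.
    Poisson-like mean-variance scaling; strictly compositional.
MSSD
    Symmetric Scaled Dirichlet (zeta = 2, all shapes equal to 1/A)
    composition + multinomial sampling.  Satisfies Taylor's law with
    exponent 2; strictly compositional.
PSLG
    Independent Gamma abundances (zeta = 2, mean abundances normalised to
    sum to one) + per-species Poisson sampling.  Compositional only on
    average: column sums fluctuate around the nominal depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import special

from .table import AbundanceTable

__all__ = [
    "SLMParams",
    "GammaParams",
    "ModelSpec",
    "MODEL_NAMES",
    "gamma_from_slm",
    "slm_from_gamma",
    "params_from_taylor",
    "sigma_from_A",
    "A_from_sigma",
    "draw_mad",
    "scaled_dirichlet_logpdf",
    "sample_scaled_dirichlet",
    "sample_md",
    "sample_mssd",
    "sample_pslg",
    "sample_model",
    "simulate_slm",
]

MODEL_NAMES = ("md", "mssd", "pslg")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ----------------------------------------------------------------------
# parameter containers
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SLMParams:
    """Ecological parameters of the stochastic logistic model.

    K : carrying capacity (relative-abundance scale, > 0)
    sigma : width of environmental noise, must lie in (0, 2) for a
        stationary distribution to exist
    tau : growth timescale; irrelevant at stationarity and consumed only
        by :func:`simulate_slm`
    """

    K: np.ndarray
    sigma: np.ndarray
    tau: np.ndarray = field(default=1.0)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        K, sigma, tau = np.broadcast_arrays(
            np.atleast_1d(np.asarray(self.K, dtype=float)),
            np.atleast_1d(np.asarray(self.sigma, dtype=float)),
            np.atleast_1d(np.asarray(self.tau, dtype=float)),
        )
        if (K <= 0).any():
            raise ValueError("carrying capacity K must be positive")
        if (sigma <= 0).any() or (sigma >= 2).any():
            raise ValueError(
                "sigma must lie in (0, 2): outside this range the stationary "
                "Gamma shape (2 - sigma)/sigma is non-positive"
            )
        if (tau <= 0).any():
            raise ValueError("tau must be positive")
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "tau", tau)


@dataclass(frozen=True)
class GammaParams:
    """Shape/rate parameters of per-species Gamma abundance distributions."""

    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        alpha, beta = np.broadcast_arrays(
            np.atleast_1d(np.asarray(self.alpha, dtype=float)),
            np.atleast_1d(np.asarray(self.beta, dtype=float)),
        )
        if (alpha <= 0).any():
            raise ValueError("Gamma shape alpha must be positive")
        if (beta <= 0).any():
            raise ValueError("Gamma rate beta must be positive")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)

    @property
    def alpha0(self) -> float:
        return float(self.alpha.sum())

    @property
    def mean(self) -> np.ndarray:
        return self.alpha / self.beta

    @property
    def variance(self) -> np.ndarray:
        return self.alpha / self.beta**2


@dataclass
class ModelSpec:
    """A generative model plus the reduced parameter set needed to sample it.

    ``mu``/``lam`` locate and scale the (log) mean-abundance distribution,
    ``A`` is the Taylor's-law amplitude and ``zeta`` the Taylor exponent
    (1 for MD, 2 for MSSD and PSLG).  ``depths`` are the per-sample read
    totals N_r.  The MSSD is scale invariant in the mean abundances, so it
    ignores ``mu``; its free parameters are (lambda, A) only.
    """

    model: Literal["md", "mssd", "pslg"]
    lam: float
    A: float
    S: int
    depths: np.ndarray
    mu: float | None = None
    zeta: int | None = None
    mad_family: str = "log_laplace"

    def __post_init__(self) -> None:
        self.model = str(self.model).lower()  # type: ignore[assignment]
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODEL_NAMES}")
        if self.zeta is None:
            self.zeta = 1 if self.model == "md" else 2
        expected = 1 if self.model == "md" else 2
        if self.zeta != expected:
            raise ValueError(f"model {self.model!r} requires zeta={expected}")
        if not self.lam > 0:
            raise ValueError("MAD scale lam must be positive")
        if not self.A > 0:
            raise ValueError("Taylor amplitude A must be positive")
        if self.S < 1:
            raise ValueError("S must be at least 1")
        self.depths = np.atleast_1d(np.asarray(self.depths, dtype=np.int64))
        if (self.depths <= 0).any():
            raise ValueError("depths must be positive integers")
        if self.model != "mssd" and self.mu is None:
            raise ValueError(f"model {self.model!r} needs the MAD location mu")
        if self.model == "mssd" and self.mu is None:
            self.mu = 0.0  # irrelevant: the MSSD is scale invariant

    @property
    def R(self) -> int:
        return int(self.depths.size)

    @property
    def free_parameters(self) -> tuple[str, ...]:
        """Names of the independently fitted parameters of this model."""
        if self.model == "mssd":
            return ("lam", "A")
        return ("mu", "lam", "A")


# ----------------------------------------------------------------------
# parameter maps
# ----------------------------------------------------------------------
def gamma_from_slm(params: SLMParams) -> GammaParams:
    """Stationary Gamma parameters of the stochastic logistic model.

    alpha = (2 - sigma)/sigma and beta = 2/(sigma*K); the implied stationary
    mean is K*(1 - sigma/2) and variance K^2*(sigma/2)*(1 - sigma/2).
    """
    alpha = (2.0 - params.sigma) / params.sigma
    beta = 2.0 / (params.sigma * params.K)
    return GammaParams(alpha=alpha, beta=beta)


def slm_from_gamma(params: GammaParams, tau=1.0) -> SLMParams:
    """Moment inversion of :func:`gamma_from_slm` (tau is not identifiable)."""
    sigma = 2.0 / (params.alpha + 1.0)
    K = 2.0 / (sigma * params.beta)
    return SLMParams(K=K, sigma=sigma, tau=tau)


def params_from_taylor(mean_abundances, A: float, zeta: int) -> GammaParams:
    """Per-species Gamma parameters implied by Taylor's law.

    alpha_i = xbar_i^(2-zeta)/A and beta_i = xbar_i^(1-zeta)/A, so the
    Gamma mean is xbar_i and variance A*xbar_i^zeta.  For zeta=2 all the
    shapes collapse to the constant 1/A; for zeta=1 all the rates collapse
    to the constant 1/A (which cancels from the Dirichlet composition).
    """
    xbar = np.atleast_1d(np.asarray(mean_abundances, dtype=float))
    if (xbar <= 0).any():
        raise ValueError("mean abundances must be strictly positive")
    if not A > 0:
        raise ValueError("Taylor amplitude A must be positive")
    if zeta not in (1, 2):
        raise ValueError("zeta must be 1 or 2")
    alpha = xbar ** (2 - zeta) / A
    beta = xbar ** (1 - zeta) / A
    return GammaParams(alpha=alpha, beta=np.broadcast_to(beta, alpha.shape).copy())


def sigma_from_A(A: float) -> float:
    """Environmental-noise width from the zeta=2 Taylor amplitude.

    Inverts alpha = (2 - sigma)/sigma = 1/A to sigma = 2A/(1 + A); strictly
    increasing in A, with range (0, 2).  A > 1 corresponds to sigma > 1, the
    regime whose abundance-fluctuation distribution diverges at zero.
    """
    A = np.asarray(A, dtype=float)
    if (A <= 0).any():
        raise ValueError("Taylor amplitude A must be positive")
    out = 2.0 * A / (1.0 + A)
    return float(out) if out.ndim == 0 else out


def A_from_sigma(sigma: float) -> float:
    """Inverse of :func:`sigma_from_A`: A = sigma/(2 - sigma)."""
    sigma = np.asarray(sigma, dtype=float)
    if (sigma <= 0).any() or (sigma >= 2).any():
        raise ValueError("sigma must lie in (0, 2)")
    out = sigma / (2.0 - sigma)
    return float(out) if out.ndim == 0 else out


# ----------------------------------------------------------------------
# mean-abundance distribution draws
# ----------------------------------------------------------------------
def draw_mad(mu: float, lam: float, size: int, family: str = "log_laplace", seed=None) -> np.ndarray:
    """Draw mean abundances xbar from the MAD family on the log scale."""
    rng = _rng(seed)
    if family == "log_laplace":
        return np.exp(rng.laplace(mu, lam, size))
    if family == "log_normal":
        return np.exp(rng.normal(mu, lam, size))
    raise ValueError(f"unknown MAD family {family!r}")


# ----------------------------------------------------------------------
# scaled Dirichlet
# ----------------------------------------------------------------------
def scaled_dirichlet_logpdf(v, params: GammaParams, tol: float = 1e-8) -> float | np.ndarray:
    """Log density of the Scaled Dirichlet distribution on the open simplex.

    log p(v) = sum_i (alpha_i - 1) log v_i - alpha_0 log(sum_i beta_i v_i)
               - log Z,   Z = B(alpha) / prod_i beta_i^alpha_i,

    with B the S-variate Beta function.  The density is invariant under a
    common rescaling of the rates beta -> c*beta.
    """
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    V = np.atleast_2d(v)
    alpha, beta = params.alpha, params.beta
    if V.shape[1] != alpha.size:
        raise ValueError("composition dimension does not match parameters")
    if (V <= 0).any() or (np.abs(V.sum(axis=1) - 1.0) > tol).any():
        raise ValueError("compositions must lie in the open simplex (v_i > 0, sum v = 1)")
    a0 = alpha.sum()
    log_B = special.gammaln(alpha).sum() - special.gammaln(a0)
    log_Z = log_B - (alpha * np.log(beta)).sum()
    out = ((alpha - 1.0) * np.log(V)).sum(axis=1) - a0 * np.log(V @ beta) - log_Z
    return float(out[0]) if single else out


def sample_scaled_dirichlet(params: GammaParams, n_samples: int, seed=None) -> np.ndarray:
    """Exact Scaled Dirichlet sampler via normalised independent Gamma draws.

    Returns an (n_samples, S) array of compositions; each row sums to one.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    rng = _rng(seed)
    g = rng.gamma(params.alpha, 1.0 / params.beta, size=(n_samples, params.alpha.size))
    # guard against underflow to an all-zero row for extreme shape parameters
    g = np.clip(g, np.finfo(float).tiny, None)
    return g / g.sum(axis=1, keepdims=True)


# ----------------------------------------------------------------------
# count-table samplers
# ----------------------------------------------------------------------
def _multinomial_counts(compositions: np.ndarray, depths: np.ndarray, rng) -> np.ndarray:
    S = compositions.shape[1]
    counts = np.empty((S, depths.size), dtype=np.int64)
    for r in range(depths.size):
        counts[:, r] = rng.multinomial(depths[r], compositions[r])
    return counts


def _finish_table(counts: np.ndarray, depths: np.ndarray, model: str) -> AbundanceTable:
    return AbundanceTable(counts=counts, cohort=np.array([model] * depths.size, dtype=object))


def sample_md(spec: ModelSpec, seed=None, mean_abundances=None) -> AbundanceTable:
    """Multinomial Dirichlet cohort: Dirichlet(alpha_i = xbar_i/A) + multinomial.

    Column sums equal the requested depths exactly.
    """
    if spec.model != "md":
        raise ValueError("spec.model must be 'md'")
    rng = _rng(seed)
    xbar = (
        np.asarray(mean_abundances, dtype=float)
        if mean_abundances is not None
        else draw_mad(spec.mu, spec.lam, spec.S, spec.mad_family, rng)
    )
    gp = params_from_taylor(xbar, spec.A, zeta=1)
    comp = sample_scaled_dirichlet(gp, spec.R, rng)  # equal rates -> plain Dirichlet
    counts = _multinomial_counts(comp, spec.depths, rng)
    return _finish_table(counts, spec.depths, "md")


def sample_mssd(spec: ModelSpec, seed=None, mean_abundances=None) -> AbundanceTable:
    """Multinomial Symmetric Scaled Dirichlet cohort (zeta = 2).

    Compositions come from the Symmetric Scaled Dirichlet (all shapes 1/A,
    rates proportional to 1/xbar_i), counts from a multinomial per sample;
    strict compositionality (column sums equal depths exactly).
    """
    if spec.model != "mssd":
        raise ValueError("spec.model must be 'mssd'")
    rng = _rng(seed)
    xbar = (
        np.asarray(mean_abundances, dtype=float)
        if mean_abundances is not None
        else draw_mad(spec.mu, spec.lam, spec.S, spec.mad_family, rng)
    )
    gp = params_from_taylor(xbar, spec.A, zeta=2)
    comp = sample_scaled_dirichlet(gp, spec.R, rng)
    counts = _multinomial_counts(comp, spec.depths, rng)
    return _finish_table(counts, spec.depths, "mssd")


def sample_pslg(spec: ModelSpec, seed=None, mean_abundances=None) -> AbundanceTable:
    """Poisson Stochastic Logistic Growth cohort (zeta = 2).

    Mean abundances are renormalised to sum to one, each species' relative
    abundance is drawn independently from its Gamma marginal, and counts are
    Poisson(N_r * v_i).  Column sums equal the depths only on average.
    """
    if spec.model != "pslg":
        raise ValueError("spec.model must be 'pslg'")
    rng = _rng(seed)
    xbar = (
        np.asarray(mean_abundances, dtype=float)
        if mean_abundances is not None
        else draw_mad(spec.mu, spec.lam, spec.S, spec.mad_family, rng)
    )
    xbar = xbar / xbar.sum()  # compositional on average
    gp = params_from_taylor(xbar, spec.A, zeta=2)
    v = rng.gamma(gp.alpha, 1.0 / gp.beta, size=(spec.R, spec.S))
    counts = rng.poisson(spec.depths[None, :] * v.T).astype(np.int64)
    # reference totals are the realised classified-read sums, as for data
    return _finish_table(counts, spec.depths, "pslg")


_SAMPLERS = {"md": sample_md, "mssd": sample_mssd, "pslg": sample_pslg}


def sample_model(spec: ModelSpec, seed=None, mean_abundances=None) -> AbundanceTable:
    """Dispatch to the sampler named by ``spec.model``."""
    return _SAMPLERS[spec.model](spec, seed=seed, mean_abundances=mean_abundances)


# ----------------------------------------------------------------------
# SDE integration
# ----------------------------------------------------------------------
def simulate_slm(
    params: SLMParams,
    dt: float = 0.01,
    t_max: float = 100.0,
    x0=None,
    seed=None,
    record_every: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama integration of the stochastic logistic SDE (Ito).

    Integrates dx = x/tau*(1 - x/K) dt + sqrt(sigma/tau)*x dW for each
    species in ``params``.  Returns ``(times, trajectory)`` where the
    trajectory has shape (n_recorded, n_species).  The long-run histogram is
    consistent with the stationary Gamma of :func:`gamma_from_slm`.
    """
    K, sigma, tau = params.K, params.sigma, params.tau
    if dt <= 0 or t_max <= dt:
        raise ValueError("need 0 < dt < t_max")
    if dt > 0.1 * tau.min():
        raise ValueError("dt must be small compared to the growth timescale tau")
    rng = _rng(seed)
    x = np.broadcast_to(
        np.asarray(K if x0 is None else x0, dtype=float), K.shape
    ).astype(float).copy()
    if (x <= 0).any():
        raise ValueError("initial abundances must be positive")
    n_steps = int(round(t_max / dt))
    times, traj = [], []
    sqrt_noise = np.sqrt(sigma / tau * dt)
    for step in range(1, n_steps + 1):
        x = x + x / tau * (1.0 - x / K) * dt + sqrt_noise * x * rng.standard_normal(x.shape)
        if not np.isfinite(x).all():
            raise FloatingPointError(
                "trajectory left the finite range; reduce dt (the Euler-Maruyama "
                "step is too coarse for this sigma/tau)"
            )
        # multiplicative noise cannot cross zero in continuous time; clip the
        # rare discretisation overshoot instead of losing the trajectory
        np.clip(x, 1e-300, None, out=x)
        if step % record_every == 0:
            times.append(step * dt)
            traj.append(x.copy())
    return np.asarray(times), np.asarray(traj)
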