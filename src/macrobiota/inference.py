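"""Fitting the reduced parameter set (mu, lambda, A -> sigma) from a table.

The mean-abundance distribution (MAD) is fitted per family by maximum
likelihood on the log scale:

* Log-Laplace: ``mu = median(log vbar)``, ``lambda = mean |log vbar - mu|``
* Log-Normal:  ``mu = mean(log vbar)``,   ``lambda = std(log vbar)``

Family selection uses BIC = k ln n - 2 lnL with k = 2 for both families, so
the comparison reduces to a likelihood contrast with equal penalty.  Both
BICs are computed from the log-transformed data: the 1/x Jacobian is common
to the two families and cancels from the comparison, and on the log scale
the BICs are positive at microbiome abundance scales, which is what makes
the conventional ratio reading ("ratio > 1 favours Log-Laplace") well
defined.  A sign guard enforces this, and the difference
``delta_bic = BIC_LL - BIC_LN`` (negative favours Log-Laplace) is always
reported alongside as the pathology-free fallback.

Taylor's law is fitted by ordinary least squares of log variance on log
mean; a free fit estimates (log A, zeta) and a constrained fit pins the
exponent and estimates log A as ``mean(log var - zeta * log mean)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .generative import ModelSpec
from .patterns import mean_abundance, taylor_points
from .table import AbundanceTable

__all__ = [
    "MADFit",
    "TaylorFit",
    "fit_mad",
    "bic_ratio",
    "fit_taylor",
    "bootstrap_se",
    "debiased_taylor_points",
    "estimate_amplitude",
    "fit_model",
]

_MIN_SPECIES = 10


@dataclass
class MADFit:
    """Maximum-likelihood fit of the mean-abundance distribution."""

    family: str  # selected family: "log_laplace" or "log_normal"
    mu: float  # location of log vbar for the selected family
    lam: float  # scale of log vbar for the selected family
    bic_log_laplace: float
    bic_log_normal: float
    bic_ratio: float  # BIC_LN / BIC_LL; > 1 favours Log-Laplace
    delta_bic: float  # BIC_LL - BIC_LN; < 0 favours Log-Laplace
    n: int
    n_excluded_zeros: int = 0
    se_lam: float | None = None
    params: dict | None = None  # per-family (mu, lam)


@dataclass
class TaylorFit:
    """OLS fit of Taylor's law, variance = A * mean^zeta, on log-log points."""

    zeta: float  # free-fit exponent
    A: float  # free-fit amplitude exp(intercept)
    zeta_fixed: float  # pinned exponent of the constrained fit
    A_fixed: float  # constrained-fit amplitude
    r2_free: float
    r2_fixed: float
    ratio: float  # r2_fixed / r2_free
    n: int


def _laplace_loglik(y: np.ndarray, mu: float, lam: float) -> float:
    return float(-np.abs(y - mu).sum() / lam - y.size * np.log(2.0 * lam))


def _normal_loglik(y: np.ndarray, mu: float, lam: float) -> float:
    return float(-0.5 * ((y - mu) ** 2).sum() / lam**2 - y.size * np.log(lam * np.sqrt(2 * np.pi)))


def fit_mad(mean_abundances, family: str = "auto") -> MADFit:
    """Fit the MAD to strictly positive mean abundances.

    Zeros are excluded (their count is recorded); fewer than 10 positive
    values is an error.  ``family`` is one of ``"log_laplace"``,
    ``"log_normal"`` or ``"auto"`` (BIC selection).
    """
    x = np.asarray(mean_abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("mean abundances must be non-negative")
    n_zeros = int((x == 0).sum())
    x = x[x > 0]
    if x.size < _MIN_SPECIES:
        raise ValueError(f"need at least {_MIN_SPECIES} strictly positive mean abundances")
    y = np.log(x)
    n = y.size

    mu_ll = float(np.median(y))
    lam_ll = float(np.abs(y - mu_ll).mean())
    mu_ln = float(y.mean())
    lam_ln = float(y.std(ddof=0))
    if lam_ll <= 0 or lam_ln <= 0:
        raise ValueError("degenerate (constant) log abundances; MAD scale undefined")

    k = 2
    bic_ll = k * np.log(n) - 2.0 * _laplace_loglik(y, mu_ll, lam_ll)
    bic_ln = k * np.log(n) - 2.0 * _normal_loglik(y, mu_ln, lam_ln)
    delta = bic_ll - bic_ln
    ratio = bic_ln / bic_ll if (bic_ll > 0) == (bic_ln > 0) else float("nan")

    if family == "auto":
        family = "log_laplace" if delta < 0 else "log_normal"
    if family == "log_laplace":
        mu, lam = mu_ll, lam_ll
    elif family == "log_normal":
        mu, lam = mu_ln, lam_ln
    else:
        raise ValueError(f"unknown MAD family {family!r}")

    return MADFit(
        family=family,
        mu=mu,
        lam=lam,
        bic_log_laplace=float(bic_ll),
        bic_log_normal=float(bic_ln),
        bic_ratio=float(ratio),
        delta_bic=float(delta),
        n=n,
        n_excluded_zeros=n_zeros,
        params={"log_laplace": (mu_ll, lam_ll), "log_normal": (mu_ln, lam_ln)},
    )


def bic_ratio(bic_log_laplace: float, bic_log_normal: float) -> float:
    """Family-selection statistic BIC_LN / BIC_LL; values > 1 favour Log-Laplace.

    Requires both BICs on the same, positive, scale (guaranteed when both
    are computed from log-transformed data at microbiome scales).  If the
    BICs disagree in sign the ratio would invert its reading, so an error
    directs the caller to the ``delta_bic`` fallback.
    """
    if (bic_log_laplace > 0) != (bic_log_normal > 0):
        raise ValueError(
            "BIC values disagree in sign; the ratio is not interpretable — "
            "use the delta_bic (BIC_LL - BIC_LN) fallback instead"
        )
    return bic_log_normal / bic_log_laplace


def fit_taylor(points, fixed_zeta: float = 2.0) -> TaylorFit:
    """Fit Taylor's law to per-species (mean, variance) pairs.

    ``points`` is a ``(means, variances)`` pair of arrays.  Species with
    non-positive mean or variance are dropped (log undefined).  At least 10
    usable pairs, and more than one distinct mean, are required.
    """
    means, variances = (np.asarray(a, dtype=float) for a in points)
    ok = (means > 0) & (variances > 0)
    means, variances = means[ok], variances[ok]
    if means.size < _MIN_SPECIES:
        raise ValueError(f"need at least {_MIN_SPECIES} positive (mean, variance) pairs")
    lm, lv = np.log(means), np.log(variances)
    if np.ptp(lm) == 0:
        raise ValueError("degenerate input: all means identical")

    zeta, log_A = np.polyfit(lm, lv, 1)
    ss_tot = ((lv - lv.mean()) ** 2).sum()
    if ss_tot == 0:
        # all variances identical: the free fit is exact and flat
        ss_tot = np.inf
    resid_free = lv - (zeta * lm + log_A)
    r2_free = 1.0 - (resid_free**2).sum() / ss_tot

    log_A_fixed = float((lv - fixed_zeta * lm).mean())
    resid_fixed = lv - (fixed_zeta * lm + log_A_fixed)
    r2_fixed = 1.0 - (resid_fixed**2).sum() / ss_tot
    if not np.isfinite(r2_free) or np.isinf(ss_tot):
        r2_free = r2_fixed = 1.0

    return TaylorFit(
        zeta=float(zeta),
        A=float(np.exp(log_A)),
        zeta_fixed=float(fixed_zeta),
        A_fixed=float(np.exp(log_A_fixed)),
        r2_free=float(r2_free),
        r2_fixed=float(r2_fixed),
        ratio=float(r2_fixed / r2_free) if r2_free != 0 else float("nan"),
        n=int(means.size),
    )


def bootstrap_se(estimator, data, n_boot: int = 1000, seed=None) -> float:
    """Nonparametric bootstrap standard error of ``estimator(data)``.

    Resampling is over species (rows of ``data`` if 2-D, elements if 1-D),
    since both the MAD and Taylor's law are species-level patterns.  The
    estimator may fail on at most 10% of the resamples.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    data = np.asarray(data)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = data.shape[0]
    values, failures = [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            values.append(float(estimator(data[idx])))
        except Exception:
            failures += 1
    if failures > 0.1 * n_boot:
        raise RuntimeError(f"estimator failed on {failures}/{n_boot} bootstrap resamples")
    return float(np.std(values, ddof=1))


def debiased_taylor_points(
    table: AbundanceTable,
    zeta: int = 2,
    min_occupancy: float = 0.5,
    sampling_correction: bool = True,
    compositional_correction: bool | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Taylor points corrected for read sampling and compositional coupling.

    Two finite-size effects bias the raw mean-variance points upward and
    flatten their scaling:

    * read sampling adds about ``vbar/N`` to each species' across-sample
      variance (removed by :func:`~macrobiota.patterns.taylor_points` with
      ``sampling_correction``);
    * normalising by the fluctuating community total couples every species
      to the dominant ones: to first order the variance of a zeta = 2
      community is multiplied by ``1 + sum_j w_j^2 - 2 w_i`` with ``w`` the
      mean-abundance weights.  This factor is divided out when
      ``compositional_correction`` applies (default: only for zeta = 2,
      where the factor is exact to first order).
    """
    mean, var = taylor_points(table, min_occupancy, sampling_correction=sampling_correction)
    if compositional_correction is None:
        compositional_correction = zeta == 2
    if compositional_correction:
        vbar = mean_abundance(table)
        tot = vbar.sum()
        c2 = float((vbar**2).sum() / tot**2)
        factor = np.clip(1.0 + c2 - 2.0 * mean / tot, 0.05, None)
        var = var / factor
    return mean, var


def estimate_amplitude(table: AbundanceTable, max_share: float = 0.2, min_core: int = 4) -> float:
    """Robust zeta = 2 Taylor-amplitude estimate from log-abundance fluctuations.

    For a zeta = 2 community every species shares the Gamma shape
    ``alpha = 1/A``, and on the log scale ``Var(log v_i) = psi'(alpha) + C``
    where ``psi'`` is the trigamma function and ``C`` is the common-mode
    variance contributed by the fluctuating community total (normalisation
    couples every species to the dominant ones).  ``C`` is directly
    estimable as the typical cross-species covariance of log abundances, so
    the estimator is

        psi'(alpha) = median_i Var(log v_i) - median_{i<j} Cov(log v_i, log v_j)

    over "core" species (always present, mean share below ``max_share``),
    with the per-species read-sampling variance of log counts (~ mean 1/c)
    subtracted.  Unlike the variance-mean regression this inversion is
    insensitive to a dominant species, because the common mode is removed
    empirically rather than by a first-order expansion.  Falls back to the
    regression amplitude of :func:`debiased_taylor_points` when fewer than
    ``min_core`` core species exist.
    """
    A = _amplitude_from_arrays(table.counts, table.depths, max_share, min_core)
    if A is None:
        m, s2 = debiased_taylor_points(table, zeta=2)
        return fit_taylor((m, s2), fixed_zeta=2).A_fixed
    return A


def _amplitude_from_arrays(
    counts: np.ndarray, depths: np.ndarray, max_share: float = 0.2, min_core: int = 4
) -> float | None:
    """Array-level core of :func:`estimate_amplitude`; None if too few core species."""
    from scipy import optimize, special

    v = counts / np.where(depths > 0, depths, 1)
    occ = (counts > 0).mean(axis=1)
    vbar = v.mean(axis=1)
    core = (occ == 1.0) & (vbar < max_share)
    if core.sum() < min_core and max_share < 0.5:
        core = (occ == 1.0) & (vbar < 0.5)
    if core.sum() < min_core:
        return None
    lv = np.log(v[core])
    samp = (1.0 / np.maximum(counts[core], 1)).mean(axis=1)
    var = lv.var(axis=1, ddof=1) - samp
    centred = lv - lv.mean(axis=1, keepdims=True)
    cov = centred @ centred.T / (lv.shape[1] - 1)
    common = float(np.median(cov[np.triu_indices(cov.shape[0], k=1)]))
    psi1 = float(np.median(var) - common)
    lo, hi = 1e-4, 1e4
    psi1 = float(np.clip(psi1, special.polygamma(1, hi), special.polygamma(1, lo)))
    alpha = optimize.brentq(lambda a: special.polygamma(1, a) - psi1, lo, hi)
    return 1.0 / alpha


def fit_model(
    table: AbundanceTable,
    model: str,
    min_occupancy: float = 0.5,
    mad_family: str = "auto",
    debias: bool = True,
) -> tuple[ModelSpec, MADFit, TaylorFit]:
    """Fit a generative model's free parameters from a count table.

    Fitting happens on the table with no cutoff applied: the MAD gives
    (mu, lambda), the mean-variance points give A at the model's pinned
    exponent (zeta = 1 for MD, 2 for MSSD/PSLG).  With ``debias`` (default)
    the Taylor points are corrected for read-sampling and (for zeta = 2)
    compositional-coupling inflation via :func:`debiased_taylor_points`, so
    that the amplitude fed back into generation is that of the underlying
    composition rather than of its sampled image.  Returns the
    ready-to-sample :class:`ModelSpec` with the underlying MAD/Taylor fits.
    """
    model = model.lower()
    if table.n_samples < 2:
        raise ValueError("fitting needs at least 2 samples")
    vbar = mean_abundance(table)
    mad = fit_mad(vbar, family=mad_family)
    zeta = 1 if model == "md" else 2
    if debias:
        pts = debiased_taylor_points(table, zeta=zeta, min_occupancy=min_occupancy)
    else:
        pts = taylor_points(table, min_occupancy=min_occupancy)
    tl = fit_taylor(pts, fixed_zeta=zeta)
    A = tl.A_fixed
    if debias and zeta == 2:
        # log-fluctuation inversion is far more robust than the regression
        # amplitude when a dominant species drives the community total
        A = estimate_amplitude(table)
    gamma = int((table.counts.sum(axis=1) > 0).sum())
    spec = ModelSpec(
        model=model,
        mu=None if model == "mssd" else mad.mu,
        lam=mad.lam,
        A=A,
        S=gamma,
        depths=table.depths.copy(),
        mad_family=mad.family if mad.family in ("log_laplace", "log_normal") else "log_laplace",
    )
    return spec, mad, tl
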