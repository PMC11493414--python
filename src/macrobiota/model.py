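"""Model/Results front end tying fitting, simulation and scoring together.

Usage mirrors the fit-then-inspect style of statistical modelling packages::

    model = CompositionalEcologyModel(table, model="mssd")
    res = model.fit(seed=0)
    print(res.summary())
    sims = res.simulate(n_realizations=5, seed=1)
    report = res.compare(n_realizations=20, seed=2)

The Results object carries the fitted parameters (mu, lambda, A and the
implied environmental-noise width sigma), their bootstrap standard errors,
the family-selection diagnostics, and hangs simulation, model comparison and
the two diagnostic plots off itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .comparison import ScoreReport, compare_models
from .generative import ModelSpec, sample_model, sigma_from_A
from .inference import (
    MADFit,
    TaylorFit,
    _amplitude_from_arrays,
    bootstrap_se,
    debiased_taylor_points,
    fit_mad,
    fit_model,
    fit_taylor,
)
from .patterns import mean_abundance, taylor_points
from .table import AbundanceTable

__all__ = ["CompositionalEcologyModel", "EcologyFitResults"]


class CompositionalEcologyModel:
    """A constrained compositional generative model bound to a count table.

    Parameters
    ----------
    table
        The species x sample count table the model is fitted to.
    model
        One of ``"mssd"`` (Symmetric Scaled Dirichlet + multinomial,
        Taylor exponent 2), ``"pslg"`` (independent Gammas + Poisson,
        exponent 2) or ``"md"`` (Dirichlet + multinomial, exponent 1).
    min_occupancy
        Occupancy threshold for the species entering the Taylor's-law fit.
    mad_family
        ``"auto"`` (BIC selection), ``"log_laplace"`` or ``"log_normal"``.
    """

    def __init__(
        self,
        table: AbundanceTable,
        model: str = "mssd",
        min_occupancy: float = 0.5,
        mad_family: str = "auto",
    ) -> None:
        self.table = table
        self.model_name = model.lower()
        self.min_occupancy = min_occupancy
        self.mad_family = mad_family

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, cohort=None, **kwargs) -> "CompositionalEcologyModel":
        """Build from a species-indexed DataFrame with samples as columns."""
        return cls(AbundanceTable.from_dataframe(df, cohort=cohort), **kwargs)

    def fit(self, bootstrap: bool = True, n_boot: int = 200, seed=None) -> "EcologyFitResults":
        """Fit (mu, lambda, A) at kappa = 0 and return a results object."""
        spec, mad, tl = fit_model(
            self.table, self.model_name, min_occupancy=self.min_occupancy, mad_family=self.mad_family
        )
        bse = {}
        if bootstrap:
            rng = np.random.default_rng(seed)
            vbar = mean_abundance(self.table)
            bse["lam"] = bootstrap_se(
                lambda d: fit_mad(d, family=mad.family).lam, vbar[vbar > 0], max(n_boot, 100), rng
            )
            if spec.zeta == 2:
                # resample species and re-run the log-fluctuation inversion
                n_boot = max(n_boot, 100)
                S = self.table.n_species
                vals = []
                for _ in range(n_boot):
                    idx = rng.integers(0, S, S)
                    a = _amplitude_from_arrays(self.table.counts[idx], self.table.depths)
                    if a is not None:
                        vals.append(a)
                if len(vals) < 0.9 * n_boot:
                    raise RuntimeError("amplitude estimator failed on >10% of bootstrap resamples")
                bse["A"] = float(np.std(vals, ddof=1))
            else:
                m, s2 = debiased_taylor_points(
                    self.table, zeta=spec.zeta, min_occupancy=self.min_occupancy
                )
                pts = np.column_stack([m, s2])
                bse["A"] = bootstrap_se(
                    lambda d: fit_taylor((d[:, 0], d[:, 1]), fixed_zeta=spec.zeta).A_fixed,
                    pts,
                    max(n_boot, 100),
                    rng,
                )
        return EcologyFitResults(self, spec, mad, tl, bse)


class EcologyFitResults:
    """Fitted parameters, uncertainties and diagnostics of one model fit."""

    def __init__(
        self,
        model: CompositionalEcologyModel,
        spec: ModelSpec,
        mad_fit: MADFit,
        taylor_fit: TaylorFit,
        bse: dict,
    ) -> None:
        self.model = model
        self.spec = spec
        self.mad_fit = mad_fit
        self.taylor_fit = taylor_fit
        self._bse = dict(bse)

    # ------------------------------------------------------------------
    @property
    def params(self) -> pd.Series:
        vals = {
            "mu": self.spec.mu if "mu" in self.spec.free_parameters else np.nan,
            "lam": self.spec.lam,
            "A": self.spec.A,
            "sigma": sigma_from_A(self.spec.A),
            "zeta": float(self.spec.zeta),
        }
        return pd.Series(vals, name=self.spec.model)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            {k: self._bse.get(k, np.nan) for k in ("lam", "A")}, name=f"{self.spec.model}_se"
        )

    @property
    def sigma(self) -> float:
        """Environmental-noise width implied by the Taylor amplitude."""
        return sigma_from_A(self.spec.A)

    # ------------------------------------------------------------------
    def summary(self) -> str:
        p, se = self.params, self.bse
        mad, tl = self.mad_fit, self.taylor_fit
        free = ", ".join(self.spec.free_parameters)
        lines = [
            "Compositional ecology model fit",
            "=" * 46,
            f"model:            {self.spec.model.upper()}  (zeta = {self.spec.zeta})",
            f"table:            S = {self.model.table.n_species}, R = {self.model.table.n_samples}"
            f", gamma = {self.spec.S}",
            f"free parameters:  {free}  ({len(self.spec.free_parameters)})",
            "-" * 46,
            f"MAD family:       {mad.family}  (BIC ratio LN/LL = {mad.bic_ratio:.3f})",
        ]
        if "mu" in self.spec.free_parameters:
            lines.append(f"mu (MAD location) {p['mu']:12.4f}")
        lines += [
            f"lambda (MAD scale){p['lam']:12.4f}  +/- {se['lam']:.4f}"
            if np.isfinite(se["lam"])
            else f"lambda (MAD scale){p['lam']:12.4f}",
            f"A (TL amplitude)  {p['A']:12.4f}  +/- {se['A']:.4f}"
            if np.isfinite(se["A"])
            else f"A (TL amplitude)  {p['A']:12.4f}",
            f"sigma (noise)     {p['sigma']:12.4f}  ({'> 1: dysbiotic-like' if p['sigma'] > 1 else '< 1: healthy-like'})",
            "-" * 46,
            f"TL free exponent  {tl.zeta:12.4f}  (R2 free {tl.r2_free:.4f})",
            f"TL fixed exponent {tl.zeta_fixed:12.4f}  (R2 fixed {tl.r2_fixed:.4f}, ratio {tl.ratio:.4f})",
            f"TL species used   {tl.n:12d}",
            f"MAD species used  {mad.n:12d}  ({mad.n_excluded_zeros} zero excluded)",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """Structured record of the fit (serialises to JSON)."""
        return {
            "model": self.spec.model,
            "zeta": self.spec.zeta,
            "free_parameters": list(self.spec.free_parameters),
            "params": {k: (None if not np.isfinite(v) else float(v)) for k, v in self.params.items()},
            "bse": {k: (None if not np.isfinite(v) else float(v)) for k, v in self.bse.items()},
            "mad": {
                "family": self.mad_fit.family,
                "mu": self.mad_fit.mu,
                "lam": self.mad_fit.lam,
                "bic_log_laplace": self.mad_fit.bic_log_laplace,
                "bic_log_normal": self.mad_fit.bic_log_normal,
                "bic_ratio": self.mad_fit.bic_ratio,
                "delta_bic": self.mad_fit.delta_bic,
                "n": self.mad_fit.n,
                "n_excluded_zeros": self.mad_fit.n_excluded_zeros,
            },
            "taylor": {
                "zeta_free": self.taylor_fit.zeta,
                "A_free": self.taylor_fit.A,
                "zeta_fixed": self.taylor_fit.zeta_fixed,
                "A_fixed": self.taylor_fit.A_fixed,
                "r2_free": self.taylor_fit.r2_free,
                "r2_fixed": self.taylor_fit.r2_fixed,
                "ratio": self.taylor_fit.ratio,
                "n": self.taylor_fit.n,
            },
        }

    # ------------------------------------------------------------------
    def simulate(self, n_realizations: int = 1, seed=None) -> list[AbundanceTable]:
        """Generate matched cohorts (same S = gamma, R and depths as the data)."""
        rng = np.random.default_rng(seed)
        return [sample_model(self.spec, seed=rng) for _ in range(n_realizations)]

    def compare(self, models=None, **kwargs) -> ScoreReport:
        """Score this (and optionally other) models against the fitted table."""
        models = models or (self.spec.model,)
        return compare_models(
            self.model.table,
            models=models,
            min_occupancy=self.model.min_occupancy,
            mad_family=self.model.mad_family,
            **kwargs,
        )

    # ------------------------------------------------------------------
    def plot_mad(self, ax=None, bins: int = 30):
        """Histogram of log mean abundances with the fitted MAD density."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        vbar = mean_abundance(self.model.table)
        y = np.log(vbar[vbar > 0])
        ax.hist(y, bins=bins, density=True, alpha=0.5, label="data")
        grid = np.linspace(y.min(), y.max(), 400)
        mu, lam = self.mad_fit.mu, self.mad_fit.lam
        if self.mad_fit.family == "log_laplace":
            dens = np.exp(-np.abs(grid - mu) / lam) / (2 * lam)
        else:
            dens = np.exp(-((grid - mu) ** 2) / (2 * lam**2)) / (lam * np.sqrt(2 * np.pi))
        ax.plot(grid, dens, label=f"{self.mad_fit.family} fit")
        ax.set_xlabel("log mean relative abundance")
        ax.set_ylabel("density")
        ax.legend()
        return ax

    def plot_taylor(self, ax=None):
        """Mean-variance scatter with the free and constrained power-law fits."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m, s2 = taylor_points(self.model.table, self.model.min_occupancy)
        ok = (m > 0) & (s2 > 0)
        ax.loglog(m[ok], s2[ok], ".", alpha=0.4, label="species")
        grid = np.geomspace(m[ok].min(), m[ok].max(), 50)
        tl = self.taylor_fit
        ax.loglog(grid, tl.A * grid**tl.zeta, "-", label=f"free: zeta={tl.zeta:.2f}")
        ax.loglog(grid, tl.A_fixed * grid**tl.zeta_fixed, "--", label=f"fixed: zeta={tl.zeta_fixed:.0f}")
        ax.set_xlabel("mean relative abundance")
        ax.set_ylabel("variance of relative abundance")
        ax.legend()
        return ax
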