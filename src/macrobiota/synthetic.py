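"""Ground-truth synthetic cohorts emulating healthy and dysbiotic gut communities.

A cohort is generated by the MSSD pipeline: draw S mean abundances from a
heavy-tailed MAD (Log-Laplace by default, scale lambda ~ 1.41 as observed in
gut shotgun data), build Symmetric Scaled Dirichlet parameters with the
Taylor amplitude A = sigma/(2 - sigma), sample R compositions, and draw
multinomial read counts at per-sample depths.  The two shipped profiles
differ only in the environmental-noise width sigma: the healthy-like
community has sigma < 1 (modal abundance-fluctuation distribution, Gamma
shape > 1), the dysbiotic one sigma > 1 (zero-diverging fluctuations,
Gamma shape < 1, more local extinctions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .generative import A_from_sigma, ModelSpec, draw_mad, sample_mssd
from .table import AbundanceTable

__all__ = ["CohortProfile", "healthy_profile", "unhealthy_profile", "generate_cohort", "paired_cohorts"]


@dataclass(frozen=True)
class CohortProfile:
    """Ground-truth recipe for one synthetic cohort."""

    label: str
    S: int = 500
    R: int = 91
    mad_family: str = "log_laplace"
    mu: float = -9.0
    lam: float = 1.41
    sigma: float = 0.8
    depth_range: tuple[float, float] = (1e5, 1e6)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.sigma < 2:
            raise ValueError("sigma must lie in (0, 2)")
        if not self.lam > 0:
            raise ValueError("lam must be positive")
        if self.R < 2:
            raise ValueError("need at least 2 samples")
        if self.S < 10:
            raise ValueError("need at least 10 species")
        lo, hi = self.depth_range
        if not 0 < lo <= hi:
            raise ValueError("depth_range must be positive and ordered")

    @property
    def A(self) -> float:
        """Taylor amplitude implied by the noise width: A = sigma/(2 - sigma)."""
        return A_from_sigma(self.sigma)


def healthy_profile(**overrides) -> CohortProfile:
    """Healthy-like cohort: 91 samples, sigma = 0.8 < 1."""
    base = dict(label="H", S=500, R=91, sigma=0.8)
    base.update(overrides)
    return CohortProfile(**base)


def unhealthy_profile(**overrides) -> CohortProfile:
    """Dysbiotic-like cohort: 202 samples, larger species pool, sigma = 1.2 > 1."""
    base = dict(label="U", S=800, R=202, sigma=1.2)
    base.update(overrides)
    return CohortProfile(**base)


def generate_cohort(
    profile: CohortProfile, seed=None, mean_abundances=None
) -> tuple[AbundanceTable, dict]:
    """Generate one cohort and return it with its exact ground-truth record.

    ``seed`` overrides ``profile.seed``; ``mean_abundances`` bypasses the MAD
    draw (used by :func:`paired_cohorts` for common-random-number pairing).
    The record carries everything a recovery test needs: the drawn depths,
    the generating (mu, lam, sigma, A) and the model specification used.
    """
    if seed is None:
        seed = profile.seed
    rng = np.random.default_rng(seed)
    lo, hi = profile.depth_range
    depths = np.exp(rng.uniform(np.log(lo), np.log(hi), profile.R)).astype(np.int64)
    spec = ModelSpec(
        model="mssd",
        mu=profile.mu,
        lam=profile.lam,
        A=profile.A,
        S=profile.S,
        depths=depths,
        mad_family=profile.mad_family,
    )
    table = sample_mssd(spec, seed=rng, mean_abundances=mean_abundances)
    table.cohort = np.array([profile.label] * profile.R, dtype=object)
    table.sample_ids = [f"{profile.label}{j + 1:04d}" for j in range(profile.R)]
    truth = {
        "label": profile.label,
        "model": "mssd",
        "S": profile.S,
        "R": profile.R,
        "mad_family": profile.mad_family,
        "mu": profile.mu,
        "lam": profile.lam,
        "sigma": profile.sigma,
        "A": profile.A,
        "depths": depths.tolist(),
        "seed": int(seed) if isinstance(seed, (int, np.integer)) else None,
    }
    return table, truth


def paired_cohorts(
    seed=None,
    healthy: CohortProfile | None = None,
    unhealthy: CohortProfile | None = None,
    share_mad: bool = True,
) -> tuple[AbundanceTable, AbundanceTable, dict]:
    """A healthy/dysbiotic cohort pair sharing lambda and depth distribution.

    The two cohorts differ only in sigma (0.8 vs 1.2 by default) plus pool
    size and sample number; returns ``(healthy, unhealthy, truths)``.

    With ``share_mad`` (default) the two cohorts draw their mean abundances
    from one common random stream — the smaller species pool is a prefix of
    the larger — so that the sigma contrast is not drowned by the huge
    across-realization variability of the heavy-tailed MAD (common random
    numbers).
    """
    h = healthy or healthy_profile()
    u = unhealthy or unhealthy_profile(lam=h.lam, mu=h.mu, depth_range=h.depth_range)
    ss = np.random.SeedSequence(0 if seed is None else seed)
    kids = ss.spawn(3)
    shared = None
    if share_mad:
        if (h.mad_family, h.mu, h.lam) != (u.mad_family, u.mu, u.lam):
            raise ValueError("share_mad requires the two profiles to share their MAD")
        shared = draw_mad(
            h.mu, h.lam, max(h.S, u.S), h.mad_family, np.random.default_rng(kids[2])
        )
    th, rec_h = generate_cohort(
        h, seed=np.random.default_rng(kids[0]), mean_abundances=None if shared is None else shared[: h.S]
    )
    tu, rec_u = generate_cohort(
        u, seed=np.random.default_rng(kids[1]), mean_abundances=None if shared is None else shared[: u.S]
    )
    return th, tu, {"H": rec_h, "U": rec_u}
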