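"""Stationary-Gamma maps, scaled-Dirichlet density/sampler, count samplers, SDE."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

import macrobiota as mb
from macrobiota.generative import draw_mad


# ----------------------------------------------------------------------
# parameter maps
# ----------------------------------------------------------------------
@pytest.mark.parametrize(
    "K, sigma, alpha, beta",
    [(1.0, 1.0, 1.0, 2.0), (10.0, 2.0 / 3.0, 2.0, 0.3)],
)
def test_gamma_from_slm_closed_form(K, sigma, alpha, beta):
    g = mb.gamma_from_slm(mb.SLMParams(K=K, sigma=sigma))
    assert g.alpha[0] == pytest.approx(alpha)
    assert g.beta[0] == pytest.approx(beta)


def test_gamma_from_slm_moments_match_sampling():
    """Monte-Carlo mean of the stationary Gamma equals K(1 - sigma/2)."""
    K, sigma = 5.0, 0.8
    g = mb.gamma_from_slm(mb.SLMParams(K=K, sigma=sigma))
    draws = np.random.default_rng(0).gamma(g.alpha[0], 1 / g.beta[0], 1_000_000)
    assert draws.mean() == pytest.approx(K * (1 - sigma / 2), rel=3e-3)  # = 3.0
    assert draws.var() == pytest.approx(K**2 * (sigma / 2) * (1 - sigma / 2), rel=2e-2)


@pytest.mark.parametrize("sigma", [2.0, 0.0, -0.5, 2.5])
def test_slm_params_rejects_sigma_outside_open_interval(sigma):
    with pytest.raises(ValueError):
        mb.SLMParams(K=1.0, sigma=sigma)


@given(
    K=st.floats(0.001, 100.0),
    sigma=st.floats(0.05, 1.95),
)
@settings(max_examples=50, derandomize=True)
def test_gamma_slm_roundtrip_is_identity(K, sigma):
    p = mb.SLMParams(K=K, sigma=sigma)
    back = mb.slm_from_gamma(mb.gamma_from_slm(p))
    assert back.K[0] == pytest.approx(K, rel=1e-10)
    assert back.sigma[0] == pytest.approx(sigma, rel=1e-10)


def test_params_from_taylor_zeta2_equal_shapes():
    xbar = np.array([1e-4, 3e-3, 0.2])
    g = mb.params_from_taylor(xbar, A=0.5, zeta=2)
    # all shapes collapse to 1/A and means are preserved
    assert np.allclose(g.alpha, 2.0)
    assert np.allclose(g.mean, xbar)
    assert np.allclose(g.variance, 0.5 * xbar**2)


def test_params_from_taylor_point_values():
    g2 = mb.params_from_taylor([0.01], A=0.5, zeta=2)
    assert (g2.alpha[0], g2.beta[0]) == (pytest.approx(2.0), pytest.approx(200.0))
    g1 = mb.params_from_taylor([0.01], A=0.01, zeta=1)
    assert g1.alpha[0] == pytest.approx(1.0)
    # zeta = 1: rates are a constant that cancels from the Dirichlet
    gh = mb.params_from_taylor([0.01, 0.5], A=0.01, zeta=1)
    assert gh.beta[0] == gh.beta[1]


def test_params_from_taylor_rejects_nonpositive_means():
    with pytest.raises(ValueError):
        mb.params_from_taylor([0.1, 0.0], A=0.5, zeta=2)


def test_sigma_A_maps():
    assert mb.sigma_from_A(1.0) == pytest.approx(1.0)
    assert mb.sigma_from_A(1.0 / 3.0) == pytest.approx(0.5)
    assert mb.sigma_from_A(1e9) == pytest.approx(2.0, abs=1e-8)
    grid = np.linspace(0.01, 10, 50)
    vals = mb.sigma_from_A(grid)
    assert (np.diff(vals) > 0).all() and (vals > 0).all() and (vals < 2).all()
    assert mb.A_from_sigma(mb.sigma_from_A(0.7)) == pytest.approx(0.7)
    with pytest.raises(ValueError):
        mb.sigma_from_A(0.0)


# ----------------------------------------------------------------------
# scaled Dirichlet density and sampler
# ----------------------------------------------------------------------
def test_scaled_dirichlet_equal_rates_reduces_to_dirichlet():
    alpha = np.array([0.5, 2.0, 3.5])
    gp = mb.GammaParams(alpha=alpha, beta=np.full(3, 4.0))
    rng = np.random.default_rng(1)
    for _ in range(20):
        v = rng.dirichlet(np.ones(3))
        expected = stats.dirichlet(alpha).logpdf(v[:-1])
        assert mb.scaled_dirichlet_logpdf(v, gp) == pytest.approx(expected, abs=1e-10)


def test_scaled_dirichlet_rate_rescaling_invariance():
    gp = mb.GammaParams(alpha=[1.2, 0.7, 3.0], beta=[1.0, 5.0, 0.3])
    gp7 = mb.GammaParams(alpha=gp.alpha, beta=7.0 * gp.beta)
    v = np.array([0.2, 0.5, 0.3])
    assert mb.scaled_dirichlet_logpdf(v, gp) == pytest.approx(
        mb.scaled_dirichlet_logpdf(v, gp7), rel=1e-12
    )


def test_scaled_dirichlet_normalizes_on_two_simplex():
    gp = mb.GammaParams(alpha=[2.0, 3.0], beta=[1.0, 4.0])
    total, _ = integrate.quad(
        lambda x: np.exp(mb.scaled_dirichlet_logpdf(np.array([x, 1 - x]), gp)), 0, 1
    )
    assert total == pytest.approx(1.0, abs=1e-8)


def test_scaled_dirichlet_rejects_off_simplex():
    gp = mb.GammaParams(alpha=[1.0, 1.0], beta=[1.0, 1.0])
    with pytest.raises(ValueError):
        mb.scaled_dirichlet_logpdf(np.array([0.6, 0.6]), gp)


def test_sampler_rows_on_simplex():
    gp = mb.GammaParams(alpha=[0.3, 1.0, 5.0], beta=[1.0, 10.0, 0.1])
    comp = mb.sample_scaled_dirichlet(gp, 1000, seed=0)
    assert comp.shape == (1000, 3)
    assert np.abs(comp.sum(axis=1) - 1).max() < 1e-12
    assert (comp > 0).all()


def test_sampler_uniform_on_simplex_when_flat():
    """alpha = (1,1,1) with equal rates is uniform on the 2-simplex."""
    comp = mb.sample_scaled_dirichlet(
        mb.GammaParams(alpha=np.ones(3), beta=np.full(3, 2.0)), 100_000, seed=2
    )
    # marginal of v1 under the flat Dirichlet is Beta(1, 2)
    ks = stats.kstest(comp[:, 0], stats.beta(1, 2).cdf)
    assert ks.pvalue > 0.01


def _numeric_marginal_cdf_2d(gp, grid):
    pdf = np.exp([mb.scaled_dirichlet_logpdf(np.array([x, 1 - x]), gp) for x in grid])
    cdf = integrate.cumulative_trapezoid(pdf, grid, initial=0.0)
    return cdf / cdf[-1]


def test_sampler_matches_density_two_species():
    gp = mb.GammaParams(alpha=[2.0, 3.0], beta=[1.0, 4.0])
    v1 = mb.sample_scaled_dirichlet(gp, 100_000, seed=3)[:, 0]
    grid = np.linspace(1e-6, 1 - 1e-6, 4001)
    cdf = _numeric_marginal_cdf_2d(gp, grid)
    ks = np.abs(np.interp(np.sort(v1), grid, cdf) - np.arange(1, v1.size + 1) / v1.size).max()
    assert ks < 0.01


# ----------------------------------------------------------------------
# count-table samplers
# ----------------------------------------------------------------------
@pytest.mark.parametrize("model", ["md", "mssd"])
def test_multinomial_models_are_strictly_compositional(model):
    depths = np.array([1000, 5000, 20_000])
    spec = mb.ModelSpec(model=model, mu=-5.0, lam=1.0, A=0.5 if model == "mssd" else 0.05,
                        S=50, depths=depths)
    table = mb.sample_model(spec, seed=0)
    assert np.array_equal(table.counts.sum(axis=0), depths)


def test_pslg_compositional_only_on_average():
    """Column sums fluctuate like Poisson around the nominal depth.

    A tiny amplitude isolates the read-sampling fluctuations from the
    compositional ones, so the variance/mean ratio of column sums is ~1.
    """
    depths = np.full(600, 10_000)
    spec = mb.ModelSpec(model="pslg", mu=-5.0, lam=1.0, A=1e-4, S=80, depths=depths)
    table = mb.sample_pslg(spec, seed=1)
    sums = table.counts.sum(axis=0)
    assert sums.mean() == pytest.approx(10_000, rel=0.01)
    assert not np.array_equal(sums, depths)  # not exact
    assert 0.5 < sums.var(ddof=1) / sums.mean() < 2.0


def test_pslg_species_independent_before_sampling():
    spec = mb.ModelSpec(model="pslg", mu=-3.0, lam=0.5, A=0.5, S=10, depths=np.full(400, 50_000))
    table = mb.sample_pslg(spec, seed=2)
    v = table.counts / 50_000.0  # nominal depth, keeps columns independent
    corr = np.corrcoef(v)
    off = corr[np.triu_indices(10, k=1)]
    assert np.abs(off).max() < 0.2


def test_mssd_taylor_exponent_near_two(mssd_cohort):
    tl = mb.fit_taylor(mb.taylor_points(mssd_cohort))
    assert tl.zeta == pytest.approx(2.0, abs=0.2)


def test_md_taylor_exponent_near_one(md_cohort):
    tl = mb.fit_taylor(mb.taylor_points(md_cohort))
    assert tl.zeta == pytest.approx(1.0, abs=0.2)


def test_md_small_A_approaches_multinomial_variance():
    """As A -> 0 the Dirichlet concentration diverges and only read sampling remains."""
    xbar = np.array([0.5, 0.3, 0.15, 0.05])
    depths = np.full(3000, 2000)
    spec = mb.ModelSpec(model="md", mu=0.0, lam=1.0, A=1e-7, S=4, depths=depths)
    table = mb.sample_md(spec, seed=3, mean_abundances=xbar)
    v = table.relative_abundances()
    mean, var = v.mean(axis=1), v.var(axis=1, ddof=1)
    expected = mean * (1 - mean) / 2000
    assert np.allclose(var / expected, 1.0, atol=0.15)


def test_mssd_dispersion_shrinks_with_A():
    xbar = np.exp(np.random.default_rng(4).laplace(-5, 1.0, 100))
    depths = np.full(50, 100_000)
    spread = []
    for A in (2.0, 0.01):
        spec = mb.ModelSpec(model="mssd", lam=1.0, A=A, S=100, depths=depths)
        t = mb.sample_mssd(spec, seed=5, mean_abundances=xbar)
        m, s2 = mb.taylor_points(t, min_occupancy=1.0)
        spread.append(np.median(s2 / m**2))
    assert spread[1] < spread[0] / 10


def test_samplers_reproducible_under_seed():
    spec = mb.ModelSpec(model="mssd", lam=1.4, A=0.5, S=40, depths=np.full(10, 10_000))
    a = mb.sample_mssd(spec, seed=7)
    b = mb.sample_mssd(spec, seed=7)
    assert np.array_equal(a.counts, b.counts)


def test_draw_mad_families_match_theory():
    rng = np.random.default_rng(8)
    x = draw_mad(-9.0, 1.4, 200_000, "log_laplace", rng)
    y = np.log(x)
    assert np.median(y) == pytest.approx(-9.0, abs=0.02)
    assert np.abs(y + 9.0).mean() == pytest.approx(1.4, rel=0.02)
    x = draw_mad(-9.0, 1.4, 200_000, "log_normal", rng)
    assert np.log(x).std() == pytest.approx(1.4, rel=0.02)
    with pytest.raises(ValueError):
        draw_mad(0, 1, 10, "cauchy", rng)


# ----------------------------------------------------------------------
# SDE integration
# ----------------------------------------------------------------------
def test_slm_stationary_matches_analytic_gamma():
    """sigma=0.5, K=1: stationary law is Gamma(shape 3, rate 4)."""
    params = mb.SLMParams(K=np.full(300, 1.0), sigma=np.full(300, 0.5))
    _, traj = mb.simulate_slm(params, dt=0.005, t_max=80.0, seed=0, record_every=4000)
    samples = traj[2:].ravel()  # discard burn-in, keep decorrelated snapshots
    ks = stats.kstest(samples, stats.gamma(3.0, scale=1 / 4.0).cdf)
    assert ks.pvalue > 0.01


def test_slm_deterministic_logistic_limit():
    params = mb.SLMParams(K=2.0, sigma=1e-6, tau=1.0)
    _, traj = mb.simulate_slm(params, dt=0.01, t_max=30.0, x0=0.1, seed=1)
    assert traj[-1, 0] == pytest.approx(2.0, rel=1e-2)


def test_slm_time_average_matches_gamma_mean():
    params = mb.SLMParams(K=1.0, sigma=0.8, tau=1.0)
    _, traj = mb.simulate_slm(params, dt=0.005, t_max=4000.0, seed=2, record_every=20)
    assert traj[traj.shape[0] // 10 :].mean() == pytest.approx(1.0 * (1 - 0.4), rel=0.05)


def test_slm_rejects_coarse_dt():
    with pytest.raises(ValueError):
        mb.simulate_slm(mb.SLMParams(K=1.0, sigma=0.5, tau=1.0), dt=0.5, t_max=10.0)
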