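"""MAD fitting and family selection, Taylor fits, bootstrap, model fitting."""

import numpy as np
import pytest

import macrobiota as mb
from macrobiota.generative import draw_mad
from macrobiota.inference import debiased_taylor_points, estimate_amplitude


# ----------------------------------------------------------------------
# MAD
# ----------------------------------------------------------------------
def test_fit_mad_symmetric_two_level_data():
    """Values at e^-1 and e^1: Laplace MLE gives mu = 0, lambda = 1."""
    data = np.array([np.e**-1, np.e] * 5)
    fit = mb.fit_mad(data, family="log_laplace")
    assert fit.mu == pytest.approx(0.0)
    assert fit.lam == pytest.approx(1.0)


def test_fit_mad_recovers_log_laplace_scale():
    x = draw_mad(-9.0, 1.0, 100_000, "log_laplace", seed=0)
    fit = mb.fit_mad(x, family="log_laplace")
    assert fit.lam == pytest.approx(1.0, abs=0.01)
    assert fit.mu == pytest.approx(-9.0, abs=0.02)


@pytest.mark.parametrize("lam_true", [1.407, 1.413])
def test_fit_mad_at_reported_gut_scales(lam_true):
    """Recovery at the lambda values reported for gut shotgun cohorts."""
    x = draw_mad(-9.0, lam_true, 10_000, "log_laplace", seed=1)
    fit = mb.fit_mad(x, family="log_laplace")
    assert fit.lam == pytest.approx(lam_true, abs=0.05)


def test_fit_mad_excludes_zeros_and_counts_them():
    x = np.concatenate([draw_mad(-5, 1.0, 50, "log_laplace", seed=2), np.zeros(7)])
    fit = mb.fit_mad(x)
    assert fit.n == 50 and fit.n_excluded_zeros == 7


def test_fit_mad_requires_enough_positive_values():
    with pytest.raises(ValueError):
        mb.fit_mad(np.ones(5))
    with pytest.raises(ValueError):
        mb.fit_mad(-np.ones(20))


def test_mad_scale_invariant_location_shifts():
    x = draw_mad(-9.0, 1.3, 5000, "log_laplace", seed=3)
    for family in ("log_laplace", "log_normal"):
        a, b = mb.fit_mad(x, family), mb.fit_mad(100.0 * x, family)
        assert b.lam == pytest.approx(a.lam, rel=1e-9)
        assert b.mu == pytest.approx(a.mu + np.log(100.0), rel=1e-9)


def test_bic_selects_generating_family():
    ll = draw_mad(-9, 1.4, 20_000, "log_laplace", seed=4)
    ln = draw_mad(-9, 1.4, 20_000, "log_normal", seed=5)
    fit_ll, fit_ln = mb.fit_mad(ll), mb.fit_mad(ln)
    assert fit_ll.family == "log_laplace" and fit_ll.bic_ratio > 1 and fit_ll.delta_bic < 0
    assert fit_ln.family == "log_normal" and fit_ln.bic_ratio < 1 and fit_ln.delta_bic > 0


def test_bic_ratio_orientation_and_sign_guard():
    assert mb.bic_ratio(100.0, 100.0) == 1.0
    assert mb.bic_ratio(100.0, 120.0) > 1  # Log-Laplace preferred
    with pytest.raises(ValueError, match="delta_bic"):
        mb.bic_ratio(-5.0, 5.0)


# ----------------------------------------------------------------------
# Taylor's law
# ----------------------------------------------------------------------
def test_fit_taylor_exact_quadratic_points():
    m = np.geomspace(1e-6, 1e-2, 30)
    fit = mb.fit_taylor((m, 0.5 * m**2))
    assert fit.zeta == pytest.approx(2.0, abs=1e-9)
    assert fit.A == pytest.approx(0.5, rel=1e-9)
    assert fit.A_fixed == pytest.approx(0.5, rel=1e-9)
    assert fit.r2_free == pytest.approx(1.0, abs=1e-9)
    assert fit.ratio == pytest.approx(1.0, abs=1e-9)


def test_fit_taylor_exact_linear_points():
    m = np.geomspace(1e-6, 1e-2, 30)
    fit = mb.fit_taylor((m, m), fixed_zeta=1)
    assert fit.zeta == pytest.approx(1.0, abs=1e-9)
    assert fit.A_fixed == pytest.approx(1.0, rel=1e-9)


def test_fit_taylor_rejects_degenerate_input():
    with pytest.raises(ValueError):
        mb.fit_taylor((np.full(30, 1e-3), np.full(30, 1e-7)))
    with pytest.raises(ValueError):
        mb.fit_taylor(([1e-3], [1e-7]))


def test_taylor_recovery_on_mssd_cohort(mssd_cohort):
    """Sampling-corrected points recover the exponent and amplitude (truth A=0.5)."""
    pts = debiased_taylor_points(mssd_cohort, zeta=2)
    fit = mb.fit_taylor(pts)
    assert fit.zeta == pytest.approx(2.0, abs=0.1)
    assert estimate_amplitude(mssd_cohort) == pytest.approx(0.5, rel=0.2)


# ----------------------------------------------------------------------
# bootstrap
# ----------------------------------------------------------------------
def test_bootstrap_se_constant_data_is_zero():
    assert mb.bootstrap_se(np.mean, np.full(50, 3.0), 200, seed=0) == 0.0


def test_bootstrap_se_scales_like_inverse_sqrt_n():
    rng = np.random.default_rng(1)
    sizes = [100, 1000, 10_000]
    ses = [mb.bootstrap_se(np.mean, rng.normal(0, 1, n), 300, seed=2) for n in sizes]
    slope = np.polyfit(np.log(sizes), np.log(ses), 1)[0]
    assert slope == pytest.approx(-0.5, abs=0.1)


def test_bootstrap_se_reproducible_and_guarded():
    data = np.random.default_rng(3).normal(size=200)
    a = mb.bootstrap_se(np.std, data, 150, seed=9)
    b = mb.bootstrap_se(np.std, data, 150, seed=9)
    assert a == b
    with pytest.raises(ValueError):
        mb.bootstrap_se(np.mean, data, 50, seed=0)

    def flaky(_):
        raise RuntimeError("nope")

    with pytest.raises(RuntimeError):
        mb.bootstrap_se(flaky, data, 100, seed=0)


# ----------------------------------------------------------------------
# model fitting
# ----------------------------------------------------------------------
def test_mssd_has_exactly_two_free_parameters(mssd_cohort):
    spec, _, _ = mb.fit_model(mssd_cohort, "mssd")
    assert spec.free_parameters == ("lam", "A")
    assert len(spec.free_parameters) == 2


@pytest.mark.parametrize("model, n_free", [("md", 3), ("pslg", 3)])
def test_three_parameter_models(mssd_cohort, model, n_free):
    spec, _, _ = mb.fit_model(mssd_cohort, model)
    assert len(spec.free_parameters) == n_free
    assert spec.zeta == (1 if model == "md" else 2)


def test_fit_model_roundtrip_recovery():
    """Median recovery of (lambda, A) from MSSD cohorts at S=500, R=200."""
    lam_hat, A_hat = [], []
    for seed in range(5):
        table, truth = mb.generate_cohort(
            mb.CohortProfile(label="T", S=500, R=200, sigma=0.8), seed=seed
        )
        spec, mad, _ = mb.fit_model(table, "mssd")
        lam_hat.append(mad.lam / truth["lam"])
        A_hat.append(spec.A / truth["A"])
    assert np.median(lam_hat) == pytest.approx(1.0, abs=0.05)
    assert np.median(A_hat) == pytest.approx(1.0, abs=0.2)


def test_sigma_reported_alongside_A(mssd_cohort):
    res = mb.CompositionalEcologyModel(mssd_cohort, model="mssd").fit(bootstrap=False)
    assert res.params["sigma"] == pytest.approx(mb.sigma_from_A(res.params["A"]))
    # the health/dysbiosis discriminator: A > 1 exactly when sigma > 1
    for A in (0.2, 0.99, 1.01, 5.0):
        assert (A > 1) == (mb.sigma_from_A(A) > 1)


def test_fit_model_uses_gamma_for_species_pool(toy_table):
    with pytest.raises(ValueError):
        mb.fit_model(toy_table.select_samples(np.array([0])), "mssd")
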