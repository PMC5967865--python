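import numpy as np
import pytest
from scipy.optimize import curve_fit

from sybodykit import binding
from sybodykit.binding import (
    DoseResponse,
    InhibitionParams,
    KineticParams,
    MeltCurve,
    MeltParams,
    SchildParams,
    boltzmann,
    delta_tm,
    fit_1to1,
    fit_inhibition,
    fit_melt,
    fit_schild,
    inhibition_curve,
    kd_from_rates,
    round_sig,
    schild_ratio,
    simulate_sensorgram,
)


# -- basics -----------------------------------------------------------------------


def test_kd_from_rates_and_round_sig():
    assert kd_from_rates(1e5, 1e-3) == pytest.approx(1e-8)
    assert round_sig(4.004e-8) == 4.00e-8
    assert round_sig(58.8235, 3) == 58.8
    with pytest.raises(ValueError):
        kd_from_rates(0.0, 1e-3)
    with pytest.raises(ValueError):
        kd_from_rates(1e5, -1.0)


def test_parameter_validation():
    with pytest.raises(ValueError):
        SchildParams(B=1e-6, alpha=0.0)
    with pytest.raises(ValueError):
        SchildParams(B=1e-6, alpha=1.5)
    with pytest.raises(ValueError):
        InhibitionParams(y0=0.0, a=1.0, ic50=0.0)
    with pytest.raises(ValueError):
        MeltParams(bottom=10.0, top=5.0, tm=40.0, slope=-1.0)


# -- 1:1 kinetics -----------------------------------------------------------------


KIN = KineticParams(kon=2.0e5, koff=5.0e-3, rmax=120.0)


def test_sensorgram_zero_concentration_is_flat():
    g = simulate_sensorgram(KIN, 0.0)
    assert np.all(g.responses == 0.0)


def test_sensorgram_plateau_matches_isotherm():
    c = 4 * KIN.kd
    g = simulate_sensorgram(KIN, c, t_assoc=20000.0, t_dissoc=0.0, dt=100.0)
    req = KIN.rmax * c / (c + KIN.kd)
    assert g.responses[-1] == pytest.approx(req, rel=1e-10)


def test_sensorgram_continuous_at_phase_boundary():
    g = simulate_sensorgram(KIN, KIN.kd, t_assoc=120.0, t_dissoc=10.0, dt=0.01)
    i = int(np.searchsorted(g.times, 120.0))
    assert abs(g.responses[i + 1] - g.responses[i - 1]) < 0.05


def test_fit_1to1_noiseless_recovery():
    grams = [simulate_sensorgram(KIN, f * KIN.kd) for f in (0.2, 1.0, 5.0)]
    params, fit = fit_1to1(grams)
    assert fit.converged
    assert params.kon == pytest.approx(KIN.kon, rel=1e-6)
    assert params.koff == pytest.approx(KIN.koff, rel=1e-6)
    assert params.rmax == pytest.approx(KIN.rmax, rel=1e-6)


def test_fit_1to1_flat_data_flagged():
    grams = [simulate_sensorgram(KIN, 0.0)]
    params, fit = fit_1to1(grams)
    assert not fit.converged


# -- Schild-type competition -------------------------------------------------------


def test_schild_ratio_properties():
    p = SchildParams(B=1.0e-6, alpha=0.017)
    assert schild_ratio(0.0, p) == 1.0
    assert schild_ratio(p.B, p) == pytest.approx(2.0 / (1.0 + p.alpha))
    # saturation at 1/alpha for x >> B
    assert schild_ratio(1.0, p) == pytest.approx(1.0 / p.alpha, rel=1e-3)
    assert p.saturating_ratio == pytest.approx(58.8235, rel=1e-4)


def test_fit_schild_noiseless_recovery():
    p = SchildParams(B=1.0e-6, alpha=0.017)
    x = np.array([0.0, 5e-6, 1e-5, 2.5e-5, 5e-5, 1e-4])
    params, fit = fit_schild(x, schild_ratio(x, p))
    assert fit.converged
    assert params.B == pytest.approx(p.B, rel=1e-6)
    assert params.alpha == pytest.approx(p.alpha, rel=1e-6)


def test_fit_schild_flat_ratio_means_no_competition():
    x = np.array([0.0, 1e-6, 1e-5, 1e-4])
    params, fit = fit_schild(x, np.ones_like(x))
    assert fit.converged
    assert params.alpha == pytest.approx(1.0, abs=0.05)


# -- hyperbolic inhibition ---------------------------------------------------------


def test_inhibition_curve_properties():
    p = InhibitionParams(y0=20.0, a=80.0, ic50=62e-9)
    assert inhibition_curve(0.0, p) == pytest.approx(100.0)
    assert inhibition_curve(p.ic50, p) == pytest.approx(p.y0 + p.a / 2)
    assert inhibition_curve(1.0, p) == pytest.approx(p.y0, rel=1e-4)


def test_fit_inhibition_noiseless_recovery():
    p = InhibitionParams(y0=20.0, a=80.0, ic50=62e-9)
    x = np.array([0.0, 1e-9, 3e-9, 9e-9, 27e-9, 81e-9, 243e-9, 729e-9])
    params, fit = fit_inhibition(DoseResponse(x=x, y=inhibition_curve(x, p)))
    assert fit.converged
    assert params.ic50 == pytest.approx(p.ic50, rel=1e-6)
    assert params.y0 == pytest.approx(p.y0, rel=1e-6)


def test_fit_inhibition_agrees_with_curve_fit_oracle():
    # independent optimizer on the same noisy data must reach the same minimum
    p = InhibitionParams(y0=20.0, a=80.0, ic50=62e-9)
    x = np.array([0.0, 1e-9, 3e-9, 9e-9, 27e-9, 81e-9, 243e-9, 729e-9])
    rng = np.random.default_rng(12)
    y = np.asarray(inhibition_curve(x, p)) + rng.normal(0, 1.0, size=x.shape)
    params, fit = fit_inhibition(DoseResponse(x=x, y=y))

    def model(x, y0, a, ic50):
        return y0 + a * ic50 / (ic50 + x)

    popt, _ = curve_fit(model, x, y, p0=[15.0, 90.0, 1e-7], maxfev=10000)
    ours = model(x, params.y0, params.a, params.ic50)
    theirs = model(x, *popt)
    # same minimum up to optimizer stopping tolerances
    np.testing.assert_allclose(ours, theirs, rtol=2e-3)
    assert np.linalg.norm(y - ours) == pytest.approx(np.linalg.norm(y - theirs), rel=1e-3)


# -- Boltzmann melt ----------------------------------------------------------------


MELT = MeltParams(bottom=100.0, top=1000.0, tm=42.0, slope=-1.5)


def test_boltzmann_midpoint():
    assert boltzmann(MELT.tm, MELT) == pytest.approx((MELT.bottom + MELT.top) / 2)


def test_fit_melt_noiseless_recovery():
    t = np.linspace(30.0, 60.0, 16)
    params, fit = fit_melt(MeltCurve(temperatures=t, signals=boltzmann(t, MELT)))
    assert fit.converged
    assert params.tm == pytest.approx(MELT.tm, rel=1e-6)
    assert params.slope == pytest.approx(MELT.slope, rel=1e-6)
    assert params.bottom == pytest.approx(MELT.bottom, rel=1e-6)
    assert params.top == pytest.approx(MELT.top, rel=1e-6)


def test_fit_melt_rising_curve():
    rising = MeltParams(bottom=0.0, top=1.0, tm=45.0, slope=2.0)
    t = np.linspace(30.0, 60.0, 16)
    params, fit = fit_melt(MeltCurve(temperatures=t, signals=boltzmann(t, rising)))
    assert fit.converged
    assert params.tm == pytest.approx(45.0, rel=1e-6)


def test_fit_melt_flat_curve_flagged():
    t = np.linspace(30.0, 60.0, 16)
    params, fit = fit_melt(MeltCurve(temperatures=t, signals=np.full_like(t, 5.0)))
    assert not fit.converged


def test_delta_tm():
    apo = MeltParams(bottom=100.0, top=1000.0, tm=42.0, slope=-1.5)
    bound = MeltParams(bottom=100.0, top=1000.0, tm=48.1, slope=-1.5)
    assert delta_tm(bound, apo) == pytest.approx(6.1)
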