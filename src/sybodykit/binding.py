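"""Binding and stability models: 1:1 SPR kinetics, Schild competition, IC50, melting.

Four quantitative models characterize selected sybodies:

* 1:1 Langmuir interaction for SPR sensorgrams.  During association at analyte
  concentration C the response follows
  ``R(t) = Rmax * C/(C + KD) * (1 - exp(-(kon*C + koff) t))`` and during
  dissociation ``R(t) = R_end * exp(-koff * (t - t_assoc))``, with
  ``KD = koff/kon``.
* Schild-type allosteric competition: the affinity ratio of a binder measured
  in the presence (KD') and absence (KD) of a competitor at concentration x is
  ``y = (x/B + 1) / (alpha*x/B + 1)`` where B is the competitor's own KD and
  alpha the allosteric constant; the ratio saturates at 1/alpha.
* Hyperbolic inhibition of enzymatic activity,
  ``y = y0 + a * IC50 / (IC50 + x)``: 100% activity at x=0 decays to the
  residual y0, with half-maximal inhibition at x = IC50.
* Boltzmann sigmoidal melting,
  ``S(T) = bottom + (top - bottom) / (1 + exp((Tm - T)/slope))``: the apparent
  melting temperature Tm is the inflection; a binder-induced stabilization is
  reported as delta-Tm between two fits.

All fitters use bounded nonlinear least squares (lmfit) with documented
initialization heuristics, return parameter standard errors, and flag rather
than hide non-convergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import lmfit
import numpy as np

__all__ = [
    "KineticParams",
    "SchildParams",
    "InhibitionParams",
    "MeltParams",
    "Sensorgram",
    "MeltCurve",
    "DoseResponse",
    "FitResult",
    "kd_from_rates",
    "round_sig",
    "simulate_sensorgram",
    "fit_1to1",
    "schild_ratio",
    "fit_schild",
    "inhibition_curve",
    "fit_inhibition",
    "boltzmann",
    "fit_melt",
    "delta_tm",
]


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (reporting convention for rate tables)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def kd_from_rates(kon: float, koff: float) -> float:
    """Equilibrium dissociation constant KD = koff / kon [M]."""
    if kon <= 0 or koff <= 0:
        raise ValueError("rate constants must be positive")
    return koff / kon


@dataclass(frozen=True)
class KineticParams:
    """1:1 interaction parameters: kon [1/(M s)], koff [1/s], Rmax [RU]."""

    kon: float
    koff: float
    rmax: float = 100.0

    def __post_init__(self) -> None:
        if self.kon <= 0 or self.koff <= 0 or self.rmax <= 0:
            raise ValueError("kinetic parameters must be positive")

    @property
    def kd(self) -> float:
        return self.koff / self.kon


@dataclass(frozen=True)
class SchildParams:
    """Competitor affinity B [M] and allosteric constant alpha (0 < alpha <= 1)."""

    B: float
    alpha: float

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise ValueError("B must be positive")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")

    @property
    def saturating_ratio(self) -> float:
        return 1.0 / self.alpha


@dataclass(frozen=True)
class InhibitionParams:
    """Residual activity y0 [%], inhibitable span a [%], IC50 [M]."""

    y0: float
    a: float
    ic50: float

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("IC50 must be positive")


@dataclass(frozen=True)
class MeltParams:
    """Boltzmann sigmoid: baseline signals and apparent melting temperature [degC]."""

    bottom: float
    top: float
    tm: float
    slope: float

    def __post_init__(self) -> None:
        if self.bottom >= self.top:
            raise ValueError("bottom must be below top")


@dataclass(frozen=True)
class FitResult:
    params: Mapping[str, float]
    stderr: Mapping[str, float | None]
    residual_norm: float
    converged: bool
    message: str = ""
    nfev: int = 0


@dataclass(frozen=True)
class Sensorgram:
    """Time-indexed SPR response at one analyte concentration.

    ``t_assoc`` ends the association phase; later times are dissociation.
    """

    times: np.ndarray
    responses: np.ndarray
    concentration: float
    t_assoc: float
    replicate: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        responses = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "responses", responses)
        if times.shape != responses.shape:
            raise ValueError("times and responses must have the same shape")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class MeltCurve:
    temperatures: np.ndarray
    signals: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "temperatures", np.asarray(self.temperatures, dtype=float))
        object.__setattr__(self, "signals", np.asarray(self.signals, dtype=float))


@dataclass(frozen=True)
class DoseResponse:
    x: np.ndarray
    y: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))


# -- 1:1 kinetics ---------------------------------------------------------------


def _one_to_one(
    t: np.ndarray, kon: float, koff: float, rmax: float, conc: float, t_assoc: float
) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if conc == 0:
        return np.zeros_like(t)
    kobs = kon * conc + koff
    req = rmax * conc / (conc + koff / kon)
    assoc = req * (1.0 - np.exp(-kobs * np.minimum(t, t_assoc)))
    r_end = req * (1.0 - np.exp(-kobs * t_assoc))
    dissoc = r_end * np.exp(-koff * np.maximum(t - t_assoc, 0.0))
    return np.where(t <= t_assoc, assoc, dissoc)


def simulate_sensorgram(
    params: KineticParams,
    concentration: float,
    t_assoc: float = 120.0,
    t_dissoc: float = 300.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Sensorgram:
    """Closed-form 1:1 sensorgram, optionally with additive Gaussian noise."""
    if concentration < 0:
        raise ValueError("analyte concentration must be >= 0")
    if t_assoc <= 0 or t_dissoc < 0:
        raise ValueError("phase durations must be positive")
    times = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    responses = _one_to_one(times, params.kon, params.koff, params.rmax, concentration, t_assoc)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        responses = responses + rng.normal(0.0, noise_sd, size=responses.shape)
    return Sensorgram(times=times, responses=responses, concentration=concentration, t_assoc=t_assoc)


def _failed_fit(message: str, names: Sequence[str]) -> FitResult:
    return FitResult(
        params={n: float("nan") for n in names},
        stderr={n: None for n in names},
        residual_norm=float("nan"),
        converged=False,
        message=message,
    )


def _result_from_lmfit(out: lmfit.minimizer.MinimizerResult, names: Sequence[str]) -> FitResult:
    params = {n: float(out.params[n].value) for n in names}
    stderr = {
        n: (float(out.params[n].stderr) if out.params[n].stderr is not None else None)
        for n in names
    }
    residual_norm = float(np.sqrt(np.sum(np.asarray(out.residual) ** 2)))
    return FitResult(
        params=params,
        stderr=stderr,
        residual_norm=residual_norm,
        converged=bool(out.success),
        message=str(out.message),
        nfev=int(out.nfev),
    )


def fit_1to1(grams: Sequence[Sensorgram]) -> tuple[KineticParams | None, FitResult]:
    """Global 1:1 fit of kon, koff, Rmax across sensorgrams at several concentrations.

    Initialization: Rmax and KD from an isotherm through the association
    plateaus, koff from the log-linear dissociation decay, kon = koff/KD.
    Degenerate input (flat or all-zero responses) returns a flagged,
    non-converged result instead of raising.
    """
    names = ("kon", "koff", "rmax")
    grams = [g for g in grams if g.concentration > 0]
    if not grams:
        return None, _failed_fit("no sensorgrams with nonzero analyte concentration", names)
    max_resp = max(float(np.max(np.abs(g.responses))) for g in grams)
    if max_resp <= 0 or all(float(np.std(g.responses)) < 1e-12 for g in grams):
        return None, _failed_fit("degenerate input: flat responses", names)

    koff0 = _koff_init(grams)
    kd0, rmax0 = _isotherm_init(grams)
    kon0 = koff0 / kd0

    p = lmfit.Parameters()
    p.add("kon", value=kon0, min=1.0, max=1e12)
    p.add("koff", value=koff0, min=1e-8, max=1e3)
    p.add("rmax", value=rmax0, min=max_resp * 0.5, max=max_resp * 100)

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        kon, koff, rmax = pars["kon"].value, pars["koff"].value, pars["rmax"].value
        res = [
            _one_to_one(g.times, kon, koff, rmax, g.concentration, g.t_assoc) - g.responses
            for g in grams
        ]
        return np.concatenate(res)

    out = lmfit.minimize(residual, p, method="least_squares")
    fit = _result_from_lmfit(out, names)
    if not fit.converged:
        return None, fit
    kin = KineticParams(kon=fit.params["kon"], koff=fit.params["koff"], rmax=fit.params["rmax"])
    return kin, fit


def _koff_init(grams: Sequence[Sensorgram]) -> float:
    rates = []
    for g in grams:
        mask = g.times > g.t_assoc
        t, r = g.times[mask], g.responses[mask]
        pos = r > max(1e-6, 0.01 * np.max(np.abs(g.responses)))
        if pos.sum() >= 3:
            slope = np.polyfit(t[pos], np.log(r[pos]), 1)[0]
            if slope < 0:
                rates.append(-slope)
    return float(np.median(rates)) if rates else 1e-2


def _isotherm_init(grams: Sequence[Sensorgram]) -> tuple[float, float]:
    concs = np.array([g.concentration for g in grams])
    plateaus = np.array(
        [float(np.max(g.responses[g.times <= g.t_assoc])) for g in grams]
    )
    rmax0 = float(plateaus.max()) * 1.5
    half = rmax0 / 2 / 1.5
    above = plateaus >= half
    kd0 = float(concs[np.argmin(np.abs(plateaus - half))]) if above.any() else float(concs.max())
    return max(kd0, 1e-12), max(rmax0, 1e-6)


# -- Schild competition -----------------------------------------------------------


def schild_ratio(x: float | np.ndarray, params: SchildParams) -> float | np.ndarray:
    """Affinity ratio KD'/KD at competitor concentration x.

    y(0) = 1, monotone nondecreasing, saturating at 1/alpha.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("competitor concentration must be >= 0")
    y = (x / params.B + 1.0) / (params.alpha * x / params.B + 1.0)
    return float(y) if y.ndim == 0 else y


def fit_schild(
    x: Sequence[float], ratios: Sequence[float]
) -> tuple[SchildParams | None, FitResult]:
    """Fit competitor affinity B and allosteric constant alpha to affinity ratios.

    Initialization: alpha from the reciprocal of the largest observed ratio,
    B from the concentration nearest the half-saturation ratio.
    """
    names = ("B", "alpha")
    x = np.asarray(x, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    if x.size < 3:
        return None, _failed_fit("need at least 3 competitor concentrations", names)

    alpha0 = min(1.0, 1.0 / max(float(ratios.max()), 1.0 + 1e-6))
    positive = x[x > 0]
    b0 = float(np.median(positive)) if positive.size else 1.0

    p = lmfit.Parameters()
    p.add("B", value=b0, min=1e-12, max=1e3)
    p.add("alpha", value=max(alpha0, 1e-6), min=1e-9, max=1.0)

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        sp = SchildParams(B=pars["B"].value, alpha=pars["alpha"].value)
        return schild_ratio(x, sp) - ratios

    out = lmfit.minimize(residual, p, method="least_squares")
    fit = _result_from_lmfit(out, names)
    if not fit.converged:
        return None, fit
    return SchildParams(B=fit.params["B"], alpha=fit.params["alpha"]), fit


# -- hyperbolic inhibition --------------------------------------------------------


def inhibition_curve(x: float | np.ndarray, params: InhibitionParams) -> float | np.ndarray:
    """Residual activity [%] at inhibitor concentration x: y = y0 + a*IC50/(IC50 + x)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("inhibitor concentration must be >= 0")
    y = params.y0 + params.a * params.ic50 / (params.ic50 + x)
    return float(y) if y.ndim == 0 else y


def fit_inhibition(data: DoseResponse) -> tuple[InhibitionParams | None, FitResult]:
    """Fit y0, a and IC50 to a dose-response table of residual activities.

    Initialization: y0 from the lowest observed activity, a from the span,
    IC50 from the concentration where activity crosses half the span.
    """
    names = ("y0", "a", "ic50")
    x, y = data.x, data.y
    if x.size < 4:
        return None, _failed_fit("need at least 4 dose-response points", names)
    y0_init = float(y.min())
    a_init = max(float(y.max() - y.min()), 1e-6)
    half = y0_init + a_init / 2
    positive = x[x > 0]
    ic50_init = float(positive[np.argmin(np.abs(y[x > 0] - half))]) if positive.size else 1.0

    p = lmfit.Parameters()
    p.add("y0", value=y0_init, min=-50.0, max=200.0)
    p.add("a", value=a_init, min=1e-9, max=500.0)
    p.add("ic50", value=max(ic50_init, 1e-15), min=1e-15, max=1.0)

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        ip = InhibitionParams(y0=pars["y0"].value, a=pars["a"].value, ic50=pars["ic50"].value)
        return inhibition_curve(x, ip) - y

    out = lmfit.minimize(residual, p, method="least_squares")
    fit = _result_from_lmfit(out, names)
    if not fit.converged:
        return None, fit
    return InhibitionParams(y0=fit.params["y0"], a=fit.params["a"], ic50=fit.params["ic50"]), fit


# -- Boltzmann melting -------------------------------------------------------------


def boltzmann(T: float | np.ndarray, params: MeltParams) -> float | np.ndarray:
    """Boltzmann sigmoid signal at temperature T."""
    T = np.asarray(T, dtype=float)
    y = params.bottom + (params.top - params.bottom) / (1.0 + np.exp((params.tm - T) / params.slope))
    return float(y) if y.ndim == 0 else y


def fit_melt(curve: MeltCurve) -> tuple[MeltParams | None, FitResult]:
    """Fit a Boltzmann sigmoid to a melt curve; Tm is the inflection temperature.

    Initialization: bottom/top from the signal extremes, Tm from the
    temperature of the steepest signal change, slope from the gradient there.
    A flat curve returns a flagged non-converged result.
    """
    names = ("bottom", "top", "tm", "slope")
    T, S = curve.temperatures, curve.signals
    if T.size < 6:
        return None, _failed_fit("need at least 6 temperature points", names)
    span = float(S.max() - S.min())
    if span < 1e-12 or span < 0.01 * max(abs(float(S.mean())), 1e-12):
        return None, _failed_fit("degenerate input: flat melt curve", names)

    grad = np.gradient(S, T)
    steepest = int(np.argmax(np.abs(grad)))
    tm0 = float(T[steepest])
    slope0 = max(abs(span / (4 * grad[steepest])), 0.1)
    # with the bottom < top convention, signal rising with T needs slope > 0,
    # falling (the usual melt of a binding signal) needs slope < 0
    rising = grad[steepest] > 0

    t_lo, t_hi = float(T.min()), float(T.max())
    p = lmfit.Parameters()
    p.add("bottom", value=float(S.min()), min=float(S.min()) - span, max=float(S.max()))
    p.add("top", value=float(S.max()), min=float(S.min()), max=float(S.max()) + span)
    p.add("tm", value=tm0, min=t_lo, max=t_hi)
    if rising:
        p.add("slope", value=slope0, min=1e-3, max=(t_hi - t_lo))
    else:
        p.add("slope", value=-slope0, min=-(t_hi - t_lo), max=-1e-3)

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        b, t = pars["bottom"].value, pars["top"].value
        y = b + (t - b) / (1.0 + np.exp((pars["tm"].value - T) / pars["slope"].value))
        return y - S

    out = lmfit.minimize(residual, p, method="least_squares")
    fit = _result_from_lmfit(out, names)
    if not fit.converged:
        return None, fit
    if fit.params["bottom"] >= fit.params["top"]:
        return None, _failed_fit("fit collapsed: bottom >= top", names)
    mp = MeltParams(
        bottom=fit.params["bottom"],
        top=fit.params["top"],
        tm=fit.params["tm"],
        slope=fit.params["slope"],
    )
    return mp, fit


def delta_tm(with_binder: MeltParams, without_binder: MeltParams) -> float:
    """Apparent stabilization: Tm(with binder) - Tm(without binder) [degC]."""
    return with_binder.tm - without_binder.tm
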