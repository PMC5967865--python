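"""Selection-cascade analytics: qPCR quantification, enrichment, diversity, ELISA.

Binder enrichment during ribosome/phage display selection is monitored by
absolute qPCR: a standard curve (Ct versus log10 copies) converts cycle
thresholds of eluted polynucleotides into copy numbers, and enrichment is the
fold excess of copies eluted against the target versus an analogous selection
against a background protein.  Diversity bottlenecks along the cascade
(display -> capture -> recovery -> infection) are modelled at expectation
level with the classic distinct-count formula for sampling with replacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "StandardCurve",
    "QuantResult",
    "EnrichmentResult",
    "CascadeParams",
    "CascadeStage",
    "quantify",
    "enrichment_fold",
    "expected_unique",
    "estimate_diversity",
    "cascade_diversity",
    "elisa_call",
    "elisa_plate_summary",
]


# -- qPCR ----------------------------------------------------------------------


@dataclass(frozen=True)
class StandardCurve:
    """Linear qPCR calibration Ct = intercept + slope * log10(copies).

    A perfect doubling per cycle gives slope -1/log10(2) = -3.32; PCR
    efficiency is 10**(-1/slope) - 1.
    """

    slope: float
    intercept: float
    primer_pair: str | None = None
    ct_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative (Ct falls as copies rise)")

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @classmethod
    def from_dilution_series(
        cls, copies: Sequence[float], ct: Sequence[float], primer_pair: str | None = None
    ) -> "StandardCurve":
        log_copies = np.log10(np.asarray(copies, dtype=float))
        ct = np.asarray(ct, dtype=float)
        slope, intercept = np.polyfit(log_copies, ct, 1)
        return cls(
            slope=float(slope),
            intercept=float(intercept),
            primer_pair=primer_pair,
            ct_range=(float(ct.min()), float(ct.max())),
        )

    def copies_from_ct(self, ct: float) -> float:
        return 10.0 ** ((self.intercept - ct) / -self.slope)


@dataclass(frozen=True)
class QuantResult:
    sample_id: str
    copies: float
    copies_sd: float
    ct_mean: float
    ct_sd: float
    n_replicates: int
    out_of_range: bool = False


def quantify(
    measurements: pd.DataFrame,
    curve: StandardCurve,
    aggregate: str = "ct_mean",
) -> list[QuantResult]:
    """Convert replicate Ct measurements into absolute copy numbers.

    ``measurements`` needs columns sample_id, primer_pair, Ct, replicate.
    Replicates are aggregated per sample as mean Ct then transformed
    (``aggregate="ct_mean"``, default) or transformed per replicate then
    averaged (``aggregate="copies_mean"``).  Ct values outside the calibrated
    range only set a warning flag on the result.
    """
    required = {"sample_id", "primer_pair", "Ct", "replicate"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"qPCR table is missing columns: {sorted(missing)}")
    if (measurements["Ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    if curve.primer_pair is not None:
        mism = set(measurements["primer_pair"]) - {curve.primer_pair}
        if mism:
            raise ValueError(f"standard curve is for {curve.primer_pair!r}, data has {sorted(mism)}")

    ln10_over_slope = math.log(10.0) / abs(curve.slope)
    results = []
    for sample_id, grp in measurements.groupby("sample_id", sort=False):
        ct = grp["Ct"].to_numpy(dtype=float)
        ct_mean, ct_sd = float(ct.mean()), float(ct.std(ddof=1)) if len(ct) > 1 else 0.0
        if aggregate == "ct_mean":
            copies = curve.copies_from_ct(ct_mean)
            copies_sd = copies * ln10_over_slope * ct_sd  # delta method on the log-linear curve
        elif aggregate == "copies_mean":
            per_rep = np.array([curve.copies_from_ct(c) for c in ct])
            copies = float(per_rep.mean())
            copies_sd = float(per_rep.std(ddof=1)) if len(ct) > 1 else 0.0
        else:
            raise ValueError(f"unknown aggregate mode {aggregate!r}")
        out_of_range = False
        if curve.ct_range is not None:
            lo, hi = curve.ct_range
            out_of_range = bool(ct_mean < lo or ct_mean > hi)
        results.append(
            QuantResult(
                sample_id=str(sample_id),
                copies=copies,
                copies_sd=copies_sd,
                ct_mean=ct_mean,
                ct_sd=ct_sd,
                n_replicates=len(ct),
                out_of_range=out_of_range,
            )
        )
    return results


@dataclass(frozen=True)
class EnrichmentResult:
    fold: float
    fold_sd: float
    lower_bound: bool = False  # background undetectable; fold is a floor, not a ratio


def enrichment_fold(
    target_copies: float,
    background_copies: float,
    target_sd: float = 0.0,
    background_sd: float = 0.0,
    detection_floor: float = 1.0,
) -> EnrichmentResult:
    """Fold excess of copies eluted against the target versus a background protein.

    An undetectable background (<= 0 copies) cannot give a finite ratio; the
    result is then the ratio against ``detection_floor`` flagged as a lower
    bound.  SDs propagate by the first-order formula for a ratio of
    independent means.
    """
    if target_copies < 0:
        raise ValueError("target copies must be >= 0")
    lower_bound = background_copies <= 0
    denom = detection_floor if lower_bound else background_copies
    fold = target_copies / denom
    rel = 0.0
    if target_copies > 0:
        rel += (target_sd / target_copies) ** 2
    if not lower_bound and background_copies > 0:
        rel += (background_sd / background_copies) ** 2
    return EnrichmentResult(fold=fold, fold_sd=fold * math.sqrt(rel), lower_bound=lower_bound)


# -- diversity through the cascade ---------------------------------------------


def expected_unique(n: float, diversity: float) -> float:
    """Expected number of distinct members in ``n`` uniform draws from ``diversity``.

    E[unique] = D * (1 - (1 - 1/D)**n); valid for real-valued n (expectation
    of a thinned sampling step).  Numerically stable for very large D via
    expm1/log1p.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if diversity < 1:
        raise ValueError("diversity must be >= 1")
    if n == 0:
        return 0.0
    if diversity == 1:
        return 1.0
    # D * (1 - exp(n * log(1 - 1/D)))
    return -diversity * math.expm1(n * math.log1p(-1.0 / diversity))


def estimate_diversity(unique: float, n: float, d_max: float = 1e18) -> float:
    """Invert expected_unique: pool diversity consistent with ``unique`` of ``n`` draws."""
    if not 0 < unique <= n:
        raise ValueError("need 0 < unique <= n")
    if unique == n:
        return math.inf
    return float(brentq(lambda d: expected_unique(n, d) - unique, unique, d_max, xtol=1e-9))


@dataclass(frozen=True)
class CascadeParams:
    """Expectation-level model of the selection cascade's sampling steps.

    Defaults follow the published platform: 1e12 complexes displayed on
    ribosomes from a pool of 9e12 sampled library molecules, a per-molecule
    capture probability for target binding in round 1, recovery of the eluted
    pool by RT-PCR into a focused phage library of 1e7 members, of which only
    2-5% of eluted phages infect cells.
    """

    library_diversity: float = 8.3e17
    sampled_molecules: float = 9e12
    displayed: float = 1e12
    capture_probability: float = 5e-6
    recovered_molecules: float = 1e9
    phage_library_size: float = 1e7
    infection_rate: float = 0.02

    def __post_init__(self) -> None:
        if not 0 < self.infection_rate <= 1:
            raise ValueError("infection rate must be in (0, 1]")
        if not 0 < self.capture_probability <= 1:
            raise ValueError("capture probability must be in (0, 1]")


@dataclass(frozen=True)
class CascadeStage:
    name: str
    draws: float
    diversity: float
    loss_fraction: float


@dataclass(frozen=True)
class CascadeResult:
    stages: tuple[CascadeStage, ...]
    bottleneck: str

    @property
    def final_diversity(self) -> float:
        return self.stages[-1].diversity


def cascade_diversity(params: CascadeParams) -> CascadeResult:
    """Expected distinct sybodies surviving each step of the selection cascade.

    Each step draws ``n`` molecules from the preceding pool (uniform sampling
    with replacement at expectation level) and keeps
    expected_unique(n, D_prev) distinct members.  The bottleneck is the stage
    with the largest fractional diversity loss.
    """
    steps = [
        ("display", min(params.sampled_molecules, params.displayed)),
        ("capture", params.displayed * params.capture_probability),
        ("recovery", params.recovered_molecules),
        ("phage_library", params.phage_library_size),
        ("infection", params.phage_library_size * params.infection_rate),
    ]
    stages: list[CascadeStage] = []
    diversity = float(params.library_diversity)
    for name, draws in steps:
        new_div = expected_unique(draws, max(diversity, 1.0))
        new_div = min(new_div, diversity)  # a sampling step cannot create diversity
        loss = 0.0 if diversity == 0 else 1.0 - new_div / diversity
        stages.append(CascadeStage(name=name, draws=draws, diversity=new_div, loss_fraction=loss))
        diversity = new_div
    bottleneck = max(stages, key=lambda s: s.loss_fraction).name
    return CascadeResult(stages=tuple(stages), bottleneck=bottleneck)


# -- ELISA hit calling ----------------------------------------------------------


@dataclass(frozen=True)
class ElisaCall:
    hit: bool
    ratio: float
    background_floored: bool = False


def elisa_call(
    signal: float,
    background: float,
    threshold_ratio: float = 3.0,
    background_floor: float = 0.01,
) -> ElisaCall:
    """Call a well positive when signal/background meets the threshold ratio.

    Backgrounds below ``background_floor`` absorbance are replaced by the floor
    (and flagged) so that near-zero control wells cannot inflate ratios.
    """
    if signal < 0 or background < 0:
        raise ValueError("absorbances must be >= 0")
    floored = background < background_floor
    denom = background_floor if floored else background
    ratio = signal / denom
    return ElisaCall(hit=bool(ratio >= threshold_ratio), ratio=ratio, background_floored=floored)


def elisa_plate_summary(
    plate: pd.DataFrame,
    threshold_ratio: float = 3.0,
    background_floor: float = 0.01,
) -> pd.DataFrame:
    """Call every well of a plate table (row, col, absorbance, well_class).

    ``well_class`` distinguishes 'sample' wells from 'background' wells; the
    background absorbance is the mean of the background wells.  Returns the
    sample wells with ratio and hit columns; the fraction positive is
    ``out["hit"].mean()``.
    """
    required = {"row", "col", "absorbance", "well_class"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"ELISA table is missing columns: {sorted(missing)}")
    background = plate.loc[plate["well_class"] == "background", "absorbance"].mean()
    if np.isnan(background):
        raise ValueError("plate has no background wells")
    samples = plate[plate["well_class"] == "sample"].copy()
    calls = [
        elisa_call(a, background, threshold_ratio, background_floor)
        for a in samples["absorbance"]
    ]
    samples["ratio"] = [c.ratio for c in calls]
    samples["hit"] = [c.hit for c in calls]
    return samples
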