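import itertools
import math

import numpy as np
import pandas as pd
import pytest

from sybodykit import selection
from sybodykit.selection import (
    CascadeParams,
    StandardCurve,
    cascade_diversity,
    elisa_call,
    elisa_plate_summary,
    enrichment_fold,
    estimate_diversity,
    expected_unique,
    quantify,
)


# -- standard curves and quantification ------------------------------------------


def test_curve_validation_and_efficiency():
    with pytest.raises(ValueError):
        StandardCurve(slope=3.3, intercept=38.0)
    perfect = StandardCurve(slope=-1.0 / math.log10(2.0), intercept=38.0)
    assert perfect.efficiency == pytest.approx(1.0)


def test_curve_fit_and_inversion():
    true = StandardCurve(slope=-3.42, intercept=38.5)
    copies = [1e3, 1e4, 1e5, 1e6, 1e7]
    ct = [true.intercept + true.slope * math.log10(c) for c in copies]
    fit = StandardCurve.from_dilution_series(copies, ct, primer_pair="qPCR_RD")
    assert fit.slope == pytest.approx(true.slope)
    assert fit.intercept == pytest.approx(true.intercept)
    for c in copies:
        assert fit.copies_from_ct(true.intercept + true.slope * math.log10(c)) == pytest.approx(c)


def _qpcr_table(curve, sample_copies, replicates=3, ct_jitter=0.0, rng=None):
    rows = []
    for sample, copies in sample_copies.items():
        ct = curve.intercept + curve.slope * math.log10(copies)
        for r in range(replicates):
            jitter = rng.normal(0, ct_jitter) if ct_jitter else 0.0
            rows.append({"sample_id": sample, "primer_pair": "qPCR_RD",
                         "Ct": ct + jitter, "replicate": r})
    return pd.DataFrame(rows)


def test_quantify_noiseless_inversion():
    curve = StandardCurve(slope=-3.42, intercept=38.5, primer_pair="qPCR_RD")
    table = _qpcr_table(curve, {"a": 1e4, "b": 2.5e6})
    results = {r.sample_id: r for r in quantify(table, curve)}
    assert results["a"].copies == pytest.approx(1e4, rel=1e-12)
    assert results["b"].copies == pytest.approx(2.5e6, rel=1e-12)
    assert results["a"].copies_sd == pytest.approx(0.0, abs=1e-6)


def test_quantify_aggregate_modes_and_errors():
    curve = StandardCurve(slope=-3.42, intercept=38.5, primer_pair="qPCR_RD")
    table = _qpcr_table(curve, {"a": 1e5})
    ct_mean = quantify(table, curve, aggregate="ct_mean")[0]
    copies_mean = quantify(table, curve, aggregate="copies_mean")[0]
    assert ct_mean.copies == pytest.approx(copies_mean.copies)
    with pytest.raises(ValueError, match="aggregate"):
        quantify(table, curve, aggregate="median")
    with pytest.raises(ValueError, match="missing columns"):
        quantify(table.drop(columns=["replicate"]), curve)
    other = table.assign(primer_pair="other")
    with pytest.raises(ValueError, match="other"):
        quantify(other, curve)


def test_quantify_flags_out_of_range():
    curve = StandardCurve(slope=-3.42, intercept=38.5, primer_pair="qPCR_RD",
                          ct_range=(15.0, 30.0))
    table = _qpcr_table(curve, {"low": 10.0})  # Ct ~ 35, above range
    assert quantify(table, curve)[0].out_of_range


# -- enrichment ------------------------------------------------------------------


def test_enrichment_trivials_and_scale_invariance():
    r = enrichment_fold(1.7e5, 1.0e3)
    assert r.fold == pytest.approx(170.0)
    assert not r.lower_bound
    scaled = enrichment_fold(1.7e6, 1.0e4)
    assert scaled.fold == pytest.approx(r.fold)


def test_enrichment_sd_propagation():
    r = enrichment_fold(100.0, 10.0, target_sd=10.0, background_sd=1.0)
    expected_rel = math.sqrt((10 / 100) ** 2 + (1 / 10) ** 2)
    assert r.fold_sd == pytest.approx(r.fold * expected_rel)


def test_enrichment_lower_bound_on_zero_background():
    r = enrichment_fold(500.0, 0.0, detection_floor=1.0)
    assert r.lower_bound
    assert r.fold == pytest.approx(500.0)


def test_enrichment_fold_monte_carlo_cv_coverage():
    # the propagated SD tracks the Monte-Carlo spread of the ratio within 10%
    rng = np.random.default_rng(0)
    target, background, sd_t, sd_b = 1000.0, 100.0, 50.0, 5.0
    folds = rng.normal(target, sd_t, 20000) / rng.normal(background, sd_b, 20000)
    analytic = enrichment_fold(target, background, sd_t, sd_b).fold_sd
    assert analytic == pytest.approx(folds.std(), rel=0.1)


# -- diversity -------------------------------------------------------------------


def test_expected_unique_trivials():
    assert expected_unique(0, 100) == 0.0
    assert expected_unique(1, 100) == pytest.approx(1.0)
    assert expected_unique(5, 1) == 1.0
    # saturates at the pool diversity
    assert expected_unique(1e6, 10) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        expected_unique(-1, 10)
    with pytest.raises(ValueError):
        expected_unique(5, 0.5)


def test_expected_unique_matches_exhaustive_enumeration():
    # exact expectation by enumerating every outcome of n draws from D labels
    for D, n in [(2, 5), (3, 4), (5, 3), (10, 3)]:
        total = 0
        for outcome in itertools.product(range(D), repeat=n):
            total += len(set(outcome))
        exact = total / D**n
        assert expected_unique(n, D) == pytest.approx(exact, rel=1e-12)


def test_expected_unique_monte_carlo():
    rng = np.random.default_rng(1)
    draws = [len(np.unique(rng.integers(0, 100, size=48))) for _ in range(5000)]
    assert expected_unique(48, 100) == pytest.approx(np.mean(draws), rel=0.02)


def test_expected_unique_stable_for_huge_diversity():
    # n << D: essentially every draw is unique
    assert expected_unique(9e12, 8.3e17) == pytest.approx(9e12, rel=1e-4)


def test_estimate_diversity_inverts():
    u = expected_unique(500, 1000)
    assert estimate_diversity(u, 500) == pytest.approx(1000, rel=1e-6)
    assert estimate_diversity(48, 48) == math.inf
    with pytest.raises(ValueError):
        estimate_diversity(49, 48)


# -- cascade ---------------------------------------------------------------------


def test_cascade_monotone_and_bottleneck():
    result = cascade_diversity(CascadeParams())
    divs = [s.diversity for s in result.stages]
    assert all(a >= b for a, b in zip(divs, divs[1:]))
    assert result.final_diversity <= CascadeParams().library_diversity
    assert result.bottleneck == "display"


def test_cascade_full_infection_keeps_more_diversity():
    low = cascade_diversity(CascadeParams(infection_rate=0.02))
    high = cascade_diversity(CascadeParams(infection_rate=1.0))
    assert high.final_diversity >= low.final_diversity


def test_cascade_parameter_validation():
    with pytest.raises(ValueError):
        CascadeParams(infection_rate=0.0)
    with pytest.raises(ValueError):
        CascadeParams(capture_probability=2.0)


def test_cascade_matches_scaled_down_stochastic_simulation():
    # simulate the same chain of uniform sampling steps at toy scale
    params = CascadeParams(
        library_diversity=2000,
        sampled_molecules=1500,
        displayed=1000,
        capture_probability=0.2,
        recovered_molecules=150,
        phage_library_size=100,
        infection_rate=0.5,
    )
    expected = cascade_diversity(params).final_diversity
    rng = np.random.default_rng(3)
    finals = []
    draws = [1000, 200, 150, 100, 50]
    for _ in range(400):
        pool = np.arange(2000)
        for n in draws:
            pool = np.unique(rng.choice(pool, size=n, replace=True))
        finals.append(len(pool))
    assert expected == pytest.approx(np.mean(finals), rel=0.05)


# -- ELISA -----------------------------------------------------------------------


def test_elisa_call_trivials():
    assert elisa_call(0.9, 0.1).hit
    assert not elisa_call(0.2, 0.1).hit
    floored = elisa_call(0.5, 0.0)
    assert floored.background_floored
    with pytest.raises(ValueError):
        elisa_call(-0.1, 0.1)


def test_elisa_plate_summary_hit_fraction():
    rows = []
    for i in range(40):
        rows.append({"row": "A", "col": i, "absorbance": 0.6, "well_class": "sample"})
    for i in range(40, 48):
        rows.append({"row": "H", "col": i, "absorbance": 0.15, "well_class": "sample"})
    for i in range(8):
        rows.append({"row": "H", "col": 90 + i, "absorbance": 0.1, "well_class": "background"})
    out = elisa_plate_summary(pd.DataFrame(rows))
    assert len(out) == 48
    assert out["hit"].sum() == 40
    assert out["hit"].mean() == pytest.approx(40 / 48)


def test_elisa_plate_requires_background():
    df = pd.DataFrame([{"row": "A", "col": 1, "absorbance": 0.5, "well_class": "sample"}])
    with pytest.raises(ValueError, match="background"):
        elisa_plate_summary(df)
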