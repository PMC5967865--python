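"""Synthetic datasets for every analysis the package performs.

Each scenario generates, from a fully serializable configuration and a seed,
the input tables/records the consuming module expects plus a *truth* record of
the generating parameters, so parameter-recovery tests can compare fits
against ground truth.  Generation is deterministic per seed.

Regimes mirror the published experiments: maltose competition series
0-100 uM, sybody inhibition series 0-81 nM with a nanomolar IC50, SPA-TS
temperature gradients of 30-60 or 23-53 degC, qPCR standard curves with
95-98% efficiency, and selection enrichments of order 10-200 fold.

Default noise levels: SPR 1% of Rmax, melt curves 2% of the signal span,
qPCR Ct standard deviation 0.15 cycles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd

from . import binding, library, selection

__all__ = ["ScenarioConfig", "generate", "SCENARIOS"]

SPR_NOISE_FRACTION_OF_RMAX = 0.01
MELT_NOISE_FRACTION_OF_SPAN = 0.02
QPCR_CT_SD = 0.15


@dataclass(frozen=True)
class ScenarioConfig:
    """A named scenario with its generating parameters, noise model and seed."""

    scenario: str
    seed: int
    params: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


@dataclass(frozen=True)
class Dataset:
    config: ScenarioConfig
    data: dict[str, Any]
    truth: dict[str, Any]

    def write(self, outdir: str | Path) -> list[Path]:
        """Write tables as CSV, sequence sets as FASTA, and a truth JSON sidecar."""
        from .io import write_fasta

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        for name, obj in self.data.items():
            if isinstance(obj, pd.DataFrame):
                path = outdir / f"{name}.csv"
                obj.to_csv(path, index=False)
            elif isinstance(obj, list) and obj and isinstance(obj[0], library.LibraryMember):
                path = outdir / f"{name}.fasta"
                write_fasta(obj, path)
            else:
                path = outdir / f"{name}.json"
                path.write_text(json.dumps(obj, indent=2, default=str))
            written.append(path)
        truth_path = outdir / "truth.json"
        truth_path.write_text(
            json.dumps({"config": dataclasses.asdict(self.config), "truth": self.truth},
                       indent=2, default=str)
        )
        written.append(truth_path)
        return written


def _library_scenario(cfg: ScenarioConfig) -> Dataset:
    p = dict(cfg.params)
    lib = p.get("library", "concave")
    n = int(p.get("n", 100))
    scheme = library.scheme_for(lib)
    members = library.sample_library(scheme, n=n, seed=cfg.seed)
    return Dataset(cfg, {"members": members}, {"library": lib, "n": n})


def _qpcr_dilution(cfg: ScenarioConfig) -> Dataset:
    """Dilution series of known copies under a log-linear standard curve."""
    p = dict(cfg.params)
    efficiency = float(p.get("efficiency", 0.96))  # published band: 95-98%
    intercept = float(p.get("intercept", 38.0))
    copies = [float(c) for c in p.get("copies", [10.0**k for k in range(3, 9)])]
    replicates = int(p.get("replicates", 3))
    ct_sd = float(p.get("ct_sd", QPCR_CT_SD))
    slope = -1.0 / np.log10(1.0 + efficiency)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for i, c in enumerate(copies):
        ct_true = intercept + slope * np.log10(c)
        for r in range(replicates):
            rows.append(
                {
                    "sample_id": f"dil_{i}",
                    "primer_pair": "qPCR_RD",
                    "Ct": ct_true + (rng.normal(0.0, ct_sd) if ct_sd > 0 else 0.0),
                    "replicate": r,
                }
            )
    truth = {
        "efficiency": efficiency,
        "slope": slope,
        "intercept": intercept,
        "copies": {f"dil_{i}": c for i, c in enumerate(copies)},
    }
    return Dataset(cfg, {"qpcr": pd.DataFrame(rows)}, truth)


def _qpcr_selection(cfg: ScenarioConfig) -> Dataset:
    """Target versus background elution measurements with a known enrichment fold."""
    p = dict(cfg.params)
    efficiency = float(p.get("efficiency", 0.96))
    intercept = float(p.get("intercept", 38.0))
    background = float(p.get("background_copies", 1e3))
    fold = float(p.get("fold", 170.0))  # regime of the published enrichments
    replicates = int(p.get("replicates", 3))
    ct_sd = float(p.get("ct_sd", QPCR_CT_SD))
    slope = -1.0 / np.log10(1.0 + efficiency)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for sample, copies in (("target", background * fold), ("background", background)):
        ct_true = intercept + slope * np.log10(copies)
        for r in range(replicates):
            rows.append(
                {
                    "sample_id": sample,
                    "primer_pair": "qPCR_RD",
                    "Ct": ct_true + (rng.normal(0.0, ct_sd) if ct_sd > 0 else 0.0),
                    "replicate": r,
                }
            )
    truth = {
        "efficiency": efficiency,
        "slope": slope,
        "intercept": intercept,
        "fold": fold,
        "background_copies": background,
    }
    return Dataset(cfg, {"qpcr": pd.DataFrame(rows)}, truth)


def _elisa_plate(cfg: ScenarioConfig) -> Dataset:
    """A 96-well plate with a known fraction of true hits over background wells."""
    p = dict(cfg.params)
    hit_fraction = float(p.get("hit_fraction", 0.6))
    signal_ratio = float(p.get("signal_ratio", 5.0))
    background_abs = float(p.get("background_absorbance", 0.08))
    cv = float(p.get("cv", 0.10))
    n_background = int(p.get("n_background", 8))
    rng = np.random.default_rng(cfg.seed)
    rows = []
    wells = [(r, c) for r in "ABCDEFGH" for c in range(1, 13)]
    n_samples = len(wells) - n_background
    n_hits = int(round(hit_fraction * n_samples))
    is_hit = np.array([True] * n_hits + [False] * (n_samples - n_hits))
    rng.shuffle(is_hit)
    k = 0
    for i, (r, c) in enumerate(wells):
        if i >= n_samples:
            rows.append({"row": r, "col": c, "well_class": "background",
                         "absorbance": max(background_abs * (1 + rng.normal(0, cv)), 0.0)})
            continue
        mean = background_abs * (signal_ratio if is_hit[k] else 1.0)
        rows.append({"row": r, "col": c, "well_class": "sample",
                     "absorbance": max(mean * (1 + rng.normal(0, cv)), 0.0)})
        k += 1
    truth = {"hit_fraction": n_hits / n_samples, "signal_ratio": signal_ratio,
             "background_absorbance": background_abs}
    return Dataset(cfg, {"plate": pd.DataFrame(rows)}, truth)


def _spr_1to1(cfg: ScenarioConfig) -> Dataset:
    """Multi-concentration 1:1 sensorgrams around a published-regime KD."""
    p = dict(cfg.params)
    kon = float(p.get("kon", 1.86e5))
    koff = float(p.get("koff", 7.44e-3))
    rmax = float(p.get("rmax", 100.0))
    kin = binding.KineticParams(kon=kon, koff=koff, rmax=rmax)
    concentrations = [float(c) for c in p.get(
        "concentrations", [kin.kd * f for f in (1 / 9, 1 / 3, 1.0, 3.0, 9.0)]
    )]
    noise_sd = float(p.get("noise_sd", SPR_NOISE_FRACTION_OF_RMAX * rmax))
    t_assoc = float(p.get("t_assoc", 120.0))
    t_dissoc = float(p.get("t_dissoc", 300.0))
    dt = float(p.get("dt", 2.0))
    rows = []
    for i, c in enumerate(concentrations):
        g = binding.simulate_sensorgram(
            kin, c, t_assoc=t_assoc, t_dissoc=t_dissoc, dt=dt,
            noise_sd=noise_sd, seed=cfg.seed + i,
        )
        for t, r in zip(g.times, g.responses):
            rows.append({"time": t, "response": r, "concentration": c,
                         "phase": "association" if t <= t_assoc else "dissociation"})
    truth = {"kon": kon, "koff": koff, "rmax": rmax, "kd": kin.kd, "noise_sd": noise_sd,
             "t_assoc": t_assoc}
    return Dataset(cfg, {"sensorgrams": pd.DataFrame(rows)}, truth)


def _schild(cfg: ScenarioConfig) -> Dataset:
    """Affinity-ratio series over the published maltose concentration range."""
    p = dict(cfg.params)
    B = float(p.get("B", 1.0e-6))  # 1.0 uM maltose affinity
    alpha = float(p.get("alpha", 0.017))
    x = np.array([float(v) for v in p.get("x", [0.0, 5e-6, 10e-6, 25e-6, 50e-6, 100e-6])])
    noise_cv = float(p.get("noise_cv", 0.0))
    sp = binding.SchildParams(B=B, alpha=alpha)
    y = np.asarray(binding.schild_ratio(x, sp), dtype=float)
    if noise_cv > 0:
        rng = np.random.default_rng(cfg.seed)
        y = y * (1 + rng.normal(0.0, noise_cv, size=y.shape))
    df = pd.DataFrame({"x": x, "ratio": y})
    return Dataset(cfg, {"schild": df}, {"B": B, "alpha": alpha, "noise_cv": noise_cv})


def _inhibition(cfg: ScenarioConfig) -> Dataset:
    """ATPase-inhibition dose response in the published nanomolar-IC50 regime."""
    p = dict(cfg.params)
    y0 = float(p.get("y0", 20.0))
    a = float(p.get("a", 80.0))
    ic50 = float(p.get("ic50", 62e-9))
    # published sybody series 0-81 nM, extended to resolve the plateau
    x = np.array([float(v) for v in p.get(
        "x", [0.0, 1e-9, 3e-9, 9e-9, 27e-9, 81e-9, 243e-9, 729e-9]
    )])
    noise_sd = float(p.get("noise_sd", 0.0))
    replicates = int(p.get("replicates", 3))
    ip = binding.InhibitionParams(y0=y0, a=a, ic50=ic50)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for r in range(replicates):
        y = np.asarray(binding.inhibition_curve(x, ip), dtype=float)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=y.shape)
        for xi, yi in zip(x, y):
            rows.append({"x": xi, "y": yi, "replicate": r})
    return Dataset(cfg, {"dose_response": pd.DataFrame(rows)},
                   {"y0": y0, "a": a, "ic50": ic50, "noise_sd": noise_sd})


def _melt(cfg: ScenarioConfig) -> Dataset:
    """Paired SPA-TS melt curves with and without a stabilizing binder."""
    p = dict(cfg.params)
    tm = float(p.get("tm", 42.0))
    delta_tm = float(p.get("delta_tm", 6.1))  # published stabilization regime
    slope = float(p.get("slope", -1.5))  # binding signal decays with temperature
    bottom = float(p.get("bottom", 100.0))
    top = float(p.get("top", 1000.0))
    t_grid = np.array([float(v) for v in p.get("temperatures", np.linspace(30.0, 60.0, 12))])
    noise_sd = float(p.get("noise_sd", MELT_NOISE_FRACTION_OF_SPAN * (top - bottom)))
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for condition, tm_c in (("apo", tm), ("with_binder", tm + delta_tm)):
        mp = binding.MeltParams(bottom=bottom, top=top, tm=tm_c, slope=slope)
        y = np.asarray(binding.boltzmann(t_grid, mp), dtype=float)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=y.shape)
        for t, s in zip(t_grid, y):
            rows.append({"temperature": t, "signal": s, "condition": condition})
    truth = {"tm": tm, "delta_tm": delta_tm, "slope": slope, "bottom": bottom,
             "top": top, "noise_sd": noise_sd}
    return Dataset(cfg, {"melt": pd.DataFrame(rows)}, truth)


SCENARIOS: dict[str, Callable[[ScenarioConfig], Dataset]] = {
    "library": _library_scenario,
    "qpcr_dilution": _qpcr_dilution,
    "qpcr_selection": _qpcr_selection,
    "elisa_plate": _elisa_plate,
    "spr_1to1": _spr_1to1,
    "schild": _schild,
    "inhibition": _inhibition,
    "melt": _melt,
}


def generate(config: ScenarioConfig) -> Dataset:
    """Generate the dataset and truth record for a scenario configuration."""
    try:
        maker = SCENARIOS[config.scenario]
    except KeyError:
        raise ValueError(
            f"unknown scenario {config.scenario!r}; available: {sorted(SCENARIOS)}"
        ) from None
    return maker(config)
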