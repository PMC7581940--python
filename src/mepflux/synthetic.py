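"""Synthetic ¹³CO₂-labeling drought experiments with known ground truth.

Generates every input the pipeline consumes — isoprene labeling time
courses from the cascade model, isotopologue spectra with natural ¹³C
abundance, PTR-MS channel traces, drying pot-weight series, and a tidy
physiological measurement table — for replicated control / moderate /
severe drought treatments, together with a ground-truth manifest of the
true fluxes, plateaus and pool sizes.

Default scenario conditions mirror the drought study being emulated:
50-min labeling window; five replicate trees per treatment; control
plateau ~0.85 with DXP/MEcDP enriched to ~75% against an IDP + DMADP
reference of ~87%; moderate drought plateau ~0.60 with the flux reduced
by 37%; severe drought plateau ~0.15 (insufficient incorporation for a
flux estimate); photosynthesis reduced 70% / 96% and ABA raised 6.7- /
12.8-fold under moderate / severe stress.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import binom

from .cascade import CascadeParams, LabelingTimeCourse, cascade_fraction
from .isotopologue import (
    ISOPRENE_CARBONS,
    NATURAL_13C_ABUNDANCE,
    IsotopologueSpectrum,
    PtrmsTrace,
    natural_abundance_matrix,
)
from .physiology import WateringSeries

__all__ = [
    "TreatmentSpec",
    "ScenarioConfig",
    "ExperimentBundle",
    "simulate_time_course",
    "simulate_spectrum",
    "simulate_ptrms",
    "simulate_pot_weights",
    "simulate_experiment",
    "write_bundle",
]

#: carbon counts of the analytes carried through the pipeline
CARBONS = {"DXP": 5, "MEcDP": 5, "IDP+DMADP": 5, "isoprene": 5}
REFERENCE_SPECIES = "IDP+DMADP"


@dataclass(frozen=True)
class TreatmentSpec:
    """Ground-truth parameters of one drought treatment."""

    params: CascadeParams
    #: end-of-run fractional enrichment per species (plastidial pools share
    #: the IDP+DMADP plateau; whole-tissue DXP/MEcDP are diluted by
    #: extra-plastidial pools)
    enrichments: Mapping[str, float]
    #: whole-tissue pool sizes, nmol g⁻¹ DW
    total_pools: Mapping[str, float]
    #: physiological means keyed by variable_id
    phys_means: Mapping[str, float]


def _default_treatments() -> dict[str, TreatmentSpec]:
    # plastidial pools (A, B, C) in nmol g-1 DW; flux in nmol g-1 DW min-1.
    # Magnitudes chosen so the 50-min window spans >= 3 slowest time
    # constants (max pool / J <= ~10 min) for labeled treatments.
    control = TreatmentSpec(
        params=CascadeParams(2.0, 1.0, 0.5, flux=0.2, plateau=0.85),
        enrichments={"DXP": 0.75, "MEcDP": 0.75, "IDP+DMADP": 0.87,
                     "isoprene": 0.85},
        total_pools={"DXP": 2.0 / (0.75 / 0.87),
                     "MEcDP": 1.0 / (0.75 / 0.87),
                     "IDP+DMADP": 0.5},
        phys_means={"photosynthesis": 100.0, "aba": 10.0, "isoprene_emission": 1.5},
    )
    moderate = TreatmentSpec(
        params=CascadeParams(1.1, 0.55, 0.5, flux=0.126, plateau=0.60),
        enrichments={"DXP": 0.45, "MEcDP": 0.45, "IDP+DMADP": 0.60,
                     "isoprene": 0.60},
        total_pools={"DXP": 1.1 / (0.45 / 0.60),
                     "MEcDP": 0.55 / (0.45 / 0.60),
                     "IDP+DMADP": 0.5},
        phys_means={"photosynthesis": 30.0, "aba": 67.0, "isoprene_emission": 1.3},
    )
    severe = TreatmentSpec(
        params=CascadeParams(1.0, 0.5, 0.5, flux=0.08, plateau=0.15),
        enrichments={"DXP": 0.15, "MEcDP": 0.15, "IDP+DMADP": 0.15,
                     "isoprene": 0.15},
        total_pools={"DXP": 1.0, "MEcDP": 0.5, "IDP+DMADP": 0.5},
        phys_means={"photosynthesis": 4.0, "aba": 128.0, "isoprene_emission": 0.6},
    )
    return {"control": control, "moderate": moderate, "severe": severe}


@dataclass(frozen=True)
class ScenarioConfig:
    """Full scenario: treatments, replication, time grid, noise, seed."""

    treatments: dict[str, TreatmentSpec] = field(default_factory=_default_treatments)
    n_replicates: int = 5
    time_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(2.0, 50.0, 25)
    )
    fraction_cv: float = 0.03
    intensity_cv: float = 0.05
    p_natural: float = NATURAL_13C_ABUNDANCE
    spectrum_total_intensity: float = 1.0e4
    phys_cv: float = 0.10
    pot_initial_g: float = 10000.0
    pot_final_g: float = 6000.0
    pot_decay_rate: float = 0.12
    n_days: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for name in ("fraction_cv", "intensity_cv", "phys_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        grid = np.asarray(self.time_grid, dtype=float)
        if grid.ndim != 1 or grid.size < 3 or np.any(np.diff(grid) <= 0):
            raise ValueError("time_grid must be 1-D, increasing, >= 3 points")
        object.__setattr__(self, "time_grid", grid)


@dataclass
class ExperimentBundle:
    """All generated tables plus the ground-truth manifest."""

    time_courses: pd.DataFrame
    spectra: pd.DataFrame
    pools: pd.DataFrame
    pot_weights: pd.DataFrame
    anchors: pd.DataFrame
    reference_weights: pd.DataFrame
    measurements: pd.DataFrame
    manifest: pd.DataFrame


def simulate_time_course(
    params: CascadeParams,
    grid,
    noise_cv: float = 0.03,
    seed: int | np.random.Generator = 0,
    replicate_id: str = "",
) -> LabelingTimeCourse:
    """Noisy labeling time course from the cascade model.

    Fractions are the model curve perturbed multiplicatively,
    f·(1 + ε) with ε ~ N(0, CV), clipped to [0, 1].
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t = np.asarray(grid, dtype=float)
    f = cascade_fraction(t, params)
    if noise_cv > 0:
        f = f * (1.0 + rng.normal(0.0, noise_cv, size=t.shape))
    return LabelingTimeCourse(t, np.clip(f, 0.0, 1.0), "isoprene", replicate_id)


def _spectrum_probs(fraction: float, n: int, p_natural: float) -> np.ndarray:
    # positional-labeling binomial mixed with natural abundance on the
    # tracer-unlabeled carbons
    probs = binom.pmf(np.arange(n + 1), n, fraction)
    return natural_abundance_matrix(n, p_natural) @ probs


def simulate_spectrum(
    fraction: float,
    n: int = ISOPRENE_CARBONS,
    p_natural: float = NATURAL_13C_ABUNDANCE,
    total_intensity: float = 1.0e4,
    noise_cv: float = 0.0,
    seed: int | np.random.Generator = 0,
    analyte_id: str = "",
) -> IsotopologueSpectrum:
    """Isotopologue spectrum for a pool labeled to the given fraction.

    Each carbon position carries tracer ¹³C with probability ``fraction``
    (binomial isotopologue mixing); natural abundance is convolved on the
    remaining positions, so correcting the noiseless spectrum recovers
    ``fraction`` exactly.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    intens = _spectrum_probs(fraction, n, p_natural) * total_intensity
    if noise_cv > 0:
        intens = np.clip(intens * (1.0 + rng.normal(0.0, noise_cv, size=intens.shape)),
                         0.0, None)
    return IsotopologueSpectrum(n, intens, analyte_id)


def simulate_ptrms(
    params: CascadeParams,
    grid,
    emission_cps: float = 5000.0,
    background_cps: float = 50.0,
    primary_cps: float = 5.0e5,
    water_cluster_cps: float = 5.0e3,
    drift_pressure: float = 2.2,
    p_natural: float = NATURAL_13C_ABUNDANCE,
    noise_cv: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> PtrmsTrace:
    """PTR-MS m/z 69-74 trace of isoprene during a labeling run.

    The instantaneous isoprene signal is distributed across isotopologue
    channels according to the labeling state f(t) of the precursor pool,
    on top of a uniform background.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t = np.asarray(grid, dtype=float)
    f = np.atleast_1d(cascade_fraction(t, params))
    channels = np.empty((t.size, ISOPRENE_CARBONS + 1))
    for i, frac in enumerate(f):
        channels[i] = background_cps + emission_cps * _spectrum_probs(
            float(frac), ISOPRENE_CARBONS, p_natural
        )
    if noise_cv > 0:
        channels = np.clip(channels * (1.0 + rng.normal(0.0, noise_cv, channels.shape)),
                           0.0, None)
    return PtrmsTrace(t, channels, primary_cps, water_cluster_cps, drift_pressure)


def simulate_pot_weights(
    initial: float,
    final: float,
    decay_rate: float,
    days: int,
    seed: int | np.random.Generator = 0,
    round_to_gram: bool = False,
    tree_id: str = "",
) -> WateringSeries:
    """Exponentially drying pot: weight(d) = final + (initial-final) e^(-k d)."""
    if not initial > final:
        raise ValueError("initial must exceed final")
    if decay_rate < 0:
        raise ValueError("decay_rate must be >= 0")
    d = np.arange(days + 1)
    w = final + (initial - final) * np.exp(-decay_rate * d)
    if round_to_gram:
        w = np.round(w)
    return WateringSeries(d, w, initial, final, tree_id)


def _rep_ids(treatment: str, n: int) -> list[str]:
    return [f"{treatment}_{i + 1}" for i in range(n)]


def simulate_experiment(config: ScenarioConfig | None = None) -> ExperimentBundle:
    """Generate the complete synthetic experiment for a scenario.

    Bit-reproducible given the configuration (including its seed).
    """
    cfg = config if config is not None else ScenarioConfig()
    rng = np.random.default_rng(cfg.seed)

    tc_rows, spec_rows, pool_rows, manifest_rows = [], [], [], []
    weight_rows, anchor_rows, meas_rows = [], [], []

    for treatment, spec in cfg.treatments.items():
        for rep in _rep_ids(treatment, cfg.n_replicates):
            # isoprene labeling time course
            tc = simulate_time_course(spec.params, cfg.time_grid,
                                      cfg.fraction_cv, rng, rep)
            for t, f in zip(tc.times, tc.fractions):
                tc_rows.append({"replicate_id": rep, "treatment": treatment,
                                "species_id": "isoprene", "time_min": t,
                                "fraction": f})

            # end-of-run isotopologue spectra and total pools per species
            for species, enr in spec.enrichments.items():
                if species == "isoprene":
                    continue
                sp = simulate_spectrum(enr, CARBONS[species], cfg.p_natural,
                                       cfg.spectrum_total_intensity,
                                       cfg.intensity_cv, rng, species)
                for shift, inten in enumerate(sp.intensities):
                    spec_rows.append({"sample_id": rep, "species_id": species,
                                      "mass_shift": shift, "intensity": inten})
                total = spec.total_pools[species] * (
                    1.0 + rng.normal(0.0, cfg.intensity_cv)
                )
                pool_rows.append({
                    "replicate_id": rep, "treatment": treatment,
                    "species_id": species,
                    "total_pool_nmol_gDW": max(total, 0.0),
                    "final_enrichment": float(
                        np.clip(enr * (1.0 + rng.normal(0.0, cfg.fraction_cv)), 0, 1)
                    ),
                })

            # drying pot (control pots barely dry)
            k = 0.002 if treatment == "control" else cfg.pot_decay_rate
            ws = simulate_pot_weights(cfg.pot_initial_g, cfg.pot_final_g, k,
                                      cfg.n_days, rng, round_to_gram=True,
                                      tree_id=rep)
            for d, w in zip(ws.days, ws.daily_weights):
                weight_rows.append({"tree_id": rep, "day": int(d), "weight_g": w})
            anchor_rows.append({"tree_id": rep, "initial_g": cfg.pot_initial_g,
                                "final_g": cfg.pot_final_g})

            # physiological measurements
            for var, mean in spec.phys_means.items():
                meas_rows.append({
                    "variable_id": var, "treatment": treatment, "tree_id": rep,
                    "value": mean * (1.0 + rng.normal(0.0, cfg.phys_cv)),
                })

            p = spec.params
            manifest_rows.append({
                "replicate_id": rep, "treatment": treatment,
                "true_flux": p.flux, "true_plateau": p.plateau,
                "pool_dxp": p.pool_dxp, "pool_mecdp": p.pool_mecdp,
                "pool_idpdmadp": p.pool_idpdmadp,
            })

    # well-watered reference group for the ATR: constant daily transpiration
    atr0 = (cfg.pot_initial_g - cfg.pot_final_g) * (
        1.0 - np.exp(-cfg.pot_decay_rate)
    )
    ref_rows = []
    for i in range(cfg.n_replicates):
        noise = rng.normal(0.0, 0.02 * atr0, size=cfg.n_days + 1)
        w = cfg.pot_initial_g - atr0 * np.arange(cfg.n_days + 1) + noise
        w[0] = cfg.pot_initial_g
        for d in range(cfg.n_days + 1):
            ref_rows.append({"tree_id": f"ww_{i + 1}", "day": d,
                             "weight_g": round(w[d])})

    return ExperimentBundle(
        time_courses=pd.DataFrame(tc_rows),
        spectra=pd.DataFrame(spec_rows),
        pools=pd.DataFrame(pool_rows),
        pot_weights=pd.DataFrame(weight_rows),
        anchors=pd.DataFrame(anchor_rows),
        reference_weights=pd.DataFrame(ref_rows),
        measurements=pd.DataFrame(meas_rows),
        manifest=pd.DataFrame(manifest_rows),
    )


def write_bundle(bundle: ExperimentBundle, out_dir) -> dict[str, Path]:
    """Write every bundle table as CSV into ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("time_courses", "spectra", "pools", "pot_weights",
                 "anchors", "reference_weights", "measurements", "manifest"):
        path = out / f"{name}.csv"
        getattr(bundle, name).to_csv(path, index=False)
        paths[name] = path
    return paths
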