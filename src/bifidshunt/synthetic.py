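"""Synthetic-data generators for every pipeline input.

Each generator emulates one assay of the fermentation study design:

* growth: sigmoidal OD600 time series from the logistic growth model with
  additive Gaussian noise (clipped at zero) plus a no-carbohydrate blank;
* fermentation: endproduct panels from the forward bifid-shunt model,
  scaled by the mM of substrate consumed, with multiplicative lognormal
  noise (concentrations are positive, so the error model is multiplicative);
* qPCR: Ct values whose dCt offsets encode configured fold changes against
  an endogenous control, with additive Gaussian Ct noise;
* calibration: linear detector responses for standard series.

All randomness flows from one integer seed; identical seeds give identical
output.  Default presets mimic the four study substrates (galactose,
lactose, LNT, LNnT): growth asymptote and rate near the lactose condition
(asymptote 1.27, k 0.56 1/h), and an LNnT-like metabolic shift
(f about 0.5, g about 0.9) producing measurable formate and an elevated
acetate:lactate ratio.  These presets are illustrative study conditions,
not fitted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import eval_growth_model
from .stoichiometry import ShuntParameters, SubstrateSpec, get_substrate, predict_fluxes

__all__ = [
    "GrowthSimSpec",
    "FermentationSimSpec",
    "ExpressionSimSpec",
    "CalibrationSimSpec",
    "SimulationConfig",
    "simulate_growth",
    "simulate_fermentation",
    "simulate_cts",
    "simulate_calibration",
    "default_config",
]

STANDARD_LEVELS_MM = (0.5, 1.0, 5.0, 10.0, 20.0, 50.0)  # external-standard series


@dataclass(frozen=True)
class GrowthSimSpec:
    strain: str
    substrate: str
    od_asym: float
    k: float
    tc: float
    noise_sd: float = 0.02
    n_replicates: int = 3
    t_max_h: float = 48.0
    n_timepoints: int = 49


@dataclass(frozen=True)
class FermentationSimSpec:
    strain: str
    substrate: str
    f: float
    g: float
    substrate_consumed_mM: float
    pre_fermentation_mM: float
    noise_cv: float = 0.05
    n_replicates: int = 3


@dataclass(frozen=True)
class ExpressionSimSpec:
    gene: str
    condition: str
    fold_change: float
    ct_noise_sd: float = 0.3
    n_replicates: int = 3
    n_technical: int = 3


@dataclass(frozen=True)
class CalibrationSimSpec:
    analyte: str
    slope: float
    intercept: float
    response_noise_sd: float = 0.0
    levels_mM: tuple = STANDARD_LEVELS_MM


@dataclass
class SimulationConfig:
    seed: int
    growth: list[GrowthSimSpec] = field(default_factory=list)
    fermentation: list[FermentationSimSpec] = field(default_factory=list)
    expression: list[ExpressionSimSpec] = field(default_factory=list)
    calibration: list[CalibrationSimSpec] = field(default_factory=list)
    control_gene: str = "Blon_0393"
    control_ct: float = 20.0
    reference_condition: str = "lactose"
    base_dct: float = 3.0


def simulate_growth(config: SimulationConfig) -> pd.DataFrame:
    """Long-format growth table (strain, substrate, replicate, time_h, od600).

    Includes one blank replicate per strain (substrate "none", zero signal
    plus noise) so downstream blank correction is exercised.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for spec in config.growth:
        t = np.linspace(0.0, spec.t_max_h, spec.n_timepoints)
        clean = eval_growth_model(spec.od_asym, spec.k, spec.tc, t)
        for rep in range(1, spec.n_replicates + 1):
            noisy = np.clip(clean + rng.normal(0.0, spec.noise_sd, t.size), 0.0, None)
            rows.extend(
                {
                    "strain": spec.strain,
                    "substrate": spec.substrate,
                    "replicate": f"r{rep}",
                    "time_h": ti,
                    "od600": yi,
                }
                for ti, yi in zip(t, noisy)
            )
    blank_sd = float(np.mean([s.noise_sd for s in config.growth])) if config.growth else 0.0
    for strain in sorted({s.strain for s in config.growth}):
        t = np.linspace(0.0, 48.0, 49)
        blank_noise = rng.normal(0.0, blank_sd, t.size) if blank_sd > 0 else np.zeros(t.size)
        rows.extend(
            {
                "strain": strain,
                "substrate": "none",
                "replicate": "blank1",
                "time_h": ti,
                "od600": max(yi, 0.0),
            }
            for ti, yi in zip(t, blank_noise)
        )
    return pd.DataFrame(rows)


def simulate_fermentation(config: SimulationConfig) -> pd.DataFrame:
    """Endproduct panels (mM) from the forward stoichiometric model.

    Concentrations are S x per-mole yields times lognormal multiplicative
    noise with the configured CV; the residual substrate concentration is
    pre-fermentation minus consumed.  Zero yields stay exactly zero.
    """
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for spec in config.fermentation:
        substrate = get_substrate(spec.substrate)
        flux = predict_fluxes(substrate, ShuntParameters(f=spec.f, g=spec.g))
        yields = flux.as_dict()
        sigma = (
            np.sqrt(np.log1p(spec.noise_cv**2)) if spec.noise_cv > 0 else 0.0
        )
        for rep in range(1, spec.n_replicates + 1):
            for analyte, per_mole in yields.items():
                true_mM = spec.substrate_consumed_mM * per_mole
                if sigma > 0 and true_mM > 0:
                    noise = rng.lognormal(-0.5 * sigma**2, sigma)
                else:
                    noise = 1.0
                rows.append(
                    {
                        "sample": f"{spec.strain}_{spec.substrate}_r{rep}",
                        "strain": spec.strain,
                        "substrate": spec.substrate,
                        "replicate": f"r{rep}",
                        "analyte": analyte,
                        "concentration_mM": true_mM * noise,
                    }
                )
            rows.append(
                {
                    "sample": f"{spec.strain}_{spec.substrate}_r{rep}",
                    "strain": spec.strain,
                    "substrate": spec.substrate,
                    "replicate": f"r{rep}",
                    "analyte": f"residual_{spec.substrate}",
                    "concentration_mM": spec.pre_fermentation_mM
                    - spec.substrate_consumed_mM,
                }
            )
    return pd.DataFrame(rows)


def simulate_cts(config: SimulationConfig) -> pd.DataFrame:
    """Ct records encoding the configured fold changes.

    Control Cts are Normal(control_ct, sd); target Cts are
    control + base_dct − log2(fold) + noise, so ddCt analysis against the
    reference condition recovers the configured folds (exactly at zero
    noise).
    """
    rng = np.random.default_rng(config.seed + 2)
    rows = []
    conditions = sorted({s.condition for s in config.expression})
    if config.reference_condition not in conditions:
        conditions.append(config.reference_condition)
    genes = sorted({s.gene for s in config.expression})
    spec_map = {(s.gene, s.condition): s for s in config.expression}
    n_reps = max((s.n_replicates for s in config.expression), default=3)
    n_tech = max((s.n_technical for s in config.expression), default=3)
    sd_default = max((s.ct_noise_sd for s in config.expression), default=0.0)
    for condition in conditions:
        for rep in range(1, n_reps + 1):
            sample = f"{condition}_r{rep}"
            control_ct = config.control_ct + (
                rng.normal(0.0, sd_default) if sd_default > 0 else 0.0
            )
            for tech in range(1, n_tech + 1):
                rows.append(
                    {
                        "sample": sample,
                        "condition": condition,
                        "gene": config.control_gene,
                        "role": "endogenous_control",
                        "technical_replicate": f"t{tech}",
                        "ct": control_ct,
                    }
                )
            for gene in genes:
                spec = spec_map.get((gene, condition))
                if condition == config.reference_condition:
                    fold, sd = 1.0, (spec.ct_noise_sd if spec else sd_default)
                elif spec is None:
                    continue
                else:
                    fold, sd = spec.fold_change, spec.ct_noise_sd
                true_ct = control_ct + config.base_dct - np.log2(fold)
                bio_shift = rng.normal(0.0, sd) if sd > 0 else 0.0
                for tech in range(1, n_tech + 1):
                    rows.append(
                        {
                            "sample": sample,
                            "condition": condition,
                            "gene": gene,
                            "role": "target",
                            "technical_replicate": f"t{tech}",
                            "ct": true_ct + bio_shift,
                        }
                    )
    return pd.DataFrame(rows)


def simulate_calibration(config: SimulationConfig) -> pd.DataFrame:
    """Standards table (analyte, concentration_mM, response)."""
    rng = np.random.default_rng(config.seed + 3)
    rows = []
    for spec in config.calibration:
        for level in spec.levels_mM:
            resp = spec.slope * level + spec.intercept
            if spec.response_noise_sd > 0:
                resp += rng.normal(0.0, spec.response_noise_sd)
            rows.append(
                {
                    "analyte": spec.analyte,
                    "concentration_mM": level,
                    "response": resp,
                }
            )
    return pd.DataFrame(rows)


def default_config(seed: int = 0) -> SimulationConfig:
    """Study-condition presets for one strain on the four substrates."""
    strain = "ATCC15697"
    growth = [
        GrowthSimSpec(strain, "galactose", od_asym=1.20, k=0.61, tc=9.0),
        GrowthSimSpec(strain, "lactose", od_asym=1.27, k=0.56, tc=8.0),
        GrowthSimSpec(strain, "lnt", od_asym=1.19, k=0.51, tc=10.0),
        GrowthSimSpec(strain, "lnnt", od_asym=0.85, k=0.57, tc=10.0),
    ]
    fermentation = [
        FermentationSimSpec(strain, "galactose", f=0.02, g=0.5, substrate_consumed_mM=43.0, pre_fermentation_mM=111.0),
        FermentationSimSpec(strain, "lactose", f=0.02, g=0.5, substrate_consumed_mM=24.0, pre_fermentation_mM=58.0),
        FermentationSimSpec(strain, "lnt", f=0.05, g=0.8, substrate_consumed_mM=12.0, pre_fermentation_mM=28.0),
        FermentationSimSpec(strain, "lnnt", f=0.50, g=0.90, substrate_consumed_mM=10.0, pre_fermentation_mM=28.0),
    ]
    expression = [
        ExpressionSimSpec("Blon_0881", "lnt", fold_change=19.34),
        ExpressionSimSpec("Blon_0881", "lnnt", fold_change=18.71),
        ExpressionSimSpec("Blon_0882", "lnt", fold_change=21.84),
        ExpressionSimSpec("Blon_0882", "lnnt", fold_change=20.61),
    ]
    calibration = [
        CalibrationSimSpec("lactate", slope=1200.0, intercept=30.0),
        CalibrationSimSpec("acetate", slope=900.0, intercept=20.0),
        CalibrationSimSpec("formate", slope=700.0, intercept=10.0),
        CalibrationSimSpec("ethanol", slope=500.0, intercept=5.0),
    ]
    return SimulationConfig(
        seed=seed,
        growth=growth,
        fermentation=fermentation,
        expression=expression,
        calibration=calibration,
    )
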