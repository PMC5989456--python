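"""External-standard calibration, sugar consumption, and carbon recovery.

HPLC analytes are quantified against linear external-standard curves
(response = slope * concentration + intercept).  Sugar consumption is the
percentage of the pre-fermentation carbohydrate consumed; carbon recovery
is the percentage of consumed substrate carbon accounted for by the four
secreted metabolites (lactate C3, acetate C2, formate C1, ethanol C2).
CO2 does not appear: pyruvate-formate-lyase retains the carboxyl carbon in
formate, so the fermentation is carbon-closed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .stoichiometry import METABOLITE_CARBONS, SubstrateSpec

__all__ = [
    "CalibrationCurve",
    "MetabolitePanel",
    "build_calibration",
    "quantify",
    "sugar_consumption",
    "carbon_recovery",
    "average_duplicates",
]

R2_FLOOR = 0.99  # warn below this calibration quality
DUPLICATE_DISCORDANCE = 0.10  # flag duplicate injections differing by >10%


@dataclass(frozen=True)
class CalibrationCurve:
    analyte: str
    standard_concentrations: np.ndarray
    responses: np.ndarray
    slope: float
    intercept: float
    r_squared: float


@dataclass
class MetabolitePanel:
    """Measured mM concentrations for one fermentation sample."""

    sample_id: str
    strain: str
    substrate: str
    concentrations: dict[str, float]  # lactate/acetate/formate/ethanol, mM
    residual_sugars: dict[str, float] = field(default_factory=dict)
    pre_fermentation_substrate_mM: float = 0.0

    def __post_init__(self) -> None:
        for name, val in {**self.concentrations, **self.residual_sugars}.items():
            if val < 0:
                raise ValueError(f"negative concentration for {name}: {val}")


def build_calibration(
    standards, responses=None, *, analyte: str = "", fit_intercept: bool = True
) -> CalibrationCurve:
    """Ordinary least-squares calibration line from standards.

    ``standards`` may be an iterable of (concentration_mM, response) pairs,
    or concentrations with ``responses`` given separately.  Requires at
    least two distinct concentrations and non-constant responses; warns when
    r-squared falls below 0.99.
    """
    if responses is None:
        pairs = np.asarray(list(standards), dtype=float)
        conc, resp = pairs[:, 0], pairs[:, 1]
    else:
        conc = np.asarray(standards, dtype=float)
        resp = np.asarray(responses, dtype=float)
    if np.unique(conc).size < 2:
        raise ValueError("calibration requires >= 2 distinct standard concentrations")
    if np.ptp(resp) == 0:
        raise ValueError("zero-variance responses: detector not responding")
    if fit_intercept:
        design = np.column_stack([conc, np.ones_like(conc)])
        (slope, intercept), *_ = np.linalg.lstsq(design, resp, rcond=None)
    else:
        slope = float(conc @ resp / (conc @ conc))
        intercept = 0.0
    pred = slope * conc + intercept
    ss_res = float(np.sum((resp - pred) ** 2))
    ss_tot = float(np.sum((resp - resp.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    if r2 < R2_FLOOR:
        warnings.warn(
            f"calibration for {analyte or 'analyte'}: r^2 = {r2:.4f} below {R2_FLOOR}"
        )
    return CalibrationCurve(analyte, conc, resp, float(slope), float(intercept), r2)


def quantify(response, curve: CalibrationCurve) -> tuple[np.ndarray, np.ndarray]:
    """Invert the calibration: (response − intercept)/slope, in mM.

    Negative results are clipped to zero and flagged.  Returns
    (concentrations, clipped_flags); scalars in, scalars out.
    """
    if curve.slope <= 0:
        raise ValueError(f"calibration slope must be positive, got {curve.slope}")
    scalar = np.isscalar(response)
    resp = np.atleast_1d(np.asarray(response, dtype=float))
    conc = (resp - curve.intercept) / curve.slope
    clipped = conc < 0
    conc = np.clip(conc, 0.0, None)
    if scalar:
        return float(conc[0]), bool(clipped[0])
    return conc, clipped


def average_duplicates(values) -> tuple[float, bool]:
    """Average technical duplicate measurements; flag discordance > 10%
    of the mean."""
    vals = np.asarray(values, dtype=float)
    mean = float(vals.mean())
    discordant = bool(
        vals.size > 1 and mean > 0 and np.ptp(vals) > DUPLICATE_DISCORDANCE * mean
    )
    return mean, discordant


def sugar_consumption(pre_mM: float, post_mM: float) -> float:
    """Percent of the pre-fermentation carbohydrate consumed.

    100*(pre − post)/pre.  A post-fermentation concentration above the
    starting one yields a negative percentage with a warning (it is
    reported, not clipped: it usually flags a quantitation problem).
    """
    if pre_mM <= 0:
        raise ValueError("pre-fermentation concentration must be positive")
    if post_mM < 0:
        raise ValueError("post-fermentation concentration must be non-negative")
    pct = 100.0 * (pre_mM - post_mM) / pre_mM
    if pct < 0:
        warnings.warn(
            f"post-fermentation sugar ({post_mM} mM) exceeds pre ({pre_mM} mM)"
        )
    return pct


def carbon_recovery(
    panel: MetabolitePanel,
    substrate: SubstrateSpec,
    consumed_mM: float | None = None,
) -> float:
    """Percent of consumed-substrate carbon recovered in secreted metabolites.

    Metabolite carbon (mM x carbons per molecule, summed over lactate,
    acetate, formate, ethanol) divided by consumed substrate carbon
    (consumed mM x substrate carbon atoms).  Consumed substrate defaults to
    pre-fermentation minus the residual substrate sugar; recovery above
    100% is possible on real data (e.g. hydrolysis products of residual
    oligosaccharide counted as metabolized).
    """
    if consumed_mM is None:
        residual = panel.residual_sugars.get(panel.substrate, 0.0)
        consumed_mM = panel.pre_fermentation_substrate_mM - residual
    consumed_carbon = consumed_mM * substrate.carbon_atoms
    if consumed_carbon <= 0:
        raise ValueError("consumed substrate carbon must be positive")
    metabolite_carbon = sum(
        conc * METABOLITE_CARBONS[name]
        for name, conc in panel.concentrations.items()
        if name in METABOLITE_CARBONS
    )
    return 100.0 * metabolite_carbon / consumed_carbon
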