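"""Forward and inverse stoichiometric model of the bifid shunt (F6PPK pathway).

Bifidobacteria ferment hexoses through the fructose-6-phosphate
phosphoketolase (F6PPK) pathway: per 2 moles of hexose, phosphoketolase
cleavage yields 3 moles of acetyl-phosphate (dephosphorylated to acetate by
acetate kinase, one ATP each) and 2 moles of glyceraldehyde-3-phosphate that
are oxidized to pyruvate (one ATP each).  With lactate dehydrogenase closing
the redox balance, the canonical endproduct yield is 3 acetate : 2 lactate
(molar ratio 1.5).

Two partition parameters extend the canonical stoichiometry:

``f``
    Fraction of the pyruvate pool routed through pyruvate-formate-lyase
    (PFL) instead of lactate dehydrogenase.  Each diverted pyruvate yields
    one formate plus one acetyl-CoA.
``g``
    Fraction of that acetyl-CoA converted to acetate (acetate kinase, one
    extra ATP); the remainder is reduced to ethanol, regenerating two NAD+
    per mole.

N-acetylglucosamine (GlcNAc) residues of milk oligosaccharides are
deacetylated/deaminated before entering the pathway: each residue releases
one mole of free acetate (no ATP) and contributes its glucosamine backbone
as one hexose equivalent.

All yields are expressed per mole of substrate; the single scale factor
``S`` (mM substrate consumed) converts to concentrations when fitting
measured panels.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "SubstrateSpec",
    "ShuntParameters",
    "FluxPrediction",
    "RatioSet",
    "ShuntFit",
    "SUBSTRATES",
    "load_substrate_registry",
    "get_substrate",
    "predict_fluxes",
    "theoretical_ratios",
    "fit_shunt",
]

# carbons per mole of each secreted metabolite (molecular formulas:
# lactate C3H6O3, acetate C2H4O2, formate CH2O2, ethanol C2H6O)
METABOLITE_CARBONS: Mapping[str, int] = {
    "lactate": 3,
    "acetate": 2,
    "formate": 1,
    "ethanol": 2,
}


@dataclass(frozen=True)
class SubstrateSpec:
    """Composition of a fermentable carbohydrate.

    Parameters
    ----------
    hexose_equivalents : float
        Hexose units entering the F6PPK pathway per mole of substrate.
        GlcNAc residues count here through their glucosamine backbone.
    glcnac_residues : float
        N-acetylglucosamine residues per mole; each releases one free
        acetate upon deacetylation.
    carbon_atoms : float
        Total carbons per mole (6 per plain hexose, 8 per GlcNAc).
    activation_atp_per_hexose : float
        ATP spent importing/phosphorylating each hexose equivalent.
    glcnac_bypass : float
        Fraction of GlcNAc backbones diverted to anabolism instead of
        catabolism (default 0: full catabolism).
    """

    name: str
    hexose_equivalents: float
    glcnac_residues: float
    carbon_atoms: float
    molar_mass: float
    activation_atp_per_hexose: float = 1.0
    glcnac_bypass: float = 0.0

    def __post_init__(self) -> None:
        if self.hexose_equivalents <= 0:
            raise ValueError(f"{self.name}: hexose_equivalents must be positive")
        if self.glcnac_residues < 0 or self.glcnac_residues > self.hexose_equivalents:
            raise ValueError(
                f"{self.name}: glcnac_residues must be in [0, hexose_equivalents]"
            )
        if not 0.0 <= self.glcnac_bypass <= 1.0:
            raise ValueError(f"{self.name}: glcnac_bypass must be in [0, 1]")

    @property
    def catabolized_hexose(self) -> float:
        """Hexose equivalents actually entering the pathway (after bypass)."""
        return self.hexose_equivalents - self.glcnac_bypass * self.glcnac_residues


@dataclass(frozen=True)
class ShuntParameters:
    """Flux-partition parameters of the pyruvate node.

    ``f`` is the pyruvate fraction routed to pyruvate-formate-lyase;
    ``g`` is the acetyl-CoA fraction converted to acetate (remainder to
    ethanol).  With ``enforce_redox_balance`` set and ``f > 0``, ``g`` is
    pinned at 1/2 so PFL flux is redox-neutral (one ethanol regenerates the
    two NADH freed by two pyruvates skipping lactate dehydrogenase).
    """

    f: float
    g: float
    enforce_redox_balance: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must be in [0, 1], got {self.f}")
        if not 0.0 <= self.g <= 1.0:
            raise ValueError(f"g must be in [0, 1], got {self.g}")
        if self.enforce_redox_balance and self.f > 0 and self.g != 0.5:
            object.__setattr__(self, "g", 0.5)


@dataclass(frozen=True)
class FluxPrediction:
    """Predicted endproducts, ATP and redox residual per mole substrate."""

    acetate_mol: float
    lactate_mol: float
    formate_mol: float
    ethanol_mol: float
    deacetylation_acetate_mol: float
    atp_mol: float
    nadh_residual_mol: float
    carbon_in_products_mol: float

    def as_dict(self) -> dict[str, float]:
        return {
            "acetate": self.acetate_mol,
            "lactate": self.lactate_mol,
            "formate": self.formate_mol,
            "ethanol": self.ethanol_mol,
        }


_UNDEFINED = float("nan")


@dataclass(frozen=True)
class RatioSet:
    """Molar endproduct ratios; NaN value + flag marks a zero denominator."""

    aa_la: float
    fa_la: float
    fa_aa: float
    et_la: float
    aa_la_defined: bool = True
    fa_la_defined: bool = True
    fa_aa_defined: bool = True
    et_la_defined: bool = True

    def defined(self) -> dict[str, float]:
        """Return only the defined ratios (undefined ones are excluded,
        never zero-filled)."""
        out = {}
        for name in ("aa_la", "fa_la", "fa_aa", "et_la"):
            if getattr(self, f"{name}_defined"):
                out[name] = getattr(self, name)
        return out


def _safe_ratio(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return _UNDEFINED, False
    return num / den, True


def predict_fluxes(
    substrate: SubstrateSpec,
    shunt: ShuntParameters,
    atp_per_gap: float = 1.0,
) -> FluxPrediction:
    """Forward stoichiometric prediction per mole of substrate.

    With H hexose equivalents and N GlcNAc residues:

    * acetyl-phosphate acetate: (3/2)·H  (phosphoketolase cleavage)
    * pyruvate pool: H, split f : (1−f) between PFL and lactate
    * lactate: H·(1−f); formate: H·f
    * shunt acetate: H·f·g; ethanol: H·f·(1−g)
    * deacetylation acetate: N (free acetate, no ATP)
    * ATP: acetate kinase on acetyl-P (3/2·H) + GAP→pyruvate (H, one ATP
      per the F6PPK convention; configurable via ``atp_per_gap``) + acetate
      kinase on shunt acetyl-CoA (H·f·g) − activation cost
    * NADH residual (produced − consumed): H·f·(2g − 1)

    Carbon is conserved exactly for every (f, g) in the unit square.
    """
    f, g = shunt.f, shunt.g
    H = substrate.catabolized_hexose
    N = substrate.glcnac_residues

    acetyl_p_acetate = 1.5 * H
    lactate = H * (1.0 - f)
    formate = H * f
    shunt_acetate = H * f * g
    ethanol = H * f * (1.0 - g)
    deacetylation_acetate = float(N)
    acetate = acetyl_p_acetate + shunt_acetate + deacetylation_acetate

    atp = (
        acetyl_p_acetate
        + atp_per_gap * H
        + shunt_acetate
        - substrate.activation_atp_per_hexose * H
    )
    nadh_residual = H * f * (2.0 * g - 1.0)

    carbon = (
        METABOLITE_CARBONS["acetate"] * acetate
        + METABOLITE_CARBONS["lactate"] * lactate
        + METABOLITE_CARBONS["formate"] * formate
        + METABOLITE_CARBONS["ethanol"] * ethanol
    )
    return FluxPrediction(
        acetate_mol=acetate,
        lactate_mol=lactate,
        formate_mol=formate,
        ethanol_mol=ethanol,
        deacetylation_acetate_mol=deacetylation_acetate,
        atp_mol=atp,
        nadh_residual_mol=nadh_residual,
        carbon_in_products_mol=carbon,
    )


def theoretical_ratios(flux: FluxPrediction) -> RatioSet:
    """Endproduct molar ratios of a flux prediction.

    Zero denominators yield an undefined flag, never an infinity.
    """
    aa_la, aa_la_ok = _safe_ratio(flux.acetate_mol, flux.lactate_mol)
    fa_la, fa_la_ok = _safe_ratio(flux.formate_mol, flux.lactate_mol)
    fa_aa, fa_aa_ok = _safe_ratio(flux.formate_mol, flux.acetate_mol)
    et_la, et_la_ok = _safe_ratio(flux.ethanol_mol, flux.lactate_mol)
    return RatioSet(
        aa_la=aa_la, fa_la=fa_la, fa_aa=fa_aa, et_la=et_la,
        aa_la_defined=aa_la_ok, fa_la_defined=fa_la_ok,
        fa_aa_defined=fa_aa_ok, et_la_defined=et_la_ok,
    )


@dataclass(frozen=True)
class ShuntFit:
    """Result of the inverse flux-partition estimation."""

    params: ShuntParameters
    substrate_consumed_mM: float
    residual_norm: float
    g_identifiable: bool
    boundary_hit: bool
    n_observed: int


def _panel_vector(panel: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    analytes = [a for a in ("lactate", "acetate", "formate", "ethanol") if a in panel]
    obs = np.array([panel[a] for a in analytes], dtype=float)
    return analytes, obs


def fit_shunt(
    panel: Mapping[str, float],
    substrate: SubstrateSpec,
    grid_points: int = 5,
) -> ShuntFit:
    """Estimate (f, g, S) from a measured endproduct panel.

    Bounded least squares minimizing the mismatch between observed mM
    concentrations and ``S`` times the per-mole yields of
    :func:`predict_fluxes`, multi-started from a ``grid_points`` ×
    ``grid_points`` grid over (f, g) to avoid local minima.  Ties are
    broken by smallest residual, then smallest f.

    When formate and ethanol are both absent the shunt is off and g is not
    identifiable: the fit returns f = 0 with ``g_identifiable=False``.

    Parameters
    ----------
    panel : mapping
        mM concentrations keyed by analyte name; lactate plus at least one
        further endproduct (acetate, formate or ethanol) are required.
    """
    if "lactate" not in panel or len(set(panel) & {"acetate", "formate", "ethanol"}) < 1:
        raise ValueError("panel must contain lactate and at least one other analyte")
    analytes, obs = _panel_vector(panel)
    if np.any(obs < 0):
        raise ValueError("panel concentrations must be non-negative")
    if np.all(obs == 0):
        raise ValueError("all-zero panel: nothing to fit")

    def yields(f: float, g: float) -> np.ndarray:
        flux = predict_fluxes(substrate, ShuntParameters(f=f, g=g))
        d = flux.as_dict()
        return np.array([d[a] for a in analytes])

    shunt_products_absent = (
        panel.get("formate", 0.0) == 0.0 and panel.get("ethanol", 0.0) == 0.0
    )
    if shunt_products_absent:
        # f = 0 exactly; only S is free and has a closed-form LS solution
        y0 = yields(0.0, 0.5)
        s_hat = float(obs @ y0 / (y0 @ y0))
        resid = obs - s_hat * y0
        return ShuntFit(
            params=ShuntParameters(f=0.0, g=0.5),  # g is a placeholder; see flag
            substrate_consumed_mM=s_hat,
            residual_norm=float(np.linalg.norm(resid)),
            g_identifiable=False,
            boundary_hit=True,
            n_observed=len(obs),
        )

    s_scale = float(obs.max()) / max(substrate.hexose_equivalents, 1.0)

    def residuals(theta: np.ndarray) -> np.ndarray:
        f, g, s = theta
        return s * yields(f, g) - obs

    best = None
    grid = np.linspace(0.0, 1.0, grid_points)
    for f0 in grid:
        for g0 in grid:
            sol = least_squares(
                residuals,
                x0=np.array([f0, g0, max(s_scale, 1e-6)]),
                bounds=([0.0, 0.0, 0.0], [1.0, 1.0, np.inf]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            cost = float(np.linalg.norm(sol.fun))
            key = (round(cost, 12), round(float(sol.x[0]), 12))
            if best is None or key < best[0]:
                best = (key, sol)
    sol = best[1]
    f_hat, g_hat, s_hat = (float(v) for v in sol.x)
    eps = 1e-9
    boundary = (
        f_hat < eps or f_hat > 1 - eps or g_hat < eps or g_hat > 1 - eps
    )
    return ShuntFit(
        params=ShuntParameters(f=f_hat, g=g_hat),
        substrate_consumed_mM=s_hat,
        residual_norm=float(np.linalg.norm(sol.fun)),
        g_identifiable=True,
        boundary_hit=boundary,
        n_observed=len(obs),
    )


def load_substrate_registry(path=None) -> dict[str, SubstrateSpec]:
    """Load the substrate registry CSV (built-in registry by default)."""
    if path is None:
        path = importlib.resources.files("bifidshunt.data") / "substrates.csv"
    df = pd.read_csv(path)
    registry: dict[str, SubstrateSpec] = {}
    for row in df.itertuples(index=False):
        registry[row.name] = SubstrateSpec(
            name=row.name,
            hexose_equivalents=float(row.hexose_equivalents),
            glcnac_residues=float(row.glcnac_residues),
            carbon_atoms=float(row.carbon_atoms),
            molar_mass=float(row.molar_mass),
        )
    return registry


SUBSTRATES: dict[str, SubstrateSpec] = {
    s.name: s
    for s in (
        SubstrateSpec("glucose", 1, 0, 6, 180.16),
        SubstrateSpec("galactose", 1, 0, 6, 180.16),
        SubstrateSpec("lactose", 2, 0, 12, 342.30),
        SubstrateSpec("glcnac", 1, 1, 8, 221.21),
        SubstrateSpec("lnt", 4, 1, 26, 707.63),
        SubstrateSpec("lnnt", 4, 1, 26, 707.63),
    )
}


def get_substrate(name: str) -> SubstrateSpec:
    """Look up a built-in substrate by (case-insensitive) name."""
    key = name.lower()
    if key not in SUBSTRATES:
        raise KeyError(
            f"unknown substrate {name!r}; known: {sorted(SUBSTRATES)}"
        )
    return SUBSTRATES[key]
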