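"""Forward/inverse bifid-shunt stoichiometry.

The independent oracle for the inverse fit is an exhaustive grid search
over (f, g); forward predictions are checked against hand stoichiometry.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bifidshunt.stoichiometry import (
    SUBSTRATES,
    ShuntParameters,
    SubstrateSpec,
    fit_shunt,
    get_substrate,
    load_substrate_registry,
    predict_fluxes,
    theoretical_ratios,
)

UNIT = st.floats(0.0, 1.0, allow_nan=False)
HEX2 = SubstrateSpec("hexose2", 2, 0, 12, 342.30)


def grid_search_oracle(panel, substrate, n=101):
    """Exhaustive (f, g) grid with closed-form least-squares scale S."""
    analytes = [a for a in ("lactate", "acetate", "formate", "ethanol") if a in panel]
    obs = np.array([panel[a] for a in analytes])
    best = None
    for f in np.linspace(0, 1, n):
        for g in np.linspace(0, 1, n):
            d = predict_fluxes(substrate, ShuntParameters(f, g)).as_dict()
            y = np.array([d[a] for a in analytes])
            s = obs @ y / (y @ y)
            cost = float(np.sum((s * y - obs) ** 2))
            if best is None or cost < best[0] - 1e-15:
                best = (cost, f, g, s)
    return best[1:]


class TestForwardModel:
    def test_canonical_hexose_yield(self, hexose2):
        """2 hexoses, no shunt: 3 acetate + 2 lactate, nothing else."""
        flux = predict_fluxes(hexose2, ShuntParameters(0.0, 0.5))
        assert flux.acetate_mol == 3.0
        assert flux.lactate_mol == 2.0
        assert flux.formate_mol == 0.0
        assert flux.ethanol_mol == 0.0
        assert flux.nadh_residual_mol == 0.0
        assert theoretical_ratios(flux).aa_la == 1.5

    def test_full_shunt_formate_acetate_ratio(self, hexose2):
        """Complete PFL diversion with full acetate conversion: 2 formate,
        5 acetate, ratio 2:5."""
        flux = predict_fluxes(hexose2, ShuntParameters(1.0, 1.0))
        assert flux.formate_mol == 2.0
        assert flux.acetate_mol == 5.0
        assert theoretical_ratios(flux).fa_aa == pytest.approx(0.4, abs=0)

    def test_lnt_deacetylation_acetate(self):
        """LNT (4 hexose eq, 1 GlcNAc), no shunt: 7 acetate vs 4 lactate."""
        flux = predict_fluxes(get_substrate("lnt"), ShuntParameters(0.0, 0.5))
        assert flux.acetate_mol == 7.0
        assert flux.lactate_mol == 4.0
        assert flux.deacetylation_acetate_mol == 1.0
        assert theoretical_ratios(flux).aa_la == 1.75

    def test_half_ethanol_split_gives_unit_ethanol_lactate(self, hexose2):
        """f=2/3 with half of acetyl-CoA to ethanol balances ethanol and
        lactate 1:1."""
        flux = predict_fluxes(hexose2, ShuntParameters(2 / 3, 0.5))
        assert theoretical_ratios(flux).et_la == pytest.approx(1.0, rel=1e-12)
        assert flux.nadh_residual_mol == pytest.approx(0.0, abs=1e-12)

    def test_atp_per_hexose_no_shunt(self, hexose2):
        """1.5 ATP per hexose equivalent at f=0 with unit activation cost."""
        flux = predict_fluxes(hexose2, ShuntParameters(0.0, 0.5))
        assert flux.atp_mol / hexose2.hexose_equivalents == pytest.approx(1.5)

    @pytest.mark.parametrize("name", sorted(SUBSTRATES))
    def test_no_shunt_closes_redox(self, name):
        flux = predict_fluxes(get_substrate(name), ShuntParameters(0.0, 0.3))
        assert flux.formate_mol == 0.0
        assert flux.ethanol_mol == 0.0
        assert flux.nadh_residual_mol == 0.0

    @given(f=UNIT, g=UNIT, name=st.sampled_from(sorted(SUBSTRATES)))
    @settings(max_examples=200, deadline=None)
    def test_carbon_conservation(self, f, g, name):
        """2*acetate + 3*lactate + formate + 2*ethanol carbon equals the
        substrate's carbon count for every flux partition."""
        sub = get_substrate(name)
        flux = predict_fluxes(sub, ShuntParameters(f, g))
        carbon = (
            2 * flux.acetate_mol + 3 * flux.lactate_mol
            + flux.formate_mol + 2 * flux.ethanol_mol
        )
        assert carbon == pytest.approx(sub.carbon_atoms, rel=1e-12)
        assert flux.carbon_in_products_mol == pytest.approx(sub.carbon_atoms, rel=1e-12)

    @given(f=UNIT, g=UNIT)
    @settings(max_examples=100, deadline=None)
    def test_redox_residual_closed_form(self, f, g):
        """NADH residual is H*f*(2g-1): zero iff f=0 or g=1/2."""
        flux = predict_fluxes(HEX2, ShuntParameters(f, g))
        assert flux.nadh_residual_mol == pytest.approx(2 * f * (2 * g - 1), abs=1e-12)

    def test_acetate_lactate_ratio_monotone_in_f_and_g(self, hexose2):
        grid = np.linspace(0.01, 0.99, 9)
        for g in (0.2, 0.8):
            ratios = [
                theoretical_ratios(predict_fluxes(hexose2, ShuntParameters(f, g))).aa_la
                for f in grid
            ]
            assert np.all(np.diff(ratios) >= 0)
        for f in (0.3, 0.7):
            ratios = [
                theoretical_ratios(predict_fluxes(hexose2, ShuntParameters(f, g))).aa_la
                for g in grid
            ]
            assert np.all(np.diff(ratios) >= 0)

    def test_redox_balance_enforcement_pins_g(self):
        p = ShuntParameters(0.4, 0.9, enforce_redox_balance=True)
        assert p.g == 0.5

    def test_invalid_parameters_rejected(self, hexose2):
        with pytest.raises(ValueError):
            ShuntParameters(-0.1, 0.5)
        with pytest.raises(ValueError):
            ShuntParameters(0.5, 1.2)
        with pytest.raises(ValueError):
            SubstrateSpec("bad", 0, 0, 0, 1.0)
        with pytest.raises(ValueError):
            SubstrateSpec("bad", 1, 2, 6, 1.0)


class TestRatios:
    def test_zero_lactate_flags_undefined(self, hexose2):
        flux = predict_fluxes(hexose2, ShuntParameters(1.0, 1.0))
        ratios = theoretical_ratios(flux)
        assert flux.lactate_mol == 0.0
        assert not ratios.aa_la_defined
        assert "aa_la" not in ratios.defined()
        assert ratios.fa_aa_defined

    @given(f=st.floats(0.01, 0.99), g=UNIT)
    @settings(max_examples=50, deadline=None)
    def test_defined_ratios_nonnegative(self, f, g):
        ratios = theoretical_ratios(predict_fluxes(HEX2, ShuntParameters(f, g)))
        assert all(v >= 0 for v in ratios.defined().values())


class TestInverseFit:
    def test_noiseless_recovery_matches_grid_oracle(self, hexose2):
        """Exact recovery of (f, g, S) from a noiseless forward panel, and
        agreement with the exhaustive grid-search oracle."""
        truth_f, truth_g, truth_s = 0.5, 0.5, 20.0
        d = predict_fluxes(hexose2, ShuntParameters(truth_f, truth_g)).as_dict()
        panel = {k: truth_s * v for k, v in d.items()}
        fit = fit_shunt(panel, hexose2)
        assert fit.params.f == pytest.approx(truth_f, abs=1e-6)
        assert fit.params.g == pytest.approx(truth_g, abs=1e-6)
        assert fit.substrate_consumed_mM == pytest.approx(truth_s, abs=1e-6)
        f_o, g_o, s_o = grid_search_oracle(panel, hexose2)
        assert fit.params.f == pytest.approx(f_o, abs=0.01)
        assert fit.params.g == pytest.approx(g_o, abs=0.01)

    @pytest.mark.parametrize("truth", [(0.1, 0.9, 40.0), (0.8, 0.2, 5.0)])
    def test_noiseless_recovery_other_regimes(self, truth):
        f, g, s = truth
        lnnt = get_substrate("lnnt")
        d = predict_fluxes(lnnt, ShuntParameters(f, g)).as_dict()
        fit = fit_shunt({k: s * v for k, v in d.items()}, lnnt)
        assert fit.params.f == pytest.approx(f, abs=1e-6)
        assert fit.params.g == pytest.approx(g, abs=1e-6)
        assert fit.substrate_consumed_mM == pytest.approx(s, abs=1e-6)

    def test_noisy_recovery_of_f(self, hexose2, rng):
        """Mean |f_hat - f| < 0.1 across 100 panels at 5% CV noise."""
        truth_f, truth_g, truth_s = 0.4, 0.7, 25.0
        d = predict_fluxes(hexose2, ShuntParameters(truth_f, truth_g)).as_dict()
        sigma = np.sqrt(np.log1p(0.05**2))
        errs = []
        for _ in range(100):
            panel = {
                k: truth_s * v * rng.lognormal(-0.5 * sigma**2, sigma)
                for k, v in d.items()
            }
            fit = fit_shunt(panel, hexose2, grid_points=3)
            errs.append(abs(fit.params.f - truth_f))
        assert np.mean(errs) < 0.1

    def test_absent_shunt_products_mark_g_unidentifiable(self, hexose2):
        fit = fit_shunt({"lactate": 20.0, "acetate": 30.0, "formate": 0.0,
                         "ethanol": 0.0}, hexose2)
        assert fit.params.f == 0.0
        assert not fit.g_identifiable

    def test_published_lnnt_means_imply_strong_shunt(self):
        """Observed LNnT endproduct means (lactate 29.5, formate 16.3,
        ethanol 2.5 mM; acetate unreported) require f above 0.3."""
        fit = fit_shunt(
            {"lactate": 29.5, "formate": 16.3, "ethanol": 2.5},
            get_substrate("lnnt"),
        )
        assert fit.params.f > 0.3

    def test_all_zero_panel_rejected(self, hexose2):
        with pytest.raises(ValueError):
            fit_shunt({"lactate": 0.0, "acetate": 0.0}, hexose2)

    def test_negative_concentration_rejected(self, hexose2):
        with pytest.raises(ValueError):
            fit_shunt({"lactate": -1.0, "acetate": 3.0}, hexose2)


def test_builtin_registry_consistency():
    """Registry CSV matches the in-code registry, and every built-in obeys
    the carbon bookkeeping 6*(H-N) + 8*N."""
    reg = load_substrate_registry()
    assert set(reg) == set(SUBSTRATES)
    for name, sub in reg.items():
        assert sub.carbon_atoms == 6 * (
            sub.hexose_equivalents - sub.glcnac_residues
        ) + 8 * sub.glcnac_residues
        assert SUBSTRATES[name].hexose_equivalents == sub.hexose_equivalents
    with pytest.raises(KeyError):
        get_substrate("sucrose")
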