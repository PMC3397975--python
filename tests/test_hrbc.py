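import numpy as np
import pytest

from nessflux.hrbc import (
    EXCHANGE_SPECIES,
    FREE_FLUX_REACTIONS,
    RBCEnvironment,
    RBCFreeFluxes,
    exchange_rates,
    extracellular_H,
    free_flux_basis,
    load_hrbc_network,
    optimal_g6pdh,
    optimal_g6pdh_numeric,
    ppp_fraction,
    ppp_fraction_bounds,
)
from nessflux.netio import validate_network


@pytest.fixture(scope="module")
def basis(hrbc_net):
    return free_flux_basis(hrbc_net)


def random_env(rng):
    return RBCEnvironment(
        x={k: float(rng.uniform(2e-4, 2e-1)) for k in ("GLC", "LAC", "K", "NA", "CO2")}
    )


class TestFixture:
    def test_cardinality(self, hrbc_net):
        assert hrbc_net.M == 30          # metabolites
        assert hrbc_net.N == 23          # 21 reactions + ATPase + NADPHase

    def test_fixture_validates(self, hrbc_net):
        assert validate_network(hrbc_net) == []

    def test_pumps_present(self, hrbc_net):
        rids = hrbc_net.reaction_ids
        assert "ATPase" in rids and "NADPHase" in rids

    def test_atpase_moves_ions_with_opposite_signs(self, hrbc_net):
        stoich = {r.id: r.stoich for r in hrbc_net.reactions}["ATPase"]
        assert stoich["KX"] < 0 < stoich["NAX"]

    def test_boundary_species_are_the_five_exchanged(self, hrbc_net):
        boundary = {s.id for s in hrbc_net.species if s.is_boundary}
        assert boundary == set(EXCHANGE_SPECIES)


class TestFreeFluxBasis:
    def test_null_space_dimension_three(self, hrbc_net):
        S_int = hrbc_net.internal_stoichiometric_matrix()
        assert hrbc_net.N - np.linalg.matrix_rank(S_int) == 3

    def test_zero_input_zero_output(self, basis):
        np.testing.assert_array_equal(basis(RBCFreeFluxes(0.0, 0.0, 0.0)), 0.0)

    def test_designated_coordinates_reproduced(self, basis):
        f = RBCFreeFluxes(1.3, -0.2, 0.8)
        v = basis(f)
        for rid, val in zip(FREE_FLUX_REACTIONS, f.as_array()):
            assert basis.flux(f, rid) == pytest.approx(val, abs=1e-12)
        assert v.shape == (23,)

    def test_mass_balance_identically(self, hrbc_net, basis):
        rng = np.random.default_rng(0)
        S_int = hrbc_net.internal_stoichiometric_matrix()
        for _ in range(100):
            f = RBCFreeFluxes(*rng.normal(0, 1.0, size=3))
            assert np.abs(S_int @ basis(f)).max() < 1e-12


class TestExchangeRates:
    def test_linearity_and_zero(self, hrbc_net, basis):
        r0 = exchange_rates(RBCFreeFluxes(0.0, 0.0, 0.0), hrbc_net, basis)
        assert all(v == 0.0 for v in r0.values())
        r1 = exchange_rates(RBCFreeFluxes(1.0, 0.2, 0.5), hrbc_net, basis)
        r2 = exchange_rates(RBCFreeFluxes(2.0, 0.4, 1.0), hrbc_net, basis)
        for k in r1:
            assert r2[k] == pytest.approx(2 * r1[k], abs=1e-12)

    def test_glucose_rate_is_minus_uptake(self, hrbc_net, basis):
        rates = exchange_rates(RBCFreeFluxes(0.7, 0.1, 0.4), hrbc_net, basis)
        assert rates["GLC"] == pytest.approx(-0.7, abs=1e-12)

    def test_full_ppp_routing_gives_carbon_factor_six(self, hrbc_net, basis):
        # all glucose carbon leaves as CO2 when u_g6pdh = 6 u_glc
        g = 1.0
        rates = exchange_rates(RBCFreeFluxes(g, 0.0, 6 * g), hrbc_net, basis)
        assert rates["CO2"] / g == pytest.approx(6.0, abs=1e-10)
        assert rates["LAC"] == pytest.approx(0.0, abs=1e-10)

    def test_carbon_conservation(self, hrbc_net, basis):
        rng = np.random.default_rng(1)
        for _ in range(100):
            f = RBCFreeFluxes(*rng.normal(0, 1.0, size=3))
            rates = exchange_rates(f, hrbc_net, basis)
            # 6 C in GLC, 3 in LAC, 1 in CO2
            assert 6 * (-rates["GLC"]) == pytest.approx(
                3 * rates["LAC"] + rates["CO2"], abs=1e-12
            )


class TestExtracellularH:
    def test_zero_fluxes(self, hrbc_net, basis):
        assert extracellular_H(RBCFreeFluxes(0, 0, 0), net=hrbc_net, basis=basis) == 0.0

    def test_inverse_concentration_scaling(self, hrbc_net, basis):
        env = RBCEnvironment()
        env2 = RBCEnvironment(x={k: 3.0 * v for k, v in env.x.items()})
        f = RBCFreeFluxes(1.0, 0.1, 0.7)
        H1 = extracellular_H(f, env, hrbc_net, basis)
        H2 = extracellular_H(f, env2, hrbc_net, basis)
        assert H2 == pytest.approx(H1 / 3.0, rel=1e-12)

    def test_term_by_term_recomputation(self, hrbc_net, basis):
        env = RBCEnvironment()
        f = RBCFreeFluxes(0.8, 0.2, 1.1)
        rates = exchange_rates(f, hrbc_net, basis)
        expected = sum(rates[k] ** 2 / env.x[k] for k in rates)
        assert extracellular_H(f, env, hrbc_net, basis) == pytest.approx(expected)


class TestOptimalG6PDH:
    def test_closed_form_matches_numeric_oracle(self, hrbc_net, basis):
        rng = np.random.default_rng(7)
        for _ in range(25):
            env = random_env(rng)
            g = float(rng.uniform(0.1, 2.0))
            d = float(rng.uniform(0.0, 1.0))
            z_closed, _, _ = optimal_g6pdh(g, d, env)
            z_num = optimal_g6pdh_numeric(g, d, env, hrbc_net, basis)
            assert z_closed == pytest.approx(z_num, rel=1e-8, abs=1e-10)

    def test_co2_dominant_limit_routes_all_glucose_to_ppp(self):
        env = RBCEnvironment(
            x={"GLC": 5e-3, "LAC": 1e-3, "K": 4e-3, "NA": 0.14, "CO2": 1e4}
        )
        z, a, b = optimal_g6pdh(1.0, 0.0, env)
        assert a == pytest.approx(6.0, abs=1e-2)
        F, _ = ppp_fraction(z, 1.0)
        assert F > 0.99

    def test_ab_invariant_under_common_rescaling(self):
        rng = np.random.default_rng(9)
        env = random_env(rng)
        scaled = RBCEnvironment(x={k: 7.3 * v for k, v in env.x.items()})
        _, a1, b1 = optimal_g6pdh(1.0, 0.5, env)
        _, a2, b2 = optimal_g6pdh(1.0, 0.5, scaled)
        assert a1 == pytest.approx(a2, rel=1e-12)
        assert b1 == pytest.approx(b2, rel=1e-12)

    def test_requires_positive_uptake(self):
        with pytest.raises(ValueError):
            optimal_g6pdh(0.0)


class TestPPPFraction:
    def test_endpoints(self):
        assert ppp_fraction(0.0, 1.0) == (0.0, False)
        assert ppp_fraction(6.0, 1.0) == (1.0, False)

    def test_linearity(self):
        F1, _ = ppp_fraction(1.0, 1.0)
        F2, _ = ppp_fraction(2.0, 1.0)
        assert F2 == pytest.approx(2 * F1)

    def test_clipping_flag(self):
        F, clipped = ppp_fraction(7.0, 1.0)
        assert clipped and F == 1.0
        with pytest.raises(ValueError):
            ppp_fraction(1.0, 0.0)


class TestPPPBounds:
    def test_bounds_bracket_interior_operation(self, hrbc_net, basis):
        env = RBCEnvironment()
        F_min, F_max = ppp_fraction_bounds(env)
        assert 0.0 <= F_min < F_max <= 1.0
        _, a, b = optimal_g6pdh(1.0, 0.0, env)
        d_max = (6.0 - a) / (3.0 + b)
        for d in np.linspace(0.0, d_max, 7):
            z, _, _ = optimal_g6pdh(1.0, d, env)
            F, _ = ppp_fraction(z, 1.0)
            assert F_min - 1e-12 <= F <= F_max + 1e-12

    def test_grid_search_oracle(self, hrbc_net, basis):
        # joint 1e-3-resolution grid over (u_dpgm, u_g6pdh) at u_glc = 1,
        # restricted to the admissible regime (non-negative shunt, PPP, LAC
        # export and pump fluxes); extremes of F at the per-column optimal z
        # must match the closed form.
        env = RBCEnvironment()
        g = 1.0
        S = hrbc_net.stoichiometric_matrix()
        idx = hrbc_net.species_index()
        T = basis.matrix
        d_grid = np.linspace(0.0, 2.5, 2501)
        z_grid = np.linspace(0.0, 6.0, 6001)
        rate_rows = {k: S[idx[sp], :] @ T for sp, k in EXCHANGE_SPECIES.items()}
        coeffs = {k: (row @ np.array([g, 0, 0]), row[1], row[2])
                  for k, row in rate_rows.items()}
        D, Z = np.meshgrid(d_grid, z_grid, indexing="ij")
        H = np.zeros_like(D)
        for k, (c0, cd, cz) in coeffs.items():
            H += (c0 + cd * D + cz * Z) ** 2 / env.x[k]
        z_opt = z_grid[np.argmin(H, axis=1)]
        # regime: shunt from 0 up to where the pump (or lactate export)
        # would have to run backwards at the optimal PPP routing
        lac_c = coeffs["LAC"]
        lac = lac_c[0] + lac_c[1] * d_grid + lac_c[2] * z_opt
        pump_row = S[idx["NAX"], :] @ T / 3.0        # ATPase flux
        pump = (pump_row @ np.array([g, 0, 0])) + pump_row[1] * d_grid + pump_row[2] * z_opt
        admissible = (lac >= -1e-9) & (pump >= -1e-9) & (z_opt >= 0)
        F_vals = z_opt[admissible] / (6.0 * g)
        F_min, F_max = ppp_fraction_bounds(env)
        assert F_vals.min() == pytest.approx(F_min, abs=2e-3)
        assert F_vals.max() == pytest.approx(F_max, abs=2e-3)

    def test_monotone_in_co2(self):
        # optimal PPP routing (at zero shunt flux) grows with CO2 capacity
        base = {"GLC": 5e-3, "LAC": 1e-3, "K": 4e-3, "NA": 0.14}
        last = -1.0
        for co2 in [1e-4, 1e-3, 1e-2, 1e-1, 1.0]:
            env = RBCEnvironment(x={**base, "CO2": co2})
            z, _, _ = optimal_g6pdh(1.0, 0.0, env)
            F, _ = ppp_fraction(z, 1.0)
            assert F >= last
            last = F

    def test_environment_validation(self):
        with pytest.raises(ValueError):
            RBCEnvironment(x={"GLC": 1e-3})
        with pytest.raises(ValueError):
            RBCEnvironment(x={"GLC": 0.0, "LAC": 1e-3, "K": 1e-3, "NA": 1e-3, "CO2": 1e-3})
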