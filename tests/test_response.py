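"""Chain parametrization, response regimes and the antagonist extension."""

import numpy as np
import pytest

from tcrkp import (antagonist_asymptotics, antagonist_steady_state,
                   asymptotic_intermediate, asymptotic_small_L1,
                   backsubstitute, build_s_polynomial, characteristic_roots,
                   enumerate_steady_states, positive_roots, response_function,
                   solve_coefficients, solve_sigma,
                   steady_states_by_parametrization)

from conftest import random_params


class TestCharacteristicRoots:
    def test_straddle_one_and_vieta(self):
        rng = np.random.default_rng(61)
        for _ in range(100):
            p = random_params(rng)
            S = rng.uniform(0, p.ST)
            rm, rp = characteristic_roots(p, S)
            x = p.b + p.gamma * S
            assert rm < 1 < rp
            assert rm * rp == pytest.approx(p.phi / x, rel=1e-10)
            assert rm + rp == pytest.approx((p.phi + x + p.nu1) / x,
                                            rel=1e-10)
            # sharper upper bound used in the asymptotics
            assert rm < p.phi / (p.phi + p.nu1)

    def test_nu_zero_factorization(self):
        rng = np.random.default_rng(62)
        p = random_params(rng)
        S = 0.3 * p.ST
        x = p.b + p.gamma * S
        rm, rp = characteristic_roots(p, S, nu=0.0)
        assert sorted([rm, rp]) == pytest.approx(
            sorted([1.0, p.phi / x]), rel=1e-9)

    def test_degenerate_x_rejected(self, tristable_params):
        with pytest.raises(ValueError, match="positive"):
            characteristic_roots(tristable_params, 0.0)  # b = 0 here


class TestParametrization:
    def test_lemma_invariants_randomized(self):
        # r- < 1 < r+, a+- > 0, product identity, A > B and A > 0
        rng = np.random.default_rng(63)
        for _ in range(300):
            p = random_params(rng)
            S = rng.uniform(1e-6, p.ST * (1 - 1e-6))
            par = solve_coefficients(p, S)
            assert par.r_minus < 1 < par.r_plus
            assert par.a_minus > 0 and par.a_plus > 0
            assert par.A > 0 and par.A > par.B
            x = p.b + p.gamma * S
            # product identity, factors in cancellation-free form
            lhs = (x * par.r_minus ** 2 * (par.r_plus - 1.0)
                   * x * par.r_plus ** 2 * (par.r_minus - 1.0))
            rhs = -p.phi ** 2 * p.nu1 / x
            assert abs(lhs / rhs - 1) < 1e-6

    def test_alternate_coefficient_ratio_identity(self):
        # a+ = -a- (r-/r+)^(N+1) (r+-1)/(r--1)
        rng = np.random.default_rng(64)
        for _ in range(100):
            p = random_params(rng)
            S = rng.uniform(1e-6, p.ST * (1 - 1e-6))
            par = solve_coefficients(p, S)
            alt = (-par.a_minus * (par.r_minus / par.r_plus) ** (p.N + 1)
                   * (par.r_plus - 1) / (par.r_minus - 1))
            assert par.a_plus == pytest.approx(alt, rel=1e-9)

    def test_profile_sums_to_sigma_star(self):
        rng = np.random.default_rng(65)
        for _ in range(50):
            p = random_params(rng)
            sig = solve_sigma(p).sigma1
            S = rng.uniform(1e-6, p.ST * (1 - 1e-6))
            par = solve_coefficients(p, S, sig)
            assert par.profile(p.N).sum() == pytest.approx(sig, rel=1e-9)

    def test_profile_matches_backsubstitution(self, tristable_params):
        sig = solve_sigma(tristable_params)
        poly = build_s_polynomial(tristable_params, sig)
        for r in positive_roots(poly):
            ss = backsubstitute(tristable_params, sig, float(r))
            par = solve_coefficients(tristable_params, ss.S, sig.sigma1)
            assert np.allclose(par.profile(3), ss.C, rtol=1e-9)

    def test_parametrization_route_agrees_with_polynomial(self):
        rng = np.random.default_rng(66)
        for _ in range(100):
            p = random_params(rng, N=int(rng.integers(1, 4)))
            a = enumerate_steady_states(p)
            b = steady_states_by_parametrization(p)
            assert len(a) == len(b)
            for x, y in zip(a, b):
                scale = max(1.0, abs(x.S))
                assert abs(x.S - y.S) < 1e-8 * scale
                assert np.abs(x.C - y.C).max() < 1e-8


class TestResponseRegimes:
    def test_four_regimes_in_dose_response(self, dose_response_params):
        grid = np.geomspace(1e-4, 1e8, 140)
        curve = response_function(dose_response_params, L1_grid=grid,
                                  classify_branches=False)
        tab = curve.table.sort_values("logL1")
        assert tab.groupby("logL1").size().max() == 1  # monostable here
        x = tab["logL1"].to_numpy()
        y = tab["logCN"].to_numpy()
        low = x <= x[0] + 1
        slope = np.polyfit(x[low], y[low], 1)[0]
        assert abs(slope - 1) < 0.05
        dy = np.diff(y)
        falling = np.nonzero(dy < -1e-9)[0]
        assert falling.size > 0          # a strictly decreasing interval
        assert np.any(dy[falling[-1]:] > 1e-9)   # followed by increase
        sat_slope = np.polyfit(x[-15:], y[-15:], 1)[0]
        assert abs(sat_slope) < 0.05     # saturation at large dose
        assert curve.table["CN"].notna().all()

    def test_branches_match_enumeration(self, tristable_params):
        grid = np.geomspace(0.05, 5.0, 12)
        curve = response_function(tristable_params, L1_grid=grid)
        for L1, group in curve.table.groupby("logL1"):
            states = enumerate_steady_states(
                tristable_params.replace(L1=10 ** L1))
            assert len(group) == len(states)
            assert np.allclose(np.sort(group["S"].to_numpy()),
                               [s.S for s in states], rtol=1e-9)

    def test_interior_optimum_in_nu1(self, optimal_nu1_params):
        grid = np.geomspace(1e-6, 1e2, 90)
        curve = response_function(optimal_nu1_params, nu1_grid=grid,
                                  classify_branches=False)
        g = curve.table.groupby("nu1")["CN"].max()
        k = int(np.argmax(g.to_numpy()))
        assert 0 < k < len(g) - 1
        assert g.iloc[k] > 2 * g.iloc[0]
        assert g.iloc[k] > 2 * g.iloc[-1]


class TestAsymptotics:
    def test_small_dose_leading_term(self, dose_response_params):
        p = dose_response_params
        for L1, tol in [(10.0, 0.05), (0.1, 5e-3)]:
            exact = enumerate_steady_states(p.replace(L1=L1))[0].CN
            lead = float(asymptotic_small_L1(p, L1)["leading"])
            assert abs(lead / exact - 1) < tol
        # exactly linear in L1: slope one on a log-log plot
        L = np.array([1e-4, 1e-3])
        lead = asymptotic_small_L1(p, L)["leading"]
        assert np.log10(lead[1] / lead[0]) == pytest.approx(1.0, abs=1e-12)

    def test_correction_bracket_is_an_interval(self, dose_response_params):
        out = asymptotic_small_L1(dose_response_params, 5.0)
        assert out["lower"] < out["upper"]
        assert out["upper"] == out["leading"]

    def test_intermediate_scaling_exponents(self, dose_response_params):
        p = dose_response_params.replace(ST=6e7)
        a1 = float(asymptotic_intermediate(p, 1.0)["approx"])
        a4 = float(asymptotic_intermediate(p, 4.0)["approx"])
        # N = 3: C_N ~ L1^(-1/2), decreasing in dose
        assert a4 / a1 == pytest.approx(0.5, rel=1e-12)
        # increasing in nu1 through ((kR + nu1)/kR)^(1/2)
        b1 = float(asymptotic_intermediate(p.replace(nu1=4 * p.nu1), 1.0)
                   ["approx"])
        assert b1 > a1
        # N = 2: no L1 dependence at leading order
        p2 = p.replace(N=2)
        assert (float(asymptotic_intermediate(p2, 1.0)["approx"])
                == pytest.approx(float(asymptotic_intermediate(p2, 4.0)
                                       ["approx"]), rel=1e-12))

    def test_error_contract_as_ST_grows(self, dose_response_params):
        # deeper into the regime (larger ST at fixed dose) the relative
        # error of the intermediate approximation shrinks
        errs = []
        for ST in [6e5, 6e6, 6e7]:
            p = dose_response_params.replace(ST=ST, L1=10.0)
            exact = max(s.CN for s in enumerate_steady_states(p))
            approx = float(asymptotic_intermediate(p, 10.0)["approx"])
            errs.append(abs(approx / exact - 1))
        assert errs[0] > errs[1] > errs[2]

    def test_regime_violation_flagged(self, dose_response_params):
        out = asymptotic_intermediate(dose_response_params, 10.0)
        assert out["regime_ok"] is False

    def test_preconditions_enforced(self, dose_response_params):
        with pytest.raises(ValueError, match="kappa"):
            asymptotic_intermediate(
                dose_response_params.replace(kappa=1e-9), 1.0)
        with pytest.raises(ValueError, match="L1/R"):
            asymptotic_intermediate(dose_response_params, 1e9)


class TestAntagonist:
    def test_small_L2_limit_recovers_agonist_only(self, dose_response_params):
        p0 = dose_response_params.replace(L1=5.0)
        ref = enumerate_steady_states(p0)
        p = p0.replace(L2=1e-9, nu2=5e-2)
        states = antagonist_steady_state(p)
        assert len(states) == len(ref)
        for a, b in zip(ref, states):
            assert b.S == pytest.approx(a.S, rel=1e-6)
            assert (b.state.C[-1] + b.state.D[-1]
                    == pytest.approx(a.CN, rel=1e-6))

    def test_residuals_small_and_chains_differ_only_via_nu(self,
                                                           dose_response_params):
        p = dose_response_params.replace(L1=5.0, L2=20.0, nu2=5e-2)
        states = antagonist_steady_state(p)
        assert states
        for ss in states:
            assert ss.residual < 1e-6
            rmC, rpC = characteristic_roots(p, ss.S, p.nu1)
            rmD, rpD = characteristic_roots(p, ss.S, p.nu2)
            # same S, different dissociation rate: r- ordering follows nu
            assert (rmC < rmD) == (p.nu1 > p.nu2)
            assert (rpC > rpD) == (p.nu1 > p.nu2)

    def test_more_antagonist_less_response(self, dose_response_params):
        # deep intermediate regime: response falls as L2 grows although
        # L1 is fixed and receptor occupancy is negligible
        base = dose_response_params.replace(ST=6e9, L1=0.5, nu2=5e-2)
        outputs = []
        for L2 in [0.5, 1.0, 2.0]:
            p = base.replace(L2=L2)
            outputs.append(max(s.state.C[-1] + s.state.D[-1]
                               for s in antagonist_steady_state(p)))
            assert outputs[-1] > 0
        assert outputs[0] > outputs[1] > outputs[2]
        approx = [antagonist_asymptotics(base.replace(L2=L2))
                  for L2 in [0.5, 1.0, 2.0]]
        assert approx[0] > approx[1] > approx[2]

    def test_asymptotics_match_exact_in_regime(self, dose_response_params):
        p = dose_response_params.replace(ST=6e9, L1=0.5, L2=1.0, nu2=5e-2)
        exact = max(s.state.C[-1] + s.state.D[-1]
                    for s in antagonist_steady_state(p))
        assert abs(antagonist_asymptotics(p) / exact - 1) < 0.10

    def test_asymptotics_reduce_to_agonist_only(self, dose_response_params):
        p = dose_response_params.replace(ST=6e7, L1=0.5)
        with_zero = antagonist_asymptotics(p)
        agonist = float(asymptotic_intermediate(p, p.L1)["approx"])
        assert with_zero == pytest.approx(agonist, rel=1e-12)

    def test_symmetric_ligands_depend_on_total_dose(self, dose_response_params):
        p = dose_response_params.replace(ST=6e9, nu2=dose_response_params.nu1)
        a = antagonist_asymptotics(p.replace(L1=0.3, L2=0.7))
        b = antagonist_asymptotics(p.replace(L1=0.8, L2=0.2))
        assert a == pytest.approx(b, rel=1e-12)
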