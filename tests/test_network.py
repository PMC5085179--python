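"""Core mass-action dynamics: rate law, stoichiometric assembly, integration."""

import numpy as np
import pytest

from apopnet.network import (
    ExtraRateTerm,
    InvalidStateError,
    RateParameter,
    ReactionDef,
    ReactionNetwork,
    SolverOptions,
    SpeciesDef,
)

from conftest import random_network


def simple_conversion(k=2.0):
    return ReactionNetwork(
        species=[SpeciesDef("A", initial_amount=3.0), SpeciesDef("B")],
        reactions=[ReactionDef("r1", "k1", reactants={"A": 1}, products={"B": 1})],
        parameters=[RateParameter("k1", k)],
    )


def brute_force_rates(net, state):
    """Independent per-reaction loop oracle for the mass-action rate law."""
    out = []
    for rxn in net.reactions:
        r = net.parameters[rxn.rate_constant_id].value
        for sid, n in rxn.reactants.items():
            r *= state[net.species_index(sid)] ** n
        out.append(r)
    return np.array(out)


class TestEvaluateRates:
    def test_zero_state_gives_zero_rates(self, rng):
        net = random_network(rng)
        assert np.all(net.evaluate_rates(np.zeros(len(net.species))) == 0.0)

    def test_single_step_mass_action(self):
        net = simple_conversion(k=2.0)
        assert net.evaluate_rates(np.array([3.0, 0.0])) == pytest.approx([6.0])

    def test_matches_per_reaction_loop_oracle_on_random_networks(self, rng):
        for _ in range(100):
            net = random_network(rng, n_species=int(rng.integers(2, 7)),
                                 n_reactions=int(rng.integers(1, 10)))
            state = rng.uniform(0, 3, len(net.species))
            np.testing.assert_allclose(net.evaluate_rates(state),
                                       brute_force_rates(net, state), rtol=1e-12)

    def test_negative_state_beyond_tolerance_rejected(self):
        net = simple_conversion()
        with pytest.raises(InvalidStateError):
            net.evaluate_rates(np.array([-1.0, 0.0]))
        with pytest.raises(InvalidStateError):
            net.evaluate_rates(np.zeros(5))


class TestDerivative:
    def test_closed_conversion_conserves_mass(self):
        net = simple_conversion(k=0.7)
        d = net.derivative(np.array([3.0, 1.0]))
        assert d[0] == pytest.approx(-0.7 * 3.0)
        assert d[1] == pytest.approx(+0.7 * 3.0)
        assert d.sum() == pytest.approx(0.0, abs=1e-15)

    def test_matches_accumulation_oracle(self, rng):
        for _ in range(30):
            net = random_network(rng)
            state = rng.uniform(0, 2, len(net.species))
            rates = brute_force_rates(net, state)
            expected = np.zeros(len(net.species))
            for j, rxn in enumerate(net.reactions):
                for sid, n in rxn.reactants.items():
                    expected[net.species_index(sid)] -= n * rates[j]
                for sid, n in rxn.products.items():
                    expected[net.species_index(sid)] += n * rates[j]
            np.testing.assert_allclose(net.derivative(state), expected, rtol=1e-12)

    def test_linear_in_each_rate_constant(self, rng):
        net = random_network(rng)
        state = rng.uniform(0.1, 2, len(net.species))
        for pid in net.parameter_ids:
            base = net.with_parameter_value(pid, 0.0).derivative(state)
            d1 = net.with_parameter_value(pid, 1.3).derivative(state)
            d2 = net.with_parameter_value(pid, 2.6).derivative(state)
            np.testing.assert_allclose(d2 - base, 2.0 * (d1 - base), atol=1e-12)

    def test_zero_rate_constants_give_zero_derivative(self, rng):
        net = random_network(rng)
        for pid in net.parameter_ids:
            net = net.with_parameter_value(pid, 0.0)
        state = rng.uniform(0, 2, len(net.species))
        assert np.all(net.derivative(state) == 0.0)

    def test_negative_feedback_term_contribution(self):
        net = simple_conversion()
        netf = net.with_extra_terms([ExtraRateTerm("A", "B", "negative", 0.5)])
        state = np.array([2.0, 3.0])
        delta = netf.derivative(state) - net.derivative(state)
        np.testing.assert_allclose(delta, [0.0, -0.5 * 2.0 * 3.0])

    def test_clamped_input_derivative_is_zero(self):
        net = ReactionNetwork(
            species=[SpeciesDef("L", initial_amount=0.0, is_input=True),
                     SpeciesDef("X", initial_amount=1.0)],
            reactions=[ReactionDef("r", "k", reactants={"L": 1, "X": 1}, products={})],
            parameters=[RateParameter("k", 1.0)],
        )
        d = net.derivative(np.array([5.0, 1.0]))
        assert d[0] == 0.0 and d[1] < 0


class TestJacobian:
    def test_matches_finite_differences(self, rng):
        for _ in range(10):
            net = random_network(rng)
            state = rng.uniform(0.2, 2, len(net.species))
            J = net._jacobian(state)
            eps = 1e-7
            for i in range(len(state)):
                sp, sm = state.copy(), state.copy()
                sp[i] += eps
                sm[i] -= eps
                num = (net._derivative_raw(sp) - net._derivative_raw(sm)) / (2 * eps)
                np.testing.assert_allclose(J[:, i], num, rtol=1e-4, atol=1e-6)


class TestSimulate:
    def test_exponential_decay_closed_form(self):
        net = ReactionNetwork(
            species=[SpeciesDef("A", initial_amount=1.0)],
            reactions=[ReactionDef("r", "k", reactants={"A": 1}, products={})],
            parameters=[RateParameter("k", 1.0)],
        )
        traj = net.simulate(dose=0.0, t_end=5.0, n_points=50,
                            y0=np.array([1.0]))
        np.testing.assert_allclose(traj.states[:, 0], np.exp(-traj.times),
                                   rtol=1e-6, atol=1e-10)

    def test_no_stimulus_no_response(self, toy):
        traj = toy.network.simulate(dose=0.0, t_end=3600.0)
        c3 = traj.amounts("C3")
        assert np.all(c3 <= 1e-9)

    def test_supra_critical_switch_matches_fixed_step_rk_oracle(self, toy):
        """The executioner's delayed rise to its high plateau agrees with an
        independent fixed-step RK4 integration within 1%."""
        net = toy.network
        t_end = 2400.0
        traj = net.simulate(dose=1e-2, t_end=t_end, n_points=25)
        # RK4 oracle with a small fixed step
        y = net.initial_state()
        y[net.species_index("TNF")] = 1e-2
        h = 0.05
        out = [y.copy()]
        t_grid = traj.times
        k_next = 1
        t = 0.0
        f = net._derivative_raw
        while k_next < len(t_grid):
            k1 = f(y)
            k2 = f(y + 0.5 * h * k1)
            k3 = f(y + 0.5 * h * k2)
            k4 = f(y + h * k3)
            y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
            if t >= t_grid[k_next] - 1e-9:
                out.append(y.copy())
                k_next += 1
        oracle = np.array(out)
        c3 = traj.amounts("C3")
        c3_oracle = oracle[:, net.species_index("C3")]
        assert c3[-1] > 0.4  # reached the high branch
        np.testing.assert_allclose(c3, c3_oracle, rtol=0.01, atol=5e-4)

    def test_all_amounts_nonnegative_within_solver_slack(self, toy):
        opts = SolverOptions()
        traj = toy.network.simulate(dose=5e-3, t_end=7200.0, solver_opts=opts)
        assert traj.states.min() >= -10 * opts.rtol

    def test_moiety_conservation_along_trajectory(self, toy):
        """Left-null-space combinations of nu stay constant during integration."""
        net = toy.network
        cons = net.conserved_moieties()
        traj = net.simulate(dose=1e-2, t_end=7200.0)
        vals = traj.states @ cons.T
        np.testing.assert_allclose(vals, np.broadcast_to(vals[0], vals.shape),
                                   rtol=1e-6, atol=1e-8)


class TestSteadyState:
    def test_closed_two_state_detailed_balance(self):
        """A <-> B with equal rates settles to half the conserved total each."""
        net = ReactionNetwork(
            species=[SpeciesDef("I", initial_amount=0.0, is_input=True),
                     SpeciesDef("A", initial_amount=1.5),
                     SpeciesDef("B", initial_amount=0.5)],
            reactions=[ReactionDef("f", "kf", reactants={"A": 1}, products={"B": 1}),
                       ReactionDef("b", "kb", reactants={"B": 1}, products={"A": 1})],
            parameters=[RateParameter("kf", 1.0), RateParameter("kb", 1.0)],
        )
        res = net.steady_state(dose=0.0)
        assert res.converged
        assert res.state[1] == pytest.approx(1.0, rel=1e-6)
        assert res.state[2] == pytest.approx(1.0, rel=1e-6)

    def test_branches_match_long_horizon_integration(self, toy):
        """Low and high branch values agree with a 10x-longer pure integration
        (no Newton polish) within 0.1%."""
        net = toy.network
        long_opts = SolverOptions(t_max=10 * SolverOptions().t_max, ss_tol=1e-11)
        long_opts_no_polish = long_opts
        for dose in (1e-3, 1e-2):
            fast = net.steady_state(dose)
            # long-horizon oracle: raw chunked integration from scratch
            slow = net.steady_state(dose, solver_opts=long_opts_no_polish)
            assert fast.converged and slow.converged
            c3 = net.species_index("C3")
            assert fast.state[c3] == pytest.approx(slow.state[c3], rel=1e-3)

    def test_non_convergence_is_flagged_not_raised(self):
        # undamped-ish slow relaxation cut off by a tiny horizon
        net = ReactionNetwork(
            species=[SpeciesDef("I", initial_amount=0.0, is_input=True),
                     SpeciesDef("A", initial_amount=1.0)],
            reactions=[ReactionDef("r", "k", reactants={"A": 1}, products={})],
            parameters=[RateParameter("k", 1e-7)],
        )
        res = net.steady_state(dose=0.0, solver_opts=SolverOptions(t_max=10.0,
                                                                   t_chunk0=1.0))
        assert not res.converged
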