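"""Entropy production, exchange, equilibrium reference and pathway partition."""

import math

import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

import efmentropy as ef
from efmentropy.efm import find_mode
from efmentropy.entropy import R_GAS

# a strictly positive, well-scaled reactor composition (A, 2RD, 1RD, 1RL, 2RL)
conc_strategy = st.lists(
    st.floats(1e-8, 1e-3), min_size=5, max_size=5
).map(lambda c: np.array(c))


class TestEquilibriumReference:
    def test_closed_form(self, hypercycle, fig_params):
        """[A]eq = M/(1 + 2ka/k-a + 2kb/k-b); replicators at their
        detailed-balance ratios, racemic."""
        M = 1e-4
        comp = {"A": M, "2RD": 0, "1RD": 0, "1RL": 0, "2RL": 0}
        ref = ef.equilibrium_reference(hypercycle, comp)
        Ka = fig_params.ka / fig_params.k_minus_a      # 1000
        Kb = fig_params.kb / fig_params.k_minus_b      # 2000
        A_eq = M / (1 + 2 * Ka + 2 * Kb)
        assert ref.total_mass == pytest.approx(M)
        assert ref.of("A", hypercycle) == pytest.approx(A_eq, rel=1e-12)
        for sp in ("1RD", "1RL"):
            assert ref.of(sp, hypercycle) == pytest.approx(Ka * A_eq, rel=1e-12)
        for sp in ("2RD", "2RL"):
            assert ref.of(sp, hypercycle) == pytest.approx(Kb * A_eq, rel=1e-12)

    def test_detailed_balance_residuals_vanish(self, hypercycle, equilibrium_ref):
        v = ef.rate_vector(hypercycle, equilibrium_ref.c_eq)
        for fi, ri in hypercycle.reversible_pairs():
            vf, vr = v[fi - 1], v[ri - 1]
            assert vf == pytest.approx(vr, rel=1e-12)

    def test_depends_only_on_total_mass(self, hypercycle):
        """A fully chiral composition racemizes to the same reference as a
        racemic one of equal chemical mass."""
        chiral = {"A": 2e-5, "2RD": 0, "1RD": 0, "1RL": 4e-5, "2RL": 4e-5}
        racemic = {"A": 2e-5, "2RD": 2e-5, "1RD": 2e-5, "1RL": 2e-5, "2RL": 2e-5}
        ra = ef.equilibrium_reference(hypercycle, chiral)
        rb = ef.equilibrium_reference(hypercycle, racemic)
        np.testing.assert_allclose(ra.c_eq, rb.c_eq, rtol=1e-12)
        assert ra.c_eq[1] == pytest.approx(ra.c_eq[4], rel=1e-12)  # racemic

    def test_weak_binding_limit(self):
        """As both equilibrium ratios vanish, all mass sits in the resource."""
        params = ef.HypercycleParams(ka=1e-20, kb=1e-21)
        net = ef.build_hypercycle_network(params)
        ref = ef.equilibrium_reference(net, {"A": 1e-4, "2RD": 0, "1RD": 0,
                                             "1RL": 0, "2RL": 0})
        assert ref.of("A", net) == pytest.approx(1e-4, rel=1e-9)

    def test_zero_reverse_constant_rejected(self):
        net = ef.build_hypercycle_network(ef.HypercycleParams(k_minus_a=0.0))
        with pytest.raises(ef.NetworkError):
            ef.equilibrium_reference(net, {"A": 1e-4, "2RD": 0, "1RD": 0,
                                           "1RL": 0, "2RL": 0})

    def test_closed_system_relaxes_to_reference(self):
        """Long closed-system integration (f=0) lands on the computed
        detailed-balance equilibrium.

        The run starts from a perturbed equilibrium composition: the slowest
        closed-system mode (exchange between the two replicator pools
        through the minute pool of free A) has a ~2e9 s timescale, so a
        1e11 s horizon gives full convergence.
        """
        params = ef.HypercycleParams(q=0.0, delta=0.0)
        net = ef.build_hypercycle_network(params)
        base = ef.equilibrium_reference(
            net, {"A": 1e-4, "2RD": 0, "1RD": 0, "1RL": 0, "2RL": 0})
        c0 = base.c_eq * np.array([2.0, 0.7, 1.4, 1.4, 0.7])
        ref = ef.equilibrium_reference(net, c0)
        traj = ef.simulate(net, params, t_end=1e11,
                           grid=ef.GridSpec(points_per_decade=40),
                           conc0=dict(zip(net.species.labels, c0)),
                           chi0=(0.0, 0.0))
        M = traj.concentrations.sum(axis=1)
        np.testing.assert_allclose(M, M[0], rtol=1e-9)  # mass conserved
        np.testing.assert_allclose(traj.final_concentrations, ref.c_eq, rtol=1e-9)


class TestEntropyProduction:
    def test_zero_at_equilibrium(self, hypercycle, equilibrium_ref):
        assert ef.entropy_production(hypercycle, equilibrium_ref.c_eq) == \
            pytest.approx(0.0, abs=1e-25)

    @given(c=conc_strategy)
    def test_nonnegative(self, c):
        net = ef.build_hypercycle_network()
        assert ef.entropy_production(net, c) >= 0.0

    @given(c=conc_strategy)
    def test_racemic_states_split_evenly(self, c):
        """At a racemic composition the D-sector partial entropies equal
        their L-sector mirrors."""
        net = ef.build_hypercycle_network()
        racemic = np.array([c[0], c[1], c[2], c[2], c[1]])
        ref = ef.equilibrium_reference(net, racemic)
        perm = net.parity_transformation_permutation()
        for i in net.indices:
            a = ef.partial_entropy_transformation(net, racemic, ref, i)
            b = ef.partial_entropy_transformation(net, racemic, ref, perm[i])
            assert a == pytest.approx(b, rel=1e-12, abs=1e-300)


class TestStationaryEntropyFromCurrents:
    def test_closed_currents_alone_produce_nothing(self, modes, hypercycle,
                                                   mode_by_label):
        """Only the open unidirectional pathways drive production."""
        j = np.zeros(9)
        for label in ("E1", "E2", "E3", "E4", "E5"):
            j[mode_by_label[label]] = 1e-10
        assert ef.ness_entropy_from_j(j, modes, hypercycle) == 0.0

    def test_independent_of_flow_through_current(self, modes, hypercycle,
                                                 mode_by_label):
        j = np.full(9, 1e-11)
        a = ef.ness_entropy_from_j(j, modes, hypercycle)
        j2 = j.copy()
        j2[mode_by_label["E5"]] *= 1e6
        assert ef.ness_entropy_from_j(j2, modes, hypercycle) == pytest.approx(a, rel=1e-12)

    def test_one_sided_current_reports_infinity(self, modes, hypercycle,
                                                mode_by_label):
        j = np.zeros(9)
        j[mode_by_label["E8"]] = 1e-11  # forward column 1 with no reverse current
        assert math.isinf(ef.ness_entropy_from_j(j, modes, hypercycle))


class TestPartialEntropies:
    def test_forward_form_is_symbolically_the_rate_log_ratio(self):
        """R·k+[A][B][C]·ln(k+[A]/k−[B]) equals R·v_f·ln(v_f/v_r) for the
        catalytic step A+B+C → 2B+C."""
        kp, km, A, B, C = sympy.symbols("k_p k_m A B C", positive=True)
        vf = kp * A * B * C
        vr = km * B**2 * C
        assert sympy.simplify(sympy.log(vf / vr) - sympy.log(kp * A / (km * B))) == 0

    @given(c=conc_strategy)
    def test_pair_partials_sum_to_production_term(self, c):
        net = ef.build_hypercycle_network()
        ref = ef.equilibrium_reference(net, c)
        v = ef.rate_vector(net, c)
        for fi, ri in net.reversible_pairs():
            pair_term = R_GAS * (v[fi - 1] - v[ri - 1]) * math.log(v[fi - 1] / v[ri - 1])
            a = ef.partial_entropy_transformation(net, c, ref, fi)
            b = ef.partial_entropy_transformation(net, c, ref, ri)
            assert a + b == pytest.approx(pair_term, rel=1e-10, abs=1e-300)

    @given(c=conc_strategy)
    def test_flow_partials_sum_to_minus_exchange(self, c):
        net = ef.build_hypercycle_network()
        ref = ef.equilibrium_reference(net, c)
        flows = sum(
            ef.partial_entropy_transformation(net, c, ref, t.index)
            for t in net.transformations if t.kind in ("inflow", "outflow")
        )
        sigma_e = ef.exchange_entropy(net, c, ref)
        assert flows == pytest.approx(-sigma_e, rel=1e-10, abs=1e-300)

    def test_outflow_at_equilibrium_concentration_vanishes(self, hypercycle,
                                                           equilibrium_ref):
        c = equilibrium_ref.c_eq
        assert ef.partial_entropy_transformation(hypercycle, c, equilibrium_ref, 14) == 0.0

    def test_exchange_entropy_zero_at_equilibrium(self, hypercycle, equilibrium_ref):
        assert ef.exchange_entropy(hypercycle, equilibrium_ref.c_eq,
                                   equilibrium_ref) == pytest.approx(0.0, abs=1e-300)

    def test_exchange_entropy_zero_without_flow(self):
        params = ef.HypercycleParams(q=0.0)
        net = ef.build_hypercycle_network(params)
        ref = ef.equilibrium_reference(net, {"A": 1e-4, "2RD": 1e-5, "1RD": 1e-5,
                                             "1RL": 1e-5, "2RL": 1e-5})
        c = np.array([1e-4, 1e-5, 2e-5, 3e-5, 4e-5])
        assert ef.exchange_entropy(net, c, ref) == 0.0


class TestWeightsAndBalance:
    def test_stoichiometric_weights(self, hypercycle, modes):
        w = ef.efm_weights(modes, hypercycle)
        assert w[13] == pytest.approx(1 / 5)   # inflow of A feeds five pathways
        assert w[9] == pytest.approx(1 / 2)    # forward catalysis on two pathways
        assert w[2] == 1 and w[14] == 1 and w[5] == 1

    def test_weight_completeness(self, hypercycle, modes):
        """Each transformation's weight, summed over the pathways containing
        it, is exactly 1 — the combinatorial fact behind the balance identity."""
        w = ef.efm_weights(modes, hypercycle)
        for i in hypercycle.indices:
            total = sum(w[i] for m in modes if i in m.support)
            assert total == 1

    @given(c=conc_strategy)
    def test_balance_identity_at_arbitrary_states(self, c):
        """Σσ(Eᵢ) = σ − σ_e pointwise, not only at stationary states."""
        net = ef.build_hypercycle_network()
        ms = ef.enumerate_efms(net)
        ref = ef.equilibrium_reference(net, c)
        led = ef.make_ledger(net, c, ref, ms)
        scale = max(abs(led.sigma), abs(led.sigma_e), 1e-300)
        assert abs(led.balance_residual) <= 1e-12 * scale

    def test_parity_permutes_pathway_entropies(self, hypercycle, modes):
        c = np.array([1e-4, 1e-6, 2e-6, 3e-6, 4e-6])
        mirrored = c[[0, 4, 3, 2, 1]]
        ref = ef.equilibrium_reference(hypercycle, c)
        per, _ = ef.partial_entropy_efm(hypercycle, c, ref, modes)
        per_m, _ = ef.partial_entropy_efm(hypercycle, mirrored, ref, modes)
        for i, m in enumerate(modes):
            assert per_m[m.parity_partner] == pytest.approx(per[i], rel=1e-12)
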