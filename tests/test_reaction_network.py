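"""Unit and property tests for the reaction-network core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egfrsim import (
    RateLaw,
    Reaction,
    ReactionNetwork,
    Species,
    mass_action_rate,
    michaelis_menten_rate,
    ode_rhs,
    stoichiometry_matrix,
    validate_network,
)
from egfrsim.errors import ContractError, IntegrityError, NumericalError, ValidationError
from egfrsim.reaction_network import (
    MASS_ACTION_IRREVERSIBLE,
    MASS_ACTION_REVERSIBLE,
    MICHAELIS_MENTEN,
    OPAQUE_EXPRESSION,
    conserved_moieties,
)

IRR = MASS_ACTION_IRREVERSIBLE
REV = MASS_ACTION_REVERSIBLE


class TestSpecies:
    def test_rejects_negative_initial_amount(self):
        with pytest.raises(ValidationError):
            Species("X", initial_amount=-1.0)

    def test_rejects_unknown_compartment(self):
        with pytest.raises(ValidationError):
            Species("X", compartment="mitochondrion")

    def test_duplicate_id_rejected(self):
        net = ReactionNetwork()
        net.add_species(Species("X"))
        with pytest.raises(IntegrityError):
            net.add_species(Species("X"))


class TestMassActionRate:
    def test_empty_pool_gives_zero_rate(self):
        law = RateLaw(IRR, k1=3.7)
        assert mass_action_rate(law, [0.0, 12.0]) == 0.0

    def test_detailed_balance_point_gives_zero_net_rate(self):
        # k1·[EGF][EGFR] = kr1·[EGF-EGFR] => net rate 0
        law = RateLaw(REV, k1=0.003, kr1=0.06)
        egf, egfr = 10.0, 4.0
        complex_ = 0.003 * egf * egfr / 0.06
        assert mass_action_rate(law, [egf, egfr], [complex_]) == pytest.approx(0.0, abs=1e-15)

    def test_second_order_hand_multiplication(self):
        # 0.003 nM^-1 s^-1 · 10 nM · 5 nM = 0.15 nM/s (one-line oracle)
        law = RateLaw(IRR, k1=0.003)
        oracle = 0.003 * 10.0 * 5.0
        assert mass_action_rate(law, [10.0, 5.0]) == pytest.approx(oracle)
        assert oracle == pytest.approx(0.15)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            mass_action_rate(RateLaw(IRR, k1=1.0), [-1.0])

    def test_wrong_arity_rejected(self):
        with pytest.raises(ContractError):
            mass_action_rate(RateLaw(IRR, k1=1.0), [1.0, 2.0], reactant_stoich=[1])

    def test_wrong_form_rejected(self):
        with pytest.raises(ContractError):
            mass_action_rate(RateLaw(MICHAELIS_MENTEN, k2=1.0, Km=1.0), [1.0])

    @settings(max_examples=50, derandomize=True)
    @given(
        k1=st.floats(0, 1e3),
        concs=st.lists(st.floats(0, 1e4), min_size=1, max_size=4),
    )
    def test_irreversible_rate_nonnegative_on_nonnegative_states(self, k1, concs):
        assert mass_action_rate(RateLaw(IRR, k1=k1), concs) >= 0.0


class TestMichaelisMentenRate:
    def test_half_vmax_at_km_exactly(self):
        law = RateLaw(MICHAELIS_MENTEN, k2=0.7, Km=42.0)
        et = 11.0
        assert michaelis_menten_rate(law, 42.0, et) == law.vmax(et) / 2

    def test_zero_substrate_gives_zero_rate(self):
        law = RateLaw(MICHAELIS_MENTEN, k2=0.7, Km=42.0)
        assert michaelis_menten_rate(law, 0.0, 5.0) == 0.0

    def test_saturation_approaches_vmax(self):
        law = RateLaw(MICHAELIS_MENTEN, k2=0.7, Km=42.0)
        rate = michaelis_menten_rate(law, 1e6 * 42.0, 5.0)
        assert rate == pytest.approx(law.vmax(5.0), rel=1e-4)

    def test_km_must_be_positive(self):
        with pytest.raises(ValidationError):
            RateLaw(MICHAELIS_MENTEN, k2=1.0, Km=0.0)

    @settings(max_examples=50, derandomize=True)
    @given(s=st.floats(0, 1e6), s2=st.floats(0, 1e6))
    def test_monotone_and_bounded(self, s, s2):
        law = RateLaw(MICHAELIS_MENTEN, k2=0.5, Km=10.0)
        lo, hi = sorted((s, s2))
        r_lo = michaelis_menten_rate(law, lo, 3.0)
        r_hi = michaelis_menten_rate(law, hi, 3.0)
        assert r_lo <= r_hi <= law.vmax(3.0)

    def test_qss_agreement_with_full_catalytic_cycle(self, enzyme_network, mm_network):
        """MM rate matches the explicit E+S<->ES->E+P product flux within 2%
        in the validity regime Et << Km + [S]."""
        from egfrsim import SolverOptions, simulate

        # Et = 1, Km = 15, S = 100: Et/(Km+S) < 1%
        opts = SolverOptions(t_end=200.0)
        full = simulate(enzyme_network, opts)
        reduced = simulate(mm_network, opts)
        p_full = full.series("P")
        p_mm = reduced.series("P")
        # compare product formed after the fast pre-equilibration transient
        sel = full.times > 50.0
        assert np.allclose(p_mm[sel], p_full[sel], rtol=0.02)


class TestStoichiometryMatrix:
    def test_single_conversion_column(self, decay_network):
        mat = stoichiometry_matrix(decay_network)
        assert mat.tolist() == [[-1], [1]]

    def test_catalyst_conserved_over_cycle(self, enzyme_network):
        mat = stoichiometry_matrix(enzyme_network)
        idx = enzyme_network.species_index
        # E participates in both reactions but the catalytic cycle returns it
        assert mat[idx("E")].sum() == 0
        # E + ES is a conserved moiety: its row-sum vector annihilates N
        w = np.zeros(4)
        w[idx("E")] = w[idx("ES")] = 1
        assert np.all(w @ mat == 0)

    def test_modifiers_contribute_zero(self, mm_network):
        mat = stoichiometry_matrix(mm_network)
        assert np.all(mat[mm_network.species_index("E")] == 0)

    def test_dangling_reference_names_reaction(self):
        net = ReactionNetwork()
        net.add_species(Species("A"))
        net.reactions["bad"] = Reaction("bad", [("A", 1)], [("GHOST", 1)],
                                        rate_law=RateLaw(IRR, k1=1.0))
        with pytest.raises(IntegrityError, match="bad"):
            stoichiometry_matrix(net)


class TestOdeRhs:
    def test_all_zero_state_all_zero_derivatives(self, enzyme_network):
        dx = ode_rhs(enzyme_network, np.zeros(4))
        assert np.all(dx == 0)

    def test_first_order_decay_closed_form(self, decay_network):
        dx = ode_rhs(decay_network, [1.0, 0.0])
        assert dx == pytest.approx([-0.1, 0.1])

    def test_matches_handwritten_derivative_oracle(self, enzyme_network):
        """Elementwise agreement with hand-coded ODEs of the catalytic cycle."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            e, s, es, p = rng.uniform(0, 50, size=4)

            def oracle(e, s, es, p):
                v1 = 0.01 * e * s - 0.1 * es
                v2 = 0.05 * es
                return np.array([-v1 + v2, -v1, v1 - v2, v2])

            got = ode_rhs(enzyme_network, [e, s, es, p])
            assert np.allclose(got, oracle(e, s, es, p), atol=1e-12)

    def test_conserved_moieties_annihilate_rhs(self, enzyme_network):
        basis = conserved_moieties(enzyme_network)
        assert basis.shape[0] >= 2  # enzyme moiety and substrate moiety
        rng = np.random.default_rng(3)
        for _ in range(10):
            state = rng.uniform(0, 100, size=4)
            dx = ode_rhs(enzyme_network, state)
            assert np.allclose(basis @ dx, 0.0, atol=1e-12)

    def test_constant_species_derivative_forced_to_zero(self):
        net = ReactionNetwork()
        net.add_species(Species("bath", initial_amount=10.0, is_constant=True))
        net.add_species(Species("X"))
        net.add_reaction(Reaction("influx", [("bath", 1)], [("X", 1)],
                                  rate_law=RateLaw(IRR, k1=1.0)))
        dx = ode_rhs(net, [10.0, 0.0])
        assert dx[0] == 0.0 and dx[1] == pytest.approx(10.0)

    def test_state_length_mismatch_rejected(self, decay_network):
        with pytest.raises(ContractError):
            ode_rhs(decay_network, [1.0])

    def test_nonfinite_rate_names_reaction(self):
        net = ReactionNetwork()
        net.add_species(Species("A", initial_amount=1.0))
        net.add_reaction(Reaction(
            "divzero", [("A", 1)], [],
            rate_law=RateLaw(OPAQUE_EXPRESSION, expression="A / (A - A)"),
        ))
        with pytest.raises(NumericalError, match="divzero"):
            ode_rhs(net, [1.0])


class TestValidateNetwork:
    def test_empty_network_counts_zero_no_violations(self):
        report = validate_network(ReactionNetwork())
        assert report.counts == (0, 0, 0, 0)
        assert report.ok

    def test_unknown_species_reported_as_integrity_violation(self):
        net = ReactionNetwork()
        net.add_species(Species("A"))
        net.reactions["r"] = Reaction("r", [("A", 1)], [("GHOST", 1)],
                                      rate_law=RateLaw(IRR, k1=1.0))
        report = validate_network(net)
        assert len(report.dangling_references) == 1
        assert not report.ok

    def test_unreachable_species_reported(self):
        net = ReactionNetwork()
        net.add_species(Species("lonely"))
        report = validate_network(net)
        assert report.unreachable_species == ["lonely"]
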