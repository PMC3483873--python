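"""Shared fixtures: toy networks and session-scoped scenario simulations.

All fixtures are generated programmatically; the scenario trajectories are
simulated once per session because several test modules interrogate the same
runs (features, dominance, comparisons).
"""

import numpy as np
import pytest

from egfrsim import (
    RateLaw,
    Reaction,
    ReactionNetwork,
    Species,
    SolverOptions,
    build_scenario,
    simulate,
    standard_observables,
)
from egfrsim.calibration import build_mutant_receptor_model
from egfrsim.model_library import build_normal_model, set_egf
from egfrsim.reaction_network import (
    MASS_ACTION_IRREVERSIBLE,
    MASS_ACTION_REVERSIBLE,
    MICHAELIS_MENTEN,
)


@pytest.fixture()
def decay_network() -> ReactionNetwork:
    """S -> P, first order, k = 0.1 s^-1."""
    net = ReactionNetwork("decay")
    net.add_species(Species("S", initial_amount=1.0))
    net.add_species(Species("P"))
    net.add_reaction(
        Reaction("conv", [("S", 1)], [("P", 1)],
                 rate_law=RateLaw(MASS_ACTION_IRREVERSIBLE, k1=0.1))
    )
    return net


@pytest.fixture()
def enzyme_network() -> ReactionNetwork:
    """Full catalytic cycle E + S <-> ES -> E + P in mass action."""
    net = ReactionNetwork("enzyme")
    for sid, init in (("E", 1.0), ("S", 100.0), ("ES", 0.0), ("P", 0.0)):
        net.add_species(Species(sid, initial_amount=init))
    net.add_reaction(
        Reaction("bind", [("E", 1), ("S", 1)], [("ES", 1)],
                 rate_law=RateLaw(MASS_ACTION_REVERSIBLE, k1=0.01, kr1=0.1))
    )
    net.add_reaction(
        Reaction("cat", [("ES", 1)], [("E", 1), ("P", 1)],
                 rate_law=RateLaw(MASS_ACTION_IRREVERSIBLE, k1=0.05))
    )
    return net


@pytest.fixture()
def mm_network() -> ReactionNetwork:
    """Same catalytic step expressed as a Michaelis-Menten reaction."""
    net = ReactionNetwork("mm")
    for sid, init in (("E", 1.0), ("S", 100.0), ("P", 0.0)):
        net.add_species(Species(sid, initial_amount=init))
    net.add_reaction(
        Reaction("cat", [("S", 1)], [("P", 1)], modifiers=["E"],
                 rate_law=RateLaw(MICHAELIS_MENTEN, k2=0.05, Km=(0.1 + 0.05) / 0.01))
    )
    return net


@pytest.fixture(scope="session")
def solver_options() -> SolverOptions:
    return SolverOptions()


@pytest.fixture(scope="session")
def scenario_trajectories(solver_options):
    """One simulation per study scenario, shared across the whole session."""
    names = ("normal", "nsclc", "nsclc_pten_loss", "nsclc_erlotinib",
             "nsclc_pten_loss_erlotinib")
    return {name: simulate(build_scenario(name), solver_options) for name in names}


@pytest.fixture(scope="session")
def receptor_trajectories():
    """Wild-type vs mutant-receptor runs at equal expression (internalization
    contrast), on a short horizon covering the 100 s fit window."""
    opts = SolverOptions(t_end=400.0)
    wt = build_normal_model()
    set_egf(wt, 50.0)
    return {
        "wt": simulate(wt, opts),
        "mutant": simulate(build_mutant_receptor_model(), opts),
    }


@pytest.fixture(scope="session")
def observables():
    return standard_observables(build_scenario("normal"))


@pytest.fixture(scope="session")
def features_by_scenario(scenario_trajectories, observables):
    from egfrsim.kinetics_features import extract_features

    out = {}
    for name, traj in scenario_trajectories.items():
        out[name] = {
            obs_name: extract_features(traj.observable(obs), traj.times)
            for obs_name, obs in observables.items()
        }
    return out
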