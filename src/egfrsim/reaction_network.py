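"""Core data model for chemical reaction networks.

A :class:`ReactionNetwork` holds species, reactions with mass-action or
Michaelis–Menten rate laws, assignment rules and global parameters, and can
assemble the right-hand side of the corresponding ODE system::

    dx/dt = N · v(x, t)

where ``N`` is the stoichiometry matrix (species × reactions) and ``v`` the
per-reaction rate vector.  All concentrations are in nM and all times in
seconds; rate constants are s⁻¹ (first order), nM⁻¹s⁻¹ (second order) or
nM·s⁻¹ (zeroth order / Vmax).

The module is deliberately free of any biology: the EGFR models are built on
top of it by :mod:`egfrsim.model_library`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .errors import ContractError, IntegrityError, NumericalError, ValidationError
from .expressions import compile_expression, names_in

COMPARTMENTS = frozenset(
    {"extracellular", "membrane", "cytoplasm", "nucleus", "endosome"}
)

MASS_ACTION_IRREVERSIBLE = "mass_action_irreversible"
MASS_ACTION_REVERSIBLE = "mass_action_reversible"
MICHAELIS_MENTEN = "michaelis_menten"
OPAQUE_EXPRESSION = "opaque_expression"

RATE_LAW_FORMS = frozenset(
    {MASS_ACTION_IRREVERSIBLE, MASS_ACTION_REVERSIBLE, MICHAELIS_MENTEN, OPAQUE_EXPRESSION}
)


@dataclass
class Species:
    """A chemical species.

    Parameters
    ----------
    id :
        Unique short name within a network, e.g. ``"pEGF-EGFR2"``.
    compartment :
        One of ``extracellular, membrane, cytoplasm, nucleus, endosome``.
    initial_amount :
        Initial concentration in nM; must be non-negative.
    is_constant :
        If true the species is clamped (a drug bath, a buffered pool): its
        derivative is forced to zero.
    """

    id: str
    compartment: str = "cytoplasm"
    initial_amount: float = 0.0
    is_constant: bool = False
    display_name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("species id must be non-empty")
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"species {self.id!r}: compartment {self.compartment!r} not in {sorted(COMPARTMENTS)}"
            )
        if not (self.initial_amount >= 0):
            raise ValidationError(
                f"species {self.id!r}: initial_amount must be >= 0, got {self.initial_amount}"
            )
        if not self.display_name:
            self.display_name = self.id


@dataclass
class RateLaw:
    """Kinetic law of a single reaction.

    ``mass_action_irreversible``
        rate = k1 · ∏ [reactant]^stoich
    ``mass_action_reversible``
        rate = k1 · ∏ [reactant]^stoich − kr1 · ∏ [product]^stoich
    ``michaelis_menten``
        rate = k2 · Et · [S] / (Km + [S]),  Vmax = k2 · Et with Et the total
        modifier (enzyme) concentration.  Vmax is always derived, never stored.
    ``opaque_expression``
        An arbitrary arithmetic expression over species/parameter ids, used
        for imported kinetic laws that match neither pattern.
    """

    form: str
    k1: float = 0.0
    kr1: float = 0.0
    k2: float = 0.0
    Km: float = 0.0
    expression: str | None = None

    def __post_init__(self) -> None:
        if self.form not in RATE_LAW_FORMS:
            raise ContractError(f"unknown rate-law form {self.form!r}")
        for name in ("k1", "kr1", "k2", "Km"):
            if getattr(self, name) < 0:
                raise ValidationError(f"rate constant {name} must be >= 0")
        if self.form == MICHAELIS_MENTEN and not self.Km > 0:
            raise ValidationError("michaelis_menten requires Km > 0")
        if self.form == OPAQUE_EXPRESSION and not self.expression:
            raise ValidationError("opaque_expression requires an expression string")

    def vmax(self, enzyme_total: float) -> float:
        """Maximum rate ``k2 · Et`` in nM·s⁻¹ (Michaelis–Menten form only)."""
        if self.form != MICHAELIS_MENTEN:
            raise ContractError("Vmax is defined only for the michaelis_menten form")
        return self.k2 * enzyme_total


@dataclass
class Reaction:
    """A reaction: reactants → products, optionally catalysed by modifiers.

    ``reactants`` and ``products`` are lists of ``(species_id, stoichiometric
    coefficient)`` with positive integer coefficients.  Modifiers (enzymes) are
    consumed by neither side and contribute zero to the stoichiometry matrix.
    """

    id: str
    reactants: list[tuple[str, int]] = field(default_factory=list)
    products: list[tuple[str, int]] = field(default_factory=list)
    modifiers: list[str] = field(default_factory=list)
    rate_law: RateLaw = field(default_factory=lambda: RateLaw(MASS_ACTION_IRREVERSIBLE))

    def __post_init__(self) -> None:
        for side in (self.reactants, self.products):
            for sid, coeff in side:
                if not (isinstance(coeff, int) and coeff > 0):
                    raise ValidationError(
                        f"reaction {self.id!r}: stoichiometric coefficient for {sid!r} "
                        f"must be a positive integer, got {coeff!r}"
                    )
        if self.rate_law.form == MICHAELIS_MENTEN:
            if len(self.reactants) != 1:
                raise ValidationError(
                    f"reaction {self.id!r}: michaelis_menten requires exactly one substrate"
                )
            if not self.modifiers:
                raise ValidationError(
                    f"reaction {self.id!r}: michaelis_menten requires at least one modifier (enzyme)"
                )


@dataclass
class Rule:
    """An assignment rule: ``target := expression``, re-evaluated at every step."""

    id: str
    target: str
    expression: str


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_network`."""

    n_species: int
    n_reactions: int
    n_parameters: int
    n_rules: int
    dangling_references: list[str] = field(default_factory=list)
    negative_values: list[str] = field(default_factory=list)
    unreachable_species: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.dangling_references or self.negative_values)

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.n_species, self.n_reactions, self.n_parameters, self.n_rules)


class ReactionNetwork:
    """A named collection of species, reactions, rules and global parameters.

    Species order is insertion order and defines the state-vector layout used
    by :func:`stoichiometry_matrix` and :func:`ode_rhs`.
    """

    def __init__(self, name: str = "network"):
        self.name = name
        self.species: dict[str, Species] = {}
        self.reactions: dict[str, Reaction] = {}
        self.rules: dict[str, Rule] = {}
        self.parameters: dict[str, float] = {}
        self.metadata: dict = {}
        self._rev = 0

    # -- construction -------------------------------------------------------

    def add_species(self, species: Species) -> Species:
        if species.id in self.species:
            raise IntegrityError(f"duplicate species id {species.id!r}")
        self.species[species.id] = species
        self._rev += 1
        return species

    def add_reaction(self, reaction: Reaction) -> Reaction:
        if reaction.id in self.reactions:
            raise IntegrityError(f"duplicate reaction id {reaction.id!r}")
        self.reactions[reaction.id] = reaction
        self._rev += 1
        return reaction

    def add_rule(self, rule: Rule) -> Rule:
        if rule.id in self.rules:
            raise IntegrityError(f"duplicate rule id {rule.id!r}")
        self.rules[rule.id] = rule
        self._rev += 1
        return rule

    def set_parameter(self, name: str, value: float) -> None:
        self.parameters[name] = float(value)
        self._rev += 1

    def touch(self) -> None:
        """Invalidate compiled caches after in-place edits of species/reactions."""
        self._rev += 1

    def copy(self, name: str | None = None) -> "ReactionNetwork":
        """Deep, independent copy (metadata shallow-copied per key)."""
        import copy as _copy

        out = ReactionNetwork(name or self.name)
        out.species = _copy.deepcopy(self.species)
        out.reactions = _copy.deepcopy(self.reactions)
        out.rules = _copy.deepcopy(self.rules)
        out.parameters = dict(self.parameters)
        out.metadata = _copy.deepcopy(self.metadata)
        return out

    # -- queries ------------------------------------------------------------

    @property
    def species_ids(self) -> list[str]:
        return list(self.species)

    def species_index(self, sid: str) -> int:
        try:
            return self.species_ids.index(sid)
        except ValueError:
            raise IntegrityError(f"species id {sid!r} does not resolve in this network")

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_amount for s in self.species.values()], dtype=float)

    def counts(self) -> tuple[int, int, int, int]:
        """(species, reactions, parameters, rules).

        The parameter count includes both global parameters and the kinetic
        constants carried by rate laws (one per constant actually used by the
        form), matching the bookkeeping convention of SBML local parameters.
        """
        n_kinetic = 0
        for rxn in self.reactions.values():
            law = rxn.rate_law
            if law.form == MASS_ACTION_IRREVERSIBLE:
                n_kinetic += 1
            elif law.form == MASS_ACTION_REVERSIBLE:
                n_kinetic += 2
            elif law.form == MICHAELIS_MENTEN:
                n_kinetic += 2
        return (
            len(self.species),
            len(self.reactions),
            len(self.parameters) + n_kinetic,
            len(self.rules),
        )


# -- rate laws ---------------------------------------------------------------


def mass_action_rate(
    law: RateLaw,
    reactant_concentrations: Sequence[float],
    product_concentrations: Sequence[float] = (),
    reactant_stoich: Sequence[int] | None = None,
    product_stoich: Sequence[int] | None = None,
) -> float:
    """Net mass-action rate in nM·s⁻¹ (positive = net forward).

    ``k1 · ∏ [reactant]^n − kr1 · ∏ [product]^m`` for the reversible form; the
    reverse term is dropped for the irreversible form.
    """
    if law.form not in (MASS_ACTION_IRREVERSIBLE, MASS_ACTION_REVERSIBLE):
        raise ContractError(f"mass_action_rate called with form {law.form!r}")
    if reactant_stoich is not None and len(reactant_stoich) != len(reactant_concentrations):
        raise ContractError("reactant stoichiometry arity does not match concentrations")
    if product_stoich is not None and len(product_stoich) != len(product_concentrations):
        raise ContractError("product stoichiometry arity does not match concentrations")
    for c in (*reactant_concentrations, *product_concentrations):
        if c < 0:
            raise ValidationError(f"negative concentration {c} in mass_action_rate")
    r_st = reactant_stoich or [1] * len(reactant_concentrations)
    forward = law.k1 * math.prod(c**n for c, n in zip(reactant_concentrations, r_st))
    if law.form == MASS_ACTION_IRREVERSIBLE:
        return forward
    p_st = product_stoich or [1] * len(product_concentrations)
    reverse = law.kr1 * math.prod(c**n for c, n in zip(product_concentrations, p_st))
    return forward - reverse


def michaelis_menten_rate(law: RateLaw, substrate: float, enzyme_total: float) -> float:
    """Michaelis–Menten rate ``k2 · Et · [S] / (Km + [S])`` in nM·s⁻¹.

    Monotone non-decreasing in [S], bounded above by Vmax = k2·Et, and equal to
    Vmax/2 exactly at [S] = Km.
    """
    if law.form != MICHAELIS_MENTEN:
        raise ContractError(f"michaelis_menten_rate called with form {law.form!r}")
    if law.Km <= 0:
        raise ValidationError("michaelis_menten requires Km > 0")
    if substrate < 0 or enzyme_total < 0:
        raise ValidationError("negative concentration in michaelis_menten_rate")
    return law.k2 * enzyme_total * substrate / (law.Km + substrate)


# -- ODE assembly ------------------------------------------------------------


def stoichiometry_matrix(network: ReactionNetwork) -> np.ndarray:
    """Integer net-stoichiometry matrix, shape (n_species, n_reactions).

    Entry (i, j) is the product coefficient minus the reactant coefficient of
    species i in reaction j; modifiers contribute zero.
    """
    ids = network.species_ids
    index = {sid: i for i, sid in enumerate(ids)}
    mat = np.zeros((len(ids), len(network.reactions)), dtype=int)
    for j, rxn in enumerate(network.reactions.values()):
        for sid, coeff in rxn.reactants:
            if sid not in index:
                raise IntegrityError(
                    f"reaction {rxn.id!r} references unknown species {sid!r}"
                )
            mat[index[sid], j] -= coeff
        for sid, coeff in rxn.products:
            if sid not in index:
                raise IntegrityError(
                    f"reaction {rxn.id!r} references unknown species {sid!r}"
                )
            mat[index[sid], j] += coeff
        for sid in rxn.modifiers:
            if sid not in index:
                raise IntegrityError(
                    f"reaction {rxn.id!r} references unknown modifier {sid!r}"
                )
    return mat


class CompiledRHS:
    """Pre-indexed evaluator of reaction rates and the ODE right-hand side.

    Compilation resolves all species references to integer indices once so the
    per-step cost is a plain loop over reactions; stiff solvers call the RHS
    thousands of times per trajectory.
    """

    def __init__(self, network: ReactionNetwork):
        self.network = network
        self.ids = network.species_ids
        index = {sid: i for i, sid in enumerate(self.ids)}
        self.n_species = len(self.ids)
        self.stoich = stoichiometry_matrix(network).astype(float)
        self.constant_mask = np.array(
            [s.is_constant for s in network.species.values()], dtype=bool
        )
        self.reaction_ids = list(network.reactions)

        self._records = []
        needs_env = bool(network.rules)
        for rxn in network.reactions.values():
            law = rxn.rate_law
            r_idx = np.array([index[s] for s, _ in rxn.reactants], dtype=int)
            r_st = np.array([c for _, c in rxn.reactants], dtype=float)
            p_idx = np.array([index[s] for s, _ in rxn.products], dtype=int)
            p_st = np.array([c for _, c in rxn.products], dtype=float)
            m_idx = np.array([index[s] for s in rxn.modifiers], dtype=int)
            if law.form == OPAQUE_EXPRESSION:
                fn = compile_expression(law.expression)
                missing = names_in(law.expression) - set(index) - set(network.parameters) - {"t"}
                if missing:
                    raise IntegrityError(
                        f"reaction {rxn.id!r}: expression references unknown ids {sorted(missing)}"
                    )
                self._records.append(("expr", fn, None, None, None, None))
                needs_env = True
            else:
                self._records.append((law.form, law, r_idx, r_st, p_idx, p_st if law.form == MASS_ACTION_REVERSIBLE else m_idx))
        self._needs_env = needs_env
        # species targeted by assignment rules are clamped to their rule value
        self._rule_fns = []
        for rule in network.rules.values():
            fn = compile_expression(rule.expression)
            tgt = index.get(rule.target)
            self._rule_fns.append((rule.target, tgt, fn))
            if tgt is not None:
                self.constant_mask = self.constant_mask.copy()
                self.constant_mask[tgt] = True

    def _env(self, state: np.ndarray, t: float) -> dict:
        env = dict(zip(self.ids, state))
        env.update(self.network.parameters)
        env["t"] = t
        return env

    def apply_rules(self, state: np.ndarray, t: float) -> np.ndarray:
        """Evaluate assignment rules, returning a state with rule targets set."""
        if not self._rule_fns:
            return state
        state = state.copy()
        env = self._env(state, t)
        for target, tgt, fn in self._rule_fns:
            value = fn(env)
            if tgt is not None:
                if value < 0:
                    raise ValidationError(
                        f"rule for {target!r} produced a negative concentration {value}"
                    )
                state[tgt] = value
                env[target] = value
            else:
                env[target] = value
                self.network.parameters[target] = value
        return state

    def rates(self, state: np.ndarray, t: float = 0.0) -> np.ndarray:
        """Per-reaction rate vector v(x, t) in nM·s⁻¹ on the clipped state."""
        x = np.where(state > 0, state, 0.0)
        x = self.apply_rules(x, t)
        env = self._env(x, t) if self._needs_env else None
        v = np.empty(len(self._records))
        for j, rec in enumerate(self._records):
            kind = rec[0]
            if kind == MASS_ACTION_IRREVERSIBLE:
                _, law, r_idx, r_st, _, _ = rec
                v[j] = law.k1 * np.prod(x[r_idx] ** r_st)
            elif kind == MASS_ACTION_REVERSIBLE:
                _, law, r_idx, r_st, p_idx, p_st = rec
                v[j] = law.k1 * np.prod(x[r_idx] ** r_st) - law.kr1 * np.prod(
                    x[p_idx] ** p_st
                )
            elif kind == MICHAELIS_MENTEN:
                _, law, r_idx, r_st, p_idx, m_idx = rec
                s = x[r_idx[0]]
                et = float(np.sum(x[m_idx]))
                v[j] = law.k2 * et * s / (law.Km + s)
            else:  # opaque expression
                v[j] = rec[1](env)
        if not np.all(np.isfinite(v)):
            bad = self.reaction_ids[int(np.argmin(np.isfinite(v)))]
            raise NumericalError(f"non-finite rate in reaction {bad!r} at t={t}")
        return v

    def __call__(self, t: float, state: np.ndarray) -> np.ndarray:
        dx = self.stoich @ self.rates(state, t)
        dx[self.constant_mask] = 0.0
        return dx


def compile_rhs(network: ReactionNetwork) -> CompiledRHS:
    """Compile (and cache on the network) the ODE right-hand side."""
    cached = getattr(network, "_rhs_cache", None)
    if cached is not None and cached[0] == network._rev:
        return cached[1]
    rhs = CompiledRHS(network)
    network._rhs_cache = (network._rev, rhs)
    return rhs


def ode_rhs(network: ReactionNetwork, state: Sequence[float], time: float = 0.0) -> np.ndarray:
    """Derivative vector dx/dt = N·v(x, t) in nM·s⁻¹.

    Constant species and assignment-rule targets have their derivative forced
    to zero; a NaN/Inf rate raises :class:`NumericalError` naming the reaction.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (len(network.species),):
        raise ContractError(
            f"state length {state.shape} does not match species count {len(network.species)}"
        )
    return compile_rhs(network)(time, state)


def conserved_moieties(network: ReactionNetwork, tol: float = 1e-10) -> np.ndarray:
    """Basis of conserved linear combinations (left null vectors of N).

    Each row w satisfies w·dx/dt = 0 for every state, so w·x is a conserved
    moiety total of the closed sub-system it spans.
    """
    from scipy.linalg import null_space

    mat = stoichiometry_matrix(network).astype(float)
    basis = null_space(mat.T, rcond=tol)
    return basis.T


def validate_network(network: ReactionNetwork) -> ValidationReport:
    """Referential-integrity and sanity report (never raises).

    Reports dangling species references, negative constants/initial amounts,
    species appearing in no reaction, and the (species, reactions, parameters,
    rules) counts.
    """
    dangling: list[str] = []
    negative: list[str] = []
    used: set[str] = set()
    for sp in network.species.values():
        if sp.initial_amount < 0:
            negative.append(f"species {sp.id}: initial_amount {sp.initial_amount}")
    for rxn in network.reactions.values():
        for sid, _ in (*rxn.reactants, *rxn.products):
            used.add(sid)
            if sid not in network.species:
                dangling.append(f"reaction {rxn.id}: unknown species {sid!r}")
        for sid in rxn.modifiers:
            used.add(sid)
            if sid not in network.species:
                dangling.append(f"reaction {rxn.id}: unknown modifier {sid!r}")
        law = rxn.rate_law
        for name in ("k1", "kr1", "k2", "Km"):
            if getattr(law, name) < 0:
                negative.append(f"reaction {rxn.id}: {name} < 0")
    for rule in network.rules.values():
        for name in names_in(rule.expression):
            if name not in network.species and name not in network.parameters and name != "t":
                dangling.append(f"rule {rule.id}: unknown id {name!r}")
        if rule.target not in network.species and rule.target not in network.parameters:
            dangling.append(f"rule {rule.id}: unknown target {rule.target!r}")
    unreachable = [sid for sid in network.species if sid not in used]
    n_sp, n_rx, n_par, n_ru = network.counts()
    return ValidationReport(
        n_species=n_sp,
        n_reactions=n_rx,
        n_parameters=n_par,
        n_rules=n_ru,
        dangling_references=dangling,
        negative_values=negative,
        unreachable_species=unreachable,
    )
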