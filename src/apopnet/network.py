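"""Mass-action reaction networks and their deterministic dynamics.

A :class:`ReactionNetwork` couples species amounts ``C`` (amol) to reaction
rates ``J`` through the stoichiometric matrix ``nu``::

    dC/dt = nu @ J(C) + extra feedback terms

where each reaction obeys the law of mass action,
``J_B = k_B * prod_r C_r ** stoich(r)`` over the reactants ``r`` of reaction
``B``.  One species may be flagged as the clamped input (the sustained
stimulus); its derivative is forced to zero during integration.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SpeciesDef",
    "ReactionDef",
    "RateParameter",
    "ExtraRateTerm",
    "ReactionNetwork",
    "Trajectory",
    "SteadyStateResult",
    "SolverOptions",
    "InvalidStateError",
    "IntegrationError",
    "PARAMETER_CATEGORIES",
]

PARAMETER_CATEGORIES = frozenset(
    {"association", "dissociation", "degradation", "enzymatic", "production"}
)


class InvalidStateError(ValueError):
    """A species-amount vector violated a precondition (wrong length, negative)."""


class IntegrationError(RuntimeError):
    """The stiff integrator failed; carries the solver's diagnostic message."""


@dataclass(frozen=True)
class SpeciesDef:
    id: str
    name: str = ""
    initial_amount: float = 0.0
    is_input: bool = False

    def __post_init__(self):
        if self.initial_amount < 0:
            raise ValueError(f"species {self.id}: initial_amount must be >= 0")


@dataclass(frozen=True)
class ReactionDef:
    """One mass-action reaction: reactants -> products at rate k * prod C^stoich."""

    id: str
    rate_constant_id: str
    reactants: dict[str, int] = field(default_factory=dict)
    products: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for side in (self.reactants, self.products):
            for sid, n in side.items():
                if not (isinstance(n, (int, np.integer)) and n > 0):
                    raise ValueError(
                        f"reaction {self.id}: stoichiometry of {sid} must be a "
                        f"positive integer, got {n!r}"
                    )


@dataclass(frozen=True)
class RateParameter:
    id: str
    value: float
    category: str = "enzymatic"

    def __post_init__(self):
        if self.value < 0:
            raise ValueError(f"parameter {self.id}: value must be >= 0")
        if self.category not in PARAMETER_CATEGORIES:
            raise ValueError(
                f"parameter {self.id}: unknown category {self.category!r}"
            )


@dataclass(frozen=True)
class ExtraRateTerm:
    """A rate term injected directly into one species' balance equation.

    ``sign='positive'`` adds ``+strength * [source]`` to the target derivative
    (a production term); ``sign='negative'`` adds
    ``-strength * [source] * [target]`` (a bimolecular degradation term).
    """

    source: str
    target: str
    sign: str
    strength: float

    def __post_init__(self):
        if self.sign not in ("positive", "negative"):
            raise ValueError(f"sign must be 'positive' or 'negative', got {self.sign!r}")
        if self.strength < 0:
            raise ValueError("strength must be >= 0")


@dataclass
class SolverOptions:
    """Integration defaults tuned for stiff signaling kinetics (amounts in amol)."""

    rtol: float = 1e-8
    atol: float = 1e-12
    method: str = "LSODA"
    ss_tol: float = 1e-9  # relative-derivative steady-state criterion
    t_max: float = 48.0 * 3600.0  # steady-state search horizon, seconds
    t_chunk0: float = 300.0  # first integration chunk for the steady-state loop
    chunk_growth: float = 2.0
    max_step: float = np.inf
    polish: bool = True  # Newton-refine near-steady states (see steady_state)


@dataclass
class Trajectory:
    times: np.ndarray  # strictly increasing, seconds
    states: np.ndarray  # (n_times, n_species) amounts in amol
    dose: float
    species_ids: list[str]

    def amounts(self, species_id: str) -> np.ndarray:
        return self.states[:, self.species_ids.index(species_id)]


@dataclass
class SteadyStateResult:
    state: np.ndarray
    converged: bool
    t_reached: float
    max_rel_derivative: float


class ReactionNetwork:
    """An ordered collection of species, mass-action reactions and parameters."""

    def __init__(
        self,
        species: list[SpeciesDef],
        reactions: list[ReactionDef],
        parameters: list[RateParameter],
        extra_rate_terms: list[ExtraRateTerm] | None = None,
    ):
        ids = [s.id for s in species]
        if len(set(ids)) != len(ids):
            raise ValueError("species ids must be unique")
        pids = [p.id for p in parameters]
        if len(set(pids)) != len(pids):
            raise ValueError("parameter ids must be unique")

        self.species = list(species)
        self.reactions = list(reactions)
        self.parameters = {p.id: p for p in parameters}
        self.extra_rate_terms = list(extra_rate_terms or [])

        self._sidx = {s.id: i for i, s in enumerate(self.species)}
        n_s, n_r = len(self.species), len(self.reactions)

        # reactant-order matrix alpha and net stoichiometry nu (species x reactions)
        self._alpha = np.zeros((n_s, n_r))
        self.stoichiometric_matrix = np.zeros((n_s, n_r), dtype=int)
        for j, rxn in enumerate(self.reactions):
            if rxn.rate_constant_id not in self.parameters:
                raise ValueError(
                    f"reaction {rxn.id}: unknown rate constant {rxn.rate_constant_id!r}"
                )
            for sid, n in rxn.reactants.items():
                self._require_species(sid, rxn.id)
                self._alpha[self._sidx[sid], j] = n
                self.stoichiometric_matrix[self._sidx[sid], j] -= n
            for sid, n in rxn.products.items():
                self._require_species(sid, rxn.id)
                self.stoichiometric_matrix[self._sidx[sid], j] += n

        self._k = np.array(
            [self.parameters[r.rate_constant_id].value for r in self.reactions]
        )
        # sparse triplets of the reactant-order matrix, for the hot rate kernel
        sp, rx = np.nonzero(self._alpha)
        self._r_sp, self._r_rxn = sp, rx
        self._r_exp = self._alpha[sp, rx]
        self._nu_f = self.stoichiometric_matrix.astype(float)
        inputs = [i for i, s in enumerate(self.species) if s.is_input]
        if len(inputs) > 1:
            raise ValueError("at most one species may be flagged is_input")
        self._input_index = inputs[0] if inputs else None

        for term in self.extra_rate_terms:
            self._require_species(term.source, "extra term")
            self._require_species(term.target, "extra term")

    # ------------------------------------------------------------------ helpers

    def _require_species(self, sid: str, where: str) -> None:
        if sid not in self._sidx:
            raise ValueError(f"{where}: unknown species {sid!r}")

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def parameter_ids(self) -> list[str]:
        return list(self.parameters.keys())

    @property
    def input_species_id(self) -> str | None:
        return None if self._input_index is None else self.species[self._input_index].id

    def species_index(self, sid: str) -> int:
        return self._sidx[sid]

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_amount for s in self.species])

    def copy(self) -> "ReactionNetwork":
        return ReactionNetwork(
            self.species, self.reactions, list(self.parameters.values()),
            list(self.extra_rate_terms),
        )

    def with_parameter_value(self, parameter_id: str, value: float) -> "ReactionNetwork":
        """Return a copy with one rate constant replaced; self is untouched."""
        if parameter_id not in self.parameters:
            raise KeyError(f"unknown parameter {parameter_id!r}")
        params = [
            replace(p, value=value) if p.id == parameter_id else p
            for p in self.parameters.values()
        ]
        return ReactionNetwork(self.species, self.reactions, params,
                               list(self.extra_rate_terms))

    def with_extra_terms(self, terms: list[ExtraRateTerm]) -> "ReactionNetwork":
        return ReactionNetwork(self.species, self.reactions,
                               list(self.parameters.values()),
                               self.extra_rate_terms + list(terms))

    def content_hash(self) -> str:
        """Stable hash of topology, parameter values and extra terms (for caches)."""
        import hashlib

        h = hashlib.sha256()
        for s in self.species:
            h.update(f"{s.id}|{s.initial_amount!r}|{s.is_input}".encode())
        for r in self.reactions:
            h.update(
                f"{r.id}|{r.rate_constant_id}|{sorted(r.reactants.items())}|"
                f"{sorted(r.products.items())}".encode()
            )
        for p in self.parameters.values():
            h.update(f"{p.id}|{p.value!r}|{p.category}".encode())
        for t in self.extra_rate_terms:
            h.update(f"{t.source}|{t.target}|{t.sign}|{t.strength!r}".encode())
        return h.hexdigest()[:16]

    # ------------------------------------------------------------------ dynamics

    def _validate_state(self, state: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        state = np.asarray(state, dtype=float)
        if state.shape != (len(self.species),):
            raise InvalidStateError(
                f"state length {state.shape} != species count {len(self.species)}"
            )
        if np.any(state < -tol):
            bad = [self.species[i].id for i in np.where(state < -tol)[0]]
            raise InvalidStateError(f"negative amounts beyond tolerance: {bad}")
        return np.clip(state, 0.0, None)

    def _rates_raw(self, state: np.ndarray) -> np.ndarray:
        # J_B = k_B * prod over reactants of C^stoich, via sparse triplets
        J = self._k.copy()
        np.multiply.at(J, self._r_rxn,
                       np.maximum(state[self._r_sp], 0.0) ** self._r_exp)
        return J

    def evaluate_rates(self, state: np.ndarray) -> np.ndarray:
        """Mass-action rate of every reaction at the given state (amol/s)."""
        return self._rates_raw(self._validate_state(state))

    def _derivative_raw(self, state: np.ndarray) -> np.ndarray:
        dC = self._nu_f @ self._rates_raw(state)
        for term in self.extra_rate_terms:
            si, ti = self._sidx[term.source], self._sidx[term.target]
            if term.sign == "positive":
                dC[ti] += term.strength * state[si]
            else:
                dC[ti] -= term.strength * state[si] * state[ti]
        if self._input_index is not None:
            dC[self._input_index] = 0.0  # sustained stimulus: clamp
        return dC

    def derivative(self, state: np.ndarray) -> np.ndarray:
        """dC/dt = nu @ J plus injected feedback terms; clamped input held at 0."""
        return self._derivative_raw(self._validate_state(state))

    def _jacobian(self, state: np.ndarray) -> np.ndarray:
        """Analytic Jacobian of the derivative (speeds up the stiff solvers)."""
        state = np.maximum(state, 0.0)
        n_s, n_r = self._alpha.shape
        dJ = np.zeros((n_r, n_s))
        rates = self._rates_raw(state)
        for j in range(n_r):
            idx = np.nonzero(self._alpha[:, j])[0]
            for i in idx:
                a = self._alpha[i, j]
                others = self._k[j] * a
                for m in idx:
                    am = self._alpha[m, j]
                    if m == i:
                        if a > 1:
                            others *= state[m] ** (am - 1)
                    else:
                        others *= state[m] ** am
                dJ[j, i] = others
        J = self.stoichiometric_matrix @ dJ
        for term in self.extra_rate_terms:
            si, ti = self._sidx[term.source], self._sidx[term.target]
            if term.sign == "positive":
                J[ti, si] += term.strength
            else:
                J[ti, si] -= term.strength * state[ti]
                J[ti, ti] -= term.strength * state[si]
        if self._input_index is not None:
            J[self._input_index, :] = 0.0
        return J

    def _apply_dose(self, dose: float) -> np.ndarray:
        if self._input_index is None:
            raise ValueError("network has no is_input species to clamp")
        y0 = self.initial_state()
        y0[self._input_index] = dose
        return y0

    def simulate(
        self,
        dose: float,
        t_end: float,
        solver_opts: SolverOptions | None = None,
        n_points: int = 600,
        y0: np.ndarray | None = None,
    ) -> Trajectory:
        """Integrate the clamped-stimulus ODEs and return a dense trajectory."""
        if dose < 0:
            raise ValueError("dose must be >= 0")
        if t_end <= 0:
            raise ValueError("t_end must be > 0")
        opts = solver_opts or SolverOptions()
        if y0 is None:
            y0 = self._apply_dose(dose)
        ts = np.linspace(0.0, t_end, n_points)
        sol = solve_ivp(
            lambda t, y: self._derivative_raw(y),
            (0.0, t_end),
            y0,
            method=opts.method,
            t_eval=ts,
            rtol=opts.rtol,
            atol=opts.atol,
            max_step=opts.max_step,
            jac=lambda t, y: self._jacobian(y),
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed at dose={dose}, t_end={t_end}: {sol.message}"
            )
        states = sol.y.T.copy()
        # clip solver undershoot below atol to exactly zero
        states[(states < 0) & (states > -10 * opts.atol - 10 * opts.rtol)] = 0.0
        return Trajectory(times=sol.t.copy(), states=states, dose=dose,
                          species_ids=self.species_ids)

    def steady_state(
        self,
        dose: float,
        solver_opts: SolverOptions | None = None,
        y0: np.ndarray | None = None,
    ) -> SteadyStateResult:
        """Integrate in growing chunks until the relative derivative settles.

        Convergence requires ``max |dC/dt| / (1 + |C|) < ss_tol`` at the two most
        recent checkpoints (a window spanning >= 5% of elapsed time, since
        chunks grow geometrically); otherwise the result is flagged
        non-converged at ``t_max``.

        Once the relative derivative falls below 1e3 * ss_tol, a Newton root
        solve is attempted from the current point; the root is accepted only
        if it stays in the same basin (componentwise close to the integrated
        state), is non-negative, and is linearly stable.  Near a saddle-node
        ghost no fixed point exists and the polish is rejected, so the slow
        transient is integrated through honestly.
        """
        if dose < 0:
            raise ValueError("dose must be >= 0")
        opts = solver_opts or SolverOptions()
        y = self._apply_dose(dose) if y0 is None else np.asarray(y0, dtype=float).copy()
        t, chunk = 0.0, opts.t_chunk0
        prev_ok = False
        max_rel = np.inf
        polish_at = 1e3 * opts.ss_tol
        while t < opts.t_max:
            t_next = min(t + chunk, opts.t_max)
            sol = solve_ivp(
                lambda tt, yy: self._derivative_raw(yy),
                (t, t_next),
                y,
                method=opts.method,
                rtol=opts.rtol,
                atol=opts.atol,
                max_step=opts.max_step,
                jac=lambda tt, yy: self._jacobian(yy),
            )
            if not sol.success:
                raise IntegrationError(
                    f"steady-state integration failed at dose={dose}, "
                    f"t={t}: {sol.message}"
                )
            y = sol.y[:, -1]
            y[(y < 0) & (y > -10 * opts.atol - 10 * opts.rtol)] = 0.0
            t = t_next
            max_rel = float(np.max(np.abs(self._derivative_raw(y)) / (1.0 + np.abs(y))))
            ok = max_rel < opts.ss_tol
            if ok and prev_ok:
                return SteadyStateResult(state=y, converged=True, t_reached=t,
                                         max_rel_derivative=max_rel)
            if opts.polish and max_rel < polish_at:
                y_pol = self._polish_steady_state(y, opts)
                if y_pol is not None:
                    rel = float(np.max(np.abs(self._derivative_raw(y_pol))
                                       / (1.0 + np.abs(y_pol))))
                    if rel < opts.ss_tol:
                        return SteadyStateResult(state=y_pol, converged=True,
                                                 t_reached=t, max_rel_derivative=rel)
            prev_ok = ok
            chunk *= opts.chunk_growth
        return SteadyStateResult(state=y, converged=max_rel < opts.ss_tol,
                                 t_reached=t, max_rel_derivative=max_rel)

    def _polish_steady_state(
        self, y: np.ndarray, opts: SolverOptions
    ) -> np.ndarray | None:
        """Newton-refine a near-steady state; None if rejected (see steady_state)."""
        from scipy.optimize import root

        free = np.ones(len(self.species), dtype=bool)
        if self._input_index is not None:
            free[self._input_index] = False
        y_full = y.copy()

        def fun(z):
            y_full[free] = z
            return self._derivative_raw(y_full)[free]

        def jac(z):
            y_full[free] = z
            return self._jacobian(y_full)[np.ix_(free, free)]

        sol = root(fun, y[free], jac=jac, method="hybr")
        if not sol.success:
            return None
        z = sol.x
        scale = 1.0 + np.abs(y[free])
        if np.any(np.abs(z - y[free]) > 0.05 * scale):
            return None  # jumped out of the basin
        if np.any(z < -10 * opts.atol):
            return None
        y_full[free] = np.clip(z, 0.0, None)
        eig = np.linalg.eigvals(self._jacobian(y_full)[np.ix_(free, free)])
        if np.max(eig.real) > 0:
            return None  # unstable fixed point (e.g. the switch saddle)
        return y_full.copy()

    def conserved_moieties(self) -> np.ndarray:
        """Basis of species combinations conserved along trajectories.

        These are left-null-space vectors of nu with zero weight on the
        clamped input species (whose balance is overridden by the clamp).
        Injected feedback terms are not represented in nu, so the result is
        only meaningful for networks without extra terms.
        """
        from scipy.linalg import null_space

        nu = self.stoichiometric_matrix.astype(float)
        keep = np.ones(nu.shape[0], dtype=bool)
        if self._input_index is not None:
            keep[self._input_index] = False
        ns = null_space(nu[keep].T)
        out = np.zeros((ns.shape[1], nu.shape[0]))
        out[:, keep] = ns.T
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ReactionNetwork({len(self.species)} species, "
            f"{len(self.reactions)} reactions, {len(self.parameters)} parameters, "
            f"{len(self.extra_rate_terms)} extra terms)"
        )
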