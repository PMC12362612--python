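"""Declarative model library for the controlled multistable gene networks.

Every dynamical variant studied — the (unbalanced) toggle switch, the toggle
with self-activation, the mutual-activation motif, and each of these closed in
feedback with one or two adaptive sequestration controllers — is expressed as a
:class:`ModelSpec`: an ordered species list plus a list of typed rate terms.
From that single description both the mass-action ODE right-hand side
(:func:`rhs`) and the stochastic reaction channels (:func:`reactions`) are
derived, so the deterministic and Gillespie views of a model can never drift
apart.

The adaptive controller is the incoherent-feedforward / sequestration circuit:
the sensed species drives production of an intermediate X (rate θ) and of a
sequestering species U2 (rate ξ); X catalyses production of the output U1
(rate k); U1 and U2 annihilate pairwise at rate γ; everything decays at δ.
The output (U1, or U2 in the swapped-input variants) actuates a target species
either additively (+β·u) or through saturated degradation (−β·u·y/(y+K)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .params import KineticParams, ParameterError

__all__ = [
    "Term", "Reaction", "ControllerConfig", "ControllerRealization", "ModelSpec",
    "ModelError", "hill",
    "make_toggle", "make_isolated_controller", "make_controlled_toggle",
    "make_toggle_selfactivation", "make_controlled_mutual_activation",
    "make_controlled_tristable", "rhs", "reactions",
]

SPECIES_ORDER = ("Y1", "Y2", "X", "U1", "U2", "Xp", "U1p", "U2p")

REPRESSING = "repressing"
ACTIVATING = "activating"
ADDITIVE = "additive_activation"
DEGRADATION = "saturated_degradation"


class ModelError(ValueError):
    """Raised for inconsistent model or controller configurations."""


def hill(y, K: float, m: int, regulation: str):
    """Hill regulation function: K^m/(K^m+y^m) (repressing) or y^m/(K^m+y^m)."""
    y = np.asarray(y, dtype=float)
    Km = K ** m
    ym = y ** m
    if regulation == REPRESSING:
        return Km / (Km + ym)
    if regulation == ACTIVATING:
        return ym / (Km + ym)
    raise ModelError(f"unknown regulation {regulation!r}")


@dataclass(frozen=True)
class Term:
    """One additive rate term of the ODE system.

    kinds
    -----
    hill_production        d[target]/dt += rate * hill(source; K, m, regulation)
    linear_production      d[target]/dt += rate * [source]      (catalytic)
    input_production       d[target]/dt += rate * input_fn(t)   (exogenous drive)
    linear_decay           d[target]/dt -= rate * [target]
    sequestration          d[target]/dt -= rate*[target]*[partner] (and same on partner)
    additive_control       d[target]/dt += rate * [source]
    mm_degradation_control d[target]/dt -= rate*[source]*[target]/([target]+K)
    """

    kind: str
    target: str
    rate: float
    source: str | None = None
    partner: str | None = None
    K: float | None = None
    m: int | None = None
    regulation: str | None = None


@dataclass(frozen=True)
class Reaction:
    """A stochastic reaction channel: integer stoichiometry + propensity law.

    ``propensity(conc_state)`` evaluates the concentration-scale rate (μM/h);
    the SSA converts it to a count-scale propensity at system size Ω.
    """

    name: str
    stoichiometry: np.ndarray
    propensity: Callable[[np.ndarray], float]
    term: Term


@dataclass(frozen=True)
class ControllerConfig:
    """Architecture choices for one adaptive controller.

    ``sense_species``/``sense_regulation`` define the Hill function p(y) that
    drives X and U2 production. ``input_species`` selects which controller
    species actuates the network, ``actuation`` how (+β·u or −β·u·y/(y+K)),
    and ``target_species`` where. ``duplicated='double'`` adds a mirrored
    second controller (gain β′) acting on the other endogenous species.
    Sensing the target under target-raising actuation closes a negative
    feedback loop; sensing the non-target closes a positive one.
    """

    sense_species: str = "Y1"
    sense_regulation: str = REPRESSING
    input_species: str = "U1"
    actuation: str = ADDITIVE
    target_species: str = "Y1"
    duplicated: str = "single"

    def __post_init__(self) -> None:
        if self.sense_species not in ("Y1", "Y2"):
            raise ModelError(f"sense_species must be Y1 or Y2, got {self.sense_species!r}")
        if self.sense_regulation not in (REPRESSING, ACTIVATING):
            raise ModelError(f"invalid sense_regulation {self.sense_regulation!r}")
        if self.input_species not in ("U1", "U2"):
            raise ModelError(f"input_species must be U1 or U2, got {self.input_species!r}")
        if self.actuation not in (ADDITIVE, DEGRADATION):
            raise ModelError(f"invalid actuation {self.actuation!r}")
        if self.target_species not in ("Y1", "Y2"):
            raise ModelError(f"target_species must be Y1 or Y2, got {self.target_species!r}")
        if self.duplicated not in ("single", "double"):
            raise ModelError(f"duplicated must be 'single' or 'double', got {self.duplicated!r}")

    @property
    def feedback_sign(self) -> str:
        """Derived label: 'negative' if sensing the target species under a
        target-raising actuation (and mirror cases), else 'positive'."""
        senses_target = self.sense_species == self.target_species
        return "negative" if senses_target else "positive"

    def mirrored(self) -> "ControllerConfig":
        """The species-swapped (Y1 <-> Y2) copy used by double controllers."""
        swap = {"Y1": "Y2", "Y2": "Y1"}
        return replace(self, sense_species=swap[self.sense_species],
                       target_species=swap[self.target_species], duplicated="single")


def negative_feedback(**kw) -> ControllerConfig:
    """Controller sensing its own target Y1 (repressing Hill, U1 input)."""
    return ControllerConfig(sense_species="Y1", **kw)


def positive_feedback(**kw) -> ControllerConfig:
    """Controller sensing the non-target species Y2 (repressing Hill, U1 input)."""
    return ControllerConfig(sense_species="Y2", **kw)


@dataclass(frozen=True)
class ControllerRealization:
    """A controller instance wired into a concrete spec (possibly primed)."""

    sense_species: str
    sense_regulation: str
    input_species: str        # concrete species name actuating the target
    actuation: str
    target_species: str
    gain: float
    x_name: str
    u1_name: str
    u2_name: str


@dataclass(frozen=True)
class ModelSpec:
    """A species list + typed rate terms defining one ODE/CRN variant."""

    name: str
    species: tuple[str, ...]
    params: KineticParams
    terms: tuple[Term, ...]
    controllers: tuple[ControllerRealization, ...] = ()
    input_fn: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        for t in self.terms:
            for s in (t.target, t.source, t.partner):
                if s is not None and s != "__input__" and s not in self.species:
                    raise ModelError(f"term {t.kind} references undeclared species {s!r}")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def index(self, name: str) -> int:
        return self.species.index(name)

    @property
    def endogenous_species(self) -> tuple[str, ...]:
        return tuple(s for s in self.species if s in ("Y1", "Y2"))

    def rhs(self, state, t: float = 0.0) -> np.ndarray:
        return rhs(self, state, t)

    def reactions(self) -> list[Reaction]:
        return reactions(self)


# ---------------------------------------------------------------------------
# Right-hand side evaluation
# ---------------------------------------------------------------------------

def _term_flux(spec: ModelSpec, term: Term, state: np.ndarray, t: float) -> float:
    """Magnitude (>= 0) of one term's flux at the given state."""
    p = spec.params
    if term.kind == "hill_production":
        y = state[spec.index(term.source)]
        return term.rate * float(hill(y, term.K, term.m, term.regulation))
    if term.kind in ("linear_production", "additive_control"):
        return term.rate * state[spec.index(term.source)]
    if term.kind == "input_production":
        u = float(spec.input_fn(t))
        if u < 0 or not math.isfinite(u):
            raise ModelError(f"input signal must be finite and >= 0, got {u} at t={t}")
        return term.rate * u
    if term.kind == "linear_decay":
        return term.rate * state[spec.index(term.target)]
    if term.kind == "sequestration":
        return term.rate * state[spec.index(term.target)] * state[spec.index(term.partner)]
    if term.kind == "mm_degradation_control":
        y = state[spec.index(term.target)]
        u = state[spec.index(term.source)]
        return term.rate * u * y / (y + term.K)
    raise ModelError(f"unknown term kind {term.kind!r}")  # pragma: no cover


_PRODUCING = ("hill_production", "linear_production", "input_production", "additive_control")


def rhs(spec: ModelSpec, state, t: float = 0.0) -> np.ndarray:
    """Evaluate the deterministic right-hand side (μM/h) at ``state``.

    The state must be nonnegative and finite; the dynamics map the nonnegative
    orthant into itself because every removal term vanishes with its species.
    """
    x = np.asarray(state, dtype=float)
    if x.shape != (spec.n_species,):
        raise ModelError(f"state must have length {spec.n_species}, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ModelError("state contains NaN/inf")
    if np.any(x < 0):
        raise ModelError(f"state has negative entries: {x}")
    dx = np.zeros_like(x)
    for term in spec.terms:
        flux = _term_flux(spec, term, x, t)
        if term.kind in _PRODUCING:
            dx[spec.index(term.target)] += flux
        elif term.kind == "sequestration":
            dx[spec.index(term.target)] -= flux
            dx[spec.index(term.partner)] -= flux
        else:
            dx[spec.index(term.target)] -= flux
    return dx


def reactions(spec: ModelSpec) -> list[Reaction]:
    """Derive the stochastic reaction channels, one per term.

    The summed drift Σ stoichiometry×propensity equals :func:`rhs` at every
    nonnegative state (at system size Ω = 1; the SSA handles Ω-scaling).
    """
    if any(t.kind == "input_production" for t in spec.terms):
        raise ModelError("specs with an exogenous input signal have no autonomous "
                         "reaction list; substitute a constant-input variant")
    out: list[Reaction] = []
    n = spec.n_species
    for term in spec.terms:
        stoich = np.zeros(n, dtype=np.int64)
        if term.kind in _PRODUCING:
            stoich[spec.index(term.target)] = 1
        elif term.kind == "sequestration":
            stoich[spec.index(term.target)] = -1
            stoich[spec.index(term.partner)] = -1
        elif term.kind in ("linear_decay", "mm_degradation_control"):
            stoich[spec.index(term.target)] = -1
        else:  # pragma: no cover - defensive
            raise ModelError(f"term kind {term.kind!r} has no reaction mapping")

        def prop(state, _term=term):
            return _term_flux(spec, _term, np.asarray(state, dtype=float), 0.0)

        out.append(Reaction(name=f"{term.kind}->{term.target}", stoichiometry=stoich,
                            propensity=prop, term=term))
    return out


# ---------------------------------------------------------------------------
# Factories
# ---------------------------------------------------------------------------

def _toggle_terms(p: KineticParams) -> list[Term]:
    return [
        Term("hill_production", "Y1", p.alpha1, source="Y2", K=p.K, m=p.m, regulation=REPRESSING),
        Term("hill_production", "Y2", p.alpha2, source="Y1", K=p.K, m=p.m, regulation=REPRESSING),
        Term("linear_decay", "Y1", p.delta),
        Term("linear_decay", "Y2", p.delta),
    ]


def make_toggle(params: KineticParams) -> ModelSpec:
    """Mutually repressing two-gene toggle switch (possibly unbalanced).

    ẏ1 = α1·K^m/(K^m+y2^m) − δ·y1,  ẏ2 = α2·K^m/(K^m+y1^m) − δ·y2.
    """
    _require(params)
    return ModelSpec("toggle", ("Y1", "Y2"), params, tuple(_toggle_terms(params)))


def make_isolated_controller(params: KineticParams,
                             input_signal: Callable[[float], float]) -> ModelSpec:
    """The adaptive controller alone, driven by an exogenous signal y(t).

    u̇1 = k·x − δ·u1 − γ·u1·u2,  u̇2 = ξ·y(t) − δ·u2 − γ·u1·u2,  ẋ = θ·y(t) − δ·x.
    """
    _require(params)
    if not callable(input_signal):
        raise ModelError("input_signal must be a callable t -> y(t) >= 0")
    p = params
    terms = [
        Term("input_production", "X", p.theta, source="__input__"),
        Term("input_production", "U2", p.xi, source="__input__"),
        Term("linear_production", "U1", p.k, source="X"),
        Term("linear_decay", "X", p.delta),
        Term("linear_decay", "U1", p.delta),
        Term("linear_decay", "U2", p.delta),
        Term("sequestration", "U1", p.gamma, partner="U2"),
    ]
    return ModelSpec("isolated_controller", ("X", "U1", "U2"), params, tuple(terms),
                     input_fn=input_signal)


def _controller_terms(p: KineticParams, cfg: ControllerConfig, gain: float,
                      x_name: str, u1_name: str, u2_name: str) -> tuple[list[Term], ControllerRealization]:
    """Terms for one controller block wired to the endogenous plane."""
    terms = [
        Term("hill_production", x_name, p.theta, source=cfg.sense_species,
             K=p.K, m=p.m, regulation=cfg.sense_regulation),
        Term("hill_production", u2_name, p.xi, source=cfg.sense_species,
             K=p.K, m=p.m, regulation=cfg.sense_regulation),
        Term("linear_production", u1_name, p.k, source=x_name),
        Term("linear_decay", x_name, p.delta),
        Term("linear_decay", u1_name, p.delta),
        Term("linear_decay", u2_name, p.delta),
        Term("sequestration", u1_name, p.gamma, partner=u2_name),
    ]
    input_name = u1_name if cfg.input_species == "U1" else u2_name
    if cfg.actuation == ADDITIVE:
        terms.append(Term("additive_control", cfg.target_species, gain, source=input_name))
    else:
        terms.append(Term("mm_degradation_control", cfg.target_species, gain,
                          source=input_name, K=p.k_deg_effective))
    real = ControllerRealization(cfg.sense_species, cfg.sense_regulation, input_name,
                                 cfg.actuation, cfg.target_species, gain,
                                 x_name, u1_name, u2_name)
    return terms, real


def make_controlled_toggle(params: KineticParams,
                           config: ControllerConfig | None = None) -> ModelSpec:
    """Toggle switch in closed loop with the adaptive controller.

    The default configuration is the negative-feedback architecture: the
    controller senses its target Y1 through the repressing Hill function
    K^m/(K^m+y1^m) and adds +β·u1 to ẏ1. The positive-feedback architecture
    senses the non-target Y2 instead. ``duplicated='double'`` mirrors the
    controller onto Y2 with gain β′ (primed species X', U1', U2').
    """
    _require(params)
    cfg = config or ControllerConfig()
    if cfg.sense_regulation != REPRESSING:
        raise ModelError("the toggle switch is sensed through repressing Hill functions")
    terms = _toggle_terms(params)
    blocks, reals = _controller_terms(params, cfg, params.beta, "X", "U1", "U2")
    terms += blocks
    species = ["Y1", "Y2", "X", "U1", "U2"]
    controllers = [reals]
    if cfg.duplicated == "double":
        if params.beta_prime is None:
            raise ModelError("duplicated='double' requires beta_prime to be set")
        mcfg = cfg.mirrored()
        if mcfg.target_species == cfg.target_species:
            raise ModelError("double controllers must target distinct species")
        blocks2, real2 = _controller_terms(params, mcfg, params.beta_prime,
                                           "Xp", "U1p", "U2p")
        terms += blocks2
        species += ["Xp", "U1p", "U2p"]
        controllers.append(real2)
    name = f"controlled_toggle[{cfg.feedback_sign},{cfg.input_species}" \
           + (",double]" if cfg.duplicated == "double" else "]")
    return ModelSpec(name, tuple(species), params, tuple(terms), tuple(controllers))


def make_toggle_selfactivation(params: KineticParams, double: bool = False) -> ModelSpec:
    """Toggle switch plus activating self-loop(s) of strength α3.

    With ``double=True`` both species self-activate; at equal α's the diagonal
    dynamics reduce to ẏ = α − δ·y, which is the tristable configuration at
    the self-activation parameter set.
    """
    _require(params)
    p = params
    terms = _toggle_terms(p)
    terms.append(Term("hill_production", "Y1", p.alpha3, source="Y1",
                      K=p.K, m=p.m, regulation=ACTIVATING))
    if double:
        terms.append(Term("hill_production", "Y2", p.alpha3, source="Y2",
                          K=p.K, m=p.m, regulation=ACTIVATING))
    name = "toggle_selfactivation[double]" if double else "toggle_selfactivation"
    return ModelSpec(name, ("Y1", "Y2"), params, tuple(terms))


def _mutual_activation_terms(p: KineticParams) -> list[Term]:
    return [
        Term("hill_production", "Y1", p.alpha1, source="Y2", K=p.K, m=p.m, regulation=ACTIVATING),
        Term("hill_production", "Y2", p.alpha2, source="Y1", K=p.K, m=p.m, regulation=ACTIVATING),
        Term("linear_decay", "Y1", p.delta),
        Term("linear_decay", "Y2", p.delta),
    ]


def make_mutual_activation(params: KineticParams) -> ModelSpec:
    """Mutually activating two-gene motif (bistable: both-high / both-off)."""
    _require(params)
    return ModelSpec("mutual_activation", ("Y1", "Y2"), params,
                     tuple(_mutual_activation_terms(params)))


def make_controlled_mutual_activation(params: KineticParams,
                                      config: ControllerConfig | None = None) -> ModelSpec:
    """Mutual-activation motif inhibited by the adaptive controller.

    The controller senses through an activating Hill function and removes its
    target via saturated (Michaelis–Menten) degradation −β·u·y1/(y1+K); the
    default senses the target Y1 itself (negative feedback); the mirror senses
    Y2 (positive feedback).
    """
    _require(params)
    cfg = config or ControllerConfig(sense_species="Y1", sense_regulation=ACTIVATING,
                                     actuation=DEGRADATION)
    if cfg.actuation != DEGRADATION:
        raise ModelError("the mutual-activation controller actuates through "
                         "saturated degradation only")
    if cfg.sense_regulation != ACTIVATING:
        raise ModelError("the mutual-activation motif is sensed through "
                         "activating Hill functions")
    terms = _mutual_activation_terms(params)
    blocks, real = _controller_terms(params, cfg, params.beta, "X", "U1", "U2")
    terms += blocks
    name = f"controlled_mutual_activation[{cfg.feedback_sign},{cfg.input_species}]"
    return ModelSpec(name, ("Y1", "Y2", "X", "U1", "U2"), params,
                     tuple(terms), (real,))


def default_tristable_config(species: str, actuation: str = DEGRADATION) -> ControllerConfig:
    """Per-species controller defaults for the tristable network: saturated
    degradation senses its target through an activating Hill; additive
    activation senses it through a repressing Hill."""
    reg = ACTIVATING if actuation == DEGRADATION else REPRESSING
    return ControllerConfig(sense_species=species, sense_regulation=reg,
                            actuation=actuation, target_species=species)


def make_controlled_tristable(params: KineticParams,
                              config_y1: ControllerConfig | None = None,
                              config_y2: ControllerConfig | None = None) -> ModelSpec:
    """Double-self-activation toggle with one adaptive controller per species.

    Both controllers share (ξ, θ, k, γ, δ); the Y1 controller uses gain β and
    the Y2 controller gain β′. Each may actuate additively or via saturated
    degradation, covering both the all-inhibiting strategy and the mixed
    activate-Y1/inhibit-Y2 strategy.
    """
    _require(params)
    if (config_y1 is None) != (config_y2 is None):
        raise ModelError("provide both per-species configs or neither")
    cfg1 = config_y1 or default_tristable_config("Y1")
    cfg2 = config_y2 or default_tristable_config("Y2")
    if cfg1.target_species != "Y1" or cfg2.target_species != "Y2":
        raise ModelError("config_y1 must target Y1 and config_y2 must target Y2")
    if params.beta_prime is None:
        raise ModelError("the tristable double controller requires beta_prime")
    base = make_toggle_selfactivation(params, double=True)
    terms = list(base.terms)
    b1, r1 = _controller_terms(params, cfg1, params.beta, "X", "U1", "U2")
    b2, r2 = _controller_terms(params, cfg2, params.beta_prime, "Xp", "U1p", "U2p")
    terms += b1 + b2
    return ModelSpec("controlled_tristable",
                     ("Y1", "Y2", "X", "U1", "U2", "Xp", "U1p", "U2p"),
                     params, tuple(terms), (r1, r2))


def _require(params: KineticParams) -> None:
    if not isinstance(params, KineticParams):
        raise ParameterError(f"params must be KineticParams, got {type(params).__name__}")
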