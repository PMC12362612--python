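"""Kinetic parameters for the endogenous networks and the adaptive controller.

All concentrations are in μM and time is in hours. Two nominal sets are
provided: a symmetric toggle switch / mutual-activation
motif (α = 2.2 μM/h, K = 1 μM, m = 3, δ = 1/h) and a tristable toggle with
self-activation on both species (α = 1.2 μM/h, K = 0.5 μM, m = 4, δ = 1/h),
each optionally closed in feedback with the sequestration-based adaptive
controller (ξ = θ = 1 μM/h, k = 1/h, β = 1/h, γ = 100 /μM/h).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


class ParameterError(ValueError):
    """Raised when a kinetic parameter violates its domain constraint."""


@dataclass(frozen=True)
class KineticParams:
    """Rate constants for one model variant.

    Parameters
    ----------
    alpha1, alpha2 : float
        Maximal production rates of the endogenous species Y1 and Y2 (μM/h).
    alpha3 : float
        Strength of the activating self-loop(s), where present (μM/h).
    K : float
        Hill constant shared by all regulatory Hill functions (μM).
    m : int
        Hill cooperativity (dimensionless, ≥ 1).
    delta : float
        First-order decay rate of every species (/h).
    xi : float
        Maximal production rate of the sequestering species U2 (μM/h).
    theta : float
        Maximal production rate of the intermediate species X (μM/h).
    k : float
        Catalytic production rate of the controller output U1 from X (/h).
    beta : float
        Control gain of the (first) controller (/h).
    beta_prime : float or None
        Gain of the mirrored second controller, when one is present (/h).
    gamma : float
        Sequestration rate of the U1 + U2 annihilation reaction (/μM/h).
    K_deg : float or None
        Michaelis constant of the saturated-degradation actuation (μM).
        Defaults to ``K`` when left unset.
    """

    alpha1: float = 2.2
    alpha2: float = 2.2
    alpha3: float = 0.0
    K: float = 1.0
    m: int = 3
    delta: float = 1.0
    xi: float = 1.0
    theta: float = 1.0
    k: float = 1.0
    beta: float = 1.0
    beta_prime: float | None = None
    gamma: float = 100.0
    K_deg: float | None = None

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "alpha3", "K", "delta", "xi",
                     "theta", "k", "beta", "gamma"):
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or value < 0:
                raise ParameterError(f"{name} must be a nonnegative number, got {value!r}")
        if self.beta_prime is not None and self.beta_prime < 0:
            raise ParameterError(f"beta_prime must be nonnegative, got {self.beta_prime!r}")
        if self.K_deg is not None and self.K_deg < 0:
            raise ParameterError(f"K_deg must be nonnegative, got {self.K_deg!r}")
        if int(self.m) != self.m or self.m < 1:
            raise ParameterError(f"m must be an integer >= 1, got {self.m!r}")
        if self.delta <= 0:
            raise ParameterError(f"delta must be positive, got {self.delta!r}")

    @property
    def k_deg_effective(self) -> float:
        """Michaelis constant used by saturated-degradation terms."""
        return self.K if self.K_deg is None else self.K_deg

    @property
    def adaptive_metric(self) -> float:
        """The ratio r = ξδ/(kθ); r = 1 gives perfect adaptation."""
        kt = self.k * self.theta
        if kt == 0:
            raise ParameterError("adaptive metric undefined: k*theta = 0")
        return self.xi * self.delta / kt

    def replace(self, **changes) -> "KineticParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)


def nominal_params(**overrides) -> KineticParams:
    """Table-nominal parameters for the toggle switch / mutual activation motif."""
    return KineticParams(**overrides)


def tristable_params(**overrides) -> KineticParams:
    """Parameters for the toggle switch with self-activation on both species."""
    defaults = dict(alpha1=1.2, alpha2=1.2, alpha3=1.2, K=0.5, m=4, delta=1.0)
    defaults.update(overrides)
    return KineticParams(**defaults)
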