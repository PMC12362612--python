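"""Analysis of the isolated adaptive controller.

In the fast-sequestration limit (γ → ∞) the controller output u1 approaches
the clipped linear filter

    u1(t) ≈ max{0, (kθ − ξδ − ξs)/(s+δ)²  applied to  y(t)}

which combines a low-pass cascade with a (negative) derivative action. At the
design point r = ξδ/(kθ) = 1 the DC gain vanishes: the output perfectly adapts
to any input that settles to a constant. The approximation is realized here in
the time domain as a two-state filter cascade — ż1 = −δz1 + y, ż2 = −δz2 + z1,
output max{0, kθ·z2 − ξ·z1} — rather than by symbolic Laplace inversion; the
two are equivalent and the equivalence is checked by convolution in the tests.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .dynamics import simulate_ode
from .models import ModelError, make_isolated_controller
from .params import KineticParams

__all__ = ["adaptive_metric", "approx_output", "error_vs_gamma", "ApproxRealization"]


def adaptive_metric(params: KineticParams) -> float:
    """The design ratio r = ξδ/(kθ). r = 1 gives perfect adaptation."""
    return params.adaptive_metric


class ApproxRealization:
    """State-space realization of the fast-sequestration output approximation.

    States: z1 (first-order low-pass of the input) and z2 (its cascade);
    output rule u1 ≈ max{0, kθ·z2 − ξ·z1}, the clip applied pointwise to the
    output signal. For a constant input y0, z1 → y0/δ and z2 → y0/δ², so the
    output settles at max{0, (kθ/δ²)·y0·(1 − r)}.
    """

    def __init__(self, params: KineticParams):
        self.params = params

    def integrate(self, input_fn: Callable[[float], float], t_grid) -> np.ndarray:
        t_grid = np.asarray(t_grid, dtype=float)
        d = self.params.delta

        def f(t, z):
            y = float(input_fn(t))
            if y < 0:
                raise ModelError(f"input signal must be >= 0, got {y} at t={t}")
            return [-d * z[0] + y, -d * z[1] + z[0]]

        sol = solve_ivp(f, (t_grid[0], t_grid[-1]), [0.0, 0.0], t_eval=t_grid,
                        method="LSODA", rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise RuntimeError(f"filter integration failed: {sol.message}")
        z1, z2 = sol.y
        raw = self.params.k * self.params.theta * z2 - self.params.xi * z1
        return np.clip(raw, 0.0, None)


def approx_output(params: KineticParams, input_fn: Callable[[float], float],
                  t_grid) -> np.ndarray:
    """Fast-sequestration approximation of u1(t) on ``t_grid`` (from rest)."""
    return ApproxRealization(params).integrate(input_fn, t_grid)


def error_vs_gamma(params: KineticParams, input_fn: Callable[[float], float],
                   gammas: Sequence[float], t_grid) -> np.ndarray:
    """Sup-norm distance between the full controller's u1 and the γ→∞
    approximation, for each sequestration rate in ``gammas``.

    The full three-species controller (X, U1, U2) is integrated from rest with
    the given input; the error should shrink as γ grows.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    gammas = np.asarray(gammas, dtype=float)
    if np.any(gammas <= 0):
        raise ModelError("gammas must be positive")
    target = approx_output(params, input_fn, t_grid)
    errors = np.empty(gammas.size)
    for i, g in enumerate(gammas):
        spec = make_isolated_controller(params.replace(gamma=float(g)), input_fn)
        traj = simulate_ode(spec, np.zeros(3), float(t_grid[-1]),
                            n_points=len(t_grid))
        u1 = np.interp(t_grid, traj.times, traj.states[:, spec.index("U1")])
        errors[i] = float(np.max(np.abs(u1 - target)))
    return errors
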