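"""Equilibrium and nullcline analysis in the endogenous (y1, y2) plane.

Controlled specs are reduced to two dimensions by eliminating each controller
block at quasi-steady state (QSS): given frozen (y1, y2), the sensing Hill
value p fixes x̄ = θp/δ and the sequestration pair (ū1, ū2) through a scalar
quadratic (see :func:`controller_qss`). Nullclines, equilibrium seeding and
continuation all operate on this reduced map; located points are then lifted
to the full state and classified through the full-system Jacobian spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .models import (ADDITIVE, ModelSpec, ModelError, hill)
from .params import KineticParams

__all__ = [
    "Equilibrium", "EquilibriumSet", "NullclineCurve",
    "controller_qss", "reduced_rhs", "nullclines", "find_equilibria",
    "classify_stability", "alteration_percent", "default_box",
]

STABILITY_EPS = 1e-6   # |Re λ| below this -> "marginal"
DEDUP_TOL = 1e-4       # μM, pairwise distance below which points merge


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of the full system with its Jacobian spectrum."""

    location: np.ndarray          # full-state vector, μM
    eigenvalues: np.ndarray       # complex spectrum of the full Jacobian
    label: str                    # stable | saddle | unstable | marginal
    species: tuple[str, ...]

    @property
    def y(self) -> np.ndarray:
        """Endogenous (y1, y2) coordinates."""
        idx = [self.species.index(s) for s in ("Y1", "Y2") if s in self.species]
        return self.location[idx]

    @property
    def is_stable(self) -> bool:
        return self.label == "stable"


@dataclass
class EquilibriumSet:
    equilibria: list[Equilibrium]
    search_box: tuple[float, float]

    @property
    def stable(self) -> list[Equilibrium]:
        return [e for e in self.equilibria if e.is_stable]

    @property
    def unstable(self) -> list[Equilibrium]:
        """Everything not asymptotically stable (saddles included)."""
        return [e for e in self.equilibria if e.label in ("saddle", "unstable")]

    def __len__(self) -> int:
        return len(self.equilibria)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.equilibria:
            out[e.label] = out.get(e.label, 0) + 1
        return out

    def nearest_stable(self, point) -> Equilibrium:
        point = np.asarray(point, dtype=float)
        stable = self.stable
        if not stable:
            raise ModelError("no stable equilibria to match against")
        d = [np.linalg.norm(e.y - point) for e in stable]
        return stable[int(np.argmin(d))]


@dataclass
class NullclineCurve:
    """Sampled polyline(s) of one species' zero-derivative locus."""

    axis: int                     # 0: ẏ1 = 0, 1: ẏ2 = 0
    points: np.ndarray            # (N, 2) array of (y1, y2) samples


def controller_qss(p: float, params: KineticParams):
    """Steady state (ū1, ū2, x̄) of one controller block at sensing value p.

    With d = p(kθ − ξδ)/δ², ū1 is the positive root of
    γu² + (δ − γd)u − kθp/δ = 0 and ū2 = ū1 − d; x̄ = θp/δ.
    For γ = 0 the linear decoupled steady state is returned. Vectorized in p.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0):
        raise ModelError("sensing value p must be nonnegative")
    par = params
    x = par.theta * p_arr / par.delta
    if par.gamma == 0:
        u1 = par.k * par.theta * p_arr / par.delta ** 2
        u2 = par.xi * p_arr / par.delta
        return u1, u2, x
    d = p_arr * (par.k * par.theta - par.xi * par.delta) / par.delta ** 2
    b = par.delta - par.gamma * d
    c = -par.k * par.theta * p_arr / par.delta
    disc = b * b - 4.0 * par.gamma * c
    u1 = (-b + np.sqrt(disc)) / (2.0 * par.gamma)
    u1 = np.clip(u1, 0.0, None)
    u2 = np.clip(u1 - d, 0.0, None)
    return u1, u2, x


def _endogenous_flux(spec: ModelSpec, y1, y2):
    """Drift of (y1, y2) from the purely endogenous terms (vectorized)."""
    vals = {"Y1": np.asarray(y1, dtype=float), "Y2": np.asarray(y2, dtype=float)}
    f1 = np.zeros_like(vals["Y1"])
    f2 = np.zeros_like(vals["Y2"])
    acc = {"Y1": f1, "Y2": f2}
    for t in spec.terms:
        if t.target not in ("Y1", "Y2"):
            continue
        if t.kind == "hill_production" and t.source in ("Y1", "Y2"):
            acc[t.target] += t.rate * hill(vals[t.source], t.K, t.m, t.regulation)
        elif t.kind == "linear_decay":
            acc[t.target] -= t.rate * vals[t.target]
        # actuation terms (controller sources) are added from QSS below
    return f1, f2


def reduced_rhs(spec: ModelSpec, y1, y2):
    """(ẏ1, ẏ2) with all controller species eliminated at quasi-steady state."""
    if not set(("Y1", "Y2")) <= set(spec.species):
        raise ModelError(f"spec {spec.name!r} has no endogenous (Y1, Y2) plane")
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    f1, f2 = _endogenous_flux(spec, y1, y2)
    acc = {"Y1": f1, "Y2": f2}
    vals = {"Y1": y1, "Y2": y2}
    for ctrl in spec.controllers:
        p = hill(vals[ctrl.sense_species], spec.params.K, spec.params.m,
                 ctrl.sense_regulation)
        u1, u2, _ = controller_qss(p, spec.params)
        u_in = u1 if ctrl.input_species in ("U1", "U1p") else u2
        y_t = vals[ctrl.target_species]
        if ctrl.actuation == ADDITIVE:
            acc[ctrl.target_species] += ctrl.gain * u_in
        else:
            Kd = spec.params.k_deg_effective
            acc[ctrl.target_species] -= ctrl.gain * u_in * y_t / (y_t + Kd)
    return f1, f2


def lift_to_full_state(spec: ModelSpec, y1: float, y2: float) -> np.ndarray:
    """Embed a reduced-plane point into the full state via controller QSS."""
    state = np.zeros(spec.n_species)
    state[spec.index("Y1")] = y1
    state[spec.index("Y2")] = y2
    vals = {"Y1": y1, "Y2": y2}
    for ctrl in spec.controllers:
        p = float(hill(vals[ctrl.sense_species], spec.params.K, spec.params.m,
                       ctrl.sense_regulation))
        u1, u2, x = controller_qss(p, spec.params)
        state[spec.index(ctrl.x_name)] = x
        state[spec.index(ctrl.u1_name)] = u1
        state[spec.index(ctrl.u2_name)] = u2
    return state


def default_box(spec: ModelSpec) -> tuple[float, float]:
    """Search box [0, hi]² bounding all nullclines: 1.5× the maximal
    production-over-decay, including additive control contributions."""
    par = spec.params
    alpha_max = max(par.alpha1 + par.alpha3, par.alpha2 + par.alpha3)
    boost = sum(c.gain for c in spec.controllers if c.actuation == ADDITIVE)
    u_bound = par.k * par.theta / par.delta ** 2  # ū1 at p=1, γ→0 (worst case)
    hi = 1.5 * (alpha_max + boost * u_bound) / par.delta
    return (0.0, hi)


def nullclines(spec: ModelSpec, axis: int, grid=None,
               box: tuple[float, float] | None = None) -> NullclineCurve:
    """Sample the ẏ_axis = 0 locus on the (y1, y2) plane.

    For each grid value of the *other* species, every root of the reduced
    derivative along the axis species is bracketed by a sign scan and polished
    by bisection; columns without roots are omitted, so disconnected branches
    are represented naturally.
    """
    if axis not in (0, 1):
        raise ModelError("axis must be 0 (y1-dot) or 1 (y2-dot)")
    lo, hi = box or default_box(spec)
    grid = np.linspace(lo, hi, 241) if grid is None else np.asarray(grid, dtype=float)
    scan = np.linspace(lo, hi, 600)
    pts = []
    for other in grid:
        if axis == 0:
            f = lambda y: reduced_rhs(spec, y, np.full_like(np.asarray(y, dtype=float), other))[0]
        else:
            f = lambda y: reduced_rhs(spec, np.full_like(np.asarray(y, dtype=float), other), y)[1]
        vals = np.asarray(f(scan))
        sign = np.sign(vals)
        for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
            root = brentq(lambda y: float(f(np.array([y]))[0]), scan[i], scan[i + 1],
                          xtol=1e-10)
            pts.append((root, other) if axis == 0 else (other, root))
        for i in np.nonzero(vals == 0.0)[0]:
            pts.append((scan[i], other) if axis == 0 else (other, scan[i]))
    return NullclineCurve(axis, np.array(pts) if pts else np.empty((0, 2)))


def _newton_polish(spec: ModelSpec, seeds: np.ndarray, box: tuple[float, float],
                   tol: float, max_iter: int = 80) -> np.ndarray:
    """Damped Newton on the reduced map, vectorized over all seeds."""
    lo, hi = box
    y1 = seeds[:, 0].copy()
    y2 = seeds[:, 1].copy()
    eps = 1e-7
    for _ in range(max_iter):
        f1, f2 = reduced_rhs(spec, y1, y2)
        h1 = eps * (1.0 + np.abs(y1))
        h2 = eps * (1.0 + np.abs(y2))
        g1, g2 = reduced_rhs(spec, y1 + h1, y2)   # forward differences keep
        k1, k2 = reduced_rhs(spec, y1, y2 + h2)   # evaluations inside y >= 0
        a11 = (g1 - f1) / h1
        a21 = (g2 - f2) / h1
        a12 = (k1 - f1) / h2
        a22 = (k2 - f2) / h2
        det = a11 * a22 - a12 * a21
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        s1 = (f1 * a22 - f2 * a12) / det
        s2 = (a11 * f2 - a21 * f1) / det
        # damping: cap the step at a fraction of the box size
        norm = np.hypot(s1, s2)
        cap = 0.1 * (hi - lo)
        scale = np.where(norm > cap, cap / np.where(norm == 0, 1, norm), 1.0)
        y1 = np.clip(y1 - scale * s1, lo, hi)
        y2 = np.clip(y2 - scale * s2, lo, hi)
        bad = ~np.isfinite(y1) | ~np.isfinite(y2)
        y1[bad] = np.nan
        y2[bad] = np.nan
    f1, f2 = reduced_rhs(spec, np.nan_to_num(y1), np.nan_to_num(y2))
    ok = np.isfinite(y1) & np.isfinite(y2) & (np.abs(f1) < tol) & (np.abs(f2) < tol)
    return np.column_stack([y1[ok], y2[ok]])


def _dedup(points: np.ndarray, tol: float = DEDUP_TOL) -> np.ndarray:
    kept: list[np.ndarray] = []
    for p in points:
        if all(np.linalg.norm(p - q) > tol for q in kept):
            kept.append(p)
    return np.array(kept) if kept else np.empty((0, 2))


def find_equilibria(spec: ModelSpec, box: tuple[float, float] | None = None,
                    grid_n: int = 60, tol: float = 1e-10) -> EquilibriumSet:
    """Locate and classify all equilibria of the spec.

    A ``grid_n × grid_n`` lattice over the search box seeds a damped Newton
    iteration on the reduced (y1, y2) map; converged points are deduplicated,
    lifted to the full state through controller QSS, and classified by the
    full Jacobian spectrum.
    """
    box = box or default_box(spec)
    lo, hi = box
    g = np.linspace(lo, hi, grid_n)
    Y1, Y2 = np.meshgrid(g, g)
    seeds = np.column_stack([Y1.ravel(), Y2.ravel()])
    roots = _newton_polish(spec, seeds, box, tol)
    roots = _dedup(roots)
    eqs = []
    for y1, y2 in roots:
        full = lift_to_full_state(spec, max(y1, 0.0), max(y2, 0.0))
        try:
            eqs.append(classify_stability(spec, full))
        except ModelError:
            continue  # lifted point not a genuine full-system fixed point
    # dedup again on full (y1, y2) after classification polishing
    uniq: list[Equilibrium] = []
    for e in eqs:
        if all(np.linalg.norm(e.y - u.y) > DEDUP_TOL for u in uniq):
            uniq.append(e)
    uniq.sort(key=lambda e: (e.y[0], e.y[1]))
    return EquilibriumSet(uniq, box)


def jacobian(spec: ModelSpec, point: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    """Full-system Jacobian by central finite differences."""
    point = np.asarray(point, dtype=float)
    n = spec.n_species
    J = np.zeros((n, n))
    for j in range(n):
        h = rel_step * max(abs(point[j]), 1.0)
        up = point.copy()
        dn = point.copy()
        up[j] += h
        dn[j] = max(dn[j] - h, 0.0)
        J[:, j] = (spec.rhs(up) - spec.rhs(dn)) / (up[j] - dn[j])
    return J


def classify_stability(spec: ModelSpec, point) -> Equilibrium:
    """Classify a (near-)fixed point by the real parts of its spectrum."""
    point = np.clip(np.asarray(point, dtype=float), 0.0, None)
    res0 = np.max(np.abs(spec.rhs(point)))
    if res0 >= 1e-6:
        raise ModelError(f"point is not a fixed point (‖rhs‖∞ = {res0:.2e})")
    # polish on the full system before classification
    from scipy.optimize import root as _root
    sol = _root(lambda x: spec.rhs(np.clip(x, 0.0, None)), point, method="hybr",
                tol=1e-12)
    if sol.success and np.all(sol.x > -1e-9):
        polished = np.clip(sol.x, 0.0, None)
        if np.max(np.abs(spec.rhs(polished))) <= res0:
            point = polished
    eig = np.linalg.eigvals(jacobian(spec, point))
    re = eig.real
    if np.all(re < -STABILITY_EPS):
        label = "stable"
    elif np.all(re > STABILITY_EPS):
        label = "unstable"
    elif np.any(re > STABILITY_EPS) and np.any(re < -STABILITY_EPS):
        label = "saddle"
    else:
        label = "marginal"
    return Equilibrium(point, eig, label, spec.species)


def alteration_percent(reference_eq, new_eq, species: int | str = 0,
                       species_names: tuple[str, ...] = ("Y1", "Y2")):
    """Percent shift 100·|new − ref|/ref of one species' equilibrium value.

    Accepts Equilibrium objects or plain coordinate vectors. A zero reference
    returns the absolute difference with ``flagged=True``.
    """
    ref = reference_eq.y if isinstance(reference_eq, Equilibrium) else np.asarray(reference_eq, dtype=float)
    new = new_eq.y if isinstance(new_eq, Equilibrium) else np.asarray(new_eq, dtype=float)
    idx = species_names.index(species) if isinstance(species, str) else int(species)
    r, v = float(ref[idx]), float(new[idx])
    if r == 0.0:
        return abs(v - r), True
    return 100.0 * abs(v - r) / r, False
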