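"""Deterministic and stochastic simulation of model specs.

ODE trajectories are integrated with scipy (LSODA, stiff-capable) at tight
tolerances, since basin boundaries of the bistable networks are sensitive.
Stochastic trajectories use the exact direct-method Gillespie algorithm over
the reaction channels derived from the spec, at a system size Ω (molecules per
μM): zeroth-order concentration rates are multiplied by Ω, second-order rates
divided by Ω, so the SSA ensemble mean approaches the ODE flow as Ω grows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .models import ModelSpec, ModelError, reactions

__all__ = ["Trajectory", "simulate_ode", "simulate_ssa", "run_ensemble", "ensemble_seeds"]

# reaction-kind codes used by the compiled SSA kernel
_ZEROTH_HILL = 0      # rate * Ω * hill(n[src1]/Ω; K, m, reg)
_FIRST_ORDER = 1      # rate * n[src1]
_SECOND_ORDER = 2     # rate * n[src1] * n[src2] / Ω
_MM_DEGRADATION = 3   # rate * n[src1] * n[src2] / (n[src2] + Ω*K)


class IntegrationError(RuntimeError):
    """ODE integration failure; carries the last good time reached."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


@dataclass
class Trajectory:
    """Time-stamped state path from one ODE or SSA run.

    ``states`` is (time × species): μM for ODE runs, molecule counts for SSA.
    """

    times: np.ndarray
    states: np.ndarray
    species: tuple[str, ...]
    kind: str                    # "ode" | "ssa"
    omega: float | None = None
    seed: int | None = None

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_dataframe(self):
        import pandas as pd
        df = pd.DataFrame(self.states, columns=list(self.species))
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path, metadata_sidecar: bool = True) -> None:
        """Write the trajectory as CSV plus a JSON metadata sidecar."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        if metadata_sidecar:
            meta = {"kind": self.kind, "omega": self.omega, "seed": self.seed,
                    "species": list(self.species), "t_end": float(self.times[-1])}
            path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def simulate_ode(spec: ModelSpec, x0, t_end: float, rtol: float = 1e-8,
                 atol: float = 1e-10, n_points: int = 2000) -> Trajectory:
    """Integrate the spec's ODEs from ``x0`` (μM) to ``t_end`` (hours)."""
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (spec.n_species,):
        raise ModelError(f"x0 must have length {spec.n_species}")
    if np.any(x0 < 0):
        raise ModelError("x0 must be nonnegative")
    if t_end <= 0:
        raise ModelError("t_end must be positive")

    def f(t, x):
        # small negative excursions from the integrator are clipped before
        # term evaluation; forward invariance keeps them at roundoff scale
        return spec.rhs(np.clip(x, 0.0, None), t)

    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(f, (0.0, t_end), x0, method="LSODA", rtol=rtol, atol=atol,
                    t_eval=t_eval, dense_output=False)
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(f"ODE integration failed: {sol.message}", last)
    states = np.clip(sol.y.T, 0.0, None)
    return Trajectory(sol.t.copy(), states, spec.species, "ode")


# ---------------------------------------------------------------------------
# SSA
# ---------------------------------------------------------------------------

@njit(cache=False)
def _propensities(n, omega, code, rate, src1, src2, Kc, mc, reg, out):
    for j in range(code.size):
        c = code[j]
        if c == _ZEROTH_HILL:
            y = n[src1[j]] / omega
            ym = y ** mc[j]
            Km = Kc[j] ** mc[j]
            h = Km / (Km + ym) if reg[j] == 0 else ym / (Km + ym)
            out[j] = rate[j] * omega * h
        elif c == _FIRST_ORDER:
            out[j] = rate[j] * n[src1[j]]
        elif c == _SECOND_ORDER:
            out[j] = rate[j] * n[src1[j]] * n[src2[j]] / omega
        else:  # _MM_DEGRADATION
            denom = n[src2[j]] + omega * Kc[j]
            out[j] = rate[j] * n[src1[j]] * n[src2[j]] / denom if denom > 0 else 0.0


@njit(cache=False)
def _ssa_core(n0, t_end, stoich, code, rate, src1, src2, Kc, mc, reg,
              omega, seed, record, max_events):
    np.random.seed(seed)
    n_species = n0.size
    n = n0.copy()
    R = code.size
    a = np.empty(R)
    cap = max_events + 2 if record else 2
    times = np.empty(cap)
    states = np.empty((cap, n_species), dtype=np.int64)
    times[0] = 0.0
    states[0] = n
    idx = 0
    t = 0.0
    events = 0
    while events < max_events:
        _propensities(n, omega, code, rate, src1, src2, Kc, mc, reg, a)
        total = 0.0
        for j in range(R):
            total += a[j]
        if total <= 0.0:
            break  # absorbing state: hold until t_end
        u = np.random.random()
        while u <= 0.0:
            u = np.random.random()
        dt = -np.log(u) / total
        if t + dt > t_end:
            t = t_end
            break
        t += dt
        thresh = np.random.random() * total
        acc = 0.0
        chosen = R - 1
        for j in range(R):
            acc += a[j]
            if acc >= thresh:
                chosen = j
                break
        for i in range(n_species):
            n[i] += stoich[chosen, i]
        events += 1
        if record:
            idx += 1
            times[idx] = t
            states[idx] = n
    # terminal sample at t_end
    idx += 1
    times[idx] = t_end
    states[idx] = n
    return times[:idx + 1], states[:idx + 1], events


def _compile_reactions(spec: ModelSpec):
    """Pack the spec's reaction channels into flat arrays for the SSA kernel."""
    rxns = reactions(spec)
    R = len(rxns)
    n = spec.n_species
    stoich = np.zeros((R, n), dtype=np.int64)
    code = np.zeros(R, dtype=np.int64)
    rate = np.zeros(R)
    src1 = np.zeros(R, dtype=np.int64)
    src2 = np.zeros(R, dtype=np.int64)
    Kc = np.ones(R)
    mc = np.ones(R)
    reg = np.zeros(R, dtype=np.int64)
    for j, rx in enumerate(rxns):
        t = rx.term
        stoich[j] = rx.stoichiometry
        rate[j] = t.rate
        if t.kind == "hill_production":
            code[j] = _ZEROTH_HILL
            src1[j] = spec.index(t.source)
            Kc[j] = t.K
            mc[j] = t.m
            reg[j] = 0 if t.regulation == "repressing" else 1
        elif t.kind in ("linear_production", "additive_control"):
            code[j] = _FIRST_ORDER
            src1[j] = spec.index(t.source)
        elif t.kind == "linear_decay":
            code[j] = _FIRST_ORDER
            src1[j] = spec.index(t.target)
        elif t.kind == "sequestration":
            code[j] = _SECOND_ORDER
            src1[j] = spec.index(t.target)
            src2[j] = spec.index(t.partner)
        elif t.kind == "mm_degradation_control":
            code[j] = _MM_DEGRADATION
            src1[j] = spec.index(t.source)
            src2[j] = spec.index(t.target)
            Kc[j] = t.K
        else:  # pragma: no cover
            raise ModelError(f"no SSA mapping for term {t.kind!r}")
    return stoich, code, rate, src1, src2, Kc, mc, reg


def simulate_ssa(spec: ModelSpec, x0, t_end: float, omega: float = 1.0,
                 seed: int = 0, record: bool = True,
                 max_events: int = 2_000_000) -> Trajectory:
    """Exact direct-method Gillespie simulation at system size ``omega``.

    ``x0`` is given in concentration units (μM) and converted to integer
    counts round(x0·Ω). Identical seeds give bit-identical event sequences.
    If the total propensity reaches zero the state is absorbing and is held
    until ``t_end`` without error.
    """
    if omega < 1:
        raise ModelError("omega must be >= 1")
    if t_end <= 0:
        raise ModelError("t_end must be positive")
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (spec.n_species,) or np.any(x0 < 0):
        raise ModelError("x0 must be a nonnegative vector matching the species")
    n0 = np.rint(x0 * omega).astype(np.int64)
    packed = _compile_reactions(spec)
    times, states, events = _ssa_core(n0, float(t_end), *packed, float(omega),
                                      int(seed) % (2 ** 31), record, max_events)
    if events >= max_events:
        raise RuntimeError(f"SSA exceeded max_events={max_events} before t_end; "
                           "raise max_events or record=False")
    return Trajectory(times, states, spec.species, "ssa", omega=float(omega),
                      seed=int(seed))


def ensemble_seeds(master_seed: int, n: int) -> np.ndarray:
    """Reproducible per-run seeds derived from a master seed.

    Uses numpy's SeedSequence spawn keys so any subset of runs is reproducible
    without generating the whole sequence.
    """
    ss = np.random.SeedSequence(int(master_seed))
    return np.array([child.generate_state(1)[0] % (2 ** 31) for child in ss.spawn(n)],
                    dtype=np.int64)


def run_ensemble(spec: ModelSpec, x0, n: int, t_end: float, mode: str = "ssa",
                 omega: float = 1.0, seed: int = 0, rtol: float = 1e-8,
                 atol: float = 1e-10) -> np.ndarray:
    """Terminal states of ``n`` independent runs (rows), seeded reproducibly.

    SSA rows are molecule counts; ODE rows are concentrations (and identical
    across rows since the ODE flow is deterministic).
    """
    if n < 1:
        raise ModelError("n must be >= 1")
    if mode == "ode":
        traj = simulate_ode(spec, x0, t_end, rtol=rtol, atol=atol)
        return np.tile(traj.final_state, (n, 1))
    if mode != "ssa":
        raise ModelError(f"mode must be 'ode' or 'ssa', got {mode!r}")
    seeds = ensemble_seeds(seed, n)
    finals = np.empty((n, spec.n_species), dtype=np.int64)
    n0 = np.asarray(x0, dtype=float)
    packed = _compile_reactions(spec)
    counts0 = np.rint(n0 * omega).astype(np.int64)
    for i in range(n):
        _, states, _ = _ssa_core(counts0, float(t_end), *packed, float(omega),
                                 int(seeds[i]), False, 500_000_000)
        finals[i] = states[-1]
    return finals
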