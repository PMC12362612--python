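"""Parameter-scan drivers for the design-space analyses.

Each scan sweeps one parameter (control gain β, production ratio α2/α1,
adaptive metric r, or sequestration rate γ), locates all equilibria at every
grid point, matches stable branches across the grid by nearest-neighbour
continuation, and summarises counts, equilibrium values and percent
alterations relative to a declared baseline (by default the isolated,
uncontrolled network at the same endogenous parameters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .equilibria import EquilibriumSet, find_equilibria
from .models import (ControllerConfig, ModelSpec, ModelError,
                     make_controlled_toggle, make_toggle)
from .params import KineticParams

__all__ = ["ScanResult", "scan_gain", "scan_ratio", "scan_metric",
           "scan_sequestration", "max_alteration_vs_baseline"]


@dataclass
class ScanResult:
    """Per-grid-point equilibrium summaries of one parameter sweep."""

    parameter: str
    grid: np.ndarray
    stable_counts: np.ndarray                  # stable equilibria per point
    total_counts: np.ndarray                   # all equilibria per point
    branches: list[list[np.ndarray]]           # per point: stable (y1,y2) values
    alterations: list[float | None] = field(default_factory=list)
    fate_fractions: list[dict | None] = field(default_factory=list)
    threshold: float | None = None             # scan-specific summary
    bistable_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ModelError("scan grid must be strictly increasing")

    def to_json(self) -> str:
        payload = {
            "parameter": self.parameter,
            "grid": self.grid.tolist(),
            "stable_counts": self.stable_counts.tolist(),
            "total_counts": self.total_counts.tolist(),
            "branches": [[list(map(float, b)) for b in pt] for pt in self.branches],
            "alterations": self.alterations,
            "fate_fractions": self.fate_fractions,
            "threshold": self.threshold,
            "bistable_range": list(self.bistable_range) if self.bistable_range else None,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            self.parameter: self.grid,
            "n_stable": self.stable_counts,
            "n_total": self.total_counts,
            "max_alteration_pct": [a if a is not None else np.nan
                                   for a in (self.alterations or [None] * len(self.grid))],
        })


def _match_branches(prev: list[np.ndarray], current: list[np.ndarray]) -> list[np.ndarray]:
    """Order ``current`` stable values to continue ``prev`` branches (nearest
    neighbour); unmatched new branches are appended."""
    if not prev:
        return sorted(current, key=lambda p: (-p[0], p[1]))
    remaining = list(range(len(current)))
    ordered: list[np.ndarray] = []
    for p in prev:
        if not remaining:
            break
        j = min(remaining, key=lambda i: np.linalg.norm(current[i] - p))
        ordered.append(current[j])
        remaining.remove(j)
    ordered.extend(current[i] for i in remaining)
    return ordered


def _dominant_alteration(stable_pts: list[np.ndarray],
                         baseline_pts: list[np.ndarray]) -> float | None:
    """Max percent displacement of the stable equilibria across matched
    branches, measured as the largest coordinate shift relative to the
    reference equilibrium's dominant expression level.

    Normalising by the dominant coordinate (rather than per-species) keeps
    the measure meaningful at strongly asymmetric equilibria, where the
    minor species' own value is near zero and a per-species ratio would
    diverge for shifts that are negligible on the scale of the attractor.
    """
    if not stable_pts or not baseline_pts:
        return None
    worst = 0.0
    for pt in stable_pts:
        ref = min(baseline_pts, key=lambda b: np.linalg.norm(b - pt))
        scale = float(np.max(ref))
        if scale == 0:
            continue
        worst = max(worst, 100.0 * float(np.max(np.abs(pt - ref))) / scale)
    return worst


def max_alteration_vs_baseline(eqs: EquilibriumSet, baseline: EquilibriumSet) -> float | None:
    """Convenience wrapper of the dominant-species alteration on two sets."""
    return _dominant_alteration([e.y for e in eqs.stable],
                                [e.y for e in baseline.stable])


def _sweep(parameter: str, grid: np.ndarray,
           spec_at: Callable[[float], ModelSpec],
           baseline_at: Callable[[float], ModelSpec] | None = None,
           grid_n: int = 60) -> ScanResult:
    grid = np.asarray(grid, dtype=float)
    stable_counts = np.zeros(grid.size, dtype=int)
    total_counts = np.zeros(grid.size, dtype=int)
    branches: list[list[np.ndarray]] = []
    alterations: list[float | None] = []
    prev: list[np.ndarray] = []
    for i, value in enumerate(grid):
        eqs = find_equilibria(spec_at(float(value)), grid_n=grid_n)
        stable = [e.y for e in eqs.stable]
        stable = _match_branches(prev, stable)
        prev = stable
        stable_counts[i] = len(stable)
        total_counts[i] = len(eqs)
        branches.append(stable)
        if baseline_at is not None:
            base = find_equilibria(baseline_at(float(value)), grid_n=grid_n)
            alterations.append(_dominant_alteration(stable, [e.y for e in base.stable]))
        else:
            alterations.append(None)
    return ScanResult(parameter, grid, stable_counts, total_counts, branches,
                      alterations)


def scan_gain(base_spec_family: Callable[[float], ModelSpec],
              betas: Sequence[float],
              baseline_at: Callable[[float], ModelSpec] | None = None) -> ScanResult:
    """Sweep the control gain β; the monostability threshold is the smallest
    grid β at which exactly one stable equilibrium remains."""
    result = _sweep("beta", np.asarray(betas, dtype=float), base_spec_family,
                    baseline_at)
    mono = np.nonzero(result.stable_counts == 1)[0]
    result.threshold = float(result.grid[mono[0]]) if mono.size else None
    return result


def _contiguous_range_containing(grid: np.ndarray, ok: np.ndarray,
                                 anchor: float) -> tuple[float, float] | None:
    """Maximal contiguous grid interval with ``ok`` true containing ``anchor``."""
    idx = int(np.argmin(np.abs(grid - anchor)))
    if not ok[idx]:
        return None
    lo = idx
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = idx
    while hi < grid.size - 1 and ok[hi + 1]:
        hi += 1
    return (float(grid[lo]), float(grid[hi]))


def scan_ratio(spec_family: Callable[[float, float], ModelSpec], vary: str,
               ratios: Sequence[float], alpha_fixed: float = 2.2,
               baseline_family: Callable[[float, float], ModelSpec] | None = None,
               grid_n: int = 60) -> ScanResult:
    """Sweep the production ratio α2/α1 by varying one α at fixed other.

    ``spec_family(alpha1, alpha2)`` builds the model at those rates. The
    bistable range is the maximal contiguous grid interval with exactly two
    stable equilibria that contains ratio 1.
    """
    if vary not in ("alpha1", "alpha2"):
        raise ModelError("vary must be 'alpha1' or 'alpha2'")
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios <= 0):
        raise ModelError("ratios must be positive")

    def alphas(ratio: float) -> tuple[float, float]:
        if vary == "alpha2":
            return alpha_fixed, alpha_fixed * ratio     # ratio = alpha2/alpha1
        return alpha_fixed / ratio, alpha_fixed         # ratio = alpha2/alpha1

    spec_at = lambda r: spec_family(*alphas(r))
    baseline_at = (lambda r: baseline_family(*alphas(r))) if baseline_family else None
    result = _sweep(f"ratio({vary})", ratios, spec_at, baseline_at, grid_n=grid_n)
    result.bistable_range = _contiguous_range_containing(
        result.grid, result.stable_counts == 2, 1.0)
    return result


def scan_metric(base_spec_family: Callable[[float], ModelSpec],
                r_values: Sequence[float],
                baseline_at: Callable[[float], ModelSpec] | None = None) -> ScanResult:
    """Sweep the adaptive metric r (the caller varies ξ = r·kθ/δ inside
    ``base_spec_family``); reports per-point counts and alterations."""
    return _sweep("r", np.asarray(r_values, dtype=float), base_spec_family,
                  baseline_at)


def scan_sequestration(base_spec_family: Callable[[float], ModelSpec],
                       gammas: Sequence[float],
                       baseline_at: Callable[[float], ModelSpec] | None = None,
                       fate_protocol: dict | None = None) -> ScanResult:
    """Sweep the sequestration rate γ; optionally attach fate fractions from
    the stochastic assay at each γ (``fate_protocol`` forwards keyword
    arguments to :func:`fatebias.fate.assay_fates`)."""
    gammas = np.asarray(gammas, dtype=float)
    if np.any(gammas <= 0):
        raise ModelError("gammas must be positive")
    result = _sweep("gamma", gammas, base_spec_family, baseline_at)
    if fate_protocol is not None:
        from .fate import assay_fates
        fates = []
        for g in gammas:
            dist = assay_fates(base_spec_family(float(g)), **fate_protocol)
            fates.append({k: float(v) for k, v in dist.fractions.items()})
        result.fate_fractions = fates
    else:
        result.fate_fractions = [None] * gammas.size
    return result


def controlled_toggle_family(params: KineticParams, architecture: str = "negative",
                             input_species: str = "U1"):
    """Helper: β ↦ controlled-toggle spec with everything else fixed."""

    def build(beta: float) -> ModelSpec:
        cfg = ControllerConfig(
            sense_species="Y1" if architecture == "negative" else "Y2",
            input_species=input_species)
        return make_controlled_toggle(params.replace(beta=beta), cfg)

    return build
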