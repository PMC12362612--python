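"""Fate classification of stochastic ensembles.

A "fate" is the stable equilibrium a trajectory ends nearest to at a fixed
horizon (200 h by default). Ensembles of terminal states become
per-attractor fractions, an 8-bin endpoint histogram of a chosen species, and
a scalar bias index. SSA terminal counts are converted back to concentrations
(÷Ω) before classification so attractor locations (μM) are comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dynamics import run_ensemble
from .equilibria import EquilibriumSet, find_equilibria
from .models import ModelSpec, ModelError

__all__ = ["FateDistribution", "classify_fate", "fate_distribution",
           "bias_index", "assay_fates"]

UNRESOLVED = "unresolved"
TIE_REL_TOL = 0.05   # nearest two attractor distances within 5% -> unresolved


def attractor_labels(attractors: np.ndarray) -> list[str]:
    """Human labels for attractor coordinates in the (y1, y2) plane."""
    labels = []
    for a in np.atleast_2d(attractors):
        if a.size >= 2 and abs(a[0] - a[1]) <= 0.05 * max(a[0], a[1], 1e-12):
            labels.append("intermediate" if max(a[0], a[1]) > 1e-6 else "origin")
        elif a.size >= 2:
            labels.append("Y1-high" if a[0] > a[1] else "Y2-high")
        else:
            labels.append(f"attractor{len(labels)}")
    # disambiguate duplicates
    seen: dict[str, int] = {}
    out = []
    for lab in labels:
        if labels.count(lab) > 1:
            seen[lab] = seen.get(lab, 0) + 1
            out.append(f"{lab}#{seen[lab]}")
        else:
            out.append(lab)
    return out


@dataclass
class FateDistribution:
    """Attractor fractions and endpoint histogram of one ensemble."""

    attractors: dict[str, np.ndarray]          # label -> (y1, y2) location
    fractions: dict[str, float]                # includes an "unresolved" bucket
    histogram_counts: np.ndarray               # 8 bins of one species' endpoints
    histogram_edges: np.ndarray
    histogram_species: str
    n: int
    t_end: float
    seed: int | None = None
    omega: float | None = None
    labels: list[str] | None = None            # per-run classifications
    finals: np.ndarray | None = None           # per-run endpoints (μM)

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-12:
            raise ModelError(f"fractions must sum to 1, got {total}")
        if int(self.histogram_counts.sum()) != self.n:
            raise ModelError("histogram counts must sum to n")

    def resolved_fraction(self, label: str) -> float:
        """Fraction of *resolved* trajectories converging to ``label`` —
        the probability of converging to that attractor, with endpoints that
        could not be assigned excluded from the denominator."""
        if label not in self.attractors:
            raise ModelError(f"unknown attractor {label!r}")
        resolved = 1.0 - self.fractions.get(UNRESOLVED, 0.0)
        if resolved <= 0:
            return float("nan")
        return self.fractions[label] / resolved

    def to_json(self, path=None) -> str:
        payload = {
            "attractors": {k: list(map(float, v)) for k, v in self.attractors.items()},
            "fractions": {k: float(v) for k, v in self.fractions.items()},
            "histogram": {"species": self.histogram_species,
                          "counts": self.histogram_counts.tolist(),
                          "edges": self.histogram_edges.tolist()},
            "n": self.n, "t_end": self.t_end, "seed": self.seed, "omega": self.omega,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path) -> None:
        """Per-run endpoint/label table plus the endpoint histogram."""
        import pandas as pd
        if self.labels is None or self.finals is None:
            raise ModelError("per-run labels were not retained")
        df = pd.DataFrame(self.finals, columns=["Y1", "Y2"][: self.finals.shape[1]])
        df["fate"] = self.labels
        df.to_csv(path, index=False)


def classify_fate(final_state, attractors: dict[str, np.ndarray] | np.ndarray,
                  labels: list[str] | None = None) -> str:
    """Nearest-attractor label of one terminal state (endogenous coordinates).

    If the two nearest attractor distances differ by less than 5% relative,
    the run is labelled "unresolved" rather than force-assigned.
    """
    if isinstance(attractors, dict):
        labels = list(attractors.keys())
        locs = np.array([attractors[k] for k in labels], dtype=float)
    else:
        locs = np.atleast_2d(np.asarray(attractors, dtype=float))
        labels = labels or attractor_labels(locs)
    if locs.shape[0] == 0:
        raise ModelError("attractor list is empty")
    x = np.asarray(final_state, dtype=float)[: locs.shape[1]]
    d = np.linalg.norm(locs - x, axis=1)
    order = np.argsort(d)
    if locs.shape[0] > 1:
        d0, d1 = d[order[0]], d[order[1]]
        if d1 > 0 and (d1 - d0) / d1 < TIE_REL_TOL:
            return UNRESOLVED
        if d1 == 0:  # both attractors at x: genuinely ambiguous
            return UNRESOLVED
    return labels[int(order[0])]


def fate_distribution(finals, attractors, species: str = "Y1", bins: int = 8,
                      species_names: tuple[str, ...] = ("Y1", "Y2"),
                      t_end: float = 200.0, seed: int | None = None,
                      omega: float | None = None) -> FateDistribution:
    """Classify an ensemble of terminal states and build the 8-bin histogram.

    ``finals`` holds endogenous concentrations (rows); the histogram spans
    [0, observed max] of the chosen species with equal bins.
    """
    finals = np.atleast_2d(np.asarray(finals, dtype=float))
    if finals.shape[0] == 0:
        raise ModelError("finals is empty")
    if isinstance(attractors, dict):
        attr = {k: np.asarray(v, dtype=float) for k, v in attractors.items()}
    else:
        locs = np.atleast_2d(np.asarray(attractors, dtype=float))
        attr = dict(zip(attractor_labels(locs), locs))
    labels = [classify_fate(row, attr) for row in finals]
    n = len(labels)
    fractions = {k: labels.count(k) / n for k in attr}
    fractions[UNRESOLVED] = labels.count(UNRESOLVED) / n
    sp_idx = species_names.index(species)
    values = finals[:, sp_idx]
    hi = float(values.max())
    edges = np.linspace(0.0, hi if hi > 0 else 1.0, bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    counts[-1] += int(np.sum(values > edges[-1]))  # guard fp edge effects
    return FateDistribution(attr, fractions, counts, edges, species, n,
                            t_end=t_end, seed=seed, omega=omega,
                            labels=labels, finals=finals)


def bias_index(dist: FateDistribution, target: str) -> float:
    """fraction(target) − max fraction among the other attractors ∈ [−1, 1]."""
    if target not in dist.attractors:
        raise ModelError(f"unknown target attractor {target!r}")
    others = [v for k, v in dist.fractions.items()
              if k != target and k != UNRESOLVED]
    return dist.fractions[target] - (max(others) if others else 0.0)


def assay_fates(spec: ModelSpec, n: int = 1000, t_end: float = 200.0,
                omega: float = 1.0, seed: int = 0, species: str = "Y1",
                x0=None, equilibria: EquilibriumSet | None = None) -> FateDistribution:
    """Full assay protocol: SSA ensemble from the origin, classified against
    the spec's own stable equilibria."""
    eqs = equilibria if equilibria is not None else find_equilibria(spec)
    stable = eqs.stable
    if not stable:
        raise ModelError(f"{spec.name}: no stable equilibria to classify against")
    locs = np.array([e.y for e in stable])
    labels = attractor_labels(locs)
    x0 = np.zeros(spec.n_species) if x0 is None else np.asarray(x0, dtype=float)
    finals = run_ensemble(spec, x0, n, t_end, mode="ssa", omega=omega, seed=seed)
    endo_idx = [spec.index(s) for s in ("Y1", "Y2")]
    endo = finals[:, endo_idx].astype(float) / omega
    return fate_distribution(endo, dict(zip(labels, locs)), species=species,
                             t_end=t_end, seed=seed, omega=omega)
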