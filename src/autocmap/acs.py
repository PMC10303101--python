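"""Activation and Competition System (ACS) perturbation dynamics.

The ACS is an auto-associative recurrent probe of a trained association
matrix: one variable is clamped at maximal activation (1.0) and every other
variable, starting from a neutral resting level, evolves under the coupling
strengths until a steady state. Nodes above rest excite their neighbours in
proportion to the link strength; nodes below rest send an inhibitory signal,
so variables compete for activation. Each node's activation saturates toward
1 and decays toward the resting level, and is clipped to [0,1] every step.

For a non-clamped node i with activation aᵢ the update is

    eᵢ = Σ_{j≠i} s_{ij} (aⱼ − rest)
    Δaᵢ = γ · ( eᵢ·(1 − aᵢ)  if eᵢ ≥ 0  else  eᵢ·aᵢ ) − γ·δ·(aᵢ − rest)
    aᵢ ← clip₀¹(aᵢ + Δaᵢ)

with step gain γ, decay δ = 1. The two-node system with coupling s and one
node clamped at 1 therefore settles at the closed-form fixed point

    a* = (e + δ·rest) / (e + δ),   e = s·(1 − rest),

which is strictly increasing in the coupling s and exceeds rest whenever
s > 0. The order in which the free variables first cross an activation
threshold (rest + 0.1 by default) defines the activation hierarchy reported
alongside the steady state; it is reported as response order only, with no
causal claim.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .autocm import LinkStrengthMatrix

__all__ = [
    "ACSParams",
    "ACSResult",
    "run_acs",
    "two_node_fixed_point",
    "activation_hierarchy",
    "export_acs",
]

logger = logging.getLogger(__name__)

DECAY = 1.0  # rest-pull decay coefficient δ


@dataclass(frozen=True)
class ACSParams:
    """ACS run settings.

    variable_subset, when given, prunes the system to those labels before the
    run (the clamped variable must belong to the subset). first_passage
    threshold defaults to rest_value + 0.1.
    """

    clamp_variable: str
    clamp_value: float = 1.0
    rest_value: float = 0.5
    step_gain: float = 0.1
    max_iterations: int = 5000
    steady_tolerance: float = 1e-5
    variable_subset: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rest_value <= 1.0:
            raise ValueError("rest_value must be in [0,1]")
        if not self.step_gain > 0:
            raise ValueError("step_gain must be > 0")
        if not self.steady_tolerance > 0:
            raise ValueError("steady_tolerance must be > 0")
        if self.variable_subset is not None and self.clamp_variable not in self.variable_subset:
            raise ValueError("clamp_variable must belong to variable_subset")

    @property
    def first_passage_threshold(self) -> float:
        return self.rest_value + 0.1


@dataclass
class ACSResult:
    """Trajectories (iterations × variables), steady state and metadata."""

    labels: list[str]
    clamp_variable: str
    trajectories: np.ndarray
    steady_state: np.ndarray
    converged: bool
    iterations: int
    first_passage_threshold: float
    rest_value: float = 0.5


def two_node_fixed_point(coupling: float, rest: float = 0.5, decay: float = DECAY) -> float:
    """Closed-form steady activation of the free node in a 2-node system."""
    e = coupling * (1.0 - rest)
    return (e + decay * rest) / (e + decay)


def run_acs(strengths: LinkStrengthMatrix, params: ACSParams) -> ACSResult:
    """Clamp one variable and iterate the ACS dynamics to a steady state.

    The clamped variable is held at clamp_value every step; all others start
    at rest_value. Stops when the largest absolute activation change falls
    below steady_tolerance, or returns converged=False after max_iterations.
    """
    s = strengths.strengths
    labels = strengths.labels
    if labels is None:
        labels = [f"V{i}" for i in range(s.shape[0])]
    if params.variable_subset is not None:
        keep = [i for i, lab in enumerate(labels) if lab in params.variable_subset]
        missing = set(params.variable_subset) - {labels[i] for i in keep}
        if missing:
            raise KeyError(f"variable_subset labels not found: {sorted(missing)}")
        s = s[np.ix_(keep, keep)]
        labels = [labels[i] for i in keep]
    if params.clamp_variable not in labels:
        raise KeyError(f"clamp variable {params.clamp_variable!r} not found")
    n = len(labels)
    ci = labels.index(params.clamp_variable)

    coup = s.copy()
    np.fill_diagonal(coup, 0.0)
    free = np.arange(n) != ci

    a = np.full(n, params.rest_value)
    a[ci] = params.clamp_value
    rows = [a.copy()]
    converged = False
    for _ in range(params.max_iterations):
        e = coup @ (a - params.rest_value)
        gain = np.where(e >= 0, e * (1.0 - a), e * a)
        delta = params.step_gain * (gain - DECAY * (a - params.rest_value))
        new = np.clip(a + delta, 0.0, 1.0)
        new[ci] = params.clamp_value
        rows.append(new.copy())
        if np.abs(new[free] - a[free]).max() < params.steady_tolerance:
            a = new
            converged = True
            break
        a = new
    if not converged:
        logger.warning(
            "ACS did not reach steady state within %d iterations", params.max_iterations
        )
    traj = np.vstack(rows)
    return ACSResult(
        labels=labels,
        clamp_variable=params.clamp_variable,
        trajectories=traj,
        steady_state=traj[-1].copy(),
        converged=converged,
        iterations=traj.shape[0] - 1,
        first_passage_threshold=params.first_passage_threshold,
        rest_value=params.rest_value,
    )


def activation_hierarchy(result: ACSResult) -> list[tuple[str, int | None, float]]:
    """Rank the free variables by response timing, then intensity.

    Returns (variable, first_passage_iteration, steady_intensity) sorted by
    first-passage iteration ascending with ties broken by steady intensity
    descending; variables that never cross the threshold are listed last as
    non-responders (first_passage_iteration None).
    """
    entries: list[tuple[str, int | None, float]] = []
    for j, lab in enumerate(result.labels):
        if lab == result.clamp_variable:
            continue
        crossing = np.nonzero(result.trajectories[:, j] > result.first_passage_threshold)[0]
        first = int(crossing[0]) if crossing.size else None
        entries.append((lab, first, float(result.steady_state[j])))
    responders = sorted(
        (e for e in entries if e[1] is not None), key=lambda e: (e[1], -e[2], e[0])
    )
    silent = sorted((e for e in entries if e[1] is None), key=lambda e: (-e[2], e[0]))
    return responders + silent


def export_acs(result: ACSResult, fmt: str, path: str) -> str:
    """Write trajectories ('csv'), hierarchy ('json') or a curve plot ('png')."""
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["iteration", *result.labels])
            for it, row in enumerate(result.trajectories):
                writer.writerow([it, *[f"{x:.8f}" for x in row]])
    elif fmt == "json":
        payload = {
            "clamp_variable": result.clamp_variable,
            "converged": result.converged,
            "iterations": result.iterations,
            "first_passage_threshold": result.first_passage_threshold,
            "hierarchy": [
                {"variable": v, "first_passage_iteration": it, "steady_intensity": s}
                for v, it, s in activation_hierarchy(result)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
    elif fmt == "png":
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 5))
        for j, lab in enumerate(result.labels):
            kw = {"lw": 2.5, "color": "red"} if lab == result.clamp_variable else {"lw": 1}
            ax.plot(result.trajectories[:, j], label=lab, **kw)
        ax.set_xlabel("iteration")
        ax.set_ylabel("activation")
        ax.set_ylim(-0.02, 1.02)
        if len(result.labels) <= 20:
            ax.legend(fontsize=7, ncol=2)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
    else:
        raise ValueError(f"unknown export format {fmt!r} (csv, json, png)")
    return path
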