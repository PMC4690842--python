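"""Global material-parameter search by multiplicative updates.

Breast tissue stiffness reported in the literature varies widely, so the
registration starts from an extremal (very soft or very stiff) shear modulus
and repeatedly multiplies/divides mu and lambda by a constant factor. After
each step both sides are re-unloaded and the SSD in the central configuration
is evaluated; only steps that improve the similarity are accepted, and the
first unsuccessful step is discarded. The search does not find the "true"
stiffness - it finds a better starting point for the image-force refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["MaterialSchedule", "OptimisationTrace", "apply_material_step", "optimise_material"]


@dataclass
class MaterialSchedule:
    """Initial modulus, update factor and search direction."""

    mu0: float = 357.1  # Pa, generic starting shear modulus
    factor: float = 1.1
    direction: str = "soften"  # or "stiffen"
    max_steps: int = 20

    def __post_init__(self) -> None:
        if self.factor <= 1:
            raise ValueError("update factor must be > 1")
        if self.direction not in ("stiffen", "soften"):
            raise ValueError("direction must be 'stiffen' or 'soften'")

    @property
    def step_factor(self) -> float:
        """Multiplier applied to mu per accepted step."""
        return self.factor if self.direction == "stiffen" else 1.0 / self.factor


def apply_material_step(mu: float, factor: float, direction: str) -> float:
    """One multiplicative update of the tissue shear modulus.

    'soften' divides by the factor (a 10% reduction with factor 1.1:
    357.1 Pa -> 324.6 -> ... -> 221.7 Pa after five steps), 'stiffen'
    multiplies. Lambda is co-scaled by the caller so the Poisson ratio is
    preserved.
    """
    if factor <= 1:
        raise ValueError("update factor must be > 1")
    if direction == "stiffen":
        return mu * factor
    if direction == "soften":
        return mu / factor
    raise ValueError("direction must be 'stiffen' or 'soften'")


def mu_after_steps(mu0: float, factor: float, direction: str, n_accepted: int) -> float:
    """Modulus after ``n_accepted`` accepted steps (geometric sequence)."""
    mu = mu0
    for _ in range(n_accepted):
        mu = apply_material_step(mu, factor, direction)
    return mu


@dataclass
class OptimisationTrace:
    """Similarity and modulus history of one search."""

    mu_history: list[float] = field(default_factory=list)
    similarity_history: list[float] = field(default_factory=list)
    n_accepted: int = 0
    n_rejected: int = 0

    @property
    def best_similarity(self) -> float:
        return min(self.similarity_history)

    @property
    def best_mu(self) -> float:
        return self.mu_history[int(np.argmin(self.similarity_history))]


def optimise_material(
    evaluate: Callable[[float], float],
    schedule: MaterialSchedule,
) -> OptimisationTrace:
    """Greedy multiplicative search over the global tissue modulus.

    ``evaluate(mu)`` must re-run the unloading of both sides with tissue
    modulus ``mu`` and return the SSD in the central configuration (the
    registration core). Steps are taken while the similarity improves; the
    first non-improving step is evaluated, recorded and rejected, and the
    best configuration is returned in the trace.
    """
    trace = OptimisationTrace()
    mu = schedule.mu0
    best = evaluate(mu)
    trace.mu_history.append(mu)
    trace.similarity_history.append(best)
    for _ in range(schedule.max_steps):
        candidate = apply_material_step(mu, schedule.factor, schedule.direction)
        value = evaluate(candidate)
        trace.mu_history.append(candidate)
        trace.similarity_history.append(value)
        if value < best:
            best = value
            mu = candidate
            trace.n_accepted += 1
        else:
            # first unsuccessful update: discard and stop
            trace.n_rejected += 1
            break
    return trace
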