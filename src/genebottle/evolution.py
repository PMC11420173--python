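"""Survival and population dynamics of innate versus learned performance.

An organism's probability of still being alive decays each time step in
proportion to how badly it performs a survival-relevant task:

    p(t+1) = p(t) · [1 − α·(1 − c(t))]

where c(t) ∈ [0, 1] is the rate of correct performance at time t and
0 < α < 1 sets how much this trait contributes to survival. An organism born
competent (high innate c) loses little probability mass during the vulnerable
developmental window; one that must learn pays for every early mistake. At
the population level, cohorts reproduce in proportion to survival-to-maturity,
so the high-innate cohort takes over within a few dozen generations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = ["SurvivalModel", "survival_step", "survival_curve",
           "simulate_population", "default_scenario",
           "learning_curve_trajectory"]


def survival_step(p: float, c: float, alpha: float) -> float:
    """One application of the survival recursion."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"survival probability {p} outside [0, 1]")
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"performance {c} outside [0, 1]")
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"alpha {alpha} outside [0, 1)")
    return p * (1.0 - alpha * (1.0 - c))


@dataclass
class SurvivalModel:
    """A performance trajectory c(t) with its survival parameters."""

    alpha: float
    c: Union[Sequence[float], Callable[[int], float]]
    p0: float = 1.0

    def performance(self, t: int) -> float:
        if callable(self.c):
            return float(self.c(t))
        seq = np.asarray(self.c, dtype=np.float64)
        return float(seq[min(t, len(seq) - 1)])


def survival_curve(model: SurvivalModel, horizon: int) -> np.ndarray:
    """p(0..horizon) by iterating the recursion. For constant c this equals
    the closed form p(t) = p0 · (1 − α(1 − c))^t."""
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    p = np.empty(horizon + 1)
    p[0] = model.p0
    for t in range(horizon):
        p[t + 1] = survival_step(p[t], model.performance(t), model.alpha)
    return p


def simulate_population(cohorts: Sequence[Tuple[str, Sequence[float], float]],
                        alpha: float, generations: int,
                        horizon: int = None) -> pd.DataFrame:
    """Deterministic cohort fractions over generations.

    ``cohorts`` is a list of (label, c-trajectory, initial fraction); each
    generation every cohort's fraction is multiplied by its survival to
    maturity (the product of survival factors over the developmental horizon)
    and fractions are renormalised — proportional replacement. The horizon
    defaults to the longest trajectory length.
    """
    labels = [c[0] for c in cohorts]
    trajs = [np.asarray(c[1], dtype=np.float64) for c in cohorts]
    fracs = np.array([c[2] for c in cohorts], dtype=np.float64)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"initial fractions sum to {fracs.sum()}, not 1")
    if horizon is None:
        horizon = max(len(t) for t in trajs)
    fitness = np.array([
        survival_curve(SurvivalModel(alpha, traj), horizon)[-1]
        for traj in trajs])
    rows = [{"generation": 0, **{lab: f for lab, f in zip(labels, fracs)}}]
    for g in range(1, generations + 1):
        fracs = fracs * fitness
        total = fracs.sum()
        if total <= 0:
            raise ValueError("population went extinct (all fitness zero)")
        fracs = fracs / total
        rows.append({"generation": g, **{lab: f for lab, f in zip(labels, fracs)}})
    return pd.DataFrame(rows)


def learning_curve_trajectory(horizon: int = 20, c0: float = 0.1,
                              c_inf: float = 0.9, tau: float = 8.0) -> np.ndarray:
    """Saturating learning curve c(t) = c0 + (c∞ − c0)·(1 − exp(−t/τ)):
    chance at birth, rising toward the trained asymptote."""
    t = np.arange(horizon)
    return c0 + (c_inf - c0) * (1.0 - np.exp(-t / tau))


def default_scenario(alpha: float = 0.02, horizon: int = 20,
                     c_innate: float = 0.9) -> list:
    """Illustrative two-cohort scenario: an innate cohort born at the trained
    asymptote versus a tabula-rasa learner that reaches the same asymptote
    through experience. Parameter values are illustrative defaults (α and the
    trajectories behind the published population figures are not printed)."""
    learner = learning_curve_trajectory(horizon, c_inf=c_innate)
    innate = np.full(horizon, c_innate)
    return [("innate", innate, 0.5), ("learner", learner, 0.5)], alpha
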