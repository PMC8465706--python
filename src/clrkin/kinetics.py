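"""Forward solution of the linear kinetic system and cumulated activities.

The tracer obeys a constant-coefficient linear ODE system

    dy/dt = M y,   M[j,i] = k_{i->j} (i != j),
                   M[i,i] = -(sum_j k_{i->j}) - lambda,

with y in percent of injected activity.  Because M is constant the exact
solution is ``y(t) = expm(M t) y0``; the time-integrated ("cumulated")
activity over [0, inf) of any linear observable w.y is ``w . (-M^-1 y0)``
whenever M is strictly stable (lambda > 0, or an open system).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .parameters import ParameterSet
from .structures import BLOOD, ModelStructure, Observable

__all__ = [
    "Trajectory",
    "build_rate_matrix",
    "bolus_initial_condition",
    "solve_activities",
    "organ_activity",
    "observable_weights",
    "cumulated_activity",
    "cumulated_vector",
    "blood_contribution_fraction",
]


@dataclass(frozen=True, eq=False)
class Trajectory:
    """Solved compartment activities on a time grid.

    ``activities[p, i]`` is the percent injected activity in compartment
    ``compartments[i]`` at ``times[p]``.
    """

    times: np.ndarray
    activities: np.ndarray
    compartments: tuple[str, ...]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.activities.shape != (self.times.size, len(self.compartments)):
            raise ValueError("activities shape does not match times/compartments")

    def compartment(self, label: str) -> np.ndarray:
        return self.activities[:, self.compartments.index(label)]

    def total(self) -> np.ndarray:
        return self.activities.sum(axis=1)


def build_rate_matrix(structure: ModelStructure, params: ParameterSet) -> np.ndarray:
    """Assemble the system matrix M [1/h].

    Column sums equal ``-lambda`` exactly: every transfer moves activity
    between compartments of the system, and only physical decay removes it.
    """
    params.validate_for(structure)
    n = structure.n_compartments
    m = np.zeros((n, n))
    idx = {c: i for i, c in enumerate(structure.compartments)}
    for e in structure.edges:
        k = params.rates[e.rate]
        m[idx[e.target], idx[e.source]] += k
        m[idx[e.source], idx[e.source]] -= k
    m[np.diag_indices(n)] -= params.lam
    return m


def bolus_initial_condition(
    structure: ModelStructure, amount: float = 100.0
) -> np.ndarray:
    """Initial state: ``amount`` % in blood at t=0, all other pools empty."""
    y0 = np.zeros(structure.n_compartments)
    y0[structure.index(BLOOD)] = amount
    return y0


def solve_activities(
    structure: ModelStructure,
    params: ParameterSet,
    times: np.ndarray,
    y0: np.ndarray | None = None,
) -> Trajectory:
    """Exact matrix-exponential solution at the requested times.

    t=0 is prepended if absent so the returned trajectory always reports
    the initial condition.  Times must be non-negative and increasing.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("times must be non-negative and strictly increasing")
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
    if y0 is None:
        y0 = bolus_initial_condition(structure)
    y0 = np.asarray(y0, dtype=float)
    if y0.shape != (structure.n_compartments,) or np.any(y0 < 0):
        raise ValueError("y0 must be a non-negative vector over compartments")

    m = build_rate_matrix(structure, params)
    if not np.all(np.isfinite(m)):
        raise FloatingPointError("non-finite entries in the rate matrix")

    out = np.empty((t.size, y0.size))
    out[0] = y0 if t[0] == 0 else expm(m * t[0]) @ y0
    # propagate over increments: expm(M (t_p - t_{p-1})) is better
    # conditioned than expm(M t_p) for widely spread grids
    y = out[0].copy()
    for p in range(1, t.size):
        y = expm(m * (t[p] - t[p - 1])) @ y
        out[p] = y
    return Trajectory(times=t, activities=out, compartments=structure.compartments)


def observable_weights(
    structure: ModelStructure, params: ParameterSet, organ: str
) -> np.ndarray:
    """Weight vector w such that the organ observable is w . y."""
    try:
        obs: Observable = structure.observations[organ]
    except KeyError:
        raise KeyError(
            f"organ {organ!r} not in observation map "
            f"(known: {sorted(structure.observations)})"
        ) from None
    w = np.zeros(structure.n_compartments)
    for c in obs.compartments:
        w[structure.index(c)] += 1.0
    w[structure.index(BLOOD)] += params.fraction(obs.fraction)
    return w


def organ_activity(
    traj: Trajectory,
    structure: ModelStructure,
    params: ParameterSet,
    organ: str,
) -> np.ndarray:
    """Observable time-activity curve: member compartments + f_s * blood."""
    w = observable_weights(structure, params, organ)
    return traj.activities @ w


def cumulated_vector(
    structure: ModelStructure,
    params: ParameterSet,
    y0: np.ndarray | None = None,
) -> np.ndarray:
    """Per-compartment time integrals over [0, inf): ``-M^-1 y0`` [%·h]."""
    if y0 is None:
        y0 = bolus_initial_condition(structure)
    m = build_rate_matrix(structure, params)
    try:
        integral = np.linalg.solve(m, -np.asarray(y0, dtype=float))
    except np.linalg.LinAlgError as err:
        raise ArithmeticError(
            "cumulated activity diverges: system matrix is singular "
            "(closed system with lambda = 0?)"
        ) from err
    if np.any(integral < -1e-9 * max(1.0, float(np.max(np.abs(integral))))):
        raise ArithmeticError(
            "negative compartment integral: system is not strictly stable"
        )
    return integral


def cumulated_activity(
    structure: ModelStructure,
    params: ParameterSet,
    organ: str,
    y0: np.ndarray | None = None,
) -> float:
    """Cumulated activity Ã of an organ observable [%·h]."""
    w = observable_weights(structure, params, organ)
    return float(w @ cumulated_vector(structure, params, y0))


def blood_contribution_fraction(
    structure: ModelStructure,
    params: ParameterSet,
    organ: str,
    y0: np.ndarray | None = None,
) -> float:
    """Share of an organ's Ã contributed by its blood-fraction term, in [0,1]."""
    obs = structure.observations[organ]
    integral = cumulated_vector(structure, params, y0)
    total = float(observable_weights(structure, params, organ) @ integral)
    blood_part = params.fraction(obs.fraction) * integral[structure.index(BLOOD)]
    if total <= 0:
        raise ArithmeticError(f"organ {organ!r} has non-positive cumulated activity")
    return blood_part / total
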