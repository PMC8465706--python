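"""Simplified dosimetric estimators and cumulated-activity comparison.

Three approximations to the full compartmental model are provided, in
decreasing order of required data:

* a reduced compartmental model with the slow dry-tissue pools removed
  for every organ except the remaining tissues and the tumor;
* a per-organ biexponential fit (to the whole series, or to a four-point
  subset; the recommended subset is [2, 24, 120, 505] h), integrated in
  closed form;
* a single-point monoexponential extrapolation assuming pure physical
  decay, back-extrapolated to t=0 and integrated over [0, inf).

The comparison table mirrors the reference-versus-simplification layout
used for dosimetric evaluation: percent relative differences in Ã per
organ, with undefined entries (divergent fits) flagged rather than
raised.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .dataprep import TimeActivitySeries
from .structures import ModelStructure

logger = logging.getLogger(__name__)

__all__ = [
    "CumulatedComparison",
    "simplify_structure",
    "BiexpFit",
    "biexp_cumact",
    "best_four_point_subset",
    "monoexp_cumact",
    "compare_cumulated",
    "DEFAULT_FOUR_POINT_TIMES_H",
]

#: Recommended four-point acquisition times [h] for the reduced
#: biexponential estimator.
DEFAULT_FOUR_POINT_TIMES_H: tuple[float, ...] = (2.0, 24.0, 120.0, 505.0)

#: Organs that keep their slow pool in the reduced model.
KEEP_SLOW = ("rt", "tumor")


def simplify_structure(full: ModelStructure) -> ModelStructure:
    """Drop slow dry-tissue pools except for remaining tissues and tumor."""
    drop = [
        c
        for c in full.compartments
        if c.endswith("_slow") and c.rsplit("_", 1)[0] not in KEEP_SLOW
    ]
    return full.without_compartments(drop)


@dataclass(frozen=True)
class BiexpFit:
    """``c1 exp(-mu1 t) + c2 exp(-mu2 t)`` with closed-form integral."""

    c1: float
    mu1: float
    c2: float
    mu2: float
    wrss: float

    def __call__(self, t):
        return self.c1 * np.exp(-self.mu1 * np.asarray(t)) + self.c2 * np.exp(
            -self.mu2 * np.asarray(t)
        )

    @property
    def cumulated(self) -> float:
        if self.mu1 <= 0 or self.mu2 <= 0:
            raise ArithmeticError("divergent integral: non-positive decay rate")
        return self.c1 / self.mu1 + self.c2 / self.mu2


def biexp_cumact(
    series: TimeActivitySeries,
    time_subset: Sequence[float] | None = None,
) -> tuple[BiexpFit, float]:
    """Weighted biexponential fit and its [0, inf) integral.

    ``time_subset`` restricts the fit to the points at those times (e.g.
    the four-point clinical protocol).  Rates are unconstrained in sign
    so that data rising at late times (bladder-like) are detected: a
    non-positive fitted rate makes the integral undefined and raises
    ``ArithmeticError`` (callers may report the entry as undefined).
    """
    t_all, a_all = series.times, series.values
    sig_all = series.sigmas if series.sigmas is not None else 0.05 * np.abs(a_all)
    if time_subset is not None:
        mask = np.isin(t_all, np.asarray(time_subset, dtype=float))
        if mask.sum() < len(time_subset):
            raise ValueError("time subset not present in the series")
        t, a, sig = t_all[mask], a_all[mask], sig_all[mask]
    else:
        t, a, sig = t_all, a_all, sig_all
    if t.size < 4:
        raise ValueError("need at least 4 points for a biexponential fit")
    if np.any(a <= 0):
        raise ValueError("activities must be positive for the biexponential fit")

    span = max(t[-1] - t[0], 1.0)
    amp0 = float(a.max())

    def residuals(x):
        c1, c2, mu1, mu2 = x
        with np.errstate(over="ignore", invalid="ignore"):
            model = c1 * np.exp(-mu1 * t) + c2 * np.exp(-mu2 * t)
            out = (np.nan_to_num(model, posinf=1e30) - a) / sig
        return np.nan_to_num(out, posinf=1e30, neginf=-1e30)

    best = None
    # multi-start over rate scales; signs of the rates are free
    for f1, f2 in ((5.0, 0.2), (20.0, 1.0), (1.0, 0.05)):
        x0 = np.array([0.7 * amp0, 0.3 * amp0, f1 / span, f2 / span])
        sol = least_squares(residuals, x0, method="lm", max_nfev=20000)
        if best is None or sol.cost < best.cost:
            best = sol
    c1, c2, mu1, mu2 = best.x
    if mu1 < mu2:
        c1, c2, mu1, mu2 = c2, c1, mu2, mu1
    fit = BiexpFit(c1=c1, mu1=mu1, c2=c2, mu2=mu2, wrss=float(2 * best.cost))
    return fit, fit.cumulated


def best_four_point_subset(
    series: TimeActivitySeries,
    n_points: int = 4,
) -> tuple[tuple[float, ...], float]:
    """Exhaustive search for the best n-point acquisition subset.

    Ranks subsets of the series' time grid by the WRSS of the
    biexponential fit evaluated against the *full* series; subsets with
    divergent integrals are skipped.  Returns the winning times and
    their full-series WRSS.
    """
    t_all = series.times
    sig_all = series.sigmas if series.sigmas is not None else 0.05 * np.abs(series.values)
    best_times, best_score = None, math.inf
    for subset in combinations(t_all, n_points):
        try:
            fit, _ = biexp_cumact(series, time_subset=subset)
        except (ArithmeticError, ValueError):
            continue
        score = float(np.sum(((series.values - fit(t_all)) / sig_all) ** 2))
        if score < best_score:
            best_times, best_score = subset, score
    if best_times is None:
        raise ArithmeticError("no subset yielded a convergent biexponential fit")
    return tuple(float(t) for t in best_times), best_score


def monoexp_cumact(time_h: float, activity_pct: float, lam: float) -> float:
    """Single-point physical-decay extrapolation: Ã = A* e^{lam t*} / lam.

    Assumes the organ activity follows pure physical decay through the
    measured point ``(t*, A*)``, back-extrapolates to t=0 and integrates
    over [0, inf).
    """
    if activity_pct <= 0:
        raise ValueError("activity must be positive")
    if lam <= 0:
        raise ArithmeticError("divergent integral: decay constant must be positive")
    return activity_pct * math.exp(lam * time_h) / lam


@dataclass(frozen=True, eq=False)
class CumulatedComparison:
    """Per-organ Ã for the reference model and each simplification."""

    organs: tuple[str, ...]
    reference: Mapping[str, float]
    simplifications: Mapping[str, Mapping[str, float | None]]

    def relative_differences_pct(self) -> dict[str, dict[str, float | None]]:
        """100 (Ã_simpl - Ã_ref)/Ã_ref; None where the simplification is undefined."""
        out: dict[str, dict[str, float | None]] = {}
        for label, values in self.simplifications.items():
            col: dict[str, float | None] = {}
            for organ in self.organs:
                v = values.get(organ)
                ref = self.reference[organ]
                col[organ] = (
                    None if v is None or ref == 0 else 100.0 * (v - ref) / ref
                )
            out[label] = col
        return out

    def as_table(self) -> list[dict]:
        rel = self.relative_differences_pct()
        rows = []
        for organ in self.organs:
            row: dict = {"organ": organ, "reference": self.reference[organ]}
            for label in self.simplifications:
                d = rel[label][organ]
                row[label] = float("nan") if d is None else d
            rows.append(row)
        return rows


def compare_cumulated(
    reference: Mapping[str, float],
    simplifications: Mapping[str, Mapping[str, float | None]],
) -> CumulatedComparison:
    """Assemble the comparison for organs present in the reference.

    Missing or ``None`` entries in a simplification column are carried
    through as undefined rather than raising (e.g. divergent
    biexponential integrals for rising bladder curves).
    """
    organs = tuple(reference)
    for label, values in simplifications.items():
        missing = set(values) - set(organs)
        if missing:
            logger.warning(
                "simplification %r has entries for unknown organs: %s",
                label,
                sorted(missing),
            )
    return CumulatedComparison(
        organs=organs, reference=dict(reference), simplifications=simplifications
    )
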