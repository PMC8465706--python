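"""Weighted least-squares fitting of compartmental structures.

The fit objective is the weighted residual sum of squares

    WRSS = sum_s sum_p (A_obs[s,p] - A_model[s,p])^2 / sigma[s,p]^2

minimized by simulated annealing (geometric cooling, log-space Gaussian
proposals for rate constants, reflection at bounds, restart-from-best at
each temperature) followed by an optional derivative-free Powell polish.
Two fitting stages are provided, mirroring how the whole-body model was
assembled: decoupled subsystem fits in which the blood pool is locked to
a biexponential forcing function, and a full joint fit in which blood is
a state with a bolus initial condition.  Rate constants are free within
wide positivity bounds; blood fractions are constrained to a window
(default ±30%) around their physiological reference values.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import least_squares, minimize

from .dataprep import Dataset, TimeActivitySeries
from .kinetics import bolus_initial_condition, build_rate_matrix
from .parameters import ParameterSet
from .selection import CandidateVariant, aicc
from .structures import BLOOD, ModelStructure

logger = logging.getLogger(__name__)

__all__ = [
    "ForcingFunction",
    "FitConstraints",
    "FitResult",
    "SASchedule",
    "SAResult",
    "wrss",
    "fit_forcing_function",
    "simulated_annealing",
    "fit_subsystem",
    "fit_full_model",
    "fit_joint",
    "ORGAN_ALIASES",
]

#: Series-name -> observable-name translations (urine samples measure the
#: urinary-bladder contents).
ORGAN_ALIASES: dict[str, str] = {"urine": "bladder"}


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------


def wrss(
    dataset: Dataset | Sequence[TimeActivitySeries],
    predictions: Mapping[str, np.ndarray],
) -> float:
    """Inverse-variance weighted residual sum of squares.

    ``predictions`` maps each fitted organ to model values aligned with
    that organ's observation times (exact alignment; no interpolation).
    """
    series = dataset.series if isinstance(dataset, Dataset) else tuple(dataset)
    total = 0.0
    for s in series:
        if s.organ not in predictions:
            raise KeyError(f"no prediction supplied for organ {s.organ!r}")
        if s.sigmas is None:
            raise ValueError(f"series {s.organ!r} has no uncertainties")
        pred = np.asarray(predictions[s.organ], dtype=float)
        if pred.shape != s.times.shape:
            raise ValueError(
                f"prediction for {s.organ!r} has {pred.size} values for "
                f"{s.times.size} observation times"
            )
        total += float(np.sum(((s.values - pred) / s.sigmas) ** 2))
    return total


# ---------------------------------------------------------------------------
# Forcing function
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ForcingFunction:
    """Biexponential blood input ``A1 exp(-a1 t) + A2 exp(-a2 t)`` [%]."""

    a1: float
    alpha1: float
    a2: float
    alpha2: float

    def __post_init__(self) -> None:
        if self.alpha1 <= 0 or self.alpha2 <= 0:
            raise ValueError("forcing decay rates must be positive")

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.a1 * np.exp(-self.alpha1 * np.asarray(t)) + self.a2 * np.exp(
            -self.alpha2 * np.asarray(t)
        )

    @property
    def total(self) -> float:
        return self.a1 + self.a2


def fit_forcing_function(
    blood_series: TimeActivitySeries, total: float = 100.0
) -> tuple[ForcingFunction, float]:
    """Weighted biexponential fit of the blood curve, amplitudes summing
    to the injected bolus at t=0.

    Returns the forcing function and its residual WRSS.  If the data are
    effectively single-exponential the two rates may coincide; this is
    reported as a warning, not an error.
    """
    if len(blood_series) < 4:
        raise ValueError("need at least 4 blood points for a biexponential fit")
    t, a = blood_series.times, blood_series.values
    sig = blood_series.sigmas
    if sig is None:
        sig = 0.05 * np.abs(a)

    def residuals(x: np.ndarray) -> np.ndarray:
        a1, la1, la2 = x[0], np.exp(x[1]), np.exp(x[2])
        model = a1 * np.exp(-la1 * t) + (total - a1) * np.exp(-la2 * t)
        return (a - model) / sig

    # crude initial rates from the early/late logarithmic slopes
    span = max(t[-1] - t[0], 1.0)
    x0 = np.array([0.6 * total, math.log(5.0 / span), math.log(0.2 / span)])
    sol = least_squares(
        residuals,
        x0,
        bounds=([0.0, -20.0, -20.0], [total, 5.0, 5.0]),
        method="trf",
    )
    a1 = float(sol.x[0])
    alpha1, alpha2 = float(np.exp(sol.x[1])), float(np.exp(sol.x[2]))
    if alpha1 < alpha2:  # order: fast component first
        a1, alpha1, alpha2 = total - a1, alpha2, alpha1
    if math.isclose(alpha1, alpha2, rel_tol=1e-3):
        logger.warning(
            "biexponential blood fit degenerated to a single exponential "
            "(rates %.3g ~ %.3g)",
            alpha1,
            alpha2,
        )
    ff = ForcingFunction(a1=a1, alpha1=alpha1, a2=total - a1, alpha2=alpha2)
    return ff, float(2 * sol.cost)


# ---------------------------------------------------------------------------
# Constraints and results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitConstraints:
    """Box constraints for rates and a relative window for blood fractions.

    Rates default to [1e-8, 1e2] 1/h (spanning the physiologically
    plausible range by a wide margin); blood fractions are restricted to
    reference*(1 ± fraction_window).
    """

    rate_lower: float = 1e-8
    rate_upper: float = 1e2
    fraction_window: float = 0.30
    rate_bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def bounds_for_rate(self, name: str) -> tuple[float, float]:
        lo, hi = self.rate_bounds.get(name, (self.rate_lower, self.rate_upper))
        if not (math.isfinite(lo) and math.isfinite(hi)) or lo > hi or lo <= 0:
            raise ValueError(f"invalid rate bounds for {name!r}: ({lo}, {hi})")
        return lo, hi

    def bounds_for_fraction(self, reference: float) -> tuple[float, float]:
        lo = max(0.0, reference * (1.0 - self.fraction_window))
        hi = min(1.0, reference * (1.0 + self.fraction_window))
        return lo, hi


@dataclass(frozen=True)
class FitResult:
    """Best-fit parameters with the bookkeeping needed for model ranking."""

    params: ParameterSet
    wrss: float
    n: int
    k: int
    seed: int | None = None
    trace: tuple[float, ...] = ()
    n_evaluations: int = 0
    variant: CandidateVariant | None = None
    dataset_fingerprint: str | None = None
    forcing: ForcingFunction | None = None

    @property
    def goodness_of_fit(self) -> float:
        """WRSS per degree of freedom, N - K."""
        if self.n <= self.k:
            return float("nan")
        return self.wrss / (self.n - self.k)

    @property
    def aicc(self) -> float:
        return aicc(max(self.wrss, 1e-300), self.n, self.k)


# ---------------------------------------------------------------------------
# Simulated annealing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SASchedule:
    """Geometric cooling schedule and proposal scales."""

    n_temperatures: int = 150
    steps_per_temperature: int = 40
    cooling: float = 0.95
    step_log: float = 0.35  # proposal SD for log-scale coordinates
    step_linear: float = 0.10  # proposal SD as a fraction of the box width
    n_probe: int = 24  # random evaluations used to set the initial temperature


@dataclass(frozen=True)
class SAResult:
    x: np.ndarray
    fun: float
    trace: tuple[float, ...]
    n_evaluations: int


def _reflect(z: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Reflect out-of-box coordinates back inside [lo, hi]."""
    width = hi - lo
    z = np.where(width <= 0, lo, z)
    with np.errstate(invalid="ignore"):
        period = np.mod(z - lo, 2 * np.maximum(width, 1e-300))
        refl = np.where(period > width, 2 * width - period, period)
    return np.where(width <= 0, lo, lo + refl)


def simulated_annealing(
    objective: Callable[[np.ndarray], float],
    x0: np.ndarray,
    bounds: Sequence[tuple[float, float]],
    seed: int,
    schedule: SASchedule | None = None,
    log_scale: np.ndarray | None = None,
) -> SAResult:
    """Minimize ``objective`` inside a box by simulated annealing.

    Coordinates flagged in ``log_scale`` (rate constants) receive
    multiplicative Gaussian proposals in log space; the rest (blood
    fractions) additive proposals scaled by the box width.  Proposals
    falling outside the box are reflected back.  At the start of every
    temperature the walker restarts from the incumbent best.  The run is
    deterministic for a fixed seed, and the recorded best-so-far trace is
    non-increasing.
    """
    schedule = schedule or SASchedule()
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    x0 = np.clip(np.asarray(x0, dtype=float), lo, hi)
    if log_scale is None:
        log_scale = np.zeros(x0.size, dtype=bool)
    if np.any(lo[log_scale] <= 0):
        raise ValueError("log-scale coordinates need positive lower bounds")

    # internal coordinates: log for rates, identity otherwise
    def to_z(x: np.ndarray) -> np.ndarray:
        z = x.copy()
        z[log_scale] = np.log(x[log_scale])
        return z

    def to_x(z: np.ndarray) -> np.ndarray:
        x = z.copy()
        x[log_scale] = np.exp(z[log_scale])
        return x

    zlo, zhi = to_z(lo), to_z(hi)
    f0 = float(objective(x0))
    if not math.isfinite(f0):
        raise ValueError("objective is non-finite at the initial point")
    n_eval = 1
    best_z, best_f = to_z(x0), f0
    trace = [best_f]

    if schedule.n_temperatures == 0 or schedule.steps_per_temperature == 0:
        return SAResult(x=x0, fun=f0, trace=tuple(trace), n_evaluations=n_eval)

    # initial temperature: interquartile spread of the objective over a
    # uniform probe of the (transformed) box
    probe_vals = []
    for _ in range(schedule.n_probe):
        z = zlo + rng.random(x0.size) * (zhi - zlo)
        v = float(objective(to_x(z)))
        n_eval += 1
        if math.isfinite(v):
            probe_vals.append(v)
    if len(probe_vals) >= 4:
        q75, q25 = np.percentile(probe_vals, [75, 25])
        temp0 = max(float(q75 - q25), 1e-12)
    else:
        temp0 = max(abs(f0), 1.0)
    temp = temp0

    step = np.where(
        log_scale, schedule.step_log, schedule.step_linear * np.maximum(zhi - zlo, 1e-12)
    )
    for _ in range(schedule.n_temperatures):
        z, f = best_z.copy(), best_f  # restart from best
        # anneal the proposal scale along with the temperature
        scale = math.sqrt(max(temp / temp0, 1e-12))
        for _ in range(schedule.steps_per_temperature):
            prop = _reflect(z + rng.normal(0.0, step * scale), zlo, zhi)
            fp = float(objective(to_x(prop)))
            n_eval += 1
            if not math.isfinite(fp):
                continue
            if fp < f or rng.random() < math.exp(-(fp - f) / max(temp, 1e-300)):
                z, f = prop, fp
                if f < best_f:
                    best_z, best_f = z.copy(), f
        trace.append(best_f)
        temp *= schedule.cooling

    return SAResult(x=to_x(best_z), fun=best_f, trace=tuple(trace), n_evaluations=n_eval)


def _polish(
    objective: Callable[[np.ndarray], float],
    x: np.ndarray,
    bounds: Sequence[tuple[float, float]],
    log_scale: np.ndarray,
    maxiter: int = 40,
) -> tuple[np.ndarray, float, int]:
    """Derivative-free Powell refinement in the transformed coordinates."""
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def to_x(z: np.ndarray) -> np.ndarray:
        out = z.copy()
        out[log_scale] = np.exp(z[log_scale])
        return out

    z0 = x.copy()
    z0[log_scale] = np.log(x[log_scale])
    zlo, zhi = lo.copy(), hi.copy()
    zlo[log_scale] = np.log(lo[log_scale])
    zhi[log_scale] = np.log(hi[log_scale])
    n_eval = 0

    def fz(z: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        return float(objective(to_x(np.clip(z, zlo, zhi))))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(
            fz,
            z0,
            method="Powell",
            bounds=list(zip(zlo, zhi)),
            options={"maxiter": maxiter, "xtol": 1e-10, "ftol": 1e-12},
        )
    return to_x(np.clip(res.x, zlo, zhi)), float(res.fun), n_eval


def _polish_lsq(
    residual_fn: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    bounds: Sequence[tuple[float, float]],
    log_scale: np.ndarray,
) -> tuple[np.ndarray, float, int]:
    """Trust-region least-squares refinement in log/linear coordinates.

    Rate constants are optimized on a log scale (they are positive and
    span decades); the finite-difference Jacobian is formed there too,
    which keeps the trust region well scaled.
    """
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def to_x(z: np.ndarray) -> np.ndarray:
        out = z.copy()
        out[log_scale] = np.exp(z[log_scale])
        return out

    z0 = x.copy()
    z0[log_scale] = np.log(np.maximum(x[log_scale], lo[log_scale]))
    zlo, zhi = lo.copy(), hi.copy()
    zlo[log_scale] = np.log(lo[log_scale])
    zhi[log_scale] = np.log(hi[log_scale])
    z0 = np.clip(z0, zlo, zhi)
    sol = least_squares(
        lambda z: residual_fn(to_x(z)),
        z0,
        bounds=(zlo, zhi),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-12,
    )
    return to_x(sol.x), float(2 * sol.cost), int(sol.nfev)


# ---------------------------------------------------------------------------
# Prediction machinery shared by subsystem and full-model fits
# ---------------------------------------------------------------------------


def _observable_name(series_organ: str, structure: ModelStructure) -> str | None:
    name = ORGAN_ALIASES.get(series_organ, series_organ)
    return name if name in structure.observations else None


class _LinearPredictor:
    """Evaluates organ observables of a linear system at series times.

    ``forcing_rates`` (alpha1, alpha2) add two pseudo-compartments that
    decay at the forcing rates and feed the tissue through the blood->*
    edges without being depleted by them, which is exactly the locked
    blood curve of the decoupled stage.
    """

    def __init__(
        self,
        structure: ModelStructure,
        series: Sequence[TimeActivitySeries],
        forcing: ForcingFunction | None = None,
    ):
        self.structure = structure
        self.forcing = forcing
        self.series = [
            s for s in series if _observable_name(s.organ, structure) is not None
        ]
        dropped = [s.organ for s in series if s not in self.series]
        if dropped:
            logger.warning("series without matching observable skipped: %s", dropped)
        self.times = np.unique(np.concatenate([s.times for s in self.series]))
        self._time_index = [np.searchsorted(self.times, s.times) for s in self.series]
        comps = list(structure.compartments)
        if forcing is not None:
            comps.remove(BLOOD)
        self.comps = comps
        self.idx = {c: i for i, c in enumerate(comps)}

    def _matrix_and_y0(self, params: ParameterSet) -> tuple[np.ndarray, np.ndarray]:
        s, f = self.structure, self.forcing
        if f is None:
            m = build_rate_matrix(s, params)
            return m, bolus_initial_condition(s)
        n = len(self.comps)
        m = np.zeros((n + 2, n + 2))
        for e in s.edges:
            k = params.rates[e.rate]
            if e.source == BLOOD:
                # forcing states feed the target without being depleted
                m[self.idx[e.target], n] += k
                m[self.idx[e.target], n + 1] += k
            elif e.target == BLOOD:
                m[self.idx[e.source], self.idx[e.source]] -= k
            else:
                m[self.idx[e.target], self.idx[e.source]] += k
                m[self.idx[e.source], self.idx[e.source]] -= k
        for i in range(n):
            m[i, i] -= params.lam
        m[n, n] = -f.alpha1
        m[n + 1, n + 1] = -f.alpha2
        y0 = np.zeros(n + 2)
        y0[n], y0[n + 1] = f.a1, f.a2
        return m, y0

    def predict_per_series(self, params: ParameterSet) -> list[np.ndarray]:
        """Model values aligned with each matched series, in order."""
        m, y0 = self._matrix_and_y0(params)
        t = self.times
        states = np.empty((t.size, y0.size))
        y = expm(m * t[0]) @ y0 if t[0] > 0 else y0
        states[0] = y
        for p in range(1, t.size):
            y = expm(m * (t[p] - t[p - 1])) @ y
            states[p] = y
        preds: list[np.ndarray] = []
        for s, tidx in zip(self.series, self._time_index):
            obs = self.structure.observations[_observable_name(s.organ, self.structure)]
            w = np.zeros(y0.size)
            for c in obs.compartments:
                w[self.idx[c]] += 1.0
            frac = params.fraction(obs.fraction)
            if frac:
                if self.forcing is None:
                    w[self.idx[BLOOD]] += frac
                else:
                    n = len(self.comps)
                    w[n] += frac
                    w[n + 1] += frac
            preds.append((states @ w)[tidx])
        return preds

    def predict(self, params: ParameterSet) -> dict[str, np.ndarray]:
        """Per-organ predictions (requires organ names to be unique)."""
        organs = [s.organ for s in self.series]
        if len(set(organs)) != len(organs):
            raise ValueError(
                "duplicate organ series; merge them (e.g. PET/SPECT) before "
                "requesting per-organ predictions"
            )
        return dict(zip(organs, self.predict_per_series(params)))

    def weighted_residuals(self, params: ParameterSet) -> np.ndarray:
        return np.concatenate(
            [
                (s.values - pred) / s.sigmas
                for s, pred in zip(self.series, self.predict_per_series(params))
            ]
        )

    def wrss(self, params: ParameterSet) -> float:
        r = self.weighted_residuals(params)
        return float(r @ r)

    @property
    def n_points(self) -> int:
        return sum(len(s) for s in self.series)


def _free_parameters(
    structure: ModelStructure,
    constraints: FitConstraints,
    reference_fractions_pct: Mapping[str, float],
) -> tuple[list[str], list[str], list[tuple[float, float]], np.ndarray]:
    """Free rate/fraction names, their box bounds and the log-scale mask."""
    rate_names = list(structure.rate_names)
    frac_names = list(structure.fraction_names)
    bounds = [constraints.bounds_for_rate(r) for r in rate_names]
    for fname in frac_names:
        organ = fname.removeprefix("f_")
        ref_pct = reference_fractions_pct.get(organ)
        if ref_pct is None:
            raise KeyError(
                f"no reference blood fraction for organ {organ!r} "
                f"(needed to bound {fname!r})"
            )
        bounds.append(constraints.bounds_for_fraction(ref_pct / 100.0))
    log_scale = np.array([True] * len(rate_names) + [False] * len(frac_names))
    return rate_names, frac_names, bounds, log_scale


def _pack(
    params: ParameterSet, rate_names: Sequence[str], frac_names: Sequence[str]
) -> np.ndarray:
    return np.array(
        [params.rates[r] for r in rate_names]
        + [params.blood_fractions[f] for f in frac_names]
    )


def _unpack(
    x: np.ndarray,
    rate_names: Sequence[str],
    frac_names: Sequence[str],
    lam: float,
) -> ParameterSet:
    nr = len(rate_names)
    return ParameterSet(
        rates=dict(zip(rate_names, x[:nr])),
        blood_fractions=dict(zip(frac_names, x[nr:])),
        lam=lam,
    )


def _default_init(
    bounds: Sequence[tuple[float, float]], log_scale: np.ndarray
) -> np.ndarray:
    x = np.empty(len(bounds))
    for i, (lo, hi) in enumerate(bounds):
        x[i] = math.sqrt(lo * hi) if log_scale[i] else 0.5 * (lo + hi)
    return x


def _run_fit(
    predictor: _LinearPredictor,
    structure: ModelStructure,
    constraints: FitConstraints,
    reference_fractions_pct: Mapping[str, float],
    lam: float,
    seed: int,
    init: ParameterSet | None,
    schedule: SASchedule | None,
    polish: bool,
    fingerprint: str | None,
    variant: CandidateVariant | None = None,
    forcing: ForcingFunction | None = None,
) -> FitResult:
    rate_names, frac_names, bounds, log_scale = _free_parameters(
        structure, constraints, reference_fractions_pct
    )

    def objective(x: np.ndarray) -> float:
        return predictor.wrss(_unpack(x, rate_names, frac_names, lam))

    if init is not None:
        x0 = _pack(init, rate_names, frac_names)
    else:
        x0 = _default_init(bounds, log_scale)
    x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])

    sa = simulated_annealing(objective, x0, bounds, seed, schedule, log_scale)
    x, fun, n_eval = sa.x, sa.fun, sa.n_evaluations
    if polish == "powell":
        xp, fp, ne = _polish(objective, x, bounds, log_scale)
        n_eval += ne
        if fp < fun:
            x, fun = xp, fp
    elif polish:  # default: trust-region least squares on the residual vector
        xp, fp, ne = _polish_lsq(
            lambda xx: predictor.weighted_residuals(
                _unpack(xx, rate_names, frac_names, lam)
            ),
            x,
            bounds,
            log_scale,
        )
        n_eval += ne
        if fp < fun:
            x, fun = xp, fp
    best = _unpack(x, rate_names, frac_names, lam)
    return FitResult(
        params=best,
        wrss=fun,
        n=predictor.n_points,
        k=len(rate_names) + len(frac_names),
        seed=seed,
        trace=sa.trace,
        n_evaluations=n_eval,
        variant=variant,
        dataset_fingerprint=fingerprint,
        forcing=forcing,
    )


# ---------------------------------------------------------------------------
# Public fitting entry points
# ---------------------------------------------------------------------------


def fit_subsystem(
    forcing: ForcingFunction,
    series: TimeActivitySeries | Sequence[TimeActivitySeries] | Dataset,
    candidate: CandidateVariant,
    constraints: FitConstraints | None = None,
    reference_fractions_pct: Mapping[str, float] | None = None,
    lam: float | None = None,
    seed: int = 0,
    schedule: SASchedule | None = None,
    polish: str | bool = "lsq",
    init: ParameterSet | None = None,
) -> FitResult:
    """Fit one decoupled subsystem with the blood locked to ``forcing``.

    The candidate's blood pool is replaced by the forcing function, so
    blood->tissue edges inject ``k * h_blood(t)`` and tissue->blood edges
    are pure losses.  Physical decay applies to the tissue states (the
    forcing was fitted to decay-included blood data, so its rates already
    contain the decay).
    """
    if forcing is None:
        raise ValueError("a fitted forcing function is required for decoupled fits")
    if isinstance(series, TimeActivitySeries):
        series_list: Sequence[TimeActivitySeries] = (series,)
        fingerprint = None
        ref = reference_fractions_pct or {}
    elif isinstance(series, Dataset):
        series_list = series.series
        fingerprint = series.fingerprint()
        ref = reference_fractions_pct or series.reference_blood_fractions_pct
    else:
        series_list = tuple(series)
        fingerprint = None
        ref = reference_fractions_pct or {}
    constraints = constraints or FitConstraints()
    if lam is None:
        lam = ParameterSet().lam
    predictor = _LinearPredictor(candidate.structure, series_list, forcing=forcing)
    if not predictor.series:
        raise ValueError("no series match the candidate's observables")
    return _run_fit(
        predictor,
        candidate.structure,
        constraints,
        ref,
        lam,
        seed,
        init,
        schedule,
        polish,
        fingerprint,
        variant=candidate,
        forcing=forcing,
    )


def fit_full_model(
    dataset: Dataset,
    structure: ModelStructure,
    constraints: FitConstraints | None = None,
    init: ParameterSet | None = None,
    seed: int = 0,
    schedule: SASchedule | None = None,
    polish: str | bool = "lsq",
    lam: float | None = None,
) -> FitResult:
    """Joint fit of all rates and blood fractions with blood as a state.

    The forcing-function restriction is lifted: the blood pool evolves
    from a 100% bolus and its own series (if present) enters the
    objective.  Observables in the structure without data are excluded
    with a warning.
    """
    constraints = constraints or FitConstraints()
    if lam is None:
        lam = ParameterSet().lam
    predictor = _LinearPredictor(structure, dataset.series, forcing=None)
    observed = {_observable_name(s.organ, structure) for s in predictor.series}
    silent = set(structure.observations) - observed
    if silent:
        logger.warning("observables without data excluded from objective: %s", sorted(silent))
    return _run_fit(
        predictor,
        structure,
        constraints,
        dataset.reference_blood_fractions_pct,
        lam,
        seed,
        init,
        schedule,
        polish,
        dataset.fingerprint(),
    )


def fit_joint(
    datasets: Mapping[str, Dataset],
    structure: ModelStructure,
    free: Sequence[str] | None = None,
    tied: Sequence[str] | None = None,
    constraints: FitConstraints | None = None,
    init: ParameterSet | None = None,
    seed: int = 0,
    schedule: SASchedule | None = None,
    polish: str | bool = "lsq",
    lam: float | None = None,
) -> tuple[FitResult, dict[str, ParameterSet]]:
    """Simultaneous fit of several subjects with tied parameters.

    ``free`` parameters vary per subject (default: every rate touching a
    tumor compartment); ``tied`` parameters are shared (default: the
    rest).  The two groups must partition the free parameter names.
    Returns the combined result (parameters from the tied group plus the
    first subject's free group) and the per-subject parameter sets.
    """
    if not datasets:
        raise ValueError("no datasets supplied")
    constraints = constraints or FitConstraints()
    if lam is None:
        lam = ParameterSet().lam
    names = list(structure.rate_names) + list(structure.fraction_names)
    if free is None:
        free = [n for n in names if "tumor" in n]
    free = list(free)
    if tied is None:
        tied = [n for n in names if n not in free]
    tied = list(tied)
    overlap = set(free) & set(tied)
    if overlap:
        raise ValueError(f"parameters in both tie groups: {sorted(overlap)}")
    if set(free) | set(tied) != set(names):
        missing = set(names) - set(free) - set(tied)
        raise ValueError(f"tying specification does not cover: {sorted(missing)}")

    subjects = sorted(datasets)
    predictors = {s: _LinearPredictor(structure, datasets[s].series) for s in subjects}
    ref = {}
    for s in subjects:
        ref.update(datasets[s].reference_blood_fractions_pct)
    rate_names, frac_names, base_bounds, base_log = _free_parameters(
        structure, constraints, ref
    )
    order = rate_names + frac_names
    pos = {n: i for i, n in enumerate(order)}

    # layout: tied block, then one free block per subject
    tied_idx = [pos[n] for n in order if n in tied]
    free_idx = [pos[n] for n in order if n in free]
    tied_names = [order[i] for i in tied_idx]
    free_names = [order[i] for i in free_idx]

    bounds = [base_bounds[i] for i in tied_idx]
    log_scale = [base_log[i] for i in tied_idx]
    for _ in subjects:
        bounds += [base_bounds[i] for i in free_idx]
        log_scale += [base_log[i] for i in free_idx]
    log_scale = np.asarray(log_scale, dtype=bool)

    def split(x: np.ndarray) -> dict[str, ParameterSet]:
        nt = len(tied_idx)
        per: dict[str, ParameterSet] = {}
        for j, s in enumerate(subjects):
            block = x[nt + j * len(free_idx) : nt + (j + 1) * len(free_idx)]
            vals = dict(zip(tied_names, x[:nt])) | dict(zip(free_names, block))
            per[s] = ParameterSet(
                rates={r: vals[r] for r in rate_names},
                blood_fractions={f: vals[f] for f in frac_names},
                lam=lam,
            )
        return per

    def objective(x: np.ndarray) -> float:
        per = split(x)
        return sum(predictors[s].wrss(per[s]) for s in subjects)

    if init is not None:
        base = _pack(init, rate_names, frac_names)
    else:
        base = _default_init(base_bounds, base_log)
    x0 = np.concatenate([base[tied_idx]] + [base[free_idx]] * len(subjects))
    x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])

    sa = simulated_annealing(objective, x0, bounds, seed, schedule, log_scale)
    x, fun, n_eval = sa.x, sa.fun, sa.n_evaluations
    if polish == "powell":
        xp, fp, ne = _polish(objective, x, bounds, log_scale)
        n_eval += ne
        if fp < fun:
            x, fun = xp, fp
    elif polish:

        def joint_residuals(xx: np.ndarray) -> np.ndarray:
            per_x = split(xx)
            return np.concatenate(
                [predictors[s].weighted_residuals(per_x[s]) for s in subjects]
            )

        xp, fp, ne = _polish_lsq(joint_residuals, x, bounds, log_scale)
        n_eval += ne
        if fp < fun:
            x, fun = xp, fp

    per = split(x)
    n_total = sum(predictors[s].n_points for s in subjects)
    k_total = len(tied_idx) + len(free_idx) * len(subjects)
    combined = FitResult(
        params=per[subjects[0]],
        wrss=fun,
        n=n_total,
        k=k_total,
        seed=seed,
        trace=sa.trace,
        n_evaluations=n_eval,
    )
    return combined, per


def make_wrss_evaluator(
    dataset: Dataset,
    structure: ModelStructure,
    base: ParameterSet,
    lam: float | None = None,
) -> Callable[[Mapping[str, float]], float]:
    """Factory for a scalar WRSS evaluator over named parameter overrides.

    The returned callable accepts a mapping of rate / blood-fraction
    names to values (unmentioned parameters stay at ``base``) and returns
    the WRSS of the full model against ``dataset``; this is the default
    scalar output for sensitivity analysis.
    """
    if lam is not None:
        base = base.with_updates(lam=lam)
    predictor = _LinearPredictor(structure, dataset.series)

    def evaluate(overrides: Mapping[str, float]) -> float:
        rates = {k: v for k, v in overrides.items() if k in base.rates}
        fracs = {
            k: min(max(v, 0.0), 1.0)
            for k, v in overrides.items()
            if k in base.blood_fractions
        }
        unknown = set(overrides) - set(rates) - set(fracs)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        return predictor.wrss(base.with_updates(rates=rates, blood_fractions=fracs))

    return evaluate
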