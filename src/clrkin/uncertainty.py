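"""Monte Carlo parameter uncertainty by refitting perturbed datasets.

Each run resamples every observed activity from a normal distribution
centred on the measurement with the measurement's own standard
deviation (truncated at zero), refits the model, and the per-parameter
standard deviation over runs is reported as the parameter uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import truncnorm

from .dataprep import Dataset
from .fitting import FitConstraints, SASchedule, fit_full_model
from .parameters import ParameterSet
from .structures import ModelStructure

logger = logging.getLogger(__name__)

__all__ = ["UncertaintyResult", "perturb_dataset", "mc_uncertainty"]


@dataclass(frozen=True, eq=False)
class UncertaintyResult:
    names: tuple[str, ...]
    mean: np.ndarray
    std: np.ndarray
    runs: np.ndarray  # (n_runs_completed, n_params) per-run best fits
    wrss: np.ndarray
    n_requested: int
    n_failed: int
    seed: int

    def as_table(self) -> list[dict]:
        return [
            {"parameter": n, "mean": float(self.mean[i]), "std": float(self.std[i])}
            for i, n in enumerate(self.names)
        ]


def perturb_dataset(dataset: Dataset, seed: int) -> Dataset:
    """Resample every point from Normal(value, sigma) truncated at zero."""
    rng = np.random.default_rng(seed)
    out = []
    for s in dataset:
        if s.sigmas is None:
            raise ValueError(f"series {s.organ!r} has no sigmas to perturb with")
        new = np.empty(len(s))
        for p in range(len(s)):
            mu, sd = s.values[p], s.sigmas[p]
            if sd == 0:
                new[p] = mu
            else:
                new[p] = truncnorm.rvs(
                    (0.0 - mu) / sd, np.inf, loc=mu, scale=sd, random_state=rng
                )
        out.append(replace(s, values=new))
    return dataset.replace_series(out)


def mc_uncertainty(
    dataset: Dataset,
    structure: ModelStructure,
    constraints: FitConstraints | None = None,
    runs: int = 100,
    seed: int = 0,
    init: ParameterSet | None = None,
    schedule: SASchedule | None = None,
    polish: str | bool = "lsq",
    lam: float | None = None,
) -> UncertaintyResult:
    """Refit ``runs`` perturbed replicates and summarize parameter spread.

    Each run derives an independent perturbation seed and an independent
    optimizer seed from the master seed.  Failed runs are logged and
    excluded from the summary, never fatal.
    """
    if runs < 2:
        raise ValueError("need at least 2 Monte Carlo runs")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(runs)
    rows: list[np.ndarray] = []
    wrss_list: list[float] = []
    names: tuple[str, ...] | None = None
    n_failed = 0
    for r, child in enumerate(children):
        data_seed, sa_seed = (int(s) for s in child.generate_state(2) % (2**31))
        try:
            perturbed = perturb_dataset(dataset, data_seed)
            res = fit_full_model(
                perturbed,
                structure,
                constraints=constraints,
                init=init,
                seed=sa_seed,
                schedule=schedule,
                polish=polish,
                lam=lam,
            )
        except Exception:  # noqa: BLE001 - individual run failures are tolerated
            logger.exception("Monte Carlo run %d failed; excluded", r)
            n_failed += 1
            continue
        if names is None:
            names = tuple(res.params.rates) + tuple(res.params.blood_fractions)
        rows.append(
            np.array(
                [res.params.rates[n] for n in names if n in res.params.rates]
                + [
                    res.params.blood_fractions[n]
                    for n in names
                    if n in res.params.blood_fractions
                ]
            )
        )
        wrss_list.append(res.wrss)
    if len(rows) < 2:
        raise ArithmeticError("fewer than 2 Monte Carlo runs completed")
    table = np.vstack(rows)
    return UncertaintyResult(
        names=names,
        mean=table.mean(axis=0),
        std=table.std(axis=0, ddof=1),
        runs=table,
        wrss=np.asarray(wrss_list),
        n_requested=runs,
        n_failed=n_failed,
        seed=seed,
    )
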