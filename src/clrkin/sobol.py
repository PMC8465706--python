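"""Variance-based (Sobol) sensitivity analysis of the fit objective.

Parameters are perturbed around a base point with independent truncated
normal distributions (zero-truncation preserves rate positivity) at a
relative standard deviation of 10% by default.  First-order indices S_i
measure each parameter's direct contribution to the output variance;
total-order indices S_Ti add every interaction involving the parameter.
A parameter whose total-order index is ~0 does not influence the output
alone or in combination and can be removed from the model.

Estimators: Saltelli's two-block sampling scheme with the Jansen
formulas, at a cost of M(K+2) model evaluations for K parameters and M
samples per block.  Monte Carlo standard errors come from a bootstrap
over sample rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy.stats import truncnorm

logger = logging.getLogger(__name__)

__all__ = [
    "SobolDesign",
    "SobolResult",
    "build_design",
    "sobol_indices",
    "prune_parameters",
]


@dataclass(frozen=True, eq=False)
class SobolDesign:
    """Saltelli sample blocks for a given base point.

    ``a`` and ``b`` are independent (M, K) blocks; the K cross blocks
    AB_i (``a`` with column i replaced from ``b``) are formed lazily.
    Total model evaluations required: M(K+2).
    """

    names: tuple[str, ...]
    base: np.ndarray
    a: np.ndarray
    b: np.ndarray
    rel_sd: float
    seed: int

    @property
    def m(self) -> int:
        return self.a.shape[0]

    @property
    def k(self) -> int:
        return self.a.shape[1]

    @property
    def n_evaluations(self) -> int:
        return self.m * (self.k + 2)


@dataclass(frozen=True, eq=False)
class SobolResult:
    names: tuple[str, ...]
    s1: np.ndarray
    st: np.ndarray
    s1_se: np.ndarray
    st_se: np.ndarray
    m: int
    n_masked: int = 0

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {
            n: {
                "S1": float(self.s1[i]),
                "ST": float(self.st[i]),
                "S1_se": float(self.s1_se[i]),
                "ST_se": float(self.st_se[i]),
            }
            for i, n in enumerate(self.names)
        }


def build_design(
    base_params: Mapping[str, float],
    m: int,
    rel_sd: float = 0.10,
    seed: int = 0,
) -> SobolDesign:
    """Draw the two independent Saltelli blocks around ``base_params``.

    Each parameter is sampled from a normal centred on its base value
    with SD ``rel_sd * |base|``, truncated below at zero.  Parameters
    with base value 0 stay fixed at 0.
    """
    if m < 2:
        raise ValueError("need at least M=2 samples per block")
    if rel_sd <= 0:
        raise ValueError("relative SD must be positive")
    names = tuple(base_params)
    base = np.array([base_params[n] for n in names], dtype=float)
    rng = np.random.default_rng(seed)

    def block() -> np.ndarray:
        out = np.empty((m, base.size))
        for j, mu in enumerate(base):
            if mu == 0:
                out[:, j] = 0.0
                continue
            sd = rel_sd * abs(mu)
            a_trunc = (0.0 - mu) / sd
            out[:, j] = truncnorm.rvs(
                a_trunc, np.inf, loc=mu, scale=sd, size=m, random_state=rng
            )
        return out

    return SobolDesign(
        names=names, base=base, a=block(), b=block(), rel_sd=rel_sd, seed=seed
    )


def _jansen(
    fa: np.ndarray, fb: np.ndarray, fab: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Jansen estimators given f(A), f(B) (M,) and f(AB_i) (K, M)."""
    var = np.var(np.concatenate([fa, fb]), ddof=1)
    if var <= 0:
        return np.zeros(fab.shape[0]), np.zeros(fab.shape[0]), 0.0
    s1 = 1.0 - np.mean((fb[None, :] - fab) ** 2, axis=1) / (2 * var)
    st = np.mean((fa[None, :] - fab) ** 2, axis=1) / (2 * var)
    return s1, st, var


def sobol_indices(
    evaluator: Callable[[Mapping[str, float]], float],
    design: SobolDesign,
    n_bootstrap: int = 200,
) -> SobolResult:
    """First- and total-order indices of ``evaluator`` over the design.

    Non-finite evaluations are masked (rows dropped from every block)
    with a warning; their count is reported on the result.
    """
    names = design.names

    def run(block: np.ndarray) -> np.ndarray:
        return np.array(
            [evaluator(dict(zip(names, row))) for row in block], dtype=float
        )

    fa = run(design.a)
    fb = run(design.b)
    fab = np.empty((design.k, design.m))
    for i in range(design.k):
        abi = design.a.copy()
        abi[:, i] = design.b[:, i]
        fab[i] = run(abi)

    finite = np.isfinite(fa) & np.isfinite(fb) & np.all(np.isfinite(fab), axis=0)
    n_masked = int(design.m - finite.sum())
    if n_masked:
        logger.warning("masked %d non-finite Sobol sample rows", n_masked)
        fa, fb, fab = fa[finite], fb[finite], fab[:, finite]
    if fa.size < 2:
        raise ArithmeticError("too few finite evaluations for Sobol estimation")

    s1, st, _ = _jansen(fa, fb, fab)

    rng = np.random.default_rng(design.seed + 1)
    boot1 = np.empty((n_bootstrap, design.k))
    boott = np.empty((n_bootstrap, design.k))
    m_eff = fa.size
    for b in range(n_bootstrap):
        idx = rng.integers(0, m_eff, size=m_eff)
        b1, bt, _ = _jansen(fa[idx], fb[idx], fab[:, idx])
        boot1[b], boott[b] = b1, bt
    return SobolResult(
        names=names,
        s1=s1,
        st=st,
        s1_se=boot1.std(axis=0, ddof=1),
        st_se=boott.std(axis=0, ddof=1),
        m=m_eff,
        n_masked=n_masked,
    )


def prune_parameters(
    result: SobolResult, threshold: float = 1e-4
) -> list[str]:
    """Names whose total-order index is confidently below ``threshold``.

    A parameter is removable when S_Ti plus its Monte Carlo standard
    error stays under the threshold: it influences the output neither
    directly nor through interactions, so the corresponding exchange path
    can be dropped from the model before refitting.  With few samples the
    MC error is large and nothing is pruned — by design.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    removable = [
        n
        for i, n in enumerate(result.names)
        if result.st[i] + result.st_se[i] < threshold
    ]
    if removable:
        logger.info("prunable parameters (ST < %g): %s", threshold, removable)
    return removable
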