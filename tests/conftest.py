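import numpy as np
import pytest

from clrkin import (
    Dataset,
    ParameterSet,
    TimeActivitySeries,
    final_model,
    reference_parameters,
)
from clrkin.kinetics import bolus_initial_condition, organ_activity, solve_activities
from clrkin.structures import BLOOD, Edge, ModelStructure, Observable
from clrkin.synth import generate_dataset


@pytest.fixture(scope="session")
def structure() -> ModelStructure:
    return final_model()


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return reference_parameters()


@pytest.fixture(scope="session")
def clean_dataset(structure, params) -> Dataset:
    """Noise-free clinical-template dataset from the reference truth."""
    return generate_dataset(
        structure, params, seed=1, noise_scale=0.0, include_spinal_cord=False
    )


@pytest.fixture(scope="session")
def noisy_dataset(structure, params) -> Dataset:
    """Clinical-template dataset at the nominal 5%/10% noise levels."""
    return generate_dataset(structure, params, seed=7)


def make_random_stable_system(seed: int, n_tissues: int = 4):
    """Random open linear system: blood plus ``n_tissues`` pools, lam > 0.

    Every tissue exchanges with blood at random rates; one tissue is a
    sink.  Used as a stress pool for mass-balance / integration checks.
    """
    rng = np.random.default_rng(seed)
    comps = [BLOOD] + [f"t{i}" for i in range(n_tissues)]
    edges = []
    rates = {}
    for i in range(n_tissues):
        name_in = f"blood_to_t{i}"
        edges.append(Edge(BLOOD, f"t{i}", name_in))
        rates[name_in] = float(10 ** rng.uniform(-3, 0))
        if i != 0:  # t0 is a sink
            name_out = f"t{i}_to_blood"
            edges.append(Edge(f"t{i}", BLOOD, name_out))
            rates[name_out] = float(10 ** rng.uniform(-3, 0))
    obs = {f"t{i}": Observable((f"t{i}",), None) for i in range(n_tissues)}
    obs[BLOOD] = Observable((BLOOD,), None)
    structure = ModelStructure(tuple(comps), tuple(edges), obs)
    lam = float(10 ** rng.uniform(-3, -1.5))
    params = ParameterSet(rates=rates, lam=lam)
    return structure, params


@pytest.fixture
def random_stable_system():
    return make_random_stable_system


def make_series_dataset(
    structure: ModelStructure,
    params: ParameterSet,
    organs: list[str],
    times: np.ndarray,
    rel_sigma: float = 0.05,
    noise_scale: float = 0.0,
    seed: int = 0,
    reference_fractions_pct: dict | None = None,
) -> Dataset:
    """Small hand-rolled dataset for arbitrary structures (test helper)."""
    rng = np.random.default_rng(seed)
    traj = solve_activities(
        structure, params, times, bolus_initial_condition(structure)
    )
    idx = np.searchsorted(traj.times, times)
    series = []
    for organ in organs:
        clean = organ_activity(traj, structure, params, organ)[idx]
        noisy = clean * np.maximum(
            1.0 + noise_scale * rel_sigma * rng.standard_normal(clean.size), 0.0
        )
        series.append(
            TimeActivitySeries(
                organ=organ,
                times=times,
                values=noisy,
                sigmas=np.maximum(rel_sigma * np.abs(noisy), 1e-9),
            )
        )
    return Dataset(
        series=tuple(series),
        reference_blood_fractions_pct=reference_fractions_pct or {},
    )
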