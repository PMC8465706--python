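"""Synthetic time-activity datasets with the structure of the clinical study.

The clinical series this package was designed around were digitized from
published figures and are not deposited anywhere, so every pipeline stage
is exercised against synthetic data drawn from a known ground truth: the
kinetic model is solved forward from a 100% bolus in blood, organ
observables are sampled on a PET-like (<= 120 h) plus SPECT-like
(120-505 h) schedule, and multiplicative truncated-normal noise is
applied at the nominal relative uncertainty of each modality (5%, or 10%
for tumor SPECT).  Blood and urine (bladder-content) series are included,
as is a low-uptake spinal-cord series that the default filtering rules
subsequently discard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from .dataprep import Dataset, TimeActivitySeries
from .kinetics import bolus_initial_condition, organ_activity, solve_activities
from .parameters import (
    HUMAN_ORGAN_MASSES_G,
    HUMAN_REFERENCE_BLOOD_FRACTIONS_PCT,
    MURINE_ORGAN_MASSES_G,
    MURINE_REFERENCE_BLOOD_FRACTIONS_PCT,
    ParameterSet,
)
from .structures import ModelStructure

__all__ = [
    "AcquisitionSchedule",
    "generate_dataset",
    "generate_xenograft_dataset",
    "DEFAULT_PET_TIMES_H",
    "DEFAULT_SPECT_TIMES_H",
    "DEFAULT_XENOGRAFT_TIMES_H",
]

#: Early (PET-like) sampling grid [h], up to 120 h post-injection.
DEFAULT_PET_TIMES_H: tuple[float, ...] = (2.0, 5.0, 24.0, 48.0, 72.0, 120.0)

#: Late (SPECT-like) sampling grid [h], 120-505 h post-injection.
DEFAULT_SPECT_TIMES_H: tuple[float, ...] = (170.0, 330.0, 505.0)

#: Murine PET/CT sampling grid [h].
DEFAULT_XENOGRAFT_TIMES_H: tuple[float, ...] = (1.0, 4.0, 24.0, 48.0, 96.0)

#: Fraction of the blood curve emulating the (discarded) spinal-cord series.
SPINAL_CORD_BLOOD_FRACTION = 0.004

_CLINICAL_ORGANS = ("heart_wall", "kidneys", "lungs", "liver", "bone_marrow", "spleen")


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Sampling times and per-modality noise levels (relative SD)."""

    pet_times: tuple[float, ...] = DEFAULT_PET_TIMES_H
    spect_times: tuple[float, ...] = DEFAULT_SPECT_TIMES_H
    blood_times: tuple[float, ...] = DEFAULT_PET_TIMES_H + DEFAULT_SPECT_TIMES_H
    urine_times: tuple[float, ...] = DEFAULT_PET_TIMES_H + DEFAULT_SPECT_TIMES_H
    noise_rel: float = 0.05
    tumor_spect_noise_rel: float = 0.10

    def __post_init__(self) -> None:
        for t in self.pet_times:
            if not 0 <= t <= 120:
                raise ValueError("PET-like times must lie in [0, 120] h")
        for t in self.spect_times:
            if not 120 < t <= 505:
                raise ValueError("SPECT-like times must lie in (120, 505] h")

    @property
    def organ_times(self) -> tuple[float, ...]:
        return self.pet_times + self.spect_times


def _noisy(values: np.ndarray, rel: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative truncated-normal noise: factor ~ N(1, rel) restricted > 0."""
    if rel == 0:
        return values.copy()
    a = (0.0 - 1.0) / rel  # lower truncation at factor 0
    factors = truncnorm.rvs(a, np.inf, loc=1.0, scale=rel, size=values.size, random_state=rng)
    return values * factors


def generate_dataset(
    structure: ModelStructure,
    truth: ParameterSet,
    schedule: AcquisitionSchedule | None = None,
    seed: int = 0,
    noise_scale: float = 1.0,
    tumor_spect_scale: float = 1.0,
    include_spinal_cord: bool = True,
    bolus_pct: float = 100.0,
) -> Dataset:
    """Sample a clinical-template dataset from a known ground truth.

    Parameters
    ----------
    noise_scale:
        Multiplies the schedule's relative noise; 0 yields noise-free data
        (the attached sigmas still reflect the nominal uncertainty levels,
        mirroring how relative uncertainties are assigned to real data).
    tumor_spect_scale:
        Calibration mismatch applied to the raw tumor SPECT series (1.0 =
        no mismatch); exercises the PET/SPECT merge-and-rescale step.
    """
    schedule = schedule or AcquisitionSchedule()
    truth.validate_for(structure)
    rng = np.random.default_rng(seed)

    all_times = np.unique(
        np.concatenate(
            [schedule.organ_times, schedule.blood_times, schedule.urine_times]
        ).astype(float)
    )
    traj = solve_activities(
        structure, truth, all_times, bolus_initial_condition(structure, bolus_pct)
    )

    def at(organ: str, times: tuple[float, ...]) -> np.ndarray:
        curve = organ_activity(traj, structure, truth, organ)
        idx = np.searchsorted(traj.times, np.asarray(times))
        return curve[idx]

    series: list[TimeActivitySeries] = []
    t_organ = schedule.organ_times
    for organ in _CLINICAL_ORGANS:
        clean = at(organ, t_organ)
        obs = _noisy(clean, schedule.noise_rel * noise_scale, rng)
        series.append(
            TimeActivitySeries(
                organ=organ,
                times=np.asarray(t_organ),
                values=obs,
                sigmas=np.maximum(schedule.noise_rel * np.abs(obs), 1e-9),
                modality="synthetic",
            )
        )

    # tumor: separate PET and SPECT series, SPECT on its own (possibly
    # mismatched) calibration scale
    tumor_pet = _noisy(at("tumor", schedule.pet_times), schedule.noise_rel * noise_scale, rng)
    series.append(
        TimeActivitySeries(
            organ="tumor",
            times=np.asarray(schedule.pet_times),
            values=tumor_pet,
            sigmas=np.maximum(schedule.noise_rel * np.abs(tumor_pet), 1e-9),
            modality="PET",
        )
    )
    spect_times = (120.0,) + schedule.spect_times  # first point overlaps the PET range
    tumor_spect = tumor_spect_scale * _noisy(
        at("tumor", spect_times), schedule.tumor_spect_noise_rel * noise_scale, rng
    )
    series.append(
        TimeActivitySeries(
            organ="tumor",
            times=np.asarray(spect_times),
            values=tumor_spect,
            sigmas=np.maximum(
                schedule.tumor_spect_noise_rel * np.abs(tumor_spect), 1e-9
            ),
            modality="SPECT",
        )
    )

    if include_spinal_cord:
        blood_curve = at("blood", t_organ)
        sc = _noisy(
            SPINAL_CORD_BLOOD_FRACTION * blood_curve,
            schedule.noise_rel * noise_scale,
            rng,
        )
        series.append(
            TimeActivitySeries(
                organ="spinal_cord",
                times=np.asarray(t_organ),
                values=sc,
                sigmas=np.maximum(schedule.noise_rel * np.abs(sc), 1e-9),
                modality="synthetic",
            )
        )

    blood = _noisy(at("blood", schedule.blood_times), schedule.noise_rel * noise_scale, rng)
    series.append(
        TimeActivitySeries(
            organ="blood",
            times=np.asarray(schedule.blood_times),
            values=blood,
            sigmas=np.maximum(schedule.noise_rel * np.abs(blood), 1e-9),
            modality="blood",
        )
    )
    urine = _noisy(at("bladder", schedule.urine_times), schedule.noise_rel * noise_scale, rng)
    series.append(
        TimeActivitySeries(
            organ="urine",
            times=np.asarray(schedule.urine_times),
            values=urine,
            sigmas=np.maximum(schedule.noise_rel * np.abs(urine), 1e-9),
            modality="urine",
        )
    )

    return Dataset(
        series=tuple(series),
        masses_g=dict(HUMAN_ORGAN_MASSES_G),
        reference_blood_fractions_pct=dict(HUMAN_REFERENCE_BLOOD_FRACTIONS_PCT),
    )


def generate_xenograft_dataset(
    structure: ModelStructure,
    shared: ParameterSet,
    tumor_lines: dict[str, dict[str, float]],
    times_h: tuple[float, ...] = DEFAULT_XENOGRAFT_TIMES_H,
    seed: int = 0,
    noise_scale: float = 1.0,
    noise_rel: float = 0.05,
) -> dict[str, Dataset]:
    """Per-tumor-line murine datasets sharing organ kinetics.

    Each subject (tumor line) shares every organ rate and blood fraction
    but carries its own tumor rate constants (``tumor_lines`` maps line
    name -> overrides for tumor rates).  Organ activities are expressed
    as concentrations [%/g] using the 30 g phantom masses, so downstream
    mass scaling is exercised; no blood or urine series are produced.
    """
    if not 1 <= len(tumor_lines) <= 4:
        raise ValueError("expected 1-4 tumor lines")
    out: dict[str, Dataset] = {}
    t = np.asarray(times_h, dtype=float)
    for i, (line, tumor_rates) in enumerate(sorted(tumor_lines.items())):
        params = shared.with_updates(rates=tumor_rates)
        params.validate_for(structure)
        rng = np.random.default_rng(np.random.SeedSequence(entropy=[seed, i]))
        traj = solve_activities(structure, params, t)
        idx = np.searchsorted(traj.times, t)
        series = []
        for organ, mass in MURINE_ORGAN_MASSES_G.items():
            clean = organ_activity(traj, structure, params, organ)[idx]
            obs = _noisy(clean, noise_rel * noise_scale, rng)
            series.append(
                TimeActivitySeries(
                    organ=organ,
                    times=t,
                    values=obs / mass,
                    sigmas=np.maximum(noise_rel * np.abs(obs) / mass, 1e-12),
                    modality="PET",
                    units="percent_per_gram",
                )
            )
        tumor_clean = organ_activity(traj, structure, params, "tumor")[idx]
        tumor_obs = _noisy(tumor_clean, noise_rel * noise_scale, rng)
        series.append(
            TimeActivitySeries(
                organ="tumor",
                times=t,
                values=tumor_obs,
                sigmas=np.maximum(noise_rel * np.abs(tumor_obs), 1e-12),
                modality="PET",
            )
        )
        out[line] = Dataset(
            series=tuple(series),
            masses_g=dict(MURINE_ORGAN_MASSES_G),
            reference_blood_fractions_pct=dict(MURINE_REFERENCE_BLOOD_FRACTIONS_PCT),
        )
    return out
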