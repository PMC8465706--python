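"""Time-activity series handling and pre-fit data processing.

Covers the steps that turn reported imaging/sample data into a fittable
dataset: scaling per-mass concentrations [%/g] to whole-organ activities
[%] with reference organ masses, merging PET (early, <= 120 h) and SPECT
(late) tumor series after rescaling the SPECT branch onto the PET scale,
assigning relative measurement uncertainties, and removing excluded
points/series.  All fitting downstream runs on decay-included activities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TimeActivitySeries",
    "Dataset",
    "concentration_to_activity",
    "merge_pet_spect_tumor",
    "assign_uncertainties",
    "filter_points",
    "DEFAULT_EXCLUSIONS",
    "read_series_csv",
    "write_series_csv",
]

MODALITIES = ("PET", "SPECT", "blood", "urine", "synthetic")
SIGMA_FLOOR = 1e-6  # % injected activity; keeps inverse-variance weights finite


@dataclass(frozen=True, eq=False)
class TimeActivitySeries:
    """One organ's measured (or simulated) activity curve.

    ``units`` is ``"percent"`` (whole-organ % of injected activity) or
    ``"percent_per_gram"`` (concentration, needs mass scaling).  ``decay``
    records whether physical decay is included in the values (the default
    everywhere in this package) or has been corrected out.
    """

    organ: str
    times: np.ndarray
    values: np.ndarray
    sigmas: np.ndarray | None = None
    modality: str = "synthetic"
    units: str = "percent"
    decay: str = "decay_included"

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.sigmas is not None:
            object.__setattr__(self, "sigmas", np.asarray(self.sigmas, dtype=float))
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.units not in ("percent", "percent_per_gram"):
            raise ValueError(f"unknown units flag {self.units!r}")
        if self.decay not in ("decay_included", "decay_corrected"):
            raise ValueError(f"unknown decay flag {self.decay!r}")
        if self.times.ndim != 1 or self.values.shape != self.times.shape:
            raise ValueError("times and values must be matching 1-D arrays")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError(
                f"series {self.organ!r}: times must be >= 0 and strictly increasing"
            )
        if self.sigmas is not None and (
            self.sigmas.shape != self.times.shape or np.any(self.sigmas <= 0)
        ):
            raise ValueError(f"series {self.organ!r}: sigmas must be positive")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True, eq=False)
class Dataset:
    """A collection of series plus the masses/reference fractions they need."""

    series: tuple[TimeActivitySeries, ...]
    masses_g: Mapping[str, float] = field(default_factory=dict)
    reference_blood_fractions_pct: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.series:
            if s.units == "percent_per_gram" and s.organ not in self.masses_g:
                raise ValueError(
                    f"series {s.organ!r} is in %/g but no organ mass is provided"
                )
        for organ, f in self.reference_blood_fractions_pct.items():
            if not 0.0 <= f <= 100.0:
                raise ValueError(
                    f"reference blood fraction for {organ!r} must be in [0,100]%"
                )

    def __iter__(self):
        return iter(self.series)

    @property
    def organs(self) -> tuple[str, ...]:
        return tuple(s.organ for s in self.series)

    def get(self, organ: str, modality: str | None = None) -> TimeActivitySeries:
        hits = [
            s
            for s in self.series
            if s.organ == organ and (modality is None or s.modality == modality)
        ]
        if not hits:
            raise KeyError(f"no series for organ {organ!r} (modality={modality})")
        if len(hits) > 1:
            raise KeyError(f"ambiguous series lookup for {organ!r}: pass modality")
        return hits[0]

    def replace_series(self, new: Iterable[TimeActivitySeries]) -> "Dataset":
        return replace(self, series=tuple(new))

    @property
    def n_points(self) -> int:
        return sum(len(s) for s in self.series)

    def fingerprint(self) -> str:
        """Stable hash of the fitted coordinates, for AICc comparability checks."""
        import hashlib

        h = hashlib.sha256()
        for s in sorted(self.series, key=lambda s: (s.organ, s.modality)):
            h.update(s.organ.encode())
            h.update(s.modality.encode())
            h.update(np.ascontiguousarray(s.times).tobytes())
            h.update(np.ascontiguousarray(s.values).tobytes())
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Processing operations
# ---------------------------------------------------------------------------


def concentration_to_activity(
    series: TimeActivitySeries, mass_g: float
) -> TimeActivitySeries:
    """Scale a %/g concentration series to whole-organ % activity."""
    if series.units != "percent_per_gram":
        raise ValueError(f"series {series.organ!r} is not in %/g units")
    if not mass_g > 0:
        raise ValueError(f"organ {series.organ!r}: mass must be positive, got {mass_g}")
    return replace(
        series,
        values=series.values * mass_g,
        sigmas=None if series.sigmas is None else series.sigmas * mass_g,
        units="percent",
    )


def merge_pet_spect_tumor(
    pet: TimeActivitySeries,
    spect: TimeActivitySeries,
    junction_time_h: float = 120.0,
) -> tuple[TimeActivitySeries, float]:
    """Rescale a late SPECT series onto the PET scale and concatenate.

    The SPECT points are fit to a single exponential ``A exp(-mu t)`` by
    weighted least squares on log-activities; the series is multiplied by
    ``PET(junction) / fit(junction)`` so the merged curve is continuous at
    the junction, and any SPECT point at or before the junction (already
    covered by the PET range) is discarded.  Returns the merged series and
    the scale factor applied.
    """
    j = np.flatnonzero(np.isclose(pet.times, junction_time_h))
    if j.size == 0:
        raise ValueError(
            f"PET series {pet.organ!r} has no point at the junction "
            f"time {junction_time_h} h"
        )
    pet_at_junction = float(pet.values[j[0]])
    late = spect.times > junction_time_h
    if np.count_nonzero(late) < 2:
        raise ValueError("need at least two SPECT points after the junction time")
    if np.any(spect.values[late] <= 0):
        raise ValueError("SPECT activities must be positive for the exponential fit")

    t, a = spect.times[late], spect.values[late]
    # weighted LS on log(A): relative errors become additive
    w = None
    if spect.sigmas is not None:
        w = (a / spect.sigmas[late]) ** 2
    coef = np.polyfit(t, np.log(a), 1, w=w)
    mu, log_amp = -coef[0], coef[1]
    fit_at_junction = float(np.exp(log_amp - mu * junction_time_h))
    scale = pet_at_junction / fit_at_junction

    merged_t = np.concatenate([pet.times, t])
    merged_v = np.concatenate([pet.values, a * scale])
    merged_s = None
    if pet.sigmas is not None and spect.sigmas is not None:
        merged_s = np.concatenate([pet.sigmas, spect.sigmas[late] * scale])
    merged = replace(pet, times=merged_t, values=merged_v, sigmas=merged_s)
    logger.info(
        "merged %s SPECT onto PET at %g h with scale factor %.4g",
        pet.organ,
        junction_time_h,
        scale,
    )
    return merged, scale


def assign_uncertainties(
    dataset: Dataset,
    default_rel: float = 0.05,
    tumor_spect_rel: float = 0.10,
) -> Dataset:
    """Attach relative measurement uncertainties where none are present.

    5% of the measured activity by default; 10% for tumor SPECT points
    (where the PET/SPECT scale mismatch makes the data less reliable).
    Series that already carry sigmas (e.g. cohort dispersions for blood
    and urine) are left untouched.  Zero activities get a small floor so
    inverse-variance weights stay finite.
    """
    out = []
    for s in dataset:
        if s.sigmas is not None:
            out.append(s)
            continue
        rel = tumor_spect_rel if (s.organ == "tumor" and s.modality == "SPECT") else default_rel
        sig = rel * np.abs(s.values)
        if np.any(sig <= 0):
            logger.warning(
                "series %s/%s has zero activities; applying sigma floor %.1e",
                s.organ,
                s.modality,
                SIGMA_FLOOR,
            )
            sig = np.maximum(sig, SIGMA_FLOOR)
        out.append(replace(s, sigmas=sig))
    return dataset.replace_series(out)


#: Exclusions applied to the clinical template: the 120 h urine point
#: (unrepresentative cohort dispersion) and the whole low-uptake
#: spinal-cord series.
DEFAULT_EXCLUSIONS: tuple[tuple[str, float | None], ...] = (
    ("urine", 120.0),
    ("spinal_cord", None),
)


def filter_points(
    dataset: Dataset,
    exclusions: Sequence[tuple[str, float | None]] = DEFAULT_EXCLUSIONS,
) -> Dataset:
    """Drop excluded points or whole series.

    Each exclusion is ``(organ, time)`` to drop a single point, or
    ``(organ, None)`` to drop every series of that organ.  Exclusions that
    match nothing are logged as warnings, not errors.
    """
    out: list[TimeActivitySeries] = []
    matched = [False] * len(exclusions)
    for s in dataset:
        drop_series = False
        keep = np.ones(len(s), dtype=bool)
        for i, (organ, t) in enumerate(exclusions):
            if organ != s.organ:
                continue
            if t is None:
                drop_series = True
                matched[i] = True
                logger.info("excluding whole series %s/%s", s.organ, s.modality)
            else:
                hit = np.isclose(s.times, t)
                if hit.any():
                    keep &= ~hit
                    matched[i] = True
                    logger.info("excluding point %s @ %g h", s.organ, t)
        if drop_series:
            continue
        if keep.all():
            out.append(s)
        elif keep.any():
            out.append(
                replace(
                    s,
                    times=s.times[keep],
                    values=s.values[keep],
                    sigmas=None if s.sigmas is None else s.sigmas[keep],
                )
            )
    for (organ, t), hit in zip(exclusions, matched):
        if not hit:
            logger.warning("exclusion (%s, %s) matched no data", organ, t)
    return dataset.replace_series(out)


# ---------------------------------------------------------------------------
# CSV I/O (tidy format: organ, time_h, value, sigma, modality, units, decay)
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["organ", "time_h", "value", "sigma", "modality", "units", "decay"]


def write_series_csv(dataset: Dataset, path: str | Path) -> None:
    rows = []
    for s in dataset:
        for p in range(len(s)):
            rows.append(
                {
                    "organ": s.organ,
                    "time_h": s.times[p],
                    "value": s.values[p],
                    "sigma": np.nan if s.sigmas is None else s.sigmas[p],
                    "modality": s.modality,
                    "units": s.units,
                    "decay": s.decay,
                }
            )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_series_csv(
    path: str | Path,
    masses_g: Mapping[str, float] | None = None,
    reference_blood_fractions_pct: Mapping[str, float] | None = None,
) -> Dataset:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"series CSV missing columns: {sorted(missing)}")
    series = []
    for (organ, modality, units, decay), g in df.groupby(
        ["organ", "modality", "units", "decay"], sort=True
    ):
        g = g.sort_values("time_h")
        sig = g["sigma"].to_numpy()
        series.append(
            TimeActivitySeries(
                organ=organ,
                times=g["time_h"].to_numpy(),
                values=g["value"].to_numpy(),
                sigmas=None if np.isnan(sig).all() else sig,
                modality=modality,
                units=units,
                decay=decay,
            )
        )
    return Dataset(
        series=tuple(series),
        masses_g=dict(masses_g or {}),
        reference_blood_fractions_pct=dict(reference_blood_fractions_pct or {}),
    )
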