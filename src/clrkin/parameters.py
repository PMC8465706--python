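"""Rate-constant / blood-fraction parameter sets and reference values.

Reference numbers shipped here are the published best-fit kinetic
parameters for 131-I-CLR1404 in a human patient, the ICRP-style organ
masses and resting blood fractions used to convert per-mass activity
concentrations into whole-organ relative activities, and the murine
(30 g phantom) counterparts used for the xenograft data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .nuclides import LAMBDA_I131
from .structures import ModelStructure

__all__ = [
    "ParameterSet",
    "reference_parameters",
    "REFERENCE_RATES",
    "REFERENCE_BLOOD_FRACTIONS",
    "HUMAN_ORGAN_MASSES_G",
    "HUMAN_REFERENCE_BLOOD_FRACTIONS_PCT",
    "MURINE_ORGAN_MASSES_G",
    "MURINE_REFERENCE_BLOOD_FRACTIONS_PCT",
]


@dataclass(frozen=True)
class ParameterSet:
    """Kinetic parameters of a compartmental structure.

    Attributes
    ----------
    rates:
        Mapping edge-rate name -> first-order rate constant [1/h], >= 0.
    blood_fractions:
        Mapping blood-fraction parameter name -> fraction in [0, 1].
    lam:
        Physical decay constant [1/h] of the radiolabel (>= 0).
    """

    rates: Mapping[str, float] = field(default_factory=dict)
    blood_fractions: Mapping[str, float] = field(default_factory=dict)
    lam: float = LAMBDA_I131

    def __post_init__(self) -> None:
        import math

        for name, v in self.rates.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"rate {name!r} must be finite and >= 0, got {v}")
        for name, v in self.blood_fractions.items():
            if not math.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"blood fraction {name!r} must be in [0,1], got {v}")
        if not math.isfinite(self.lam) or self.lam < 0:
            raise ValueError(f"decay constant must be finite and >= 0, got {self.lam}")

    def validate_for(self, structure: ModelStructure) -> None:
        """Check completeness against a structure; raises KeyError naming gaps."""
        missing = [r for r in structure.rate_names if r not in self.rates]
        if missing:
            raise KeyError(f"missing rate values for edges: {missing}")
        missing_f = [
            f for f in structure.fraction_names if f not in self.blood_fractions
        ]
        if missing_f:
            raise KeyError(f"missing blood-fraction values: {missing_f}")

    def fraction(self, name: str | None) -> float:
        return 0.0 if name is None else self.blood_fractions[name]

    def with_updates(
        self,
        rates: Mapping[str, float] | None = None,
        blood_fractions: Mapping[str, float] | None = None,
        lam: float | None = None,
    ) -> "ParameterSet":
        return ParameterSet(
            rates={**self.rates, **(rates or {})},
            blood_fractions={**self.blood_fractions, **(blood_fractions or {})},
            lam=self.lam if lam is None else lam,
        )

    def restricted_to(self, structure: ModelStructure) -> "ParameterSet":
        """Drop entries not used by ``structure``."""
        return ParameterSet(
            rates={r: self.rates[r] for r in structure.rate_names if r in self.rates},
            blood_fractions={
                f: self.blood_fractions[f]
                for f in structure.fraction_names
                if f in self.blood_fractions
            },
            lam=self.lam,
        )


# ---------------------------------------------------------------------------
# Published best-fit values (human, 131-I label)
# ---------------------------------------------------------------------------

#: Best-fit rate constants [1/h].
REFERENCE_RATES: dict[str, float] = {
    "blood_to_heart_fast": 2.3e-1,
    "heart_fast_to_blood": 6.8,
    "heart_fast_to_heart_slow": 9.3e-4,
    "blood_to_kidney_fast": 1.2e-2,
    "kidney_fast_to_blood": 4.1e-1,
    "kidney_fast_to_kidney_slow": 2.1e-3,
    "blood_to_tumor_fast": 1.7e-2,
    "tumor_fast_to_blood": 2.0e1,
    "tumor_fast_to_tumor_slow": 1.0e-1,
    "tumor_slow_to_tumor_fast": 2.6e-2,
    "blood_to_lung_fast": 3.4e-3,
    "lung_fast_to_blood": 5.0e-2,
    "lung_fast_to_lung_slow": 3.6e-3,
    "blood_to_liver_fast": 6.1e-2,
    "liver_fast_to_blood": 9.2e-1,
    "liver_fast_to_liver_slow": 2.5e-3,
    "blood_to_marrow_fast": 1.0e-3,
    "marrow_fast_to_blood": 2.9e-2,
    "marrow_fast_to_marrow_slow": 2.0e-3,
    "blood_to_rt_fast": 3.6e-2,
    "rt_fast_to_blood": 2.8e-2,
    "rt_fast_to_rt_slow": 1.1e-3,
    "kidney_fast_to_bladder": 1.9e-2,
    "blood_to_spleen": 1.6e-5,
}

#: Best-fit blood fractions (dimensionless, not percent).
REFERENCE_BLOOD_FRACTIONS: dict[str, float] = {
    "f_heart_wall": 0.008,
    "f_kidneys": 0.027,
    "f_lungs": 0.077,
    "f_liver": 0.082,
    "f_bone_marrow": 0.039,
    "f_spleen": 0.013,
}

#: Monte Carlo standard deviations of the best-fit rates [1/h].
REFERENCE_RATE_STD: dict[str, float] = {
    "blood_to_heart_fast": 0.6e-1,
    "heart_fast_to_blood": 1.7,
    "heart_fast_to_heart_slow": 2.7e-4,
    "blood_to_kidney_fast": 0.7e-2,
    "kidney_fast_to_blood": 1.8e-1,
    "kidney_fast_to_kidney_slow": 0.7e-3,
    "blood_to_tumor_fast": 0.6e-2,
    "tumor_fast_to_blood": 0.8e1,
    "tumor_fast_to_tumor_slow": 0.2e-1,
    "tumor_slow_to_tumor_fast": 0.5e-2,
    "blood_to_lung_fast": 2.0e-3,
    "lung_fast_to_blood": 3.1e-2,
    "lung_fast_to_lung_slow": 1.0e-3,
    "blood_to_liver_fast": 3.1e-2,
    "liver_fast_to_blood": 3.7e-1,
    "liver_fast_to_liver_slow": 1.0e-3,
    "blood_to_marrow_fast": 0.3e-3,
    "marrow_fast_to_blood": 1.3e-2,
    "marrow_fast_to_marrow_slow": 0.9e-3,
    "blood_to_rt_fast": 0.4e-2,
    "rt_fast_to_blood": 0.4e-2,
    "rt_fast_to_rt_slow": 0.2e-3,
    "kidney_fast_to_bladder": 0.4e-2,
    "blood_to_spleen": 0.3e-5,
}

#: Human organ masses [g] for concentration -> activity scaling.
HUMAN_ORGAN_MASSES_G: dict[str, float] = {
    "heart_wall": 291.0,
    "kidneys": 357.0,
    "liver": 1810.0,
    "lungs": 950.0,
    "bone_marrow": 1064.0,
    "spleen": 187.0,
    "tumor": 38.0,
}

#: Human resting blood content per organ [%], the reference values around
#: which fitted blood fractions are constrained.
HUMAN_REFERENCE_BLOOD_FRACTIONS_PCT: dict[str, float] = {
    "heart_wall": 1.0,
    "kidneys": 2.0,
    "liver": 10.0,
    "lungs": 10.5,
    "bone_marrow": 4.0,
    "spleen": 1.4,
    "tumor": 0.0,
}

#: 30 g murine phantom organ masses [g].
MURINE_ORGAN_MASSES_G: dict[str, float] = {
    "heart_wall": 0.291,
    "kidneys": 0.374,
    "liver": 2.150,
    "lungs": 0.107,
    "bone_marrow": 1.049,
}

#: Murine reference blood fractions [%].
MURINE_REFERENCE_BLOOD_FRACTIONS_PCT: dict[str, float] = {
    "heart_wall": 1.0,
    "kidneys": 4.8,
    "liver": 23.0,
    "lungs": 2.6,
    "bone_marrow": 4.0,
}


def reference_parameters(lam: float = LAMBDA_I131) -> ParameterSet:
    """Published best-fit parameter set for the reference structure."""
    return ParameterSet(
        rates=dict(REFERENCE_RATES),
        blood_fractions=dict(REFERENCE_BLOOD_FRACTIONS),
        lam=lam,
    )
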