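"""Model selection: small-sample AIC and candidate structure enumeration.

Candidate subsystem structures follow the decoupling playbook used to
assemble the whole-body model: each organ/tissue is tried as a single
dry-tissue compartment exchanging with blood (bidirectionally or as a
sink) or as a fast/slow pair (four rates, or slow pool as a sink);
excretion is tried either through the kidney fast pool (with optional
direct blood->bladder and slow->fast return paths) or through a separate
urinary-path tissue between blood and bladder.  Fitted candidates are
ranked by the corrected Akaike criterion; lower is better.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from .structures import BLADDER, BLOOD, Edge, ModelStructure, Observable

logger = logging.getLogger(__name__)

__all__ = [
    "aicc",
    "CandidateVariant",
    "enumerate_variants",
    "select_structure",
]


def aicc(wrss_value: float, n: int, k: int, log_base: float = math.e) -> float:
    """Corrected Akaike Information Criterion for a least-squares fit.

    ``N log(WRSS/N) + 2K + 2K(K+1)/(N-K-1)`` with the natural logarithm
    by default (``log_base`` is configurable).  Requires ``N > K+1`` so
    the small-sample correction term is defined.
    """
    if wrss_value <= 0:
        raise ValueError("WRSS must be positive for the AICc log term")
    if n <= k + 1:
        raise ValueError(
            f"AICc correction undefined for N={n}, K={k} (need N > K+1)"
        )
    return (
        n * math.log(wrss_value / n) / math.log(log_base)
        + 2 * k
        + 2 * k * (k + 1) / (n - k - 1)
    )


@dataclass(frozen=True)
class CandidateVariant:
    """A candidate subsystem structure with some parent rates fixed at zero."""

    structure: ModelStructure
    zeroed: tuple[str, ...] = ()
    tag: str = ""

    def __post_init__(self) -> None:
        # zeroed names refer to the *parent* scheme; they must simply be
        # absent from (i.e. removed from) this structure
        present = set(self.structure.rate_names)
        clash = present & set(self.zeroed)
        if clash:
            raise ValueError(f"zeroed rates still present in structure: {sorted(clash)}")

    @property
    def n_free_rates(self) -> int:
        return len(self.structure.rate_names)


def _organ_scheme(stem: str, organ: str, fraction: str | None) -> ModelStructure:
    """Parent two-pool scheme for one organ (all four exchange paths)."""
    fast, slow = f"{stem}_fast", f"{stem}_slow"
    return ModelStructure(
        compartments=(BLOOD, fast, slow),
        edges=(
            Edge(BLOOD, fast, f"blood_to_{fast}"),
            Edge(fast, BLOOD, f"{fast}_to_blood"),
            Edge(fast, slow, f"{fast}_to_{slow}"),
            Edge(slow, fast, f"{slow}_to_{fast}"),
        ),
        observations={organ: Observable((fast, slow), fraction)},
    )


def enumerate_variants(
    organ: str,
    stem: str | None = None,
    fraction: str | None = None,
    excretion: bool = False,
) -> list[CandidateVariant]:
    """Candidate structures for one organ, or for the excretion pathway.

    For an organ: four variants — one dry-tissue compartment with
    bidirectional exchange or as a sink, and a fast/slow pair with four
    rates or with the slow pool as a sink.  For excretion: the
    kidney-fast route with every combination of the optional direct
    blood->bladder and slow->fast return edges, plus the urinary-path
    scheme with and without its tissue->blood return.
    """
    if excretion:
        return _excretion_variants()
    stem = stem or organ
    fast, slow = f"{stem}_fast", f"{stem}_slow"
    parent = _organ_scheme(stem, organ, fraction)

    one_comp = parent.without_compartments([slow])
    # with the slow pool gone, its observable membership reduces to {fast}
    variants = [
        CandidateVariant(
            one_comp,
            zeroed=(f"{fast}_to_{slow}", f"{slow}_to_{fast}"),
            tag="1comp_bidirectional",
        ),
        CandidateVariant(
            one_comp.without_edges([f"{fast}_to_blood"]),
            zeroed=(f"{fast}_to_blood", f"{fast}_to_{slow}", f"{slow}_to_{fast}"),
            tag="1comp_sink",
        ),
        CandidateVariant(parent, zeroed=(), tag="2comp_4rate"),
        CandidateVariant(
            parent.without_edges([f"{slow}_to_{fast}"]),
            zeroed=(f"{slow}_to_{fast}",),
            tag="2comp_slow_sink",
        ),
    ]
    return variants


def _excretion_variants() -> list[CandidateVariant]:
    kf, ks = "kidney_fast", "kidney_slow"
    kidney_parent = ModelStructure(
        compartments=(BLOOD, kf, ks, BLADDER),
        edges=(
            Edge(BLOOD, kf, f"blood_to_{kf}"),
            Edge(kf, BLOOD, f"{kf}_to_blood"),
            Edge(kf, ks, f"{kf}_to_{ks}"),
            Edge(ks, kf, f"{ks}_to_{kf}"),
            Edge(kf, BLADDER, f"{kf}_to_bladder"),
            Edge(BLOOD, BLADDER, "blood_to_bladder"),
        ),
        observations={
            "kidneys": Observable((kf, ks), "f_kidneys"),
            BLADDER: Observable((BLADDER,), None),
        },
    )
    optional = ("blood_to_bladder", f"{ks}_to_{kf}")
    variants = []
    for drop in (
        (),
        (optional[0],),
        (optional[1],),
        optional,
    ):
        tag = "kidney_route" + ("" if not drop else "_minus_" + "_and_".join(drop))
        variants.append(
            CandidateVariant(kidney_parent.without_edges(drop), zeroed=tuple(drop), tag=tag)
        )

    # urinary-path scheme: the kidneys stay a regular two-pool organ and
    # excretion runs through a separate transit tissue between blood and
    # bladder, so both schemes fit the same kidneys + urine data
    up = "urinary_path"
    urinary_parent = ModelStructure(
        compartments=(BLOOD, kf, ks, up, BLADDER),
        edges=(
            Edge(BLOOD, kf, f"blood_to_{kf}"),
            Edge(kf, BLOOD, f"{kf}_to_blood"),
            Edge(kf, ks, f"{kf}_to_{ks}"),
            Edge(BLOOD, up, f"blood_to_{up}"),
            Edge(up, BLOOD, f"{up}_to_blood"),
            Edge(up, BLADDER, f"{up}_to_bladder"),
        ),
        observations={
            "kidneys": Observable((kf, ks), "f_kidneys"),
            BLADDER: Observable((BLADDER,), None),
        },
    )
    variants.append(CandidateVariant(urinary_parent, zeroed=(), tag="urinary_route"))
    variants.append(
        CandidateVariant(
            urinary_parent.without_edges([f"{up}_to_blood"]),
            zeroed=(f"{up}_to_blood",),
            tag="urinary_route_minus_return",
        )
    )
    return variants


def select_structure(fit_results: Sequence) -> tuple[object, list[dict]]:
    """Rank fitted candidates by AICc and return the winner plus the table.

    Each entry must expose ``aicc``, ``wrss``, ``n``, ``k`` and a
    ``variant`` (or ``tag``) attribute.  Ties are broken by smaller K,
    then lexicographic tag.  A comparability warning is logged when the
    candidates were fitted to datasets of different size or fingerprint.
    """
    if not fit_results:
        raise ValueError("no fit results to rank")
    ns = {getattr(r, "n") for r in fit_results}
    prints = {getattr(r, "dataset_fingerprint", None) for r in fit_results}
    if len(ns) > 1 or len(prints) > 1:
        logger.warning(
            "AICc comparison across different datasets (N=%s, fingerprints=%s): "
            "ranking may not be meaningful",
            sorted(ns),
            sorted(str(p) for p in prints),
        )

    def tag_of(r) -> str:
        v = getattr(r, "variant", None)
        return getattr(v, "tag", None) or getattr(r, "tag", "") or ""

    ranked = sorted(fit_results, key=lambda r: (r.aicc, r.k, tag_of(r)))
    table = [
        {
            "tag": tag_of(r),
            "wrss": r.wrss,
            "goodness_of_fit": r.wrss / (r.n - r.k) if r.n > r.k else float("nan"),
            "n": r.n,
            "k": r.k,
            "aicc": r.aicc,
        }
        for r in ranked
    ]
    return ranked[0], table


def assemble_structure(
    organ_variants: dict[str, CandidateVariant],
    excretion: CandidateVariant,
) -> ModelStructure:
    """Combine per-organ winners and an excretion winner into one model.

    Compartments and edges are unioned by name (the excretion scheme may
    share the kidney pools with the kidney organ variant); the blood and
    bladder observables are added automatically.
    """
    compartments: list[str] = [BLOOD]
    edges: dict[str, Edge] = {}
    observations: dict[str, Observable] = {}

    def absorb(structure: ModelStructure) -> None:
        for c in structure.compartments:
            if c not in compartments:
                compartments.append(c)
        for e in structure.edges:
            edges.setdefault(e.rate, e)
        for organ, obs in structure.observations.items():
            observations.setdefault(organ, obs)

    for variant in organ_variants.values():
        absorb(variant.structure)
    absorb(excretion.structure)
    observations.setdefault(BLOOD, Observable((BLOOD,), None))
    return ModelStructure(
        compartments=tuple(compartments),
        edges=tuple(edges.values()),
        observations=observations,
    )
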