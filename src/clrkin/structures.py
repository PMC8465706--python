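"""Compartmental model structures.

A :class:`ModelStructure` is a directed graph of kinetically homogeneous
pools ("compartments") exchanging tracer at first-order rates, together
with an *observation map* describing how measured organ/tissue activities
are assembled from compartment activities plus a blood-fraction term:

    A_s(t) = sum_{i in s} y_i(t) + f_s * y_blood(t)

The module also builds the reference CLR1404 model: 17 compartments
(blood, urinary-bladder contents, a single spleen sink, and fast/slow
pairs for heart wall, kidneys, tumor, lungs, liver, bone marrow and the
remaining tissues) connected by 24 first-order exchange paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "Edge",
    "Observable",
    "ModelStructure",
    "final_model",
    "BLOOD",
    "BLADDER",
]

BLOOD = "blood"
BLADDER = "bladder"


@dataclass(frozen=True)
class Edge:
    """Directed transfer path ``source -> target`` bound to a named rate."""

    source: str
    target: str
    rate: str

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-edge on compartment {self.source!r}")


@dataclass(frozen=True)
class Observable:
    """Observed organ/tissue: member compartments plus optional blood fraction.

    ``fraction`` is the name of the blood-fraction parameter, or ``None``
    for organs whose blood content is treated as negligible (tumor,
    bladder contents) or that are the blood itself.
    """

    compartments: tuple[str, ...]
    fraction: str | None = None


@dataclass(frozen=True)
class ModelStructure:
    compartments: tuple[str, ...]
    edges: tuple[Edge, ...]
    observations: Mapping[str, Observable] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.compartments)) != len(self.compartments):
            raise ValueError("duplicate compartment labels")
        if BLOOD not in self.compartments:
            raise ValueError("structure must contain a 'blood' compartment")
        comps = set(self.compartments)
        for e in self.edges:
            if e.source not in comps or e.target not in comps:
                raise ValueError(
                    f"edge {e.source}->{e.target} references unknown compartment"
                )
        names = [e.rate for e in self.edges]
        if len(set(names)) != len(names):
            raise ValueError("duplicate rate names")
        for organ, obs in self.observations.items():
            for c in obs.compartments:
                if c not in comps:
                    raise ValueError(
                        f"observable {organ!r} references unknown compartment {c!r}"
                    )

    # -- lookups -------------------------------------------------------

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    @property
    def rate_names(self) -> tuple[str, ...]:
        return tuple(e.rate for e in self.edges)

    @property
    def fraction_names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for obs in self.observations.values():
            if obs.fraction is not None and obs.fraction not in seen:
                seen.append(obs.fraction)
        return tuple(seen)

    def index(self, compartment: str) -> int:
        return self.compartments.index(compartment)

    def outgoing(self, compartment: str) -> tuple[Edge, ...]:
        return tuple(e for e in self.edges if e.source == compartment)

    # -- editing helpers (used by selection / simplification) ----------

    def without_edges(self, rate_names: Sequence[str]) -> "ModelStructure":
        """Copy of the structure with the named edges removed."""
        drop = set(rate_names)
        unknown = drop - set(self.rate_names)
        if unknown:
            raise KeyError(f"unknown rate names: {sorted(unknown)}")
        return ModelStructure(
            compartments=self.compartments,
            edges=tuple(e for e in self.edges if e.rate not in drop),
            observations=self.observations,
        )

    def without_compartments(self, labels: Sequence[str]) -> "ModelStructure":
        """Copy with compartments (and their edges / observable slots) removed."""
        drop = set(labels)
        if BLOOD in drop:
            raise ValueError("cannot remove the blood compartment")
        obs = {}
        for organ, o in self.observations.items():
            members = tuple(c for c in o.compartments if c not in drop)
            if o.compartments and not members:
                continue  # observable lost every member compartment
            obs[organ] = Observable(members, o.fraction)
        return ModelStructure(
            compartments=tuple(c for c in self.compartments if c not in drop),
            edges=tuple(
                e for e in self.edges if e.source not in drop and e.target not in drop
            ),
            observations=obs,
        )


# ---------------------------------------------------------------------------
# Reference CLR1404 structure
# ---------------------------------------------------------------------------

#: Organs modelled as a fast/slow dry-tissue pair with a blood fraction.
TWO_COMPARTMENT_ORGANS = (
    ("heart_wall", "heart"),
    ("kidneys", "kidney"),
    ("lungs", "lung"),
    ("liver", "liver"),
    ("bone_marrow", "marrow"),
    ("remaining", "rt"),
)


def final_model() -> ModelStructure:
    """The reference whole-body CLR1404 structure.

    17 compartments, 24 rate constants, 6 blood fractions.  Heart wall,
    kidneys, lungs, liver, bone marrow and the remaining tissues each get
    a fast and a slow dry-tissue compartment with blood->fast,
    fast->blood and fast->slow exchange (slow pools are sinks).  The
    tumor additionally returns slow->fast.  The spleen is a single sink
    fed from blood.  Urinary excretion drains the kidney fast pool into
    the bladder contents, a sink emptied only by physical decay.
    """
    comps: list[str] = [BLOOD]
    edges: list[Edge] = []
    observations: dict[str, Observable] = {}

    for organ, stem in TWO_COMPARTMENT_ORGANS:
        fast, slow = f"{stem}_fast", f"{stem}_slow"
        comps += [fast, slow]
        edges += [
            Edge(BLOOD, fast, f"blood_to_{fast}"),
            Edge(fast, BLOOD, f"{fast}_to_blood"),
            Edge(fast, slow, f"{fast}_to_{slow}"),
        ]
        fraction = None if organ == "remaining" else f"f_{organ}"
        observations[organ] = Observable((fast, slow), fraction)

    # tumor: fast/slow with bidirectional fast<->slow, negligible blood fraction
    comps += ["tumor_fast", "tumor_slow"]
    edges += [
        Edge(BLOOD, "tumor_fast", "blood_to_tumor_fast"),
        Edge("tumor_fast", BLOOD, "tumor_fast_to_blood"),
        Edge("tumor_fast", "tumor_slow", "tumor_fast_to_tumor_slow"),
        Edge("tumor_slow", "tumor_fast", "tumor_slow_to_tumor_fast"),
    ]
    observations["tumor"] = Observable(("tumor_fast", "tumor_slow"), None)

    # spleen: single sink compartment
    comps.append("spleen")
    edges.append(Edge(BLOOD, "spleen", "blood_to_spleen"))
    observations["spleen"] = Observable(("spleen",), "f_spleen")

    # excretion: kidney fast -> bladder contents (sink)
    comps.append(BLADDER)
    edges.append(Edge("kidney_fast", BLADDER, "kidney_fast_to_bladder"))
    observations[BLADDER] = Observable((BLADDER,), None)

    observations[BLOOD] = Observable((BLOOD,), None)

    return ModelStructure(tuple(comps), tuple(edges), observations)
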