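"""Wish-list data model: prescription, hard constraints, prioritized objectives.

A wish-list drives lexicographic plan generation: hard constraints must
always hold, while objectives are optimized strictly in priority order,
each optimized value being turned into a (slightly relaxed) constraint for
all later phases.  An objective with a goal and the ``sufficient`` flag
stops being pushed once the goal is met and becomes a constraint at the
goal — the standard treatment of target coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

TOTAL_MU = "__total_mu__"     # pseudo-structure for the MU economy objective


@dataclass(frozen=True)
class Prescription:
    """Single-fraction prescription at an isodose line.

    Default: 12 Gy prescribed at the 80 % isodose with a 98 % coverage
    goal, so the in-target maximum is 12 / 0.8 = 15 Gy.
    """

    dose_gy: float = 12.0
    isodose_fraction: float = 0.8
    coverage_fraction: float = 0.98

    def __post_init__(self):
        if not 0 < self.isodose_fraction <= 1:
            raise ValueError("isodose_fraction must be in (0, 1]")
        if not 0 < self.coverage_fraction < 1:
            raise ValueError("coverage_fraction must be in (0, 1)")

    @property
    def ptv_max_gy(self) -> float:
        return self.dose_gy / self.isodose_fraction


@dataclass(frozen=True)
class Metric:
    """Dose statistic over a structure.

    kinds: ``dmax``, ``dmean``, ``tail_high`` (mean of the hottest
    ceil(alpha*n) voxels, a convex near-maximum surrogate), ``tail_low``
    (mean of the coldest ceil(alpha*n) voxels, a concave coverage
    surrogate), ``total_mu``.
    """

    kind: str
    alpha: float | None = None

    def __post_init__(self):
        if self.kind not in ("dmax", "dmean", "tail_high", "tail_low",
                             "total_mu"):
            raise ValueError(f"unknown metric kind {self.kind!r}")
        if self.kind in ("tail_high", "tail_low"):
            if self.alpha is None or not 0 < self.alpha <= 1:
                raise ValueError("tail metrics need alpha in (0, 1]")


@dataclass(frozen=True)
class HardConstraint:
    structure: str
    metric: Metric
    bound: float                   # Gy (or MU for total_mu)
    upper: bool = True             # False: metric >= bound


@dataclass(frozen=True)
class Objective:
    priority: int
    structure: str
    metric: Metric
    minimize: bool = True
    goal: float | None = None      # Gy; with sufficient=True, stop here
    sufficient: bool = False


@dataclass
class WishList:
    constraints: list[HardConstraint] = field(default_factory=list)
    objectives: list[Objective] = field(default_factory=list)
    relaxation: float = 1.03       # epsilon-constraint slip factor, >= 1

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.relaxation < 1.0:
            raise ValueError("relaxation must be >= 1")
        prios = sorted(o.priority for o in self.objectives)
        if prios != list(range(1, len(prios) + 1)):
            raise ValueError("objective priorities must be unique and "
                             "contiguous from 1")

    def structures_referenced(self) -> set[str]:
        names = {c.structure for c in self.constraints}
        names |= {o.structure for o in self.objectives}
        names.discard(TOTAL_MU)
        return names

    # -------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        return {"relaxation": self.relaxation,
                "constraints": [asdict(c) for c in self.constraints],
                "objectives": [asdict(o) for o in self.objectives]}

    @classmethod
    def from_dict(cls, d: dict) -> "WishList":
        cons = [HardConstraint(structure=c["structure"],
                               metric=Metric(**c["metric"]),
                               bound=c["bound"], upper=c.get("upper", True))
                for c in d.get("constraints", [])]
        objs = [Objective(priority=o["priority"], structure=o["structure"],
                          metric=Metric(**o["metric"]),
                          minimize=o.get("minimize", True),
                          goal=o.get("goal"),
                          sufficient=o.get("sufficient", False))
                for o in d.get("objectives", [])]
        return cls(constraints=cons, objectives=objs,
                   relaxation=d.get("relaxation", 1.03))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict())

    @classmethod
    def from_yaml(cls, text: str) -> "WishList":
        return cls.from_dict(yaml.safe_load(text))


# Default OAR maximum-dose bounds (Gy).  These are package defaults chosen
# to be consistent with single-fraction vestibular-schwannoma practice (the
# brainstem and cochlea held at or below the prescription dose, nerves at
# the in-target maximum); they are configuration, not published protocol
# values.
DEFAULT_OAR_DMAX_GY = {"brainstem": 12.0, "cochlea": 12.0,
                       "trigeminal_nerve": 15.0, "facial_nerve": 15.0}

COVERAGE_TAIL_ALPHA = 0.02


def shell_structure_name(distance_cm: float) -> str:
    d = f"{distance_cm:g}"
    return f"shell_{d}cm"


def default_vs_wishlist(prescription: Prescription = Prescription(),
                        oar_dmax_gy: dict[str, float] | None = None,
                        shell_distances_cm=(1.0, 3.0, 5.0),
                        relaxation: float = 1.03) -> WishList:
    """The default vestibular-schwannoma wish-list.

    Hard: target Dmax at the prescription maximum; OAR Dmax bounds.
    Priority 1: coverage surrogate (mean dose of the coldest 2 % of the
    target) up to the prescription dose, sufficient at goal.  Next
    priorities: minimize shell Dmax at 1, 3, 5 cm, closest shell first.
    Last: minimize total MU.
    """
    oar_dmax_gy = DEFAULT_OAR_DMAX_GY if oar_dmax_gy is None else oar_dmax_gy
    cons = [HardConstraint("ptv", Metric("dmax"), prescription.ptv_max_gy)]
    cons += [HardConstraint(s, Metric("dmax"), b)
             for s, b in oar_dmax_gy.items()]
    objs = [Objective(1, "ptv", Metric("tail_low", COVERAGE_TAIL_ALPHA),
                      minimize=False, goal=prescription.dose_gy,
                      sufficient=True)]
    for k, d in enumerate(shell_distances_cm):
        objs.append(Objective(2 + k, shell_structure_name(d), Metric("dmax")))
    objs.append(Objective(2 + len(shell_distances_cm), TOTAL_MU,
                          Metric("total_mu")))
    return WishList(constraints=cons, objectives=objs, relaxation=relaxation)
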