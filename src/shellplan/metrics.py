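"""Plan-evaluation metrics: DVH, near-maximum doses, dose-bath volumes,
coverage, conformity and rescaling.

Conventions (documented, exact, no interpolation):

* ``V_D`` uses the closed threshold dose >= D.
* ``D_f%`` is the dose of the ceil(f*n)-th hottest voxel (order statistic).
* Coverage is the percentage of target voxels at or above the prescription
  dose; plans are rescaled so that the ceil(0.98 n)-th hottest target voxel
  sits exactly at the prescription dose, which makes the order-statistic
  coverage exactly the target value.
* The prescription isodose volume (PIV) for conformity is taken within the
  body.

All metrics are functions of the multiset of voxel doses, hence invariant
under voxel reordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .wishlist import Prescription

PATIENT_VD_LEVELS_GY = (1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0)
OAR_NAMES = ("brainstem", "cochlea", "trigeminal_nerve", "facial_nerve")


@dataclass
class DVH:
    """Exact (sorted-sample) dose-volume histogram of one structure."""

    structure: str
    doses_gy: np.ndarray          # ascending
    voxel_volume_cc: float

    def __post_init__(self):
        self.doses_gy = np.sort(np.asarray(self.doses_gy, float))
        if self.doses_gy.size == 0:
            raise ValueError(f"empty structure {self.structure!r}")

    @property
    def n(self) -> int:
        return self.doses_gy.size

    @property
    def total_cc(self) -> float:
        return self.n * self.voxel_volume_cc


def dvh(dose, mask=None, voxel_volume_cc: float = 1.0,
        structure: str = "structure") -> DVH:
    """DVH from a dose grid restricted to ``mask`` (or a 1-D dose sample)."""
    d = np.asarray(dose, float)
    if mask is not None:
        d = d[np.asarray(mask, bool)]
    return DVH(structure=structure, doses_gy=d.ravel(),
               voxel_volume_cc=voxel_volume_cc)


def d_at_volume(h: DVH, fraction: float = 0.02) -> float:
    """Near-maximum dose: the ceil(fraction*n)-th hottest voxel's dose."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = int(np.ceil(fraction * h.n))
    return float(h.doses_gy[h.n - k])


def v_at_dose(h: DVH, dose_gy: float) -> tuple[float, float]:
    """(cc, %) of the structure receiving >= dose_gy."""
    if dose_gy < 0:
        raise ValueError("dose must be nonnegative")
    count = int(np.count_nonzero(h.doses_gy >= dose_gy))
    return count * h.voxel_volume_cc, 100.0 * count / h.n


def coverage(ptv_doses_gy, prescription: Prescription = Prescription()
             ) -> float:
    """Percentage of target voxels at or above the prescription dose."""
    d = np.asarray(ptv_doses_gy, float)
    if d.size == 0:
        raise ValueError("empty PTV")
    return 100.0 * float(np.count_nonzero(d >= prescription.dose_gy)) / d.size


def conformity_index(dose_3d: np.ndarray, ptv_mask: np.ndarray,
                     body_mask: np.ndarray,
                     prescription: Prescription = Prescription(),
                     variant: str = "ratio") -> float:
    """Conformity of the prescription isodose volume (PIV) to the target.

    ``ratio``: PIV / PTV volume (1 = perfectly matched volumes).
    ``inverse_overlap``: PIV * PTV / overlap^2 (1 = perfect conformity;
    undefined when PIV and PTV are disjoint, returned as NaN).
    """
    piv = (dose_3d >= prescription.dose_gy) & body_mask
    npiv, nptv = int(piv.sum()), int(ptv_mask.sum())
    if nptv == 0:
        raise ValueError("empty PTV")
    if npiv == 0:
        raise ValueError("empty prescription isodose volume")
    if variant == "ratio":
        return npiv / nptv
    if variant == "inverse_overlap":
        overlap = int((piv & ptv_mask).sum())
        if overlap == 0:
            return float("nan")
        return npiv * nptv / overlap ** 2
    raise ValueError(f"unknown CI variant {variant!r}")


def rescale_to_coverage(dose, ptv_mask=None,
                        prescription: Prescription = Prescription(),
                        target: float = 0.98,
                        max_factor: float | None = None
                        ) -> tuple[np.ndarray, float, bool]:
    """Scale dose so order-statistic coverage hits ``target`` exactly.

    The factor is prescription dose / (the ceil(target*n)-th hottest target
    voxel dose).  If ``max_factor`` is given and the required factor
    exceeds it (hard bounds would be violated by upscaling), the dose is
    returned unscaled with achieved=False.

    Returns (scaled dose, factor, achieved).
    """
    dose = np.asarray(dose, float)
    d = dose[np.asarray(ptv_mask, bool)] if ptv_mask is not None else dose
    if d.size == 0 or d.max() <= 0:
        raise ValueError("zero dose on PTV")
    k = int(np.ceil(target * d.size))
    dk = np.sort(d)[d.size - k]
    if dk <= 0:
        return dose, 1.0, False
    factor = prescription.dose_gy / dk
    # nudge up by ulps so the k-th order statistic lands at or above the
    # prescription dose after the floating-point multiply
    for _ in range(4):
        if dk * factor >= prescription.dose_gy:
            break
        factor = np.nextafter(factor, np.inf)
    if max_factor is not None and factor > max_factor * (1 + 1e-9):
        return dose, 1.0, False
    return dose * factor, float(factor), True


@dataclass
class PlanMetrics:
    """One plan's evaluation record (the standard comparison row set)."""

    ptv_v12_pct: float | None = None
    ci_ratio: float | None = None
    ci_inverse_overlap: float | None = None
    oar_d2_gy: dict[str, float] = field(default_factory=dict)
    oar_dmean_gy: dict[str, float] = field(default_factory=dict)
    patient_vd_cc: dict[float, float] = field(default_factory=dict)
    shell_d2_gy: dict[float, float] = field(default_factory=dict)
    mu: float | None = None
    nodes: int | None = None
    beams: int | None = None
    minutes: float | None = None

    def to_series(self) -> pd.Series:
        out = {"PTV V12Gy [%]": self.ptv_v12_pct,
               "CI (ratio)": self.ci_ratio,
               "CI (inverse overlap)": self.ci_inverse_overlap}
        for name in OAR_NAMES:
            out[f"{name} D2% [Gy]"] = self.oar_d2_gy.get(name)
            out[f"{name} Dmean [Gy]"] = self.oar_dmean_gy.get(name)
        for d in PATIENT_VD_LEVELS_GY:
            out[f"Patient V{d:g}Gy [cc]"] = self.patient_vd_cc.get(d)
        for d in sorted(self.shell_d2_gy):
            out[f"Shell {d:g}cm D2% [Gy]"] = self.shell_d2_gy.get(d)
        out.update({"MU": self.mu, "Nodes": self.nodes, "Beams": self.beams,
                    "Time [min]": self.minutes})
        return pd.Series(out)


def plan_report(dose_3d: np.ndarray, phantom, shell_set, plan=None,
                prescription: Prescription = Prescription(),
                delivery_minutes: float | None = None) -> PlanMetrics:
    """Compute the full evaluation record for one plan.

    Structures missing from the phantom yield explicit ``None`` entries,
    never silent zeros.
    """
    masks = phantom.masks
    if dose_3d.shape != masks["body"].shape:
        raise ValueError("dose grid does not match the phantom grid")
    vv = phantom.voxel_volume_cc
    m = PlanMetrics()
    m.ptv_v12_pct = coverage(dose_3d[masks["ptv"]], prescription)
    piv_nonempty = bool(((dose_3d >= prescription.dose_gy)
                         & masks["body"]).any())
    if piv_nonempty:   # no prescription isodose volume -> CI undefined
        m.ci_ratio = conformity_index(dose_3d, masks["ptv"], masks["body"],
                                      prescription, "ratio")
        m.ci_inverse_overlap = conformity_index(dose_3d, masks["ptv"],
                                                masks["body"], prescription,
                                                "inverse_overlap")
    for name in OAR_NAMES:
        if name not in masks or not masks[name].any():
            continue
        h = dvh(dose_3d, masks[name], vv, name)
        m.oar_d2_gy[name] = d_at_volume(h, 0.02)
        m.oar_dmean_gy[name] = float(h.doses_gy.mean())
    body_h = dvh(dose_3d, masks["body"], vv, "body")
    for dlev in PATIENT_VD_LEVELS_GY:
        m.patient_vd_cc[dlev] = v_at_dose(body_h, dlev)[0]
    for dist in shell_set.distances_cm:
        mask = shell_set[dist]
        if not mask.any():
            m.shell_d2_gy[dist] = None
            continue
        m.shell_d2_gy[dist] = d_at_volume(dvh(dose_3d, mask, vv), 0.02)
    if plan is not None:
        m.mu = plan.total_mu
        m.nodes = plan.node_count
        m.beams = plan.beam_count
        m.minutes = delivery_minutes if delivery_minutes is not None \
            else plan.delivery_minutes
    return m
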