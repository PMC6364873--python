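"""Shell structures around the target, built by Euclidean distance transform.

A shell at distance d is the thin band of voxels whose grid EDT distance to
the target lies in [d, d + thickness), intersected with the body and
excluding the target itself.  Shells close to the target capture dose
spikes leaking out of the target; far shells measure the low-dose bath.
Optimization uses shells at 1, 3 and 5 cm; evaluation adds 2 and 7 cm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

OPTIMIZATION_DISTANCES_CM = (1.0, 3.0, 5.0)
EVALUATION_DISTANCES_CM = (1.0, 2.0, 3.0, 5.0, 7.0)
DEFAULT_THICKNESS_MM = 3.0


@dataclass
class ShellSet:
    """Ordered set of disjoint distance bands around the target."""

    distances_cm: tuple[float, ...]
    thickness_mm: float
    masks: dict[float, np.ndarray]        # distance_cm -> bool mask
    clipped: set[float]                   # distances fully clipped by body

    def __iter__(self):
        return iter(self.distances_cm)

    def __getitem__(self, d_cm: float) -> np.ndarray:
        return self.masks[d_cm]


def build_shell(ptv_mask: np.ndarray, body_mask: np.ndarray, spacing_mm: float,
                distance_cm: float, thickness_mm: float = DEFAULT_THICKNESS_MM
                ) -> np.ndarray:
    """Band of voxels at EDT distance [d, d+t) from the target, inside body."""
    if not ptv_mask.any():
        raise ValueError("PTV mask is empty")
    if thickness_mm <= 0:
        raise ValueError("thickness must be positive")
    d0 = distance_cm * 10.0
    edt = ndimage.distance_transform_edt(~ptv_mask, sampling=spacing_mm)
    band = (edt >= d0) & (edt < d0 + thickness_mm)
    return band & body_mask & ~ptv_mask


def build_shell_set(ptv_mask: np.ndarray, body_mask: np.ndarray,
                    spacing_mm: float, distances_cm=EVALUATION_DISTANCES_CM,
                    thickness_mm: float = DEFAULT_THICKNESS_MM) -> ShellSet:
    """One band per distance; bands must not overlap (d_{k+1}-d_k >= t)."""
    distances_cm = tuple(float(d) for d in distances_cm)
    if any(b <= a for a, b in zip(distances_cm, distances_cm[1:])):
        raise ValueError("distances must be strictly increasing")
    gaps_mm = [10.0 * (b - a) for a, b in zip(distances_cm, distances_cm[1:])]
    if any(g < thickness_mm - 1e-9 for g in gaps_mm):
        raise ValueError(
            f"bands of thickness {thickness_mm} mm overlap at distance "
            f"spacing {min(gaps_mm):.1f} mm")
    if spacing_mm > thickness_mm:
        raise ValueError(f"voxel spacing {spacing_mm} mm exceeds shell "
                         f"thickness {thickness_mm} mm; bands may be empty")
    if not ptv_mask.any():
        raise ValueError("PTV mask is empty")
    edt = ndimage.distance_transform_edt(~ptv_mask, sampling=spacing_mm)
    masks, clipped = {}, set()
    for d in distances_cm:
        d0 = d * 10.0
        band = (edt >= d0) & (edt < d0 + thickness_mm) & body_mask & ~ptv_mask
        masks[d] = band
        if not band.any():
            clipped.add(d)
    return ShellSet(distances_cm=distances_cm, thickness_mm=thickness_mm,
                    masks=masks, clipped=clipped)


def shells_for_phantom(phantom, distances_cm=EVALUATION_DISTANCES_CM,
                       thickness_mm: float | None = None) -> ShellSet:
    """Convenience wrapper: shells for a phantom's target inside its body.

    Thickness defaults to max(3 mm, one voxel) so bands are never thinner
    than the grid can represent.
    """
    t = thickness_mm if thickness_mm is not None else max(
        DEFAULT_THICKNESS_MM, phantom.spacing_mm)
    return build_shell_set(phantom.masks["ptv"], phantom.masks["body"],
                           phantom.spacing_mm, distances_cm, t)
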