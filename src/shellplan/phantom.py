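"""Synthetic head phantoms for vestibular-schwannoma planning studies.

A phantom is a voxel grid of binary structure masks: an ellipsoidal head
(``body``), a target (``ptv``) in a lateral posterior-fossa-like position,
and the organs at risk that shape the optimization geometry — a brainstem
cylinder, a cochlea sphere and two thin nerve tubes touching the target
surface.  Voxels are isotropic; physical position = origin + index * spacing
(voxel-center convention).

The cohort generator draws target volumes log-uniformly on 1.0-7.3 cc and
target-brainstem gaps uniformly on 0-3 mm, emulating the size spread of a
clinical vestibular-schwannoma population.  Everything is seeded and
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import nibabel as nib
import yaml

from scipy import ndimage

# structures that are always generated; optic apparatus / eyes / pituitary
# receive near-zero dose in this geometry and are optional config extras
CORE_STRUCTURES = ("body", "ptv", "brainstem", "cochlea",
                   "trigeminal_nerve", "facial_nerve")

PTV_VOLUME_RANGE_CC = (1.0, 7.3)
GAP_RANGE_MM = (0.0, 3.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric recipe for one synthetic patient."""

    head_radii_mm: tuple[float, float, float] = (80.0, 95.0, 85.0)
    voxel_mm: float = 2.0
    ptv_volume_cc: float = 2.9
    ptv_brainstem_gap_mm: float = 1.5
    cochlea_offset_mm: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")
        if self.ptv_brainstem_gap_mm < 0:
            raise ValueError("ptv_brainstem_gap_mm must be nonnegative")
        if self.ptv_volume_cc <= 0:
            raise ValueError("ptv_volume_cc must be positive")


@dataclass
class Phantom:
    """Voxelized structure set of one synthetic patient."""

    spacing_mm: float
    origin_mm: np.ndarray                 # physical coordinate of voxel (0,0,0)
    masks: dict[str, np.ndarray]          # name -> bool array, common shape
    spec: PhantomSpec | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.masks.values())).shape

    @property
    def voxel_volume_cc(self) -> float:
        return self.spacing_mm ** 3 / 1000.0

    def volume_cc(self, name: str) -> float:
        return float(self.masks[name].sum()) * self.voxel_volume_cc

    def coords_mm(self, mask: np.ndarray) -> np.ndarray:
        """Physical centers (n, 3) of the True voxels of ``mask``."""
        idx = np.argwhere(mask)
        return self.origin_mm + idx * self.spacing_mm

    def validate(self) -> None:
        body = self.masks["body"]
        for name, m in self.masks.items():
            if m.shape != body.shape:
                raise ValueError(f"mask {name!r} shape mismatch")
            if name != "body" and np.any(m & ~body):
                raise ValueError(f"structure {name!r} extends outside body")
        if np.any(self.masks["ptv"] & self.masks["brainstem"]):
            raise ValueError("ptv overlaps brainstem")
        if np.any(self.masks["ptv"] & self.masks["cochlea"]):
            raise ValueError("ptv overlaps cochlea")


def _grid(head_radii_mm, voxel_mm, margin_mm=6.0):
    half = np.asarray(head_radii_mm, float) + margin_mm
    n = 2 * np.ceil(half / voxel_mm).astype(int) + 1
    origin = -(n - 1) / 2.0 * voxel_mm
    return n, origin


def _axes_mm(shape, origin, voxel_mm):
    return [origin[k] + np.arange(shape[k]) * voxel_mm for k in range(3)]


def _ellipsoid_mask(shape, origin, voxel_mm, center, semiaxes, rot=None):
    ax = _axes_mm(shape, origin, voxel_mm)
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    P = np.stack([X - center[0], Y - center[1], Z - center[2]], axis=-1)
    if rot is not None:
        P = P @ rot            # rotate world coords into ellipsoid frame
    q = (P / np.asarray(semiaxes)) ** 2
    return q.sum(axis=-1) <= 1.0


def _cylinder_mask(shape, origin, voxel_mm, center, radius, half_len, axis=2):
    ax = _axes_mm(shape, origin, voxel_mm)
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    C = [X - center[0], Y - center[1], Z - center[2]]
    trans = [C[k] for k in range(3) if k != axis]
    r2 = trans[0] ** 2 + trans[1] ** 2
    return (r2 <= radius ** 2) & (np.abs(C[axis]) <= half_len)


def _tube_mask(shape, origin, voxel_mm, p0, p1, radius):
    """Voxels within ``radius`` of segment p0-p1 (capsule)."""
    ax = _axes_mm(shape, origin, voxel_mm)
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    P = np.stack([X, Y, Z], axis=-1)
    d = np.asarray(p1, float) - np.asarray(p0, float)
    L2 = float(d @ d)
    t = np.clip(((P - p0) @ d) / max(L2, 1e-12), 0.0, 1.0)
    closest = p0 + t[..., None] * d
    dist2 = ((P - closest) ** 2).sum(axis=-1)
    return dist2 <= radius ** 2


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build one phantom deterministically from its spec.

    The target is a randomly oriented ellipsoid whose voxelized volume is
    calibrated to the requested volume; it is then shifted laterally so the
    nearest brainstem voxel sits at the requested gap (to grid resolution).

    Raises ``ValueError`` when the requested volume cannot be realized on
    the grid within 10 %, naming the minimum spacing that would work.
    """
    rng = np.random.default_rng(spec.rng_seed)
    shape, origin = _grid(spec.head_radii_mm, spec.voxel_mm)
    vox = spec.voxel_mm

    body = _ellipsoid_mask(shape, origin, vox, (0, 0, 0), spec.head_radii_mm)

    # brainstem: vertical cylinder, slightly posterior of center
    bs_center = np.array([0.0, 12.0, -10.0])
    bs_radius, bs_half_len = 8.0, 30.0
    brainstem = _cylinder_mask(shape, origin, vox, bs_center, bs_radius,
                               bs_half_len) & body

    # target: random side, random orientation, random axis ratios
    side = 1.0 if rng.random() < 0.5 else -1.0
    rot = _random_rotation(rng)
    ratios = rng.uniform(0.75, 1.3, size=3)
    ratios /= ratios.prod() ** (1 / 3)

    def ptv_at(scale: float, center: np.ndarray) -> np.ndarray:
        r = scale * ratios * (3.0 * spec.ptv_volume_cc * 1000.0 /
                              (4.0 * np.pi)) ** (1 / 3)
        return _ellipsoid_mask(shape, origin, vox, center, r, rot) & body

    target_count = spec.ptv_volume_cc / (vox ** 3 / 1000.0)
    if target_count < 8:   # fewer voxels cannot represent a 3-D target
        min_spacing = (spec.ptv_volume_cc * 1000.0 / 8.0) ** (1 / 3)
        raise ValueError(
            f"PTV volume {spec.ptv_volume_cc} cc not realizable on a "
            f"{vox} mm grid ({target_count:.1f} voxels); use spacing <= "
            f"{min_spacing:.1f} mm")
    ptv_center = np.array([side * (bs_radius + spec.ptv_brainstem_gap_mm
                                   + 12.0), bs_center[1] + rng.uniform(-4, 4),
                           bs_center[2] + rng.uniform(-6, 6)])

    # calibrate the continuous radius scale so the voxel count lands on target
    scales = np.linspace(0.8, 1.25, 61)
    counts = np.array([ptv_at(s, ptv_center).sum() for s in scales])
    best = int(np.argmin(np.abs(counts - target_count)))
    scale = float(scales[best])
    ptv = ptv_at(scale, ptv_center)
    rel_err = abs(ptv.sum() * vox ** 3 / 1000.0 - spec.ptv_volume_cc) \
        / spec.ptv_volume_cc
    if rel_err > 0.10 or ptv.sum() == 0:
        min_spacing = (spec.ptv_volume_cc * 1000.0 / 30.0) ** (1 / 3)
        raise ValueError(
            f"PTV volume {spec.ptv_volume_cc} cc not realizable on a "
            f"{vox} mm grid (error {rel_err:.1%}); use spacing <= "
            f"{min_spacing:.1f} mm")

    # shift the target along x until the surface gap to the brainstem matches
    ptv = _set_gap(ptv, brainstem, body, vox, spec.ptv_brainstem_gap_mm,
                   int(side))
    ptv &= ~brainstem

    ptv_idx = np.argwhere(ptv)
    ptv_c = origin + ptv_idx.mean(axis=0) * vox

    # cochlea: small sphere anterior-medial of the target
    coch_r = max(2.5, 0.7 * vox)
    ptv_halfwidth = scale * ratios.max() * (3.0 * spec.ptv_volume_cc * 1000.0
                                            / (4.0 * np.pi)) ** (1 / 3)
    coch_center = ptv_c + np.array([0.0, -(ptv_halfwidth + coch_r
                                           + spec.cochlea_offset_mm), 0.0])
    cochlea = _ellipsoid_mask(shape, origin, vox, coch_center,
                              (coch_r,) * 3) & body & ~ptv
    if not cochlea.any():
        # sphere smaller than a voxel: fall back to the enclosing voxel
        ci = np.rint((coch_center - origin) / vox).astype(int)
        if np.all(ci >= 0) and np.all(ci < shape):
            single = np.zeros_like(cochlea)
            single[tuple(ci)] = True
            cochlea = single & body & ~ptv

    # nerve tubes starting at the target surface
    nerve_r = max(1.5, 0.7 * vox)
    surf = _surface_points(ptv, origin, vox)
    trig_dir = np.array([-0.3 * side, -1.0, 0.3])
    fac_dir = np.array([side, 0.2, -0.2])
    trig_p0 = surf[np.argmax(surf @ trig_dir)]
    fac_p0 = surf[np.argmax(surf @ fac_dir)]
    trigeminal = _tube_mask(shape, origin, vox, trig_p0,
                            trig_p0 + 22 * trig_dir / np.linalg.norm(trig_dir),
                            nerve_r) & body & ~ptv
    facial = _tube_mask(shape, origin, vox, fac_p0,
                        fac_p0 + 18 * fac_dir / np.linalg.norm(fac_dir),
                        nerve_r) & body & ~ptv

    p = Phantom(spacing_mm=vox, origin_mm=origin,
                masks={"body": body, "ptv": ptv, "brainstem": brainstem,
                       "cochlea": cochlea, "trigeminal_nerve": trigeminal,
                       "facial_nerve": facial},
                spec=spec)
    p.validate()
    return p


def _set_gap(ptv, brainstem, body, vox, gap_mm, side):
    """Shift the target by whole voxels along x to match the requested gap."""
    dist = ndimage.distance_transform_edt(~brainstem, sampling=vox)
    for _ in range(64):
        d = dist[ptv].min()
        if gap_mm <= d < gap_mm + vox:
            break
        step = -side if d > gap_mm else side   # move toward / away from stem
        shifted = np.roll(ptv, step, axis=0)
        if d <= gap_mm and np.any(shifted & brainstem):
            break                              # cannot back off further
        ptv = shifted
    return ptv & body


def _surface_points(mask, origin, vox):
    eroded = ndimage.binary_erosion(mask)
    surf = mask & ~eroded
    if not surf.any():
        surf = mask
    return origin + np.argwhere(surf) * vox


def generate_cohort(n: int, base: PhantomSpec | None = None,
                    seed: int = 7) -> list[Phantom]:
    """Generate ``n`` phantoms with cohort-level variation.

    Target volumes are log-uniform on [1.0, 7.3] cc, target-brainstem gaps
    uniform on [0, 3] mm; each phantom gets a child seed derived from
    ``seed``, so the cohort is reproducible as a whole.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base or PhantomSpec()
    rng = np.random.default_rng(seed)
    lo, hi = PTV_VOLUME_RANGE_CC
    vols = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    gaps = rng.uniform(*GAP_RANGE_MM, size=n)
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)
    cohort = []
    for k in range(n):
        spec = PhantomSpec(head_radii_mm=base.head_radii_mm,
                           voxel_mm=base.voxel_mm,
                           ptv_volume_cc=float(vols[k]),
                           ptv_brainstem_gap_mm=float(gaps[k]),
                           cochlea_offset_mm=base.cochlea_offset_mm,
                           rng_seed=int(child_seeds[k]))
        cohort.append(generate_phantom(spec))
    return cohort


# ---------------------------------------------------------------- round trip

def write_phantom(p: Phantom, path) -> None:
    """Write masks as a 4-D NIfTI volume plus a YAML sidecar."""
    from pathlib import Path
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    names = list(p.masks)
    vol = np.stack([p.masks[n] for n in names], axis=-1).astype(np.uint8)
    affine = np.diag([p.spacing_mm] * 3 + [1.0])
    affine[:3, 3] = p.origin_mm
    nib.save(nib.Nifti1Image(vol, affine), path / "structures.nii.gz")
    meta = {"structures": names, "spacing_mm": float(p.spacing_mm),
            "origin_mm": [float(v) for v in p.origin_mm]}
    if p.spec is not None:
        meta["spec"] = asdict(p.spec)
        meta["spec"]["head_radii_mm"] = list(p.spec.head_radii_mm)
    (path / "structures.yaml").write_text(yaml.safe_dump(meta))


def read_phantom(path) -> Phantom:
    from pathlib import Path
    path = Path(path)
    meta = yaml.safe_load((path / "structures.yaml").read_text())
    img = nib.load(path / "structures.nii.gz")
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], atol=1e-6):
        raise ValueError(f"anisotropic spacing {zooms} not supported "
                         "(isotropic voxels only)")
    names = meta["structures"]
    unknown = [n for n in names if n not in CORE_STRUCTURES]
    if unknown:
        raise ValueError(f"unknown structure label(s) {unknown}; expected "
                         f"a subset of {CORE_STRUCTURES}")
    vol = np.asarray(img.dataobj).astype(bool)
    if vol.shape[-1] != len(names):
        raise ValueError("structure count mismatch between volume and sidecar")
    masks = {n: np.ascontiguousarray(vol[..., k]) for k, n in enumerate(names)}
    spec = None
    if "spec" in meta:
        s = dict(meta["spec"])
        s["head_radii_mm"] = tuple(s["head_radii_mm"])
        spec = PhantomSpec(**s)
    return Phantom(spacing_mm=float(meta["spacing_mm"]),
                   origin_mm=np.asarray(meta["origin_mm"], float),
                   masks=masks, spec=spec)
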