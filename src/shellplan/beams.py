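"""Non-coplanar candidate beams and the sparse dose-influence matrix.

The treatment unit is modelled as a set of fixed nodes on a spherical cap
around the head (default 179, matching a full-head robotic node path), each
delivering circular cone beams with an Iris-style variable aperture
restricted to 10-40 mm diameter.  Per-beam dose follows an analytic
water-equivalent kernel:

    dose(v) = output * (SAD / s)^2 * exp(-mu * (depth(v) - ref_depth))
              * P(rho(v); R(s), sigma)

with s the source-to-voxel distance along the axis, depth the in-body path
length from entry to voxel (sampled along the ray), rho the off-axis
distance, R the field radius scaled to the voxel plane and P a flat core
with an error-function penumbra.  Dose is zero outside the body.  Stacking
columns over all candidate beams gives the sparse influence matrix A in
cGy per MU, so plan dose is d = A w / 100 in Gy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import sparse
from scipy.special import erfc

#: Iris-style discrete aperture diameters (mm), clinical 10-40 mm window
COLLIMATOR_SET_MM = (10.0, 12.5, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0)
DEFAULT_NODE_COUNT = 179


@dataclass(frozen=True)
class BeamKernelParams:
    """Analytic cone-beam kernel parameters (water-equivalent body)."""

    sad_mm: float = 800.0            # source-axis distance
    mu_att_per_mm: float = 0.005     # effective linear attenuation (~6 MV)
    penumbra_sigma_mm: float = 2.0
    ref_depth_mm: float = 15.0
    output_cgy_per_mu: float = 1.0   # calibration at SAD, ref depth, on axis
    depth_samples: int = 64          # ray-sampling resolution for depth

    def __post_init__(self):
        for name in ("sad_mm", "mu_att_per_mm", "penumbra_sigma_mm",
                     "ref_depth_mm", "output_cgy_per_mu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class CandidateBeam:
    node_index: int
    aim_point_mm: tuple[float, float, float]
    collimator_diameter_mm: float

    def __post_init__(self):
        if not 10.0 <= self.collimator_diameter_mm <= 40.0:
            raise ValueError("collimator diameter outside the 10-40 mm window")


@dataclass
class NodeSet:
    positions_mm: np.ndarray          # (count, 3)

    @property
    def count(self) -> int:
        return len(self.positions_mm)

    def min_pairwise_angle_deg(self) -> float:
        u = self.positions_mm / np.linalg.norm(self.positions_mm, axis=1,
                                               keepdims=True)
        cos = np.clip(u @ u.T, -1, 1)
        np.fill_diagonal(cos, -1)
        return float(np.degrees(np.arccos(cos.max()))) if self.count > 1 \
            else 180.0


def generate_node_set(count: int = DEFAULT_NODE_COUNT,
                      head_radii_mm=(80.0, 95.0, 85.0),
                      cap_angle_deg: float = 120.0,
                      standoff_mm: float = 700.0,
                      body_check=None) -> NodeSet:
    """Quasi-uniform nodes on a spherical cap above the head.

    A Fibonacci spiral over the cap (polar angle from +z up to
    ``cap_angle_deg``) gives deterministic, well-separated directions; all
    nodes sit at max(head radius) + standoff from the head centre.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    radius = float(np.max(head_radii_mm)) + standoff_mm
    i = np.arange(count)
    cos_cap = np.cos(np.radians(cap_angle_deg))
    # apex first: u=0 -> cos(theta)=1
    u = (i + 0.5) / count if count > 1 else np.array([0.0])
    cos_t = 1.0 - u * (1.0 - cos_cap)
    sin_t = np.sqrt(np.clip(1 - cos_t ** 2, 0, None))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = i * golden
    pos = radius * np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi),
                             cos_t], axis=1)
    if body_check is not None and any(body_check(p) for p in pos):
        raise ValueError("standoff places nodes inside the body")
    q = (pos / np.asarray(head_radii_mm)) ** 2
    if np.any(q.sum(axis=1) <= 1.0):
        raise ValueError("standoff places nodes inside the head ellipsoid")
    return NodeSet(positions_mm=pos)


def choose_collimators(ptv_volume_cc: float, n: int = 3,
                       fraction: float = 1.1) -> tuple[float, ...]:
    """Pick the ``n`` apertures nearest to ``fraction`` x the target's
    equivalent diameter — the aperture range a planner would load for a
    target of that size.  Slightly larger than the equivalent diameter by
    default, so the flat core plus penumbra can hold the 80 % isodose on
    the target surface."""
    d_eq_mm = 10.0 * (6.0 * ptv_volume_cc / np.pi) ** (1 / 3)
    want = fraction * d_eq_mm
    order = np.argsort(np.abs(np.asarray(COLLIMATOR_SET_MM) - want))
    return tuple(sorted(COLLIMATOR_SET_MM[k] for k in order[:n]))


# ------------------------------------------------------------------ kernel

def _depth_mm(points_from, points_to, body, origin, spacing, n_samples):
    """In-body path length from each source point to each voxel centre,
    sampled at ``n_samples`` points along the ray (nearest-voxel lookup)."""
    d = points_to - points_from            # (m, 3)
    length = np.linalg.norm(d, axis=1)
    t = (np.arange(n_samples) + 0.5) / n_samples
    pts = points_from + t[:, None, None] * d[None, :, :]   # (N, m, 3)
    idx = np.rint((pts - origin) / spacing).astype(np.int64)
    inside = np.all((idx >= 0) & (idx < np.asarray(body.shape)), axis=-1)
    flat = np.zeros(idx.shape[:2], dtype=bool)
    ii = idx[inside]
    flat[inside] = body[ii[:, 0], ii[:, 1], ii[:, 2]]
    return flat.sum(axis=0) * length / n_samples


def beam_dose_column(beam: CandidateBeam, node_pos_mm: np.ndarray,
                     kernel: BeamKernelParams, body_coords_mm: np.ndarray,
                     body, origin, spacing,
                     support_cut_sigma: float = 5.0) -> np.ndarray:
    """Dense dose column (cGy/MU) over the body voxels for one beam."""
    p = np.asarray(node_pos_mm, float)
    a = np.asarray(beam.aim_point_mm, float)
    axis = a - p
    axis /= np.linalg.norm(axis)
    rel = body_coords_mm - p
    s = rel @ axis
    dose = np.zeros(len(body_coords_mm))
    ahead = s > 1e-6
    if not ahead.any():
        warnings.warn("beam misses the body entirely; zero column")
        return dose
    rho = np.linalg.norm(rel - np.outer(s, axis), axis=1)
    R = 0.5 * beam.collimator_diameter_mm * s / kernel.sad_mm
    sup = ahead & (rho - R < support_cut_sigma * kernel.penumbra_sigma_mm)
    if not sup.any():
        warnings.warn("beam misses the body entirely; zero column")
        return dose
    depth = _depth_mm(p, body_coords_mm[sup], body, origin, spacing,
                      kernel.depth_samples)
    pen = 0.5 * erfc((rho[sup] - R[sup]) /
                     (np.sqrt(2.0) * kernel.penumbra_sigma_mm))
    dose[sup] = (kernel.output_cgy_per_mu * (kernel.sad_mm / s[sup]) ** 2
                 * np.exp(-kernel.mu_att_per_mm * (depth - kernel.ref_depth_mm))
                 * pen)
    return dose


def beam_dose(beam: CandidateBeam, node_pos_mm, kernel: BeamKernelParams,
              phantom) -> np.ndarray:
    """Full-grid 3-D dose array (cGy/MU) for one beam; zero outside body."""
    body = phantom.masks["body"]
    coords = phantom.coords_mm(body)
    col = beam_dose_column(beam, node_pos_mm, kernel, coords, body,
                           phantom.origin_mm, phantom.spacing_mm)
    out = np.zeros(body.shape)
    out[body] = col
    return out


# ------------------------------------------------------- influence matrix

@dataclass(frozen=True)
class AimPolicy:
    """Aim at the target centroid, plus optionally k random interior points."""
    n_random_interior: int = 0
    seed: int = 0


@dataclass
class InfluenceMatrix:
    A: sparse.csc_matrix                 # (body voxels, beams), cGy per MU
    beams: list[CandidateBeam]
    nodes: NodeSet
    voxel_index: np.ndarray              # (nb, 3) grid indices of body voxels
    grid_shape: tuple[int, int, int]
    kernel: BeamKernelParams

    @property
    def n_beams(self) -> int:
        return self.A.shape[1]

    def dose_gy(self, w: np.ndarray) -> np.ndarray:
        """Dose over body voxels (Gy) for beamweights w (MU)."""
        return (self.A @ w) / 100.0

    def dose_3d_gy(self, w: np.ndarray) -> np.ndarray:
        out = np.zeros(self.grid_shape)
        out[tuple(self.voxel_index.T)] = self.dose_gy(w)
        return out

    def rows_for(self, mask: np.ndarray) -> np.ndarray:
        """Row indices of A for the True voxels of a grid mask."""
        flat = np.zeros(self.grid_shape, dtype=np.int64) - 1
        flat[tuple(self.voxel_index.T)] = np.arange(len(self.voxel_index))
        rows = flat[mask]
        if np.any(rows < 0):
            raise ValueError("mask contains voxels outside the body")
        return rows


def build_influence_matrix(nodes: NodeSet, collimators, aim_policy: AimPolicy,
                           kernel: BeamKernelParams, phantom,
                           truncation_rel: float = 1e-6,
                           max_nnz: int = 80_000_000) -> InfluenceMatrix:
    """Assemble A over candidate beams = aim points x nodes x collimators.

    Entries below ``truncation_rel`` x column max are dropped; candidate
    ordering (node, aim, collimator) and interior-point sampling are
    deterministic under the policy seed.
    """
    body = phantom.masks["body"]
    ptv = phantom.masks["ptv"]
    if not ptv.any():
        raise ValueError("empty PTV")
    if nodes.count < 1 or not collimators:
        raise ValueError("empty candidate set")
    coords = phantom.coords_mm(body)
    vidx = np.argwhere(body)
    centroid = phantom.coords_mm(ptv).mean(axis=0)
    aims = [centroid]
    if aim_policy.n_random_interior > 0:
        rng = np.random.default_rng(aim_policy.seed)
        interior = phantom.coords_mm(ptv)
        picks = rng.choice(len(interior),
                           size=min(aim_policy.n_random_interior,
                                    len(interior)), replace=False)
        aims.extend(interior[picks])

    beams, cols_data, cols_rows, indptr = [], [], [], [0]
    nnz = 0
    cut = 5.0  # support cut in penumbra sigmas
    for ni in range(nodes.count):
        p = nodes.positions_mm[ni]
        # geometric support (s, rho, R) per beam of this node
        node_beams, sups, geo = [], [], []
        rel = coords - p
        for aim in aims:
            axis = np.asarray(aim) - p
            axis /= np.linalg.norm(axis)
            s = rel @ axis
            rho = np.linalg.norm(rel - np.outer(s, axis), axis=1)
            for dia in collimators:
                R = 0.5 * dia * s / kernel.sad_mm
                sup = (s > 1e-6) & (rho - R < cut * kernel.penumbra_sigma_mm)
                node_beams.append(CandidateBeam(
                    node_index=ni, aim_point_mm=tuple(float(v) for v in aim),
                    collimator_diameter_mm=float(dia)))
                sups.append(sup)
                geo.append((s, rho, R))
        # depth depends only on the source position: compute once per node
        # over the union of the beam supports
        union = np.logical_or.reduce(sups)
        uidx = np.flatnonzero(union)
        depth_u = _depth_mm(p, coords[uidx], body, phantom.origin_mm,
                            phantom.spacing_mm, kernel.depth_samples)
        depth_map = np.zeros(len(coords))
        depth_map[uidx] = depth_u
        for b, sup, (s, rho, R) in zip(node_beams, sups, geo):
            col = np.zeros(len(coords))
            if sup.any():
                pen = 0.5 * erfc((rho[sup] - R[sup]) /
                                 (np.sqrt(2.0) * kernel.penumbra_sigma_mm))
                col[sup] = (kernel.output_cgy_per_mu
                            * (kernel.sad_mm / s[sup]) ** 2
                            * np.exp(-kernel.mu_att_per_mm
                                     * (depth_map[sup] - kernel.ref_depth_mm))
                            * pen)
            if col.max() > 0:
                rows = np.flatnonzero(col > truncation_rel * col.max())
            else:
                rows = np.array([], dtype=np.int64)
            nnz += len(rows)
            if nnz > max_nnz:
                raise MemoryError(
                    f"influence matrix exceeds max_nnz={max_nnz}")
            beams.append(b)
            cols_rows.append(rows)
            cols_data.append(col[rows])
            indptr.append(nnz)
    A = sparse.csc_matrix(
        (np.concatenate(cols_data), np.concatenate(cols_rows),
         np.asarray(indptr)), shape=(len(coords), len(beams)))
    return InfluenceMatrix(A=A, beams=beams, nodes=nodes, voxel_index=vidx,
                           grid_shape=body.shape, kernel=kernel)


def save_influence_matrix(im: InfluenceMatrix, path) -> None:
    from pathlib import Path
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sparse.save_npz(path / "A.npz", im.A)
    np.savez(path / "grid.npz", voxel_index=im.voxel_index,
             grid_shape=np.asarray(im.grid_shape),
             node_positions=im.nodes.positions_mm)
    manifest = {"kernel": asdict(im.kernel),
                "beams": [{"node_index": b.node_index,
                           "aim_point_mm": list(b.aim_point_mm),
                           "collimator_diameter_mm": b.collimator_diameter_mm}
                          for b in im.beams]}
    (path / "beams.json").write_text(json.dumps(manifest))


def load_influence_matrix(path) -> InfluenceMatrix:
    from pathlib import Path
    path = Path(path)
    A = sparse.load_npz(path / "A.npz").tocsc()
    g = np.load(path / "grid.npz")
    manifest = json.loads((path / "beams.json").read_text())
    beams = [CandidateBeam(node_index=b["node_index"],
                           aim_point_mm=tuple(b["aim_point_mm"]),
                           collimator_diameter_mm=b["collimator_diameter_mm"])
             for b in manifest["beams"]]
    return InfluenceMatrix(
        A=A, beams=beams, nodes=NodeSet(positions_mm=g["node_positions"]),
        voxel_index=g["voxel_index"], grid_shape=tuple(g["grid_shape"]),
        kernel=BeamKernelParams(**manifest["kernel"]))
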