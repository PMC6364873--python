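"""Beam geometry and dose kernel: calibration, attenuation, brute-force
column oracle, influence-matrix invariants."""

import numpy as np
import pytest
from scipy.special import erfc

from shellplan.phantom import Phantom
from shellplan.beams import (generate_node_set, choose_collimators,
                             CandidateBeam, BeamKernelParams, AimPolicy,
                             NodeSet, beam_dose, build_influence_matrix,
                             COLLIMATOR_SET_MM)


def slab_phantom(shape=(21, 21, 41), spacing=1.0):
    """Homogeneous all-body block with a small central target."""
    body = np.ones(shape, bool)
    ptv = np.zeros(shape, bool)
    c = tuple(s // 2 for s in shape)
    ptv[c[0] - 2:c[0] + 3, c[1] - 2:c[1] + 3, c[2] - 2:c[2] + 3] = True
    masks = {"body": body, "ptv": ptv}
    origin = -np.array([(s - 1) / 2.0 for s in shape]) * spacing
    return Phantom(spacing_mm=spacing, origin_mm=origin, masks=masks)


# ------------------------------------------------------------------ nodes

def test_node_set_count_radius_and_separation():
    radii = (80.0, 95.0, 85.0)
    ns = generate_node_set(179, radii, standoff_mm=700.0)
    assert ns.count == 179
    r = np.linalg.norm(ns.positions_mm, axis=1)
    assert np.allclose(r, max(radii) + 700.0)
    # brute-force O(n^2) pairwise angular separation
    u = ns.positions_mm / r[:, None]
    cos = np.clip(u @ u.T, -1, 1)
    np.fill_diagonal(cos, -1)
    assert np.degrees(np.arccos(cos.max())) > 1.0


def test_single_node_is_apex():
    ns = generate_node_set(1, (80.0, 95.0, 85.0), standoff_mm=700.0)
    assert ns.count == 1
    assert ns.positions_mm[0][2] == pytest.approx(795.0)
    assert abs(ns.positions_mm[0][0]) < 1e-9


def test_standoff_inside_head_rejected():
    with pytest.raises(ValueError, match="inside"):
        generate_node_set(10, (80.0, 95.0, 85.0), standoff_mm=-20.0)


def test_collimator_window_enforced():
    with pytest.raises(ValueError, match="10-40"):
        CandidateBeam(0, (0, 0, 0), 45.0)
    with pytest.raises(ValueError, match="10-40"):
        CandidateBeam(0, (0, 0, 0), 8.0)
    assert all(10 <= d <= 40 for d in COLLIMATOR_SET_MM)
    assert all(10 <= d <= 40 for d in choose_collimators(7.3, n=4))


# ----------------------------------------------------------------- kernel

def test_on_axis_calibration_is_exact():
    # source placed inside the slab so the sampled depth equals the axis
    # distance exactly; with SAD = ref depth the calibration point gives
    # the configured output exactly
    p = slab_phantom(spacing=1.0)
    kern = BeamKernelParams(sad_mm=15.0, ref_depth_mm=15.0,
                            penumbra_sigma_mm=0.1, mu_att_per_mm=0.005,
                            output_cgy_per_mu=2.5)
    src = np.array([0.0, 0.0, -15.0])
    beam = CandidateBeam(0, (0.0, 0.0, 5.0), 10.0)
    dose = beam_dose(beam, src, kern, p)
    ix = tuple(np.rint((np.zeros(3) - p.origin_mm) / p.spacing_mm
                       ).astype(int))
    assert dose[ix] == pytest.approx(2.5, rel=1e-9)


def test_exponential_attenuation_halves_at_ln2_over_mu():
    mu = np.log(2) / 20.0
    p = slab_phantom(shape=(21, 21, 61), spacing=1.0)
    kern = BeamKernelParams(sad_mm=15.0, ref_depth_mm=15.0,
                            penumbra_sigma_mm=0.1, mu_att_per_mm=mu)
    src = np.array([0.0, 0.0, -25.0])
    beam = CandidateBeam(0, (0.0, 0.0, 20.0), 10.0)
    dose = beam_dose(beam, src, kern, p)

    def at(z):
        ix = np.rint((np.array([0, 0, z]) - p.origin_mm) / p.spacing_mm)
        return dose[tuple(ix.astype(int))]

    d1, d2 = at(-10.0), at(10.0)          # s = 15 and s = 35 = 15 + ln2/mu
    ratio_no_invsq = (d1 / d2) * (15.0 / 35.0) ** 2
    assert ratio_no_invsq == pytest.approx(2.0, rel=1e-6)


def test_column_matches_straightforward_reimplementation():
    """Independent per-voxel loop (no vectorization, no sharing) against
    the production column."""
    p = slab_phantom(shape=(8, 8, 8), spacing=2.0)
    kern = BeamKernelParams(depth_samples=16)
    src = np.array([30.0, 10.0, 200.0])
    beam = CandidateBeam(0, (0.0, 0.0, 0.0), 12.5)
    got = beam_dose(beam, src, kern, p)

    axis = np.array(beam.aim_point_mm) - src
    axis = axis / np.linalg.norm(axis)
    want = np.zeros(p.shape)
    body = p.masks["body"]
    for i in range(8):
        for j in range(8):
            for k in range(8):
                if not body[i, j, k]:
                    continue
                x = p.origin_mm + np.array([i, j, k]) * p.spacing_mm
                s = float((x - src) @ axis)
                if s <= 1e-6:
                    continue
                rho = float(np.linalg.norm((x - src) - s * axis))
                R = 0.5 * beam.collimator_diameter_mm * s / kern.sad_mm
                if rho - R >= 5.0 * kern.penumbra_sigma_mm:
                    continue
                L = float(np.linalg.norm(x - src))
                inside = 0
                for q in range(kern.depth_samples):
                    pt = src + (q + 0.5) / kern.depth_samples * (x - src)
                    ix = np.rint((pt - p.origin_mm) / p.spacing_mm)
                    if np.all(ix >= 0) and np.all(ix < np.array(p.shape)):
                        if body[tuple(ix.astype(int))]:
                            inside += 1
                depth = inside * L / kern.depth_samples
                pen = 0.5 * erfc((rho - R) /
                                 (np.sqrt(2) * kern.penumbra_sigma_mm))
                want[i, j, k] = ((kern.sad_mm / s) ** 2
                                 * np.exp(-kern.mu_att_per_mm
                                          * (depth - kern.ref_depth_mm))
                                 * pen)
    assert np.max(np.abs(got - want)) < 1e-9


def test_beam_missing_body_warns_and_returns_zero(small_phantom):
    kern = BeamKernelParams()
    src = np.array([0.0, 0.0, 800.0])
    beam = CandidateBeam(0, (0.0, 0.0, 2000.0), 20.0)  # aims away
    with pytest.warns(UserWarning, match="misses the body"):
        dose = beam_dose(beam, src, kern, small_phantom)
    assert not dose.any()


# ------------------------------------------------------- influence matrix

def test_candidate_count_is_nodes_times_collimators(small_phantom):
    ns = generate_node_set(179, small_phantom.spec.head_radii_mm)
    im = build_influence_matrix(ns, (15.0, 20.0, 25.0), AimPolicy(0, 0),
                                BeamKernelParams(), small_phantom)
    assert im.n_beams == 537
    assert np.all(im.A.data >= 0)


def test_truncation_threshold_changes_columns_negligibly(small_phantom):
    ns = generate_node_set(12, small_phantom.spec.head_radii_mm)
    kern = BeamKernelParams()
    exact = build_influence_matrix(ns, (20.0,), AimPolicy(0, 0), kern,
                                   small_phantom, truncation_rel=0.0)
    trunc = build_influence_matrix(ns, (20.0,), AimPolicy(0, 0), kern,
                                   small_phantom, truncation_rel=1e-6)
    for j in range(exact.n_beams):
        te = exact.A[:, j].sum()
        tt = trunc.A[:, j].sum()
        assert abs(te - tt) <= 1e-4 * te


def test_dose_linearity_against_accumulated_kernels(small_phantom):
    ns = generate_node_set(6, small_phantom.spec.head_radii_mm)
    kern = BeamKernelParams()
    im = build_influence_matrix(ns, (20.0,), AimPolicy(0, 0), kern,
                                small_phantom, truncation_rel=0.0)
    w = np.array([3.0, 0.0, 1.5, 0.0, 2.0, 0.25])
    want = np.zeros(small_phantom.shape)
    for j, wj in enumerate(w):
        if wj:
            want += wj * beam_dose(im.beams[j],
                                   ns.positions_mm[im.beams[j].node_index],
                                   kern, small_phantom)
    got = im.dose_3d_gy(w) * 100.0         # back to cGy
    assert np.allclose(got, want, atol=1e-9)


def test_inverse_square_decay_in_near_vacuum():
    p = slab_phantom(shape=(15, 15, 61), spacing=1.0)
    kern = BeamKernelParams(mu_att_per_mm=1e-12, penumbra_sigma_mm=0.5)
    src = np.array([0.0, 0.0, 400.0])
    beam = CandidateBeam(0, (0.0, 0.0, 0.0), 40.0)
    dose = beam_dose(beam, src, kern, p)
    on_axis = dose[7, 7, ::-1]             # increasing source distance
    on_axis = on_axis[on_axis > 0]
    assert np.all(np.diff(on_axis) < 0)


def test_matrix_build_is_deterministic(small_phantom):
    ns = generate_node_set(10, small_phantom.spec.head_radii_mm)
    kw = dict(nodes=ns, collimators=(15.0, 25.0),
              aim_policy=AimPolicy(2, 99), kernel=BeamKernelParams(),
              phantom=small_phantom)
    a = build_influence_matrix(**kw)
    b = build_influence_matrix(**kw)
    assert (a.A != b.A).nnz == 0
    assert [x.aim_point_mm for x in a.beams] == \
        [x.aim_point_mm for x in b.beams]
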