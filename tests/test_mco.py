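"""Lexicographic solver: toy optima, hard-constraint respect, equivariance,
sparsification and the delivery/extraction helpers."""

import numpy as np
import pytest
from scipy import sparse

from shellplan.wishlist import (Prescription, Metric, HardConstraint,
                                Objective, WishList, TOTAL_MU,
                                default_vs_wishlist)
from shellplan.mco import (tail_mean_high, tail_mean_low, solve_lexicographic,
                           sparsify, estimate_delivery, DeliveryModel,
                           extract_shell_dmax, InfeasibleError, Plan,
                           ShellConstraintSet, metric_value)


# ------------------------------------------------------------- tail means

@pytest.mark.parametrize("vals,alpha,hi,lo", [
    ([7.0] * 5, 0.3, 7.0, 7.0),               # uniform
    ([1, 2, 3, 4], 0.5, 3.5, 1.5),            # hottest/coldest halves
    ([1, 2, 3, 4], 1.0, 2.5, 2.5),            # alpha=1 is the mean
    ([5, 1, 9], 0.01, 9.0, 1.0),              # ceil -> single voxel
])
def test_tail_means(vals, alpha, hi, lo):
    assert tail_mean_high(vals, alpha) == pytest.approx(hi)
    assert tail_mean_low(vals, alpha) == pytest.approx(lo)


def test_tail_mean_rejects_empty_and_bad_alpha():
    with pytest.raises(ValueError):
        tail_mean_high([], 0.5)
    with pytest.raises(ValueError):
        tail_mean_low([1.0], 1.5)


# -------------------------------------------------------------- wish-list

def test_default_wishlist_structure_and_roundtrip():
    wl = default_vs_wishlist()
    assert wl.constraints[0].structure == "ptv"
    assert wl.constraints[0].bound == pytest.approx(15.0)  # 12 / 0.8
    shell_objs = [o for o in wl.objectives if o.structure.startswith("shell")]
    assert [o.structure for o in shell_objs] == \
        ["shell_1cm", "shell_3cm", "shell_5cm"]
    assert sorted(o.priority for o in shell_objs) == [2, 3, 4]
    assert wl.objectives[-1].structure == TOTAL_MU
    back = WishList.from_yaml(wl.to_yaml())
    assert back.to_dict() == wl.to_dict()


def test_priorities_must_be_contiguous():
    with pytest.raises(ValueError, match="contiguous"):
        WishList(objectives=[Objective(1, "a", Metric("dmax")),
                             Objective(3, "b", Metric("dmax"))])


def test_prescription_implied_maximum():
    assert Prescription().ptv_max_gy == pytest.approx(15.0)
    with pytest.raises(ValueError):
        Prescription(isodose_fraction=0.0)


# ----------------------------------------------------------------- solver

def _coverage_objective(goal=12.0, alpha=0.4):
    return Objective(1, "ptv", Metric("tail_low", alpha), minimize=False,
                     goal=goal, sufficient=True)


def test_decoupled_toy_reaches_zero_shell_dose():
    A = np.eye(2)
    wl = WishList(
        constraints=[HardConstraint("ptv", Metric("dmax"), 12.0)],
        objectives=[_coverage_objective(alpha=1.0),
                    Objective(2, "shell", Metric("dmax")),
                    Objective(3, TOTAL_MU, Metric("total_mu"))],
        relaxation=1.0)
    plan, rep = solve_lexicographic(A, wl, {"ptv": [0], "shell": [1]})
    assert plan.weights == pytest.approx([12.0, 0.0], abs=1e-7)
    assert rep.phases[0].status == "goal_reached"
    assert rep.phases[1].achieved == pytest.approx(0.0, abs=1e-9)


def test_hard_constraints_respected_on_random_instances(rng):
    for _ in range(5):
        A = rng.uniform(0, 1, size=(12, 6))
        structures = {"ptv": np.arange(4), "oar": np.arange(4, 8),
                      "shell": np.arange(8, 12)}
        wl = WishList(
            constraints=[HardConstraint("ptv", Metric("dmax"), 15.0),
                         HardConstraint("oar", Metric("dmax"), 8.0)],
            objectives=[_coverage_objective(),
                        Objective(2, "shell", Metric("dmax")),
                        Objective(3, TOTAL_MU, Metric("total_mu"))])
        plan, rep = solve_lexicographic(A, wl, structures)
        dose = A @ plan.weights
        assert dose[structures["ptv"]].max() <= 15.0 * (1 + 1e-6)
        assert dose[structures["oar"]].max() <= 8.0 * (1 + 1e-6)
        # phase bounds hold for the final weights too
        for ph in rep.phases:
            if ph.metric_kind == "dmax":
                val = dose[structures[ph.structure]].max()
                assert val <= ph.bound_after * (1 + 1e-6) + 1e-9


def test_infeasible_hard_constraints_name_a_violator():
    A = np.eye(2)
    wl = WishList(
        constraints=[HardConstraint("ptv", Metric("dmax"), 10.0),
                     HardConstraint("ptv", Metric("tail_low", 1.0), 12.0,
                                    upper=False)],
        objectives=[Objective(1, TOTAL_MU, Metric("total_mu"))])
    with pytest.raises(InfeasibleError, match="ptv"):
        solve_lexicographic(A, wl, {"ptv": [0, 1]})


def test_scale_equivariance(rng):
    A = rng.uniform(0.1, 1, size=(6, 4))
    structures = {"ptv": np.arange(3), "shell": np.arange(3, 6)}
    wl = WishList(
        constraints=[HardConstraint("ptv", Metric("dmax"), 15.0)],
        objectives=[_coverage_objective(),
                    Objective(2, "shell", Metric("dmax")),
                    Objective(3, TOTAL_MU, Metric("total_mu"))])
    p1, _ = solve_lexicographic(A, wl, structures)
    c = 4.0
    p2, _ = solve_lexicographic(c * A, wl, structures)
    assert np.allclose(p2.weights, p1.weights / c, atol=1e-6)
    assert np.allclose(A @ p1.weights, c * A @ p2.weights, atol=1e-6)


def test_relaxation_monotonicity(rng):
    A = rng.uniform(0.1, 1, size=(6, 4))
    structures = {"ptv": np.arange(2), "s1": np.arange(2, 4),
                  "s2": np.arange(4, 6)}
    cons = [HardConstraint("ptv", Metric("tail_low", 1.0), 12.0,
                           upper=False)]
    objs = [Objective(1, "s1", Metric("dmax")),
            Objective(2, "s2", Metric("dmax"))]
    tight, _ = solve_lexicographic(
        A, WishList(constraints=cons, objectives=objs, relaxation=1.0),
        structures)
    loose, _ = solve_lexicographic(
        A, WishList(constraints=cons, objectives=objs, relaxation=1.03),
        structures)
    d_tight, d_loose = A @ tight.weights, A @ loose.weights
    # same first-priority optimum; slack at priority 1 can only help 2
    assert d_loose[structures["s2"]].max() \
        <= d_tight[structures["s2"]].max() + 1e-7


# --------------------------------------------------------------- sparsify

def test_sparsify_is_identity_when_under_limit():
    A = np.eye(2)
    wl = WishList(
        constraints=[HardConstraint("ptv", Metric("tail_low", 1.0), 12.0,
                                    upper=False)],
        objectives=[Objective(1, TOTAL_MU, Metric("total_mu"))])
    plan, _ = solve_lexicographic(A, wl, {"ptv": [0]})
    out, _, ok = sparsify(plan, A, wl, {"ptv": [0]}, max_beams=5)
    assert ok and np.array_equal(out.weights, plan.weights)


def test_sparsify_prunes_and_objectives_cannot_improve(rng):
    A = rng.uniform(0, 1, size=(8, 12))
    structures = {"ptv": np.arange(4), "shell": np.arange(4, 8)}
    wl = WishList(
        constraints=[HardConstraint("ptv", Metric("dmax"), 15.0),
                     HardConstraint("ptv", Metric("tail_low", 0.5), 12.0,
                                    upper=False)],
        objectives=[Objective(1, "shell", Metric("dmax")),
                    Objective(2, TOTAL_MU, Metric("total_mu"))])
    plan, rep = solve_lexicographic(A, wl, structures)
    out, rep2, ok = sparsify(plan, A, wl, structures, max_beams=4,
                             weight_floor=0.05)
    dose = A @ out.weights
    # restricted candidate set: shell optimum can only stay or worsen
    assert dose[structures["shell"]].max() \
        >= rep.phases[0].achieved - 1e-7
    assert dose[structures["ptv"]].max() <= 15.0 * (1 + 1e-6)


# ------------------------------------------------------ delivery estimate

def test_delivery_time_components():
    model = DeliveryModel(setup_min=5.0, sec_per_node=15.0, sec_per_beam=3.0,
                          mu_per_min=600.0)
    empty = Plan(weights=np.zeros(3), beams=[], node_count=0, beam_count=0,
                 total_mu=0.0)
    assert estimate_delivery(empty, model) == pytest.approx(5.0)
    plan = Plan(weights=np.ones(3), beams=[], node_count=2, beam_count=3,
                total_mu=1200.0)
    t1 = estimate_delivery(plan, model)
    plan2 = Plan(weights=np.ones(3), beams=[], node_count=2, beam_count=3,
                 total_mu=2400.0)
    assert estimate_delivery(plan2, model) - t1 \
        == pytest.approx(1200.0 / 600.0)
    # logged plausibility point at clinical-scale counts (no assertion
    # against any external value, just monotone sanity)
    big = Plan(weights=np.ones(3), beams=[], node_count=56, beam_count=162,
               total_mu=4899.0)
    assert estimate_delivery(big, model) > t1


# ------------------------------------------------- shell Dmax extraction

def _toy_im_uniform(dose_cgy_per_mu=100.0, n=9):
    from shellplan.beams import InfluenceMatrix, NodeSet, BeamKernelParams
    shape = (n, n, n)
    body = np.ones(shape, bool)
    vidx = np.argwhere(body)
    A = sparse.csc_matrix(np.full((n ** 3, 1), dose_cgy_per_mu))
    return InfluenceMatrix(A=A, beams=[], nodes=NodeSet(np.zeros((1, 3))),
                           voxel_index=vidx, grid_shape=shape,
                           kernel=BeamKernelParams())


def test_extract_uniform_dose_gives_100_cgy_everywhere():
    from shellplan.shells import build_shell_set
    im = _toy_im_uniform()
    ptv = np.zeros(im.grid_shape, bool)
    ptv[4, 4, 4] = True
    ss = build_shell_set(ptv, np.ones(im.grid_shape, bool), 10.0,
                         (0.5, 1.5, 2.5), thickness_mm=10.0)
    plan = Plan(weights=np.ones(1), beams=[], node_count=1, beam_count=1,
                total_mu=1.0)
    cons = extract_shell_dmax(plan, im, ss)
    assert [cons.dmax_cgy[d] for d in cons.distances_cm] == [100, 100, 100]


def test_extract_matches_brute_force_max_and_warns_on_inversion(rng):
    from shellplan.shells import build_shell_set
    im = _toy_im_uniform()
    im.A = sparse.csc_matrix(rng.uniform(10, 500, size=(9 ** 3, 1)))
    ptv = np.zeros(im.grid_shape, bool)
    ptv[4, 4, 4] = True
    ss = build_shell_set(ptv, np.ones(im.grid_shape, bool), 10.0,
                         (0.5, 1.5), thickness_mm=10.0)
    plan = Plan(weights=np.ones(1), beams=[], node_count=1, beam_count=1,
                total_mu=1.0)
    dose = im.dose_gy(plan.weights)
    brute = {d: np.rint(100 * dose[im.rows_for(ss[d])].max())
             for d in ss}
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        cons = extract_shell_dmax(plan, im, ss)
    assert cons.dmax_cgy == brute
    # force an inverted profile: hot voxel on the outer shell only
    vals = np.full((9 ** 3, 1), 100.0)
    outer_row = im.rows_for(ss[1.5])[0]
    vals[outer_row, 0] = 400.0
    im.A = sparse.csc_matrix(vals)
    with pytest.warns(UserWarning, match="nonincreasing"):
        extract_shell_dmax(plan, im, ss)


def test_shell_constraint_set_validation():
    with pytest.raises(ValueError, match="positive"):
        ShellConstraintSet((1.0, 3.0), {1.0: 0.0, 3.0: 100.0})
    s = ShellConstraintSet((1.0, 3.0, 5.0),
                           {1.0: 426.0, 3.0: 162.0, 5.0: 120.0})
    assert s.nonincreasing()
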