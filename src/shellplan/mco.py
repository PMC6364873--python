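"""Lexicographic epsilon-constraint optimization of beam weights.

Each wish-list objective is optimized in priority order; after phase k the
achieved value is frozen into a constraint (relaxed by the slip factor
delta >= 1) for all later phases, so lower priorities can never degrade a
higher-priority result by more than the slip.  Every phase is a linear
program over nonnegative beam weights: maximum doses become per-voxel rows,
and percentile-type metrics are linearized through their tail-mean (CVaR)
representation with auxiliary variables.  The returned plan is
Pareto-prioritized: no feasible plan improves a higher-priority value
without violating an earlier bound.

The tail-mean surrogate for coverage is sound by construction: if the mean
dose of the coldest ceil(0.02 n) target voxels is at least the prescription
dose, then at most ceil(0.02 n) - 1 voxels are below it, so V(prescription)
exceeds 98 % exactly.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .beams import InfluenceMatrix
from .wishlist import (WishList, HardConstraint, Objective, Metric, TOTAL_MU,
                       shell_structure_name)

_ABS_SLACK = 1e-7


class InfeasibleError(RuntimeError):
    pass


# -------------------------------------------------------------- tail means

def tail_mean_high(values, alpha: float) -> float:
    """Mean of the hottest ceil(alpha*n) values (CVaR-style near-max)."""
    v = np.sort(np.asarray(values, float))
    if v.size == 0:
        raise ValueError("empty structure")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    k = int(np.ceil(alpha * v.size))
    return float(v[-k:].mean())


def tail_mean_low(values, alpha: float) -> float:
    """Mean of the coldest ceil(alpha*n) values."""
    v = np.sort(np.asarray(values, float))
    if v.size == 0:
        raise ValueError("empty structure")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    k = int(np.ceil(alpha * v.size))
    return float(v[:k].mean())


def metric_value(metric: Metric, dose_gy: np.ndarray, rows, w=None) -> float:
    """Exact (post-hoc) value of a wish-list metric."""
    if metric.kind == "total_mu":
        return float(np.sum(w))
    d = dose_gy[rows]
    if metric.kind == "dmax":
        return float(d.max())
    if metric.kind == "dmean":
        return float(d.mean())
    if metric.kind == "tail_high":
        return tail_mean_high(d, metric.alpha)
    return tail_mean_low(d, metric.alpha)


# ------------------------------------------------------------------- plan

@dataclass
class Plan:
    """Beam weights (MU) with derived delivery counts."""

    weights: np.ndarray
    beams: list                          # active CandidateBeam objects
    node_count: int
    beam_count: int
    total_mu: float
    delivery_minutes: float | None = None
    provenance: dict = field(default_factory=dict)

    @classmethod
    def from_weights(cls, w: np.ndarray, im: InfluenceMatrix | None,
                     provenance: dict | None = None,
                     zero_floor_rel: float = 1e-9) -> "Plan":
        w = np.asarray(w, float).copy()
        if w.size and w.max() > 0:
            w[w < zero_floor_rel * w.max()] = 0.0
        active = np.flatnonzero(w > 0)
        beams = [im.beams[j] for j in active] if im is not None else []
        nodes = len({b.node_index for b in beams}) if beams else 0
        return cls(weights=w, beams=beams, node_count=nodes,
                   beam_count=len(active), total_mu=float(w.sum()),
                   provenance=provenance or {})


@dataclass
class PhaseResult:
    priority: int
    structure: str
    metric_kind: str
    status: str                 # optimal | goal_reached | infeasible
    achieved: float | None
    bound_after: float | None


@dataclass
class SolveReport:
    phases: list[PhaseResult] = field(default_factory=list)
    infeasible_constraint: str | None = None

    @property
    def feasible(self) -> bool:
        return all(p.status != "infeasible" for p in self.phases) \
            and self.infeasible_constraint is None


# -------------------------------------------------------------- LP builder

class _LP:
    """Incremental sparse LP: min c.x  s.t.  A_ub x <= b_ub, bounds."""

    def __init__(self, n_w: int):
        self.n_w = n_w
        self.nvar = n_w
        self.bounds = [(0.0, None)] * n_w
        self._r, self._c, self._v, self.b = [], [], [], []
        self.nrow = 0
        self.c_entries: list[tuple[int, float]] = []

    def new_var(self, lb=None, ub=None) -> int:
        self.bounds.append((lb, ub))
        self.nvar += 1
        return self.nvar - 1

    def add_block(self, M: sparse.spmatrix, b: np.ndarray,
                  extra: list[tuple[np.ndarray, np.ndarray]] = ()):
        """Rows M w + sum(extra cols) <= b; extra = [(col_idx_per_row, val)]."""
        M = M.tocoo()
        m = M.shape[0]
        self._r.append(M.row + self.nrow)
        self._c.append(M.col)
        self._v.append(M.data)
        for cols, vals in extra:
            self._r.append(np.arange(m) + self.nrow)
            self._c.append(np.asarray(cols))
            self._v.append(np.broadcast_to(np.asarray(vals, float), (m,)))
        self.b.extend(np.broadcast_to(b, (m,)).tolist())
        self.nrow += m

    def add_row(self, cols, vals, ub):
        self._r.append(np.full(len(cols), self.nrow))
        self._c.append(np.asarray(cols))
        self._v.append(np.asarray(vals, float))
        self.b.append(ub)
        self.nrow += 1

    def solve(self):
        c = np.zeros(self.nvar)
        for j, v in self.c_entries:
            c[j] += v
        if self.nrow:
            A = sparse.coo_matrix(
                (np.concatenate(self._v),
                 (np.concatenate(self._r), np.concatenate(self._c))),
                shape=(self.nrow, self.nvar)).tocsr()
            # interior point handles the flat, degenerate max-dose phases
            # better than simplex on these instances; fall back if it bails
            res = linprog(c, A_ub=A, b_ub=np.asarray(self.b),
                          bounds=self.bounds, method="highs-ipm")
            if res.status not in (0, 2):
                res = linprog(c, A_ub=A, b_ub=np.asarray(self.b),
                              bounds=self.bounds, method="highs")
        else:
            res = linprog(c, bounds=self.bounds, method="highs")
        return res


# maximum-dose blocks larger than this use lazy row generation: solve with
# a subset of voxel rows, add violated rows, repeat until clean
LAZY_DMAX_THRESHOLD = 256
_LAZY_SEED_ROWS = 64
_LAZY_TOL = 1e-6


def _lazy_subset(structure: str, rows: np.ndarray,
                 lazy_rows: dict | None) -> np.ndarray:
    if lazy_rows is None or len(rows) <= LAZY_DMAX_THRESHOLD:
        return rows
    if structure not in lazy_rows:
        pick = np.linspace(0, len(rows) - 1, _LAZY_SEED_ROWS).astype(int)
        lazy_rows[structure] = rows[pick]
    return lazy_rows[structure]


def _add_constraint(lp: _LP, con: HardConstraint, A_gy, structures,
                    lazy_rows: dict | None = None):
    m = con.metric
    if m.kind == "total_mu":
        sign = 1.0 if con.upper else -1.0
        lp.add_row(np.arange(lp.n_w), np.full(lp.n_w, sign),
                   sign * con.bound)
        return
    rows = structures[con.structure]
    if m.kind == "dmax":
        rows = _lazy_subset(con.structure, rows, lazy_rows)
    Ar = A_gy[rows]
    if m.kind == "dmax":
        if not con.upper:
            raise ValueError("dmax lower bounds are not supported")
        lp.add_block(Ar, np.full(Ar.shape[0], float(con.bound)))
    elif m.kind == "dmean":
        mean_row = np.asarray(Ar.mean(axis=0)).ravel()
        cols = np.flatnonzero(mean_row)
        sign = 1.0 if con.upper else -1.0
        lp.add_row(cols, sign * mean_row[cols], sign * con.bound)
    elif m.kind == "tail_high":
        if not con.upper:
            raise ValueError("tail_high lower bounds are not supported")
        zeta, u = _tail_high_vars(lp, Ar)
        k = int(np.ceil(m.alpha * Ar.shape[0]))
        lp.add_row([zeta] + list(u), [1.0] + [1.0 / k] * len(u), con.bound)
    elif m.kind == "tail_low":
        if con.upper:
            raise ValueError("tail_low upper bounds are not supported")
        zeta, u = _tail_low_vars(lp, Ar)
        k = int(np.ceil(m.alpha * Ar.shape[0]))
        lp.add_row([zeta] + list(u), [-1.0] + [1.0 / k] * len(u), -con.bound)
    else:
        raise ValueError(m.kind)


def _tail_high_vars(lp: _LP, Ar):
    """zeta free, u >= 0 with  A_r w - zeta - u_r <= 0; tail-high =
    min zeta + (1/k) sum u over that polytope."""
    mrows = Ar.shape[0]
    zeta = lp.new_var(None, None)
    u0 = lp.nvar
    for _ in range(mrows):
        lp.new_var(0.0, None)
    u = np.arange(u0, u0 + mrows)
    lp.add_block(Ar, np.zeros(mrows),
                 extra=[(np.full(mrows, zeta), -1.0), (u, -1.0)])
    return zeta, u


def _tail_low_vars(lp: _LP, Ar):
    """zeta free, u >= 0 with  zeta - A_r w - u_r <= 0; tail-low =
    max zeta - (1/k) sum u."""
    mrows = Ar.shape[0]
    zeta = lp.new_var(None, None)
    u0 = lp.nvar
    for _ in range(mrows):
        lp.new_var(0.0, None)
    u = np.arange(u0, u0 + mrows)
    lp.add_block(-Ar, np.zeros(mrows),
                 extra=[(np.full(mrows, zeta), 1.0), (u, -1.0)])
    return zeta, u


def _add_objective(lp: _LP, obj: Objective, A_gy, structures,
                   lazy_rows: dict | None = None):
    """Install min c.x for this phase; returns sign so achieved=sign*fun."""
    m = obj.metric
    if m.kind == "total_mu":
        lp.c_entries = [(j, 1.0) for j in range(lp.n_w)]
        return 1.0
    rows = structures[obj.structure]
    if m.kind == "dmax":
        rows = _lazy_subset(obj.structure, rows, lazy_rows)
    Ar = A_gy[rows]
    if m.kind == "dmax":
        t = lp.new_var(None, None)
        lp.add_block(Ar, np.zeros(Ar.shape[0]),
                     extra=[(np.full(Ar.shape[0], t), -1.0)])
        lp.c_entries = [(t, 1.0)]
        return 1.0
    if m.kind == "dmean":
        mean_row = np.asarray(Ar.mean(axis=0)).ravel()
        lp.c_entries = [(j, mean_row[j]) for j in np.flatnonzero(mean_row)]
        return 1.0
    if m.kind == "tail_high":
        zeta, u = _tail_high_vars(lp, Ar)
        k = int(np.ceil(m.alpha * Ar.shape[0]))
        lp.c_entries = [(zeta, 1.0)] + [(j, 1.0 / k) for j in u]
        return 1.0
    if m.kind == "tail_low":
        # maximize zeta - (1/k) sum u, optionally capped at the goal
        zeta, u = _tail_low_vars(lp, Ar)
        k = int(np.ceil(m.alpha * Ar.shape[0]))
        lp.c_entries = [(zeta, -1.0)] + [(j, 1.0 / k) for j in u]
        if obj.sufficient and obj.goal is not None:
            lp.add_row([zeta] + list(u), [1.0] + [-1.0 / k] * len(u),
                       obj.goal)
        return -1.0
    raise ValueError(m.kind)


def _coerce_A(A):
    if isinstance(A, InfluenceMatrix):
        return (A.A.tocsr() / 100.0), A       # cGy/MU -> Gy/MU
    M = sparse.csr_matrix(A, dtype=float)
    return M, None


def _feasibility(A_gy, constraints, structures) -> bool:
    lp = _LP(A_gy.shape[1])
    for con in constraints:
        _add_constraint(lp, con, A_gy, structures)
    return lp.solve().status == 0


def _name_violator(A_gy, constraints, structures) -> str:
    for k, con in enumerate(constraints):
        rest = constraints[:k] + constraints[k + 1:]
        if _feasibility(A_gy, rest, structures):
            return f"{con.structure} {con.metric.kind} " \
                   f"{'<=' if con.upper else '>='} {con.bound}"
    return "a combination of hard constraints"


def _solve_phase(A_gy, active, obj, structures, lazy_rows,
                 max_lazy_iter: int = 500):
    """One lexicographic phase with lazy maximum-dose row generation.

    Large Dmax blocks enter the LP through a growing subset of voxel rows;
    after each solve, voxels violating their bound (or exceeding the
    current Dmax-objective level) are appended and the phase re-solved,
    until no violations remain.  The converged solution is identical to
    the full-row LP's.
    """
    n_w = A_gy.shape[1]
    for _ in range(max_lazy_iter):
        lp = _LP(n_w)
        for con in active:
            _add_constraint(lp, con, A_gy, structures, lazy_rows)
        sign = _add_objective(lp, obj, A_gy, structures, lazy_rows)
        res = lp.solve()
        if res.status != 0:
            return res, sign, None, None
        w = res.x[:n_w]
        dose = A_gy @ w
        grew = False
        for con in active:
            if con.metric.kind != "dmax":
                continue
            rows = structures[con.structure]
            if len(rows) <= LAZY_DMAX_THRESHOLD:
                continue
            grew |= _grow_lazy(lazy_rows, con.structure, rows, dose,
                               con.bound)
        achieved = float(sign * res.fun)
        if obj.metric.kind == "dmax":
            rows = structures[obj.structure]
            if len(rows) > LAZY_DMAX_THRESHOLD:
                grew |= _grow_lazy(lazy_rows, obj.structure, rows, dose,
                                   achieved)
                achieved = max(achieved, float(dose[rows].max()))
        if not grew:
            return res, sign, w, achieved
    raise RuntimeError("lazy constraint generation did not converge")


def _grow_lazy(lazy_rows, name, rows, dose, level, batch: int = 256) -> bool:
    viol = rows[dose[rows] > level + _LAZY_TOL]
    if viol.size == 0:
        return False
    worst = viol[np.argsort(dose[viol])[::-1][:batch]]
    before = lazy_rows[name].size
    lazy_rows[name] = np.union1d(lazy_rows[name], worst)
    # no actual growth: remaining violations are solver-tolerance noise on
    # rows already present
    return lazy_rows[name].size > before


def solve_lexicographic(A, wishlist: WishList, structures: dict,
                        provenance: dict | None = None,
                        lazy_rows: dict | None = None
                        ) -> tuple[Plan, SolveReport]:
    """Run the phase-by-phase lexicographic optimization.

    ``A`` is an InfluenceMatrix (cGy/MU) or any matrix in Gy per unit
    weight; ``structures`` maps structure names to row indices of A.
    Raises ``InfeasibleError`` naming a violating constraint when the hard
    constraint set admits no plan.
    """
    A_gy, im = _coerce_A(A)
    missing = wishlist.structures_referenced() - set(structures)
    if missing:
        raise KeyError(f"wish-list references unknown structures {missing}")
    active = list(wishlist.constraints)
    report = SolveReport()
    w = None
    if lazy_rows is None:
        lazy_rows = {}      # persists across phases (and callers may share)
    for obj in sorted(wishlist.objectives, key=lambda o: o.priority):
        res, sign, w, achieved = _solve_phase(A_gy, active, obj, structures,
                                              lazy_rows)
        if res.status != 0:
            if obj.priority == 1 and not _feasibility(A_gy, active,
                                                      structures):
                name = _name_violator(A_gy, wishlist.constraints, structures)
                report.infeasible_constraint = name
                report.phases.append(PhaseResult(
                    obj.priority, obj.structure, obj.metric.kind,
                    "infeasible", None, None))
                raise InfeasibleError(
                    f"hard constraints infeasible; violating: {name}")
            raise RuntimeError(
                f"solver failed in phase {obj.priority} (status "
                f"{res.status}: {res.message})")
        if obj.minimize:
            bound = wishlist.relaxation * achieved + _ABS_SLACK
            active.append(HardConstraint(obj.structure, obj.metric, bound,
                                         upper=True))
            status = "optimal"
        else:
            goal_met = (obj.goal is not None
                        and achieved >= obj.goal - 1e-6)
            if obj.sufficient and goal_met:
                bound = obj.goal
                status = "goal_reached"
            else:
                bound = achieved / wishlist.relaxation - _ABS_SLACK
                status = "optimal"
            active.append(HardConstraint(obj.structure, obj.metric, bound,
                                         upper=False))
        report.phases.append(PhaseResult(obj.priority, obj.structure,
                                         obj.metric.kind, status, achieved,
                                         bound))
    prov = dict(provenance or {})
    prov["wishlist_sha1"] = hashlib.sha1(
        wishlist.to_yaml().encode()).hexdigest()[:12]
    plan = Plan.from_weights(w, im, provenance=prov)
    return plan, report


# ---------------------------------------------------------------- sparsify

def sparsify(plan: Plan, A, wishlist: WishList, structures: dict,
             max_beams: int = 250, weight_floor: float = 0.02,
             max_iter: int = 10) -> tuple[Plan, SolveReport, bool]:
    """Prune low-weight beams and re-solve on the reduced candidate set.

    Iterates until the active beam count is at most ``max_beams`` or a
    fixed point is reached.  Returns (plan, last report, reached_target).
    Because pruning only restricts the feasible set, objective values can
    only stay or worsen relative to the unrestricted optimum.
    """
    A_gy, im = _coerce_A(A)
    current, report = plan, None
    allowed = current.weights > 0
    for _ in range(max_iter):
        if current.beam_count <= max_beams:
            return current, report, True
        wmax = current.weights.max()
        keep = current.weights >= weight_floor * wmax
        if keep.sum() == allowed.sum():           # fixed point
            break
        allowed = keep
        A_sub = A_gy[:, np.flatnonzero(allowed)]
        try:
            sub_plan, report = solve_lexicographic(A_sub, wishlist,
                                                   structures)
        except InfeasibleError:
            return current, report, False
        w_full = np.zeros_like(current.weights)
        w_full[np.flatnonzero(allowed)] = sub_plan.weights
        current = Plan.from_weights(w_full, im,
                                    provenance=dict(plan.provenance,
                                                    sparsified=True))
    return current, report, current.beam_count <= max_beams


# ------------------------------------------------------------ delivery time

@dataclass(frozen=True)
class DeliveryModel:
    """Linear delivery-time surrogate; coefficients are package defaults."""
    setup_min: float = 5.0
    sec_per_node: float = 15.0
    sec_per_beam: float = 3.0
    mu_per_min: float = 600.0


def estimate_delivery(plan: Plan,
                      model: DeliveryModel = DeliveryModel()) -> float:
    """Minutes = setup + node travel + per-beam overhead + beam-on time."""
    return (model.setup_min
            + plan.node_count * model.sec_per_node / 60.0
            + plan.beam_count * model.sec_per_beam / 60.0
            + plan.total_mu / model.mu_per_min)


# -------------------------------------------------- shell Dmax extraction

@dataclass
class ShellConstraintSet:
    """Per-distance shell maximum doses in cGy (integer-rounded)."""

    distances_cm: tuple[float, ...]
    dmax_cgy: dict[float, float]

    def __post_init__(self):
        vals = [self.dmax_cgy[d] for d in self.distances_cm]
        if any(v <= 0 for v in vals):
            raise ValueError("shell Dmax values must be positive")

    def nonincreasing(self) -> bool:
        vals = [self.dmax_cgy[d] for d in self.distances_cm]
        return all(b <= a for a, b in zip(vals, vals[1:]))

    def as_array(self) -> np.ndarray:
        return np.array([self.dmax_cgy[d] for d in self.distances_cm])


def extract_shell_dmax(plan: Plan, im: InfluenceMatrix, shell_set,
                       round_to_cgy: bool = True) -> ShellConstraintSet:
    """Maximum voxel dose per shell under the plan, in cGy.

    Empty shells are excluded with a warning; a non-monotone profile
    (inner shell colder than an outer one) is reported, not raised.
    """
    dose = im.dose_gy(plan.weights)
    dmax, dists = {}, []
    for d in shell_set.distances_cm:
        mask = shell_set[d]
        if not mask.any():
            warnings.warn(f"shell at {d} cm is empty; excluded")
            continue
        v = 100.0 * float(dose[im.rows_for(mask)].max())
        dmax[d] = float(np.rint(v)) if round_to_cgy else v
        dists.append(d)
    out = ShellConstraintSet(distances_cm=tuple(dists), dmax_cgy=dmax)
    if not out.nonincreasing():
        warnings.warn("shell Dmax profile is not nonincreasing with "
                      "distance")
    return out
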