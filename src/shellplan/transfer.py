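"""Step two of the automated workflow, and the fixed-constraint experiment.

Step one (``mco.solve_lexicographic`` with the default wish-list) produces
a Pareto-prioritized pre-plan whose shell maximum doses at 1, 3 and 5 cm
are extracted as individualized constraints.  Step two re-plans under
those constraints with a simpler objective stack — coverage to goal, then
monitor-unit economy — emulating a clinical optimizer fed a planning
template.  The fixed-constraint arm (fAUTO) repeats step two with the
population-mean constraints instead of the individualized ones; patients
whose re-plan cannot reach 98 % coverage even after rescaling are flagged
unacceptable.

A deliberately simpler weighted baseline planner (coverage to goal, then
MU, with no shell control at all) stands in for manual planning when
comparing dose-bath behaviour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .phantom import Phantom, PhantomSpec, generate_cohort
from .beams import (BeamKernelParams, AimPolicy, InfluenceMatrix,
                    generate_node_set, choose_collimators,
                    build_influence_matrix, DEFAULT_NODE_COUNT)
from .shells import (ShellSet, shells_for_phantom, OPTIMIZATION_DISTANCES_CM,
                     EVALUATION_DISTANCES_CM)
from .wishlist import (Prescription, WishList, HardConstraint, Objective,
                       Metric, TOTAL_MU, DEFAULT_OAR_DMAX_GY,
                       COVERAGE_TAIL_ALPHA, default_vs_wishlist,
                       shell_structure_name)
from .mco import (Plan, SolveReport, ShellConstraintSet, InfeasibleError,
                  solve_lexicographic, extract_shell_dmax, estimate_delivery,
                  DeliveryModel)
from .metrics import (PlanMetrics, plan_report, rescale_to_coverage,
                      coverage, OAR_NAMES)

# half the constraint rounding unit (1 cGy), so that integer-rounded
# constraints remain feasible for the plan they were extracted from
_ROUNDING_SLACK_GY = 0.005


@dataclass
class ExperimentConfig:
    """Study conditions for the cohort experiment."""

    seed: int = 7
    n_patients: int = 20
    voxel_mm: float = 4.0
    node_count: int = DEFAULT_NODE_COUNT
    n_collimators: int = 2
    n_random_aim_points: int = 1
    prescription: Prescription = field(default_factory=Prescription)
    oar_dmax_gy: dict = field(default_factory=lambda:
                              dict(DEFAULT_OAR_DMAX_GY))
    relaxation: float = 1.03
    kernel: BeamKernelParams = field(default_factory=BeamKernelParams)
    delivery: DeliveryModel = field(default_factory=DeliveryModel)
    opt_distances_cm: tuple = OPTIMIZATION_DISTANCES_CM
    eval_distances_cm: tuple = EVALUATION_DISTANCES_CM


@dataclass
class PatientContext:
    phantom: Phantom
    im: InfluenceMatrix
    shells_opt: ShellSet
    shells_eval: ShellSet
    structures: dict


def build_patient_context(phantom: Phantom, config: ExperimentConfig,
                          aim_seed: int) -> PatientContext:
    nodes = generate_node_set(config.node_count,
                              phantom.spec.head_radii_mm if phantom.spec
                              else (80.0, 95.0, 85.0))
    collims = choose_collimators(phantom.volume_cc("ptv"),
                                 n=config.n_collimators)
    im = build_influence_matrix(
        nodes, collims, AimPolicy(config.n_random_aim_points, aim_seed),
        config.kernel, phantom)
    shells_opt = shells_for_phantom(phantom, config.opt_distances_cm)
    shells_eval = shells_for_phantom(phantom, config.eval_distances_cm)
    structures = {n: im.rows_for(phantom.masks[n])
                  for n in ("ptv",) + OAR_NAMES if phantom.masks[n].any()}
    for d in shells_opt:
        if shells_opt[d].any():
            structures[shell_structure_name(d)] = im.rows_for(shells_opt[d])
    return PatientContext(phantom, im, shells_opt, shells_eval, structures)


# --------------------------------------------------------- step-two plans

def _coverage_then_mu_objectives(prescription: Prescription):
    return [Objective(1, "ptv", Metric("tail_low", COVERAGE_TAIL_ALPHA),
                      minimize=False, goal=prescription.dose_gy,
                      sufficient=True),
            Objective(2, TOTAL_MU, Metric("total_mu"))]


def plan_with_shell_constraints(ctx: PatientContext,
                                shell_constraints: ShellConstraintSet,
                                prescription: Prescription = Prescription(),
                                oar_dmax_gy: dict | None = None,
                                relaxation: float = 1.03,
                                lazy_rows: dict | None = None
                                ) -> tuple[Plan | None, SolveReport]:
    """Re-plan with shell Dmax values imposed as hard constraints.

    Objectives: coverage surrogate to goal, then total-MU economy.  An
    infeasible constraint set yields (None, report); there is no silent
    relaxation.
    """
    oar_dmax_gy = DEFAULT_OAR_DMAX_GY if oar_dmax_gy is None else oar_dmax_gy
    cons = [HardConstraint("ptv", Metric("dmax"), prescription.ptv_max_gy)]
    cons += [HardConstraint(s, Metric("dmax"), b)
             for s, b in oar_dmax_gy.items() if s in ctx.structures]
    for d in shell_constraints.distances_cm:
        name = shell_structure_name(d)
        if name not in ctx.structures:
            continue
        bound = shell_constraints.dmax_cgy[d] / 100.0 + _ROUNDING_SLACK_GY
        cons.append(HardConstraint(name, Metric("dmax"), bound))
    wl = WishList(constraints=cons,
                  objectives=_coverage_then_mu_objectives(prescription),
                  relaxation=relaxation)
    try:
        return solve_lexicographic(ctx.im, wl, ctx.structures,
                                   lazy_rows=lazy_rows)
    except InfeasibleError as e:
        report = SolveReport(infeasible_constraint=str(e))
        return None, report


def plan_baseline(ctx: PatientContext,
                  prescription: Prescription = Prescription(),
                  oar_dmax_gy: dict | None = None,
                  relaxation: float = 1.03,
                  lazy_rows: dict | None = None) -> tuple[Plan, SolveReport]:
    """Coverage-then-MU planner with no shell control.

    Emulates the behaviour this workflow is designed to improve on: the
    plan meets coverage and the organ-at-risk bounds, and spends its
    remaining freedom on delivery economy rather than on containing dose
    spillage.
    """
    oar_dmax_gy = DEFAULT_OAR_DMAX_GY if oar_dmax_gy is None else oar_dmax_gy
    cons = [HardConstraint("ptv", Metric("dmax"), prescription.ptv_max_gy)]
    cons += [HardConstraint(s, Metric("dmax"), b)
             for s, b in oar_dmax_gy.items() if s in ctx.structures]
    wl = WishList(constraints=cons,
                  objectives=_coverage_then_mu_objectives(prescription),
                  relaxation=relaxation)
    return solve_lexicographic(ctx.im, wl, ctx.structures,
                               lazy_rows=lazy_rows)


def population_mean_constraints(sets: list[ShellConstraintSet]
                                ) -> ShellConstraintSet:
    """Per-distance arithmetic mean, rounded to the nearest integer cGy."""
    if not sets:
        raise ValueError("need at least one constraint set")
    dists = sets[0].distances_cm
    for s in sets[1:]:
        if s.distances_cm != dists:
            raise ValueError("mismatched shell distance lists")
    mean = np.mean([s.as_array() for s in sets], axis=0)
    return ShellConstraintSet(
        distances_cm=dists,
        dmax_cgy={d: float(np.rint(v)) for d, v in zip(dists, mean)})


# ------------------------------------------------------------- evaluation

@dataclass
class ArmResult:
    plan: Plan | None
    report: SolveReport | None
    metrics: PlanMetrics | None
    coverage_pct: float | None
    rescale_factor: float | None
    rescale_achieved: bool
    acceptable: bool
    structure_dmax_gy: dict = field(default_factory=dict)


def evaluate_arm(plan: Plan | None, report, ctx: PatientContext,
                 config: ExperimentConfig) -> ArmResult:
    """Rescale to 98 % coverage when the hard bounds allow it, then score.

    Upscaling is limited by the tightest hard maximum-dose bound (target
    or OAR); a plan that cannot reach 98 % coverage within those bounds is
    kept unscaled and flagged unacceptable.
    """
    if plan is None:
        return ArmResult(None, report, None, None, None, False, False, {})
    dose3d = ctx.im.dose_3d_gy(plan.weights)
    bounds = {"ptv": config.prescription.ptv_max_gy,
              **{k: v for k, v in config.oar_dmax_gy.items()
                 if k in ctx.phantom.masks}}
    max_factor = np.inf
    for name, bound in bounds.items():
        dmax = dose3d[ctx.phantom.masks[name]].max()
        if dmax > 0:
            max_factor = min(max_factor, (bound + 1e-6) / dmax)
    scaled, factor, achieved = rescale_to_coverage(
        dose3d, ctx.phantom.masks["ptv"], config.prescription,
        target=config.prescription.coverage_fraction, max_factor=max_factor)
    cov = coverage(scaled[ctx.phantom.masks["ptv"]], config.prescription)
    plan = replace(plan, weights=plan.weights * factor,
                   total_mu=plan.total_mu * factor)
    minutes = estimate_delivery(plan, config.delivery)
    m = plan_report(scaled, ctx.phantom, ctx.shells_eval, plan,
                    config.prescription, minutes)
    ok = cov >= 100.0 * config.prescription.coverage_fraction - 1e-9
    dmax = {name: float(scaled[ctx.phantom.masks[name]].max())
            for name in ("ptv",) + OAR_NAMES
            if name in ctx.phantom.masks and ctx.phantom.masks[name].any()}
    return ArmResult(plan, report, m, cov, factor, achieved, ok, dmax)


@dataclass
class PatientResult:
    index: int
    spec: PhantomSpec | None
    constraints: ShellConstraintSet | None = None
    pre: ArmResult | None = None
    auto: ArmResult | None = None
    fauto: ArmResult | None = None
    baseline: ArmResult | None = None
    error: str | None = None


@dataclass
class TransferResult:
    config: ExperimentConfig
    patients: list[PatientResult]
    fixed_constraints: ShellConstraintSet | None

    def constraints_table(self) -> pd.DataFrame:
        """Per-patient individualized shell Dmax values (cGy) with the
        population mean +/- SD row appended."""
        from .compare import aggregate_mean_sd
        rows, idx = [], []
        for p in self.patients:
            if p.constraints is None:
                continue
            rows.append({f"shell {d:g} cm [cGy]": p.constraints.dmax_cgy[d]
                         for d in p.constraints.distances_cm})
            idx.append(f"Pt {p.index + 1}")
        df = pd.DataFrame(rows, index=idx)
        summary = {}
        for col in df.columns:
            mean, sd = aggregate_mean_sd(df[col], round_to_int=True)
            summary[col] = f"{mean:g}+-{sd:g}"
        df.loc["Mean+-SD"] = summary
        return df

    def arm_metrics(self, arm: str) -> pd.DataFrame:
        rows, idx = [], []
        for p in self.patients:
            a = getattr(p, arm)
            if a is not None and a.metrics is not None:
                rows.append(a.metrics.to_series())
                idx.append(p.index)
        return pd.DataFrame(rows, index=idx)

    def unacceptable_fauto(self) -> list[int]:
        """Patients whose fixed-constraint plan misses coverage while
        their individualized plan is acceptable."""
        return [p.index for p in self.patients
                if p.auto is not None and p.auto.acceptable
                and p.fauto is not None and not p.fauto.acceptable]


def run_cohort_experiment(cohort: list[Phantom] | None = None,
                          config: ExperimentConfig = ExperimentConfig(),
                          progress: bool = False) -> TransferResult:
    """Full two-step workflow over a cohort.

    Per patient: lexicographic pre-plan, shell constraint extraction,
    individualized re-plan (AUTO) and no-shell baseline; then the
    population-mean constraints over all successful patients, and the
    fixed-constraint re-plan (fAUTO).  Stage failures are recorded per
    patient and the experiment continues.
    """
    if cohort is None:
        cohort = generate_cohort(config.n_patients,
                                 PhantomSpec(voxel_mm=config.voxel_mm),
                                 seed=config.seed)
    if len(cohort) < 2:
        raise ValueError("cohort experiment needs at least 2 patients")
    # aim-point seeds derive from the experiment seed and the phantom's own
    # seed, so identical patients get identical candidate beams
    aim_seeds = [
        np.random.SeedSequence(
            [config.seed,
             ph.spec.rng_seed if ph.spec is not None else i]
        ).generate_state(1)[0] % (2 ** 31)
        for i, ph in enumerate(cohort)]
    patients, contexts, lazies = [], [], []
    for i, ph in enumerate(cohort):
        pr = PatientResult(index=i, spec=ph.spec)
        ctx = None
        lazy: dict = {}    # binding max-dose rows, shared across re-plans
        try:
            ctx = build_patient_context(ph, config, int(aim_seeds[i]))
            # wish-list restricted to the structures this patient has
            wl = default_vs_wishlist(
                config.prescription,
                {k: v for k, v in config.oar_dmax_gy.items()
                 if k in ctx.structures},
                config.opt_distances_cm, config.relaxation)
            pre_plan, pre_rep = solve_lexicographic(ctx.im, wl,
                                                    ctx.structures,
                                                    lazy_rows=lazy)
            pr.constraints = extract_shell_dmax(pre_plan, ctx.im,
                                                ctx.shells_opt)
            pr.pre = evaluate_arm(pre_plan, pre_rep, ctx, config)
            auto_plan, auto_rep = plan_with_shell_constraints(
                ctx, pr.constraints, config.prescription,
                config.oar_dmax_gy, config.relaxation, lazy_rows=lazy)
            pr.auto = evaluate_arm(auto_plan, auto_rep, ctx, config)
            base_plan, base_rep = plan_baseline(ctx, config.prescription,
                                                config.oar_dmax_gy,
                                                config.relaxation,
                                                lazy_rows=lazy)
            pr.baseline = evaluate_arm(base_plan, base_rep, ctx, config)
        except Exception as e:                      # noqa: BLE001
            pr.error = f"{type(e).__name__}: {e}"
            warnings.warn(f"patient {i}: {pr.error}")
        patients.append(pr)
        contexts.append(ctx)
        lazies.append(lazy)
        if progress:
            cov = pr.auto.coverage_pct if pr.auto else None
            print(f"patient {i}: AUTO coverage "
                  f"{cov if cov is None else round(cov, 2)}")
    good = [p.constraints for p in patients if p.constraints is not None]
    fixed = population_mean_constraints(good) if good else None
    for pr, ctx, lazy in zip(patients, contexts, lazies):
        if ctx is None or pr.error is not None or fixed is None:
            continue
        try:
            f_plan, f_rep = plan_with_shell_constraints(
                ctx, fixed, config.prescription, config.oar_dmax_gy,
                config.relaxation, lazy_rows=lazy)
            pr.fauto = evaluate_arm(f_plan, f_rep, ctx, config)
        except Exception as e:                      # noqa: BLE001
            pr.error = f"fAUTO {type(e).__name__}: {e}"
            warnings.warn(f"patient {pr.index}: {pr.error}")
        if progress and pr.fauto is not None:
            print(f"patient {pr.index}: fAUTO coverage "
                  f"{round(pr.fauto.coverage_pct, 2)}"
                  f"{'' if pr.fauto.acceptable else '  (unacceptable)'}")
    return TransferResult(config=config, patients=patients,
                          fixed_constraints=fixed)
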