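# shellplan

Automated, individualized shell-constrained inverse planning for robotic
radiosurgery — at desk scale, on synthetic head phantoms.

## The problem

Stereotactic radiosurgery of benign vestibular schwannoma delivers a
single fraction of 12 Gy, prescribed at the 80 % isodose (in-target
maximum 15 Gy), to a small target (1–7 cc) adjacent to the brainstem and
cochlea. Patients live for decades after treatment, so the *dose bath*
(low-to-intermediate dose spread through normal tissue) and *dose spikes*
(fingers of high dose leaking from the target along beam directions)
matter for secondary-tumor risk — yet conventional planning optimizes
them only as far as planner time and patience allow.

`shellplan` implements a two-step automated workflow that makes dose
spillage a first-class optimization objective:

1. **Prioritized pre-optimization.** A wish-list drives lexicographic
   (ε-constraint) optimization of non-coplanar cone-beam weights: hard
   maximum-dose constraints (target ≤ 15 Gy, OAR bounds), then target
   coverage V12Gy > 98 % via a convex cold-tail-mean surrogate, then
   minimization of the maximum dose on shells at 1, 3 and 5 cm from the
   target (closest first), then monitor-unit economy. Every phase is a
   linear program over beam weights w ≥ 0 with dose d = A·w from a
   sparse influence matrix; solutions are Pareto-prioritized.
2. **Constraint transfer.** The achieved shell maxima are extracted as
   *individualized* Dmax constraints (integer cGy) and the patient is
   re-planned under them with a simpler deliverable objective stack
   (coverage to goal, then MU) — the step a clinical system would run
   from a planning template.

The package also runs the companion experiment: replace each patient's
individualized constraints with the population means ("fixed"
constraints, fAUTO) and measure what breaks; and it ships the complete
evaluation and paired-statistics apparatus (DVH, D2%, V_D, conformity,
rescaling to exactly 98 % coverage, exact Wilcoxon signed-rank tests,
percent-difference matrices).

## Worked example

One synthetic patient on a compact grid — generate, pre-optimize,
extract constraints:

```python
from shellplan import (PhantomSpec, generate_phantom, default_vs_wishlist,
                       solve_lexicographic, extract_shell_dmax)
from shellplan.transfer import ExperimentConfig, build_patient_context

spec = PhantomSpec(head_radii_mm=(50, 55, 50), voxel_mm=4.0,
                   ptv_volume_cc=2.9, ptv_brainstem_gap_mm=1.0, rng_seed=11)
phantom = generate_phantom(spec)
ctx = build_patient_context(phantom, ExperimentConfig(node_count=60),
                            aim_seed=5)
plan, report = solve_lexicographic(ctx.im, default_vs_wishlist(),
                                   ctx.structures)
for ph in report.phases:
    print(f"priority {ph.priority}  {ph.structure:<12} {ph.status:<12} "
          f"achieved {ph.achieved:.3f}")
cons = extract_shell_dmax(plan, ctx.im, ctx.shells_opt)
print("individualized shell Dmax [cGy]:", cons.dmax_cgy)
print(f"beams {plan.beam_count}, nodes {plan.node_count}, "
      f"MU {plan.total_mu:.0f}")
```

prints

```
priority 1  ptv          goal_reached achieved 12.000
priority 2  shell_1cm    optimal      achieved 2.759
priority 3  shell_3cm    optimal      achieved 1.099
priority 4  shell_5cm    optimal      achieved 0.772
priority 5  __total_mu__ optimal      achieved 1653.136
individualized shell Dmax [cGy]: {1.0: 284.0, 3.0: 113.0, 5.0: 79.0}
beams 42, nodes 35, MU 1653
```

Reading: the coverage surrogate reached its 12 Gy goal (so V12Gy > 98 %
before any rescaling); the hottest voxel 1 cm from the target was pushed
down to 2.76 Gy = 276 cGy, 1.10 Gy at 3 cm, 0.77 Gy at 5 cm (rounded to
284/113/79 cGy after the final MU phase spends its 3 % slip); the plan
uses 42 beams from 35 nodes. Those three cGy values are exactly what
step two re-imposes as this patient's hard shell constraints.

The same workflow from the shell:

```
shellplan phantom --volume-cc 2.9 --gap-mm 1.0 --seed 11 --out pt0/
shellplan plan --phantom-dir pt0/ --out plan0/
shellplan experiment --n 20 --seed 7 --voxel-mm 4.0 --out results/
```

On the default 20-phantom cohort (target volumes log-uniform on
1.0–7.3 cc, 4 mm grid, 179 nodes) the experiment reports: every
individualized plan acceptable (coverage ≥ 98 % with all OAR bounds
held), shell D2% at 1–7 cm below the no-shell baseline planner for 100 %
of (patient, shell) pairs, mean body V1Gy 119 cc vs 195 cc for the
baseline, and 6 of 20 patients whose fixed-constraint (fAUTO) plan falls
below 98 % coverage — population-mean shell constraints are too tight
for a substantial minority, which is the case for individualization.

## Layout

| module | contents |
|---|---|
| `shellplan.phantom` | seeded synthetic head phantoms and cohorts, NIfTI round trip |
| `shellplan.beams` | node sets, cone-beam kernel, sparse influence matrix |
| `shellplan.shells` | distance-transform shell bands (optimization and evaluation sets) |
| `shellplan.wishlist` | prescription, metrics, hard constraints, prioritized objectives |
| `shellplan.mco` | lexicographic LP solver, tail-mean surrogates, sparsification, shell-Dmax extraction |
| `shellplan.transfer` | step-two re-planning, fixed-constraint experiment, baseline planner |
| `shellplan.metrics` | DVH, D2%, V_D, coverage, conformity, exact rescaling |
| `shellplan.compare` | percent differences, exact/approximate Wilcoxon, cohort tables |
| `shellplan.reference` | the embedded 20-patient clinical shell-Dmax table |

See `docs/methods.md` for the model, conventions, and limitations.
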