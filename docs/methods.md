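# Methods

## Model structure

The model is a discrete-time Markov cohort simulation with 13 mutually
exclusive health states and a 1-year cycle. The living states are
Normal; DM (type-2 diabetes); PD at Hoehn–Yahr (H-Y) stages 1, 2, 3 and
4⁺; and PD comorbid with DM at the same four stages. Death is split
into three absorbing cause-specific states (PD, DM, other causes);
the split does not change costs or QALYs — death carries zero reward —
but it makes the 13-state count explicit and lets tests assert
cause-specific absorption separately.

Structural assumptions:

* PD progression is irreversible (no H-Y back-transitions) and incident
  PD always enters at H-Y 1; incidence and progression cannot happen in
  the same cycle.
* DM precedes PD: Normal can become DM or PD, DM can become PD+DM, but
  PD-only patients never acquire DM (the epidemiology of onset ages
  makes that pathway second-order, and the source analysis omits it).
* Background (other-cause) mortality applies to every living state, on
  top of DM mortality in diabetic states and H-Y-stage-specific PD
  mortality in PD states. Whether PD-stage mortality was meant as
  all-cause within PD states is not decidable from the source text; we
  chose the literal reading (background mortality everywhere). PD-stage
  mortality (0.010/0.048/0.080/0.199) is not age-dependent.
* Competing risks within a cycle combine as
  q = 1 − Π(1 − pₖ), allocated to causes proportionally to the
  constant-hazard weights −ln(1 − pₖ); a certain cause (pₖ = 1)
  absorbs everything. Disease onset and stage progression then apply to
  the survivors, all folded into a single row-stochastic matrix.
* The cohort is an expected-value (fractional-person) cohort of 1,000
  entering at age 40 with DM prevalence 0.0605; occupancies are never
  rounded.

## Parameters

Every input is a printed value of the source inventory: age-banded
annual incidences (PD, DM, PD-given-DM), age-banded DM and other-cause
mortality, stage-specific PD mortality, annual stage-transition rates
for PD (0.3237, 0.068, 0.3192) and PD+DM (0.4369, 0.1462, 0.3192),
treatment-effect multipliers, costs and utilities. Age bands are
inclusive-lower/exclusive-upper with an open top band. Parameters with
printed plausible ranges (51 of them) are registered for sensitivity
analysis; parameters without ranges are held fixed.

Decisions where the printed tables disagree with themselves:

* **Effect multipliers.** The treated-rate table's arithmetic implies
  m₁–m₃ = 0.947/0.239/0.206 while the input-parameter table lists
  0.981/0.245/0.214 (ranges 0.95–0.99 / 0.20–0.32 / 0.17–0.28). The
  base case uses the implied multipliers — they generate the treated
  rates actually printed — and the listed ranges serve as SA bounds.
  Since 0.947 falls below the listed low bound 0.95, the m₁ range is
  extended down to 0.947 so every range brackets its base value.
* **PD+DM treated λ₃.** The table prints 0.0210 with the annotation
  "= 0.3192 × 0.206", but that product is 0.0658 — the very value the
  PD-only row prints for the identical product. The default uses the
  arithmetic (0.0658); `use_printed_pddm_lambda3: true` restores the
  printed figure.
* **Derived treated columns.** Exenatide DM mortality is always
  recomputed as conventional mortality × 0.88 (reproducing the printed
  treated column at its 5 printed decimals), never sampled
  independently of its parents; the same holds for treated transition
  rates. Treated rates are kept unrounded internally and rounded to 4
  decimals only for display.
* **DM productivity loss** is listed for ages 40–69 only; it is set to
  0 from age 70 (retirement).

The inventory ships as a strict, versioned YAML/JSON schema
(`fixtures/published_defaults.yaml`); unknown or missing keys and
out-of-range values are load errors, because a silently misspelled
parameter would corrupt the analysis downstream.

## Rewards

Costs (NT$/yr, societal perspective, 2020 value as printed, no CPI
re-adjustment): Normal costs nothing; DM costs its age-banded medical
cost plus age-banded productivity loss; PD states cost stage-specific
medical care + home care (H-Y 3–4⁺) + stage-specific productivity
loss; PD+DM states use the PD+DM medical schedule (assumed to include
DM care; `pddm_cost_adds_dm_medical` adds the DM medical schedule on
top) plus home care, PD productivity loss and DM productivity loss.
The add-on arm additionally accrues NT$33,926.8/yr of drug cost in
every covered state.

Utilities: Normal is 0.92 (ages 40–64) / 0.84 (65+); DM subtracts 0.04
plus an annual decline of 0.003; PD states use stage utilities
0.708/0.678/0.622/0.499; PD+DM subtracts the DM decrement from the
stage utility; exenatide adds 0.08 in covered diabetic states. Values
are clamped to [0, 1]. The DM annual decline is applied by model time
(cycle index) rather than time-in-state, because a cohort model does
not track entry times; this slightly overstates the decline for
late-onset DM and can be switched off
(`dm_decline_by_model_time: false`).

Rewards accrue on start-of-cycle occupancy for cycles 0–49 and are
discounted at 3%/yr by (1+r)^(−t), identically for costs, LYs and
QALYs; undiscounted totals are reported alongside. No half-cycle
correction is applied by default (the source describes none);
`reward_timing: half_cycle` switches to adjacent-boundary averaging.

## Treatment arm and coverage

In the add-on arm, exenatide effects and cost apply to the DM, PD and
PD+DM living states from entry onward (treatment continues until
death). Covering DM-only patients is the reading most consistent with
the source — its tornado discussion singles out DM/normal utilities,
and DM-specific mortality and utility effects are listed — but it is
not stated outright, so `exenatide_coverage` is configurable. The
conventional arm applies no effect and no drug cost anywhere.

## Structural switches and calibration

Four things the source text under-determines are exposed as config
switches, with defaults chosen once:

| switch | default | alternative |
|---|---|---|
| `rate_conversion` | `exponential` (1 − e^(−λ)) | `identity` (min(λ, 1)) |
| `reward_timing` | `start` | `half_cycle` |
| `dm_cost_accrual` | `per_arm` | `equalized` |
| `exenatide_coverage` | dm, pd, pd_dm | any subset |

`dm_cost_accrual: equalized` charges the DM background cost stream
(medical + productivity) of the *comparator* arm to both arms, so the
arms differ only through drug cost and non-DM states. It implements
the source's statement that the two strategies were assigned the same
DM costs; the default keeps the standard cohort bookkeeping (each
arm's own occupancy), which is also the cleaner economic accounting.

Reproduction status, measured by this package's own runs: life
expectancy, QALY totals and the QALY gain land close to the published
values under the defaults (conventional arm 21.74 LY vs 21.75; QALY
gain 0.386 vs 0.39; conventional QALYs 19.25 vs 18.45). The published
cost quantities are internally inconsistent: every cost figure in the
published results table differs from the corresponding prose figure by
exactly 1.03⁴ ≈ 1.1255 (e.g. incremental cost 104,744 vs 117,890),
i.e. a four-year discounting/base-year offset, while the QALY figures
agree. Our conventional-arm total cost matches the prose-scale value
within 2%. The incremental cost decomposes into drug cost
(NT$124.9k = 3.68 discounted treated person-years × 33,926.8) plus
survival-driven DM costs (NT$41.7k); the published increment is
consistent with pure drug cost on ~3.5 person-years and no
survival-cost component (the `equalized` mode, which yields
NT$125.2k). No combination of the switches reaches the published
table-scale increment of NT$104,744; the corresponding acceptance test
is left failing rather than tuned. Every switch combination classifies
the add-on as very cost-effective (ICER well below GDP per capita),
which is the decision-relevant conclusion.

## Sensitivity analyses

* **One-way (tornado).** Each of the 51 ranged parameters is pushed to
  its printed low and high bound with everything else at base; the full
  pipeline is re-run and entries are sorted by ICER-excursion width
  (ties alphabetically). Excursions are applied to copies, so the sweep
  is side-effect-free. A bound excursion may cross a neighbouring
  stage's base utility; the cross-stage monotonicity rule is enforced
  on full parameter sets, not on one-way excursions.
* **Probabilistic (PSA).** Each of 1,000 iterations draws every ranged
  parameter independently and uniformly from its bounds (the source
  names no distribution), recomputes derived quantities, and runs both
  arms. Joint draws that violate cross-parameter coherence (the H-Y
  utility ranges overlap, so independent draws can invert the stage
  ordering) are redrawn and counted. The CEAC reports the fraction of
  iterations with positive NMB over a WTP grid (default 0–3× GDP per
  capita); the ICER plane reports per-iteration (ΔE, ΔC) with quadrant
  counts. Everything is reproducible given the seed.
* **Scenarios.** (1) Exenatide reduces PD incidence among treated DM
  patients by 30% — the value behind the published scenario results;
  the source's methods text says 20%, which remains available. (2)
  Early-stage efficacy: the stage-2→3 effect multiplier replaces the
  stage-1→2 multiplier and the treated λ₁ values are re-derived
  (the strongest reading of "replace the 1→2 rate with the 2→3 one").

## Verification strategy

The cohort engine is checked three ways: against exact geometric-series
closed forms on a two-state constant-hazard toy model (agreement to
1e-10); against an individual-level microsimulation that samples
trajectories from the same per-cycle matrix rows and accrues the same
rewards (agreement within 3 Monte-Carlo standard errors on the default
inventory and on 20 random sets from the plausible ranges; 20,000–60,000
individuals per run keep each comparison under a second); and against
structural invariants (cohort-mass conservation to 1e-9,
row-stochasticity to 1e-12, death absorption, H-Y irreversibility,
zero-discount equivalence, exact linearity of ΔC and ICER in a global
cost scaling, QALY ≤ LY).

The microsimulation shares the transition probabilities with the cohort
engine by construction, so these tests validate propagation and
accrual, not the probability construction itself; the latter is pinned
by the table-driven parameter tests and the closed-form competing-risk
examples.

## What the default inventory does and does not emulate

The shipped parameter set is the published inventory of a Taiwanese
population model: community screening incidences, NHIRD-derived costs
and mortality, Japanese H-Y utilities. Passing tests show the pipeline
reproduces that model's arithmetic and its decision conclusion; they do
not validate the underlying epidemiology, generalise beyond Taiwan, or
capture DM complication costs, medication non-adherence, DM onset after
PD, or DM severity — all outside the model's scope by design.

## Known limitations

* The published incremental-cost figures cannot be reproduced at table
  scale under any documented switch combination (see calibration above);
  the discrepancy is documented rather than fitted.
* PSA draws are independent uniforms; correlations between parameters
  (e.g. across age bands of one table) are not modelled.
* The per-iteration redraw of incoherent utility draws truncates the
  joint distribution slightly toward monotone stage orderings. Together
  with the model's convexity in the discount rate and mortalities this
  biases PSA means ≈5% above the deterministic run at range mid-points,
  so the mean-convergence check carries a 10% relative tolerance rather
  than a pure Monte-Carlo (3 SE) one.
* The PD-only variant of the analysis (without the DM pathway) is not
  modelled; its structure is not described in the source.
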