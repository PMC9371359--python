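# pdcea

Markov cohort cost-effectiveness analysis of **add-on exenatide** versus
conventional pharmacotherapy for **Parkinson's disease (PD) when type-2
diabetes mellitus (DM) co-occurs**, from a societal perspective in
Taiwan (costs in NT$, 2020 value).

Exenatide, a GLP-1 agonist used in type-2 diabetes, slows PD progression
in randomised trials, and pre-existing DM raises both the incidence and
the progression rate of PD. This package implements the decision model
that weighs the drug's cost against the quality-adjusted life years
(QALYs) it buys in a population carrying both risks, for health
economists and modellers who want a fully scripted, testable version of
that analysis.

## Model

A 13-state discrete-time Markov cohort model with 1-year cycles:

* **Normal**, **DM**, four PD states by Hoehn–Yahr stage (HY1–HY4⁺),
  four PD+DM states by stage, and three absorbing cause-specific death
  states (PD, DM, other causes).
* A cohort of 1,000 enters at age 40 (DM prevalence 0.0605) and is
  propagated 50 cycles. PD progression is irreversible; DM precedes PD;
  incident PD enters at HY1.
* Stage progression uses annual transition rates λ₁–λ₃ converted to
  probabilities (default p = 1 − e^(−λ)); exenatide multiplies the rates
  by m₁–m₃ = 0.947/0.239/0.206, multiplies DM mortality by 0.88, and
  adds 0.08 utility in diabetic states.
* Within a cycle, cause-specific deaths compete
  (total = 1 − Π(1 − pₖ), allocated by constant-hazard weights), then
  disease onset/progression occurs among survivors.
* Costs (drugs, PD/DM medical care, home care, productivity losses) and
  utilities accrue on start-of-cycle occupancy, discounted at 3%/year.
  Strategies are compared by incremental cost-effectiveness ratio
  ICER = ΔC/ΔE and net monetary benefit NMB = WTP·ΔE − ΔC against the
  WHO willingness-to-pay threshold of one GDP per capita (NT$839,558).

One-way (tornado), probabilistic (1,000 Monte-Carlo draws, CEAC, ICER
plane) and scenario sensitivity analyses are included, plus two
independent oracles (closed-form toy models and an individual-level
microsimulation) that must agree with the cohort engine.

## Worked example

```python
from pdcea import published_defaults, run_base_case

conv, exe, inc = run_base_case(published_defaults())
print(f"conventional: {conv.ly:.2f} LY, {conv.qaly:.2f} QALY, NT${conv.cost:,.0f}")
print(f"add-on:       {exe.ly:.2f} LY, {exe.qaly:.2f} QALY, NT${exe.cost:,.0f}")
print(f"dQALY {inc.delta_qaly:.3f}  dCost NT${inc.delta_cost:,.0f}  "
      f"ICER NT${inc.icer_per_qaly:,.0f}/QALY  [{inc.classification}]")
```

prints

```
conventional: 21.74 LY, 19.25 QALY, NT$1,754,932
add-on:       21.87 LY, 19.63 QALY, NT$1,921,434
dQALY 0.386  dCost NT$166,502  ICER NT$431,763/QALY  [very cost-effective]
```

Per person over the 50-year horizon, add-on exenatide yields 0.386 extra
discounted QALYs for NT$166,502 extra discounted cost; at
NT$431,763/QALY the ICER sits well below GDP per capita, so the add-on
classifies as very cost-effective under the WHO rule. See
`docs/methods.md` for how these figures relate to the published ones and
which structural switches move them.

The same pipeline is available from the shell:

```bash
pdcea run --out results/
pdcea tornado --out results/
pdcea psa --iterations 1000 --seed 1 --out results/
pdcea ceac --iterations 1000 --seed 1 --out results/
pdcea scenarios --out results/
```

Each command writes CSV/JSON artifacts and a run manifest; runs are
reproducible given the config (and seed, where stochastic).

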