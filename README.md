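# abfekit

Adaptive alchemical absolute binding free-energy (ABFE) protocols and
disorder–order population cycles, with synthetic sampling backends that
carry exact analytic ground truth.

## The problem

Absolute binding free-energy calculations decouple a ligand from its
environment along a ladder of alchemical λ windows, once in the protein
site and once in solution, and recover ΔG° of binding from the two legs
plus restraint bookkeeping. When the ligand sits against a flexible,
partially disordered protein region, a handful of λ windows — typically
where Lennard-Jones interactions are partially decoupled — relax far more
slowly than the rest, and allocating equal sampling to every window wastes
most of the budget. `abfekit` implements an adaptive protocol: replicated
sampling proceeds in fixed epochs, the free-energy change of each
neighbouring window pair is estimated with MBAR/BAR after every epoch, and
pairs whose across-replicate spread has dropped below a threshold τ stop
sampling while noisy pairs are carried forward. The same package provides
the downstream analysis that motivates such calculations for
disorder-to-order transitions: a binned 2D free-energy surface over
collective variables with macrostate populations, and the two-state
thermodynamic cycle that converts macrostate-resolved binding free
energies into ligand-induced population shifts of a protein
disorder–order equilibrium — the mechanism by which a ligand such as a
potent MDM2 piperidinone can fold an intrinsically disordered "lid" upon
binding while another ligand leaves it disordered.

Everything is exercised end to end on synthetic backends (harmonic window
ladders with AR(1) "slow" windows; exactly sampleable two-basin 2D
surfaces) whose free energies are known in closed form, so unbiasedness,
resource savings and calibration are tested against truth rather than
against another simulation.

For whom: method developers and students of alchemical free-energy
protocols who want a compact, fully testable implementation of
MBAR-driven per-window convergence control and the associated
thermodynamic-cycle analysis.

## Core quantities

- MBAR self-consistency: `f_k = -ln Σ_n exp(-u_kn) / Σ_l n_l exp(f_l - u_ln)`
  over reduced potentials `u_kn`; BAR is the K = 2 case.
- Adaptive rule: pair (i, i+1) retires when the standard deviation of its
  MBAR/BAR free-energy change across n = 5 replicates drops to
  τ = 0.100 kcal/mol; both windows of a live pair stay active.
- Assembly: `ΔG°_bind = ΔG_free − ΔG_bound − ΔG_restraint_on − ΔG_ss`, with
  the Boresch standard-state term
  `ΔG_ss = −RT ln[8π²V°√(Πk_i)/(r0² sinθA0 sinθB0 (2πRT)³)]`.
- Two-state cycle: `p_ordered = σ(−ΔG_conf/RT)` (logistic), with
  `ΔG_conf,complex = ΔG_conf,apo − (ΔG_bind,dis − ΔG_bind,ord)`.

## Worked example

A ligand with a 3 kcal/mol preference for the ordered lid macrostate,
binding a protein whose apo ordered state sits 1.5 kcal/mol uphill:

```
$ abfekit cycle --dg-conf-apo 1.5 --dg-ordered -13.0 --dg-disordered -10.0
```

prints (columns abridged):

```
preference  p_ordered_apo         p_ordered_apo_pct  p_ordered_complex   p_ordered_complex_pct  dG_bind_apparent
3.0         0.07366451197130039   7                  0.9263354880286996  93                     -11.5
```

i.e. the apo ordered state is populated at ~7%, and the ligand's
preference flips the complex to ~93% ordered — a conformational-selection
population shift. With a 0.5 kcal/mol preference instead, the complex
only reaches ~16% ordered. The apparent ΔG° (−11.5 kcal/mol here) is the
population-weighted affinity an experiment like ITC would see. ITC-style
bookkeeping is available directly:

```
$ abfekit itc --kd 5e-12 --dh -20.9
kd_M    dG_kcal_mol          dH_kcal_mol  minus_TdS_kcal_mol  temperature_K
5e-12   -15.417363375832577  -20.9        5.482636624167421   298.15
```

(a 5 pM binder costs −15.4 kcal/mol at 298.15 K; binding is enthalpy
driven with an entropic penalty). The protocols run from a config file:

```
$ abfekit run-adaptive --config cfg.yaml --out run/
$ abfekit run-static   --config cfg.yaml --out run_ref/
```

emitting per-epoch convergence profiles (TSV), epoch records (JSON) and
the assembled ΔG° with its replicate spread. On the default 76-window
synthetic ladder with two slow windows, the adaptive run retires most
pairs after the 2-epoch guard and concentrates sampling on the slow
windows, using ~4–5× fewer samples than the 10-epoch static reference at
a statistically indistinguishable estimate (tested over 50 seeds).

Library use mirrors the CLI: `MBAR(table).fit()`, `bar_pair(table)`,
`run_adaptive(config, ladder_spec)`, `UmbrellaPMF(cvs, e1, e2).fit()`,
`macrostate_population(grid, mask)`, `CycleSpec(...)` /
`complex_population(spec)`.

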