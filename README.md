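# simmkit

Bistable switch motifs for cell-cycle transitions: mass-action ODE models,
saddle-node (fold) detection, control-plane mapping and checkpoint scenarios.

## The problem

Cell-cycle transitions (Start, G1/S, G2/M, metaphase-to-anaphase) are guarded
by pairs of an **activator** (a cyclin-dependent kinase, or the
anaphase-promoting complex APC) and an **inhibitor** that stalls it (a CKI
such as Sic1, or the mitotic checkpoint complex MCC). In the recurring wiring
pattern modelled here, the inhibitor is simultaneously

1. a **stoichiometric inhibitor** - it binds the activator tightly and
   sequesters it, and
2. a **multiply modified substrate** - the activator modifies it in two or
   more distributive steps (multi-site phosphorylation of Sic1,
   poly-ubiquitination of the MCC's Cdc20 subunit), and the hyper-modified
   form no longer binds.

This double-negative feedback loop (SIMM: substrate-inhibitor, multiply
modified) makes the transition a one-way toggle: two stable steady states,
checkpoint **engaged** (activator sequestered) and **disengaged** (activator
free), separated by an unstable state. Moving the totals across a saddle-node
(fold) threshold flips the switch, and returning them does not flip it back.

## The core model

For the basic motif with enzyme A and inhibitor I, all steps are elementary
mass action (A and I are present at comparable concentrations, so
Michaelis-Menten rate laws are not valid):

```
A + I  <->  A:I   ->  A + IM      (k_as1, k_di1, k_cat1)   tight, slow
A + IM <->  A:IM  ->  A + IMM     (k_as2, k_di2, k_cat2)   weak, fast
IM -> I,   IMM -> IM              (k_dm1, k_dm2)           de-modification
```

with conservation `A_T = A + [A:I] + [A:IM]` and
`I_T = I + [A:I] + IM + [A:IM] + IMM`. Because
`K_m2 = (k_di2 + k_cat2)/k_as2 = 1.02 U` is two orders of magnitude above
`K_m1 = 0.01 U`, the second modification can be collapsed to a single
bimolecular step `A + IM -> A + IMM` at
`k_m = k_cat2 k_as2/(k_cat2 + k_di2)` (the SIMM\* motif), and the tight
complex can be eliminated with the total quasi-steady-state approximation
(TQSSA), leaving a two-variable phase plane in the functional inhibitor
`I_hat = I + [A:I]` and `IMM`.

Six ready-made instantiations ship with their published rate-constant
catalogues (concentrations in U ~ 10 nM, time in T ~ 1 min): `simm`,
`simm_star`, the TQSSA reduction, the budding-yeast G1/S switch (`sic_clb`,
`cln_sic_clb`) and the mitotic checkpoint (`mcc_apc`, `cycb_mcc_apc`). The
APC and Mad2 totals of the mitotic models default to 1 U and 2 U - they are
not part of the published catalogue and were reconstructed to reproduce the
published thresholds; see `docs/methods.md`.

## Worked example

Steady states of the basic motif at its neutral point (`A_T = 1`, `I_T = 4`):

```
$ simmkit roots -m simm
I            I_M        I_MM       C          C_M      residual  max_re_eig stable degenerate label
2.406603722  0.4969...  0.1005...  0.9938...  0.0020.. 5.829e-16 -0.595459  1      0          engaged
0.060719...  0.4064...  2.6667...  0.8128...  0.0533.. 8.771e-15  0.829665  0      0          intermediate
0.002819...  0.1020...  3.6187...  0.2040...  0.0723.. 5.621e-15 -0.375812  1      0          disengaged
```

Three roots: the engaged state (almost all enzyme locked in the tight A:I
complex, free-A fraction 0.004), the disengaged state (free-A fraction 0.72)
and the unstable separatrix between them - the signature of a bistable
checkpoint. Sweeping `I_T` downward at `A_T = 1`,

```
$ simmkit sweep -m simm --set A_T=1 --symbol I_T --range 1.5:4.0 --out sweep.tsv
```

locates the fold at `I_T = 2.423` where the engaged branch disappears
(threshold for checkpoint release); sweeping `A_T` upward at `I_T = 4` gives
the companion fold at `A_T = 1.637`. For the mitotic checkpoint,

```python
from simmkit import get_preset, build_mcc_apc, find_threshold, mitotic_release_in_vitro

params = get_preset("mcc_apc")
model = build_mcc_apc(params)
find_threshold(model, params, "X_tens", "up", (0.0, 1.0)).value  # 0.957
r = mitotic_release_in_vitro(params)
r.transition_time, r.final_label                                 # (46.7, 'disengaged')
```

the engaged branch survives until the fraction of centromeres under spindle
tension exceeds 0.957 - a single misaligned chromosome among ~25 holds the
checkpoint - and after tension appears everywhere at once, release takes a
46.7 T lag while the excess of functional MCC is poly-ubiquitinated.

Models round-trip through a restricted XPPAUT dialect
(`simmkit export-ode -m simm --out simm.ode`), and time-course scenarios for
the yeast G1/S cycle and mitotic-checkpoint release run via
`simmkit scenario {g1s,invitro,invivo}`.

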