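# Methods

`capnet` models steady-state two-phase (red-blood-cell + plasma) flow and
contrast-microbubble transport in an arteriolar tree of rat skeletal muscle,
together with the derivation chain that turns intravital video microscopy
(IVVM) measurements of single capillaries into hemodynamic quantities. Its
purpose is to ask one question quantitatively: can a redistribution of
arteriolar flow — less diameter asymmetry at bifurcations plus a higher
driving pressure, as seen under euglycemic hyperinsulinemia — raise the
number of contrast microbubbles in the capillary bed *without* opening any
new capillaries?

## Constitutive laws (`rheology`)

Three empirical laws of microvascular blood flow, in the in vivo
Pries-type formulation, with all constants in `RheologyParams`:

* **Apparent viscosity** `eta_rel(D, HD)`: relative to plasma, as a function
  of diameter D (um) and discharge hematocrit HD. The `(D/(D-1.1))^2`
  factors fold in an effective endothelial surface layer; the law's domain
  is D > 3 um.
* **Fahraeus effect** `HT/HD = HD + (1-HD)(1 + 1.7 e^{-0.415D} - 0.6 e^{-0.011D})`.
  Because RBCs ride the fast centerline, the volume-averaged (tube)
  hematocrit HT is below the flow-averaged (discharge) hematocrit HD. At
  HD = 0.42 this gives HT = 35.6% in a 75-um arteriole and 29.5% at 11 um.
  The ratio has its minimum near 12 um and rises back toward 1 in large
  vessels; the inverse map (needed to recover HD from a measured capillary
  HT) is evaluated by bracketed Brent root-finding to 1e-12 in HD.
* **Phase separation** at a diverging bifurcation: the RBC flux fraction
  into a daughter is a logit-linear function of its blood flow fraction
  FQB, with intercept A (favoring the narrower daughter), slope
  B = 1 + 6.98(1-HD)/Df, and a zero-flux cutoff X0 = 0.964(1-HD)/Df below
  which a branch receives plasma but *no* cells. The form is antisymmetric,
  so complementary daughters always sum to one (cell conservation is exact
  by construction).

## Network generation (`netgen`)

The generator is constraint-driven, not a reconstruction of measured
morphometry. It separates three ingredients:

1. **Topology.** Exactly `n_terminals_target` (default 214) terminals; at
   every node the terminal count is split by a seeded Beta(`topology_skew`,
   `topology_skew`) fraction (default 8), giving variable path depths —
   terminals are reached after different numbers of bifurcations depending
   on the flow path, as in real trees — and hence a wide terminal flow
   spectrum (about 1.5 decades between extremes at the default skew).
2. **Flow-balanced reference diameters.** Daughter cross-sections obey
   `Da^2 + Db^2 = gamma * Dp^2`; the daughter ratio at each bifurcation is
   calibrated, using the flow solver itself, so that the *zero-asymmetry*
   network splits blood flow exactly 50:50 everywhere. This is a functional
   statement of Murray-like sizing — vessels are proportioned to the demand
   they feed — and it makes the flow distribution respond to diameter
   asymmetry rather than to accidents of subtree shape. `gamma` (default
   search lands near 1.25) is bisected so the mean terminal diameter hits
   11 um from the 75-um root.
3. **Asymmetry.** Each bifurcation's daughter ratio is perturbed by a
   folded-normal draw of random sign (sd/mean = 0.35), with the network
   mean pinned exactly to the requested value: 0.07 for the baseline (BN)
   network, 0.055 for the simulated-hyperinsulinemia (SHI) variant.
   "Asymmetry" throughout means this relative daughter-diameter difference
   in excess of the flow-balanced reference ratio; for a balanced-reference
   bifurcation it reduces to `|Da-Db| / mean(Da, Db)`.

`rescale_asymmetry` produces the SHI tree from the BN tree by scaling every
perturbation by 0.055/0.07, preserving topology, reference ratios, and
segment lengths — a paired within-network intervention. The implied
diameter changes are second order: total vascular volume changes by ~0.3%
(well under 1%).

Segment lengths are `length_per_diameter x D` with the ratio (13.66) a
calibration constant (below). The default network and its seed (20190) are
a *frozen reference realization*: the calibrated constants belong to this
network the way a study's results belong to its one measured morphometry.
Re-drawing the topology shifts, for example, the baseline zero-bubble
fraction by several points.

## Flow solution (`flow_solver`)

Boundary conditions are a fixed pressure drop between the inlet and *all*
terminal outlets (12 mm Hg BN, 18 mm Hg SHI) and inlet discharge hematocrit
0.42. On a tree with equal outlet pressures the linear subproblem is solved
exactly by series-parallel collapse (no sparse solver, no truncation
error). The nonlinearity — viscosity depends on hematocrit, hematocrit
redistribution depends on flow — is handled by damped fixed-point
iteration (under-relaxation 0.5 on HD; the phase-separation cutoff makes
the undamped map oscillate), converged when the largest relative change in
segment HD and flow is below 1e-8 (typically ~20 sweeps). A final exact
propagation pass guarantees blood and RBC conservation at every node to
machine precision in the reported state. Convergence criteria and damping
are this package's choices; nothing in the modelled physics prescribes
them.

Useful checks forced by the physics: flows scale exactly linearly with the
pressure drop while all hematocrits and splits are invariant; the
flow-weighted mean discharge hematocrit over terminals equals the inlet
value exactly; tube hematocrit falls from 35.6% at the root to a terminal
mean of ~28.2% (the paired SHI solve leaves the terminal mean essentially
unchanged while narrowing its spread).

## Microbubble transport (`microbubble`)

Microbubbles are ~1:6000 as numerous as RBCs, so they are modelled as an
expectation flux, not discrete particles. The inlet rate is set by the
capillary bed's RBC demand: 2.2e4 capillaries x 12 RBC/s = 2.64e5 RBC/s,
divided by 6000 = 44 bubbles/s for the baseline network. Because the
bubble:RBC ratio is a property of the infused blood, the SHI inlet rate
scales with the solved inlet RBC flow (x1.48).

At bifurcations wider than 30 um bubbles partition exactly like RBCs.
Below 30 um they are *more* preferential, reflecting rigid-sphere
exclusion from the near-wall plasma layer. The small-vessel law keeps the
RBC logit form with three changes, all frozen after a one-time calibration
(below): the zero-flux cutoff is pinned to the 30-um threshold scale
(`cutoff_inflation` = 23.44 times the RBC cutoff evaluated at the
threshold and reference hematocrit 0.42) instead of growing as 1/Df; it
scales with the local plasma fraction as `((1-HD)/0.58)^0.5`
(`hd_sensitivity` = 0.5), so plasma-rich low-flow paths exclude bubbles
more strongly; and the logit slope carries a gain (`slope_gain` = 0.3 on
B; the effective midpoint slope in flow-fraction space remains much
steeper than the RBC law's because the admissible band is so narrow).
Zeros are exact — the cutoff yields true zero flux, so "no microbubbles"
needs no epsilon.

Per-segment resident counts are flux x transit time (length / bubble
velocity); the bubble velocity defaults to the RBC velocity (centerline
bias), with a blood-velocity alternative switchable. The capillary census
distributes the 2.2e4 capillaries uniformly over the terminals (102.8
each), splits each terminal's blood and bubble flux equally among its
capillaries, and computes per-capillary residence with the same
flux-x-transit rule at the capillary diameter.

### Calibration, frozen once against baseline statistics only

Four constants were fit to four *baseline* observables, then frozen before
any SHI quantity was read off:

| constant | value | baseline target |
|---|---|---|
| `cutoff_inflation` | 23.44 | 60% of terminals with zero bubble flux |
| `slope_gain`, `hd_sensitivity` | 0.3, 0.5 | 4.7% of terminals carrying > 1 bubble/s |
| `length_per_diameter` | 13.66 | 31.5 bubbles resident in the arteriolar tree |
| capillary length (at 4.5 um diameter) | 706 um | 178 bubbles resident in the capillary bed |

The 706-um "capillary length" is an effective path length through the
capillary network from terminal arteriole to venule, not an anatomical
single-capillary length. With these frozen, the SHI run is a prediction:
19.2% zero-bubble terminals, a 108% increase in terminals carrying
bubbles, arteriolar residents essentially unchanged (31.8), and capillary
residents up 23% (218). The mechanism is visible in the numbers: the
bubble flux moves into slower, previously bubble-free flow paths whose
transit times are long, so capillary residency rises even though every
capillary carried RBCs and plasma in both conditions.

## IVVM derivation chain (`ivvm`)

From frame-wise RBC velocity (mm/s) and lineal density (RBC/mm) plus the
capillary diameter: tube hematocrit = lineal density x 65 um^3 (rat RBC
volume) / lumen volume per mm; supply rate = mean over frames of
velocity x density (the frame-wise product is kept because the two
covary); discharge hematocrit by Fahraeus inversion at the capillary
diameter; blood velocity = (HT/HD) x RBC velocity; plasma velocity from
`v_blood = HT v_RBC + (1-HT) v_plasma`; flows in pL/s assuming circular
cross-sections, with `Q_blood = Q_RBC + Q_plasma` holding identically.
Hemoglobin O2 saturation comes from the 442/454-nm optical-density ratio
under an affine calibration that must be supplied (the in vivo calibration
constants are instrument-specific; synthetic data uses the identity).

Flow-state classification of a 30-s signed velocity trace: *stopped* if
stationary throughout (|v| <= 0.005 mm/s, about a tenth of a pixel per
frame at usual magnifications); *intermittent* if any shorter stationary
spell or any direction reversal; *continuous* otherwise. Functional
capillary density is capillaries crossing a reference line per mm of line.

Group statistics follow the paired design: per-variable paired t tests,
percent changes, and capillary-level OLS of percent flow change on
baseline flow (RBC and plasma separately) with a Wald-Wolfowitz runs test
on the residuals.

## Synthetic studies (`synth`)

The generator emulates the *shape* of a paired clamp experiment: 8 animals
x 10 fields x 3 capillaries, each measured at baseline and clamp at 21
frames/s for 30 s. Baseline latents are lognormal across capillaries
(velocity mean 0.15 mm/s, tube hematocrit mean 0.17, CV 0.45 — the paper
class of studies reports group SEs, not between-capillary variances, so
the CV is an assumption); diameters uniform on 3.5-5.5 um; flow states
drawn 85/10/5% continuous/intermittent/stopped with traces built to match.
Clamp values are generated *conditionally on baseline* (the paired
structure): a velocity multiplier with mean 1.49, and an RBC-flow
multiplier whose mean percent change declines with baseline flow
(-120%/(pL/s) around the expected baseline flow, mean x1.80) — low-flow
capillaries gain the most, i.e. redistribution. Observed frames are latent
x independent 10% jitter.

Two caveats are inherent, not bugs. First, velocity x1.49 and RBC flow
x1.80 with strictly unchanged hematocrit are mutually inconsistent
(flow = velocity x density x cell volume); the generator honors the two
flow-side multipliers, so the implied per-capillary hematocrit shifts by
~20% on average. Second, the hematocrit shift leaks a weak dependence into
the plasma-flow percent-change regression (slope an order of magnitude
smaller than the RBC-flow slope, r^2 ~ 0.04); the programmed contrast —
strong negative RBC-flow dependence, near-zero plasma dependence — is
recovered. Zero-noise configurations reproduce latents through the full
derivation chain to 1e-9, and at default noise the programmed velocity
multiplier and the negative slope are recovered within the 95% CI across
100 seeded replicates.

What passing these tests does *not* show: the generator contains no
optics, no motion artifacts, no segmentation errors, no within-field
spatial correlation, and its noise model is stationary — agreement on
synthetic data demonstrates the derivation chain's correctness, not
robustness to real video.

## Problem sizes and determinism

The default network (427 segments) solves in well under a second; the full
paired workflow including tree generation and reference calibration runs
in ~15 s. All randomness flows from explicit integer seeds; identical
seeds give byte-identical serialized networks and datasets. The reported
model numbers are deterministic functions of the frozen reference network
and calibration.

## Known limitations

* Diverging tree only: no venules, no converging bifurcations, no
  capillary network topology; the capillary bed enters only through the
  uniform census.
* Steady state: no pulsatility, compliance, regulation, or oxygen
  transport.
* The small-vessel bubble law is a calibrated phenomenological form chosen
  to express "more preferential than RBCs below 30 um"; its constants are
  tied to the frozen reference network realization.
* Bubble fluxes are expectations; no stochastic single-bubble transit or
  acoustic destruction/replenishment physics.
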