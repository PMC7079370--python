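# Methods

## The agent model

A single osteoblast is three nested concentric spheres: nucleus (radius
2), cytoplasm (radius 5) and an extracellular shell (radius 7, arbitrary
micrometre-like units; only ratios to the interaction range matter).
Every molecule is an agent with a species, an activation flag, a bound
partner and a position. Mobile agents take isotropic Gaussian steps
(default 0.5 length units per 1 s step) with radial reflection at the
walls of the shell their species may occupy; integrins are static on the
cell surface. A binding rule lets a seeker query all molecules within
*R*<sub>inter</sub> (default 1.0 at full counts) and react with the nearest
eligible one; each agent participates in at most one binding per step, and
conflicts are resolved in a seeded random permutation order — the first
claimant wins and the loser skips the step. Timer-driven rules
(state transitions, complex dissociations, production, degradation) arm a
clock drawn uniformly on `[0, 2T]` when an agent enters a label with
applicable rules; uniform supports make the population's dissociation
times uniformly distributed, the bookkeeping view of a Poisson decay.
When several timed rules apply, each is sampled and the earliest wins.

Two dissociation routes exist, mirroring the two ways a complex can end:
the complex's own clock fires (e.g. the RAF:MEK complex matures, MEK
activates and breaks away, RAF is released still active), or a personal
activation-cycle clock of one member fires and the state-changed molecule
breaks the complex up (e.g. RAF deactivating mid-complex aborts it).
Personal clocks persist across binding and release rather than resetting,
so a molecule's active lifetime is not rejuvenated by rebinding.
Alternative semantics (suspending or deferring personal clocks while
bound) were evaluated and discarded: both let long-timer complexes
accumulate without turnover and wash out the slow-timer waiting-time
structure the model is meant to exhibit.

### Network skeleton

The default network is a documented skeleton of the mechanotransduction
cascade: load-driven integrin activation; integrin-contact activation of
RAF; RAF:MEK complex formation and timed MEK activation; MEK:ERK complex
with two competing outcomes (ERK activation vs unproductive relaxation);
ERK-driven RUNX2 phosphorylation; and a transcription/translation tail
(active RUNX2 produces mRNA; a ribosome translates each transcript once,
packaging the product into a vesicle that matures into extracellular
matrix protein; transcripts are cleared). The initial 8890 agents are
split integrin-heavy with balanced MAPK pools (integrin 2000, RAF 1200,
MEK 1500, ERK 1500, RUNX2 800, ribosome 1500, vesicle 200, ECM protein
190); the split and every timer are configuration, not constants.

The six swept ACS timer means default to
`T_RAFact+MEKd->MEKact` = 90 s, `T_MEKact->MEKd` = 90 s,
`T_MEKact+ERKd->ERKact` = 10 s, `T_MEKact+ERKd->MEKact` = 90 s,
`T_ERKact->ERKd` = 90 s, `T_ERKact+RUNX2d->ERKact` = 10 s. These
baselines were chosen (once) so the baseline model shows the qualitative
fingerprints the analysis is designed to expose — a bimodal RAF:MEK
waiting-time density at fast activation timers and a persistent complex
pool at slow ones; they are the package's own defaults, exposed in full
in the configuration schema. Auxiliary timers: integrin deactivation
50 s, RAF deactivation 90 s, RUNX2 deactivation 300 s, transcription
2000 s, translation 300 s, secretion 200 s, transcript decay
2000/300 s.

### Load coupling

The square wave has magnitude *M* for the first half-period and baseline
m₀ = 100 µPa for the second, phase 0 (high first, 50% duty). An inactive
integrin activates per step with probability
k·(load − m₀)/(M<sub>ref</sub> − m₀), k = 0.05 at M<sub>ref</sub> = 10,000 µPa — zero
exactly at baseline (the switch contract) and saturating most integrins
within ~100 s at the reference magnitude.

### Count rescaling

`apply_scale(config, s)` multiplies every initial count by `s` (rounding
half-up) and *R*<sub>inter</sub> by `s^(-1/3)`, keeping `n·R³` — the expected
number of potential partners inside an interaction sphere — constant, so
the average binding kinetics survive the thinning. Collective features
do not all survive: the ERK:MEK upper waiting-time mode (below) needs
the full molecule count.

## The inversion pipeline

Defaults for 1 s count series: τ₁ = 50 s (forward moving-average
de-trending window; long enough to pass the sub-minute fluctuations and
short enough to track the load response), τ₂ = 10 s (local second-moment
window), Epanechnikov kernel with bandwidth w = 2.5 s on a 0.25 s grid
(the kernel must bridge the 1 s spacing of integer SIPs or the density
degenerates into a comb; w ≈ 2.5·dt is the smallest bandwidth that
smooths the discretisation), reflection at τ = 0. The synthetic-signal
experiments, sampled at dt = 0.1 s, use τ₁ = 20 s, τ₂ = 1 s and
w = 0.5 s.

The de-trending convention Δy<sup>I</sup> = y<sup>I</sup> − y rectifies *downward* count
excursions (bursts of molecules leaving a state) into positive
fluctuations; the synthetic generator plants its events in that direction
when validating the pipeline.

Peak acceptance requires a genuine drop after the candidate:
∃ t₂ before the next candidate with
y<sup>III</sup>(t₂) + σ(t₂) ≤ y<sup>III</sup>(t₁). The weaker literal comparison
(y<sup>III</sup>(t₂) − σ(t₂) < y<sup>III</sup>(t₁)), which any sub-peak point satisfies, is
retained behind `literal_predicate=True` for comparison. Two further
detection choices matter:

* **Peak-flank merging.** A σ-crossing within τ₂/4 of an accepted peak
  is the peak's own rise or fall; keeping it would register the same
  critical event two or three samples apart and flood the SIP statistics
  with spurious 1–2 s intervals. Boundary events inside that margin are
  dropped (`boundary_margin`, default τ₂/4 in the epoch pipeline, 0 in
  the raw `detect_events`).
* **Noise floor.** `min_height` discards peak candidates below
  `min_height × median(σ)`. The median is used because an event inflates
  σ inside its own window. The floor is 0 by default (molecular count
  fluctuations *are* the signal); the synthetic recovery experiments use
  3.0 to suppress pure measurement-noise maxima, the standard 3σ false
  alarm rate for Gaussian noise.

SIPs are weighted by the amplitude of the initiating event, smoothed,
and normalised by the trapezoidal integral; every `WTDResult` asserts
ψ ≥ 0 and ∫ψ = 1 ± 10⁻⁶ on construction. Epoch-resolved densities use a
10,000 s epoch. Replicate bands are pointwise mean ± 1.96·SE (10
replicates by default); the bounds are not probability densities, and
their pointwise coverage is only meaningful on the support of the
distribution (the near-zero tails are strongly skewed).

Mode reporting uses a 10% relative height floor plus a 5% relative
prominence floor, filtering finite-bandwidth sampling wiggles.

## What the synthetic generator emulates

`make_spiked_signal` produces slow trend + symmetric triangular pulses
(width 3·dt) at planted times + white Gaussian noise. This reproduces
the features the inversion relies on — a slow trend, asynchronous large
spikes, stationary noise, and a known inter-event distribution — but not
the self-exciting, integer-valued, load-modulated character of real
count series. Passing recovery tests therefore demonstrate the
*inversion* is faithful (events found, SIP distribution recovered), not
that the detection thresholds are optimal for any particular molecular
signal.

## Reproduction problem sizes

The full sensitivity sweep behind the headline waiting-time results is
cluster-scale (thousands of day-long full-count runs); the package's
reproduction protocols are sized for one CPU:

* RAF:MEK timer conditions (10 s and 1320 s): 1/8 counts (1113 agents),
  3×10⁴ s, 10 seeds, epoch [10⁴, 2×10⁴] s. The test suite uses 3 seeds
  and 2×10⁴ s of the same protocol.
* ERK:MEK 8 s-timer condition: full counts (8890 agents), 2×10⁴ s, 4
  seeds. Full counts are required: the upper waiting-time mode is a
  collective synchronisation effect that is absent at 1/8, 1/4 and 1/2
  scale, one of the finite-size effects the count-rescaling argument
  does not cover.
* Support bound: largest τ with ψ ≥ 1% of the density maximum, measured
  per run on a grid extending to 600 s, maximised over all runs.

## Known limitations

* The skeleton network omits scaffold-mediated feedback and all
  signalling outside the integrin–MAPK–RUNX2 axis (WNT in particular),
  and collapses transcription/translation to timed production rules.
* At the 1320 s activation timer with a 1000 s load period, the model
  goes fully quiet during low-load half-periods (integrin activation is
  exactly zero at baseline and the complex pool drains within minutes),
  so quiet gaps of several hundred seconds enter the waiting-time
  statistics; the support bound of ψ then exceeds 100 s at every count
  scale tested. Keeping residual baseline signalling alive would need
  additional network structure the skeleton does not encode.
* One timer slot per agent means competing timed rules race by repeated
  sampling (production vs deactivation on active RUNX2), a documented
  simplification.
* A secondary ERK:MEK waiting-time mode near 9–14 s appears in some
  full-scale replicates at the 8 s productive timer (and requires full
  counts — it is absent at 1/8 to 1/2 scale), but it is weak and
  replicate-dependent: averaging over seeds or extending the epoch
  smears it into a monotone tail. A robust upper mode near 15–17 s, as
  a stronger reference would predict, likely needs the feedback
  structure the skeleton omits.
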