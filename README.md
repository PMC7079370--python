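# osteosip

Stochastic agent-based simulation of osteoblast mechanotransduction and
waiting-time analysis of critical molecular events.

Bone-forming osteoblasts convert mechanical load sensed by membrane
integrins into biochemical signalling through the RAF → MEK → ERK → RUNX2
cascade, ultimately driving transcription and deposition of
extracellular-matrix protein. The molecular count signals such a system
produces are non-ergodic and noisy, yet their large, abrupt fluctuations
carry structure: the *waiting times* between critical events are a
signature of the underlying activation-cycle dynamics. `osteosip` is for
computational biologists who want to simulate such a network at the
single-molecule (agent) level and to extract event-recurrence statistics
from any molecular count time series — simulated or otherwise.

## What it computes

Two coupled components:

**Simulator.** Each molecule is an agent performing constrained Brownian
motion in nested spherical compartments (nucleus, cytoplasm, membrane,
extracellular space). Agents bind their nearest eligible partner within an
interaction range *R*<sub>inter</sub>; complexes and activation states evolve by
internal timers drawn uniformly on `[0, 2T]`, where the means
*T*<sub>•→•</sub> are the activation-cycle-switch (ACS) parameters of the
cascade. Membrane integrins are switched on by a square-wave load of
magnitude *M* and period *P* (baseline 100 µPa) and off by their own
timer. Output is a `StateTimeSeries`: per-second counts *y<sub>i</sub>(t)* of every
(species, activation, bound-partner, compartment) label.

**Inversion pipeline.** A count series is treated as a subordinated
process: a parent process on natural (event-index) time composed with a
directing process t(t*) = Σ<sub>j≤i</sub> T<sub>j</sub> whose increments
τ<sub>i</sub> — the signal interim periods (SIPs) — are what we estimate.
The pipeline computes

* trend y<sup>I</sup> = Â<sub>τ1</sub> y (forward moving average) and
  fluctuation Δy<sup>I</sup> = y<sup>I</sup> − y,
* local fluctuation amplitude σ(t) over a centred τ₂ window,
* the Hilbert-transform envelope y<sub>env</sub> = |Ĥ Δy<sup>I</sup>| and the
  rectified series y<sup>III</sup> = max(Δy<sup>I</sup> − y<sub>env</sub>, 0),
* critical events ℰ: prominent peaks of y<sup>III</sup> (a peak is accepted when
  the signal later drops at least one σ below it) pooled with
  quiet-region boundary crossings of y<sup>III</sup> − σ,
* the amplitude-weighted SIP density, smoothed with a compact
  Epanechnikov kernel and normalised to the waiting-time distribution
  ψ(τ), with epoch-resolved variants ψ<sub>t</sub>(τ) and replicate
  confidence bands.

A forward generator of subordinated processes with planted event times
(`osteosip.synthetic`) provides ground truth for validating the whole
inversion.

## Worked example

Waiting-time modes of the RAF:MEK complex at a fast (10 s) MEK-activation
timer, on a 1/8-count model (`examples/complex_waiting_times.py`):

```
$ python examples/complex_waiting_times.py
RAF:MEK complexes (mean):  13.8
critical events in epoch:  479
psi mode at tau =  3.75 s   (height 0.097)
psi mode at tau = 14.75 s   (height 0.056)
```

479 critical events were found in a 10,000 s epoch of the complex count
signal. The density ψ(τ) is bimodal: dissociation bursts recur every
~4 s inside an activation cycle (dominant mode), with a weaker ~15 s
recurrence from quiet-period alternation. Validating the pipeline against
planted ground truth (`examples/planted_signal_recovery.py`):

```
$ python examples/planted_signal_recovery.py
seeds:             5
mean recall:       1.000
mean precision:    0.997
planted modes:     [4.0, 9.0]
max mode error:    1.25 s
```

Nearly every planted event is recovered with almost no spurious
detections, and the planted bimodal SIP distribution is reproduced.

A thin CLI wraps the same library calls:

```bash
osteosip simulate config.yaml --replicates 10 -o runs/
osteosip analyze runs/counts_seed*.tsv --label MEK.any.RAF.any -o analysis/
osteosip validate --seeds 10 -o validation/
```

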