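"""Validating the inversion pipeline on planted subordinated signals.

Generates noisy signals whose event times come from a known bimodal
gamma mixture (means 4 s and 9 s), runs the full event-detection /
WTD pipeline blind, and scores the recovery.  High recall/precision and
small mode errors show the pipeline inverts the subordination faithfully.
"""

from osteosip import recovery_experiment

mixture = {"name": "mixture",
           "components": [{"name": "gamma", "mean": 4.0, "shape": 20.0},
                          {"name": "gamma", "mean": 9.0, "shape": 20.0}],
           "weights": [0.5, 0.5]}

report = recovery_experiment(mixture, n_events=600, amplitude=10.0,
                             noise_sd=1.0, dt=0.1, n_seeds=5, seed=0,
                             planted_modes=[4.0, 9.0])
summary = report.summary()

print(f"seeds:             {summary['n_seeds']}")
print(f"mean recall:       {summary['mean_recall']:.3f}")
print(f"mean precision:    {summary['mean_precision']:.3f}")
print(f"planted modes:     {summary['planted_modes']}")
print(f"max mode error:    {summary['max_mode_error']:.2f} s")
# Recall/precision near 1 mean nearly every planted event is found with
# almost no spurious detections; the mode error is the distance between
# each planted SIP mode and its recovered counterpart.
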