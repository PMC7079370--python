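"""A subordinated random walk and its directing process.

Builds a unit-step counting process on natural time and subordinates it
with gamma-distributed waiting times.  Regions dense in events appear as
stretched portions of the trajectory, sparse regions as shrunk plateaus.
"""

import numpy as np

from osteosip import SubordinationSpec, generate_subordinated

spec = SubordinationSpec(
    directing={"name": "gamma", "mean": 6.0, "shape": 2.0},
    parent_step={"name": "constant", "value": 1.0},
    n_events=200, seed=4, dt=1.0)

times, x, event_times = generate_subordinated(spec)
sips = np.diff(np.concatenate([[0.0], event_times]))

print(f"events:                 {spec.n_events}")
print(f"physical span:          {event_times[-1]:.0f} s")
print(f"mean SIP:               {sips.mean():.2f} s (planted mean 6)")
print(f"longest plateau:        {sips.max():.1f} s")
print(f"trajectory final value: {x[-1]:.0f} (one unit step per event)")
# The directing process t(t*) maps natural time (event index) to physical
# time; its increments are the SIPs the inversion pipeline estimates.
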