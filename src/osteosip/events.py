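"""Critical-event detection and directing-process construction.

Critical events of a rectified fluctuation series ``yIII`` are (i)
prominent peaks -- strict local maxima followed, before the next
candidate, by a drop of at least one local standard deviation -- and (ii)
the boundaries of quiet regions where ``yIII`` sits below the local
fluctuation amplitude ``sigma``.  The merged, time-ordered event set is a
realisation of the directing process: its increments are the signal
interim periods (SIPs) whose distribution the analysis estimates.

This module contains no randomness: identical inputs give identical
events, and jointly rescaling ``yIII`` and ``sigma`` leaves the event set
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PEAK = "peak"
QUIET_START = "quiet_start"
QUIET_END = "quiet_end"


@dataclass(frozen=True, order=True)
class CriticalEvent:
    time: float
    amplitude: float
    kind: str


@dataclass
class DirectingProcess:
    """Cumulative physical times of the critical events.

    ``physical_times[i]`` is the physical time of the i-th event (natural
    time i); ``sips[i] = physical_times[i+1] - physical_times[i]`` and
    ``amplitudes[i]`` is the amplitude of the event initiating SIP i.
    """

    physical_times: np.ndarray
    amplitudes: np.ndarray
    kinds: tuple[str, ...]

    def __post_init__(self) -> None:
        self.physical_times = np.asarray(self.physical_times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.physical_times.size < 2:
            raise ValueError("insufficient events: need at least 2")
        if np.any(np.diff(self.physical_times) <= 0):
            raise ValueError("physical times must be strictly increasing")

    @property
    def natural_times(self) -> np.ndarray:
        return np.arange(self.physical_times.size)

    @property
    def sips(self) -> np.ndarray:
        return np.diff(self.physical_times)

    @property
    def n_events(self) -> int:
        return int(self.physical_times.size)


def detect_peaks(yIII: np.ndarray, sigma: np.ndarray,
                 times: np.ndarray | None = None,
                 min_height: float = 0.0,
                 literal_predicate: bool = False) -> list[CriticalEvent]:
    """Detect prominent peaks of the rectified series.

    A candidate peak (strict local maximum) at ``t1`` is accepted when some
    later point ``t2``, no further than the next candidate, drops at least
    one local standard deviation below it:
    ``yIII(t2) + sigma(t2) <= yIII(t1)``.  Searching only up to the next
    candidate prevents one deep trough from validating every earlier peak.

    ``min_height`` optionally discards candidates smaller than
    ``min_height * median(sigma)`` before the prominence test.  The median
    of the local fluctuation amplitude is a robust noise floor that is not
    inflated by the events themselves (an event sitting inside its own
    sigma window raises the local value).  The floor is zero by default
    and is used when a known measurement-noise level must be suppressed.

    With ``literal_predicate=True`` the acceptance test is the weaker
    ``yIII(t2) - sigma(t2) < yIII(t1)``, which any sub-peak point
    satisfies; it is retained for comparison only.
    """
    yIII = np.asarray(yIII, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if yIII.shape != sigma.shape:
        raise ValueError("yIII and sigma must be aligned")
    n = yIII.size
    if n < 3:
        return []
    t = np.arange(n, dtype=float) if times is None else np.asarray(times, float)
    interior = np.flatnonzero(
        (yIII[1:-1] > yIII[:-2]) & (yIII[1:-1] > yIII[2:])) + 1
    if min_height > 0:
        floor = min_height * float(np.median(sigma))
        interior = interior[yIII[interior] >= floor]
    events: list[CriticalEvent] = []
    for c, i in enumerate(interior):
        j_end = interior[c + 1] if c + 1 < interior.size else n - 1
        seg = slice(i + 1, j_end + 1)
        if literal_predicate:
            ok = np.any(yIII[seg] - sigma[seg] < yIII[i])
        else:
            ok = np.any(yIII[seg] + sigma[seg] <= yIII[i])
        if ok:
            events.append(CriticalEvent(float(t[i]), float(yIII[i]), PEAK))
    return events


def detect_quiet_boundaries(yIII: np.ndarray, sigma: np.ndarray,
                            times: np.ndarray | None = None
                            ) -> list[CriticalEvent]:
    """Events at the boundaries of quiet regions.

    A quiet region is where ``yIII - sigma`` is below zero; each downward
    crossing emits a ``quiet_start`` and each upward crossing a
    ``quiet_end`` at the first sample on the new side.
    """
    yIII = np.asarray(yIII, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if yIII.shape != sigma.shape:
        raise ValueError("yIII and sigma must be aligned")
    n = yIII.size
    if n < 2:
        return []
    t = np.arange(n, dtype=float) if times is None else np.asarray(times, float)
    d = yIII - sigma
    below = d < 0
    events: list[CriticalEvent] = []
    for i in np.flatnonzero(below[1:] != below[:-1]) + 1:
        kind = QUIET_START if below[i] else QUIET_END
        events.append(CriticalEvent(float(t[i]), float(yIII[i]), kind))
    return events


def detect_events(yIII: np.ndarray, sigma: np.ndarray,
                  times: np.ndarray | None = None,
                  include_boundaries: bool = True,
                  min_height: float = 0.0,
                  boundary_margin: float = 0.0) -> list[CriticalEvent]:
    """Pooled critical events: prominent peaks plus, by default, quiet
    region boundaries.

    ``boundary_margin`` (seconds) drops boundary events closer than the
    margin to an accepted peak: a sigma-crossing on the flank of a peak is
    that peak's own rise or fall, and keeping it would register the same
    critical event twice a couple of samples apart.
    """
    peaks = detect_peaks(yIII, sigma, times, min_height=min_height)
    if not include_boundaries:
        return peaks
    boundaries = detect_quiet_boundaries(yIII, sigma, times)
    if boundary_margin > 0 and peaks:
        peak_times = np.array([e.time for e in peaks])
        boundaries = [e for e in boundaries
                      if np.min(np.abs(peak_times - e.time)) > boundary_margin]
    return peaks + boundaries


def build_directing(events: list[CriticalEvent]) -> DirectingProcess:
    """Merge, sort and de-duplicate events into a directing process.

    Events at equal times collapse to one (a peak wins over a boundary);
    the result is invariant to the input ordering.
    """
    if len(events) < 2:
        raise ValueError("insufficient events: need at least 2")
    # sort by time; peaks first among equal times so they win de-duplication
    ordered = sorted(events, key=lambda e: (e.time, e.kind != PEAK))
    merged: list[CriticalEvent] = []
    for ev in ordered:
        if merged and ev.time == merged[-1].time:
            continue
        merged.append(ev)
    if len(merged) < 2:
        raise ValueError("insufficient events: need at least 2 distinct times")
    return DirectingProcess(
        physical_times=np.array([e.time for e in merged]),
        amplitudes=np.array([e.amplitude for e in merged]),
        kinds=tuple(e.kind for e in merged),
    )
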