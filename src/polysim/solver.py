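"""Exact SSA main loop with event interleaving and trajectory logging.

The loop is the classic Gillespie iteration: refresh dependent
propensities, draw τ ~ Exponential(total), select a channel proportionally
to its propensity, fire it.  Timed events are interleaved exactly: when
``t + τ`` would cross the next event time, the clock advances to the event,
the event is applied, τ is discarded and redrawn — exact by memorylessness
of the exponential clocks.

All stochastic choices (τ, channel, site, particle, motif) draw from one
seeded 64-bit generator in a fixed order, so identical (model, seed,
solver) gives identical trajectories bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import ValidationError
from .selection import make_store, waiting_time_sample  # noqa: F401 (re-export)
from .system import ReactionSystem

#: stored totals are recomputed from scratch this often to bound float drift
REFRESH_EVERY = 1_000_000


@dataclass
class Trajectory:
    """Logged time series of the selected observables."""
    times: List[float]
    observables: Dict[str, List[int]]
    event_count: int
    t_end: float
    seed: int
    solver: str
    firings: Optional[List[Tuple[float, int]]] = field(default=None, repr=False)

    def series(self, name: str) -> List[int]:
        return self.observables[name]

    def final(self, name: str) -> int:
        return self.observables[name][-1]

    def to_dataframe(self):
        import pandas as pd
        data = {"time": self.times}
        data.update(self.observables)
        return pd.DataFrame(data)


def run(system: ReactionSystem, t_end: float, seed: int,
        solver: str = "cr", log_period: float = 1.0,
        max_events: Optional[int] = None,
        record_firings: bool = False) -> Trajectory:
    """Simulate ``system`` until ``t_end`` (may be ``math.inf`` to run until
    every propensity is exhausted), returning the logged trajectory.

    The simulation stops at ``t_end``, or earlier when the total propensity
    is zero and no timed events remain, or after ``max_events`` firings
    (used for per-event cost measurements).
    """
    if not (t_end > 0.0):
        raise ValidationError("t_end must be positive")
    if not (log_period > 0.0):
        raise ValidationError("log_period must be positive")
    system.finalize()
    rng = np.random.Generator(np.random.PCG64(seed))
    channels = system.channels
    read_map = system.read_map
    store = make_store(solver, len(channels))
    for ch in channels:
        store.set(ch.index, ch.compute())

    events = system.events  # sorted by finalize()
    n_events = len(events)
    ei = 0

    obs = [(name, system.observable_getter(name))
           for name in system.observables]
    times: List[float] = []
    series: Dict[str, List[int]] = {name: [] for name, _ in obs}

    def log(at: float) -> None:
        times.append(at)
        for name, getter in obs:
            series[name].append(getter())

    def refresh(touched) -> None:
        for key in touched:
            dependents = read_map.get(key)
            if dependents:
                for ci in dependents:
                    ch = channels[ci]
                    store.set(ci, ch.compute())

    def full_refresh() -> None:
        for ch in channels:
            store.set(ch.index, ch.compute())
        store.refresh()

    t = 0.0
    next_log = 0.0
    fired = 0
    firings: Optional[List[Tuple[float, int]]] = [] if record_firings else None
    rand = rng.random
    finite_end = math.isfinite(t_end)

    while True:
        total = store.total
        if total <= 1e-12:
            full_refresh()
            total = store.total
            if total <= 0.0:
                # nothing can fire: jump to the next event, if any
                if ei < n_events and events[ei].time <= t_end:
                    et = events[ei].time
                    while next_log < et:
                        log(next_log)
                        next_log += log_period
                    t = et
                    touched: List[tuple] = []
                    while ei < n_events and events[ei].time == et:
                        touched.extend(events[ei].apply())
                        ei += 1
                    refresh(touched)
                    continue
                if finite_end:
                    while next_log <= t_end:
                        log(next_log)
                        next_log += log_period
                    t = t_end
                break
        u = rand()
        while u <= 0.0:
            u = rand()
        t_next = t - math.log(u) / total
        if ei < n_events and t_next >= events[ei].time \
                and events[ei].time <= t_end:
            et = events[ei].time
            while next_log < et:
                log(next_log)
                next_log += log_period
            t = et
            touched = []
            while ei < n_events and events[ei].time == et:
                touched.extend(events[ei].apply())
                ei += 1
            refresh(touched)
            continue  # τ discarded; redrawn from the post-event state
        if t_next > t_end:
            while next_log <= t_end:
                log(next_log)
                next_log += log_period
            t = t_end
            break
        while next_log < t_next:
            log(next_log)
            next_log += log_period
        t = t_next
        j = store.select(rng)
        if j is None:  # numeric residue in the stored total
            full_refresh()
            continue
        touched = channels[j].fire(rng)
        fired += 1
        if firings is not None:
            firings.append((t, j))
        refresh(touched)
        if fired % REFRESH_EVERY == 0:
            full_refresh()
        if max_events is not None and fired >= max_events:
            break

    if not times or times[-1] < t:
        log(t)
    return Trajectory(times=times, observables=series, event_count=fired,
                      t_end=t, seed=seed, solver=solver, firings=firings)
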