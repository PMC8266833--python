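"""Per-event cost measurement on n-cascade benchmarks.

The quantity of interest is the asymptotic, hardware-relative cost of one
SSA iteration as the number of reaction channels R grows.  Two care points
make the measurement honest:

* the cascade is timed in its *spread* regime (molecules distributed along
  the pathway), which is the state a long cascade run spends almost all of
  its events in; timing from the initial all-at-stage-zero state would let
  the linear scan of the direct method stop after a handful of channels;
* one-off costs (channel wiring, initial propensity fill, both O(R)) are
  cancelled by differencing the wall time of two runs with different event
  budgets but identical seeds, so only the marginal per-event cost remains.
"""

from __future__ import annotations

import math
import time

from .builders import build_n_cascade
from .errors import ValidationError
from .solver import run


def spread_cascade(system, n: int) -> None:
    """Distribute the cascade's molecules evenly along the pathway, the
    representative mid-run state of a long conversion cascade."""
    chems = [system.free_chemicals[f"A_{i}"] for i in range(n + 1)]
    total = sum(c.count for c in chems)
    for c in chems:
        c.count = 0
    m = min(total, n)
    if m < 1:
        raise ValidationError("cascade holds no molecules to spread")
    stride = n // m
    placed = 0
    for i in range(m):
        chems[i * stride].count += 1
        placed += 1
    chems[0].count += total - placed


def per_event_cost(n: int, solver: str, warmup_events: int,
                   measured_events: int, seed: int = 1) -> float:
    """Marginal wall-clock seconds per reaction event for one solver on a
    spread n-cascade, with setup cost differenced away."""

    def timed(budget: int) -> float:
        system = build_n_cascade(n)
        spread_cascade(system, n)
        system.finalize()
        t0 = time.perf_counter()
        run(system, t_end=math.inf, seed=seed, solver=solver,
            log_period=1e12, max_events=budget)
        return time.perf_counter() - t0

    t_short = timed(warmup_events)
    t_long = timed(warmup_events + measured_events)
    return max(t_long - t_short, 1e-12) / measured_events


def scaling_ratios(r_small: int = 100, r_large: int = 100_000,
                   seed: int = 1):
    """Growth factors of the per-event cost from r_small to r_large
    channels for the direct and composition–rejection solvers."""
    costs = {}
    for solver, budgets in (("direct", {r_small: (2000, 20000),
                                        r_large: (50, 200)}),
                            ("cr", {r_small: (2000, 20000),
                                    r_large: (2000, 20000)})):
        small = per_event_cost(r_small, solver, *budgets[r_small], seed=seed)
        large = per_event_cost(r_large, solver, *budgets[r_large], seed=seed)
        costs[solver] = (small, large, large / small)
    return costs
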