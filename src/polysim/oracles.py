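"""Independent analytic and brute-force oracles.

Every oracle here is a closed form or a distributional test that does not
share code with the engine paths it is used to check: exponential waiting
times, Erlang transit through linear cascades, harmonic-mean elongation
cycle speed, the replication-fork recruitment arithmetic, and
Kolmogorov–Smirnov comparisons for waiting-time and cross-solver
equivalence checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .errors import ValidationError


@dataclass
class OracleReport:
    """One validation statistic with its acceptance decision."""
    name: str
    observed: float
    expected: float
    tolerance: Optional[float]  # absolute tolerance, or None for p-value tests
    p_value: Optional[float]
    alpha: Optional[float]
    passed: bool

    def row(self):
        return (self.name, self.observed, self.expected, self.tolerance,
                self.p_value, self.alpha, self.passed)


def erlang_transit_mean(n_stages: int, rate_per_stage: float) -> float:
    """Expected per-molecule transit time through n first-order stages:
    the Erlang(n, rate) mean n/rate."""
    if n_stages < 1 or rate_per_stage <= 0:
        raise ValidationError("need n >= 1 and rate > 0")
    return n_stages / rate_per_stage


def elongation_speed_oracle(step_rates: Sequence[float]) -> float:
    """Mean per-position speed of a sequential elongation cycle
    (loading -> polymerization -> translocation): the harmonic combination
    1/Σ(1/k_i).  The limiting-step rate is an upper bound on this; with the
    standard rate settings the cycle runs 10-25% below the headline
    per-process speed."""
    if not step_rates:
        raise ValidationError("need at least one step rate")
    if any(k <= 0 for k in step_rates):
        raise ValidationError("step rates must be positive")
    return 1.0 / sum(1.0 / k for k in step_rates)


def okazaki_recruitment_interval(fragment_bp: float = 1000.0,
                                 fork_speed_bps: float = 750.0) -> float:
    """Seconds between lagging-strand polymerase recruitments: fragment
    length over fork speed (1000 bp at 750 bp/s -> 1.33 s)."""
    if fragment_bp <= 0 or fork_speed_bps <= 0:
        raise ValidationError("fragment length and fork speed must be positive")
    return fragment_bp / fork_speed_bps


def recruitment_balance(dnap_free: float, recruitment_rate: float) -> float:
    """|DNAP_free| x r_recruitment; a balanced replication build makes this
    equal the fork's recruitment frequency 1/interval = 3/4 per second."""
    if dnap_free < 0 or recruitment_rate < 0:
        raise ValidationError("inputs must be non-negative")
    return dnap_free * recruitment_rate


def distributional_test(samples: Sequence[float],
                        reference: Union[Callable, Sequence[float]],
                        alpha: float = 0.01,
                        name: str = "ks") -> OracleReport:
    """One- or two-sample Kolmogorov–Smirnov decision at level ``alpha``.

    ``reference`` is either a cdf callable (one-sample) or a second sample
    (two-sample).  Requires at least 100 samples.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 100:
        raise ValidationError("need at least 100 samples")
    if callable(reference):
        stat, p = stats.kstest(samples, reference)
    else:
        reference = np.asarray(reference, dtype=float)
        if reference.size < 100:
            raise ValidationError("need at least 100 reference samples")
        stat, p = stats.ks_2samp(samples, reference)
    return OracleReport(name=name, observed=float(stat), expected=0.0,
                        tolerance=None, p_value=float(p), alpha=alpha,
                        passed=bool(p > alpha))


# ----------------------------------------------------------------------
# engine-backed measurement helpers (the quantity measured is still judged
# against the independent closed forms above)
# ----------------------------------------------------------------------

def simulate_recruitment_intervals(propensity: float, n_events: int,
                                   seed: int) -> np.ndarray:
    """Inter-recruitment intervals of a constant-propensity recruitment
    channel (a buffered pool firing a first-order conversion), simulated
    with the engine; exponential with the given rate."""
    from .system import ReactionSystem
    from .solver import run

    if propensity <= 0 or n_events < 1:
        raise ValidationError("need positive propensity and n_events >= 1")
    system = ReactionSystem()
    pool = system.add_free_chemical("DNAP_signal", 15, buffered=True)
    system.add_free_chemical("recruited", 0)
    system.add_chemical_reaction([(pool, 1)], [("recruited", 1)],
                                 k_forward=propensity / 15)
    traj = run(system, t_end=float("inf"), seed=seed, solver="direct",
               log_period=1e9, max_events=n_events, record_firings=True)
    times = np.array([t for t, _ in traj.firings])
    return np.diff(np.concatenate([[0.0], times]))


def simulate_cascade_transit_times(n_stages: int, molecules: int,
                                   seed: int) -> np.ndarray:
    """Arrival times of every molecule at the end of a unit-rate cascade
    (all molecules start at stage 0 at t=0, so arrival time = transit
    time); checked against the Erlang mean n_stages."""
    from .builders import build_n_cascade
    from .solver import run

    system = build_n_cascade(n_stages, total_events=n_stages * molecules)
    traj = run(system, t_end=float("inf"), seed=seed, solver="tree",
               log_period=1e9, record_firings=True)
    last = len(system.channels) - 1
    return np.array([t for t, j in traj.firings if j == last])


def write_report(reports: List[OracleReport], path: str) -> None:
    """Oracle reports as a TSV table."""
    with open(path, "w") as fh:
        fh.write("name\tobserved\texpected\ttolerance\tp_value\talpha\tpass\n")
        for r in reports:
            fh.write("\t".join("" if v is None else str(v)
                               for v in r.row()) + "\n")
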