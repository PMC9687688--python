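"""Synthetic keystroke cohorts with class-dependent timing structure.

Real keystroke-dynamics studies of Parkinson's disease observe slower,
more variable hold times, longer between-key intervals, and a left/right
asymmetry in the affected hand.  The simulator emulates exactly that
statistical structure: per subject, key regions (left half L, right half
R, space bar S) are drawn i.i.d. from a region distribution, transitions
are the ordered pairs of consecutive regions, and the three timing series
are drawn from truncated-at-zero normal distributions whose (mean, sd)
depend on the class.  Parkinson subjects additionally receive an additive
offset on left-side hold times, modelling one-sided motor impairment.

Event timestamps advance by the drawn latency values, so simulated logs
satisfy the chronological-ordering invariant and round-trip through the
Tappy text format unchanged.

This is statistical plumbing for testing the pipeline end to end, not a
clinical keystroke model.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sstats

from .tappy_io import HEALTHY, PARKINSON, KeystrokeEvent, REGIONS, SubjectLog

__all__ = [
    "ClassTimings",
    "SimConfig",
    "simulate_cohort",
    "default_scenario",
    "separated_scenario",
    "null_scenario",
]


@dataclass(frozen=True)
class ClassTimings:
    """(mean, sd) in milliseconds for each timing series of one class."""

    hold: tuple[float, float]
    latency: tuple[float, float]
    flight: tuple[float, float]

    def __post_init__(self) -> None:
        for name in ("hold", "latency", "flight"):
            m, s = getattr(self, name)
            if m <= 0 or s <= 0:
                raise ValueError(f"{name} mean and sd must be positive")


@dataclass
class SimConfig:
    """Cohort generator configuration.

    ``asymmetry`` is an additive offset (ms) applied to left-region hold
    times of Parkinson subjects only.  ``lognormal=True`` swaps the
    truncated normal for a log-normal with the same mean and sd, for
    heavier-tailed timing distributions.
    """

    n_healthy: int = 55
    n_parkinson: int = 162
    events_per_subject: int | tuple[int, int] = 300
    healthy: ClassTimings = field(
        default_factory=lambda: ClassTimings((85.0, 25.0), (200.0, 60.0), (120.0, 50.0))
    )
    parkinson: ClassTimings = field(
        default_factory=lambda: ClassTimings((110.0, 40.0), (260.0, 90.0), (160.0, 70.0))
    )
    region_probs: tuple[float, float, float] = (0.47, 0.47, 0.06)  # L, R, S
    asymmetry: float = 15.0
    lognormal: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.region_probs, dtype=float)
        if p.size != 3 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("region_probs must be 3 non-negative values summing to 1")


def _draw_positive(rng, mean, sd, size, lognormal):
    if lognormal:
        sigma2 = np.log(1.0 + (sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), size=size)
    # truncated-at-zero normal via scipy's parameterization
    a = (0.0 - mean) / sd
    u = rng.random(size)
    return _sstats.truncnorm.ppf(u, a, np.inf, loc=mean, scale=sd)


def _simulate_subject(
    rng: np.random.Generator,
    subject_id: str,
    label: str,
    n_events: int,
    timings: ClassTimings,
    region_probs,
    asymmetry: float,
    lognormal: bool,
) -> SubjectLog:
    regions = rng.choice(list(REGIONS), size=n_events, p=list(region_probs))
    hold = _draw_positive(rng, *timings.hold, n_events, lognormal)
    latency = _draw_positive(rng, *timings.latency, n_events, lognormal)
    flight = _draw_positive(rng, *timings.flight, n_events, lognormal)
    if label == PARKINSON and asymmetry:
        hold = hold + np.where(regions == "L", asymmetry, 0.0)

    day = _dt.date(2020, 1, 6)
    t_ms = 9 * 3600 * 1000.0  # session starts at 09:00
    events = []
    prev = regions[0]
    for i in range(n_events):
        t_ms += latency[i]
        ms = int(round(t_ms)) % (24 * 3600 * 1000)
        time = (_dt.datetime.min + _dt.timedelta(milliseconds=ms)).time()
        events.append(
            KeystrokeEvent(
                subject_id=subject_id,
                date=day + _dt.timedelta(days=int(t_ms // (24 * 3600 * 1000))),
                time=time,
                region=str(regions[i]),
                hold_time=float(hold[i]),
                transition=str(prev) + str(regions[i]),
                latency=float(latency[i]),
                flight=float(flight[i]),
            )
        )
        prev = regions[i]
    return SubjectLog(subject_id=subject_id, label=label, events=events)


def simulate_cohort(config: SimConfig | None = None) -> list[SubjectLog]:
    """Generate healthy then Parkinson subject logs, deterministic by seed."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    ev = config.events_per_subject
    logs: list[SubjectLog] = []
    specs = [(HEALTHY, config.healthy, config.n_healthy), (PARKINSON, config.parkinson, config.n_parkinson)]
    for label, timings, count in specs:
        for i in range(count):
            n_events = int(ev if isinstance(ev, int) else rng.integers(ev[0], ev[1] + 1))
            logs.append(
                _simulate_subject(
                    rng,
                    f"{label[:2]}{i:04d}",
                    label,
                    n_events,
                    timings,
                    config.region_probs,
                    config.asymmetry,
                    config.lognormal,
                )
            )
    return logs


def default_scenario() -> SimConfig:
    """Imbalanced cohort matching the study conditions: 162 PD / 55 healthy.

    Parkinson timings are slower and more variable than healthy ones, with
    a mild left-side hold-time asymmetry, so the cohort is imbalanced yet
    separable — the regime the oversampling + classification pipeline is
    built for.
    """
    return SimConfig()


def separated_scenario(n_per_class: int = 40, gap_sd: float = 3.0, seed: int = 0) -> SimConfig:
    """Strongly separated balanced cohort for learnability experiments.

    Class hold/latency/flight means differ by ``gap_sd`` pooled standard
    deviations, so a working pipeline should classify held-out subjects
    nearly perfectly.
    """
    sd_h, sd_l, sd_f = 12.0, 40.0, 30.0
    healthy = ClassTimings((80.0, sd_h), (190.0, sd_l), (110.0, sd_f))
    parkinson = ClassTimings(
        (80.0 + gap_sd * sd_h, sd_h),
        (190.0 + gap_sd * sd_l, sd_l),
        (110.0 + gap_sd * sd_f, sd_f),
    )
    return SimConfig(
        n_healthy=n_per_class,
        n_parkinson=n_per_class,
        events_per_subject=200,
        healthy=healthy,
        parkinson=parkinson,
        asymmetry=10.0,
        seed=seed,
    )


def null_scenario(n_per_class: int = 40, seed: int = 0) -> SimConfig:
    """Negative control: identical class distributions, zero asymmetry.

    Any classifier trained on this cohort should perform at chance; the
    pipeline uses it to detect information leakage.
    """
    timings = ClassTimings((85.0, 25.0), (200.0, 60.0), (120.0, 50.0))
    return SimConfig(
        n_healthy=n_per_class,
        n_parkinson=n_per_class,
        events_per_subject=200,
        healthy=timings,
        parkinson=timings,
        asymmetry=0.0,
        seed=seed,
    )
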