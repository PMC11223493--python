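"""Synthetic nanopore recordings with known ground truth.

The simulator is statistical, not biophysical: translocation events are
ideal square current pulses superposed on a noisy open-pore baseline and
shaped by the acquisition low-pass filter. Per analyte class it draws

* Poisson event arrivals at rate ``correction_factor * concentration``
  (events/s), mirroring how event rates scale with concentration,
* log-normal dwell times (parameterized by arithmetic mean/SD),
* normal blockade depths.

Optionally a class can carry within-event structure (a sinusoidal ripple
or extra in-event white noise) so that classifiers which look at event
*shape* can be compared against ones that only see duration and depth.

Every random draw comes from a single seeded generator in a documented
order (classes processed in sorted name order; per class: event count,
start times, dwell times, depths, ripple phases), so identical seeds give
bit-identical traces and annotations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .sigproc import lowpass_filter
from .trace import CurrentTrace

logger = logging.getLogger(__name__)

#: Default per-class generative parameters. Correction factors (events/s/uM)
#: and the cA6 dwell statistics are the workflow's calibration constants;
#: dwell defaults for cA3/4 and cA5 are chosen to reproduce the qualitative
#: duration ordering cA3/4 < cA5 < cA6. All classes block ~400 pA: the cOA
#: stoichiometries differ in dwell time, not blockade depth.
DEFAULT_CLASSES: dict[str, "ClassParams"] = {}


@dataclass
class ClassParams:
    """Generative description of one analyte class.

    Dwell times are log-normal, parameterized by their *arithmetic* mean
    and SD in seconds; blockade depths are normal in pA.
    """

    concentration: float  # uM
    correction_factor: float  # events / s / uM
    dwell_mean: float  # s
    dwell_sd: float  # s
    blockade_mean: float  # pA
    blockade_sd: float  # pA
    ripple_amplitude: float = 0.0  # pA, within-event sinusoidal ripple
    ripple_frequency: float = 0.0  # Hz
    event_noise_sd: float = 0.0  # pA, extra white noise inside events

    @property
    def rate(self) -> float:
        """Event arrival rate in events/s."""
        return self.correction_factor * self.concentration

    def lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) of log dwell matching the arithmetic mean/SD."""
        m, s = self.dwell_mean, self.dwell_sd
        sigma2 = np.log1p((s / m) ** 2)
        mu = np.log(m) - sigma2 / 2.0
        return mu, float(np.sqrt(sigma2))


DEFAULT_CLASSES.update(
    {
        "cA3/4": ClassParams(10.0, 0.17, 110e-6, 40e-6, 400.0, 30.0),
        "cA5": ClassParams(10.0, 0.62, 180e-6, 60e-6, 400.0, 30.0),
        "cA6": ClassParams(10.0, 0.12, 315e-6, 26e-6, 400.0, 30.0),
    }
)


@dataclass
class SimulationConfig:
    """Full generative description of one synthetic recording."""

    classes: dict[str, ClassParams]
    sampling_rate: float = 500e3  # Hz
    duration: float = 10.0  # s
    open_pore_current: float = 580.0  # pA (alpha-HL in 3 M KCl at +200 mV)
    baseline_noise_sd: float = 30.0  # pA
    voltage: float = 120.0  # mV
    filter_cutoff: float | None = 100e3  # Hz; None disables shaping
    min_gap: float = 2e-3  # s, enforced separation between events
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if self.baseline_noise_sd < 0:
            raise ValueError("baseline_noise_sd must be non-negative")
        if self.filter_cutoff is not None and not 0 < self.filter_cutoff < self.sampling_rate / 2:
            raise ValueError("filter_cutoff must lie in (0, Nyquist)")
        for name, cls in self.classes.items():
            if cls.concentration < 0:
                raise ValueError(f"class {name!r}: concentration must be >= 0")
            if not cls.correction_factor > 0:
                raise ValueError(f"class {name!r}: correction factor must be > 0")
            if not cls.dwell_mean > 0:
                raise ValueError(f"class {name!r}: dwell mean must be > 0")
            if cls.dwell_sd < 0:
                raise ValueError(f"class {name!r}: dwell sd must be >= 0")
            if not cls.blockade_mean < self.open_pore_current:
                raise ValueError(f"class {name!r}: blockade mean must be below the open-pore current")

    def expected_occupancy(self) -> float:
        """Expected fraction of trace time occupied by events (incl. gaps)."""
        return sum(c.rate * (c.dwell_mean + self.min_gap) for c in self.classes.values())


@dataclass
class GroundTruthAnnotation:
    """One injected event in a synthetic trace (truth channel)."""

    event_index: int
    label: str
    start: int  # sample index, inclusive
    end: int  # sample index, exclusive
    duration: float  # s, as realized on the sample grid
    depth: float  # pA

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("annotation must satisfy start < end")


_MAX_REJECTION_ROUNDS = 1000


def _draw_class_events(name: str, cls: ClassParams, config: SimulationConfig, rng: np.random.Generator):
    """Draw (starts, durations, depths, phases) for one class."""
    n = rng.poisson(cls.rate * config.duration)
    mu, sigma = cls.lognormal_params()
    durations = rng.lognormal(mu, sigma, size=n)
    # events must fit inside the trace
    durations = np.minimum(durations, 0.9 * config.duration)
    starts = rng.uniform(0.0, config.duration - durations, size=n)
    depths = rng.normal(cls.blockade_mean, cls.blockade_sd, size=n)
    depths = np.clip(depths, 0.0, config.open_pore_current)
    phases = rng.uniform(0.0, 2 * np.pi, size=n)
    return starts, durations, depths, phases


def simulate_trace(config: SimulationConfig) -> tuple[CurrentTrace, list[GroundTruthAnnotation]]:
    """Generate a synthetic recording and its ground-truth annotations.

    Events are square pulses with class-specific depth and width, arrivals
    Poisson with rate ``CF_x * concentration_x``, superposed on the
    open-pore baseline plus Gaussian noise and shaped by a zero-phase
    4-pole Bessel low-pass at ``filter_cutoff``. Overlapping arrivals are
    resolved by rejection-resampling of start times.

    Raises
    ------
    ValueError
        If the configuration is invalid, or the total event rate makes
        rejection resampling infeasible (expected occupancy > 50%).
    """
    config.validate()
    if config.expected_occupancy() > 0.5:
        raise ValueError(
            "expected event occupancy exceeds 50% of the trace; "
            "rejection resampling of arrival times is infeasible"
        )
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n_samples = int(round(config.duration * fs))

    starts_l, durs_l, depths_l, phases_l, labels_l = [], [], [], [], []
    class_order = sorted(config.classes)
    for name in class_order:
        cls = config.classes[name]
        if cls.rate == 0:
            continue
        s, d, z, p = _draw_class_events(name, cls, config, rng)
        starts_l.append(s)
        durs_l.append(d)
        depths_l.append(z)
        phases_l.append(p)
        labels_l.extend([name] * s.size)

    if starts_l:
        starts = np.concatenate(starts_l)
        durations = np.concatenate(durs_l)
        depths = np.concatenate(depths_l)
        phases = np.concatenate(phases_l)
    else:
        starts = durations = depths = phases = np.empty(0)
    labels = np.array(labels_l, dtype=object)

    # rejection-resample start times until no two events overlap (incl. gap)
    for _ in range(_MAX_REJECTION_ROUNDS):
        order = np.argsort(starts, kind="stable")
        starts, durations, depths, phases, labels = (
            starts[order], durations[order], depths[order], phases[order], labels[order],
        )
        if starts.size < 2:
            break
        ends = starts + durations + config.min_gap
        keep_end = np.maximum.accumulate(ends[:-1])
        collide = np.concatenate([[False], starts[1:] < keep_end])
        if not collide.any():
            break
        starts = starts.copy()
        starts[collide] = rng.uniform(0.0, config.duration - durations[collide], size=int(collide.sum()))
    else:
        raise RuntimeError("could not place events without overlap; lower the event rate")

    samples = config.open_pore_current + rng.normal(0.0, config.baseline_noise_sd, size=n_samples)

    annotations: list[GroundTruthAnnotation] = []
    for i in range(starts.size):
        s0 = int(round(starts[i] * fs))
        width = max(1, int(round(durations[i] * fs)))
        s1 = min(s0 + width, n_samples)
        if s1 <= s0:
            continue
        seg = slice(s0, s1)
        samples[seg] -= depths[i]
        cls = config.classes[labels[i]]
        if cls.ripple_amplitude > 0 and cls.ripple_frequency > 0:
            t = np.arange(s1 - s0) / fs
            samples[seg] += cls.ripple_amplitude * np.sin(2 * np.pi * cls.ripple_frequency * t + phases[i])
        if cls.event_noise_sd > 0:
            samples[seg] += rng.normal(0.0, cls.event_noise_sd, size=s1 - s0)
        annotations.append(
            GroundTruthAnnotation(
                event_index=len(annotations),
                label=str(labels[i]),
                start=s0,
                end=s1,
                duration=(s1 - s0) / fs,
                depth=float(depths[i]),
            )
        )

    trace = CurrentTrace(
        samples=samples,
        sampling_rate=fs,
        voltage=config.voltage,
        metadata={
            "open_pore_current_pA": config.open_pore_current,
            "filter_cutoff_hz": config.filter_cutoff,
            **config.metadata,
        },
    )
    if config.filter_cutoff is not None:
        trace = lowpass_filter(trace, config.filter_cutoff)
    return trace, annotations


def annotations_to_frame(annotations: list[GroundTruthAnnotation]) -> pd.DataFrame:
    """Tabulate annotations (event_id, class, start, end, duration_s, depth_pA)."""
    return pd.DataFrame(
        {
            "event_id": [a.event_index for a in annotations],
            "class": [a.label for a in annotations],
            "start": [a.start for a in annotations],
            "end": [a.end for a in annotations],
            "duration_s": [a.duration for a in annotations],
            "depth_pA": [a.depth for a in annotations],
        }
    )


def simulate_eic_peaks(
    concentrations: dict[str, float],
    response_factors: dict[str, float],
    noise_rel_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate LC-MS extracted-ion-chromatogram peak areas.

    Peak area = response_factor * concentration * (1 + eps) with
    eps ~ Normal(0, noise_rel_sd). Negative areas are clipped to 0 with a
    warning.
    """
    if noise_rel_sd < 0:
        raise ValueError("noise_rel_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for species in concentrations:
        conc = concentrations[species]
        rf = response_factors[species]
        if conc < 0 or rf < 0:
            raise ValueError("concentrations and response factors must be >= 0")
        area = rf * conc * (1.0 + (rng.normal(0.0, noise_rel_sd) if noise_rel_sd > 0 else 0.0))
        if area < 0:
            warnings.warn(f"negative simulated peak area for {species!r} clipped to 0")
            area = 0.0
        rows.append({"species": species, "concentration_uM": conc, "area": area})
    return pd.DataFrame(rows)


def match_events_to_annotations(
    events,
    annotations: list[GroundTruthAnnotation],
    coordinate_ratio: float = 1.0,
) -> list[str | None]:
    """Ground-truth label for each detected event, or None if unmatched.

    An event matches the annotation whose raw-sample interval contains the
    event's midpoint; *coordinate_ratio* converts the event's (possibly
    decimated) sample coordinates back to raw ones (e.g. 6.25 for
    500 kHz -> 80 kHz).
    """
    starts = np.array([a.start for a in annotations])
    ends = np.array([a.end for a in annotations])
    labels: list[str | None] = []
    for ev in events:
        mid = (ev.start + ev.end) / 2 * coordinate_ratio
        hit = np.flatnonzero((starts <= mid) & (mid < ends))
        labels.append(annotations[hit[0]].label if hit.size else None)
    return labels


def spawn_config(config: SimulationConfig, index: int) -> SimulationConfig:
    """Copy of *config* with a child seed, for chunked long recordings."""
    if config.seed is None:
        return replace(config)
    child = np.random.SeedSequence(config.seed).spawn(index + 1)[index]
    return replace(config, seed=int(child.generate_state(1)[0] % (2**31)))
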