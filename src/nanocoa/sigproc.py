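"""Trace processing: filtering, decimation, event detection and features.

The processing chain mirrors standard resistive-pulse practice: the raw
current is low-pass filtered (zero-phase 4-pole Bessel), decimated with a
median-conserving scheme, and events are extracted as maximal runs of
samples below a threshold at 65% of the open-pore current. Each event is
summarized by its dwell time (duration) and mean current blockade, and can
be turned into a fixed-length normalized tensor for the CNN classifier.

Summary statistics of event populations are fitted with the distributions
they empirically follow: log-normal dwell times, normal blockade depths,
and a single-exponential survival model (with offset) for the dwell time
constant, bootstrapped for its uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import optimize, signal as sps, stats as spstats

from .trace import CurrentTrace

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# filtering / decimation / baseline


def bessel_sos(cutoff: float, sampling_rate: float, order: int = 4) -> np.ndarray:
    """Second-order sections of the digital Bessel low-pass used throughout."""
    if not 0 < cutoff < sampling_rate / 2:
        raise ValueError("cutoff must lie strictly between 0 and the Nyquist frequency")
    return sps.bessel(order, cutoff, btype="low", fs=sampling_rate, output="sos", norm="mag")


def lowpass_filter(trace: CurrentTrace, cutoff: float, order: int = 4) -> CurrentTrace:
    """Zero-phase (forward-backward) Bessel low-pass; DC gain 1.

    Forward-backward application keeps event boundaries unshifted at the
    cost of squaring the magnitude response.
    """
    sos = bessel_sos(cutoff, trace.sampling_rate, order=order)
    filtered = sps.sosfiltfilt(sos, trace.samples)
    out = trace.with_samples(filtered)
    out.metadata = {**out.metadata, "digital_filter_hz": cutoff}
    return out


def decimate_median(trace: CurrentTrace, target_rate: float) -> CurrentTrace:
    """Median-conserving decimation to (approximately) *target_rate*.

    The trace is cut into consecutive windows whose lengths follow the
    repeating pattern implied by the rational ratio sampling_rate /
    target_rate (e.g. 500 kHz -> 80 kHz gives the window pattern
    [6, 6, 6, 7], mean 6.25); each output sample is the median of one
    window, which suppresses isolated outlier samples.
    """
    if not target_rate > 0:
        raise ValueError("target_rate must be positive")
    if not target_rate < trace.sampling_rate:
        raise ValueError("target_rate must be below the current sampling rate")
    ratio = Fraction(trace.sampling_rate / target_rate).limit_denominator(10_000)
    q, p = ratio.numerator, ratio.denominator  # q input samples per p output samples
    n = trace.n_samples
    m = (n * p) // q  # number of complete windows
    bounds = (np.arange(m + 1, dtype=np.int64) * q) // p
    widths = np.diff(bounds)
    out = np.empty(m)
    for w in np.unique(widths):
        idx = np.flatnonzero(widths == w)
        block = trace.samples[bounds[idx, None] + np.arange(w)]
        out[idx] = np.median(block, axis=1)
    new_rate = trace.sampling_rate * p / q
    return trace.with_samples(out, sampling_rate=new_rate)


def estimate_open_pore(trace: CurrentTrace, baseline_frac: float = 0.8) -> float:
    """Estimate the open-pore (baseline) current of a trace, in pA.

    Robust to event content: the estimate is the median of all samples
    above ``baseline_frac`` times a high-quantile anchor (the 90th
    percentile), so blockade samples do not enter the estimate.

    Raises
    ------
    ValueError
        If the trace is dominated by blockades (more than half of the
        samples below ``baseline_frac`` x anchor) or the estimate is not
        positive (degenerate input).
    """
    anchor = float(np.percentile(trace.samples, 90))
    if not anchor > 0:
        raise ValueError("cannot estimate open-pore current: trace has no positive baseline level")
    mask = trace.samples > baseline_frac * anchor
    if np.count_nonzero(~mask) > trace.n_samples / 2:
        raise ValueError(
            "trace dominated by blockades: more than 50% of samples below "
            f"{baseline_frac:.0%} of the baseline anchor"
        )
    open_pore = float(np.median(trace.samples[mask]))
    if not open_pore > 0:
        raise ValueError("estimated open-pore current is not positive")
    return open_pore


# ---------------------------------------------------------------------------
# event detection


@dataclass
class TranslocationEvent:
    """One detected current blockade (resistive pulse)."""

    start: int  # sample index, inclusive (in the analyzed trace's grid)
    end: int  # sample index, exclusive
    duration: float  # s
    delta_i: float  # mean current blockade, pA
    rel_blockade: float  # delta_i / open-pore current
    trace_id: str | None = None

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("event must satisfy end > start")
        if not self.duration > 0:
            raise ValueError("event duration must be positive")


def detect_events(
    trace: CurrentTrace,
    open_pore: float,
    threshold_frac: float = 0.65,
    min_event_samples: int = 2,
) -> list[TranslocationEvent]:
    """Extract events as maximal runs of samples below the threshold.

    The threshold sits at ``threshold_frac`` (default 65%) of the
    open-pore current; samples exactly at the threshold count as baseline.
    Runs shorter than ``min_event_samples`` are discarded as single-sample
    noise spikes.
    """
    if not open_pore > 0:
        raise ValueError("open_pore must be positive")
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must lie in (0, 1)")
    threshold = threshold_frac * open_pore
    below = trace.samples < threshold
    edges = np.flatnonzero(np.diff(np.concatenate(([False], below, [False]))))
    starts, ends = edges[::2], edges[1::2]
    events: list[TranslocationEvent] = []
    for s, e in zip(starts, ends):
        if e - s < min_event_samples:
            continue
        seg = trace.samples[s:e]
        delta_i = open_pore - float(np.mean(seg))
        events.append(
            TranslocationEvent(
                start=int(s),
                end=int(e),
                duration=(e - s) / trace.sampling_rate,
                delta_i=delta_i,
                rel_blockade=delta_i / open_pore,
                trace_id=trace.trace_id,
            )
        )
    return events


# ---------------------------------------------------------------------------
# classifier input tensors


def log_duration_stats(durations: np.ndarray) -> tuple[float, float]:
    """Mean and SD of log10 duration, for z-scoring the duration feature.

    Computed on the *training* set and reused verbatim at prediction time.
    """
    ld = np.log10(np.asarray(durations, dtype=float))
    sd = float(np.std(ld))
    if sd == 0:
        sd = 1.0
    return float(np.mean(ld)), sd


def to_event_tensor(
    trace: CurrentTrace,
    event: TranslocationEvent,
    flank: int = 47,
    width: int = 250,
    duration_stats: tuple[float, float] | None = None,
) -> np.ndarray | None:
    """Fixed-length normalized classifier input for one event.

    The event segment plus ``flank`` baseline points on each side is
    centered on the mean of the two flank regions (so normalized flanks
    average ~0, encoding the relative blockade), scaled by the segment's
    standard deviation, right-padded with zeros to ``width`` points, and
    the log10-transformed event duration (z-scored with the training-set
    ``duration_stats`` when given) is appended as the final feature.

    Returns ``None`` (with a logged warning) for events too close to the
    trace edge or longer than ``width - 2 * flank`` samples.
    """
    n_event = event.end - event.start
    if n_event > width - 2 * flank:
        logger.warning(
            "event at sample %d is %d samples long; exceeds tensor capacity %d -> skipped",
            event.start, n_event, width - 2 * flank,
        )
        return None
    if event.start < flank or event.end + flank > trace.n_samples:
        logger.warning("event at sample %d within %d samples of the trace edge -> skipped", event.start, flank)
        return None
    seg = trace.samples[event.start - flank : event.end + flank]
    flanks = np.concatenate([seg[:flank], seg[-flank:]])
    sd = float(np.std(seg))
    if sd == 0:
        logger.warning("event at sample %d has zero segment variance -> skipped", event.start)
        return None
    normalized = (seg - float(np.mean(flanks))) / sd
    out = np.zeros(width + 1)
    out[: normalized.size] = normalized
    feat = np.log10(event.duration)
    if duration_stats is not None:
        mu, s = duration_stats
        feat = (feat - mu) / s
    out[-1] = feat
    return out


def events_to_tensors(
    trace: CurrentTrace,
    events: list[TranslocationEvent],
    flank: int = 47,
    width: int = 250,
    duration_stats: tuple[float, float] | None = None,
) -> tuple[np.ndarray, list[TranslocationEvent], int]:
    """Tensorize all events of a trace; returns (X, kept events, n skipped)."""
    tensors, kept = [], []
    n_skipped = 0
    for ev in events:
        t = to_event_tensor(trace, ev, flank=flank, width=width, duration_stats=duration_stats)
        if t is None:
            n_skipped += 1
        else:
            tensors.append(t)
            kept.append(ev)
    X = np.vstack(tensors) if tensors else np.empty((0, width + 1))
    return X, kept, n_skipped


# ---------------------------------------------------------------------------
# distribution fits


@dataclass
class DurationFit:
    """Maximum-likelihood log-normal fit of event dwell times."""

    location: float  # mean of log duration
    scale: float  # SD of log duration
    mean: float  # arithmetic mean, s
    sd: float  # arithmetic SD, s
    n: int
    ks_statistic: float


@dataclass
class BlockadeFit:
    """Maximum-likelihood normal fit of blockade depths."""

    mean: float  # pA
    sd: float  # pA
    n: int


@dataclass
class BootstrapResult:
    """Bootstrapped single-exponential dwell time constant."""

    tau: float  # s, mean over resamples
    tau_sd: float  # s, SD over resamples (the reported uncertainty)
    t0: float  # s, mean fitted offset
    n_resamples: int
    n_failed: int


def _check_fit_input(values: np.ndarray, minimum: int, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.size < minimum:
        raise ValueError(f"need at least {minimum} {name} values, got {values.size}")
    if np.ptp(values) == 0:
        raise ValueError(f"degenerate {name} sample: all values equal (zero variance)")
    return values


def fit_duration_lognormal(durations: np.ndarray) -> DurationFit:
    """ML log-normal fit; also reports the implied arithmetic mean/SD."""
    durations = _check_fit_input(durations, 10, "duration")
    if np.any(durations <= 0):
        raise ValueError("durations must be positive")
    ld = np.log(durations)
    mu = float(np.mean(ld))
    sigma = float(np.std(ld))
    mean = float(np.exp(mu + sigma**2 / 2))
    sd = float(mean * np.sqrt(np.expm1(sigma**2)))
    ks = spstats.kstest(durations, spstats.lognorm(s=sigma, scale=np.exp(mu)).cdf).statistic
    return DurationFit(location=mu, scale=sigma, mean=mean, sd=sd, n=durations.size, ks_statistic=float(ks))


def fit_blockade_normal(blockades: np.ndarray) -> BlockadeFit:
    """ML normal fit of blockade depths."""
    blockades = _check_fit_input(blockades, 10, "blockade")
    return BlockadeFit(mean=float(np.mean(blockades)), sd=float(np.std(blockades)), n=blockades.size)


def _fit_shifted_exponential(durations: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of S(t) = exp(-(t - t0)/tau) to the empirical survival."""
    t = np.sort(durations)
    surv = 1.0 - np.arange(t.size) / t.size  # S(t_i-) = P(T >= t_i)
    t0_init = float(t[0])
    tau_init = max(float(np.mean(t) - t[0]), 1e-12)

    def model(x, tau, t0):
        return np.exp(-np.clip(x - t0, 0.0, None) / tau)

    popt, _ = optimize.curve_fit(
        model, t, surv, p0=(tau_init, t0_init), maxfev=2000,
        bounds=((1e-15, -np.inf), (np.inf, np.inf)),
    )
    return float(popt[0]), float(popt[1])


def bootstrap_duration(
    durations: np.ndarray,
    n_resamples: int = 1000,
    seed: int | None = None,
) -> BootstrapResult:
    """Bootstrap the dwell time constant of a shifted-exponential survival.

    Each resample (same size, with replacement) is fitted with
    S(t) = exp(-(t - t0)/tau), tau and t0 free; the reported uncertainty is
    the SD of the bootstrapped time constants. Resamples whose fit does not
    converge are dropped; more than 10% failures is an error.
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size < 20:
        raise ValueError("need at least 20 durations to bootstrap")
    rng = np.random.default_rng(seed)
    taus, t0s = [], []
    n_failed = 0
    for _ in range(n_resamples):
        resample = rng.choice(durations, size=durations.size, replace=True)
        try:
            tau, t0 = _fit_shifted_exponential(resample)
        except RuntimeError:
            n_failed += 1
            continue
        taus.append(tau)
        t0s.append(t0)
    if n_failed > 0.1 * n_resamples:
        raise RuntimeError(f"{n_failed}/{n_resamples} bootstrap fits failed to converge")
    if n_failed:
        logger.warning("%d/%d bootstrap fits dropped (non-convergence)", n_failed, n_resamples)
    return BootstrapResult(
        tau=float(np.mean(taus)),
        tau_sd=float(np.std(taus)),
        t0=float(np.mean(t0s)),
        n_resamples=n_resamples,
        n_failed=n_failed,
    )
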