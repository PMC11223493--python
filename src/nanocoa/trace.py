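"""Ionic-current trace container.

A :class:`CurrentTrace` is the raw input of the whole workflow: a uniformly
sampled ionic current (in pA) through a single protein nanopore, together
with the acquisition metadata needed downstream (sampling rate, applied
bias, analyte annotations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CurrentTrace:
    """A sampled ionic-current recording.

    Parameters
    ----------
    samples
        Current samples in pA.
    sampling_rate
        Acquisition rate in Hz (samples per second).
    voltage
        Applied bias in mV, if known.
    metadata
        Free-form annotations (analyte, concentration in uM, hardware
        filter cutoff in Hz, ...). Unknown keys are preserved by I/O.
    trace_id
        Identifier used to group events by their source recording.
    """

    samples: np.ndarray
    sampling_rate: float
    voltage: float | None = None
    metadata: dict = field(default_factory=dict)
    trace_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace length in seconds."""
        return self.n_samples / self.sampling_rate

    def time(self) -> np.ndarray:
        """Per-sample time axis in seconds (starting at 0)."""
        return np.arange(self.n_samples) / self.sampling_rate

    def with_samples(self, samples: np.ndarray, sampling_rate: float | None = None) -> "CurrentTrace":
        """Copy of this trace with new samples (and optionally a new rate)."""
        return CurrentTrace(
            samples=samples,
            sampling_rate=self.sampling_rate if sampling_rate is None else sampling_rate,
            voltage=self.voltage,
            metadata=dict(self.metadata),
            trace_id=self.trace_id,
        )
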