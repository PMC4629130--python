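"""Spike-train extraction and firing-rate statistics for single-sensillum
recordings (SSR).

The quantification chain follows the conventional SSR protocol for insect
olfaction: action potentials are detected extracellularly from the sensillum
shaft, counted in a 500 ms window before and after stimulus onset, and the
baseline-subtracted count difference is doubled to give a response in
spikes/s.  Temporal structure is summarized as a peristimulus time
histogram (PSTH) with 100 ms bins over the 2 s following onset.

All neurons housed in a sensillum are pooled: whole-sensillum rates are the
quantity of interest, so no spike sorting into units is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    DegenerateThresholdError,
    InsufficientBaselineError,
    InvalidBinningError,
    InvalidParameterError,
    OutOfRangeError,
)

#: response / baseline counting window (s); the conventional SSR half-second
COUNT_WINDOW_S = 0.5


@dataclass
class VoltageTrace:
    """Single-channel extracellular voltage recording.

    Parameters
    ----------
    samples : array of float
        Amplitudes in µV.
    sampling_rate : float
        Samples per second (the reference acquisitions run at 96 kHz).
    stimulus_onset : float or None
        Time of odor onset in seconds from the start of the trace.
    stimulus_duration : float
        Odor pulse length in seconds; 0.5 s by convention.
    """

    samples: np.ndarray
    sampling_rate: float
    stimulus_onset: float | None = None
    stimulus_duration: float = 0.5
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InvalidParameterError("trace must be a 1-D sample array")
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be positive")
        if self.stimulus_onset is not None and not (
            0.0 <= self.stimulus_onset < self.duration
        ):
            raise InvalidParameterError(
                "stimulus_onset must lie within the trace"
            )

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass
class SpikeTrain:
    """Timestamped action potentials from one recording.

    ``spike_times`` are seconds from the start of the recording, strictly
    increasing, all within ``[0, duration)``.
    """

    spike_times: np.ndarray
    duration: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.duration <= 0:
            raise InvalidParameterError("duration must be positive")
        t = self.spike_times
        if t.size:
            if t[0] < 0 or t[-1] >= self.duration:
                raise InvalidParameterError(
                    "spike times must lie in [0, duration)"
                )
            if np.any(np.diff(t) <= 0):
                raise InvalidParameterError(
                    "spike times must be strictly increasing"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class PSTH:
    """Peristimulus time histogram anchored at stimulus onset.

    ``counts[i]`` is the number of spikes in the half-open bin
    ``[onset + i*bin_width, onset + (i+1)*bin_width)``.
    """

    counts: np.ndarray
    bin_width: float = 0.1
    window: float = 2.0
    onset: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        n = int(round(self.window / self.bin_width))
        if self.counts.size != n:
            raise InvalidBinningError(
                f"expected {n} bins for window {self.window} s at "
                f"{self.bin_width} s, got {self.counts.size}"
            )

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def rates(self) -> np.ndarray:
        """Per-bin firing rates in spikes/s."""
        return self.counts / self.bin_width

    @property
    def bin_edges(self) -> np.ndarray:
        return self.onset + self.bin_width * np.arange(self.n_bins + 1)


def detect_spikes(
    trace: VoltageTrace,
    threshold_k: float = 5.0,
    refractory: float = 0.002,
    polarity: str = "negative",
    absolute_threshold: float | None = None,
) -> SpikeTrain:
    """Detect spikes by adaptive amplitude thresholding.

    The threshold is ``threshold_k`` times a robust estimate of the noise
    standard deviation (median absolute deviation scaled by 1.4826), so it
    tolerates amplitude drift and does not require a noise-free segment.  A
    spike is recorded at each local extremum of a supra-threshold excursion;
    extrema closer than ``refractory`` seconds to a larger accepted peak are
    suppressed.

    Parameters
    ----------
    threshold_k : float
        Threshold in units of the robust noise SD (ignored when
        ``absolute_threshold`` is given).
    refractory : float
        Minimum separation between detected spikes, in seconds.
    polarity : {"negative", "positive", "both"}
        Which excursions count as spikes.
    absolute_threshold : float, optional
        Threshold in µV; required for noiseless traces where the adaptive
        scale degenerates to zero.
    """
    if polarity not in ("negative", "positive", "both"):
        raise InvalidParameterError(f"unknown polarity {polarity!r}")
    x = trace.samples
    if x.size == 0:
        raise InvalidParameterError("empty trace")
    if absolute_threshold is None:
        if threshold_k <= 0:
            raise InvalidParameterError("threshold_k must be positive")
        mad = np.median(np.abs(x - np.median(x)))
        sigma = 1.4826 * mad
        if sigma == 0.0:
            raise DegenerateThresholdError(
                "robust noise scale is zero (flat or noiseless trace); "
                "pass absolute_threshold instead"
            )
        threshold = threshold_k * sigma
    else:
        if absolute_threshold <= 0:
            raise InvalidParameterError("absolute_threshold must be positive")
        threshold = absolute_threshold

    if polarity == "negative":
        y = -x
    elif polarity == "positive":
        y = x
    else:
        y = np.abs(x)
    distance = max(1, int(round(refractory * trace.sampling_rate)))
    peaks, _ = find_peaks(y, height=threshold, distance=distance)
    times = peaks / trace.sampling_rate
    meta = dict(trace.metadata)
    meta.setdefault("stimulus_onset", trace.stimulus_onset)
    return SpikeTrain(times, duration=trace.duration, metadata=meta)


def count_window(train: SpikeTrain, start: float, width: float) -> int:
    """Number of spikes in the half-open window ``[start, start + width)``.

    The half-open convention makes adjacent windows partition the recording
    with no double counting; a spike exactly at ``start + width`` belongs to
    the next window.
    """
    if width <= 0:
        raise InvalidParameterError("window width must be positive")
    if start < 0 or start + width > train.duration + 1e-12:
        raise OutOfRangeError(
            f"window [{start}, {start + width}) outside recording "
            f"[0, {train.duration}]"
        )
    lo, hi = np.searchsorted(train.spike_times, [start, start + width], "left")
    return int(hi - lo)


def firing_rate(train: SpikeTrain, onset: float) -> float:
    """Baseline-subtracted response rate in spikes/s.

    Counts spikes in the 500 ms before and after ``onset`` and returns
    ``(post - pre) * 2``, the count difference converted to spikes/s.
    Negative values are meaningful (inhibitory responses) and are not
    clipped.
    """
    if onset < COUNT_WINDOW_S:
        raise InsufficientBaselineError(
            "onset must be >= 0.5 s so a full pre-stimulus window exists"
        )
    pre = count_window(train, onset - COUNT_WINDOW_S, COUNT_WINDOW_S)
    post = count_window(train, onset, COUNT_WINDOW_S)
    return (post - pre) / COUNT_WINDOW_S


def compute_psth(
    train: SpikeTrain,
    onset: float,
    window: float = 2.0,
    bin_width: float = 0.1,
) -> PSTH:
    """Bin spikes into a PSTH over ``[onset, onset + window)``.

    Defaults give 20 bins of 100 ms over the 2 s following stimulus onset.
    Bin counts sum exactly to ``count_window(train, onset, window)``.
    """
    n_bins = window / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise InvalidBinningError(
            f"window {window} s is not an integer multiple of "
            f"bin width {bin_width} s"
        )
    n_bins = int(round(n_bins))
    if onset < 0 or onset + window > train.duration + 1e-12:
        raise OutOfRangeError("PSTH window extends beyond the recording")
    edges = onset + bin_width * np.arange(n_bins + 1)
    idx = np.searchsorted(train.spike_times, edges, "left")
    counts = np.diff(idx)
    return PSTH(counts, bin_width=bin_width, window=window, onset=onset)


def warn_overlapping(train: SpikeTrain, width_s: float) -> bool:
    """Warn if any inter-spike interval is shorter than a template width."""
    isi = np.diff(train.spike_times)
    if isi.size and np.any(isi < width_s):
        warnings.warn(
            "spikes closer than the template width; waveforms will overlap "
            "additively",
            stacklevel=3,
        )
        return True
    return False
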