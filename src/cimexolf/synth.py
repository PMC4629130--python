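"""Seeded synthetic-data generator for the whole quantification chain.

Every analysis stage in this package can be exercised offline against
simulated inputs whose statistical structure matches what the real assays
produce:

* **Spike trains** are sampled from an inhomogeneous Poisson process by
  thinning, with a hard 2 ms refractory period.  The instantaneous rate is
  a spontaneous baseline plus a dose- and time-dependent evoked component:
  the evoked amplitude follows a Hill function of the stimulus dose, and
  the time course is either *phasic* (exponential decay from onset) or
  *tonic* (sustained through the 500 ms stimulus, then a slow decay, so
  firing stays elevated through the 2 s analysis window).
* **Voltage traces** render a spike waveform template at each spike time
  plus white Gaussian noise, reproducing the geometry of the reference
  acquisitions (e.g. 10 s at 96 kHz -> 960 000 samples).
* **Response matrices** run the replicate protocol in silico: >= 6 seeded
  replicates per odorant-sensillum pair at a reference dose, scored with
  the same baseline-subtracted 500 ms counting rule the analysis uses.
* **Oocyte current traces** show a baseline, an inward (negative) current
  deflection with Hill-scaled peak amplitude, exponential desensitization
  and washout, for voltage-clamp amplitude extraction and EC50 fitting.

Because the refractory period deletes events, naive thinning at rate *r*
realizes a lower observed rate.  The generator compensates exactly for the
non-paralyzable dead time *d* by driving the thinning at
``lambda = r / (1 - r*d)``, whose observed steady-state rate is
``lambda / (1 + lambda*d) = r``.  Configured rates are therefore realized
rates, which is what every Monte-Carlo calibration in the test-suite
checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError
from .spikes import SpikeTrain, VoltageTrace, warn_overlapping

#: hard refractory period (s) for spike generation
REFRACTORY_S = 0.002
#: slow decay constant (s) applied to tonic responses after stimulus offset
TONIC_OFFSET_TAU_S = 2.0

_KERNELS = ("phasic", "tonic")


@dataclass(frozen=True)
class ResponseProfile:
    """Generative description of one odorant-sensillum interaction.

    Parameters
    ----------
    sensillum_type : str
        One of the six sensillum tokens (Da, Db, Dg, C, E1, E2).
    odorant_id : str
    baseline_rate : float
        Spontaneous firing rate, spikes/s.
    max_evoked_rate : float
        Saturating evoked rate increment, spikes/s.
    kernel : {"phasic", "tonic"}
        Temporal shape of the evoked component.
    phasic_decay_constant : float, optional
        Exponential decay constant (s); required iff kernel is phasic.
    ec50_dose : float
        Hill midpoint on the dose axis (log10 v/v dilution for SSR).
    hill_coefficient : float
        Hill slope, > 0.
    """

    sensillum_type: str
    odorant_id: str
    baseline_rate: float
    max_evoked_rate: float
    kernel: str = "tonic"
    phasic_decay_constant: float | None = None
    ec50_dose: float = -3.0
    hill_coefficient: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.max_evoked_rate < 0:
            raise InvalidParameterError("rates must be non-negative")
        if self.kernel not in _KERNELS:
            raise InvalidParameterError(f"unknown kernel {self.kernel!r}")
        if self.kernel == "phasic":
            if self.phasic_decay_constant is None or (
                self.phasic_decay_constant <= 0
            ):
                raise InvalidParameterError(
                    "phasic kernel requires phasic_decay_constant > 0"
                )
        if self.hill_coefficient <= 0:
            raise InvalidParameterError("hill_coefficient must be positive")

    def evoked_amplitude(self, dose: float) -> float:
        """Evoked rate increment (spikes/s) at a log10 dose via the Hill law."""
        return self.max_evoked_rate / (
            1.0 + 10.0 ** (self.hill_coefficient * (self.ec50_dose - dose))
        )

    def rate(
        self,
        t: np.ndarray,
        dose: float,
        stimulus_onset: float,
        stimulus_duration: float = 0.5,
    ) -> np.ndarray:
        """Instantaneous firing rate r(t) in spikes/s."""
        t = np.asarray(t, dtype=float)
        s = t - stimulus_onset
        k = np.zeros_like(t)
        on = s >= 0
        if self.kernel == "phasic":
            k[on] = np.exp(-s[on] / self.phasic_decay_constant)
        else:
            sustained = on & (s <= stimulus_duration)
            decay = on & (s > stimulus_duration)
            k[sustained] = 1.0
            k[decay] = np.exp(
                -(s[decay] - stimulus_duration) / TONIC_OFFSET_TAU_S
            )
        return self.baseline_rate + self.evoked_amplitude(dose) * k


@dataclass(frozen=True)
class SpikeTemplate:
    """Extracellular spike waveform used to render voltage traces."""

    waveform: np.ndarray
    sampling_rate: float
    polarity: str = "negative"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "waveform", np.asarray(self.waveform, dtype=float)
        )
        if self.waveform.size < 3:
            raise InvalidParameterError("waveform too short")
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be positive")
        if self.polarity not in ("negative", "positive"):
            raise InvalidParameterError("polarity must be negative|positive")
        peak = self.waveform.min() if self.polarity == "negative" else (
            self.waveform.max()
        )
        if abs(peak) < np.abs(self.waveform).max() * (1 - 1e-9):
            raise InvalidParameterError(
                "dominant extremum must match the declared polarity"
            )

    @property
    def width_s(self) -> float:
        return self.waveform.size / self.sampling_rate

    @property
    def peak_amplitude(self) -> float:
        return float(np.abs(self.waveform).max())

    @property
    def peak_index(self) -> int:
        """Sample offset of the dominant extremum within the waveform."""
        if self.polarity == "negative":
            return int(np.argmin(self.waveform))
        return int(np.argmax(self.waveform))


def make_template(
    sampling_rate: float,
    width_ms: float = 1.2,
    amplitude_uv: float = 100.0,
    polarity: str = "negative",
) -> SpikeTemplate:
    """Build a biphasic spike template with its dominant lobe at the center.

    The waveform is a main Gaussian lobe at the center sample plus a smaller
    opposite-polarity after-lobe, which is a reasonable cartoon of an
    extracellular action potential and keeps the detected peak aligned with
    the generating spike time.
    """
    n = int(round(width_ms / 1000.0 * sampling_rate))
    n = max(n | 1, 5)  # odd, so a center sample exists
    i = np.arange(n) - n // 2
    sigma = n / 8.0
    main = np.exp(-0.5 * (i / sigma) ** 2)
    after = 0.35 * np.exp(-0.5 * ((i - n / 4.0) / (1.5 * sigma)) ** 2)
    w = amplitude_uv * (main - after)
    if polarity == "negative":
        w = -w
    return SpikeTemplate(w, sampling_rate, polarity)


def _compensated_intensity(rate: np.ndarray | float, refractory: float):
    """Thinning intensity realizing ``rate`` under non-paralyzable dead time."""
    if refractory == 0:
        return rate
    load = np.asarray(rate) * refractory
    if np.any(load >= 0.9):
        raise InvalidParameterError(
            "requested rate too close to the refractory limit "
            f"(1/{refractory} spikes/s)"
        )
    return rate / (1.0 - load)


def gen_spike_train(
    profile: ResponseProfile,
    dose: float,
    duration: float,
    stimulus_onset: float,
    stimulus_duration: float = 0.5,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    refractory: float = REFRACTORY_S,
) -> SpikeTrain:
    """Sample one spike train from a response profile.

    Inhomogeneous Poisson thinning: candidate events are drawn from a
    homogeneous process at the peak compensated intensity, accepted with
    probability proportional to the local intensity, then filtered through
    the hard refractory period.  Identical inputs and seed reproduce the
    identical train.

    ``duration`` must leave at least 2 s after onset so the full PSTH
    analysis window exists.
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")
    if stimulus_onset <= 0 or stimulus_duration <= 0:
        raise InvalidParameterError("onset and stimulus duration must be > 0")
    if duration < stimulus_onset + 2.0 - 1e-9:
        raise InvalidParameterError(
            "duration must extend >= 2 s beyond stimulus onset"
        )
    rng = np.random.default_rng(seed)
    peak_rate = profile.baseline_rate + profile.evoked_amplitude(dose)
    lam_max = float(_compensated_intensity(peak_rate, refractory))
    if lam_max <= 0:
        return SpikeTrain(np.empty(0), duration, _train_meta(profile, dose))
    n_cand = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, n_cand))
    u = rng.uniform(size=n_cand)
    lam = _compensated_intensity(
        profile.rate(cand, dose, stimulus_onset, stimulus_duration),
        refractory,
    )
    accepted = cand[u < lam / lam_max]
    if refractory > 0 and accepted.size:
        kept = []
        last = -np.inf
        for t in accepted:
            if t - last >= refractory:
                kept.append(t)
                last = t
        accepted = np.asarray(kept)
    meta = _train_meta(profile, dose)
    meta["stimulus_onset"] = stimulus_onset
    meta["stimulus_duration"] = stimulus_duration
    return SpikeTrain(accepted, duration, meta)


def _train_meta(profile: ResponseProfile, dose: float) -> dict:
    return {
        "sensillum_type": profile.sensillum_type,
        "odorant_id": profile.odorant_id,
        "dose": dose,
        "kernel": profile.kernel,
    }


def gen_voltage_trace(
    train: SpikeTrain,
    template: SpikeTemplate,
    sampling_rate: float = 96000.0,
    noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> VoltageTrace:
    """Render a spike train as an extracellular voltage trace.

    The template is added at the sample index nearest each spike time (its
    dominant extremum lands on that index) on top of white Gaussian noise of
    SD ``noise_sd`` µV.  Overlapping templates raise a warning and are
    summed.
    """
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be non-negative")
    if sampling_rate != template.sampling_rate:
        raise InvalidParameterError(
            "template was built for a different sampling rate"
        )
    nyquist_width = 2.0 / sampling_rate
    if template.width_s < nyquist_width:
        raise InvalidParameterError("sampling rate too low for the template")
    n = int(round(train.duration * sampling_rate))
    rng = np.random.default_rng(seed)
    x = (
        rng.normal(0.0, noise_sd, n)
        if noise_sd > 0
        else np.zeros(n, dtype=float)
    )
    warn_overlapping(train, template.width_s)
    w = template.waveform
    for t in train.spike_times:
        center = int(round(t * sampling_rate))
        start = center - template.peak_index
        stop = start + w.size
        lo, hi = max(start, 0), min(stop, n)
        if lo < hi:
            x[lo:hi] += w[lo - start : hi - start]
    meta = dict(train.metadata)
    return VoltageTrace(
        x,
        sampling_rate,
        stimulus_onset=meta.get("stimulus_onset"),
        stimulus_duration=meta.get("stimulus_duration", 0.5),
        metadata=meta,
    )


def gen_response_matrix(
    profiles,
    classes: dict,
    n_replicates: int = 6,
    dose: float = -2.0,
    seed: int = 0,
    stimulus_onset: float = 1.0,
    duration: float = 3.5,
    stimulus_duration: float = 0.5,
):
    """Run the replicate SSR protocol in silico and assemble the matrix.

    For every profile, ``n_replicates`` independent seeded trains are drawn
    at the reference ``dose`` and scored with the baseline-subtracted
    500 ms counting rule.  Returns ``(ResponseMatrix, records)`` where
    ``records`` is the tidy per-replicate rate table (columns: odorant,
    odorant_class, sensillum, replicate, spikes_per_s).

    The profile set must cover all six sensillum types and every odorant
    must appear in ``classes``.
    """
    import pandas as pd

    from .errors import SchemaError
    from .panel import SENSILLA
    from .spikes import firing_rate
    from .tuning import build_response_matrix

    profiles = sorted(
        profiles, key=lambda p: (p.odorant_id, p.sensillum_type)
    )
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    present = {p.sensillum_type for p in profiles}
    missing = set(SENSILLA) - present
    if missing:
        raise SchemaError(f"profiles missing sensillum types: {missing}")
    for p in profiles:
        if p.odorant_id not in classes:
            raise SchemaError(f"odorant {p.odorant_id!r} has no class label")

    streams = np.random.SeedSequence(seed).spawn(len(profiles) * n_replicates)
    rows = []
    k = 0
    for p in profiles:
        for rep in range(n_replicates):
            train = gen_spike_train(
                p,
                dose=dose,
                duration=duration,
                stimulus_onset=stimulus_onset,
                stimulus_duration=stimulus_duration,
                seed=streams[k],
            )
            k += 1
            rows.append(
                {
                    "odorant": p.odorant_id,
                    "odorant_class": classes[p.odorant_id],
                    "sensillum": p.sensillum_type,
                    "replicate": rep,
                    "spikes_per_s": firing_rate(train, stimulus_onset),
                }
            )
    records = pd.DataFrame(rows)
    matrix = build_response_matrix(records, dose_label=f"1:10^{-dose:g} v/v")
    return matrix, records


@dataclass
class OocyteCurrentTrace:
    """Whole-cell current trace from a voltage-clamped oocyte.

    ``current`` is in nA (inward currents negative, holding at -80 mV);
    ``application_window`` marks the odorant perfusion interval in seconds.
    """

    time: np.ndarray
    current: np.ndarray
    application_window: tuple[float, float] | None
    dose: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time.shape != self.current.shape:
            raise InvalidParameterError("time and current must align")


def gen_current_trace(
    ec50: float,
    hill: float,
    emax: float,
    doses,
    desensitization_tau: float = 3.0,
    noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    sampling_rate: float = 200.0,
    pre_s: float = 2.0,
    application_s: float = 10.0,
    wash_s: float = 5.0,
    rise_s: float = 0.2,
    wash_tau: float = 0.5,
) -> list[OocyteCurrentTrace]:
    """Simulate one voltage-clamp dose series (one trace per dose).

    Each trace shows a flat baseline, an inward deflection whose noiseless
    peak is exactly ``emax / (1 + (ec50/dose)**hill)`` nA, exponential
    desensitization during the 10 s application, and washout back to
    baseline.  Doses are molar, positive and ascending.
    """
    doses = np.asarray(doses, dtype=float)
    if ec50 <= 0:
        raise InvalidParameterError("ec50 must be positive")
    if emax <= 0 or hill <= 0:
        raise InvalidParameterError("emax and hill must be positive")
    if doses.size == 0 or np.any(doses <= 0) or np.any(np.diff(doses) <= 0):
        raise InvalidParameterError("doses must be positive and ascending")
    if desensitization_tau <= 0:
        raise InvalidParameterError("desensitization_tau must be positive")
    dt = 1.0 / sampling_rate
    # snap segment boundaries to the sample grid so the peak sample exists
    pre_s = round(pre_s / dt) * dt
    rise_s = max(round(rise_s / dt), 1) * dt
    total = pre_s + application_s + wash_s
    t = np.arange(int(round(total / dt))) * dt
    rng = np.random.default_rng(seed)
    traces = []
    for d in doses:
        peak = emax / (1.0 + (ec50 / d) ** hill)
        s = t - pre_s
        shape = np.zeros_like(t)
        rising = (s >= 0) & (s < rise_s)
        desens = (s >= rise_s) & (s <= application_s)
        wash = s > application_s
        # raised-cosine rise: smooth approach to the peak (value exactly 1
        # at s = rise_s, which falls on the sample grid)
        shape[rising] = 0.5 * (1.0 - np.cos(np.pi * s[rising] / rise_s))
        shape[desens] = np.exp(-(s[desens] - rise_s) / desensitization_tau)
        end_level = np.exp(-(application_s - rise_s) / desensitization_tau)
        shape[wash] = end_level * np.exp(-(s[wash] - application_s) / wash_tau)
        current = -peak * shape
        if noise_sd > 0:
            current = current + rng.normal(0.0, noise_sd, t.size)
        traces.append(
            OocyteCurrentTrace(
                t,
                current,
                application_window=(pre_s, pre_s + application_s),
                dose=float(d),
                metadata={"ec50": ec50, "hill": hill, "emax": emax},
            )
        )
    return traces
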