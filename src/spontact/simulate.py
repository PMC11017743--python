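"""Forward simulation of in-vivo DRG calcium recordings with known truth.

The generator emulates the regime in which slow genetically encoded calcium
indicators (GCaMP6s) report spontaneous firing of sensory neurons: a minority
of neurons fire at low rates (< 1 Hz) as a homogeneous Poisson process, each
action potential produces a slow double-exponential fluorescence transient,
summed transients saturate near a ceiling, and the raw signal sits on a
per-neuron baseline corrupted by slow drift, recording-wide movement
artifacts and per-frame Gaussian noise.  A lidocaine-block event can silence
peripherally driven neurons mid-recording, and stimulus epochs can add
evoked transients — both with per-neuron ground truth recorded in
:class:`SimulationTruth`, so every downstream detector can be scored against
a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .trace import ACTIVE, INACTIVE, LabelSet, TraceMatrix

__all__ = [
    "GCaMPKernel",
    "SimulationConfig",
    "SimulationTruth",
    "generate_spike_trains",
    "render_fluorescence",
    "generate_benchmark",
    "generate_training_cohort",
    "COHORT_WORLDS",
]


@dataclass(frozen=True)
class GCaMPKernel:
    """Impulse response of a calcium indicator to one action potential.

    The kernel is a difference of exponentials,
    ``h(t) ∝ exp(−t/decay_tau) − exp(−t/rise_tau)``, scaled so its peak
    equals ``unit_amplitude`` (ΔF/F0 percent per spike).  Summed transients
    are soft-capped at ``saturation_ceiling``, reproducing the saturation of
    slow indicators under sustained firing (around 0.5 Hz for GCaMP6s in
    DRG neurons).
    """

    indicator_name: str = "GCaMP6s"
    rise_tau: float = 0.18        # s
    decay_tau: float = 1.5        # s
    unit_amplitude: float = 30.0  # % ΔF/F0 per action potential
    saturation_ceiling: float = 300.0  # % ΔF/F0, soft cap on summed transients

    def __post_init__(self) -> None:
        if not (self.rise_tau > 0 and self.decay_tau > 0):
            raise ValueError("time constants must be positive")
        if not self.decay_tau > self.rise_tau:
            raise ValueError("decay_tau must exceed rise_tau")
        if not self.unit_amplitude > 0:
            raise ValueError("unit_amplitude must be positive")
        if not self.saturation_ceiling > 0:
            raise ValueError("saturation_ceiling must be positive")

    @property
    def peak_time(self) -> float:
        """Time of the kernel maximum (closed form for the two-exponential)."""
        r, d = self.rise_tau, self.decay_tau
        return r * d / (d - r) * math.log(d / r)

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Kernel values at times ``t`` (seconds); zero for t < 0."""
        t = np.asarray(t, dtype=float)
        tt = np.maximum(t, 0.0)
        raw = np.exp(-tt / self.decay_tau) - np.exp(-tt / self.rise_tau)
        raw = np.where(t >= 0, raw, 0.0)
        peak = (math.exp(-self.peak_time / self.decay_tau)
                - math.exp(-self.peak_time / self.rise_tau))
        return self.unit_amplitude * raw / peak


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world for one synthetic recording.

    Defaults describe the benchmark regime: 200 neurons, a quarter of them
    spontaneously active at 0.1–0.5 Hz, 301 s at 3.65 Hz (1099 frames),
    Gaussian noise of 5 %ΔF/F0 equivalent, mild slow drift and occasional
    shared movement artifacts.
    """

    n_neurons: int = 200
    fraction_active: float = 0.25
    firing_rate_range: tuple[float, float] = (0.1, 0.5)  # Hz
    sampling_rate: float = 3.65   # Hz
    duration: float = 301.0       # s
    noise_sd: float = 5.0         # % ΔF/F0 equivalent, white per-frame
    slow_noise_sd: float = 2.0    # % ΔF/F0, correlated baseline fluctuation
    slow_noise_tau: float = 1.0   # s, its correlation time
    baseline_mean: float = 100.0  # a.u.
    baseline_sd: float = 20.0     # a.u.
    drift_amplitude: float = 0.02     # fraction of baseline
    artifact_rate: float = 0.5        # events / minute, shared across neurons
    artifact_amplitude: float = 0.05  # fraction of baseline
    lidocaine_time: float | None = None  # s
    evoked_epochs: tuple[tuple[float, float, float], ...] = ()
    evoked_amplitude: float = 100.0  # % ΔF/F0 of an evoked transient
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.firing_rate_range
        if hi < lo or lo <= 0:
            raise ValueError(
                f"invalid firing_rate_range ({lo}, {hi}): need 0 < low <= high")
        if not (0.0 <= self.fraction_active <= 1.0):
            raise ValueError("fraction_active must lie in [0, 1]")
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be positive")
        if self.duration * self.sampling_rate < 200:
            raise ValueError("duration × sampling_rate must be ≥ 200 frames")
        for onset, offset, p in self.evoked_epochs:
            if not (offset > onset >= 0):
                raise ValueError(f"bad evoked epoch ({onset}, {offset})")
            if not (0.0 <= p <= 1.0):
                raise ValueError("response_probability must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        """Frames on the grid t = 0, 1/rate, …, ≤ duration."""
        return int(math.floor(self.duration * self.sampling_rate)) + 1


@dataclass
class SimulationTruth:
    """Ground truth underlying one synthetic recording."""

    labels: list[str]                     # active / inactive, per neuron
    spike_times: list[np.ndarray]         # s, spontaneous spikes per neuron
    peripherally_driven: np.ndarray       # bool per neuron
    firing_rates: np.ndarray              # Hz per neuron (0 for inactive)
    evoked_responses: np.ndarray | None = None  # (n_neurons, n_epochs) bool
    neuron_ids: list[str] = field(default_factory=list)

    @property
    def n_neurons(self) -> int:
        return len(self.labels)

    def label_set(self) -> LabelSet:
        ids = self.neuron_ids or [f"n{i}" for i in range(self.n_neurons)]
        return LabelSet(dict(zip(ids, self.labels)), source="simulated_truth")


def generate_spike_trains(config: SimulationConfig) -> SimulationTruth:
    """Draw per-neuron spontaneous spike trains from the configured world.

    Exactly ``round(fraction_active × n_neurons)`` neurons are marked active;
    each gets a Poisson spike train at a rate drawn uniformly from
    ``firing_rate_range``.  Active neurons are peripherally driven, so if a
    lidocaine event is configured their spikes stop at ``lidocaine_time``.
    Active neurons are guaranteed at least one spike (pre-lidocaine), so the
    label and the spike train always agree.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_neurons
    n_active = int(round(config.fraction_active * n))
    active_idx = rng.choice(n, size=n_active, replace=False)
    is_active = np.zeros(n, dtype=bool)
    is_active[active_idx] = True

    lo, hi = config.firing_rate_range
    # window in which spikes can occur: up to lidocaine for driven neurons
    spike_horizon = (config.lidocaine_time
                     if config.lidocaine_time is not None else config.duration)

    labels: list[str] = []
    spikes: list[np.ndarray] = []
    rates = np.zeros(n)
    for i in range(n):
        if not is_active[i]:
            labels.append(INACTIVE)
            spikes.append(np.empty(0))
            continue
        rate = rng.uniform(lo, hi)
        rates[i] = rate
        for _ in range(100):
            count = rng.poisson(rate * config.duration)
            t = np.sort(rng.uniform(0.0, config.duration, size=count))
            t = t[t < spike_horizon]
            if t.size:  # active ⇔ ≥1 spontaneous spike, by contract
                break
        labels.append(ACTIVE)
        spikes.append(t)

    return SimulationTruth(
        labels=labels,
        spike_times=spikes,
        peripherally_driven=is_active.copy(),
        firing_rates=rates,
        neuron_ids=[f"n{i}" for i in range(n)],
    )


def _shared_artifact(rng: np.random.Generator, t: np.ndarray,
                     config: SimulationConfig) -> np.ndarray:
    """Recording-wide movement component: tapered random-walk bursts."""
    out = np.zeros_like(t)
    if config.artifact_rate <= 0 or config.artifact_amplitude <= 0:
        return out
    n_events = rng.poisson(config.artifact_rate * config.duration / 60.0)
    fs = config.sampling_rate
    for _ in range(n_events):
        onset = rng.uniform(0.0, config.duration)
        length = rng.uniform(0.5, 3.0)  # s
        n_burst = max(int(round(length * fs)), 2)
        i0 = int(round(onset * fs))
        if i0 >= t.size:
            continue
        walk = np.cumsum(rng.standard_normal(n_burst))
        taper = np.sin(np.linspace(0.0, np.pi, n_burst))  # returns to zero
        burst = walk * taper
        peak = np.max(np.abs(burst))
        if peak > 0:
            burst *= config.artifact_amplitude * rng.uniform(0.5, 1.5) / peak
        sl = slice(i0, min(i0 + n_burst, t.size))
        out[sl] += burst[: sl.stop - sl.start]
    return out


def render_fluorescence(truth: SimulationTruth, kernel: GCaMPKernel,
                        config: SimulationConfig) -> TraceMatrix:
    """Render raw fluorescence from spike trains through the forward model.

    raw[i, t] = b_i (1 + drift_i(t) + artifact(t) + u_i(t)) (1 + S_i(t)/100) + ε,
    where S_i is the spike train convolved with the indicator kernel
    (percent ΔF/F0), soft-capped at the saturation ceiling, plus any evoked
    transients; u_i is a correlated Ornstein-Uhlenbeck baseline fluctuation;
    ε is i.i.d. Gaussian with SD noise_sd·b_i/100 and frames are clipped at
    zero.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = truth.n_neurons
    t = np.arange(config.n_frames) / config.sampling_rate

    for st in truth.spike_times:
        if st.size and (st.min() < 0 or st.max() > config.duration):
            raise ValueError("spike times must lie within [0, duration]")

    # per-spike transients on the frame grid
    transients = np.zeros((n, t.size))
    for i, st in enumerate(truth.spike_times):
        for s in st:
            transients[i] += kernel.evaluate(t - s)

    # evoked responses: kernel-shaped transient at epoch onset
    n_epochs = len(config.evoked_epochs)
    responders = np.zeros((n, n_epochs), dtype=bool)
    for j, (onset, _offset, p) in enumerate(config.evoked_epochs):
        responders[:, j] = rng.uniform(size=n) < p
        shape = (config.evoked_amplitude / kernel.unit_amplitude
                 * kernel.evaluate(t - onset))
        transients[responders[:, j]] += shape
    truth.evoked_responses = responders if n_epochs else None

    np.minimum(transients, kernel.saturation_ceiling, out=transients)

    baselines = config.baseline_mean + config.baseline_sd * rng.standard_normal(n)
    baselines = np.maximum(baselines, 1e-3)

    # slow per-neuron drift: one sinusoid with random phase, period ~ recording
    phases = rng.uniform(0.0, 2 * np.pi, size=n)
    periods = config.duration * rng.uniform(0.8, 1.5, size=n)
    drift = config.drift_amplitude * np.sin(
        2 * np.pi * t[None, :] / periods[:, None] + phases[:, None])

    artifact = _shared_artifact(rng, t, config)

    # correlated per-neuron baseline fluctuation (hemodynamics, focus wobble):
    # stationary Ornstein-Uhlenbeck process, rate-independent by construction
    slow = np.zeros((n, t.size))
    if config.slow_noise_sd > 0:
        a = math.exp(-1.0 / (config.slow_noise_tau * config.sampling_rate))
        innov = (config.slow_noise_sd / 100.0) * math.sqrt(1.0 - a * a) \
            * rng.standard_normal((n, t.size))
        slow[:, 0] = (config.slow_noise_sd / 100.0) \
            * rng.standard_normal(n)
        for k in range(1, t.size):
            slow[:, k] = a * slow[:, k - 1] + innov[:, k]

    raw = (baselines[:, None] * (1.0 + drift + artifact[None, :] + slow)
           * (1.0 + transients / 100.0))
    if config.noise_sd > 0:
        raw = raw + (config.noise_sd / 100.0) * baselines[:, None] \
            * rng.standard_normal(raw.shape)
    np.clip(raw, 0.0, None, out=raw)

    return TraceMatrix(
        values=raw,
        sampling_rate=config.sampling_rate,
        neuron_ids=truth.neuron_ids or None,
        normalized=False,
        provenance=[{"step": "simulate", "seed": config.seed,
                     "indicator": kernel.indicator_name}],
    )


def generate_benchmark(
    config: SimulationConfig | None = None,
    kernel: GCaMPKernel | None = None,
) -> tuple[TraceMatrix, LabelSet, SimulationTruth]:
    """Simulate one recording and return (raw traces, truth labels, truth)."""
    config = config or SimulationConfig()
    kernel = kernel or GCaMPKernel()
    truth = generate_spike_trains(config)
    traces = render_fluorescence(truth, kernel, config)
    return traces, truth.label_set(), truth


# Noise worlds of the simulated training cohort: (white noise %ΔF/F0,
# slow-noise SD %ΔF/F0, slow-noise tau s, artifact events/min).  The spread
# emulates a realistic multi-animal cohort — quiet well-clamped preparations
# alongside movement-heavy and low-SNR ones — so classifiers cannot treat
# any single noise signature as the marker of inactivity.
COHORT_WORLDS: tuple[tuple[float, float, float, float], ...] = (
    (3.0, 2.0, 0.5, 0.3),
    (4.0, 6.0, 1.5, 0.5),
    (5.0, 3.0, 1.0, 0.5),
    (6.0, 10.0, 3.0, 1.0),
    (8.0, 2.0, 0.5, 1.0),
    (8.0, 8.0, 2.0, 1.5),
    (10.0, 4.0, 1.0, 2.0),
    (12.0, 6.0, 3.0, 1.0),
)


def generate_training_cohort(
    seed: int = 0,
    n_neurons: int = 100,
    kernel: GCaMPKernel | None = None,
    worlds: Sequence[tuple[float, float, float, float]] = COHORT_WORLDS,
) -> list[tuple[TraceMatrix, float, LabelSet]]:
    """Simulate a multi-animal lidocaine cohort for classifier training.

    Each entry is ``(raw traces, lidocaine_time, lidocaine verdicts)`` in the
    shape the training-set builder expects: recordings long enough for a
    pre-lidocaine head segment and a >5-minutes-post-lidocaine tail segment,
    with the block applied mid-recording.  Noise parameters vary across
    recordings per ``worlds``.
    """
    kernel = kernel or GCaMPKernel()
    out = []
    for i, (noise, slow, tau, art) in enumerate(worlds):
        config = SimulationConfig(
            n_neurons=n_neurons,
            duration=2 * 301.0 + 60.0,
            lidocaine_time=331.0,
            noise_sd=noise, slow_noise_sd=slow, slow_noise_tau=tau,
            artifact_rate=art,
            seed=(seed * 1009 + i) % (2 ** 31),
        )
        traces, labels, _truth = generate_benchmark(config, kernel)
        out.append((traces, config.lidocaine_time, labels))
    return out
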