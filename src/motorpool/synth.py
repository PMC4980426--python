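"""Synthetic data with the statistical structure the analyses assume.

Three generators:

* :func:`simulate_peristalsis` — multi-segment peristaltic contraction
  waves: per segment, a longitudinal (LO1-like) and a transverse (LT2-like)
  muscle-length trace. Contractions are smooth raised-cosine dips of the
  muscle length recurring at the wave frequency; the wave propagates from
  segment to segment with a programmable intersegmental delay, and within
  each segment the transverse muscle's contraction is shifted by a
  programmable intrasegmental phase lag (default 42 degrees of a cycle,
  the lag characteristic of forward crawling). Cycle-to-cycle period
  jitter and additive Gaussian noise emulate biological variability.

* :func:`simulate_calcium_traces` — the same segmental drive convolved with
  an exponential rise/decay kernel emulating a genetically encoded calcium
  indicator (GCaMP-like), with baseline and noise: per segment a reference
  motor-neuron trace (in phase with the segment's longitudinal drive) and a
  lagged interneuron trace.

* :func:`simulate_connectome` — a two-motor-neuron synapse-count graph with
  programmable presynaptic partner counts, shared-partner overlap, and a
  programmable Pearson correlation between the synapse counts that shared
  partners place onto the two neurons (lognormal weights coupled by a
  Gaussian copula on the log scale).

All generators are deterministic under their seed; random streams are split
per trace by a label hash so output does not depend on evaluation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .connectome import ConnectomeGraph, NeuronRecord, SynapticEdge
from .kinematics import MuscleLengthTrace
from .traces import TimeSeriesTrace

__all__ = [
    "PeristalsisConfig",
    "CalciumKernelConfig",
    "SyntheticConnectomeConfig",
    "simulate_peristalsis",
    "simulate_calcium_traces",
    "simulate_connectome",
]


def _label_rng(seed: int, label: str) -> np.random.Generator:
    """Per-label child generator: reproducible and order-independent."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass(frozen=True)
class PeristalsisConfig:
    """Parameters of the synthetic peristaltic wave.

    Defaults describe forward crawling as recorded in the semi-intact
    preparation: a 0.3 Hz wave sampled at 10 Hz for 120 s, three imaged
    segments 0.4 s apart, 42-degree intrasegmental lag of the transverse
    muscle, 20% contraction depth with contraction occupying 40% of the
    cycle, 2% length noise and 2% period jitter.
    """

    wave_frequency: float = 0.3  # Hz
    n_segments: int = 3
    intersegmental_delay: float = 0.4  # s per segment
    intrasegmental_lag: float = 42.0  # degrees of a cycle
    contraction_depth: float = 0.2  # fraction of resting length
    contraction_duty: float = 0.4  # fraction of the cycle in contraction
    noise_sd: float = 0.02  # fraction of resting length
    cycle_jitter_sd: float = 0.02  # fraction of the period
    duration: float = 120.0  # s
    sampling_rate: float = 10.0  # Hz
    resting_length: float = 100.0  # arbitrary length units
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.wave_frequency <= 0:
            problems.append("wave_frequency must be > 0")
        if not 0 < self.contraction_depth < 1:
            problems.append("contraction_depth must be in (0, 1)")
        if not 0 < self.contraction_duty < 1:
            problems.append("contraction_duty must be in (0, 1)")
        if self.sampling_rate <= 4 * self.wave_frequency:
            problems.append("sampling_rate must exceed 4 x wave_frequency")
        if self.n_segments < 1:
            problems.append("n_segments must be >= 1")
        if self.duration <= 2 / self.wave_frequency:
            problems.append("duration must cover at least two wave cycles")
        if self.noise_sd < 0 or self.cycle_jitter_sd < 0:
            problems.append("noise_sd and cycle_jitter_sd must be >= 0")
        if self.resting_length <= 0:
            problems.append("resting_length must be > 0")
        if problems:
            raise ValueError("invalid PeristalsisConfig: " + "; ".join(problems))

    @property
    def period(self) -> float:
        return 1.0 / self.wave_frequency


@dataclass(frozen=True)
class CalciumKernelConfig:
    """Exponential rise/decay indicator kernel (GCaMP-like), with baseline
    fluorescence and additive noise in the same arbitrary units."""

    rise_time: float = 0.1  # s
    decay_time: float = 0.4  # s
    baseline: float = 1.0
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.rise_time < self.decay_time:
            raise ValueError("need decay_time > rise_time > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _cycle_boundaries(config: PeristalsisConfig, t_min: float, t_max: float) -> np.ndarray:
    """Jittered cycle onset times covering [t_min, t_max].

    One boundary sequence is shared by every trace of a simulation (common
    central drive); per-cycle periods are T * (1 + eps) with eps Gaussian,
    clipped at +-3 sd and at -50% so periods stay positive.
    """
    T = config.period
    rng = _label_rng(config.seed, "__cycle_jitter__")
    n_fwd = int(np.ceil((t_max) / T)) + 3
    n_bwd = int(np.ceil(max(0.0, -t_min) / T)) + 3
    eps = rng.normal(0.0, config.cycle_jitter_sd, size=n_fwd + n_bwd)
    if config.cycle_jitter_sd > 0:
        lim = min(3 * config.cycle_jitter_sd, 0.5)
        eps = np.clip(eps, -lim, lim)
    periods = T * (1.0 + eps)
    # boundary 0 at t=0; forward periods first, then backward
    fwd = np.concatenate([[0.0], np.cumsum(periods[:n_fwd])])
    bwd = -np.cumsum(periods[n_fwd:][::-1])[::-1]
    return np.concatenate([bwd, fwd])


def _pulse_train(times: np.ndarray, boundaries: np.ndarray, duty: float) -> np.ndarray:
    """Raised-cosine contraction pulse, one bump of width ``duty`` per cycle."""
    idx = np.searchsorted(boundaries, times, side="right") - 1
    if idx.min() < 0 or idx.max() >= boundaries.size - 1:
        raise RuntimeError("pulse-train boundaries do not cover evaluation times")
    c = (times - boundaries[idx]) / (boundaries[idx + 1] - boundaries[idx])
    pulse = np.where(c < duty, 0.5 * (1.0 - np.cos(2.0 * np.pi * c / duty)), 0.0)
    return pulse


def _segment_labels(config: PeristalsisConfig) -> list[tuple[str, int, float]]:
    """(label, segment index, extra lag in degrees) for each muscle trace."""
    out = []
    for s in range(config.n_segments):
        seg = f"A{s + 1}"
        out.append((f"LO1_{seg}", s, 0.0))
        out.append((f"LT2_{seg}", s, config.intrasegmental_lag))
    return out


def simulate_peristalsis(config: PeristalsisConfig) -> list[MuscleLengthTrace]:
    """Simulate muscle-length traces for two muscles in each segment.

    Returns, per segment s (0-based), ``LO1_A{s+1}`` and ``LT2_A{s+1}``;
    segment s is delayed by ``s * intersegmental_delay`` and the LT2 trace
    additionally by ``intrasegmental_lag/360`` of a period, implemented as
    time shifts of one shared jittered pulse train so the programmed lag is
    exact at the wave frequency.
    """
    n = int(round(config.duration * config.sampling_rate))
    times = np.arange(n) / config.sampling_rate
    max_shift = (
        (config.n_segments - 1) * abs(config.intersegmental_delay)
        + abs(config.intrasegmental_lag) / 360.0 * config.period
    )
    boundaries = _cycle_boundaries(config, -max_shift - config.period, config.duration + max_shift + config.period)
    out: list[MuscleLengthTrace] = []
    for label, s, lag_deg in _segment_labels(config):
        shift = s * config.intersegmental_delay + lag_deg / 360.0 * config.period
        pulse = _pulse_train(times - shift, boundaries, config.contraction_duty)
        values = config.resting_length * (1.0 - config.contraction_depth * pulse)
        if config.noise_sd > 0:
            rng = _label_rng(config.seed, label)
            values = values + rng.normal(
                0.0, config.noise_sd * config.resting_length, size=n
            )
        out.append(
            MuscleLengthTrace(
                trace=TimeSeriesTrace(
                    label=label, sampling_rate=config.sampling_rate, values=values
                )
            )
        )
    return out


def simulate_calcium_traces(
    config: PeristalsisConfig, kernel: CalciumKernelConfig | None = None
) -> list[TimeSeriesTrace]:
    """Simulate indicator traces: per segment, a reference motor neuron
    (``aCC_A{s}``, in phase with the segment's longitudinal drive) and a
    lagged interneuron (``IN_A{s}``, shifted by the intrasegmental lag).

    Each neuron's pulse train is convolved with the indicator kernel
    ``(1 - exp(-t/rise)) * exp(-t/decay)`` (peak-normalized); both members
    of a pair share the kernel, so their relative phase at the wave
    frequency is preserved.
    """
    kernel = kernel or CalciumKernelConfig()
    n = int(round(config.duration * config.sampling_rate))
    dt = 1.0 / config.sampling_rate
    times = np.arange(n) * dt
    tk = np.arange(0.0, kernel.rise_time + 6.0 * kernel.decay_time, dt)
    k = (1.0 - np.exp(-tk / kernel.rise_time)) * np.exp(-tk / kernel.decay_time)
    k = k / k.max()
    max_shift = (
        (config.n_segments - 1) * abs(config.intersegmental_delay)
        + abs(config.intrasegmental_lag) / 360.0 * config.period
    )
    boundaries = _cycle_boundaries(
        config, -max_shift - config.period, config.duration + max_shift + config.period
    )
    out: list[TimeSeriesTrace] = []
    for s in range(config.n_segments):
        seg = f"A{s + 1}"
        seg_shift = s * config.intersegmental_delay
        for name, lag_deg in (("aCC", 0.0), ("IN", config.intrasegmental_lag)):
            label = f"{name}_{seg}"
            shift = seg_shift + lag_deg / 360.0 * config.period
            pulse = _pulse_train(times - shift, boundaries, config.contraction_duty)
            activity = np.convolve(pulse, k)[:n]
            values = kernel.baseline + activity
            if kernel.noise_sd > 0:
                rng = _label_rng(config.seed, label)
                values = values + rng.normal(0.0, kernel.noise_sd, size=n)
            out.append(
                TimeSeriesTrace(
                    label=label, sampling_rate=config.sampling_rate, values=values
                )
            )
    return out


@dataclass(frozen=True)
class SyntheticConnectomeConfig:
    """Two motor neurons with programmable shared presynaptic structure.

    Defaults mirror a functionally similar motor-neuron pair: 55 + 54
    presynaptic partners with 34 shared (union 75), and shared partners
    whose synapse counts onto the two neurons correlate at Pearson r = 0.76
    on the count scale. ``weight_distribution`` gives the lognormal
    parameters of synapse counts (log-mean and log-sd).
    """

    n_partners_a: int = 55
    n_partners_b: int = 54
    n_shared: int = 34
    weight_distribution: dict = field(
        default_factory=lambda: {"mean_log": 1.5, "sd_log": 0.8}
    )
    shared_weight_correlation: float = 0.76
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shared < 0 or self.n_partners_a < 0 or self.n_partners_b < 0:
            raise ValueError("partner counts must be >= 0")
        if self.n_shared > min(self.n_partners_a, self.n_partners_b):
            raise ValueError("n_shared exceeds a partner count")
        if not -1.0 <= self.shared_weight_correlation <= 1.0:
            raise ValueError("shared_weight_correlation must be in [-1, 1]")
        if self.n_shared < 3 and self.shared_weight_correlation != 0.0:
            raise ValueError(
                "a nonzero shared_weight_correlation needs n_shared >= 3"
            )


def _log_scale_correlation(r_count: float, sd_log: float) -> float:
    """Log-scale Gaussian correlation reproducing a count-scale Pearson r
    for equal-sd lognormal margins: inverts
    r = (exp(rho*s^2) - 1) / (exp(s^2) - 1)."""
    if r_count == 0.0:
        return 0.0
    arg = 1.0 + r_count * np.expm1(sd_log**2)
    if arg <= 0:
        raise ValueError(
            f"count-scale correlation {r_count} infeasible for sd_log={sd_log}"
        )
    rho = float(np.log(arg) / sd_log**2)
    if not -1.0 <= rho <= 1.0:
        raise ValueError(
            f"count-scale correlation {r_count} infeasible for sd_log={sd_log}"
        )
    return rho


def simulate_connectome(config: SyntheticConnectomeConfig) -> ConnectomeGraph:
    """Build the two-motor-neuron graph ``MN_A``/``MN_B``.

    Shared partners (``S001``...) synapse onto both motor neurons with
    lognormal counts coupled at the programmed count-scale correlation;
    private partners (``PA…``/``PB…``) synapse onto one. Counts are rounded
    to integers with a floor of 1 synapse.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0x5EED,)))
    mu = float(config.weight_distribution["mean_log"])
    sd = float(config.weight_distribution["sd_log"])
    rho = _log_scale_correlation(config.shared_weight_correlation, sd)

    neurons = [
        NeuronRecord("MN_A", cell_class="motor_neuron", pool="A", segment="A1"),
        NeuronRecord("MN_B", cell_class="motor_neuron", pool="B", segment="A1"),
    ]
    edges: list[SynapticEdge] = []

    def _count(z: float) -> int:
        return max(1, int(round(np.exp(z))))

    if config.n_shared > 0:
        cov = sd**2 * np.array([[1.0, rho], [rho, 1.0]])
        z = rng.multivariate_normal([mu, mu], cov, size=config.n_shared)
        for i in range(config.n_shared):
            pid = f"S{i + 1:03d}"
            neurons.append(NeuronRecord(pid, cell_class="interneuron"))
            edges.append(SynapticEdge(pid, "MN_A", _count(z[i, 0])))
            edges.append(SynapticEdge(pid, "MN_B", _count(z[i, 1])))
    for prefix, target, n_priv in (
        ("PA", "MN_A", config.n_partners_a - config.n_shared),
        ("PB", "MN_B", config.n_partners_b - config.n_shared),
    ):
        zs = rng.normal(mu, sd, size=n_priv)
        for i in range(n_priv):
            pid = f"{prefix}{i + 1:03d}"
            neurons.append(NeuronRecord(pid, cell_class="interneuron"))
            edges.append(SynapticEdge(pid, target, _count(zs[i])))
    return ConnectomeGraph(neurons, edges)
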