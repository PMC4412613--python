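"""Seeded stochastic simulator of multi-channel patch currents.

Each channel is a two-state (closed <-> open) continuous-time Markov chain
with opening rate alpha and closing rate beta (s^-1); the stationary open
probability is Po = alpha / (alpha + beta).  Gating is simulated
event-driven (exact exponential dwell times), then discretised
sample-and-hold at the recording rate, which avoids the bias of per-sample
Bernoulli schemes.  The open-channel current follows the linear chord model

    i(V) = g * (V - E_rev) / 1000        [pA, with g in pS and V in mV]

in the tonoplast sign convention (voltage = cytoplasm minus vacuole), so a
95.5 pS channel at -80 mV carries -7.64 pA when open.  Gaussian baseline
noise is added before the recording filter, a 4-pole Bessel-type digital
low-pass mimicking the acquisition chain (10 kHz sampling, 2 kHz filter by
default).

Voltage dependence, when enabled, enters through a Boltzmann factor on the
alpha/beta ratio split symmetrically between the two rates:

    alpha(V) = alpha * exp(+(V - v_half) / (2 s)),
    beta(V)  = beta  * exp(-(V - v_half) / (2 s)),

giving Po(V) a Boltzmann shape with midpoint v_half and slope s.  Ligand
conditions (Ca2+, Mg2+, pH) are represented as alternative (alpha, beta)
presets, not mechanistic binding schemes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import InvalidInputError, ProtocolError

__all__ = [
    "StepProtocol",
    "GatingModel",
    "Trace",
    "make_step_protocol",
    "simulate_patch_current",
    "simulate_constant_voltage",
    "apply_recording_filter",
    "DEFAULT_SAMPLING_HZ",
    "DEFAULT_FILTER_HZ",
    "DEFAULT_NOISE_SD_PA",
]

DEFAULT_SAMPLING_HZ = 10_000.0
DEFAULT_FILTER_HZ = 2_000.0
DEFAULT_NOISE_SD_PA = 0.5
DEFAULT_CLOSE_RATE_S = 50.0


@dataclass(frozen=True)
class StepProtocol:
    """Holding / test-step / tail voltage protocol.

    The canonical recording protocol is 0.5 s holding, 3 s test steps in
    20 mV increments spanning about -100...+80 mV, and a 0.3 s tail pulse.
    """

    holding_mV: float = 0.0
    holding_s: float = 0.5
    test_start_mV: float = -100.0
    test_stop_mV: float = 80.0
    test_step_mV: float = 20.0
    test_s: float = 3.0
    tail_mV: float = 0.0
    tail_s: float = 0.3

    def __post_init__(self):
        for name in ("holding_s", "test_s", "tail_s"):
            if getattr(self, name) <= 0:
                raise ProtocolError(f"{name} must be > 0")
        span = self.test_stop_mV - self.test_start_mV
        if span == 0:
            return
        if self.test_step_mV == 0:
            raise ProtocolError("test_step_mV must be nonzero for a voltage range")
        n = span / self.test_step_mV
        if n < 0 or abs(n - round(n)) > 1e-9:
            raise ProtocolError(
                f"step {self.test_step_mV} mV does not divide the range "
                f"{self.test_start_mV}..{self.test_stop_mV} mV"
            )

    @property
    def n_sweeps(self) -> int:
        span = self.test_stop_mV - self.test_start_mV
        if span == 0:
            return 1
        return int(round(span / self.test_step_mV)) + 1

    @property
    def sweep_voltages_mV(self) -> tuple[float, ...]:
        return tuple(self.test_start_mV + i * self.test_step_mV
                     for i in range(self.n_sweeps))

    @property
    def sweep_duration_s(self) -> float:
        return self.holding_s + self.test_s + self.tail_s


def make_step_protocol(holding_mV: float, holding_s: float,
                       test_start_mV: float, test_stop_mV: float,
                       test_step_mV: float, test_s: float,
                       tail_mV: float, tail_s: float) -> StepProtocol:
    """Construct and validate a :class:`StepProtocol`."""
    return StepProtocol(holding_mV, holding_s, test_start_mV, test_stop_mV,
                        test_step_mV, test_s, tail_mV, tail_s)


@dataclass(frozen=True)
class GatingModel:
    """Per-channel two-state gating parameters and the chord current model."""

    n_channels: int = 1
    open_rate_s: float = 10.0          # alpha
    close_rate_s: float = DEFAULT_CLOSE_RATE_S  # beta
    unitary_conductance_pS: float = 95.5
    reversal_mV: float = 0.0
    v_half_mV: float | None = None     # optional Boltzmann modulation
    slope_mV: float | None = None

    def __post_init__(self):
        if self.n_channels < 1:
            raise InvalidInputError("n_channels must be >= 1")
        if self.open_rate_s < 0 or self.close_rate_s <= 0:
            raise InvalidInputError("rates must be positive (open rate may be 0)")
        if self.unitary_conductance_pS <= 0:
            raise InvalidInputError("unitary conductance must be > 0")
        if (self.v_half_mV is None) != (self.slope_mV is None):
            raise InvalidInputError("v_half and slope must be set together")

    @classmethod
    def from_open_probability(cls, po: float, *, n_channels: int = 1,
                              unitary_conductance_pS: float = 95.5,
                              reversal_mV: float = 0.0,
                              close_rate_s: float = DEFAULT_CLOSE_RATE_S,
                              **kw) -> "GatingModel":
        """Build a model with a given stationary Po at fixed closing rate."""
        if not (0.0 <= po < 1.0):
            raise InvalidInputError("Po must be in [0, 1)")
        alpha = close_rate_s * po / (1.0 - po)
        return cls(n_channels=n_channels, open_rate_s=alpha,
                   close_rate_s=close_rate_s,
                   unitary_conductance_pS=unitary_conductance_pS,
                   reversal_mV=reversal_mV, **kw)

    def rates_at(self, voltage_mV: float) -> tuple[float, float]:
        if self.v_half_mV is None:
            return self.open_rate_s, self.close_rate_s
        x = (voltage_mV - self.v_half_mV) / (2.0 * self.slope_mV)
        return self.open_rate_s * math.exp(x), self.close_rate_s * math.exp(-x)

    def stationary_po(self, voltage_mV: float | None = None) -> float:
        a, b = self.rates_at(voltage_mV if voltage_mV is not None else 0.0)
        return a / (a + b)

    def unitary_current_pA(self, voltage_mV: float) -> float:
        return self.unitary_conductance_pS * (voltage_mV - self.reversal_mV) / 1000.0


@dataclass
class Trace:
    """Uniformly sampled current trace (pA) with recording metadata."""

    samples_pA: np.ndarray
    sampling_rate_hz: float
    voltage_mV: float
    filter_hz: float | None = None
    configuration: str = "cytoplasm-out"
    seed: int | None = None
    sweep_index: int | None = None
    segments_s: dict | None = None      # {"holding": .., "test": .., "tail": ..}
    segment_voltages_mV: dict | None = None
    truth: GatingModel | None = None

    def __post_init__(self):
        self.samples_pA = np.asarray(self.samples_pA, dtype=float)
        if not np.all(np.isfinite(self.samples_pA)):
            raise InvalidInputError("trace contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples_pA.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz

    def test_segment(self, settle_filter_taus: float = 10.0) -> np.ndarray:
        """Quasi-stationary samples: the test-pulse region after the filter settles.

        The first ``settle_filter_taus`` filter time constants (10 by
        default) after the step are discarded; traces recorded at a single
        constant voltage are trimmed the same way at their start.
        """
        settle = 0.0
        if self.filter_hz:
            settle = settle_filter_taus / (2.0 * math.pi * self.filter_hz)
        n_settle = int(math.ceil(settle * self.sampling_rate_hz))
        if self.segments_s is None:
            return self.samples_pA[n_settle:]
        i0 = int(round(self.segments_s.get("holding", 0.0) * self.sampling_rate_hz))
        i1 = i0 + int(round(self.segments_s["test"] * self.sampling_rate_hz))
        return self.samples_pA[i0 + n_settle:i1]


def _sample_channel_states(rng: np.random.Generator, alpha: float, beta: float,
                           sample_times: np.ndarray, t0: float,
                           state0: int) -> tuple[np.ndarray, int, float]:
    """Sample-and-hold states of one channel over the given sample times.

    Returns (states at sample times, state at the end, end time), starting
    from ``state0`` at time ``t0``.  Dwell times are exact exponentials.
    """
    t_end = sample_times[-1] + (sample_times[1] - sample_times[0] if
                                sample_times.size > 1 else 0.0)
    if alpha == 0.0 and state0 == 0:
        return np.zeros(sample_times.size, dtype=np.int8), 0, t_end
    times = [t0]
    states = [state0]
    t, st = t0, state0
    while t < t_end:
        rate = beta if st == 1 else alpha
        if rate == 0.0:
            break
        t = t + rng.exponential(1.0 / rate)
        st = 1 - st
        times.append(t)
        states.append(st)
    times = np.asarray(times)
    state_arr = np.asarray(states, dtype=np.int8)
    idx = np.searchsorted(times, sample_times, side="right") - 1
    out = state_arr[idx]
    # state at t_end
    end_idx = np.searchsorted(times, t_end, side="right") - 1
    return out, int(state_arr[end_idx]), t_end


def _check_aliasing(alpha: float, beta: float, sampling_rate_hz: float):
    dwell = min(1.0 / alpha if alpha > 0 else math.inf, 1.0 / beta)
    if dwell < 2.0 / sampling_rate_hz:
        warnings.warn(
            f"mean dwell time {dwell * 1e3:.3g} ms is shorter than two sampling "
            "intervals; gating will be aliased",
            stacklevel=3,
        )


def simulate_constant_voltage(model: GatingModel, voltage_mV: float,
                              duration_s: float,
                              noise_sd_pA: float = DEFAULT_NOISE_SD_PA,
                              seed: int = 0,
                              sampling_rate_hz: float = DEFAULT_SAMPLING_HZ,
                              filter_hz: float | None = DEFAULT_FILTER_HZ,
                              configuration: str = "cytoplasm-out") -> Trace:
    """Simulate a single constant-voltage recording (the Fig.-style holdings).

    Channels start from their stationary distribution, so the trace is
    stationary from the first sample.  Reproducible per seed.
    """
    if noise_sd_pA < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    alpha, beta = model.rates_at(voltage_mV)
    _check_aliasing(alpha, beta, sampling_rate_hz)
    n = int(round(duration_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    po = alpha / (alpha + beta) if alpha + beta > 0 else 0.0
    open_count = np.zeros(n, dtype=np.int32)
    for _ in range(model.n_channels):
        s0 = int(rng.random() < po)
        states, _, _ = _sample_channel_states(rng, alpha, beta, t, 0.0, s0)
        open_count += states
    current = open_count * model.unitary_current_pA(voltage_mV)
    if noise_sd_pA > 0:
        current = current + rng.normal(0.0, noise_sd_pA, size=n)
    trace = Trace(samples_pA=current, sampling_rate_hz=sampling_rate_hz,
                  voltage_mV=voltage_mV, filter_hz=None,
                  configuration=configuration, seed=seed, truth=model)
    if filter_hz is not None:
        trace = apply_recording_filter(trace, filter_hz)
    return trace


def simulate_patch_current(model: GatingModel, protocol: StepProtocol,
                           noise_sd_pA: float = DEFAULT_NOISE_SD_PA,
                           seed: int = 0,
                           sampling_rate_hz: float = DEFAULT_SAMPLING_HZ,
                           filter_hz: float | None = DEFAULT_FILTER_HZ,
                           configuration: str = "whole-vacuole") -> list[Trace]:
    """Simulate one trace per protocol sweep; channels evolve across segments.

    Each sweep uses an independent child RNG derived from ``seed`` and the
    sweep index, so single sweeps can be regenerated bit-identically.
    """
    if noise_sd_pA < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    traces = []
    n_hold = int(round(protocol.holding_s * sampling_rate_hz))
    n_test = int(round(protocol.test_s * sampling_rate_hz))
    n_tail = int(round(protocol.tail_s * sampling_rate_hz))
    for k, v_test in enumerate(protocol.sweep_voltages_mV):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))
        segs = [(protocol.holding_mV, n_hold), (v_test, n_test),
                (protocol.tail_mV, n_tail)]
        total = n_hold + n_test + n_tail
        current = np.zeros(total)
        for _ in range(model.n_channels):
            a0, b0 = model.rates_at(protocol.holding_mV)
            state = int(rng.random() < (a0 / (a0 + b0) if a0 + b0 > 0 else 0.0))
            pos = 0
            for v_seg, n_seg in segs:
                if n_seg == 0:
                    continue
                alpha, beta = model.rates_at(v_seg)
                _check_aliasing(alpha, beta, sampling_rate_hz)
                t = np.arange(n_seg) / sampling_rate_hz
                states, state, _ = _sample_channel_states(rng, alpha, beta, t,
                                                          0.0, state)
                current[pos:pos + n_seg] += states * model.unitary_current_pA(v_seg)
                pos += n_seg
        if noise_sd_pA > 0:
            current = current + rng.normal(0.0, noise_sd_pA, size=total)
        trace = Trace(
            samples_pA=current, sampling_rate_hz=sampling_rate_hz,
            voltage_mV=v_test, filter_hz=None, configuration=configuration,
            seed=seed, sweep_index=k,
            segments_s={"holding": protocol.holding_s, "test": protocol.test_s,
                        "tail": protocol.tail_s},
            segment_voltages_mV={"holding": protocol.holding_mV, "test": v_test,
                                 "tail": protocol.tail_mV},
            truth=model,
        )
        if filter_hz is not None:
            trace = apply_recording_filter(trace, filter_hz)
        traces.append(trace)
    return traces


def apply_recording_filter(trace: Trace, cutoff_hz: float) -> Trace:
    """Low-pass the trace with a 4-pole Bessel-type digital filter.

    Causal (like the acquisition hardware), DC gain 1; the filter state is
    initialised to the first sample so there is no startup transient on a
    settled baseline.
    """
    nyquist = trace.sampling_rate_hz / 2.0
    if cutoff_hz >= nyquist:
        raise InvalidInputError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency {nyquist} Hz"
        )
    sos = signal.bessel(4, cutoff_hz, fs=trace.sampling_rate_hz, output="sos")
    zi = signal.sosfilt_zi(sos) * trace.samples_pA[0]
    filtered, _ = signal.sosfilt(sos, trace.samples_pA, zi=zi)
    out = replace_trace(trace, samples_pA=filtered, filter_hz=cutoff_hz)
    return out


def replace_trace(trace: Trace, **kw) -> Trace:
    """Dataclass ``replace`` helper (Trace is mutable, so copy explicitly)."""
    fields = dict(
        samples_pA=trace.samples_pA, sampling_rate_hz=trace.sampling_rate_hz,
        voltage_mV=trace.voltage_mV, filter_hz=trace.filter_hz,
        configuration=trace.configuration, seed=trace.seed,
        sweep_index=trace.sweep_index, segments_s=trace.segments_s,
        segment_voltages_mV=trace.segment_voltages_mV, truth=trace.truth,
    )
    fields.update(kw)
    return Trace(**fields)
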