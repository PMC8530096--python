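"""Synthetic signal generators.

Three benchmark series of graded complexity — a pure 50 Hz sine (regular),
a logistic-map series (deterministic chaos) and white Gaussian noise
(stochastic) — plus a labelled three-state multichannel recording that
emulates the interictal / preictal / ictal regimes of epileptic EEG for
end-to-end pipeline testing.  All stochastic generators are seeded and
bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MultichannelSeries

__all__ = [
    "SimulationSpec",
    "LabeledRecording",
    "StateInterval",
    "STATES",
    "gen_sine",
    "gen_chaotic",
    "gen_gaussian",
    "gen_simulation",
    "gen_epileptic_like",
]

#: canonical state names, in label-index order
STATES = ("interictal", "preictal", "ictal")


@dataclass(frozen=True)
class SimulationSpec:
    """Recipe for one benchmark series.

    Defaults match the simulation study configuration: 400 samples, and for
    the sine a 50 Hz tone sampled at 400 Hz, i.e. one second of signal with
    8 samples per cycle.  The coarse sampling matters: it keeps the sine's
    pairwise template distances on a small discrete set, which is what puts
    the regular series below the stochastic ones at every scale factor.
    """

    kind: str = "gaussian"
    n_samples: int = 400
    sampling_rate: float = 400.0
    frequency_hz: float = 50.0
    seed: int = 0
    map_parameter: float = 4.0  # logistic-map control parameter
    burn_in: int = 100

    def __post_init__(self) -> None:
        if self.kind not in ("sine", "chaotic", "gaussian"):
            raise ValueError(f"unknown simulation kind {self.kind!r}")
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")


@dataclass(frozen=True)
class StateInterval:
    start_s: float
    end_s: float
    state: str

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if not self.end_s > self.start_s:
            raise ValueError(f"empty interval [{self.start_s}, {self.end_s})")


@dataclass(frozen=True)
class LabeledRecording:
    """A multichannel series plus ordered, gap-free state intervals."""

    series: MultichannelSeries
    state_intervals: tuple[StateInterval, ...]

    def __post_init__(self) -> None:
        ivals = tuple(self.state_intervals)
        dur = self.series.duration_s
        if ivals[0].start_s != 0.0:
            raise ValueError("state intervals must start at 0")
        for a, b in zip(ivals, ivals[1:]):
            if b.start_s != a.end_s:
                raise ValueError(f"gap/overlap between intervals at {a.end_s} vs {b.start_s}")
        if dur is not None and abs(ivals[-1].end_s - dur) > 1e-9:
            raise ValueError(
                f"intervals end at {ivals[-1].end_s} s but recording lasts {dur} s"
            )
        object.__setattr__(self, "state_intervals", ivals)

    def state_at(self, t_s: float) -> str:
        for iv in self.state_intervals:
            if iv.start_s <= t_s < iv.end_s:
                return iv.state
        return self.state_intervals[-1].state


def gen_sine(spec: SimulationSpec) -> MultichannelSeries:
    """Unit-amplitude sinusoid at ``spec.frequency_hz`` (default 50 Hz)."""
    if spec.sampling_rate <= 2 * spec.frequency_hz:
        raise ValueError(
            f"sampling rate {spec.sampling_rate} Hz violates Nyquist for a "
            f"{spec.frequency_hz} Hz tone"
        )
    t = np.arange(spec.n_samples) / spec.sampling_rate
    x = np.sin(2 * np.pi * spec.frequency_hz * t)
    return MultichannelSeries(values=x[None, :], sampling_rate=spec.sampling_rate)


def gen_chaotic(spec: SimulationSpec) -> MultichannelSeries:
    """Logistic-map series ``x_{k+1} = a x_k (1 - x_k)`` with ``a=4``.

    The initial point is drawn from the seed, and the first ``burn_in``
    iterates are discarded so the series sits on the attractor; all values
    lie strictly in (0, 1).
    """
    rng = np.random.default_rng(spec.seed)
    x = float(rng.uniform(0.05, 0.95))
    a = spec.map_parameter
    for _ in range(spec.burn_in):
        x = a * x * (1.0 - x)
    out = np.empty(spec.n_samples)
    for k in range(spec.n_samples):
        x = a * x * (1.0 - x)
        out[k] = x
    return MultichannelSeries(values=out[None, :], sampling_rate=spec.sampling_rate)


def gen_gaussian(spec: SimulationSpec) -> MultichannelSeries:
    """I.i.d. standard-normal noise."""
    rng = np.random.default_rng(spec.seed)
    x = rng.standard_normal(spec.n_samples)
    return MultichannelSeries(values=x[None, :], sampling_rate=spec.sampling_rate)


_GENERATORS = {"sine": gen_sine, "chaotic": gen_chaotic, "gaussian": gen_gaussian}


def gen_simulation(spec: SimulationSpec) -> MultichannelSeries:
    """Dispatch on ``spec.kind``."""
    return _GENERATORS[spec.kind](spec)


# ---------------------------------------------------------------------------
# three-state EEG-like recording
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """1/f-shaped noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1] if n > 1 else 1.0
    spectrum /= np.sqrt(freqs)
    x = np.fft.irfft(spectrum, n)
    return x / np.std(x)


def _interictal(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    # broadband 1/f background: intermediate complexity
    return 30.0 * _pink_noise(rng, n)


def _preictal(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    # sparse large epileptiform spikes over a quiet background.  The heavy
    # tail concentrates the pairwise-distance histogram in its lowest bins,
    # giving the lowest distribution entropy of the three regimes.
    x = 5.0 * rng.standard_normal(n)
    mask = rng.random(n) < 0.01
    x[mask] += 200.0 * rng.choice([-1.0, 1.0], int(mask.sum()))
    return x


def _ictal(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    # high-amplitude chaotic discharge (logistic map) mixed with noise
    x = float(rng.uniform(0.1, 0.9))
    chaos = np.empty(n)
    for k in range(n):
        x = 4.0 * x * (1.0 - x)
        chaos[k] = x
    chaos = (chaos - 0.5) / np.std(chaos)
    return 120.0 * chaos + 5.0 * rng.standard_normal(n)


_REGIMES = {"interictal": _interictal, "preictal": _preictal, "ictal": _ictal}


def gen_epileptic_like(
    channels: int = 3,
    segment_minutes: tuple[float, float, float] = (10.0, 10.0, 2.0),
    sampling_rate: float = 256.0,
    seed: int = 0,
) -> LabeledRecording:
    """Concatenate interictal, preictal and ictal-like regimes per channel.

    The three regimes are designed to be separable by multiscale entropy —
    ictal epochs the most complex, preictal the least — mirroring the
    ordering observed on real epileptic EEG; they do not model clinical EEG
    morphology.  Segment lengths are in minutes, in state order
    (interictal, preictal, ictal).
    """
    if channels < 1:
        raise ValueError(f"channels must be >= 1, got {channels}")
    if len(segment_minutes) != 3 or any(m <= 0 for m in segment_minutes):
        raise ValueError(f"segment_minutes must be 3 positive values, got {segment_minutes}")
    rng = np.random.default_rng(seed)
    seg_samples = [int(round(m * 60 * sampling_rate)) for m in segment_minutes]
    pieces = []
    for ch in range(channels):
        ch_pieces = [
            _REGIMES[state](rng, n, sampling_rate)
            for state, n in zip(STATES, seg_samples)
        ]
        pieces.append(np.concatenate(ch_pieces))
    values = np.vstack(pieces)
    series = MultichannelSeries(
        values=values,
        sampling_rate=sampling_rate,
        channel_names=tuple(f"SYN{ch + 1}" for ch in range(channels)),
    )
    bounds = np.concatenate([[0], np.cumsum(seg_samples)]) / sampling_rate
    intervals = tuple(
        StateInterval(start_s=float(bounds[i]), end_s=float(bounds[i + 1]), state=STATES[i])
        for i in range(3)
    )
    return LabeledRecording(series=series, state_intervals=intervals)
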