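"""Optogenetic stimulation waveform classes.

Five waveform families are supported, each parameterised by optical
irradiance amplitude (mW/mm^2) and class-specific temporal parameters:

``standard``
    Constant-frequency train of rectangular pulses (amplitude, frequency,
    pulse width).
``nested``
    Fast rectangular pulses at ``pulse_freq`` gated by a slower on/off
    train cycle (``train_freq``, ``train_width``).
``poisson``
    Rectangular pulses whose inter-pulse intervals are exponential waiting
    times of a homogeneous Poisson process with the given center frequency,
    floored at a refractory period.
``sine``
    Offset sinusoid spanning [0, amplitude] (irradiance cannot be negative).
``double_sine``
    Sum of two zero-phase sinusoids with magnitudes split by a ratio
    parameter, rescaled so the minimum is 0 and the maximum is the
    amplitude.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numpy.random import Generator

__all__ = [
    "WaveformSpec",
    "StimWaveform",
    "PSDEstimate",
    "PARAM_BOUNDS",
    "PARAM_NAMES",
    "N_PARAMS",
    "DEFAULT_FREQ_GRID",
    "gen_waveform",
    "validate_nested",
    "sample_parameters",
    "waveform_spectrum",
]

KINDS = ("standard", "nested", "poisson", "sine", "double_sine")

#: Parameter bounds per waveform class, (low, high) in the units of the field.
PARAM_BOUNDS: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "standard": {
        "amplitude": (10.0, 50.0),
        "freq": (5.0, 42.0),
        "pulse_width": (0.002, 0.010),
    },
    "poisson": {
        "amplitude": (10.0, 50.0),
        "freq": (5.0, 42.0),
        "pulse_width": (0.002, 0.010),
    },
    "nested": {
        "amplitude": (10.0, 50.0),
        "pulse_freq": (20.0, 100.0),
        "pulse_width": (0.002, 0.005),
        "train_freq": (2.0, 12.0),
        "train_width": (0.020, 0.080),
    },
    "sine": {
        "amplitude": (10.0, 50.0),
        "freq": (2.0, 50.0),
    },
    "double_sine": {
        "amplitude": (10.0, 50.0),
        "freq1": (2.0, 50.0),
        "freq2": (2.0, 50.0),
        "ratio": (0.0, 1.0),
    },
}

#: Ordered parameter names per class (amplitude first).
PARAM_NAMES = {kind: tuple(PARAM_BOUNDS[kind]) for kind in KINDS}

#: Parameter-space dimensionality per class.
N_PARAMS = {kind: len(PARAM_BOUNDS[kind]) for kind in KINDS}

#: Discrete stimulation frequencies used by grid sampling.
DEFAULT_FREQ_GRID = (5.0, 7.0, 11.0, 17.0, 23.0, 29.0, 35.0, 42.0)


class WaveformValidationError(ValueError):
    """A waveform parameter violates its bounds or structural constraints."""


@dataclass(frozen=True)
class WaveformSpec:
    """Tagged parameter record for one stimulation waveform.

    Fields irrelevant to ``kind`` are ``None``.
    """

    kind: str
    amplitude: float
    freq: float | None = None
    pulse_width: float | None = None
    train_freq: float | None = None
    pulse_freq: float | None = None
    train_width: float | None = None
    freq1: float | None = None
    freq2: float | None = None
    ratio: float | None = None

    def params(self) -> dict[str, float]:
        """Class-relevant parameters as an ordered dict."""
        return {name: getattr(self, name) for name in PARAM_NAMES[self.kind]}

    def validate(self) -> None:
        """Raise :class:`WaveformValidationError` on any violation."""
        if self.kind not in KINDS:
            raise WaveformValidationError(f"unknown waveform kind {self.kind!r}")
        bounds = PARAM_BOUNDS[self.kind]
        for name, (lo, hi) in bounds.items():
            value = getattr(self, name)
            if value is None:
                raise WaveformValidationError(
                    f"{self.kind} spec missing required field {name!r}"
                )
            if not np.isfinite(value) or not (lo <= value <= hi):
                raise WaveformValidationError(
                    f"{self.kind} field {name!r}={value} outside [{lo}, {hi}]"
                )
        for name in set(f.name for f in _spec_fields()) - set(bounds) - {"kind"}:
            if getattr(self, name) is not None:
                raise WaveformValidationError(
                    f"{self.kind} spec carries irrelevant field {name!r}"
                )
        if self.kind == "nested":
            ok, reason = validate_nested(self)
            if not ok:
                raise WaveformValidationError(f"invalid nested spec: {reason}")

    def to_row(self) -> dict[str, float | str]:
        """Serialize as one flat row (absent fields omitted)."""
        row: dict[str, float | str] = {"kind": self.kind}
        row.update(self.params())
        return row

    @classmethod
    def from_row(cls, row: Mapping[str, object]) -> "WaveformSpec":
        kind = str(row["kind"])
        kwargs = {}
        for name in PARAM_NAMES[kind]:
            value = row.get(name)
            if value is None or (isinstance(value, float) and np.isnan(value)):
                raise WaveformValidationError(f"row missing field {name!r}")
            kwargs[name] = float(value)  # type: ignore[arg-type]
        return cls(kind=kind, **kwargs)


def _spec_fields():
    import dataclasses

    return dataclasses.fields(WaveformSpec)


@dataclass(frozen=True)
class StimWaveform:
    """Sampled irradiance time series for one stimulation trial."""

    samples: np.ndarray
    fs: float
    duration: float
    spec: WaveformSpec

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, float))


@dataclass(frozen=True)
class PSDEstimate:
    """Power spectral density on an ascending frequency grid."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self):
        freqs = np.asarray(self.freqs, float)
        power = np.asarray(self.power, float)
        if freqs.shape != power.shape:
            raise ValueError("freqs and power must have the same length")
        if freqs.size > 1 and not np.all(np.diff(freqs) > 0):
            raise ValueError("freqs must be strictly increasing")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)


def validate_nested(spec: WaveformSpec) -> tuple[bool, str]:
    """Check that a nested spec produces a genuinely nested pulse train.

    Invalid when fewer than two pulse periods fit within the train window
    (the waveform degenerates to a standard train) or when the train window
    is at least as long as the train period (adjacent trains overlap).
    """
    if spec.kind != "nested":
        raise ValueError("validate_nested requires a nested spec")
    if spec.train_width >= 1.0 / spec.train_freq:
        return False, "trains overlap"
    if int(np.floor(spec.train_width * spec.pulse_freq)) < 2:
        return False, "degenerates to standard"
    return True, "ok"


def _pulse_train(
    onsets: np.ndarray, amplitude: float, pulse_width: float, n: int, fs: float
) -> np.ndarray:
    """Rectangular pulses with onsets snapped to the sample grid.

    A pulse occupies max(1, round(pulse_width*fs)) samples.
    """
    out = np.zeros(n)
    width = max(1, int(round(pulse_width * fs)))
    starts = np.round(np.asarray(onsets) * fs).astype(int)
    for s in starts:
        if 0 <= s < n:
            out[s : min(n, s + width)] = amplitude
    return out


def _standard_onsets(freq: float, duration: float) -> np.ndarray:
    # onsets at k/freq for k = 0 .. floor(T*f) (excluding t >= T)
    n_onsets = int(np.floor(duration * freq - 1e-12)) + 1
    onsets = np.arange(n_onsets) / freq
    return onsets[onsets < duration]


def _poisson_onsets(
    freq: float, duration: float, refractory: float, rng: Generator
) -> np.ndarray:
    onsets = []
    t = 0.0
    while True:
        # exponential waiting time, redrawn while below the refractory floor
        while True:
            gap = rng.exponential(1.0 / freq)
            if gap >= refractory:
                break
        t += gap
        if t >= duration:
            break
        onsets.append(t)
    return np.asarray(onsets)


def _offset_sine(amplitude: float, freq: float, t: np.ndarray) -> np.ndarray:
    return amplitude * (np.sin(2 * np.pi * freq * t) + 1.0) / 2.0


def gen_waveform(
    spec: WaveformSpec,
    duration: float = 5.0,
    fs: float = 2000.0,
    rng: Generator | None = None,
    *,
    refractory: float = 0.001,
    validate: bool = True,
) -> StimWaveform:
    """Render a waveform spec into an irradiance time series.

    Parameters
    ----------
    spec
        Validated waveform parameters.
    duration
        Waveform length in seconds (default 5 s, one stimulation epoch).
    fs
        Sampling rate in Hz; must be >= 1000.
    rng
        Seeded generator; required for the poisson class, ignored otherwise.
    refractory
        Minimum inter-pulse interval (s) for the poisson class.
    validate
        Skip bounds checking when False (test hook, e.g. zero amplitude).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs < 1000:
        raise ValueError("fs must be >= 1000 Hz")
    if validate:
        spec.validate()

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    A = spec.amplitude

    if spec.kind == "standard":
        samples = _pulse_train(
            _standard_onsets(spec.freq, duration), A, spec.pulse_width, n, fs
        )
    elif spec.kind == "poisson":
        if rng is None:
            raise ValueError("poisson waveform requires a seeded rng")
        onsets = _poisson_onsets(spec.freq, duration, refractory, rng)
        samples = _pulse_train(onsets, A, spec.pulse_width, n, fs)
    elif spec.kind == "nested":
        # continuous pulse train at pulse_freq masked by the train windows
        carrier = _pulse_train(
            _standard_onsets(spec.pulse_freq, duration), A, spec.pulse_width, n, fs
        )
        phase = np.mod(t, 1.0 / spec.train_freq)
        samples = carrier * (phase < spec.train_width)
    elif spec.kind == "sine":
        samples = _offset_sine(A, spec.freq, t)
    elif spec.kind == "double_sine":
        raw = spec.ratio * np.sin(2 * np.pi * spec.freq1 * t) + (
            1.0 - spec.ratio
        ) * np.sin(2 * np.pi * spec.freq2 * t)
        lo, hi = raw.min(), raw.max()
        if hi - lo < 1e-12 or A == 0:
            samples = np.zeros(n)
        else:
            samples = A * (raw - lo) / (hi - lo)
    else:
        raise WaveformValidationError(f"unknown waveform kind {spec.kind!r}")

    return StimWaveform(samples=samples, fs=fs, duration=duration, spec=spec)


def _uniform_spec(kind: str, bounds, rng: Generator) -> WaveformSpec:
    kwargs = {name: rng.uniform(lo, hi) for name, (lo, hi) in bounds.items()}
    return WaveformSpec(kind=kind, **kwargs)


def sample_parameters(
    kind: str,
    strategy: str = "random",
    n: int = 1,
    rng: Generator | None = None,
    *,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    grid: Mapping[str, Sequence[float]] | None = None,
    max_redraws: int = 10_000,
) -> list[WaveformSpec]:
    """Sample ``n`` parameter vectors from one waveform class.

    ``random`` draws each parameter uniformly over its bounds; ``grid``
    draws without replacement from the Cartesian product of per-dimension
    grid values. Nested draws failing :func:`validate_nested` are discarded
    and redrawn (random) or dropped from the candidate grid.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if kind not in KINDS:
        raise ValueError(f"unknown waveform kind {kind!r}")
    if rng is None:
        rng = np.random.default_rng()
    bounds = dict(bounds or PARAM_BOUNDS[kind])

    if strategy == "random":
        specs: list[WaveformSpec] = []
        redraws = 0
        while len(specs) < n:
            spec = _uniform_spec(kind, bounds, rng)
            if kind == "nested" and not validate_nested(spec)[0]:
                redraws += 1
                if redraws > max_redraws:
                    raise RuntimeError("nested resampling failed to converge")
                continue
            specs.append(spec)
        return specs

    if strategy == "grid":
        if grid is None:
            grid = default_grid(kind, bounds)
        names = list(grid)
        candidates = [
            WaveformSpec(kind=kind, **dict(zip(names, values)))
            for values in itertools.product(*(grid[name] for name in names))
        ]
        if kind == "nested":
            candidates = [c for c in candidates if validate_nested(c)[0]]
        if n > len(candidates):
            raise ValueError(
                f"requested {n} grid points but only {len(candidates)} available"
            )
        idx = rng.choice(len(candidates), size=n, replace=False)
        return [candidates[i] for i in sorted(idx)]

    raise ValueError(f"unknown sampling strategy {strategy!r}")


def default_grid(
    kind: str, bounds: Mapping[str, tuple[float, float]] | None = None
) -> dict[str, np.ndarray]:
    """Default sampling grid: the discrete frequency values crossed with
    5 amplitude levels; 3 levels for remaining dimensions."""
    bounds = dict(bounds or PARAM_BOUNDS[kind])
    grid: dict[str, np.ndarray] = {}
    for name, (lo, hi) in bounds.items():
        if name == "amplitude":
            grid[name] = np.linspace(lo, hi, 5)
        elif name in ("freq", "freq1", "freq2", "pulse_freq"):
            values = np.asarray(DEFAULT_FREQ_GRID)
            grid[name] = values[(values >= lo) & (values <= hi)]
            if grid[name].size == 0:
                grid[name] = np.linspace(lo, hi, 5)
        else:
            grid[name] = np.linspace(lo, hi, 3)
    return grid


def waveform_spectrum(
    spec: WaveformSpec,
    duration: float = 5.0,
    fs: float = 2000.0,
    n_realizations: int = 1,
    rng: Generator | None = None,
    *,
    refractory: float = 0.001,
    fmax: float | None = None,
) -> PSDEstimate:
    """Power spectral density of the waveform itself (not the LFP).

    Stochastic classes (poisson) are averaged over ``n_realizations``
    independent draws; deterministic classes give the same answer for any
    realization count. The DC component is removed before the PSD so that
    the irradiance offset does not mask the oscillatory structure.
    """
    from scipy.signal import periodogram

    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    stochastic = spec.kind == "poisson"
    reps = n_realizations if stochastic else 1
    if stochastic and rng is None:
        rng = np.random.default_rng()

    acc = None
    freqs = None
    for _ in range(reps):
        wf = gen_waveform(
            spec, duration, fs, rng, refractory=refractory, validate=False
        )
        x = wf.samples - wf.samples.mean()
        freqs, pxx = periodogram(x, fs=fs)
        acc = pxx if acc is None else acc + pxx
    power = acc / reps
    if fmax is not None:
        keep = freqs <= fmax
        freqs, power = freqs[keep], power[keep]
    return PSDEstimate(freqs=freqs, power=power)
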