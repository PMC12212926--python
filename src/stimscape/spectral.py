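"""Per-trial spectral features: multitaper PSD, bandpower percent change
against the session baseline, modulation profiles, lag autocorrelation, and
the fixed 164-dimensional log-PSD feature vector over 0-50 Hz."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from functools import lru_cache

from scipy.signal.windows import dpss

from .waveforms import PSDEstimate

__all__ = [
    "THETA_BAND",
    "GAMMA_BAND",
    "CANONICAL_BANDS",
    "N_FEATURES",
    "FEATURE_FREQS",
    "FeatureRecord",
    "multitaper_psd",
    "bandpower",
    "band_percent_change",
    "closest_band",
    "modulation_profile",
    "autocorr_at_freq",
    "feature_vector",
    "feature_table",
]

#: Canonical hippocampal bands (Hz).
THETA_BAND = (4.0, 10.0)
GAMMA_BAND = (32.0, 50.0)
CANONICAL_BANDS: Mapping[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": THETA_BAND,
    "beta": (10.0, 32.0),
    "low_gamma": GAMMA_BAND,
}

#: Fixed feature grid: 164 frequency values spanning 0-50 Hz.
N_FEATURES = 164
FEATURE_FREQS = np.linspace(0.0, 50.0, N_FEATURES)

_LOG_FLOOR = 1e-12


@dataclass(frozen=True)
class FeatureRecord:
    """Spectral summary of one trial."""

    trial_id: str
    theta_pct: float
    gamma_pct: float
    logpsd_vec: np.ndarray

    def __post_init__(self):
        vec = np.asarray(self.logpsd_vec, float)
        if vec.shape != (N_FEATURES,):
            raise ValueError(f"logpsd_vec must have length {N_FEATURES}")
        object.__setattr__(self, "logpsd_vec", vec)


@lru_cache(maxsize=8)
def _dpss_cached(n: int, nw: float, n_tapers: int) -> np.ndarray:
    return dpss(n, nw, Kmax=n_tapers)


def multitaper_psd(
    trace: np.ndarray,
    fs: float,
    fmax: float = 100.0,
    *,
    nw: float = 3.0,
    n_tapers: int = 5,
) -> PSDEstimate:
    """Multitaper PSD over [0, fmax] using DPSS tapers on the full segment.

    Defaults (time-bandwidth product 3, 5 tapers) follow common practice for
    5 s hippocampal LFP segments. The estimate is an average of per-taper
    periodograms and is deterministic.
    """
    trace = np.asarray(trace, float)
    if trace.ndim != 1:
        raise ValueError("trace must be 1-D")
    if trace.size < 2 * fs:
        raise ValueError("trace must be at least 2 s long")
    if fs < 2 * fmax:
        raise ValueError("fs must be at least twice fmax")
    n = trace.size
    tapers = _dpss_cached(n, nw, n_tapers)  # (n_tapers, n), unit-energy rows
    spectra = np.abs(np.fft.rfft(tapers * trace[None, :], axis=1)) ** 2
    power = spectra.mean(axis=0) / fs
    # one-sided density: double all bins except DC (and Nyquist when present)
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    keep = freqs <= fmax
    return PSDEstimate(freqs=freqs[keep], power=power[keep])


def bandpower(psd: PSDEstimate, band: tuple[float, float]) -> float:
    """Integrated power over the half-open interval [lo, hi).

    Bin-sum integration (power * df) keeps adjacent bands exactly additive.
    """
    lo, hi = band
    if lo >= hi:
        raise ValueError("band must satisfy lo < hi")
    freqs = psd.freqs
    if lo < freqs[0] - 1e-9 or hi > freqs[-1] + 1e-9:
        raise ValueError(f"band {band} outside PSD range [{freqs[0]}, {freqs[-1]}]")
    df = freqs[1] - freqs[0]
    mask = (freqs >= lo) & (freqs < hi)
    return float(psd.power[mask].sum() * df)


def band_percent_change(
    stim_psd: PSDEstimate,
    band: tuple[float, float],
    session_baseline: float,
) -> float:
    """Percent change of stimulation bandpower vs the session baseline.

    ``session_baseline`` is the mean pre-stimulation bandpower over all
    trials in the recording session, making the metric scale-invariant.
    """
    if session_baseline <= 0:
        raise ValueError("session baseline power must be positive")
    return 100.0 * (bandpower(stim_psd, band) - session_baseline) / session_baseline


def closest_band(freq: float) -> tuple[str, tuple[float, float]]:
    """Canonical band containing (or nearest to) a stimulation frequency."""
    best, best_dist = None, np.inf
    for name, (lo, hi) in CANONICAL_BANDS.items():
        if lo <= freq < hi:
            return name, (lo, hi)
        dist = min(abs(freq - lo), abs(freq - hi))
        if dist < best_dist:
            best, best_dist = name, dist
    return best, CANONICAL_BANDS[best]


def modulation_profile(
    stim_psds: Sequence[PSDEstimate],
    baseline_psd: PSDEstimate,
    freq_bins: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean per-frequency-bin bandpower percent change across trials.

    ``baseline_psd`` is the session-average pre-stimulation PSD. Returns
    (bin centers, mean percent change per bin) over 0-100 Hz by default.
    """
    if len(stim_psds) == 0:
        raise ValueError("modulation profile requires at least one trial")
    if freq_bins is None:
        freq_bins = np.arange(0.0, 102.0, 2.0)
    freq_bins = np.asarray(freq_bins, float)
    centers = (freq_bins[:-1] + freq_bins[1:]) / 2.0
    base = np.array(
        [bandpower(baseline_psd, (lo, hi)) for lo, hi in zip(freq_bins, freq_bins[1:])]
    )
    if np.any(base <= 0):
        raise ValueError("baseline PSD has empty bins over the requested range")
    pct = np.zeros((len(stim_psds), centers.size))
    for i, psd in enumerate(stim_psds):
        stim = np.array(
            [bandpower(psd, (lo, hi)) for lo, hi in zip(freq_bins, freq_bins[1:])]
        )
        pct[i] = 100.0 * (stim - base) / base
    return centers, pct.mean(axis=0)


def autocorr_at_freq(trace: np.ndarray, fs: float, freq: float) -> float:
    """Normalized autocorrelation coefficient at the lag nearest 1/freq.

    Uses the biased estimator (normalised by the lag-0 value), so the
    coefficient lies in [-1, 1] and is invariant to trace rescaling.
    """
    if freq <= 0:
        raise ValueError("freq must be positive")
    trace = np.asarray(trace, float)
    lag = int(round(fs / freq))
    if lag >= trace.size or trace.size <= 2 * fs / freq:
        raise ValueError("trace too short for the requested lag")
    x = trace - trace.mean()
    denom = float(np.mean(x * x))
    if denom == 0:
        raise ValueError("constant trace has undefined autocorrelation")
    # mean-product form so the finite overlap does not shrink the coefficient
    r = float(np.mean(x[:-lag] * x[lag:]) / denom)
    return float(np.clip(r, -1.0, 1.0))


def feature_vector(stim_psd: PSDEstimate) -> np.ndarray:
    """Log-scaled PSD interpolated onto the fixed 164-point 0-50 Hz grid."""
    if stim_psd.freqs[0] > 0.0 or stim_psd.freqs[-1] < 50.0:
        raise ValueError("PSD must cover the 0-50 Hz range")
    interp = np.interp(FEATURE_FREQS, stim_psd.freqs, stim_psd.power)
    return np.log(np.maximum(interp, _LOG_FLOOR))


def feature_table(
    trial_table: pd.DataFrame,
    signals: Mapping[str, Mapping[str, np.ndarray]],
    fs: float,
    *,
    fmax: float = 100.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Compute per-trial spectral features for a simulated experiment.

    Session baselines are the mean pre-stimulation theta/gamma bandpowers
    over all trials within each recording session. Returns a feature table
    (trial metadata + ``theta_pct``/``gamma_pct``) and the matrix of
    164-dim log-PSD vectors aligned with the table rows.
    """
    pre_band: dict[str, tuple[float, float]] = {}
    stim_psds: dict[str, PSDEstimate] = {}
    for trial_id in trial_table["trial_id"]:
        segs = signals[trial_id]
        pre_psd = multitaper_psd(segs["pre"], fs, fmax)
        stim_psds[trial_id] = multitaper_psd(segs["stim"], fs, fmax)
        pre_band[trial_id] = (
            bandpower(pre_psd, THETA_BAND),
            bandpower(pre_psd, GAMMA_BAND),
        )
    base = pd.DataFrame(
        {
            "trial_id": list(pre_band),
            "theta_pre": [v[0] for v in pre_band.values()],
            "gamma_pre": [v[1] for v in pre_band.values()],
        }
    )
    merged = trial_table.merge(base, on="trial_id")
    session_means = merged.groupby("session_id")[["theta_pre", "gamma_pre"]].transform(
        "mean"
    )
    rows = []
    vecs = np.empty((len(merged), N_FEATURES))
    for i, row in enumerate(merged.itertuples(index=False)):
        psd = stim_psds[row.trial_id]
        theta_pct = band_percent_change(
            psd, THETA_BAND, float(session_means["theta_pre"].iloc[i])
        )
        gamma_pct = band_percent_change(
            psd, GAMMA_BAND, float(session_means["gamma_pre"].iloc[i])
        )
        rows.append({"theta_pct": theta_pct, "gamma_pct": gamma_pct})
        vecs[i] = feature_vector(psd)
    out = pd.concat([merged.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
    return out.drop(columns=["theta_pre", "gamma_pre"]), vecs
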