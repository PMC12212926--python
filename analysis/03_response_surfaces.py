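"""Fit parameter -> gamma-power response surfaces and the
entrainment-vs-frequency profile.

Per subject, a GP regression maps standard-pulse parameters (amplitude,
frequency, pulse width) to low-gamma percent change; kernel choice follows
cross-validated NMSE over subjects. A separate grid-frequency experiment
tests, per discrete stimulation frequency, whether power in the nearest
canonical band rises above baseline (one-sided Wilcoxon).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from stimscape.simulate import SimConfig, _trial_parts
from stimscape.spectral import bandpower, closest_band, multitaper_psd
from stimscape.surfaces import (
    entrainment_vs_frequency,
    fit_surface,
    predict_surface,
    select_kernel,
)
from stimscape.waveforms import DEFAULT_FREQ_GRID, WaveformSpec

PARAMS = ["amplitude", "freq", "pulse_width"]


def surfaces(feats: pd.DataFrame, out: Path):
    std = feats[feats["kind"] == "standard"]
    datasets = [
        (sub[PARAMS].to_numpy(), sub["gamma_pct"].to_numpy())
        for _, sub in std.groupby("subject_id")
    ]
    choice = select_kernel(datasets, folds=5)
    print(f"cross-validated kernel choice: mean={choice[0]}, cov={choice[1]}")

    rows = []
    for (subject, sub), (X, y) in zip(std.groupby("subject_id"), datasets):
        model = fit_surface(X, y, choice)
        amps = np.linspace(10, 50, 9)
        freqs = np.linspace(5, 42, 16)
        grid = np.array([[a, f, 0.005] for a in amps for f in freqs])
        mu, sd = predict_surface(model, grid)
        best = grid[np.argmax(mu)]
        print(
            f"  {subject}: gamma-maximizing parameters amp={best[0]:.0f} "
            f"mW/mm^2, freq={best[1]:.1f} Hz "
            f"({model.outlier_idx.size} outliers removed)"
        )
        for (a, f, pw), m, s in zip(grid, mu, sd):
            rows.append(
                {"subject": subject, "amplitude": a, "freq": f,
                 "pred_gamma_pct": m, "pred_sd": s}
            )
    pd.DataFrame(rows).to_csv(out / "gamma_surface.csv", index=False)


def entrainment(seed: int, out: Path, n_per_freq: int = 40):
    cfg = SimConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for f in DEFAULT_FREQ_GRID:
        band = closest_band(f)[1]
        spec = WaveformSpec(kind="standard", amplitude=50, freq=f, pulse_width=0.005)
        pres, stims = [], []
        for _ in range(n_per_freq):
            pre, bg, r = _trial_parts(spec, "quiescence", cfg, rng, 1.0)
            pres.append(bandpower(multitaper_psd(pre, cfg.fs, 100.0), band))
            stims.append(bandpower(multitaper_psd(bg + r, cfg.fs, 100.0), band))
        base = float(np.mean(pres))
        rows.extend(
            {"freq": f, "stim_band_pct": 100 * (v - base) / base} for v in stims
        )
    result = entrainment_vs_frequency(pd.DataFrame(rows), list(DEFAULT_FREQ_GRID))
    result.to_csv(out / "entrainment_vs_frequency.csv", index=False)
    print("entrainment at the stimulated band (one-sided Wilcoxon):")
    for row in result.itertuples(index=False):
        star = "*" if row.p_value < 0.01 else " "
        print(f"  {row.freq:5.0f} Hz  mean {row.mean_pct:+8.1f}%  p={row.p_value:.2e} {star}")
    sig = result[result["p_value"] < 0.01]
    if not sig.empty:
        print(f"lowest frequency with significant entrainment: {sig['freq'].min():.0f} Hz")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=23)
    args = ap.parse_args()
    feats = pd.read_csv(args.out / "features.csv")
    surfaces(feats, args.out)
    entrainment(args.seed, args.out)


if __name__ == "__main__":
    main()
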