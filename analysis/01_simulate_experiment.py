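"""Simulate a desk-scale stimulation experiment.

Generates all five waveform parameter spaces for four synthetic subjects at
a tenth of the in-vivo trial schedule (the schedule itself is the full
600/750/1750-per-space design, scaled uniformly), alternating behavioral
conditions across sessions, and writes the trial table plus the signal
container under results/.
"""

import argparse
from pathlib import Path

import numpy as np

from stimscape.simulate import SimConfig, simulate_experiment

SPACES = ["sine", "standard", "poisson", "double_sine", "nested"]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--scale", type=float, default=0.1,
                    help="fraction of the full per-space trial schedule")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = SimConfig(n_subjects=4, session_size=60)
    rng = np.random.default_rng(args.seed)
    table, _ = simulate_experiment(
        SPACES, cfg, rng,
        trials_scale=args.scale,
        out_path=str(args.out / "signals.h5"),
    )
    table.to_csv(args.out / "trials.csv", index=False)

    stim = table[table["kind"] != "behavior"]
    print(f"simulated {len(table)} trials ({len(stim)} stimulation) "
          f"for {table['subject_id'].nunique()} subjects")
    print(stim.groupby("kind").size().to_string())
    print(f"wrote {args.out / 'trials.csv'} and {args.out / 'signals.h5'}")


if __name__ == "__main__":
    main()
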