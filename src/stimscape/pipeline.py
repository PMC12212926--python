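"""End-to-end orchestration: simulate -> features -> latent -> stats.

``run_full_analysis`` executes the stages in order against a single YAML
config and seed, writing per-stage outputs and a run manifest (config
snapshot, per-stage seeds, output digests) under the output directory.
Stages communicate through files only, so a failed run can be inspected
and reasoned about stage by stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .latent import (
    AMPLITUDE_THRESHOLD,
    DEFAULT_SIGMA,
    DEFAULT_THRESHOLD,
    density_boundary,
    dice,
    embed,
    preprocess_trials,
    region_metrics,
)
from .simulate import SimConfig, simulate_experiment
from .spectral import feature_table
from .stats import bootstrap_friedman

__all__ = ["run_full_analysis", "cli", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "spaces": ["standard", "nested", "poisson", "sine", "double_sine"],
    "trials_scale": 1.0,
    "method": "umap",
    "sigma": DEFAULT_SIGMA,
    "threshold": DEFAULT_THRESHOLD,
    "amplitude_threshold": AMPLITUDE_THRESHOLD,
    "n_replicates": 5,
    "sim": {},
}

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}


def _load_config(config: str | Path | Mapping | None) -> dict:
    if config is None:
        cfg = {}
    elif isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(config)
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {**DEFAULT_CONFIG, **cfg}
    bad_sim = set(merged["sim"]) - _SIM_FIELDS
    if bad_sim:
        raise ValueError(f"unknown sim config keys: {sorted(bad_sim)}")
    if merged["method"] not in ("umap", "tsne", "pca"):
        raise ValueError(f"unknown embedding method {merged['method']!r}")
    return merged


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def run_full_analysis(
    config: str | Path | Mapping | None,
    seed: int,
    out_dir: str | Path,
) -> dict:
    """Run the full pipeline and return the run manifest.

    Produces per-waveform normalized areas, the DICE-vs-behavior table and
    bootstrapped Friedman p-values for both metrics, per subject, under
    ``out_dir``.
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ["simulate", "embed", "stats"], ss.spawn(3)
        )
    }
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "stage_seeds": stage_seeds,
        "config": cfg,
        "stages": {},
        "timestamps": {},
    }

    def finish_stage(name: str, outputs: list[Path]):
        manifest["stages"][name] = {p.name: _digest(p) for p in outputs}
        manifest["timestamps"][name] = time.time()
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(_manifest_for_dump(manifest), fh, sort_keys=True)

    # stage 1: simulate
    sim_cfg = SimConfig(**cfg["sim"])
    rng = np.random.default_rng(stage_seeds["simulate"])
    trials_path = out / "trials.csv"
    signals_path = out / "signals.h5"
    table, signals = simulate_experiment(
        cfg["spaces"],
        sim_cfg,
        rng,
        trials_scale=cfg["trials_scale"],
        out_path=str(signals_path),
    )
    table.to_csv(trials_path, index=False)
    finish_stage("simulate", [trials_path, signals_path])

    # stage 2: spectral features
    features_path = out / "features.csv"
    logpsd_path = out / "logpsd.npy"
    feats, vecs = feature_table(table, signals, sim_cfg.fs)
    feats.to_csv(features_path, index=False)
    np.save(logpsd_path, vecs)
    finish_stage("features", [features_path, logpsd_path])

    # stage 3: latent space, per subject
    latent_dir = out / "latent"
    latent_dir.mkdir(exist_ok=True)
    keep_table, keep_vecs = preprocess_trials(
        feats, vecs, cfg["amplitude_threshold"]
    )
    area_frames, dice_frames = [], []
    points_by_subject: dict[str, dict[str, np.ndarray]] = {}
    latent_outputs = []
    for subject, sub_table in keep_table.groupby("subject_id"):
        idx = sub_table.index.to_numpy()
        emb = embed(keep_vecs[idx], cfg["method"], seed=stage_seeds["embed"])
        emb_table = sub_table.iloc[emb.index].reset_index(drop=True)
        coords_path = latent_dir / f"{subject}_embedding.csv"
        pd.concat(
            [
                emb_table[["trial_id", "kind"]],
                pd.DataFrame(emb.coords, columns=["x", "y"]),
            ],
            axis=1,
        ).to_csv(coords_path, index=False)
        groups = {
            kind: emb.coords[(emb_table["kind"] == kind).to_numpy()]
            for kind in emb_table["kind"].unique()
        }
        points_by_subject[subject] = groups
        masks = {
            kind: density_boundary(pts, cfg["sigma"], cfg["threshold"], kind)
            for kind, pts in groups.items()
        }
        total = density_boundary(emb.coords, cfg["sigma"], cfg["threshold"], "total")
        areas, dice_table = region_metrics(masks, total)
        areas.insert(0, "subject", subject)
        area_frames.append(areas)
        d = dice_table.reset_index(names="group")
        d.insert(0, "subject", subject)
        dice_frames.append(d)
        latent_outputs.append(coords_path)
    areas_path = out / "normalized_areas.csv"
    dice_path = out / "dice_table.csv"
    pd.concat(area_frames).to_csv(areas_path, index=False)
    pd.concat(dice_frames).to_csv(dice_path, index=False)
    finish_stage("latent", latent_outputs + [areas_path, dice_path])

    # stage 4: bootstrapped Friedman statistics
    sigma, thresh = cfg["sigma"], cfg["threshold"]
    totals = {
        s: density_boundary(
            np.vstack(list(groups.values())), sigma, thresh
        ).count
        for s, groups in points_by_subject.items()
    }

    def area_metric(subject, resampled):
        return {
            g: density_boundary(pts, sigma, thresh).count / totals[subject]
            for g, pts in resampled.items()
        }

    def dice_metric(subject, resampled):
        beh = density_boundary(resampled["behavior"], sigma, thresh)
        return {
            g: dice(density_boundary(pts, sigma, thresh), beh)
            for g, pts in resampled.items()
        }

    stats_rng = np.random.default_rng(stage_seeds["stats"])
    report = {}
    for name, metric in [("normalized_area", area_metric), ("dice_vs_behavior", dice_metric)]:
        res = bootstrap_friedman(
            metric,
            points_by_subject,
            n_replicates=cfg["n_replicates"],
            rng=stats_rng,
        )
        report[name] = {
            "statistic": res.statistic,
            "df": res.df,
            "p_value": res.p_value,
            "n_replicates": res.n_replicates,
            "subject_level_p": res.subject_level_p,
        }
    stats_path = out / "stats.yaml"
    with open(stats_path, "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=True)
    finish_stage("stats", [stats_path])
    return manifest


def _manifest_for_dump(manifest: dict) -> dict:
    out = json.loads(json.dumps(manifest, default=str))
    return out


def cli():
    """Console entry point: ``stimscape run --config cfg.yaml --seed 11 --out runs/``."""
    import click

    @click.group(name="stimscape")
    def group():
        """Irregular-stimulation waveform analysis pipeline."""

    @group.command()
    @click.option("--config", type=click.Path(exists=True), default=None)
    @click.option("--seed", type=int, default=0, show_default=True)
    @click.option("--out", type=click.Path(), required=True)
    def run(config, seed, out):
        """Run simulate -> features -> latent -> stats end to end."""
        manifest = run_full_analysis(config, seed, out)
        click.echo(yaml.safe_dump({"stages": list(manifest["stages"])}))

    group()
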