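"""Neural latent space: 2-D embeddings of per-trial log-PSD vectors,
kernel-density boundary masks on a fixed grid, normalized areas, DICE
overlaps and nearest-neighbor inspection.

The boundary primitive follows a fixed recipe: embedding coordinates are
min-max normalized to [-1, 1], densities are evaluated on a 200 x 200 grid
spanning [-1.1, 1.1] as an average of unit-mass symmetric 2-D Gaussian
kernels (sigma = 0.05), and a group's region is the set of grid nodes where
the density strictly exceeds 0.01.
"""

from __future__ import annotations


from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GRID_SIZE",
    "GRID_RANGE",
    "DEFAULT_SIGMA",
    "DEFAULT_THRESHOLD",
    "AMPLITUDE_THRESHOLD",
    "Embedding2D",
    "RegionMask",
    "preprocess_trials",
    "embed",
    "normalize_coords",
    "density_boundary",
    "dice",
    "region_metrics",
    "query_neighbors",
]

GRID_SIZE = 200
GRID_RANGE = (-1.1, 1.1)
DEFAULT_SIGMA = 0.05
DEFAULT_THRESHOLD = 0.01
#: stimulation trials below this irradiance (mW/mm^2) are excluded.
AMPLITUDE_THRESHOLD = 30.0


@dataclass(frozen=True)
class Embedding2D:
    """Per-trial 2-D coordinates after outlier exclusion and normalization.

    ``index`` holds the positions (into the input feature matrix) of the
    retained trials, so labels can be re-aligned by the caller.
    """

    coords: np.ndarray
    index: np.ndarray
    method: str
    norm_lo: np.ndarray
    norm_hi: np.ndarray


@dataclass(frozen=True)
class RegionMask:
    """Boolean occupancy of one trial group over the fixed evaluation grid."""

    mask: np.ndarray
    grid: np.ndarray
    label: str = ""

    def __post_init__(self):
        mask = np.asarray(self.mask, bool)
        if mask.shape != (GRID_SIZE, GRID_SIZE):
            raise ValueError(f"mask must be {GRID_SIZE}x{GRID_SIZE}")
        object.__setattr__(self, "mask", mask)

    @property
    def count(self) -> int:
        return int(self.mask.sum())


def grid_axis() -> np.ndarray:
    return np.linspace(GRID_RANGE[0], GRID_RANGE[1], GRID_SIZE)


def preprocess_trials(
    table: pd.DataFrame,
    features: np.ndarray,
    amplitude_threshold: float = AMPLITUDE_THRESHOLD,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Drop low-amplitude stimulation trials; behavior trials always survive.

    The exclusion is a strict inequality: amplitude < threshold is removed.
    """
    features = np.asarray(features, float)
    if len(table) != len(features):
        raise ValueError("table and feature matrix must align")
    is_behavior = table["kind"].eq("behavior")
    amp = table.get("amplitude")
    if amp is None:
        if not is_behavior.all():
            raise ValueError("stimulation trials require amplitude labels")
        keep = np.ones(len(table), bool)
    else:
        keep = (is_behavior | (amp >= amplitude_threshold)).to_numpy()
    if not keep.any():
        raise ValueError("no trials survive the amplitude exclusion")
    return table.loc[keep].reset_index(drop=True), features[keep]


def normalize_coords(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Min-max normalize each axis to [-1, 1]; idempotent.

    Degenerate axes (a single distinct value) map to 0.
    """
    coords = np.asarray(coords, float)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    span = hi - lo
    out = np.zeros_like(coords)
    for d in range(coords.shape[1]):
        if span[d] > 0:
            out[:, d] = 2.0 * (coords[:, d] - lo[d]) / span[d] - 1.0
    return out, lo, hi


def _mean_pairwise_distances(coords: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(coords))
    n = coords.shape[0]
    return d.sum(axis=1) / max(n - 1, 1)


def embed(
    features: np.ndarray,
    method: str = "umap",
    seed: int = 0,
    *,
    outlier_sd: float = 3.0,
    **method_kwargs,
) -> Embedding2D:
    """Reduce the feature matrix to 2-D and apply latent-space exclusions.

    Library adapters (umap-learn, scikit-learn t-SNE/PCA) produce the raw
    coordinates; trials whose mean pairwise Euclidean distance to all other
    embedded points exceeds three standard deviations above the average are
    dropped, and the surviving coordinates are min-max normalized to [-1, 1].
    """
    X = np.asarray(features, float)
    if X.ndim != 2 or X.shape[0] < 10:
        raise ValueError("embed requires a 2-D matrix with at least 10 rows")
    if method == "pca":
        from sklearn.decomposition import PCA

        raw = PCA(n_components=2, random_state=seed).fit_transform(X)
    elif method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = method_kwargs.pop("perplexity", min(30.0, (X.shape[0] - 1) / 3))
        raw = TSNE(
            n_components=2, random_state=seed, perplexity=perplexity, **method_kwargs
        ).fit_transform(X)
    elif method == "umap":
        import umap

        raw = umap.UMAP(
            n_components=2, random_state=seed, **method_kwargs
        ).fit_transform(X)
        raw = np.asarray(raw, float)
    else:
        raise ValueError(f"unknown embedding method {method!r}")

    mean_d = _mean_pairwise_distances(raw)
    cut = mean_d.mean() + outlier_sd * mean_d.std()
    keep = np.flatnonzero(mean_d <= cut)
    coords, lo, hi = normalize_coords(raw[keep])
    return Embedding2D(
        coords=coords, index=keep, method=method, norm_lo=lo, norm_hi=hi
    )


def density_boundary(
    points: np.ndarray,
    sigma: float = DEFAULT_SIGMA,
    threshold: float = DEFAULT_THRESHOLD,
    label: str = "",
) -> RegionMask:
    """Gaussian-KDE occupancy mask on the fixed 200 x 200 grid.

    The density is the average of unit-mass 2-D Gaussian kernels (a true
    probability density); a node belongs to the region when its density
    strictly exceeds ``threshold``. An empty point set gives an empty mask.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    axis = grid_axis()
    points = np.asarray(points, float).reshape(-1, 2)
    if points.shape[0] == 0:
        return RegionMask(np.zeros((GRID_SIZE, GRID_SIZE), bool), axis, label)
    gx, gy = np.meshgrid(axis, axis, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    norm = 1.0 / (2.0 * np.pi * sigma**2 * points.shape[0])
    density = np.zeros(nodes.shape[0])
    # chunked to bound the (n_nodes x n_points) distance matrix memory
    chunk = 4000
    for start in range(0, nodes.shape[0], chunk):
        block = nodes[start : start + chunk]
        d2 = (
            (block[:, None, 0] - points[None, :, 0]) ** 2
            + (block[:, None, 1] - points[None, :, 1]) ** 2
        )
        density[start : start + chunk] = norm * np.exp(-d2 / (2 * sigma**2)).sum(
            axis=1
        )
    mask = (density > threshold).reshape(GRID_SIZE, GRID_SIZE)
    return RegionMask(mask, axis, label)


def dice(x: RegionMask, y: RegionMask) -> float:
    """Sorenson-DICE overlap 2|X & Y| / (|X| + |Y|); 0 for two empty masks."""
    if not np.array_equal(x.grid, y.grid):
        raise ValueError("masks evaluated on different grids")
    total = x.count + y.count
    if total == 0:
        return 0.0
    inter = int(np.logical_and(x.mask, y.mask).sum())
    return 2.0 * inter / total


def region_metrics(
    masks: Mapping[str, RegionMask], total: RegionMask
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalized areas plus the pairwise DICE table.

    Areas are counted in grid points: ``normalized_area`` divides by the
    total-boundary count, ``grid_fraction`` by the full grid (the form in
    which representative occupancies are usually quoted).
    """
    if total.count == 0:
        raise ValueError("total mask is empty")
    for m in masks.values():
        if not np.array_equal(m.grid, total.grid):
            raise ValueError("masks evaluated on different grids")
    areas = pd.DataFrame(
        {
            "group": list(masks),
            "points": [m.count for m in masks.values()],
            "grid_fraction": [
                m.count / (GRID_SIZE * GRID_SIZE) for m in masks.values()
            ],
            "normalized_area": [m.count / total.count for m in masks.values()],
        }
    )
    labels = list(masks)
    d = pd.DataFrame(
        [[dice(masks[a], masks[b]) for b in labels] for a in labels],
        index=labels,
        columns=labels,
    )
    return areas, d


def query_neighbors(
    coords: np.ndarray,
    labels: pd.DataFrame,
    query: Sequence[float],
    k: int = 50,
    logpsd: np.ndarray | None = None,
) -> dict:
    """Inspect the k Euclidean-nearest trials around a latent-space point.

    Returns their row indices, a label histogram by waveform class, and
    (when the log-PSD cache is given) the mean log-PSD across them.
    """
    coords = np.asarray(coords, float)
    if k > coords.shape[0]:
        raise ValueError("k exceeds the number of embedded points")
    d = np.linalg.norm(coords - np.asarray(query, float)[None, :], axis=1)
    idx = np.argsort(d, kind="stable")[:k]
    out = {
        "indices": idx,
        "kind_counts": labels.iloc[idx]["kind"].value_counts().to_dict(),
        "labels": labels.iloc[idx].reset_index(drop=True),
    }
    if logpsd is not None:
        out["mean_logpsd"] = np.asarray(logpsd, float)[idx].mean(axis=0)
    return out
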