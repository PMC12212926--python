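"""Latent space: exclusions, embeddings, KDE boundary masks, region
metrics and neighbor queries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.ndimage import label as cc_label

from stimscape.latent import (
    DEFAULT_SIGMA,
    DEFAULT_THRESHOLD,
    GRID_SIZE,
    RegionMask,
    density_boundary,
    dice,
    embed,
    grid_axis,
    normalize_coords,
    preprocess_trials,
    query_neighbors,
    region_metrics,
)


def brute_force_mask(points, sigma=DEFAULT_SIGMA, threshold=DEFAULT_THRESHOLD):
    """Independent KDE evaluation: explicit loop-free full-grid formula."""
    axis = grid_axis()
    gx, gy = np.meshgrid(axis, axis, indexing="ij")
    points = np.asarray(points, float).reshape(-1, 2)
    density = np.zeros(gx.shape)
    for px, py in points:
        density += np.exp(-((gx - px) ** 2 + (gy - py) ** 2) / (2 * sigma**2))
    density /= 2 * np.pi * sigma**2 * len(points)
    return density > threshold


def mask_from_count(count, label=""):
    flat = np.zeros(GRID_SIZE * GRID_SIZE, bool)
    flat[:count] = True
    return RegionMask(flat.reshape(GRID_SIZE, GRID_SIZE), grid_axis(), label)


class TestPreprocess:
    def test_strict_amplitude_inequality(self):
        table = pd.DataFrame(
            {
                "kind": ["sine"] * 5,
                "amplitude": [10.0, 25.0, 29.9, 30.0, 45.0],
            }
        )
        feats = np.arange(5 * 3.0).reshape(5, 3)
        kept, kept_feats = preprocess_trials(table, feats)
        assert kept["amplitude"].tolist() == [30.0, 45.0]
        assert kept_feats.shape == (2, 3)

    def test_zero_threshold_is_identity(self):
        table = pd.DataFrame({"kind": ["sine"] * 3, "amplitude": [10.0, 20.0, 30.0]})
        kept, _ = preprocess_trials(table, np.zeros((3, 2)), amplitude_threshold=0)
        assert len(kept) == 3

    def test_behavior_trials_always_survive(self):
        table = pd.DataFrame(
            {
                "kind": ["sine"] * 100 + ["behavior"] * 50,
                "amplitude": [20.0] * 50 + [40.0] * 50 + [np.nan] * 50,
            }
        )
        kept, _ = preprocess_trials(table, np.zeros((150, 2)))
        assert len(kept) == 100
        assert (kept["kind"] == "behavior").sum() == 50


class TestEmbed:
    def test_pca_recovers_rank_two_structure(self):
        """On an exactly rank-2 matrix the embedding is an affine image of
        the planted 2-D scores (normalization makes the map affine rather
        than orthogonal, so the residual of an affine regression is the
        faithful notion of 'same structure')."""
        rng = np.random.default_rng(0)
        scores = rng.standard_normal((80, 2))
        basis, _ = np.linalg.qr(rng.standard_normal((164, 2)))
        X = scores @ basis.T
        emb = embed(X, "pca", seed=0)
        design = np.column_stack([scores[emb.index], np.ones(len(emb.index))])
        _, residual, _, _ = np.linalg.lstsq(design, emb.coords, rcond=None)
        assert np.all(residual < 1e-6)

    def test_planted_far_outlier_is_dropped(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 164))
        X[17] += 100.0
        emb = embed(X, "pca", seed=0)
        assert 17 not in emb.index

    def test_umap_is_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 164))
        a = embed(X, "umap", seed=7)
        b = embed(X, "umap", seed=7)
        np.testing.assert_array_equal(a.coords, b.coords)

    @pytest.mark.parametrize("method", ["pca", "tsne"])
    def test_adapters_produce_normalized_2d(self, method):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 164))
        emb = embed(X, method, seed=0)
        assert emb.coords.shape[1] == 2
        assert emb.coords.min() >= -1 and emb.coords.max() <= 1

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            embed(np.zeros((20, 164)), "isomap", seed=0)

    def test_normalization_is_idempotent(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(-5, 3, size=(40, 2))
        once, _, _ = normalize_coords(coords)
        twice, _, _ = normalize_coords(once)
        np.testing.assert_array_equal(once, twice)
        assert once.min(axis=0) == pytest.approx([-1, -1])
        assert once.max(axis=0) == pytest.approx([1, 1])


class TestDensityBoundary:
    def test_empty_point_set_gives_empty_mask(self):
        assert density_boundary(np.empty((0, 2))).count == 0

    def test_single_point_matches_brute_force_exactly(self):
        mask = density_boundary(np.array([[0.0, 0.0]]))
        np.testing.assert_array_equal(mask.mask, brute_force_mask([[0.0, 0.0]]))
        assert mask.count > 0

    def test_two_separated_clusters_give_two_components(self):
        rng = np.random.default_rng(5)
        a = rng.normal([-0.5, 0.0], 0.02, size=(40, 2))
        b = rng.normal([0.5, 0.0], 0.02, size=(40, 2))
        mask = density_boundary(np.vstack([a, b]))
        expected = brute_force_mask(np.vstack([a, b]))
        np.testing.assert_array_equal(mask.mask, expected)
        _, n_components = cc_label(mask.mask)
        assert n_components == 2

    def test_occupancy_monotone_in_threshold(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(0, 0.2, size=(50, 2))
        counts = [
            density_boundary(pts, threshold=th).count for th in (0.005, 0.01, 0.05)
        ]
        assert counts[0] >= counts[1] >= counts[2]

    def test_adding_distant_point_grows_occupancy(self):
        rng = np.random.default_rng(7)
        pts = rng.normal([-0.5, -0.5], 0.05, size=(30, 2))
        base = density_boundary(pts).count
        # one far point barely dilutes the cluster density but adds its own
        # above-threshold disk, so occupancy grows
        grown = density_boundary(np.vstack([pts, [0.8, 0.8]])).count
        assert grown >= base


class TestRegionMetrics:
    def test_representative_grid_fractions(self):
        counts = {
            "standard": 8006,
            "sine": 5579,
            "nested": 6549,
            "poisson": 2020,
            "behavior": 2776,
        }
        masks = {k: mask_from_count(c, k) for k, c in counts.items()}
        total = mask_from_count(max(counts.values()) + 100, "total")
        areas, _ = region_metrics(masks, total)
        fractions = dict(zip(areas["group"], areas["grid_fraction"]))
        assert round(100 * fractions["standard"], 1) == 20.0
        assert round(100 * fractions["sine"], 2) == 13.95
        assert round(100 * fractions["nested"], 2) == 16.37
        assert round(100 * fractions["poisson"], 2) == 5.05
        assert round(100 * fractions["behavior"], 2) == 6.94

    def test_dice_identities(self):
        x = mask_from_count(500)
        y = RegionMask(np.roll(x.mask, 600), grid_axis())
        assert dice(x, x) == 1.0
        assert dice(x, y) == 0.0 or np.logical_and(x.mask, y.mask).any()

    def test_nested_region_dice_value(self):
        x = mask_from_count(100)
        big = mask_from_count(300)
        assert dice(x, big) == pytest.approx(2 * 100 / 400)

    @given(
        na=st.integers(0, 400),
        nb=st.integers(0, 400),
        shift=st.integers(0, 200),
    )
    def test_dice_symmetric_and_bounded(self, na, nb, shift):
        a = mask_from_count(na)
        b = RegionMask(np.roll(mask_from_count(nb).mask, shift), grid_axis())
        d = dice(a, b)
        assert 0.0 <= d <= 1.0
        assert d == dice(b, a)
        if na > 0:
            assert dice(a, a) == 1.0

    def test_grid_mismatch_rejected(self):
        x = mask_from_count(10)
        bad = RegionMask(x.mask, x.grid + 1.0)
        with pytest.raises(ValueError, match="grid"):
            dice(x, bad)

    def test_group_subset_area_stays_near_or_below_one(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(0, 0.3, size=(100, 2))
        sub = pts[:40]
        total = density_boundary(pts)
        masks = {"sub": density_boundary(sub)}
        areas, _ = region_metrics(masks, total)
        # KDE tails of a subset can poke past the union boundary slightly
        assert areas["normalized_area"].iloc[0] <= 1.1


class TestQueryNeighbors:
    def test_k_equals_n_returns_grand_mean(self):
        rng = np.random.default_rng(9)
        coords = rng.uniform(-1, 1, size=(30, 2))
        labels = pd.DataFrame({"kind": ["sine"] * 30})
        logpsd = rng.standard_normal((30, 164))
        out = query_neighbors(coords, labels, [0.0, 0.0], k=30, logpsd=logpsd)
        np.testing.assert_allclose(out["mean_logpsd"], logpsd.mean(axis=0))
        with pytest.raises(ValueError):
            query_neighbors(coords, labels, [0.0, 0.0], k=31)

    def test_default_k_is_50(self):
        import inspect

        assert inspect.signature(query_neighbors).parameters["k"].default == 50

    def test_planted_cluster_is_retrieved(self):
        rng = np.random.default_rng(10)
        behavior = rng.normal([0.5, 0.5], 0.02, size=(60, 2))
        other = rng.normal([-0.5, -0.5], 0.3, size=(60, 2))
        coords = np.vstack([behavior, other])
        labels = pd.DataFrame({"kind": ["behavior"] * 60 + ["sine"] * 60})
        out = query_neighbors(coords, labels, [0.5, 0.5], k=50)
        assert out["kind_counts"].get("behavior", 0) >= 45
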