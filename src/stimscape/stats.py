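"""Group-comparison statistics, including the hierarchical bootstrapped
Friedman procedure for latent-space metrics.

The bootstrapped Friedman test models variability at the level of
stimulation trials: for each of N replicates, every subject x group trial
set is resampled with replacement at its original size and the group metric
recomputed; each subject x replicate then forms one block of a Friedman
rank test across groups (so 4 subjects x 5 replicates = 20 blocks and
df = groups - 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.random import Generator
from scipy import stats as sps

__all__ = [
    "kruskal_wallis_compare",
    "sign_test",
    "friedman_from_blocks",
    "BootstrapFriedmanResult",
    "bootstrap_friedman",
]


def kruskal_wallis_compare(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction and chi-squared p-value."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs at least two values")
    if np.ptp(np.concatenate(arrays)) == 0:
        # all values identical: no rank variation at all
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def sign_test(values: np.ndarray) -> tuple[int, float]:
    """Exact two-sided binomial sign test on the count of positive values.

    Exact zeros are dropped first. Returns (number of positives among the
    nonzero values, p-value); p is 2 * min(tail probabilities), capped at 1.
    """
    values = np.asarray(values, float)
    nonzero = values[values != 0]
    if nonzero.size == 0:
        raise ValueError("sign test undefined when all values are zero")
    n = nonzero.size
    k = int(np.sum(nonzero > 0))
    lower = sps.binom.cdf(k, n, 0.5)
    upper = sps.binom.sf(k - 1, n, 0.5)
    return k, float(min(1.0, 2.0 * min(lower, upper)))


def friedman_from_blocks(blocks: np.ndarray) -> tuple[float, int, float]:
    """Friedman rank test on a (n_blocks, n_groups) value matrix.

    Returns (statistic, df, p). Fully tied data (every block constant)
    yields statistic 0 and p = 1.
    """
    blocks = np.atleast_2d(np.asarray(blocks, float))
    n, k = blocks.shape
    if k < 3:
        raise ValueError("Friedman test requires at least three groups")
    if n < 2:
        raise ValueError("Friedman test requires at least two blocks")
    if np.all(blocks == blocks[:, :1]):
        return 0.0, k - 1, 1.0
    stat, p = sps.friedmanchisquare(*[blocks[:, j] for j in range(k)])
    if not np.isfinite(stat):  # residual full-tie degenerate case
        return 0.0, k - 1, 1.0
    return float(stat), k - 1, float(p)


@dataclass(frozen=True)
class BootstrapFriedmanResult:
    """Outcome of the hierarchical bootstrapped Friedman test."""

    replicate_values: pd.DataFrame  # subject, replicate, group, value
    statistic: float
    df: int
    p_value: float
    n_replicates: int
    seed: int | None
    subject_level_statistic: float
    subject_level_p: float


def bootstrap_friedman(
    metric_fn: Callable[[str, Mapping[str, np.ndarray]], Mapping[str, float]],
    data: Mapping[str, Mapping[str, np.ndarray]],
    compare_groups: Sequence[str] | None = None,
    n_replicates: int = 5,
    rng: Generator | None = None,
    *,
    seed: int | None = None,
    resample: bool = True,
    max_retries: int = 5,
) -> BootstrapFriedmanResult:
    """Hierarchical bootstrap + Friedman rank test across groups.

    Parameters
    ----------
    metric_fn
        ``metric_fn(subject_id, resampled_by_group) -> {group: value}`` for
        the groups under comparison. It receives the resampled trial-level
        data of *all* groups for the subject, so overlap metrics that need
        a reference group (e.g. DICE against behavior) can be expressed.
    data
        ``data[subject][group]`` is an indexable array of trial-level items
        (rows are resampled with replacement at original size).
    compare_groups
        Groups entering the Friedman comparison (default: all groups of the
        first subject).
    resample
        When False (with ``n_replicates=1``) the metric is computed on the
        original data, giving the plain subject-level Friedman test.
    """
    subjects = list(data)
    if len(subjects) < 2:
        raise ValueError("need at least two subjects")
    all_groups = list(data[subjects[0]])
    if compare_groups is None:
        compare_groups = all_groups
    if len(compare_groups) < 2:
        raise ValueError("need at least two groups")
    if rng is None:
        rng = np.random.default_rng(seed)

    def one_metric(subject: str, local_rng: Generator, do_resample: bool):
        sub = data[subject]
        resampled = {}
        for g in all_groups:
            arr = np.asarray(sub[g])
            if do_resample and arr.shape[0] > 0:
                idx = local_rng.integers(0, arr.shape[0], size=arr.shape[0])
                resampled[g] = arr[idx]
            else:
                resampled[g] = arr
        return metric_fn(subject, resampled)

    rows = []
    for r in range(n_replicates):
        for subject in subjects:
            result = None
            for _ in range(max_retries):
                try:
                    result = one_metric(subject, rng, resample)
                    break
                except Exception:  # noqa: BLE001 - retried with fresh draws
                    continue
            if result is None:
                raise RuntimeError(
                    f"metric_fn failed {max_retries} times for {subject}"
                )
            for g in compare_groups:
                rows.append(
                    {
                        "subject": subject,
                        "replicate": r,
                        "group": g,
                        "value": float(result[g]),
                    }
                )
    table = pd.DataFrame(rows)
    pivot = table.pivot_table(
        index=["subject", "replicate"], columns="group", values="value"
    )[list(compare_groups)]
    stat, df, p = friedman_from_blocks(pivot.to_numpy())

    # secondary analysis: subject-level only, no trial resampling
    sub_rows = []
    for subject in subjects:
        result = one_metric(subject, rng, do_resample=False)
        sub_rows.append([float(result[g]) for g in compare_groups])
    sub_stat, _, sub_p = friedman_from_blocks(np.asarray(sub_rows))

    return BootstrapFriedmanResult(
        replicate_values=table,
        statistic=stat,
        df=df,
        p_value=p,
        n_replicates=n_replicates,
        seed=seed,
        subject_level_statistic=sub_stat,
        subject_level_p=sub_p,
    )
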