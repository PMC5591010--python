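"""Statistical tests: two-sided bootstrap difference-of-means and two-sided
Fisher's exact test.

The bootstrap test compares the means of two independent groups of unequal
size: each resample redraws both groups with replacement at their original
sizes and recomputes the mean difference; the two-sided p-value is the
smaller sign-crossing tail probability doubled, with add-one smoothing so p
is never exactly zero. This is a percentile bootstrap on the difference of
means, not a permutation test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["bootstrap_mean_diff_test", "BootstrapResult", "fisher_exact_two_sided", "FisherResult"]

#: resamples used for within-gene category comparisons
DEFAULT_RESAMPLES_WITHIN = 100_000
#: resamples used for comparisons against different-gene pairs
DEFAULT_RESAMPLES_ACROSS = 1_000


@dataclass(frozen=True)
class BootstrapResult:
    observed_diff: float
    p_two_sided: float
    n_resamples: int


def bootstrap_mean_diff_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_resamples: int = DEFAULT_RESAMPLES_WITHIN,
    seed: int = 0,
) -> BootstrapResult:
    """Two-sided bootstrap test for a difference in group means.

    observed_diff = mean(a) - mean(b). Each of *n_resamples* iterations
    independently redraws both groups with replacement at their original
    sizes; p = min(1, 2 * min(P(diff* <= 0), P(diff* >= 0))) with add-one
    smoothing P = (count + 1) / (n_resamples + 1). Deterministic given *seed*.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    observed = float(a.mean() - b.mean())
    # chunked to bound memory at large resample counts
    chunk = max(1, min(n_resamples, 10_000_000 // max(a.size + b.size, 1)))
    n_le = 0
    n_ge = 0
    done = 0
    while done < n_resamples:
        m = min(chunk, n_resamples - done)
        means_a = a[rng.integers(0, a.size, size=(m, a.size))].mean(axis=1)
        means_b = b[rng.integers(0, b.size, size=(m, b.size))].mean(axis=1)
        diffs = means_a - means_b
        n_le += int((diffs <= 0).sum())
        n_ge += int((diffs >= 0).sum())
        done += m
    p_le = (n_le + 1) / (n_resamples + 1)
    p_ge = (n_ge + 1) / (n_resamples + 1)
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return BootstrapResult(observed_diff=observed, p_two_sided=p, n_resamples=n_resamples)


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    p: float


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The p-value sums the probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's
    (probability-mass two-sided rule). The odds ratio is the sample odds
    ratio a*d / (b*c), NaN when 0/0.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValueError("table cells must be integers")
        arr = arr.astype(int)
    if (arr < 0).any():
        raise ValueError("table cells must be non-negative")
    if arr.sum() == 0:
        raise ValueError("table must have at least one positive entry")
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    num = a * d
    den = b * c
    if den == 0:
        odds = math.nan if num == 0 else math.inf
    else:
        odds = num / den
    p = float(sps.fisher_exact(arr, alternative="two-sided")[1])
    return FisherResult(odds_ratio=odds, p=min(p, 1.0))
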