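"""Small statistical helpers for correlated Monte Carlo output."""

from __future__ import annotations

import numpy as np

__all__ = ["batch_means_se", "moments_with_se"]


def batch_means_se(samples: np.ndarray, n_batches: int = 20) -> float:
    """Standard error of the mean of a (possibly autocorrelated) series.

    Splits the series into ``n_batches`` contiguous blocks and uses the
    spread of the block means; valid once blocks are longer than the
    autocorrelation time.
    """
    x = np.asarray(samples, dtype=float).ravel()
    n_batches = min(n_batches, x.size)
    if n_batches < 2:
        raise ValueError("need at least 2 batches")
    blocks = np.array_split(x, n_batches)
    means = np.array([b.mean() for b in blocks])
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def moments_with_se(samples: np.ndarray, n_batches: int = 20) -> dict:
    """Mean and variance of a series with batch-means standard errors."""
    x = np.asarray(samples, dtype=float).ravel()
    mean_se = batch_means_se(x, n_batches)
    # variance via batch means of the squared deviations
    dev2 = (x - x.mean()) ** 2
    var_se = batch_means_se(dev2, n_batches)
    return {
        "mean": float(x.mean()),
        "mean_se": mean_se,
        "var": float(x.var(ddof=1)),
        "var_se": var_se,
        "n": int(x.size),
    }
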