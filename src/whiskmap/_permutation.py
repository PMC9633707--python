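"""Vectorized Monte-Carlo permutation machinery.

All permutation tests in the package reduce to the same primitive: shuffle a
pooled set of single-trial values between two groups of fixed sizes and
recompute the difference of group means. The shuffle is represented as a
boolean indicator matrix (one row per iteration, ``n_a`` True entries marking
group-A membership), so a whole null distribution is two matrix products.

Monte-Carlo p-values use the add-one convention (k+1)/(N+1), which avoids
p = 0 and is standard for sampled permutation nulls.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "permutation_indicator",
    "null_mean_diffs",
    "mc_p",
    "perm_diff_test",
]


def permutation_indicator(n_a: int, n_tot: int, n_perm: int,
                          rng: np.random.Generator) -> np.ndarray:
    """(n_perm, n_tot) boolean matrix; each row marks a random size-n_a subset."""
    if not 0 < n_a < n_tot:
        raise ValueError("need 0 < n_a < n_tot")
    r = rng.random((n_perm, n_tot))
    kth = np.partition(r, n_a - 1, axis=1)[:, n_a - 1 : n_a]
    return r <= kth


def null_mean_diffs(values: np.ndarray, n_a: int,
                    indicator: np.ndarray) -> np.ndarray:
    """Null mean(A) − mean(B) for pooled ``values`` under each shuffle row.

    ``values`` may be (n_tot,) or (n_tot, k) for k simultaneous tests sharing
    the same group sizes; returns (n_perm,) or (n_perm, k).
    """
    values = np.asarray(values, dtype=float)
    n_tot = values.shape[0]
    n_b = n_tot - n_a
    ind = indicator.astype(float)
    sum_a = ind @ values
    total = values.sum(axis=0)
    return sum_a / n_a - (total - sum_a) / n_b


def mc_p(null: np.ndarray, observed, alternative: str = "greater") -> np.ndarray:
    """Add-one Monte-Carlo p-value(s) of ``observed`` against ``null``.

    ``null`` has iterations on axis 0; ``observed`` broadcasts against the
    remaining axes. alternative: 'greater', 'less' or 'two-sided'.
    """
    n = null.shape[0]
    # ties with the observed statistic must count as "at least as extreme";
    # the vectorized null is computed by a different float path than the
    # observed value, so allow a tiny tolerance when comparing
    eps = 1e-9 * np.maximum(1.0, np.abs(observed))
    if alternative == "greater":
        k = (null >= observed - eps).sum(axis=0)
    elif alternative == "less":
        k = (null <= observed + eps).sum(axis=0)
    elif alternative == "two-sided":
        k = (np.abs(null) >= np.abs(observed) - eps).sum(axis=0)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (k + 1) / (n + 1)


def perm_diff_test(a: np.ndarray, b: np.ndarray, n_perm: int,
                   rng: np.random.Generator,
                   alternative: str = "greater") -> tuple[float, float]:
    """Permutation test for mean(a) − mean(b); returns (observed, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both trial sets must be non-empty")
    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    ind = permutation_indicator(a.size, pooled.size, n_perm, rng)
    null = null_mean_diffs(pooled, a.size, ind)
    return observed, float(mc_p(null, observed, alternative))
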