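"""Two-sample randomisation test on mean isotope values.

The observed statistic is the absolute difference of group means.  Under
the null of exchangeability the pooled values are randomly reallocated to
the two groups (keeping group sizes) and the statistic recomputed; the
p-value is the add-one-corrected exceedance proportion

    p = (1 + #{|T*| >= |T_obs|}) / (1 + n_permutations)

so p is never exactly zero at finite permutation counts.  Ties with the
observed statistic count as exceedances.  When the number of distinct
allocations C(n_a + n_b, n_a) is small the test can enumerate them all and
report the exact proportion instead.

The test makes no normality or equal-variance assumption, which suits the
small per-species sample sizes typical of stranding data.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np

__all__ = ["RandomisationResult", "randomisation_test"]

DEFAULT_PERMUTATIONS = 10_000
EXHAUSTIVE_LIMIT = 10**6  # enumerate exactly when C(n, n_a) is at most this


@dataclass(frozen=True)
class RandomisationResult:
    observed_diff: float  # mean(a) − mean(b), ‰
    abs_observed: float
    n_permutations: int
    p_value: float
    alpha: float
    significant: bool
    seed: int | None
    exhaustive: bool = False


def randomisation_test(
    a: Sequence[float],
    b: Sequence[float],
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    alpha: float = 0.05,
    exhaustive: bool | None = None,
) -> RandomisationResult:
    """Two-sided randomisation test for a difference in means.

    ``exhaustive=None`` (default) picks Monte-Carlo sampling; pass ``True``
    to force full enumeration of all C(n_a+n_b, n_a) allocations (exact
    p-value, no add-one correction), allowed only below a size cap.  Both
    groups need at least two values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")

    observed = a.mean() - b.mean()
    abs_obs = abs(observed)
    pool = np.concatenate([a, b])
    na, n = a.size, a.size + b.size
    total = pool.sum()

    if exhaustive:
        n_alloc = comb(n, na)
        if n_alloc > EXHAUSTIVE_LIMIT:
            raise ValueError(f"{n_alloc} allocations exceed the exhaustive cap")
        exceed = 0
        for idx in combinations(range(n), na):
            sa = pool[list(idx)].sum()
            diff = sa / na - (total - sa) / (n - na)
            if abs(diff) >= abs_obs - 1e-12:
                exceed += 1
        p = exceed / n_alloc
        return RandomisationResult(
            float(observed), float(abs_obs), n_alloc, p, alpha, p < alpha, seed, True
        )

    rng = np.random.default_rng(seed)
    # vectorised permutations: random keys -> the first na positions of each
    # row's argsort form a uniform random na-subset of the pool
    keys = rng.random((n_permutations, n))
    idx = np.argsort(keys, axis=1)[:, :na]
    sa = pool[idx].sum(axis=1)
    diffs = sa / na - (total - sa) / (n - na)
    exceed = int(np.count_nonzero(np.abs(diffs) >= abs_obs - 1e-12))
    p = (1 + exceed) / (1 + n_permutations)
    return RandomisationResult(
        float(observed), float(abs_obs), n_permutations, p, alpha, p < alpha, seed, False
    )
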