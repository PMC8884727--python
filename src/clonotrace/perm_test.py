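"""Mouse-level permutation test for group differences.

Compares an observed between-group effect (by default the absolute
difference of group means of a per-mouse statistic, a two-sided test) to
its distribution over random regroupings of the pooled mice.  When the
number of distinct regroupings C(nA+nB, nA) is small enough the null is
enumerated exhaustively and the p-value is the fraction of regroupings
(including the observed one) whose effect is at least the observed one;
otherwise regroupings are sampled Monte Carlo with the add-one correction
p = (1 + #{null >= observed}) / (1 + n_perm).  Ties count toward the
numerator, so p is always in (0, 1] and never below 1/n_permutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Callable, Sequence

import numpy as np

#: relative tolerance when comparing permuted effects to the observed one;
#: guards against last-ulp differences in re-ordered float sums
_REL_TOL = 1e-9


def abs_mean_difference(a: np.ndarray, b: np.ndarray) -> float:
    """Default two-sided effect: |mean(A) - mean(B)|."""
    return abs(float(np.mean(a)) - float(np.mean(b)))


def mean_difference(a: np.ndarray, b: np.ndarray) -> float:
    """One-sided effect: mean(A) - mean(B)."""
    return float(np.mean(a)) - float(np.mean(b))


@dataclass
class PermutationResult:
    observed_effect: float
    null_effects: np.ndarray
    p_value: float
    n_permutations: int
    mode: str  # "exhaustive" | "monte_carlo"
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "observed_effect": self.observed_effect,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "mode": self.mode,
            "seed": self.seed,
        }


def permutation_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    effect: Callable[[np.ndarray, np.ndarray], float] = abs_mean_difference,
    max_exhaustive: int = 100_000,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Permutation test of a per-mouse statistic between two groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("values must be finite")

    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    observed = effect(a, b)
    tol = _REL_TOL * max(1.0, abs(observed))

    n_comb = comb(n, na)
    if n_comb <= max_exhaustive:
        if effect is abs_mean_difference or effect is mean_difference:
            # vectorized fast path for the difference-of-means statistics
            idx = np.fromiter(
                (i for c in combinations(range(n), na) for i in c), dtype=np.intp
            ).reshape(n_comb, na)
            sums_a = pooled[idx].sum(axis=1)
            total = pooled.sum()
            diffs = sums_a / na - (total - sums_a) / (n - na)
            null = np.abs(diffs) if effect is abs_mean_difference else diffs
        else:
            null = np.empty(n_comb)
            all_idx = set(range(n))
            for j, c in enumerate(combinations(range(n), na)):
                rest = sorted(all_idx - set(c))
                null[j] = effect(pooled[list(c)], pooled[rest])
        p = float(np.count_nonzero(null >= observed - tol)) / n_comb
        return PermutationResult(
            observed_effect=observed,
            null_effects=null,
            p_value=p,
            n_permutations=n_comb,
            mode="exhaustive",
            seed=seed,
        )

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for j in range(n_perm):
        perm = rng.permutation(pooled)
        null[j] = effect(perm[:na], perm[na:])
    p = (1.0 + float(np.count_nonzero(null >= observed - tol))) / (1.0 + n_perm)
    return PermutationResult(
        observed_effect=observed,
        null_effects=null,
        p_value=p,
        n_permutations=n_perm,
        mode="monte_carlo",
        seed=seed,
    )


def batch_permutation_tests(
    stats: "pd.DataFrame",
    group_a: str,
    group_b: str,
    value_columns: Sequence[str] | None = None,
    **kwargs,
):
    """Run the permutation test for many per-mouse statistics at once.

    ``stats`` has one row per mouse with a "group" column and one column
    per statistic; returns a DataFrame with one row per statistic.
    """
    import pandas as pd

    cols = value_columns or [c for c in stats.columns if c not in ("mouse", "group")]
    rows = []
    for col in cols:
        va = stats.loc[stats["group"] == group_a, col].dropna()
        vb = stats.loc[stats["group"] == group_b, col].dropna()
        res = permutation_test(va.to_numpy(), vb.to_numpy(), **kwargs)
        rows.append(
            {
                "statistic": col,
                "mean_a": float(va.mean()),
                "mean_b": float(vb.mean()),
                **res.to_dict(),
            }
        )
    return pd.DataFrame(rows)
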