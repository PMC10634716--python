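"""The footprint enrichment statistic and its Monte-Carlo multinomial null.

Around a bound CTCF site, short-fragment 5' read ends pile up on the
positive strand upstream (quadrant Q2) and the negative strand downstream
(Q4) of the motif center, while reads in Q1 ('+' downstream) and Q3 ('-'
upstream) imply MNase cuts under the protected DNA. The test statistic is

    alpha_hat = min(n2, n4) / max(n1, n3)

with n_i the read count in quadrant i; min/max enforce a pile-up in *both*
Q2 and Q4 so a one-sided pile-up cannot be called as binding.

Under the null (no binding) each read falls in each quadrant with
probability 1/4 independently, i.e. (n1..n4) ~ Multinomial(N, 1/4). The
null distribution of log2(alpha_hat) is tabulated empirically per total
count N on a fixed grid 0.00..5.00 (step 0.01, i.e. alpha_hat in [1, 32]),
for N from ``n_min`` to ``n_max``; larger N reuse the ``n_max`` row, whose
p-values have effectively converged. Observed statistics are snapped *down*
to the grid (conservative), and p-values are floored at 1/reps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

__all__ = [
    "QuadrantCounts",
    "NullTable",
    "GRID",
    "ff_statistic",
    "stat_grid_index",
    "build_null_table",
    "pvalue",
]

GRID = np.arange(501) / 100.0  # log2(alpha_hat) grid, 0.00 .. 5.00
GRID_TOP = 5.0


@dataclass(frozen=True)
class QuadrantCounts:
    """Strand x side read counts around a candidate center.

    Q2: '+' upstream of center; Q1: '+' at/downstream; Q3: '-' upstream;
    Q4: '-' at/downstream.
    """

    n1: int
    n2: int
    n3: int
    n4: int

    def __post_init__(self) -> None:
        if min(self.n1, self.n2, self.n3, self.n4) < 0:
            raise ValueError("quadrant counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n1 + self.n2 + self.n3 + self.n4


def ff_statistic(q: QuadrantCounts) -> float:
    """log2(min(n2,n4) / max(n1,n3)), capped at the grid top (5.0).

    Returns ``-inf`` (not enriched) when min(n2,n4) = 0 — both Q2 and Q4
    must contain reads — and the cap when the denominator is 0 with a
    non-zero numerator.
    """
    mn = min(q.n2, q.n4)
    mx = max(q.n1, q.n3)
    if mn == 0:
        return -np.inf
    if mx == 0:
        return GRID_TOP
    return min(np.log2(mn / mx), GRID_TOP)


def stat_grid_index(n1, n2, n3, n4) -> np.ndarray:
    """Vectorized grid index of the statistic; -1 where log2(alpha_hat) < 0.

    The index is floor(100 * log2(alpha_hat)) clipped to [0, 500] — the
    largest grid value <= the observed statistic (conservative snap-down).
    """
    n1 = np.asarray(n1, dtype=np.int64)
    n2 = np.asarray(n2, dtype=np.int64)
    n3 = np.asarray(n3, dtype=np.int64)
    n4 = np.asarray(n4, dtype=np.int64)
    mn = np.minimum(n2, n4)
    mx = np.maximum(n1, n3)
    idx = np.full(mn.shape, -1, dtype=np.int64)
    cap = (mn > 0) & (mx == 0)
    idx[cap] = 500
    ok = (mn > 0) & (mx > 0)
    if ok.any():
        ratio = mn[ok] / mx[ok]
        lg = np.log2(ratio)
        val = np.where(lg < 0, -1, np.minimum(np.floor(lg * 100), 500))
        idx[ok] = val.astype(np.int64)
    return idx


@dataclass
class NullTable:
    """Per-N empirical survival function of log2(alpha_hat) under the null.

    ``survival[N - n_min, j] = P(log2(alpha_hat) >= GRID[j] | N)`` estimated
    from ``reps`` multinomial draws per N. Rows are non-increasing along the
    grid by construction.
    """

    n_min: int
    n_max: int
    reps: int
    seed: Optional[int]
    survival: np.ndarray  # shape (n_max - n_min + 1, 501)
    low_reps: bool = False

    @property
    def grid(self) -> np.ndarray:
        return GRID

    def row(self, n: int) -> np.ndarray:
        """Survival row for total count n (n > n_max reuses the n_max row)."""
        if n < self.n_min:
            raise ValueError(f"N={n} below table minimum {self.n_min}")
        return self.survival[min(n, self.n_max) - self.n_min]

    def pvalues(self, n1, n2, n3, n4) -> np.ndarray:
        """Vectorized p-value lookup; NaN where N < n_min (no test)."""
        n1 = np.atleast_1d(np.asarray(n1, dtype=np.int64))
        n2 = np.atleast_1d(np.asarray(n2, dtype=np.int64))
        n3 = np.atleast_1d(np.asarray(n3, dtype=np.int64))
        n4 = np.atleast_1d(np.asarray(n4, dtype=np.int64))
        total = n1 + n2 + n3 + n4
        idx = stat_grid_index(n1, n2, n3, n4)
        p = np.ones(total.shape, dtype=float)
        rows = np.clip(total, self.n_min, self.n_max) - self.n_min
        lookup = idx >= 0
        p[lookup] = self.survival[rows[lookup], idx[lookup]]
        p = np.maximum(p, 1.0 / self.reps)
        p[total < self.n_min] = np.nan
        return p

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            survival=self.survival,
            n_min=self.n_min,
            n_max=self.n_max,
            reps=self.reps,
            seed=-1 if self.seed is None else self.seed,
            low_reps=self.low_reps,
            grid=GRID,
        )

    @classmethod
    def load(cls, path) -> "NullTable":
        with np.load(path) as z:
            seed = int(z["seed"])
            return cls(
                n_min=int(z["n_min"]),
                n_max=int(z["n_max"]),
                reps=int(z["reps"]),
                seed=None if seed < 0 else seed,
                survival=z["survival"],
                low_reps=bool(z["low_reps"]),
            )


def build_null_table(
    n_min: int = 5,
    n_max: int = 500,
    reps: int = 1_000_000,
    seed: Optional[int] = None,
) -> NullTable:
    """Simulate the multinomial null and tabulate survival per total count.

    For each N in [n_min, n_max], draws ``reps`` samples of
    (n1..n4) ~ Multinomial(N, [1/4]*4), computes log2(alpha_hat) and bins it
    on the grid; the survival function is the reverse cumulative bin mass.
    Reproducible bit-for-bit given ``seed``.
    """
    if not (1 <= n_min <= n_max):
        raise ValueError("require 1 <= n_min <= n_max")
    low_reps = reps < 100_000
    rng = np.random.default_rng(seed)
    rows = np.empty((n_max - n_min + 1, 501), dtype=float)
    p = [0.25] * 4
    for i, n in enumerate(range(n_min, n_max + 1)):
        counts = rng.multinomial(n, p, size=reps)
        idx = stat_grid_index(counts[:, 0], counts[:, 1], counts[:, 2], counts[:, 3])
        hist = np.bincount(idx[idx >= 0], minlength=501)
        rows[i] = hist[::-1].cumsum()[::-1] / reps
    return NullTable(
        n_min=n_min, n_max=n_max, reps=reps, seed=seed,
        survival=rows, low_reps=low_reps,
    )


def pvalue(q: QuadrantCounts, table: NullTable) -> Optional[float]:
    """P-value for one set of quadrant counts; ``None`` when N < n_min."""
    if q.total < table.n_min:
        return None
    p = table.pvalues(q.n1, q.n2, q.n3, q.n4)
    return float(p[0])
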