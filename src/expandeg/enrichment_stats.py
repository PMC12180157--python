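"""Exact one-sided hypergeometric over/under-representation tests and the
equivalent 2x2 one-sided Fisher test.

Tail probabilities are computed by exact summation of log-space PMF terms
(log-gamma binomials combined with logsumexp), with no normal approximation.
P-values are returned at full precision; callers that mirror published
reporting round to two significant figures for display. The engine never
filters by a significance threshold — 0.05 is presentation metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import false_discovery_control

__all__ = [
    "Contingency",
    "EnrichmentResult",
    "hypergeom_over",
    "hypergeom_under",
    "fisher_one_sided",
    "enrich",
    "enrich_batch",
    "round_sig",
]


@dataclass(frozen=True)
class Contingency:
    """Sampling-without-replacement counts: a sample of n from a population
    of N holding K marked items, with k marked items observed in the sample."""

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        for name in ("N", "K", "n", "k"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.K > self.N or self.n > self.N:
            raise ValueError(f"K and n must not exceed N: {self}")
        if self.k > min(self.n, self.K):
            raise ValueError(f"k exceeds min(n, K): {self}")
        if self.n - self.k > self.N - self.K:
            raise ValueError(f"n - k exceeds N - K (too many unmarked in sample): {self}")

    @property
    def fold(self) -> float:
        """Relative representation (k/n) / (K/N); NaN when undefined."""
        if self.n == 0 or self.K == 0:
            return float("nan")
        return (self.k / self.n) / (self.K / self.N)


def _log_binom(a: np.ndarray | int, b: np.ndarray | int) -> np.ndarray:
    return gammaln(np.asarray(a) + 1) - gammaln(np.asarray(b) + 1) - gammaln(np.asarray(a) - np.asarray(b) + 1)


def _tail(c: Contingency, upper: bool) -> float:
    lo = max(0, c.n + c.K - c.N)
    hi = min(c.n, c.K)
    if upper:
        if c.k <= lo:
            return 1.0
        ks = np.arange(c.k, hi + 1)
    else:
        if c.k >= hi:
            return 1.0
        ks = np.arange(lo, c.k + 1)
    logpmf = (
        _log_binom(c.K, ks)
        + _log_binom(c.N - c.K, c.n - ks)
        - _log_binom(c.N, c.n)
    )
    return float(min(1.0, np.exp(logsumexp(logpmf))))


def hypergeom_over(k: int, n: int, K: int, N: int) -> float:
    """Over-representation tail P(X >= k) for X ~ Hypergeom(N, K, n)."""
    return _tail(Contingency(N=int(N), K=int(K), n=int(n), k=int(k)), upper=True)


def hypergeom_under(k: int, n: int, K: int, N: int) -> float:
    """Under-representation tail P(X <= k)."""
    return _tail(Contingency(N=int(N), K=int(K), n=int(n), k=int(k)), upper=False)


def fisher_one_sided(a: int, b: int, c: int, d: int, direction: str = "over") -> float:
    """One-sided exact test on the 2x2 table [[a, b], [c, d]].

    Identical to the hypergeometric tail with N = a+b+c+d, K = a+b,
    n = a+c, k = a. The all-zero table returns p = 1 by convention.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("contingency cells must be non-negative")
    N = a + b + c + d
    if N == 0:
        return 1.0
    if direction == "over":
        return hypergeom_over(a, a + c, a + b, N)
    if direction == "under":
        return hypergeom_under(a, a + c, a + b, N)
    raise ValueError(f"direction must be 'over' or 'under', got {direction!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    contingency: Contingency
    direction: str
    p_value: float
    universe: str = ""
    label: str = ""

    @property
    def fold(self) -> float:
        return self.contingency.fold


def enrich(
    subset: Iterable,
    prop: Iterable,
    universe: Iterable,
    direction: str = "over",
    universe_name: str = "",
    label: str = "",
) -> EnrichmentResult:
    """Test whether `prop` is over/under-represented in `subset` relative to
    `universe`. The property is evaluated as membership of `prop` restricted
    to the universe; the subset must be contained in the universe."""
    uni = set(universe)
    sub = set(subset)
    if not sub <= uni:
        stray = sorted(sub - uni)[:3]
        raise ValueError(f"subset is not contained in the universe (e.g. {stray})")
    marked = set(prop) & uni
    c = Contingency(N=len(uni), K=len(marked), n=len(sub), k=len(sub & marked))
    if direction == "over":
        p = _tail(c, upper=True)
    elif direction == "under":
        p = _tail(c, upper=False)
    else:
        raise ValueError(f"direction must be 'over' or 'under', got {direction!r}")
    return EnrichmentResult(c, direction, p, universe_name, label)


def enrich_batch(
    manifest: pd.DataFrame,
    sets: Mapping[str, Iterable],
    bh_column: bool = False,
) -> pd.DataFrame:
    """Run a battery of enrichment tests from a manifest.

    manifest columns: test_id, universe, subset, property, direction; each
    of universe/subset/property names a key of `sets`. Raw p-values are
    reported per the source analyses; `bh_column=True` adds an opt-in
    Benjamini-Hochberg column across the battery.
    """
    rows = []
    for rec in manifest.itertuples(index=False):
        res = enrich(
            sets[rec.subset], sets[rec.property], sets[rec.universe],
            direction=rec.direction, universe_name=rec.universe, label=rec.test_id,
        )
        c = res.contingency
        rows.append(
            {
                "test_id": rec.test_id,
                "universe": rec.universe,
                "subset": rec.subset,
                "property": rec.property,
                "direction": rec.direction,
                "k": c.k,
                "n": c.n,
                "K": c.K,
                "N": c.N,
                "fold": c.fold,
                "p_value": res.p_value,
            }
        )
    out = pd.DataFrame(rows)
    if bh_column and len(out):
        out["p_bh"] = false_discovery_control(out["p_value"].to_numpy(), method="bh")
    return out


def round_sig(x: float, digits: int = 2) -> float:
    """Round to `digits` significant figures (published p-value style)."""
    if x == 0 or not np.isfinite(x):
        return x
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (digits - 1))
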