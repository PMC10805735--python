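"""Nonparametric and t-based group comparisons.

The tests implemented here are the ones used downstream on window means,
nuclear intensities and assay outputs:

* two-sided Mann-Whitney U (exact by enumeration for small tie-free
  samples, otherwise tie-corrected normal approximation with continuity
  correction);
* two-sided Steel-Dwass all-pairs comparison: pairwise rank statistics
  referred to the studentized range distribution with infinite degrees of
  freedom, which controls the family-wise error over all pairs without an
  omnibus pre-test;
* two-sided paired t and one-sample t.

The statistics and p-value logic are implemented here directly (the exact
Mann-Whitney null by dynamic programming over rank sums, the studentized
range survival function by numerical integration of the normal kernel);
``scipy`` supplies only ranking and the normal / t distribution functions.
Two-sided p-values follow the min(1, 2 * smaller tail) convention
throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as sps

from .errors import ConfigError, ZeroVarianceError

EXACT_CAP = 14  # exact Mann-Whitney enumeration up to n_x + n_y <= this


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    method_variant: str  # exact | normal_tie_corrected | studentized_range | t
    pair: tuple[str, str] | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


@lru_cache(maxsize=64)
def _exact_u_counts(m: int, n: int) -> tuple[int, ...]:
    """Number of rank assignments with each U value, for group sizes m, n.

    Classical recurrence c(u; m, n) = c(u - n; m - 1, n) + c(u; m, n - 1):
    the largest observation belongs either to the first group (contributing
    n to U) or to the second.  Total count is C(m + n, m).
    """
    table: list[list[np.ndarray | None]] = [[None] * (n + 1) for _ in range(m + 1)]

    def c(mi: int, ni: int) -> np.ndarray:
        if table[mi][ni] is not None:
            return table[mi][ni]
        if mi == 0 or ni == 0:
            arr = np.zeros(mi * ni + 1, dtype=object)
            arr[0] = 1
        else:
            arr = np.zeros(mi * ni + 1, dtype=object)
            a = c(mi - 1, ni)  # largest value in group 1: adds ni to U
            arr[ni : ni + a.size] += a
            b = c(mi, ni - 1)  # largest value in group 2: adds 0
            arr[: b.size] += b
        table[mi][ni] = arr
        return arr

    return tuple(int(v) for v in c(m, n))


def exact_mann_whitney_p(u: float, m: int, n: int) -> float:
    """Two-sided exact p for an observed U with tie-free data."""
    counts = _exact_u_counts(m, n)
    total = math.comb(m + n, m)
    u_small = min(u, m * n - u)
    tail = sum(counts[: int(math.floor(u_small)) + 1])
    return min(1.0, 2.0 * tail / total)


def _tie_term(pooled: np.ndarray) -> float:
    _, t = np.unique(pooled, return_counts=True)
    return float(np.sum(t**3 - t))


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    continuity: bool = True,
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``mode="auto"`` uses the exact enumeration null when
    n_x + n_y <= 14 and the data are tie-free, otherwise the normal
    approximation with tie-corrected variance and (optionally) a 0.5
    continuity correction.  Identical constant samples give the defined
    degenerate result p = 1 (flagged) rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    m, n = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # mid-ranks
    u_x = float(ranks[:m].sum() - m * (m + 1) / 2.0)
    has_ties = np.unique(pooled).size < pooled.size

    use_exact = mode == "exact" or (mode == "auto" and m + n <= EXACT_CAP and not has_ties)
    if use_exact:
        if has_ties:
            raise ValueError("exact mode requires tie-free data")
        p = exact_mann_whitney_p(u_x, m, n)
        return TestResult("mann_whitney_u", u_x, p, (m, n), "exact")

    mu = m * n / 2.0
    tie = _tie_term(pooled)
    var = m * n / 12.0 * ((m + n + 1) - tie / ((m + n) * (m + n - 1)))
    if var <= 0:
        return TestResult(
            "mann_whitney_u", u_x, 1.0, (m, n), "normal_tie_corrected", degenerate=True
        )
    dev = abs(u_x - mu)
    if continuity:
        dev = max(dev - 0.5, 0.0)
    z = dev / math.sqrt(var)
    p = min(1.0, 2.0 * float(sps.norm.sf(z)))
    return TestResult("mann_whitney_u", u_x, p, (m, n), "normal_tie_corrected")


# ---------------------------------------------------------------------------
# Studentized range (infinite degrees of freedom)
# ---------------------------------------------------------------------------


# fixed integration grid for the studentized-range integral: phi(z) is below
# 1e-32 beyond |z| = 12, and Simpson at step 0.005 resolves the smooth
# integrand far beyond the documented 1e-8 absolute tolerance
_SR_GRID = np.linspace(-12.0, 12.0, 4801)
_SR_PDF = None
_SR_CDF = None


def studentized_range_sf(q: float, k: int) -> float:
    """P(Q_{k, inf} >= q): survival function of the studentized range of k
    independent standard normals, by numerical integration over the normal
    kernel of the maximum (absolute accuracy well below 1e-8).

    CDF(q) = k * Int phi(z) * [Phi(z) - Phi(z - q)]^(k-1) dz; at k = 2 this
    reduces to P(|Z| >= q / sqrt(2)).
    """
    global _SR_PDF, _SR_CDF
    if k < 2:
        raise ValueError("k must be >= 2")
    if q <= 0:
        return 1.0
    if _SR_PDF is None:
        _SR_PDF = sps.norm.pdf(_SR_GRID)
        _SR_CDF = sps.norm.cdf(_SR_GRID)
    integrand = k * _SR_PDF * (_SR_CDF - sps.norm.cdf(_SR_GRID - q)) ** (k - 1)
    cdf = float(integrate.simpson(integrand, x=_SR_GRID))
    return float(min(max(1.0 - cdf, 0.0), 1.0))


def _pair_rank_statistic(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Standardized rank-sum statistic of one pair with tie correction.

    Returns (t, var); var = 0 signals a degenerate (constant) pooled pair.
    """
    m, n = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    big_n = m + n
    r_a = float(ranks[:m].sum())
    expect = m * (big_n + 1) / 2.0
    var = m * n / (big_n * (big_n - 1.0)) * (
        float(np.sum(ranks**2)) - big_n * (big_n + 1.0) ** 2 / 4.0
    )
    if var <= 0:
        return 0.0, 0.0
    return (r_a - expect) / math.sqrt(var), var


def steel_dwass(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    method: str = "asymptotic",
    n_resamples: int = 100_000,
    seed: int | None = None,
) -> list[TestResult]:
    """Two-sided Steel-Dwass all-pairs comparison among k >= 2 groups.

    For each pair, mid-ranks within the pooled pair give a tie-corrected
    standardized statistic t; the asymptotic p is
    P(Q_{k, inf} >= sqrt(2) * |t|).  ``method="permutation"`` instead refers
    each |t| to the permutation distribution of the *maximum* standardized
    pair statistic (same family-wise null, finite-sample), using
    ``n_resamples`` label shuffles.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be nonempty")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]

    t_obs = {}
    degenerate = {}
    for i, j in pairs:
        t, var = _pair_rank_statistic(arrays[i], arrays[j])
        t_obs[(i, j)] = t
        degenerate[(i, j)] = var == 0.0

    if method == "asymptotic":
        results = []
        for i, j in pairs:
            if degenerate[(i, j)]:
                results.append(
                    TestResult(
                        "steel_dwass", 0.0, 1.0, (arrays[i].size, arrays[j].size),
                        "studentized_range", pair=(labels[i], labels[j]),
                        degenerate=True,
                    )
                )
                continue
            t = t_obs[(i, j)]
            p = studentized_range_sf(math.sqrt(2.0) * abs(t), k)
            results.append(
                TestResult(
                    "steel_dwass", t, p, (arrays[i].size, arrays[j].size),
                    "studentized_range", pair=(labels[i], labels[j]),
                )
            )
        return results

    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    pooled = np.concatenate(arrays)
    sizes = [a.size for a in arrays]
    starts = np.cumsum([0] + sizes)
    max_t = np.empty(n_resamples)
    # vectorize in chunks: permute the pooled sample, recompute all pair stats
    chunk = 2000
    done = 0
    while done < n_resamples:
        c = min(chunk, n_resamples - done)
        perm = np.argsort(rng.random((c, pooled.size)), axis=1)
        shuffled = pooled[perm]
        mt = np.zeros(c)
        for i, j in pairs:
            a = shuffled[:, starts[i] : starts[i + 1]]
            b = shuffled[:, starts[j] : starts[j + 1]]
            both = np.concatenate([a, b], axis=1)
            ranks = sps.rankdata(both, axis=1)
            m, n = sizes[i], sizes[j]
            big_n = m + n
            r_a = ranks[:, :m].sum(axis=1)
            expect = m * (big_n + 1) / 2.0
            var = m * n / (big_n * (big_n - 1.0)) * (
                (ranks**2).sum(axis=1) - big_n * (big_n + 1.0) ** 2 / 4.0
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                t = np.where(var > 0, (r_a - expect) / np.sqrt(var), 0.0)
            mt = np.maximum(mt, np.abs(t))
        max_t[done : done + c] = mt
        done += c

    results = []
    for i, j in pairs:
        if degenerate[(i, j)]:
            p, t, deg = 1.0, 0.0, True
        else:
            t = t_obs[(i, j)]
            p = float(np.mean(max_t >= abs(t) - 1e-12))
            deg = False
        results.append(
            TestResult(
                "steel_dwass", t, p, (arrays[i].size, arrays[j].size),
                "permutation", pair=(labels[i], labels[j]), degenerate=deg,
            )
        )
    return results


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------


def paired_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided paired t test on the differences x - y (df = n - 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    sd = float(d.std(ddof=1))
    if sd == 0:
        raise ZeroVarianceError(
            "paired differences have zero variance; the t statistic is undefined"
        )
    n = d.size
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = min(1.0, 2.0 * float(sps.t.sf(abs(t), n - 1)))
    return TestResult("paired_t", t, p, (n, n), "t")


def one_sample_t(x: Sequence[float], mu0: float) -> TestResult:
    """Two-sided one-sample t test of H0: mean = mu0 (df = n - 1)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two observations")
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ZeroVarianceError(
            "sample has zero variance; the t statistic is undefined"
        )
    n = x.size
    t = float((x.mean() - mu0) / (sd / math.sqrt(n)))
    p = min(1.0, 2.0 * float(sps.t.sf(abs(t), n - 1)))
    return TestResult("one_sample_t", t, p, (n,), "t")


# ---------------------------------------------------------------------------
# Condition comparison report
# ---------------------------------------------------------------------------


def compare_conditions(
    windows: dict[str, pd.DataFrame],
    params: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Compare inside- and outside-window means across conditions.

    ``windows`` maps condition label -> window-means table (columns
    ``inside_mean``, ``outside_mean``, optionally ``cell_id``).  Two
    conditions are compared with the Mann-Whitney U test, three or more
    with the Steel-Dwass all-pairs test, separately for each window - the
    standard design for this kind of core-shell redistribution experiment.

    ``params``, when given, maps condition -> the profiling parameters the
    window means were computed with; any mismatch raises
    :class:`ConfigError` to prevent apples-to-oranges comparisons.
    """
    if len(windows) < 2:
        raise ValueError("need at least two conditions")
    if params is not None:
        ref = None
        for cond, p in params.items():
            q = {k: v for k, v in p.items()}
            if ref is None:
                ref = q
            elif q != ref:
                raise ConfigError(
                    f"profiling parameters for condition {cond!r} differ from the "
                    "others; window means are not comparable"
                )
    labels = list(windows)
    rows = []
    for window in ("inside", "outside"):
        col = f"{window}_mean"
        groups = [windows[c][col].dropna().to_numpy() for c in labels]
        meta = {}
        for c in labels:
            tbl = windows[c]
            meta[c] = {
                "n_nucleoli": int(tbl[col].notna().sum()),
                "n_cells": int(
                    tbl.loc[tbl[col].notna(), ["field_id", "cell_id"]]
                    .drop_duplicates()
                    .shape[0]
                )
                if {"field_id", "cell_id"} <= set(tbl.columns)
                else None,
            }
        if len(labels) == 2:
            res = [
                mann_whitney_u(groups[0], groups[1])
            ]
            res[0].pair = (labels[0], labels[1])
        else:
            res = steel_dwass(groups, labels=labels)
        for r in res:
            a, b = r.pair
            rows.append(
                {
                    "window": window,
                    "test": r.test_name,
                    "group_a": a,
                    "group_b": b,
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "n_a": meta[a]["n_nucleoli"],
                    "n_b": meta[b]["n_nucleoli"],
                    "cells_a": meta[a]["n_cells"],
                    "cells_b": meta[b]["n_cells"],
                    "method_variant": r.method_variant,
                    "degenerate": r.degenerate,
                }
            )
    return pd.DataFrame(rows)
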