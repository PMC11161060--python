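"""Subset-vs-bulk resampling inference.

The workhorse is a bootstrap median test: is the median of a gene subset
(e.g. wing-development genes) unusually high or low relative to random
gene selections of the same size drawn from the full population?  Each of
``n_iter`` cycles draws ``|subset|`` genes *without replacement* from the
total gene set (subset members included — the null is "a random selection
from all genes") and records the null median; the reported tail
probabilities are add-one smoothed, so p = 0 is impossible and ties count
toward both tails.

Also here: an exact enumeration version of the same test (used as ground
truth on small populations), hypergeometric gene-set overlap enrichment,
empirical-CDF shift summaries, and per-subset median fold-changes with a
bootstrap standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Union

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BootstrapResult",
    "EnrichmentResult",
    "ShiftSummary",
    "bootstrap_median_test",
    "exact_median_test",
    "hypergeometric_enrichment",
    "distribution_shift",
    "subset_median_foldchange",
    "bh_adjust",
]


@dataclass
class BootstrapResult:
    subset_size: int
    observed_median: float
    n_iter: int
    count_ge: int  # null medians >= observed (ties on both sides)
    count_le: int
    p_upper: float  # (count_ge + 1) / (n_iter + 1)
    p_lower: float
    direction: str  # higher / lower / none
    seed: Optional[int]


@dataclass
class EnrichmentResult:
    universe_size: int
    set_a_size: int
    set_b_size: int
    overlap: int
    expected_overlap: float
    fold_enrichment: float
    p_value: float  # upper tail, P(X >= overlap)


def _null_medians(
    values: np.ndarray, k: int, n_iter: int, rng: np.random.Generator
) -> np.ndarray:
    """Medians of ``n_iter`` draws of ``k`` values without replacement.

    Vectorized in chunks: random sort keys + argpartition give uniform
    without-replacement samples; chunk size keeps memory near ~60 MB.
    """
    n = values.size
    out = np.empty(n_iter)
    chunk = max(1, min(n_iter, int(8_000_000 / max(n, 1))))
    done = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k] if k < n else np.tile(
            np.arange(n), (m, 1)
        )
        out[done : done + m] = np.median(values[idx], axis=1)
        done += m
    return out


def _resolve_subset(
    values: Union[pd.Series, Sequence[float]],
    subset: Iterable,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (population array, subset-value array) from Series+IDs or
    array+positions."""
    if isinstance(values, pd.Series):
        subset_ids = list(subset)
        missing = [g for g in subset_ids if g not in values.index]
        if missing:
            raise KeyError(f"subset IDs missing from values: {sorted(missing)[:10]}")
        return values.to_numpy(dtype=float), values.loc[subset_ids].to_numpy(dtype=float)
    pop = np.asarray(values, dtype=float)
    pos = np.asarray(list(subset))
    if pos.dtype.kind not in "iub":
        raise TypeError("with array-valued populations, subset must be positions")
    if pos.size and (pos.min() < 0 or pos.max() >= pop.size):
        raise IndexError("subset positions out of range")
    return pop, pop[pos]


def _median_resample_test(
    population: np.ndarray,
    subset_values: np.ndarray,
    n_iter: int,
    seed: Optional[int],
) -> BootstrapResult:
    k = subset_values.size
    if k == 0:
        raise ValueError("subset is empty")
    if k >= population.size:
        raise ValueError("subset must be strictly smaller than the population")
    if n_iter < 1000:
        warnings.warn(f"n_iter={n_iter} < 1000: tail probabilities are unstable")
    rng = np.random.default_rng(seed)
    observed = float(np.median(subset_values))
    nulls = _null_medians(population, k, n_iter, rng)
    count_ge = int((nulls >= observed).sum())
    count_le = int((nulls <= observed).sum())
    p_upper = (count_ge + 1) / (n_iter + 1)
    p_lower = (count_le + 1) / (n_iter + 1)
    if p_upper < p_lower:
        direction = "higher"
    elif p_lower < p_upper:
        direction = "lower"
    else:
        direction = "none"
    return BootstrapResult(
        subset_size=k,
        observed_median=observed,
        n_iter=n_iter,
        count_ge=count_ge,
        count_le=count_le,
        p_upper=p_upper,
        p_lower=p_lower,
        direction=direction,
        seed=seed,
    )


def bootstrap_median_test(
    values: Union[pd.Series, Sequence[float]],
    subset: Iterable,
    n_iter: int = 1_000_000,
    seed: Optional[int] = None,
) -> BootstrapResult:
    """Resampling test of a subset median against random same-size selections.

    Parameters
    ----------
    values:
        Per-gene metric over the whole population.  A ``pd.Series`` indexed
        by gene ID (then ``subset`` holds IDs) or a plain array (then
        ``subset`` holds integer positions).
    subset:
        The gene subset of interest; must be non-empty and strictly smaller
        than the population.  Subset members stay in the sampling pool.
    n_iter:
        Number of random selections (the study default is 1,000,000; tests
        and quick looks can use far fewer).
    seed:
        Seed for the random generator; identical seed + inputs reproduce
        the result exactly.
    """
    population, subset_values = _resolve_subset(values, subset)
    return _median_resample_test(population, subset_values, n_iter, seed)


def exact_median_test(
    values: Union[pd.Series, Sequence[float]],
    subset: Iterable,
    max_combinations: int = 10**6,
) -> Dict[str, float]:
    """Exact version of the bootstrap median test by full enumeration.

    Enumerates every C(N, k) selection and returns the exact unsmoothed
    tail probabilities ``{"p_upper", "p_lower", "observed_median",
    "n_combinations"}``.  Refuses when C(N, k) exceeds ``max_combinations``.
    """
    population, subset_values = _resolve_subset(values, subset)
    k = subset_values.size
    n = population.size
    if k == 0 or k >= n:
        raise ValueError("subset must be non-empty and smaller than the population")
    total = comb(n, k)
    if total > max_combinations:
        raise ValueError(
            f"C({n},{k}) = {total} combinations exceed the enumeration limit "
            f"({max_combinations})"
        )
    observed = float(np.median(subset_values))
    srt = np.sort(population)
    mid_hi = k // 2
    mid_lo = (k - 1) // 2
    n_ge = n_le = 0
    for combo in combinations(srt, k):
        med = (combo[mid_lo] + combo[mid_hi]) / 2.0
        if med >= observed:
            n_ge += 1
        if med <= observed:
            n_le += 1
    return {
        "p_upper": n_ge / total,
        "p_lower": n_le / total,
        "observed_median": observed,
        "n_combinations": total,
    }


def hypergeometric_enrichment(
    set_a: Iterable, set_b: Iterable, universe: Iterable
) -> EnrichmentResult:
    """Upper-tail hypergeometric test of the overlap between two gene sets.

    With N = |universe|, K = |A|, n = |B| and X the overlap of a random
    n-subset with A, p = P(X >= observed overlap).  Equivalent to a
    one-sided Fisher exact test, and symmetric in A and B.
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    stray = (a | b) - u
    if stray:
        raise ValueError(f"sets contain IDs outside the universe: {sorted(stray)[:10]}")
    N, K, n = len(u), len(a), len(b)
    overlap = len(a & b)
    expected = K * n / N if N else 0.0
    p = float(hypergeom.sf(overlap - 1, N, K, n)) if N else 1.0
    fold = overlap / expected if expected > 0 else np.nan
    return EnrichmentResult(
        universe_size=N,
        set_a_size=K,
        set_b_size=n,
        overlap=overlap,
        expected_overlap=expected,
        fold_enrichment=fold,
        p_value=min(p, 1.0),
    )


@dataclass
class ShiftSummary:
    """Empirical-CDF comparison of a gene subset against the bulk."""

    grid: np.ndarray
    cdf_subset: np.ndarray
    cdf_bulk: np.ndarray
    median_subset: float
    median_bulk: float
    median_diff: float
    ks_distance: float
    bootstrap: Optional[BootstrapResult]


def distribution_shift(
    subset_values: Sequence[float],
    bulk_values: Sequence[float],
    n_iter: int = 100_000,
    seed: Optional[int] = None,
) -> ShiftSummary:
    """Summarize how a subset's value distribution shifts against the bulk.

    Returns right-continuous empirical CDFs on the shared value grid, the
    median difference (subset - bulk), the Kolmogorov-Smirnov distance, and
    a bootstrap median test of the subset against random same-size draws
    from the bulk (skipped with ``n_iter=0`` or when the subset is not
    smaller than the bulk).
    """
    sub = np.sort(np.asarray(subset_values, dtype=float))
    bulk = np.sort(np.asarray(bulk_values, dtype=float))
    if sub.size == 0:
        raise ValueError("subset is empty")
    if bulk.size == 0:
        raise ValueError("bulk is empty")
    grid = np.unique(np.concatenate([sub, bulk]))
    cdf_sub = np.searchsorted(sub, grid, side="right") / sub.size
    cdf_bulk = np.searchsorted(bulk, grid, side="right") / bulk.size
    med_s, med_b = float(np.median(sub)), float(np.median(bulk))
    boot = None
    if n_iter and sub.size < bulk.size:
        boot = _median_resample_test(bulk, sub, n_iter, seed)
    return ShiftSummary(
        grid=grid,
        cdf_subset=cdf_sub,
        cdf_bulk=cdf_bulk,
        median_subset=med_s,
        median_bulk=med_b,
        median_diff=med_s - med_b,
        ks_distance=float(np.abs(cdf_sub - cdf_bulk).max()),
        bootstrap=boot,
    )


def subset_median_foldchange(
    fc_table: pd.Series,
    subsets: Mapping[str, Iterable],
    n_boot_se: int = 1000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Median fold-change per named subset, with a bootstrap standard error.

    The SE is the standard deviation of the subset median over
    ``n_boot_se`` within-subset resamples with replacement.  Subsets
    smaller than 3 get their median but the SE is flagged unreliable.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for name in sorted(subsets):
        ids = list(subsets[name])
        missing = [g for g in ids if g not in fc_table.index]
        if missing:
            raise KeyError(
                f"subset {name!r}: members missing from fold-change table: "
                f"{sorted(missing)[:10]}"
            )
        vals = fc_table.loc[ids].to_numpy(dtype=float)
        if vals.size == 0:
            warnings.warn(f"subset {name!r} is empty; skipped")
            continue
        med = float(np.median(vals))
        resamples = vals[rng.integers(0, vals.size, size=(n_boot_se, vals.size))]
        se = float(np.median(resamples, axis=1).std(ddof=0))
        unreliable = vals.size < 3
        if unreliable:
            warnings.warn(f"subset {name!r} has < 3 members; SE unreliable")
        rows.append((name, vals.size, med, se, unreliable))
    return pd.DataFrame(
        rows, columns=["subset", "n", "median_fc", "se", "se_unreliable"]
    ).set_index("subset")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (FDR within one report)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
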