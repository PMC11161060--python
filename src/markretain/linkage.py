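"""Cross-stage linkage: how embryonic chromatin state relates to
condition differences and later-stage expression.

Covers the direction split of per-gene K4/K27 ratios between conditions,
expression of extreme-decile chromatin gene sets, the retention-expression
rank correlation, and enrichment of annotated target sets among
differentially expressed genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .stats import (
    BootstrapResult,
    EnrichmentResult,
    bh_adjust,
    bootstrap_median_test,
    hypergeometric_enrichment,
)

__all__ = [
    "direction_fractions",
    "decile_expression_association",
    "retention_expression_correlation",
    "de_set_enrichment",
    "LinkageReport",
]

log = logging.getLogger(__name__)


def direction_fractions(
    table: pd.DataFrame, tol: float = 0.0
) -> Tuple[float, float, float]:
    """Fractions of detectable genes whose K4/K27 ratio moved down / up.

    A gene counts as *lower* when ``ratio_treated < ratio_ctrl * (1 - tol)``
    and *higher* when ``ratio_treated > ratio_ctrl * (1 + tol)``; the rest
    are *unchanged*.  ``tol`` is a relative tolerance band (default 0 =
    strict inequality).  Returns ``(frac_lower, frac_higher,
    frac_unchanged)``.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    det = table[table["detectable"]] if "detectable" in table.columns else table
    det = det.dropna(subset=["ratio_ctrl", "ratio_treated"])
    if det.empty:
        raise ValueError("no detectable genes with defined ratios")
    rc = det["ratio_ctrl"].to_numpy(dtype=float)
    rt = det["ratio_treated"].to_numpy(dtype=float)
    lower = rt < rc * (1.0 - tol)
    higher = rt > rc * (1.0 + tol)
    n = det.shape[0]
    frac_lower = lower.sum() / n
    frac_higher = higher.sum() / n
    return float(frac_lower), float(frac_higher), float(1.0 - frac_lower - frac_higher)


def decile_expression_association(
    selections: Mapping[str, Iterable[str]],
    expression: pd.Series,
    n_iter: int = 100_000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Expression of extreme chromatin-decile gene sets against the bulk.

    For each named selection (e.g. top/bottom 10 % by embryonic H3K4me3)
    reports mean expression +- SE over the resolvable genes and the
    bootstrap median test of the set against the full expression table.
    Gene IDs missing from the expression table are dropped with a logged
    count; a selection with no resolvable genes is an error.
    """
    rows = []
    for name in sorted(selections):
        ids = list(selections[name])
        present = [g for g in ids if g in expression.index]
        dropped = len(ids) - len(present)
        if dropped:
            log.warning("selection %r: %d gene IDs not in expression table", name, dropped)
        if not present:
            raise ValueError(f"selection {name!r} has no genes in the expression table")
        vals = expression.loc[present].to_numpy(dtype=float)
        boot = bootstrap_median_test(expression, present, n_iter=n_iter, seed=seed)
        rows.append(
            (
                name,
                len(present),
                dropped,
                float(vals.mean()),
                float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan,
                float(np.median(vals)),
                boot.p_upper,
                boot.p_lower,
                boot.direction,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "selection", "n", "n_dropped", "mean", "se", "median",
            "p_upper", "p_lower", "direction",
        ],
    ).set_index("selection")


def retention_expression_correlation(
    retention: pd.Series,
    expression: pd.Series,
    n_boot: int = 1000,
    seed: Optional[int] = None,
    ci_level: float = 0.95,
) -> Dict[str, float]:
    """Spearman correlation between H3K4me3 retention and expression.

    Pairs genes by ID (missing IDs dropped with a logged count; at least
    10 pairs required), computes the Spearman rank correlation, and
    attaches a percentile bootstrap confidence interval over gene
    resamples.  Constant inputs have no defined rank correlation and
    raise.
    """
    shared = retention.index.intersection(expression.index)
    dropped = (len(retention) - len(shared)) + (len(expression) - len(shared))
    if dropped:
        log.warning("retention/expression: %d unpaired gene IDs dropped", dropped)
    if len(shared) < 10:
        raise ValueError(f"need >= 10 paired genes, got {len(shared)}")
    x = retention.loc[shared].to_numpy(dtype=float)
    y = expression.loc[shared].to_numpy(dtype=float)
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("rank correlation undefined for constant input")
    rho, p = spearmanr(x, y)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n = x.size
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        if np.unique(x[idx]).size < 2 or np.unique(y[idx]).size < 2:
            boots[b] = np.nan
            continue
        boots[b] = spearmanr(x[idx], y[idx])[0]
    alpha = 1.0 - ci_level
    lo, hi = np.nanquantile(boots, [alpha / 2, 1 - alpha / 2])
    return {
        "rho": float(rho),
        "p_value": float(p),
        "n": int(n),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "ci_level": ci_level,
    }


def de_set_enrichment(
    up: Iterable[str],
    down: Iterable[str],
    target_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Enrichment of target gene sets among up-/down-regulated genes.

    One-sided hypergeometric p per (direction x target set), BH-adjusted
    within the report.
    """
    uni = set(universe)
    rows = []
    for direction, de_set in (("up", set(up)), ("down", set(down))):
        for name in sorted(target_sets):
            res = hypergeometric_enrichment(target_sets[name], de_set, uni)
            rows.append(
                (
                    direction, name, res.universe_size, res.set_a_size,
                    res.set_b_size, res.overlap, res.expected_overlap,
                    res.fold_enrichment, res.p_value,
                )
            )
    report = pd.DataFrame(
        rows,
        columns=[
            "direction", "target_set", "universe", "n_target", "n_de",
            "overlap", "expected", "fold", "p_value",
        ],
    )
    report["bh_fdr"] = bh_adjust(report["p_value"].to_numpy())
    return report


@dataclass
class LinkageReport:
    """Bundle of the cross-stage linkage outputs for one run."""

    frac_lower: float
    frac_higher: float
    frac_unchanged: float
    tolerance: float
    decile_summaries: pd.DataFrame
    retention_expression: Dict[str, float]
    enrichment: pd.DataFrame
    extras: Dict[str, float] = field(default_factory=dict)

    def to_json_dict(self) -> Dict:
        return {
            "frac_lower": self.frac_lower,
            "frac_higher": self.frac_higher,
            "frac_unchanged": self.frac_unchanged,
            "tolerance": self.tolerance,
            "retention_expression": self.retention_expression,
            "decile_summaries": self.decile_summaries.reset_index().to_dict("records"),
            "enrichment": self.enrichment.to_dict("records"),
            **self.extras,
        }
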