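"""Gene-level aggregation and per-gene chromatin statistics.

Binned signal is aggregated over each gene body (bins are assigned to a
gene when their midpoint falls inside the gene interval, which avoids
double-counting between adjacent genes).  From the four aggregated levels
(H3K4me3/H3K27me3 x control/treated) the module derives the per-gene
K4/K27 ratio, the H3K4me3 *retention* score (treated / control level — a
retention of 1 means the mark fully resisted the global suppression), a
+-k-SD classification of per-bin differences, extreme-decile gene
selection, a differential-expression filter and the qPCR 2^-ddCt
fold-change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .signal import BinnedTrack

__all__ = [
    "aggregate_gene_signal",
    "mark_ratio",
    "retention_score",
    "build_gene_table",
    "RegionDiffResult",
    "classify_region_changes",
    "select_extreme",
    "filter_differential",
    "ddct_fold_change",
]


def aggregate_gene_signal(track: BinnedTrack, genes: pd.DataFrame) -> pd.Series:
    """Sum bin values over each gene body.

    A bin contributes to a gene when its midpoint lies in ``[start, end)``;
    strand is ignored.  Genes on chromosomes absent from the track get level
    0 with a warning.  Returns a Series indexed by ``gene_id`` in the input
    gene order.
    """
    genes = genes.reset_index(drop=True)
    levels = np.zeros(len(genes))
    unknown: List[str] = []
    for chrom, sub in genes.groupby("chrom", sort=False):
        if chrom not in track.values:
            unknown.append(str(chrom))
            continue
        mids = track.midpoints(chrom)
        cs = np.concatenate(([0.0], np.cumsum(track.values[chrom])))
        lo = np.searchsorted(mids, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(mids, sub["end"].to_numpy(), side="left")
        levels[sub.index.to_numpy()] = cs[hi] - cs[lo]
    if unknown:
        warnings.warn(
            f"gene chromosomes missing from track (level set to 0): {sorted(set(unknown))}"
        )
    return pd.Series(levels, index=pd.Index(genes["gene_id"], name="gene_id"))


def mark_ratio(k4, k27, pseudocount: float = 1.0):
    """Active/repressive mark ratio, ``k4 / k27``.

    A pseudocount replaces the denominator only when ``k27`` is exactly 0;
    ``k4 == 0`` gives ratio 0 regardless.  Accepts scalars or aligned arrays.
    """
    k4a = np.asarray(k4, dtype=float)
    k27a = np.asarray(k27, dtype=float)
    if (k4a < 0).any() or (k27a < 0).any():
        raise ValueError("mark levels must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    denom = np.where(k27a == 0, pseudocount, k27a)
    out = k4a / denom
    if np.isscalar(k4) and np.isscalar(k27):
        return float(out)
    return out


def retention_score(k4_treated, k4_ctrl):
    """H3K4me3 retention: treated level divided by control level.

    Intended for detectable genes only (control level > 0); a zero control
    level raises rather than silently producing infinity.
    """
    t = np.asarray(k4_treated, dtype=float)
    c = np.asarray(k4_ctrl, dtype=float)
    if (t < 0).any() or (c < 0).any():
        raise ValueError("mark levels must be non-negative")
    if (c == 0).any():
        raise ValueError(
            "retention undefined for genes with zero control level; "
            "filter to detectable genes first"
        )
    out = t / c
    if np.isscalar(k4_treated) and np.isscalar(k4_ctrl):
        return float(out)
    return out


def build_gene_table(
    k4_ctrl: pd.Series,
    k4_treated: pd.Series,
    k27_ctrl: pd.Series,
    k27_treated: pd.Series,
    detect_floor: float = 0.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Assemble the per-gene signal table from four aggregated level series.

    A gene is *detectable* when its control H3K4me3 level exceeds
    ``detect_floor``; ratio and retention statistics are NaN for
    non-detectable genes and must be excluded from downstream summaries
    (the ``detectable`` column flags them).
    """
    idx = k4_ctrl.index
    for name, s in (
        ("k4_treated", k4_treated),
        ("k27_ctrl", k27_ctrl),
        ("k27_treated", k27_treated),
    ):
        if not s.index.equals(idx):
            raise ValueError(f"{name} index does not match k4_ctrl index")
    table = pd.DataFrame(
        {
            "k4_ctrl": k4_ctrl.astype(float),
            "k4_treated": k4_treated.astype(float),
            "k27_ctrl": k27_ctrl.astype(float),
            "k27_treated": k27_treated.astype(float),
        }
    )
    table["detectable"] = table["k4_ctrl"] > detect_floor
    table["ratio_ctrl"] = mark_ratio(table["k4_ctrl"], table["k27_ctrl"], pseudocount)
    table["ratio_treated"] = mark_ratio(table["k4_treated"], table["k27_treated"], pseudocount)
    det = table["detectable"]
    table["retention"] = np.nan
    table.loc[det, "retention"] = (
        table.loc[det, "k4_treated"] / table.loc[det, "k4_ctrl"]
    )
    table.loc[~det, ["ratio_ctrl", "ratio_treated"]] = np.nan
    return table


@dataclass
class RegionDiffResult:
    """Per-bin treated-minus-control differences classified against
    mean +- k*SD."""

    table: pd.DataFrame  # chrom, start, value_ctrl, value_treated, diff, cls
    mean: float
    sd: float
    k_sd: float
    n_above: int
    n_below: int
    n_within: int


def classify_region_changes(
    ctrl: BinnedTrack, treated: BinnedTrack, k_sd: float = 2.0
) -> RegionDiffResult:
    """Classify every bin by its treated-control difference.

    ``diff = treated - ctrl`` per bin; with mean mu and SD sigma over all
    bins (all chromosomes), a bin is ``above`` when diff > mu + k*sigma,
    ``below`` when diff < mu - k*sigma, else ``within``.  sigma = 0 (e.g.
    identical tracks) classifies everything as within, with a warning.
    """
    if not ctrl.same_binning(treated):
        raise ValueError("control and treated tracks must share binning")
    recs = []
    for chrom in ctrl.chroms:
        off = ctrl.offsets[chrom]
        starts = off + np.arange(ctrl.values[chrom].size) * ctrl.bin_width
        recs.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "value_ctrl": ctrl.values[chrom],
                    "value_treated": treated.values[chrom],
                }
            )
        )
    table = pd.concat(recs, ignore_index=True) if recs else pd.DataFrame(
        columns=["chrom", "start", "value_ctrl", "value_treated"]
    )
    diff = table["value_treated"].to_numpy() - table["value_ctrl"].to_numpy()
    table["diff"] = diff
    mu = float(diff.mean()) if diff.size else 0.0
    sigma = float(diff.std(ddof=0)) if diff.size else 0.0
    cls = np.full(diff.size, "within", dtype=object)
    if sigma == 0:
        if diff.size:
            warnings.warn("zero variance of differences; all bins classified 'within'")
    else:
        cls[diff > mu + k_sd * sigma] = "above"
        cls[diff < mu - k_sd * sigma] = "below"
    table["cls"] = cls
    return RegionDiffResult(
        table=table,
        mean=mu,
        sd=sigma,
        k_sd=float(k_sd),
        n_above=int((cls == "above").sum()),
        n_below=int((cls == "below").sum()),
        n_within=int((cls == "within").sum()),
    )


def select_extreme(
    table: pd.DataFrame,
    metric: str,
    fraction: float = 0.10,
    side: str = "top",
) -> List[str]:
    """Select the top or bottom ``fraction`` of detectable genes by a metric.

    The set size is ``round(fraction * n_detectable)`` (half-up).  Boundary
    ties are broken deterministically by ascending gene ID, with a warning
    when the tie actually bites.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError(f"fraction must lie in (0, 0.5], got {fraction}")
    if side not in {"top", "bottom"}:
        raise ValueError(f"side must be 'top' or 'bottom', got {side!r}")
    if metric not in table.columns:
        raise ValueError(f"metric column {metric!r} not in table")
    det = table[table.get("detectable", True) == True]  # noqa: E712
    det = det[det[metric].notna()]
    n = len(det)
    k = int(np.floor(fraction * n + 0.5))
    if k == 0:
        return []
    # stable sort after an index sort => ties resolved by ascending gene ID
    ordered = det.sort_index().sort_values(
        metric, ascending=(side == "bottom"), kind="mergesort"
    )
    chosen = ordered.iloc[:k]
    boundary = chosen[metric].iloc[-1]
    n_tied = int((det[metric] == boundary).sum())
    n_tied_chosen = int((chosen[metric] == boundary).sum())
    if n_tied > n_tied_chosen:
        warnings.warn(
            f"boundary tie at {metric}={boundary!r}: {n_tied} genes tie, "
            f"{n_tied_chosen} kept by ascending gene ID"
        )
    return list(chosen.index)


def filter_differential(
    stats_table: pd.DataFrame,
    fc_min: float = 1.5,
    p_max: float = 0.05,
) -> Tuple[Set[str], Set[str]]:
    """Split genes into up/down-regulated sets by fold-change and p-value.

    ``up``: fold_change > fc_min and p < p_max; ``down``: fold_change <
    1/fc_min and p < p_max (fold-change is a treated/control ratio).
    """
    for col in ("fold_change", "p_value"):
        if col not in stats_table.columns:
            raise ValueError(f"stats table missing column {col!r}")
    if fc_min <= 1:
        raise ValueError("fc_min must exceed 1")
    fc = stats_table["fold_change"]
    p = stats_table["p_value"]
    up = set(stats_table.index[(fc > fc_min) & (p < p_max)])
    down = set(stats_table.index[(fc < 1.0 / fc_min) & (p < p_max)])
    return up, down


def ddct_fold_change(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """qPCR relative expression by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference housekeeping gene) within each
    condition; ddCt = dCt(treated) - dCt(control); fold = 2^-ddCt.
    """
    vals = [ct_target_treated, ct_ref_treated, ct_target_ctrl, ct_ref_ctrl]
    if not all(np.isfinite(vals)):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
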