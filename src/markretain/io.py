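"""Plain-text genomics I/O: bedGraph tracks, BED6 gene models, gene-set
lists and TSV tables.

All coordinates are 0-based half-open, matching the BED/bedGraph
conventions.  Readers validate ordering and overlap and report violations
with line numbers; writers emit deterministic byte-stable text so that
re-runs with the same seed diff clean.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Union

import numpy as np
import pandas as pd

from .signal import BinnedTrack

PathLike = Union[str, Path]

BED_COLUMNS = ["chrom", "start", "end", "gene_id", "score", "strand"]


class FormatError(ValueError):
    """A malformed input file; the message carries file and line number."""


def _fmt(value: float) -> str:
    """Compact float formatting (integers render without a decimal point)."""
    return format(value, "g")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(track: BinnedTrack, path: PathLike) -> None:
    """Write a 4-column bedGraph (no track line), one line per bin."""
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_bins():
            fh.write(f"{chrom}\t{start}\t{end}\t{_fmt(value)}\n")


def read_bedgraph(path: PathLike, bin_width: int | None = None) -> BinnedTrack:
    """Read a bedGraph into a :class:`BinnedTrack`.

    Requires fixed-width, sorted, non-overlapping intervals per chromosome;
    gaps (omitted zero bins) are tolerated when they are a whole number of
    bins and are filled with 0.  The bin width is inferred from the first
    record unless given.
    """
    path = Path(path)
    per_chrom: Dict[str, List[tuple[int, float]]] = {}
    offsets: Dict[str, int] = {}
    last_end: Dict[str, int] = {}
    width = bin_width
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, s, e, v = parts[0], parts[1], parts[2], parts[3]
            try:
                start, end, value = int(s), int(e), float(v)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparsable record: {exc}") from None
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative signal value")
            if width is None:
                width = end - start
            if end - start != width:
                raise FormatError(
                    f"{path}:{lineno}: bin width {end - start} != expected {width}"
                )
            if chrom in last_end:
                if start < last_end[chrom]:
                    raise FormatError(
                        f"{path}:{lineno}: overlapping or unsorted interval on {chrom}"
                    )
                gap = start - last_end[chrom]
                if gap % width != 0:
                    raise FormatError(
                        f"{path}:{lineno}: gap of {gap} bp is not a whole number of bins"
                    )
            else:
                offsets[chrom] = start
                per_chrom[chrom] = []
            per_chrom[chrom].append((start, value))
            last_end[chrom] = end
    if width is None:
        raise FormatError(f"{path}: no data lines")
    values: Dict[str, np.ndarray] = {}
    for chrom, recs in per_chrom.items():
        n = (last_end[chrom] - offsets[chrom]) // width
        arr = np.zeros(n)
        for start, value in recs:
            arr[(start - offsets[chrom]) // width] = value
        values[chrom] = arr
    return BinnedTrack(width, values, offsets)


# ---------------------------------------------------------------------------
# BED6 gene models
# ---------------------------------------------------------------------------

def write_bed(genes: pd.DataFrame, path: PathLike) -> None:
    """Write a gene annotation as BED6 (score column fixed at 0)."""
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene_id}\t0\t{row.strand}\n"
            )


def read_bed(path: PathLike) -> pd.DataFrame:
    """Read a BED6 annotation into a DataFrame with columns
    gene_id/chrom/start/end/strand; validates coordinates and ID uniqueness."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED columns")
            chrom, s, e, name, _score, strand = parts[:6]
            try:
                start, end = int(s), int(e)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            if strand not in {"+", "-", "."}:
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            rows.append((name, chrom, start, end, strand))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    if genes["gene_id"].duplicated().any():
        dupes = genes.loc[genes["gene_id"].duplicated(), "gene_id"].tolist()
        raise FormatError(f"{path}: duplicated gene IDs: {dupes[:5]}")
    return genes


# ---------------------------------------------------------------------------
# Gene sets and tables
# ---------------------------------------------------------------------------

def write_gene_set(ids: Iterable[str], path: PathLike) -> None:
    """One gene ID per line, sorted for byte stability."""
    with open(path, "w") as fh:
        for gid in sorted(ids):
            fh.write(f"{gid}\n")


def read_gene_set(path: PathLike) -> List[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_table(df: pd.DataFrame, path: PathLike, index: bool = True) -> None:
    """TSV with header row; floats rendered via repr round-trip."""
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def read_table(path: PathLike, index_col: Union[int, str, None] = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required columns {missing}")
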