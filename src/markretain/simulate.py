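"""Seeded synthetic data with the statistical structure of an
ether-induced chromatin-suppression experiment.

The generator emulates a two-condition, two-mark ChIP experiment in an
early embryo plus a later-stage (imaginal-disc) transcriptome:

* H3K4me3 is suppressed genome-wide in the treated condition by a
  multiplicative factor ``suppression_s``; per-gene *retention*
  (treated/control level) scatters around that factor.
* A designated "wing-like" gene subset retains the mark preferentially
  (``retention_boost_r`` times the bulk).
* H3K27me3 is unchanged between conditions.
* Retention is positively rank-coupled to baseline expression, and
  later-stage expression is positively rank-coupled to post-treatment
  H3K4me3 (``expression_coupling_rho``); the wing-like subset is
  up-regulated at the later stage in the treated lineage.
* Bin-level counts carry negative-binomial noise (Poisson in the
  zero-dispersion limit); ``noise_dispersion=None`` emits exact expected
  values, which keeps analytic oracles exact in tests.

Everything is driven by one integer seed through named per-stage RNG
streams, so outputs are byte-reproducible and each stage can be
regenerated independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .signal import BinnedTrack

__all__ = [
    "SimulationParams",
    "generate_annotation",
    "generate_gene_sets",
    "simulate_tracks",
    "simulate_expression",
    "simulate_protein_foldchanges",
    "simulate_dataset",
    "SyntheticDataset",
]

# fixed per-stage RNG stream ids (seeded as default_rng([seed, stream]))
_STREAMS = {
    "annotation": 0,
    "tracks": 1,
    "expression": 2,
    "proteins": 3,
    "gene_sets": 4,
    "latents": 5,
}

TRACK_NAMES = ("k4_ctrl", "k4_treated", "k27_ctrl", "k27_treated")


@dataclass
class SimulationParams:
    """Generative parameters for the synthetic experiment.

    Defaults are the reference study conditions used throughout the test
    suite: 1,000 genes, 50 % global H3K4me3 suppression, a 10 % wing-like
    subset with a 1.6x retention boost, and a 0.8 rank coupling between
    chromatin state and expression.
    """

    n_genes: int = 1000
    genome_length: int = 6_000_000  # bp, split evenly across chromosomes
    n_chromosomes: int = 2
    gene_length_mean: float = 2000.0  # bp
    gene_length_sd: float = 400.0  # bp
    bin_width_k4: int = 100  # bp (H3K4me3 resolution)
    bin_width_k27: int = 1000  # bp (H3K27me3 resolution)
    baseline_k4_log_mean: float = 3.0  # log-normal per-bin gene signal
    baseline_k4_log_sd: float = 1.0
    baseline_k27_log_mean: float = 3.0
    baseline_k27_log_sd: float = 0.8
    suppression_s: float = 0.5  # global multiplicative K4 suppression, (0, 1]
    subset_fraction: float = 0.10  # wing-like share of genes
    retention_boost_r: float = 1.6  # extra retention of subset genes, >= 1
    expression_coupling_rho: float = 0.8  # target Spearman, chromatin vs expression
    retention_jitter_sd: float = 0.25  # sd of per-gene log retention scatter
    noise_dispersion: Optional[float] = 0.1  # NB overdispersion; 0 = Poisson; None = off
    background_level: float = 1.0  # mean off-gene signal per bin
    de_log2_effect: float = 1.0  # later-stage log2 up-shift of subset genes (treated)
    n_expression_replicates: int = 3
    expression_rep_noise_sd: float = 0.2  # log-scale replicate noise
    protein_log2_sd: float = 0.5
    protein_log2_shifts: Dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if not 0 < self.suppression_s <= 1:
            raise ValueError(f"suppression_s must lie in (0, 1], got {self.suppression_s}")
        if self.retention_boost_r < 1:
            raise ValueError(f"retention_boost_r must be >= 1, got {self.retention_boost_r}")
        if not 0 < self.subset_fraction < 1:
            raise ValueError(f"subset_fraction must lie in (0, 1), got {self.subset_fraction}")
        if not 0 <= self.expression_coupling_rho <= 1:
            raise ValueError("expression_coupling_rho must lie in [0, 1]")
        if self.noise_dispersion is not None and self.noise_dispersion < 0:
            raise ValueError("noise_dispersion must be >= 0 (or None to disable noise)")
        if self.genome_length % (self.n_chromosomes * self.bin_width_k27) != 0:
            raise ValueError(
                "genome_length must split into chromosomes of whole K27 bins"
            )

    def rng(self, stream: str) -> np.random.Generator:
        """Named per-stage generator; independent of other stages."""
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])

    def to_dict(self) -> Dict:
        return asdict(self)


@dataclass
class SyntheticDataset:
    """One complete synthetic experiment (all stages, one seed)."""

    params: SimulationParams
    annotation: pd.DataFrame  # gene_id, chrom, start, end, strand, wing_like
    subset: List[str]  # wing-like gene IDs
    gene_sets: Dict[str, List[str]]
    tracks: Dict[str, BinnedTrack]
    embryo_expression: pd.DataFrame
    later_expression: pd.DataFrame
    protein_foldchanges: pd.DataFrame


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(params: SimulationParams) -> Tuple[pd.DataFrame, List[str]]:
    """Place non-overlapping genes on the synthetic genome.

    Returns the annotation (sorted, 0-based half-open, random strands, a
    boolean ``wing_like`` column) and the wing-like subset as a sorted ID
    list of size ``round(n_genes * subset_fraction)``.
    """
    rng = params.rng("annotation")
    cols = ["gene_id", "chrom", "start", "end", "strand", "wing_like"]
    if params.n_genes == 0:
        return pd.DataFrame(columns=cols), []

    chrom_len = params.genome_length // params.n_chromosomes
    counts = np.full(params.n_chromosomes, params.n_genes // params.n_chromosomes)
    counts[: params.n_genes % params.n_chromosomes] += 1

    min_len = max(3 * params.bin_width_k4, 1)
    rows = []
    gid = 0
    for ci in range(params.n_chromosomes):
        n = int(counts[ci])
        if n == 0:
            continue
        lengths = np.maximum(
            np.round(rng.normal(params.gene_length_mean, params.gene_length_sd, n)),
            min_len,
        ).astype(int)
        slack = chrom_len - int(lengths.sum())
        if slack < 0:
            raise ValueError(
                f"genome too small: chromosome {ci} needs {lengths.sum()} bp for "
                f"{n} genes but has {chrom_len} bp"
            )
        # sorted uniform offsets into the slack keep genes non-overlapping
        gaps = np.floor(np.sort(rng.uniform(0, slack, n))).astype(int)
        starts = gaps + np.concatenate(([0], np.cumsum(lengths[:-1])))
        strands = rng.choice(["+", "-"], size=n)
        for j in range(n):
            rows.append(
                (f"g{gid:05d}", f"chr{ci + 1}", int(starts[j]),
                 int(starts[j] + lengths[j]), strands[j])
            )
            gid += 1
    genes = pd.DataFrame(rows, columns=cols[:5])

    k = int(np.floor(params.n_genes * params.subset_fraction + 0.5))
    subset_idx = rng.choice(params.n_genes, size=k, replace=False)
    wing = np.zeros(params.n_genes, dtype=bool)
    wing[subset_idx] = True
    genes["wing_like"] = wing
    return genes, sorted(genes.loc[wing, "gene_id"])


def generate_gene_sets(
    annotation: pd.DataFrame, params: SimulationParams
) -> Dict[str, List[str]]:
    """Named gene sets mirroring the study's lists.

    ``wing_genes`` is the designated subset; ``trx_targets`` contains all
    wing genes plus a random 15 % of the rest (Trithorax maintains wing
    genes, so its target list is enriched for them); ``ubx_targets`` and
    ``hsp90_clients`` are random draws of 20 % and 25 % of genes.
    """
    rng = params.rng("gene_sets")
    ids = annotation["gene_id"].to_numpy()
    wing = annotation.loc[annotation["wing_like"], "gene_id"].to_numpy()
    non_wing = annotation.loc[~annotation["wing_like"], "gene_id"].to_numpy()

    def sample(pool: np.ndarray, frac: float) -> np.ndarray:
        k = int(np.floor(len(pool) * frac + 0.5))
        return pool[rng.choice(len(pool), size=k, replace=False)] if len(pool) else pool

    trx = np.concatenate([wing, sample(non_wing, 0.15)])
    ubx = sample(ids, 0.20)
    hsp90 = sample(ids, 0.25)
    return {
        "wing_genes": sorted(wing),
        "trx_targets": sorted(trx),
        "ubx_targets": sorted(ubx),
        "hsp90_clients": sorted(hsp90),
    }


# ---------------------------------------------------------------------------
# per-gene latent state (shared between tracks and expression)
# ---------------------------------------------------------------------------

def _spearman_to_pearson(rho_s: float) -> float:
    """Bivariate-normal Pearson correlation achieving a target Spearman."""
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def gene_latents(annotation: pd.DataFrame, params: SimulationParams) -> pd.DataFrame:
    """Per-gene latent state: baseline mark levels and retention multiplier.

    ``lambda_k4`` / ``kappa_k27`` are log-normal per-bin baseline signal
    levels.  ``retention`` is ``suppression_s * retention_boost_r^wing *
    eta`` where log eta has sd ``retention_jitter_sd`` and is rank-coupled
    (Gaussian copula) to the K4 baseline with target Spearman
    ``expression_coupling_rho`` — genes expressed higher at baseline retain
    the mark better.  Median eta = 1, so the bulk median retention stays at
    ``suppression_s``.
    """
    rng = params.rng("latents")
    n = len(annotation)
    z_k4 = rng.standard_normal(n)
    lam = np.exp(params.baseline_k4_log_mean + params.baseline_k4_log_sd * z_k4)
    kappa = np.exp(
        params.baseline_k27_log_mean
        + params.baseline_k27_log_sd * rng.standard_normal(n)
    )
    a = _spearman_to_pearson(params.expression_coupling_rho)
    z_eta = a * z_k4 + np.sqrt(max(0.0, 1.0 - a * a)) * rng.standard_normal(n)
    eta = np.exp(params.retention_jitter_sd * z_eta)
    retention = params.suppression_s * eta * np.where(
        annotation["wing_like"].to_numpy(), params.retention_boost_r, 1.0
    )
    return pd.DataFrame(
        {
            "lambda_k4": lam,
            "kappa_k27": kappa,
            "z_k4": z_k4,
            "retention": retention,
        },
        index=pd.Index(annotation["gene_id"], name="gene_id"),
    )


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def _gene_bin_spans(
    annotation: pd.DataFrame, chrom: str, n_bins: int, bw: int
) -> Iterable[Tuple[int, int, int]]:
    """(row position, first bin, last bin+1) per gene, by the midpoint rule."""
    sub = annotation[annotation["chrom"] == chrom]
    mids = (np.arange(n_bins) + 0.5) * bw
    lo = np.searchsorted(mids, sub["start"].to_numpy(), side="left")
    hi = np.searchsorted(mids, sub["end"].to_numpy(), side="left")
    return zip(sub.index.to_numpy(), lo, hi)


def _add_noise(
    expected: np.ndarray, dispersion: Optional[float], rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial counts around the expected value.

    var = mu + dispersion * mu^2; dispersion 0 is the Poisson limit; None
    returns the expectation itself (noise disabled).
    """
    if dispersion is None:
        return expected.copy()
    if dispersion == 0:
        return rng.poisson(expected).astype(float)
    r = 1.0 / dispersion
    p = r / (r + expected)
    return rng.negative_binomial(r, p).astype(float)


def simulate_tracks(
    annotation: pd.DataFrame,
    params: SimulationParams,
    latents: Optional[pd.DataFrame] = None,
    n_replicates: int = 1,
) -> Dict[str, BinnedTrack]:
    """Simulate the four coverage tracks (mark x condition).

    Expected values: off-gene bins sit at ``background_level`` in every
    track (non-specific background does not respond to treatment); bins
    inside a gene carry the gene's baseline level, multiplied in the
    treated H3K4me3 track by the gene's retention
    (``suppression_s`` x subset boost x per-gene jitter).  H3K27me3 shares
    expectations between conditions.  With ``n_replicates > 1``, noisy
    replicates are averaged (the merging rule for biological replicates).
    """
    if latents is None:
        latents = gene_latents(annotation, params)
    if not annotation["gene_id"].to_numpy().shape[0] == len(latents):
        raise ValueError("latents do not match annotation")
    rng = params.rng("tracks")
    annotation = annotation.reset_index(drop=True)
    chrom_len = params.genome_length // params.n_chromosomes
    chroms = [f"chr{i + 1}" for i in range(params.n_chromosomes)]

    lam = latents["lambda_k4"].to_numpy()
    kappa = latents["kappa_k27"].to_numpy()
    retention = latents["retention"].to_numpy()

    expected: Dict[str, Dict[str, np.ndarray]] = {t: {} for t in TRACK_NAMES}
    for chrom in chroms:
        for mark, bw in (("k4", params.bin_width_k4), ("k27", params.bin_width_k27)):
            n_bins = chrom_len // bw
            ctrl = np.full(n_bins, float(params.background_level))
            trt = np.full(n_bins, float(params.background_level))
            for row, lo, hi in _gene_bin_spans(annotation, chrom, n_bins, bw):
                if mark == "k4":
                    ctrl[lo:hi] = lam[row]
                    trt[lo:hi] = lam[row] * retention[row]
                else:
                    ctrl[lo:hi] = kappa[row]
                    trt[lo:hi] = kappa[row]
            expected[f"{mark}_ctrl"][chrom] = ctrl
            expected[f"{mark}_treated"][chrom] = trt

    tracks: Dict[str, BinnedTrack] = {}
    for name in TRACK_NAMES:
        bw = params.bin_width_k4 if name.startswith("k4") else params.bin_width_k27
        values: Dict[str, np.ndarray] = {}
        for chrom in chroms:
            reps = [
                _add_noise(expected[name][chrom], params.noise_dispersion, rng)
                for _ in range(max(1, n_replicates))
            ]
            values[chrom] = np.mean(reps, axis=0)
        tracks[name] = BinnedTrack(bw, values)
    return tracks


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    annotation: pd.DataFrame,
    k4_treated_levels: pd.Series,
    params: SimulationParams,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Embryo and later-stage expression tables (FPKM-like units).

    Embryo expression is a noisy monotone image of the baseline H3K4me3
    level.  Later-stage expression is rank-coupled (Gaussian copula) to
    the supplied per-gene post-treatment H3K4me3 levels with target
    Spearman ``expression_coupling_rho``, and is emitted as control and
    treated replicate columns; wing-like genes are up-shifted by
    ``de_log2_effect`` log2 units in the treated lineage.
    """
    ids = pd.Index(annotation["gene_id"], name="gene_id")
    if not ids.equals(k4_treated_levels.index):
        extra = k4_treated_levels.index.difference(ids)
        missing = ids.difference(k4_treated_levels.index)
        raise ValueError(
            f"gene IDs of k4_treated_levels do not match annotation "
            f"(missing {list(missing[:5])}, unexpected {list(extra[:5])})"
        )
    rng = params.rng("expression")
    latents = gene_latents(annotation, params)
    n = len(ids)

    # embryo: monotone in baseline K4 with modest biological noise
    embryo = np.exp(
        1.0
        + 1.0 * latents["z_k4"].to_numpy()
        + 0.3 * rng.standard_normal(n)
    )
    embryo_df = pd.DataFrame({"embryo_fpkm": embryo}, index=ids)

    # later stage: Gaussian copula against the realized treated-K4 ranks
    k4 = k4_treated_levels.to_numpy(dtype=float)
    ranks = rankdata(k4, method="average")
    z_k4 = _norm_scores(ranks)
    a = _spearman_to_pearson(params.expression_coupling_rho)
    z_later = a * z_k4 + np.sqrt(max(0.0, 1.0 - a * a)) * rng.standard_normal(n)
    base_log = 1.5 + 1.2 * z_later
    up = np.where(annotation["wing_like"].to_numpy(), params.de_log2_effect, 0.0)

    cols = {}
    for r in range(params.n_expression_replicates):
        cols[f"later_ctrl_rep{r + 1}"] = np.exp(
            base_log + params.expression_rep_noise_sd * rng.standard_normal(n)
        )
    for r in range(params.n_expression_replicates):
        cols[f"later_treated_rep{r + 1}"] = np.exp(
            base_log
            + up * np.log(2.0)
            + params.expression_rep_noise_sd * rng.standard_normal(n)
        )
    later_df = pd.DataFrame(cols, index=ids)
    return embryo_df, later_df


def _norm_scores(ranks: np.ndarray) -> np.ndarray:
    """Map ranks to standard-normal scores (Blom-type, (r - 0.5)/n)."""
    from scipy.stats import norm

    return norm.ppf((ranks - 0.5) / ranks.size)


# ---------------------------------------------------------------------------
# proteins
# ---------------------------------------------------------------------------

def simulate_protein_foldchanges(
    gene_sets: Mapping[str, Iterable[str]],
    params: SimulationParams,
) -> pd.DataFrame:
    """Protein-level fold-changes (treated/control) over the union of sets.

    Per-protein log2 fold-changes are normal with sd ``protein_log2_sd``
    and a location shift equal to the sum of ``protein_log2_shifts`` of the
    sets the protein belongs to (default shift 0 — median fold-change 1).
    The table carries one boolean membership column per non-empty set.
    """
    rng = params.rng("proteins")
    sets = {name: sorted(set(ids)) for name, ids in gene_sets.items()}
    for name in [n for n, ids in sets.items() if not ids]:
        warnings.warn(f"gene set {name!r} is empty; omitted from the protein table")
        del sets[name]
    universe = sorted(set().union(*sets.values())) if sets else []
    shifts = np.zeros(len(universe))
    membership = {}
    for name, ids in sets.items():
        mask = np.isin(universe, ids)
        membership[f"in_{name}"] = mask
        shifts += mask * float(params.protein_log2_shifts.get(name, 0.0))
    log2fc = shifts + params.protein_log2_sd * rng.standard_normal(len(universe))
    table = pd.DataFrame(
        {"fold_change": 2.0 ** log2fc, **membership},
        index=pd.Index(universe, name="gene_id"),
    )
    return table


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------

def simulate_dataset(params: SimulationParams) -> SyntheticDataset:
    """Run every generator stage in the canonical order, one seed."""
    from .genes import aggregate_gene_signal

    annotation, subset = generate_annotation(params)
    latents = gene_latents(annotation, params)
    gene_sets = generate_gene_sets(annotation, params)
    tracks = simulate_tracks(annotation, params, latents=latents)
    k4_treated_levels = aggregate_gene_signal(tracks["k4_treated"], annotation)
    embryo, later = simulate_expression(annotation, k4_treated_levels, params)
    proteins = simulate_protein_foldchanges(gene_sets, params)
    return SyntheticDataset(
        params=params,
        annotation=annotation,
        subset=subset,
        gene_sets=gene_sets,
        tracks=tracks,
        embryo_expression=embryo,
        later_expression=later,
        protein_foldchanges=proteins,
    )
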