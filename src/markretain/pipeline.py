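"""End-to-end pipeline: simulate (or load) -> normalize -> aggregate ->
subset tests -> linkage, driven by one YAML config.

Each stage writes plain-text outputs (bedGraph / TSV / JSON) into the
output directory and the run closes with a manifest recording package
version, parameters, per-stage seeds and SHA-256 checksums of every file
written, so identical configs reproduce byte-identical runs.

One global seed fans out to per-stage seeds as ``seed + stage_index``
(simulate=0, normalize=1, aggregate=2, subset=3, link=4), so any stage can
be re-run in isolation with a known seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml
from scipy.stats import ttest_ind

from . import io as mio
from .genes import (
    aggregate_gene_signal,
    build_gene_table,
    classify_region_changes,
    filter_differential,
    select_extreme,
)
from .linkage import (
    LinkageReport,
    de_set_enrichment,
    decile_expression_association,
    direction_fractions,
    retention_expression_correlation,
)
from .signal import BinnedTrack, apply_background_threshold, percentile_normalize, smooth_track
from .simulate import SimulationParams, SyntheticDataset, simulate_dataset
from .stats import bh_adjust, bootstrap_median_test, subset_median_foldchange

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "validate_inputs"]

log = logging.getLogger("markretain.pipeline")

_STAGES = ("simulate", "normalize", "aggregate", "subset", "link")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Exactly one of ``simulation`` (generator parameters) or ``inputs``
    (paths to tracks/annotation/gene sets/tables) must be present.
    """

    simulation: Optional[SimulationParams] = None
    inputs: Optional[Dict] = None
    # processing
    window_bp: int = 100
    threshold_quantile: float = 95.0
    normalize: bool = True
    # stats
    n_iter: int = 100_000
    seed: int = 0
    tolerance: float = 0.05
    fdr_level: float = 0.05
    detect_floor: float = 0.0
    pseudocount: float = 1.0
    extreme_fraction: float = 0.10
    fc_min: float = 1.5
    p_max: float = 0.05

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ConfigError(
                "config must contain exactly one of a 'simulation' block or "
                "an 'inputs' block"
            )

    @classmethod
    def from_dict(cls, raw: Dict) -> "PipelineConfig":
        known_blocks = {"simulation", "inputs", "processing", "stats"}
        unknown = set(raw) - known_blocks
        if unknown:
            raise ConfigError(f"unknown config blocks: {sorted(unknown)}")
        sim = raw.get("simulation")
        processing = raw.get("processing", {}) or {}
        stats = raw.get("stats", {}) or {}
        kwargs: Dict = {}
        for key in ("window_bp", "threshold_quantile", "normalize"):
            if key in processing:
                kwargs[key] = processing[key]
        for key in (
            "n_iter", "seed", "tolerance", "fdr_level", "detect_floor",
            "pseudocount", "extreme_fraction", "fc_min", "p_max",
        ):
            if key in stats:
                kwargs[key] = stats[key]
        try:
            if sim is not None and "seed" not in sim:
                # global seed fans out; the simulate stage has index 0
                sim = {**sim, "seed": int(stats.get("seed", 0))}
            sim_params = SimulationParams(**sim) if sim is not None else None
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad simulation block: {exc}") from None
        return cls(simulation=sim_params, inputs=raw.get("inputs"), **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def stage_seed(self, stage: str) -> int:
        return int(self.seed) + _STAGES.index(stage)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _effective_window(window_bp: int, bin_width: int) -> int:
    """Smoothing window for a track; falls back to one bin when the
    requested window is not a multiple of the bin width (e.g. a 100 bp
    window on 1,000 bp H3K27me3 bins)."""
    if window_bp % bin_width == 0 and window_bp >= bin_width:
        return window_bp
    return bin_width


def _load_inputs(inputs: Dict) -> SyntheticDataset:
    """Read user-supplied files into the same container the simulator emits."""
    required = {"tracks", "annotation"}
    missing = required - set(inputs)
    if missing:
        raise ConfigError(f"inputs block missing keys: {sorted(missing)}")
    tracks = {
        name: mio.read_bedgraph(path) for name, path in inputs["tracks"].items()
    }
    for name in ("k4_ctrl", "k4_treated", "k27_ctrl", "k27_treated"):
        if name not in tracks:
            raise ConfigError(f"inputs.tracks missing track {name!r}")
    annotation = mio.read_bed(inputs["annotation"])
    annotation["wing_like"] = False
    gene_sets = {
        name: mio.read_gene_set(path)
        for name, path in (inputs.get("gene_sets") or {}).items()
    }
    embryo = (
        mio.read_table(inputs["embryo_expression"])
        if inputs.get("embryo_expression")
        else pd.DataFrame(index=pd.Index([], name="gene_id"))
    )
    later = (
        mio.read_table(inputs["later_expression"])
        if inputs.get("later_expression")
        else pd.DataFrame(index=pd.Index([], name="gene_id"))
    )
    proteins = (
        mio.read_table(inputs["protein_foldchanges"])
        if inputs.get("protein_foldchanges")
        else pd.DataFrame(index=pd.Index([], name="gene_id"))
    )
    return SyntheticDataset(
        params=None,  # type: ignore[arg-type]
        annotation=annotation,
        subset=gene_sets.get("wing_genes", []),
        gene_sets=gene_sets,
        tracks=tracks,
        embryo_expression=embryo,
        later_expression=later,
        protein_foldchanges=proteins,
    )


def _de_stats(later: pd.DataFrame) -> pd.DataFrame:
    """Two-group differential expression on later-stage replicate columns.

    Welch t-test on log2(FPKM + 1) between *_treated_rep* and *_ctrl_rep*
    columns; fold-change is the ratio of condition means (small pseudocount
    guards empty denominators).
    """
    ctrl_cols = [c for c in later.columns if "_ctrl_rep" in c]
    trt_cols = [c for c in later.columns if "_treated_rep" in c]
    if len(ctrl_cols) < 2 or len(trt_cols) < 2:
        raise ValueError("need >= 2 replicate columns per condition for DE testing")
    ctrl = later[ctrl_cols].to_numpy(dtype=float)
    trt = later[trt_cols].to_numpy(dtype=float)
    eps = 1e-9
    fc = (trt.mean(axis=1) + eps) / (ctrl.mean(axis=1) + eps)
    _, p = ttest_ind(
        np.log2(trt + 1.0), np.log2(ctrl + 1.0), axis=1, equal_var=False
    )
    return pd.DataFrame({"fold_change": fc, "p_value": p}, index=later.index)


def run_pipeline(config: PipelineConfig, outdir) -> Dict:
    """Execute every stage and return the manifest (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    def emit(relpath: str, writer) -> Path:
        """Write atomically (tmp file + rename) and record the path."""
        final = outdir / relpath
        final.parent.mkdir(parents=True, exist_ok=True)
        tmp = final.with_name(final.name + ".tmp")
        writer(tmp)
        os.replace(tmp, final)
        written.append(final)
        return final

    manifest: Dict = {
        "package": "markretain",
        "stages": [],
        "seeds": {s: config.stage_seed(s) for s in _STAGES},
        "parameters": {
            "window_bp": config.window_bp,
            "threshold_quantile": config.threshold_quantile,
            "normalize": config.normalize,
            "n_iter": config.n_iter,
            "seed": config.seed,
            "tolerance": config.tolerance,
            "fdr_level": config.fdr_level,
            "detect_floor": config.detect_floor,
            "pseudocount": config.pseudocount,
            "extreme_fraction": config.extreme_fraction,
            "fc_min": config.fc_min,
            "p_max": config.p_max,
        },
    }
    try:
        from importlib.metadata import version

        manifest["version"] = version("markretain")
    except Exception:  # pragma: no cover - not installed
        manifest["version"] = "unknown"

    def stage(name):
        log.info("[%s] starting", name)
        manifest["stages"].append(name)

    # ------------------------------------------------------------------ 1
    stage("simulate")
    try:
        if config.simulation is not None:
            params = config.simulation
            data = simulate_dataset(params)
            manifest["parameters"]["simulation"] = params.to_dict()
            emit("annotation.bed", lambda p: mio.write_bed(data.annotation, p))
            for name, ids in data.gene_sets.items():
                emit(f"sets/{name}.txt", lambda p, ids=ids: mio.write_gene_set(ids, p))
            for name, track in data.tracks.items():
                emit(f"tracks/{name}.bedgraph", lambda p, t=track: mio.write_bedgraph(t, p))
            emit(
                "embryo_expression.tsv",
                lambda p: mio.write_table(data.embryo_expression, p),
            )
            emit(
                "later_expression.tsv",
                lambda p: mio.write_table(data.later_expression, p),
            )
            emit(
                "protein_foldchanges.tsv",
                lambda p: mio.write_table(data.protein_foldchanges, p),
            )
            emit(
                "params.yaml",
                lambda p: Path(p).write_text(
                    yaml.safe_dump(params.to_dict(), sort_keys=True)
                ),
            )
        else:
            data = _load_inputs(config.inputs)
            manifest["input_checksums"] = {
                key: _sha256(Path(path))
                for key, path in _flatten_input_paths(config.inputs).items()
            }
    except (ConfigError, mio.FormatError):
        raise
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    # ------------------------------------------------------------------ 2
    stage("normalize")
    try:
        smoothed: Dict[str, BinnedTrack] = {}
        normalized: Dict[str, BinnedTrack] = {}
        for name, track in data.tracks.items():
            win = _effective_window(config.window_bp, track.bin_width)
            sm = smooth_track(track, win)
            smoothed[name] = sm
            if config.normalize:
                norm = percentile_normalize(sm)
                normalized[name] = norm
                thr = apply_background_threshold(norm, config.threshold_quantile)
                emit(
                    f"normalized/{name}.bedgraph",
                    lambda p, t=thr: mio.write_bedgraph(t, p),
                )
    except Exception as exc:
        raise RuntimeError(f"stage 'normalize' failed: {exc}") from exc

    # ------------------------------------------------------------------ 3
    stage("aggregate")
    try:
        ann = data.annotation
        levels = {
            name: aggregate_gene_signal(track, ann) for name, track in smoothed.items()
        }
        gene_table = build_gene_table(
            levels["k4_ctrl"],
            levels["k4_treated"],
            levels["k27_ctrl"],
            levels["k27_treated"],
            detect_floor=config.detect_floor,
            pseudocount=config.pseudocount,
        )
        emit("gene_signal.tsv", lambda p: mio.write_table(gene_table, p))
        region_summary = {}
        source = normalized if config.normalize else smoothed
        for mark in ("k4", "k27"):
            res = classify_region_changes(source[f"{mark}_ctrl"], source[f"{mark}_treated"])
            region_summary[mark] = {
                "mean_diff": res.mean,
                "sd_diff": res.sd,
                "n_above": res.n_above,
                "n_below": res.n_below,
                "n_within": res.n_within,
            }
        emit(
            "region_diff_summary.json",
            lambda p: Path(p).write_text(json.dumps(region_summary, indent=2, sort_keys=True)),
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'aggregate' failed: {exc}") from exc

    # ------------------------------------------------------------------ 4
    stage("subset")
    try:
        seed = config.stage_seed("subset")
        detectable = gene_table[gene_table["detectable"]]
        retention = detectable["retention"]
        rows = []
        for si, (name, ids) in enumerate(sorted(data.gene_sets.items())):
            in_pop = [g for g in ids if g in retention.index]
            if not in_pop or len(in_pop) >= len(retention):
                continue
            boot = bootstrap_median_test(
                retention, in_pop, n_iter=config.n_iter, seed=seed + si
            )
            rows.append(
                (name, "retention", boot.subset_size, boot.observed_median,
                 boot.p_upper, boot.p_lower, boot.direction)
            )
        subset_report = pd.DataFrame(
            rows,
            columns=["subset", "metric", "n", "observed_median", "p_upper",
                     "p_lower", "direction"],
        )
        if len(subset_report):
            two_sided = np.minimum(
                1.0, 2.0 * subset_report[["p_upper", "p_lower"]].min(axis=1)
            )
            subset_report["bh_fdr"] = bh_adjust(two_sided.to_numpy())
        emit("subset_tests.tsv", lambda p: mio.write_table(subset_report.set_index("subset"), p))

        if len(data.protein_foldchanges):
            fc = data.protein_foldchanges["fold_change"]
            member_cols = [c for c in data.protein_foldchanges.columns if c.startswith("in_")]
            prot_sets = {
                c[3:]: list(data.protein_foldchanges.index[data.protein_foldchanges[c]])
                for c in member_cols
            }
            prot = subset_median_foldchange(fc, prot_sets, seed=seed + 1000)
            emit("protein_subset_medians.tsv", lambda p: mio.write_table(prot, p))
    except Exception as exc:
        raise RuntimeError(f"stage 'subset' failed: {exc}") from exc

    # ------------------------------------------------------------------ 5
    stage("link")
    try:
        seed = config.stage_seed("link")
        frac_lower, frac_higher, frac_unchanged = direction_fractions(
            gene_table, tol=config.tolerance
        )
        top = select_extreme(gene_table, "k4_treated", config.extreme_fraction, "top")
        bottom = select_extreme(gene_table, "k4_treated", config.extreme_fraction, "bottom")

        extras: Dict = {}
        decile = pd.DataFrame()
        enrich = pd.DataFrame()
        retention_expr: Dict[str, float] = {}
        later = data.later_expression
        if len(later):
            later_mean = later[[c for c in later.columns if "_ctrl_rep" in c]].mean(axis=1)
            decile = decile_expression_association(
                {"top_k4": top, "bottom_k4": bottom},
                later_mean,
                n_iter=config.n_iter,
                seed=seed,
            )
            de = _de_stats(later)
            up, down = filter_differential(de, config.fc_min, config.p_max)
            extras["n_up"] = len(up)
            extras["n_down"] = len(down)
            enrich = de_set_enrichment(
                up, down, data.gene_sets, list(later.index)
            )
        if len(data.embryo_expression):
            retention_expr = retention_expression_correlation(
                gene_table.loc[gene_table["detectable"], "retention"],
                data.embryo_expression.iloc[:, 0],
                seed=seed + 1,
            )
        report = LinkageReport(
            frac_lower=frac_lower,
            frac_higher=frac_higher,
            frac_unchanged=frac_unchanged,
            tolerance=config.tolerance,
            decile_summaries=decile,
            retention_expression=retention_expr,
            enrichment=enrich,
            extras=extras,
        )
        emit(
            "linkage.json",
            lambda p: Path(p).write_text(json.dumps(report.to_json_dict(), indent=2, default=float)),
        )
        if len(enrich):
            emit("enrichment.tsv", lambda p: mio.write_table(enrich, p, index=False))
    except Exception as exc:
        raise RuntimeError(f"stage 'link' failed: {exc}") from exc

    manifest["outputs"] = {
        str(p.relative_to(outdir)): _sha256(p) for p in sorted(written)
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _flatten_input_paths(inputs: Dict) -> Dict[str, str]:
    flat: Dict[str, str] = {}
    for key, val in inputs.items():
        if isinstance(val, dict):
            for sub, path in val.items():
                flat[f"{key}.{sub}"] = str(path)
        elif val:
            flat[key] = str(val)
    return flat


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

def validate_inputs(inputs: Dict) -> List[str]:
    """Validate input files without running the pipeline.

    Returns a list of violation strings (``file:line: message``); an empty
    list means everything checked out.  Checks: bedGraph sorted /
    non-overlapping / fixed-width, BED well-formed with unique IDs, TSV
    tables with a gene_id column, gene-set IDs a subset of the annotation.
    """
    violations: List[str] = []
    annotation = None
    if inputs.get("annotation"):
        try:
            annotation = mio.read_bed(inputs["annotation"])
        except (mio.FormatError, OSError) as exc:
            violations.append(str(exc))
    for name, path in (inputs.get("tracks") or {}).items():
        try:
            mio.read_bedgraph(path)
        except (mio.FormatError, OSError) as exc:
            violations.append(str(exc))
    known = set(annotation["gene_id"]) if annotation is not None else None
    for name, path in (inputs.get("gene_sets") or {}).items():
        try:
            ids = mio.read_gene_set(path)
        except OSError as exc:
            violations.append(str(exc))
            continue
        if known is not None:
            for gid in ids:
                if gid not in known:
                    violations.append(f"{path}: unknown gene ID {gid!r}")
    for key in ("embryo_expression", "later_expression", "protein_foldchanges"):
        if inputs.get(key):
            try:
                df = mio.read_table(inputs[key])
                if df.index.name != "gene_id":
                    violations.append(f"{inputs[key]}: first column must be 'gene_id'")
            except (OSError, pd.errors.ParserError) as exc:
                violations.append(str(exc))
    return violations
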