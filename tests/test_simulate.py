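"""Synthetic-data generator: determinism, packing, identity limits,
parameter recovery and the chromatin-expression couplings."""

import io as _io

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from markretain import io as mio
from markretain.genes import aggregate_gene_signal
from markretain.simulate import (
    SimulationParams,
    gene_latents,
    generate_annotation,
    generate_gene_sets,
    simulate_expression,
    simulate_protein_foldchanges,
    simulate_tracks,
)


def params(**kw):
    base = dict(n_genes=100, genome_length=600_000, seed=7)
    base.update(kw)
    return SimulationParams(**base)


class TestAnnotation:
    def test_empty_genome(self):
        genes, subset = generate_annotation(params(n_genes=0))
        assert genes.empty and subset == []

    def test_subset_size_follows_rounding_rule(self):
        genes, subset = generate_annotation(params(n_genes=100, subset_fraction=0.1))
        assert len(subset) == 10
        assert genes["wing_like"].sum() == 10

    def test_genes_sorted_and_non_overlapping(self):
        genes, _ = generate_annotation(params(n_genes=200, genome_length=1_000_000))
        for _, sub in genes.groupby("chrom"):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            assert np.all(starts < ends)
            assert np.all(starts[1:] >= ends[:-1])

    def test_fixed_seed_gives_identical_bed_bytes(self, tmp_path):
        outs = []
        for run in range(2):
            genes, _ = generate_annotation(params(seed=7))
            path = tmp_path / f"run{run}.bed"
            mio.write_bed(genes, path)
            outs.append(path.read_bytes())
        assert outs[0] == outs[1]

    def test_infeasible_packing_raises_capacity_error(self):
        with pytest.raises(ValueError, match="genome too small"):
            generate_annotation(params(n_genes=100, genome_length=6000,
                                       gene_length_mean=2000, gene_length_sd=1))


class TestTracks:
    def test_identity_parameters_conserve_tracks(self):
        p = params(suppression_s=1.0, retention_boost_r=1.0,
                   retention_jitter_sd=0.0, noise_dispersion=None)
        genes, _ = generate_annotation(p)
        tracks = simulate_tracks(genes, p)
        for mark in ("k4", "k27"):
            for chrom in tracks[f"{mark}_ctrl"].chroms:
                np.testing.assert_array_equal(
                    tracks[f"{mark}_ctrl"].values[chrom],
                    tracks[f"{mark}_treated"].values[chrom],
                )

    def test_noise_free_retention_is_exactly_s_for_bulk_genes(self):
        p = params(suppression_s=0.5, retention_jitter_sd=0.0, noise_dispersion=None)
        genes, subset = generate_annotation(p)
        tracks = simulate_tracks(genes, p)
        k4c = aggregate_gene_signal(tracks["k4_ctrl"], genes)
        k4t = aggregate_gene_signal(tracks["k4_treated"], genes)
        bulk = [g for g in genes["gene_id"] if g not in set(subset)]
        np.testing.assert_allclose((k4t / k4c)[bulk], 0.5)
        np.testing.assert_allclose((k4t / k4c)[subset], 0.8)  # 0.5 * 1.6

    def test_k27_expectations_shared_between_conditions(self):
        p = params(noise_dispersion=None)
        genes, _ = generate_annotation(p)
        tracks = simulate_tracks(genes, p)
        for chrom in tracks["k27_ctrl"].chroms:
            np.testing.assert_array_equal(
                tracks["k27_ctrl"].values[chrom], tracks["k27_treated"].values[chrom]
            )

    def test_off_gene_bins_at_background(self):
        p = params(noise_dispersion=None, background_level=2.5)
        genes, _ = generate_annotation(p)
        tracks = simulate_tracks(genes, p)
        track = tracks["k4_treated"]
        gene_bins = set()
        for _, g in genes.iterrows():
            mids = track.midpoints(g.chrom)
            gene_bins |= {
                (g.chrom, i) for i in np.flatnonzero((mids >= g.start) & (mids < g.end))
            }
        off = [
            track.values[c][i]
            for c in track.chroms
            for i in range(track.values[c].size)
            if (c, i) not in gene_bins
        ]
        assert np.allclose(off, 2.5)

    def test_subset_retention_gap_recovers_boost(self):
        """Mean subset/bulk retention ratio concentrates at r over seeds."""
        ratios = []
        for seed in range(20):
            p = SimulationParams(n_genes=500, genome_length=3_000_000, seed=seed,
                                 suppression_s=0.5, retention_boost_r=1.6)
            genes, subset = generate_annotation(p)
            tracks = simulate_tracks(genes, p)
            k4c = aggregate_gene_signal(tracks["k4_ctrl"], genes)
            k4t = aggregate_gene_signal(tracks["k4_treated"], genes)
            ret = k4t / k4c
            bulk = [g for g in genes["gene_id"] if g not in set(subset)]
            ratios.append(np.median(ret[subset]) / np.median(ret[bulk]))
        ratios = np.asarray(ratios)
        assert ratios.mean() > 1.0
        ci = 3 * ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 1.6) < max(ci, 0.1)

    def test_replicate_merging_is_mean_of_replicates(self):
        p = params(noise_dispersion=None)
        genes, _ = generate_annotation(p)
        single = simulate_tracks(genes, p, n_replicates=1)
        merged = simulate_tracks(genes, p, n_replicates=3)
        # noise-free replicates are identical, so their mean equals one run
        for chrom in single["k4_ctrl"].chroms:
            np.testing.assert_allclose(
                single["k4_ctrl"].values[chrom], merged["k4_ctrl"].values[chrom]
            )


class TestExpression:
    def later_rho(self, p, n=2000):
        genes, _ = generate_annotation(p)
        lat = gene_latents(genes, p)
        k4 = pd.Series(
            (lat["lambda_k4"] * lat["retention"]).to_numpy(),
            index=pd.Index(genes["gene_id"], name="gene_id"),
        )
        _, later = simulate_expression(genes, k4, p)
        ctrl = later[[c for c in later.columns if "_ctrl_rep" in c]].mean(axis=1)
        return spearmanr(k4, ctrl)[0]

    def test_zero_coupling_gives_near_zero_rank_correlation(self):
        p = SimulationParams(n_genes=2000, genome_length=12_000_000,
                             expression_coupling_rho=0.0, seed=5)
        assert abs(self.later_rho(p)) < 0.07

    def test_target_coupling_achieved(self):
        p = SimulationParams(n_genes=2000, genome_length=12_000_000,
                             expression_coupling_rho=0.8, seed=3)
        assert 0.7 <= self.later_rho(p) <= 0.9

    def test_perfect_coupling_no_noise_is_exact_rank_agreement(self):
        p = SimulationParams(n_genes=500, genome_length=3_000_000,
                             expression_coupling_rho=1.0,
                             expression_rep_noise_sd=0.0,
                             de_log2_effect=0.0, seed=1)
        genes, _ = generate_annotation(p)
        lat = gene_latents(genes, p)
        k4 = pd.Series(lat["lambda_k4"].to_numpy(),
                       index=pd.Index(genes["gene_id"], name="gene_id"))
        _, later = simulate_expression(genes, k4, p)
        assert spearmanr(k4, later["later_ctrl_rep1"])[0] == pytest.approx(1.0)

    def test_mismatched_gene_ids_rejected(self):
        p = params()
        genes, _ = generate_annotation(p)
        bad = pd.Series(1.0, index=pd.Index(["nope"], name="gene_id"))
        with pytest.raises(ValueError, match="do not match"):
            simulate_expression(genes, bad, p)

    def test_retention_coupled_to_baseline_expression(self):
        p = SimulationParams(n_genes=2000, genome_length=12_000_000,
                             expression_coupling_rho=0.8, seed=2)
        genes, _ = generate_annotation(p)
        lat = gene_latents(genes, p)
        rho = spearmanr(lat["lambda_k4"], lat["retention"])[0]
        assert 0.7 <= rho <= 0.9


class TestProteins:
    def test_zero_shifts_give_unit_medians(self):
        p = SimulationParams(n_genes=2000, genome_length=12_000_000, seed=4)
        genes, _ = generate_annotation(p)
        sets = generate_gene_sets(genes, p)
        table = simulate_protein_foldchanges(sets, p)
        for name in sets:
            med = table.loc[table[f"in_{name}"], "fold_change"].median()
            assert med == pytest.approx(1.0, abs=0.12)

    def test_shifted_subset_exceeds_bulk_median(self):
        p = SimulationParams(n_genes=1000, genome_length=6_000_000, seed=4,
                             protein_log2_shifts={"wing_genes": 0.3})
        genes, _ = generate_annotation(p)
        sets = generate_gene_sets(genes, p)
        table = simulate_protein_foldchanges(sets, p)
        wing_med = table.loc[table["in_wing_genes"], "fold_change"].median()
        bulk_med = table.loc[~table["in_wing_genes"], "fold_change"].median()
        assert wing_med > bulk_med

    def test_empty_subset_warned_and_omitted(self):
        p = params()
        with pytest.warns(UserWarning, match="empty"):
            table = simulate_protein_foldchanges({"a": ["g1", "g2"], "b": []}, p)
        assert "in_b" not in table.columns and "in_a" in table.columns


class TestDeterminismAndValidation:
    def test_identical_seed_gives_identical_bedgraph_bytes(self):
        outs = []
        for _ in range(2):
            p = params(seed=13)
            genes, _ = generate_annotation(p)
            tracks = simulate_tracks(genes, p)
            buf = _io.StringIO()
            for chrom, start, end, v in tracks["k4_treated"].iter_bins():
                buf.write(f"{chrom}\t{start}\t{end}\t{v!r}\n")
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    @pytest.mark.parametrize(
        "bad",
        [
            dict(suppression_s=0.0),
            dict(suppression_s=1.5),
            dict(retention_boost_r=0.9),
            dict(subset_fraction=0.0),
            dict(subset_fraction=1.0),
            dict(noise_dispersion=-0.1),
            dict(expression_coupling_rho=1.2),
        ],
    )
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            params(**bad)
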