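"""Determinism, planted geometry, moment checks, referential integrity."""

import numpy as np
import pandas as pd
import pytest

from sirna_callus.simulate import (
    GroundTruth,
    PlantedLocus,
    SimulationConfig,
    SizingError,
    generate_genome,
    plant_duplex_loci,
    simulate_all,
    simulate_gene_expression,
    simulate_methylation,
    simulate_srna_libraries,
)

COUNT_COLS = ["count_CK", "count_I", "count_II", "count_III"]


def _loci_only_truth(loci):
    return GroundTruth(planted_loci=loci, cleavage_links=[], methyl_links=[],
                       cluster_labels={})


def _single_tag_loci(n, lfc=(0.0, 0.0, 0.0)):
    return [
        PlantedLocus(
            locus_id=f"loc{i}", kind="decoy_single", chrom="chr1", start=0, end=21,
            length=21, plus_tag_id=f"t{i}", minus_tag_id=None, plus_seq="", minus_seq=None,
            lfc=tuple(lfc),
        )
        for i in range(n)
    ]


class TestGenome:
    def test_deterministic_and_disjoint(self):
        cfg = SimulationConfig(genome_length=100_000, n_genes=50, seed=7)
        g1, genes1, excl1 = generate_genome(cfg)
        g2, genes2, excl2 = generate_genome(cfg)
        assert g1 == g2 and genes1 == genes2 and excl1 == excl2
        assert len(genes1) == 50
        spans = sorted((g.start, g.end) for g in genes1)
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))
        assert all(0 <= g.start < g.end <= cfg.genome_length for g in genes1)
        assert all(0 <= s < e <= cfg.genome_length for _, s, e, _ in excl1)

    def test_no_genes(self):
        cfg = SimulationConfig(genome_length=50_000, n_genes=0, n_cleavage_links=0,
                               n_methyl_links=0, seed=1)
        _, genes, excl = generate_genome(cfg)
        assert genes == []

    def test_impossible_packing_names_deficit(self):
        cfg = SimulationConfig(genome_length=1000, n_genes=500)
        with pytest.raises(SizingError, match="deficit"):
            generate_genome(cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="length weights"):
            SimulationConfig(sirna_length_weights={21: 0.5}).validate()
        with pytest.raises(ValueError, match="planted_lfc"):
            SimulationConfig(planted_lfc=0.0).validate()


class TestPlantedGeometry:
    def test_duplexes_satisfy_and_near_misses_violate_the_predicate(self, bundle):
        for loc in bundle.truth.planted_loci:
            if loc.kind == "decoy_single":
                continue
            # reconstruct the two alignments implied by the planted span
            minus = (loc.start, loc.start + loc.length)
            plus = (loc.end - loc.length, loc.end)
            holds = plus[0] - minus[0] == 2 and plus[1] - minus[1] == 2
            assert holds == (loc.kind == "duplex")

    def test_tags_match_their_genome_strands(self, bundle):
        from sirna_callus.catalog import revcomp

        seq = bundle.genome["chr1"]
        for loc in bundle.truth.planted_loci:
            if loc.plus_seq is not None:
                assert loc.plus_seq == seq[loc.end - loc.length : loc.end]
            if loc.minus_seq is not None:
                assert loc.minus_seq == revcomp(seq[loc.start : loc.start + loc.length])

    def test_referential_integrity(self, bundle):
        gene_ids = {g.gene_id for g in bundle.genes}
        tag_ids = set(bundle.tag_table["tag_id"])
        for s, g, _ in bundle.truth.cleavage_links:
            assert g in gene_ids and s in tag_ids
        for s, g, _, _ in bundle.truth.methyl_links:
            assert g in gene_ids and s in tag_ids
        assert set(bundle.truth.cluster_labels) <= gene_ids

    def test_loci_avoid_excluded_intervals(self, bundle):
        for loc in bundle.truth.planted_loci:
            for _, s, e, _ in bundle.excluded:
                assert loc.end <= s or loc.start >= e


class TestSRNACounts:
    def test_poisson_limit_moments(self):
        cfg = SimulationConfig(baseline_mean=100.0, dispersion=0.0, seed=5)
        truth = _loci_only_truth(_single_tag_loci(1000))
        table = simulate_srna_libraries(truth, cfg)
        counts = table["count_CK"].to_numpy()
        se = np.sqrt(100.0 / len(counts))
        assert abs(counts.mean() - 100.0) < 3 * se
        # Poisson: variance equals the mean (allow sampling slack)
        assert abs(counts.var() - 100.0) < 15

    def test_planted_fold_change_ratio(self):
        cfg = SimulationConfig(baseline_mean=100.0, dispersion=0.001, planted_lfc=2.0,
                               seed=6)
        truth = _loci_only_truth(_single_tag_loci(200, lfc=(2.0, 0.0, 0.0)))
        table = simulate_srna_libraries(truth, cfg)
        ratio = table["count_I"].mean() / table["count_CK"].mean()
        assert 3.0 < ratio < 5.3

    def test_library_size_scaling(self):
        cfg = SimulationConfig(baseline_mean=100.0, dispersion=0.0,
                               library_sizes=(1e6, 2e6, 1e6, 1e6), seed=7)
        truth = _loci_only_truth(_single_tag_loci(1000))
        table = simulate_srna_libraries(truth, cfg)
        ratio = table["count_I"].mean() / table["count_CK"].mean()
        assert 1.9 < ratio < 2.1

    def test_deterministic(self):
        cfg = SimulationConfig(seed=8)
        b1 = simulate_all(cfg)
        b2 = simulate_all(cfg)
        for attr in ("tag_table", "gene_table", "region_signal", "degradome"):
            pd.testing.assert_frame_equal(getattr(b1, attr), getattr(b2, attr))
        assert b1.genome == b2.genome

    def test_different_seeds_differ(self):
        t1 = simulate_all(SimulationConfig(seed=1)).tag_table
        t2 = simulate_all(SimulationConfig(seed=2)).tag_table
        assert not t1.equals(t2)


class TestGeneExpression:
    def test_linked_gene_profile_is_antiproportional(self, bundle):
        from sirna_callus.simulate import _gene_lfc_profiles

        profiles = _gene_lfc_profiles(bundle.truth, bundle.config)
        by_tag = {}
        for loc in bundle.truth.planted_loci:
            for t in loc.tag_ids():
                by_tag[t] = loc
        for s, g, _ in bundle.truth.cleavage_links:
            assert np.allclose(profiles[g], -np.asarray(by_tag[s].lfc))

    def test_unlinked_gene_stationary(self, bundle):
        linked = set(bundle.truth.cluster_labels) | set(bundle.truth.decoy_de_genes)
        cfg = bundle.config
        table = bundle.gene_table.set_index("gene_id")
        unlinked = [g for g in table.index if g not in linked]
        means = table.loc[unlinked, COUNT_COLS].mean()
        # all four library means near the common baseline
        se = cfg.gene_baseline_mean / np.sqrt(len(unlinked))
        assert np.all(np.abs(means - cfg.gene_baseline_mean) < 4 * se)

    def test_unknown_gene_link_rejected(self, bundle):
        bad = GroundTruth(
            planted_loci=[], cleavage_links=[("t1", "nope", (0, 21))],
            methyl_links=[], cluster_labels={},
        )
        with pytest.raises(ValueError, match="unknown gene"):
            simulate_gene_expression(bundle.genes, bad, bundle.config)


class TestMethylation:
    def test_hyper_region_ratio(self, bundle):
        cfg = bundle.config
        signal = bundle.region_signal.set_index("region_id")
        hyper = [
            f"mr{i + 1:04d}"
            for i, (_, _, _, d) in enumerate(bundle.truth.methyl_links)
            if d == "hyper"
        ]
        sub = signal.loc[hyper]
        ratios = sub["count_I"] / sub["count_CK"]
        se = cfg.ratio_planted / np.sqrt(cfg.region_baseline_mean)
        assert np.all(np.abs(ratios - cfg.ratio_planted) < 3.5 * se + 1)

    def test_no_links_means_no_planted_signal(self):
        cfg = SimulationConfig(n_methyl_links=0, seed=9)
        b = simulate_all(cfg)
        counts = b.region_signal[COUNT_COLS].to_numpy(dtype=float)
        ck = counts[:, 0]
        stage_means = counts[:, 1:].mean(axis=1)
        # stationary: no region drifts beyond counting noise
        assert np.all(np.abs(stage_means - ck) < 6 * np.sqrt(np.maximum(ck, 1)))

    def test_regions_inside_gene_spans(self, bundle):
        genes = {g.gene_id: g for g in bundle.genes}
        for r in bundle.region_table.to_dict("records"):
            g = genes[r["gene_id"]]
            assert g.start <= r["start"] < r["end"] <= g.end
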