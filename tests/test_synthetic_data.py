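"""Planted-truth fixture generation: genomes, counts, network, bundle."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from budmine.comparative_genomics import REVERSE
from budmine.errors import ConfigurationError
from budmine.network_hubs import node_degrees
from budmine.synthetic_data import (
    DOWN,
    EARLY_ONLY,
    NULL,
    SHARED_UP,
    SPECIES_A,
    SPECIES_B,
    BlockSpec,
    HubSpec,
    PlantedTruth,
    SimulationConfig,
    read_bundle,
    simulate_annotations,
    simulate_counts,
    simulate_genomes,
    simulate_network,
    write_bundle,
)


def _one_block_config(orientation="forward"):
    return SimulationConfig(
        n_genes_per_species=60,
        n_chromosomes=1,
        frac_one_to_many=0.0,
        block_spec=(BlockSpec("chr1", "chr1", 5, 21, 10, orientation),),
        class_sizes={},
        hub_spec=HubSpec(n_hubs=1, hub_degree=5, background_edges=0),
        seed=3,
    )


class TestSimulateGenomes:
    def test_forced_one_to_one_map_and_single_block(self):
        config = _one_block_config()
        catalog_a, catalog_b, orthomap, truth = simulate_genomes(config)
        assert len(catalog_a) == len(catalog_b) == 60
        pairs = orthomap.pairs()
        assert len(pairs) == 60  # every gene paired 1:1
        assert len(orthomap.one_to_one_pairs()) == 60
        assert len(truth.blocks) == 1
        assert len(truth.blocks[0].anchors) == 10

    def test_reverse_block_ranks_decrease(self):
        config = _one_block_config(REVERSE)
        catalog_a, catalog_b, _, truth = simulate_genomes(config)
        ranks_b = [
            catalog_b.position(gene_b)[1] for _, gene_b in truth.blocks[0].anchors
        ]
        assert ranks_b == sorted(ranks_b, reverse=True)
        ranks_a = [
            catalog_a.position(gene_a)[1] for gene_a, _ in truth.blocks[0].anchors
        ]
        assert ranks_a == sorted(ranks_a)

    def test_same_seed_is_byte_identical(self, small_config, tmp_path):
        world = {}
        for name in ("one", "two"):
            catalog_a, catalog_b, orthomap, truth = simulate_genomes(small_config)
            counts_a, design_a = simulate_counts(catalog_a, small_config, truth)
            counts_b, design_b = simulate_counts(catalog_b, small_config, truth)
            network, truth = simulate_network(truth, small_config)
            out = tmp_path / name
            write_bundle(out, catalog_a, catalog_b, orthomap, truth,
                         counts_a, design_a, counts_b, design_b, network)
            world[name] = out
        for f in sorted(p.name for p in world["one"].iterdir()):
            assert (world["one"] / f).read_bytes() == (world["two"] / f).read_bytes()

    def test_overlapping_block_windows_rejected(self):
        config = SimulationConfig(
            n_genes_per_species=100,
            n_chromosomes=1,
            block_spec=(
                BlockSpec("chr1", "chr1", 5, 5, 10),
                BlockSpec("chr1", "chr1", 8, 40, 10),
            ),
            class_sizes={},
        )
        with pytest.raises(ConfigurationError, match="overlap"):
            simulate_genomes(config)

    def test_block_exceeding_chromosome_rejected(self):
        config = SimulationConfig(
            n_genes_per_species=30,
            n_chromosomes=1,
            block_spec=(BlockSpec("chr1", "chr1", 25, 1, 10),),
            class_sizes={},
        )
        with pytest.raises(ConfigurationError, match="exceeds"):
            simulate_genomes(config)

    def test_one_to_many_fraction_present(self, small_world):
        orthomap = small_world["orthomap"]
        sizes = [len(gb) for _, _, gb in orthomap.records]
        frac = sum(1 for s in sizes if s > 1) / len(sizes)
        assert 0.03 < frac < 0.25  # configured 0.1, binomial wiggle


class TestSimulateCounts:
    def test_poisson_mean_of_planted_early_genes(self):
        config = SimulationConfig(
            n_genes_per_species=2000,
            n_chromosomes=2,
            block_spec=(),
            class_sizes={EARLY_ONLY: 200},
            dispersion=0.0,
            effect_log2fc=2.0,
            baseline_mean=100.0,
            seed=21,
        )
        catalog_a, _, _, truth = simulate_genomes(config)
        counts, design = simulate_counts(catalog_a, config, truth)
        early = sorted(truth.genes_of_class(SPECIES_A, EARLY_ONLY))
        sample = design.sample_for("A340", "P")  # early-role, pre-flowering
        vals = counts.counts.loc[early, sample]
        se = np.sqrt(400 / len(early))
        assert abs(vals.mean() - 400) < 3 * se

    def test_null_genes_flat_between_stages(self):
        config = SimulationConfig(
            n_genes_per_species=3000,
            n_chromosomes=2,
            block_spec=(),
            class_sizes={},
            dispersion=0.0,
            seed=5,
        )
        catalog_a, _, _, truth = simulate_genomes(config)
        counts, design = simulate_counts(catalog_a, config, truth)
        s1 = design.sample_for("A340", "S1")
        p = design.sample_for("A340", "P")
        ratio = counts.counts[p].mean() / counts.counts[s1].mean()
        se = np.sqrt(2 / (100 * 3000))  # se of a ratio of Poisson means
        assert abs(ratio - 1) < 3 * se

    def test_library_size_scales_means(self):
        base = SimulationConfig(
            n_genes_per_species=2000, n_chromosomes=2, block_spec=(),
            class_sizes={}, dispersion=0.0, seed=13,
        )
        doubled = replace(base, library_size=2 * base.library_size)
        catalog, _, _, truth = simulate_genomes(base)
        c1, d1 = simulate_counts(catalog, base, truth)
        c2, _ = simulate_counts(catalog, doubled, truth)
        ratio = c2.counts.to_numpy().mean() / c1.counts.to_numpy().mean()
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_poisson_variance_to_mean(self):
        # with dispersion 0 counts are Poisson: var/mean near 1
        config = SimulationConfig(
            n_genes_per_species=200, n_chromosomes=1, block_spec=(),
            class_sizes={}, dispersion=0.0, baseline_mean=80.0, seed=2,
        )
        catalog, _, _, truth = simulate_genomes(config)
        counts, design = simulate_counts(catalog, config, truth)
        dormancy = [
            design.sample_for(g, "S1") for g, _ in config.genotypes
        ] + [design.sample_for(g, "S2") for g, _ in config.genotypes]
        mat = counts.counts[dormancy].to_numpy()
        ratio = mat.var(axis=1, ddof=1).mean() / mat.mean(axis=1).mean()
        assert 0.8 < ratio < 1.2

    def test_shared_up_rises_in_all_genotypes_early_only_in_early(self, small_world):
        config = small_world["config"]
        counts, design = small_world["counts_a"], small_world["design_a"]
        truth = small_world["truth"]
        shared = sorted(truth.genes_of_class(SPECIES_A, SHARED_UP))
        early_only = sorted(truth.genes_of_class(SPECIES_A, EARLY_ONLY))
        for genotype, role in config.genotypes:
            s1 = design.sample_for(genotype, "S1")
            p = design.sample_for(genotype, "P")
            fold_shared = (
                counts.counts.loc[shared, p].mean()
                / counts.counts.loc[shared, s1].mean()
            )
            assert fold_shared > 2.5
            fold_early = (
                counts.counts.loc[early_only, p].mean()
                / counts.counts.loc[early_only, s1].mean()
            )
            if role == "early":
                assert fold_early > 2.5
            else:
                assert 0.7 < fold_early < 1.4


class TestSimulateNetwork:
    def test_planted_hub_degrees_and_maximum(self, small_world):
        truth, net = small_world["truth"], small_world["network"]
        degrees = node_degrees(net)
        hub_degree = small_world["config"].hub_spec.hub_degree
        for hub in truth.hubs:
            assert degrees[hub] == hub_degree
        non_hub_max = max(
            (d for n, d in degrees.items() if n not in truth.hubs), default=0
        )
        assert non_hub_max < hub_degree

    def test_handshake_lemma(self, small_world):
        net = small_world["network"]
        assert sum(node_degrees(net).values()) == 2 * net.n_edges

    def test_background_zero_gives_exact_edge_count(self):
        config = SimulationConfig(
            n_genes_per_species=300, n_chromosomes=1, block_spec=(),
            class_sizes={EARLY_ONLY: 40},
            hub_spec=HubSpec(n_hubs=2, hub_degree=7, background_edges=0),
            seed=17,
        )
        _, _, _, truth = simulate_genomes(config)
        net, truth = simulate_network(truth, config)
        assert net.n_edges == 2 * 7  # hubs never adjacent, exact identity

    def test_capacity_validation(self):
        config = SimulationConfig(
            n_genes_per_species=100, n_chromosomes=1, block_spec=(),
            class_sizes={EARLY_ONLY: 10},
            hub_spec=HubSpec(n_hubs=1, hub_degree=5, background_edges=10_000),
            seed=1,
        )
        _, _, _, truth = simulate_genomes(config)
        with pytest.raises(ConfigurationError, match="capacity"):
            simulate_network(truth, config)

    def test_scores_within_string_range(self, small_world):
        frame = small_world["network"].to_frame()
        assert frame["combined_score"].between(400, 1000).all()


class TestTruthAndBundleRoundTrip:
    def test_truth_tsv_roundtrip(self, tmp_path, small_world):
        truth = small_world["truth"]
        path = tmp_path / "truth.tsv"
        truth.write_tsv(path)
        again = PlantedTruth.from_tsv(path)
        assert again.classes == {
            sp: dict(genes) for sp, genes in truth.classes.items()
        }
        assert again.orthologue_pairs == truth.orthologue_pairs
        assert again.blocks == truth.blocks
        assert again.hubs == truth.hubs

    def test_bundle_roundtrip(self, tmp_path, small_world):
        w = small_world
        out = tmp_path / "bundle"
        write_bundle(out, w["catalog_a"], w["catalog_b"], w["orthomap"], w["truth"],
                     w["counts_a"], w["design_a"], w["counts_b"], w["design_b"],
                     w["network"], w["domains"], w["terms"])
        back = read_bundle(out)
        pd.testing.assert_frame_equal(back["catalog_a"].frame, w["catalog_a"].frame)
        assert back["orthomap"].records == w["orthomap"].records
        pd.testing.assert_frame_equal(back["counts_a"].counts, w["counts_a"].counts)
        pd.testing.assert_frame_equal(
            back["counts_b"].counts, w["counts_b"].counts
        )
        assert (back["counts_a"].library_sizes == w["counts_a"].library_sizes).all()
        pd.testing.assert_frame_equal(back["design_a"].frame, w["design_a"].frame)
        assert back["truth"].blocks == w["truth"].blocks
        assert back["network"].to_frame().equals(w["network"].to_frame())
        pd.testing.assert_frame_equal(back["domains"], w["domains"])


def test_annotations_cover_early_genes(small_world):
    domains, terms = small_world["domains"], small_world["terms"]
    truth = small_world["truth"]
    early = truth.genes_of_class(SPECIES_A, EARLY_ONLY)
    genes_with_domains = set(domains["gene_id"])
    assert len(genes_with_domains & early) >= len(early) * 0.3
    assert set(terms.loc[terms["term_id"] == "T0001", "gene_id"]) <= early
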