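"""Orthologue parsing, tandem detection, collinearity chaining, projection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from budmine.comparative_genomics import (
    FORWARD,
    REVERSE,
    GeneCatalog,
    OrthologueMap,
    chain_collinear_blocks,
    detect_tandem,
    project_candidates,
    read_blocks,
    read_orthofinder_orthologues,
    write_blocks,
    write_orthofinder_orthologues,
)
from budmine.errors import ParseError, ValidationError
from budmine.mining import GeneSet
from budmine.synthetic_data import SPECIES_A, simulate_genomes

from oracles import chain_blocks_exhaustive


def _linear_catalog(species, n, chrom="chr1", prefix="g"):
    frame = pd.DataFrame(
        {
            "gene_id": [f"{prefix}{i}" for i in range(1, n + 1)],
            "chrom": chrom,
            "rank": range(1, n + 1),
            "length_bp": 1000,
        }
    )
    return GeneCatalog(species, frame)


class TestOrthologueTable:
    def test_dialect_parsing(self, tmp_path):
        path = tmp_path / "orth.tsv"
        path.write_text(
            "Orthogroup\tspA\tspB\n"
            "OG0000001\tg1\tG1, G2\n"
            "OG0000002\tg2\tG3\n"
        )
        omap = read_orthofinder_orthologues(path, "spA", "spB")
        assert len(omap) == 2
        assert omap.orthologues_of("g1") == ("G1", "G2")
        assert omap.one_to_one_pairs() == [("g2", "G3")]

    def test_empty_cell_rejected(self, tmp_path):
        path = tmp_path / "orth.tsv"
        path.write_text("Orthogroup\tA\tB\nOG1\t\tG1\n")
        with pytest.raises(ParseError, match="2"):
            read_orthofinder_orthologues(path)

    def test_wrong_column_count_names_line(self, tmp_path):
        path = tmp_path / "orth.tsv"
        path.write_text("Orthogroup\tA\tB\nOG1\tg1\tG1\tjunk\n")
        with pytest.raises(ParseError, match=":2"):
            read_orthofinder_orthologues(path)

    def test_duplicate_gene_across_orthogroups_rejected(self):
        with pytest.raises(ValidationError, match="g1"):
            OrthologueMap("A", "B", (("OG1", ("g1",), ("G1",)),
                                     ("OG2", ("g1",), ("G2",))))

    def test_roundtrip_of_simulated_map(self, tmp_path, small_world):
        omap = small_world["orthomap"]
        path = tmp_path / "orth.tsv"
        write_orthofinder_orthologues(omap, path)
        again = read_orthofinder_orthologues(path, omap.species_a, omap.species_b)
        assert again.records == omap.records


class TestDetectTandem:
    def test_same_chromosome_within_gap(self):
        cat = _linear_catalog("sp", 10)
        hits = detect_tandem([("g3", "g5")], cat, max_tandem_gap=5)
        assert len(hits) == 1
        assert hits[0].rank_distance == 2

    def test_cross_chromosome_excluded(self):
        frame = pd.DataFrame(
            {
                "gene_id": ["a1", "b1"],
                "chrom": ["chr1", "chr2"],
                "rank": [1, 1],
                "length_bp": 500,
            }
        )
        cat = GeneCatalog("sp", frame)
        assert detect_tandem([("a1", "b1")], cat) == []

    def test_matches_bruteforce_on_random_fixture(self):
        rng = np.random.default_rng(4)
        cat = _linear_catalog("sp", 50)
        genes = [f"g{i}" for i in range(1, 51)]
        pairs = [
            tuple(rng.choice(genes, 2, replace=False)) for _ in range(60)
        ]
        got = {
            (t.gene_a, t.gene_b) for t in detect_tandem(pairs, cat, max_tandem_gap=5)
        }
        expected = {
            (a, b)
            for a, b in pairs
            if 1 <= abs(int(a[1:]) - int(b[1:])) <= 5
        }
        assert got == expected

    def test_unknown_gene_is_keyed_error(self):
        cat = _linear_catalog("sp", 5)
        with pytest.raises(ValidationError, match="zz"):
            detect_tandem([("g1", "zz")], cat)


class TestChainCollinearBlocks:
    def test_perfect_diagonal(self):
        cat_a = _linear_catalog("A", 10, prefix="a")
        cat_b = _linear_catalog("B", 10, prefix="b")
        pairs = [(f"a{i}", f"b{i}") for i in range(1, 7)]
        blocks = chain_collinear_blocks(pairs, cat_a, cat_b)
        assert len(blocks) == 1
        assert blocks[0].orientation == FORWARD
        assert blocks[0].size == 6

    def test_perfect_antidiagonal(self):
        cat_a = _linear_catalog("A", 10, prefix="a")
        cat_b = _linear_catalog("B", 10, prefix="b")
        pairs = [(f"a{i}", f"b{7 - i}") for i in range(1, 7)]
        blocks = chain_collinear_blocks(pairs, cat_a, cat_b)
        assert len(blocks) == 1
        assert blocks[0].orientation == REVERSE
        assert blocks[0].size == 6

    def test_two_disjoint_constructed_blocks_returned_exactly(self):
        cat_a = _linear_catalog("A", 100, prefix="a")
        cat_b = _linear_catalog("B", 100, prefix="b")
        pairs = [(f"a{i}", f"b{i}") for i in range(1, 8)]
        pairs += [(f"a{i}", f"b{141 - i}") for i in range(60, 68)]
        blocks = chain_collinear_blocks(pairs, cat_a, cat_b)
        assert {(b.orientation, b.size) for b in blocks} == {
            (FORWARD, 7), (REVERSE, 8)
        }

    def test_min_size_validation(self):
        cat = _linear_catalog("A", 5)
        with pytest.raises(ValidationError):
            chain_collinear_blocks([], cat, cat, min_size=1)

    def test_anchor_partition_and_invariants(self, small_world):
        blocks = chain_collinear_blocks(
            small_world["orthomap"].pairs(),
            small_world["catalog_a"],
            small_world["catalog_b"],
        )
        seen = set()
        for block in blocks:
            block.validate(max_gap=25)
            for rank_pair in block.ranks:
                key = (block.chrom_a, block.chrom_b, rank_pair)
                assert key not in seen
                seen.add(key)

    def test_recovers_planted_blocks(self, small_world):
        truth = small_world["truth"]
        blocks = chain_collinear_blocks(
            small_world["orthomap"].pairs(),
            small_world["catalog_a"],
            small_world["catalog_b"],
        )
        found = {frozenset(b.anchors) for b in blocks}
        for planted in truth.blocks:
            if len(planted.anchors) >= 5:
                assert any(
                    frozenset(planted.anchors) <= anchors for anchors in found
                )

    @given(st.integers(0, 2**30))
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_points = int(rng.integers(2, 16))
        max_rank = 30
        points = set()
        while len(points) < n_points:
            points.add((int(rng.integers(1, max_rank + 1)),
                        int(rng.integers(1, max_rank + 1))))
        points = sorted(points)
        # deduplicate rank_a collisions: one gene per rank on each side
        cat_a = _linear_catalog("A", max_rank, prefix="a")
        cat_b = _linear_catalog("B", max_rank, prefix="b")
        pairs = [(f"a{ra}", f"b{rb}") for ra, rb in points]
        min_size, max_gap = 3, int(rng.integers(2, 10))
        blocks = chain_collinear_blocks(
            pairs, cat_a, cat_b, min_size=min_size, max_gap=max_gap
        )
        expected = chain_blocks_exhaustive(points, min_size, max_gap)
        got = [(b.orientation, list(b.ranks)) for b in blocks]
        assert got == [(orient, chain) for orient, chain in expected]

    def test_blocks_file_roundtrip(self, tmp_path):
        cat_a = _linear_catalog("A", 10, prefix="a")
        cat_b = _linear_catalog("B", 10, prefix="b")
        pairs = [(f"a{i}", f"b{i}") for i in range(1, 7)]
        blocks = chain_collinear_blocks(pairs, cat_a, cat_b)
        path = tmp_path / "blocks.txt"
        write_blocks(blocks, path)
        assert read_blocks(path) == blocks


class TestProjectCandidates:
    def _setup(self):
        omap = OrthologueMap(
            "A", "B",
            (
                ("OG1", ("a1",), ("b1",)),
                ("OG2", ("a2",), ("b2", "b3")),
            ),
        )
        cat_a = _linear_catalog("A", 5, prefix="a")
        cat_b = _linear_catalog("B", 5, prefix="b")
        pairs = [(f"a{i}", f"b{i}") for i in range(1, 6)]
        blocks = chain_collinear_blocks(pairs, cat_a, cat_b, min_size=2)
        return omap, blocks

    def test_enumerated_projection(self):
        omap, blocks = self._setup()
        candidates = GeneSet("cand", "A", frozenset({"a1", "a2", "a9"}),
                             (("test", "fixture"),))
        deg_b = pd.DataFrame(
            {"gene_id": ["b1", "b2"], "log2fc": [2.0, 2.0], "call": ["ns", "up"]}
        )
        report = project_candidates(candidates, omap, blocks, deg_b)
        frame = report.frame.set_index("gene_id")
        assert frame.loc["a9", "orthology_class"] == "none"
        assert not frame.loc["a9", "collinear"]
        assert frame.loc["a2", "orthology_class"] == "one-to-many"
        assert frame.loc["a2", "collinear"]  # (a2, b2) is a block anchor
        assert frame.loc["a2", "up_in_b"]
        assert frame.loc["a1", "orthology_class"] == "one-to-one"
        assert report.n_orthologues == 3
        assert report.n_collinear <= report.n_orthologues
        assert report.n_up <= report.n_orthologues

    def test_species_mismatch_detected(self):
        omap, blocks = self._setup()
        candidates = GeneSet("cand", "A", frozenset({"a1"}), (("t", "f"),))
        deg_wrong = pd.DataFrame(
            {"gene_id": ["a1"], "log2fc": [0.0], "call": ["ns"]}
        )
        with pytest.raises(ValidationError, match="mismatch"):
            project_candidates(candidates, omap, blocks, deg_wrong)

    def test_planted_block_genes_project_collinear(self, small_world):
        truth = small_world["truth"]
        blocks = chain_collinear_blocks(
            small_world["orthomap"].pairs(),
            small_world["catalog_a"],
            small_world["catalog_b"],
        )
        block_genes = {a for b in truth.blocks for a, _ in b.anchors if len(b.anchors) >= 5}
        outside = (
            set(small_world["catalog_a"].frame["gene_id"])
            - {a for b in truth.blocks for a, _ in b.anchors}
        )
        sample_outside = sorted(outside)[:20]
        gs = GeneSet("mixed", SPECIES_A,
                     frozenset(block_genes | set(sample_outside)), (("t", "f"),))
        report = project_candidates(gs, small_world["orthomap"], blocks)
        frame = report.frame.set_index("gene_id")
        assert frame.loc[sorted(block_genes), "collinear"].all()


class TestGFF3Catalog:
    def test_ranks_from_gff3(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t500\t1499\t.\t+\t.\tID=gB\n"
            "chr1\tsrc\tgene\t100\t399\t.\t+\t.\tID=gA\n"
            "chr2\tsrc\tgene\t10\t59\t.\t-\t.\tID=gC\n"
            "chr1\tsrc\tmRNA\t100\t399\t.\t+\t.\tID=t1;Parent=gA\n"
        )
        cat = GeneCatalog.from_gff3(gff, "sp")
        assert cat.position("gA") == ("chr1", 1)
        assert cat.position("gB") == ("chr1", 2)
        assert cat.position("gC") == ("chr2", 1)
        assert cat.length_bp("gA") == 300

    def test_malformed_line_reports_position(self, tmp_path):
        gff = tmp_path / "bad.gff3"
        gff.write_text("chr1\tsrc\tgene\t1\t10\n")
        with pytest.raises(ParseError, match=":1"):
            GeneCatalog.from_gff3(gff, "sp")
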