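"""Two-species synthetic fixtures with planted ground truth.

The generator emulates the study design the pipeline targets: two closely
related tree species, a mostly one-to-one orthologue map with constructed
collinear blocks, one expression library per genotype x bud stage (no
replicates — the design assumed by the conditional two-library test), and
planted gene classes driving the expected mining outcome:

* ``SHARED_UP``   — upregulated toward pre-flowering in every genotype;
* ``EARLY_ONLY``  — upregulated only in early-flowering genotypes (the
  planted candidate class the mining stage must recover);
* ``LATE_ONLY``   — upregulated only in late-flowering genotypes;
* ``DOWN``        — halved toward pre-flowering in every genotype;
* ``NULL``        — flat.

Planted log2 effects reach their full value at the final (pre-flowering)
stage and interpolate linearly on the log2 scale across intermediate
stages, reproducing gradual-rise expression patterns.  Counts are drawn
negative-binomially with variance m + alpha*m^2 (Poisson at alpha = 0).
A protein-interaction network over the planted early-only genes carries a
few high-degree hub nodes against a degree-capped random background.

All randomness flows from the single integer seed in the configuration
through explicit per-stage generators; no global state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .comparative_genomics import (
    FORWARD,
    REVERSE,
    CollinearBlock,
    GeneCatalog,
    OrthologueMap,
    write_orthofinder_orthologues,
    read_orthofinder_orthologues,
)
from .errors import ConfigurationError, ValidationError
from .expression import CountMatrix, SampleDesign
from .network_hubs import PPINetwork, write_edge_list, read_edge_list

__all__ = [
    "SHARED_UP",
    "EARLY_ONLY",
    "LATE_ONLY",
    "DOWN",
    "NULL",
    "SPECIES_A",
    "SPECIES_B",
    "REFERENCE_DEPTH",
    "BlockSpec",
    "HubSpec",
    "SimulationConfig",
    "PlantedTruth",
    "simulate_genomes",
    "simulate_counts",
    "simulate_network",
    "simulate_annotations",
    "write_bundle",
    "read_bundle",
]

SHARED_UP = "SHARED_UP"
EARLY_ONLY = "EARLY_ONLY"
LATE_ONLY = "LATE_ONLY"
DOWN = "DOWN"
NULL = "NULL"
CLASSES = (SHARED_UP, EARLY_ONLY, LATE_ONLY, DOWN, NULL)

SPECIES_A = "pper"  # late-blooming reference species (peach-like)
SPECIES_B = "pmum"  # early-blooming partner species (mei-like)

#: library size at which ``baseline_mean`` is the expected dormancy count;
#: per-sample means scale proportionally with the configured library size
REFERENCE_DEPTH = 5_000_000

# rng stream ids (mixed with the config seed via SeedSequence)
_STREAM_GENOMES = 1
_STREAM_COUNTS_A = 2
_STREAM_COUNTS_B = 3
_STREAM_NETWORK = 4
_STREAM_ANNOTATION = 5


@dataclass(frozen=True)
class BlockSpec:
    """A constructed collinear block: matching rank windows on a chromosome
    pair, reversed in species B for ``reverse`` orientation."""

    chrom_a: str
    chrom_b: str
    start_a: int
    start_b: int
    length: int
    orientation: str = FORWARD

    def __post_init__(self):
        if self.length < 1:
            raise ConfigurationError("block length must be >= 1")
        if self.start_a < 1 or self.start_b < 1:
            raise ConfigurationError("block start ranks are 1-based")
        if self.orientation not in (FORWARD, REVERSE):
            raise ConfigurationError(f"unknown orientation {self.orientation!r}")


@dataclass(frozen=True)
class HubSpec:
    n_hubs: int = 3
    hub_degree: int = 13
    background_edges: int = 150
    background_degree_cap: int = 5

    def __post_init__(self):
        if self.n_hubs < 0 or self.hub_degree < 1:
            raise ConfigurationError("hub_spec counts must be positive")
        if self.background_edges < 0 or self.background_degree_cap < 0:
            raise ConfigurationError("background settings must be non-negative")


def _default_blocks() -> tuple[BlockSpec, ...]:
    return (
        BlockSpec("chr1", "chr1", 101, 101, 40, FORWARD),
        BlockSpec("chr2", "chr2", 51, 51, 30, REVERSE),
        BlockSpec("chr3", "chr4", 201, 151, 25, FORWARD),
        BlockSpec("chr5", "chr5", 11, 31, 20, FORWARD),
    )


def _default_class_sizes() -> dict[str, int]:
    return {SHARED_UP: 200, EARLY_ONLY: 200, LATE_ONLY: 200, DOWN: 200}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for fixture generation.

    Defaults reproduce the design the pipeline is built for: two early- and
    two late-flowering genotypes of species A sampled over four dormancy
    stages plus a pre-flowering stage, one early-flowering cultivar of
    species B, 10,000 genes per species, planted log2 fold change 2, and
    mild negative-binomial overdispersion (alpha = 0.05).
    """

    n_genes_per_species: int = 10_000
    n_chromosomes: int = 8
    frac_one_to_many: float = 0.05
    block_spec: tuple[BlockSpec, ...] = field(default_factory=_default_blocks)
    class_sizes: Mapping[str, int] = field(default_factory=_default_class_sizes)
    effect_log2fc: float = 2.0
    baseline_mean: float = 100.0
    dispersion: float = 0.05
    library_size: int = REFERENCE_DEPTH
    genotypes: tuple[tuple[str, str], ...] = (
        ("A340", "early"),
        ("A209", "early"),
        ("A323", "late"),
        ("A318", "late"),
    )
    genotypes_b: tuple[tuple[str, str], ...] = (("ZaoLve", "early"),)
    stages: tuple[str, ...] = ("S1", "S2", "S3", "S4", "P")
    hub_spec: HubSpec = field(default_factory=HubSpec)
    seed: int = 0

    def __post_init__(self):
        if self.n_genes_per_species < 1 or self.n_chromosomes < 1:
            raise ConfigurationError("gene and chromosome counts must be positive")
        if not (0 <= self.frac_one_to_many <= 1):
            raise ConfigurationError("frac_one_to_many must lie in [0, 1]")
        if self.effect_log2fc <= 0:
            raise ConfigurationError("effect_log2fc must be positive")
        if self.baseline_mean <= 0:
            raise ConfigurationError("baseline_mean must be positive")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be non-negative")
        if self.library_size < 1:
            raise ConfigurationError("library_size must be positive")
        if len(self.stages) < 2:
            raise ConfigurationError("at least two stages are required")
        if len(set(self.stages)) != len(self.stages):
            raise ConfigurationError("stage labels must be unique")
        unknown = set(self.class_sizes) - set(CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown gene classes: {sorted(unknown)}")
        if any(v < 0 for v in self.class_sizes.values()):
            raise ConfigurationError("class sizes must be non-negative")
        if sum(self.class_sizes.values()) > self.n_genes_per_species:
            raise ConfigurationError("class sizes exceed the number of genes")
        for name, role in tuple(self.genotypes) + tuple(self.genotypes_b):
            if role not in ("early", "late"):
                raise ConfigurationError(f"genotype {name!r} has unknown role {role!r}")

    def chromosome_names(self) -> list[str]:
        return [f"chr{i}" for i in range(1, self.n_chromosomes + 1)]

    def chromosome_sizes(self) -> dict[str, int]:
        base, extra = divmod(self.n_genes_per_species, self.n_chromosomes)
        return {
            name: base + (1 if i < extra else 0)
            for i, name in enumerate(self.chromosome_names())
        }


@dataclass(frozen=True)
class BlockTruth:
    chrom_a: str
    chrom_b: str
    orientation: str
    anchors: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth planted by the generator: per-species gene classes,
    orthologue pairs, collinear blocks, and hub identities."""

    classes: Mapping[str, Mapping[str, str]]  # species -> gene -> class
    orthologue_pairs: tuple[tuple[str, str, str], ...]  # (gene_a, gene_b, orthogroup)
    blocks: tuple[BlockTruth, ...]
    hubs: tuple[str, ...]

    def genes_of_class(self, species: str, label: str) -> set[str]:
        return {
            g for g, c in self.classes.get(species, {}).items() if c == label
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for species in sorted(self.classes):
            for gene in sorted(self.classes[species]):
                rows.append(("class", species, gene, self.classes[species][gene], ""))
        for gene_a, gene_b, og in self.orthologue_pairs:
            rows.append(("orthopair", gene_a, gene_b, og, ""))
        for i, block in enumerate(self.blocks, start=1):
            for gene_a, gene_b in block.anchors:
                rows.append(
                    ("block", gene_a, gene_b,
                     f"{block.chrom_a}&{block.chrom_b}", f"{i}:{block.orientation}")
                )
        for hub in self.hubs:
            rows.append(("hub", hub, "", "", ""))
        return pd.DataFrame(rows, columns=["record", "f1", "f2", "f3", "f4"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PlantedTruth":
        frame = frame.fillna("")
        classes: dict[str, dict[str, str]] = {}
        pairs: list[tuple[str, str, str]] = []
        blocks: dict[int, tuple[str, str, str, list[tuple[str, str]]]] = {}
        hubs: list[str] = []
        for record, f1, f2, f3, f4 in frame.itertuples(index=False):
            if record == "class":
                classes.setdefault(f1, {})[f2] = f3
            elif record == "orthopair":
                pairs.append((f1, f2, f3))
            elif record == "block":
                idx_s, orientation = f4.split(":")
                chrom_a, chrom_b = f3.split("&")
                entry = blocks.setdefault(
                    int(idx_s), (chrom_a, chrom_b, orientation, [])
                )
                entry[3].append((f1, f2))
            elif record == "hub":
                hubs.append(f1)
            else:
                raise ValidationError(f"unknown truth record type {record!r}")
        block_objs = tuple(
            BlockTruth(ca, cb, orient, tuple(anchors))
            for _, (ca, cb, orient, anchors) in sorted(blocks.items())
        )
        return cls(
            {sp: dict(genes) for sp, genes in classes.items()},
            tuple(pairs),
            block_objs,
            tuple(hubs),
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PlantedTruth":
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        return cls.from_frame(frame)


# ---------------------------------------------------------------------------
# genomes, orthology, synteny
# ---------------------------------------------------------------------------

def _make_catalog(species: str, prefix: str, config: SimulationConfig,
                  rng: np.random.Generator) -> GeneCatalog:
    rows = []
    i = 0
    for ci, chrom in enumerate(config.chromosome_names(), start=1):
        n = config.chromosome_sizes()[chrom]
        for rank in range(1, n + 1):
            rows.append((f"{prefix}{ci:02d}G{rank:05d}", chrom, rank))
            i += 1
    frame = pd.DataFrame(rows, columns=["gene_id", "chrom", "rank"])
    frame["length_bp"] = rng.integers(300, 5001, size=len(frame))
    return GeneCatalog(species, frame)


def _validate_blocks(config: SimulationConfig) -> None:
    sizes = config.chromosome_sizes()
    windows: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for spec in config.block_spec:
        for side, chrom, start in (
            ("A", spec.chrom_a, spec.start_a),
            ("B", spec.chrom_b, spec.start_b),
        ):
            if chrom not in sizes:
                raise ConfigurationError(f"block chromosome {chrom!r} does not exist")
            end = start + spec.length - 1
            if end > sizes[chrom]:
                raise ConfigurationError(
                    f"block window {start}..{end} exceeds {chrom} "
                    f"length {sizes[chrom]} (species {side})"
                )
            for lo, hi in windows.get((side, chrom), []):
                if start <= hi and end >= lo:
                    raise ConfigurationError(
                        f"block windows overlap on species {side} {chrom}"
                    )
            windows.setdefault((side, chrom), []).append((start, end))


def simulate_genomes(
    config: SimulationConfig,
) -> tuple[GeneCatalog, GeneCatalog, OrthologueMap, PlantedTruth]:
    """Generate both gene catalogues, the orthologue map, and planted truth
    (classes, orthologue pairs, constructed collinear blocks)."""
    _validate_blocks(config)
    rng = np.random.default_rng([config.seed, _STREAM_GENOMES])
    catalog_a = _make_catalog(SPECIES_A, "Pp", config, rng)
    catalog_b = _make_catalog(SPECIES_B, "Pm", config, rng)

    by_pos_a = {
        (c, r): g
        for g, c, r in zip(
            catalog_a.frame["gene_id"], catalog_a.frame["chrom"], catalog_a.frame["rank"]
        )
    }
    by_pos_b = {
        (c, r): g
        for g, c, r in zip(
            catalog_b.frame["gene_id"], catalog_b.frame["chrom"], catalog_b.frame["rank"]
        )
    }

    records: list[tuple[str, tuple[str, ...], tuple[str, ...]]] = []
    truth_pairs: list[tuple[str, str, str]] = []
    block_truths: list[BlockTruth] = []
    used_a: set[str] = set()
    used_b: set[str] = set()
    og_counter = 1

    for spec in config.block_spec:
        anchors = []
        for i in range(spec.length):
            rank_a = spec.start_a + i
            rank_b = (
                spec.start_b + i
                if spec.orientation == FORWARD
                else spec.start_b + spec.length - 1 - i
            )
            gene_a = by_pos_a[(spec.chrom_a, rank_a)]
            gene_b = by_pos_b[(spec.chrom_b, rank_b)]
            if gene_a in used_a or gene_b in used_b:
                raise ConfigurationError("block windows reuse genes")
            used_a.add(gene_a)
            used_b.add(gene_b)
            og = f"OG{og_counter:07d}"
            og_counter += 1
            records.append((og, (gene_a,), (gene_b,)))
            truth_pairs.append((gene_a, gene_b, og))
            anchors.append((gene_a, gene_b))
        block_truths.append(
            BlockTruth(spec.chrom_a, spec.chrom_b, spec.orientation, tuple(anchors))
        )

    rest_a = [g for g in catalog_a.frame["gene_id"] if g not in used_a]
    rest_b = [g for g in catalog_b.frame["gene_id"] if g not in used_b]
    rest_a = list(rng.permutation(rest_a))
    rest_b = list(rng.permutation(rest_b))
    one_to_many = rng.random(len(rest_a)) < config.frac_one_to_many

    bi = 0
    for ai, gene_a in enumerate(rest_a):
        take = 2 if one_to_many[ai] else 1
        if bi + take > len(rest_b):
            break  # remaining genes stay unassigned (species-specific)
        genes_b = tuple(rest_b[bi : bi + take])
        bi += take
        og = f"OG{og_counter:07d}"
        og_counter += 1
        records.append((og, (gene_a,), genes_b))
        for gene_b in genes_b:
            truth_pairs.append((gene_a, gene_b, og))

    orthomap = OrthologueMap(SPECIES_A, SPECIES_B, tuple(records))

    # planted classes in species A; species-B genes inherit through orthology
    planted = [c for c in CLASSES if c != NULL and config.class_sizes.get(c, 0) > 0]
    n_planted = sum(config.class_sizes.get(c, 0) for c in planted)
    explicit_null = config.class_sizes.get(NULL, 0)
    chosen = rng.choice(
        catalog_a.frame["gene_id"].to_numpy(), size=n_planted, replace=False
    )
    classes_a = {g: NULL for g in catalog_a.frame["gene_id"]}
    offset = 0
    for label in planted:
        k = config.class_sizes.get(label, 0)
        for g in chosen[offset : offset + k]:
            classes_a[g] = label
        offset += k
    class_by_a = dict(classes_a)
    classes_b = {g: NULL for g in catalog_b.frame["gene_id"]}
    for gene_a, gene_b, _ in truth_pairs:
        classes_b[gene_b] = class_by_a[gene_a]

    truth = PlantedTruth(
        {SPECIES_A: classes_a, SPECIES_B: classes_b},
        tuple(truth_pairs),
        tuple(block_truths),
        hubs=(),
    )
    return catalog_a, catalog_b, orthomap, truth


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _class_effect(label: str, role: str, effect: float) -> float:
    """Planted log2 effect at the pre-flowering stage for a gene class under
    a genotype role."""
    if label == SHARED_UP:
        return effect
    if label == EARLY_ONLY:
        return effect if role == "early" else 0.0
    if label == LATE_ONLY:
        return effect if role == "late" else 0.0
    if label == DOWN:
        return -1.0  # halve toward pre-flowering
    return 0.0


def simulate_counts(
    catalog: GeneCatalog,
    config: SimulationConfig,
    truth: PlantedTruth,
) -> tuple[CountMatrix, SampleDesign]:
    """Draw one count library per (genotype, stage) for one species."""
    species = catalog.species
    if species == SPECIES_A:
        genotypes, stream = config.genotypes, _STREAM_COUNTS_A
    elif species == SPECIES_B:
        genotypes, stream = config.genotypes_b, _STREAM_COUNTS_B
    else:
        raise ValidationError(f"unknown simulated species {species!r}")
    classes = truth.classes.get(species)
    if classes is None:
        raise ValidationError(f"truth has no classes for species {species!r}")

    rng = np.random.default_rng([config.seed, stream])
    genes = list(catalog.frame["gene_id"])
    labels = np.array([classes[g] for g in genes])
    n_stages = len(config.stages)
    depth_factor = config.library_size / REFERENCE_DEPTH

    columns = {}
    design_rows = []
    for genotype, role in genotypes:
        full_effect = np.array(
            [_class_effect(l, role, config.effect_log2fc) for l in labels]
        )
        for order, stage in enumerate(config.stages, start=1):
            frac = (order - 1) / (n_stages - 1)
            mean = config.baseline_mean * np.exp2(full_effect * frac) * depth_factor
            if config.dispersion == 0:
                draw = rng.poisson(mean)
            else:
                n_param = 1.0 / config.dispersion
                p_param = 1.0 / (1.0 + config.dispersion * mean)
                draw = rng.negative_binomial(n_param, p_param)
            sample_id = f"{species}_{genotype}_{stage}"
            columns[sample_id] = draw
            design_rows.append(
                (sample_id, species, genotype, stage, order, role)
            )

    counts = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    library_sizes = pd.Series(config.library_size, index=counts.columns)
    design = SampleDesign(
        pd.DataFrame(
            design_rows,
            columns=["sample_id", "species", "genotype", "stage", "stage_order", "role"],
        )
    )
    return CountMatrix(counts, library_sizes), design


# ---------------------------------------------------------------------------
# interaction network
# ---------------------------------------------------------------------------

def simulate_network(
    truth: PlantedTruth, config: SimulationConfig
) -> tuple[PPINetwork, PlantedTruth]:
    """Build an undirected scored interaction network over the planted
    early-only genes with ``n_hubs`` planted hubs of exact degree
    ``hub_degree`` and a degree-capped random background.

    Returns the network and the truth updated with hub identities.
    """
    spec = config.hub_spec
    nodes = sorted(truth.genes_of_class(SPECIES_A, EARLY_ONLY))
    if len(nodes) < 2:
        raise ConfigurationError("network needs at least two early-only genes")
    if spec.hub_degree >= len(nodes):
        raise ConfigurationError("hub_degree must be smaller than the node count")
    if spec.n_hubs > len(nodes) - spec.hub_degree:
        raise ConfigurationError("too many hubs for the available nodes")

    rng = np.random.default_rng([config.seed, _STREAM_NETWORK])
    hubs = sorted(rng.choice(nodes, size=spec.n_hubs, replace=False).tolist())
    non_hubs = [n for n in nodes if n not in set(hubs)]

    edges: dict[tuple[str, str], int] = {}

    def add_edge(u: str, v: str) -> None:
        key = (u, v) if u < v else (v, u)
        edges[key] = int(rng.integers(400, 1001))

    for hub in hubs:
        neighbours = rng.choice(non_hubs, size=spec.hub_degree, replace=False)
        for v in neighbours:
            add_edge(hub, str(v))

    max_bg = len(non_hubs) * spec.background_degree_cap // 2
    capacity = min(max_bg, len(non_hubs) * (len(non_hubs) - 1) // 2)
    if spec.background_edges > capacity:
        raise ConfigurationError(
            f"background_edges={spec.background_edges} exceeds capacity {capacity}"
        )
    bg_degree = {n: 0 for n in non_hubs}
    added = 0
    attempts = 0
    max_attempts = 500 * max(1, spec.background_edges)
    while added < spec.background_edges:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigurationError(
                "could not place background edges under the degree cap"
            )
        u, v = rng.choice(non_hubs, size=2, replace=False)
        u, v = str(u), str(v)
        key = (u, v) if u < v else (v, u)
        if key in edges:
            continue
        if (
            bg_degree[u] >= spec.background_degree_cap
            or bg_degree[v] >= spec.background_degree_cap
        ):
            continue
        add_edge(u, v)
        bg_degree[u] += 1
        bg_degree[v] += 1
        added += 1

    frame = pd.DataFrame(
        [(u, v, s) for (u, v), s in sorted(edges.items())],
        columns=["node_a", "node_b", "combined_score"],
    )
    net = PPINetwork.from_frame(frame, min_score=0)
    return net, replace(truth, hubs=tuple(hubs))


# ---------------------------------------------------------------------------
# annotations (domains and terms) for the downstream stages
# ---------------------------------------------------------------------------

#: domain signatures assigned to planted regulator genes, keyed by family
_TF_SIGNATURES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("MADS-box", ("SRF-TF",)),
    ("AP2/ERF", ("AP2",)),
    ("RAV", ("AP2", "B3")),
    ("MYB", ("Myb_DNA-binding",)),
    ("WRKY", ("WRKY",)),
    ("bZIP", ("bZIP_1",)),
    ("HSF", ("HSF_DNA-bind",)),
    ("Dof", ("Zf-Dof",)),
)
_NON_TF_DOMAINS = ("PK_Tyr_Ser-Thr", "NB-ARC", "Ribosomal_L26", "GolS", "PEBP")


def simulate_annotations(
    catalog: GeneCatalog,
    truth: PlantedTruth,
    config: SimulationConfig,
    tf_fraction: float = 0.5,
    n_terms: int = 8,
    term_background: float = 0.02,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthesize gene -> domain and gene -> term annotation tables.

    About ``tf_fraction`` of the planted early-only genes receive a
    transcription-factor domain signature; other genes receive generic
    domains at random.  One functional term is enriched in the planted
    early-only class; the rest annotate random background genes.

    Returns ``(domains, terms)`` frames with columns (gene_id, domain) and
    (term_id, gene_id).
    """
    rng = np.random.default_rng([config.seed, _STREAM_ANNOTATION])
    genes = list(catalog.frame["gene_id"])
    early = sorted(truth.genes_of_class(catalog.species, EARLY_ONLY))

    domain_rows: list[tuple[str, str]] = []
    n_tf = int(round(tf_fraction * len(early)))
    tf_genes = rng.choice(early, size=n_tf, replace=False) if n_tf else []
    for gene in tf_genes:
        _, sig = _TF_SIGNATURES[int(rng.integers(len(_TF_SIGNATURES)))]
        for domain in sig:
            domain_rows.append((str(gene), domain))
    others = rng.choice(genes, size=max(1, len(genes) // 20), replace=False)
    for gene in others:
        domain_rows.append(
            (str(gene), _NON_TF_DOMAINS[int(rng.integers(len(_NON_TF_DOMAINS)))])
        )
    domains = (
        pd.DataFrame(sorted(set(domain_rows)), columns=["gene_id", "domain"])
    )

    term_rows: list[tuple[str, str]] = []
    enriched = rng.choice(early, size=max(1, len(early) // 2), replace=False)
    for gene in enriched:
        term_rows.append(("T0001", str(gene)))
    for t in range(2, n_terms + 1):
        members = rng.choice(
            genes, size=max(2, int(term_background * len(genes))), replace=False
        )
        for gene in members:
            term_rows.append((f"T{t:04d}", str(gene)))
    terms = pd.DataFrame(sorted(set(term_rows)), columns=["term_id", "gene_id"])
    return domains, terms


# ---------------------------------------------------------------------------
# fixture bundle I/O
# ---------------------------------------------------------------------------

def write_bundle(
    outdir,
    catalog_a: GeneCatalog,
    catalog_b: GeneCatalog,
    orthomap: OrthologueMap,
    truth: PlantedTruth,
    counts_a: CountMatrix,
    design_a: SampleDesign,
    counts_b: CountMatrix,
    design_b: SampleDesign,
    network: PPINetwork,
    domains: pd.DataFrame | None = None,
    terms: pd.DataFrame | None = None,
) -> None:
    """Write the fixture bundle directory of plain TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog_a.write_tsv(outdir / f"catalog_{catalog_a.species}.tsv")
    catalog_b.write_tsv(outdir / f"catalog_{catalog_b.species}.tsv")
    write_orthofinder_orthologues(orthomap, outdir / "orthologues.tsv")
    truth.write_tsv(outdir / "truth.tsv")
    counts_a.write_tsv(outdir / f"counts_{catalog_a.species}.tsv")
    counts_b.write_tsv(outdir / f"counts_{catalog_b.species}.tsv")
    design = pd.concat([design_a.frame, design_b.frame], ignore_index=True)
    design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    lib = pd.concat([counts_a.library_sizes, counts_b.library_sizes])
    lib.rename_axis("sample_id").rename("library_size").to_frame().to_csv(
        outdir / "library_sizes.tsv", sep="\t"
    )
    write_edge_list(network, outdir / "edges.tsv")
    if domains is not None:
        domains.to_csv(outdir / "domains.tsv", sep="\t", index=False)
    if terms is not None:
        terms.to_csv(outdir / "terms.tsv", sep="\t", index=False)


def read_bundle(indir) -> dict:
    """Re-read a fixture bundle; returns a dict of in-memory objects."""
    indir = Path(indir)
    catalog_a = GeneCatalog.from_tsv(indir / f"catalog_{SPECIES_A}.tsv", SPECIES_A)
    catalog_b = GeneCatalog.from_tsv(indir / f"catalog_{SPECIES_B}.tsv", SPECIES_B)
    orthomap = read_orthofinder_orthologues(
        indir / "orthologues.tsv", SPECIES_A, SPECIES_B
    )
    truth = PlantedTruth.from_tsv(indir / "truth.tsv")
    lib = pd.read_csv(indir / "library_sizes.tsv", sep="\t", index_col="sample_id")[
        "library_size"
    ]
    design_all = pd.read_csv(
        indir / "design.tsv", sep="\t",
        dtype={"sample_id": str, "species": str, "genotype": str, "stage": str,
               "role": str},
    )
    out = {
        "catalog_a": catalog_a,
        "catalog_b": catalog_b,
        "orthomap": orthomap,
        "truth": truth,
        "network": read_edge_list(indir / "edges.tsv", min_score=0),
    }
    for species, key in ((SPECIES_A, "a"), (SPECIES_B, "b")):
        counts = CountMatrix.from_tsv(indir / f"counts_{species}.tsv")
        counts = CountMatrix(counts.counts, lib.reindex(counts.counts.columns))
        out[f"counts_{key}"] = counts
        out[f"design_{key}"] = SampleDesign(
            design_all[design_all["species"] == species].reset_index(drop=True)
        )
    for name in ("domains", "terms"):
        path = indir / f"{name}.tsv"
        if path.exists():
            out[name] = pd.read_csv(path, sep="\t", dtype=str)
    return out
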