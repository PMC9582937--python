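"""Configuration-driven orchestration of the full mining analysis.

The end-to-end flow: simulate (or load) the two-species fixture ->
FPKM -> per-genotype DEG calling -> cross-genotype set mining ->
collinearity chaining and cross-species projection -> expression-pattern
clustering -> TF classification and term enrichment -> network hub
selection -> plain-text report plus a machine-readable run manifest with
per-output digests.  Any stage failure aborts the run with the failing
stage named; re-running with the same configuration and seed reproduces
identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .annotation_tf import (
    DEFAULT_FAMILY_RULES,
    classify_tf_families,
    hypergeometric_enrichment,
    summarize_tf_families,
)
from .comparative_genomics import chain_collinear_blocks, project_candidates, write_blocks
from .deg_stats import ContrastSpec, call_degs
from .errors import ConfigurationError, StageError, ValidationError
from .expression import compute_fpkm, cluster_patterns, zscore_rows
from .mining import (
    GeneSet,
    MiningDesign,
    early_specific_candidates,
    foldchange_correlation,
    membership_table,
    shared_upregulated,
)
from .network_hubs import extract_subnetwork, read_edge_list, select_hubs
from .synthetic_data import (
    EARLY_ONLY,
    SPECIES_A,
    SPECIES_B,
    SimulationConfig,
    simulate_annotations,
    simulate_counts,
    simulate_genomes,
    simulate_network,
    write_bundle,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "write_report"]

logger = logging.getLogger("budmine")


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and paths for a full pipeline run.

    ``simulation`` defines the synthetic study; thresholds feed the
    corresponding stages and are validated up front so a bad configuration
    fails before any output is written.
    """

    outdir: str = "budmine_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    alpha: float = 0.01
    min_log2fc: float = 1.0
    min_score: int = 400
    min_size: int = 5
    max_gap: int = 25
    max_tandem_gap: int = 5
    k_clusters: int = 5
    hub_rule: Mapping[str, int] = field(default_factory=lambda: {"top_k": 3})
    seed: int | None = None

    def __post_init__(self):
        if not (0 < self.alpha <= 1):
            raise ConfigurationError("alpha must lie in (0, 1]")
        if self.min_log2fc < 0:
            raise ConfigurationError("min_log2fc must be non-negative")
        if not (0 <= self.min_score <= 1000):
            raise ConfigurationError("min_score must lie in 0..1000")
        if self.min_size < 2:
            raise ConfigurationError("min_size must be >= 2")
        if self.max_gap < 1 or self.max_tandem_gap < 1:
            raise ConfigurationError("gap thresholds must be >= 1")
        if self.k_clusters < 1:
            raise ConfigurationError("k_clusters must be >= 1")
        if set(self.hub_rule.keys()) not in ({"min_degree"}, {"top_k"}):
            raise ConfigurationError("hub_rule must set min_degree or top_k")
        if self.seed is not None:
            object.__setattr__(
                self, "simulation", replace(self.simulation, seed=int(self.seed))
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        sim_doc = doc.pop("simulation", {})
        from .synthetic_data import BlockSpec, HubSpec

        if "block_spec" in sim_doc:
            sim_doc["block_spec"] = tuple(
                BlockSpec(**b) for b in sim_doc["block_spec"]
            )
        if "hub_spec" in sim_doc:
            sim_doc["hub_spec"] = HubSpec(**sim_doc["hub_spec"])
        if "genotypes" in sim_doc:
            sim_doc["genotypes"] = tuple(tuple(g) for g in sim_doc["genotypes"])
        if "genotypes_b" in sim_doc:
            sim_doc["genotypes_b"] = tuple(tuple(g) for g in sim_doc["genotypes_b"])
        if "stages" in sim_doc:
            sim_doc["stages"] = tuple(sim_doc["stages"])
        if "class_sizes" in sim_doc:
            sim_doc["class_sizes"] = dict(sim_doc["class_sizes"])
        try:
            simulation = SimulationConfig(**sim_doc)
            return cls(simulation=simulation, **doc)
        except TypeError as exc:
            raise ConfigurationError(f"bad config key: {exc}") from exc


@dataclass
class RunManifest:
    """Machine-readable record of one pipeline run."""

    config: dict
    seed: int
    version: str
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, outputs: Mapping[str, Path], counts: Mapping[str, int]):
        self.stages[stage] = {
            "outputs": {
                name: _sha256(path) for name, path in sorted(outputs.items())
            },
            "records": dict(sorted(counts.items())),
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "config": self.config,
                "stages": self.stages,
            },
            indent=2,
            sort_keys=True,
        )

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages in dependency order under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    manifest = RunManifest(
        config=_jsonable(asdict(config)), seed=sim.seed, version=__version__
    )

    def stage(name):
        logger.info("stage %s", name)
        return _StageTimer(name)

    try:
        with stage("simulate"):
            catalog_a, catalog_b, orthomap, truth = simulate_genomes(sim)
            counts_a, design_a = simulate_counts(catalog_a, sim, truth)
            counts_b, design_b = simulate_counts(catalog_b, sim, truth)
            network, truth = simulate_network(truth, sim)
            domains, terms = simulate_annotations(catalog_a, truth, sim)
            bundle = outdir / "bundle"
            write_bundle(
                bundle, catalog_a, catalog_b, orthomap, truth,
                counts_a, design_a, counts_b, design_b, network, domains, terms,
            )
            manifest.record(
                "simulate",
                {p.name: p for p in sorted(bundle.iterdir())},
                {
                    "genes_a": len(catalog_a),
                    "genes_b": len(catalog_b),
                    "orthogroups": len(orthomap),
                    "network_edges": network.n_edges,
                },
            )

        with stage("fpkm"):
            fpkm_a = compute_fpkm(counts_a, catalog_a)
            fpkm_b = compute_fpkm(counts_b, catalog_b)
            paths = {}
            for species, fpkm in ((SPECIES_A, fpkm_a), (SPECIES_B, fpkm_b)):
                p = outdir / f"fpkm_{species}.tsv"
                fpkm.write_tsv(p)
                paths[p.name] = p
            manifest.record(
                "fpkm", paths,
                {"genes_a": len(fpkm_a.values), "genes_b": len(fpkm_b.values)},
            )

        with stage("deg"):
            deg_tables: dict[str, pd.DataFrame] = {}
            paths = {}
            counts_map = {SPECIES_A: (counts_a, design_a), SPECIES_B: (counts_b, design_b)}
            genotype_lists = {
                SPECIES_A: sim.genotypes, SPECIES_B: sim.genotypes_b
            }
            record_counts = {}
            for species, genotypes in genotype_lists.items():
                counts, design = counts_map[species]
                for genotype, _role in genotypes:
                    stages_of = design.stages_of(genotype)
                    contrast = ContrastSpec(
                        genotype, stages_of[0], stages_of[-1],
                        alpha=config.alpha, min_log2fc=config.min_log2fc,
                    )
                    table = call_degs(counts, design, contrast)
                    deg_tables[genotype] = table
                    p = outdir / f"deg_{genotype}.tsv"
                    table.to_csv(p, sep="\t", index=False)
                    paths[p.name] = p
                    record_counts[f"up_{genotype}"] = int((table["call"] == "up").sum())
                    record_counts[f"down_{genotype}"] = int(
                        (table["call"] == "down").sum()
                    )
            manifest.record("deg", paths, record_counts)

        with stage("mine"):
            early = tuple(g for g, r in sim.genotypes if r == "early")
            late = tuple(g for g, r in sim.genotypes if r == "late")
            design_spec = MiningDesign(early=early, late=late)
            a_tables = {g: deg_tables[g] for g, _ in sim.genotypes}
            shared = shared_upregulated(
                {g: a_tables[g] for g in early}, species=SPECIES_A, label="shared_up"
            )
            candidates = early_specific_candidates(
                design_spec, a_tables, species=SPECIES_A, label="early_specific"
            )
            up_sets = [
                GeneSet(g, SPECIES_A,
                        frozenset(t.loc[t["call"] == "up", "gene_id"]))
                for g, t in sorted(a_tables.items())
            ]
            matrix, pattern_counts = membership_table(up_sets)
            r, slope, intercept, n_corr = foldchange_correlation(
                a_tables[early[0]], a_tables[early[1]]
            ) if len(early) >= 2 else (float("nan"),) * 3 + (0,)
            paths = {}
            for gs, fname in ((shared, "shared_up.tsv"), (candidates, "candidates.tsv")):
                p = outdir / fname
                gs.write_tsv(p)
                paths[p.name] = p
            p = outdir / "membership.tsv"
            matrix.astype(int).to_csv(p, sep="\t")
            paths[p.name] = p
            p = outdir / "correlation.tsv"
            pd.DataFrame(
                [{"pair": "early_pair", "r": r, "slope": slope,
                  "intercept": intercept, "n": n_corr}]
            ).to_csv(p, sep="\t", index=False)
            paths[p.name] = p
            manifest.record(
                "mine", paths,
                {"shared_up": len(shared), "candidates": len(candidates),
                 "patterns": len(pattern_counts)},
            )

        with stage("synteny"):
            blocks = chain_collinear_blocks(
                orthomap.pairs(), catalog_a, catalog_b,
                min_size=config.min_size, max_gap=config.max_gap,
            )
            p = outdir / "blocks.txt"
            write_blocks(blocks, p)
            manifest.record("synteny", {p.name: p}, {"blocks": len(blocks)})

        with stage("project"):
            genotype_b = sim.genotypes_b[0][0]
            projection = project_candidates(
                candidates, orthomap, blocks, deg_tables[genotype_b]
            )
            p = outdir / "projection.tsv"
            projection.write_tsv(p)
            manifest.record(
                "project", {p.name: p},
                {"candidates": projection.n_candidates,
                 "orthologues": projection.n_orthologues,
                 "collinear": projection.n_collinear,
                 "up_in_b": projection.n_up},
            )

        with stage("cluster"):
            cluster_genes = candidates.sorted_members()
            if len(cluster_genes) >= config.k_clusters and len(cluster_genes) >= 2:
                z = zscore_rows(
                    compute_fpkm(counts_a, catalog_a)
                )
                z_sub = type(z)(
                    z.values.loc[cluster_genes], z.unit, z.constant_genes
                )
                labels = cluster_patterns(z_sub, k=config.k_clusters)
            else:
                labels = pd.Series(
                    [1] * len(cluster_genes),
                    index=pd.Index(cluster_genes, name="gene_id"), name="cluster",
                )
            p = outdir / "clusters.tsv"
            labels.to_frame().to_csv(p, sep="\t")
            manifest.record(
                "cluster", {p.name: p},
                {"genes": len(labels),
                 "clusters": int(labels.nunique()) if len(labels) else 0},
            )

        with stage("tf"):
            domain_map: dict[str, set[str]] = {}
            for gene_id, domain in domains.itertuples(index=False):
                domain_map.setdefault(gene_id, set()).add(domain)
            candidate_domains = {
                g: d for g, d in domain_map.items() if g in candidates.members
            }
            records = classify_tf_families(candidate_domains, DEFAULT_FAMILY_RULES)
            summary = summarize_tf_families(records)
            p1 = outdir / "tf_records.tsv"
            pd.DataFrame(
                [
                    {"gene_id": r.gene_id, "family": r.family,
                     "evidence": ",".join(r.evidence_domains)}
                    for r in records
                ], columns=["gene_id", "family", "evidence"],
            ).to_csv(p1, sep="\t", index=False)
            p2 = outdir / "tf_summary.tsv"
            summary.to_csv(p2, sep="\t", index=False)
            manifest.record(
                "tf", {p1.name: p1, p2.name: p2},
                {"tf_records": len(records), "families": len(summary)},
            )

        with stage("enrich"):
            term_map: dict[str, set[str]] = {}
            for term_id, gene_id in terms.itertuples(index=False):
                term_map.setdefault(term_id, set()).add(gene_id)
            universe = set().union(*term_map.values()) if term_map else set()
            testable = candidates.members & universe
            enrichment = hypergeometric_enrichment(testable, universe, term_map)
            p = outdir / "enrichment.tsv"
            enrichment.to_csv(p, sep="\t", index=False)
            manifest.record("enrich", {p.name: p}, {"terms_tested": len(enrichment)})

        with stage("network"):
            net = read_edge_list(outdir / "bundle" / "edges.tsv",
                                 min_score=config.min_score)
            report = select_hubs(net, config.hub_rule)
            p = outdir / "hubs.tsv"
            report.to_frame().to_csv(p, sep="\t", index=False)
            paths = {p.name: p}
            sub_sizes = {}
            for hub in report.hubs:
                sub = extract_subnetwork(net, hub, radius=1)
                sp = outdir / f"subnetwork_{hub}.tsv"
                sub.to_frame().to_csv(sp, sep="\t", index=False)
                paths[sp.name] = sp
                sub_sizes[f"subnetwork_{hub}"] = sub.n_edges
            manifest.record(
                "network", paths,
                {"nodes": net.n_nodes, "edges": net.n_edges,
                 "hubs": len(report.hubs), **sub_sizes},
            )

        with stage("report"):
            report_text = write_report(
                manifest,
                {
                    "deg_tables": deg_tables,
                    "pattern_counts": pattern_counts,
                    "shared": shared,
                    "candidates": candidates,
                    "projection": projection,
                    "clusters": labels,
                    "tf_summary": summary,
                    "enrichment": enrichment,
                    "hub_report": report,
                },
            )
            p = outdir / "report.txt"
            p.write_text(report_text)
            manifest.record("report", {p.name: p}, {"lines": report_text.count("\n")})
    except ValidationError:
        raise
    except Exception as exc:
        current = getattr(_StageTimer, "active", None)
        raise StageError(current or "unknown", str(exc)) from exc

    manifest.write(outdir / "manifest.json")
    return manifest


class _StageTimer:
    active: str | None = None

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        _StageTimer.active = self.name
        self.start = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        elapsed = time.perf_counter() - self.start
        if exc_type is None:
            logger.info("stage %s done in %.2fs", self.name, elapsed)
        else:
            logger.error("stage %s failed after %.2fs", self.name, elapsed)
        _StageTimer.active = None
        return False


def write_report(manifest: RunManifest, outputs: Mapping[str, Any]) -> str:
    """Assemble the human-readable run report (pure function of its
    inputs; regenerating from the same outputs is byte-identical)."""
    for key in ("deg_tables", "shared", "candidates", "projection",
                "tf_summary", "enrichment", "hub_report"):
        if key not in outputs:
            raise ValidationError(f"report is missing stage output {key!r}")
    lines: list[str] = []
    lines.append("# Early-flowering gene mining report")
    lines.append(f"seed: {manifest.seed}")
    lines.append("")
    lines.append("## Differentially expressed genes per genotype")
    for genotype in sorted(outputs["deg_tables"]):
        table = outputs["deg_tables"][genotype]
        up = int((table["call"] == "up").sum())
        down = int((table["call"] == "down").sum())
        lines.append(f"  {genotype}: {up} up, {down} down, {len(table)} detected")
    lines.append("")
    lines.append("## Cross-genotype sets")
    lines.append(f"  shared upregulated: {len(outputs['shared'])}")
    lines.append(f"  early-specific candidates: {len(outputs['candidates'])}")
    if "pattern_counts" in outputs:
        lines.append("  membership patterns (flags in genotype order):")
        for pattern, count in sorted(outputs["pattern_counts"].items()):
            lines.append(f"    {pattern}: {count}")
    lines.append("")
    projection = outputs["projection"]
    lines.append("## Cross-species projection of candidates")
    lines.append(f"  candidates: {projection.n_candidates}")
    lines.append(f"  with orthologue: {projection.n_with_orthologue}")
    lines.append(f"  orthologues total: {projection.n_orthologues}")
    lines.append(f"  collinear: {projection.n_collinear}")
    lines.append(f"  upregulated in partner species: {projection.n_up}")
    lines.append("")
    if "clusters" in outputs:
        clusters = outputs["clusters"]
        lines.append("## Expression-pattern clusters (candidates)")
        if len(clusters):
            sizes = clusters.value_counts().sort_index()
            for label, size in sizes.items():
                lines.append(f"  cluster {label}: {size} genes")
        else:
            lines.append("  cluster sizes: 0 (no candidate genes)")
        lines.append("")
    lines.append("## Transcription-factor families among candidates")
    summary = outputs["tf_summary"]
    if len(summary):
        for _, row in summary.iterrows():
            lines.append(f"  {row['family']}: {row['count']} ({row['percent']}%)")
    else:
        lines.append("  none classified")
    lines.append("")
    lines.append("## Term enrichment (top 5 by adjusted p)")
    enrichment = outputs["enrichment"]
    if len(enrichment):
        for row in enrichment.head(5).itertuples(index=False):
            lines.append(
                f"  {row.term_id}: k={row.k}/{row.K}, p_adj={row.p_adj:.3g}"
            )
    else:
        lines.append("  no terms tested")
    lines.append("")
    lines.append("## Network hubs")
    hub_report = outputs["hub_report"]
    if hub_report.hubs:
        for hub in hub_report.hubs:
            lines.append(f"  {hub}: degree {hub_report.degrees[hub]}")
    else:
        lines.append("  none selected")
    lines.append("")
    return "\n".join(lines)
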