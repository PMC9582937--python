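"""Cross-species gene correspondence: orthologue tables, tandem duplicates,
collinear (syntenic) block chaining on gene order ranks, and projection of
candidate gene sets into the partner species.

Gene positions are abstracted to 1-based order ranks along chromosomes, the
representation used by rank-based synteny tools: a collinear block is a
maximal chain of homologous gene pairs whose ranks increase together
(forward) or run in opposite directions (reverse), with bounded rank gaps
between consecutive anchors on both sides.  Blocks are extracted greedily,
longest chain first, removing anchors after each extraction — a deliberate
simplification of full alignment-score chaining whose correctness criterion
is defined exactly (and checked against exhaustive enumeration in the test
suite).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ParseError, ValidationError
from .mining import GeneSet

__all__ = [
    "GeneCatalog",
    "OrthologueMap",
    "CollinearBlock",
    "TandemPair",
    "ProjectionReport",
    "read_orthofinder_orthologues",
    "write_orthofinder_orthologues",
    "detect_tandem",
    "chain_collinear_blocks",
    "write_blocks",
    "read_blocks",
    "project_candidates",
]

FORWARD = "forward"
REVERSE = "reverse"


# ---------------------------------------------------------------------------
# gene catalogues
# ---------------------------------------------------------------------------

@dataclass
class GeneCatalog:
    """Per-species gene coordinates as (chromosome, order rank, length).

    ``frame`` columns: gene_id, chrom, rank (1-based, contiguous per
    chromosome), length_bp (longest-transcript length).
    """

    species: str
    frame: pd.DataFrame

    def __post_init__(self):
        required = ["gene_id", "chrom", "rank", "length_bp"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"catalog missing columns: {missing}")
        self.frame = self.frame[required].reset_index(drop=True)
        if self.frame["gene_id"].duplicated().any():
            dups = self.frame.loc[self.frame["gene_id"].duplicated(), "gene_id"]
            raise ValidationError(f"duplicate gene ids in catalog: {sorted(set(dups))[:5]}")
        if (self.frame["length_bp"] <= 0).any():
            raise ValidationError("catalog contains non-positive transcript lengths")
        for chrom, sub in self.frame.groupby("chrom"):
            ranks = sorted(sub["rank"])
            if ranks != list(range(1, len(ranks) + 1)):
                raise ValidationError(
                    f"ranks on chromosome {chrom!r} are not contiguous 1..n"
                )
        self._pos = {
            g: (c, int(r))
            for g, c, r in zip(
                self.frame["gene_id"], self.frame["chrom"], self.frame["rank"]
            )
        }
        self._len = dict(zip(self.frame["gene_id"], self.frame["length_bp"].astype(int)))

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, gene: str) -> bool:
        return gene in self._pos

    def position(self, gene: str) -> tuple[str, int]:
        try:
            return self._pos[gene]
        except KeyError:
            raise ValidationError(
                f"gene {gene!r} absent from catalog of {self.species!r}"
            ) from None

    def length_bp(self, gene: str) -> int:
        try:
            return self._len[gene]
        except KeyError:
            raise ValidationError(
                f"gene {gene!r} absent from catalog of {self.species!r}"
            ) from None

    def lengths(self, genes: Sequence[str]) -> pd.Series:
        missing = [g for g in genes if g not in self._len]
        if missing:
            raise ValidationError(
                f"genes absent from catalog of {self.species!r}: {missing[:10]}"
            )
        return pd.Series([self._len[g] for g in genes], index=list(genes), name="length_bp")

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, species: str) -> "GeneCatalog":
        frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
        return cls(species, frame)

    @classmethod
    def from_gff3(cls, path, species: str, feature_type: str = "gene") -> "GeneCatalog":
        """Derive order ranks from a GFF3 file: genes on each sequence are
        ordered by start coordinate (1-based, inclusive), ties broken by
        gene id; length_bp is end − start + 1 of the gene feature.
        """
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 9:
                    raise ParseError(
                        f"GFF3 line has {len(parts)} columns, expected 9",
                        path=path, line=lineno,
                    )
                seqid, _, ftype, start, end, _, _, _, attrs = parts
                if ftype != feature_type:
                    continue
                m = re.search(r"(?:^|;)ID=([^;]+)", attrs)
                if not m:
                    raise ParseError("gene feature lacks an ID attribute",
                                     path=path, line=lineno)
                rows.append((m.group(1), seqid, int(start), int(end)))
        if not rows:
            raise ParseError(f"no {feature_type!r} features found", path=path)
        df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
        df["length_bp"] = df["end"] - df["start"] + 1
        df = df.sort_values(["chrom", "start", "gene_id"], kind="mergesort")
        df["rank"] = df.groupby("chrom").cumcount() + 1
        return cls(species, df[["gene_id", "chrom", "rank", "length_bp"]])


# ---------------------------------------------------------------------------
# orthologue tables
# ---------------------------------------------------------------------------

@dataclass
class OrthologueMap:
    """Orthogroup records between a species pair, preserving one-to-many
    structure: each record is (orthogroup id, genes in A, genes in B)."""

    species_a: str
    species_b: str
    records: tuple[tuple[str, tuple[str, ...], tuple[str, ...]], ...]

    def __post_init__(self):
        recs = []
        seen_a: dict[str, str] = {}
        seen_b: dict[str, str] = {}
        for og, genes_a, genes_b in self.records:
            genes_a, genes_b = tuple(genes_a), tuple(genes_b)
            if not genes_a or not genes_b:
                raise ValidationError(f"orthogroup {og} has an empty side")
            for g in genes_a:
                if g in seen_a:
                    raise ValidationError(
                        f"gene {g!r} appears in orthogroups {seen_a[g]} and {og}"
                    )
                seen_a[g] = og
            for g in genes_b:
                if g in seen_b:
                    raise ValidationError(
                        f"gene {g!r} appears in orthogroups {seen_b[g]} and {og}"
                    )
                seen_b[g] = og
            recs.append((og, genes_a, genes_b))
        self.records = tuple(recs)
        self._by_a: dict[str, tuple[str, ...]] = {}
        for og, genes_a, genes_b in self.records:
            for g in genes_a:
                self._by_a[g] = genes_b

    def __len__(self) -> int:
        return len(self.records)

    def orthologues_of(self, gene_a: str) -> tuple[str, ...]:
        """Species-B orthologues of a species-A gene (empty if unassigned)."""
        return self._by_a.get(gene_a, ())

    def pairs(self) -> list[tuple[str, str]]:
        """All (gene_a, gene_b) pairs expanded from orthogroups."""
        out = []
        for _, genes_a, genes_b in self.records:
            for a in genes_a:
                for b in genes_b:
                    out.append((a, b))
        return out

    def one_to_one_pairs(self) -> list[tuple[str, str]]:
        return [
            (ga[0], gb[0])
            for _, ga, gb in self.records
            if len(ga) == 1 and len(gb) == 1
        ]


def read_orthofinder_orthologues(
    path, species_a: str = "A", species_b: str = "B"
) -> OrthologueMap:
    """Parse the species-pair orthologue TSV dialect: a header line
    ``Orthogroup<TAB>SpeciesA<TAB>SpeciesB`` followed by rows whose gene
    cells are ", "-separated lists."""
    records = []
    with open(path) as fh:
        header = fh.readline()
        cols = header.rstrip("\n").split("\t")
        if len(cols) != 3:
            raise ParseError(
                f"orthologue header has {len(cols)} columns, expected 3",
                path=path, line=1,
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ParseError(
                    f"orthologue row has {len(parts)} columns, expected 3",
                    path=path, line=lineno,
                )
            og, cell_a, cell_b = parts
            genes_a = tuple(g for g in (s.strip() for s in cell_a.split(",")) if g)
            genes_b = tuple(g for g in (s.strip() for s in cell_b.split(",")) if g)
            if not genes_a or not genes_b:
                raise ParseError(
                    f"orthogroup {og} has an empty gene cell", path=path, line=lineno
                )
            records.append((og, genes_a, genes_b))
    return OrthologueMap(species_a, species_b, tuple(records))


def write_orthofinder_orthologues(orthomap: OrthologueMap, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"Orthogroup\t{orthomap.species_a}\t{orthomap.species_b}\n")
        for og, genes_a, genes_b in orthomap.records:
            fh.write(f"{og}\t{', '.join(genes_a)}\t{', '.join(genes_b)}\n")


# ---------------------------------------------------------------------------
# tandem duplicates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TandemPair:
    species: str
    gene_a: str
    gene_b: str
    chrom: str
    rank_distance: int


def detect_tandem(
    pairs: Iterable[tuple[str, str]],
    catalog: GeneCatalog,
    max_tandem_gap: int = 5,
) -> list[TandemPair]:
    """Within-species homolog pairs on the same chromosome whose rank
    distance is between 1 and ``max_tandem_gap`` (default 5), ordered by
    (chromosome, smaller rank)."""
    if max_tandem_gap < 1:
        raise ValidationError("max_tandem_gap must be >= 1")
    out = []
    for gene_a, gene_b in pairs:
        chrom_a, rank_a = catalog.position(gene_a)
        chrom_b, rank_b = catalog.position(gene_b)
        if chrom_a != chrom_b:
            continue
        dist = abs(rank_a - rank_b)
        if 1 <= dist <= max_tandem_gap:
            out.append(
                TandemPair(catalog.species, gene_a, gene_b, chrom_a, dist)
            )
    out.sort(key=lambda t: (t.chrom, min(catalog.position(t.gene_a)[1],
                                         catalog.position(t.gene_b)[1])))
    return out


# ---------------------------------------------------------------------------
# collinear block chaining
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    orientation: str  # forward | reverse
    anchors: tuple[tuple[str, str], ...]      # (gene_a, gene_b) in chain order
    ranks: tuple[tuple[int, int], ...]        # matching (rank_a, rank_b)

    @property
    def size(self) -> int:
        return len(self.anchors)

    def validate(self, max_gap: int) -> None:
        """Re-check monotonicity and gap invariants post hoc."""
        ra = [r[0] for r in self.ranks]
        rb = [r[1] for r in self.ranks]
        if any(b <= a for a, b in zip(ra, ra[1:])):
            raise ValidationError("block ranks not strictly increasing in species A")
        if self.orientation == FORWARD:
            if any(b <= a for a, b in zip(rb, rb[1:])):
                raise ValidationError("forward block not increasing in species B")
        elif self.orientation == REVERSE:
            if any(b >= a for a, b in zip(rb, rb[1:])):
                raise ValidationError("reverse block not decreasing in species B")
        else:
            raise ValidationError(f"unknown orientation {self.orientation!r}")
        gaps_a = [b - a for a, b in zip(ra, ra[1:])]
        gaps_b = [abs(b - a) for a, b in zip(rb, rb[1:])]
        if any(g > max_gap for g in gaps_a + gaps_b):
            raise ValidationError("block anchor gap exceeds max_gap")


def _longest_chain(
    anchors: list[tuple[int, int, str, str]],
    orientation: str,
    max_gap: int,
) -> list[int] | None:
    """Longest valid chain (as indices into ``anchors``) for one orientation;
    among equal-length chains the one with the lexicographically smallest
    (rank_a, rank_b) anchor sequence.  Returns None when no chain of length
    >= 2 exists (singletons are never useful blocks)."""
    n = len(anchors)
    if n == 0:
        return None
    order = sorted(range(n), key=lambda i: (anchors[i][0], anchors[i][1]))
    sign = 1 if orientation == FORWARD else -1

    def links(i: int, j: int) -> bool:
        ra_i, rb_i = anchors[i][0], anchors[i][1]
        ra_j, rb_j = anchors[j][0], anchors[j][1]
        if ra_j <= ra_i or ra_j - ra_i > max_gap:
            return False
        db = sign * (rb_j - rb_i)
        return 0 < db and abs(rb_j - rb_i) <= max_gap

    # longest chain starting at each anchor, processed in descending rank_a
    best_from = [1] * n
    for i in sorted(range(n), key=lambda i: -anchors[i][0]):
        for j in range(n):
            if links(i, j) and best_from[j] + 1 > best_from[i]:
                best_from[i] = best_from[j] + 1
    max_len = max(best_from)
    if max_len < 2:
        return None

    # lexicographically smallest reconstruction among maximal chains
    chain = []
    candidates = [i for i in order if best_from[i] == max_len]
    current = candidates[0]
    chain.append(current)
    remaining = max_len - 1
    while remaining > 0:
        nexts = [
            j for j in order
            if links(current, j) and best_from[j] == remaining
        ]
        current = nexts[0]
        chain.append(current)
        remaining -= 1
    return chain


def chain_collinear_blocks(
    pairs: Iterable[tuple[str, str]],
    catalog_a: GeneCatalog,
    catalog_b: GeneCatalog,
    min_size: int = 5,
    max_gap: int = 25,
) -> list[CollinearBlock]:
    """Chain cross-species homolog pairs into collinear blocks.

    Per chromosome pair, match points (rank_a, rank_b) are chained by
    dynamic programming into the longest forward and reverse runs with
    per-step gaps <= ``max_gap``; the globally longest chain is extracted,
    its anchors removed, and the process repeats while chains of at least
    ``min_size`` remain.  Ties are broken by smaller start rank_a, then
    start rank_b, then forward before reverse.
    """
    if min_size < 2:
        raise ValidationError("min_size must be >= 2")
    if max_gap < 1:
        raise ValidationError("max_gap must be >= 1")

    by_chrom_pair: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    seen = set()
    for gene_a, gene_b in pairs:
        chrom_a, rank_a = catalog_a.position(gene_a)
        chrom_b, rank_b = catalog_b.position(gene_b)
        key = (chrom_a, chrom_b, rank_a, rank_b)
        if key in seen:
            continue
        seen.add(key)
        by_chrom_pair.setdefault((chrom_a, chrom_b), []).append(
            (rank_a, rank_b, gene_a, gene_b)
        )

    blocks: list[CollinearBlock] = []
    for (chrom_a, chrom_b) in sorted(by_chrom_pair):
        anchors = by_chrom_pair[(chrom_a, chrom_b)]
        while True:
            best = None  # (-(len), start_ra, start_rb, orient_rank, chain, orientation)
            for orient_rank, orientation in enumerate((FORWARD, REVERSE)):
                chain = _longest_chain(anchors, orientation, max_gap)
                if chain is None or len(chain) < min_size:
                    continue
                start = anchors[chain[0]]
                key = (-len(chain), start[0], start[1], orient_rank)
                if best is None or key < best[0]:
                    best = (key, chain, orientation)
            if best is None:
                break
            _, chain, orientation = best
            chosen = [anchors[i] for i in chain]
            blocks.append(
                CollinearBlock(
                    chrom_a,
                    chrom_b,
                    orientation,
                    tuple((a[2], a[3]) for a in chosen),
                    tuple((a[0], a[1]) for a in chosen),
                )
            )
            used = set(chain)
            anchors = [a for i, a in enumerate(anchors) if i not in used]
    for block in blocks:
        block.validate(max_gap)
    return blocks


def write_blocks(blocks: Sequence[CollinearBlock], path) -> None:
    """Write blocks in a plain-text format: a ``## block`` header per block
    followed by tab-separated anchor gene pairs."""
    with open(path, "w") as fh:
        for i, block in enumerate(blocks, start=1):
            fh.write(
                f"## block {i}: {block.chrom_a}&{block.chrom_b} "
                f"{block.orientation} {block.size}\n"
            )
            for (gene_a, gene_b), (rank_a, rank_b) in zip(block.anchors, block.ranks):
                fh.write(f"{gene_a}\t{gene_b}\t{rank_a}\t{rank_b}\n")


def read_blocks(path) -> list[CollinearBlock]:
    blocks: list[CollinearBlock] = []
    header_re = re.compile(
        r"^## block \d+: (\S+)&(\S+) (forward|reverse) (\d+)$"
    )
    current = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                m = header_re.match(line)
                if not m:
                    raise ParseError("malformed block header", path=path, line=lineno)
                if current is not None:
                    blocks.append(_finish_block(current))
                current = (m.group(1), m.group(2), m.group(3), [])
            else:
                if current is None:
                    raise ParseError("anchor line before any block header",
                                     path=path, line=lineno)
                parts = line.split("\t")
                if len(parts) != 4:
                    raise ParseError("anchor line must have 4 columns",
                                     path=path, line=lineno)
                current[3].append((parts[0], parts[1], int(parts[2]), int(parts[3])))
    if current is not None:
        blocks.append(_finish_block(current))
    return blocks


def _finish_block(current) -> CollinearBlock:
    chrom_a, chrom_b, orientation, rows = current
    return CollinearBlock(
        chrom_a,
        chrom_b,
        orientation,
        tuple((r[0], r[1]) for r in rows),
        tuple((r[2], r[3]) for r in rows),
    )


# ---------------------------------------------------------------------------
# candidate projection
# ---------------------------------------------------------------------------

@dataclass
class ProjectionReport:
    """Per-candidate orthology/collinearity/regulation status in species B.

    ``frame`` columns: gene_id, orthology_class (one-to-one | one-to-many |
    none), orthologues (comma-joined), collinear (bool), up_in_b (bool).
    """

    frame: pd.DataFrame
    n_candidates: int
    n_with_orthologue: int
    n_orthologues: int
    n_collinear: int
    n_up: int

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def project_candidates(
    candidates: GeneSet,
    orthomap: OrthologueMap,
    blocks: Sequence[CollinearBlock],
    deg_table_b: pd.DataFrame | None = None,
) -> ProjectionReport:
    """Project a species-A candidate gene set into species B.

    Per candidate: its orthologue list and class, whether some block anchor
    joins the candidate to one of its orthologues, and whether any
    orthologue was called upregulated in the species-B contrast.
    """
    up_b: set[str] = set()
    if deg_table_b is not None:
        overlap = set(deg_table_b["gene_id"]) & candidates.members
        if overlap:
            raise ValidationError(
                "species-B DEG table contains candidate (species-A) gene ids — "
                f"species mismatch? e.g. {sorted(overlap)[:5]}"
            )
        up_b = set(deg_table_b.loc[deg_table_b["call"] == "up", "gene_id"])

    anchor_pairs = {pair for block in blocks for pair in block.anchors}
    rows = []
    n_orth_total = 0
    for gene in candidates.sorted_members():
        orthologues = orthomap.orthologues_of(gene)
        if len(orthologues) == 0:
            klass = "none"
        elif len(orthologues) == 1:
            klass = "one-to-one"
        else:
            klass = "one-to-many"
        collinear = any((gene, o) in anchor_pairs for o in orthologues)
        up = any(o in up_b for o in orthologues)
        n_orth_total += len(orthologues)
        rows.append(
            {
                "gene_id": gene,
                "orthology_class": klass,
                "orthologues": ",".join(orthologues),
                "collinear": collinear,
                "up_in_b": up,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["gene_id", "orthology_class", "orthologues", "collinear", "up_in_b"],
    )
    with_orth = int((frame["orthology_class"] != "none").sum()) if len(frame) else 0
    return ProjectionReport(
        frame=frame,
        n_candidates=len(candidates),
        n_with_orthologue=with_orth,
        n_orthologues=n_orth_total,
        n_collinear=int(frame["collinear"].sum()) if len(frame) else 0,
        n_up=int(frame["up_in_b"].sum()) if len(frame) else 0,
    )
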