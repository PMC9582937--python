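"""Count-matrix containers, FPKM conversion, per-gene standardization and
expression-pattern clustering.

FPKM(g, s) = counts(g, s) * 1e9 / (length_bp(g) * library_size(s)), with the
gene length taken as the longest-transcript length recorded in the gene
catalogue.  Library sizes default to column totals of the count matrix but
can be supplied explicitly (e.g. total mapped fragments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .comparative_genomics import GeneCatalog
from .errors import ValidationError

__all__ = [
    "CountMatrix",
    "SampleDesign",
    "ExpressionMatrix",
    "compute_fpkm",
    "zscore_rows",
    "cluster_patterns",
]

ROLE_EARLY = "early"
ROLE_LATE = "late"


@dataclass
class CountMatrix:
    """Non-negative integer gene x sample read counts with per-sample
    library sizes (defaulting to column sums)."""

    counts: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            raise ValidationError("duplicate gene ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in count matrix")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(np.int64)
        else:
            self.library_sizes = pd.Series(self.library_sizes).reindex(
                self.counts.columns
            )
            if self.library_sizes.isna().any():
                missing = list(
                    self.counts.columns[self.library_sizes.isna()]
                )
                raise ValidationError(f"library sizes missing for samples: {missing}")
            self.library_sizes = self.library_sizes.astype(np.int64)
        if (self.library_sizes <= 0).any():
            raise ValidationError("library sizes must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def write_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, library_sizes=None) -> "CountMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(frame, library_sizes)


@dataclass
class SampleDesign:
    """Sample metadata: species, genotype, ordered stage, and the
    genotype's flowering role (early vs late).

    Within each species, (genotype, stage) is unique and each genotype has a
    single maximal stage_order — its pre-flowering sample.
    """

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "species", "genotype", "stage", "stage_order", "role")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"design missing columns: {missing}")
        self.frame = self.frame[list(self.REQUIRED)].reset_index(drop=True)
        if self.frame["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids in design")
        bad_roles = set(self.frame["role"]) - {ROLE_EARLY, ROLE_LATE}
        if bad_roles:
            raise ValidationError(f"unknown roles in design: {sorted(bad_roles)}")
        for species, sub in self.frame.groupby("species"):
            if sub.duplicated(["genotype", "stage"]).any():
                raise ValidationError(
                    f"duplicate (genotype, stage) pairs within species {species!r}"
                )
            for genotype, gsub in sub.groupby("genotype"):
                orders = gsub["stage_order"]
                if (orders == orders.max()).sum() != 1:
                    raise ValidationError(
                        f"genotype {genotype!r} must have exactly one maximal "
                        "stage_order (the pre-flowering sample)"
                    )

    def sample_for(self, genotype: str, stage: str) -> str:
        sub = self.frame[
            (self.frame["genotype"] == genotype) & (self.frame["stage"] == stage)
        ]
        if len(sub) != 1:
            raise ValidationError(
                f"no unique sample for genotype {genotype!r}, stage {stage!r}"
            )
        return str(sub["sample_id"].iloc[0])

    def genotypes(self, species: str | None = None) -> list[str]:
        frame = self.frame
        if species is not None:
            frame = frame[frame["species"] == species]
        return list(dict.fromkeys(frame["genotype"]))

    def stages_of(self, genotype: str) -> list[str]:
        sub = self.frame[self.frame["genotype"] == genotype]
        sub = sub.sort_values("stage_order")
        return list(sub["stage"])

    def role_of(self, genotype: str) -> str:
        roles = set(self.frame.loc[self.frame["genotype"] == genotype, "role"])
        if len(roles) != 1:
            raise ValidationError(f"genotype {genotype!r} has inconsistent roles")
        return roles.pop()

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SampleDesign":
        frame = pd.read_csv(
            path, sep="\t",
            dtype={"sample_id": str, "species": str, "genotype": str, "stage": str,
                   "role": str},
        )
        return cls(frame)


@dataclass
class ExpressionMatrix:
    """Real-valued gene x sample matrix tagged with its unit (fpkm or
    zscore); rows that were constant before z-scoring are flagged."""

    values: pd.DataFrame
    unit: str
    constant_genes: frozenset[str] = frozenset()

    UNITS = ("fpkm", "zscore")

    def __post_init__(self):
        if self.unit not in self.UNITS:
            raise ValidationError(f"unknown expression unit {self.unit!r}")
        if self.unit == "fpkm" and (self.values.to_numpy() < 0).any():
            raise ValidationError("FPKM values must be non-negative")
        self.constant_genes = frozenset(self.constant_genes)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# unit: {self.unit}\n")
            out = self.values.copy()
            out.index.name = "gene_id"
            out.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        with open(path) as fh:
            first = fh.readline().strip()
            unit = "fpkm"
            if first.startswith("# unit:"):
                unit = first.split(":", 1)[1].strip()
                frame = pd.read_csv(fh, sep="\t", index_col="gene_id")
            else:
                fh.seek(0)
                frame = pd.read_csv(fh, sep="\t", index_col="gene_id")
        return cls(frame, unit)


def compute_fpkm(counts: CountMatrix, catalog: GeneCatalog) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped fragments."""
    lengths = catalog.lengths(counts.gene_ids)
    mat = counts.counts.to_numpy(dtype=float)
    denom = lengths.to_numpy(dtype=float)[:, None] * counts.library_sizes.to_numpy(
        dtype=float
    )[None, :]
    fpkm = mat * 1e9 / denom
    frame = pd.DataFrame(fpkm, index=counts.counts.index, columns=counts.counts.columns)
    return ExpressionMatrix(frame, "fpkm")


def zscore_rows(
    expr: ExpressionMatrix, sample_subset: Sequence[str] | None = None
) -> ExpressionMatrix:
    """Standardize each gene over the given samples (mean 0, unit sample
    variance, ddof=1); constant rows map to all zeros and are flagged."""
    if sample_subset is None:
        sample_subset = list(expr.values.columns)
    sample_subset = list(sample_subset)
    if len(sample_subset) == 0:
        raise ValidationError("sample subset must be non-empty")
    unknown = [s for s in sample_subset if s not in expr.values.columns]
    if unknown:
        raise ValidationError(f"unknown sample ids: {unknown}")
    sub = expr.values[sample_subset]
    mat = sub.to_numpy(dtype=float)
    means = mat.mean(axis=1, keepdims=True)
    sds = mat.std(axis=1, ddof=1, keepdims=True) if mat.shape[1] > 1 else np.zeros_like(means)
    constant = (sds[:, 0] == 0) | ~np.isfinite(sds[:, 0])
    safe_sds = np.where(sds == 0, 1.0, sds)
    z = (mat - means) / safe_sds
    z[constant, :] = 0.0
    frame = pd.DataFrame(z, index=sub.index, columns=sub.columns)
    flagged = frozenset(np.asarray(sub.index)[constant])
    return ExpressionMatrix(frame, "zscore", flagged)


def cluster_patterns(expr: ExpressionMatrix, k: int = 5) -> pd.Series:
    """Agglomerative (Ward, Euclidean) clustering of gene expression
    patterns cut at ``k`` clusters.

    Returns a gene -> cluster-label Series with labels renumbered 1..k by
    descending cluster size; ties broken by the smallest member gene id.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    n = len(expr.values)
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of genes ({n})")
    genes = list(expr.values.index)
    if k == n:
        raw = np.arange(1, n + 1)
    else:
        linkage = hierarchy.linkage(
            expr.values.to_numpy(dtype=float), method="ward", metric="euclidean"
        )
        raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    # renumber deterministically: by size desc, tie by smallest gene id
    order = {}
    groups: dict[int, list[str]] = {}
    for gene, label in zip(genes, raw):
        groups.setdefault(int(label), []).append(gene)
    ranked = sorted(
        groups.items(), key=lambda item: (-len(item[1]), min(item[1]))
    )
    for new_label, (old_label, _) in enumerate(ranked, start=1):
        order[old_label] = new_label
    return pd.Series(
        [order[int(l)] for l in raw], index=pd.Index(genes, name="gene_id"),
        name="cluster",
    )
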