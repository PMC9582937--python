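"""Cross-genotype set logic for candidate gene mining.

Early- and late-flowering genotypes are contrasted between a dormancy
reference stage and the pre-flowering stage.  Candidate early-flowering
regulators are the genes upregulated in *every* early-flowering genotype
while *not* upregulated in any late-flowering genotype, where
"not upregulated" means the gene was detected in that genotype's contrast
but called down or non-significant, or was not detected at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "GeneSet",
    "MiningDesign",
    "shared_upregulated",
    "early_specific_candidates",
    "membership_table",
    "foldchange_correlation",
]


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of gene identifiers with derivation provenance."""

    label: str
    species: str
    members: frozenset[str]
    provenance: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def sorted_members(self) -> list[str]:
        return sorted(self.members)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"set_label": self.label, "gene_id": self.sorted_members()}
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class MiningDesign:
    """Which genotypes count as early vs late flowering, and the matched
    stage contrast used for each genotype.

    ``contrasts`` maps genotype name to ``(reference_stage, test_stage)``;
    matching of "same chilling requirement" stages across genotypes is
    metadata supplied by the analyst, not inferred.
    """

    early: tuple[str, ...]
    late: tuple[str, ...] = ()
    contrasts: Mapping[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "early", tuple(self.early))
        object.__setattr__(self, "late", tuple(self.late))
        if not self.early:
            raise ValidationError("at least one early-flowering genotype is required")
        overlap = set(self.early) & set(self.late)
        if overlap:
            raise ValidationError(
                f"genotypes cannot be both early and late: {sorted(overlap)}"
            )

    @property
    def genotypes(self) -> tuple[str, ...]:
        return self.early + self.late


def _up_set(deg_table: pd.DataFrame) -> set[str]:
    return set(deg_table.loc[deg_table["call"] == "up", "gene_id"])


def _detected_set(deg_table: pd.DataFrame) -> set[str]:
    return set(deg_table["gene_id"])


def shared_upregulated(
    deg_tables: Mapping[str, pd.DataFrame],
    species: str = "",
    label: str = "shared_up",
) -> GeneSet:
    """Intersection of upregulated-call sets across genotypes.

    Parameters
    ----------
    deg_tables
        Mapping from genotype name to that genotype's DEG table
        (columns ``gene_id`` and ``call``).
    """
    if len(deg_tables) == 0:
        raise ValidationError("shared_upregulated needs at least one DEG table")
    provenance = []
    shared: set[str] | None = None
    for genotype in sorted(deg_tables):
        ups = _up_set(deg_tables[genotype])
        provenance.append(("up_set", f"{genotype}:{len(ups)}"))
        shared = ups if shared is None else shared & ups
    return GeneSet(label, species, frozenset(shared), tuple(provenance))


def early_specific_candidates(
    design: MiningDesign,
    deg_tables: Mapping[str, pd.DataFrame],
    species: str = "",
    label: str = "early_specific",
) -> GeneSet:
    """Genes upregulated in all early genotypes and non-upregulated in all
    late genotypes.

    The non-upregulated set of a late genotype is its detected universe
    minus its up-calls; genes undetected in a late genotype are treated as
    non-upregulated.  With no late genotypes this reduces to
    :func:`shared_upregulated` over the early genotypes.
    """
    missing = [g for g in design.genotypes if g not in deg_tables]
    if missing:
        raise ValidationError(f"missing DEG tables for genotypes: {missing}")

    provenance = []
    result: set[str] | None = None
    for genotype in design.early:
        ups = _up_set(deg_tables[genotype])
        provenance.append(("early_up_set", f"{genotype}:{len(ups)}"))
        result = ups if result is None else result & ups
    for genotype in design.late:
        ups = _up_set(deg_tables[genotype])
        # complement within that genotype's detected universe, plus anything
        # it never detected at all
        provenance.append(("late_up_set_excluded", f"{genotype}:{len(ups)}"))
        result = result - ups
    return GeneSet(label, species, frozenset(result), tuple(provenance))


def membership_table(
    gene_sets: Sequence[GeneSet],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Binary membership matrix over the union of members, plus exact counts
    for every non-empty intersection pattern.

    The pattern key is a string of 0/1 flags in the order of ``gene_sets``
    (UpSet-style); counts over all patterns sum to the union size.
    """
    if len(gene_sets) == 0:
        raise ValidationError("membership_table needs at least one gene set")
    labels = [gs.label for gs in gene_sets]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"gene set labels must be unique, got {labels}")
    union = sorted(set().union(*(gs.members for gs in gene_sets)))
    matrix = pd.DataFrame(
        {gs.label: [g in gs.members for g in union] for gs in gene_sets},
        index=pd.Index(union, name="gene_id"),
        dtype=bool,
    )
    counts: dict[str, int] = {}
    for row in matrix.itertuples(index=False):
        key = "".join("1" if v else "0" for v in row)
        counts[key] = counts.get(key, 0) + 1
    return matrix, counts


def foldchange_correlation(
    deg_table_a: pd.DataFrame, deg_table_b: pd.DataFrame
) -> tuple[float, float, float, int]:
    """Pearson correlation and least-squares line of log2 fold changes over
    the genes detected in both contrasts.

    Returns ``(r, slope, intercept, n)``.
    """
    merged = pd.merge(
        deg_table_a[["gene_id", "log2fc"]],
        deg_table_b[["gene_id", "log2fc"]],
        on="gene_id",
        suffixes=("_a", "_b"),
    )
    n = len(merged)
    if n < 3:
        raise ValidationError(
            f"fold-change correlation needs >= 3 shared detected genes, got {n}"
        )
    x = merged["log2fc_a"].to_numpy(float)
    y = merged["log2fc_b"].to_numpy(float)
    fit = stats.linregress(x, y)
    r = float(np.corrcoef(x, y)[0, 1])
    return r, float(fit.slope), float(fit.intercept), n
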