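"""Rule-based transcription-factor family classification and term
enrichment.

Families are assigned from domain signatures: a rule names the domains
that must all be present, domains that must be absent, and a priority so
that composite signatures (e.g. AP2 + B3 -> RAV) win over their simpler
parents (AP2 alone -> AP2/ERF).  The shipped default rule table covers the
common plant TF families and can be replaced wholesale from a TSV file.

Term enrichment is the upper-tail hypergeometric test P(X >= k) for the
overlap k between a gene set of size n and a term of size K in a universe
of size N, Benjamini–Hochberg-adjusted across the tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParseError, ValidationError

__all__ = [
    "FamilyRule",
    "TFRecord",
    "DEFAULT_FAMILY_RULES",
    "load_family_rules",
    "classify_tf_families",
    "summarize_tf_families",
    "hypergeometric_enrichment",
    "load_tf_catalog",
]


@dataclass(frozen=True)
class FamilyRule:
    """Domain-signature rule for one TF family: every required domain must
    be present, no forbidden domain may be, and the highest priority wins."""

    family: str
    required: frozenset[str]
    forbidden: frozenset[str] = frozenset()
    priority: int = 1

    def __post_init__(self):
        object.__setattr__(self, "required", frozenset(self.required))
        object.__setattr__(self, "forbidden", frozenset(self.forbidden))
        if not self.required:
            raise ValidationError(f"rule for {self.family!r} has no required domains")
        if self.required & self.forbidden:
            raise ValidationError(
                f"rule for {self.family!r} requires and forbids the same domain"
            )

    def matches(self, domains: frozenset[str]) -> bool:
        return self.required <= domains and not (self.forbidden & domains)


DEFAULT_FAMILY_RULES: tuple[FamilyRule, ...] = (
    FamilyRule("MADS-box", {"SRF-TF"}),
    FamilyRule("AP2/ERF", {"AP2"}, priority=1),
    FamilyRule("RAV", {"AP2", "B3"}, priority=2),
    FamilyRule("MYB", {"Myb_DNA-binding"}),
    FamilyRule("WRKY", {"WRKY"}),
    FamilyRule("bZIP", {"bZIP_1"}),
    FamilyRule("HSF", {"HSF_DNA-bind"}),
    FamilyRule("TALE", {"Homeobox", "ELK"}, priority=2),
    FamilyRule("Dof", {"Zf-Dof"}),
    FamilyRule("ARF", {"Auxin_resp"}),
    FamilyRule("FAR1", {"FAR1"}),
)


@dataclass(frozen=True)
class TFRecord:
    gene_id: str
    family: str
    evidence_domains: tuple[str, ...] = ()
    orthologue_id: str | None = None


def _validate_rules(rules: Sequence[FamilyRule]) -> None:
    for i, a in enumerate(rules):
        for b in rules[i + 1 :]:
            if a.priority != b.priority:
                continue
            # one signature specializing the other at equal priority makes
            # the winner ill-defined; incidental overlaps are resolved by
            # the family-name tie-break instead
            nested = a.required <= b.required or b.required <= a.required
            compatible = not (a.required & b.forbidden) and not (
                b.required & a.forbidden
            )
            if nested and compatible:
                raise ValidationError(
                    f"rules {a.family!r} and {b.family!r} overlap at equal "
                    f"priority {a.priority}"
                )


def load_family_rules(path) -> tuple[FamilyRule, ...]:
    """Load a rule table TSV with columns family, required (comma-joined),
    forbidden (comma-joined, may be empty), priority."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required_cols = {"family", "required", "forbidden", "priority"}
    if not required_cols <= set(frame.columns):
        raise ParseError(
            f"rules file must have columns {sorted(required_cols)}", path=path
        )
    rules = []
    for row in frame.itertuples(index=False):
        rules.append(
            FamilyRule(
                row.family,
                frozenset(d for d in row.required.split(",") if d),
                frozenset(d for d in row.forbidden.split(",") if d),
                int(row.priority),
            )
        )
    return tuple(rules)


def classify_tf_families(
    gene_domains: Mapping[str, Iterable[str]],
    rules: Sequence[FamilyRule] = DEFAULT_FAMILY_RULES,
) -> list[TFRecord]:
    """Assign each gene the family of the highest-priority matching rule;
    genes matching no rule are omitted.  Ties within a priority level are
    excluded up front by rule validation; rule order never matters."""
    _validate_rules(rules)
    records = []
    for gene in sorted(gene_domains):
        domains = frozenset(gene_domains[gene])
        matching = [r for r in rules if r.matches(domains)]
        if not matching:
            continue
        winner = sorted(matching, key=lambda r: (-r.priority, r.family))[0]
        records.append(
            TFRecord(gene, winner.family, tuple(sorted(winner.required & domains)))
        )
    return records


def summarize_tf_families(records: Sequence[TFRecord]) -> pd.DataFrame:
    """Counts and percentages per family, sorted by descending count then
    family name; percentages are of all classified records, reported to one
    decimal place."""
    if len(records) == 0:
        return pd.DataFrame(columns=["family", "count", "percent"])
    counts: dict[str, int] = {}
    for record in records:
        counts[record.family] = counts.get(record.family, 0) + 1
    total = len(records)
    rows = sorted(counts.items(), key=lambda item: (-item[1], item[0]))
    return pd.DataFrame(
        {
            "family": [f for f, _ in rows],
            "count": [c for _, c in rows],
            "percent": [round(100.0 * c / total, 1) for _, c in rows],
        }
    )


def hypergeometric_enrichment(
    gene_set: Iterable[str],
    universe: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each term in ``gene_set``.

    Term gene lists are intersected with the universe before testing; terms
    with zero overlap with the gene set are skipped.  Returns a frame with
    columns term_id, k, n, K, N, p_raw, p_adj sorted by adjusted then raw
    p-value.
    """
    universe = set(universe)
    gene_set = set(gene_set)
    outside = gene_set - universe
    if outside:
        raise ValidationError(
            f"genes outside the universe: {sorted(outside)[:10]}"
        )
    N = len(universe)
    n = len(gene_set)
    rows = []
    for term_id in sorted(term_map):
        term_genes = set(term_map[term_id]) & universe
        K = len(term_genes)
        k = len(term_genes & gene_set)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, k, n, K, N, min(1.0, p)))
    frame = pd.DataFrame(
        rows, columns=["term_id", "k", "n", "K", "N", "p_raw"]
    )
    if len(frame):
        from .deg_stats import bh_adjust

        frame["p_adj"] = bh_adjust(frame["p_raw"])
        frame = frame.sort_values(
            ["p_adj", "p_raw", "term_id"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        frame["p_adj"] = []
    return frame


def load_tf_catalog() -> pd.DataFrame:
    """Curated catalogue of 25 early-flowering-associated transcription
    factors of the peach/mei species pair (gene, partner-species
    orthologue, family, preferred name)."""
    with resources.files("budmine.data").joinpath(
        "early_flowering_tf_catalog.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)
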