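"""Differential expression between two replicate-free count libraries.

The test is the exact conditional test for digital expression data: given a
gene observed ``x`` times in a reference library of size ``N1``, the count
``y`` in a second library of size ``N2`` follows, under the null of equal
relative expression, the conditional distribution

    p(y | x) = (N2/N1)^y * (x+y)! / (x! * y! * (1 + N2/N1)^(x+y+1)),

a negative binomial in ``y`` with x+1 "successes" and success probability
N1/(N1+N2).  Tail probabilities are accumulated in log space via log-gamma
terms; the numerically smaller tail is always summed directly (the upper
tail by adaptive summation upward from ``y`` until increments are
negligible), and the larger tail is obtained from the total-probability
identity, so neither tail suffers cancellation.

Two-sided p-values double the smaller tail (capped at 1), the standard
construction for discrete one-parameter tests.  Fold changes use a +1
pseudocount on both counts — in the fold change only, never in the test
statistic — to keep log2 ratios finite at zero counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .expression import CountMatrix, SampleDesign

__all__ = [
    "ContrastSpec",
    "ac_tail_prob",
    "ac_two_sided_p",
    "bh_adjust",
    "call_degs",
    "DEFAULT_ALPHA",
    "DEFAULT_MIN_LOG2FC",
]

DEFAULT_ALPHA = 0.01
DEFAULT_MIN_LOG2FC = 1.0

LOWER = "lower"
UPPER = "upper"

#: stop extending the upper-tail sum once the last term falls this far (in
#: nats) below the running total; the remaining geometric tail is then
#: bounded well under 1e-12 of the sum for N2/N1 <= 2
_LOG_CUTOFF = 60.0
_CHUNK = 256


@dataclass(frozen=True)
class ContrastSpec:
    """A within-genotype stage contrast: reference (dormancy) stage vs test
    (pre-flowering) stage, with calling thresholds."""

    genotype: str
    stage_a: str
    stage_b: str
    alpha: float = DEFAULT_ALPHA
    min_log2fc: float = DEFAULT_MIN_LOG2FC

    def __post_init__(self):
        if self.stage_a == self.stage_b:
            raise ValidationError("contrast stages must differ")
        if not (0 < self.alpha <= 1):
            raise ValidationError("alpha must be in (0, 1]")
        if self.min_log2fc < 0:
            raise ValidationError("min_log2fc must be non-negative")


def _check_count(value, name: str) -> int:
    if isinstance(value, (bool, np.bool_)):
        raise ValidationError(f"{name} must be an integer count")
    f = float(value)
    if not f.is_integer():
        raise ValidationError(f"{name} must be an integer count, got {value!r}")
    i = int(f)
    if i < 0:
        raise ValidationError(f"{name} must be non-negative, got {value!r}")
    return i


def _log_pmf(x: int, ks: np.ndarray, log_rho: float, log1p_rho: float) -> np.ndarray:
    """log p(k | x) for an array of k, with rho = N2/N1."""
    return (
        ks * log_rho
        - (x + ks + 1) * log1p_rho
        + gammaln(x + ks + 1)
        - gammaln(x + 1)
        - gammaln(ks + 1)
    )


def _lower_sum(x: int, y: int, log_rho: float, log1p_rho: float) -> float:
    """Direct summation of p(k|x) for k = 0..y (y may be -1 -> 0)."""
    if y < 0:
        return 0.0
    ks = np.arange(0, y + 1, dtype=float)
    return float(np.exp(logsumexp(_log_pmf(x, ks, log_rho, log1p_rho))))

def _upper_sum(x: int, y: int, log_rho: float, log1p_rho: float) -> float:
    """Adaptive direct summation of p(k|x) for k >= y, extending in chunks
    until the newest term is negligible relative to the running total."""
    total = -np.inf
    k0 = y
    while True:
        ks = np.arange(k0, k0 + _CHUNK, dtype=float)
        terms = _log_pmf(x, ks, log_rho, log1p_rho)
        total = np.logaddexp(total, logsumexp(terms))
        if terms[-1] < total - _LOG_CUTOFF:
            return float(np.exp(total))
        k0 += _CHUNK


def _mode(x: int, rho: float) -> int:
    # pmf ratio p(k+1)/p(k) = rho/(1+rho) * (x+k+1)/(k+1) crosses 1 near x*rho
    return max(0, math.floor(x * rho))


def ac_tail_prob(x, y, N1, N2, tail: str) -> float:
    """Exact conditional tail probability for a two-library count pair.

    ``lower`` is P(Y <= y | x), ``upper`` is P(Y >= y | x), both under the
    null of equal relative expression in libraries of sizes N1 (where x was
    observed) and N2 (where y was observed).
    """
    x = _check_count(x, "x")
    y = _check_count(y, "y")
    if N1 <= 0 or N2 <= 0:
        raise ValidationError("library sizes must be positive")
    if tail not in (LOWER, UPPER):
        raise ValidationError(f"tail must be 'lower' or 'upper', got {tail!r}")
    rho = N2 / N1
    log_rho = math.log(rho)
    log1p_rho = math.log1p(rho)
    mode = _mode(x, rho)
    if tail == LOWER:
        if y >= mode:
            p = 1.0 - _upper_sum(x, y + 1, log_rho, log1p_rho)
        else:
            p = _lower_sum(x, y, log_rho, log1p_rho)
    else:
        if y == 0:
            return 1.0
        if y > mode:
            p = _upper_sum(x, y, log_rho, log1p_rho)
        else:
            p = 1.0 - _lower_sum(x, y - 1, log_rho, log1p_rho)
    return min(1.0, max(0.0, p))


def ac_two_sided_p(x, y, N1, N2) -> float:
    """Two-sided p-value: twice the smaller conditional tail, capped at 1."""
    lo = ac_tail_prob(x, y, N1, N2, LOWER)
    hi = ac_tail_prob(x, y, N1, N2, UPPER)
    return min(1.0, 2.0 * min(lo, hi))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, clipped to <= 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def call_degs(
    counts: CountMatrix,
    design: SampleDesign,
    contrast: ContrastSpec,
) -> pd.DataFrame:
    """Call differentially expressed genes for one genotype's stage
    contrast.

    The gene universe is restricted to genes detected in the contrast
    (x + y > 0).  Columns of the returned table: gene_id, x, y, N1, N2,
    log2fc, p_raw, p_adj, call (up | down | ns); log2fc uses the +1
    pseudocount convention log2(((y+1)/N2) / ((x+1)/N1)).
    """
    sample_a = design.sample_for(contrast.genotype, contrast.stage_a)
    sample_b = design.sample_for(contrast.genotype, contrast.stage_b)
    for s in (sample_a, sample_b):
        if s not in counts.counts.columns:
            raise ValidationError(f"sample {s!r} missing from count matrix")
    x = counts.counts[sample_a].to_numpy(np.int64)
    y = counts.counts[sample_b].to_numpy(np.int64)
    N1 = int(counts.library_sizes[sample_a])
    N2 = int(counts.library_sizes[sample_b])

    detected = (x + y) > 0
    genes = np.asarray(counts.gene_ids)[detected]
    x, y = x[detected], y[detected]

    log2fc = np.log2(((y + 1) / N2) / ((x + 1) / N1))
    p_raw = np.array([ac_two_sided_p(xi, yi, N1, N2) for xi, yi in zip(x, y)])
    p_adj = bh_adjust(p_raw) if len(p_raw) else np.array([])

    call = np.full(len(genes), "ns", dtype=object)
    sig = p_adj <= contrast.alpha
    call[sig & (log2fc >= contrast.min_log2fc)] = "up"
    call[sig & (log2fc <= -contrast.min_log2fc)] = "down"

    return pd.DataFrame(
        {
            "gene_id": genes,
            "x": x,
            "y": y,
            "N1": N1,
            "N2": N2,
            "log2fc": log2fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "call": call,
        }
    )
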