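"""Target annotation and the two target-level statistics.

* :func:`annotate_targets` classifies each call's target against a gene
  model (intron / exon / intergenic).
* :func:`intron_preference_test` is a one-df goodness-of-fit chi-square of
  the observed intronic fraction against a null fraction.
* :func:`recurrence_permutation_test` is the permutation null for recurrent
  gene hits: each of ``n_events`` somatic events is independently
  gene-targeting with probability ``p_gene`` and, if so, placed uniformly
  among ``n_genes`` genes; the empirical p-value is the fraction of
  permutations in which any gene is hit twice or more (a birthday-collision
  null).  :func:`recurrence_analytic_p` is its closed-form counterpart,
  used as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import GeneModel, TestResult
from .insertion_detection import InsertionCall


@dataclass(frozen=True)
class TargetAnnotation:
    """Region classification of one call's target midpoint."""

    call_id: str
    region_class: str  # intron | exon | intergenic
    gene_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.region_class in ("intron", "exon") and not self.gene_names:
            raise ValueError("genic annotation requires a gene name")


@dataclass
class RecurrenceConfig:
    """Parameters of the gene-recurrence permutation null."""

    n_events: int = 83
    p_gene: float = 0.61
    n_genes: int = 51_573
    n_permutations: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_gene <= 1.0):
            raise ValueError("p_gene must lie in [0, 1]")
        if self.n_genes < 1 or self.n_permutations < 1:
            raise ValueError("n_genes and n_permutations must be >= 1")


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def annotate_targets(
    calls: Sequence[InsertionCall], genes: GeneModel
) -> list[TargetAnnotation]:
    """Classify each call's target midpoint as intron / exon / intergenic.

    A target inside overlapping genes is assigned to all of them (exon takes
    precedence when the classes disagree) but contributes once to
    region-class tallies.
    """
    out = []
    for c in calls:
        region, names = genes.classify(c.target.chrom, c.target.midpoint)
        out.append(TargetAnnotation(call_id=c.call_id, region_class=region, gene_names=names))
    return out


def annotate_calls(calls: Sequence[InsertionCall], genes: GeneModel) -> list[InsertionCall]:
    """Return calls with region_class/gene_names filled in (for VCF output)."""
    annotated = []
    for c, a in zip(calls, annotate_targets(calls, genes)):
        annotated.append(replace(c, region_class=a.region_class, gene_names=a.gene_names))
    return annotated


def tally_regions(annotations: Sequence[TargetAnnotation]) -> dict[str, int]:
    tally = {"intron": 0, "exon": 0, "intergenic": 0}
    for a in annotations:
        tally[a.region_class] += 1
    return tally


# ---------------------------------------------------------------------------
# Intron preference
# ---------------------------------------------------------------------------


def intron_preference_test(n_intronic: int, n_total: int, p_null: float) -> TestResult:
    """One-df goodness-of-fit chi-square for intronic targeting.

    Observed (n_intronic, n_total - n_intronic) against expected
    (n_total * p_null, n_total * (1 - p_null)); no continuity correction;
    p from the upper tail of chi-square with 1 df.
    """
    if not (0.0 < p_null < 1.0):
        raise ValueError("p_null must lie strictly inside (0, 1)")
    if not (0 <= n_intronic <= n_total):
        raise ValueError("need 0 <= n_intronic <= n_total")
    observed = np.array([n_intronic, n_total - n_intronic], dtype=float)
    expected = np.array([n_total * p_null, n_total * (1.0 - p_null)])
    chi2, p = stats.chisquare(observed, expected)
    return TestResult(name="intron-preference-chi2", statistic=float(chi2), p_value=float(p), df=1)


def invert_intron_chi2(n_intronic: int, n_total: int, chi2_value: float) -> float:
    """Solve for the null intronic fraction at which the observed split would
    yield the given chi-square statistic (root below the observed fraction).

    Used to check internal consistency of a reported (chi2, p) pair when the
    null fraction itself is unreported.
    """
    from scipy.optimize import brentq

    obs = n_intronic / n_total

    def f(p):
        return intron_preference_test(n_intronic, n_total, p).statistic - chi2_value

    return brentq(f, 1e-9, obs - 1e-9)


# ---------------------------------------------------------------------------
# Gene recurrence
# ---------------------------------------------------------------------------


def recurrence_permutation_test(cfg: RecurrenceConfig, chunk_size: int = 100_000) -> TestResult:
    """Monte-Carlo p-value for >=2 events hitting one gene.

    Each permutation draws K ~ Binomial(n_events, p_gene) gene-targeting
    events, places them uniformly among n_genes genes, and scores a hit when
    any gene receives two or more.  Vectorized in chunks; fixed seed gives an
    identical p.  The statistic reported is the hit count.
    """
    rng = np.random.default_rng(cfg.seed)
    hits = 0
    remaining = cfg.n_permutations
    while remaining > 0:
        c = min(chunk_size, remaining)
        k = rng.binomial(cfg.n_events, cfg.p_gene, size=c)
        kmax = int(k.max()) if c else 0
        if kmax >= 2:
            draws = rng.integers(0, cfg.n_genes, size=(c, kmax), dtype=np.int64)
            # pad unused slots with distinct negative values so they never collide
            cols = np.arange(kmax)
            draws = np.where(cols[None, :] < k[:, None], draws, -(cols[None, :] + 1))
            draws.sort(axis=1)
            hits += int((np.diff(draws, axis=1) == 0).any(axis=1).sum())
        remaining -= c
    p = hits / cfg.n_permutations
    return TestResult(name="gene-recurrence-permutation", statistic=float(hits), p_value=p)


def recurrence_analytic_p(cfg: RecurrenceConfig) -> float:
    """Exact collision probability: E_K[1 - prod_{i<K}(1 - i/n_genes)] with
    K ~ Binomial(n_events, p_gene).  Independent closed-form oracle for
    :func:`recurrence_permutation_test`."""
    k = np.arange(cfg.n_events + 1)
    weights = stats.binom.pmf(k, cfg.n_events, cfg.p_gene)
    # log prod_{i=0}^{k-1} (1 - i/G), k = 0..n_events
    i = np.arange(cfg.n_events)
    log_terms = np.log1p(-np.minimum(i, cfg.n_genes - 1) / cfg.n_genes)
    # if k exceeds the number of genes a collision is certain
    log_no_collision = np.concatenate([[0.0], np.cumsum(log_terms)])
    no_collision = np.where(k <= cfg.n_genes, np.exp(log_no_collision), 0.0)
    return float(np.sum(weights * (1.0 - no_collision)))
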