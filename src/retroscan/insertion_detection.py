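"""Insertion calling from source-anchored discordant read pairs.

The caller follows the count-based rule used for 3' transductions from a
single source element: keep pairs with exactly one mate in the source
region, single-linkage-cluster the distal mates, and emit a call when a
cluster reaches the support threshold (>=3 pairs in tumors by default).
Somatic status is assigned by subtracting a sensitive matched-normal call
set (no mapping-quality floor, >=2 supporting pairs) whose breakpoints are
flanked by 500 bp on both sides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .core import DiscordantPair, Interval

logger = logging.getLogger(__name__)


@dataclass
class CallerConfig:
    """Detection thresholds.

    The tumor side requires MAPQ >= 20 with >= 3 supporting pairs; the
    matched normal is called with maximal sensitivity (no MAPQ floor,
    >= 2 pairs) so that the 500 bp flank subtraction removes germline
    signal reliably.
    """

    tumor_min_mapq: int = 20
    tumor_min_support: int = 3
    normal_min_mapq: int = 0
    normal_min_support: int = 2
    flank_bp: int = 500
    cluster_window_bp: int = 1000
    anchor_tolerance_bp: int = 1000

    def __post_init__(self) -> None:
        if self.tumor_min_support < 1 or self.normal_min_support < 1:
            raise ValueError("support thresholds must be >= 1")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")

    def min_support(self, tissue: str) -> int:
        return self.tumor_min_support if tissue == "tumor" else self.normal_min_support

    def min_mapq(self, tissue: str) -> int:
        return self.tumor_min_mapq if tissue == "tumor" else self.normal_min_mapq


@dataclass(frozen=True)
class InsertionCluster:
    """A cluster of distal mates supporting one candidate insertion."""

    sample_id: str
    tissue: str
    target: Interval  # spans all distal-mate positions in the cluster
    pair_ids: tuple[str, ...]
    min_mapq_used: int

    @property
    def support(self) -> int:
        return len(self.pair_ids)


@dataclass(frozen=True)
class InsertionCall:
    """A called insertion of source-locus sequence at a target interval."""

    call_id: str
    sample_id: str
    tissue: str
    target: Interval
    support: int
    pair_ids: tuple[str, ...]
    min_mapq_used: int
    status: str  # somatic | germline | unfiltered
    source_locus: Interval
    region_class: Optional[str] = None
    gene_names: tuple[str, ...] = ()


@dataclass(frozen=True)
class GermlinePolymorphism:
    """A germline insertion merged across carriers of a cohort."""

    target: Interval
    carriers: tuple[str, ...]
    n_cohort: int
    calls: tuple[InsertionCall, ...]

    @property
    def frequency(self) -> float:
        return len(self.carriers) / self.n_cohort


# ---------------------------------------------------------------------------
# Stage 1: source anchoring
# ---------------------------------------------------------------------------


def select_source_anchored(
    pairs: Sequence[DiscordantPair], source: Interval, min_mapq: int = 0
) -> list[DiscordantPair]:
    """Keep pairs with exactly one mate inside the source interval and both
    mates at MAPQ >= min_mapq, reoriented so mateA is the source-side mate."""
    out = []
    for p in pairs:
        a_in = source.contains(p.mateA.chrom, p.mateA.pos)
        b_in = source.contains(p.mateB.chrom, p.mateB.pos)
        if a_in == b_in:  # neither, or both (a pair internal to the source)
            continue
        if p.mateA.mapq < min_mapq or p.mateB.mapq < min_mapq:
            continue
        if b_in:
            p = replace(p, mateA=p.mateB, mateB=p.mateA)
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# Stage 2: distal-mate clustering
# ---------------------------------------------------------------------------


def cluster_distal_mates(
    pairs: Sequence[DiscordantPair], window_bp: int = 1000
) -> list[InsertionCluster]:
    """Single-linkage clustering of distal-mate positions.

    Pairs are grouped per (sample, tissue, distal chromosome); within a
    group, consecutive sorted positions at most ``window_bp`` apart join one
    cluster.  Output is deterministic and independent of input order
    (positions sorted, ties broken by pair_id); clusters are reported sorted
    by (chrom, start).
    """
    groups: dict[tuple, list[DiscordantPair]] = {}
    for p in pairs:
        groups.setdefault((p.sample_id, p.tissue, p.mateB.chrom), []).append(p)

    clusters = []
    for (sample_id, tissue, chrom), members in groups.items():
        members.sort(key=lambda p: (p.mateB.pos, p.pair_id))
        current: list[DiscordantPair] = []
        for p in members:
            if current and p.mateB.pos - current[-1].mateB.pos > window_bp:
                clusters.append(_make_cluster(sample_id, tissue, chrom, current))
                current = []
            current.append(p)
        if current:
            clusters.append(_make_cluster(sample_id, tissue, chrom, current))
    clusters.sort(key=lambda c: (c.target.chrom, c.target.start, c.sample_id, c.tissue))
    return clusters


def _make_cluster(sample_id, tissue, chrom, members) -> InsertionCluster:
    positions = [p.mateB.pos for p in members]
    return InsertionCluster(
        sample_id=sample_id,
        tissue=tissue,
        target=Interval(chrom, min(positions), max(positions) + 1),
        pair_ids=tuple(p.pair_id for p in members),
        min_mapq_used=min(min(p.mateA.mapq, p.mateB.mapq) for p in members),
    )


# ---------------------------------------------------------------------------
# Stage 3: support thresholding
# ---------------------------------------------------------------------------


def call_insertions(
    clusters: Sequence[InsertionCluster],
    min_support: int,
    source_locus: Interval,
) -> list[InsertionCall]:
    """Promote clusters with support >= min_support to (unfiltered) calls."""
    calls = []
    dropped = 0
    for i, c in enumerate(clusters):
        if c.support < min_support:
            dropped += 1
            continue
        calls.append(
            InsertionCall(
                call_id=f"{c.sample_id}.{c.tissue}.c{i}",
                sample_id=c.sample_id,
                tissue=c.tissue,
                target=c.target,
                support=c.support,
                pair_ids=c.pair_ids,
                min_mapq_used=c.min_mapq_used,
                status="unfiltered",
                source_locus=source_locus,
            )
        )
    if dropped:
        logger.info("dropped %d clusters below support %d", dropped, min_support)
    return calls


# ---------------------------------------------------------------------------
# Stage 4: somatic subtraction
# ---------------------------------------------------------------------------


def filter_somatic(
    tumor_calls: Sequence[InsertionCall],
    normal_calls: Sequence[InsertionCall],
    flank_bp: int = 500,
) -> tuple[list[InsertionCall], list[InsertionCall]]:
    """Partition tumor calls into (somatic, germline) by matched-normal subtraction.

    A tumor call whose target interval intersects any normal-call target
    expanded by ``flank_bp`` on both sides is labeled germline; the rest are
    somatic.  Calls removed as germline are retained (not discarded): they
    carry the cohort's germline polymorphisms.
    """
    cases = {c.sample_id for c in tumor_calls} | {c.sample_id for c in normal_calls}
    if len(cases) > 1:
        raise ValueError(f"filter_somatic expects one case, got samples {sorted(cases)}")
    flanked = [n.target.expanded(flank_bp) for n in normal_calls]
    somatic, germline = [], []
    for t in tumor_calls:
        if any(t.target.overlaps(f) for f in flanked):
            germline.append(replace(t, status="germline"))
        else:
            somatic.append(replace(t, status="somatic"))
    return somatic, germline


# ---------------------------------------------------------------------------
# Stage 5: cohort germline genotyping
# ---------------------------------------------------------------------------


def genotype_germline(
    germline_calls: Sequence[InsertionCall],
    n_cohort: int,
    anchor_tolerance_bp: int = 1000,
) -> list[GermlinePolymorphism]:
    """Merge germline calls across samples into cohort polymorphisms.

    Calls on one chromosome whose target midpoints chain within
    ``anchor_tolerance_bp`` (single linkage) are one polymorphism; its
    carrier list and cohort frequency follow.
    """
    by_chrom: dict[str, list[InsertionCall]] = {}
    for c in germline_calls:
        if c.status != "germline":
            raise ValueError(f"call {c.call_id} is not germline")
        by_chrom.setdefault(c.target.chrom, []).append(c)

    polys = []
    for chrom, calls in sorted(by_chrom.items()):
        calls.sort(key=lambda c: (c.target.midpoint, c.call_id))
        block: list[InsertionCall] = []
        for c in calls:
            if block and c.target.midpoint - block[-1].target.midpoint > anchor_tolerance_bp:
                polys.append(_make_polymorphism(chrom, block, n_cohort))
                block = []
            block.append(c)
        if block:
            polys.append(_make_polymorphism(chrom, block, n_cohort))
    return polys


def _make_polymorphism(chrom, block, n_cohort) -> GermlinePolymorphism:
    return GermlinePolymorphism(
        target=Interval(chrom, min(c.target.start for c in block), max(c.target.end for c in block)),
        carriers=tuple(sorted({c.sample_id for c in block})),
        n_cohort=n_cohort,
        calls=tuple(block),
    )


# ---------------------------------------------------------------------------
# Convenience: one case end to end
# ---------------------------------------------------------------------------


def detect_case(
    tumor_pairs: Sequence[DiscordantPair],
    normal_pairs: Sequence[DiscordantPair],
    source: Interval,
    config: Optional[CallerConfig] = None,
) -> dict:
    """Run anchoring, clustering, calling and somatic filtering for one
    tumor/normal case.  Returns a dict with per-stage outputs and counts."""
    cfg = config or CallerConfig()
    result: dict = {"counts": {}}
    calls = {}
    for tissue, pairs in (("tumor", tumor_pairs), ("normal", normal_pairs)):
        anchored = select_source_anchored(pairs, source, cfg.min_mapq(tissue))
        clusters = cluster_distal_mates(anchored, cfg.cluster_window_bp)
        calls[tissue] = call_insertions(clusters, cfg.min_support(tissue), source)
        result["counts"][tissue] = {
            "pairs": len(pairs),
            "source_anchored": len(anchored),
            "clusters": len(clusters),
            "calls": len(calls[tissue]),
        }
    somatic, germline = filter_somatic(calls["tumor"], calls["normal"], cfg.flank_bp)
    result.update(
        tumor_calls=calls["tumor"], normal_calls=calls["normal"],
        somatic=somatic, germline=germline,
    )
    result["counts"]["somatic"] = len(somatic)
    result["counts"]["germline"] = len(germline)
    return result
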