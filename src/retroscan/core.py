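"""Shared domain types for the retroscan pipeline.

All coordinates are 0-based half-open internally.  External formats are
converted at the I/O boundary (BED/bedGraph are already half-open; SAM,
GFF3 and VCF are 1-based and converted on read/write).
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

MISSING = -1  # genotype missing-call sentinel

#: Reference coordinates (GRCh37) of the uniquely mappable 669 bp 3' end of the
#: source L1 element in TTC28 intron 1.  Recorded for documentation only; the
#: pipeline operates on whatever source region its configuration names.
TTC28_L1_TAIL_GRCH37 = ("22", 29_065_455, 29_066_124)


def stable_seed(seed: int, label: str) -> int:
    """Derive a per-stage RNG seed (< 2**31) deterministically from a global seed.

    Uses SHA-256 so the derivation is stable across Python processes and
    versions (unlike the builtin ``hash``).
    """
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# Intervals
# ---------------------------------------------------------------------------

_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def expanded(self, flank: int, chrom_length: Optional[int] = None) -> "Interval":
        end = self.end + flank
        if chrom_length is not None:
            end = min(end, chrom_length)
        return Interval(self.chrom, max(0, self.start - flank), end)

    def contains_interval(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @classmethod
    def parse(cls, region: str) -> "Interval":
        """Parse ``CHR:START-END``, taking the printed coordinates verbatim as
        half-open (start inclusive, end exclusive).

        This matches the convention under which source-element coordinates
        are quoted in the copy-number literature this package follows, where
        ``22:29,065,455-29,066,124`` denotes a 669 bp region (end − start).
        """
        m = _REGION_RE.match(region)
        if not m:
            raise ValueError(f"cannot parse region {region!r}")
        chrom, start, end = m.group(1), m.group(2), m.group(3)
        return cls(chrom, int(start.replace(",", "")), int(end.replace(",", "")))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Gene:
    """A gene with ordered, non-overlapping exons; introns are the gaps."""

    name: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"gene {self.name}: empty exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.name}: exons overlap or are unsorted")
            prev_end = e
        if self.exons and (self.exons[0][0] < self.start or self.exons[-1][1] > self.end):
            raise ValueError(f"gene {self.name}: exons outside transcript bounds")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return tuple(out)


class GeneModel:
    """A collection of genes supporting point classification into
    exon / intron / intergenic space."""

    def __init__(self, genes: Sequence[Gene]):
        self.genes = list(genes)
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: (g.start, g.end, g.name))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneModel) and sorted(
            self.genes, key=lambda g: g.name
        ) == sorted(other.genes, key=lambda g: g.name)

    def genes_at(self, chrom: str, pos: int) -> list[Gene]:
        return [
            g
            for g in self._by_chrom.get(chrom, [])
            if g.start <= pos < g.end
        ]

    def classify(self, chrom: str, pos: int) -> tuple[str, tuple[str, ...]]:
        """Classify a genomic point as exon / intron / intergenic.

        A point inside overlapping genes reports all gene names; exon takes
        precedence over intron when genes disagree.  Exon boundaries follow
        half-open arithmetic: the base at an exon start belongs to the exon,
        the base at its (exclusive) end does not.
        """
        hits = self.genes_at(chrom, pos)
        if not hits:
            return "intergenic", ()
        in_exon = any(
            s <= pos < e for g in hits for (s, e) in g.exons
        )
        names = tuple(sorted({g.name for g in hits}))
        return ("exon" if in_exon else "intron"), names

    def intronic_bp(self) -> int:
        return sum(e - s for g in self.genes for (s, e) in g.introns)

    def exonic_bp(self) -> int:
        return sum(e - s for g in self.genes for (s, e) in g.exons)

    def intronic_fraction(self, chrom_lengths: dict[str, int]) -> float:
        """Fraction of the genome that is intronic (assumes non-overlapping genes)."""
        return self.intronic_bp() / sum(chrom_lengths.values())


# ---------------------------------------------------------------------------
# Discordant read pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Mate:
    chrom: str
    pos: int  # 0-based leftmost mapped position
    strand: str  # "+" or "-"
    mapq: int

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class DiscordantPair:
    """One aligned read pair whose mates map discordantly: different
    chromosomes, or the same chromosome at a separation above the
    concordance limit."""

    pair_id: str
    sample_id: str
    tissue: str  # "tumor" | "normal"
    mateA: Mate
    mateB: Mate

    def is_discordant(self, concordance_limit: int) -> bool:
        if self.mateA.chrom != self.mateB.chrom:
            return True
        return abs(self.mateA.pos - self.mateB.pos) > concordance_limit


DiscordantPairSet = list  # list[DiscordantPair]


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------


@dataclass
class CoverageTrack:
    """Binned mean sequencing depth for one sample/tissue.

    ``bins`` has columns chrom, start, end, depth with non-overlapping sorted
    intervals per chromosome.
    """

    sample_id: str
    tissue: str
    bins: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "depth"}
        if not required.issubset(self.bins.columns):
            raise ValueError(f"coverage bins need columns {sorted(required)}")
        if (self.bins["depth"] < 0).any():
            raise ValueError("coverage depth must be >= 0")
        for chrom, sub in self.bins.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if not (np.diff(starts) >= 0).all() or (starts[1:] < ends[:-1]).any():
                raise ValueError(f"coverage bins overlap or unsorted on {chrom}")

    def chromosomes(self) -> list[str]:
        return list(self.bins["chrom"].unique())

    def mean_depth(self, region: Optional[Interval] = None, chrom: Optional[str] = None) -> float:
        """Length-weighted mean depth over a region, a chromosome, or everything."""
        b = self.bins
        if region is not None:
            b = b[b["chrom"] == region.chrom]
            start = np.maximum(b["start"].to_numpy(), region.start)
            end = np.minimum(b["end"].to_numpy(), region.end)
            lengths = np.maximum(end - start, 0)
        elif chrom is not None:
            b = b[b["chrom"] == chrom]
            lengths = (b["end"] - b["start"]).to_numpy()
        else:
            lengths = (b["end"] - b["start"]).to_numpy()
        total = lengths.sum()
        if total == 0:
            raise ValueError("coverage track does not cover the requested region")
        return float((b["depth"].to_numpy() * lengths).sum() / total)


# ---------------------------------------------------------------------------
# Genotype matrices
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Biallelic genotype calls over one chromosome's ordered markers.

    Calls count alternate alleles: 0, 1, 2, or ``MISSING`` (-1).
    """

    chrom: str
    sample_ids: list[str]
    positions: np.ndarray  # sorted, strictly increasing
    calls: np.ndarray  # (n_samples, n_markers) int8

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.positions.ndim != 1 or len(self.positions) < 1:
            raise ValueError("positions must be a 1-D array")
        if not (np.diff(self.positions) > 0).all():
            raise ValueError("marker positions must be strictly increasing")
        if self.calls.shape != (len(self.sample_ids), len(self.positions)):
            raise ValueError("calls shape inconsistent with samples x markers")
        valid = np.isin(self.calls, [MISSING, 0, 1, 2])
        if not valid.all():
            raise ValueError("genotype calls must be in {0,1,2,missing}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.positions)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in genotype matrix") from None

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.chrom == other.chrom
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# Statistical test results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    name: str
    statistic: float
    p_value: float
    df: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def as_dict(self) -> dict:
        d = {"test": self.name, "statistic": self.statistic, "p_value": self.p_value}
        if self.df is not None:
            d["df"] = self.df
        if self.ci_low is not None:
            d["ci_95"] = [self.ci_low, self.ci_high]
        return d
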