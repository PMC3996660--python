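"""Coverage-ratio copy-number evidence for retrotransposition.

Because retrotransposition is copy-and-paste, every carried insertion adds
one haploid copy of the source element's uniquely mappable 3' end somewhere
in the genome.  Reads from those extra copies still map to the source
region, so its depth, normalised by the depth of its whole chromosome,
rises by ~vaf/2 per carried event.  The statistic here is that ratio, and
the group comparison is a Welch t-test of carriers against non-carriers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import CoverageTrack, Interval, TestResult


@dataclass(frozen=True)
class CoverageRatio:
    """Mean depth over a region divided by mean depth over its chromosome."""

    sample_id: str
    region: Interval
    ratio: float

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise ValueError("coverage ratio must be >= 0")


def region_coverage_ratio(track: CoverageTrack, region: Interval) -> CoverageRatio:
    """Length-weighted mean depth in ``region`` over the length-weighted mean
    depth of the region's whole chromosome.

    Raises if the track does not cover the region's chromosome, or if the
    chromosome mean depth is zero (the ratio is then undefined).
    """
    if region.chrom not in set(track.bins["chrom"]):
        raise ValueError(f"track does not cover chromosome {region.chrom}")
    chrom_mean = track.mean_depth(chrom=region.chrom)
    if chrom_mean == 0:
        raise ValueError("chromosome mean depth is zero; ratio undefined")
    region_mean = track.mean_depth(region=region)
    return CoverageRatio(sample_id=track.sample_id, region=region, ratio=region_mean / chrom_mean)


def compare_ratio_groups(
    carriers: Sequence[CoverageRatio], noncarriers: Sequence[CoverageRatio]
) -> TestResult:
    """Two-sided Welch t-test of carrier vs non-carrier coverage ratios.

    Returns t, p and the 95% confidence interval for the difference in group
    means (carriers minus non-carriers).
    """
    if len(carriers) < 2 or len(noncarriers) < 2:
        raise ValueError("both groups need at least 2 samples")
    a = np.array([r.ratio for r in carriers])
    b = np.array([r.ratio for r in noncarriers])
    res = stats.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(0.95)
    return TestResult(
        name="coverage-ratio-welch-t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.df),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
    )
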