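import dataclasses
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retroscan.core import DiscordantPair, Interval, Mate
from retroscan.insertion_detection import (
    CallerConfig,
    call_insertions,
    cluster_distal_mates,
    detect_case,
    filter_somatic,
    genotype_germline,
    select_source_anchored,
)
from retroscan.synthetic_data import InsertionSpec, build_reference, simulate_sample

SOURCE = Interval("chrS", 10_000, 16_000)


def pair(pid, posA=10_500, posB=5_000, chromB="chr2", mapqA=60, mapqB=60,
         chromA="chrS", sample="S0", tissue="tumor"):
    return DiscordantPair(
        pair_id=pid, sample_id=sample, tissue=tissue,
        mateA=Mate(chromA, posA, "+", mapqA),
        mateB=Mate(chromB, posB, "-", mapqB),
    )


def brute_force_single_linkage(positions, window):
    """Independent oracle: exhaustive transitive closure of the
    within-window relation over all position pairs."""
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        if abs(positions[i] - positions[j]) <= window:
            parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(positions[i])
    return sorted(sorted(g) for g in groups.values())


class TestSelectSourceAnchored:
    def test_both_mates_in_source_excluded(self):
        p = pair("p", posA=10_500, chromB="chrS", posB=15_000)
        assert select_source_anchored([p], SOURCE) == []

    def test_mapq_below_floor_excluded(self):
        p = pair("p", mapqA=19)
        assert select_source_anchored([p], SOURCE, min_mapq=20) == []
        assert len(select_source_anchored([p], SOURCE, min_mapq=0)) == 1

    def test_distal_mate_other_chromosome_included_and_reoriented(self):
        # source mate arrives as mateB: selection must swap it to mateA
        p = DiscordantPair(
            pair_id="p", sample_id="S0", tissue="tumor",
            mateA=Mate("chr2", 5_000, "-", 60),
            mateB=Mate("chrS", 10_500, "+", 60),
        )
        (kept,) = select_source_anchored([p], SOURCE, min_mapq=20)
        assert kept.mateA.chrom == "chrS"
        assert kept.mateB.chrom == "chr2"

    def test_neither_mate_in_source_excluded(self):
        p = pair("p", chromA="chr3", posA=123)
        assert select_source_anchored([p], SOURCE) == []


class TestClusterDistalMates:
    def test_chained_positions_one_cluster(self):
        pairs = [pair(f"p{i}", posB=b) for i, b in enumerate([1000, 1400, 1900])]
        (c,) = cluster_distal_mates(pairs, window_bp=1000)
        assert c.support == 3
        assert c.target == Interval("chr2", 1000, 1901)

    def test_distant_positions_split(self):
        pairs = [pair("p0", posB=1000), pair("p1", posB=5000)]
        clusters = cluster_distal_mates(pairs, window_bp=1000)
        assert [c.support for c in clusters] == [1, 1]

    def test_transitive_chain_with_outlier(self):
        # positions {0, 900, 1800, 5000}: chain of three plus a singleton
        pairs = [pair(f"p{i}", posB=b) for i, b in enumerate([0, 900, 1800, 5000])]
        clusters = cluster_distal_mates(pairs, window_bp=1000)
        assert sorted(sorted(p.mateB.pos for p in [pairs[int(x[1])] for x in c.pair_ids]) for c in clusters) == [
            [0, 900, 1800],
            [5000],
        ]

    def test_order_invariance(self):
        pairs = [pair(f"p{i}", posB=b) for i, b in enumerate([3000, 100, 2500, 90_000])]
        a = cluster_distal_mates(pairs, 1000)
        b = cluster_distal_mates(list(reversed(pairs)), 1000)
        assert a == b

    def test_groups_split_by_sample_tissue_chrom(self):
        pairs = [
            pair("p0", posB=1000),
            pair("p1", posB=1000, tissue="normal"),
            pair("p2", posB=1000, chromB="chr3"),
        ]
        assert len(cluster_distal_mates(pairs, 1000)) == 3

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        positions=st.lists(st.integers(0, 20_000), min_size=1, max_size=50),
        window=st.integers(1, 5_000),
    )
    def test_matches_brute_force_oracle(self, positions, window):
        pairs = [pair(f"p{i:03d}", posB=b) for i, b in enumerate(positions)]
        clusters = cluster_distal_mates(pairs, window)
        got = sorted(
            sorted(p.mateB.pos for p in pairs if p.pair_id in c.pair_ids)
            for c in clusters
        )
        assert got == brute_force_single_linkage(positions, window)


class TestCallInsertions:
    @pytest.mark.parametrize("support,min_support,called", [(3, 3, True), (2, 3, False)])
    def test_support_threshold_boundary(self, support, min_support, called):
        pairs = [pair(f"p{i}", posB=1000 + 10 * i) for i in range(support)]
        clusters = cluster_distal_mates(pairs, 1000)
        calls = call_insertions(clusters, min_support, SOURCE)
        assert bool(calls) is called

    def test_min_support_one_promotes_every_cluster(self):
        pairs = [pair(f"p{i}", posB=10_000 * i) for i in range(4)]
        clusters = cluster_distal_mates(pairs, 1000)
        assert len(call_insertions(clusters, 1, SOURCE)) == len(clusters)

    def test_monotone_in_min_support(self):
        rng = np.random.default_rng(5)
        pairs = [pair(f"p{i}", posB=int(b)) for i, b in enumerate(rng.integers(0, 50_000, 40))]
        clusters = cluster_distal_mates(pairs, 1000)
        counts = [len(call_insertions(clusters, k, SOURCE)) for k in range(1, 8)]
        assert counts == sorted(counts, reverse=True)


class TestFilterSomatic:
    def _call(self, start, end, tissue="tumor", sample="S0"):
        pairs = tuple(f"x{i}" for i in range(3))
        from retroscan.insertion_detection import InsertionCall

        return InsertionCall(
            call_id=f"{sample}.{tissue}.{start}", sample_id=sample, tissue=tissue,
            target=Interval("chr2", start, end), support=3, pair_ids=pairs,
            min_mapq_used=60, status="unfiltered", source_locus=SOURCE,
        )

    def test_normal_call_within_flank_marks_germline(self):
        tumor = [self._call(10_000, 10_001)]
        normal = [self._call(10_400, 10_401, tissue="normal")]  # 400 bp away
        somatic, germline = filter_somatic(tumor, normal, flank_bp=500)
        assert somatic == [] and len(germline) == 1
        assert germline[0].status == "germline"

    def test_normal_call_beyond_flank_stays_somatic(self):
        tumor = [self._call(10_000, 10_001)]
        normal = [self._call(10_601, 10_602, tissue="normal")]  # 600 bp > 500
        somatic, germline = filter_somatic(tumor, normal, flank_bp=500)
        assert len(somatic) == 1 and germline == []
        assert somatic[0].status == "somatic"

    def test_empty_normal_set_all_somatic(self):
        tumor = [self._call(1_000, 1_001), self._call(90_000, 90_001)]
        somatic, germline = filter_somatic(tumor, [], flank_bp=500)
        assert len(somatic) == 2 and germline == []

    def test_partition_is_exact(self):
        tumor = [self._call(s, s + 1) for s in (1_000, 5_000, 20_000)]
        normal = [self._call(5_100, 5_101, tissue="normal")]
        somatic, germline = filter_somatic(tumor, normal, 500)
        assert len(somatic) + len(germline) == len(tumor)
        assert {c.call_id for c in somatic}.isdisjoint({c.call_id for c in germline})

    def test_mismatched_cases_rejected(self):
        with pytest.raises(ValueError, match="one case"):
            filter_somatic([self._call(1, 2)], [self._call(1, 2, sample="S1")], 500)


class TestGenotypeGermline:
    def _germ(self, sample, start):
        from retroscan.insertion_detection import InsertionCall

        return InsertionCall(
            call_id=f"{sample}.{start}", sample_id=sample, tissue="tumor",
            target=Interval("chr2", start, start + 200), support=5, pair_ids=(),
            min_mapq_used=60, status="germline", source_locus=SOURCE,
        )

    def test_cohort_frequency_counts_carriers(self):
        calls = [self._germ(f"S{i}", 10_000 + 30 * i) for i in range(4)]
        (poly,) = genotype_germline(calls, n_cohort=92, anchor_tolerance_bp=1000)
        assert len(poly.carriers) == 4
        assert poly.frequency == pytest.approx(4 / 92)

    def test_no_calls_no_polymorphisms(self):
        assert genotype_germline([], n_cohort=92) == []

    def test_distant_insertions_never_merged(self):
        calls = [self._germ("S0", 10_000), self._germ("S1", 1_010_000)]
        polys = genotype_germline(calls, n_cohort=92, anchor_tolerance_bp=1000)
        assert len(polys) == 2

    def test_non_germline_input_rejected(self):
        bad = dataclasses.replace(self._germ("S0", 1), status="somatic")
        with pytest.raises(ValueError):
            genotype_germline([bad], n_cohort=92)


class TestRecoveryOnSyntheticData:
    """Planted-truth recovery for a single cohort (the multi-seed sweep lives
    in the acceptance suite)."""

    def test_planted_events_recovered_with_correct_status(
        self, small_ref, demo_specs, small_config
    ):
        truth = {
            (sp.target_chrom, sp.target_pos, sp.status, carrier)
            for sp in demo_specs
            for carrier in sp.carrier_samples
        }
        found = set()
        for sid in [f"S{i:03d}" for i in range(small_config.n_samples)]:
            sim = simulate_sample(small_ref, demo_specs, sid, small_config)
            res = detect_case(sim["tumor"][0], sim["normal"][0], small_ref.source_locus)
            for status, calls in (("somatic", res["somatic"]), ("germline", res["germline"])):
                for c in calls:
                    matches = [
                        t for t in truth
                        if t[0] == c.target.chrom and t[3] == sid and t[2] == status
                        and c.target.start - 1000 <= t[1] <= c.target.end + 1000
                    ]
                    assert matches, f"false-positive {status} call at {c.target} in {sid}"
                    found.update(matches)
        assert found == truth
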