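"""Synthetic tumor/normal cohorts with planted L1 retrotranspositions.

The generator emulates the observable footprint of 3' transductions from a
single full-length L1 source element whose last 669 bp (the "unique tail")
are uniquely mappable:

* discordant read pairs with one mate in the unique tail and the other mate
  within fragment-length distance of the insertion target;
* a copy-number gain of the tail region in carriers (one haploid copy
  equivalent per carried insertion, scaled by the cell fraction carrying it);
* genotype matrices in which carriers of a germline insertion share a founder
  haplotype around the insertion site.

Reads are simulated at the alignment level (mapped coordinates, strands and
mapping qualities), not as FASTQ: upstream alignment is outside the model.
Donor genomes are represented by coordinate arithmetic on insertion records;
:func:`junction_sequences` optionally renders literal junction sequence for a
planted event (5' truncation, poly(A) tail, optional 3'-end inversion).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import (
    CoverageTrack,
    DiscordantPair,
    Gene,
    GeneModel,
    GenotypeMatrix,
    Interval,
    Mate,
    MISSING,
    stable_seed,
)

import pandas as pd

TISSUES = ("tumor", "normal")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror a deep-coverage whole-genome design: >=40x mean depth,
    100 bp paired-end reads, and a fragment length (mean 400 bp, sd 50 bp)
    that makes a 500 bp breakpoint flank meaningful.
    """

    n_samples: int = 8
    coverage_depth: float = 40.0  # mean sequenced bases per reference bp
    fragment_length_mean: float = 400.0
    fragment_length_sd: float = 50.0
    read_length: int = 100
    seed: int = 0

    # toy genome geometry
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chrA": 2_000_000, "chrB": 2_000_000, "chrC": 1_000_000}
    )
    source_chrom: str = "chrA"
    source_start: int = 1_000_000
    source_length: int = 6_000  # full-length L1 is ~6 kb
    unique_tail_length: int = 669
    # gene layout: evenly spaced multi-exon genes on every chromosome except
    # around the source element
    gene_length: int = 40_000
    gene_spacing: int = 60_000
    n_exons_per_gene: int = 5
    exon_length: int = 1_000

    # coverage binning
    bin_size: int = 1_000

    # discordant-pair noise: random mismapped pairs per sample/tissue, plus a
    # low rate of spurious pairs anchored in the unique tail
    noise_pairs_mean: float = 30.0
    source_noise_pairs_mean: float = 1.0

    polya_length: int = 30

    def __post_init__(self) -> None:
        if self.coverage_depth <= 0:
            raise ValueError("coverage_depth must be > 0")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.unique_tail_length > self.source_length:
            raise ValueError("unique tail cannot exceed the source element length")
        if self.read_length <= 0 or self.fragment_length_mean <= 2 * self.read_length:
            raise ValueError("fragment length must exceed two read lengths")

    @property
    def concordance_limit(self) -> int:
        """Mate separation beyond which a pair counts as discordant."""
        return int(self.fragment_length_mean + 4 * self.fragment_length_sd)

    @property
    def expected_pairs_per_copy(self) -> float:
        """Expected discordant pairs supporting one insertion at cell fraction 1.

        Fragment (physical) coverage at a point is depth*F/(2R); half of the
        fragments from the carrier haplotype straddle a junction with one full
        read on each side ((F-2R)/F), and both junctions of a 3' transduction
        are anchored in uniquely mappable source sequence.  Net:
        depth * (F - 2R) / (2R), i.e. 40 pairs per event at the defaults.
        """
        f, r = self.fragment_length_mean, self.read_length
        return self.coverage_depth * (f - 2 * r) / (2 * r)


@dataclass(frozen=True)
class InsertionSpec:
    """A planted retrotransposition event (the simulation truth record)."""

    spec_id: str
    target_chrom: str
    target_pos: int
    status: str  # "somatic" | "germline"
    carrier_samples: tuple[str, ...]
    vaf: float = 1.0  # fraction of tumor cells carrying the event
    truncation_offset: int = 5_484  # bp downstream of ORF1 start where insert begins
    inserted_length: int = 449
    polyA: bool = True
    invert_3prime: bool = False

    def __post_init__(self) -> None:
        if self.inserted_length < 1:
            raise ValueError("inserted_length must be >= 1")
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError("vaf must lie in [0, 1]")
        if self.status not in ("somatic", "germline"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "germline" and self.vaf != 1.0:
            raise ValueError("germline insertions are constitutional: vaf must be 1")


@dataclass
class ToyReference:
    """A toy genome: chromosomes, one source L1 with a unique 3' tail, genes."""

    chrom_lengths: dict[str, int]
    source_locus: Interval
    unique_tail: Interval
    genes: GeneModel

    def __post_init__(self) -> None:
        if not self.source_locus.contains_interval(self.unique_tail):
            raise ValueError("unique_tail must lie within source_locus")
        for g in self.genes:
            if g.chrom not in self.chrom_lengths:
                raise ValueError(f"gene {g.name} on unknown chromosome {g.chrom}")
            if g.end > self.chrom_lengths[g.chrom]:
                raise ValueError(f"gene {g.name} extends past chromosome end")

    def intronic_fraction(self) -> float:
        return self.genes.intronic_fraction(self.chrom_lengths)

    def validate_specs(self, specs: Sequence[InsertionSpec], sample_ids: Sequence[str]) -> None:
        known = set(sample_ids)
        for spec in specs:
            if spec.target_chrom not in self.chrom_lengths:
                raise ValueError(f"{spec.spec_id}: unknown target chromosome")
            if not (0 <= spec.target_pos < self.chrom_lengths[spec.target_chrom]):
                raise ValueError(f"{spec.spec_id}: target outside chromosome")
            if self.source_locus.contains(spec.target_chrom, spec.target_pos):
                raise ValueError(
                    f"{spec.spec_id}: target inside the source locus (self-insertion unsupported)"
                )
            unknown = set(spec.carrier_samples) - known
            if unknown:
                raise ValueError(f"{spec.spec_id}: unknown carriers {sorted(unknown)}")


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------


def build_reference(config: SimulationConfig) -> ToyReference:
    """Build the toy reference genome implied by a :class:`SimulationConfig`.

    Genes are laid out on a regular grid on every chromosome, skipping a
    window around the source element so insertions near the source stay
    rejectable without gene-model ambiguity.
    """
    if len(config.chrom_lengths) < 2:
        raise ValueError("toy genome needs at least 2 chromosomes")
    src_start = config.source_start
    src_end = src_start + config.source_length
    if src_end > config.chrom_lengths[config.source_chrom]:
        raise ValueError("source element extends past its chromosome")
    source = Interval(config.source_chrom, src_start, src_end)
    tail = Interval(config.source_chrom, src_end - config.unique_tail_length, src_end)

    genes = []
    for chrom, length in sorted(config.chrom_lengths.items()):
        g_index = 0
        pos = config.gene_spacing // 2
        while pos + config.gene_length <= length:
            gene_iv = Interval(chrom, pos, pos + config.gene_length)
            # keep genes clear of the source element and its flanks
            if not (chrom == source.chrom and gene_iv.overlaps(source.expanded(config.gene_length))):
                exons = _exon_layout(pos, config.gene_length, config.n_exons_per_gene, config.exon_length)
                genes.append(
                    Gene(
                        name=f"{chrom}_g{g_index}",
                        chrom=chrom,
                        strand="+" if g_index % 2 == 0 else "-",
                        start=pos,
                        end=pos + config.gene_length,
                        exons=exons,
                    )
                )
                g_index += 1
            pos += config.gene_spacing
    return ToyReference(dict(config.chrom_lengths), source, tail, GeneModel(genes))


def _exon_layout(start: int, gene_length: int, n_exons: int, exon_length: int) -> tuple[tuple[int, int], ...]:
    """Evenly spaced exons: first exon at the transcript start, last ending at
    the transcript end."""
    if n_exons == 1:
        return ((start, start + gene_length),)
    gap = (gene_length - n_exons * exon_length) // (n_exons - 1)
    exons = []
    pos = start
    for i in range(n_exons - 1):
        exons.append((pos, pos + exon_length))
        pos += exon_length + gap
    exons.append((start + gene_length - exon_length, start + gene_length))
    return tuple(exons)


# ---------------------------------------------------------------------------
# Per-sample simulation
# ---------------------------------------------------------------------------


def simulate_sample(
    ref: ToyReference,
    specs: Sequence[InsertionSpec],
    sample_id: str,
    config: SimulationConfig,
) -> dict[str, tuple[list[DiscordantPair], CoverageTrack]]:
    """Simulate tumor and normal observations for one sample.

    Returns ``{"tumor": (pairs, coverage), "normal": (pairs, coverage)}``.
    Somatic insertions leave their footprint in the tumor only; germline
    insertions appear in both tissues at constitutional dosage.
    """
    ref.validate_specs(specs, [sample_id] + [s for sp in specs for s in sp.carrier_samples])
    out = {}
    for tissue in TISSUES:
        rng = np.random.default_rng(
            [config.seed, stable_seed(config.seed, f"{sample_id}:{tissue}")]
        )
        carried = [
            sp
            for sp in specs
            if sample_id in sp.carrier_samples
            and (sp.status == "germline" or tissue == "tumor")
        ]
        pairs = _simulate_pairs(ref, carried, sample_id, tissue, config, rng)
        track = _simulate_coverage(ref, carried, sample_id, tissue, config, rng)
        out[tissue] = (pairs, track)
    return out


def _simulate_pairs(ref, carried, sample_id, tissue, config, rng) -> list[DiscordantPair]:
    pairs: list[DiscordantPair] = []
    counter = 0
    tail = ref.unique_tail
    f_mean = config.fragment_length_mean
    read_len = config.read_length

    for sp in carried:
        vaf = 1.0 if sp.status == "germline" else sp.vaf
        n = rng.poisson(config.expected_pairs_per_copy * vaf)
        chrom_len = ref.chrom_lengths[sp.target_chrom]
        for _ in range(n):
            a_pos = int(rng.integers(tail.start, tail.end - read_len))
            # distal mate lands within fragment distance on either side of the junction
            offset = int(rng.integers(read_len // 2, int(f_mean)))
            if rng.random() < 0.5:
                b_pos, b_strand = sp.target_pos - offset, "+"
            else:
                b_pos, b_strand = sp.target_pos + offset, "-"
            b_pos = int(np.clip(b_pos, 0, chrom_len - read_len))
            pairs.append(
                DiscordantPair(
                    pair_id=f"{sample_id}.{tissue}.p{counter}",
                    sample_id=sample_id,
                    tissue=tissue,
                    mateA=Mate(tail.chrom, a_pos, "+", 60),
                    mateB=Mate(sp.target_chrom, b_pos, b_strand, 60),
                )
            )
            counter += 1

    pairs.extend(
        _noise_pairs(ref, sample_id, tissue, config, rng, start_index=counter)
    )
    return pairs


def _noise_pairs(ref, sample_id, tissue, config, rng, start_index: int) -> list[DiscordantPair]:
    """Background discordant noise: mismapped pairs scattered genome-wide, and
    a trickle of spurious pairs anchored in the unique tail (these exercise
    the mapping-quality and support thresholds downstream)."""
    chroms = sorted(ref.chrom_lengths)
    lengths = np.array([ref.chrom_lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    pairs = []
    counter = start_index

    n_noise = rng.poisson(config.noise_pairs_mean)
    for _ in range(n_noise):
        ca, cb = rng.choice(len(chroms), size=2, p=weights)
        pa = int(rng.integers(0, ref.chrom_lengths[chroms[ca]] - config.read_length))
        pb = int(rng.integers(0, ref.chrom_lengths[chroms[cb]] - config.read_length))
        if ca == cb and abs(pa - pb) <= config.concordance_limit:
            pb = (pb + 10 * config.concordance_limit) % (
                ref.chrom_lengths[chroms[cb]] - config.read_length
            )
        pairs.append(
            DiscordantPair(
                pair_id=f"{sample_id}.{tissue}.p{counter}",
                sample_id=sample_id,
                tissue=tissue,
                mateA=Mate(chroms[ca], pa, "+" if rng.random() < 0.5 else "-", int(rng.integers(0, 61))),
                mateB=Mate(chroms[cb], pb, "+" if rng.random() < 0.5 else "-", int(rng.integers(0, 61))),
            )
        )
        counter += 1

    tail = ref.unique_tail
    n_src = rng.poisson(config.source_noise_pairs_mean)
    for _ in range(n_src):
        cb = rng.choice(len(chroms), p=weights)
        pb = int(rng.integers(0, ref.chrom_lengths[chroms[cb]] - config.read_length))
        pairs.append(
            DiscordantPair(
                pair_id=f"{sample_id}.{tissue}.p{counter}",
                sample_id=sample_id,
                tissue=tissue,
                mateA=Mate(tail.chrom, int(rng.integers(tail.start, tail.end)), "+", int(rng.integers(0, 61))),
                mateB=Mate(chroms[cb], pb, "-", int(rng.integers(0, 61))),
            )
        )
        counter += 1
    return pairs


def _simulate_coverage(ref, carried, sample_id, tissue, config, rng) -> CoverageTrack:
    """Poisson-binned depth; bins overlapping the unique tail are split at the
    tail boundaries and elevated by vaf/2 of the base depth per carried copy
    (one extra haploid tail copy per insertion in a diploid background)."""
    extra_copies = sum(
        (1.0 if sp.status == "germline" else sp.vaf) for sp in carried
    )
    tail_mult = 1.0 + extra_copies / 2.0

    rows = []
    for chrom in sorted(ref.chrom_lengths):
        length = ref.chrom_lengths[chrom]
        edges = set(range(0, length, config.bin_size))
        edges.add(length)
        if chrom == ref.unique_tail.chrom:
            edges.update((ref.unique_tail.start, ref.unique_tail.end))
        edges = sorted(edges)
        for s, e in zip(edges, edges[1:]):
            mult = tail_mult if (
                chrom == ref.unique_tail.chrom
                and s >= ref.unique_tail.start
                and e <= ref.unique_tail.end
            ) else 1.0
            lam = config.coverage_depth * mult * (e - s)
            depth = rng.poisson(lam) / (e - s)
            rows.append((chrom, s, e, depth))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "depth"])
    return CoverageTrack(sample_id=sample_id, tissue=tissue, bins=bins)


def simulate_cohort(
    ref: ToyReference,
    specs: Sequence[InsertionSpec],
    config: SimulationConfig,
    sample_ids: Optional[Sequence[str]] = None,
) -> dict[str, dict[str, tuple[list[DiscordantPair], CoverageTrack]]]:
    """Simulate every sample of a cohort; returns {sample_id: simulate_sample(...)}."""
    if sample_ids is None:
        sample_ids = [f"S{i:03d}" for i in range(config.n_samples)]
    ref.validate_specs(specs, sample_ids)
    return {sid: simulate_sample(ref, specs, sid, config) for sid in sample_ids}


# ---------------------------------------------------------------------------
# Genotype simulation
# ---------------------------------------------------------------------------


def simulate_genotypes(
    n_samples: int,
    n_markers: int,
    marker_positions: Optional[np.ndarray] = None,
    founder: Optional[dict] = None,
    seed: int = 0,
    chrom: str = "chrB",
    allele_freqs: Optional[np.ndarray] = None,
    missing_rate: float = 0.01,
    sample_ids: Optional[Sequence[str]] = None,
    marker_spacing: int = 1_250,
) -> GenotypeMatrix:
    """Simulate a biallelic genotype matrix with an optional founder haplotype.

    ``founder`` is ``{"carrier_ids": [...], "haplotype_interval": (start, end)}``:
    carriers all inherit one shared haplotype across the interval (so no pair
    of carriers can be opposing homozygotes there); everything else is drawn
    independently under Hardy-Weinberg at per-marker allele frequencies
    (default Uniform(0.1, 0.5), emulating common array markers).
    """
    if n_markers < 2:
        raise ValueError("need at least 2 markers")
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    sample_ids = list(sample_ids)
    if marker_positions is None:
        marker_positions = np.arange(1, n_markers + 1) * marker_spacing
    marker_positions = np.asarray(marker_positions, dtype=np.int64)
    if allele_freqs is None:
        allele_freqs = rng.uniform(0.1, 0.5, size=n_markers)
    allele_freqs = np.asarray(allele_freqs, dtype=float)

    calls = rng.binomial(2, allele_freqs, size=(n_samples, n_markers)).astype(np.int8)

    if founder is not None and founder.get("carrier_ids"):
        carriers = [sample_ids.index(c) for c in founder["carrier_ids"]]
        lo, hi = founder["haplotype_interval"]
        if lo < marker_positions[0] or hi > marker_positions[-1]:
            raise ValueError("founder haplotype interval outside marker range")
        in_iv = (marker_positions >= lo) & (marker_positions <= hi)
        shared_hap = rng.binomial(1, allele_freqs[in_iv])
        for ci in carriers:
            other_hap = rng.binomial(1, allele_freqs[in_iv])
            calls[ci, in_iv] = (shared_hap + other_hap).astype(np.int8)

    if missing_rate > 0:
        miss = rng.random((n_samples, n_markers)) < missing_rate
        if founder is not None and founder.get("carrier_ids"):
            # keep the planted haplotype fully observed in carriers
            carrier_rows = np.array([sample_ids.index(c) for c in founder["carrier_ids"]])
            miss[np.ix_(carrier_rows, np.nonzero(in_iv)[0])] = False
        calls[miss] = MISSING

    return GenotypeMatrix(chrom=chrom, sample_ids=sample_ids, positions=marker_positions, calls=calls)


# ---------------------------------------------------------------------------
# Truth files & junction rendering
# ---------------------------------------------------------------------------


def write_truth(specs: Sequence[InsertionSpec], config: SimulationConfig, prefix) -> tuple[Path, Path]:
    """Write planted-insertion truth as BED6 + a JSON sidecar.

    BED name is the spec id; BED score is the expected per-carrier support
    (discordant-pair count) implied by the simulation model.  Downstream
    recovery tests read truth only from these files.
    """
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    json_path = prefix.with_suffix(".json")
    with open(bed_path, "w") as fh:
        for sp in sorted(specs, key=lambda s: (s.target_chrom, s.target_pos, s.spec_id)):
            vaf = 1.0 if sp.status == "germline" else sp.vaf
            score = int(round(config.expected_pairs_per_copy * vaf))
            fh.write(
                f"{sp.target_chrom}\t{sp.target_pos}\t{sp.target_pos + 1}\t"
                f"{sp.spec_id}\t{score}\t.\n"
            )
    with open(json_path, "w") as fh:
        json.dump([dataclasses.asdict(sp) for sp in specs], fh, indent=1, default=list)
    return bed_path, json_path


def read_truth(json_path) -> list[InsertionSpec]:
    with open(json_path) as fh:
        records = json.load(fh)
    return [
        InsertionSpec(**{**r, "carrier_samples": tuple(r["carrier_samples"])})
        for r in records
    ]


# toy source-element sequence model used only for junction rendering
_BASES = np.array(list("ACGT"))


def junction_sequences(spec: InsertionSpec, config: SimulationConfig, flank: int = 30) -> dict[str, str]:
    """Render literal sequence around the two junctions of a planted event.

    Produces a deterministic toy L1 sequence (seeded from the simulation
    seed), applies the 5' truncation (insert starts ``truncation_offset`` bp
    downstream of the ORF1 start), an optional 3'-end inversion, and the
    poly(A) tail.  Used for worked examples and sequence-level tests, not by
    the detection pipeline.
    """
    rng = np.random.default_rng([config.seed, 0xE1])
    l1 = "".join(rng.choice(_BASES, size=config.source_length))
    target_flank_5 = "".join(rng.choice(_BASES, size=flank))
    target_flank_3 = "".join(rng.choice(_BASES, size=flank))

    start = spec.truncation_offset
    insert = l1[start : start + spec.inserted_length]
    if spec.invert_3prime:
        half = len(insert) // 2
        comp = str.maketrans("ACGT", "TGCA")
        insert = insert[:half] + insert[half:].translate(comp)[::-1]
    tail = "A" * config.polya_length if spec.polyA else ""
    return {
        "five_prime": target_flank_5 + insert[:flank],
        "three_prime": (insert + tail)[-flank:] + target_flank_3,
        "insert": insert + tail,
    }


def write_junction_fasta(specs: Sequence[InsertionSpec], config: SimulationConfig, path) -> Path:
    """Optional FASTA emitter for the literal junction sequences of each spec."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = []
    for sp in specs:
        seqs = junction_sequences(sp, config)
        for side in ("five_prime", "three_prime"):
            records.append(
                SeqRecord(Seq(seqs[side]), id=f"{sp.spec_id}|{side}", description="")
            )
    path = Path(path)
    SeqIO.write(records, str(path), "fasta")
    return path
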