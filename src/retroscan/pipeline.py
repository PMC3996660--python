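"""End-to-end orchestration: simulate -> detect -> annotate -> stats -> cnv
-> haplotype, with a reproducible run manifest.

A single global seed expands deterministically into per-stage seeds
(SHA-256 of ``seed:stage``), so any stage can be re-run in isolation.  The
manifest records the verbatim configuration, every derived seed, the
filter-chain counts and all summary statistics; re-running from the same
config reproduces all outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io_formats
from .annotation_stats import (
    RecurrenceConfig,
    annotate_calls,
    annotate_targets,
    intron_preference_test,
    recurrence_permutation_test,
    tally_regions,
)
from .copy_number import compare_ratio_groups, region_coverage_ratio
from .core import Interval, stable_seed
from .haplotype_analysis import carrier_length_test
from .insertion_detection import CallerConfig, detect_case, genotype_germline
from .synthetic_data import (
    InsertionSpec,
    SimulationConfig,
    ToyReference,
    build_reference,
    simulate_genotypes,
    simulate_sample,
    write_truth,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run on simulated data."""

    seed: int = 0
    out_dir: str = "retroscan_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    recurrence: RecurrenceConfig = field(default_factory=RecurrenceConfig)
    max_gap: int = 2000
    n_markers: int = 1200
    log_level: str = "INFO"
    # insertion plan: somatic events per carrier drawn from this vaf ladder,
    # plus one germline polymorphism shared by `germline_carriers` samples
    somatic_vafs: tuple[float, ...] = (0.3, 0.4, 0.5, 0.7, 1.0)
    germline_carriers: int = 3

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_insertion_plan(ref: ToyReference, config: RunConfig) -> list[InsertionSpec]:
    """The demo cohort's planted truth: one somatic insertion per vaf in the
    ladder, spread over the first samples, plus one germline polymorphism on
    a gene-free stretch of chrB shared by the first `germline_carriers`."""
    rng = np.random.default_rng(stable_seed(config.seed, "insertion-plan"))
    samples = [f"S{i:03d}" for i in range(config.simulation.n_samples)]
    specs = []
    target_chroms = [c for c in sorted(ref.chrom_lengths) if c != ref.source_locus.chrom]
    for i, vaf in enumerate(config.somatic_vafs):
        chrom = target_chroms[i % len(target_chroms)]
        pos = int(rng.integers(50_000, ref.chrom_lengths[chrom] - 50_000))
        specs.append(
            InsertionSpec(
                spec_id=f"som{i}",
                target_chrom=chrom,
                target_pos=pos,
                status="somatic",
                carrier_samples=(samples[i % len(samples)],),
                vaf=vaf,
                truncation_offset=int(rng.integers(4_000, 5_800)),
                inserted_length=int(rng.integers(200, 1_500)),
            )
        )
    germ_chrom = target_chroms[0]
    specs.append(
        InsertionSpec(
            spec_id="germ0",
            target_chrom=germ_chrom,
            target_pos=ref.chrom_lengths[germ_chrom] // 2 + 17_000,
            status="germline",
            carrier_samples=tuple(samples[: config.germline_carriers]),
            vaf=1.0,
            invert_3prime=True,
        )
    )
    return specs


def run_pipeline(config: RunConfig, specs: Optional[Sequence[InsertionSpec]] = None) -> dict:
    """Execute the full pipeline; returns the run manifest (also written to
    ``out_dir/manifest.json``)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim = dataclasses.replace(config.simulation, seed=stable_seed(config.seed, "simulate"))
    ref = build_reference(sim)
    if specs is None:
        specs = default_insertion_plan(ref, config)
    ref.validate_specs(specs, [f"S{i:03d}" for i in range(sim.n_samples)])
    samples = [f"S{i:03d}" for i in range(sim.n_samples)]

    manifest: dict = {
        "config": config.to_dict(),
        "seeds": {
            "simulate": sim.seed,
            "genotypes": stable_seed(config.seed, "genotypes"),
            "recurrence": stable_seed(config.seed, "recurrence"),
        },
        "reference": {
            "chrom_lengths": ref.chrom_lengths,
            "source_locus": str(ref.source_locus),
            "unique_tail": str(ref.unique_tail),
            "n_genes": len(ref.genes),
            "intronic_fraction": ref.intronic_fraction(),
        },
        "outputs": {},
        "counts": {},
        "stats": {},
    }

    # ------------------------------------------------------------ simulate
    truth_bed, truth_json = write_truth(specs, sim, out / "truth")
    manifest["outputs"]["truth_bed"] = truth_bed.name
    manifest["outputs"]["truth_json"] = truth_json.name
    io_formats.write_gene_model(ref.genes, out / "genes.bed12")
    manifest["outputs"]["genes"] = "genes.bed12"

    tracks = {}
    pair_files = {}
    for sid in samples:
        tissues = simulate_sample(ref, specs, sid, sim)
        for tissue, (pairs, track) in tissues.items():
            io_formats.write_pairs(pairs, out / f"{sid}.{tissue}.pairs.tsv")
            io_formats.write_coverage(track, out / f"{sid}.{tissue}.bedgraph")
            tracks[(sid, tissue)] = track
            pair_files[(sid, tissue)] = pairs

    # -------------------------------------------------------------- detect
    counts = {"pairs": 0, "source_anchored": 0, "clusters": 0, "calls": 0, "somatic": 0}
    somatic_calls, germline_calls = [], []
    for sid in samples:
        res = detect_case(
            pair_files[(sid, "tumor")], pair_files[(sid, "normal")],
            ref.source_locus, config.caller,
        )
        for tissue in ("tumor", "normal"):
            counts["pairs"] += res["counts"][tissue]["pairs"]
            counts["source_anchored"] += res["counts"][tissue]["source_anchored"]
        counts["clusters"] += res["counts"]["tumor"]["clusters"]
        counts["calls"] += res["counts"]["tumor"]["calls"]
        counts["somatic"] += res["counts"]["somatic"]
        somatic_calls.extend(res["somatic"])
        germline_calls.extend(res["germline"])
    manifest["counts"].update(counts)

    all_calls = annotate_calls(somatic_calls + germline_calls, ref.genes)
    contigs = {c: l for c, l in ref.chrom_lengths.items()}
    io_formats.write_calls(all_calls, out / "calls.vcf", contigs=contigs)
    manifest["outputs"]["calls"] = "calls.vcf"

    polymorphisms = genotype_germline(
        [c for c in all_calls if c.status == "germline"],
        n_cohort=len(samples),
        anchor_tolerance_bp=config.caller.anchor_tolerance_bp,
    )
    manifest["counts"]["germline_polymorphisms"] = len(polymorphisms)
    manifest["stats"]["germline_frequencies"] = [
        {"target": str(p.target), "carriers": list(p.carriers), "frequency": p.frequency}
        for p in polymorphisms
    ]

    # ------------------------------------------------------------ annotate
    somatic_annotated = [c for c in all_calls if c.status == "somatic"]
    annotations = annotate_targets(somatic_annotated, ref.genes)
    tally = tally_regions(annotations)
    manifest["stats"]["region_tally"] = tally
    with open(out / "annotations.tsv", "w") as fh:
        fh.write("call_id\tregion_class\tgenes\n")
        for a in annotations:
            fh.write(f"{a.call_id}\t{a.region_class}\t{','.join(a.gene_names)}\n")
    manifest["outputs"]["annotations"] = "annotations.tsv"

    # --------------------------------------------------------------- stats
    n_somatic = len(somatic_annotated)
    if n_somatic > 0:
        chi = intron_preference_test(tally["intron"], n_somatic, ref.intronic_fraction())
        manifest["stats"]["intron_preference"] = chi.as_dict()
        rec_cfg = dataclasses.replace(
            config.recurrence, seed=stable_seed(config.seed, "recurrence")
        )
        rec = recurrence_permutation_test(rec_cfg)
        manifest["stats"]["gene_recurrence"] = rec.as_dict()
    else:
        logger.info("no somatic calls: skipping intron-preference and recurrence tests")
        manifest["stats"]["skipped"] = "no somatic calls; target-level tests not run"

    # ----------------------------------------------------------------- cnv
    carrier_ids = sorted(
        {c.sample_id for c in all_calls if c.status in ("somatic", "germline")}
    )
    ratios = {
        sid: region_coverage_ratio(tracks[(sid, "tumor")], ref.unique_tail)
        for sid in samples
    }
    carrier_ratios = [ratios[s] for s in samples if s in carrier_ids]
    other_ratios = [ratios[s] for s in samples if s not in carrier_ids]
    manifest["stats"]["coverage_ratios"] = {s: ratios[s].ratio for s in samples}
    if len(carrier_ratios) >= 2 and len(other_ratios) >= 2:
        cnv = compare_ratio_groups(carrier_ratios, other_ratios)
        manifest["stats"]["coverage_ratio_test"] = cnv.as_dict()
    else:
        logger.info("coverage-ratio test skipped: group below 2 samples")

    # ----------------------------------------------------------- haplotype
    germ_specs = [sp for sp in specs if sp.status == "germline"]
    if germ_specs:
        sp = germ_specs[0]
        gt_seed = manifest["seeds"]["genotypes"]
        chrom_len = ref.chrom_lengths[sp.target_chrom]
        positions = np.linspace(1, chrom_len - 1, config.n_markers).astype(np.int64)
        half = chrom_len // 4
        founder = {
            "carrier_ids": list(sp.carrier_samples),
            "haplotype_interval": (
                max(int(positions[0]), sp.target_pos - half),
                min(int(positions[-1]), sp.target_pos + half),
            ),
        }
        matrix = simulate_genotypes(
            n_samples=len(samples), n_markers=config.n_markers,
            marker_positions=positions, founder=founder, seed=gt_seed,
            chrom=sp.target_chrom, sample_ids=samples,
        )
        io_formats.write_genotypes(matrix, out / "genotypes.tsv")
        manifest["outputs"]["genotypes"] = "genotypes.tsv"
        carriers = list(sp.carrier_samples)
        others = [s for s in samples if s not in carriers]
        if len(carriers) >= 2 and len(others) >= 2:
            hap = carrier_length_test(matrix, carriers, others, sp.target_pos, config.max_gap)
            manifest["stats"]["haplotype_length_test"] = hap.as_dict()

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    manifest["outputs"]["manifest"] = "manifest.json"
    return manifest
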