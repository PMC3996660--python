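"""Readers and writers for the pipeline's external representations.

Formats supported:

* discordant pairs — SAM (read-only, via pysam) and a TSV dialect (read/write);
* gene models — BED12 and GFF3 (read), BED12 (write);
* coverage — bedGraph (read/write);
* insertion calls — VCF 4.2 (read/write, via pysam);
* genotype matrices — TSV, one chromosome per file (read/write).

Positions in SAM, GFF3 and VCF are 1-based and converted to the internal
0-based half-open convention at this boundary; BED and bedGraph are already
half-open.  The pair-TSV dialect uses 1-based positions (SAM-like).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .core import (
    CoverageTrack,
    DiscordantPair,
    Gene,
    GeneModel,
    GenotypeMatrix,
    Interval,
    Mate,
    MISSING,
)

logger = logging.getLogger(__name__)

DEFAULT_CONCORDANCE_LIMIT = 600  # fragment_length_mean + 4 sd at default library

PAIR_TSV_COLUMNS = [
    "pair_id", "sample", "tissue",
    "chromA", "posA", "strandA", "mapqA",
    "chromB", "posB", "strandB", "mapqB",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


# ---------------------------------------------------------------------------
# Discordant pairs
# ---------------------------------------------------------------------------


def read_pairs(
    path,
    dialect: str,
    sample_id: Optional[str] = None,
    tissue: Optional[str] = None,
    concordance_limit: int = DEFAULT_CONCORDANCE_LIMIT,
) -> list[DiscordantPair]:
    """Read aligned read pairs and keep only the discordant ones.

    ``dialect`` is ``"sam"`` or ``"tsv"``.  SAM records carry no sample or
    tissue labels, so both must be supplied for that dialect.  Pairs passing
    the concordance test (same chromosome, separation <= limit) are dropped
    with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        pairs = _read_pairs_tsv(path)
    elif dialect == "sam":
        if sample_id is None or tissue is None:
            raise ValueError("SAM dialect needs explicit sample_id and tissue")
        pairs = _read_pairs_sam(path, sample_id, tissue)
    else:
        raise ValueError(f"unknown pair dialect {dialect!r}")

    kept = [p for p in pairs if p.is_discordant(concordance_limit)]
    if len(kept) < len(pairs):
        logger.info(
            "dropped %d concordant of %d pairs from %s",
            len(pairs) - len(kept), len(pairs), path,
        )
    return kept


def _read_pairs_tsv(path: Path) -> list[DiscordantPair]:
    pairs = []
    with open(path) as fh:
        header = fh.readline()
        if header and header.rstrip("\n").split("\t") != PAIR_TSV_COLUMNS:
            raise FormatError(f"{path}: line 1: not a pair TSV header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(PAIR_TSV_COLUMNS):
                raise FormatError(f"{path}: line {lineno}: expected {len(PAIR_TSV_COLUMNS)} columns")
            try:
                pairs.append(
                    DiscordantPair(
                        pair_id=fields[0], sample_id=fields[1], tissue=fields[2],
                        mateA=Mate(fields[3], int(fields[4]) - 1, fields[5], int(fields[6])),
                        mateB=Mate(fields[7], int(fields[8]) - 1, fields[9], int(fields[10])),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return pairs


def _read_pairs_sam(path: Path, sample_id: str, tissue: str) -> list[DiscordantPair]:
    """Pair SAM records by QNAME, using RNEXT/PNEXT only as a consistency
    check; unsorted input is accepted."""
    by_name: dict[str, pysam.AlignedSegment] = {}
    pairs = []
    try:
        sam = pysam.AlignmentFile(str(path), "r", check_sq=False)
    except ValueError as exc:
        raise FormatError(f"{path}: not parseable as SAM: {exc}") from exc
    with sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            mate = by_name.pop(rec.query_name, None)
            if mate is None:
                by_name[rec.query_name] = rec
                continue
            first, second = (mate, rec) if mate.is_read1 else (rec, mate)
            pairs.append(
                DiscordantPair(
                    pair_id=rec.query_name, sample_id=sample_id, tissue=tissue,
                    mateA=Mate(first.reference_name, first.reference_start,
                               "-" if first.is_reverse else "+", first.mapping_quality),
                    mateB=Mate(second.reference_name, second.reference_start,
                               "-" if second.is_reverse else "+", second.mapping_quality),
                )
            )
    if by_name:
        logger.info("%s: %d reads had no mapped mate in file", path, len(by_name))
    return pairs


def write_pairs(pairs: Sequence[DiscordantPair], path) -> Path:
    """Write pairs in the TSV dialect (1-based positions)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(PAIR_TSV_COLUMNS) + "\n")
        for p in pairs:
            fh.write(
                f"{p.pair_id}\t{p.sample_id}\t{p.tissue}\t"
                f"{p.mateA.chrom}\t{p.mateA.pos + 1}\t{p.mateA.strand}\t{p.mateA.mapq}\t"
                f"{p.mateB.chrom}\t{p.mateB.pos + 1}\t{p.mateB.strand}\t{p.mateB.mapq}\n"
            )
    return path


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


def read_gene_model(path, format: str) -> GeneModel:
    """Read a gene model from BED12 or GFF3.

    BED12 blocks become exons.  In GFF3, ``exon`` features are grouped by
    their gene ancestor (via gffutils).  Overlapping exons within one gene
    are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "bed12":
        return _read_gene_model_bed12(path)
    if format == "gff3":
        return _read_gene_model_gff3(path)
    raise ValueError(f"unknown gene model format {format!r}")


def _read_gene_model_bed12(path: Path) -> GeneModel:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}: line {lineno}: BED12 needs 12 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name, strand = fields[3], fields[5]
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}: line {lineno}: block count mismatch")
            exons = tuple((start + s, start + s + sz) for s, sz in zip(starts, sizes))
            try:
                genes.append(Gene(name, chrom, strand, start, end, exons))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return GeneModel(genes)


def _read_gene_model_gff3(path: Path) -> GeneModel:
    import gffutils

    with open(path) as fh:
        head = fh.readline()
    if not head.startswith("##gff-version"):
        raise FormatError(f"{path}: missing ##gff-version pragma")
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = sorted(
            (f.start - 1, f.end)  # GFF3 is 1-based inclusive
            for f in db.children(g, featuretype="exon")
        )
        name = g.attributes.get("Name", [g.id])[0]
        try:
            genes.append(Gene(name, g.seqid, g.strand, g.start - 1, g.end, tuple(exons)))
        except ValueError as exc:
            raise FormatError(f"{path}: gene {name}: {exc}") from exc
    return GeneModel(genes)


def write_gene_model(model: GeneModel, path) -> Path:
    """Write a gene model as BED12 (one transcript per gene)."""
    path = Path(path)
    with open(path, "w") as fh:
        for g in sorted(model, key=lambda g: (g.chrom, g.start, g.name)):
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, _ in g.exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n"
            )
    return path


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------


def read_coverage(path, sample_id: str, tissue: str) -> CoverageTrack:
    """Read a bedGraph coverage track (chrom, start, end, depth)."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "depth"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "depth": float},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: not parseable as bedGraph: {exc}") from exc
    return CoverageTrack(sample_id=sample_id, tissue=tissue, bins=df)


def write_coverage(track: CoverageTrack, path) -> Path:
    path = Path(path)
    track.bins.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")
    return path


# ---------------------------------------------------------------------------
# Insertion calls (VCF)
# ---------------------------------------------------------------------------

_VCF_INFO_FIELDS = [
    ("SVTYPE", "1", "String", "Structural variant type"),
    ("SRC", "1", "String", "Source locus of the inserted sequence (chrom:start-end, half-open)"),
    ("SUPPORT", "1", "Integer", "Number of supporting discordant read pairs"),
    ("STATUS", "1", "String", "somatic, germline, or unfiltered"),
    ("SAMPLE", "1", "String", "Sample the call was made in"),
    ("TISSUE", "1", "String", "Tissue the call was made in"),
    ("ENDPOS", "1", "Integer", "End of the target interval (half-open)"),
    ("REGION", "1", "String", "Target region class: intron, exon or intergenic"),
    ("GENE", ".", "String", "Gene(s) containing the target"),
]


def write_calls(calls, path, contigs: Optional[dict[str, int]] = None) -> Path:
    """Write insertion calls as VCF 4.2 with one INS record per call."""
    from .insertion_detection import InsertionCall  # cycle guard

    path = Path(path)
    header = pysam.VariantHeader()
    if contigs is None:
        contigs = {}
        for c in calls:
            contigs[c.target.chrom] = max(contigs.get(c.target.chrom, 0), c.target.end + 1)
    for name, length in sorted(contigs.items()):
        header.contigs.add(name, length=length)
    for name, number, vtype, desc in _VCF_INFO_FIELDS:
        header.info.add(name, number, vtype, desc)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in sorted(calls, key=lambda c: (c.target.chrom, c.target.start)):
            rec = vcf.new_record(
                contig=call.target.chrom,
                start=call.target.start,
                stop=call.target.start + 1,
                alleles=("N", "<INS>"),
                id=call.call_id,
            )
            rec.info["SVTYPE"] = "INS"
            rec.info["SRC"] = f"{call.source_locus.chrom}:{call.source_locus.start}-{call.source_locus.end}"
            rec.info["SUPPORT"] = call.support
            rec.info["STATUS"] = call.status
            rec.info["SAMPLE"] = call.sample_id
            rec.info["TISSUE"] = call.tissue
            rec.info["ENDPOS"] = call.target.end
            if call.region_class is not None:
                rec.info["REGION"] = call.region_class
            if call.gene_names:
                rec.info["GENE"] = list(call.gene_names)
            vcf.write(rec)
    return path


def read_calls(path):
    """Read a VCF produced by :func:`write_calls` back into InsertionCall objects."""
    from .insertion_detection import InsertionCall

    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.info.get("SVTYPE") != "INS":
                raise FormatError(f"{path}: record {rec.id}: not an INS call")
            src_chrom, span = rec.info["SRC"].split(":")
            s, e = span.split("-")
            calls.append(
                InsertionCall(
                    call_id=rec.id,
                    sample_id=rec.info["SAMPLE"],
                    tissue=rec.info["TISSUE"],
                    target=Interval(rec.contig, rec.start, rec.info["ENDPOS"]),
                    support=rec.info["SUPPORT"],
                    pair_ids=(),
                    min_mapq_used=0,
                    status=rec.info["STATUS"],
                    source_locus=Interval(src_chrom, int(s), int(e)),
                    region_class=rec.info.get("REGION"),
                    gene_names=tuple(rec.info.get("GENE", ())),
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Genotype matrices
# ---------------------------------------------------------------------------


def read_genotypes(path, chrom: str = "chr?") -> GenotypeMatrix:
    """Read a genotype matrix TSV: header of marker positions, one row per
    sample, calls in {0,1,2,NA}."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "sample":
            raise FormatError(f"{path}: first header column must be 'sample'")
        try:
            positions = np.array([int(x) for x in header[1:]], dtype=np.int64)
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer marker position: {exc}") from exc
        sample_ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(positions) + 1:
                raise FormatError(f"{path}: line {lineno}: wrong column count")
            sample_ids.append(fields[0])
            try:
                rows.append([MISSING if v == "NA" else int(v) for v in fields[1:]])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return GenotypeMatrix(
        chrom=chrom, sample_ids=sample_ids,
        positions=positions, calls=np.array(rows, dtype=np.int8),
    )


def write_genotypes(matrix: GenotypeMatrix, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(str(p) for p in matrix.positions) + "\n")
        for sid, row in zip(matrix.sample_ids, matrix.calls):
            fh.write(sid + "\t" + "\t".join("NA" if v == MISSING else str(v) for v in row) + "\n")
    return path
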