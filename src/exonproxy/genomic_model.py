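"""Core genomic data model: intervals, annotation records, and GTF/BED/FASTA I/O.

Coordinates are 1-based and inclusive throughout (the GTF convention);
conversion to/from BED's 0-based half-open system happens only at the BED
readers/writers. Interval arithmetic uses closed-interval semantics: two
intervals that touch with a gap of zero bases ([1,10] and [11,20]) merge,
a one-base gap does not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

# rank used by the deterministic GTF writer: gene < transcript < exon < other
_FEATURE_RANK = {"gene": 0, "transcript": 1, "exon": 2}


class GtfParseError(ValueError):
    """A malformed GTF line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


class IntervalContractError(ValueError):
    """Interval arithmetic called with mixed seqnames or strands."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded span on a named sequence, 1-based inclusive at both ends."""

    seqname: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seqname == other.seqname
            and self.start <= other.end
            and other.start <= self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.seqname != other.seqname:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seqname == other.seqname
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:
        return f"{self.seqname}:{self.start}-{self.end}({self.strand})"


def _check_homogeneous(intervals: Sequence[GenomicInterval], what: str) -> None:
    seqnames = {iv.seqname for iv in intervals}
    strands = {iv.strand for iv in intervals}
    if len(seqnames) > 1:
        raise IntervalContractError(f"{what}: mixed seqnames {sorted(seqnames)}")
    if len(strands) > 1:
        raise IntervalContractError(f"{what}: mixed strands {sorted(strands)}")


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of closed intervals on one seqname/strand.

    Returns a sorted, pairwise-disjoint list covering exactly the union of
    the input bases. Adjacent intervals (zero-base gap) are merged.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    if not ivs:
        return []
    _check_homogeneous(ivs, "merge_intervals")
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start <= last.end + 1:  # overlap or zero-gap adjacency
            if iv.end > last.end:
                merged[-1] = replace(last, end=iv.end)
        else:
            merged.append(iv)
    return merged


def subtract_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Bases in ``a`` and not in ``b``, merged and sorted."""
    a_merged = merge_intervals(a)
    b_list = list(b)
    if not a_merged:
        return []
    if not b_list:
        return a_merged
    _check_homogeneous(a_merged + b_list, "subtract_intervals")
    b_merged = merge_intervals(b_list)
    out: list[GenomicInterval] = []
    for iv in a_merged:
        cur_start = iv.start
        for cut in b_merged:
            if cut.end < cur_start or cut.start > iv.end:
                continue
            if cut.start > cur_start:
                out.append(replace(iv, start=cur_start, end=cut.start - 1))
            cur_start = max(cur_start, cut.end + 1)
            if cur_start > iv.end:
                break
        if cur_start <= iv.end:
            out.append(replace(iv, start=cur_start, end=iv.end))
    return out


def intersect_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Bases in both ``a`` and ``b``, merged and sorted."""
    a_merged = merge_intervals(a)
    b_list = list(b)
    if not a_merged or not b_list:
        return []
    return subtract_intervals(a_merged, subtract_intervals(a_merged, b_list))


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    """Number of distinct bases covered (inputs may overlap)."""
    return sum(iv.length for iv in merge_intervals(intervals))


# ---------------------------------------------------------------------------
# GTF records and hierarchical models
# ---------------------------------------------------------------------------


@dataclass
class FeatureRecord:
    """One GTF line: an interval plus type, source, score, frame, attributes.

    ``attributes`` is an ordered mapping and is written back in the same
    order it was parsed, in Ensembl syntax (``key "value";`` pairs).
    """

    interval: GenomicInterval
    feature_type: str
    source: str = "exonproxy"
    score: Optional[float] = None
    frame: Optional[int] = None
    attributes: dict[str, str] = field(default_factory=dict)

    @property
    def gene_id(self) -> Optional[str]:
        return self.attributes.get("gene_id")

    @property
    def transcript_id(self) -> Optional[str]:
        return self.attributes.get("transcript_id")

    def to_gtf_line(self) -> str:
        iv = self.interval
        score = "." if self.score is None else format(self.score, "g")
        frame = "." if self.frame is None else str(self.frame)
        attrs = " ".join(f'{k} "{v}";' for k, v in self.attributes.items())
        return "\t".join(
            [
                iv.seqname,
                self.source,
                self.feature_type,
                str(iv.start),
                str(iv.end),
                score,
                iv.strand,
                frame,
                attrs,
            ]
        )


def _parse_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise GtfParseError(lineno, f"malformed attribute {chunk!r}")
        key, _, value = chunk.partition(" ")
        value = value.strip()
        if len(value) >= 2 and value[0] == '"' and value[-1] == '"':
            value = value[1:-1]
        attrs[key] = value
    return attrs


def parse_gtf_line(line: str, lineno: int = 0) -> FeatureRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 9:
        raise GtfParseError(lineno, f"expected 9 tab-separated columns, got {len(fields)}")
    seqname, source, ftype, start_s, end_s, score_s, strand, frame_s, attr_s = fields
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise GtfParseError(lineno, f"non-integer coordinates {start_s!r}/{end_s!r}") from exc
    if strand not in STRANDS:
        raise GtfParseError(lineno, f"bad strand {strand!r}")
    try:
        interval = GenomicInterval(seqname, start, end, strand)
    except ValueError as exc:
        raise GtfParseError(lineno, str(exc)) from exc
    score = None if score_s == "." else float(score_s)
    frame = None if frame_s == "." else int(frame_s)
    if frame is not None and frame not in (0, 1, 2):
        raise GtfParseError(lineno, f"bad frame {frame_s!r}")
    attrs = _parse_attributes(attr_s, lineno)
    return FeatureRecord(interval, ftype, source, score, frame, attrs)


@dataclass
class TranscriptModel:
    """A transcript: ordered exons plus optional CDS/UTR/stop-codon records."""

    transcript_id: str
    gene_id: str
    seqname: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    other_records: list[FeatureRecord] = field(default_factory=list)
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        for iv in self.exons:
            if iv.seqname != self.seqname or iv.strand != self.strand:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon {iv} disagrees with "
                    f"{self.seqname}({self.strand})"
                )
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start <= prev.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons {prev} / {nxt}"
                )

    @property
    def spliced_length(self) -> int:
        return sum(iv.length for iv in self.exons)

    @property
    def span(self) -> GenomicInterval:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        return GenomicInterval(
            self.seqname, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def records_of_type(self, feature_type: str) -> list[FeatureRecord]:
        return [r for r in self.other_records if r.feature_type == feature_type]


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    transcripts: list[TranscriptModel] = field(default_factory=list)
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.transcripts:
            seqnames = {t.seqname for t in self.transcripts}
            strands = {t.strand for t in self.transcripts}
            if len(seqnames) > 1 or len(strands) > 1:
                raise ValueError(
                    f"gene {self.gene_id}: transcripts span multiple "
                    f"seqnames/strands ({seqnames}, {strands})"
                )

    @property
    def seqname(self) -> str:
        return self.transcripts[0].seqname

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def biotype(self) -> str:
        return self.attributes.get("gene_biotype", "protein_coding")

    @property
    def span(self) -> GenomicInterval:
        exons = [iv for t in self.transcripts for iv in t.exons]
        if not exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        return GenomicInterval(
            self.seqname,
            min(iv.start for iv in exons),
            max(iv.end for iv in exons),
            self.strand,
        )

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(f"gene {self.gene_id} has no transcript {transcript_id}")

    def exonic_union(self) -> list[GenomicInterval]:
        return merge_intervals(iv for t in self.transcripts for iv in t.exons)


@dataclass
class Annotation:
    """A parsed annotation: flat records plus assembled gene models.

    ``records`` (in file order) is the source of truth for writing; the
    ``genes`` list is an assembled hierarchical view. ``orphans`` are
    sub-gene features that lacked the ids needed to attach them; they are
    reported and written back verbatim, never dropped.
    """

    records: list[FeatureRecord] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    orphans: list[FeatureRecord] = field(default_factory=list)
    header: list[str] = field(default_factory=list)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"no gene with gene_id {gene_id!r}")

    def gene_by_name(self, gene_name: str) -> GeneModel:
        for g in self.genes:
            if g.gene_name == gene_name:
                return g
        raise KeyError(f"no gene with gene_name {gene_name!r}")

    def gene_ids(self) -> set[str]:
        return {r.gene_id for r in self.records if r.gene_id}


def assemble_genes(
    records: Sequence[FeatureRecord],
) -> tuple[list[GeneModel], list[FeatureRecord]]:
    """Group flat records into GeneModels by gene_id/transcript_id.

    Returns (genes, orphans). A gene-level record is optional: genes are
    synthesized from transcripts when absent. Sub-gene records without a
    transcript_id (or any record without a gene_id) are orphans.
    """
    gene_attrs: dict[str, dict[str, str]] = {}
    tx_records: dict[str, dict[str, FeatureRecord | list]] = {}
    gene_order: list[str] = []
    tx_of_gene: dict[str, list[str]] = {}
    orphans: list[FeatureRecord] = []

    for rec in records:
        gid = rec.gene_id
        if gid is None:
            orphans.append(rec)
            logger.warning("orphan record (no gene_id): %s %s", rec.feature_type, rec.interval)
            continue
        if gid not in tx_of_gene:
            gene_order.append(gid)
            tx_of_gene[gid] = []
        if rec.feature_type == "gene":
            gene_attrs[gid] = dict(rec.attributes)
            continue
        tid = rec.transcript_id
        if tid is None:
            orphans.append(rec)
            logger.warning(
                "orphan record (no transcript_id): %s %s", rec.feature_type, rec.interval
            )
            continue
        if tid not in tx_records:
            tx_records[tid] = {"gene_id": gid, "exons": [], "other": [], "attrs": {}}
            tx_of_gene[gid].append(tid)
        entry = tx_records[tid]
        if rec.feature_type == "transcript":
            entry["attrs"] = dict(rec.attributes)
        elif rec.feature_type == "exon":
            entry["exons"].append(rec.interval)
        else:
            entry["other"].append(rec)

    genes: list[GeneModel] = []
    for gid in gene_order:
        transcripts = []
        for tid in tx_of_gene[gid]:
            entry = tx_records[tid]
            ivs = entry["exons"] or [r.interval for r in entry["other"]]
            if not ivs:
                continue
            seqname = ivs[0].seqname
            strand = ivs[0].strand
            transcripts.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gid,
                    seqname=seqname,
                    strand=strand,
                    exons=list(entry["exons"]),
                    other_records=list(entry["other"]),
                    attributes=entry["attrs"],
                )
            )
        attrs = gene_attrs.get(gid, {})
        gene_name = attrs.get("gene_name", gid)
        if not gene_name and transcripts:
            gene_name = gid
        if transcripts or attrs:
            genes.append(GeneModel(gid, gene_name or gid, transcripts, attrs))
    return genes, orphans


def read_gtf(path) -> Annotation:
    """Parse an Ensembl-dialect GTF into flat records and gene models."""
    records: list[FeatureRecord] = []
    header: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                header.append(line.rstrip("\n"))
                continue
            if not line.strip():
                continue
            records.append(parse_gtf_line(line, lineno))
    genes, orphans = assemble_genes(records)
    return Annotation(records=records, genes=genes, orphans=orphans, header=header)


def _record_sort_key(rec: FeatureRecord):
    rank = _FEATURE_RANK.get(rec.feature_type, 3)
    return (
        rec.interval.seqname,
        rec.interval.start,
        rec.gene_id or "",
        rec.transcript_id or "",
        rank,
        -rec.interval.end,
        rec.feature_type,
    )


def write_gtf(annotation: Annotation | Sequence[FeatureRecord], path) -> None:
    """Write records with LF endings in a deterministic order.

    Ordering is (seqname, start, gene, transcript, gene<transcript<exon<other),
    so a read->write->read cycle is a fixed point after the first pass.
    """
    if isinstance(annotation, Annotation):
        records = annotation.records
        header = annotation.header
    else:
        records = list(annotation)
        header = []
    with open(path, "w", newline="\n") as fh:
        for line in header:
            fh.write(line + "\n")
        for rec in sorted(records, key=_record_sort_key):
            fh.write(rec.to_gtf_line() + "\n")


def gene_to_records(
    gene: GeneModel,
    emit: Sequence[str] = ("gene", "transcript", "exon", "other"),
    source: str = "exonproxy",
) -> list[FeatureRecord]:
    """Flatten a GeneModel back into GTF records."""
    out: list[FeatureRecord] = []
    span = gene.span
    if "gene" in emit:
        attrs = {"gene_id": gene.gene_id, "gene_name": gene.gene_name,
                 "gene_biotype": gene.biotype}
        attrs.update({k: v for k, v in gene.attributes.items() if k not in attrs})
        out.append(FeatureRecord(span, "gene", source=source, attributes=attrs))
    for tx in gene.transcripts:
        base = {
            "gene_id": gene.gene_id,
            "transcript_id": tx.transcript_id,
            "gene_name": gene.gene_name,
            "gene_biotype": gene.biotype,
        }
        if "transcript" in emit:
            attrs = dict(base)
            attrs.update({k: v for k, v in tx.attributes.items() if k not in attrs})
            out.append(FeatureRecord(tx.span, "transcript", source=source, attributes=attrs))
        if "exon" in emit:
            exons = tx.exons if tx.strand == "+" else list(reversed(tx.exons))
            for i, iv in enumerate(exons, start=1):
                attrs = dict(base)
                attrs["exon_number"] = str(i)
                out.append(FeatureRecord(iv, "exon", source=source, attributes=attrs))
        if "other" in emit:
            out.extend(tx.other_records)
    return out


# ---------------------------------------------------------------------------
# Read placements and BED I/O
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Placement:
    """One aligned read/molecule: possibly split into blocks across junctions.

    Blocks share seqname and strand, are sorted and non-overlapping; a
    spliced read emits one block per exon segment it touches.
    """

    name: str
    blocks: tuple[GenomicInterval, ...]
    sample: str = "sample1"

    def __post_init__(self):
        if not self.blocks:
            raise ValueError("placement needs at least one block")
        _check_homogeneous(self.blocks, f"placement {self.name}")

    @property
    def seqname(self) -> str:
        return self.blocks[0].seqname

    @property
    def strand(self) -> str:
        return self.blocks[0].strand

    @property
    def start(self) -> int:
        return self.blocks[0].start

    @property
    def end(self) -> int:
        return self.blocks[-1].end


def interval_to_bed6(iv: GenomicInterval, name: str = ".", score: str = "0") -> str:
    return "\t".join(
        [iv.seqname, str(iv.start - 1), str(iv.end), name, score, iv.strand]
    )


def bed6_to_interval(line: str) -> tuple[GenomicInterval, str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise ValueError(f"expected >=6 BED columns, got {len(fields)}")
    seqname, start0, end, name, _score, strand = fields[:6]
    return GenomicInterval(seqname, int(start0) + 1, int(end), strand), name


def write_bed6(intervals: Iterable[tuple[GenomicInterval, str]], path) -> None:
    with open(path, "w", newline="\n") as fh:
        for iv, name in intervals:
            fh.write(interval_to_bed6(iv, name) + "\n")


def placement_to_bed12(p: Placement) -> str:
    chrom_start = p.start - 1
    chrom_end = p.end
    sizes = ",".join(str(b.length) for b in p.blocks) + ","
    starts = ",".join(str(b.start - 1 - chrom_start) for b in p.blocks) + ","
    return "\t".join(
        [
            p.seqname,
            str(chrom_start),
            str(chrom_end),
            p.name,
            "0",
            p.strand,
            str(chrom_start),
            str(chrom_end),
            "0,0,0",
            str(len(p.blocks)),
            sizes,
            starts,
        ]
    )


def write_bed12(placements: Iterable[Placement], path) -> None:
    with open(path, "w", newline="\n") as fh:
        for p in placements:
            fh.write(placement_to_bed12(p) + "\n")


def read_bed_placements(path, sample: str = "sample1") -> list[Placement]:
    """Read BED6 or BED12 placements (blocked alignments supported)."""
    out: list[Placement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: fewer than 6 BED columns")
            seqname = fields[0]
            chrom_start = int(fields[1])
            name = fields[3]
            strand = fields[5]
            if len(fields) >= 12:
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
                blocks = tuple(
                    GenomicInterval(
                        seqname, chrom_start + off + 1, chrom_start + off + size, strand
                    )
                    for off, size in zip(starts, sizes)
                )
            else:
                blocks = (
                    GenomicInterval(seqname, chrom_start + 1, int(fields[2]), strand),
                )
            out.append(Placement(name=name, blocks=blocks, sample=sample))
    return out


def read_bam_placements(
    path,
    sample: str = "sample1",
    cell_tag: Optional[str] = None,
    exclude_multimappers: bool = True,
) -> Iterator[Placement]:
    """Stream placements from a coordinate-sorted BAM/SAM via pysam.

    Secondary/supplementary/unmapped records are skipped; when
    ``exclude_multimappers`` is set, reads flagged NH>1 are skipped too.
    When ``cell_tag`` (e.g. "CB") is given, the tag value becomes the
    per-placement sample identifier.
    """
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for aln in bam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if exclude_multimappers and aln.has_tag("NH") and aln.get_tag("NH") > 1:
                continue
            strand = "-" if aln.is_reverse else "+"
            blocks = tuple(
                GenomicInterval(aln.reference_name, s + 1, e, strand)
                for s, e in aln.get_blocks()
            )
            if not blocks:
                continue
            samp = sample
            if cell_tag and aln.has_tag(cell_tag):
                samp = str(aln.get_tag(cell_tag))
            yield Placement(name=aln.query_name, blocks=blocks, sample=samp)


# ---------------------------------------------------------------------------
# FASTA and minimal SAM output
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w", newline="\n") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_sam(
    placements: Iterable[Placement], seq_lengths: Mapping[str, int], path
) -> None:
    """Write placements as a minimal unpaired SAM (no SEQ/QUAL stored)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in seq_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for p in placements:
            flag = 16 if p.strand == "-" else 0
            cigar_parts = []
            prev_end = None
            for b in p.blocks:
                if prev_end is not None:
                    gap = b.start - prev_end - 1
                    if gap > 0:
                        cigar_parts.append(f"{gap}N")
                cigar_parts.append(f"{b.length}M")
                prev_end = b.end
            fh.write(
                "\t".join(
                    [
                        p.name,
                        str(flag),
                        p.seqname,
                        str(p.start),
                        "255",
                        "".join(cigar_parts),
                        "*",
                        "0",
                        "0",
                        "*",
                        "*",
                    ]
                )
                + "\n"
            )
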