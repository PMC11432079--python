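"""Locate a donor exon in a related genome sequence by Smith-Waterman local
alignment, over both strands, returning stranded 1-based genomic coordinates
suitable for :func:`exonproxy.annotation_editor.graft_terminal_exon`.

Intended for desk-scale searches against a user-supplied locus or chromosome
slice (FASTA), e.g., finding the gorilla coordinates of a human terminal exon
when the orthologous isoform is not annotated. Whole-genome seeded search is
a job for a dedicated aligner, not this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

from Bio import Align
from Bio.Seq import Seq

_STRAND_ORDER = {"+": 0, "-": 1}


@dataclass(frozen=True)
class Scoring:
    """BLASTN-like default scoring for nucleotide local alignment."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


@dataclass(frozen=True)
class LocalAlignmentHit:
    seqname: str
    start: int  # 1-based inclusive, forward coordinates
    end: int
    strand: str
    score: float
    identity: float  # percent, matches / alignment columns
    query_start: int  # 1-based inclusive span of the query that aligned
    query_end: int

    def __post_init__(self):
        if self.score < 0:
            raise ValueError("score must be >= 0")
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError("identity must be in [0, 100]")
        if self.end < self.start:
            raise ValueError("empty target interval")

    def to_bed6(self) -> str:
        return "\t".join(
            [
                self.seqname,
                str(self.start - 1),
                str(self.end),
                "hit",
                format(self.score, "g"),
                self.strand,
            ]
        )


@dataclass
class LocateResult:
    best: Optional[LocalAlignmentHit]
    runners_up: list[LocalAlignmentHit]

    @property
    def found(self) -> bool:
        return self.best is not None


def _make_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _alignment_stats(alignment) -> tuple[int, int, int, int, float]:
    """(t_start, t_end, q_start, q_end, identity%) from a Bio.Align alignment
    (0-based half-open coords in, 1-based inclusive out)."""
    t_blocks, q_blocks = alignment.aligned
    t_start = int(t_blocks[0][0])
    t_end = int(t_blocks[-1][1])
    q_start = int(q_blocks[0][0])
    q_end = int(q_blocks[-1][1])
    target = alignment.target
    query = alignment.query
    matches = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for i in range(te - ts):
            if target[ts + i] == query[qs + i]:
                matches += 1
    columns = (t_end - t_start) + (q_end - q_start) - sum(
        te - ts for ts, te in t_blocks
    )  # aligned columns including gaps on either side
    identity = 100.0 * matches / columns if columns else 0.0
    return t_start + 1, t_end, q_start + 1, q_end, identity


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def locate_exon(
    query: str,
    target: Union[Mapping[str, str], str],
    scoring: Scoring = Scoring(),
    min_score: Optional[float] = None,
    min_query_length: int = 50,
) -> LocateResult:
    """Best Smith-Waterman local hit of ``query`` over both strands of every
    target sequence.

    ``target`` is a {seqname: sequence} mapping or a FASTA path. The reverse
    strand is searched by aligning the reverse-complemented query; hit
    coordinates are always reported on the forward coordinate system with a
    strand flag. Ties break deterministically: lowest target start, then
    "+" before "-". ``min_score`` defaults to 0.8 x the maximum attainable
    score (a perfect full-length match); a best hit below it yields a
    not-found result rather than an exception.
    """
    query = query.upper().replace("\n", "").replace(" ", "")
    if len(query) < min_query_length:
        raise ValueError(
            f"query is {len(query)} bp; at least {min_query_length} required"
        )
    if isinstance(target, (str, bytes)) or hasattr(target, "__fspath__"):
        from .genomic_model import read_fasta

        target = read_fasta(target)
    if min_score is None:
        min_score = 0.8 * scoring.match * len(query)

    aligner = _make_aligner(scoring)
    hits: list[LocalAlignmentHit] = []
    for seqname in target:
        seq = target[seqname].upper()
        for strand, q in (("+", query), ("-", revcomp(query))):
            alignments = aligner.align(seq, q)
            if len(alignments) == 0 or alignments.score <= 0:
                continue
            aln = alignments[0]
            t_start, t_end, q_start, q_end, identity = _alignment_stats(aln)
            if strand == "-":
                # query span reported on the original (not revcomped) query
                q_start, q_end = len(query) - q_end + 1, len(query) - q_start + 1
            hits.append(
                LocalAlignmentHit(
                    seqname=seqname,
                    start=t_start,
                    end=t_end,
                    strand=strand,
                    score=float(alignments.score),
                    identity=identity,
                    query_start=q_start,
                    query_end=q_end,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.seqname, h.start, _STRAND_ORDER[h.strand]))
    if not hits or hits[0].score < min_score:
        return LocateResult(best=None, runners_up=hits)
    return LocateResult(best=hits[0], runners_up=hits[1:])


def hits_to_tsv(hits: Sequence[LocalAlignmentHit], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("seqname\tstart\tend\tstrand\tscore\tidentity\tquery_start\tquery_end\n")
        for h in hits:
            fh.write(
                f"{h.seqname}\t{h.start}\t{h.end}\t{h.strand}\t{h.score:g}\t"
                f"{h.identity:.2f}\t{h.query_start}\t{h.query_end}\n"
            )
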