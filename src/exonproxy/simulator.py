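"""Synthetic fixtures and a 3'-biased read simulator.

Everything every other module needs for testing is generated here, with
explicit seeds and no downloads:

* :func:`make_fixture` — a toy two-isoform gene with the THRA-style 3'
  topology (shared exons, one read-through terminal exon, one downstream
  terminal exon) plus a matching random genome sequence.
* :func:`thra_locus` — a synthetic reconstruction of the human THRA locus
  whose 3'-terminal entries carry the published GRCh38 coordinates (exon 9b
  and the three annotated exon-10 variants); upstream exons are invented.
* :func:`gorilla_thra1_locus` — a synthetic gorilla THRA1 model on the
  minus strand with the published 5' boundary, for exercising the
  terminal-exon graft.
* :func:`simulate_reads` — single-end reads drawn from a known molar
  isoform mixture, with the read 3' end placed a truncated-exponential
  distance from the transcript 3' end (the 10X-style tag-library bias), or
  uniformly (bulk-style, where molecules yield fragments in proportion to
  their length).

Reads are emitted one per molecule (a UMI-collapsed world); spliced reads
crossing exon junctions come out as multi-block placements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genomic_model import (
    Annotation,
    GeneModel,
    GenomicInterval,
    Placement,
    TranscriptModel,
    assemble_genes,
    gene_to_records,
)
from .proxy_finder import GroupingSpec

logger = logging.getLogger(__name__)

DEFAULT_READ_LENGTH = 91
DEFAULT_BIAS_SCALE = 400.0


class TopologyError(ValueError):
    """Requested fixture topology is geometrically infeasible."""


@dataclass
class Fixture:
    """A toy gene plus its annotation, grouping spec and genome sequence."""

    gene: GeneModel
    annotation: Annotation
    grouping: GroupingSpec
    sequences: dict[str, str]


@dataclass
class MixtureSpec:
    """Ground truth for a simulation: molar fractions + bias model + seed."""

    fractions: Sequence[float]
    n_reads: int
    read_length: int = DEFAULT_READ_LENGTH
    bias_scale: float = DEFAULT_BIAS_SCALE
    mode: str = "three_prime"  # or "uniform" (bulk-like)
    seed: int = 0
    sample: str = "sample1"

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(self.fractions)}")
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be non-negative")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if self.bias_scale <= 0:
            raise ValueError("bias_scale must be positive")
        if self.mode not in ("three_prime", "uniform"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


def _annotation_from_genes(genes: Sequence[GeneModel]) -> Annotation:
    records = [rec for g in genes for rec in gene_to_records(g)]
    assembled, orphans = assemble_genes(records)
    return Annotation(records=records, genes=assembled, orphans=orphans)


def _mirror(iv: GenomicInterval, pivot: int) -> GenomicInterval:
    return GenomicInterval(iv.seqname, pivot - iv.end, pivot - iv.start, "-")


def make_fixture(
    preset: str = "thra-like",
    seed: int = 0,
    n_shared_exons: int = 8,
    shared_exon_length: int = 150,
    intron_length: int = 500,
    anchor_exon_length: int = 400,
    readthrough_length: int = 3294,
    downstream_gap: int = 392,
    downstream_exon_length: int = 848,
    seqname: str = "chrT",
    strand: str = "+",
    origin: int = 10_000,
    gene_id: str = "G1",
    gene_name: str = "TOY",
    transcript_ids: Sequence[str] = ("ISO1", "ISO2"),
) -> Fixture:
    """Build the two-isoform toy gene plus a deterministic random genome.

    Topology (transcription order): ``n_shared_exons`` shared exons, then an
    anchor exon (the exon-9a analogue). Isoform 1 reads through the anchor
    into a ``readthrough_length`` extension (its terminal exon = anchor +
    extension, the exon-9b analogue); isoform 2 splices the anchor to a
    separate downstream terminal exon (the exon-10 analogue). The default
    lengths of the two isoform-specific stretches (3294 and 848 bp) mirror
    the human THRA locus.
    """
    if preset != "thra-like":
        raise TopologyError(f"unknown preset {preset!r}")
    for name, val in (
        ("n_shared_exons", n_shared_exons),
        ("shared_exon_length", shared_exon_length),
        ("intron_length", intron_length),
        ("anchor_exon_length", anchor_exon_length),
        ("readthrough_length", readthrough_length),
        ("downstream_exon_length", downstream_exon_length),
    ):
        if val < 1:
            raise TopologyError(f"{name} must be >= 1, got {val}")
    if downstream_gap < 1:
        raise TopologyError(
            "downstream_gap must be >= 1 (a touching terminal exon would merge "
            "into the read-through exon)"
        )

    # lay out in transcription order on a forward axis, then mirror for "-"
    shared: list[GenomicInterval] = []
    pos = origin
    for _ in range(n_shared_exons):
        shared.append(GenomicInterval(seqname, pos, pos + shared_exon_length - 1, "+"))
        pos += shared_exon_length + intron_length
    anchor = GenomicInterval(seqname, pos, pos + anchor_exon_length - 1, "+")
    readthrough_terminal = GenomicInterval(
        seqname, anchor.start, anchor.end + readthrough_length, "+"
    )
    ds_start = readthrough_terminal.end + downstream_gap + 1
    downstream_terminal = GenomicInterval(
        seqname, ds_start, ds_start + downstream_exon_length - 1, "+"
    )

    if strand == "-":
        pivot = origin + downstream_terminal.end  # arbitrary fixed pivot
        shared = [_mirror(iv, pivot) for iv in reversed(shared)]
        anchor = _mirror(anchor, pivot)
        readthrough_terminal = _mirror(readthrough_terminal, pivot)
        downstream_terminal = _mirror(downstream_terminal, pivot)
        shared = sorted(shared, key=lambda iv: iv.start)

    tid1, tid2 = transcript_ids
    tx1 = TranscriptModel(
        transcript_id=tid1,
        gene_id=gene_id,
        seqname=seqname,
        strand=strand,
        exons=sorted(shared + [readthrough_terminal], key=lambda iv: iv.start),
    )
    tx2 = TranscriptModel(
        transcript_id=tid2,
        gene_id=gene_id,
        seqname=seqname,
        strand=strand,
        exons=sorted(shared + [anchor, downstream_terminal], key=lambda iv: iv.start),
    )
    gene = GeneModel(
        gene_id=gene_id,
        gene_name=gene_name,
        transcripts=[tx1, tx2],
        attributes={"gene_biotype": "protein_coding"},
    )

    rng = np.random.default_rng(seed)
    seq_len = gene.span.end + 500
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=seq_len)])

    grouping = GroupingSpec(
        gene_id=gene_id, groups={f"{gene_name}1": [tid1], f"{gene_name}2": [tid2]}
    )
    return Fixture(
        gene=gene,
        annotation=_annotation_from_genes([gene]),
        grouping=grouping,
        sequences={seqname: seq},
    )


# ---------------------------------------------------------------------------
# THRA-locus fixtures (synthetic; 3'-terminal coordinates are the published
# GRCh38 / gorGor6 ones, upstream exons are invented)
# ---------------------------------------------------------------------------

#: published GRCh38 coordinates of the THRA 3'-terminal entries (chr17, "+")
THRA_EXON_9A = (40_088_900, 40_089_333)  # end is published (9b starts at +1); start invented
THRA_EXON_9B_ENTRIES = ((40_088_900, 40_092_627), (40_088_900, 40_089_730))
THRA_EXON_10_ENTRIES = (
    (40_093_020, 40_093_613),
    (40_093_137, 40_093_867),
    (40_093_020, 40_093_867),
)

DEFAULT_THRA1_IDS = ("ENST00000450525", "SYNTX0000000001")
DEFAULT_THRA2_IDS = ("ENST00000264637", "ENST00000584985", "SYNTX0000000002")


def thra_locus(
    thra1_ids: Sequence[str] = DEFAULT_THRA1_IDS,
    thra2_ids: Sequence[str] = DEFAULT_THRA2_IDS,
    seqname: str = "chr17",
) -> Fixture:
    """Synthetic human THRA locus.

    Isoform-1 variants end in the read-through exon 9b (two annotated
    entries, both ending where the published counting region does);
    isoform-2 variants end in exon 10 (three annotated entries). Upstream
    shared exons 1-8 and the exon-9a start are invented; everything the
    proxy computation depends on (the 3'-terminal entry boundaries and the
    9a/9b junction) carries the published coordinates. Transcript id lists
    are configurable because the published isoform-1 id list is ambiguous.
    """
    if len(thra1_ids) != len(THRA_EXON_9B_ENTRIES):
        raise ValueError(f"need {len(THRA_EXON_9B_ENTRIES)} isoform-1 ids")
    if len(thra2_ids) != len(THRA_EXON_10_ENTRIES):
        raise ValueError(f"need {len(THRA_EXON_10_ENTRIES)} isoform-2 ids")

    shared = [
        GenomicInterval(seqname, s, s + 199, "+")
        for s in range(40_062_000, 40_062_000 + 8 * 3_000, 3_000)
    ]
    anchor = GenomicInterval(seqname, *THRA_EXON_9A, "+")
    gene_id = "ENSG00000126351"

    transcripts = []
    for tid, (s, e) in zip(thra1_ids, THRA_EXON_9B_ENTRIES):
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                seqname=seqname,
                strand="+",
                exons=shared + [GenomicInterval(seqname, s, e, "+")],
            )
        )
    for tid, (s, e) in zip(thra2_ids, THRA_EXON_10_ENTRIES):
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                seqname=seqname,
                strand="+",
                exons=shared + [anchor, GenomicInterval(seqname, s, e, "+")],
            )
        )
    gene = GeneModel(
        gene_id=gene_id,
        gene_name="THRA",
        transcripts=transcripts,
        attributes={"gene_biotype": "protein_coding"},
    )
    grouping = GroupingSpec(
        gene_id=gene_id,
        groups={"THRA1": list(thra1_ids), "THRA2": list(thra2_ids)},
    )
    return Fixture(
        gene=gene,
        annotation=_annotation_from_genes([gene]),
        grouping=grouping,
        sequences={},
    )


def gorilla_thra1_locus(seqname: str = "chr5") -> GeneModel:
    """Synthetic gorilla THRA1 gene model on the minus strand.

    The 5' gene boundary (41,888,473) matches the published custom locus;
    the nine exon bodies are invented. Serves as the recipient for grafting
    an exon-10 analogue located by homology search.
    """
    exons = []
    end = 41_888_473
    for _ in range(9):
        exons.append(GenomicInterval(seqname, end - 199, end, "-"))
        end -= 3_200
    tx = TranscriptModel(
        transcript_id="XM_019026893",
        gene_id="THRA_GGO",
        seqname=seqname,
        strand="-",
        exons=sorted(exons, key=lambda iv: iv.start),
    )
    return GeneModel(
        gene_id="THRA_GGO",
        gene_name="THRA1",
        transcripts=[tx],
        attributes={"gene_biotype": "protein_coding"},
    )


#: published gorilla coordinates for the exon-10 graft (minus strand)
GORILLA_EXON10_DONOR = (41_857_944, 41_858_305)


def make_homology_fixture(
    seed: int = 0,
    query_length: int = 363,
    target_length: int = 4_000,
    embed_at: int = 1_500,
    strand: str = "-",
    seqname: str = "locus",
) -> tuple[str, dict[str, str], GenomicInterval]:
    """A random target sequence with the (possibly reverse-complemented)
    query embedded at a known position; returns (query, target, truth)."""
    from .homology_locator import revcomp

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    query = "".join(bases[rng.integers(0, 4, size=query_length)])
    target = list("".join(bases[rng.integers(0, 4, size=target_length)]))
    insert = revcomp(query) if strand == "-" else query
    target[embed_at - 1 : embed_at - 1 + query_length] = list(insert)
    truth = GenomicInterval(seqname, embed_at, embed_at + query_length - 1, strand)
    return query, {seqname: "".join(target)}, truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _transcription_order(tx: TranscriptModel) -> list[GenomicInterval]:
    return tx.exons if tx.strand == "+" else list(reversed(tx.exons))


def transcript_to_genomic_blocks(
    tx: TranscriptModel, tx_start: int, tx_end: int
) -> tuple[GenomicInterval, ...]:
    """Map a 1-based inclusive transcript-coordinate interval (5'->3') to
    genomic blocks, splitting across exon junctions."""
    if tx_start < 1 or tx_end > tx.spliced_length or tx_end < tx_start:
        raise ValueError(
            f"transcript interval [{tx_start},{tx_end}] outside "
            f"[1,{tx.spliced_length}]"
        )
    blocks = []
    offset = 0  # transcript bases consumed before current exon
    for exon in _transcription_order(tx):
        lo = max(tx_start, offset + 1)
        hi = min(tx_end, offset + exon.length)
        if lo <= hi:
            if tx.strand == "+":
                g_start = exon.start + (lo - offset - 1)
                g_end = exon.start + (hi - offset - 1)
            else:
                g_end = exon.end - (lo - offset - 1)
                g_start = exon.end - (hi - offset - 1)
            blocks.append(GenomicInterval(exon.seqname, g_start, g_end, tx.strand))
        offset += exon.length
    return tuple(sorted(blocks, key=lambda iv: iv.start))


def _truncated_exponential(rng, scale: float, upper: float, size: int) -> np.ndarray:
    """Inverse-CDF draws from Exp(scale) truncated to [0, upper]."""
    u = rng.random(size)
    z = 1.0 - np.exp(-upper / scale)
    return -scale * np.log1p(-u * z)


def simulate_reads(fixture: Fixture, spec: MixtureSpec) -> list[Placement]:
    """Draw single-end reads from a known molar mixture of the fixture's
    isoforms; one placement per molecule, named ``<transcript_id>:<i>`` so
    the source isoform stays recoverable as ground truth."""
    txs = fixture.gene.transcripts
    if len(spec.fractions) != len(txs):
        raise ValueError(
            f"{len(spec.fractions)} fractions for {len(txs)} isoforms"
        )
    rl = spec.read_length
    for tx, f in zip(txs, spec.fractions):
        if f > 0 and rl > tx.spliced_length:
            raise ValueError(
                f"read_length {rl} exceeds spliced length "
                f"{tx.spliced_length} of {tx.transcript_id}"
            )

    rng = np.random.default_rng(spec.seed)
    weights = np.asarray(spec.fractions, dtype=float)
    if spec.mode == "uniform":
        # bulk chemistry: fragments per molecule scale with the number of
        # possible placements on the molecule
        weights = weights * np.array([tx.spliced_length - rl + 1 for tx in txs])
    weights = weights / weights.sum()
    iso_idx = rng.choice(len(txs), size=spec.n_reads, p=weights)

    placements: list[Placement] = []
    for k, tx in enumerate(txs):
        n_k = int(np.sum(iso_idx == k))
        if n_k == 0:
            continue
        L = tx.spliced_length
        if spec.mode == "three_prime":
            x = np.floor(
                _truncated_exponential(rng, spec.bias_scale, L - rl, n_k)
            ).astype(int)
            starts = L - x - rl + 1  # transcript coordinate of the read 5' end
        else:
            starts = rng.integers(1, L - rl + 2, size=n_k)
        read_ids = np.flatnonzero(iso_idx == k)
        for i, s in zip(read_ids, starts):
            blocks = transcript_to_genomic_blocks(tx, int(s), int(s) + rl - 1)
            placements.append(
                Placement(
                    name=f"{tx.transcript_id}:{i}",
                    blocks=blocks,
                    sample=spec.sample,
                )
            )
    return placements


def true_isoform(placement: Placement) -> str:
    """Recover the source transcript id encoded in a simulated read name."""
    return placement.name.rsplit(":", 1)[0]


# ---------------------------------------------------------------------------
# Recovery helpers: simulate -> count -> estimate, used to validate the
# proxy approach against known mixtures
# ---------------------------------------------------------------------------


def recover_mixture_fractions(
    fixture: Fixture, spec: MixtureSpec, correct_capture: bool = True
):
    """Simulate reads and estimate molar isoform fractions from proxy counts.

    For 3'-biased (tag/UMI) simulations the estimate is the count share per
    proxy, divided by each proxy's 3'-capture probability under the stated
    bias model when ``correct_capture`` is set. For uniform (bulk) simulations
    the estimate is the TPM share (count / proxy length, renormalized).
    Returns a pandas Series indexed by group name.
    """
    from .proxy_finder import find_proxies
    from .quantifier import (
        count_overlaps,
        isoform_fraction,
        isoform_fraction_from_counts,
        three_prime_capture_probability,
        tpm,
    )

    proxies, groups, _ = find_proxies(fixture.gene, fixture.grouping)
    reads = simulate_reads(fixture, spec)
    counts = count_overlaps(reads, proxies)
    if spec.mode == "uniform":
        table = tpm(counts, {p.group_name: p.proxy_length for p in proxies})
        frac = isoform_fraction(table)
    else:
        caps = None
        if correct_capture:
            tx_of_group = {
                g.name: fixture.gene.transcript(sorted(g.transcript_ids)[0])
                for g in groups
            }
            caps = {
                p.group_name: three_prime_capture_probability(
                    p.proxy_length,
                    tx_of_group[p.group_name].spliced_length,
                    spec.bias_scale,
                    spec.read_length,
                )
                for p in proxies
            }
        frac = isoform_fraction_from_counts(counts, caps)
    return frac[spec.sample]


def depth_ladder_errors(
    fixture: Fixture,
    fractions: Sequence[float],
    depths: Sequence[int] = (1_000, 10_000, 100_000),
    n_replicates: int = 8,
    base_seed: int = 0,
    **spec_kwargs,
) -> dict[int, float]:
    """Mean absolute error of the recovered second-group fraction at each
    read depth, averaged over ``n_replicates`` independent sub-seeds.

    Averaging replicates estimates the depth-wise error level itself, which
    decreases with depth for a consistent estimator; a single draw per depth
    would compare noise realizations instead.
    """
    truth = fractions[1]
    errors: dict[int, float] = {}
    for d_i, depth in enumerate(depths):
        errs = []
        for r in range(n_replicates):
            seed = (base_seed * 1_000_003 + d_i * 9_973 + r) % (2**31 - 1)
            spec = MixtureSpec(
                fractions=fractions, n_reads=depth, seed=seed, **spec_kwargs
            )
            frac = recover_mixture_fractions(fixture, spec)
            errs.append(abs(float(frac.iloc[1]) - truth))
        errors[depth] = float(np.mean(errs))
    return errors
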