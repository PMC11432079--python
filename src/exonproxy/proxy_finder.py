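"""Partition a gene's transcripts into 3'-end isoform groups and compute the
genomic region that uniquely distinguishes each group (its "proxy region").

Splicing isoforms that differ only at the 3' end (e.g., thyroid hormone
receptor alpha, where isoform 1 ends in read-through exon 9b and isoform 2
in downstream exon 10) cannot be told apart by gene-level counting, but the
3'-terminal stretch unique to each isoform can stand in as a countable
surrogate — which is exactly where 3'-tag libraries place their reads.

The proxy region of a group is the strand-aware union of its transcripts'
3'-most exons (plus annotated 3'UTR and stop-codon records) minus every
exonic base of transcripts outside the group.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .genomic_model import (
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    merge_intervals,
    subtract_intervals,
    intersect_intervals,
)

logger = logging.getLogger(__name__)

#: below this proxy length (bp) the region is rejected outright by default
DEFAULT_MIN_LENGTH = 100
#: below this length a warning is logged: short regions leave little room
#: for a ~90 bp tag read to land uniquely
WARN_LENGTH = 300


class GroupingError(ValueError):
    """Invalid isoform grouping (unknown or doubly-assigned transcripts)."""


class NotDistinguishableError(ValueError):
    """The group's 3'-terminal region is fully shared with other transcripts."""

    def __init__(self, group_name: str, colliding: Sequence[str]):
        self.group_name = group_name
        self.colliding = list(colliding)
        super().__init__(
            f"group {group_name!r}: 3'-terminal region is entirely covered by "
            f"exons of {', '.join(self.colliding) or 'other transcripts'}; "
            "isoforms are not 3'-distinguishable"
        )


@dataclass(frozen=True)
class IsoformGroup:
    """A named set of transcripts sharing a 3' end (e.g., 'THRA2')."""

    name: str
    transcript_ids: frozenset[str]

    def __post_init__(self):
        if not self.transcript_ids:
            raise GroupingError(f"group {self.name!r} has no transcripts")


@dataclass(frozen=True)
class ProxyRegion:
    """The merged genomic region unique to one group's 3' end."""

    group_name: str
    intervals: tuple[GenomicInterval, ...]

    @property
    def proxy_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    @property
    def seqname(self) -> str:
        return self.intervals[0].seqname

    @property
    def strand(self) -> str:
        return self.intervals[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.seqname,
            min(iv.start for iv in self.intervals),
            max(iv.end for iv in self.intervals),
            self.strand,
        )


@dataclass
class GroupingSpec:
    """Declarative grouping: explicit ``{name: [transcript_id, ...]}`` or auto.

    In auto mode transcripts are grouped by identical 3'-most exon;
    group names are then generated in 5'->3' order of the terminal exon
    (``G1``, ``G2``, ...). Transcripts not named by an explicit spec go to
    the ``unassigned`` pool: they contribute no proxy but their exons still
    mask every group's proxy region.
    """

    gene_id: str
    groups: Optional[dict[str, list[str]]] = None
    auto: bool = False
    min_length: int = DEFAULT_MIN_LENGTH

    @classmethod
    def from_mapping(cls, data: Mapping) -> "GroupingSpec":
        return cls(
            gene_id=data["gene_id"],
            groups={k: list(v) for k, v in data.get("groups", {}).items()} or None,
            auto=bool(data.get("auto", False)),
            min_length=int(data.get("min_length", DEFAULT_MIN_LENGTH)),
        )

    @classmethod
    def from_file(cls, path) -> "GroupingSpec":
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_mapping(data)


def three_prime_boundary(iv: GenomicInterval) -> int:
    """The 3'-most coordinate of an interval, strand-aware."""
    if iv.strand == "+":
        return iv.end
    if iv.strand == "-":
        return iv.start
    raise ValueError("3' boundary requires an explicit strand")


def terminal_exons(tx: TranscriptModel) -> list[GenomicInterval]:
    """All exons whose 3' boundary equals the transcript's 3'-most boundary.

    Normally a single exon; fragmented annotations may tie, in which case
    all tied exons are taken (and the caller's log records it).
    """
    if not tx.exons:
        raise ValueError(f"transcript {tx.transcript_id} has zero exons")
    if tx.strand == "+":
        best = max(iv.end for iv in tx.exons)
        hits = [iv for iv in tx.exons if iv.end == best]
    else:
        best = min(iv.start for iv in tx.exons)
        hits = [iv for iv in tx.exons if iv.start == best]
    if len(hits) > 1:
        logger.warning(
            "transcript %s: %d exons tie for the 3'-most boundary", tx.transcript_id, len(hits)
        )
    return hits


def partition_transcripts(
    gene: GeneModel, spec: GroupingSpec
) -> tuple[list[IsoformGroup], frozenset[str]]:
    """Assign every transcript to exactly one group or to the unassigned pool.

    Returns (groups, unassigned transcript ids).
    """
    all_ids = [t.transcript_id for t in gene.transcripts]
    if spec.auto and spec.groups:
        raise GroupingError("grouping spec cannot be both auto and explicit")
    if spec.auto:
        by_terminal: dict[tuple, list[str]] = {}
        for tx in gene.transcripts:
            key = tuple((iv.start, iv.end) for iv in terminal_exons(tx))
            by_terminal.setdefault(key, []).append(tx.transcript_id)
        # order groups 5'->3' by terminal boundary
        def sort_key(item):
            key, _ = item
            boundary = key[0][1] if gene.strand == "+" else -key[0][0]
            return boundary

        ordered = sorted(by_terminal.items(), key=sort_key)
        groups = [
            IsoformGroup(name=f"G{i}", transcript_ids=frozenset(ids))
            for i, (_, ids) in enumerate(ordered, start=1)
        ]
        return groups, frozenset()

    if not spec.groups:
        raise GroupingError("grouping spec names no groups and auto=False")
    seen: dict[str, str] = {}
    groups = []
    for name, ids in spec.groups.items():
        for tid in ids:
            if tid not in all_ids:
                raise GroupingError(
                    f"group {name!r}: transcript {tid!r} not found in gene {gene.gene_id}"
                )
            if tid in seen:
                raise GroupingError(
                    f"transcript {tid!r} assigned to both {seen[tid]!r} and {name!r}"
                )
            seen[tid] = name
        groups.append(IsoformGroup(name=name, transcript_ids=frozenset(ids)))
    unassigned = frozenset(tid for tid in all_ids if tid not in seen)
    if unassigned:
        logger.info(
            "gene %s: %d transcripts left unassigned (%s)",
            gene.gene_id,
            len(unassigned),
            ", ".join(sorted(unassigned)),
        )
    return groups, unassigned


def terminal_region(group: IsoformGroup, gene: GeneModel) -> list[GenomicInterval]:
    """Strand-aware union over the group's transcripts of
    3'-most exon(s) + annotated 3'UTR + stop codon."""
    intervals: list[GenomicInterval] = []
    for tid in sorted(group.transcript_ids):
        tx = gene.transcript(tid)
        intervals.extend(terminal_exons(tx))
        for rec in tx.other_records:
            if rec.feature_type in ("three_prime_utr", "stop_codon"):
                intervals.append(rec.interval)
    return merge_intervals(intervals)


def distinguishing_region(
    group: IsoformGroup,
    gene: GeneModel,
    others: Sequence[IsoformGroup] = (),
    unassigned: frozenset[str] = frozenset(),
    min_length: int = DEFAULT_MIN_LENGTH,
    on_short: str = "error",
) -> ProxyRegion:
    """Terminal region of the group minus every exonic base of transcripts
    outside it (other groups plus the unassigned pool)."""
    outside_ids = set()
    for g in others:
        if g.name != group.name:
            outside_ids |= set(g.transcript_ids)
    outside_ids |= set(unassigned)
    outside_ids -= set(group.transcript_ids)

    term = terminal_region(group, gene)
    mask = merge_intervals(
        iv for tx in gene.transcripts if tx.transcript_id in outside_ids for iv in tx.exons
    )
    region = subtract_intervals(term, mask) if mask else term
    if not region:
        colliding = [
            g.name
            for g in others
            if g.name != group.name
            and intersect_intervals(
                term,
                [iv for tid in g.transcript_ids for iv in gene.transcript(tid).exons],
            )
        ]
        raise NotDistinguishableError(group.name, colliding)
    length = sum(iv.length for iv in region)
    if length < min_length:
        msg = (
            f"group {group.name!r}: proxy region is only {length} bp "
            f"(min_length={min_length})"
        )
        if on_short == "error":
            raise ValueError(msg)
        logger.warning(msg)
    elif length < WARN_LENGTH:
        logger.warning(
            "group %s: proxy region is short (%d bp); a ~90 bp tag read has "
            "little room to land uniquely",
            group.name,
            length,
        )
    return ProxyRegion(group_name=group.name, intervals=tuple(region))


def find_proxies(
    gene: GeneModel, spec: GroupingSpec
) -> tuple[list[ProxyRegion], list[IsoformGroup], frozenset[str]]:
    """One-call orchestration: partition, then a disjoint proxy per group."""
    groups, unassigned = partition_transcripts(gene, spec)
    proxies = [
        distinguishing_region(
            g, gene, others=groups, unassigned=unassigned, min_length=spec.min_length
        )
        for g in groups
    ]
    # cross-group disjointness is guaranteed by construction (each proxy
    # excludes the other groups' exons); assert it anyway
    for i, a in enumerate(proxies):
        for b in proxies[i + 1 :]:
            if intersect_intervals(list(a.intervals), list(b.intervals)):
                raise AssertionError(
                    f"proxies {a.group_name} and {b.group_name} overlap (internal bug)"
                )
    return proxies, groups, unassigned


def proxies_to_bed(proxies: Sequence[ProxyRegion], path) -> None:
    from .genomic_model import write_bed6

    write_bed6(
        ((iv, p.group_name) for p in proxies for iv in p.intervals), path
    )
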