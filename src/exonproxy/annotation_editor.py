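"""Rewrite a gene annotation so each proxy region becomes a standalone
pseudo-gene that gene-level quantifiers (e.g., 10X-style reference builders)
count separately, while shared exons stay under the original gene.

"Pseudo-gene" here is an annotation-engineering device — a fresh
gene_id/transcript_id/gene_name wrapped around an isoform-specific region —
not a biological pseudogene.

Also provides :func:`graft_terminal_exon` for constructing an isoform locus
in a related genome where the isoform's terminal exon is not annotated
(located there, e.g., by local alignment of the human exon sequence).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .genomic_model import (
    Annotation,
    FeatureRecord,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    assemble_genes,
    gene_to_records,
    intersect_intervals,
    merge_intervals,
    subtract_intervals,
)
from .proxy_finder import ProxyRegion

logger = logging.getLogger(__name__)

PSEUDOGENE_FEATURES = ("gene", "transcript", "exon")


class IdCollisionError(ValueError):
    """A new gene/transcript id already exists in the annotation."""


class SplitError(ValueError):
    """The split plan is inconsistent with the annotation."""


@dataclass
class PlanEntry:
    group_name: str
    new_gene_id: str
    new_transcript_id: str
    gene_name: str
    intervals: list[GenomicInterval]


@dataclass
class SplitPlan:
    """Provenance record of a gene split, serializable as a JSON sidecar."""

    source_gene_id: str
    entries: list[PlanEntry] = field(default_factory=list)
    retained_intervals: list[GenomicInterval] = field(default_factory=list)
    emitted_features: tuple[str, ...] = PSEUDOGENE_FEATURES

    def to_json(self) -> str:
        def iv(i: GenomicInterval):
            return {"seqname": i.seqname, "start": i.start, "end": i.end, "strand": i.strand}

        return json.dumps(
            {
                "source_gene_id": self.source_gene_id,
                "emitted_features": list(self.emitted_features),
                "retained_intervals": [iv(i) for i in self.retained_intervals],
                "groups": [
                    {
                        "group_name": e.group_name,
                        "gene_id": e.new_gene_id,
                        "transcript_id": e.new_transcript_id,
                        "gene_name": e.gene_name,
                        "intervals": [iv(i) for i in e.intervals],
                    }
                    for e in self.entries
                ],
            },
            indent=2,
        )

    def write(self, path) -> None:
        with open(path, "w", newline="\n") as fh:
            fh.write(self.to_json() + "\n")


def default_id_scheme(source_gene_id: str, group_name: str) -> tuple[str, str]:
    """New (gene_id, transcript_id) for a pseudo-gene: ``<gene_id>-<GROUP>``."""
    gid = f"{source_gene_id}-{group_name}"
    return gid, f"{gid}-T1"


def _trim_record(rec: FeatureRecord, cut: Sequence[GenomicInterval]) -> list[FeatureRecord]:
    """Subtract ``cut`` bases from one record, splitting it if needed."""
    pieces = subtract_intervals([rec.interval], cut)
    return [dataclasses.replace(rec, interval=p) for p in pieces]


def split_gene(
    annotation: Annotation,
    gene_id: str,
    proxies: Sequence[ProxyRegion],
    id_scheme=default_id_scheme,
    emit_features: Sequence[str] = PSEUDOGENE_FEATURES,
    gene_biotype: Optional[str] = None,
    source: str = "exonproxy",
    on_existing: str = "error",
) -> tuple[Annotation, SplitPlan]:
    """Carve each proxy region out of ``gene_id`` into its own pseudo-gene.

    Every record of the source gene is trimmed by the proxy union (records
    fully inside a proxy disappear from the original gene); transcript and
    gene spans are recomputed from what remains. All records of other genes
    pass through untouched. Splitting an annotation that already contains
    the pseudo-gene ids raises (``on_existing="error"``) or returns the
    input unchanged (``on_existing="skip"``) — never a double split.
    """
    gene = annotation.gene(gene_id)
    if not proxies:
        raise SplitError("no proxy regions supplied")

    proxy_union: list[GenomicInterval] = []
    for p in proxies:
        for q in proxies:
            if p is not q and intersect_intervals(list(p.intervals), list(q.intervals)):
                raise SplitError(
                    f"proxy regions {p.group_name} and {q.group_name} overlap"
                )
    proxy_union = merge_intervals(iv for p in proxies for iv in p.intervals)

    existing_ids = annotation.gene_ids()
    new_ids = {}
    for p in proxies:
        new_gid, new_tid = id_scheme(gene_id, p.group_name)
        if new_gid in existing_ids:
            if on_existing == "skip":
                logger.info("gene %s already split (found %s); skipping", gene_id, new_gid)
                plan = SplitPlan(source_gene_id=gene_id)
                return annotation, plan
            raise IdCollisionError(
                f"gene_id {new_gid!r} already present; annotation appears "
                f"to be split already"
            )
        new_ids[p.group_name] = (new_gid, new_tid)

    biotype = gene_biotype or gene.biotype

    out_records: list[FeatureRecord] = []
    retained_gene_records: list[FeatureRecord] = []
    for rec in annotation.records:
        if rec.gene_id != gene_id:
            out_records.append(rec)
            continue
        if rec.feature_type in ("gene", "transcript"):
            continue  # spans recomputed below
        retained_gene_records.extend(_trim_record(rec, proxy_union))

    # recompute transcript and gene spans from retained exons
    retained_exons_by_tx: dict[str, list[GenomicInterval]] = {}
    for rec in retained_gene_records:
        if rec.feature_type == "exon" and rec.transcript_id:
            retained_exons_by_tx.setdefault(rec.transcript_id, []).append(rec.interval)

    tx_attr = {
        t.transcript_id: t.attributes for t in gene.transcripts
    }
    all_retained_exons: list[GenomicInterval] = []
    span_records: list[FeatureRecord] = []
    for tid, exons in retained_exons_by_tx.items():
        exons = sorted(exons, key=lambda iv: iv.start)
        all_retained_exons.extend(exons)
        span = GenomicInterval(
            exons[0].seqname, exons[0].start, exons[-1].end, exons[0].strand
        )
        attrs = {
            "gene_id": gene_id,
            "transcript_id": tid,
            "gene_name": gene.gene_name,
            "gene_biotype": gene.biotype,
        }
        attrs.update({k: v for k, v in tx_attr.get(tid, {}).items() if k not in attrs})
        span_records.append(
            FeatureRecord(span, "transcript", source=source, attributes=attrs)
        )
    if all_retained_exons:
        g_exons = merge_intervals(all_retained_exons)
        g_span = GenomicInterval(
            g_exons[0].seqname, g_exons[0].start, g_exons[-1].end, g_exons[0].strand
        )
        g_attrs = {
            "gene_id": gene_id,
            "gene_name": gene.gene_name,
            "gene_biotype": gene.biotype,
        }
        g_attrs.update({k: v for k, v in gene.attributes.items() if k not in g_attrs})
        span_records.insert(0, FeatureRecord(g_span, "gene", source=source, attributes=g_attrs))

    out_records.extend(span_records)
    out_records.extend(retained_gene_records)

    # pseudo-gene records
    plan = SplitPlan(
        source_gene_id=gene_id,
        retained_intervals=merge_intervals(all_retained_exons) if all_retained_exons else [],
        emitted_features=tuple(emit_features),
    )
    retained_union = plan.retained_intervals
    for p in proxies:
        new_gid, new_tid = new_ids[p.group_name]
        if retained_union and intersect_intervals(list(p.intervals), retained_union):
            raise SplitError(
                f"proxy {p.group_name} overlaps a retained exon of {gene_id} "
                "(upstream proxy computation is inconsistent)"
            )
        base = {
            "gene_id": new_gid,
            "transcript_id": new_tid,
            "gene_name": p.group_name,
            "gene_biotype": biotype,
        }
        span = p.span
        if "gene" in emit_features:
            attrs = {k: v for k, v in base.items() if k != "transcript_id"}
            out_records.append(FeatureRecord(span, "gene", source=source, attributes=attrs))
        if "transcript" in emit_features:
            out_records.append(
                FeatureRecord(span, "transcript", source=source, attributes=dict(base))
            )
        if "exon" in emit_features:
            ivs = p.intervals if p.strand == "+" else tuple(reversed(p.intervals))
            for i, iv in enumerate(ivs, start=1):
                attrs = dict(base)
                attrs["exon_number"] = str(i)
                out_records.append(
                    FeatureRecord(iv, "exon", source=source, attributes=attrs)
                )
        plan.entries.append(
            PlanEntry(
                group_name=p.group_name,
                new_gene_id=new_gid,
                new_transcript_id=new_tid,
                gene_name=p.group_name,
                intervals=list(p.intervals),
            )
        )

    genes, orphans = assemble_genes(out_records)
    edited = Annotation(
        records=out_records, genes=genes, orphans=orphans, header=list(annotation.header)
    )
    return edited, plan


class GraftError(ValueError):
    """Donor exon incompatible with the recipient gene model."""


def graft_terminal_exon(
    gene: GeneModel,
    donor_exon: GenomicInterval,
    new_names: dict,
    utr_length: int = 0,
    stop_codon: Optional[GenomicInterval] = None,
    template_transcript_id: Optional[str] = None,
) -> GeneModel:
    """Build a new single-transcript gene: an existing transcript's exons
    5' of the donor, plus the donor as the new terminal exon.

    This reconstructs an unannotated isoform locus in a related genome once
    the terminal exon's coordinates are known (e.g., from local alignment of
    the orthologous exon sequence). ``new_names`` supplies ``gene_id``,
    ``transcript_id`` and ``gene_name``. An optional 3'UTR record of
    ``utr_length`` bp is appended immediately downstream of the donor
    (strand-aware); an explicit ``stop_codon`` interval may be added too —
    both geometries vary between annotation sources, so neither is guessed.
    """
    if donor_exon.seqname != gene.seqname:
        raise GraftError(
            f"donor exon on {donor_exon.seqname}, gene on {gene.seqname}"
        )
    if donor_exon.strand != gene.strand:
        raise GraftError(
            f"donor exon strand {donor_exon.strand!r} != gene strand {gene.strand!r}"
        )
    for tx in gene.transcripts:
        for iv in tx.exons:
            if iv.overlaps(donor_exon):
                raise GraftError(
                    f"donor exon {donor_exon} overlaps existing exon {iv} "
                    f"of {tx.transcript_id}"
                )

    if template_transcript_id is not None:
        template = gene.transcript(template_transcript_id)
    else:
        template = max(
            gene.transcripts,
            key=lambda t: (len(t.exons), t.spliced_length, t.transcript_id),
        )

    if gene.strand == "+":
        upstream = [iv for iv in template.exons if iv.end < donor_exon.start]
    else:
        upstream = [iv for iv in template.exons if iv.start > donor_exon.end]
    if not upstream:
        raise GraftError(
            "no exon of the template transcript lies 5' of the donor exon"
        )
    exons = sorted(upstream + [donor_exon], key=lambda iv: iv.start)

    other: list[FeatureRecord] = []
    attrs_base = {
        "gene_id": new_names["gene_id"],
        "transcript_id": new_names["transcript_id"],
        "gene_name": new_names["gene_name"],
        "gene_biotype": gene.biotype,
    }
    if utr_length > 0:
        if gene.strand == "+":
            utr = GenomicInterval(
                gene.seqname, donor_exon.end + 1, donor_exon.end + utr_length, "+"
            )
        else:
            utr = GenomicInterval(
                gene.seqname, donor_exon.start - utr_length, donor_exon.start - 1, "-"
            )
        other.append(
            FeatureRecord(utr, "three_prime_utr", attributes=dict(attrs_base))
        )
    if stop_codon is not None:
        other.append(
            FeatureRecord(stop_codon, "stop_codon", attributes=dict(attrs_base))
        )

    new_tx = TranscriptModel(
        transcript_id=new_names["transcript_id"],
        gene_id=new_names["gene_id"],
        seqname=gene.seqname,
        strand=gene.strand,
        exons=exons,
        other_records=other,
        attributes={},
    )
    return GeneModel(
        gene_id=new_names["gene_id"],
        gene_name=new_names["gene_name"],
        transcripts=[new_tx],
        attributes={"gene_biotype": gene.biotype},
    )


def add_gene(annotation: Annotation, gene: GeneModel, source: str = "exonproxy") -> Annotation:
    """Append a GeneModel's records to an annotation (new ids required)."""
    if gene.gene_id in annotation.gene_ids():
        raise IdCollisionError(f"gene_id {gene.gene_id!r} already present")
    records = annotation.records + gene_to_records(gene, source=source)
    genes, orphans = assemble_genes(records)
    return Annotation(
        records=records, genes=genes, orphans=orphans, header=list(annotation.header)
    )
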