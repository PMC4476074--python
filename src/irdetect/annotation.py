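"""Gene annotation parsing and intron catalog construction.

Parses GFF3/GTF gene models and derives the genome-wide catalog of introns,
each with its flanking exons and strand-aware splice-site coordinates. All
internal coordinates are 0-based half-open; the 1-based inclusive convention
of GFF/GTF is converted at the parsing boundary, which keeps length
arithmetic unambiguous and makes the catalog directly exchangeable as BED.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import gffutils

logger = logging.getLogger("irdetect")


class AnnotationParseError(ValueError):
    """Raised when the annotation stream cannot be parsed."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


@dataclass
class GeneModel:
    """A gene with its transcripts' ordered exon chains.

    ``union_exonic_length`` is the number of base pairs covered by the union
    of all exons across transcripts (the denominator of gene-level RPKM).
    """

    gene_id: str
    transcripts: list[tuple[str, list[GenomicInterval]]]
    span: GenomicInterval = field(init=False)
    union_exonic_length: int = field(init=False)

    def __post_init__(self) -> None:
        exons = [e for _, chain in self.transcripts for e in chain]
        if not exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        chrom = exons[0].chrom
        strand = exons[0].strand
        self.span = GenomicInterval(
            chrom, min(e.start for e in exons), max(e.end for e in exons), strand
        )
        self.union_exonic_length = sum(
            e - s for s, e in merge_intervals((e.start, e.end) for e in exons)
        )

    @property
    def exon_union(self) -> list[tuple[int, int]]:
        return merge_intervals(
            (e.start, e.end) for _, chain in self.transcripts for e in chain
        )


@dataclass(frozen=True)
class IntronRecord:
    """An annotated intron: the gap between two consecutive exons.

    ``ss5_pos``/``ss3_pos`` are the donor (exon-to-intron) and acceptor
    (intron-to-exon) boundary coordinates in transcription direction: on the
    minus strand the donor sits at ``interval.end``.
    """

    intron_id: str
    interval: GenomicInterval
    gene_id: str
    upstream_exon: GenomicInterval
    downstream_exon: GenomicInterval
    ss5_pos: int
    ss3_pos: int

    def __post_init__(self) -> None:
        if self.upstream_exon.end != self.interval.start:
            raise ValueError("upstream exon must abut the intron start")
        if self.downstream_exon.start != self.interval.end:
            raise ValueError("downstream exon must abut the intron end")


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, returned sorted and disjoint."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _validate_lines(text: str) -> None:
    # gffutils reports dialect failures without positions; a cheap pre-pass
    # pins malformed lines to their line number.
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise AnnotationParseError(
                f"malformed annotation line {lineno}: expected 9 tab-separated "
                f"fields, got {len(fields)}"
            )
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise AnnotationParseError(
                f"malformed annotation line {lineno}: non-integer coordinates"
            ) from exc
        if start < 1 or end < start:
            raise AnnotationParseError(
                f"malformed annotation line {lineno}: invalid span {start}-{end}"
            )


def parse_annotation(annotation: str | os.PathLike | TextIO) -> list[GeneModel]:
    """Parse a GFF3 or GTF stream into gene models.

    Accepts a path or an open text handle. Exon coordinates are converted
    from 1-based inclusive to 0-based half-open. Exons whose parent
    transcript cannot be resolved are skipped with a warning.
    """
    if hasattr(annotation, "read"):
        text = annotation.read()
    else:
        with open(annotation) as fh:
            text = fh.read()
    _validate_lines(text)
    try:
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise AnnotationParseError(f"annotation could not be parsed: {exc}") from exc

    genes: list[GeneModel] = []
    orphans = 0
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        transcripts: list[tuple[str, list[GenomicInterval]]] = []
        for tx in db.children(gene, level=1, order_by="start"):
            exons = [
                GenomicInterval(e.seqid, e.start - 1, e.end, e.strand or ".")
                for e in db.children(tx, featuretype="exon", order_by="start")
            ]
            if exons:
                transcripts.append((tx.id, exons))
        if transcripts:
            genes.append(GeneModel(gene.id, transcripts))
    for exon in db.features_of_type("exon"):
        if not exon.attributes.get("Parent") and not exon.attributes.get(
            "transcript_id"
        ):
            orphans += 1
    if orphans:
        warnings.warn(f"skipped {orphans} exon(s) with no parent transcript")
    return genes


def derive_introns(genes: Iterable[GeneModel]) -> list[IntronRecord]:
    """Enumerate introns as the gaps between consecutive exons.

    Identical gaps arising in several transcripts (or genes) are emitted
    once, keyed on (chrom, start, end, strand); flanking exons come from the
    first defining transcript in input order. Unstranded introns are treated
    as plus-strand for splice-site assignment, with a warning.
    """
    seen: dict[tuple[str, int, int, str], IntronRecord] = {}
    warned_unstranded = False
    for gene in genes:
        for _, exons in gene.transcripts:
            ordered = sorted(exons, key=lambda e: e.start)
            for up, down in zip(ordered, ordered[1:]):
                key = (up.chrom, up.end, down.start, up.strand)
                if key in seen:
                    continue
                interval = GenomicInterval(up.chrom, up.end, down.start, up.strand)
                if interval.strand == "-":
                    ss5, ss3 = interval.end, interval.start
                else:
                    if interval.strand == "." and not warned_unstranded:
                        logger.warning(
                            "unstranded intron(s): assigning 5' splice site to "
                            "the lower coordinate"
                        )
                        warned_unstranded = True
                    ss5, ss3 = interval.start, interval.end
                seen[key] = IntronRecord(
                    intron_id=f"{interval.chrom}:{interval.start}-"
                    f"{interval.end}:{interval.strand}",
                    interval=interval,
                    gene_id=gene.gene_id,
                    upstream_exon=up,
                    downstream_exon=down,
                    ss5_pos=ss5,
                    ss3_pos=ss3,
                )
    return sorted(
        seen.values(),
        key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end),
    )


def write_intron_bed(catalog: Sequence[IntronRecord], path: str | os.PathLike) -> None:
    """Write the intron catalog as 6-column BED."""
    with open(path, "w") as fh:
        for rec in catalog:
            iv = rec.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.intron_id}\t0\t{iv.strand}\n"
            )


def read_intervals_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read a BED(3+) file as a list of intervals (0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            strand = fields[5] if len(fields) > 5 else "."
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
    return out
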