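"""Per-sample feature extraction from spliced alignments, and depth normalization.

For every intron and condition, seven features are extracted from
uniquely-mapped reads:

* ``n_intron`` — unspliced reads fully contained in the intron;
* ``n_exon``   — reads fully contained in either flanking exon;
* ``n_junc``   — spliced reads whose block gap matches the intron exactly,
  with a minimum aligned anchor on each side;
* ``n_5ss``/``n_3ss`` — unspliced reads straddling the donor/acceptor
  boundary with a minimum overhang on both the exonic and intronic side;
* ``n_coverage`` — fraction of intron positions covered by at least one read;
* ``n_expression`` — gene-level RPKM on the union exon model.

"Within" means full containment of the aligned span, not mere overlap:
boundary-straddling reads are a signal of their own (``n_5ss``/``n_3ss``) and
containment keeps the count features disjoint.

Library-depth normalization uses the standard normalization scale (SNS): the
minimum per-sample mapped-read total. Each raw count is divided by its
sample's total and multiplied by the SNS, and replicate-normalized counts are
summed per condition. Normalized counts stay fractional; rounding would bias
small counts.
"""

from __future__ import annotations

import os
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import GeneModel, IntronRecord

DEFAULT_MIN_ANCHOR = 4
DEFAULT_MIN_OVERHANG = 1
DEFAULT_MAPQ = 20

#: canonical column order of the feature table
FEATURE_COLUMNS = [
    "intron_id", "chrom", "start", "end", "strand",
    "TNintron", "TNexon", "TNjunc", "TN5ss", "TN3ss", "TNcoverage", "TNexpression",
    "CNintron", "CNexon", "CNjunc", "CN5ss", "CN3ss", "CNcoverage", "CNexpression",
]


@dataclass(frozen=True)
class AlignedRead:
    """A mapped read reduced to its aligned blocks.

    ``blocks`` is an ordered tuple of (start, end) reference intervals; two
    or more blocks mean the read is spliced across one or more gaps.
    """

    read_id: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]
    unique: bool = True

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def spliced(self) -> bool:
        return len(self.blocks) > 1

    def gaps(self) -> list[tuple[int, int]]:
        return [
            (a[1], b[0]) for a, b in zip(self.blocks, self.blocks[1:])
        ]


@dataclass
class NormalizationPlan:
    """Scale factors mapping each sample's counts onto the SNS depth."""

    sample_totals: dict[str, int]
    sns: int
    scale_factors: dict[str, float]


def _blocks_from_cigar(pos: int, cigartuples) -> tuple[tuple[int, int], ...]:
    # M/=/X/D consume reference within a block; N opens a new block.
    blocks: list[tuple[int, int]] = []
    cur = pos
    block_start = pos
    for op, length in cigartuples:
        if op in (0, 7, 8, 2):  # M, =, X, D
            cur += length
        elif op == 3:  # N: splice gap
            if cur > block_start:
                blocks.append((block_start, cur))
            cur += length
            block_start = cur
        # I, S, H, P consume no reference
    if cur > block_start:
        blocks.append((block_start, cur))
    return tuple(blocks)


def load_reads(
    path: str | os.PathLike, mapq_threshold: int = DEFAULT_MAPQ
) -> tuple[list[AlignedRead], int]:
    """Load primary mapped reads from a SAM/BAM file.

    Returns (reads, total_mapped). A read is flagged unique if its NH tag
    equals 1, or, lacking the tag, if its mapping quality is at least
    ``mapq_threshold``.
    """
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(os.fspath(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.has_tag("NH"):
                unique = aln.get_tag("NH") == 1
            else:
                unique = aln.mapping_quality >= mapq_threshold
            reads.append(
                AlignedRead(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    blocks=_blocks_from_cigar(
                        aln.reference_start, aln.cigartuples or []
                    ),
                    unique=unique,
                )
            )
    return reads, len(reads)


class ReadIndex:
    """Per-chromosome start-sorted read index for overlap queries."""

    def __init__(self, reads: Iterable[AlignedRead]):
        by_chrom: dict[str, list[AlignedRead]] = {}
        self.n_reads = 0
        for r in reads:
            by_chrom.setdefault(r.chrom, []).append(r)
            self.n_reads += 1
        self._chroms: dict[str, tuple[list[int], list[AlignedRead], int]] = {}
        for chrom, rs in by_chrom.items():
            rs.sort(key=lambda r: (r.start, r.end, r.read_id))
            starts = [r.start for r in rs]
            max_span = max((r.end - r.start for r in rs), default=0)
            self._chroms[chrom] = (starts, rs, max_span)

    def overlapping(self, chrom: str, start: int, end: int) -> list[AlignedRead]:
        entry = self._chroms.get(chrom)
        if entry is None:
            return []
        starts, rs, max_span = entry
        lo = bisect_left(starts, start - max_span)
        hi = bisect_right(starts, end - 1)
        return [r for r in rs[lo:hi] if r.end > start]


def count_intron_reads(reads: ReadIndex | Iterable[AlignedRead], intron: IntronRecord) -> int:
    """Unspliced unique reads fully contained in the intron."""
    iv = intron.interval
    return sum(
        1
        for r in _candidates(reads, iv.chrom, iv.start, iv.end)
        if r.unique and not r.spliced and iv.contains(r.start, r.end)
    )


def count_flanking_exon_reads(
    reads: ReadIndex | Iterable[AlignedRead], intron: IntronRecord
) -> int:
    """Unique reads whose aligned span lies entirely within either flanking exon."""
    n = 0
    counted: set[int] = set()
    for idx, exon in enumerate((intron.upstream_exon, intron.downstream_exon)):
        for r in _candidates(reads, exon.chrom, exon.start, exon.end):
            if r.unique and exon.contains(r.start, r.end) and id(r) not in counted:
                counted.add(id(r))
                n += 1
    return n


def count_junction_reads(
    reads: ReadIndex | Iterable[AlignedRead],
    intron: IntronRecord,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> int:
    """Spliced unique reads with a block gap exactly matching the intron.

    Requires at least ``min_anchor`` aligned bases in the blocks on each
    side of the matching gap.
    """
    if min_anchor < 1:
        raise ValueError("min_anchor must be >= 1")
    iv = intron.interval
    n = 0
    for r in _candidates(reads, iv.chrom, iv.start, iv.end):
        if not (r.unique and r.spliced):
            continue
        for i, gap in enumerate(r.gaps()):
            if gap == (iv.start, iv.end):
                left = r.blocks[i]
                right = r.blocks[i + 1]
                if (left[1] - left[0]) >= min_anchor and (
                    right[1] - right[0]
                ) >= min_anchor:
                    n += 1
                break
    return n


def count_splice_site_reads(
    reads: ReadIndex | Iterable[AlignedRead],
    intron: IntronRecord,
    side: str,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> int:
    """Unspliced unique reads straddling the 5' or 3' splice-site boundary.

    The read span must extend at least ``min_overhang`` bases into both the
    exonic and the intronic side of the boundary.
    """
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    if side == "5ss":
        boundary = intron.ss5_pos
    elif side == "3ss":
        boundary = intron.ss3_pos
    else:
        raise ValueError(f"side must be '5ss' or '3ss', got {side!r}")
    iv = intron.interval
    n = 0
    for r in _candidates(reads, iv.chrom, boundary - min_overhang, boundary + min_overhang):
        if (
            r.unique
            and not r.spliced
            and r.start <= boundary - min_overhang
            and r.end >= boundary + min_overhang
        ):
            n += 1
    return n


def intron_coverage(
    reads: ReadIndex | Iterable[AlignedRead], intron: IntronRecord
) -> float:
    """Fraction of intron positions covered by >=1 unique read (spliced blocks count)."""
    iv = intron.interval
    length = len(iv)
    covered = np.zeros(length, dtype=bool)
    for r in _candidates(reads, iv.chrom, iv.start, iv.end):
        if not r.unique:
            continue
        for bs, be in r.blocks:
            lo = max(bs, iv.start) - iv.start
            hi = min(be, iv.end) - iv.start
            if hi > lo:
                covered[lo:hi] = True
    return float(covered.sum()) / length


def gene_rpkm(exonic_read_count: float, total_mapped: float, union_exonic_length: int) -> float:
    """Reads per kilobase of union exon model per million mapped reads."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    if union_exonic_length <= 0:
        raise ValueError("union_exonic_length must be > 0")
    return 1e9 * exonic_read_count / (total_mapped * union_exonic_length)


def count_gene_exonic_reads(
    reads: ReadIndex | Iterable[AlignedRead], gene: GeneModel
) -> int:
    """Unique reads with at least one aligned block overlapping the gene's exon union."""
    union = gene.exon_union
    span = gene.span
    n = 0
    for r in _candidates(reads, span.chrom, span.start, span.end):
        if not r.unique:
            continue
        if any(
            bs < ue and be > us
            for bs, be in r.blocks
            for us, ue in union
        ):
            n += 1
    return n


def _candidates(
    reads: ReadIndex | Iterable[AlignedRead], chrom: str, start: int, end: int
) -> Iterable[AlignedRead]:
    if isinstance(reads, ReadIndex):
        return reads.overlapping(chrom, start, end)
    return [r for r in reads if r.chrom == chrom and r.start < end and r.end > start]


def build_normalization_plan(sample_totals: Mapping[str, int]) -> NormalizationPlan:
    """SNS plan: sns = min(total); factor[s] = sns / total[s]."""
    if not sample_totals:
        raise ValueError("at least one sample is required")
    for name, total in sample_totals.items():
        if total <= 0:
            raise ValueError(f"sample {name!r} has non-positive total {total}")
    sns = min(sample_totals.values())
    return NormalizationPlan(
        sample_totals=dict(sample_totals),
        sns=sns,
        scale_factors={s: sns / t for s, t in sample_totals.items()},
    )


def extract_sample_counts(
    index: ReadIndex,
    catalog: Sequence[IntronRecord],
    genes: Sequence[GeneModel],
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Raw per-intron count features and per-gene exonic counts for one sample."""
    rows = []
    for intron in catalog:
        rows.append(
            {
                "intron_id": intron.intron_id,
                "n_intron": count_intron_reads(index, intron),
                "n_exon": count_flanking_exon_reads(index, intron),
                "n_junc": count_junction_reads(index, intron, min_anchor),
                "n_5ss": count_splice_site_reads(index, intron, "5ss", min_overhang),
                "n_3ss": count_splice_site_reads(index, intron, "3ss", min_overhang),
            }
        )
    counts = pd.DataFrame(rows).set_index("intron_id")
    gene_exonic = {g.gene_id: count_gene_exonic_reads(index, g) for g in genes}
    return counts, gene_exonic


def _condition_features(
    sample_reads: Mapping[str, list[AlignedRead]],
    catalog: Sequence[IntronRecord],
    genes: Sequence[GeneModel],
    plan: NormalizationPlan,
    min_anchor: int,
    min_overhang: int,
) -> pd.DataFrame:
    count_cols = ["n_intron", "n_exon", "n_junc", "n_5ss", "n_3ss"]
    norm = None
    gene_norm: dict[str, float] = {g.gene_id: 0.0 for g in genes}
    pooled: list[AlignedRead] = []
    for sample, reads in sample_reads.items():
        index = ReadIndex(reads)
        counts, gene_exonic = extract_sample_counts(
            index, catalog, genes, min_anchor, min_overhang
        )
        factor = plan.scale_factors[sample]
        scaled = counts[count_cols] * factor
        norm = scaled if norm is None else norm + scaled
        for gid, c in gene_exonic.items():
            gene_norm[gid] += c * factor
        pooled.extend(reads)

    # coverage is a fraction, not a count: computed on pooled, unscaled reads
    pooled_index = ReadIndex(pooled)
    norm["n_coverage"] = [
        intron_coverage(pooled_index, intron) for intron in catalog
    ]
    effective_total = plan.sns * len(sample_reads)
    gene_len = {g.gene_id: g.union_exonic_length for g in genes}
    rpkm = {
        gid: gene_rpkm(c, effective_total, gene_len[gid])
        for gid, c in gene_norm.items()
    }
    norm["n_expression"] = [rpkm[intron.gene_id] for intron in catalog]
    return norm


def build_feature_table(
    treatment: Mapping[str, list[AlignedRead]],
    control: Mapping[str, list[AlignedRead]],
    catalog: Sequence[IntronRecord],
    genes: Sequence[GeneModel],
    plan: NormalizationPlan | None = None,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> pd.DataFrame:
    """Assemble the per-intron treatment/control feature table.

    ``treatment``/``control`` map sample names to read lists. Per condition,
    each count feature is the sum over replicates of raw count times the
    sample's SNS scale factor; coverage is computed on the pooled replicate
    reads; expression is RPKM from pooled normalized exonic counts against
    an effective library size of SNS times the replicate count.
    """
    if not treatment or not control:
        raise ValueError("at least one sample per condition is required")
    if not catalog:
        import warnings

        warnings.warn("empty intron catalog: returning empty feature table")
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    if plan is None:
        totals = {
            s: len(reads) for s, reads in {**dict(treatment), **dict(control)}.items()
        }
        plan = build_normalization_plan(totals)

    t_feat = _condition_features(
        treatment, catalog, genes, plan, min_anchor, min_overhang
    )
    c_feat = _condition_features(
        control, catalog, genes, plan, min_anchor, min_overhang
    )

    base = pd.DataFrame(
        {
            "intron_id": [i.intron_id for i in catalog],
            "chrom": [i.interval.chrom for i in catalog],
            "start": [i.interval.start for i in catalog],
            "end": [i.interval.end for i in catalog],
            "strand": [i.interval.strand for i in catalog],
        }
    ).set_index("intron_id")
    rename_t = {
        "n_intron": "TNintron", "n_exon": "TNexon", "n_junc": "TNjunc",
        "n_5ss": "TN5ss", "n_3ss": "TN3ss", "n_coverage": "TNcoverage",
        "n_expression": "TNexpression",
    }
    rename_c = {k: "C" + v[1:] for k, v in rename_t.items()}
    table = base.join(t_feat.rename(columns=rename_t)).join(
        c_feat.rename(columns=rename_c)
    )
    return table.reset_index()[FEATURE_COLUMNS]


def write_feature_tsv(
    table: pd.DataFrame, path: str | os.PathLike, header_comment: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_feature_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
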