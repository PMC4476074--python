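"""Synthetic annotation and spliced-alignment generator with planted IR truth.

The generator emits a toy genome annotation (multi-exon genes on one
synthetic chromosome) and seeded per-replicate alignment records for a
treatment and a control condition. Every intron is assigned exactly one
truth class:

* ``true_ir``       — treatment-only retention: the intron is tiled to full
  coverage and both splice-site boundaries gain straddling reads, while the
  control keeps only spliced junction evidence;
* ``fp_boundary``   — boundary-straddling reads without interior signal
  (reads pile up at the splice sites but the intron body stays empty);
* ``fp_cluster``    — one dense interior pile-up covering under half of the
  intron positions;
* ``fp_expression`` — a gene-level two-fold expression shift with intron,
  exon and junction counts scaled proportionally in both conditions;
* ``clean``         — exon and junction reads only.

Reads are written directly as alignment records (no error model, no aligner
in the loop): fixed-length single-end reads, all flagged uniquely mapped,
placed by seeded uniform sampling. Identical configs yield byte-identical
output files.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import GeneModel, GenomicInterval, IntronRecord, derive_introns, parse_annotation
from .features import AlignedRead

TRUTH_CLASSES = ("true_ir", "fp_boundary", "fp_cluster", "fp_expression", "clean")

DEFAULT_CHROM = "simchr1"


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic dataset.

    Defaults emulate a small two-replicate differential IR experiment:
    20 four-exon genes (60 introns), 10% of introns planted as true IR and
    10% as each false-positive archetype.
    """

    n_genes: int = 20
    exons_per_gene: int = 4
    exon_length: int = 200
    intron_length: int = 150
    base_depth: int = 30          # exon reads per exon per replicate
    junction_depth: int = 8       # junction reads per intron per replicate
    read_length: int = 50
    ir_fraction: float = 0.10
    fp_boundary_fraction: float = 0.10
    fp_cluster_fraction: float = 0.10
    fp_expression_fraction: float = 0.10
    replicates_per_condition: int = 2
    seed: int = 0
    chrom: str = DEFAULT_CHROM

    def __post_init__(self) -> None:
        fracs = (
            self.ir_fraction, self.fp_boundary_fraction,
            self.fp_cluster_fraction, self.fp_expression_fraction,
        )
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("class fractions must lie in [0,1] and sum to <= 1")
        if self.exon_length < 20 or self.intron_length < 20:
            raise ValueError("exon and intron lengths must be >= 20")
        if self.read_length > self.intron_length:
            raise ValueError("intron too short for the configured read length")
        if self.read_length > self.exon_length:
            raise ValueError("exon too short for the configured read length")
        if int(0.4 * self.intron_length) < self.read_length:
            raise ValueError(
                "intron too short to host a sub-half-intron read cluster; "
                "use intron_length >= 2.5 * read_length"
            )
        if self.exons_per_gene < 2:
            raise ValueError("need at least 2 exons per gene to have introns")

    @property
    def gene_length(self) -> int:
        return (
            self.exons_per_gene * self.exon_length
            + (self.exons_per_gene - 1) * self.intron_length
        )

    @property
    def sample_names(self) -> tuple[list[str], list[str]]:
        r = self.replicates_per_condition
        return (
            [f"treat{i + 1}" for i in range(r)],
            [f"ctrl{i + 1}" for i in range(r)],
        )


@dataclass(frozen=True)
class TruthRecord:
    intron_id: str
    klass: str


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    gff3: str
    genes: list[GeneModel]
    catalog: list[IntronRecord]
    truth: list[TruthRecord]
    samples: dict[str, list[AlignedRead]] = field(default_factory=dict)

    @property
    def treatment(self) -> dict[str, list[AlignedRead]]:
        names = self.config.sample_names[0]
        return {n: self.samples[n] for n in names}

    @property
    def control(self) -> dict[str, list[AlignedRead]]:
        names = self.config.sample_names[1]
        return {n: self.samples[n] for n in names}

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t.intron_id, t.klass) for t in self.truth],
            columns=["intron_id", "class"],
        )


def generate_annotation(
    config: SimulationConfig,
) -> tuple[str, list[GeneModel], list[IntronRecord]]:
    """Deterministic GFF3 for ``n_genes`` multi-exon genes, plus the catalog.

    Genes are laid head-to-tail with a 500 bp spacer, alternating strands.
    The returned catalog is exactly what ``derive_introns`` yields on the
    emitted annotation.
    """
    lines = ["##gff-version 3"]
    for g in range(config.n_genes):
        gid = f"gene{g + 1:03d}"
        strand = "+" if g % 2 == 0 else "-"
        gstart = 100 + g * (config.gene_length + 500)  # 0-based
        gend = gstart + config.gene_length
        lines.append(
            f"{config.chrom}\tsim\tgene\t{gstart + 1}\t{gend}\t.\t{strand}\t.\tID={gid}"
        )
        tid = f"{gid}.1"
        lines.append(
            f"{config.chrom}\tsim\tmRNA\t{gstart + 1}\t{gend}\t.\t{strand}\t.\t"
            f"ID={tid};Parent={gid}"
        )
        for e in range(config.exons_per_gene):
            estart = gstart + e * (config.exon_length + config.intron_length)
            eend = estart + config.exon_length
            lines.append(
                f"{config.chrom}\tsim\texon\t{estart + 1}\t{eend}\t.\t{strand}\t.\t"
                f"ID={tid}.exon{e + 1};Parent={tid}"
            )
    gff3 = "\n".join(lines) + "\n"
    genes = parse_annotation(io.StringIO(gff3))
    catalog = derive_introns(genes)
    return gff3, genes, catalog


def assign_truth_classes(
    config: SimulationConfig,
    catalog: Sequence[IntronRecord],
    rng: np.random.Generator,
) -> list[TruthRecord]:
    """Partition the catalog into the five truth classes.

    The expression-shift archetype acts at gene level, so whole genes are
    drawn for it until its intron quota is met; the remaining archetypes are
    drawn per intron from the other genes.
    """
    n = len(catalog)
    k_expr = int(round(config.fp_expression_fraction * n))
    by_gene: dict[str, list[str]] = {}
    for rec in catalog:
        by_gene.setdefault(rec.gene_id, []).append(rec.intron_id)
    gene_ids = sorted(by_gene)
    rng.shuffle(gene_ids)
    expr_introns: set[str] = set()
    expr_genes: set[str] = set()
    for gid in gene_ids:
        if len(expr_introns) >= k_expr:
            break
        expr_genes.add(gid)
        expr_introns.update(by_gene[gid])

    remaining = [r.intron_id for r in catalog if r.intron_id not in expr_introns]
    rng.shuffle(remaining)
    k_ir = int(round(config.ir_fraction * n))
    k_b = int(round(config.fp_boundary_fraction * n))
    k_c = int(round(config.fp_cluster_fraction * n))
    classes: dict[str, str] = {i: "fp_expression" for i in expr_introns}
    cursor = 0
    for klass, k in (("true_ir", k_ir), ("fp_boundary", k_b), ("fp_cluster", k_c)):
        for intron_id in remaining[cursor:cursor + k]:
            classes[intron_id] = klass
        cursor += k
    for intron_id in remaining[cursor:]:
        classes[intron_id] = "clean"
    return [TruthRecord(rec.intron_id, classes[rec.intron_id]) for rec in catalog]


def _unspliced(qname: str, chrom: str, start: int, length: int) -> AlignedRead:
    return AlignedRead(qname, chrom, ((start, start + length),), unique=True)


def _boundary_starts(
    rng: np.random.Generator, boundary: int, n: int, read_length: int, max_exonic: int
) -> list[int]:
    # exonic-side overhang drawn in [10, max_exonic]; read straddles the boundary
    return [boundary - int(rng.integers(10, max_exonic + 1)) for _ in range(n)]


def _tile_starts(intron: IntronRecord, read_length: int) -> list[int]:
    # step <= read_length guarantees gap-free coverage of the whole intron
    iv = intron.interval
    step = max(1, read_length // 2)
    starts = list(range(iv.start, iv.end - read_length + 1, step))
    if starts[-1] != iv.end - read_length:
        starts.append(iv.end - read_length)
    return starts


def simulate_alignments(
    config: SimulationConfig,
    catalog: Sequence[IntronRecord],
    genes: Sequence[GeneModel],
) -> tuple[dict[str, list[AlignedRead]], list[TruthRecord]]:
    """Seeded per-replicate reads for both conditions, plus truth labels."""
    rng = np.random.default_rng(config.seed)
    truth = assign_truth_classes(config, catalog, rng)
    klass_of = {t.intron_id: t.klass for t in truth}
    expr_genes = {
        rec.gene_id for rec in catalog if klass_of[rec.intron_id] == "fp_expression"
    }
    gene_of = {g.gene_id: g for g in genes}
    L = config.read_length
    treat_names, ctrl_names = config.sample_names
    samples: dict[str, list[AlignedRead]] = {}

    for condition, names in (("T", treat_names), ("C", ctrl_names)):
        for sample in names:
            reads: list[AlignedRead] = []
            serial = 0

            def tag() -> str:
                nonlocal serial
                serial += 1
                return f"{sample}.r{serial}"

            for gid in sorted(gene_of):
                gene = gene_of[gid]
                boost = 2 if (condition == "T" and gid in expr_genes) else 1
                for _, exons in gene.transcripts:
                    for exon in exons:
                        for _ in range(config.base_depth * boost):
                            s = int(rng.integers(exon.start, exon.end - L + 1))
                            reads.append(_unspliced(tag(), exon.chrom, s, L))
            for intron in catalog:
                iv = intron.interval
                boost = 2 if (
                    condition == "T" and intron.gene_id in expr_genes
                ) else 1
                for _ in range(config.junction_depth * boost):
                    a = int(rng.integers(10, L - 10 + 1))
                    reads.append(
                        AlignedRead(
                            tag(), iv.chrom,
                            ((iv.start - a, iv.start), (iv.end, iv.end + L - a)),
                            unique=True,
                        )
                    )
                klass = klass_of[intron.intron_id]
                if klass == "true_ir" and condition == "T":
                    for s in _tile_starts(intron, L):
                        reads.append(_unspliced(tag(), iv.chrom, s, L))
                    # extra interior reads vary the retention strength per intron
                    for _ in range(int(rng.integers(2, 7))):
                        s = int(rng.integers(iv.start, iv.end - L + 1))
                        reads.append(_unspliced(tag(), iv.chrom, s, L))
                    for b in (iv.start, iv.end):
                        for s in _boundary_starts(rng, b, 5, L, L - 10):
                            reads.append(_unspliced(tag(), iv.chrom, s, L))
                elif klass == "fp_boundary" and condition == "T":
                    for b in (iv.start, iv.end):
                        for s in _boundary_starts(rng, b, 5, L, 30):
                            reads.append(_unspliced(tag(), iv.chrom, s, L))
                elif klass == "fp_cluster" and condition == "T":
                    w = int(0.4 * len(iv))
                    ws = iv.start + int(rng.integers(0, len(iv) - w + 1))
                    for _ in range(12):
                        s = ws + int(rng.integers(0, w - L + 1))
                        reads.append(_unspliced(tag(), iv.chrom, s, L))
                elif klass == "fp_expression":
                    passes = 2 if condition == "T" else 1
                    for _ in range(passes):
                        for s in _tile_starts(intron, L):
                            reads.append(_unspliced(tag(), iv.chrom, s, L))
                    nb = 8 if condition == "T" else 4
                    for b in (iv.start, iv.end):
                        for s in _boundary_starts(rng, b, nb, L, L - 10):
                            reads.append(_unspliced(tag(), iv.chrom, s, L))
            reads.sort(key=lambda r: (r.chrom, r.start, r.end, r.read_id))
            samples[sample] = reads
    return samples, truth


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full synthetic dataset: annotation, catalog, reads, truth."""
    gff3, genes, catalog = generate_annotation(config)
    samples, truth = simulate_alignments(config, catalog, genes)
    return SimulatedDataset(
        config=config, gff3=gff3, genes=genes, catalog=catalog,
        truth=truth, samples=samples,
    )


def chrom_length(config: SimulationConfig) -> int:
    return 200 + config.n_genes * (config.gene_length + 500)


def write_sam(
    reads: Sequence[AlignedRead],
    path: str | os.PathLike,
    chrom_lengths: dict[str, int],
) -> None:
    """Write reads as a coordinate-sorted SAM file (uniquely mapped, NH:1)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in sorted(chrom_lengths.items())],
    }
    with pysam.AlignmentFile(os.fspath(path), "wh", header=header) as out:
        tids = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
        for r in sorted(reads, key=lambda r: (r.chrom, r.start, r.end, r.read_id)):
            a = pysam.AlignedSegment()
            a.query_name = r.read_id
            a.reference_id = tids[r.chrom]
            a.reference_start = r.start
            a.mapping_quality = 60
            cigar = []
            prev_end = None
            for bs, be in r.blocks:
                if prev_end is not None:
                    cigar.append((3, bs - prev_end))  # N
                cigar.append((0, be - bs))  # M
                prev_end = be
            a.cigartuples = cigar
            a.flag = 0
            a.set_tag("NH", 1)
            out.write(a)


def write_dataset(dataset: SimulatedDataset, outdir: str | os.PathLike) -> dict[str, str]:
    """Write GFF3, per-sample SAM files and the truth TSV; return the paths."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    gff_path = os.path.join(outdir, "annotation.gff3")
    with open(gff_path, "w") as fh:
        fh.write(dataset.gff3)
    paths["annotation"] = gff_path
    lengths = {dataset.config.chrom: chrom_length(dataset.config)}
    for sample, reads in dataset.samples.items():
        sam_path = os.path.join(outdir, f"{sample}.sam")
        write_sam(reads, sam_path, lengths)
        paths[sample] = sam_path
    truth_path = os.path.join(outdir, "truth.tsv")
    dataset.truth_frame().to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths


def simulate_predictions(
    catalog: Sequence[IntronRecord],
    truth: Sequence[TruthRecord],
    seed: int,
    n_sets: int = 3,
    hit_rate: float = 0.9,
    fp_rate: float = 0.05,
) -> list[list[GenomicInterval]]:
    """Noisy external-predictor interval lists for vote labeling.

    Each of ``n_sets`` predictors reports a planted-IR intron with
    probability ``hit_rate`` and any other intron with probability
    ``fp_rate``; intervals match catalog coordinates exactly. Synthetic
    stand-ins for real predictor output.
    """
    rng = np.random.default_rng(seed)
    klass_of = {t.intron_id: t.klass for t in truth}
    sets: list[list[GenomicInterval]] = []
    for _ in range(n_sets):
        intervals = []
        for rec in catalog:
            p = hit_rate if klass_of[rec.intron_id] == "true_ir" else fp_rate
            if rng.random() < p:
                intervals.append(rec.interval)
        sets.append(intervals)
    return sets


def make_separable_matrix(
    n: int = 500,
    n_shifted: int = 3,
    shift: float = 5.0,
    seed: int = 0,
    pos_fraction: float = 0.5,
) -> pd.DataFrame:
    """Synthetic labeled 17-feature matrix with a planted mean shift.

    All features are standard normal; positive rows get a ``shift``-pooled-SD
    shift on the first ``n_shifted`` designated features (intronic and
    splice-site counts). Useful for classifier calibration checks.
    """
    from .irclassifier import MATRIX_COLUMNS

    rng = np.random.default_rng(seed)
    n_pos = int(round(pos_fraction * n))
    X = rng.normal(size=(n, len(MATRIX_COLUMNS)))
    shifted_cols = ["TNintron", "TN5ss", "TN3ss", "TNcoverage", "DIE", "DIJ"][:n_shifted]
    labels = np.array(["yes"] * n_pos + ["no"] * (n - n_pos))
    perm = rng.permutation(n)
    labels = labels[perm]
    frame = pd.DataFrame(X, columns=MATRIX_COLUMNS)
    for col in shifted_cols:
        frame.loc[labels == "yes", col] += shift
    frame["label"] = labels
    frame.index = [f"synthintron{i:04d}" for i in range(n)]
    frame.index.name = "intron_id"
    return frame
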