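"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain per-read / per-line loops, deliberately
sharing no code with the package internals.
"""

from __future__ import annotations

import math
from collections import defaultdict


def brute_count_intron(reads, intron) -> int:
    n = 0
    for r in reads:
        if r.chrom != intron.interval.chrom or not r.unique or len(r.blocks) != 1:
            continue
        (s, e), = r.blocks
        if s >= intron.interval.start and e <= intron.interval.end:
            n += 1
    return n


def brute_count_exon(reads, intron) -> int:
    n = 0
    for r in reads:
        if not r.unique:
            continue
        s, e = r.blocks[0][0], r.blocks[-1][1]
        for exon in (intron.upstream_exon, intron.downstream_exon):
            if r.chrom == exon.chrom and s >= exon.start and e <= exon.end:
                n += 1
                break
    return n


def brute_count_junc(reads, intron, min_anchor=4) -> int:
    n = 0
    target = (intron.interval.start, intron.interval.end)
    for r in reads:
        if r.chrom != intron.interval.chrom or not r.unique or len(r.blocks) < 2:
            continue
        for i in range(len(r.blocks) - 1):
            gap = (r.blocks[i][1], r.blocks[i + 1][0])
            if gap == target:
                la = r.blocks[i][1] - r.blocks[i][0]
                ra = r.blocks[i + 1][1] - r.blocks[i + 1][0]
                if la >= min_anchor and ra >= min_anchor:
                    n += 1
                break
    return n


def brute_count_ss(reads, intron, side, min_overhang=1) -> int:
    boundary = intron.ss5_pos if side == "5ss" else intron.ss3_pos
    n = 0
    for r in reads:
        if r.chrom != intron.interval.chrom or not r.unique or len(r.blocks) != 1:
            continue
        (s, e), = r.blocks
        if s + min_overhang <= boundary <= e - min_overhang:
            n += 1
    return n


def brute_coverage(reads, intron) -> float:
    covered = set()
    for r in reads:
        if r.chrom != intron.interval.chrom or not r.unique:
            continue
        for bs, be in r.blocks:
            for pos in range(max(bs, intron.interval.start), min(be, intron.interval.end)):
                covered.add(pos)
    return len(covered) / (intron.interval.end - intron.interval.start)


def brute_gene_exonic(reads, gene) -> int:
    exons = [(e.start, e.end) for _, chain in gene.transcripts for e in chain]
    n = 0
    for r in reads:
        if r.chrom != gene.span.chrom or not r.unique:
            continue
        hit = False
        for bs, be in r.blocks:
            for es, ee in exons:
                if bs < ee and be > es:
                    hit = True
        if hit:
            n += 1
    return n


def brute_parse_gff3(text: str):
    """Line-by-line GFF3 reader: {gene_id: {tx_id: [(chrom,start0,end,strand)]}}."""
    genes = defaultdict(lambda: defaultdict(list))
    tx_to_gene = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";"))
        if f[2] in ("mRNA", "transcript"):
            tx_to_gene[attrs["ID"]] = attrs["Parent"]
        elif f[2] == "exon":
            tx = attrs["Parent"]
            genes[tx_to_gene[tx]][tx].append(
                (f[0], int(f[3]) - 1, int(f[4]), f[6])
            )
    return {g: dict(txs) for g, txs in genes.items()}


def brute_intron_set(text: str) -> set:
    """Deduplicated (chrom, start, end, strand) gaps over all transcripts."""
    out = set()
    for txs in brute_parse_gff3(text).values():
        for exons in txs.values():
            exons = sorted(exons, key=lambda e: e[1])
            for a, b in zip(exons, exons[1:]):
                out.add((a[0], a[2], b[1], a[3]))
    return out


def brute_entropy(labels) -> float:
    counts = defaultdict(int)
    for x in labels:
        counts[x] += 1
    total = sum(counts.values())
    return -sum(c / total * math.log2(c / total) for c in counts.values())


def brute_info_gain(bin_ids, labels) -> float:
    h = brute_entropy(labels)
    groups = defaultdict(list)
    for b, y in zip(bin_ids, labels):
        groups[b].append(y)
    cond = sum(len(g) / len(labels) * brute_entropy(g) for g in groups.values())
    return h - cond
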