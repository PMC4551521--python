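"""Readers and writers for the pipeline's file formats.

Plain-text formats throughout: BED for interval tracks (0-based half-open),
GFF3 for contigs/scaffolds (converted to 1-based inclusive on output), TSV
for pileups, simulation truth and phased blocks, VCF for bulk SNP calls, and
the whitespace-delimited ``frag`` / ``allvars`` pair consumed by the phaser.
All writers are deterministic so write -> read -> write is byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .phaser import FragmentMatrix, HaplotypeBlock
from .phase_prep import SnpLocus
from .scaffolding import Contig, Scaffold

__all__ = [
    "read_bed",
    "write_bed",
    "write_gff3",
    "read_gff3",
    "write_truth_tsv",
    "read_truth_tsv",
    "write_pileups_tsv",
    "read_pileups_tsv",
    "write_bulk_vcf",
    "read_bulk_vcf",
    "read_frag",
    "read_allvars",
    "write_phased_tsv",
    "read_phased_tsv",
    "write_phased_vcf",
]


# --------------------------------------------------------------------- BED

def read_bed(path) -> list[tuple[str, int, int]]:
    """Read a 3+ column BED file into (chrom, start, end) tuples."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bed(intervals, path, chrom: str | None = None) -> None:
    """Write (start, end) pairs (with a fixed chrom) or (chrom, start, end) triples."""
    lines = []
    for iv in intervals:
        if len(iv) == 2:
            lines.append(f"{chrom}\t{iv[0]}\t{iv[1]}")
        else:
            lines.append(f"{iv[0]}\t{iv[1]}\t{iv[2]}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# -------------------------------------------------------------------- GFF3

def write_gff3(features, path=None, source: str = "cellhap") -> str:
    """Write contigs/scaffolds as GFF3 (1-based inclusive coordinates).

    Feature type is ``contig`` or ``scaffold`` by object class; the library
    id and read count go into the attribute column. Returns the text.
    """
    lines = ["##gff-version 3"]
    for i, f in enumerate(features):
        if isinstance(f, Contig):
            ftype = "contig"
            attrs = f"ID=contig{i};read_count={f.read_count}"
        elif isinstance(f, Scaffold):
            ftype = "scaffold"
            attrs = f"ID=scaffold{i}"
            if f.library_id:
                attrs += f";library={f.library_id}"
            if f.flags:
                attrs += f";flags={','.join(f.flags)}"
        else:
            raise TypeError(f"cannot serialise {type(f).__name__}")
        lines.append(
            f"{f.chrom}\t{source}\t{ftype}\t{f.start + 1}\t{f.end}\t.\t.\t.\t{attrs}"
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_gff3(path) -> list:
    """Read contig/scaffold features back (coordinates to 0-based half-open)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _src, ftype, start, end, _score, _strand, _phase, attrs = line.split("\t")
        start0, end0 = int(start) - 1, int(end)
        kv = dict(item.split("=", 1) for item in attrs.split(";") if "=" in item)
        if ftype == "contig":
            out.append(Contig(chrom, start0, end0, int(kv.get("read_count", 1))))
        elif ftype == "scaffold":
            flags = tuple(kv["flags"].split(",")) if "flags" in kv else ()
            out.append(Scaffold(chrom, start0, end0, kv.get("library", ""), flags=flags))
    return out


# ------------------------------------------------------------ truth / pileups

def write_truth_tsv(truth, path=None) -> str:
    """Phased truth as TSV: CHROM, POS (1-based), HAP0, HAP1."""
    lines = ["CHROM\tPOS\tHAP0\tHAP1"]
    for pos, a0, a1 in zip(truth.snp_positions, truth.hap0, truth.hap1):
        lines.append(f"{truth.chrom_name}\t{pos + 1}\t{a0}\t{a1}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_pileups_tsv(libraries, truth, path=None, include_zero: bool = False) -> str:
    """Per-library allele counts at truth loci: CHROM POS REF_COUNT ALT_COUNT LIBRARY_ID."""
    lines = ["CHROM\tPOS\tREF_COUNT\tALT_COUNT\tLIBRARY_ID"]
    for lib in libraries:
        for pos, rc, ac in zip(truth.snp_positions, lib.ref_counts, lib.alt_counts):
            if include_zero or rc or ac:
                lines.append(f"{truth.chrom_name}\t{pos + 1}\t{rc}\t{ac}\t{lib.library_id}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_pileups_tsv(path) -> dict[str, dict[tuple[str, int], tuple[int, int]]]:
    """Pileups keyed by library id, then (chrom, pos) -> (ref, alt) counts."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.LIBRARY_ID, {})[(row.CHROM, int(row.POS))] = (
            int(row.REF_COUNT),
            int(row.ALT_COUNT),
        )
    return out


# --------------------------------------------------------------------- VCF

_VCF_HEADER = """##fileformat=VCFv4.2
##source=cellhap
##contig=<ID={chrom},length={length}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tBULK
"""


def write_bulk_vcf(truth, path, depth: int = 30, ref_base: str = "A", alt_base: str = "C") -> None:
    """Bulk-sample VCF for a simulated truth: every truth SNP is 0/1.

    Simulated loci carry synthetic bases (all ref=A, alt=C); only genotype
    and depth matter downstream.
    """
    lines = [_VCF_HEADER.format(chrom=truth.chrom_name, length=truth.chrom_length).rstrip("\n")]
    for pos in truth.snp_positions:
        lines.append(
            f"{truth.chrom_name}\t{pos + 1}\t.\t{ref_base}\t{alt_base}\t50\tPASS\t.\tGT:DP\t0/1:{depth}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_bulk_vcf(path):
    """Yield (chrom, pos, ref, alts, genotype, depth) from a VCF via cyvcf2."""
    from cyvcf2 import VCF

    for variant in VCF(str(path)):
        gts = variant.genotypes[0]
        alleles = [g for g in gts[:-1] if g >= 0]
        if len(set(alleles)) > 1:
            genotype = "het"
        elif alleles and alleles[0] > 0:
            genotype = "hom_alt"
        else:
            genotype = "hom_ref"
        try:
            depth = float(variant.format("DP")[0][0])
        except (TypeError, KeyError):
            depth = float(variant.INFO.get("DP", 0) or 0)
        yield (variant.CHROM, variant.POS, variant.REF, list(variant.ALT), genotype, depth)


# ------------------------------------------------------------- frag/allvars

def read_frag(path) -> FragmentMatrix:
    """Parse a frag file (``B id s1 a1 s2 a2 ...``) into a FragmentMatrix."""
    fragments = []
    max_locus = 0
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        n_blocks = int(parts[0])
        fid = parts[1]
        calls: dict[int, int] = {}
        cursor = 2
        for _ in range(n_blocks):
            start = int(parts[cursor])
            alleles = parts[cursor + 1]
            cursor += 2
            for offset, ch in enumerate(alleles):
                calls[start + offset] = int(ch)
        max_locus = max(max_locus, max(calls))
        fragments.append((fid, calls))
    return FragmentMatrix(n_loci=max_locus, fragments=fragments)


def read_allvars(path) -> list[SnpLocus]:
    """Parse an allvars file (TSV: index chrom pos ref alt), index order."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        idx, chrom, pos, ref, alt = line.split("\t")
        rows.append((int(idx), SnpLocus(chrom, int(pos), ref, alt)))
    rows.sort(key=lambda r: r[0])
    return [locus for _, locus in rows]


# ----------------------------------------------------------- phased blocks

def write_phased_tsv(blocks: list[HaplotypeBlock], loci: list[SnpLocus], path=None) -> str:
    """Phased blocks as TSV: CHROM POS LOCUS_INDEX HAP0 HAP1 BLOCK_ID."""
    lines = ["CHROM\tPOS\tLOCUS_INDEX\tHAP0\tHAP1\tBLOCK_ID"]
    for bid, block in enumerate(blocks):
        for idx, a0, a1 in zip(block.locus_indices, block.hap0, block.hap1):
            locus = loci[int(idx) - 1]
            lines.append(f"{locus.chrom}\t{locus.pos}\t{idx}\t{a0}\t{a1}\tblock{bid}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_phased_tsv(path) -> tuple[list[HaplotypeBlock], list[SnpLocus]]:
    """Rebuild blocks (and minimal loci) from a phased-blocks TSV.

    MEC and fragment membership are not serialised; reread blocks carry
    ``mec=0`` and empty fragment lists. Loci are reconstructed with the
    synthetic ref/alt placeholders used by the truth writer.
    """
    by_block: dict[str, list[tuple[int, int, int]]] = {}
    loci_by_index: dict[int, SnpLocus] = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        chrom, pos, idx, a0, a1, bid = line.split("\t")
        by_block.setdefault(bid, []).append((int(idx), int(a0), int(a1)))
        loci_by_index[int(idx)] = SnpLocus(chrom, int(pos), "A", "C")
    blocks = []
    for bid in sorted(by_block, key=lambda b: min(r[0] for r in by_block[b])):
        rows = sorted(by_block[bid])
        blocks.append(
            HaplotypeBlock(
                locus_indices=np.array([r[0] for r in rows]),
                hap0=np.array([r[1] for r in rows]),
                hap1=np.array([r[2] for r in rows]),
                mec=0,
                fragment_ids=[],
            )
        )
    n = max(loci_by_index) if loci_by_index else 0
    loci = [loci_by_index.get(i, SnpLocus("NA", i, "A", "C")) for i in range(1, n + 1)]
    return blocks, loci


def write_phased_vcf(blocks: list[HaplotypeBlock], loci: list[SnpLocus], path) -> None:
    """Phased VCF with ``|``-separated GT and block-scoped phase sets (PS)."""
    chrom = loci[0].chrom if loci else "NA"
    header = (
        "##fileformat=VCFv4.2\n"
        "##source=cellhap\n"
        f"##contig=<ID={chrom}>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE"
    )
    rows = []
    for block in blocks:
        ps = int(block.locus_indices[0])
        for idx, a0, a1 in zip(block.locus_indices, block.hap0, block.hap1):
            locus = loci[int(idx) - 1]
            rows.append(
                (locus.pos, f"{locus.chrom}\t{locus.pos}\t.\t{locus.ref_allele}\t"
                            f"{locus.alt_allele}\t.\tPASS\t.\tGT:PS\t{a0}|{a1}:{ps}")
            )
    rows.sort()
    Path(path).write_text(header + "\n" + "\n".join(r[1] for r in rows) + "\n")
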