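"""VCF and tabular I/O.

Reading goes through cyvcf2; only bi-allelic SNPs with a GT field are kept
(multi-allelic sites and indels are skipped and counted).  Writing emits a
minimal VCF v4.2 with GT only.  Internally positions are 0-based half-open;
the conversion to VCF's 1-based coordinates happens here and nowhere else.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    FormatError,
    GenomeLayout,
    GenomicInterval,
    InputError,
    PopulationSpec,
    VariantMatrix,
)

logger = logging.getLogger(__name__)

_NUCS = frozenset("ACGT")


def read_vcf(path: str | Path, layout: GenomeLayout) -> VariantMatrix:
    """Read bi-allelic SNPs from a VCF into a :class:`VariantMatrix`.

    Half-missing genotypes are coded MISSING.  Phased haplotypes are kept
    only when every genotype in the file is phased.  Raises
    :class:`InputError` for a variant on a chromosome absent from ``layout``.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = tuple(vcf.samples)
    if not samples:
        raise InputError(f"VCF {path} contains no samples")

    chroms: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    geno_rows: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    all_phased = True
    skipped = 0
    for variant in vcf:
        if (
            len(variant.ALT) != 1
            or variant.REF not in _NUCS
            or variant.ALT[0] not in _NUCS
        ):
            skipped += 1
            continue
        if variant.CHROM not in layout.chrom_names:
            raise InputError(f"variant on unknown chromosome {variant.CHROM!r}")
        gts = variant.genotypes  # [allele0, allele1, phased] per sample
        row = np.empty(len(samples), dtype=np.int8)
        hrow = np.zeros((len(samples), 2), dtype=np.int8)
        for i, gt in enumerate(gts):
            a0, a1 = gt[0], gt[1]
            if a0 < 0 or a1 < 0:
                row[i] = MISSING
            else:
                row[i] = a0 + a1
                hrow[i, 0], hrow[i, 1] = a0, a1
            if not gt[2]:
                all_phased = False
        chroms.append(variant.CHROM)
        pos.append(variant.POS - 1)
        ref.append(variant.REF)
        alt.append(variant.ALT[0])
        geno_rows.append(row)
        hap_rows.append(hrow)
    vcf.close()
    if skipped:
        logger.info("skipped %d non-bi-allelic-SNP records in %s", skipped, path)

    genotypes = (
        np.vstack(geno_rows) if geno_rows else np.empty((0, len(samples)), np.int8)
    )
    haplotypes = None
    if all_phased and hap_rows and not np.any(genotypes == MISSING):
        haplotypes = np.stack(hap_rows)
    matrix = VariantMatrix(
        sample_ids=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref_allele=np.array(ref, dtype=object),
        alt_allele=np.array(alt, dtype=object),
        genotypes=genotypes,
        haplotypes=haplotypes,
    )
    matrix.check_against_layout(layout)
    return matrix


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_GT_PHASED = {0: ("0", "0"), 1: None, 2: ("1", "1")}


def write_vcf(matrix: VariantMatrix, layout: GenomeLayout, path: str | Path) -> None:
    """Write a minimal VCF v4.2 (GT only) with contig lines from ``layout``."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for name, length in zip(layout.chrom_names, layout.chrom_lengths):
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        phased = matrix.haplotypes is not None
        for v in range(matrix.n_variants):
            if phased:
                gts = [
                    f"{matrix.haplotypes[v, s, 0]}|{matrix.haplotypes[v, s, 1]}"
                    if matrix.genotypes[v, s] != MISSING
                    else ".|."
                    for s in range(matrix.n_samples)
                ]
            else:
                gts = [_GT_STRINGS[int(g)] for g in matrix.genotypes[v]]
            fh.write(
                f"{matrix.chrom[v]}\t{matrix.pos[v] + 1}\t.\t"
                f"{matrix.ref_allele[v]}\t{matrix.alt_allele[v]}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED5-style intervals (0-based half-open).

    Column 4 is the name, column 5 the category/trait label.  Raises
    :class:`FormatError` naming the offending line for start >= end.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end or start < 0:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval start={start} end={end}"
                )
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            category = parts[4] if len(parts) > 4 and parts[4] != "." else None
            out.append(GenomicInterval(chrom, start, end, name=name, category=category))
    return out


def write_intervals(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.category is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.category is not None:
                cols.append(iv.category)
            fh.write("\t".join(cols) + "\n")


def read_layout_table(path: str | Path) -> GenomeLayout:
    """Tab-separated chromosome table: name, length, autosome flag (1/0).

    A missing third column marks every chromosome as autosomal.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need at least name and length columns")
    flags = (
        df[2].astype(int).astype(bool).tolist()
        if df.shape[1] >= 3
        else [True] * len(df)
    )
    return GenomeLayout(
        chrom_names=tuple(df[0]),
        chrom_lengths=tuple(df[1].astype(int)),
        autosome_flags=tuple(flags),
    )


def read_population_table(path: str | Path) -> PopulationSpec:
    """Tab-separated sample -> population table (two columns, no header)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need sample and population columns")
    return PopulationSpec(assignments=dict(zip(df[0], df[1])))
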