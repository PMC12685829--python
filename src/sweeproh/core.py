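"""Core domain types shared by every analysis stage.

Coordinates are 0-based half-open everywhere inside the package; the VCF
reader/writer converts to and from VCF's 1-based convention and BED files
are already native.  Genotypes are coded 0 (hom-ref), 1 (het), 2 (hom-alt)
and :data:`MISSING` (-1); a half-missing call (e.g. ``./1``) is treated as
fully missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

MISSING: int = -1

__all__ = [
    "MISSING",
    "GenomeLayout",
    "GenomicInterval",
    "PopulationSpec",
    "VariantMatrix",
    "WindowGrid",
    "make_windows",
    "filter_maf_missing",
    "ld_prune",
]


class FormatError(ValueError):
    """Malformed input file."""


class InputError(ValueError):
    """Structurally valid file with inadmissible content."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names, lengths (bp) and autosome flags."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    autosome_flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths) or len(
            self.chrom_names
        ) != len(self.autosome_flags):
            raise ValueError("layout fields must have equal length")
        if any(length <= 0 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome name in layout")

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise InputError(f"unknown chromosome {chrom!r}") from None

    def is_autosome(self, chrom: str) -> bool:
        return self.autosome_flags[self.chrom_names.index(chrom)]

    @property
    def autosome_length(self) -> int:
        """L_AUTO, the denominator of F_ROH."""
        return sum(
            length
            for length, auto in zip(self.chrom_lengths, self.autosome_flags)
            if auto
        )


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    category: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class PopulationSpec:
    """sample_id -> population label assignment."""

    assignments: Mapping[str, str]

    def samples_of(self, pop: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == pop]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignments.values():
            seen.setdefault(p)
        return list(seen)

    def validate_against(self, sample_ids: Sequence[str]) -> None:
        missing = [s for s in sample_ids if s not in self.assignments]
        if missing:
            raise InputError(f"samples without population assignment: {missing}")


@dataclass
class VariantMatrix:
    """Samples x bi-allelic SNPs with positions.

    ``genotypes`` is an (n_variants, n_samples) int8 array of codes
    {0, 1, 2, MISSING}; ``haplotypes``, when present, is
    (n_variants, n_samples, 2) with allele codes {0, 1} whose unordered sum
    reproduces the genotype code.
    """

    sample_ids: tuple[str, ...]
    chrom: np.ndarray  # (n_variants,) str
    pos: np.ndarray  # (n_variants,) int64, 0-based
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    genotypes: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.pos), len(self.sample_ids)):
            raise ValueError("genotype matrix shape mismatch")
        self.validate()

    def validate(self) -> None:
        codes = np.unique(self.genotypes)
        allowed = {MISSING, 0, 1, 2}
        if not set(codes.tolist()) <= allowed:
            raise ValueError(f"illegal genotype codes {set(codes.tolist()) - allowed}")
        for chrom, idx in self.chrom_slices().items():
            p = self.pos[idx]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        if self.haplotypes is not None:
            hsum = self.haplotypes.sum(axis=2).astype(np.int8)
            known = self.genotypes != MISSING
            if not np.array_equal(hsum[known], self.genotypes[known]):
                raise ValueError("haplotypes inconsistent with genotype codes")

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous index slice per chromosome, in file order."""
        out: dict[str, slice] = {}
        if self.n_variants == 0:
            return out
        chroms = np.asarray(self.chrom)
        boundaries = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(chroms)]])
        for s, e in zip(starts, ends):
            name = str(chroms[s])
            if name in out:
                raise ValueError(f"chromosome {name} not contiguous in matrix")
            out[name] = slice(int(s), int(e))
        return out

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise InputError(f"unknown sample {sample_id!r}") from None

    def take_variants(self, index: np.ndarray) -> "VariantMatrix":
        return VariantMatrix(
            sample_ids=self.sample_ids,
            chrom=np.asarray(self.chrom)[index],
            pos=self.pos[index],
            ref_allele=np.asarray(self.ref_allele)[index],
            alt_allele=np.asarray(self.alt_allele)[index],
            genotypes=self.genotypes[index],
            haplotypes=None if self.haplotypes is None else self.haplotypes[index],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "VariantMatrix":
        idx = np.array([self.sample_index(s) for s in sample_ids])
        return VariantMatrix(
            sample_ids=tuple(sample_ids),
            chrom=np.asarray(self.chrom),
            pos=self.pos,
            ref_allele=np.asarray(self.ref_allele),
            alt_allele=np.asarray(self.alt_allele),
            genotypes=self.genotypes[:, idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, idx],
        )

    def allele_counts(self, variant_index: slice | np.ndarray, sample_idx: np.ndarray):
        """(alt allele count, total non-missing allele count) per variant."""
        g = self.genotypes[variant_index][:, sample_idx]
        known = g != MISSING
        alt = np.where(known, g, 0).sum(axis=1)
        n = 2 * known.sum(axis=1)
        return alt.astype(np.int64), n.astype(np.int64)

    def check_against_layout(self, layout: GenomeLayout) -> None:
        for chrom, sl in self.chrom_slices().items():
            if chrom not in layout.chrom_names:
                raise InputError(f"variant on unknown chromosome {chrom!r}")
            if self.pos[sl][-1] >= layout.length_of(chrom):
                raise InputError(
                    f"variant beyond end of {chrom} "
                    f"(pos {int(self.pos[sl][-1]) + 1} > length {layout.length_of(chrom)})"
                )


@dataclass(frozen=True)
class WindowGrid:
    """Sliding windows (0-based half-open) over a genome layout."""

    windows: tuple[GenomicInterval, ...]
    size: int
    step: int


def make_windows(layout: GenomeLayout, size: int, step: int) -> WindowGrid:
    """Sliding windows of ``size`` bp advancing by ``step`` bp per chromosome.

    Starts are 0, step, 2*step, ... while start < chromosome length; the
    final window is truncated at the chromosome end.
    """
    if size <= 0 or step <= 0:
        raise ValueError("window size and step must be positive")
    if step > size:
        raise ValueError("step must not exceed window size")
    windows: list[GenomicInterval] = []
    for chrom, length in zip(layout.chrom_names, layout.chrom_lengths):
        for start in range(0, length, step):
            windows.append(GenomicInterval(chrom, start, min(start + size, length)))
    return WindowGrid(windows=tuple(windows), size=size, step=step)


def _maf(matrix: VariantMatrix) -> np.ndarray:
    g = matrix.genotypes
    known = g != MISSING
    alt = np.where(known, g, 0).sum(axis=1)
    n = 2 * known.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return np.where(np.isnan(p), 0.0, np.minimum(p, 1 - p))


def filter_maf_missing(
    matrix: VariantMatrix, maf_min: float, max_missing_frac: float
) -> VariantMatrix:
    """Keep variants with MAF >= maf_min and missing fraction <= max_missing_frac.

    MAF is computed over non-missing genotypes only.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    missing_frac = (matrix.genotypes == MISSING).mean(axis=1)
    keep = (_maf(matrix) >= maf_min) & (missing_frac <= max_missing_frac)
    return matrix.take_variants(np.flatnonzero(keep))


def ld_prune(
    matrix: VariantMatrix,
    window_snps: int = 50,
    step_snps: int = 10,
    r2_max: float = 0.1,
) -> VariantMatrix:
    """Greedy LD pruning in the style of PLINK ``--indep-pairwise``.

    Scans each chromosome left to right in windows of ``window_snps`` SNPs
    advancing by ``step_snps``.  Within a window, while any retained pair has
    r^2 > ``r2_max``, one SNP of the worst pair is dropped: the one with the
    lower minor-allele frequency, or the later position on a tie.  r^2 is the
    composite (genotype-correlation) estimate of
    :func:`sweeproh.windowstats.compute_r2`.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    maf = _maf(matrix)
    keep = np.ones(matrix.n_variants, dtype=bool)
    for _, sl in matrix.chrom_slices().items():
        lo, hi = sl.start, sl.stop
        for wstart in range(lo, hi, step_snps):
            wend = min(wstart + window_snps, hi)
            idx = [i for i in range(wstart, wend) if keep[i]]
            r2m = _pairwise_r2(matrix.genotypes, idx)
            np.fill_diagonal(r2m, np.nan)
            r2m[np.tril_indices(len(idx))] = np.nan
            alive = np.ones(len(idx), dtype=bool)
            while np.any(alive):
                sub = np.where(np.outer(alive, alive), r2m, np.nan)
                if not np.any(sub > r2_max):
                    break
                ka, kb = np.unravel_index(np.nanargmax(sub), sub.shape)
                i, j = idx[int(ka)], idx[int(kb)]
                if maf[i] < maf[j]:
                    drop, kd = i, int(ka)
                elif maf[j] < maf[i]:
                    drop, kd = j, int(kb)
                elif matrix.pos[j] > matrix.pos[i]:
                    drop, kd = j, int(kb)
                else:
                    drop, kd = i, int(ka)
                keep[drop] = False
                alive[kd] = False
            if wend == hi:
                break
    return matrix.take_variants(np.flatnonzero(keep))


def _pairwise_r2(genotypes: np.ndarray, idx: list[int]) -> np.ndarray:
    """Composite r^2 matrix for a set of SNPs (NaN where undefined).

    Matches :func:`sweeproh.windowstats.compute_r2` (squared Pearson
    correlation of dosages over pairwise-complete samples).
    """
    from .windowstats import compute_r2  # deferred: windowstats imports core

    m = len(idx)
    g = genotypes[idx].astype(np.float64)
    out = np.full((m, m), np.nan)
    if m == 0:
        return out
    if not np.any(g == MISSING):
        sd = g.std(axis=1)
        ok = sd > 0
        if np.any(ok):
            c = np.corrcoef(g[ok])
            sub = np.square(np.atleast_2d(c))
            out[np.ix_(np.flatnonzero(ok), np.flatnonzero(ok))] = sub
        return out
    for a in range(m):
        for b in range(a + 1, m):
            r2 = compute_r2(g[a], g[b], phased=False)
            out[a, b] = out[b, a] = np.nan if r2 is None else r2
    return out
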