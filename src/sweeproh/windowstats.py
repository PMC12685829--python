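"""Per-site and per-window population-genetic statistics.

Implements nucleotide diversity (pi), Tajima's D, Hudson's F_ST with
ratio-of-averages window aggregation, the pi-ratio between two populations,
and LD r-squared with distance-binned decay curves.

Conventions
-----------
* pi is reported per bp of window length (summed per-site heterozygosity
  divided by window span), so pi-ratios are scale-free.
* All per-site statistics use pairwise-complete allele counts; a site with
  fewer than 2 non-missing alleles in a population is skipped.
* Undefined values (zero denominators) are ``None``, never NaN sentinels;
  downstream threshold selection excludes them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    MISSING,
    GenomicInterval,
    InputError,
    PopulationSpec,
    VariantMatrix,
    WindowGrid,
)

logger = logging.getLogger(__name__)

__all__ = [
    "WindowStat",
    "LDDecayCurve",
    "site_pi",
    "pi_windows",
    "tajimas_d",
    "hudson_fst_site",
    "fst_windows",
    "pi_ratio_windows",
    "compute_r2",
    "ld_decay",
]


@dataclass
class WindowStat:
    """Statistics for one genomic window."""

    window: GenomicInterval
    n_snps: int = 0
    pi_by_pop: dict[str, float] = field(default_factory=dict)
    fst: float | None = None
    pi_ratio: float | None = None
    tajima_d_by_pop: dict[str, float | None] = field(default_factory=dict)


@dataclass(frozen=True)
class LDDecayCurve:
    """Mean r-squared per physical-distance bin."""

    bin_edges: np.ndarray  # (n_bins + 1,) bp
    mean_r2: np.ndarray  # (n_bins,), NaN where pair_counts == 0
    pair_counts: np.ndarray
    max_distance: int
    maf_min: float


def site_pi(alt_count: int | np.ndarray, n_alleles: int | np.ndarray):
    """Per-site nucleotide diversity: unbiased heterozygosity 2p(1-p)n/(n-1).

    Equals the mean pairwise difference over the n alleles at the site.
    """
    alt = np.asarray(alt_count, dtype=np.float64)
    n = np.asarray(n_alleles, dtype=np.float64)
    if np.any(n < 2):
        raise ValueError("site_pi requires at least 2 alleles")
    p = alt / n
    result = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    return float(result) if result.ndim == 0 else result


def _window_indices(matrix: VariantMatrix, grid: WindowGrid) -> list[np.ndarray]:
    """Variant indices falling in each window (sorted positions assumed)."""
    slices = matrix.chrom_slices()
    out: list[np.ndarray] = []
    for w in grid.windows:
        sl = slices.get(w.chrom)
        if sl is None:
            out.append(np.empty(0, dtype=np.int64))
            continue
        p = matrix.pos[sl]
        lo = int(np.searchsorted(p, w.start, side="left"))
        hi = int(np.searchsorted(p, w.end, side="left"))
        out.append(np.arange(sl.start + lo, sl.start + hi, dtype=np.int64))
    return out


def _pop_site_arrays(matrix: VariantMatrix, sample_idx: np.ndarray):
    """Per-variant (alt count, allele count, site pi) for one population."""
    alt, n = matrix.allele_counts(slice(None), sample_idx)
    pi = np.zeros(matrix.n_variants)
    ok = n >= 2
    if np.any(ok):
        pi[ok] = site_pi(alt[ok], n[ok])
    return alt, n, pi, ok


def pi_windows(
    matrix: VariantMatrix,
    pops: PopulationSpec,
    grid: WindowGrid,
    tajima: bool = True,
) -> list[WindowStat]:
    """Windowed per-bp pi (and Tajima's D) for every population.

    Windows without SNPs get pi = 0 and n_snps = 0; Tajima's D is ``None``
    for windows with no segregating sites in a population.
    """
    pops.validate_against(matrix.sample_ids)
    per_pop: dict[str, tuple] = {}
    for pop in pops.populations:
        members = [s for s in matrix.sample_ids if pops.assignments[s] == pop]
        if len(members) < 2:
            raise InputError(f"population {pop!r} has fewer than 2 samples")
        idx = np.array([matrix.sample_index(s) for s in members])
        per_pop[pop] = (_pop_site_arrays(matrix, idx), 2 * len(members))

    stats: list[WindowStat] = []
    for w, snps in zip(grid.windows, _window_indices(matrix, grid)):
        st = WindowStat(window=w, n_snps=len(snps))
        for pop, ((alt, n, pi, ok), n_max) in per_pop.items():
            st.pi_by_pop[pop] = float(pi[snps].sum()) / w.length
            if tajima:
                use = snps[ok[snps]]
                st.tajima_d_by_pop[pop] = tajimas_d(
                    alt[use], n_max, n_alleles=n[use], pi_sum=float(pi[use].sum())
                )
        stats.append(st)
    return stats


def _tajima_constants(n: int) -> tuple[float, float, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d(
    alt_counts: np.ndarray,
    n: int,
    n_alleles: np.ndarray | None = None,
    pi_sum: float | None = None,
) -> float | None:
    """Tajima's D from per-site alternate-allele counts.

    ``n`` is the allele sample size fixing the constants (2N for diploid
    genotype data under infinite sites).  ``n_alleles`` optionally gives the
    realized non-missing allele count per site (defaults to ``n``
    everywhere); ``pi_sum`` optionally supplies the precomputed window sum
    of per-site pi.  Returns ``None`` when there are no segregating sites.
    """
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    alt = np.asarray(alt_counts, dtype=np.int64)
    nal = np.full(len(alt), n, dtype=np.int64) if n_alleles is None else np.asarray(
        n_alleles, dtype=np.int64
    )
    seg = (alt > 0) & (alt < nal)
    S = int(seg.sum())
    if S == 0:
        return None
    if pi_sum is None:
        pi_sum = float(site_pi(alt[seg], nal[seg]).sum()) if S else 0.0
    a1, e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    return (pi_sum - S / a1) / math.sqrt(var)


def hudson_fst_site(p1: float, n1: int, p2: float, n2: int) -> tuple[float, float]:
    """Hudson's per-site F_ST components (numerator, denominator).

    N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1);
    D = p1(1-p2) + p2(1-p1).  Returned separately so windows can aggregate
    as a ratio of averages.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("hudson_fst_site requires >= 2 alleles per population")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def fst_windows(
    matrix: VariantMatrix,
    pops: PopulationSpec,
    pop_a: str,
    pop_b: str,
    grid: WindowGrid,
    stats: list[WindowStat] | None = None,
) -> list[WindowStat]:
    """Window F_ST between two populations (Hudson, ratio of averages).

    Windows whose summed denominator is zero get ``None``.  Sites with
    fewer than 2 non-missing alleles in either population are skipped.
    Negative window values are kept as computed (clamping, if any, is a
    reporting decision).
    """
    for pop in (pop_a, pop_b):
        if pop not in pops.populations:
            raise InputError(f"unknown population {pop!r}")
    idx_a = np.array(
        [matrix.sample_index(s) for s in matrix.sample_ids if pops.assignments[s] == pop_a]
    )
    idx_b = np.array(
        [matrix.sample_index(s) for s in matrix.sample_ids if pops.assignments[s] == pop_b]
    )
    alt1, n1 = matrix.allele_counts(slice(None), idx_a)
    alt2, n2 = matrix.allele_counts(slice(None), idx_b)
    ok = (n1 >= 2) & (n2 >= 2)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.debug("F_ST: skipped %d sites with < 2 alleles", n_skipped)
    num = np.zeros(matrix.n_variants)
    den = np.zeros(matrix.n_variants)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(ok, alt1 / np.maximum(n1, 1), 0.0)
        p2 = np.where(ok, alt2 / np.maximum(n2, 1), 0.0)
    num[ok] = (
        (p1[ok] - p2[ok]) ** 2
        - p1[ok] * (1 - p1[ok]) / (n1[ok] - 1)
        - p2[ok] * (1 - p2[ok]) / (n2[ok] - 1)
    )
    den[ok] = p1[ok] * (1 - p2[ok]) + p2[ok] * (1 - p1[ok])

    if stats is None:
        stats = [
            WindowStat(window=w, n_snps=len(s))
            for w, s in zip(grid.windows, _window_indices(matrix, grid))
        ]
    for st, snps in zip(stats, _window_indices(matrix, grid)):
        d = float(den[snps].sum())
        st.fst = float(num[snps].sum()) / d if d > 0 else None
    return stats


def pi_ratio_windows(
    stats: list[WindowStat], reference_pop: str, target_pop: str
) -> list[WindowStat]:
    """Attach pi_ratio = pi_reference / pi_target per window.

    ``None`` (undefined) when the target population's pi is zero; such
    windows are excluded from empirical thresholds and never selected.
    """
    for st in stats:
        pi_ref = st.pi_by_pop[reference_pop]
        pi_tgt = st.pi_by_pop[target_pop]
        st.pi_ratio = pi_ref / pi_tgt if pi_tgt > 0 else None
    return stats


def compute_r2(
    g1: np.ndarray, g2: np.ndarray, phased: bool = False
) -> float | None:
    """LD r-squared between two loci.

    Phased: classical r^2 = D^2 / (pA pa pB pb) from 0/1 haplotype vectors.
    Unphased: squared Pearson correlation of genotype dosages over
    pairwise-complete samples (composite / Rogers-Huff form).  ``None``
    when either locus has zero variance or fewer than 2 complete pairs.
    """
    g1 = np.asarray(g1, dtype=np.float64)
    g2 = np.asarray(g2, dtype=np.float64)
    if g1.shape != g2.shape:
        raise ValueError("genotype vectors must have equal length")
    if phased:
        pa, pb = g1.mean(), g2.mean()
        if pa in (0.0, 1.0) or pb in (0.0, 1.0):
            return None
        d = (g1 * g2).mean() - pa * pb
        return d * d / (pa * (1 - pa) * pb * (1 - pb))
    ok = (g1 != MISSING) & (g2 != MISSING)
    if ok.sum() < 2:
        return None
    x, y = g1[ok], g2[ok]
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return None
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def ld_decay(
    matrix: VariantMatrix,
    pop_samples: list[str] | None = None,
    max_distance: int = 1_000_000,
    maf_min: float = 0.05,
    max_missing_frac: float = 0.4,
    n_bins: int = 100,
) -> LDDecayCurve:
    """Distance-binned mean r-squared over all intra-chromosome SNP pairs.

    Pairs at distance <= ``max_distance`` (inclusive) contribute to the bin
    of their distance; undefined r-squared values are skipped.  The MAF and
    call-rate filters are applied before pairing.
    """
    from .core import filter_maf_missing

    if pop_samples is not None:
        matrix = matrix.subset_samples(pop_samples)
    matrix = filter_maf_missing(matrix, maf_min, max_missing_frac)
    edges = np.linspace(0, max_distance, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for _, sl in matrix.chrom_slices().items():
        p = matrix.pos[sl]
        g = matrix.genotypes[sl].astype(np.float64)
        no_missing = not np.any(g == MISSING)
        if no_missing:
            mean = g.mean(axis=1, keepdims=True)
            centered = g - mean
            sd = g.std(axis=1)
        for i in range(len(p)):
            j_hi = int(np.searchsorted(p, p[i] + max_distance, side="right"))
            if j_hi <= i + 1:
                continue
            js = np.arange(i + 1, j_hi)
            if no_missing:
                if sd[i] == 0:
                    continue
                ok = sd[js] > 0
                js = js[ok]
                if len(js) == 0:
                    continue
                cov = centered[js] @ centered[i] / g.shape[1]
                r2s = np.square(cov / (sd[i] * sd[js]))
            else:
                r2s = np.array(
                    [compute_r2(g[i], g[j], phased=False) for j in js], dtype=object
                )
                keep = np.array([r is not None for r in r2s])
                js, r2s = js[keep], r2s[keep].astype(np.float64)
                if len(js) == 0:
                    continue
            dists = p[js] - p[i]
            bins = np.minimum(
                np.searchsorted(edges, dists, side="right") - 1, n_bins - 1
            )
            np.add.at(sums, bins, r2s)
            np.add.at(counts, bins, 1)
    if counts.sum() == 0:
        logger.warning("LD decay: no eligible SNP pairs")
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDDecayCurve(
        bin_edges=edges,
        mean_r2=mean,
        pair_counts=counts,
        max_distance=max_distance,
        maf_min=maf_min,
    )
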