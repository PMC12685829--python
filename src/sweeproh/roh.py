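"""Runs of homozygosity: PLINK-style detection, F_ROH, common ROH, islands.

The detector follows the sliding-window scan of PLINK ``--homozyg``: windows
of ``window_snps`` consecutive SNPs are scored as homozygous "hits" when
they contain at most ``window_het_max`` heterozygous and
``window_missing_max`` missing calls; each SNP's hit fraction is the share
of hit windows among the windows covering it (only windows fully inside the
chromosome's SNP list count), and SNPs at or above
``window_hit_threshold`` become ROH-eligible.  Maximal runs of eligible
SNPs, split at inter-SNP gaps above ``max_gap_kb``, are kept when they meet
the SNP-count, length and density filters.  Segment coordinates are
half-open: first member SNP position to last member position + 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import MISSING, GenomeLayout, GenomicInterval, VariantMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ROHParams",
    "ROHSegment",
    "ROHIsland",
    "FrohReport",
    "detect_roh",
    "detect_roh_all",
    "f_roh",
    "common_roh",
    "snp_roh_ratio",
    "roh_islands",
]

#: Length-class bins in bp: 0.1-0.5 Mb, 0.5-1 Mb, >= 1 Mb (left-closed).
LENGTH_CLASSES: tuple[tuple[int, float], ...] = (
    (100_000, 500_000),
    (500_000, 1_000_000),
    (1_000_000, float("inf")),
)
CLASS_LABELS: tuple[str, ...] = ("0.1-0.5Mb", "0.5-1Mb", ">1Mb")


@dataclass(frozen=True)
class ROHParams:
    """PLINK ``--homozyg`` parameter block."""

    window_snps: int = 50
    window_het_max: int = 1
    window_missing_max: int = 5
    window_hit_threshold: float = 0.05
    min_snps: int = 50
    min_kb: float = 100.0
    min_density_kb_per_snp: float = 100.0
    max_gap_kb: float = 1000.0

    def __post_init__(self) -> None:
        if self.window_snps < 1 or self.min_snps < 1:
            raise ValueError("SNP counts must be positive")
        if not 0 < self.window_hit_threshold <= 1:
            raise ValueError("window_hit_threshold must be in (0, 1]")
        if min(self.min_kb, self.min_density_kb_per_snp, self.max_gap_kb) <= 0:
            raise ValueError("kb parameters must be positive")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous tract of one sample (half-open bp coordinates)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_snps: int
    het_count: int = 0
    missing_count: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=self.sample_id)


@dataclass(frozen=True)
class ROHIsland:
    """Population-level high-homozygosity interval."""

    chrom: str
    start: int
    end: int
    n_snps: int
    peak_ratio: float
    mean_ratio: float

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class FrohReport:
    """Per-sample genomic inbreeding F_ROH = sum(L_ROH) / L_AUTO."""

    total: dict[str, float]
    by_class: dict[str, dict[str, float]]  # class label -> sample -> F
    per_chromosome: dict[str, dict[str, float]]  # chrom -> sample -> F
    n_segments: dict[str, int]

    def population_summary(self, assignments: dict[str, str]):
        """Mean and SD of F_ROH per population (total and per class)."""
        import pandas as pd

        rows = []
        for sample, total in self.total.items():
            row = {"sample": sample, "population": assignments.get(sample), "froh": total}
            for label in CLASS_LABELS:
                row[f"froh_{label}"] = self.by_class[label][sample]
            rows.append(row)
        df = pd.DataFrame(rows)
        return df.groupby("population").agg(["mean", "std"])


def detect_roh(
    matrix: VariantMatrix, sample_id: str, params: ROHParams = ROHParams()
) -> list[ROHSegment]:
    """Call ROH segments for one sample."""
    s = matrix.sample_index(sample_id)
    segments: list[ROHSegment] = []
    for chrom, sl in matrix.chrom_slices().items():
        g = matrix.genotypes[sl, s]
        pos = matrix.pos[sl]
        segments.extend(_scan_chromosome(sample_id, chrom, g, pos, params))
    return segments


def detect_roh_all(
    matrix: VariantMatrix, params: ROHParams = ROHParams()
) -> list[ROHSegment]:
    out: list[ROHSegment] = []
    for sample_id in matrix.sample_ids:
        out.extend(detect_roh(matrix, sample_id, params))
    return out


def _scan_chromosome(
    sample_id: str, chrom: str, g: np.ndarray, pos: np.ndarray, params: ROHParams
) -> list[ROHSegment]:
    n = len(g)
    W = params.window_snps
    if n < W:
        logger.debug("%s: %d SNPs < window of %d, no ROH calls", chrom, n, W)
        return []
    het = (g == 1).astype(np.int64)
    mis = (g == MISSING).astype(np.int64)
    # window i covers SNPs [i, i+W); cumulative sums give counts per window
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    n_windows = n - W + 1
    win_het = chet[W:] - chet[:-W]
    win_mis = cmis[W:] - cmis[:-W]
    hit = (win_het <= params.window_het_max) & (win_mis <= params.window_missing_max)

    # per-SNP fraction of hit windows among windows covering the SNP
    chit = np.concatenate([[0], np.cumsum(hit.astype(np.int64))])
    j = np.arange(n)
    w_lo = np.maximum(j - W + 1, 0)
    w_hi = np.minimum(j, n_windows - 1)
    covering = w_hi - w_lo + 1
    hits = chit[w_hi + 1] - chit[w_lo]
    eligible = hits / covering >= params.window_hit_threshold

    max_gap = int(params.max_gap_kb * 1000)
    segments: list[ROHSegment] = []
    run_start: int | None = None
    for j in range(n + 1):
        boundary = j == n or not eligible[j]
        gap_break = (
            j < n
            and j > 0
            and eligible[j]
            and run_start is not None
            and pos[j] - pos[j - 1] > max_gap
        )
        if run_start is not None and (boundary or gap_break):
            segments.extend(
                _finalize_run(sample_id, chrom, g, pos, run_start, j, params)
            )
            run_start = None
        if j < n and eligible[j] and run_start is None:
            run_start = j
    return segments


def _finalize_run(
    sample_id: str,
    chrom: str,
    g: np.ndarray,
    pos: np.ndarray,
    lo: int,
    hi: int,
    params: ROHParams,
) -> list[ROHSegment]:
    n_snps = hi - lo
    start = int(pos[lo])
    end = int(pos[hi - 1]) + 1
    length = end - start
    if n_snps < params.min_snps or length < params.min_kb * 1000:
        return []
    if length / 1000.0 / n_snps > params.min_density_kb_per_snp:
        return []
    seg = g[lo:hi]
    return [
        ROHSegment(
            sample_id=sample_id,
            chrom=chrom,
            start=start,
            end=end,
            n_snps=n_snps,
            het_count=int((seg == 1).sum()),
            missing_count=int((seg == MISSING).sum()),
        )
    ]


def f_roh(
    segments: list[ROHSegment],
    layout: GenomeLayout,
    sample_ids: list[str] | None = None,
) -> FrohReport:
    """F_ROH per sample: total, per length class, and per chromosome.

    Non-autosomal segments are dropped (logged).  ``sample_ids`` lists the
    samples to report (defaults to those appearing in ``segments``), so
    samples without any ROH still get F_ROH = 0.
    """
    l_auto = layout.autosome_length
    if l_auto == 0:
        raise ValueError("layout has no autosomes (L_AUTO = 0)")
    auto = [s for s in segments if layout.is_autosome(s.chrom)]
    dropped = len(segments) - len(auto)
    if dropped:
        logger.info("F_ROH: dropped %d non-autosomal segments", dropped)
    if sample_ids is None:
        sample_ids = sorted({s.sample_id for s in auto})
    total = {s: 0.0 for s in sample_ids}
    by_class = {label: {s: 0.0 for s in sample_ids} for label in CLASS_LABELS}
    per_chrom: dict[str, dict[str, float]] = {
        c: {s: 0.0 for s in sample_ids}
        for c, a in zip(layout.chrom_names, layout.autosome_flags)
        if a
    }
    n_segments = {s: 0 for s in sample_ids}
    for seg in auto:
        if seg.sample_id not in total:
            continue
        total[seg.sample_id] += seg.length / l_auto
        n_segments[seg.sample_id] += 1
        per_chrom[seg.chrom][seg.sample_id] += seg.length / layout.length_of(seg.chrom)
        for (lo, hi), label in zip(LENGTH_CLASSES, CLASS_LABELS):
            if lo <= seg.length < hi:
                by_class[label][seg.sample_id] += seg.length / l_auto
                break
    return FrohReport(
        total=total, by_class=by_class, per_chromosome=per_chrom, n_segments=n_segments
    )


def common_roh(
    segments: list[ROHSegment], min_samples: int = 2
) -> list[GenomicInterval]:
    """Maximal intervals where >= ``min_samples`` distinct samples are in ROH.

    Intervals carry the maximal support depth in ``name`` (as a string);
    abutting intervals merge.
    """
    by_chrom: dict[str, list[ROHSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        events: dict[int, int] = {}
        # per-sample merged coverage so overlapping segments of one sample
        # cannot inflate depth
        per_sample: dict[str, list[tuple[int, int]]] = {}
        for seg in by_chrom[chrom]:
            per_sample.setdefault(seg.sample_id, []).append((seg.start, seg.end))
        for ivs in per_sample.values():
            for start, end in _merge_pairs(ivs):
                events[start] = events.get(start, 0) + 1
                events[end] = events.get(end, 0) - 1
        depth = 0
        run_start: int | None = None
        max_support = 0
        prev = None
        for x in sorted(events):
            if run_start is not None:
                max_support = max(max_support, depth)
            depth += events[x]
            if depth >= min_samples and run_start is None:
                run_start = x
                max_support = depth
            elif depth < min_samples and run_start is not None:
                out.append(
                    GenomicInterval(chrom, run_start, x, name=str(max_support))
                )
                run_start = None
            prev = x
        assert run_start is None  # depth returns to 0 at the last end event
    return out


def _merge_pairs(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for start, end in sorted(ivs):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(a, b) for a, b in merged]


def snp_roh_ratio(
    segments: list[ROHSegment],
    matrix: VariantMatrix,
    pop_samples: list[str],
    within_roh_only: bool = False,
) -> np.ndarray:
    """Per-SNP fraction of the population's samples whose ROH cover the SNP.

    With ``within_roh_only`` the ratio is NaN at SNPs covered by no ROH at
    all (they are then excluded from island thresholds); the default reports
    the plain fraction at every SNP.
    """
    members = set(pop_samples)
    count = np.zeros(matrix.n_variants, dtype=np.int64)
    slices = matrix.chrom_slices()
    for seg in segments:
        if seg.sample_id not in members or seg.chrom not in slices:
            continue
        sl = slices[seg.chrom]
        p = matrix.pos[sl]
        lo = int(np.searchsorted(p, seg.start, side="left"))
        hi = int(np.searchsorted(p, seg.end, side="left"))
        count[sl.start + lo : sl.start + hi] += 1
    ratio = count / len(pop_samples)
    if within_roh_only:
        ratio = np.where(count > 0, ratio, np.nan)
    return ratio


def roh_islands(
    ratios: np.ndarray,
    matrix: VariantMatrix,
    tail: float = 0.01,
    merge_gap: int = 100_000,
) -> list[ROHIsland]:
    """ROH islands: runs of SNPs in the top ``tail`` of the ROH ratio.

    The threshold is the ties-inclusive k-th largest ratio among SNPs with
    nonzero coverage (k = ceil(tail * N)); member SNPs closer than
    ``merge_gap`` merge into one island spanning first to last member.
    """
    from .sweep import empirical_threshold

    ratios = np.asarray(ratios, dtype=np.float64)
    covered = ratios[np.isfinite(ratios) & (ratios > 0)]
    if len(covered) == 0:
        return []
    threshold = empirical_threshold(covered.tolist(), tail)
    if np.all(covered == covered[0]):
        logger.warning(
            "all nonzero ROH ratios equal (%.4f); islands cover every covered SNP",
            covered[0],
        )
    member = np.isfinite(ratios) & (ratios >= threshold) & (ratios > 0)
    islands: list[ROHIsland] = []
    for chrom, sl in matrix.chrom_slices().items():
        idx = np.flatnonzero(member[sl]) + sl.start
        if len(idx) == 0:
            continue
        runs: list[list[int]] = [[int(idx[0])]]
        for i in idx[1:]:
            if matrix.pos[i] - matrix.pos[runs[-1][-1]] <= merge_gap:
                runs[-1].append(int(i))
            else:
                runs.append([int(i)])
        for run in runs:
            r = ratios[run]
            islands.append(
                ROHIsland(
                    chrom=chrom,
                    start=int(matrix.pos[run[0]]),
                    end=int(matrix.pos[run[-1]]) + 1,
                    n_snps=len(run),
                    peak_ratio=float(np.max(r)),
                    mean_ratio=float(np.mean(r)),
                )
            )
    return islands
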