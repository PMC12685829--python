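"""Joint empirical-tail sweep calling and interval overlap.

Candidate sweep windows are those in the upper empirical tail of BOTH the
F_ST and the pi-ratio distribution; the two cutoffs are resolved
independently from each statistic's own defined values, then applied as a
conjunction (the upper-right quadrant of the F_ST vs pi-ratio cloud).
Selected windows merge into regions, which are annotated with the mean
member-window Tajima's D and intersected with ROH islands and QTL tracks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .core import GenomicInterval
from .windowstats import WindowStat

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "SweepRegion",
    "OverlapReport",
    "empirical_threshold",
    "resolve_thresholds",
    "select_windows",
    "merge_regions",
    "annotate_tajima",
    "intersect",
    "qtl_overlap",
]


@dataclass
class ScanConfig:
    """Resolved thresholds for one scan tail."""

    tail: float
    reference_pop: str
    target_pop: str
    fst_threshold: float | None = None
    pi_ratio_threshold: float | None = None
    treat_zero_pi_as_max: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.tail < 1:
            raise ValueError("tail must be in (0, 1)")


@dataclass
class SweepRegion:
    """A merged run of jointly selected windows."""

    chrom: str
    start: int
    end: int
    n_windows: int
    max_fst: float
    max_pi_ratio: float | None
    mean_tajima_d: dict[str, float | None] = field(default_factory=dict)
    members: list[WindowStat] = field(default_factory=list)

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class OverlapReport:
    """QTL hits of a set of candidate regions, tallied by trait category."""

    n_qtls_hit: int
    category_counts: dict[str, int]
    category_percent: dict[str, float]
    hits: list[GenomicInterval]


def empirical_threshold(values: list[float], tail: float) -> float:
    """Ties-inclusive k-th largest value, k = ceil(tail * N).

    Downstream selection uses ``value >= threshold``, so the selected count
    can exceed k when the k-th largest is tied.
    """
    finite = [v for v in values if math.isfinite(v)]
    if not finite:
        raise ValueError("empirical_threshold needs at least one finite value")
    if not 0 < tail < 1:
        raise ValueError("tail must be in (0, 1)")
    k = math.ceil(tail * len(finite))
    return sorted(finite, reverse=True)[k - 1]


def resolve_thresholds(stats: list[WindowStat], config: ScanConfig) -> ScanConfig:
    """Fill the F_ST and pi-ratio cutoffs from their empirical distributions.

    Undefined values (None) are excluded before taking the tail; with
    ``treat_zero_pi_as_max`` the pi-ratio of zero-diversity target windows
    is treated as +inf for selection but still excluded from the quantile.
    """
    fst_values = [st.fst for st in stats if st.fst is not None]
    ratio_values = [st.pi_ratio for st in stats if st.pi_ratio is not None]
    config.fst_threshold = empirical_threshold(fst_values, config.tail)
    config.pi_ratio_threshold = empirical_threshold(ratio_values, config.tail)
    logger.info(
        "tail %.2f%%: F_ST >= %.4f and pi-ratio >= %.4f",
        100 * config.tail,
        config.fst_threshold,
        config.pi_ratio_threshold,
    )
    return config


def select_windows(stats: list[WindowStat], config: ScanConfig) -> list[WindowStat]:
    """Windows passing BOTH resolved cutoffs (undefined never selects,
    unless ``treat_zero_pi_as_max`` rescues zero-target-pi windows)."""
    if config.fst_threshold is None or config.pi_ratio_threshold is None:
        config = resolve_thresholds(stats, config)
    out = []
    for st in stats:
        if st.fst is None or st.fst < config.fst_threshold:
            continue
        if st.pi_ratio is None:
            if not (
                config.treat_zero_pi_as_max
                and st.pi_by_pop.get(config.target_pop) == 0.0
                and st.n_snps > 0
            ):
                continue
        elif st.pi_ratio < config.pi_ratio_threshold:
            continue
        out.append(st)
    return out


def merge_regions(
    selected: list[WindowStat], max_join_gap: int = 0
) -> list[SweepRegion]:
    """Merge overlapping/abutting (gap <= max_join_gap) selected windows.

    Region F_ST and pi-ratio are the max over members; Tajima's D is the
    member mean (attached by :func:`annotate_tajima`).
    """
    ordered = sorted(selected, key=lambda s: (s.window.chrom, s.window.start))
    regions: list[SweepRegion] = []
    for st in ordered:
        w = st.window
        if (
            regions
            and regions[-1].chrom == w.chrom
            and w.start <= regions[-1].end + max_join_gap
        ):
            r = regions[-1]
            r.end = max(r.end, w.end)
            r.n_windows += 1
            r.max_fst = max(r.max_fst, st.fst)
            if st.pi_ratio is not None:
                r.max_pi_ratio = (
                    st.pi_ratio
                    if r.max_pi_ratio is None
                    else max(r.max_pi_ratio, st.pi_ratio)
                )
            r.members.append(st)
        else:
            regions.append(
                SweepRegion(
                    chrom=w.chrom,
                    start=w.start,
                    end=w.end,
                    n_windows=1,
                    max_fst=st.fst,
                    max_pi_ratio=st.pi_ratio,
                    members=[st],
                )
            )
    return regions


def annotate_tajima(
    regions: list[SweepRegion], pops: list[str]
) -> list[SweepRegion]:
    """Attach the mean member-window Tajima's D per population.

    ``None`` when every member window is undefined for that population.
    """
    for region in regions:
        for pop in pops:
            values = [
                st.tajima_d_by_pop.get(pop)
                for st in region.members
                if st.tajima_d_by_pop.get(pop) is not None
            ]
            region.mean_tajima_d[pop] = (
                sum(values) / len(values) if values else None
            )
    return regions


def intersect(
    a: list[GenomicInterval], b: list[GenomicInterval]
) -> list[GenomicInterval]:
    """Maximal intervals covered by both input sets (as coverage sets)."""
    cov_a = _coverage(a)
    cov_b = _coverage(b)
    out: list[GenomicInterval] = []
    for chrom in sorted(set(cov_a) & set(cov_b)):
        ia = iter(cov_a[chrom])
        ib = iter(cov_b[chrom])
        x = next(ia, None)
        y = next(ib, None)
        while x is not None and y is not None:
            lo = max(x[0], y[0])
            hi = min(x[1], y[1])
            if lo < hi:
                out.append(GenomicInterval(chrom, lo, hi))
            if x[1] <= y[1]:
                x = next(ia, None)
            else:
                y = next(ib, None)
    return out


def _coverage(ivs: list[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    """Union of intervals per chromosome as sorted disjoint pairs."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in ivs:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, pairs in by_chrom.items():
        merged: list[list[int]] = []
        for start, end in sorted(pairs):
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        out[chrom] = [(a, b) for a, b in merged]
    return out


def qtl_overlap(
    regions: list[GenomicInterval], qtls: list[GenomicInterval]
) -> OverlapReport:
    """Count QTLs intersecting any region, once per QTL, tallied by category.

    QTLs without a category are grouped under "uncategorized" (logged).
    """
    cov = _coverage(regions)
    hits: list[GenomicInterval] = []
    counts: dict[str, int] = {}
    n_uncat = 0
    for qtl in qtls:
        pairs = cov.get(qtl.chrom, [])
        if not any(qtl.start < end and start < qtl.end for start, end in pairs):
            continue
        hits.append(qtl)
        category = qtl.category
        if category is None:
            category = "uncategorized"
            n_uncat += 1
        counts[category] = counts.get(category, 0) + 1
    if n_uncat:
        logger.info("%d QTL hits lacked a category column", n_uncat)
    total = len(hits)
    percent = {
        cat: 100.0 * c / total for cat, c in counts.items()
    } if total else {}
    return OverlapReport(
        n_qtls_hit=total,
        category_counts=counts,
        category_percent=percent,
        hits=hits,
    )
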