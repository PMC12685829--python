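"""Synthetic genotype data with known truth.

The genome-scale generator draws independent bi-allelic SNPs whose
population allele frequencies follow the Balding-Nichols model: an
ancestral frequency p per SNP, and each population's frequency from
Beta(p(1-F)/F, (1-p)(1-F)/F) with drift parameter F.  For populations
drifted equally this gives the closed-form expectation F_ST = F, which the
differentiation scan can be checked against analytically.  Sweeps are
planted by pushing a region's target-population frequencies toward the
nearer fixation point; autozygous tracts are planted by collapsing one
sample's heterozygous calls to a random homozygote.  Sites are independent
given their frequencies (no background LD); a separate single-locus Kingman
coalescent with infinite-sites mutations supplies neutral replicates for
calibrating Tajima's D.

Everything is reproducible from the seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenomeLayout, GenomicInterval, PopulationSpec, VariantMatrix

__all__ = [
    "SimParams",
    "SimTruth",
    "CoalescentRep",
    "simulate_populations",
    "plant_sweep",
    "plant_roh",
    "simulate_coalescent",
]


@dataclass(frozen=True)
class SimParams:
    """Generator configuration.

    ``sweep_specs`` entries are (population label, interval, intensity in
    (0, 1]); ``roh_specs`` entries are (sample_id, interval).  Population
    labels are ``pop1..popN`` and sample ids ``pop<i>_s<j>``.
    """

    layout: GenomeLayout
    n_pops: int = 2
    samples_per_pop: int = 20
    snp_spacing_mean: int = 1000
    divergence_F: float = 0.2
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    sweep_specs: tuple[tuple[str, GenomicInterval, float], ...] = ()
    roh_specs: tuple[tuple[str, GenomicInterval], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.divergence_F < 1:
            raise ValueError("divergence_F must be in (0, 1)")
        if self.n_pops < 1 or self.samples_per_pop < 1:
            raise ValueError("need at least one population and sample")
        if not self.layout.chrom_names:
            raise ValueError("empty genome layout")
        for _, iv, intensity in self.sweep_specs:
            if not 0 < intensity <= 1:
                raise ValueError("sweep intensity must be in (0, 1]")
            if iv.end > self.layout.length_of(iv.chrom):
                raise ValueError(f"sweep interval {iv} outside layout")
        for _, iv in self.roh_specs:
            if iv.end > self.layout.length_of(iv.chrom):
                raise ValueError(f"ROH interval {iv} outside layout")

    @property
    def pop_labels(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_pops)]

    def sample_ids(self) -> list[str]:
        return [
            f"pop{i + 1}_s{j + 1:02d}"
            for i in range(self.n_pops)
            for j in range(self.samples_per_pop)
        ]

    def population_spec(self) -> PopulationSpec:
        return PopulationSpec(
            assignments={
                s: s.split("_")[0] for s in self.sample_ids()
            }
        )


@dataclass(frozen=True)
class SimTruth:
    """Planted signal locations and realized per-sample autozygosity."""

    sweep_intervals: tuple[tuple[str, GenomicInterval, float], ...]
    roh_intervals: dict[str, tuple[GenomicInterval, ...]]
    realized_autozygous_fraction: dict[str, float]
    params: SimParams


def _poisson_positions(
    rng: np.random.Generator, length: int, mean_spacing: int
) -> np.ndarray:
    """SNP positions as a Poisson process, deduplicated and sorted."""
    n_draw = max(int(2 * length / mean_spacing) + 20, 20)
    gaps = rng.exponential(mean_spacing, size=n_draw)
    pos = np.cumsum(gaps)
    while len(pos) and pos[-1] < length:
        extra = rng.exponential(mean_spacing, size=n_draw)
        pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
    pos = np.unique(pos[pos < length].astype(np.int64))
    return pos[pos >= 0]


def simulate_populations(params: SimParams) -> tuple[VariantMatrix, SimTruth]:
    """Generate genotypes under Balding-Nichols drift and plant all signals."""
    rng = np.random.default_rng(params.seed)
    sample_ids = params.sample_ids()
    pop_of_sample = np.repeat(np.arange(params.n_pops), params.samples_per_pop)
    n_samples = len(sample_ids)

    chroms: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    hap_blocks: list[np.ndarray] = []
    lo, hi = params.ancestral_freq_range
    F = params.divergence_F
    for chrom, length in zip(params.layout.chrom_names, params.layout.chrom_lengths):
        pos = _poisson_positions(rng, length, params.snp_spacing_mean)
        n_var = len(pos)
        p_anc = rng.uniform(lo, hi, size=n_var)
        pop_freq = rng.beta(
            np.outer(p_anc, np.ones(params.n_pops)) * (1 - F) / F,
            np.outer(1 - p_anc, np.ones(params.n_pops)) * (1 - F) / F,
        )  # (n_var, n_pops)
        freq_per_sample = pop_freq[:, pop_of_sample]  # (n_var, n_samples)
        haps = (
            rng.random((n_var, n_samples, 2)) < freq_per_sample[:, :, None]
        ).astype(np.int8)
        chroms.append(np.full(n_var, chrom, dtype=object))
        positions.append(pos)
        hap_blocks.append(haps)

    haplotypes = (
        np.concatenate(hap_blocks)
        if hap_blocks
        else np.empty((0, n_samples, 2), np.int8)
    )
    n_var_total = sum(len(p) for p in positions)
    matrix = VariantMatrix(
        sample_ids=tuple(sample_ids),
        chrom=np.concatenate(chroms) if chroms else np.empty(0, object),
        pos=np.concatenate(positions) if positions else np.empty(0, np.int64),
        ref_allele=np.full(n_var_total, "A", dtype=object),
        alt_allele=np.full(n_var_total, "G", dtype=object),
        genotypes=haplotypes.sum(axis=2).astype(np.int8),
        haplotypes=haplotypes,
    )

    spec = params.population_spec()
    for pop, region, intensity in params.sweep_specs:
        matrix = plant_sweep(matrix, spec.samples_of(pop), region, intensity, rng)
    for sample, region in params.roh_specs:
        matrix = plant_roh(matrix, sample, region, rng)

    truth = SimTruth(
        sweep_intervals=tuple(params.sweep_specs),
        roh_intervals=_group_roh(params.roh_specs),
        realized_autozygous_fraction=_realized_fractions(params),
        params=params,
    )
    return matrix, truth


def _group_roh(specs) -> dict[str, tuple[GenomicInterval, ...]]:
    out: dict[str, list[GenomicInterval]] = {}
    for sample, iv in specs:
        out.setdefault(sample, []).append(iv)
    return {s: tuple(ivs) for s, ivs in out.items()}


def _realized_fractions(params: SimParams) -> dict[str, float]:
    """Planted autosomal ROH bp (union per sample) over L_AUTO."""
    l_auto = params.layout.autosome_length
    out: dict[str, float] = {}
    for sample, ivs in _group_roh(params.roh_specs).items():
        total = 0
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in ivs:
            if params.layout.is_autosome(iv.chrom):
                by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for pairs in by_chrom.values():
            merged: list[list[int]] = []
            for start, end in sorted(pairs):
                if merged and start <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], end)
                else:
                    merged.append([start, end])
            total += sum(b - a for a, b in merged)
        out[sample] = total / l_auto
    return out


def plant_sweep(
    matrix: VariantMatrix,
    pop_samples: list[str],
    region: GenomicInterval,
    intensity: float,
    rng: np.random.Generator,
) -> VariantMatrix:
    """Push a region's allele frequencies toward fixation in one population.

    Each in-region SNP's target-population genotypes are resampled from
    p' = (1 - intensity) * p + intensity * round(p), where p is the current
    realized frequency in that population; intensity 1 fixes every SNP
    (zero diversity inside the region), intensity 0 is the identity.
    """
    if not 0 <= intensity <= 1:
        raise ValueError("intensity must be in [0, 1]")
    if intensity == 0:
        return matrix
    s_idx = np.array([matrix.sample_index(s) for s in pop_samples])
    v_idx = _region_variant_indices(matrix, region)
    if len(v_idx) == 0:
        return matrix
    g = matrix.genotypes.copy()
    haps = None if matrix.haplotypes is None else matrix.haplotypes.copy()
    sub = g[np.ix_(v_idx, s_idx)]
    known = sub != -1
    alt = np.where(known, sub, 0).sum(axis=1)
    n = 2 * known.sum(axis=1)
    p = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
    target = (p >= 0.5).astype(np.float64)
    p_new = (1 - intensity) * p + intensity * target
    new_haps = (
        rng.random((len(v_idx), len(s_idx), 2)) < p_new[:, None, None]
    ).astype(np.int8)
    new_g = new_haps.sum(axis=2).astype(np.int8)
    # missing entries stay missing
    old = g[np.ix_(v_idx, s_idx)]
    new_g = np.where(old == -1, old, new_g)
    g[np.ix_(v_idx, s_idx)] = new_g
    if haps is not None:
        for k, v in enumerate(v_idx):
            haps[v, s_idx, :] = new_haps[k]
    return replace_matrix(matrix, g, haps)


def plant_roh(
    matrix: VariantMatrix,
    sample_id: str,
    region: GenomicInterval,
    rng: np.random.Generator,
) -> VariantMatrix:
    """Make one sample homozygous across a region.

    Each in-region SNP duplicates one of the sample's current alleles:
    heterozygotes collapse to hom-ref or hom-alt with probability 1/2
    each; homozygotes and missing calls are untouched (idempotent).
    """
    s = matrix.sample_index(sample_id)
    v_idx = _region_variant_indices(matrix, region)
    g = matrix.genotypes.copy()
    haps = None if matrix.haplotypes is None else matrix.haplotypes.copy()
    col = g[v_idx, s]
    het = col == 1
    pick = (rng.random(int(het.sum())) < 0.5).astype(np.int8) * 2  # 0 or 2
    col = col.copy()
    col[het] = pick
    g[v_idx, s] = col
    if haps is not None:
        haps[v_idx, s, 0] = np.where(col == -1, haps[v_idx, s, 0], (col // 2))
        haps[v_idx, s, 1] = np.where(col == -1, haps[v_idx, s, 1], (col // 2))
    return replace_matrix(matrix, g, haps)


def replace_matrix(
    matrix: VariantMatrix, genotypes: np.ndarray, haplotypes: np.ndarray | None
) -> VariantMatrix:
    return VariantMatrix(
        sample_ids=matrix.sample_ids,
        chrom=np.asarray(matrix.chrom),
        pos=matrix.pos,
        ref_allele=np.asarray(matrix.ref_allele),
        alt_allele=np.asarray(matrix.alt_allele),
        genotypes=genotypes,
        haplotypes=haplotypes,
    )


def _region_variant_indices(
    matrix: VariantMatrix, region: GenomicInterval
) -> np.ndarray:
    sl = matrix.chrom_slices().get(region.chrom)
    if sl is None:
        return np.empty(0, dtype=np.int64)
    p = matrix.pos[sl]
    lo = int(np.searchsorted(p, region.start, side="left"))
    hi = int(np.searchsorted(p, region.end, side="left"))
    return np.arange(sl.start + lo, sl.start + hi, dtype=np.int64)


@dataclass(frozen=True)
class CoalescentRep:
    """One neutral replicate: haplotypes (sites x n) plus tree summaries."""

    haplotypes: np.ndarray
    tmrca: float
    total_branch_length: float


def simulate_coalescent(
    n: int, theta: float, reps: int, seed: int
) -> list[CoalescentRep]:
    """Kingman coalescent with infinite-sites mutations at one locus.

    With k active lineages the next coalescence is Exponential with rate
    k(k-1)/2 (time in units of 2N generations); mutations fall on each
    branch as Poisson(theta/2 * branch length) and each creates one
    segregating site carried by the branch's leaf descendants.
    """
    if n < 2:
        raise ValueError("coalescent needs n >= 2 haplotypes")
    if theta <= 0:
        raise ValueError("theta must be positive")
    rng = np.random.default_rng(seed)
    out: list[CoalescentRep] = []
    for _ in range(reps):
        active: list[tuple[frozenset[int], float]] = [
            (frozenset({i}), 0.0) for i in range(n)
        ]
        closed: list[tuple[frozenset[int], float]] = []
        t = 0.0
        total_len = 0.0
        while len(active) > 1:
            k = len(active)
            dt = rng.exponential(2.0 / (k * (k - 1)))
            t += dt
            total_len += k * dt
            active = [(d, length + dt) for d, length in active]
            i, j = rng.choice(k, size=2, replace=False)
            i, j = (int(i), int(j)) if i < j else (int(j), int(i))
            d1, l1 = active[j]
            d0, l0 = active[i]
            closed.append((d0, l0))
            closed.append((d1, l1))
            del active[j]
            active[i] = (d0 | d1, 0.0)
        sites: list[np.ndarray] = []
        for desc, length in closed:
            n_mut = rng.poisson(theta / 2.0 * length)
            if n_mut:
                col = np.zeros(n, dtype=np.int8)
                col[list(desc)] = 1
                sites.extend([col] * int(n_mut))
        haps = (
            np.vstack(sites) if sites else np.empty((0, n), dtype=np.int8)
        )
        out.append(
            CoalescentRep(haplotypes=haps, tmrca=t, total_branch_length=total_len)
        )
    return out
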