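"""Synthetic population-genetics data with the structure the pipeline assumes.

Population allele frequencies follow the Balding-Nichols model: around an
ancestral frequency p, each population draws its frequency from
Beta(p(1-F)/F, (1-p)(1-F)/F), so the expected divergence between populations
equals F. Pools are binomial read counts at Poisson (or fixed) depth;
individuals are Hardy-Weinberg binomial(2, p) dosages. An admixture step
shifts one population's frequencies toward another's by a proportion alpha,
and an assay-degradation step injects the defects the QC cascade exists to
catch (missingness, monomorphic markers, duplicated markers, hot NTC wells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .datatypes import AlleleCountMatrix, GenotypeMatrix, NTCTable

log = logging.getLogger("gsikit")


@dataclass
class SimParams:
    """Simulation settings; defaults mirror the study's post-QC scale —
    81 markers, two stocks at divergence ~0.115, 100 individuals per stock."""

    n_snps: int = 81
    n_pops: int = 2
    divergence_F: float = 0.115
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    pool_depth: int = 100
    fixed_depth: bool = False
    pool_haploid_size: int = 100
    n_per_pop: int = 100
    introgression_alpha: float = 0.0
    missing_rate: float = 0.02
    n_monomorphic: int = 0
    n_duplicates: int = 0
    duplicate_flip_rate: float = 0.0
    ntc_hot_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1 or self.n_pops < 2:
            raise ValueError("need n_snps >= 1 and n_pops >= 2")
        if not (0.0 <= self.divergence_F < 1.0):
            raise ValueError("divergence_F must lie in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must sit within (0, 0.5]")
        if self.pool_depth < 1 or self.pool_haploid_size < 1 or self.n_per_pop < 1:
            raise ValueError("depth, pool size and n_per_pop must be positive")
        if not (0.0 <= self.introgression_alpha <= 1.0):
            raise ValueError("introgression_alpha must lie in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_monomorphic < 0 or self.n_duplicates < 0:
            raise ValueError("n_monomorphic and n_duplicates must be >= 0")

    def with_(self, **kw) -> "SimParams":
        return replace(self, **kw)


def draw_population_frequencies(params: SimParams) -> np.ndarray:
    """Draw a (n_snps, n_pops) matrix of population allele frequencies.

    Ancestral frequencies are uniform over the minor-allele range folded with
    its mirror image (so reference/alternate orientation is random). F = 0 is
    the documented no-divergence limit: every population gets the ancestral
    frequency exactly.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.ancestral_maf_range
    maf = rng.uniform(lo, hi, size=params.n_snps)
    flip = rng.random(params.n_snps) < 0.5
    p = np.where(flip, 1.0 - maf, maf)
    F = params.divergence_F
    if F == 0.0:
        return np.tile(p[:, None], (1, params.n_pops))
    scale = (1.0 - F) / F
    freqs = rng.beta(
        p[:, None] * scale, (1.0 - p[:, None]) * scale,
        size=(params.n_snps, params.n_pops),
    )
    # beta draws can hit 0/1 at float precision; clamp to keep (0,1) open
    eps = 1e-9
    return np.clip(freqs, eps, 1.0 - eps)


def simulate_pools(freqs: np.ndarray, params: SimParams) -> AlleleCountMatrix:
    """Binomial pool read counts at Poisson(pool_depth) (or fixed) depth."""
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    n_snps, n_pops = freqs.shape
    if params.fixed_depth:
        depth = np.full((n_snps, n_pops), params.pool_depth, dtype=np.int64)
    else:
        depth = rng.poisson(params.pool_depth, size=(n_snps, n_pops))
    alt = rng.binomial(depth, freqs)
    n_zero = int((depth == 0).sum())
    if n_zero:
        log.info("simulate_pools: %d zero-depth cells", n_zero)
    return AlleleCountMatrix(
        snp_ids=[f"snp{i}" for i in range(n_snps)],
        pool_ids=[f"pool{j}" for j in range(n_pops)],
        ref_counts=depth - alt,
        alt_counts=alt,
        pool_haploid_sizes=np.full(n_pops, params.pool_haploid_size),
    )


def simulate_genotypes(
    freqs: np.ndarray, params: SimParams, epoch: str = "baseline"
) -> GenotypeMatrix:
    """Hardy-Weinberg individual dosages: Binomial(2, p_pop) per SNP."""
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    n_snps, n_pops = freqs.shape
    blocks, sample_ids, labels = [], [], []
    for j in range(n_pops):
        blocks.append(
            rng.binomial(2, freqs[:, j], size=(params.n_per_pop, n_snps)).astype(float)
        )
        sample_ids += [f"pop{j}_s{i}" for i in range(params.n_per_pop)]
        labels += [f"pop{j}"] * params.n_per_pop
    return GenotypeMatrix(
        sample_ids=sample_ids,
        marker_ids=[f"snp{i}" for i in range(n_snps)],
        dosage=np.vstack(blocks),
        labels=labels,
        epoch=[epoch] * len(sample_ids),
    )


def apply_introgression(
    target_freqs: np.ndarray, source_freqs: np.ndarray, alpha: float
) -> np.ndarray:
    """Admix a proportion ``alpha`` of the source gene pool into the target:
    returns (1 - alpha) * target + alpha * source elementwise."""
    target_freqs = np.asarray(target_freqs, dtype=float)
    source_freqs = np.asarray(source_freqs, dtype=float)
    if target_freqs.shape != source_freqs.shape:
        raise ValueError(
            f"frequency vectors differ in shape: "
            f"{target_freqs.shape} vs {source_freqs.shape}"
        )
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    return (1.0 - alpha) * target_freqs + alpha * source_freqs


def degrade_assay(
    gm: GenotypeMatrix, params: SimParams
) -> tuple[GenotypeMatrix, NTCTable, dict]:
    """Inject assay defects and return (degraded matrix, NTC table, truth).

    Missing calls at ``missing_rate`` uniformly, ``n_monomorphic`` constant
    markers appended, ``n_duplicates`` correlated copies of random markers
    appended (exact copies unless ``duplicate_flip_rate`` > 0), and an NTC
    table whose first ``ntc_hot_fraction`` of markers fluoresce above 0.2.
    The truth dict names every injected defect so QC can be audited.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 3]))
    dosage = gm.dosage.copy()
    marker_ids = list(gm.marker_ids)

    miss_mask = rng.random(dosage.shape) < params.missing_rate
    dosage[miss_mask] = np.nan

    mono_ids = []
    for k in range(params.n_monomorphic):
        mid = f"mono{k}"
        mono_ids.append(mid)
        marker_ids.append(mid)
        dosage = np.column_stack(
            [dosage, np.full(dosage.shape[0], float(rng.integers(0, 3)))]
        )

    dup_pairs = []
    n_orig = gm.n_markers
    if params.n_duplicates:
        sources = rng.choice(n_orig, size=params.n_duplicates, replace=False)
        for k, src in enumerate(sources):
            mid = f"dup{k}_{gm.marker_ids[src]}"
            col = dosage[:, src].copy()
            if params.duplicate_flip_rate > 0:
                flips = rng.random(col.shape[0]) < params.duplicate_flip_rate
                col[flips] = rng.integers(0, 3, size=int(flips.sum())).astype(float)
            dup_pairs.append((gm.marker_ids[src], mid))
            marker_ids.append(mid)
            dosage = np.column_stack([dosage, col])

    n_hot = int(round(params.ntc_hot_fraction * len(marker_ids)))
    hot_ids = list(rng.choice(marker_ids, size=n_hot, replace=False)) if n_hot else []
    fluor = rng.uniform(0.0, 0.15, size=len(marker_ids))
    for m in hot_ids:
        fluor[marker_ids.index(m)] = rng.uniform(0.25, 1.0)
    ntc = NTCTable(list(marker_ids), fluor)

    degraded = GenotypeMatrix(
        sample_ids=list(gm.sample_ids),
        marker_ids=marker_ids,
        dosage=dosage,
        labels=list(gm.labels) if gm.labels is not None else None,
        epoch=list(gm.epoch) if gm.epoch is not None else None,
    )
    truth = {
        "monomorphic_markers": mono_ids,
        "duplicate_pairs": dup_pairs,
        "ntc_hot_markers": hot_ids,
        "n_missing_injected": int(miss_mask.sum()),
        "missing_rate": params.missing_rate,
    }
    return degraded, ntc, truth


def simulate_study(
    params: SimParams, novel_alpha: float | None = None
) -> dict:
    """Convenience wrapper producing the full study layout: true frequencies,
    pooled counts, a baseline genotype set and (optionally) a novel-epoch set
    whose target population (pop0) is admixed toward pop1 by ``novel_alpha``."""
    freqs = draw_population_frequencies(params)
    pools = simulate_pools(freqs, params)
    baseline = simulate_genotypes(freqs, params, epoch="baseline")
    out = {"freqs": freqs, "pools": pools, "baseline": baseline}
    if novel_alpha is not None:
        novel_freqs = freqs.copy()
        novel_freqs[:, 0] = apply_introgression(
            freqs[:, 0], freqs[:, 1], novel_alpha
        )
        novel = simulate_genotypes(
            novel_freqs, params.with_(seed=params.seed + 1), epoch="novel"
        )
        novel.sample_ids = [f"novel_{s}" for s in novel.sample_ids]
        out["novel_freqs"] = novel_freqs
        out["novel"] = novel
    return out
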