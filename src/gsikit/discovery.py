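"""Pooled-FST marker discovery: one-to-many contrast and outlier selection.

Per-SNP FST uses the Hudson-form estimator with a pool-seq effective sample
size: a pool of n_c gene copies sequenced to depth d provides
n_eff = n_c * d / (n_c + d - 1) effective allele draws. With allele
frequencies p1, p2 estimated from read counts,

    FST = [(p1 - p2)^2 - p1(1-p1)/(n_eff1 - 1) - p2(1-p2)/(n_eff2 - 1)]
          / [p1(1-p2) + p2(1-p1)]

and the multi-locus value is the ratio of summed numerators to summed
denominators (never the mean of per-SNP ratios).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import AlleleCountMatrix, PanelDefinition

log = logging.getLogger("gsikit")


@dataclass
class FstResult:
    """Per-SNP FST (NaN where undefined) plus the multi-locus estimate."""

    snp_ids: list[str]
    fst: np.ndarray
    n_eff_target: np.ndarray
    n_eff_rest: np.ndarray
    multi_locus_fst: float

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.fst)


@dataclass
class GroupCounts:
    ref: np.ndarray
    alt: np.ndarray
    haploid_size: int

    @property
    def depth(self) -> np.ndarray:
        return self.ref + self.alt


def one_to_many_counts(
    acm: AlleleCountMatrix, target: str
) -> tuple[GroupCounts, GroupCounts]:
    """Split an allele-count matrix into target-pool counts and the
    read-count sum over every other pool (haploid sizes add)."""
    if target not in acm.pool_ids:
        raise KeyError(f"unknown target pool {target!r}")
    if acm.n_pools < 2:
        raise ValueError("one-to-many contrast needs >= 2 pools")
    t = acm.pool_ids.index(target)
    rest = [j for j in range(acm.n_pools) if j != t]
    tgt = GroupCounts(
        ref=acm.ref_counts[:, t].copy(),
        alt=acm.alt_counts[:, t].copy(),
        haploid_size=int(acm.pool_haploid_sizes[t]),
    )
    oth = GroupCounts(
        ref=acm.ref_counts[:, rest].sum(axis=1),
        alt=acm.alt_counts[:, rest].sum(axis=1),
        haploid_size=int(acm.pool_haploid_sizes[rest].sum()),
    )
    return tgt, oth


def _effective_size(haploid_size: int, depth: np.ndarray) -> np.ndarray:
    """Pool-seq effective number of allele draws, n_c*d/(n_c+d-1)."""
    d = depth.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(d > 0, haploid_size * d / (haploid_size + d - 1.0), np.nan)


def pooled_fst(
    snp_ids: list[str], target: GroupCounts, rest: GroupCounts
) -> FstResult:
    """Hudson-form pooled FST per SNP with multi-locus ratio of averages.

    SNPs with zero depth in either group, effective size <= 1, or a zero
    denominator (both groups fixed for the same allele) get NaN.
    """
    d1, d2 = target.depth, rest.depth
    n1 = _effective_size(target.haploid_size, d1)
    n2 = _effective_size(rest.haploid_size, d2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(d1 > 0, target.alt / d1.astype(float), np.nan)
        p2 = np.where(d2 > 0, rest.alt / d2.astype(float), np.nan)
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (n1 - 1.0)
            - p2 * (1 - p2) / (n2 - 1.0)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst = num / den
    bad = (
        np.isnan(p1) | np.isnan(p2)
        | (n1 <= 1) | (n2 <= 1)
        | (den == 0) | np.isnan(den)
    )
    fst = np.where(bad, np.nan, fst)
    n_bad = int(bad.sum())
    if n_bad:
        log.info("pooled_fst: %d SNPs with undefined FST", n_bad)
    ok = ~bad
    multi = float(num[ok].sum() / den[ok].sum()) if ok.any() else float("nan")
    return FstResult(
        snp_ids=list(snp_ids),
        fst=fst,
        n_eff_target=n1,
        n_eff_rest=n2,
        multi_locus_fst=multi,
    )


def one_to_many_fst(acm: AlleleCountMatrix, target: str) -> FstResult:
    tgt, oth = one_to_many_counts(acm, target)
    return pooled_fst(acm.snp_ids, tgt, oth)


def select_outliers(
    fst: FstResult, quantile: float = 0.99, min_fst: float | None = None
) -> PanelDefinition:
    """Markers at or above the empirical FST quantile (linear-interpolation
    convention), optionally floored at ``min_fst``; sorted by descending FST."""
    ok = fst.defined()
    if not ok.any():
        raise ValueError("cannot select outliers: all FST values undefined")
    values = fst.fst[ok]
    thresh = float(np.quantile(values, quantile))
    if min_fst is not None:
        thresh = max(thresh, min_fst)
    keep = [
        (fst.snp_ids[i], float(fst.fst[i]))
        for i in np.flatnonzero(ok)
        if fst.fst[i] >= thresh
    ]
    keep.sort(key=lambda kv: (-kv[1], kv[0]))
    for m, v in keep:
        log.info("select_outliers: kept %s (FST=%.4f >= %.4f)", m, v, thresh)
    return PanelDefinition(
        marker_ids=[m for m, _ in keep],
        provenance=["fst_outlier"] * len(keep),
        score=[v for _, v in keep],
    )
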