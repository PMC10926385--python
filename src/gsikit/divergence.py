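"""FST divergence monitoring between sampling epochs.

Per-marker FST between two populations is the Weir-Cockerham (1984) theta,
built from the among-population (a), among-individual-within-population (b)
and within-individual (c) variance components of the allele-frequency /
heterozygosity decomposition:

    theta = a / (a + b + c)

with the multi-locus value the ratio of summed components Sa / S(a+b+c)
(ratio of averages, never the mean of per-marker ratios). Negative
per-marker estimates are retained — truncating at zero would bias an
epoch-to-epoch contrast. The Hudson estimator is provided as a cross-check.

The epoch contrast runs the estimator separately on a baseline and a novel
sample set over their shared markers and reports per-marker deltas, medians
and multi-locus values — the monitoring readout for allelic-profile shift
(e.g. introgression lowering most markers' divergence while a few rise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import GenotypeMatrix
from .discovery import FstResult

log = logging.getLogger("gsikit")


def _wc_components(
    dosage: np.ndarray, group_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker Weir-Cockerham a, b, c for two groups of diploids.

    ``dosage`` is samples x markers with NaN missing; ``group_mask`` flags
    group-1 membership. Markers with fewer than 2 genotyped individuals in
    either group, or zero total variance, yield NaN components.
    """
    r = 2
    groups = (group_mask, ~group_mask)
    n_i = np.stack([(~np.isnan(dosage[g])).sum(axis=0) for g in groups]).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = np.stack([np.nanmean(dosage[g], axis=0) / 2.0 for g in groups])
    h_i = np.stack([_het_freq(dosage[g]) for g in groups])

    n_sum = n_i.sum(axis=0)
    n_bar = n_sum / r
    n_c = (n_sum - (n_i**2).sum(axis=0) / n_sum) / (r - 1)
    p_bar = (n_i * p_i).sum(axis=0) / n_sum
    s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum(axis=0) / n_sum

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (n_bar / n_c) * (
            s2
            - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0)
            / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2.0

    bad = (n_i < 2).any(axis=0) | np.isnan(p_i).any(axis=0)
    for comp in (a, b, c):
        comp[bad] = np.nan
    return a, b, c


def _het_freq(dosage: np.ndarray) -> np.ndarray:
    obs = ~np.isnan(dosage)
    het = np.where(obs & (dosage == 1.0), 1.0, 0.0).sum(axis=0)
    n = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, het / n, np.nan)


def wc_fst_per_snp(gm: GenotypeMatrix, group_labels: tuple[str, str]) -> FstResult:
    """Per-marker Weir-Cockerham theta for the two named populations.

    Markers with zero total variance (a + b + c = 0) are undefined and
    excluded from the multi-locus ratio.
    """
    if gm.labels is None:
        raise ValueError("genotype matrix must carry population labels")
    lab = np.asarray(gm.labels)
    g1, g2 = group_labels
    use = np.isin(lab, (g1, g2))
    if not use.any():
        raise ValueError(f"no samples labelled {g1!r} or {g2!r}")
    dosage = gm.dosage[use]
    mask = lab[use] == g1
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError("both populations must be present")
    a, b, c = _wc_components(dosage, mask)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / denom
    undef = np.isnan(denom) | (denom == 0)
    theta = np.where(undef, np.nan, theta)
    n_undef = int(undef.sum())
    if n_undef:
        log.info("wc_fst_per_snp: %d markers undefined", n_undef)
    ok = ~undef
    multi = float(a[ok].sum() / denom[ok].sum()) if ok.any() else float("nan")
    n1 = (~np.isnan(dosage[mask])).sum(axis=0).astype(float)
    n2 = (~np.isnan(dosage[~mask])).sum(axis=0).astype(float)
    return FstResult(
        snp_ids=list(gm.marker_ids),
        fst=theta,
        n_eff_target=2 * n1,
        n_eff_rest=2 * n2,
        multi_locus_fst=multi,
    )


def hudson_fst_per_snp(gm: GenotypeMatrix, group_labels: tuple[str, str]) -> FstResult:
    """Hudson-form theta from genotype allele frequencies (cross-check
    estimator; sample-size corrected with haploid counts 2n)."""
    if gm.labels is None:
        raise ValueError("genotype matrix must carry population labels")
    lab = np.asarray(gm.labels)
    g1, g2 = group_labels
    res = []
    for g in (g1, g2):
        d = gm.dosage[lab == g]
        n = (~np.isnan(d)).sum(axis=0).astype(float) * 2  # haploid
        with np.errstate(invalid="ignore"):
            p = np.nanmean(d, axis=0) / 2.0
        res.append((p, n))
    (p1, n1), (p2, n2) = res
    with np.errstate(invalid="ignore", divide="ignore"):
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / (n1 - 1)
               - p2 * (1 - p2) / (n2 - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst = num / den
    bad = np.isnan(p1) | np.isnan(p2) | (n1 <= 2) | (n2 <= 2) | (den == 0)
    fst = np.where(bad, np.nan, fst)
    ok = ~bad
    multi = float(num[ok].sum() / den[ok].sum()) if ok.any() else float("nan")
    return FstResult(list(gm.marker_ids), fst, n1, n2, multi)


@dataclass
class DivergenceContrast:
    """Baseline-vs-novel FST readout over the shared markers."""

    marker_ids: list[str]
    fst_baseline: np.ndarray
    fst_novel: np.ndarray
    delta: np.ndarray  # novel - baseline
    median_baseline: float
    median_novel: float
    mean_baseline: float
    mean_novel: float
    multi_locus_baseline: float
    multi_locus_novel: float
    increased_markers: list[str]

    def to_dict(self) -> dict:
        return {
            "marker_ids": self.marker_ids,
            "fst_baseline": [None if np.isnan(v) else float(v)
                             for v in self.fst_baseline],
            "fst_novel": [None if np.isnan(v) else float(v)
                          for v in self.fst_novel],
            "delta": [None if np.isnan(v) else float(v) for v in self.delta],
            "median_baseline": self.median_baseline,
            "median_novel": self.median_novel,
            "mean_baseline": self.mean_baseline,
            "mean_novel": self.mean_novel,
            "multi_locus_baseline": self.multi_locus_baseline,
            "multi_locus_novel": self.multi_locus_novel,
            "increased_markers": self.increased_markers,
        }


def epoch_contrast(
    gm: GenotypeMatrix,
    group_labels: tuple[str, str],
    baseline_epoch: str = "baseline",
    novel_epoch: str = "novel",
    report_threshold: float = 0.05,
) -> DivergenceContrast:
    """Weir-Cockerham FST per epoch on shared markers, with per-marker delta
    and the markers whose divergence rose by more than ``report_threshold``.

    Medians and means are taken over markers with a defined FST in the
    respective epoch; both the per-marker mean and the multi-locus
    ratio-of-averages are reported as population-level summaries.
    """
    if gm.epoch is None:
        raise ValueError("genotype matrix must carry epoch tags")
    ep = np.asarray(gm.epoch)
    for name in (baseline_epoch, novel_epoch):
        if not (ep == name).any():
            raise ValueError(f"epoch {name!r} has no samples")
    results = {}
    for name in (baseline_epoch, novel_epoch):
        ids = [s for s, e in zip(gm.sample_ids, ep) if e == name]
        sub = gm.subset_samples(ids)
        lab = np.asarray(sub.labels)
        if not ((lab == group_labels[0]).any() and (lab == group_labels[1]).any()):
            raise ValueError(
                f"epoch {name!r} must contain both populations {group_labels}"
            )
        results[name] = wc_fst_per_snp(sub, group_labels)
    fa = results[baseline_epoch].fst
    fb = results[novel_epoch].fst
    delta = fb - fa
    increased = [
        m for m, d in zip(gm.marker_ids, delta)
        if not np.isnan(d) and d > report_threshold
    ]

    def _median(v: np.ndarray) -> float:
        ok = ~np.isnan(v)
        return float(np.median(v[ok])) if ok.any() else float("nan")

    def _mean(v: np.ndarray) -> float:
        ok = ~np.isnan(v)
        return float(np.mean(v[ok])) if ok.any() else float("nan")

    return DivergenceContrast(
        marker_ids=list(gm.marker_ids),
        fst_baseline=fa,
        fst_novel=fb,
        delta=delta,
        median_baseline=_median(fa),
        median_novel=_median(fb),
        mean_baseline=_mean(fa),
        mean_novel=_mean(fb),
        multi_locus_baseline=results[baseline_epoch].multi_locus_fst,
        multi_locus_novel=results[novel_epoch].multi_locus_fst,
        increased_markers=increased,
    )
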