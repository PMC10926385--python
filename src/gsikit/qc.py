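"""Genotype-call quality-control cascade.

Six filters applied in a fixed order, matching the assay-cleanup narrative:

1. marker call rate (drop iff called fraction <= 80%, boundary inclusive),
2. no-template-control fluorescence (drop iff NTC > 0.2, strict, or the NTC
   signal falls inside any called genotype cluster's fluorescence range),
3. sample missingness (drop iff missing fraction > 20%, strict),
4. monomorphic markers (all non-missing calls a single dosage),
5. near-zero variance (most/second-most frequent call ratio > 19 AND
   distinct calls < 10% of non-missing calls),
6. greedy pruning of correlated marker pairs (|Pearson r| > 0.90).

Every drop decision is recorded with the marker/sample id, the rule name and
the triggering value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import GenotypeMatrix, NTCTable, RunConfig

log = logging.getLogger("gsikit")

QC_STAGES = (
    "call_rate",
    "ntc",
    "sample_missingness",
    "monomorphic",
    "near_zero_variance",
    "correlation",
)


@dataclass
class QcReport:
    dropped_markers: list[tuple[str, str, float]] = field(default_factory=list)
    dropped_samples: list[tuple[str, str, float]] = field(default_factory=list)
    #: (stage, markers_after, samples_after) in execution order
    kept_counts: list[tuple[str, int, int]] = field(default_factory=list)

    def drop_marker(self, marker: str, rule: str, value: float) -> None:
        self.dropped_markers.append((marker, rule, float(value)))
        log.info("QC drop marker %s: rule=%s value=%.4g", marker, rule, value)

    def drop_sample(self, sample: str, rule: str, value: float) -> None:
        self.dropped_samples.append((sample, rule, float(value)))
        log.info("QC drop sample %s: rule=%s value=%.4g", sample, rule, value)

    def record_stage(self, stage: str, gm: GenotypeMatrix) -> None:
        self.kept_counts.append((stage, gm.n_markers, gm.n_samples))

    def to_dict(self) -> dict:
        return {
            "dropped_markers": [list(t) for t in self.dropped_markers],
            "dropped_samples": [list(t) for t in self.dropped_samples],
            "kept_counts": [list(t) for t in self.kept_counts],
        }


def filter_call_rate(
    gm: GenotypeMatrix, max_drop: float = 0.80, report: QcReport | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop markers whose call rate is at or below ``max_drop``."""
    report = report or QcReport()
    rate = 1.0 - gm.missing_mask.mean(axis=0)
    keep = []
    for j, m in enumerate(gm.marker_ids):
        if rate[j] <= max_drop:
            report.drop_marker(m, "call_rate", rate[j])
        else:
            keep.append(m)
    return gm.subset_markers(keep), report


def filter_ntc(
    gm: GenotypeMatrix,
    ntc: NTCTable | None,
    fluor_max: float = 0.2,
    report: QcReport | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop markers whose NTC fluoresces above ``fluor_max`` (strict >) or
    within any supplied genotype-cluster fluorescence range. Markers without
    an NTC record pass."""
    report = report or QcReport()
    if ntc is None:
        return gm, report
    keep = []
    for m in gm.marker_ids:
        f = ntc.fluorescence_of(m)
        if f is None:
            keep.append(m)
            continue
        if f > fluor_max:
            report.drop_marker(m, "ntc", f)
            continue
        ranges = (ntc.cluster_ranges or {}).get(m, [])
        if any(lo <= f <= hi for lo, hi in ranges):
            report.drop_marker(m, "ntc_cluster_overlap", f)
            continue
        keep.append(m)
    return gm.subset_markers(keep), report


def filter_sample_missingness(
    gm: GenotypeMatrix, max_missing: float = 0.20, report: QcReport | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop samples whose missing fraction strictly exceeds ``max_missing``."""
    report = report or QcReport()
    frac = gm.missing_mask.mean(axis=1)
    keep = []
    for i, s in enumerate(gm.sample_ids):
        if frac[i] > max_missing:
            report.drop_sample(s, "sample_missingness", frac[i])
        else:
            keep.append(s)
    return gm.subset_samples(keep), report


def filter_monomorphic(
    gm: GenotypeMatrix, report: QcReport | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop markers whose non-missing calls are all one dosage value
    (missing calls are ignored; an all-missing marker is also dropped)."""
    report = report or QcReport()
    keep = []
    for j, m in enumerate(gm.marker_ids):
        col = gm.dosage[:, j]
        obs = col[~np.isnan(col)]
        n_distinct = len(np.unique(obs))
        if n_distinct <= 1:
            report.drop_marker(m, "monomorphic", float(n_distinct))
        else:
            keep.append(m)
    return gm.subset_markers(keep), report


def filter_near_zero_variance(
    gm: GenotypeMatrix,
    freq_ratio_cut: float = 19.0,
    unique_pct_cut: float = 10.0,
    report: QcReport | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop markers that are nearly constant: the ratio of the most to the
    second most frequent call exceeds ``freq_ratio_cut`` AND distinct calls
    make up less than ``unique_pct_cut`` percent of non-missing calls."""
    report = report or QcReport()
    keep = []
    for j, m in enumerate(gm.marker_ids):
        col = gm.dosage[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            report.drop_marker(m, "near_zero_variance", 0.0)
            continue
        _, counts = np.unique(obs, return_counts=True)
        counts = np.sort(counts)[::-1]
        ratio = counts[0] / counts[1] if len(counts) > 1 else np.inf
        unique_pct = 100.0 * len(counts) / obs.size
        if ratio > freq_ratio_cut and unique_pct < unique_pct_cut:
            report.drop_marker(m, "near_zero_variance", float(ratio))
        else:
            keep.append(m)
    return gm.subset_markers(keep), report


def _pairwise_abs_corr(dosage: np.ndarray) -> np.ndarray:
    """|Pearson r| on pairwise-complete observations; pairs with < 3 complete
    observations, or a constant member, get 0."""
    n_markers = dosage.shape[1]
    corr = np.zeros((n_markers, n_markers))
    for a in range(n_markers):
        for b in range(a + 1, n_markers):
            both = ~np.isnan(dosage[:, a]) & ~np.isnan(dosage[:, b])
            if both.sum() < 3:
                log.info("prune_correlated: pair (%d,%d) has < 3 complete "
                         "observations; correlation treated as 0", a, b)
                continue
            x, y = dosage[both, a], dosage[both, b]
            if x.std() == 0 or y.std() == 0:
                continue
            corr[a, b] = corr[b, a] = abs(np.corrcoef(x, y)[0, 1])
    return corr


def prune_correlated(
    gm: GenotypeMatrix, cutoff: float = 0.90, report: QcReport | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Greedy pruning of correlated marker sets to single representatives.

    While any pair exceeds the cutoff, take the highest-|r| pair and remove
    its member with the larger mean absolute correlation to the remaining
    markers (ties remove the later-indexed marker). Deterministic in marker
    order.
    """
    if gm.n_markers < 2:
        return gm, report or QcReport()
    report = report or QcReport()
    corr = _pairwise_abs_corr(gm.dosage)
    active = list(range(gm.n_markers))
    while True:
        sub = corr[np.ix_(active, active)]
        np.fill_diagonal(sub, 0.0)
        if sub.max() <= cutoff:
            break
        a_i, b_i = np.unravel_index(int(np.argmax(sub)), sub.shape)
        mean_a = sub[a_i].sum() / (len(active) - 1)
        mean_b = sub[b_i].sum() / (len(active) - 1)
        if mean_a > mean_b:
            drop_local = a_i
        elif mean_b > mean_a:
            drop_local = b_i
        else:
            drop_local = max(a_i, b_i)
        drop = active[drop_local]
        report.drop_marker(
            gm.marker_ids[drop], "correlation", float(sub[a_i, b_i])
        )
        active.remove(drop)
    return gm.subset_markers([gm.marker_ids[j] for j in active]), report


def run_qc(
    gm: GenotypeMatrix,
    ntc: NTCTable | None = None,
    config: RunConfig | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Full cascade in canonical order; raises if any stage empties the panel."""
    config = config or RunConfig()
    report = QcReport()
    report.kept_counts.append(("input", gm.n_markers, gm.n_samples))

    stages = (
        ("call_rate", lambda g: filter_call_rate(
            g, config.call_rate_max_drop, report)),
        ("ntc", lambda g: filter_ntc(g, ntc, config.ntc_fluor_max, report)),
        ("sample_missingness", lambda g: filter_sample_missingness(
            g, config.missingness_max, report)),
        ("monomorphic", lambda g: filter_monomorphic(g, report)),
        ("near_zero_variance", lambda g: filter_near_zero_variance(
            g, config.nzv_freq_ratio, config.nzv_unique_pct, report)),
        ("correlation", lambda g: prune_correlated(
            g, config.corr_cutoff, report)),
    )
    for stage, fn in stages:
        gm, _ = fn(gm)
        report.record_stage(stage, gm)
        if gm.n_markers == 0 or gm.n_samples == 0:
            raise ValueError(f"panel exhausted after QC stage {stage!r}")
    return gm, report
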