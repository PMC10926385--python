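"""Shared domain types for the stock-identification pipeline.

Conventions used throughout the package:

* genomic coordinates are 0-based half-open (BED convention); VCF positions
  are converted on read,
* a missing genotype call is ``NaN`` in the float dosage matrix — never a
  numeric code — so no arithmetic step can silently treat it as data,
* dosage is the alternate-allele count of a diploid genotype: 0, 1 or 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np

#: Sentinel for a missing genotype call (float NaN; ``dosage != dosage`` tests it).
MISSING: float = float("nan")

#: Default CSV token for a missing call.
MISSING_TOKEN: str = "NA"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class AlleleCountMatrix:
    """SNP x pool ref/alt read counts with per-pool haploid sizes.

    Each SNP is biallelic by construction: only a reference and an alternate
    allele are tracked, and per-cell depth is ``ref + alt``.
    """

    snp_ids: list[str]
    pool_ids: list[str]
    ref_counts: np.ndarray  # (n_snps, n_pools) non-negative ints
    alt_counts: np.ndarray  # (n_snps, n_pools) non-negative ints
    pool_haploid_sizes: np.ndarray  # (n_pools,) positive ints

    def __post_init__(self) -> None:
        self.ref_counts = np.asarray(self.ref_counts, dtype=np.int64)
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int64)
        self.pool_haploid_sizes = np.asarray(self.pool_haploid_sizes, dtype=np.int64)
        _check_unique(self.snp_ids, "SNP")
        _check_unique(self.pool_ids, "pool")
        shape = (len(self.snp_ids), len(self.pool_ids))
        if self.ref_counts.shape != shape or self.alt_counts.shape != shape:
            raise ValueError(
                f"count matrices must both be {shape}; got "
                f"ref {self.ref_counts.shape}, alt {self.alt_counts.shape}"
            )
        if (self.ref_counts < 0).any() or (self.alt_counts < 0).any():
            raise ValueError("read counts must be non-negative")
        if self.pool_haploid_sizes.shape != (len(self.pool_ids),):
            raise ValueError("one haploid size per pool required")
        if (self.pool_haploid_sizes <= 0).any():
            raise ValueError("pool haploid sizes must be positive")

    @property
    def depth(self) -> np.ndarray:
        return self.ref_counts + self.alt_counts

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_pools(self) -> int:
        return len(self.pool_ids)


@dataclass
class GenotypeMatrix:
    """Sample x marker dosage matrix with optional population labels.

    ``dosage`` holds values in {0, 1, 2} with NaN for missing; ``labels`` is a
    population label per sample and ``epoch`` a free-text batch tag (e.g.
    ``"baseline"`` vs ``"novel"``).
    """

    sample_ids: list[str]
    marker_ids: list[str]
    dosage: np.ndarray  # (n_samples, n_markers) float, NaN = missing
    labels: Optional[list[str]] = None
    epoch: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.marker_ids, "marker")
        shape = (len(self.sample_ids), len(self.marker_ids))
        if self.dosage.shape != shape:
            raise ValueError(f"dosage must be {shape}, got {self.dosage.shape}")
        obs = self.dosage[~np.isnan(self.dosage)]
        if not np.isin(obs, (0.0, 1.0, 2.0)).all():
            bad = obs[~np.isin(obs, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosage values must be 0, 1, 2 or missing; found {bad}")
        for name in ("labels", "epoch"):
            val = getattr(self, name)
            if val is not None and len(val) != len(self.sample_ids):
                raise ValueError(f"{name} must have one entry per sample")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def subset_markers(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = {m: j for j, m in enumerate(self.marker_ids)}
        cols = [idx[m] for m in keep]
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            marker_ids=list(keep),
            dosage=self.dosage[:, cols].copy(),
            labels=list(self.labels) if self.labels is not None else None,
            epoch=list(self.epoch) if self.epoch is not None else None,
        )

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in keep]
        return GenotypeMatrix(
            sample_ids=list(keep),
            marker_ids=list(self.marker_ids),
            dosage=self.dosage[rows, :].copy(),
            labels=[self.labels[i] for i in rows] if self.labels is not None else None,
            epoch=[self.epoch[i] for i in rows] if self.epoch is not None else None,
        )


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    name: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start (half-open): "
                f"{self.chrom}:{self.start}-{self.end}"
            )


@dataclass
class IntervalSet:
    """Ordered collection of 0-based half-open genomic intervals."""

    records: list[Interval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class PanelDefinition:
    """Ordered marker list with provenance tags and selection scores.

    ``provenance`` values are ``fst_outlier``, ``linkage_block`` or ``both``
    (also ``pca_contribution`` after panel reduction).
    """

    marker_ids: list[str]
    provenance: list[str]
    score: list[float]

    def __post_init__(self) -> None:
        _check_unique(self.marker_ids, "marker")
        n = len(self.marker_ids)
        if len(self.provenance) != n or len(self.score) != n:
            raise ValueError("provenance and score must align with marker_ids")

    def __len__(self) -> int:
        return len(self.marker_ids)


@dataclass
class NTCTable:
    """Per-marker no-template-control fluorescence, optionally with the
    fluorescence intervals of the called genotype clusters."""

    marker_ids: list[str]
    ntc_fluorescence: np.ndarray  # (n_markers,) non-negative
    cluster_ranges: Optional[dict[str, list[tuple[float, float]]]] = None

    def __post_init__(self) -> None:
        self.ntc_fluorescence = np.asarray(self.ntc_fluorescence, dtype=float)
        _check_unique(self.marker_ids, "marker")
        if self.ntc_fluorescence.shape != (len(self.marker_ids),):
            raise ValueError("one fluorescence value per marker required")
        if (self.ntc_fluorescence < 0).any():
            raise ValueError("NTC fluorescence must be non-negative")

    def fluorescence_of(self, marker: str) -> Optional[float]:
        try:
            i = self.marker_ids.index(marker)
        except ValueError:
            return None
        return float(self.ntc_fluorescence[i])


@dataclass
class RunConfig:
    """All pipeline thresholds in one place.

    Defaults reproduce the published filter cascade: markers with call rate
    <= 80% or NTC fluorescence > 0.2 are dropped, samples with > 20%
    missingness are dropped, and the membership line sits at probability 0.5.
    """

    call_rate_max_drop: float = 0.80   # marker dropped iff call rate <= this
    ntc_fluor_max: float = 0.2         # marker dropped iff NTC fluor > this
    missingness_max: float = 0.20      # sample dropped iff missing frac > this
    nzv_freq_ratio: float = 19.0       # near-zero-variance: top/second call ratio
    nzv_unique_pct: float = 10.0       # near-zero-variance: % distinct calls
    corr_cutoff: float = 0.90          # |r| pruning threshold
    outlier_quantile: float = 0.99     # FST outlier quantile
    contribution_quantile: float = 0.70  # PCA contribution quantile
    membership_threshold: float = 0.5  # strict > for target-class assignment
    test_fraction: float = 0.20        # stratified hold-out fraction
    seed: int = 0
    mtry_min: int = 2
    mtry_max: int = 10
    node_min: int = 2
    node_max: int = 10
    n_trees: int = 500

    _FRACTIONS = (
        "call_rate_max_drop",
        "missingness_max",
        "membership_threshold",
        "test_fraction",
        "outlier_quantile",
        "contribution_quantile",
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in self._FRACTIONS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or math.isnan(v):
                raise ValueError(f"config {name} must lie in [0, 1], got {v}")
        if self.ntc_fluor_max < 0:
            raise ValueError("ntc_fluor_max must be >= 0")
        if self.corr_cutoff < 0 or self.corr_cutoff > 1:
            raise ValueError("corr_cutoff must lie in [0, 1]")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")
        for name in ("mtry_min", "mtry_max", "node_min", "node_max", "n_trees"):
            if getattr(self, name) < 1:
                raise ValueError(f"config {name} must be a positive integer")

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        """Load a flat ``key = value`` config file; unknown keys are an error."""
        known = {f.name: f.type for f in fields(cls) if not f.name.startswith("_")}
        kwargs: dict[str, float | int] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key = value")
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                kwargs[key] = int(val) if known[key] == "int" else float(val)
        return cls(**kwargs)  # type: ignore[arg-type]

    def replace(self, **overrides) -> "RunConfig":
        data = {f.name: getattr(self, f.name) for f in fields(self)
                if not f.name.startswith("_")}
        data.update(overrides)
        return RunConfig(**data)
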