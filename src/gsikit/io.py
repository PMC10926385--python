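"""Readers and writers for the pipeline's text formats.

Genotype matrices travel as sample x marker CSV (header row of marker names,
one row per sample, optional ``population`` / ``epoch`` columns, "NA" for a
missing call by default). Allele counts travel as long-format CSV
(snp_id, pool_id, ref, alt). Intervals are BED 3+; panels and reports are
JSON. VCF is read-only via cyvcf2.
"""

from __future__ import annotations

import json
import logging
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import (
    AlleleCountMatrix,
    GenotypeMatrix,
    Interval,
    IntervalSet,
    NTCTable,
    PanelDefinition,
)

log = logging.getLogger("gsikit")

_RESERVED_COLUMNS = ("population", "epoch")


def read_genotype_csv(
    path: str,
    missing_token: str = "NA",
    sample_column: str = "sample",
) -> GenotypeMatrix:
    """Parse a sample x marker dosage CSV.

    Cells must be 0, 1, 2 or the missing token; anything else raises a
    :class:`ValueError` naming the offending row and column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if sample_column not in df.columns:
        raise ValueError(f"{path}: missing required {sample_column!r} column")
    sample_ids = df[sample_column].tolist()
    if len(set(sample_ids)) != len(sample_ids):
        dup = next(s for s in sample_ids if sample_ids.count(s) > 1)
        raise ValueError(f"{path}: duplicate sample id {dup!r}")

    labels = df["population"].tolist() if "population" in df.columns else None
    epoch = df["epoch"].tolist() if "epoch" in df.columns else None
    marker_cols = [c for c in df.columns
                   if c != sample_column and c not in _RESERVED_COLUMNS]

    dosage = np.empty((len(df), len(marker_cols)), dtype=float)
    for j, col in enumerate(marker_cols):
        for i, tok in enumerate(df[col]):
            tok = tok.strip()
            if tok == missing_token:
                dosage[i, j] = np.nan
            elif tok in ("0", "1", "2"):
                dosage[i, j] = float(tok)
            else:
                raise ValueError(
                    f"{path}: invalid dosage {tok!r} at sample "
                    f"{sample_ids[i]!r}, marker {col!r}"
                )
    return GenotypeMatrix(sample_ids, marker_cols, dosage, labels=labels, epoch=epoch)


def write_genotype_csv(
    gm: GenotypeMatrix, path: str, missing_token: str = "NA"
) -> None:
    df = pd.DataFrame(
        {"sample": gm.sample_ids}
        | ({"population": gm.labels} if gm.labels is not None else {})
        | ({"epoch": gm.epoch} if gm.epoch is not None else {})
    )
    for j, m in enumerate(gm.marker_ids):
        col = gm.dosage[:, j]
        df[m] = [missing_token if np.isnan(v) else str(int(v)) for v in col]
    df.to_csv(path, index=False)


def read_bed(path: str) -> IntervalSet:
    """Read a BED 3+ file as 0-based half-open intervals, order preserved."""
    records: list[Interval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"iv{lineno}"
            try:
                records.append(Interval(chrom, start, end, name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(records)


def write_bed(ivs: IntervalSet, path: str) -> None:
    with open(path, "w") as fh:
        for iv in ivs:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def read_vcf_dosage(path: str) -> GenotypeMatrix:
    """Read GT fields of a VCF into dosages (0/0 -> 0, 0/1 -> 1, 1/1 -> 2,
    ./. -> missing). Multi-allelic records are skipped with a warning."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            log.warning(
                "skipping multi-allelic record %s:%s", rec.CHROM, rec.POS
            )
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types
        col = np.where(gt == 0, 0.0,
                       np.where(gt == 1, 1.0,
                                np.where(gt == 3, 2.0, np.nan)))
        marker_ids.append(rec.ID if rec.ID not in (None, ".")
                          else f"{rec.CHROM}_{rec.POS - 1}")
        columns.append(col)
    if n_skipped:
        log.warning("skipped %d multi-allelic records in %s", n_skipped, path)
    dosage = (np.column_stack(columns) if columns
              else np.empty((len(sample_ids), 0)))
    return GenotypeMatrix(sample_ids, marker_ids, dosage)


def read_allele_counts_csv(path: str, sizes_path: Optional[str] = None) -> AlleleCountMatrix:
    """Read a long-format allele-count CSV (snp_id, pool_id, ref, alt).

    Pool haploid sizes come either from a ``haploid_size`` column or from a
    two-column CSV at *sizes_path* (pool_id, haploid_size).
    """
    df = pd.read_csv(path)
    required = {"snp_id", "pool_id", "ref", "alt"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: required columns {sorted(required)}")
    snp_ids = list(dict.fromkeys(df["snp_id"].astype(str)))
    pool_ids = list(dict.fromkeys(df["pool_id"].astype(str)))
    si = {s: i for i, s in enumerate(snp_ids)}
    pj = {p: j for j, p in enumerate(pool_ids)}
    ref = np.zeros((len(snp_ids), len(pool_ids)), dtype=np.int64)
    alt = np.zeros_like(ref)
    for row in df.itertuples(index=False):
        i, j = si[str(row.snp_id)], pj[str(row.pool_id)]
        ref[i, j] = row.ref
        alt[i, j] = row.alt
    if "haploid_size" in df.columns:
        sizes_map = (df.groupby("pool_id")["haploid_size"].first()).to_dict()
        sizes = np.array([sizes_map[p] for p in pool_ids], dtype=np.int64)
    elif sizes_path is not None:
        sdf = pd.read_csv(sizes_path)
        smap = dict(zip(sdf["pool_id"].astype(str), sdf["haploid_size"]))
        sizes = np.array([smap[p] for p in pool_ids], dtype=np.int64)
    else:
        raise ValueError(
            f"{path}: provide a haploid_size column or a pool-sizes CSV"
        )
    return AlleleCountMatrix(snp_ids, pool_ids, ref, alt, sizes)


def write_allele_counts_csv(acm: AlleleCountMatrix, path: str) -> None:
    rows = []
    for i, s in enumerate(acm.snp_ids):
        for j, p in enumerate(acm.pool_ids):
            rows.append((s, p, int(acm.ref_counts[i, j]),
                         int(acm.alt_counts[i, j]),
                         int(acm.pool_haploid_sizes[j])))
    pd.DataFrame(
        rows, columns=["snp_id", "pool_id", "ref", "alt", "haploid_size"]
    ).to_csv(path, index=False)


def read_ntc_csv(path: str) -> NTCTable:
    """Read per-marker NTC fluorescence; optional ``cluster_lo``/``cluster_hi``
    columns give one fluorescence interval per called genotype cluster."""
    df = pd.read_csv(path)
    if not {"marker_id", "ntc_fluorescence"}.issubset(df.columns):
        raise ValueError(f"{path}: required columns marker_id, ntc_fluorescence")
    grouped = df.groupby("marker_id", sort=False)
    marker_ids = list(grouped.groups)
    fluor = grouped["ntc_fluorescence"].first().to_numpy(dtype=float)
    ranges: Optional[dict[str, list[tuple[float, float]]]] = None
    if {"cluster_lo", "cluster_hi"}.issubset(df.columns):
        ranges = {}
        for m, sub in grouped:
            ivals = [(float(lo), float(hi))
                     for lo, hi in zip(sub["cluster_lo"], sub["cluster_hi"])
                     if not (pd.isna(lo) or pd.isna(hi))]
            if ivals:
                ranges[str(m)] = ivals
    return NTCTable([str(m) for m in marker_ids], fluor, cluster_ranges=ranges)


def write_ntc_csv(ntc: NTCTable, path: str) -> None:
    rows = []
    for m, f in zip(ntc.marker_ids, ntc.ntc_fluorescence):
        ivals = (ntc.cluster_ranges or {}).get(m)
        if ivals:
            for lo, hi in ivals:
                rows.append((m, float(f), lo, hi))
        else:
            rows.append((m, float(f), np.nan, np.nan))
    pd.DataFrame(
        rows, columns=["marker_id", "ntc_fluorescence", "cluster_lo", "cluster_hi"]
    ).to_csv(path, index=False)


def write_panel_json(panel: PanelDefinition, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "marker_ids": panel.marker_ids,
                "provenance": panel.provenance,
                "score": [float(s) for s in panel.score],
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def read_panel_json(path: str) -> PanelDefinition:
    with open(path) as fh:
        d = json.load(fh)
    return PanelDefinition(d["marker_ids"], d["provenance"], d["score"])
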