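"""PCA-contribution panel reduction.

The combined marker panel is reduced to the markers contributing most to
between-population separation: PCA on the sample x marker dosage (or
frequency) matrix, a per-marker contribution score from the absolute
loadings of the first two components weighted by their explained-variance
fractions, and selection of markers scoring at or above a quantile of the
score distribution (default the 70th percentile).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import PanelDefinition


@dataclass
class PcaSummary:
    marker_ids: list[str]
    loadings: np.ndarray  # (n_markers, n_components), unit-norm columns
    explained_variance_fraction: np.ndarray  # non-increasing, sums to <= 1


def pca_loadings(
    matrix: np.ndarray,
    marker_ids: list[str] | None = None,
    center: bool = True,
    scale: bool = False,
) -> PcaSummary:
    """Principal components of an observations x markers matrix via SVD.

    Loadings are unit-norm eigenvectors of the (centered, optionally
    scaled) covariance matrix; missing values must be imputed beforehand.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 observations and >= 2 markers")
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; impute first")
    if marker_ids is None:
        marker_ids = [f"m{j}" for j in range(X.shape[1])]
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            j = int(np.flatnonzero(sd == 0)[0])
            raise ValueError(
                f"marker {marker_ids[j]!r} is constant; run QC "
                "(monomorphic / near-zero-variance filters) before scaling"
            )
        X = X / sd
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    var = s**2 / (X.shape[0] - 1)
    frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    return PcaSummary(
        marker_ids=list(marker_ids),
        loadings=vt.T,
        explained_variance_fraction=frac,
    )


def contribution_scores(pca: PcaSummary, n_components: int = 2) -> np.ndarray:
    """Variance-weighted absolute loadings summed over the leading components:
    score_j = sum_k w_k |L_jk| with w_k the explained-variance fraction.
    Set ``weighted=False`` behaviour by passing weights of 1 via
    :func:`contribution_scores_unweighted`."""
    k = min(n_components, pca.loadings.shape[1])
    if n_components > pca.loadings.shape[1]:
        raise ValueError(
            f"requested {n_components} components, only "
            f"{pca.loadings.shape[1]} available"
        )
    w = pca.explained_variance_fraction[:k]
    return (np.abs(pca.loadings[:, :k]) * w).sum(axis=1)


def contribution_scores_unweighted(pca: PcaSummary, n_components: int = 2) -> np.ndarray:
    """Plain |L1| + |L2| + ... over the leading components (no variance weights)."""
    if n_components > pca.loadings.shape[1]:
        raise ValueError("not enough components")
    return np.abs(pca.loadings[:, :n_components]).sum(axis=1)


def select_top_contributors(
    marker_ids: list[str],
    scores: np.ndarray,
    quantile: float = 0.70,
    mode: str = "percentile",
) -> PanelDefinition:
    """Markers whose contribution clears the selection rule.

    ``percentile`` (default): score >= the empirical quantile of all scores
    (linear interpolation; ties at the threshold all kept).
    ``cumulative``: the smallest top-scoring set whose summed contribution
    reaches ``quantile`` of the total — the alternative reading of a
    "70% contribution" rule.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no scores to select from")
    order = np.argsort(-scores, kind="stable")
    if mode == "percentile":
        thresh = float(np.quantile(scores, quantile))
        keep = [int(i) for i in order if scores[i] >= thresh]
    elif mode == "cumulative":
        total = scores.sum()
        keep, acc = [], 0.0
        for i in order:
            keep.append(int(i))
            acc += scores[i]
            if total > 0 and acc >= quantile * total:
                break
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    return PanelDefinition(
        marker_ids=[marker_ids[i] for i in keep],
        provenance=["pca_contribution"] * len(keep),
        score=[float(scores[i]) for i in keep],
    )


def reduce_panel(
    matrix: np.ndarray,
    marker_ids: list[str],
    quantile: float = 0.70,
    n_components: int = 2,
    center: bool = True,
    scale: bool = False,
    mode: str = "percentile",
) -> tuple[PanelDefinition, PcaSummary]:
    """One-call pipeline: PCA -> contribution scores -> quantile selection."""
    pca = pca_loadings(matrix, marker_ids, center=center, scale=scale)
    scores = contribution_scores(pca, n_components=n_components)
    panel = select_top_contributors(marker_ids, scores, quantile=quantile, mode=mode)
    return panel, pca
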