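"""Normalization, PCA and loading-rank factor extraction.

The profiling computation: global median normalization of the feature
matrix, feature-centered (unscaled) PCA over the samples of one batch,
extraction of the top-k features by signed PC1 loading, and the
cross-batch intersection of those factor lists.

Loadings are reported on a "PC score" scale (unit loading x singular
value / sqrt(n-1)) so their magnitudes track the intensity swing of the
underlying feature; ranking is invariant to that scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .binning import BinGrid, FeatureMatrix

__all__ = [
    "median_normalize",
    "PcaResult",
    "run_pca",
    "Factor",
    "top_loadings",
    "FactorPair",
    "common_factors",
    "plot_scores",
    "plot_loadings",
]


def median_scale_factors(m: FeatureMatrix, reference: str | None = None) -> pd.Series:
    """Per-sample multipliers of global median normalization.

    Medians are computed over the features that are positive in every
    sample (so absent features cannot drag a median to zero); each
    sample's factor is reference_median / sample_median.  The reference
    is the first sample's median unless ``reference`` names another
    sample.
    """
    df = m.values
    common = (df > 0).all(axis=1)
    if not common.any():
        raise ValueError("no feature is positive in all samples")
    med = df.loc[common].median(axis=0)
    zero = med[med <= 0]
    if len(zero):
        raise ValueError(f"zero median over the common-positive set: sample {zero.index[0]!r}")
    ref = med[reference] if reference is not None else med.iloc[0]
    return ref / med


def median_normalize(m: FeatureMatrix, reference: str | None = None) -> FeatureMatrix:
    """Global median normalization: rescale every sample so medians agree."""
    return FeatureMatrix(
        m.values * median_scale_factors(m, reference), m.meta.copy(), m.grid
    )


@dataclass
class PcaResult:
    """Feature-centered PCA of one batch's samples.

    scores: components x samples; loadings: features x components on the
    PC-score scale; per-component sign fixed so the largest-|loading|
    feature loads positively.
    """

    scores: np.ndarray
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    sample_ids: list[str]
    singular_values: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[0]


def run_pca(m: FeatureMatrix, components: int = 2) -> PcaResult:
    """Unscaled PCA: samples as observations, features mean-centered.

    Requests for more components than samples allow are truncated with
    a warning rather than failing.
    """
    df = m.values
    n_samples = df.shape[1]
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    max_k = min(n_samples - 1, df.shape[0])
    if components > max_k:
        warnings.warn(f"components truncated from {components} to {max_k}")
        components = max_k
    X = df.values.T  # samples x features
    pca = PCA(n_components=components, svd_solver="full")
    scores = pca.fit_transform(X)  # samples x k
    load_unit = pca.components_.T  # features x k
    scale = pca.singular_values_ / np.sqrt(n_samples - 1)
    loadings = load_unit * scale
    # sign convention: dominant feature of each component loads positively
    for j in range(components):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PcaResult(
        scores=scores.T,
        loadings=pd.DataFrame(
            loadings, index=df.index, columns=[f"PC{j + 1}" for j in range(components)]
        ),
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean=pca.mean_,
        sample_ids=list(df.columns),
        singular_values=pca.singular_values_,
    )


@dataclass(frozen=True)
class Factor:
    """One grid cell selected by its PC1 loading rank."""

    feature_id: str
    pc1: float
    pc2: float
    rank: int
    batch: str
    mz_lo: float = 0.0
    mz_hi: float = 0.0
    scan_lo: int = 0
    scan_hi: int = 0

    @classmethod
    def from_feature_id(cls, fid: str, pc1: float, pc2: float, rank: int, batch: str) -> "Factor":
        m_lo, m_hi, s_lo, s_hi = BinGrid.parse_feature_id(fid)
        return cls(fid, pc1, pc2, rank, batch, m_lo, m_hi, s_lo, s_hi)


def top_loadings(
    p: PcaResult, component: int = 0, k: int = 20, batch: str = ""
) -> list[Factor]:
    """Top-k features by signed loading on one component, ranks 1..k.

    Descending signed value; ties broken by feature identifier
    ascending.  PC1/PC2 values are carried along for reporting.
    """
    if component >= p.loadings.shape[1]:
        raise ValueError(f"component {component} not available")
    if k > len(p.loadings):
        raise ValueError("k exceeds the feature count")
    col = p.loadings.iloc[:, component]
    order = sorted(zip(-col.values, col.index), key=lambda t: (t[0], t[1]))
    pc2 = p.loadings.iloc[:, 1] if p.loadings.shape[1] > 1 else None
    out = []
    for rank, (neg, fid) in enumerate(order[:k], start=1):
        out.append(
            Factor.from_feature_id(
                fid, -neg, float(pc2[fid]) if pc2 is not None else 0.0, rank, batch
            )
        )
    return out


@dataclass(frozen=True)
class FactorPair:
    """A factor found in both batches (possibly over a merged scan span)."""

    feature_id: str
    factor_a: Factor
    factor_b: Factor


def _merge_adjacent(factors: Sequence[Factor]) -> list[Factor]:
    """Coalesce factors with identical m/z bin and contiguous scan bins."""
    by_mz: dict[tuple[float, float], list[Factor]] = {}
    for f in factors:
        by_mz.setdefault((f.mz_lo, f.mz_hi), []).append(f)
    merged: list[Factor] = []
    for group in by_mz.values():
        group.sort(key=lambda f: f.scan_lo)
        chain = [group[0]]
        for f in group[1:]:
            if f.scan_lo == chain[-1].scan_hi:
                chain.append(f)
            else:
                merged.append(_collapse(chain))
                chain = [f]
        merged.append(_collapse(chain))
    return merged


def _collapse(chain: list[Factor]) -> Factor:
    if len(chain) == 1:
        return chain[0]
    best = min(chain, key=lambda f: f.rank)
    fid = f"{best.mz_lo:g}-{best.mz_hi:g}|{chain[0].scan_lo}-{chain[-1].scan_hi}"
    return replace(best, feature_id=fid, scan_lo=chain[0].scan_lo, scan_hi=chain[-1].scan_hi)


def common_factors(
    a: Sequence[Factor], b: Sequence[Factor], merge_adjacent: bool = False
) -> list[FactorPair]:
    """Intersect two batches' factor lists.

    Without merging, factors pair on identical feature identifiers.
    With ``merge_adjacent``, same-m/z factors in contiguous scan bins are
    first coalesced within each batch (so an elution straddling a scan
    boundary becomes one spanned factor), then pairs are formed where
    the m/z bins match and the scan spans overlap.  Output preserves
    batch-a rank order.
    """
    if merge_adjacent:
        a = _merge_adjacent(a)
        b = _merge_adjacent(b)
        pairs = []
        for fa in sorted(a, key=lambda f: f.rank):
            for fb in b:
                if (fa.mz_lo, fa.mz_hi) == (fb.mz_lo, fb.mz_hi) and (
                    fa.scan_lo < fb.scan_hi and fb.scan_lo < fa.scan_hi
                ):
                    span_lo = min(fa.scan_lo, fb.scan_lo)
                    span_hi = max(fa.scan_hi, fb.scan_hi)
                    fid = f"{fa.mz_lo:g}-{fa.mz_hi:g}|{span_lo}-{span_hi}"
                    pairs.append(FactorPair(fid, fa, fb))
                    break
        return pairs
    index_b = {f.feature_id: f for f in b}
    return [
        FactorPair(fa.feature_id, fa, index_b[fa.feature_id])
        for fa in sorted(a, key=lambda f: f.rank)
        if fa.feature_id in index_b
    ]


def plot_scores(p: PcaResult, meta: pd.DataFrame, path) -> None:
    """PC1-PC2 score plot, samples labeled by day."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    days = meta.loc[p.sample_ids, "day"]
    sc = ax.scatter(p.scores[0], p.scores[1] if p.n_components > 1 else 0 * p.scores[0],
                    c=days, cmap="viridis")
    for i, s in enumerate(p.sample_ids):
        ax.annotate(str(days.iloc[i]), (p.scores[0][i], p.scores[1][i] if p.n_components > 1 else 0),
                    fontsize=7)
    fig.colorbar(sc, label="day")
    ax.set_xlabel(f"PC1 ({p.explained_variance_ratio[0]:.0%})")
    if p.n_components > 1:
        ax.set_ylabel(f"PC2 ({p.explained_variance_ratio[1]:.0%})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_loadings(p: PcaResult, path, highlight: Sequence[str] = ()) -> None:
    """PC1-PC2 loading scatter, optionally highlighting selected factors."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    x = p.loadings.iloc[:, 0]
    y = p.loadings.iloc[:, 1] if p.loadings.shape[1] > 1 else 0 * x
    ax.scatter(x, y, s=4, alpha=0.4, color="grey")
    for fid in highlight:
        ax.scatter([x[fid]], [y[fid]], s=20, color="crimson")
        ax.annotate(fid, (x[fid], y[fid]), fontsize=6)
    ax.set_xlabel("PC1 loading")
    ax.set_ylabel("PC2 loading")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
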