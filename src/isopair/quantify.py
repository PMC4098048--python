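"""Metabolome-wide internal standardisation and its evaluation.

Because every native feature co-elutes with its own uniformly
¹³C-labelled analogue, the labelled area is a perfect per-feature
internal standard: dividing area(M) by area(M′) cancels any
multiplicative distortion — matrix effects, injection-volume drift,
source fluctuations — that acts on both isotopologues alike.  This
module computes the ratio matrix and the evaluation statistics used to
demonstrate the effect: per-feature coefficient-of-variation summaries
(5 % histogram bins, capped at 120 %), range scaling, and PCA with
per-group 95 % covariance ellipses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .bracketing import BracketedFeature

__all__ = [
    "RatioMatrix",
    "CvSummary",
    "GroupEllipse",
    "PcaResult",
    "internal_standardise",
    "areas_frame",
    "cv_summary",
    "range_scale",
    "pca",
]


@dataclass
class RatioMatrix:
    """¹²C/¹³C area ratios, features × samples (NaN = undefined)."""

    values: pd.DataFrame
    sample_groups: dict[str, str] = field(default_factory=dict)


@dataclass
class CvSummary:
    """CV distribution of one sample type's replicates."""

    bin_edges: np.ndarray      # 0, 5, ..., 120 (%)
    counts: np.ndarray
    median_cv: float           # %
    p90_cv: float              # %
    n_features: int


@dataclass
class GroupEllipse:
    """95 % covariance ellipse of one sample group in PC1/PC2."""

    center: np.ndarray
    cov: np.ndarray
    width: float
    height: float
    angle_deg: float


@dataclass
class PcaResult:
    scores: pd.DataFrame               # samples × PCs
    loadings: pd.DataFrame             # features × PCs
    explained_pct: np.ndarray
    ellipses: dict[str, GroupEllipse] = field(default_factory=dict)


def areas_frame(
    brackets: list[BracketedFeature], samples: list[str], which: str = "m"
) -> pd.DataFrame:
    """Raw area matrix (features × samples) for M (``which='m'``) or
    M′ (``which='mprime'``); missing cells are NaN."""
    attr = {"m": "area_m", "mprime": "area_mprime"}[which]
    data = np.full((len(brackets), len(samples)), np.nan)
    for i, b in enumerate(brackets):
        for j, s in enumerate(samples):
            e = b.per_sample.get(s)
            if e is not None:
                v = getattr(e, attr)
                if v is not None:
                    data[i, j] = v
    return pd.DataFrame(data, columns=samples)


def internal_standardise(
    brackets: list[BracketedFeature],
    samples: list[str],
    sample_groups: dict[str, str] | None = None,
) -> RatioMatrix:
    """Per-cell ¹²C/¹³C area ratio on a file basis.

    A cell is defined only where both areas exist and the labelled area
    is non-zero; everything else stays NaN — division by zero or
    imputation never occurs.
    """
    m = areas_frame(brackets, samples, "m")
    mp = areas_frame(brackets, samples, "mprime")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = m.values / mp.values
    ratio[~np.isfinite(ratio)] = np.nan
    ratio[(mp.values == 0)] = np.nan
    return RatioMatrix(
        values=pd.DataFrame(ratio, columns=samples),
        sample_groups=dict(sample_groups or {}),
    )


def cv_summary(values: pd.DataFrame | np.ndarray) -> CvSummary:
    """Per-feature CV distribution across replicate columns.

    Only rows complete in all replicates enter the statistics (no
    imputation).  CV = sample standard deviation (n−1) / mean · 100 %;
    the histogram uses 5 % bins with values above 120 % capped into the
    overflow bin, so the counts conserve the number of features.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a features x replicates matrix with >= 2 replicates")
    complete = ~np.isnan(arr).any(axis=1)
    arr = arr[complete]
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / mean * 100.0, 0.0)
    edges = np.arange(0.0, 125.0, 5.0)
    counts, _ = np.histogram(np.clip(cv, 0.0, 120.0), bins=edges)
    return CvSummary(
        bin_edges=edges,
        counts=counts,
        median_cv=float(np.median(cv)) if cv.size else float("nan"),
        p90_cv=float(np.percentile(cv, 90)) if cv.size else float("nan"),
        n_features=int(cv.size),
    )


def range_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-feature range scaling: (x − mean) / (max − min).

    Constant rows (max == min) carry no information on this scale and
    are dropped with a warning.  All scaled values lie in [−1, 1].
    """
    arr = matrix.values.astype(float)
    rng = arr.max(axis=1) - arr.min(axis=1)
    keep = rng > 0
    if not keep.all():
        warnings.warn(
            f"range_scale: dropping {int((~keep).sum())} constant feature row(s)",
            stacklevel=2,
        )
    arr = arr[keep]
    scaled = (arr - arr.mean(axis=1, keepdims=True)) / rng[keep, None]
    return pd.DataFrame(scaled, columns=matrix.columns, index=matrix.index[keep])


def _ellipse(points: np.ndarray, level: float = 0.95) -> GroupEllipse:
    center = points.mean(axis=0)
    cov = np.cov(points, rowvar=False)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    scale = chi2.ppf(level, df=2)
    # eigh returns ascending order; major axis last
    width = 2.0 * np.sqrt(scale * evals[1])
    height = 2.0 * np.sqrt(scale * evals[0])
    angle = np.degrees(np.arctan2(evecs[1, 1], evecs[0, 1]))
    return GroupEllipse(
        center=center, cov=cov, width=float(width),
        height=float(height), angle_deg=float(angle),
    )


def pca(
    scaled: pd.DataFrame,
    sample_groups: dict[str, str] | None = None,
    n_components: int = 2,
) -> PcaResult:
    """PCA of the range-scaled matrix, samples as observations.

    Implemented as an SVD eigendecomposition of the sample covariance
    (features are variables, already mean-centred by range scaling).
    Variance of null components of rank-deficient input is 0.  Per
    sample group a 95 % covariance ellipse is fitted in the PC1/PC2
    plane.
    """
    if scaled.shape[1] < 2 or scaled.shape[0] < 2:
        raise ValueError("need >= 2 samples and >= 2 features")
    samples = list(scaled.columns)
    x = scaled.values.T                       # samples x features
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest-magnitude loading of each PC positive
    for k in range(s.size):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    var = s**2 / max(x.shape[0] - 1, 1)
    total = var.sum()
    explained = var / total * 100.0 if total > 0 else np.zeros_like(var)
    k = min(n_components, s.size)
    pcs = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame((u * s)[:, :k], index=samples, columns=pcs)
    loadings = pd.DataFrame(vt[:k].T, index=scaled.index, columns=pcs)
    ellipses: dict[str, GroupEllipse] = {}
    if sample_groups:
        for group in sorted(set(sample_groups.values())):
            member = [s_ for s_ in samples if sample_groups.get(s_) == group]
            if len(member) >= 2 and k >= 2:
                ellipses[group] = _ellipse(
                    scores.loc[member, ["PC1", "PC2"]].values
                )
    return PcaResult(
        scores=scores,
        loadings=loadings,
        explained_pct=explained[:k],
        ellipses=ellipses,
    )
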