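"""Chromatographic confirmation of scan-level pairs into feature pairs.

A scan-level m/z cluster only claims that the SIL isotope pattern recurs
at one m/z; confirmation requires that the native (M) and labelled (M′)
extracted ion chromatograms hold co-eluting, similarly shaped peaks —
isotopologues of one metabolite co-elute perfectly, background does not.
Peaks are picked with a continuous-wavelet-transform (Mexican-hat
ridge-line) detector, matched across the two XICs within a retention-time
window, and validated by the Pearson correlation of their peak shapes.

Confirmed feature pairs are then de-isotoped (removing pairs seeded on
M+1 or M′−1 instead of the true monoisotopic/fully labelled signals) and
convoluted into feature groups, each group collecting the adducts,
in-source fragments and charge states of one metabolite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .isotope_math import DELTA_C, PROTON_MASS
from .mz_io import Run, XIC, extract_xic
from .pair_scan import MzCluster

__all__ = [
    "FeatureParams",
    "ChromPeak",
    "FeaturePair",
    "FeatureGroup",
    "pick_peaks",
    "pair_features",
    "deisotope",
    "group_features",
    "plausibility_flag",
    "features_to_frame",
    "features_from_frame",
]


@dataclass(frozen=True)
class FeatureParams:
    """Chromatographic confirmation and grouping settings."""

    max_shift_scans: int = 15          # M vs M′ apex tolerance
    min_peak_corr: float = 0.5         # M/M′ shape correlation threshold
    group_window_scans: int = 10       # co-elution window for grouping
    group_corr: float = 0.85           # shape correlation for grouping
    cwt_scales: tuple[int, ...] = (2, 3, 4, 6, 8, 12, 16)
    cwt_snr: float = 3.0
    deisotope_rt_tol_scans: int = 15

    def __post_init__(self) -> None:
        if not (0 < self.min_peak_corr <= 1 and 0 < self.group_corr <= 1):
            raise ValueError("correlation thresholds must lie in (0, 1]")
        if self.max_shift_scans < 1 or self.group_window_scans < 1:
            raise ValueError("windows must be >= 1 scan")


@dataclass(frozen=True, eq=False)
class ChromPeak:
    """One detected chromatographic peak on an XIC."""

    apex_scan: int
    left_scan: int
    right_scan: int
    area: float                # trapezoidal, intensity·scan units
    shape: np.ndarray          # raw intensities over [left, right]


@dataclass(frozen=True, eq=False)
class FeaturePair:
    """A chromatographically confirmed ¹²C/U-¹³C feature pair."""

    mz_m: float
    rt_seconds: float
    z: int
    n_c: int
    area_m: float
    area_mprime: float
    corr: float
    apex_scan: int
    left_scan: int = -1
    right_scan: int = -1
    shape_m: np.ndarray | None = None
    flags: tuple[str, ...] = ()

    @property
    def mz_mprime(self) -> float:
        return self.mz_m + self.n_c * DELTA_C / self.z


@dataclass
class FeatureGroup:
    """All feature pairs attributed to one metabolite."""

    group_id: int
    members: list[FeaturePair]
    representative_rt: float


def _ricker(points: int, a: float) -> np.ndarray:
    """Mexican-hat (ricker) wavelet, matching the classical normalisation."""
    vec = np.arange(points) - (points - 1.0) / 2.0
    xsq = (vec / a) ** 2
    amp = 2.0 / (np.sqrt(3.0 * a) * np.pi**0.25)
    return amp * (1.0 - xsq) * np.exp(-xsq / 2.0)


def _local_maxima(row: np.ndarray) -> np.ndarray:
    """Indices of strict-left / non-strict-right local maxima."""
    if row.size < 3:
        return np.empty(0, dtype=int)
    idx = np.nonzero(
        (row[1:-1] > row[:-2]) & (row[1:-1] >= row[2:]) & (row[1:-1] > 0)
    )[0]
    return idx + 1


def _cwt_ridge_apexes(
    x: np.ndarray, scales: tuple[int, ...], min_snr: float
) -> list[int]:
    """Mexican-hat CWT ridge-line apex detection.

    The signal is convolved with ricker wavelets at each scale; local
    maxima of the coefficient rows are linked into ridge lines from the
    largest scale downwards (nearest neighbour within half a scale, up
    to two skipped rows).  Ridges spanning at least a quarter of the
    scales whose best coefficient clears the SNR threshold — noise being
    the 10th percentile of the absolute smallest-scale coefficients —
    yield an apex at their smallest-scale position.
    """
    scales_arr = np.sort(np.asarray(scales))
    rows = [
        np.convolve(x, _ricker(min(10 * int(a), x.size), a), mode="same")
        for a in scales_arr
    ]
    maxima = [set(_local_maxima(r).tolist()) for r in rows]
    noise = np.percentile(np.abs(rows[0]), 10)
    min_length = max(2, len(scales_arr) // 4)
    ridges = []  # each: dict(pos, gap, points=[(row, pos)])
    for pos in sorted(maxima[-1]):
        ridges.append({"pos": pos, "gap": 0, "points": [(len(rows) - 1, pos)]})
    for r in range(len(rows) - 2, -1, -1):
        avail = sorted(maxima[r])
        taken: set[int] = set()
        for ridge in ridges:
            if ridge["gap"] > 2:
                continue
            window = max(1, int(np.ceil(scales_arr[r] / 2.0)))
            best = None
            for cand in avail:
                if cand in taken or abs(cand - ridge["pos"]) > window:
                    continue
                if best is None or abs(cand - ridge["pos"]) < abs(best - ridge["pos"]):
                    best = cand
            if best is None:
                ridge["gap"] += 1
            else:
                taken.add(best)
                ridge["gap"] = 0
                ridge["pos"] = best
                ridge["points"].append((r, best))
        for cand in avail:
            if cand not in taken:
                ridges.append({"pos": cand, "gap": 0, "points": [(r, cand)]})
    apexes = []
    for ridge in ridges:
        pts = ridge["points"]
        if len(pts) < min_length:
            continue
        coef = max(rows[r][p] for r, p in pts)
        snr = coef / noise if noise > 0 else np.inf
        if snr < min_snr:
            continue
        apexes.append(pts[-1][1])  # smallest scale reached
    return sorted(set(apexes))


def pick_peaks(xic: XIC, params: FeatureParams) -> list[ChromPeak]:
    """CWT (Mexican-hat ridge-line) peak detection on one XIC.

    Apexes come from the wavelet ridge-line/SNR filter; boundaries are
    found by walking from each apex to the nearest valley or zero, and
    the area is the trapezoidal sum of the raw XIC between them.
    Deterministic for fixed input and settings.
    """
    x = xic.intensities
    if x.size == 0 or float(x.max()) <= 0.0:
        return []
    idx = _cwt_ridge_apexes(x, params.cwt_scales, params.cwt_snr)
    peaks: list[ChromPeak] = []
    seen: set[int] = set()
    for i in np.atleast_1d(idx).astype(int):
        # snap to the local maximum (ridge lines can be off by a scan or two)
        lo = max(0, i - 3)
        hi = min(x.size, i + 4)
        apex = lo + int(np.argmax(x[lo:hi]))
        if apex in seen or x[apex] <= 0:
            continue
        seen.add(apex)
        left = apex
        while left > 0 and 0 < x[left - 1] < x[left]:
            left -= 1
        right = apex
        while right < x.size - 1 and 0 < x[right + 1] < x[right]:
            right += 1
        peaks.append(
            ChromPeak(
                apex_scan=apex,
                left_scan=left,
                right_scan=right,
                area=float(np.trapezoid(x[left : right + 1])),
                shape=x[left : right + 1].copy(),
            )
        )
    peaks.sort(key=lambda p: p.apex_scan)
    return peaks


def _window_values(peak: ChromPeak, lo: int, hi: int) -> np.ndarray:
    """Peak shape over scans [lo, hi], zeros outside its boundaries."""
    out = np.zeros(hi - lo + 1)
    a = max(peak.left_scan, lo)
    b = min(peak.right_scan, hi)
    if b >= a:
        out[a - lo : b - lo + 1] = peak.shape[
            a - peak.left_scan : b - peak.left_scan + 1
        ]
    return out


def shape_correlation(a: ChromPeak, b: ChromPeak) -> float:
    """Pearson correlation of two peak shapes over the union of their
    boundary windows, absent scans filled with 0."""
    lo = min(a.left_scan, b.left_scan)
    hi = max(a.right_scan, b.right_scan)
    va = _window_values(a, lo, hi)
    vb = _window_values(b, lo, hi)
    if va.std() == 0 or vb.std() == 0:
        return 0.0
    return float(np.corrcoef(va, vb)[0, 1])


def pair_features(
    cluster: MzCluster,
    run: Run,
    params: FeatureParams,
    xic_ppm: float = 2.5,
) -> list[FeaturePair]:
    """Confirm one m/z cluster chromatographically.

    XICs are extracted at the cluster's monoisotopic m/z and at the
    labelled partner m/z; every M-peak is matched to the nearest M′-peak
    within ``±max_shift_scans`` (ties toward higher M′ area) and kept if
    the Pearson correlation of the two shapes exceeds the threshold.
    """
    mz_m = cluster.mean_mz_m
    mz_mp = mz_m + cluster.n_c * DELTA_C / cluster.z
    xic_m = extract_xic(run, mz_m, xic_ppm)
    xic_mp = extract_xic(run, mz_mp, xic_ppm)
    peaks_m = pick_peaks(xic_m, params)
    peaks_mp = pick_peaks(xic_mp, params)
    if not peaks_m or not peaks_mp:
        return []
    rts = run.rts
    out: list[FeaturePair] = []
    for pm in peaks_m:
        candidates = [
            pp
            for pp in peaks_mp
            if abs(pp.apex_scan - pm.apex_scan) <= params.max_shift_scans
        ]
        if not candidates:
            continue
        best = min(
            candidates,
            key=lambda pp: (abs(pp.apex_scan - pm.apex_scan), -pp.area),
        )
        corr = shape_correlation(pm, best)
        if corr > params.min_peak_corr:
            out.append(
                FeaturePair(
                    mz_m=mz_m,
                    rt_seconds=float(rts[pm.apex_scan]),
                    z=cluster.z,
                    n_c=cluster.n_c,
                    area_m=pm.area,
                    area_mprime=best.area,
                    corr=corr,
                    apex_scan=pm.apex_scan,
                    left_scan=pm.left_scan,
                    right_scan=pm.right_scan,
                    shape_m=pm.shape,
                )
            )
    return out


def deisotope(
    pairs: list[FeaturePair],
    ppm: float = 2.5,
    rt_tol_scans: int = 15,
) -> list[FeaturePair]:
    """Remove feature pairs seeded on M+1 or M′−1 isotopologues.

    A falsely seeded pair shows a reduced carbon count and/or an
    increased monoisotopic m/z relative to the correctly seeded pair of
    the same ion: its "M" lies on the native isotopologue grid of a
    co-eluting pair Q at the same charge (k spacings above Q's
    monoisotopic signal, k ≥ 0) while claiming at least k fewer carbons
    (at least one fewer for k = 0, the M′−1 shadow that shares M but
    pairs it with a lower labelled isotopologue).  Removal is evaluated
    against the original list in a single pass, so the operation is
    idempotent and order-independent.
    """
    kept = []
    for p in pairs:
        shadow = False
        for q in pairs:
            if q is p or q.z != p.z or q.n_c <= p.n_c:
                continue
            if abs(q.apex_scan - p.apex_scan) > rt_tol_scans:
                continue
            spacing = DELTA_C / p.z
            k = round((p.mz_m - q.mz_m) / spacing)
            if k < 0 or p.n_c + max(k, 1) > q.n_c:
                continue
            if abs(p.mz_m - (q.mz_m + k * spacing)) <= ppm * 1e-6 * p.mz_m:
                shadow = True
                break
        if not shadow:
            kept.append(p)
    return kept


def group_features(
    pairs: list[FeaturePair], run: Run, params: FeatureParams
) -> list[FeatureGroup]:
    """Convolute feature pairs into metabolite groups.

    Two pairs are connected iff their M apexes lie within the grouping
    window and their M peak shapes correlate at or above the grouping
    threshold; groups are the connected components, so every pair lands
    in exactly one group.
    """
    n = len(pairs)
    if n == 0:
        return []
    rows, cols = [], []
    chrom = [
        ChromPeak(
            apex_scan=p.apex_scan,
            left_scan=p.left_scan,
            right_scan=p.right_scan,
            area=p.area_m,
            shape=p.shape_m if p.shape_m is not None else np.ones(1),
        )
        for p in pairs
    ]
    for i in range(n):
        for j in range(i + 1, n):
            if abs(pairs[i].apex_scan - pairs[j].apex_scan) > params.group_window_scans:
                continue
            if shape_correlation(chrom[i], chrom[j]) >= params.group_corr:
                rows.append(i)
                cols.append(j)
    graph = coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    n_comp, labels = connected_components(graph, directed=False)
    groups = []
    for g in range(n_comp):
        members = [pairs[i] for i in np.nonzero(labels == g)[0]]
        groups.append(
            FeatureGroup(
                group_id=g,
                members=members,
                representative_rt=float(
                    np.median([m.rt_seconds for m in members])
                ),
            )
        )
    groups.sort(key=lambda grp: grp.representative_rt)
    for new_id, grp in enumerate(groups):
        grp.group_id = new_id
    return groups


def plausibility_flag(pairs: list[FeaturePair]) -> list[FeaturePair]:
    """Annotate chemically implausible pairs (not removed by default).

    A feature pair whose neutral-mass estimate exceeds 700 u while its
    m/z spacing corresponds to fewer than 10 carbon atoms cannot be a
    plausible metabolite ion (too few carbons for so large a molecule)
    and is flagged ``implausible``.
    """
    out = []
    for p in pairs:
        mass = p.mz_m * p.z - p.z * PROTON_MASS
        if mass > 700.0 and p.n_c < 10:
            out.append(replace(p, flags=p.flags + ("implausible",)))
        else:
            out.append(p)
    return out


_FEATURE_COLUMNS = [
    "mz_m", "rt_seconds", "z", "n_c", "area_m", "area_mprime",
    "corr", "apex_scan", "left_scan", "right_scan", "group_id", "flags",
]


def features_to_frame(
    pairs: list[FeaturePair], groups: list[FeatureGroup] | None = None
) -> pd.DataFrame:
    """Feature-pair table in the documented TSV column order."""
    gid = {}
    if groups:
        for grp in groups:
            for m in grp.members:
                gid[id(m)] = grp.group_id
    return pd.DataFrame(
        [
            {
                "mz_m": p.mz_m,
                "rt_seconds": p.rt_seconds,
                "z": p.z,
                "n_c": p.n_c,
                "area_m": p.area_m,
                "area_mprime": p.area_mprime,
                "corr": p.corr,
                "apex_scan": p.apex_scan,
                "left_scan": p.left_scan,
                "right_scan": p.right_scan,
                "group_id": gid.get(id(p), -1),
                "flags": ";".join(p.flags),
            }
            for p in pairs
        ],
        columns=_FEATURE_COLUMNS,
    )


def features_from_frame(frame: pd.DataFrame) -> list[FeaturePair]:
    """Rebuild feature pairs from a TSV table (shapes are not stored)."""
    out = []
    for row in frame.itertuples(index=False):
        flags = getattr(row, "flags", "")
        flags = tuple(str(flags).split(";")) if isinstance(flags, str) and flags else ()
        out.append(
            FeaturePair(
                mz_m=float(row.mz_m),
                rt_seconds=float(row.rt_seconds),
                z=int(row.z),
                n_c=int(row.n_c),
                area_m=float(row.area_m),
                area_mprime=float(row.area_mprime),
                corr=float(row.corr),
                apex_scan=int(row.apex_scan),
                left_scan=int(row.left_scan),
                right_scan=int(row.right_scan),
                flags=flags,
            )
        )
    return out
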