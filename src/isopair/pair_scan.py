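"""Scan-wise detection of ¹²C/U-¹³C MS signal pairs and m/z clustering.

Every centroid MS¹ scan is searched for the SIL-specific four-signal
pattern: a monoisotopic native signal M, its first heavy isotopologue
M+1, the fully labelled partner M′ = M + n_C·1.00335/z and its residual
isotopologue M′−1.  A candidate (M, M′) at charge z and carbon count n_C
is accepted only if both principal signals exceed the intensity
threshold, the M+1/M ratio matches the natural first-order binomial
expectation and the M′−1/M′ ratio matches the enriched one, each within
a relative abundance tolerance.  The charge state is thereby deduced
from the isotopologue spacing itself.

Accepted scan-level pairs of one run are then clustered on m/z —
hierarchical average linkage per (n_C, z), split top-down wherever a
cluster spans more than ±10 ppm — so that redundant detections of one
chromatographic peak collapse into one m/z cluster.  Clusters seen in
fewer than ``min_scans`` distinct scans are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree

from .isotope_math import DELTA_C, EnrichmentModel
from .mz_io import Run, Spectrum

__all__ = [
    "PairParams",
    "SignalPair",
    "MzCluster",
    "detect_signal_pairs",
    "detect_run_pairs",
    "cluster_pairs",
    "pairs_to_frame",
]


@dataclass(frozen=True)
class PairParams:
    """Scan-level pair-detection settings (defaults: the validated
    Orbitrap workflow values)."""

    min_intensity: float = 5000.0       # counts, on both M and M′
    min_scans: int = 3                  # scans a pair must recur in
    ppm: float = 2.5                    # m/z matching tolerance
    abundance_tol: float = 0.20         # relative isotopologue-ratio error
    z_range: tuple[int, ...] = (1, 2, 3)
    nc_range: tuple[int, int] = (1, 60)
    cluster_ppm: float = 10.0           # m/z cluster split width
    enrichment: EnrichmentModel = field(default_factory=EnrichmentModel)

    def __post_init__(self) -> None:
        if self.min_scans < 1 or self.ppm <= 0 or self.abundance_tol <= 0:
            raise ValueError("invalid PairParams")


@dataclass(frozen=True)
class SignalPair:
    """One scan-level M/M′ detection annotated with z and n_C."""

    scan_index: int
    rt_seconds: float
    mz_m: float
    mz_mprime: float
    intensity_m: float
    intensity_m1: float
    intensity_mprime: float
    intensity_mprime_minus1: float
    z: int
    n_c: int


@dataclass
class MzCluster:
    """Redundant scan-level detections of one metabolite ion."""

    n_c: int
    z: int
    mean_mz_m: float
    member_pairs: list[SignalPair]

    @property
    def n_scans(self) -> int:
        return len({p.scan_index for p in self.member_pairs})


def _nearest_within(
    mz: np.ndarray, targets: np.ndarray, ppm: float
) -> np.ndarray:
    """Index of the peak nearest each target within ±ppm, else -1."""
    idx = np.searchsorted(mz, targets)
    left = np.clip(idx - 1, 0, mz.size - 1)
    right = np.clip(idx, 0, mz.size - 1)
    d_left = np.abs(mz[left] - targets)
    d_right = np.abs(mz[right] - targets)
    best = np.where(d_right < d_left, right, left)
    ok = np.abs(mz[best] - targets) <= ppm * 1e-6 * targets
    return np.where(ok, best, -1)


def _ratio_ok(observed: np.ndarray, expected: np.ndarray, tol: float):
    """Relative abundance band: observed/expected in [1−tol, 1/(1−tol)]."""
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = observed / expected
    return (rel >= 1.0 - tol) & (rel <= 1.0 / (1.0 - tol))


def detect_signal_pairs(
    spectrum: Spectrum, params: PairParams
) -> list[SignalPair]:
    """All validated M/M′ signal pairs in one centroid scan.

    For each peak M above the intensity threshold, each charge and each
    carbon count in range, the pair is emitted iff (a) M′ exists at the
    expected spacing with sufficient intensity, (b) M+1 is present with
    a natural-abundance-consistent ratio to M, and (c) M′−1 is present
    with an enrichment-consistent ratio to M′.  A pair of physical peaks
    validating at several charges is reported at the smallest one.
    """
    mz, inten = spectrum.mz, spectrum.intensity
    if mz.size < 4:
        return []
    seeds = np.nonzero(inten >= params.min_intensity)[0]
    if seeds.size == 0:
        return []
    n_lo, n_hi = params.nc_range
    ns = np.arange(n_lo, n_hi + 1)
    p_nat = params.enrichment.p_natural
    p_enr = params.enrichment.p_enriched
    exp_m1 = ns * p_nat / (1.0 - p_nat)
    exp_mp1 = ns * (1.0 - p_enr) / p_enr
    found: dict[tuple[int, int], SignalPair] = {}
    for z in sorted(params.z_range):
        spacing = DELTA_C / z
        mz_m = mz[seeds]
        # (a) fully labelled partner at n·Δ/z
        targets = mz_m[:, None] + ns[None, :] * spacing
        mp_idx = _nearest_within(mz, targets.ravel(), params.ppm).reshape(
            targets.shape
        )
        cand_s, cand_n = np.nonzero(
            (mp_idx >= 0)
            & np.where(mp_idx >= 0, inten[mp_idx] >= params.min_intensity, False)
        )
        if cand_s.size == 0:
            continue
        si = seeds[cand_s]
        mpi = mp_idx[cand_s, cand_n]
        # (b) natural M+1 present with valid ratio to M
        m1_idx = _nearest_within(mz, mz[si] + spacing, params.ppm)
        ok = m1_idx >= 0
        m1_ratio = np.where(ok, inten[m1_idx] / inten[si], np.nan)
        ok &= _ratio_ok(m1_ratio, exp_m1[cand_n], params.abundance_tol)
        # (c) enriched M′−1 present with valid ratio to M′
        mp1_idx = _nearest_within(mz, mz[mpi] - spacing, params.ppm)
        ok &= mp1_idx >= 0
        mp1_ratio = np.where(
            mp1_idx >= 0, inten[mp1_idx] / inten[mpi], np.nan
        )
        ok &= _ratio_ok(mp1_ratio, exp_mp1[cand_n], params.abundance_tol)
        for j in np.nonzero(ok)[0]:
            key = (int(si[j]), int(mpi[j]))
            if key in found:        # smaller z seen first
                continue
            found[key] = SignalPair(
                scan_index=spectrum.scan_index,
                rt_seconds=spectrum.rt_seconds,
                mz_m=float(mz[si[j]]),
                mz_mprime=float(mz[mpi[j]]),
                intensity_m=float(inten[si[j]]),
                intensity_m1=float(inten[m1_idx[j]]),
                intensity_mprime=float(inten[mpi[j]]),
                intensity_mprime_minus1=float(inten[mp1_idx[j]]),
                z=z,
                n_c=int(ns[cand_n[j]]),
            )
    return sorted(found.values(), key=lambda p: (p.mz_m, p.z, p.n_c))


def detect_run_pairs(run: Run, params: PairParams) -> list[SignalPair]:
    """Scan-level detection over a whole run (concatenated per scan)."""
    out: list[SignalPair] = []
    for spectrum in run:
        out.extend(detect_signal_pairs(spectrum, params))
    return out


def _split_node(node, values: np.ndarray, max_ppm: float) -> list[list[int]]:
    members = node.pre_order(lambda leaf: leaf.id)
    vals = values[members]
    mean = vals.mean()
    if np.all(np.abs(vals - mean) <= max_ppm * 1e-6 * mean):
        return [members]
    return _split_node(node.left, values, max_ppm) + _split_node(
        node.right, values, max_ppm
    )


def cluster_pairs(
    pairs: list[SignalPair],
    max_ppm: float = 10.0,
    min_scans: int = 3,
) -> list[MzCluster]:
    """Group redundant scan-level pairs into per-(n_C, z) m/z clusters.

    Average-linkage hierarchical clustering of the monoisotopic m/z
    values, partitioned by exact (n_C, z) first; the tree is cut
    top-down, splitting every node whose members deviate more than
    ``±max_ppm`` from the node mean.  Clusters covering fewer than
    ``min_scans`` distinct scans are discarded.
    """
    by_key: dict[tuple[int, int], list[SignalPair]] = {}
    for p in pairs:
        by_key.setdefault((p.n_c, p.z), []).append(p)
    clusters: list[MzCluster] = []
    for (n_c, z), group in sorted(by_key.items()):
        values = np.array([p.mz_m for p in group])
        if len(group) == 1:
            parts = [[0]]
        else:
            tree = to_tree(linkage(values[:, None], method="average"))
            parts = _split_node(tree, values, max_ppm)
        for members in parts:
            sub = [group[i] for i in members]
            if len({p.scan_index for p in sub}) < min_scans:
                continue
            clusters.append(
                MzCluster(
                    n_c=n_c,
                    z=z,
                    mean_mz_m=float(values[members].mean()),
                    member_pairs=sorted(sub, key=lambda p: p.scan_index),
                )
            )
    clusters.sort(key=lambda c: (c.mean_mz_m, c.n_c, c.z))
    return clusters


def pairs_to_frame(pairs: list[SignalPair]) -> pd.DataFrame:
    """Scan-level pair table in the documented TSV column order."""
    return pd.DataFrame(
        [
            {
                "scan": p.scan_index,
                "rt_seconds": p.rt_seconds,
                "mz_m": p.mz_m,
                "mz_mprime": p.mz_mprime,
                "z": p.z,
                "n_c": p.n_c,
                "intensity_m": p.intensity_m,
                "intensity_m1": p.intensity_m1,
                "intensity_mprime": p.intensity_mprime,
                "intensity_mprime_minus1": p.intensity_mprime_minus1,
            }
            for p in pairs
        ],
        columns=[
            "scan", "rt_seconds", "mz_m", "mz_mprime", "z", "n_c",
            "intensity_m", "intensity_m1", "intensity_mprime",
            "intensity_mprime_minus1",
        ],
    )
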