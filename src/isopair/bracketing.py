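"""Cross-sample bracketing of feature pairs and targeted re-integration.

Feature pairs detected independently per run are matched into one data
matrix: two detections belong to the same bracketed feature when they
agree on carbon count (exactly), m/z (within ppm) and retention time
(within a tolerance), compared in that order.  Matching is greedy with
the strongest feature (largest total area) as anchor, which makes it
deterministic and independent of sample order.

Features missed in some runs by the restrictive pair-filtering criteria
are then searched for in a targeted way: peaks are picked in the M and
M′ XICs around the consensus retention time and integrated without
re-checking isotopologue abundances or peak-shape similarity.  Nothing
is imputed — a feature with no signal stays absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_extract import FeatureParams, FeaturePair, pick_peaks
from .isotope_math import DELTA_C
from .mz_io import Run, extract_xic

__all__ = [
    "BracketParams",
    "SampleEntry",
    "BracketedFeature",
    "bracket",
    "reintegrate",
    "reintegrate_all",
    "matrix_to_frame",
]


@dataclass(frozen=True)
class BracketParams:
    """Cross-sample matching tolerances."""

    ppm: float = 10.0               # m/z tolerance
    rt_tol_seconds: float = 9.0     # retention-time tolerance (0.15 min)

    def __post_init__(self) -> None:
        if self.ppm <= 0 or self.rt_tol_seconds <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class SampleEntry:
    area_m: float | None
    area_mprime: float | None
    found_by: str                   # detected | reintegrated | absent


@dataclass
class BracketedFeature:
    """One feature pair tracked over all samples."""

    consensus_mz_m: float
    consensus_rt: float
    n_c: int
    z: int
    per_sample: dict[str, SampleEntry] = field(default_factory=dict)

    @property
    def mz_mprime(self) -> float:
        return self.consensus_mz_m + self.n_c * DELTA_C / self.z


def bracket(
    per_sample_pairs: dict[str, list[FeaturePair]],
    params: BracketParams | None = None,
) -> list[BracketedFeature]:
    """Match feature pairs across samples into bracketed features.

    Greedy: the unassigned pair with the largest total area anchors a
    bracket; per other sample the closest unassigned pair agreeing on
    (n_C, z) exactly and lying within the m/z and Rt tolerances joins
    it.  Consensus m/z and Rt are intensity-weighted means of the
    members.  Pairs with conflicting (n_C, z) are never merged.
    """
    params = params or BracketParams()
    if not per_sample_pairs:
        raise ValueError("at least one sample required")
    entries = [
        (sample, p)
        for sample, pairs in sorted(per_sample_pairs.items())
        for p in pairs
    ]
    order = sorted(
        range(len(entries)),
        key=lambda i: -(entries[i][1].area_m + entries[i][1].area_mprime),
    )
    assigned = [False] * len(entries)
    brackets: list[BracketedFeature] = []
    for i in order:
        if assigned[i]:
            continue
        anchor_sample, anchor = entries[i]
        members: dict[str, tuple[int, FeaturePair]] = {anchor_sample: (i, anchor)}
        for j, (sample, p) in enumerate(entries):
            if assigned[j] or j == i or sample in members:
                continue
            if p.n_c != anchor.n_c or p.z != anchor.z:
                continue
            if abs(p.mz_m - anchor.mz_m) > params.ppm * 1e-6 * anchor.mz_m:
                continue
            if abs(p.rt_seconds - anchor.rt_seconds) > params.rt_tol_seconds:
                continue
            cur = members.get(sample)
            if cur is None or abs(p.mz_m - anchor.mz_m) < abs(
                cur[1].mz_m - anchor.mz_m
            ):
                members[sample] = (j, p)
        weights = np.array(
            [m.area_m + m.area_mprime for _, m in members.values()]
        )
        mzs = np.array([m.mz_m for _, m in members.values()])
        rts = np.array([m.rt_seconds for _, m in members.values()])
        feat = BracketedFeature(
            consensus_mz_m=float(np.average(mzs, weights=weights)),
            consensus_rt=float(np.average(rts, weights=weights)),
            n_c=anchor.n_c,
            z=anchor.z,
        )
        for sample, (j, p) in members.items():
            assigned[j] = True
            feat.per_sample[sample] = SampleEntry(
                area_m=p.area_m, area_mprime=p.area_mprime, found_by="detected"
            )
        brackets.append(feat)
    for feat in brackets:
        for sample in per_sample_pairs:
            feat.per_sample.setdefault(
                sample, SampleEntry(None, None, "absent")
            )
    brackets.sort(key=lambda b: (b.consensus_rt, b.consensus_mz_m))
    return brackets


def _targeted_area(
    run: Run,
    mz: float,
    rt_center: float,
    params: BracketParams,
    feature_params: FeatureParams,
    xic_ppm: float,
):
    xic = extract_xic(run, mz, xic_ppm)
    rts = run.rts
    best = None
    for peak in pick_peaks(xic, feature_params):
        drt = abs(rts[peak.apex_scan] - rt_center)
        if drt <= params.rt_tol_seconds and (best is None or drt < best[0]):
            best = (drt, peak)
    return best[1] if best else None


def reintegrate(
    run: Run,
    bracket_feature: BracketedFeature,
    params: BracketParams | None = None,
    feature_params: FeatureParams | None = None,
    xic_ppm: float = 2.5,
) -> tuple[float | None, float | None]:
    """Targeted integration of one bracketed feature in one run.

    Peaks are picked in the M and M′ XICs within the Rt tolerance of the
    consensus retention time; abundance-ratio and shape checks are not
    applied, but the M/M′ co-elution window is still enforced when both
    peaks are found.  Missing signals return ``None`` (no imputation).
    """
    params = params or BracketParams()
    feature_params = feature_params or FeatureParams()
    pm = _targeted_area(
        run, bracket_feature.consensus_mz_m,
        bracket_feature.consensus_rt, params, feature_params, xic_ppm,
    )
    pp = _targeted_area(
        run, bracket_feature.mz_mprime,
        bracket_feature.consensus_rt, params, feature_params, xic_ppm,
    )
    if pm is not None and pp is not None:
        if abs(pm.apex_scan - pp.apex_scan) > feature_params.max_shift_scans:
            pp = None
    return (
        pm.area if pm is not None else None,
        pp.area if pp is not None else None,
    )


def reintegrate_all(
    runs: dict[str, Run],
    brackets: list[BracketedFeature],
    params: BracketParams | None = None,
    feature_params: FeatureParams | None = None,
    xic_ppm: float = 2.5,
) -> None:
    """Fill absent cells of the data matrix by targeted integration."""
    for feat in brackets:
        for sample, entry in feat.per_sample.items():
            if entry.found_by != "absent" or sample not in runs:
                continue
            area_m, area_mp = reintegrate(
                runs[sample], feat, params, feature_params, xic_ppm
            )
            if area_m is not None or area_mp is not None:
                entry.area_m = area_m
                entry.area_mprime = area_mp
                entry.found_by = "reintegrated"


def matrix_to_frame(
    brackets: list[BracketedFeature], samples: list[str] | None = None
) -> pd.DataFrame:
    """Data-matrix TSV layout: one row per bracketed feature, paired
    area columns and a found_by status column per sample."""
    if samples is None:
        seen: dict[str, None] = {}
        for b in brackets:
            for s in b.per_sample:
                seen.setdefault(s)
        samples = sorted(seen)
    rows = []
    for b in brackets:
        row: dict = {
            "mz_m": b.consensus_mz_m,
            "rt_seconds": b.consensus_rt,
            "n_c": b.n_c,
            "z": b.z,
        }
        for s in samples:
            e = b.per_sample.get(s, SampleEntry(None, None, "absent"))
            row[f"area_m:{s}"] = e.area_m
            row[f"area_mprime:{s}"] = e.area_mprime
            row[f"found_by:{s}"] = e.found_by
        rows.append(row)
    cols = ["mz_m", "rt_seconds", "n_c", "z"] + [
        f"{k}:{s}" for s in samples for k in ("area_m", "area_mprime", "found_by")
    ]
    return pd.DataFrame(rows, columns=cols)
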