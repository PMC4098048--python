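"""Per-file workflow wiring: scans → signal pairs → clusters → feature
pairs → de-isotoped pairs → feature groups.

This is the single-run composition used by the CLI and the test suite;
every stage is an operation of the corresponding module and the stage
counts are returned for logging (the per-file data-reduction cascade).
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import PipelineConfig
from .feature_extract import (
    FeatureGroup,
    FeaturePair,
    deisotope,
    group_features,
    pair_features,
    plausibility_flag,
)
from .mz_io import Run
from .pair_scan import MzCluster, SignalPair, cluster_pairs, detect_run_pairs

__all__ = ["StageCounts", "DetectionResult", "detect_features"]


@dataclass
class StageCounts:
    ms_signals: int
    signal_pairs: int
    clusters: int
    feature_pairs: int
    deisotoped: int
    groups: int


@dataclass
class DetectionResult:
    signal_pairs: list[SignalPair]
    clusters: list[MzCluster]
    feature_pairs: list[FeaturePair]
    groups: list[FeatureGroup]
    counts: StageCounts


def detect_features(run: Run, config: PipelineConfig | None = None) -> DetectionResult:
    """Run the full per-file detection cascade on one centroid run."""
    config = config or PipelineConfig()
    signal_pairs = detect_run_pairs(run, config.pair)
    clusters = cluster_pairs(
        signal_pairs,
        max_ppm=config.pair.cluster_ppm,
        min_scans=config.pair.min_scans,
    )
    pairs: list[FeaturePair] = []
    for cluster in clusters:
        pairs.extend(
            pair_features(cluster, run, config.feature, xic_ppm=config.pair.ppm)
        )
    deiso = deisotope(
        pairs,
        ppm=config.pair.ppm,
        rt_tol_scans=config.feature.deisotope_rt_tol_scans,
    )
    deiso = plausibility_flag(deiso)
    groups = group_features(deiso, run, config.feature)
    counts = StageCounts(
        ms_signals=sum(len(s) for s in run),
        signal_pairs=len(signal_pairs),
        clusters=len(clusters),
        feature_pairs=len(pairs),
        deisotoped=len(deiso),
        groups=len(groups),
    )
    return DetectionResult(
        signal_pairs=signal_pairs,
        clusters=clusters,
        feature_pairs=deiso,
        groups=groups,
        counts=counts,
    )
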