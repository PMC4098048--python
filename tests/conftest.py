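import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from isopair.isotope_math import (
    DELTA_C,
    expected_m1_ratio,
    expected_mprime_minus1_ratio,
)
from isopair.mz_io import Run, Spectrum

# the worked single-spectrum example: a 30-carbon metabolite (neutral
# monoisotopic mass 624.3827 u) observed as [M+H]+ in a 1:1 native/labelled
# mixture at 99.5 % enrichment
FIG_MZ_M = 625.38998
FIG_MZ_MPRIME = 655.49048
FIG_NC = 30
FIG_P_ENR = 0.995
FIG_P_NAT = 0.0111


def pair_spectrum(
    intensity_m: float = 1e6,
    intensity_mprime: float = 1e6,
    m1_scale: float = 1.0,
    drop: tuple[str, ...] = (),
    scan_index: int = 0,
    rt: float = 60.0,
) -> Spectrum:
    """Four-signal SIL pattern (M, M+1, M′−1, M′) at binomial ratios."""
    peaks = {
        "m": (FIG_MZ_M, intensity_m),
        "m1": (
            FIG_MZ_M + DELTA_C,
            intensity_m * expected_m1_ratio(FIG_NC, FIG_P_NAT) * m1_scale,
        ),
        "mp1": (
            FIG_MZ_MPRIME - DELTA_C,
            intensity_mprime * expected_mprime_minus1_ratio(FIG_NC, FIG_P_ENR),
        ),
        "mp": (FIG_MZ_MPRIME, intensity_mprime),
    }
    kept = sorted(v for k, v in peaks.items() if k not in drop)
    return Spectrum(
        scan_index=scan_index,
        rt_seconds=rt,
        mz=np.array([p[0] for p in kept]),
        intensity=np.array([p[1] for p in kept]),
    )


@pytest.fixture
def fig_spectrum() -> Spectrum:
    return pair_spectrum()


def gaussian_run(
    traces: list[tuple[float, float, int, float]], n_scans: int = 200
) -> Run:
    """Run with Gaussian XIC traces: (mz, height, apex_scan, sigma_scans)."""
    spectra = []
    s = np.arange(n_scans)
    for i in range(n_scans):
        mzs, intens = [], []
        for mz, height, apex, sigma in traces:
            v = height * np.exp(-((i - apex) ** 2) / (2 * sigma**2))
            if v >= 1.0:
                mzs.append(mz)
                intens.append(v)
        order = np.argsort(mzs)
        spectra.append(
            Spectrum(
                scan_index=i,
                rt_seconds=float(i + 1),
                mz=np.array(mzs)[order] if mzs else np.empty(0),
                intensity=np.array(intens)[order] if mzs else np.empty(0),
            )
        )
    return Run(spectra=spectra)
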