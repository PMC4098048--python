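import numpy as np
import pytest

from isopair.feature_extract import (
    FeatureParams,
    FeaturePair,
    deisotope,
    group_features,
    pair_features,
    pick_peaks,
    plausibility_flag,
)
from isopair.isotope_math import DELTA_C
from isopair.mz_io import XIC
from isopair.pair_scan import MzCluster

from .conftest import gaussian_run


def _xic(values):
    return XIC(target_mz=500.0, ppm_window=2.5, intensities=np.asarray(values, float))


def _gauss(n, apex, sigma, height=1e6):
    s = np.arange(n)
    x = height * np.exp(-((s - apex) ** 2) / (2 * sigma**2))
    x[x < 1.0] = 0.0
    return x


def _pair(mz_m, n_c, apex, z=1, sigma=4.0, n_scans=200, area=1e6):
    shape = _gauss(41, 20, sigma)[_gauss(41, 20, sigma) > 0]
    left = apex - len(shape) // 2
    return FeaturePair(
        mz_m=mz_m,
        rt_seconds=float(apex + 1),
        z=z,
        n_c=n_c,
        area_m=area,
        area_mprime=area,
        corr=1.0,
        apex_scan=apex,
        left_scan=left,
        right_scan=left + len(shape) - 1,
        shape_m=shape,
    )


class TestPickPeaks:
    def test_single_gaussian(self):
        peaks = pick_peaks(_xic(_gauss(200, 50, 4.0)), FeatureParams())
        assert len(peaks) == 1
        assert abs(peaks[0].apex_scan - 50) <= 1
        assert peaks[0].left_scan < 50 < peaks[0].right_scan
        # trapezoidal area of a Gaussian ~ height * sigma * sqrt(2 pi)
        assert peaks[0].area == pytest.approx(1e6 * 4 * np.sqrt(2 * np.pi), rel=0.02)

    def test_all_zero(self):
        assert pick_peaks(_xic(np.zeros(100)), FeatureParams()) == []

    def test_two_separated_gaussians(self):
        x = _gauss(200, 60, 4.0) + _gauss(200, 100, 4.0, height=5e5)
        peaks = pick_peaks(_xic(x), FeatureParams())
        assert len(peaks) == 2
        assert abs(peaks[0].apex_scan - 60) <= 1
        assert abs(peaks[1].apex_scan - 100) <= 1

    def test_deterministic(self):
        x = _gauss(300, 80, 3.0) + _gauss(300, 150, 5.0)
        a = pick_peaks(_xic(x), FeatureParams())
        b = pick_peaks(_xic(x), FeatureParams())
        assert [(p.apex_scan, p.left_scan, p.right_scan) for p in a] == [
            (p.apex_scan, p.left_scan, p.right_scan) for p in b
        ]


class TestPairFeatures:
    def _cluster(self, mz=500.0, n_c=30, z=1):
        return MzCluster(n_c=n_c, z=z, mean_mz_m=mz, member_pairs=[])

    def test_identical_gaussians_pair(self):
        mz_m = 500.0
        mz_mp = mz_m + 30 * DELTA_C
        run = gaussian_run([(mz_m, 1e6, 50, 4.0), (mz_mp, 1e6, 50, 4.0)])
        pairs = pair_features(self._cluster(), run, FeatureParams())
        assert len(pairs) == 1
        assert pairs[0].corr == pytest.approx(1.0, abs=1e-9)
        assert pairs[0].area_m == pytest.approx(pairs[0].area_mprime, rel=1e-6)

    def test_shift_beyond_window_rejected(self):
        mz_m = 500.0
        mz_mp = mz_m + 30 * DELTA_C
        run = gaussian_run([(mz_m, 1e6, 50, 4.0), (mz_mp, 1e6, 70, 4.0)])
        assert pair_features(self._cluster(), run, FeatureParams()) == []

    def test_noise_partner_rejected(self):
        # M is a clean peak; the labelled trace is flat noise: either no
        # peak survives the ridge filter or its shape correlation is low
        rng = np.random.default_rng(123)
        mz_m = 500.0
        mz_mp = mz_m + 30 * DELTA_C
        run = gaussian_run([(mz_m, 1e6, 50, 4.0)])
        for spec in run:
            spec.mz = np.append(spec.mz, mz_mp)
            spec.intensity = np.append(spec.intensity, rng.uniform(10, 100))
        assert pair_features(self._cluster(), run, FeatureParams()) == []


class TestDeisotope:
    def test_m1_shadow_removed(self):
        p1 = _pair(625.38998, 30, 50)
        p2 = _pair(625.38998 + DELTA_C, 29, 50)
        kept = deisotope([p1, p2])
        assert kept == [p1]

    def test_mprime_minus1_shadow_removed(self):
        p1 = _pair(625.38998, 30, 50)
        p3 = _pair(625.38998, 29, 50)
        assert deisotope([p1, p3]) == [p1]

    def test_single_pair_unchanged(self):
        p = _pair(625.38998, 30, 50)
        assert deisotope([p]) == [p]

    def test_non_coeluting_kept(self):
        p1 = _pair(625.38998, 30, 50)
        p2 = _pair(625.38998 + DELTA_C, 29, 120)
        assert deisotope([p1, p2]) == [p1, p2]

    def test_higher_isotopologue_shadow_removed(self):
        # shadow seeded on M+2 with a carbon count four lower
        p1 = _pair(625.38998, 30, 50)
        p4 = _pair(625.38998 + 2 * DELTA_C, 26, 50)
        assert deisotope([p1, p4]) == [p1]

    def test_idempotent(self):
        pairs = [
            _pair(625.38998, 30, 50),
            _pair(625.38998 + DELTA_C, 29, 50),
            _pair(700.0, 20, 90),
            _pair(700.0, 19, 90),
        ]
        once = deisotope(pairs)
        twice = deisotope(once)
        assert once == twice


class TestGroupFeatures:
    def test_adducts_of_one_metabolite_grouped(self):
        run = gaussian_run([])
        pairs = [
            _pair(500.0, 30, 50),
            _pair(522.0, 30, 50),
            _pair(482.0, 30, 50),
        ]
        groups = group_features(pairs, run, FeatureParams())
        assert len(groups) == 1
        assert len(groups[0].members) == 3

    def test_separated_metabolites_not_grouped(self):
        run = gaussian_run([])
        pairs = [_pair(500.0, 30, 50), _pair(600.0, 20, 150)]
        groups = group_features(pairs, run, FeatureParams())
        assert len(groups) == 2

    def test_anticorrelated_coeluting_not_grouped(self):
        run = gaussian_run([])
        a = _pair(500.0, 30, 50)
        down = np.linspace(1e6, 1.0, a.right_scan - a.left_scan + 1)
        b = FeaturePair(
            mz_m=600.0, rt_seconds=51.0, z=1, n_c=20,
            area_m=1e6, area_mprime=1e6, corr=1.0,
            apex_scan=50, left_scan=a.left_scan, right_scan=a.right_scan,
            shape_m=down,
        )
        groups = group_features([a, b], run, FeatureParams())
        assert len(groups) == 2

    def test_partition(self):
        run = gaussian_run([])
        rng = np.random.default_rng(7)
        pairs = [
            _pair(400.0 + i, 10 + i, int(rng.integers(30, 170)))
            for i in range(15)
        ]
        groups = group_features(pairs, run, FeatureParams())
        seen = [id(m) for g in groups for m in g.members]
        assert sorted(seen) == sorted(id(p) for p in pairs)
        assert len(seen) == len(set(seen))

    def test_empty(self):
        assert group_features([], gaussian_run([]), FeatureParams()) == []


class TestPlausibilityFlag:
    @pytest.mark.parametrize(
        "mz, n_c, flagged",
        [
            (751.5073, 5, True),    # ~750.5 u with < 10 carbons
            (751.5073, 30, False),
            (301.0073, 5, False),
        ],
    )
    def test_rule(self, mz, n_c, flagged):
        (out,) = plausibility_flag([_pair(mz, n_c, 50)])
        assert ("implausible" in out.flags) is flagged
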