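import numpy as np
import pandas as pd
import pytest

from isopair.bracketing import BracketedFeature, SampleEntry
from isopair.quantify import (
    areas_frame,
    cv_summary,
    internal_standardise,
    pca,
    range_scale,
)


def _bracket_with(cells):
    """cells: sample -> (area_m, area_mprime)."""
    b = BracketedFeature(consensus_mz_m=500.0, consensus_rt=100.0, n_c=12, z=1)
    for s, (am, amp) in cells.items():
        b.per_sample[s] = SampleEntry(am, amp, "detected")
    return b


class TestInternalStandardise:
    def test_examples(self):
        b = _bracket_with({"a": (1e6, 5e5), "b": (5e5, 5e5), "c": (1e5, None)})
        rm = internal_standardise([b], ["a", "b", "c"])
        assert rm.values.loc[0, "a"] == pytest.approx(2.0)
        assert rm.values.loc[0, "b"] == pytest.approx(1.0)
        assert np.isnan(rm.values.loc[0, "c"])

    def test_zero_labelled_area_undefined(self):
        b = _bracket_with({"a": (1e6, 0.0)})
        rm = internal_standardise([b], ["a"])
        assert np.isnan(rm.values.loc[0, "a"])

    def test_matrix_effect_cancellation(self):
        """Multiplying one sample's M and M′ areas by any c > 0 leaves its
        ratio column unchanged — the mechanism of the IS correction."""
        b1 = _bracket_with({"a": (1e6, 4e5), "b": (2e6, 8e5)})
        b2 = _bracket_with({"a": (3e5, 3e5), "b": (9e5, 4e5)})
        before = internal_standardise([b1, b2], ["a", "b"]).values
        c = 3.7
        for b in (b1, b2):
            e = b.per_sample["a"]
            e.area_m *= c
            e.area_mprime *= c
        after = internal_standardise([b1, b2], ["a", "b"]).values
        pd.testing.assert_frame_equal(before, after)


class TestCvSummary:
    def test_example_ten_percent(self):
        s = cv_summary(np.array([[100.0, 110.0, 90.0]]))
        assert s.median_cv == pytest.approx(10.0)
        assert s.n_features == 1

    def test_constant_is_zero(self):
        s = cv_summary(np.array([[5.0, 5.0, 5.0]]))
        assert s.median_cv == 0.0

    def test_overflow_bin(self):
        # CV ~171 %: capped into the final (115-120) bin
        arr = np.array([[1.0, 1.0, 300.0]])
        s = cv_summary(arr)
        assert s.counts[-1] == 1
        assert s.counts.sum() == s.n_features == 1

    def test_counts_conserved_and_incomplete_rows_dropped(self):
        rng = np.random.default_rng(0)
        arr = rng.uniform(50, 150, size=(40, 5))
        arr[3, 2] = np.nan
        s = cv_summary(arr)
        assert s.counts.sum() == s.n_features == 39

    def test_too_few_replicates(self):
        with pytest.raises(ValueError):
            cv_summary(np.array([[1.0]]))


class TestRangeScale:
    def test_example(self):
        out = range_scale(pd.DataFrame([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.values[0], [-0.5, 0.0, 0.5])

    def test_constant_row_dropped_with_warning(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]])
        with pytest.warns(UserWarning, match="constant"):
            out = range_scale(df)
        assert len(out) == 1

    def test_bounded(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(30, 8)) * rng.uniform(1, 100, (30, 1)))
        out = range_scale(df)
        assert (out.values >= -1.0).all() and (out.values <= 1.0).all()


class TestPca:
    def test_perfectly_correlated_features(self):
        df = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0]],
            columns=list("abcd"),
        )
        res = pca(range_scale(df))
        assert res.explained_pct[0] == pytest.approx(100.0)

    def test_variance_ordering(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(20, 6)), columns=list("abcdef"))
        res = pca(range_scale(df), n_components=5)
        ev = res.explained_pct
        assert np.all(np.diff(ev) <= 1e-9)
        assert ev.sum() <= 100.0 + 1e-9

    def test_matches_sklearn(self):
        """Independent cross-check of scores against scikit-learn's PCA."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(15, 7)), columns=[f"s{i}" for i in range(7)])
        scaled = range_scale(df)
        ours = pca(scaled, n_components=2)
        ref = sklearn.PCA(n_components=2).fit(scaled.values.T)
        np.testing.assert_allclose(
            np.abs(ours.scores.values),
            np.abs(ref.transform(scaled.values.T)),
            atol=1e-8,
        )

    def test_group_separation_and_ellipses(self):
        rng = np.random.default_rng(11)
        n_feat = 25
        a = rng.normal(0.0, 0.05, size=(n_feat, 4))
        b = rng.normal(1.0, 0.05, size=(n_feat, 4))
        df = pd.DataFrame(
            np.hstack([a, b]),
            columns=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)],
        )
        groups = {c: c[0] for c in df.columns}
        res = pca(range_scale(df), groups)
        pc1 = res.scores["PC1"]
        ga = pc1[[c for c in df.columns if c.startswith("a")]]
        gb = pc1[[c for c in df.columns if c.startswith("b")]]
        assert ga.max() < gb.min() or gb.max() < ga.min()
        assert set(res.ellipses) == {"a", "b"}
        ell = res.ellipses["a"]
        assert ell.width >= ell.height >= 0.0

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            pca(pd.DataFrame([[1.0, 2.0]]))


def test_areas_frame_missing_cells():
    b = _bracket_with({"a": (1e6, 4e5)})
    b.per_sample["b"] = SampleEntry(None, None, "absent")
    m = areas_frame([b], ["a", "b"], "m")
    assert m.loc[0, "a"] == 1e6
    assert np.isnan(m.loc[0, "b"])
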