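import math

import numpy as np
import pandas as pd
import pytest

import stfusion as sf


def _matrix_with_library_sizes(libs, n_genes=1):
    """One-gene matrix whose library sizes are exactly ``libs``."""
    counts = pd.DataFrame(
        {f"g{j}": [int(v) if j == 0 else 0 for v in libs] for j in range(n_genes)},
        index=[f"{i + 1}x1" for i in range(len(libs))],
    )
    return sf.CountMatrix(counts=counts, sample="s")


class TestQcSpots:
    def test_constant_libraries_all_retained(self):
        m = _matrix_with_library_sizes([100] * 5)
        assert sf.qc_spots(m).n_spots == 5

    def test_low_outlier_removed_by_hand_computation(self):
        # logs {1,5,5,5,5}: median 5, raw MAD 0 -> cut-off 5, first spot out
        libs = [round(math.e), round(math.e**5)] + [round(math.e**5)] * 3
        libs[0] = int(round(math.exp(1)))
        m = _matrix_with_library_sizes(libs)
        kept = sf.qc_spots(m, n_mads=3)
        assert kept.n_spots == 4
        assert "1x1" not in kept.counts.index

    def test_infinite_threshold_is_identity_on_positive_spots(self):
        m = _matrix_with_library_sizes([1, 10, 100, 1000])
        assert sf.qc_spots(m, n_mads=math.inf).n_spots == 4

    def test_zero_library_spot_always_removed(self):
        m = _matrix_with_library_sizes([0, 10, 10, 10])
        with pytest.warns(UserWarning, match="zero library"):
            kept = sf.qc_spots(m)
        assert "1x1" not in kept.counts.index

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        m = _matrix_with_library_sizes(rng.integers(1, 5000, size=40))
        previous = None
        for n_mads in [0.5, 1, 2, 3, math.inf]:
            kept = set(sf.qc_spots(m, n_mads=n_mads).counts.index)
            if previous is not None:
                assert previous <= kept  # stricter cut keeps a subset
            previous = kept


class TestFilterGenes:
    def test_all_zero_gene_removed(self):
        counts = pd.DataFrame(
            {"dead": [0, 0, 0, 0], "ok": [2, 2, 2, 2]},
            index=["1x1", "2x1", "3x1", "4x1"],
        )
        m = sf.filter_genes(sf.CountMatrix(counts=counts))
        assert m.genes == ["ok"]

    def test_detection_criterion_beats_total(self):
        # total 5 but detected in only 1 spot -> removed under defaults
        counts = pd.DataFrame(
            {"spiky": [5, 0, 0, 0], "ok": [2, 2, 2, 2]},
            index=["1x1", "2x1", "3x1", "4x1"],
        )
        m = sf.filter_genes(sf.CountMatrix(counts=counts))
        assert m.genes == ["ok"]

    def test_zero_thresholds_identity(self):
        counts = pd.DataFrame(
            {"a": [0, 0], "b": [1, 0]}, index=["1x1", "2x1"]
        )
        m = sf.filter_genes(
            sf.CountMatrix(counts=counts), min_total=0, min_detected_spots=0
        )
        assert m.genes == ["a", "b"]

    def test_everything_removed_is_an_error(self):
        counts = pd.DataFrame({"a": [1, 0]}, index=["1x1", "2x1"])
        with pytest.raises(ValueError, match="no genes survive"):
            sf.filter_genes(sf.CountMatrix(counts=counts))


class TestNormalize:
    def test_equal_libraries_give_unit_factors(self):
        counts = pd.DataFrame(
            {"a": [3, 3], "b": [7, 7]}, index=["1x1", "2x1"]
        )
        nm = sf.normalize(sf.CountMatrix(counts=counts))
        assert np.allclose(nm.size_factors, 1.0)
        pd.testing.assert_frame_equal(nm.values, counts.astype(float))

    def test_library_size_factors_by_hand(self):
        counts = pd.DataFrame(
            {"a": [100], "b": [0]}, index=["1x1"]
        )
        counts = pd.DataFrame(
            {"a": [100, 300]}, index=["1x1", "2x1"]
        )
        nm = sf.normalize(sf.CountMatrix(counts=counts))
        assert nm.size_factors.tolist() == [0.5, 1.5]

    def test_doubling_counts_leaves_size_factors_and_proportions_unchanged(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.integers(1, 30, size=(5, 4)),
            index=[f"{i + 1}x1" for i in range(5)],
            columns=list("abcd"),
        )
        nm1 = sf.normalize(sf.CountMatrix(counts=counts))
        nm2 = sf.normalize(sf.CountMatrix(counts=counts * 2))
        # sequencing the same library twice as deep changes no size factor
        assert np.allclose(nm1.size_factors, nm2.size_factors)
        # and relative (within-spot) expression is unchanged
        prop1 = nm1.values.div(nm1.values.sum(axis=1), axis=0)
        prop2 = nm2.values.div(nm2.values.sum(axis=1), axis=0)
        pd.testing.assert_frame_equal(prop1, prop2)

    def test_rank_order_preserved_per_spot(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(6, 5)),
            index=[f"{i + 1}x1" for i in range(6)],
            columns=list("abcde"),
        )
        counts.iloc[:, 0] += 1  # ensure positive library sizes
        m = sf.CountMatrix(counts=counts)
        nm = sf.normalize(m)
        for spot in counts.index:
            raw = counts.loc[spot].rank()
            norm = nm.values.loc[spot].rank()
            pd.testing.assert_series_equal(raw, norm)

    def test_pooled_factors_average_one_and_track_library_size(self, default_sim):
        _, cm, _, _ = default_sim
        sub = sf.CountMatrix(
            counts=cm.counts.iloc[:200, :300].copy(), sample=cm.sample
        )
        nm = sf.normalize(sub, method="pooled")
        assert nm.size_factors.mean() == pytest.approx(1.0, abs=1e-9)
        assert (nm.size_factors > 0).all()
        lib = sub.library_sizes()
        assert np.corrcoef(nm.size_factors, lib)[0, 1] > 0.5

    def test_pooled_falls_back_when_too_few_spots(self):
        counts = pd.DataFrame(
            {"a": [10, 30], "b": [5, 15]}, index=["1x1", "2x1"]
        )
        with pytest.warns(UserWarning, match="falling back"):
            nm = sf.normalize(sf.CountMatrix(counts=counts), method="pooled")
        assert nm.size_factors.tolist() == [0.5, 1.5]


class TestSdFilter:
    def _nm(self, frame):
        sf_ = pd.Series(1.0, index=frame.index)
        return sf.NormalizedMatrix(values=frame, size_factors=sf_)

    def test_constant_gene_removed(self):
        frame = pd.DataFrame(
            {"flat": [2.0, 2.0, 2.0], "var": [1.0, 2.0, 3.0]},
            index=["1x1", "2x1", "3x1"],
        )
        assert sf.sd_filter(self._nm(frame)) == ["var"]

    def test_two_point_gene_kept_by_hand(self):
        # values {1,3}: mean 2, sample sd = sqrt(2) ~ 1.414 >= 0.2
        frame = pd.DataFrame({"g": [1.0, 3.0]}, index=["1x1", "2x1"])
        assert sf.sd_filter(self._nm(frame)) == ["g"]

    def test_zero_frac_removes_only_zero_mean_genes(self):
        frame = pd.DataFrame(
            {"zero": [0.0, 0.0], "flat": [1.0, 1.0]}, index=["1x1", "2x1"]
        )
        assert sf.sd_filter(self._nm(frame), frac=0.0) == ["flat"]

    def test_single_spot_errors(self):
        frame = pd.DataFrame({"g": [1.0, 2.0]}, index=["1x1", "2x1"])
        with pytest.raises(ValueError, match="sd undefined"):
            sf.sd_filter(self._nm(frame), spots=["1x1"])
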