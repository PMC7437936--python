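import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stfusion as sf

from conftest import random_count_matrix


def brute_cscores(counts5, counts3):
    """Independent re-derivation: per-spot max-of-ratios with 5'-wins sign."""
    counts5 = [float(c) for c in counts5]
    counts3 = [float(c) for c in counts3]
    m5 = sum(counts5) / len(counts5)
    m3 = sum(counts3) / len(counts3)
    out = []
    for c5, c3 in zip(counts5, counts3):
        r5 = c5 / m5 if m5 > 0 else 0.0
        r3 = c3 / m3 if m3 > 0 else 0.0
        out.append(-r5 if r5 >= r3 else r3)
    return out


class TestGeneRatio:
    def test_constant_gene_is_all_ones(self):
        assert np.allclose(sf.gene_ratio([5, 5, 5, 5]), 1.0)

    def test_hand_computed_ratios(self):
        assert sf.gene_ratio([0, 2, 4, 2]).tolist() == [0.0, 1.0, 2.0, 1.0]

    def test_all_zero_gene_is_zero_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            r = sf.gene_ratio([0, 0, 0])
        assert r.tolist() == [0.0, 0.0, 0.0]

    def test_ratios_average_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 30, size=rng.integers(1, 20))
            if x.sum() == 0:
                continue
            assert sf.gene_ratio(x).mean() == pytest.approx(1.0, abs=1e-9)

    def test_pseudocount_all_zero_gene_is_one(self):
        assert np.allclose(sf.gene_ratio([0, 0], pseudocount=True), 1.0)


class TestCScoreValue:
    def test_occurrence_branch(self):
        assert sf.cscore_value(1.0, 3.0) == 3.0

    def test_tie_goes_to_absence(self):
        assert sf.cscore_value(2.0, 2.0) == -2.0

    def test_double_zero_collapses_to_plain_zero(self):
        c = sf.cscore_value(0.0, 0.0)
        assert c == 0.0 and not np.signbit(c)

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            sf.cscore_value(-0.1, 1.0)


class TestCScoreMap:
    def test_worked_example(self, tiny_counts):
        cs = sf.cscore_map(tiny_counts, ("SLC45A3", "ELK4"))
        spiked = cs.table.loc["2x2"]
        assert spiked["r5"] == pytest.approx(1.0)
        assert spiked["r3"] == pytest.approx(3.0)
        assert spiked["cscore"] == pytest.approx(3.0)
        assert spiked["label"] == "occurrence"
        first = cs.table.loc["1x1"]
        assert first["r5"] == pytest.approx(1.0)
        assert first["r3"] == pytest.approx(1 / 3)
        assert first["cscore"] == pytest.approx(-1.0)
        assert first["label"] == "absence"

    def test_missing_gene_named(self, tiny_counts):
        with pytest.raises(KeyError, match="NOPE"):
            sf.cscore_map(tiny_counts, ("NOPE", "ELK4"))

    def test_pseudocount_on_silent_pair_forces_minus_one(self):
        counts = pd.DataFrame(
            {"a": [0, 0, 0], "b": [0, 0, 0]}, index=["1x1", "2x1", "3x1"]
        )
        cs = sf.cscore_map(sf.CountMatrix(counts=counts), ("a", "b"),
                           pseudocount=True)
        assert np.allclose(cs.cscores, -1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            m = random_count_matrix(rng)
            g5, g3 = m.genes[0], m.genes[1]
            with np.errstate(all="ignore"):
                cs = sf.cscore_map(m, (g5, g3))
            expected = brute_cscores(m.counts[g5], m.counts[g3])
            assert np.allclose(cs.cscores, expected, atol=1e-12)

    def test_mean_law(self):
        rng = np.random.default_rng(3)
        m = random_count_matrix(rng, n_spots=30)
        g5, g3 = m.genes[0], m.genes[1]
        if m.counts[g5].sum() and m.counts[g3].sum():
            cs = sf.cscore_map(m, (g5, g3))
            assert cs.table["r5"].mean() == pytest.approx(1.0, abs=1e-9)
            assert cs.table["r3"].mean() == pytest.approx(1.0, abs=1e-9)


class TestLabelsAndGrades:
    @pytest.mark.parametrize(
        "c,strict,fig3",
        [
            (1.5, "occurrence", "occurrence"),
            (0.0, "neutral", "absence"),
            (-0.5, "absence", "absence"),
        ],
    )
    def test_both_conventions(self, c, strict, fig3):
        assert sf.label_spot(c, "strict") == strict
        assert sf.label_spot(c, "fig3") == fig3

    def test_occ_threshold_shifts_boundary(self):
        assert sf.label_spot(0.3, "strict", occ_threshold=0.5) == "neutral"
        assert sf.label_spot(0.6, "strict", occ_threshold=0.5) == "occurrence"

    @pytest.mark.parametrize(
        "c,grade",
        [
            (0.5, "mild_occurrence"),
            (1.2, "strong_occurrence"),
            (1.0, "strong_occurrence"),
            (-0.2, "mild_absence"),
            (-1.0, "strong_absence"),
            (-3.0, "strong_absence"),
        ],
    )
    def test_grades(self, c, grade):
        assert sf.grade_spot(c) == grade

    def test_nonpositive_mild_rejected(self):
        with pytest.raises(ValueError):
            sf.grade_spot(1.0, mild=0.0)


# ---- property tests -------------------------------------------------------

counts_pairs = st.lists(
    st.tuples(st.integers(0, 50), st.integers(0, 50)), min_size=2, max_size=30
)


@given(counts_pairs)
@settings(deadline=None, max_examples=100)
def test_sign_law(pairs):
    """cscore <= 0 exactly when the 5' ratio dominates, in every spot."""
    c5, c3 = zip(*pairs)
    with np.errstate(all="ignore"):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r5 = sf.gene_ratio(np.array(c5, float))
            r3 = sf.gene_ratio(np.array(c3, float))
    for a, b in zip(r5, r3):
        c = sf.cscore_value(a, b)
        assert (c <= 0) == (a >= b)
        assert abs(c) == max(a, b)


@given(counts_pairs, st.sampled_from([2, 10, 1000]))
@settings(deadline=None, max_examples=60)
def test_scale_invariance(pairs, factor):
    """Multiplying one gene's counts by c > 0 changes no C-score."""
    c5, c3 = zip(*pairs)
    index = [f"{i + 1}x1" for i in range(len(pairs))]
    base = pd.DataFrame({"a": c5, "b": c3}, index=index)
    scaled = base.copy()
    scaled["a"] = scaled["a"] * factor
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cs1 = sf.cscore_map(sf.CountMatrix(counts=base), ("a", "b"))
        cs2 = sf.cscore_map(sf.CountMatrix(counts=scaled), ("a", "b"))
    assert np.allclose(cs1.cscores, cs2.cscores)


@given(counts_pairs)
@settings(deadline=None, max_examples=60)
def test_exchange_antisymmetry(pairs):
    """Swapping the pair flips every spot with r5 != r3 across the axis."""
    c5, c3 = zip(*pairs)
    index = [f"{i + 1}x1" for i in range(len(pairs))]
    counts = pd.DataFrame({"a": c5, "b": c3}, index=index)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fwd = sf.cscore_map(sf.CountMatrix(counts=counts), ("a", "b"))
        rev = sf.cscore_map(sf.CountMatrix(counts=counts), ("b", "a"))
    for spot in counts.index:
        f, r = fwd.table.loc[spot], rev.table.loc[spot]
        if f["r5"] != f["r3"]:
            assert (f["cscore"] > 0) == (r["cscore"] <= 0)
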