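"""Landscape statistics: GC, profiles, correlations, length trends."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from satfold import FoldOptions
from satfold.sequence import NucleotideSequence
from satfold.stats import (
    UndefinedCorrelationError,
    aggregate_profile,
    correlate_features,
    correlate_missegregation,
    gc_content,
    length_sensitivity,
    pearson,
    profile_windows,
)


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [
        ("GCGC", 1.0),
        ("ATAT", 0.0),
        ("ATGCN", 0.5),   # N excluded from the denominator
        ("ACGT", 0.5),
    ])
    def test_worked_values(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")

    def test_all_n_flags_zero(self):
        assert gc_content("NNNN") == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=200),
           st.randoms(use_true_random=False))
    def test_shuffle_invariant(self, seq, rnd):
        chars = list(seq)
        rnd.shuffle(chars)
        assert gc_content("".join(chars)) == pytest.approx(gc_content(seq))


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        assert pearson(x, x) == pytest.approx(1.0)

    def test_perfect_negative_affine(self):
        x = np.arange(10.0)
        assert pearson(x, -2 * x + 7) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_zero_variance_is_an_error_not_nan(self):
        with pytest.raises(UndefinedCorrelationError, match="variance"):
            pearson([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson([1, 2], [3, 4])

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_matches_textbook_two_pass_formula(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=20), rng.normal(size=20)
        xm, ym = x - x.mean(), y - y.mean()
        ref = float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))
        assert pearson(x, y) == pytest.approx(ref, abs=1e-12)


def _profile_frame(rows):
    from satfold.stats import PROFILE_COLUMNS

    df = pd.DataFrame(rows)
    for c in PROFILE_COLUMNS:
        if c not in df:
            df[c] = np.nan
    return df[PROFILE_COLUMNS]


class TestProfiles:
    def test_empty_window_list(self, params):
        prof = profile_windows([], params)
        assert prof.empty

    def test_single_poly_a_window(self, params):
        w = NucleotideSequence("A" * 500, id="w0", chrom="chr1",
                               region_label="coding")
        prof = profile_windows([w], params, ensemble=False)
        row = prof.iloc[0]
        assert row.mfe == 0.0 and row.abs_mfe == 0.0
        assert row.gc_fraction == 0.0 and row.dyad_density == 0.0

    def test_aggregate_means_equal_row_means(self, params):
        rows = [
            {"chrom": "c1", "region_label": "coding", "window_id": f"w{i}",
             "window_length": 100, "mfe": m, "abs_mfe": abs(m),
             "gc_fraction": 0.5, "dyad_density": 0.1}
            for i, m in enumerate([-10.0, -20.0, -30.0])
        ]
        by_chrom, by_region = aggregate_profile(_profile_frame(rows))
        assert by_region.loc["coding", ("mfe", "mean")] == pytest.approx(-20.0)
        assert by_region.loc["coding", ("mfe", "std")] == pytest.approx(10.0)

    def test_aggregation_permutation_invariant(self, params):
        rows = [
            {"chrom": f"c{i % 3}", "region_label": "coding", "window_id": f"w{i}",
             "window_length": 100, "mfe": -float(i), "abs_mfe": float(i),
             "gc_fraction": 0.4 + i / 100, "dyad_density": 0.02 * i}
            for i in range(9)
        ]
        a = aggregate_profile(_profile_frame(rows))[1]
        b = aggregate_profile(_profile_frame(rows[::-1]))[1]
        pd.testing.assert_frame_equal(a, b)


class TestCorrelateFeatures:
    def _mk(self, gc_drives=True, sigma=0.0, n_chrom=6):
        rng = np.random.default_rng(1)
        rows = []
        for k in range(n_chrom):
            gc = 0.35 + 0.04 * k
            dd = 0.02 + 0.005 * k
            abs_mfe = (100 * gc if gc_drives else 5.0) + rng.normal(0, sigma)
            rows.append({"chrom": f"c{k}", "region_label": "active_hor",
                         "window_id": f"w{k}", "window_length": 500,
                         "mfe": -abs_mfe, "abs_mfe": abs_mfe,
                         "gc_fraction": gc, "dyad_density": dd})
        return _profile_frame(rows)

    def test_gc_driven_construction_r_to_one(self):
        rep = correlate_features(self._mk(sigma=0.0))
        assert rep.r_abs_mfe_gc.iloc[0] == pytest.approx(1.0)

    def test_constant_dyad_density_is_undefined(self):
        prof = self._mk()
        prof["dyad_density"] = 0.05
        with pytest.raises(UndefinedCorrelationError):
            correlate_features(prof)

    def test_requires_three_chromosomes(self):
        with pytest.raises(UndefinedCorrelationError, match="3"):
            correlate_features(self._mk(n_chrom=2))


class TestCorrelateMissegregation:
    def test_linear_inverse_relation_gives_minus_one(self):
        prob = {f"c{k}": 0.05 * k for k in range(6)}
        abs_mfe = {f"c{k}": 50 - 100 * prob[f"c{k}"] for k in range(6)}
        r, n = correlate_missegregation(abs_mfe, prob)
        assert r == pytest.approx(-1.0)
        assert n == 6

    def test_equal_probabilities_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            correlate_missegregation({"a": 1.0, "b": 2.0, "c": 3.0},
                                     {"a": 0.1, "b": 0.1, "c": 0.1})

    def test_unmatched_chromosomes_dropped(self):
        abs_mfe = {f"c{k}": float(k) for k in range(5)}
        prob = {f"c{k}": 0.01 * k for k in range(1, 7)}
        r, n = correlate_missegregation(abs_mfe, prob)
        assert n == 4

    def test_label_shuffle_destroys_signal_in_expectation(self):
        rng = np.random.default_rng(0)
        k = 12
        prob = {f"c{i}": 0.02 * i for i in range(k)}
        abs_mfe = {f"c{i}": 50 - 500 * prob[f"c{i}"] for i in range(k)}
        rs = []
        names = list(prob)
        for _ in range(300):
            perm = rng.permutation(names)
            shuffled = {a: prob[b] for a, b in zip(names, perm)}
            try:
                r, _ = correlate_missegregation(abs_mfe, shuffled)
                rs.append(r)
            except UndefinedCorrelationError:
                pass
        assert abs(np.mean(rs)) < 0.15

    def test_probabilities_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            correlate_missegregation({"a": 1.0, "b": 2.0, "c": 3.0},
                                     {"a": 0.1, "b": 1.4, "c": 0.2})


class TestLengthSensitivity:
    def _prof(self, means, L):
        rows = []
        for region, m in means.items():
            for k in range(3):
                rows.append({"chrom": f"c{k}", "region_label": region,
                             "window_id": f"{region}{k}", "window_length": L,
                             "mfe": m + 0.1 * k, "abs_mfe": abs(m),
                             "gc_fraction": 0.4, "dyad_density": 0.05})
        return _profile_frame(rows)

    def test_identical_orderings_preserved(self):
        means = {"active_hor": -20.0, "divergent_hor": -15.0, "coding": -40.0}
        rep = length_sensitivity({
            500: self._prof(means, 500),
            1000: self._prof({k: 2 * v for k, v in means.items()}, 1000),
        })
        assert rep.ordering_preserved.all()

    def test_inverted_fixture_raises_flag(self):
        means = {"active_hor": -20.0, "divergent_hor": -15.0, "coding": -40.0}
        inverted = {"active_hor": -20.0, "divergent_hor": -45.0, "coding": -40.0}
        rep = length_sensitivity({
            500: self._prof(means, 500),
            1000: self._prof(inverted, 1000),
        })
        assert not rep[rep.window_length == 1000].ordering_preserved.iloc[0]

    def test_region_set_mismatch(self):
        a = self._prof({"coding": -10.0, "rdna": -20.0, "active_hor": -30.0}, 500)
        b = self._prof({"coding": -10.0, "rdna": -20.0}, 1000)
        with pytest.raises(ValueError, match="region sets"):
            length_sensitivity({500: a, 1000: b})
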