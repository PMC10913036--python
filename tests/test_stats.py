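import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from oscillotrack import (
    DegenerateInputError,
    InvalidParameterError,
    correlate,
    holm_adjust,
    linear_trend,
    paired_contrast,
    sqrt_transform,
)

JITTERS = [0.0, 0.2, 0.4, 0.6, 0.8]


def make_table(values_fn, n_subjects=8, stimuli=("click",), rng=None):
    rows = []
    for s in range(n_subjects):
        for stim in stimuli:
            for j in JITTERS:
                rows.append(
                    {
                        "subject_id": f"s{s}",
                        "stimulus": stim,
                        "rate": 4.5,
                        "jitter": j,
                        "peak_plv": values_fn(s, stim, j, rng),
                    }
                )
    return pd.DataFrame(rows)


class TestSqrtTransform:
    @pytest.mark.parametrize("x,expected", [(0.0, 0.0), (1.0, 1.0), (0.25, 0.5)])
    def test_known_values(self, x, expected):
        assert sqrt_transform([x])[0] == expected

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20))
    def test_preserves_ordering(self, values):
        order = np.argsort(values)
        assert np.array_equal(np.argsort(sqrt_transform(values)[order]), np.arange(len(values)))

    def test_negative_rejected(self):
        with pytest.raises(InvalidParameterError):
            sqrt_transform([-0.1])


class TestLinearTrend:
    def test_deterministic_decline_detected(self):
        tbl = make_table(lambda s, st_, j, r: 0.8 - 0.3 * j)
        res = linear_trend(tbl)
        assert res.slope == pytest.approx(-0.3)
        assert res.p < 0.05
        assert res.t < 0

    def test_constant_values_give_null_result(self):
        tbl = make_table(lambda s, st_, j, r: 0.5)
        res = linear_trend(tbl)
        assert res.t == 0.0
        assert res.p == 1.0

    def test_unbalanced_cells_rejected_with_listing(self):
        tbl = make_table(lambda s, st_, j, r: 0.5)
        tbl = tbl.drop(index=3)
        with pytest.raises(InvalidParameterError, match="missing"):
            linear_trend(tbl)

    def test_null_pvalues_are_uniform(self):
        # permuting factor labels (equivalently: iid values) must give a
        # uniform p-value distribution
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(300):
            tbl = make_table(lambda s, st_, j, r: r.normal(), rng=rng)
            pvals.append(linear_trend(tbl).p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestPairedContrast:
    def _two_stim(self, offset, noise_sd=0.0, n=8, seed=0):
        rng = np.random.default_rng(seed)
        return make_table(
            lambda s, st_, j, r: 0.5
            + (offset if st_ == "syllable" else 0.0)
            + (rng.normal(0, noise_sd) if noise_sd else 0.0),
            n_subjects=n,
            stimuli=("click", "syllable"),
        )

    def test_identical_columns_give_unit_p(self):
        res = paired_contrast(self._two_stim(0.0), at={"jitter": 0.2})
        assert res.mean_diff == 0.0
        assert res.p == 1.0

    def test_noiseless_shift_flags_exact_separation(self):
        res = paired_contrast(self._two_stim(0.1), at={"jitter": 0.2})
        assert res.exact_separation
        assert res.p == 0.0
        assert res.mean_diff == pytest.approx(-0.1)  # click - syllable

    def test_shifted_with_noise_detected(self):
        res = paired_contrast(self._two_stim(0.1, noise_sd=0.02, n=12), at={"jitter": 0.4})
        assert res.p < 0.01

    def test_missing_pairs_rejected(self):
        tbl = self._two_stim(0.1)
        tbl = tbl[~((tbl.subject_id == "s0") & (tbl.stimulus == "click"))]
        with pytest.raises(InvalidParameterError):
            paired_contrast(tbl, at={"jitter": 0.2})

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(1234)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            _, p = sps.ttest_rel(a, b)
            rejections += p < 0.05
        # sanity anchor for the paired machinery at alpha = 0.05
        assert abs(rejections / n_rep - 0.05) < 0.02


class TestCorrelate:
    def test_perfect_correlation(self, rng):
        x = rng.standard_normal(24)
        r, p = correlate(x, x)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_affine_anticorrelation(self, rng):
        x = rng.standard_normal(24)
        r, _ = correlate(x, -2 * x + 3)
        assert r == pytest.approx(-1.0)

    def test_recovers_population_correlation(self):
        rng = np.random.default_rng(7)
        rho = 0.65
        rs = []
        for _ in range(1000):
            x = rng.standard_normal(24)
            y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(24)
            rs.append(correlate(x, y)[0])
        assert abs(np.mean(rs) - rho) < 0.03

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            correlate(np.ones(10), np.arange(10.0))


class TestHolm:
    def test_adjusted_at_least_raw_and_bounded(self):
        p = np.array([0.001, 0.02, 0.04, 0.3, 0.8])
        adj = holm_adjust(p)
        assert np.all(adj >= p)
        assert np.all(adj <= 1.0)

    def test_single_p_unchanged(self):
        assert holm_adjust([0.03])[0] == pytest.approx(0.03)
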