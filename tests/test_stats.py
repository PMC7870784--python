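"""The hypergeometric tails against exact-rational oracles, and BH-FDR properties."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import draws_upper_tail, rational_lower_tail, rational_upper_tail
from pmsnet import HypergeomParams, bh_adjust, hypergeom_lower_printed, hypergeom_upper
from pmsnet.stats import hypergeom_upper_many


def _all_params(m_values):
    for m in m_values:
        for j in range(0, m + 1):
            for n in range(0, m + 1):
                for x in range(0, min(j, n) + 1):
                    yield m, j, n, x


class TestUpperTail:
    def test_certain_event_is_one(self):
        assert hypergeom_upper(m=100, j=10, n=5, x=0) == 1.0

    def test_small_exact_value(self):
        # 1 - C(3,2)/C(5,2) = 1 - 3/10
        assert hypergeom_upper(m=5, j=2, n=2, x=1) == pytest.approx(0.7, abs=1e-15)

    def test_exact_rational_example(self):
        expected = rational_upper_tail(20, 6, 5, 3)
        assert expected == Fraction(509, 3876)  # frozen from the oracle
        got = hypergeom_upper(m=20, j=6, n=5, x=3)
        assert got == pytest.approx(float(expected), rel=1e-12)

    def test_matches_rational_oracle_exhaustively(self):
        for m, j, n, x in _all_params(range(1, 16)):
            expected = float(rational_upper_tail(m, j, n, x))
            got = hypergeom_upper(m=m, j=j, n=n, x=x)
            assert got == pytest.approx(expected, rel=1e-12, abs=1e-300), (m, j, n, x)

    def test_rational_oracle_agrees_with_draw_enumeration(self):
        # validates the oracle itself on tiny universes
        for m, j, n, x in _all_params(range(1, 9)):
            assert rational_upper_tail(m, j, n, x) == draws_upper_tail(m, j, n, x)

    def test_monotone_non_increasing_in_x(self):
        for m, j, n in [(30, 10, 8), (50, 25, 20), (12, 6, 6)]:
            vals = [hypergeom_upper(m=m, j=j, n=n, x=x) for x in range(min(j, n) + 1)]
            assert all(a >= b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            (dict(m=10, j=11, n=5, x=0), "j"),
            (dict(m=10, j=5, n=11, x=0), "n"),
            (dict(m=10, j=5, n=4, x=5), "x"),
            (dict(m=-1, j=0, n=0, x=0), "m"),
        ],
    )
    def test_invariant_violations_name_the_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            HypergeomParams(**kwargs)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(0)
        m = 200
        j = rng.integers(0, m + 1, size=50)
        n = rng.integers(0, m + 1, size=50)
        x = rng.integers(0, np.minimum(j, n) + 1)
        vec = hypergeom_upper_many(m, j, n, x)
        for ji, ni, xi, vi in zip(j, n, x, vec):
            assert vi == pytest.approx(hypergeom_upper(m=m, j=int(ji), n=int(ni), x=int(xi)))


class TestLowerTail:
    def test_full_support_is_one(self):
        assert hypergeom_lower_printed(m=40, j=7, n=9, x=7) == 1.0

    def test_small_exact_value(self):
        assert hypergeom_lower_printed(m=5, j=2, n=2, x=0) == pytest.approx(0.3, abs=1e-15)

    def test_complement_identity_sweep(self):
        m, j, n = 15, 5, 4
        for x in range(1, min(j, n) + 1):
            upper = hypergeom_upper(m=m, j=j, n=n, x=x)
            lower = hypergeom_lower_printed(m=m, j=j, n=n, x=x - 1)
            assert upper == pytest.approx(1.0 - lower, abs=1e-12)

    def test_matches_rational_oracle(self):
        for m, j, n, x in _all_params(range(1, 13)):
            expected = float(rational_lower_tail(m, j, n, x))
            assert hypergeom_lower_printed(m=m, j=j, n=n, x=x) == pytest.approx(
                expected, rel=1e-12, abs=1e-300
            )


class TestBHAdjust:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.5], [0.5]),
            ([0.001, 0.5], [0.002, 0.5]),
        ],
    )
    def test_worked_examples(self, raw, expected):
        assert list(bh_adjust(raw).adjusted) == pytest.approx(expected, abs=1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust([0.2, 1.5])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust([-0.1])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(max_examples=200, deadline=None)
    def test_never_decreases_and_preserves_order(self, raw):
        out = bh_adjust(raw)
        assert len(out.adjusted) == len(raw)
        for r, a in zip(raw, out.adjusted):
            assert a >= r - 1e-15
            assert 0.0 <= a <= 1.0
        # re-adjusting already-adjusted values can only push them further up
        again = bh_adjust(out.adjusted)
        for before, after in zip(out.adjusted, again.adjusted):
            assert after >= before - 1e-15

    def test_matches_reference_step_up_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(123)
        for _ in range(300):
            size = rng.integers(1, 60)
            raw = rng.random(size) ** rng.uniform(0.5, 3.0)
            ours = np.asarray(bh_adjust(raw).adjusted)
            _, ref, _, _ = multipletests(raw, method="fdr_bh")
            np.testing.assert_allclose(ours, ref, rtol=1e-12, atol=1e-15)
            for alpha in (0.001, 0.01, 0.05, 0.2):
                assert (ours < alpha).sum() == (ref < alpha).sum()

    def test_ties_receive_identical_adjusted_values(self):
        out = bh_adjust([0.02, 0.5, 0.02, 0.02])
        assert out.adjusted[0] == out.adjusted[2] == out.adjusted[3]
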