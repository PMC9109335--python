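"""Pairwise reference aligners: NW, Gotoh and sub-additive run costs."""

import math
import random

import pytest
from hypothesis import given, strategies as st

from bialignment import (
    ScoringConfig,
    SubadditiveGapParams,
    SubstitutionTable,
    gotoh_align,
    nw_align,
    subadditive_align,
)
from bialignment.oracle import brute_force_pairwise

from conftest import random_params


def _cfg(match=1, mismatch=-1, gap_open=-200.0, gap_extend=-50.0):
    return ScoringConfig(
        substitution=SubstitutionTable.match_mismatch("AB", match, mismatch),
        gap_open=gap_open,
        gap_extend=gap_extend,
        mode="affine_gap",
    )


def _random_pair(rng, max_len=4):
    return (
        "".join(rng.choice("AB") for _ in range(rng.randint(0, max_len))),
        "".join(rng.choice("AB") for _ in range(rng.randint(0, max_len))),
    )


class TestNeedlemanWunsch:
    def test_empty_inputs_score_zero(self):
        score, (ra, rb) = nw_align("", "", _cfg())
        assert score == 0 and ra == rb == ""

    def test_two_matches(self):
        score, rows = nw_align("AB", "AB", _cfg(match=1, mismatch=-1, gap_extend=-2))
        assert score == 2
        assert rows == ("AB", "AB")

    def test_matches_brute_force_enumeration(self):
        rng = random.Random(11)
        for _ in range(60):
            a, b = _random_pair(rng)
            cfg = _cfg(
                match=rng.randint(1, 5),
                mismatch=rng.randint(-4, 1),
                gap_extend=rng.randint(-4, 0),
            )
            g = cfg.gap_extend
            expect = brute_force_pairwise(
                a, b, lambda i, j: cfg.substitution.score(a[i], b[j]),
                lambda l: l * g,
            )
            score, rows = nw_align(a, b, cfg)
            assert score == pytest.approx(expect)
            assert rows[0].replace("-", "") == a and rows[1].replace("-", "") == b


class TestGotoh:
    def test_single_run_costs_open_plus_extends(self):
        score, rows = gotoh_align("AA", "", _cfg(gap_open=-200, gap_extend=-50))
        assert score == -300
        assert rows == ("AA", "--")

    def test_zero_opening_equals_linear_model(self):
        rng = random.Random(5)
        for _ in range(40):
            a, b = _random_pair(rng)
            cfg = _cfg(
                match=rng.randint(1, 5),
                mismatch=rng.randint(-4, 1),
                gap_open=0.0,
                gap_extend=rng.randint(-4, 0),
            )
            assert gotoh_align(a, b, cfg)[0] == pytest.approx(nw_align(a, b, cfg)[0])

    def test_matches_brute_force_run_scoring(self):
        rng = random.Random(23)
        for _ in range(60):
            a, b = _random_pair(rng)
            cfg = _cfg(
                match=rng.randint(1, 5),
                mismatch=rng.randint(-4, 1),
                gap_open=rng.randint(-8, 0),
                gap_extend=rng.randint(-4, 0),
            )
            go, ge = cfg.gap_open, cfg.gap_extend
            expect = brute_force_pairwise(
                a, b, lambda i, j: cfg.substitution.score(a[i], b[j]),
                lambda l: go + l * ge,
            )
            score, rows = gotoh_align(a, b, cfg)
            assert score == pytest.approx(expect)
            assert rows[0].replace("-", "") == a and rows[1].replace("-", "") == b

    @given(st.integers(0, 5_000))
    def test_harsher_extension_never_helps(self, seed):
        rng = random.Random(seed)
        a, b = _random_pair(rng)
        cfg = _cfg(gap_open=-3, gap_extend=-1)
        harsher = _cfg(gap_open=-3, gap_extend=-2)
        assert gotoh_align(a, b, harsher)[0] <= gotoh_align(a, b, cfg)[0]


def _subadditive_params(rng):
    """Random run-cost parameters that really are sub-additive:
    a <= 0, c_log <= 0 and |c_log| <= -a / ln 2."""
    a = rng.randint(-8, -1)
    c = -rng.random() * (-a / math.log(2)) * 0.9
    b = rng.randint(-4, 0)
    return SubadditiveGapParams(a=a, b=b, c_log=c)


class TestSubadditive:
    def test_single_run_closed_form(self):
        params = SubadditiveGapParams(a=-7.0, b=-2.0, c_log=-1.5)
        got = subadditive_align("AAA", "", params, _cfg())
        assert got == pytest.approx(-7.0 - 6.0 - 1.5 * math.log(3))

    def test_affine_limit_equals_gotoh(self):
        rng = random.Random(31)
        for _ in range(40):
            a, b = _random_pair(rng)
            go, ge = rng.randint(-8, 0), rng.randint(-4, 0)
            cfg = _cfg(match=rng.randint(1, 5), gap_open=go, gap_extend=ge)
            params = SubadditiveGapParams(a=go, b=ge, c_log=0.0)
            for method in ("direct", "run_length"):
                got = subadditive_align(a, b, params, cfg, method=method)
                assert got == pytest.approx(gotoh_align(a, b, cfg)[0])

    def test_both_formulations_agree(self):
        rng = random.Random(43)
        for _ in range(40):
            a, b = _random_pair(rng)
            cfg = _cfg(match=rng.randint(1, 5), mismatch=rng.randint(-3, 1))
            params = _subadditive_params(rng)
            direct = subadditive_align(a, b, params, cfg, method="direct")
            runlen = subadditive_align(a, b, params, cfg, method="run_length")
            assert direct == pytest.approx(runlen)

    def test_matches_brute_force_run_scoring(self):
        rng = random.Random(59)
        for _ in range(40):
            a, b = _random_pair(rng)
            cfg = _cfg(match=rng.randint(1, 5), mismatch=rng.randint(-3, 1))
            params = _subadditive_params(rng)
            expect = brute_force_pairwise(
                a, b, lambda i, j: cfg.substitution.score(a[i], b[j]), params.cost
            )
            got = subadditive_align(a, b, params, cfg, method="run_length")
            assert got == pytest.approx(expect)

    def test_extension_increment_telescopes(self):
        params = SubadditiveGapParams(a=-5.0, b=-1.0, c_log=-0.7)
        total = 0.0
        for l in range(1, 6):
            total += params.cost(l) - params.cost(l - 1)
        assert total == pytest.approx(params.cost(5))
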