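"""Bi-alignment DP engines: state spaces, banding, tracebacks, reductions."""

import random
from dataclasses import replace

import pytest
from hypothesis import given, strategies as st

from bialignment import (
    INITIAL_STATE,
    ScoringConfig,
    SubstitutionTable,
    band_filter,
    bialign,
    gotoh_align,
    reachable_states,
    score_bialignment,
)
from bialignment.core import LengthMismatchError, UnknownSymbolError, decompose
from bialignment.engine import fill_tables, traceback
from bialignment.fixtures import FixtureSpec, generate_fixture
from bialignment.oracle import brute_force_bialign, enumerate_bialignment_columns

from conftest import random_instance, random_params


class TestStateSpace:
    def test_reachable_tuple_count(self):
        states = reachable_states()
        assert len(states) == 51
        assert 3**4 - len(states) == 30
        assert INITIAL_STATE in states

    def test_oracle_enumeration_realizes_every_state(self):
        """End states collected over *all* bi-alignments of a (2,2) instance
        equal the constructively computed closure."""
        observed = set()
        for cols in enumerate_bialignment_columns(2, 2):
            state = INITIAL_STATE
            for col in cols:
                state = state.update(col)
            observed.add(state)
        assert observed == set(reachable_states())

    def test_mode_state_table_sizes(self, toy_table):
        expected = {"linear": 1, "affine_gap": 9, "affine_shift": 9, "affine_both": 51}
        for mode, n in expected.items():
            cfg = ScoringConfig(substitution=toy_table, mode=mode, lambda_max=1)
            res = bialign("AB", "A", "HC", "H", cfg)
            assert res.n_states == n
            assert res.n_column_types == 15


class TestBand:
    def test_lambda_zero_keeps_diagonal_cells_only(self):
        assert band_filter(3, 5, 3, 5, 0)
        assert not band_filter(3, 5, 4, 5, 0)
        assert not band_filter(3, 5, 3, 4, 0)

    def test_wide_band_equals_unbanded(self, toy_table):
        rng = random.Random(2)
        for _ in range(20):
            seqs = random_instance(rng, max_len=4)
            cfg = random_params(rng, mode="affine_both", lambda_max=None)
            wide = replace(cfg, lambda_max=max(4, len(seqs[0]), len(seqs[1])))
            assert bialign(*seqs, wide).score == bialign(*seqs, cfg).score

    def test_cell_count_scales_quadratically_at_fixed_lambda(self, default_cfg):
        counts = {}
        for n in (10, 20, 40):
            fx = generate_fixture(FixtureSpec(length=n, n_shifts=0, magnitudes=()))
            tables = fill_tables(*fx[:4], default_cfg)
            counts[n] = tables.n_cells
        assert 3.5 < counts[20] / counts[10] < 4.5
        assert 3.5 < counts[40] / counts[20] < 4.5

    @given(st.integers(0, 3_000))
    def test_score_monotone_in_lambda(self, seed):
        rng = random.Random(seed)
        seqs = random_instance(rng, max_len=4)
        cfg = random_params(rng, mode="affine_both")
        scores = [
            bialign(*seqs, replace(cfg, lambda_max=lam)).score for lam in (0, 1, 2)
        ]
        assert scores == sorted(scores)


class TestEngineBasics:
    def test_empty_inputs(self, default_cfg):
        res = bialign("", "", "", "", default_cfg)
        assert res.score == 0
        assert res.alignment.columns == []

    def test_identical_inputs_all_match_closed_form(self, default_cfg):
        rng = random.Random(9)
        seq = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(30))
        struct = "".join(rng.choice("HETC") for _ in range(30))
        expected = sum(
            default_cfg.substitution.score(ch, ch) for ch in seq
        ) + 30 * default_cfg.structure_match
        for lam in (0, 2):
            res = bialign(
                seq, seq, struct, struct, replace(default_cfg, lambda_max=lam)
            )
            assert res.score == expected
            assert res.alignment.shift_count == 0
            assert all(col.shift == 0 for col in res.alignment.columns)

    def test_length_mismatch_rejected(self, default_cfg):
        with pytest.raises(LengthMismatchError):
            bialign("AC", "AC", "H", "HH", default_cfg)

    def test_unknown_residue_rejected(self, toy_table):
        cfg = ScoringConfig(substitution=toy_table)
        with pytest.raises(UnknownSymbolError):
            bialign("AZ", "A", "HC", "H", cfg)

    @given(st.integers(0, 3_000))
    def test_swapping_objects_preserves_score(self, seed):
        rng = random.Random(seed)
        seq_a, seq_b, str_a, str_b = random_instance(rng, max_len=3)
        cfg = random_params(rng, mode="affine_both", lambda_max=2)
        fwd = bialign(seq_a, seq_b, str_a, str_b, cfg).score
        rev = bialign(seq_b, seq_a, str_b, str_a, cfg).score
        assert fwd == rev


class TestTraceback:
    def test_rescoring_round_trip(self):
        rng = random.Random(77)
        for _ in range(25):
            seqs = random_instance(rng, max_len=4)
            mode = rng.choice(["linear", "affine_gap", "affine_shift", "affine_both"])
            cfg = random_params(rng, mode=mode, lambda_max=rng.choice([0, 1, 2, None]))
            res = bialign(*seqs, cfg)
            res.alignment.validate()
            assert score_bialignment(res.alignment, cfg) == pytest.approx(res.score)
            parts = decompose(res.alignment, cfg)
            assert parts["total"] == pytest.approx(res.score)

    def test_ties_resolve_to_fewest_shifts(self):
        """Among score-co-optimal bi-alignments the engine returns one with
        the minimum shift count (simpler shifts preferred)."""
        rng = random.Random(123)
        checked = 0
        for _ in range(40):
            seqs = random_instance(rng, max_len=2)
            mode = rng.choice(["linear", "affine_gap", "affine_both"])
            cfg = random_params(rng, mode=mode)
            best, optima = brute_force_bialign(*seqs, cfg)
            res = bialign(*seqs, cfg)
            assert res.score == pytest.approx(best)
            min_shifts = min(o.shift_count for o in optima)
            assert res.alignment.shift_count == min_shifts
            checked += len(optima) > 1
        assert checked >= 5  # the sweep really exercised ambiguous instances

    def test_deterministic_output(self, default_cfg):
        fx = generate_fixture(FixtureSpec(seed=5))
        first = bialign(*fx[:4], default_cfg)
        second = bialign(*fx[:4], default_cfg)
        assert first.alignment.columns == second.alignment.columns

    def test_corrupt_tables_detected(self, toy_table):
        cfg = ScoringConfig(substitution=toy_table, mode="affine_gap", lambda_max=1)
        tables = fill_tables("AB", "A", "HC", "H", cfg)
        tables.back[:] = -1
        with pytest.raises(Exception):
            traceback(tables)


class TestReductions:
    def test_forbidden_shifts_reduce_to_gotoh_on_combined_score(self, toy_table):
        """lambda = 0 plus a big shift penalty: bi-alignment equals Gotoh on
        the combined sequence+structure column score (gap columns then hit
        both U and V, hence doubled gap parameters)."""
        rng = random.Random(17)
        for _ in range(30):
            n1, n2 = rng.randint(0, 6), rng.randint(0, 6)
            seq_a = "".join(rng.choice("AB") for _ in range(n1))
            seq_b = "".join(rng.choice("AB") for _ in range(n2))
            str_a = "".join(rng.choice("HC") for _ in range(n1))
            str_b = "".join(rng.choice("HC") for _ in range(n2))
            for mode in ("affine_gap", "affine_both"):
                cfg = random_params(
                    rng, mode=mode, lambda_max=0, shift_extend=-10**6
                )
                combined = lambda i, j: (
                    cfg.substitution.score(seq_a[i], seq_b[j])
                    + (
                        cfg.structure_match
                        if str_a[i] == str_b[j]
                        else cfg.structure_mismatch
                    )
                )
                pair_cfg = replace(
                    cfg,
                    gap_open=2 * cfg.gap_open_effective,
                    gap_extend=2 * cfg.gap_extend,
                    mode="affine_gap",
                )
                expect = gotoh_align(seq_a, seq_b, pair_cfg, score_fn=combined)[0]
                got = bialign(seq_a, seq_b, str_a, str_b, cfg)
                assert got.score == pytest.approx(expect)
                assert got.alignment.shift_count == 0

    def test_zero_openings_collapse_affine_to_linear(self):
        rng = random.Random(29)
        for _ in range(35):
            seqs = random_instance(rng, max_len=4)
            base = random_params(
                rng, mode="linear", gap_open=0, shift_open=0, lambda_max=2
            )
            linear = bialign(*seqs, base).score
            for mode in ("affine_gap", "affine_shift", "affine_both"):
                assert bialign(*seqs, replace(base, mode=mode)).score == linear
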