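import math

import numpy as np
import pytest

from pairsub.errors import MasterFileError, MatrixError, MatrixParseError
from pairsub.matrices import (
    Conservation,
    FrequencyModel,
    MatrixConfig,
    PREDEFINED_MATRICES,
    SubstitutionMatrix,
    conservation_call,
    load_predefined,
    log_odds_from_frequencies,
    lookup,
    parse_master_file,
    parse_matrix_text,
    parse_predefined_spec,
    recover_pair_frequencies,
)

TOY_TEXT = "# toy\nA C\nA 1 -1\nC -1 1\n"


class TestPredefined:
    @pytest.mark.parametrize("name", PREDEFINED_MATRICES)
    def test_all_ten_load_and_are_symmetric(self, name):
        m = load_predefined(name)
        assert np.array_equal(m.scores, m.scores.T)
        assert len(m.alphabet) >= 20
        assert set("ACDEFGHIKLMNPQRSTVWY") <= set(m.alphabet)

    def test_blosum62_e_q_scores_2(self, blosum62):
        assert blosum62.lookup("E", "Q") == 2.0

    def test_unknown_name_lists_available(self):
        with pytest.raises(MatrixError, match="PAM30"):
            load_predefined("PAM999")

    def test_case_insensitive(self):
        assert load_predefined("blosum62") == load_predefined("BLOSUM62")

    def test_text_round_trip(self, blosum62):
        assert parse_matrix_text(blosum62.to_text(), "B62") == blosum62

    def test_bundled_file_reparse_equals_load(self):
        from importlib import resources

        text = (resources.files("pairsub") / "data" / "BLOSUM62.txt").read_text("utf-8")
        assert parse_matrix_text(text, "BLOSUM62") == load_predefined("BLOSUM62")


class TestParseMatrixText:
    def test_toy_two_by_two(self):
        m = parse_matrix_text(TOY_TEXT, "toy")
        assert m.alphabet == ("A", "C")
        assert m.lookup("A", "A") == 1.0
        assert m.lookup("A", "C") == -1.0

    def test_missing_cell_names_row(self):
        with pytest.raises(MatrixParseError, match="row 'C'"):
            parse_matrix_text("A C\nA 1 -1\nC -1\n", "toy")

    def test_non_numeric_cell_names_context(self):
        with pytest.raises(MatrixParseError, match="'x'"):
            parse_matrix_text("A C\nA 1 x\nC -1 1\n", "toy")

    def test_non_square(self):
        with pytest.raises(MatrixParseError, match="non-square"):
            parse_matrix_text("A C\nA 1 -1\n", "toy")

    def test_unknown_row_label(self):
        with pytest.raises(MatrixParseError, match="'D'"):
            parse_matrix_text("A C\nA 1 -1\nD -1 1\n", "toy")

    def test_asymmetry_is_error_by_default(self):
        with pytest.raises(MatrixParseError, match="asymmetric"):
            parse_matrix_text("A C\nA 1 -1\nC -2 1\n", "toy")

    def test_asymmetry_symmetrize_flag_averages(self):
        m = parse_matrix_text("A C\nA 1 -1\nC -2 1\n", "toy", symmetrize=True)
        assert m.lookup("A", "C") == -1.5

    def test_real_values_accepted(self):
        m = parse_matrix_text("A C\nA 1.5 -0.25\nC -0.25 2.0\n", "toy")
        assert m.lookup("A", "A") == 1.5


class TestMasterFile:
    def write_toy(self, tmp_path, name="dis.txt"):
        (tmp_path / name).write_text(TOY_TEXT)

    def test_repeat_filename_with_penalties(self, tmp_path):
        self.write_toy(tmp_path)
        master = tmp_path / "master.txt"
        master.write_text("dis.txt -3.2 -0.1\ndis.txt -10 -0.6\n")
        configs = parse_master_file(master)
        assert [c.label for c in configs] == ["CM0", "CM1"]
        assert (configs[0].gap_open, configs[0].gap_extend) == (-3.2, -0.1)
        assert (configs[1].gap_open, configs[1].gap_extend) == (-10.0, -0.6)
        assert configs[0].matrix == configs[1].matrix

    def test_missing_penalties(self, tmp_path):
        self.write_toy(tmp_path, "m.txt")
        master = tmp_path / "master.txt"
        master.write_text("m.txt\n")
        with pytest.raises(MasterFileError, match="missing penalties"):
            parse_master_file(master)

    def test_single_penalty_is_missing_penalties(self, tmp_path):
        self.write_toy(tmp_path, "m.txt")
        master = tmp_path / "master.txt"
        master.write_text("m.txt -3\n")
        with pytest.raises(MasterFileError, match="missing penalties"):
            parse_master_file(master)

    def test_unresolvable_filename(self, tmp_path):
        master = tmp_path / "master.txt"
        master.write_text("ghost.txt -3 -1\n")
        with pytest.raises(MasterFileError, match="not found"):
            parse_master_file(master)

    def test_empty_master_is_empty_list(self, tmp_path):
        master = tmp_path / "master.txt"
        master.write_text("")
        assert parse_master_file(master) == []

    def test_no_master_file_dedicated_error(self, tmp_path):
        with pytest.raises(MasterFileError, match="master file"):
            parse_master_file(tmp_path / "absent.txt")


class TestLookupAndConservation:
    def test_blosum62_symmetric_lookup_all_pairs(self, blosum62):
        for a in blosum62.alphabet:
            for b in blosum62.alphabet:
                assert lookup(blosum62, a, b) == lookup(blosum62, b, a)

    def test_gap_lookup_is_undefined(self, blosum62):
        with pytest.raises(MatrixError, match="undefined"):
            lookup(blosum62, "-", "A")

    def test_unknown_residue_strict(self, toy_matrix):
        with pytest.raises(MatrixError, match="'W'"):
            toy_matrix.lookup("W", "A")

    def test_unknown_residue_lenient_scores_zero(self, toy_matrix):
        assert toy_matrix.lookup("W", "A", lenient=True) == 0.0

    def test_e_q_is_conservative(self, blosum62):
        assert conservation_call(blosum62, "E", "Q") is Conservation.CONSERVATIVE

    def test_negative_score_non_conservative(self, toy_matrix):
        assert toy_matrix.conservation_call("A", "C") is Conservation.NON_CONSERVATIVE

    def test_zero_score_neutral(self):
        m = SubstitutionMatrix("z", "AC", np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert m.conservation_call("A", "C") is Conservation.NEUTRAL

    def test_sign_partition_exhaustive(self, blosum62):
        for a in blosum62.alphabet:
            for b in blosum62.alphabet:
                s = blosum62.lookup(a, b)
                call = blosum62.conservation_call(a, b)
                expected = (
                    Conservation.CONSERVATIVE
                    if s > 0
                    else Conservation.NON_CONSERVATIVE
                    if s < 0
                    else Conservation.NEUTRAL
                )
                assert call is expected


def uniform_model(k=3, q_scale=1.0, lam=1.0):
    alphabet = tuple("ACD"[:k])
    p = np.full(k, 1.0 / k)
    q = np.outer(p, p) * q_scale
    return FrequencyModel(alphabet=alphabet, pair_frequencies=q, background=p, scale=lam)


class TestLogOdds:
    def test_q_equal_expected_gives_zero_matrix(self):
        m = log_odds_from_frequencies(uniform_model())
        assert np.allclose(m.scores, 0.0)

    def test_doubling_lambda_halves_scores(self):
        m1 = log_odds_from_frequencies(uniform_model(q_scale=2.0, lam=1.0))
        m2 = log_odds_from_frequencies(uniform_model(q_scale=2.0, lam=2.0))
        assert np.allclose(m1.scores, 2.0 * m2.scores, atol=1e-12)

    def test_hand_evaluated_entry(self):
        # q = 0.02, p_i = p_j = 0.1, lambda = ln 2  ->  s = ln(2) / ln(2) = 1
        p = np.array([0.1, 0.9])
        q = np.array([[0.02, 0.08], [0.08, 0.81]])
        model = FrequencyModel(("A", "C"), q, p, math.log(2.0))
        m = log_odds_from_frequencies(model)
        assert m.lookup("A", "A") == pytest.approx(1.0, abs=1e-12)

    def test_zero_probability_is_domain_error(self):
        p = np.array([0.5, 0.5])
        q = np.array([[0.0, 0.25], [0.25, 0.25]])
        with pytest.raises(MatrixError):
            FrequencyModel(("A", "C"), q, p, 1.0)

    def test_nonpositive_lambda_rejected(self):
        p = np.array([0.5, 0.5])
        q = np.outer(p, p)
        with pytest.raises(MatrixError, match="lambda"):
            FrequencyModel(("A", "C"), q, p, 0.0)

    def test_inverse_recovers_pair_frequencies(self):
        rng = np.random.default_rng(7)
        p = rng.dirichlet(np.ones(4))
        base = rng.uniform(0.05, 0.5, size=(4, 4))
        q = (base + base.T) / 2.0
        model = FrequencyModel(tuple("ACDE"), q, p, 0.7)
        m = log_odds_from_frequencies(model)
        assert np.allclose(recover_pair_frequencies(m, model), q, atol=1e-12)


class TestMatrixConfig:
    def test_positive_penalties_are_negated(self, toy_matrix):
        cfg = MatrixConfig(matrix=toy_matrix, gap_open=3.0, gap_extend=0.5, label="x")
        assert cfg.gap_open == -3.0
        assert cfg.gap_extend == -0.5

    def test_gap_cost_first_position_pays_both(self, toy_matrix):
        cfg = MatrixConfig(matrix=toy_matrix, gap_open=-2.0, gap_extend=-1.0, label="x")
        assert cfg.gap_cost(0) == 0.0
        assert cfg.gap_cost(1) == -3.0
        assert cfg.gap_cost(3) == -5.0

    def test_predefined_spec_parsing(self):
        configs = parse_predefined_spec("BLOSUM62:-10:-0.5,PAM70:-10:-0.5")
        assert [c.label for c in configs] == ["BLOSUM62", "PAM70"]
        assert configs[0].gap_open == -10.0

    def test_predefined_spec_bad_shape(self):
        with pytest.raises(MatrixError, match="NAME:gap_open:gap_extend"):
            parse_predefined_spec("BLOSUM62:-10")
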