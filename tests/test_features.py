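"""Feature encoding: name grammar, readers, frequency table, providers."""

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from cleavesite.dataset import PeptideWindow, ProteinRecord
from cleavesite.errors import FormatError, ValidationError
from cleavesite.features import (
    ATCHLEY_FACTORS,
    FAMILY_ORDER,
    FAMILY_WIDTHS,
    PSSM_ALPHABET,
    FrequencyTable,
    PSSMProfile,
    build_frequency_table,
    encode_residue,
    encode_windows,
    feature_names,
    format_feature_name,
    load_pssm,
    parse_feature_name,
    synthetic_providers,
    write_pssm,
)
from cleavesite.synthesize import MotifSpec


class TestNameGrammar:
    def test_grammar_round_trips_for_all_columns(self):
        for w in (16, 18, 20, 22):
            names = feature_names(w)
            assert len(names) == w * 32
            assert len(set(names)) == len(names)
            for name in names:
                s, fam, k = parse_feature_name(name)
                assert format_feature_name(s, fam, k) == name

    def test_known_landmark_names(self):
        names = feature_names(22)
        # site 11, pssm column 20 targets valine
        assert "AA11_pssm_20" in names
        assert PSSM_ALPHABET[20 - 1] == "V"
        assert PSSM_ALPHABET[4 - 1] == "D" and PSSM_ALPHABET[2 - 1] == "R"

    def test_family_order_within_each_site(self):
        names = feature_names(16)
        per_site = names[:32]
        fams = [parse_feature_name(n)[1] for n in per_site]
        widths = [fams.count(f) for f in FAMILY_ORDER]
        assert fams == [f for f in FAMILY_ORDER for _ in range(FAMILY_WIDTHS[f])]
        assert widths == [20, 1, 5, 2, 3, 1]

    def test_bad_names_rejected(self):
        for bad in ("AA0_pssm_21", "AA3_zzz_1", "pssm_1", "AA2_pssm_0"):
            with pytest.raises(ValidationError):
                parse_feature_name(bad)


class TestPSSMReader:
    def test_small_fixture(self, tmp_path):
        prof = PSSMProfile(np.arange(100).reshape(5, 20))
        write_pssm(prof, "ACDEF", tmp_path / "m.pssm")
        back = load_pssm(tmp_path / "m.pssm", sequence="ACDEF")
        assert back.scores.shape == (5, 20)
        np.testing.assert_array_equal(back.scores, prof.scores)

    def test_malformed_row_reports_line(self, tmp_path):
        text = "  " + "   ".join(PSSM_ALPHABET) + "\n    1 A " + " 1" * 19 + "\n"
        (tmp_path / "bad.pssm").write_text(text)
        with pytest.raises(FormatError, match="bad.pssm:2"):
            load_pssm(tmp_path / "bad.pssm")

    def test_length_mismatch(self, tmp_path):
        write_pssm(PSSMProfile(np.zeros((3, 20))), "ACD", tmp_path / "m.pssm")
        with pytest.raises(FormatError, match="3 rows"):
            load_pssm(tmp_path / "m.pssm", sequence="ACDEF")

    @settings(max_examples=25, derandomize=True,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(seed=st.integers(0, 2 ** 31 - 1))
    def test_round_trip_random_integer_matrices(self, seed, tmp_path):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(1, 30))
        scores = rng.integers(-12, 13, size=(L, 20)).astype(float)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), L))
        write_pssm(PSSMProfile(scores), seq, tmp_path / "r.pssm")
        back = load_pssm(tmp_path / "r.pssm", sequence=seq)
        np.testing.assert_array_equal(back.scores, scores)


class TestFrequencyTable:
    def _win(self, residues):
        return PeptideWindow(residues, len(residues), 1, ("A", 1))

    def test_degenerate_point_mass(self):
        wins = [self._win("A" * 10 + "R" + "A" * 11) for _ in range(10)]
        table = build_frequency_table(wins)
        assert table.lookup(11, "R") == 1.0

    def test_hand_counted_mixture(self):
        wins = [self._win(c + "A" * 15) for c in "AAXC"]
        table = build_frequency_table(wins)
        assert table.lookup(1, "A") == 0.5
        assert table.lookup(1, "X") == 0.25
        assert table.lookup(1, "C") == 0.25

    def test_rows_always_sum_to_one(self, small_bundle):
        table = build_frequency_table(small_bundle["positives"])
        np.testing.assert_allclose(table.table.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            build_frequency_table([])


class TestEncodeResidue:
    def _freq(self):
        t = np.full((22, 21), 1 / 21)
        return FrequencyTable(t)

    def test_padding_symbol_is_all_zero(self):
        vec = encode_residue("X", 3, np.ones(20), 0.9, ("H", "b"), self._freq())
        assert vec.shape == (32,) and not vec.any()

    def test_concatenation_layout(self):
        table = np.full((22, 21), 0.0)
        table[:, 0] = 0.5   # symbol A
        table[:, 1:] = 0.5 / 20
        freq = FrequencyTable(table)
        pssm_row = np.arange(20.0)
        vec = encode_residue("A", 4, pssm_row, 0.2, ("H", "b"), freq)
        np.testing.assert_array_equal(vec[:20], pssm_row)
        assert vec[20] == 0.2
        np.testing.assert_array_equal(vec[21:26], ATCHLEY_FACTORS["A"])
        np.testing.assert_array_equal(vec[26:28], [1, 0])  # buried
        np.testing.assert_array_equal(vec[28:31], [1, 0, 0])  # helix
        assert vec[31] == 0.5

    def test_one_hot_alternatives(self):
        freq = self._freq()
        v = encode_residue("C", 1, np.zeros(20), 0.0, ("E", "e"), freq)
        np.testing.assert_array_equal(v[26:28], [0, 1])
        np.testing.assert_array_equal(v[28:31], [0, 1, 0])
        v = encode_residue("C", 1, np.zeros(20), 0.0, ("O", "b"), freq)
        np.testing.assert_array_equal(v[28:31], [0, 0, 1])

    def test_unknown_symbol(self):
        with pytest.raises(ValidationError):
            encode_residue("B", 1, np.zeros(20), 0.0, ("H", "b"), self._freq())


class TestEncodeWindows:
    @pytest.mark.parametrize("w,expected", [(16, 512), (18, 576), (20, 640),
                                            (22, 704)])
    def test_column_counts(self, small_bundle, w, expected):
        from cleavesite.dataset import positive_windows

        b = small_bundle
        wins = positive_windows(b["records"], w)
        freq = build_frequency_table(wins)
        matrix = encode_windows(wins, b["providers"], freq)
        assert matrix.values.shape == (len(wins), expected)
        assert matrix.columns == feature_names(w)

    def test_encoding_is_pure(self, small_bundle):
        b = small_bundle
        m1 = encode_windows(b["positives"], b["providers"], b["freq"])
        m2 = encode_windows(b["positives"], b["providers"], b["freq"])
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_all_x_window_is_zero_row(self, small_bundle):
        b = small_bundle
        win = PeptideWindow("X" * 22, 22, 0,
                            (b["records"][0].accession, 5))
        m = encode_windows([win], b["providers"], b["freq"])
        assert not m.values.any()

    def test_missing_provider_names_accession(self, small_bundle):
        b = small_bundle
        win = PeptideWindow("A" * 22, 22, 0, ("UNKNOWN", 30))
        with pytest.raises(KeyError, match="UNKNOWN"):
            encode_windows([win], b["providers"], b["freq"])

    def test_changing_freq_table_touches_only_freq_columns(self, small_bundle):
        b = small_bundle
        other = FrequencyTable(np.full((22, 21), 1 / 21))
        m1 = encode_windows(b["positives"], b["providers"], b["freq"])
        m2 = encode_windows(b["positives"], b["providers"], other)
        changed = {
            m1.columns[j]
            for j in np.flatnonzero((m1.values != m2.values).any(axis=0))
        }
        assert changed  # the two tables do differ
        assert all(parse_feature_name(c)[1] == "freq" for c in changed)


class TestSyntheticProviders:
    def test_deterministic_under_seed(self, small_bundle):
        recs = small_bundle["records"]
        p1 = synthetic_providers(recs, MotifSpec(), np.random.default_rng(3))
        p2 = synthetic_providers(recs, MotifSpec(), np.random.default_rng(3))
        acc = recs[0].accession
        np.testing.assert_array_equal(p1.pssm_for(acc).scores,
                                      p2.pssm_for(acc).scores)
        assert p1.structure_for(acc).ss == p2.structure_for(acc).ss

    def test_profile_lengths_match(self, small_bundle):
        small_bundle["providers"].validate(small_bundle["records"])

    def test_pssm_argmax_tracks_sequence(self, small_bundle):
        recs = small_bundle["records"]
        prov = small_bundle["providers"]
        hits = total = 0
        for r in recs:
            am = prov.pssm_for(r.accession).scores.argmax(axis=1)
            own = np.array([PSSM_ALPHABET.index(c) for c in r.sequence])
            hits += int((am == own).sum())
            total += len(r.sequence)
        assert hits / total >= 0.8
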