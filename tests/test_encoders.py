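import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acp_ada.encoders import (
    EncoderConfig,
    encode_aac,
    encode_aaindex_full,
    encode_bpf,
    encode_dataset,
)
from acp_ada.io import ALPHABET, AA_TO_INDEX, PeptideRecord
from acp_ada.preprocess import LengthConfig, normalize_length
from acp_ada.selection import SelectionModel

CFG10 = EncoderConfig(Lx=10, k_bpf=7, n_selected=5)


def norm(seq, lx=10, label=None):
    return normalize_length(PeptideRecord("p", seq, label=label), LengthConfig(lx))


class TestBPF:
    @pytest.mark.parametrize("aa,hot", [("A", 0), ("C", 1), ("Y", 19)])
    def test_first_position_one_hot(self, aa, hot):
        vec = encode_bpf(norm(aa * 10), CFG10)
        group = vec[:20]
        assert group[hot] == 1.0 and group.sum() == 1.0

    def test_known_flat_indices(self):
        # A,C,D,E,F,G,H occupy alphabet positions 0..6 -> flat 20i + i
        vec = encode_bpf(norm("ACDEFGH"), CFG10)
        assert set(np.flatnonzero(vec)) == {0, 21, 42, 63, 84, 105, 126}

    def test_pad_only_prefix_is_all_zero(self):
        rec = PeptideRecord("p", "X" * 10)
        assert not encode_bpf(rec, CFG10).any()

    def test_rejects_unnormalized_record(self):
        with pytest.raises(ValueError, match="normalized"):
            encode_bpf(PeptideRecord("p", "ACD"), CFG10)

    @given(seq=st.text(alphabet=ALPHABET, min_size=1, max_size=10))
    def test_one_hot_group_structure(self, seq):
        rec = norm(seq)
        vec = encode_bpf(rec, CFG10)
        groups = vec.reshape(7, 20)
        assert set(np.unique(vec)) <= {0.0, 1.0}
        # exactly one hot entry per non-pad position, zero for pad
        expected = [1 if aa != "X" else 0 for aa in rec.sequence[:7]]
        assert groups.sum(axis=1).tolist() == expected


class TestAAIndex:
    def test_constant_property_fills_every_slot(self, toy_table):
        vec = encode_aaindex_full(norm("ACDEFGHIKL"), toy_table, CFG10)
        assert vec.shape == (10 * 2,)
        assert np.all(vec[0::2] == 1.0)  # p_const slots

    def test_single_residue_lookup(self, toy_table):
        # "A" + 9 pads: only the first n_properties entries are non-pad
        vec = encode_aaindex_full(norm("A"), toy_table, CFG10)
        np.testing.assert_array_equal(vec[:2], toy_table.residue_profile("A"))
        assert not vec[2:].any()

    def test_residue_major_layout(self, toy_table):
        vec = encode_aaindex_full(norm("CY"), toy_table, CFG10)
        # position 0 = C (rank 1), position 1 = Y (rank 19)
        assert vec[1] == 1.0 and vec[3] == 19.0

    def test_full_dimension_with_packaged_table(self, property_table):
        cfg = EncoderConfig(Lx=40)
        vec = encode_aaindex_full(norm("ACDEF", lx=40), property_table, cfg)
        assert vec.shape == (40 * property_table.n_properties,)

    def test_scaled_properties_are_zero_mean(self, property_table):
        cfg = EncoderConfig(Lx=20, scale_properties=True)
        rec = norm("ACDEFGHIKLMNPQRSTVWY", lx=20)
        vec = encode_aaindex_full(rec, property_table, cfg).reshape(20, -1)
        np.testing.assert_allclose(vec.mean(axis=0), 0.0, atol=1e-12)


class TestAAC:
    def test_single_residue_type(self):
        vec = encode_aac(norm("AAAA"), CFG10)
        assert vec[AA_TO_INDEX["A"]] == 1.0 and vec.sum() == 1.0

    def test_uniform_twenty_mer(self):
        vec = encode_aac(norm(ALPHABET, lx=20), EncoderConfig(Lx=20))
        np.testing.assert_allclose(vec, 0.05)

    def test_half_and_half(self):
        vec = encode_aac(norm("ACCA"), CFG10)
        assert vec[AA_TO_INDEX["A"]] == 0.5 and vec[AA_TO_INDEX["C"]] == 0.5
        assert vec.sum() == 1.0

    def test_original_length_denominator_switch(self):
        cfg = EncoderConfig(Lx=10, aac_denominator="original")
        rec = norm("A" * 15)  # truncated to 10, original length 15
        vec = encode_aac(rec, cfg)
        assert vec[AA_TO_INDEX["A"]] == pytest.approx(10 / 15)

    def test_all_pad_sequence_rejected(self):
        with pytest.raises(ValueError, match="all-pad"):
            encode_aac(PeptideRecord("p", "X" * 10), CFG10)

    @given(seq=st.text(alphabet=ALPHABET, min_size=1, max_size=10))
    def test_sums_to_one_for_unpadded_content(self, seq):
        vec = encode_aac(norm(seq), CFG10)
        assert vec.sum() == pytest.approx(1.0)


class TestEncodeDataset:
    def _selection(self, table, cfg):
        d = cfg.Lx * table.n_properties
        return SelectionModel(tuple(range(cfg.n_selected)),
                              (0.0,) * cfg.n_selected, d)

    def test_default_geometry_is_210(self, property_table):
        cfg = EncoderConfig(Lx=50)
        recs = [norm("ACDEFGHIKL", lx=50, label=1),
                norm("KKKKRRRR", lx=50, label=0)]
        fm, y = encode_dataset(recs, property_table,
                               self._selection(property_table, cfg), cfg)
        assert fm.X.shape == (2, 210)
        assert fm.blocks == {"bpf": (0, 140), "aaindex": (140, 190),
                             "aac": (190, 210)}
        assert y.tolist() == [1, 0]

    def test_empty_record_list(self, property_table):
        cfg = EncoderConfig(Lx=50)
        fm, y = encode_dataset([], property_table,
                               self._selection(property_table, cfg), cfg)
        assert fm.X.shape == (0, 210) and y is None

    def test_row_equals_manual_concatenation(self, toy_table):
        cfg = CFG10
        rec = norm("ACDEFGHIKL")
        sel = self._selection(toy_table, cfg)
        fm, _ = encode_dataset([rec], toy_table, sel, cfg)
        manual = np.concatenate([
            encode_bpf(rec, cfg),
            encode_aaindex_full(rec, toy_table, cfg)[:cfg.n_selected],
            encode_aac(rec, cfg),
        ])
        np.testing.assert_array_equal(fm.X[0], manual)

    def test_block_subsets_change_dimension(self, toy_table):
        rec = norm("ACDEFGHIKL")
        fm, _ = encode_dataset([rec], toy_table, None, CFG10, blocks=("aac",))
        assert fm.X.shape == (1, 20)
        fm, _ = encode_dataset([rec], toy_table, None, CFG10,
                               blocks=("bpf", "aac"))
        assert fm.X.shape == (1, 160)

    def test_aaindex_block_requires_selection(self, toy_table):
        with pytest.raises(ValueError, match="SelectionModel"):
            encode_dataset([norm("ACD")], toy_table, None, CFG10)

    def test_dimension_mismatch_rejected(self, toy_table):
        bad = SelectionModel((0, 1, 2, 3, 4), (0.0,) * 5, 99)
        with pytest.raises(ValueError, match="fitted"):
            encode_dataset([norm("ACD")], toy_table, bad, CFG10)

    def test_permutation_beyond_k_leaves_bpf_and_aac_unchanged(self, toy_table):
        cfg = CFG10
        a = norm("ACDEFGHIKL")
        b = norm("ACDEFGHLKI")  # tail IKL -> LKI
        sel = self._selection(toy_table, cfg)
        fa, _ = encode_dataset([a], toy_table, sel, cfg)
        fb, _ = encode_dataset([b], toy_table, sel, cfg)
        np.testing.assert_array_equal(fa.block("bpf"), fb.block("bpf"))
        np.testing.assert_array_equal(fa.block("aac"), fb.block("aac"))

    def test_csv_export_has_block_names(self, toy_table, tmp_path):
        cfg = CFG10
        sel = self._selection(toy_table, cfg)
        fm, _ = encode_dataset([norm("ACDEFGHIKL")], toy_table, sel, cfg)
        df = fm.to_dataframe()
        assert list(df.columns[:2]) == ["bpf_0", "bpf_1"]
        assert list(df.columns[-2:]) == ["aac_W", "aac_Y"]
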