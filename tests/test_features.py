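"""Windowed feature extraction: oracle equivalence and invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morfnet.features import (
    BinaryMapping,
    ChannelStandardizer,
    DISORDER_PROMOTING_MAPPING,
    EntropyChannel,
    FeatureSetSpec,
    ScaleChannel,
    WindowConfig,
    build_feature_matrices,
    feature_tensor,
    pad_counts,
    residue_features,
    topological_entropy,
    window_vectors,
)
from morfnet.io_formats import STANDARD_AMINO_ACIDS, AnnotatedSequence, PropertyScale

from conftest import oracle_residue_features, oracle_topological_entropy


def make_scale(values_by_aa, accession="TST0000001"):
    vals = {aa: values_by_aa.get(aa, 0.0) for aa in STANDARD_AMINO_ACIDS}
    return PropertyScale(accession, "test scale", vals)


def single_scale_spec(scale):
    return FeatureSetSpec("one", (ScaleChannel(scale),))


class TestPadCounts:
    @pytest.mark.parametrize(
        "N,expected",
        [(45, (22, 22)), (10, (4, 5)), (2, (0, 1)), (90, (44, 45)), (3, (1, 1))],
    )
    def test_left_floor_right_ceiling(self, N, expected):
        assert pad_counts(N) == expected

    def test_total_padding_keeps_L_window_positions(self):
        for N in range(2, 30):
            left, right = pad_counts(N)
            assert left + right == N - 1

    def test_window_below_two_rejected(self):
        with pytest.raises(ValueError):
            pad_counts(1)


class TestTopologicalEntropy:
    def test_constant_string_gives_zero(self):
        assert topological_entropy("0000000000") == 0.0
        assert topological_entropy("1" * 17) == 0.0

    def test_de_bruijn_prefix_gives_one(self):
        # first 10 symbols contain all 8 distinct 3-mers
        assert topological_entropy("0001011100") == pytest.approx(1.0)

    def test_alternating_string(self):
        # only {010, 101} occur among the 3-mers of the counted prefix
        assert topological_entropy("0101010101") == pytest.approx(1.0 / 3.0)

    def test_matches_brute_force_on_all_strings_up_to_length_10(self):
        for n in range(2, 11):
            for word in itertools.product("01", repeat=n):
                s = "".join(word)
                assert topological_entropy(s) == pytest.approx(
                    oracle_topological_entropy(s), abs=1e-12
                )

    def test_invariant_under_complementation(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            bits = "".join(str(b) for b in rng.integers(0, 2, size=20))
            flipped = bits.translate(str.maketrans("01", "10"))
            assert topological_entropy(bits) == pytest.approx(
                topological_entropy(flipped)
            )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            topological_entropy("0")


class TestWindowVectors:
    def test_constant_sequence_zero_fill_arithmetic(self):
        scale = make_scale({"A": 2.0})
        seq = AnnotatedSequence("c", "AAAAA")
        v = window_vectors(seq, single_scale_spec(scale), 3)
        # N=3 pads one zero each side; first window = (0+2+2)/3
        assert v[0, 0] == pytest.approx(4.0 / 3.0)
        assert v[2, 0] == pytest.approx(2.0)
        assert v.shape == (5, 1)

    def test_zero_scale_gives_zero_channel(self):
        scale = make_scale({})
        seq = AnnotatedSequence("z", "MKVLIVQ")
        v = window_vectors(seq, single_scale_spec(scale), 4)
        assert np.all(v == 0.0)

    def test_entropy_channel_padded_positions_are_zero_symbols(self):
        spec = FeatureSetSpec("e", (EntropyChannel(BinaryMapping(frozenset("A"))),))
        seq = AnnotatedSequence("e1", "AAAAAAAAAA")
        v = window_vectors(seq, spec, 10)
        # the window aligned with the all-A run is all ones -> entropy 0;
        # edge windows mix padded zeros with ones, giving positive complexity
        assert v[4, 0] == pytest.approx(0.0)
        assert v[0, 0] > 0.0


class TestResidueFeatures:
    def test_constant_vectors_are_fixed_point(self):
        v = np.full((9, 4), 3.25)
        x = residue_features(v, 9, 5)
        assert np.allclose(x, 3.25)

    def test_hand_worked_left_edge_cover(self):
        # L=7, N=3: residue 1 (padded pos 2) is covered by windows {1, 2}
        v = np.arange(1.0, 8.0)[:, None]
        x = residue_features(v, 7, 3)
        assert x[0, 0] == pytest.approx((1.0 + 2.0) / 2.0)
        # interior residue j=4 covered by windows {3,4,5}
        assert x[3, 0] == pytest.approx(4.0)

    def test_interior_residue_averages_exactly_n_windows(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=(40, 2))
        N = 7
        x = residue_features(v, 40, N)
        left, _ = pad_counts(N)
        j = 20  # 1-based interior
        lo, hi = j + left - N + 1, j + left
        assert np.allclose(x[j - 1], v[lo - 1 : hi].mean(axis=0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            residue_features(np.zeros((5, 2)), 6, 3)

    @given(
        st.integers(min_value=1, max_value=50),
        st.integers(min_value=2, max_value=12),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=120, deadline=None)
    def test_streaming_equals_brute_force_oracle(self, L, N, seed):
        rng = np.random.default_rng(seed)
        residues = "".join(rng.choice(list(STANDARD_AMINO_ACIDS), size=L))
        values = dict(zip(STANDARD_AMINO_ACIDS, rng.normal(size=20)))
        scale = make_scale(values)
        seq = AnnotatedSequence("p", residues)
        v = window_vectors(seq, single_scale_spec(scale), N)
        x = residue_features(v, L, N)
        expected = oracle_residue_features(residues, values, N)
        assert np.allclose(x[:, 0], expected, atol=1e-9)

    def test_cover_weights_sum_to_one(self):
        # averaging a channel of ones must return ones everywhere
        for N in (2, 5, 10, 13):
            v = np.ones((25, 1))
            assert np.allclose(residue_features(v, 25, N), 1.0)


class TestBuildFeatureMatrices:
    def test_default_shapes_for_three_set_widths(self, random_scale):
        seq = AnnotatedSequence("s", "ACDEFGHIKLMNPQRSTVWY" * 6)
        for F in (16, 13, 14):
            channels = tuple(
                ScaleChannel(
                    PropertyScale(f"S{c:07d}", "x", random_scale.values)
                )
                for c in range(F - 1)
            ) + (EntropyChannel(),)
            spec = FeatureSetSpec(f"w{F}", channels)
            mats = build_feature_matrices(seq, spec)
            assert all(m.matrix.shape == (3, F) for m in mats)
            assert len(mats) == len(seq)
            assert [m.position for m in mats[:3]] == [1, 2, 3]

    def test_single_residue_sequence(self, random_scale):
        seq = AnnotatedSequence("one", "M")
        spec = single_scale_spec(random_scale)
        mats = build_feature_matrices(seq, spec, WindowConfig((2, 3)))
        assert len(mats) == 1
        assert mats[0].matrix.shape == (2, 1)
        # with one residue every window average equals the single window
        v2 = window_vectors(seq, spec, 2)
        assert mats[0].matrix[0, 0] == pytest.approx(v2[0, 0])

    def test_channel_permutation_permutes_columns(self, random_scale):
        rng = np.random.default_rng(11)
        scales = [
            make_scale(dict(zip(STANDARD_AMINO_ACIDS, rng.normal(size=20))),
                       accession=f"P{i:07d}")
            for i in range(4)
        ]
        seq = AnnotatedSequence("perm", "MKVLIVQWERTYACDF")
        spec = FeatureSetSpec("fwd", tuple(ScaleChannel(s) for s in scales))
        perm = [2, 0, 3, 1]
        spec_p = FeatureSetSpec(
            "perm", tuple(ScaleChannel(scales[i]) for i in perm)
        )
        t = feature_tensor(seq, spec)
        tp = feature_tensor(seq, spec_p)
        assert np.allclose(tp, t[:, :, perm])


class TestStandardizer:
    def test_fit_transform_zeroes_mean_and_unit_sd(self):
        rng = np.random.default_rng(5)
        x = rng.normal(2.0, 3.0, size=(200, 3, 4))
        std = ChannelStandardizer()
        z = std.fit_transform(x)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=0), 1.0, atol=1e-9)

    def test_constant_channel_passes_through_with_warning(self):
        x = np.random.default_rng(0).normal(size=(50, 2, 2))
        x[:, 0, 0] = 7.0
        std = ChannelStandardizer()
        with pytest.warns(UserWarning, match="constant"):
            z = std.fit_transform(x)
        assert np.allclose(z[:, 0, 0], 7.0)

    def test_transform_uses_training_parameters_only(self):
        rng = np.random.default_rng(1)
        train = rng.normal(size=(100, 2, 2))
        other = rng.normal(5.0, 2.0, size=(50, 2, 2))
        std = ChannelStandardizer().fit(train)
        z = std.transform(other)
        expected = (other - train.mean(axis=0)) / train.std(axis=0)
        assert np.allclose(z, expected)

    def test_double_transform_is_not_identity(self):
        x = np.array([[[0.0]], [[2.0]]])
        std = ChannelStandardizer().fit(x)
        once = std.transform(x)
        twice = std.transform(once)
        assert not np.allclose(once, twice)

    def test_empty_fitting_set_rejected(self):
        with pytest.raises(ValueError):
            ChannelStandardizer().fit(np.zeros((1, 2, 2)))
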