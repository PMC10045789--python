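"""Thresholding, entropy coding, color transforms and the container."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stegowave import (
    CompressedContainer,
    CompressionConfig,
    ConfigError,
    ContractError,
    CorruptionError,
    FormatError,
    Image8,
    PhantomSpec,
    ThresholdRule,
    TruncationError,
    compress,
    decompress,
    generate_phantom,
    hard_threshold,
    huffman_decode,
    huffman_encode,
    mse,
    rct_forward,
    rct_inverse,
    rgb_to_ycbcr,
    shannon_entropy,
    soft_threshold,
    ycbcr_to_rgb,
)
from stegowave.compression import SymbolModel, mean_code_length, threshold_tree
from stegowave.wavelet import packet_decompose, packet_reconstruct
from tests.conftest import random_image


class TestThresholds:
    @pytest.mark.parametrize(
        "x,t,hard,soft",
        [(5, 3, 5, 2), (-5, 3, -5, -2), (2, 3, 0, 0), (-2, 3, 0, 0), (7, 0, 7, 7)],
    )
    def test_pointwise_rules(self, x, t, hard, soft):
        assert hard_threshold(np.array([x]), t)[0] == hard
        assert soft_threshold(np.array([x]), t)[0] == soft

    def test_negative_threshold_rejected(self):
        for fn in (hard_threshold, soft_threshold):
            with pytest.raises(ContractError):
                fn(np.array([1.0]), -1)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.floats(-100, 100, allow_nan=False),
        st.floats(0, 50, allow_nan=False),
    )
    def test_shrinkage_ordering(self, x, t):
        xs = np.array([x])
        assert abs(soft_threshold(xs, t)[0]) <= abs(hard_threshold(xs, t)[0]) <= abs(x)

    def test_lossless_rule_refuses_positive_t(self):
        with pytest.raises(ConfigError):
            ThresholdRule("none", 10.0)


class TestEntropyAndHuffman:
    @pytest.mark.parametrize(
        "probs,expected",
        [([0.25] * 4, 2.0), ([0.5, 0.5], 1.0), ([2 / 3, 1 / 3], 0.9183)],
    )
    def test_entropy_values(self, probs, expected):
        assert shannon_entropy(probs) == pytest.approx(expected, abs=1e-4)

    def test_unnormalized_probabilities_rejected(self):
        with pytest.raises(ContractError):
            shannon_entropy([0.5, 0.4])

    def test_two_symbol_stream_mean_length(self):
        symbols = [97, 97, 98]
        _, n_bits, lengths = huffman_encode(symbols)
        assert n_bits == 3  # one bit per symbol
        h = shannon_entropy([2 / 3, 1 / 3])
        lbar = mean_code_length(lengths, {97: 2, 98: 1})
        assert h <= lbar < h + 1

    def test_degenerate_single_symbol_alphabet(self):
        data, n_bits, lengths = huffman_encode([7] * 10)
        assert n_bits == 10 and lengths == {7: 1}
        assert huffman_decode(data, lengths, 10, n_bits).tolist() == [7] * 10

    def test_empty_input_rejected(self):
        with pytest.raises(ContractError):
            huffman_encode([])

    def test_truncated_stream_raises(self):
        data, n_bits, lengths = huffman_encode([1, 2, 3, 1, 1])
        with pytest.raises(TruncationError):
            huffman_decode(data, lengths, 50, n_bits)

    @pytest.mark.parametrize("alphabet,size", [(4, 200), (40, 2000), (300, 5000)])
    def test_round_trip_and_entropy_bound(self, rng, alphabet, size):
        symbols = rng.integers(-alphabet, alphabet, size=size)
        data, n_bits, lengths = huffman_encode(symbols)
        assert np.array_equal(huffman_decode(data, lengths, size, n_bits), symbols)
        model = SymbolModel.from_symbols(symbols)
        assert model.entropy <= n_bits / size < model.entropy + 1


class TestColorTransforms:
    @pytest.mark.parametrize(
        "rgb,ycc",
        [((1, 1, 1), (1.0, 0.0, 0.0)), ((0, 0, 0), (0.0, 0.0, 0.0)), ((100, 50, 25), (62.5, -22.5, 27.5))],
    )
    def test_forward_matrix_rows(self, rgb, ycc):
        img = Image8(np.array([[rgb]], dtype=np.uint8))
        planes = rgb_to_ycbcr(img)
        got = tuple(float(p[0, 0]) for p in planes.planes)
        assert got == pytest.approx(ycc)

    def test_gray_input_rejected(self):
        with pytest.raises(ContractError):
            rgb_to_ycbcr(Image8([[1]]))

    def test_exact_inverse_round_trips(self, rng):
        img = random_image(rng, 16, 16, rgb=True)
        assert ycbcr_to_rgb(rgb_to_ycbcr(img)) == img

    def test_printed_inverse_is_only_approximate(self, rng):
        img = random_image(rng, 32, 32, rgb=True)
        approx = ycbcr_to_rgb(rgb_to_ycbcr(img), approximate=True)
        exact = ycbcr_to_rgb(rgb_to_ycbcr(img))
        assert exact == img
        dev = np.abs(approx.samples.astype(int) - img.samples.astype(int)).max()
        assert dev > 0  # the traditional rounded matrix does not invert exactly

    @pytest.mark.parametrize(
        "rgb,yvu",
        [((100, 50, 25), (56, 50, -25)), ((9, 9, 9), (9, 0, 0)), ((255, 0, 255), (127, 255, 255))],
    )
    def test_rct_worked_triples(self, rgb, yvu):
        assert rct_forward(rgb) == yvu
        assert rct_inverse(*yvu) == rgb

    def test_rct_out_of_range_rejected(self):
        with pytest.raises(ContractError):
            rct_forward((300, 0, 0))

    def test_rct_identity_lattice_and_random(self, rng):
        lattice = np.arange(0, 256, 32)
        for r in lattice:
            for g in lattice:
                for b in lattice:
                    assert rct_inverse(*rct_forward((r, g, b))) == (r, g, b)
        triples = rng.integers(0, 256, size=(10_000, 3))
        img = Image8(triples.reshape(100, 100, 3).astype(np.uint8))
        assert rct_inverse(rct_forward(img)) == img


class TestContainer:
    def test_lossless_round_trip_all_phantoms(self):
        for kind in ("constant", "gradient", "ellipse", "speckle"):
            for rgb in (False, True):
                img = generate_phantom(
                    PhantomSpec(37, 41, kind, noise_sd=3.0, seed=11, rgb=rgb)
                )
                assert decompress(compress(img)) == img

    def test_serialization_survives_bytes(self, rng):
        img = random_image(rng, 20, 20, rgb=True)
        blob = compress(img).to_bytes()
        assert decompress(CompressedContainer.from_bytes(blob)) == img

    def test_constant_image_compresses_below_raw(self):
        img = generate_phantom(PhantomSpec(64, 64, "constant", seed=0))
        assert compress(img).n_bytes < img.samples.size

    def test_bad_magic_is_format_error(self, rng):
        blob = compress(random_image(rng, 8, 8)).to_bytes()
        with pytest.raises(FormatError):
            CompressedContainer.from_bytes(b"XXXX" + blob[4:])

    def test_truncation_and_corruption_detected(self, rng):
        blob = compress(random_image(rng, 8, 8)).to_bytes()
        with pytest.raises(CorruptionError):
            CompressedContainer.from_bytes(blob[: len(blob) // 2])
        tampered = bytearray(blob)
        tampered[10] ^= 0xFF
        with pytest.raises(CorruptionError):
            CompressedContainer.from_bytes(bytes(tampered))

    def test_threshold_none_and_t0_hard_agree(self, rng):
        img = random_image(rng, 16, 16)
        a = compress(img, CompressionConfig(threshold=ThresholdRule("none", 0.0)))
        b = compress(img, CompressionConfig(threshold=ThresholdRule("hard", 0.0)))
        pa = huffman_decode(a.planes[0].body, a.planes[0].lengths,
                            a.planes[0].n_coeffs, a.planes[0].n_bits)
        pb = huffman_decode(b.planes[0].body, b.planes[0].lengths,
                            b.planes[0].n_coeffs, b.planes[0].n_bits)
        assert np.array_equal(pa, pb)

    def test_save_load_file(self, tmp_path, rng):
        img = random_image(rng, 12, 9)
        path = tmp_path / "z.msc"
        compress(img).save(path)
        assert decompress(CompressedContainer.load(path)) == img


class TestLossyBookkeeping:
    def test_mse_equals_removed_energy_over_n(self, ellipse128):
        x = ellipse128.samples.astype(float)
        for t in (5.0, 10.0, 20.0):
            tree = packet_decompose(x, depth=2, arithmetic="float")
            shrunk, removed = threshold_tree(tree, ThresholdRule("soft", t))
            rec = packet_reconstruct(shrunk)
            err = float(np.sum((rec - x) ** 2))
            assert err == pytest.approx(removed, rel=1e-6)

    def test_psnr_non_increasing_in_threshold(self, ellipse128):
        from stegowave import psnr

        values = []
        for t in (0.0, 5.0, 10.0, 20.0):
            mode = "none" if t == 0 else "soft"
            cfg = CompressionConfig(
                threshold=ThresholdRule(mode, t), arithmetic="float"
            )
            out = decompress(compress(ellipse128, cfg))
            values.append(psnr(ellipse128, out))
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert all(math.isfinite(v) for v in values)
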