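"""Architecture semantics: tokenisation, windowed/shifted attention, merging,
the U-shaped decoder, and checkpointing."""

import numpy as np
import pytest

from mssit.autodiff import Tensor
from mssit.icosphere import (
    build_icosphere,
    build_patch_partition,
    build_window_map,
    face_children,
)
from mssit.model import (
    MSSiT,
    MSSiTConfig,
    MSSiTUNet,
    load_checkpoint,
    patch_merge,
    save_checkpoint,
    tokenize,
)
from mssit.nn import Linear, WindowAttention


@pytest.fixture(scope="module")
def tiny_config():
    return MSSiTConfig(
        num_input_channels=2, input_order=4, base_dim=8,
        depths=(1, 1, 1, 1), heads=(2, 2, 2, 2), mlp_ratio=2.0, task="regression",
    )


@pytest.fixture(scope="module")
def tiny_model(tiny_config):
    return MSSiT(tiny_config, np.random.default_rng(0))


@pytest.fixture(scope="module")
def tiny_input(tiny_config):
    V = build_icosphere(tiny_config.input_order).n_vertices
    return np.random.default_rng(1).standard_normal((2, V, 2))


class TestTokenize:
    def test_token_dimensions_ico6(self):
        part = build_patch_partition(build_icosphere(6), build_icosphere(5))
        values = np.zeros((40962, 4))
        tokens = tokenize(values, part.patch_vertex_ids)
        assert tokens.shape == (20480, 24)  # C * |t5| = 4 * 6

    def test_constant_signal_gives_identical_tokens(self):
        part = build_patch_partition(build_icosphere(3), build_icosphere(2))
        tokens = tokenize(np.full((642, 3), 1.25), part.patch_vertex_ids)
        assert np.abs(tokens - tokens[0]).max() == 0

    def test_matches_direct_gather(self, rng):
        part = build_patch_partition(build_icosphere(3), build_icosphere(2))
        values = rng.standard_normal((642, 3))
        tokens = tokenize(values, part.patch_vertex_ids)
        for i in [0, 17, 319]:
            expect = np.concatenate(
                [values[part.patch_vertex_ids[i], c] for c in range(3)]
            )
            assert np.array_equal(tokens[i], expect)


class TestPatchMerge:
    def test_shape_20480_to_5120(self):
        x = Tensor(np.zeros((1, 20480, 8)))
        assert patch_merge(x).shape == (1, 5120, 32)

    def test_constant_stays_constant(self):
        x = Tensor(np.ones((1, 320, 4)))
        out = patch_merge(x).data
        assert np.abs(out - 1.0).max() == 0

    def test_matches_face_children_gather(self, rng):
        x = rng.standard_normal((1, 1280, 6))
        merged = patch_merge(Tensor(x)).data[0]
        for f in [0, 100, 319]:
            kids = face_children(f, 3)
            assert np.array_equal(merged[f], x[0, kids].ravel())


class TestWindowAttention:
    def test_shift_zero_equals_windowed(self, rng):
        wmap = build_window_map(1, 0.5, input_order=4)
        attn = WindowAttention(8, 2, np.random.default_rng(2))
        x = Tensor(rng.standard_normal((1, wmap.seq_len, 8)))
        a = attn(x, wmap, shift=0).data
        b = attn(x, wmap, shift=0).data
        assert np.array_equal(a, b)

    def test_cross_window_locality(self, rng):
        # perturbing a token in one window leaves other windows unchanged (shift 0)
        wmap = build_window_map(1, 0.5, input_order=4)
        attn = WindowAttention(8, 2, np.random.default_rng(2))
        x = rng.standard_normal((1, wmap.seq_len, 8))
        base = attn(Tensor(x), wmap, shift=0).data
        x2 = x.copy()
        x2[0, 3] += 10.0  # token 3 lives in window 0
        pert = attn(Tensor(x2), wmap, shift=0).data
        w = wmap.window_size
        assert np.abs(pert[0, w:] - base[0, w:]).max() == 0
        assert np.abs(pert[0, :w] - base[0, :w]).max() > 0

    def test_matches_masked_global_attention(self, rng):
        # brute-force oracle: global attention with -inf scores across windows
        wmap = build_window_map(1, 0.5, input_order=4)  # 20 windows of 64
        d, h = 8, 2
        attn = WindowAttention(d, h, np.random.default_rng(3))
        x = rng.standard_normal((1, wmap.seq_len, d))
        for shift in (0, wmap.shift):
            ours = attn(Tensor(x), wmap, shift=shift).data[0]
            oracle = _masked_global_attention(attn, x[0], wmap, shift)
            assert np.abs(ours - oracle).max() < 1e-10

    def test_attention_rows_are_distributions(self, rng):
        wmap = build_window_map(1, 0.5, input_order=4)
        attn = WindowAttention(8, 2, np.random.default_rng(2))
        sink = []
        attn(Tensor(rng.standard_normal((1, wmap.seq_len, 8))), wmap, shift=0, attn_sink=sink)
        a = sink[0]
        assert a.shape == (1, wmap.n_windows, 2, 64, 64)
        assert np.abs(a.sum(-1) - 1.0).max() < 1e-12


def _masked_global_attention(attn, x, wmap, shift):
    """Independent reference: full L x L attention masked outside windows."""

    def lin(layer, v):
        return v @ layer.weight.data + layer.bias.data

    xs = np.roll(x, -shift, axis=0)
    L, d = xs.shape
    h = attn.heads
    dh = d // h
    q, k, v = lin(attn.q, xs), lin(attn.k, xs), lin(attn.v, xs)
    win = wmap.window_of
    mask = win[:, None] == win[None, :]  # (L, L)
    out = np.zeros_like(xs)
    for head in range(h):
        sl = slice(head * dh, (head + 1) * dh)
        scores = q[:, sl] @ k[:, sl].T / np.sqrt(dh)
        scores[~mask] = -np.inf
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        a = e / e.sum(axis=1, keepdims=True)
        out[:, sl] = a @ v[:, sl]
    return np.roll(lin(attn.proj, out), shift, axis=0)


class TestForwardRegression:
    def test_level_token_counts_via_attention(self, tiny_model, tiny_input):
        out, info = tiny_model(tiny_input, return_attention=True)
        lengths = [a[0].shape[1] * a[0].shape[3] for a in info["attention"]]
        assert lengths == [1280, 320, 80, 20]  # ico4-input pyramid
        cfg6 = MSSiTConfig(num_input_channels=1, input_order=6, base_dim=8,
                           depths=(1, 1, 1, 1), heads=(1, 1, 1, 1))
        expected6 = [20 * 4 ** (6 - l) for l in range(1, 5)]
        assert expected6 == [20480, 5120, 1280, 320]

    def test_scalar_output(self, tiny_model, tiny_input):
        out = tiny_model(tiny_input)
        assert out.shape == (2, 1)

    def test_deterministic_forward(self, tiny_model, tiny_input):
        a = tiny_model(tiny_input).data
        b = tiny_model(tiny_input).data
        assert np.array_equal(a, b)

    def test_complexity_contract(self, tiny_model, tiny_input):
        # attention score entries per level = w_l * L_l, far below L_l^2
        _, info = tiny_model(tiny_input, return_attention=True)
        for wmap, sink in zip(tiny_model.encoder.window_maps, info["attention"]):
            a = sink[0]
            entries = a.shape[1] * a.shape[3] * a.shape[4]
            assert entries == wmap.seq_len * wmap.window_size
            if not wmap.is_global:
                assert entries < wmap.seq_len**2

    def test_shape_preserved_by_blocks(self, tiny_model, tiny_input):
        from mssit.model import tokenize as tok

        enc = tiny_model.encoder
        x = Tensor(tok(tiny_input, enc.patch_vertex_ids)) + enc.pos_embed
        x = enc.input_norm(x)
        for l in range(4):
            x = enc.projections[l](x)
            shape_in = x.shape
            for block in enc.levels[l]:
                x = block(x, enc.window_maps[l])
            assert x.shape == shape_in
            if l < 3:
                x = patch_merge(x)


class TestSegmentation:
    @pytest.fixture(scope="class")
    @staticmethod
    def unet():
        cfg = MSSiTConfig(num_input_channels=2, input_order=4, base_dim=8,
                          depths=(1, 1, 1, 1), heads=(2, 2, 2, 2), mlp_ratio=2.0,
                          task="segmentation", num_outputs=5)
        return MSSiTUNet(cfg, np.random.default_rng(4))

    def test_output_covers_all_vertices(self, unet, tiny_input):
        logits = unet(tiny_input)
        assert logits.shape == (2, 2562, 5)

    def test_softmax_rows_sum_to_one(self, unet, tiny_input):
        probs = unet(tiny_input).softmax(-1).data
        assert np.abs(probs.sum(-1) - 1.0).max() < 1e-6

    def test_num_classes_validated(self):
        with pytest.raises(ValueError):
            MSSiTConfig(task="segmentation", num_outputs=1)


class TestPartitionUp:
    def test_upsamples_fourfold(self, rng):
        from mssit.model import patch_partition_up

        x = Tensor(rng.standard_normal((1, 320, 8)))
        skip = Tensor(rng.standard_normal((1, 1280, 4)))
        proj = Linear(12, 4, np.random.default_rng(0))
        out = patch_partition_up(x, skip, proj)
        assert out.shape == (1, 1280, 4)

    def test_zero_skip_identity_projection_copies_parent(self, rng):
        from mssit.model import patch_partition_up

        d = 4
        x = rng.standard_normal((1, 80, d))
        skip = Tensor(np.zeros((1, 320, d)))
        proj = Linear(2 * d, d, np.random.default_rng(0))
        proj.weight.data = np.vstack([np.eye(d), np.zeros((d, d))])
        proj.bias.data = np.zeros(d)
        out = patch_partition_up(Tensor(x), skip, proj).data
        assert np.abs(out[0] - np.repeat(x[0], 4, axis=0)).max() < 1e-12

    def test_roundtrip_merge_then_partition_on_constants(self):
        from mssit.model import patch_partition_up

        d = 4
        x = Tensor(np.ones((1, 320, d)))
        merged = patch_merge(x)  # (1, 80, 4d)
        reduce = Linear(4 * d, d, np.random.default_rng(0))
        reduce.weight.data = np.vstack([np.eye(d)] * 4) / 4.0
        reduce.bias.data = np.zeros(d)
        coarse = reduce(merged)
        proj = Linear(2 * d, d, np.random.default_rng(0))
        proj.weight.data = np.vstack([np.eye(d), np.zeros((d, d))])
        proj.bias.data = np.zeros(d)
        back = patch_partition_up(coarse, Tensor(np.zeros((1, 320, d))), proj)
        assert np.abs(back.data - x.data).max() < 1e-12


def test_checkpoint_roundtrip(tmp_path, tiny_model, tiny_input):
    before = tiny_model(tiny_input).data
    path = tmp_path / "ck.npz"
    save_checkpoint(path, tiny_model, {"norm_mu": np.array([0.0, 0.0])})
    model, extra = load_checkpoint(path)
    assert np.array_equal(model(tiny_input).data, before)
    assert np.array_equal(extra["norm_mu"], [0.0, 0.0])


def test_config_validation():
    with pytest.raises(ValueError):
        MSSiTConfig(task="unknown")
    with pytest.raises(ValueError):
        MSSiTConfig(input_order=3)
    with pytest.raises(ValueError):
        MSSiTConfig(shift_fraction=1.0)
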