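"""The MS-SiT network: tokenisation, hierarchical encoder, task heads.

The encoder operates on a token sequence indexed by the faces of the patch
grid (one level below the input mesh).  Each of the four levels first
projects the sequence linearly to a ``2^(l-1) * D``-dimensional embedding,
applies a stack of local-MHSA blocks (windowed + shifted-window attention),
and then merges sibling patches 4-to-1 — a stride-4 reshape under the
canonical face ordering — halving the spatial resolution while the feature
dimension doubles.  The last level skips the merge.  For regression and
classification the final sequence is averaged into a single token and fed
to a linear head.  The segmentation variant keeps per-level encoder outputs
and mirrors them with a decoder that upsamples 1-to-4 (patch partition),
concatenates skip connections and predicts per-corner class logits that are
scatter-averaged onto the mesh vertices.

For an ico6 input the token counts per level are 20480, 5120, 1280 and 320,
with 64-patch attention windows at levels 1-3 and global attention over the
320 ico2 patches at level 4.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concat
from .icosphere import WindowMap, build_icosphere, build_patch_partition, build_window_map
from .nn import Dropout, LayerNorm, Linear, LocalMHSABlock, Module
from .surface_io import SurfaceSignal

__all__ = ["MSSiTConfig", "TokenSequence", "MSSiT", "MSSiTUNet", "build_model",
           "tokenize", "patch_merge", "save_checkpoint", "load_checkpoint"]

N_LEVELS = 4


@dataclass
class MSSiTConfig:
    """Architectural hyperparameters.

    ``base_dim``, ``depths``, ``heads`` and ``mlp_ratio`` default to a
    Swin-T-like parameterisation.  Window sizes are fixed by the icosphere
    rule and are not configurable.  ``shift_fraction`` 0.5 shifts half of
    each 64-patch window.  ``decoder_depths`` (segmentation only) gives the
    number of local-MHSA blocks per decoder level, shallowest-last.
    """

    num_input_channels: int = 4
    input_order: int = 6
    base_dim: int = 96
    depths: tuple[int, int, int, int] = (2, 2, 6, 2)
    heads: tuple[int, int, int, int] = (3, 6, 12, 24)
    shift_fraction: float = 0.5
    mlp_ratio: float = 4.0
    dropout: float = 0.0
    task: str = "regression"
    num_outputs: int = 1
    decoder_depths: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        if self.task not in ("regression", "classification", "segmentation"):
            raise ValueError(f"unknown task {self.task!r}")
        if len(self.depths) != N_LEVELS or len(self.heads) != N_LEVELS:
            raise ValueError("depths and heads must have 4 entries")
        if self.input_order < N_LEVELS:
            raise ValueError("input_order must be >= 4 so all levels have a grid")
        if self.task == "segmentation" and self.num_outputs < 2:
            raise ValueError("segmentation needs num_outputs (classes) >= 2")
        if not 0.0 <= self.shift_fraction < 1.0:
            raise ValueError("shift_fraction must be in [0, 1)")

    def level_dim(self, level: int) -> int:
        return 2 ** (level - 1) * self.base_dim

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MSSiTConfig":
        d = dict(d)
        for k in ("depths", "heads", "decoder_depths"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class TokenSequence:
    """Ordered patch-feature sequence at one encoder level."""

    tokens: np.ndarray  # (L, d)
    level: int
    grid_order: int

    def __post_init__(self) -> None:
        if self.tokens.shape[0] != 20 * 4**self.grid_order:
            raise ValueError(
                f"sequence length {self.tokens.shape[0]} inconsistent with grid order {self.grid_order}"
            )
        if not np.isfinite(self.tokens).all():
            raise ValueError("token sequence contains non-finite entries")


def tokenize(values: np.ndarray, patch_vertex_ids: np.ndarray) -> np.ndarray:
    """Gather per-vertex channels into the flattened patch-token array.

    ``values`` is (V, C) or (B, V, C); each token concatenates, channel by
    channel, the 6 patch-vertex values in canonical patch order, giving
    feature dimension ``C * 6``.
    """
    single = values.ndim == 2
    if single:
        values = values[None]
    B = values.shape[0]
    L, P = patch_vertex_ids.shape
    gathered = values[:, patch_vertex_ids, :]  # (B, L, 6, C)
    tokens = gathered.transpose(0, 1, 3, 2).reshape(B, L, -1)
    return tokens[0] if single else tokens


def patch_merge(x: Tensor) -> Tensor:
    """Merge sibling patches 4-to-1: (B, L, d) -> (B, L/4, 4d).

    Valid because face ``f``'s children occupy positions ``4f..4f+3``.
    """
    B, L, d = x.shape
    if L % 4 or L < 80:
        raise ValueError(f"cannot merge sequence of length {L}")
    return x.reshape(B, L // 4, 4 * d)


def patch_partition_up(x: Tensor, skip: Tensor, proj: Linear) -> Tensor:
    """Decoder upsampling: copy each token to its 4 children, concat skip, project."""
    B, L, d = x.shape
    Bs, Ls, ds = skip.shape
    if Ls != 4 * L:
        raise ValueError(f"skip length {Ls} must be 4x coarse length {L}")
    up = x.repeat(4, axis=1)  # (B, 4L, d)
    return proj(concat([up, skip], axis=-1))


class _Encoder(Module):
    def __init__(self, config: MSSiTConfig, rng: np.random.Generator):
        self.config = config
        C = config.num_input_channels
        m = config.input_order
        part = build_patch_partition(build_icosphere(m), build_icosphere(m - 1))
        self.patch_vertex_ids = part.patch_vertex_ids  # static, not a parameter
        L0 = part.n_patches
        d0 = 6 * C
        self.pos_embed = Tensor(rng.normal(0.0, 0.02, size=(L0, d0)), requires_grad=True)
        self.input_norm = LayerNorm(d0)
        self.input_dropout = Dropout(config.dropout)
        self.window_maps = [
            build_window_map(l, config.shift_fraction, input_order=m) for l in range(1, N_LEVELS + 1)
        ]
        self.projections: list[Linear] = []
        self.levels: list[list[LocalMHSABlock]] = []
        d_in = d0
        for l in range(1, N_LEVELS + 1):
            dim = config.level_dim(l)
            self.projections.append(Linear(d_in, dim, rng))
            self.levels.append(
                [LocalMHSABlock(dim, config.heads[l - 1], config.mlp_ratio, rng)
                 for _ in range(config.depths[l - 1])]
            )
            d_in = 4 * dim  # after merge the feature dim quadruples

    def __call__(self, values: np.ndarray, *, training: bool = False,
                 rng: np.random.Generator | None = None,
                 attn_sinks: list[list] | None = None,
                 keep_levels: bool = False):
        tokens = tokenize(values, self.patch_vertex_ids)
        if tokens.ndim == 2:
            tokens = tokens[None]
        x = Tensor(tokens) + self.pos_embed
        x = self.input_norm(x)
        x = self.input_dropout(x, rng, training)
        per_level: list[Tensor] = []
        for l in range(N_LEVELS):
            x = self.projections[l](x)
            sink = attn_sinks[l] if attn_sinks is not None else None
            for block in self.levels[l]:
                x = block(x, self.window_maps[l], attn_sink=sink)
            if keep_levels:
                per_level.append(x)
            if l < N_LEVELS - 1:
                x = patch_merge(x)
        return (x, per_level) if keep_levels else x


class MSSiT(Module):
    """MS-SiT for regression / classification: encoder, mean token, linear head."""

    def __init__(self, config: MSSiTConfig, rng: np.random.Generator | None = None):
        if config.task not in ("regression", "classification"):
            raise ValueError("MSSiT handles regression/classification; use MSSiTUNet for segmentation")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.config = config
        self.encoder = _Encoder(config, rng)
        self.final_norm = LayerNorm(config.level_dim(N_LEVELS))
        self.head = Linear(config.level_dim(N_LEVELS), config.num_outputs, rng, zero_bias=True)

    def __call__(self, values: np.ndarray, *, training: bool = False,
                 rng: np.random.Generator | None = None,
                 return_attention: bool = False):
        sinks = [[] for _ in range(N_LEVELS)] if return_attention else None
        x = self.encoder(values, training=training, rng=rng, attn_sinks=sinks)
        x = self.final_norm(x)
        out = self.head(x.mean(axis=1))  # (B, num_outputs)
        if return_attention:
            return out, {"attention": sinks}
        return out

    def predict(self, signal: SurfaceSignal | np.ndarray) -> np.ndarray:
        values = signal.values if isinstance(signal, SurfaceSignal) else np.asarray(signal)
        if values.ndim == 2:
            return self(values[None]).data[0]
        return self(values).data


class MSSiTUNet(Module):
    """U-shaped MS-SiT for vertex-wise segmentation.

    The decoder mirrors the encoder: patch partition (1-to-4 upsampling)
    with skip connections down to the patch grid, then a head producing 6
    per-corner logit vectors per patch, scatter-averaged onto the mesh
    vertices (patch corners are shared between patches).
    """

    def __init__(self, config: MSSiTConfig, rng: np.random.Generator | None = None):
        if config.task != "segmentation":
            raise ValueError("MSSiTUNet requires task='segmentation'")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.config = config
        self.encoder = _Encoder(config, rng)
        self.up_projections: list[Linear] = []
        self.decoder_levels: list[list[LocalMHSABlock]] = []
        # decode from level 4 grid back to level 1 grid
        for i, l in enumerate(range(N_LEVELS - 1, 0, -1)):
            d_coarse = config.level_dim(l + 1)
            d_skip = config.level_dim(l)
            self.up_projections.append(Linear(d_coarse + d_skip, d_skip, rng))
            self.decoder_levels.append(
                [LocalMHSABlock(d_skip, config.heads[l - 1], config.mlp_ratio, rng)
                 for _ in range(config.decoder_depths[i] if i < len(config.decoder_depths) else 1)]
            )
        K = config.num_outputs
        self.head = Linear(config.level_dim(1), 6 * K, rng, zero_bias=True)
        self.n_vertices = build_icosphere(config.input_order).n_vertices
        self._scatter_index = self.encoder.patch_vertex_ids.ravel()

    def __call__(self, values: np.ndarray, *, training: bool = False,
                 rng: np.random.Generator | None = None,
                 return_attention: bool = False):
        sinks = [[] for _ in range(N_LEVELS)] if return_attention else None
        x, skips = self.encoder(values, training=training, rng=rng,
                                attn_sinks=sinks, keep_levels=True)
        # x is the level-4 output (no merge); decode back up
        for i, l in enumerate(range(N_LEVELS - 1, 0, -1)):
            x = patch_partition_up(x, skips[l - 1], self.up_projections[i])
            for block in self.decoder_levels[i]:
                x = block(x, self.encoder.window_maps[l - 1])
        B, L, _ = x.shape
        K = self.config.num_outputs
        corner_logits = self.head(x).reshape(B, L * 6, K)
        logits = corner_logits.scatter_mean(self._scatter_index, self.n_vertices)  # (B, V, K)
        if return_attention:
            return logits, {"attention": sinks}
        return logits

    def predict_labels(self, signal: SurfaceSignal | np.ndarray) -> np.ndarray:
        values = signal.values if isinstance(signal, SurfaceSignal) else np.asarray(signal)
        single = values.ndim == 2
        logits = self(values[None] if single else values).data
        labels = logits.argmax(axis=-1)
        return labels[0] if single else labels


def build_model(config: MSSiTConfig, rng: np.random.Generator | None = None) -> MSSiT | MSSiTUNet:
    cls = MSSiTUNet if config.task == "segmentation" else MSSiT
    return cls(config, rng)


def save_checkpoint(path, model: Module, extra: dict | None = None) -> None:
    """Single-archive checkpoint: model config (JSON) + parameter arrays + extras."""
    payload: dict[str, np.ndarray] = {f"param/{k}": v for k, v in model.state_dict().items()}
    payload["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8
    )
    for k, v in (extra or {}).items():
        payload[f"extra/{k}"] = np.asarray(v)
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_checkpoint(path) -> tuple[MSSiT | MSSiTUNet, dict[str, np.ndarray]]:
    with np.load(path, allow_pickle=False) as npz:
        cfg = MSSiTConfig.from_dict(json.loads(bytes(npz["__config__"]).decode()))
        model = build_model(cfg)
        state = {k[len("param/"):]: npz[k] for k in npz.files if k.startswith("param/")}
        extra = {k[len("extra/"):]: npz[k] for k in npz.files if k.startswith("extra/")}
    model.load_state_dict(state)
    return model, extra
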