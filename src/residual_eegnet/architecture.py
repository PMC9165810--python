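"""Residual-EEGNet block system and model assembly.

The network is a deepened EEGNet operating on one implicit input map of
shape (64 channels, 720 time points):

* ``Conv2Dtype0`` — temporal convolution, kernel (1, 64), 1 -> F1 maps,
  batch norm.
* ``Conv2Dtype1`` x 10 — temporal convolution (1, 64), F1 -> F1, batch
  norm, identity-shortcut residual add.  Temporal extent is preserved
  ('same' padding), so the tenth block still emits 64 x 720 feature maps —
  the layer Grad-CAM reads.
* ``Conv2Dtype2`` — spatial convolution (64, 1) collapsing the electrode
  axis, F1 -> F1*D maps, max-norm cap 1 on each filter, batch norm, ELU,
  average pooling (1, 4), dropout 0.25.
* ``Conv2Dtype3`` x 5 — depthwise (1, 16) + pointwise (1, 1) separable
  convolution, batch norm, residual add.
* ``Conv2Dtype4`` — depthwise + pointwise, batch norm, residual add, ELU,
  average pooling (1, 8), dropout 0.25.
* ``Classifier`` — convolution spanning the full remaining temporal
  extent, F2 -> n_class maps, log-softmax.

Defaults F1=8, D=2, F2=16, n_class=3.  With floor-division pooling the
remaining extent after both pools of a 720-sample epoch is 22, so the
classifier kernel is derived from the traced extent at build time (a
warning notes when it differs from the nominal 23).  Ablation toggles
remove the residual adds, batch norm, or dropout without touching
anything else.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from residual_eegnet import nn
from residual_eegnet._rng import substream
from residual_eegnet.data_model import EPOCH_SAMPLES, N_CHANNELS

log = logging.getLogger(__name__)

NOMINAL_CLASSIFIER_KERNEL = 23


@dataclass
class ModelConfig:
    """Architectural hyperparameters and ablation toggles."""

    F1: int = 8
    D: int = 2
    F2: int = 16
    n_class: int = 3
    n_type1_blocks: int = 10
    n_type3_blocks: int = 5
    temporal_kernel: int = 64
    spatial_kernel: int = N_CHANNELS
    separable_kernel: int = 16
    pool1: int = 4
    pool2: int = 8
    dropout_p: float = 0.25
    maxnorm_c: float = 1.0
    use_residual: bool = True
    use_batchnorm: bool = True
    use_dropout: bool = True
    elu_after_residual: bool = False

    def __post_init__(self):
        counts = (self.F1, self.D, self.F2, self.n_class, self.n_type1_blocks,
                  self.n_type3_blocks, self.temporal_kernel, self.spatial_kernel,
                  self.separable_kernel, self.pool1, self.pool2)
        if any(int(c) < 1 for c in counts):
            raise ValueError("all architectural counts must be >= 1")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must be in [0, 1)")
        if self.maxnorm_c <= 0:
            raise ValueError("maxnorm_c must be positive")
        if self.F2 != self.F1 * self.D:
            warnings.warn(
                f"F2={self.F2} differs from F1*D={self.F1 * self.D}; "
                "the separable stage always emits F1*D maps",
                stacklevel=2,
            )

    def to_jsonable(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_jsonable(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class BlockSummary:
    name: str
    kind: str
    in_maps: int
    out_maps: int
    out_channels: int
    out_samples: int
    n_params: int


@dataclass
class LayerSummary:
    blocks: list[BlockSummary] = field(default_factory=list)
    notes: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.blocks)

    def row(self, name: str) -> BlockSummary:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)

    def to_table(self) -> str:
        head = f"{'block':<16}{'kind':<22}{'in':>4}{'out':>4}{'chan':>6}{'time':>6}{'params':>9}"
        lines = [head, "-" * len(head)]
        for b in self.blocks:
            lines.append(
                f"{b.name:<16}{b.kind:<22}{b.in_maps:>4}{b.out_maps:>4}"
                f"{b.out_channels:>6}{b.out_samples:>6}{b.n_params:>9}"
            )
        total = sum(b.n_params for b in self.blocks)
        lines.append("-" * len(head))
        lines.append(f"{'total':<16}{'':<22}{'':>4}{'':>4}{'':>6}{'':>6}{total:>9}")
        return "\n".join(lines)


def residual_add(block_input: np.ndarray, block_output: np.ndarray) -> np.ndarray:
    """Identity-shortcut sum; shapes must match exactly (no projection)."""
    if block_input.shape != block_output.shape:
        raise ValueError(
            f"residual add needs identical shapes, got {block_input.shape} "
            f"vs {block_output.shape}"
        )
    return block_input + block_output


project_maxnorm = nn.project_maxnorm


def _maybe_residual(inner: list[nn.Layer], cfg: ModelConfig) -> nn.Layer:
    seq = nn.Sequential(inner)
    return nn.Residual(seq) if cfg.use_residual else seq


def build_model(config: ModelConfig, seed: int = 0, dtype=np.float64,
                input_samples: int = EPOCH_SAMPLES) -> nn.Model:
    """Assemble the forward-composable model for 64 x ``input_samples`` epochs."""
    cfg = config
    rng = substream(seed, "init")
    F1, D = cfg.F1, cfg.D
    F2 = F1 * D
    blocks: list[tuple[str, nn.Layer]] = []

    def bn(maps, name):
        return [nn.BatchNorm(maps, dtype=dtype, name=name)] if cfg.use_batchnorm else []

    def dropout():
        return [nn.Dropout(cfg.dropout_p)] if cfg.use_dropout else []

    blocks.append((
        "conv2dtype0",
        nn.Sequential(
            [nn.TemporalConv(1, F1, cfg.temporal_kernel, rng, dtype, name="t0.conv",
                             skip_input_grad=True)]
            + bn(F1, "t0.bn")
        ),
    ))
    for i in range(1, cfg.n_type1_blocks + 1):
        inner = [nn.TemporalConv(F1, F1, cfg.temporal_kernel, rng, dtype,
                                 name=f"t1.{i}.conv")] + bn(F1, f"t1.{i}.bn")
        layer = _maybe_residual(inner, cfg)
        if cfg.elu_after_residual:
            layer = nn.Sequential([layer, nn.ELU()])
        blocks.append((f"conv2dtype1.{i}", layer))
    blocks.append((
        "conv2dtype2",
        nn.Sequential(
            [nn.SpatialConv(F1, F2, cfg.spatial_kernel, rng, dtype,
                            maxnorm_c=cfg.maxnorm_c, name="t2.conv")]
            + bn(F2, "t2.bn")
            + [nn.ELU(), nn.AvgPoolTime(cfg.pool1)]
            + dropout()
        ),
    ))
    for i in range(1, cfg.n_type3_blocks + 1):
        inner = (
            [nn.DepthwiseTemporalConv(F2, cfg.separable_kernel, rng, dtype,
                                      name=f"t3.{i}.dw"),
             nn.PointwiseConv(F2, F2, rng, dtype, name=f"t3.{i}.pw")]
            + bn(F2, f"t3.{i}.bn")
        )
        layer = _maybe_residual(inner, cfg)
        if cfg.elu_after_residual:
            layer = nn.Sequential([layer, nn.ELU()])
        blocks.append((f"conv2dtype3.{i}", layer))
    inner4 = (
        [nn.DepthwiseTemporalConv(F2, cfg.separable_kernel, rng, dtype, name="t4.dw"),
         nn.PointwiseConv(F2, F2, rng, dtype, name="t4.pw")]
        + bn(F2, "t4.bn")
    )
    blocks.append((
        "conv2dtype4",
        nn.Sequential(
            [_maybe_residual(inner4, cfg), nn.ELU(), nn.AvgPoolTime(cfg.pool2)]
            + dropout()
        ),
    ))
    t_final = (input_samples // cfg.pool1) // cfg.pool2
    if t_final < 1:
        raise ValueError("input too short for the configured pooling")
    if t_final != NOMINAL_CLASSIFIER_KERNEL:
        log.warning(
            "classifier kernel derived from traced extent is (1, %d), not the "
            "nominal (1, %d)", t_final, NOMINAL_CLASSIFIER_KERNEL,
        )
    blocks.append((
        "classifier",
        nn.Sequential([
            nn.TimeCollapseConv(F2, cfg.n_class, t_final, rng, dtype, name="cls"),
            nn.LogSoftmax(),
        ]),
    ))
    model = nn.Model(blocks)
    model.config = cfg  # type: ignore[attr-defined]
    model.input_samples = input_samples  # type: ignore[attr-defined]
    return model


_KINDS = {
    "conv2dtype0": "temporal conv + BN",
    "conv2dtype1": "temporal conv residual",
    "conv2dtype2": "spatial conv + pool",
    "conv2dtype3": "separable conv residual",
    "conv2dtype4": "separable conv + pool",
    "classifier": "full-extent conv + logsoftmax",
}


def model_summary(model: nn.Model,
                  input_geometry: tuple[int, int] = (N_CHANNELS, EPOCH_SAMPLES)
                  ) -> LayerSummary:
    """Trace per-block output extents and parameter counts.

    Runs one zero forward pass in eval mode on the given (channels,
    samples) geometry; the default configuration yields 19 blocks
    (1 + 10 + 1 + 5 + 1 + 1).
    """
    channels, samples = input_geometry
    x = nn.to_internal(np.zeros((1, 1, channels, samples)))
    summary = LayerSummary(notes={"batchnorm_eps": 1e-5, "batchnorm_momentum": 0.1})
    in_maps = 1
    for name, layer in model.blocks:
        x = layer.forward(x, train=False)
        if x.ndim == 4:  # time-major (T, F, N, C)
            out_maps, out_ch, out_t = x.shape[1], x.shape[3], x.shape[0]
        else:  # classifier scores (N, n_class)
            out_maps, out_ch, out_t = x.shape[1], 1, 1
        kind = _KINDS.get(name.split(".")[0], "block")
        n_params = sum(p.value.size for p in layer.parameters())
        summary.blocks.append(
            BlockSummary(name, kind, in_maps, out_maps, out_ch, out_t, n_params)
        )
        in_maps = out_maps
    return summary
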