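"""Bi-directional ConvLSTM segmentation head.

The method's core computation: each (slice, attention-map) pair is
stacked as a 2-channel image and passed through two residual blocks;
the resulting feature-map sequence runs through two ConvLSTM passes,
forward and backward, whose hidden states are fused per position
(channel concatenation by default, elementwise sum optionally); a final
convolution stack maps the fused features of the target position to a
single-channel logit map, and a sigmoid yields the per-pixel thrombus
probability.  Training minimizes focal loss against the target slice's
ground-truth mask with plain SGD.

ConvLSTM gate equations (sigma = logistic, * = convolution, o = Hadamard):

    i_t = sigma(W_xi * x_t + W_hi * H_{t-1} [+ W_ci o C_{t-1}] + b_i)
    f_t = sigma(W_xf * x_t + W_hf * H_{t-1} [+ W_cf o C_{t-1}] + b_f)
    g_t = tanh (W_xg * x_t + W_hg * H_{t-1}                    + b_g)
    C_t = f_t o C_{t-1} + i_t o g_t
    o_t = sigma(W_xo * x_t + W_ho * H_{t-1} [+ W_co o C_t]     + b_o)
    H_t = o_t o tanh(C_t)

Peephole (cell-to-gate) terms are on by default and per-channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .augment import PairSequence
from .backbone import AttentionMap
from .nn import SGD, BatchNorm2d, Conv2d, Module, Parameter, Tensor, concat, conv2d
from .nn.layers import he_normal
from .training import TrainConfig, focal_loss

__all__ = [
    "HeadConfig",
    "ConvLSTMState",
    "ConvLSTMCell",
    "ResidualBlock",
    "BiCLSTMHead",
    "convlstm_step",
    "run_bidirectional",
    "predict",
    "train_head",
    "focal_loss",
]


@dataclass(frozen=True)
class HeadConfig:
    """Architecture and inference settings of the sequence head.

    Defaults follow the reference architecture: 64-filter residual
    blocks, a 128-filter ConvLSTM in each direction, concatenation
    fusion absorbed by a 64-filter convolution, 3x3 ConvLSTM kernels,
    peepholes enabled.  ``prediction_threshold`` uses >= so ties go to
    foreground.
    """

    in_channels: int = 2
    residual_filters: int = 64
    clstm_filters: int = 128
    fusion_filters: int = 64
    fusion_mode: str = "concat"
    kernel_size: int = 3
    peephole: bool = True
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    prediction_threshold: float = 0.5
    output_scope: str = "target_slice"

    def __post_init__(self):
        if self.fusion_mode not in ("concat", "sum"):
            raise ValueError("fusion_mode must be 'concat' or 'sum'")
        if self.output_scope not in ("target_slice", "all_slices"):
            raise ValueError("output_scope must be 'target_slice' or 'all_slices'")
        if not (0.0 <= self.prediction_threshold <= 1.0):
            raise ValueError("prediction_threshold must be in [0, 1]")
        if not (0.0 <= self.focal_alpha <= 1.0) or self.focal_gamma < 0:
            raise ValueError("invalid focal loss parameters")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")


class ConvLSTMState(NamedTuple):
    """Hidden and cell feature maps, zero-initialized at sequence start."""

    h: Tensor
    c: Tensor


class ResidualBlock(Module):
    """Conv-BN-ReLU-Conv-BN with a ReLU-capped residual connection.

    The skip path is the identity when the channel count already matches,
    otherwise a 1x1 projection.
    """

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(in_channels, out_channels, 3, rng)
        self.bn1 = BatchNorm2d(out_channels)
        self.conv2 = Conv2d(out_channels, out_channels, 3, rng)
        self.bn2 = BatchNorm2d(out_channels)
        if in_channels != out_channels:
            self.project = Conv2d(in_channels, out_channels, 1, rng)
        else:
            self.project = None

    def forward(self, x: Tensor) -> Tensor:
        f = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        skip = x if self.project is None else self.project(x)
        return (skip + f).relu()


class ConvLSTMCell(Module):
    """ConvLSTM cell with 2D-convolutional gates and optional peepholes."""

    def __init__(
        self,
        in_channels: int,
        filters: int = 128,
        kernel_size: int = 3,
        peephole: bool = True,
        rng: np.random.Generator | int = 0,
    ):
        super().__init__()
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.in_channels = in_channels
        self.filters = filters
        self.kernel_size = kernel_size
        self.peephole = peephole
        k = kernel_size
        fan_x, fan_h = in_channels * k * k, filters * k * k
        for gate in "ifog":
            setattr(
                self,
                f"w_x{gate}",
                Parameter(he_normal(rng, (filters, in_channels, k, k), fan_x)),
            )
            setattr(
                self,
                f"w_h{gate}",
                Parameter(he_normal(rng, (filters, filters, k, k), fan_h)),
            )
            setattr(self, f"b_{gate}", Parameter(np.zeros(filters)))
        if peephole:
            for gate in "ifo":
                setattr(self, f"w_c{gate}", Parameter(np.zeros((1, filters, 1, 1))))
        # forget-gate bias at 1 keeps early cell memory open
        self.b_f.data[:] = 1.0

    def zero_state(self, batch: int, height: int, width: int) -> ConvLSTMState:
        shape = (batch, self.filters, height, width)
        return ConvLSTMState(Tensor(np.zeros(shape)), Tensor(np.zeros(shape)))

    def step(self, x: Tensor, state: ConvLSTMState | None = None) -> ConvLSTMState:
        B, C, H, W = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {C}")
        if state is None:
            state = self.zero_state(B, H, W)
        h, c = state
        if h.shape != (B, self.filters, H, W):
            raise ValueError(f"state shape {h.shape} incompatible with input {x.shape}")

        def gate(name: str, extra: Tensor | None = None) -> Tensor:
            pre = conv2d(x, getattr(self, f"w_x{name}"), getattr(self, f"b_{name}")) + conv2d(
                h, getattr(self, f"w_h{name}")
            )
            if extra is not None:
                pre = pre + extra
            return pre

        peep = lambda name, cell: (
            getattr(self, f"w_c{name}") * cell if self.peephole else None
        )
        i = gate("i", peep("i", c)).sigmoid()
        f = gate("f", peep("f", c)).sigmoid()
        g = gate("g").tanh()
        c_new = f * c + i * g
        o = gate("o", peep("o", c_new)).sigmoid()
        h_new = o * c_new.tanh()
        return ConvLSTMState(h_new, c_new)


def convlstm_step(
    x_t: Tensor | np.ndarray, state: ConvLSTMState | None, params: ConvLSTMCell
) -> ConvLSTMState:
    """One ConvLSTM gate update; ``state=None`` starts from zeros."""
    x_t = x_t if isinstance(x_t, Tensor) else Tensor(x_t)
    return params.step(x_t, state)


def run_bidirectional(
    seq: list[Tensor],
    params_fwd: ConvLSTMCell,
    params_bwd: ConvLSTMCell,
    fusion_mode: str = "concat",
) -> list[Tensor]:
    """Forward and backward ConvLSTM passes with per-position fusion.

    The backward pass runs over the reversed sequence and its outputs are
    re-reversed so position t fuses the two directions' views of the same
    element.  ``concat`` stacks channels [fwd; bwd]; ``sum`` adds them.
    """
    if not seq:
        raise ValueError("empty sequence")
    if fusion_mode not in ("concat", "sum"):
        raise ValueError("fusion_mode must be 'concat' or 'sum'")
    state = None
    fwd = []
    for x in seq:
        state = params_fwd.step(x if isinstance(x, Tensor) else Tensor(x), state)
        fwd.append(state.h)
    state = None
    bwd = []
    for x in reversed(seq):
        state = params_bwd.step(x if isinstance(x, Tensor) else Tensor(x), state)
        bwd.append(state.h)
    bwd.reverse()
    if fusion_mode == "concat":
        return [concat([f, b], axis=1) for f, b in zip(fwd, bwd)]
    return [f + b for f, b in zip(fwd, bwd)]


def _pair_to_input(img: np.ndarray, att) -> Tensor:
    a = att.values if isinstance(att, AttentionMap) else np.asarray(att, dtype=np.float64)
    x = np.stack([np.asarray(img, dtype=np.float64) / 255.0, a])
    return Tensor(x[None])


class BiCLSTMHead(Module):
    """The full sequence-to-target-mask model."""

    kind = "head"

    def __init__(self, cfg: HeadConfig | None = None, rng: np.random.Generator | int = 0):
        super().__init__()
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.cfg = cfg or HeadConfig()
        c = self.cfg
        self.res1 = ResidualBlock(c.in_channels, c.residual_filters, rng)
        self.res2 = ResidualBlock(c.residual_filters, c.residual_filters, rng)
        self.cell_fwd = ConvLSTMCell(
            c.residual_filters, c.clstm_filters, c.kernel_size, c.peephole, rng
        )
        self.cell_bwd = ConvLSTMCell(
            c.residual_filters, c.clstm_filters, c.kernel_size, c.peephole, rng
        )
        fused_channels = c.clstm_filters * (2 if c.fusion_mode == "concat" else 1)
        self.fusion_conv = Conv2d(fused_channels, c.fusion_filters, 3, rng)
        self.out_conv = Conv2d(c.fusion_filters, 1, 1, rng)
        self.trained = False

    def forward(self, seq: PairSequence):
        """Probability map(s): one (1,1,H,W) Tensor per requested position."""
        frames = [self.res2(self.res1(_pair_to_input(img, att))) for img, att in seq.pairs]
        fused = run_bidirectional(frames, self.cell_fwd, self.cell_bwd, self.cfg.fusion_mode)
        if self.cfg.output_scope == "target_slice":
            positions = [seq.target_index]
        else:
            positions = list(range(len(fused)))
        probs = [
            self.out_conv(self.fusion_conv(fused[t]).relu()).sigmoid() for t in positions
        ]
        return probs[0] if self.cfg.output_scope == "target_slice" else probs


def predict(
    model: BiCLSTMHead,
    seq: PairSequence,
    allow_untrained: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Probability map and thresholded binary mask for the target slice.

    Thresholding uses >= (ties go to foreground).  Raises on a model whose
    parameters were never trained or loaded, unless explicitly allowed.
    """
    if not model.trained and not allow_untrained:
        raise RuntimeError("model parameters not trained/loaded; pass allow_untrained=True")
    was_training = model.training
    model.eval()
    out = model(seq)
    if was_training:
        model.train()
    prob_t = out if isinstance(out, Tensor) else out[seq.target_index]
    probs = prob_t.data[0, 0]
    mask = (probs >= model.cfg.prediction_threshold).astype(np.uint8)
    return probs, mask


def train_head(
    model: BiCLSTMHead,
    sequences: list[tuple[PairSequence, np.ndarray]],
    train_cfg: TrainConfig,
    augment=None,
) -> tuple[BiCLSTMHead, list[float]]:
    """SGD training on (sequence, target GT mask) samples; focal loss.

    Learning rate defaults to 0.005.  ``augment``, if given, is called as
    ``augment(seq, gt, rng)`` per step for on-the-fly whole-sequence
    augmentation.  Deterministic given the seed: the sampling order and
    every array operation are reproducible.
    """
    if not sequences:
        raise ValueError("empty training set")
    lr = train_cfg.lr if train_cfg.lr is not None else 0.005
    opt = SGD(model.parameters(), lr=lr, momentum=train_cfg.momentum)
    rng = np.random.default_rng(train_cfg.seed)
    losses: list[float] = []
    model.train()
    for _ in range(train_cfg.steps):
        seq, gt = sequences[int(rng.integers(len(sequences)))]
        if augment is not None:
            seq, gt = augment(seq, gt, rng)
        out = model(seq)
        prob = out if isinstance(out, Tensor) else out[seq.target_index]
        loss = focal_loss(
            prob,
            np.asarray(gt, dtype=np.float64)[None, None],
            alpha=model.cfg.focal_alpha,
            gamma=model.cfg.focal_gamma,
        )
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(loss.item())
    model.trained = True
    model.eval()
    return model, losses
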