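"""Deterministic toy network and synthetic-data generators.

Everything downstream (the dream engine, the temporal-coherence chain, the
statistics) is exercised against the artifacts built here, so every generator
is a pure function of its spec, seed included.

The toy network stands in for a large pretrained classification network: it
exposes forward activations at named layers and the gradient of a scalar
activation objective with respect to the input image, which is the whole
contract the dream engine needs.  Weights are random (seeded), not trained —
layer-depth-dependent dream texture emerges from architecture alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConvOp",
    "ReluOp",
    "MaxPoolOp",
    "ToyNetSpec",
    "ToyConvNet",
    "build_toy_net",
    "default_toy_net",
    "SyntheticVideoSpec",
    "generate_synthetic_video",
    "ASCQ_DIMENSIONS",
    "SyntheticRatingsSpec",
    "generate_synthetic_ratings",
    "SyntheticTimingSpec",
    "generate_synthetic_timing",
]


# ---------------------------------------------------------------------------
# Toy network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvOp:
    """2-D cross-correlation layer, stride 1, 'same' spatial output.

    ``pad_mode`` selects zero padding or cyclic (wrap) padding; with wrap
    padding the whole net is exactly equivariant to cyclic image shifts,
    which pairs with equirectangular frames whose left/right edges meet.
    """

    out_channels: int
    kernel: int = 3
    pad_mode: Literal["zero", "wrap"] = "zero"

    def __post_init__(self) -> None:
        if self.kernel % 2 != 1 or self.kernel < 1:
            raise ValueError("kernel size must be odd and positive")
        if self.out_channels < 1:
            raise ValueError("out_channels must be >= 1")


@dataclass(frozen=True)
class ReluOp:
    pass


@dataclass(frozen=True)
class MaxPoolOp:
    """2x2 max pool, stride 2; requires even spatial dims."""


LayerDef = tuple[str, "ConvOp | ReluOp | MaxPoolOp"]


@dataclass(frozen=True)
class ToyNetSpec:
    """Architecture + seed; identical spec => bit-identical weights.

    ``weight_scale`` multiplies the uniform init half-width 0.5 * fan_in^-1/2.
    """

    layer_defs: tuple[LayerDef, ...]
    seed: int = 0
    weight_scale: float = 1.0

    def __post_init__(self) -> None:
        ids = [lid for lid, _ in self.layer_defs]
        if len(set(ids)) != len(ids):
            raise ValueError("layer ids must be unique")
        for lid, op in self.layer_defs:
            if not isinstance(op, (ConvOp, ReluOp, MaxPoolOp)):
                raise ValueError(f"unknown layer operation for {lid!r}: {op!r}")


def _pad_index(h: int, w: int, p: int, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Index maps (rows, cols) from padded pixel to source pixel; -1 marks
    zero-padding (no source)."""
    rows = np.arange(-p, h + p)
    cols = np.arange(-p, w + p)
    if mode == "wrap":
        return rows % h, cols % w
    rows = np.where((rows >= 0) & (rows < h), rows, -1)
    cols = np.where((cols >= 0) & (cols < w), cols, -1)
    return rows, cols


def _pad(x: np.ndarray, p: int, mode: str) -> np.ndarray:
    if p == 0:
        return x
    if mode == "wrap":
        return np.pad(x, ((p, p), (p, p), (0, 0)), mode="wrap")
    return np.pad(x, ((p, p), (p, p), (0, 0)), mode="constant")


def _pad_adjoint(gxp: np.ndarray, h: int, w: int, p: int, mode: str) -> np.ndarray:
    """Adjoint of `_pad`: scatter-add padded-gradient pixels back to sources."""
    if p == 0:
        return gxp
    rows, cols = _pad_index(h, w, p, mode)
    out = np.zeros((h, w, gxp.shape[2]), dtype=gxp.dtype)
    rmask, cmask = rows >= 0, cols >= 0
    sub = gxp[np.ix_(rmask, cmask)]
    np.add.at(out, (rows[rmask][:, None], cols[cmask][None, :]), sub)
    return out


class ToyConvNet:
    """Seeded conv net satisfying the LayerActivationModel contract.

    ``activations(image, layer_id)`` runs the forward pass up to the named
    layer; ``input_gradient(image, layer_id, channel=None)`` returns the
    gradient of the dream objective (half the sum of squared activations at
    that layer, optionally restricted to one channel) with respect to every
    input pixel, plus the objective value itself.  Weights are fixed at
    construction; backprop never touches them.
    """

    def __init__(self, spec: ToyNetSpec):
        self.spec = spec
        self.layer_ids: list[str] = [lid for lid, _ in spec.layer_defs]
        rng = np.random.default_rng(spec.seed)
        self._weights: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        in_ch = 3
        for lid, op in spec.layer_defs:
            if isinstance(op, ConvOp):
                fan_in = in_ch * op.kernel * op.kernel
                a = 0.5 * spec.weight_scale / np.sqrt(fan_in)
                w = rng.uniform(-a, a, size=(op.out_channels, in_ch, op.kernel, op.kernel))
                b = np.zeros(op.out_channels)
                self._weights[lid] = (w, b)
                in_ch = op.out_channels

    # -- forward -----------------------------------------------------------

    def _forward(self, image: np.ndarray, layer_id: str) -> list[tuple[str, np.ndarray]]:
        """Activations of every layer up to and including layer_id (inputs
        cached for backprop)."""
        if layer_id not in self.layer_ids:
            raise KeyError(f"unknown layer id {layer_id!r}; have {self.layer_ids}")
        x = np.asarray(image, dtype=np.float64)
        if x.ndim != 3 or x.shape[2] != 3:
            raise ValueError("image must be H x W x 3")
        if not np.all(np.isfinite(x)):
            raise ValueError("image contains non-finite values")
        trace: list[tuple[str, np.ndarray]] = [("__input__", x)]
        for lid, op in self.spec.layer_defs:
            if isinstance(op, ConvOp):
                w, b = self._weights[lid]
                p = op.kernel // 2
                xp = _pad(x, p, op.pad_mode)
                win = np.lib.stride_tricks.sliding_window_view(xp, (op.kernel, op.kernel), axis=(0, 1))
                # win: (H, W, Cin, K, K); w: (Cout, Cin, K, K)
                x = np.einsum("hwckl,ockl->hwo", win, w, optimize=True) + b
            elif isinstance(op, ReluOp):
                x = np.maximum(x, 0.0)
            elif isinstance(op, MaxPoolOp):
                h, w_, c = x.shape
                if h % 2 or w_ % 2:
                    raise ValueError("max-pool input dims must be even")
                x = x.reshape(h // 2, 2, w_ // 2, 2, c).max(axis=(1, 3))
            trace.append((lid, x))
            if lid == layer_id:
                break
        return trace

    def activations(self, image: np.ndarray, layer_id: str) -> np.ndarray:
        return self._forward(image, layer_id)[-1][1]

    # -- backward ----------------------------------------------------------

    def input_gradient(
        self, image: np.ndarray, layer_id: str, channel: int | None = None
    ) -> tuple[np.ndarray, float]:
        """Gradient of 0.5 * sum(a^2) at `layer_id` w.r.t. the input image.

        Returns ``(grad, objective)``; with ``channel`` set, the objective is
        restricted to that activation channel (guided dream).
        """
        trace = self._forward(image, layer_id)
        act = trace[-1][1]
        if channel is None:
            grad = act.copy()
            obj = 0.5 * float(np.sum(act * act))
        else:
            grad = np.zeros_like(act)
            grad[..., channel] = act[..., channel]
            obj = 0.5 * float(np.sum(act[..., channel] ** 2))

        ops = dict(self.spec.layer_defs)
        for i in range(len(trace) - 1, 0, -1):
            lid, out = trace[i]
            inp = trace[i - 1][1]
            op = ops[lid]
            if isinstance(op, ConvOp):
                w, _b = self._weights[lid]
                k, p = op.kernel, op.kernel // 2
                gpad = np.pad(grad, ((k - 1, k - 1), (k - 1, k - 1), (0, 0)), mode="constant")
                win = np.lib.stride_tricks.sliding_window_view(gpad, (k, k), axis=(0, 1))
                # full correlation with spatially flipped kernels, out<->in swapped
                gxp = np.einsum("hwokl,ockl->hwc", win, w[:, :, ::-1, ::-1], optimize=True)
                grad = _pad_adjoint(gxp, inp.shape[0], inp.shape[1], p, op.pad_mode)
            elif isinstance(op, ReluOp):
                grad = grad * (out > 0.0)
            elif isinstance(op, MaxPoolOp):
                h, w_, c = inp.shape
                blocks = inp.reshape(h // 2, 2, w_ // 2, 2, c).transpose(0, 2, 4, 1, 3).reshape(h // 2, w_ // 2, c, 4)
                arg = blocks.argmax(axis=3)
                g = np.zeros_like(blocks)
                np.put_along_axis(g, arg[..., None], grad[..., None], axis=3)
                grad = g.reshape(h // 2, w_ // 2, c, 2, 2).transpose(0, 3, 1, 4, 2).reshape(h, w_, c)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError("non-finite values in backpropagated gradient")
        return grad, obj


def build_toy_net(spec: ToyNetSpec) -> ToyConvNet:
    """Construct the seeded toy network (deterministic in the spec)."""
    return ToyConvNet(spec)


def default_toy_net(seed: int = 0, pad_mode: Literal["zero", "wrap"] = "zero") -> ToyConvNet:
    """Three conv+rectifier blocks, 3->8->16->16 channels, 3x3 kernels.

    Selectable activation layers: ``relu1`` (shallow), ``relu2`` (middle),
    ``relu3`` (deep).
    """
    defs: tuple[LayerDef, ...] = (
        ("conv1", ConvOp(8, pad_mode=pad_mode)),
        ("relu1", ReluOp()),
        ("conv2", ConvOp(16, pad_mode=pad_mode)),
        ("relu2", ReluOp()),
        ("conv3", ConvOp(16, pad_mode=pad_mode)),
        ("relu3", ReluOp()),
    )
    return build_toy_net(ToyNetSpec(layer_defs=defs, seed=seed))


# ---------------------------------------------------------------------------
# Synthetic video with ground-truth flow
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticVideoSpec:
    """Moving-texture video: static textured background plus a textured patch
    translated by an integer (dx, dy) per frame.  Ground-truth flow is
    exactly (dx, dy) inside the patch footprint of the current frame and
    (0, 0) elsewhere."""

    n_frames: int = 8
    width: int = 64
    height: int = 64
    patch_size: int = 24
    patch_x0: int = 8
    patch_y0: int = 20
    dx: int = 3
    dy: int = 0
    bg_smooth: float = 2.0
    patch_smooth: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def generate_synthetic_video(
    spec: SyntheticVideoSpec,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Frames (H x W x 3 float in [0, 255]) and per-pair ground-truth flow
    (H x W x 2, [..., 0] = dx along columns, [..., 1] = dy along rows).

    The background texture is smoothed with cyclic boundary handling so the
    left/right frame edges are continuous, as in equirectangular footage.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(spec.seed)
    h, w, s = spec.height, spec.width, spec.patch_size
    bg = gaussian_filter(rng.uniform(0, 255, (h, w, 3)), (spec.bg_smooth, spec.bg_smooth, 0), mode="wrap")
    patch = gaussian_filter(rng.uniform(0, 255, (s, s, 3)), (spec.patch_smooth, spec.patch_smooth, 0))

    frames: list[np.ndarray] = []
    flows: list[np.ndarray] = []
    for t in range(spec.n_frames):
        x0 = spec.patch_x0 + t * spec.dx
        y0 = spec.patch_y0 + t * spec.dy
        if x0 < 0 or y0 < 0 or x0 + s > w or y0 + s > h:
            raise ValueError(f"patch translated outside frame at frame {t}")
        f = bg.copy()
        f[y0 : y0 + s, x0 : x0 + s] = patch
        frames.append(np.clip(f, 0.0, 255.0))
        if t >= 1:
            flow = np.zeros((h, w, 2))
            flow[y0 : y0 + s, x0 : x0 + s, 0] = spec.dx
            flow[y0 : y0 + s, x0 : x0 + s, 1] = spec.dy
            flows.append(flow)
    return frames, flows


# ---------------------------------------------------------------------------
# Synthetic questionnaire ratings
# ---------------------------------------------------------------------------

#: The 17 altered-states-of-consciousness questionnaire dimensions.
ASCQ_DIMENSIONS: tuple[str, ...] = (
    "intensity", "patterns", "imagery", "mood", "ego", "arousal", "strange",
    "vivid", "time", "space", "muddle", "merge", "control", "spirit",
    "peace", "float", "past",
)


@dataclass(frozen=True)
class SyntheticRatingsSpec:
    """Two-condition visual-analog ratings with known standardized effects.

    ``delta`` maps dimension -> standardized paired effect (mean difference
    over SD of differences); dimensions absent from the map get 0.  Ratings
    live on a [0, 100] visual-analog scale and are clipped to it.
    """

    n_subjects: int = 12
    dimensions: tuple[str, ...] = ASCQ_DIMENSIONS
    delta: dict[str, float] = field(default_factory=dict)
    conditions: tuple[str, str] = ("control", "hallucination_machine")
    baseline_mean: float = 40.0
    baseline_sd: float = 12.0
    diff_sd: float = 10.0
    scale: tuple[float, float] = (0.0, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for dim, d in self.delta.items():
            if not np.isfinite(d):
                raise ValueError(f"delta for {dim!r} must be finite")


def generate_synthetic_ratings(spec: SyntheticRatingsSpec) -> pd.DataFrame:
    """Complete long-format table (subject, condition, dimension, rating)."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.scale
    rows = []
    for dim in spec.dimensions:
        d = spec.delta.get(dim, 0.0)
        base = rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_subjects)
        diff = rng.normal(d * spec.diff_sd, spec.diff_sd, spec.n_subjects)
        a = np.clip(base, lo, hi)
        b = np.clip(base + diff, lo, hi)
        for s in range(spec.n_subjects):
            rows.append((s, spec.conditions[0], dim, a[s]))
            rows.append((s, spec.conditions[1], dim, b[s]))
    return pd.DataFrame(rows, columns=["subject", "condition", "dimension", "rating"])


# ---------------------------------------------------------------------------
# Synthetic temporal-production responses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticTimingSpec:
    """Tone-cued temporal production with scalar-timing noise.

    Produced interval ~ target * (1 + bias) + Normal(0, (weber * target)^2),
    truncated at a small positive floor — scalar timing: noise SD grows
    linearly with the target.  Tone metadata (pitch per target, 250 ms cue)
    is carried for table completeness; no audio is rendered.
    """

    target_intervals: dict[str, float] = field(
        default_factory=lambda: {"low": 1.0, "mid": 2.0, "high": 4.0}
    )
    tone_hz: dict[str, float] = field(
        default_factory=lambda: {"low": 220.0, "mid": 440.0, "high": 1760.0}
    )
    tone_ms: float = 250.0
    n_subjects: int = 21
    n_trials: int = 5
    blocks: tuple[str, ...] = ("control", "hallucination_machine")
    weber: float = 0.15
    bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weber < 0:
            raise ValueError("weber fraction must be >= 0")


def generate_synthetic_timing(spec: SyntheticTimingSpec) -> pd.DataFrame:
    """(subject, block, video_type, target_s, produced_s) trial rows."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for s in range(spec.n_subjects):
        for block_i, video_type in enumerate(spec.blocks):
            for name, target in spec.target_intervals.items():
                produced = target * (1.0 + spec.bias) + rng.normal(
                    0.0, spec.weber * target, spec.n_trials
                )
                produced = np.maximum(produced, 1e-3)
                for p in produced:
                    rows.append((s, block_i, video_type, target, p))
    return pd.DataFrame(
        rows, columns=["subject", "block", "video_type", "target_s", "produced_s"]
    )
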