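"""Single-image Deep Dream by multi-octave gradient ascent.

The engine clamps a chosen network layer and iteratively rewrites the input
image to amplify whatever that layer already responds to: the ascent
objective is half the sum of squared layer activations (optionally one
channel, for guided dreams).  Dreaming runs coarse-to-fine over an octave
pyramid; the dreamed detail found at each scale is carried up in a detail
buffer.  A random cyclic pixel jitter before every step (undone after)
suppresses grid artifacts.

Shallow layers yield geometric textures; deep layers yield object-like
content — the simple/complex hallucination distinction the engine emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._imageops import WORKING_RANGE, as_image, clamp, resize_bilinear

__all__ = [
    "DreamConfig",
    "LAYER_PRESETS",
    "objective",
    "ascent_step",
    "octave_sizes",
    "dream_image",
    "apply_zoom",
]

#: Named layer presets mirroring the classic choice of a higher layer
#: (object-like content), a middle layer (object parts) and a lower layer
#: (geometric features), mapped onto the toy net's three rectifier outputs.
LAYER_PRESETS = {"higher": "relu3", "middle": "relu2", "lower": "relu1"}


@dataclass(frozen=True)
class DreamConfig:
    """All dream parameters, defaulting to the published video settings:
    octaves 3, octave scale 1.8, 32 iterations per octave, jitter 32 px,
    zoom 1 (disabled), step size 1.5."""

    layer_id: str = LAYER_PRESETS["higher"]
    octaves: int = 3
    octave_scale: float = 1.8
    iterations: int = 32
    jitter: int = 32
    zoom: float = 1.0
    step_size: float = 1.5
    seed: int = 0
    channel: int | None = None  # guided dream: restrict objective to one channel

    def __post_init__(self) -> None:
        if self.octaves < 1:
            raise ValueError("octaves must be >= 1")
        if self.octave_scale <= 1:
            raise ValueError("octave_scale must be > 1")
        if self.iterations < 0 or self.jitter < 0 or self.step_size < 0:
            raise ValueError("iterations, jitter and step_size must be >= 0")
        if self.zoom < 1:
            raise ValueError("zoom must be >= 1")

    def with_preset(self, preset: str) -> "DreamConfig":
        return replace(self, layer_id=LAYER_PRESETS[preset])


def objective(activations: np.ndarray) -> float:
    """Half the sum of squared activations of the clamped layer."""
    a = np.asarray(activations, dtype=np.float64)
    if a.size == 0:
        raise ValueError("empty activation tensor")
    return 0.5 * float(np.sum(a * a))


def ascent_step(
    image: np.ndarray,
    model,
    layer_id: str,
    step_size: float,
    jitter: int,
    rng: np.random.Generator,
    channel: int | None = None,
) -> np.ndarray:
    """One jittered gradient-ascent step on the image.

    Draws a cyclic shift uniform on [-jitter, jitter]^2, shifts, adds
    ``step_size * g / mean(|g|)`` (the scale-free Deep Dream step), shifts
    back and clamps to the working range.  A uniformly zero gradient leaves
    the image unchanged.
    """
    if step_size < 0 or jitter < 0:
        raise ValueError("step_size and jitter must be >= 0")
    image = as_image(image)
    ox = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
    oy = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
    shifted = np.roll(image, (oy, ox), axis=(0, 1))
    grad, _obj = model.input_gradient(shifted, layer_id, channel=channel)
    scale = np.mean(np.abs(grad))
    if scale > 0 and step_size > 0:
        shifted = shifted + step_size * grad / scale
    out = np.roll(shifted, (-oy, -ox), axis=(0, 1))
    return clamp(out)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def octave_sizes(
    base_hw: tuple[int, int], octaves: int, octave_scale: float
) -> list[tuple[int, int]]:
    """Pyramid sizes from smallest to largest; the last equals the base.

    size_k = round(base / octave_scale**k), rounding half away from zero.
    """
    if octaves < 1:
        raise ValueError("octaves must be >= 1")
    h, w = base_hw
    sizes = []
    for k in range(octaves - 1, -1, -1):
        f = octave_scale**k
        sh, sw = _round_half_away(h / f), _round_half_away(w / f)
        if sh < 8 or sw < 8:
            raise ValueError(
                f"octave {k} size {sh}x{sw} below the 8 px minimum; "
                "reduce octaves or octave_scale"
            )
        sizes.append((sh, sw))
    return sizes


def dream_image(
    image: np.ndarray, model, config: DreamConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Dream one image over the octave pyramid; deterministic given the seed.

    Classic octave loop: for each size ascending, resize the base image,
    upsample the accumulated detail buffer, add, run the per-octave ascent
    iterations, and bank the new detail (result minus resized base).
    """
    image = as_image(image)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sizes = octave_sizes(image.shape[:2], config.octaves, config.octave_scale)
    detail = np.zeros((*sizes[0], 3))
    out = image
    for size in sizes:
        base = resize_bilinear(image, size)
        detail = resize_bilinear(detail, size)
        out = clamp(base + detail)
        for _ in range(config.iterations):
            out = ascent_step(
                out, model, config.layer_id, config.step_size, config.jitter, rng,
                channel=config.channel,
            )
        detail = out - base
    return out


def apply_zoom(image: np.ndarray, zoom: float) -> np.ndarray:
    """Centre-crop to 1/zoom of the extent and resize back (dream-zoom).

    zoom = 1 is the identity.
    """
    if zoom < 1:
        raise ValueError("zoom must be >= 1")
    image = as_image(image)
    if zoom == 1.0:
        return image.copy()
    h, w = image.shape[:2]
    ch, cw = _round_half_away(h / zoom), _round_half_away(w / zoom)
    if ch < 2 or cw < 2:
        raise ValueError("zoom crop smaller than 2 px")
    r0, c0 = (h - ch) // 2, (w - cw) // 2
    crop = image[r0 : r0 + ch, c0 : c0 + cw]
    return resize_bilinear(crop, (h, w))
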