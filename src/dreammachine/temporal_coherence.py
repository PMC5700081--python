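"""Optical-flow temporal coherence between consecutive dreamed frames.

Dreaming each frame from scratch flickers: hallucinatory content has no
frame-to-frame identity.  The fix is inheritance — estimate dense optical
flow from the previous raw frame to the current one, warp the previous
*dreamed* frame along that flow so its hallucinatory patterns track scene
motion, and blend it convexly into the current raw frame before dreaming.
The blend weight is per-pixel: 0.9 where flow magnitude exceeds a threshold
(moving foreground) and 0.1 in static background, which keeps static regions
from saturating under repeated inheritance.

Flow convention: ``flow[r, c] = (dx, dy)`` is the displacement of the scene
point now at pixel (r, c), previous -> current, so the backward warp
``out(p) = prev(p - flow(p))`` aligns the previous frame with the current.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.registration import optical_flow_ilk

from ._imageops import as_image, to_gray

__all__ = [
    "CoherenceConfig",
    "estimate_flow",
    "warp_by_flow",
    "flow_ratio_map",
    "blend_frames",
    "coherent_input",
]


@dataclass(frozen=True)
class CoherenceConfig:
    """Blending and flow-estimator settings.

    fg_ratio / bg_ratio are the published 0.9 / 0.1 blend weights for
    high-flow (moving) and low-flow (static) areas; flow_threshold (px)
    separates the two.  The estimator is iterative Lucas-Kanade with the
    fixed settings recorded here; ``carry`` selects whether the full previous
    dreamed frame or only its dreamed-minus-raw residual is inherited, and
    ``warp`` can disable motion-compensation of the inherited content.
    """

    fg_ratio: float = 0.9
    bg_ratio: float = 0.1
    flow_threshold: float = 1.0
    ilk_radius: int = 7
    ilk_num_warp: int = 10
    ilk_gaussian: bool = False
    carry: Literal["frame", "residual"] = "frame"
    warp: bool = True
    equirect: bool = False

    def __post_init__(self) -> None:
        for r in (self.fg_ratio, self.bg_ratio):
            if not 0.0 <= r <= 1.0:
                raise ValueError("blend ratios must lie in [0, 1]")
        if self.flow_threshold < 0:
            raise ValueError("flow_threshold must be >= 0")


def estimate_flow(
    prev: np.ndarray, cur: np.ndarray, config: CoherenceConfig = CoherenceConfig()
) -> np.ndarray:
    """Dense displacement field previous -> current, H x W x 2 (dx, dy).

    Deterministic for fixed inputs and settings.
    """
    prev, cur = as_image(prev), as_image(cur)
    if prev.shape != cur.shape:
        raise ValueError(f"frame dims differ: {prev.shape} vs {cur.shape}")
    g_prev, g_cur = to_gray(prev), to_gray(cur)
    # reference = current: ILK returns (v, u) with prev(p + (v, u)) ~ cur(p),
    # i.e. the negative of our previous->current displacement.
    v, u = optical_flow_ilk(
        g_cur, g_prev,
        radius=config.ilk_radius,
        num_warp=config.ilk_num_warp,
        gaussian=config.ilk_gaussian,
    )
    flow = np.stack([-u, -v], axis=-1).astype(np.float64)
    return flow


def warp_by_flow(
    image: np.ndarray, flow: np.ndarray, equirect: bool = False
) -> np.ndarray:
    """Backward-warp: output(p) = image(p - flow(p)), bilinear sampling.

    Out-of-bounds samples clamp to the nearest edge; in equirect mode the
    horizontal axis wraps (left/right edges are physically contiguous) while
    the vertical axis still clamps (poles).
    """
    image = as_image(image)
    flow = np.asarray(flow, dtype=np.float64)
    if flow.shape[:2] != image.shape[:2] or flow.shape[2] != 2:
        raise ValueError("flow dims must match frame dims")
    if not np.all(np.isfinite(flow)):
        raise ValueError("non-finite flow")
    h, w = image.shape[:2]
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    rows = rr - flow[..., 1]
    cols = cc - flow[..., 0]
    rows = np.clip(rows, 0, h - 1)
    if equirect:
        mode = "grid-wrap"  # rows already clamped in-range; wraps columns
    else:
        mode = "nearest"
        cols = np.clip(cols, 0, w - 1)
    out = np.empty_like(image)
    for c in range(3):
        out[..., c] = map_coordinates(image[..., c], [rows, cols], order=1, mode=mode)
    return out


def flow_ratio_map(flow: np.ndarray, config: CoherenceConfig = CoherenceConfig()) -> np.ndarray:
    """Per-pixel blend weight: fg_ratio where ||flow|| > threshold, else bg_ratio."""
    flow = np.asarray(flow, dtype=np.float64)
    mag = np.hypot(flow[..., 0], flow[..., 1])
    return np.where(mag > config.flow_threshold, config.fg_ratio, config.bg_ratio)


def blend_frames(
    cur_raw: np.ndarray, warped_prev_dreamed: np.ndarray, ratio_map: np.ndarray
) -> np.ndarray:
    """Convex per-pixel blend: ratio * inherited + (1 - ratio) * current raw."""
    cur_raw = as_image(cur_raw)
    warped_prev_dreamed = as_image(warped_prev_dreamed)
    ratio = np.asarray(ratio_map, dtype=np.float64)
    if cur_raw.shape != warped_prev_dreamed.shape or ratio.shape != cur_raw.shape[:2]:
        raise ValueError("dims of frames and ratio map must match")
    if np.any(ratio < 0) or np.any(ratio > 1):
        raise ValueError("blend ratios must lie in [0, 1]")
    return ratio[..., None] * warped_prev_dreamed + (1.0 - ratio[..., None]) * cur_raw


def coherent_input(
    prev_raw: np.ndarray,
    prev_dreamed: np.ndarray,
    cur_raw: np.ndarray,
    config: CoherenceConfig = CoherenceConfig(),
) -> np.ndarray:
    """Full coherence chain: flow -> warp inherited content -> ratio map ->
    blend into the current raw frame.  Returns the frame to dream next."""
    flow = estimate_flow(prev_raw, cur_raw, config)
    if config.carry == "residual":
        inherited = prev_dreamed - prev_raw
        if config.warp:
            # warp operates on [0, 255] images; shift the residual into range
            inherited = warp_by_flow(
                np.clip(inherited * 0.5 + 127.5, 0, 255), flow, config.equirect
            ) * 2.0 - 255.0
        ratio = flow_ratio_map(flow, config)
        out = cur_raw + ratio[..., None] * inherited
        return np.clip(out, 0.0, 255.0)
    inherited = warp_by_flow(prev_dreamed, flow, config.equirect) if config.warp else prev_dreamed
    ratio = flow_ratio_map(flow, config)
    return blend_frames(cur_raw, inherited, ratio)
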