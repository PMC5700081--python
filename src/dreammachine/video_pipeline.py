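"""Per-frame video orchestration: read -> flow -> warp -> blend -> dream -> write.

Frame 0 is dreamed directly; every later frame first inherits motion-tracked
hallucinatory content from its predecessor via the temporal-coherence chain,
then is dreamed.  Equirectangular (2:1 panoramic) frames get their left/right
edges wrap-padded before dreaming so the seam stays continuous; the vertical
edges are poles and are never wrapped.

A PNG sequence on disk is the canonical interchange (codec-independent);
every run emits a manifest (config, seeds, per-frame objectives and timings)
sufficient to re-run bit-identically.  Per-frame RNG streams are derived from
(config seed, frame index), so randomness is independent of execution order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from ._imageops import as_image
from .dream_core import DreamConfig, apply_zoom, dream_image, objective
from .temporal_coherence import CoherenceConfig, coherent_input

__all__ = [
    "PipelineConfig",
    "FrameSource",
    "DirectoryFrameSource",
    "ListFrameSource",
    "FrameSink",
    "DirectoryFrameSink",
    "ListFrameSink",
    "read_frames",
    "write_frames",
    "equirect_pad",
    "equirect_unpad",
    "frame_rng",
    "process_video",
    "config_from_manifest",
]

logger = logging.getLogger("dreammachine")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs: dream + coherence settings, panorama handling
    and source metadata (frame rate / resolution are metadata only; the
    published videos ran at 16 fps, 4096 x 2048)."""

    dream: DreamConfig = field(default_factory=DreamConfig)
    coherence: CoherenceConfig = field(default_factory=CoherenceConfig)
    equirect: bool = False
    wrap_pad: int = 16
    frame_rate: float = 16.0

    def __post_init__(self) -> None:
        if self.wrap_pad < 0:
            raise ValueError("wrap_pad must be >= 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")


# ---------------------------------------------------------------------------
# Frame IO
# ---------------------------------------------------------------------------

class FrameSource:
    """Ordered access to uniformly sized frames (H x W x 3 float in [0, 255])."""

    def __len__(self) -> int:  # pragma: no cover - interface
        raise NotImplementedError

    def __iter__(self):  # pragma: no cover - interface
        raise NotImplementedError


class ListFrameSource(FrameSource):
    def __init__(self, frames):
        self.frames = [as_image(f) for f in frames]
        if not self.frames:
            raise ValueError("no frames")

    def __len__(self):
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


class DirectoryFrameSource(FrameSource):
    """PNG sequence read in lexicographic filename order."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.files = sorted(self.path.glob("*.png"))
        if not self.files:
            raise FileNotFoundError(f"no frames (*.png) in {self.path}")

    def __len__(self):
        return len(self.files)

    def __iter__(self):
        shape = None
        for i, f in enumerate(self.files):
            try:
                arr = iio.imread(f)
            except Exception as exc:  # noqa: BLE001 - re-raise with index
                raise IOError(f"unreadable frame {i} ({f.name}): {exc}") from exc
            if arr.ndim == 2:
                arr = np.stack([arr] * 3, axis=-1)
            arr = arr[..., :3].astype(np.float64)
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError(
                    f"frame {i} ({f.name}) size {arr.shape} differs from {shape}"
                )
            yield arr


class FrameSink:
    def write(self, index: int, frame: np.ndarray) -> None:  # pragma: no cover
        raise NotImplementedError

    def write_manifest(self, manifest: dict) -> None:  # pragma: no cover
        raise NotImplementedError


class ListFrameSink(FrameSink):
    def __init__(self):
        self.frames: list[np.ndarray] = []
        self.manifest: dict | None = None

    def write(self, index: int, frame: np.ndarray) -> None:
        assert index == len(self.frames), "frames must arrive in order"
        self.frames.append(frame)

    def write_manifest(self, manifest: dict) -> None:
        self.manifest = manifest


class DirectoryFrameSink(FrameSink):
    """Writes frame_0000.png ... plus manifest.json."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.path.mkdir(parents=True, exist_ok=True)

    def write(self, index: int, frame: np.ndarray) -> None:
        arr = np.clip(np.round(frame), 0, 255).astype(np.uint8)
        iio.imwrite(self.path / f"frame_{index:04d}.png", arr)

    def write_manifest(self, manifest: dict) -> None:
        (self.path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_frames(path: str | Path) -> DirectoryFrameSource:
    return DirectoryFrameSource(path)


def write_frames(sink_path: str | Path, frames) -> DirectoryFrameSink:
    sink = DirectoryFrameSink(sink_path)
    for i, f in enumerate(frames):
        sink.write(i, f)
    return sink


# ---------------------------------------------------------------------------
# Equirectangular seam handling
# ---------------------------------------------------------------------------

def equirect_pad(image: np.ndarray, pad: int) -> np.ndarray:
    """Copy `pad` columns cyclically onto the left/right edges.

    Gives the dream engine real context across the panoramic seam; vertical
    edges (poles) are left alone.
    """
    image = as_image(image)
    if pad == 0:
        return image.copy()
    if pad >= image.shape[1] // 2:
        raise ValueError("pad must be < width/2")
    return np.concatenate([image[:, -pad:], image, image[:, :pad]], axis=1)


def equirect_unpad(image: np.ndarray, pad: int) -> np.ndarray:
    image = as_image(image)
    if pad == 0:
        return image.copy()
    return image[:, pad:-pad].copy()


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def frame_rng(seed: int, frame_index: int) -> np.random.Generator:
    """Per-frame RNG derived from (config seed, frame index): frame-level
    execution order cannot reorder randomness."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(frame_index,)))


def _config_dict(config: PipelineConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_manifest(manifest: dict) -> PipelineConfig:
    """Rebuild the exact run configuration recorded in a manifest."""
    c = manifest["config"]
    return PipelineConfig(
        dream=DreamConfig(**c["dream"]),
        coherence=CoherenceConfig(**c["coherence"]),
        equirect=c["equirect"],
        wrap_pad=c["wrap_pad"],
        frame_rate=c["frame_rate"],
    )


def process_video(source: FrameSource, model, config: PipelineConfig, sink: FrameSink) -> dict:
    """Dream a frame sequence with temporal coherence; returns the manifest.

    Frame 0: dreamed directly.  Frame t >= 1: optical flow raw_{t-1}->raw_t,
    warp dreamed_{t-1}, per-pixel ratio map, blend with raw_t, then dream.
    Dream-zoom (when configured > 1) is applied to the blended input before
    dreaming.  The manifest records config, per-frame seeds, objective values
    and timings, and suffices to re-run bit-identically.
    """
    dcfg, ccfg = config.dream, config.coherence
    ccfg = dataclasses.replace(ccfg, equirect=config.equirect)
    prev_raw: np.ndarray | None = None
    prev_dreamed: np.ndarray | None = None
    objectives: list[float] = []
    timings: list[float] = []
    n = 0
    shape = None
    for t, raw in enumerate(source):
        raw = as_image(raw)
        if shape is None:
            shape = raw.shape
        elif raw.shape != shape:
            raise ValueError(f"frame {t} size {raw.shape} differs from {shape}")
        t0 = time.perf_counter()
        if t == 0:
            inp = raw
        else:
            inp = coherent_input(prev_raw, prev_dreamed, raw, ccfg)
        if dcfg.zoom > 1:
            inp = apply_zoom(inp, dcfg.zoom)
        if config.equirect and config.wrap_pad > 0:
            inp = equirect_pad(inp, config.wrap_pad)
        rng = frame_rng(dcfg.seed, t)
        dreamed = dream_image(inp, model, dcfg, rng)
        if config.equirect and config.wrap_pad > 0:
            dreamed = equirect_unpad(dreamed, config.wrap_pad)
        obj = objective(model.activations(dreamed, dcfg.layer_id))
        dt = time.perf_counter() - t0
        logger.info("frame %d: objective=%.6g time=%.3fs", t, obj, dt)
        sink.write(t, dreamed)
        objectives.append(obj)
        timings.append(dt)
        prev_raw, prev_dreamed = raw, dreamed
        n += 1
    if n == 0:
        raise ValueError("no frames")
    manifest = {
        "config": _config_dict(config),
        "seed": dcfg.seed,
        "frame_seeds": [[dcfg.seed, t] for t in range(n)],
        "n_frames": n,
        "frame_size": list(shape),
        "objectives": objectives,
        "timings_s": timings,
    }
    sink.write_manifest(manifest)
    return manifest
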