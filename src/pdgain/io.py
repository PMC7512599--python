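"""Reading and writing frame stacks, labels, and run configuration."""

from __future__ import annotations

import glob
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

from .sequence import FrameSequence

__all__ = ["RunConfig", "read_sequence", "write_sequence", "write_labels_csv"]


@dataclass(frozen=True)
class RunConfig:
    """Serializable analysis configuration (round-trips through JSON)."""

    alpha_grid: tuple = ()
    log_base: float = 2.0
    lag: int = 1
    basis_mode: str = "first"
    k: int = 2
    seed: int = 0
    standardize: bool = False
    pca_mode: str = "variance95"
    paths: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        data["alpha_grid"] = tuple(data.get("alpha_grid", ()))
        return cls(**data)


def _infer_depth(frames: Sequence[np.ndarray], hint: int | None) -> int:
    if hint is not None:
        if hint not in (8, 12, 16):
            raise ValueError("bit depth hint must be 8, 12 or 16")
        return hint
    dtype = frames[0].dtype
    if dtype == np.uint8:
        return 8
    if dtype == np.uint16:
        # 12-bit data is commonly carried in 16-bit containers
        peak = max(int(f.max()) for f in frames)
        return 12 if peak <= 4095 else 16
    raise ValueError(f"cannot infer bit depth from dtype {dtype}; pass a hint")


def _read_one(path: str) -> list[np.ndarray]:
    if path.lower().endswith((".tif", ".tiff")):
        data = tifffile.imread(path)
        if data.ndim == 2:
            return [data]
        return [page for page in data]  # multi-page: one frame per page
    img = iio.imread(path)
    if img.ndim == 3:  # collapse trivial channel axes
        if img.shape[-1] in (3, 4):
            raise ValueError(f"{path}: color images are not supported")
        return [page for page in img]
    return [img]


def read_sequence(path_or_glob, bit_depth: int | None = None) -> FrameSequence:
    """Load a stack from a glob, directory, file list, or multi-page TIFF.

    Frames are ordered by sorted filename (and page order within a file).
    Mixed shapes or dtypes across files raise with the offending file named.
    """
    if isinstance(path_or_glob, (list, tuple)):
        paths = [str(p) for p in path_or_glob]
    elif os.path.isdir(path_or_glob):
        paths = sorted(
            os.path.join(path_or_glob, f)
            for f in os.listdir(path_or_glob)
            if f.lower().endswith((".tif", ".tiff", ".png"))
        )
    else:
        paths = sorted(glob.glob(str(path_or_glob)))
        if not paths and os.path.exists(str(path_or_glob)):
            paths = [str(path_or_glob)]
    if not paths:
        raise FileNotFoundError(f"no readable frames under {path_or_glob!r}")
    frames: list[np.ndarray] = []
    for p in paths:
        for frame in _read_one(p):
            frame = np.asarray(frame)
            if frames:
                if frame.shape != frames[0].shape:
                    raise ValueError(f"{p}: frame shape {frame.shape} differs from {frames[0].shape}")
                if frame.dtype != frames[0].dtype:
                    raise ValueError(f"{p}: dtype {frame.dtype} differs from {frames[0].dtype}")
            frames.append(frame)
    depth = _infer_depth(frames, bit_depth)
    return FrameSequence(frames=tuple(frames), bit_depth=depth)


def write_sequence(seq: FrameSequence, target, fmt: str = "tiff") -> list[str]:
    """Write a sequence as a multi-page TIFF (``target`` is a file) or as
    numbered PNG/TIFF files (``target`` is a directory).  Returns the paths
    written."""
    dtype = np.uint8 if seq.bit_depth == 8 else np.uint16
    stack = [f.astype(dtype) for f in seq]
    target = str(target)
    if target.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(target, np.stack(stack), photometric="minisblack")
        return [target]
    os.makedirs(target, exist_ok=True)
    ext = "png" if fmt == "png" else "tif"
    paths = []
    for i, frame in enumerate(stack):
        path = os.path.join(target, f"frame_{i:04d}.{ext}")
        if ext == "tif":
            tifffile.imwrite(path, frame)
        else:
            iio.imwrite(path, frame)
        paths.append(path)
    return paths


def write_labels_csv(path, pair_indices, labels) -> None:
    with open(path, "w") as fh:
        fh.write("image_index,cluster\n")
        for idx, lab in zip(pair_indices, labels):
            fh.write(f"{int(idx)},{int(lab)}\n")
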