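"""Multi-channel image container with voxel geometry and TIFF round-trip.

All analysis operates on :class:`ImageStack`: a dict of named 2D ``(Y, X)``
or 3D ``(Z, Y, X)`` float arrays sharing one shape, a physical voxel size in
micrometres per axis, and the acquisition bit depth (8 or 16).  Arrays are
kept as float64 in memory; quantisation to integers happens only on TIFF
write, so noiseless synthetic fixtures preserve exact arithmetic relations
between channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """Named intensity channels over a common pixel grid.

    Parameters
    ----------
    channels
        Mapping from channel name (e.g. ``"DAPI"``, ``"H3K27me3"``) to a 2D
        or 3D array.  All channels must share one shape.
    voxel_size
        Physical size of one voxel in µm per axis, in array axis order
        (``(dy, dx)`` for 2D, ``(dz, dy, dx)`` for 3D).
    bit_depth
        8 or 16; intensities must lie in ``[0, 2**bit_depth - 1]``.
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, ...]
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageStack requires at least one channel")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        self.channels = {k: np.asarray(v, dtype=np.float64) for k, v in self.channels.items()}
        shapes = {v.shape for v in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels differ in shape: {shapes}")
        (shape,) = shapes
        if len(shape) not in (2, 3):
            raise ValueError(f"channels must be 2D or 3D, got shape {shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != len(shape):
            raise ValueError(
                f"voxel_size has {len(self.voxel_size)} entries for a {len(shape)}D image"
            )
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        vmax = self.intensity_max
        for name, arr in self.channels.items():
            lo, hi = float(arr.min()), float(arr.max())
            if lo < 0 or hi > vmax:
                raise ValueError(
                    f"channel {name!r} has values [{lo}, {hi}] outside "
                    f"[0, {vmax}] for bit depth {self.bit_depth}"
                )

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def intensity_max(self) -> float:
        return float(2**self.bit_depth - 1)

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"unknown channel {name!r}; available: {self.channel_names}"
            ) from None

    def in_plane_pitch(self) -> float:
        """Smaller in-plane pixel pitch in µm (last two axes)."""
        return min(self.voxel_size[-2:])

    # ------------------------------------------------------------------ I/O

    def to_tiff(self, path) -> None:
        """Write as a multi-page TIFF, one page (or z-stack) per channel.

        Channel names, voxel size and bit depth are stored as JSON in the
        ImageDescription tag; intensities are rounded to the native integer
        dtype of the bit depth.
        """
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        stack = np.stack(
            [np.clip(np.rint(a), 0, self.intensity_max).astype(dtype) for a in self.channels.values()]
        )
        meta = {
            "chromoquant": {
                "channels": self.channel_names,
                "voxel_size_um": list(self.voxel_size),
                "bit_depth": self.bit_depth,
            }
        }
        tifffile.imwrite(
            path, stack, description=json.dumps(meta), photometric="minisblack"
        )

    @classmethod
    def from_tiff(cls, path) -> "ImageStack":
        """Read an image written by :meth:`to_tiff` (or any channel-first TIFF)."""
        with tifffile.TiffFile(path) as tif:
            stack = tif.asarray()
            desc = tif.pages[0].description or ""
        meta = None
        try:
            meta = json.loads(desc).get("chromoquant")
        except (json.JSONDecodeError, AttributeError):
            meta = None
        if meta is None:
            # Plain TIFF: first axis is the channel axis, channels get generic names.
            names = [f"ch{i}" for i in range(stack.shape[0])]
            voxel = (1.0,) * (stack.ndim - 1)
            bit_depth = 8 if stack.dtype == np.uint8 else 16
        else:
            names = meta["channels"]
            voxel = tuple(meta["voxel_size_um"])
            bit_depth = int(meta["bit_depth"])
        return cls(
            channels={n: stack[i] for i, n in enumerate(names)},
            voxel_size=voxel,
            bit_depth=bit_depth,
        )


@dataclass
class LabeledMask:
    """Integer-labeled segmentation mask (0 = background) with helpers."""

    labels: np.ndarray
    voxel_size: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labeled mask must be integer-typed")

    def ids(self) -> list[int]:
        return [int(i) for i in np.unique(self.labels) if i != 0]

    def binary(self, label: int) -> np.ndarray:
        return self.labels == label

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.labels.astype(np.uint16))

    @classmethod
    def from_tiff(cls, path) -> "LabeledMask":
        return cls(labels=tifffile.imread(path).astype(np.int64))
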