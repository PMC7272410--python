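"""Velocity-map images and their HDF5 container.

Pixel convention: pixel (0, 0) is the top-left corner, x runs rightward
(columns), y downward (rows); the laser polarisation axis is the vertical
image axis.  The image centre is stored in fractional pixel coordinates
(x, y).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["Image", "ImageFormatError", "read_image", "write_image", "read_image_stack", "write_image_stack"]


class ImageFormatError(ValueError):
    """Raised for malformed image containers or invalid image metadata."""


@dataclass
class Image:
    """A 2-D grid of electron counts (real-valued for expectation images)."""

    counts: np.ndarray
    center: tuple[float, float] | None = None  # (x, y) fractional pixels
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ImageFormatError("image grid must be 2-D")
        if not np.all(np.isfinite(self.counts)):
            raise ImageFormatError("image contains non-finite values")
        ny, nx = self.counts.shape
        if self.center is None:
            # geometric centre of the pixel grid
            self.center = ((nx - 1) / 2.0, (ny - 1) / 2.0)
        cx, cy = self.center
        if not (0 <= cx <= nx - 1 and 0 <= cy <= ny - 1):
            raise ImageFormatError(f"stated centre {self.center} lies outside the {nx}x{ny} grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def _write_frame(group: h5py.Group, image: Image) -> None:
    group.create_dataset("counts", data=image.counts)
    group.attrs["centre"] = np.asarray(image.center, dtype=float)
    for key, val in image.metadata.items():
        group.attrs[key] = val


def _read_frame(group: h5py.Group) -> Image:
    counts = np.asarray(group["counts"])
    attrs = dict(group.attrs)
    centre = attrs.pop("centre", None)
    if centre is not None:
        centre = tuple(float(v) for v in centre)
    return Image(counts, center=centre, metadata=attrs)


def write_image(image: Image, path) -> None:
    """Write a single image (group ``frame``) to an HDF5 container."""
    with h5py.File(path, "w") as fh:
        _write_frame(fh.create_group("frame"), image)


def read_image(path) -> Image:
    with h5py.File(path, "r") as fh:
        if "frame" not in fh:
            raise ImageFormatError(f"{path}: missing 'frame' group")
        return _read_frame(fh["frame"])


def write_image_stack(frames: list[tuple[float, Image]], path) -> None:
    """Write a delay-ordered image stack, one HDF5 group per delay.

    Each group stores dataset ``counts`` plus attrs ``delay_fs`` and whatever
    metadata (``seed``, ``n_electrons``, ...) the image carries.
    """
    with h5py.File(path, "w") as fh:
        for i, (delay, image) in enumerate(frames):
            g = fh.create_group(f"delay_{i:04d}")
            g.attrs["delay_fs"] = float(delay)
            _write_frame(g, image)


def read_image_stack(path) -> list[tuple[float, Image]]:
    frames: list[tuple[float, Image]] = []
    with h5py.File(path, "r") as fh:
        names = sorted(n for n in fh if n.startswith("delay_"))
        if not names:
            raise ImageFormatError(f"{path}: no delay groups found")
        for name in names:
            g = fh[name]
            delay = float(g.attrs["delay_fs"])
            img = _read_frame(g)
            img.metadata["delay_fs"] = delay
            frames.append((delay, img))
    frames.sort(key=lambda pair: pair[0])
    return frames
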