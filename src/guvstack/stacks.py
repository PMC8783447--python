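"""Confocal z-stack container and multi-page TIFF I/O.

An :class:`ImageStack` holds one fluorescence channel of a z-stack together
with its physical calibration.  Multi-channel files store pages in one of
two interleaving dialects, which the reader must be told about explicitly:

``z-major``
    all z-sections of channel 0, then all of channel 1, ...
``channel-major``
    for each z, one page per channel (ch0, ch1, ch0, ch1, ...).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

#: Default lateral calibration: a 1,024-px field of view spanning 127.3 µm.
DEFAULT_FIELD_OF_VIEW_UM = 127.3
DEFAULT_FRAME_PX = 1024
DEFAULT_PIXEL_SIZE_UM = DEFAULT_FIELD_OF_VIEW_UM / DEFAULT_FRAME_PX
DEFAULT_Z_SPACING_UM = 1.0


@dataclass
class ImageStack:
    """One channel's 3-D intensity grid plus physical calibration.

    Parameters
    ----------
    sections : ndarray, shape (n_z, height, width)
        Intensity sections in ascending z order.
    pixel_size : float
        Lateral calibration, µm per pixel.
    z_spacing : float
        Axial step between sections, µm.
    channel_name : str
        Free-text channel label (e.g. ``"lipid"`` or ``"protein"``).
    """

    sections: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    z_spacing: float = DEFAULT_Z_SPACING_UM
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.sections = np.asarray(self.sections)
        if self.sections.ndim != 3:
            raise ValueError("sections must be a (n_z, height, width) array")
        if self.pixel_size <= 0 or self.z_spacing <= 0:
            raise ValueError("pixel_size and z_spacing must be positive")

    @property
    def n_sections(self) -> int:
        return self.sections.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.sections.shape[1:]

    def __len__(self) -> int:
        return self.n_sections

    def __getitem__(self, z: int) -> np.ndarray:
        return self.sections[z]


def read_stacks(
    path,
    n_channels: int = 1,
    interleaving: str = "z-major",
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    z_spacing: float = DEFAULT_Z_SPACING_UM,
    channel_names: list[str] | None = None,
) -> list[ImageStack]:
    """Read a multi-page TIFF into one ImageStack per channel.

    ``interleaving`` declares the page order dialect (see module docstring);
    it cannot be inferred reliably from the file itself.
    """
    pages = np.asarray(tifffile.imread(path))
    if pages.ndim == 2:  # single-page file
        pages = pages[None]
    n_pages = pages.shape[0]
    if n_pages % n_channels:
        raise ValueError(
            f"{n_pages} pages not divisible by {n_channels} channels"
        )
    n_z = n_pages // n_channels
    if interleaving == "z-major":
        per_channel = [pages[c * n_z : (c + 1) * n_z] for c in range(n_channels)]
    elif interleaving == "channel-major":
        per_channel = [pages[c::n_channels] for c in range(n_channels)]
    else:
        raise ValueError(f"unknown interleaving dialect: {interleaving!r}")
    names = channel_names or [f"ch{c}" for c in range(n_channels)]
    return [
        ImageStack(sec, pixel_size=pixel_size, z_spacing=z_spacing, channel_name=nm)
        for sec, nm in zip(per_channel, names)
    ]


def write_stack(path, stack: ImageStack) -> None:
    """Write a stack as a 16-bit multi-page TIFF (values clipped to uint16)."""
    data = np.clip(np.rint(stack.sections), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, data.astype(np.uint16))
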