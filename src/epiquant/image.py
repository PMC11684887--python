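"""In-memory container for multichannel fluorescence images.

A :class:`MultiplexImage` is a mapping of channel name -> 2-D intensity grid
sharing one pixel grid and physical pixel size. Channels are stored as the
dtype they were created or read with (float32 for synthetic pre-quantization
data, uint8/uint16 for scanner output); no silent rescaling ever happens.

Coordinates are (row, col), origin at the top-left, 0-based, half-open extents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator

import numpy as np

from .errors import MissingChannelError


@dataclass
class MultiplexImage:
    """Named-channel intensity grids with a shared pixel size.

    Parameters
    ----------
    channels
        Mapping from channel name to a 2-D ``numpy`` array. All arrays must
        share one shape.
    pixel_size_um
        Physical edge length of one pixel in micrometres.
    bit_depth
        Nominal bit depth of the acquisition (8 or 16); informational for
        float data.
    """

    channels: Dict[str, np.ndarray]
    pixel_size_um: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels have inconsistent shapes: {shapes}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple:
        if not self.channels:
            return (0, 0)
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list:
        return list(self.channels)

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def __iter__(self) -> Iterator[str]:
        return iter(self.channels)

    def get(self, name: str) -> np.ndarray:
        """Return the channel grid for ``name`` or raise MissingChannelError."""
        try:
            return self.channels[name]
        except KeyError:
            raise MissingChannelError(name, self.channels) from None

    def copy(self) -> "MultiplexImage":
        return MultiplexImage(
            {k: v.copy() for k, v in self.channels.items()},
            pixel_size_um=self.pixel_size_um,
            bit_depth=self.bit_depth,
        )

    def area_um2(self, n_pixels: int) -> float:
        """Convert a pixel count to square micrometres."""
        return float(n_pixels) * self.pixel_size_um**2
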