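"""Readers and writers for images, label masks, tables, and configuration.

Images travel as multichannel TIFF (OME metadata carries channel names and
the physical pixel size); label masks as single-channel 16- or 32-bit TIFF;
tables as CSV with documented headers; configuration and manifests as
JSON/YAML. Intensity values are preserved exactly — no silent rescaling.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import tifffile
import yaml

from .errors import ConfigurationError, MissingChannelError, PixelSizeError
from .image import MultiplexImage


def write_multiplex(image: MultiplexImage, path) -> None:
    """Write an image as OME-TIFF, one page per channel, names in metadata."""
    path = Path(path)
    names = image.channel_names
    stack = np.stack([image.channels[n] for n in names])
    tifffile.imwrite(
        path,
        stack,
        ome=True,
        metadata={
            "axes": "CYX",
            "Channel": {"Name": names},
            "PhysicalSizeX": image.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": image.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
        },
    )


def _ome_channel_names(tif: "tifffile.TiffFile") -> Optional[List[str]]:
    if not tif.ome_metadata:
        return None
    try:
        meta = tifffile.xml2dict(tif.ome_metadata)
        img = meta["OME"]["Image"]
        if isinstance(img, list):
            img = img[0]
        chans = img["Pixels"]["Channel"]
        if isinstance(chans, dict):
            chans = [chans]
        names = [c.get("Name") for c in chans]
        if all(names):
            return [str(n) for n in names]
    except (KeyError, TypeError):
        return None
    return None


def _ome_pixel_size(tif: "tifffile.TiffFile") -> Optional[float]:
    if not tif.ome_metadata:
        return None
    try:
        meta = tifffile.xml2dict(tif.ome_metadata)
        img = meta["OME"]["Image"]
        if isinstance(img, list):
            img = img[0]
        return float(img["Pixels"]["PhysicalSizeX"])
    except (KeyError, TypeError, ValueError):
        return None


def read_multiplex(
    path,
    channel_map: Optional[Dict[str, int]] = None,
    pixel_size_um: Optional[float] = None,
) -> MultiplexImage:
    """Read a TIFF/OME-TIFF as named channels.

    Channel names come from OME metadata when present; ``channel_map``
    (name -> page index) overrides or supplies them. Values are preserved at
    their stored dtype. The pixel size must be present in metadata or
    overridden, otherwise :class:`PixelSizeError` is raised.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        ome_names = _ome_channel_names(tif)
        ome_px = _ome_pixel_size(tif)
    if data.ndim == 2:
        data = data[None]
    n_pages = data.shape[0]

    if channel_map is not None:
        for name, idx in channel_map.items():
            if not (0 <= idx < n_pages):
                raise MissingChannelError(name, list(range(n_pages)))
        channels = {name: data[idx] for name, idx in channel_map.items()}
    elif ome_names is not None and len(ome_names) == n_pages:
        channels = {name: data[i] for i, name in enumerate(ome_names)}
    else:
        channels = {f"channel{i}": data[i] for i in range(n_pages)}

    px = pixel_size_um if pixel_size_um is not None else ome_px
    if px is None:
        raise PixelSizeError(
            f"{path}: pixel size absent from metadata and not overridden"
        )
    bit_depth = 8 if data.dtype == np.uint8 else 16
    return MultiplexImage(channels, pixel_size_um=float(px), bit_depth=bit_depth)


def write_labels(labels: np.ndarray, path) -> None:
    """Write a label grid as 16-bit TIFF (32-bit when labels exceed 65535)."""
    labels = np.asarray(labels)
    dtype = np.uint16 if labels.max() < 2**16 else np.uint32
    tifffile.imwrite(Path(path), labels.astype(dtype))


def read_labels(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


def write_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(Path(path), mask.astype(np.uint8))


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; round-trips through YAML/JSON."""

    output_dir: str = "epiquant_out"
    image_path: Optional[str] = None
    probability_maps_path: Optional[str] = None
    # simulation fallback when no image path is given
    simulate: Optional[dict] = None
    # channel-name mapping
    nuclei_channel: str = "nuclei"
    membrane_channels: List[str] = field(default_factory=lambda: ["membrane1",
                                                                  "membrane2"])
    target_channel: str = "target"
    lysosome_channel: Optional[str] = None
    tuft_channel: Optional[str] = None
    # stage parameters
    pixel_size_um: Optional[float] = None
    band_px: int = 2
    cutoff_bins: int = 256
    min_cell_area_um2: float = 25.0
    max_cell_area_um2: float = 700.0
    nucleus_min_area_um2: float = 5.0
    nucleus_max_area_um2: float = 200.0
    max_debris_overlap: float = 0.5
    tuft_min_area_um2: float = 20.0
    tuft_max_area_um2: float = 700.0
    n_rois: int = 5
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
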