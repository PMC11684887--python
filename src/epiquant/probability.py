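"""Per-class pixel probability maps: external ingestion and a baseline classifier.

The segmentation consumes per-pixel class probabilities over at least
{background, tissue, nuclei, membrane, debris}. Two provenances are
supported:

external
    Maps exported by an interactive pixel-classification tool, read from a
    multichannel TIFF (or HDF5) with one page/dataset per class. They are
    validated (per-pixel sums within 1e-3 of 1) and renormalized.

baseline
    A deterministic, non-interactive classifier built from the image itself:
    per-channel background subtraction (separable grey opening), Gaussian
    smoothing, rescaling to [0, 1], followed by class scores normalized per
    pixel. The debris score is a multi-channel co-saturation heuristic
    (min of rescaled nuclei and membrane signal), which in normal tissue is
    near zero because nuclear and membrane staining are spatially disjoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import MalformedMapError, MissingChannelError
from .image import MultiplexImage

CORE_CLASSES = ("background", "tissue", "nuclei", "membrane", "debris")


@dataclass
class ProbabilityMaps:
    """Ordered per-class probability grids with per-pixel sum 1."""

    class_names: List[str]
    maps: np.ndarray  # (C, H, W) float32
    provenance: str = "baseline"

    def __post_init__(self) -> None:
        if self.maps.ndim != 3 or self.maps.shape[0] != len(self.class_names):
            raise MalformedMapError(
                f"maps shape {self.maps.shape} does not match "
                f"{len(self.class_names)} classes"
            )

    @property
    def shape(self) -> tuple:
        return self.maps.shape[1:]

    def get(self, name: str) -> np.ndarray:
        try:
            return self.maps[self.class_names.index(name)]
        except ValueError:
            raise MissingChannelError(name, self.class_names) from None

    def argmax_class(self) -> np.ndarray:
        """Per-pixel index of the most probable class."""
        return np.argmax(self.maps, axis=0)


def _normalize(stack: np.ndarray, tol: float) -> np.ndarray:
    sums = stack.sum(axis=0)
    if np.any(np.abs(sums - 1.0) > tol):
        worst = float(np.abs(sums - 1.0).max())
        raise MalformedMapError(
            f"per-pixel class sums deviate from 1 by up to {worst:.4g} (> {tol})"
        )
    return (stack / sums).astype(np.float32)


def load_probability_maps(path, class_names: Sequence[str]) -> ProbabilityMaps:
    """Load externally exported maps (multichannel TIFF or HDF5).

    The file must contain one page (TIFF) or one dataset (HDF5, keyed by
    class name) per class; per-pixel sums must be within 1e-3 of 1 and are
    renormalized exactly.
    """
    path = Path(path)
    class_names = list(class_names)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as fh:
            missing = [c for c in class_names if c not in fh]
            if missing:
                raise MalformedMapError(f"HDF5 file lacks datasets {missing}")
            stack = np.stack([np.asarray(fh[c], dtype=np.float64)
                              for c in class_names])
    else:
        import tifffile

        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.shape[0] != len(class_names):
            raise MalformedMapError(
                f"file has {data.shape[0]} channels, expected {len(class_names)}"
            )
        stack = data.astype(np.float64)
    return ProbabilityMaps(class_names, _normalize(stack, 1e-3),
                           provenance="external")


def save_probability_maps(maps: ProbabilityMaps, path) -> None:
    """Write maps as a multichannel float32 TIFF plus a class-name sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, maps.maps.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"classes": maps.class_names}))


@dataclass
class BaselineParams:
    """Tunables of the baseline classifier.

    channel_scales, when given, fix the intensity normalization per score
    channel ({'nuclei': s, 'membrane': s, 'any': s}); otherwise a robust
    per-image percentile is used.
    """

    smooth_sigma_px: float = 0.5
    background_radius_px: int = 15
    tissue_weight: float = 0.45
    tissue_foreground_threshold: float = 0.05
    tissue_close_radius_px: int = 5
    background_floor: float = 0.05
    scale_percentile: float = 99.5
    channel_scales: Optional[Dict[str, float]] = None
    membrane_channels: Sequence[str] = ("membrane1", "membrane2")
    extra_signal_channels: Sequence[str] = ("target",)


def _prep_channel(x: np.ndarray, params: BaselineParams,
                  smooth: bool = True, subtract: bool = True) -> np.ndarray:
    x = x.astype(np.float64)
    if subtract and params.background_radius_px > 0:
        size = 2 * params.background_radius_px + 1
        x = x - ndimage.grey_opening(x, size=(size, size))
    if smooth and params.smooth_sigma_px > 0:
        x = ndimage.gaussian_filter(x, params.smooth_sigma_px)
    return np.clip(x, 0, None)


def _rescale(x: np.ndarray, key: str, params: BaselineParams) -> np.ndarray:
    if params.channel_scales and key in params.channel_scales:
        scale = params.channel_scales[key]
    else:
        pos = x[x > 0]
        scale = float(np.percentile(pos, params.scale_percentile)) if pos.size else 0.0
    if scale <= 0:
        return np.zeros_like(x)
    return np.clip(x / scale, 0.0, 1.0)


def baseline_probability(
    image: MultiplexImage, params: Optional[BaselineParams] = None
) -> ProbabilityMaps:
    """Deterministic five-class probability maps from channel intensities.

    Requires ``nuclei`` and at least one membrane channel. Scores:

    - nuclei: rescaled nuclei signal;
    - membrane: rescaled sum of membrane channels;
    - tissue: the morphological closing of the thresholded non-nuclear
      signal, scaled by ``tissue_weight`` — compact support, so isolated
      cells do not grow a halo, while marker-free interiors are filled;
    - debris: min(nuclei, membrane) rescaled signal (co-saturation);
    - background: a constant floor.

    Per-pixel scores are normalized to sum to 1. With fixed
    ``channel_scales`` the nuclei-class probability is non-decreasing in the
    nuclei-channel intensity at any pixel.
    """
    params = params or BaselineParams()
    if "nuclei" not in image:
        raise MissingChannelError("nuclei", image.channel_names)
    mem_names = [c for c in params.membrane_channels if c in image]
    if not mem_names:
        raise MissingChannelError(params.membrane_channels[0], image.channel_names)

    nuc = _prep_channel(image.get("nuclei"), params)
    mem = _prep_channel(
        np.sum([image.get(c).astype(np.float64) for c in mem_names], axis=0), params
    )
    nuc_r = _rescale(nuc, "nuclei", params)
    mem_r = _rescale(mem, "membrane", params)

    # tissue support comes from the raw signal: unsmoothed so the support is
    # compact (no halo beyond the outermost membrane), and without background
    # subtraction because broad diffuse cytoplasmic signal is itself the
    # evidence of tissue and would be flattened by any opening window
    any_sig = _prep_channel(
        np.sum([image.get(c).astype(np.float64) for c in mem_names], axis=0),
        params, smooth=False, subtract=False,
    )
    for c in params.extra_signal_channels:
        if c in image:
            any_sig = np.maximum(
                any_sig,
                _prep_channel(image.get(c), params, smooth=False,
                              subtract=False),
            )
    any_r = _rescale(any_sig, "any", params)

    s_nuc = nuc_r
    s_mem = mem_r
    fg = any_r > params.tissue_foreground_threshold
    if fg.any() and params.tissue_close_radius_px > 0:
        r = params.tissue_close_radius_px
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        padded = np.pad(fg, r)  # room for dilation: no erosion bite at borders
        closed = ndimage.binary_closing(padded,
                                        structure=(yy**2 + xx**2) <= r**2)
        fg = closed[r:-r, r:-r]
    s_tis = params.tissue_weight * fg.astype(np.float64)
    s_deb = np.minimum(nuc_r, mem_r)
    s_bg = np.full(nuc_r.shape, params.background_floor)

    stack = np.stack([s_bg, s_tis, s_nuc, s_mem, s_deb])
    stack = stack / stack.sum(axis=0)
    return ProbabilityMaps(list(CORE_CLASSES), stack.astype(np.float32),
                           provenance="baseline")
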