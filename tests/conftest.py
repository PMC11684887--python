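"""Shared fixtures: small synthetic slides, segmented once per session."""

from dataclasses import dataclass

import numpy as np
import pytest

from epiquant import (
    CellLabelMap,
    TissueConfig,
    baseline_probability,
    detect_nuclei,
    generate_tissue,
    measure_cells,
    partition_compartments,
    segment_cells,
)


@dataclass
class SegmentedSlide:
    config: TissueConfig
    image: object
    truth: object
    prob: object
    nuclei: np.ndarray
    cells: CellLabelMap
    comps: object
    records: object


def segment_slide(cfg: TissueConfig) -> SegmentedSlide:
    image, truth = generate_tissue(cfg)
    prob = baseline_probability(image)
    nuclei = detect_nuclei(prob, pixel_size_um=cfg.pixel_size_um)
    cells = segment_cells(image, prob, nuclei)
    comps = partition_compartments(cells, band_px=cfg.membrane_band_px)
    records = measure_cells(image, cells, comps, nuclei=nuclei,
                            debris_map=truth.debris_mask)
    return SegmentedSlide(cfg, image, truth, prob, nuclei, cells, comps, records)


def match_cells(truth, cells: CellLabelMap):
    """true label -> recovered label via the true seed position (0 if lost)."""
    out = {}
    for lab in range(1, truth.n_cells + 1):
        r, c = np.round(truth.seeds_rc[lab - 1]).astype(int)
        out[lab] = int(cells.labels[r, c])
    return out


@pytest.fixture(scope="session")
def clean_slide():
    """50-cell slide, zero blur/noise, fixed membrane fraction 0.7."""
    cfg = TissueConfig(
        image_height_px=220, image_width_px=220, pixel_size_um=1.0,
        n_cells=50, membrane_fraction_per_cell=0.7, seed=3,
    )
    return generate_tissue(cfg)


@pytest.fixture(scope="session")
def segmented_clean():
    """200-cell zero-noise slide put through the whole segmentation stack."""
    cfg = TissueConfig(
        image_height_px=360, image_width_px=360, pixel_size_um=1.0,
        n_cells=200, membrane_fraction_per_cell=0.6, seed=7,
    )
    return segment_slide(cfg)


@pytest.fixture(scope="session")
def segmented_noisy():
    """200-cell slide with realistic blur and shot-like noise (SNR ~ 10)."""
    base = TissueConfig(
        image_height_px=360, image_width_px=360, pixel_size_um=1.0,
        n_cells=200, membrane_fraction_per_cell=0.6, blur_sigma_px=0.5,
        noise_model="gaussian", seed=11,
    )
    cfg = TissueConfig(
        **{**base.__dict__, "gaussian_noise_sigma": base.gaussian_sigma_for_snr(10.0)}
    )
    return segment_slide(cfg)
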