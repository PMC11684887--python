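"""Segmentation contracts: seeding, partition, compartments, debris exclusion."""

import numpy as np
import pytest
from scipy import ndimage

from epiquant import (
    CellLabelMap,
    ConfigurationError,
    EpiquantError,
    ProbabilityMaps,
    TissueConfig,
    detect_nuclei,
    exclude_debris,
    generate_tissue,
    measure_cells,
    partition_compartments,
    segment_cells,
)
from epiquant.morphology import boundary_pixels, erode_labels
from epiquant.probability import CORE_CLASSES

from conftest import match_cells, segment_slide


def _maps_from_nuclei_mask(mask):
    """Probability maps with the given mask as the nuclei class."""
    H, W = mask.shape
    maps = np.zeros((5, H, W), dtype=np.float32)
    i_nuc = list(CORE_CLASSES).index("nuclei")
    maps[i_nuc][mask] = 1.0
    maps[0][~mask] = 1.0
    return ProbabilityMaps(list(CORE_CLASSES), maps)


def test_no_nuclei_in_empty_maps():
    pm = _maps_from_nuclei_mask(np.zeros((64, 64), dtype=bool))
    assert detect_nuclei(pm).max() == 0


def test_single_round_nucleus_detected():
    yy, xx = np.mgrid[:64, :64]
    mask = ((yy - 32) ** 2 + (xx - 32) ** 2) <= 5**2
    labels = detect_nuclei(_maps_from_nuclei_mask(mask), pixel_size_um=1.0)
    assert labels.max() == 1


def test_nucleus_count_matches_truth(segmented_clean):
    assert segmented_clean.nuclei.max() == segmented_clean.truth.n_cells


def test_zero_seeds_zero_cells(segmented_clean):
    img = segmented_clean.image
    empty = np.zeros(img.shape, dtype=np.int32)
    cells = segment_cells(img, segmented_clean.prob, empty)
    assert cells.n_cells == 0


def test_shape_mismatch_rejected(segmented_clean):
    with pytest.raises(EpiquantError):
        segment_cells(
            segmented_clean.image,
            segmented_clean.prob,
            np.zeros((4, 4), dtype=np.int32),
        )


def test_single_isolated_cell_high_jaccard():
    cfg = TissueConfig(image_height_px=128, image_width_px=128,
                       pixel_size_um=1.0, n_cells=1, seed=2)
    s = segment_slide(cfg)
    truth_mask = s.truth.cell_label_mask == 1
    got = match_cells(s.truth, s.cells)[1]
    assert got > 0
    rec_mask = s.cells.labels == got
    jac = (truth_mask & rec_mask).sum() / (truth_mask | rec_mask).sum()
    assert jac >= 0.90


def test_cell_count_under_noise(segmented_noisy):
    n = segmented_noisy.cells.n_cells - len(segmented_noisy.cells.excluded)
    assert abs(n - 200) <= 10  # within 5%


def test_partition_no_double_labels(segmented_noisy):
    # a label grid is a partition by construction; check seeds instead:
    # every non-excluded cell contains exactly one nucleus
    s = segmented_noisy
    labels = s.cells.labels
    nuc_per_cell = np.bincount(
        labels[(s.nuclei > 0) & (labels > 0)].ravel(),
        minlength=s.cells.n_cells + 1,
    )
    seeds = np.zeros(s.cells.n_cells + 1, dtype=int)
    for lab in np.unique(s.nuclei[s.nuclei > 0]):
        owner = np.bincount(labels[s.nuclei == lab].ravel()).argmax()
        if owner > 0:
            seeds[owner] += 1
    present = np.unique(labels[labels > 0])
    assert (seeds[present] == 1).all()
    assert (nuc_per_cell[present] >= 1).all()


def test_boundary_matches_generator_partition(segmented_clean):
    """Zero noise: watershed boundary within 1 px of the true partition."""
    s = segmented_clean
    tb = boundary_pixels(s.truth.cell_label_mask)
    rb = boundary_pixels(s.cells.labels)
    dist = ndimage.distance_transform_edt(~rb)
    assert np.median(dist[tb]) <= 1.0


def test_square_cell_band_areas():
    labels = np.zeros((14, 14), dtype=np.int32)
    labels[2:12, 2:12] = 1  # 10x10 cell
    comp = partition_compartments(CellLabelMap(labels, 1.0), band_px=1)
    assert comp.membrane_mask.sum() == 36
    assert comp.cytoplasm_mask.sum() == 64
    assert not (comp.membrane_mask & comp.cytoplasm_mask).any()
    assert ((comp.membrane_mask | comp.cytoplasm_mask) == (labels > 0)).all()


def test_tiny_cell_excluded_for_band():
    labels = np.zeros((8, 8), dtype=np.int32)
    labels[2:5, 2:5] = 1  # 3x3 cell
    comp = partition_compartments(CellLabelMap(labels, 1.0), band_px=2)
    assert comp.excluded == {1: "too-small-for-band"}


def test_band_px_must_be_positive():
    with pytest.raises(ConfigurationError):
        partition_compartments(CellLabelMap(np.zeros((4, 4), np.int32), 1.0), 0)


def test_compartment_areas_conserve_cell_area(segmented_noisy):
    rec = segmented_noisy.records
    ok = rec["membrane_area_px"] + rec["cytoplasm_area_px"] == rec["cell_area_px"]
    assert ok.all()


def test_erode_labels_respects_label_boundaries():
    labels = np.zeros((6, 10), dtype=np.int32)
    labels[1:5, 1:5] = 1
    labels[1:5, 5:9] = 2  # touching cells share an internal boundary
    interior = erode_labels(labels, 1)
    # the shared column pair erodes from both sides
    assert not interior[:, 4].any() and not interior[:, 5].any()
    assert interior.sum() == 2 * 2 * 2


def test_exclude_debris_none_when_clean(segmented_clean):
    rec = exclude_debris(segmented_clean.records, max_overlap=0.5)
    assert not (rec["exclusion_reason"] == "debris").any()


def test_exclude_debris_planted_cells():
    cfg = TissueConfig(image_height_px=300, image_width_px=300,
                       pixel_size_um=1.0, n_cells=120, n_debris_blobs=5,
                       seed=17)
    img, truth = generate_tissue(cfg)
    s = segment_slide(cfg)
    rec = measure_cells(s.image, s.cells, s.comps, nuclei=s.nuclei,
                        debris_map=truth.debris_mask)
    rec = exclude_debris(rec, max_overlap=0.5)
    # expected: true cells covered > 50% by the planted debris
    lab = truth.cell_label_mask
    areas = np.bincount(lab.ravel())
    dcounts = np.bincount(lab[truth.debris_mask & (lab > 0)].ravel(),
                          minlength=len(areas))
    expect = {
        l for l in range(1, truth.n_cells + 1)
        if dcounts[l] / areas[l] > 0.5
    }
    mapping = match_cells(truth, s.cells)
    got = set(rec.loc[rec["exclusion_reason"] == "debris", "cell_id"])
    assert {mapping[l] for l in expect if mapping[l]} == got
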