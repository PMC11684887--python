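"""Cell censuses: tuft filters, per-region counts, morphometry."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage
from scipy.spatial import cKDTree

from epiquant import (
    EpiquantError,
    TissueConfig,
    TuftFilters,
    count_positive_per_region,
    detect_tuft_cells,
    generate_tissue,
    organoid_metrics,
    plant_tuft_distractors,
    tuft_frequency,
    villus_crypt_ratio,
)
from conftest import segment_slide


@pytest.fixture(scope="module")
def tuft_slide():
    """2000-cell zero-noise slide with 10 tufts + 10 single-violation blobs."""
    cfg = TissueConfig(
        image_height_px=800, image_width_px=800, pixel_size_um=1.0,
        n_cells=2000, membrane_fraction_per_cell=0.6, n_tuft_cells=10, seed=5,
    )
    img, truth = generate_tissue(cfg)
    img = plant_tuft_distractors(img, truth, n_per_kind=(4, 3, 3), seed=6)
    s = segment_slide(cfg)
    names = s.prob.class_names
    cls = s.prob.argmax_class()
    tissue = np.isin(cls, [names.index(c)
                           for c in ("tissue", "nuclei", "membrane")])
    return img, truth, s, tissue


def _detect(img, truth, s, tissue, filters=None):
    return detect_tuft_cells(
        img.get("tuft"), s.cells, s.nuclei, tissue,
        debris_mask=truth.debris_mask, filters=filters, pixel_size_um=1.0,
    )


def test_planted_tufts_accepted_and_reasons_match(tuft_slide):
    img, truth, s, tissue = tuft_slide
    tufts = _detect(img, truth, s, tissue)
    assert int(tufts["accepted"].sum()) == 10
    rej = tufts[~tufts["accepted"]]
    assert len(rej) == 10
    tree = cKDTree(rej[["centroid_row", "centroid_col"]].to_numpy())
    for _, d in truth.distractors.iterrows():
        _, i = tree.query([d["row"], d["col"]])
        assert rej.iloc[i]["rejection_reason"] == d["expected_reason"]


def test_each_rejection_lifts_with_its_filter(tuft_slide):
    """Disabling the violated filter re-accepts the distractor."""
    img, truth, s, tissue = tuft_slide
    relaxed = {
        "size": TuftFilters(min_area_um2=0.0),
        "location": TuftFilters(max_debris_overlap=1.0),
        "no-nucleus": TuftFilters(min_nucleus_overlap=0.0),
    }
    base = _detect(img, truth, s, tissue)
    for reason, filt in relaxed.items():
        n_reason = (base["rejection_reason"] == reason).sum()
        assert n_reason > 0
        lifted = _detect(img, truth, s, tissue, filters=filt)
        assert int(lifted["accepted"].sum()) == 10 + n_reason


def test_tuft_frequency_recovered(tuft_slide):
    img, truth, s, tissue = tuft_slide
    tufts = _detect(img, truth, s, tissue)
    summary = tuft_frequency(tufts, s.records)
    assert summary.tuft_frequency == pytest.approx(10 / 2000, abs=0.005)
    assert 0.0 <= summary.tuft_frequency <= 1.0


def test_tuft_frequency_arithmetic():
    tufts = pd.DataFrame({"accepted": [True] * 5})
    records = pd.DataFrame({"excluded": [False] * 1000})
    assert tuft_frequency(tufts, records).tuft_frequency == pytest.approx(0.005)
    none = pd.DataFrame({"accepted": []})
    assert tuft_frequency(none, records).tuft_frequency == 0.0
    with pytest.raises(EpiquantError):
        tuft_frequency(tufts, pd.DataFrame({"excluded": []}))


def test_missing_tissue_mask_errors(tuft_slide):
    img, truth, s, _ = tuft_slide
    with pytest.raises(EpiquantError):
        detect_tuft_cells(img.get("tuft"), s.cells, s.nuclei, None)


# --- per-region positive nuclei --------------------------------------------

def _nucleus_grid(n_regions=4, per_region=5, positive_per_region=3):
    """Rows of nucleus disks; first k per region carry marker signal."""
    H, W = 40, n_regions * 50
    nuclei = np.zeros((H, W), dtype=np.int32)
    marker = np.zeros((H, W), dtype=np.float32)
    regions = []
    lab = 0
    for reg in range(n_regions):
        m = np.zeros((H, W), dtype=bool)
        m[:, reg * 50 : (reg + 1) * 50] = True
        regions.append(m)
        for i in range(per_region):
            lab += 1
            r, c = 6 + (i % 4) * 9, reg * 50 + 8 + (i // 4) * 20
            yy, xx = np.mgrid[:H, :W]
            disk = ((yy - r) ** 2 + (xx - c) ** 2) <= 9
            nuclei[disk] = lab
            if i < positive_per_region:
                marker[disk] = 100.0
    return marker, nuclei, regions


def test_region_counts_planted():
    marker, nuclei, regions = _nucleus_grid(n_regions=6, positive_per_region=3)
    rc = count_positive_per_region(marker, nuclei, regions, threshold=50.0)
    assert (rc.counts["n_positive_nuclei"] == 3).all()
    assert rc.mean_per_region == pytest.approx(3.0)


def test_region_counts_no_positives():
    marker, nuclei, regions = _nucleus_grid(positive_per_region=0)
    rc = count_positive_per_region(marker, nuclei, regions, threshold=50.0)
    assert (rc.counts["n_positive_nuclei"] == 0).all()
    assert rc.mean_per_region == 0.0


def test_region_mean_is_exact_arithmetic():
    marker, nuclei, regions = _nucleus_grid(n_regions=4, positive_per_region=2)
    rc = count_positive_per_region(marker, nuclei, regions, threshold=50.0)
    assert rc.mean_per_region == rc.counts["n_positive_nuclei"].sum() / 4


def test_overlapping_regions_rejected():
    marker, nuclei, regions = _nucleus_grid()
    with pytest.raises(EpiquantError):
        count_positive_per_region(marker, nuclei, [regions[0], regions[0]])


# --- morphometry ------------------------------------------------------------

def test_villus_crypt_single_pair():
    assert villus_crypt_ratio([(300.0, 100.0)]) == pytest.approx(3.0)


def test_villus_crypt_mean_of_ratios():
    assert villus_crypt_ratio([(200, 100), (400, 100)]) == pytest.approx(3.0)


def test_villus_crypt_unit_invariance():
    pairs_um = [(310.0, 95.0), (280.0, 120.0)]
    pairs_px = [(v / 0.32, c / 0.32) for v, c in pairs_um]
    assert villus_crypt_ratio(pairs_um) == pytest.approx(
        villus_crypt_ratio(pairs_px)
    )


def test_villus_crypt_rejects_nonpositive():
    with pytest.raises(EpiquantError):
        villus_crypt_ratio([(300.0, 0.0)])


def _disk(radius, pad=5):
    n = 2 * radius + 2 * pad
    yy, xx = np.mgrid[:n, :n]
    return ((yy - n / 2) ** 2 + (xx - n / 2) ** 2) <= radius**2


def test_circle_perimeter_within_3_percent():
    rec = organoid_metrics(_disk(50), n_plated_cells=1, pixel_size_um=1.0)
    assert rec.perimeters_um[0] == pytest.approx(2 * np.pi * 50, rel=0.03)


def test_perimeter_error_shrinks_with_radius():
    errs = []
    for r in (10, 25, 50, 100):
        rec = organoid_metrics(_disk(r), n_plated_cells=1)
        errs.append(abs(rec.perimeters_um[0] - 2 * np.pi * r) / (2 * np.pi * r))
    assert errs == sorted(errs, reverse=True)


def test_forming_rate():
    mask = np.zeros((40, 40), dtype=bool)
    for i in range(12):
        mask[3 * (i // 4) + 2, 3 * (i % 4) + 2] = True
    rec = organoid_metrics(mask, n_plated_cells=480)
    assert rec.n_objects == 12
    assert rec.forming_rate == pytest.approx(0.025)


def test_empty_mask_zero_rate():
    rec = organoid_metrics(np.zeros((10, 10), dtype=bool), n_plated_cells=100)
    assert rec.n_objects == 0 and rec.forming_rate == 0.0


def test_plated_cells_must_be_positive():
    with pytest.raises(EpiquantError):
        organoid_metrics(_disk(5), n_plated_cells=0)
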