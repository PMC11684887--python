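"""Localization scoring, the automatic cutoff, summaries, and the heatmap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiquant import (
    CellLabelMap,
    DegenerateInputError,
    EpiquantError,
    auto_cutoff,
    render_ratio_heatmap,
    score_cells,
    summarize,
)
from conftest import match_cells


def _records(mm, cm, mt=None, ct=None):
    n = len(mm)
    mt = mt if mt is not None else np.asarray(mm) * 10
    ct = ct if ct is not None else np.asarray(cm) * 40
    return pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "target_membrane_mean": mm,
            "target_cytoplasm_mean": cm,
            "target_membrane_total": mt,
            "target_cytoplasm_total": ct,
            "excluded": [False] * n,
        }
    )


def test_ratio_arithmetic():
    table = score_cells(_records([200.0], [100.0]))
    assert table.loc[0, "ratio"] == pytest.approx(2.0)


def test_uniform_intensity_gives_unit_ratio():
    # same per-pixel mean in both compartments
    table = score_cells(_records([50.0], [50.0], mt=[50.0 * 36], ct=[50.0 * 64]))
    assert table.loc[0, "ratio"] == pytest.approx(1.0)
    assert table.loc[0, "membrane_fraction"] == pytest.approx(36 / 100)


def test_excluded_cells_absent():
    rec = _records([1.0, 2.0], [1.0, 1.0])
    rec.loc[1, "excluded"] = True
    assert list(score_cells(rec)["cell_id"]) == [1]


def test_unknown_channel_errors():
    with pytest.raises(EpiquantError):
        score_cells(_records([1.0], [1.0]), target_channel="sglt1")


def test_conservation_membrane_plus_cytoplasm(segmented_clean):
    """Compartment totals add up to the whole-cell intensity, per cell."""
    s = segmented_clean
    t = s.image.get("target").astype(np.float64)
    labels = s.cells.labels
    totals = np.bincount(labels.ravel(), weights=t.ravel(),
                         minlength=s.cells.n_cells + 1)
    rec = s.records
    got = rec["target_membrane_total"] + rec["target_cytoplasm_total"]
    np.testing.assert_allclose(got, totals[rec["cell_id"]], rtol=1e-9)


def test_measured_fraction_tracks_truth(segmented_noisy):
    s = segmented_noisy
    table = score_cells(s.records).set_index("cell_id")
    mapping = match_cells(s.truth, s.cells)
    err = [
        abs(table.loc[rl, "membrane_fraction"]
            - s.truth.true_membrane_fraction[tl])
        for tl, rl in mapping.items()
        if rl and rl in table.index
    ]
    assert np.mean(err) < 0.05


# --- automatic cutoff -------------------------------------------------------

def _slope_criterion_oracle(scores, bins=256):
    """Brute-force re-derivation of the knee: the last score range sparser
    than the unit-square diagonal before the curve re-enters a dense mode."""
    s = np.sort(np.asarray(scores, float))[::-1]
    smin, smax = s.min(), s.max()
    counts, edges = np.histogram(s, bins=bins, range=(smin, smax))
    counts = np.convolve(counts, np.ones(5) / 5, mode="same")
    dense = (counts / counts.sum()) * bins >= 1.0  # per-bin slope vs diagonal
    # walk from top bin down; find last sparse->dense boundary
    for b in range(bins - 1):
        lower = bins - 2 - b
        if not dense[lower + 1] and dense[lower]:
            return edges[lower + 1]
    return None


def test_two_cluster_threshold_in_gap():
    rng = np.random.default_rng(1)
    s = np.concatenate([rng.uniform(9, 11, 500), rng.uniform(99, 101, 500)])
    res = auto_cutoff(s)
    assert 11 < res.threshold < 99
    oracle = _slope_criterion_oracle(s)
    assert oracle is not None and 11 < oracle < 99
    assert res.n_positive == 500 and res.n_negative == 500


def test_constant_scores_error():
    with pytest.raises(DegenerateInputError):
        auto_cutoff([5.0] * 50)


def test_too_few_scores_error():
    with pytest.raises(DegenerateInputError):
        auto_cutoff([1.0, 2.0, 3.0])


def test_lognormal_mixture_separation():
    """Two-component lognormal mixture, modes a decade apart: >= 95% accuracy."""
    rng = np.random.default_rng(12)
    labels = rng.random(2000) < 0.5
    s = np.where(labels,
                 rng.lognormal(np.log(100), 0.4, 2000),
                 rng.lognormal(np.log(10), 0.4, 2000))
    res = auto_cutoff(s)
    acc = ((s > res.threshold) == labels).mean()
    assert acc >= 0.95
    mode_lo = np.exp(np.log(10) - 0.4**2)
    mode_hi = np.exp(np.log(100) - 0.4**2)
    assert mode_lo < res.threshold < mode_hi


@settings(deadline=None, max_examples=20, derandomize=True)
@given(scale=st.floats(min_value=1e-3, max_value=1e3))
def test_cutoff_scale_invariance(scale):
    rng = np.random.default_rng(5)
    s = np.concatenate([rng.uniform(9, 11, 200), rng.uniform(99, 101, 200)])
    t1 = auto_cutoff(s).threshold
    t2 = auto_cutoff(s * scale).threshold
    assert t2 == pytest.approx(t1 * scale, rel=1e-9)


# --- summaries and heatmap --------------------------------------------------

def test_summarize_mean_and_counts():
    table = pd.DataFrame({"ratio": [1.0, 2.0, 3.0]})
    s = summarize(table, bins=10)
    assert s.mean_ratio == pytest.approx(2.0)
    assert s.hist_counts.sum() == 3


def test_summarize_empty_errors():
    with pytest.raises(EpiquantError):
        summarize(pd.DataFrame({"ratio": []}))


def test_cohort_means_ordered():
    """Higher true membrane fraction -> strictly higher mean ratio."""
    from conftest import segment_slide
    from epiquant import TissueConfig

    means = []
    for f, seed in ((0.4, 31), (0.6, 32)):
        base = TissueConfig(
            image_height_px=360, image_width_px=360, pixel_size_um=1.0,
            n_cells=200, membrane_fraction_per_cell=f, blur_sigma_px=0.5,
            noise_model="gaussian", seed=seed,
        )
        cfg = TissueConfig(**{**base.__dict__,
                              "gaussian_noise_sigma":
                              base.gaussian_sigma_for_snr(10.0)})
        s = segment_slide(cfg)
        means.append(summarize(score_cells(s.records)).mean_ratio)
    assert means[1] > means[0]


def _one_cell_map():
    labels = np.zeros((10, 10), dtype=np.int32)
    labels[2:8, 2:8] = 1
    return CellLabelMap(labels, 1.0)


def test_heatmap_top_of_range_color():
    cells = _one_cell_map()
    table = pd.DataFrame({"cell_id": [1], "ratio": [5.0]})
    rgb, meta = render_ratio_heatmap(cells, table, vmin=0.0, vmax=5.0)
    import matplotlib as mpl

    top = (np.array(mpl.colormaps["viridis"](1.0)[:3]) * 255).astype(np.uint8)
    assert (rgb[4, 4] == top).all()
    assert meta["vmax"] == 5.0


def test_heatmap_equal_ratios_equal_colors():
    labels = np.zeros((10, 14), dtype=np.int32)
    labels[2:8, 2:6] = 1
    labels[2:8, 8:12] = 2
    cells = CellLabelMap(labels, 1.0)
    table = pd.DataFrame({"cell_id": [1, 2], "ratio": [2.5, 2.5]})
    rgb, _ = render_ratio_heatmap(cells, table)
    assert (rgb[4, 4] == rgb[4, 9]).all()


def test_heatmap_missing_id_listed():
    with pytest.raises(EpiquantError, match="9"):
        render_ratio_heatmap(_one_cell_map(),
                             pd.DataFrame({"cell_id": [9], "ratio": [1.0]}))


def test_heatmap_round_trip_within_quantization(segmented_clean):
    """Pixel colors invert back to ratios within colormap quantization."""
    import matplotlib as mpl

    s = segmented_clean
    table = score_cells(s.records)
    rgb, meta = render_ratio_heatmap(s.cells, table)
    lut = (np.array(mpl.colormaps["viridis"](np.linspace(0, 1, 256))[:, :3])
           * 255).astype(int)
    rng = np.random.default_rng(0)
    ids = rng.choice(table["cell_id"].to_numpy(), size=100, replace=True)
    vals = table.set_index("cell_id")["ratio"]
    step = (meta["vmax"] - meta["vmin"]) / 255
    for cid in ids:
        rr, cc = np.argwhere(s.cells.labels == cid)[0]
        dist = np.abs(lut - rgb[rr, cc].astype(int)).sum(axis=1)
        recovered = meta["vmin"] + dist.argmin() / 255 * (meta["vmax"] - meta["vmin"])
        assert abs(recovered - vals[cid]) <= 2 * step + 1e-9
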