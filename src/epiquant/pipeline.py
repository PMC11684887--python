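"""End-to-end orchestration: probability -> segmentation -> scoring -> summaries.

``run_pipeline`` executes the stages in order, writes every artifact under
the configured output directory, and returns a :class:`RunManifest` listing
per-stage outputs, cell counts, and wall times. Any stage error aborts the
run with the stage name and cause recorded in the manifest (written to disk
before the error propagates). Given one config and seed the run is fully
deterministic, down to byte-identical CSV tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .census import TuftFilters, detect_tuft_cells, tuft_frequency
from .coloc import average_sample, coloc_pair, grid_rois
from .errors import DegenerateInputError, StageError
from .image import MultiplexImage
from .io import (
    PipelineConfig,
    read_multiplex,
    write_labels,
    write_mask,
    write_multiplex,
)
from .localization import auto_cutoff, render_ratio_heatmap, score_cells, summarize
from .probability import BaselineParams, baseline_probability, load_probability_maps, save_probability_maps
from .segmentation import (
    CellLabelMap,
    SegmentationParams,
    detect_nuclei,
    exclude_debris,
    measure_cells,
    partition_compartments,
    segment_cells,
)
from .synthetic import TissueConfig, generate_tissue

logger = logging.getLogger("epiquant")


@dataclass
class StageRecord:
    stage: str
    wall_s: float
    n_cells: Optional[int] = None
    outputs: List[str] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)
    error: Optional[str] = None


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: List[StageRecord] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "version": self.version,
            "stages": [dataclasses.asdict(s) for s in self.stages],
        }

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @property
    def output_files(self) -> List[str]:
        return [f for s in self.stages for f in s.outputs]


class _Runner:
    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest = RunManifest(config=config.to_dict(), version=__version__)
        self.manifest_path = self.out / "manifest.json"

    def stage(self, name):
        runner = self

        class _Ctx:
            def __enter__(ctx):
                ctx.rec = StageRecord(stage=name, wall_s=0.0)
                ctx.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return ctx.rec

            def __exit__(ctx, exc_type, exc, tb):
                ctx.rec.wall_s = round(time.perf_counter() - ctx.t0, 4)
                if exc is not None:
                    ctx.rec.error = f"{exc_type.__name__}: {exc}"
                    runner.manifest.stages.append(ctx.rec)
                    runner.manifest.write(runner.manifest_path)
                    raise StageError(name, exc) from exc
                runner.manifest.stages.append(ctx.rec)
                logger.info(
                    "stage %s: done in %.2fs (n_cells=%s)",
                    name, ctx.rec.wall_s, ctx.rec.n_cells,
                )
                return False

        return _Ctx()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every configured stage and return the manifest.

    Stage order: input (load or simulate) -> probability -> nuclei ->
    segmentation -> compartments -> measurement (+ debris exclusion) ->
    scoring -> cutoff -> summaries (+ colocalization and census when the
    corresponding channels are configured).
    """
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    r = _Runner(config)
    out = r.out
    truth = None

    with r.stage("input") as rec:
        if config.image_path:
            image = read_multiplex(
                config.image_path, pixel_size_um=config.pixel_size_um
            )
        elif config.simulate is not None:
            sim = dict(config.simulate)
            sim.setdefault("seed", config.seed)
            image, truth = generate_tissue(TissueConfig(**sim))
            img_path = out / "simulated.ome.tif"
            write_multiplex(image, img_path)
            write_labels(truth.cell_label_mask, out / "true_cells.tif")
            truth.to_frame().to_csv(out / "true_cells.csv", index=False)
            rec.outputs += [str(img_path), str(out / "true_cells.tif"),
                           str(out / "true_cells.csv")]
        else:
            raise FileNotFoundError("config names neither image_path nor simulate")

    with r.stage("probability") as rec:
        if config.probability_maps_path:
            from .probability import CORE_CLASSES

            prob = load_probability_maps(
                config.probability_maps_path, CORE_CLASSES
            )
        else:
            prob = baseline_probability(
                image,
                BaselineParams(membrane_channels=tuple(config.membrane_channels)),
            )
        prob_path = out / "probability_maps.tif"
        save_probability_maps(prob, prob_path)
        rec.outputs.append(str(prob_path))

    with r.stage("nuclei") as rec:
        nuclei = detect_nuclei(
            prob,
            min_area_um2=config.nucleus_min_area_um2,
            max_area_um2=config.nucleus_max_area_um2,
            pixel_size_um=image.pixel_size_um,
        )
        rec.n_cells = int(nuclei.max())
        p = out / "nuclei.tif"
        write_labels(nuclei, p)
        rec.outputs.append(str(p))

    with r.stage("segmentation") as rec:
        cells = segment_cells(
            image,
            prob,
            nuclei,
            SegmentationParams(
                membrane_channels=tuple(config.membrane_channels),
                min_cell_area_um2=config.min_cell_area_um2,
                max_cell_area_um2=config.max_cell_area_um2,
            ),
        )
        rec.n_cells = cells.n_cells
        p = out / "cells.tif"
        write_labels(cells.labels, p)
        rec.outputs.append(str(p))

    with r.stage("compartments") as rec:
        comps = partition_compartments(cells, band_px=config.band_px)
        rec.outputs = []

    with r.stage("measurement") as rec:
        debris = prob.argmax_class() == prob.class_names.index("debris")
        records = measure_cells(image, cells, comps, nuclei=nuclei,
                                debris_map=debris)
        records = exclude_debris(records, max_overlap=config.max_debris_overlap)
        rec.n_cells = int(len(records))
        p = out / "cells.csv"
        records.to_csv(p, index=False)
        rec.outputs.append(str(p))

    with r.stage("scoring") as rec:
        table = score_cells(records, target_channel=config.target_channel)
        rec.n_cells = int(len(table))
        p = out / "localization.csv"
        table.to_csv(p, index=False)
        rec.outputs.append(str(p))

    with r.stage("cutoff") as rec:
        try:
            cut = auto_cutoff(table["score"].to_numpy(), bins=config.cutoff_bins)
            cut_dict = {
                "threshold": cut.threshold,
                "method": cut.method,
                "bins": cut.bins,
                "n_positive": cut.n_positive,
                "n_negative": cut.n_negative,
            }
        except DegenerateInputError as e:
            cut_dict = {"error": str(e)}
            rec.warnings.append(f"cutoff degenerate: {e}")
        p = out / "cutoff.json"
        p.write_text(json.dumps(cut_dict, indent=2))
        rec.outputs.append(str(p))

    with r.stage("summary") as rec:
        summ = summarize(table)
        hist = pd.DataFrame(
            {
                "bin_left": summ.hist_edges[:-1],
                "bin_right": summ.hist_edges[1:],
                "count": summ.hist_counts,
            }
        )
        p_hist = out / "ratio_histogram.csv"
        hist.to_csv(p_hist, index=False)
        rgb, meta = render_ratio_heatmap(cells, table)
        p_map = out / "ratio_heatmap.png"
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        plt.imsave(p_map, rgb)
        (out / "ratio_heatmap.json").write_text(json.dumps(meta))
        (out / "summary.json").write_text(
            json.dumps({"mean_ratio": summ.mean_ratio, "n_cells": summ.n_cells})
        )
        rec.n_cells = summ.n_cells
        rec.outputs += [str(p_hist), str(p_map),
                        str(out / "ratio_heatmap.json"), str(out / "summary.json")]

    if config.lysosome_channel and config.lysosome_channel in image:
        with r.stage("colocalization") as rec:
            rois = grid_rois(image.shape, config.n_rois)
            results = [
                coloc_pair(
                    image.get(config.target_channel),
                    image.get(config.lysosome_channel),
                    roi_mask=m,
                    threshold_method="bimodal",
                    roi_id=str(i),
                )
                for i, m in enumerate(rois)
            ]
            sample = average_sample(results, sample_id="run",
                                    expected_n=config.n_rois)
            rows = [
                {
                    "roi_id": c.roi_id,
                    "pearson_r": c.pearson_r,
                    "manders_m1": c.manders_m1,
                    "manders_m2": c.manders_m2,
                    "n_pixels": c.n_pixels,
                }
                for c in results
            ]
            rows.append(
                {
                    "roi_id": "mean",
                    "pearson_r": sample.pearson_r,
                    "manders_m1": sample.manders_m1,
                    "manders_m2": sample.manders_m2,
                    "n_pixels": sum(c.n_pixels for c in results),
                }
            )
            p = out / "colocalization.csv"
            pd.DataFrame(rows).to_csv(p, index=False)
            rec.outputs.append(str(p))

    if config.tuft_channel and config.tuft_channel in image:
        with r.stage("census") as rec:
            cls = prob.argmax_class()
            names = prob.class_names
            tissue_mask = np.isin(
                cls, [names.index(c) for c in ("tissue", "nuclei", "membrane")]
            )
            debris = cls == names.index("debris")
            if truth is not None:
                debris = debris | truth.debris_mask
            tufts = detect_tuft_cells(
                image.get(config.tuft_channel),
                cells,
                nuclei,
                tissue_mask,
                debris_mask=debris,
                filters=TuftFilters(
                    min_area_um2=config.tuft_min_area_um2,
                    max_area_um2=config.tuft_max_area_um2,
                ),
                pixel_size_um=image.pixel_size_um,
            )
            summary = tuft_frequency(
                tufts, records,
                tissue_area_um2=image.area_um2(int((cells.labels > 0).sum())),
            )
            p = out / "tuft_cells.csv"
            tufts.to_csv(p, index=False)
            (out / "census.json").write_text(
                json.dumps(dataclasses.asdict(summary))
            )
            rec.n_cells = summary.n_tuft_accepted
            rec.outputs += [str(p), str(out / "census.json")]

    r.manifest.write(r.manifest_path)
    return r.manifest
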