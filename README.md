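# epiquant

Per-cell quantification of multiplex immunofluorescence slides of intestinal
epithelium, built for studies of apical-transporter mistrafficking such as
microvillus inclusion disease (MVID). In MVID models, transporters like SGLT1
and NHE3 leave the brush-border membrane and accumulate in the cytoplasm or
in lysosomes; quantifying that shift across tens of thousands of epithelial
cells per slide is the job this package automates.

The pipeline:

1. **Pixel probability maps** — per-pixel class scores over {background,
   tissue, nuclei, membrane, debris}, either ingested from an external pixel
   classifier's export or computed by a deterministic baseline classifier.
2. **Cell segmentation** — nuclei detected from the nuclei-class map seed a
   marker-controlled watershed over the combined membrane-marker relief;
   each cell is split into a membrane band (the outer `band_px` ring, default
   2 px) and the cytoplasm; debris-covered cells are excluded.
3. **Localization scoring** — per cell, the membrane/cytoplasm intensity
   ratio `r = mean_mem / max(mean_cyto, ε)` and the bounded membrane
   fraction `f = total_mem / (total_mem + total_cyto)`; positive/negative
   calls use an automatic "inverse-slope" cutoff: scores are discretized,
   and the threshold sits where the normalized rank curve re-enters a dense
   mode after a region sparser than the unit-square diagonal (inverse slope
   > 1). Populations are summarized as histograms, means, and a per-cell
   ratio heatmap.
4. **Colocalization** — Pearson's r and Manders' M1/M2
   (`M1 = Σ A·[B > t_B] / Σ A`) between a transporter and a lysosome channel
   over ROIs, averaged per sample (conventionally five ROIs per animal).
5. **Cell census** — tuft cells (DCLK1-like marker blobs filtered by size,
   location, and presence of a detectable nucleus) per mucosal cell;
   marker-positive nuclei per crypt region; villus/crypt length ratios; and
   organoid perimeter / forming-rate metrics.

Because no public imaging dataset accompanies this kind of study, the
package ships a first-class synthetic tissue generator
(`epiquant.synthetic`) that emulates the structure the pipeline assumes —
polygonal cell sheets with one nucleus per cell, boundary-concentrated
membrane signal, a controllable per-cell membrane fraction of the target
channel, lysosomal puncta with a plantable intensity overlap, tuft cells,
debris smears, blur, and photon-like noise — with complete ground truth, so
every stage is validated against known answers.

## Worked example

`examples/02_segment_and_score.py` simulates a 200-cell slide whose cells
carry 60% of their transporter signal on the membrane band, under realistic
blur and shot noise (SNR ≈ 10), then runs the full measurement:

```
segmented 200 cells from 200 planted
mean membrane/cytoplasm ratio: 1.880 (1.0 would mean no membrane enrichment)
measured membrane fraction: 0.567 vs true 0.600
auto cutoff at score 87.4: 190 positive / 10 negative cells
```

All 200 cells are recovered; the measured membrane fraction tracks the
planted 0.60 to within a few percent (the small deficit is boundary-pixel
blur); and the automatic cutoff calls the overwhelming majority of this
uniformly-positive cohort positive. The other scripts in `examples/` cover
simulation, colocalization (a planted 40% overlap is recovered as
M1 = 0.400), the tuft census with single-violation distractors, the
end-to-end pipeline with its run manifest, and morphometry.

## Command line

A thin CLI wraps the library:

```sh
epiquant simulate --out slide/ --n-cells 500 --pixel-size 1.0 --seed 7
epiquant segment slide/image.ome.tif --out seg/
epiquant score seg/cells.csv --out scores/
epiquant coloc slide/image.ome.tif --channel-a target --channel-b lysosome
epiquant census slide/image.ome.tif --out census/
epiquant run --config pipeline.yaml
epiquant report run_dir/
```

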