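# Methods

## The measurement problem

In intestinal epithelium, apical transporters (SGLT1, NHE3) normally sit on
the brush-border membrane. When apical trafficking fails — as in MVID — they
redistribute into the cytoplasm and into lysosomes. The pipeline turns a
multichannel fluorescence slide (nuclei, one or two membrane markers, a
target transporter, optionally a lysosome marker and a tuft-cell marker)
into per-cell statistics of that redistribution: a membrane/cytoplasm
intensity ratio and a bounded membrane fraction per cell, positive/negative
calls, transporter–lysosome colocalization coefficients, and rare-cell
censuses.

## Synthetic tissue generator

No public imaging dataset exists for this study type, so validation rests on
a generator with closed-form ground truth.

**Geometry.** Cell seeds sit on a hexagonal lattice with spacing
d = 1.9·r (r = cell radius in px; the hexagonal Voronoi cell of that lattice
has area ≈ πr²), jittered by an amplitude tied to the radius-dispersion
parameter, filled in scan order so the occupied band forms a contiguous
sheet with genuine background. Pixels are assigned to the nearest seed
within 0.75·d, producing disjoint, contiguous, polygonal cells each
containing its seed. The nucleus is a disk centred on the seed with area
`nucleus_fraction × cell area`, clipped strictly inside the cell. The
membrane band is the cell minus its label-aware 4-connected erosion by
`membrane_band_px` (default 2); the segmentation side uses the identical
construction, which makes compartment recovery exact on noise-free slides.

**Channels.** Per cell, the target channel places fraction `f` of
`target_total_intensity` uniformly on the band and `1 − f` uniformly on the
interior (`f` may be one value, a per-cell list, or a uniform range).
Membrane channels carry per-cell gain variation (uniform 0.7–1.3) on the
band; lysosome puncta are small interior disks; tuft cells are whole-cell
marker fills on cells chosen with enforced seed spacing so candidate blobs
never merge; debris smears are random-walk disk unions that add high
intensity to every channel and set the debris mask. When a planted
target/lysosome overlap is requested, the target channel is redistributed so
that *exactly* that fraction of its total intensity lies inside puncta —
Manders M1 at threshold 0 then has a closed-form truth. Blur (Gaussian PSF)
is applied before noise; noise is Gaussian, Poisson on scaled intensities,
or both. One `numpy` Generator seeded from the config drives everything;
identical (config, seed) pairs are bit-identical.

**Distractor planting** (`plant_tuft_distractors`) paints marker blobs that
each violate exactly one census filter: a nucleus-centred blob below any
sane minimum area ("size"); a well-formed blob on a cell simultaneously
covered by planted debris ("location" — debris intensity is added to the
nuclei/membrane channels only, so the marker channel's candidate set stays
clean); and a blob placed where it overlaps no nucleus ("no-nucleus").
Hosts keep clear of tuft cells, of each other, and of image borders.

**What the generator does not emulate.** 3-D tissue and Swiss-roll
geometry, optical vignetting, chromatic shifts between channels, spatially
correlated autofluorescence, and biological covariation between markers.
Passing tests therefore demonstrate correctness of the measurement chain
under the stated image-formation model, not performance on arbitrary real
slides; on real data the external-probability-map path exists precisely so a
trained pixel classifier can absorb the appearance variation the baseline
heuristic cannot.

## Baseline pixel classifier

Scores per class, normalized per pixel to sum to 1 (validated to 1e-6):
nuclei and membrane are the background-subtracted, lightly smoothed
(σ = 0.5 px), percentile-rescaled channel intensities; background is a
constant floor (0.05); debris is the minimum of the rescaled nuclei and
membrane signals — a co-saturation heuristic that is near zero in normal
tissue because nuclear and membrane staining are spatially disjoint, and
which keeps the nuclei-class probability provably non-decreasing in nuclei
intensity. The tissue score is `0.45 ×` the morphological closing (disk
r = 5, padded so borders do not erode) of the thresholded raw signal.

Two deliberate choices here: background subtraction is a separable
square-window grey opening (a rolling-ball equivalent at tractable cost on
multi-megapixel slides), and it is *not* applied to the tissue-support
signal — broad diffuse cytoplasmic intensity is itself the evidence of
tissue and would be flattened by any opening window. Using raw, unsmoothed
signal for tissue support also keeps the support compact, so an isolated
cell acquires no halo.

External maps (multichannel TIFF or HDF5, one plane per class) are accepted
whenever per-pixel sums are within 1e-3 of 1, and renormalized exactly.

## Segmentation

Nuclei: the nuclei-class map is thresholded at 0.5, 4-connected components
are split at distance-transform peaks (minimum separation 4 px) and filtered
by area (defaults 5–200 µm²). Cells: a watershed from the nucleus seeds over
a relief equal to the membrane-probability-weighted sum of rescaled membrane
channels, smoothed with σ = 1 px — the smoothing centres the ridge inside
membrane walls whose two sides differ in brightness, which is what bounds
the boundary error at zero noise to ≤ 1 px (median). Growth is restricted to
pixels whose argmax class is tissue/nuclei/membrane *and* that lie on tissue
support, so cells stop at the true sheet edge rather than at the smear of
membrane signal beyond it. Cells below 25 µm² are removed and recorded as
excluded (`too-small`); cells whose erosion by the band width is empty are
excluded as `too-small-for-band`; cells more than 50% covered by debris are
excluded as `debris`. 4-connectivity is used throughout to prevent diagonal
leaks across 1-px membranes.

## Localization scoring and the automatic cutoff

Per non-excluded cell: ratio = membrane mean / max(cytoplasm mean, ε) with
ε = 1 intensity quantum (avoids infinities while preserving order), and
membrane fraction = membrane total / cell total, which has a generator-side
closed truth and is the recovery statistic in the tests. The
positive/negative call uses the membrane mean score by default (ratio by
option).

The cutoff operationalizes "inverse slope of discretized pixel values" as
follows: scores are discretized into 256 equal-width bins; bin counts are
smoothed with a 5-bin moving average; on the normalized curve of (cumulative
cell fraction, bin value) walked from the top bin down, segments through
dense score ranges are flatter than the unit-square diagonal and segments
through sparse ranges (tails, the valley between two populations) are
steeper — their inverse slope exceeds 1. The threshold is the bin edge at
the **last** steep-to-flat transition, i.e. where the curve re-enters a
dense mode coming down from the bright population. This places the
threshold strictly inside the gap of a well-separated two-cluster
population and in the valley of a lognormal mixture (≥ 95% label accuracy at
one decade of mode separation, the design target since the one-line verbal
description admits several readings). Fewer than 10 scores, or scores with
no spread, raise a degenerate-input error rather than producing a silent
cutoff. The construction is scale-equivariant: multiplying all scores by c
multiplies the threshold by exactly c.

## Colocalization

Pearson over ROI pixels (undefined — and an error — for a constant channel);
Manders M1/M2 with per-channel thresholds from the configured method:
`none` (t = 0; the exact planted-overlap contract), `bimodal` (per-channel
Otsu, the default stand-in for plugin-style auto-thresholding), or `costes`
(iterative regression threshold). Per-sample results are the arithmetic mean
over ROIs; a count different from the conventional five warns but never
errors. Default ROIs are five vertical strips; mask-defined ROIs are
accepted anywhere.

## Censuses and morphometry

Tuft candidates are connected components of the thresholded marker channel.
The primary threshold is Otsu over in-tissue, non-debris pixels (debris
smears stain every channel and would otherwise drag the threshold above the
marker); when at least 10 location-valid candidates exist, the automatic
cutoff on their mean intensities removes dim spurious blobs, but only if the
split reveals a real intensity gap (ratio > 1.5) — a unimodal candidate
population stays intact, and equal-intensity candidates (where the cutoff
must raise) are all kept. Filters, applied in the order size → location →
no-nucleus so each rejection carries one primary reason: area within
20–700 µm²; ≥ 50% inside tissue and ≤ 50% on debris; nucleus overlap ≥ 0.1.
The size bounds and overlap thresholds are config values, not asserted
facts. Frequency is reported per non-excluded mucosal cell.

Positive-nuclei-per-region counts assign each nucleus to the region holding
its centroid (overlapping regions are an error) and threshold nucleus mean
intensities (given, or Otsu). Villus/crypt ratio is the mean of per-region
length ratios from an annotation table. Organoid perimeters use the
corner-corrected Crofton contour estimator (raw pixel-edge counting
overestimates a circle's perimeter by ~27%; Crofton is within 0.4% at
r = 50 px and its error shrinks with radius); forming rate is object count
over plated cells.

## Problem sizes and numerical choices

Tests and the acceptance script run at 1 µm/px with 8 µm cell radius
(≈ 220 px²/cell), the package's chosen benchmark scale: recovery fixtures
use 500 cells per membrane-fraction level at SNR ≈ 10 (Gaussian noise sigma
set from the mean interior intensity), segmentation fidelity uses 200-cell
slides, cohort comparisons 5,000 cells per arm over three seeds, and the
scale demonstration a 30,000-cell slide (2650² px) end to end. The default
config exposes 0.32 µm/px and 16-bit depth for scanner-resolution imagery;
neither is asserted anywhere.

Noise is applied after blur; intensities are clipped at zero. The measured
membrane fraction is defined against pre-blur truth, so optical blur
introduces a real, documented bias (band intensity bleeding across the 2-px
compartment edge): about −0.05 at f = 0.8 under a σ = 1 px PSF, a fraction
of that at σ = 0.5 px. Watershed ties are resolved by scikit-image's
deterministic flooding order; all randomness flows from explicit seeds; CSV
outputs are byte-reproducible for a fixed config and seed.

## Known limitations

The baseline classifier is a heuristic for well-behaved staining, not a
trained model; real slides should use exported probability maps. The
generator's planar geometry cannot probe errors caused by out-of-plane
cells or folds beyond the debris model. The inverse-slope cutoff assumes the
score distribution has at most a few modes; heavily overlapping populations
yield a threshold at the sparsest point with no accuracy guarantee. Tuft
detection assumes marker-positive cells are spatially separated; merged
candidates would be filtered by the size bound rather than split.
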