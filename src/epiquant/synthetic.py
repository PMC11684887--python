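"""Seeded synthetic epithelial-tissue image generator with full ground truth.

The generator emulates the statistical structure of a stained intestinal
mucosa slide as the analysis pipeline assumes it: a contiguous sheet of
polygonal epithelial cells (one nucleus each), membrane markers concentrated
on cell boundaries, a target-transporter channel whose per-cell intensity is
split between a boundary band and the interior with a controllable membrane
fraction, optional lysosomal puncta with a plantable intensity overlap,
sparse tuft cells carrying a dedicated marker, and tissue-fold/debris smears,
followed by optical blur and photon-like noise.

Geometry is a nearest-seed partition of a jittered hexagonal point lattice,
clipped to a tissue band: contiguous, pairwise-disjoint polygonal cells whose
count and mean size are controlled in closed form at any scale. The membrane
band is the cell minus its 4-connected erosion by ``membrane_band_px``; the
segmentation side uses the identical construction, so compartment recovery is
exact on noise-free fixtures.

Everything is driven by one :class:`numpy.random.Generator` seeded from
``TissueConfig.seed``; identical (config, seed) pairs yield bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ConfigurationError
from .image import MultiplexImage
from .morphology import erode_labels

NOISE_MODELS = ("none", "gaussian", "poisson", "poisson+gaussian")

MembraneFractionSpec = Union[float, Tuple[float, float], Sequence[float]]


@dataclass
class TissueConfig:
    """Parameters of one synthetic slide.

    ``membrane_fraction_per_cell`` may be a scalar (same true fraction for
    every cell), a ``(low, high)`` tuple (per-cell uniform draw), or a
    sequence of length ``n_cells``.
    """

    image_height_px: int = 512
    image_width_px: int = 512
    pixel_size_um: float = 0.32
    n_cells: int = 200
    cell_radius_um: float = 8.0
    cell_radius_dispersion: float = 0.15
    nucleus_fraction: float = 0.25
    membrane_band_px: int = 2
    membrane_fraction_per_cell: MembraneFractionSpec = 0.5
    target_total_intensity: float = 20000.0
    nucleus_intensity: float = 200.0
    membrane_intensity: float = 200.0
    n_membrane_channels: int = 2
    n_tuft_cells: int = 0
    tuft_marker_intensity: float = 150.0
    n_lysosome_puncta_per_cell: int = 0
    lysosome_intensity: float = 300.0
    lysosome_punctum_radius_px: int = 2
    coloc_overlap_fraction: float = 0.0
    n_debris_blobs: int = 0
    debris_intensity: float = 1500.0
    blur_sigma_px: float = 0.0
    noise_model: str = "none"
    gaussian_noise_sigma: float = 10.0
    photons_per_unit: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ConfigurationError("image dimensions must be positive")
        if self.pixel_size_um <= 0 or self.cell_radius_um <= 0:
            raise ConfigurationError("pixel size and cell radius must be positive")
        if self.n_cells < 0:
            raise ConfigurationError("n_cells must be non-negative")
        if not (0 <= self.cell_radius_dispersion < 1):
            raise ConfigurationError("cell_radius_dispersion must be in [0, 1)")
        if not (0 < self.nucleus_fraction < 1):
            raise ConfigurationError("nucleus_fraction must be in (0, 1)")
        if self.membrane_band_px < 1:
            raise ConfigurationError("membrane_band_px must be >= 1")
        if self.membrane_band_px >= self.cell_radius_px:
            raise ConfigurationError(
                "membrane_band_px >= cell radius in px: no interior left"
            )
        if self.n_tuft_cells > self.n_cells:
            raise ConfigurationError("n_tuft_cells exceeds n_cells")
        if self.n_tuft_cells < 0 or self.n_lysosome_puncta_per_cell < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.n_debris_blobs < 0:
            raise ConfigurationError("n_debris_blobs must be non-negative")
        if not (0.0 <= self.coloc_overlap_fraction <= 1.0):
            raise ConfigurationError("coloc_overlap_fraction must be in [0, 1]")
        if self.blur_sigma_px < 0:
            raise ConfigurationError("blur_sigma_px must be non-negative")
        if self.noise_model not in NOISE_MODELS:
            raise ConfigurationError(
                f"noise_model must be one of {NOISE_MODELS}, got {self.noise_model!r}"
            )
        if self.n_membrane_channels not in (1, 2):
            raise ConfigurationError("n_membrane_channels must be 1 or 2")
        self._validate_membrane_fraction()

    def _validate_membrane_fraction(self) -> None:
        spec = self.membrane_fraction_per_cell
        if isinstance(spec, (int, float)):
            vals = [float(spec)]
        elif isinstance(spec, tuple) and len(spec) == 2:
            vals = [float(spec[0]), float(spec[1])]
            if vals[0] > vals[1]:
                raise ConfigurationError("membrane fraction range must be (low, high)")
        else:
            vals = [float(v) for v in spec]
            if self.n_cells and len(vals) != self.n_cells:
                raise ConfigurationError(
                    "membrane_fraction_per_cell sequence must have length n_cells"
                )
        for v in vals:
            if not (0.0 < v < 1.0):
                raise ConfigurationError("membrane fractions must lie in (0, 1)")

    @property
    def cell_radius_px(self) -> float:
        return self.cell_radius_um / self.pixel_size_um

    @property
    def seed_spacing_px(self) -> float:
        # Hexagonal Voronoi cell of side spacing d has area (sqrt(3)/2) d^2;
        # d = 1.9 r makes that ~= pi r^2.
        return 1.9 * self.cell_radius_px

    @property
    def expected_cell_area_px(self) -> float:
        return math.pi * self.cell_radius_px**2

    def gaussian_sigma_for_snr(self, snr: float) -> float:
        """Gaussian noise sigma giving roughly ``snr`` on interior target pixels."""
        per_pixel = self.target_total_intensity / self.expected_cell_area_px
        return per_pixel / snr


@dataclass
class SyntheticGroundTruth:
    """Generator-side truth against which every pipeline stage is validated.

    Per-cell arrays are indexed by label (index 0 unused).
    """

    cell_label_mask: np.ndarray
    nucleus_label_mask: np.ndarray
    membrane_band_mask: np.ndarray
    true_membrane_fraction: np.ndarray
    tuft_flags: np.ndarray
    debris_mask: np.ndarray
    puncta_mask: np.ndarray
    planted_overlap_fraction: Optional[float]
    seeds_rc: np.ndarray
    seed_spacing_px: float
    config: TissueConfig
    distractors: Optional[pd.DataFrame] = None

    @property
    def n_cells(self) -> int:
        return int(self.cell_label_mask.max())

    @property
    def labels(self) -> np.ndarray:
        return np.arange(1, self.n_cells + 1)

    def to_frame(self) -> pd.DataFrame:
        """Per-cell ground-truth table (one row per cell)."""
        n = self.n_cells
        areas = np.bincount(self.cell_label_mask.ravel(), minlength=n + 1)
        return pd.DataFrame(
            {
                "cell_id": np.arange(1, n + 1),
                "seed_row": self.seeds_rc[:, 0],
                "seed_col": self.seeds_rc[:, 1],
                "area_px": areas[1:],
                "true_membrane_fraction": self.true_membrane_fraction[1 : n + 1],
                "tuft": self.tuft_flags[1 : n + 1],
            }
        )


def _hex_lattice(cfg: TissueConfig) -> np.ndarray:
    """Row-major hexagonal lattice sites inside the tissue band."""
    d = cfg.seed_spacing_px
    dy = d * math.sqrt(3.0) / 2.0
    margin = max(2.0, 0.8 * d)
    sites = []
    row = 0
    y = margin
    while y <= cfg.image_height_px - margin:
        x = margin + (d / 2.0 if row % 2 else 0.0)
        while x <= cfg.image_width_px - margin:
            sites.append((y, x))
            x += d
        y += dy
        row += 1
    return np.asarray(sites, dtype=float).reshape(-1, 2)


def _paint_disks(shape, centers_rc, radius):
    """Boolean mask of disks of one radius at integer centers."""
    mask = np.zeros(shape, dtype=bool)
    if len(centers_rc) == 0:
        return mask
    r = int(math.ceil(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = (dy**2 + dx**2) <= radius**2
    offs = np.argwhere(disk) - r
    pts = np.asarray(centers_rc, dtype=int)[:, None, :] + offs[None, :, :]
    pts = pts.reshape(-1, 2)
    ok = (
        (pts[:, 0] >= 0)
        & (pts[:, 0] < shape[0])
        & (pts[:, 1] >= 0)
        & (pts[:, 1] < shape[1])
    )
    pts = pts[ok]
    mask[pts[:, 0], pts[:, 1]] = True
    return mask


def _resolve_membrane_fractions(cfg: TissueConfig, rng) -> np.ndarray:
    spec = cfg.membrane_fraction_per_cell
    n = cfg.n_cells
    if isinstance(spec, (int, float)):
        return np.full(n, float(spec))
    if isinstance(spec, tuple) and len(spec) == 2:
        return rng.uniform(spec[0], spec[1], size=n)
    return np.asarray([float(v) for v in spec], dtype=float)


def _select_spaced_cells(seeds, rng, n_wanted, min_dist, forbidden=(),
                         allow_partial=False):
    """Greedy seeded selection of cell labels with pairwise seed spacing."""
    order = rng.permutation(len(seeds))
    chosen: list[int] = []
    forbidden_pts = [seeds[i - 1] for i in forbidden]
    for idx in order:
        p = seeds[idx]
        pts = [seeds[j] for j in chosen] + forbidden_pts
        if all(np.hypot(*(p - q)) > min_dist for q in pts):
            chosen.append(idx)
            if len(chosen) == n_wanted:
                break
    if len(chosen) < n_wanted and not allow_partial:
        raise ConfigurationError(
            f"cannot place {n_wanted} spaced marker cells among {len(seeds)} cells"
        )
    return np.asarray(sorted(i + 1 for i in chosen))  # labels


def _redistribute_target(
    target: np.ndarray,
    puncta_mask: np.ndarray,
    cell_mask: np.ndarray,
    overlap: float,
) -> np.ndarray:
    """Move exactly ``overlap`` of total target intensity into puncta pixels."""
    total = float(target.sum())
    out = np.zeros_like(target)
    if total == 0:
        return out
    n_in = int(puncta_mask.sum())
    if n_in == 0:
        if overlap > 0:
            raise ConfigurationError("cannot plant overlap > 0 without puncta")
        return target.copy()
    if overlap > 0:
        out[puncta_mask] = overlap * total / n_in
    outside = ~puncta_mask
    sum_outside = float(target[outside].sum())
    if overlap < 1.0:
        if sum_outside > 0:
            out[outside] = target[outside] * ((1.0 - overlap) * total / sum_outside)
        else:
            # no residual structure to scale: spread uniformly over cell pixels
            dest = outside & cell_mask
            if not dest.any():
                dest = outside
            out[dest] = (1.0 - overlap) * total / dest.sum()
    return out


def generate_tissue(config: TissueConfig):
    """Generate one synthetic slide.

    Returns
    -------
    (MultiplexImage, SyntheticGroundTruth)
        Channels present: ``nuclei``, ``membrane1`` (and ``membrane2``),
        ``target``; plus ``lysosome`` when puncta are configured and ``tuft``
        when tuft cells are configured.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.image_height_px, cfg.image_width_px
    shape = (H, W)

    labels = np.zeros(shape, dtype=np.int32)
    dist_to_seed = np.full(shape, np.inf)
    seeds = np.zeros((cfg.n_cells, 2), dtype=float)

    if cfg.n_cells > 0:
        sites = _hex_lattice(cfg)
        if len(sites) < cfg.n_cells:
            raise ConfigurationError(
                f"image holds at most {len(sites)} cells at this radius; "
                f"{cfg.n_cells} requested"
            )
        seeds = sites[: cfg.n_cells].copy()
        jitter_amp = (0.15 + 0.5 * cfg.cell_radius_dispersion) * cfg.cell_radius_px
        seeds += rng.uniform(-jitter_amp, jitter_amp, size=seeds.shape)
        seeds[:, 0] = np.clip(seeds[:, 0], 1, H - 2)
        seeds[:, 1] = np.clip(seeds[:, 1], 1, W - 2)

        clip_dist = 0.75 * cfg.seed_spacing_px
        tree = cKDTree(seeds)
        rows, cols = np.mgrid[0:H, 0:W]
        coords = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
        dist, idx = tree.query(coords, k=1, distance_upper_bound=clip_dist)
        inside = np.isfinite(dist)
        lab_flat = np.zeros(H * W, dtype=np.int32)
        lab_flat[inside] = idx[inside].astype(np.int32) + 1
        labels = lab_flat.reshape(shape)
        dist_to_seed = np.where(inside.reshape(shape), dist.reshape(shape), np.inf)

    n = cfg.n_cells
    areas = np.bincount(labels.ravel(), minlength=n + 1)[: n + 1]

    # nuclei: disks centred on the seed, clipped strictly inside the cell
    interior1 = erode_labels(labels, 1)
    rn = np.zeros(n + 1)
    if n:
        rn[1:] = np.sqrt(cfg.nucleus_fraction * np.maximum(areas[1:], 1) / math.pi)
    nucleus_mask = (
        (labels > 0) & interior1 & (dist_to_seed <= rn[labels])
    )
    if n:
        # guarantee one nucleus pixel per cell even for degenerate small cells
        have = np.bincount(labels[nucleus_mask].ravel(), minlength=n + 1)[1:] > 0
        for lab in np.nonzero(~have)[0] + 1:
            r0, c0 = np.round(seeds[lab - 1]).astype(int)
            if labels[r0, c0] == lab:
                nucleus_mask[r0, c0] = True
            else:
                pix = np.argwhere(labels == lab)
                if len(pix):
                    nucleus_mask[tuple(pix[0])] = True
    nucleus_label_mask = np.where(nucleus_mask, labels, 0).astype(np.int32)

    # membrane band / interior split
    interior_band = erode_labels(labels, cfg.membrane_band_px)
    band_mask = (labels > 0) & ~interior_band
    band_counts = np.bincount(labels[band_mask].ravel(), minlength=n + 1)[: n + 1]
    int_counts = np.bincount(labels[interior_band].ravel(), minlength=n + 1)[: n + 1]

    channels: dict[str, np.ndarray] = {}
    channels["nuclei"] = (cfg.nucleus_intensity * nucleus_mask).astype(np.float32)

    for k in range(cfg.n_membrane_channels):
        gain = np.zeros(n + 1, dtype=np.float32)
        if n:
            gain[1:] = rng.uniform(0.7, 1.3, size=n)
        ch = np.where(band_mask, cfg.membrane_intensity * gain[labels], 0.0)
        channels[f"membrane{k + 1}"] = ch.astype(np.float32)

    fractions = np.zeros(n + 1)
    if n:
        planted = _resolve_membrane_fractions(cfg, rng)
        fractions[1:] = planted
        fractions[1:][int_counts[1:] == 0] = 1.0  # no interior left: all in band
    band_val = np.zeros(n + 1)
    int_val = np.zeros(n + 1)
    if n:
        nz = band_counts[1:] > 0
        band_val[1:][nz] = (
            fractions[1:][nz] * cfg.target_total_intensity / band_counts[1:][nz]
        )
        nzi = int_counts[1:] > 0
        int_val[1:][nzi] = (
            (1.0 - fractions[1:][nzi]) * cfg.target_total_intensity / int_counts[1:][nzi]
        )
    target = np.where(band_mask, band_val[labels], 0.0) + np.where(
        interior_band, int_val[labels], 0.0
    )
    target = target.astype(np.float32)

    # tuft cells: whole-cell marker on spaced cells
    tuft_flags = np.zeros(n + 1, dtype=bool)
    if cfg.n_tuft_cells > 0:
        tuft_labels = _select_spaced_cells(
            seeds, rng, cfg.n_tuft_cells, 1.15 * cfg.seed_spacing_px
        )
        tuft_flags[tuft_labels] = True
        gain = np.zeros(n + 1, dtype=np.float32)
        gain[tuft_labels] = rng.uniform(0.9, 1.1, size=len(tuft_labels))
        channels["tuft"] = np.where(
            tuft_flags[labels], cfg.tuft_marker_intensity * gain[labels], 0.0
        ).astype(np.float32)

    # lysosomal puncta in cell interiors
    puncta_mask = np.zeros(shape, dtype=bool)
    if cfg.n_lysosome_puncta_per_cell > 0 and n > 0:
        order = np.argsort(labels.ravel(), kind="stable")
        flat = labels.ravel()[order]
        starts = np.searchsorted(flat, np.arange(1, n + 1))
        ends = np.searchsorted(flat, np.arange(1, n + 1), side="right")
        interior_flat = interior_band.ravel()[order]
        centers = []
        for lab in range(1, n + 1):
            sl = slice(starts[lab - 1], ends[lab - 1])
            pix = order[sl][interior_flat[sl]]
            if len(pix) == 0:
                continue
            take = rng.choice(pix, size=min(cfg.n_lysosome_puncta_per_cell, len(pix)),
                              replace=False)
            centers.extend((p // W, p % W) for p in np.atleast_1d(take))
        puncta_mask = _paint_disks(shape, centers, cfg.lysosome_punctum_radius_px)
        channels["lysosome"] = np.where(
            puncta_mask, cfg.lysosome_intensity, 0.0
        ).astype(np.float32)

    planted_overlap = None
    if cfg.coloc_overlap_fraction > 0 or (
        cfg.n_lysosome_puncta_per_cell > 0 and cfg.coloc_overlap_fraction == 0
    ):
        if cfg.n_lysosome_puncta_per_cell > 0:
            target = _redistribute_target(
                target, puncta_mask, labels > 0, cfg.coloc_overlap_fraction
            ).astype(np.float32)
            planted_overlap = float(cfg.coloc_overlap_fraction)
    channels["target"] = target

    # debris / tissue-fold smears: irregular multi-channel high-intensity blobs
    debris_mask = np.zeros(shape, dtype=bool)
    if cfg.n_debris_blobs > 0:
        for _ in range(cfg.n_debris_blobs):
            r0 = rng.uniform(0, H)
            c0 = rng.uniform(0, W)
            pos = np.array([r0, c0])
            centers = []
            for _ in range(6):
                centers.append(pos.copy())
                pos = pos + rng.normal(0, 4.0, size=2)
            blob = _paint_disks(shape, np.round(centers).astype(int),
                                rng.uniform(3.0, 8.0))
            debris_mask |= blob
        for name in channels:
            bump = cfg.debris_intensity * rng.uniform(0.7, 1.3)
            channels[name] = np.where(
                debris_mask, channels[name] + bump, channels[name]
            ).astype(np.float32)

    # image formation: blur, then noise
    if cfg.blur_sigma_px > 0:
        for name in channels:
            channels[name] = ndimage.gaussian_filter(
                channels[name], cfg.blur_sigma_px
            ).astype(np.float32)
    channels = _apply_noise(channels, cfg, rng)

    image = MultiplexImage(channels, pixel_size_um=cfg.pixel_size_um,
                           bit_depth=16)
    truth = SyntheticGroundTruth(
        cell_label_mask=labels,
        nucleus_label_mask=nucleus_label_mask,
        membrane_band_mask=band_mask,
        true_membrane_fraction=fractions,
        tuft_flags=tuft_flags,
        debris_mask=debris_mask,
        puncta_mask=puncta_mask,
        planted_overlap_fraction=planted_overlap,
        seeds_rc=seeds,
        seed_spacing_px=cfg.seed_spacing_px,
        config=cfg,
    )
    return image, truth


def _apply_noise(channels, cfg: TissueConfig, rng):
    if cfg.noise_model == "none":
        return channels
    out = {}
    for name, ch in channels.items():
        x = ch.astype(np.float64)
        if cfg.noise_model in ("poisson", "poisson+gaussian"):
            lam = np.clip(x * cfg.photons_per_unit, 0, None)
            x = rng.poisson(lam).astype(np.float64) / cfg.photons_per_unit
        if cfg.noise_model in ("gaussian", "poisson+gaussian"):
            x = x + rng.normal(0.0, cfg.gaussian_noise_sigma, size=x.shape)
        out[name] = np.clip(x, 0, None).astype(np.float32)
    return out


def plant_coloc(
    image: MultiplexImage,
    truth: SyntheticGroundTruth,
    overlap: float,
    seed: int = 0,
    n_puncta_per_cell: int = 3,
    punctum_radius_px: int = 2,
    lysosome_intensity: float = 300.0,
):
    """Add a lysosome-puncta channel and plant an exact target/puncta overlap.

    Redistributes the target channel so that exactly ``overlap`` of its total
    intensity lies inside puncta (intended for pre-noise images). Returns a
    new image; ``truth.planted_overlap_fraction`` is set in place.
    """
    if not (0.0 <= overlap <= 1.0):
        raise ConfigurationError("overlap must lie in [0, 1]")
    target = image.get("target")
    rng = np.random.default_rng(seed)
    labels = truth.cell_label_mask
    puncta = truth.puncta_mask
    out = image.copy()
    if not puncta.any():
        interior = erode_labels(labels, truth.config.membrane_band_px)
        pix = np.flatnonzero(interior.ravel())
        n = truth.n_cells * n_puncta_per_cell
        if len(pix) == 0 or n == 0:
            raise ConfigurationError("no interior pixels to place puncta in")
        take = rng.choice(pix, size=min(n, len(pix)), replace=False)
        W = labels.shape[1]
        centers = [(p // W, p % W) for p in take]
        puncta = _paint_disks(labels.shape, centers, punctum_radius_px)
        truth.puncta_mask = puncta
    out.channels["lysosome"] = np.where(puncta, lysosome_intensity, 0.0).astype(
        np.float32
    )
    out.channels["target"] = _redistribute_target(
        target.astype(np.float64), puncta, labels > 0, overlap
    ).astype(np.float32)
    truth.planted_overlap_fraction = float(overlap)
    return out


def plant_tuft_distractors(
    image: MultiplexImage,
    truth: SyntheticGroundTruth,
    n_per_kind: Union[int, Sequence[int]] = 3,
    kinds: Sequence[str] = ("size", "location", "no-nucleus"),
    marker_intensity: Optional[float] = None,
    ok_radius_px: float = 3.0,
    small_radius_px: float = 1.0,
    seed: int = 0,
):
    """Paint tuft-marker blobs that each violate exactly one census filter.

    kinds
      ``size``       a well-placed, nucleus-overlapping blob below any sane
                     minimum area;
      ``location``   a well-sized, nucleus-overlapping blob on a cell that is
                     simultaneously covered by planted debris;
      ``no-nucleus`` a well-sized blob inside tissue placed to overlap no
                     nucleus at all.

    Appends rows to ``truth.distractors`` (kind, row, col, expected_reason)
    and returns the modified image (tuft channel is edited in place on a copy).
    """
    rng = np.random.default_rng(seed)
    cfg = truth.config
    if isinstance(n_per_kind, int):
        per_kind = [n_per_kind] * len(kinds)
    else:
        per_kind = list(n_per_kind)
        if len(per_kind) != len(kinds):
            raise ConfigurationError("n_per_kind sequence must match kinds")
    if marker_intensity is None:
        marker_intensity = cfg.tuft_marker_intensity
    labels = truth.cell_label_mask
    shape = labels.shape
    out = image.copy()
    tuft_ch = out.channels.get("tuft")
    if tuft_ch is None:
        tuft_ch = np.zeros(shape, dtype=np.float32)
    tuft_ch = tuft_ch.copy()

    nucleus_dt = ndimage.distance_transform_edt(~(truth.nucleus_label_mask > 0))
    # keep blob centres clear of the image border so disks are never clipped
    in_bounds = np.zeros(shape, dtype=bool)
    m = int(math.ceil(ok_radius_px)) + 1
    in_bounds[m:-m, m:-m] = True

    forbidden = list(np.nonzero(truth.tuft_flags)[0])
    if truth.distractors is not None and len(truth.distractors):
        prev = truth.distractors[["row", "col"]].to_numpy()
        tree = cKDTree(truth.seeds_rc)
        forbidden.extend(int(i) + 1 for i in tree.query(prev)[1])
    rows = []
    for kind, n_kind in zip(kinds, per_kind):
        # over-request hosts: a host without a nucleus-free spot is skipped
        candidates = _select_spaced_cells(
            truth.seeds_rc,
            rng,
            min(4 * n_kind, max(truth.n_cells - len(forbidden), n_kind)),
            1.15 * truth.seed_spacing_px,
            forbidden=forbidden,
            allow_partial=True,
        )
        hosts = []
        for lab in candidates:
            sr, sc = np.round(truth.seeds_rc[lab - 1]).astype(int)
            if not in_bounds[sr, sc]:
                continue
            if kind == "no-nucleus":
                cand = (truth.cell_label_mask == lab) & (
                    nucleus_dt > ok_radius_px + 0.5
                ) & in_bounds
                if not cand.any():
                    continue
            hosts.append(lab)
            if len(hosts) == n_kind:
                break
        if len(hosts) < n_kind:
            raise ConfigurationError(
                f"cannot place {n_kind} {kind!r} distractors"
            )
        forbidden.extend(hosts)
        for lab in hosts:
            seed_rc = np.round(truth.seeds_rc[lab - 1]).astype(int)
            if kind == "size":
                blob = _paint_disks(shape, [seed_rc], small_radius_px)
                center = seed_rc
                reason = "size"
            elif kind == "location":
                cell = labels == lab
                truth.debris_mask = truth.debris_mask | cell
                for name in ("nuclei", "membrane1", "membrane2"):
                    if name in out.channels:
                        out.channels[name] = np.where(
                            cell,
                            out.channels[name] + cfg.debris_intensity,
                            out.channels[name],
                        ).astype(np.float32)
                blob = _paint_disks(shape, [seed_rc], ok_radius_px) & (labels > 0)
                center = seed_rc
                reason = "location"
            elif kind == "no-nucleus":
                cand = (labels == lab) & (nucleus_dt > ok_radius_px + 0.5) & in_bounds
                pix = np.argwhere(cand)
                center = pix[rng.integers(len(pix))]
                blob = _paint_disks(shape, [center], ok_radius_px) & (labels > 0)
                blob &= ~(truth.nucleus_label_mask > 0)
                reason = "no-nucleus"
            else:
                raise ConfigurationError(f"unknown distractor kind {kind!r}")
            tuft_ch = np.where(blob, marker_intensity, tuft_ch).astype(np.float32)
            rows.append(
                {
                    "kind": kind,
                    "row": int(center[0]),
                    "col": int(center[1]),
                    "expected_reason": reason,
                }
            )
    out.channels["tuft"] = tuft_ch
    new = pd.DataFrame(rows)
    truth.distractors = (
        new if truth.distractors is None else pd.concat(
            [truth.distractors, new], ignore_index=True
        )
    )
    return out
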