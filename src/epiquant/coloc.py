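"""Pearson and Manders colocalization over ROIs with per-sample averaging.

Quantifies how much of a transporter channel sits in lysosomal structures:
Pearson's r over ROI pixels, and Manders' split coefficients
M1 = sum(A | B > t_B) / sum(A) and M2 symmetric. Thresholds come from the
configured method: ``bimodal`` (per-channel Otsu, the default stand-in for
the plugin-style auto threshold), ``costes`` (iterative regression
threshold), or ``none`` (t = 0, the exact contract for planted-overlap
fixtures). Per-sample results are the arithmetic mean over ROIs —
conventionally five representative regions per animal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .errors import DegenerateInputError, EpiquantError


@dataclass
class ColocResult:
    pearson_r: float
    manders_m1: float
    manders_m2: float
    threshold_a: float
    threshold_b: float
    n_pixels: int
    roi_id: Optional[str] = None


@dataclass
class SampleColoc:
    sample_id: str
    results: List[ColocResult]
    pearson_r: float
    manders_m1: float
    manders_m2: float


def _costes_thresholds(a: np.ndarray, b: np.ndarray) -> tuple:
    """Iterative regression thresholds: highest (t_a, t_b) on the regression
    line below which the two channels are uncorrelated."""
    slope, intercept = np.polyfit(a, b, 1)
    t_a = float(a.max())
    step = (a.max() - a.min()) / 200.0 or 1.0
    while t_a > a.min():
        t_b = slope * t_a + intercept
        below = (a < t_a) & (b < t_b)
        if below.sum() > 2:
            sa, sb = a[below], b[below]
            if sa.std() > 0 and sb.std() > 0:
                r = float(np.corrcoef(sa, sb)[0, 1])
                if r <= 0:
                    break
        t_a -= step
    return float(t_a), float(slope * t_a + intercept)


def coloc_pair(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    roi_mask: Optional[np.ndarray] = None,
    threshold_method: str = "bimodal",
    roi_id: Optional[str] = None,
) -> ColocResult:
    """Colocalization coefficients of two channels over one ROI.

    Raises on shape mismatch, empty ROI, or a channel that is constant
    within the ROI (Pearson undefined).
    """
    a = np.asarray(channel_a, dtype=np.float64)
    b = np.asarray(channel_b, dtype=np.float64)
    if a.shape != b.shape:
        raise EpiquantError(f"channel shapes differ: {a.shape} vs {b.shape}")
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        if roi_mask.shape != a.shape:
            raise EpiquantError("ROI mask shape differs from channels")
        a, b = a[roi_mask], b[roi_mask]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size == 0:
        raise EpiquantError("empty ROI")
    if a.std() == 0 or b.std() == 0:
        raise DegenerateInputError("constant channel within ROI: Pearson undefined")

    pearson = float(np.corrcoef(a, b)[0, 1])

    if threshold_method == "none":
        t_a = t_b = 0.0
    elif threshold_method == "bimodal":
        t_a = float(threshold_otsu(a))
        t_b = float(threshold_otsu(b))
    elif threshold_method == "costes":
        t_a, t_b = _costes_thresholds(a, b)
    else:
        raise EpiquantError(f"unknown threshold method {threshold_method!r}")

    sum_a, sum_b = a.sum(), b.sum()
    m1 = float(a[b > t_b].sum() / sum_a) if sum_a > 0 else 0.0
    m2 = float(b[a > t_a].sum() / sum_b) if sum_b > 0 else 0.0
    return ColocResult(
        pearson_r=pearson,
        manders_m1=m1,
        manders_m2=m2,
        threshold_a=t_a,
        threshold_b=t_b,
        n_pixels=int(a.size),
        roi_id=roi_id,
    )


def average_sample(
    results: Sequence[ColocResult],
    sample_id: str = "sample",
    expected_n: int = 5,
) -> SampleColoc:
    """Arithmetic per-sample mean over ROI results.

    Warns (never errors) when the ROI count differs from the conventional
    ``expected_n``.
    """
    results = list(results)
    if not results:
        raise EpiquantError("cannot average an empty result list")
    if len(results) != expected_n:
        warnings.warn(
            f"sample {sample_id!r}: {len(results)} ROIs averaged "
            f"(convention is {expected_n})",
            stacklevel=2,
        )
    return SampleColoc(
        sample_id=sample_id,
        results=results,
        pearson_r=float(np.mean([r.pearson_r for r in results])),
        manders_m1=float(np.mean([r.manders_m1 for r in results])),
        manders_m2=float(np.mean([r.manders_m2 for r in results])),
    )


def grid_rois(shape: tuple, n_rois: int = 5) -> List[np.ndarray]:
    """Split a slide into ``n_rois`` vertical strips as default ROI masks."""
    H, W = shape
    edges = np.linspace(0, W, n_rois + 1).astype(int)
    out = []
    for i in range(n_rois):
        m = np.zeros(shape, dtype=bool)
        m[:, edges[i] : edges[i + 1]] = True
        out.append(m)
    return out
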