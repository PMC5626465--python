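"""Quantitative evaluation of perfusion-deficit maps.

Implements the evaluation toolkit used to compare perfusion maps:

* contrast-to-noise ratio, CNR = |mean(lesion) - mean(normal)| / SD(normal),
  and effective CNR = CNR x sqrt(number of lesion voxels) — the Rose
  detectability scaling (a larger lesion needs less per-voxel contrast to be
  seen);
* a majority-vote "unbiased" lesion mask (voxel in >= ``min_votes`` of the
  supplied reader masks) used as a map-neutral region for CNR;
* lesion volumes (cm^3), spatial-overlap decomposition of two masks relative
  to their union, Bland-Altman inter-rater agreement, and Pearson volume
  correlation.

Standard deviations are sample (n-1) throughout; set ``ddof=0`` where a
population convention is preferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import MetricError, ShapeError
from .tsp_core import pearson_r

__all__ = [
    "CnrReport",
    "OverlapReport",
    "BlandAltmanReport",
    "cnr",
    "unbiased_lesion",
    "lesion_volume",
    "overlap_stats",
    "bland_altman",
    "volume_correlation",
]


@dataclass
class CnrReport:
    """CNR of one map over one lesion/normal-tissue pair."""

    cnr: float
    effective_cnr: float
    n_lesion_voxels: int
    lesion_volume_cm3: float
    mean_lesion: float
    mean_normal: float
    sd_normal: float


@dataclass
class OverlapReport:
    """Spatial decomposition of two lesion masks relative to their union."""

    overlap_volume_cm3: float
    only_in_a_cm3: float
    only_in_b_cm3: float
    percent_overlap: float
    percent_only_a: float
    percent_only_b: float


@dataclass
class BlandAltmanReport:
    """Bland-Altman agreement between two paired measurement lists."""

    bias: float
    loa_lower: float
    loa_upper: float
    means: np.ndarray
    differences: np.ndarray


def _map_values(perfusion_map) -> tuple[np.ndarray, np.ndarray]:
    """Accept a SimilarityMap/TtpMap (values + defined) or a bare array."""
    values = getattr(perfusion_map, "values", None)
    if values is None:
        values = np.asarray(perfusion_map, dtype=np.float64)
        return values, np.isfinite(values)
    return np.asarray(values, dtype=np.float64), np.asarray(perfusion_map.defined, dtype=bool)


def cnr(perfusion_map, lesion: np.ndarray, healthy: np.ndarray,
        voxel_dims=(0.9375, 0.9375, 7.0), ddof: int = 1) -> CnrReport:
    """Contrast-to-noise ratio of a map between lesion and healthy tissue.

    CNR = |mean(lesion) - mean(normal)| / SD(normal); effective CNR scales
    by sqrt(n lesion voxels).  Lesion and healthy sets must be disjoint and
    non-empty; only map-defined voxels enter the statistics.  A zero healthy
    SD yields NaN (undefined-CNR flag), not an exception.
    """
    values, defined = _map_values(perfusion_map)
    lesion = np.asarray(lesion, dtype=bool)
    healthy = np.asarray(healthy, dtype=bool)
    if lesion.shape != values.shape or healthy.shape != values.shape:
        raise ShapeError("lesion/healthy masks must match the map grid")
    if np.logical_and(lesion, healthy).any():
        raise MetricError("lesion and healthy masks overlap")
    lesion_def = lesion & defined
    healthy_def = healthy & defined
    if not lesion_def.any() or not healthy_def.any():
        raise MetricError("lesion and healthy sets must both contain defined map voxels")

    n_lesion = int(lesion_def.sum())
    mean_lesion = float(values[lesion_def].mean())
    mean_normal = float(values[healthy_def].mean())
    sd_normal = float(values[healthy_def].std(ddof=ddof))
    c = abs(mean_lesion - mean_normal) / sd_normal if sd_normal > 0 else float("nan")
    return CnrReport(cnr=c,
                     effective_cnr=c * float(np.sqrt(n_lesion)),
                     n_lesion_voxels=n_lesion,
                     lesion_volume_cm3=lesion_volume(lesion_def, voxel_dims),
                     mean_lesion=mean_lesion, mean_normal=mean_normal,
                     sd_normal=sd_normal)


def unbiased_lesion(masks, min_votes: int = 4) -> np.ndarray:
    """Majority-vote lesion: voxel included iff present in >= ``min_votes``
    of the input masks.  With min_votes = 1 this is the union; with
    min_votes = len(masks), the intersection."""
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if len(masks) < min_votes:
        raise MetricError(f"need at least min_votes={min_votes} masks, got {len(masks)}")
    if min_votes < 1:
        raise MetricError("min_votes must be >= 1")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ShapeError("all masks must share one grid")
    votes = np.sum(masks, axis=0)
    return votes >= min_votes


def lesion_volume(mask: np.ndarray, voxel_dims=(0.9375, 0.9375, 7.0)) -> float:
    """Mask volume in cm^3: voxel count x voxel volume."""
    if any(d <= 0 for d in voxel_dims):
        raise MetricError(f"voxel dimensions must be positive: {voxel_dims}")
    n = int(np.asarray(mask, dtype=bool).sum())
    return n * float(np.prod(voxel_dims)) / 1000.0


def overlap_stats(a: np.ndarray, b: np.ndarray,
                  voxel_dims=(0.9375, 0.9375, 7.0)) -> OverlapReport:
    """Intersection / A-only / B-only volumes and their percentages of the
    union of the two masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ShapeError("masks must share one grid")
    inter = a & b
    only_a = a & ~b
    only_b = b & ~a
    union = int(a.sum() + b.sum() - inter.sum())
    if union == 0:
        raise MetricError("both masks are empty; overlap undefined")
    return OverlapReport(
        overlap_volume_cm3=lesion_volume(inter, voxel_dims),
        only_in_a_cm3=lesion_volume(only_a, voxel_dims),
        only_in_b_cm3=lesion_volume(only_b, voxel_dims),
        percent_overlap=100.0 * int(inter.sum()) / union,
        percent_only_a=100.0 * int(only_a.sum()) / union,
        percent_only_b=100.0 * int(only_b.sum()) / union,
    )


def bland_altman(volumes_reader1, volumes_reader2, loa_factor: float = 1.96
                 ) -> BlandAltmanReport:
    """Bland-Altman agreement: bias = mean paired difference; 95% limits of
    agreement = bias +/- 1.96 x sample SD of the differences."""
    v1 = np.asarray(volumes_reader1, dtype=np.float64)
    v2 = np.asarray(volumes_reader2, dtype=np.float64)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise MetricError("need two equal-length 1D lists of paired volumes")
    if v1.size < 2:
        raise MetricError("Bland-Altman needs n >= 2 pairs (SD undefined for n = 1)")
    diffs = v1 - v2
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanReport(bias=bias,
                             loa_lower=bias - loa_factor * sd,
                             loa_upper=bias + loa_factor * sd,
                             means=(v1 + v2) / 2.0,
                             differences=diffs)


def volume_correlation(volumes_a, volumes_b) -> tuple[float, float]:
    """Pearson correlation of two paired volume lists with a two-sided p
    from the t distribution on n - 2 degrees of freedom."""
    a = np.asarray(volumes_a, dtype=np.float64)
    b = np.asarray(volumes_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise MetricError("need two equal-length 1D lists")
    if a.size < 3:
        raise MetricError("correlation needs n >= 3 pairs")
    r = pearson_r(a, b)
    if np.isnan(r):
        return float("nan"), float("nan")
    n = a.size
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)
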