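"""Temporal similarity perfusion (TSP) mapping.

The method is model-free: instead of fitting a kinetic model or deconvolving
an arterial input function, every brain voxel's signal-intensity time-series
is scored by its Pearson product-moment correlation (R) against a
healthy-tissue reference series.  Healthy tissue has an essentially uniform
bolus passage, so healthy voxels score near 1; under-perfused tissue has a
delayed, dispersed and/or decreased passage and scores low or negative.
Because Pearson's R is invariant to positive affine transforms of either
series, the maps are intrinsically standardised — no windowing is needed to
compare across patients.

Two entry points mirror the two modes of use:

* :func:`seed_similarity_map` — reference is a single seed voxel's series
  (the interactive, "click a voxel" mode); fast enough to recompute a whole
  map per cursor move.
* :func:`automated_tsp` — unattended iterative mode: start from the mean
  series of all brain voxels, correlate, keep voxels with R above a
  threshold (default 0.6), re-average and re-correlate; repeated twice by
  default.  The final map is the TSP map.

:func:`segment_lesion` turns a map into a binary perfusion-deficit mask by
thresholding and connected-component size filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import IterationError, ParameterError, SeedError, ShapeError
from .ingest import BrainMask, DynamicSeries

__all__ = [
    "SimilarityMap",
    "ReferenceSeries",
    "pearson_r",
    "seed_similarity_map",
    "automated_tsp",
    "threshold_sweep",
    "segment_lesion",
    "dice",
]


@dataclass
class SimilarityMap:
    """Per-voxel Pearson's R against a reference series.

    ``values`` holds NaN outside ``defined``; a voxel is undefined when it
    lies outside the brain mask or its time-series has zero variance (R does
    not exist there — it is flagged, never silently set to 0).
    """

    values: np.ndarray
    defined: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.defined = np.asarray(self.defined, dtype=bool)
        if self.values.shape != self.defined.shape:
            raise ShapeError("values and defined-mask shapes differ")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class ReferenceSeries:
    """Mean healthy-tissue signal per dynamic plus the number of voxels that
    contributed to the average."""

    series: np.ndarray
    n_voxels: int

    def __post_init__(self):
        self.series = np.asarray(self.series, dtype=np.float64)
        if self.series.ndim != 1:
            raise ShapeError("reference series must be 1D")


def pearson_r(series_a, series_b) -> float:
    """Pearson product-moment correlation of two equal-length series.

    Returns NaN (the undefined-result flag) when either series has zero
    variance; raises :class:`ShapeError` on length mismatch or length < 3.
    """
    a = np.asarray(series_a, dtype=np.float64).ravel()
    b = np.asarray(series_b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ShapeError(f"series lengths differ: {a.size} vs {b.size}")
    if a.size < 3:
        raise ShapeError(f"need at least 3 samples, got {a.size}")
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da @ da) * (db @ db))
    if denom == 0:
        return float("nan")
    return float(np.clip((da @ db) / denom, -1.0, 1.0))


def _correlate_against(data2d: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Vectorised Pearson R of every row of ``data2d`` against ``reference``.

    Rows with zero variance get NaN.  A zero-variance reference makes every
    value NaN.
    """
    ref = reference - reference.mean()
    ref_norm = np.sqrt(ref @ ref)
    centred = data2d - data2d.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", centred, centred))
    out = np.full(data2d.shape[0], np.nan)
    if ref_norm == 0:
        return out
    ok = norms > 0
    out[ok] = (centred[ok] @ ref) / (norms[ok] * ref_norm)
    np.clip(out, -1.0, 1.0, out=out)
    return out


def _masked_timeseries(series: DynamicSeries, mask: BrainMask) -> np.ndarray:
    if mask.shape != series.shape:
        raise ShapeError(f"mask shape {mask.shape} != series grid {series.shape}")
    return series.data[mask.mask]


def _to_map(values_1d: np.ndarray, mask: BrainMask, provenance: dict) -> SimilarityMap:
    values = np.full(mask.shape, np.nan)
    values[mask.mask] = values_1d
    defined = np.zeros(mask.shape, dtype=bool)
    defined[mask.mask] = np.isfinite(values_1d)
    return SimilarityMap(values=values, defined=defined, provenance=provenance)


def seed_similarity_map(series: DynamicSeries, mask: BrainMask,
                        seed: tuple[int, int, int]) -> SimilarityMap:
    """Correlation map of every brain voxel against one seed voxel's series.

    This is the interactive mode: a whole-brain map at the standard 80x80x20
    grid recomputes in well under a second, so the map can follow the cursor.
    """
    seed = tuple(int(i) for i in seed)
    if len(seed) != 3 or not all(0 <= i < s for i, s in zip(seed, mask.shape)):
        raise SeedError(f"seed {seed} outside the grid {mask.shape}")
    if not mask.mask[seed]:
        raise SeedError(f"seed {seed} is outside the brain mask")
    seed_series = series.data[seed]
    if np.ptp(seed_series) == 0:
        raise SeedError(f"seed {seed} has a constant time-series; R undefined")
    data2d = _masked_timeseries(series, mask)
    values = _correlate_against(data2d, seed_series)
    return _to_map(values, mask, {"mode": "seed", "seed": seed})


def automated_tsp(series: DynamicSeries, mask: BrainMask, threshold: float = 0.6,
                  refinement_repeats: int = 2
                  ) -> tuple[SimilarityMap, list[ReferenceSeries]]:
    """Unattended iterative TSP map.

    Iteration 0 takes the mean signal series over all brain-mask voxels as
    the healthy-tissue reference and correlates every voxel against it.
    Each of the ``refinement_repeats`` refinements then re-thresholds the
    *current full-brain map* at ``R > threshold``, recomputes the reference
    as the mean over the surviving voxels, and recomputes the map.  Voxels
    with zero temporal variance never contribute to a reference.

    Returns the final map and the reference history (initial + one entry per
    refinement, each with its contributing voxel count).
    """
    if not 0 < threshold < 1:
        raise ParameterError(f"threshold must be in (0, 1), got {threshold}")
    if refinement_repeats < 0:
        raise ParameterError("refinement_repeats must be >= 0")
    if mask.n_voxels == 0:
        raise IterationError("brain mask is empty", iteration=0, threshold=threshold)

    data2d = _masked_timeseries(series, mask)
    variable = np.ptp(data2d, axis=1) > 0
    if not variable.any():
        raise IterationError("no voxel in the mask has temporal variance",
                             iteration=0, threshold=threshold)

    contributing = variable
    history: list[ReferenceSeries] = []
    values = None
    for iteration in range(refinement_repeats + 1):
        if iteration > 0:
            contributing = variable & np.isfinite(values) & (values > threshold)
            if not contributing.any():
                raise IterationError(
                    f"refinement {iteration}: no voxel exceeds R > {threshold}",
                    iteration=iteration, threshold=threshold)
        reference = data2d[contributing].mean(axis=0)
        history.append(ReferenceSeries(series=reference, n_voxels=int(contributing.sum())))
        values = _correlate_against(data2d, reference)

    provenance = {"mode": "iterative", "threshold": threshold,
                  "refinement_repeats": refinement_repeats,
                  "n_contributing": [h.n_voxels for h in history]}
    return _to_map(values, mask, provenance), history


def threshold_sweep(series: DynamicSeries, mask: BrainMask,
                    thresholds=(0.5, 0.6, 0.7, 0.8, 0.9),
                    lesion_mask: np.ndarray | None = None,
                    refinement_repeats: int = 2):
    """Automated TSP maps across a set of refinement thresholds.

    Returns ``(maps, stats)`` where ``maps`` is ``{threshold: SimilarityMap}``
    and ``stats`` a list of dicts per threshold.  If ``lesion_mask`` is
    given, each dict carries the mean map value inside the lesion, inside
    healthy tissue (brain minus lesion), and their difference — the
    separation statistics used to assess threshold robustness.
    """
    thresholds = sorted(float(t) for t in thresholds)
    for t in thresholds:
        if not 0 < t < 1:
            raise ParameterError(f"threshold {t} outside (0, 1)")
    if lesion_mask is not None:
        lesion_mask = np.asarray(lesion_mask, dtype=bool)
        if lesion_mask.shape != mask.shape:
            raise ShapeError("lesion mask grid differs from brain mask")

    maps: dict[float, SimilarityMap] = {}
    stats: list[dict] = []
    for t in thresholds:
        smap, history = automated_tsp(series, mask, threshold=t,
                                      refinement_repeats=refinement_repeats)
        maps[t] = smap
        row = {"threshold": t, "n_contributing_final": history[-1].n_voxels}
        if lesion_mask is not None:
            in_lesion = smap.defined & lesion_mask
            in_healthy = smap.defined & mask.mask & ~lesion_mask
            row["mean_lesion"] = float(smap.values[in_lesion].mean()) if in_lesion.any() else float("nan")
            row["mean_healthy"] = float(smap.values[in_healthy].mean()) if in_healthy.any() else float("nan")
            row["difference"] = row["mean_healthy"] - row["mean_lesion"]
        stats.append(row)
    return maps, stats


def segment_lesion(smap: SimilarityMap, cutoff: float = 0.6,
                   min_cluster_volume_mm3: float = 1000.0,
                   voxel_dims=(0.9375, 0.9375, 7.0)) -> np.ndarray:
    """Binary perfusion-deficit mask from a similarity map.

    Defined voxels with R below ``cutoff`` are grouped by 26-connectivity;
    clusters smaller than ``min_cluster_volume_mm3`` are discarded as noise.
    Undefined voxels (masked dropout, not perfusion signal) are never part
    of a lesion.  An empty result is a valid "no deficit detected" outcome.
    """
    if not -1 <= cutoff <= 1:
        raise ParameterError(f"cutoff must be in [-1, 1], got {cutoff}")
    candidate = smap.defined & (smap.values < cutoff)
    if not candidate.any():
        return np.zeros(smap.shape, dtype=bool)
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labels, n = ndimage.label(candidate, structure=structure)
    voxel_vol = float(np.prod(voxel_dims))
    min_voxels = min_cluster_volume_mm3 / voxel_vol
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= min_voxels)
    keep = keep[keep != 0]
    return np.isin(labels, keep)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient of two binary masks (1 if both empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ShapeError("mask shapes differ")
    total = a.sum() + b.sum()
    if total == 0:
        return 1.0
    return 2.0 * float(np.logical_and(a, b).sum()) / float(total)
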