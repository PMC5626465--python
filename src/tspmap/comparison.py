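"""Time-to-peak (TTP) comparator maps.

TTP is the simplest conventional perfusion parameter: the time at which a
voxel's bolus-passage signal reaches its minimum (i.e. peak contrast
concentration).  It is computed here directly from the raw series so that
TSP maps can be benchmarked against a traditional map on the same phantom
data.  No deconvolution (MTT/CBF/Tmax) is performed — those require an
arterial input function, which the similarity approach deliberately avoids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError, ShapeError
from .ingest import BrainMask, DynamicSeries

__all__ = ["TtpMap", "ttp_map"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class TtpMap:
    """Per-voxel time-to-peak in seconds; NaN outside ``defined``."""

    values: np.ndarray
    defined: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.defined = np.asarray(self.defined, dtype=bool)
        if self.values.shape != self.defined.shape:
            raise ShapeError("values and defined-mask shapes differ")

    @property
    def shape(self):
        return self.values.shape


def ttp_map(series: DynamicSeries, mask: BrainMask, smoothing_fwhm: float = 0.0) -> TtpMap:
    """TTP = TR x argmin over t of the signal, per brain-mask voxel.

    Ties are broken toward the earliest dynamic (so a constant series maps
    to 0 s).  Unsmoothed values are therefore quantised to multiples of TR.
    ``smoothing_fwhm`` (mm) optionally applies isotropic Gaussian smoothing
    to the resulting map (not to the raw series), restricted to the mask by
    normalised convolution so lesion values do not bleed into background.
    """
    if smoothing_fwhm < 0:
        raise ParameterError("smoothing_fwhm must be >= 0")
    if mask.shape != series.shape:
        raise ShapeError(f"mask shape {mask.shape} != series grid {series.shape}")

    argmin = np.argmin(series.data, axis=3).astype(np.float64)
    values = argmin * series.tr
    defined = mask.mask.copy()
    values[~defined] = np.nan

    if smoothing_fwhm > 0:
        sigma_vox = [smoothing_fwhm * _FWHM_TO_SIGMA / d for d in series.voxel_dims]
        filled = np.where(defined, values, 0.0)
        smooth = ndimage.gaussian_filter(filled, sigma_vox)
        weight = ndimage.gaussian_filter(defined.astype(np.float64), sigma_vox)
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(defined, smooth / weight, np.nan)

    return TtpMap(values=values, defined=defined)
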