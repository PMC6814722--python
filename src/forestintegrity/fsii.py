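"""Forest Structural Integrity Index (FSII): SCI under human pressure.

FSII = SCI / human-pressure weight, where the weight classes the human
footprint score (HFP, a 0-50 cumulative pressure index): Low pressure
(weight 1) for HFP < 4, Medium (5) for 4 <= HFP <= 15, High (10) for
HFP > 15. The attainable range is therefore 0.1 (SCI 1 under high
pressure) to 18 (SCI 18 under low pressure); high values flag
structurally complex forest under low human pressure.

Note: the published weight table's row for SCI 1 lists 0.2 under low
pressure where the formula gives 1.0; this package follows the formula
(see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats as _stats

from forestintegrity.grids import (
    GridSpec, RasterLayer, NODATA_FLOAT, resample_nearest,
)

__all__ = [
    "PressureClass", "PressureThresholds",
    "pressure_class", "fsii_value", "compute_fsii",
]


class PressureClass(Enum):
    """Human-pressure class with its divisor weight."""
    LOW = 1
    MED = 5
    HIGH = 10

    @property
    def weight(self) -> int:
        return self.value


@dataclass(frozen=True)
class PressureThresholds:
    """Cutpoints and weights for classing the human footprint score.

    ``low_below`` and ``high_above`` bound the medium class inclusively:
    HFP < low_below is low pressure, low_below <= HFP <= high_above is
    medium, HFP > high_above is high.
    """

    low_below: float = 4.0
    high_above: float = 15.0
    weights: tuple[int, int, int] = (1, 5, 10)


DEFAULT_THRESHOLDS = PressureThresholds()


def pressure_class(hfp: float,
                   thresholds: PressureThresholds = DEFAULT_THRESHOLDS
                   ) -> PressureClass | None:
    """Class a human footprint score; ``None`` for negative or non-finite."""
    if hfp is None or not np.isfinite(hfp) or hfp < 0:
        return None
    if hfp < thresholds.low_below:
        return PressureClass.LOW
    if hfp <= thresholds.high_above:
        return PressureClass.MED
    return PressureClass.HIGH


def fsii_value(sci: int, p: PressureClass) -> float:
    """FSII for one cell: SCI divided by the pressure weight."""
    if not 1 <= sci <= 18 or sci != int(sci):
        raise ValueError(f"SCI must be an integer in 1..18, got {sci}")
    return sci / p.weight


def _pressure_weights(hfp: np.ndarray, mask: np.ndarray,
                      thresholds: PressureThresholds) -> np.ndarray:
    w_low, w_med, w_high = thresholds.weights
    w = np.full(hfp.shape, np.nan)
    ok = mask & np.isfinite(hfp) & (hfp >= 0)
    w[ok & (hfp < thresholds.low_below)] = w_low
    w[ok & (hfp >= thresholds.low_below) & (hfp <= thresholds.high_above)] = w_med
    w[ok & (hfp > thresholds.high_above)] = w_high
    return w


def _modal_aggregate(sci: RasterLayer, target: GridSpec) -> RasterLayer:
    """Modal SCI value of the fine cells whose centers fall in each coarse cell."""
    xs, ys = sci.spec.cell_centers()
    xx, yy = np.meshgrid(xs, ys)
    row, col = target.cell_of(xx, yy)
    inside = target.contains(row, col) & sci.mask
    out = np.full(target.shape, sci.nodata, dtype=sci.values.dtype)
    flat = row[inside] * target.n_cols + col[inside]
    vals = sci.values[inside]
    for cell in np.unique(flat):
        sel = vals[flat == cell]
        out[cell // target.n_cols, cell % target.n_cols] = _stats.mode(sel).mode
    return RasterLayer(target, out, sci.nodata, "sci")


def compute_fsii(sci_layer: RasterLayer, hfp_layer: RasterLayer,
                 thresholds: PressureThresholds = DEFAULT_THRESHOLDS,
                 at_hfp_resolution: bool = False,
                 nodata: float = NODATA_FLOAT) -> RasterLayer:
    """Overlay human pressure on SCI.

    By default the (typically ~1 km) HFP layer is upsampled
    nearest-neighbor onto the 30 m SCI grid and the division is cell-wise
    at 30 m. With ``at_hfp_resolution=True`` the SCI is instead aggregated
    (modal value) to the HFP grid, for the coarse-resolution reading of
    the index. Nodata in either input propagates.
    """
    if sci_layer.spec.crs_id != hfp_layer.spec.crs_id:
        raise ValueError("SCI and HFP layers must share a CRS")

    if at_hfp_resolution:
        sci_layer = _modal_aggregate(sci_layer, hfp_layer.spec)
        hfp = hfp_layer
    elif hfp_layer.spec == sci_layer.spec:
        hfp = hfp_layer
    else:
        hfp = resample_nearest(hfp_layer, sci_layer.spec)

    w = _pressure_weights(hfp.values.astype(float), hfp.mask, thresholds)
    sci_ok = sci_layer.mask & (sci_layer.values >= 1) & (sci_layer.values <= 18)
    ok = sci_ok & np.isfinite(w)
    out = np.full(sci_layer.spec.shape, nodata, dtype=float)
    out[ok] = sci_layer.values[ok].astype(float) / w[ok]
    return RasterLayer(sci_layer.spec, out, nodata, "fsii")
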