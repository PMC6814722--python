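"""Forest Structural Condition Index (SCI) classification.

The SCI scores a 30 m forest pixel 1..18 from three co-registered layers:
percent tree cover (reference 2010), canopy height in meters (reference
2012), and the year of the most recent stand-replacing loss encoded as
0 (none since 2000) or 1..17 (calendar year 2000 + code). Weight 1 marks
recently disturbed, open-canopy, or short stands; 18 marks tall,
closed-canopy stands with no recorded loss.

Boundary conventions follow the published conditional-mask formulation:
cover < 25 is the masked (weight 1) class, so exactly 25% is forested;
height <= 5 m is the shortest class; interior class upper bounds are
inclusive (a 15 m stand is in the 5-15 m class, a 20 m stand in 15-20 m).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from forestintegrity.grids import LayerStack, RasterLayer, NODATA_BYTE

__all__ = [
    "CoverClass", "HeightClass", "LossEpoch", "SCIWeightTable",
    "classify_cover", "classify_height", "classify_loss",
    "sci_weight", "compute_sci", "DEFAULT_WEIGHTS",
]


class CoverClass(Enum):
    """Canopy-cover percentage class."""
    BELOW25 = "BELOW25"    # < 25 %
    C25_75 = "C25_75"      # 25-75 %
    C75_95 = "C75_95"      # > 75-95 %
    ABOVE95 = "ABOVE95"    # > 95 %


class HeightClass(Enum):
    """Canopy-height class in meters."""
    H0_5 = "H0_5"          # 0-5 m
    H5_15 = "H5_15"        # > 5-15 m
    H15_20 = "H15_20"      # > 15-20 m
    H20PLUS = "H20PLUS"    # > 20 m


class LossEpoch(Enum):
    """Time-since-loss epoch from the loss-year code."""
    NONE = "NONE"          # code 0: no loss since 2000
    MID = "MID"            # codes 1-12: loss 2001-2012
    RECENT = "RECENT"      # codes 13-17: loss 2013-2017


_COVER_ORDER = [CoverClass.C25_75, CoverClass.C75_95, CoverClass.ABOVE95]
_HEIGHT_ORDER = [HeightClass.H5_15, HeightClass.H15_20, HeightClass.H20PLUS]


def _default_weights() -> dict[tuple[LossEpoch, HeightClass, CoverClass], int]:
    w: dict[tuple[LossEpoch, HeightClass, CoverClass], int] = {}
    for epoch in LossEpoch:
        for h in HeightClass:
            for c in CoverClass:
                w[(epoch, h, c)] = 1
    # weights climb 2..10 (loss 2001-2012) and 10..18 (no loss) across the
    # nine tall/closed combinations, ordered by height then cover class
    for base, epoch in ((1, LossEpoch.MID), (9, LossEpoch.NONE)):
        k = base
        for h in _HEIGHT_ORDER:
            for c in _COVER_ORDER:
                k += 1
                w[(epoch, h, c)] = k
    return w


@dataclass
class SCIWeightTable:
    """The (loss epoch, height class, cover class) -> 1..18 lookup.

    The default table assigns weight 1 to any pixel with recent loss
    (2013-2017), cover below 25 %, or height at most 5 m, and otherwise
    increases with height class, cover class, and time since loss.
    Users can export, edit, and reload the table as CSV to re-weight.
    """

    weight: dict[tuple[LossEpoch, HeightClass, CoverClass], int] = field(
        default_factory=_default_weights)

    def __call__(self, epoch: LossEpoch, h: HeightClass, c: CoverClass) -> int:
        return self.weight[(epoch, h, c)]

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["loss_epoch", "height_class", "cover_class", "weight"])
            for (e, h, c), v in sorted(
                    self.weight.items(),
                    key=lambda kv: (kv[0][0].value, kv[0][1].value, kv[0][2].value)):
                w.writerow([e.value, h.value, c.value, v])

    @classmethod
    def from_csv(cls, path) -> "SCIWeightTable":
        weights: dict[tuple[LossEpoch, HeightClass, CoverClass], int] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                key = (LossEpoch(row["loss_epoch"]),
                       HeightClass(row["height_class"]),
                       CoverClass(row["cover_class"]))
                weights[key] = int(row["weight"])
        missing = {(e, h, c) for e in LossEpoch for h in HeightClass
                   for c in CoverClass} - set(weights)
        if missing:
            raise ValueError(f"weight table incomplete: {len(missing)} cells missing")
        return cls(weights)


DEFAULT_WEIGHTS = SCIWeightTable()


def classify_cover(cover_pct: float) -> CoverClass | None:
    """Class of a canopy-cover percentage; ``None`` for out-of-range input."""
    if cover_pct is None or not np.isfinite(cover_pct):
        return None
    if not 0 <= cover_pct <= 100:
        return None
    if cover_pct < 25:
        return CoverClass.BELOW25
    if cover_pct <= 75:
        return CoverClass.C25_75
    if cover_pct <= 95:
        return CoverClass.C75_95
    return CoverClass.ABOVE95


def classify_height(height_m: float) -> HeightClass | None:
    """Class of a canopy height in meters; ``None`` for negative input."""
    if height_m is None or not np.isfinite(height_m) or height_m < 0:
        return None
    if height_m <= 5:
        return HeightClass.H0_5
    if height_m <= 15:
        return HeightClass.H5_15
    if height_m <= 20:
        return HeightClass.H15_20
    return HeightClass.H20PLUS


def classify_loss(code: int) -> LossEpoch | None:
    """Epoch of a loss-year code 0..17; ``None`` outside that range."""
    if code is None or not np.isfinite(code) or code != int(code):
        return None
    code = int(code)
    if code == 0:
        return LossEpoch.NONE
    if 1 <= code <= 12:
        return LossEpoch.MID
    if 13 <= code <= 17:
        return LossEpoch.RECENT
    return None


def sci_weight(epoch: LossEpoch, h: HeightClass, c: CoverClass,
               table: SCIWeightTable = DEFAULT_WEIGHTS) -> int:
    """SCI weight 1..18 for a (loss epoch, height class, cover class) triple."""
    return table(epoch, h, c)


def _cover_index(cover: np.ndarray) -> np.ndarray:
    """0=BELOW25, 1=C25_75, 2=C75_95, 3=ABOVE95, -1 invalid."""
    idx = np.full(cover.shape, -1, dtype=np.int8)
    ok = np.isfinite(cover) & (cover >= 0) & (cover <= 100)
    idx[ok & (cover < 25)] = 0
    idx[ok & (cover >= 25) & (cover <= 75)] = 1
    idx[ok & (cover > 75) & (cover <= 95)] = 2
    idx[ok & (cover > 95)] = 3
    return idx


def _height_index(height: np.ndarray) -> np.ndarray:
    idx = np.full(height.shape, -1, dtype=np.int8)
    ok = np.isfinite(height) & (height >= 0)
    idx[ok & (height <= 5)] = 0
    idx[ok & (height > 5) & (height <= 15)] = 1
    idx[ok & (height > 15) & (height <= 20)] = 2
    idx[ok & (height > 20)] = 3
    return idx


def _epoch_index(loss: np.ndarray) -> np.ndarray:
    """0=NONE, 1=MID, 2=RECENT, -1 invalid."""
    idx = np.full(loss.shape, -1, dtype=np.int8)
    ok = np.isfinite(loss) & (loss == np.floor(loss))
    idx[ok & (loss == 0)] = 0
    idx[ok & (loss >= 1) & (loss <= 12)] = 1
    idx[ok & (loss >= 13) & (loss <= 17)] = 2
    return idx


_EPOCHS = [LossEpoch.NONE, LossEpoch.MID, LossEpoch.RECENT]
_HEIGHTS = [HeightClass.H0_5, HeightClass.H5_15, HeightClass.H15_20,
            HeightClass.H20PLUS]
_COVERS = [CoverClass.BELOW25, CoverClass.C25_75, CoverClass.C75_95,
           CoverClass.ABOVE95]


def compute_sci(stack: LayerStack,
                table: SCIWeightTable = DEFAULT_WEIGHTS,
                nodata: int = NODATA_BYTE) -> RasterLayer:
    """Classify every cell of an aligned cover/height/loss stack to SCI 1..18.

    Any cell with nodata or out-of-range input in any layer is nodata in
    the output.
    """
    cover = np.where(stack.cover.mask, stack.cover.values, np.nan).astype(float)
    height = np.where(stack.height.mask, stack.height.values, np.nan).astype(float)
    loss = np.where(stack.loss.mask, stack.loss.values, np.nan).astype(float)

    ci = _cover_index(cover)
    hi = _height_index(height)
    ei = _epoch_index(loss)

    lut = np.zeros((3, 4, 4), dtype=np.uint8)
    for a, epoch in enumerate(_EPOCHS):
        for b, h in enumerate(_HEIGHTS):
            for c, cov in enumerate(_COVERS):
                lut[a, b, c] = table(epoch, h, cov)

    valid = (ci >= 0) & (hi >= 0) & (ei >= 0)
    out = np.full(cover.shape, nodata, dtype=np.uint8)
    out[valid] = lut[ei[valid], hi[valid], ci[valid]]
    return RasterLayer(stack.cover.spec, out, nodata, "sci")
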