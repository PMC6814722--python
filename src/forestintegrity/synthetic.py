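"""Synthetic landscapes, human-footprint surfaces, and lidar point clouds.

The generator produces inputs with known truth so every pipeline stage can
be exercised without satellite or airborne data:

* patchy SCI landscapes built by seeded region growing, together with
  cover/height/loss layers drawn from each cell's SCI class's admissible
  region — so reclassifying the layers recovers the generated truth
  exactly;
* a coarse human-footprint surface (uniform 0-50 per ~1 km cell);
* lidar point clouds whose vertical structure grows more complex with SCI
  class, from a three-stratum (ground / understory / canopy) Gaussian
  mixture per class over a smooth synthetic terrain;
* grouped (transect / patch) regression samples with known fixed slope
  and random-intercept variances for exercising the mixed-model suite.

The canopy profile model saturates by default above class 14 (classes
14-18 share a profile), mirroring the observed flattening of foliage
height diversity at the top of the condition scale; pass
``saturate=False`` for a strictly increasing profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from forestintegrity.grids import (
    GridSpec, RasterLayer, LayerStack, NODATA_BYTE, NODATA_FLOAT,
)
from forestintegrity.lidar import PointCloud, GROUND, VEGETATION, N_BINS
from forestintegrity.sci import (
    CoverClass, HeightClass, LossEpoch, DEFAULT_WEIGHTS,
)

__all__ = [
    "LandscapeConfig", "CanopyProfileModel",
    "generate_landscape", "generate_point_cloud",
    "generate_validation_samples", "expected_fhd",
]

# sampling ranges per class, kept clear of the class boundaries so float
# round-off cannot flip a cell's class
_COVER_RANGE = {
    CoverClass.BELOW25: (2.0, 24.0),
    CoverClass.C25_75: (25.5, 74.5),
    CoverClass.C75_95: (75.5, 94.5),
    CoverClass.ABOVE95: (95.5, 100.0),
}
_HEIGHT_RANGE = {
    HeightClass.H0_5: (0.0, 4.9),
    HeightClass.H5_15: (5.5, 14.5),
    HeightClass.H15_20: (15.1, 19.9),
    HeightClass.H20PLUS: (20.5, 40.0),
}


def _loss_code(epoch: LossEpoch, rng: np.random.Generator) -> int:
    if epoch is LossEpoch.NONE:
        return 0
    if epoch is LossEpoch.MID:
        return int(rng.integers(1, 13))
    return int(rng.integers(13, 18))


def _inverse_table() -> dict[int, list[tuple[LossEpoch, HeightClass, CoverClass]]]:
    inv: dict[int, list] = {w: [] for w in range(1, 19)}
    for key, w in DEFAULT_WEIGHTS.weight.items():
        inv[w].append(key)
    return inv


_INVERSE = _inverse_table()


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of the synthetic landscape generator.

    ``sci_class_probabilities`` (length 18, summing to 1) sets the
    frequency of each SCI class among patch seeds; the default is
    uniform so all 18 classes appear on a reasonably sized grid.
    """

    n_rows: int = 60
    n_cols: int = 60
    cell_size: float = 30.0
    n_patches: int = 60
    sci_class_probabilities: tuple[float, ...] = tuple([1 / 18] * 18)
    hfp_cell_size: float = 990.0
    crs_id: int = 32722
    origin_x: float = 500_000.0
    origin_y: float = 8_000_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.sci_class_probabilities)
        if len(p) != 18 or not np.isclose(p.sum(), 1.0):
            raise ValueError("sci_class_probabilities must be 18 values summing to 1")
        ratio = self.hfp_cell_size / self.cell_size
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("hfp_cell_size must be a multiple of cell_size")


def _grow_regions(n_rows: int, n_cols: int, n_patches: int,
                  probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Seeded region growing: random seeds, classes drawn from ``probs``,
    grown by randomized dilation until the grid is filled."""
    sci = np.zeros((n_rows, n_cols), dtype=np.int16)  # 0 = unassigned
    n_seed = min(n_patches, n_rows * n_cols)
    flat = rng.choice(n_rows * n_cols, size=n_seed, replace=False)
    classes = rng.choice(np.arange(1, 19), size=n_seed, p=probs)
    sci[flat // n_cols, flat % n_cols] = classes

    shifts = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    while (sci == 0).any():
        order = rng.permutation(4)
        grew = False
        for si in order:
            dr, dc = shifts[si]
            src = np.full_like(sci, 0)
            r0, r1 = max(dr, 0), n_rows + min(dr, 0)
            c0, c1 = max(dc, 0), n_cols + min(dc, 0)
            src[r0:r1, c0:c1] = sci[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
            take = (sci == 0) & (src != 0)
            # randomly skip some cells so patch boundaries are irregular
            take &= rng.random(sci.shape) < 0.6
            sci[take] = src[take]
            grew = grew or bool(take.any())
        if not grew:
            continue
    return sci


def generate_landscape(config: LandscapeConfig
                       ) -> tuple[LayerStack, RasterLayer]:
    """Generate a patchy landscape and its ground-truth SCI.

    Cover, height, and loss values are drawn uniformly from each cell's
    SCI class's admissible region of the classification table, so running
    the classifier on the returned stack recovers ``truth`` exactly. The
    human-footprint layer lives on its own coarser grid.
    """
    rng = np.random.default_rng(config.seed)
    probs = np.asarray(config.sci_class_probabilities)
    sci = _grow_regions(config.n_rows, config.n_cols, config.n_patches,
                        probs, rng)

    spec = GridSpec(config.origin_x, config.origin_y, config.cell_size,
                    config.n_rows, config.n_cols, config.crs_id)
    cover = np.zeros(spec.shape, dtype=np.float32)
    height = np.zeros(spec.shape, dtype=np.float32)
    loss = np.zeros(spec.shape, dtype=np.uint8)

    for r in range(config.n_rows):
        for c in range(config.n_cols):
            w = int(sci[r, c])
            if w == 1:
                # weight 1 is a union of causes; pick one at random
                cause = rng.integers(3)
                if cause == 0:  # recent loss, anything else
                    epoch = LossEpoch.RECENT
                    hcls = rng.choice(list(HeightClass))
                    ccls = rng.choice(list(CoverClass))
                elif cause == 1:  # open canopy
                    epoch = rng.choice([LossEpoch.NONE, LossEpoch.MID])
                    hcls = rng.choice(list(HeightClass))
                    ccls = CoverClass.BELOW25
                else:  # short stand
                    epoch = rng.choice([LossEpoch.NONE, LossEpoch.MID])
                    hcls = HeightClass.H0_5
                    ccls = rng.choice(list(CoverClass))
            else:
                options = _INVERSE[w]
                epoch, hcls, ccls = options[rng.integers(len(options))]
            lo, hi = _COVER_RANGE[ccls]
            cover[r, c] = rng.uniform(lo, hi)
            lo, hi = _HEIGHT_RANGE[hcls]
            height[r, c] = rng.uniform(lo, hi)
            loss[r, c] = _loss_code(epoch, rng)

    ratio = int(round(config.hfp_cell_size / config.cell_size))
    hfp_spec = GridSpec(
        config.origin_x, config.origin_y, config.hfp_cell_size,
        -(-config.n_rows // ratio), -(-config.n_cols // ratio),
        config.crs_id)
    hfp_vals = rng.uniform(0, 50, size=hfp_spec.shape).astype(np.float32)

    stack = LayerStack(
        cover=RasterLayer(spec, cover, NODATA_FLOAT, "cover_pct"),
        height=RasterLayer(spec, height, NODATA_FLOAT, "height_m"),
        loss=RasterLayer(spec, loss, NODATA_BYTE, "loss_year_code"),
        hfp=RasterLayer(hfp_spec, hfp_vals, NODATA_FLOAT, "hfp"),
    )
    truth = RasterLayer(spec, sci.astype(np.uint8), NODATA_BYTE, "sci")
    return stack, truth


@dataclass(frozen=True)
class CanopyProfileModel:
    """Per-SCI-class vertical foliage profile and point density.

    Each class's vegetation heights follow a three-stratum Gaussian
    mixture (ground vegetation / understory / canopy); the canopy stratum
    mean sits inside the class's height bin and the mixture broadens with
    class, so the Shannon entropy of the 1 m binned profile — the
    expected foliage height diversity — is non-decreasing in class.
    ``saturate=True`` reuses the class-14 profile for classes 15-18.
    """

    saturate: bool = True
    base_density: float = 12.0     # vegetation pts/m^2 for class 1
    density_slope: float = 0.4     # added pts/m^2 per class level
    #: optional per-class replacement strata: {class: ((w, mean, sd), ...)}
    overrides: dict | None = None

    def _level(self, sci_class: int) -> int:
        if not 1 <= sci_class <= 18:
            raise ValueError(f"SCI class must be in 1..18, got {sci_class}")
        return min(sci_class, 14) if self.saturate else sci_class

    def density(self, sci_class: int) -> float:
        """Expected vegetation point density (pts/m^2) for a class."""
        return self.base_density + self.density_slope * self._level(sci_class)

    def strata(self, sci_class: int) -> list[tuple[float, float, float]]:
        """(weight, mean height m, sd m) of the class's strata."""
        if self.overrides and sci_class in self.overrides:
            return [tuple(s) for s in self.overrides[sci_class]]
        L = self._level(sci_class)
        top = 2.0 + 26.0 * (L - 1) / 13.0
        w_ground = max(0.10, 0.40 - 0.022 * L)
        w_under = 0.15 + 0.012 * L
        w_canopy = 1.0 - w_ground - w_under
        return [
            (w_ground, 0.3, 0.4),
            (w_under, 0.4 * top, 0.3 + 0.15 * top),
            (w_canopy, top, 0.8 + 0.3 * L),
        ]

    def binned_profile(self, sci_class: int) -> np.ndarray:
        """Probability of each 1 m height bin [i, i+1), i = 0..69.

        Matches the measurement pipeline: draws below 0 are clamped into
        bin 0 and draws above 70 m are filtered out (the bin mass is
        renormalized accordingly).
        """
        edges = np.arange(0, N_BINS + 1, dtype=float)
        p = np.zeros(N_BINS)
        for w, mu, sd in self.strata(sci_class):
            cdf = norm.cdf(edges, loc=mu, scale=sd)
            inc = np.diff(cdf)
            inc[0] += cdf[0]            # clamp: mass below 0 joins bin 0
            p += w * inc
        return p / p.sum()              # drop (renormalize away) mass > 70 m


def expected_fhd(model: CanopyProfileModel, sci_class: int) -> float:
    """Exact Shannon entropy of the model's binned height profile."""
    p = model.binned_profile(sci_class)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _terrain(x: np.ndarray, y: np.ndarray, base: float,
             amplitude: float) -> np.ndarray:
    return (base
            + amplitude * np.sin(x / 180.0)
            + amplitude * np.cos(y / 240.0))


def generate_point_cloud(truth: RasterLayer,
                         model: CanopyProfileModel,
                         seed: int,
                         acquisition_year: int = 2015,
                         ground_density: float = 0.5,
                         terrain_base: float = 150.0,
                         terrain_amplitude: float = 4.0) -> PointCloud:
    """Simulate a classified lidar cloud over a truth SCI layer.

    Per cell, the vegetation return count is Poisson at the class's
    density; heights come from the class's stratum mixture and sit on a
    smooth sinusoidal terrain. Ground returns are scattered uniformly at
    ``ground_density`` points/m^2.
    """
    rng = np.random.default_rng(seed)
    spec = truth.spec
    area = spec.cell_size**2

    xs_parts, ys_parts, zs_parts, cls_parts = [], [], [], []
    for r in range(spec.n_rows):
        for c in range(spec.n_cols):
            if not truth.mask[r, c]:
                continue
            w = int(truth.values[r, c])
            x0 = spec.origin_x + c * spec.cell_size
            y0 = spec.origin_y - (r + 1) * spec.cell_size

            n_g = rng.poisson(ground_density * area)
            if n_g:
                gx = rng.uniform(x0, x0 + spec.cell_size, n_g)
                gy = rng.uniform(y0, y0 + spec.cell_size, n_g)
                xs_parts.append(gx)
                ys_parts.append(gy)
                zs_parts.append(_terrain(gx, gy, terrain_base, terrain_amplitude))
                cls_parts.append(np.full(n_g, GROUND, dtype=np.int8))

            n_v = rng.poisson(model.density(w) * area)
            if n_v:
                vx = rng.uniform(x0, x0 + spec.cell_size, n_v)
                vy = rng.uniform(y0, y0 + spec.cell_size, n_v)
                strata = model.strata(w)
                weights = np.array([s[0] for s in strata])
                pick = rng.choice(len(strata), size=n_v, p=weights / weights.sum())
                mu = np.array([s[1] for s in strata])[pick]
                sd = np.array([s[2] for s in strata])[pick]
                h = rng.normal(mu, sd)
                xs_parts.append(vx)
                ys_parts.append(vy)
                zs_parts.append(_terrain(vx, vy, terrain_base,
                                         terrain_amplitude) + h)
                cls_parts.append(np.full(n_v, VEGETATION, dtype=np.int8))

    if xs_parts:
        x = np.concatenate(xs_parts)
        y = np.concatenate(ys_parts)
        z = np.concatenate(zs_parts)
        cls = np.concatenate(cls_parts)
    else:
        x = y = z = np.empty(0)
        cls = np.empty(0, dtype=np.int8)
    return PointCloud(x, y, z, cls, acquisition_year=acquisition_year,
                      crs_id=truth.spec.crs_id)


def generate_validation_samples(n_transects: int = 10,
                                patches_per_transect: int = 20,
                                cells_per_patch: int = 9,
                                intercept: float = 0.6,
                                slope: float = 0.15,
                                sd_transect: float = 0.25,
                                sd_patch: float = 0.12,
                                sd_resid: float = 0.08,
                                seed: int = 0):
    """Grouped FHD-on-SCI samples with known mixed-model structure.

    Each record is ``intercept + slope*sci + u_transect + v_patch + e``
    with Gaussian random intercepts at both grouping levels. Patch SCI
    values are drawn uniformly from 1..18. Defaults give a strong
    condition-to-structure signal with grouping variances that dominate
    the residual, the regime the nested-model comparison is designed for.
    Returns a DataFrame with columns transect_id, patch_id, sci, fhd.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_transects):
        u = rng.normal(0, sd_transect)
        for p in range(patches_per_transect):
            v = rng.normal(0, sd_patch)
            sci = int(rng.integers(1, 19))
            eps = rng.normal(0, sd_resid, size=cells_per_patch)
            fhd = intercept + slope * sci + u + v + eps
            for e in fhd:
                rows.append((f"T{t:02d}", f"T{t:02d}P{p:03d}", sci, e))
    return pd.DataFrame(rows, columns=["transect_id", "patch_id", "sci", "fhd"])
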