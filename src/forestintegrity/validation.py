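"""SCI-versus-FHD validation: sampling from homogeneous patch cores and
model comparison.

Because a lidar footprint and the 30 m condition grid are never perfectly
co-registered, validation cells are drawn only from the cores of
homogeneous SCI patches: connected components of constant SCI at least
3 x 3 cells in size, with every cell within 90 m of the patch perimeter
removed. Cells whose recorded loss post-dates the lidar acquisition are
masked out first. The per-cell (FHD, SCI) records, grouped by transect
and patch, feed three models of increasing structure:

    FHD = SCI + e                      (baseline OLS)
    FHD = SCI + (1|transect) + e       (random transect intercept)
    FHD = SCI + (1|transect/patch) + e (patch nested in transect)

Models are fit by maximum likelihood and compared on AIC; marginal
(fixed-effects) and conditional (fixed + random) R-squared are reported
in the variance-partition sense.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
import statsmodels.api as sm
import statsmodels.formula.api as smf

from forestintegrity.grids import RasterLayer, NODATA_BYTE
from forestintegrity.lidar import FHDGrid

__all__ = [
    "PatchMap", "ModelFit",
    "mask_post_acquisition_loss", "label_patches", "extract_cores",
    "build_samples", "fit_ols", "fit_random_intercept", "compare_models",
    "sci_distribution_by_class",
]

MODEL_FORMULAS = {
    "ols": "FHD = SCI + e",
    "ri_transect": "FHD = SCI + (1|transect) + e",
    "ri_nested": "FHD = SCI + (1|transect/patch) + e",
}


@dataclass
class PatchMap:
    """Connected components of constant SCI.

    ``labels`` holds integer component ids (0 = background/nodata);
    ``sci_of`` and ``size_of`` map each label to its SCI value and cell
    count.
    """

    labels: RasterLayer
    sci_of: dict[int, int]
    size_of: dict[int, int]


@dataclass
class ModelFit:
    """One fitted model of FHD on SCI."""

    name: str
    intercept: float
    slope: float
    aic: float
    r2_marginal: float
    r2_conditional: float
    variance_components: dict[str, float] = field(default_factory=dict)
    n_obs: int = 0
    converged: bool = True

    @property
    def formula(self) -> str:
        return MODEL_FORMULAS.get(self.name, self.name)


def mask_post_acquisition_loss(sci: RasterLayer, loss: RasterLayer,
                               year: int) -> RasterLayer:
    """Nodata-out SCI cells whose loss year is after the lidar acquisition.

    ``year`` is the acquisition calendar year; loss codes are years minus
    2000. A loss in the acquisition year itself is retained (the
    comparison is strict).
    """
    if sci.spec != loss.spec:
        raise ValueError("SCI and loss layers must share a GridSpec")
    if not 2001 <= year <= 2017:
        raise ValueError(f"acquisition year {year} outside 2001..2017")
    cutoff = year - 2000
    drop = loss.mask & (loss.values > cutoff)
    out = sci.values.copy()
    out[drop] = sci.nodata
    return sci.with_values(out)


def label_patches(sci: RasterLayer, connectivity: int = 1) -> PatchMap:
    """Label connected components of equal SCI value (4-connectivity).

    Nodata cells get label 0. ``connectivity=2`` switches to
    8-connectivity.
    """
    vals = np.where(sci.mask, sci.values.astype(np.int64), -1)
    labels = measure.label(vals, connectivity=connectivity, background=-1)
    sci_of: dict[int, int] = {}
    size_of: dict[int, int] = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        where = labels == lab
        sci_of[int(lab)] = int(vals[where][0])
        size_of[int(lab)] = int(where.sum())
    layer = RasterLayer(sci.spec, labels.astype(np.int32), 0, "class_label")
    return PatchMap(layer, sci_of, size_of)


def extract_cores(patches: PatchMap, min_cells: int = 9,
                  buffer_m: float = 90.0) -> RasterLayer:
    """Core cells of sufficiently large patches after a perimeter buffer.

    A cell survives if its patch has at least ``min_cells`` cells and
    every cell within ``buffer_m`` (Chebyshev distance, i.e. a square
    window) belongs to the same patch — equivalently, erosion of each
    patch by ``buffer_m / cell_size`` cells. Cells near the raster edge
    are treated as bordering background. Returns a 0/1 mask layer.
    """
    cell = patches.labels.spec.cell_size
    r = buffer_m / cell
    if abs(r - round(r)) > 1e-9:
        raise ValueError(f"buffer {buffer_m} m is not a multiple of the "
                         f"{cell} m cell size")
    r = int(round(r))
    labels = patches.labels.values

    size = 2 * r + 1
    if r == 0:
        core = labels != 0
    else:
        lo = ndimage.minimum_filter(labels, size=size, mode="constant", cval=0)
        hi = ndimage.maximum_filter(labels, size=size, mode="constant", cval=0)
        core = (labels != 0) & (lo == labels) & (hi == labels)

    big = np.isin(labels, [lab for lab, n in patches.size_of.items()
                           if n >= min_cells])
    mask = (core & big).astype(np.uint8)
    return RasterLayer(patches.labels.spec, mask, NODATA_BYTE, "class_label")


def build_samples(fhd: FHDGrid, sci: RasterLayer, cores: RasterLayer,
                  transect_id: str, patches: PatchMap | None = None
                  ) -> pd.DataFrame:
    """One validation record per cell passing all three masks.

    A cell contributes a record when its FHD is valid (dense enough), its
    SCI is not nodata, and it lies in a homogeneous-patch core. Returns a
    DataFrame with columns ``transect_id, patch_id, row, col, sci, fhd``.
    """
    if fhd.fhd.spec != sci.spec or cores.spec != sci.spec:
        raise ValueError("FHD, SCI, and core layers must share a GridSpec")
    keep = fhd.valid & sci.mask & (cores.values == 1)
    rows, cols = np.nonzero(keep)
    patch = (patches.labels.values[rows, cols].astype(int)
             if patches is not None else np.zeros(len(rows), dtype=int))
    return pd.DataFrame({
        "transect_id": transect_id,
        "patch_id": patch,
        "row": rows,
        "col": cols,
        "sci": sci.values[rows, cols].astype(float),
        "fhd": fhd.fhd.values[rows, cols].astype(float),
    })


def _check_samples(samples: pd.DataFrame) -> pd.DataFrame:
    required = {"sci", "fhd"}
    if not required <= set(samples.columns):
        raise ValueError(f"samples need columns {sorted(required)}")
    if len(samples) < 3:
        raise ValueError("need at least 3 records to fit")
    if samples["sci"].nunique() < 2:
        raise ValueError("degenerate design: a single SCI value")
    return samples.reset_index(drop=True)


def _aic(llf: float, k_params: int) -> float:
    return -2.0 * llf + 2.0 * k_params


def fit_ols(samples: pd.DataFrame) -> ModelFit:
    """Baseline ordinary least squares of FHD on SCI (continuous).

    AIC is computed from the Gaussian maximum likelihood with the
    residual variance counted as a parameter, so it is directly
    comparable with the mixed-model AICs.
    """
    samples = _check_samples(samples)
    X = sm.add_constant(samples["sci"].to_numpy())
    res = sm.OLS(samples["fhd"].to_numpy(), X).fit()
    sigma2 = res.ssr / res.nobs  # ML variance estimate
    r2 = float(res.rsquared)
    return ModelFit(
        name="ols",
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        aic=_aic(float(res.llf), 3),  # intercept, slope, sigma^2
        r2_marginal=r2,
        r2_conditional=r2,
        variance_components={"residual": float(sigma2)},
        n_obs=int(res.nobs),
    )


def fit_random_intercept(samples: pd.DataFrame,
                         grouping: str = "transect") -> ModelFit:
    """Gaussian linear mixed model of FHD on SCI with random intercepts.

    ``grouping='transect'`` fits a random intercept per transect;
    ``grouping='patch_in_transect'`` adds a nested random intercept of
    patch within transect (one shared variance for patches). Fit by
    maximum likelihood so AIC is comparable with :func:`fit_ols`.
    R-squared follows the variance-partition convention: marginal uses
    the fixed-effects variance only, conditional adds the random-effect
    variances.
    """
    samples = _check_samples(samples)
    if grouping not in ("transect", "patch_in_transect"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if "transect_id" not in samples.columns:
        raise ValueError("samples need a transect_id column")
    if samples["transect_id"].nunique() < 2:
        raise ValueError("need at least 2 transects for a random intercept")

    df = samples.copy()
    df["transect_id"] = df["transect_id"].astype(str)
    if grouping == "patch_in_transect":
        if "patch_id" not in df.columns:
            raise ValueError("nested grouping needs a patch_id column")
        df["patch_id"] = df["patch_id"].astype(str)
        model = smf.mixedlm("fhd ~ sci", df, groups="transect_id",
                            re_formula="1",
                            vc_formula={"patch": "0 + C(patch_id)"})
        name = "ri_nested"
        k = 2 + 2 + 1  # fixed + (transect var, patch var) + residual
    else:
        model = smf.mixedlm("fhd ~ sci", df, groups="transect_id",
                            re_formula="1")
        name = "ri_transect"
        k = 2 + 1 + 1

    res = model.fit(reml=False)
    if not res.converged:
        raise RuntimeError(
            f"mixed model ({name}) did not converge on {len(df)} records; "
            "check group structure and scaling")

    fe = np.asarray(res.fe_params)
    X = np.column_stack([np.ones(len(df)), df["sci"].to_numpy()])
    var_fixed = float(np.var(X @ fe))
    var_transect = float(np.asarray(res.cov_re).ravel()[0])
    var_patch = float(res.vcomp[0]) if len(res.vcomp) else 0.0
    var_resid = float(res.scale)
    var_random = var_transect + var_patch
    total = var_fixed + var_random + var_resid

    comps = {"transect": var_transect, "residual": var_resid}
    if grouping == "patch_in_transect":
        comps["patch_in_transect"] = var_patch

    return ModelFit(
        name=name,
        intercept=float(fe[0]),
        slope=float(fe[1]),
        aic=_aic(float(res.llf), k),
        r2_marginal=var_fixed / total,
        r2_conditional=(var_fixed + var_random) / total,
        variance_components=comps,
        n_obs=len(df),
        converged=bool(res.converged),
    )


def compare_models(fits: list[ModelFit]) -> pd.DataFrame:
    """Model-selection table sorted by AIC ascending (stable on ties)."""
    if not fits:
        raise ValueError("no fits to compare")
    n = {f.n_obs for f in fits}
    if len(n) > 1:
        raise ValueError("fits were estimated on different sample sets")
    rows = [{
        "name": f.name,
        "formula": f.formula,
        "aic": f.aic,
        "r2_marginal": f.r2_marginal,
        "r2_conditional": f.r2_conditional,
    } for f in fits]
    return (pd.DataFrame(rows)
            .sort_values("aic", kind="stable")
            .reset_index(drop=True))


def sci_distribution_by_class(sci: RasterLayer, classes: RasterLayer,
                              class_names: dict[int, str] | None = None
                              ) -> pd.DataFrame:
    """Relative frequency of each SCI value 1..18 within each forest class.

    Rows are forest classes (e.g. plantation, older secondary, primary),
    columns SCI values; each row sums to 1 over the class's valid cells.
    """
    if sci.spec != classes.spec:
        raise ValueError("SCI and class layers must share a GridSpec")
    ok = sci.mask & classes.mask
    s = sci.values[ok].astype(int)
    c = classes.values[ok].astype(int)
    tab = pd.crosstab(c, s, normalize="index")
    tab = tab.reindex(columns=range(1, 19), fill_value=0.0)
    tab.columns = [int(x) for x in tab.columns]
    tab.index.name = "forest_class"
    tab.columns.name = "sci"
    if class_names:
        tab.index = [class_names.get(i, str(i)) for i in tab.index]
        tab.index.name = "forest_class"
    return tab
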