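"""Petri-dish phototaxis assay scoring.

A population of cells is left to migrate in a dish with a light source
at one side; a picture of the empty dish (background) and of the dish
after the assay are compared.  The phototaxis index is the fraction of
background-subtracted cell-signal intensity that ends up in the
light-facing half of the dish: 0.5 means no net light-directed
migration, 1 means all signal moved toward the light, 0 away from it.
Populations are tested against the 0.5 null with a one-sample t-test,
with Holm adjustment across a species battery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

_LIGHT_AXES = {
    "right": (1.0, 0.0),
    "left": (-1.0, 0.0),
    "top": (0.0, -1.0),
    "bottom": (0.0, 1.0),
}


def light_axis_from(direction) -> np.ndarray:
    """Unit vector pointing toward the light source.

    ``direction`` is one of left/right/top/bottom (image convention:
    x right, y down) or an angle in degrees (0 = +x, counterclockwise
    in mathematical convention).
    """
    if isinstance(direction, str):
        try:
            v = np.array(_LIGHT_AXES[direction.lower()])
        except KeyError:
            raise ValueError(f"unknown light direction {direction!r}") from None
        return v
    ang = np.deg2rad(float(direction))
    return np.array([np.cos(ang), -np.sin(ang)])


def detect_dish_mask(background: np.ndarray) -> np.ndarray:
    """Boolean dish mask from the background image by intensity circle fit.

    The dish interior is brighter than the surround; Otsu thresholding
    followed by an equivalent-disk fit of the largest region gives a
    clean circular mask robust to vignetting.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label, regionprops

    bw = background > threshold_otsu(background)
    lab = label(bw)
    regions = regionprops(lab)
    if not regions:
        raise ValueError("no dish found in background image")
    best = max(regions, key=lambda r: r.area)
    cy, cx = best.centroid
    radius = np.sqrt(best.area / np.pi)
    yy, xx = np.mgrid[0 : background.shape[0], 0 : background.shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


@dataclass
class PhototaxisAssay:
    """One dish image pair plus the light geometry."""

    background_img: np.ndarray
    assay_img: np.ndarray
    light_axis: np.ndarray
    dish_mask: np.ndarray = None

    def __post_init__(self):
        self.background_img = np.asarray(self.background_img, dtype=float)
        self.assay_img = np.asarray(self.assay_img, dtype=float)
        if self.background_img.shape != self.assay_img.shape:
            raise ValueError("background and assay images must have the same shape")
        if self.dish_mask is None:
            self.dish_mask = detect_dish_mask(self.background_img)
        self.dish_mask = np.asarray(self.dish_mask, dtype=bool)
        if self.dish_mask.shape != self.assay_img.shape:
            raise ValueError("dish mask shape mismatch")
        if not self.dish_mask.any():
            raise ValueError("dish mask is empty")
        v = np.asarray(self.light_axis, dtype=float)
        self.light_axis = v / np.linalg.norm(v)


@dataclass
class PhototaxisResult:
    index: float = np.nan
    front_intensity_sum: float = np.nan
    total_intensity_sum: float = np.nan
    defined: bool = True
    n_replicates: int = 0
    mean_index: float = np.nan
    t_stat: float = np.nan
    p_value: float = np.nan
    p_adj: float = np.nan
    significant: bool = False
    direction: str = "none"


def phototaxis_index(assay: PhototaxisAssay, literal_area_form: bool = False) -> PhototaxisResult:
    """Phototaxis index of one dish.

    The assay-minus-background difference (negatives clipped to zero,
    restricted to the dish mask) is summed over the light-facing half
    and over the whole dish; the index is their ratio.  The half split
    is by sign of the projection of pixel position (about the dish-mask
    centroid) onto the light axis; pixels exactly on the dividing line
    count as front.

    With ``literal_area_form`` the published mean-intensity × area
    product is evaluated instead of the sum ratio; the two agree exactly
    when "intensity" is read as the half/whole mean, in which case the
    areas cancel.

    A dish with zero total difference intensity yields an undefined
    (NaN) index flagged via ``defined=False`` — not 0.5.
    """
    diff = np.clip(assay.assay_img - assay.background_img, 0.0, None)
    mask = assay.dish_mask
    yy, xx = np.mgrid[0 : diff.shape[0], 0 : diff.shape[1]]
    cx = xx[mask].mean()
    cy = yy[mask].mean()
    proj = (xx - cx) * assay.light_axis[0] + (yy - cy) * assay.light_axis[1]
    front = mask & (proj >= 0)
    total_sum = float(diff[mask].sum())
    front_sum = float(diff[front].sum())
    if total_sum == 0.0:
        return PhototaxisResult(front_intensity_sum=front_sum, total_intensity_sum=total_sum,
                                defined=False)
    if literal_area_form:
        front_area = int(front.sum())
        total_area = int(mask.sum())
        index = (front_sum / front_area * front_area) / (total_sum / total_area * total_area)
    else:
        index = front_sum / total_sum
    return PhototaxisResult(index=index, front_intensity_sum=front_sum,
                            total_intensity_sum=total_sum)


def phototaxis_test(indices, null: float = 0.5, alpha: float = 0.05) -> PhototaxisResult:
    """Two-sided one-sample t-test of replicate indices against 0.5.

    Positive phototaxis is declared when p < alpha and the mean index is
    above the null; negative when below.  With zero variance at exactly
    the null the statistic is undefined and the result non-significant.
    """
    x = np.asarray(indices, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 replicates")
    if np.allclose(x.std(ddof=1), 0.0) and np.isclose(x.mean(), null):
        return PhototaxisResult(n_replicates=x.size, mean_index=float(x.mean()),
                                t_stat=np.nan, p_value=1.0, significant=False)
    t, p = stats.ttest_1samp(x, null)
    mean = float(x.mean())
    sig = bool(p < alpha)
    direction = "positive" if mean > null else ("negative" if mean < null else "none")
    return PhototaxisResult(n_replicates=x.size, mean_index=mean, t_stat=float(t),
                            p_value=float(p), significant=sig,
                            direction=direction if sig else "none")


def phototaxis_battery(indices_by_species: dict, null: float = 0.5, alpha: float = 0.05,
                       adjust: str = "holm") -> dict:
    """Test a battery of species with multiple-testing adjustment.

    Per-species one-sample t-tests against the null, p-values adjusted
    across the battery (Holm by default; any statsmodels method name).
    Returns ``{species: PhototaxisResult}`` with ``p_adj`` filled and
    significance decided on the adjusted p-value.
    """
    species = list(indices_by_species)
    results = {s: phototaxis_test(indices_by_species[s], null=null, alpha=alpha)
               for s in species}
    pvals = [results[s].p_value for s in species]
    _, p_adj, _, _ = multipletests(pvals, alpha=alpha, method=adjust)
    for s, pa in zip(species, p_adj):
        r = results[s]
        r.p_adj = float(pa)
        r.significant = bool(pa < alpha)
        if not r.significant:
            r.direction = "none"
        elif r.mean_index > null:
            r.direction = "positive"
        elif r.mean_index < null:
            r.direction = "negative"
    return results
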