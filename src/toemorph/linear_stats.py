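"""Landmark-derived linear measurements and their univariate statistics.

All measurements are taken on *unaligned* millimetre coordinates, so they
carry absolute size (Procrustes alignment would remove it).  Distances are
defined on the anatomical landmark numbering:

* pad width      = |LM5 - LM6|
* pad length     = |mid(LM3, LM4) - mid(LM7, LM8)|
* proximal length= |mid(LM1, LM2) - mid(LM3, LM4)|
* total length   = pad length + proximal length (by construction, exactly)
* lamella height = mean distance between adjacent lamella-edge landmarks
                   (10-12, 12-14, 14-16, 16-18 and 11-13, 13-15, 15-17, 17-19)

The landmark-polygon area closes the toe outline distal of LM3/LM4 through
the claw base; it is deliberately distinct from a digitized toepad area
(which extends to the nearest phalangeal joint) and the two are kept as
separate columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from shapely.geometry import Polygon
from statsmodels.stats.anova import anova_lm

from .gpa import centroid_size
from .scheme import Configuration, LandmarkScheme

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = [
    "pad_width_mm", "pad_length_mm", "proximal_len_mm", "total_toe_len_mm",
    "lamella_height_mm", "lm_polygon_area_mm2", "centroid_size_mm",
]


def _curve_interiors(config: Configuration) -> list[np.ndarray]:
    if config.stripped:
        return list(config.curve_points)
    return [c[1:-1] for c in config.curve_points]


def _pad_outline(config: Configuration, scheme: LandmarkScheme) -> np.ndarray:
    """Closed pad/toe outline: outline landmarks interleaved with their curves."""
    by_anchor = {
        (c.start_anchor, c.end_anchor): i for i, c in enumerate(scheme.curves)
    }
    interiors = _curve_interiors(config)
    lms = scheme.pad_outline_landmarks
    pts = [config.landmark(lms[0])]
    for a, b in zip(lms[:-1], lms[1:]):
        if (a, b) in by_anchor:
            seg = interiors[by_anchor[(a, b)]]
        elif (b, a) in by_anchor:
            seg = interiors[by_anchor[(b, a)]][::-1]
        else:
            seg = np.empty((0, 2))
        pts.extend([seg, [config.landmark(b)]])
    return np.vstack(pts)


def polygon_area(config: Configuration, scheme: LandmarkScheme) -> float:
    """Shoelace area (mm^2) of the closed toe outline distal of LM3/LM4.

    Orientation-independent and invariant to rotation/translation.  If the
    outline self-intersects a warning is issued and the absolute shoelace
    value is still returned.
    """
    poly = _pad_outline(config, scheme)
    if len(poly) < 3:
        raise ValueError(f"{config.specimen_id}: outline has fewer than 3 points")
    if not Polygon(poly).is_valid:
        warnings.warn(
            f"{config.specimen_id}: pad outline is self-intersecting; "
            "returning absolute shoelace value",
            stacklevel=2,
        )
    return shoelace_area(poly)


def shoelace_area(points: np.ndarray) -> float:
    """Absolute shoelace area of a closed polygon given by its vertices."""
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def measure(config: Configuration, scheme: LandmarkScheme) -> dict:
    """All linear measurements of one specimen (unaligned mm coordinates)."""
    lm = config.landmark
    mid = lambda i, j: (lm(i) + lm(j)) / 2.0  # noqa: E731
    pad_width = float(np.linalg.norm(lm(5) - lm(6)))
    pad_length = float(np.linalg.norm(mid(3, 4) - mid(7, 8)))
    proximal = float(np.linalg.norm(mid(1, 2) - mid(3, 4)))
    heights = [
        float(np.linalg.norm(lm(a) - lm(b))) for a, b in scheme.lamella_height_pairs
    ]
    all_pts = np.vstack([config.fixed_points, *_curve_interiors(config)])
    return {
        "specimen_id": config.specimen_id,
        "pad_width_mm": pad_width,
        "pad_length_mm": pad_length,
        "proximal_len_mm": proximal,
        "total_toe_len_mm": pad_length + proximal,
        "lamella_height_mm": float(np.mean(heights)),
        "lm_polygon_area_mm2": polygon_area(config, scheme),
        "centroid_size_mm": centroid_size(all_pts),
    }


def measurement_table(
    configs: list[Configuration],
    scheme: LandmarkScheme,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-specimen measurement rows, inner-joined to metadata if given."""
    table = pd.DataFrame([measure(c, scheme) for c in configs])
    if metadata is not None:
        table = table.merge(
            metadata.reset_index(drop=True), on="specimen_id", how="inner"
        )
    return table


@dataclass(frozen=True)
class TestResult:
    """A two-group Welch t-test on (optionally transformed) values."""

    statistic: float
    df: float
    p: float
    transform: str
    mean_a: float  # transformed scale
    mean_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    back_mean_a: float  # back-transformed scale
    back_mean_b: float
    back_ci_a: tuple[float, float]
    back_ci_b: tuple[float, float]
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.p <= 1.0


_TRANSFORMS = {
    "none": (lambda x: x, lambda x: x),
    "ln": (np.log, np.exp),
    "sqrt": (np.sqrt, np.square),
}


def welch_t_test(values_a, values_b, transform: str = "none") -> TestResult:
    """Two-sided unequal-variance t-test with Welch-Satterthwaite df.

    Group means and 95% confidence intervals are reported on the
    transformed scale and back-transformed by applying the inverse
    transform to the interval bounds.
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    fwd, inv = _TRANSFORMS[transform]
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if transform in ("ln", "sqrt") and (np.any(a <= 0) or np.any(b <= 0)):
        bad_a = np.flatnonzero(a <= 0)
        bad_b = np.flatnonzero(b <= 0)
        raise ValueError(
            f"non-positive values under {transform}: group a indices "
            f"{bad_a.tolist()}, group b indices {bad_b.tolist()}"
        )
    ta, tb = fwd(a), fwd(b)
    res = scipy.stats.ttest_ind(ta, tb, equal_var=False)

    def mean_ci(x):
        m = float(x.mean())
        se = float(x.std(ddof=1) / np.sqrt(len(x)))
        half = scipy.stats.t.ppf(0.975, len(x) - 1) * se
        return m, (m - half, m + half)

    ma, cia = mean_ci(ta)
    mb, cib = mean_ci(tb)
    return TestResult(
        statistic=float(res.statistic), df=float(res.df), p=float(res.pvalue),
        transform=transform,
        mean_a=ma, mean_b=mb, ci_a=cia, ci_b=cib,
        back_mean_a=float(inv(ma)), back_mean_b=float(inv(mb)),
        back_ci_a=tuple(float(inv(v)) for v in cia),
        back_ci_b=tuple(float(inv(v)) for v in cib),
        n_a=len(a), n_b=len(b),
    )


def percent_difference(mean_focal: float, mean_reference: float) -> float:
    """Percent difference of a focal mean relative to a reference mean."""
    if not mean_reference > 0:
        raise ValueError("reference mean must be positive")
    return round(100.0 * (mean_focal - mean_reference) / mean_reference, 2)


#: The standard urban-vs-forest comparison battery: measurement column,
#: transform, and how the per-specimen value is derived from the table.
RATIO_BATTERY = {
    "width_length_ratio": ("ln", lambda t: t.pad_width_mm / t.pad_length_mm),
    "total_toe_length": ("ln", lambda t: t.total_toe_len_mm),
    "pad_fraction_of_toe": ("ln", lambda t: t.pad_length_mm / t.total_toe_len_mm),
    "proximal_length": ("ln", lambda t: t.proximal_len_mm),
    "pad_area": ("ln", lambda t: t.measured_pad_area_mm2),
    "lamella_count": ("sqrt", lambda t: t.lamella_count.astype(float)),
    "lamella_height": ("ln", lambda t: t.lamella_height_mm),
}


def ratio_analysis(
    measurements: pd.DataFrame,
    group_col: str = "habitat",
    focal: str = "urban",
    reference: str = "forest",
) -> dict:
    """Run the full urban-vs-forest comparison battery.

    Returns a dict of :class:`TestResult` keyed by comparison name, plus a
    ``"raw_ratio_means"`` entry with the per-group means of the raw
    width/length ratio.
    """
    g_a = measurements[measurements[group_col] == focal]
    g_b = measurements[measurements[group_col] == reference]
    if len(g_a) < 2 or len(g_b) < 2:
        raise ValueError(f"need >=2 specimens per {group_col} group")
    out: dict = {}
    for name, (transform, derive) in RATIO_BATTERY.items():
        try:
            out[name] = welch_t_test(derive(g_a), derive(g_b), transform=transform)
        except AttributeError:
            logger.info("skipping %s: required column missing", name)
    out["raw_ratio_means"] = {
        focal: float((g_a.pad_width_mm / g_a.pad_length_mm).mean()),
        reference: float((g_b.pad_width_mm / g_b.pad_length_mm).mean()),
    }
    return out


#: Named generalized-linear-model ANOVAs relating pad area, pad length,
#: lamella height and lamella count (type-II sums of squares throughout).
GLM_MODELS = {
    "area_by_lamellae": "ln_area ~ ln_height * sqrt_count",
    "height_by_padlen_habitat": "ln_height ~ ln_padlen * habitat",
    "count_by_padlen_habitat": "sqrt_count ~ ln_padlen * habitat",
    "height_by_count": "ln_height ~ sqrt_count",
}


def _derived_columns(measurements: pd.DataFrame) -> pd.DataFrame:
    t = measurements.copy()
    if "measured_pad_area_mm2" in t:
        t["ln_area"] = np.log(t.measured_pad_area_mm2)
    t["ln_height"] = np.log(t.lamella_height_mm)
    t["ln_padlen"] = np.log(t.pad_length_mm)
    if "lamella_count" in t:
        t["sqrt_count"] = np.sqrt(t.lamella_count.astype(float))
    return t


def glm_anova_type2(measurements: pd.DataFrame, model: str) -> pd.DataFrame:
    """Gaussian linear model with type-II per-term F tests.

    ``model`` is a named model from :data:`GLM_MODELS` or an explicit
    formula over the derived columns (``ln_area``, ``ln_height``,
    ``ln_padlen``, ``sqrt_count``) and metadata columns.
    """
    formula = GLM_MODELS.get(model, model)
    data = _derived_columns(measurements)
    fit = smf.ols(formula, data=data).fit()
    if fit.model.exog.shape[1] > np.linalg.matrix_rank(fit.model.exog):
        raise ValueError(
            f"rank-deficient design for {formula!r}: aliased terms among "
            f"{fit.model.exog_names}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = anova_lm(fit, typ=2)
    table = table.rename(
        columns={"sum_sq": "SS", "PR(>F)": "p", "F": "F"}
    )
    table.attrs["formula"] = formula
    table.attrs["nobs"] = int(fit.nobs)
    return table


def icc_repeatability(replicates: pd.DataFrame,
                      specimen_col: str = "specimen_id",
                      value_col: str = "value") -> dict:
    """One-way random-effects repeatability of replicated measurements.

    ``replicates`` is long-format: one row per measurement, with a specimen
    identifier and a value.  Variance is decomposed by one-way ANOVA; the
    among-specimen component uses the unbalanced-design coefficient, and
    ICC = among / (among + within).
    """
    groups = replicates.groupby(specimen_col)[value_col]
    ns = groups.size()
    if len(ns) < 2:
        raise ValueError("need at least two specimens")
    if (ns < 2).all():
        raise ValueError("need at least two replicates for some specimen")
    n_total = int(ns.sum())
    a = len(ns)
    grand = replicates[value_col].mean()
    means = groups.mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((replicates[value_col] - means.loc[
        replicates[specimen_col]].to_numpy()) ** 2).sum())
    ms_within = ss_within / (n_total - a)
    ms_between = ss_between / (a - 1)
    k0 = (n_total - float((ns**2).sum()) / n_total) / (a - 1)
    among = max((ms_between - ms_within) / k0, 0.0)
    within = ms_within
    icc = among / (among + within) if among + within > 0 else 0.0
    return {"icc": icc, "within_var": within, "among_var": among}


def sm_version() -> str:
    return sm.__version__
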