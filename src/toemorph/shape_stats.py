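"""Multivariate inference on Procrustes-aligned shapes.

The central object is :class:`ProcrustesAnova`, a linear model on the
flattened aligned coordinates fitted by least squares, with type-II sums
of squares per term and significance assessed by residual randomization
(RRPP): for each term, the residuals of its reduced model are permuted and
the term's F statistic recomputed, giving ``p = (#{F* >= F} + 1) /
(n_perm + 1)``.  Disparity, PCA, between-group PCA and CVA follow the
conventions of the standard morphometric toolkits: disparity is the
Procrustes variance of model residuals per group, CVA operates in a
retained principal-component space and scales its axes to unit pooled
within-group variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .gpa import AlignedSample

__all__ = [
    "ProcrustesAnova", "ProcrustesAnovaResults", "procrustes_anova",
    "morphological_disparity", "DisparityResult",
    "shape_pca", "between_group_pca", "PcaResult",
    "group_mean_shapes", "cva", "cva_randomization_null", "CvaResult",
    "allometry_test",
]


# ---------------------------------------------------------------------------
# design-matrix machinery

def _parse_formula(formula: str) -> list[str]:
    """Expand a minimal Wilkinson formula RHS into an ordered term list."""
    terms: list[str] = []
    for chunk in formula.replace("~", "").split("+"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "*" in chunk:
            factors = [f.strip() for f in chunk.split("*")]
            terms.extend(f for f in factors if f not in terms)
            inter = ":".join(factors)
            if inter not in terms:
                terms.append(inter)
        elif chunk not in terms:
            terms.append(chunk)
    return terms


def _term_block(design: pd.DataFrame, term: str) -> np.ndarray:
    """Design block for one term (treatment coding; ':' for interactions)."""
    factors = term.split(":")
    block = np.ones((len(design), 1))
    for f in factors:
        col = design[f]
        if pd.api.types.is_numeric_dtype(col):
            part = np.asarray(col, dtype=float)[:, None]
        else:
            part = pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)
        block = np.concatenate(
            [block[:, i : i + 1] * part for i in range(block.shape[1])], axis=1
        )
    return block


def _ortho_basis(x: np.ndarray, against: np.ndarray | None = None) -> np.ndarray:
    """Orthonormal column basis of x, optionally orthogonal to `against`."""
    if against is not None and against.shape[1]:
        x = x - against @ (against.T @ x)
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-9 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


@dataclass
class ProcrustesAnovaResults:
    """Fitted Procrustes ANOVA: per-term table and permutation settings."""

    table: pd.DataFrame  # rows: terms, Residuals, Total
    n_permutations: int
    seed: int
    formula: str

    def summary(self) -> str:
        lines = [
            f"Procrustes ANOVA (type II SS, RRPP, {self.n_permutations} "
            f"permutations, seed {self.seed})",
            f"shape ~ {self.formula}",
            self.table.to_string(float_format=lambda v: f"{v:.5g}"),
        ]
        return "\n".join(lines)

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p_perm"])


class ProcrustesAnova:
    """Linear model of flattened shape coordinates on a factorial design.

    Parameters
    ----------
    shape : AlignedSample or (n, k) array
        Aligned shape data; an AlignedSample is flattened internally.
    design : DataFrame
        One row per specimen, aligned with the shape rows; columns referred
        to by the formula may be categorical or numeric.
    formula : str
        Right-hand side over design columns, e.g. ``"habitat * municipality"``
        or ``"log_size"``.
    """

    def __init__(self, shape, design: pd.DataFrame,
                 formula: str = "habitat * municipality") -> None:
        self.y = shape.flat() if isinstance(shape, AlignedSample) else np.asarray(
            shape, dtype=float)
        if len(self.y) != len(design):
            raise ValueError("shape data and design have different lengths")
        if self.y.std() == 0:
            raise ValueError("constant shape data")
        self.design = design.reset_index(drop=True)
        self.formula = formula
        self.terms = _parse_formula(formula)
        self._blocks = {t: _term_block(self.design, t) for t in self.terms}

    def fit(self, n_perm: int = 999, seed: int = 0) -> ProcrustesAnovaResults:
        y = self.y
        n = len(y)
        intercept = np.ones((n, 1)) / np.sqrt(n)
        q_full = _ortho_basis(
            np.column_stack([np.ones((n, 1))] + [self._blocks[t] for t in self.terms])
        )
        df_res = n - q_full.shape[1]
        if df_res <= 0:
            raise ValueError("no residual degrees of freedom")
        ss_total = float(((y - y.mean(axis=0)) ** 2).sum())
        rss_full = float((y**2).sum() - ((q_full.T @ y) ** 2).sum())

        def contains(u: str, t: str) -> bool:
            return set(t.split(":")) < set(u.split(":"))

        rng = np.random.default_rng(seed)
        perms = np.stack([rng.permutation(n) for _ in range(n_perm)])

        rows = []
        for t in self.terms:
            others = [u for u in self.terms if u != t and not contains(u, t)]
            x_red = np.column_stack(
                [np.ones((n, 1))] + [self._blocks[u] for u in others]
            )
            q_red = _ortho_basis(x_red)
            q_t = _ortho_basis(self._blocks[t], against=q_red)
            df_t = q_t.shape[1]
            if df_t == 0:
                raise ValueError(f"term {t!r} has zero degrees of freedom")
            ss_t = float(((q_t.T @ y) ** 2).sum())
            f_obs = (ss_t / df_t) / (rss_full / df_res)

            fitted = q_red @ (q_red.T @ y)
            resid = y - fitted
            f_null = _rrpp_f(fitted, resid, perms, q_t, q_full, df_t, df_res)
            p = (np.count_nonzero(f_null >= f_obs) + 1) / (n_perm + 1)
            sd = f_null.std(ddof=1)
            z = (f_obs - f_null.mean()) / sd if sd > 0 else np.nan
            rows.append({
                "term": t, "df": df_t, "SS": ss_t, "MS": ss_t / df_t,
                "R2": ss_t / ss_total, "F": f_obs, "Z": z, "p_perm": p,
            })
        rows.append({
            "term": "Residuals", "df": df_res, "SS": rss_full,
            "MS": rss_full / df_res, "R2": rss_full / ss_total,
            "F": np.nan, "Z": np.nan, "p_perm": np.nan,
        })
        rows.append({
            "term": "Total", "df": n - 1, "SS": ss_total, "MS": np.nan,
            "R2": 1.0, "F": np.nan, "Z": np.nan, "p_perm": np.nan,
        })
        table = pd.DataFrame(rows).set_index("term")
        return ProcrustesAnovaResults(
            table=table, n_permutations=n_perm, seed=seed, formula=self.formula
        )


def _rrpp_f(fitted: np.ndarray, resid: np.ndarray, perms: np.ndarray,
            q_t: np.ndarray, q_full: np.ndarray, df_t: int, df_res: int,
            chunk: int = 64) -> np.ndarray:
    """F statistics of one term under residual randomization (batched)."""
    n_perm = len(perms)
    out = np.empty(n_perm)
    qt_f = q_t.T @ fitted
    qfull_f = q_full.T @ fitted
    norm_fitted = float((fitted**2).sum())
    norm_resid = float((resid**2).sum())
    for lo in range(0, n_perm, chunk):
        p_idx = perms[lo : lo + chunk]
        e = resid[p_idx]  # (c, n, k)
        qt_e = np.matmul(q_t.T[None], e)
        qfull_e = np.matmul(q_full.T[None], e)
        cross = np.einsum("nk,cnk->c", fitted, e)
        ss_t = ((qt_f[None] + qt_e) ** 2).sum(axis=(1, 2))
        norm_y = norm_fitted + 2 * cross + norm_resid
        rss = norm_y - ((qfull_f[None] + qfull_e) ** 2).sum(axis=(1, 2))
        out[lo : lo + len(p_idx)] = (ss_t / df_t) / (rss / df_res)
    return out


def procrustes_anova(aligned, design: pd.DataFrame,
                     formula: str = "habitat * municipality",
                     n_perm: int = 999, seed: int = 0) -> ProcrustesAnovaResults:
    """Convenience wrapper: build and fit a :class:`ProcrustesAnova`."""
    return ProcrustesAnova(aligned, design, formula).fit(n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# disparity

@dataclass
class DisparityResult:
    """Per-group Procrustes variance with a permutation test on differences."""

    procrustes_variance: dict
    pairwise_abs_diff: dict
    pairwise_p: dict
    relative_excess: dict  # (a, b) -> (PV_a - PV_b) / PV_b
    n_permutations: int
    seed: int

    def summary(self) -> str:
        lines = ["Morphological disparity (Procrustes variance of residuals)"]
        for g, pv in self.procrustes_variance.items():
            lines.append(f"  {g}: PV = {pv:.6g}")
        for pair, d in self.pairwise_abs_diff.items():
            lines.append(
                f"  |PV({pair[0]}) - PV({pair[1]})| = {d:.6g}, "
                f"p = {self.pairwise_p[pair]:.4g}, "
                f"relative excess = {self.relative_excess[pair]:+.1%}"
            )
        return "\n".join(lines)


def _group_pv(resid: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    pv = np.empty(n_groups)
    for g in range(n_groups):
        r = resid[codes == g]
        pv[g] = ((r - r.mean(axis=0)) ** 2).sum() / len(r)
    return pv


def morphological_disparity(
    aligned, groups, covariate_groups=None, n_perm: int = 999, seed: int = 0
) -> DisparityResult:
    """Shape disparity per group, optionally adjusting for a covariate factor.

    Disparity is the Procrustes variance: the mean squared Procrustes
    distance of each specimen from its group mean, computed on the
    residuals of a linear model on ``covariate_groups`` when given.  The
    absolute pairwise difference in Procrustes variance is tested by
    permuting group labels.
    """
    y = aligned.flat() if isinstance(aligned, AlignedSample) else np.asarray(aligned)
    groups = pd.Series(list(groups)).reset_index(drop=True)
    labels = sorted(groups.unique())
    codes = groups.map({g: i for i, g in enumerate(labels)}).to_numpy()
    counts = np.bincount(codes, minlength=len(labels))
    if counts.min() < 3:
        raise ValueError("every group needs at least 3 specimens")

    if covariate_groups is not None:
        design = pd.DataFrame({"g": list(covariate_groups)})
        x = np.column_stack([np.ones(len(y)), _term_block(design, "g")])
        q = _ortho_basis(x)
        resid = y - q @ (q.T @ y)
    else:
        resid = y - y.mean(axis=0)

    pv_obs = _group_pv(resid, codes, len(labels))
    rng = np.random.default_rng(seed)
    pairs = [
        (labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]
    obs_diff = {
        (a, b): abs(pv_obs[labels.index(a)] - pv_obs[labels.index(b)])
        for a, b in pairs
    }
    exceed = {pair: 0 for pair in pairs}
    for _ in range(n_perm):
        perm_codes = rng.permutation(codes)
        pv = _group_pv(resid, perm_codes, len(labels))
        for a, b in pairs:
            if abs(pv[labels.index(a)] - pv[labels.index(b)]) >= obs_diff[(a, b)]:
                exceed[(a, b)] += 1
    p = {pair: (exceed[pair] + 1) / (n_perm + 1) for pair in pairs}
    rel = {
        (a, b): (pv_obs[labels.index(a)] - pv_obs[labels.index(b)])
        / pv_obs[labels.index(b)]
        for a, b in pairs
    }
    return DisparityResult(
        procrustes_variance={g: float(pv_obs[i]) for i, g in enumerate(labels)},
        pairwise_abs_diff={k: float(v) for k, v in obs_diff.items()},
        pairwise_p=p,
        relative_excess={k: float(v) for k, v in rel.items()},
        n_permutations=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ordination

@dataclass
class PcaResult:
    """Eigen-decomposition of shape covariance with shape projections."""

    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    scores: np.ndarray  # (n, n_axes)
    axes: np.ndarray  # (n_axes, k) loading vectors, unit norm
    center: np.ndarray  # (k,) mean shape used for centering
    extreme_shapes: list  # per axis: (min_shape, max_shape) as (p, 2) arrays
    group_mean_scores: pd.DataFrame | None = None

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)

    def summary(self) -> str:
        rows = [
            f"  PC{i + 1}: {pct:.1f}% of variance"
            for i, pct in enumerate(self.percent_variance[:5])
        ]
        return "Shape PCA\n" + "\n".join(rows)


def _project_extremes(scores: np.ndarray, axes: np.ndarray,
                      center: np.ndarray) -> list:
    out = []
    p2 = center.size // 2
    for i in range(axes.shape[0]):
        lo = center + scores[:, i].min() * axes[i]
        hi = center + scores[:, i].max() * axes[i]
        out.append((lo.reshape(p2, 2), hi.reshape(p2, 2)))
    return out


def shape_pca(aligned) -> PcaResult:
    """Principal components of the flattened aligned coordinates.

    Axes are ordered by descending eigenvalue; per-axis extreme shapes are
    the consensus displaced to the minimum and maximum observed score.
    """
    y = aligned.flat() if isinstance(aligned, AlignedSample) else np.asarray(aligned)
    if len(y) < 3:
        raise ValueError("PCA needs at least 3 specimens")
    center = y.mean(axis=0)
    yc = y - center
    u, s, vt = np.linalg.svd(yc, full_matrices=False)
    nonnull = s**2 > (s.max() ** 2) * 1e-12 if s.max() > 0 else s > -1
    s, vt, u = s[nonnull], vt[nonnull], u[:, nonnull]
    eig = s**2 / (len(y) - 1)
    scores = u * s
    return PcaResult(
        eigenvalues=eig,
        percent_variance=100.0 * eig / eig.sum(),
        scores=scores,
        axes=vt,
        center=center,
        extreme_shapes=_project_extremes(scores, vt, center),
    )


def between_group_pca(aligned, groups) -> PcaResult:
    """PCA of group mean shapes, with all specimens projected onto the axes.

    Axis count is at most (number of groups - 1).
    """
    y = aligned.flat() if isinstance(aligned, AlignedSample) else np.asarray(aligned)
    groups = pd.Series(list(groups)).reset_index(drop=True)
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError("between-group PCA needs at least 2 groups")
    means = np.stack([y[(groups == g).to_numpy()].mean(axis=0) for g in labels])
    center = means.mean(axis=0)
    u, s, vt = np.linalg.svd(means - center, full_matrices=False)
    vt = vt[: len(labels) - 1]
    s = s[: len(labels) - 1]
    eig = s**2 / max(len(labels) - 1, 1)
    scores = (y - center) @ vt.T
    total = eig.sum()
    pct = 100.0 * eig / total if total > 0 else np.zeros_like(eig)
    group_scores = pd.DataFrame(
        (means - center) @ vt.T,
        index=labels,
        columns=[f"bgPC{i + 1}" for i in range(vt.shape[0])],
    )
    return PcaResult(
        eigenvalues=eig,
        percent_variance=pct,
        scores=scores,
        axes=vt,
        center=center,
        extreme_shapes=_project_extremes(scores, vt, center),
        group_mean_scores=group_scores,
    )


def group_mean_shapes(shapes, groups, space: str = "procrustes") -> dict:
    """Arithmetic mean shape per group.

    ``space="procrustes"`` expects an AlignedSample (or (n, p, 2) array) of
    aligned coordinates.  ``space="pre_alignment_mm"`` expects unaligned
    (n, p, 2) mm coordinates and registers them by translation only (common
    centroid) before averaging, so absolute size differences survive.
    """
    if isinstance(shapes, AlignedSample):
        coords = shapes.coords
    else:
        coords = np.asarray(shapes, dtype=float)
    groups = pd.Series(groups).reset_index(drop=True)
    if space == "pre_alignment_mm":
        coords = coords - coords.mean(axis=1, keepdims=True)
    elif space != "procrustes":
        raise ValueError(f"unknown space {space!r}")
    if isinstance(groups.dtype, pd.CategoricalDtype):
        levels = list(groups.cat.categories)
    else:
        levels = sorted(groups.unique())
    out = {}
    for g in levels:
        mask = (groups == g).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        out[g] = coords[mask].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# canonical variate analysis

@dataclass
class CvaResult:
    """CVA in retained-PC space, axes scaled to unit within-group variance."""

    scores: np.ndarray  # (n, g-1) canonical scores
    axes_scorespace: np.ndarray  # (g-1, r) axes in retained-PC space
    shape_axes: np.ndarray  # (g-1, k) unit-norm axes mapped to shape space
    percent_variation: np.ndarray  # share of total shape variance per axis
    separation: float  # |mean score difference| on CV1 (2-group case)
    group_means: pd.DataFrame
    groups: list
    n_retained: int
    extreme_shapes: list
    null_summary: dict | None = None

    def summary(self) -> str:
        lines = [
            f"CVA ({len(self.groups)} groups, {self.n_retained} retained PCs)",
            f"  CV1 captures {self.percent_variation[0]:.2f}% of shape variance",
            f"  group separation on CV1: {self.separation:.3f} "
            "(within-group sd units)",
        ]
        if self.null_summary is not None:
            ns = self.null_summary
            lines.append(
                f"  label-randomization null ({ns['n_rand']} draws, seed "
                f"{ns['seed']}): mean {ns['mean']:.3f}, sd {ns['sd']:.3f}, "
                f"max {ns['max']:.3f}; observed "
                f"{'exceeds' if ns['observed_exceeds_max'] else 'within'} null max"
            )
        return "\n".join(lines)


def _retained_scores(y: np.ndarray, n_groups: int, retain_variance: float):
    center = y.mean(axis=0)
    yc = y - center
    u, s, vt = np.linalg.svd(yc, full_matrices=False)
    eig = s**2
    eig_frac = np.cumsum(eig) / eig.sum()
    r_var = int(np.searchsorted(eig_frac, retain_variance) + 1)
    r_max = len(y) - n_groups - 1
    r = max(1, min(r_var, r_max, int((s > 1e-12 * s.max()).sum())))
    z = (u * s)[:, :r]
    return z, vt[:r], center, float(((yc) ** 2).sum() / (len(y) - 1))


def cva(aligned, groups, retain_variance: float = 0.95) -> CvaResult:
    """Canonical variate analysis of shape by group.

    The shape data are first reduced to principal-component scores
    retaining the smaller of (axes explaining ``retain_variance`` of the
    variance) and (n - g - 1) dimensions.  CV axes solve the generalized
    eigenproblem of between-group versus pooled within-group covariance in
    that score space and are scaled so pooled within-group score variance
    is 1; a 2-group analysis yields exactly one axis.
    """
    y = aligned.flat() if isinstance(aligned, AlignedSample) else np.asarray(aligned)
    groups = pd.Series(list(groups)).reset_index(drop=True)
    labels = sorted(groups.unique())
    g = len(labels)
    if g < 2:
        raise ValueError("CVA needs at least 2 groups")
    z, v_ret, center, total_var = _retained_scores(y, g, retain_variance)
    return _cva_core(z, v_ret, center, total_var, y, groups, labels)


def _cva_core(z, v_ret, center, total_var, y, groups, labels) -> CvaResult:
    n, r = z.shape
    g = len(labels)
    codes = groups.map({lab: i for i, lab in enumerate(labels)}).to_numpy()
    grand = z.mean(axis=0)
    w = np.zeros((r, r))
    b = np.zeros((r, r))
    means = np.empty((g, r))
    for i in range(g):
        zi = z[codes == i]
        means[i] = zi.mean(axis=0)
        dev = zi - means[i]
        w += dev.T @ dev
        d = (means[i] - grand)[:, None]
        b += len(zi) * (d @ d.T)
    w /= n - g
    b /= g - 1
    try:
        evals, evecs = scipy.linalg.eigh(b, w)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError(
            "singular within-group covariance; retain fewer PC dimensions"
        ) from exc
    order = np.argsort(evals)[::-1][: g - 1]
    a = evecs[:, order].T  # (g-1, r); eigh normalizes a' W a = 1
    scores = (z - grand) @ a.T
    shape_axes = a @ v_ret
    shape_axes = shape_axes / np.linalg.norm(shape_axes, axis=1, keepdims=True)
    yc = y - y.mean(axis=0)
    proj_var = ((yc @ shape_axes.T) ** 2).sum(axis=0) / (n - 1)
    group_means = pd.DataFrame(
        (means - grand) @ a.T, index=labels,
        columns=[f"CV{i + 1}" for i in range(g - 1)],
    )
    if g == 2:
        separation = float(abs(group_means.iloc[0, 0] - group_means.iloc[1, 0]))
    else:
        separation = float(np.abs(group_means.iloc[:, 0].to_numpy()[:, None]
                                  - group_means.iloc[:, 0].to_numpy()).max())
    return CvaResult(
        scores=scores,
        axes_scorespace=a,
        shape_axes=shape_axes,
        percent_variation=100.0 * proj_var / total_var,
        separation=separation,
        group_means=group_means,
        groups=labels,
        n_retained=r,
        extreme_shapes=_project_extremes(scores, shape_axes, center),
    )


def cva_randomization_null(
    aligned, groups, n_rand: int = 100, seed: int = 0,
    retain_variance: float = 0.95,
) -> CvaResult:
    """CVA plus a label-randomization null for its group separation.

    Group labels are permuted ``n_rand`` times preserving group sizes and
    the full CVA re-run each time; the summary reports the mean, sd and
    maximum null separation and whether the observed separation exceeds
    the null maximum.  CVA axes can separate arbitrary labels by chance in
    high dimensions, so only comparison against this null is meaningful.
    """
    if n_rand < 2:
        raise ValueError("need at least 2 randomizations")
    y = aligned.flat() if isinstance(aligned, AlignedSample) else np.asarray(aligned)
    groups = pd.Series(list(groups)).reset_index(drop=True)
    labels = sorted(groups.unique())
    z, v_ret, center, total_var = _retained_scores(y, len(labels), retain_variance)
    observed = _cva_core(z, v_ret, center, total_var, y, groups, labels)
    rng = np.random.default_rng(seed)
    seps = np.empty(n_rand)
    garr = groups.to_numpy()
    for i in range(n_rand):
        perm = pd.Series(rng.permutation(garr))
        seps[i] = _cva_core(z, v_ret, center, total_var, y, perm, labels).separation
    observed.null_summary = {
        "n_rand": n_rand,
        "seed": seed,
        "mean": float(seps.mean()),
        "sd": float(seps.std(ddof=1)),
        "max": float(seps.max()),
        "observed": observed.separation,
        "observed_exceeds_max": bool(observed.separation > seps.max()),
        "null_separations": seps,
    }
    return observed


# ---------------------------------------------------------------------------
# allometry

def allometry_test(aligned, size, n_perm: int = 999, seed: int = 0):
    """Procrustes regression of shape on log size, plus PC-size correlations.

    ``size`` may be centroid size, a measured area, or body length; it must
    be positive.  Returns the RRPP ANOVA results and a dict of Pearson
    correlations of PC1-PC3 scores with log size.
    """
    size = np.asarray(size, dtype=float)
    if np.any(size <= 0):
        raise ValueError("size values must be positive")
    design = pd.DataFrame({"log_size": np.log(size)})
    res = ProcrustesAnova(aligned, design, "log_size").fit(n_perm=n_perm, seed=seed)
    pca = shape_pca(aligned)
    corrs = {}
    for i in range(min(3, pca.scores.shape[1])):
        r, _ = scipy.stats.pearsonr(pca.scores[:, i], np.log(size))
        corrs[f"PC{i + 1}"] = float(r)
    return res, corrs
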