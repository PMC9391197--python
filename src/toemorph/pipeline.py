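"""End-to-end orchestration: ingest, align, measure, analyze, report.

`run_pipeline` executes the full analysis sequence on either real TPS +
metadata inputs or a synthetic population specification: validation,
anchor stripping, side mirroring, generalized Procrustes alignment with
sliding, the multivariate shape analyses (Procrustes ANOVA, disparity,
PCA, between-group PCA, CVA with randomization null, allometry), and the
linear-measurement battery with its GLM ANOVAs.  All tables, plots, and a
JSON manifest of versions and seeds are written to the output directory;
re-running with the same configuration reproduces every numeric output.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__, gpa, linear_stats, scheme as scheme_mod, shape_stats
from .scheme import (
    Configuration,
    LandmarkScheme,
    default_scheme,
    mirror_configuration,
    strip_anchor_semilandmarks,
    validate_configuration,
)
from .synthetic import PopulationSpec, sample_population
from .tps_io import Dataset, assemble_dataset, read_metadata, read_tps, write_tps

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    tps_path: str | None = None
    metadata_path: str | None = None
    synthetic: PopulationSpec | None = None
    default_dpi: float | None = None
    scheme_path: str | None = None
    gpa_max_iter: int = 100
    gpa_tol: float = 1e-6
    slide: bool = True
    n_perm: int = 999
    n_cva_rand: int = 100
    retain_variance: float = 0.95
    seed: int = 0
    outdir: str = "toemorph_results"
    make_plots: bool = True

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["synthetic"] = None if self.synthetic is None else "PopulationSpec"
        return d


@dataclass
class ResultBundle:
    """Typed results of a full pipeline run."""

    dataset: Dataset
    configs: list[Configuration]
    aligned: gpa.AlignedSample
    measurements: pd.DataFrame
    anova: shape_stats.ProcrustesAnovaResults
    disparity: shape_stats.DisparityResult
    pca: shape_stats.PcaResult
    bgpca: shape_stats.PcaResult
    cva: shape_stats.CvaResult
    allometry: tuple
    ratio_tests: dict
    glm_tables: dict
    manifest: dict = field(default_factory=dict)


def prepare_configurations(
    dataset: Dataset, scheme: LandmarkScheme, strip_tol_mm: float = 1e-6
) -> list[Configuration]:
    """Validate, strip anchor semilandmarks, and mirror right-side records."""
    configs = []
    for rec in dataset.records:
        side = "left"
        if "side" in dataset.metadata.columns:
            side = str(dataset.metadata.loc[rec.specimen_id, "side"])
        config = validate_configuration(rec, scheme, side=side)
        config = strip_anchor_semilandmarks(config, scheme, tol_mm=strip_tol_mm)
        config = mirror_configuration(config)
        configs.append(config)
    return configs


def run_pipeline(config: RunConfig) -> ResultBundle:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sch = (
        scheme_mod.load_scheme(config.scheme_path)
        if config.scheme_path
        else default_scheme()
    )

    if config.synthetic is not None:
        sample = sample_population(config.synthetic, sch)
        sample.write(
            outdir / "synthetic.tps",
            outdir / "synthetic_metadata.csv",
            outdir / "synthetic_truth.csv",
        )
        dataset = sample.to_dataset()
    elif config.tps_path and config.metadata_path:
        records = read_tps(config.tps_path)
        metadata = read_metadata(config.metadata_path)
        dataset = assemble_dataset(records, metadata, default_dpi=config.default_dpi)
    else:
        raise ValueError("RunConfig needs either input paths or a synthetic spec")

    configs = prepare_configurations(dataset, sch)
    meta = dataset.metadata.reset_index(drop=True)

    aligned = gpa.gpa_align(
        configs, sch, max_iter=config.gpa_max_iter, tol=config.gpa_tol,
        slide=config.slide,
    )

    measurements = linear_stats.measurement_table(configs, sch, meta)

    anova = shape_stats.procrustes_anova(
        aligned, meta, "habitat * municipality",
        n_perm=config.n_perm, seed=config.seed,
    )
    disparity = shape_stats.morphological_disparity(
        aligned, meta["habitat"], covariate_groups=meta["municipality"],
        n_perm=config.n_perm, seed=config.seed + 1,
    )
    pca = shape_stats.shape_pca(aligned)
    bgpca = shape_stats.between_group_pca(aligned, meta["habitat"])
    cva_res = shape_stats.cva_randomization_null(
        aligned, meta["habitat"], n_rand=config.n_cva_rand,
        seed=config.seed + 2, retain_variance=config.retain_variance,
    )
    allometry = shape_stats.allometry_test(
        aligned, aligned.centroid_sizes, n_perm=config.n_perm,
        seed=config.seed + 3,
    )
    ratio_tests = linear_stats.ratio_analysis(measurements)
    glm_tables = {
        name: linear_stats.glm_anova_type2(measurements, name)
        for name in linear_stats.GLM_MODELS
    }

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "statsmodels": linear_stats.sm_version(),
        "config": config.to_dict(),
        "seeds": {
            "anova": config.seed, "disparity": config.seed + 1,
            "cva_null": config.seed + 2, "allometry": config.seed + 3,
        },
        "n_specimens": len(configs),
        "n_dropped": len(dataset.dropped),
        "gpa_iterations": aligned.iterations_run,
        "gpa_converged": aligned.converged,
        "sliding_passes": len(aligned.sliding_log),
    }

    bundle = ResultBundle(
        dataset=dataset, configs=configs, aligned=aligned,
        measurements=measurements, anova=anova, disparity=disparity,
        pca=pca, bgpca=bgpca, cva=cva_res, allometry=allometry,
        ratio_tests=ratio_tests, glm_tables=glm_tables, manifest=manifest,
    )
    _write_outputs(bundle, outdir, config)
    return bundle


def _write_outputs(bundle: ResultBundle, outdir: Path, config: RunConfig) -> None:
    aligned = bundle.aligned
    n, p, _ = aligned.coords.shape
    flat = pd.DataFrame(
        aligned.flat(),
        index=pd.Index(aligned.specimen_ids, name="specimen_id"),
        columns=[f"{ax}{i + 1}" for i in range(p) for ax in ("x", "y")],
    )
    flat.to_csv(outdir / "aligned_coordinates.csv")
    bundle.measurements.to_csv(outdir / "measurements.csv", index=False)
    bundle.anova.table.to_csv(outdir / "procrustes_anova.csv")

    sch = scheme_mod.default_scheme() if config.scheme_path is None else (
        scheme_mod.load_scheme(config.scheme_path))
    shape_records = [_shape_record(aligned.consensus, sch, "consensus")]
    for i, (lo, hi) in enumerate(bundle.cva.extreme_shapes, start=1):
        shape_records.append(_shape_record(lo, sch, f"CV{i}_min"))
        shape_records.append(_shape_record(hi, sch, f"CV{i}_max"))
    write_tps(shape_records, outdir / "projected_shapes.tps")

    disp = bundle.disparity
    pd.DataFrame([
        {
            "group_a": a, "group_b": b,
            "pv_a": disp.procrustes_variance[a],
            "pv_b": disp.procrustes_variance[b],
            "abs_diff": diff, "p": disp.pairwise_p[(a, b)],
            "relative_excess": disp.relative_excess[(a, b)],
        }
        for (a, b), diff in disp.pairwise_abs_diff.items()
    ]).to_csv(outdir / "disparity.csv", index=False)

    pd.DataFrame([
        {
            "comparison": name, "transform": res.transform,
            "t": res.statistic, "df": res.df, "p": res.p,
            "mean_urban": res.back_mean_a, "mean_forest": res.back_mean_b,
        }
        for name, res in bundle.ratio_tests.items()
        if name != "raw_ratio_means"
    ]).to_csv(outdir / "linear_tests.csv", index=False)
    for name, table in bundle.glm_tables.items():
        table.to_csv(outdir / f"glm_{name}.csv")
    scores = pd.DataFrame(
        bundle.pca.scores[:, :10],
        index=pd.Index(aligned.specimen_ids, name="specimen_id"),
        columns=[f"PC{i + 1}" for i in range(min(10, bundle.pca.scores.shape[1]))],
    )
    scores["CV1"] = bundle.cva.scores[:, 0]
    scores.to_csv(outdir / "ordination_scores.csv")

    report = _render_report(bundle)
    (outdir / "report.md").write_text(report, encoding="utf-8")
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.manifest, fh, indent=2, default=str)

    if config.make_plots:
        qc_overlays(bundle.configs, aligned, outdir)
        _ordination_plots(bundle, outdir)


def _shape_record(points: np.ndarray, sch: LandmarkScheme, name: str):
    """Package a flattened shape (consensus or projection) as a TPS record."""
    from .tps_io import RawRecord

    config = scheme_mod.unflatten(np.asarray(points), sch, specimen_id=name)
    return RawRecord(name, config.fixed_points, list(config.curve_points))


def _render_report(bundle: ResultBundle) -> str:
    pct = bundle.pca.percent_variance
    parts = [
        "# Toe shape analysis report",
        f"Specimens analyzed: {bundle.manifest['n_specimens']} "
        f"(dropped: {bundle.manifest['n_dropped']})",
        "",
        "## Procrustes ANOVA",
        bundle.anova.summary(),
        "",
        "## Disparity",
        bundle.disparity.summary(),
        "",
        "## Ordination",
        f"PC1 {pct[0]:.1f}%, PC2 {pct[1]:.1f}%, PC3 {pct[2]:.1f}% of variance",
        bundle.cva.summary(),
        "",
        "## Linear measurements (urban vs forest)",
    ]
    for name, res in bundle.ratio_tests.items():
        if name == "raw_ratio_means":
            parts.append(
                f"- raw width/length ratio means: urban {res['urban']:.3f}, "
                f"forest {res['forest']:.3f}"
            )
            continue
        parts.append(
            f"- {name} ({res.transform}): t = {res.statistic:.2f}, "
            f"df = {res.df:.1f}, p = {res.p:.4g}"
        )
    parts.append("")
    parts.append("## GLM ANOVAs (type II)")
    for name, table in bundle.glm_tables.items():
        parts.append(f"### {name}")
        parts.append(table.to_string(float_format=lambda v: f"{v:.4g}"))
    return "\n".join(parts)


def qc_overlays(
    configs: list[Configuration], aligned: gpa.AlignedSample, outdir
) -> pd.DataFrame:
    """Pre/post-alignment all-specimen overlays plus an outlier ranking.

    The outlier score is each specimen's Procrustes distance to the
    consensus, listed descending (ties broken by specimen id) for review
    of bent or misdigitized toes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fig, axes = plt.subplots(1, 2, figsize=(10, 5))
    for config in configs:
        pts = np.vstack([config.fixed_points, *config.curve_points])
        pts = pts - pts.mean(axis=0)
        axes[0].plot(pts[:, 0], pts[:, 1], ".", ms=1, alpha=0.3)
    axes[0].set_title("before alignment (centered, mm)")
    for shape in aligned.coords:
        axes[1].plot(shape[:, 0], shape[:, 1], ".", ms=1, alpha=0.3)
    axes[1].plot(aligned.consensus[:, 0], aligned.consensus[:, 1], "k.", ms=3)
    axes[1].set_title("after Procrustes alignment")
    for ax in axes:
        ax.set_aspect("equal")
    fig.savefig(outdir / "qc_overlays.png", dpi=120)
    plt.close(fig)

    scores = pd.DataFrame({
        "specimen_id": aligned.specimen_ids,
        "outlier_score": aligned.distances_to_consensus(),
    }).sort_values(
        ["outlier_score", "specimen_id"], ascending=[False, True]
    ).reset_index(drop=True)
    scores.to_csv(outdir / "outlier_scores.csv", index=False)
    return scores


def _ordination_plots(bundle: ResultBundle, outdir: Path) -> None:
    meta = bundle.dataset.metadata.reset_index(drop=True)
    habitat = meta["habitat"].to_numpy()
    colors = {"urban": "0.4", "forest": "forestgreen"}
    fig, ax = plt.subplots(figsize=(6, 5))
    for hab in np.unique(habitat):
        m = habitat == hab
        ax.scatter(bundle.pca.scores[m, 0], bundle.pca.scores[m, 1],
                   s=12, alpha=0.6, label=hab, color=colors.get(hab))
    ax.set_xlabel(f"PC1 ({bundle.pca.percent_variance[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({bundle.pca.percent_variance[1]:.1f}%)")
    ax.legend()
    fig.savefig(outdir / "pca_scores.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for hab in np.unique(habitat):
        ax.hist(bundle.cva.scores[habitat == hab, 0], bins=20, alpha=0.6,
                label=hab, color=colors.get(hab))
    ax.set_xlabel("CV1 score")
    ax.legend()
    fig.savefig(outdir / "cva_histogram.png", dpi=120)
    plt.close(fig)

    means = shape_stats.group_mean_shapes(bundle.aligned, habitat)
    fig, ax = plt.subplots(figsize=(5, 6))
    for hab, shape in means.items():
        ax.plot(shape[:, 0], shape[:, 1], ".", label=hab, color=colors.get(hab))
    ax.set_aspect("equal")
    ax.legend()
    ax.set_title("mean aligned shapes")
    fig.savefig(outdir / "mean_shapes.png", dpi=120)
    plt.close(fig)
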