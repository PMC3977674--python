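"""End-to-end pipeline: simulate -> build-models -> analyze -> stats -> report.

Each stage reads/writes plain files under one output directory so stages can
be re-run independently:

    data/       stimulus PNG masks, fixations.csv, manifest.txt
    models/     ROI mask PNGs, part-cut CSVs, model diagnostics
    analysis/   mmc.csv (participant,group,model,mmc), metrics.csv
    stats/      anova.csv, comparisons.csv, metric_tests.csv
    report/     report.txt, mmc_means.png
    run_manifest.txt   config echo + master seed (written by `all`)

All randomness flows from the single master seed in the config (or the
``--seed`` override) through per-stage derived seeds, so a re-run with the
same config and seed reproduces every output byte for byte.
"""

from __future__ import annotations

import configparser
import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .contour import extract_contour
from .fixations import preprocess, read_fixations, scanpath_metrics
from .geometry import ViewingGeometry
from .overlap import FroaConfig, run_froa
from .roi import PolarityParams, RoiMask, build_all_models, build_part_boundary_mask, \
    compute_part_cuts, detect_concavity_extrema
from .stats import mixed_anova, planned_comparisons, two_sample_tests
from .synthetic import ExperimentDesign, GroupSpec, ScanPathConfig, generate_experiment

__all__ = ["PipelineConfig", "load_config", "run", "ConfigError"]

logger = logging.getLogger(__name__)

MODEL_LABELS = ("concave", "convex", "part_boundary")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class GroupConfig:
    name: str
    roi_preference: float = 0.0
    target_model: str | None = None
    step_mean: float | None = None
    step_shape: float = 3.0
    duration_mean: float = 197.0
    duration_shape: float = 18.0


@dataclass
class PipelineConfig:
    seed: int = 0
    geometry: ViewingGeometry = field(default_factory=ViewingGeometry)
    families: tuple[str, ...] = ("dumbbell", "elbow")
    jitter: tuple[float, float] = (0.95, 1.15)
    n_participants_per_group: int = 4
    n_trials: int = 6
    n_fixations: int = 8
    groups: list[GroupConfig] = field(default_factory=list)
    smoothing_sigma: float = 15.0
    polarity: PolarityParams = field(default_factory=PolarityParams)
    prominence: float = 0.01
    band_px: float = 8.0
    froa: FroaConfig = field(default_factory=FroaConfig)
    pooled: bool = True
    bonferroni: bool = False

    def validate(self) -> None:
        if self.froa.n_iterations < 100:
            raise ConfigError("froa.n_iterations must be >= 100")
        if self.froa.region_radius_deg <= 0:
            raise ConfigError("froa.region_radius_deg must be positive")
        if self.n_participants_per_group < 2:
            raise ConfigError("need >= 2 participants per group")
        if self.n_trials < 1 or self.n_fixations < 2:
            raise ConfigError("n_trials >= 1 and n_fixations >= 2 required")
        if self.smoothing_sigma < 1 or self.prominence <= 0 or self.band_px < 1:
            raise ConfigError("shape-model parameters out of range")
        if len(self.groups) != 2:
            raise ConfigError("exactly two task groups are required")
        for g in self.groups:
            if not 0 <= g.roi_preference <= 1:
                raise ConfigError(f"group {g.name}: roi_preference outside [0, 1]")
            if g.target_model is not None and g.target_model not in MODEL_LABELS:
                raise ConfigError(f"group {g.name}: unknown target_model {g.target_model!r}")


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a flat INI config; ``path='demo'`` loads the packaged demo."""
    parser = configparser.ConfigParser(interpolation=None)
    if str(path) == "demo":
        text = importlib.resources.files("froa.data").joinpath("demo.ini").read_text()
        parser.read_string(text)
    else:
        if not Path(path).exists():
            raise ConfigError(f"config file not found: {path}")
        parser.read(path)

    def get(section, key, cast, default):
        if parser.has_option(section, key):
            raw = parser.get(section, key).strip()
            if raw == "":
                return None
            try:
                return cast(raw)
            except ValueError as e:
                raise ConfigError(f"[{section}] {key}: {e}") from e
        return default

    cfg = PipelineConfig()
    cfg.seed = get("run", "seed", int, 0)
    cfg.geometry = ViewingGeometry(
        get("geometry", "frame_px", int, 800), get("geometry", "frame_deg", float, 18.0)
    )
    fams = get("stimuli", "families", str, None)
    if fams:
        cfg.families = tuple(f.strip() for f in fams.split(",") if f.strip())
    cfg.jitter = (
        get("stimuli", "jitter_lo", float, 0.95),
        get("stimuli", "jitter_hi", float, 1.15),
    )
    cfg.n_participants_per_group = get("design", "n_participants_per_group", int, 4)
    cfg.n_trials = get("design", "n_trials", int, 6)
    cfg.n_fixations = get("design", "n_fixations", int, 8)
    for section in parser.sections():
        if not section.startswith("group."):
            continue
        name = section.split(".", 1)[1]
        cfg.groups.append(
            GroupConfig(
                name=name,
                roi_preference=get(section, "roi_preference", float, 0.0),
                target_model=get(section, "target_model", str, None),
                step_mean=get(section, "step_mean", float, None),
                step_shape=get(section, "step_shape", float, 3.0),
                duration_mean=get(section, "duration_mean", float, 197.0),
                duration_shape=get(section, "duration_shape", float, 18.0),
            )
        )
    if not cfg.groups:
        cfg.groups = [
            GroupConfig("basic", 0.8, "concave", duration_mean=198.15),
            GroupConfig("subordinate", 0.8, "concave", duration_mean=195.99),
        ]
    cfg.smoothing_sigma = get("shape_models", "smoothing_sigma", float, 15.0)
    cfg.polarity = PolarityParams(
        kappa_min=get("shape_models", "kappa_min", float, 0.005),
        r_min=get("shape_models", "r_min", float, 2.0),
        r_max=get("shape_models", "r_max", float, 20.0),
        kappa_sat=get("shape_models", "kappa_sat", float, 0.05),
    )
    cfg.prominence = get("shape_models", "prominence", float, 0.01)
    cfg.band_px = get("shape_models", "band_px", float, 8.0)
    cfg.froa = FroaConfig(
        region_radius_deg=get("froa", "region_radius_deg", float, 1.0),
        n_iterations=get("froa", "n_iterations", int, 1000),
        null_density=get("froa", "null_density", str, "uniform_object"),
        sidedness=get("froa", "sidedness", str, "one-sided"),
        seed=cfg.seed,
    )
    cfg.pooled = get("stats", "pooled", lambda s: s.lower() == "true", True)
    cfg.bonferroni = get("stats", "bonferroni", lambda s: s.lower() == "true", False)
    cfg.validate()
    return cfg


def _design(cfg: PipelineConfig) -> ExperimentDesign:
    groups = [
        GroupSpec(
            g.name,
            cfg.n_participants_per_group,
            ScanPathConfig(
                n_fixations=cfg.n_fixations,
                roi_preference=g.roi_preference,
                step_mean=g.step_mean,
                step_shape=g.step_shape,
                duration_mean=g.duration_mean,
                duration_shape=g.duration_shape,
            ),
            target_model=g.target_model,
        )
        for g in cfg.groups
    ]
    return ExperimentDesign(
        groups=groups,
        n_trials=cfg.n_trials,
        families=cfg.families,
        metric_jitter=cfg.jitter,
        geometry=cfg.geometry,
    )


def simulate(cfg: PipelineConfig, outdir: Path) -> Path:
    data_dir = Path(outdir) / "data"
    generate_experiment(_design(cfg), data_dir, seed=cfg.seed)
    logger.info("simulated dataset written to %s", data_dir)
    return data_dir


def _load_mask(path: Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) >= 128


def build_models(cfg: PipelineConfig, outdir: Path) -> Path:
    data_dir = Path(outdir) / "data"
    model_dir = Path(outdir) / "models"
    model_dir.mkdir(parents=True, exist_ok=True)
    diag_rows = []
    for png in sorted((data_dir / "stimuli").glob("*.png")):
        stim = png.stem
        sil = extract_contour(_load_mask(png))
        from .contour import compute_curvature

        curv = compute_curvature(sil, cfg.smoothing_sigma)
        from .roi import build_polarity_masks

        concave, convex = build_polarity_masks(curv, sil, cfg.polarity)
        extrema = detect_concavity_extrema(curv, cfg.prominence)
        cuts = compute_part_cuts(sil, extrema)
        part = build_part_boundary_mask(sil, cuts, cfg.band_px)
        for roi in (concave, convex, part):
            Image.fromarray(roi.mask.astype(np.uint8) * 255).save(
                model_dir / f"{stim}__{roi.label}.png"
            )
        pd.DataFrame(
            [
                (k, *c.endpoints[0], *c.endpoints[1], c.length)
                for k, c in enumerate(cuts)
            ],
            columns=["cut_id", "x1", "y1", "x2", "y2", "length_px"],
        ).to_csv(model_dir / f"{stim}__cuts.csv", index=False, float_format="%.3f",
                 lineterminator="\n")
        both = concave.mask & convex.mask
        union = concave.mask | convex.mask
        diag_rows.append(
            (stim, concave.area_px, convex.area_px, part.area_px, len(cuts),
             both.sum() / union.sum() if union.any() else 0.0)
        )
    pd.DataFrame(
        diag_rows,
        columns=["stimulus", "concave_px", "convex_px", "part_boundary_px",
                 "n_cuts", "polarity_overlap_frac"],
    ).to_csv(model_dir / "diagnostics.csv", index=False, float_format="%.4f",
             lineterminator="\n")
    logger.info("ROI models written to %s", model_dir)
    return model_dir


def analyze(cfg: PipelineConfig, outdir: Path) -> Path:
    outdir = Path(outdir)
    data_dir, model_dir = outdir / "data", outdir / "models"
    out = outdir / "analysis"
    out.mkdir(parents=True, exist_ok=True)
    fix = read_fixations(data_dir / "fixations.csv")
    stimuli = {p.stem: _load_mask(p) for p in sorted((data_dir / "stimuli").glob("*.png"))}
    roi_models: dict[str, dict[str, RoiMask]] = {}
    for stim in stimuli:
        roi_models[stim] = {
            label: RoiMask(_load_mask(model_dir / f"{stim}__{label}.png"), label)
            for label in MODEL_LABELS
        }
    mmc_table = run_froa(fix, stimuli, roi_models, cfg.geometry, cfg.froa)
    mmc_table.to_csv(out / "mmc.csv", index=False, float_format="%.6f", lineterminator="\n")
    retained, _ = preprocess(fix, cfg.geometry)
    scanpath_metrics(retained, cfg.geometry).to_csv(
        out / "metrics.csv", index=False, float_format="%.6f", lineterminator="\n"
    )
    logger.info("MMC table and scanpath metrics written to %s", out)
    return out


def stats(cfg: PipelineConfig, outdir: Path) -> Path:
    outdir = Path(outdir)
    out = outdir / "stats"
    out.mkdir(parents=True, exist_ok=True)
    mmc_table = pd.read_csv(outdir / "analysis" / "mmc.csv")
    metrics = pd.read_csv(outdir / "analysis" / "metrics.csv")
    anova = mixed_anova(mmc_table)
    anova.to_csv(out / "anova.csv", index=False, float_format="%.6g", lineterminator="\n")
    comps = planned_comparisons(mmc_table, bonferroni=cfg.bonferroni)
    pd.DataFrame(
        [(c.label, c.kind, c.statistic, c.df, c.p, c.note) for c in comps],
        columns=["contrast", "kind", "statistic", "df", "p", "note"],
    ).to_csv(out / "comparisons.csv", index=False, float_format="%.6g", lineterminator="\n")
    tests = two_sample_tests(metrics, pooled=cfg.pooled)
    pd.DataFrame(
        [(c.label, c.kind, c.statistic, c.df, c.p, c.note) for c in tests],
        columns=["contrast", "kind", "statistic", "df", "p", "note"],
    ).to_csv(out / "metric_tests.csv", index=False, float_format="%.6g", lineterminator="\n")
    logger.info("group statistics written to %s", out)
    return out


def report(cfg: PipelineConfig, outdir: Path) -> Path:
    outdir = Path(outdir)
    out = outdir / "report"
    out.mkdir(parents=True, exist_ok=True)
    anova = pd.read_csv(outdir / "stats" / "anova.csv")
    comps = pd.read_csv(outdir / "stats" / "comparisons.csv")
    tests = pd.read_csv(outdir / "stats" / "metric_tests.csv")
    mmc_table = pd.read_csv(outdir / "analysis" / "mmc.csv")

    lines = ["FROA pipeline report", "=" * 60, ""]
    lines.append("Mean MMC (percentage points above the 95% chance bound):")
    means = mmc_table.groupby(["group", "model"])["mmc"].agg(["mean", "sem"])
    for (g, m), r in means.iterrows():
        lines.append(f"  {g:>12s} {m:<14s} M = {r['mean']:7.2f}  SE = {r['sem']:.2f}")
    lines.append("")
    lines.append("Mixed ANOVA (Task x Model) on MMC:")
    df_between_err = int(anova.loc[anova["effect"].str.startswith("subjects"), "df"].iloc[0])
    df_within_err = int(anova.loc[anova["effect"].str.contains("x subjects"), "df"].iloc[0])
    for _, r in anova.iterrows():
        if np.isnan(r["F"]):
            continue
        err_df = df_between_err if r["effect"] == "group" else df_within_err
        lines.append(
            f"  {r['effect']:<16s} F({int(r['df'])}, {err_df}) "
            f"= {r['F']:.2f}, p = {r['p']:.4g}, pes = {r['pes']:.3f}"
        )
    lines.append("")
    lines.append("Planned comparisons:")
    for _, r in comps.iterrows():
        lines.append(f"  {r['contrast']:<40s} {r['kind']} = {r['statistic']:8.3f}, p = {r['p']:.4g}")
    lines.append("")
    lines.append("Scanpath metrics (between groups):")
    for _, r in tests.iterrows():
        dfs = "" if pd.isna(r["df"]) else f"({int(r['df'])})"
        lines.append(f"  {r['contrast']:<46s} {r['kind']}{dfs} = {r['statistic']:8.3f}, p = {r['p']:.4g}")
    (out / "report.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    piv = mmc_table.groupby(["model", "group"])["mmc"].mean().unstack()
    err = mmc_table.groupby(["model", "group"])["mmc"].sem().unstack()
    piv.plot.bar(yerr=err, ax=ax, rot=0)
    ax.set_ylabel("MMC (percentage points)")
    ax.set_xlabel("ROI model")
    ax.axhline(0, color="k", lw=0.8)
    fig.tight_layout()
    fig.savefig(out / "mmc_means.png", dpi=120)
    plt.close(fig)
    logger.info("report written to %s", out)
    return out


STAGES = {
    "simulate": simulate,
    "build-models": build_models,
    "analyze": analyze,
    "stats": stats,
    "report": report,
}


def run(subcommand: str, cfg: PipelineConfig, outdir: str | Path) -> Path:
    """Run one pipeline stage (or ``all``) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if subcommand == "all":
        for name in ("simulate", "build-models", "analyze", "stats", "report"):
            STAGES[name](cfg, outdir)
        manifest = [f"froa_version={__version__}", f"seed={cfg.seed}"]
        manifest += [f"{k}={v}" for k, v in sorted(vars(cfg).items()) if k != "groups"]
        for g in cfg.groups:
            manifest.append(f"group.{g.name}={g}")
        (outdir / "run_manifest.txt").write_text("\n".join(map(str, manifest)) + "\n")
        return outdir
    if subcommand not in STAGES:
        raise ConfigError(f"unknown subcommand {subcommand!r}")
    return STAGES[subcommand](cfg, outdir)
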