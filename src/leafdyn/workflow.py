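"""End-to-end pipeline: simulate (or ingest scans) -> extract -> dynamics
(3-day and 6-day) -> ANOVA screen -> SVM diagnosis -> report.

A single config object (YAML-serialisable) drives the run; every output is
a UTF-8 CSV with a header row, rows sorted deterministically and floats
printed with a fixed format, so two runs with the same seed are
byte-identical.  A manifest records the seed, the effective config and a
SHA-256 hash of every artifact.  Dropped or missing observations are
logged with machine-readable reasons, never silently discarded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diagnosis import SVMConfig, best_position_summary, evaluate_grid
from .dynamics import build_interval_scheme, dynamic_features, fit_report
from .imaging import FEATURE_COLUMNS, LeafImage, extract_batch
from .screening import anova_grid, screen_features
from .synthetic import DEFAULT_PROFILES, ExperimentConfig, generate_experiment

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


@dataclass
class PipelineConfig:
    """Source of truth for one pipeline run."""

    out_dir: str = "run"
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    images_dir: str | None = None        # set -> ingest real scans, skip simulation
    meta_csv: str | None = None
    save_images: bool = False
    hue_cut: float = 75.0
    threshold: str | float = "otsu"
    spacings: tuple = (3, 6)
    drop_final: bool = True
    alpha: float = 0.05
    svm: SVMConfig = field(default_factory=SVMConfig)
    positions: tuple = ("FIL", "1st", "2nd", "3rd")
    combined_positions: tuple = (("FIL", "3rd"),)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        exp_raw = raw.pop("experiment", {})
        svm_raw = raw.pop("svm", {})
        profiles = exp_raw.pop("profiles", None)
        exp = ExperimentConfig(**exp_raw)
        if profiles is not None:
            exp.profiles = {
                level: dataclasses.replace(DEFAULT_PROFILES[level], **kw)
                for level, kw in profiles.items()
            }
        cfg = cls(experiment=exp, svm=SVMConfig(**svm_raw), **raw)
        cfg.experiment.master_seed = cfg.seed
        return cfg


def _write_csv(df: pd.DataFrame, path: Path, sort_by=None):
    if sort_by:
        df = df.sort_values(sort_by, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_images(images_dir: str | Path, meta_csv: str | Path):
    """Ingest real scans: PNG/TIFF files described by a metadata CSV
    (columns image_path, plant_id, treatment, year, dat, leaf_position, dpi)."""
    from PIL import Image

    meta = pd.read_csv(meta_csv)
    images = []
    for rec in meta.to_dict("records"):
        arr = np.asarray(Image.open(Path(images_dir) / rec["image_path"]).convert("RGB"))
        images.append(LeafImage(
            pixels=arr, dpi=float(rec["dpi"]), plant_id=str(rec["plant_id"]),
            treatment=str(rec["treatment"]), dat=int(rec["dat"]),
            leaf_position=str(rec["leaf_position"]), year=int(rec.get("year", 0)),
        ))
    return images


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute every stage and return the run directory.

    Artifacts: features.csv, dyn3.csv, dyn6.csv, anova3.csv, anova6.csv,
    fits.csv, report/accuracy.csv, report/best_position.csv,
    report/confusions.json, manifest.json (+ images/, truth.csv, meta.csv
    for synthetic runs with ``save_images``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report").mkdir(exist_ok=True)
    artifacts: list[Path] = []

    # --- acquire observations ------------------------------------------------
    if cfg.images_dir is not None:
        stage = "ingest"
        images = load_images(cfg.images_dir, cfg.meta_csv)
    else:
        stage = "simulate"
        cfg.experiment.master_seed = cfg.seed
        exp = generate_experiment(
            cfg.experiment, out_dir=out if cfg.save_images else None
        )
        if cfg.save_images:
            images = load_images(out, out / "meta.csv")
            artifacts += [out / "truth.csv", out / "meta.csv"]
        else:
            images = exp.images
            _write_csv(exp.truth_table, out / "truth.csv")
            artifacts.append(out / "truth.csv")
    log.info("%s: %d observations", stage, len(images))

    # --- extract -------------------------------------------------------------
    features = extract_batch(images, hue_cut=cfg.hue_cut, threshold=cfg.threshold)
    _write_csv(features, out / "features.csv",
               sort_by=["plant_id", "dat", "leaf_position"])
    artifacts.append(out / "features.csv")

    # --- dynamics + growth fits ---------------------------------------------
    schedule = sorted(features["dat"].unique())
    dyn_by_spacing = {}
    for spacing in cfg.spacings:
        scheme = build_interval_scheme(schedule, spacing, drop_final=cfg.drop_final)
        dyn = dynamic_features(features, scheme)
        dyn_by_spacing[spacing] = dyn
        path = out / f"dyn{spacing}.csv"
        _write_csv(dyn, path, sort_by=["plant_id", "leaf_position", "period"])
        artifacts.append(path)

    fits = fit_report(features)
    _write_csv(fits, out / "fits.csv",
               sort_by=["treatment", "leaf_position", "characteristic", "model"])
    artifacts.append(out / "fits.csv")

    # --- screen --------------------------------------------------------------
    for spacing, dyn in dyn_by_spacing.items():
        screened = screen_features(dyn, alpha=cfg.alpha)
        path = out / f"anova{spacing}.csv"
        _write_csv(screened, path)
        artifacts.append(path)

    # --- diagnose ------------------------------------------------------------
    report, confusions = evaluate_grid(
        dyn_by_spacing, positions=cfg.positions,
        combined_positions=cfg.combined_positions, cfg=cfg.svm,
    )
    _write_csv(report, out / "report" / "accuracy.csv",
               sort_by=["spacing", "data_set", "positions"])
    _write_csv(best_position_summary(report), out / "report" / "best_position.csv")
    conf_json = {
        f"{sp}|{ds}|{pos}": conf.to_dict() for (sp, ds, pos), conf in
        sorted(confusions.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2]))
    }
    conf_path = out / "report" / "confusions.json"
    conf_path.write_text(json.dumps(conf_json, indent=1, sort_keys=True))
    artifacts += [out / "report" / "accuracy.csv",
                  out / "report" / "best_position.csv", conf_path]

    # --- manifest ------------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(cfg), default=str)),
        "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(artifacts)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def make_report(run_dir: str | Path) -> Path:
    """Render a Markdown summary (plus growth-curve PNG) of a finished run.

    Missing artifacts are reported section-by-section; the report is still
    produced.
    """
    run = Path(run_dir)
    (run / "report").mkdir(parents=True, exist_ok=True)
    lines = ["# Leaf-dynamics nitrogen diagnosis report", ""]

    def _section(title, path, render):
        lines.append(f"## {title}")
        if not path.exists():
            lines.append(f"_artifact `{path.name}` absent_")
            lines.append("")
            return
        render(pd.read_csv(path))
        lines.append("")

    def _fits(df):
        piv = df.pivot_table(index=["characteristic", "model"],
                             columns="treatment", values="aic")
        lines.append("AIC per growth model (lower is better):")
        lines.append("")
        lines.append(piv.round(3).to_markdown())

    for spacing in (3, 6):
        def _anova(df, spacing=spacing):
            grid = anova_grid(df)
            lines.append(grid.to_markdown())
        _section(f"ANOVA screen, {spacing}-day interval",
                 run / f"anova{spacing}.csv", _anova)

    def _accuracy(df):
        lines.append(df.round(3).to_markdown(index=False))

    _section("Growth-model comparison", run / "fits.csv", _fits)
    _section("Diagnostic accuracy (training = resubstitution, validation = LOOCV)",
             run / "report" / "accuracy.csv", _accuracy)
    _section("Best leaf position per data set",
             run / "report" / "best_position.csv", _accuracy)

    fig_path = run / "report" / "growth_curves.png"
    feats = run / "features.csv"
    if feats.exists():
        try:
            _plot_growth_curves(pd.read_csv(feats), fig_path)
            lines.append(f"![growth curves]({fig_path.relative_to(run)})")
        except Exception as exc:                      # plotting is best-effort
            log.warning("growth-curve plot failed: %s", exc)

    out = run / "report" / "report.md"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text("\n".join(lines))
    return out


def _plot_growth_curves(features: pd.DataFrame, path: Path):
    """Replicate-mean FIL area trajectories with fitted logistic overlays."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .dynamics import fit_growth_model

    fil = features[features["leaf_position"] == "FIL"]
    fig, ax = plt.subplots(figsize=(6, 4))
    for treatment, grp in fil.groupby("treatment"):
        traj = grp.groupby("dat")["LA"].mean()
        ax.plot(traj.index, traj.values, "o", label=treatment)
        try:
            f = fit_growth_model(traj.index.values, traj.values, "logistic")
            tt = np.linspace(traj.index.min(), traj.index.max(), 200)
            a, k, t0 = f.params
            ax.plot(tt, a / (1 + np.exp(-k * (tt - t0))), "-", alpha=0.7)
        except Exception:
            pass
    ax.set_xlabel("days after transplanting")
    ax.set_ylabel("leaf area (cm$^2$)")
    ax.legend(title="treatment")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
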