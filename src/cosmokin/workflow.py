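"""End-to-end pipeline: simulate → (detect → colocalize) → fit → compare → report.

Runs are driven by a single flat TOML config so an analysis is reproducible
from one file: the config (serialized verbatim), a manifest with seeds,
content hashes and per-stage row counts, and every intermediate table land in
the output directory.  Rerunning with the same config and seed reproduces
byte-identical CSV/JSON payloads; plots are artifacts only and are excluded
from hashing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import imaging, kinetics, synthetic
from .kinetics import AssemblyTimeSeries, KineticFit
from .synthetic import KineticTruth, SimConfig

__all__ = ["PipelineConfig", "ConditionSpec", "run_pipeline", "make_report", "load_config"]

log = logging.getLogger("cosmokin")


@dataclass(frozen=True)
class ConditionSpec:
    """One protein/condition to simulate and fit."""

    label: str
    n_steps: int = 1
    k_per_min: float = 0.1057
    c_max: float = 0.87
    mutant: bool = False

    @property
    def truth(self) -> KineticTruth:
        return KineticTruth(self.n_steps, self.k_per_min, self.c_max)


@dataclass
class PipelineConfig:
    """Everything a run needs; ``seed`` is mandatory."""

    seed: int
    output_dir: Path = Path("cosmokin_run")
    conditions: list[ConditionSpec] = field(
        default_factory=lambda: [ConditionSpec("Ndc10-like")]
    )
    render_images: bool = False
    n_image_fields: int = 2  # fields rendered per timepoint when imaging
    sim: dict[str, Any] = field(default_factory=dict)
    psf_sigma_px: float = 1.3
    threshold_k: float = 5.0
    radius_px: float = imaging.DEFAULT_RADIUS_PX
    fit_threshold: float = kinetics.DEFAULT_THRESHOLD
    n_boot: int = 200
    t_max: float | None = None
    log_level: str = "INFO"
    stages: tuple[str, ...] = ("simulate", "fit", "report")

    def sim_config(self, condition: ConditionSpec, index: int) -> SimConfig:
        kwargs = dict(self.sim)
        kwargs.pop("seed", None)
        return SimConfig(
            seed=int((self.seed * 1000 + index) % (2**31)),
            kinetic_truth=condition.truth,
            mutant_mode=condition.mutant,
            **kwargs,
        )


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    if "seed" not in raw:
        raise ValueError("config must set a seed")
    conditions = [ConditionSpec(**c) for c in raw.pop("conditions", [])] or [
        ConditionSpec("Ndc10-like")
    ]
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    cfg_kwargs = {k: v for k, v in raw.items() if k in known and k != "conditions"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(conditions=conditions, **cfg_kwargs)
    cfg.output_dir = Path(cfg.output_dir)
    cfg.stages = tuple(cfg.stages)
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n")


def _simulate_condition(
    cfg: PipelineConfig, cond: ConditionSpec, index: int, out: Path
) -> tuple[AssemblyTimeSeries, list[Path]]:
    sim_cfg = cfg.sim_config(cond, index)
    outputs: list[Path] = []
    if cfg.render_images:
        groups: dict[tuple[float, int], list] = {}
        import tifffile

        for rep in range(sim_cfg.n_replicates):
            for t in sim_cfg.timepoints_min:
                pairs = []
                for i in range(cfg.n_image_fields):
                    fseed = int(
                        np.random.SeedSequence(
                            [sim_cfg.seed, rep, int(round(t * 1000)), i]
                        ).generate_state(1)[0] % (2**31)
                    )
                    dna, gfp, _ = synthetic.simulate_field_pair(sim_cfg, t, rep, seed=fseed)
                    pairs.append((dna, gfp))
                    for img, tag in ((dna, "647"), (gfp, "488")):
                        p = out / f"{cond.label}_{t:g}min_rep{rep}_field{i}_{tag}.tif"
                        tifffile.imwrite(p, img.pixels.astype(np.float32))
                        outputs.append(p)
                groups[(float(t), rep)] = pairs
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # small rendered runs are below 3000 DNAs
            series = imaging.score_field_series(
                groups, cfg.psf_sigma_px, cfg.threshold_k, cfg.radius_px,
                protein_label=cond.label,
                condition_label="mutant" if cond.mutant else "wild-type",
            )
    else:
        series, _ = synthetic.simulate_series(sim_cfg)
        series.protein_label = cond.label
    p = out / f"{cond.label}_series.csv"
    series.to_csv(p)
    outputs.append(p)
    return series, outputs


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest.

    A stage failure halts the run; partial outputs stay on disk next to a
    ``FAILED`` marker naming the stage.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_json(
        out / "config.json",
        {
            **{
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k != "conditions"
            },
            "conditions": [dataclasses.asdict(c) for c in config.conditions],
        },
    )
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "stages": {},
    }
    series_by_cond: dict[str, AssemblyTimeSeries] = {}
    fits: list[KineticFit] = []
    current_stage = "simulate"
    try:
        if "simulate" in config.stages:
            stage_out: dict[str, Any] = {"outputs": {}, "rows": {}}
            for i, cond in enumerate(config.conditions):
                log.info("simulating %s", cond.label)
                series, paths = _simulate_condition(config, cond, i, out)
                series_by_cond[cond.label] = series
                for p in paths:
                    if p.suffix in (".csv", ".json"):
                        stage_out["outputs"][p.name] = _sha256(p)
                stage_out["rows"][cond.label] = int(len(series.data))
            manifest["stages"]["simulate"] = stage_out

        if "fit" in config.stages:
            current_stage = "fit"
            stage_out = {"outputs": {}, "rows": {}}
            for i, cond in enumerate(config.conditions):
                series = series_by_cond[cond.label]
                log.info("fitting %s", cond.label)
                fit = kinetics.select_model(
                    series, threshold=config.fit_threshold, t_max=config.t_max
                )
                if config.n_boot > 0 and fit.informative:
                    kinetics.estimate_uncertainties(
                        series, fit, n_boot=config.n_boot,
                        seed=int((config.seed * 7919 + i) % (2**31)),
                    )
                fits.append(fit)
                p = out / f"{cond.label}_fit.json"
                _write_json(p, fit.to_dict())
                stage_out["outputs"][p.name] = _sha256(p)
            manifest["stages"]["fit"] = stage_out

        if "report" in config.stages and fits:
            current_stage = "report"
            paths = make_report(fits, series_by_cond, out)
            manifest["stages"]["report"] = {
                "outputs": {p.name: _sha256(p) for p in paths if p.suffix == ".csv"}
            }
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={current_stage}\nerror={exc}\n")
        raise
    _write_json(out / "manifest.json", manifest)
    return manifest


def make_report(
    fits: list[KineticFit],
    series_by_label: dict[str, AssemblyTimeSeries],
    out: Path,
) -> list[Path]:
    """Fit table, assembly ordering and fraction-vs-time plots.

    Plots show per-timepoint mean fractions with replicate-SD error bars and
    the overlaid best-fit curve; censored timing renders as "> t_max min".
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    import pandas as pd

    rows = [f.to_dict(with_candidates=False) for f in fits]
    table = pd.DataFrame(rows)
    p = out / "fit_table.csv"
    table.to_csv(p, index=False)
    paths.append(p)

    if len(fits) >= 2:
        order = kinetics.compare_curves(fits)
        p = out / "assembly_order.csv"
        order.to_csv(p, index=False)
        paths.append(p)
        diffs = kinetics.t30_differences(fits)
        p = out / "t30_differences.csv"
        diffs.to_csv(p, index=False)
        paths.append(p)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for f in fits:
        s = series_by_label.get(f.protein_label)
        if s is None:
            continue
        summ = s.summary()
        eb = ax.errorbar(
            summ["time_min"], 100 * summ["mean_fraction"],
            yerr=100 * summ["replicate_sd"], fmt="o", capsize=2,
            label=f"{f.protein_label} ({f.t30.render()})",
        )
        tg = np.linspace(0, summ["time_min"].max(), 200)
        ax.plot(tg, 100 * np.asarray(f.curve(tg)), color=eb.lines[0].get_color())
    ax.set_xlabel("incubation time (min)")
    ax.set_ylabel("colocalized DNAs (%)")
    ax.axhline(100 * fits[0].threshold, ls=":", color="gray", lw=0.8)
    ax.legend(fontsize=8)
    fig.tight_layout()
    p = out / "colocalization_vs_time.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    paths.append(p)
    return paths
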