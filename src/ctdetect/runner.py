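"""End-to-end scenario orchestration: simulate -> detect -> resample -> summarize.

Tables are the contract; plots are conveniences written alongside.  Every
run emits a JSON manifest with the config snapshot, seed, library versions,
per-stage wall times and a sha256 checksum of every output file, so that a
re-run with the same seed can be verified bit-for-bit on the tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import (
    write_counts,
    write_metadata,
    write_panel,
    write_sensitivity,
)
from .detection import stratified_sensitivity, tumor_fraction_table
from .errors import StageError
from .resampling import ResamplingPlan, binomial_model_check, downsample_panel, downscale_fraction
from .simulate import ScenarioConfig, make_panel, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    scenario: dict
    resampling: dict
    seed: int
    versions: dict
    outputs: dict = field(default_factory=dict)  # path -> sha256
    stage_seconds: dict = field(default_factory=dict)
    created: str = ""

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_run_config(path) -> tuple[ScenarioConfig, ResamplingPlan]:
    """Load a single YAML file with ``scenario:`` and ``resampling:`` sections."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    scenario = ScenarioConfig(**raw.get("scenario", {}))
    plan = ResamplingPlan(**raw.get("resampling", {}))
    return scenario, plan


def run_scenario(
    config: ScenarioConfig,
    plan: ResamplingPlan,
    outdir,
    make_plots: bool = True,
) -> RunManifest:
    """Run the full pipeline on a synthetic cohort and write all outputs.

    Outputs under ``outdir``: panel.tsv, counts.tsv, metadata.tsv,
    tumor_fractions.tsv, burden_sensitivity.tsv, panel_sensitivity.tsv,
    fraction_sensitivity.tsv (when the plan lists fractions),
    model_check.tsv, figures (PNG) and manifest.json.  Any stage failure
    raises :class:`StageError` naming the stage; earlier outputs are kept.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        scenario=config.to_dict(),
        resampling=plan.to_dict(),
        seed=config.seed,
        versions={
            "ctdetect": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    state: dict = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        logger.info("stage %s: start", name)
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageError(name, exc) from exc
        dt = time.perf_counter() - t0
        manifest.stage_seconds[name] = round(dt, 3)
        logger.info("stage %s: done in %.2fs", name, dt)

    def _simulate():
        panel = make_panel(config.panel_size)
        table, records = simulate_cohort(config, panel)
        write_panel(panel, outdir / "panel.tsv")
        write_counts(table, outdir / "counts.tsv")
        write_metadata(records, outdir / "metadata.tsv")
        state.update(panel=panel, table=table, records=records)

    def _detect():
        table, records = state["table"], state["records"]
        strat = stratified_sensitivity(table, records, thresholds=plan.thresholds)
        strat.to_csv(outdir / "burden_sensitivity.tsv", sep="\t", index=False, lineterminator="\n")
        tumor_fraction_table(table).to_csv(
            outdir / "tumor_fractions.tsv", sep="\t", index=False, lineterminator="\n"
        )

    def _downsample():
        grid = downsample_panel(state["table"], state["records"], plan)
        write_sensitivity(grid, outdir / "panel_sensitivity.tsv")
        state["panel_grid"] = grid

    def _downscale():
        if not plan.fractions:
            logger.info("no target fractions in plan; skipping fraction down-scaling")
            return
        grid = downscale_fraction(state["table"], state["records"], plan)
        write_sensitivity(grid, outdir / "fraction_sensitivity.tsv")
        state["fraction_grid"] = grid

    def _model_check():
        report = binomial_model_check(state["table"], seed=plan.seed)
        report.to_csv(outdir / "model_check.tsv", sep="\t", index=False, lineterminator="\n")

    def _plots():
        if not make_plots:
            return
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if "panel_grid" in state:
            _plot_grid(
                state["panel_grid"], x="panel_size", path=outdir / "panel_sensitivity.png",
                xlabel="panel size (sites)", logx=True, plt=plt,
            )
        if "fraction_grid" in state:
            full = state["fraction_grid"]
            sub = full[full["panel_size"] == full["panel_size"].max()]
            _plot_grid(
                sub, x="fraction", path=outdir / "fraction_sensitivity.png",
                xlabel="tumor fraction", logx=True, plt=plt,
            )

    stage("simulate", _simulate)
    stage("detect", _detect)
    stage("downsample-panel", _downsample)
    stage("downscale-fraction", _downscale)
    stage("model-check", _model_check)
    stage("plots", _plots)

    for p in sorted(outdir.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest.outputs[p.name] = _sha256(p)
    (outdir / "manifest.json").write_text(manifest.to_json() + "\n", encoding="utf-8")
    return manifest


def _plot_grid(grid: pd.DataFrame, x: str, path, xlabel: str, logx: bool, plt):
    fig, ax = plt.subplots(figsize=(6, 4))
    thr = grid["threshold"].min()
    sub = grid[grid["threshold"] == thr]
    for arm, g in sub.groupby("arm"):
        g = g.sort_values(x)
        xs = g[x].astype(float)
        ax.errorbar(xs, g["mean"], yerr=g["se"], marker="o", capsize=3, label=arm)
    if logx:
        ax.set_xscale("log")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(f"sensitivity (threshold >= {thr} SNVs)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
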