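"""End-to-end orchestration: simulate -> decompose -> features -> analyze.

A single configuration (programmatic or TOML) drives all stages; the run is
deterministic given (config, seed).  The report mirrors the result-table
structure of windowed stabilization studies: one row per variable and window
length with the ANOVA summary (F, corrected dfs, p, Greenhouse-Geisser
epsilon), the complete-case count, the stabilization window and any
transient plateaus.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import (SignalParams, StudyConfig, _update_dataclass,
                     default_study_config)
from .errors import ConfigError, InsufficientDataError
from .features import build_window_grid, extract_features
from .eda import decompose_recording
from .io import write_feature_table, write_results_table
from .stats import StabilizationResult, analyze_variable
from .synthetic import VARIABLES, SyntheticDataset, generate_study

logger = logging.getLogger("tostab.pipeline")

REPORT_COLUMNS = (
    "variable", "window_len_s", "F", "df1", "df2", "p", "epsilon",
    "correction_applied", "n_total", "n_complete", "stabilized_at_s",
    "plateaus",
)


@dataclass(frozen=True)
class AnalysisConfig:
    alpha: float = 0.05
    window_lengths: tuple[float, ...] = (2.0, 5.0)
    step: float = 2.0
    horizon: float = 12.0
    variables: tuple[str, ...] = VARIABLES
    unit: str = "attempt"

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")
        if self.unit not in ("attempt", "driver"):
            raise ConfigError("unit must be 'attempt' or 'driver'")
        unknown = set(self.variables) - set(VARIABLES)
        if unknown:
            raise ConfigError(f"unknown variables {sorted(unknown)}")


@dataclass(frozen=True)
class PipelineConfig:
    study: StudyConfig = field(default_factory=default_study_config)
    signals: SignalParams = field(default_factory=SignalParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def validate(self) -> None:
        self.study.validate()
        self.signals.validate()
        self.analysis.validate()

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Read a TOML config with optional [study], [signals] and [analysis]
    tables; any unknown key is rejected before computation starts."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = PipelineConfig()
    known = {"study", "signals", "analysis"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config section(s) {sorted(unknown)}")
    changes = {}
    for section in known & set(raw):
        changes[section] = _update_dataclass(getattr(cfg, section),
                                             raw[section], section)
    cfg = dataclasses.replace(cfg, **changes)
    cfg.validate()
    return cfg


def _result_row(res: StabilizationResult) -> dict:
    plateaus = ";".join(f"{a:g}-{b:g}" for a, b in res.plateaus)
    return {
        "variable": res.variable,
        "window_len_s": res.window_length,
        "F": res.anova.f,
        "df1": res.anova.df1,
        "df2": res.anova.df2,
        "p": res.anova.p,
        "epsilon": res.anova.epsilon,
        "correction_applied": int(res.anova.correction_applied),
        "n_total": res.n_total,
        "n_complete": res.n_complete,
        "stabilized_at_s": res.stabilized_at,
        "plateaus": plateaus,
    }


def analyze_dataset(
    dataset: SyntheticDataset,
    analysis: AnalysisConfig | None = None,
    outdir: Path | None = None,
) -> tuple[pd.DataFrame, dict[str, StabilizationResult]]:
    """Feature extraction and stabilization analysis for every variable and
    window length; returns the report table and the detailed results keyed
    by ``"<variable>:<length>"``."""
    ana = analysis or AnalysisConfig()
    ana.validate()
    decomps = None
    if "sc" in ana.variables:
        logger.info("decomposing %d GSR records", len(dataset.recordings))
        decomps = {
            rec.event_id: decompose_recording(rec["gsr_us"],
                                              rate=dataset.config.rate_gsr)
            for rec in dataset.recordings
        }
    rows = []
    details: dict[str, StabilizationResult] = {}
    for length in ana.window_lengths:
        grid = build_window_grid(length, ana.step, ana.horizon)
        features = extract_features(dataset.recordings, dataset.events, grid,
                                    variables=ana.variables,
                                    decompositions=decomps)
        if outdir is not None:
            write_feature_table(features, Path(outdir) / f"features_{length:g}s.csv")
        for variable in ana.variables:
            try:
                res = analyze_variable(features, variable, length,
                                       alpha=ana.alpha, unit=ana.unit, grid=grid)
            except InsufficientDataError as err:
                logger.warning("skipping %s at %gs windows: %s",
                               variable, length, err)
                continue
            rows.append(_result_row(res))
            details[f"{variable}:{length:g}"] = res
    report = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    report = report.sort_values(["variable", "window_len_s"],
                                kind="stable").reset_index(drop=True)
    return report, details


def run_pipeline(
    config: PipelineConfig | str | Path | None = None,
    seed: int | None = None,
    outdir: str | Path | None = None,
    plots: bool = False,
) -> pd.DataFrame:
    """Execute all stages; identical (config, seed) yields an identical
    report.  When ``outdir`` is given, per-stage artifacts (feature tables,
    report CSV/JSON, optional plots) are persisted there."""
    if config is None:
        cfg = PipelineConfig()
    elif isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = config
    cfg.validate()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    logger.info("stage simulate: %d events", cfg.study.n_events())
    dataset = generate_study(cfg.study, cfg.signals, seed)
    report, details = analyze_dataset(dataset, cfg.analysis, outdir=out)
    report.attrs["config_hash"] = cfg.hash()
    report.attrs["seed"] = dataset.seed
    report.attrs["n_events"] = len(dataset.events)
    if out is not None:
        render_report(report, out, details=details, plots=plots,
                      dataset=dataset)
    return report


def render_report(
    table: pd.DataFrame,
    outdir,
    details: dict[str, StabilizationResult] | None = None,
    plots: bool = False,
    dataset: SyntheticDataset | None = None,
) -> None:
    """Write the report CSV, a JSON copy with metadata, a plain-text summary
    and (optionally) per-variable mean-profile plots with window markers."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if table.empty:
        logger.warning("rendering an empty report table")
    write_results_table(table, out / "report.csv")
    payload = {
        "metadata": {k: table.attrs.get(k) for k in
                     ("config_hash", "seed", "n_events")},
        "results": json.loads(table.to_json(orient="records")),
    }
    (out / "report.json").write_text(json.dumps(payload, indent=1) + "\n")

    lines = ["Post-takeover stabilization summary", ""]
    for _, row in table.iterrows():
        stab = (f"stabilized at {row.stabilized_at_s:g} s"
                if pd.notna(row.stabilized_at_s)
                else "not stabilized within the horizon")
        lines.append(
            f"{row.variable:>13s} ({row.window_len_s:g} s windows): "
            f"F({row.df1:.1f}, {row.df2:.1f}) = {row.F:.2f}, p = {row.p:.3g}, "
            f"eps = {row.epsilon:.2f}, n = {row.n_complete}; {stab}"
        )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")

    if plots and dataset is not None:
        _plot_profiles(table, dataset, out)


def _plot_profiles(table: pd.DataFrame, dataset: SyntheticDataset, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    from . import synthetic as syn

    lat = syn.neutral_latents(dataset.params)
    t = np.linspace(0, 17, 400)
    profiles = {
        "winding": syn.steering_sd_profile(t, dataset.params, lat),
        "speed": syn.speed_profile(t, dataset.params, lat),
        "eoff": syn.off_road_probability(t, dataset.params, lat),
        "pd": syn.pupil_profile(t, dataset.params, lat),
        "hr": syn.heart_rate_profile(t, dataset.params, lat),
    }
    for name, prof in profiles.items():
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.plot(t, prof, lw=1.5)
        for w in np.arange(0, 13, 2):
            ax.axvline(w, color="0.8", lw=0.5, zorder=0)
        sub = table[table["variable"] == name]
        for _, row in sub.iterrows():
            if pd.notna(row.stabilized_at_s):
                ax.axvline(row.stabilized_at_s, color="C3", ls="--", lw=1)
        ax.set_xlabel("time since takeover (s)")
        ax.set_title(name)
        fig.tight_layout()
        fig.savefig(out / f"profile_{name}.png", dpi=100)
        plt.close(fig)
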