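"""End-to-end pipeline driver: simulate -> saccades -> classify ->
modulate -> bootstrap -> correlate -> report.

Every stage writes its output as plain CSV/JSON into the run directory;
the effective configuration (including the seed) is persisted so a rerun
with the same seed reproduces all artifacts byte for byte.
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

from . import behavior_link, io, pseudopop, session
from .errors import ConfigurationError
from .pseudopop import BootstrapConfig
from .synth import GeneratorParams, SUBTYPES, generate_session, params_from_dict

log = logging.getLogger("scvigor")


@dataclass(frozen=True)
class PipelineConfig:
    """Run configuration; defaults reproduce the study's stated values.

    ``onset_threshold``/``blink_threshold``: saccade speed thresholds of
    30 and 700 deg/s.  ``alpha``: 0.05 for every test.  The analysis
    windows themselves live with their operations (classification,
    value modulation); the bootstrap sizes here default to 25 pooled
    units and 25 pseudo-trials per tertile.
    """

    out_dir: str = "run"
    seed: int = 0
    session_dir: str | None = None          # ingest instead of simulate
    generator: GeneratorParams | None = None
    bootstrap_repeats: int = 1000
    bootstrap_n_pool: int = 25
    bootstrap_n_pseudo: int = 25
    alpha: float = 0.05
    auroc_permutations: int = 1000
    figure9_convention: bool = True          # report 1 - AUROC (published style)
    bootstrap_conditions: bool = False       # also run good/bad-split bootstrap

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", None)
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(f"bad pipeline config: {exc}") from exc
        if gen is not None:
            cfg = dataclasses.replace(cfg, generator=params_from_dict(gen))
        return cfg

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            from .synth import _params_to_jsonable
            d["generator"] = _params_to_jsonable(self.generator)
        return d


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_jsonable(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    log.info("stage=start seed=%d config=%s", config.seed, chash)
    persisted = config.to_jsonable()
    persisted.pop("out_dir", None)  # implied by location; keeps reruns byte-stable
    (out / "config.json").write_text(
        json.dumps(persisted, indent=2, sort_keys=True, default=str) + "\n")

    # --- simulate / ingest -------------------------------------------------
    if config.session_dir is not None:
        bundle = io.read_session(config.session_dir)
    else:
        gen = config.generator or GeneratorParams(seed=config.seed)
        if config.generator is None:
            gen = dataclasses.replace(gen, seed=config.seed)
        bundle = generate_session(gen)
        io.write_session(bundle, out / "session")
    log.info("stage=session seed=%d units=%d trials=%d", config.seed,
             len(bundle.units), len(bundle.trials))

    # --- saccades ----------------------------------------------------------
    saccades = session.analyze_saccades(bundle)
    saccades.to_csv(out / "saccades.csv", index=False, float_format="%.4f")

    # --- classification ----------------------------------------------------
    classes = session.classify(bundle, saccades, alpha=config.alpha)
    classes.to_csv(out / "classes.csv", index=False, float_format="%.6g")

    # --- value modulation --------------------------------------------------
    modulation = session.modulation_table(
        bundle, saccades, classes, n_perm=config.auroc_permutations,
        seed=config.seed, figure_convention=config.figure9_convention)
    modulation.to_csv(out / "modulation.csv", index=False, float_format="%.6g")

    # --- bootstrap ---------------------------------------------------------
    boot_cfg = BootstrapConfig(n_pool=config.bootstrap_n_pool,
                               n_pseudo_trials=config.bootstrap_n_pseudo,
                               n_repeats=config.bootstrap_repeats,
                               seed=config.seed)
    rasters = session.unit_rasters(bundle, saccades)
    boot_frames = []
    for subtype in SUBTYPES:
        units = session.unit_traces(bundle, saccades, classes, subtype, rasters)
        if not units:
            continue
        conds = ("good", "bad") if config.bootstrap_conditions else None
        try:
            df = pseudopop.bootstrap_population(units, boot_cfg, conditions=conds)
        except Exception as exc:  # degenerate tertile/condition split
            log.warning("stage=bootstrap subtype=%s skipped: %s", subtype, exc)
            continue
        df.insert(0, "subtype", subtype)
        boot_frames.append(df)
    boot = (pd.concat(boot_frames, ignore_index=True)
            if boot_frames else pd.DataFrame())
    (out / "boot_summary.json").write_text(
        boot.to_json(orient="records", indent=2, double_precision=6) + "\n")

    # --- behavior-link indices ---------------------------------------------
    rows = session.index_rows(bundle, saccades, classes, modulation)
    indices = behavior_link.build_index_table(rows) if rows else pd.DataFrame()
    indices.to_csv(out / "indices.csv", index=False, float_format="%.6g")

    # --- report ------------------------------------------------------------
    report_dir = out / "report"
    report_dir.mkdir(exist_ok=True)
    write_report(report_dir, saccades, classes, modulation, indices, boot)
    log.info("stage=done seed=%d config=%s", config.seed, chash)
    return out


def write_report(report_dir: Path, saccades: pd.DataFrame, classes: pd.DataFrame,
                 modulation: pd.DataFrame, indices: pd.DataFrame,
                 boot: pd.DataFrame) -> None:
    """Summary tables and basic figures for a completed run."""
    val = saccades[saccades["valid"]]
    behavior = (val.groupby("condition")[["rt_ms", "pv_deg_s", "amplitude_deg"]]
                .agg(["mean", "std", "count"]))
    behavior.to_csv(report_dir / "behavior_summary.csv", float_format="%.4f")

    counts = classes.groupby(["subtype", "exclusion_reason"]).size()
    counts.rename("n").to_csv(report_dir / "classification_counts.csv")

    if len(modulation):
        mod = (modulation.assign(significant=modulation["signed_rank_p"] < 0.05)
               .groupby(["subtype", "sign"]).size().rename("n"))
        mod.to_csv(report_dir / "modulation_proportions.csv")

    if len(indices):
        behavior_link.modulation_overlap(indices).to_csv(
            report_dir / "overlap_counts.csv", index=False)

    _plots(report_dir, saccades, modulation)


def _plots(report_dir: Path, saccades: pd.DataFrame,
           modulation: pd.DataFrame) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 3))
    val = saccades[saccades["valid"]]
    for cond, color in (("good", "tab:red"), ("bad", "tab:blue")):
        sub = val[val["condition"] == cond]
        axes[0].hist(sub["rt_ms"], bins=20, alpha=0.5, color=color, label=cond)
        axes[1].scatter(sub["amplitude_deg"], sub["pv_deg_s"], s=8,
                        color=color, label=cond)
    axes[0].set_xlabel("reaction time (ms)")
    axes[1].set_xlabel("amplitude (deg)")
    axes[1].set_ylabel("peak velocity (deg/s)")
    axes[0].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(report_dir / "behavior.png", dpi=100)
    plt.close(fig)
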