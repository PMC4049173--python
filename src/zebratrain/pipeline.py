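"""End-to-end orchestration: simulate -> metrics -> peri-CS typing -> group stats.

A :class:`RunConfig` (loadable from YAML) fully determines a run: one seed,
a cohort spec, analysis options and an output directory. Re-running the same
config reproduces every output file bit-identically.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import pandas as pd
import yaml

from . import io as zio
from .exceptions import InvalidConfigError, ZebratrainError
from .metrics import compute_cell_metrics
from .pericomplex import (ClassifierConfig, classify_response_type,
                          peri_cs_histogram, type_contingency)
from .presets import CellPreset, KernelParams, PopulationConfig, WashinSpec, WaveformParams
from .stats import pearson_chi2, two_sample_t
from .synthetic import generate_population

log = logging.getLogger("zebratrain")

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class CohortSpec:
    preset: CellPreset
    n_cells: int


@dataclass
class RunConfig:
    seed: int
    duration_s: float
    cohorts: List[CohortSpec]
    out_dir: Path
    bin_width_ms: float = 5.0
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    washin: Optional[WashinSpec] = None

    def validate(self) -> None:
        self.population_config().validate()
        if self.bin_width_ms <= 0:
            raise InvalidConfigError("bin_width_ms must be > 0")

    def population_config(self) -> PopulationConfig:
        return PopulationConfig(
            presets=[(c.preset, c.n_cells) for c in self.cohorts],
            duration_s=self.duration_s, seed=self.seed, washin=self.washin)


def _preset_from_dict(d: dict) -> CellPreset:
    d = dict(d)
    if "kernel_params" in d:
        d["kernel_params"] = KernelParams(**d["kernel_params"])
    if "waveform_params" in d:
        d["waveform_params"] = WaveformParams(**d["waveform_params"])
    if "response_type_probs" in d:
        d["response_type_probs"] = tuple(d["response_type_probs"])
    return CellPreset(**d)


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML (see README for the schema)."""
    raw = yaml.safe_load(Path(path).read_text())
    try:
        cohorts = [CohortSpec(preset=_preset_from_dict(c["preset"]),
                              n_cells=int(c["n_cells"]))
                   for c in raw["cohorts"]]
        cfg = RunConfig(
            seed=int(raw["seed"]),
            duration_s=float(raw["duration_s"]),
            cohorts=cohorts,
            out_dir=Path(raw.get("out_dir", "zebratrain_run")),
            bin_width_ms=float(raw.get("bin_width_ms", 5.0)),
        )
        if "classifier" in raw:
            cfg.classifier = ClassifierConfig(**raw["classifier"])
        if "washin" in raw:
            w = raw["washin"]
            cfg.washin = WashinSpec(drug_onset_s=float(w["drug_onset_s"]),
                                    effect_fraction=float(w["effect_fraction"]),
                                    time_constant_s=float(w.get("time_constant_s", 60.0)))
    except (KeyError, TypeError, ValueError) as exc:
        raise InvalidConfigError(f"bad run config {path}: {exc}") from exc
    return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate -> metrics -> peri-CS typing -> group stats; write a report.

    Outputs under ``config.out_dir``: spike files + ``manifest.json``,
    ``metrics.csv``, ``pericss.csv``, ``report.json``. Returns the report
    dict. Any stage error aborts with the stage name and offending cell id.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("stage=simulate seed=%d n_cohorts=%d duration=%.1fs",
                 config.seed, len(config.cohorts), config.duration_s)
        recordings, manifest = generate_population(config.population_config())
        zio.write_population(recordings, out,
                             manifest_extra={"seed": manifest["seed"],
                                             "duration_s": manifest["duration_s"]})

        log.info("stage=metrics n_cells=%d", len(recordings))
        rows = []
        for rec in recordings:
            try:
                rows.append(compute_cell_metrics(rec).as_row())
            except ZebratrainError as exc:
                raise ZebratrainError(
                    f"stage=metrics cell={rec.cell_id}: {exc}") from exc
        metrics_df = pd.DataFrame(rows)
        meta = pd.DataFrame([{"cell_id": r.cell_id,
                              "zebrin_identity": r.zebrin_identity,
                              "lobule": r.lobule,
                              "true_type": (r.ground_truth or {}).get("response_type")}
                             for r in recordings])
        metrics_df = meta.merge(metrics_df, on="cell_id")
        metrics_df.to_csv(out / "metrics.csv", index=False, float_format="%.6g")

        log.info("stage=pericss bin_width_ms=%.1f", config.bin_width_ms)
        peri_rows = []
        import warnings
        for rec in recordings:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    prof = peri_cs_histogram(rec.ss_times, rec.cs_times,
                                             bin_width_ms=config.bin_width_ms,
                                             duration_s=rec.duration)
                    label = classify_response_type(prof, config.classifier)
            except ZebratrainError as exc:
                raise ZebratrainError(
                    f"stage=pericss cell={rec.cell_id}: {exc}") from exc
            row = {"cell_id": rec.cell_id, "assigned_type": label,
                   "n_cs": prof.n_cs, "baseline_hz": prof.baseline_hz,
                   "pause_end_ms": prof.pause_end_ms,
                   "osc_score_z": prof.diagnostics["osc_score_z"]}
            for c, r in zip(prof.bin_centers_ms, prof.rates_hz):
                row[f"rate_{c:+.1f}ms"] = r
            peri_rows.append(row)
        peri_df = pd.DataFrame(peri_rows)
        peri_df.to_csv(out / "pericss.csv", index=False, float_format="%.6g")

        log.info("stage=stats")
        report = {"seed": config.seed, "n_cells": len(recordings),
                  "group_summaries": {}, "comparisons": {}}
        merged = metrics_df.merge(peri_df[["cell_id", "assigned_type"]], on="cell_id")
        for ident, sub in merged.groupby("zebrin_identity"):
            report["group_summaries"][ident] = {
                "n": int(len(sub)),
                "ss_rate_hz": [float(sub["ss_rate_hz"].mean()),
                               float(sub["ss_rate_hz"].std(ddof=1))],
                "cs_rate_hz": [float(sub["cs_rate_hz"].mean()),
                               float(sub["cs_rate_hz"].std(ddof=1))],
                "mean_cv2": [float(sub["ss_mean_cv2"].mean()),
                             float(sub["ss_mean_cv2"].std(ddof=1))],
                "cf_pause_ms": [float(sub["cf_pause_ms"].mean()),
                                float(sub["cf_pause_ms"].std(ddof=1))],
            }
        neg = merged[merged.zebrin_identity == "negative"]
        pos = merged[merged.zebrin_identity == "positive"]
        if len(neg) >= 2 and len(pos) >= 2:
            for col, name in (("ss_rate_hz", "ss_rate"), ("cs_rate_hz", "cs_rate"),
                              ("ss_mean_cv2", "mean_cv2"), ("cf_pause_ms", "cf_pause")):
                res = two_sample_t(neg[col].dropna().to_numpy(),
                                   pos[col].dropna().to_numpy())
                report["comparisons"][name] = {
                    "t": res.value, "df": res.df, "p": res.p}
            table = type_contingency(merged["assigned_type"],
                                     merged["zebrin_identity"])
            if table[:, 0].sum() > 0:
                chi = pearson_chi2(table)
                report["comparisons"]["facilitation_type"] = {
                    "table": table.tolist(), "chi2": chi.value, "p": chi.p}
        type_counts = (merged.groupby(["zebrin_identity", "assigned_type"])
                       .size().unstack(fill_value=0))
        report["type_counts"] = {k: dict(v) for k, v in
                                 type_counts.astype(int).iterrows()}
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True,
                                                    default=float) + "\n")
        log.info("stage=done out=%s", out)
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
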