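"""Configuration-driven end-to-end run: cohort -> ascertainment -> prediction -> gap.

A run either loads a cohort from CSV files or simulates one; it then writes
per-patient ascertainment, the demographic summary, the BP-screening gap,
gap reports overall and per organization, rendered summary tables, and a
manifest (config hash + seed + version) sufficient to reproduce the run.
All outputs are deterministic given config + seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import ascertain as asc_mod
from . import estimator as est_mod
from . import gap as gap_mod
from .codesets import CodeSets, DEFAULT_CODE_SETS
from .cohort import Cohort, eligible_patients, read_cohort, summarize_demographics, write_cohort
from .simulate import SimulationParams, generate_cohort, generate_reference_table
from .types import LEVELS

log = logging.getLogger("htngap")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; exactly one of input_dir / simulate set."""

    out_dir: str
    observation_year: int = 2016
    input_dir: str | None = None
    simulate: SimulationParams | None = None
    reference_table: str | None = None        # strata CSV (required with input_dir)
    reference_buckets: str | None = None      # bucket-distribution CSV
    code_sets: str | None = None              # YAML; defaults when absent
    levels: tuple[str, ...] = LEVELS
    modes: tuple[str, ...] = gap_mod.MODES
    ci_method: str = "reference_se"
    seed: int = 0

    def validate(self) -> None:
        if (self.input_dir is None) == (self.simulate is None):
            raise ValueError("exactly one of input_dir / simulate must be set")
        if self.input_dir is not None and self.reference_table is None:
            raise ValueError("a reference_table path is required when loading a cohort")

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, tuple):
                return [plain(v) for v in obj]
            if isinstance(obj, list):
                return [plain(v) for v in obj]
            if isinstance(obj, dict):
                return {("|".join(map(str, _flat(k))) if isinstance(k, tuple) else k):
                        plain(v) for k, v in obj.items()}
            return obj

        def _flat(key):
            out = []
            for part in key:
                out += _flat(part) if isinstance(part, tuple) else [part]
            return out

        d = dataclasses.asdict(self)
        return plain(d)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # output location is not part of the run identity
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulate", None)
        for key in ("levels", "modes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        if sim is not None:
            for key in ("demographic_mix", "true_htn_prevalence"):
                if key in sim:
                    sim[key] = {tuple(k.split("|")): v for k, v in sim[key].items()}
            if "comorbidity_prevalence" in sim:
                sim["comorbidity_prevalence"] = {
                    (parts[0], tuple(parts[1:])): v
                    for k, v in sim["comorbidity_prevalence"].items()
                    for parts in [k.split("|")]}
            if "bp_model" in sim and isinstance(sim["bp_model"], dict):
                from .simulate import BpModel
                sim["bp_model"] = BpModel(**{k: tuple(v) if isinstance(v, list) else v
                                             for k, v in sim["bp_model"].items()})
            if "org_tilt_range" in sim and isinstance(sim["org_tilt_range"], list):
                sim["org_tilt_range"] = tuple(sim["org_tilt_range"])
            cfg.simulate = SimulationParams(**sim)
        return cfg


def default_config_yaml() -> str:
    """A fully explicit template config for `htngap config init`."""
    cfg = RunConfig(out_dir="results/run", simulate=SimulationParams(n_patients=20_000,
                                                                     org_count=5, seed=1))
    return yaml.safe_dump(cfg.to_dict(), sort_keys=True)


def _fmt_pct(x: float) -> str:
    return f"{x:.1f}"


def render_level_table(reports: pd.DataFrame, n: int) -> str:
    """Markdown table of observed vs predicted by evidence level and mode."""
    if not len(reports):
        raise ValueError("no reports to render")
    lines = ["| Quantity | " + " | ".join(lev for lev in LEVELS if lev in set(reports["level"])) + " |"]
    levels = [lev for lev in LEVELS if lev in set(reports["level"])]
    lines.append("|" + "---|" * (len(levels) + 1))
    first_mode = reports["comorbidity_mode"].iloc[0]
    obs = {r.level: r for r in reports[reports["comorbidity_mode"] == first_mode].itertuples()}
    lines.append("| Observed, % | " + " | ".join(_fmt_pct(obs[l].observed_pct) for l in levels) + " |")
    lines.append("| Observed, millions | "
                 + " | ".join(f"{gap_mod.millions2(obs[l].observed_pct / 100.0 * n):.2f}"
                              for l in levels) + " |")
    for mode in sorted(set(reports["comorbidity_mode"])):
        sub = {r.level: r for r in reports[reports["comorbidity_mode"] == mode].itertuples()}
        label = ("organization comorbidity data" if mode == "org_comorbidity"
                 else "reference comorbidity data")
        lines.append(f"| Predicted ({label}), % (95% CI) | " + " | ".join(
            f"{_fmt_pct(sub[l].predicted_pct)} ({_fmt_pct(sub[l].predicted_ci_low_pct)}-"
            f"{_fmt_pct(sub[l].predicted_ci_high_pct)})" for l in levels) + " |")
        lines.append(f"| Difference ({label}), pp | " + " | ".join(
            _fmt_pct(sub[l].diff_pp) for l in levels) + " |")
        lines.append(f"| Additional patients ({label}) | " + " | ".join(
            f"{sub[l].additional_patients:,}" for l in levels) + " |")
    return "\n".join(lines) + "\n"


def render_org_table(reports: pd.DataFrame) -> str:
    """Markdown table of per-organization observed/predicted prevalence."""
    if not len(reports):
        raise ValueError("no reports to render")
    levels = [lev for lev in LEVELS if lev in set(reports["level"])]
    header = "| Organization | " + " | ".join(
        f"Observed {l}, % | Predicted {l}, %" for l in levels) + " |"
    lines = [header, "|" + "---|" * (1 + 2 * len(levels))]
    mode = ("org_comorbidity" if "org_comorbidity" in set(reports["comorbidity_mode"])
            else reports["comorbidity_mode"].iloc[0])
    sub = reports[reports["comorbidity_mode"] == mode]
    for org in sorted(sub["org_id"].unique()):
        by_level = {r.level: r for r in sub[sub["org_id"] == org].itertuples()}
        cells = []
        for l in levels:
            r = by_level[l]
            cells += [_fmt_pct(r.observed_pct), _fmt_pct(r.predicted_pct)]
        lines.append(f"| {org} | " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a summary dict of key results and paths."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        log.info("stage %s", name)

    try:
        stage("load")
        if config.simulate is not None:
            params = dataclasses.replace(config.simulate, seed=config.seed)
            cohort, truth = generate_cohort(params)
            reference = generate_reference_table(params)
            write_cohort(cohort, out / "cohort")
            truth_out = truth.copy()
            truth_out.to_csv(out / "cohort" / "ground_truth.csv", index=False)
            reference.write(out / "cohort" / "reference_table.csv",
                            out / "cohort" / "reference_buckets.csv")
        else:
            cohort = read_cohort(config.input_dir, config.observation_year)
            reference = est_mod.ReferenceTable.read(config.reference_table,
                                                    config.reference_buckets)
        code_sets = (CodeSets.from_yaml(config.code_sets) if config.code_sets
                     else DEFAULT_CODE_SETS)

        stage("eligibility")
        eligible = eligible_patients(cohort)
        if not eligible:
            raise ValueError("no eligible patients in cohort")
        log.info("eligible patients: %d / %d", len(eligible), len(cohort.patients))

        stage("ascertain")
        asc = asc_mod.ascertain(cohort, eligible, code_sets)
        asc.to_csv(out / "ascertainment.csv", index=False)

        stage("demographics")
        demo = summarize_demographics(cohort, eligible)
        demo.to_csv(out / "demographics.csv", index=False, float_format="%.6f")

        stage("bp_screening_gap")
        overall_gap, per_org_gap = asc_mod.bp_screening_gap(cohort, eligible)
        bp_df = pd.concat([pd.Series({"overall": overall_gap}), per_org_gap])
        bp_df.rename_axis("org_id").rename("no_bp_share").to_frame().to_csv(
            out / "bp_screening_gap.csv", float_format="%.6f")

        stage("gap")
        overall_reports = gap_mod.cohort_gaps(cohort, reference, code_sets,
                                              config.levels, config.modes,
                                              eligible=eligible,
                                              ci_method=config.ci_method)
        overall_df = pd.DataFrame([r.to_row() for r in overall_reports])
        org_df, extrema = gap_mod.per_org_gaps(cohort, reference, code_sets,
                                               config.levels, config.modes,
                                               ci_method=config.ci_method)
        gap_df = pd.concat([overall_df, org_df], ignore_index=True)
        gap_df.to_csv(out / "gap_report.csv", index=False, float_format="%.6f")

        stage("render")
        (out / "table_levels.md").write_text(render_level_table(overall_df, len(eligible)))
        (out / "table_orgs.md").write_text(render_org_table(org_df))

        stage("manifest")
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "htngap_version": __version__,
            "n_patients": int(len(cohort.patients)),
            "n_eligible": int(len(eligible)),
            "bp_screening_gap": overall_gap,
            "extrema": {f"{k[0]}|{k[1]}": v for k, v in extrema.items()
                        if isinstance(k, tuple)},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception:
        log.exception("pipeline failed")
        raise
    return {
        "out_dir": str(out),
        "n_eligible": len(eligible),
        "bp_screening_gap": overall_gap,
        "overall": overall_df,
        "per_org": org_df,
        "extrema": extrema,
    }
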