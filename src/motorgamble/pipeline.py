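"""Pipeline orchestration: generate -> fit -> select -> recover -> stats.

Every stage reads and writes flat CSV/JSON artefacts in an output
directory, so any stage can be rerun or resumed from the files of the
stages before it. A run is described by a YAML config with one master
seed; per-stage RNG streams are derived from it deterministically, so the
same config and seed reproduce identical artefacts.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import selection, stats
from .inference import fit_mle
from .models import AA_WINNER, ModelSpec, enumerate_models
from .recovery import TYPICAL_AA_SETS, parameter_recovery
from .synthetic import CohortConfig, generate_cohort
from .task import (
    TRIAL_CSV_COLUMNS,
    N_TRIALS,
    SuccessRateTable,
    estimate_success_table,
    read_trials_csv,
    value_combinations,
    write_trials_csv,
)

STAGES = ("generate", "fit", "select", "recover", "stats")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {},  # CohortConfig overrides
    "fit": {"n_restarts": 20, "models": "all"},
    "recover": {"n_sims": 10, "n_restarts": 10},
    "stats": {"bin_width": 10.0, "n_boot": 1000, "n_perm": 1000},
}


class PipelineDependencyError(RuntimeError):
    """A stage was requested without the artefacts of its upstream stage."""


def load_config(path=None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def _stage_seed(master_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([master_seed, STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seed, artefacts, timings."""

    config: dict
    seed: int
    package_version: str
    stages: dict = field(default_factory=dict)

    def add_stage(self, name: str, artefacts: list[str], n_records: int, seconds: float):
        self.stages[name] = {
            "artefacts": artefacts,
            "n_records": n_records,
            "seconds": round(seconds, 3),
        }

    @property
    def artefacts(self) -> list[str]:
        return [a for s in self.stages.values() for a in s["artefacts"]]

    def to_json_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "package_version": self.package_version,
            "stages": self.stages,
        }

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2, sort_keys=True))


def _require(outdir: Path, filename: str, stage: str) -> Path:
    path = outdir / filename
    if not path.exists():
        raise PipelineDependencyError(
            f"stage '{stage}' needs {filename}; run the upstream stage first"
        )
    return path


def stage_generate(cfg: dict, outdir: Path, seed: int) -> tuple[list[str], int]:
    cohort_cfg = CohortConfig.from_dict({**cfg.get("cohort", {}), "seed": seed})
    sessions, truth, surface = generate_cohort(cohort_cfg)
    write_trials_csv(sessions, outdir / "cohort.csv")
    truth.to_csv(outdir / "truth.csv", index=False)
    surface.to_csv(outdir / "surface_true.csv")
    return ["cohort.csv", "truth.csv", "surface_true.csv"], len(sessions)


def stage_fit(cfg: dict, outdir: Path, seed: int) -> tuple[list[str], int]:
    sessions = read_trials_csv(_require(outdir, "cohort.csv", "fit"))
    table = estimate_success_table(sessions, mode="group")
    table.to_csv(outdir / "success_table.csv")
    fit_cfg = cfg.get("fit", {})
    model_codes = fit_cfg.get("models", "all")
    specs = (
        list(enumerate_models())
        if model_codes == "all"
        else [ModelSpec.from_code(c) for c in model_codes]
    )
    n_restarts = int(fit_cfg.get("n_restarts", 20))
    rows = []
    for s in sessions:
        for spec in specs:
            fit = fit_mle(s, spec, table, n_restarts=n_restarts, seed=seed)
            rows.append(fit.as_row())
    fits = pd.DataFrame(rows)
    fits.to_csv(outdir / "fits.csv", index=False)
    return ["fits.csv", "success_table.csv"], len(fits)


def stage_select(cfg: dict, outdir: Path, seed: int) -> tuple[list[str], int]:
    fits = pd.read_csv(_require(outdir, "fits.csv", "select"))
    report = selection.compare_models(fits)
    report.lr_tallies = selection.lr_split_counts(fits) or None
    report.summed.rename_axis("spec").to_csv(outdir / "comparison.csv")
    if len(report.winners):
        report.winners.to_csv(outdir / "winner_matrix.csv")
    Path(outdir / "comparison.json").write_text(
        json.dumps(report.to_json_dict(), indent=2, sort_keys=True)
    )
    arts = ["comparison.csv", "comparison.json"]
    if len(report.winners):
        arts.append("winner_matrix.csv")
    return arts, len(report.summed)


def stage_recover(cfg: dict, outdir: Path, seed: int) -> tuple[list[str], int]:
    sessions = read_trials_csv(_require(outdir, "cohort.csv", "recover"))
    table = estimate_success_table(sessions, mode="group")
    rec_cfg = cfg.get("recover", {})
    report = parameter_recovery(
        TYPICAL_AA_SETS,
        AA_WINNER,
        n_sims=int(rec_cfg.get("n_sims", 10)),
        session_template=sessions[0],
        success_table=table,
        seed=seed,
        n_restarts=int(rec_cfg.get("n_restarts", 10)),
    )
    report.summary.to_csv(outdir / "recovery.csv", index=False)
    return ["recovery.csv"], len(report.summary)


_EDUCATION_CODE = {"school": 0, "university": 1, "advanced": 2}


def _covariates(sessions) -> np.ndarray:
    gender = np.array([0.0 if s.gender == "male" else 1.0 for s in sessions])
    edu = np.array([float(_EDUCATION_CODE.get(s.education, 1)) for s in sessions])
    return np.column_stack([gender, edu])


def stage_stats(cfg: dict, outdir: Path, seed: int) -> tuple[list[str], int]:
    sessions = read_trials_csv(_require(outdir, "cohort.csv", "stats"))
    table = estimate_success_table(sessions, mode="group")
    st_cfg = cfg.get("stats", {})
    bin_width = float(st_cfg.get("bin_width", 10.0))
    n_boot = int(st_cfg.get("n_boot", 1000))
    n_perm = int(st_cfg.get("n_perm", 1000))

    rows = []
    for s in sessions:
        rew, pun = stats.optimality_discrepancy(s, table)
        rows.append(
            {
                "participant_id": s.participant_id,
                "age_group": s.age_group,
                "optimality_reward": rew,
                "optimality_punishment": pun,
            }
        )
    opt = pd.DataFrame(rows)
    opt.to_csv(outdir / "optimality.csv", index=False)

    curves = stats.binned_gamble_rate(
        sessions, table, bin_width=bin_width, n_boot=n_boot, seed=seed
    )
    curves.to_csv(outdir / "curves.csv", index=False)

    summary: dict = {}
    age = opt["age_group"].to_numpy(dtype=float)
    covars = _covariates(sessions)
    ok = np.isfinite(opt["optimality_reward"].to_numpy())
    if ok.sum() >= 10 and len(np.unique(age[ok])) > 1:
        res = stats.partial_spearman(
            opt["optimality_reward"].to_numpy()[ok], age[ok], covars[ok],
            n_boot=n_boot, n_perm=n_perm, seed=seed,
        )
        summary["optimality_reward_vs_age"] = {
            "r": res.r, "ci": [res.ci_low, res.ci_high], "p": res.p, "n": res.n,
        }

    fits_path = outdir / "fits.csv"
    if fits_path.exists():
        fits = pd.read_csv(fits_path)
        aa = fits[fits["spec"] == AA_WINNER.code]
        if len(aa) and "delta_plus" in aa.columns:
            merged = opt.merge(aa[["participant_id", "delta_plus"]], on="participant_id")
            res = stats.partial_spearman(
                merged["delta_plus"].to_numpy(),
                merged["age_group"].to_numpy(dtype=float),
                _covariates(
                    [s for s in sessions if s.participant_id in set(merged["participant_id"])]
                ),
                n_boot=n_boot, n_perm=n_perm, seed=seed,
            )
            summary["delta_plus_vs_age"] = {
                "r": res.r, "ci": [res.ci_low, res.ci_high], "p": res.p, "n": res.n,
            }
    Path(outdir / "stats.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return ["optimality.csv", "curves.csv", "stats.json"], len(opt)


_STAGE_FNS = {
    "generate": stage_generate,
    "fit": stage_fit,
    "select": stage_select,
    "recover": stage_recover,
    "stats": stage_stats,
}


def run_pipeline(
    config_path=None,
    output_dir=".",
    stages=STAGES,
    seed: int | None = None,
) -> RunManifest:
    """Run the requested stages in dependency order and write a manifest.

    ``seed`` overrides the config's master seed. Stages not requested are
    skipped; a stage whose upstream artefacts are missing raises
    :class:`PipelineDependencyError`.
    """
    cfg = load_config(config_path)
    master_seed = int(cfg["seed"] if seed is None else seed)
    cfg["seed"] = master_seed
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    try:
        pkg_version = _pkg_version("motorgamble")
    except Exception:
        pkg_version = "unknown"
    manifest = RunManifest(config=cfg, seed=master_seed, package_version=pkg_version)
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        artefacts, n_records = _STAGE_FNS[stage](cfg, outdir, _stage_seed(master_seed, stage))
        manifest.add_stage(stage, artefacts, n_records, time.perf_counter() - t0)
    manifest.write(outdir / "manifest.json")
    return manifest


@dataclass
class ValidationReport:
    """Schema and structure check of a trial-by-trial CSV."""

    n_rows: int
    n_participants: int
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_trials(csv_path) -> ValidationReport:
    """Validate a trial table: schema, completeness, value combinations, bounds.

    Malformed rows are enumerated in the report, never silently dropped.
    """
    df = pd.read_csv(csv_path)
    violations: list[str] = []
    missing = [c for c in TRIAL_CSV_COLUMNS if c not in df.columns]
    if missing:
        return ValidationReport(len(df), 0, [f"missing columns: {missing}"])

    if not df["choice"].dropna().isin([0, 1]).all():
        bad = df.index[~df["choice"].isna() & ~df["choice"].isin([0, 1])].tolist()
        violations.append(f"choice outside {{0,1}} at rows {bad[:10]}")
    if not df["domain"].isin(["reward", "punishment"]).all():
        violations.append("unknown domain values")
    if not df["target_level"].between(1, 7).all():
        violations.append("target_level outside 1..7")
    if not df["age_group"].between(1, 6).all():
        violations.append("age_group outside 1..6")
    if (df["screen_inches"] <= 0).any():
        violations.append("non-positive screen_inches")
    skipped = df[df["choice"] == 0]
    if skipped["motor_success"].notna().any():
        violations.append("motor_success recorded on skipped trials")

    combos = {(d, s, f) for d, _, s, f in value_combinations()}
    for pid, grp in df.groupby("participant_id"):
        if len(grp) != N_TRIALS:
            violations.append(f"participant {pid}: {len(grp)} trials, expected {N_TRIALS}")
            continue
        seen = grp.groupby(["domain", "success_value", "fail_value"]).size()
        for key, count in seen.items():
            if key not in combos:
                violations.append(f"participant {pid}: invalid value combination {key}")
            elif count != 7:
                violations.append(
                    f"participant {pid}: combination {key} appears {count}x, expected 7"
                )
    return ValidationReport(len(df), df["participant_id"].nunique(), violations)
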