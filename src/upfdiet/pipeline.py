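"""Pipeline orchestration and table-style report export.

``run_pipeline`` executes impute → score → model → compare on one input
bundle and writes CSV reports plus a machine-readable JSON run summary.
Reports regenerate bit-identically from the same configuration and seeds.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__, impute, instrument, intake, models, synthetic

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "table5_matrix",
           "write_simulation_bundle"]

log = logging.getLogger("upfdiet")

DIETARY_INDICES = ("pei_upf", "hei2010", "energy_kcal_per_day",
                   "fat_g_per_day")
NEONATAL_OUTCOMES = ("thigh_skinfold_mm", "subscap_skinfold_mm",
                     "neonate_bodyfat_pct")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths, seeds and step toggles for one pipeline run."""

    out_dir: Path
    responses_path: Path | None = None
    cohort_path: Path | None = None
    instrument_path: Path | None = None   # packaged default when None
    composition_path: Path | None = None
    nova_map_path: Path | None = None
    impute_seed: int = 0
    alpha: float = 0.05
    impute_trees: int = 100
    do_impute: bool = True
    do_score: bool = True
    do_fit: bool = True
    do_compare: bool = True

    def validate(self) -> None:
        for name in ("responses_path", "cohort_path", "instrument_path",
                     "composition_path", "nova_map_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.do_score and self.responses_path is None:
            raise ValueError("scoring enabled but no responses file given")
        if self.do_fit and not self.do_score and self.cohort_path is None:
            raise ValueError(
                "modeling enabled without scoring requires a cohort CSV")
        if self.do_fit and self.cohort_path is None:
            raise ValueError("modeling requires a cohort covariate CSV")


def table5_matrix(table: pd.DataFrame, indices: Sequence[str],
                  outcomes: Sequence[str],
                  covariates: Sequence[str] = ("age", "race_aa",
                                               "clinic_high", "obese",
                                               "moderate_pa_pct"),
                  ) -> pd.DataFrame:
    """Single-dietary-index p-value matrix (indices × outcomes).

    For each cell, the p-value of the index term in an adjusted model with
    that index as the only dietary predictor; neonatal outcomes also adjust
    for gestational age at measurement.
    """
    table = models.encode_design(table)
    out = pd.DataFrame(index=list(indices), columns=list(outcomes),
                       dtype=float)
    for outcome in outcomes:
        covs = list(covariates)
        if outcome in NEONATAL_OUTCOMES:
            covs.append("gestational_age_at_measure")
        for index in indices:
            fit = models._ols(table, outcome,
                              [index] + [c for c in covs if c != index])
            out.loc[index, outcome] = fit.pvalues[index]
    return out


def _load_inputs(cfg: RunConfig):
    if cfg.instrument_path is not None:
        inst = instrument.read_instrument(cfg.instrument_path)
    else:
        inst = instrument.default_instrument()
    if cfg.composition_path is not None or cfg.nova_map_path is not None:
        if not (cfg.composition_path and cfg.nova_map_path):
            raise ValueError("composition and NOVA map paths go together")
        items = instrument.read_food_table(cfg.composition_path,
                                           cfg.nova_map_path)
    else:
        items = instrument.default_food_table()
    return inst, items


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the enabled stages in order, writing reports to ``cfg.out_dir``.

    Returns the run summary (also written as ``run_summary.json``).
    Raises :class:`PipelineError` naming the failing stage.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "python": sys.version.split()[0],
        "impute_seed": cfg.impute_seed,
        "alpha": cfg.alpha,
        "stages": {},
        "reports": [],
    }

    def emit(name: str, df: pd.DataFrame, index=False, rounded=False):
        path = out / name
        df.to_csv(path, index=index)
        summary["reports"].append(name)
        if rounded:
            disp = df.copy()
            for c in disp.select_dtypes(float).columns:
                disp[c] = disp[c].map(_report_round)
            disp_path = out / name.replace(".csv", "_display.csv")
            disp.to_csv(disp_path, index=index)
            summary["reports"].append(disp_path.name)

    inst, items = _load_inputs(cfg)
    responses = None
    profiles = None
    cohort = None

    if cfg.responses_path is not None:
        responses = instrument.read_responses(cfg.responses_path, inst, items)
        log.info("read %d response sets", len(responses))
        summary["stages"]["read"] = {"n_subjects": len(responses),
                                     "n_items": len(items)}

    if cfg.do_impute and responses is not None:
        try:
            responses, result = impute.impute_responses(
                responses, items, seed=cfg.impute_seed,
                n_trees=cfg.impute_trees)
            frame = impute.responses_to_frame(responses, items)
            report = pd.DataFrame({
                "variable": result.oob_error.index,
                "missing_count": [int(frame[c].isna().sum())
                                  for c in result.oob_error.index],
                "oob_error": result.oob_error.values,
            })
            emit("imputation_report.csv", report)
            summary["stages"]["impute"] = {
                "n_iter": result.n_iter, "converged": result.converged,
                "n_imputed_vars": len(result.oob_error)}
        except Exception as e:  # noqa: BLE001
            raise PipelineError("impute", e) from e

    if cfg.do_score and responses is not None:
        try:
            profiles = [intake.build_profile(r, items, inst)
                        for r in responses]
            emit("profiles.csv", intake.profiles_to_frame(profiles))
            shares = intake.group_share_table(profiles)
            emit("group_shares.csv", shares.reset_index(names="nova_group"),
                 rounded=True)
            summary["stages"]["score"] = {"n_profiles": len(profiles)}
        except Exception as e:  # noqa: BLE001
            raise PipelineError("score", e) from e

    if cfg.cohort_path is not None:
        cohort = instrument.read_cohort_table(cfg.cohort_path)
        if profiles is not None:
            scored = intake.profiles_to_frame(profiles).set_index(
                "subject_id")["pei_upf"]
            matched = cohort["subject_id"].map(scored)
            if matched.notna().all():
                log.info("replacing cohort pei_upf with scored values")
                cohort = cohort.assign(pei_upf=matched.to_numpy())
                summary["stages"]["score"]["pei_source"] = "scored_responses"

    fits = {}
    if cfg.do_fit:
        if cohort is None:
            raise PipelineError("fit", ValueError("no cohort table"))
        try:
            for outcome in ("gwg_kg", *NEONATAL_OUTCOMES):
                covs = (models.NEONATAL_COVARIATES
                        if outcome in NEONATAL_OUTCOMES
                        else models.MATERNAL_COVARIATES)
                fit = models.fit_ancova(
                    cohort, outcome, covariates=covs,
                    candidate_interactions=models
                    .DEFAULT_CANDIDATE_INTERACTIONS,
                    alpha=cfg.alpha)
                fits[outcome] = fit
                emit(f"model_{outcome}.csv",
                     fit.table().reset_index(names="term"), rounded=True)
                diag = models.diagnostics(fit)
                emit(f"diagnostics_{outcome}.csv", diag.as_frame())
            summary["stages"]["fit"] = {
                o: {"n": f.n, "adj_r2": f.adj_r_squared,
                    "retained_interactions":
                        f.design["retained_interactions"]}
                for o, f in fits.items()}
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError("fit", e) from e

    if cfg.do_compare:
        if cohort is None:
            raise PipelineError("compare", ValueError("no cohort table"))
        try:
            rows = []
            for outcome in ("gwg_kg", *NEONATAL_OUTCOMES):
                covs = list(models.MATERNAL_COVARIATES)
                if outcome in NEONATAL_OUTCOMES:
                    covs.append("gestational_age_at_measure")
                rec = models.compare_indices(cohort, outcome, "pei_upf",
                                             "hei2010", covariates=covs)
                rows.append({
                    "outcome": outcome, "adj_r2_pei_upf": rec.adj_r2_a,
                    "adj_r2_hei2010": rec.adj_r2_b, "f_stat": rec.f_stat,
                    "p_value": rec.p_value})
            emit("index_comparison.csv", pd.DataFrame(rows), rounded=True)
            t5 = table5_matrix(cohort, DIETARY_INDICES,
                               ("gwg_kg", *NEONATAL_OUTCOMES))
            emit("table5_pvalues.csv", t5.reset_index(names="dietary_index"))
            r, ci = models.pearson_ci(cohort["pei_upf"], cohort["hei2010"])
            summary["stages"]["compare"] = {
                "pearson_r_pei_hei": r, "pearson_ci": list(ci)}
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError("compare", e) from e

    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary


def _report_round(v: float) -> float:
    """Published-table precision: 1 decimal at |v| >= 0.1, 1 sig fig below."""
    if not np.isfinite(v) or v == 0:
        return v
    if abs(v) >= 0.1:
        return round(v, 1)
    exp = int(np.floor(np.log10(abs(v))))
    return round(v, -exp)


def write_simulation_bundle(config: synthetic.GeneratorConfig, seed: int,
                            out_dir: Path) -> dict:
    """Write a self-consistent synthetic input bundle to ``out_dir``.

    Contains the instrument, composition table, NOVA map, MCAR-masked
    responses and a cohort CSV whose PEI-UPF column is the share realized by
    scoring the *unmasked* responses (outcomes are generated from it).
    """
    import shutil

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = Path(instrument.__file__).parent / "data"
    for fname in ("instrument.yaml", "composition.csv", "nova_map.csv"):
        shutil.copy(data / fname, out / fname)

    inst = instrument.default_instrument()
    items = instrument.default_food_table()
    masked, unmasked, targets = synthetic.generate_responses(
        config, inst, items, seed=seed)
    realized = np.array([intake.build_profile(r, items, inst).pei_upf
                         for r in unmasked])
    cohort = synthetic.generate_cohort(config, seed=seed + 1,
                                       pei_upf=realized)
    instrument.write_responses(masked, out / "responses.csv")
    cohort.drop(columns=["race_aa", "clinic_high", "obese"]).to_csv(
        out / "cohort.csv", index=False)
    return {"n_subjects": len(cohort), "seed": seed,
            "mean_target_pei": float(np.mean(targets)),
            "mean_realized_pei": float(np.mean(realized)),
            "files": ["instrument.yaml", "composition.csv", "nova_map.csv",
                      "responses.csv", "cohort.csv"]}
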