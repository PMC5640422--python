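"""End-to-end orchestration: generate or load a cohort, apply the
observation process, fit the measurement models, impute education, build
every index, and run the validation and comparison analyses, writing all
artifacts to an output directory stamped with the configuration hash.

Artifacts are deterministic given the configuration (timestamps appear on
console logging only, never inside artifacts), so re-running a config
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as coh
from . import imputation as imp
from . import indices as idx
from . import measurement as mm
from . import validity as val

logger = logging.getLogger("childses.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Run configuration layered over documented defaults."""

    input: str = "synthetic"            # "synthetic" or a cohort CSV path
    output_dir: str = "childses_run"
    seed: int = 0
    n_respondents: int = 31169
    spec_overrides: dict = field(default_factory=dict)
    item_factor_map: dict = field(default_factory=dict)   # overrides
    n_factor_candidates: tuple = (1, 2, 3)
    run_validation: bool = True
    run_comparison: bool = True
    run_delta_r2: bool = False
    delta_r2: dict = field(default_factory=lambda: {
        "n": 7783, "r2_true": 0.07, "threshold": 0.01, "reps": 10000,
        "rho_between": val.DEFAULT_RHO_BETWEEN})

    def validate(self) -> None:
        known = set(coh.ALL_ITEMS)
        for item in self.item_factor_map:
            if item not in known:
                raise PipelineError(
                    "config", f"item-factor map names unknown item {item!r}")
        if not isinstance(self.seed, (int, np.integer)):
            raise PipelineError("config", "seed must be an integer")

    def to_yaml(self) -> str:
        d = {k: v for k, v in self.__dict__.items()}
        d["n_factor_candidates"] = list(self.n_factor_candidates)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        cfg = cls()
        for k, v in data.items():
            if not hasattr(cfg, k):
                raise PipelineError("config", f"unknown config key {k!r}")
            setattr(cfg, k, v)
        cfg.n_factor_candidates = tuple(cfg.n_factor_candidates)
        return cfg

    @property
    def config_hash(self) -> str:
        """Hash of the data-and-measurement configuration.  The artifact
        destination and the stage toggles are excluded: the same cohort and
        measurement settings hash identically wherever the artifacts go and
        whichever analysis batteries are switched on."""
        d = yaml.safe_load(self.to_yaml())
        for key in ("output_dir", "run_validation", "run_comparison",
                    "run_delta_r2", "delta_r2"):
            d.pop(key, None)
        return hashlib.sha256(
            yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:16]


def build_spec(config: PipelineConfig) -> coh.CohortSpec:
    spec = coh.CohortSpec(n_respondents=config.n_respondents, seed=config.seed)
    for key, value in config.spec_overrides.items():
        if not hasattr(spec, key):
            raise PipelineError("config", f"unknown spec override {key!r}")
        current = getattr(spec, key)
        if isinstance(current, dict) and isinstance(value, dict) and value:
            merged = dict(current)
            merged.update(value)
            setattr(spec, key, merged)
        else:
            # non-dict values and empty dicts replace the default outright
            # (an empty mapping means "clear", e.g. no module subsampling)
            setattr(spec, key, value)
    spec.validate()
    return spec


def _apply_item_map(schemas, item_map):
    if not item_map:
        return schemas
    return [mm.ItemSchema(name=s.name, levels=s.levels,
                          factor=item_map.get(s.name, s.factor))
            for s in schemas]


@dataclass
class ScaleFit:
    name: str
    selection: mm.StructureSelection
    solution: mm.FactorSolution       # refit on retained items
    scores: pd.DataFrame              # respondent_id, eta_<label> columns
    scale: pd.Series                  # z-scored scale, indexed like scores


def fit_scale(table: pd.DataFrame, schemas, name: str,
              candidates=(1, 2, 3), rotation_seed: int = 0,
              orientation_map=None) -> ScaleFit:
    """EFA structure search, item retention, refit, and full-information
    scoring for one scale."""
    corr = mm.build_correlation_matrix(table, schemas)
    solutions = []
    for m in candidates:
        try:
            solutions.append(mm.fit_efa(corr, m, rotation_seed=rotation_seed))
        except mm.MeasurementError:
            continue
    if not solutions:
        raise PipelineError("measurement", f"{name}: no admissible factor model")
    selection = mm.select_structure(solutions)
    retained = [s for s in schemas if s.name in selection.retained_items]
    if len(retained) < 2:
        raise PipelineError("measurement", f"{name}: fewer than 2 items retained")
    if len(retained) < len(schemas):
        corr_r = mm.build_correlation_matrix(table, retained)
        p = len(retained)
        # the retained item set may admit fewer factors than were selected
        m_refit = min(selection.solution.n_factors, (p - 1) // 2)
        m_refit = max(m_refit, 1)
        solution = mm.fit_efa(corr_r, m_refit, rotation_seed=rotation_seed)
    else:
        solution = selection.solution
    labels = mm.label_factors(solution, retained)
    if len(set(labels)) < len(labels):  # de-duplicate defensively
        seen: dict = {}
        dedup = []
        for l in labels:
            seen[l] = seen.get(l, 0) + 1
            dedup.append(f"{l}_{seen[l]}" if labels.count(l) > 1 else l)
        labels = dedup
    scores = mm.score_respondents(solution, table, retained)
    rename = {f"eta{k+1}": f"eta_{labels[k]}" for k in range(solution.n_factors)}
    scores = scores.rename(columns=rename)
    orientation = [1.0] * solution.n_factors
    if orientation_map:
        # strip any de-duplication suffix before the lookup
        orientation = [orientation_map.get(l.rstrip("_0123456789"), 1.0)
                       for l in labels]
    scale = mm.build_scale(scores, [f"eta_{l}" for l in labels], orientation)
    return ScaleFit(name=name, selection=selection, solution=solution,
                    scores=scores, scale=scale)


#: factor orientations: every factor is reflected (if needed) to point
#: toward more capital before the member scores are summed into a scale
SCALE_ORIENTATION = {
    "maternal_investment": 1.0, "family_structure": 1.0,
    "avg_financial_resources": 1.0, "financial_instability": -1.0,
}


def run_measurement(table: pd.DataFrame, config: PipelineConfig):
    """Fit both scales and return (cSC fit, cFC fit, table with score and
    scale columns merged in)."""
    recoded = coh.recode_never_lived(table)
    csc_s = _apply_item_map(coh.csc_schemas(), config.item_factor_map)
    cfc_s = _apply_item_map(coh.cfc_schemas(), config.item_factor_map)
    csc_fit = fit_scale(recoded, csc_s, "csc",
                        candidates=config.n_factor_candidates,
                        rotation_seed=config.seed,
                        orientation_map=SCALE_ORIENTATION)
    cfc_fit = fit_scale(recoded, cfc_s, "cfc",
                        candidates=config.n_factor_candidates,
                        rotation_seed=config.seed,
                        orientation_map=SCALE_ORIENTATION)
    out = table.copy()
    for fit, scale_col in ((csc_fit, "csc"), (cfc_fit, "cfc")):
        merged = fit.scores.copy()
        merged[scale_col] = fit.scale.to_numpy()
        eta_cols = [c for c in merged.columns if c.startswith("eta_")]
        out = out.merge(merged[["respondent_id", scale_col] + eta_cols],
                        on="respondent_id", how="left")
    return csc_fit, cfc_fit, out


def solution_report(fit: ScaleFit) -> str:
    """Plain-text report of a fitted measurement model."""
    s = fit.solution
    lines = [f"scale: {fit.name}",
             f"n_factors: {s.n_factors} (fit rules met: {fit.selection.met_fit_rules})",
             f"factors: {', '.join(s.factor_labels)}",
             f"chi2 = {s.chi2:.3f} on df = {s.df} (effective n = {s.effective_n})",
             f"RMSEA = {s.rmsea:.4f}  CFI = {s.cfi:.4f}",
             f"eigenvalues: {np.array2string(s.eigenvalues, precision=3)}",
             f"dropped items: {fit.selection.dropped_items or 'none'}",
             "", "loadings (geomin-rotated):"]
    for i, item in enumerate(s.item_names):
        row = "  ".join(f"{v:+.3f}" for v in s.loadings[i])
        lines.append(f"  {item:26s} {row}")
    lines.append("")
    lines.append("factor correlations:")
    for i in range(s.n_factors):
        lines.append("  " + "  ".join(f"{v:+.3f}" for v in s.phi[i]))
    lines.append("")
    lines.append("thresholds:")
    for item in s.item_names:
        tau = s.thresholds[item]
        lines.append(f"  {item:26s} " + "  ".join(f"{v:+.3f}" for v in tau))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# N accounting / flowchart
# ---------------------------------------------------------------------------

def emit_flowchart(accounting: dict) -> str:
    """Text flowchart of per-analysis inclusions and exclusions.

    ``accounting`` maps analysis name to ``{"input": N, "analyzed": n,
    "exclusions": {reason: count}}``; for every analysis the input must
    equal analyzed plus the itemized exclusions (a mismatch indicates a
    pipeline bug and is a hard error).
    """
    lines = ["Sample accounting", "================="]
    for name, acc in accounting.items():
        total_excl = sum(acc["exclusions"].values())
        if acc["input"] != acc["analyzed"] + total_excl:
            raise PipelineError(
                "flowchart",
                f"accounting mismatch for {name!r}: input {acc['input']} != "
                f"analyzed {acc['analyzed']} + excluded {total_excl}")
        lines.append(f"{name}: input N = {acc['input']}")
        for reason, count in acc["exclusions"].items():
            lines.append(f"  - excluded, {reason}: {count}")
        lines.append(f"  -> analyzed N = {acc['analyzed']}")
    return "\n".join(lines) + "\n"


def _block_accounting(table: pd.DataFrame, blocks: dict) -> dict:
    """Independent achievable-N accounting for each specification block and
    outcome: input = analyzed + missing-outcome + missing-predictor."""
    accounting = {}
    n = len(table)
    for label, cols in blocks.items():
        pred_ok = np.ones(n, dtype=bool)
        for c in cols:
            pred_ok &= ~np.isnan(val._clean(table[c].to_numpy()))
        if label == "Hargrove":
            pred_ok &= table["hargrove_eligible"].to_numpy() == 1.0
        for outcome in val.COMPARISON_OUTCOMES:
            out_ok = ~np.isnan(val._clean(table[outcome].to_numpy()))
            analyzed = int((pred_ok & out_ok).sum())
            accounting[f"{label} / {outcome}"] = {
                "input": n, "analyzed": analyzed,
                "exclusions": {
                    "missing outcome": int((~out_ok).sum()),
                    "missing predictor (outcome observed)":
                        int((out_ok & ~pred_ok).sum()),
                }}
    return accounting


# ---------------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage in order and write artifacts; returns the output
    directory.  Any stage failure aborts with the stage name."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = f"config_hash: {config.config_hash}\nseed: {config.seed}\n"
    run_log = [f"config_hash={config.config_hash}", f"seed={config.seed}"]

    # --- generate or load ---------------------------------------------------
    try:
        if config.input == "synthetic":
            spec = build_spec(config)
            table = coh.generate_cohort(spec)
            run_log.append(f"generate: n={len(table)}")
            table = coh.apply_missingness(table, spec)
            run_log.append("missingness: applied")
        else:
            table = coh.read_cohort(config.input)
            run_log.append(f"load: {config.input} n={len(table)}")
    except Exception as exc:
        raise PipelineError("generate", str(exc)) from exc
    coh.write_cohort(table, out_dir / "cohort.csv")

    # --- measurement --------------------------------------------------------
    try:
        csc_fit, cfc_fit, table = run_measurement(table, config)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("measurement", str(exc)) from exc
    for fit in (csc_fit, cfc_fit):
        (out_dir / f"solution_{fit.name}.txt").write_text(
            stamp + solution_report(fit))
        loadings = pd.DataFrame(fit.solution.loadings,
                                index=fit.solution.item_names,
                                columns=fit.solution.factor_labels)
        loadings.to_csv(out_dir / f"loadings_{fit.name}.csv")
        run_log.append(
            f"measurement {fit.name}: n_factors={fit.solution.n_factors} "
            f"scored={len(fit.scores)} "
            f"excluded_all_items_missing={len(table) - len(fit.scores)}")

    # --- imputation and indices ---------------------------------------------
    try:
        table, audit = imp.impute_parent_education(table, seed=config.seed)
        table["chc"] = imp.build_chc(table["mother_edu_imputed"],
                                     table["father_edu_imputed"])
        run_log.append(f"imputation: imputed={int(audit['n_imputed'].sum())} "
                       f"coverage=100%")
    except Exception as exc:
        raise PipelineError("imputation", str(exc)) from exc
    audit.to_csv(out_dir / "imputation_audit.csv", index=False)
    try:
        table = idx.attach_indices(table, table["csc"], table["cfc"], table["chc"])
    except Exception as exc:
        raise PipelineError("indices", str(exc)) from exc
    run_log.append("indices: attached validated, Luo, Glymour, Hargrove")
    coh.write_cohort(table, out_dir / "cohort_with_measures.csv")

    # --- validation battery -------------------------------------------------
    if config.run_validation:
        try:
            battery = val.run_validity_battery(table)
            alphas = scale_reliabilities(table)
        except Exception as exc:
            raise PipelineError("validation", str(exc)) from exc
        battery.to_csv(out_dir / "validity_battery.csv", index=False)
        alphas.to_csv(out_dir / "reliability.csv", index=False)
        run_log.append(f"validation: {len(battery)} regressions")

    # --- comparison tables --------------------------------------------------
    if config.run_comparison:
        try:
            comp = val.run_comparison_tables(table)
        except Exception as exc:
            raise PipelineError("comparison", str(exc)) from exc
        comp["complete_case"].to_csv(out_dir / "table_complete_case.csv", index=False)
        comp["achievable"].to_csv(out_dir / "table_achievable.csv", index=False)
        accounting = _block_accounting(table, val.comparison_blocks(table))
        flow = emit_flowchart(accounting)
        (out_dir / "flowchart.txt").write_text(stamp + flow)
        run_log.append(f"comparison: complete_case_n={comp['complete_case_n']}")

    # --- delta-R2 simulation ------------------------------------------------
    if config.run_delta_r2:
        try:
            params = dict(config.delta_r2)
            point = val.delta_r2_significance(
                n=params["n"], r2_true=params["r2_true"],
                rho_between=params["rho_between"], reps=params["reps"],
                threshold=params["threshold"], seed=config.seed)
            sweep = val.delta_r2_sensitivity(
                n=params["n"], r2_true=params["r2_true"], reps=params["reps"],
                threshold=params["threshold"], seed=config.seed)
        except Exception as exc:
            raise PipelineError("delta_r2", str(exc)) from exc
        pd.DataFrame([{"probability": point, **params}]).to_csv(
            out_dir / "delta_r2.csv", index=False)
        sweep.to_csv(out_dir / "delta_r2_sensitivity.csv", index=False)
        run_log.append(f"delta_r2: probability={point:.4f}")

    (out_dir / "run_log.txt").write_text("\n".join(run_log) + "\n")
    (out_dir / "config.yaml").write_text(
        f"# config_hash: {config.config_hash}\n" + config.to_yaml())
    logger.info("pipeline complete: %s", out_dir)
    return out_dir


def scale_reliabilities(table: pd.DataFrame) -> pd.DataFrame:
    """Standardized alpha for the two scales and their sub-factors, among
    complete responders on each item set."""
    recoded = coh.recode_never_lived(table)
    sets = {
        "csc": list(coh.CSC_ITEMS),
        "maternal_investment": ["mom_effort", "mom_teach", "mom_attention"],
        "family_structure": ["parent_figures", "lived_with_mother",
                             "lived_with_father", "lived_with_grandparents"],
        "cfc": [c for c in coh.CFC_ITEMS if c != "mother_worked"],
        "avg_financial_resources": ["ses3", "ses5", "father_occ", "father_unemp"],
        "financial_instability": ["moved_financial", "fin_help", "bankruptcy",
                                  "lost_business"],
    }
    rows = []
    for name, cols in sets.items():
        try:
            r = val.cronbach_alpha_standardized(
                coh.keyed_items(recoded, cols), scale=name)
            rows.append({"scale": name, "k": r.k, "n": r.n,
                         "r_bar": r.r_bar, "alpha": r.alpha})
        except val.ValidityError as exc:
            rows.append({"scale": name, "k": len(cols), "n": 0,
                         "r_bar": np.nan, "alpha": np.nan})
            logger.warning("reliability %s: %s", name, exc)
    return pd.DataFrame(rows)
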