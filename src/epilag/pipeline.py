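"""Configuration, orchestration and file plumbing for a full reproducible run.

A run is described by one YAML-serializable :class:`RunConfig` and executes
simulate -> preprocess -> factors -> model/inference -> downstream, writing
every tabular artifact as CSV (sample ids are the join key everywhere) and a
manifest with seeds, parameter and artifact hashes.  Under a fixed seed two
runs produce identical artifacts and manifests (modulo the timestamp field).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import downstream as ds
from . import synthdata as sd
from .dlnm import lag_basis, cross_basis
from .factors import assign_cpgs, fit_factors, kmo, parallel_analysis
from .inference import TestLedger, analyze_factor, select_random_effects, sidak_level
from .preprocess import beta_from_signals, encode_covariates, filter_probes, trim_outliers
from .robustlmm import ModelSpec, rlrt_null_distribution

__all__ = ["RunConfig", "run_all", "validate_inputs", "STAGES"]

log = logging.getLogger("epilag")

STAGES = ("simulate", "preprocess", "factors", "fit", "downstream")

_DEFAULTS: dict = {
    "seed": 0,
    "n_pairs": 189,
    "outdir": "epilag_run",
    "cohort": {},
    "exposure": {"mean": 12.97, "sd": 8.25, "ar_coef": 0.7,
                 "seasonal_amplitude": 0.25, "seasonal_phase": 0.0},
    "truth": {
        "lag_curve": {"type": "null"},  # or {"type": "gaussian", center, width, scale}
        "n_probes": {"IGF2": 24, "H19": 16},
        "n_factors": {"IGF2": 3, "H19": 2},
        "loading": 0.7,
        "batch_sd": [0.3, 0.2, 0.2],
        "noise_sd": 1.0,
        "mediation": [0.0, 0.0, 0.0],
        "affected_factor": 0,
        "sex_effect": 0.0,
    },
    "methylation": {"frac_probes_outlier": 0.1, "cell_outlier_rate": 0.02,
                    "frac_probes_missing": 0.1, "cell_missing_rate": 0.15,
                    "total_intensity": 10000.0, "beta_scale": 0.5},
    "factors": {"cutoff": 0.45, "pa_sims": 200, "pa_quantile": 0.95,
                "min_total_variance": 0.60, "max_rmsr": 0.042},
    "dlnm": {"n_knots": 3, "delta": 5.0},
    "model": {"k_fixed": 1.345, "k_random": 1.345,
              "re_candidates": ["plate", "sentrix_row", "sentrix_col"],
              "rlrt_nsim": 299, "re_alpha": 0.05, "fwer": 0.05,
              "stratified": True},
    "downstream": {"enabled": True, "n_transcripts": 2000, "linked": 100,
                   "r": 0.5, "n_boot": 1000, "growth_noise_sd": 0.2},
    "sensitivity": {"enabled": False},
}


def _merge(base: dict, override: dict) -> dict:
    out = {}
    for k, v in base.items():
        if k in override and isinstance(v, dict) and isinstance(override[k], dict):
            out[k] = _merge(v, override[k])
        elif k in override:
            out[k] = override[k]
        else:
            out[k] = v
    for k in override:
        if k not in base:
            out[k] = override[k]
    return out


@dataclass
class RunConfig:
    """All knobs of a run; round-trips through YAML byte-identically."""

    settings: dict = field(default_factory=lambda: json.loads(json.dumps(_DEFAULTS)))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(settings=_merge(json.loads(json.dumps(_DEFAULTS)), d))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.settings, fh, sort_keys=True)

    def __getitem__(self, key):
        return self.settings[key]


def _truth_from_config(cfg: RunConfig):
    t = cfg["truth"]
    lc = t["lag_curve"]
    if lc.get("type", "null") == "null":
        curve = sd.lag_curve_null()
    elif lc["type"] == "gaussian":
        curve = sd.lag_curve_gaussian(center=lc.get("center", 34.0),
                                      width=lc.get("width", 3.0),
                                      scale=lc.get("scale", 0.02))
    else:
        raise ValueError(f"unknown lag_curve type {lc.get('type')!r}")
    return sd.default_truth(
        n_probes=dict(t["n_probes"]), n_factors=dict(t["n_factors"]),
        loading=t["loading"], lag_curve=curve, batch_sd=tuple(t["batch_sd"]),
        noise_sd=t["noise_sd"], mediation=tuple(t["mediation"]),
        affected_factor=t["affected_factor"], sex_effect=t["sex_effect"],
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig, last_stage: str = "downstream",
            outdir=None) -> dict:
    """Execute the pipeline through ``last_stage`` and write all artifacts.

    Returns the manifest dict (also written to ``manifest.json``).  Any stage
    failure propagates after the artifacts produced so far are on disk.
    """
    if last_stage not in STAGES:
        raise ValueError(f"unknown stage {last_stage!r}")
    n_stage = STAGES.index(last_stage)
    out = Path(outdir or config["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    rng = np.random.default_rng(seed)
    stage_seeds = {s: int(rng.integers(2**31 - 1)) for s in
                   ("cohort", "exposure", "methylation", "transcriptome",
                    "rlrt", "pa", "mediation", "growth")}
    artifacts: dict[str, str] = {}

    def save(df: pd.DataFrame, name: str):
        p = out / name
        df.to_csv(p)
        artifacts[name] = str(p)

    # ---- simulate -------------------------------------------------------
    log.info("stage simulate")
    cohort = sd.generate_cohort(int(config["n_pairs"]), stage_seeds["cohort"],
                                params=config["cohort"])
    exposure = sd.generate_exposure(cohort, stage_seeds["exposure"], **config["exposure"])
    truth, annotation = _truth_from_config(config)
    M, U, beta_raw, true_scores = sd.generate_methylation(
        cohort, exposure, truth, annotation, stage_seeds["methylation"],
        **config["methylation"])
    save(cohort, "cohort.csv")
    save(exposure, "exposure.csv")
    save(M, "signals_M.csv")
    save(U, "signals_U.csv")
    save(annotation.set_index("probe_id"), "annotation.csv")
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump({
            "lag_curve": truth.lag_curve.tolist(),
            "batch_sd": list(truth.batch_sd), "noise_sd": truth.noise_sd,
            "mediation": list(truth.mediation),
            "affected_factor": truth.affected_factor,
        }, fh, sort_keys=True)
    artifacts["truth.yaml"] = str(out / "truth.yaml")
    manifest = _finish_manifest(config, out, artifacts, stage_seeds, "simulate")
    if n_stage < 1:
        return manifest

    # ---- preprocess -----------------------------------------------------
    log.info("stage preprocess")
    beta = pd.DataFrame(beta_from_signals(M.to_numpy(), U.to_numpy()),
                        index=M.index, columns=M.columns)
    beta[M.isna() | U.isna()] = np.nan
    trimmed = beta.copy()
    for pid in trimmed.index:
        trimmed.loc[pid], _ = trim_outliers(trimmed.loc[pid].to_numpy())
    per_gene, report = filter_probes(trimmed, annotation)
    design = encode_covariates(cohort)
    save(report.to_frame().set_index("probe_id"), "filter_report.csv")
    for g, bg in per_gene.items():
        save(bg, f"beta_{g}.csv")
    manifest = _finish_manifest(config, out, artifacts, stage_seeds, "preprocess")
    if n_stage < 2:
        return manifest

    # ---- factors --------------------------------------------------------
    log.info("stage factors")
    fcfg = config["factors"]
    solutions, summaries, score_cols = {}, {}, {}
    for g, bg in per_gene.items():
        Xg = bg.T  # samples x probes
        if Xg.shape[1] < 3:
            log.warning("gene %s has <3 probes after filtering; skipped", g)
            continue
        msa = kmo(Xg.to_numpy())
        k = parallel_analysis(Xg.to_numpy(), n_sims=fcfg["pa_sims"],
                              quantile=fcfg["pa_quantile"], seed=stage_seeds["pa"])
        if k == 0:
            log.warning("parallel analysis retained 0 factors for %s", g)
            continue
        k = min(k, Xg.shape[1] - 1)
        sol = fit_factors(Xg, n_factors=k, max_iter=5000)
        solutions[g] = sol
        summaries[g] = {
            "kmo": float(msa), "n_factors": int(k),
            "total_explained": sol.total_explained, "rmsr": sol.rmsr,
            "meets_variance_rule": bool(sol.total_explained > fcfg["min_total_variance"]),
            "meets_kelly_rmsr": bool(sol.rmsr < fcfg["max_rmsr"]),
            "assignments": {f: {p: float(l) for p, l in s.items()}
                            for f, s in assign_cpgs(sol, fcfg["cutoff"]).items()},
        }
        save(sol.loadings, f"loadings_{g}.csv")
        cols = {}
        for f in sol.scores.columns:
            cols[f"{g}_{f}"] = sol.scores[f]
        score_cols[g] = pd.DataFrame(cols, index=sol.scores.index)
        save(score_cols[g], f"scores_{g}.csv")
    with open(out / "factor_summary.yaml", "w") as fh:
        yaml.safe_dump(summaries, fh, sort_keys=True)
    artifacts["factor_summary.yaml"] = str(out / "factor_summary.yaml")
    manifest = _finish_manifest(config, out, artifacts, stage_seeds, "factors")
    if n_stage < 3:
        return manifest

    # ---- fit (DLNM + mixed models + inference) --------------------------
    log.info("stage fit")
    mcfg = config["model"]
    basis = lag_basis(n_knots=int(config["dlnm"]["n_knots"]))
    cb = cross_basis(exposure, basis)
    data = pd.concat([design.matrix, cb.to_frame(index=cohort.index),
                      cohort[["plate", "sentrix_row", "sentrix_col"]]], axis=1)
    covs = [c for c in design.matrix.columns]
    ledgers, results, fit_meta = {}, {}, {}
    # the RLRT null law depends only on the design and grouping: simulate once
    null_stats = {}
    probe_spec = ModelSpec(response="__r", crossbasis=cb.column_names,
                           covariates=covs, groups=list(mcfg["re_candidates"]))
    X_probe = pd.concat([pd.Series(0.0, index=data.index, name="__r"), data], axis=1)
    for comp in mcfg["re_candidates"]:
        _, Xd, codes = probe_spec.build(X_probe)
        null_stats[comp] = rlrt_null_distribution(
            Xd, {comp: codes[comp]}, int(mcfg["rlrt_nsim"]), stage_seeds["rlrt"])
    for g, sc in score_cols.items():
        m = sc.shape[1]
        ledger = TestLedger(gene=g, m=m, fwer=mcfg["fwer"],
                            stratified=bool(mcfg["stratified"]))
        lev_all = sidak_level(m, mcfg["fwer"])
        lev_strat = sidak_level(2 * m, mcfg["fwer"]) if mcfg["stratified"] else None
        dat_g = pd.concat([sc, data], axis=1)
        lrt_rows = []
        for col in sc.columns:
            spec = ModelSpec(response=col, crossbasis=cb.column_names,
                             covariates=covs, groups=[])
            sel = select_random_effects(spec, dat_g, list(mcfg["re_candidates"]),
                                        alpha=mcfg["re_alpha"], null_stats=null_stats)
            spec.groups = sel["selected"]
            res = analyze_factor(col, spec, dat_g, basis, conf_level=lev_all,
                                 conf_level_stratified=lev_strat,
                                 k_fixed=mcfg["k_fixed"], k_random=mcfg["k_random"],
                                 delta=config["dlnm"]["delta"])
            results[col] = res
            lrt_rows.append({"factor": col, "stat": res.lrt_stat,
                             "df": res.lrt_df, "p": res.lrt_p,
                             "groups": ",".join(spec.groups)})
            fsum = pd.DataFrame({
                "estimate": res.fit.beta,
                "se": np.sqrt(np.diag(res.fit.cov_beta)),
            })
            fsum.index.name = "term"
            save(fsum, f"fit_{col}.csv")
            fit_meta[col] = {
                "sigma2": float(res.fit.sigma2),
                "tau2": {g: float(t) for g, t in res.fit.tau2.items()},
                "k_fixed": float(mcfg["k_fixed"]),
                "k_random": float(mcfg["k_random"]),
                "converged": bool(res.fit.converged),
                "n_iter": int(res.fit.n_iter),
            }
            save(res.effects_all.weekly, f"effects_weekly_{col}.csv")
            save(res.effects_all.windows, f"effects_windows_{col}.csv")
            if res.effects_boys is not None:
                save(res.effects_boys.windows, f"effects_windows_{col}_boys.csv")
                save(res.effects_girls.windows, f"effects_windows_{col}_girls.csv")
        ledger.lrt = pd.DataFrame(lrt_rows).set_index("factor")
        ledgers[g] = ledger
        save(ledger.lrt, f"lrt_{g}.csv")
    with open(out / "test_ledger.yaml", "w") as fh:
        yaml.safe_dump({g: {"m": l.m, "m_effective": l.m_effective,
                            "fwer": l.fwer, "conf_level": l.conf_level}
                        for g, l in ledgers.items()}, fh, sort_keys=True)
    artifacts["test_ledger.yaml"] = str(out / "test_ledger.yaml")
    with open(out / "fits.yaml", "w") as fh:
        yaml.safe_dump(fit_meta, fh, sort_keys=True)
    artifacts["fits.yaml"] = str(out / "fits.yaml")

    if config["sensitivity"]["enabled"] and results:
        from .inference import run_sensitivity
        first = next(iter(results))
        gene = first.split("_")[0]
        spec0 = ModelSpec(response=first, crossbasis=cb.column_names,
                          covariates=covs, groups=results[first].groups_used)
        dat_g = pd.concat([pd.concat(list(score_cols.values()), axis=1), data],
                          axis=1)
        sens = run_sensitivity(spec0, dat_g, exposure, cohort, basis,
                               conf_level=ledgers[gene].conf_level,
                               k_main=mcfg["k_fixed"],
                               delta=config["dlnm"]["delta"])
        save(sens["k_choice"], "sensitivity_k_windows.csv")
        save(sens["df_choice"]["information_criteria"], "sensitivity_ic.csv")
        save(sens["preterm_excluded"]["effects"].windows,
             "sensitivity_preterm_windows.csv")
        with open(out / "sensitivity.yaml", "w") as fh:
            yaml.safe_dump({
                "n_preterm_dropped": sens["preterm_excluded"]["n_dropped"],
                "unconstrained_vs_df5": sens["df_choice"]["unconstrained_vs_df5"],
            }, fh, sort_keys=True)
        artifacts["sensitivity.yaml"] = str(out / "sensitivity.yaml")
    manifest = _finish_manifest(config, out, artifacts, stage_seeds, "fit")
    run_all.last_results = {"ledgers": ledgers, "results": results,
                            "solutions": solutions, "cohort": cohort,
                            "exposure": exposure, "design": design}
    if n_stage < 4:
        return manifest

    # ---- downstream -----------------------------------------------------
    dcfg = config["downstream"]
    if dcfg["enabled"] and results:
        log.info("stage downstream")
        first = next(iter(results))
        score = pd.concat([sc for sc in score_cols.values()], axis=1)[first]
        expr, linked = sd.generate_transcriptome(
            cohort, pd.DataFrame({first: score}), stage_seeds["transcriptome"],
            n_transcripts=int(dcfg["n_transcripts"]), linked=int(dcfg["linked"]),
            r=dcfg["r"], target_factor=0)
        table, selected = ds.correlate_transcripts(score, expr)
        sets = sd.make_gene_sets(list(expr.index), linked, stage_seeds["transcriptome"])
        ds.write_gmt(sets, out / "gene_sets.gmt")
        artifacts["gene_sets.gmt"] = str(out / "gene_sets.gmt")
        ora_tab = ds.ora(selected, sets, list(expr.index))
        save(table.head(200), "transcript_rank.csv")
        save(ora_tab, "ora.csv")

        pi_outcome = sd.generate_growth_outcome(
            cohort, exposure, true_scores, truth, stage_seeds["growth"],
            noise_sd=dcfg["growth_noise_sd"])
        cov_no_sex = design.matrix
        coef, se, p = ds.growth_regression(pi_outcome, score, cov_no_sex)
        med = ds.mediate(ds.last3_mean_exposure(exposure, cohort), score,
                         pi_outcome, cov_no_sex, n_boot=int(dcfg["n_boot"]),
                         seed=stage_seeds["mediation"])
        with open(out / "downstream.yaml", "w") as fh:
            yaml.safe_dump({
                "growth_regression": {"factor": first, "coef_per_sd": float(coef),
                                      "se": float(se), "p": float(p)},
                "mediation": {"a": med.a, "b": med.b, "c_prime": med.c_prime,
                              "indirect": med.indirect, "total": med.total,
                              "ci": [med.ci_lower, med.ci_upper],
                              "n_boot": med.n_boot},
            }, fh, sort_keys=True)
        artifacts["downstream.yaml"] = str(out / "downstream.yaml")
    return _finish_manifest(config, out, artifacts, stage_seeds, "downstream")


def _finish_manifest(config, out: Path, artifacts, stage_seeds, stage) -> dict:
    manifest = {
        "created": datetime.now(timezone.utc).isoformat(),
        "stage": stage,
        "seed": int(config["seed"]),
        "stage_seeds": stage_seeds,
        "config_sha256": hashlib.sha256(yaml.safe_dump(
            {k: v for k, v in config.settings.items() if k != "outdir"},
            sort_keys=True).encode()).hexdigest(),
        "artifacts": {k: _sha256(Path(v)) for k, v in artifacts.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def validate_inputs(paths: dict) -> dict:
    """Cross-file consistency checks on user-supplied inputs.

    ``paths`` maps names (cohort, exposure, beta, annotation, expression) to
    CSV paths.  Errors are misalignments that make the analysis impossible;
    warnings cover recoverable issues (e.g. sample order differences, which
    the pipeline resolves by id).
    """
    errors, warn = [], []
    tabs = {}
    for name, p in paths.items():
        try:
            tabs[name] = pd.read_csv(p, index_col=0)
        except Exception as exc:  # noqa: BLE001 - report, do not crash
            errors.append(f"{name}: unreadable ({exc})")
    cohort = tabs.get("cohort")
    exposure = tabs.get("exposure")
    beta = tabs.get("beta")
    ann = tabs.get("annotation")
    if exposure is not None:
        if exposure.shape[1] != 40:
            errors.append(f"exposure: expected 40 weekly columns, got {exposure.shape[1]}")
        elif (exposure.to_numpy(float) < 0).any():
            errors.append("exposure: negative values present")
    if beta is not None:
        vals = beta.to_numpy(float)
        bad = np.argwhere((vals < 0) | (vals > 1))
        if len(bad):
            i, j = bad[0]
            errors.append(f"beta: value out of [0,1] at probe {beta.index[i]}, "
                          f"sample {beta.columns[j]}")
    if cohort is not None and exposure is not None and exposure.shape[1] == 40:
        a, b = set(cohort.index), set(exposure.index)
        if a != b:
            errors.append(f"cohort/exposure sample ids differ: {sorted(a ^ b)[:5]}")
        elif list(cohort.index) != list(exposure.index):
            warn.append("cohort/exposure sample order differs; aligned by id")
    if cohort is not None and beta is not None:
        a, b = set(cohort.index), set(beta.columns)
        if a != b:
            errors.append(f"cohort/beta sample ids differ: {sorted(a ^ b)[:5]}")
    if beta is not None and ann is not None:
        missing = set(beta.index) - set(ann.index)
        if missing:
            errors.append(f"annotation missing probes: {sorted(missing)[:5]}")
    if "expression" in tabs and cohort is not None:
        a, b = set(cohort.index), set(tabs["expression"].columns)
        if a != b:
            errors.append(f"cohort/expression sample ids differ: {sorted(a ^ b)[:5]}")
    return {"ok": not errors, "errors": errors, "warnings": warn}
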