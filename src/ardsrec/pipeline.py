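"""End-to-end pipeline: simulate -> subgroup split -> regression screen ->
recognition (Naive Bayes and mixture) -> consolidated report.

Every stochastic stage receives a sub-seed derived from the run seed via
``numpy.random.SeedSequence``, logged in the run manifest, so a run is a
pure function of (config, seed).
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import (CollinearityError, DegenerateInputError,
                     InsufficientDataError, InvalidInputError)
from .mixture import bootstrap_fractions, ks_compare
from .naive_bayes import (bootstrap_boundary, classify_recognized, fit_kde2d,
                          nb_recognition_by_severity, posterior_odds)
from .errors import UndefinedOddsError
from .regression import (SCREEN_FACTORS_ARDS, SCREEN_FACTORS_CONTROL,
                         covariate_analysis, multivariable_select,
                         sensitivity_filter, univariable_screen)
from .synthetic import generate_cohort, read_cohort_csv, write_cohort_csv
from .types import (AnalysisConfig, Cohort, CohortConfig, MixtureFit,
                    PatientRecord, RecognitionEstimate, Severity,
                    SEVERITY_ORDER, Subgroup)

logger = logging.getLogger(__name__)


def split_subgroups(records: Sequence[PatientRecord]
                    ) -> dict[Subgroup, list[PatientRecord]]:
    """Partition into pooled-documented, ARDS non-documented and control
    non-documented subgroups (disjoint; union is the input)."""
    out: dict[Subgroup, list[PatientRecord]] = {s: [] for s in Subgroup}
    for r in records:
        out[r.subgroup].append(r)
    return out


def summarize_recognition(nb_estimates: Sequence[RecognitionEstimate],
                          mixture_fits: Sequence[MixtureFit],
                          records: Sequence[PatientRecord]) -> pd.DataFrame:
    """One row per severity: documented n and %, NB %, mixture mean % with
    99% CI.  Full precision; see :func:`render_report` for the rounded view."""
    if not nb_estimates and not mixture_fits:
        raise InvalidInputError("at least one method's estimates are required")
    nb = {e.severity: e for e in nb_estimates}
    mx = {m.severity: m for m in mixture_fits}
    ards = [r for r in records if r.cohort is Cohort.ARDS]
    rows = []
    for severity in SEVERITY_ORDER:
        stratum = [r for r in ards if r.severity is severity]
        doc_n = sum(r.documented for r in stratum)
        e, m = nb.get(severity), mx.get(severity)
        rows.append({
            "severity": severity.value,
            "n": len(stratum),
            "documented_n": doc_n,
            "documented_pct": 100.0 * doc_n / len(stratum) if stratum else np.nan,
            "naive_bayes_pct": 100.0 * e.fraction if e else np.nan,
            "mixture_pct": 100.0 * m.mean if m and m.mean is not None else np.nan,
            "mixture_ci99_low": 100.0 * m.ci99[0] if m and m.ci99 else np.nan,
            "mixture_ci99_high": 100.0 * m.ci99[1] if m and m.ci99 else np.nan,
        })
    return pd.DataFrame(rows)


def render_report(table: pd.DataFrame) -> str:
    """Human-readable recognition table with integer percentages."""
    lines = ["Physician recognition of ARDS by hypoxemia severity",
             "severity    n  doc_n  doc%  naive_bayes%  mixture% [99% CI]"]
    for _, row in table.iterrows():
        def pct(v):
            return "NA" if pd.isna(v) else f"{v:.0f}"
        ci = "NA" if pd.isna(row["mixture_ci99_low"]) else (
            f"[{row['mixture_ci99_low']:.0f}, {row['mixture_ci99_high']:.0f}]")
        lines.append(f"{row['severity']:<9} {row['n']:>4}  {row['documented_n']:>5}"
                     f"  {pct(row['documented_pct']):>4}"
                     f"  {pct(row['naive_bayes_pct']):>12}"
                     f"  {pct(row['mixture_pct']):>7} {ci}")
    return "\n".join(lines) + "\n"


@dataclass
class RunManifest:
    """Audit record of one pipeline run."""

    config: dict
    seed: int
    sub_seeds: dict
    outputs: dict
    counts: dict
    version: str = __version__
    stages: list[str] = field(default_factory=list)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)


def load_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise InvalidInputError("config must be a mapping")
    return data


def _build_configs(raw: dict, seed: Optional[int]
                   ) -> tuple[Optional[CohortConfig], AnalysisConfig, Optional[str]]:
    cohort_block = raw.get("cohort", {})
    analysis_block = raw.get("analysis", {})
    input_csv = raw.get("input_csv")
    analysis = AnalysisConfig(**analysis_block)
    if seed is not None:
        analysis.seed = seed
    cohort = None
    if input_csv is None:
        cohort = CohortConfig(**cohort_block)
    return cohort, analysis, input_csv


def _sub_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("simulate", "nb_bootstrap", "mixture_bootstrap", "spare")
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(names, children)}


def _regression_rows(results, subgroup, analysis_name):
    rows = []
    for res in results:
        for k, factor in enumerate(res.factors):
            rows.append({
                "analysis": analysis_name, "subgroup": subgroup,
                "factor": factor, "beta": res.betas[k],
                "ci99_low": res.ci99[k, 0], "ci99_high": res.ci99[k, 1],
                "p": res.p_values[k], "n": res.n,
                "significant": res.significant, "status": res.status,
            })
    return rows


def run_pipeline(config: Optional[dict] = None, out_dir="results",
                 seed: Optional[int] = None) -> RunManifest:
    """Execute the full analysis and write all artefacts under ``out_dir``."""
    raw = dict(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_cfg, analysis_cfg, input_csv = _build_configs(raw, seed)
    seeds = _sub_seeds(analysis_cfg.seed)
    stages: list[str] = []
    outputs: dict[str, str] = {}

    # --- stage 1: cohort ---------------------------------------------------
    if input_csv is not None:
        records = read_cohort_csv(input_csv)
        stages.append(f"load: {len(records)} records from {input_csv}")
    else:
        cohort_cfg = dataclasses.replace(cohort_cfg, seed=seeds["simulate"])
        records = generate_cohort(cohort_cfg)
        stages.append(f"simulate: {len(records)} records "
                      f"(sub-seed {seeds['simulate']})")
    cohort_path = out / "cohort.csv"
    write_cohort_csv(records, cohort_path)
    outputs["cohort"] = str(cohort_path)

    # --- stage 2: subgroups ------------------------------------------------
    groups = split_subgroups(records)
    ards = [r for r in records if r.cohort is Cohort.ARDS]
    controls = [r for r in records if r.cohort is Cohort.CONTROL]
    stages.append("split: " + ", ".join(
        f"{s.value}={len(g)}" for s, g in groups.items()))

    # --- stage 3: regression screen ---------------------------------------
    rows = []
    screens = {}
    def _screen(cohort_records, factors, label, analysis_name):
        """Per-factor screen; factors degenerate in this cohort (constant or
        all-missing) are skipped with a log line, mirroring the 'category
        not used' convention."""
        results = []
        for factor in factors:
            try:
                results += univariable_screen(cohort_records, [factor],
                                              analysis_cfg)
            except (DegenerateInputError, CollinearityError) as exc:
                stages.append(f"{analysis_name} {label}/{factor}: "
                              f"skipped ({exc})")
        return results

    for name, cohort_records, factors in (
            ("ARDS", ards, SCREEN_FACTORS_ARDS),
            ("control", controls, SCREEN_FACTORS_CONTROL)):
        results = _screen(cohort_records, factors, name, "univariable")
        screens[name] = results
        rows += _regression_rows(results, name, "univariable")
        for crit in ("duration_gt_12h", "pbw_central_95"):
            filtered = sensitivity_filter(cohort_records, crit)
            rows += _regression_rows(
                _screen(filtered, factors, name, f"sensitivity_{crit}"),
                name, f"sensitivity_{crit}")
        try:
            rows += _regression_rows(
                covariate_analysis(cohort_records, analysis_cfg),
                name, "covariate_logistic")
        except DegenerateInputError as exc:
            stages.append(f"covariate {name}: skipped ({exc})")
    sig_ards = [res.factors[0].split("[")[0] for res in screens["ARDS"]
                if res.significant]
    selection = multivariable_select(ards, sorted(set(sig_ards)), analysis_cfg)
    if selection.status == "ok":
        selection.best.significant = None
        rows += _regression_rows([selection.best], "ARDS", "multivariable")
    reg_path = out / "regression.csv"
    pd.DataFrame(rows).to_csv(reg_path, index=False)
    outputs["regression"] = str(reg_path)
    log_path = out / "model_selection.log"
    log_path.write_text("\n".join(
        [f"status: {selection.status}",
         f"candidates: {selection.n_candidates}"] + selection.log) + "\n")
    outputs["model_selection_log"] = str(log_path)
    stages.append(f"regress: {len(rows)} rows, multivariable {selection.status}")

    # --- stage 4: Naive Bayes recognition ----------------------------------
    doc = groups[Subgroup.POOLED_DOC]
    ctrl_nondoc = groups[Subgroup.CONTROL_NONDOC]
    ards_nondoc = groups[Subgroup.ARDS_NONDOC]
    if len(doc) < 5 or len(ctrl_nondoc) < 5:
        raise InsufficientDataError(
            "recognition stages need at least 5 documented and 5 "
            "control non-documented reference patients")
    dens_doc = fit_kde2d([(r.pbw_kg, r.vt_std) for r in doc], analysis_cfg)
    dens_ctrl = fit_kde2d([(r.pbw_kg, r.vt_std) for r in ctrl_nondoc],
                          analysis_cfg)
    cls_rows = []
    for r in ards_nondoc:
        try:
            odds = posterior_odds((r.pbw_kg, r.vt_std), dens_doc, dens_ctrl,
                                  analysis_cfg.priors)
        except UndefinedOddsError:
            odds = np.nan
        recognized = classify_recognized(r, dens_doc, dens_ctrl,
                                         analysis_cfg.priors)
        cls_rows.append({"patient_id": r.patient_id,
                         "severity": r.severity.value,
                         "odds": odds, "recognized": int(recognized)})
    cls_path = out / "nb_classifications.csv"
    pd.DataFrame(cls_rows).to_csv(cls_path, index=False)
    outputs["nb_classifications"] = str(cls_path)
    nb_estimates = nb_recognition_by_severity(ards, dens_doc, dens_ctrl,
                                              analysis_cfg)
    band = bootstrap_boundary(ctrl_nondoc, doc, seed=seeds["nb_bootstrap"],
                              config=analysis_cfg)
    boundary_path = out / "nb_boundary.csv"
    pd.DataFrame({"pbw": band.pbw, "vt_boundary": band.vt_boundary,
                  "band_low": band.band_low, "band_high": band.band_high}
                 ).to_csv(boundary_path, index=False)
    outputs["nb_boundary"] = str(boundary_path)
    stages.append(f"recognize-nb: {len(cls_rows)} classified "
                  f"(sub-seed {seeds['nb_bootstrap']})")

    # --- stage 5: mixture recognition --------------------------------------
    mixture_fits = []
    for k, severity in enumerate(SEVERITY_ORDER):
        stratum = [r for r in (ards if analysis_cfg.mixture_include_documented
                               else ards_nondoc) if r.severity is severity]
        ctrl_stratum = [r for r in ctrl_nondoc if r.severity is severity]
        if len(stratum) < 5 or not ctrl_stratum:
            logger.warning("severity %s skipped: stratum too small", severity.value)
            continue
        mixture_fits.append(bootstrap_fractions(
            stratum, doc, ctrl_stratum, severity=severity,
            seed=seeds["mixture_bootstrap"] + k, config=analysis_cfg))
    rec_rows = []
    for e in nb_estimates:
        rec_rows.append({"severity": e.severity.value, "method": "naive_bayes",
                         "f_mean": e.fraction, "ci99_low": np.nan,
                         "ci99_high": np.nan, "delta": np.nan, "n": e.n})
    for m in mixture_fits:
        rec_rows.append({"severity": m.severity.value, "method": "mixture",
                         "f_mean": m.mean, "ci99_low": m.ci99[0],
                         "ci99_high": m.ci99[1], "delta": m.delta, "n": m.n})
    rec_path = out / "recognition.csv"
    pd.DataFrame(rec_rows).to_csv(rec_path, index=False)
    outputs["recognition"] = str(rec_path)
    ks_rows = []
    for i in range(len(mixture_fits)):
        for j in range(i + 1, len(mixture_fits)):
            a, b = mixture_fits[i], mixture_fits[j]
            d_stat, p, sig = ks_compare(a.bootstrap_fractions,
                                        b.bootstrap_fractions, analysis_cfg)
            ks_rows.append({"pair": f"{a.severity.value}-{b.severity.value}",
                            "D": d_stat, "p": p, "significant": int(sig)})
    ks_path = out / "ks.csv"
    pd.DataFrame(ks_rows).to_csv(ks_path, index=False)
    outputs["ks"] = str(ks_path)
    stages.append(f"recognize-mixture: {len(mixture_fits)} strata "
                  f"(sub-seed {seeds['mixture_bootstrap']})")

    # --- stage 6: report ----------------------------------------------------
    table = summarize_recognition(nb_estimates, mixture_fits, records)
    report_path = out / "report.txt"
    report_path.write_text(render_report(table))
    outputs["report"] = str(report_path)
    summary_path = out / "recognition_summary.csv"
    table.to_csv(summary_path, index=False)
    outputs["recognition_summary"] = str(summary_path)
    stages.append("report")

    counts = {
        "n_records": len(records),
        "n_ards": len(ards),
        "n_control": len(controls),
        **{s.value: len(g) for s, g in groups.items()},
    }
    assert counts["ards_nondocumented"] + sum(r.documented for r in ards) \
        == counts["n_ards"]
    manifest = RunManifest(config=raw, seed=analysis_cfg.seed, sub_seeds=seeds,
                           outputs=outputs, counts=counts, stages=stages)
    (out / "manifest.yaml").write_text(manifest.to_yaml())
    for line in stages:
        logger.info(line)
    return manifest
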