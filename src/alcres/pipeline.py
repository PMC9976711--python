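"""End-to-end pipeline: simulate -> score -> risk -> resist -> assoc -> sem.

Each stage reads the previous stage's CSV outputs from the run directory
and writes its own, so any stage can be re-run in isolation; a manifest
records the configuration, seed, and stage-level sample sizes.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Mapping

import numpy as np
import pandas as pd

from alcres import assoc, genrisk, resistance, scales, sem, synthdata
from alcres.config import ConfigError, PipelineConfig

logger = logging.getLogger(__name__)

#: Path model of the social-influence analysis: two latent parenting-quality
#: factors (four scale-score indicators each) plus observed monitoring
#: predicting three mediators, and all six upstream variables predicting the
#: resistance outcome.  Exogenous predictors covary freely, as do the
#: mediators' disturbances.
SEM_MODEL = """
fq =~ f_bonding + f_closeness + f_communication + f_involvement
mq =~ m_bonding + m_closeness + m_communication + m_involvement
peer_drinking ~ fq + mq + monitoring
partner_drinking ~ fq + mq + monitoring
social_competence ~ fq + mq + monitoring
resistance ~ fq + mq + monitoring + peer_drinking + partner_drinking + social_competence
fq ~~ mq
fq ~~ monitoring
mq ~~ monitoring
peer_drinking ~~ partner_drinking
peer_drinking ~~ social_competence
partner_drinking ~~ social_competence
"""

PHENOTYPES = ("initiation", "hed", "aud")


def _out(cfg: PipelineConfig, name: str) -> str:
    os.makedirs(cfg.outdir, exist_ok=True)
    return os.path.join(cfg.outdir, name)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> dict[str, str]:
    if cfg.input_subjects:
        raise ConfigError("simulate stage requested but input_subjects is set")
    subjects, relatives = synthdata.simulate_panel(cfg.sim)
    paths = synthdata.write_panel(subjects, relatives, cfg.sim, cfg.outdir)
    logger.info("simulated %d subjects in %d families", len(subjects), cfg.sim.n_families)
    return paths


def _load_inputs(cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    subj_path = cfg.input_subjects or _out(cfg, "subjects.csv")
    rel_path = cfg.input_relatives or _out(cfg, "relatives.csv")
    for p in (subj_path, rel_path):
        if not os.path.exists(p):
            raise ConfigError(
                f"input file {p!r} not found; run the simulate stage or set input paths"
            )
    return pd.read_csv(subj_path), pd.read_csv(rel_path)


def stage_score(cfg: PipelineConfig) -> pd.DataFrame:
    subjects_df, _ = _load_inputs(cfg)
    scored = scales.score_subjects(subjects_df)
    factor_scores, fits = scales.relationship_quality_scores(scored, seed=cfg.seed)
    out = scored.merge(factor_scores, on="subject_id")
    out.to_csv(_out(cfg, "scores.csv"), index=False)
    report = {
        parent: {
            "chi_square": fit.chi_square,
            "df": fit.df,
            "cfi": fit.cfi,
            "srmr": fit.srmr,
            "loadings_raw": fit.loadings.tolist(),
            "standardized_loadings": (
                fit.loadings / np.sqrt(fit.loadings**2 + np.maximum(fit.residual_variances, 0.0))
            ).tolist(),
            "n": fit.n,
            "heywood": fit.heywood,
            "acceptable_fit": bool(fit.cfi > 0.90 and fit.srmr < 0.08),
        }
        for parent, fit in fits.items()
    }
    with open(_out(cfg, "cfa_report.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    return out


def stage_risk(cfg: PipelineConfig) -> pd.DataFrame:
    subjects_df, relatives_df = _load_inputs(cfg)
    gr = genrisk.compute_genetic_risk(
        subjects_df, relatives_df, fhd_form=cfg.fhd_form, fhd_log_base=cfg.fhd_log_base
    )
    gr.to_csv(_out(cfg, "genrisk.csv"), index=False)
    return gr


def stage_resist(cfg: PipelineConfig) -> pd.DataFrame:
    subjects_df, _ = _load_inputs(cfg)
    gr = pd.read_csv(_out(cfg, "genrisk.csv"))
    res, fits = resistance.resistance_phenotypes(
        subjects_df,
        gr,
        cluster_mode=cfg.cluster_mode,
        tie_method=cfg.tie_method,
        residual_frailty=cfg.residual_frailty,
    )
    res.to_csv(_out(cfg, "resistance.csv"), index=False)
    hr_rows = []
    for key, fit in fits.items():
        tab = fit.hr_ci(cfg.alpha)
        tab.insert(0, "model", key)
        tab["frailty_variance"] = fit.frailty_variance
        tab["n"] = len(fit.subject_ids)
        tab["n_events"] = fit.n_events
        hr_rows.append(tab)
    pd.concat(hr_rows, ignore_index=True).to_csv(_out(cfg, "cox_report.csv"), index=False)
    for pheno in ("initiation", "hed"):
        n = int((res["phenotype"] == pheno).sum())
        logger.info("%s subsample n=%d", pheno, n)
    return res


def _predictor_frame(cfg: PipelineConfig, subjects_df: pd.DataFrame) -> pd.DataFrame:
    scores = pd.read_csv(_out(cfg, "scores.csv"))
    pred = scores[["subject_id", "father_quality", "mother_quality", "monitoring"]].copy()
    return pred.merge(
        subjects_df[["subject_id", "peer_drinking", "partner_drinking", "social_competence"]],
        on="subject_id",
    )


def stage_assoc(cfg: PipelineConfig) -> pd.DataFrame:
    subjects_df, _ = _load_inputs(cfg)
    res = pd.read_csv(_out(cfg, "resistance.csv"))
    pred = _predictor_frame(cfg, subjects_df)
    tab = assoc.univariable_table(res, pred, subjects_df, nodes=cfg.quadrature_nodes)
    tab.to_csv(_out(cfg, "assoc_results.csv"), index=False)
    return tab


def build_sem_dataset(
    scores_df: pd.DataFrame,
    subjects_df: pd.DataFrame,
    resistance_df: pd.DataFrame,
    phenotype: str,
) -> pd.DataFrame:
    """Analysis table for one phenotype's path model (missing = NaN, FIML)."""
    res = resistance_df.loc[
        resistance_df["phenotype"] == phenotype, ["subject_id", "value"]
    ].rename(columns={"value": "resistance"})
    cols = [
        "subject_id",
        "f_bonding", "f_closeness", "f_communication", "f_involvement",
        "m_bonding", "m_closeness", "m_communication", "m_involvement",
        "monitoring",
    ]
    data = scores_df[cols].merge(
        subjects_df[
            ["subject_id", "family_id", "ancestry_group",
             "peer_drinking", "partner_drinking", "social_competence"]
        ],
        on="subject_id",
    )
    # subjects outside the phenotype's subsample carry no outcome row; they
    # are excluded (the subsample defines the analysis set)
    data = data.merge(res, on="subject_id", how="inner")
    return data


def stage_sem(cfg: PipelineConfig) -> pd.DataFrame:
    subjects_df, _ = _load_inputs(cfg)
    scores_df = pd.read_csv(_out(cfg, "scores.csv"))
    res = pd.read_csv(_out(cfg, "resistance.csv"))
    model_cols = sem.parse_model(SEM_MODEL).observed_vars()

    results = []
    lrt_rows = []
    for pheno in PHENOTYPES:
        data = build_sem_dataset(scores_df, subjects_df, res, pheno)
        fit = sem.fit_sem(
            SEM_MODEL, data[model_cols], starts=cfg.sem_starts, seed=cfg.seed
        )
        tab = fit.standardized.copy()
        tab.insert(0, "phenotype", pheno)
        tab.insert(1, "group", "pooled")
        tab["n"] = fit.n
        results.append(tab[tab["kind"].isin(["loading", "path", "correlation"])])

        # ancestry moderation: free vs all-structural-paths-equal
        groups = data["ancestry_group"]
        if groups.nunique() >= 2 and groups.value_counts().min() >= 50:
            paths = sem.structural_path_labels(sem.parse_model(SEM_MODEL))
            free, constrained = sem.fit_multigroup(
                SEM_MODEL, data[model_cols], groups, paths,
                starts=cfg.sem_starts, seed=cfg.seed, compute_se=True,
            )
            test = sem.lrt(free, constrained)
            lrt_rows.append(
                {
                    "phenotype": pheno,
                    "constraints": "all_structural_paths",
                    "stat": test.stat,
                    "df": test.df,
                    "p": test.p,
                    "n_per_group": json.dumps({str(k): v for k, v in free.n_per_group.items()}),
                }
            )
            for g, gfit in free.groups.items():
                gtab = gfit.standardized.copy()
                gtab.insert(0, "phenotype", pheno)
                gtab.insert(1, "group", str(g))
                gtab["n"] = gfit.n
                results.append(gtab[gtab["kind"].isin(["loading", "path", "correlation"])])
            # follow-up single-path constraints when the omnibus test rejects
            if test.p < cfg.alpha:
                for lab in paths:
                    f1, c1 = sem.fit_multigroup(
                        SEM_MODEL, data[model_cols], groups, [lab],
                        starts=1, seed=cfg.seed,
                    )
                    t1 = sem.lrt(f1, c1)
                    lrt_rows.append(
                        {
                            "phenotype": pheno,
                            "constraints": lab,
                            "stat": t1.stat,
                            "df": t1.df,
                            "p": t1.p,
                            "n_per_group": json.dumps(
                                {str(k): v for k, v in f1.n_per_group.items()}
                            ),
                        }
                    )

    out = pd.concat(results, ignore_index=True)
    out.to_csv(_out(cfg, "sem_results.csv"), index=False)
    pd.DataFrame(
        lrt_rows, columns=["phenotype", "constraints", "stat", "df", "p", "n_per_group"]
    ).to_csv(_out(cfg, "sem_lrt.csv"), index=False)
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

STAGES = ("simulate", "score", "risk", "resist", "assoc", "sem")

#: defaults not stated by the source analysis, surfaced in the manifest
ASSUMPTION_KEYS = (
    "fhd_form", "fhd_log_base", "residual_frailty", "tie_method",
    "quadrature_nodes", "sem_starts",
)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages in order; abort with the stage name on failure."""
    cfg.validate()
    manifest: dict = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "config_hash": cfg.sim.config_hash(),
        "assumptions": {k: getattr(cfg, k) for k in ASSUMPTION_KEYS},
        "stages": {},
    }
    for stage in STAGES:
        if stage == "simulate" and cfg.input_subjects:
            continue
        fn = globals()[f"stage_{stage}"]
        try:
            out = fn(cfg)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        if isinstance(out, pd.DataFrame):
            manifest["stages"][stage] = {"rows": int(len(out))}
        else:
            manifest["stages"][stage] = {"outputs": out}
        logger.info("stage %s done", stage)
    with open(_out(cfg, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    report = make_report(cfg.outdir, alpha=cfg.alpha)
    with open(_out(cfg, "report.md"), "w") as fh:
        fh.write(report)
    return manifest


def make_report(outdir: str, alpha: float = 0.05) -> str:
    """Markdown summary; estimates whose 95% CI excludes 0 are bolded."""

    def fmt(beta, lo, hi):
        cell = f"{beta:.2f} [{lo:.2f}, {hi:.2f}]"
        return f"**{cell}**" if not (lo <= 0.0 <= hi) else cell

    lines = ["# Pipeline report", ""]
    assoc_path = os.path.join(outdir, "assoc_results.csv")
    if os.path.exists(assoc_path):
        tab = pd.read_csv(assoc_path)
        lines += ["## Univariable associations", ""]
        if tab.empty:
            lines += ["(no results)", ""]
        else:
            outcomes = [o for o in PHENOTYPES if o in set(tab["outcome"])]
            header = "| predictor | " + " | ".join(outcomes) + " |"
            lines += [header, "|" + "---|" * (len(outcomes) + 1)]
            for pred in tab["predictor"].unique():
                cells = []
                for o in outcomes:
                    row = tab[(tab["predictor"] == pred) & (tab["outcome"] == o)]
                    cells.append(
                        fmt(*row.iloc[0][["beta_std", "ci_low", "ci_high"]])
                        if len(row)
                        else ""
                    )
                lines.append(f"| {pred} | " + " | ".join(cells) + " |")
            lines.append("")
    sem_path = os.path.join(outdir, "sem_results.csv")
    if os.path.exists(sem_path):
        tab = pd.read_csv(sem_path)
        lines += ["## Structural equation models (standardized)", ""]
        if tab.empty:
            lines += ["(no results)", ""]
        else:
            lines += [
                "| phenotype | group | kind | parameter | estimate [95% CI] |",
                "|---|---|---|---|---|",
            ]
            for row in tab.itertuples():
                if not np.isfinite(row.std_se):
                    cell = f"{row.std_estimate:.2f}"
                else:
                    cell = fmt(row.std_estimate, row.std_ci_low, row.std_ci_high)
                lines.append(
                    f"| {row.phenotype} | {row.group} | {row.kind} | {row.label} | {cell} |"
                )
            lines.append("")
    lrt_path = os.path.join(outdir, "sem_lrt.csv")
    if os.path.exists(lrt_path):
        tab = pd.read_csv(lrt_path)
        if not tab.empty:
            lines += ["## Ancestry moderation (likelihood-ratio tests)", ""]
            lines += ["| phenotype | constraints | chi-square | df | p |", "|---|---|---|---|---|"]
            for row in tab.itertuples():
                stat = f"{row.stat:.2f}"
                p = f"{row.p:.3f}"
                if row.p < alpha:
                    stat, p = f"**{stat}**", f"**{p}**"
                lines.append(f"| {row.phenotype} | {row.constraints} | {stat} | {row.df} | {p} |")
            lines.append("")
    return "\n".join(lines)
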