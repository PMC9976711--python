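# alcres

Analysis pipeline for studying **realized alcohol resistance** — healthier-
than-expected drinking outcomes among adolescents at high genetic risk — on
fully synthetic family panels. The package implements every stage of the
analysis as tested, reusable code:

1. **`alcres.synthdata`** — seeded generator of families with a shared latent
   liability, a polygenic-score proxy, pedigree relatives with AUD symptom
   counts, parenting/monitoring item responses loading on latent
   relationship-quality factors, mediators generated from a standardized
   structural model, and Weibull proportional-hazards onset ages (alcohol
   initiation and heavy episodic drinking) with right censoring and
   stage-wise attrition.
2. **`alcres.scales`** — instrument scoring (bonding, closeness,
   communication, involvement, monitoring) and one-factor CFAs (ML/FIML,
   chi-square, CFI, SRMR, regression-method factor scores).
3. **`alcres.genrisk`** — family history density (degree-weighted log
   symptom counts), within-ancestry PRS standardization, high-genetic-risk
   subsetting (non-zero FHD or top-quartile PRS).
4. **`alcres.resistance`** — family-clustered Cox models (shared gamma
   frailty via penalized partial likelihood with profile-likelihood frailty
   variance, or cluster-robust sandwich), Breslow baseline hazard,
   martingale/deviance residuals (positive = onset sooner than expected =
   lower resistance), rule-based AUD-resistance coding, and the three
   analysis subsamples.
5. **`alcres.assoc`** — univariable family-clustered models: random-intercept
   linear models for deviance-residual outcomes and a Gauss–Hermite
   random-intercept probit for the binary AUD outcome.
6. **`alcres.sem`** — a compact FIML SEM engine (lavaan-style model syntax,
   RAM parameterization, analytic gradients, pattern-grouped case-wise
   likelihood, multi-group fitting with equality constraints,
   likelihood-ratio tests, standardized solutions with delta-method CIs).
7. **`alcres.cli` / `alcres.pipeline`** — orchestration, YAML config, run
   manifests, and a markdown report (estimates whose 95% CI excludes zero
   are bolded).

## CLI

```bash
alcres all --seed 7 --outdir out          # full pipeline on a synthetic panel
alcres simulate --config cfg.yaml         # or stage by stage:
alcres score --outdir out
alcres risk --outdir out
alcres resist --outdir out
alcres assoc --outdir out
alcres sem --outdir out
```

Outputs land in the run directory: `subjects.csv`, `relatives.csv`,
`scores.csv`, `genrisk.csv`, `resistance.csv`, `cox_report.csv`,
`assoc_results.csv` (predictor-by-outcome table), `sem_results.csv`
(standardized loadings/paths/correlations with 95% CIs), `sem_lrt.csv`
(ancestry moderation tests), `run_manifest.json`, and `report.md`.

Configuration is YAML mirroring `alcres.config.PipelineConfig`; every
default that is an analysis assumption rather than a stated choice is listed
under `assumptions` in the run manifest.

## Notes

- Binary endogenous variables (partner drinking, the AUD code) are treated
  as continuous in the Gaussian SEM; the univariable stage models the AUD
  outcome with a proper random-intercept probit.
- The SEM stage is unclustered by family; the univariable stage clusters.
- `fit_family_lm` uses random family intercepts; a fixed-effects variant is
  a possible extension.
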