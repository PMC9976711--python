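"""Seeded synthetic family panels with the structure the analysis assumes.

The generator produces adolescent subjects nested in families, each with a
latent liability shared within family, a noisy polygenic-score proxy of
that liability, pedigree relatives with symptom counts driven by the family
component, parenting/monitoring item responses loading on latent
relationship-quality factors, mediator variables generated from a
standardized structural model, and Weibull proportional-hazards onset ages
for alcohol initiation and heavy episodic drinking with right censoring.

Everything is deterministic given ``SimConfig.seed``: each stage draws from
its own generator derived from ``(seed, stage-tag)``.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from alcres.config import (
    EXOG_COVS,
    MEDIATORS,
    PARENT_PREDICTORS,
    STRUCTURAL_PATHS,
    ConfigError,
    SimConfig,
)

# item counts and response formats per instrument
ITEM_FORMATS: dict[str, tuple[int, int, int]] = {
    # scale -> (n_items, min_response, max_response); closeness handled apart
    "bond": (12, 1, 4),
    "comm": (3, 0, 1),
    "inv": (6, 0, 1),
}
CLOSENESS_FORMATS = ((1, 4), (1, 3))  # two items on different response scales
MONITORING_FORMAT = (3, 1, 4)  # 1 = always ... 4 = rarely (negatively keyed)

FIRST_DEGREE_LABELS = ("father", "mother", "full sibling")
SECOND_DEGREE_LABELS = ("grandparent", "parental sibling", "half sibling")

#: columns masked by stage-wise attrition (drawn from the follow-up assessment)
FOLLOWUP_FIELDS = ("peer_drinking", "partner_drinking", "social_competence")


@dataclass
class RelativeRecord:
    """A first- or second-degree non-descendant relative of a family."""

    family_id: int
    relative_id: str
    degree: int
    relation_label: str
    aud_max_symptoms: int

    def __post_init__(self) -> None:
        if self.degree not in (1, 2):
            raise ValueError(f"degree must be 1 or 2, got {self.degree}")
        expected = FIRST_DEGREE_LABELS if self.degree == 1 else SECOND_DEGREE_LABELS
        if self.relation_label not in expected:
            raise ValueError(
                f"relation {self.relation_label!r} inconsistent with degree {self.degree}"
            )
        if self.aud_max_symptoms < 0:
            raise ValueError("aud_max_symptoms must be non-negative")


@dataclass
class Subject:
    """One adolescent proband; simulation-only fields are prefixed ``sim_``
    in the CSV output and withheld from analysis stages."""

    family_id: int
    subject_id: str
    sex: int = 0
    baseline_age: float = 14.0
    ancestry_group: str = "EA"
    has_mother_data: int = 1
    has_father_data: int = 1
    pc1: float = 0.0
    pc2: float = 0.0
    prs: float = float("nan")
    items: dict[str, tuple[float, ...]] = field(default_factory=dict)
    peer_drinking: float = float("nan")
    partner_drinking: float = float("nan")
    social_competence: float = float("nan")
    onset_age_initiation: float = float("nan")
    event_initiation: int = 0
    onset_age_hed: float = float("nan")
    event_hed: int = 0
    initiated_at_baseline: int = 0
    hed_at_baseline: int = 0
    drinker: int = 0
    aud_diagnosed: int = 0
    last_assessment_age: float = float("nan")
    # simulation-only ground truth
    true_liability: float = float("nan")
    resist_latent: float = float("nan")
    fq_latent: float = float("nan")
    mq_latent: float = float("nan")
    mon_latent: float = float("nan")
    extras: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stage 1: families, liabilities, PRS, relatives
# ---------------------------------------------------------------------------

def generate_families(cfg: SimConfig) -> tuple[list[Subject], list[RelativeRecord]]:
    """Draw families of related subjects plus their pedigree relatives.

    Liability decomposes as ``a_f + e_i`` with ``Var(a_f) = h2_liability``
    and total variance 1; the polygenic score is
    ``sqrt(prs_r2) * liability + sqrt(1 - prs_r2) * noise`` so its squared
    correlation with liability equals ``prs_r2``.  Relatives share the
    family component (fully for first degree, half for second) and their
    AUD maximum symptom counts are Poisson with log-mean linear in their
    own liability.
    """
    cfg.validate()
    rng = cfg.rng("families")
    subjects: list[Subject] = []
    relatives: list[RelativeRecord] = []
    h2 = cfg.h2_liability
    lo, hi = cfg.censor_age_range

    for fam in range(cfg.n_families):
        n_kids = 1 + rng.poisson(max(cfg.mean_family_size - 1.0, 0.0))
        a_f = rng.normal(0.0, math.sqrt(h2)) if h2 > 0 else 0.0
        ancestry = "EA" if rng.random() < 0.65 else "AA"
        for k in range(n_kids):
            liab = a_f + rng.normal(0.0, math.sqrt(max(1.0 - h2, 0.0)))
            prs = (
                math.sqrt(cfg.prs_r2) * liab
                + math.sqrt(max(1.0 - cfg.prs_r2, 0.0)) * rng.normal()
            )
            subjects.append(
                Subject(
                    family_id=fam,
                    subject_id=f"F{fam:05d}S{k}",
                    sex=int(rng.random() < 0.5),
                    baseline_age=float(rng.uniform(11.0, 17.0)),
                    ancestry_group=ancestry,
                    has_mother_data=int(rng.random() < 0.92),
                    has_father_data=int(rng.random() < 0.80),
                    pc1=float(rng.normal()),
                    pc2=float(rng.normal()),
                    prs=float(prs),
                    last_assessment_age=float(rng.uniform(lo, hi)),
                    true_liability=float(liab),
                )
            )
        n_rel = rng.poisson(cfg.mean_relatives)
        for r in range(n_rel):
            degree = 1 if rng.random() < cfg.relatedness_mix[0] else 2
            labels = FIRST_DEGREE_LABELS if degree == 1 else SECOND_DEGREE_LABELS
            label = labels[rng.integers(len(labels))]
            share = 1.0 if degree == 1 else 0.5
            rel_liab = share * a_f + rng.normal(
                0.0, math.sqrt(max(1.0 - share * share * h2, 1e-12))
            )
            lam = math.exp(
                cfg.relative_symptom_intercept + cfg.relative_symptom_slope * rel_liab
            )
            relatives.append(
                RelativeRecord(
                    family_id=fam,
                    relative_id=f"F{fam:05d}R{r}",
                    degree=degree,
                    relation_label=label,
                    aud_max_symptoms=int(rng.poisson(lam)),
                )
            )
    return subjects, relatives


# ---------------------------------------------------------------------------
# stage 2: social block (latents, items, mediators)
# ---------------------------------------------------------------------------

def _discretize(z: np.ndarray, n_cat: int, lo: int, rng_dummy=None) -> np.ndarray:
    """Equal-probability threshold discretization of standard-normal scores."""
    cuts = stats.norm.ppf(np.arange(1, n_cat) / n_cat)
    return lo + np.searchsorted(cuts, z)


def _continuous_response(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Monotone map of normal scores into the response range (no rounding)."""
    return lo + (hi - lo) * stats.norm.cdf(z)


def simulate_social_block(subjects: list[Subject], cfg: SimConfig) -> list[Subject]:
    """Populate parenting latents, item responses, and mediators in place.

    Parent-quality latents and monitoring follow the configured exogenous
    correlations; mediators and the resistance disturbance follow the
    standardized structural coefficients in ``cfg.path_matrix``; items load
    on scale factors that in turn load on the parent latents with the
    configured loadings, then are discretized to each instrument's response
    format at equal-probability normal thresholds.
    """
    cfg.validate()
    rng = cfg.rng("social")
    n = len(subjects)
    if n == 0:
        return subjects

    order = list(PARENT_PREDICTORS) + list(MEDIATORS) + ["resist"]
    idx = {v: i for i, v in enumerate(order)}

    exog_cov = np.eye(3)
    for key in EXOG_COVS:
        a, b = key.split("~~")
        exog_cov[idx[a], idx[b]] = exog_cov[idx[b], idx[a]] = cfg.path_matrix.get(key, 0.0)
    exog = rng.multivariate_normal(np.zeros(3), exog_cov, size=n, method="cholesky")
    values = {v: exog[:, i] for i, v in enumerate(PARENT_PREDICTORS)}

    # recursive structural equations, each variable completed to unit variance
    sigma = cfg.social_covariance()
    for v in list(MEDIATORS) + ["resist"]:
        eta = np.zeros(n)
        for p in order:
            coef = cfg.path_matrix.get(f"{v}~{p}", 0.0)
            if coef:
                eta += coef * values[p]
        resid_sd = math.sqrt(_disturbance_variance(cfg, sigma, idx, v))
        values[v] = eta + resid_sd * rng.normal(size=n)

    item_rel = cfg.item_reliability  # share of scale-factor variance per raw item

    def draw_items(factor: np.ndarray, lam: float, n_items: int, fmt: tuple[int, int]):
        eta_s = lam * factor + math.sqrt(1.0 - lam * lam) * rng.normal(size=n)
        cols = []
        for _ in range(n_items):
            z = math.sqrt(item_rel) * eta_s + math.sqrt(1.0 - item_rel) * rng.normal(size=n)
            if cfg.discretize_items:
                cols.append(_discretize(z, fmt[1] - fmt[0] + 1, fmt[0]).astype(float))
            else:
                cols.append(_continuous_response(z, fmt[0], fmt[1]))
        return np.column_stack(cols)

    blocks: dict[str, np.ndarray] = {}
    for parent, prefix in (("father", "f"), ("mother", "m")):
        lam_bond, lam_close, lam_comm, lam_inv = cfg.loadings[parent]
        factor = values["fq"] if parent == "father" else values["mq"]
        blocks[f"{prefix}_bond"] = draw_items(factor, lam_bond, 12, (1, 4))
        close_eta = lam_close * factor + math.sqrt(1 - lam_close**2) * rng.normal(size=n)
        close_cols = []
        for fmt in CLOSENESS_FORMATS:
            z = math.sqrt(item_rel) * close_eta + math.sqrt(1 - item_rel) * rng.normal(size=n)
            if cfg.discretize_items:
                close_cols.append(_discretize(z, fmt[1] - fmt[0] + 1, fmt[0]).astype(float))
            else:
                close_cols.append(_continuous_response(z, fmt[0], fmt[1]))
        blocks[f"{prefix}_close"] = np.column_stack(close_cols)
        blocks[f"{prefix}_comm"] = draw_items(factor, lam_comm, 3, (0, 1))
        blocks[f"{prefix}_inv"] = draw_items(factor, lam_inv, 6, (0, 1))

    # monitoring: responses negatively keyed (1 = always), reverse-coded later
    mon_cols = []
    for _ in range(MONITORING_FORMAT[0]):
        z = math.sqrt(item_rel) * values["mon"] + math.sqrt(1 - item_rel) * rng.normal(size=n)
        if cfg.discretize_items:
            mon_cols.append(5.0 - _discretize(z, 4, 1))
        else:
            mon_cols.append(5.0 - _continuous_response(z, 1, 4))
    blocks["mon"] = np.column_stack(mon_cols)

    peer = _discretize(values["peer"], 4, 1).astype(float)
    partner = (values["partner"] > 0).astype(float)
    soc = values["soc"].copy()

    for i, subj in enumerate(subjects):
        subj.fq_latent = float(values["fq"][i])
        subj.mq_latent = float(values["mq"][i])
        subj.mon_latent = float(values["mon"][i])
        subj.resist_latent = float(values["resist"][i])
        subj.peer_drinking = float(peer[i])
        subj.partner_drinking = float(partner[i])
        subj.social_competence = float(soc[i])
        subj.items = {name: tuple(col[i]) for name, col in blocks.items()}
        if not subj.has_father_data:
            subj.items = {
                k: (tuple(np.full(len(v), np.nan)) if k.startswith("f_") else v)
                for k, v in subj.items.items()
            }
        if not subj.has_mother_data:
            subj.items = {
                k: (tuple(np.full(len(v), np.nan)) if k.startswith("m_") else v)
                for k, v in subj.items.items()
            }
    return subjects


def _disturbance_variance(cfg: SimConfig, sigma: np.ndarray, idx: dict[str, int], v: str) -> float:
    """Residual variance completing variable ``v`` to unit total variance."""
    order = list(PARENT_PREDICTORS) + list(MEDIATORS) + ["resist"]
    eta_var = 0.0
    coefs = {p: cfg.path_matrix.get(f"{v}~{p}", 0.0) for p in order}
    for a, ca in coefs.items():
        for b, cb in coefs.items():
            eta_var += ca * cb * sigma[idx[a], idx[b]]
    resid = 1.0 - eta_var
    if resid <= 0:
        raise ConfigError(f"paths into {v!r} explain >= 100% of its variance")
    return resid


# ---------------------------------------------------------------------------
# stage 3: onsets, censoring, AUD status
# ---------------------------------------------------------------------------

_PREDICTOR_ALIASES = {"liability": "true_liability", "resist": "resist_latent"}


def _linear_predictor(subjects: Sequence[Subject], hrs: dict[str, float]) -> np.ndarray:
    eta = np.zeros(len(subjects))
    for key, log_hr in hrs.items():
        if not np.isfinite(log_hr):
            raise ConfigError(f"log hazard ratio for {key!r} must be finite")
        attr = _PREDICTOR_ALIASES.get(key, key)
        vals = []
        for s in subjects:
            if attr in s.extras:
                vals.append(s.extras[attr])
            elif hasattr(s, attr):
                vals.append(getattr(s, attr))
            else:
                raise ConfigError(f"log_hr refers to unknown predictor {key!r}")
        eta += log_hr * np.asarray(vals, dtype=float)
    return eta


def _weibull_onset(
    rng: np.random.Generator, shape: float, scale: float, eta: np.ndarray, floor: np.ndarray
) -> np.ndarray:
    """Onset times from a Weibull PH law, left-truncated at ``floor``.

    Solves Lambda(t) = Lambda(floor) + E with E ~ Exp(1), where
    Lambda(t) = (t/scale)^shape * exp(eta); floor = 0 gives the plain law.
    """
    e = rng.exponential(size=len(eta))
    base = (np.maximum(floor, 0.0) / scale) ** shape
    return scale * (base + e * np.exp(-eta)) ** (1.0 / shape)


def simulate_onsets(subjects: list[Subject], cfg: SimConfig) -> list[Subject]:
    """Draw initiation and heavy-episodic-drinking onsets plus AUD status.

    Both processes are Weibull proportional hazards on the age scale with
    linear predictors from ``cfg.log_hr``; the HED hazard is truncated at
    the initiation age so HED never precedes initiation.  Events are
    observed iff onset does not exceed the (uniform, independent) censoring
    age; the AUD probability among drinkers follows a probit in liability
    and the social-resistance disturbance, with intercept calibrated to
    ``aud_prev_target``.
    """
    cfg.validate()
    if cfg.hazard_shape <= 0:
        raise ConfigError("hazard_shape must be positive")
    rng = cfg.rng("onsets")
    if not subjects:
        return subjects

    eta_init = _linear_predictor(subjects, cfg.log_hr.get("initiation", {}))
    eta_hed = _linear_predictor(subjects, cfg.log_hr.get("hed", {}))

    onset_init = _weibull_onset(
        rng, cfg.hazard_shape, cfg.hazard_scale["initiation"], eta_init,
        np.zeros(len(subjects)),
    )
    onset_hed = _weibull_onset(
        rng, cfg.hazard_shape, cfg.hazard_scale["hed"], eta_hed, onset_init
    )

    censor = np.array([s.last_assessment_age for s in subjects])
    baseline = np.array([s.baseline_age for s in subjects])

    ev_init = onset_init <= censor
    ev_hed = (onset_hed <= censor) & ev_init
    t_init = np.minimum(onset_init, censor)
    t_hed = np.minimum(onset_hed, censor)

    # AUD probability among drinkers: probit in liability + social disturbance,
    # intercept calibrated so the drinker prevalence matches the target
    liab = np.array([s.true_liability for s in subjects])
    res = np.array([s.resist_latent for s in subjects])
    res = np.where(np.isfinite(res), res, 0.0)
    drinkers = ev_init & (censor >= 15.0)
    score = 0.8 * liab + 0.4 * res

    def prevalence_gap(c0: float) -> float:
        return float(np.mean(stats.norm.cdf(c0 + score[drinkers]))) - cfg.aud_prev_target

    if drinkers.any() and 0.0 < cfg.aud_prev_target < 1.0:
        c0 = optimize.brentq(prevalence_gap, -8.0, 8.0)
        p_aud = stats.norm.cdf(c0 + score)
    else:
        p_aud = np.zeros(len(subjects))
    aud = drinkers & (rng.random(len(subjects)) < p_aud)

    for i, s in enumerate(subjects):
        s.onset_age_initiation = float(t_init[i])
        s.event_initiation = int(ev_init[i])
        s.onset_age_hed = float(t_hed[i])
        s.event_hed = int(ev_hed[i])
        s.initiated_at_baseline = int(ev_init[i] and onset_init[i] <= baseline[i])
        s.hed_at_baseline = int(ev_hed[i] and onset_hed[i] <= baseline[i])
        s.drinker = int(ev_init[i])
        s.aud_diagnosed = int(aud[i])
    return subjects


# ---------------------------------------------------------------------------
# stage 4: missingness
# ---------------------------------------------------------------------------

def apply_missingness(subjects: list[Subject], cfg: SimConfig) -> list[Subject]:
    """MCAR masks on the follow-up measures; baseline measures kept intact."""
    cfg.validate()
    rate = cfg.missing_rate_per_stage
    if rate == 0.0 or not subjects:
        return subjects
    rng = cfg.rng("missing")
    mask = rng.random(len(subjects)) < rate
    for i, s in enumerate(subjects):
        if mask[i]:
            for fld in FOLLOWUP_FIELDS:
                setattr(s, fld, float("nan"))
    return subjects


SEM_OBSERVED_COLUMNS = (
    "f_bonding", "f_closeness", "f_communication", "f_involvement",
    "m_bonding", "m_closeness", "m_communication", "m_involvement",
    "monitoring", "peer_drinking", "partner_drinking", "social_competence",
    "resistance",
)


def simulate_sem_observed(cfg: SimConfig, n: int, seed: int | None = None) -> pd.DataFrame:
    """Scale-level observed variables drawn directly from the path model.

    Latents, mediators, and the resistance outcome follow
    ``cfg.social_covariance()`` exactly (all unit variance); the eight
    indicator columns are continuous, ``lambda * factor + unique noise``.
    This bypasses item discretization and scoring, so the generating
    loadings and structural coefficients are recoverable without
    attenuation — the configuration used for estimator validation.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    sigma = cfg.social_covariance()
    order = list(PARENT_PREDICTORS) + list(MEDIATORS) + ["resist"]
    Z = rng.multivariate_normal(np.zeros(len(order)), sigma, size=n, method="cholesky")
    vals = {v: Z[:, i] for i, v in enumerate(order)}
    cols: dict[str, np.ndarray] = {}
    scale_names = ("bonding", "closeness", "communication", "involvement")
    for prefix, parent, lat in (("f", "father", "fq"), ("m", "mother", "mq")):
        for lam, scale in zip(cfg.loadings[parent], scale_names):
            cols[f"{prefix}_{scale}"] = lam * vals[lat] + math.sqrt(1 - lam * lam) * rng.normal(size=n)
    cols["monitoring"] = vals["mon"]
    cols["peer_drinking"] = vals["peer"]
    cols["partner_drinking"] = vals["partner"]
    cols["social_competence"] = vals["soc"]
    cols["resistance"] = vals["resist"]
    return pd.DataFrame(cols, columns=list(SEM_OBSERVED_COLUMNS))


def simulate_panel(cfg: SimConfig) -> tuple[list[Subject], list[RelativeRecord]]:
    """Run all four generation stages in order."""
    subjects, relatives = generate_families(cfg)
    simulate_social_block(subjects, cfg)
    simulate_onsets(subjects, cfg)
    apply_missingness(subjects, cfg)
    return subjects, relatives


# ---------------------------------------------------------------------------
# frame conversion and CSV output
# ---------------------------------------------------------------------------

ITEM_COLUMNS: list[tuple[str, int]] = (
    [(f"{p}_bond", 12) for p in "fm"]
    + [(f"{p}_close", 2) for p in "fm"]
    + [(f"{p}_comm", 3) for p in "fm"]
    + [(f"{p}_inv", 6) for p in "fm"]
    + [("mon", 3)]
)

_SIM_ONLY = ("true_liability", "resist_latent", "fq_latent", "mq_latent", "mon_latent")


def subjects_to_frame(subjects: Sequence[Subject]) -> pd.DataFrame:
    """Wide per-subject table; simulation-only columns get a ``sim_`` prefix."""
    rows = []
    for s in subjects:
        row: dict[str, Any] = {
            "family_id": s.family_id,
            "subject_id": s.subject_id,
            "sex": s.sex,
            "baseline_age": s.baseline_age,
            "ancestry_group": s.ancestry_group,
            "has_mother_data": s.has_mother_data,
            "has_father_data": s.has_father_data,
            "pc1": s.pc1,
            "pc2": s.pc2,
            "prs": s.prs,
            "peer_drinking": s.peer_drinking,
            "partner_drinking": s.partner_drinking,
            "social_competence": s.social_competence,
            "onset_age_initiation": s.onset_age_initiation,
            "event_initiation": s.event_initiation,
            "onset_age_hed": s.onset_age_hed,
            "event_hed": s.event_hed,
            "initiated_at_baseline": s.initiated_at_baseline,
            "hed_at_baseline": s.hed_at_baseline,
            "drinker": s.drinker,
            "aud_diagnosed": s.aud_diagnosed,
            "last_assessment_age": s.last_assessment_age,
        }
        for name, count in ITEM_COLUMNS:
            vals = s.items.get(name, (float("nan"),) * count)
            for j in range(count):
                row[f"{name}_{j + 1}"] = vals[j] if j < len(vals) else float("nan")
        for fld in _SIM_ONLY:
            row[f"sim_{fld}"] = getattr(s, fld)
        rows.append(row)
    return pd.DataFrame(rows)


def relatives_to_frame(relatives: Sequence[RelativeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family_id": r.family_id,
                "relative_id": r.relative_id,
                "degree": r.degree,
                "relation_label": r.relation_label,
                "aud_max_symptoms": r.aud_max_symptoms,
            }
            for r in relatives
        ],
        columns=["family_id", "relative_id", "degree", "relation_label", "aud_max_symptoms"],
    )


def frame_to_subjects(df: pd.DataFrame) -> list[Subject]:
    subjects = []
    for _, row in df.iterrows():
        items = {}
        for name, count in ITEM_COLUMNS:
            items[name] = tuple(float(row[f"{name}_{j + 1}"]) for j in range(count))
        kwargs = {
            fld: row[fld]
            for fld in (
                "family_id", "subject_id", "sex", "baseline_age", "ancestry_group",
                "has_mother_data", "has_father_data", "pc1", "pc2", "prs",
                "peer_drinking", "partner_drinking", "social_competence",
                "onset_age_initiation", "event_initiation", "onset_age_hed",
                "event_hed", "initiated_at_baseline", "hed_at_baseline",
                "drinker", "aud_diagnosed", "last_assessment_age",
            )
        }
        for fld in _SIM_ONLY:
            col = f"sim_{fld}"
            if col in row:
                kwargs[fld] = row[col]
        subjects.append(Subject(items=items, **kwargs))
    return subjects


def frame_to_relatives(df: pd.DataFrame) -> list[RelativeRecord]:
    return [
        RelativeRecord(
            family_id=int(r.family_id),
            relative_id=str(r.relative_id),
            degree=int(r.degree),
            relation_label=str(r.relation_label),
            aud_max_symptoms=int(r.aud_max_symptoms),
        )
        for r in df.itertuples()
    ]


def write_panel(
    subjects: Sequence[Subject],
    relatives: Sequence[RelativeRecord],
    cfg: SimConfig,
    outdir: str,
) -> dict[str, str]:
    """Emit subjects.csv, relatives.csv, a data dictionary, and a manifest."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "subjects": os.path.join(outdir, "subjects.csv"),
        "relatives": os.path.join(outdir, "relatives.csv"),
        "dictionary": os.path.join(outdir, "data_dictionary.md"),
        "manifest": os.path.join(outdir, "manifest.json"),
    }
    subjects_to_frame(subjects).to_csv(paths["subjects"], index=False)
    relatives_to_frame(relatives).to_csv(paths["relatives"], index=False)
    with open(paths["dictionary"], "w") as fh:
        fh.write(_data_dictionary())
    with open(paths["manifest"], "w") as fh:
        json.dump(
            {"config": cfg.to_dict(), "seed": cfg.seed, "config_hash": cfg.config_hash()},
            fh,
            indent=2,
        )
    return paths


def _data_dictionary() -> str:
    lines = [
        "# subjects.csv",
        "",
        "| column | description |",
        "|---|---|",
        "| family_id | integer family index (cluster for all family-clustered models) |",
        "| subject_id | unique subject label |",
        "| sex | 0 = male, 1 = female |",
        "| baseline_age | age in years at the baseline assessment |",
        "| ancestry_group | EA / AA analysis stratum |",
        "| has_mother_data / has_father_data | 1 if the parent's measures are present |",
        "| pc1, pc2 | synthetic nuisance covariates (ancestry-PC stand-ins) |",
        "| prs | polygenic score (noisy liability proxy, unstandardized) |",
        "| f_bond_1..12 / m_bond_1..12 | bonding items, responses 1-4 |",
        "| f_close_1..2 / m_close_1..2 | closeness items (4-point and 3-point) |",
        "| f_comm_1..3 / m_comm_1..3 | communication items, 0/1 |",
        "| f_inv_1..6 / m_inv_1..6 | involvement items, 0/1 |",
        "| mon_1..3 | monitoring items, 1 = always ... 4 = rarely (reverse-coded at scoring) |",
        "| peer_drinking | ordinal 1-4, follow-up measure |",
        "| partner_drinking | binary, follow-up measure |",
        "| social_competence | continuous, follow-up measure |",
        "| onset_age_initiation / event_initiation | observed time and event flag, alcohol initiation |",
        "| onset_age_hed / event_hed | observed time and event flag, heavy episodic drinking |",
        "| initiated_at_baseline / hed_at_baseline | 1 if onset preceded the baseline assessment |",
        "| drinker | 1 if alcohol initiation was ever observed |",
        "| aud_diagnosed | 1 if AUD diagnostic criteria were met (age >= 15) |",
        "| last_assessment_age | age at last assessment (censoring age) |",
        "| sim_* | simulation ground truth, withheld from analysis stages |",
        "",
        "# relatives.csv",
        "",
        "| column | description |",
        "|---|---|",
        "| family_id | family of the proband(s) |",
        "| relative_id | unique relative label |",
        "| degree | 1 or 2 (degree of relatedness) |",
        "| relation_label | father, mother, full sibling, grandparent, parental sibling, half sibling |",
        "| aud_max_symptoms | maximum lifetime AUD symptom count (non-negative integer) |",
        "",
    ]
    return "\n".join(lines)
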