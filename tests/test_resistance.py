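import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from alcres import resistance as rz
from alcres.config import SimConfig
from alcres.resistance import (
    CoxError,
    CoxFit,
    SurvivalRecord,
    build_analysis_subsamples,
    code_aud_resistance,
    fit_clustered_cox,
    residuals,
)
from alcres import synthdata


def make_records(times, events, xs, fams=None):
    fams = fams if fams is not None else list(range(len(times)))
    return [
        SurvivalRecord(f"s{i}", fams[i], t, e, {"x": float(x)})
        for i, (t, e, x) in enumerate(zip(times, events, xs))
    ]


# fabricated 6-subject dataset: exposed subjects fail earlier
TIMES6 = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
EVENTS6 = [1, 1, 1, 1, 0, 1]
X6 = [1.0, 1.0, 0.0, 1.0, 0.0, 0.0]


def breslow_pl(beta, times, events, xs):
    """Independent, literal implementation of the Breslow partial likelihood."""
    ll = 0.0
    for i, (t, d, x) in enumerate(zip(times, events, xs)):
        if not d:
            continue
        risk = [math.exp(beta * xj) for tj, xj in zip(times, xs) if tj >= t]
        ll += beta * x - math.log(sum(risk))
    return ll


def test_beta_matches_brute_force_partial_likelihood():
    recs = make_records(TIMES6, EVENTS6, X6)
    fit = fit_clustered_cox(recs, "robust")
    oracle = optimize.minimize_scalar(
        lambda b: -breslow_pl(b, TIMES6, EVENTS6, X6), bounds=(-5, 5), method="bounded",
        options={"xatol": 1e-10},
    )
    assert fit.beta[0] == pytest.approx(oracle.x, abs=1e-6)
    assert fit.loglik == pytest.approx(-oracle.fun, abs=1e-8)


def test_beta_matches_lifelines():
    rng = np.random.default_rng(0)
    n = 300
    x = rng.normal(size=n)
    t = rng.exponential(scale=np.exp(-0.5 * x))
    e = (t < np.quantile(t, 0.8)).astype(int)
    t = np.minimum(t, np.quantile(t, 0.8))
    recs = make_records(t, e, x)
    fit = fit_clustered_cox(recs, "robust")

    from lifelines import CoxPHFitter

    df = pd.DataFrame({"t": t, "e": e, "x": x})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="t", event_col="e")
    assert fit.beta[0] == pytest.approx(cph.params_["x"], abs=1e-5)


def test_efron_ties_match_lifelines():
    rng = np.random.default_rng(1)
    n = 200
    x = rng.normal(size=n)
    t = np.ceil(rng.exponential(scale=np.exp(-0.4 * x)) * 4)  # heavy ties
    e = rng.random(n) < 0.8
    recs = make_records(t, e.astype(int), x)
    fit = fit_clustered_cox(recs, "robust", tie_method="efron")

    from lifelines import CoxPHFitter

    df = pd.DataFrame({"t": t, "e": e.astype(int), "x": x})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="t", event_col="e")  # lifelines uses Efron
    assert fit.beta[0] == pytest.approx(cph.params_["x"], abs=1e-5)


def test_constant_covariate_dropped():
    recs = [
        SurvivalRecord(f"s{i}", i, t, e, {"x": float(x), "z": 1.0})
        for i, (t, e, x) in enumerate(zip(TIMES6, EVENTS6, X6))
    ]
    fit = fit_clustered_cox(recs, "robust")
    assert fit.dropped == ["z"]
    assert fit.names == ["x"]


def test_all_censored_errors():
    recs = make_records([1, 2, 3], [0, 0, 0], [0.0, 1.0, 0.5])
    with pytest.raises(CoxError, match="no events"):
        fit_clustered_cox(recs, "robust")


def test_nonpositive_time_rejected():
    with pytest.raises(CoxError, match="positive"):
        SurvivalRecord("s", 0, 0.0, 1, {"x": 1.0})


def test_partial_likelihood_beats_null():
    recs = make_records(TIMES6, EVENTS6, X6)
    fit = fit_clustered_cox(recs, "robust")
    assert fit.loglik >= breslow_pl(0.0, TIMES6, EVENTS6, X6)


def test_martingale_residuals_sum_to_zero():
    # Breslow ties, no frailty: residuals sum to ~0 at the MLE
    rng = np.random.default_rng(2)
    n = 500
    x = rng.normal(size=n)
    t = rng.exponential(scale=np.exp(-0.3 * x))
    e = np.ones(n, int)
    fit = fit_clustered_cox(make_records(t, e, x), "robust")
    assert abs(fit.martingale.sum()) < 1e-6 * n


def test_hr_ci_consistency():
    recs = make_records(TIMES6, EVENTS6, X6)
    fit = fit_clustered_cox(recs, "robust")
    tab = fit.hr_ci()
    # HR CI excludes 1 iff beta CI excludes 0
    beta_excludes = (fit.beta[0] - 1.96 * fit.se[0]) * (fit.beta[0] + 1.96 * fit.se[0]) > 0
    hr_excludes = (tab["hr_low"][0] - 1) * (tab["hr_high"][0] - 1) > 0
    assert beta_excludes == hr_excludes
    assert (np.diff(fit.baseline_cumhaz) >= 0).all()


# ---------------------------------------------------------------------------
# residual closed forms
# ---------------------------------------------------------------------------

def _residual_fixture(times, events, cumhaz_eta):
    """CoxFit shell with a prescribed Lambda0(t_i) * exp(eta_i)."""
    n = len(times)
    fit = CoxFit(
        names=[], beta=np.empty(0), se=np.empty(0), loglik=0.0,
        baseline_times=np.asarray(times, float),
        baseline_jumps=np.empty(0),
        cluster_mode="robust", frailty_variance=0.0, frailty_by_family={},
        subject_ids=[f"s{i}" for i in range(n)],
        family_ids=np.arange(n), times=np.asarray(times, float),
        events=np.asarray(events, int), eta0=np.zeros(n),
        martingale=np.empty(0), deviance=np.empty(0),
    )
    lam = np.asarray(cumhaz_eta, float)
    fit.cumhaz_at = lambda t: lam  # closed-form evaluation point
    return fit


def test_censored_zero_hazard_residuals():
    fit = _residual_fixture([1.0], [0], [0.0])
    m, d = residuals(fit)
    assert m[0] == 0.0 and d[0] == 0.0


def test_censored_half_hazard_residuals():
    fit = _residual_fixture([1.0], [0], [0.5])
    m, d = residuals(fit)
    assert m[0] == pytest.approx(-0.5)
    assert d[0] == pytest.approx(-1.0)


def test_event_unit_hazard_residuals():
    fit = _residual_fixture([1.0], [1], [1.0])
    m, d = residuals(fit)
    assert m[0] == pytest.approx(0.0)
    assert d[0] == pytest.approx(0.0, abs=1e-7)


def test_deviance_formula_event_case():
    fit = _residual_fixture([1.0], [1], [0.25])
    m, d = residuals(fit)
    assert m[0] == pytest.approx(0.75)
    expected = math.copysign(math.sqrt(-2 * (0.75 + math.log(0.25))), 0.75)
    assert d[0] == pytest.approx(expected)


def test_deviance_sign_and_censoring_properties(resistance_outputs):
    _, fits = resistance_outputs
    for key, fit in fits.items():
        assert np.all(np.sign(fit.deviance) == np.sign(fit.martingale)) or np.allclose(
            fit.deviance[np.sign(fit.deviance) != np.sign(fit.martingale)], 0.0
        )
        censored = fit.events == 0
        assert (fit.deviance[censored] <= 1e-12).all(), key


def test_robust_and_frailty_residuals_agree(subjects_frame, genrisk_frame):
    res_r, fits_r = rz.resistance_phenotypes(
        subjects_frame, genrisk_frame, cluster_mode="robust"
    )
    res_f, fits_f = rz.resistance_phenotypes(
        subjects_frame, genrisk_frame, cluster_mode="gamma_frailty",
        residual_frailty="marginal",
    )
    merged = res_r.merge(res_f, on=["subject_id", "phenotype"], suffixes=("_r", "_f"))
    for pheno in ("initiation", "hed"):
        sub = merged[merged["phenotype"] == pheno]
        r = np.corrcoef(sub["value_r"], sub["value_f"])[0, 1]
        assert r > 0.9, (pheno, r)


def test_null_simulation_positive_slope_on_environmental_frailty():
    # genetic covariates unrelated to hazard; onset driven by an
    # environmental (social) component -> deviance residuals positively
    # track the environmental log-frailty ("sooner than expected" = positive)
    cfg = SimConfig(
        n_families=1000,
        mean_family_size=2.0,
        log_hr={"initiation": {"resist": 0.8}, "hed": {}},
        missing_rate_per_stage=0.0,
        seed=43,
    )
    subjects, relatives = synthdata.simulate_panel(cfg)
    sdf = synthdata.subjects_to_frame(subjects)
    assert len(subjects) >= 2000
    from alcres import genrisk as gr_mod

    gr = gr_mod.compute_genetic_risk(sdf, synthdata.relatives_to_frame(relatives))
    res, fits = rz.resistance_phenotypes(sdf, gr, cluster_mode="robust")
    init = res[res["phenotype"] == "initiation"].merge(
        sdf[["subject_id", "sim_resist_latent"]], on="subject_id"
    )
    slope = np.polyfit(init["sim_resist_latent"], init["value"], 1)[0]
    se = np.sqrt(
        np.var(init["value"]) / (len(init) * np.var(init["sim_resist_latent"]))
    )
    assert slope / se > 2.326  # one-sided alpha = .01


def test_gamma_frailty_recovers_clustering():
    # strong family clustering in the hazard -> positive fitted frailty
    # variance; near-independent data -> theta at/near zero
    cfg = SimConfig(
        n_families=400, mean_family_size=3.0, h2_liability=0.8,
        log_hr={"initiation": {"liability": 1.2}, "hed": {}},
        missing_rate_per_stage=0.0, seed=47,
    )
    subjects, _ = synthdata.simulate_panel(cfg)
    recs = [
        SurvivalRecord(s.subject_id, s.family_id, s.onset_age_initiation,
                       s.event_initiation, {"sex": float(s.sex)})
        for s in subjects
    ]
    fit = fit_clustered_cox(recs, "gamma_frailty")
    assert fit.frailty_variance > 0.05
    assert set(fit.frailty_by_family) == {s.family_id for s in subjects}


def test_residuals_marginal_vs_conditional_differ_with_frailty(subjects_frame, genrisk_frame):
    _, fits = rz.resistance_phenotypes(
        subjects_frame, genrisk_frame, cluster_mode="gamma_frailty"
    )
    fit = next(f for f in fits.values() if f.frailty_variance > 0)
    m_cond, _ = residuals(fit, "conditional")
    m_marg, _ = residuals(fit, "marginal")
    assert not np.allclose(m_cond, m_marg)


# ---------------------------------------------------------------------------
# AUD coding and subsamples
# ---------------------------------------------------------------------------

def _toy(**kw):
    base = {
        "aud_diagnosed": 0, "drinker": 1, "last_assessment_age": 25.0,
    }
    base.update(kw)
    return base


def test_aud_coding_rules():
    df = pd.DataFrame(
        [
            _toy(aud_diagnosed=1, last_assessment_age=16.0),   # diagnosed at 16 -> 0
            _toy(last_assessment_age=24.0),                    # drinker through 24, clean -> 1
            _toy(last_assessment_age=21.0),                    # not assessed through 23 -> missing
            _toy(drinker=0),                                   # non-drinker -> missing
            _toy(aud_diagnosed=1, last_assessment_age=14.0),   # diagnosis impossible < 15 -> missing
        ]
    )
    code = code_aud_resistance(df)
    assert code[0] == 0.0
    assert code[1] == 1.0
    assert np.isnan(code[2])
    assert np.isnan(code[3])
    assert np.isnan(code[4])


def test_subsample_hand_count():
    # toy panel of 10 subjects with stated statuses
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(10)],
            "family_id": list(range(10)),
            "initiated_at_baseline": [1, 0, 0, 0, 1, 0, 0, 0, 0, 0],
            "hed_at_baseline":       [0, 0, 1, 0, 0, 0, 1, 0, 0, 0],
            "drinker":               [1, 1, 1, 1, 1, 1, 1, 1, 0, 1],
            "aud_diagnosed":         [0, 1, 0, 0, 0, 0, 0, 0, 0, 0],
            "last_assessment_age":   [25, 20, 25, 25, 21, 25, 25, 25, 25, 25],
        }
    )
    gr = pd.DataFrame(
        {
            "subject_id": df["subject_id"],
            "fhd": [0.5, 0.0, 1.0, 0.0, 0.2, 0.4, 0.0, 0.3, 0.6, 0.0],
            "prs_z": [0.0] * 10,
            "prs_top_quartile": [0, 1, 0, 0, 0, 0, 0, 0, 0, 0],
            "high_risk": [True, True, True, False, True, True, False, True, True, False],
        }
    )
    masks = build_analysis_subsamples(df, gr)
    # hand counts: initiation excludes s0, s4 -> 8; hed excludes s2, s6 -> 8
    assert masks["initiation"].sum() == 8
    assert masks["hed"].sum() == 8
    # aud: high_risk AND code non-missing.
    # codes: s0=1, s1=0 (diagnosed, age>=15), s2=1, s3=1, s4=missing(<23),
    #        s5=1, s6=1, s7=1, s8=missing(non-drinker), s9=1
    # high_risk & non-missing -> s0, s1, s2, s5, s7 = 5
    assert masks["aud"].sum() == 5
    assert not masks["initiation"][0] and not masks["initiation"][4]
    assert not masks["aud"][3]  # fhd 0, prs below cut -> excluded


def test_resistance_frame_shape(resistance_outputs, subjects_frame):
    res, _ = resistance_outputs
    assert set(res["phenotype"]) == {"initiation", "hed", "aud"}
    assert (res["sign_convention"] == rz.SIGN_CONVENTION).all()
    aud_vals = res.loc[res["phenotype"] == "aud", "value"]
    assert set(aud_vals).issubset({0.0, 1.0})
    n_init = (res["phenotype"] == "initiation").sum()
    expected = (subjects_frame["initiated_at_baseline"] != 1).sum()
    assert n_init == expected
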