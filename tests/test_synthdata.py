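import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from alcres import synthdata
from alcres.config import ConfigError, SimConfig


def test_empty_panel():
    cfg = SimConfig(n_families=0, seed=0)
    subjects, relatives = synthdata.generate_families(cfg)
    assert subjects == [] and relatives == []


def test_seed_determinism_byte_identical():
    cfg = SimConfig(n_families=50, seed=1)
    s1, r1 = synthdata.simulate_panel(cfg)
    s2, r2 = synthdata.simulate_panel(SimConfig(n_families=50, seed=1))
    csv1 = synthdata.subjects_to_frame(s1).to_csv(index=False)
    csv2 = synthdata.subjects_to_frame(s2).to_csv(index=False)
    assert csv1 == csv2
    assert synthdata.relatives_to_frame(r1).to_csv() == synthdata.relatives_to_frame(r2).to_csv()


def test_different_seeds_differ():
    a = synthdata.subjects_to_frame(synthdata.simulate_panel(SimConfig(n_families=30, seed=1))[0])
    b = synthdata.subjects_to_frame(synthdata.simulate_panel(SimConfig(n_families=30, seed=2))[0])
    assert not a.equals(b)


def _family_mean_liability_corr(liab: np.ndarray, fam: np.ndarray) -> float:
    means = pd.Series(liab).groupby(fam).transform("mean").to_numpy()
    return float(np.corrcoef(means, liab)[0, 1])


def test_family_liability_correlation_matches_mc_oracle():
    # brute-force oracle: same generative equations (family + individual
    # Gaussian components), written independently at large n
    rng = np.random.default_rng(99)
    h2 = 0.5
    n_fam_oracle = 100_000
    sizes = 1 + rng.poisson(1.0, size=n_fam_oracle)
    fam_o = np.repeat(np.arange(n_fam_oracle), sizes)
    a = np.repeat(rng.normal(0, math.sqrt(h2), size=n_fam_oracle), sizes)
    liab_o = a + rng.normal(0, math.sqrt(1 - h2), size=len(fam_o))
    oracle = _family_mean_liability_corr(liab_o, fam_o)

    cfg = SimConfig(n_families=2000, h2_liability=0.5, seed=3)
    subjects, _ = synthdata.generate_families(cfg)
    liab = np.array([s.true_liability for s in subjects])
    fam = np.array([s.family_id for s in subjects])
    observed = _family_mean_liability_corr(liab, fam)
    assert abs(observed - oracle) < 0.05


def test_within_family_liability_correlation_positive():
    cfg = SimConfig(n_families=2000, h2_liability=0.5, seed=5)
    subjects, _ = synthdata.generate_families(cfg)
    df = pd.DataFrame(
        {"fam": [s.family_id for s in subjects], "liab": [s.true_liability for s in subjects]}
    )
    sizes = df.groupby("fam").size()
    df = df[df["fam"].isin(sizes[sizes >= 2].index)]
    groups = [g["liab"].to_numpy() for _, g in df.groupby("fam")]
    f, p = stats.f_oneway(*groups)
    assert f > 1.0 and p / 2 < 0.01  # one-sided at alpha = .01


def test_prs_r2_calibration():
    cfg = SimConfig(n_families=2700, mean_family_size=2.0, prs_r2=0.15, seed=7)
    subjects, _ = synthdata.generate_families(cfg)
    liab = np.array([s.true_liability for s in subjects])
    prs = np.array([s.prs for s in subjects])
    assert len(subjects) >= 5000
    r2 = np.corrcoef(prs, liab)[0, 1] ** 2
    assert abs(r2 - 0.15) < 0.05


def test_relative_records_consistent(relatives_frame):
    assert set(relatives_frame["degree"]).issubset({1, 2})
    assert (relatives_frame["aud_max_symptoms"] >= 0).all()
    first = relatives_frame[relatives_frame["degree"] == 1]
    assert set(first["relation_label"]).issubset(set(synthdata.FIRST_DEGREE_LABELS))
    second = relatives_frame[relatives_frame["degree"] == 2]
    assert set(second["relation_label"]).issubset(set(synthdata.SECOND_DEGREE_LABELS))


def test_relative_record_validates_degree_label():
    with pytest.raises(ValueError, match="inconsistent"):
        synthdata.RelativeRecord(0, "r", 1, "grandparent", 2)
    with pytest.raises(ValueError, match="degree"):
        synthdata.RelativeRecord(0, "r", 3, "father", 2)
    with pytest.raises(ValueError, match="non-negative"):
        synthdata.RelativeRecord(0, "r", 1, "father", -1)


# ---------------------------------------------------------------------------
# onsets
# ---------------------------------------------------------------------------

def test_exponential_median_closed_form():
    # shape = 1 and no covariate effects -> exponential onset ages; the
    # Kaplan-Meier median must match scale * ln 2 (closed-form oracle)
    scale = 17.0
    cfg = SimConfig(
        n_families=2700,
        mean_family_size=2.0,
        hazard_shape=1.0,
        hazard_scale={"initiation": scale, "hed": scale},
        log_hr={"initiation": {}, "hed": {}},
        censor_age_range=(200.0, 300.0),  # effectively uncensored
        seed=11,
    )
    subjects, _ = synthdata.generate_families(cfg)
    synthdata.simulate_social_block(subjects, cfg)
    synthdata.simulate_onsets(subjects, cfg)
    n = len(subjects)
    assert n >= 5000
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(
        [s.onset_age_initiation for s in subjects],
        [s.event_initiation for s in subjects],
    )
    expected = scale * math.log(2)
    # MC error of the sample median: 1 / (2 f(m) sqrt(n))
    se = 1.0 / (2.0 * (math.exp(-math.log(2)) / scale) * math.sqrt(n))
    assert abs(km.median_survival_time_ - expected) < 4 * se


def test_infinite_log_hr_rejected():
    cfg = SimConfig(n_families=5, seed=0)
    subjects, _ = synthdata.generate_families(cfg)
    synthdata.simulate_social_block(subjects, cfg)
    cfg.log_hr["initiation"]["liability"] = float("inf")
    with pytest.raises(ConfigError):
        synthdata.simulate_onsets(subjects, cfg)


def test_unknown_predictor_rejected():
    cfg = SimConfig(n_families=5, seed=0)
    subjects, _ = synthdata.generate_families(cfg)
    synthdata.simulate_social_block(subjects, cfg)
    cfg.log_hr["initiation"]["no_such_field"] = 0.5
    with pytest.raises(ConfigError, match="no_such_field"):
        synthdata.simulate_onsets(subjects, cfg)


def test_hed_never_precedes_initiation(panel):
    for s in panel[0]:
        if s.event_hed:
            assert s.event_initiation == 1
            assert s.onset_age_hed >= s.onset_age_initiation - 1e-9


def test_onset_consistency(panel):
    for s in panel[0]:
        assert s.onset_age_initiation > 0
        assert s.onset_age_initiation <= s.last_assessment_age + 1e-9
        if s.event_initiation and not s.initiated_at_baseline:
            # analysis-subsample invariant: observed onsets after baseline
            assert s.onset_age_initiation >= s.baseline_age - 1e-9


def test_doubled_hazard_recovered_by_cox():
    # subgroup with exp(eta) doubled -> downstream Cox HR ~ 2 within 3 SE
    cfg = SimConfig(
        n_families=1500,
        mean_family_size=2.0,
        h2_liability=0.0,
        hazard_shape=3.0,
        hazard_scale={"initiation": 0.5, "hed": 20.0},
        log_hr={"initiation": {}, "hed": {"exposed": math.log(2.0)}},
        censor_age_range=(18.0, 30.0),
        missing_rate_per_stage=0.0,
        seed=13,
    )
    subjects, _ = synthdata.generate_families(cfg)
    synthdata.simulate_social_block(subjects, cfg)
    rng = np.random.default_rng(17)
    for s in subjects:
        s.extras["exposed"] = float(rng.random() < 0.5)
    synthdata.simulate_onsets(subjects, cfg)

    from alcres.resistance import SurvivalRecord, fit_clustered_cox

    recs = [
        SurvivalRecord(
            s.subject_id, s.family_id, s.onset_age_hed, s.event_hed,
            {"exposed": s.extras["exposed"]},
        )
        for s in subjects
    ]
    fit = fit_clustered_cox(recs, "robust")
    assert abs(fit.beta[0] - math.log(2.0)) < 3 * fit.se[0]


# ---------------------------------------------------------------------------
# social block
# ---------------------------------------------------------------------------

def test_null_path_structure():
    paths = {k: 0.0 for k in SimConfig().path_matrix}
    cfg = SimConfig(n_families=1000, mean_family_size=2.0, path_matrix=paths, seed=19)
    subjects, _ = synthdata.generate_families(cfg)
    synthdata.simulate_social_block(subjects, cfg)
    assert len(subjects) >= 2000
    fq = np.array([s.fq_latent for s in subjects])
    mon = np.array([s.mon_latent for s in subjects])
    for med in ("peer_drinking", "social_competence"):
        vals = np.array([getattr(s, med) for s in subjects])
        assert abs(np.corrcoef(fq, vals)[0, 1]) < 0.05
        assert abs(np.corrcoef(mon, vals)[0, 1]) < 0.05


def test_item_ranges(subjects_frame):
    for j in range(1, 13):
        col = subjects_frame[f"f_bond_{j}"].dropna()
        assert col.between(1, 4).all()
    for j in range(1, 4):
        assert subjects_frame[f"m_comm_{j}"].dropna().isin([0.0, 1.0]).all()
        assert subjects_frame[f"mon_{j}"].dropna().between(1, 4).all()
    assert subjects_frame["f_close_2"].dropna().between(1, 3).all()
    assert subjects_frame["peer_drinking"].dropna().between(1, 4).all()
    assert subjects_frame["partner_drinking"].dropna().isin([0.0, 1.0]).all()


def test_missing_parent_data_blanks_items(subjects_frame):
    no_father = subjects_frame[subjects_frame["has_father_data"] == 0]
    assert len(no_father) > 0
    assert no_father[[f"f_bond_{j}" for j in range(1, 13)]].isna().all().all()
    assert no_father[[f"m_bond_{j}" for j in range(1, 13)]].notna().any().any()


def test_near_deterministic_loadings_recovered_by_cfa():
    cfg = SimConfig(
        n_families=1500,
        mean_family_size=2.0,
        loadings={"father": (0.99,) * 4, "mother": (0.99,) * 4},
        item_reliability=0.999,
        discretize_items=False,
        missing_rate_per_stage=0.0,
        seed=23,
    )
    subjects, _ = synthdata.generate_families(cfg)
    for s in subjects:
        s.has_father_data = 1
        s.has_mother_data = 1
    synthdata.simulate_social_block(subjects, cfg)
    sdf = synthdata.subjects_to_frame(subjects)

    from alcres import scales

    scored = scales.score_subjects(sdf)
    fit = scales.fit_one_factor_cfa(
        scored[["f_bonding", "f_closeness", "f_communication", "f_involvement"]]
    )
    std = fit.loadings / np.sqrt(fit.loadings**2 + np.maximum(fit.residual_variances, 0.0))
    # the continuous response map is monotone but nonlinear, so recovery of
    # the 0.99 loadings is near-exact, not exact
    assert (np.abs(std) > 0.93).all()


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def test_zero_missing_rate_leaves_everything():
    cfg = SimConfig(n_families=100, missing_rate_per_stage=0.0, seed=29)
    subjects, _ = synthdata.simulate_panel(cfg)
    assert not any(np.isnan(s.peer_drinking) for s in subjects)


def test_missingness_binomial_calibration():
    cfg = SimConfig(n_families=950, mean_family_size=2.0, missing_rate_per_stage=0.38, seed=31)
    subjects, _ = synthdata.simulate_panel(cfg)
    n = len(subjects)
    assert n >= 1800
    observed = np.mean([not np.isnan(s.peer_drinking) for s in subjects])
    half_width = 2.576 * math.sqrt(0.62 * 0.38 / n)
    assert abs(observed - 0.62) < half_width


def test_missingness_masks_deterministic():
    cfg = SimConfig(n_families=200, missing_rate_per_stage=0.3, seed=37)
    s1, _ = synthdata.simulate_panel(cfg)
    s2, _ = synthdata.simulate_panel(SimConfig(n_families=200, missing_rate_per_stage=0.3, seed=37))
    m1 = [np.isnan(s.peer_drinking) for s in s1]
    m2 = [np.isnan(s.peer_drinking) for s in s2]
    assert m1 == m2


# ---------------------------------------------------------------------------
# output files and round trips
# ---------------------------------------------------------------------------

def test_write_panel_and_roundtrip(tmp_path, panel, small_cfg):
    subjects, relatives = panel
    paths = synthdata.write_panel(subjects, relatives, small_cfg, str(tmp_path))
    sdf = pd.read_csv(paths["subjects"])
    rdf = pd.read_csv(paths["relatives"])
    assert len(sdf) == len(subjects)
    assert len(rdf) == len(relatives)
    import json

    manifest = json.loads((tmp_path / "manifest.json").read_text())
    assert manifest["seed"] == small_cfg.seed
    assert (tmp_path / "data_dictionary.md").exists()
    back = synthdata.frame_to_subjects(sdf)
    assert back[0].subject_id == subjects[0].subject_id
    assert back[10].items["f_bond"] == pytest.approx(subjects[10].items["f_bond"], nan_ok=True)


def test_sem_observed_generator_matches_implied_covariance():
    cfg = SimConfig(seed=41)
    df = synthdata.simulate_sem_observed(cfg, 20000, seed=41)
    sigma = cfg.social_covariance()
    # mediator block covariances match the configured implied covariance
    got = np.cov(
        df[["peer_drinking", "partner_drinking", "social_competence", "resistance"]].T
    )
    assert np.allclose(got, sigma[3:, 3:], atol=0.05)
    lam = cfg.loadings["father"][0]
    r = np.corrcoef(df["f_bonding"], df["m_bonding"])[0, 1]
    expected = lam * lam * sigma[0, 1]
    assert abs(r - expected) < 0.05
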