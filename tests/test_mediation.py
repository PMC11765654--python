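"""Joint mediation model: likelihood unit checks, sampler contracts, PPC."""

import numpy as np
import pandas as pd
import pytest

from canopymed import data_io, mediation, synthetic
from canopymed._pg import pg_draw, pg_mean
from canopymed.errors import ModelSpecError, ValidationError
from canopymed.mediation import MediationCoefficients


def test_can_log_likelihood_hand_computed():
    c = MediationCoefficients(alpha_C=0.2, beta_C=-0.5, lam=0.3, tau=-0.1, phi=1.0)
    FE = [1, 0, 1]
    LD = [2.0, 1.0, 0.5]
    TD = [1.0, 0.0, -1.0]
    FCT = [0.5, -0.5, 0.0]
    CAN = [1, 0, 1]
    want = 0.0
    for fe, ld, td, f, y in zip(FE, LD, TD, FCT, CAN):
        psi = 0.2 - 0.5 * fe + 0.3 * ld - 0.1 * td + 1.0 * f
        p = 1.0 / (1.0 + np.exp(-psi))
        want += np.log(p) if y else np.log(1 - p)
    got = mediation.can_log_likelihood(c, FE, LD, TD, FCT, CAN)
    assert got == pytest.approx(want, abs=1e-10)


def test_pg_draws_match_analytic_mean():
    rng = np.random.default_rng(0)
    for z in (0.0, 0.5, 2.0, -3.0):
        draws = pg_draw(np.full(20000, z), rng)
        assert draws.mean() == pytest.approx(float(pg_mean(z)), rel=0.02)
        assert (draws > 0).all()


def test_fit_is_deterministic_given_seed(small_study):
    cap = small_study["captures_complete"].iloc[:150]
    model = mediation.build_joint_model(cap, small_study["fct_priors"])
    a = mediation.fit(model, chains=2, warmup=30, draws=40, seed=5)
    b = mediation.fit(model, chains=2, warmup=30, draws=40, seed=5)
    for k in mediation.COEFFICIENT_NAMES:
        assert np.array_equal(a.draws[k], b.draws[k])
    c = mediation.fit(model, chains=2, warmup=30, draws=40, seed=6)
    assert not np.array_equal(a.draws["alpha_C"], c.draws["alpha_C"])


def test_sampler_config_validation(small_study):
    model = mediation.build_joint_model(
        small_study["captures_complete"].iloc[:50], None
    )
    with pytest.raises(ValidationError, match="chains"):
        mediation.fit(model, chains=1)
    with pytest.raises(ValidationError):
        mediation.fit(model, chains=2, draws=1)


def test_zero_captures_prior_only_model():
    cap = pd.DataFrame(
        columns=[
            "individual_id", "timestamp", "site_id", "habitat", "stratum",
            "species", "tribe", "LD", "TD",
        ]
    )
    model = mediation.build_joint_model(cap, None)
    post = mediation.fit(model, chains=2, warmup=20, draws=100, seed=0)
    # posterior ~ the diffuse coefficient prior
    assert abs(post.draws["alpha_C"].std() - 100.0) < 30.0
    assert post.draws["sigma_L"].max() <= 50.0


def test_single_habitat_design_flagged(small_study):
    cap = small_study["captures_complete"]
    forest_only = cap[cap["habitat"] != "edge"].copy()
    model = mediation.build_joint_model(forest_only, small_study["fct_priors"])
    assert not model.identified
    post = mediation.fit(model, chains=2, warmup=20, draws=40, seed=1)
    assert not post.converged


def test_missing_covariates_require_abiotic_block(small_study):
    cap = small_study["captures_complete"].copy()
    cap.loc[cap.index[:5], "LD"] = np.nan
    with pytest.raises(ModelSpecError, match="missing LD"):
        mediation.build_joint_model(cap, None)
    with pytest.raises(ModelSpecError, match="complete-data"):
        mediation.build_joint_model(cap.drop(columns=["LD", "TD"]), None)


def test_joint_and_two_stage_fits_agree_without_missingness():
    """With complete loggers at tiny observation noise, the joint fit and the
    complete-data fit on directly attached LD/TD agree."""
    cfg = synthetic.GeneratorConfig(
        n_days=5, mediator_source="abiotic",
        logger_missing_rate=0.0, mar_first_half_factor=1.0,
        sigma_obs_light=0.02, sigma_obs_temp=0.02,
        never_instrumented={"edge": 0, "ridge": 0, "valley": 0},
    )
    ds = synthetic.gen_dataset(cfg, seed=13, n_captures=250, oracle_K=1000)
    state = data_io.loggers_to_state(ds["loggers"], ds["sites"])

    attached = data_io.attach_abiotic(ds["captures"], state)
    direct = mediation.build_joint_model(attached, ds["fct_priors"])
    post_direct = mediation.fit(
        direct, chains=2, warmup=300, draws=500, seed=3, thin=2
    )

    joint = mediation.build_joint_model(
        ds["captures"], ds["fct_priors"], abiotic_state=state
    )
    post_joint = mediation.fit(
        joint, chains=2, warmup=300, draws=500, seed=4, thin=2
    )
    for k in ("alpha_L", "beta_L", "sigma_L", "alpha_T", "beta_T", "gamma_T", "sigma_T"):
        a = float(post_direct.draws[k].mean())
        b = float(post_joint.draws[k].mean())
        assert a == pytest.approx(b, abs=0.05), k


def test_ppc_self_consistent_model(fitted_posterior):
    """Data really drawn from the fitted family: discrepancy p-values central
    and the calibration table close to the diagonal."""
    report = mediation.posterior_predictive_check(fitted_posterior, seed=0)
    assert report.fraction_central() >= 0.9
    calib = report.calibration
    big = calib[calib["n"] >= 30]
    p = big["predicted_mean"]
    binom_sd = np.sqrt(p * (1 - p) / big["n"])
    assert (
        np.abs(p - big["empirical_freq"]) <= 0.1 + 2 * binom_sd
    ).all()


def test_ppc_detects_misspecification(small_study):
    """Quadratic truth in the TD equation: at least one discrepancy p-value
    goes extreme."""
    rng = np.random.default_rng(9)
    cap = small_study["captures_complete"].copy()
    LD = cap["LD"].to_numpy()
    cap["TD"] = 0.5 + 0.9 * LD**2 + rng.normal(0, 0.3, len(cap))
    model = mediation.build_joint_model(cap, small_study["fct_priors"])
    post = mediation.fit(model, chains=2, warmup=200, draws=300, seed=2)
    report = mediation.posterior_predictive_check(post, seed=0)
    assert min(report.pvalues.values()) < 0.05 or max(report.pvalues.values()) > 0.95


def test_parameter_recovery_complete_data(small_study):
    """Posterior concentrates near the generative coefficients; the species
    composition scale is checked more loosely because tendencies are
    themselves inferred (their posterior spread inflates sigma_F)."""
    ds = small_study
    model = mediation.build_joint_model(ds["captures_complete"], ds["fct_priors"])
    post = mediation.fit(model, chains=2, warmup=400, draws=700, seed=17, thin=3)
    true = ds["truth"].coefficients
    tight = (
        "alpha_L", "beta_L", "sigma_L", "alpha_T", "beta_T", "gamma_T", "sigma_T",
    )
    for k in tight:
        mean = float(post.draws[k].mean())
        sd = float(post.draws[k].std())
        assert abs(mean - getattr(true, k)) < 4 * sd + 0.02, k
    for k in ("alpha_C", "beta_C", "phi"):
        mean = float(post.draws[k].mean())
        sd = float(post.draws[k].std())
        assert abs(mean - getattr(true, k)) < 4 * sd + 0.1, k
    assert abs(float(post.draws["beta_F"].mean()) - true.beta_F) < 0.5
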