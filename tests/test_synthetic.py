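"""The synthetic study generator: determinism, realism checks, oracles."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from canopymed import data_io, synthetic
from canopymed.mediation import MediationCoefficients, expit
from canopymed.stratification import counts_from_captures, delta_edge_table


def test_byte_identical_given_seed(tmp_path):
    cfg = synthetic.GeneratorConfig(n_days=3)
    for d in ("a", "b"):
        synthetic.write_dataset(
            synthetic.gen_dataset(cfg, seed=9, oracle_K=1000), tmp_path / d
        )
    for name in ("captures.csv", "loggers.csv", "sites.csv", "fct_priors.csv", "truth.json"):
        assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False), name


def test_study_scale_defaults():
    ds = synthetic.gen_dataset(synthetic.GeneratorConfig(), seed=21, oracle_K=1000)
    cap = ds["captures"]
    assert len(ds["sites"]) == 32
    assert 400 <= len(cap) <= 1000  # ~1.6 captures/site-day over 14 days
    assert 55 <= cap["species"].nunique() <= 90
    assert cap["tribe"].nunique() <= 12
    # fct prior table misses the configured fraction of species
    n_sp = ds["truth"].species.shape[0]
    assert len(ds["fct_priors"]) == n_sp - round(0.3 * n_sp)


def test_mcar_gap_rate():
    cfg = synthetic.GeneratorConfig(
        n_days=10, logger_missing_rate=0.2, mar_first_half_factor=1.0,
        never_instrumented={"edge": 0, "ridge": 0, "valley": 0},
    )
    rng = np.random.default_rng(5)
    sites = synthetic.gen_sites(cfg, rng)
    loggers, _ = synthetic.gen_abiotic(cfg, sites, rng)
    T = cfg.n_days * 24
    expected_full = sum(
        (T if j % 2 == 0 else T // 2) * 4 for j in range(len(sites))
    )
    frac_obs = len(loggers) / expected_full
    assert frac_obs == pytest.approx(0.8, abs=0.01)


def test_mar_missingness_heavier_in_first_half():
    cfg = synthetic.GeneratorConfig(
        n_days=10, logger_missing_rate=0.1, mar_first_half_factor=3.0,
        never_instrumented={"edge": 0, "ridge": 0, "valley": 0},
    )
    rng = np.random.default_rng(5)
    sites = synthetic.gen_sites(cfg, rng)
    loggers, _ = synthetic.gen_abiotic(cfg, sites, rng)
    half = synthetic.START + pd.Timedelta(hours=cfg.n_days * 24 // 2)
    n_first = (loggers["timestamp"] < half).sum()
    n_second = (loggers["timestamp"] >= half).sum()
    assert n_first < n_second


def test_zero_noise_observations_equal_diurnal_curves():
    cfg = synthetic.GeneratorConfig(
        n_days=2, sigma_proc_light=1e-9, sigma_proc_temp=1e-9,
        sigma_obs_light=1e-9, sigma_obs_temp=1e-9,
        logger_missing_rate=0.0, mar_first_half_factor=1.0,
        never_instrumented={"edge": 0, "ridge": 0, "valley": 0},
    )
    rng = np.random.default_rng(1)
    sites = synthetic.gen_sites(cfg, rng)
    loggers, latent = synthetic.gen_abiotic(cfg, sites, rng)
    temp = loggers[loggers["variable"] == "temperature_C"].copy()
    temp["hour"] = temp["timestamp"].dt.hour
    one = temp[(temp["site_id"] == "s11") & (temp["stratum"] == "canopy")]
    curve = synthetic._curve(
        cfg.curves[("ridge", "canopy", "temperature_C")], one["hour"].to_numpy()
    )
    assert np.allclose(one["value"].to_numpy(), curve, atol=1e-2)


def test_edge_understory_resembles_forest_canopy():
    """Daytime light at the edge understory ranks with the forest canopy,
    far above the forest understory."""
    cfg = synthetic.GeneratorConfig(n_days=10)
    rng = np.random.default_rng(2)
    sites = synthetic.gen_sites(cfg, rng)
    loggers, _ = synthetic.gen_abiotic(cfg, sites, rng)
    summary = data_io.hourly_summary(loggers, sites)
    light = summary[(summary["variable"] == "log_light") & summary["hour"].between(9, 15)]

    def day_mean(habitat, stratum):
        cell = light[(light["habitat"] == habitat) & (light["stratum"] == stratum)]
        return cell["mean"].mean()

    eu = day_mean("edge", "understory")
    fc = day_mean("ridge", "canopy")
    fu = day_mean("ridge", "understory")
    assert abs(eu - fc) < abs(eu - fu)
    assert eu > fu


def test_canopy_probability_driven_by_species_tendency():
    c = MediationCoefficients(
        alpha_F=0.0, beta_F=0.0, sigma_F=1.2, alpha_C=0.0, beta_C=0.0,
        lam=0.0, tau=0.0, phi=2.0,
        alpha_L=1.0, beta_L=0.0, sigma_L=0.5,
        alpha_T=0.5, beta_T=0.0, gamma_T=0.3, sigma_T=0.5,
    )
    cfg = synthetic.GeneratorConfig(coefficients=c)
    ds = synthetic.gen_dataset(cfg, seed=8, n_captures=4000, oracle_K=1000)
    cap = ds["captures"]
    fct = ds["truth"].species.set_index("species")["fct"]
    counts = cap.groupby("species").agg(
        n=("stratum", "size"), canopy=("stratum", lambda s: (s == "canopy").sum())
    )
    big = counts[counts["n"] >= 40]
    assert len(big) >= 5
    for sp, row in big.iterrows():
        p_hat = row["canopy"] / row["n"]
        p_true = float(expit(2.0 * fct[sp]))
        tol = 4 * np.sqrt(max(p_true * (1 - p_true), 0.01) / row["n"])
        assert abs(p_hat - p_true) <= tol, sp


def test_all_zero_coefficients_give_half_canopy():
    c = MediationCoefficients(sigma_L=0.5, sigma_T=0.5, sigma_F=0.5)
    ds = synthetic.gen_dataset(
        synthetic.GeneratorConfig(coefficients=c), seed=4, n_captures=3000, oracle_K=1000
    )
    frac = (ds["captures"]["stratum"] == "canopy").mean()
    assert frac == pytest.approx(0.5, abs=4 * 0.5 / np.sqrt(3000))


def test_negative_edge_coefficient_yields_positive_delta_excess():
    c = MediationCoefficients(
        alpha_L=1.2, beta_L=-0.9, sigma_L=0.6, alpha_T=0.8, beta_T=0.5,
        gamma_T=0.4, sigma_T=0.5, alpha_F=0.0, beta_F=0.0, sigma_F=0.9,
        alpha_C=0.0, beta_C=-1.5, lam=0.0, tau=0.0, phi=1.0,
    )
    ds = synthetic.gen_dataset(
        synthetic.GeneratorConfig(coefficients=c), seed=6, n_captures=2000, oracle_K=1000
    )
    rows = delta_edge_table(counts_from_captures(ds["captures"]))
    nontied = rows[rows["delta_edge"] != 0]
    frac_pos = (nontied["delta_edge"] > 0).mean()
    assert frac_pos > 0.65


def test_oracle_effects_zero_and_structure():
    zero = MediationCoefficients()
    eff = synthetic.oracle_effects(zero, K=10_000, seed=0)
    assert all(v == 0.0 for v in eff.values())

    bF_only = MediationCoefficients(
        alpha_F=-0.4, beta_F=0.8, sigma_F=0.9, phi=0.9, alpha_C=0.3
    )
    eff = synthetic.oracle_effects(bF_only, K=400_000, seed=1)
    assert eff["light_effect"] == 0.0 and eff["temperature_effect"] == 0.0
    assert eff["NDE"] == 0.0
    assert eff["SCE"] > 0.05
    # quadrature cross-check of the 1-D Gaussian-logistic integral
    x, w = np.polynomial.hermite_e.hermegauss(201)

    def gauss_logistic(mu, sd):
        return float(np.sum(w / np.sqrt(2 * np.pi) * expit(mu + sd * x)))

    sce_quad = gauss_logistic(0.3 + 0.9 * 0.4, 0.9 * 0.9) - gauss_logistic(
        0.3 + 0.9 * (-0.4), 0.9 * 0.9
    )
    assert eff["SCE"] == pytest.approx(sce_quad, abs=1e-3)


def test_oracle_effects_monte_carlo_stability():
    a = synthetic.oracle_effects(synthetic.GeneratorConfig().coefficients, K=1_000_000, seed=1)
    b = synthetic.oracle_effects(synthetic.GeneratorConfig().coefficients, K=1_000_000, seed=2)
    for k in a:
        assert a[k] == pytest.approx(b[k], abs=1.5e-3)
    total = a["NDE"] + a["light_effect"] + a["temperature_effect"] + a["SCE"]
    assert total == pytest.approx(a["TCE"], abs=1e-12)


def test_regression_mode_mediators_follow_structural_equations():
    cfg = synthetic.GeneratorConfig()
    ds = synthetic.gen_dataset(cfg, seed=30, n_captures=8000, oracle_K=1000)
    c = cfg.coefficients
    FE = (ds["captures"]["habitat"] == "edge").to_numpy().astype(int)
    LD = ds["truth"].capture_LD
    for a in (0, 1):
        want = c.alpha_L + c.beta_L * a
        sel = FE == a
        assert LD[sel].mean() == pytest.approx(
            want, abs=4 * c.sigma_L / np.sqrt(sel.sum())
        )
    # realized observation-level tendencies track the composition equation
    fct = ds["truth"].species.set_index("species")["fct"]
    fct_i = fct.reindex(ds["captures"]["species"]).to_numpy()
    shift = fct_i[FE == 1].mean() - fct_i[FE == 0].mean()
    assert shift == pytest.approx(c.beta_F, abs=0.1)
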