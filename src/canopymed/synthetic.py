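"""Synthetic study generator with known ground truth.

Emulates the field design the analysis assumes: 32 paired canopy /
understory trap sites (10 edge, 12 ridge, 10 valley), hourly loggers with
diurnal light/temperature curves that differ by habitat and stratum
(canopy brighter and hotter by day, slightly cooler at night; the edge
understory resembling the forest canopy), species with tribe-clustered
canopy tendencies and log-series abundances, capture strata drawn from
the logistic outcome model, and realistic missingness (never-instrumented
sites, gap rates higher in the first half of the study, species absent
from the canopy-tendency prior table).

Two mediator regimes:

* ``mediator_source="regression"`` (default) draws each capture's LD/TD
  directly from the structural equations, so the configured coefficients
  are the exact generative truth — the regime for parameter-recovery and
  coverage studies.
* ``mediator_source="abiotic"`` reads LD/TD off the latent diurnal
  series at the capture's habitat and hour — the regime for end-to-end
  pipeline runs, where the structural-equation coefficients describe the
  realized contrasts only approximately.

Species identity is assigned by drawing a target tendency from the FCT
structural equation and picking a species with probability proportional
to abundance times a narrow Gaussian kernel around the target, so the
observation-level FCT distribution tracks the configured equation while
keeping a long-tailed abundance structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import HABITATS, write_table
from .errors import ValidationError
from .mediation import MediationCoefficients, expit

START = pd.Timestamp("2015-06-01")

#: (level, first-harmonic amplitude, peak hour, second-harmonic amplitude)
Curve = tuple[float, float, float, float]

DEFAULT_CURVES: dict[tuple[str, str, str], Curve] = {
    # log light: edge understory sits near the forest canopy, far above the
    # forest understory; all curves peak near midday
    ("edge", "canopy", "log_light"): (5.0, 4.5, 13.0, 0.5),
    ("edge", "understory", "log_light"): (4.2, 4.0, 13.0, 0.5),
    ("ridge", "canopy", "log_light"): (4.8, 4.3, 13.0, 0.5),
    ("ridge", "understory", "log_light"): (1.8, 1.8, 13.0, 0.2),
    ("valley", "canopy", "log_light"): (4.7, 4.2, 13.0, 0.5),
    ("valley", "understory", "log_light"): (1.7, 1.7, 13.0, 0.2),
    # temperature: canopy amplitude exceeds understory amplitude, so canopy
    # is hotter by day and cooler at night
    ("edge", "canopy", "temperature_C"): (26.5, 3.5, 14.0, 0.8),
    ("edge", "understory", "temperature_C"): (26.0, 3.0, 14.0, 0.6),
    ("ridge", "canopy", "temperature_C"): (26.0, 3.2, 14.0, 0.8),
    ("ridge", "understory", "temperature_C"): (25.0, 1.5, 14.0, 0.3),
    ("valley", "canopy", "temperature_C"): (25.8, 3.2, 14.0, 0.8),
    ("valley", "understory", "temperature_C"): (24.8, 1.5, 14.0, 0.3),
}


@dataclass
class GeneratorConfig:
    """Study conditions for the generator; defaults mirror the study scale."""

    n_sites: dict = field(
        default_factory=lambda: {"edge": 10, "ridge": 12, "valley": 10}
    )
    n_species: int = 90
    n_tribes: int = 12
    tribe_mean_sd: float = 1.0        # between-tribe spread of FCT hypermeans
    tribe_within_sd: float = 0.7      # within-tribe spread of species FCT
    coefficients: MediationCoefficients = field(
        default_factory=lambda: MediationCoefficients(
            alpha_L=1.2, beta_L=-0.9, sigma_L=0.6,
            alpha_T=0.8, beta_T=0.5, gamma_T=0.4, sigma_T=0.5,
            alpha_F=-0.4, beta_F=0.8, sigma_F=0.9,
            alpha_C=0.3, beta_C=-0.9, lam=0.1, tau=-0.1, phi=0.9,
        )
    )
    curves: dict = field(default_factory=lambda: dict(DEFAULT_CURVES))
    rho: float = 0.6
    sigma_proc_light: float = 0.3
    sigma_proc_temp: float = 0.4
    sigma_obs_light: float = 0.2      # log scale
    sigma_obs_temp: float = 0.3
    n_days: int = 14
    capture_rate: float = 1.6         # expected captures per site-day
    capture_hours: tuple[int, int] = (8, 16)   # daylight trap window, inclusive
    mediator_source: str = "regression"
    species_kernel_sd: float = 0.15   # FCT-target matching bandwidth
    logseries_p: float = 0.95         # abundance long-tail parameter
    logger_missing_rate: float = 0.1
    mar_first_half_factor: float = 2.5  # missingness inflation, first half of study
    never_instrumented: dict = field(
        default_factory=lambda: {"edge": 1, "ridge": 3, "valley": 1}
    )
    fct_prior_missing_fraction: float = 0.3
    fct_prior_noise_sd: float = 0.2
    fct_prior_sd_range: tuple[float, float] = (0.3, 0.6)

    def __post_init__(self):
        for rate in (self.logger_missing_rate, self.fct_prior_missing_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValidationError("rates must lie in [0, 1]")
        if self.mediator_source not in ("regression", "abiotic"):
            raise ValidationError("mediator_source must be 'regression' or 'abiotic'")


@dataclass
class GroundTruth:
    """Everything the generator knows that the analyst must recover."""

    coefficients: MediationCoefficients
    species: pd.DataFrame             # species, tribe, fct
    latent_series: np.ndarray         # (12, T) analysis-scale latent states
    capture_LD: np.ndarray
    capture_TD: np.ndarray
    oracle: dict[str, float] | None = None


def _curve(curve: Curve, hours: np.ndarray) -> np.ndarray:
    level, amp, peak, amp2 = curve
    w = 2.0 * np.pi / 24.0
    return (
        level
        + amp * np.cos(w * (hours - peak))
        + amp2 * np.cos(2 * w * (hours - peak))
    )


def gen_sites(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    i = 1
    for habitat in HABITATS:
        for _ in range(config.n_sites[habitat]):
            rows.append(
                {
                    "site_id": f"s{i:02d}",
                    "habitat": habitat,
                    "canopy_height_m": round(float(np.clip(rng.normal(22.7, 5.3), 8, 40)), 1),
                    "understory_height_m": round(float(np.clip(rng.normal(0.9, 0.2), 0.3, 2.0)), 1),
                }
            )
            i += 1
    return pd.DataFrame(rows)


def gen_abiotic(
    config: GeneratorConfig, sites: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate the 12 latent series and per-site logger records with gaps.

    Returns the logger table (storage units: lux and °C) and the (12, T)
    latent matrix on the analysis scale. Sites of one habitat share the
    habitat-level latent series; their loggers add observation noise.
    Alternate sites log every other hour; a configured number of sites
    per habitat carry no logger at all; records drop out at the MCAR rate
    inflated in the first half of the study (missingness explainable by
    time, hence MAR).
    """
    from .abiotic import SERIES  # local import to avoid cycle at module load

    T = config.n_days * 24
    hours = np.arange(T) % 24
    latent = np.empty((len(SERIES), T))
    for s, key in enumerate(SERIES):
        base = _curve(config.curves[key], hours)
        sig = config.sigma_proc_light if key[2] == "log_light" else config.sigma_proc_temp
        e = np.empty(T)
        e[0] = 3.0 * sig * rng.standard_normal()
        innov = sig * rng.standard_normal(T)
        for t in range(1, T):
            e[t] = config.rho * e[t - 1] + innov[t]
        latent[s] = base + e

    series_pos = {key: i for i, key in enumerate(SERIES)}
    skip = {
        h: set(
            sites.loc[sites["habitat"] == h, "site_id"]
            .sample(n=k, random_state=int(rng.integers(2**31)))
            .tolist()
        )
        for h, k in config.never_instrumented.items()
    }
    records = []
    timestamps = START + pd.to_timedelta(np.arange(T), unit="h")
    for j, site in sites.iterrows():
        if site["site_id"] in skip.get(site["habitat"], set()):
            continue
        cadence = 1 if j % 2 == 0 else 2
        t_idx = np.arange(0, T, cadence)
        for stratum in ("canopy", "understory"):
            for var, storage in (("log_light", "light_lux"), ("temperature_C", "temperature_C")):
                s = series_pos[(site["habitat"], stratum, var)]
                noise_sd = config.sigma_obs_light if var == "log_light" else config.sigma_obs_temp
                vals = latent[s, t_idx] + noise_sd * rng.standard_normal(t_idx.size)
                if var == "log_light":
                    vals = np.maximum(np.exp(vals) - 1.0, 0.0)
                p_miss = np.full(t_idx.size, config.logger_missing_rate)
                p_miss[t_idx < T // 2] = np.minimum(
                    config.logger_missing_rate * config.mar_first_half_factor, 1.0
                )
                keep = rng.uniform(size=t_idx.size) >= p_miss
                for t, v in zip(t_idx[keep], vals[keep]):
                    records.append(
                        (timestamps[t], site["site_id"], stratum, storage, round(float(v), 3))
                    )
    loggers = pd.DataFrame(
        records, columns=["timestamp", "site_id", "stratum", "variable", "value"]
    )
    return loggers, latent


def _gen_species(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    tribe_means = rng.normal(0.0, config.tribe_mean_sd, size=config.n_tribes)
    tribe_of = rng.integers(config.n_tribes, size=config.n_species)
    fct = tribe_means[tribe_of] + config.tribe_within_sd * rng.standard_normal(config.n_species)
    abundance = rng.logseries(config.logseries_p, size=config.n_species).astype(float)
    return pd.DataFrame(
        {
            "species": [f"Species sp{i + 1:03d}" for i in range(config.n_species)],
            "tribe": [f"Tribus{t + 1:02d}" for t in tribe_of],
            "fct": fct,
            "abundance": abundance,
        }
    )


def gen_captures(
    config: GeneratorConfig,
    sites: pd.DataFrame,
    latent: np.ndarray,
    rng: np.random.Generator,
    *,
    n_captures: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the capture table and its ground truth.

    With ``n_captures`` unset the count is Poisson at ``capture_rate``
    per site-day (~700 at study scale). Capture hours are uniform over
    the daylight trap window.
    """
    from .abiotic import series_index

    c = config.coefficients
    species = _gen_species(config, rng)
    if n_captures is None:
        n_captures = int(rng.poisson(config.capture_rate * len(sites) * config.n_days))
    site_rows = sites.sample(
        n=n_captures, replace=True, random_state=int(rng.integers(2**31))
    ).reset_index(drop=True)
    day = rng.integers(config.n_days, size=n_captures)
    h_lo, h_hi = config.capture_hours
    hour = rng.integers(h_lo, h_hi + 1, size=n_captures)
    t_idx = day * 24 + hour
    FE = (site_rows["habitat"] == "edge").to_numpy().astype(int)

    # species composition: FCT target from the structural equation, species
    # matched by abundance x Gaussian kernel (Gumbel-max draw per capture)
    target = c.alpha_F + c.beta_F * FE + c.sigma_F * rng.standard_normal(n_captures)
    logw = (
        np.log(species["abundance"].to_numpy())[None, :]
        - (species["fct"].to_numpy()[None, :] - target[:, None]) ** 2
        / (2.0 * config.species_kernel_sd**2)
    )
    gumbel = rng.gumbel(size=logw.shape)
    sp_idx = np.argmax(logw + gumbel, axis=1)
    fct_i = species["fct"].to_numpy()[sp_idx]

    if config.mediator_source == "regression":
        LD = c.alpha_L + c.beta_L * FE + c.sigma_L * rng.standard_normal(n_captures)
        TD = (
            c.alpha_T + c.beta_T * FE + c.gamma_T * LD
            + c.sigma_T * rng.standard_normal(n_captures)
        )
    else:
        hab = site_rows["habitat"].to_numpy()
        lc = np.array([series_index(h, "canopy", "log_light") for h in hab])
        lu = np.array([series_index(h, "understory", "log_light") for h in hab])
        tc = np.array([series_index(h, "canopy", "temperature_C") for h in hab])
        tu = np.array([series_index(h, "understory", "temperature_C") for h in hab])
        LD = latent[lc, t_idx] - latent[lu, t_idx]
        TD = latent[tc, t_idx] - latent[tu, t_idx]

    psi = c.alpha_C + c.beta_C * FE + c.lam * LD + c.tau * TD + c.phi * fct_i
    CAN = (rng.uniform(size=n_captures) < expit(psi)).astype(int)

    captures = pd.DataFrame(
        {
            "individual_id": [f"b{i + 1:04d}" for i in range(n_captures)],
            "timestamp": START + pd.to_timedelta(t_idx, unit="h"),
            "site_id": site_rows["site_id"],
            "habitat": site_rows["habitat"],
            "stratum": np.where(CAN == 1, "canopy", "understory"),
            "species": species["species"].to_numpy()[sp_idx],
            "tribe": species["tribe"].to_numpy()[sp_idx],
        }
    )
    truth = GroundTruth(
        coefficients=c,
        species=species[["species", "tribe", "fct"]],
        latent_series=latent,
        capture_LD=LD,
        capture_TD=TD,
    )
    return captures, truth


def gen_fct_priors(
    config: GeneratorConfig, truth: GroundTruth, rng: np.random.Generator
) -> pd.DataFrame:
    """Noisy prior-study table for a random subset of species; the rest missing."""
    sp = truth.species
    n_missing = int(round(config.fct_prior_missing_fraction * len(sp)))
    order = rng.permutation(len(sp))
    keep = np.sort(order[n_missing:])
    lo, hi = config.fct_prior_sd_range
    rows = sp.iloc[keep].copy()
    rows["logit_mean"] = rows["fct"] + config.fct_prior_noise_sd * rng.standard_normal(len(rows))
    rows["logit_sd"] = rng.uniform(lo, hi, size=len(rows))
    return rows[["species", "tribe", "logit_mean", "logit_sd"]].reset_index(drop=True)


def oracle_effects(
    coeffs: MediationCoefficients, K: int = 1_000_000, seed: int = 0
) -> dict[str, float]:
    """Brute-force effect oracle at the true parameter vector.

    An independent Monte Carlo evaluation (own code path, very large K,
    common random numbers) of the same telescoping contrasts the
    decomposition stage reports; serves as the recovery target for
    synthetic studies.
    """
    rng = np.random.default_rng(seed)
    zL = rng.standard_normal(K)
    zT = rng.standard_normal(K)
    zF = rng.standard_normal(K)

    def mean_can(a, a_L, a_T, a_TL, a_F):
        LD = coeffs.alpha_L + coeffs.beta_L * a_L + coeffs.sigma_L * zL
        LD_td = coeffs.alpha_L + coeffs.beta_L * a_TL + coeffs.sigma_L * zL
        TD = coeffs.alpha_T + coeffs.beta_T * a_T + coeffs.gamma_T * LD_td + coeffs.sigma_T * zT
        FCT = coeffs.alpha_F + coeffs.beta_F * a_F + coeffs.sigma_F * zF
        return float(
            np.mean(
                expit(
                    coeffs.alpha_C + coeffs.beta_C * a
                    + coeffs.lam * LD + coeffs.tau * TD + coeffs.phi * FCT
                )
            )
        )

    p0 = mean_can(0, 0, 0, 0, 0)
    p1 = mean_can(1, 0, 0, 0, 0)
    p2 = mean_can(1, 1, 0, 0, 0)
    p3 = mean_can(1, 1, 1, 1, 0)
    p4 = mean_can(1, 1, 1, 1, 1)
    out = {
        "NDE": p1 - p0,
        "light_effect": p2 - p1,
        "temperature_effect": p3 - p2,
        "SCE": p4 - p3,
        "TCE": p4 - p0,
    }
    out["edge_effect"] = out["TCE"] - out["SCE"]
    return out


def gen_dataset(
    config: GeneratorConfig, seed: int, *, n_captures: int | None = None,
    oracle_K: int = 1_000_000,
) -> dict:
    """Generate one complete study: sites, loggers, captures, priors, truth."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sites = gen_sites(config, rng)
    loggers, latent = gen_abiotic(config, sites, rng)
    captures, truth = gen_captures(config, sites, latent, rng, n_captures=n_captures)
    fct_priors = gen_fct_priors(config, truth, rng)
    truth.oracle = oracle_effects(
        config.coefficients, K=oracle_K, seed=int(np.random.default_rng(seed).integers(2**31))
    )
    return {
        "config": config,
        "seed": seed,
        "sites": sites,
        "loggers": loggers,
        "captures": captures,
        "fct_priors": fct_priors,
        "truth": truth,
    }


def write_dataset(dataset: dict, outdir) -> None:
    """Serialize a generated study: CSV tables plus truth.json (byte-stable)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(dataset["captures"], outdir / "captures.csv")
    write_table(dataset["loggers"], outdir / "loggers.csv")
    write_table(dataset["sites"], outdir / "sites.csv")
    write_table(dataset["fct_priors"], outdir / "fct_priors.csv")
    truth = dataset["truth"]
    cfg = asdict(dataset["config"])
    cfg["coefficients"] = dataset["config"].coefficients.as_dict()
    cfg["curves"] = {"|".join(k): v for k, v in cfg["curves"].items()}
    payload = {
        "seed": dataset["seed"],
        "config": cfg,
        "true_coefficients": truth.coefficients.as_dict(),
        "oracle_effects": truth.oracle,
        "species_fct": truth.species.to_dict(orient="list"),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=2)
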