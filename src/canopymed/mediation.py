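"""Joint Bayesian mediation model on the causal graph FE -> {LD, TD, FCT} -> CAN.

The structural causal model has the forest-edge indicator FE as exposure,
the canopy-capture indicator CAN as binary outcome, and three mediators:
the canopy-minus-understory log-light difference LD, the temperature
difference TD (itself downstream of LD), and the species forest canopy
tendency FCT. The regression system, with exactly the graph's edges and
no interactions:

    LD_i  ~ Normal(alpha_L + beta_L FE_i, sigma_L^2)
    TD_i  ~ Normal(alpha_T + beta_T FE_i + gamma_T LD_i, sigma_T^2)
    FCT_i ~ Normal(alpha_F + beta_F FE_i, sigma_F^2),  FCT_i = FCT of species(i)
    CAN_i ~ Bernoulli(logit^-1(alpha_C + beta_C FE_i + lambda LD_i
                                + tau TD_i + phi FCT_i))

Priors on regression coefficients are effectively flat (Normal(0, 100),
diffuse at the data scale but proper, so prior-only runs are well
defined); error sds get Uniform(0, 50]. The missing-data blocks — the
abiotic state space (:mod:`canopymed.abiotic`) and the tribe-level FCT
hierarchy (:mod:`canopymed.fct`) — share the joint posterior, so missing
LD/TD/FCT values are parameters estimated together with the regressions.

Sampling is a Pólya-Gamma-augmented Gibbs sweep: PG augmentation turns
the logistic likelihood conditionally Gaussian, making every block
conjugate (coefficients, sds, species FCT values, tribe hypers) and
letting latent abiotic states be drawn exactly by FFBS with the
regression terms entering as Gaussian pseudo-observations through each
capture's stratum contrasts. Convergence is gated on split-R-hat and
effective sample size (arviz); a Gibbs sweep has no divergent
transitions, so the divergence count is structurally zero.

One deliberate modularization: the three Gaussian analysis regressions
are fit from the current draws of their (possibly latent) responses but
do not feed back into those latents. A Gaussian regression whose
response is a free latent and whose error sd carries a flat prior has
an unbounded density spike — sd -> 0 with every latent pinned to the
regression line — and blocked conditionals funnel straight into it, so
the latent species tendencies are updated from their study priors, the
tribe hierarchy and the capture outcomes, and the latent abiotic states
from the logger likelihood, the state dynamics and the capture
outcomes (a cut posterior in the sense of Plummer's "Cuts in Bayesian
graphical models"; the bounded logistic outcome term keeps information
flowing from captures into all imputations). The counterfactual
machinery uses the regressions generatively, so effect definitions are
unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from . import abiotic as ab
from ._pg import pg_draw
from .data_io import can_indicator, fe_indicator
from .errors import ModelSpecError, ValidationError
from .fct import FCTBlock, build_fct_block

logger = logging.getLogger("canopymed")

_COEF_PRIOR_SD = 100.0
_SD_CAP = 50.0

COEFFICIENT_NAMES = [
    "alpha_L", "beta_L", "sigma_L",
    "alpha_T", "beta_T", "gamma_T", "sigma_T",
    "alpha_F", "beta_F", "sigma_F",
    "alpha_C", "beta_C", "lam", "tau", "phi",
]


@dataclass(frozen=True)
class MediationCoefficients:
    """One complete set of structural-equation parameters."""

    alpha_L: float = 0.0
    beta_L: float = 0.0
    sigma_L: float = 1.0
    alpha_T: float = 0.0
    beta_T: float = 0.0
    gamma_T: float = 0.0
    sigma_T: float = 1.0
    alpha_F: float = 0.0
    beta_F: float = 0.0
    sigma_F: float = 1.0
    alpha_C: float = 0.0
    beta_C: float = 0.0
    lam: float = 0.0
    tau: float = 0.0
    phi: float = 0.0

    def __post_init__(self):
        for name in ("sigma_L", "sigma_T", "sigma_F"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def can_log_likelihood(coeffs: MediationCoefficients, FE, LD, TD, FCT, CAN) -> float:
    """Bernoulli-logit log-likelihood of the outcome block."""
    FE, LD, TD, FCT, CAN = (np.asarray(a, dtype=float) for a in (FE, LD, TD, FCT, CAN))
    psi = (
        coeffs.alpha_C + coeffs.beta_C * FE + coeffs.lam * LD
        + coeffs.tau * TD + coeffs.phi * FCT
    )
    p = expit(psi)
    return float(np.sum(CAN * np.log(p) + (1 - CAN) * np.log1p(-p)))


@dataclass
class MediationModel:
    """Assembled joint model: design arrays plus optional missing-data blocks."""

    FE: np.ndarray
    CAN: np.ndarray
    species_idx: np.ndarray
    fct_block: FCTBlock
    LD_obs: np.ndarray | None = None       # observed covariates (complete-data mode)
    TD_obs: np.ndarray | None = None
    abiotic_block: ab.AbioticBlock | None = None
    capture_t: np.ndarray | None = None    # hour-grid index per capture (joint mode)
    capture_habitat: np.ndarray | None = None
    identified: bool = True

    @property
    def n(self) -> int:
        return len(self.FE)

    @property
    def joint(self) -> bool:
        return self.abiotic_block is not None


def build_joint_model(
    captures: pd.DataFrame,
    fct_priors: pd.DataFrame | None = None,
    *,
    abiotic_state: pd.DataFrame | None = None,
) -> MediationModel:
    """Assemble the joint model from a capture table.

    Two modes:

    * complete-data — ``captures`` carries observed ``LD``/``TD`` columns
      with no missing values; the abiotic block is omitted.
    * joint — ``abiotic_state`` (the tidy analysis-scale logger table from
      :func:`canopymed.data_io.loggers_to_state`) is given; per-capture
      LD/TD are latent contrasts of the 12-series state space and any
      missingness is handled inside the posterior.
    """
    fct_block = build_fct_block(captures, fct_priors)
    sp_pos = {sp: i for i, sp in enumerate(fct_block.species)}
    species_idx = np.array([sp_pos[s] for s in captures["species"]], dtype=int)
    FE = fe_indicator(captures["habitat"])
    CAN = can_indicator(captures["stratum"])
    if len(FE) and (FE.min() == FE.max()):
        logger.warning(
            "all captures share FE=%d: edge coefficients are unidentified; "
            "model flagged", int(FE[0]) if len(FE) else -1
        )
        identified = False
    else:
        identified = len(FE) > 0

    if abiotic_state is not None:
        span = (
            (captures["timestamp"].min(), captures["timestamp"].max())
            if len(captures)
            else None
        )
        block = ab.build_state_space(abiotic_state, span=span)
        capture_t = block.timestamp_to_t(captures["timestamp"]) if len(captures) else np.array([], int)
        return MediationModel(
            FE=FE, CAN=CAN, species_idx=species_idx, fct_block=fct_block,
            abiotic_block=block, capture_t=capture_t,
            capture_habitat=captures["habitat"].to_numpy(),
            identified=identified,
        )

    for col in ("LD", "TD"):
        if col not in captures.columns:
            raise ModelSpecError(
                f"complete-data model needs an observed {col} column "
                "(or pass abiotic_state for joint imputation)"
            )
        if captures[col].isna().any():
            raise ModelSpecError(
                f"missing {col} values but no abiotic block to impute them; "
                "pass abiotic_state to fit the joint model"
            )
    return MediationModel(
        FE=FE, CAN=CAN, species_idx=species_idx, fct_block=fct_block,
        LD_obs=captures["LD"].to_numpy(dtype=float),
        TD_obs=captures["TD"].to_numpy(dtype=float),
        identified=identified,
    )


# --------------------------------------------------------------------------
# Gibbs machinery


def _sample_linreg(rng, X, y, sigma):
    """Conjugate draw of regression coefficients given the error sd."""
    p = X.shape[1]
    A = X.T @ X / sigma**2 + np.eye(p) / _COEF_PRIOR_SD**2
    rhs = X.T @ y / sigma**2
    L = np.linalg.cholesky(A)
    mean = np.linalg.solve(A, rhs)
    return mean + np.linalg.solve(L.T, rng.standard_normal(p))


def _sample_sigma(rng, resid, n) -> float:
    """Flat-on-sigma conditional, Uniform(0, 50] support."""
    if n < 3:
        return float(rng.uniform(0.1, _SD_CAP))
    ss = float(np.sum(resid**2))
    shape = (n - 1) / 2.0
    for _ in range(100):
        sd = float(np.sqrt(ss / 2.0 / rng.gamma(shape)))
        if sd <= _SD_CAP:
            return max(sd, 1e-6)
    return _SD_CAP


class _JointGibbs:
    def __init__(self, model: MediationModel, rng: np.random.Generator):
        self.m = model
        self.rng = rng
        n = model.n
        S = model.fct_block.n_species
        Tn = model.fct_block.n_tribes
        self.coef = {name: 0.0 for name in COEFFICIENT_NAMES}
        for name in ("sigma_L", "sigma_T", "sigma_F"):
            self.coef[name] = 1.0
        self.fct = rng.normal(0.0, 0.5, size=S)
        prior = model.fct_block
        self.fct[prior.has_prior] = prior.prior_mean[prior.has_prior]
        self.tribe_mu = rng.normal(0.0, 0.5, size=Tn)
        self.tribe_sd = np.full(Tn, 1.0)
        self.omega = np.full(n, 0.25)
        if model.joint:
            self.ab = ab.AbioticGibbs(model.abiotic_block, rng)
            self._roles = self._capture_roles()
            self.LD = np.zeros(n)
            self.TD = np.zeros(n)
            self._refresh_contrasts()
        else:
            self.ab = None
            self.LD = model.LD_obs
            self.TD = model.TD_obs

    # -- joint-mode helpers ------------------------------------------------

    def _capture_roles(self):
        hab = self.m.capture_habitat
        return {
            "lc": np.array([ab.series_index(h, "canopy", "log_light") for h in hab]),
            "lu": np.array([ab.series_index(h, "understory", "log_light") for h in hab]),
            "tc": np.array([ab.series_index(h, "canopy", "temperature_C") for h in hab]),
            "tu": np.array([ab.series_index(h, "understory", "temperature_C") for h in hab]),
        }

    def _refresh_contrasts(self):
        X, t, r = self.ab.X, self.m.capture_t, self._roles
        self.LD = X[r["lc"], t] - X[r["lu"], t]
        self.TD = X[r["tc"], t] - X[r["tu"], t]

    def _psi(self):
        c = self.coef
        return (
            c["alpha_C"] + c["beta_C"] * self.m.FE
            + c["lam"] * self.LD + c["tau"] * self.TD
            + c["phi"] * self.fct[self.m.species_idx]
        )

    def _mediation_pseudo_obs(self):
        """(12, T) precision and precision*mean arrays from the outcome term.

        For a capture at habitat h and hour t, the PG-augmented logistic
        outcome term is Gaussian in each of the four series values of
        that (h, t) with the others held fixed, giving exact Gaussian
        pseudo-observations for the FFBS update. The LD/TD analysis
        regressions deliberately do not feed back into the states (module
        docstring: a Gaussian regression with a free error sd and latent
        responses has an unbounded density spike at sd -> 0); imputation
        information flows from the logger likelihood, the state dynamics
        and the capture outcomes.
        """
        m, c = self.m, self.coef
        S, T = ab.N_SERIES, m.abiotic_block.n_hours
        prec = np.zeros((S, T))
        pm = np.zeros((S, T))
        t = m.capture_t
        r = self._roles
        kappa = m.CAN - 0.5
        psi = self._psi()

        def add(role, p_i, pm_i):
            np.add.at(prec, (r[role], t), p_i)
            np.add.at(pm, (r[role], t), pm_i)

        x_lc, x_lu = self.ab.X[r["lc"], t], self.ab.X[r["lu"], t]
        x_tc, x_tu = self.ab.X[r["tc"], t], self.ab.X[r["tu"], t]
        # psi = coef * v + d  ->  prec omega*coef^2, pm coef*(kappa - omega*d)
        for role, coef_v, v in (
            ("lc", c["lam"], x_lc),
            ("lu", -c["lam"], x_lu),
            ("tc", c["tau"], x_tc),
            ("tu", -c["tau"], x_tu),
        ):
            if abs(coef_v) < 1e-12:
                continue
            d = psi - coef_v * v
            add(role, self.omega * coef_v**2, coef_v * (kappa - self.omega * d))
        return prec, pm

    # -- Gibbs blocks ------------------------------------------------------

    def _update_outcome_coefs(self):
        m, rng = self.m, self.rng
        if m.n == 0:
            for name in ("alpha_C", "beta_C", "lam", "tau", "phi"):
                self.coef[name] = rng.normal(0.0, _COEF_PRIOR_SD)
            return
        Xc = np.column_stack(
            [np.ones(m.n), m.FE, self.LD, self.TD, self.fct[m.species_idx]]
        )
        kappa = m.CAN - 0.5
        A = (Xc * self.omega[:, None]).T @ Xc + np.eye(5) / _COEF_PRIOR_SD**2
        rhs = Xc.T @ kappa
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, rhs)
        draw = mean + np.linalg.solve(L.T, rng.standard_normal(5))
        for name, val in zip(("alpha_C", "beta_C", "lam", "tau", "phi"), draw):
            self.coef[name] = float(val)

    def _update_regression(self, names, design_cols, y, sigma_name):
        rng, m = self.rng, self.m
        p = len(names)
        if m.n < p + 2:
            for name in names:
                self.coef[name] = rng.normal(0.0, _COEF_PRIOR_SD)
            self.coef[sigma_name] = _sample_sigma(rng, np.empty(0), m.n)
            return
        X = np.column_stack(design_cols)
        beta = _sample_linreg(rng, X, y, self.coef[sigma_name])
        for name, val in zip(names, beta):
            self.coef[name] = float(val)
        resid = y - X @ beta
        self.coef[sigma_name] = _sample_sigma(rng, resid, m.n)

    def _update_fct(self):
        m, c, rng = self.m, self.coef, self.rng
        blk = m.fct_block
        S = blk.n_species
        prec = np.where(
            blk.has_prior, 1.0 / blk.prior_sd**2, 1.0 / self.tribe_sd[blk.tribe_idx] ** 2
        )
        pm = np.where(
            blk.has_prior,
            blk.prior_mean / np.where(np.isfinite(blk.prior_sd), blk.prior_sd, 1.0) ** 2,
            self.tribe_mu[blk.tribe_idx] / self.tribe_sd[blk.tribe_idx] ** 2,
        )
        if m.n:
            sp = m.species_idx
            # no composition-regression term here: the FCT block is cut
            # (module docstring); tendencies are informed by study priors,
            # the tribe hierarchy and the capture outcomes
            # CAN PG term: psi = phi * FCT_s + rest
            phi = c["phi"]
            if abs(phi) > 1e-12:
                rest = self._psi() - phi * self.fct[sp]
                kappa = m.CAN - 0.5
                prec = prec + phi**2 * np.bincount(sp, weights=self.omega, minlength=S)
                pm = pm + phi * np.bincount(
                    sp, weights=kappa - self.omega * rest, minlength=S
                )
        var = 1.0 / prec
        self.fct = pm * var + np.sqrt(var) * rng.standard_normal(S)

    def _update_tribe_hypers(self):
        blk, rng = self.m.fct_block, self.rng
        for tix in range(blk.n_tribes):
            members = (~blk.has_prior) & (blk.tribe_idx == tix)
            k = int(members.sum())
            sd = self.tribe_sd[tix]
            if k == 0:
                self.tribe_mu[tix] = rng.normal(0.0, blk.tribe_mean_prior_sd)
                self.tribe_sd[tix] = abs(rng.normal(0.0, blk.tribe_sd_prior_scale)) + 1e-3
                continue
            vals = self.fct[members]
            post_prec = k / sd**2 + 1.0 / blk.tribe_mean_prior_sd**2
            post_mean = (vals.sum() / sd**2) / post_prec
            self.tribe_mu[tix] = post_mean + rng.standard_normal() / np.sqrt(post_prec)
            # half-normal prior on sd: random-walk MH on log sd
            mu = self.tribe_mu[tix]
            prop = float(sd * np.exp(0.4 * rng.standard_normal()))
            def logpost(s):
                return (
                    -k * np.log(s)
                    - np.sum((vals - mu) ** 2) / (2 * s**2)
                    - s**2 / (2 * blk.tribe_sd_prior_scale**2)
                    + np.log(s)  # Jacobian of the log-scale walk
                )
            if np.log(rng.uniform()) < logpost(prop) - logpost(sd):
                self.tribe_sd[tix] = prop

    def sweep(self):
        m, rng = self.m, self.rng
        if m.n:
            self.omega = pg_draw(self._psi(), rng)
        self._update_outcome_coefs()
        FE1 = np.ones(m.n)
        self._update_regression(
            ("alpha_L", "beta_L"), (FE1, m.FE), self.LD, "sigma_L"
        )
        self._update_regression(
            ("alpha_T", "beta_T", "gamma_T"), (FE1, m.FE, self.LD), self.TD, "sigma_T"
        )
        self._update_regression(
            ("alpha_F", "beta_F"), (FE1, m.FE), self.fct[m.species_idx], "sigma_F"
        )
        self._update_fct()
        self._update_tribe_hypers()
        if self.ab is not None:
            logger_prec, logger_pm = self.ab.obs_precisions()
            for s in range(ab.N_SERIES):
                prec, pm = self._mediation_pseudo_obs()
                self.ab.ffbs_series(s, logger_prec + prec, logger_pm + pm)
                self._refresh_contrasts()
            for s in range(ab.N_SERIES):
                self.ab.update_params_series(s)


# --------------------------------------------------------------------------
# fit + posterior container


@dataclass
class MediationPosterior:
    """Joint posterior draws with sampler diagnostics.

    ``draws[name]`` has shape (chains, draws) for scalar parameters,
    (chains, draws, S) for species FCT values and (chains, draws, n) for
    imputed per-capture LD/TD (joint mode only).
    """

    model: MediationModel
    draws: dict[str, np.ndarray]
    rhat: dict[str, float]
    ess: dict[str, float]
    divergences: int = 0
    converged: bool = False
    seed: int | None = None

    @property
    def n_draws(self) -> int:
        shape = self.draws["alpha_C"].shape
        return shape[0] * shape[1]

    def coefficient_draws(self) -> pd.DataFrame:
        """Flat (chains*draws, 15) table of structural coefficients."""
        return pd.DataFrame(
            {name: self.draws[name].reshape(-1) for name in COEFFICIENT_NAMES}
        )

    def coefficients(self, flat_index: int) -> MediationCoefficients:
        table = {
            name: float(self.draws[name].reshape(-1)[flat_index])
            for name in COEFFICIENT_NAMES
        }
        return MediationCoefficients(**table)

    def posterior_means(self) -> MediationCoefficients:
        return MediationCoefficients(
            **{name: float(self.draws[name].mean()) for name in COEFFICIENT_NAMES}
        )


def _diagnostics(draws: dict[str, np.ndarray]) -> tuple[dict, dict]:
    import arviz as az

    scalars = {k: v for k, v in draws.items() if v.ndim == 2}
    idata = az.from_dict(posterior={k: v for k, v in scalars.items()})
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    rhat = {k: float(rhat_ds[k].values) for k in scalars}
    ess = {k: float(ess_ds[k].values) for k in scalars}
    return rhat, ess


def fit(
    model: MediationModel,
    *,
    chains: int = 2,
    warmup: int = 500,
    draws: int = 500,
    seed: int = 0,
    thin: int = 1,
    rhat_max: float = 1.01,
    ess_min: float = 400.0,
    store_imputations: bool = True,
) -> MediationPosterior:
    """Run the Gibbs sampler; reproducible given ``seed``.

    Non-convergence never fails silently: the returned posterior carries
    ``converged=False`` and a warning is logged. At least two chains are
    required so split-R-hat is meaningful.
    """
    if chains < 2:
        raise ValidationError("need >= 2 chains to assess convergence")
    if draws < 2 or warmup < 0 or thin < 1:
        raise ValidationError("invalid sampler configuration")
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(chains)
    kept = draws
    store: dict[str, np.ndarray] = {
        name: np.empty((chains, kept)) for name in COEFFICIENT_NAMES
    }
    S = model.fct_block.n_species
    Tn = model.fct_block.n_tribes
    store["fct"] = np.empty((chains, kept, S))
    store["tribe_mu"] = np.empty((chains, kept, Tn))
    store["tribe_sd"] = np.empty((chains, kept, Tn))
    if model.joint and store_imputations:
        store["LD"] = np.empty((chains, kept, model.n))
        store["TD"] = np.empty((chains, kept, model.n))

    for c in range(chains):
        rng = np.random.default_rng(child[c])
        gibbs = _JointGibbs(model, rng)
        for _ in range(warmup):
            gibbs.sweep()
        for d in range(kept):
            for _ in range(thin):
                gibbs.sweep()
            for name in COEFFICIENT_NAMES:
                store[name][c, d] = gibbs.coef[name]
            store["fct"][c, d] = gibbs.fct
            store["tribe_mu"][c, d] = gibbs.tribe_mu
            store["tribe_sd"][c, d] = gibbs.tribe_sd
            if model.joint and store_imputations:
                store["LD"][c, d] = gibbs.LD
                store["TD"][c, d] = gibbs.TD

    rhat, ess = _diagnostics(store)
    checked = COEFFICIENT_NAMES
    worst_rhat = max(rhat[k] for k in checked)
    worst_ess = min(ess[k] for k in checked)
    converged = bool(worst_rhat <= rhat_max and worst_ess >= ess_min)
    if not converged:
        logger.warning(
            "posterior failed the convergence gate: max R-hat %.4f (<= %.3f), "
            "min ESS %.0f (>= %.0f)",
            worst_rhat, rhat_max, worst_ess, ess_min,
        )
    if not model.identified:
        converged = False
        logger.warning("degenerate design (single FE level): run marked non-converged")
    return MediationPosterior(
        model=model, draws=store, rhat=rhat, ess=ess,
        divergences=0, converged=converged, seed=seed,
    )


# --------------------------------------------------------------------------
# posterior predictive checks


@dataclass
class PPCReport:
    """Discrepancy p-values for the linear regressions, calibration for CAN."""

    pvalues: dict[str, float]
    calibration: pd.DataFrame
    n_checks: int = field(init=False)

    def __post_init__(self):
        self.n_checks = len(self.pvalues)

    def fraction_central(self, lo: float = 0.05, hi: float = 0.95) -> float:
        vals = np.array(list(self.pvalues.values()))
        return float(np.mean((vals > lo) & (vals < hi)))


def _skew(x: np.ndarray, axis=None) -> np.ndarray:
    mu = np.mean(x, axis=axis, keepdims=True)
    sd = np.std(x, axis=axis, keepdims=True) + 1e-12
    return np.squeeze(np.mean(((x - mu) / sd) ** 3, axis=axis))


def posterior_predictive_check(
    posterior: MediationPosterior,
    *,
    max_draws: int = 200,
    n_bins: int = 10,
    seed: int = 0,
) -> PPCReport:
    """Replicate each regression's data per posterior draw and score discrepancies.

    For LD/TD/FCT: p-values P(T(y_rep) >= T(y)) for T in {mean, sd, skew}.
    For CAN: a log-loss discrepancy p-value plus a reliability table of
    predicted-probability bins against empirical canopy frequency.
    """
    m = posterior.model
    rng = np.random.default_rng(seed)
    total = posterior.n_draws
    idx = np.linspace(0, total - 1, min(max_draws, total)).astype(int)
    flat = {k: v.reshape(total, *v.shape[2:]) for k, v in posterior.draws.items()}

    if m.joint:
        LD = flat["LD"][idx]
        TD = flat["TD"][idx]
    else:
        LD = np.broadcast_to(m.LD_obs, (len(idx), m.n))
        TD = np.broadcast_to(m.TD_obs, (len(idx), m.n))
    FCT_i = flat["fct"][idx][:, m.species_idx]
    FE = m.FE

    pvals: dict[str, float] = {}

    def score(eq: str, y_obs: np.ndarray, mean_rep: np.ndarray, sd_rep: np.ndarray):
        y_rep = mean_rep + sd_rep[:, None] * rng.standard_normal(mean_rep.shape)
        for stat, fn in (("mean", np.mean), ("sd", np.std), ("skew", _skew)):
            t_rep = fn(y_rep, axis=1)
            t_obs = fn(y_obs, axis=-1)
            t_obs = np.atleast_1d(t_obs)
            if t_obs.size == 1:
                pvals[f"{eq}_{stat}"] = float(np.mean(t_rep >= t_obs[0]))
            else:  # observed series varies by draw (imputed responses)
                pvals[f"{eq}_{stat}"] = float(np.mean(t_rep >= t_obs))

    score(
        "LD", LD[0] if not m.joint else LD,
        flat["alpha_L"][idx][:, None] + flat["beta_L"][idx][:, None] * FE,
        flat["sigma_L"][idx],
    )
    score(
        "TD", TD[0] if not m.joint else TD,
        flat["alpha_T"][idx][:, None]
        + flat["beta_T"][idx][:, None] * FE
        + flat["gamma_T"][idx][:, None] * LD,
        flat["sigma_T"][idx],
    )
    score(
        "FCT", FCT_i,
        flat["alpha_F"][idx][:, None] + flat["beta_F"][idx][:, None] * FE,
        flat["sigma_F"][idx],
    )

    # CAN: per-draw probabilities
    psi = (
        flat["alpha_C"][idx][:, None]
        + flat["beta_C"][idx][:, None] * FE
        + flat["lam"][idx][:, None] * LD
        + flat["tau"][idx][:, None] * TD
        + flat["phi"][idx][:, None] * FCT_i
    )
    p = expit(psi)
    eps = 1e-9
    obs_ll = -np.mean(
        m.CAN * np.log(p + eps) + (1 - m.CAN) * np.log(1 - p + eps), axis=1
    )
    can_rep = (rng.uniform(size=p.shape) < p).astype(float)
    rep_ll = -np.mean(
        can_rep * np.log(p + eps) + (1 - can_rep) * np.log(1 - p + eps), axis=1
    )
    pvals["CAN_logloss"] = float(np.mean(rep_ll >= obs_ll))

    pbar = p.mean(axis=0)
    bins = np.clip((pbar * n_bins).astype(int), 0, n_bins - 1)
    calib = pd.DataFrame({"bin": bins, "predicted": pbar, "observed": m.CAN})
    calibration = (
        calib.groupby("bin")
        .agg(predicted_mean=("predicted", "mean"), empirical_freq=("observed", "mean"),
             n=("observed", "size"))
        .reset_index()
    )
    return PPCReport(pvalues=pvals, calibration=calibration)
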