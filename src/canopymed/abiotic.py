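"""Joint state-space model of the 12 hourly abiotic series.

Each habitat×stratum×variable combination — 3 habitats × 2 strata ×
{temperature °C, log light} — is one latent hourly series. A series
follows a diurnal harmonic baseline (first and second harmonics of the
24 h cycle) with AR(1) deviations:

    x_t = b(hour_t) + e_t,   e_t = rho * e_{t-1} + eps_t,
    eps_t ~ Normal(0, sigma_proc^2),  e_0 ~ Normal(0, (3 sigma_proc)^2)

and logger records are noisy measurements ``y ~ Normal(x_t, sigma_obs^2)``.
Series are keyed by habitat type, not site: every logger at any site of
one habitat×stratum informs that habitat's shared series, which is what
makes captures at never-instrumented sites imputable. Hours with no
observation carry latent states with no likelihood term, so missing
values are ordinary parameters of the joint posterior.

Conditional on the series parameters the model is linear-Gaussian, so the
Gibbs sweep samples latent states exactly by forward filtering/backward
sampling (FFBS) and the parameters from their conjugate (or truncated
conjugate) conditionals. External Gaussian pseudo-observations — the
mediation regressions seen through a capture's canopy-minus-understory
contrasts — enter the FFBS update additively, which is how the joint
mediation/missing-data posterior couples to this block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import HABITATS, STRATA
from .errors import ModelSpecError

VARIABLES_ANALYSIS = ("log_light", "temperature_C")

#: fixed enumeration of the 12 latent series
SERIES: list[tuple[str, str, str]] = [
    (h, s, v) for h in HABITATS for s in STRATA for v in VARIABLES_ANALYSIS
]
N_SERIES = len(SERIES)  # 12
_SERIES_INDEX = {key: i for i, key in enumerate(SERIES)}

_HARMONICS = 2
N_BASELINE = 1 + 2 * _HARMONICS
_SD_CAP = 50.0


def series_index(habitat: str, stratum: str, variable: str) -> int:
    try:
        return _SERIES_INDEX[(habitat, stratum, variable)]
    except KeyError as exc:
        raise ModelSpecError(
            f"no abiotic series for {(habitat, stratum, variable)!r}"
        ) from exc


def harmonic_design(hours: np.ndarray) -> np.ndarray:
    """Design matrix [1, cos wh, sin wh, cos 2wh, sin 2wh], w = 2*pi/24."""
    w = 2.0 * np.pi / 24.0
    h = np.asarray(hours, dtype=float)
    return np.column_stack(
        [np.ones_like(h), np.cos(w * h), np.sin(w * h), np.cos(2 * w * h), np.sin(2 * w * h)]
    )


@dataclass(frozen=True)
class AbioticPriors:
    """Broad informative priors on the per-series mean level (logit of nothing:
    plain measurement units). Temperature levels are centred on regional
    records; log-light levels differ by stratum. Artifact defaults,
    config-overridable."""

    temperature_mean: float = 25.0
    temperature_sd: float = 5.0
    log_light_canopy_mean: float = 6.0
    log_light_understory_mean: float = 2.0
    log_light_sd: float = 3.0
    harmonic_sd: float = 10.0

    def mu_prior(self, stratum: str, variable: str) -> tuple[float, float]:
        if variable == "temperature_C":
            return self.temperature_mean, self.temperature_sd
        if stratum == "canopy":
            return self.log_light_canopy_mean, self.log_light_sd
        return self.log_light_understory_mean, self.log_light_sd


@dataclass
class AbioticBlock:
    """Design arrays for the 12-series state space over a fixed hour grid."""

    start: pd.Timestamp
    n_hours: int
    hours_of_day: np.ndarray           # (T,) int hour-of-day
    design: np.ndarray                 # (T, 5) harmonic design
    obs_series: np.ndarray             # (N,) int series index per observation
    obs_t: np.ndarray                  # (N,) int time index
    obs_value: np.ndarray              # (N,) float, analysis scale
    priors: AbioticPriors = field(default_factory=AbioticPriors)

    def timestamp_to_t(self, timestamps: pd.Series) -> np.ndarray:
        t = ((pd.to_datetime(timestamps) - self.start) / pd.Timedelta(hours=1)).astype(int)
        t = np.asarray(t)
        if np.any((t < 0) | (t >= self.n_hours)):
            raise ModelSpecError("timestamp outside the state-space hour grid")
        return t


def build_state_space(
    state: pd.DataFrame,
    *,
    priors: AbioticPriors | None = None,
    span: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> AbioticBlock:
    """Assemble the state-space block from an analysis-scale observation table.

    ``state`` is the tidy frame produced by
    :func:`canopymed.data_io.loggers_to_state` (columns habitat, stratum,
    variable, timestamp, value; light already log transformed). ``span``
    widens the latent grid beyond the observed range, e.g. to cover
    capture hours.
    """
    priors = priors or AbioticPriors()
    bad = ~state["variable"].isin(VARIABLES_ANALYSIS)
    if bad.any():
        raise ModelSpecError(
            f"observation maps to no series: variable {state.loc[bad.idxmax(), 'variable']!r} "
            "(expected analysis-scale names; light must be log transformed first)"
        )
    ts = pd.to_datetime(state["timestamp"])
    start = ts.min() if span is None else min(ts.min(), pd.Timestamp(span[0]))
    end = ts.max() if span is None else max(ts.max(), pd.Timestamp(span[1]))
    start = start.floor("h")
    n_hours = int((end.ceil("h") - start) / pd.Timedelta(hours=1)) + 1
    grid = start + pd.to_timedelta(np.arange(n_hours), unit="h")
    hours_of_day = grid.hour.to_numpy()

    obs_series = np.array(
        [series_index(h, s, v) for h, s, v in zip(state["habitat"], state["stratum"], state["variable"])],
        dtype=int,
    )
    obs_t = ((ts - start) / pd.Timedelta(hours=1)).astype(int).to_numpy()
    return AbioticBlock(
        start=start,
        n_hours=n_hours,
        hours_of_day=hours_of_day,
        design=harmonic_design(hours_of_day),
        obs_series=obs_series,
        obs_t=obs_t,
        obs_value=state["value"].to_numpy(dtype=float),
        priors=priors,
    )


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b))
    u = min(max(u, 1e-12), 1 - 1e-12)
    return mean + sd * stats.norm.ppf(u)


def _inv_gamma_sd(rng: np.random.Generator, sum_sq: float, n_terms: float, floor: float = 1e-4) -> float:
    """Draw sigma from the flat-on-sigma conditional: sigma^2 ~ IG((n-1)/2, SS/2)."""
    shape = max((n_terms - 1.0) / 2.0, 0.5)
    rate = sum_sq / 2.0 + 1e-12
    for _ in range(100):
        var = rate / rng.gamma(shape)
        sd = float(np.sqrt(var))
        if sd <= _SD_CAP:
            return max(sd, floor)
    return _SD_CAP


class AbioticGibbs:
    """Gibbs machinery for the abiotic block (standalone or inside the joint model).

    State per chain: latent matrix ``X`` (12, T), baseline coefficients
    ``beta`` (12, 5), AR coefficients ``rho``, process and observation
    sds. The sweep optionally accepts external per-(series, t) Gaussian
    pseudo-observations as precision / precision-times-mean arrays.
    """

    def __init__(
        self,
        block: AbioticBlock,
        rng: np.random.Generator,
        *,
        fix_sigma_obs: float | None = None,
    ):
        self.block = block
        self.rng = rng
        self.fix_sigma_obs = fix_sigma_obs
        T, S = block.n_hours, N_SERIES
        pr = block.priors
        self.beta = np.zeros((S, N_BASELINE))
        self.rho = np.full(S, 0.6)
        self.sig_proc = np.full(S, 1.0)
        self.sig_obs = np.full(S, fix_sigma_obs if fix_sigma_obs is not None else 0.5)
        self._obs_by_series = [np.flatnonzero(block.obs_series == s) for s in range(S)]
        for s, (h, strat, var) in enumerate(SERIES):
            m0, _ = pr.mu_prior(strat, var)
            self.beta[s, 0] = m0
            idx = self._obs_by_series[s]
            if idx.size:
                self.beta[s, 0] = float(np.mean(block.obs_value[idx]))
        self.X = self.beta @ block.design.T  # (S, T) start at baseline
        self.rho += rng.uniform(-0.1, 0.1, size=S)
        self.X += rng.normal(0.0, 0.1, size=self.X.shape)

    # -- likelihood-side helpers -------------------------------------------------

    def obs_precisions(self) -> tuple[np.ndarray, np.ndarray]:
        """Logger contributions: per-(series, t) precision and precision*mean."""
        T, S = self.block.n_hours, N_SERIES
        prec = np.zeros((S, T))
        pm = np.zeros((S, T))
        w = 1.0 / self.sig_obs[self.block.obs_series] ** 2
        np.add.at(prec, (self.block.obs_series, self.block.obs_t), w)
        np.add.at(pm, (self.block.obs_series, self.block.obs_t), w * self.block.obs_value)
        return prec, pm

    def ffbs_series(self, s: int, prec: np.ndarray, pm: np.ndarray) -> None:
        """Sample series ``s`` exactly given its parameters and Gaussian obs."""
        T = self.block.n_hours
        b = self.block.design @ self.beta[s]
        rho, q = self.rho[s], self.sig_proc[s] ** 2
        # deviations e = x - b; observation info on e
        obs_prec = prec[s]
        obs_pm = pm[s] - obs_prec * b
        m = np.empty(T)
        P = np.empty(T)
        mp_arr = np.empty(T)
        Pp_arr = np.empty(T)
        mp, Pp = 0.0, 9.0 * q
        for t in range(T):
            if t > 0:
                mp = rho * m[t - 1]
                Pp = rho * rho * P[t - 1] + q
            mp_arr[t], Pp_arr[t] = mp, Pp
            post_prec = 1.0 / Pp + obs_prec[t]
            P[t] = 1.0 / post_prec
            m[t] = P[t] * (mp / Pp + obs_pm[t])
        e = np.empty(T)
        z = self.rng.standard_normal(T)
        e[T - 1] = m[T - 1] + np.sqrt(P[T - 1]) * z[T - 1]
        for t in range(T - 2, -1, -1):
            Pp_next = rho * rho * P[t] + q
            J = P[t] * rho / Pp_next
            mean = m[t] + J * (e[t + 1] - rho * m[t])
            var = P[t] - J * rho * P[t]
            e[t] = mean + np.sqrt(max(var, 1e-12)) * z[t]
        self.X[s] = b + e

    def update_params_series(self, s: int) -> None:
        blk, rng = self.block, self.rng
        T = blk.n_hours
        x = self.X[s]
        B = blk.design
        rho, q = self.rho[s], self.sig_proc[s] ** 2
        h, strat, var = SERIES[s]
        m0, sd0 = blk.priors.mu_prior(strat, var)

        # baseline coefficients (quasi-differenced regression, conjugate normal)
        Xd = np.vstack([B[0] / 3.0, B[1:] - rho * B[:-1]])
        yd = np.concatenate([[x[0] / 3.0], x[1:] - rho * x[:-1]])
        prior_prec = np.diag(
            [1.0 / sd0**2] + [1.0 / blk.priors.harmonic_sd**2] * (N_BASELINE - 1)
        )
        prior_mean = np.array([m0] + [0.0] * (N_BASELINE - 1))
        A = Xd.T @ Xd / q + prior_prec
        rhs = Xd.T @ yd / q + prior_prec @ prior_mean
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, rhs)
        self.beta[s] = mean + np.linalg.solve(L.T, rng.standard_normal(N_BASELINE))

        # AR coefficient (truncated normal conditional)
        b = B @ self.beta[s]
        e = x - b
        den = float(np.sum(e[:-1] ** 2))
        if den > 1e-8:
            mean_r = float(np.sum(e[:-1] * e[1:])) / den
            sd_r = float(np.sqrt(q / den))
            self.rho[s] = _trunc_normal(rng, mean_r, sd_r, -0.995, 0.995)

        # process sd (initial deviation enters with its 3x inflation)
        eps = e[1:] - self.rho[s] * e[:-1]
        ss = float(np.sum(eps**2) + e[0] ** 2 / 9.0)
        self.sig_proc[s] = _inv_gamma_sd(rng, ss, T)

        # observation sd, only when estimated and the series has enough data
        idx = self._obs_by_series[s]
        if self.fix_sigma_obs is None and idx.size >= 3:
            r = blk.obs_value[idx] - x[blk.obs_t[idx]]
            self.sig_obs[s] = _inv_gamma_sd(rng, float(np.sum(r**2)), idx.size, floor=1e-3)

    def sweep(self, extra: tuple[np.ndarray, np.ndarray] | None = None) -> None:
        """One full Gibbs sweep: states by FFBS, then per-series parameters.

        ``extra`` carries (precision, precision*mean) arrays of shape
        (12, T) with the mediation-side pseudo-observations; the caller
        must refresh them between sweeps because they depend on the other
        series' current states.
        """
        prec, pm = self.obs_precisions()
        if extra is not None:
            prec = prec + extra[0]
            pm = pm + extra[1]
        for s in range(N_SERIES):
            self.ffbs_series(s, prec, pm)
        for s in range(N_SERIES):
            self.update_params_series(s)


@dataclass
class AbioticPosterior:
    """Posterior draws from a standalone abiotic fit."""

    block: AbioticBlock
    states: np.ndarray      # (chains, draws, 12, T)
    mu: np.ndarray          # (chains, draws, 12) baseline levels
    rho: np.ndarray
    sig_proc: np.ndarray
    sig_obs: np.ndarray

    def state_mean(self) -> np.ndarray:
        return self.states.mean(axis=(0, 1))

    def state_summary_frame(self) -> pd.DataFrame:
        mean = self.state_mean()
        sd = self.states.std(axis=(0, 1))
        rows = []
        for s, (h, strat, var) in enumerate(SERIES):
            for t in range(self.block.n_hours):
                rows.append((h, strat, var, t, mean[s, t], sd[s, t]))
        return pd.DataFrame(
            rows, columns=["habitat", "stratum", "variable", "t", "mean", "sd"]
        )

    def impute_LD_TD(self, captures: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Per-draw LD/TD contrasts for each capture; shape (total draws, n)."""
        t_idx = self.block.timestamp_to_t(captures["timestamp"])
        flat = self.states.reshape(-1, N_SERIES, self.block.n_hours)
        lc = np.array([series_index(h, "canopy", "log_light") for h in captures["habitat"]])
        lu = np.array([series_index(h, "understory", "log_light") for h in captures["habitat"]])
        tc = np.array([series_index(h, "canopy", "temperature_C") for h in captures["habitat"]])
        tu = np.array([series_index(h, "understory", "temperature_C") for h in captures["habitat"]])
        LD = flat[:, lc, t_idx] - flat[:, lu, t_idx]
        TD = flat[:, tc, t_idx] - flat[:, tu, t_idx]
        return LD, TD


def fit_abiotic(
    block: AbioticBlock,
    *,
    chains: int = 2,
    warmup: int = 300,
    draws: int = 300,
    seed: int = 0,
    fix_sigma_obs: float | None = None,
) -> AbioticPosterior:
    """Standalone Gibbs fit of the abiotic block (no capture coupling)."""
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(chains)
    T = block.n_hours
    states = np.empty((chains, draws, N_SERIES, T))
    mu = np.empty((chains, draws, N_SERIES))
    rho = np.empty((chains, draws, N_SERIES))
    sig_proc = np.empty((chains, draws, N_SERIES))
    sig_obs = np.empty((chains, draws, N_SERIES))
    for c in range(chains):
        rng = np.random.default_rng(child_seeds[c])
        gibbs = AbioticGibbs(block, rng, fix_sigma_obs=fix_sigma_obs)
        for _ in range(warmup):
            gibbs.sweep()
        for d in range(draws):
            gibbs.sweep()
            states[c, d] = gibbs.X
            mu[c, d] = gibbs.beta[:, 0]
            rho[c, d] = gibbs.rho
            sig_proc[c, d] = gibbs.sig_proc
            sig_obs[c, d] = gibbs.sig_obs
    return AbioticPosterior(
        block=block, states=states, mu=mu, rho=rho, sig_proc=sig_proc, sig_obs=sig_obs
    )
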