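"""Potential-outcomes effect decomposition on the mediation posterior.

Effects are contrasts of expected canopy probability under counterfactual
settings of the exposure and the mediators, written CAN(a, LD(a_L),
TD(a_T, LD(a_TL)), FCT(a_F)) with every mediator argument explicit. The
five reported effects arise from one telescoping sequence of settings:

    S0 = (0, LD(0), TD(0, LD(0)), FCT(0))
    S1 = (1, LD(0), TD(0, LD(0)), FCT(0))   NDE          = E[S1] - E[S0]
    S2 = (1, LD(1), TD(0, LD(0)), FCT(0))   light effect = E[S2] - E[S1]
    S3 = (1, LD(1), TD(1, LD(1)), FCT(0))   temp effect  = E[S3] - E[S2]
    S4 = (1, LD(1), TD(1, LD(1)), FCT(1))   SCE          = E[S4] - E[S3]

    TCE = E[S4] - E[S0],   edge effect = TCE - SCE.

Expectations over the mediator distributions are Monte Carlo averages
with common random numbers: one set of base normals (z_L, z_T, z_F) per
Monte Carlo replicate is reused across all five settings, so the
telescoping identity NDE + light + temperature + SCE = TCE holds to
floating-point rounding in every posterior draw, and the contrasts have
sharply reduced Monte Carlo variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConvergenceError, ValidationError
from .mediation import MediationCoefficients, MediationPosterior, expit

EFFECT_NAMES = ["light_effect", "temperature_effect", "SCE", "NDE", "TCE", "edge_effect"]


@dataclass(frozen=True)
class CounterfactualSetting:
    """Explicit mediator arguments for one expected-canopy evaluation.

    ``a`` is the exposure entering the outcome equation directly; ``a_L``
    the exposure generating LD; ``a_T`` the exposure in TD's own
    equation; ``a_TL`` the exposure of the LD draw that feeds TD; ``a_F``
    the exposure generating FCT. No defaults: every argument must be
    chosen deliberately.
    """

    a: int
    a_L: int
    a_T: int
    a_TL: int
    a_F: int

    def __post_init__(self):
        for f in ("a", "a_L", "a_T", "a_TL", "a_F"):
            if getattr(self, f) not in (0, 1):
                raise ValidationError(f"counterfactual argument {f} must be 0 or 1")


#: the telescoping sequence S0..S4 (module docstring)
TELESCOPE = [
    CounterfactualSetting(0, 0, 0, 0, 0),
    CounterfactualSetting(1, 0, 0, 0, 0),
    CounterfactualSetting(1, 1, 0, 0, 0),
    CounterfactualSetting(1, 1, 1, 1, 0),
    CounterfactualSetting(1, 1, 1, 1, 1),
]


def simulate_mediators(
    coeffs: MediationCoefficients,
    a_L: int,
    a_T: int,
    K: int,
    rng: np.random.Generator,
    *,
    a_TL: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """K draws of (LD, TD) under the given mediator exposures.

    The LD value entering the TD equation is drawn under ``a_TL``
    (defaulting to ``a_L``) using the same base normal as the LD draw
    itself — common random numbers across counterfactual settings.
    """
    if K < 1:
        raise ValidationError("K must be >= 1")
    if a_TL is None:
        a_TL = a_L
    zL = rng.standard_normal(K)
    zT = rng.standard_normal(K)
    LD = coeffs.alpha_L + coeffs.beta_L * a_L + coeffs.sigma_L * zL
    LD_for_TD = coeffs.alpha_L + coeffs.beta_L * a_TL + coeffs.sigma_L * zL
    TD = (
        coeffs.alpha_T + coeffs.beta_T * a_T + coeffs.gamma_T * LD_for_TD
        + coeffs.sigma_T * zT
    )
    return LD, TD


def _setting_probability(
    coeffs: MediationCoefficients,
    setting: CounterfactualSetting,
    zL: np.ndarray,
    zT: np.ndarray,
    zF: np.ndarray,
) -> float:
    """Mean canopy probability for one setting given shared base normals."""
    LD = coeffs.alpha_L + coeffs.beta_L * setting.a_L + coeffs.sigma_L * zL
    LD_for_TD = coeffs.alpha_L + coeffs.beta_L * setting.a_TL + coeffs.sigma_L * zL
    TD = (
        coeffs.alpha_T + coeffs.beta_T * setting.a_T + coeffs.gamma_T * LD_for_TD
        + coeffs.sigma_T * zT
    )
    FCT = coeffs.alpha_F + coeffs.beta_F * setting.a_F + coeffs.sigma_F * zF
    psi = (
        coeffs.alpha_C + coeffs.beta_C * setting.a
        + coeffs.lam * LD + coeffs.tau * TD + coeffs.phi * FCT
    )
    return float(np.mean(expit(psi)))


def expected_canopy(
    coeffs: MediationCoefficients,
    setting: CounterfactualSetting,
    population_size: int,
    K: int,
    rng: np.random.Generator,
) -> float:
    """Monte Carlo E{CAN(setting)} over ``population_size * K`` mediator draws.

    Every covariate role of the reference population is replaced by a
    counterfactual draw, so the population only fixes the number of Monte
    Carlo replicates per posterior draw.
    """
    if population_size < 1:
        raise ValidationError("population must be nonempty")
    M = population_size * K
    zL, zT, zF = (rng.standard_normal(M) for _ in range(3))
    return _setting_probability(coeffs, setting, zL, zT, zF)


@dataclass
class EffectEstimates:
    """Per-draw effect values and posterior summaries."""

    draws: pd.DataFrame          # one row per posterior draw, EFFECT_NAMES columns
    K: int
    seed: int
    n_population: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in EFFECT_NAMES:
            v = self.draws[name].to_numpy()
            rows.append(
                {
                    "effect": name,
                    "mean": v.mean(),
                    "q25": np.quantile(v, 0.25),
                    "q75": np.quantile(v, 0.75),
                    "q2.5": np.quantile(v, 0.025),
                    "q97.5": np.quantile(v, 0.975),
                }
            )
        return pd.DataFrame(rows).set_index("effect")

    def to_dict(self) -> dict:
        s = self.summary()
        return {
            "K": self.K,
            "seed": self.seed,
            "n_population": self.n_population,
            "effects": {
                name: {
                    "mean": float(s.loc[name, "mean"]),
                    "ci50": [float(s.loc[name, "q25"]), float(s.loc[name, "q75"])],
                    "ci95": [float(s.loc[name, "q2.5"]), float(s.loc[name, "q97.5"])],
                }
                for name in EFFECT_NAMES
            },
        }


def decompose_coefficients(
    coeffs: MediationCoefficients,
    *,
    M: int,
    rng: np.random.Generator,
) -> dict[str, float]:
    """One telescoping pass at a single parameter vector with M CRN replicates."""
    zL, zT, zF = (rng.standard_normal(M) for _ in range(3))
    p = [_setting_probability(coeffs, s, zL, zT, zF) for s in TELESCOPE]
    out = {
        "NDE": p[1] - p[0],
        "light_effect": p[2] - p[1],
        "temperature_effect": p[3] - p[2],
        "SCE": p[4] - p[3],
        "TCE": p[4] - p[0],
    }
    out["edge_effect"] = out["TCE"] - out["SCE"]
    return out


def effect_decomposition(
    posterior: MediationPosterior,
    *,
    population_size: int | None = None,
    K: int = 1000,
    seed: int = 0,
    max_draws: int | None = None,
    force: bool = False,
) -> EffectEstimates:
    """Compute the five effects (plus TCE-derived edge effect) per posterior draw.

    Refuses a non-converged posterior unless ``force``; ``max_draws``
    thins the posterior evenly for speed. Base normals are redrawn per
    posterior draw from a seeded stream, shared across the five settings
    of that draw (common random numbers).
    """
    if not posterior.converged and not force:
        raise ConvergenceError(
            "posterior failed its convergence gate; pass force=True to "
            "decompose anyway"
        )
    n_pop = population_size or max(posterior.model.n, 1)
    total = posterior.n_draws
    idx = (
        np.arange(total)
        if max_draws is None or max_draws >= total
        else np.linspace(0, total - 1, max_draws).astype(int)
    )
    rng = np.random.default_rng(seed)
    M = n_pop * K
    records = []
    for flat_i in idx:
        coeffs = posterior.coefficients(int(flat_i))
        records.append(decompose_coefficients(coeffs, M=M, rng=rng))
    draws = pd.DataFrame.from_records(records, columns=EFFECT_NAMES)
    return EffectEstimates(draws=draws, K=K, seed=seed, n_population=n_pop)
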