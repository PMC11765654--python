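"""Species-level forest canopy tendency (FCT): informative priors and tribe hierarchy.

FCT is a species trait on the logit scale: the baseline tendency of a
species to occur in the canopy. For species whose canopy probability was
estimated in earlier work, a normal prior on the logit scale is obtained
by least-squares fitting a normal distribution to logit-transformed
posterior quantiles of canopy probability. Species absent from the prior
table (e.g. whole genera never scored) are imputed hierarchically by
tribe: their FCT is drawn from a tribe-level normal whose mean and sd get
weakly-informative hyperpriors, so taxonomic relatives share information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logit

from .errors import ModelSpecError, ValidationError

#: hyperprior defaults on the logit scale
TRIBE_MEAN_PRIOR_SD = 2.5
TRIBE_SD_PRIOR_SCALE = 1.5

FCT_PRIOR_COLUMNS = ["species", "tribe", "logit_mean", "logit_sd"]


class LogitNormalFit(NamedTuple):
    logit_mean: float
    logit_sd: float
    rss: float


def fit_logit_normal_from_quantiles(
    quantile_pairs: Sequence[tuple[float, float]]
) -> LogitNormalFit:
    """Least-squares normal fit to logit-transformed quantiles.

    ``quantile_pairs`` are (probability, canopy-probability-value) pairs
    from a posterior distribution on (0, 1). On the logit scale a normal
    with mean mu and sd sigma has quantile ``mu + sigma * z_p``, so the
    fit is linear least squares of logit(value) on the standard normal
    quantile z_p. Returns the fitted (mu, sigma) and the residual sum of
    squares of the quantile fit.
    """
    if len(quantile_pairs) < 2:
        raise ValidationError("need at least two quantile pairs")
    probs = np.array([p for p, _ in quantile_pairs], dtype=float)
    values = np.array([v for _, v in quantile_pairs], dtype=float)
    if np.any(np.diff(probs) <= 0) or np.any((probs <= 0) | (probs >= 1)):
        raise ValidationError("quantile probabilities must be strictly increasing in (0,1)")
    if np.any((values <= 0) | (values >= 1)):
        raise ValidationError("quantile values at 0 or 1 have no logit")
    z = stats.norm.ppf(probs)
    y = logit(values)
    X = np.column_stack([np.ones_like(z), z])
    coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    mu, sigma = float(coef[0]), float(coef[1])
    if sigma <= 0:
        raise ValidationError("fitted logit sd is non-positive; quantiles are not increasing")
    rss = float(res[0]) if res.size else float(np.sum((X @ coef - y) ** 2))
    return LogitNormalFit(mu, sigma, rss)


def read_fct_priors(path) -> pd.DataFrame:
    """Read the species prior table (species,tribe,logit_mean,logit_sd).

    Species without priors are simply absent; the hierarchy imputes them.
    """
    df = pd.read_csv(path)
    missing = [c for c in FCT_PRIOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"fct prior table missing column(s) {missing}")
    df["logit_mean"] = df["logit_mean"].astype(float)
    df["logit_sd"] = df["logit_sd"].astype(float)
    if (df["logit_sd"] <= 0).any():
        raise ValidationError("logit_sd must be > 0")
    if df["species"].duplicated().any():
        raise ValidationError("duplicate species in fct prior table")
    return df.reset_index(drop=True)


@dataclass
class FCTBlock:
    """Per-species prior arrays for the joint sampler.

    Species order is fixed; ``has_prior`` marks species with a
    prior-study normal, the rest are imputed from their tribe's
    hyperdistribution.
    """

    species: list[str]
    tribes: list[str]
    tribe_idx: np.ndarray       # (S,) index into tribes
    has_prior: np.ndarray       # (S,) bool
    prior_mean: np.ndarray      # (S,) logit_mean (0 where imputed)
    prior_sd: np.ndarray        # (S,) logit_sd (inf where imputed)
    tribe_mean_prior_sd: float = TRIBE_MEAN_PRIOR_SD
    tribe_sd_prior_scale: float = TRIBE_SD_PRIOR_SCALE

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_tribes(self) -> int:
        return len(self.tribes)


def build_fct_block(
    captures: pd.DataFrame, priors: pd.DataFrame | None = None
) -> FCTBlock:
    """Assemble the FCT hierarchy for every species in the capture table.

    Every capture's species must map to exactly one tribe; a species with
    conflicting tribes across rows is rejected. Species present in the
    prior table get their informative normal; the rest are flagged for
    tribe-level imputation.
    """
    sp_tribe = captures[["species", "tribe"]].drop_duplicates()
    conflict = sp_tribe["species"].duplicated()
    if conflict.any():
        raise ModelSpecError(
            f"species {sp_tribe.loc[conflict.idxmax(), 'species']!r} maps to multiple tribes"
        )
    bad_tribe = sp_tribe["tribe"].isin(["", "nan"]) | sp_tribe["tribe"].isna()
    if bad_tribe.any():
        raise ModelSpecError(
            f"species {sp_tribe.loc[bad_tribe.idxmax(), 'species']!r} has unknown tribe"
        )
    sp_tribe = sp_tribe.sort_values("species").reset_index(drop=True)
    species = sp_tribe["species"].tolist()
    tribes = sorted(sp_tribe["tribe"].unique())
    tribe_pos = {t: i for i, t in enumerate(tribes)}
    tribe_idx = np.array([tribe_pos[t] for t in sp_tribe["tribe"]], dtype=int)

    S = len(species)
    has_prior = np.zeros(S, dtype=bool)
    prior_mean = np.zeros(S)
    prior_sd = np.full(S, np.inf)
    if priors is not None and len(priors):
        lut = priors.set_index("species")
        for i, sp in enumerate(species):
            if sp in lut.index:
                has_prior[i] = True
                prior_mean[i] = float(lut.loc[sp, "logit_mean"])
                prior_sd[i] = float(lut.loc[sp, "logit_sd"])
    return FCTBlock(
        species=species,
        tribes=tribes,
        tribe_idx=tribe_idx,
        has_prior=has_prior,
        prior_mean=prior_mean,
        prior_sd=prior_sd,
    )
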