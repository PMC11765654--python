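"""Tabular I/O, the light transformation, capture/abiotic alignment, hourly summaries.

All tables are pandas DataFrames with fixed column sets; readers validate
closed vocabularies (habitat, stratum, variable) and key uniqueness and
raise :class:`~canopymed.errors.ParseError` / ``ValidationError`` with the
offending CSV line where possible.

Conventions: comma-separated UTF-8 CSV with a mandatory header row,
ISO-8601 timestamps in local time, hour-of-day buckets ``[h, h+1)``.
Light is analysed on the natural-log scale as ``ln(lux + offset)`` with a
default offset of 1.0 so that zero lux (night) maps to 0.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger("canopymed")

HABITATS = ("edge", "ridge", "valley")
STRATA = ("canopy", "understory")
VARIABLES = ("temperature_C", "light_lux")

#: analysis-scale variable names (light is log transformed)
ANALYSIS_VARIABLES = ("temperature_C", "log_light")

CAPTURE_COLUMNS = [
    "individual_id",
    "timestamp",
    "site_id",
    "habitat",
    "stratum",
    "species",
    "tribe",
]
LOGGER_COLUMNS = ["timestamp", "site_id", "stratum", "variable", "value"]
SITE_COLUMNS = ["site_id", "habitat", "canopy_height_m", "understory_height_m"]
SUMMARY_COLUMNS = [
    "habitat",
    "stratum",
    "variable",
    "hour",
    "mean",
    "ci_half_width",
    "n",
]

DEFAULT_CAPTURE_HOUR = 12
DEFAULT_LIGHT_OFFSET = 1.0


def fe_indicator(habitat) -> np.ndarray:
    """Forest-edge indicator: 1 at edge sites, 0 at ridge/valley (forest) sites."""
    arr = np.asarray(habitat)
    return (arr == "edge").astype(int)


def can_indicator(stratum) -> np.ndarray:
    """Canopy-capture indicator: 1 for canopy traps, 0 for understory traps."""
    arr = np.asarray(stratum)
    return (arr == "canopy").astype(int)


def _read_csv(path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # header/encoding level failure
        raise ParseError(f"could not read {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}", line=1)
    return df[columns]


def _parse_timestamps(raw: pd.Series, *, default_hour: int | None = None) -> pd.Series:
    ts = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    bad = ts.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise ParseError(f"unparseable ISO-8601 timestamp {raw[bad.idxmax()]!r}", line=line)
    if default_hour is not None:
        dateonly = ~raw.str.contains("T") & ~raw.str.contains(" ")
        if dateonly.any():
            logger.warning(
                "%d capture timestamp(s) have day resolution; assigning "
                "representative hour %02d:00",
                int(dateonly.sum()),
                default_hour,
            )
            ts = ts.where(~dateonly, ts + pd.Timedelta(hours=default_hour))
    return ts.dt.floor("h")


def _check_enum(df: pd.DataFrame, col: str, allowed: tuple[str, ...]) -> None:
    bad = ~df[col].isin(allowed)
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise ValidationError(
            f"unknown {col} {df.loc[bad.idxmax(), col]!r} (line {line}); "
            f"allowed: {allowed}"
        )


def read_captures(path, *, default_hour: int = DEFAULT_CAPTURE_HOUR) -> pd.DataFrame:
    """Read a capture table (one row per unique marked individual).

    Day-resolution timestamps are assigned the representative hour
    ``default_hour`` (trap checks have day resolution; the assumption is
    logged and propagates to LD/TD construction).
    """
    df = _read_csv(path, CAPTURE_COLUMNS)
    df["timestamp"] = _parse_timestamps(df["timestamp"], default_hour=default_hour)
    _check_enum(df, "habitat", HABITATS)
    _check_enum(df, "stratum", STRATA)
    dup = df["individual_id"].duplicated()
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise ValidationError(
            f"duplicate individual_id {df.loc[dup.idxmax(), 'individual_id']!r} "
            f"(line {line}); recaptures must be excluded upstream"
        )
    return df.reset_index(drop=True)


def read_loggers(path) -> pd.DataFrame:
    """Read hourly logger records (temperature °C / light lux), with gaps allowed."""
    df = _read_csv(path, LOGGER_COLUMNS)
    df["timestamp"] = _parse_timestamps(df["timestamp"])
    _check_enum(df, "stratum", STRATA)
    _check_enum(df, "variable", VARIABLES)
    try:
        df["value"] = df["value"].astype(float)
    except ValueError as exc:
        raise ParseError(f"non-numeric logger value: {exc}") from exc
    neg = (df["variable"] == "light_lux") & (df["value"] < 0)
    if neg.any():
        line = int(neg.idxmax()) + 2
        raise ValidationError(f"negative light_lux value (line {line})")
    key = ["timestamp", "site_id", "stratum", "variable"]
    dup = df.duplicated(subset=key)
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise ValidationError(f"duplicate logger record for key {key} (line {line})")
    return df.reset_index(drop=True)


def read_sites(path) -> pd.DataFrame:
    """Read the site table: one paired canopy/understory trap site per row."""
    df = _read_csv(path, SITE_COLUMNS)
    _check_enum(df, "habitat", HABITATS)
    dup = df["site_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"duplicate site_id {df.loc[dup.idxmax(), 'site_id']!r}"
        )
    for col in ("canopy_height_m", "understory_height_m"):
        df[col] = df[col].astype(float)
    return df.reset_index(drop=True)


def write_table(df: pd.DataFrame, path) -> None:
    """Write any pipeline table as CSV (ISO timestamps, no index)."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def log_transform_light(lux, offset: float = DEFAULT_LIGHT_OFFSET):
    """Natural-log light transform ``ln(lux + offset)``.

    Light filtered multiplicatively through vegetation is approximately
    lognormal and insect photoreception follows the Weber–Fechner law, so
    the analysis operates on log light. The additive offset (default 1.0,
    recorded in run metadata) keeps night-time zero lux finite.
    """
    if offset <= 0:
        raise ValidationError("light offset must be > 0")
    arr = np.asarray(lux, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("negative lux is outside the domain of the light transform")
    out = np.log(arr + offset)
    return float(out) if np.isscalar(lux) or arr.ndim == 0 else out


def validate_site_consistency(captures: pd.DataFrame, sites: pd.DataFrame) -> None:
    """Every capture's site must appear in the site table with matching habitat."""
    merged = captures.merge(
        sites[["site_id", "habitat"]], on="site_id", how="left", suffixes=("", "_site")
    )
    unknown = merged["habitat_site"].isna()
    if unknown.any():
        raise ValidationError(
            f"capture site_id {merged.loc[unknown.idxmax(), 'site_id']!r} "
            "not in site table"
        )
    mismatch = merged["habitat"] != merged["habitat_site"]
    if mismatch.any():
        raise ValidationError(
            f"capture habitat disagrees with site table for site_id "
            f"{merged.loc[mismatch.idxmax(), 'site_id']!r}"
        )


def loggers_to_state(
    loggers: pd.DataFrame,
    sites: pd.DataFrame,
    *,
    light_offset: float = DEFAULT_LIGHT_OFFSET,
    by: str = "habitat",
) -> pd.DataFrame:
    """Collapse logger records to an observed abiotic state table.

    Returns a tidy frame ``<by>, stratum, variable, timestamp, value`` on
    the analysis scale (light log transformed, variable renamed
    ``log_light``). With ``by="habitat"`` (default) sites of one habitat
    are averaged into a shared habitat-level series; ``by="site_id"``
    keeps per-site series, in which case captures at never-instrumented
    sites cannot be matched and come out flagged missing.
    """
    if by not in ("habitat", "site_id"):
        raise ValidationError("by must be 'habitat' or 'site_id'")
    df = loggers.merge(sites[["site_id", "habitat"]], on="site_id", how="left")
    if df["habitat"].isna().any():
        raise ValidationError("logger record at a site_id missing from the site table")
    is_light = df["variable"] == "light_lux"
    df.loc[is_light, "value"] = log_transform_light(
        df.loc[is_light, "value"].to_numpy(), light_offset
    )
    df.loc[is_light, "variable"] = "log_light"
    state = (
        df.groupby([by, "stratum", "variable", "timestamp"], as_index=False)["value"]
        .mean()
    )
    return state


def attach_abiotic(captures: pd.DataFrame, state: pd.DataFrame) -> pd.DataFrame:
    """Attach per-capture canopy-minus-understory abiotic contrasts.

    ``LD`` is the log-light difference and ``TD`` the temperature difference
    between canopy and understory at the capture hour, matched on habitat
    (or on site when the state table is site-level). Unresolvable
    contrasts are flagged missing (NaN), never dropped — downstream the
    joint model imputes them.
    """
    key = "site_id" if "site_id" in state.columns else "habitat"
    wide = state.pivot_table(
        index=[key, "timestamp"],
        columns=["variable", "stratum"],
        values="value",
        aggfunc="mean",
    )

    def contrast(var: str) -> pd.Series:
        try:
            c = wide[(var, "canopy")]
            u = wide[(var, "understory")]
        except KeyError:
            return pd.Series(np.nan, index=wide.index)
        return c - u

    diffs = pd.DataFrame(
        {"LD": contrast("log_light"), "TD": contrast("temperature_C")}
    ).reset_index()
    out = captures.merge(diffs, on=[key, "timestamp"], how="left")
    n_missing = int(out["LD"].isna().sum() + out["TD"].isna().sum())
    if n_missing:
        logger.warning(
            "%d capture abiotic contrast value(s) unresolvable from the observed "
            "state; flagged missing for joint imputation",
            n_missing,
        )
    return out


def hourly_summary(
    loggers: pd.DataFrame,
    sites: pd.DataFrame,
    *,
    light_offset: float = DEFAULT_LIGHT_OFFSET,
    transform_light: bool = True,
) -> pd.DataFrame:
    """Hour-of-day means with 95% CI half-widths per habitat×stratum×variable.

    The CI half-width is ``1.96·sd/√n``; single-observation cells report a
    half-width of 0 and are flagged in the log. Empty cells are simply
    absent from the output. With ``transform_light`` the light variable is
    summarised on the analysis (log) scale and labelled ``log_light``.
    """
    df = loggers.merge(sites[["site_id", "habitat"]], on="site_id", how="left")
    if transform_light:
        is_light = df["variable"] == "light_lux"
        df.loc[is_light, "value"] = log_transform_light(
            df.loc[is_light, "value"].to_numpy(), light_offset
        )
        df.loc[is_light, "variable"] = "log_light"
    df["hour"] = df["timestamp"].dt.hour
    grouped = df.groupby(["habitat", "stratum", "variable", "hour"])["value"]
    summary = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    singletons = summary["n"] == 1
    if singletons.any():
        logger.warning(
            "%d hourly summary cell(s) have a single observation; CI half-width "
            "reported as 0",
            int(singletons.sum()),
        )
    summary["sd"] = summary["sd"].fillna(0.0)
    summary["ci_half_width"] = 1.96 * summary["sd"] / np.sqrt(summary["n"])
    return summary[SUMMARY_COLUMNS]
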