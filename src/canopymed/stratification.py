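"""Canopy probabilities, the delta-edge index, sensitivity filters, and the sign G-test.

The question: do more species than expected by chance show a *decreased*
canopy probability at forest edges? For each species common to edge and
forest we compute the canopy probability (canopy captures / total
captures) in each habitat class and the delta-edge index

    delta_edge = forest canopy probability − edge canopy probability,

positive when a species descends toward the understory at the edge.
Under the no-pattern null, positive and non-positive delta-edge values
are equally likely, which a two-cell likelihood-ratio G-test against a
50:50 expectation evaluates (ties — delta_edge exactly 0 — count as
non-positive, a conservative convention).

Two sensitivity filters are provided: dropping obligate understory
genera (Caligo, Eryphanis, Taygetis), and requiring at least three
individuals in each habitat class.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

UNDERSTORY_GENERA = frozenset({"Caligo", "Eryphanis", "Taygetis"})
COUNT_COLUMNS = ["EC", "EU", "FC", "FU"]


def load_table2_counts() -> pd.DataFrame:
    """Packaged per-species stratum counts for the 41 edge∩forest species."""
    ref = importlib.resources.files("canopymed") / "fixtures" / "table2.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return validate_counts(df)


def validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a species×stratum count table (columns species,EC,EU,FC,FU)."""
    missing = [c for c in ["species", *COUNT_COLUMNS] if c not in df.columns]
    if missing:
        raise ValidationError(f"count table missing column(s) {missing}")
    counts = df[COUNT_COLUMNS]
    if (counts.to_numpy() < 0).any():
        raise ValidationError("negative stratum count")
    edge_total = df["EC"] + df["EU"]
    forest_total = df["FC"] + df["FU"]
    absent = (edge_total == 0) | (forest_total == 0)
    if absent.any():
        raise ValidationError(
            "species absent from a habitat class: "
            f"{df.loc[absent, 'species'].tolist()}; the common-species table "
            "requires presence in both edge and forest"
        )
    return df.reset_index(drop=True)


def counts_from_captures(captures: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a capture table into per-species EC/EU/FC/FU counts.

    Only species present in both edge and forest (ridge+valley) habitat
    classes — the common-species set — are returned.
    """
    edge = captures["habitat"] == "edge"
    canopy = captures["stratum"] == "canopy"
    cells = pd.DataFrame(
        {
            "species": captures["species"],
            "EC": (edge & canopy).astype(int),
            "EU": (edge & ~canopy).astype(int),
            "FC": (~edge & canopy).astype(int),
            "FU": (~edge & ~canopy).astype(int),
        }
    )
    counts = cells.groupby("species", as_index=False).sum()
    common = ((counts["EC"] + counts["EU"]) > 0) & ((counts["FC"] + counts["FU"]) > 0)
    return counts[common].reset_index(drop=True)


def canopy_probability(canopy_count, understory_count):
    """Canopy captures divided by total captures; undefined at zero total."""
    c = np.asarray(canopy_count, dtype=float)
    u = np.asarray(understory_count, dtype=float)
    total = c + u
    if np.any(total <= 0):
        raise ValidationError(
            "canopy probability undefined for zero total count; "
            "filter the species out first"
        )
    out = c / total
    return float(out) if out.ndim == 0 else out


def genus_of(species) -> pd.Series:
    """Genus parsed as the first token of the binomial."""
    return pd.Series(species).str.split().str[0]


def delta_edge_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-species canopy probabilities, delta edge, and its sign class.

    ``sign_class`` is "positive" iff delta_edge > 0; exact zeros are
    "nonpositive" (the tie rule used in the G-test).
    """
    df = validate_counts(counts).copy()
    df["genus"] = genus_of(df["species"])
    df["edge_canopy_prob"] = canopy_probability(df["EC"], df["EU"])
    df["forest_canopy_prob"] = canopy_probability(df["FC"], df["FU"])
    df["delta_edge"] = df["forest_canopy_prob"] - df["edge_canopy_prob"]
    df["sign_class"] = np.where(df["delta_edge"] > 0, "positive", "nonpositive")
    return df


def filter_understory_genera(
    rows: pd.DataFrame, genera: frozenset[str] | set[str] = UNDERSTORY_GENERA
) -> pd.DataFrame:
    """Drop species whose genus is in ``genera`` (obligate understory taxa)."""
    genus = genus_of(rows["species"])
    return rows[~genus.isin(genera)].reset_index(drop=True)


def filter_min_counts(rows: pd.DataFrame, min_per_habitat: int = 3) -> pd.DataFrame:
    """Keep species with at least ``min_per_habitat`` individuals in each habitat class."""
    keep = ((rows["EC"] + rows["EU"]) >= min_per_habitat) & (
        (rows["FC"] + rows["FU"]) >= min_per_habitat
    )
    return rows[keep].reset_index(drop=True)


@dataclass(frozen=True)
class GTestResult:
    """Two-cell goodness-of-fit G-test against a 50:50 sign expectation."""

    n_species: int
    n_positive: int
    G: float
    df: int
    p: float


def g_test_sign(n_positive: int, n_total: int) -> GTestResult:
    """Likelihood-ratio G-test of the positive/non-positive sign split.

    ``G = 2·Σ O·ln(O/E)`` over the two sign cells with ``E = n_total/2``;
    cells with ``O = 0`` contribute 0 (the ``x·ln x → 0`` limit), so the
    statistic is defined for all splits. p is the chi-square (df=1) upper
    tail.
    """
    if n_total < 1:
        raise ValidationError("G-test requires at least one species")
    if not 0 <= n_positive <= n_total:
        raise ValidationError("n_positive must lie in [0, n_total]")
    observed = np.array([n_positive, n_total - n_positive], dtype=float)
    expected = n_total / 2.0
    pos = observed > 0  # zero cells contribute 0 (x ln x -> 0 limit)
    terms = observed[pos] * np.log(observed[pos] / expected)
    G = float(2.0 * terms.sum())
    p = float(stats.chi2.sf(G, df=1))
    return GTestResult(n_species=n_total, n_positive=int(n_positive), G=G, df=1, p=p)


def g_test_from_rows(rows: pd.DataFrame) -> GTestResult:
    """Run the sign G-test on a delta-edge table."""
    n_pos = int((rows["sign_class"] == "positive").sum())
    return g_test_sign(n_pos, len(rows))


def gtest_report(
    counts: pd.DataFrame,
    *,
    genera: frozenset[str] | set[str] = UNDERSTORY_GENERA,
    min_per_habitat: int = 3,
) -> dict:
    """The full three-test suite: all common species; genus filter; genus+min-count.

    Returns a JSON-serialisable dict with the delta-edge rows implicit in
    each test's n and the three G-test results.
    """
    rows = delta_edge_table(counts)
    no_understory = filter_understory_genera(rows, genera)
    strict = filter_min_counts(no_understory, min_per_habitat)
    report = {
        "all_common_species": asdict(g_test_from_rows(rows)),
        "understory_genera_removed": asdict(g_test_from_rows(no_understory)),
        "min_count_filtered": asdict(g_test_from_rows(strict)),
        "filters": {
            "understory_genera": sorted(genera),
            "min_per_habitat": min_per_habitat,
        },
    }
    return report


def write_gtest_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
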