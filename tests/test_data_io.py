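"""Readers, the light transform, capture/abiotic alignment, hourly summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from canopymed import data_io, synthetic
from canopymed.errors import ParseError, ValidationError

CAPTURES_CSV = """individual_id,timestamp,site_id,habitat,stratum,species,tribe
b1,2015-06-01T10:00:00,s01,edge,canopy,Adelpha iphiclus,Limenitidini
b2,2015-06-01,s02,ridge,understory,Nessaea aglaura,Biblidini
b3,2015-06-02T14:00:00,s03,valley,canopy,Morpho helenor,Morphini
"""


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


def test_read_captures_wellformed(tmp_path):
    df = data_io.read_captures(_write(tmp_path, "c.csv", CAPTURES_CSV))
    assert len(df) == 3
    # day-resolution row got the representative hour
    assert df.loc[1, "timestamp"] == pd.Timestamp("2015-06-01T12:00:00")


def test_read_captures_rejects_unknown_stratum(tmp_path):
    bad = CAPTURES_CSV.replace("understory", "mid")
    with pytest.raises(ValidationError, match="stratum"):
        data_io.read_captures(_write(tmp_path, "c.csv", bad))


def test_read_captures_rejects_duplicate_individual(tmp_path):
    bad = CAPTURES_CSV.replace("b2", "b1")
    with pytest.raises(ValidationError, match="duplicate individual_id"):
        data_io.read_captures(_write(tmp_path, "c.csv", bad))


def test_read_captures_parse_error_names_line(tmp_path):
    bad = CAPTURES_CSV.replace("2015-06-02T14:00:00", "not-a-date")
    with pytest.raises(ParseError, match="line 4"):
        data_io.read_captures(_write(tmp_path, "c.csv", bad))


def test_capture_roundtrip_identity(tmp_path):
    df = data_io.read_captures(_write(tmp_path, "c.csv", CAPTURES_CSV))
    data_io.write_table(df, tmp_path / "out.csv")
    again = data_io.read_captures(tmp_path / "out.csv")
    pd.testing.assert_frame_equal(df, again)


def test_logger_roundtrip_and_validation(tmp_path):
    loggers = pd.DataFrame(
        {
            "timestamp": pd.to_datetime(["2015-06-01T10:00:00"] * 2),
            "site_id": ["s01", "s01"],
            "stratum": ["canopy", "understory"],
            "variable": ["light_lux", "temperature_C"],
            "value": [1000.0, 24.5],
        }
    )
    data_io.write_table(loggers, tmp_path / "l.csv")
    again = data_io.read_loggers(tmp_path / "l.csv")
    pd.testing.assert_frame_equal(loggers, again)
    dup = pd.concat([loggers, loggers.iloc[[0]]], ignore_index=True)
    data_io.write_table(dup, tmp_path / "d.csv")
    with pytest.raises(ValidationError, match="duplicate logger"):
        data_io.read_loggers(tmp_path / "d.csv")
    neg = loggers.assign(value=[-1.0, 24.5])
    data_io.write_table(neg, tmp_path / "n.csv")
    with pytest.raises(ValidationError, match="negative light"):
        data_io.read_loggers(tmp_path / "n.csv")


def test_log_transform_values():
    assert data_io.log_transform_light(0.0, 1.0) == 0.0
    assert data_io.log_transform_light(np.e - 1, 1.0) == pytest.approx(1.0, abs=1e-12)
    assert data_io.log_transform_light(1000.0, 1.0) == pytest.approx(
        np.log(1001.0), abs=1e-12
    )
    with pytest.raises(ValidationError):
        data_io.log_transform_light(-0.5)
    with pytest.raises(ValidationError):
        data_io.log_transform_light(1.0, offset=0.0)


@given(st.floats(0, 1e6), st.floats(0, 1e6))
def test_log_transform_monotone(a, b):
    lo, hi = sorted((a, b))
    if lo < hi:
        assert data_io.log_transform_light(lo) < data_io.log_transform_light(hi)


def _toy_state(ld_c=7.0, ld_u=3.0, t_c=26.0, t_u=24.0):
    ts = pd.Timestamp("2015-06-01T12:00:00")
    return pd.DataFrame(
        {
            "habitat": ["edge"] * 4,
            "stratum": ["canopy", "understory", "canopy", "understory"],
            "variable": ["log_light", "log_light", "temperature_C", "temperature_C"],
            "timestamp": [ts] * 4,
            "value": [ld_c, ld_u, t_c, t_u],
        }
    )


def _toy_captures(ts="2015-06-01T12:00:00", habitat="edge"):
    return pd.DataFrame(
        {
            "individual_id": ["b1"],
            "timestamp": [pd.Timestamp(ts)],
            "site_id": ["s01"],
            "habitat": [habitat],
            "stratum": ["canopy"],
            "species": ["Adelpha iphiclus"],
            "tribe": ["Limenitidini"],
        }
    )


def test_attach_abiotic_contrasts():
    out = data_io.attach_abiotic(_toy_captures(), _toy_state())
    assert out.loc[0, "LD"] == pytest.approx(4.0)
    assert out.loc[0, "TD"] == pytest.approx(2.0)
    # equal strata -> zero contrasts
    out0 = data_io.attach_abiotic(_toy_captures(), _toy_state(5.0, 5.0, 24.0, 24.0))
    assert out0.loc[0, "LD"] == 0.0 and out0.loc[0, "TD"] == 0.0


def test_attach_abiotic_antisymmetric_under_stratum_swap():
    state = _toy_state()
    swapped = state.copy()
    swapped["stratum"] = swapped["stratum"].map(
        {"canopy": "understory", "understory": "canopy"}
    )
    a = data_io.attach_abiotic(_toy_captures(), state)
    b = data_io.attach_abiotic(_toy_captures(), swapped)
    assert a.loc[0, "LD"] == pytest.approx(-b.loc[0, "LD"])
    assert a.loc[0, "TD"] == pytest.approx(-b.loc[0, "TD"])


def test_attach_abiotic_flags_unresolvable_as_missing():
    # hour outside the series range
    out = data_io.attach_abiotic(_toy_captures(ts="2015-06-03T09:00:00"), _toy_state())
    assert np.isnan(out.loc[0, "LD"]) and np.isnan(out.loc[0, "TD"])


def test_attach_abiotic_site_level_missing_for_uninstrumented_site():
    """A capture at a site with no logger ever deployed is flagged, not dropped."""
    cfg = synthetic.GeneratorConfig(n_days=2)
    rng = np.random.default_rng(3)
    sites = synthetic.gen_sites(cfg, rng)
    loggers, _ = synthetic.gen_abiotic(cfg, sites, rng)
    state = data_io.loggers_to_state(loggers, sites, by="site_id")
    bare = sorted(set(sites["site_id"]) - set(loggers["site_id"]))
    assert bare, "generator should leave some sites uninstrumented"
    cap = _toy_captures(ts="2015-06-01T12:00:00")
    cap["site_id"] = bare[0]
    out = data_io.attach_abiotic(cap, state)
    assert np.isnan(out.loc[0, "LD"])


def test_hourly_summary_hand_computed():
    ts = pd.to_datetime(["2015-06-01T10:30:00", "2015-06-02T10:10:00", "2015-06-01T11:00:00"])
    loggers = pd.DataFrame(
        {
            "timestamp": ts,
            "site_id": ["s01"] * 3,
            "stratum": ["canopy"] * 3,
            "variable": ["temperature_C"] * 3,
            "value": [24.0, 26.0, 30.0],
        }
    )
    sites = pd.DataFrame(
        {"site_id": ["s01"], "habitat": ["edge"], "canopy_height_m": [20.0], "understory_height_m": [1.0]}
    )
    out = data_io.hourly_summary(loggers, sites).set_index("hour")
    assert out.loc[10, "mean"] == pytest.approx(25.0)
    assert out.loc[10, "ci_half_width"] == pytest.approx(1.96 * np.sqrt(2.0) / np.sqrt(2))
    assert out.loc[10, "n"] == 2
    # single-record cell: half-width reported as 0
    assert out.loc[11, "ci_half_width"] == 0.0 and out.loc[11, "n"] == 1


def test_hourly_summary_tracks_generator_curve():
    """Cell means converge to the generator's diurnal temperature curve."""
    cfg = synthetic.GeneratorConfig(
        n_days=35,
        logger_missing_rate=0.0,
        mar_first_half_factor=1.0,
        never_instrumented={"edge": 0, "ridge": 0, "valley": 0},
    )
    rng = np.random.default_rng(11)
    sites = synthetic.gen_sites(cfg, rng)
    loggers, _ = synthetic.gen_abiotic(cfg, sites, rng)
    summary = data_io.hourly_summary(loggers, sites)
    cell = summary[
        (summary["habitat"] == "ridge")
        & (summary["stratum"] == "canopy")
        & (summary["variable"] == "temperature_C")
    ].set_index("hour")
    curve = synthetic._curve(
        cfg.curves[("ridge", "canopy", "temperature_C")], np.arange(24)
    )
    # the latent AR(1) deviation is shared by every site that hour, so the
    # cell-mean sd is var_e/n_days + var_obs/n (lag-24 corr negligible)
    var_e = cfg.sigma_proc_temp**2 / (1 - cfg.rho**2)
    for h in range(24):
        n = cell.loc[h, "n"]
        assert n >= 200
        sd_mean = np.sqrt(var_e / cfg.n_days + cfg.sigma_obs_temp**2 / n)
        assert abs(cell.loc[h, "mean"] - curve[h]) < 3 * sd_mean + 0.02
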