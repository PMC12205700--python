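"""Community scores, score-to-physical-unit conversions, moisture classes.

The conversion oracle is an independent direct evaluation of each printed
relation (plain math.* expressions, no shared code with the package).
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phytoind import (
    classify_moisture,
    community_score,
    convert_regime,
    convert_regimes,
    plot_scores,
    read_releves,
)
from phytoind.indication import ConversionDomainError
from phytoind.indicators import load_indicator_table
from phytoind.scales import DIDUKH_SCALES

# independent oracle: one lambda per relation, written from the printed text
ORACLE = {
    "Hd": lambda h: 18.65 * math.exp(0.15 * h),
    "fH": lambda f: 0.042 * f - 0.032,
    "Ae": lambda a: (100 - a**4) / (100 * (a**4 + 1700)),
    "Rc": lambda r: 2.26 * math.log(r) + 1.88,
    "Sl": lambda s: 2 ** (0.6 * s + 1),
    "Ca": lambda c: 14 * c**4.5 / (c**4.5 + 45000),
    "Nt": lambda n: 5 * n**3.7 / (n**3.7 + 345),
    "Tm": lambda t: 0.21 * t,
    "Om": lambda o: 0.54 * o - 7,
    "Kn": lambda k: 10 * k + 41,
    "Cr": lambda c: 3.83 * c - 38.17,
    "Lc": lambda l: 0.22 * l,
    "L": lambda l: 0.22 * l,
}


@pytest.mark.parametrize("scale_id", sorted(ORACLE))
def test_conversions_match_oracle_on_dense_grid(scale_id):
    g = DIDUKH_SCALES.get(scale_id)
    hi = g.n_gradations if g else 9
    for score in np.linspace(1.0, hi, 997):
        assert convert_regime(scale_id, float(score)) == pytest.approx(
            ORACLE[scale_id](float(score)), abs=1e-9
        )


@pytest.mark.parametrize(
    "scale_id,score,expected",
    [
        ("Rc", 1, 1.88),           # ln 1 = 0
        ("Sl", 0, 2.0),            # 2^1
        ("Nt", 0, 0.0),
        ("Om", 0, -7.0),
        ("Kn", 0, 41.0),
        ("Cr", 0, -38.17),
        ("Hd", 10, 18.65 * math.exp(1.5)),
        ("Nt", 11, 5 * 11**3.7 / (11**3.7 + 345)),
        ("Cr", 10, 0.13),
    ],
)
def test_conversion_anchor_points(scale_id, score, expected):
    assert convert_regime(scale_id, score) == pytest.approx(expected, abs=1e-9)


def test_rc_domain_error():
    with pytest.raises(ConversionDomainError):
        convert_regime("Rc", 0)


def test_unknown_scale_rejected():
    with pytest.raises(KeyError):
        convert_regime("Xx", 5)


@pytest.mark.parametrize("scale_id", sorted(set(ORACLE) - {"Ae"}))
def test_conversions_monotone_increasing(scale_id):
    g = DIDUKH_SCALES.get(scale_id)
    lo = 0.1 if scale_id == "Rc" else 1.0
    grid = np.linspace(lo, g.n_gradations if g else 9, 500)
    vals = np.array([convert_regime(scale_id, float(s)) for s in grid])
    assert (np.diff(vals) > 0).all()


def test_aeration_decreasing_for_ae_ge_1():
    grid = np.linspace(1.0, 15.0, 500)
    vals = np.array([convert_regime("Ae", float(s)) for s in grid])
    assert (np.diff(vals) < 0).all()


def test_saturating_limits():
    assert convert_regime("Ca", 1e6) == pytest.approx(14.0, abs=1e-3)
    assert convert_regime("Nt", 1e6) == pytest.approx(5.0, abs=1e-3)


def test_regime_bounds_over_scale_ranges():
    """N in [0, 5) and CaO+MgO in [0, 14) over any non-negative score."""
    for s in np.linspace(0, 50, 300):
        assert 0 <= convert_regime("Nt", float(s)) < 5
        assert 0 <= convert_regime("Ca", float(s)) < 14


# --- community scores -------------------------------------------------------


def _make_rs_and_table(tmp_path, covers):
    rel = ["plot_id,species,cover"]
    for sp, c in covers.items():
        rel.append(f"p1,{sp},{c}")
    (tmp_path / "r.csv").write_text("\n".join(rel) + "\n")
    (tmp_path / "i.csv").write_text(
        "species,Hd,hemeroby_grade\nSp a,10,\nSp b,12,\nSp c,14,\n"
    )
    rs = read_releves(tmp_path / "r.csv")
    table = load_indicator_table(tmp_path / "i.csv")
    return rs, table


def test_presence_mean(tmp_path):
    rs, table = _make_rs_and_table(tmp_path, {"Sp a": 50, "Sp b": 25, "Sp c": 25})
    out = community_score(rs, table, "Hd", weighting="presence")
    assert out.loc["p1", "score"] == pytest.approx(12.0)
    assert out.loc["p1", "n_species_used"] == 3


def test_cover_weighted_mean(tmp_path):
    rs, table = _make_rs_and_table(tmp_path, {"Sp a": 50, "Sp b": 25, "Sp c": 25})
    out = community_score(rs, table, "Hd", weighting="cover")
    assert out.loc["p1", "score"] == pytest.approx((500 + 300 + 350) / 100)


def test_min_species_guard(tmp_path, caplog):
    rs, table = _make_rs_and_table(tmp_path, {"Sp a": 50, "Sp b": 25})
    with caplog.at_level("WARNING"):
        out = community_score(rs, table, "Hd", min_species=3)
    assert np.isnan(out.loc["p1", "score"])
    assert "plot" in caplog.text


def test_presence_invariant_to_cover_rescaling(synthetic_survey):
    com, rs, _ = synthetic_survey
    a = plot_scores(rs, com.table, ("Hd",), weighting="presence")
    scaled = rs.covers * 0.5
    from phytoind import ReleveSet

    rs2 = ReleveSet(scaled, rs.plots.copy())
    b = plot_scores(rs2, com.table, ("Hd",), weighting="presence")
    pd.testing.assert_frame_equal(a, b)


def test_cover_mode_invariant_to_constant_rescaling(synthetic_survey):
    com, rs, _ = synthetic_survey
    a = plot_scores(rs, com.table, ("Hd",), weighting="cover")
    from phytoind import ReleveSet

    rs2 = ReleveSet(rs.covers * 0.25, rs.plots.copy())
    b = plot_scores(rs2, com.table, ("Hd",), weighting="cover")
    pd.testing.assert_frame_equal(a, b, atol=1e-12)


def test_convert_regimes_column_names(synthetic_survey):
    com, rs, _ = synthetic_survey
    raw = plot_scores(rs, com.table, ("Hd", "Rc", "Lc", "L"))
    phys = convert_regimes(raw)
    assert {"W_mm", "pH", "log_lighting", "log_lighting_L"} <= set(phys.columns)
    valid = raw["Hd"].notna()
    assert (phys.loc[valid, "W_mm"] > 0).all()


# --- moisture classes -------------------------------------------------------


@pytest.mark.parametrize(
    "w,label",
    [
        (59.9, "very_low"),
        (60.0, "low"),
        (90.0, "satisfactory"),
        (129.999, "satisfactory"),
        (130.0, "good"),
        (160.0, "very_good"),
        (200.0, "very_good"),
        (0.0, "very_low"),
    ],
)
def test_moisture_class_boundaries(w, label):
    assert classify_moisture(w) == label


@settings(derandomize=True, max_examples=300)
@given(st.floats(min_value=0, max_value=300, allow_nan=False))
def test_moisture_class_total_and_ordered(w):
    label = classify_moisture(w)
    bounds = {
        "very_low": (0, 60), "low": (60, 90), "satisfactory": (90, 130),
        "good": (130, 160), "very_good": (160, math.inf),
    }
    lo, hi = bounds[label]
    assert lo <= w < hi


def test_moisture_class_negative_rejected():
    with pytest.raises(ValueError):
        classify_moisture(-1.0)
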