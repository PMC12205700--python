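"""Phytoindication: community indicator scores and their physical conversions.

The community score of a plot on an ordinal indicator scale is the mean of
the scores of the species recorded in it (presence-weighted by default; a
projective-cover-weighted mean is available as a switch, since classical
phytoindication practice uses the unweighted mean but some workers weight by
cover).  Community scores are then converted into physical environmental
quantities through a fixed set of published regression/saturation relations,
one per Didukh factor:

===========  =============================================  ==================
scale        conversion                                     output (units)
===========  =============================================  ==================
Hd           W  = 18.65 * exp(0.15 * Hd)                    productive moisture, mm / 1 m soil layer
fH           omega = 0.042 * fH - 0.032                     moisture irregularity (0..0.5)
Ae           P  = (100 - Ae^4) / (100 * (Ae^4 + 1700))      air-filled porosity (printed-formula output; see docs)
Rc           pH = 2.26 * ln(Rc) + 1.88                      soil pH
Sl           S  = 2^(0.6 * Sl + 1)                          salt content, ug/l
Ca           CaO+MgO = 14 * Ca^4.5 / (Ca^4.5 + 45000)       carbonates, %
Nt           N  = 5 * Nt^3.7 / (Nt^3.7 + 345)               nitrogen, g/kg
Tm           RB = 0.21 * Tm                                 radiation balance, gJ m-2 yr-1
Om           Hum = 0.54 * Om - 7                            precipitation - evaporation, mm/day
Kn           SKn = 10 * Kn + 41                             Ivanov continentality scale
Cr           Temp = 3.83 * Cr - 38.17                       mean coldest-month temperature, deg C
Lc (or L)    log_lighting = 0.22 * score                    log10 relative light
===========  =============================================  ==================

Every conversion is implemented exactly as printed, with no post-hoc
rescaling.  The aeration relation's output magnitude (~6e-4 at Ae = 1) is
implausible as a literal percentage; it is nevertheless reported verbatim as
formula output (see the methods note).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .indicators import IndicatorTable, match_species
from .releves import ReleveSet
from .scales import get_scale

logger = logging.getLogger(__name__)

DEFAULT_MIN_SPECIES = 3


class ConversionDomainError(ValueError):
    """Score outside the mathematical domain of a conversion (e.g. Rc <= 0)."""


def _w_mm(h):
    return 18.65 * np.exp(0.15 * np.asarray(h, dtype=float))


def _omega(fh):
    return 0.042 * np.asarray(fh, dtype=float) - 0.032


def _porosity(ae):
    a = np.asarray(ae, dtype=float) ** 4
    return (100.0 - a) / (100.0 * (a + 1700.0))


def _ph(rc):
    rc = np.asarray(rc, dtype=float)
    if np.any(rc <= 0):
        raise ConversionDomainError("pH conversion requires Rc > 0 (logarithm)")
    return 2.26 * np.log(rc) + 1.88


def _salt(sl):
    return 2.0 ** (0.6 * np.asarray(sl, dtype=float) + 1.0)


def _carbonate(ca):
    c = np.asarray(ca, dtype=float) ** 4.5
    return 14.0 * c / (c + 45000.0)


def _nitrogen(nt):
    n = np.asarray(nt, dtype=float) ** 3.7
    return 5.0 * n / (n + 345.0)


def _radiation(tm):
    return 0.21 * np.asarray(tm, dtype=float)


def _humidity(om):
    return 0.54 * np.asarray(om, dtype=float) - 7.0


def _continentality(kn):
    return 10.0 * np.asarray(kn, dtype=float) + 41.0


def _cold_temp(cr):
    return 3.83 * np.asarray(cr, dtype=float) - 38.17


def _log_light(l):
    return 0.22 * np.asarray(l, dtype=float)


@dataclass(frozen=True)
class Conversion:
    scale_id: str
    output: str
    units: str
    func: Callable


#: Conversion registry keyed by scale id.  ``L`` routes the Ellenberg light
#: score through the same light relation as the Didukh ``Lc`` factor (the
#: relation is stated for the Ellenberg L-value; applying it to Lc is a
#: config choice, see :func:`convert_regimes`).
CONVERSIONS: dict[str, Conversion] = {
    c.scale_id: c
    for c in [
        Conversion("Hd", "W_mm", "mm", _w_mm),
        Conversion("fH", "omega", "dimensionless", _omega),
        Conversion("Ae", "P_porosity", "printed-formula output", _porosity),
        Conversion("Rc", "pH", "pH units", _ph),
        Conversion("Sl", "S_salt", "ug/l", _salt),
        Conversion("Ca", "CaO_MgO_pct", "%", _carbonate),
        Conversion("Nt", "N_gkg", "g/kg", _nitrogen),
        Conversion("Tm", "RB", "gJ m-2 yr-1", _radiation),
        Conversion("Om", "Hum_mm", "mm/day", _humidity),
        Conversion("Kn", "SKn", "Ivanov scale", _continentality),
        Conversion("Cr", "Temp_coldest_C", "deg C", _cold_temp),
        Conversion("Lc", "log_lighting", "log10 relative light", _log_light),
        Conversion("L", "log_lighting_L", "log10 relative light", _log_light),
    ]
}


def convert_regime(scale_id: str, score):
    """Convert a community indicator score to its physical quantity.

    Defined for any positive real score; values outside the scale's ordinal
    range are converted anyway but flagged with a warning (soft check).
    Scalar in, scalar out; array in, array out.
    """
    if scale_id not in CONVERSIONS:
        raise KeyError(
            f"no conversion for scale {scale_id!r}; available: {sorted(CONVERSIONS)}"
        )
    conv = CONVERSIONS[scale_id]
    arr = np.asarray(score, dtype=float)
    sdef = get_scale(scale_id)
    finite = arr[np.isfinite(arr)]
    if finite.size and ((finite < 1) | (finite > sdef.n_gradations)).any():
        logger.warning(
            "%s score(s) outside ordinal range [1, %d]; converting anyway",
            scale_id,
            sdef.n_gradations,
        )
    out = conv.func(arr)
    if np.isscalar(score) or np.ndim(score) == 0:
        return float(out)
    return out


def community_score(
    rs: ReleveSet,
    table: IndicatorTable,
    scale_id: str,
    weighting: str = "presence",
    min_species: int = DEFAULT_MIN_SPECIES,
) -> pd.DataFrame:
    """Per-plot community mean score on one scale.

    presence mode: arithmetic mean of the scores of species present;
    cover mode: cover-weighted mean sum(c_i s_i) / sum(c_i).
    Plots with fewer than ``min_species`` scored species get a missing score
    (with a warning).  Returns a DataFrame with columns ``score`` and
    ``n_species_used`` indexed by plot.
    """
    get_scale(scale_id)
    if weighting not in ("presence", "cover"):
        raise ValueError(f"weighting must be 'presence' or 'cover', got {weighting!r}")

    report = match_species(table, rs.species)
    sp_scores = pd.Series(
        {q: table.data.at[stored, scale_id] for q, stored in report.matched.items()},
        dtype=float,
    ).reindex(rs.species)

    covers = rs.covers.to_numpy(dtype=float)  # NaN = absent
    scores = sp_scores.to_numpy(dtype=float)
    has_score = np.isfinite(scores)
    present = np.isfinite(covers)
    usable = present & has_score[None, :]
    n_used = usable.sum(axis=1)

    if weighting == "presence":
        w = usable.astype(float)
    else:
        w = np.where(usable, covers, 0.0)
    wsum = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = (w * np.where(has_score[None, :], scores[None, :], 0.0)).sum(axis=1) / wsum
    vals = np.where((n_used >= min_species) & (wsum > 0), vals, np.nan)

    n_skipped = int(((n_used < min_species) & (n_used > 0)).sum())
    if n_skipped:
        logger.warning(
            "%s: %d plot(s) with < %d scored species; score reported missing",
            scale_id,
            n_skipped,
            min_species,
        )
    return pd.DataFrame(
        {"score": vals, "n_species_used": n_used.astype(int)}, index=rs.covers.index
    )


def plot_scores(
    rs: ReleveSet,
    table: IndicatorTable,
    scale_ids: tuple[str, ...] | None = None,
    weighting: str = "presence",
    min_species: int = DEFAULT_MIN_SPECIES,
) -> pd.DataFrame:
    """Community scores for several scales at once (plots x scale ids)."""
    if scale_ids is None:
        scale_ids = table.scale_set
    cols = {
        sid: community_score(rs, table, sid, weighting, min_species)["score"]
        for sid in scale_ids
    }
    return pd.DataFrame(cols, index=rs.covers.index)


def convert_regimes(
    scores: pd.DataFrame, light_from: str = "Lc"
) -> pd.DataFrame:
    """Convert a plot x scale score table into physical quantities.

    ``light_from`` selects which light score feeds the log-light relation
    when both a Didukh ``Lc`` and an Ellenberg ``L`` column are present
    (both are converted if both exist; this flag only controls which one is
    published under the canonical ``log_lighting`` name).
    """
    out = {}
    for sid in scores.columns:
        if sid not in CONVERSIONS:
            continue
        conv = CONVERSIONS[sid]
        name = conv.output
        if sid in ("Lc", "L"):
            name = "log_lighting" if sid == light_from else f"log_lighting_{sid}"
        col = scores[sid]
        if sid == "Rc":
            valid = col > 0
            vals = pd.Series(np.nan, index=col.index)
            if valid.any():
                vals[valid] = conv.func(col[valid].to_numpy())
            out[name] = vals
        else:
            out[name] = pd.Series(conv.func(col.to_numpy()), index=col.index)
    return pd.DataFrame(out, index=scores.index)


def regimes_table(
    rs: ReleveSet,
    table: IndicatorTable,
    weighting: str = "presence",
    min_species: int = DEFAULT_MIN_SPECIES,
) -> pd.DataFrame:
    """Full per-plot output: raw community score columns then converted
    physical-quantity columns (the package's canonical per-plot CSV)."""
    raw = plot_scores(rs, table, None, weighting, min_species)
    phys = convert_regimes(raw)
    return pd.concat([raw, phys], axis=1)


#: Productive-moisture supply classes for agricultural plants (mm in the
#: 1 m soil layer); boundaries are lower-inclusive half-open intervals.
MOISTURE_CLASS_BOUNDS = [
    (0.0, 60.0, "very_low"),
    (60.0, 90.0, "low"),
    (90.0, 130.0, "satisfactory"),
    (130.0, 160.0, "good"),
    (160.0, math.inf, "very_good"),
]


def classify_moisture(w_mm: float) -> str:
    """Classify a productive-moisture value (mm) into supply classes:
    <60 very_low, [60,90) low, [90,130) satisfactory, [130,160) good,
    >=160 very_good."""
    if not math.isfinite(w_mm) or w_mm < 0:
        raise ValueError(f"W_mm must be a finite non-negative number, got {w_mm!r}")
    for lo, hi, label in MOISTURE_CLASS_BOUNDS:
        if lo <= w_mm < hi:
            return label
    raise AssertionError("unreachable")
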