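"""Plot-level hemeroby and naturalness indices.

Hemeroby is an ordinal measure of human-induced transformation of a plant
community, graded per species on a 7-step scale (1 = ahemerobic, untouched;
7 = metahemerobic, fully artificial).  The plot hemeroby index implemented
here is the community-(cover-)weighted mean grade — the standard
operationalisation in the hemeroby literature.  Naturalness is a distinct
index, not a mirror of hemeroby: the share of the plot's species count (or
cover) contributed by species of grade <= ``natural_threshold`` (default 3,
i.e. ahemerobic through mesohemerobic).  Keeping the two definitions
independent lets them carry different information, as they do in ordinations
of disturbed vegetation where their loadings differ in magnitude, not just
sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indicators import IndicatorTable, match_species
from .releves import ReleveSet
from .scales import HEMEROBY_COLUMN

logger = logging.getLogger(__name__)

DEFAULT_NATURAL_THRESHOLD = 3
DEFAULT_MIN_SPECIES = 3


@dataclass
class HemerobyResult:
    """Per-plot hemeroby/naturalness table.

    ``table`` columns: hemeroby_index in [1, 7], naturalness_index in [0, 1],
    n_species_used, cover_fraction_scored in [0, 1].
    """

    table: pd.DataFrame
    weighting: str
    natural_threshold: int

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


def plot_hemeroby(
    rs: ReleveSet,
    table: IndicatorTable,
    weighting: str = "presence",
    natural_threshold: int = DEFAULT_NATURAL_THRESHOLD,
    min_species: int = DEFAULT_MIN_SPECIES,
) -> HemerobyResult:
    """Compute hemeroby and naturalness indices for every plot.

    hemeroby_index: (cover-)weighted mean hemeroby grade of the species
    scored in the plot.  naturalness_index: share of the species count
    (presence mode) or of the scored cover (cover mode) contributed by
    species with grade <= natural_threshold.  Plots with fewer than
    ``min_species`` scored species get missing indices with a warning.
    """
    if weighting not in ("presence", "cover"):
        raise ValueError(f"weighting must be 'presence' or 'cover', got {weighting!r}")
    if not 1 <= natural_threshold <= 6:
        raise ValueError("natural_threshold must be in [1, 6]")

    report = match_species(table, rs.species)
    grades = pd.Series(
        {q: table.data.at[s, HEMEROBY_COLUMN] for q, s in report.matched.items()},
        dtype=float,
    ).reindex(rs.species)

    covers = rs.covers.to_numpy(dtype=float)
    g = grades.to_numpy(dtype=float)
    present = np.isfinite(covers)
    scored = present & np.isfinite(g)[None, :]
    n_used = scored.sum(axis=1)

    cover_filled = np.where(present, covers, 0.0)
    total_cover = cover_filled.sum(axis=1)
    scored_cover = np.where(scored, cover_filled, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cover_frac = np.where(total_cover > 0, scored_cover / total_cover, 0.0)

    w = scored.astype(float) if weighting == "presence" else np.where(scored, cover_filled, 0.0)
    wsum = w.sum(axis=1)
    gz = np.where(np.isfinite(g), g, 0.0)
    natural = np.isfinite(g) & (g <= natural_threshold)
    with np.errstate(invalid="ignore", divide="ignore"):
        hemeroby_index = (w * gz[None, :]).sum(axis=1) / wsum
        naturalness = (w * natural[None, :]).sum(axis=1) / wsum

    ok = (n_used >= min_species) & (wsum > 0)
    hemeroby_index = np.where(ok, hemeroby_index, np.nan)
    naturalness = np.where(ok, naturalness, np.nan)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning(
            "hemeroby: %d plot(s) with < %d graded species; indices missing",
            n_skipped,
            min_species,
        )

    out = pd.DataFrame(
        {
            "hemeroby_index": hemeroby_index,
            "naturalness_index": naturalness,
            "n_species_used": n_used.astype(int),
            "cover_fraction_scored": cover_frac,
        },
        index=rs.covers.index,
    )
    return HemerobyResult(out, weighting, natural_threshold)


def group_hemeroby_contrast(
    result: HemerobyResult, groups: pd.Series | dict
) -> pd.DataFrame:
    """Per-group mean +- sample SD of both indices, ordered by group label.

    ``groups`` maps plot_id -> association label.  Groups with a single plot
    get a missing SD.  Requires at least two groups.
    """
    groups = pd.Series(groups)
    tab = result.table.join(groups.rename("group"), how="inner")
    if tab["group"].nunique() < 2:
        raise ValueError("group_hemeroby_contrast requires >= 2 groups")
    rows = []
    for label, sub in sorted(tab.groupby("group"), key=lambda kv: str(kv[0])):
        row = {"group": label, "n_plots": len(sub)}
        for col in ("hemeroby_index", "naturalness_index"):
            vals = sub[col].dropna()
            row[f"{col}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) >= 2 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
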