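"""Species-level indicator value tables.

An :class:`IndicatorTable` holds, per species, one optional ordinal score on
each configured scale plus an optional hemeroby grade.  The on-disk format is
a plain CSV: column 1 ``species``, one column per scale id, then
``hemeroby_grade``; empty cell = missing.  Missing scores are first-class
(``NaN``), never 0 — zero is out of range on every scale and must not be a
sentinel.

Species-name matching is exact after whitespace/case normalisation only;
fuzzy or synonym matching is deliberately excluded because silent taxonomic
guessing corrupts community indicator means.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .scales import ALL_SCALES, HEMEROBY_COLUMN, HEMEROBY_MAX, HEMEROBY_MIN, get_scale

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")


def normalize_species_name(name: str) -> str:
    """Strip, collapse internal whitespace, and case-fold a species name."""
    return _WS.sub(" ", str(name).strip()).casefold()


class IndicatorValidationError(ValueError):
    """A score fell outside its scale's [1, n_gradations] range (strict mode)."""

    def __init__(self, message: str, offending: list[tuple[str, str, float]]):
        super().__init__(message)
        #: list of (species, scale_id, value) triples
        self.offending = offending


@dataclass
class IndicatorTable:
    """Per-species indicator scores on named ordinal scales.

    ``data`` is indexed by the *display* species name; a parallel normalised
    index is kept for matching.  Columns are scale ids plus ``hemeroby_grade``.
    """

    data: pd.DataFrame
    scale_set: tuple[str, ...]
    _norm_index: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._norm_index:
            self._norm_index = {
                normalize_species_name(s): s for s in self.data.index
            }
        if len(self._norm_index) != len(self.data.index):
            dupes = self.data.index[
                pd.Index([normalize_species_name(s) for s in self.data.index]).duplicated()
            ].tolist()
            raise IndicatorValidationError(
                f"duplicate species after normalisation: {dupes}",
                [(d, "species", np.nan) for d in dupes],
            )

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def scores(self, scale_id: str) -> pd.Series:
        """All species scores on one scale (NaN = missing)."""
        get_scale(scale_id)
        return self.data[scale_id]

    def lookup(self, name: str) -> pd.Series | None:
        """Row for a species, matched after normalisation; None if absent."""
        key = self._norm_index.get(normalize_species_name(name))
        return None if key is None else self.data.loc[key]


def _validate_frame(
    df: pd.DataFrame, scale_set: tuple[str, ...], strict: bool
) -> pd.DataFrame:
    offending: list[tuple[str, str, float]] = []
    for sid in scale_set:
        sdef = get_scale(sid)
        col = pd.to_numeric(df[sid], errors="coerce")
        bad = col.notna() & ((col < 1) | (col > sdef.n_gradations))
        for sp, val in col[bad].items():
            offending.append((str(sp), sid, float(val)))
        if not strict:
            col = col.mask(bad)
        df[sid] = col
    if HEMEROBY_COLUMN in df.columns:
        col = pd.to_numeric(df[HEMEROBY_COLUMN], errors="coerce")
        bad = col.notna() & (
            (col < HEMEROBY_MIN) | (col > HEMEROBY_MAX) | (col != col.round())
        )
        for sp, val in col[bad].items():
            offending.append((str(sp), HEMEROBY_COLUMN, float(val)))
        if not strict:
            col = col.mask(bad)
        df[HEMEROBY_COLUMN] = col
    else:
        df[HEMEROBY_COLUMN] = np.nan

    if offending:
        msg = "; ".join(f"{sp}: {sid}={val!r}" for sp, sid, val in offending)
        if strict:
            raise IndicatorValidationError(f"out-of-range scores: {msg}", offending)
        logger.warning("nulled %d out-of-range scores: %s", len(offending), msg)
    return df


def load_indicator_table(
    path: str | Path,
    scale_set: tuple[str, ...] | None = None,
    strict: bool = True,
) -> IndicatorTable:
    """Load and validate a species indicator-value CSV.

    Parameters
    ----------
    path : path to a UTF-8 CSV with a ``species`` column, one column per
        scale id and optionally ``hemeroby_grade``.
    scale_set : scale ids to read; defaults to every known scale found in
        the header.
    strict : if True (default) out-of-range scores raise
        :class:`IndicatorValidationError`; if False they are nulled with a
        logged warning.
    """
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    if "species" not in df.columns:
        raise ValueError(f"{path}: missing required 'species' column")
    if scale_set is None:
        scale_set = tuple(c for c in df.columns if c in ALL_SCALES)
    else:
        missing = [s for s in scale_set if s not in df.columns]
        if missing:
            raise ValueError(f"{path}: scale columns absent from header: {missing}")
    df = df.set_index("species")
    df.index = df.index.map(lambda s: _WS.sub(" ", str(s).strip()))
    keep = list(scale_set) + (
        [HEMEROBY_COLUMN] if HEMEROBY_COLUMN in df.columns else []
    )
    df = df[keep].copy()
    df = _validate_frame(df, tuple(scale_set), strict)
    return IndicatorTable(df, tuple(scale_set))


def write_indicator_table(table: IndicatorTable, path: str | Path) -> None:
    """Write the table back to CSV (round-trips all non-missing cells)."""
    out = table.data.copy()
    out.index.name = "species"
    out.to_csv(path)  # default float repr round-trips bit-exactly


@dataclass
class MatchReport:
    """Outcome of matching a list of names against an indicator table."""

    matched: dict[str, str]  # query name -> stored display name
    unmatched: list[str]

    @property
    def n_matched(self) -> int:
        return len(self.matched)


def match_species(table: IndicatorTable, names: list[str]) -> MatchReport:
    """Match names exactly after normalisation; unmatched names are reported,
    never silently dropped."""
    matched: dict[str, str] = {}
    unmatched: list[str] = []
    for name in names:
        key = table._norm_index.get(normalize_species_name(name))
        if key is None:
            unmatched.append(name)
        else:
            matched[name] = key
    if unmatched:
        logger.warning(
            "%d species without indicator values: %s",
            len(unmatched),
            ", ".join(unmatched[:10]) + ("..." if len(unmatched) > 10 else ""),
        )
    return MatchReport(matched, unmatched)
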