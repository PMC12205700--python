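"""Relevé (plot x species projective cover) input/output.

A relevé is one standardised vegetation sample plot (default 4 x 4 m = 16 m2)
recording each species present and its projective cover as a percentage of
plot area.  Covers are stored as percentages in (0, 100]; absence is not
stored.  Summed plot cover may exceed 100 — vegetation is layered — and is
never renormalised at ingest.

Two CSV layouts are supported and produce identical ``ReleveSet`` objects:

* long: columns ``plot_id, species, cover[, x, y, date]``, one row per
  occurrence;
* wide: first column ``plot_id``, remaining columns species names, cells are
  covers (empty/0 = absent).

Cover cells may be percentages or Braun-Blanquet abundance codes
(``r + 1 2 3 4 5``), converted at ingest via fixed class midpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .indicators import normalize_species_name

logger = logging.getLogger(__name__)

#: Braun-Blanquet code -> percent-cover midpoint.
BRAUN_BLANQUET_MIDPOINTS: dict[str, float] = {
    "r": 0.1,
    "+": 0.5,
    "1": 2.5,
    "2": 15.0,
    "3": 37.5,
    "4": 62.5,
    "5": 87.5,
}


def braun_blanquet_to_percent(code: str) -> float:
    """Convert one Braun-Blanquet abundance code to its percent midpoint."""
    try:
        return BRAUN_BLANQUET_MIDPOINTS[str(code).strip()]
    except KeyError:
        raise ValueError(
            f"unknown Braun-Blanquet code {code!r}; expected one of "
            f"{sorted(BRAUN_BLANQUET_MIDPOINTS)}"
        ) from None


class ReleveValidationError(ValueError):
    pass


@dataclass
class ReleveSet:
    """Plot x species projective-cover matrix with plot metadata.

    ``covers`` is a wide DataFrame (index plot_id, columns species display
    names) with NaN for absence and values in (0, 100] for presence.
    ``plots`` carries per-plot metadata (optional x, y, date).
    """

    covers: pd.DataFrame
    plots: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    plot_area_m2: float = 16.0

    def __post_init__(self) -> None:
        if self.plots is None:
            self.plots = pd.DataFrame(index=self.covers.index)
        vals = self.covers.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() <= 0 or finite.max() > 100):
            raise ReleveValidationError(
                "stored covers must lie in (0, 100]; got "
                f"range [{finite.min()}, {finite.max()}]"
            )
        if self.covers.index.has_duplicates:
            dup = self.covers.index[self.covers.index.duplicated()].tolist()
            raise ReleveValidationError(f"duplicate plot_ids: {dup}")
        richness = self.covers.notna().sum(axis=1)
        if len(self.covers) and (richness < 1).any():
            empty = richness.index[richness < 1].tolist()
            raise ReleveValidationError(f"plots with zero species: {empty}")

    @property
    def plot_ids(self) -> list[str]:
        return list(self.covers.index)

    @property
    def species(self) -> list[str]:
        return list(self.covers.columns)

    @property
    def n_plots(self) -> int:
        return len(self.covers)

    def richness(self) -> pd.Series:
        """Species count per plot."""
        return self.covers.notna().sum(axis=1)

    def total_cover(self) -> pd.Series:
        """Summed projective cover per plot (may exceed 100)."""
        return self.covers.sum(axis=1, skipna=True)

    def presence(self) -> pd.DataFrame:
        """Boolean presence matrix."""
        return self.covers.notna()

    def to_long(self) -> pd.DataFrame:
        """Long-form occurrences: plot_id, species, cover."""
        long = self.covers.stack().rename("cover").reset_index()
        long.columns = ["plot_id", "species", "cover"]
        return long

    def equals(self, other: "ReleveSet") -> bool:
        """Sparse equality: same plots, species-wise identical occurrences."""
        a = self.to_long().sort_values(["plot_id", "species"]).reset_index(drop=True)
        b = other.to_long().sort_values(["plot_id", "species"]).reset_index(drop=True)
        return (
            list(self.covers.index) == list(other.covers.index)
            and a.shape == b.shape
            and (a[["plot_id", "species"]].values == b[["plot_id", "species"]].values).all()
            and np.allclose(a["cover"].values, b["cover"].values)
        )


def _dedup_species(columns: list[str]) -> None:
    norm = [normalize_species_name(c) for c in columns]
    if len(set(norm)) != len(norm):
        seen: dict[str, str] = {}
        dupes = []
        for c, n in zip(columns, norm):
            if n in seen:
                dupes.append((seen[n], c))
            seen[n] = c
        raise ReleveValidationError(f"species duplicated after normalisation: {dupes}")


def _parse_cover_column(col: pd.Series, mode: str) -> pd.Series:
    """Parse covers as percent or Braun-Blanquet codes.

    mode: 'percent', 'code', or 'auto' (codes if any cell is a non-numeric
    BB symbol or the column's non-empty values are all BB codes containing
    'r'/'+').
    """
    s = col.astype("string").str.strip()
    s = s.replace({"": pd.NA, "0": pd.NA, "0.0": pd.NA})
    if mode == "auto":
        nonempty = s.dropna()
        is_code = nonempty.isin(list(BRAUN_BLANQUET_MIDPOINTS))
        has_symbol = nonempty.isin(["r", "+"]).any()
        mode = "code" if (len(nonempty) and is_code.all() and has_symbol) else "percent"
    if mode == "code":
        def _as_code(v):
            # numeric readers may render "2" as "2.0"; normalise back
            try:
                f = float(v)
                if f.is_integer():
                    return str(int(f))
            except ValueError:
                pass
            return str(v)

        return s.map(
            lambda v: braun_blanquet_to_percent(_as_code(v)) if pd.notna(v) else np.nan
        )
    out = pd.to_numeric(s, errors="raise").astype(float)
    return out


def read_releves(
    path: str | Path,
    layout: str = "long",
    cover_mode: str = "auto",
    plot_area_m2: float = 16.0,
) -> ReleveSet:
    """Read a relevé CSV in ``long`` or ``wide`` layout.

    ``cover_mode`` is ``percent``, ``code`` (Braun-Blanquet) or ``auto``
    (per-column detection, overridable).
    """
    if layout == "long":
        df = pd.read_csv(
            path, dtype={"plot_id": str, "species": str}, float_precision="round_trip"
        )
        required = {"plot_id", "species", "cover"}
        if not required.issubset(df.columns):
            raise ReleveValidationError(
                f"{path}: long layout requires columns {sorted(required)}"
            )
        dup = df.duplicated(subset=["plot_id", "species"], keep=False)
        if dup.any():
            pairs = df.loc[dup, ["plot_id", "species"]].drop_duplicates().values.tolist()
            raise ReleveValidationError(f"duplicate (plot, species) pairs: {pairs}")
        df["cover"] = _parse_cover_column(df["cover"], cover_mode)
        df = df[df["cover"].notna()]
        if (df["cover"] > 100).any():
            bad = df[df["cover"] > 100][["plot_id", "species", "cover"]].values.tolist()
            raise ReleveValidationError(f"cover > 100%: {bad}")
        wide = df.pivot(index="plot_id", columns="species", values="cover")
        meta_cols = [c for c in ("x", "y", "date") if c in df.columns]
        plots = (
            df.groupby("plot_id")[meta_cols].first()
            if meta_cols
            else pd.DataFrame(index=wide.index)
        )
        plots = plots.reindex(wide.index)
    elif layout == "wide":
        df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
        plot_col = df.columns[0]
        df = df.set_index(plot_col)
        df.index = df.index.astype(str)
        if df.index.has_duplicates:
            raise ReleveValidationError(
                f"duplicate plot_ids: {df.index[df.index.duplicated()].tolist()}"
            )
        parsed = {c: _parse_cover_column(df[c], cover_mode) for c in df.columns}
        wide = pd.DataFrame(parsed, index=df.index)
        if (wide > 100).any().any():
            raise ReleveValidationError("cover > 100% in wide table")
        plots = pd.DataFrame(index=wide.index)
    else:
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")

    wide = wide.dropna(axis=1, how="all")
    _dedup_species(list(wide.columns))
    wide.index.name = "plot_id"
    wide.columns.name = "species"
    return ReleveSet(wide, plots, plot_area_m2=plot_area_m2)


def write_releves(rs: ReleveSet, path: str | Path, layout: str = "long") -> None:
    """Write a ReleveSet to CSV; ``read_releves`` round-trips it."""
    if layout == "long":
        long = rs.to_long()
        for c in ("x", "y", "date"):
            if c in rs.plots.columns:
                long[c] = long["plot_id"].map(rs.plots[c])
        long.to_csv(path, index=False)
    elif layout == "wide":
        out = rs.covers.copy()
        out.to_csv(path)
    else:
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")


@dataclass
class ReleveSummary:
    """Whole-set descriptive statistics (mean +- SD convention: sample SD)."""

    n_plots: int
    n_species: int
    richness_mean: float
    richness_sd: float
    richness_min: int
    richness_max: int
    cover_mean: float
    cover_sd: float
    cover_min: float
    cover_max: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def summarize_releves(rs: ReleveSet) -> ReleveSummary:
    """Species count plus per-plot richness and summed-cover statistics.

    SD uses the n-1 (sample) denominator.  Summed cover is reported as-is;
    values above 100 are possible for layered vegetation.
    """
    if rs.n_plots == 0:
        raise ReleveValidationError("empty ReleveSet")
    rich = rs.richness()
    cov = rs.total_cover()
    return ReleveSummary(
        n_plots=rs.n_plots,
        n_species=len(rs.species),
        richness_mean=float(rich.mean()),
        richness_sd=float(rich.std(ddof=1)) if rs.n_plots > 1 else float("nan"),
        richness_min=int(rich.min()),
        richness_max=int(rich.max()),
        cover_mean=float(cov.mean()),
        cover_sd=float(cov.std(ddof=1)) if rs.n_plots > 1 else float("nan"),
        cover_min=float(cov.min()),
        cover_max=float(cov.max()),
    )
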