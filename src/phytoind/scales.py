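"""Definitions of the ordinal indicator scales used throughout the package.

Two scale systems are supported: the 12-factor Didukh system of edaphic and
climatic ordinal scales (soil humidity Hd, moisture variability fH, aeration
Ae, acidity Rc, salt regime Sl, carbonate content Ca, nitrogen Nt, thermal
regime Tm, ombroregime Om, continentality Kn, cryoregime Cr, light Lc) and
the six classical Ellenberg scales (L, T, K, F, R, N).  Each scale is an
ordinal axis with a fixed number of gradations; species carry one optional
score per scale, plots carry community means of those scores.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ScaleDefinition:
    """One ordinal indicator scale.

    Attributes
    ----------
    scale_id : str
        Short symbol, e.g. ``"Hd"`` or (Ellenberg) ``"L"``.
    n_gradations : int
        Number of ordinal gradations; valid scores lie in ``[1, n_gradations]``.
    description : str
        What the scale indicates.
    system : str
        ``"didukh"`` or ``"ellenberg"``.
    """

    scale_id: str
    n_gradations: int
    description: str
    system: str

    def __post_init__(self) -> None:
        if self.n_gradations <= 0:
            raise ValueError(f"{self.scale_id}: n_gradations must be positive")

    def in_range(self, score: float) -> bool:
        return 1.0 <= score <= float(self.n_gradations)


DIDUKH_SCALES: dict[str, ScaleDefinition] = {
    s.scale_id: s
    for s in [
        ScaleDefinition("Hd", 23, "soil humidity regime", "didukh"),
        ScaleDefinition("fH", 12, "soil moisture variability", "didukh"),
        ScaleDefinition("Ae", 15, "soil aeration regime", "didukh"),
        ScaleDefinition("Rc", 15, "soil acidity regime", "didukh"),
        ScaleDefinition("Sl", 19, "soil salt regime", "didukh"),
        ScaleDefinition("Ca", 13, "soil carbonate content", "didukh"),
        ScaleDefinition("Nt", 11, "soil nitrogen content", "didukh"),
        ScaleDefinition("Tm", 17, "thermal regime", "didukh"),
        ScaleDefinition("Om", 23, "ombroregime (atmospheric humidity)", "didukh"),
        ScaleDefinition("Kn", 17, "climate continentality", "didukh"),
        ScaleDefinition("Cr", 15, "cryoregime (coldest-month severity)", "didukh"),
        ScaleDefinition("Lc", 9, "light regime", "didukh"),
    ]
}

ELLENBERG_SCALES: dict[str, ScaleDefinition] = {
    s.scale_id: s
    for s in [
        ScaleDefinition("L", 9, "Ellenberg light", "ellenberg"),
        ScaleDefinition("T", 9, "Ellenberg temperature", "ellenberg"),
        ScaleDefinition("K", 9, "Ellenberg continentality", "ellenberg"),
        ScaleDefinition("F", 12, "Ellenberg moisture", "ellenberg"),
        ScaleDefinition("R", 9, "Ellenberg reaction", "ellenberg"),
        ScaleDefinition("N", 9, "Ellenberg nutrients", "ellenberg"),
    ]
}

ALL_SCALES: dict[str, ScaleDefinition] = {**DIDUKH_SCALES, **ELLENBERG_SCALES}

#: Column name for the per-species hemeroby grade (7-grade ordinal scale,
#: 1 = ahemerobic ... 7 = metahemerobic).
HEMEROBY_COLUMN = "hemeroby_grade"
HEMEROBY_MIN, HEMEROBY_MAX = 1, 7


def get_scale(scale_id: str) -> ScaleDefinition:
    """Return the definition for ``scale_id`` or raise ``KeyError``."""
    try:
        return ALL_SCALES[scale_id]
    except KeyError:
        raise KeyError(
            f"unknown scale {scale_id!r}; known: {sorted(ALL_SCALES)}"
        ) from None
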