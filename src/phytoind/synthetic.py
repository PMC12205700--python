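"""Synthetic relevé, indicator-table and terrain generators.

The generators emulate the statistical structure a floodplain vegetation
survey hands to the analysis pipeline, so every stage is testable without
field data:

* a Gaussian niche model on three latent gradients (moisture — dominant,
  trophy, light).  Each association holds a niche optimum; its member
  species scatter around it.  Plots sample species with probability
  proportional to niche overlap, so community composition tracks the
  gradients the way relevé data do.
* species indicator scores on every ordinal scale are deterministic
  functions of the species' latent position plus noise, with signs chosen
  so that dry-end species also score high on moisture variability,
  aeration, thermal and continentality scales and low on ombroregime —
  the correlation structure a drawdown-affected floodplain shows.
* hemeroby grades are coupled to dryness (dry, open substrates are the
  disturbed ones), so hemeroby/naturalness recovery tests have signal.
* terrain grids are a flat base plus parameterised paraboloid depressions
  (floodplain-lake analogues) whose analytic volumes are retained as
  ground truth.

Default calibration targets the published survey statistics: 135 plots,
146 species, 12 associations, per-plot richness 12.1 +- 4.6 in [5, 28],
total projective cover about 50 +- 24 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .indicators import IndicatorTable
from .morphometry import TerrainGrid
from .releves import ReleveSet
from .scales import ALL_SCALES, HEMEROBY_COLUMN

# latent-position recipes per scale: value in [0,1] from (moisture mu,
# trophy tau, light lam); w0 is an intercept so mid-scale is reachable
_SCALE_RECIPES: dict[str, tuple[float, float, float, float]] = {
    # scale: (w0, w_mu, w_tau, w_lam); value01 = w0 + w_mu*mu + ...
    "Hd": (0.0, 1.0, 0.0, 0.0),
    "fH": (1.0, -1.0, 0.0, 0.0),
    "Ae": (1.0, -1.0, 0.0, 0.0),
    "Rc": (0.35, 0.0, 0.3, 0.0),
    "Sl": (0.2, -0.2, 0.5, 0.0),
    "Ca": (0.7, -0.6, 0.2, 0.0),
    "Nt": (0.05, 0.35, 0.6, 0.0),
    "Tm": (0.2, -0.6, 0.2, 0.0),
    "Om": (0.25, 0.7, 0.0, 0.0),
    "Kn": (0.25, -0.5, 0.0, 0.0),
    "Cr": (0.35, -0.3, 0.0, 0.0),
    "Lc": (0.1, -0.3, 0.0, 0.7),
    "L": (0.1, -0.3, 0.0, 0.7),
    "T": (0.2, -0.6, 0.2, 0.0),
    "K": (0.25, -0.5, 0.0, 0.0),
    "F": (0.0, 1.0, 0.0, 0.0),
    "R": (0.35, 0.0, 0.3, 0.0),
    "N": (0.05, 0.35, 0.6, 0.0),
}


@dataclass
class CommunityScenario:
    """Parameters of the synthetic survey.

    Defaults reproduce the reference survey's headline statistics (plots,
    species pool, richness and cover distributions, 12 associations along
    a dominant moisture gradient) and switch the dry <-> disturbed
    coupling on so hemeroby recovery has signal.
    """

    n_associations: int = 12
    n_plots: int = 135
    exclusive_per_association: int = 11
    n_generalists: int = 14
    richness_mean: float = 12.1
    richness_sd: float = 4.6
    richness_min: int = 5
    richness_max: int = 28
    cover_meanlog: float = 0.9
    cover_sdlog: float = 1.0
    niche_breadth: float = 0.05
    generalist_breadth: float = 0.20
    gradient_weights: tuple[float, float, float] = (1.0, 0.6, 0.4)
    plot_jitter: float = 0.02
    species_scatter: float = 0.02
    hemeroby_coupling: float = 0.8
    score_noise: float = 1.0
    indicators_per_association: int = 3
    seed: int = 1

    @property
    def n_species(self) -> int:
        return self.n_associations * self.exclusive_per_association + self.n_generalists

    def plots_per_association(self) -> list[int]:
        base, extra = divmod(self.n_plots, self.n_associations)
        return [base + (1 if a < extra else 0) for a in range(self.n_associations)]


@dataclass
class SyntheticCommunity:
    """Generator output: indicator table + species/association metadata."""

    table: IndicatorTable
    species_meta: pd.DataFrame  # index species: association, is_indicator, mu, tau, lam
    association_optima: pd.DataFrame  # index association id: mu, tau, lam, hemeroby_loc


def _association_optima(scn: CommunityScenario, rng: np.random.Generator) -> pd.DataFrame:
    ids = [f"A{a + 1:02d}" for a in range(scn.n_associations)]
    n = scn.n_associations
    mu = (np.arange(n) + 0.5) / n
    tau = rng.uniform(0.05, 0.95, n)
    lam = rng.uniform(0.05, 0.95, n)
    hem = 1.0 + 6.0 * (
        scn.hemeroby_coupling * (1.0 - mu)
        + (1.0 - scn.hemeroby_coupling) * rng.uniform(0, 1, scn.n_associations)
    )
    return pd.DataFrame(
        {"mu": mu, "tau": tau, "lam": lam, "hemeroby_loc": np.clip(hem, 1, 7)},
        index=pd.Index(ids, name="association"),
    )


def generate_indicator_table(
    scenario: CommunityScenario | None = None, seed: int | None = None
) -> SyntheticCommunity:
    """Draw a species pool with indicator scores and hemeroby grades.

    Species scores are drawn around their association's niche optima,
    truncated to scale ranges; hemeroby grades around the association's
    hemeroby location (rounded, clipped to [1, 7]).  Same seed => identical
    output.
    """
    scn = scenario or CommunityScenario()
    rng = np.random.default_rng(scn.seed if seed is None else seed)
    optima = _association_optima(scn, rng)

    rows = []
    for assoc, opt in optima.iterrows():
        for k in range(scn.exclusive_per_association):
            rows.append(
                {
                    "species": f"{assoc} species {k + 1:02d}",
                    "association": assoc,
                    "is_indicator": k < scn.indicators_per_association,
                    "mu": float(np.clip(opt.mu + rng.normal(0, scn.species_scatter), 0, 1)),
                    "tau": float(np.clip(opt.tau + rng.normal(0, scn.species_scatter), 0, 1)),
                    "lam": float(np.clip(opt.lam + rng.normal(0, scn.species_scatter), 0, 1)),
                    "breadth": scn.niche_breadth,
                }
            )
    for k in range(scn.n_generalists):
        rows.append(
            {
                "species": f"Generalist species {k + 1:02d}",
                "association": None,
                "is_indicator": False,
                "mu": float(rng.uniform(0, 1)),
                "tau": float(rng.uniform(0, 1)),
                "lam": float(rng.uniform(0, 1)),
                "breadth": scn.generalist_breadth,
            }
        )
    meta = pd.DataFrame(rows).set_index("species")

    data = pd.DataFrame(index=meta.index)
    for sid, (w0, wm, wt, wl) in _SCALE_RECIPES.items():
        g = ALL_SCALES[sid].n_gradations
        v = w0 + wm * meta["mu"] + wt * meta["tau"] + wl * meta["lam"]
        noise = rng.normal(0, scn.score_noise / max(g - 1, 1), len(meta))
        data[sid] = 1.0 + (g - 1) * np.clip(v + noise, 0.0, 1.0)

    hem_loc = meta["association"].map(optima["hemeroby_loc"])
    # generalists: hemeroby from their own dryness with the same coupling
    free = hem_loc.isna()
    hem_loc[free] = 1.0 + 6.0 * (
        scn.hemeroby_coupling * (1.0 - meta.loc[free, "mu"])
        + (1.0 - scn.hemeroby_coupling) * rng.uniform(0, 1, int(free.sum()))
    )
    grades = np.clip(
        np.round(hem_loc.astype(float) + rng.normal(0, 0.5, len(meta))), 1, 7
    )
    data[HEMEROBY_COLUMN] = grades

    table = IndicatorTable(data, tuple(_SCALE_RECIPES))
    return SyntheticCommunity(table, meta, optima)


def generate_releves(
    scenario: CommunityScenario | None = None,
    community: SyntheticCommunity | None = None,
    seed: int | None = None,
) -> tuple[ReleveSet, pd.Series]:
    """Sample plots from the niche model; returns (ReleveSet, true labels).

    Each plot draws a latent position near its association's optimum and
    samples its richness-many species without replacement with probability
    proportional to Gaussian niche overlap; covers are lognormal truncated
    to (0, 100].  Per-plot richness is resampled into the configured range.
    """
    scn = scenario or CommunityScenario()
    rng = np.random.default_rng((scn.seed if seed is None else seed) + 1)
    if community is None:
        community = generate_indicator_table(scn, seed=scn.seed if seed is None else seed)
    meta = community.species_meta
    optima = community.association_optima
    if scn.richness_min > scn.n_species:
        raise ValueError(
            f"richness_min {scn.richness_min} exceeds species pool {scn.n_species}"
        )

    pos = meta[["mu", "tau", "lam"]].to_numpy()
    breadth = meta["breadth"].to_numpy()
    gw = np.asarray(scn.gradient_weights)

    plot_rows = []
    labels = {}
    covers: dict[str, dict[str, float]] = {}
    counter = 0
    for assoc, n_plots_a in zip(optima.index, scn.plots_per_association()):
        opt = optima.loc[assoc, ["mu", "tau", "lam"]].to_numpy(dtype=float)
        for _ in range(n_plots_a):
            counter += 1
            pid = f"P{counter:03d}"
            labels[pid] = assoc
            x = np.clip(opt + rng.normal(0, scn.plot_jitter, 3), 0, 1)
            d2 = ((gw[None, :] * (pos - x[None, :]) ** 2).sum(axis=1)) / (
                2.0 * breadth**2
            )
            logw = -d2
            # richness resampled into range
            for _ in range(1000):
                k = int(round(rng.normal(scn.richness_mean, scn.richness_sd)))
                if scn.richness_min <= k <= scn.richness_max:
                    break
            else:
                raise ValueError("could not sample richness within configured range")
            # Gumbel top-k = weighted sampling without replacement
            keys = logw + rng.gumbel(0, 1, len(logw))
            chosen = np.argsort(keys)[::-1][:k]
            cov = np.exp(rng.normal(scn.cover_meanlog, scn.cover_sdlog, k))
            cov = np.clip(cov, 1e-3, 100.0)
            covers[pid] = {
                meta.index[j]: float(c) for j, c in zip(chosen, cov)
            }
            plot_rows.append({"plot_id": pid})

    wide = pd.DataFrame.from_dict(covers, orient="index").reindex(list(covers))
    wide = wide[[s for s in meta.index if s in wide.columns]]
    wide.index.name = "plot_id"
    wide.columns.name = "species"
    rs = ReleveSet(wide, pd.DataFrame(index=wide.index))
    return rs, pd.Series(labels, name="association")


def generate_terrain(
    nx: int = 50,
    ny: int = 50,
    n_depressions: int = 3,
    depth_range: tuple[float, float] = (2.0, 8.0),
    seed: int = 1,
    cell_size: float = 12.5,
    base_elevation: float = 20.0,
    radius_range_cells: tuple[float, float] = (5.0, 12.0),
) -> tuple[TerrainGrid, pd.DataFrame]:
    """Flat base surface plus non-overlapping paraboloid depressions.

    Returns (grid, depressions) where ``depressions`` holds per-depression
    centre, radius, depth and the closed-form volume below the rim plane
    (pi r^2 d / 2) as analytic ground truth for a water level at
    ``base_elevation``.
    """
    if nx < 10 or ny < 10:
        raise ValueError("grid dimensions must be >= 10")
    rng = np.random.default_rng(seed)
    z = np.full((ny, nx), base_elevation, dtype=float)
    yy, xx = np.mgrid[0:ny, 0:nx]

    placed: list[dict] = []
    attempts = 0
    while len(placed) < n_depressions and attempts < 1000:
        attempts += 1
        r_cells = rng.uniform(*radius_range_cells)
        cx = rng.uniform(r_cells + 1, nx - r_cells - 1)
        cy = rng.uniform(r_cells + 1, ny - r_cells - 1)
        if any(
            np.hypot(cx - p["cx_cells"], cy - p["cy_cells"])
            < r_cells + p["radius_cells"] + 1
            for p in placed
        ):
            continue
        depth = rng.uniform(*depth_range)
        rho2 = ((xx - cx) ** 2 + (yy - cy) ** 2) / r_cells**2
        z -= depth * np.clip(1.0 - rho2, 0.0, None)
        r_m = r_cells * cell_size
        placed.append(
            {
                "cx_cells": cx,
                "cy_cells": cy,
                "radius_cells": r_cells,
                "radius_m": r_m,
                "depth_m": depth,
                "analytic_volume_m3": np.pi * r_m**2 * depth / 2.0,
            }
        )
    if len(placed) < n_depressions:
        raise ValueError("could not place non-overlapping depressions; enlarge grid")
    grid = TerrainGrid(z, cell_size)
    return grid, pd.DataFrame(placed)
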