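"""End-to-end orchestration of the analysis stages.

``run_pipeline`` chains relevé ingest -> phytoindication -> hemeroby ->
TWINSPAN classification -> fidelity/synoptic table -> ordination (and
morphometry when a DEM and water-level scenarios are configured), writing
every intermediate artifact as plain CSV/JSON plus a run manifest (config
hash, package version, seed, per-stage row counts).  Identical config and
inputs produce byte-identical outputs; no stage mutates upstream artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .hemeroby import group_hemeroby_contrast, plot_hemeroby
from .indication import regimes_table
from .indicators import load_indicator_table
from .morphometry import change_table, measure_scenarios, read_ascii_grid
from .ordination import filter_significant_loadings, pca_environment, summarize_by_group
from .releves import read_releves, summarize_releves
from .twinspan import fidelity, make_pseudospecies, synoptic_table, twinspan

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_RUNTIME = 3


@dataclass
class PipelineConfig:
    """Validated pipeline settings; unknown keys are rejected at load."""

    releves_path: str = ""
    releves_layout: str = "long"
    indicator_path: str = ""
    dem_path: str | None = None
    output_dir: str = "output"
    weighting: str = "presence"
    min_species: int = 3
    cut_levels: tuple[float, ...] = (0.0, 2.0, 5.0, 10.0, 20.0)
    max_levels: int = 6
    min_group: int = 5
    min_eigenvalue: float = 0.45
    alpha: float = 0.05
    phi_threshold: float = 0.25
    natural_threshold: int = 3
    water_levels: dict[str, float] = field(default_factory=dict)
    change_pairs: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 1

    def __post_init__(self) -> None:
        if self.weighting not in ("presence", "cover"):
            raise ValueError(f"weighting must be presence|cover, got {self.weighting!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not -1 <= self.phi_threshold <= 1:
            raise ValueError("phi_threshold must be in [-1, 1]")
        if not 1 <= self.natural_threshold <= 6:
            raise ValueError("natural_threshold must be in [1, 6]")
        if self.min_species < 1 or self.min_group < 1 or self.max_levels < 0:
            raise ValueError("min_species, min_group >= 1 and max_levels >= 0")
        self.cut_levels = tuple(float(c) for c in self.cut_levels)
        self.change_pairs = [tuple(p) for p in self.change_pairs]

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def config_hash(self) -> str:
        settings = dataclasses.asdict(self)
        settings.pop("output_dir")  # where outputs land does not alter them
        payload = json.dumps(settings, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts
        logger.info("stage %s: %s", stage, counts)

    try:
        # 1. ingest
        rs = read_releves(config.releves_path, layout=config.releves_layout)
        table = load_indicator_table(config.indicator_path)
        summary = summarize_releves(rs)
        pd.DataFrame([summary.as_dict()]).to_csv(out / "releve_summary.csv", index=False)
        record("ingest", n_plots=rs.n_plots, n_species=len(rs.species))

        # 2. phytoindication
        regimes = regimes_table(rs, table, config.weighting, config.min_species)
        record("phytoindication", n_plots=len(regimes), n_columns=regimes.shape[1])

        # 3. hemeroby
        hem = plot_hemeroby(
            rs, table, config.weighting, config.natural_threshold, config.min_species
        )
        per_plot = regimes.join(hem.table[["hemeroby_index", "naturalness_index"]])
        per_plot.to_csv(out / "plot_regimes.csv", float_format="%.6g")
        record("hemeroby", n_plots=len(hem.table))

        # 4. classification
        psm = make_pseudospecies(rs, config.cut_levels)
        tree = twinspan(psm, config.max_levels, config.min_group, config.min_eigenvalue)
        groups = tree.terminal_groups()
        tree.to_json(out / "division_tree.json")
        groups.rename("group").to_csv(out / "plot_groups.csv")
        record(
            "classification",
            n_pseudospecies=psm.binary.shape[1],
            n_groups=tree.n_groups,
        )

        # 5. fidelity + synoptic table (needs >= 2 terminal groups)
        if groups.nunique() >= 2:
            fid = fidelity(rs, groups, equalize=True)
            fid.to_csv(out / "fidelity.csv", index=False, float_format="%.6g")
            pct, diag = synoptic_table(
                rs, groups, fid, config.alpha, config.phi_threshold
            )
            pct.join(diag).to_csv(out / "synoptic_table.csv", float_format="%.6g")
            record(
                "fidelity",
                n_entries=len(fid),
                n_diagnostic=int(diag["diagnostic"].sum()),
            )
        else:
            logger.warning("single terminal group; fidelity stage skipped")
            record("fidelity", skipped=True)

        # 6. ordination
        env = per_plot[
            [c for c in per_plot.columns if c in table.scale_set]
            + ["hemeroby_index", "naturalness_index"]
        ]
        res = pca_environment(env)
        eig = pd.DataFrame(
            {
                "eigenvalue": res.eigenvalues,
                "explained_pct": res.explained_pct,
            },
            index=res.loadings.columns,
        )
        eig.to_csv(out / "eigenvalues.csv", float_format="%.6g")
        masked = filter_significant_loadings(res, alpha=config.alpha)
        masked.to_csv(out / "loadings_significant.csv", float_format="%.4g")
        res.scores.to_csv(out / "pc_scores.csv", float_format="%.6g")
        summarize_by_group(env, groups).to_csv(
            out / "group_means.csv", float_format="%.6g"
        )
        if groups.nunique() >= 2:
            group_hemeroby_contrast(hem, groups).to_csv(
                out / "hemeroby_by_group.csv", float_format="%.6g"
            )
        record("ordination", retained=res.retained, n_plots=res.n_plots)

        # 7. morphometry (optional)
        if config.dem_path and config.water_levels:
            grid = read_ascii_grid(config.dem_path)
            measures = measure_scenarios(grid, config.water_levels)
            pd.DataFrame([m.as_dict() for m in measures]).to_csv(
                out / "morphometry.csv", index=False, float_format="%.10g"
            )
            if config.change_pairs:
                change_table(measures, config.change_pairs).to_csv(
                    out / "morphometry_changes.csv", float_format="%.1f"
                )
            record("morphometry", n_scenarios=len(measures))
        else:
            record("morphometry", skipped=True)

    except Exception as exc:  # annotate failing stage before re-raising
        done = ", ".join(manifest["stages"]) or "none"
        logger.error("pipeline aborted after stages [%s]: %s", done, exc)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
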