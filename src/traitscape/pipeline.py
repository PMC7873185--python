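"""End-to-end pipeline: generate -> metrics -> indices -> null models -> models.

A single :class:`RunConfig` drives every stage; each stage is also callable
on its own via the library API or the CLI verbs, so real survey/trait data
can replace the synthetic module at any point. Re-running with the same
config reproduces every CSV byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .functional import functional_index_table
from .io import write_ground_truth_yaml, write_map_csv, write_networks_geojson
from .landscape import predictor_correlations
from .nullmodels import NullAnalysisResult, run_null_analysis
from .response import render_group_table, run_response_stage
from .synth import (
    TAXA,
    TRAIT_SPECS_BY_TAXON,
    FilterSpec,
    SyntheticConfig,
    generate_study,
)

log = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Run-level knobs around a :class:`SyntheticConfig`."""

    synthetic: SyntheticConfig = dataclasses.field(default_factory=SyntheticConfig)
    n_null: int = 999
    alpha: float = 0.05
    delta_aicc: float = 2.0
    snap_tol: float = 0.5
    out_dir: str = "scratch/run"
    write_maps: bool = True

    def __post_init__(self) -> None:
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.delta_aicc <= 0 or self.snap_tol < 0:
            raise ValueError("thresholds must be positive")

    # -- YAML round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["filters"] = [
            dataclasses.asdict(f) for f in self.synthetic.filters
        ]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        syn = dict(d.pop("synthetic", {}))
        filters = tuple(FilterSpec(**f) for f in syn.pop("filters", []))
        for key in ("years", "grassland_to_crop", "hedgerow_loss",
                    "patch_seed_range", "grassland_share_range",
                    "hedgerow_density_range", "grassland_plots_range",
                    "hedgerow_sections_range"):
            if key in syn and isinstance(syn[key], list):
                syn[key] = tuple(syn[key])
        return cls(synthetic=SyntheticConfig(filters=filters, **syn), **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; return the run directory with tables + provenance.

    Aborting stages raise with the stage name; outputs are deterministic
    functions of the config (the synthetic seed covers all randomness).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    seed = config.synthetic.seed

    t0 = time.perf_counter()
    study = generate_study(config.synthetic, snap_tol=config.snap_tol)
    timings["simulate+metrics"] = time.perf_counter() - t0

    # --- emit stage inputs/outputs
    study.landscape_vars.to_csv(out / "landscape_variables.csv", index=False)
    corr_frames = []
    for year in config.synthetic.years:
        corr, flags = predictor_correlations(study.landscape_vars, year=year)
        for a, b, rho in flags:
            log.warning("year %s: |rho(%s, %s)| = %.2f above screen", year, a, b, rho)
        corr_frames.append(corr.assign(year=year))
    pd.concat(corr_frames).to_csv(out / "predictor_correlations.csv")
    if config.write_maps:
        maps_dir = out / "maps"
        maps_dir.mkdir(exist_ok=True)
        for (window, year), lu_map in sorted(study.series.maps.items()):
            write_map_csv(lu_map, maps_dir / f"{window}_{year}.csv")
        write_networks_geojson(study.series.networks, out / "hedgerows.geojson")
    for taxon in TAXA:
        study.surveys[taxon].to_csv(out / f"surveys_{taxon}.csv", index=False)
        study.pools[taxon].to_csv(out / f"pool_{taxon}.csv")
    write_ground_truth_yaml(config.synthetic, out / "ground_truth.yaml")

    # --- functional indices
    t0 = time.perf_counter()
    indices: dict[str, pd.DataFrame] = {}
    for taxon in TAXA:
        traits = list(TRAIT_SPECS_BY_TAXON[taxon])
        table = functional_index_table(study.surveys[taxon], study.pools[taxon], traits)
        table.insert(0, "group", taxon)
        indices[taxon] = table
    pd.concat(indices.values()).to_csv(out / "functional_indices.csv", index=False)
    timings["indices"] = time.perf_counter() - t0

    # --- null models + ES + classification
    t0 = time.perf_counter()
    null_results: dict[str, NullAnalysisResult] = {}
    for t_idx, taxon in enumerate(TAXA):
        null_results[taxon] = run_null_analysis(
            study.surveys[taxon],
            study.pools[taxon],
            list(TRAIT_SPECS_BY_TAXON[taxon]),
            n_null=config.n_null,
            seed=np.random.default_rng([seed, 23, t_idx]),
            alpha=config.alpha,
            group=taxon,
        )
        res = null_results[taxon]
        res.es_table.to_csv(out / f"effect_sizes_{taxon}.csv", index=False)
        res.classifications.to_csv(out / f"classification_{taxon}.csv", index=False)
        res.gating.to_csv(out / f"gating_{taxon}.csv", index=False)
    timings["null_models"] = time.perf_counter() - t0

    # --- landscape-response models
    t0 = time.perf_counter()
    results = run_response_stage(
        indices,
        null_results,
        study.landscape_vars,
        config.synthetic.years,
        delta_threshold=config.delta_aicc,
        normality_alpha=config.alpha,
    )
    results.to_csv(out / "response_models.csv", index=False)
    for taxon in TAXA:
        if (results["group"] == taxon).any():
            render_group_table(results, taxon).to_csv(out / f"table_{taxon}.csv")
    timings["response"] = time.perf_counter() - t0

    manifest = {
        "traitscape_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "config_hash": config.config_hash(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    config.to_yaml(out / "config.yaml")
    (out / "run.log").write_text(
        "".join(f"{stage}: {dt:.2f}s\n" for stage, dt in timings.items())
    )
    return out
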