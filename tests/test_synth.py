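"""Generator tests: pools, landscape series, community assembly."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import traitscape as ts
from traitscape.landscape import GRASSLAND, HEDGEROW
from traitscape.synth import (
    PLANT_TRAIT_SPECS,
    TRAIT_SPECS_BY_TAXON,
    FilterSpec,
    TraitDistributionSpec,
    assemble_communities,
    generate_landscape_series,
    generate_species_pool,
)


class TestSpeciesPool:
    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            TraitDistributionSpec("bad", 5, 1, 3, 1)
        with pytest.raises(ValueError):
            TraitDistributionSpec("bad", 1, 5, 3, 0)

    def test_discrete_lifespan_index_in_bounds(self):
        pool = generate_species_pool(PLANT_TRAIT_SPECS, 300, seed=1)
        assert set(np.unique(pool["lifespan_index"])) <= {1.0, 2.0, 3.0, 4.0}
        assert set(np.unique(pool["clonal_index"])) <= {1.0, 2.0, 3.0, 4.0, 5.0}

    def test_values_clipped_to_range(self):
        pool = generate_species_pool(TRAIT_SPECS_BY_TAXON["birds"], 500, seed=2)
        for name, spec in TRAIT_SPECS_BY_TAXON["birds"].items():
            assert pool[name].between(spec.minimum, spec.maximum).all()

    def test_degenerate_spread_collapses_to_mean(self):
        specs = {"t": TraitDistributionSpec("t", 0, 10, 4.0, 1e-9)}
        pool = generate_species_pool(specs, 2, seed=3)
        assert pool["t"].to_numpy() == pytest.approx([4.0, 4.0], abs=1e-6)

    def test_abundances_positive_and_normalised(self):
        pool = generate_species_pool(PLANT_TRAIT_SPECS, 173, seed=4)
        a = pool["regional_abundance"]
        assert (a > 0).all()
        assert a.sum() == pytest.approx(1.0)

    def test_seed_determinism(self):
        p1 = generate_species_pool(PLANT_TRAIT_SPECS, 50, seed=9)
        p2 = generate_species_pool(PLANT_TRAIT_SPECS, 50, seed=9)
        pd.testing.assert_frame_equal(p1, p2)

    def test_too_small_pool_rejected(self):
        with pytest.raises(ValueError):
            generate_species_pool(PLANT_TRAIT_SPECS, 1, seed=0)


class TestLandscapeSeries:
    def test_conservation_across_years(self, coarse_study):
        areas = {}
        for (w, y), m in coarse_study.series.maps.items():
            assert m.class_proportions().sum() == pytest.approx(1.0)
            areas.setdefault(w, set()).add(m.window_area)
        assert all(len(v) == 1 for v in areas.values())

    def test_no_change_limit_years_identical(self):
        cfg = ts.SyntheticConfig(
            seed=5, cell_size_m=20.0, grassland_to_crop=(0, 0), hedgerow_loss=(0, 0)
        )
        series = generate_landscape_series(cfg)
        for w in series.windows:
            first = series.maps[(w, cfg.years[0])].grid
            for y in cfg.years[1:]:
                assert np.array_equal(series.maps[(w, y)].grid, first)
                assert np.array_equal(
                    series.networks[(w, y)].segments,
                    series.networks[(w, cfg.years[0])].segments,
                )

    def test_full_conversion_removes_grassland(self):
        cfg = ts.SyntheticConfig(
            seed=6, cell_size_m=20.0, grassland_to_crop=(1.0, 1.0)
        )
        series = generate_landscape_series(cfg)
        for w in series.windows:
            final = series.maps[(w, cfg.years[-1])].grid
            assert (final != GRASSLAND).all()

    def test_half_hedgerow_loss_within_granularity(self):
        cfg = ts.SyntheticConfig(
            seed=7,
            cell_size_m=20.0,
            grassland_to_crop=(0.0, 0.0),
            hedgerow_loss=(0.5, 0.0),
            conversion_concentration=0.0,  # exact interval means
        )
        series = generate_landscape_series(cfg)
        for w in series.windows:
            before = ts.hedgerow_amount(series.networks[(w, cfg.years[0])])
            after = ts.hedgerow_amount(series.networks[(w, cfg.years[1])])
            if before < 10 * cfg.hedgerow_spacing_m:
                continue  # too few segments for the ratio to be meaningful
            # deletion granularity: one whole lattice segment
            assert abs(after - 0.5 * before) <= cfg.hedgerow_spacing_m

    def test_habitat_free_windows_counts(self, coarse_study):
        cfg = coarse_study.config
        lv = coarse_study.landscape_vars
        for year in cfg.years:
            sub = lv[lv["year"] == year]
            assert (sub["grassland_amount"] == 0).sum() == cfg.n_windows_without_grassland
            assert (sub["hedgerow_amount"] == 0).sum() == cfg.n_windows_without_hedgerow

    def test_monotone_loss_of_habitat(self, coarse_study):
        lv = coarse_study.landscape_vars.pivot_table(
            index="window", columns="year", values="hedgerow_amount"
        )
        y0, y1, y2 = coarse_study.config.years
        assert (lv[y1] <= lv[y0] + 1e-9).all()
        assert (lv[y2] <= lv[y1] + 1e-9).all()

    def test_cell_size_must_divide_window(self):
        with pytest.raises(ValueError):
            ts.SyntheticConfig(cell_size_m=300.0)

    def test_determinism(self):
        cfg = ts.SyntheticConfig(seed=8, cell_size_m=20.0)
        s1 = generate_landscape_series(cfg)
        s2 = generate_landscape_series(cfg)
        for key in s1.maps:
            assert np.array_equal(s1.maps[key].grid, s2.maps[key].grid)
            assert np.array_equal(s1.networks[key].segments, s2.networks[key].segments)


class TestAssembly:
    def test_counts_within_window_maximum(self, default_study):
        for taxon, surv in default_study.surveys.items():
            assert (surv["count"] >= 1).all()
            assert (surv["count"] <= surv["max_count"]).all()
            assert surv["species"].isin(default_study.pools[taxon].index).all()

    def test_empty_habitat_emits_no_surveys(self, default_study):
        lv = default_study.landscape_vars
        cur = lv[lv["year"] == "current"].set_index("window")
        no_grass = set(cur.index[cur["grassland_amount"] == 0])
        assert no_grass
        assert not (
            set(default_study.surveys["grassland_plants"]["window"]) & no_grass
        )
        no_hedge = set(cur.index[cur["hedgerow_amount"] == 0])
        assert not (
            set(default_study.surveys["hedgerow_plants"]["window"]) & no_hedge
        )

    def test_bird_surveys_cover_all_windows(self, default_study):
        surv = default_study.surveys["birds"]
        assert surv["window"].nunique() == default_study.config.n_windows
        assert (surv["max_count"] == default_study.config.bird_points).all()

    def test_unknown_filter_trait_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec("birds", "seed_mass", "grassland_amount", "current", 1.0)
        with pytest.raises(ValueError):
            FilterSpec("birds", "body_mass", "nonexistent", "current", 1.0)
        with pytest.raises(ValueError):
            FilterSpec("birds", "body_mass", "grassland_amount", "current", -1.0)

    def test_strong_filter_reduces_realized_trait_variance(self, default_study):
        """Gaussian filtering concentrates dominance: occurrence-weighted trait
        variance drops below its neutral-assembly value in >= 90% of windows."""
        from traitscape.functional import build_weights, cwv

        cfg = default_study.config
        lv = default_study.landscape_vars
        pools = default_study.pools
        filt_cfg = dataclasses.replace(
            cfg,
            filters=(
                FilterSpec(
                    "grassland_plants",
                    "flowering_onset",
                    "grassland_amount",
                    "current",
                    30.0,
                    target="both",
                ),
            ),
        )
        neutral = assemble_communities(
            pools, lv, cfg, rng=np.random.default_rng(1234)
        )["grassland_plants"]
        filtered = assemble_communities(
            pools, lv, filt_cfg, rng=np.random.default_rng(1234)
        )["grassland_plants"]
        v0 = cwv(
            build_weights(neutral, "occurrence_rate"),
            pools["grassland_plants"],
            "flowering_onset",
        )
        v1 = cwv(
            build_weights(filtered, "occurrence_rate"),
            pools["grassland_plants"],
            "flowering_onset",
        )
        common = v0.index.intersection(v1.index)
        frac = (v1.loc[common] < v0.loc[common]).mean()
        assert frac >= 0.9

    def test_assembly_determinism(self, default_study):
        cfg = default_study.config
        s1 = assemble_communities(
            default_study.pools,
            default_study.landscape_vars,
            cfg,
            rng=np.random.default_rng(5),
        )
        s2 = assemble_communities(
            default_study.pools,
            default_study.landscape_vars,
            cfg,
            rng=np.random.default_rng(5),
        )
        for taxon in s1:
            pd.testing.assert_frame_equal(s1[taxon], s2[taxon])
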